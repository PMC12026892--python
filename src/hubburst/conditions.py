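"""Reference study conditions for the four reporter genes in nuclear cycle 14.

The reporters are *snail* (``sna``, Dorsal target, ventral surface),
*short gastrulation* (``sog``, Dorsal target, lateral surface), and the
non-target *hunchback* imaged on the ventral (``hb_v``) and lateral
(``hb_l``) surfaces. The numbers below parameterize the synthetic generators
so each downstream stage can be exercised under the per-gene regime it is
meant to quantify: dwell-time mixtures for interaction classification,
peak cross-correlation lags for the lag analysis, and hub arrival/dwell
offsets for burst-hub linking.

Dwell mixtures list (short, mid, long) component means in minutes. The
short-lived component mean (0.3 min, roughly frame-scale transient contacts)
is a package default; spreads are set to 10% of each mean so the components
are well separated, which is the regime the mixture-recovery protocol assumes.
"""

from __future__ import annotations

from .config import DwellMixture

__all__ = [
    "GENES",
    "DWELL_NC14",
    "PEAK_LAG_NC14",
    "HUB_ARRIVAL_DWELL_NC14",
    "dwell_mixture_nc14",
]

GENES = ("sna", "sog", "hb_v", "hb_l")

#: (short, mid, long) dwell component means, minutes, nc14
_DWELL_MEANS = {
    "sna": (0.30, 1.35, 10.04),
    "sog": (0.30, 1.55, 5.39),
    "hb_v": (0.30, 0.90, 3.00),
    "hb_l": (0.30, 0.88, 2.77),
}

_DWELL_WEIGHTS = (0.45, 0.35, 0.20)


def dwell_mixture_nc14(gene: str) -> DwellMixture:
    """Well-separated three-component dwell mixture for one gene."""
    means = _DWELL_MEANS[gene]
    return DwellMixture(
        weights=_DWELL_WEIGHTS,
        means_min=means,
        sds_min=tuple(0.10 * m for m in means),
    )


DWELL_NC14 = {gene: dwell_mixture_nc14(gene) for gene in GENES}

#: peak cross-correlation lag (minutes) between MS2 and hub intensity, nc14;
#: positive lag = hub signal follows the MS2 signal
PEAK_LAG_NC14 = {"sna": 1.06, "sog": -1.81}

#: (arrival lead before non-first bursts, dwell after burst start), minutes
HUB_ARRIVAL_DWELL_NC14 = {
    "sna": (20.95, 23.16),
    "sog": (8.38, 13.02),
    "hb_v": (4.15, 4.99),
    "hb_l": (1.48, 4.40),
}
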