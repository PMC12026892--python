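"""Cohort aggregation and report rendering.

Aggregation is two-level: nuclei are first averaged within each embryo, then
embryos are averaged into the cohort, so the reported spread is the standard
deviation *between embryo replicates* (sd is omitted when fewer than two
embryos contribute). The mid-interphase window used for box-plot style
summaries is the middle third of the cycle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["aggregate", "mid_interphase_window", "render_report", "config_hash"]


def aggregate(
    table: pd.DataFrame,
    value_cols: Sequence[str],
    group_cols: Sequence[str] = ("frame",),
    embryo_col: str = "embryo_id",
) -> pd.DataFrame:
    """Nuclei -> embryo -> cohort aggregation.

    Input rows are per nucleus (or per nucleus-frame); rows are first meaned
    within ``embryo_col`` per group, then meaned across embryos. ``sd`` is the
    between-embryo standard deviation (ddof=1), NaN when a group has a single
    embryo; ``n`` counts contributing embryos. Result is invariant to the
    ordering of nuclei within an embryo.
    """
    if embryo_col not in table.columns:
        table = table.assign(**{embryo_col: 0})
    per_embryo = (
        table.groupby([*group_cols, embryo_col], sort=True)[list(value_cols)]
        .mean()
        .reset_index()
    )
    out = per_embryo.groupby(list(group_cols), sort=True)[list(value_cols)].agg(
        ["mean", "std", "count"]
    )
    out.columns = [f"{c}_{stat}" if stat != "count" else f"{c}_n"
                   for c, stat in out.columns]
    # sd is only meaningful between >= 2 embryo replicates
    for c in value_cols:
        out.loc[out[f"{c}_n"] < 2, f"{c}_std"] = np.nan
    return out.reset_index()


def mid_interphase_window(n_frames: int) -> Tuple[int, int]:
    """Middle third of the cycle, as an inclusive frame range."""
    lo = n_frames // 3
    hi = max(lo, (2 * n_frames) // 3 - 1)
    return lo, hi


def config_hash(config) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def render_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    cfg_hash: str = "",
    survival: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Dict[str, Path]:
    """Write summary tables, figures, and an HTML index.

    Deterministic: the same inputs produce byte-identical tables. An empty
    cohort produces a report with explicit "no data" placeholders rather
    than an error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    panels = []

    for name, frame in tables.items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        written[name] = p

    def _save(fig, name):
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[name] = p
        panels.append(name)

    if survival is not None and len(survival[0]):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.step(survival[0], survival[1], where="post")
        ax.set_xlabel("duration (min)")
        ax.set_ylabel("fraction of runs $\\geq$ t")
        ax.set_title("hub interaction survival")
        fig.tight_layout()
        _save(fig, "survival")

    tc = tables.get("interaction_timecourse")
    if tc is not None and len(tc):
        fig, ax = plt.subplots(figsize=(4, 3))
        mean_cols = [c for c in tc.columns if c.endswith("_mean")]
        for c in mean_cols:
            base = c[: -len("_mean")]
            ax.plot(tc["frame"], tc[c], label=base)
            sd = tc.get(f"{base}_std")
            if sd is not None:
                ax.fill_between(
                    tc["frame"], tc[c] - sd, tc[c] + sd, alpha=0.3
                )
        ax.set_xlabel("frame")
        ax.legend(fontsize=6)
        fig.tight_layout()
        _save(fig, "timecourse")

    bursts = tables.get("bursts")
    if bursts is not None and len(bursts) and "amplitude" in bursts.columns:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot([bursts["amplitude"].dropna()], tick_labels=["amplitude"])
        fig.tight_layout()
        _save(fig, "burst_amplitude")

    empty = all(len(t) == 0 for t in tables.values()) and survival is None
    manifest = {
        "config_hash": cfg_hash,
        "tables": sorted(k for k in tables),
        "figures": sorted(panels),
        "no_data": bool(empty),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = mpath

    rows = "".join(
        f"<li>{k}: {v.name}</li>" for k, v in sorted(written.items())
    )
    body = "<p>no data</p>" if empty else f"<ul>{rows}</ul>"
    (out_dir / "index.html").write_text(
        f"<html><body><h1>hubburst report</h1>"
        f"<p>config hash: {cfg_hash}</p>{body}</body></html>"
    )
    written["index"] = out_dir / "index.html"
    return written
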