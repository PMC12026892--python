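import logging

import numpy as np
import pytest

import hubburst as hb

logging.getLogger("hubburst").setLevel(logging.ERROR)

#: acquisition frame interval, minutes (11.56 s per volume)
DT_MIN = 11.56 / 60.0
#: (dz, dy, dx) voxel size, um
VOXEL_ZYX = (0.3, 0.104, 0.104)


@pytest.fixture(scope="session")
def dt_min() -> float:
    return DT_MIN


@pytest.fixture(scope="session")
def voxel_zyx():
    return VOXEL_ZYX


def grid_trapezoid_spec(dt: float, rise_frames=5, plateau_frames=15,
                        fall_frames=10, amplitude=100.0) -> hb.MS2Spec:
    """Burst spec whose trapezoid vertices all land on the frame grid, so
    amplitude/duration/output/loading rate have exact closed forms."""
    rise = rise_frames * dt
    return hb.MS2Spec(
        peak_amplitude=amplitude,
        loading_rate=amplitude / rise,
        plateau_min=plateau_frames * dt,
        decay_rate_per_min=1.0 / (fall_frames * dt),
        decay_shape="linear",
        inter_burst_interval_min=(rise_frames + plateau_frames + fall_frames + 10) * dt,
    )


@pytest.fixture(scope="session")
def tiny_movie():
    """Small two-channel movie with ground truth, shared across tests."""
    cfg = hb.SimulationConfig(
        seed=11,
        n_frames=10,
        nucleus=hb.NucleusSpec(count=2, drift_speed_um_per_min=0.2),
        hubs=hb.HubSpec(density_per_um3=0.25),
        ms2=hb.MS2Spec(
            first_burst_start_min=0.3,
            inter_burst_interval_min=3.0,
            peak_amplitude=4000.0,
            loading_rate=8000.0,
            plateau_min=0.5,
            decay_rate_per_min=4.0,
        ),
    )
    movie, truth = hb.simulate_embryo_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def tiny_movie_segmented(tiny_movie):
    from hubburst.nuclei import segment_nuclei_volume, track_nuclei

    cfg, movie, truth = tiny_movie
    vz = cfg.voxel_size_zyx
    labels4d = np.stack(
        [segment_nuclei_volume(movie[t, 0], voxel_size_zyx=vz)
         for t in range(cfg.n_frames)]
    )
    tracks = track_nuclei(list(labels4d), vz)
    return cfg, movie, truth, labels4d, tracks
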