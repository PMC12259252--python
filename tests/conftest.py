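import numpy as np
import pytest

from mccquant.synthetic import (AcquisitionSpec, FlowFieldSpec,
                                simulate_tracks, healthy_flow)


def separated_grid(n_cols: int, n_rows: int, acq: AcquisitionSpec,
                   margin: float = 4.0) -> np.ndarray:
    """Initial bead positions on a regular grid, guaranteeing a large
    minimum inter-bead distance for linking audits."""
    xs = np.linspace(margin, acq.field_width - margin, n_cols)
    ys = np.linspace(margin, acq.field_height - margin, n_rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@pytest.fixture
def noise_free_flow():
    return FlowFieldSpec(base_speed=5.0, base_direction=0.0,
                         angular_jitter_sd=0.0, patch_direction_sd=0.0,
                         diffusion_coeff=0.0, immobile_fraction=0.0)


@pytest.fixture
def noise_free_acq():
    return AcquisitionSpec(seed=0, n_frames=10, n_beads=20, dropout_prob=0.0,
                           localization_noise_sd=0.0, noise_sd=0.0)


@pytest.fixture
def small_truth():
    return simulate_tracks(healthy_flow(),
                           AcquisitionSpec(seed=11, n_frames=12, n_beads=60))
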