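"""Synthetic bead-transport recordings and morphometry fixtures.

The simulator produces ground-truthed data with the statistical structure the
downstream analysis assumes: beads advected by a patchwise flow field over a
ciliated surface, Brownian jitter, detection dropout, rendered time-lapse
frames, confocal-style z-stacks for cilia-height measurement, and epithelial
polyline traces with ciliated/non-ciliated labels.

Units: all geometry in micrometres (μm), time in seconds. Image coordinates
have the origin at the top-left corner with y increasing downward; the pixel
with index (row i, column j) covers [j*p, (j+1)*p) x [i*p, (i+1)*p) μm for
pixel size p, so its centre sits at ((j+0.5)*p, (i+0.5)*p).

All randomness flows from a single integer seed through named child
generators (motion, dropout, rendering), so each sub-process is
independently reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FlowFieldSpec",
    "AcquisitionSpec",
    "GroundTruthSet",
    "ZStackSim",
    "simulate_tracks",
    "render_frames",
    "simulate_zstack",
    "simulate_epithelial_trace",
    "save_stack",
    "load_stack",
    "healthy_flow",
    "injured_flow",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class FlowFieldSpec:
    """Ground-truth flow driving bead advection.

    The field is tiled into fixed square patches of side ``patch_size``; each
    patch carries its own flow direction drawn once around ``base_direction``
    with circular spread ``patch_direction_sd``. A coherent surface
    (``patch_direction_sd`` near 0) transports beads in straight, parallel
    paths; a damaged surface (large spread) produces erratic, inconsistent
    movement. ``immobile_fraction`` models beads stuck to the surface.
    """

    base_speed: float = 10.0          # μm/s
    base_direction: float = 0.0       # radians, CCW from +x
    angular_jitter_sd: float = 0.2    # radians, per-step direction noise
    patch_size: float = 20.0          # μm
    patch_direction_sd: float = 0.15  # radians, patch spread
    diffusion_coeff: float = 0.5      # μm²/s
    immobile_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("base_speed", "base_direction", "angular_jitter_sd",
                     "patch_size", "patch_direction_sd", "diffusion_coeff",
                     "immobile_fraction"):
            _require(math.isfinite(getattr(self, name)), name, "must be finite")
        _require(self.base_speed >= 0, "base_speed", "must be >= 0")
        _require(self.angular_jitter_sd >= 0, "angular_jitter_sd", "must be >= 0")
        _require(self.patch_size > 0, "patch_size", "must be > 0")
        _require(self.patch_direction_sd >= 0, "patch_direction_sd", "must be >= 0")
        _require(self.diffusion_coeff >= 0, "diffusion_coeff", "must be >= 0")
        _require(0.0 <= self.immobile_fraction <= 1.0,
                 "immobile_fraction", "must be in [0, 1]")


def healthy_flow(**overrides) -> FlowFieldSpec:
    """Coherent directional transport (intact ciliated surface)."""
    return FlowFieldSpec(**{**dict(base_speed=10.0, angular_jitter_sd=0.2,
                                   patch_direction_sd=0.15,
                                   diffusion_coeff=0.5,
                                   immobile_fraction=0.0), **overrides})


def injured_flow(**overrides) -> FlowFieldSpec:
    """Spatially heterogeneous, erratic transport (damaged surface)."""
    return FlowFieldSpec(**{**dict(base_speed=4.0, angular_jitter_sd=1.0,
                                   patch_direction_sd=2.0,
                                   diffusion_coeff=0.5,
                                   immobile_fraction=0.15), **overrides})


@dataclass(frozen=True)
class AcquisitionSpec:
    """Recording geometry and noise model.

    Defaults mirror the assay protocol: frames every 136 ms over a
    258.33 x 64.20 μm field with 300-600 beads in view. ``n_beads=None``
    draws the count uniformly from [300, 600].
    """

    frame_interval: float = 0.136     # s
    n_frames: int = 30
    field_width: float = 258.33       # μm
    field_height: float = 64.20       # μm
    n_beads: int | None = None
    dropout_prob: float = 0.05        # per bead per frame
    localization_noise_sd: float = 0.05  # μm
    pixel_size: float = 0.33          # μm/px
    psf_sigma: float = 0.5            # μm
    spot_peak: float = 200.0          # intensity units
    background_level: float = 100.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.n_frames >= 7, "n_frames",
                 "must be >= 7 so at least one full analysis window exists")
        _require(self.field_width > 0, "field_width", "must be > 0")
        _require(self.field_height > 0, "field_height", "must be > 0")
        if self.n_beads is not None:
            _require(self.n_beads >= 1, "n_beads", "must be >= 1")
        _require(0.0 <= self.dropout_prob < 1.0, "dropout_prob",
                 "must be in [0, 1)")
        _require(self.localization_noise_sd >= 0, "localization_noise_sd",
                 "must be >= 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.psf_sigma > 0, "psf_sigma", "must be > 0")


@dataclass
class GroundTruthSet:
    """True per-bead, per-frame positions and visibility.

    ``positions`` has shape (n_beads, n_frames, 2) in μm; ``visible`` marks
    detectable observations (inside the field, not censored, not dropped).
    Beads that leave the field are censored — invisible from first exit on.
    """

    positions: np.ndarray
    visible: np.ndarray
    flow: FlowFieldSpec
    acq: AcquisitionSpec

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n, t = self.positions.shape[:2]
        bead = np.repeat(np.arange(n), t)
        frame = np.tile(np.arange(t), n)
        return pd.DataFrame({
            "bead_id": bead,
            "frame": frame,
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
            "visible": self.visible.ravel().astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, flow: FlowFieldSpec | None = None,
                 acq: AcquisitionSpec | None = None) -> "GroundTruthSet":
        df = pd.read_csv(path)
        n = int(df["bead_id"].max()) + 1
        t = int(df["frame"].max()) + 1
        pos = np.zeros((n, t, 2))
        vis = np.zeros((n, t), dtype=bool)
        b = df["bead_id"].to_numpy()
        f = df["frame"].to_numpy()
        pos[b, f, 0] = df["x_um"].to_numpy()
        pos[b, f, 1] = df["y_um"].to_numpy()
        vis[b, f] = df["visible"].to_numpy().astype(bool)
        return cls(pos, vis, flow or FlowFieldSpec(), acq or AcquisitionSpec())

    def detections(self, localization_noise_sd: float | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Visible observations as a detection table (frame, x_um, y_um,
        intensity), optionally jittered by localization noise."""
        sd = (self.acq.localization_noise_sd
              if localization_noise_sd is None else localization_noise_sd)
        b, f = np.nonzero(self.visible)
        xy = self.positions[b, f].copy()
        if sd > 0:
            if rng is None:
                rng = np.random.default_rng(
                    np.random.SeedSequence(self.acq.seed).spawn(4)[3])
            xy += rng.normal(0.0, sd, size=xy.shape)
        df = pd.DataFrame({"frame": f, "x_um": xy[:, 0], "y_um": xy[:, 1],
                           "intensity": np.full(len(f), self.acq.spot_peak)})
        return df.sort_values(["frame", "intensity"],
                              ascending=[True, False]).reset_index(drop=True)


def _named_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    return {name: np.random.default_rng(c)
            for name, c in zip(("motion", "dropout", "render", "observe"),
                               children)}


def simulate_tracks(flow: FlowFieldSpec, acq: AcquisitionSpec,
                    init_positions: np.ndarray | None = None) -> GroundTruthSet:
    """Simulate bead trajectories under patchwise advection + diffusion.

    Per step: x_{t+1} = x_t + v(x_t)·Δt + η with η ~ N(0, 2·D·Δt·I) per axis;
    v has magnitude ``base_speed`` (zero for immobile beads) and direction
    equal to the local patch direction plus per-step angular jitter. Beads
    exiting the field are censored (invisible thereafter); visible beads are
    independently hidden with ``dropout_prob`` per frame.

    ``init_positions`` (n, 2) overrides the uniform initial placement, e.g.
    to build well-separated fields for linking audits.
    """
    rngs = _named_rngs(acq.seed)
    motion, dropout = rngs["motion"], rngs["dropout"]

    if init_positions is not None:
        init_positions = np.asarray(init_positions, dtype=float)
        n = init_positions.shape[0]
    elif acq.n_beads is not None:
        n = acq.n_beads
    else:
        n = int(motion.integers(300, 601))
    t_n, dt = acq.n_frames, acq.frame_interval
    w, h = acq.field_width, acq.field_height

    # patch grid with margin so beads briefly outside still see a direction
    margin = max(w, h)
    nx = int(np.ceil((w + 2 * margin) / flow.patch_size))
    ny = int(np.ceil((h + 2 * margin) / flow.patch_size))
    patch_dirs = motion.normal(flow.base_direction, flow.patch_direction_sd,
                               size=(ny, nx))
    if flow.patch_direction_sd == 0:
        patch_dirs = np.full((ny, nx), flow.base_direction)

    immobile = motion.random(n) < flow.immobile_fraction

    if init_positions is not None:
        pos0 = init_positions
    else:
        pos0 = np.column_stack([motion.uniform(0, w, n),
                                motion.uniform(0, h, n)])

    positions = np.empty((n, t_n, 2))
    positions[:, 0] = pos0
    step_sd = math.sqrt(2.0 * flow.diffusion_coeff * dt)

    for t in range(t_n - 1):
        p = positions[:, t]
        ix = np.clip(((p[:, 0] + margin) // flow.patch_size).astype(int), 0, nx - 1)
        iy = np.clip(((p[:, 1] + margin) // flow.patch_size).astype(int), 0, ny - 1)
        theta = patch_dirs[iy, ix]
        if flow.angular_jitter_sd > 0:
            theta = theta + motion.normal(0.0, flow.angular_jitter_sd, n)
        v = flow.base_speed * np.column_stack([np.cos(theta), np.sin(theta)])
        v[immobile] = 0.0
        eta = motion.normal(0.0, step_sd, (n, 2)) if step_sd > 0 else 0.0
        positions[:, t + 1] = p + v * dt + eta

    in_field = ((positions[:, :, 0] >= 0) & (positions[:, :, 0] <= w)
                & (positions[:, :, 1] >= 0) & (positions[:, :, 1] <= h))
    # censor: once a bead exits it stays invisible even if it re-enters
    censored_visible = np.logical_and.accumulate(in_field, axis=1)
    dropped = dropout.random((n, t_n)) < acq.dropout_prob
    visible = censored_visible & ~dropped
    return GroundTruthSet(positions, visible, flow, acq)


def render_frames(truth: GroundTruthSet) -> np.ndarray:
    """Render a time-lapse stack: one 2D image per frame, each visible bead an
    isotropic Gaussian spot of width ``psf_sigma``, plus background and
    Gaussian read noise. Returns float32 array (n_frames, H, W)."""
    acq = truth.acq
    rng = _named_rngs(acq.seed)["render"]
    px = acq.pixel_size
    W = int(acq.field_width // px)
    H = int(acq.field_height // px)
    sigma_px = acq.psf_sigma / px
    delta_mode = acq.psf_sigma < px
    if delta_mode:
        warnings.warn("psf_sigma smaller than one pixel; spots rendered on "
                      "the nearest pixel", stacklevel=2)
    stack = np.zeros((truth.n_frames, H, W), dtype=np.float64)
    r = max(1, int(np.ceil(4 * sigma_px)))
    for t in range(truth.n_frames):
        img = stack[t]
        for b in np.nonzero(truth.visible[:, t])[0]:
            x, y = truth.positions[b, t]
            cj, ci = x / px - 0.5, y / px - 0.5  # centre in index coords
            if delta_mode:
                j, i = int(round(cj)), int(round(ci))
                if 0 <= i < H and 0 <= j < W:
                    img[i, j] += acq.spot_peak
                continue
            j0, j1 = max(0, int(cj) - r), min(W, int(cj) + r + 2)
            i0, i1 = max(0, int(ci) - r), min(H, int(ci) + r + 2)
            if j0 >= j1 or i0 >= i1:
                continue
            jj = np.arange(j0, j1)
            ii = np.arange(i0, i1)
            gx = np.exp(-((jj - cj) ** 2) / (2 * sigma_px ** 2))
            gy = np.exp(-((ii - ci) ** 2) / (2 * sigma_px ** 2))
            img[i0:i1, j0:j1] += acq.spot_peak * np.outer(gy, gx)
    stack += acq.background_level
    if acq.noise_sd > 0:
        stack += rng.normal(0.0, acq.noise_sd, stack.shape)
    return stack.astype(np.float32)


def save_stack(path, stack: np.ndarray, pixel_size: float,
               z_step: float | None = None, **extra) -> None:
    """Write a multi-page TIFF carrying pixel-size (and optional z-step)
    metadata in the image description (JSON)."""
    meta = {"pixel_size_um": pixel_size, **extra}
    if z_step is not None:
        meta["z_step_um"] = z_step
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def load_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON metadata (pixel size, z-step)."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return stack, meta


@dataclass
class ZStackSim:
    """Synthetic two-channel confocal volume for cilia-height measurement.

    ``junction`` holds a tight-junction-marker channel concentrated at one
    z-plane per cell (the apical reference); ``cilia`` holds a cilia-marker
    channel occupying z from that plane up to the true cilia height. Shapes
    are (nz, ny, nx); ``labels`` (ny, nx) gives the per-cell footprint mask.
    """

    junction: np.ndarray
    cilia: np.ndarray
    labels: np.ndarray
    z_step: float
    pixel_size: float
    true_heights: np.ndarray          # μm, per cell (cell_id = index + 1)
    junction_z_index: np.ndarray
    sub_resolution: np.ndarray        # flagged where height < z_step


def simulate_zstack(n_cells: int, height_mean: float = 5.0,
                    height_sd: float = 1.0, z_step: float = 1.0,
                    seed: int = 0, n_z: int = 34, cell_px: int = 10,
                    pixel_size: float = 0.5) -> ZStackSim:
    """Generate a labelled z-stack with known per-cell cilia heights.

    Cells are square footprints tiled on a grid. Heights are drawn
    Normal(height_mean, height_sd), truncated to stay positive. Cells with
    height below one z-step are still generated and flagged sub-resolution.
    """
    _require(z_step > 0, "z_step", "must be > 0")
    _require(height_mean > 0, "height_mean", "must be > 0")
    _require(n_cells >= 1, "n_cells", "must be >= 1")
    rng = np.random.default_rng(seed)
    heights = rng.normal(height_mean, height_sd, n_cells)
    heights = np.abs(heights)
    heights[heights <= 0] = min(height_mean, z_step) / 2

    grid = int(np.ceil(np.sqrt(n_cells)))
    ny = nx = grid * cell_px
    labels = np.zeros((ny, nx), dtype=np.int32)
    junction_z = rng.integers(1, 4, n_cells)  # apical plane varies per cell
    junction = np.full((n_z, ny, nx), 100.0)
    cilia = np.full((n_z, ny, nx), 100.0)

    for c in range(n_cells):
        gy, gx = divmod(c, grid)
        sl = (slice(gy * cell_px, (gy + 1) * cell_px),
              slice(gx * cell_px, (gx + 1) * cell_px))
        labels[sl] = c + 1
        jz = int(junction_z[c])
        junction[jz][sl] += 1000.0
        top = min(n_z - 1, jz + int(np.floor(heights[c] / z_step)))
        for z in range(jz, top + 1):
            cilia[z][sl] += 800.0

    junction += rng.normal(0, 10.0, junction.shape)
    cilia += rng.normal(0, 10.0, cilia.shape)
    return ZStackSim(junction, cilia, labels, z_step, pixel_size,
                     heights, junction_z, heights < z_step)


def simulate_epithelial_trace(total_length: float, ciliated_fraction: float,
                              n_segments: int, seed: int = 0):
    """Polyline trace of an epithelial surface with per-segment ciliated
    labels whose length-weighted ciliated share matches ``ciliated_fraction``
    to within one segment's length (largest-remainder allocation on equal
    segments; which segments carry the label is randomized by ``seed``).

    Returns a :class:`mccquant.morphometry.EpithelialTrace`.
    """
    from .morphometry import EpithelialTrace

    _require(n_segments >= 1, "n_segments", "must be >= 1")
    _require(total_length > 0, "total_length", "must be > 0")
    _require(0.0 <= ciliated_fraction <= 1.0, "ciliated_fraction",
             "must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seg_len = total_length / n_segments
    # gently undulating path of equal-length straight segments
    angles = rng.normal(0.0, 0.15, n_segments)
    steps = seg_len * np.column_stack([np.cos(angles), np.sin(angles)])
    vertices = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    n_cil = int(np.floor(ciliated_fraction * n_segments + 0.5))
    flags = np.zeros(n_segments, dtype=bool)
    if n_cil > 0:
        flags[rng.choice(n_segments, size=n_cil, replace=False)] = True
    return EpithelialTrace(vertices=vertices, ciliated=flags)
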