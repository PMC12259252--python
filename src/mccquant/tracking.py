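"""Bead detection, frame-to-frame linking, and track selection.

Detection finds local maxima of a difference-of-Gaussians filtered frame that
exceed background by a robust-sd threshold, then refines each to sub-pixel
precision with an intensity-weighted centroid. Linking solves a gated linear
assignment problem between consecutive frames (global squared-displacement
minimum among pairs closer than ``max_disp``); there is no gap closing, so a
missed detection ends a track and a new identity begins afterwards.

Eligibility and selection implement the assay protocol: a track qualifies
for analysis when it spans at least ``min_intervals`` + 1 consecutive frames
(default 6 intervals = 7 frames = 0.816 s at 136 ms/frame), and 10 eligible
tracks are sampled uniformly at random per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .synthetic import load_stack

__all__ = [
    "Track",
    "SelectionSpec",
    "detect_beads",
    "link_detections",
    "eligible_tracks",
    "select_beads",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
    "read_trackmate_csv",
    "robust_sd",
]

_GATE_COST = 1e12


def robust_sd(values: np.ndarray) -> float:
    """Robust standard deviation via the scaled median absolute deviation."""
    v = np.asarray(values, dtype=float).ravel()
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


@dataclass
class Track:
    """One bead identity: detections over strictly consecutive frames."""

    track_id: int
    frames: np.ndarray                # int, gap-free arithmetic run, step 1
    xy: np.ndarray                    # (n, 2) μm
    intensity: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.intensity is None:
            self.intensity = np.zeros(len(self.frames))
        if len(self.frames) == 0:
            raise ValueError("track must contain at least one detection")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be consecutive (no gaps)")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SelectionSpec:
    """Track eligibility and random-selection parameters."""

    n_select: int = 10
    min_intervals: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select: must be >= 1")
        if self.min_intervals < 1:
            raise ValueError("min_intervals: must be >= 1")


def detect_beads(stack, threshold_sd: float = 5.0,
                 psf_sigma_hint: float = 0.5,
                 pixel_size: float | None = None) -> pd.DataFrame:
    """Localize bead spots in every frame of a time-lapse stack.

    ``stack`` is either an (n_frames, H, W) array (then ``pixel_size`` is
    required) or a path to a TIFF written by :func:`synthetic.save_stack`
    carrying pixel-size metadata. Detections are sub-pixel intensity-weighted
    centroids in μm, ordered per frame by descending intensity.
    """
    if isinstance(stack, (str, bytes)) or hasattr(stack, "__fspath__"):
        stack, meta = load_stack(stack)
        if "pixel_size_um" not in meta:
            raise ValueError("stack metadata missing required field "
                             "'pixel_size_um'")
        pixel_size = float(meta["pixel_size_um"])
    if pixel_size is None:
        raise ValueError("pixel_size must be provided for array input")
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    sigma_px = max(psf_sigma_hint / pixel_size, 0.5)
    win = int(np.ceil(sigma_px))
    rows = []
    for t, frame in enumerate(stack):
        dog = (ndimage.gaussian_filter(frame, sigma_px)
               - ndimage.gaussian_filter(frame, 2.5 * sigma_px))
        rsd = robust_sd(dog)
        if rsd == 0:
            rsd = np.finfo(float).tiny
        peaks = peak_local_max(dog, min_distance=max(1, int(round(sigma_px))),
                               threshold_abs=float(np.median(dog))
                               + threshold_sd * rsd, exclude_border=False)
        if len(peaks) == 0:
            continue
        bg_sub = frame - np.median(frame)
        H, W = frame.shape
        for i, j in peaks:
            i0, i1 = max(0, i - win), min(H, i + win + 1)
            j0, j1 = max(0, j - win), min(W, j + win + 1)
            patch = np.clip(bg_sub[i0:i1, j0:j1], 0, None)
            tot = patch.sum()
            if tot <= 0:
                continue
            ii, jj = np.mgrid[i0:i1, j0:j1]
            ci = float((patch * ii).sum() / tot)
            cj = float((patch * jj).sum() / tot)
            rows.append((t, (cj + 0.5) * pixel_size, (ci + 0.5) * pixel_size,
                         float(tot)))
    df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity"])
    return df.sort_values(["frame", "intensity"],
                          ascending=[True, False]).reset_index(drop=True)


def link_detections(detections: pd.DataFrame, max_disp: float) -> list[Track]:
    """Link detections across frames into gap-free tracks.

    Between each consecutive frame pair a one-to-one assignment minimizing
    total squared displacement is solved, with pairs farther than
    ``max_disp`` forbidden. Unmatched detections start new tracks; a track
    ends at the first frame with no match. Track ids are assigned in birth
    order, ties broken by descending intensity then ascending x.
    """
    if max_disp <= 0:
        raise ValueError("max_disp: must be > 0")
    if len(detections) == 0:
        return []
    det = detections.sort_values("frame").reset_index(drop=True)
    frames = det["frame"].to_numpy(dtype=int)
    xy = det[["x_um", "y_um"]].to_numpy(dtype=float)
    inten = (det["intensity"].to_numpy(dtype=float)
             if "intensity" in det else np.zeros(len(det)))

    by_frame = {f: np.nonzero(frames == f)[0] for f in np.unique(frames)}
    tracks: list[dict] = []           # each: {"rows": [det row indices]}
    active: list[int] = []            # indices into tracks with head at prev
    next_id = 0
    prev_frame = None

    for f in sorted(by_frame):
        cur = by_frame[f]
        matched_cur = np.zeros(len(cur), dtype=bool)
        if prev_frame is not None and f == prev_frame + 1 and active:
            heads = np.array([tracks[a]["rows"][-1] for a in active])
            d = np.linalg.norm(xy[heads][:, None, :] - xy[cur][None, :, :],
                               axis=2)
            cost = np.where(d <= max_disp, d ** 2, _GATE_COST)
            ri, ci = linear_sum_assignment(cost)
            new_active = []
            taken = set()
            for r, c in zip(ri, ci):
                if d[r, c] <= max_disp:
                    tracks[active[r]]["rows"].append(int(cur[c]))
                    new_active.append(active[r])
                    matched_cur[c] = True
                    taken.add(r)
            active = new_active
        else:
            active = []
        # births, ordered by descending intensity then ascending x
        unmatched = cur[~matched_cur]
        order = np.lexsort((xy[unmatched, 0], -inten[unmatched]))
        for row in unmatched[order]:
            tracks.append({"id": next_id, "rows": [int(row)]})
            active.append(len(tracks) - 1)
            next_id += 1
        prev_frame = f
    return [Track(t["id"], frames[t["rows"]], xy[t["rows"]],
                  inten[t["rows"]]) for t in tracks]


def _longest_run_length(frames: np.ndarray) -> int:
    if len(frames) == 0:
        return 0
    breaks = np.nonzero(np.diff(frames) != 1)[0]
    bounds = np.concatenate([[-1], breaks, [len(frames) - 1]])
    return int(np.max(np.diff(bounds)))


def eligible_tracks(tracks: list[Track],
                    spec: SelectionSpec = SelectionSpec()) -> list[Track]:
    """Tracks spanning at least ``min_intervals`` + 1 consecutive frames
    (default 7 frames = 6 intervals = 0.816 s at 136 ms/frame)."""
    need = spec.min_intervals + 1
    return [t for t in tracks if _longest_run_length(t.frames) >= need]


def select_beads(eligible: list[Track],
                 spec: SelectionSpec = SelectionSpec()) -> list[Track]:
    """Uniform random sample of ``n_select`` eligible tracks, seeded and
    deterministic; returned in ascending track-id order."""
    if len(eligible) < spec.n_select:
        raise ValueError(f"only {len(eligible)} eligible tracks available, "
                         f"need n_select={spec.n_select}")
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(eligible), size=spec.n_select, replace=False)
    chosen = [eligible[i] for i in idx]
    return sorted(chosen, key=lambda t: t.track_id)


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to (track_id, frame, x_um, y_um, intensity)."""
    rows = []
    for t in tracks:
        for k in range(len(t)):
            rows.append((t.track_id, int(t.frames[k]), t.xy[k, 0],
                         t.xy[k, 1], t.intensity[k]))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "intensity"])


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from a flat table; rows of one track_id whose
    frames contain gaps are split into separate gap-free tracks, with fresh
    ids assigned in order of appearance."""
    tracks: list[Track] = []
    next_id = 0
    for tid, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        frames = g["frame"].to_numpy(dtype=int)
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        inten = (g["intensity"].to_numpy(dtype=float)
                 if "intensity" in g else np.zeros(len(g)))
        breaks = np.nonzero(np.diff(frames) != 1)[0] + 1
        for seg in np.split(np.arange(len(frames)), breaks):
            tracks.append(Track(next_id, frames[seg], xy[seg], inten[seg]))
            next_id += 1
    return tracks


def read_trackmate_csv(path) -> pd.DataFrame:
    """Read a TrackMate-style spot/track export into the canonical flat
    layout (track_id, frame, x_um, y_um).

    Accepts plain single-header CSVs with columns TRACK_ID, FRAME,
    POSITION_X, POSITION_Y, as well as TrackMate 7 exports whose first rows
    repeat human-readable labels and units (non-numeric rows are dropped).
    """
    raw = pd.read_csv(path)
    cols = {c.strip().upper(): c for c in raw.columns}
    # native layout (track_id, frame, x_um, y_um) is accepted as-is
    aliases = {"POSITION_X": "X_UM", "POSITION_Y": "Y_UM"}
    for canon, alt in aliases.items():
        if canon not in cols and alt in cols:
            cols[canon] = cols[alt]
    required = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"TrackMate table missing columns: {missing}")
    df = raw[[cols[c] for c in required]].copy()
    df.columns = ["track_id", "frame", "x_um", "y_um"]
    df = df.apply(pd.to_numeric, errors="coerce").dropna()
    df["track_id"] = df["track_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)
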