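"""Transport statistics: traveling linearity and directional uniformity.

Both statistics are computed on a 7-frame (6-interval) analysis window per
bead. With frames every 136 ms the window spans 0.816 s.

Traveling linearity of one bead is α/β, where α is the net displacement from
the window's first to its last position and β the summed length of the six
consecutive steps; 1 means perfectly straight motion, values near 0 a
convoluted path. Directional uniformity of one recording is |Φ| / mean(|φ|),
where φ_i is bead i's window displacement vector and Φ the mean of the
(by default 10) φ vectors; 1 means all beads move in the same direction and
0 complete cancellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import Track, _longest_run_length

__all__ = [
    "TrackWindow",
    "RecordMetrics",
    "SampleMetrics",
    "make_window",
    "traveling_linearity",
    "directional_uniformity",
    "record_metrics",
    "aggregate_sample",
    "per_bead_table",
    "per_record_table",
    "per_animal_table",
    "WINDOW_INTERVALS",
    "WINDOW_FRAMES",
]

logger = logging.getLogger(__name__)

WINDOW_INTERVALS = 6
WINDOW_FRAMES = WINDOW_INTERVALS + 1
_ROUNDOFF = 1e-12


@dataclass(frozen=True)
class TrackWindow:
    """Seven consecutive positions (frames t = 0..6) of one bead."""

    positions: np.ndarray             # (7, 2) μm
    track_id: int = -1

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.shape != (WINDOW_FRAMES, 2):
            raise ValueError(f"window must hold exactly {WINDOW_FRAMES} "
                             f"positions, got shape {p.shape}")
        object.__setattr__(self, "positions", p)

    @property
    def alpha(self) -> float:
        """Net displacement |position(6) − position(0)| in μm."""
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    @property
    def beta(self) -> float:
        """Total path length: sum of the 6 consecutive step lengths, μm."""
        return float(np.linalg.norm(np.diff(self.positions, axis=0),
                                    axis=1).sum())

    @property
    def phi(self) -> np.ndarray:
        """Trajectory vector position(6) − position(0), μm; |φ| = α."""
        return self.positions[-1] - self.positions[0]


def make_window(track: Track) -> TrackWindow:
    """First 7 frames of the track's longest consecutive run.

    The earliest-window rule is deterministic and avoids biasing toward fast
    late segments of long tracks.
    """
    run = _longest_run_length(track.frames)
    if run < WINDOW_FRAMES:
        raise ValueError(f"track {track.track_id} has only {run} consecutive "
                         f"frames; {WINDOW_FRAMES} required")
    breaks = np.nonzero(np.diff(track.frames) != 1)[0]
    bounds = np.concatenate([[0], breaks + 1, [len(track.frames)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s >= WINDOW_FRAMES:
            return TrackWindow(track.xy[s:s + WINDOW_FRAMES], track.track_id)
    raise AssertionError("unreachable")


def traveling_linearity(w: TrackWindow) -> float:
    """α/β ∈ [0, 1]; undefined (raises) for a perfectly stationary bead."""
    beta = w.beta
    if beta == 0:
        raise ZeroDivisionError("beta = 0: stationary bead, linearity "
                                "undefined")
    lin = w.alpha / beta
    return float(min(lin, 1.0)) if lin <= 1.0 + _ROUNDOFF else lin


def directional_uniformity(phis) -> float:
    """|mean(φ)| / mean(|φ|) ∈ [0, 1] for a set of trajectory vectors."""
    phis = np.asarray(phis, dtype=float)
    if phis.ndim != 2 or phis.shape[0] == 0 or phis.shape[1] != 2:
        raise ValueError("phis must be a non-empty list of 2-vectors")
    norms = np.linalg.norm(phis, axis=1)
    denom = norms.mean()
    if denom == 0:
        raise ZeroDivisionError("all trajectory vectors are zero; "
                                "uniformity undefined")
    u = float(np.linalg.norm(phis.mean(axis=0)) / denom)
    # clip only representational round-off, never logic errors
    return min(u, 1.0) if u <= 1.0 + _ROUNDOFF else u


@dataclass
class RecordMetrics:
    """Per-recording statistics from the selected beads."""

    record_id: str
    linearities: np.ndarray           # per usable bead, in [0, 1]
    phis: np.ndarray                  # (n_used, 2) μm
    Phi: np.ndarray                   # mean trajectory vector, μm
    uniformity: float
    n_used: int
    n_excluded: int
    track_ids: list = field(default_factory=list)
    alphas: np.ndarray = field(default=None)
    betas: np.ndarray = field(default=None)


def record_metrics(tracks: list[Track], record_id: str = "record") -> RecordMetrics:
    """Compute per-bead linearities and the record's directional uniformity
    from the selected tracks. Stationary beads (β = 0, ratio undefined) are
    excluded from both statistics and the exclusion is logged."""
    linearities, phis, ids, alphas, betas = [], [], [], [], []
    n_excluded = 0
    for t in tracks:
        w = make_window(t)
        try:
            lin = traveling_linearity(w)
        except ZeroDivisionError:
            n_excluded += 1
            continue
        linearities.append(lin)
        phis.append(w.phi)
        ids.append(t.track_id)
        alphas.append(w.alpha)
        betas.append(w.beta)
    if n_excluded:
        logger.info("record %s: excluded %d stationary bead(s) (beta = 0)",
                    record_id, n_excluded)
    if len(linearities) < 2:
        raise ValueError(f"record {record_id}: only {len(linearities)} usable "
                         f"beads after excluding {n_excluded}; need >= 2")
    phis = np.asarray(phis)
    return RecordMetrics(record_id=record_id,
                         linearities=np.asarray(linearities),
                         phis=phis, Phi=phis.mean(axis=0),
                         uniformity=directional_uniformity(phis),
                         n_used=len(linearities), n_excluded=n_excluded,
                         track_ids=ids, alphas=np.asarray(alphas),
                         betas=np.asarray(betas))


@dataclass
class SampleMetrics:
    """Animal-level aggregation over (typically two) recordings."""

    animal_id: str
    records: list
    uniformity: float                 # unweighted mean over records
    linearities: np.ndarray           # pooled per-bead values

    @property
    def mean_linearity(self) -> float:
        return float(self.linearities.mean())


def aggregate_sample(records: list[RecordMetrics],
                     animal_id: str = "animal") -> SampleMetrics:
    """Animal uniformity = unweighted mean of record uniformities;
    linearities pooled across records."""
    if len(records) == 0:
        raise ValueError("at least one record required")
    return SampleMetrics(
        animal_id=animal_id,
        records=list(records),
        uniformity=float(np.mean([r.uniformity for r in records])),
        linearities=np.concatenate([r.linearities for r in records]),
    )


def per_bead_table(samples: list[SampleMetrics],
                   group: str | None = None) -> pd.DataFrame:
    rows = []
    for s in samples:
        for r in s.records:
            for tid, lin, a, b in zip(r.track_ids, r.linearities,
                                      r.alphas, r.betas):
                rows.append((group, s.animal_id, r.record_id, tid, a, b, lin))
    df = pd.DataFrame(rows, columns=["group", "animal_id", "record_id",
                                     "track_id", "alpha_um", "beta_um",
                                     "linearity"])
    return df.drop(columns=["group"]) if group is None else df


def per_record_table(samples: list[SampleMetrics],
                     group: str | None = None) -> pd.DataFrame:
    rows = []
    for s in samples:
        for r in s.records:
            rows.append((group, s.animal_id, r.record_id, r.uniformity,
                         float(r.linearities.mean()), r.n_used, r.n_excluded))
    df = pd.DataFrame(rows, columns=["group", "animal_id", "record_id",
                                     "directional_uniformity",
                                     "mean_linearity", "n_used", "n_excluded"])
    return df.drop(columns=["group"]) if group is None else df


def per_animal_table(samples: list[SampleMetrics],
                     group: str | None = None) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append((group, s.animal_id, s.uniformity, s.mean_linearity,
                     len(s.records), len(s.linearities)))
    df = pd.DataFrame(rows, columns=["group", "animal_id",
                                     "directional_uniformity",
                                     "mean_linearity", "n_records", "n_beads"])
    return df.drop(columns=["group"]) if group is None else df
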