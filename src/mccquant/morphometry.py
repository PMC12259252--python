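"""Confocal morphometry: cilia height, ciliated surface, positive areas.

Implements the measurement procedures used on fixed tissue and air-liquid
interface (ALI) cultures:

* per-cell cilia height from a two-channel z-stack, measured from the
  tight-junction (ZO-1) reference plane to the top of the cilia-marker
  (acetylated α-tubulin) signal;
* ciliated-surface percentage along a traced epithelial polyline;
* positive-area percentage on merged z-projection images (e.g. acrolein
  adducts);
* positive-cell density normalized to a 200 × 200 μm (40,000 μm²) reference
  region (e.g. CellROX / LipiRADICAL counts);
* total flux inside rectangular regions of interest for whole-animal
  fluorescence imaging.

Intensity thresholds are expressed as robust-sd offsets above background
(median / scaled-MAD), so they are invariant to absolute grayscale level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import robust_sd
from .synthetic import load_stack

__all__ = [
    "EpithelialTrace",
    "ProjectionImage",
    "RectROI",
    "REFERENCE_AREA_UM2",
    "REFERENCE_SIDE_UM",
    "ciliated_fraction",
    "cilia_heights",
    "positive_area_fraction",
    "positive_cell_density",
    "roi_total_flux",
    "roi_flux_table",
]

REFERENCE_SIDE_UM = 200.0
REFERENCE_AREA_UM2 = REFERENCE_SIDE_UM ** 2  # 40,000 μm²


@dataclass
class EpithelialTrace:
    """Polyline trace of an epithelial surface with per-segment ciliated
    labels. ``vertices`` is (n+1, 2) μm; ``ciliated`` is (n,) bool."""

    vertices: np.ndarray
    ciliated: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.ciliated = np.asarray(self.ciliated, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n+1, 2) array")
        if len(self.ciliated) != len(self.vertices) - 1:
            raise ValueError("need one ciliated flag per segment")
        if len(self.ciliated) < 1:
            raise ValueError("trace must contain at least one segment")
        if np.any(self.segment_lengths() <= 0):
            raise ValueError("all segment lengths must be > 0")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Vertex table (x_um, y_um, ciliated_flag); the flag on row i labels
        the segment starting at vertex i (last row repeats the final flag)."""
        flags = np.append(self.ciliated, self.ciliated[-1]).astype(int)
        return pd.DataFrame({"x_um": self.vertices[:, 0],
                             "y_um": self.vertices[:, 1],
                             "ciliated_flag": flags})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpithelialTrace":
        df = pd.read_csv(path)
        verts = df[["x_um", "y_um"]].to_numpy()
        flags = df["ciliated_flag"].to_numpy().astype(bool)[:-1]
        return cls(vertices=verts, ciliated=flags)


@dataclass
class ProjectionImage:
    """Merged grayscale z-projection with pixel-size metadata."""

    image: np.ndarray
    pixel_size: float                 # μm/px
    n_sections: int = 1               # z-sections merged

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if np.any(self.image < 0):
            raise ValueError("projection intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def ciliated_fraction(trace: EpithelialTrace) -> float:
    """Percentage of the traced epithelial length covered by ciliated
    segments: 100 x (ciliated length) / (total length)."""
    lengths = trace.segment_lengths()
    total = lengths.sum()
    if total == 0:
        raise ValueError("trace has zero total length")
    return 100.0 * float(lengths[trace.ciliated].sum() / total)


def _background_threshold(values: np.ndarray, threshold_sd: float) -> float:
    """Background + threshold_sd robust sd, with background estimated from
    the lower half of the intensity distribution so that large positive
    regions do not inflate the estimate."""
    v = np.asarray(values, dtype=float).ravel()
    lower = v[v <= np.median(v)]
    bg = float(np.median(lower))
    rsd = robust_sd(lower)
    return bg + threshold_sd * rsd


def cilia_heights(junction: np.ndarray, cilia: np.ndarray,
                  labels: np.ndarray, z_step: float | None = None,
                  intensity_threshold_sd: float = 5.0,
                  volume_path=None) -> pd.DataFrame:
    """Per-cell cilia height from a two-channel z-stack.

    For each labelled cell footprint, the junction reference plane is the z
    with maximal junction-channel signal, and the cilia top is the highest z
    whose cilia-channel signal inside the footprint exceeds background by
    ``intensity_threshold_sd`` robust sd. Height is their difference in μm
    (never negative); cells with no supra-threshold cilia signal get height
    0 and ``flagged`` True.

    ``volume_path`` may name a TIFF written with z-step metadata holding
    both channels stacked as (2, nz, ny, nx); its absence of a z-step is an
    error.
    """
    if volume_path is not None:
        vol, meta = load_stack(volume_path)
        if "z_step_um" not in meta:
            raise ValueError("volume metadata missing required field "
                             "'z_step_um'")
        z_step = float(meta["z_step_um"])
        junction, cilia = vol[0], vol[1]
    if z_step is None:
        raise ValueError("z_step must be provided for array input")
    junction = np.asarray(junction, dtype=float)
    cilia = np.asarray(cilia, dtype=float)
    labels = np.asarray(labels)
    # cilia voxels are a sparse minority of the volume, so plain median/MAD
    # over all voxels is a sound background estimate here
    threshold = (float(np.median(cilia))
                 + intensity_threshold_sd * robust_sd(cilia))

    rows = []
    for cell_id in np.unique(labels):
        if cell_id == 0:
            continue
        mask = labels == cell_id
        jz = int(np.argmax(junction[:, mask].sum(axis=1)))
        supra = np.nonzero(cilia[:, mask].max(axis=1) > threshold)[0]
        supra = supra[supra >= jz]
        if len(supra) == 0:
            top, height, flagged = jz, 0.0, True
        else:
            top = int(supra.max())
            height = (top - jz) * z_step
            flagged = False
        rows.append((int(cell_id), jz * z_step, top * z_step, height, flagged))
    return pd.DataFrame(rows, columns=["cell_id", "junction_z_um",
                                       "cilia_top_z_um", "height_um",
                                       "flagged"])


def positive_area_fraction(img: ProjectionImage | np.ndarray,
                           threshold_sd: float = 5.0) -> float:
    """Percentage of pixels above background + ``threshold_sd`` robust sd.

    A constant image has no definable background spread; it returns 0% with
    a warning.
    """
    arr = img.image if isinstance(img, ProjectionImage) else np.asarray(img,
                                                                        dtype=float)
    if np.ptp(arr) == 0:
        warnings.warn("constant image: positive area undefined, returning 0%",
                      stacklevel=2)
        return 0.0
    threshold = _background_threshold(arr, threshold_sd)
    return 100.0 * float(np.mean(arr > threshold))


def positive_cell_density(count: float, region_side: float) -> float:
    """Scale a cell count in a square region of side ``region_side`` μm to
    the 200 × 200 μm (40,000 μm²) reference area."""
    if region_side <= 0:
        raise ValueError("region_side must be > 0")
    return count * REFERENCE_AREA_UM2 / region_side ** 2


@dataclass(frozen=True)
class RectROI:
    """Rectangular region of interest in pixel coordinates."""

    row: int
    col: int
    height: int
    width: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def roi_total_flux(image: np.ndarray, roi: RectROI) -> float:
    """Summed intensity inside a rectangular ROI."""
    image = np.asarray(image, dtype=float)
    if roi.height <= 0 or roi.width <= 0:
        raise ValueError("ROI has zero area")
    if (roi.row < 0 or roi.col < 0 or roi.row + roi.height > image.shape[0]
            or roi.col + roi.width > image.shape[1]):
        raise ValueError("ROI extends outside the image")
    return float(image[roi.row:roi.row + roi.height,
                       roi.col:roi.col + roi.width].sum())


def roi_flux_table(images: list[np.ndarray], rois: list[RectROI],
                   labels: list[str] | None = None) -> pd.DataFrame:
    """Total flux for a comparison set; all ROIs must share one size."""
    shapes = {r.shape for r in rois}
    if len(shapes) > 1:
        raise ValueError(f"ROIs in a comparison set must have identical "
                         f"dimensions, got {sorted(shapes)}")
    labels = labels or [f"image_{i}" for i in range(len(images))]
    return pd.DataFrame({
        "label": labels,
        "total_flux": [roi_total_flux(im, r) for im, r in zip(images, rois)],
    })
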