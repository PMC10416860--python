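"""Biomarker morphometry: turn binary masks into the crisp features the
fuzzy engine consumes.

All coordinates are raster convention (row 0 at the top, rows increase
downward). Anatomically, a smaller row index is *higher* in the retina, so
an HRF whose centroid row is strictly less than the OPL upper-boundary row
at its column lies above the OPL; ties count as within-or-below, which is
the conservative (higher-severity) reading.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

__all__ = [
    "OPLBoundary",
    "HRFFeature",
    "CystoidFeature",
    "BiomarkerFeatures",
    "extract_components",
    "opl_upper_boundary",
    "hrf_positions",
    "cystoid_parameters",
    "aggregate_features",
]

ABOVE_OPL = "above_opl"
WITHIN_OR_BELOW_OPL = "within_or_below_opl"


def _check_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return mask.astype(np.uint8)


@dataclass
class OPLBoundary:
    """Per-column row of the OPL upper edge; interpolated where absent."""

    rows: np.ndarray  # float, length = image width
    valid: np.ndarray  # bool, True where the mask itself had OPL pixels


@dataclass
class HRFFeature:
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    position: str  # ABOVE_OPL | WITHIN_OR_BELOW_OPL


@dataclass
class CystoidFeature:
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    h_diameter_um: float
    v_diameter_um: float


@dataclass
class BiomarkerFeatures:
    """Crisp input vector for severity grading."""

    dril_present: bool = False
    dril_central: bool = False
    dril_extent_um: float | None = None
    n_hrf_above: int = 0
    n_hrf_within_below: int = 0
    cystoid_count: int = 0
    total_cystoid_area_um2: float = 0.0
    max_h_diameter_um: float = 0.0
    max_v_diameter_um: float = 0.0
    um_per_px: float = 11.7

    def __post_init__(self):
        if self.dril_central and not self.dril_present:
            raise ValueError("dril_central requires dril_present")
        if min(self.n_hrf_above, self.n_hrf_within_below, self.cystoid_count) < 0:
            raise ValueError("counts must be nonnegative")
        if self.cystoid_count == 0 and (self.max_h_diameter_um or self.max_v_diameter_um):
            raise ValueError("diameters must be 0 when there are no cystoids")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "BiomarkerFeatures":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def extract_components(mask: np.ndarray, min_component_area: int = 3):
    """8-connected components of area >= ``min_component_area``.

    Returns a list of (centroid (row, col), area_px, pixel-index arrays),
    sorted by centroid column then row.
    """
    mask = _check_binary(mask)
    labelled = measure.label(mask, connectivity=2)
    comps = []
    for region in measure.regionprops(labelled):
        if region.area < min_component_area:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        comps.append(((float(region.centroid[0]), float(region.centroid[1])), int(region.area), (rr, cc)))
    comps.sort(key=lambda t: (t[0][1], t[0][0]))
    return comps


def opl_upper_boundary(opl_mask: np.ndarray) -> OPLBoundary:
    """Per-column minimum row of the OPL mask, linearly interpolated over
    gaps and extended by the nearest valid value at the edges."""
    mask = _check_binary(opl_mask, "opl_mask")
    valid = mask.any(axis=0)
    if not valid.any():
        raise ValueError("OPL mask is empty; no boundary can be derived")
    h, w = mask.shape
    first_row = np.where(valid, np.argmax(mask, axis=0), 0).astype(float)
    cols = np.arange(w)
    rows = np.interp(cols, cols[valid], first_row[valid])
    return OPLBoundary(rows=rows, valid=valid)


def hrf_positions(hrf_components, boundary: OPLBoundary) -> list[HRFFeature]:
    """Classify each HRF component as above vs within/below the OPL."""
    feats = []
    for centroid, area, _pixels in hrf_components:
        col = int(round(centroid[1]))
        col = min(max(col, 0), len(boundary.rows) - 1)
        pos = ABOVE_OPL if centroid[0] < boundary.rows[col] else WITHIN_OR_BELOW_OPL
        feats.append(HRFFeature(centroid=centroid, area_px=area, position=pos))
    return feats


def cystoid_parameters(
    cystoid_mask: np.ndarray, um_per_px: float, min_component_area: int = 3
) -> list[CystoidFeature]:
    """Count, area and axis-aligned bounding-box diameters of each cystoid.

    The bounding rectangle is axis-aligned so its width and height are the
    horizontal and vertical diameters; area is the component pixel count.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    mask = _check_binary(cystoid_mask, "cystoid_mask")
    feats = []
    for centroid, area, (rr, cc) in extract_components(mask, min_component_area):
        h_px = int(cc.max() - cc.min() + 1)
        v_px = int(rr.max() - rr.min() + 1)
        feats.append(
            CystoidFeature(
                centroid=centroid,
                area_px=area,
                area_um2=area * um_per_px**2,
                h_diameter_um=h_px * um_per_px,
                v_diameter_um=v_px * um_per_px,
            )
        )
    return feats


def aggregate_features(
    dril_label: str,
    dril_centrality: str | None,
    hrf_feats: list[HRFFeature],
    cystoid_feats: list[CystoidFeature],
    um_per_px: float,
    dril_extent_um: float | None = None,
) -> BiomarkerFeatures:
    """Fold per-lesion features into the engine's crisp input vector."""
    if dril_label not in ("normal", "dril"):
        raise ValueError(f"unknown dril_label {dril_label!r}")
    if dril_label == "normal" and dril_centrality not in (None, "n/a"):
        raise ValueError("dril_centrality given for a normal scan")
    return BiomarkerFeatures(
        dril_present=dril_label == "dril",
        dril_central=dril_label == "dril" and dril_centrality == "central",
        dril_extent_um=dril_extent_um,
        n_hrf_above=sum(1 for f in hrf_feats if f.position == ABOVE_OPL),
        n_hrf_within_below=sum(1 for f in hrf_feats if f.position == WITHIN_OR_BELOW_OPL),
        cystoid_count=len(cystoid_feats),
        total_cystoid_area_um2=float(sum(f.area_um2 for f in cystoid_feats)),
        max_h_diameter_um=max((f.h_diameter_um for f in cystoid_feats), default=0.0),
        max_v_diameter_um=max((f.v_diameter_um for f in cystoid_feats), default=0.0),
        um_per_px=um_per_px,
    )
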