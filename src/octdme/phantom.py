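"""Synthetic OCT B-scan phantoms with paired ground truth.

A phantom is a horizontally layered retina on a dark vitreous background:
a foveal depression in the inner surface, five bands (GCL-IPL, INL, OPL,
ONL, RPE) of alternating reflectivity, and three lesion families —

* DRIL: local erasure of the inner-layer banding over a column interval,
* HRF: small bright disks,
* cystoid spaces: dark ellipses inside the retinal band,

plus multiplicative speckle-like noise. Every phantom carries its masks and
a ground-truth biomarker record, so all downstream stages can be exercised
and scored without clinical data. Generation is a pure function of the spec
(including its seed): the same spec always yields the same bundle.

Coordinates are raster convention: row 0 at the top, rows increase downward.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .features import BiomarkerFeatures

__all__ = [
    "PhantomGeometryError",
    "PhantomSpec",
    "PhantomBundle",
    "default_phantom_spec",
    "generate_phantom",
    "generate_dataset",
    "save_dataset",
    "spec_to_yaml",
    "spec_from_yaml",
]

# band reflectivities, top to bottom
_VITREOUS = 0.05
_BAND_LEVELS = (0.60, 0.30, 0.62, 0.22, 0.85)  # GCL-IPL, INL, OPL, ONL, RPE
_BELOW_RPE = 0.10
_HRF_LEVEL = 0.92
_CYST_LEVEL = 0.08

_OPL_BAND = 2  # index of the OPL within _BAND_LEVELS / layer_depths


class PhantomGeometryError(ValueError):
    """Raised when a lesion or layer specification does not fit the image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Complete geometric description of one phantom.

    ``layer_depths`` are cumulative row offsets from the inner retinal
    surface to the bottom of each band (GCL-IPL, INL, OPL, ONL, RPE).
    ``um_per_px`` is the isotropic pixel pitch in micrometres.
    """

    height_px: int = 192
    width_px: int = 192
    um_per_px: float = 11.7
    fovea_col: int = 96
    surface_row: int = 38
    layer_depths: tuple[int, ...] = (36, 56, 71, 108, 121)
    fovea_depth_px: int = 40
    fovea_sigma_px: float = 18.0
    dril_region: tuple[int, int] | None = None
    hrf_list: tuple[tuple[int, int, int], ...] = ()
    cystoid_list: tuple[tuple[int, int, int, int], ...] = ()
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.height_px <= 0 or self.width_px <= 0:
            raise PhantomGeometryError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise PhantomGeometryError("um_per_px must be positive")
        if not 0 <= self.fovea_col < self.width_px:
            raise PhantomGeometryError("fovea_col outside image")
        if list(self.layer_depths) != sorted(self.layer_depths) or len(self.layer_depths) != 5:
            raise PhantomGeometryError("layer_depths must be 5 nondecreasing offsets")
        if self.surface_row + self.layer_depths[-1] >= self.height_px:
            raise PhantomGeometryError("retina extends beyond the image bottom")
        if self.fovea_depth_px >= self.layer_depths[1]:
            raise PhantomGeometryError("foveal depression deeper than the inner layers")
        if self.dril_region is not None:
            c0, c1 = self.dril_region
            if not (0 <= c0 < c1 <= self.width_px):
                raise PhantomGeometryError(f"dril_region {self.dril_region} outside image")
        for k, (r, c, rad) in enumerate(self.hrf_list):
            if not (rad >= 1 and rad <= r < self.height_px - rad and rad <= c < self.width_px - rad):
                raise PhantomGeometryError(f"HRF #{k} at {(r, c, rad)} does not fit inside the image")
        surf = self.surface_profile()
        band_bottom = self.surface_row + self.layer_depths[-1]
        for k, (r, c, a, b) in enumerate(self.cystoid_list):
            if a < 1 or b < 1:
                raise PhantomGeometryError(f"cystoid #{k} has non-positive semiaxes")
            c0, c1 = c - a, c + a
            if not (0 <= c0 and c1 < self.width_px):
                raise PhantomGeometryError(f"cystoid #{k} at {(r, c, a, b)} exceeds image columns")
            top = int(np.ceil(surf[c0 : c1 + 1].max())) + 1
            if r - b < top or r + b >= band_bottom:
                raise PhantomGeometryError(f"cystoid #{k} at {(r, c, a, b)} leaves the retinal band")

    # -- geometry helpers -------------------------------------------------

    def surface_profile(self) -> np.ndarray:
        """Inner-surface row per column, dipping at the fovea."""
        cols = np.arange(self.width_px)
        dip = self.fovea_depth_px * np.exp(-0.5 * ((cols - self.fovea_col) / self.fovea_sigma_px) ** 2)
        return self.surface_row + dip

    def opl_band_rows(self) -> tuple[int, int]:
        """(top, bottom) rows of the OPL band; constant across columns."""
        return (
            self.surface_row + self.layer_depths[_OPL_BAND - 1],
            self.surface_row + self.layer_depths[_OPL_BAND],
        )

    def central_window(self) -> tuple[float, float]:
        """Column interval of the 1 mm central foveal window."""
        half = 500.0 / self.um_per_px
        return self.fovea_col - half, self.fovea_col + half


@dataclass
class PhantomBundle:
    image: np.ndarray
    hrf_mask: np.ndarray
    cystoid_mask: np.ndarray
    opl_mask: np.ndarray
    dril_label: str  # 'normal' | 'dril'
    dril_centrality: str  # 'central' | 'non_central' | 'n/a'
    truth_features: BiomarkerFeatures
    spec: PhantomSpec


def default_phantom_spec(height_px: int = 192, width_px: int = 192, **overrides) -> PhantomSpec:
    """Spec with layer geometry scaled proportionally to the image height."""
    s = height_px / 192.0
    base = dict(
        height_px=height_px,
        width_px=width_px,
        fovea_col=width_px // 2,
        surface_row=round(38 * s),
        layer_depths=tuple(round(d * s) for d in (36, 56, 71, 108, 121)),
        fovea_depth_px=round(40 * s),
        fovea_sigma_px=18.0 * s,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def _render_layers(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    rows = np.arange(h)[:, None]
    surf = spec.surface_profile()[None, :]
    img = np.full((h, w), _VITREOUS, dtype=np.float64)
    # inner boundaries interpolate between the (dipping) surface and the fixed
    # OPL top, so inner layers pinch at the fovea; outer bands stay flat.
    opl_top = spec.surface_row + spec.layer_depths[_OPL_BAND - 1]
    inner_frac = np.array([0.0, spec.layer_depths[0] / spec.layer_depths[1], 1.0])
    bounds = [surf + f * (opl_top - surf) for f in inner_frac]  # surface, b0, opl_top
    flat = [spec.surface_row + d for d in spec.layer_depths[_OPL_BAND:]]  # opl_end, onl_end, rpe_end
    edges = bounds + [np.full((1, w), v, dtype=float) for v in flat]
    for lo, hi, level in zip(edges[:-1], edges[1:], _BAND_LEVELS):
        img[(rows >= lo) & (rows < hi)] = level
    img[(rows >= edges[-1])] = _BELOW_RPE
    return img


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom and its ground-truth masks and biomarker record."""
    h, w = spec.height_px, spec.width_px
    img = _render_layers(spec)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    surf = spec.surface_profile()
    opl_top, opl_bottom = spec.opl_band_rows()

    # DRIL: replace the inner-layer banding (surface..OPL bottom) by its mean
    if spec.dril_region is not None:
        c0, c1 = spec.dril_region
        band = (rows >= surf[None, :]) & (rows < opl_bottom) & (cols >= c0) & (cols < c1)
        img[band] = img[band].mean()

    # cystoid spaces: dark ellipses; each must stay a separate 8-connected blob
    cystoid_mask = np.zeros((h, w), dtype=np.uint8)
    cyst_truth = []
    for k, (r, c, a, b) in enumerate(spec.cystoid_list):
        ell = ((cols - c) / a) ** 2 + ((rows - r) / b) ** 2 <= 1.0
        if (cystoid_mask[ell] != 0).any():
            raise PhantomGeometryError(f"cystoid #{k} overlaps an earlier cystoid")
        cystoid_mask[ell] = 1
        rr, cc = np.nonzero(ell)
        cyst_truth.append(
            dict(
                area_px=int(ell.sum()),
                h_px=int(cc.max() - cc.min() + 1),
                v_px=int(rr.max() - rr.min() + 1),
            )
        )
    if len(spec.cystoid_list) > 1:
        from skimage import measure as _measure

        n_comp = _measure.label(cystoid_mask, connectivity=2).max()
        if n_comp != len(spec.cystoid_list):
            raise PhantomGeometryError(
                f"cystoid ellipses touch: {len(spec.cystoid_list)} requested, {n_comp} separate blobs"
            )
    img[cystoid_mask == 1] = _CYST_LEVEL

    # HRF: bright disks
    hrf_mask = np.zeros((h, w), dtype=np.uint8)
    n_above = n_below = 0
    for r, c, rad in spec.hrf_list:
        disk = (cols - c) ** 2 + (rows - r) ** 2 <= rad**2
        hrf_mask[disk] = 1
        if r < opl_top:
            n_above += 1
        else:
            n_below += 1
    img[hrf_mask == 1] = _HRF_LEVEL

    # OPL mask: the OPL band, erased where DRIL removes the boundary
    opl_mask = np.zeros((h, w), dtype=np.uint8)
    opl_mask[opl_top:opl_bottom, :] = 1
    if spec.dril_region is not None:
        opl_mask[:, spec.dril_region[0] : spec.dril_region[1]] = 0

    rng = np.random.default_rng(spec.seed)
    img = np.clip(img * (1.0 + spec.noise_sigma * rng.standard_normal((h, w))), 0.0, 1.0)

    dril = spec.dril_region is not None
    centrality = "n/a"
    if dril:
        lo, hi = spec.central_window()
        c0, c1 = spec.dril_region
        centrality = "central" if (c0 < hi and c1 > lo) else "non_central"
    truth = BiomarkerFeatures(
        dril_present=dril,
        dril_central=centrality == "central",
        dril_extent_um=(spec.dril_region[1] - spec.dril_region[0]) * spec.um_per_px if dril else None,
        n_hrf_above=n_above,
        n_hrf_within_below=n_below,
        cystoid_count=len(spec.cystoid_list),
        total_cystoid_area_um2=float(sum(c["area_px"] for c in cyst_truth)) * spec.um_per_px**2,
        max_h_diameter_um=max((c["h_px"] for c in cyst_truth), default=0) * spec.um_per_px,
        max_v_diameter_um=max((c["v_px"] for c in cyst_truth), default=0) * spec.um_per_px,
        um_per_px=spec.um_per_px,
    )
    return PhantomBundle(
        image=img.astype(np.float32),
        hrf_mask=hrf_mask,
        cystoid_mask=cystoid_mask,
        opl_mask=opl_mask,
        dril_label="dril" if dril else "normal",
        dril_centrality=centrality,
        truth_features=truth,
        spec=spec,
    )


# -- dataset sampling ----------------------------------------------------

_KNOWN_LABELS = {"normal", "dril", "dril_central", "dril_non_central"}


def _sample_lesions(spec: PhantomSpec, rng: np.random.Generator, hrf_range, cystoid_range):
    """Random, mutually disjoint HRF disks and cystoid ellipses for one phantom."""
    h, w, um = spec.height_px, spec.width_px, spec.um_per_px
    surf = spec.surface_profile()
    opl_top, opl_bottom = spec.opl_band_rows()
    band_bottom = spec.surface_row + spec.layer_depths[-1]
    occupied = np.zeros((h, w), dtype=bool)

    cystoids = []
    for _ in range(int(rng.integers(cystoid_range[0], cystoid_range[1] + 1))):
        for _try in range(60):
            a = max(2, round(rng.uniform(120, 650) / 2 / um))  # h-diameter 120-650 um
            b = max(2, round(rng.uniform(90, 420) / 2 / um))
            c = int(rng.integers(a + 1, w - a - 1))
            # keep cystoids at/below the INL so the bright inner band (used by
            # the foveal localizer) stays intact
            inl_start = spec.surface_row + spec.layer_depths[0]
            top = max(int(np.ceil(surf[c - a : c + a + 1].max())) + 2, inl_start)
            if top + b + 2 >= band_bottom - b - 2:
                continue
            r = int(rng.integers(top + b + 1, band_bottom - b - 1))
            rr = slice(max(r - b - 2, 0), r + b + 3)
            cc = slice(max(c - a - 2, 0), c + a + 3)
            if occupied[rr, cc].any():
                continue
            occupied[rr, cc] = True
            cystoids.append((r, c, a, b))
            break

    hrfs = []
    for _ in range(int(rng.integers(hrf_range[0], hrf_range[1] + 1))):
        for _try in range(60):
            rad = int(rng.integers(2, 4))
            c = int(rng.integers(rad + 1, w - rad - 1))
            above = rng.random() < 0.5
            if above:
                lo, hi = int(surf[c]) + rad + 2, opl_top - rad - 1
            else:
                lo, hi = opl_top + rad, band_bottom - rad - 1
            if hi <= lo:
                continue
            r = int(rng.integers(lo, hi))
            rr = slice(max(r - rad - 1, 0), r + rad + 2)
            cc = slice(max(c - rad - 1, 0), c + rad + 2)
            if occupied[rr, cc].any():
                continue
            occupied[rr, cc] = True
            hrfs.append((r, c, rad))
            break
    return tuple(hrfs), tuple(cystoids)


def _sample_dril_region(spec: PhantomSpec, central: bool, rng: np.random.Generator):
    lo, hi = spec.central_window()
    w = spec.width_px
    width = max(6, round(rng.uniform(500, 1200) / spec.um_per_px))
    if central:
        width = min(width, w - 2)
        a = max(0, int(np.floor(lo)) - width + 2)
        b = min(w - width, max(int(np.ceil(hi)) - 2, a))
        c0 = int(rng.integers(a, b + 1))
        return (c0, c0 + width)
    # non-central: region must not intersect the central window
    left_max = int(np.floor(lo))  # region may occupy columns [0, left_max)
    right_start = min(w, int(np.ceil(hi)) + 1)
    right_max = w - right_start
    sides = []
    if left_max >= 6:
        sides.append("L")
    if right_max >= 6:
        sides.append("R")
    if not sides:
        raise PhantomGeometryError("image too narrow for a non-central DRIL region")
    side = sides[int(rng.integers(0, len(sides)))]
    if side == "L":
        width = min(width, left_max)
        c0 = int(rng.integers(0, left_max - width + 1))
    else:
        width = min(width, right_max)
        c0 = int(rng.integers(right_start, w - width + 1))
    return (c0, c0 + width)


def generate_dataset(
    n: int,
    class_mix: dict[str, float],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    hrf_range: tuple[int, int] = (0, 5),
    cystoid_range: tuple[int, int] = (0, 3),
) -> list[PhantomBundle]:
    """Sample ``n`` labelled phantoms with the requested class balance.

    Labels: 'normal', 'dril' (centrality alternating), 'dril_central',
    'dril_non_central'. Fractions must sum to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(class_mix) - _KNOWN_LABELS
    if unknown:
        raise ValueError(f"unknown labels in class_mix: {sorted(unknown)}")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    if base_spec is None:
        base_spec = default_phantom_spec()

    labels = []
    keys = sorted(class_mix)
    counts = {k: int(round(class_mix[k] * n)) for k in keys}
    while sum(counts.values()) < n:
        counts[keys[0]] += 1
    while sum(counts.values()) > n:
        counts[max(keys, key=lambda k: counts[k])] -= 1
    for k in keys:
        labels += [k] * counts[k]

    rng = np.random.default_rng(seed)
    labels = [labels[i] for i in rng.permutation(len(labels))]
    bundles = []
    dril_toggle = 0
    for i, label in enumerate(labels):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        jitter = 1.0 + sub.uniform(-0.05, 0.05)
        spec0 = dataclasses.replace(
            base_spec,
            fovea_col=int(np.clip(base_spec.fovea_col + sub.integers(-base_spec.width_px // 12, base_spec.width_px // 12 + 1), 0, base_spec.width_px - 1)),
            layer_depths=tuple(round(d * jitter) for d in base_spec.layer_depths),
            seed=int(sub.integers(0, 2**31 - 1)),
        )
        if label == "dril":
            central = dril_toggle % 2 == 0
            dril_toggle += 1
        elif label == "dril_central":
            central = True
        elif label == "dril_non_central":
            central = False
        dril_region = None
        if label != "normal":
            dril_region = _sample_dril_region(spec0, central, sub)
        hrfs, cysts = _sample_lesions(spec0, sub, hrf_range, cystoid_range)
        spec = dataclasses.replace(spec0, dril_region=dril_region, hrf_list=hrfs, cystoid_list=cysts)
        bundles.append(generate_phantom(spec))
    return bundles


# -- serialization -------------------------------------------------------


def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    if d["hrf_list"]:
        d["hrf_list"] = [list(t) for t in spec.hrf_list]
    if d["cystoid_list"]:
        d["cystoid_list"] = [list(t) for t in spec.cystoid_list]
    Path(path).write_text(yaml.safe_dump(d))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("layer_depths", "dril_region"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    d["hrf_list"] = tuple(tuple(t) for t in d.get("hrf_list") or ())
    d["cystoid_list"] = tuple(tuple(t) for t in d.get("cystoid_list") or ())
    return PhantomSpec(**d)


def _write_png(path: Path, arr: np.ndarray) -> None:
    if arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=np.float64) * 255.0, 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_dataset(bundles: list[PhantomBundle], out_dir: str | Path) -> Path:
    """Write images and masks as PNG (masks 0/255) plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "dril_label", "dril_centrality", "n_hrf", "n_cystoid", "seed"])
        for i, b in enumerate(bundles):
            stem = f"phantom_{i:04d}"
            _write_png(out / f"{stem}.png", b.image)
            for name, m in (("hrf", b.hrf_mask), ("cystoid", b.cystoid_mask), ("opl", b.opl_mask)):
                _write_png(out / f"{stem}_{name}_mask.png", m * 255)
            wr.writerow(
                [f"{stem}.png", b.dril_label, b.dril_centrality, len(b.spec.hrf_list), len(b.spec.cystoid_list), b.spec.seed]
            )
    return manifest
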