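"""End-to-end orchestration: OCT scan -> biomarkers -> features -> severity.

Stage order follows the clinical workflow: classify DRIL presence; if DRIL
is present, localize the 1 mm foveal window and classify centrality (when
the scan is normal the centrality stage is skipped and non-central flows
to the engine); segment HRF, OPL and cystoid spaces; extract morphometric
features; run the fuzzy engine.

Segmentation masks live on the network's input grid, so when the scan is
larger or smaller than that grid the micrometre calibration is rescaled by
the ratio of scan width to grid width before morphometry.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import __version__
from .classification import classify_dril, classify_dril_centrality, load_classifier, locate_foveal_roi
from .features import aggregate_features, cystoid_parameters, extract_components, hrf_positions, opl_upper_boundary
from .fuzzy import default_rulebase, grade_features, rulebase_from_yaml
from .segmentation import load_model, predict_mask

__all__ = ["PipelineConfig", "CaseReport", "run_case", "run_batch", "load_pipeline_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    um_per_px: float = 11.7
    dril_model: str | None = None
    centrality_model: str | None = None
    hrf_model: str | None = None
    opl_model: str | None = None
    cystoid_model: str | None = None
    binarization_threshold: float = 0.5
    min_component_area: int = 3
    rulebase_path: str | None = None
    seed: int = 0
    out_dir: str = "reports"
    letterbox: bool = False

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CaseReport:
    input_path: str
    dril_present: bool
    dril_probability: float
    dril_central: bool
    n_hrf_above: int
    n_hrf_within_below: int
    cystoid_count: int
    total_cystoid_area_um2: float
    max_h_diameter_um: float
    max_v_diameter_um: float
    severity_grade: str
    severity_score: float
    advisories: dict
    fired_rules: list
    no_findings: bool
    seed: int
    software_version: str
    config_hash: str
    error: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def _load_image(path_or_array) -> np.ndarray:
    if isinstance(path_or_array, (str, Path)):
        arr = np.asarray(Image.open(path_or_array), dtype=np.float32)
    else:
        arr = np.asarray(path_or_array, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _write_mask_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def run_case(image, config: PipelineConfig, models: dict | None = None, write: bool = True) -> CaseReport:
    """Grade one scan. ``models`` may carry preloaded model objects under the
    keys dril/centrality/hrf/opl/cystoid to avoid reloading checkpoints."""
    input_path = str(image) if isinstance(image, (str, Path)) else "<array>"
    models = dict(models or {})

    def get_model(name, loader):
        if name in models:
            return models[name]
        path = getattr(config, f"{name}_model")
        if path is None:
            raise FileNotFoundError(f"no {name} model configured")
        models[name] = loader(path)
        return models[name]

    img = _load_image(image)

    stage = "dril-classification"
    try:
        dril_clf = get_model("dril", load_classifier)
        label, prob = classify_dril(dril_clf, img)
        dril_present = label == "dril"

        stage = "centrality"
        dril_central = False
        if dril_present:
            roi = locate_foveal_roi(img, um_per_px=config.um_per_px)
            cent_clf = get_model("centrality", load_classifier)
            dril_central = classify_dril_centrality(cent_clf, img, roi) == "central"
        else:
            log.info("scan classified normal; centrality stage skipped, non-central assumed")

        stage = "segmentation"
        masks = {}
        for target in ("hrf", "opl", "cystoid"):
            model = get_model(target, load_model)
            masks[target] = predict_mask(model, img, config.binarization_threshold, target=target)

        stage = "feature-extraction"
        grid_w = masks["hrf"].shape[1]
        eff_um = config.um_per_px * (img.shape[1] / grid_w)
        hrf_comps = extract_components(masks["hrf"], config.min_component_area)
        try:
            boundary = opl_upper_boundary(masks["opl"])
            hrf_feats = hrf_positions(hrf_comps, boundary)
        except ValueError:
            log.warning("OPL segmentation empty; treating all HRF as within/below")
            from .features import HRFFeature, WITHIN_OR_BELOW_OPL

            hrf_feats = [HRFFeature(c, a, WITHIN_OR_BELOW_OPL) for c, a, _ in hrf_comps]
        cyst_feats = cystoid_parameters(masks["cystoid"], eff_um, config.min_component_area)
        features = aggregate_features(
            "dril" if dril_present else "normal",
            ("central" if dril_central else "non_central") if dril_present else None,
            hrf_feats,
            cyst_feats,
            eff_um,
        )

        stage = "fuzzy-grading"
        rulebase = rulebase_from_yaml(config.rulebase_path) if config.rulebase_path else default_rulebase()
        result = grade_features(features, rulebase)

        no_findings = not dril_present and not hrf_feats and not cyst_feats
        report = CaseReport(
            input_path=input_path,
            dril_present=dril_present,
            dril_probability=prob,
            dril_central=dril_central,
            n_hrf_above=features.n_hrf_above,
            n_hrf_within_below=features.n_hrf_within_below,
            cystoid_count=features.cystoid_count,
            total_cystoid_area_um2=features.total_cystoid_area_um2,
            max_h_diameter_um=features.max_h_diameter_um,
            max_v_diameter_um=features.max_v_diameter_um,
            severity_grade=result.grade,
            severity_score=result.score,
            advisories=result.advisories,
            fired_rules=[list(t) for t in result.fired_rules],
            no_findings=no_findings,
            seed=config.seed,
            software_version=__version__,
            config_hash=config.hash(),
        )
    except Exception as exc:  # stage-tagged failure report
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(input_path).stem if input_path != "<array>" else "case"
        report.to_json(out / f"{stem}_report.json")
        for target, mask in masks.items():
            _write_mask_png(mask, out / f"{stem}_{target}_mask.png")
    return report


def run_batch(manifest_csv: str | Path, config: PipelineConfig, models: dict | None = None) -> Path:
    """One report per manifest row; a failing case is recorded, not fatal.

    Returns the path of the summary CSV."""
    manifest_csv = Path(manifest_csv)
    base = manifest_csv.parent
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = out / "summary.csv"
    with open(manifest_csv) as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        log.warning("manifest %s is empty", manifest_csv)
    models = dict(models or {})
    with open(summary, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(
            ["path", "grade", "score", "dril_present", "dril_central", "n_hrf_above", "n_hrf_within_below", "cystoid_count", "error"]
        )
        for row in rows:
            path = base / row["path"]
            try:
                rep = run_case(path, config, models=models)
                wr.writerow(
                    [row["path"], rep.severity_grade, f"{rep.severity_score:.4f}", rep.dril_present, rep.dril_central,
                     rep.n_hrf_above, rep.n_hrf_within_below, rep.cystoid_count, ""]
                )
            except Exception as exc:
                log.error("case %s failed: %s", path, exc)
                wr.writerow([row["path"], "", "", "", "", "", "", "", str(exc)])
    return summary
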