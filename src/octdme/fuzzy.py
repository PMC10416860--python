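"""Mamdani fuzzy inference for DME severity grading.

The rule base encodes the clinical evidence linking OCT biomarkers to
visual-acuity outcomes: central DRIL, HRF at or below the OPL, and large or
numerous cystoid spaces predict worse acuity (Severe); small cystoid
diameters (<450 um horizontal, <300 um vertical) predict preserved acuity
(Mild); non-central DRIL and intermediate HRF counts feed Moderate.
Literature-reported probabilities (58/73/62/69%) become rule weights.

Inference is max-min Mamdani: rule activation is the weighted minimum of
antecedent memberships, consequent sets are clipped at the activation and
max-aggregated over a [0, 1] severity universe, and the centroid of the
aggregate is the crisp score. Cut points 0.35 and 0.65 map the score to
Mild / Moderate / Severe. Advisory rules (dexamethasone response,
driving/reading warning, ranibizumab response) are crisp side outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import BiomarkerFeatures

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "RuleBase",
    "SeverityResult",
    "default_rulebase",
    "fuzzify",
    "infer",
    "defuzzify",
    "grade",
    "advisories",
    "grade_features",
    "rulebase_to_yaml",
    "rulebase_from_yaml",
]

log = logging.getLogger(__name__)

GRADES = ("Mild", "Moderate", "Severe")
MILD_CUT = 0.35
SEVERE_CUT = 0.65
N_UNIVERSE = 101  # discretization of the severity universe [0, 1]

H_DIAMETER_CUT_UM = 450.0
V_DIAMETER_CUT_UM = 300.0


@dataclass(frozen=True)
class MembershipFunction:
    """shape 'trapezoid' (a,b,c,d), 'triangle' (a,b,c) or 'crisp_bool' (v,)."""

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self):
        n = {"trapezoid": 4, "triangle": 3, "crisp_bool": 1}.get(self.shape)
        if n is None:
            raise ValueError(f"unknown shape {self.shape!r}")
        if len(self.breakpoints) != n:
            raise ValueError(f"{self.shape} needs {n} breakpoints")
        if self.shape != "crisp_bool" and list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be nondecreasing")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "crisp_bool":
            want = self.breakpoints[0] >= 0.5
            return ((x >= 0.5) == want).astype(float)
        if self.shape == "triangle":
            a, b, c = self.breakpoints
            pts, vals = (a, b, c), (0.0, 1.0, 0.0)
        else:
            a, b, c, d = self.breakpoints
            pts, vals = (a, b, c, d), (0.0, 1.0, 1.0, 0.0)
        # plateau edges: a==b means the shoulder is fully open on the left
        mu = np.interp(x, pts, vals)
        if self.shape == "trapezoid":
            a, b, c, d = self.breakpoints
            if a == b:
                mu = np.where(x <= a, 1.0, mu)
            if c == d:
                mu = np.where(x >= d, 1.0, mu)
        else:
            a, b, c = self.breakpoints
            if a == b:
                mu = np.where(x <= a, 1.0, mu)
            if b == c:
                mu = np.where(x >= c, 1.0, mu)
        return mu


@dataclass(frozen=True)
class LinguisticVariable:
    name: str
    universe: tuple[float, float, str]  # (min, max, units)
    terms: dict[str, MembershipFunction]

    def covers(self, n: int = 201) -> bool:
        lo, hi, _ = self.universe
        xs = np.linspace(lo, hi, n)
        total = np.zeros(n)
        for mf in self.terms.values():
            total = np.maximum(total, mf(xs))
        return bool((total > 0).all())


@dataclass(frozen=True)
class FuzzyRule:
    rule_id: str
    antecedents: tuple[tuple[str, str], ...]  # (variable, term), AND-connected
    consequent: tuple[str, str]  # ('severity', grade-term) or ('advisory', flag)
    weight: float = 1.0
    provenance: str = ""

    def __post_init__(self):
        if not self.antecedents:
            raise ValueError("rule needs at least one antecedent")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must be in (0, 1]")
        if self.consequent[0] not in ("severity", "advisory"):
            raise ValueError("consequent kind must be 'severity' or 'advisory'")


@dataclass
class RuleBase:
    variables: dict[str, LinguisticVariable]
    rules: list[FuzzyRule]
    severity_terms: dict[str, MembershipFunction]


@dataclass
class SeverityResult:
    grade: str
    score: float
    fired_rules: list[tuple[str, float]]
    advisories: dict[str, bool]


def _bool_var(name: str, false_term: str, true_term: str) -> LinguisticVariable:
    return LinguisticVariable(
        name,
        (0.0, 1.0, "bool"),
        {
            false_term: MembershipFunction("crisp_bool", (0.0,)),
            true_term: MembershipFunction("crisp_bool", (1.0,)),
        },
    )


def _count_var(name: str) -> LinguisticVariable:
    return LinguisticVariable(
        name,
        (0.0, 20.0, "count"),
        {
            "none": MembershipFunction("trapezoid", (0.0, 0.0, 0.0, 1.0)),
            "some": MembershipFunction("trapezoid", (0.0, 1.0, 20.0, 20.0)),
            "few": MembershipFunction("trapezoid", (0.0, 1.0, 2.0, 4.0)),
            "many": MembershipFunction("trapezoid", (2.0, 4.0, 20.0, 20.0)),
        },
    )


def default_rulebase() -> RuleBase:
    """The evidence-derived rule base (nine source rules plus the implied
    large-diameter complements)."""
    variables = {
        "dril_present": _bool_var("dril_present", "absent", "present"),
        "dril_central": _bool_var("dril_central", "non_central", "central"),
        "hrf_total": _count_var("hrf_total"),
        "hrf_within_below": _count_var("hrf_within_below"),
        "cystoid_count": _count_var("cystoid_count"),
        "h_diameter": LinguisticVariable(
            "h_diameter",
            (0.0, 2000.0, "um"),
            {
                "small": MembershipFunction("trapezoid", (0.0, 0.0, 400.0, 500.0)),
                "large": MembershipFunction("trapezoid", (400.0, 500.0, 2000.0, 2000.0)),
            },
        ),
        "v_diameter": LinguisticVariable(
            "v_diameter",
            (0.0, 2000.0, "um"),
            {
                "small": MembershipFunction("trapezoid", (0.0, 0.0, 265.0, 335.0)),
                "large": MembershipFunction("trapezoid", (265.0, 335.0, 2000.0, 2000.0)),
            },
        ),
    }
    severity_terms = {
        "mild": MembershipFunction("triangle", (0.05, 0.15, 0.25)),
        "moderate": MembershipFunction("triangle", (0.3, 0.5, 0.7)),
        "severe": MembershipFunction("triangle", (0.75, 0.85, 0.95)),
    }
    R = FuzzyRule
    rules = [
        R(
            "dril_central_severe",
            (("dril_present", "present"), ("dril_central", "central")),
            ("severity", "severe"),
            1.0,
            "Sun et al.: DRIL extending >0.5 mm within the central 1 mm foveal area predicts lower VA",
        ),
        R(
            "dril_noncentral_moderate",
            (("dril_present", "present"), ("dril_central", "non_central")),
            ("severity", "moderate"),
            1.0,
            "Sun et al. (complement): DRIL outside the central foveal window carries intermediate risk",
        ),
        R(
            "hrf_sub_opl_many_severe",
            (("hrf_within_below", "many"),),
            ("severity", "severe"),
            1.0,
            "Bolz et al.: HRF on the ONL/OPL border or below deflects more light and worsens VA",
        ),
        R(
            "hrf_sub_opl_few_moderate",
            (("hrf_within_below", "few"),),
            ("severity", "moderate"),
            1.0,
            "Bolz et al. / Arthi et al.: HRF burden correlates with SRF and DME severity",
        ),
        R(
            "cystoid_many_severe",
            (("cystoid_count", "many"),),
            ("severity", "severe"),
            1.0,
            "Nagai et al.: high number and area of cystoids predict worse VA",
        ),
        R(
            "h_diam_large_severe",
            (("cystoid_count", "some"), ("h_diameter", "large")),
            ("severity", "severe"),
            0.58,
            "Yalcin et al.: 58% probability of VA < 20/60 with horizontal cyst diameter >= 450 um",
        ),
        R(
            "h_diam_small_mild",
            (("cystoid_count", "some"), ("h_diameter", "small")),
            ("severity", "mild"),
            0.73,
            "Yalcin et al.: 73% probability of VA >= 20/60 with horizontal cyst diameter < 450 um",
        ),
        R(
            "v_diam_large_severe",
            (("cystoid_count", "some"), ("v_diameter", "large")),
            ("severity", "severe"),
            0.62,
            "Yalcin et al.: 62% probability of VA < 20/60 with vertical cyst diameter >= 300 um",
        ),
        R(
            "v_diam_small_mild",
            (("cystoid_count", "some"), ("v_diameter", "small")),
            ("severity", "mild"),
            0.69,
            "Yalcin et al.: 69% probability of VA >= 20/60 with vertical cyst diameter < 300 um",
        ),
        R(
            "dex_responsive",
            (("dril_present", "absent"), ("hrf_total", "none")),
            ("advisory", "dex_responsive"),
            1.0,
            "Zur et al.: eyes without DRIL and HRF respond better to dexamethasone implants",
        ),
        R(
            "driving_reading_warning",
            (("cystoid_count", "some"), ("h_diameter", "large"), ("v_diameter", "large")),
            ("advisory", "driving_reading_warning"),
            1.0,
            "Cysts >450 um horizontal and >300 um vertical: high chance of BCVA < 20/60; advise against driving and reading",
        ),
        R(
            "ranibizumab_responsive",
            (("cystoid_count", "some"), ("h_diameter", "small"), ("v_diameter", "small")),
            ("advisory", "ranibizumab_responsive"),
            1.0,
            "Cysts <450 um horizontal and <300 um vertical: high probability of responding to ranibizumab",
        ),
    ]
    return RuleBase(variables=variables, rules=rules, severity_terms=severity_terms)


def _feature_inputs(features: BiomarkerFeatures) -> dict[str, float]:
    return {
        "dril_present": float(features.dril_present),
        "dril_central": float(features.dril_central),
        "hrf_total": float(features.n_hrf_above + features.n_hrf_within_below),
        "hrf_within_below": float(features.n_hrf_within_below),
        "cystoid_count": float(features.cystoid_count),
        "h_diameter": float(features.max_h_diameter_um),
        "v_diameter": float(features.max_v_diameter_um),
    }


def fuzzify(features: BiomarkerFeatures, variables: dict[str, LinguisticVariable]):
    """Crisp features -> {(variable, term): membership degree}."""
    crisp = _feature_inputs(features)
    memberships = {}
    for name, var in variables.items():
        x = crisp[name]
        lo, hi, _ = var.universe
        if not lo <= x <= hi:
            log.warning("feature %s=%.3g outside universe [%g, %g]; clamping", name, x, lo, hi)
            x = min(max(x, lo), hi)
        for term, mf in var.terms.items():
            memberships[(name, term)] = float(mf(x))
    return memberships


def rule_activations(memberships, rulebase: RuleBase) -> dict[str, float]:
    acts = {}
    for rule in rulebase.rules:
        degrees = []
        for var, term in rule.antecedents:
            if (var, term) not in memberships:
                raise KeyError(f"rule {rule.rule_id!r} references unknown variable/term ({var}, {term})")
            degrees.append(memberships[(var, term)])
        acts[rule.rule_id] = rule.weight * min(degrees)
    return acts


def infer(memberships, rulebase: RuleBase, n_points: int = N_UNIVERSE) -> np.ndarray:
    """Max-aggregated clipped consequents of the severity rules on [0, 1]."""
    xs = np.linspace(0.0, 1.0, n_points)
    agg = np.zeros(n_points)
    acts = rule_activations(memberships, rulebase)
    for rule in rulebase.rules:
        if rule.consequent[0] != "severity":
            continue
        term = rulebase.severity_terms[rule.consequent[1]]
        agg = np.maximum(agg, np.minimum(acts[rule.rule_id], term(xs)))
    return agg


def defuzzify(aggregate: np.ndarray) -> float:
    """Centroid of the aggregate on the discretized [0, 1] universe; 0 if empty."""
    aggregate = np.asarray(aggregate, dtype=float)
    xs = np.linspace(0.0, 1.0, len(aggregate))
    mass = aggregate.sum()
    if mass == 0.0:
        return 0.0
    return float((xs * aggregate).sum() / mass)


def grade(score: float) -> str:
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < MILD_CUT:
        return "Mild"
    if score < SEVERE_CUT:
        return "Moderate"
    return "Severe"


def advisories(features: BiomarkerFeatures) -> dict[str, bool]:
    """Crisp advisory flags; cystoid advisories are false when no cystoid exists."""
    has_cyst = features.cystoid_count > 0
    return {
        "dex_responsive": (not features.dril_present)
        and (features.n_hrf_above + features.n_hrf_within_below == 0),
        "driving_reading_warning": has_cyst
        and features.max_h_diameter_um > H_DIAMETER_CUT_UM
        and features.max_v_diameter_um > V_DIAMETER_CUT_UM,
        "ranibizumab_responsive": has_cyst
        and features.max_h_diameter_um < H_DIAMETER_CUT_UM
        and features.max_v_diameter_um < V_DIAMETER_CUT_UM,
    }


def grade_features(features: BiomarkerFeatures, rulebase: RuleBase | None = None) -> SeverityResult:
    """fuzzify -> infer -> defuzzify -> grade, plus advisory flags."""
    if rulebase is None:
        rulebase = default_rulebase()
    memberships = fuzzify(features, rulebase.variables)
    acts = rule_activations(memberships, rulebase)
    agg = infer(memberships, rulebase)
    score = defuzzify(agg)
    if agg.sum() == 0.0:
        log.warning("no severity rule activated; defaulting to Mild with score 0")
    return SeverityResult(
        grade=grade(score),
        score=score,
        fired_rules=sorted(((rid, a) for rid, a in acts.items() if a > 0.0), key=lambda t: -t[1]),
        advisories=advisories(features),
    )


# -- YAML round trip so clinicians can edit rules without code changes ----


def rulebase_to_yaml(rulebase: RuleBase, path: str | Path) -> None:
    doc = {
        "variables": {
            name: {
                "universe": list(var.universe),
                "terms": {t: {"shape": mf.shape, "breakpoints": list(mf.breakpoints)} for t, mf in var.terms.items()},
            }
            for name, var in rulebase.variables.items()
        },
        "severity_terms": {
            t: {"shape": mf.shape, "breakpoints": list(mf.breakpoints)} for t, mf in rulebase.severity_terms.items()
        },
        "rules": [
            {
                "id": r.rule_id,
                "if": [list(a) for a in r.antecedents],
                "then": list(r.consequent),
                "weight": r.weight,
                "provenance": r.provenance,
            }
            for r in rulebase.rules
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def rulebase_from_yaml(path: str | Path) -> RuleBase:
    doc = yaml.safe_load(Path(path).read_text())

    def mf(d):
        return MembershipFunction(d["shape"], tuple(d["breakpoints"]))

    variables = {
        name: LinguisticVariable(name, tuple(v["universe"]), {t: mf(d) for t, d in v["terms"].items()})
        for name, v in doc["variables"].items()
    }
    severity_terms = {t: mf(d) for t, d in doc["severity_terms"].items()}
    rules = [
        FuzzyRule(
            rule_id=r["id"],
            antecedents=tuple(tuple(a) for a in r["if"]),
            consequent=tuple(r["then"]),
            weight=r.get("weight", 1.0),
            provenance=r.get("provenance", ""),
        )
        for r in doc["rules"]
    ]
    return RuleBase(variables=variables, rules=rules, severity_terms=severity_terms)
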