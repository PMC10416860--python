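"""Fuzzy engine: rule base content, inference oracle, crisp limit,
monotonicity and the qualitative severity patterns."""

import itertools

import numpy as np
import pytest

from octdme.features import BiomarkerFeatures
from octdme.fuzzy import (
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    RuleBase,
    advisories,
    default_rulebase,
    defuzzify,
    fuzzify,
    grade,
    grade_features,
    infer,
    rulebase_from_yaml,
    rulebase_to_yaml,
)


def features(**over):
    base = dict(
        dril_present=False,
        dril_central=False,
        n_hrf_above=0,
        n_hrf_within_below=0,
        cystoid_count=0,
        total_cystoid_area_um2=0.0,
        max_h_diameter_um=0.0,
        max_v_diameter_um=0.0,
        um_per_px=11.7,
    )
    base.update(over)
    return BiomarkerFeatures(**base)


class TestRuleBase:
    def test_contains_central_dril_severe_rule(self):
        rb = default_rulebase()
        assert any(
            ("dril_central", "central") in r.antecedents and r.consequent == ("severity", "severe")
            for r in rb.rules
        )

    def test_contains_dex_advisory_rule(self):
        rb = default_rulebase()
        dex = [r for r in rb.rules if r.consequent == ("advisory", "dex_responsive")]
        assert len(dex) == 1
        assert ("dril_present", "absent") in dex[0].antecedents

    def test_provenance_and_weights(self):
        for r in default_rulebase().rules:
            assert r.provenance
            assert 0.0 < r.weight <= 1.0

    def test_input_variables_cover_their_universes(self):
        for var in default_rulebase().variables.values():
            assert var.covers(), var.name


class TestFuzzify:
    def test_crossover_at_450um(self):
        m = fuzzify(features(cystoid_count=1, max_h_diameter_um=450.0, max_v_diameter_um=1.0), default_rulebase().variables)
        assert m[("h_diameter", "small")] == pytest.approx(0.5)
        assert m[("h_diameter", "large")] == pytest.approx(0.5)

    def test_zero_diameter_is_fully_small(self):
        m = fuzzify(features(), default_rulebase().variables)
        assert m[("h_diameter", "small")] == 1.0
        assert m[("h_diameter", "large")] == 0.0

    def test_crisp_boolean(self):
        m = fuzzify(features(dril_present=True, dril_central=True), default_rulebase().variables)
        assert m[("dril_central", "central")] == 1.0
        assert m[("dril_central", "non_central")] == 0.0

    def test_out_of_universe_input_is_clamped(self):
        m = fuzzify(features(cystoid_count=1, max_h_diameter_um=5000.0), default_rulebase().variables)
        assert m[("h_diameter", "large")] == 1.0


class TestInferDefuzzify:
    def test_no_activation_falls_back_to_mild(self):
        res = grade_features(features())
        assert res.grade == "Mild" and res.score == 0.0
        severity_ids = {r.rule_id for r in default_rulebase().rules if r.consequent[0] == "severity"}
        assert not severity_ids & {rid for rid, _ in res.fired_rules}

    def test_single_rule_identity(self):
        rb = default_rulebase()
        m = fuzzify(features(dril_present=True, dril_central=True), rb.variables)
        agg = infer(m, rb)
        xs = np.linspace(0, 1, len(agg))
        assert np.allclose(agg, rb.severity_terms["severe"](xs))

    def test_matches_pointwise_oracle_on_random_features(self):
        rb = default_rulebase()
        r = np.random.default_rng(42)
        for _ in range(50):
            f = features(
                dril_present=bool(r.integers(2)),
                n_hrf_within_below=int(r.integers(0, 8)),
                cystoid_count=int(r.integers(0, 6)),
            )
            f.dril_central = f.dril_present and bool(r.integers(2))
            if f.cystoid_count:
                f.max_h_diameter_um = float(r.uniform(0, 900))
                f.max_v_diameter_um = float(r.uniform(0, 600))
            m = fuzzify(f, rb.variables)
            agg = infer(m, rb)
            # independent pointwise evaluation
            xs = np.linspace(0, 1, 101)
            oracle = np.zeros(101)
            for i, x in enumerate(xs):
                best = 0.0
                for rule in rb.rules:
                    if rule.consequent[0] != "severity":
                        continue
                    act = rule.weight * min(m[a] for a in rule.antecedents)
                    best = max(best, min(act, float(rb.severity_terms[rule.consequent[1]](x))))
                oracle[i] = best
            assert np.allclose(agg, oracle)
            assert defuzzify(agg) == pytest.approx(
                float((xs * oracle).sum() / oracle.sum()) if oracle.sum() else 0.0
            )

    def test_defuzzify_symmetric_triangle(self):
        xs = np.linspace(0, 1, 101)
        tri = np.maximum(0.0, 1.0 - np.abs(xs - 0.5) / 0.2)
        assert defuzzify(tri) == pytest.approx(0.5)

    def test_defuzzify_rectangle(self):
        xs = np.linspace(0, 1, 101)
        rect = ((xs >= 0.6) & (xs <= 1.0)).astype(float)
        assert defuzzify(rect) == pytest.approx(0.8)

    def test_defuzzify_within_support(self):
        r = np.random.default_rng(0)
        for _ in range(20):
            agg = r.random(101) * (r.random(101) > 0.7)
            if agg.sum() == 0:
                continue
            xs = np.linspace(0, 1, 101)
            support = xs[agg > 0]
            assert support.min() <= defuzzify(agg) <= support.max()


class TestGradeCutpoints:
    @pytest.mark.parametrize("score,expected", [(0.10, "Mild"), (0.34, "Mild"), (0.50, "Moderate"), (0.90, "Severe"), (0.65, "Severe")])
    def test_cutpoints(self, score, expected):
        assert grade(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade(1.2)


class TestAdvisories:
    def test_dex_when_no_dril_no_hrf(self):
        assert advisories(features(cystoid_count=2, max_h_diameter_um=300, max_v_diameter_um=100))["dex_responsive"]

    def test_driving_warning_for_large_cyst(self):
        a = advisories(features(cystoid_count=1, max_h_diameter_um=500, max_v_diameter_um=350))
        assert a["driving_reading_warning"] and not a["ranibizumab_responsive"]

    def test_no_cystoids_no_cyst_advisories(self):
        a = advisories(features())
        assert not a["driving_reading_warning"] and not a["ranibizumab_responsive"]


class TestQualitativePatterns:
    def test_benign_grades_mild(self):
        assert grade_features(features()).grade == "Mild"

    def test_central_dril_with_severe_findings_grades_severe(self):
        f = features(
            dril_present=True,
            dril_central=True,
            n_hrf_within_below=5,
            cystoid_count=1,
            max_h_diameter_um=500.0,
            max_v_diameter_um=350.0,
        )
        assert grade_features(f).grade == "Severe"

    def test_noncentral_dril_with_moderate_findings_grades_moderate(self):
        f = features(
            dril_present=True,
            dril_central=False,
            n_hrf_above=2,
            cystoid_count=1,
            max_h_diameter_um=300.0,
            max_v_diameter_um=200.0,
        )
        assert grade_features(f).grade == "Moderate"


class TestMonotonicity:
    def _score(self, **over):
        return grade_features(features(**over)).score

    def test_h_diameter_sweep(self):
        scores = [
            self._score(cystoid_count=1, max_h_diameter_um=h, max_v_diameter_um=100.0)
            for h in np.linspace(0, 1000, 41)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_v_diameter_sweep(self):
        scores = [
            self._score(cystoid_count=1, max_h_diameter_um=100.0, max_v_diameter_um=v)
            for v in np.linspace(0, 800, 41)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_sub_opl_hrf_count_sweep(self):
        for cyst in (0, 1):
            scores = [
                self._score(n_hrf_within_below=k, cystoid_count=cyst,
                            max_h_diameter_um=200.0 if cyst else 0.0,
                            max_v_diameter_um=150.0 if cyst else 0.0)
                for k in range(0, 9)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_centrality_flip_never_decreases(self):
        for kwargs in (
            dict(),
            dict(n_hrf_within_below=2),
            dict(cystoid_count=1, max_h_diameter_um=300.0, max_v_diameter_um=200.0),
        ):
            lo = self._score(dril_present=True, dril_central=False, **kwargs)
            hi = self._score(dril_present=True, dril_central=True, **kwargs)
            assert hi >= lo - 1e-9


class TestCrispLimit:
    def test_engine_reduces_to_crisp_rule_table(self):
        """With crisp antecedents and near-rectangular consequents the engine
        must reproduce a plain boolean rule table, enumerated exhaustively."""
        variables = {
            f"b{i}": LinguisticVariable(
                f"b{i}",
                (0.0, 1.0, "bool"),
                {"false": MembershipFunction("crisp_bool", (0.0,)), "true": MembershipFunction("crisp_bool", (1.0,))},
            )
            for i in range(3)
        }
        rects = {
            "mild": MembershipFunction("trapezoid", (0.00, 0.01, 0.32, 0.33)),
            "moderate": MembershipFunction("trapezoid", (0.34, 0.35, 0.655, 0.66)),
            "severe": MembershipFunction("trapezoid", (0.67, 0.68, 0.99, 1.0)),
        }
        # truth table: grade index = number of true antecedents, capped at 2
        table = {}
        rules = []
        for bits in itertools.product((0, 1), repeat=3):
            g = ("mild", "moderate", "severe")[min(sum(bits), 2)]
            table[bits] = g.capitalize() if g != "moderate" else "Moderate"
            rules.append(
                FuzzyRule(
                    rule_id=f"r{bits}",
                    antecedents=tuple((f"b{i}", "true" if b else "false") for i, b in enumerate(bits)),
                    consequent=("severity", g),
                )
            )
        rb = RuleBase(variables=variables, rules=rules, severity_terms=rects)
        for bits in itertools.product((0, 1), repeat=3):
            memberships = {}
            for i, b in enumerate(bits):
                memberships[(f"b{i}", "true")] = float(b)
                memberships[(f"b{i}", "false")] = float(1 - b)
            score = defuzzify(infer(memberships, rb))
            assert grade(score) == table[bits], bits


def test_rulebase_yaml_roundtrip(tmp_path):
    rb = default_rulebase()
    rulebase_to_yaml(rb, tmp_path / "rules.yaml")
    rb2 = rulebase_from_yaml(tmp_path / "rules.yaml")
    for f in (
        features(),
        features(dril_present=True, dril_central=True, n_hrf_within_below=5),
        features(cystoid_count=2, max_h_diameter_um=480.0, max_v_diameter_um=310.0),
    ):
        a, b = grade_features(f, rb), grade_features(f, rb2)
        assert (a.grade, a.score) == (b.grade, b.score)
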