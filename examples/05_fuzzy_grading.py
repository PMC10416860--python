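"""Grade three reference biomarker profiles with the fuzzy engine."""

from octdme import BiomarkerFeatures, grade_features

cases = {
    "benign (no findings)": BiomarkerFeatures(),
    "non-central DRIL, small cyst": BiomarkerFeatures(
        dril_present=True, n_hrf_above=2,
        cystoid_count=1, max_h_diameter_um=300.0, max_v_diameter_um=200.0,
    ),
    "central DRIL, 5 sub-OPL HRF, 500x350 um cyst": BiomarkerFeatures(
        dril_present=True, dril_central=True, n_hrf_within_below=5,
        cystoid_count=1, max_h_diameter_um=500.0, max_v_diameter_um=350.0,
    ),
}
for name, f in cases.items():
    r = grade_features(f)
    fired = ", ".join(rid for rid, _ in r.fired_rules[:3]) or "none"
    print(f"{name:46s} -> {r.grade:8s} score {r.score:.3f}  rules: {fired}")
    print(f"{'':46s}    advisories: {[k for k, v in r.advisories.items() if v]}")
# Scores are aggregate centroids on [0,1]; grades use cut points 0.35/0.65.
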