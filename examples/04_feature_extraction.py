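"""From segmentation masks to the crisp biomarker feature vector."""

from octdme import (
    aggregate_features,
    cystoid_parameters,
    default_phantom_spec,
    extract_components,
    generate_phantom,
    hrf_positions,
    opl_upper_boundary,
)

spec = default_phantom_spec(
    hrf_list=((60, 40, 2), (112, 150, 3)),  # one above, one below the OPL
    cystoid_list=((104, 90, 12, 8),),       # ~280 x 200 um cyst
)
b = generate_phantom(spec)
um = spec.um_per_px
hrf = hrf_positions(extract_components(b.hrf_mask, 3), opl_upper_boundary(b.opl_mask))
cysts = cystoid_parameters(b.cystoid_mask, um, 3)
features = aggregate_features("normal", None, hrf, cysts, um)
print([f.position for f in hrf])
print(f"cyst: {cysts[0].h_diameter_um:.0f} x {cysts[0].v_diameter_um:.0f} um, "
      f"area {cysts[0].area_um2:.0f} um^2")
print(features.to_json())
# The feature vector is exactly what the fuzzy engine consumes; HRF below
# the OPL and large cysts raise the eventual severity score.
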