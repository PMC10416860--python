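"""Classification metrics on a 30-scan confusion matrix, and the
deterministic foveal-ROI localizer on a phantom."""

from octdme import (
    ConfusionCounts,
    accuracy,
    default_phantom_spec,
    evaluation_report,
    f1,
    generate_phantom,
    locate_foveal_roi,
    sensitivity,
    specificity,
)

# 30 test scans, sensitivity 0.875, specificity 1.0 -> TP=14 FP=0 FN=2 TN=14
c = ConfusionCounts(tp=14, fp=0, fn=2, tn=14)
print(f"accuracy {accuracy(c)*100:.2f}%  sensitivity {sensitivity(c):.3f}  "
      f"specificity {specificity(c):.1f}  F1 {f1(c):.5f}")
print(evaluation_report(ConfusionCounts(tp=14, fp=2, fn=1, tn=13)))

b = generate_phantom(default_phantom_spec(fovea_col=120))
roi = locate_foveal_roi(b.image, um_per_px=11.7)
print(f"true fovea col 120 -> detected {roi.col_center}, 1 mm window = {roi.width_px} px")
# The localizer finds the foveal depression as the thinnest point of the
# bright retinal band; no learned detector is needed.
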