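"""Train a boosting ensemble and evaluate it on an independent split.

Simulates labeled windows with a planted motif (positives carry a
GGACU-phased compositional bias, negatives are uniform), then runs the
standard protocol: 70/30 stratified split, train on the training part,
report Sn/Sp/ACC/MCC/F1/AUROC on the held-out part.
"""

from rna6ma import (
    ModelConfig,
    generate_synthetic,
    independent_test,
    planted_profile,
)

ds = generate_synthetic(200, 200, bias=planted_profile(0.9), seed=42)
print(f"simulated {len(ds)} windows; class counts {ds.class_counts()}")

config = ModelConfig(family="boosting", variant="gradient-boost", seed=42)
report = independent_test(config, ds, test_fraction=0.3, seed=42)

print(f"train/test: {report.details['n_train']}/{report.details['n_test']}")
print(f"Sn={report.sn:.3f}  Sp={report.sp:.3f}  ACC={report.acc:.3f}")
print(f"MCC={report.mcc:.3f}  F1={report.f1:.3f}  AUROC={report.auroc:.3f}")
# ACC near 1 and AUROC near 1 mean the planted positional bias is strong
# enough for the moment-reduced encoding to separate the classes on
# windows the model never saw.
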