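"""10-fold cross-validation, with a no-signal control.

Runs the k-fold protocol twice: once on windows with a planted motif
(real signal) and once on pure background noise (no signal). The first
should score far above chance, the second should sit near ACC = 0.5 —
a quick sanity check that the pipeline does not manufacture signal.
"""

from rna6ma import (
    ModelConfig,
    generate_synthetic,
    kfold_cv,
    planted_profile,
    uniform_profile,
)

config = ModelConfig(family="boosting", variant="hist-gradient-boost", seed=1)

for label, bias in (("planted motif", planted_profile(0.9)),
                    ("no signal", uniform_profile())):
    ds = generate_synthetic(100, 100, bias=bias, seed=1)
    report = kfold_cv(config, ds, k=10, seed=1)
    accs = [f["ACC"] for f in report.per_fold]
    print(f"{label}: pooled ACC={report.acc:.3f} AUROC={report.auroc:.3f} "
          f"fold ACC range [{min(accs):.2f}, {max(accs):.2f}]")
# The pooled numbers tally every sample exactly once across the 10 test
# folds; the per-fold range shows the dispersion behind the headline.
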