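"""Repeated-holdout evaluation with sensitivity, specificity and ROC/AUC.

Every repeat refits the whole pipeline (standardization included) on the
training rows only, so the reported rates are leakage-free estimates of
screening performance.
"""

from wkelm import (
    KernelSpec,
    SimConfig,
    SplitPlan,
    TrainConfig,
    fit,
    run_protocol,
    simulate_dataset,
)

ds = simulate_dataset(SimConfig(n_samples=192, effect_size=1.5, seed=3))
plan = SplitPlan(scheme="repeated_holdout", train_fraction=2 / 3, repeats=3, seed=0)


def pipeline(X_train, y_train):
    return fit(X_train, y_train, KernelSpec(), TrainConfig(E=1.0))


reports, aggregate = run_protocol(ds, plan, pipeline)

for i, rep in enumerate(reports):
    c = rep.counts
    print(
        f"repeat {i}: TP={c.TP} TN={c.TN} FP={c.FP} FN={c.FN}  "
        f"SEA={rep.sensitivity:.4f} SPA={rep.specificity:.4f} "
        f"OC={rep.overall:.4f} AUC={rep.auc:.4f}"
    )
print(
    "aggregate means: "
    f"sensitivity={aggregate['sensitivity']:.4f} "
    f"specificity={aggregate['specificity']:.4f} "
    f"overall={aggregate['overall']:.4f} "
    f"auc={aggregate['auc']:.4f}"
)
# sensitivity = detected PD fraction, specificity = cleared healthy fraction;
# AUC is threshold-free: the probability a random PD recording outscores a
# random healthy one
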