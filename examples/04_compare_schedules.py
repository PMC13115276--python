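"""Matched-privacy comparison: dual dynamic schedule vs static DP-SGD.

Both algorithms are calibrated to spend the same eps=3 budget, trained over
the same five seeds on the same splits, and compared on minority-class
(few-shot) accuracy and MCC — the metrics that matter under severe
imbalance.
"""

from sdd_dpsgd import (
    ScheduleConfig,
    TrainConfig,
    generate_gaussian_mixture,
    ham10000_like_preset,
    run_comparison,
    train_val_split,
)

dataset = generate_gaussian_mixture(ham10000_like_preset(n_samples=3500, seed=0))
train_ds, val_ds = train_val_split(dataset, fraction=0.8, seed=0)

schedule = ScheduleConfig(total_iterations=2000, sigma0=1.0, c0=5.0,
                          gamma=0.9, beta=0.8, clip_decay=0.6, rho=0.3, n=3)
template = TrainConfig(schedule=schedule, learning_rate=0.05, batch_size=128)

table = run_comparison(
    train_ds, val_ds, schedule, template,
    eps_targets=[3.0], seeds=[1, 2, 3, 4, 5], delta=1e-3,
)
cols = ["algorithm", "accuracy_mean", "mcc_mean",
        "few_shot_accuracy_mean", "large_shot_accuracy_mean"]
print(table.aggregate[cols].round(4).to_string(index=False))
# At matched privacy the dual dynamic schedule should retain more
# minority-class signal: higher mean few-shot accuracy and MCC than the
# static baseline over the seed set.
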