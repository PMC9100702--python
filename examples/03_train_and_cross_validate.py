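"""Cross-validated comparison of the baseline GCN and the full RBF-GCN.

Runs the desk-scale protocol (20 regions, 150 subjects, 100 epochs, 5-fold
stratified CV) on the three-way staging task. Takes a couple of minutes.
"""

from rbfgcn import (
    RBFConfig,
    SyntheticCohortConfig,
    TrainConfig,
    cross_validate,
    generate_cohort,
)

networks, _ = generate_cohort(SyntheticCohortConfig.scaled_down(seed=1))
train_config = TrainConfig(epochs=100, folds=5, seed=1)

for arm in ("baseline", "rbf_gcn_c"):
    model_config = RBFConfig.from_arm(arm, n_classes=3, hidden=16, mlp_hidden=16)
    result = cross_validate(networks, "NC_vs_MCI_vs_AD", model_config,
                            train_config)
    print(f"{arm:10s} multiclass ACC = {result.summary()['ACC']}")
# Typical output: baseline around 55-62% and rbf_gcn_c several points higher
# (mean ± sd across the 5 folds). Binary tasks additionally report SEN/SPE.
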