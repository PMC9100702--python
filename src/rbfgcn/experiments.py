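"""Reduced-scale ablation experiments over the synthetic cohort.

The full-scale reference protocol (500 epochs, 10-fold CV, 148-region
networks, 502 subjects) is too heavy for routine desk runs, so the package
defines one fixed scaled-down protocol used by its own regression checks:
20-region networks, 50 subjects per stage (n=150), 100 epochs, 5-fold
stratified CV, 16 hidden units, multiclass task. Replicates differ in both
the generated cohort and the training seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import RBFConfig
from .synthetic import SyntheticCohortConfig, generate_cohort
from .train_eval import TrainConfig, cross_validate

__all__ = ["ScaledProtocol", "scaled_ablation_experiment"]

ORDERING_ARMS = ("baseline", "anna", "rbf_gcn_c", "rbf_gcn_a")


@dataclass
class ScaledProtocol:
    """The desk-scale experimental conditions."""

    epochs: int = 100
    folds: int = 5
    hidden: int = 16
    task: str = "NC_vs_MCI_vs_AD"
    arms: tuple[str, ...] = ORDERING_ARMS
    n_replicates: int = 5


def scaled_ablation_experiment(
    seed: int, protocol: ScaledProtocol | None = None
) -> list[dict[str, float]]:
    """Mean CV accuracy per arm for each seed replicate.

    Replicate ``r`` uses seed ``seed + r`` for cohort generation, fold
    assignment and training, so replicates are independent experiments.
    """
    protocol = protocol or ScaledProtocol()
    results = []
    for r in range(protocol.n_replicates):
        rep_seed = int((seed + r) % (2**31))
        networks, _ = generate_cohort(
            SyntheticCohortConfig.scaled_down(seed=rep_seed)
        )
        accs: dict[str, float] = {}
        for arm in protocol.arms:
            n_classes = 3 if protocol.task == "NC_vs_MCI_vs_AD" else 2
            config = RBFConfig.from_arm(
                arm, n_classes=n_classes,
                hidden=protocol.hidden, mlp_hidden=protocol.hidden,
            )
            result = cross_validate(
                networks, protocol.task, config,
                TrainConfig(epochs=protocol.epochs, folds=protocol.folds,
                            seed=rep_seed),
            )
            accs[arm] = result.mean("acc")
        results.append(accs)
    return results


def ordering_holds(accs: dict[str, float]) -> bool:
    """Full-model >= ANNA-only >= baseline, for both fusion rules."""
    return (
        accs["rbf_gcn_c"] >= accs["anna"] >= accs["baseline"]
        and accs["rbf_gcn_a"] >= accs["anna"]
    )
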