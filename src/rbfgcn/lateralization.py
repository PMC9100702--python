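"""Hemispheric-lateralization and regional-burden statistics.

Three analyses motivate the model architecture and are reproduced here on any
cohort of attributed brain networks:

1. **Regional amyloid differences** between diagnostic cohorts: the per-region
   difference of mean SUVR, e.g. NC vs AD, showing that amyloid burden has
   region-specific affinity.
2. **Six weighted graph measures** per node — strength, betweenness,
   clustering coefficient, PageRank, participation coefficient and
   within-module degree z-score — computed on the weighted structural graph.
3. **Paired Wilcoxon signed-rank tests** between homologous left/right
   regions (region ``i`` pairs with region ``i + m/2``), applied to amyloid
   levels and to each graph measure, quantifying hemispheric lateralization.

Weighted-measure conventions (the most widely used forms): betweenness uses
edge lengths ``1/w``; clustering is the Onnela geometric-mean triangle form;
the participation coefficient is ``P_i = 1 - sum_s (k_is / k_i)^2``; the
within-module degree z-score standardizes intra-module strength within each
module; PageRank uses damping 0.85. Modules come from seeded Louvain
modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .hemisphere import extract_hemispheres
from .network_data import BrainNetwork

__all__ = [
    "RegionalDifferenceProfile",
    "GraphMeasureTable",
    "PairedTestResult",
    "MEASURES",
    "regional_difference",
    "graph_measures",
    "detect_modules",
    "paired_wilcoxon",
    "lateralization_report",
    "mean_adjacency",
]

MEASURES = (
    "within_module_z",
    "strength",
    "betweenness",
    "participation",
    "clustering",
    "pagerank",
)


@dataclass(frozen=True)
class RegionalDifferenceProfile:
    """Per-region difference of cohort-mean attribute values (a minus b)."""

    values: np.ndarray
    cohort_pair: str


def regional_difference(
    cohort_a: list[BrainNetwork],
    cohort_b: list[BrainNetwork],
    attribute: int = 0,
    pair_label: str = "a_vs_b",
) -> RegionalDifferenceProfile:
    """Mean attribute per region in cohort a minus the same in cohort b."""
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be nonempty")
    mean_a = np.mean([n.attributes[:, attribute] for n in cohort_a], axis=0)
    mean_b = np.mean([n.attributes[:, attribute] for n in cohort_b], axis=0)
    if mean_a.shape != mean_b.shape:
        raise ValueError("cohorts have different node counts")
    return RegionalDifferenceProfile(mean_a - mean_b, pair_label)


def _to_graph(A: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(A.shape[0]))
    rows, cols = np.nonzero(np.triu(A, k=1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        w = float(A[i, j])
        G.add_edge(i, j, weight=w, length=1.0 / w)
    return G


def detect_modules(A: np.ndarray, seed: int = 0) -> np.ndarray:
    """Louvain modularity-maximizing partition; returns a node->module array.

    Deterministic for a fixed seed. Isolated nodes get their own modules.
    """
    G = _to_graph(np.asarray(A, dtype=float))
    communities = nx.algorithms.community.louvain_communities(
        G, weight="weight", seed=seed
    )
    modules = np.empty(A.shape[0], dtype=int)
    for s, nodes in enumerate(sorted(communities, key=min)):
        for i in nodes:
            modules[i] = s
    return modules


@dataclass(frozen=True)
class GraphMeasureTable:
    """Per-node values of the six weighted graph measures."""

    table: pd.DataFrame  # columns = MEASURES, one row per node

    def __getitem__(self, measure: str) -> np.ndarray:
        return self.table[measure].to_numpy()


def graph_measures(
    A: np.ndarray, modules: np.ndarray | None = None, seed: int = 0
) -> GraphMeasureTable:
    """All six per-node measures on a weighted undirected graph.

    ``modules`` defaults to :func:`detect_modules` on ``A``. Isolated nodes
    get strength 0, clustering 0, participation 0.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[0]
    if modules is None:
        modules = detect_modules(A, seed=seed)
    modules = np.asarray(modules, dtype=int)
    if modules.shape != (m,):
        raise ValueError(f"modules must map all {m} nodes, got {modules.shape}")
    G = _to_graph(A)

    strength = A.sum(axis=1)
    betweenness_d = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([betweenness_d[i] for i in range(m)])
    clustering_d = nx.clustering(G, weight="weight")
    clustering = np.array([clustering_d[i] for i in range(m)])
    if G.number_of_edges() > 0:
        pagerank_d = nx.pagerank(G, alpha=0.85, weight="weight", tol=1e-12,
                                 max_iter=5000)
    else:
        pagerank_d = {i: 1.0 / m for i in range(m)}
    pagerank = np.array([pagerank_d[i] for i in range(m)])

    # strength toward each module: kappa[i, s] = sum of weights from i into s
    n_mod = modules.max() + 1
    kappa = np.zeros((m, n_mod))
    for s in range(n_mod):
        kappa[:, s] = A[:, modules == s].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        participation = 1.0 - np.nansum(
            (kappa / np.where(strength > 0, strength, np.nan)[:, None]) ** 2,
            axis=1,
        )
    participation[strength == 0] = 0.0

    intra = kappa[np.arange(m), modules]
    z = np.zeros(m)
    for s in range(n_mod):
        members = modules == s
        mu = intra[members].mean()
        sd = intra[members].std()  # population sd, Guimera-Amaral convention
        if sd > 0:
            z[members] = (intra[members] - mu) / sd
    table = pd.DataFrame(
        {
            "within_module_z": z,
            "strength": strength,
            "betweenness": betweenness,
            "participation": participation,
            "clustering": clustering,
            "pagerank": pagerank,
        }
    )
    return GraphMeasureTable(table)


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test between homologous regions."""

    statistic: float
    p_value: float
    n_pairs: int
    measure: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def paired_wilcoxon(
    left: np.ndarray, right: np.ndarray, measure: str = ""
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on matched left/right values.

    Zero differences are dropped; ties get mid-ranks. The exact null
    distribution is used for up to 25 nonzero pairs, otherwise the normal
    approximation with continuity correction. If every difference is zero the
    test is degenerate and reported with p = 1.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"pair length mismatch: {left.shape} vs {right.shape}")
    diffs = left - right
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return PairedTestResult(0.0, 1.0, 0, measure)
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", correction=True,
            alternative="two-sided", method=method,
        )
    except ValueError:
        # exact method refuses ties in ranks; fall back to the approximation
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", correction=True,
            alternative="two-sided", method="approx",
        )
    return PairedTestResult(
        float(res.statistic), float(res.pvalue), int(nonzero.size), measure
    )


def mean_adjacency(cohort: list[BrainNetwork]) -> np.ndarray:
    """Population-mean adjacency matrix across a cohort."""
    if not cohort:
        raise ValueError("cohort is empty")
    return np.mean([n.adjacency for n in cohort], axis=0)


@dataclass
class LateralizationReport:
    """Everything needed for the left-vs-right population comparison figures."""

    amyloid_test: PairedTestResult
    measure_tests: dict[str, PairedTestResult]
    left_mean_suvr: np.ndarray
    right_mean_suvr: np.ndarray
    left_measures: GraphMeasureTable
    right_measures: GraphMeasureTable
    difference_matrix: np.ndarray  # A_l - A_r of the population topology

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": "amyloid", "statistic": self.amyloid_test.statistic,
             "p_value": self.amyloid_test.p_value,
             "n_pairs": self.amyloid_test.n_pairs}
        ]
        rows += [
            {"measure": name, "statistic": t.statistic, "p_value": t.p_value,
             "n_pairs": t.n_pairs}
            for name, t in self.measure_tests.items()
        ]
        return pd.DataFrame(rows)


def lateralization_report(
    cohort: list[BrainNetwork],
    mode: str = "population",
    seed: int = 0,
) -> LateralizationReport:
    """Left-vs-right paired comparison of amyloid and the six graph measures.

    ``mode="population"`` (default) analyses the population-mean network and
    population-mean SUVR per region; ``mode="subject"`` computes per-subject
    values and averages them across subjects per region before pairing. Both
    hemispheres share one module partition, detected on homologous-average
    topology so module labels are comparable across sides.
    """
    if mode not in ("population", "subject"):
        raise ValueError(f"mode must be 'population' or 'subject', got {mode!r}")
    m = cohort[0].m
    half = m // 2

    A_bar = mean_adjacency(cohort)
    A_l, A_r = A_bar[:half, :half], A_bar[half:, half:]
    modules = detect_modules((A_l + A_r) / 2.0, seed=seed)

    if mode == "population":
        suvr = np.mean([n.suvr for n in cohort], axis=0)
        left_suvr, right_suvr = suvr[:half], suvr[half:]
        left_meas = graph_measures(A_l, modules=modules)
        right_meas = graph_measures(A_r, modules=modules)
    else:
        suvr_stack = np.stack([n.suvr for n in cohort])
        left_suvr = suvr_stack[:, :half].mean(axis=0)
        right_suvr = suvr_stack[:, half:].mean(axis=0)
        l_tabs, r_tabs = [], []
        for net in cohort:
            l_net, r_net = extract_hemispheres(net)
            l_tabs.append(graph_measures(l_net.adjacency, modules=modules).table)
            r_tabs.append(graph_measures(r_net.adjacency, modules=modules).table)
        left_meas = GraphMeasureTable(
            sum(l_tabs[1:], l_tabs[0].copy()) / len(l_tabs)
        )
        right_meas = GraphMeasureTable(
            sum(r_tabs[1:], r_tabs[0].copy()) / len(r_tabs)
        )

    amyloid_test = paired_wilcoxon(left_suvr, right_suvr, measure="amyloid")
    measure_tests = {
        name: paired_wilcoxon(left_meas[name], right_meas[name], measure=name)
        for name in MEASURES
    }
    return LateralizationReport(
        amyloid_test=amyloid_test,
        measure_tests=measure_tests,
        left_mean_suvr=left_suvr,
        right_mean_suvr=right_suvr,
        left_measures=left_meas,
        right_measures=right_meas,
        difference_matrix=A_l - A_r,
    )
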