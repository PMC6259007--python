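"""Permutation-based comparison of two symptom networks.

Given two independent groups measured on the same items, the test pools
all cases, repeatedly reassigns them at random to groups of the original
sizes, re-estimates both networks per permutation, and compares observed
statistics with their permutation distributions:

* M  — network structure invariance: max over node pairs |w_A - w_B|;
* S  — global strength invariance: |sum|w_A| - sum|w_B|| over pairs;
* global expected influence — the same contrast on *signed* sums;
* per-edge differences, and per-node expected-influence differences.

p-values use the add-one convention (1 + #{perm >= obs}) / (1 + iterations),
so they are never zero.  Per-edge / per-node p-values are uncorrected by
default (Holm adjustment available by flag).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datasets import SymptomDataset, ValidationError
from .ggm import (
    CorrelationMatrix,
    EstimationConfig,
    _estimate_from_correlation,
    correlation,
    nearest_psd_correlation,
    precision_to_partial,
)
from .network import Network

__all__ = [
    "ComparisonConfig",
    "ComparisonResult",
    "stat_structure",
    "stat_global_strength",
    "stat_global_ei",
    "nct",
    "centrality_invariance",
    "balance_groups",
]


@dataclass(frozen=True)
class ComparisonConfig:
    iterations: int = 1000
    seed: int = 0
    estimator: str = "regularized"  # or "unregularized"
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    edge_test_correction: str = "none"  # or "holm"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.estimator not in ("regularized", "unregularized"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.edge_test_correction not in ("none", "holm"):
            raise ValidationError("edge_test_correction must be 'none' or 'holm'")


def _check_labels(net_a: Network, net_b: Network) -> None:
    if net_a.labels != net_b.labels:
        raise ValidationError("networks must share the same node labels and order")


def stat_structure(net_a: Network, net_b: Network) -> float:
    """M: maximum absolute edge difference over all node pairs."""
    _check_labels(net_a, net_b)
    return float(np.abs(net_a.upper_weights() - net_b.upper_weights()).max())


def stat_global_strength(net_a: Network, net_b: Network) -> float:
    """S: absolute difference of the groups' absolute-edge sums."""
    _check_labels(net_a, net_b)
    return float(
        abs(np.abs(net_a.upper_weights()).sum() - np.abs(net_b.upper_weights()).sum())
    )


def stat_global_ei(net_a: Network, net_b: Network) -> float:
    """Global expected influence contrast: |sum w_A - sum w_B| (signed sums)."""
    _check_labels(net_a, net_b)
    return float(abs(net_a.upper_weights().sum() - net_b.upper_weights().sum()))


def _partial_weights(X: np.ndarray, labels, config: ComparisonConfig) -> np.ndarray:
    """Partial-correlation weight matrix of a raw score matrix."""
    n, p = X.shape
    if X.std(axis=0).min() == 0:
        raise ValidationError("constant item in permuted group")
    method = config.estimation.method
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        from scipy import stats as _stats

        R = np.atleast_2d(_stats.spearmanr(X).statistic)
    else:
        raise ValidationError(
            f"correlation method {method!r} is not supported in permutation tests"
        )
    np.fill_diagonal(R, 1.0)
    R, _ = nearest_psd_correlation(R)
    if config.estimator == "unregularized":
        K = np.linalg.pinv(R, hermitian=True)
        return precision_to_partial(K, labels=labels).weights
    S = CorrelationMatrix(
        labels=tuple(labels), values=R, method=config.estimation.method, n=n
    )
    return _estimate_from_correlation(S, config.estimation).network.weights


@dataclass
class ComparisonResult:
    labels: tuple[str, ...]
    n_a: int
    n_b: int
    estimator: str
    iterations: int
    # observed statistics
    m: float
    s_global: float
    global_ei: float
    edge_diffs: np.ndarray  # per-pair |w_A - w_B|, upper-triangle order
    node_ei_diffs: np.ndarray  # per-node |EI_A - EI_B|
    network_a: Network
    network_b: Network
    # permutation p-values
    p_m: float
    p_s_global: float
    p_global_ei: float
    p_edges: np.ndarray
    p_nodes: np.ndarray
    n_failed_iterations: int = 0


def _stats_from_weights(wa: np.ndarray, wb: np.ndarray):
    iu = np.triu_indices(wa.shape[0], k=1)
    ua, ub = wa[iu], wb[iu]
    edge = np.abs(ua - ub)
    m = edge.max()
    s = abs(np.abs(ua).sum() - np.abs(ub).sum())
    ei = abs(ua.sum() - ub.sum())
    node = np.abs(wa.sum(axis=1) - wb.sum(axis=1))
    return m, s, ei, edge, node


def nct(
    data_a: SymptomDataset,
    data_b: SymptomDataset,
    config: ComparisonConfig = ComparisonConfig(),
) -> ComparisonResult:
    """Permutation network comparison test between two independent groups.

    Re-runs the configured estimation pipeline (including EBIC selection for
    the regularized estimator) on every permuted split.  Estimator failures
    in a permutation are re-drawn (counted, capped at 5% of iterations).
    """
    if data_a.items != data_b.items:
        raise ValidationError("groups must be measured on the same item set")
    labels = data_a.items
    Xa = data_a.scores.astype(float)
    Xb = data_b.scores.astype(float)
    na, nb = len(Xa), len(Xb)
    wa = _partial_weights(Xa, labels, config)
    wb = _partial_weights(Xb, labels, config)
    m, s, ei, edge, node = _stats_from_weights(wa, wb)

    pool = np.vstack([Xa, Xb])
    rng = np.random.default_rng(config.seed)
    ge_m = ge_s = ge_ei = 0
    ge_edge = np.zeros_like(edge)
    ge_node = np.zeros_like(node)
    n_failed = 0
    max_failures = max(1, int(0.05 * config.iterations))
    for _ in range(config.iterations):
        while True:
            perm = rng.permutation(na + nb)
            try:
                pa = _partial_weights(pool[perm[:na]], labels, config)
                pb = _partial_weights(pool[perm[na:]], labels, config)
            except Exception:
                n_failed += 1
                if n_failed > max_failures:
                    raise ValidationError(
                        "estimator failed in more than 5% of permutations"
                    )
                continue
            break
        pm, ps, pei, pedge, pnode = _stats_from_weights(pa, pb)
        ge_m += pm >= m
        ge_s += ps >= s
        ge_ei += pei >= ei
        ge_edge += pedge >= edge
        ge_node += pnode >= node
    it = config.iterations
    p_edges = (1.0 + ge_edge) / (1.0 + it)
    p_nodes = (1.0 + ge_node) / (1.0 + it)
    if config.edge_test_correction == "holm":
        p_edges = multipletests(p_edges, method="holm")[1]
        p_nodes = multipletests(p_nodes, method="holm")[1]
    return ComparisonResult(
        labels=labels,
        n_a=na,
        n_b=nb,
        estimator=config.estimator,
        iterations=it,
        m=float(m),
        s_global=float(s),
        global_ei=float(ei),
        edge_diffs=edge,
        node_ei_diffs=node,
        network_a=Network(labels=labels, weights=wa),
        network_b=Network(labels=labels, weights=wb),
        p_m=(1.0 + ge_m) / (1.0 + it),
        p_s_global=(1.0 + ge_s) / (1.0 + it),
        p_global_ei=(1.0 + ge_ei) / (1.0 + it),
        p_edges=p_edges,
        p_nodes=p_nodes,
        n_failed_iterations=n_failed,
    )


def centrality_invariance(
    data_a: SymptomDataset,
    data_b: SymptomDataset,
    config: ComparisonConfig = ComparisonConfig(),
) -> dict[str, float]:
    """Per-node expected-influence invariance p-values (one per node)."""
    res = nct(data_a, data_b, config)
    return dict(zip(res.labels, res.p_nodes.tolist()))


def balance_groups(
    data_a: SymptomDataset, data_b: SymptomDataset, seed: int = 0
) -> tuple[SymptomDataset, SymptomDataset]:
    """Subsample the larger group (without replacement) to the smaller n.

    Addresses the known size-imbalance instability of the permutation test;
    returns the groups in their original order.  Equal sizes are a no-op
    (with a warning).
    """
    na, nb = data_a.n_cases, data_b.n_cases
    if na == nb:
        warnings.warn("groups already balanced; returning inputs unchanged")
        return data_a, data_b
    rng = np.random.default_rng(seed)
    if na > nb:
        rows = np.sort(rng.choice(na, size=nb, replace=False))
        return data_a.subset(rows), data_b
    rows = np.sort(rng.choice(nb, size=na, replace=False))
    return data_a, data_b.subset(rows)
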