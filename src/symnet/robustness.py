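"""Bootstrap robustness checks for estimated networks.

Three procedures, mirroring standard practice in network psychometrics:

* edge-weight accuracy — nonparametric bootstrap (resampling cases with
  replacement), giving per-edge quantile confidence intervals;
* centrality stability — case-dropping bootstrap (subsampling without
  replacement at a grid of drop proportions) and the correlation-stability
  (CS) coefficient: the largest drop proportion at which the correlation
  between subsample and full-sample centralities stays >= 0.7 with 95%
  probability;
* bootstrapped difference tests for pairs of edges or pairs of node
  centralities from the same bootstrap run (no multiple-testing
  correction, matching the source tools' default).

All procedures are deterministic given the seed in :class:`BootstrapConfig`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .centrality import centrality_table
from .datasets import SymptomDataset, ValidationError
from .ggm import EstimationConfig, estimate_network, unregularized_partials
from .network import Network

__all__ = [
    "BootstrapConfig",
    "EdgeBootstrap",
    "StabilityResult",
    "bootstrap_edges",
    "case_dropping",
    "cs_coefficient",
    "difference_test",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 2000
    seed: int = 0
    drop_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    ci_level: float = 0.95
    cs_cor_threshold: float = 0.7
    cs_probability: float = 0.95

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if any(not (0 < q < 0.95) for q in self.drop_proportions):
            raise ValidationError("drop proportions must lie in (0, 0.95)")
        for name in ("ci_level", "cs_cor_threshold", "cs_probability"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")


def _fit_network(data: SymptomDataset, est: EstimationConfig, regularized: bool) -> Network:
    if regularized:
        return estimate_network(data, est).network
    return unregularized_partials(data, est.method)


@dataclass
class EdgeBootstrap:
    """Per-edge bootstrap distributions and CIs, plus node-centrality draws."""

    network: Network
    edge_names: list[tuple[str, str]]
    edge_point: np.ndarray
    edge_draws: np.ndarray  # (B, n_pairs)
    node_draws: dict[str, np.ndarray]  # index -> (B, p)
    ci: pd.DataFrame
    n_retried: int
    config: BootstrapConfig
    run_id: int = field(default_factory=lambda: 0)


def bootstrap_edges(
    data: SymptomDataset,
    est_config: EstimationConfig = EstimationConfig(),
    boot_config: BootstrapConfig = BootstrapConfig(),
    regularized: bool = True,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of edge weights (and node centralities).

    Each replicate resamples ``n_cases`` cases with replacement and re-runs
    the full estimator.  Replicates in which the estimator fails are retried
    with a fresh resample; retries are counted and capped at 5% of B.
    """
    rng = np.random.default_rng(boot_config.seed)
    net0 = _fit_network(data, est_config, regularized)
    point = net0.upper_weights()
    names = net0.edge_labels()
    B, n = boot_config.B, data.n_cases
    edge_draws = np.empty((B, point.size))
    node_draws = {
        "strength": np.empty((B, net0.n_nodes)),
        "expected_influence": np.empty((B, net0.n_nodes)),
    }
    max_retries = max(1, int(0.05 * B))
    n_retried = 0
    for b in range(B):
        while True:
            rows = rng.integers(0, n, size=n)
            try:
                net = _fit_network(data.subset(rows), est_config, regularized)
            except Exception:
                n_retried += 1
                if n_retried > max_retries:
                    raise ValidationError(
                        "estimator failed in more than 5% of bootstrap replicates"
                    )
                continue
            break
        edge_draws[b] = net.upper_weights()
        w = net.weights
        node_draws["strength"][b] = np.abs(w).sum(axis=1)
        node_draws["expected_influence"][b] = w.sum(axis=1)
    alpha = 1.0 - boot_config.ci_level
    lo = np.quantile(edge_draws, alpha / 2, axis=0)
    hi = np.quantile(edge_draws, 1 - alpha / 2, axis=0)
    ci = pd.DataFrame(
        {
            "node_i": [a for a, _ in names],
            "node_j": [b for _, b in names],
            "estimate": point,
            "boot_mean": edge_draws.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeBootstrap(
        network=net0,
        edge_names=names,
        edge_point=point,
        edge_draws=edge_draws,
        node_draws=node_draws,
        ci=ci,
        n_retried=n_retried,
        config=boot_config,
        run_id=boot_config.seed,
    )


@dataclass
class StabilityResult:
    """Case-dropping bootstrap correlations, per index and drop proportion."""

    proportions: tuple[float, ...]
    #: index name -> (n_proportions, B) array of correlations with the
    #: full-sample centralities; NaN marks an undefined (constant) replicate.
    correlations: dict[str, np.ndarray]
    full_centralities: pd.DataFrame
    config: BootstrapConfig


def case_dropping(
    data: SymptomDataset,
    est_config: EstimationConfig = EstimationConfig(),
    boot_config: BootstrapConfig = BootstrapConfig(),
    regularized: bool = True,
    indices: tuple[str, ...] = ("strength", "expected_influence", "closeness", "betweenness"),
) -> StabilityResult:
    """Case-dropping (subsampling) bootstrap of centrality stability.

    For each drop proportion q, B subsamples of round((1-q) n) cases are
    drawn without replacement; each replicate records the Pearson
    correlation between the subsample's node centralities and the
    full-sample centralities.  Proportions whose retained size falls below
    p + 5 are skipped with a warning.  Replicates with a constant
    centrality vector have no defined correlation and are recorded as NaN.
    """
    rng = np.random.default_rng(boot_config.seed)
    net0 = _fit_network(data, est_config, regularized)
    full = centrality_table(net0)
    n, p = data.n_cases, data.n_items
    kept_props = []
    for q in boot_config.drop_proportions:
        if round((1 - q) * n) < p + 5:
            warnings.warn(f"drop proportion {q} skipped: too few retained cases")
            continue
        kept_props.append(q)
    cors = {ix: np.full((len(kept_props), boot_config.B), np.nan) for ix in indices}
    for qi, q in enumerate(kept_props):
        m = round((1 - q) * n)
        for b in range(boot_config.B):
            rows = rng.choice(n, size=m, replace=False)
            try:
                net = _fit_network(data.subset(rows), est_config, regularized)
            except Exception:
                continue  # recorded as NaN
            sub = centrality_table(net)
            for ix in indices:
                x = sub[ix].to_numpy()
                y = full[ix].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    continue
                cors[ix][qi, b] = np.corrcoef(x, y)[0, 1]
    return StabilityResult(
        proportions=tuple(kept_props),
        correlations=cors,
        full_centralities=full,
        config=boot_config,
    )


def cs_coefficient(stability: StabilityResult, index: str = "expected_influence") -> float:
    """Correlation-stability coefficient for one centrality index.

    The largest drop proportion q such that, at q and every smaller tested
    proportion, the lower ``cs_probability`` quantile of the bootstrap
    correlations is >= ``cs_cor_threshold`` ("correlation of 0.7 or greater
    with 95% probability").  Replicates with undefined correlations count
    as failures.  Returns 0.0 if the condition already fails at the
    smallest proportion.
    """
    cfg = stability.config
    cors = stability.correlations[index]
    cs = 0.0
    for qi, q in enumerate(stability.proportions):
        row = np.where(np.isnan(cors[qi]), -1.0, cors[qi])
        lower = np.quantile(row, 1.0 - cfg.cs_probability)
        if lower >= cfg.cs_cor_threshold:
            cs = q
        else:
            break
    return float(cs)


def difference_test(
    boot: EdgeBootstrap,
    kind: str,
    a: tuple[str, str] | str,
    b: tuple[str, str] | str,
    other: EdgeBootstrap | None = None,
) -> dict:
    """Bootstrapped difference test between two edges or two node centralities.

    Both elements must come from the same bootstrap run.  The CI of (a - b)
    at the run's ci_level is formed from the bootstrap draws; the difference
    is "significant" iff the CI excludes zero.  No multiple-testing
    correction is applied.
    """
    if other is not None and other.run_id != boot.run_id:
        raise ValidationError("elements must come from the same bootstrap run")
    if kind == "edge":
        names = {tuple(nm): k for k, nm in enumerate(boot.edge_names)}
        def col(e):
            e = tuple(e)
            if e not in names and (e[1], e[0]) in names:
                e = (e[1], e[0])
            if e not in names:
                raise ValidationError(f"unknown edge {e!r}")
            return boot.edge_draws[:, names[e]], boot.edge_point[names[e]]
        da, pa = col(a)
        db, pb = col(b)
    elif kind in ("strength", "expected_influence"):
        labels = boot.network.labels
        ia, ib = labels.index(a), labels.index(b)
        draws = boot.node_draws[kind]
        da, db = draws[:, ia], draws[:, ib]
        full = boot.network.weights
        pa = float(np.abs(full[ia]).sum()) if kind == "strength" else float(full[ia].sum())
        pb = float(np.abs(full[ib]).sum()) if kind == "strength" else float(full[ib].sum())
    else:
        raise ValidationError(f"unknown element kind {kind!r}")
    diff = da - db
    alpha = 1.0 - boot.config.ci_level
    lo = float(np.quantile(diff, alpha / 2))
    hi = float(np.quantile(diff, 1 - alpha / 2))
    return {
        "difference": float(pa - pb),
        "ci": (lo, hi),
        "significant": bool(lo > 0.0 or hi < 0.0),
    }
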