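"""Gaussian graphical model estimation for ordinal symptom data.

Pipeline: sample correlation matrix (Pearson by default, Spearman or
polychoric by flag) -> graphical lasso solved along a log-spaced penalty
path -> EBIC model selection -> partial-correlation network.

The graphical lasso maximizes the penalized Gaussian log-likelihood

    log det K - trace(S K) - lambda * sum_{i != j} |k_ij|

over positive-definite precision matrices K, via block coordinate descent
(one lasso subproblem per column of the working covariance).  The diagonal
is not penalized, so the working covariance keeps diag(W) = diag(S).  Edge
weights are the partial correlations rho_ij = -k_ij / sqrt(k_ii * k_jj).

Model selection uses the extended BIC,

    EBIC = -2 loglik + E log n + 4 E gamma log p,

where E is the number of nonzero upper-triangle precision entries and
gamma (default 0.5) controls the sparsity bias of the selection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit
from scipy import optimize, stats

from .datasets import SymptomDataset, ValidationError
from .network import Network

__all__ = [
    "EstimationConfig",
    "CorrelationMatrix",
    "NetworkFit",
    "correlation",
    "polychoric",
    "glasso",
    "precision_to_partial",
    "ebic",
    "estimate_network",
    "unregularized_partials",
    "mean_edge_weight",
    "layout_fruchterman_reingold",
    "nearest_psd_correlation",
]

#: estimated edges with |rho| below this are clamped to exactly zero, making
#: "edge present" well defined.
EDGE_CLAMP = 1e-10


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge within its iteration budget."""


@dataclass(frozen=True)
class EstimationConfig:
    """Hyperparameters of the regularized network estimator.

    gamma: EBIC sparsity parameter (>= 0; 0 reduces EBIC to BIC).
    n_lambda: length of the log-spaced penalty path.
    lambda_min_ratio: smallest penalty as a fraction of lambda_max.
    method: input correlation, one of {"pearson", "spearman", "polychoric"}.
    """

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    method: str = "pearson"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValidationError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValidationError("lambda_min_ratio must lie in (0, 1)")
        if self.method not in ("pearson", "spearman", "polychoric"):
            raise ValidationError(f"unknown correlation method {self.method!r}")


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with provenance."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str
    n: int
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        self.values = (v + v.T) / 2.0


@dataclass
class NetworkFit:
    """Selected network plus the full EBIC path trace."""

    network: Network
    lambda_selected: float
    #: rows of (lambda, loglik, n_edges, ebic) in path (decreasing-lambda) order
    ebic_path: np.ndarray = field(repr=False)
    correlation: CorrelationMatrix = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# correlations


def nearest_psd_correlation(R: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues to ``floor`` and rescale to unit diagonal.

    Returns the repaired matrix and a flag saying whether repair was needed.
    Idempotent: a PSD matrix is returned unchanged (up to symmetrization).
    """
    R = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -1e-12:  # already PSD (up to numerical noise)
        return R, False
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0, True


def correlation(data: SymptomDataset, method: str = "pearson") -> CorrelationMatrix:
    """Item-by-item correlation matrix of a symptom dataset.

    Zero-variance items are an error (the item is named); matrices that are
    not positive semi-definite (possible for pairwise polychoric) are
    repaired by eigenvalue clipping and flagged.
    """
    X = data.scores.astype(float)
    n, p = X.shape
    if n < p + 1:
        warnings.warn(
            f"n_cases={n} < n_items+1={p + 1}: correlation matrix may be singular",
            stacklevel=2,
        )
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = data.items[int(np.argmin(sd))]
        raise ValidationError(f"item {bad!r} has zero variance")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        R = stats.spearmanr(X).statistic
        R = np.atleast_2d(R)
    elif method == "polychoric":
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                R[i, j] = R[j, i] = polychoric(X[:, i], X[:, j])
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    np.fill_diagonal(R, 1.0)
    R, repaired = nearest_psd_correlation(R)
    return CorrelationMatrix(
        labels=data.items, values=R, method=method, n=n, psd_repaired=repaired
    )


def _thresholds(x: np.ndarray) -> np.ndarray:
    """Normal-quantile thresholds from the marginal cumulative frequencies."""
    levels, counts = np.unique(x, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("polychoric requires >= 2 observed categories")
    cum = np.cumsum(counts)[:-1] / x.size
    return stats.norm.ppf(cum)


def polychoric(item_x: np.ndarray, item_y: np.ndarray, bound: float = 0.999) -> float:
    """Two-step maximum-likelihood polychoric correlation of two ordinal items.

    Step 1 fixes the latent thresholds at the normal quantiles of the
    marginal cumulative frequencies; step 2 maximizes the bivariate-normal
    cell likelihood over the latent correlation rho on (-bound, bound).
    """
    x = np.asarray(item_x).ravel()
    y = np.asarray(item_y).ravel()
    if x.size != y.size:
        raise ValidationError("items must have equal length")
    tx = _thresholds(x)
    ty = _thresholds(y)
    # observed contingency table over the category grid
    xl = np.unique(x)
    yl = np.unique(y)
    table = np.zeros((len(xl), len(yl)))
    for i, xv in enumerate(xl):
        mask = x == xv
        for j, yv in enumerate(yl):
            table[i, j] = np.count_nonzero(y[mask] == yv)
    if np.count_nonzero(table) <= 1:
        raise ValidationError("degenerate table: all mass in one cell")
    # grid of upper-corner CDF evaluation points (finite stand-in for +inf)
    BIG = 10.0
    bx = np.concatenate([tx, [BIG]])
    by = np.concatenate([ty, [BIG]])
    pts = np.array([[a, b] for a in bx for b in by])

    def cell_probs(rho: float) -> np.ndarray:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        F = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf(pts)
        F = F.reshape(len(bx), len(by))
        Fp = np.zeros((len(bx) + 1, len(by) + 1))
        Fp[1:, 1:] = F
        cells = Fp[1:, 1:] - Fp[:-1, 1:] - Fp[1:, :-1] + Fp[:-1, :-1]
        return np.clip(cells, 1e-12, None)

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(cell_probs(rho))))

    res = optimize.minimize_scalar(
        nll, bounds=(-bound, bound), method="bounded", options={"xatol": 1e-5}
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# graphical lasso


@njit(cache=False)
def _glasso_cd(S, lam, W, B, max_outer, outer_tol, max_inner, inner_tol):
    """Block coordinate descent for the off-diagonal-penalized graphical lasso.

    W and B are modified in place (enables warm starts along a penalty path).
    Returns (K, n_outer_iterations, converged_flag).
    """
    p = S.shape[0]
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    b = np.empty(p - 1)
    it = 0
    converged = False
    for it in range(1, max_outer + 1):
        max_d = 0.0
        for j in range(p):
            r = 0
            for a in range(p):
                if a == j:
                    continue
                s12[r] = S[a, j]
                b[r] = B[r, j]
                c = 0
                for bb in range(p):
                    if bb == j:
                        continue
                    W11[r, c] = W[a, bb]
                    c += 1
                r += 1
            # lasso: min 0.5 b'W11 b - s12'b + lam |b|_1
            for _ in range(max_inner):
                delta = 0.0
                for k in range(p - 1):
                    g = s12[k]
                    for m in range(p - 1):
                        if m != k:
                            g -= W11[k, m] * b[m]
                    if g > lam:
                        bn = (g - lam) / W11[k, k]
                    elif g < -lam:
                        bn = (g + lam) / W11[k, k]
                    else:
                        bn = 0.0
                    d = abs(bn - b[k])
                    if d > delta:
                        delta = d
                    b[k] = bn
                if delta < inner_tol:
                    break
            for k in range(p - 1):
                B[k, j] = b[k]
            r = 0
            for a in range(p):
                if a == j:
                    continue
                w = 0.0
                for m in range(p - 1):
                    w += W11[r, m] * b[m]
                d = abs(w - W[a, j])
                if d > max_d:
                    max_d = d
                W[a, j] = w
                W[j, a] = w
                r += 1
        if max_d < outer_tol:
            converged = True
            break
    # recover the precision matrix from W and the column regressions
    K = np.empty((p, p))
    for j in range(p):
        dot = 0.0
        r = 0
        for a in range(p):
            if a == j:
                continue
            dot += W[a, j] * B[r, j]
            r += 1
        k22 = 1.0 / (W[j, j] - dot)
        K[j, j] = k22
        r = 0
        for a in range(p):
            if a == j:
                continue
            K[a, j] = -B[r, j] * k22
            r += 1
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, it, converged


def glasso(
    S: np.ndarray | CorrelationMatrix,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-8,
    inner_tol: float = 1e-10,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """L1-penalized precision matrix for correlation input ``S``.

    Only off-diagonal entries are penalized.  ``warm`` may carry (W, B) state
    from a previous solve at a nearby penalty; both arrays are updated in
    place, which is how the path estimator warm-starts.
    """
    Sm = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    p = Sm.shape[0]
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if warm is None:
        W = Sm.copy()
        B = np.zeros((p - 1, p))
    else:
        W, B = warm
    scale = max(np.mean(np.abs(Sm - np.diag(np.diag(Sm)))), 1e-12)
    K, n_iter, converged = _glasso_cd(
        Sm, float(lam), W, B, max_iter, tol * scale, 200, inner_tol
    )
    if not converged:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(lambda={lam:.4g}, p={p})"
        )
    return K


def precision_to_partial(K: np.ndarray, labels=None) -> Network:
    """Partial-correlation network from a precision matrix.

    rho_ij = -k_ij / sqrt(k_ii * k_jj); diagonal set to zero.
    """
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValidationError("precision matrix has a non-positive diagonal entry")
    denom = np.sqrt(np.outer(d, d))
    W = -K / denom
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    W = np.clip(W, -1.0, 1.0)
    W[np.abs(W) < EDGE_CLAMP] = 0.0
    if labels is None:
        labels = tuple(f"V{i + 1}" for i in range(K.shape[0]))
    return Network(labels=tuple(labels), weights=W)


def ebic(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2 loglik + E log n + 4 E gamma log p."""
    if n <= 0 or p <= 1 or n_edges < 0:
        raise ValidationError("require n > 0, p > 1, n_edges >= 0")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def _gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValidationError("precision estimate is not positive definite")
    p = S.shape[0]
    return 0.5 * n * (logdet - np.trace(S @ K) - p * np.log(2 * np.pi))


def estimate_network(
    data: SymptomDataset, config: EstimationConfig = EstimationConfig()
) -> NetworkFit:
    """EBIC-selected regularized partial-correlation network of a dataset.

    The penalty path is ``n_lambda`` log-spaced values running from
    lambda_max = max off-diagonal |S| down to lambda_max * lambda_min_ratio;
    solutions are warm-started along the path.  The fit whose EBIC is lowest
    is returned (ties broken toward the sparser, larger-penalty fit).
    """
    S = correlation(data, config.method)
    return _estimate_from_correlation(S, config)


def _estimate_from_correlation(
    S: CorrelationMatrix, config: EstimationConfig
) -> NetworkFit:
    Sm = S.values
    p = Sm.shape[0]
    off = np.abs(Sm - np.diag(np.diag(Sm)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-4  # perfectly diagonal input: degenerate but legal
    path = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
    W = Sm.copy()
    B = np.zeros((p - 1, p))
    records = np.empty((config.n_lambda, 4))
    best = None
    # path solves warm-start from the previous penalty; model selection does
    # not need the oracle-grade tolerance of a standalone glasso() call
    for k, lam in enumerate(path):
        K = glasso(Sm, lam, tol=1e-5, inner_tol=1e-8, warm=(W, B))
        Koff = K - np.diag(np.diag(K))
        n_edges = int(np.count_nonzero(np.abs(np.triu(Koff)) > EDGE_CLAMP))
        ll = _gaussian_loglik(Sm, K, S.n)
        crit = ebic(ll, n_edges, S.n, p, config.gamma)
        records[k] = (lam, ll, n_edges, crit)
        if best is None or crit < best[1] - 1e-12:
            best = (k, crit, K.copy())
    k_sel, _, K_sel = best
    net = precision_to_partial(K_sel, labels=S.labels)
    net.meta.update(
        method=S.method,
        n=S.n,
        gamma=config.gamma,
        lambda_selected=float(path[k_sel]),
        psd_repaired=S.psd_repaired,
    )
    return NetworkFit(
        network=net,
        lambda_selected=float(path[k_sel]),
        ebic_path=records,
        correlation=S,
    )


def unregularized_partials(
    data_or_corr: SymptomDataset | CorrelationMatrix, method: str = "pearson"
) -> Network:
    """Partial correlations by direct (pseudo-)inversion of the correlation
    matrix — the lambda = 0 estimator used for sensitivity analyses."""
    S = (
        data_or_corr
        if isinstance(data_or_corr, CorrelationMatrix)
        else correlation(data_or_corr, method)
    )
    K = np.linalg.pinv(S.values, hermitian=True)
    net = precision_to_partial(K, labels=S.labels)
    net.meta.update(method=S.method, n=S.n, lambda_selected=0.0)
    return net


def mean_edge_weight(network: Network, include_zeros: bool = True) -> float:
    """Mean of the p(p-1)/2 upper-triangle edge weights.

    By default structural zeros count in the denominator (a per-pair
    average); ``include_zeros=False`` averages over present edges only.
    """
    if network.n_nodes < 2:
        raise ValidationError("mean edge weight needs at least two nodes")
    w = network.upper_weights()
    if not include_zeros:
        w = w[w != 0.0]
        if w.size == 0:
            return 0.0
    return float(w.mean())


def layout_fruchterman_reingold(
    network: Network, seed: int = 0, iterations: int = 100
) -> dict[str, np.ndarray]:
    """Force-directed node coordinates; |weight| acts as attraction strength.

    Deterministic for a fixed seed.  A single node sits at the origin.
    """
    g = network.to_graph()
    for _, _, d in g.edges(data=True):
        d["abs_weight"] = abs(d["weight"])
    if network.n_nodes == 1:
        return {network.labels[0]: np.zeros(2)}
    pos = nx.spring_layout(
        g, weight="abs_weight", seed=seed, iterations=iterations
    )
    return {lab: np.asarray(pos[lab], dtype=float) for lab in network.labels}
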