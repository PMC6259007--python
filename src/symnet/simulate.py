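"""Synthetic ordinal symptom data with known network structure.

The generator is a Gaussian copula: a latent multivariate normal with
covariance implied by a target sparse partial-correlation matrix is
discretized through per-item thresholds into 0-4 severity scores.
Thresholds are chosen by inverse-CDF matching of target category means
(a discretized-normal marginal whose mean equals the published item mean
exactly), so simulated marginals emulate the published subgroup tables.

The 17-node presets mimic the structure reported for veteran PTSD symptom
networks: a dense positive backbone (symptom data have a strong general
factor, which is what pushes nodewise predictability toward ~50%), marquee
edges between hypervigilance/startle (E3:E4), the two avoidance items
(C1:C2), loss of interest/detachment (D5:D6) and detachment/restricted
affect (D6:D7), and a weakly connected trauma-amnesia node (D1).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .datasets import PTSD17_ITEMS, SymptomDataset, ValidationError

__all__ = [
    "ScenarioSpec",
    "build_precision",
    "latent_correlation",
    "thresholds_for_moments",
    "sample_latent",
    "sample_ordinal",
    "two_group_scenario",
    "preset_ptsd17",
    "table1_fixture",
    "Table1Fixture",
]

N_CATEGORIES = 5


@dataclass
class ScenarioSpec:
    """Generative description of one synthetic symptom-data group.

    partials: target partial-correlation matrix (symmetric, zero diagonal).
    thresholds: (p, 4) strictly increasing latent cut-points per item.
    n: cases per group.  connectivity_scale: multiplier applied to the
    second group's partials in two-group designs.
    """

    items: tuple[str, ...]
    partials: np.ndarray
    thresholds: np.ndarray
    n: int = 500
    connectivity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        P = np.asarray(self.partials, dtype=float)
        p = len(self.items)
        if P.shape != (p, p) or not np.allclose(P, P.T):
            raise ValidationError("partials must be a symmetric p x p matrix")
        if np.any(np.diag(P) != 0):
            raise ValidationError("partials must have zero diagonal")
        if np.any(np.abs(P) >= 1):
            raise ValidationError("|partial| must be < 1")
        self.partials = (P + P.T) / 2.0
        T = np.asarray(self.thresholds, dtype=float)
        if T.shape != (p, N_CATEGORIES - 1):
            raise ValidationError(f"thresholds must be (p, {N_CATEGORIES - 1})")
        if np.any(np.diff(T, axis=1) <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        self.thresholds = T
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.connectivity_scale < 0:
            raise ValidationError("connectivity_scale must be >= 0")


def build_precision(
    partials: np.ndarray, eig_floor: float = 1e-3, max_inflation: float = 20.0
) -> tuple[np.ndarray, float]:
    """Precision matrix whose partial correlations are (a scaling of) the target.

    Sets k_ii = 1 and k_ij = -rho_ij; if the result is not positive definite
    the diagonal is inflated uniformly (k_ii = 1 + tau) until the smallest
    eigenvalue reaches ``eig_floor``.  Returns (K, factor) where ``factor``
    = 1/(1 + tau) <= 1 is the scaling the achieved partials carry relative
    to the targets.
    """
    P = np.asarray(partials, dtype=float)
    p = P.shape[0]
    K = np.eye(p) - P
    ev_min = float(np.linalg.eigvalsh(K).min())
    tau = 0.0
    if ev_min < eig_floor:
        tau = eig_floor - ev_min
        if 1.0 + tau > max_inflation:
            raise ValidationError(
                "partials admit no positive-definite completion within the "
                f"inflation budget (needed diagonal {1 + tau:.2f})"
            )
        K = (1.0 + tau) * np.eye(p) - P
    return K, 1.0 / (1.0 + tau)


def latent_correlation(K: np.ndarray) -> np.ndarray:
    """Correlation matrix of the latent Gaussian implied by precision K."""
    Sig = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sig))
    C = Sig / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def _discretized_normal_mean(mu: float, sd: float) -> float:
    cuts = (np.arange(N_CATEGORIES - 1) + 0.5 - mu) / sd
    cdf = stats.norm.cdf(cuts)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return float(probs @ np.arange(N_CATEGORIES))


def thresholds_for_moments(mean: float, sd: float) -> np.ndarray:
    """Latent cut-points whose discretized-normal marginal has the target mean.

    The category distribution is a normal with the target SD discretized at
    half-integer boundaries; its location is root-solved so the implied
    categorical mean equals ``mean`` exactly, then the cumulative category
    probabilities are mapped to standard-normal quantiles.
    """
    if not (0.0 < mean < N_CATEGORIES - 1):
        raise ValidationError("target mean must lie strictly inside (0, 4)")
    if sd <= 0:
        raise ValidationError("target sd must be > 0")
    mu = optimize.brentq(
        lambda m: _discretized_normal_mean(m, sd) - mean, -10.0, 14.0, xtol=1e-12
    )
    cuts = (np.arange(N_CATEGORIES - 1) + 0.5 - mu) / sd
    cum = np.clip(stats.norm.cdf(cuts), 1e-12, 1 - 1e-12)
    return stats.norm.ppf(cum)


def _rng_for(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def sample_latent(spec: ScenarioSpec, rng=None) -> np.ndarray:
    """Continuous latent draws (n, p) from the implied Gaussian model."""
    rng = _rng_for(spec.seed) if rng is None else rng
    K, _ = build_precision(spec.partials)
    C = latent_correlation(K)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    Z = rng.standard_normal((spec.n, len(spec.items)))
    return Z @ L.T


def sample_ordinal(spec: ScenarioSpec, rng=None) -> SymptomDataset:
    """One group of ordinal 0-4 scores drawn from the scenario's copula."""
    Z = sample_latent(spec, rng=rng)
    p = len(spec.items)
    X = np.empty_like(Z, dtype=np.int64)
    for i in range(p):
        X[:, i] = np.searchsorted(spec.thresholds[i], Z[:, i])
    return SymptomDataset(items=spec.items, scores=X, meta={"seed": spec.seed})


def two_group_scenario(spec: ScenarioSpec) -> tuple[SymptomDataset, SymptomDataset]:
    """Two independent groups: A from the base partials, B from the base
    partials multiplied by ``connectivity_scale``.

    Child seeds are spawned from the master seed (numpy SeedSequence), so
    group A's draws do not depend on whether group B is generated.
    """
    scaled = spec.partials * spec.connectivity_scale
    build_precision(scaled)  # raises if the scaled matrix has no PD completion
    child_a, child_b = np.random.SeedSequence(spec.seed).spawn(2)
    a = sample_ordinal(replace(spec, seed=spec.seed), rng=_rng_for(child_a))
    spec_b = replace(spec, partials=scaled, seed=spec.seed)
    b = sample_ordinal(spec_b, rng=_rng_for(child_b))
    a.group = np.repeat("A", a.n_cases)
    b.group = np.repeat("B", b.n_cases)
    return a, b


# ---------------------------------------------------------------------------
# 17-node PTSD-like presets

_IDX = {k: i for i, k in enumerate(PTSD17_ITEMS)}
_CLUSTER = {k: k[0] for k in PTSD17_ITEMS}

#: dense positive backbone on two-thirds of the non-D1 pairs
_BACKGROUND = 0.0725
#: extra weight for pairs inside the same DSM-IV cluster (B, C, D, E)
_WITHIN_BOOST = 0.032
#: trauma-related amnesia keeps only two weak links (least-central node)
_D1_EDGES = {"B3": 0.16, "C1": 0.16}
#: marquee symptom pairs reported as the strongest edges across subgroups
_MARQUEE = {
    ("E3", "E4"): 0.30,
    ("C1", "C2"): 0.28,
    ("D5", "D6"): 0.25,
    ("D6", "D7"): 0.23,
    ("B2", "B3"): 0.20,
    ("B1", "E1"): 0.10,
    ("B5", "E2"): 0.12,
    ("B5", "E3"): 0.12,
}
#: in the high-combat preset the intrusive-thoughts/irritability edge is elevated
_HIGH_COMBAT_B1E1 = 0.28

#: published per-item means and SDs by subgroup (the marginal targets)
_TABLE2_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "subthreshold": {
        "B1": (1.38, 1.20), "B2": (1.26, 1.36), "B3": (1.02, 1.35),
        "B4": (1.23, 1.28), "B5": (1.02, 1.30), "C1": (0.92, 1.17),
        "C2": (0.84, 1.20), "D1": (0.47, 0.95), "D5": (1.03, 1.22),
        "D6": (1.27, 1.36), "D7": (1.07, 1.32), "E1": (1.57, 1.30),
        "E2": (0.86, 1.26), "E3": (1.63, 1.43), "E4": (1.42, 1.41),
        "E5": (1.55, 1.45), "E6": (2.22, 1.43),
    },
    "clinical": {
        "B1": (2.35, 1.18), "B2": (2.22, 1.38), "B3": (2.16, 1.46),
        "B4": (2.25, 1.29), "B5": (2.22, 1.40), "C1": (2.06, 1.39),
        "C2": (1.99, 1.45), "D1": (1.37, 1.49), "D5": (2.37, 1.38),
        "D6": (2.47, 1.36), "D7": (2.23, 1.47), "E1": (2.25, 1.42),
        "E2": (1.89, 1.50), "E3": (2.62, 1.25), "E4": (2.37, 1.31),
        "E5": (2.57, 1.28), "E6": (2.92, 1.22),
    },
    "low_combat": {
        "B1": (2.35, 1.21), "B2": (2.27, 1.46), "B3": (2.05, 1.54),
        "B4": (2.15, 1.38), "B5": (2.19, 1.47), "C1": (2.09, 1.39),
        "C2": (1.95, 1.50), "D1": (1.29, 1.51), "D5": (2.28, 1.45),
        "D6": (2.38, 1.42), "D7": (2.07, 1.50), "E1": (2.25, 1.43),
        "E2": (1.91, 1.54), "E3": (2.60, 1.30), "E4": (2.39, 1.37),
        "E5": (2.44, 1.31), "E6": (2.84, 1.23),
    },
    "high_combat": {
        "B1": (2.69, 1.17), "B2": (2.70, 1.33), "B3": (2.44, 1.51),
        "B4": (2.51, 1.33), "B5": (2.55, 1.36), "C1": (2.40, 1.40),
        "C2": (2.32, 1.51), "D1": (1.53, 1.57), "D5": (2.65, 1.29),
        "D6": (2.80, 1.27), "D7": (2.57, 1.42), "E1": (2.63, 1.32),
        "E2": (2.12, 1.58), "E3": (2.89, 1.16), "E4": (2.70, 1.26),
        "E5": (2.76, 1.25), "E6": (3.15, 1.11),
    },
}

_PRESET_N = {"subthreshold": 138, "clinical": 138, "low_combat": 639, "high_combat": 273}


def preset_partials(group: str = "clinical") -> np.ndarray:
    """The 17-node base partial-correlation matrix of the presets."""
    p = len(PTSD17_ITEMS)
    P = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = PTSD17_ITEMS[i], PTSD17_ITEMS[j]
            if a == "D1" or b == "D1":
                continue
            if (i + j) % 3 == 0:
                continue  # deterministic true-zero pattern
            w = _BACKGROUND
            if _CLUSTER[a] == _CLUSTER[b]:
                w += _WITHIN_BOOST
            P[i, j] = P[j, i] = w
    for other, w in _D1_EDGES.items():
        i, j = _IDX["D1"], _IDX[other]
        P[i, j] = P[j, i] = w
    marquee = dict(_MARQUEE)
    if group == "high_combat":
        marquee[("B1", "E1")] = _HIGH_COMBAT_B1E1
    for (a, b), w in marquee.items():
        i, j = _IDX[a], _IDX[b]
        P[i, j] = P[j, i] = max(P[i, j], w)
    return P


def preset_ptsd17(group: str = "clinical", n: int | None = None, seed: int = 0) -> ScenarioSpec:
    """17-node scenario emulating one published veteran subgroup.

    ``group`` is one of ``clinical`` (the full-criteria sample),
    ``subthreshold``, ``low_combat`` or ``high_combat``.  Thresholds match
    the subgroup's published item means exactly (in expectation); the base
    partials carry the marquee edges with E3:E4 the strongest, and D1 as the
    weakly connected node.
    """
    if group not in _TABLE2_MOMENTS:
        raise ValidationError(
            f"unknown preset {group!r}; choose from {sorted(_TABLE2_MOMENTS)}"
        )
    moments = _TABLE2_MOMENTS[group]
    T = np.vstack([thresholds_for_moments(*moments[item]) for item in PTSD17_ITEMS])
    return ScenarioSpec(
        items=PTSD17_ITEMS,
        partials=preset_partials(group),
        thresholds=T,
        n=n if n is not None else _PRESET_N[group],
        seed=seed,
    )


#: heterogeneous strong 8-node structure used for stability demonstrations:
#: a weighted ring with chords, giving well-separated node centralities that
#: subsamples can recover almost exactly at large n ("near-noiseless" data).
_STRONG8_EDGES = {
    (0, 1): 0.40, (1, 2): 0.34, (2, 3): 0.30, (3, 4): 0.26,
    (4, 5): 0.22, (5, 6): 0.30, (6, 7): 0.36, (0, 3): 0.18,
    (1, 5): 0.14, (2, 6): 0.12, (0, 7): 0.10, (4, 7): 0.16,
}


def preset_strong8(n: int = 10000, seed: int = 0) -> ScenarioSpec:
    """Small, strongly connected scenario with heterogeneous edge weights.

    Useful for stability studies: at large n the estimated centralities are
    nearly noiseless, so case-dropping correlations stay high at every
    tested proportion.
    """
    p = 8
    P = np.zeros((p, p))
    for (i, j), w in _STRONG8_EDGES.items():
        P[i, j] = P[j, i] = w
    thr = np.tile(thresholds_for_moments(2.0, 1.3), (p, 1))
    return ScenarioSpec(
        items=tuple(f"V{i + 1}" for i in range(p)),
        partials=P,
        thresholds=thr,
        n=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# published demographics (typed fixture, no recomputation)


@dataclass(frozen=True)
class SummaryRecord:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CountPair:
    a: int  # first-listed group count
    b: int  # second-listed group count


@dataclass(frozen=True)
class Table1Fixture:
    """The published demographic summaries, transcribed as typed records.

    Top comparison: subthreshold (n=138) vs full-criteria (n=912).
    Bottom comparison: low (CES<25, n=639) vs high (CES>25, n=273) combat.
    """

    age: dict
    ces: dict
    dts: dict
    gender: dict
    race: dict


def table1_fixture() -> Table1Fixture:
    return Table1Fixture(
        age={
            "entire": SummaryRecord(36.33, 9.53, 1050),
            "subthreshold": SummaryRecord(36.82, 9.31, 138),
            "full": SummaryRecord(36.25, 9.57, 912),
            "low_combat": SummaryRecord(37.00, 9.66, 639),
            "high_combat": SummaryRecord(34.5, 9.14, 273),
        },
        ces={
            "entire": SummaryRecord(17.13, 10.48, 1050),
            "subthreshold": SummaryRecord(12.54, 9.62, 138),
            "full": SummaryRecord(17.83, 10.44, 912),
            "low_combat": SummaryRecord(12.56, 7.51, 639),
            "high_combat": SummaryRecord(30.16, 3.86, 273),
        },
        dts={
            "entire": SummaryRecord(36.92, 17.7, 1050),
            "subthreshold": SummaryRecord(20.38, 13.89, 138),
            "full": SummaryRecord(39.36, 16.87, 912),
            "low_combat": SummaryRecord(37.59, 17.11, 639),
            "high_combat": SummaryRecord(43.48, 15.55, 273),
        },
        gender={
            # female / male counts per group
            "subthreshold": {"female": 29, "male": 109},
            "full": {"female": 170, "male": 742},
            "low_combat": {"female": 151, "male": 488},
            "high_combat": {"female": 19, "male": 254},
        },
        race={
            # caucasian / non-caucasian counts per group
            "subthreshold": {"caucasian": 57, "non_caucasian": 81},
            "full": {"caucasian": 444, "non_caucasian": 468},
            "low_combat": {"caucasian": 275, "non_caucasian": 364},
            "high_combat": {"caucasian": 169, "non_caucasian": 104},
        },
    )
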