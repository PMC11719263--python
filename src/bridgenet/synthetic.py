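"""Synthetic ordinal survey data with a known partial-correlation truth.

The generative model is a latent multivariate Gaussian whose precision matrix
encodes a sparse two-community conditional-dependence structure (lifestyle
vs health-outcome items, optionally joined by bridge edges).  Each latent
coordinate is discretised through per-item cutpoints into a 5-point Likert
response.  Because the truth is known exactly, the estimation, redundancy,
centrality and stability stages can all be validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_survey import Codebook, ItemSpec, SurveyMatrix

_PD_EPS = 1e-8


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-item cutpoints slicing the latent scale into 5 ordered categories.

    ``cutpoints`` has shape (p, 4) and each row is strictly increasing.  The
    default slices the standard normal into equal 20% masses; shifted rows
    produce skewed category distributions like those seen in real surveys.
    """

    cutpoints: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.cutpoints, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 4:
            raise ValueError("cutpoints must have shape (p, 4)")
        if not (np.diff(cp, axis=1) > 0).all():
            raise ValueError("each item's cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", cp)

    @property
    def p(self) -> int:
        return self.cutpoints.shape[0]

    @classmethod
    def equal_mass(cls, p: int) -> "ThresholdScheme":
        """Equal-probability cutpoints: every category has 20% mass."""
        row = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
        return cls(np.tile(row, (p, 1)))

    @classmethod
    def skewed(cls, p: int, seed: int = 0, shift_range: tuple[float, float] = (-0.8, 0.6)) -> "ThresholdScheme":
        """Shifted cutpoints yielding item means roughly in the 2.6-3.9 band."""
        rng = np.random.default_rng(seed)
        base = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
        shifts = rng.uniform(*shift_range, size=p)
        return cls(base[None, :] + shifts[:, None])

    def category_probabilities(self) -> np.ndarray:
        """(p, 5) matrix of implied marginal category masses."""
        cdf = stats.norm.cdf(self.cutpoints)
        return np.diff(np.concatenate([np.zeros((self.p, 1)), cdf, np.ones((self.p, 1))], axis=1))


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Known population structure: sparse partial correlations over two communities."""

    partial_corr: np.ndarray
    community: tuple[str, ...]
    item_ids: tuple[str, ...]
    bridge_edges: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.partial_corr, dtype=float)
        if P.shape[0] != P.shape[1]:
            raise ValueError("partial_corr must be square")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("partial_corr must be symmetric")
        if np.any(np.abs(np.diag(P)) > 0):
            raise ValueError("partial_corr must have zero diagonal")
        if np.any(np.abs(P) >= 1):
            raise ValueError("partial correlations must lie in (-1, 1)")
        object.__setattr__(self, "partial_corr", P)
        if np.linalg.eigvalsh(self.precision()).min() <= _PD_EPS:
            raise ValueError("implied precision matrix is not positive definite")

    @property
    def p(self) -> int:
        return self.partial_corr.shape[0]

    def precision(self) -> np.ndarray:
        """Unit-diagonal precision matrix implied by the partial correlations."""
        return np.eye(self.p) - self.partial_corr

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent Gaussian (normalised precision inverse)."""
        sigma = np.linalg.inv(self.precision())
        d = np.sqrt(np.diag(sigma))
        return sigma / np.outer(d, d)

    def edge_set(self, tol: float = 0.0) -> set[tuple[int, int]]:
        i, j = np.triu_indices(self.p, k=1)
        nz = np.abs(self.partial_corr[i, j]) > tol
        return set(zip(i[nz].tolist(), j[nz].tolist()))

    def codebook(self) -> Codebook:
        return Codebook(
            tuple(
                ItemSpec(id=i, community=c, description=f"synthetic item {i}")
                for i, c in zip(self.item_ids, self.community)
            )
        )


def _enforce_pd(P: np.ndarray, max_retries: int = 30) -> np.ndarray:
    """Shrink off-diagonal weights toward diagonal dominance until PD."""
    K = np.eye(P.shape[0]) - P
    if np.linalg.eigvalsh(K).min() > _PD_EPS:
        return P
    row = np.abs(P).sum(axis=1).max()
    if row >= 1:
        # one-shot diagonal dominance rescaling, then geometric retries
        P = P * (0.95 / row)
    for _ in range(max_retries):
        K = np.eye(P.shape[0]) - P
        if np.linalg.eigvalsh(K).min() > _PD_EPS:
            return P
        P = P * 0.9
    raise ValueError("could not rescale partial correlations to a positive-definite precision")


def generate_true_network(
    p_lifestyle: int = 15,
    p_outcome: int = 13,
    within_density: float = 0.2,
    n_bridge: int = 3,
    weight_range: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
    bridge_edges: list[tuple[str, str, float]] | None = None,
    extra_edges: list[tuple[str, str, float]] | None = None,
) -> TrueNetworkSpec:
    """Draw a sparse two-community partial-correlation truth.

    Within-community edges appear independently with probability
    ``within_density``; exactly ``n_bridge`` cross-community edges are placed
    uniformly at random unless an explicit ``bridge_edges`` list is given.
    ``extra_edges`` pins additional (item, item, weight) entries, e.g. to
    plant a hub.  Positive definiteness is enforced by shrinking all weights
    toward diagonal dominance; declared zeros stay exact zeros.
    """
    if not (0 <= within_density <= 1):
        raise ValueError("within_density must lie in [0, 1]")
    lo, hi = weight_range
    if not (0 < lo <= hi < 1):
        raise ValueError("weight_range must be a sub-interval of (0, 1)")
    rng = np.random.default_rng(seed)
    ids = tuple(f"L{i+1}" for i in range(p_lifestyle)) + tuple(
        f"H{i+1}" for i in range(p_outcome)
    )
    community = ("lifestyle",) * p_lifestyle + ("outcome",) * p_outcome
    idx = {name: k for k, name in enumerate(ids)}
    p = len(ids)
    P = np.zeros((p, p))

    for block in (range(p_lifestyle), range(p_lifestyle, p)):
        nodes = list(block)
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                if rng.random() < within_density:
                    w = rng.uniform(lo, hi)
                    P[nodes[a], nodes[b]] = P[nodes[b], nodes[a]] = w

    if bridge_edges is None:
        cross = [(i, j) for i in range(p_lifestyle) for j in range(p_lifestyle, p)]
        if n_bridge > len(cross):
            raise ValueError("n_bridge exceeds the number of cross-community pairs")
        chosen = rng.choice(len(cross), size=n_bridge, replace=False)
        bridge_edges = [
            (ids[cross[k][0]], ids[cross[k][1]], float(rng.uniform(lo, hi))) for k in chosen
        ]
    for a, b, w in bridge_edges:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w
    for a, b, w in extra_edges or []:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w

    P = _enforce_pd(P)
    final_bridges = tuple(
        (a, b, float(P[idx[a], idx[b]])) for a, b, _ in bridge_edges
    )
    return TrueNetworkSpec(
        partial_corr=P, community=community, item_ids=ids, bridge_edges=final_bridges, seed=seed
    )


def sample_likert(
    truth: TrueNetworkSpec,
    thresholds: ThresholdScheme | None = None,
    n: int = 1000,
    seed: int = 0,
    country: str = "synthetic",
) -> SurveyMatrix:
    """Draw n respondents: latent Gaussian vectors discretised into levels 1-5."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if thresholds is None:
        thresholds = ThresholdScheme.equal_mass(truth.p)
    if thresholds.p != truth.p:
        raise ValueError("threshold scheme and truth disagree on item count")
    sigma = truth.latent_correlation()
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by TrueNetworkSpec
        raise ValueError("truth correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, truth.p)) @ L.T
    levels = np.empty_like(latent, dtype=float)
    for j in range(truth.p):
        levels[:, j] = np.searchsorted(thresholds.cutpoints[j], latent[:, j]) + 1
    return SurveyMatrix(pd.DataFrame(levels, columns=list(truth.item_ids)), country)


def inject_redundant_item(
    matrix: SurveyMatrix,
    source_item: str,
    agreement: float = 0.9,
    seed: int = 0,
    new_id: str | None = None,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> SurveyMatrix:
    """Append a near-duplicate of ``source_item`` for redundancy-screen tests.

    Each cell copies the source with probability ``agreement`` and is
    otherwise redrawn uniformly from the levels.
    """
    if not (0 < agreement <= 1):
        raise ValueError("agreement must lie in (0, 1]")
    if source_item not in matrix.item_ids:
        raise KeyError(f"unknown source item {source_item!r}")
    rng = np.random.default_rng(seed)
    src = matrix.data[source_item].to_numpy(copy=True)
    clone = src.copy()
    redraw = rng.random(len(clone)) >= agreement
    clone[redraw] = rng.choice(levels, size=int(redraw.sum()))
    clone[np.isnan(src)] = np.nan
    data = matrix.data.copy()
    data[new_id or f"{source_item}dup"] = clone
    return SurveyMatrix(data, matrix.country)
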