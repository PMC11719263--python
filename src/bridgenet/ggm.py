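"""Sparse Gaussian graphical model estimation with EBIC penalty selection.

The estimator follows the standard regularised-partial-correlation recipe:
compute an item correlation matrix, fit the graphical lasso along a
descending log-spaced penalty path, score every fit with the extended BIC,
and convert the selected precision matrix to partial correlations

    w_ij = -K_ij / sqrt(K_ii K_jj)

so that a zero entry means conditional independence given all other items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

try:  # warm-startable path solver (private but stable in the pinned sklearn)
    from sklearn.covariance._graph_lasso import _graphical_lasso as _glasso_warm
except ImportError:  # pragma: no cover
    _glasso_warm = None

from .io_survey import SurveyMatrix


@dataclass
class GGMConfig:
    """Tuning knobs for the penalised fit and model selection.

    n_lambda / lambda_min_ratio define the log-spaced penalty path from
    lambda_max = max |off-diagonal correlation| down to lambda_max * ratio.
    gamma is the EBIC edge-count hyperparameter (0 recovers plain BIC);
    zero_tolerance separates solver zeros from genuinely small weights in
    the edge census.
    """

    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    gamma: float = 0.5
    zero_tolerance: float = 1e-8
    method: str = "pearson"
    glasso_tol: float = 1e-3  # dual-gap tolerance; selection is insensitive below this
    glasso_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class CorrelationEstimate:
    matrix: np.ndarray
    n_effective: int
    method: str = "pearson"
    pd_repaired: bool = False
    item_ids: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GGMNetwork:
    """Estimated network: symmetric partial-correlation weights, zero diagonal."""

    weights: np.ndarray
    item_ids: list[str]
    lambda_selected: float
    ebic: float
    n_effective: int
    zero_tolerance: float = 1e-8
    community: dict[str, str] | None = None

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def total_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def nonzero_edges(self) -> int:
        i, j = np.triu_indices(self.p, k=1)
        return int((np.abs(self.weights[i, j]) > self.zero_tolerance).sum())

    def edge_list(self, nonzero_only: bool = True) -> pd.DataFrame:
        i, j = np.triu_indices(self.p, k=1)
        w = self.weights[i, j]
        df = pd.DataFrame(
            {
                "item_i": [self.item_ids[a] for a in i],
                "item_j": [self.item_ids[b] for b in j],
                "weight": w,
            }
        )
        if nonzero_only:
            df = df[df.weight.abs() > self.zero_tolerance].reset_index(drop=True)
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.item_ids, columns=self.item_ids)


def correlation_matrix(
    matrix: SurveyMatrix, method: str = "pearson"
) -> CorrelationEstimate:
    """Listwise-complete item correlation matrix with PSD repair if needed."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    complete = matrix.data.dropna(axis=0)
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")
    sd = complete.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance item(s): {dead}")
    S = complete.corr(method=method).to_numpy()
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    repaired = False
    eigval, eigvec = np.linalg.eigh(S)
    if eigval.min() < 0:
        eigval = np.clip(eigval, 0, None)
        S = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
        repaired = True
    return CorrelationEstimate(
        matrix=S, n_effective=n, method=method, pd_repaired=repaired,
        item_ids=matrix.item_ids,
    )


def lambda_grid(S: CorrelationEstimate, config: GGMConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalty path from max |off-diag| down by the ratio."""
    config = config or GGMConfig()
    offdiag = S.matrix - np.diag(np.diag(S.matrix))
    lam_max = float(np.abs(offdiag).max())
    if lam_max == 0:
        warnings.warn("all off-diagonal correlations are zero; degenerate penalty grid")
        return np.array([0.0])
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio), config.n_lambda
    )


def penalised_precision(
    S: CorrelationEstimate | np.ndarray,
    lam: float,
    config: GGMConfig | None = None,
) -> np.ndarray:
    """Graphical-lasso precision estimate at penalty ``lam``.

    Maximises log det K - tr(SK) - lam * sum_{i!=j} |K_ij|.  lam = 0 falls
    back to direct inversion (the saturated MLE).
    """
    config = config or GGMConfig()
    Smat = S.matrix if isinstance(S, CorrelationEstimate) else np.asarray(S, float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0:
        return np.linalg.inv(Smat)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, K = graphical_lasso(
                Smat,
                alpha=float(lam),
                tol=config.glasso_tol,
                max_iter=config.glasso_max_iter,
            )
    except FloatingPointError as exc:
        raise RuntimeError(
            f"graphical lasso failed to converge at lambda={lam:.6g} "
            f"(max_iter={config.glasso_max_iter})"
        ) from exc
    return (K + K.T) / 2.0


def _glasso_once(Smat: np.ndarray, lam: float, config: GGMConfig, cov_init):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if _glasso_warm is not None:
            res = _glasso_warm(
                Smat, lam, cov_init=cov_init,
                tol=config.glasso_tol, max_iter=config.glasso_max_iter,
            )
            return res[0], res[1]
        # pragma: no cover - fallback without warm starts
        return graphical_lasso(
            Smat, alpha=lam, tol=config.glasso_tol, max_iter=config.glasso_max_iter
        )


def _precision_path(Smat: np.ndarray, lams: np.ndarray, config: GGMConfig):
    """Yield (lam, K) along a descending penalty path, warm-starting each fit.

    A penalty whose fit is too ill-conditioned for the solver (possible in
    the dense small-lambda tail on near-singular correlation matrices) is
    skipped with a warning; EBIC selection proceeds on the remaining grid.
    """
    cov = None
    yielded = False
    for lam in lams:
        if lam == 0:
            yield 0.0, np.linalg.inv(Smat)
            yielded = True
            continue
        try:
            cov, K = _glasso_once(Smat, float(lam), config, cov)
        except FloatingPointError:
            try:  # a stale warm start can itself destabilise the solve
                cov, K = _glasso_once(Smat, float(lam), config, None)
            except FloatingPointError:
                warnings.warn(
                    f"graphical lasso ill-conditioned at lambda={lam:.6g}; skipped"
                )
                cov = None
                continue
        yield float(lam), (K + K.T) / 2.0
        yielded = True
    if not yielded:
        raise RuntimeError("graphical lasso failed at every penalty on the grid")


def to_partial_correlations(K: np.ndarray) -> np.ndarray:
    """Scale a precision matrix to partial correlations, zeroing the diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    W = -K / np.sqrt(np.outer(d, d))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    W[K == 0] = 0.0  # preserve exact solver zeros
    np.fill_diagonal(W, 0.0)
    return W


def ebic_score(
    K: np.ndarray,
    S: CorrelationEstimate | np.ndarray,
    n: int,
    gamma: float = 0.5,
    zero_tolerance: float = 1e-8,
) -> float:
    """Extended BIC of a fitted precision matrix.

    EBIC = -2 L + E log n + 4 E gamma log p with E the nonzero edge count
    and the Gaussian profile likelihood taken as
    L = (n/2)(log det K - tr(SK) + p), so a diagonal K on an identity S
    scores exactly 0.  The +p constant cancels in model selection.
    """
    Smat = S.matrix if isinstance(S, CorrelationEstimate) else np.asarray(S, float)
    K = np.asarray(K, dtype=float)
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    L = (n / 2.0) * (logdet - np.trace(Smat @ K) + p)
    i, j = np.triu_indices(p, k=1)
    E = int((np.abs(K[i, j]) > zero_tolerance).sum())
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def estimate_network(
    matrix: SurveyMatrix,
    config: GGMConfig | None = None,
    community: dict[str, str] | None = None,
) -> GGMNetwork:
    """Full estimation: correlations -> penalty path -> EBIC pick -> weights.

    Deterministic given its inputs; EBIC ties resolve to the sparsest
    (largest-penalty) fit because the path is scanned in descending order.
    """
    config = config or GGMConfig()
    S = correlation_matrix(matrix, method=config.method)
    lams = lambda_grid(S, config)
    best = None
    for lam, K in _precision_path(S.matrix, lams, config):
        score = ebic_score(K, S, S.n_effective, config.gamma, config.zero_tolerance)
        if best is None or score < best[0]:
            best = (score, lam, K)
    score, lam, K = best
    W = to_partial_correlations(K)
    W[np.abs(W) <= config.zero_tolerance] = 0.0
    return GGMNetwork(
        weights=W,
        item_ids=matrix.item_ids,
        lambda_selected=lam,
        ebic=score,
        n_effective=S.n_effective,
        zero_tolerance=config.zero_tolerance,
        community=community,
    )
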