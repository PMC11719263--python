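"""Topological-overlap screening of redundant survey items.

Two items are redundant when they correlate strongly with each other and
their correlation profiles with every remaining item are statistically
indistinguishable — i.e. they measure one construct twice.  Candidate pairs
are tested with the back-transformed-average Fisher-z statistic for two
dependent overlapping correlations; a pair is flagged when fewer than a
threshold proportion of those comparisons differ significantly.  Flagged
groups are then collapsed to a single representative item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

from .io_survey import SurveyMatrix


@dataclass
class RedundancyReport:
    """Outcome of the screen: flagged pairs and the reduction they imply."""

    bad_pairs: list[tuple[str, str, float]]
    alpha: float = 0.01
    proportion_threshold: float = 0.25
    corr_floor: float = 0.5
    dropped_items: list[str] = field(default_factory=list)
    kept_for: dict[str, str] = field(default_factory=dict)

    def flagged_items(self) -> set[str]:
        return {x for a, b, _ in self.bad_pairs for x in (a, b)}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "bad_pairs": [[a, b, p] for a, b, p in self.bad_pairs],
                "alpha": self.alpha,
                "proportion_threshold": self.proportion_threshold,
                "corr_floor": self.corr_floor,
                "dropped_items": self.dropped_items,
                "kept_for": self.kept_for,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def dependent_correlation_test(
    r_az: float, r_bz: float, r_ab: float, n: int
) -> tuple[float, float]:
    """Test H0: rho(a,z) = rho(b,z) for correlations sharing variable z.

    Back-transformed-average Fisher-z statistic for two dependent
    overlapping correlations::

        z1 = atanh(r_az), z2 = atanh(r_bz), rbar = tanh((z1+z2)/2)
        psi = r_ab(1-2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_ab^2)/2
        c   = psi / (1-rbar^2)^2
        Z   = (z1-z2) sqrt(n-3) / sqrt(2-2c)

    Returns (Z, two-sided p-value).
    """
    for name, r in (("r_az", r_az), ("r_bz", r_bz), ("r_ab", r_ab)):
        if not -1 < r < 1:
            raise ValueError(f"{name}={r} must lie strictly in (-1, 1)")
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    z1 = np.arctanh(r_az)
    z2 = np.arctanh(r_bz)
    rbar = np.tanh((z1 + z2) / 2.0)
    psi = r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)
    c = psi / (1 - rbar**2) ** 2
    # degenerate geometry (e.g. r_ab ~ 1) can push c marginally past 1
    c = float(np.clip(c, -1.0, 1.0 - 1e-12))
    z_stat = (z1 - z2) * np.sqrt(n - 3) / np.sqrt(2 - 2 * c)
    p_value = 2 * stats.norm.sf(abs(z_stat))
    return float(z_stat), float(p_value)


def _clip_corr(r: float, eps: float = 1e-12) -> float:
    return float(np.clip(r, -1 + eps, 1 - eps))


def find_redundant_pairs(
    matrix: SurveyMatrix,
    alpha: float = 0.01,
    proportion_threshold: float = 0.25,
    corr_floor: float = 0.5,
    method: str = "pearson",
) -> RedundancyReport:
    """Flag item pairs whose correlation profiles are indistinguishable.

    For every pair (a, b) with |r(a,b)| >= ``corr_floor``, the dependent
    correlation test compares r(a,z) to r(b,z) for each third item z.  The
    pair is flagged when the proportion of the p-2 comparisons significant
    at ``alpha`` falls below ``proportion_threshold``.  Correlations use
    pairwise-complete observations.
    """
    ids = matrix.item_ids
    p = len(ids)
    if p < 3:
        raise ValueError("redundancy screening needs at least 3 items")
    corr = matrix.data.corr(method=method)
    notna = matrix.data.notna().astype(int).to_numpy()
    pair_n = notna.T @ notna  # pairwise-complete counts

    bad: list[tuple[str, str, float]] = []
    for i in range(p):
        for j in range(i + 1, p):
            r_ab = corr.iloc[i, j]
            if not np.isfinite(r_ab) or abs(r_ab) < corr_floor:
                continue
            n_sig = 0
            n_tests = 0
            for k in range(p):
                if k in (i, j):
                    continue
                r_az, r_bz = corr.iloc[i, k], corr.iloc[j, k]
                if not (np.isfinite(r_az) and np.isfinite(r_bz)):
                    continue
                n = int(min(pair_n[i, j], pair_n[i, k], pair_n[j, k]))
                if n <= 3:
                    continue
                _, pval = dependent_correlation_test(
                    _clip_corr(r_az), _clip_corr(r_bz), _clip_corr(r_ab), n
                )
                n_tests += 1
                n_sig += pval < alpha
            if n_tests == 0:
                continue
            prop = n_sig / n_tests
            if prop < proportion_threshold:
                bad.append((ids[i], ids[j], prop))
    return RedundancyReport(
        bad_pairs=bad,
        alpha=alpha,
        proportion_threshold=proportion_threshold,
        corr_floor=corr_floor,
    )


def reduce_items(
    matrix: SurveyMatrix,
    report: RedundancyReport,
    keep: list[str] | None = None,
) -> SurveyMatrix:
    """Collapse each connected group of flagged pairs to one kept item.

    The default policy keeps the group member with the largest mean |r| to
    all items outside the group (ties broken by lowest item id); an explicit
    ``keep`` list overrides per group.  The report's ``dropped_items`` and
    ``kept_for`` fields are filled in as a side effect.
    """
    if keep:
        flagged = report.flagged_items()
        unknown = [k for k in keep if k not in flagged]
        if unknown:
            raise ValueError(f"keep-list items not among flagged pairs: {unknown}")

    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b, _ in report.bad_pairs)
    corr = matrix.data.corr().abs() if graph.number_of_nodes() else None

    dropped: list[str] = []
    kept_for: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        group = sorted(comp)
        chosen = None
        if keep:
            overrides = [k for k in keep if k in comp]
            if len(overrides) > 1:
                raise ValueError(f"keep-list names several items of one group: {overrides}")
            chosen = overrides[0] if overrides else None
        if chosen is None:
            outside = [c for c in matrix.item_ids if c not in comp]
            if outside:
                scores = corr.loc[group, outside].mean(axis=1)
                chosen = scores.loc[scores == scores.max()].index.min()
            else:
                chosen = group[0]
        for item in group:
            if item != chosen:
                dropped.append(item)
                kept_for[item] = chosen

    report.dropped_items = sorted(dropped)
    report.kept_for = kept_for
    remaining = [c for c in matrix.item_ids if c not in kept_for]
    return matrix.select(remaining)
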