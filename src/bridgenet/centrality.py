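"""Node-importance indices for signed partial-correlation networks.

Expected influence (EI, one-step) sums a node's signed edge weights —
unlike strength it does not take absolute values, so inhibitory edges count
against a node.  Bridge expected influence (BEI, one-step) restricts the sum
to edges reaching the *other* declared community, picking out the variables
that couple the lifestyle cluster to the health-outcome cluster.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .ggm import GGMNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .resampling import DifferenceTestMatrix


def expected_influence(net: GGMNetwork) -> pd.Series:
    """One-step expected influence: EI(i) = sum_j w_ij (signed)."""
    return pd.Series(net.weights.sum(axis=1), index=net.item_ids, name="EI")


def bridge_expected_influence(net: GGMNetwork) -> pd.Series:
    """One-step bridge expected influence: signed edges into other communities."""
    if not net.community:
        raise ValueError("bridge expected influence needs community labels")
    labels = [net.community[i] for i in net.item_ids]
    if len(set(labels)) < 2:
        raise ValueError("need at least two communities")
    lab = np.asarray(labels)
    cross = lab[:, None] != lab[None, :]
    return pd.Series((net.weights * cross).sum(axis=1), index=net.item_ids, name="BEI1")


def centrality_table(net: GGMNetwork) -> pd.DataFrame:
    """EI (and BEI when communities are declared) with descending ranks."""
    out = pd.DataFrame({"EI": expected_influence(net)})
    if net.community:
        out["BEI1"] = bridge_expected_influence(net)
    for col in list(out.columns):
        out[f"rank_{col}"] = out[col].rank(ascending=False, method="min").astype(int)
    return out


def identify_top(
    values: pd.Series,
    difftest: "DifferenceTestMatrix",
    restrict: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Return the top node plus any node statistically tied with it.

    The argmax is taken over ``restrict`` when given (e.g. lifestyle nodes
    only, for bridge selection); a candidate joins the top set when its
    Holm-adjusted difference-test p-value against the argmax is >= alpha.
    The set is ordered by descending index value.
    """
    candidates = list(restrict) if restrict is not None else list(values.index)
    missing = [c for c in candidates if c not in values.index]
    if missing:
        raise ValueError(f"restriction names unknown nodes: {missing}")
    sub = values.loc[candidates]
    top = sub.idxmax()
    tied = [top]
    for node in candidates:
        if node == top:
            continue
        if difftest.adjusted_p(top, node) >= alpha:
            tied.append(node)
    return sorted(tied, key=lambda x: (-values[x], x))


def top_edges(net: GGMNetwork, k: int = 3) -> pd.DataFrame:
    """k strongest edges by |weight|, signed weights rounded to 2 decimals.

    Ties in |weight| break lexicographically on the item-id pair.  Fewer
    than k nonzero edges simply yields a shorter table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = net.edge_list(nonzero_only=True)
    if edges.empty:
        return edges.assign(weight=edges.get("weight", pd.Series(dtype=float)))
    edges = edges.assign(abs_w=edges.weight.abs())
    edges = edges.sort_values(
        ["abs_w", "item_i", "item_j"], ascending=[False, True, True]
    ).head(k)
    edges = edges.drop(columns="abs_w").reset_index(drop=True)
    edges["weight"] = edges["weight"].round(2)
    return edges
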