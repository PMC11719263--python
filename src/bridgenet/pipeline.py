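"""Per-country orchestration and cross-country tabulation.

One country's analysis runs: redundancy screen on the pooled item set, then
three networks — lifestyle items, health-outcome items, and the pooled
bridge network — each with bootstrap difference tests and a case-dropping
stability check.  Central/bridge variables are reported only when the
corresponding network's CS coefficient exceeds 0.25; otherwise the summary
carries NA for that column, mirroring how under-stable networks are left
uninterpreted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .centrality import (
    bridge_expected_influence,
    centrality_table,
    expected_influence,
    identify_top,
    top_edges,
)
from .ggm import GGMConfig, GGMNetwork, estimate_network
from .io_survey import Codebook, SurveyMatrix, required_sample_size
from .redundancy import RedundancyReport, find_redundant_pairs, reduce_items
from .resampling import (
    DEFAULT_DROP_GRID,
    case_dropping_bootstrap,
    centrality_difference_test,
    cs_coefficient,
    nonparametric_bootstrap,
)

logger = logging.getLogger(__name__)

CS_GATE = 0.25  # strict ">": a network at exactly 0.25 is not interpreted


def complete_graph_edges(p: int) -> int:
    """Edges of the complete graph on p nodes: p(p-1)/2."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return p * (p - 1) // 2


def percent_nonzero(nonzero: int, total: int) -> float:
    """Share of realised edges as a 1-decimal percentage (round half to even)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= nonzero <= total):
        raise ValueError("need 0 <= nonzero <= total")
    return float(round(100.0 * nonzero / total, 1))


@dataclass
class PipelineConfig:
    """Everything one country run needs; YAML-serialisable."""

    ggm: GGMConfig = field(default_factory=GGMConfig)
    redundancy_alpha: float = 0.01
    redundancy_proportion: float = 0.25
    redundancy_corr_floor: float = 0.5
    global_drop: list[str] | None = None  # fixed drop list replacing the screen
    B_boot: int = 1000
    B_case: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    cs_threshold: float = CS_GATE
    alpha: float = 0.05
    top_k_edges: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ggm = GGMConfig(**raw.pop("ggm", {}))
        if "drop_grid" in raw:
            raw["drop_grid"] = tuple(raw["drop_grid"])
        return cls(ggm=ggm, **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["drop_grid"] = list(self.drop_grid)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class NetworkSummary:
    """One network's row fragment: census, strongest edges, stability."""

    name: str
    nonzero_edges: int
    total_edges: int
    percent_nonzero: float
    top_edges: list[tuple[str, str, float]]
    cs_coefficient: float

    @property
    def interpretable(self) -> bool:
        return self.cs_coefficient > CS_GATE


@dataclass
class CountrySummary:
    """Machine-readable analogue of one row of the cross-country table."""

    country: str
    n: int
    networks: dict[str, NetworkSummary]
    central_lifestyle: list[str] | None
    central_outcome: list[str] | None
    bridge_lifestyle: list[str] | None
    bridge_edge: tuple[str, str, float] | None
    redundancy: RedundancyReport | None = None
    warnings: list[str] = field(default_factory=list)
    #: per-network side tables (centrality, stability, difference tests,
    #: edge lists) keyed e.g. "centrality_lifestyle"; not serialised to JSON
    artifacts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "n": self.n,
            "networks": {
                k: {
                    "nonzero_edges": v.nonzero_edges,
                    "total_edges": v.total_edges,
                    "percent_nonzero": v.percent_nonzero,
                    "top_edges": [list(e) for e in v.top_edges],
                    "cs_coefficient": v.cs_coefficient,
                    "interpretable": v.interpretable,
                }
                for k, v in self.networks.items()
            },
            "central_lifestyle": self.central_lifestyle,
            "central_outcome": self.central_outcome,
            "bridge_lifestyle": self.bridge_lifestyle,
            "bridge_edge": list(self.bridge_edge) if self.bridge_edge else None,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _network_summary(name: str, net: GGMNetwork, cs: float, k: int) -> NetworkSummary:
    edges = top_edges(net, k=k)
    return NetworkSummary(
        name=name,
        nonzero_edges=net.nonzero_edges,
        total_edges=net.total_edges,
        percent_nonzero=percent_nonzero(net.nonzero_edges, net.total_edges),
        top_edges=[tuple(r) for r in edges.itertuples(index=False)],
        cs_coefficient=cs,
    )


def _bridge_edge_of(net: GGMNetwork, node: str) -> tuple[str, str, float] | None:
    """Strongest cross-community edge incident to ``node``."""
    comm = net.community or {}
    i = net.item_ids.index(node)
    best = None
    for j, other in enumerate(net.item_ids):
        if other == node or comm.get(other) == comm.get(node):
            continue
        w = net.weights[i, j]
        if abs(w) > net.zero_tolerance and (best is None or abs(w) > abs(best[2])):
            best = (node, other, round(float(w), 2))
    return best


def run_country(
    matrix: SurveyMatrix,
    codebook: Codebook,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> CountrySummary:
    """Full per-country analysis; deterministic given the seed.

    Redundancy reduction happens once on the pooled item set (or applies
    ``config.global_drop`` verbatim); the lifestyle, outcome and bridge
    networks are then estimated on the reduced items.  Each network gets a
    nonparametric bootstrap (difference tests) and a case-dropping bootstrap
    (CS); central and bridge variables are reported only when CS clears the
    gate.  A sample below the planning rule logs a warning and proceeds.
    """
    config = config or PipelineConfig()
    notes: list[str] = []
    p_all = len(codebook.item_ids)
    need = required_sample_size(p_all)
    if matrix.n < need:
        msg = f"n={matrix.n} below planning-rule requirement {need} for p={p_all}"
        logger.warning(msg)
        notes.append(msg)

    pooled = matrix.select(codebook.item_ids)
    if config.global_drop is not None:
        report = RedundancyReport(bad_pairs=[], dropped_items=sorted(config.global_drop))
        report.kept_for = {d: "(global)" for d in report.dropped_items}
        reduced = pooled.select([c for c in pooled.item_ids if c not in set(config.global_drop)])
    else:
        report = find_redundant_pairs(
            pooled,
            alpha=config.redundancy_alpha,
            proportion_threshold=config.redundancy_proportion,
            corr_floor=config.redundancy_corr_floor,
        )
        reduced = reduce_items(pooled, report)

    comm = codebook.communities
    life_ids = [i for i in reduced.item_ids if comm.get(i) == "lifestyle"]
    out_ids = [i for i in reduced.item_ids if comm.get(i) == "outcome"]
    parts = {
        "lifestyle": (life_ids, None, "EI"),
        "outcome": (out_ids, None, "EI"),
        "bridge": (reduced.item_ids, {i: comm[i] for i in reduced.item_ids}, "BEI1"),
    }

    summaries: dict[str, NetworkSummary] = {}
    selections: dict[str, list[str] | None] = {}
    artifacts: dict = {}
    bridge_net = None
    for k, (name, (ids, community, index)) in enumerate(parts.items()):
        sub = reduced.select(ids)
        net = estimate_network(sub, config.ggm, community=community)
        ens = nonparametric_bootstrap(
            sub, config.ggm, B=config.B_boot, seed=seed + 1000 * (k + 1), community=community
        )
        difftest = centrality_difference_test(ens, index=index, alpha=config.alpha)
        profile = case_dropping_bootstrap(
            sub, config.ggm, grid=config.drop_grid, B=config.B_case,
            seed=seed + 1000 * (k + 1) + 500, index=index, community=community,
        )
        cs = cs_coefficient(profile)
        summaries[name] = _network_summary(name, net, cs, config.top_k_edges)
        artifacts[f"edges_{name}"] = net.edge_list()
        artifacts[f"matrix_{name}"] = net.to_frame()
        artifacts[f"centrality_{name}"] = centrality_table(net)
        artifacts[f"stability_{name}"] = profile.to_frame()
        artifacts[f"difftest_{name}"] = difftest.to_frame()

        if summaries[name].cs_coefficient > config.cs_threshold:
            if index == "EI":
                values = expected_influence(net)
                selections[name] = identify_top(values, difftest, alpha=config.alpha)
            else:
                values = bridge_expected_influence(net)
                selections[name] = identify_top(
                    values, difftest, restrict=life_ids, alpha=config.alpha
                )
        else:
            selections[name] = None
        if name == "bridge":
            bridge_net = net

    bridge_sel = selections["bridge"]
    bridge_edge = (
        _bridge_edge_of(bridge_net, bridge_sel[0]) if bridge_sel else None
    )
    summary = CountrySummary(
        country=matrix.country,
        n=matrix.n,
        networks=summaries,
        central_lifestyle=selections["lifestyle"],
        central_outcome=selections["outcome"],
        bridge_lifestyle=bridge_sel,
        bridge_edge=bridge_edge,
        redundancy=report,
        warnings=notes,
        artifacts=artifacts,
    )
    for name, net_summary in summary.networks.items():
        sel = {"lifestyle": summary.central_lifestyle,
               "outcome": summary.central_outcome,
               "bridge": summary.bridge_lifestyle}[name]
        assert (sel is not None) == (
            net_summary.cs_coefficient > config.cs_threshold
        ), "CS gating inconsistency"
    return summary


def summarize_across_countries(summaries: list[CountrySummary]) -> dict:
    """Group countries by their central/bridge variables (NA rows excluded).

    A country whose top set holds several statistically tied variables is
    listed under each of them.  Returns, per column, the number of distinct
    variable types and the member countries of each group.
    """
    if not summaries:
        raise ValueError("need at least one country summary")
    out: dict[str, dict] = {}
    for col in ("central_lifestyle", "central_outcome", "bridge_lifestyle"):
        groups: dict[str, list[str]] = {}
        for s in summaries:
            sel = getattr(s, col)
            if not sel:
                continue
            for var in sel:
                groups.setdefault(var, []).append(s.country)
        groups = {k: sorted(v) for k, v in sorted(groups.items())}
        out[col] = {"n_types": len(groups), "groups": groups}
    return out


def summary_table(summaries: list[CountrySummary]) -> pd.DataFrame:
    """Flat one-row-per-country table mirroring the cross-country summary."""
    rows = []
    for s in summaries:
        row: dict = {"country": s.country, "n": s.n}
        for name, ns in s.networks.items():
            row[f"{name}_nonzero"] = ns.nonzero_edges
            row[f"{name}_total"] = ns.total_edges
            row[f"{name}_pct"] = ns.percent_nonzero
            row[f"{name}_cs"] = ns.cs_coefficient
        row["central_lifestyle"] = "=".join(s.central_lifestyle) if s.central_lifestyle else "NA"
        row["central_outcome"] = "=".join(s.central_outcome) if s.central_outcome else "NA"
        row["bridge_lifestyle"] = "=".join(s.bridge_lifestyle) if s.bridge_lifestyle else "NA"
        if s.bridge_edge:
            a, b, w = s.bridge_edge
            row["bridge_edge"] = f"{a}-{b} ({w:.2f})"
        else:
            row["bridge_edge"] = "NA"
        rows.append(row)
    return pd.DataFrame(rows)
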