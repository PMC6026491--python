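"""Four-branch intersection and the gene-resolved cooperation network.

The sequence-level branches (motif enrichment and ChIP-derived target
enrichment) contribute evidence at transcription-factor *family* resolution,
because homologous family members share sequence logos.  The transcriptomic
branches contribute gene-resolved evidence and carry direction.  A TF enters
the cooperation network when its family is supported by every branch and the
TF itself passes the gene-level transcriptomic filters, including (by
default) a directional activation score of at least +2 indicating the TF is
active when the epigenomic factor is active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import (
    ALL_BRANCHES,
    BRANCH_TFT_TX,
    BRANCH_URA_TX,
    DERecord,
    EnrichmentRecord,
    Regulon,
)
from .families import FamilyResult, TFClassTable, UNMAPPED, map_to_family

logger = logging.getLogger(__name__)


def intersect_families(
    family_results: Mapping[str, Sequence[FamilyResult]],
    alpha: float = 0.05,
    required_branches: Sequence[str] = ALL_BRANCHES,
) -> set[str]:
    """Family barcodes significant in every required branch."""
    missing = [b for b in required_branches if b not in family_results]
    if missing:
        raise ValueError(f"missing branch results: {missing}")
    if not required_branches:
        raise ValueError("at least one branch is required")
    sets = [
        {r.barcode for r in family_results[b] if r.best_adj_p < alpha}
        for b in required_branches
    ]
    return set.intersection(*sets)


def refine_to_genes(
    families: set[str],
    gene_level_records: Mapping[str, Sequence[EnrichmentRecord]],
    table: TFClassTable,
    alpha: float = 0.05,
    require_direction: bool = True,
    z_threshold: float = 2.0,
) -> list[str]:
    """Gene-resolved TFs surviving all four lines of evidence.

    ``gene_level_records`` maps the two transcriptomic branches to their
    BH-adjusted records.  A TF is kept iff its family is in ``families``,
    both transcriptomic branches call it at ``alpha``, and (when direction
    is required) its activation z is defined and at least ``z_threshold``
    with the sign meaning "active alongside the epigenomic factor".
    Multiple TFs per family are permitted.
    """
    for branch in (BRANCH_TFT_TX, BRANCH_URA_TX):
        if branch not in gene_level_records:
            raise ValueError(f"missing gene-level branch {branch}")
    tft = {r.unit: r for r in gene_level_records[BRANCH_TFT_TX]}
    ura = {r.unit: r for r in gene_level_records[BRANCH_URA_TX]}
    kept = []
    for tf in sorted(set(tft) & set(ura)):
        if map_to_family(tf, table) not in families:
            continue
        if tft[tf].adj_pvalue is None or ura[tf].adj_pvalue is None:
            raise ValueError(f"records for {tf} must be BH-adjusted")
        if tft[tf].adj_pvalue >= alpha or ura[tf].adj_pvalue >= alpha:
            continue
        if require_direction:
            z = ura[tf].z
            if z is None or z < z_threshold:
                continue
        kept.append(tf)
    return kept


@dataclass(frozen=True)
class NetworkEdge:
    tf: str
    target: str
    sign: int
    motif_hit: bool
    peak_promoter: bool
    de_target: bool


@dataclass
class CooperationNetwork:
    """TFs cooperating with the epigenomic regulator plus shared targets."""

    regulator: str
    tfs: pd.DataFrame            # symbol, barcode, per-branch adj_p, z
    families: set[str]
    edges: list[NetworkEdge]
    targets: set[str]
    graph: nx.DiGraph = field(repr=False)

    @property
    def isolated_tfs(self) -> list[str]:
        with_edges = {e.tf for e in self.edges}
        return sorted(set(self.tfs["symbol"]) - with_edges)


def build_network(
    tfs: Sequence[str],
    regulons: Mapping[str, Regulon],
    de_records: Sequence[DERecord],
    epigenomic_target_genes: set[str],
    motif_hits: Mapping[str, set[str]] | None = None,
    regulator: str = "regulator",
    families: set[str] | None = None,
    table: TFClassTable | None = None,
    branch_records: Mapping[str, Mapping[str, EnrichmentRecord]] | None = None,
    alpha: float = 0.05,
) -> CooperationNetwork:
    """Assemble the cooperation network for the selected TFs.

    Edges are regulon edges restricted to targets that are both
    differentially expressed and epigenomic targets; each edge carries
    evidence flags (motif hit in the target promoter, promoter peak,
    differential expression).  TFs with no surviving edge are retained as
    isolated nodes with a warning.
    """
    de_genes = {r.gene for r in de_records if r.adj_pvalue < alpha}
    motif_hits = motif_hits or {}
    branch_records = branch_records or {}
    edges: list[NetworkEdge] = []
    rows = []
    graph = nx.DiGraph()
    for tf in tfs:
        barcode = map_to_family(tf, table) if table is not None else UNMAPPED
        row: dict[str, object] = {"symbol": tf, "barcode": barcode}
        for branch in ALL_BRANCHES:
            rec = branch_records.get(branch, {}).get(tf)
            row[f"adj_p_{branch}"] = None if rec is None else rec.adj_pvalue
            if branch == BRANCH_URA_TX:
                row["z"] = None if rec is None else rec.z
        rows.append(row)
        graph.add_node(tf, kind="tf")
        reg = regulons.get(tf)
        if reg is None:
            logger.warning("TF %s has no regulon; kept as isolated node", tf)
            continue
        n_edges = 0
        for target in sorted(reg.targets):
            if target in de_genes and target in epigenomic_target_genes:
                edge = NetworkEdge(
                    tf=tf,
                    target=target,
                    sign=reg.edges[target],
                    motif_hit=target in motif_hits.get(tf, ()),
                    peak_promoter=True,
                    de_target=True,
                )
                if not graph.has_edge(tf, target):
                    edges.append(edge)
                    graph.add_node(target, kind="target")
                    graph.add_edge(tf, target, **edge.__dict__)
                    n_edges += 1
        if n_edges == 0:
            logger.warning("TF %s has no surviving edge; isolated node", tf)
    cols = ["symbol", "barcode"] + [f"adj_p_{b}" for b in ALL_BRANCHES] + ["z"]
    tf_frame = pd.DataFrame(rows, columns=cols)
    return CooperationNetwork(
        regulator=regulator,
        tfs=tf_frame,
        families=set(families or set()),
        edges=edges,
        targets={e.target for e in edges},
        graph=graph,
    )


@dataclass(frozen=True)
class ConnectivityStats:
    target_degree: pd.DataFrame   # target, n_tfs
    tf_out_degree: pd.DataFrame   # tf, n_targets
    n_hyperconnected: int
    k: int


def connectivity_stats(network: CooperationNetwork, k: int = 3) -> ConnectivityStats:
    """Per-target TF-degree, per-TF out-degree and hyperconnected count.

    A target is hyperconnected when at least ``k`` cooperating TFs share it.
    """
    tdeg: dict[str, int] = {}
    odeg: dict[str, int] = {tf: 0 for tf in network.tfs["symbol"]}
    for e in network.edges:
        tdeg[e.target] = tdeg.get(e.target, 0) + 1
        odeg[e.tf] = odeg.get(e.tf, 0) + 1
    target_degree = pd.DataFrame(
        sorted(tdeg.items()), columns=["target", "n_tfs"]
    )
    tf_out = pd.DataFrame(sorted(odeg.items()), columns=["tf", "n_targets"])
    n_hyper = int(sum(v >= k for v in tdeg.values()))
    return ConnectivityStats(target_degree, tf_out, n_hyper, k)


@dataclass(frozen=True)
class ShareReport:
    n_selected: int
    n_total: int
    pct: float
    text: str
    threshold_pct: float
    below_threshold: bool


def network_share_report(
    n_selected_tfs: int, n_total_tfs: int, threshold_pct: float = 0.8
) -> ShareReport:
    """Selected TFs as a percentage of all classified TFs.

    Reports ``100 * n_selected / n_total`` together with a comparison
    against ``threshold_pct`` (a specificity bound for the final network).
    """
    if n_total_tfs <= 0:
        raise ValueError("n_total_tfs must be positive")
    if not (0 <= n_selected_tfs <= n_total_tfs):
        raise ValueError("n_selected_tfs must lie in [0, n_total_tfs]")
    pct = 100.0 * n_selected_tfs / n_total_tfs
    return ShareReport(
        n_selected=n_selected_tfs,
        n_total=n_total_tfs,
        pct=pct,
        text=f"{pct:.2f}%",
        threshold_pct=threshold_pct,
        below_threshold=pct < threshold_pct,
    )
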