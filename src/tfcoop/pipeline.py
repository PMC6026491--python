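"""End-to-end orchestration of the four-branch cooperation workflow.

Stages: differential peak calling -> peak annotation -> differential
expression -> motif enrichment (AME), ChIP target enrichment (TFT),
transcriptomic target enrichment (TFT) and upstream-regulator scoring
(URA) -> family harmonization -> four-way intersection -> gene-level
refinement -> cooperation network and connectivity reports.

:func:`run_study` works on an in-memory :class:`~tfcoop.simulate.Study`;
:func:`run_pipeline` is the file-based wrapper that reads every input,
runs the same stages, and writes all intermediate and final tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as tio
from .annotation import annotate_peaks, differential_peaks, peaks_to_genes
from .enrichment import (
    ALL_BRANCHES,
    BRANCH_AME_CHIP,
    BRANCH_TFT_CHIP,
    BRANCH_TFT_TX,
    BRANCH_URA_TX,
    DERecord,
    EnrichmentRecord,
    Regulon,
    adjust_records,
    classify_regulation,
    differential_expression,
    fisher_one_sided,
    tft_enrichment,
    upstream_regulator,
)
from .families import TFClassTable, aggregate_family
from .motif import PSSM, batch_best_int_scores
from .network import (
    CooperationNetwork,
    build_network,
    connectivity_stats,
    intersect_families,
    network_share_report,
    refine_to_genes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Statistical knobs shared by the in-memory and file-based runners."""

    alpha: float = 0.05
    promoter_bp: int = 1000
    hit_pvalue_threshold: float = 1e-4
    z_threshold: float = 2.0
    min_overlap: int = 4
    require_direction: bool = True
    include_gene_body: bool = False
    branches: Sequence[str] = ALL_BRANCHES
    regulator: str = "regulator"
    hyperconnected_k: int = 3

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.promoter_bp <= 0:
            raise ValueError("promoter_bp must be positive")
        unknown = set(self.branches) - set(ALL_BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches {unknown}")


@dataclass
class PipelineResult:
    epigenomic_target_genes: set[str]
    de_records: list[DERecord]
    regulation_summary: object
    branch_records: dict[str, list[EnrichmentRecord]]
    family_results: dict[str, list]
    intersected_families: set[str]
    recovered_tfs: list[str]
    network: CooperationNetwork
    connectivity: object
    share: object


def motif_hit_genes(
    promoters: Mapping[str, str], pssm: PSSM, hit_pvalue_threshold: float
) -> set[str]:
    """Genes whose promoter carries a motif hit at the exact-p threshold."""
    genes = list(promoters)
    seqs = [promoters[g] for g in genes]
    cutoff = pssm.score_distribution().score_threshold(hit_pvalue_threshold)
    best = batch_best_int_scores(seqs, pssm)
    return {g for g, b in zip(genes, best) if b >= cutoff}


def run_study(
    promoters: Mapping[str, str],
    gene_models,
    peaks_control,
    peaks_knockdown,
    expr_control: pd.DataFrame,
    expr_knockdown: pd.DataFrame,
    regulons: Mapping[str, Regulon],
    motifs: Mapping[str, PSSM],
    tfclass: TFClassTable,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates."""
    params = params or PipelineParams()
    alpha = params.alpha

    # epigenomic target regions: binding defined by loss of signal after
    # knockdown, i.e. peaks gained in the control condition
    gained_ctrl, _ = differential_peaks(peaks_control, peaks_knockdown)
    annotations = annotate_peaks(gained_ctrl, gene_models, params.promoter_bp)
    target_genes = peaks_to_genes(annotations, params.include_gene_body)

    de_records = differential_expression(expr_control, expr_knockdown, alpha)
    de_set = [r for r in de_records if r.adj_pvalue < alpha]
    summary = classify_regulation(de_set)
    de_genes = {r.gene for r in de_set}
    measured = {r.gene for r in de_records}

    modeled = set(promoters)
    fg_ids = sorted(g for g in target_genes if g in modeled)
    bg_ids = sorted(modeled - set(fg_ids))

    raw: list[EnrichmentRecord] = []
    hit_sets: dict[str, set[str]] = {}
    if BRANCH_AME_CHIP in params.branches:
        if not fg_ids or not bg_ids:
            raise RuntimeError("AME branch needs non-empty foreground and background")
        modeled_ids = fg_ids + bg_ids
        seqs = [promoters[g] for g in modeled_ids]
        fg_set = set(fg_ids)
        for tf in sorted(motifs):
            # single scan per motif serves both the enrichment test and
            # the per-gene hit sets used as network evidence flags
            pssm = motifs[tf]
            cutoff = pssm.score_distribution().score_threshold(
                params.hit_pvalue_threshold
            )
            best = batch_best_int_scores(seqs, pssm)
            hits = {g for g, b in zip(modeled_ids, best) if b >= cutoff}
            hit_sets[tf] = hits
            a = len(hits & fg_set)
            c = len(hits) - a
            raw.append(
                EnrichmentRecord(
                    unit=pssm.name,
                    branch=BRANCH_AME_CHIP,
                    pvalue=fisher_one_sided(
                        a, len(fg_ids) - a, c, len(bg_ids) - c
                    ),
                    n_support=a,
                )
            )
    if BRANCH_TFT_CHIP in params.branches:
        for tf in sorted(regulons):
            raw.append(
                tft_enrichment(
                    set(fg_ids), regulons[tf], modeled, branch=BRANCH_TFT_CHIP
                )
            )
    if BRANCH_TFT_TX in params.branches:
        for tf in sorted(regulons):
            raw.append(
                tft_enrichment(de_genes, regulons[tf], measured, branch=BRANCH_TFT_TX)
            )
    if BRANCH_URA_TX in params.branches:
        for tf in sorted(regulons):
            raw.append(
                upstream_regulator(
                    de_records, regulons[tf], alpha=alpha,
                    min_overlap=params.min_overlap,
                )
            )
    adjusted = adjust_records(raw)
    branch_records = {b: [r for r in adjusted if r.branch == b] for b in params.branches}

    family_results = {
        b: aggregate_family(recs, tfclass, alpha)
        for b, recs in branch_records.items()
    }
    families = intersect_families(
        family_results, alpha, required_branches=tuple(params.branches)
    )

    gene_level = {
        b: branch_records[b]
        for b in (BRANCH_TFT_TX, BRANCH_URA_TX)
        if b in branch_records
    }
    if set(gene_level) == {BRANCH_TFT_TX, BRANCH_URA_TX}:
        recovered = refine_to_genes(
            families, gene_level, tfclass, alpha,
            require_direction=params.require_direction,
            z_threshold=params.z_threshold,
        )
    else:
        # without both transcriptomic branches there is no gene resolution;
        # fall back to all members of the intersected families
        recovered = sorted(
            m for bc in families for m in tfclass.members(bc)
        )

    per_branch_by_unit = {
        b: {r.unit: r for r in recs} for b, recs in branch_records.items()
    }
    network = build_network(
        recovered,
        regulons,
        de_records,
        set(fg_ids),
        motif_hits=hit_sets,
        regulator=params.regulator,
        families=families,
        table=tfclass,
        branch_records=per_branch_by_unit,
        alpha=alpha,
    )
    connectivity = connectivity_stats(network, k=params.hyperconnected_k)
    share = network_share_report(len(recovered), max(tfclass.n_members, 1))
    return PipelineResult(
        epigenomic_target_genes=set(fg_ids),
        de_records=de_records,
        regulation_summary=summary,
        branch_records=branch_records,
        family_results=family_results,
        intersected_families=families,
        recovered_tfs=recovered,
        network=network,
        connectivity=connectivity,
        share=share,
    )


@dataclass
class PipelineConfig:
    """File-based configuration; paths plus :class:`PipelineParams` knobs."""

    promoters: Path
    gene_models: Path
    peaks_control: Path
    peaks_knockdown: Path
    expr_control: Path
    expr_knockdown: Path
    regulons: Path
    motifs: Path
    tfclass: Path
    outdir: Path
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**raw.pop("params", {}))
        paths = {k: Path(v) for k, v in raw.items() if k != "seed"}
        return cls(params=params, seed=int(raw.get("seed", 0)), **{
            k: v for k, v in paths.items() if k != "seed"
        })

    def digest(self) -> str:
        blob = json.dumps(
            {
                **{k: str(getattr(self, k)) for k in (
                    "promoters", "gene_models", "peaks_control", "peaks_knockdown",
                    "expr_control", "expr_knockdown", "regulons", "motifs",
                    "tfclass", "outdir",
                )},
                "params": dataclasses.asdict(self.params),
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _records_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit": r.unit,
                "branch": r.branch,
                "pvalue": r.pvalue,
                "adj_pvalue": r.adj_pvalue,
                "z": r.z,
                "n_support": r.n_support,
            }
            for r in records
        ],
        columns=["unit", "branch", "pvalue", "adj_pvalue", "z", "n_support"],
    )


def run_pipeline(config: PipelineConfig) -> tuple[PipelineResult, dict[str, Path]]:
    """Read all inputs, run every stage and write result tables.

    Returns the in-memory result and a manifest of written files.  Runs
    are deterministic: the same configuration produces byte-identical
    outputs, and the manifest records the configuration digest.
    """
    for name in (
        "promoters", "gene_models", "peaks_control", "peaks_knockdown",
        "expr_control", "expr_knockdown", "regulons", "motifs", "tfclass",
    ):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")

    stage = "read inputs"
    try:
        promoters = tio.read_fasta(config.promoters)
        gene_models = tio.read_gene_models(config.gene_models)
        peaks_control = tio.read_bed(config.peaks_control)
        peaks_knockdown = tio.read_bed(config.peaks_knockdown)
        expr_control = tio.read_expression(config.expr_control)
        expr_knockdown = tio.read_expression(config.expr_knockdown)
        regulons = tio.read_regulons(config.regulons)
        motifs = {p.name: p for p in tio.read_meme(config.motifs)}
        tfclass = tio.read_tfclass(config.tfclass)
        stage = "run analysis"
        result = run_study(
            promoters, gene_models, peaks_control, peaks_knockdown,
            expr_control, expr_knockdown, regulons, motifs, tfclass,
            config.params,
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    tio.write_de_table(outdir / "de_table.tsv", result.de_records)
    manifest["de_table"] = outdir / "de_table.tsv"

    for branch, recs in result.branch_records.items():
        path = outdir / f"enrichment_{branch}.tsv"
        _records_frame(recs).to_csv(path, sep="\t", index=False)
        manifest[f"enrichment_{branch}"] = path

    for branch, fams in result.family_results.items():
        path = outdir / f"families_{branch}.tsv"
        pd.DataFrame([dataclasses.asdict(f) for f in fams]).to_csv(
            path, sep="\t", index=False
        )
        manifest[f"families_{branch}"] = path

    edges_path = outdir / "network_edges.tsv"
    pd.DataFrame(
        [dataclasses.asdict(e) for e in result.network.edges],
        columns=["tf", "target", "sign", "motif_hit", "peak_promoter", "de_target"],
    ).to_csv(edges_path, sep="\t", index=False)
    manifest["network_edges"] = edges_path

    nodes_path = outdir / "network_nodes.tsv"
    result.network.tfs.to_csv(nodes_path, sep="\t", index=False)
    manifest["network_nodes"] = nodes_path

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "branches": list(config.params.branches),
        "n_epigenomic_target_genes": len(result.epigenomic_target_genes),
        "n_de_genes": int(
            sum(r.adj_pvalue < config.params.alpha for r in result.de_records)
        ),
        "pct_positively_regulated": result.regulation_summary.fraction_positive_pct,
        "pct_negatively_regulated": result.regulation_summary.fraction_negative_pct,
        "intersected_families": sorted(result.intersected_families),
        "recovered_tfs": result.recovered_tfs,
        "n_hyperconnected_targets": result.connectivity.n_hyperconnected,
        "network_share_pct": result.share.pct,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    manifest["summary"] = summary_path

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {k: str(v) for k, v in sorted(manifest.items())},
            indent=1, sort_keys=True,
        )
        + "\n"
    )
    manifest["manifest"] = manifest_path
    logger.info("pipeline finished: %d TFs recovered", len(result.recovered_tfs))
    return result, manifest


def run_study_object(study, params: PipelineParams | None = None) -> PipelineResult:
    """Convenience wrapper running :func:`run_study` on a simulated study."""
    return run_study(
        study.promoters,
        study.gene_models,
        study.peaks_control,
        study.peaks_knockdown,
        study.expr_control,
        study.expr_knockdown,
        study.regulons,
        study.motifs,
        study.tfclass,
        params,
    )
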