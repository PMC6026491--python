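"""Self-contained toy study generator with known ground truth.

The generator emulates a knockdown study of an epigenomic master regulator:
a set of "cooperating" transcription factors has (i) binding motifs planted
in the promoters of its regulon targets, (ii) differential promoter peaks
(present in control, lost upon knockdown of the epigenomic factor) at those
promoters, and (iii) replicate expression matrices in which the regulon
targets shift directionally when the factor is knocked down — with the sign
set by the regulon edge sign times the direction of factor loss (an
activating target of a cooperating TF goes *down* under knockdown).

Decoy TFs are supported in only the branches named in ``decoy_spec`` and
are constructed so that the violated branch is structurally null rather
than merely at chance level: a decoy lacking motif support has its motif
planted away from the epigenomic target promoters; a decoy lacking peak
support draws its regulon from genes without differential peaks; a decoy
lacking directional support shifts its targets with exactly balanced signs.
An optional family "sibling" shares a cooperating TF's motif and family
barcode but has no functional support of its own, exercising the
family-versus-gene resolution of the downstream intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval
from .enrichment import (
    BRANCH_AME_CHIP,
    BRANCH_TFT_CHIP,
    BRANCH_TFT_TX,
    BRANCH_URA_TX,
    Regulon,
)
from .families import FamilyEntry, TFClassTable
from .motif import ALPHABET, PSSM

REGULATOR = "EPIFACTOR"

_DEFAULT_DECOYS: Mapping[str, frozenset[str]] = {
    # supported branches; the missing one is structurally violated
    "DECOY_NOAME": frozenset({BRANCH_TFT_CHIP, BRANCH_URA_TX, BRANCH_TFT_TX}),
    "DECOY_NOCHIP": frozenset({BRANCH_AME_CHIP, BRANCH_URA_TX, BRANCH_TFT_TX}),
    "DECOY_NOURA": frozenset({BRANCH_AME_CHIP, BRANCH_TFT_CHIP, BRANCH_TFT_TX}),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic knockdown experiment.

    Defaults describe a compact but realistic microarray-scale design: a
    few hundred modeled promoters, strongly occupied cooperating motifs
    against a sparse background, high but imperfect differential peak
    rates, and a two-unit log2 expression effect over triplicates.
    """

    seed: int = 0
    n_genes: int = 600
    promoter_len: int = 1000
    n_tfs: int = 10
    n_cooperating: int = 3
    regulon_size: int = 60
    motif_len: int = 10
    fg_occupancy: float = 0.8
    bg_occupancy: float = 0.05
    peak_rate_target: float = 0.8
    peak_rate_bg: float = 0.05
    lfc_effect: float = 2.0
    lfc_noise_sd: float = 0.25
    n_replicates: int = 3
    decoy_spec: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_DECOYS)
    )
    n_siblings: int = 1
    gc_content: float = 0.5
    motif_sharpness: float = 0.9
    gene_length: int = 2000
    gene_spacing: int = 3000
    peak_len: int = 200

    def __post_init__(self):
        if not (0 <= self.bg_occupancy < self.fg_occupancy <= 1):
            raise ValueError("require 0 <= bg_occupancy < fg_occupancy <= 1")
        if self.n_cooperating > self.n_tfs:
            raise ValueError("n_cooperating must not exceed n_tfs")
        n_special = self.n_cooperating + len(self.decoy_spec) + self.n_siblings
        if n_special > self.n_tfs:
            raise ValueError(
                "n_tfs must cover cooperating TFs, decoy_spec entries and siblings"
            )
        if not (self.promoter_len > self.motif_len >= 4):
            raise ValueError("require promoter_len > motif_len >= 4")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        if not (0.25 <= self.motif_sharpness <= 1):
            raise ValueError("motif_sharpness must lie in [0.25, 1]")
        if self.regulon_size < 1 or self.regulon_size > self.n_genes:
            raise ValueError("regulon_size must lie in [1, n_genes]")
        for tf, branches in self.decoy_spec.items():
            bad = set(branches) - {
                BRANCH_AME_CHIP, BRANCH_TFT_CHIP, BRANCH_URA_TX, BRANCH_TFT_TX
            }
            if bad:
                raise ValueError(f"decoy_spec[{tf!r}] names unknown branches {bad}")
        if not (0 <= self.peak_rate_bg <= 1 and 0 <= self.peak_rate_target <= 1):
            raise ValueError("peak rates must lie in [0, 1]")
        if self.lfc_noise_sd < 0:
            raise ValueError("lfc_noise_sd must be non-negative")
        if self.gene_spacing <= self.promoter_len:
            raise ValueError("gene_spacing must exceed promoter_len")
        if self.peak_len > self.promoter_len:
            raise ValueError("peak_len must not exceed promoter_len")

    @property
    def base_composition(self) -> np.ndarray:
        at = (1 - self.gc_content) / 2
        gc = self.gc_content / 2
        return np.array([at, gc, gc, at])


@dataclass
class GroundTruth:
    cooperating_tfs: set[str]
    regulons: dict[str, dict[str, int]]
    planted_sites: list[tuple[str, str, int, str]]  # (gene, tf, offset, strand)
    de_true: set[str]
    peak_true: set[str]
    decoy_tfs: set[str]
    sibling_tfs: set[str]


@dataclass
class Study:
    """In-memory bundle of everything a pipeline run consumes."""

    config: SimConfig
    promoters: dict[str, str]                 # gene -> promoter sequence
    gene_models: list[GeneModel]
    peaks_control: list[GenomicInterval]
    peaks_knockdown: list[GenomicInterval]
    expr_control: pd.DataFrame
    expr_knockdown: pd.DataFrame
    regulons: dict[str, Regulon]
    motifs: dict[str, PSSM]
    tfclass: TFClassTable
    truth: GroundTruth


def _tf_names(config: SimConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    coop = [f"COOP{i + 1}" for i in range(config.n_cooperating)]
    decoys = sorted(config.decoy_spec)
    siblings = [f"SIB_{coop[i % len(coop)]}" for i in range(config.n_siblings)] if coop else []
    n_null = config.n_tfs - len(coop) - len(decoys) - len(siblings)
    nulls = [f"NULL{i + 1}" for i in range(n_null)]
    return coop, decoys, siblings, nulls


def _sample_motif(rng: np.random.Generator, config: SimConfig, name: str) -> PSSM:
    consensus = rng.integers(0, 4, size=config.motif_len)
    mat = np.full((config.motif_len, 4), (1 - config.motif_sharpness) / 3)
    mat[np.arange(config.motif_len), consensus] = config.motif_sharpness
    return PSSM(name, mat, pseudocount=0.01)


def _plant(
    rng: np.random.Generator,
    promoters: dict[str, np.ndarray],
    gene: str,
    pssm: PSSM,
    tf: str,
    sites: list[tuple[str, str, int, str]],
) -> None:
    """Insert one instance sampled column-wise from the raw matrix."""
    w = pssm.width
    seq = promoters[gene]
    offset = int(rng.integers(0, len(seq) - w + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    inst = np.array([
        rng.choice(4, p=pssm.raw_matrix[i] / pssm.raw_matrix[i].sum())
        for i in range(w)
    ])
    if strand == "-":
        inst = (3 - inst)[::-1]  # reverse complement
    seq[offset:offset + w] = inst
    sites.append((gene, tf, offset, strand))


def generate_study(config: SimConfig) -> Study:
    """Generate the full toy study; fully deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    coop, decoys, siblings, nulls = _tf_names(config)
    sibling_of = {s: s.split("_", 1)[1] for s in siblings}
    all_tfs = coop + decoys + siblings + nulls

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    margin = 5000
    gene_models = []
    for i, g in enumerate(genes):
        start = margin + i * (config.gene_length + config.gene_spacing)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_models.append(
            GeneModel(g, "chr1", start, start + config.gene_length, strand)
        )
    models = {g.gene: g for g in gene_models}

    # background promoter sequence, i.i.d. with configurable composition
    comp = config.base_composition
    promoters_arr = {
        g: rng.choice(4, size=config.promoter_len, p=comp) for g in genes
    }

    # motifs (siblings share their cooperating partner's matrix)
    motifs: dict[str, PSSM] = {}
    for tf in coop + decoys + nulls:
        motifs[tf] = _sample_motif(rng, config, tf)
    for s, partner in sibling_of.items():
        motifs[s] = PSSM(s, motifs[partner].raw_matrix, pseudocount=0.01)

    # regulons: random signed target sets; the peak-violating decoys are
    # drawn later, restricted to peak-free genes
    def draw_regulon(pool: Sequence[str]) -> dict[str, int]:
        targets = rng.choice(len(pool), size=config.regulon_size, replace=False)
        return {
            pool[int(t)]: (1 if rng.random() < 0.65 else -1) for t in targets
        }

    nochip_decoys = [d for d in decoys if BRANCH_TFT_CHIP not in config.decoy_spec[d]]
    regulon_edges: dict[str, dict[str, int]] = {}
    for tf in all_tfs:
        if tf in nochip_decoys:
            continue
        regulon_edges[tf] = draw_regulon(genes)

    # differential promoter peaks: present in control, lost upon knockdown
    peak_true: set[str] = set()
    for tf in coop + [d for d in decoys if BRANCH_TFT_CHIP in config.decoy_spec[d]]:
        for target in sorted(regulon_edges[tf]):
            if rng.random() < config.peak_rate_target:
                peak_true.add(target)
    for g in genes:
        if g not in peak_true and rng.random() < config.peak_rate_bg:
            peak_true.add(g)

    for d in nochip_decoys:
        pool = [g for g in genes if g not in peak_true]
        if len(pool) < config.regulon_size:
            raise ValueError(
                f"regulon_size: only {len(pool)} peak-free genes available for "
                f"decoy {d}; lower regulon_size or peak rates, or raise n_genes"
            )
        regulon_edges[d] = draw_regulon(pool)

    def promoter_peak(gene: str) -> GenomicInterval:
        lo, hi = models[gene].promoter_window(config.promoter_len)
        start = int(rng.integers(lo, hi - config.peak_len + 1))
        return GenomicInterval("chr1", start, start + config.peak_len, name=f"pk_{gene}")

    peaks_control: list[GenomicInterval] = []
    peaks_knockdown: list[GenomicInterval] = []
    for g in sorted(peak_true):
        peaks_control.append(promoter_peak(g))
    # non-differential peaks shared by both conditions (gene bodies)
    for g in genes:
        if rng.random() < 0.15:
            m = models[g]
            start = int(rng.integers(m.start, m.end - config.peak_len + 1))
            shared = GenomicInterval("chr1", start, start + config.peak_len, name=f"sh_{g}")
            peaks_control.append(shared)
            peaks_knockdown.append(shared)
    # knockdown-only noise peaks (gain of signal after factor loss)
    for g in genes:
        if rng.random() < 0.03:
            peaks_knockdown.append(promoter_peak(g))

    # motif planting
    planted_sites: list[tuple[str, str, int, str]] = []
    peak_list = sorted(peak_true)
    for tf in all_tfs:
        pssm = motifs[tf]
        if tf in sibling_of:
            continue  # sibling shares its partner's motif; no separate planting
        if tf in coop or (tf in decoys and BRANCH_TFT_CHIP in config.decoy_spec[tf]
                          and BRANCH_AME_CHIP in config.decoy_spec[tf]):
            fg_genes = set(regulon_edges[tf])
        elif tf in decoys and BRANCH_AME_CHIP in config.decoy_spec[tf]:
            fg_genes = set(peak_list)  # motif support without own peak targets
        else:
            fg_genes = set()
        if tf in decoys and BRANCH_AME_CHIP not in config.decoy_spec[tf]:
            # structural violation: never planted in epigenomic target promoters
            bg_pool = [g for g in genes if g not in peak_true]
        else:
            bg_pool = [g for g in genes if g not in fg_genes]
        for g in sorted(fg_genes):
            if rng.random() < config.fg_occupancy:
                _plant(rng, promoters_arr, g, pssm, tf, planted_sites)
        for g in bg_pool:
            if rng.random() < config.bg_occupancy:
                _plant(rng, promoters_arr, g, pssm, tf, planted_sites)

    # expression: knockdown of the factor silences cooperating TFs, so an
    # activating edge (+1) pushes its target down (negative log fold change)
    shift = {g: 0.0 for g in genes}
    expr_supported = [
        tf for tf in coop + decoys
        if tf in coop or BRANCH_TFT_TX in config.decoy_spec[tf]
    ]
    for tf in expr_supported:
        consistent = tf in coop or BRANCH_URA_TX in config.decoy_spec[tf]
        targets = sorted(regulon_edges[tf])
        if consistent:
            for target in targets:
                if shift[target] != 0.0:
                    continue  # first regulator wins on shared targets
                shift[target] = -regulon_edges[tf][target] * config.lfc_effect
        else:
            # structurally violate directionality: choose each remaining
            # target's shift so the TF's net edge/response consistency
            # (including collisions already fixed by earlier regulators)
            # stays balanced around zero
            balance = 0
            for target in targets:
                sign = regulon_edges[tf][target]
                if shift[target] != 0.0:
                    balance += int(np.sign(-shift[target] * sign))
            for target in targets:
                if shift[target] != 0.0:
                    continue
                flip = -1 if balance > 0 else 1
                shift[target] = -regulon_edges[tf][target] * config.lfc_effect * flip
                balance += flip

    de_true = {g for g in genes if shift[g] != 0.0}
    base = rng.normal(8.0, 1.0, size=config.n_genes)
    rep_sd = config.lfc_noise_sd * np.sqrt(config.n_replicates / 2.0)
    shape = (config.n_genes, config.n_replicates)
    ctrl = base[:, None] + rng.normal(0.0, 1.0, size=shape) * rep_sd
    kd = (
        base[:, None]
        + np.array([shift[g] for g in genes])[:, None]
        + rng.normal(0.0, 1.0, size=shape) * rep_sd
    )
    rep_cols = [f"rep{j + 1}" for j in range(config.n_replicates)]
    expr_control = pd.DataFrame(ctrl, index=genes, columns=rep_cols)
    expr_knockdown = pd.DataFrame(kd, index=genes, columns=rep_cols)

    # TFClass fixture: one family per TF, siblings join their partner
    entries = []
    barcode_members: dict[str, set[str]] = {}
    for i, tf in enumerate(coop + decoys + nulls):
        barcode = f"{i % 3 + 1}.{i // 3 + 1}.{i + 1}"
        barcode_members[barcode] = {tf}
        if tf in sibling_of.values():
            barcode_members[barcode].update(
                s for s, p in sibling_of.items() if p == tf
            )
    for barcode, members in barcode_members.items():
        entries.append(
            FamilyEntry(barcode, f"family_{barcode.replace('.', '_')}", frozenset(members))
        )
    tfclass = TFClassTable(entries)

    promoters = {
        g: "".join(ALPHABET[b] for b in promoters_arr[g]) for g in genes
    }
    regulons = {tf: Regulon(tf, dict(sorted(e.items()))) for tf, e in regulon_edges.items()}
    truth = GroundTruth(
        cooperating_tfs=set(coop),
        regulons={tf: dict(r.edges) for tf, r in regulons.items()},
        planted_sites=planted_sites,
        de_true=de_true,
        peak_true=peak_true,
        decoy_tfs=set(decoys),
        sibling_tfs=set(siblings),
    )
    return Study(
        config=config,
        promoters=promoters,
        gene_models=gene_models,
        peaks_control=peaks_control,
        peaks_knockdown=peaks_knockdown,
        expr_control=expr_control,
        expr_knockdown=expr_knockdown,
        regulons=regulons,
        motifs=motifs,
        tfclass=tfclass,
        truth=truth,
    )


def write_fixture(outdir: str | Path, study: Study) -> dict[str, Path]:
    """Write the study to plain-text files; returns the file manifest.

    Re-reading the files with :func:`read_fixture` reproduces the
    in-memory study (sequences and tables bit-exactly; expression values
    at the printed precision).
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "promoters": outdir / "promoters.fasta",
        "gene_models": outdir / "gene_models.tsv",
        "peaks_control": outdir / "peaks_control.bed",
        "peaks_knockdown": outdir / "peaks_knockdown.bed",
        "expr_control": outdir / "expr_control.tsv",
        "expr_knockdown": outdir / "expr_knockdown.tsv",
        "regulons": outdir / "regulons.tsv",
        "motifs": outdir / "motifs.meme",
        "tfclass": outdir / "tfclass.tsv",
        "truth": outdir / "truth.json",
    }
    tio.write_fasta(manifest["promoters"], study.promoters)
    tio.write_gene_models(manifest["gene_models"], study.gene_models)
    tio.write_bed(manifest["peaks_control"], study.peaks_control)
    tio.write_bed(manifest["peaks_knockdown"], study.peaks_knockdown)
    tio.write_expression(manifest["expr_control"], study.expr_control)
    tio.write_expression(manifest["expr_knockdown"], study.expr_knockdown)
    tio.write_regulons(manifest["regulons"], study.regulons)
    tio.write_meme(manifest["motifs"], list(study.motifs.values()))
    tio.write_tfclass(manifest["tfclass"], study.tfclass)
    truth = study.truth
    manifest["truth"].write_text(
        json.dumps(
            {
                "cooperating_tfs": sorted(truth.cooperating_tfs),
                "regulons": {
                    tf: dict(sorted(edges.items()))
                    for tf, edges in sorted(truth.regulons.items())
                },
                "planted_sites": sorted(truth.planted_sites),
                "de_true": sorted(truth.de_true),
                "peak_true": sorted(truth.peak_true),
                "decoy_tfs": sorted(truth.decoy_tfs),
                "sibling_tfs": sorted(truth.sibling_tfs),
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    return manifest


def read_fixture(outdir: str | Path, config: SimConfig | None = None) -> Study:
    """Read a study fixture written by :func:`write_fixture`."""
    from . import io as tio

    outdir = Path(outdir)
    truth_raw = json.loads((outdir / "truth.json").read_text())
    truth = GroundTruth(
        cooperating_tfs=set(truth_raw["cooperating_tfs"]),
        regulons={
            tf: {g: int(s) for g, s in edges.items()}
            for tf, edges in truth_raw["regulons"].items()
        },
        planted_sites=[tuple(s) for s in truth_raw["planted_sites"]],
        de_true=set(truth_raw["de_true"]),
        peak_true=set(truth_raw["peak_true"]),
        decoy_tfs=set(truth_raw["decoy_tfs"]),
        sibling_tfs=set(truth_raw["sibling_tfs"]),
    )
    motifs = {p.name: p for p in tio.read_meme(outdir / "motifs.meme")}
    return Study(
        config=config if config is not None else SimConfig(),
        promoters=tio.read_fasta(outdir / "promoters.fasta"),
        gene_models=tio.read_gene_models(outdir / "gene_models.tsv"),
        peaks_control=tio.read_bed(outdir / "peaks_control.bed"),
        peaks_knockdown=tio.read_bed(outdir / "peaks_knockdown.bed"),
        expr_control=tio.read_expression(outdir / "expr_control.tsv"),
        expr_knockdown=tio.read_expression(outdir / "expr_knockdown.tsv"),
        regulons=tio.read_regulons(outdir / "regulons.tsv"),
        motifs=motifs,
        tfclass=tio.read_tfclass(outdir / "tfclass.tsv"),
        truth=truth,
    )
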