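"""Statistical branches: motif enrichment, TF-target enrichment, upstream
regulator scoring, differential expression and multiple-testing control.

Four branches of evidence are produced, tagged by the constants below:

* ``AME_chip``  — motif over-representation in epigenomic target promoters
  versus the remaining promoters (Fisher exact on best-hit thresholding).
* ``TFT_chip``  — hypergeometric enrichment of a TF's regulon among
  epigenomic target genes.
* ``TFT_tx``    — hypergeometric enrichment of a TF's regulon among
  differentially expressed genes.
* ``URA_tx``    — the same overlap test plus a directional activation
  z-score computed from the signs of the regulon edges and the observed
  expression changes.

The activation score follows the standard upstream-regulator formula
``z = (N_consistent - N_inconsistent) / sqrt(N)`` over the N regulon
targets that are differentially expressed.  Differential expression is
measured as knockdown-versus-control of the epigenomic factor, so observed
directions are inverted before the consistency count: positive z means the
regulator is active when the epigenomic factor is present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motif import PSSM, batch_best_int_scores

BRANCH_AME_CHIP = "AME_chip"
BRANCH_TFT_CHIP = "TFT_chip"
BRANCH_URA_TX = "URA_tx"
BRANCH_TFT_TX = "TFT_tx"
ALL_BRANCHES = (BRANCH_AME_CHIP, BRANCH_TFT_CHIP, BRANCH_URA_TX, BRANCH_TFT_TX)


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential expression statistics (knockdown vs control)."""

    gene: str
    log_fc: float
    pvalue: float
    adj_pvalue: float
    direction: int  # sign of log_fc; +1 for log_fc == 0

    def __post_init__(self):
        if not (0 <= self.pvalue <= 1 and 0 <= self.adj_pvalue <= 1):
            raise ValueError(f"gene {self.gene}: p-values must lie in [0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError(f"gene {self.gene}: direction must be -1 or +1")


@dataclass(frozen=True)
class Regulon:
    """A TF's signed target set: +1 activating, -1 repressing edges."""

    tf: str
    edges: Mapping[str, int]

    def __post_init__(self):
        if len(self.edges) == 0:
            raise ValueError(f"regulon {self.tf}: needs at least one edge")
        bad = [t for t, s in self.edges.items() if s not in (-1, 1)]
        if bad:
            raise ValueError(f"regulon {self.tf}: edge signs must be -1/+1 ({bad[:3]})")

    @property
    def targets(self) -> set[str]:
        return set(self.edges)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One TF or motif result from one evidence branch."""

    unit: str
    branch: str
    pvalue: float
    adj_pvalue: float | None = None
    z: float | None = None
    n_support: int = 0


def differential_expression(
    expr_control: pd.DataFrame,
    expr_knockdown: pd.DataFrame,
    alpha: float = 0.05,
) -> list[DERecord]:
    """Per-gene Welch t-test on log-scale expression, BH-adjusted.

    Both frames are genes x replicates on the log scale with matching gene
    indices.  ``log_fc`` is mean(knockdown) - mean(control).  Genes with
    zero pooled variance get p = 0 when their means differ and p = 1
    otherwise (the degenerate noise-free case).
    """
    if expr_control.shape[1] < 2 or expr_knockdown.shape[1] < 2:
        raise ValueError("need at least 2 replicates per condition")
    if set(expr_control.index) != set(expr_knockdown.index):
        raise ValueError("conditions must cover the same gene set")
    kd = expr_knockdown.loc[expr_control.index]
    a = expr_control.to_numpy(float)
    b = kd.to_numpy(float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(pvals)
    pvals[degenerate] = np.where(np.abs(lfc[degenerate]) > 0, 0.0, 1.0)
    adj = bh_adjust(pvals)
    out = []
    for gene, l, p, q in zip(expr_control.index, lfc, pvals, adj):
        out.append(
            DERecord(
                gene=str(gene),
                log_fc=float(l),
                pvalue=float(p),
                adj_pvalue=float(q),
                direction=-1 if l < 0 else 1,
            )
        )
    return out


@dataclass(frozen=True)
class RegulationSummary:
    positively_regulated: frozenset[str]
    negatively_regulated: frozenset[str]
    fraction_positive_pct: float | None
    fraction_negative_pct: float | None
    defined: bool


def classify_regulation(
    de_records: Iterable[DERecord], perturbation: str = "knockdown"
) -> RegulationSummary:
    """Split differential genes by the sign of regulation by the factor.

    Under a knockdown perturbation, genes that go down (direction -1) are
    positively regulated by the factor's activity and genes that go up are
    negatively regulated.  Fractions are percentages rounded to one
    decimal.  The input is taken to be the differential gene set (filter
    on ``adj_pvalue`` before calling).
    """
    if perturbation not in ("knockdown", "overexpression"):
        raise ValueError("perturbation must be 'knockdown' or 'overexpression'")
    flip = -1 if perturbation == "knockdown" else 1
    records = list(de_records)
    pos = frozenset(r.gene for r in records if r.direction == flip)
    neg = frozenset(r.gene for r in records if r.direction == -flip)
    total = len(pos) + len(neg)
    if total == 0:
        return RegulationSummary(pos, neg, None, None, defined=False)
    fpos = round(100.0 * len(pos) / total, 1)
    fneg = round(100.0 * len(neg) / total, 1)
    return RegulationSummary(pos, neg, fpos, fneg, defined=True)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact enrichment-tail p for the 2x2 table [[a, b], [c, d]].

    Upper (enrichment) tail of the hypergeometric distribution with all
    margins fixed: ``P(X >= a)`` for ``X ~ Hypergeom(M=a+b+c+d, K=a+b,
    n=a+c)``.  An all-zero table has p = 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"cell {name} must be a non-negative integer")
    total = a + b + c + d
    if total == 0:
        return 1.0
    p = float(stats.hypergeom.sf(a - 1, total, a + b, a + c))
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def motif_enrichment(
    foreground_seqs: Sequence[str],
    background_seqs: Sequence[str],
    pssm: PSSM,
    hit_pvalue_threshold: float = 1e-4,
) -> EnrichmentRecord:
    """Motif over-representation in foreground vs background promoters.

    A sequence is a hit when its best window's exact score p-value is at
    most ``hit_pvalue_threshold``; hit counts go into a one-sided Fisher
    exact test.  BH adjustment across motifs is the caller's job.
    """
    if len(foreground_seqs) == 0:
        raise ValueError("foreground sequence set must be non-empty")
    if len(background_seqs) == 0:
        raise ValueError("background sequence set must be non-empty")
    for s in (*foreground_seqs, *background_seqs):
        if len(s) < pssm.width:
            raise ValueError("all sequences must be at least the motif width")
    dist = pssm.score_distribution()
    cutoff = dist.score_threshold(hit_pvalue_threshold)
    fg = batch_best_int_scores(foreground_seqs, pssm)
    bg = batch_best_int_scores(background_seqs, pssm)
    a = int(np.sum(fg >= cutoff))
    c = int(np.sum(bg >= cutoff))
    p = fisher_one_sided(a, len(foreground_seqs) - a, c, len(background_seqs) - c)
    return EnrichmentRecord(
        unit=pssm.name, branch=BRANCH_AME_CHIP, pvalue=p, n_support=a
    )


def tft_enrichment(
    query_genes: Iterable[str],
    regulon: Regulon,
    universe: Iterable[str],
    branch: str = BRANCH_TFT_CHIP,
) -> EnrichmentRecord:
    """Hypergeometric upper-tail enrichment of a regulon in a query set."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    targets = regulon.targets & universe
    k = len(query & targets)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(targets), len(query)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return EnrichmentRecord(unit=regulon.tf, branch=branch, pvalue=p, n_support=k)


def upstream_regulator(
    de_records: Sequence[DERecord],
    regulon: Regulon,
    alpha: float = 0.05,
    min_overlap: int = 4,
) -> EnrichmentRecord:
    """Directional upstream-regulator score plus overlap enrichment.

    ``de_records`` covers all measured genes; the differential set is
    ``adj_pvalue < alpha``.  The overlap p-value is the hypergeometric tail
    against the measured-gene universe.  The activation z sums edge-sign /
    observed-direction agreement over the overlapping differential targets
    (knockdown directions inverted, see module docstring) and is reported
    only when the overlap reaches ``min_overlap``.
    """
    universe = {r.gene for r in de_records}
    de = {r.gene: r for r in de_records if r.adj_pvalue < alpha}
    rec = tft_enrichment(set(de), regulon, universe, branch=BRANCH_URA_TX)
    overlap = [g for g in regulon.targets if g in de]
    z = None
    if len(overlap) >= min_overlap:
        consistency = [-de[g].direction * regulon.edges[g] for g in overlap]
        z = float(np.sum(consistency) / np.sqrt(len(overlap)))
    return replace(rec, z=z, n_support=len(overlap))


def adjust_records(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """BH-adjust p-values within each branch, preserving record order."""
    out: list[EnrichmentRecord | None] = [None] * len(records)
    by_branch: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_branch.setdefault(r.branch, []).append(i)
    for idxs in by_branch.values():
        adj = bh_adjust([records[i].pvalue for i in idxs])
        for i, q in zip(idxs, adj):
            out[i] = replace(records[i], adj_pvalue=float(q))
    return [r for r in out if r is not None]
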