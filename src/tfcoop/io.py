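"""Readers and writers for the plain-text formats the workflow consumes.

Dialects: FASTA promoters (header = gene symbol); BED6 peaks (0-based
half-open); TSV gene models ``gene  chrom  start  end  strand``; TSV
expression matrices (genes x replicates, one file per condition); TSV
regulons ``tf  target  sign``; MEME minimal motif files; TSV TFClass
tables ``barcode  family_name  member``.  Malformed lines are rejected
with the file, line number and offending field named.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, GenomicInterval
from .enrichment import DERecord, Regulon
from .families import FamilyEntry, TFClassTable
from .motif import PSSM


class FormatError(ValueError):
    """A file violated its dialect; message names file, line and field."""


def _fail(path, lineno, msg):
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ------------------------------------------------------------------ BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, "BED needs at least 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            if start >= end or start < 0:
                _fail(path, lineno, f"invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                _fail(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                _fail(path, lineno, f"invalid strand {strand!r}")
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------- gene models

_GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise FormatError(f"{path}:1: header must be {_GENE_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                _fail(path, lineno, "expected 5 tab-separated fields")
            gene, chrom, start_s, end_s, strand = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            try:
                out.append(GeneModel(gene, chrom, start, end, strand))
            except ValueError as e:
                _fail(path, lineno, str(e))
    return out


def write_gene_models(path: str | Path, models: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for m in models:
            fh.write(f"{m.gene}\t{m.chrom}\t{m.start}\t{m.end}\t{m.strand}\n")


# ----------------------------------------------------------- expression

def read_expression(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix needs replicate columns")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene {dup!r}")
    if not np.issubdtype(frame.to_numpy().dtype, np.number):
        raise FormatError(f"{path}: non-numeric expression values")
    frame.index.name = "gene"
    return frame


def write_expression(path: str | Path, frame: pd.DataFrame) -> None:
    out = frame.copy()
    out.index.name = "gene"
    # 17 significant digits round-trip float64 exactly
    out.to_csv(path, sep="\t", float_format="%.17g")


# ------------------------------------------------------------- DE table

_DE_COLUMNS = ["gene", "log_fc", "pvalue", "adj_pvalue"]


def read_de_table(path: str | Path) -> list[DERecord]:
    frame = pd.read_csv(path, sep="\t")
    if list(frame.columns)[:4] != _DE_COLUMNS:
        raise FormatError(f"{path}:1: header must start with {_DE_COLUMNS}")
    out = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            lfc = float(row.log_fc)
            out.append(
                DERecord(
                    gene=str(row.gene),
                    log_fc=lfc,
                    pvalue=float(row.pvalue),
                    adj_pvalue=float(row.adj_pvalue),
                    direction=-1 if lfc < 0 else 1,
                )
            )
        except (TypeError, ValueError) as e:
            _fail(path, i, str(e))
    return out


def write_de_table(path: str | Path, records: Sequence[DERecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DE_COLUMNS + ["direction"]) + "\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.log_fc:.6f}\t{r.pvalue:.6g}"
                f"\t{r.adj_pvalue:.6g}\t{r.direction:+d}\n"
            )


# -------------------------------------------------------------- regulons

def read_regulons(path: str | Path) -> dict[str, Regulon]:
    edges: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["tf", "target", "sign"]:
            raise FormatError(f"{path}:1: header must be ['tf', 'target', 'sign']")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                _fail(path, lineno, "expected 3 tab-separated fields")
            tf, target, sign_s = fields
            if sign_s not in ("-1", "+1", "1"):
                _fail(path, lineno, f"sign must be -1 or +1, got {sign_s!r}")
            per = edges.setdefault(tf, {})
            if target in per:
                _fail(path, lineno, f"duplicate target {target!r} for {tf}")
            per[target] = int(sign_s)
    return {tf: Regulon(tf, e) for tf, e in edges.items()}


def write_regulons(path: str | Path, regulons: Mapping[str, Regulon]) -> None:
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tsign\n")
        for tf in sorted(regulons):
            for target, sign in sorted(regulons[tf].edges.items()):
                fh.write(f"{tf}\t{target}\t{sign:+d}\n")


# --------------------------------------------------------------- TFClass

def read_tfclass(path: str | Path) -> TFClassTable:
    rows: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["barcode", "family_name", "member"]:
            raise FormatError(
                f"{path}:1: header must be ['barcode', 'family_name', 'member']"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                _fail(path, lineno, "expected 3 tab-separated fields")
            barcode, family_name, member = fields
            name, members = rows.setdefault(barcode, (family_name, set()))
            if name != family_name:
                _fail(path, lineno, f"conflicting names for family {barcode}")
            members.add(member)
    try:
        return TFClassTable(
            FamilyEntry(b, name, frozenset(members))
            for b, (name, members) in rows.items()
        )
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_tfclass(path: str | Path, table: TFClassTable) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tfamily_name\tmember\n")
        for e in table.entries:
            for m in sorted(e.members):
                fh.write(f"{e.barcode}\t{e.family_name}\t{m}\n")


# ---------------------------------------------------------- MEME minimal

_MEME_HEADER = "MEME version 4"


def read_meme(path: str | Path) -> list[PSSM]:
    """Read a MEME minimal motif file (letter-probability matrix blocks)."""
    text = Path(path).read_text().splitlines()
    background = None
    motifs: list[PSSM] = []
    i = 0
    if not text or not text[0].startswith("MEME version"):
        raise FormatError(f"{path}:1: expected 'MEME version' header")
    while i < len(text):
        line = text[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = text[i].split()
            try:
                pairs = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
                background = np.array([pairs[b] for b in "ACGT"])
            except (KeyError, ValueError, IndexError):
                _fail(path, i + 1, "malformed background frequency line")
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(text) and not text[i].strip().startswith("letter-probability"):
                if text[i].strip().startswith("MOTIF"):
                    _fail(path, i, f"motif {name!r} has no probability matrix")
                i += 1
            if i >= len(text):
                _fail(path, len(text), f"motif {name!r} has no probability matrix")
            m = re.search(r"w=\s*(\d+)", text[i])
            if not m:
                _fail(path, i + 1, "letter-probability line lacks w=")
            w = int(m.group(1))
            rows = []
            for k in range(w):
                i += 1
                try:
                    vals = [float(v) for v in text[i].split()]
                except (ValueError, IndexError):
                    _fail(path, i + 1, f"malformed matrix row for motif {name!r}")
                if len(vals) != 4:
                    _fail(path, i + 1, "matrix rows must have 4 columns (ACGT)")
                rows.append(vals)
            try:
                motifs.append(PSSM(name, rows, background=background))
            except ValueError as e:
                _fail(path, i + 1, str(e))
        i += 1
    return motifs


def write_meme(path: str | Path, pssms: Sequence[PSSM]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_MEME_HEADER}\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pssms:
            bg = pssms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                f"A {bg[0]:.17g} C {bg[1]:.17g} G {bg[2]:.17g} T {bg[3]:.17g}\n\n"
            )
        for p in pssms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.raw_matrix:
                # full precision so fixtures round-trip bit-exactly
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")
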