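"""Readers/writers for the formats the pipeline touches, plus the quality gate.

Conventions
-----------
All genomic coordinates are 1-based inclusive (GFF3 convention), in every
table this package reads or writes.  Assemblies may contain ``N`` bases;
they count toward length but are excluded from GC arithmetic downstream.

Draft genomes enter the pipeline with CheckM-style metadata (completeness,
contamination) and optional rRNA intervals; the quality gate keeps a genome
iff completeness > 50 % and contamination < 5 % (strict inequalities).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import translate_cds

GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "cds", "protein"]
ALN_COLUMNS = [
    "read_id", "genome_id", "contig_id", "percent_identity",
    "alignment_length", "subject_start", "subject_end", "bitscore",
]
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class GenomeRecord:
    """One (possibly draft) genome assembly with its quality metadata.

    rrna_intervals are (contig_id, start, end), 1-based inclusive.
    """

    genome_id: str
    contigs: list[tuple[str, str]]
    completeness: float | None = 100.0
    contamination: float | None = 0.0
    rrna_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        if self.total_length == 0:
            raise ValueError(f"{self.genome_id}: empty assembly")
        lengths = dict(self.lengths())
        for cid, start, end in self.rrna_intervals:
            if cid not in lengths:
                raise ValueError(f"{self.genome_id}: rRNA interval on unknown contig {cid!r}")
            if not (1 <= start <= end <= lengths[cid]):
                raise ValueError(f"{self.genome_id}: rRNA interval {start}-{end} outside contig {cid!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def lengths(self) -> list[tuple[str, int]]:
        return [(cid, len(s)) for cid, s in self.contigs]

    def sequence(self, contig_id: str) -> str:
        for cid, s in self.contigs:
            if cid == contig_id:
                return s
        raise KeyError(contig_id)


@dataclass
class GeneTable:
    """Ordered gene coordinates with CDS and protein sequences.

    The backing DataFrame has columns ``gene_id, contig_id, start, end,
    strand, cds, protein`` and is sorted by (contig_id, start).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"GeneTable missing columns {missing}")
        df = self.df.loc[:, GENE_COLUMNS].copy()
        if (df["end"] < df["start"]).any():
            bad = df.loc[df["end"] < df["start"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad!r}: end < start")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.df = df.sort_values(["contig_id", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def proteins(self) -> list[str]:
        return [p for p in self.df["protein"] if isinstance(p, str) and p]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class ReadAlignmentTable:
    """Best-hit-per-(read, genome) alignment table (BLAST outfmt-6 lineage)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ALN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ReadAlignmentTable missing columns {missing}")
        df = self.df.loc[:, ALN_COLUMNS].copy()
        if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
            raise ValueError("percent_identity outside [0, 100]")
        if (df["alignment_length"] < 1).any():
            raise ValueError("alignment_length < 1")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) pairs.

    Ids are the first whitespace-delimited header token; record order is
    preserved.  Sequence data before the first header is a parse error.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}")
            break
    out = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables

def _extract_cds(genome: GenomeRecord, contig_id: str, start: int, end: int, strand: str) -> str:
    seq = genome.sequence(contig_id)[start - 1: end]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_gene_table(
    path: str | Path,
    dialect: str = "gff3",
    genome: GenomeRecord | None = None,
) -> GeneTable:
    """Read gene coordinates from GFF3 (CDS rows) or a 7-column TSV dialect.

    The TSV dialect has columns gene_id, contig_id, start, end, strand, cds,
    protein (header row required); cds/protein may be empty.  When sequences
    are absent and ``genome`` is given, the CDS is extracted from the
    assembly and translated.
    """
    path = Path(path)
    rows: list[dict] = []
    if dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(parts)}")
                contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
                if ftype != "CDS":
                    continue
                gene_id = None
                for kv in attrs.split(";"):
                    k, _, v = kv.partition("=")
                    if k.strip() in ("ID", "locus_tag"):
                        gene_id = v.strip()
                        break
                if gene_id is None:
                    gene_id = f"{contig}_{start}_{end}"
                rows.append(dict(gene_id=gene_id, contig_id=contig, start=int(start),
                                 end=int(end), strand=strand, cds="", protein=""))
    elif dialect == "prodigal_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"cds": str, "protein": str},
                         keep_default_na=False)
        for col in GENE_COLUMNS[:5]:
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        for col in ("cds", "protein"):
            if col not in df.columns:
                df[col] = ""
        rows = df.loc[:, GENE_COLUMNS].to_dict("records")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for row in rows:
        row["start"] = int(row["start"])
        row["end"] = int(row["end"])
        if row["end"] < row["start"]:
            raise ValueError(f"gene {row['gene_id']!r}: end {row['end']} < start {row['start']}")
        if genome is not None:
            known = {cid for cid, _ in genome.contigs}
            if row["contig_id"] not in known:
                raise ValueError(f"gene {row['gene_id']!r}: unknown contig {row['contig_id']!r}")
            if not row["cds"]:
                row["cds"] = _extract_cds(genome, row["contig_id"], row["start"],
                                          row["end"], row["strand"])
            if not row["protein"] and len(row["cds"]) % 3 == 0:
                row["protein"] = translate_cds(row["cds"])
    return GeneTable(pd.DataFrame(rows, columns=GENE_COLUMNS))


# ---------------------------------------------------------------------------
# Alignment tables

def read_alignment_table(path: str | Path, genome_id: str | None = None) -> ReadAlignmentTable:
    """Read a BLAST outfmt-6 table and collapse to one best hit per read.

    The subject id is taken as the contig id; ``genome_id`` labels all rows
    (defaults to the subject id).  Best hit = highest bitscore, ties broken
    by percent identity (desc) then lexicographic subject id.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#",
                         dtype={"qseqid": str, "sseqid": str})
        df["pident"] = pd.to_numeric(df["pident"])
        df["bitscore"] = pd.to_numeric(df["bitscore"])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed BLAST tabular input: {exc}") from exc
    sub_lo = df[["sstart", "send"]].min(axis=1)
    sub_hi = df[["sstart", "send"]].max(axis=1)
    out = pd.DataFrame({
        "read_id": df["qseqid"],
        "genome_id": genome_id if genome_id is not None else df["sseqid"],
        "contig_id": df["sseqid"],
        "percent_identity": df["pident"].astype(float),
        "alignment_length": df["length"].astype(int),
        "subject_start": sub_lo.astype(int),
        "subject_end": sub_hi.astype(int),
        "bitscore": df["bitscore"].astype(float),
    })
    return ReadAlignmentTable(collapse_best_hits(out))


def collapse_best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the single best hit per (read_id, genome_id).

    Deterministic tie-break: bitscore desc, percent_identity desc,
    contig_id asc, subject_start asc.
    """
    ordered = df.sort_values(
        ["read_id", "genome_id", "bitscore", "percent_identity", "contig_id", "subject_start"],
        ascending=[True, True, False, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["read_id", "genome_id"], keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metadata and intervals

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a genome metadata TSV (genome_id, completeness, contamination)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("genome_id", "completeness", "contamination"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_rrna_intervals(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read rRNA intervals from a TSV (genome_id, contig_id, start, end).

    Coordinates are 1-based inclusive (unlike BED's half-open convention).
    """
    df = pd.read_csv(path, sep="\t")
    return [(r.genome_id, r.contig_id, int(r.start), int(r.end)) for r in df.itertuples()]


def quality_filter(
    genomes: Sequence[GenomeRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 5.0,
) -> tuple[list[GenomeRecord], list[tuple[GenomeRecord, str]]]:
    """Partition genomes by the draft-quality gate.

    Kept iff completeness > ``min_completeness`` AND contamination <
    ``max_contamination`` (both strict).  Genomes with missing metadata are
    rejected with reason ``"no_metadata"``.
    """
    kept: list[GenomeRecord] = []
    rejected: list[tuple[GenomeRecord, str]] = []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            rejected.append((g, "no_metadata"))
        elif not g.completeness > min_completeness:
            rejected.append((g, f"completeness<={min_completeness:g}"))
        elif not g.contamination < max_contamination:
            rejected.append((g, f"contamination>={max_contamination:g}"))
        else:
            kept.append(g)
    return kept, rejected
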