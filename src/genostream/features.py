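"""Per-genome streamlining metrics.

GC content, intergenic spacers, completeness-corrected genome size, gene
density, proteome elemental cost (N-ARSC / C-ARSC), amino-acid usage, and
CD-HIT-style paralog counts — the feature vector a streamlining comparison
between genome groups is built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import align_proteins, KmerCandidateIndex
from .io import GeneTable, GenomeRecord
from .tables import AMINO_ACIDS, C_SIDECHAIN, N_SIDECHAIN

PARALOG_THRESHOLDS = (90, 70, 50, 30)


@dataclass
class FeatureVector:
    genome_id: str
    gc_percent: float
    spacer_mean_bp: float | None
    spacer_median_bp: float | None
    assembly_len_bp: int
    est_genome_size_bp: float
    genes_per_mb: float
    n_arsc: float
    c_arsc: float
    aa_freq: dict[str, float] = field(default_factory=dict)
    paralogs: dict[int, int] = field(default_factory=dict)


def gc_content(genome: GenomeRecord) -> float:
    """Percent G+C over unambiguous bases; N counts toward neither side."""
    g = c = at = 0
    for _, seq in genome.contigs:
        g += seq.count("G")
        c += seq.count("C")
        at += seq.count("A") + seq.count("T")
    denom = g + c + at
    if denom == 0:
        raise ValueError(f"{genome.genome_id}: no unambiguous bases")
    return 100.0 * (g + c) / denom


def intergenic_spacers(genes: GeneTable) -> tuple[list[int], dict]:
    """Distances between consecutive genes, per contig.

    Spacer = next.start - prev.end - 1 (1-based inclusive coordinates);
    overlapping or book-ended pairs contribute 0 and overlaps are counted in
    the summary's ``n_overlaps``.  Spacers never span contig boundaries.
    Summary mean/median are None when no gene pair exists.
    """
    spacers: list[int] = []
    n_overlaps = 0
    for _, sub in genes.df.groupby("contig_id", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for i in range(1, len(sub)):
            gap = int(starts[i] - ends[i - 1] - 1)
            if gap < 0:
                n_overlaps += 1
                gap = 0
            spacers.append(gap)
    summary = {
        "mean": float(np.mean(spacers)) if spacers else None,
        "median": float(np.median(spacers)) if spacers else None,
        "n_overlaps": n_overlaps,
        "n_spacers": len(spacers),
    }
    return spacers, summary


def estimated_genome_size(genome: GenomeRecord) -> float:
    """Assembly length scaled to 100 % completeness."""
    if genome.completeness is None:
        raise ValueError(f"{genome.genome_id}: completeness missing")
    if not 0 < genome.completeness <= 100:
        raise ValueError(f"{genome.genome_id}: completeness {genome.completeness} outside (0,100]")
    return genome.total_length * 100.0 / genome.completeness


def gene_density(genes: GeneTable, est_size_bp: float, completeness: float = 100.0) -> float:
    """Genes per megabase of (estimated) genome.

    The completeness-scaled gene count over the completeness-scaled size
    equals the raw count over the raw assembly size — both scalings cancel —
    so any consistent (count, size, completeness) triple gives the same
    density.
    """
    if est_size_bp <= 0:
        raise ValueError("est_size_bp must be > 0")
    if len(genes) == 0:
        return 0.0
    scaled_count = len(genes) * 100.0 / completeness
    scaled_size_mb = est_size_bp * (100.0 / completeness) / 1e6
    return scaled_count / scaled_size_mb


def arsc(proteins: Iterable[str]) -> tuple[float, float]:
    """Residue-weighted proteome mean side-chain N and C atoms per residue.

    Pooled over all residues of all proteins (not averaged per gene);
    non-standard residues are skipped.
    """
    n_total = c_total = residues = 0
    for prot in proteins:
        for aa in prot:
            if aa in N_SIDECHAIN:
                n_total += N_SIDECHAIN[aa]
                c_total += C_SIDECHAIN[aa]
                residues += 1
    if residues == 0:
        raise ValueError("empty proteome")
    return n_total / residues, c_total / residues


def amino_acid_usage(proteins: Iterable[str]) -> dict[str, float]:
    """Fractions of the 20 standard residues across the pooled proteome."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for prot in proteins:
        for aa in prot:
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("empty proteome")
    return {aa: c / total for aa, c in counts.items()}


def greedy_cluster(
    proteins: Mapping[str, str],
    identity_threshold: float,
    coverage: float = 0.5,
    prefilter_k: int = 5,
    _pair_cache: dict | None = None,
) -> list[list[str]]:
    """CD-HIT-style greedy incremental clustering.

    Seeds are taken longest-first; a protein joins the first cluster whose
    seed it matches at global identity >= threshold with the alignment
    covering >= ``coverage`` of the shorter sequence.  Identity = matches /
    alignment columns of a +1/-1/-2 global alignment.  A shared-k-mer
    prefilter skips hopeless comparisons when the threshold is >= 50 %
    (below that the word filter would miss true pairs, as in CD-HIT).
    """
    order = sorted(proteins, key=lambda s: (-len(proteins[s]), s))
    use_filter = identity_threshold >= 50
    index = KmerCandidateIndex(dict(proteins), k=prefilter_k) if use_filter else None
    clusters: list[list[str]] = []
    seed_candidates: dict[str, set[str]] = {}
    for pid in order:
        seq = proteins[pid]
        placed = False
        if use_filter:
            cands = set(index.candidates(seq, max_candidates=len(proteins)))
        for cluster in clusters:
            seed_id = cluster[0]
            if use_filter and seed_id not in cands:
                continue
            key = (seed_id, pid)
            if _pair_cache is not None and key in _pair_cache:
                identity, cov = _pair_cache[key]
            else:
                res = align_proteins(proteins[seed_id], seq, scoring="simple")
                identity, cov = res.identity_percent, res.coverage_shorter
                if _pair_cache is not None:
                    _pair_cache[key] = (identity, cov)
            if identity >= identity_threshold and cov >= coverage:
                cluster.append(pid)
                placed = True
                break
        if not placed:
            clusters.append([pid])
    return clusters


def count_paralogs(
    proteins: Sequence[str] | Mapping[str, str],
    thresholds: Sequence[int] = PARALOG_THRESHOLDS,
) -> dict[int, int]:
    """Number of proteins in multi-member clusters per identity threshold."""
    if not proteins:
        raise ValueError("empty proteome")
    if not isinstance(proteins, Mapping):
        proteins = {f"p{i}": s for i, s in enumerate(proteins)}
    out = {}
    cache: dict = {}  # alignments shared across thresholds
    for t in thresholds:
        clusters = greedy_cluster(proteins, identity_threshold=float(t), _pair_cache=cache)
        out[int(t)] = sum(len(c) for c in clusters if len(c) >= 2)
    return out


def compute_features(
    genome: GenomeRecord,
    genes: GeneTable,
    include_paralogs: bool = True,
    paralog_thresholds: Sequence[int] = PARALOG_THRESHOLDS,
) -> FeatureVector:
    """Full streamlining feature vector for one genome."""
    spacers, summary = intergenic_spacers(genes)
    est_size = estimated_genome_size(genome)
    proteins = genes.proteins
    n_arsc_v, c_arsc_v = arsc(proteins)
    return FeatureVector(
        genome_id=genome.genome_id,
        gc_percent=gc_content(genome),
        spacer_mean_bp=summary["mean"],
        spacer_median_bp=summary["median"],
        assembly_len_bp=genome.total_length,
        est_genome_size_bp=est_size,
        genes_per_mb=gene_density(genes, est_size, genome.completeness or 100.0),
        n_arsc=n_arsc_v,
        c_arsc=c_arsc_v,
        aa_freq=amino_acid_usage(proteins),
        paralogs=count_paralogs(proteins, paralog_thresholds) if include_paralogs else {},
    )


def features_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """One row per genome; documented column order, aa_* and paralog_* expanded."""
    rows = []
    for v in vectors:
        row: dict = {
            "genome_id": v.genome_id,
            "gc_percent": v.gc_percent,
            "spacer_mean_bp": math.nan if v.spacer_mean_bp is None else v.spacer_mean_bp,
            "spacer_median_bp": math.nan if v.spacer_median_bp is None else v.spacer_median_bp,
            "assembly_len_bp": v.assembly_len_bp,
            "est_genome_size_bp": v.est_genome_size_bp,
            "genes_per_mb": v.genes_per_mb,
            "n_arsc": v.n_arsc,
            "c_arsc": v.c_arsc,
        }
        for aa in AMINO_ACIDS:
            row[f"aa_{aa}"] = v.aa_freq.get(aa, math.nan)
        for t, c in sorted(v.paralogs.items(), reverse=True):
            row[f"paralogs_{t}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
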