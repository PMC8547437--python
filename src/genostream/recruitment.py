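"""Metagenomic read-recruitment metrics and genomospecies clustering.

A recruitment run takes a best-hit read alignment table against one genome,
masks the rRNA operon (whose cross-taxon conservation otherwise inflates
recruitment), applies the 98 % identity / 50 nt filter, and reports RPKG
(reads per kilobase of genome per gigabase of metagenome), breadth of
coverage, a presence call (RPKG >= 3 and coverage >= 70 %), and ANIr — the
mean/median identity of recruited reads, a proxy for intrapopulation
sequence diversity — with a 1 %-binned identity histogram for linear
recruitment plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import DnaSeedIndex, align_dna_to_window
from .io import GenomeRecord, ReadAlignmentTable, collapse_best_hits

HIST_BINS = np.arange(70, 101)  # 1 % bins over [70, 100]


@dataclass
class RecruitmentProfile:
    genome_id: str
    sample_id: str
    n_reads_recruited: int
    rpkg: float
    coverage_fraction: float
    present: bool
    anir_mean: float
    anir_median: float
    identity_histogram: np.ndarray = field(default_factory=lambda: np.zeros(30, dtype=int))


@dataclass
class Genomospecies:
    members: list[str]
    min_pairwise_ani: float
    abundance_coherence: float  # min pairwise abundance correlation (NaN if any undefined)
    ani_only_pairs: list[tuple[str, str]] = field(default_factory=list)


def mask_rrna(
    alignments: ReadAlignmentTable,
    genome: GenomeRecord,
) -> tuple[ReadAlignmentTable, int]:
    """Drop hits overlapping any rRNA interval by >= 1 nt.

    Returns the filtered table and the effective genome length (assembly
    length minus total masked length) to use for RPKG and coverage.
    """
    df = alignments.df
    keep = np.ones(len(df), dtype=bool)
    masked_total = 0
    for cid, start, end in genome.rrna_intervals:
        masked_total += end - start + 1
        overlap = (
            (df["contig_id"] == cid)
            & (df["subject_start"] <= end)
            & (df["subject_end"] >= start)
        )
        keep &= ~overlap
    effective_len = genome.total_length - masked_total
    return ReadAlignmentTable(df.loc[keep]), effective_len


def recruit(
    alignments: ReadAlignmentTable,
    min_identity: float = 98.0,
    min_len: int = 50,
) -> ReadAlignmentTable:
    """Keep hits with identity >= min_identity and length >= min_len (inclusive)."""
    df = alignments.df
    keep = (df["percent_identity"] >= min_identity) & (df["alignment_length"] >= min_len)
    return ReadAlignmentTable(df.loc[keep])


def rpkg(n_reads: int, genome_len_bp_effective: float, metagenome_bp: float) -> float:
    """Reads per kilobase of genome per gigabase of metagenome."""
    if genome_len_bp_effective <= 0 or metagenome_bp <= 0:
        raise ValueError("genome and metagenome lengths must be > 0")
    return n_reads / (genome_len_bp_effective / 1e3 * metagenome_bp / 1e9)


def coverage(alignments: ReadAlignmentTable, genome_len_effective: float) -> float:
    """Breadth: fraction of unmasked positions covered by >= 1 kept alignment."""
    if genome_len_effective <= 0:
        raise ValueError("genome length must be > 0")
    df = alignments.df
    if df.empty:
        return 0.0
    covered = 0
    for _, sub in df.groupby("contig_id"):
        ivals = sub[["subject_start", "subject_end"]].sort_values("subject_start").to_numpy()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        covered += cur_e - cur_s + 1
    return min(1.0, covered / genome_len_effective)


def presence_call(rpkg_value: float, coverage_fraction: float,
                  min_rpkg: float = 3.0, min_coverage: float = 0.70) -> bool:
    """Present iff RPKG >= 3 and breadth >= 70 % (both inclusive)."""
    return rpkg_value >= min_rpkg and coverage_fraction >= min_coverage


def anir(
    alignments: ReadAlignmentTable,
    lower_identity: float = 90.0,
    hist_floor: float = 70.0,
) -> tuple[float, float, np.ndarray]:
    """ANIr mean/median over reads with identity >= lower_identity.

    The histogram counts reads per 1 % identity bin over [70, 100] (values
    below the plot floor are dropped; 100 % falls in the top bin), so its
    total equals the reads retained for plotting.  Mean/median are NaN when
    no read clears ``lower_identity``.
    """
    ids = alignments.df["percent_identity"].to_numpy(dtype=float)
    above = ids[ids >= lower_identity]
    hist_vals = ids[ids >= hist_floor]
    hist, _ = np.histogram(np.clip(hist_vals, hist_floor, 100.0 - 1e-9), bins=HIST_BINS)
    if above.size == 0:
        return math.nan, math.nan, hist
    return float(np.mean(above)), float(np.median(above)), hist


def map_reads(
    reads: Sequence[tuple[str, str]],
    genome: GenomeRecord,
    min_report_identity: float = 70.0,
) -> ReadAlignmentTable:
    """Internal read aligner: exact k-mer seed + edlib window refinement.

    Suited to the substitution-only synthetic reads; production recruitment
    uses pre-computed BLAST tabular files via io.read_alignment_table.
    Reads with no seed or identity below ``min_report_identity`` are absent
    from the table.
    """
    rows = []
    indexes = {cid: DnaSeedIndex(seq) for cid, seq in genome.contigs}
    for rid, seq in reads:
        best = None
        for cid, idx in indexes.items():
            hit = align_dna_to_window(seq, idx, pad=20)
            if hit is None:
                continue
            if best is None or hit.score > best[1].score:
                best = (cid, hit)
        if best is None:
            continue
        cid, hit = best
        if hit.identity_percent < min_report_identity:
            continue
        rows.append(dict(
            read_id=rid, genome_id=genome.genome_id, contig_id=cid,
            percent_identity=hit.identity_percent,
            alignment_length=hit.alignment_length,
            subject_start=hit.target_start, subject_end=hit.target_end,
            bitscore=hit.score,
        ))
    if not rows:
        return ReadAlignmentTable(pd.DataFrame(
            columns=["read_id", "genome_id", "contig_id", "percent_identity",
                     "alignment_length", "subject_start", "subject_end", "bitscore"]
        ).astype({"percent_identity": float, "alignment_length": int,
                  "subject_start": int, "subject_end": int, "bitscore": float}))
    return ReadAlignmentTable(collapse_best_hits(pd.DataFrame(rows)))


def recruitment_profile(
    alignments: ReadAlignmentTable,
    genome: GenomeRecord,
    sample_id: str,
    metagenome_bp: float,
    min_identity: float = 98.0,
    min_len: int = 50,
    anir_floor: float = 90.0,
) -> RecruitmentProfile:
    """Full per-(genome, sample) recruitment profile.

    RPKG/coverage/presence use the 98 %/50 nt-filtered table; ANIr and the
    histogram use the broader (unfiltered down to the plot floor) table, as
    in linear recruitment plots.
    """
    masked, effective_len = mask_rrna(alignments, genome)
    strict = recruit(masked, min_identity=min_identity, min_len=min_len)
    r = rpkg(len(strict), effective_len, metagenome_bp)
    cov = coverage(strict, effective_len)
    mean_id, median_id, hist = anir(masked, lower_identity=anir_floor)
    return RecruitmentProfile(
        genome_id=genome.genome_id, sample_id=sample_id,
        n_reads_recruited=len(strict), rpkg=r, coverage_fraction=cov,
        present=presence_call(r, cov),
        anir_mean=mean_id, anir_median=median_id, identity_histogram=hist,
    )


def genomospecies_cluster(
    ani: pd.DataFrame,
    abundance: pd.DataFrame,
    ani_min: float = 85.0,
    r_min: float = 0.8,
) -> list[Genomospecies]:
    """Single-linkage clustering on [ANI >= ani_min AND abundance r >= r_min].

    ``abundance`` is a genomes x samples RPKG matrix sharing the ANI
    matrix's genome ids.  A pair with an undefined correlation (constant
    abundance profile) falls back to the ANI criterion alone and is flagged
    in the resulting cluster's ``ani_only_pairs``.
    """
    ids = sorted(set(ani.index) & set(abundance.index))
    parent = {g: g for g in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    linked_ani_only = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            v = ani.loc[ga, gb]
            if pd.isna(v) or v < ani_min:
                continue
            pa = abundance.loc[ga].to_numpy(dtype=float)
            pb = abundance.loc[gb].to_numpy(dtype=float)
            if np.std(pa) == 0 or np.std(pb) == 0:
                ok, flagged = True, True
            else:
                ok, flagged = float(np.corrcoef(pa, pb)[0, 1]) >= r_min, False
            if ok:
                ra, rb = find(ga), find(gb)
                parent[ra] = rb
                if flagged:
                    linked_ani_only.append((ga, gb))
    clusters: dict[str, list[str]] = {}
    for g in ids:
        clusters.setdefault(find(g), []).append(g)
    out = []
    for members in sorted(clusters.values()):
        if len(members) > 1:
            vals = [ani.loc[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
            min_ani = float(np.nanmin(vals))
            rs = []
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pa = abundance.loc[a].to_numpy(dtype=float)
                    pb = abundance.loc[b].to_numpy(dtype=float)
                    if np.std(pa) > 0 and np.std(pb) > 0:
                        rs.append(float(np.corrcoef(pa, pb)[0, 1]))
            coherence = min(rs) if rs else math.nan
        else:
            min_ani, coherence = 100.0, math.nan
        flagged = [(a, b) for a, b in linked_ani_only if a in members and b in members]
        out.append(Genomospecies(members=members, min_pairwise_ani=min_ani,
                                 abundance_coherence=coherence, ani_only_pairs=flagged))
    return out
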