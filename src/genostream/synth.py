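"""Synthetic genome, ortholog, and metagenomic-read generator.

The generator emulates the two SAR116 subclade profiles — a streamlined
low-GC group (LGC: GC ~30.6 %, spacers ~18 bp, ~1,036 genes/Mb, strong
purifying selection) and a higher-GC group (HGC: GC ~45.1 %, spacers
~51 bp, ~963 genes/Mb) — so every downstream stage of the pipeline can be
exercised, and its parameter recovery verified, without any external data.

Design highlights
-----------------
* GC is controlled by *codon* sampling, not per-base sampling: codon
  probabilities are an exponential-family tilt over the 61 sense codons,
  solved numerically so that expected GC — and, when requested, expected
  side-chain N and C per residue (N-ARSC / C-ARSC) — hit the profile
  targets exactly.  Amino-acid usage therefore co-varies with GC the way
  it does in real proteomes (low GC enriches AT-rich codons such as
  lysine/asparagine).
* Intergenic spacers are truncated-at-zero normals rounded to integers;
  spacer and rRNA base composition use the same expected GC as coding
  sequence, so genome-wide GC is unbiased.
* Ortholog divergence is a proposal–acceptance codon process: candidate
  single-nucleotide changes are proposed with transition:transversion
  weight kappa:1, changes creating stops are rejected, nonsynonymous
  candidates are accepted with probability omega and synonymous ones
  always.  Realized synonymous/nonsynonymous counts are logged as truth.
* Everything is deterministic under a seed (numpy SeedSequence spawning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .io import GeneTable, GenomeRecord
from .tables import (
    CODON_C,
    CODON_GC,
    CODON_INDEX,
    CODON_N,
    NEIGHBOR_DEST,
    NEIGHBOR_IS_SYN,
    NEIGHBOR_IS_TS,
    SENSE_CODONS,
    CODON_AA,
)

RRNA_OPERON_LEN = 4500  # nt; one 16S-23S-5S operon planted per genome
_NT = np.array(list("ACGT"))
_CODON_STR = np.array(SENSE_CODONS)
_AA_STR = np.array(CODON_AA)


class ParameterError(ValueError):
    """A generator profile parameter is outside its valid range."""


# ---------------------------------------------------------------------------
# Codon distribution calibration

@lru_cache(maxsize=64)
def codon_distribution(
    gc_target: float,
    n_arsc_target: float | None = None,
    c_arsc_target: float | None = None,
) -> np.ndarray:
    """Probabilities over the 61 sense codons matching the given moments.

    Codon weights are ``exp(x*gc + a*N_side + b*C_side)``; ``x`` (and,
    when ARSC targets are given, ``a`` and ``b``) are solved so that the
    expected per-base GC equals ``gc_target`` and the expected side-chain
    N/C per residue equal the targets.
    """
    if not 0 < gc_target < 1:
        raise ParameterError(f"gc_target must be in (0,1), got {gc_target}")

    def probs(x: float, a: float = 0.0, b: float = 0.0) -> np.ndarray:
        lw = x * CODON_GC + a * CODON_N + b * CODON_C
        p = np.exp(lw - lw.max())
        return p / p.sum()

    if n_arsc_target is None and c_arsc_target is None:
        x = brentq(lambda x: probs(x) @ CODON_GC / 3 - gc_target, -50, 50, xtol=1e-14)
        return probs(x)
    if n_arsc_target is None or c_arsc_target is None:
        raise ParameterError("give both or neither of n_arsc_target/c_arsc_target")

    def moments(v: np.ndarray) -> np.ndarray:
        p = probs(*v)
        return np.array([
            p @ CODON_GC / 3 - gc_target,
            p @ CODON_N - n_arsc_target,
            p @ CODON_C - c_arsc_target,
        ])

    sol = root(moments, np.zeros(3), tol=1e-13)
    if not sol.success or np.abs(moments(sol.x)).max() > 1e-9:
        raise ParameterError(
            f"codon distribution infeasible for GC={gc_target}, "
            f"N-ARSC={n_arsc_target}, C-ARSC={c_arsc_target}"
        )
    return probs(*sol.x)


# ---------------------------------------------------------------------------
# Profiles

@dataclass(frozen=True)
class SubcladeProfile:
    """Generator parameters for one subclade of genomes."""

    name: str
    gc_target: float
    spacer_mean_bp: float
    spacer_sd_bp: float
    genes_per_mb: float
    omega: float
    kappa: float = 2.0
    gene_len_mean_nt: float | None = None  # derived from genes_per_mb if None
    gene_len_sd_nt: float | None = None    # default: 10% of the mean
    n_arsc_target: float | None = None
    c_arsc_target: float | None = None
    target_sub_per_codon: float = 0.10     # total pairwise divergence within the subclade
    paralog_family_sizes: tuple[int, ...] = ()
    read_identity: float = 0.95
    n_stations: int = 4
    abundance_matrix: tuple[tuple[float, ...], ...] | None = None  # genomes x stations

    def __post_init__(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ParameterError(f"gc_target must be in (0,1), got {self.gc_target}")
        if self.omega < 0:
            raise ParameterError("omega must be >= 0")
        if self.spacer_mean_bp < 0 or self.spacer_sd_bp < 0:
            raise ParameterError("spacer parameters must be non-negative")

    def codon_probs(self) -> np.ndarray:
        return codon_distribution(self.gc_target, self.n_arsc_target, self.c_arsc_target)

    def gene_length_nt(self, n_genes: int) -> float:
        """Mean gene length consistent with the profile's nominal gene density.

        Layout per genome: n genes, n spacers, one rRNA operon — so density
        genes_per_mb implies mean gene length 1e6/density − spacer_mean −
        rrna_len/n.
        """
        if self.gene_len_mean_nt is not None:
            return self.gene_len_mean_nt
        mean = 1e6 / self.genes_per_mb - self.spacer_mean_bp - RRNA_OPERON_LEN / n_genes
        if mean < 90:
            raise ParameterError("profile implies mean gene length < 30 codons")
        return mean


#: Low-GC (streamlined) subclade profile: GC 30.55 %, spacer 18.36±4.71 bp,
#: 1,036 genes/Mb, median dN/dS 0.09, N-ARSC 0.331, C-ARSC 3.08.
LGC_PROFILE = SubcladeProfile(
    name="LGC", gc_target=0.3055, spacer_mean_bp=18.36, spacer_sd_bp=4.71,
    genes_per_mb=1036.0, omega=0.09, n_arsc_target=0.331, c_arsc_target=3.08,
    paralog_family_sizes=(3, 2, 2), read_identity=0.99,
)

#: High-GC subclade profile: GC 45.10 %, spacer 50.94±7.53 bp, 963 genes/Mb,
#: dN/dS 0.065 (the strongly purifying HGC2-A genus), N-ARSC 0.336,
#: C-ARSC 2.91.
HGC_PROFILE = SubcladeProfile(
    name="HGC", gc_target=0.4510, spacer_mean_bp=50.94, spacer_sd_bp=7.53,
    genes_per_mb=963.0, omega=0.065, n_arsc_target=0.336, c_arsc_target=2.91,
    paralog_family_sizes=(3, 2, 2), read_identity=0.99,
)

DEFAULT_PROFILES = (HGC_PROFILE, LGC_PROFILE)


# ---------------------------------------------------------------------------
# Truth records

@dataclass
class SyntheticTruth:
    """Ground truth for every generated entity (test oracle sidecar).

    genomes:  genome_id -> {gc_fraction, spacers, gene_count, gene_lengths,
              rrna_interval, paralog_families}
    pairs:    "a|b|gene" -> {syn, nonsyn, n_codons, omega, target_sub_per_codon}
    reads:    read_id -> {genome_id, contig_id, start, end, identity, n_sub}
    """

    genomes: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    reads: dict = field(default_factory=dict)

    def update(self, other: "SyntheticTruth") -> None:
        self.genomes.update(other.genomes)
        self.pairs.update(other.pairs)
        self.reads.update(other.reads)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Low-level helpers

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_NT[rng.choice(4, size=n, p=_base_probs(gc))]) if n else ""


def _sample_gene(rng: np.random.Generator, probs: np.ndarray, mean_nt: float, sd_nt: float) -> np.ndarray:
    n_codons = max(30, int(np.rint(rng.normal(mean_nt / 3.0, sd_nt / 3.0))))
    return rng.choice(61, size=n_codons, p=probs)


def codons_to_cds(codons: np.ndarray) -> str:
    return "".join(_CODON_STR[codons])


def codons_to_protein(codons: np.ndarray) -> str:
    return "".join(_AA_STR[codons])


def cds_to_codons(cds: str) -> np.ndarray:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    try:
        return np.array([CODON_INDEX[cds[i:i + 3]] for i in range(0, len(cds), 3)])
    except KeyError as exc:
        raise ValueError(f"internal stop or invalid codon {exc.args[0]!r}") from exc


def _evolve_codons(
    codons: np.ndarray,
    omega: float,
    kappa: float,
    n_substitutions: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Apply ``n_substitutions`` accepted changes; return (seq, n_syn, n_nonsyn).

    Proposals: uniform codon site, one of its nine single-nucleotide
    neighbours with probability proportional to kappa (transition) or 1
    (transversion).  Stop-creating proposals are rejected outright;
    nonsynonymous proposals are accepted with probability omega.
    """
    seq = codons.copy()
    weights = np.where(NEIGHBOR_IS_TS, kappa, 1.0)
    weights /= weights.sum(axis=1, keepdims=True)
    n_syn = n_nonsyn = 0
    attempts = 0
    max_attempts = 1000 * (n_substitutions + 10)
    while n_syn + n_nonsyn < n_substitutions:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("substitution process failed to accept enough proposals")
        i = rng.integers(len(seq))
        c = seq[i]
        j = rng.choice(9, p=weights[c])
        dest = NEIGHBOR_DEST[c, j]
        if dest < 0:
            continue
        if NEIGHBOR_IS_SYN[c, j]:
            seq[i] = dest
            n_syn += 1
        elif rng.random() < omega:
            seq[i] = dest
            n_nonsyn += 1
    return seq, n_syn, n_nonsyn


# ---------------------------------------------------------------------------
# Public operations

def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    if not seq or rate <= 0:
        return seq
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    arr = np.array([code[b] for b in seq])
    mask = rng.random(len(arr)) < rate
    if mask.any():
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return "".join(_NT[arr])


def _plant_paralogs(
    genes: list[np.ndarray],
    profile: SubcladeProfile,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[list[int]]]:
    """Overwrite random genes with lightly diverged copies of a family source."""
    families: list[list[int]] = []
    sizes = profile.paralog_family_sizes
    if sizes and sum(sizes) <= len(genes):
        pool = list(rng.permutation(len(genes))[: sum(sizes)])
        for k in sizes:
            members, pool = pool[:k], pool[k:]
            src = genes[members[0]]
            for m in members[1:]:
                n_sub = rng.poisson(0.02 * len(src))
                genes[m], _, _ = _evolve_codons(src, 1.0, profile.kappa, n_sub, rng)
            families.append(sorted(int(m) for m in members))
    return genes, families


def generate_genome(
    profile: SubcladeProfile,
    n_genes: int,
    seed: int,
    genome_id: str | None = None,
    genes: list[np.ndarray] | None = None,
    noncoding: tuple[list[str], str] | None = None,
) -> tuple[GenomeRecord, GeneTable, SyntheticTruth]:
    """Generate one single-contig genome under a subclade profile.

    Genes (codon draws from the calibrated distribution unless pre-evolved
    ``genes`` are supplied) are laid head-to-tail separated by integer
    truncated-normal spacers; one rRNA operon is appended at the contig end
    and recorded in the genome's rrna_intervals.  Paralog families listed in
    the profile are planted as high-identity gene copies.  ``noncoding``
    optionally supplies pre-built (spacer sequences, rRNA sequence) — used
    by build_subclade_dataset so genomes of one subclade share ancestral
    intergenic DNA instead of drawing it independently.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gid = genome_id or f"{profile.name}_g{seed}"
    probs = profile.codon_probs()
    mean_nt = profile.gene_length_nt(n_genes)
    sd_nt = profile.gene_len_sd_nt if profile.gene_len_sd_nt is not None else 0.1 * mean_nt

    if genes is None:
        genes = [_sample_gene(rng, probs, mean_nt, sd_nt) for _ in range(n_genes)]
        genes, families = _plant_paralogs(genes, profile, rng)
    else:
        # pre-evolved genes: paralog families (if any) were planted upstream,
        # in the shared ancestor, so all genomes agree on family loci
        genes = [g.copy() for g in genes]
        families = []
        if len(genes) != n_genes:
            raise ParameterError("len(genes) != n_genes")

    if noncoding is not None:
        spacer_seqs, rrna_seq = noncoding
        if len(spacer_seqs) != n_genes:
            raise ParameterError("need one noncoding spacer per gene")
    else:
        spacer_seqs = [
            _random_dna(rng, max(0, int(np.rint(rng.normal(profile.spacer_mean_bp,
                                                           profile.spacer_sd_bp)))),
                        profile.gc_target)
            for _ in range(n_genes)
        ]
        rrna_seq = _random_dna(rng, RRNA_OPERON_LEN, profile.gc_target)

    contig_id = f"{gid}_c1"
    parts: list[str] = []
    rows = []
    spacers: list[int] = []
    pos = 1
    for i, g in enumerate(genes):
        cds = codons_to_cds(g)
        start, end = pos, pos + len(cds) - 1
        rows.append(dict(gene_id=f"{gid}_{i + 1:05d}", contig_id=contig_id,
                         start=start, end=end, strand="+",
                         cds=cds, protein=codons_to_protein(g)))
        parts.append(cds)
        spacers.append(len(spacer_seqs[i]))
        parts.append(spacer_seqs[i])
        pos = end + len(spacer_seqs[i]) + 1
    rrna_start = pos
    parts.append(rrna_seq)
    rrna_end = rrna_start + len(rrna_seq) - 1

    sequence = "".join(parts)
    genome = GenomeRecord(
        genome_id=gid,
        contigs=[(contig_id, sequence)],
        completeness=100.0,
        contamination=0.0,
        rrna_intervals=[(contig_id, rrna_start, rrna_end)],
    )
    table = GeneTable(pd.DataFrame(rows))
    gc = (sequence.count("G") + sequence.count("C")) / len(sequence)
    truth = SyntheticTruth(genomes={gid: dict(
        gc_fraction=gc,
        spacers=[int(s) for s in spacers],
        gene_count=n_genes,
        gene_lengths=[int(len(g) * 3) for g in genes],
        rrna_interval=[contig_id, int(rrna_start), int(rrna_end)],
        paralog_families=families,
        profile=profile.name,
    )})
    return genome, table, truth


def evolve_ortholog_pair(
    cds: str,
    omega: float,
    kappa: float,
    target_sub_per_codon: float,
    seed: int,
) -> tuple[str, str, SyntheticTruth]:
    """Evolve two lineages independently from a common ancestral CDS.

    ``target_sub_per_codon`` is the expected total number of accepted
    substitutions per codon across the *pair* (half per lineage, Poisson
    distributed).  Realized synonymous/nonsynonymous counts are returned in
    the truth record.
    """
    codons = cds_to_codons(cds)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_lineage = target_sub_per_codon / 2.0 * len(codons)
    out = []
    counts = []
    for _ in range(2):
        n_sub = int(rng.poisson(per_lineage))
        evolved, n_syn, n_nonsyn = _evolve_codons(codons, omega, kappa, n_sub, rng)
        out.append(evolved)
        counts.append((n_syn, n_nonsyn))
    truth = SyntheticTruth(pairs={"a|b": dict(
        syn=counts[0][0] + counts[1][0],
        nonsyn=counts[0][1] + counts[1][1],
        n_codons=len(codons),
        omega=omega,
        kappa=kappa,
        target_sub_per_codon=target_sub_per_codon,
    )})
    return codons_to_cds(out[0]), codons_to_cds(out[1]), truth


def simulate_reads(
    genome: GenomeRecord,
    n_reads: int,
    read_len: int = 100,
    identity: float = 0.95,
    seed: int = 0,
    id_prefix: str | None = None,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Simulate substitution-only reads at uniform positions.

    Each base is substituted independently with probability ``1 - identity``
    to one of the three other bases; truth records the origin interval
    (1-based inclusive) and realized identity per read.
    """
    if not 0 <= identity <= 1:
        raise ParameterError(f"identity must be in [0,1], got {identity}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    prefix = id_prefix or f"{genome.genome_id}_read"
    contigs = [(cid, s) for cid, s in genome.contigs if len(s) >= read_len]
    if n_reads and not contigs:
        raise ParameterError("read_len exceeds every contig length")
    lengths = np.array([len(s) for _, s in contigs], dtype=float)
    reads: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(n_reads):
        ci = int(rng.choice(len(contigs), p=lengths / lengths.sum()))
        cid, seq = contigs[ci]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        frag = np.array([code[b] for b in seq[start:start + read_len]])
        mask = rng.random(read_len) < (1 - identity)
        if mask.any():
            frag[mask] = (frag[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        rid = f"{prefix}_{i + 1:06d}"
        reads.append((rid, "".join(_NT[frag])))
        truth.reads[rid] = dict(
            genome_id=genome.genome_id, contig_id=cid,
            start=start + 1, end=start + read_len,
            identity=1 - int(mask.sum()) / read_len, n_sub=int(mask.sum()),
        )
    return reads, truth


def fragment_genome(
    genome: GenomeRecord,
    genes: GeneTable,
    n_contigs: int,
    seed: int = 0,
) -> tuple[GenomeRecord, GeneTable]:
    """Split a single-contig genome into contigs at intergenic midpoints.

    Emulates draft-assembly fragmentation (contig breaks never fall inside
    a gene) so spacer handling at contig edges can be exercised.  Gene and
    rRNA coordinates are remapped onto the new contigs.
    """
    if len(genome.contigs) != 1:
        raise ParameterError("fragment_genome expects a single-contig genome")
    if n_contigs < 2 or n_contigs > len(genes):
        raise ParameterError("n_contigs must be in [2, n_genes]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    old_cid, seq = genome.contigs[0]
    df = genes.df
    # candidate breakpoints: midpoint of each between-gene spacer
    mids = ((df["end"].to_numpy()[:-1] + df["start"].to_numpy()[1:]) // 2) + 1
    cuts = sorted(rng.choice(len(mids), size=n_contigs - 1, replace=False))
    breakpoints = [int(mids[c]) for c in cuts]  # first position of next contig
    bounds = [1] + breakpoints + [len(seq) + 1]

    contigs = []
    rows = []
    rrna = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        cid = f"{genome.genome_id}_c{k + 1}"
        contigs.append((cid, seq[lo - 1: hi - 1]))
        sub = df[(df["start"] >= lo) & (df["end"] < hi)]
        for r in sub.itertuples():
            rows.append(dict(gene_id=r.gene_id, contig_id=cid,
                             start=r.start - lo + 1, end=r.end - lo + 1,
                             strand=r.strand, cds=r.cds, protein=r.protein))
        for icid, istart, iend in genome.rrna_intervals:
            if lo <= istart and iend < hi:
                rrna.append((cid, istart - lo + 1, iend - lo + 1))
    new_genome = GenomeRecord(
        genome_id=genome.genome_id, contigs=contigs,
        completeness=genome.completeness, contamination=genome.contamination,
        rrna_intervals=rrna,
    )
    return new_genome, GeneTable(pd.DataFrame(rows))


@dataclass
class SubcladeBundle:
    """Everything build_subclade_dataset produced, plus its truth sidecar."""

    genomes: dict[str, GenomeRecord]
    gene_tables: dict[str, GeneTable]
    groups: dict[str, list[str]]                       # profile name -> genome ids
    profiles: dict[str, SubcladeProfile]
    reads_per_station: dict[str, list[tuple[str, str]]]  # station -> (read_id, seq)
    station_sizes_bp: dict[str, int]
    truth: SyntheticTruth


def build_subclade_dataset(
    profiles: tuple[SubcladeProfile, ...] = DEFAULT_PROFILES,
    n_genomes: int = 3,
    seed: int = 0,
    n_genes: int = 120,
    reads_per_unit_abundance: int = 800,
    read_len: int = 100,
) -> SubcladeBundle:
    """Generate per-profile genome sets, within-profile orthologs, and reads.

    Genomes within a profile descend from a common ancestral gene set, each
    lineage evolved at the profile's omega to half the profile's
    ``target_sub_per_codon`` — so every within-profile genome pair is an
    ortholog set at the profile's nominal divergence.  Station read sets are
    scaled by the profile's abundance matrix (default: uniform abundance 1).
    """
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate profile names: {names}")
    if not profiles:
        raise ParameterError("need at least one profile")

    ss = np.random.SeedSequence(seed)
    truth = SyntheticTruth()
    genomes: dict[str, GenomeRecord] = {}
    gene_tables: dict[str, GeneTable] = {}
    groups: dict[str, list[str]] = {}
    n_stations = max(p.n_stations for p in profiles)
    reads_per_station: dict[str, list[tuple[str, str]]] = {
        f"station_{s + 1}": [] for s in range(n_stations)
    }

    for p_idx, profile in enumerate(profiles):
        p_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(p_ss)
        probs = profile.codon_probs()
        mean_nt = profile.gene_length_nt(n_genes)
        sd_nt = profile.gene_len_sd_nt if profile.gene_len_sd_nt is not None else 0.1 * mean_nt
        ancestor = [_sample_gene(rng, probs, mean_nt, sd_nt) for _ in range(n_genes)]
        ancestor, anc_families = _plant_paralogs(ancestor, profile, rng)
        anc_spacers = [
            _random_dna(rng, max(0, int(np.rint(rng.normal(profile.spacer_mean_bp,
                                                           profile.spacer_sd_bp)))),
                        profile.gc_target)
            for _ in range(n_genes)
        ]
        anc_rrna = _random_dna(rng, RRNA_OPERON_LEN, profile.gc_target)
        per_lineage = profile.target_sub_per_codon / 2.0
        noncoding_rate = per_lineage / 3.0  # per-nt, matches the coding substitution rate

        if profile.abundance_matrix is not None:
            abundance = np.asarray(profile.abundance_matrix, dtype=float)
            if abundance.shape != (n_genomes, profile.n_stations):
                raise ParameterError(
                    f"{profile.name}: abundance matrix must be {n_genomes}x{profile.n_stations}"
                )
        else:
            # default biogeography: one station gradient per subclade, shared
            # by its genomes (genomospecies-like coherent abundance profiles)
            base = [2.0, 1.0, 0.5, 0.0]
            gradient = [base[(s + p_idx) % len(base)] for s in range(profile.n_stations)]
            abundance = np.tile(gradient, (n_genomes, 1))

        groups[profile.name] = []
        evolved_sets: list[list[np.ndarray]] = []
        for g_idx in range(n_genomes):
            gid = f"{profile.name}_{g_idx + 1:02d}"
            evolved = []
            for gene_i, anc in enumerate(ancestor):
                n_sub = int(rng.poisson(per_lineage * len(anc)))
                new, n_syn, n_nonsyn = _evolve_codons(anc, profile.omega, profile.kappa, n_sub, rng)
                evolved.append(new)
                truth.pairs[f"ancestor|{gid}|{gene_i}"] = dict(
                    syn=n_syn, nonsyn=n_nonsyn, n_codons=len(anc),
                    omega=profile.omega, kappa=profile.kappa,
                )
            evolved_sets.append(evolved)
            noncoding = (
                [_mutate_dna(s, noncoding_rate, rng) for s in anc_spacers],
                _mutate_dna(anc_rrna, noncoding_rate, rng),
            )
            genome_seed = int(rng.integers(2 ** 31))
            genome, table, g_truth = generate_genome(
                profile, n_genes, genome_seed, genome_id=gid, genes=evolved,
                noncoding=noncoding,
            )
            genomes[gid] = genome
            gene_tables[gid] = table
            g_truth.genomes[gid]["paralog_families"] = [list(f) for f in anc_families]
            truth.update(g_truth)
            groups[profile.name].append(gid)

            for s_idx in range(profile.n_stations):
                n_reads = int(round(abundance[g_idx, s_idx] * reads_per_unit_abundance))
                if n_reads == 0:
                    continue
                read_seed = int(rng.integers(2 ** 31))
                reads, r_truth = simulate_reads(
                    genome, n_reads, read_len=read_len,
                    identity=profile.read_identity, seed=read_seed,
                    id_prefix=f"station_{s_idx + 1}_{gid}",
                )
                reads_per_station[f"station_{s_idx + 1}"].extend(reads)
                truth.update(r_truth)

    station_sizes = {
        st: sum(len(seq) for _, seq in reads) for st, reads in reads_per_station.items()
    }
    return SubcladeBundle(
        genomes=genomes, gene_tables=gene_tables, groups=groups,
        profiles={p.name: p for p in profiles},
        reads_per_station=reads_per_station,
        station_sizes_bp=station_sizes, truth=truth,
    )
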