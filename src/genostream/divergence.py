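"""Pairwise genome relatedness (ANIb) and selection pressure (dN/dS).

The dN/dS pipeline mirrors the classical comparative protocol: reciprocal
best hits between proteomes (>75 % amino-acid identity), back-translation of
the protein alignment to a codon alignment, then an approximate-counting
estimator of dN and dS in the style of Yang & Nielsen (2000): synonymous and
nonsynonymous site counts weighted by an estimated transition/transversion
ratio kappa, equal-weight multiple-pathway averaging for codons differing at
more than one position, and Jukes-Cantor-style multiple-hit correction of
the two proportions.  Codon frequencies are treated as equal; an independent
NG86 estimator (kappa = 1, exhaustive pathway enumeration, separate code
path) ships alongside as a cross-check oracle.

ANI follows the ANIb fragment convention: the query genome is cut into
1,020-nt fragments, each is located and aligned against the subject, hits
with >=30 % identity over >=70 % of the fragment are kept, and ANI is the
mean identity of kept fragments (reciprocal mean reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import DnaSeedIndex, KmerCandidateIndex, align_dna_to_window, align_proteins
from .io import GeneTable, GenomeRecord
from .tables import (
    NEIGHBOR_DEST,
    NEIGHBOR_IS_SYN,
    NEIGHBOR_IS_TS,
    CODON_AA,
    CODON_INDEX,
    STOP_CODONS,
    TRANSITION,
    translate_cds,
)

ANI_FRAGMENT_LEN = 1020
DEFAULT_OMEGA_CAP = 10.0


# ---------------------------------------------------------------------------
# ANIb

@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: float                # percent; NaN when no fragment passes
    n_fragments_used: int
    coverage_fraction: float  # kept fragments / total fragments


def _one_way_ani(
    query: GenomeRecord,
    index: DnaSeedIndex,
    frag_len: int,
    min_identity: float,
    min_cov: float,
) -> tuple[float, int, int]:
    identities = []
    total = 0
    for _, seq in query.contigs:
        for i in range(0, len(seq), frag_len):
            frag = seq[i:i + frag_len]
            if len(frag) < 100:
                continue
            total += 1
            hit = align_dna_to_window(frag, index, pad=50)
            if hit is None:
                continue
            if hit.identity_percent >= min_identity and hit.alignment_length >= min_cov * len(frag):
                identities.append(hit.identity_percent)
    mean = float(np.mean(identities)) if identities else math.nan
    return mean, len(identities), total


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    frag_len: int = ANI_FRAGMENT_LEN,
    min_identity: float = 30.0,
    min_cov: float = 0.7,
) -> AniResult:
    """Reciprocal fragment-based ANI between two genomes.

    ANI is undefined (NaN) when no fragment passes the 30 %/70 % keep rule
    in either direction — distinct from an ANI of 0.
    """
    idx_b = DnaSeedIndex("".join(s for _, s in b.contigs))
    idx_a = DnaSeedIndex("".join(s for _, s in a.contigs))
    ab, n_ab, tot_ab = _one_way_ani(a, idx_b, frag_len, min_identity, min_cov)
    ba, n_ba, tot_ba = _one_way_ani(b, idx_a, frag_len, min_identity, min_cov)
    vals = [v for v in (ab, ba) if not math.isnan(v)]
    return AniResult(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        ani=float(np.mean(vals)) if vals else math.nan,
        n_fragments_used=n_ab + n_ba,
        coverage_fraction=(n_ab + n_ba) / (tot_ab + tot_ba) if tot_ab + tot_ba else 0.0,
    )


def ani_matrix(genomes: Mapping[str, GenomeRecord], **kwargs) -> pd.DataFrame:
    """Square symmetric ANI matrix (percent; diagonal 100)."""
    ids = sorted(genomes)
    mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    for gid in ids:
        mat.loc[gid, gid] = 100.0
    for ga, gb in itertools.combinations(ids, 2):
        res = fragment_ani(genomes[ga], genomes[gb], **kwargs)
        mat.loc[ga, gb] = res.ani
        mat.loc[gb, ga] = res.ani
    return mat


def species_prefilter(ani: pd.DataFrame, threshold: float = 95.0) -> list[tuple[str, str]]:
    """Genome pairs within the species definition: ANI strictly > threshold."""
    pairs = []
    ids = list(ani.index)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            v = ani.loc[ga, gb]
            if not pd.isna(v) and v > threshold:
                pairs.append((ga, gb))
    return pairs


# ---------------------------------------------------------------------------
# Reciprocal best hits

def _best_hit(
    seq: str,
    index: KmerCandidateIndex,
    max_candidates: int = 5,
) -> tuple[str, float, float] | None:
    """(subject_id, score, identity_percent) of the best BLOSUM62 match."""
    best = None
    for sid in index.candidates(seq, max_candidates=max_candidates):
        res = align_proteins(seq, index.sequences[sid], scoring="blosum62")
        key = (res.score, res.identity_percent, sid)
        if best is None or key > best[0]:
            best = (key, sid, res.score, res.identity_percent)
    if best is None:
        return None
    return best[1], best[2], best[3]


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = 75.0,
) -> list[tuple[str, str, float]]:
    """One-to-one ortholog pairs (gene_a, gene_b, identity_percent).

    A pair is kept iff each protein is the other's best-scoring global
    BLOSUM62 match (ties broken by identity then id) and the alignment
    identity is strictly greater than ``min_identity``.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    idx_a = KmerCandidateIndex(dict(proteome_a))
    idx_b = KmerCandidateIndex(dict(proteome_b))
    best_ab = {pid: _best_hit(seq, idx_b) for pid, seq in proteome_a.items()}
    best_ba = {pid: _best_hit(seq, idx_a) for pid, seq in proteome_b.items()}
    pairs = []
    for pid_a, hit in best_ab.items():
        if hit is None:
            continue
        pid_b, _score, identity = hit
        back = best_ba.get(pid_b)
        if back is not None and back[0] == pid_a and identity > min_identity:
            pairs.append((pid_a, pid_b, identity))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Codon alignment (pal2nal-style back-translation)

def codon_align(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str],
) -> tuple[str, str]:
    """Back-translate a gapped protein alignment onto the two CDS.

    Terminal stop codons are dropped; each residue is replaced by its codon
    and each protein gap by '---'.  A translation mismatch raises, naming
    the first discordant residue.
    """
    out = []
    for cds, gapped, label in ((cds_a, protein_alignment[0], "a"), (cds_b, protein_alignment[1], "b")):
        if len(cds) % 3:
            raise ValueError(f"cds_{label} length not divisible by 3")
        if cds[-3:].upper() in STOP_CODONS:
            cds = cds[:-3]
        prot = translate_cds(cds)
        ungapped = gapped.replace("-", "")
        if len(prot) != len(ungapped):
            raise ValueError(f"cds_{label}: protein length {len(prot)} != alignment row {len(ungapped)}")
        for i, (x, y) in enumerate(zip(prot, ungapped)):
            if x != y:
                raise ValueError(f"cds_{label}: residue {i + 1} translates to {x!r}, alignment has {y!r}")
        row = []
        k = 0
        for ch in gapped:
            if ch == "-":
                row.append("---")
            else:
                row.append(cds[3 * k: 3 * k + 3])
                k += 1
        out.append("".join(row))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# YN-style dN/dS

@dataclass
class DnDsResult:
    dn: float
    ds: float
    omega: float        # NaN when ds == 0 (undefined, not infinite)
    kappa: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int


def _comparable_columns(aligned_a: str, aligned_b: str) -> list[tuple[str, str]]:
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if len(aligned_a) % 3:
        raise ValueError("codon alignment length not divisible by 3")
    cols = []
    for i in range(0, len(aligned_a), 3):
        ca, cb = aligned_a[i:i + 3].upper(), aligned_b[i:i + 3].upper()
        if ca in CODON_INDEX and cb in CODON_INDEX:
            cols.append((ca, cb))
    return cols


@lru_cache(maxsize=None)
def _position_degeneracy(codon: str, pos: int) -> str:
    """'fourfold', 'nondegenerate', or 'mixed' at one codon position."""
    aa = CODON_AA[CODON_INDEX[codon]]
    syn = nonsyn = 0
    for nt in "ACGT":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if alt in STOP_CODONS:
            nonsyn += 1
            continue
        if CODON_AA[CODON_INDEX[alt]] == aa:
            syn += 1
        else:
            nonsyn += 1
    if syn == 3:
        return "fourfold"
    if syn == 0:
        return "nondegenerate"
    return "mixed"


def _k80_kappa(n_sites: int, n_ts: int, n_tv: int) -> float | None:
    if n_sites == 0:
        return None
    p, q = n_ts / n_sites, n_tv / n_sites
    a1, a2 = 1 - 2 * p - q, 1 - 2 * q
    if a1 <= 0 or a2 <= 0:
        return None
    ts_dist = -0.5 * math.log(a1) + 0.25 * math.log(a2)
    tv_dist = -0.25 * math.log(a2)
    if tv_dist <= 0:
        return None
    k = ts_dist / tv_dist
    return min(max(k, 0.1), 50.0)


def estimate_kappa(cols: Sequence[tuple[str, str]], default: float = 2.0) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate positions (K80 formulas, classes combined by site count)."""
    stats = {"fourfold": [0, 0, 0], "nondegenerate": [0, 0, 0]}  # sites, ts, tv
    for ca, cb in cols:
        for pos in range(3):
            da, db = _position_degeneracy(ca, pos), _position_degeneracy(cb, pos)
            if da != db or da == "mixed":
                continue
            s = stats[da]
            s[0] += 1
            if ca[pos] != cb[pos]:
                if TRANSITION[ca[pos]] == cb[pos]:
                    s[1] += 1
                else:
                    s[2] += 1
    estimates = []
    for cls in ("fourfold", "nondegenerate"):
        n, ts, tv = stats[cls]
        k = _k80_kappa(n, ts, tv)
        if k is not None:
            estimates.append((n, k))
    if not estimates:
        return default
    total = sum(n for n, _ in estimates)
    return sum(n * k for n, k in estimates) / total


@lru_cache(maxsize=100_000)
def _codon_site_split(codon_idx: int, kappa: float) -> tuple[float, float]:
    """(syn_sites, nonsyn_sites) of one codon, kappa-weighted.

    Stop-creating changes are excluded from numerator and denominator, so
    each position contributes one site and every codon contributes three.
    """
    syn_sites = 0.0
    for pos in range(3):
        sw = tw = 0.0
        for j in range(3 * pos, 3 * pos + 3):
            if NEIGHBOR_DEST[codon_idx, j] < 0:
                continue
            w = kappa if NEIGHBOR_IS_TS[codon_idx, j] else 1.0
            tw += w
            if NEIGHBOR_IS_SYN[codon_idx, j]:
                sw += w
        if tw > 0:
            syn_sites += sw / tw
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) step counts over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all are used.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid = []
    blocked = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        steps = []
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                hit_stop = True
            steps.append((cur, nxt))
            cur = nxt
        counts = [0.0, 0.0]
        for x, y in steps:
            if x in STOP_CODONS or y in STOP_CODONS:
                counts[1] += 1  # count stop-passing steps as nonsynonymous
            elif CODON_AA[CODON_INDEX[x]] == CODON_AA[CODON_INDEX[y]]:
                counts[0] += 1
            else:
                counts[1] += 1
        (blocked if hit_stop else valid).append(counts)
    use = valid if valid else blocked
    syn = sum(c[0] for c in use) / len(use)
    nonsyn = sum(c[1] for c in use) / len(use)
    return syn, nonsyn


def _jc_correct(p: float) -> float:
    if p <= 0:
        return 0.0
    x = 1 - 4.0 * p / 3.0
    if x <= 0:
        return math.inf
    return -0.75 * math.log(x)


def yn_dnds(codon_alignment: tuple[str, str], kappa: float | None = None) -> DnDsResult:
    """dN, dS, and omega from a (possibly gapped) codon alignment.

    Gapped and stop-containing columns are skipped.  omega is NaN (flagged
    undefined) when dS = 0.  ``kappa`` overrides the internal estimate.
    """
    cols = _comparable_columns(*codon_alignment)
    if not cols:
        raise ValueError("no comparable (ungapped, stop-free) codon columns")
    k = estimate_kappa(cols) if kappa is None else kappa
    syn_sites = nonsyn_sites = 0.0
    syn_d = nonsyn_d = 0.0
    for ca, cb in cols:
        sa, na = _codon_site_split(CODON_INDEX[ca], k)
        sb, nb = _codon_site_split(CODON_INDEX[cb], k)
        syn_sites += (sa + sb) / 2
        nonsyn_sites += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb)
        syn_d += sd
        nonsyn_d += nd
    ps = syn_d / syn_sites if syn_sites else 0.0
    pn = nonsyn_d / nonsyn_sites if nonsyn_sites else 0.0
    ds, dn = _jc_correct(ps), _jc_correct(pn)
    omega = dn / ds if ds > 0 and math.isfinite(ds) else math.nan
    return DnDsResult(dn=dn, ds=ds, omega=omega, kappa=k,
                      syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
                      syn_diffs=syn_d, nonsyn_diffs=nonsyn_d, n_codons=len(cols))


# ---------------------------------------------------------------------------
# Independent NG86 oracle (deliberately separate code path)

_GENETIC_CODE: dict[str, str] = {}
for _c in CODON_INDEX:
    _GENETIC_CODE[_c] = CODON_AA[CODON_INDEX[_c]]


def _ng86_codon_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    nonsyn = 0.0
    for pos in range(3):
        s = n = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if _GENETIC_CODE[alt] == _GENETIC_CODE[codon]:
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
            nonsyn += n / (s + n)
    return syn, nonsyn


def ng86_dnds(codon_alignment: tuple[str, str]) -> DnDsResult:
    """Nei-Gojobori (1986) estimator: unweighted sites, exhaustive pathway
    enumeration, Jukes-Cantor correction.  Test oracle for yn_dnds."""
    aligned_a, aligned_b = codon_alignment
    syn_sites = nonsyn_sites = syn_d = nonsyn_d = 0.0
    n_cols = 0
    for i in range(0, len(aligned_a), 3):
        ca, cb = aligned_a[i:i + 3].upper(), aligned_b[i:i + 3].upper()
        if ca not in _GENETIC_CODE or cb not in _GENETIC_CODE:
            continue
        n_cols += 1
        for codon in (ca, cb):
            s, n = _ng86_codon_sites(codon)
            syn_sites += s / 2
            nonsyn_sites += n / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        pathways = []
        for order in itertools.permutations(diff):
            cur, s_cnt, n_cnt, ok = ca, 0.0, 0.0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                if _GENETIC_CODE[nxt] == _GENETIC_CODE[cur]:
                    s_cnt += 1
                else:
                    n_cnt += 1
                cur = nxt
            if ok:
                pathways.append((s_cnt, n_cnt))
        if not pathways:  # all pathways blocked by stops: count as nonsynonymous
            pathways = [(0.0, float(len(diff)))]
        syn_d += sum(p[0] for p in pathways) / len(pathways)
        nonsyn_d += sum(p[1] for p in pathways) / len(pathways)
    if n_cols == 0:
        raise ValueError("no comparable codon columns")
    ps = syn_d / syn_sites if syn_sites else 0.0
    pn = nonsyn_d / nonsyn_sites if nonsyn_sites else 0.0
    ds = _jc_correct(ps)
    dn = _jc_correct(pn)
    omega = dn / ds if ds > 0 and math.isfinite(ds) else math.nan
    return DnDsResult(dn=dn, ds=ds, omega=omega, kappa=1.0,
                      syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
                      syn_diffs=syn_d, nonsyn_diffs=nonsyn_d, n_codons=n_cols)


# ---------------------------------------------------------------------------
# Per-pair and per-group aggregation

@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    protein_identity: float
    dn: float
    ds: float
    omega: float


def pair_dnds(
    table_a: GeneTable,
    table_b: GeneTable,
    min_identity: float = 75.0,
    estimator: str = "yn",
) -> list[OrthologPair]:
    """RBH orthologs between two gene tables, each scored with yn_dnds."""
    prot_a = {r.gene_id: r.protein for r in table_a.df.itertuples() if r.protein}
    prot_b = {r.gene_id: r.protein for r in table_b.df.itertuples() if r.protein}
    cds_a = {r.gene_id: r.cds for r in table_a.df.itertuples()}
    cds_b = {r.gene_id: r.cds for r in table_b.df.itertuples()}
    fn = yn_dnds if estimator == "yn" else ng86_dnds
    out = []
    for ga, gb, identity in reciprocal_best_hits(prot_a, prot_b, min_identity=min_identity):
        res = align_proteins(prot_a[ga], prot_b[gb], scoring="blosum62")
        aln = codon_align(cds_a[ga], cds_b[gb], (res.aligned_a, res.aligned_b))
        d = fn(aln)
        out.append(OrthologPair(gene_a=ga, gene_b=gb, protein_identity=identity,
                                dn=d.dn, ds=d.ds, omega=d.omega))
    return out


def group_dnds(
    groups: Mapping[str, Sequence[str]],
    pair_omegas: Mapping[tuple[str, str], Sequence[float]],
    omega_cap: float = DEFAULT_OMEGA_CAP,
) -> pd.DataFrame:
    """Per-group dN/dS summary.

    Per genome pair, ortholog omegas are pooled after removing undefined
    values and values >= ``omega_cap`` (methodological-artifact filter,
    applied per ortholog); the per-pair median is then summarized per group
    (median / mean / SD over pairs).  Groups with no qualifying pair get a
    NaN row.
    """
    member_of = {g: name for name, members in groups.items() for g in members}
    pair_medians: dict[str, list[float]] = {name: [] for name in groups}
    for (ga, gb), omegas in sorted(pair_omegas.items()):
        if member_of.get(ga) != member_of.get(gb) or ga not in member_of:
            continue
        vals = [w for w in omegas if not math.isnan(w) and w < omega_cap]
        if vals:
            pair_medians[member_of[ga]].append(float(np.median(vals)))
    rows = []
    for name in sorted(groups):
        meds = pair_medians[name]
        rows.append({
            "group": name,
            "n_pairs": len(meds),
            "median_omega": float(np.median(meds)) if meds else math.nan,
            "mean_omega": float(np.mean(meds)) if meds else math.nan,
            "sd_omega": float(np.std(meds, ddof=1)) if len(meds) > 1 else math.nan,
        })
    return pd.DataFrame(rows).set_index("group")
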