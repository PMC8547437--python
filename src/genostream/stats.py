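"""Group comparison statistics, PCA, and the end-to-end two-subclade report.

Quantitative features are summarized as mean ± SD per group and compared
with a two-sided unpaired t test (Welch by default — the safe choice for
subclades of unequal size and variance — with a pooled-variance Student
toggle).  No multiple-testing correction is applied, and the report says
so.  The PCA standardizes each variable and eigendecomposes the
correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .divergence import ani_matrix, group_dnds, pair_dnds, species_prefilter
from .features import compute_features, features_table, greedy_cluster
from .recruitment import genomospecies_cluster, map_reads, recruitment_profile
from .synth import SubcladeBundle

PCA_VARIABLES = ("dnds", "gc_percent", "spacer_mean_bp", "est_genome_size_bp",
                 "n_arsc", "c_arsc", "paralogs")


@dataclass
class GroupComparison:
    feature: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool  # at alpha = 0.05, two-sided, uncorrected


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature_name: str,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided unpaired t test (Welch unless ``equal_var``)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        # degenerate: no within-group variation (common on tiny synthetic runs)
        t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (math.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        feature=feature_name,
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
        t_statistic=t, p_value=p, significant=p < alpha,
    )


def pca_features(
    table: pd.DataFrame,
    variables: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on standardized variables (correlation-matrix eigendecomposition).

    Rows with any missing selected value are dropped (their ids are recorded
    in ``scores.attrs['dropped']``).  Returns (scores, loadings,
    variance_explained); loadings columns are unit eigenvectors with a
    deterministic sign convention (largest-magnitude entry positive).
    """
    sub = table.loc[:, list(variables)]
    keep = sub.notna().all(axis=1)
    dropped = list(table.index[~keep])
    sub = sub.loc[keep]
    if len(sub) < 3:
        raise ValueError("PCA needs >= 3 complete rows")
    x = sub.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    corr = z.T @ z / (len(z) - 1)  # correlation matrix; 0 rows for constant vars
    np.fill_diagonal(corr, 1.0)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    scores = pd.DataFrame(z @ eigvec, index=sub.index,
                          columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])])
    scores.attrs["dropped"] = dropped
    loadings = pd.DataFrame(eigvec, index=list(variables), columns=scores.columns)
    var_explained = eigval / eigval.sum()
    return scores, loadings, var_explained


def linear_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Squared Pearson correlation and the sign of the fitted slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, int(np.sign(r)) if r != 0 else 0


def normalize_functional_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each category column to [0, 1] by its maximum across genera.

    All-zero columns stay 0 (no division by zero).  Idempotent.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    out = counts.astype(float).copy()
    for col in out.columns:
        m = out[col].max()
        if m > 0:
            out[col] = out[col] / m
    return out


def cluster_genes_for_genus(
    proteins: Mapping[str, str],
    identity: float = 70.0,
    coverage: float = 0.5,
) -> list[list[str]]:
    """Pool a genus's proteomes and cluster at 70 % identity / 50 % coverage.

    Same greedy clusterer as the paralog counter; cluster representatives
    (first member of each cluster) feed downstream functional annotation.
    """
    return greedy_cluster(proteins, identity_threshold=identity, coverage=coverage)


# ---------------------------------------------------------------------------
# End-to-end report

_FLOAT_FMT = "%.6g"


def build_report(
    bundle: SubcladeBundle,
    outdir: str | Path,
    equal_var: bool = False,
    paralog_threshold_for_pca: int = 50,
) -> dict[str, pd.DataFrame]:
    """Run features -> divergence -> recruitment -> statistics on a bundle.

    Writes features.tsv, comparisons.tsv, pca_scores.tsv, presence.tsv and a
    human-readable report.txt to ``outdir``; returns the tables.  The run is
    deterministic: regenerating the bundle with the same seed reproduces
    every output byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    vectors = [
        compute_features(bundle.genomes[gid], bundle.gene_tables[gid])
        for gid in sorted(bundle.genomes)
    ]
    feats = features_table(vectors).set_index("genome_id")
    group_of = {g: name for name, members in bundle.groups.items() for g in members}
    feats["group"] = [group_of[g] for g in feats.index]

    # --- divergence ---------------------------------------------------
    ani = ani_matrix(bundle.genomes)
    pairs = species_prefilter(ani)
    pair_omegas = {}
    per_genome_omegas: dict[str, list[float]] = {g: [] for g in feats.index}
    for ga, gb in pairs:
        if group_of[ga] != group_of[gb]:
            continue
        orthologs = pair_dnds(bundle.gene_tables[ga], bundle.gene_tables[gb])
        omegas = [o.omega for o in orthologs]
        pair_omegas[(ga, gb)] = omegas
        finite = [w for w in omegas if not math.isnan(w) and w < 10.0]
        if finite:
            med = float(np.median(finite))
            per_genome_omegas[ga].append(med)
            per_genome_omegas[gb].append(med)
    dnds_summary = group_dnds(bundle.groups, pair_omegas)
    feats["dnds"] = [
        float(np.median(v)) if (v := per_genome_omegas[g]) else math.nan
        for g in feats.index
    ]
    feats["paralogs"] = [v.paralogs.get(paralog_threshold_for_pca, math.nan)
                         for v in sorted(vectors, key=lambda v: v.genome_id)]

    # --- group comparisons --------------------------------------------
    compare_features = ["gc_percent", "spacer_mean_bp", "spacer_median_bp",
                        "est_genome_size_bp", "genes_per_mb", "n_arsc",
                        "c_arsc", "dnds", "paralogs"]
    group_names = sorted(bundle.groups)
    comp_rows = []
    for i, na in enumerate(group_names):
        for nb in group_names[i + 1:]:
            for feat in compare_features:
                va = feats.loc[feats["group"] == na, feat].dropna()
                vb = feats.loc[feats["group"] == nb, feat].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                c = compare_groups(va, vb, feat, equal_var=equal_var)
                comp_rows.append({
                    "group_a": na, "group_b": nb, "feature": c.feature,
                    "mean_a": c.mean_a, "sd_a": c.sd_a,
                    "mean_b": c.mean_b, "sd_b": c.sd_b,
                    "t": c.t_statistic, "p": c.p_value,
                    "significant": c.significant,
                })
    comparisons = pd.DataFrame(comp_rows)

    # --- PCA ------------------------------------------------------------
    try:
        scores, loadings, var_exp = pca_features(feats, PCA_VARIABLES)
        scores = scores.copy()
        scores["group"] = [group_of[g] for g in scores.index]
    except ValueError:
        scores = pd.DataFrame()
        var_exp = np.array([])

    # --- recruitment ----------------------------------------------------
    presence_rows = []
    abundance = pd.DataFrame(
        0.0, index=sorted(bundle.genomes), columns=sorted(bundle.reads_per_station),
    )
    for station in sorted(bundle.reads_per_station):
        reads = bundle.reads_per_station[station]
        meta_bp = bundle.station_sizes_bp[station]
        for gid in sorted(bundle.genomes):
            genome = bundle.genomes[gid]
            table = map_reads(reads, genome)
            prof = recruitment_profile(table, genome, station, max(meta_bp, 1))
            presence_rows.append({
                "genome_id": gid, "sample_id": station,
                "n_reads": prof.n_reads_recruited, "rpkg": prof.rpkg,
                "coverage": prof.coverage_fraction, "present": prof.present,
                "anir_median": prof.anir_median,
            })
            abundance.loc[gid, station] = prof.rpkg
    presence = pd.DataFrame(presence_rows)
    genomospecies = genomospecies_cluster(ani, abundance)

    # --- write ----------------------------------------------------------
    feats_out = feats.reset_index()
    feats_out.to_csv(outdir / "features.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    scores.reset_index().to_csv(outdir / "pca_scores.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
    presence.to_csv(outdir / "presence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    ani.reset_index().to_csv(outdir / "ani.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    lines = ["Two-subclade streamlining report", "=" * 34, ""]
    for name in group_names:
        sub = feats[feats["group"] == name]
        lines.append(f"Group {name} (n={len(sub)} genomes):")
        for feat in compare_features:
            vals = sub[feat].dropna()
            if len(vals):
                lines.append(f"  {feat:<20s} {vals.mean():.4g} ± {vals.std(ddof=1):.3g}")
        if name in dnds_summary.index and not math.isnan(dnds_summary.loc[name, "median_omega"]):
            lines.append(
                f"  dN/dS (pair medians)  median {dnds_summary.loc[name, 'median_omega']:.4g}"
                f" over {int(dnds_summary.loc[name, 'n_pairs'])} pairs"
            )
        lines.append("")
    if len(comparisons):
        lines.append("Group comparisons (two-sided unpaired t test, alpha=0.05,")
        lines.append("no multiple-testing correction):")
        for r in comparisons.itertuples():
            star = " *" if r.significant else ""
            lines.append(f"  {r.group_a} vs {r.group_b} {r.feature:<20s} p={r.p:.3g}{star}")
        lines.append("")
    if var_exp.size:
        lines.append("PCA variance explained: "
                     + ", ".join(f"PC{i + 1} {v:.1%}" for i, v in enumerate(var_exp[:3])))
    lines.append(f"Genomospecies: {len(genomospecies)}")
    for gs in genomospecies:
        lines.append(f"  [{', '.join(gs.members)}] min ANI {gs.min_pairwise_ani:.2f}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    return {"features": feats_out, "comparisons": comparisons, "pca_scores": scores,
            "presence": presence, "ani": ani, "dnds": dnds_summary}
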