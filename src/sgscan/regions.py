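"""High-diversity outlier regions, haplogroups, and allelic-bias integration.

Outlier detection operationalises "a run of windows with exceptional
diversity inside the rearrangement": maximal runs of consecutive windows
with nucleotide diversity above the 95th percentile, significance by a
circular-rotation permutation test on the windowed Tajima's D track
(rotations preserve window autocorrelation).  Haplogroups are found by
silhouette-selected average-linkage clustering of pairwise Hamming
distances, with groups below a minimum size reported as ungrouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .phasing import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class OutlierRegion:
    contig: str
    start: int
    end: int
    window_index: tuple[int, int]  # [first, last] window indices, inclusive
    mean_pi: float
    mean_tajimas_d: float
    background_pi: float
    background_tajimas_d: float
    perm_p: float


def rotation_permutation_p(
    values: np.ndarray,
    span: tuple[int, int],
    n_perms: int,
    seed: int = 0,
) -> float:
    """P(mean over a random circular rotation's same-length run >= observed).

    ``span`` is an inclusive index pair into ``values``.  NA values are
    treated as absent from the means.  Includes the observed statistic in
    the null count, so p > 0.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = span
    obs = np.nanmean(values[lo : hi + 1])
    rng = np.random.default_rng(seed)
    n = len(values)
    shifts = rng.integers(1, n, size=n_perms)
    count = 1
    for s in shifts:
        rotated = np.roll(values, int(s))
        if np.nanmean(rotated[lo : hi + 1]) >= obs:
            count += 1
    return count / (n_perms + 1)


def detect_outlier_regions(
    stats: pd.DataFrame,
    min_windows: int = 5,
    n_perms: int = 1000,
    seed: int = 0,
    pi_quantile: float = 0.95,
) -> list[OutlierRegion]:
    """Find maximal runs of high-diversity windows and test their Tajima's D.

    ``stats`` must carry ``contig``, ``start``, ``end``, ``pi`` and
    ``tajimas_d`` columns (one row per window, in genomic order).
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    pi = stats["pi"].to_numpy(dtype=float)
    td = stats["tajimas_d"].to_numpy(dtype=float)
    thr = np.nanquantile(pi, pi_quantile)
    high = np.nan_to_num(pi, nan=-np.inf) > thr

    regions: list[OutlierRegion] = []
    i = 0
    n = len(stats)
    while i < n:
        if not high[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and high[j + 1] and (
            stats["contig"].iloc[j + 1] == stats["contig"].iloc[i]
        ):
            j += 1
        if j - i + 1 >= min_windows:
            inside = slice(i, j + 1)
            outside = np.ones(n, dtype=bool)
            outside[inside] = False
            regions.append(
                OutlierRegion(
                    contig=str(stats["contig"].iloc[i]),
                    start=int(stats["start"].iloc[i]),
                    end=int(stats["end"].iloc[j]),
                    window_index=(i, j),
                    mean_pi=float(np.nanmean(pi[inside])),
                    mean_tajimas_d=float(np.nanmean(td[inside])),
                    background_pi=float(np.nanmean(pi[outside])),
                    background_tajimas_d=float(np.nanmean(td[outside])),
                    perm_p=rotation_permutation_p(td, (i, j), n_perms, seed),
                )
            )
        i = j + 1
    return regions


def pairwise_hamming(H: HaplotypeSet) -> np.ndarray:
    """Pairwise mismatch fraction over pairwise-complete sites.

    Returns a symmetric matrix with zero diagonal; pairs sharing no sites
    get NA.
    """
    if H.n_haps < 2:
        raise ValueError("need at least 2 haplotypes")
    a = H.alleles
    n = H.n_haps
    out = np.zeros((n, n))
    for i in range(n):
        valid_i = a[i] >= 0
        for j in range(i + 1, n):
            shared = valid_i & (a[j] >= 0)
            ns = int(shared.sum())
            if ns == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                frac = float((a[i, shared] != a[j, shared]).mean())
                out[i, j] = out[j, i] = frac
    return out


@dataclass
class HaplogroupPartition:
    labels: np.ndarray  # per-hap group id (1-based); 0 = ungrouped
    group_sizes: dict[int, int]
    mean_within: float
    mean_between: float

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


def cluster_haplogroups(
    distmat: np.ndarray,
    min_size: int = 3,
    max_k: int = 5,
) -> HaplogroupPartition:
    """Average-linkage clustering, k chosen by mean silhouette over 2..max_k.

    Clusters smaller than ``min_size`` are reported as ungrouped (label 0).
    With fewer than 4 haplotypes, or no structure (all-zero distances), a
    single group is returned with a warning.
    """
    from sklearn.metrics import silhouette_score

    distmat = np.asarray(distmat, dtype=float)
    n = distmat.shape[0]
    if n < 4 or np.nanmax(distmat) == 0:
        logger.warning("cluster_haplogroups: no structure, single group")
        labels = np.ones(n, dtype=int)
        return HaplogroupPartition(
            labels=labels,
            group_sizes={1: n},
            mean_within=float(np.nanmean(squareform(distmat, checks=False)))
            if n > 1
            else 0.0,
            mean_between=np.nan,
        )

    condensed = squareform(distmat, checks=False)
    Z = linkage(condensed, method="average")
    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, min(max_k, n - 1) + 1):
        labels = fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(distmat, labels, metric="precomputed")
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_labels is None:
        best_labels = np.ones(n, dtype=int)

    # drop undersized clusters, relabel survivors 1..g by size
    sizes = {g: int((best_labels == g).sum()) for g in np.unique(best_labels)}
    keep = [g for g, s in sizes.items() if s >= min_size]
    keep.sort(key=lambda g: -sizes[g])
    labels = np.zeros(n, dtype=int)
    for new, old in enumerate(keep, start=1):
        labels[best_labels == old] = new
    group_sizes = {new: sizes[old] for new, old in enumerate(keep, start=1)}

    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == 0 or labels[j] == 0 or not np.isfinite(distmat[i, j]):
                continue
            (within if labels[i] == labels[j] else between).append(
                distmat[i, j]
            )
    return HaplogroupPartition(
        labels=labels,
        group_sizes=group_sizes,
        mean_within=float(np.mean(within)) if within else np.nan,
        mean_between=float(np.mean(between)) if between else np.nan,
    )


def haplogroup_dxy(
    h1: HaplotypeSet,
    h2: HaplotypeSet,
    zal2: HaplotypeSet,
    windows,
    mask=None,
) -> pd.DataFrame:
    """Three d_XY tracks: ZAL2-vs-group1, ZAL2-vs-group2, group1-vs-group2."""
    from .popgen import dxy

    return pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "dxy_z2_h1": (
                dxy(zal2, h1, windows, mask) if h1.n_haps else np.nan
            ),
            "dxy_z2_h2": (
                dxy(zal2, h2, windows, mask) if h2.n_haps else np.nan
            ),
            "dxy_h1_h2": (
                dxy(h1, h2, windows, mask)
                if h1.n_haps and h2.n_haps
                else np.nan
            ),
        }
    )


MAJOR, MINOR, MISSING_CAT = 0, 1, 2
CATEGORY_NAMES = {MAJOR: "MAJOR", MINOR: "MINOR", MISSING_CAT: "MISSING"}


def genotype_plot_matrix(
    H: HaplotypeSet, sw_alleles: np.ndarray
) -> np.ndarray:
    """Categorical haplotype-by-site matrix against the SW reference allele.

    ``sw_alleles`` is aligned with ``H.positions``; ``-1`` marks sites
    absent from the SW genome (whole column becomes MISSING).
    """
    sw = np.asarray(sw_alleles, dtype=np.int8)
    if len(sw) != len(H.positions):
        raise ValueError("SW allele vector must match the site grid")
    out = np.full(H.alleles.shape, MISSING_CAT, dtype=np.int8)
    known = (H.alleles >= 0) & (sw >= 0)[None, :]
    out[known & (H.alleles == sw[None, :])] = MAJOR
    out[known & (H.alleles != sw[None, :])] = MINOR
    return out


def allelic_bias(
    tbl: pd.DataFrame,
    min_total: int = 20,
) -> pd.DataFrame:
    """Per-gene allelic bias with a signed-rank test against 0.5 and BH-FDR.

    ``tbl`` columns: ``gene``, ``sample``, ``zal2m_count``, ``zal2_count``.
    Genes whose summed counts fall below ``min_total`` are excluded.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    excluded = 0
    for gene, grp in tbl.groupby("gene", sort=True):
        m_sum = int(grp["zal2m_count"].sum())
        z_sum = int(grp["zal2_count"].sum())
        if m_sum + z_sum < min_total:
            excluded += 1
            continue
        totals = grp["zal2m_count"] + grp["zal2_count"]
        ok = totals > 0
        props = (grp.loc[ok, "zal2m_count"] / totals[ok]).to_numpy()
        diffs = props - 0.5
        if len(diffs) == 0 or np.all(diffs == 0):
            p = 1.0
        else:
            try:
                p = float(sps.wilcoxon(diffs).pvalue)
            except ValueError:
                p = 1.0
        log2_ratio = (
            np.log2(m_sum / z_sum) if m_sum > 0 and z_sum > 0 else np.nan
        )
        rows.append(
            {
                "gene": gene,
                "zal2m_sum": m_sum,
                "zal2_sum": z_sum,
                "log2_ratio": log2_ratio,
                "n_samples": int(ok.sum()),
                "p": p,
            }
        )
    if excluded:
        logger.info("allelic_bias: %d genes below min_total excluded", excluded)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out.attrs["n_excluded"] = excluded
    return out


def gene_h_assignment(
    genes: pd.DataFrame,
    h_bins: pd.DataFrame,
) -> pd.Series:
    """Per-gene H: the overlapping bin's value, or the mean over several.

    ``genes`` needs ``gene``, ``start``, ``end`` (0-based half-open);
    ``h_bins`` needs ``start``, ``end``, ``max_h``.  Genes overlapping no
    bin get NA.
    """
    bs = h_bins["start"].to_numpy()
    be = h_bins["end"].to_numpy()
    bh = h_bins["max_h"].to_numpy(dtype=float)
    out = []
    for _, g in genes.iterrows():
        sel = (bs < g["end"]) & (be > g["start"])
        out.append(float(bh[sel].mean()) if sel.any() else np.nan)
    return pd.Series(out, index=genes["gene"].to_numpy(), name="h")


def ab_h_association(
    ab: pd.DataFrame,
    gene_h: pd.Series,
) -> dict:
    """OLS of per-gene log2 allelic ratio on log2 H.

    Positive slope = rising H predicts bias toward the rearranged allele.
    Returns NA slope/p when the predictor is degenerate.
    """
    merged = ab.set_index("gene").join(gene_h.rename("h"), how="inner")
    merged = merged[
        np.isfinite(merged["log2_ratio"]) & np.isfinite(merged["h"]) & (
            merged["h"] > 0
        )
    ]
    n = len(merged)
    if n < 3 or merged["h"].nunique() < 2:
        return {"slope": np.nan, "p": np.nan, "n": n}
    x = np.log2(merged["h"].to_numpy())
    y = merged["log2_ratio"].to_numpy()
    if np.allclose(x, x[0]):
        return {"slope": np.nan, "p": np.nan, "n": n}
    res = sps.linregress(x, y)
    return {"slope": float(res.slope), "p": float(res.pvalue), "n": n}


def morph_bias_enrichment(
    de_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Two-proportion z-test per tissue: DE-gene fraction inside vs outside
    the rearrangement, with BH correction across tissues.

    ``de_flags`` columns: ``tissue``, ``de_inside``, ``n_inside``,
    ``de_outside``, ``n_outside``.  A zero marginal triggers a Fisher
    exact fallback.
    """
    from statsmodels.stats.multitest import multipletests
    from statsmodels.stats.proportion import proportions_ztest

    rows = []
    for _, r in de_flags.iterrows():
        if min(r["n_inside"], r["n_outside"]) <= 0:
            raise ValueError("both gene counts must be positive")
        de = np.array([r["de_inside"], r["de_outside"]])
        n = np.array([r["n_inside"], r["n_outside"]])
        if de.min() == 0 or (n - de).min() == 0:
            table = [[de[0], n[0] - de[0]], [de[1], n[1] - de[1]]]
            stat, p = sps.fisher_exact(table)
            kind = "fisher"
        else:
            stat, p = proportions_ztest(de, n)
            kind = "ztest"
        rows.append(
            {
                "tissue": r["tissue"],
                "prop_inside": de[0] / n[0],
                "prop_outside": de[1] / n[1],
                "statistic": float(stat),
                "p": float(p),
                "test": kind,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
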