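"""Windowed diversity/divergence statistics with accessible-site correction.

All window denominators use the accessible length of the window (the
breadth-of-coverage correction), not its span; windows with zero
accessible length get NA.  Per-site estimators use the unbiased form
``n/(n-1) * 2p(1-p)`` with ``n`` the non-missing haplotype count at the
site.  Values are per-site fractions; format as percent only at output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import AccessibilityMask, GenotypeMatrix, Window
from .phasing import FixedDifferenceSet, HaplotypeSet

logger = logging.getLogger(__name__)


def _site_counts(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, n, k): non-missing haplotype count and derived count."""
    if isinstance(obj, HaplotypeSet):
        n, k = obj.allele_counts()
        return obj.positions, n, k
    if isinstance(obj, GenotypeMatrix):
        dose = obj.alt_dosage()
        valid = dose >= 0
        n = 2 * valid.sum(axis=1)
        k = np.where(valid, dose, 0).sum(axis=1)
        return obj.pos, n, k
    raise TypeError(f"unsupported input type: {type(obj)!r}")


def _window_slices(positions: np.ndarray, windows: Sequence[Window]):
    pos0 = positions - 1
    for w in windows:
        lo = int(np.searchsorted(pos0, w.start))
        hi = int(np.searchsorted(pos0, w.end))
        yield w, slice(lo, hi)


def _pi_per_site(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    out = np.zeros(len(n), dtype=float)
    ok = n >= 2
    p = np.divide(k, n, out=np.zeros(len(n)), where=ok)
    out[ok] = (n[ok] / (n[ok] - 1.0)) * 2.0 * p[ok] * (1.0 - p[ok])
    return out


def nucleotide_diversity(
    obj: HaplotypeSet | GenotypeMatrix,
    windows: Sequence[Window],
    mask: AccessibilityMask | None = None,
) -> np.ndarray:
    """Per-window nucleotide diversity (accessible-length denominator)."""
    positions, n, k = _site_counts(obj)
    per_site = _pi_per_site(n, k)
    out = np.empty(len(windows))
    for i, (w, sl) in enumerate(_window_slices(positions, windows)):
        l_acc = w.l_acc if mask is None else mask.accessible_length(
            w.contig, w.start, w.end
        )
        out[i] = per_site[sl].sum() / l_acc if l_acc > 0 else np.nan
    return out


def dxy(
    pop1: HaplotypeSet | GenotypeMatrix,
    pop2: HaplotypeSet | GenotypeMatrix,
    windows: Sequence[Window],
    mask: AccessibilityMask | None = None,
) -> np.ndarray:
    """Per-window between-population divergence on a shared site grid."""
    pos1, n1, k1 = _site_counts(pop1)
    pos2, n2, k2 = _site_counts(pop2)
    if len(pos1) != len(pos2) or np.any(pos1 != pos2):
        raise ValueError("populations must share a site grid")
    ok = (n1 >= 1) & (n2 >= 1)
    p1 = np.divide(k1, n1, out=np.zeros(len(n1)), where=ok)
    p2 = np.divide(k2, n2, out=np.zeros(len(n2)), where=ok)
    per_site = np.where(ok, p1 * (1 - p2) + p2 * (1 - p1), 0.0)
    out = np.empty(len(windows))
    for i, (w, sl) in enumerate(_window_slices(pos1, windows)):
        l_acc = w.l_acc if mask is None else mask.accessible_length(
            w.contig, w.start, w.end
        )
        out[i] = per_site[sl].sum() / l_acc if l_acc > 0 else np.nan
    return out


def fixed_diff_density(
    fd: FixedDifferenceSet,
    windows: Sequence[Window],
    mask: AccessibilityMask | None = None,
) -> np.ndarray:
    """Fixed differences per accessible bp, per window."""
    out = np.empty(len(windows))
    pos0 = fd.pos - 1
    for i, w in enumerate(windows):
        sel = (np.asarray(fd.contig) == w.contig) & (pos0 >= w.start) & (
            pos0 < w.end
        )
        l_acc = w.l_acc if mask is None else mask.accessible_length(
            w.contig, w.start, w.end
        )
        out[i] = sel.sum() / l_acc if l_acc > 0 else np.nan
    return out


def fst(
    pop1: HaplotypeSet | GenotypeMatrix,
    pop2: HaplotypeSet | GenotypeMatrix,
    windows: Sequence[Window],
    estimator: str = "hudson",
) -> np.ndarray:
    """Per-window F_ST, Hudson estimator as a ratio of averages.

    ``estimator="wc"`` selects Weir & Cockerham instead.
    """
    pos1, n1, k1 = _site_counts(pop1)
    pos2, n2, k2 = _site_counts(pop2)
    if len(pos1) != len(pos2) or np.any(pos1 != pos2):
        raise ValueError("populations must share a site grid")
    ok = (n1 >= 2) & (n2 >= 2)
    p1 = np.divide(k1, n1, out=np.zeros(len(n1)), where=ok)
    p2 = np.divide(k2, n2, out=np.zeros(len(n2)), where=ok)
    if estimator == "hudson":
        num = np.where(
            ok,
            (p1 - p2) ** 2
            - np.divide(p1 * (1 - p1), n1 - 1, where=ok, out=np.zeros(len(n1)))
            - np.divide(p2 * (1 - p2), n2 - 1, where=ok, out=np.zeros(len(n2))),
            0.0,
        )
        den = np.where(ok, p1 * (1 - p2) + p2 * (1 - p1), 0.0)
    elif estimator == "wc":
        # Weir & Cockerham (1984) theta-hat for haploid samples
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2 - (n1**2 + n2**2) / np.maximum(n1 + n2, 1)) / 1.0
        pbar = np.divide(
            n1 * p1 + n2 * p2, n1 + n2, where=ok, out=np.zeros(len(n1))
        )
        s2 = np.divide(
            n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2,
            nbar,
            where=ok,
            out=np.zeros(len(n1)),
        )
        num = np.where(ok, s2 - (pbar * (1 - pbar) - s2 / 2) / (nbar - 1), 0.0)
        den = np.where(
            ok, nc / nbar * pbar * (1 - pbar) + s2 * (1 - nc / nbar), 0.0
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    out = np.empty(len(windows))
    for i, (w, sl) in enumerate(_window_slices(pos1, windows)):
        d = den[sl].sum()
        out[i] = num[sl].sum() / d if d > 0 else np.nan
    return out


def _tajima_constants(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(
    H: HaplotypeSet, windows: Sequence[Window]
) -> np.ndarray:
    """Per-window Tajima's D from complete-case sites."""
    complete = (H.alleles >= 0).all(axis=0)
    n = H.n_haps
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    k = H.alleles.clip(min=0).sum(axis=0)
    seg = complete & (k > 0) & (k < n)
    pos = H.positions
    a1 = (1.0 / np.arange(1, n)).sum()
    e1, e2 = _tajima_constants(n)
    p = k / n
    pi_site = np.where(seg, (n / (n - 1.0)) * 2.0 * p * (1 - p), 0.0)

    out = np.empty(len(windows))
    for i, (w, sl) in enumerate(_window_slices(pos, windows)):
        S = int(seg[sl].sum())
        if S == 0:
            out[i] = np.nan
            continue
        pi_sum = pi_site[sl].sum()
        var = e1 * S + e2 * S * (S - 1)
        out[i] = (pi_sum - S / a1) / np.sqrt(var)
    return out


@dataclass
class SFS:
    """Folded (minor-allele-count) site frequency spectrum."""

    counts: np.ndarray  # index i = minor allele count i, i in 1..n//2
    n_haplotypes: int
    singletons_excluded: bool

    def total(self) -> int:
        return int(self.counts.sum())


def folded_sfs(H: HaplotypeSet, exclude_singletons: bool = False) -> SFS:
    """Histogram of minor-allele counts over complete-case segregating sites."""
    complete = (H.alleles >= 0).all(axis=0)
    n = H.n_haps
    k = H.alleles.clip(min=0).sum(axis=0)
    seg = complete & (k > 0) & (k < n)
    minor = np.minimum(k[seg], n - k[seg])
    if exclude_singletons:
        minor = minor[minor > 1]
    counts = np.zeros(n // 2 + 1, dtype=np.int64)
    np.add.at(counts, minor, 1)
    return SFS(
        counts=counts[1:],
        n_haplotypes=n,
        singletons_excluded=exclude_singletons,
    )


# ---------------------------------------------------------------------------
# coding-sequence diversity (Nei-Gojobori mutational-opportunity counting)
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        from itertools import product

        for c in product("ACGT", repeat=3):
            codon_s = "".join(c)
            _CODON_TABLE[codon_s] = str(Seq(codon_s).translate())
    return _CODON_TABLE[codon]


def nei_gojobori_codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    Each of the nine single-base changes contributes 1/3 site, classified
    by the standard codon table; changes to stop codons count as
    nonsynonymous.
    """
    codon = codon.upper()
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if _translate(mutant) == aa and aa != "*":
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


@dataclass
class CodingDiversity:
    """Per-gene (or gene-window) coding diversity summary."""

    table: pd.DataFrame  # gene, n_sites, s_sites, pi_n_sum, pi_s_sum, ...


def pin_pis(
    H: HaplotypeSet,
    ann,
    alleles: tuple[np.ndarray, np.ndarray],
    gene_window: int = 20,
    gene_step: int = 5,
) -> CodingDiversity:
    """pi_N and pi_S per gene and over sliding gene windows.

    ``alleles`` gives (ref_base, alt_base) arrays aligned with
    ``H.positions`` so each SNP can be classified against the reference
    codon.  Genes whose reference CDS is not a clean ORF are skipped with a
    warning.
    """
    from .io_core import reverse_complement

    ref_base, alt_base = (np.asarray(a, dtype=object) for a in alleles)
    n, k = H.allele_counts()
    pi_site = _pi_per_site(n, k)
    pos0 = H.positions - 1

    bad = set(ann.validate())
    rows = []
    for gene in ann.genes:
        if gene.gene_id in bad:
            logger.warning("gene %s: invalid ORF, skipped", gene.gene_id)
            continue
        seq = gene.cds_sequence(ann.reference).upper()
        n_sites = s_sites = 0.0
        for ci in range(len(seq) // 3):
            nn, ss = nei_gojobori_codon_sites(seq[3 * ci : 3 * ci + 3])
            n_sites += nn
            s_sites += ss

        cds_pos = gene.cds_positions()  # genomic 0-based, translation order
        lookup = {int(p): j for j, p in enumerate(cds_pos)}
        pi_n_sum = pi_s_sum = 0.0
        lo = np.searchsorted(pos0, gene.span[0])
        hi = np.searchsorted(pos0, gene.span[1])
        for si in range(lo, hi):
            j = lookup.get(int(pos0[si]))
            if j is None or pi_site[si] == 0:
                continue
            ci, off = divmod(j, 3)
            codon = seq[3 * ci : 3 * ci + 3]
            alt = str(alt_base[si]).upper()
            refb = str(ref_base[si]).upper()
            if gene.strand == "-":
                alt = reverse_complement(alt)
                refb = reverse_complement(refb)
            if codon[off] != refb:
                # site's ref allele disagrees with the reference codon;
                # classify the change between the two observed alleles
                codon = codon[:off] + refb + codon[off + 1 :]
            mutant = codon[:off] + alt + codon[off + 1 :]
            if _translate(mutant) == _translate(codon) and _translate(codon) != "*":
                pi_s_sum += pi_site[si]
            else:
                pi_n_sum += pi_site[si]

        rows.append(
            {
                "gene": gene.gene_id,
                "start": gene.span[0],
                "end": gene.span[1],
                "n_sites": n_sites,
                "s_sites": s_sites,
                "pi_n_sum": pi_n_sum,
                "pi_s_sum": pi_s_sum,
                "pi_n": pi_n_sum / n_sites if n_sites else np.nan,
                "pi_s": pi_s_sum / s_sites if s_sites else np.nan,
            }
        )
    per_gene = pd.DataFrame(rows)

    win_rows = []
    for w0 in range(0, max(len(per_gene) - gene_window + 1, 0), gene_step):
        blk = per_gene.iloc[w0 : w0 + gene_window]
        pi_n = blk["pi_n_sum"].sum() / blk["n_sites"].sum()
        pi_s = blk["pi_s_sum"].sum() / blk["s_sites"].sum()
        win_rows.append(
            {
                "first_gene": blk["gene"].iloc[0],
                "last_gene": blk["gene"].iloc[-1],
                "start": blk["start"].iloc[0],
                "end": blk["end"].iloc[-1],
                "pi_n": pi_n,
                "pi_s": pi_s,
                "pin_pis": pi_n / pi_s if pi_s > 0 else np.nan,
            }
        )
    per_gene.attrs["windows"] = pd.DataFrame(win_rows)
    return CodingDiversity(table=per_gene)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_decay(
    H: HaplotypeSet, max_dist: int, bin_width: int
) -> pd.DataFrame:
    """Mean pairwise r^2 within distance bins from phased haplotypes.

    r^2 = D^2 / (pA pa pB pb) from haplotype frequencies over
    pairwise-complete haplotypes; monomorphic pairs are skipped.
    """
    pos = H.positions
    a = H.alleles
    nbins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    S = len(pos)
    for i in range(S):
        hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        for j in range(i + 1, hi):
            valid = (a[:, i] >= 0) & (a[:, j] >= 0)
            nv = int(valid.sum())
            if nv < 2:
                continue
            x = a[valid, i].astype(float)
            y = a[valid, j].astype(float)
            pa = x.mean()
            pb = y.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            pab = (x * y).mean()
            d = pab - pa * pb
            r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
            b = int((pos[j] - pos[i] - 1) // bin_width)
            if b < nbins:
                sums[b] += r2
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_low": np.arange(nbins) * bin_width,
            "dist_high": (np.arange(nbins) + 1) * bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def pairwise_r2(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """r^2 between two sites given per-haplotype alleles (no missing)."""
    pa = hap_i.mean()
    pb = hap_j.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    d = (hap_i * hap_j).mean() - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


# ---------------------------------------------------------------------------
# effective-size ratio
# ---------------------------------------------------------------------------


def ne_ratio(
    pi_num: np.ndarray,
    pi_den: np.ndarray,
    bootstrap: dict | None = None,
) -> dict:
    """Ratio of mean per-window synonymous diversity, with bootstrap SE.

    ``bootstrap`` keys: ``reps`` (default 1000), ``seed``.  Windows are the
    resampling blocks.  Pairs with NA in either series are dropped.
    """
    pi_num = np.asarray(pi_num, dtype=float)
    pi_den = np.asarray(pi_den, dtype=float)
    if len(pi_num) != len(pi_den):
        raise ValueError("series must be paired per window")
    keep = np.isfinite(pi_num) & np.isfinite(pi_den)
    pi_num, pi_den = pi_num[keep], pi_den[keep]
    den = pi_den.mean() if len(pi_den) else 0.0
    if den == 0:
        return {"ratio": np.nan, "se": np.nan, "ci": (np.nan, np.nan)}
    ratio = pi_num.mean() / den

    bootstrap = bootstrap or {}
    reps = int(bootstrap.get("reps", 1000))
    rng = np.random.default_rng(bootstrap.get("seed", 0))
    n = len(pi_num)
    idx = rng.integers(0, n, size=(reps, n))
    bnum = pi_num[idx].mean(axis=1)
    bden = pi_den[idx].mean(axis=1)
    ok = bden > 0
    ratios = bnum[ok] / bden[ok]
    return {
        "ratio": float(ratio),
        "se": float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan,
        "ci": (
            float(np.percentile(ratios, 2.5)),
            float(np.percentile(ratios, 97.5)),
        )
        if len(ratios)
        else (np.nan, np.nan),
    }


def chromosome_count_ne_ratio(
    n_het: int, n_standard_hom: int, n_rearranged_hom: int = 0
) -> float:
    """Rearranged-to-standard effective-size ratio implied by chromosome
    counts: each heterokaryotype carries one chromosome of each
    arrangement, each homokaryotype two of one kind."""
    rearranged = n_het + 2 * n_rearranged_hom
    standard = n_het + 2 * n_standard_hom
    if standard == 0:
        return np.nan
    return rearranged / standard


# ---------------------------------------------------------------------------
# assembled per-window table
# ---------------------------------------------------------------------------


def window_stat_table(
    pop1: HaplotypeSet,
    pop2: HaplotypeSet | None,
    fd: FixedDifferenceSet | None,
    windows: Sequence[Window],
    mask: AccessibilityMask | None = None,
) -> pd.DataFrame:
    """Per-window record table: coordinates, L_acc, S, pi (pop1), and when
    available d_XY, d_f, F_ST (pop1 vs pop2) and Tajima's D (pop1)."""
    df = pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "l_acc": [
                w.l_acc
                if mask is None
                else mask.accessible_length(w.contig, w.start, w.end)
                for w in windows
            ],
            "n_snps": [w.s for w in windows],
        }
    )
    df["pi"] = nucleotide_diversity(pop1, windows, mask)
    df["tajimas_d"] = tajimas_d(pop1, windows)
    df["n_pop1"] = pop1.n_haps
    if pop2 is not None:
        df["dxy"] = dxy(pop1, pop2, windows, mask)
        df["fst"] = fst(pop1, pop2, windows)
        df["n_pop2"] = pop2.n_haps
    if fd is not None:
        df["d_f"] = fixed_diff_density(fd, windows, mask)
    return df
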