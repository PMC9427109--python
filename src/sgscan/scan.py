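"""Sweep and balancing-selection scans.

The sweep statistic is the pairwise-homozygosity-tract H: for a focal
position it averages, over all haplotype pairs, the distance between the
nearest flanking mismatches (truncated at the contig ends — a conservative
choice that deflates H near edges).  Window summaries are the maximum H
per window; significance is an empirical p-value computed within bins of
windows with similar SNP counts.

The balancing statistic is a kernel-weighted excess of neighbouring SNPs
at folded frequencies similar to the core SNP's, normalised so its neutral
expectation is approximately zero.  It is a stand-in for allele-frequency
-spectrum-based balancing scans, validated by recovery properties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import Window
from .phasing import HaplotypeSet


@dataclass
class HScanTrack:
    """Per-focal-site H values plus (optionally) window summaries."""

    positions: np.ndarray
    h: np.ndarray
    contig_length: int


def h_statistic(
    H: HaplotypeSet,
    contig_length: int,
    focal_positions: np.ndarray | None = None,
) -> HScanTrack:
    """Mean pairwise identity-tract length around each focal position.

    For each haplotype pair the tract runs from the nearest mismatching
    SNP strictly left of the focal position (or the contig start) to the
    nearest mismatching SNP strictly right of it (or the contig end).
    Sites missing in either haplotype are skipped for that pair.
    """
    if H.n_haps < 2:
        raise ValueError("need at least 2 haplotypes")
    if focal_positions is None:
        focal_positions = H.positions
    focal = np.asarray(focal_positions, dtype=np.int64)
    a = H.alleles
    pos = H.positions.astype(np.int64)
    n = H.n_haps
    total = np.zeros(len(focal), dtype=float)
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            valid = (a[i] >= 0) & (a[j] >= 0)
            mism = pos[valid & (a[i] != a[j])]
            n_pairs += 1
            if len(mism) == 0:
                total += contig_length
                continue
            ir = np.searchsorted(mism, focal, side="right")
            il = np.searchsorted(mism, focal, side="left") - 1
            right = np.where(
                ir < len(mism), mism[np.minimum(ir, len(mism) - 1)], contig_length
            )
            left = np.where(il >= 0, mism[np.maximum(il, 0)], 0)
            total += right - left
    return HScanTrack(
        positions=focal, h=total / n_pairs, contig_length=contig_length
    )


def window_max_h(track: HScanTrack, windows: Sequence[Window]) -> pd.DataFrame:
    """Max H per window plus the focal-site count; empty windows get NA."""
    pos0 = track.positions - 1
    rows = []
    for w in windows:
        lo = int(np.searchsorted(pos0, w.start))
        hi = int(np.searchsorted(pos0, w.end))
        rows.append(
            {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "n_snps": hi - lo,
                "max_h": track.h[lo:hi].max() if hi > lo else np.nan,
            }
        )
    return pd.DataFrame(rows)


def empirical_p_by_snp_bins(
    summaries: pd.DataFrame,
    bin_width: int = 50,
    merge_threshold: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical p per window, ranked within SNP-count bins.

    Windows are binned by SNP count in ``bin_width`` increments; windows
    with more than ``merge_threshold`` SNPs share a single merged bin.
    Within a bin, ``p = (#windows with summary >= focal) / bin size`` (the
    focal window counts itself, so p > 0).  Windows with zero SNPs are
    excluded.
    """
    df = summaries.copy()
    df = df[df["n_snps"] > 0].reset_index(drop=True)
    bin_id = np.where(
        df["n_snps"] > merge_threshold,
        -1,
        (df["n_snps"] - 1) // bin_width,
    )
    df["snp_bin"] = bin_id
    pvals = np.empty(len(df))
    for b in np.unique(bin_id):
        sel = np.nonzero(bin_id == b)[0]
        vals = df.loc[sel, "max_h"].to_numpy()
        m = len(sel)
        for idx, v in zip(sel, vals):
            pvals[idx] = np.sum(vals >= v) / m
    df["empirical_p"] = pvals
    df["candidate"] = df["empirical_p"] < alpha
    return df


@dataclass
class BetaTrack:
    table: pd.DataFrame  # position, folded_freq, beta, n_neighbours


def _neutral_mean_weight(f_core: float, d: float, n: int) -> float:
    """Expected kernel weight for a neighbour drawn from the neutral
    folded SFS (P(derived count i) ~ 1/i) with n haplotypes."""
    i = np.arange(1, n)
    p = (1.0 / i) / (1.0 / i).sum()
    folded = np.minimum(i, n - i) / n
    w = np.maximum(0.0, 1.0 - np.abs(folded - f_core) / d)
    return float((p * w).sum())


def beta_statistic(
    H: HaplotypeSet,
    window_bp: int = 10_000,
    kernel_halfwidth: float = 0.2,
    core_positions: np.ndarray | None = None,
) -> BetaTrack:
    """Kernel-similarity excess of neighbouring folded frequencies.

    For core SNP with folded frequency ``f``, neighbours within
    ``window_bp`` are weighted by ``max(0, 1 - |f_i - f|/d)``; the weighted
    count, rescaled by the neutral mean weight so its expectation matches
    the raw count under uniform frequencies, is converted to a Watterson
    theta and compared with the unweighted one:
    ``beta = theta_weighted - theta_W``.  Cores without neighbours get NA.
    """
    n, k = H.allele_counts()
    seg = (n >= 2) & (k > 0) & (k < n)
    pos = H.positions[seg]
    p = k[seg] / n[seg]
    folded = np.minimum(p, 1 - p)
    nh = H.n_haps
    a1 = (1.0 / np.arange(1, nh)).sum()

    if core_positions is None:
        core_positions = pos
    rows = []
    for cpos in np.asarray(core_positions, dtype=np.int64):
        ci = np.searchsorted(pos, cpos)
        if ci >= len(pos) or pos[ci] != cpos:
            continue
        lo = np.searchsorted(pos, cpos - window_bp)
        hi = np.searchsorted(pos, cpos + window_bp, side="right")
        sel = np.r_[lo:ci, ci + 1 : hi]
        S = len(sel)
        if S == 0:
            rows.append(
                {
                    "position": cpos,
                    "folded_freq": folded[ci],
                    "beta": np.nan,
                    "n_neighbours": 0,
                }
            )
            continue
        w = np.maximum(
            0.0, 1.0 - np.abs(folded[sel] - folded[ci]) / kernel_halfwidth
        )
        mean_w = _neutral_mean_weight(float(folded[ci]), kernel_halfwidth, nh)
        theta_w = S / a1
        theta_b = (w.sum() / mean_w) / a1
        rows.append(
            {
                "position": cpos,
                "folded_freq": folded[ci],
                "beta": theta_b - theta_w,
                "n_neighbours": S,
            }
        )
    return BetaTrack(table=pd.DataFrame(rows))


@dataclass
class DStatTrack:
    table: pd.DataFrame  # window coords, abba, baba, d


def patterson_d(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    positions: np.ndarray,
    windows: Sequence[Window],
) -> DStatTrack:
    """Windowed ABBA-BABA D from four aligned allele-frequency series."""
    series = [np.asarray(x, dtype=float) for x in (p1, p2, p3, p4)]
    if len({len(s) for s in series}) != 1 or len(series[0]) != len(positions):
        raise ValueError("frequency series must be aligned")
    q1, q2, q3, q4 = series
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    rows = []
    for w in windows:
        lo = int(np.searchsorted(pos0, w.start))
        hi = int(np.searchsorted(pos0, w.end))
        sa = abba[lo:hi].sum()
        sb = baba[lo:hi].sum()
        rows.append(
            {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "abba": sa,
                "baba": sb,
                "d": (sa - sb) / (sa + sb) if (sa + sb) > 0 else np.nan,
            }
        )
    return DStatTrack(table=pd.DataFrame(rows))
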