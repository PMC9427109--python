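"""Arrangement-diagnostic fixed differences and chromosome-of-origin phasing.

A *fixed difference* is a site at which every standard homokaryotype (TS)
is homozygous for one allele, every rearranged homokaryotype (SW) is
homozygous for the other, and every heterokaryotype (WS) is heterozygous.
Such sites diagnose the chromosome of origin of any fragment that overlaps
one of them, which in turn lets us build arrangement-resolved
pseudo-haplotypes for heterokaryotypic samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import GenotypeMatrix, SampleMeta, MISSING
from .simulate import FragmentSet, SimTruth, ZAL2, ZAL2M, CLASS_NAMES

logger = logging.getLogger(__name__)

# fragment labels
LBL_ZAL2, LBL_ZAL2M, LBL_UNASSIGNED, LBL_CONFLICT = 0, 1, 2, 3
LABEL_NAMES = {
    LBL_ZAL2: "ZAL2",
    LBL_ZAL2M: "ZAL2m",
    LBL_UNASSIGNED: "unassigned",
    LBL_CONFLICT: "conflict",
}


@dataclass
class FixedDifferenceSet:
    """Ordered diagnostic sites with the allele carried by each arrangement.

    Alleles are in 0/1 genotype coding (0 = VCF REF, 1 = ALT).
    """

    contig: np.ndarray
    pos: np.ndarray  # 1-based, strictly increasing per contig
    z2_allele: np.ndarray  # (S,) uint8
    z2m_allele: np.ndarray
    n_ts: int = 0
    n_ws: int = 0
    n_sw: int = 0
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.z2_allele = np.asarray(self.z2_allele, dtype=np.uint8)
        self.z2m_allele = np.asarray(self.z2m_allele, dtype=np.uint8)
        if np.any(self.z2_allele == self.z2m_allele):
            raise ValueError("arrangement alleles must differ at every site")

    def __len__(self) -> int:
        return len(self.pos)

    def to_vcf(self, path: str | Path, contig_lengths: dict[str, int]) -> None:
        """Emit fixed differences as a sites-only VCF with INFO tags
        ``Z2_ALLELE`` and ``Z2M_ALLELE``."""
        ref = self.ref if self.ref is not None else np.full(len(self), "A")
        alt = self.alt if self.alt is not None else np.full(len(self), "T")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for ctg, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={ctg},length={ln}>\n")
            fh.write(
                '##INFO=<ID=Z2_ALLELE,Number=1,Type=String,'
                'Description="Allele on the standard arrangement">\n'
                '##INFO=<ID=Z2M_ALLELE,Number=1,Type=String,'
                'Description="Allele on the rearranged arrangement">\n'
            )
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for i in range(len(self)):
                alleles = (str(ref[i]), str(alt[i]))
                info = (
                    f"Z2_ALLELE={alleles[self.z2_allele[i]]};"
                    f"Z2M_ALLELE={alleles[self.z2m_allele[i]]}"
                )
                fh.write(
                    f"{self.contig[i]}\t{self.pos[i]}\t.\t{alleles[0]}\t"
                    f"{alleles[1]}\t.\tPASS\t{info}\n"
                )


def call_fixed_differences(
    G: GenotypeMatrix,
    meta: SampleMeta,
    allow_missing: float = 0.0,
) -> FixedDifferenceSet:
    """Find sites showing the morph-consistent fixed-difference pattern.

    Requires at least one sample of each morph.  Per morph class, the
    fraction of missing genotypes at a site must not exceed
    ``allow_missing``; the pattern is then evaluated on non-missing calls.
    """
    groups = {}
    for morph in ("TS", "WS", "SW"):
        ids = [s for s in meta.samples_of_morph(morph) if s in G.samples]
        if not ids:
            raise ValueError(f"no {morph} samples available")
        groups[morph] = G.sample_index(ids)

    dose = G.alt_dosage()  # (S, n), -1 missing

    def class_ok(idx, want):
        d = dose[:, idx]
        miss = d == MISSING
        frac = miss.mean(axis=1)
        ok_missing = frac <= allow_missing
        has_data = (~miss).any(axis=1)
        if want == "het":
            good = ((d == 1) | miss).all(axis=1)
            return ok_missing & has_data & good, None
        hom0 = ((d == 0) | miss).all(axis=1)
        hom2 = ((d == 2) | miss).all(axis=1)
        allele = np.where(hom2, 1, 0).astype(np.uint8)
        return ok_missing & has_data & (hom0 | hom2), allele

    ts_ok, ts_allele = class_ok(groups["TS"], "hom")
    sw_ok, sw_allele = class_ok(groups["SW"], "hom")
    ws_ok, _ = class_ok(groups["WS"], "het")
    keep = ts_ok & sw_ok & ws_ok & (ts_allele != sw_allele)

    logger.info("call_fixed_differences: %d sites match the pattern", keep.sum())
    return FixedDifferenceSet(
        contig=np.asarray(G.contig)[keep],
        pos=G.pos[keep],
        z2_allele=ts_allele[keep],
        z2m_allele=sw_allele[keep],
        n_ts=len(groups["TS"]),
        n_ws=len(groups["WS"]),
        n_sw=len(groups["SW"]),
        ref=np.asarray(G.ref)[keep],
        alt=np.asarray(G.alt)[keep],
    )


def pattern_null_probability(
    n_ts: int, n_ws: int, n_sw: int, labelings: int = 2
) -> float:
    """Probability of the morph-consistent pattern at one site by chance.

    Under independent Hardy-Weinberg genotypes with allele frequency 0.5,
    each homozygote class has probability 1/4 per sample and the
    heterozygote class 1/2; ``labelings`` counts the admissible assignments
    of alleles to the two homozygote classes (default 2).
    """
    if labelings < 1:
        raise ValueError("labelings must be >= 1")
    if min(n_ts, n_ws, n_sw) < 0 or n_ts + n_ws + n_sw == 0:
        raise ValueError("counts must be non-negative and not all zero")
    return labelings * 0.25 ** (n_ts + n_sw) * 0.5**n_ws


@dataclass
class AssignmentResult:
    """Per-fragment chromosome-of-origin labels and a count summary."""

    labels: np.ndarray  # (F,) int8 codes LBL_*
    counts: dict[str, int]
    assignment_rate: float

    def label_names(self) -> list[str]:
        return [LABEL_NAMES[int(c)] for c in self.labels]


def assign_fragments(
    frags: FragmentSet, fd: FixedDifferenceSet
) -> AssignmentResult:
    """Label fragments by the arrangement their fixed-difference alleles match.

    A fragment overlapping at least one fixed-difference site is labelled
    with the arrangement matched by *all* its overlapped diagnostic
    alleles; mixed matches yield ``conflict``; fragments with no overlap
    are ``unassigned``.
    """
    F = frags.n_fragments
    # map fixed-difference positions onto the fragment site grid
    grid = frags.positions
    idx = np.searchsorted(grid, fd.pos)
    ok = (idx < len(grid)) & (grid[np.minimum(idx, len(grid) - 1)] == fd.pos)
    is_fd = np.zeros(len(grid), dtype=bool)
    z2_at = np.zeros(len(grid), dtype=np.uint8)
    z2m_at = np.zeros(len(grid), dtype=np.uint8)
    is_fd[idx[ok]] = True
    z2_at[idx[ok]] = fd.z2_allele[ok]
    z2m_at[idx[ok]] = fd.z2m_allele[ok]

    obs_site = frags.site_index
    obs_is_fd = is_fd[obs_site]
    counts_per_frag = np.diff(frags.offsets)
    obs_frag = np.repeat(np.arange(F), counts_per_frag)

    n_fd = np.zeros(F, dtype=np.int64)
    n_z2 = np.zeros(F, dtype=np.int64)
    n_z2m = np.zeros(F, dtype=np.int64)
    sel = obs_is_fd
    np.add.at(n_fd, obs_frag[sel], 1)
    m2 = sel & (frags.allele == z2_at[obs_site])
    np.add.at(n_z2, obs_frag[m2], 1)
    m2m = sel & (frags.allele == z2m_at[obs_site])
    np.add.at(n_z2m, obs_frag[m2m], 1)

    labels = np.full(F, LBL_CONFLICT, dtype=np.int8)
    labels[n_fd == 0] = LBL_UNASSIGNED
    labels[(n_fd > 0) & (n_z2 == n_fd)] = LBL_ZAL2
    labels[(n_fd > 0) & (n_z2m == n_fd)] = LBL_ZAL2M

    counts = {
        name: int((labels == code).sum()) for code, name in LABEL_NAMES.items()
    }
    assigned = counts["ZAL2"] + counts["ZAL2m"]
    rate = assigned / F if F else 0.0
    return AssignmentResult(labels=labels, counts=counts, assignment_rate=rate)


def assignment_rate_check(result: AssignmentResult, truth: SimTruth) -> dict:
    """Compare the fragment assignment rate with the rearrangement's share
    of the contig (the rate is bounded above by that share)."""
    a, b = truth.config.inversion
    frac = (b - a) / truth.config.contig_length
    return {
        "assignment_rate": result.assignment_rate,
        "inversion_fraction": frac,
        "rate_over_fraction": (
            result.assignment_rate / frac if frac > 0 else float("nan")
        ),
    }


@dataclass
class HaplotypeSet:
    """Haplotype alleles over a shared site grid, labelled by arrangement.

    ``alleles`` is ``(n_haps, n_sites)`` int8 with ``-1`` for missing.
    """

    contig: str
    positions: np.ndarray  # 1-based, sorted
    alleles: np.ndarray
    labels: list[str]  # per-hap arrangement class
    sources: list[str]  # per-hap source sample id

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.labels), len(self.positions)):
            raise ValueError("alleles shape mismatch")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    def subset_class(self, label: str) -> "HaplotypeSet":
        keep = [i for i, lb in enumerate(self.labels) if lb == label]
        return self.take_haps(keep)

    def take_haps(self, idx) -> "HaplotypeSet":
        idx = list(idx)
        return HaplotypeSet(
            contig=self.contig,
            positions=self.positions,
            alleles=self.alleles[idx],
            labels=[self.labels[i] for i in idx],
            sources=[self.sources[i] for i in idx],
        )

    def take_sites(self, mask: np.ndarray) -> "HaplotypeSet":
        return HaplotypeSet(
            contig=self.contig,
            positions=self.positions[mask],
            alleles=self.alleles[:, mask],
            labels=self.labels,
            sources=self.sources,
        )

    def restrict(self, start: int, end: int) -> "HaplotypeSet":
        """Sites with 0-based coordinate in [start, end)."""
        p0 = self.positions - 1
        return self.take_sites((p0 >= start) & (p0 < end))

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (non-missing haplotype count, derived-allele count)."""
        valid = self.alleles >= 0
        n = valid.sum(axis=0)
        k = np.where(valid, self.alleles, 0).sum(axis=0)
        return n, k

    @classmethod
    def from_truth(
        cls, truth: SimTruth, region: tuple[int, int] | None = None
    ) -> "HaplotypeSet":
        labels = [CLASS_NAMES[int(c)] for c in truth.arrangement]
        sources = [truth.samples[i // 2] for i in range(len(labels))]
        hs = cls(
            contig=truth.config.contig,
            positions=truth.positions,
            alleles=truth.haplotypes.astype(np.int8),
            labels=labels,
            sources=sources,
        )
        if region is not None:
            hs = hs.restrict(*region)
        return hs

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        from .io_core import write_table

        df = pd.DataFrame(
            self.alleles,
            columns=[str(p) for p in self.positions],
        )
        df.insert(0, "source", self.sources)
        df.insert(0, "class", self.labels)
        write_table(df, path)

    @classmethod
    def from_tsv(cls, path: str | Path, contig: str = "") -> "HaplotypeSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        labels = list(df["class"])
        sources = list(df["source"])
        site_cols = [c for c in df.columns if c not in ("class", "source")]
        return cls(
            contig=contig,
            positions=np.array([int(c) for c in site_cols], dtype=np.int64),
            alleles=df[site_cols].to_numpy(dtype=np.int8),
            labels=labels,
            sources=sources,
        )


def build_pseudo_haplotypes(
    G: GenotypeMatrix,
    meta: SampleMeta,
    fd: FixedDifferenceSet,
    frags: FragmentSet,
    result: AssignmentResult,
    region: tuple[int, int],
    min_support: int = 2,
) -> HaplotypeSet:
    """Arrangement-resolved pseudo-haplotypes over sites inside ``region``.

    For each WS sample the allele at a site is the majority allele among
    that sample's fragments labelled to the class and covering the site,
    requiring at least ``min_support`` observations; ties or thin support
    give missing.  TS samples contribute two standard-arrangement
    haplotypes and SW samples two rearranged ones directly from homozygous
    genotypes; their heterozygous sites are left missing on both
    haplotypes rather than randomly phased.
    """
    contig = frags.contig
    in_region = (np.asarray(G.contig) == contig) & (
        (G.pos - 1 >= region[0]) & (G.pos - 1 < region[1])
    )
    grid = G.pos[in_region]
    n_sites = len(grid)
    dose = G.alt_dosage()[in_region]

    # map fragment observations onto the region grid
    obs_pos = frags.positions[frags.site_index]
    gidx = np.searchsorted(grid, obs_pos)
    obs_ok = (gidx < n_sites) & (grid[np.minimum(gidx, n_sites - 1)] == obs_pos)
    counts_per_frag = np.diff(frags.offsets)
    obs_frag = np.repeat(np.arange(frags.n_fragments), counts_per_frag)
    obs_sample = frags.sample_index[obs_frag]
    obs_label = result.labels[obs_frag]

    alleles_rows: list[np.ndarray] = []
    labels: list[str] = []
    sources: list[str] = []
    frag_sample_ids = frags.samples

    for sample in meta.samples:
        if sample not in G.samples:
            continue
        morph = meta.morph_of(sample)
        col = G.sample_index([sample])[0]
        d = dose[:, col]
        if morph in ("TS", "SW"):
            hom = (d == 0) | (d == 2)
            hap = np.where(hom, (d == 2).astype(np.int8), MISSING).astype(
                np.int8
            )
            hap[d == MISSING] = MISSING
            cls = "ZAL2" if morph == "TS" else "ZAL2m"
            alleles_rows += [hap, hap.copy()]
            labels += [cls, cls]
            sources += [sample, sample]
            continue

        # WS: majority vote among labelled fragments, per class
        try:
            fsi = frag_sample_ids.index(sample)
        except ValueError:
            fsi = -1
        for cls_code, cls_name in ((LBL_ZAL2, "ZAL2"), (LBL_ZAL2M, "ZAL2m")):
            hap = np.full(n_sites, MISSING, dtype=np.int8)
            if fsi >= 0:
                sel = obs_ok & (obs_sample == fsi) & (obs_label == cls_code)
                if not sel.any():
                    logger.warning(
                        "sample %s: no %s-labelled fragments", sample, cls_name
                    )
                else:
                    votes1 = np.zeros(n_sites, dtype=np.int64)
                    votes0 = np.zeros(n_sites, dtype=np.int64)
                    g = gidx[sel]
                    alle = frags.allele[sel]
                    np.add.at(votes1, g[alle == 1], 1)
                    np.add.at(votes0, g[alle == 0], 1)
                    total = votes0 + votes1
                    call1 = (votes1 > votes0) & (total >= min_support)
                    call0 = (votes0 > votes1) & (total >= min_support)
                    hap[call1] = 1
                    hap[call0] = 0
            alleles_rows.append(hap)
            labels.append(cls_name)
            sources.append(sample)

    return HaplotypeSet(
        contig=contig,
        positions=grid,
        alleles=np.vstack(alleles_rows) if alleles_rows else
        np.empty((0, n_sites), dtype=np.int8),
        labels=labels,
        sources=sources,
    )
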