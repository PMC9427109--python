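"""Unit tests for the windowed statistics, with independent brute-force
oracles frozen in-line (pairwise Hamming sums, direct estimator formulas,
exhaustive codon enumeration)."""

import itertools

import numpy as np
import pytest

from sgscan.io_core import Window
from sgscan.phasing import FixedDifferenceSet, HaplotypeSet
from sgscan.popgen import (
    chromosome_count_ne_ratio,
    dxy,
    fixed_diff_density,
    folded_sfs,
    fst,
    ld_decay,
    ne_ratio,
    nei_gojobori_codon_sites,
    nucleotide_diversity,
    pairwise_r2,
    pin_pis,
    tajimas_d,
    window_stat_table,
)


def hapset(alleles, positions=None, label="ZAL2"):
    alleles = np.asarray(alleles, dtype=np.int8)
    n, s = alleles.shape
    positions = np.asarray(
        positions if positions is not None else range(10, 10 * s + 10, 10)
    )
    return HaplotypeSet(
        contig="c",
        positions=positions,
        alleles=alleles,
        labels=[label] * n,
        sources=[f"h{i}" for i in range(n)],
    )


def win(start, end, l_acc=None):
    return Window("c", start, end, l_acc=l_acc if l_acc is not None else end - start)


# independent oracles -------------------------------------------------------


def pi_oracle(alleles, l_acc):
    """Mean pairwise Hamming distance over all haplotype pairs / L."""
    n = len(alleles)
    total = 0.0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += np.sum(alleles[i] != alleles[j])
        pairs += 1
    return total / pairs / l_acc


def dxy_oracle(a1, a2, l_acc):
    total = sum(
        np.sum(x != y) for x in a1 for y in a2
    )
    return total / (len(a1) * len(a2)) / l_acc


def hudson_fst_oracle(a1, a2):
    num = den = 0.0
    for s in range(a1.shape[1]):
        p1 = a1[:, s].mean()
        p2 = a2[:, s].mean()
        n1, n2 = len(a1), len(a2)
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    return num / den if den > 0 else np.nan


def tajima_oracle(alleles):
    n, s_total = alleles.shape
    k = alleles.sum(axis=0)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    pi = 0.0
    for i, j in itertools.combinations(range(n), 2):
        pi += np.sum(alleles[i] != alleles[j])
    pi /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def r2_oracle(x, y):
    pab = np.mean(x & y)
    pa, pb = x.mean(), y.mean()
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestPi:
    def test_monomorphic_zero(self):
        H = hapset(np.zeros((4, 3)))
        assert nucleotide_diversity(H, [win(0, 100)])[0] == 0

    def test_two_two_split(self):
        H = hapset([[0], [0], [1], [1]])
        got = nucleotide_diversity(H, [win(0, 100, l_acc=100)])[0]
        assert got == pytest.approx(0.6667 / 100, rel=1e-3)

    def test_mask_denominator_scaling(self):
        H = hapset([[0], [1]])
        full = nucleotide_diversity(H, [win(0, 100, l_acc=100)])[0]
        half = nucleotide_diversity(H, [win(0, 100, l_acc=50)])[0]
        assert half == pytest.approx(2 * full)

    def test_zero_accessible_is_nan(self):
        H = hapset([[0], [1]])
        assert np.isnan(nucleotide_diversity(H, [win(0, 100, l_acc=0)])[0])

    def test_matches_genotype_path(self, rng):
        from sgscan.io_core import GenotypeMatrix

        alleles = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
        H = hapset(alleles, positions=np.arange(1, 31))
        g = alleles.reshape(5, 2, 30).transpose(2, 0, 1)
        G = GenotypeMatrix(
            contigs={"c": 100},
            contig=np.full(30, "c", dtype=object),
            pos=np.arange(1, 31),
            ref=np.full(30, "A", dtype=object),
            alt=np.full(30, "T", dtype=object),
            genotypes=np.ascontiguousarray(g),
            mean_depth=np.full(30, 30.0),
            samples=[f"s{i}" for i in range(5)],
        )
        w = [win(0, 100)]
        assert nucleotide_diversity(H, w)[0] == pytest.approx(
            nucleotide_diversity(G, w)[0], rel=1e-12
        )

    def test_oracle_random_instances(self, rng):
        # unbiased estimator == mean pairwise Hamming / L on complete data
        for _ in range(50):
            n = rng.integers(2, 8)
            s = rng.integers(1, 20)
            alleles = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            H = hapset(alleles, positions=np.arange(1, s + 1))
            got = nucleotide_diversity(H, [win(0, 100)])[0]
            assert got == pytest.approx(pi_oracle(alleles, 100), rel=1e-10, abs=1e-15)


class TestDxy:
    def test_identical_fixed_pops(self):
        a = np.ones((3, 2), dtype=np.int8)
        assert dxy(hapset(a), hapset(a), [win(0, 50)])[0] == 0

    def test_reciprocally_fixed(self):
        got = dxy(
            hapset([[0], [0]]), hapset([[1], [1]]), [win(0, 100, l_acc=50)]
        )[0]
        assert got == pytest.approx(0.02)

    def test_quarter_three_quarter(self):
        p1 = hapset([[0], [0], [0], [1]])
        p2 = hapset([[1], [1], [1], [0]])
        got = dxy(p1, p2, [win(0, 100, l_acc=1)])[0]
        assert got == pytest.approx(0.625)

    def test_oracle_random_instances(self, rng):
        for _ in range(50):
            s = rng.integers(1, 15)
            a1 = rng.integers(0, 2, size=(rng.integers(2, 6), s)).astype(np.int8)
            a2 = rng.integers(0, 2, size=(rng.integers(2, 6), s)).astype(np.int8)
            got = dxy(
                hapset(a1, positions=np.arange(1, s + 1)),
                hapset(a2, positions=np.arange(1, s + 1)),
                [win(0, 40)],
            )[0]
            assert got == pytest.approx(dxy_oracle(a1, a2, 40), rel=1e-10, abs=1e-15)

    def test_dxy_bounds_pi_for_fixed_classes(self):
        # reciprocally monophyletic fixed classes: dxy >= within-pi
        a1 = np.array([[0, 0, 1], [0, 1, 0]], dtype=np.int8)
        a2 = np.array([[1, 0, 0] , [1, 1, 1]], dtype=np.int8)
        a1[:, 0] = 0
        a2[:, 0] = 1  # class-diagnostic site
        w = [win(0, 40)]
        d = dxy(hapset(a1), hapset(a2), w)[0]
        assert d >= nucleotide_diversity(hapset(a1), w)[0]
        assert d >= nucleotide_diversity(hapset(a2), w)[0]


class TestFst:
    def test_equal_freqs_near_zero(self):
        # estimator has an O(1/n) negative bias term; vanishes for large n
        a = np.zeros((2000, 4), dtype=np.int8)
        a[:1000] = 1
        got = fst(hapset(a), hapset(a.copy()), [win(0, 100)])[0]
        assert abs(got) < 1e-3

    def test_reciprocally_fixed_is_one(self):
        got = fst(
            hapset(np.zeros((5, 2), dtype=np.int8)),
            hapset(np.ones((5, 2), dtype=np.int8)),
            [win(0, 100)],
        )[0]
        assert got == pytest.approx(1.0)

    def test_spec_example_point_two_point_eight(self):
        a1 = np.zeros((10, 1), dtype=np.int8)
        a1[:2] = 1
        a2 = np.zeros((10, 1), dtype=np.int8)
        a2[:8] = 1
        got = fst(hapset(a1), hapset(a2), [win(0, 100)])[0]
        assert got == pytest.approx((0.36 - 2 * 0.16 / 9) / 0.68, rel=1e-10)

    def test_oracle_random_instances(self, rng):
        for _ in range(50):
            s = rng.integers(1, 15)
            a1 = rng.integers(0, 2, size=(rng.integers(3, 8), s)).astype(np.int8)
            a2 = rng.integers(0, 2, size=(rng.integers(3, 8), s)).astype(np.int8)
            got = fst(
                hapset(a1, positions=np.arange(1, s + 1)),
                hapset(a2, positions=np.arange(1, s + 1)),
                [win(0, 40)],
            )[0]
            want = hudson_fst_oracle(a1, a2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_hudson_identity_on_balanced_design(self, rng):
        # Hudson F_ST == 1 - pi_within/pi_between with the matching
        # definitions of within/between (per-site averages)
        a1 = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        a2 = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        pos = np.arange(1, 13)
        got = fst(hapset(a1, positions=pos), hapset(a2, positions=pos), [win(0, 40)])[0]
        num = den = 0.0
        for s in range(12):
            p1, p2 = a1[:, s].mean(), a2[:, s].mean()
            # within = sum of per-pop unbiased heterozygosities pq*n/(n-1)
            hw = p1 * (1 - p1) * 8 / 7 + p2 * (1 - p2) * 8 / 7
            hb = p1 * (1 - p2) + p2 * (1 - p1)
            num += hw
            den += hb
        assert got == pytest.approx(1 - num / den, rel=1e-10)

    def test_wc_estimator_available(self, rng):
        a1 = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
        a2 = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
        got = fst(hapset(a1), hapset(a2), [win(0, 40)], estimator="wc")[0]
        assert np.isfinite(got)


class TestTajimasD:
    def test_no_segregating_sites_nan(self):
        H = hapset(np.zeros((4, 2)))
        assert np.isnan(tajimas_d(H, [win(0, 100)])[0])

    def test_three_singletons_n4(self):
        a = np.zeros((4, 3), dtype=np.int8)
        a[0, 0] = a[1, 1] = a[2, 2] = 1
        got = tajimas_d(hapset(a), [win(0, 100)])[0]
        assert got == pytest.approx(-0.754, abs=5e-4)

    def test_oracle_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(4, 10)
            s = rng.integers(1, 20)
            a = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            got = tajimas_d(hapset(a, positions=np.arange(1, s + 1)), [win(0, 40)])[0]
            want = tajima_oracle(a)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)


class TestFoldedSfs:
    def test_example_with_and_without_singletons(self):
        # n=6, minor counts {1,1,2,3}
        a = np.zeros((6, 4), dtype=np.int8)
        a[0, 0] = 1
        a[1, 1] = 1
        a[:2, 2] = 1
        a[:3, 3] = 1
        s_on = folded_sfs(hapset(a), exclude_singletons=True)
        assert s_on.counts.tolist() == [0, 1, 1]
        s_off = folded_sfs(hapset(a), exclude_singletons=False)
        assert s_off.counts.tolist() == [2, 1, 1]

    def test_total_equals_segregating_sites(self, rng):
        a = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        k = a.sum(axis=0)
        expected = int(((k > 0) & (k < 8)).sum())
        assert folded_sfs(hapset(a)).total() == expected


class TestNeiGojobori:
    def test_ttt_codon(self):
        n, s = nei_gojobori_codon_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_exhaustive_enumeration_all_sense_codons(self):
        from Bio.Seq import Seq

        stops = {"TAA", "TAG", "TGA"}
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            if codon in stops:
                continue
            aa = str(Seq(codon).translate())
            syn = 0.0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    if str(Seq(mut).translate()) == aa:
                        syn += 1 / 3
            got_n, got_s = nei_gojobori_codon_sites(codon)
            assert got_s == pytest.approx(syn, rel=1e-10)
            assert got_n + got_s == pytest.approx(3.0)

    def test_pin_pis_on_constructed_gene(self):
        # gene ATG AAA TTT GGC TAA-less: 4 codons, variants at known sites
        from sgscan.io_core import CDSAnnotation, CDSGene

        ref = {"c": "ATGAAATTTGGC"}
        gene = CDSGene("g1", "t1", "c", "+", [(0, 12)])
        ann = CDSAnnotation([gene], ref)
        # variant at pos 9 (0-based 8): TTT -> TTC (synonymous, third pos)
        # variant at pos 4 (0-based 3): AAA -> CAA (nonsynonymous, first pos)
        positions = np.array([4, 9])
        alleles_ref = np.array(["A", "T"], dtype=object)
        alleles_alt = np.array(["C", "C"], dtype=object)
        a = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
        H = hapset(a, positions=positions)
        cd = pin_pis(H, ann, (alleles_ref, alleles_alt), gene_window=1, gene_step=1)
        row = cd.table.iloc[0]
        assert row["n_sites"] + row["s_sites"] == pytest.approx(12.0)
        pi_site = 4 / 3 * 2 * 0.5 * 0.5
        assert row["pi_n"] == pytest.approx(pi_site / row["n_sites"], rel=1e-10)
        assert row["pi_s"] == pytest.approx(pi_site / row["s_sites"], rel=1e-10)

    def test_fourfold_third_position_only(self):
        from sgscan.io_core import CDSAnnotation, CDSGene

        ref = {"c": "ATGGGAGGGCCC"}
        gene = CDSGene("g1", "t1", "c", "+", [(0, 12)])
        ann = CDSAnnotation([gene], ref)
        # GGA -> GGT at third position (4-fold degenerate): synonymous only
        H = hapset(np.array([[0], [1]], dtype=np.int8), positions=np.array([6]))
        cd = pin_pis(
            H, ann, (np.array(["A"], dtype=object), np.array(["T"], dtype=object)),
            gene_window=1, gene_step=1,
        )
        assert cd.table.iloc[0]["pi_n"] == 0.0
        assert cd.table.iloc[0]["pi_s"] > 0

    def test_internal_stop_gene_skipped(self):
        from sgscan.io_core import CDSAnnotation, CDSGene

        ref = {"c": "ATGTAAGGGCCCATGAAATTTGGC"}
        bad = CDSGene("bad", "tb", "c", "+", [(0, 12)])
        good = CDSGene("good", "tg", "c", "+", [(12, 24)])
        ann = CDSAnnotation([bad, good], ref)
        H = hapset(np.array([[0], [1]], dtype=np.int8), positions=np.array([21]))
        cd = pin_pis(
            H, ann, (np.array(["T"], dtype=object), np.array(["C"], dtype=object)),
            gene_window=1, gene_step=1,
        )
        assert cd.table["gene"].tolist() == ["good"]


class TestLd:
    def test_perfect_ld(self):
        H = hapset([[1, 1], [1, 1], [0, 0], [0, 0]])
        df = ld_decay(H, max_dist=100, bin_width=100)
        assert df["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_zero_ld(self):
        H = hapset([[1, 1], [1, 0], [0, 1], [0, 0]])
        df = ld_decay(H, max_dist=100, bin_width=100)
        assert df["mean_r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_third(self):
        # haplotypes {AB, Ab, AB, ab}
        H = hapset([[1, 1], [1, 0], [1, 1], [0, 0]])
        df = ld_decay(H, max_dist=100, bin_width=100)
        assert df["mean_r2"].iloc[0] == pytest.approx(1 / 3, rel=1e-10)

    def test_oracle_random_pairs(self, rng):
        for _ in range(50):
            n = rng.integers(4, 10)
            x = rng.integers(0, 2, size=n)
            y = rng.integers(0, 2, size=n)
            if x.var() == 0 or y.var() == 0:
                continue
            got = pairwise_r2(x.astype(float), y.astype(float))
            assert got == pytest.approx(r2_oracle(x, y), rel=1e-10, abs=1e-15)


class TestNeRatio:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        res = ne_ratio(x, x.copy())
        assert res["ratio"] == pytest.approx(1.0)

    def test_zero_denominator(self):
        res = ne_ratio(np.array([1.0]), np.array([0.0]))
        assert np.isnan(res["ratio"])

    def test_chromosome_count_expectation(self):
        # 50% heterokaryotypes + 50% standard homozygotes
        assert round(chromosome_count_ne_ratio(50, 50), 2) == 0.33

    def test_neutral_simulation_ratio(self, neutral_batch):
        from sgscan.io_core import AccessibilityMask, make_windows

        cfg = neutral_batch[0].config
        mask = AccessibilityMask.full({cfg.contig: cfg.contig_length})
        a, b = cfg.inversion
        wins = [
            w
            for w in make_windows({cfg.contig: cfg.contig_length}, 25_000, mask=mask)
            if w.start >= a and w.end <= b
        ]
        # one genealogy per replicate inside the non-recombining span, so
        # replicates (not windows) are the honest bootstrap blocks
        pim, piz = [], []
        for truth in neutral_batch:
            H = HaplotypeSet.from_truth(truth)
            pim.append(
                np.nanmean(nucleotide_diversity(H.subset_class("ZAL2m"), wins, mask))
            )
            piz.append(
                np.nanmean(nucleotide_diversity(H.subset_class("ZAL2"), wins, mask))
            )
        res = ne_ratio(
            np.array(pim), np.array(piz), {"reps": 2000, "seed": 0}
        )
        lo, hi = res["ci"]
        assert lo <= 1 / 3 <= hi


class TestWindowStatTable:
    def test_columns_and_dispatch(self, rng):
        a1 = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
        a2 = rng.integers(0, 2, size=(4, 20)).astype(np.int8)
        H1 = hapset(a1, positions=np.arange(5, 205, 10))
        H2 = hapset(a2, positions=np.arange(5, 205, 10))
        fd = FixedDifferenceSet(
            contig=np.array(["c"], dtype=object),
            pos=np.array([55]),
            z2_allele=np.array([0]),
            z2m_allele=np.array([1]),
        )
        df = window_stat_table(H1, H2, fd, [win(0, 100), win(100, 200)])
        for col in ("pi", "tajimas_d", "dxy", "fst", "d_f", "l_acc", "n_snps"):
            assert col in df.columns
        assert df["d_f"].iloc[0] == pytest.approx(1 / 100)
        assert df["d_f"].iloc[1] == 0

    def test_fixed_diff_density_counting(self):
        fd = FixedDifferenceSet(
            contig=np.full(5, "c", dtype=object),
            pos=np.array([10, 20, 30, 40, 150]),
            z2_allele=np.zeros(5, dtype=np.uint8),
            z2m_allele=np.ones(5, dtype=np.uint8),
        )
        wins = [win(0, 100), win(100, 200)]
        d = fixed_diff_density(fd, wins)
        assert d[0] == pytest.approx(4 / 100)
        total = sum(
            dd * w.l_acc for dd, w in zip(fixed_diff_density(fd, wins), wins)
        )
        assert total == pytest.approx(5)
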