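"""Forward Wright-Fisher simulation of a balanced two-arrangement supergene.

The simulated population mimics the study system: two chromosomal
arrangement classes (standard ``ZAL2`` and rearranged ``ZAL2m``) segregate
in a diploid population with near-obligate disassortative mating between
heterokaryotypes (WS) and standard homokaryotypes (TS), recombination
suppressed inside the rearranged span in heterokaryotypes, finite-sites
neutral mutation, optional selective sweeps on either arrangement, and an
optional negative-frequency-dependent (NFDS) balanced locus inside the
rearrangement that maintains two divergent haplotype backbones.

Generations are discrete and non-overlapping; selection is applied at
parent sampling (viability selection), multiplicatively across loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import AccessibilityMask, CDSGene, SampleMeta, write_table

ZAL2, ZAL2M = 0, 1
CLASS_NAMES = {ZAL2: "ZAL2", ZAL2M: "ZAL2m"}
CLASS_CODES = {"ZAL2": ZAL2, "ZAL2m": ZAL2M}

_MORPH_OF_PAIR = {(0, 0): "TS", (0, 1): "WS", (1, 0): "WS", (1, 1): "SW"}


@dataclass
class SweepSpec:
    """A positively selected allele arising on one arrangement class."""

    position: int  # 1-based
    arrangement: str = "ZAL2m"
    s: float = 0.1
    start_gen: int = 0
    n_init_copies: int = 2
    reintroduce: bool = True  # re-seed the allele if lost by drift


@dataclass
class BalancedSpec:
    """An NFDS-balanced locus inside the rearrangement.

    At generation zero the rearranged haplotypes are split into two
    backbone groups differing at ``n_backbone`` sites inside ``region``;
    the group-defining marker allele is held near frequency 0.5 among
    rearranged chromosomes by negative frequency dependence with
    coefficient ``s_b``.
    """

    region: tuple[int, int]  # 0-based half-open, inside the inversion
    s_b: float = 0.5
    n_backbone: int = 40
    split: float = 0.5  # initial fraction of rearranged haps in group 2


@dataclass
class SimConfig:
    n_individuals: int = 500
    contig_length: int = 1_000_000
    contig: str = "chr2"
    inversion: tuple[int, int] = (200_000, 800_000)  # 0-based half-open
    mu: float = 2.5e-7
    r: float = 2.5e-7
    c: float = 0.0  # heterokaryotype recombination factor inside inversion
    mating_fidelity: float = 0.99  # fraction of WS x TS pairings
    generations: int = 2000
    n_init_fixed_diffs: int = 300
    init_standing_variation: bool = True
    init_theta_scale: float = 1.0  # scales initial standing variation
    sweep: SweepSpec | None = None
    balanced: BalancedSpec | None = None
    n_genes: int = 40
    ensure_sw: int = 1  # guarantee this many SW individuals in the output
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.inversion
        if not (0 <= a < b <= self.contig_length):
            raise ValueError("inversion span must satisfy 0 <= a < b <= length")
        if not (0.0 <= self.mating_fidelity <= 1.0):
            raise ValueError("mating fidelity must be in [0, 1]")
        if not (0.0 <= self.c <= 1.0):
            raise ValueError("suppression factor must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "inversion" in raw:
            raw["inversion"] = tuple(raw["inversion"])
        if raw.get("sweep"):
            raw["sweep"] = SweepSpec(**raw["sweep"])
        if raw.get("balanced"):
            bal = dict(raw["balanced"])
            bal["region"] = tuple(bal["region"])
            raw["balanced"] = BalancedSpec(**bal)
        return cls(**raw)


class ArrangementLostError(RuntimeError):
    def __init__(self, arrangement: str, generation: int):
        self.generation = generation
        super().__init__(
            f"arrangement {arrangement} lost at generation {generation}"
        )


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate_population`."""

    config: SimConfig
    positions: np.ndarray  # (S,) 1-based, sorted
    haplotypes: np.ndarray  # (2N, S) uint8
    arrangement: np.ndarray  # (2N,) 0=ZAL2, 1=ZAL2m
    samples: list[str]
    morphs: list[str]
    sweep_positions: list[int]
    balanced_position: int | None
    haplogroup: np.ndarray | None  # per-hap group label (rearranged only), -1 else
    arrangement_freq_traj: np.ndarray  # per-generation ZAL2m frequency

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def morph_of_pair(self, i: int) -> str:
        a = self.arrangement
        return _MORPH_OF_PAIR[(int(a[2 * i]), int(a[2 * i + 1]))]

    def fixed_difference_positions(self) -> np.ndarray:
        """1-based positions fixed for different alleles between classes."""
        h2 = self.haplotypes[self.arrangement == ZAL2]
        hm = self.haplotypes[self.arrangement == ZAL2M]
        if len(h2) == 0 or len(hm) == 0:
            return np.array([], dtype=np.int64)
        mono2 = (h2 == h2[0]).all(axis=0)
        monom = (hm == hm[0]).all(axis=0)
        fixed = mono2 & monom & (h2[0] != hm[0])
        return self.positions[fixed]

    def sample_meta(self, rng: np.random.Generator | None = None) -> SampleMeta:
        import pandas as pd

        rng = rng or np.random.default_rng(self.config.seed + 7)
        return SampleMeta(
            pd.DataFrame(
                {
                    "sample": self.samples,
                    "morph": self.morphs,
                    "sex": rng.choice(["M", "F"], size=len(self.samples)),
                    "location": "SIM",
                }
            )
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "positions": self.positions.tolist(),
            "haplotypes": ["".join(map(str, row)) for row in self.haplotypes],
            "arrangement": self.arrangement.tolist(),
            "samples": self.samples,
            "morphs": self.morphs,
            "sweep_positions": self.sweep_positions,
            "balanced_position": self.balanced_position,
            "haplogroup": (
                self.haplogroup.tolist() if self.haplogroup is not None else None
            ),
            "arrangement_freq_traj": self.arrangement_freq_traj.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["inversion"] = list(cfg.inversion)
    return d


# ---------------------------------------------------------------------------
# population state helpers
# ---------------------------------------------------------------------------


def _neutral_sfs_counts(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k derived-allele counts from the neutral SFS P(i) ~ 1/i."""
    i = np.arange(1, n)
    p = (1.0 / i) / (1.0 / i).sum()
    return rng.choice(i, size=k, p=p)


def _draw_positions(
    k: int, lo: int, hi: int, taken: set[int], rng: np.random.Generator
) -> np.ndarray:
    """k distinct 1-based positions in [lo, hi], avoiding ``taken``."""
    out: list[int] = []
    while len(out) < k:
        cand = rng.integers(lo, hi + 1, size=k - len(out))
        for p in cand:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
    return np.array(out, dtype=np.int64)


class _Population:
    """Mutable simulation state: site columns (unsorted during the run,
    sorted once at the end) and haplotype rows."""

    def __init__(self, haps, positions, arr):
        self.haps = haps  # (2N, S) uint8
        self.positions = positions  # (S,) int64, unique
        self.arr = arr  # (2N,) uint8
        self.taken = set(int(p) for p in positions)

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    def col_of(self, position: int) -> int | None:
        hits = np.nonzero(self.positions == position)[0]
        return int(hits[0]) if len(hits) else None

    def add_sites(self, positions: np.ndarray, carriers: list[np.ndarray]) -> None:
        """Append new columns (one per position)."""
        if len(positions) == 0:
            return
        cols = np.zeros((self.n_haps, len(positions)), dtype=np.uint8)
        for j, rows in enumerate(carriers):
            cols[rows, j] = 1
        self.positions = np.concatenate([self.positions, positions])
        self.haps = np.hstack([self.haps, cols])
        self.taken.update(int(p) for p in positions)

    def prune(self, keep_positions: set[int]) -> None:
        """Drop globally monomorphic columns (except ``keep_positions``)."""
        colsum = self.haps.sum(axis=0)
        poly = (colsum > 0) & (colsum < self.n_haps)
        if keep_positions:
            poly |= np.isin(self.positions, list(keep_positions))
        dropped = self.positions[~poly]
        self.taken.difference_update(int(p) for p in dropped)
        self.positions = self.positions[poly]
        self.haps = self.haps[:, poly]

    def sort_columns(self) -> None:
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.haps = np.ascontiguousarray(self.haps[:, order])


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


def _init_population(cfg: SimConfig, rng: np.random.Generator):
    n = cfg.n_individuals
    n_ts = n // 2
    arr = np.zeros(2 * n, dtype=np.uint8)
    # WS individuals carry the rearrangement on one haplotype
    for i in range(n_ts, n):
        arr[2 * i + rng.integers(0, 2)] = ZAL2M

    pop = _Population(
        haps=np.empty((2 * n, 0), dtype=np.uint8),
        positions=np.array([], dtype=np.int64),
        arr=arr,
    )
    a, b = cfg.inversion

    # fixed differences between the arrangement classes, inside the inversion
    if cfg.n_init_fixed_diffs:
        fd_pos = _draw_positions(
            cfg.n_init_fixed_diffs, a + 1, b, pop.taken, rng
        )
        m_rows = np.nonzero(arr == ZAL2M)[0]
        pop.add_sites(fd_pos, [m_rows] * len(fd_pos))

    # balanced backbones: two divergent groups of rearranged haplotypes
    haplogroup0 = None
    balanced_pos = None
    if cfg.balanced is not None:
        r0, r1 = cfg.balanced.region
        if not (a <= r0 < r1 <= b):
            raise ValueError("balanced region must lie inside the inversion")
        m_rows = np.nonzero(arr == ZAL2M)[0]
        n_g2 = max(1, int(round(cfg.balanced.split * len(m_rows))))
        g2 = rng.choice(m_rows, size=n_g2, replace=False)
        haplogroup0 = np.full(2 * n, -1, dtype=np.int8)
        haplogroup0[arr == ZAL2M] = 1
        haplogroup0[g2] = 2
        balanced_pos = int((r0 + r1) // 2)
        while balanced_pos in pop.taken:
            balanced_pos += 1
        bb_pos = _draw_positions(
            cfg.balanced.n_backbone, r0 + 1, r1, pop.taken, rng
        )
        pop.add_sites(
            np.append(bb_pos, balanced_pos),
            [g2] * (len(bb_pos) + 1),
        )

    # neutral standing variation near equilibrium, per arrangement class
    if cfg.init_standing_variation:
        for code in (ZAL2, ZAL2M):
            rows = np.nonzero(arr == code)[0]
            nc = len(rows)
            if nc < 2:
                continue
            # per-bp theta for a haploid class of nc chromosomes
            theta = 2.0 * nc * cfg.mu * cfg.init_theta_scale
            a1 = (1.0 / np.arange(1, nc)).sum()
            k = rng.poisson(theta * cfg.contig_length * a1)
            counts = _neutral_sfs_counts(nc, k, rng)
            positions = _draw_positions(k, 1, cfg.contig_length, pop.taken, rng)
            carriers = [
                rng.choice(rows, size=int(cnt), replace=False) for cnt in counts
            ]
            pop.add_sites(positions, carriers)

    return pop, haplogroup0, balanced_pos


def _fitness(pop: _Population, cfg: SimConfig, balanced_pos, active_sweeps):
    n = cfg.n_individuals
    w = np.ones(n)
    for spec in active_sweeps:
        col = pop.col_of(spec.position)
        if col is None:
            continue
        code = CLASS_CODES[spec.arrangement]
        carrier = (pop.haps[:, col] == 1) & (pop.arr == code)
        copies = carrier.reshape(n, 2).sum(axis=1)
        w *= (1.0 + spec.s) ** copies
    if cfg.balanced is not None and balanced_pos is not None:
        col = pop.col_of(balanced_pos)
        if col is not None:
            on_m = pop.arr == ZAL2M
            if on_m.any():
                freq = pop.haps[on_m, col].mean()
                mult = max(0.05, 1.0 + cfg.balanced.s_b * (0.5 - freq))
                copies = ((pop.haps[:, col] == 1) & on_m).reshape(n, 2).sum(axis=1)
                w *= mult**copies
    return w


def _choose_parents(pop, cfg, w, rng):
    n = cfg.n_individuals
    pairs = pop.arr.reshape(n, 2)
    morph_code = pairs.sum(axis=1)  # 0=TS, 1=WS, 2=SW
    ws = np.nonzero(morph_code == 1)[0]
    ts = np.nonzero(morph_code == 0)[0]
    p_all = w / w.sum()
    mothers = np.empty(n, dtype=np.intp)
    fathers = np.empty(n, dtype=np.intp)
    dis = rng.random(n) < cfg.mating_fidelity
    if len(ws) == 0 or len(ts) == 0:
        dis[:] = False
    n_dis = int(dis.sum())
    if n_dis:
        pw = w[ws] / w[ws].sum()
        pt = w[ts] / w[ts].sum()
        mothers[dis] = rng.choice(ws, size=n_dis, p=pw)
        fathers[dis] = rng.choice(ts, size=n_dis, p=pt)
    n_rand = n - n_dis
    if n_rand:
        idx = np.nonzero(~dis)[0]
        mothers[idx] = rng.choice(n, size=n_rand, p=p_all)
        fathers[idx] = rng.choice(n, size=n_rand, p=p_all)
        same = mothers[idx] == fathers[idx]
        while same.any():
            fathers[idx[same]] = rng.choice(n, size=int(same.sum()), p=p_all)
            same = mothers[idx] == fathers[idx]
    return mothers, fathers


def _gametes(pop: _Population, cfg: SimConfig, parents, rng):
    """One gamete per parent index; returns (haps, arrangement labels)."""
    n = len(parents)
    a, b = cfg.inversion
    L = cfg.contig_length
    inv_len = b - a
    h0 = 2 * parents
    h1 = h0 + 1
    het = pop.arr[h0] != pop.arr[h1]
    lam_out = cfg.r * (L - inv_len)
    lam_in = cfg.r * inv_len * np.where(het, cfg.c, 1.0)
    n_out = rng.poisson(lam_out, size=n)
    n_in = rng.poisson(lam_in)
    start = rng.integers(0, 2, size=n)
    nb = n_out + n_in

    out = np.empty((n, pop.haps.shape[1]), dtype=np.uint8)
    out_arr = np.empty(n, dtype=np.uint8)
    simple = nb == 0
    pick = np.where(start == 0, h0, h1)
    out[simple] = pop.haps[pick[simple]]
    out_arr[simple] = pop.arr[pick[simple]]

    slow = np.nonzero(~simple)[0]
    if len(slow):
        pos_mid = pop.positions.astype(float) - 0.5  # 0-based site midpoints
        M = len(slow)
        no = n_out[slow]
        ni = n_in[slow]
        kmax = int((no + ni).max())
        col = np.arange(kmax)[None, :]
        u = rng.random((M, kmax))
        span_out = float(a + (L - b))
        x_out = u * span_out
        x_out = np.where(x_out < a, x_out, x_out + inv_len)
        x_in = a + u * inv_len
        is_out = col < no[:, None]
        is_in = (col >= no[:, None]) & (col < (no + ni)[:, None])
        bk = np.where(is_out, x_out, np.where(is_in, x_in, np.inf))
        # crossover parity per site: count breakpoints left of each site
        cnt = np.zeros((M, len(pos_mid)), dtype=np.int8)
        for j in range(kmax):
            cnt += pos_mid[None, :] > bk[:, [j]]
        from_h1 = (cnt + start[slow][:, None]) % 2 == 1
        out[slow] = np.where(from_h1, pop.haps[h1[slow]], pop.haps[h0[slow]])
        # arrangement identity travels with whoever contributes the
        # inversion start
        pa = ((bk < a + 0.5).sum(axis=1) + start[slow]) % 2
        out_arr[slow] = np.where(pa == 1, pop.arr[h1[slow]], pop.arr[h0[slow]])
    return out, out_arr


def simulate_population(cfg: SimConfig) -> SimTruth:
    """Run the forward simulation and return ground truth.

    Raises :class:`ArrangementLostError` if either arrangement class goes
    extinct, reporting the generation index.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    pop, _, balanced_pos = _init_population(cfg, rng)

    keep_positions: set[int] = set()
    if cfg.sweep is not None:
        keep_positions.add(cfg.sweep.position)
    if balanced_pos is not None:
        keep_positions.add(balanced_pos)

    sweep_active = False
    traj = np.empty(cfg.generations, dtype=float)
    exp_muts = 2 * n * cfg.mu * cfg.contig_length

    for gen in range(cfg.generations):
        traj[gen] = (pop.arr == ZAL2M).mean()
        for code in (ZAL2, ZAL2M):
            if not (pop.arr == code).any():
                raise ArrangementLostError(CLASS_NAMES[code], gen)

        # sweep introduction / drift-loss reintroduction
        if cfg.sweep is not None and gen >= cfg.sweep.start_gen:
            col = pop.col_of(cfg.sweep.position)
            code = CLASS_CODES[cfg.sweep.arrangement]
            lost = col is None or not (
                (pop.haps[:, col] == 1) & (pop.arr == code)
            ).any()
            if lost and (not sweep_active or cfg.sweep.reintroduce):
                rows = np.nonzero(pop.arr == code)[0]
                chosen = rng.choice(
                    rows,
                    size=min(cfg.sweep.n_init_copies, len(rows)),
                    replace=False,
                )
                if col is None:
                    pop.add_sites(
                        np.array([cfg.sweep.position], dtype=np.int64),
                        [chosen],
                    )
                else:
                    pop.haps[chosen, col] = 1
                sweep_active = True

        active = (
            [cfg.sweep]
            if cfg.sweep is not None and gen >= cfg.sweep.start_gen
            else []
        )
        w = _fitness(pop, cfg, balanced_pos, active)
        mothers, fathers = _choose_parents(pop, cfg, w, rng)

        g1, a1 = _gametes(pop, cfg, mothers, rng)
        g2, a2 = _gametes(pop, cfg, fathers, rng)
        haps = np.empty((2 * n, pop.haps.shape[1]), dtype=np.uint8)
        haps[0::2] = g1
        haps[1::2] = g2
        arr = np.empty(2 * n, dtype=np.uint8)
        arr[0::2] = a1
        arr[1::2] = a2
        pop.haps = haps
        pop.arr = arr

        # finite-sites mutation; colliding draws are re-drawn
        k = rng.poisson(exp_muts)
        if k:
            positions = _draw_positions(k, 1, cfg.contig_length, pop.taken, rng)
            rows = rng.integers(0, 2 * n, size=k)
            pop.add_sites(positions, [np.array([r]) for r in rows])

        if gen % 10 == 9:
            pop.prune(keep_positions)

    pop.prune(keep_positions)
    pop.sort_columns()

    samples = [f"S{i:04d}" for i in range(n)]
    morphs = [
        _MORPH_OF_PAIR[(int(pop.arr[2 * i]), int(pop.arr[2 * i + 1]))]
        for i in range(n)
    ]

    # Guarantee rare rearranged homozygotes in the emitted cohort by
    # resampling extra SW individuals from the standing pool of rearranged
    # haplotypes (mirrors deliberate sampling of rare homozygous birds).
    n_sw = morphs.count("SW")
    if cfg.ensure_sw > n_sw:
        m_rows = np.nonzero(pop.arr == ZAL2M)[0]
        for j in range(cfg.ensure_sw - n_sw):
            if len(m_rows) < 2:
                break
            picked = rng.choice(m_rows, size=2, replace=False)
            pop.haps = np.vstack([pop.haps, pop.haps[picked]])
            pop.arr = np.append(pop.arr, pop.arr[picked])
            samples.append(f"SWX{j:02d}")
            morphs.append("SW")

    haplogroup = None
    if balanced_pos is not None:
        col = pop.col_of(balanced_pos)
        haplogroup = np.full(len(pop.arr), -1, dtype=np.int8)
        if col is not None:
            on_m = pop.arr == ZAL2M
            haplogroup[on_m] = np.where(pop.haps[on_m, col] == 1, 2, 1)

    return SimTruth(
        config=cfg,
        positions=pop.positions,
        haplotypes=pop.haps,
        arrangement=pop.arr,
        samples=samples,
        morphs=morphs,
        sweep_positions=(
            [cfg.sweep.position] if cfg.sweep is not None else []
        ),
        balanced_position=balanced_pos,
        haplogroup=haplogroup,
        arrangement_freq_traj=traj,
    )


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def emit_vcf(
    truth: SimTruth,
    vcf_path: str | Path,
    meta_path: str | Path | None = None,
    bed_path: str | Path | None = None,
    inaccessible_fraction: float = 0.0,
    gap_size: int = 1000,
    mean_depth: float = 30.0,
    reference: dict[str, str] | None = None,
    seed: int | None = None,
) -> tuple[SampleMeta, AccessibilityMask]:
    """Write unphased genotypes as VCF plus sample metadata and a mask.

    The accessibility mask is the whole contig minus optional random gaps
    (``inaccessible_fraction`` of the contig in ``gap_size`` chunks).
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    L = cfg.contig_length
    ctg = cfg.contig
    n = truth.n_individuals

    if reference is not None:
        refseq = reference[ctg]
        ref_alleles = np.array([refseq[p - 1] for p in truth.positions])
    else:
        ref_alleles = _BASES[rng.integers(0, 4, size=len(truth.positions))]
    # alt differs from ref at every site
    shift = rng.integers(1, 4, size=len(truth.positions))
    base_idx = np.searchsorted(_BASES, np.char.upper(ref_alleles.astype(str)))
    alt_alleles = _BASES[(base_idx + shift) % 4]

    depth = rng.poisson(mean_depth, size=(len(truth.positions), n))

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ctg},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(truth.samples)
            + "\n"
        )
        hap_pairs = truth.haplotypes.reshape(n, 2, -1)
        for j, pos in enumerate(truth.positions):
            a0 = hap_pairs[:, 0, j]
            a1 = hap_pairs[:, 1, j]
            lo = np.minimum(a0, a1)
            hi = np.maximum(a0, a1)
            gts = [
                f"{lo[i]}/{hi[i]}:{depth[j, i]}" for i in range(n)
            ]
            fh.write(
                f"{ctg}\t{pos}\t.\t{ref_alleles[j]}\t{alt_alleles[j]}\t.\t"
                "PASS\t.\tGT:DP\t" + "\t".join(gts) + "\n"
            )

    meta = truth.sample_meta()
    if meta_path is not None:
        meta.to_tsv(meta_path)

    if inaccessible_fraction > 0:
        n_gaps = int(round(inaccessible_fraction * L / gap_size))
        starts = rng.choice(L // gap_size, size=n_gaps, replace=False) * gap_size
        gaps = np.sort(starts)
        acc = []
        cur = 0
        for g in gaps:
            if g > cur:
                acc.append((cur, g))
            cur = max(cur, g + gap_size)
        if cur < L:
            acc.append((cur, L))
        mask = AccessibilityMask({ctg: np.array(acc, dtype=np.int64)})
    else:
        mask = AccessibilityMask.full({ctg: L})
    if bed_path is not None:
        mask.to_bed(bed_path)
    return meta, mask


@dataclass
class FragmentSet:
    """Read-pair surrogates: per-fragment (position, allele) observations.

    Stored flat: fragment ``k`` covers SNP observations
    ``offsets[k]:offsets[k+1]`` in ``site_index``/``allele``.
    ``source_class`` retains the true arrangement of the source haplotype
    for recovery scoring.
    """

    samples: list[str]
    contig: str
    sample_index: np.ndarray  # (F,)
    start: np.ndarray  # (F,) 0-based
    end: np.ndarray  # (F,)
    offsets: np.ndarray  # (F+1,)
    site_index: np.ndarray  # (K,) indices into `positions`
    allele: np.ndarray  # (K,) uint8
    positions: np.ndarray  # site grid, 1-based
    error_rate: float
    source_class: np.ndarray  # (F,) uint8 truth label

    @property
    def n_fragments(self) -> int:
        return len(self.start)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        obs = []
        for k in range(self.n_fragments):
            lo, hi = self.offsets[k], self.offsets[k + 1]
            obs.append(
                ",".join(
                    f"{self.positions[self.site_index[i]]}:{self.allele[i]}"
                    for i in range(lo, hi)
                )
            )
        df = pd.DataFrame(
            {
                "sample": [self.samples[i] for i in self.sample_index],
                "contig": self.contig,
                "start": self.start,
                "end": self.end,
                "observations": obs,
                "source_class": [
                    CLASS_NAMES[int(c)] for c in self.source_class
                ],
            }
        )
        write_table(df, path)

    @classmethod
    def from_tsv(cls, path: str | Path, error_rate: float = 0.0) -> "FragmentSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        samples = list(dict.fromkeys(df["sample"]))
        sample_idx = {s: i for i, s in enumerate(samples)}
        parsed = []
        for raw in df["observations"]:
            if not raw:
                parsed.append([])
                continue
            parsed.append(
                [
                    (int(p), int(a))
                    for p, a in (tok.split(":") for tok in str(raw).split(","))
                ]
            )
        positions = np.array(
            sorted({p for frag in parsed for p, _ in frag}), dtype=np.int64
        )
        counts = np.array([len(f) for f in parsed], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        flat_pos = np.array(
            [p for frag in parsed for p, _ in frag], dtype=np.int64
        )
        allele = np.array(
            [a for frag in parsed for _, a in frag], dtype=np.uint8
        )
        site_index = np.searchsorted(positions, flat_pos)
        src = np.array(
            [CLASS_CODES.get(c, 0) for c in df["source_class"]],
            dtype=np.uint8,
        )
        return cls(
            samples=samples,
            contig=str(df["contig"].iloc[0]) if len(df) else "",
            sample_index=np.array(
                [sample_idx[s] for s in df["sample"]], dtype=np.int64
            ),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            offsets=offsets,
            site_index=site_index,
            allele=allele,
            positions=positions,
            error_rate=error_rate,
            source_class=src,
        )


def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated [0..c) ranges for each c in counts."""
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    out[starts[counts > 0]] = np.concatenate(
        [[0], 1 - counts[counts > 0][:-1]]
    )
    return np.cumsum(out)


def emit_fragments(
    truth: SimTruth,
    fragment_length: int = 1000,
    mean_depth: float = 5.0,
    error_rate: float = 0.0,
    samples: Sequence[str] | None = None,
    seed: int | None = None,
) -> FragmentSet:
    """Sample fragments uniformly from each individual's two haplotypes.

    The expected fragment count per sample is
    ``mean_depth * contig_length / fragment_length``.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    L = cfg.contig_length
    positions = truth.positions

    if samples is None:
        samples = truth.samples
    sample_ids = list(samples)
    idx_of = {s: i for i, s in enumerate(truth.samples)}

    per_sample = int(round(mean_depth * L / fragment_length))
    frag_sample = []
    frag_start = []
    frag_row = []
    for si, s in enumerate(sample_ids):
        ind = idx_of[s]
        side = rng.integers(0, 2, size=per_sample)
        starts = rng.integers(0, max(1, L - fragment_length + 1), size=per_sample)
        frag_sample.append(np.full(per_sample, si, dtype=np.int64))
        frag_start.append(starts)
        frag_row.append(2 * ind + side)

    sample_index = np.concatenate(frag_sample)
    start = np.concatenate(frag_start)
    row = np.concatenate(frag_row)
    end = start + fragment_length

    lo = np.searchsorted(positions - 1, start)
    hi = np.searchsorted(positions - 1, end)
    counts = hi - lo
    offsets = np.concatenate([[0], np.cumsum(counts)])
    site_index = np.repeat(lo, counts) + _ranges(counts)
    rows_flat = np.repeat(row, counts)
    allele = truth.haplotypes[rows_flat, site_index].astype(np.uint8)
    if error_rate > 0:
        flip = rng.random(len(allele)) < error_rate
        allele = np.where(flip, 1 - allele, allele).astype(np.uint8)

    return FragmentSet(
        samples=sample_ids,
        contig=cfg.contig,
        sample_index=sample_index,
        start=start,
        end=end,
        offsets=offsets.astype(np.int64),
        site_index=site_index.astype(np.int64),
        allele=allele,
        positions=positions,
        error_rate=error_rate,
        source_class=truth.arrangement[row].astype(np.uint8),
    )


_SENSE_CODONS = None


def _non_stop_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from itertools import product

        stops = {"TAA", "TAG", "TGA"}
        _SENSE_CODONS = [
            "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in stops
        ]
    return _SENSE_CODONS


def emit_annotation(
    cfg: SimConfig,
    gff_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    gene_length: int = 300,
    seed: int | None = None,
) -> tuple[list[CDSGene], dict[str, str]]:
    """Generate a reference sequence with non-overlapping single-CDS genes.

    Each gene is a clean ORF (start codon, no internal stops, length a
    multiple of three, terminal stop codon outside the reported CDS frame
    check).  Strands alternate.  Returns the gene models and the reference.
    """
    if cfg.n_genes < 1:
        raise ValueError("gene count must be >= 1")
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be a multiple of 3")
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    L = cfg.contig_length
    slot = L // cfg.n_genes
    if slot < gene_length + 6:
        raise ValueError("contig too small for requested gene count")

    seq = rng.integers(0, 4, size=L)
    codons = _non_stop_codons()
    genes: list[CDSGene] = []
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    for g in range(cfg.n_genes):
        margin = slot - gene_length
        start = g * slot + int(rng.integers(0, max(1, margin - 3)))
        n_codons = gene_length // 3
        body = ["ATG"] + [
            codons[rng.integers(0, len(codons))] for _ in range(n_codons - 1)
        ]
        orf = "".join(body)
        strand = "+" if g % 2 == 0 else "-"
        placed = orf if strand == "+" else "".join(
            "TGCA"["ACGT".index(ch)] for ch in reversed(orf)
        )
        for off, ch in enumerate(placed):
            seq[start + off] = base_to_idx[ch]
        genes.append(
            CDSGene(
                gene_id=f"gene{g:03d}",
                transcript_id=f"tx{g:03d}",
                contig=cfg.contig,
                strand=strand,
                cds=[(start, start + gene_length)],
            )
        )

    reference = {cfg.contig: "".join("ACGT"[i] for i in seq)}
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{cfg.contig}\n")
            s = reference[cfg.contig]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in genes:
                s0, e0 = gene.span
                fh.write(
                    f"{cfg.contig}\tsgscan\tgene\t{s0 + 1}\t{e0}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}\n"
                )
                fh.write(
                    f"{cfg.contig}\tsgscan\tmRNA\t{s0 + 1}\t{e0}\t.\t"
                    f"{gene.strand}\t.\tID={gene.transcript_id};"
                    f"Parent={gene.gene_id}\n"
                )
                for s, e in gene.cds:
                    fh.write(
                        f"{cfg.contig}\tsgscan\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t0\tID=cds-{gene.transcript_id};"
                        f"Parent={gene.transcript_id}\n"
                    )
    return genes, reference


def emit_expression(
    truth: SimTruth,
    genes: Sequence[CDSGene],
    cis_effect_map: dict[str, float],
    dispersion: float = 0.05,
    mean_depth: float = 500.0,
    seed: int | None = None,
):
    """Allele-resolved expression counts for WS samples.

    Per gene and sample, a total count is drawn from a negative binomial
    with the given mean and dispersion, then split binomially with the
    rearranged-allele proportion ``2**e / (1 + 2**e)`` where ``e`` is the
    gene's log2 allelic-ratio shift.
    """
    import pandas as pd

    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 4 if seed is None else seed)
    ws = [s for s, m in zip(truth.samples, truth.morphs) if m == "WS"]
    gene_ids = [g.gene_id for g in genes]
    unknown = set(cis_effect_map) - set(gene_ids)
    if unknown:
        raise KeyError(f"cis effects given for unknown genes: {sorted(unknown)}")

    rows = []
    for g in genes:
        e = cis_effect_map.get(g.gene_id, 0.0)
        p_m = 2.0**e / (1.0 + 2.0**e)
        for s in ws:
            if dispersion > 0:
                nb_n = 1.0 / dispersion
                nb_p = nb_n / (nb_n + mean_depth)
                total = rng.negative_binomial(nb_n, nb_p)
            else:
                total = rng.poisson(mean_depth)
            z2m = rng.binomial(total, p_m)
            rows.append(
                {
                    "gene": g.gene_id,
                    "sample": s,
                    "zal2m_count": int(z2m),
                    "zal2_count": int(total - z2m),
                }
            )
    return pd.DataFrame(rows)


def emit_all(truth: SimTruth, outdir: str | Path, **kwargs) -> dict[str, Path]:
    """Write the full fixture bundle for a simulation into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    paths = {
        "vcf": outdir / "sim.vcf",
        "meta": outdir / "samples.tsv",
        "mask": outdir / "mask.bed",
        "gff": outdir / "genes.gff3",
        "fasta": outdir / "ref.fa",
        "fragments": outdir / "fragments.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    genes, reference = emit_annotation(
        cfg, gff_path=paths["gff"], fasta_path=paths["fasta"]
    )
    emit_vcf(
        truth,
        paths["vcf"],
        meta_path=paths["meta"],
        bed_path=paths["mask"],
        reference=reference,
        **kwargs,
    )
    frags = emit_fragments(truth)
    frags.to_tsv(paths["fragments"])
    expr = emit_expression(truth, genes, {})
    write_table(expr, paths["expression"])
    truth.to_json(paths["truth"])
    return paths
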