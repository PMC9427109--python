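"""Core data model and standard-format I/O.

Conventions used throughout the package:

* VCF positions are kept 1-based; every internal interval (masks, windows,
  CDS spans, the rearrangement span) is 0-based half-open ``[start, end)``.
* Genotypes are unordered diploid allele pairs over ``{0, 1}``; missing
  calls are encoded as ``-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MORPHS = ("TS", "WS", "SW")

MISSING = -1


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMeta:
    """Per-sample metadata: morph, sex and collection location.

    ``morph`` must be one of ``TS`` (standard homokaryotype), ``WS``
    (heterokaryotype) or ``SW`` (rearranged homokaryotype).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "morph"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        bad = set(self.table["morph"]) - set(MORPHS)
        if bad:
            raise ValueError(f"unknown morph labels: {sorted(bad)}")
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMeta":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.table, path)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def morph_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample, "morph"]
        if row.empty:
            raise KeyError(f"unknown sample: {sample!r}")
        return str(row.iloc[0])

    def samples_of_morph(self, morph: str) -> list[str]:
        if morph not in MORPHS:
            raise ValueError(f"unknown morph {morph!r}")
        sel = self.table["morph"] == morph
        return list(self.table.loc[sel, "sample"])


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a cohort.

    Attributes
    ----------
    contigs:
        Mapping of contig id to contig length in bp.
    contig, pos:
        Per-site contig id and 1-based position; positions are strictly
        increasing within a contig.
    ref, alt:
        Per-site reference and alternate allele strings.
    genotypes:
        ``(n_sites, n_samples, 2)`` int8 array of allele pairs with ``-1``
        for missing calls.  The pair is unordered (unphased).
    mean_depth:
        Per-site mean read depth over non-missing samples.
    samples:
        Ordered sample ids matching the genotype columns.
    """

    contigs: dict[str, int]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    mean_depth: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_samples, 2)")
        for ctg in dict.fromkeys(self.contig):
            p = self.pos[np.asarray(self.contig) == ctg]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")
        ok = (self.genotypes >= -1) & (self.genotypes <= 1)
        if not ok.all():
            raise ValueError("genotype entries must be in {-1, 0, 1}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample: {exc.args[0]!r}") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            contigs=self.contigs,
            contig=np.asarray(self.contig)[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            genotypes=self.genotypes[index],
            mean_depth=np.asarray(self.mean_depth)[index],
            samples=self.samples,
        )

    def alt_dosage(self) -> np.ndarray:
        """Per-site per-sample alt allele count; ``-1`` where missing."""
        g = self.genotypes
        miss = (g < 0).any(axis=2)
        dose = g.clip(min=0).sum(axis=2).astype(np.int8)
        dose[miss] = MISSING
        return dose


@dataclass
class VcfFilterParams:
    """Site filters applied on read: missingness, MAF and mean depth."""

    max_missing_fraction: float = 0.0
    min_maf: float = 0.05
    min_mean_dp: float = 5.0
    max_mean_dp: float = 80.0


def read_vcf(
    path: str | Path,
    meta: SampleMeta,
    filters: VcfFilterParams | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF, applying site filters.

    Sites are dropped when any genotype fraction above
    ``max_missing_fraction`` is missing, when the minor allele frequency is
    below ``min_maf``, or when the mean per-sample depth falls outside
    ``[min_mean_dp, max_mean_dp]``.  Multiallelic and non-SNP records are
    skipped.  Pass ``filters=None`` to keep every biallelic SNP.

    The number of sites removed by each filter is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    known = set(meta.samples)
    unknown = [s for s in vcf.samples if s not in known]
    if unknown:
        raise ValueError(f"VCF sample(s) not in metadata: {unknown}")
    samples = list(vcf.samples)
    n = len(samples)

    contigs: dict[str, int] = {}
    for ctg, length in zip(vcf.seqnames, vcf.seqlens):
        contigs[ctg] = int(length)

    removed = {"multiallelic_or_non_snp": 0, "missing": 0, "maf": 0, "mean_dp": 0}
    keep_contig: list[str] = []
    keep_pos: list[int] = []
    keep_ref: list[str] = []
    keep_alt: list[str] = []
    keep_gt: list[np.ndarray] = []
    keep_dp: list[float] = []

    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            removed["multiallelic_or_non_snp"] += 1
            continue
        gts = np.array([row[:2] for row in var.genotypes], dtype=np.int8)
        miss = (gts < 0).any(axis=1)
        gts[miss] = MISSING

        dp = var.format("DP")
        if dp is None:
            mean_dp = float("nan")
        else:
            dp = dp.astype(float).ravel()[:n]
            valid = ~miss & np.isfinite(dp) & (dp >= 0)
            mean_dp = float(dp[valid].mean()) if valid.any() else float("nan")

        if filters is not None:
            if miss.mean() > filters.max_missing_fraction:
                removed["missing"] += 1
                continue
            alleles = gts[~miss]
            if alleles.size == 0:
                removed["missing"] += 1
                continue
            p = alleles.mean()
            if min(p, 1.0 - p) < filters.min_maf:
                removed["maf"] += 1
                continue
            if np.isfinite(mean_dp) and not (
                filters.min_mean_dp <= mean_dp <= filters.max_mean_dp
            ):
                removed["mean_dp"] += 1
                continue

        keep_contig.append(var.CHROM)
        keep_pos.append(var.POS)
        keep_ref.append(var.REF)
        keep_alt.append(var.ALT[0])
        keep_gt.append(gts)
        keep_dp.append(mean_dp)

    logger.info("read_vcf: kept %d sites, removed %s", len(keep_pos), removed)

    genotypes = (
        np.stack(keep_gt) if keep_gt else np.empty((0, n, 2), dtype=np.int8)
    )
    return GenotypeMatrix(
        contigs=contigs,
        contig=np.array(keep_contig, dtype=object),
        pos=np.array(keep_pos, dtype=np.int64),
        ref=np.array(keep_ref, dtype=object),
        alt=np.array(keep_alt, dtype=object),
        genotypes=genotypes,
        mean_depth=np.array(keep_dp, dtype=float),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# accessibility mask
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityMask:
    """Per-contig accessible intervals, 0-based half-open, sorted, merged."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for ctg, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            clean[ctg] = _merge_intervals(iv)
        self.intervals = clean

    @classmethod
    def from_bed(cls, path: str | Path) -> "AccessibilityMask":
        """Load a BED3 file; overlapping intervals are merged with a warning."""
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                ctg, start, end = line.split("\t")[:3]
                raw.setdefault(ctg, []).append((int(start), int(end)))
        intervals = {}
        for ctg, ivs in raw.items():
            arr = np.array(sorted(ivs), dtype=np.int64)
            merged = _merge_intervals(arr)
            if len(merged) < len(arr):
                logger.warning(
                    "mask on %s: merged %d overlapping/abutting intervals",
                    ctg,
                    len(arr) - len(merged),
                )
            intervals[ctg] = merged
        return cls(intervals)

    @classmethod
    def full(cls, contigs: Mapping[str, int]) -> "AccessibilityMask":
        return cls({c: np.array([[0, length]]) for c, length in contigs.items()})

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ctg, iv in self.intervals.items():
                for s, e in iv:
                    fh.write(f"{ctg}\t{s}\t{e}\n")

    def accessible_length(self, contig: str, start: int, end: int) -> int:
        """Total accessible bp overlapping ``[start, end)`` on ``contig``."""
        iv = self.intervals.get(contig)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.minimum(np.maximum(iv[:, 0], start), end)
        hi = np.minimum(np.maximum(iv[:, 1], start), end)
        return int((hi - lo).sum())

    def is_accessible(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: is each 0-based position inside the mask."""
        iv = self.intervals.get(contig)
        positions = np.asarray(positions, dtype=np.int64)
        if iv is None or len(iv) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < iv[idx[ok], 1]
        return out


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


# alias mirroring the CLI verb
load_mask = AccessibilityMask.from_bed


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """A genomic tile: 0-based half-open span, accessible length, SNP count."""

    contig: str
    start: int
    end: int
    l_acc: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if self.l_acc > self.end - self.start:
            raise ValueError("accessible length exceeds window span")
        if self.s < 0:
            raise ValueError("negative SNP count")


def make_windows(
    contigs: Mapping[str, int],
    size: int,
    step: int | None = None,
    mask: AccessibilityMask | None = None,
    sites: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[Window]:
    """Tile contigs with fixed-size windows.

    Trailing partial windows shorter than ``size`` are dropped.  ``sites``
    is an optional ``(contig_array, pos_array)`` pair of 1-based SNP
    positions used to fill the per-window SNP count; ``mask`` fills the
    accessible length (defaults to the full span).
    """
    if size <= 0 or (step is not None and step <= 0):
        raise ValueError("size and step must be positive")
    step = step or size
    windows: list[Window] = []
    for ctg, length in contigs.items():
        if sites is not None:
            sel = np.asarray(sites[0]) == ctg
            pos0 = np.sort(np.asarray(sites[1], dtype=np.int64)[sel]) - 1
        for start in range(0, length - size + 1, step):
            end = start + size
            l_acc = (
                mask.accessible_length(ctg, start, end)
                if mask is not None
                else size
            )
            s = 0
            if sites is not None:
                s = int(
                    np.searchsorted(pos0, end) - np.searchsorted(pos0, start)
                )
            windows.append(Window(ctg, start, end, l_acc=l_acc, s=s))
    return windows


# ---------------------------------------------------------------------------
# CDS annotation
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CDSGene:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    cds: list[tuple[int, int]]  # 0-based half-open, in genomic order

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def cds_positions(self) -> np.ndarray:
        """0-based genomic positions of CDS bases in translation order."""
        parts = [np.arange(s, e, dtype=np.int64) for s, e in self.cds]
        out = np.concatenate(parts)
        return out[::-1] if self.strand == "-" else out

    def cds_sequence(self, ref: Mapping[str, str]) -> str:
        seq = "".join(ref[self.contig][s:e] for s, e in self.cds)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class CDSAnnotation:
    """CDS intervals per gene plus a reference sequence handle.

    ``reference`` maps contig id to its full sequence string (as loaded by
    :func:`read_fasta`).
    """

    genes: list[CDSGene]
    reference: dict[str, str]

    def validate(self) -> list[str]:
        """Return ids of genes whose reference CDS is not a clean ORF."""
        bad = []
        for g in self.genes:
            seq = g.cds_sequence(self.reference).upper()
            if len(seq) % 3 != 0:
                bad.append(g.gene_id)
                continue
            codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
            if any(c in _STOPS for c in codons):
                bad.append(g.gene_id)
        return bad


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_gff3(path: str | Path, reference: dict[str, str]) -> CDSAnnotation:
    """Parse CDS features from a GFF3 file into a :class:`CDSAnnotation`.

    Genes are grouped by the ``Parent`` (transcript) attribute of CDS rows;
    the transcript's ``Parent``/``gene_id`` gives the gene id.
    """
    cds_rows: dict[str, list[tuple[str, int, int, str]]] = {}
    tx_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ctg, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in {"mRNA", "transcript"}:
                tx_gene[attr.get("ID", "")] = attr.get(
                    "Parent", attr.get("ID", "")
                )
            elif ftype == "CDS":
                parent = attr.get("Parent", attr.get("ID", "gene"))
                cds_rows.setdefault(parent, []).append(
                    (ctg, int(start) - 1, int(end), strand)
                )
    genes = []
    for tx, rows in cds_rows.items():
        rows.sort(key=lambda r: r[1])
        genes.append(
            CDSGene(
                gene_id=tx_gene.get(tx, tx),
                transcript_id=tx,
                contig=rows[0][0],
                strand=rows[0][3],
                cds=[(s, e) for _, s, e, _ in rows],
            )
        )
    genes.sort(key=lambda g: (g.contig, g.span[0]))
    return CDSAnnotation(genes=genes, reference=reference)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(records, path: str | Path) -> None:
    """Write records as TSV: header row, ``NA`` for missing, 6 significant
    digits for floats, deterministic column order."""
    if isinstance(records, pd.DataFrame):
        df = records
    elif isinstance(records, dict):
        df = pd.DataFrame(records)
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
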