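"""Core genotype data model and standard-format IO.

Diploid genotypes are held as alt-allele dosages (0, 1, 2) with a dedicated
missing sentinel, over an ordered cohort of samples and a variant table sorted
by (contig, position). Phase is deliberately discarded: every statistic in this
package (heterozygosity, HWE, IBS/IBD moments, runs of homozygosity) is
phase-free, so "0/1" and "1/0" both map to dosage 1.

Coordinates follow the VCF convention: 1-based, inclusive. Contig order is the
header order of the source VCF, falling back to first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING = -1

_BASES = frozenset("ACGT")
_REGIONS = ("north", "central", "south")


class InputError(ValueError):
    """Unreadable or absent input."""


class FormatError(ValueError):
    """Structurally invalid input (bad VCF, bad metadata table)."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested on data for which it is undefined."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP: contig, 1-based position, REF/ALT bases, QUAL."""

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(
                f"REF and ALT must differ at {self.contig}:{self.pos}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member: id, pack, and geographic region."""

    sample_id: str
    pack_id: str = "unknown"
    region: str = "central"

    def __post_init__(self) -> None:
        if self.region not in _REGIONS:
            raise FormatError(
                f"region for {self.sample_id!r} must be one of "
                f"{_REGIONS}, got {self.region!r}"
            )


class GenotypeMatrix:
    """Samples x variants alt-dosage matrix with sample and variant tables.

    Parameters
    ----------
    samples
        Ordered cohort members.
    variants
        DataFrame with columns ``contig, pos, ref, alt, qual``, sorted by
        (contig, pos) with strictly increasing positions within each contig.
        Contig order is taken as the order of first appearance.
    dosages
        Integer array of shape (n_samples, n_variants) with values in
        {0, 1, 2, MISSING}.
    """

    VARIANT_COLUMNS = ("contig", "pos", "ref", "alt", "qual")

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        variants: pd.DataFrame,
        dosages: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_id in cohort")
        variants = variants.reset_index(drop=True)
        missing_cols = set(self.VARIANT_COLUMNS) - set(variants.columns)
        if missing_cols:
            raise FormatError(f"variant table lacks columns {sorted(missing_cols)}")
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(self.samples), len(variants)):
            raise FormatError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("dosages must be in {0,1,2} or MISSING")
        self._check_sorted(variants)
        self.variants = variants
        self.dosages = dosages

    @staticmethod
    def _check_sorted(variants: pd.DataFrame) -> None:
        contigs = variants["contig"].to_numpy()
        pos = variants["pos"].to_numpy()
        seen: dict[str, int] = {}
        last_contig = None
        for i in range(len(variants)):
            c = contigs[i]
            if c != last_contig:
                if c in seen:
                    raise FormatError(
                        f"contig {c!r} appears in non-contiguous blocks "
                        f"(record {c}:{pos[i]})"
                    )
                seen[c] = i
                last_contig = c
            elif pos[i] <= pos[i - 1]:
                raise FormatError(
                    f"positions not strictly increasing within contig at "
                    f"{c}:{pos[i]} (previous {pos[i - 1]})"
                )

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(r.contig, int(r.pos), r.ref, r.alt, float(r.qual))
            for r in self.variants.itertuples(index=False)
        ]

    @property
    def contigs(self) -> list[str]:
        """Contigs in first-appearance order."""
        return list(dict.fromkeys(self.variants["contig"]))

    # -- subsetting ---------------------------------------------------------

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix with the variants selected by a boolean mask or index
        array, in original order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        else:
            index = np.sort(index)
        return GenotypeMatrix(
            self.samples,
            self.variants.iloc[index],
            self.dosages[:, index],
        )

    def take_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.variants,
            self.dosages[idx, :],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_samples} samples x "
            f"{self.n_variants} variants)"
        )


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    require_complete: bool = False,
    samples: Sequence[SampleRecord] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic single-base REF/ALT records are kept; multiallelic and
    non-SNP records are skipped and counted on the returned matrix as
    ``gm.n_skipped_non_snp``. With ``require_complete``, variants with any
    missing genotype are dropped (counted as ``gm.n_dropped_incomplete``).

    ``samples`` optionally attaches pack/region metadata by sample id; VCF
    sample order is always preserved.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on parse failure
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    if len(vcf.samples) == 0:
        raise FormatError(f"{path}: VCF has no sample columns")
    has_gt = any(
        h.info().get("HeaderType") == "FORMAT" and h.info().get("ID") == "GT"
        for h in vcf.header_iter()
    )
    if not has_gt:
        raise FormatError(f"{path}: VCF header declares no GT FORMAT field")

    meta = {s.sample_id: s for s in samples} if samples else {}
    sample_records = [
        meta.get(sid, SampleRecord(sample_id=sid)) for sid in vcf.samples
    ]

    header_order = {c: i for i, c in enumerate(vcf.seqnames)}
    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    n_skipped = 0
    last: dict[str, int] = {}
    contig_rank: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        contig = v.CHROM
        if contig not in contig_rank:
            contig_rank[contig] = header_order.get(
                contig, len(header_order) + len(contig_rank)
            )
        if contig in last and v.POS <= last[contig]:
            raise FormatError(
                f"{path}: unsorted positions within contig at "
                f"{contig}:{v.POS} (previous {last[contig]})"
            )
        last[contig] = v.POS
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(sample_records), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            dos[i] = MISSING if (a < 0 or b < 0) else a + b
        rows.append(
            (contig, v.POS, v.REF, v.ALT[0],
             float(v.QUAL) if v.QUAL is not None else float("nan"))
        )
        dosage_rows.append(dos)
    vcf.close()

    variants = pd.DataFrame(rows, columns=list(GenotypeMatrix.VARIANT_COLUMNS))
    if len(variants):
        order = np.lexsort(
            (variants["pos"].to_numpy(),
             variants["contig"].map(contig_rank).to_numpy())
        )
        variants = variants.iloc[order]
        dosages = np.array(dosage_rows, dtype=np.int8).T[:, order]
    else:
        dosages = np.zeros((len(sample_records), 0), dtype=np.int8)

    n_dropped_incomplete = 0
    if require_complete and len(variants):
        complete = ~(dosages == MISSING).any(axis=0)
        n_dropped_incomplete = int((~complete).sum())
        variants = variants.iloc[np.flatnonzero(complete)]
        dosages = dosages[:, complete]

    gm = GenotypeMatrix(sample_records, variants, dosages)
    gm.n_skipped_non_snp = n_skipped  # type: ignore[attr-defined]
    gm.n_dropped_incomplete = n_dropped_incomplete  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a GT-only VCF v4.2 that :func:`read_vcf` inverts exactly.

    Dosage 1 is emitted as ``0/1`` (phase is not represented), MISSING as
    ``./.``. An empty variant table produces a header-only VCF.
    """
    path = Path(path)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contig_max: dict[str, int] = {}
    for contig, pos in zip(gm.variants["contig"], gm.variants["pos"]):
        contig_max[contig] = max(contig_max.get(contig, 0), int(pos))
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise InputError(f"cannot write VCF {path}: {exc}") from exc
    with fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=packstats\n")
        for contig, length in contig_max.items():
            fh.write(f"##contig=<ID={contig},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        contigs = gm.variants["contig"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        ref = gm.variants["ref"].to_numpy()
        alt = gm.variants["alt"].to_numpy()
        qual = gm.variants["qual"].to_numpy()
        for j in range(gm.n_variants):
            q = "." if np.isnan(qual[j]) else f"{qual[j]:g}"
            gts = "\t".join(gt_code[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{contigs[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t{q}\t.\t.\tGT\t{gts}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a tab-separated sample metadata table.

    Expected header: ``sample_id  pack_id  region`` with region in
    {north, central, south}. Duplicate ids or unknown regions are errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "pack_id", "region"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: sample table needs columns {sorted(needed)}, "
            f"found {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        if row.region not in _REGIONS:
            raise FormatError(
                f"{path}: unknown region {row.region!r} for sample "
                f"{row.sample_id!r} (expected one of {_REGIONS})"
            )
        records.append(SampleRecord(row.sample_id, row.pack_id, row.region))
    return records


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(s.sample_id, s.pack_id, s.region) for s in samples],
        columns=["sample_id", "pack_id", "region"],
    ).to_csv(path, sep="\t", index=False)
    return path
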