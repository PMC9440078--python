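"""Runs of homozygosity and genomic inbreeding coefficients.

ROH are called per sample with a sliding-window genotype scan: windows of
``window_snps`` consecutive SNPs (one-SNP steps) are scored as homozygous
"hits" when they contain at most ``window_max_het`` heterozygous and
``window_max_missing`` missing calls; a SNP becomes *eligible* when at least
``window_hit_threshold`` of the complete windows containing it are hits and
its own call is not heterozygous. Candidate segments are maximal runs of
consecutive eligible SNPs, split where adjacent SNPs sit more than
``max_gap_kb`` apart, and kept when they contain at least
``min_snps_segment`` SNPs, span at least ``min_length_kb`` and average no
more than ``min_density_kb_per_snp`` kb per SNP. Segment coordinates are
SNP-anchored (first to last SNP of the run, inclusive). Missing calls do not
terminate runs but count toward the window missing limit.

Inbreeding coefficients:

    F_HOM = (O_hom - E_hom) / (N - E_hom)

with O_hom the observed homozygous-marker count, E_hom the expected count
under HWE at cohort frequencies (unbiased, 2n/(2n-1)-corrected), N the
marker count; and

    F_ROH = L_ROH / L_total

the fraction of the SNP-covered genome lying in ROH, with L_total summed
over contigs as (last SNP - first SNP + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeMatrix, UndefinedStatisticError
from .variant_qc import alt_allele_frequencies

#: ROH length bins in Mb; first bin closed at 0.5 so the minimum-length
#: segment has a home, later bins left-open/right-closed.
ROH_BINS_MB = (0.5, 1.0, 1.5, 2.0, 2.5)
ROH_BIN_LABELS = ("0.5-1.0", "1.0-1.5", "1.5-2.0", "2.0-2.5", ">2.5")


@dataclass(frozen=True)
class ROHParams:
    """The eight sliding-window ROH conditions (lengths in kb)."""

    min_snps_segment: int = 25
    min_length_kb: float = 500.0
    min_density_kb_per_snp: float = 25.0
    window_snps: int = 25
    max_gap_kb: float = 1000.0
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps_segment < 1:
            raise ValueError("SNP counts must be >= 1")
        if not (0.0 < self.window_hit_threshold <= 1.0):
            raise ValueError("window_hit_threshold must be in (0,1]")
        if min(self.window_max_het, self.window_max_missing) < 0:
            raise ValueError("window limits must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    contig: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass
class InbreedingCoefficients:
    sample_id: str
    o_hom: int
    e_hom: float
    n_markers: int
    f_hom: float
    l_roh: int = 0
    l_total: int = 0
    f_roh: float = 0.0


def detect_roh(
    gm: GenotypeMatrix,
    sample_id: str,
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Call ROH segments for one sample (see module docstring for the scan
    semantics). Contigs with fewer SNPs than one window yield no segments."""
    si = gm.sample_index(sample_id)
    dos = gm.dosages[si]
    contigs = gm.variants["contig"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for contig in dict.fromkeys(contigs):
        m = contigs == contig
        segments.extend(
            _detect_roh_contig(sample_id, contig, pos[m], dos[m], params)
        )
    return segments


def _detect_roh_contig(
    sample_id: str,
    contig: str,
    pos: np.ndarray,
    dos: np.ndarray,
    params: ROHParams,
) -> list[ROHSegment]:
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    het = (dos == 1).astype(int)
    mis = (dos == MISSING).astype(int)
    # windows start at 0 .. n-w; cumulative sums give per-window counts
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(n - w + 1)
    hits = (
        (chet[starts + w] - chet[starts] <= params.window_max_het)
        & (cmis[starts + w] - cmis[starts] <= params.window_max_missing)
    ).astype(int)
    # windows covering SNP i start in [i-w+1, i] intersected with valid range
    chits = np.concatenate([[0], np.cumsum(hits)])
    i = np.arange(n)
    lo = np.clip(i - w + 1, 0, n - w)
    hi = np.minimum(i, n - w)
    n_windows = hi - lo + 1
    n_hits = chits[hi + 1] - chits[lo]
    hit_rate = n_hits / n_windows
    eligible = (hit_rate >= params.window_hit_threshold) & (het == 0)

    segments = []
    run_start = None
    prev = None
    for k in range(n + 1):
        end_run = True
        if k < n and eligible[k]:
            if run_start is None:
                run_start = k
                end_run = False
            elif (pos[k] - pos[prev]) / 1000.0 > params.max_gap_kb:
                _emit(segments, sample_id, contig, pos, run_start, prev, params)
                run_start = k
                end_run = False
            else:
                end_run = False
            prev = k
        elif run_start is None:
            continue
        if end_run and run_start is not None:
            _emit(segments, sample_id, contig, pos, run_start, prev, params)
            run_start = None
    return segments


def _emit(segments, sample_id, contig, pos, first, last, params) -> None:
    n_snps = last - first + 1
    length_kb = (pos[last] - pos[first] + 1) / 1000.0
    if n_snps < params.min_snps_segment:
        return
    if length_kb < params.min_length_kb:
        return
    if length_kb / n_snps > params.min_density_kb_per_snp:
        return
    segments.append(
        ROHSegment(sample_id, contig, int(pos[first]), int(pos[last]), n_snps)
    )


def detect_roh_cohort(
    gm: GenotypeMatrix, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    segs: list[ROHSegment] = []
    for sid in gm.sample_ids:
        segs.extend(detect_roh(gm, sid, params))
    return segs


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segments as a .hom-style table."""
    return pd.DataFrame(
        [
            (s.sample_id, s.contig, s.start, s.end, s.n_snps, s.length_kb)
            for s in segments
        ],
        columns=["sample_id", "contig", "start", "end", "n_snps", "kb"],
    )


def bin_roh_lengths(
    segments: list[ROHSegment],
    samples: list[str] | None = None,
    packs: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Total ROH length (Mb) per sample in the five length bins, plus
    per-pack averages of the per-sample bin totals when ``packs`` maps
    sample_id -> pack_id. Bin totals sum to each sample's total ROH length."""
    if samples is None:
        samples = sorted({s.sample_id for s in segments})
    per_sample = pd.DataFrame(
        0.0, index=pd.Index(samples, name="sample_id"), columns=list(ROH_BIN_LABELS)
    )
    for seg in segments:
        mb = seg.length_bp / 1e6
        per_sample.loc[seg.sample_id, _bin_label(mb)] += mb
    if packs is None:
        return per_sample, None
    pack_series = pd.Series({s: packs.get(s, "unknown") for s in samples})
    per_pack = per_sample.groupby(pack_series).mean()
    per_pack.index.name = "pack_id"
    return per_sample, per_pack


def _bin_label(mb: float) -> str:
    for upper, label in zip(ROH_BINS_MB[1:], ROH_BIN_LABELS[:-1]):
        if mb <= upper:
            return label
    return ROH_BIN_LABELS[-1]


def f_hom(
    gm: GenotypeMatrix, sample_id: str, freqs: np.ndarray | None = None
) -> InbreedingCoefficients:
    """Excess-homozygosity inbreeding coefficient for one sample.

    Only sites polymorphic in the cohort and called in the sample contribute.
    The expected homozygous count uses the unbiased per-site expected
    heterozygosity 2p(1-p) * 2n/(2n-1), so the cohort-average F_HOM is
    centered on zero under HWE.
    """
    si = gm.sample_index(sample_id)
    dos = gm.dosages[si]
    p = alt_allele_frequencies(gm.dosages) if freqs is None else np.asarray(freqs)
    present_all = gm.dosages != MISSING
    n_called = present_all.sum(axis=0)
    usable = (
        (dos != MISSING)
        & np.isfinite(p)
        & (p > 0.0)
        & (p < 1.0)
        & (n_called >= 1)
    )
    n_markers = int(usable.sum())
    if n_markers == 0:
        raise UndefinedStatisticError(
            f"no polymorphic called marker for sample {sample_id!r}"
        )
    o_hom = int(((dos == 0) | (dos == 2))[usable].sum())
    n_chr = 2.0 * n_called[usable]
    h_exp = 2.0 * p[usable] * (1.0 - p[usable]) * n_chr / (n_chr - 1.0)
    e_hom = float((1.0 - h_exp).sum())
    if n_markers == e_hom:
        raise UndefinedStatisticError("F_HOM undefined: N equals E_hom")
    return InbreedingCoefficients(
        sample_id=sample_id,
        o_hom=o_hom,
        e_hom=e_hom,
        n_markers=n_markers,
        f_hom=(o_hom - e_hom) / (n_markers - e_hom),
    )


def snp_covered_length(gm: GenotypeMatrix) -> int:
    """L_total: sum over contigs of (last SNP - first SNP + 1)."""
    total = 0
    contigs = gm.variants["contig"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    for contig in dict.fromkeys(contigs):
        cpos = pos[contigs == contig]
        total += int(cpos.max() - cpos.min() + 1)
    return total


def f_roh(segments: list[ROHSegment], l_total: int) -> float:
    """Fraction of the SNP-covered genome lying in ROH."""
    if l_total <= 0:
        raise ValueError("l_total must be positive")
    return sum(s.length_bp for s in segments) / l_total


def inbreeding_table(
    gm: GenotypeMatrix,
    segments: list[ROHSegment],
    params: ROHParams = ROHParams(),
) -> pd.DataFrame:
    """Per-sample F_HOM and F_ROH table for a cohort."""
    l_total = snp_covered_length(gm)
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in gm.sample_ids}
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    freqs = alt_allele_frequencies(gm.dosages)
    rows = []
    for sid in gm.sample_ids:
        coef = f_hom(gm, sid, freqs=freqs)
        coef.l_total = l_total
        coef.l_roh = sum(s.length_bp for s in by_sample[sid])
        coef.f_roh = f_roh(by_sample[sid], l_total)
        rows.append(coef.__dict__)
    return pd.DataFrame(rows)
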