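"""Variant-level QC and windowed LD pruning.

Filters mirror the conventional post-calling workflow for a complete-call
cohort: drop non-biallelic records, low-QUAL sites (QUAL <= threshold),
incomplete sites, sites out of Hardy-Weinberg equilibrium (exact test), and
low-MAF sites (MAF <= threshold). Removal is attributed to the first failing
criterion in the fixed order biallelic -> qual -> call rate -> HWE -> MAF so
report counts are deterministic.

LD pruning reproduces the sliding-window pairwise-r2 scheme
(window / step / r2 threshold, e.g. 25 5 0.5 or the stringent 200 20 0.2):
within each window any retained pair with r2 above the threshold loses one
member; r2 is the squared Pearson correlation of unphased dosage vectors
(composite LD).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_model import (
    MISSING,
    GenotypeMatrix,
    UndefinedStatisticError,
    VariantRecord,
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class QCThresholds:
    """Variant-retention thresholds.

    A site is *removed* when qual <= min_qual, HWE p <= max_hwe_p, or
    MAF <= min_maf (all bounds inclusive on the removal side), and, with
    ``require_complete``, when any genotype is missing.
    """

    min_qual: float = 30.0
    max_hwe_p: float = 1e-5
    min_maf: float = 0.05
    require_complete: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_hwe_p <= 1.0):
            raise ValueError("max_hwe_p must be in [0,1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0,0.5]")


@dataclass(frozen=True)
class LDPruneParams:
    """Sliding-window pairwise pruning parameters (window, step in SNPs)."""

    window_snps: int = 25
    step_snps: int = 5
    r2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not (1 <= self.step_snps <= self.window_snps):
            raise ValueError("step_snps must be in [1, window_snps]")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0,1]")


#: Stringent pruning regime used for the bottleneck-test marker subset.
STRINGENT_PRUNE = LDPruneParams(window_snps=200, step_snps=20, r2_threshold=0.2)


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_nonbiallelic: int = 0
    n_removed_qual: int = 0
    n_removed_call: int = 0
    n_removed_hwe: int = 0
    n_removed_maf: int = 0
    ts_tv_input: float | None = None
    ts_tv_output: float | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - (
            self.n_removed_nonbiallelic
            + self.n_removed_qual
            + self.n_removed_call
            + self.n_removed_hwe
            + self.n_removed_maf
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["n_retained"] = self.n_retained
        return d


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Conditions on the observed allele counts and sums, over every heterozygote
    count compatible with them, the probabilities of configurations no more
    likely than the observed one. This is the genotype-exact test in its
    standard (non-mid-p) form.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined with zero genotypes")
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    # het counts share the parity of the rare allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    log_probs = np.array([_log_hwe_prob(n, n_alt, int(h)) for h in hets])
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    # tolerance absorbs float noise on exactly-tied configurations
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


def _log_hwe_prob(n: int, n_alt: int, n_het: int) -> float:
    """Log unnormalized conditional probability of ``n_het`` heterozygotes
    given ``n`` diploids and ``n_alt`` alt alleles."""
    n_hom_alt = (n_alt - n_het) // 2
    n_hom_ref = n - n_het - n_hom_alt
    if n_hom_alt < 0 or n_hom_ref < 0:
        return -np.inf
    return (
        n_het * np.log(2.0)
        + lgamma(n + 1)
        - lgamma(n_hom_ref + 1)
        - lgamma(n_het + 1)
        - lgamma(n_hom_alt + 1)
    )


def hwe_test_sites(dosages: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per variant column of a dosage matrix (missing
    entries ignored). All-missing columns get NaN."""
    dosages = np.asarray(dosages)
    out = np.empty(dosages.shape[1])
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        key = (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# Allele frequency
# ---------------------------------------------------------------------------

def site_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from one site's dosage vector (missing ignored)."""
    dosages = np.asarray(dosages)
    dosages = dosages[dosages != MISSING]
    if dosages.size == 0:
        raise UndefinedStatisticError("MAF undefined at an all-missing site")
    p = dosages.sum() / (2.0 * dosages.size)
    return float(min(p, 1.0 - p))


def alt_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per variant column, NaN where all calls missing."""
    dosages = np.asarray(dosages)
    present = dosages != MISSING
    n = present.sum(axis=0)
    total = np.where(present, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, total / (2.0 * n), np.nan)


def site_mafs(dosages: np.ndarray) -> np.ndarray:
    p = alt_allele_frequencies(dosages)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_filters(
    gm: GenotypeMatrix, thr: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant-retention filters; every removal is attributed once, to
    the first failing criterion in the order biallelic -> qual -> call rate
    -> HWE -> MAF.

    The matrix is assumed already SNP-only (ingestion skips non-biallelic
    records); the biallelic count here covers matrices built in memory with
    non-ACGT alleles, normally zero.
    """
    if gm.n_variants == 0:
        raise UndefinedStatisticError("cannot filter an empty matrix")
    rep = QCReport(n_input=gm.n_variants)
    rep.ts_tv_input = ts_tv_ratio(gm.variant_records(), allow_empty=True)

    ref = gm.variants["ref"].to_numpy()
    alt = gm.variants["alt"].to_numpy()
    biallelic = (
        np.isin(ref, list("ACGT")) & np.isin(alt, list("ACGT")) & (ref != alt)
    )
    qual = gm.variants["qual"].to_numpy(dtype=float)
    qual_ok = ~(qual <= thr.min_qual)  # NaN QUAL passes
    complete = ~(gm.dosages == MISSING).any(axis=0)
    call_ok = complete | (not thr.require_complete)

    alive = biallelic.copy()
    rep.n_removed_nonbiallelic = int((~biallelic).sum())
    rep.n_removed_qual = int((alive & ~qual_ok).sum())
    alive &= qual_ok
    rep.n_removed_call = int((alive & ~call_ok).sum())
    alive &= call_ok

    hwe_p = np.ones(gm.n_variants)
    idx = np.flatnonzero(alive)
    if idx.size:
        hwe_p[idx] = hwe_test_sites(gm.dosages[:, idx])
    hwe_ok = hwe_p > thr.max_hwe_p
    rep.n_removed_hwe = int((alive & ~hwe_ok).sum())
    alive &= hwe_ok

    maf = site_mafs(gm.dosages)
    maf_ok = maf > thr.min_maf
    rep.n_removed_maf = int((alive & ~maf_ok).sum())
    alive &= maf_ok

    out = gm.take_variants(alive)
    rep.ts_tv_output = ts_tv_ratio(out.variant_records(), allow_empty=True)
    return out, rep


def ts_tv_ratio(
    variants: Sequence[VariantRecord], allow_empty: bool = False
) -> float | None:
    """Transition/transversion ratio over REF->ALT substitutions.

    Returns None (the explicit no-transversion marker) when there are
    transitions but no transversions.
    """
    if not variants:
        if allow_empty:
            return None
        raise UndefinedStatisticError("Ts/Tv undefined with zero variants")
    ts = sum(1 for v in variants if (v.ref, v.alt) in _TRANSITIONS)
    tv = len(variants) - ts
    if tv == 0:
        return None
    return ts / tv


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    gm: GenotypeMatrix, params: LDPruneParams = LDPruneParams()
) -> tuple[GenotypeMatrix, list[str]]:
    """Sliding-window pairwise LD pruning.

    Per contig, windows of ``window_snps`` retained variants advance by
    ``step_snps``; while any retained pair in the window has r2 above the
    threshold, the pair with the largest r2 is resolved by removing its
    lower-MAF member (later position on ties). Zero-variance sites carry no
    LD information and are treated as r2 = 0. Survivors keep their original
    order; the second return value lists removed variants as "contig:pos".
    """
    n = gm.n_variants
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return gm, []
    maf = site_mafs(gm.dosages)
    contigs = gm.variants["contig"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    # r2 is compared strictly; cap just below 1 so threshold 1 still removes
    # exactly collinear sites (r2 == 1) and nothing else
    thr_eff = min(params.r2_threshold, 1.0 - 1e-9)

    # passes repeat until a fixpoint so that no scheduled window on the final
    # survivor list retains a pair above the threshold
    while True:
        n_before = int(keep.sum())
        for contig in dict.fromkeys(contigs):
            cidx = np.flatnonzero(contigs == contig)
            start = 0
            while True:
                live = cidx[keep[cidx]]
                window = live[start : start + params.window_snps]
                if len(window) >= 2:
                    _prune_window(gm.dosages, window, maf, keep, thr_eff)
                if start + params.window_snps >= len(live):
                    break
                start += params.step_snps
        if int(keep.sum()) == n_before:
            break
    removed = [f"{contigs[i]}:{pos[i]}" for i in np.flatnonzero(~keep)]
    return gm.take_variants(keep), removed


def _prune_window(
    dosages: np.ndarray,
    window: np.ndarray,
    maf: np.ndarray,
    keep: np.ndarray,
    r2_threshold: float,
) -> None:
    sub = dosages[:, window].astype(float)
    sub[sub == MISSING] = np.nan
    if np.isnan(sub).any():
        r2 = _pairwise_complete_r2(sub)
    else:
        sd = sub.std(axis=0)
        ok = sd > 0
        r2 = np.zeros((len(window), len(window)))
        if ok.sum() >= 2:
            c = np.corrcoef(sub[:, ok].T)
            r2[np.ix_(ok, ok)] = c * c
    np.fill_diagonal(r2, 0.0)
    active = np.ones(len(window), dtype=bool)
    while True:
        masked = np.where(np.outer(active, active), r2, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= r2_threshold:
            break
        vi, vj = window[i], window[j]
        if maf[vi] < maf[vj] or (maf[vi] == maf[vj] and vi > vj):
            drop_local, drop_global = i, vi
        else:
            drop_local, drop_global = j, vj
        active[drop_local] = False
        keep[drop_global] = False


def _pairwise_complete_r2(sub: np.ndarray) -> np.ndarray:
    m = sub.shape[1]
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(sub[:, i]) & ~np.isnan(sub[:, j])
            if ok.sum() < 2:
                continue
            a, b = sub[ok, i], sub[ok, j]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2
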