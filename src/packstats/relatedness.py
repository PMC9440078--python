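"""Pairwise IBD relatedness by method of moments.

For each pair of samples the observed genome-wide proportions of sites
sharing 0, 1 or 2 alleles identical by state (IBS) are inverted, through
allele-frequency-dependent expectations, into the probabilities Z0, Z1, Z2 of
sharing 0, 1 or 2 alleles identical by descent. Relatedness is summarized as

    PI-HAT = P(IBD=2) + 0.5 * P(IBD=1).

The expected IBS proportions use the standard finite-sample corrections for
allele frequencies estimated from the cohort itself (products of allele draws
are replaced by their unbiased counterparts); without them PI-HAT is inflated
at cohort sizes like n = 71. Negative moment estimates are truncated to zero
and the triple renormalized to sum to one (the bounded estimator).

Relationship categories follow fixed PI-HAT thresholds: first degree >= 0.50,
second degree in [0.25, 0.50), distant in (0, 0.25), unrelated exactly 0
after bounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeMatrix, UndefinedStatisticError
from .variant_qc import alt_allele_frequencies

CATEGORIES = ("first", "second", "distant", "unrelated")

#: Pairs with fewer jointly informative sites than this are flagged.
MIN_INFORMATIVE_DEFAULT = 100


@dataclass
class PairRelatedness:
    id1: str
    id2: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_sites: int
    category: str
    low_confidence: bool = False


def pair_count(k: int) -> int:
    """Number of unordered sample pairs, k(k-1)/2."""
    if k < 2:
        raise ValueError("pair count needs k >= 2 samples")
    return k * (k - 1) // 2


def ibs_counts(
    gm: GenotypeMatrix, pair: tuple[str, str]
) -> tuple[int, int, int]:
    """Counts of sites where a pair shares 0, 1, 2 alleles identical by state.

    Opposite homozygotes share 0 alleles; het vs het shares 2; otherwise the
    IBS state is 2 - |dosage difference|. Sites missing in either sample are
    ignored.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must be two distinct samples")
    da = gm.dosages[gm.sample_index(a)]
    db = gm.dosages[gm.sample_index(b)]
    ok = (da != MISSING) & (db != MISSING)
    if not ok.any():
        raise UndefinedStatisticError(
            f"no jointly called site for pair ({a}, {b})"
        )
    ibs = 2 - np.abs(da[ok].astype(int) - db[ok].astype(int))
    return (
        int((ibs == 0).sum()),
        int((ibs == 1).sum()),
        int((ibs == 2).sum()),
    )


def estimate_ibd(
    gm: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    min_informative: int = MIN_INFORMATIVE_DEFAULT,
) -> list[PairRelatedness]:
    """Method-of-moments Z0/Z1/Z2 and PI-HAT for every unordered pair.

    ``freqs`` optionally supplies external alt-allele frequencies (one per
    variant); by default frequencies are estimated from the cohort. Sites
    monomorphic in the frequency source are skipped (count available via the
    module logger return attribute ``estimate_ibd.n_skipped_monomorphic``).
    Sites are treated as independent, so an LD-pruned matrix should be used.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    if freqs is None:
        p = alt_allele_frequencies(gm.dosages)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (gm.n_variants,):
            raise ValueError("freqs must have one entry per variant")
    present = gm.dosages != MISSING
    n_alleles = 2.0 * present.sum(axis=0)

    # corrections need >= 4 observed allele copies; polymorphic sites only
    usable = (
        np.isfinite(p) & (p > 0.0) & (p < 1.0) & (n_alleles >= 4)
    )
    estimate_ibd.n_skipped_monomorphic = int((~usable).sum())  # type: ignore[attr-defined]
    if not usable.any():
        raise UndefinedStatisticError("no polymorphic site available")

    dos = gm.dosages[:, usable]
    p = p[usable]
    n_alleles = n_alleles[usable]
    e00_s, e10_s, e20_s, e11_s, e21_s = _expected_ibs_site(p, n_alleles)

    out: list[PairRelatedness] = []
    ids = gm.sample_ids
    for i in range(len(ids)):
        di = dos[i]
        oki = di != MISSING
        for j in range(i + 1, len(ids)):
            dj = dos[j]
            ok = oki & (dj != MISSING)
            n_sites = int(ok.sum())
            if n_sites == 0:
                raise UndefinedStatisticError(
                    f"no jointly called site for pair ({ids[i]}, {ids[j]})"
                )
            diff = np.abs(di[ok].astype(int) - dj[ok].astype(int))
            o0 = float((diff == 2).mean())
            o1 = float((diff == 1).mean())
            o2 = 1.0 - o0 - o1
            e00 = float(e00_s[ok].mean())
            e10 = float(e10_s[ok].mean())
            e20 = float(e20_s[ok].mean())
            e11 = float(e11_s[ok].mean())
            e21 = float(e21_s[ok].mean())

            z0 = o0 / e00 if e00 > 0 else 0.0
            z1 = (o1 - z0 * e10) / e11 if e11 > 0 else 0.0
            z2 = o2 - z0 * e20 - z1 * e21
            z0, z1, z2 = _bound_z(z0, z1, z2)
            pi_hat = z2 + 0.5 * z1
            out.append(
                PairRelatedness(
                    id1=ids[i],
                    id2=ids[j],
                    z0=z0,
                    z1=z1,
                    z2=z2,
                    pi_hat=pi_hat,
                    n_sites=n_sites,
                    category=assign_category(pi_hat),
                    low_confidence=n_sites < min_informative,
                )
            )
    return out


def _expected_ibs_site(
    p: np.ndarray, n_alleles: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Per-site expected IBS probabilities given IBD state (vectorized, with
    the finite-sample correction factors)."""
    q = 1.0 - p
    A = n_alleles
    x = p * A
    y = q * A
    c1 = A / (A - 1.0)
    c2 = A / (A - 2.0)
    c3 = A / (A - 3.0)
    p2 = (x - 1.0) / x
    p3 = (x - 2.0) / x
    p4 = (x - 3.0) / x
    q2 = (y - 1.0) / y
    q3 = (y - 2.0) / y
    q4 = (y - 3.0) / y
    ccc = c1 * c2 * c3
    cc = c1 * c2
    e00 = 2.0 * p * p * q * q * p2 * q2 * ccc
    e10 = 4.0 * p**3 * q * p2 * p3 * ccc + 4.0 * p * q**3 * q2 * q3 * ccc
    e20 = (
        p**4 * p2 * p3 * p4 * ccc
        + q**4 * q2 * q3 * q4 * ccc
        + 4.0 * p * p * q * q * p2 * q2 * ccc
    )
    e11 = 2.0 * p * p * q * p2 * cc + 2.0 * p * q * q * q2 * cc
    e21 = (
        p**3 * p2 * p3 * cc
        + q**3 * q2 * q3 * cc
        + p * p * q * p2 * cc
        + p * q * q * q2 * cc
    )
    # corrections can go slightly negative at minimal allele counts
    return tuple(np.clip(e, 0.0, 1.0) for e in (e00, e10, e20, e11, e21))


def _bound_z(z0: float, z1: float, z2: float) -> tuple[float, float, float]:
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    s = z.sum()
    if s == 0.0:
        return 0.0, 0.0, 1.0  # degenerate; never reached with real data
    z = z / s
    return float(z[0]), float(z[1]), float(z[2])


def assign_category(pi_hat: float) -> str:
    """Relationship category from PI-HAT: >=0.50 first, [0.25,0.50) second,
    (0,0.25) distant, exactly 0 unrelated."""
    if not (0.0 <= pi_hat <= 1.0):
        raise ValueError(f"PI-HAT must be in [0,1], got {pi_hat}")
    if pi_hat >= 0.50:
        return "first"
    if pi_hat >= 0.25:
        return "second"
    if pi_hat > 0.0:
        return "distant"
    return "unrelated"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_relatedness(pairs: list[PairRelatedness]) -> pd.DataFrame:
    """Per-category pair counts, cohort portions (%, 2 dp half-up) and mean
    Z0/Z1/Z2/PI-HAT, with a Total row."""
    if not pairs:
        raise ValueError("no pairs to summarize")
    df = pd.DataFrame([p.__dict__ for p in pairs])
    total = len(df)
    rows = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        rows.append(
            {
                "category": cat,
                "n_pairs": len(sub),
                "portion_pct": round_half_up(100.0 * len(sub) / total, 2),
                "mean_z0": sub["z0"].mean() if len(sub) else np.nan,
                "mean_z1": sub["z1"].mean() if len(sub) else np.nan,
                "mean_z2": sub["z2"].mean() if len(sub) else np.nan,
                "mean_pi_hat": sub["pi_hat"].mean() if len(sub) else np.nan,
            }
        )
    rows.append(
        {
            "category": "total",
            "n_pairs": total,
            "portion_pct": 100.0,
            "mean_z0": df["z0"].mean(),
            "mean_z1": df["z1"].mean(),
            "mean_z2": df["z2"].mean(),
            "mean_pi_hat": df["pi_hat"].mean(),
        }
    )
    return pd.DataFrame(rows)


def pairs_to_frame(pairs: list[PairRelatedness]) -> pd.DataFrame:
    """Pairwise table in the conventional .genome-style layout."""
    df = pd.DataFrame([p.__dict__ for p in pairs])
    return df.rename(
        columns={
            "id1": "ID1",
            "id2": "ID2",
            "z0": "Z0",
            "z1": "Z1",
            "z2": "Z2",
            "pi_hat": "PI_HAT",
        }
    )
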