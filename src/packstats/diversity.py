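"""Per-site diversity metrics and the heterozygosity-excess bottleneck test.

A population that has just passed through a bottleneck is in mutation-drift
disequilibrium: allelic diversity is lost faster than heterozygosity, so for a
few generations observed heterozygosity H_O sits above the Hardy-Weinberg
expectation H_E computed from the surviving allele frequencies. The
standardized difference test aggregates the per-locus excess
delta_l = H_O,l - H_E,l into a Z-score

    T2 = L^(-1/2) * sum_l delta_l / sigma_l,

where sigma_l is the per-locus null standard deviation of delta_l, and rejects
mutation-drift equilibrium (one-sided, 5%) when T2 >= 1.645.

sigma choices
-------------
``analytic`` (default)
    Delta-method null SD of H_O - H_E_hat when the allele frequency is
    estimated from the same sample: sigma_l = H_E,l / sqrt(n). The errors of
    H_O and H_E_hat are strongly positively correlated, which is why this is
    smaller than the binomial SD of H_O alone; H_E is first made unbiased with
    the 2n/(2n-1) factor so the null expectation of delta is exactly zero.
``binomial``
    sqrt(H_E(1-H_E)/n), the binomial SD of the observed heterozygote
    proportion at known frequency. Kept for sensitivity analysis; it ignores
    the H_O/H_E error correlation and over-estimates sigma, so T2 is
    conservative in scale (and, without the bias factor, badly off-center).
``mc``
    Monte-Carlo SD of delta under HWE resampling at the estimated frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_model import MISSING, GenotypeMatrix, UndefinedStatisticError
from .variant_qc import hwe_test_sites

#: One-sided 5% standard-normal critical value of the T2 rejection rule.
T2_CRITICAL_5PCT = 1.645


@dataclass
class BottleneckResult:
    """Outcome of the standardized-difference heterozygosity-excess test."""

    t2: float
    n_loci: int
    p_one_sided: float
    sigma_mode: str
    mean_sigma: float

    @property
    def reject_5pct(self) -> bool:
        # tiny slack keeps the >= rule stable against float rounding when
        # T2 lands exactly on the critical value
        return self.t2 >= T2_CRITICAL_5PCT - 1e-9

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["reject_5pct"] = self.reject_5pct
        d["critical_value"] = T2_CRITICAL_5PCT
        return d


@dataclass
class PiWindow:
    contig: str
    start: int
    end: int
    n_snps: int
    pi: float


def site_diversity(gm: GenotypeMatrix, hwe: bool = True) -> pd.DataFrame:
    """Per-site MAF, H_O, H_E = 2p(1-p), delta = H_O - H_E and (optionally)
    the exact HWE p-value.

    All-missing sites are excluded; their count is available on the result as
    ``df.attrs["n_all_missing"]``.
    """
    present = gm.dosages != MISSING
    n_called = present.sum(axis=0)
    usable = n_called > 0
    dos = gm.dosages[:, usable]
    present = present[:, usable]
    n_called = n_called[usable]

    n_het = ((dos == 1) & present).sum(axis=0)
    alt = np.where(present, dos, 0).sum(axis=0)
    p = alt / (2.0 * n_called)
    h_obs = n_het / n_called
    h_exp = 2.0 * p * (1.0 - p)

    df = pd.DataFrame(
        {
            "contig": gm.variants["contig"].to_numpy()[usable],
            "pos": gm.variants["pos"].to_numpy()[usable],
            "n_called": n_called,
            "maf": np.minimum(p, 1.0 - p),
            "h_obs": h_obs,
            "h_exp": h_exp,
            "delta": h_obs - h_exp,
        }
    )
    if hwe:
        df["hwe_p"] = hwe_test_sites(dos)
    df.attrs["n_all_missing"] = int((~usable).sum())
    return df


def nucleotide_diversity_windows(
    gm: GenotypeMatrix, window_bp: int = 10_000
) -> pd.DataFrame:
    """Nucleotide diversity in fixed, non-overlapping windows tiling each
    contig from position 1.

    Per window, pi = sum_sites [2 c_ref c_alt / (n_chr (n_chr - 1))] /
    window_bp, i.e. the mean pairwise difference per base; the site term is
    the unbiased heterozygosity over the 2n sampled chromosomes. Windows with
    no SNP have pi = 0; every window, including the last partial one, is
    normalized by the full nominal width.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    present = gm.dosages != MISSING
    n_chr = 2.0 * present.sum(axis=0)
    c_alt = np.where(present, gm.dosages, 0).sum(axis=0)
    c_ref = n_chr - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(
            n_chr >= 2, 2.0 * c_ref * c_alt / (n_chr * (n_chr - 1.0)), 0.0
        )

    contigs = gm.variants["contig"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    rows = []
    for contig in dict.fromkeys(contigs):
        m = contigs == contig
        cpos = pos[m]
        cpi = site_pi[m]
        win = (cpos - 1) // window_bp
        n_windows = int(win.max()) + 1
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows, dtype=int)
        np.add.at(sums, win, cpi)
        np.add.at(counts, win, 1)
        for w in range(n_windows):
            rows.append(
                (
                    contig,
                    w * window_bp + 1,
                    (w + 1) * window_bp,
                    int(counts[w]),
                    sums[w] / window_bp,
                )
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps", "pi"])


def bottleneck_t2(
    sites: pd.DataFrame,
    n_samples: int,
    sigma: str = "analytic",
    form: str = "standardized",
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
) -> BottleneckResult:
    """Standardized-difference heterozygosity-excess test.

    ``sites`` needs columns ``h_obs`` and ``h_exp`` (as from
    :func:`site_diversity`). Loci fixed in the sample (H_E = 0) carry no
    information and are excluded from L. ``form="sqrt"`` reproduces the
    alternative printed form sum(delta_l * sqrt(sigma_l)) / sqrt(L) instead
    of the standardized sum.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    h_obs = np.asarray(sites["h_obs"], dtype=float)
    h_exp = np.asarray(sites["h_exp"], dtype=float)

    n_chr = 2.0 * n_samples
    h_exp_u = h_exp * n_chr / (n_chr - 1.0)  # unbiased expected heterozygosity
    if sigma == "analytic":
        sig = h_exp_u / np.sqrt(n_samples)
    elif sigma == "binomial":
        sig = np.sqrt(h_exp_u * (1.0 - h_exp_u) / n_samples)
    elif sigma == "mc":
        sig = _mc_sigma(h_exp, n_samples, n_mc, rng)
    else:
        raise ValueError(f"unknown sigma mode {sigma!r}")

    keep = sig > 0
    n_loci = int(keep.sum())
    if n_loci == 0:
        raise UndefinedStatisticError(
            "T2 undefined: every locus is fixed in the sample"
        )
    delta = h_obs[keep] - h_exp_u[keep]
    if form == "standardized":
        t2 = float((delta / sig[keep]).sum() / np.sqrt(n_loci))
    elif form == "sqrt":
        t2 = float((delta * np.sqrt(sig[keep])).sum() / np.sqrt(n_loci))
    else:
        raise ValueError(f"unknown form {form!r}")
    p = float(stats.norm.sf(t2))
    return BottleneckResult(
        t2=t2,
        n_loci=n_loci,
        p_one_sided=p,
        sigma_mode=sigma,
        mean_sigma=float(sig[keep].mean()),
    )


def _mc_sigma(
    h_exp: np.ndarray,
    n_samples: int,
    n_mc: int,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Monte-Carlo null SD of delta: resample HWE genotype counts at the
    estimated allele frequency and recompute delta with re-estimated p."""
    rng = np.random.default_rng(0) if rng is None else rng
    p = 0.5 * (1.0 - np.sqrt(np.maximum(0.0, 1.0 - 2.0 * h_exp)))
    L = len(p)
    sig = np.zeros(L)
    poly = (p > 0) & (p < 1)
    probs = np.stack(
        [(1 - p[poly]) ** 2, 2 * p[poly] * (1 - p[poly]), p[poly] ** 2], axis=1
    )
    n_chr = 2.0 * n_samples
    deltas = np.empty((n_mc, int(poly.sum())))
    for r in range(n_mc):
        counts = rng.multinomial(n_samples, probs)
        het = counts[:, 1] / n_samples
        phat = (counts[:, 1] + 2 * counts[:, 2]) / n_chr
        deltas[r] = het - 2.0 * phat * (1.0 - phat) * n_chr / (n_chr - 1.0)
    sig[poly] = deltas.std(axis=0, ddof=1)
    return sig


def heterozygosity_summary(sites: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and median of MAF, H_O, H_E and delta across sites,
    plus the proportion of sites with positive delta (``df.attrs``)."""
    if len(sites) == 0:
        raise UndefinedStatisticError("summary undefined over zero sites")
    cols = ["maf", "h_obs", "h_exp", "delta"]
    out = pd.DataFrame(
        {
            "mean": [sites[c].mean() for c in cols],
            "sd": [sites[c].std(ddof=1) if len(sites) > 1 else 0.0 for c in cols],
            "median": [sites[c].median() for c in cols],
        },
        index=cols,
    )
    out.attrs["prop_delta_positive"] = float((sites["delta"] > 0).mean())
    out.attrs["n_sites"] = int(len(sites))
    return out
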