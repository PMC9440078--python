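"""QC filters, exact HWE test against an enumeration oracle, Ts/Tv, pruning."""

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pytest

from packstats.genotype_model import MISSING, UndefinedStatisticError, VariantRecord
from packstats.variant_qc import (
    LDPruneParams,
    QCThresholds,
    apply_filters,
    hwe_exact_test,
    ld_prune,
    site_maf,
    ts_tv_ratio,
)

from conftest import make_gm


# -- independent oracle: exact rational enumeration -------------------------

@lru_cache(maxsize=None)
def _conditional_distribution(n: int, n_alt: int):
    """P(het count | n diploids, n_alt alt alleles) as exact Fractions."""
    weights = {}
    for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - het) // 2
        hom_ref = n - het - hom_alt
        if hom_ref < 0 or hom_alt < 0:
            continue
        weights[het] = Fraction(
            2**het * comb(n, het) * comb(n - het, hom_alt), 1
        )
    total = sum(weights.values())
    return {h: w / total for h, w in weights.items()}


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    dist = _conditional_distribution(n, min(n_alt, 2 * n - n_alt))
    p_obs = dist[n_het]
    return float(sum(p for p in dist.values() if p <= p_obs))


class TestHweExactTest:
    def test_monomorphic_site_has_p_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(0, 10, 0), (57, 28, 15), (5, 5, 5), (1, 0, 1), (20, 2, 20)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_oracle(*counts), abs=1e-12
        )

    def test_all_configurations_up_to_total_30(self):
        for n in range(1, 31):
            for het in range(n + 1):
                for hom_alt in range(n - het + 1):
                    counts = (n - het - hom_alt, het, hom_alt)
                    assert hwe_exact_test(*counts) == pytest.approx(
                        hwe_oracle(*counts), abs=1e-12
                    ), counts

    def test_zero_total_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            hwe_exact_test(0, 0, 0)


class TestSiteMaf:
    @pytest.mark.parametrize(
        "dosages,expected",
        [((2, 2, 2, 2), 0.0), ((0, 1, 1, 2), 0.5), ((0, 0, 0, 1), 0.125)],
    )
    def test_known_values(self, dosages, expected):
        assert site_maf(np.array(dosages)) == pytest.approx(expected)

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            site_maf(np.array([MISSING, MISSING]))


class TestApplyFilters:
    def test_each_filter_claims_its_site_once(self):
        # 6 sites: qual-fail, call-fail, HWE-fail, MAF-fail, two survivors
        n = 20
        good = np.tile([0, 1, 2, 1], n // 4)
        hwe_bad = np.tile([0, 2], n // 2)  # no hets at p=0.5
        rare = np.zeros(n, dtype=int)
        rare[0] = 1  # MAF 1/40 = 0.025
        call_bad = good.copy()
        call_bad[3] = MISSING
        dos = np.stack([good, call_bad, hwe_bad, rare, good, good], axis=1)
        quals = np.array([30.0, 60, 60, 60, 60, 60])  # site 0 fails at equality
        gm = make_gm(dos, quals=quals)
        out, rep = apply_filters(gm, QCThresholds())
        assert rep.n_input == 6 and rep.n_retained == 2 == out.n_variants
        assert (
            rep.n_removed_qual,
            rep.n_removed_call,
            rep.n_removed_hwe,
            rep.n_removed_maf,
        ) == (1, 1, 1, 1)

    def test_maf_exactly_at_threshold_is_removed(self):
        n = 20  # one het in 20 samples -> MAF 0.025; 2 hets -> 0.05
        dos = np.zeros((n, 1), dtype=int)
        dos[:2, 0] = 1  # MAF exactly 0.05
        out, rep = apply_filters(make_gm(dos), QCThresholds(min_maf=0.05))
        assert rep.n_removed_maf == 1 and out.n_variants == 0

    def test_idempotent(self, rng):
        dos = rng.integers(0, 3, (30, 40))
        out1, _ = apply_filters(make_gm(dos))
        out2, rep2 = apply_filters(out1)
        assert out2.n_variants == out1.n_variants
        assert rep2.n_retained == rep2.n_input


class TestTsTv:
    def test_balanced_set_is_one(self):
        variants = [
            VariantRecord("c", 1, "A", "G"),
            VariantRecord("c", 2, "C", "T"),
            VariantRecord("c", 3, "A", "C"),
            VariantRecord("c", 4, "G", "T"),
        ]
        assert ts_tv_ratio(variants) == 1.0

    def test_no_transversion_marker(self):
        assert ts_tv_ratio([VariantRecord("c", 1, "A", "G")]) is None

    def test_counting_oracle_two_to_one(self, rng):
        ts_pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
        tv_pairs = [("A", "C"), ("C", "G"), ("G", "T"), ("T", "A")]
        variants = [
            VariantRecord("c", i + 1, *ts_pairs[i % 4]) for i in range(66)
        ] + [
            VariantRecord("c", 100 + i, *tv_pairs[i % 4]) for i in range(33)
        ]
        assert ts_tv_ratio(variants) == pytest.approx(2.0)

    def test_empty_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ts_tv_ratio([])


class TestLdPrune:
    def test_duplicate_column_loses_exactly_one(self, rng):
        base = rng.integers(0, 3, (50, 1))
        dos = np.hstack([base, base, rng.integers(0, 3, (50, 8))])
        out, removed = ld_prune(make_gm(dos), LDPruneParams(10, 5, 0.5))
        kept_pos = set(out.variants["pos"])
        assert (1000 in kept_pos) ^ (2000 in kept_pos)

    def test_independent_sites_mostly_survive(self, rng):
        p = rng.uniform(0.2, 0.5, 25)
        dos = (rng.random((200, 25)) < p).astype(int) + (
            rng.random((200, 25)) < p
        ).astype(int)
        out, removed = ld_prune(make_gm(dos), LDPruneParams(25, 5, 0.5))
        assert len(removed) == 0

    def test_three_site_window_one_high_r2_pair(self, rng):
        a = rng.integers(0, 3, 100)
        b = a.copy()
        b[:5] = (b[:5] + 1) % 3  # r2(a,b) high
        c = rng.permutation(a)  # r2 with a,b low
        out, removed = ld_prune(
            make_gm(np.stack([a, b, c], axis=1)), LDPruneParams(3, 1, 0.5)
        )
        assert len(removed) == 1 and out.n_variants == 2

    def test_threshold_one_removes_only_exact_duplicates(self, rng):
        a = rng.integers(0, 3, 80)
        b = a.copy()
        b[:10] = (b[:10] + 1) % 3  # correlated but not collinear
        dup = a.copy()
        dos = np.stack([a, b, dup], axis=1)
        out, removed = ld_prune(make_gm(dos), LDPruneParams(3, 1, 1.0))
        assert len(removed) == 1

    def test_no_retained_window_pair_above_threshold(self, rng):
        # post-hoc audit on a matrix with heavy planted LD
        base = rng.integers(0, 3, (60, 6))
        cols = [base[:, i % 6].copy() for i in range(30)]
        for i, c in enumerate(cols):
            flips = rng.random(60) < 0.1
            c[flips] = rng.integers(0, 3, flips.sum())
        dos = np.stack(cols, axis=1)
        params = LDPruneParams(10, 3, 0.4)
        out, _ = ld_prune(make_gm(dos), params)
        d = out.dosages.astype(float)
        live = np.arange(out.n_variants)
        for start in range(0, max(1, out.n_variants), params.step_snps):
            w = live[start : start + params.window_snps]
            if len(w) < 2:
                continue
            sd = d[:, w].std(axis=0)
            ok = sd > 0
            if ok.sum() < 2:
                continue
            r2 = np.corrcoef(d[:, w[ok]].T) ** 2
            np.fill_diagonal(r2, 0)
            assert r2.max() <= params.r2_threshold + 1e-9

    def test_zero_variance_site_survives(self, rng):
        dos = rng.integers(0, 3, (40, 5))
        dos[:, 2] = 1  # constant
        out, removed = ld_prune(make_gm(dos), LDPruneParams(5, 2, 0.5))
        assert 3000 in set(out.variants["pos"])
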