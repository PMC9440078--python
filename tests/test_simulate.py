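"""Synthetic-cohort generator: determinism, spectra, drift, gene dropping."""

import numpy as np
import pandas as pd
import pytest

from packstats.genotype_model import read_vcf
from packstats.simulate import (
    BottleneckConfig,
    ConfigError,
    Mating,
    SimConfig,
    apply_bottleneck,
    emit_cohort,
    expected_pi_hat,
    gene_drop,
    study_cohort_config,
    realized_tracts,
    simulate_cohort,
    simulate_founders,
    to_genotype_matrix,
)


class TestDeterminism:
    def test_same_seed_same_output(self):
        cfg = SimConfig(seed=7, n_founders=8, n_snps=500)
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        assert all(
            np.array_equal(a.haplotypes[s], b.haplotypes[s])
            for s in a.individuals
        )
        assert a.variants.equals(b.variants)

    def test_seed_changes_genotypes_not_dimensions(self, tmp_path):
        p1 = emit_cohort(SimConfig(seed=1, n_founders=6, n_snps=300), tmp_path / "a")
        p2 = emit_cohort(SimConfig(seed=2, n_founders=6, n_snps=300), tmp_path / "b")
        a, b = read_vcf(p1.vcf), read_vcf(p2.vcf)
        assert a.dosages.shape == b.dosages.shape
        assert not np.array_equal(a.dosages, b.dosages)

    def test_emitted_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimConfig(seed=5, n_founders=6, n_snps=300)
        pa = emit_cohort(cfg, tmp_path / "a")
        pb = emit_cohort(cfg, tmp_path / "b")
        assert pa.vcf.read_bytes() == pb.vcf.read_bytes()
        assert pa.sample_table.read_bytes() == pb.sample_table.read_bytes()


class TestFounders:
    def test_mean_h_exp_matches_analytic_expectation(self):
        # E[2p(1-p)] for MAF ~ U(0.05, 0.5)
        cfg = SimConfig(seed=3, n_founders=200, n_snps=20_000)
        cohort = simulate_founders(cfg)
        gm = to_genotype_matrix(cohort)
        from packstats.diversity import site_diversity

        h = site_diversity(gm, hwe=False).h_exp.mean()
        lo, hi = 0.05, 0.5
        # E[2pq] = 2(E[p] - E[p^2]) with p uniform on the MAF interval
        ep = (lo + hi) / 2
        ep2 = (hi**3 - lo**3) / (3 * (hi - lo))
        expected = 2 * (ep - ep2)
        assert h == pytest.approx(expected, abs=0.01)

    def test_infeasible_snp_density_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_snps=1000, n_contigs=1, contig_length_bp=800)


class TestBottleneck:
    def test_zero_generations_is_identity(self):
        cfg = SimConfig(
            seed=4, n_founders=10, n_snps=400,
            bottleneck=BottleneckConfig(post_size=10, generations=0),
        )
        cohort = simulate_founders(cfg)
        assert apply_bottleneck(cohort) is cohort

    def test_drifted_frequency_variance_matches_wright_fisher(self):
        # Var(p_t) ~= p0 q0 (1 - (1 - 1/2N)^t) for unconditioned drift
        rng = np.random.default_rng(8)
        p0, N, t, reps = 0.5, 50, 4, 4000
        p = np.full(reps, p0)
        for _ in range(t):
            p = rng.binomial(2 * N, p) / (2 * N)
        expected = p0 * (1 - p0) * (1 - (1 - 1 / (2 * N)) ** t)
        assert p.var() == pytest.approx(expected, rel=0.1)

    def test_severe_bottleneck_creates_detectable_excess(self):
        from packstats.diversity import bottleneck_t2, site_diversity
        from packstats.simulate import severe_bottleneck_config

        _, gm, _ = simulate_cohort(severe_bottleneck_config(seed=6, n_snps=5000))
        res = bottleneck_t2(site_diversity(gm, hwe=False), gm.n_samples)
        assert res.reject_5pct

    def test_sites_stay_polymorphic(self):
        _, gm, truth = simulate_cohort(
            SimConfig(seed=9, n_founders=30, n_snps=2000,
                      bottleneck=BottleneckConfig(post_size=4, generations=8))
        )
        p = truth.freqs["p"].to_numpy()
        assert ((p > 0) & (p < 1)).all()


class TestGeneDrop:
    def test_mendelian_consistency(self):
        matings = [Mating("F000", "F001", "kid"), Mating("kid", "F002", "gkid")]
        cfg = SimConfig(seed=10, n_founders=4, n_snps=2000, pedigree=matings)
        cohort, gm, _ = simulate_cohort(cfg)
        for child, (sire, dam) in cohort.pedigree.items():
            ch = cohort.haplotypes[child]
            for k, parent in enumerate((sire, dam)):
                ph = cohort.haplotypes[parent]
                ok = (ch[k] == ph[0]) | (ch[k] == ph[1])
                assert ok.all()

    def test_parent_offspring_truth_pi_hat(self):
        ped = {"kid": ("a", "b")}
        truth = expected_pi_hat(ped, ["a", "b", "kid"])
        d = dict(zip(zip(truth.id1, truth.id2), truth.pi_hat))
        assert d[("a", "kid")] == 0.5 and d[("b", "kid")] == 0.5
        assert ("a", "b") not in d

    def test_full_sib_mating_truth_values(self):
        ped = {
            "s1": ("a", "b"), "s2": ("a", "b"), "kid": ("s1", "s2"),
        }
        truth = expected_pi_hat(ped, ["s1", "s2", "kid"])
        d = dict(zip(zip(truth.id1, truth.id2), truth.pi_hat))
        assert d[("s1", "s2")] == 0.5
        # parent-child with inbred child: 2*phi = 2*(0.5*(phi(s1,s1)+phi(s1,s2)))
        assert d[("s1", "kid")] == pytest.approx(0.75)

    def test_cyclic_pedigree_rejected(self):
        ped = [Mating("x", "F000", "y"), Mating("y", "F001", "x")]
        cfg = SimConfig(seed=1, n_founders=2, n_snps=200, pedigree=ped)
        with pytest.raises(ConfigError):
            simulate_cohort(cfg)

    def test_no_recombination_makes_whole_contig_tracts(self):
        matings = [
            Mating("F000", "F001", "s1"),
            Mating("F000", "F001", "s2"),
            Mating("s1", "s2", "kid"),
        ]
        cfg = SimConfig(
            seed=12, n_founders=2, n_snps=1000, n_contigs=2,
            recomb_rate_cm_per_mb=0.0, pedigree=matings,
        )
        cohort, gm, _ = simulate_cohort(cfg)
        tracts = realized_tracts(cohort, ["kid"])
        contigs = gm.variants["contig"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        for _, t in tracts.iterrows():
            cpos = pos[contigs == t.contig]
            assert (t.start, t.end) == (cpos.min(), cpos.max())

    def test_marker_density_only_refines_ibd_measurement(self):
        # on one fixed gene drop, the autozygous genome fraction measured
        # from a 10x-thinned marker set agrees with the dense measurement:
        # density changes resolution, not the underlying IBD mosaic
        matings = [
            Mating("F000", "F001", "s1"),
            Mating("F000", "F001", "s2"),
        ] + [Mating("s1", "s2", f"k{i}") for i in range(8)]
        cfg = SimConfig(seed=21, n_founders=2, n_snps=20_000, pedigree=matings)
        cohort, _, _ = simulate_cohort(cfg)
        kids = [f"k{i}" for i in range(8)]
        dense = np.array(
            [np.mean(cohort.ancestry[k][0] == cohort.ancestry[k][1]) for k in kids]
        )
        thin = np.array(
            [
                np.mean(
                    cohort.ancestry[k][0, ::10] == cohort.ancestry[k][1, ::10]
                )
                for k in kids
            ]
        )
        assert np.allclose(dense, thin, atol=0.02)
        # and the family mean sits near the pedigree expectation of 0.25
        assert abs(dense.mean() - 0.25) < 0.1


class TestStudyCohortPreset:
    def test_preset_dimensions(self, tmp_path):
        paths = emit_cohort(study_cohort_config(seed=2, n_snps=4000), tmp_path)
        table = pd.read_csv(paths.sample_table, sep="\t")
        assert len(table) == 71
        assert table.pack_id.nunique() == 24
        assert set(table.region) == {"north", "central", "south"}

    def test_exactly_three_first_degree_truth_pairs(self, study_cohort_run):
        _, gm, truth = study_cohort_run
        strong = truth.expected_pi_hat[truth.expected_pi_hat.pi_hat >= 0.5]
        assert len(strong) == 3
        ids = set(gm.sample_ids)
        assert all(a in ids and b in ids for a, b in zip(strong.id1, strong.id2))

    def test_planted_first_degree_pairs_recovered(self, study_cohort_run):
        from packstats.relatedness import estimate_ibd

        _, gm, truth = study_cohort_run
        pairs = estimate_ibd(gm)
        high = {
            frozenset((p.id1, p.id2)) for p in pairs if p.pi_hat >= 0.4
        }
        expected = {
            frozenset((a, b))
            for a, b in zip(truth.expected_pi_hat.id1, truth.expected_pi_hat.id2)
            if a in set(gm.sample_ids) and b in set(gm.sample_ids)
        }
        assert high == expected
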