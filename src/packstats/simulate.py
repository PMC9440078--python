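"""Synthetic cohorts with known truth for every pipeline stage.

The generator produces the statistical structure the analysis assumes, at a
deliberately reduced scale (a few contigs, tens of thousands of SNPs):

* a founder population with a parametric site-frequency spectrum
  (MAF ~ Uniform by default), genotypes in HWE;
* an optional population bottleneck: allele frequencies drift by Wright-
  Fisher binomial resampling for a configured number of generations at the
  post-bottleneck size (conditioned on the site staying polymorphic, so rare
  alleles are preferentially lost), after which the cohort's paternal and
  maternal alleles are drawn from two finite breeding pools of the
  post-bottleneck size. The finite pools make observed heterozygosity exceed
  the Hardy-Weinberg expectation computed from cohort-estimated frequencies
  by about H_E/(2*pool size) - the transient signature a bottleneck test
  detects - as a mechanical property of the genotypes;
* a pedigree gene-dropped with recombination (Haldane map, no interference,
  default 1 cM/Mb): offspring haplotypes are crossover mosaics of parental
  haplotypes, founder-haplotype ancestry is tracked per SNP, and offspring of
  consanguineous matings therefore carry genuine autozygous tracts;
* optionally, directly planted autozygous tracts (one haplotype copied over
  the other across an interval), recorded in the truth tables.

Truth tables carry pedigree-expected PI-HAT (2 x kinship by path counting),
realized autozygous tracts (from ancestry equality), and per-site generating
frequencies. Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_model import (
    GenotypeMatrix,
    SampleRecord,
    write_sample_table,
    write_vcf,
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BottleneckConfig:
    """Pre-bottleneck size is implicit in the founder frequencies; drift runs
    ``generations`` rounds at ``post_size`` diploids (2*post_size alleles)."""

    post_size: int = 10
    generations: int = 5

    def __post_init__(self) -> None:
        if self.post_size < 2:
            raise ConfigError("post-bottleneck size must be >= 2")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")


@dataclass(frozen=True)
class Mating:
    sire: str
    dam: str
    child: str


@dataclass
class SimConfig:
    seed: int = 0
    n_founders: int = 40
    n_contigs: int = 5
    contig_length_bp: int = 50_000_000
    n_snps: int = 20_000
    founder_maf: tuple[float, float] = (0.05, 0.5)
    ts_fraction: float = 2.0 / 3.0  # transition share of REF->ALT draws
    bottleneck: BottleneckConfig | None = None
    pedigree: list[Mating] = field(default_factory=list)
    recomb_rate_cm_per_mb: float = 1.0
    cohort: list[str] | None = None  # individuals emitted; default: everyone
    #: mean number of short ancient-consanguinity autozygous tracts planted
    #: per cohort sample (Poisson), with lengths uniform on ancient_roh_kb
    ancient_roh_per_sample: float = 0.0
    ancient_roh_kb: tuple[float, float] = (550.0, 1000.0)
    n_packs: int = 24
    #: fraction of samples per region, in (north, central, south) order
    region_split: tuple[float, float, float] = (13 / 71, 21 / 71, 37 / 71)

    def __post_init__(self) -> None:
        per_contig = self.n_snps // self.n_contigs
        if per_contig > self.contig_length_bp // 2:
            raise ConfigError("contig too short for the requested SNP count")
        ids = [m.child for m in self.pedigree]
        if len(set(ids)) != len(ids):
            raise ConfigError("pedigree children must be unique")


@dataclass
class TruthTables:
    """Ground truth: pedigree-expected PI-HAT per pair, realized autozygous
    tracts per sample, generating allele frequency per site."""

    expected_pi_hat: pd.DataFrame  # id1, id2, pi_hat (pairs with pi_hat > 0)
    tracts: pd.DataFrame  # sample_id, contig, start, end, n_snps
    freqs: pd.DataFrame  # contig, pos, p


@dataclass
class SimulatedCohort:
    """Haplotype-resolved simulated individuals.

    ``haplotypes[sample]`` is a (2, n_snps) 0/1 array of alt alleles;
    ``ancestry[sample]`` holds the founder-haplotype id each allele descends
    from, which is what defines autozygosity (both haplotypes sharing an
    ancestral id over an interval).
    """

    cfg: SimConfig
    variants: pd.DataFrame  # contig, pos, ref, alt, qual
    freqs: np.ndarray  # generating alt-allele frequency per site
    haplotypes: dict[str, np.ndarray]
    ancestry: dict[str, np.ndarray]
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.haplotypes)

    def contig_sites(self) -> dict[str, np.ndarray]:
        contigs = self.variants["contig"].to_numpy()
        return {c: np.flatnonzero(contigs == c) for c in dict.fromkeys(contigs)}


def founder_id(i: int) -> str:
    return f"F{i:03d}"


def simulate_founders(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Draw founder haplotypes site-wise from the configured MAF spectrum.

    Generating frequencies are uniform on the MAF bounds, with the minor
    allele assigned to REF or ALT with equal probability, so alt frequencies
    cover both tails.
    """
    if cfg.n_founders < 1:
        raise ConfigError("need at least one founder")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    variants = _draw_variants(cfg, rng)
    maf = rng.uniform(*cfg.founder_maf, cfg.n_snps)
    flip = rng.random(cfg.n_snps) < 0.5
    p = np.where(flip, 1.0 - maf, maf)

    haplotypes: dict[str, np.ndarray] = {}
    ancestry: dict[str, np.ndarray] = {}
    for i in range(cfg.n_founders):
        hap = (rng.random((2, cfg.n_snps)) < p).astype(np.uint8)
        anc = np.empty((2, cfg.n_snps), dtype=np.int32)
        anc[0] = 2 * i
        anc[1] = 2 * i + 1
        haplotypes[founder_id(i)] = hap
        ancestry[founder_id(i)] = anc
    return SimulatedCohort(
        cfg=cfg, variants=variants, freqs=p, haplotypes=haplotypes,
        ancestry=ancestry,
    )


def _draw_variants(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_contig = cfg.n_snps // cfg.n_contigs
    counts = [per_contig] * cfg.n_contigs
    counts[-1] += cfg.n_snps - per_contig * cfg.n_contigs
    rows = []
    bases = np.array(list("ACGT"))
    for c in range(cfg.n_contigs):
        name = f"contig{c + 1}"
        pos = np.sort(
            rng.choice(cfg.contig_length_bp, size=counts[c], replace=False) + 1
        )
        ref = bases[rng.integers(0, 4, counts[c])]
        is_ts = rng.random(counts[c]) < cfg.ts_fraction
        pick = rng.integers(0, 2, counts[c])
        for j in range(counts[c]):
            alt = (
                _TRANSITION[ref[j]]
                if is_ts[j]
                else _TRANSVERSIONS[ref[j]][pick[j]]
            )
            rows.append((name, int(pos[j]), ref[j], alt, float(rng.integers(31, 100))))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])


def apply_bottleneck(
    cohort: SimulatedCohort, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Drift site frequencies through the bottleneck and redraw founder
    haplotypes from two finite parental pools at the drifted frequencies.

    Returns the input unchanged when no bottleneck is configured or the
    generation count is zero. Sites are conditioned on remaining polymorphic
    through the drift (trajectories for fixed sites are resampled), which
    preferentially discards low-MAF sites, as a real bottleneck does.
    """
    bn = cohort.cfg.bottleneck
    if bn is None or bn.generations == 0:
        return cohort
    rng = (
        np.random.default_rng(cohort.cfg.seed + 1_000_003)
        if rng is None
        else rng
    )
    n_alleles = 2 * bn.post_size
    p = cohort.freqs.copy()
    p_t = np.empty_like(p)
    todo = np.ones(len(p), dtype=bool)
    for _ in range(200):  # rejection rounds for the polymorphism condition
        if not todo.any():
            break
        pt = p[todo]
        for _g in range(bn.generations):
            pt = rng.binomial(n_alleles, pt) / n_alleles
        ok = (pt > 0.0) & (pt < 1.0)
        idx = np.flatnonzero(todo)
        p_t[idx[ok]] = pt[ok]
        todo[idx[ok]] = False
    # a site whose trajectories keep fixing retains its pre-drift frequency
    p_t[todo] = p[todo]

    # two parental allele pools of the post-bottleneck size
    pool_m = rng.binomial(n_alleles, p_t) / n_alleles
    pool_f = rng.binomial(n_alleles, p_t) / n_alleles
    haplotypes = {}
    for sid in cohort.individuals:
        pat = (rng.random(len(p_t)) < pool_m).astype(np.uint8)
        mat = (rng.random(len(p_t)) < pool_f).astype(np.uint8)
        haplotypes[sid] = np.stack([pat, mat])
    return SimulatedCohort(
        cfg=cohort.cfg,
        variants=cohort.variants,
        freqs=p_t,
        haplotypes=haplotypes,
        ancestry={s: a.copy() for s, a in cohort.ancestry.items()},
        pedigree=dict(cohort.pedigree),
    )


def gene_drop(
    cohort: SimulatedCohort, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Create every pedigree child by recombining its parents' haplotypes.

    Crossover counts per meiosis and contig are Poisson with mean equal to
    the map length (Haldane, ``recomb_rate_cm_per_mb``), positions uniform.
    Children may themselves be parents of later matings; a mating whose
    parents do not yet exist is an error.
    """
    cfg = cohort.cfg
    rng = np.random.default_rng(cfg.seed + 2_000_003) if rng is None else rng
    sites = cohort.contig_sites()
    pos = cohort.variants["pos"].to_numpy()
    out = SimulatedCohort(
        cfg=cfg,
        variants=cohort.variants,
        freqs=cohort.freqs,
        haplotypes=dict(cohort.haplotypes),
        ancestry={s: a.copy() for s, a in cohort.ancestry.items()},
        pedigree=dict(cohort.pedigree),
    )
    for mating in cfg.pedigree:
        for parent in (mating.sire, mating.dam):
            if parent not in out.haplotypes:
                raise ConfigError(
                    f"mating for {mating.child!r}: unknown parent {parent!r}"
                )
        if mating.child in out.haplotypes:
            raise ConfigError(f"duplicate individual {mating.child!r}")
        hap = np.empty((2, cfg.n_snps), dtype=np.uint8)
        anc = np.empty((2, cfg.n_snps), dtype=np.int32)
        for k, parent in enumerate((mating.sire, mating.dam)):
            chooser = _meiosis_chooser(cfg, sites, pos, rng)
            hap[k] = np.take_along_axis(
                out.haplotypes[parent], chooser[None, :], axis=0
            )[0]
            anc[k] = np.take_along_axis(
                out.ancestry[parent], chooser[None, :], axis=0
            )[0]
        out.haplotypes[mating.child] = hap
        out.ancestry[mating.child] = anc
        out.pedigree[mating.child] = (mating.sire, mating.dam)
    return out


def _meiosis_chooser(
    cfg: SimConfig,
    sites: dict[str, np.ndarray],
    pos: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Which parental haplotype (0/1) each transmitted SNP comes from."""
    chooser = np.empty(cfg.n_snps, dtype=np.int64)
    map_len = (
        cfg.contig_length_bp / 1e6 * cfg.recomb_rate_cm_per_mb / 100.0
    )  # Morgans
    for idx in sites.values():
        start = rng.integers(0, 2)
        n_cross = rng.poisson(map_len)
        if n_cross:
            cuts = np.sort(rng.uniform(0, cfg.contig_length_bp, n_cross))
            chooser[idx] = (start + np.searchsorted(cuts, pos[idx])) % 2
        else:
            chooser[idx] = start
    return chooser


def plant_tract(
    cohort: SimulatedCohort, sample_id: str, contig: str, start: int, end: int
) -> None:
    """Force autozygosity over [start, end] bp on one contig by copying the
    first haplotype (alleles and ancestry) over the second, in place."""
    if sample_id not in cohort.haplotypes:
        raise ConfigError(f"unknown sample {sample_id!r}")
    contigs = cohort.variants["contig"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    m = (contigs == contig) & (pos >= start) & (pos <= end)
    if not m.any():
        raise ConfigError(f"no SNP in {contig}:{start}-{end}")
    cohort.haplotypes[sample_id][1, m] = cohort.haplotypes[sample_id][0, m]
    cohort.ancestry[sample_id][1, m] = cohort.ancestry[sample_id][0, m]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def expected_pi_hat(
    pedigree: dict[str, tuple[str, str]], ids: list[str]
) -> pd.DataFrame:
    """Pedigree-expected PI-HAT (2 x kinship, path counting) for every pair
    among ``ids`` with a positive expectation."""
    order = {s: i for i, s in enumerate(_topological(pedigree, ids))}
    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        if a == b:
            if a in pedigree:
                return 0.5 * (1.0 + phi(*pedigree[a]))
            return 0.5
        key = (a, b) if order[a] >= order[b] else (b, a)
        if key in cache:
            return cache[key]
        younger, other = key
        if younger in pedigree:
            s, d = pedigree[younger]
            val = 0.5 * (phi(s, other) + phi(d, other))
        else:
            val = 0.0
        cache[key] = val
        return val

    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = 2.0 * phi(a, b)
            if v > 0:
                rows.append((a, b, v))
    return pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])


def _topological(
    pedigree: dict[str, tuple[str, str]], ids: list[str]
) -> list[str]:
    seen: list[str] = []
    mark: dict[str, int] = {}

    def visit(x: str) -> None:
        state = mark.get(x, 0)
        if state == 1:
            raise ConfigError(f"cyclic pedigree at {x!r}")
        if state == 2:
            return
        mark[x] = 1
        if x in pedigree:
            visit(pedigree[x][0])
            visit(pedigree[x][1])
        mark[x] = 2
        seen.append(x)

    for x in list(pedigree) + ids:
        visit(x)
    return seen


def realized_tracts(
    cohort: SimulatedCohort, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Autozygous tracts per sample: maximal runs of SNPs whose two
    haplotypes descend from the same founder haplotype (SNP-anchored bp
    coordinates)."""
    if sample_ids is None:
        sample_ids = cohort.individuals
    contigs = cohort.variants["contig"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    rows = []
    for sid in sample_ids:
        anc = cohort.ancestry[sid]
        auto = anc[0] == anc[1]
        for contig, idx in cohort.contig_sites().items():
            a = auto[idx]
            if not a.any():
                continue
            edges = np.flatnonzero(
                np.diff(np.concatenate([[0], a.astype(np.int8), [0]]))
            )
            for s, e in zip(edges[::2], edges[1::2]):
                rows.append(
                    (
                        sid,
                        contig,
                        int(pos[idx[s]]),
                        int(pos[idx[e - 1]]),
                        int(e - s),
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "contig", "start", "end", "n_snps"]
    )


def truth_tables(
    cohort: SimulatedCohort, sample_ids: list[str] | None = None
) -> TruthTables:
    if sample_ids is None:
        sample_ids = cohort.individuals
    return TruthTables(
        expected_pi_hat=expected_pi_hat(cohort.pedigree, sample_ids),
        tracts=realized_tracts(cohort, sample_ids),
        freqs=pd.DataFrame(
            {
                "contig": cohort.variants["contig"],
                "pos": cohort.variants["pos"],
                "p": cohort.freqs,
            }
        ),
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def assign_packs(
    ids: list[str], cfg: SimConfig
) -> list[SampleRecord]:
    """Contiguous blocks of samples form packs; contiguous blocks of packs
    form the three regions with the configured split (children inherit the
    cohort position they are listed at)."""
    n = len(ids)
    n_packs = min(cfg.n_packs, n)
    pack_of = [min(i * n_packs // n, n_packs - 1) for i in range(n)]
    f_north, f_central, _ = cfg.region_split
    north_packs = max(1, round(n_packs * f_north))
    central_packs = max(1, round(n_packs * f_central))
    records = []
    for i, sid in enumerate(ids):
        pk = pack_of[i]
        if pk < north_packs:
            region = "north"
        elif pk < north_packs + central_packs:
            region = "central"
        else:
            region = "south"
        records.append(SampleRecord(sid, f"pack{pk + 1:02d}", region))
    return records


def to_genotype_matrix(
    cohort: SimulatedCohort, sample_ids: list[str] | None = None
) -> GenotypeMatrix:
    """Collapse haplotypes to a GenotypeMatrix (no missing calls)."""
    if sample_ids is None:
        sample_ids = (
            cohort.cfg.cohort if cohort.cfg.cohort else cohort.individuals
        )
    samples = assign_packs(sample_ids, cohort.cfg)
    dosages = np.stack(
        [cohort.haplotypes[s].sum(axis=0) for s in sample_ids]
    ).astype(np.int8)
    return GenotypeMatrix(samples, cohort.variants, dosages)


def simulate_cohort(cfg: SimConfig) -> tuple[SimulatedCohort, GenotypeMatrix, TruthTables]:
    """Founders -> bottleneck -> gene drop, returning the haplotype-level
    cohort, the emitted GenotypeMatrix and the truth tables."""
    rng = np.random.default_rng(cfg.seed)
    cohort = simulate_founders(cfg, rng)
    cohort = apply_bottleneck(cohort, rng)
    cohort = gene_drop(cohort, rng)
    ids = cfg.cohort if cfg.cohort else cohort.individuals
    missing = [s for s in ids if s not in cohort.haplotypes]
    if missing:
        raise ConfigError(f"cohort lists unknown individuals: {missing[:3]}")
    if cfg.ancient_roh_per_sample > 0:
        _plant_ancient_roh(cohort, ids, rng)
    gm = to_genotype_matrix(cohort, ids)
    return cohort, gm, truth_tables(cohort, ids)


def _plant_ancient_roh(
    cohort: SimulatedCohort, ids: list[str], rng: np.random.Generator
) -> None:
    """Plant the short autozygous tracts left by ancient consanguinity."""
    cfg = cohort.cfg
    for sid in ids:
        for _ in range(rng.poisson(cfg.ancient_roh_per_sample)):
            contig = f"contig{rng.integers(1, cfg.n_contigs + 1)}"
            length = rng.uniform(*cfg.ancient_roh_kb) * 1000.0
            start = int(rng.integers(1, cfg.contig_length_bp - int(length)))
            try:
                plant_tract(cohort, sid, contig, start, start + int(length))
            except ConfigError:
                pass  # interval happened to contain no SNP


@dataclass
class CohortPaths:
    vcf: Path
    sample_table: Path
    truth_pairs: Path
    truth_tracts: Path
    truth_freqs: Path


def emit_cohort(cfg: SimConfig, outdir: str | Path) -> CohortPaths:
    """Write the simulated cohort (VCF + sample table + truth tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, gm, truth = simulate_cohort(cfg)
    paths = CohortPaths(
        vcf=outdir / "cohort.vcf",
        sample_table=outdir / "samples.tsv",
        truth_pairs=outdir / "truth_pairs.tsv",
        truth_tracts=outdir / "truth_tracts.tsv",
        truth_freqs=outdir / "truth_freqs.tsv",
    )
    write_vcf(gm, paths.vcf)
    write_sample_table(gm.samples, paths.sample_table)
    truth.expected_pi_hat.to_csv(paths.truth_pairs, sep="\t", index=False)
    truth.tracts.to_csv(paths.truth_tracts, sep="\t", index=False)
    truth.freqs.to_csv(paths.truth_freqs, sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def study_cohort_config(seed: int = 42, n_snps: int = 20_000) -> SimConfig:
    """The default study-shaped cohort: 71 samples in 24 packs across three
    regions, a severe recent bottleneck, and exactly three first-degree pairs
    (each planted mating keeps one parent outside the cohort)."""
    n_founders = 71
    matings = [
        Mating(sire=founder_id(i), dam=founder_id(68 + i), child=f"C{i:02d}")
        for i in range(3)
    ]
    cohort = [founder_id(i) for i in range(68)] + [m.child for m in matings]
    return SimConfig(
        seed=seed,
        n_founders=n_founders,
        n_snps=n_snps,
        bottleneck=BottleneckConfig(post_size=10, generations=5),
        pedigree=matings,
        cohort=cohort,
        # ~2 short tracts/sample puts ~0.5% of the genome in short ROH,
        # matching the F_ROH scale of a bottlenecked-but-outbred cohort
        ancient_roh_per_sample=2.0,
    )


def severe_bottleneck_config(seed: int = 0, n_snps: int = 20_000) -> SimConfig:
    """Bottleneck power-analysis preset: 71 samples, no pedigree."""
    return SimConfig(
        seed=seed,
        n_founders=71,
        n_snps=n_snps,
        bottleneck=BottleneckConfig(post_size=10, generations=5),
    )
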