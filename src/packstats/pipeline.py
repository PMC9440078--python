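"""End-to-end orchestration: qc -> prune -> diversity/bottleneck -> relate
-> roh/inbreeding -> pca, with per-stage artifacts and a consolidated report.

Stages write their artifacts into the output directory together with a
manifest keyed by a hash of the configuration and input files; a rerun with
unchanged inputs reuses the artifacts instead of recomputing. The report
contains no timestamps, so identical configurations produce byte-identical
reports (wall times go to the log file only).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, relatedness, roh, structure, variant_qc
from .genotype_model import (
    GenotypeMatrix,
    UndefinedStatisticError,
    read_sample_table,
    read_vcf,
)
from .variant_qc import LDPruneParams, QCThresholds, STRINGENT_PRUNE


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str
    sample_table: str | None = None
    outdir: str = "packstats_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    prune: LDPruneParams = field(default_factory=LDPruneParams)
    stringent_prune: LDPruneParams = field(default_factory=lambda: STRINGENT_PRUNE)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    pi_window_bp: int = 10_000
    pca_components: int = 10
    filters_before_prune: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        cfg = asdict(self)
        cfg.pop("outdir")  # where results land must not change what they are
        payload = json.dumps(
            {
                "cfg": _jsonable(cfg),
                "vcf_stat": _file_stat(self.vcf),
                "samples_stat": _file_stat(self.sample_table),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _file_stat(path: str | None):
    if path is None:
        return None
    p = Path(path)
    if not p.exists():
        return None
    st = p.stat()
    return [st.st_size, st.st_mtime_ns]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the consolidated report dict and
    writes ``report.json`` / ``report.txt`` plus per-stage artifacts under
    ``cfg.outdir``. Reruns with an unchanged configuration and inputs return
    the cached report without recomputation."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    manifest = outdir / "manifest.json"
    report_path = outdir / "report.json"
    if manifest.exists() and report_path.exists():
        try:
            if json.loads(manifest.read_text()).get("config_hash") == h:
                return json.loads(report_path.read_text())
        except json.JSONDecodeError:
            pass

    log_path = outdir / "pipeline.log"
    log = open(log_path, "w")

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                log.write(f"{name}\tFAILED\t{exc}\n")
                log.close()
                raise PipelineError(name, str(exc)) from exc
            log.write(f"{name}\tok\t{time.perf_counter() - t0:.2f}s\n")
            return out

        return wrap

    report: dict = {"config_hash": h}

    # -- ingest -------------------------------------------------------------
    def _ingest():
        samples = (
            read_sample_table(cfg.sample_table) if cfg.sample_table else None
        )
        gm = read_vcf(cfg.vcf, require_complete=False, samples=samples)
        if gm.n_variants == 0:
            raise UndefinedStatisticError("no SNP records in input VCF")
        return gm

    gm = stage("ingest")(_ingest)
    report["ingest"] = {
        "n_samples": gm.n_samples,
        "n_variants": gm.n_variants,
        "n_skipped_non_snp": getattr(gm, "n_skipped_non_snp", 0),
    }

    # -- qc and pruning (order configurable) --------------------------------
    def _qc(g):
        return variant_qc.apply_filters(g, cfg.qc)

    def _prune(g, params):
        return variant_qc.ld_prune(g, params)

    if cfg.filters_before_prune:
        gm_f, qc_report = stage("qc")(lambda: _qc(gm))
        gm_pruned, removed = stage("prune")(lambda: _prune(gm_f, cfg.prune))
    else:
        gm_p, removed = stage("prune")(lambda: _prune(gm, cfg.prune))
        gm_pruned, qc_report = stage("qc")(lambda: _qc(gm_p))
    report["qc"] = _jsonable(qc_report.to_dict())
    report["prune"] = {
        "n_removed": len(removed),
        "n_retained": gm_pruned.n_variants,
        "params": _jsonable(asdict(cfg.prune)),
    }
    (outdir / "pruned_out.txt").write_text("\n".join(removed) + ("\n" if removed else ""))

    gm_stringent, removed_s = stage("stringent_prune")(
        lambda: _prune(gm_pruned, cfg.stringent_prune)
    )
    report["stringent_prune"] = {
        "n_retained": gm_stringent.n_variants,
        "params": _jsonable(asdict(cfg.stringent_prune)),
    }

    # -- diversity & bottleneck --------------------------------------------
    def _diversity():
        sites = diversity.site_diversity(gm_pruned)
        sites_str = diversity.site_diversity(gm_stringent, hwe=False)
        pi = diversity.nucleotide_diversity_windows(gm_pruned, cfg.pi_window_bp)
        t2 = diversity.bottleneck_t2(sites_str, gm_stringent.n_samples)
        return sites, sites_str, pi, t2

    sites, sites_str, pi, t2 = stage("diversity")(_diversity)
    sites.to_csv(outdir / "site_diversity.tsv", sep="\t", index=False)
    pi.to_csv(outdir / "pi_windows.tsv", sep="\t", index=False)
    summ = diversity.heterozygosity_summary(sites)
    summ_s = diversity.heterozygosity_summary(sites_str)
    report["diversity"] = {
        "moderate_prune": _summary_dict(summ),
        "stringent_prune": _summary_dict(summ_s),
        "pi_mean": float(pi["pi"].mean()),
        "pi_sd": float(pi["pi"].std(ddof=1)),
    }
    report["bottleneck"] = _jsonable(t2.to_dict())

    # -- relatedness --------------------------------------------------------
    def _relate():
        pairs = relatedness.estimate_ibd(gm_pruned)
        return pairs, relatedness.summarize_relatedness(pairs)

    pairs, rel_summary = stage("relate")(_relate)
    relatedness.pairs_to_frame(pairs).to_csv(
        outdir / "relatedness_pairs.tsv", sep="\t", index=False
    )
    report["relatedness"] = {
        "n_pairs": len(pairs),
        "expected_pairs": relatedness.pair_count(gm_pruned.n_samples),
        "table": json.loads(rel_summary.to_json(orient="records")),
    }

    # -- roh & inbreeding ---------------------------------------------------
    def _roh():
        segs = roh.detect_roh_cohort(gm_pruned, cfg.roh_params)
        packs = {s.sample_id: s.pack_id for s in gm_pruned.samples}
        per_sample, per_pack = roh.bin_roh_lengths(
            segs, samples=gm_pruned.sample_ids, packs=packs
        )
        coef = roh.inbreeding_table(gm_pruned, segs, cfg.roh_params)
        return segs, per_sample, per_pack, coef

    segs, bins_sample, bins_pack, coef = stage("roh")(_roh)
    roh.segments_to_frame(segs).to_csv(outdir / "roh_segments.tsv", sep="\t", index=False)
    bins_sample.to_csv(outdir / "roh_bins_per_sample.tsv", sep="\t")
    bins_pack.to_csv(outdir / "roh_bins_per_pack.tsv", sep="\t")
    coef.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
    report["roh"] = {
        "n_segments": len(segs),
        "total_mb": float(sum(s.length_bp for s in segs) / 1e6),
        "per_sample_count_range": [
            int(min((coef_counts := roh.segments_to_frame(segs)
                     .groupby("sample_id").size()
                     .reindex(gm_pruned.sample_ids, fill_value=0)))),
            int(max(coef_counts)),
        ],
        "f_hom_mean": float(coef["f_hom"].mean()),
        "f_hom_sd": float(coef["f_hom"].std(ddof=1)),
        "f_roh_mean": float(coef["f_roh"].mean()),
        "f_roh_sd": float(coef["f_roh"].std(ddof=1)),
    }

    # -- pca ----------------------------------------------------------------
    pca_res = stage("pca")(
        lambda: structure.pca_of_genotypes(gm_pruned, cfg.pca_components)
    )
    pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
    report["pca"] = {
        "explained": [float(x) for x in pca_res.explained],
        "pc1_pc2_explained_pct": float(100.0 * pca_res.explained[:2].sum()),
    }

    log.close()
    report_json = json.dumps(report, indent=2, sort_keys=True)
    report_path.write_text(report_json + "\n")
    (outdir / "report.txt").write_text(_render_text(report))
    manifest.write_text(json.dumps({"config_hash": h}) + "\n")
    return report


def _summary_dict(summ: pd.DataFrame) -> dict:
    return {
        "n_sites": summ.attrs["n_sites"],
        "prop_delta_positive": summ.attrs["prop_delta_positive"],
        **{
            f"{stat}_{what}": float(summ.loc[stat, what])
            for stat in summ.index
            for what in ("mean", "sd", "median")
        },
    }


def _render_text(report: dict) -> str:
    lines = ["packstats run report", "====================", ""]
    ing = report["ingest"]
    lines.append(
        f"Input: {ing['n_samples']} samples x {ing['n_variants']} SNPs "
        f"({ing['n_skipped_non_snp']} non-SNP records skipped)"
    )
    qc = report["qc"]
    lines.append(
        f"QC: retained {qc['n_retained']} of {qc['n_input']} "
        f"(qual {qc['n_removed_qual']}, call {qc['n_removed_call']}, "
        f"HWE {qc['n_removed_hwe']}, MAF {qc['n_removed_maf']})"
    )
    lines.append(
        f"LD pruning: {report['prune']['n_retained']} SNPs retained "
        f"(stringent subset: {report['stringent_prune']['n_retained']})"
    )
    d = report["diversity"]["moderate_prune"]
    lines.append(
        f"Heterozygosity: H_O {d['h_obs_mean']:.3f} +/- {d['h_obs_sd']:.3f}, "
        f"H_E {d['h_exp_mean']:.3f} +/- {d['h_exp_sd']:.3f}, "
        f"delta>0 at {100 * d['prop_delta_positive']:.1f}% of sites"
    )
    b = report["bottleneck"]
    lines.append(
        f"Bottleneck T2 = {b['t2']:.2f} over {b['n_loci']} loci, "
        f"one-sided p = {b['p_one_sided']:.3g} "
        f"({'reject' if b['reject_5pct'] else 'retain'} at 5%)"
    )
    lines.append("Relatedness (category: pairs, portion, mean PI-HAT):")
    for row in report["relatedness"]["table"]:
        pi_hat = row["mean_pi_hat"]
        shown = f"{pi_hat:.3f}" if isinstance(pi_hat, float) and pi_hat == pi_hat else "-"
        lines.append(
            f"  {row['category']:>9}: {row['n_pairs']:5d}  "
            f"{row['portion_pct']:6.2f}%  {shown}"
        )
    r = report["roh"]
    lines.append(
        f"ROH: {r['n_segments']} segments, {r['total_mb']:.1f} Mb total; "
        f"F_ROH {r['f_roh_mean']:.4f} +/- {r['f_roh_sd']:.4f}, "
        f"F_HOM {r['f_hom_mean']:.4f} +/- {r['f_hom_sd']:.4f}"
    )
    lines.append(
        f"PCA: PC1+PC2 explain {report['pca']['pc1_pc2_explained_pct']:.1f}% "
        f"of variance"
    )
    return "\n".join(lines) + "\n"
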