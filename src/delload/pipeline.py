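"""End-to-end orchestration: filters -> classification -> burden ->
windows/sweeps -> introgression -> DDMG -> association, from one YAML
config, with per-stage TSV/BED/JSON artifacts and a machine-readable
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc, burden as burden_mod, ddmg as ddmg_mod, introgression, io, \
    windows as win_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    annotation: str
    manifest: str
    genes: str
    outdir: str
    score_track: str | None = None
    phenotypes: str | None = None
    maf_min: float = 0.05
    missing_max: float = 0.70
    sift_cutoff: float = 0.05
    gerp_cutoff: float = 2.0
    window: int = 10_000
    step: int = 5_000
    min_snps: int = 100
    quantile: float = 0.95
    fc_threshold: float = 1.0
    padj_threshold: float = 0.05
    block_size: int = 1_000_000
    burden_mode: str = "site"
    seed: int = 0
    # comparisons: name -> [cultivated population, wild population]
    comparisons: dict[str, list[str]] = field(default_factory=dict)
    # introgression: {"p1": pop, "p2": pop, "p3": pop, "outgroup": pop}
    introgression: dict[str, str] | None = None
    # association: list of {"chrom": str, "pos": int, "trait": str}
    association: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("vcf", "annotation", "manifest", "genes"):
            p = getattr(self, attr)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if not 0 <= self.maf_min <= 0.5 or not 0 <= self.missing_max <= 1:
            raise ValueError("thresholds out of range")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile out of range")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all configured stages; returns the report dict (also written to
    ``outdir/report.json``)."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict[str, Any] = {
        "parameters": {k: v for k, v in cfg.__dict__.items()},
        "inputs": {a: {"path": getattr(cfg, a), "sha256": _sha256(getattr(cfg, a))}
                   for a in ("vcf", "annotation", "manifest", "genes")},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.monotonic()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {"seconds": round(time.monotonic() - t0, 3),
                                      **(out or {})}
            log.info("stage %s done (%.2fs)", name, time.monotonic() - t0)
        return deco

    state: dict[str, Any] = {}

    @stage("load_and_filter")
    def _():
        gm_raw = io.read_vcf(cfg.vcf)
        gm = io.apply_site_filters(gm_raw, cfg.maf_min, cfg.missing_max)
        state["gm"] = gm
        state["manifest"] = io.read_manifest(cfg.manifest, gm)
        state["genes"] = io.read_gene_models(cfg.genes)
        return {"n_sites_raw": gm_raw.n_sites, "n_sites_filtered": gm.n_sites,
                "n_samples": gm.n_samples}

    @stage("classify")
    def _():
        annot = io.read_annotation_table(cfg.annotation)
        annot = io.join_annotation(state["gm"], annot)
        annot = burden_mod.classify_deleterious(annot, cfg.sift_cutoff,
                                                cfg.gerp_cutoff)
        state["annot"] = annot
        ov = burden_mod.sift_gerp_overlap(annot)
        n_del = int(annot["is_deleterious_sift"].sum())
        pct = deleterious_percentage(n_del, state["gm"].n_sites)
        return {"overlap": ov, "n_deleterious_sift": n_del,
                "deleterious_pct": pct}

    @stage("sweep_regions")
    def _():
        if cfg.score_track is None:
            state["sweeps"] = None
            return {"skipped": True}
        track = io.read_score_track(cfg.score_track)
        regions = win_mod.select_top_regions(track, cfg.quantile, label="sweep")
        state["sweeps"] = regions
        io.write_intervals(regions, os.path.join(cfg.outdir, "sweep_regions.bed"))
        return {"n_regions": len(regions), "span_bp": regions.total_span()}

    @stage("burden")
    def _():
        bt = burden_mod.burden_table(state["gm"], state["annot"],
                                     state["manifest"], state["sweeps"],
                                     mode=cfg.burden_mode)
        state["burden"] = bt
        bt.to_csv(os.path.join(cfg.outdir, "burden_table.tsv"), sep="\t",
                  index=False)
        comps = {}
        bt_idx = bt.set_index("sample")
        for name, (pa, pb) in cfg.comparisons.items():
            ga = state["manifest"].samples_of(pa)
            gb = state["manifest"].samples_of(pb)
            entry = {"burden": burden_mod.compare_groups(bt_idx["n_total"], ga, gb)}
            if "interval_freq_pct" in bt_idx:
                entry["interval_freq"] = burden_mod.compare_groups(
                    bt_idx["interval_freq_pct"], ga, gb)
            entry["burden_f_corr"] = burden_mod.burden_f_correlation(
                bt_idx.loc[ga + gb, "n_total"], bt_idx.loc[ga + gb, "F"])
            comps[name] = entry
        pd.DataFrame([
            {"comparison": n, "metric": m, **v}
            for n, e in comps.items() for m, v in e.items()
        ]).to_csv(os.path.join(cfg.outdir, "comparisons.tsv"), sep="\t",
                  index=False)
        return {"comparisons": comps}

    @stage("windows")
    def _():
        out = {}
        for name, (pa, pb) in cfg.comparisons.items():
            ga = state["manifest"].samples_of(pa)
            gb = state["manifest"].samples_of(pb)
            pi_a = win_mod.windowed_pi(state["gm"], ga, cfg.window, cfg.step)
            pi_b = win_mod.windowed_pi(state["gm"], gb, cfg.window, cfg.step)
            fst = win_mod.windowed_fst(state["gm"], ga, gb, cfg.window, cfg.step)
            io.write_score_track(pi_a, os.path.join(cfg.outdir, f"pi_{pa}.tsv"))
            io.write_score_track(pi_b, os.path.join(cfg.outdir, f"pi_{pb}.tsv"))
            io.write_score_track(fst, os.path.join(cfg.outdir, f"fst_{name}.tsv"))
            out[name] = {
                "mean_pi_a": float(np.nanmean(pi_a["value"])),
                "mean_pi_b": float(np.nanmean(pi_b["value"])),
                "mean_fst": float(np.nanmean(fst["value"])),
            }
        return out

    @stage("introgression")
    def _():
        if not cfg.introgression:
            state["introgression_regions"] = None
            return {"skipped": True}
        mf = state["manifest"]
        pops = cfg.introgression
        freqs = introgression.polarize(
            state["gm"], mf.samples_of(pops["p1"]), mf.samples_of(pops["p2"]),
            mf.samples_of(pops["p3"]), mf.samples_of(pops["outgroup"]))
        dres = introgression.jackknife_z(freqs, cfg.block_size)
        track, regions = introgression.windowed_fd(
            freqs, cfg.window, cfg.step, cfg.min_snps, cfg.quantile)
        state["introgression_regions"] = regions if len(regions) else None
        io.write_score_track(track, os.path.join(cfg.outdir, "fd_track.tsv"))
        if len(regions):
            io.write_intervals(regions,
                               os.path.join(cfg.outdir, "introgression_regions.bed"))
        enrich = None
        if len(regions):
            ga = mf.samples_of(pops["p2"])
            gb = mf.samples_of(pops["p1"])
            enrich = introgression.interval_enrichment(
                state["gm"], state["annot"], regions, ga, gb)
        d_report = {"abba": dres.abba, "baba": dres.baba, "d": dres.d,
                    "z": dres.z, "se": dres.se, "n_blocks": dres.n_blocks,
                    "significant": dres.significant,
                    "n_regions": len(regions),
                    "interval_enrichment": enrich}
        with open(os.path.join(cfg.outdir, "d_report.json"), "w") as fh:
            json.dump(d_report, fh, indent=2)
        return d_report

    @stage("ddmg")
    def _():
        out = {}
        state["ddmg"] = {}
        for name, (pa, pb) in cfg.comparisons.items():
            mat = ddmg_mod.gene_burden_matrix(state["gm"], state["annot"],
                                              state["genes"],
                                              mode=cfg.burden_mode)
            res = ddmg_mod.ddmg_test(mat, state["manifest"].samples_of(pa),
                                     state["manifest"].samples_of(pb),
                                     cfg.fc_threshold, cfg.padj_threshold)
            state["ddmg"][name] = res
            res.to_csv(os.path.join(cfg.outdir, f"ddmg_{name}.tsv"), sep="\t")
            up = int((res["class"] == "up").sum())
            down = int((res["class"] == "down").sum())
            out[name] = {"up": up, "down": down, "total": ddmg_total(up, down)}
        return out

    @stage("association")
    def _():
        if not cfg.association or cfg.phenotypes is None:
            return {"skipped": True}
        pheno = io.read_phenotypes(cfg.phenotypes)
        results = []
        for spec_ in cfg.association:
            tr = pheno[pheno["trait"] == spec_["trait"]].set_index("sample_id")["value"]
            res = assoc.genotype_group_test(state["gm"], spec_["chrom"],
                                            int(spec_["pos"]), tr,
                                            spec_.get("grouping", "REF_vs_ALT"))
            res["trait"] = spec_["trait"]
            results.append(res)
        pd.DataFrame(results).to_csv(
            os.path.join(cfg.outdir, "association.tsv"), sep="\t", index=False)
        return {"n_tests": len(results)}

    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    summary = summarize_report(report)
    summary.to_csv(os.path.join(cfg.outdir, "summary.tsv"), sep="\t",
                   index=False)
    return report


# ---------------------------------------------------------------------------
# headline-number helpers


def deleterious_percentage(n_deleterious: int, n_total: int) -> float:
    """(deleterious sites / total SNPs) x 100, to 3 decimal places."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(n_deleterious / n_total * 100.0, 3)


def ddmg_total(up: int, down: int) -> int:
    return up + down


def cohort_size(group_counts: dict[str, int] | list[int]) -> int:
    vals = group_counts.values() if isinstance(group_counts, dict) else group_counts
    return int(sum(vals))


def mean_per_sample(total: float, n_samples: int, ndigits: int = 2) -> float:
    """Average of a cohort-level total over samples (e.g. GB of reads)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round(total / n_samples, ndigits)


def summarize_report(report: dict[str, Any]) -> pd.DataFrame:
    """Flatten a pipeline report into a headline-number summary table."""
    rows: list[dict[str, Any]] = []
    st = report.get("stages", {})

    def add(metric, value):
        rows.append({"metric": metric,
                     "value": value if value is not None else "absent"})

    lf = st.get("load_and_filter", {})
    add("total_snps_raw", lf.get("n_sites_raw"))
    add("total_snps_filtered", lf.get("n_sites_filtered"))
    cl = st.get("classify", {})
    add("deleterious_sites", cl.get("n_deleterious_sift"))
    add("deleterious_pct", cl.get("deleterious_pct"))
    for name, comp in st.get("burden", {}).get("comparisons", {}).items():
        add(f"burden_mean_cultivated_{name}", comp["burden"]["mean_a"])
        add(f"burden_mean_wild_{name}", comp["burden"]["mean_b"])
        add(f"burden_p_{name}", comp["burden"]["p"])
    intro = st.get("introgression", {})
    if not intro.get("skipped"):
        add("d_statistic", intro.get("d"))
        add("d_z_score", intro.get("z"))
        add("introgression_regions", intro.get("n_regions"))
    sw = st.get("sweep_regions", {})
    if not sw.get("skipped"):
        add("sweep_regions", sw.get("n_regions"))
    for name, dd in st.get("ddmg", {}).items():
        if not isinstance(dd, dict):
            continue
        add(f"ddmg_up_{name}", dd["up"])
        add(f"ddmg_down_{name}", dd["down"])
        add(f"ddmg_total_{name}", dd["total"])
    return pd.DataFrame(rows)
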