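"""End-to-end orchestration: simulate -> associate -> depth scan -> genotype
configuration -> LTR dating -> telomere/IR scan -> dS/dN -> phylogeny, with a
run manifest and a human-readable summary report.

Every stochastic stage derives its seed from the run seed, so re-running a
manifest reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import FilterRuleSet, associate
from .depth_scan import (
    BiasClass,
    DepthTrack,
    call_sex_specific_regions,
    read_depth_tsv,
    window_medians,
)
from .genotype_config import classify_markers, infer_system
from .io_formats import (
    GenomicInterval,
    read_fasta,
    read_sex_table,
    read_vcf,
    write_bed,
    write_tsv,
)
from .ltr_dating import date_pair
from .phylo_divergence import bootstrap_tree, filter_gene_pairs, filter_codon_columns, ng86_dnds
from .repeat_scan import arm_report_rows, call_ir_arms, scan_telomere, self_dotplot
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    RepeatConfig,
    simulate_clade_alignment,
    simulate_codon_pair,
    simulate_ltr_pair,
    write_all,
)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {},  # SimConfig field overrides
    "assoc": {"alpha": 0.05, "maf_floor": 0.05, "max_gap_bp": 50_000},
    "depthscan": {"window": 1000, "min_total": 400.0, "min_consecutive": 3},
    "genotype": {"conformity_min": 0.9, "null_min": 0.5},
    "ltr": {
        "mu": 2.5e-9,
        "replicates": 1000,
        "convention": "direct",
        "length": 10_000,
        # oldest pair set so the expected divergence is 33.95 subs/kb
        "ages_myr": [13.58, 5.0, 2.0, 0.5],
    },
    "telomere": {"min_total": 1000, "max_interruption": 7},
    "irscan": {"k": 15, "min_run": 3, "min_arm": 500, "min_identity": 85.0},
    "dnds": {"n_codons": 400, "divergence": 0.05, "ds_max": 0.5},
    "phylo": {"gamma_shape": 1.0, "replicates": 200, "n_per_clade": 3,
              "length": 2000, "within": 0.01, "between": 0.2},
}


def load_config(path: str | Path | None = None, seed: int | None = None) -> dict:
    """Merge a YAML config over the defaults; an explicit seed wins."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = seed
    return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, outputs: dict[str, str], wall_s: float) -> None:
        self.stages[name] = {"outputs": outputs, "wall_seconds": round(wall_s, 3)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"version": self.version, "seed": self.seed,
                 "config": self.config, "stages": self.stages},
                indent=2, default=str,
            )
            + "\n"
        )


def _fmt_iv(iv: GenomicInterval | None) -> str:
    if iv is None:
        return "NA"
    return f"{iv.chrom}:{iv.report_start}-{iv.report_end}"


def run_all(config: dict, outdir: str | Path) -> tuple[RunManifest, dict]:
    """Execute every stage in dependency order; returns (manifest, summary).

    The summary states the inferred heterogamety system, the SDR interval and
    its male-specific sub-interval, the oldest LTR insertion age, the telomere
    and inverted-repeat tables, and — because the inputs are simulated —
    the deviation of each call from the generator's ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(config=config, seed=seed)
    summary: dict = {"seed": seed}

    # --- stage: simulate ---
    t0 = time.perf_counter()
    sim_kwargs = dict(config.get("simulate", {}))
    repeat_overrides = sim_kwargs.pop("repeats", None)
    if repeat_overrides:
        sim_kwargs["repeats"] = RepeatConfig(**repeat_overrides)
    sim = SimConfig(seed=seed, **sim_kwargs)
    paths = write_all(sim, outdir)
    truth = GroundTruth.from_json(paths["truth"])
    manifest.record("simulate", {k: str(v) for k, v in paths.items()},
                    time.perf_counter() - t0)

    # --- stage: association ---
    t0 = time.perf_counter()
    sex_table = read_sex_table(paths["sex"])
    acfg = config["assoc"]
    rules = FilterRuleSet(alpha=acfg["alpha"], maf_floor=acfg["maf_floor"])
    records = list(read_vcf(paths["vcf"], sex_table))
    results, clusters, astats = associate(
        records, sex_table, rules, max_gap_bp=acfg["max_gap_bp"]
    )
    assoc_tsv = outdir / "assoc.tsv"
    write_tsv(
        (
            {
                "chrom": r.chrom, "pos": r.pos,
                "f_ref": r.table[0][0], "f_alt": r.table[0][1],
                "m_ref": r.table[1][0], "m_alt": r.table[1][1],
                "p": f"{r.p_value:.6g}", "significant": int(r.significant),
                "cluster_id": r.cluster_id if r.cluster_id else "",
            }
            for r in results
        ),
        assoc_tsv,
        comment="sex-association scan (Fisher exact, Bonferroni)",
    )
    summary["association"] = {
        **astats,
        "bonferroni_threshold": results[0].threshold if results else None,
        "clusters": [
            {"interval": _fmt_iv(c.interval), "n_snps": c.n_snps,
             "min_p": c.min_p}
            for c in clusters
        ],
    }
    manifest.record("assoc", {"assoc": str(assoc_tsv)}, time.perf_counter() - t0)

    # --- stage: depth scan ---
    t0 = time.perf_counter()
    dcfg = config["depthscan"]
    chrom_f, dense_f = read_depth_tsv(paths["depth_f"])
    chrom_m, dense_m = read_depth_tsv(paths["depth_m"])
    n = max(len(dense_f), len(dense_m))
    import numpy as np

    dense_f = np.pad(dense_f, (0, n - len(dense_f)))
    dense_m = np.pad(dense_m, (0, n - len(dense_m)))
    track = DepthTrack(chrom_f, dense_f, dense_m)
    windows = window_medians(track, width=dcfg["window"], min_total=dcfg["min_total"])
    regions = call_sex_specific_regions(windows, min_consecutive=dcfg["min_consecutive"])
    windows_tsv = outdir / "depth_windows.tsv"
    write_tsv(
        (
            {
                "chrom": w.interval.chrom,
                "start": w.interval.report_start, "end": w.interval.report_end,
                "median_f": w.median_f, "median_m": w.median_m,
                "log2_ratio": "" if w.log2_ratio is None else f"{w.log2_ratio:.4f}",
                "class": w.bias_class.value,
            }
            for w in windows
        ),
        windows_tsv,
        comment="per-window cohort depth medians and log2((F+1)/(M+1))",
    )
    regions_bed = outdir / "sex_specific_regions.bed"
    write_bed((r.interval for r in regions), regions_bed)
    male_regions = [r for r in regions if r.bias_class is BiasClass.MALE_BIASED]
    summary["depth"] = {
        "n_windows": len(windows),
        "n_male_biased": sum(
            w.bias_class is BiasClass.MALE_BIASED for w in windows
        ),
        "regions": [
            {"interval": _fmt_iv(r.interval), "class": r.bias_class.value,
             "n_windows": r.n_windows,
             "mean_log2_ratio": round(r.mean_log2_ratio, 3)}
            for r in regions
        ],
    }
    manifest.record(
        "depthscan",
        {"windows": str(windows_tsv), "regions": str(regions_bed)},
        time.perf_counter() - t0,
    )

    # --- stage: genotype configuration / system inference ---
    t0 = time.perf_counter()
    gcfg = config["genotype"]
    configs = classify_markers(
        records, sex_table,
        conformity_min=gcfg["conformity_min"], null_min=gcfg["null_min"],
    )
    system = infer_system(configs)
    configs_tsv = outdir / "marker_configs.tsv"
    write_tsv(
        (
            {"chrom": m.chrom, "pos": m.pos, "class": m.config_class,
             "conformity": m.conformity}
            for m in configs
            if m.config_class != "unlinked"
        ),
        configs_tsv,
        comment="non-unlinked genotype configurations",
    )
    system_json = outdir / "system.json"
    system_json.write_text(
        json.dumps(
            {"system": system.system, "class_counts": system.class_counts,
             "sdr_span": _fmt_iv(system.sdr_span)},
            indent=2,
        )
        + "\n"
    )
    summary["system"] = {
        "inferred": system.system,
        "class_counts": system.class_counts,
        "sdr_span": _fmt_iv(system.sdr_span),
    }
    manifest.record(
        "genotype_config",
        {"configs": str(configs_tsv), "system": str(system_json)},
        time.perf_counter() - t0,
    )

    # --- stage: LTR dating ---
    t0 = time.perf_counter()
    lcfg = config["ltr"]
    ltr_rows = []
    oldest = None
    for i, age_myr in enumerate(lcfg["ages_myr"]):
        seq5, seq3, _ = simulate_ltr_pair(
            lcfg["length"], age_myr * 1e6, mu=lcfg["mu"],
            seed=seed + 100 + i, convention=lcfg["convention"],
        )
        pair = date_pair(
            f"ltr_{i + 1}", seq5, seq3, mu=lcfg["mu"],
            replicates=lcfg["replicates"], seed=seed + 200 + i,
            convention=lcfg["convention"],
        )
        ltr_rows.append(
            {
                "element": pair.element_id, "site_count": pair.site_count,
                "substitution_rate": f"{pair.d:.5f}",
                "se": f"{pair.se_d:.5f}",
                "age_myr": f"{pair.age_years / 1e6:.2f}",
                "se_age_myr": f"{pair.se_age_years / 1e6:.2f}",
                "true_age_myr": age_myr,
            }
        )
        if oldest is None or pair.age_years > oldest.age_years:
            oldest = pair
    ltr_tsv = outdir / "ltr_ages.tsv"
    write_tsv(ltr_rows, ltr_tsv, comment="LTR terminal-repeat insertion dating")
    summary["ltr"] = {
        "oldest_age_myr": round(oldest.age_years / 1e6, 2),
        "oldest_se_myr": round(oldest.se_age_years / 1e6, 2),
        "table": ltr_rows,
    }
    manifest.record("ltrage", {"ages": str(ltr_tsv)}, time.perf_counter() - t0)

    # --- stage: telomere + inverted repeats ---
    t0 = time.perf_counter()
    tcfg, icfg = config["telomere"], config["irscan"]
    contig = read_fasta(paths["fasta"])
    (contig_name, seq), = contig.items()
    telomeres = scan_telomere(
        seq, min_total=tcfg["min_total"],
        max_interruption=tcfg["max_interruption"], chrom=contig_name,
    )
    telo_bed = outdir / "telomeres.bed"
    write_bed(telomeres, telo_bed)
    matches = self_dotplot(seq, k=icfg["k"], min_run=icfg["min_run"], chrom=contig_name)
    arms = call_ir_arms(
        matches, seq, min_arm=icfg["min_arm"],
        min_identity=icfg["min_identity"], chrom=contig_name,
    )
    arms_tsv = outdir / "ir_arms.tsv"
    write_tsv(
        arm_report_rows(arms), arms_tsv,
        comment="inverted-repeat arms (identity over full alignment columns)",
    )
    summary["repeats"] = {
        "telomeres": [
            {"interval": _fmt_iv(t.interval), "motif": t.motif,
             "copies": t.copy_count, "bases": t.matched_bases}
            for t in telomeres
        ],
        "n_ir_arm_pairs": len(arms) // 2,
        "arm_identity_pct": [round(a.identity_pct, 1) for a in arms[::2]],
    }
    manifest.record(
        "repeat_scan",
        {"telomeres": str(telo_bed), "arms": str(arms_tsv)},
        time.perf_counter() - t0,
    )

    # --- stage: dS/dN ---
    t0 = time.perf_counter()
    ncfg = config["dnds"]
    pairs = {}
    # third pair is a deliberate high-dS "tandem paralog" exercising the filter
    for i, div in enumerate([ncfg["divergence"], ncfg["divergence"] / 2, 0.45]):
        a, b = simulate_codon_pair(ncfg["n_codons"], div, seed=seed + 300 + i)
        pairs[f"pair_{i + 1}"] = ng86_dnds(filter_codon_columns(a, b))
    kept, dropped = filter_gene_pairs(pairs, ds_max=ncfg["ds_max"])
    dnds_tsv = outdir / "dnds.tsv"
    write_tsv(
        (
            {"pair": k, "S": f"{v.S:.1f}", "N": f"{v.N:.1f}",
             "dS": f"{v.dS:.4f}", "dN": f"{v.dN:.4f}",
             "retained": int(k in kept)}
            for k, v in pairs.items()
        ),
        dnds_tsv,
        comment=f"NG86 dS/dN; {dropped} pair(s) dropped at dS > {ncfg['ds_max']}",
    )
    summary["dnds"] = {"n_pairs": len(pairs), "n_dropped_high_ds": dropped}
    manifest.record("dnds", {"dnds": str(dnds_tsv)}, time.perf_counter() - t0)

    # --- stage: phylogeny ---
    t0 = time.perf_counter()
    pcfg = config["phylo"]
    aln, true_topo = simulate_clade_alignment(
        n_per_clade=pcfg["n_per_clade"], length=pcfg["length"],
        within=pcfg["within"], between=pcfg["between"], seed=seed + 400,
    )
    tree = bootstrap_tree(
        aln, replicates=pcfg["replicates"], seed=seed + 401,
        gamma_shape=pcfg["gamma_shape"],
    )
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(tree.to_newick() + "\n")
    clade_split = frozenset(l for l in tree.leaf_names if l.startswith("X"))
    ref = min(tree.leaf_names)
    if ref in clade_split:
        clade_split = frozenset(set(tree.leaf_names) - clade_split)
    summary["phylo"] = {
        "newick": tree.to_newick(),
        "true_topology": true_topo,
        "clade_split_recovered": clade_split in tree.bipartitions(),
    }
    manifest.record("phylo", {"tree": str(tree_path)}, time.perf_counter() - t0)

    # --- ground-truth comparison ---
    comparison = {}
    if truth.sdr_interval is not None and system.sdr_span is not None:
        comparison["system_correct"] = system.system == truth.system
        comparison["sdr_start_error_bp"] = abs(
            system.sdr_span.start - truth.sdr_interval.start
        )
        comparison["sdr_end_error_bp"] = abs(
            system.sdr_span.end - truth.sdr_interval.end
        )
    if truth.core_interval is not None and male_regions:
        core_calls = [
            r for r in male_regions
            if r.interval.overlaps(truth.core_interval)
        ]
        if core_calls:
            best = max(core_calls, key=lambda r: r.n_windows)
            comparison["core_start_error_bp"] = abs(
                best.interval.start - truth.core_interval.start
            )
            comparison["core_end_error_bp"] = abs(
                best.interval.end - truth.core_interval.end
            )
    summary["truth_comparison"] = comparison

    report_path = outdir / "report.txt"
    report_path.write_text(render_report(summary))
    summary_tsv = outdir / "summary.tsv"
    write_tsv(_summary_rows(summary), summary_tsv, comment="run summary")
    manifest.record("report", {"report": str(report_path), "summary": str(summary_tsv)}, 0.0)
    manifest.to_json(outdir / "manifest.json")
    return manifest, summary


def _summary_rows(summary: dict) -> list[dict]:
    rows = [
        {"key": "inferred_system", "value": summary["system"]["inferred"]},
        {"key": "sdr_span", "value": summary["system"]["sdr_span"]},
        {"key": "n_significant_snps", "value": summary["association"]["n_significant"]},
        {"key": "n_male_biased_windows", "value": summary["depth"]["n_male_biased"]},
        {"key": "oldest_ltr_age_myr", "value": summary["ltr"]["oldest_age_myr"]},
        {"key": "n_ir_arm_pairs", "value": summary["repeats"]["n_ir_arm_pairs"]},
    ]
    for key, val in summary.get("truth_comparison", {}).items():
        rows.append({"key": f"truth:{key}", "value": val})
    return rows


def render_report(summary: dict) -> str:
    lines = [
        "sdrscan pipeline report",
        "=======================",
        f"seed: {summary['seed']}",
        "",
        f"Inferred heterogamety system: {summary['system']['inferred']}",
        f"Marker class counts: {summary['system']['class_counts']}",
        f"SDR span estimate: {summary['system']['sdr_span']}",
        "",
        f"Association: {summary['association']['n_significant']} significant SNPs "
        f"of {summary['association']['n_tested']} tested "
        f"(Bonferroni {summary['association']['bonferroni_threshold']:.3g})",
    ]
    for c in summary["association"]["clusters"]:
        lines.append(
            f"  candidate SDR cluster {c['interval']}: {c['n_snps']} SNPs, "
            f"min p = {c['min_p']:.3g}"
        )
    lines.append("")
    lines.append(
        f"Depth scan: {summary['depth']['n_male_biased']} male-biased windows "
        f"of {summary['depth']['n_windows']}"
    )
    for r in summary["depth"]["regions"]:
        lines.append(
            f"  {r['class']} region {r['interval']} "
            f"({r['n_windows']} windows, mean log2 ratio {r['mean_log2_ratio']})"
        )
    lines.append("")
    lines.append(
        f"Oldest LTR insertion: {summary['ltr']['oldest_age_myr']} ± "
        f"{summary['ltr']['oldest_se_myr']} (SE) Myr"
    )
    lines.append("")
    for t in summary["repeats"]["telomeres"]:
        lines.append(
            f"Telomeric array {t['interval']}: {t['copies']} x {t['motif']} "
            f"({t['bases']} bp)"
        )
    lines.append(
        f"Inverted-repeat arm pairs: {summary['repeats']['n_ir_arm_pairs']} "
        f"(identity % {summary['repeats']['arm_identity_pct']})"
    )
    lines.append("")
    lines.append(f"Tree: {summary['phylo']['newick']}")
    lines.append(
        f"Two-clade split recovered: {summary['phylo']['clade_split_recovered']}"
    )
    if summary.get("truth_comparison"):
        lines.append("")
        lines.append("Ground-truth comparison:")
        for key, val in summary["truth_comparison"].items():
            lines.append(f"  {key}: {val}")
    return "\n".join(lines) + "\n"
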