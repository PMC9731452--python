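"""End-to-end pipeline: simulate -> quantify -> expression -> regulation ->
motifs -> CAGE -> report.

``run_pipeline`` drives the full synthetic study from a single
:class:`RunConfig` (one seed governs every source of randomness) and writes
TSV outputs plus a markdown report.  Each stage is also callable on its own
through the library API or the CLI subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cage, expression, motifs, regulation
from .construct import ConstructTemplate
from .quantify import KmerCountTable, quantify_fastq
from .simulate import (
    SimulationConfig,
    simulate_cage,
    simulate_decay_counts,
    simulate_fraction_counts,
    simulate_plasmid_library,
    simulate_reporter_reads,
)

log = logging.getLogger("startmer")


@dataclass
class RunConfig:
    """Thresholds, sizes and flags for a full pipeline run."""

    outdir: str = "startmer_run"
    rng_seed: int = 0
    # synthetic scale
    depth: int = 5_000_000          # total reporter reads, split over replicates
    count_depth: int = 30_000_000   # per fraction/decay sample
    plasmid_depth: int = 20_000_000  # plasmid library sequencing depth
    n_replicates: int = 2
    spikein_fraction: float = 0.02
    # quantification
    max_scan: int = 60
    max_artifact_g: int = 2
    spikein_match_len: int = 15
    # expression / regulation
    min_reads: int = 50
    require_all_replicates: bool = True
    top_fraction: float = 0.05
    pseudocount: float = 0.5
    spikein_scaled_psp: bool = True
    actd_hours: float = 2.0
    # cage
    cage_genome_len: int = 160_000
    cage_n_genes: int = 150
    cage_n_tags: int = 200_000
    window: int = 1000
    # reporting
    make_plots: bool = False
    keep_fastq: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha1(
            yaml.safe_dump(params, sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"# startmer v{__version__} config={config.config_hash}\n"


def write_tsv(df, path: str | Path, config: RunConfig, index: bool = True) -> None:
    """Write a TSV with a tool-version/config-hash header line."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic study; returns the per-stage results dict.

    Outputs are written under ``config.outdir``; any stage error propagates
    with its stage name in the message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    log.info("run seed=%d config=%s outdir=%s", config.rng_seed, config.config_hash, out)
    config.to_yaml(out / "config.yaml")
    results: dict = {"config": config}
    stage = "simulate"
    try:
        results.update(_stage_simulate_quantify(config, out))
        stage = "expression"
        results.update(_stage_expression(config, out, results))
        stage = "regulation"
        results.update(_stage_regulation(config, out, results))
        stage = "motifs"
        results.update(_stage_motifs(config, out, results))
        stage = "cage"
        results.update(_stage_cage(config, out, results))
        stage = "report"
        _write_report(config, out, results)
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


# ---------------------------------------------------------------------
# stages


def _stage_simulate_quantify(config: RunConfig, out: Path) -> dict:
    template = ConstructTemplate()
    sim = SimulationConfig(
        rng_seed=config.rng_seed,
        depth=max(1, config.depth // config.n_replicates),
        count_depth=config.count_depth,
        plasmid_depth=config.plasmid_depth,
        spikein_fraction=config.spikein_fraction,
    )
    plasmid = simulate_plasmid_library(sim)
    plasmid.to_tsv(out / "plasmid_counts.tsv")

    reporter_tables: list[KmerCountTable] = []
    truths = []
    summaries = []
    for rep in range(config.n_replicates):
        fastq = out / f"reporter_rep{rep}.fastq"
        truth = simulate_reporter_reads(template, sim, fastq, replicate=rep)
        table, summary = quantify_fastq(
            fastq,
            template,
            sample_id=f"reporter_rep{rep}",
            replicate=rep,
            max_scan=config.max_scan,
            max_artifact_g=config.max_artifact_g,
            spikein_match_len=config.spikein_match_len,
        )
        log.info(
            "quantify rep%d: %d reads, %d assigned, excluded=%s, spikein=%d",
            rep, summary["n_reads"], summary["assigned"],
            summary["excluded"], summary["spikein_count"],
        )
        table.to_tsv(
            out / f"reporter_rep{rep}_counts.tsv",
            sidecar={"tss_position_distribution": summary["tss_position_distribution"]},
        )
        if not config.keep_fastq:
            fastq.unlink()
        reporter_tables.append(table)
        truths.append(truth)
        summaries.append(summary)

    fraction_tables: dict = {}
    decay_tables: dict = {}
    for cond in ("control", "torin"):
        for rep in range(config.n_replicates):
            poly, sub = simulate_fraction_counts(sim, cond, replicate=rep)
            fraction_tables.setdefault(cond, []).append((poly, sub))
            poly.to_tsv(out / f"{poly.sample_id}_counts.tsv")
            sub.to_tsv(out / f"{sub.sample_id}_counts.tsv")
        for rep in range(config.n_replicates):
            minus = simulate_decay_counts(sim, cond, 0.0, replicate=rep)
            plus = simulate_decay_counts(sim, cond, config.actd_hours, replicate=rep)
            decay_tables.setdefault(cond, []).append((plus, minus))
            plus.to_tsv(out / f"{plus.sample_id}_counts.tsv")
            minus.to_tsv(out / f"{minus.sample_id}_counts.tsv")
    return {
        "template": template,
        "sim": sim,
        "plasmid": plasmid,
        "reporter_tables": reporter_tables,
        "truths": truths,
        "summaries": summaries,
        "fraction_tables": fraction_tables,
        "decay_tables": decay_tables,
    }


def _stage_expression(config: RunConfig, out: Path, res: dict) -> dict:
    table = expression.normalize_expression(
        res["reporter_tables"],
        res["plasmid"],
        min_reads=config.min_reads,
        require_all_replicates=config.require_all_replicates,
    )
    write_tsv(table, out / "normalized_expression.tsv", config)
    det = table.loc[table["detected"], "normalized"].dropna()
    summary = expression.plus1_stratified_summary(table)
    fold = expression.expression_range(table)
    log.info(
        "expression: %d detected 7-mers, fold range %.1f, bimodality %.3f",
        len(det), fold, summary["bimodality"],
    )
    top = {}
    for nt in "AC":
        sub = det[det.index.str.startswith(nt)]
        cut = sub.quantile(1 - config.top_fraction)
        top_set = sub[sub >= cut].index
        mat = expression.positional_frequency_matrix(top_set)
        write_tsv(mat, out / f"top_{nt}_positional_frequencies.tsv", config)
        top[nt] = mat
    return {
        "expression_table": table,
        "expression_fold_range": fold,
        "plus1_summary": summary,
        "top_matrices": top,
    }


def _stage_regulation(config: RunConfig, out: Path, res: dict) -> dict:
    all_tables = []
    for cond in ("control", "torin"):
        for poly, sub in res["fraction_tables"][cond]:
            all_tables += [poly, sub]
        for plus, minus in res["decay_tables"][cond]:
            all_tables += [plus, minus]
    universe = expression.detection_filter(
        all_tables, config.min_reads, config.require_all_replicates
    )
    l2 = {}
    for cond in ("control", "torin"):
        polys = [p for p, _ in res["fraction_tables"][cond]]
        subs = [s for _, s in res["fraction_tables"][cond]]
        l2[f"psp_{cond}"] = regulation.psp_translation(
            polys, subs, universe=universe,
            spikein_scaled=config.spikein_scaled_psp,
            pseudocount=config.pseudocount,
        )
        pluses = [p for p, _ in res["decay_tables"][cond]]
        minuses = [m for _, m in res["decay_tables"][cond]]
        # spike-in scaling is essential here: the spike-in does not decay, so
        # it anchors the absolute ActD+/ActD- scale that RPM would cancel
        l2[f"decay_{cond}"] = regulation.log2_ratio(
            pluses, minuses, universe=universe,
            spikein_scaled=True, pseudocount=config.pseudocount,
        )
    reg = regulation.build_regulation_table(
        l2["psp_control"], l2["psp_torin"], l2["decay_control"], l2["decay_torin"]
    )
    write_tsv(reg, out / "regulation_table.tsv", config)
    ag_cu = regulation.condition_delta(reg, "psp", ("AG", "CT"))
    corr = {
        cond: regulation.translation_stability_correlation(reg, cond)
        for cond in ("control", "torin")
    }
    log.info(
        "regulation: %d 7-mers; AG/CU delta t=%.1f p=%.2g; r(control)=%.3f r(torin)=%.3f",
        len(reg), ag_cu["t"], ag_cu["p"],
        corr["control"]["pearson_r"], corr["torin"]["pearson_r"],
    )
    return {
        "regulation_table": reg,
        "regulation_universe": universe,
        "ag_cu_test": ag_cu,
        "translation_stability": corr,
    }


def _stage_motifs(config: RunConfig, out: Path, res: dict) -> dict:
    table = res["expression_table"]
    det = table.loc[table["detected"], "normalized"].dropna()
    class_tests = {}
    for name, cls in motifs.BUILTIN_CLASSES.items():
        if name in ("TOP_scan", "CU"):
            continue
        try:
            class_tests[name] = motifs.class_value_test(det, cls)
        except ValueError as exc:  # class too sparse at this detection depth
            class_tests[name] = {"error": str(exc)}
    reg = res["regulation_table"]
    yrun = motifs.yrun_profile(reg["delta_psp"])
    write_tsv(yrun, out / "yrun_profile.tsv", config)
    scan_psp = motifs.substitution_scan(reg["delta_psp"])
    # at shallow depth the detected set may miss the TOP background entirely;
    # fall back to every quantified 7-mer with positive normalized expression
    expr_vals = det
    if not any(motifs.match_class(s, "CYYYYNN") for s in expr_vals.index):
        expr_vals = table["normalized"].dropna()
        expr_vals = expr_vals[expr_vals > 0]
    scan_expr = motifs.substitution_scan(np.log10(expr_vals))
    write_tsv(scan_psp, out / "substitution_scan_delta_psp.tsv", config)
    write_tsv(scan_expr, out / "substitution_scan_expression.tsv", config)
    expr3 = motifs.aggregate_to_kmer(det, 3)
    delta3 = motifs.aggregate_to_kmer(reg["delta_psp"], 3)
    hybrid = motifs.hybrid_ranking(expr3, delta3)
    write_tsv(hybrid, out / "hybrid_ranking.tsv", config)
    (out / "motif_class_tests.json").write_text(json.dumps(class_tests, indent=1))
    return {
        "class_tests": class_tests,
        "yrun_profile": yrun,
        "scan_psp": scan_psp,
        "scan_expr": scan_expr,
        "expr_3mer": expr3,
        "delta_3mer": delta3,
        "hybrid": hybrid,
    }


def _stage_cage(config: RunConfig, out: Path, res: dict) -> dict:
    sim = res["sim"]
    truth = simulate_cage(
        config.cage_genome_len, config.cage_n_genes, None, sim,
        n_tags=config.cage_n_tags, window=config.window,
    )
    cage.write_genome_fasta(truth.genome, out / "cage_genome.fa")
    truth.annotation.to_bed6(out / "cage_annotation.bed")
    truth.tags.to_ctss(out / "cage_tags.ctss")
    assigned = cage.extract_promoter_tags(truth.tags, truth.annotation, config.window)
    freqs = cage.tag_kmer_frequencies(assigned, truth.genome, k=3)
    write_tsv(freqs.rename("frequency"), out / "cage_3mer_frequencies.tsv", config)
    # the endogenous comparison uses every quantified +1 A/C/T 3-mer, not
    # only the detection-passing subset
    table = res["expression_table"]
    norm = table["normalized"].dropna()
    norm = norm[norm > 0]
    expr3_all = motifs.aggregate_to_kmer(norm, 3)
    comparison = cage.compare_library_to_cage(expr3_all, freqs)
    rp_genes = truth.annotation.df.loc[
        truth.annotation.df["gene_class"] == "RP", "gene_id"
    ]
    rp = None
    if len(rp_genes):
        rp = cage.gene_subset_frequencies(
            truth.tags, truth.annotation, rp_genes, truth.genome,
            k=3, window=config.window,
        )
        write_tsv(rp.rename("frequency"), out / "cage_rp_3mer_frequencies.tsv", config)
    log.info(
        "cage: %d genes, %d tags, library-vs-cage rho=%.3f p=%.2g",
        config.cage_n_genes, truth.tags.total,
        comparison["spearman_rho"], comparison["spearman_p"],
    )
    return {"cage_truth": truth, "cage_3mer": freqs, "cage_comparison": comparison,
            "cage_rp_3mer": rp}


# ---------------------------------------------------------------------
# report


def _write_report(config: RunConfig, out: Path, res: dict) -> None:
    lines = [
        f"# startmer report (v{__version__}, config {config.config_hash}, "
        f"seed {config.rng_seed})",
        "",
        "## Quantification",
    ]
    for rep, summary in enumerate(res["summaries"]):
        lines.append(
            f"- replicate {rep}: {summary['n_reads']:,} reads, "
            f"{summary['assigned']:,} assigned to 7-mers, "
            f"excluded {summary['excluded']}, spike-in {summary['spikein_count']:,}"
        )
        dist = summary["tss_position_distribution"]
        modal = max(dist, key=dist.get)
        lines.append(
            f"  TSS position distribution (offset: fraction): "
            + ", ".join(f"{k:+d}: {v:.3f}" for k, v in dist.items())
            + f"; modal position {modal:+d} ({dist[modal]:.1%})"
        )
    det = res["expression_table"]["detected"].sum()
    lines += [
        "",
        "## Expression",
        f"- detected 7-mers (+1 A/C/T, > {config.min_reads} reads in all "
        f"replicates): {det:,}",
        f"- normalized-expression fold range (min..max): "
        f"{res['expression_fold_range']:.0f}",
        f"- pooled log10 bimodality coefficient: "
        f"{res['plus1_summary']['bimodality']:.3f}",
        "",
        res["plus1_summary"]["strata"].to_markdown(),
        "",
        "## Regulation",
        f"- regulation table entries: {len(res['regulation_table']):,}",
        f"- AG vs CU Torin translation delta: t = {res['ag_cu_test']['t']:.1f}, "
        f"p = {res['ag_cu_test']['p']:.2g}, means = {res['ag_cu_test']['strata']}",
    ]
    for cond in ("control", "torin"):
        c = res["translation_stability"][cond]
        lines.append(
            f"- translation-stability correlation ({cond}): "
            f"r = {c['pearson_r']:.3f}, rho = {c['spearman_rho']:.3f}"
        )
    lines += [
        "",
        "## Motifs",
        res["yrun_profile"].to_markdown(),
        "",
        "Substitution scan (Torin translation delta):",
        res["scan_psp"].round(3).to_markdown(),
        "",
        "Top of the TCT/TOP hybrid ranking:",
        res["hybrid"].head(8).round(3).to_markdown(),
        "",
        "## CAGE",
        f"- library vs CAGE 3-mer correlation: "
        f"rho = {res['cage_comparison']['spearman_rho']:.3f}, "
        f"p = {res['cage_comparison']['spearman_p']:.2g} "
        f"(n = {res['cage_comparison']['n']})",
    ]
    if res.get("cage_rp_3mer") is not None:
        top4 = res["cage_rp_3mer"].sort_values(ascending=False).head(4)
        lines.append(
            "- most frequent RP-gene start 3-mers: "
            + ", ".join(f"{k} ({v:.1%})" for k, v in top4.items())
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
    if config.make_plots:
        _make_plots(out, res)


def _make_plots(out: Path, res: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    det = res["expression_table"]
    det = det.loc[det["detected"], "normalized"].dropna()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for nt, color in zip("ACT", ("tab:green", "tab:blue", "tab:red")):
        vals = np.log10(det[det.index.str.startswith(nt)])
        ax.hist(vals, bins=60, alpha=0.5, label=f"+1 {nt}", color=color)
    ax.set_xlabel("log10 normalized expression")
    ax.set_ylabel("7-mers")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "expression_by_plus1.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3))
    prof = res["yrun_profile"]
    ax.errorbar(prof.index, prof["mean_delta"], yerr=prof["sd"], fmt="o-")
    ax.set_xlabel("leading pyrimidine run length k")
    ax.set_ylabel("mean Torin translation delta (log2)")
    fig.tight_layout()
    fig.savefig(out / "yrun_profile.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3))
    reg = res["regulation_table"]
    for cond, color in (("control", "0.6"), ("torin", "tab:purple")):
        ax.scatter(
            reg[f"l2_psp_{cond}"], reg[f"l2_decay_{cond}"],
            s=2, alpha=0.2, label=cond, color=color,
        )
    ax.set_xlabel("log2 P/SP")
    ax.set_ylabel("log2 ActD+/ActD-")
    ax.legend(markerscale=4)
    fig.tight_layout()
    fig.savefig(out / "translation_vs_stability.png", dpi=150)
    plt.close(fig)
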