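"""End-to-end orchestration: config, staged execution, consolidated report.

Stages run in order (islands optional) -> coverage -> metagene ->
similarity -> cluster -> tests -> specificity; each writes TSVs under the
report directory with a ``#`` comment line recording the producing command
and seed. Reruns on the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from hmcscan import annotation, association, coverage, expression, specificity
from hmcscan.intervals import ChromSizes, IntervalSet, read_bed, read_chrom_sizes

__all__ = ["PipelineConfig", "run_all", "report"]

log = logging.getLogger("hmcscan")


@dataclass
class PipelineConfig:
    """All paths and thresholds for a pipeline run.

    The config file format is flat ``key = value`` lines with optional
    ``[section]`` headers (sections are cosmetic); unknown keys warn and
    missing keys take the documented defaults.
    """

    annotation: str = ""
    chrom_sizes: str = ""
    peaks_dir: str = ""            # directory of <sample>.bed peak files
    counts: str = ""
    sample_meta: str = ""
    coverage_meta: str = ""        # metadata for the coverage samples
    gene_sets: str = ""            # optional gene_id<TAB>set_name file
    tau_mod: float = 2.5
    tau_on: float = 0.0
    tau_off: float = 0.0
    tau_cov: float = 0.0
    cluster_k: int = 5
    cluster_linkage: str = "ward"
    metagene_flank_bp: int = 2500
    metagene_body_bins: int = 40
    metagene_flank_bins: int = 25
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "[", ";")):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    log.warning("unknown config key %r ignored", key)
                    continue
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("[hmcscan]\n")
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def validate(self) -> None:
        for key in ("annotation", "chrom_sizes", "peaks_dir", "counts",
                    "sample_meta", "coverage_meta"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"config path {key} = {value!r} not found")
        if not (0 < self.cluster_k):
            raise ValueError("cluster_k must be positive")


def _write_tsv(df: pd.DataFrame, path: Path, command: str, seed: int,
               index_label: str | None = None) -> None:
    with path.open("w") as fh:
        fh.write(f"# produced by {command} (seed={seed})\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _load_peaks(peaks_dir: str,
                chrom_sizes: ChromSizes) -> Dict[str, IntervalSet]:
    beds = sorted(Path(peaks_dir).glob("*.bed"))
    if not beds:
        raise FileNotFoundError(f"no .bed files in {peaks_dir!r}")
    return {p.stem: read_bed(p, chrom_sizes) for p in beds}


def run_all(config: PipelineConfig, outdir: str | Path) -> Dict:
    """Execute every stage; returns the in-memory stage results.

    Any stage failure aborts with the stage name in the raised error.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict = {}
    manifest: List[Dict] = []
    seed = config.seed

    def stage(name: str):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            dt = time.time() - t0
            rows = len(out) if hasattr(out, "__len__") else None
            manifest.append({"stage": name, "seconds": round(dt, 3),
                             "rows": rows})
            log.info("stage %s: done in %.2fs", name, dt)
            return out
        return deco

    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    genes = annotation.read_gtf_genes(config.annotation)
    peaks = stage("load_peaks")(
        lambda: _load_peaks(config.peaks_dir, chrom_sizes))

    cov = stage("coverage")(lambda: coverage.coverage_matrix(genes, peaks))
    _write_tsv(cov, outdir / "coverage.tsv", "hmcscan coverage", seed, "gene_id")
    classes = cov.apply(lambda col: col.map(coverage.coverage_class))
    _write_tsv(classes, outdir / "coverage_classes.tsv", "hmcscan coverage",
               seed, "gene_id")
    results["coverage"] = cov

    def _metagene():
        tables = {}
        for sample, pk in peaks.items():
            prof = coverage.metagene(
                genes, pk, flank_bp=config.metagene_flank_bp,
                body_bins=config.metagene_body_bins,
                flank_bins=config.metagene_flank_bins,
                chrom_sizes=chrom_sizes)
            tables[sample] = prof.to_frame().set_index("bin")["value"]
        zone = prof.to_frame().set_index("bin")["zone"]
        out = pd.DataFrame(tables)
        out.insert(0, "zone", zone)
        return out

    meta_prof = stage("metagene")(_metagene)
    _write_tsv(meta_prof, outdir / "metagene.tsv", "hmcscan metagene", seed, "bin")
    results["metagene"] = meta_prof

    def _summary():
        rows = {}
        for sample, pk in peaks.items():
            s = coverage.enrichment_summary(pk, genes, chrom_sizes)
            rows[sample] = {
                "total_enriched_bp": s["total_enriched_bp"],
                "pct_genome_enriched": s["pct_genome_enriched"],
                "n_peaks": s["n_peaks"],
                "peak_length_mean": s["peak_length_mean"],
                "peak_length_median": s["peak_length_median"],
            }
        return pd.DataFrame(rows).T.rename_axis("sample")

    summary = stage("summary")(_summary)
    _write_tsv(summary, outdir / "enrichment_summary.tsv", "hmcscan summary", seed)
    results["summary"] = summary

    sim = stage("similarity")(lambda: association.sample_similarity(cov))
    _write_tsv(sim, outdir / "similarity.tsv", "hmcscan similarity", seed, "sample")
    results["similarity"] = sim

    counts = expression.read_counts(config.counts)
    meta = expression.read_sample_meta(config.sample_meta)
    expr = stage("expression")(
        lambda: expression.ExpressionMatrix(counts, meta))
    _write_tsv(expr.log2cpm, outdir / "log2cpm.tsv", "hmcscan expression",
               seed, "gene_id")
    results["expression"] = expr

    cov_meta = pd.read_csv(config.coverage_meta, sep="\t", index_col=0,
                           comment="#")
    gene_by_id = {g.gene_id: g for g in genes}

    def _cluster():
        out = {}
        pc = [g for g in genes if g.biotype == "protein_coding"
              and g.chrom not in chrom_sizes.sex_chroms]
        for organ in sorted(cov_meta["organ"].unique()):
            organ_samples = cov_meta.index[cov_meta["organ"] == organ]
            profs = None
            for s in organ_samples:
                p = coverage.gene_body_profiles(pc, peaks[s],
                                                config.metagene_body_bins)
                profs = p if profs is None else profs + p
            profs /= len(organ_samples)
            out[organ] = association.cluster_genes(
                profs, k=config.cluster_k, method=config.cluster_linkage)
        return out

    clusters = stage("cluster")(_cluster)
    assign = pd.DataFrame({organ: ca.labels for organ, ca in clusters.items()})
    _write_tsv(assign, outdir / "clusters.tsv", "hmcscan cluster", seed, "gene_id")
    results["clusters"] = clusters

    def _tests():
        organs = sorted(cov_meta["organ"].unique())
        frames = []
        biotype = pd.Series({g.gene_id: g.biotype for g in genes})
        for organ in organs:
            organ_cov = cov[cov_meta.index[cov_meta["organ"] == organ]]
            organ_expr_samples = expr.samples_of(organ=organ)
            vals = expr.log2cpm[organ_expr_samples].mean(axis=1)
            marked = (organ_cov > 0).any(axis=1)
            common = vals.index.intersection(marked.index)
            tab = association.marked_vs_unmarked_test(
                vals.loc[common], marked.loc[common],
                biotype.reindex(common).fillna("other"))
            tab.insert(0, "organ", organ)
            frames.append(tab.reset_index())
        return pd.concat(frames, ignore_index=True)

    tests = stage("tests")(_tests)
    _write_tsv(tests.set_index(["organ", "group"]), outdir / "tests.tsv",
               "hmcscan tests", seed)
    results["tests"] = tests

    def _specificity():
        ts = specificity.tissue_specific_genes(expr, tau_mod=config.tau_mod,
                                               tau_off=config.tau_off)
        sx = specificity.sex_specific_enrichment(cov, cov_meta,
                                                 tau_cov=config.tau_cov)
        ex = specificity.expression_5hmc_exceptions(
            expr, cov, genes, chrom_sizes, tau_on=config.tau_on,
            tau_mod=config.tau_mod, tau_cov=config.tau_cov)
        return specificity.SpecificityResult(
            brain_specific=ts["brain_specific"],
            liver_specific=ts["liver_specific"],
            sex_specific=sx,
            exception_class1=ex["class1"],
            exception_class2=ex["class2"],
            thresholds={"tau_mod": config.tau_mod, "tau_on": config.tau_on,
                        "tau_off": config.tau_off, "tau_cov": config.tau_cov},
        )

    spec_res = stage("specificity")(_specificity)
    rows = ([{"gene_id": g, "call": "brain_specific"}
             for g in sorted(spec_res.brain_specific)]
            + [{"gene_id": g, "call": "liver_specific"}
               for g in sorted(spec_res.liver_specific)]
            + [{"gene_id": g, "call": "exception_class1"}
               for g in sorted(spec_res.exception_class1)]
            + [{"gene_id": g, "call": "exception_class2"}
               for g in sorted(spec_res.exception_class2)])
    _write_tsv(pd.DataFrame(rows, columns=["gene_id", "call"]).set_index("gene_id"),
               outdir / "specificity.tsv", "hmcscan specificity", seed)
    _write_tsv(spec_res.sex_specific.set_index("gene_id")
               if len(spec_res.sex_specific) else
               pd.DataFrame(columns=["scope", "enriched_sex"]).rename_axis("gene_id"),
               outdir / "sex_specific.tsv", "hmcscan specificity", seed)
    results["specificity"] = spec_res

    (outdir / "manifest.json").write_text(json.dumps({
        "seed": seed,
        "config": {f.name: getattr(config, f.name) for f in fields(config)},
        "stages": manifest,
    }, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def report(outdir: str | Path, results: Dict, seed: int = 0,
           make_plots: bool = False) -> pd.DataFrame:
    """One-page consolidated summary across stages, written as TSV.

    With ``make_plots`` a minimal similarity heatmap and cluster-size bar
    chart are rendered alongside the TSV.
    """
    outdir = Path(outdir)
    if make_plots:
        _report_plots(outdir, results)
    lines = []
    summary = results["summary"]
    for sample, row in summary.iterrows():
        lines.append({"metric": f"pct_genome_enriched[{sample}]",
                      "value": row["pct_genome_enriched"]})
    for organ, ca in results["clusters"].items():
        for label, size in ca.sizes.items():
            lines.append({"metric": f"cluster_size[{organ}:{label}]",
                          "value": size})
    expr = results["expression"]
    for organ, ca in results["clusters"].items():
        own = expr.samples_of(organ=organ)  # trend within the organ's libraries
        med = association.cluster_expression_summary(ca, expr.log2cpm[own])
        lines.append({"metric": f"cluster_expression_trend_rho[{organ}]",
                      "value": med["trend_rho"]})
    spec_res = results["specificity"]
    lines += [
        {"metric": "n_brain_specific", "value": len(spec_res.brain_specific)},
        {"metric": "n_liver_specific", "value": len(spec_res.liver_specific)},
        {"metric": "n_exception_class1", "value": len(spec_res.exception_class1)},
        {"metric": "n_exception_class2", "value": len(spec_res.exception_class2)},
        {"metric": "n_sex_specific_overall",
         "value": int((spec_res.sex_specific["scope"] == "overall").sum())
         if len(spec_res.sex_specific) else 0},
    ]
    df = pd.DataFrame(lines).set_index("metric")
    _write_tsv(df, outdir / "report.tsv", "hmcscan report", seed)
    return df


def _report_plots(outdir: Path, results: Dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sim = results["similarity"]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    im = axes[0].imshow(sim.to_numpy(), vmin=0.5, vmax=1.0, cmap="RdBu_r")
    axes[0].set_xticks(range(len(sim)), sim.columns, rotation=90, fontsize=7)
    axes[0].set_yticks(range(len(sim)), sim.index, fontsize=7)
    axes[0].set_title("Coverage similarity (Spearman)")
    fig.colorbar(im, ax=axes[0], shrink=0.8)
    offset = 0.0
    for organ, ca in sorted(results["clusters"].items()):
        xs = np.arange(len(ca.sizes)) + offset
        axes[1].bar(xs, ca.sizes.to_numpy(), width=0.38, label=organ)
        offset += 0.4
    axes[1].set_xticks(np.arange(5) + 0.2, [f"C{i}" for i in range(1, 6)])
    axes[1].set_ylabel("genes")
    axes[1].set_title("Cluster sizes")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=110)
    plt.close(fig)
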