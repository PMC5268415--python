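"""Synthetic toy dataset with planted structure for pipeline testing.

The generator emulates the study design the pipeline targets: twelve
coverage samples (five brain regions + liver, both sexes), twenty-four
expression libraries (the same design cells with two replicates), a toy
genome of three autosomes plus X/Y analogs, and planted structure at every
level —

* organ-level relatedness of coverage profiles (thalamus/hypothalamus most
  alike, cerebellum most distinct, liver lowest overall),
* 3'-biased intragenic peak placement with ~800 bp mean peak length,
* sex-chromosome depletion with a single female-only X-linked gene (the
  Xist analog),
* negative-binomial counts whose means follow a monotone log-linear
  function of intragenic coverage, except for a designated housekeeping set
  (decoupled, constitutively high) and two planted exception classes.

Every planted quantity is recorded in :class:`SyntheticTruth` so tests can
assert recovery, and every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from hmcscan.annotation import GeneModel, write_gtf_genes
from hmcscan.intervals import ChromSizes, GenomicInterval, IntervalSet, write_bed

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_peaks",
    "simulate_counts",
    "simulate_fragments",
    "write_dataset",
]

REGIONS = ("cerebellum", "cortex", "hippocampus", "hypothalamus", "thalamus")
REGION_ABBREV = {"cerebellum": "Cb", "cortex": "Cx", "hippocampus": "Hi",
                 "hypothalamus": "Hy", "thalamus": "Th", "liver": "Lv"}
HOUSEKEEPING_CLASSES = ("citric_acid_cycle", "rna_polymerase", "ribosomal",
                        "cytoskeleton", "mitochondrial")


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; the defaults define the standard toy conditions."""

    n_genes: int = 1000
    chrom_lengths: Tuple[Tuple[str, int], ...] = (
        ("chr1", 10_000_000), ("chr2", 8_000_000), ("chr3", 7_000_000),
        ("chrX", 4_000_000), ("chrY", 1_000_000),
    )
    gene_len_log_mean: float = np.log(8000.0)
    gene_len_log_sd: float = 0.9
    gene_len_min: int = 1_000
    gene_len_max: int = 100_000
    # coverage-target distributions (organ-level Beta mixtures)
    brain_beta: Tuple[float, float] = (2.0, 1.2)
    liver_beta: Tuple[float, float] = (1.2, 2.5)
    liver_share: float = 0.55       # latent-rank sharing between organs
    sigma_forebrain: float = 0.04   # cortex/hippocampus deviation
    sigma_diencephalon: float = 0.01  # thalamus/hypothalamus split
    sigma_cerebellum: float = 0.07
    sigma_sex: float = 0.01
    zero_floor: float = 0.03        # targets below this collapse to 0
    # peak geometry
    peak_len_mean: float = 800.0
    peak_len_sd: float = 200.0
    peak_len_min: int = 100
    peak_len_max: int = 3000
    three_prime_bias: float = 2.5   # 5'-most gap weight (tapers to 0.15 at 3')
    n_background_peaks: int = 50    # intergenic peaks per sample
    # expression link: log2 cpm = a + b * coverage + organ shift
    library_size: float = 1.2e6    # expected total counts per library
    link_intercept: float = 9.5
    link_slope: float = 1.5
    nb_dispersion: float = 0.1
    liver_expr_shift: float = -0.3
    housekeeping_log2cpm: float = 11.0
    # planted gene sets
    n_housekeeping_per_class: int = 12
    n_brain_specific: int = 40
    n_liver_specific: int = 20
    n_exception_class1: int = 15
    n_exception_class2: int = 12
    specific_log2cpm: float = 10.0
    xist_coverage: float = 0.6

    @property
    def coverage_samples(self) -> List[str]:
        return [f"{REGION_ABBREV[r]}_{s}"
                for r in (*REGIONS, "liver") for s in ("F", "M")]

    @property
    def expression_samples(self) -> List[str]:
        return [f"{c}_r{k}" for c in self.coverage_samples for k in (1, 2)]


@dataclass
class SyntheticTruth:
    """Every planted parameter of one simulated dataset."""

    params: SimulationParams
    seed: int
    chrom_sizes: ChromSizes
    genes: List[GeneModel]
    coverage_targets: pd.DataFrame       # genes x 12 coverage samples
    coverage_meta: pd.DataFrame          # sample -> organ, region, sex
    expression_meta: pd.DataFrame        # sample -> organ, region, sex, replicate
    gene_sets: Dict[str, List[str]]
    xist_gene: str

    def gene_by_id(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


_BIOTYPE_PROBS = {
    "protein_coding": 0.62,
    "pseudogene": 0.14,
    "lincRNA": 0.08,
    "processed_transcript": 0.06,
    "short_ncRNA": 0.10,
}
_MOLTYPE_PROBS = {
    "enzyme": 0.25, "kinase": 0.08, "transcription_regulator": 0.12,
    "transporter": 0.12, "ion_channel": 0.08, "gpcr": 0.07, "other": 0.28,
}


def _simulate_genes(params: SimulationParams,
                    rng: np.random.Generator) -> Tuple[List[GeneModel], ChromSizes]:
    """Non-overlapping genes with log-normal lengths on the toy genome."""
    chrom_sizes = ChromSizes(dict(params.chrom_lengths))
    autosomes = [c for c in chrom_sizes.sizes if c not in chrom_sizes.sex_chroms]
    # keep sex chromosomes gene-sparse: ~4% of genes on X, ~0.5% on Y
    n_x = max(int(round(params.n_genes * 0.04)), 2)
    n_y = max(int(round(params.n_genes * 0.005)), 1)
    n_auto = params.n_genes - n_x - n_y
    auto_len = np.array([chrom_sizes[c] for c in autosomes], dtype=float)
    alloc = {c: int(round(n_auto * w)) for c, w in
             zip(autosomes, auto_len / auto_len.sum())}
    alloc[autosomes[0]] += n_auto - sum(alloc.values())
    alloc["chrX"] = n_x
    alloc["chrY"] = n_y
    genes: List[GeneModel] = []
    gid = 0
    for chrom, n in alloc.items():
        L = chrom_sizes[chrom]
        lengths = np.clip(
            rng.lognormal(params.gene_len_log_mean, params.gene_len_log_sd, n),
            params.gene_len_min, params.gene_len_max,
        ).astype(np.int64)
        while lengths.sum() > 0.7 * L and len(lengths) > 1:
            lengths = lengths[:-1]
        n = len(lengths)
        free = L - int(lengths.sum())
        gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free * 0.95).astype(np.int64)
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start, end = pos, pos + int(lengths[i])
            pos = end
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = rng.choice(list(_BIOTYPE_PROBS),
                                 p=list(_BIOTYPE_PROBS.values()))
            if biotype == "protein_coding":
                moltype = rng.choice(list(_MOLTYPE_PROBS),
                                     p=list(_MOLTYPE_PROBS.values()))
            elif biotype == "short_ncRNA":
                moltype = "microRNA" if rng.random() < 0.3 else "other"
            else:
                moltype = "other"
            genes.append(GeneModel(
                gene_id=f"G{gid:05d}", name=f"Gene{gid}",
                span=GenomicInterval(chrom, start, end, strand),
                biotype=str(biotype), molecule_type=str(moltype),
            ))
    return genes, chrom_sizes


def _assign_gene_sets(genes: List[GeneModel], params: SimulationParams,
                      rng: np.random.Generator,
                      chrom_sizes: ChromSizes) -> Tuple[Dict[str, List[str]], str]:
    """Draw disjoint planted gene sets from autosomal protein-coding genes."""
    pool = [g.gene_id for g in genes
            if g.biotype == "protein_coding"
            and g.chrom not in chrom_sizes.sex_chroms
            and g.length >= 3000]
    rng.shuffle(pool)
    sets: Dict[str, List[str]] = {}
    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        chunk = pool[cursor:cursor + n]
        cursor += n
        return chunk

    for cls in HOUSEKEEPING_CLASSES:
        sets[f"housekeeping_{cls}"] = take(params.n_housekeeping_per_class)
    sets["housekeeping"] = [g for cls in HOUSEKEEPING_CLASSES
                            for g in sets[f"housekeeping_{cls}"]]
    sets["brain_specific"] = take(params.n_brain_specific)
    sets["liver_specific"] = take(params.n_liver_specific)
    sets["exception_class1"] = take(params.n_exception_class1)
    sets["exception_class2"] = take(params.n_exception_class2)
    x_genes = [g.gene_id for g in genes if g.chrom == "chrX"]
    xist = x_genes[int(rng.integers(len(x_genes)))]
    sets["xist_analog"] = [xist]
    return sets, xist


def _coverage_targets(genes: List[GeneModel], sets: Dict[str, List[str]],
                      xist: str, params: SimulationParams,
                      rng: np.random.Generator,
                      chrom_sizes: ChromSizes) -> pd.DataFrame:
    """Planted per-gene, per-sample intragenic coverage fractions."""
    p = params
    n = len(genes)
    samples = p.coverage_samples
    u = rng.random(n)
    v_brain = stats.beta.ppf(u, *p.brain_beta)
    u_liver = np.clip(p.liver_share * u
                      + (1 - p.liver_share) * rng.random(n), 1e-9, 1 - 1e-9)
    v_liver = stats.beta.ppf(u_liver, *p.liver_beta)
    dien = v_brain + rng.normal(0, p.sigma_diencephalon * 3, n)
    region_value = {
        "cerebellum": v_brain + rng.normal(0, p.sigma_cerebellum, n),
        "cortex": v_brain + rng.normal(0, p.sigma_forebrain, n),
        "hippocampus": v_brain + rng.normal(0, p.sigma_forebrain, n),
        "hypothalamus": dien + rng.normal(0, p.sigma_diencephalon, n),
        "thalamus": dien + rng.normal(0, p.sigma_diencephalon, n),
        "liver": v_liver,
    }
    targets = {}
    for region in (*REGIONS, "liver"):
        for sex in ("F", "M"):
            col = f"{REGION_ABBREV[region]}_{sex}"
            vals = region_value[region] + rng.normal(0, p.sigma_sex, n)
            targets[col] = np.clip(vals, 0.0, 1.0)
    df = pd.DataFrame(targets, index=[g.gene_id for g in genes])[samples]
    # low-enrichment biotypes (pseudogenes, short ncRNAs) are scaled down
    lowbio = [g.gene_id for g in genes
              if g.biotype in ("pseudogene", "short_ncRNA")]
    df.loc[lowbio] *= 0.25
    df[df < p.zero_floor] = 0.0
    # sex chromosomes depleted; the Xist analog is covered only in females
    sex_genes = [g.gene_id for g in genes if g.chrom in chrom_sizes.sex_chroms]
    df.loc[sex_genes] = 0.0
    f_cols = [s for s in samples if s.endswith("_F")]
    df.loc[xist, f_cols] = p.xist_coverage
    # organ-specific genes: enriched only in their organ
    brain_cols = [s for s in samples if not s.startswith("Lv")]
    liver_cols = [s for s in samples if s.startswith("Lv")]
    nb, nl = len(sets["brain_specific"]), len(sets["liver_specific"])
    df.loc[sets["brain_specific"], brain_cols] = (
        np.clip(rng.beta(6, 2, (nb, 1)) + rng.normal(0, 0.02, (nb, len(brain_cols))),
                0.1, 1.0))
    df.loc[sets["brain_specific"], liver_cols] = 0.0
    df.loc[sets["liver_specific"], liver_cols] = (
        np.clip(rng.beta(4, 2, (nl, 1)) + rng.normal(0, 0.02, (nl, len(liver_cols))),
                0.1, 1.0))
    df.loc[sets["liver_specific"], brain_cols] = 0.0
    # exception classes override the link
    df.loc[sets["exception_class1"]] = 0.0
    n2 = len(sets["exception_class2"])
    df.loc[sets["exception_class2"]] = np.clip(
        rng.beta(5, 2, (n2, 1)) + rng.normal(0, 0.02, (n2, len(samples))),
        0.3, 1.0)
    return df


def simulate_truth(params: SimulationParams = SimulationParams(),
                   seed: int = 0) -> SyntheticTruth:
    """Build the full planted-truth object (annotation, sets, targets)."""
    rng = np.random.default_rng([seed, 1])
    genes, chrom_sizes = _simulate_genes(params, rng)
    sets, xist = _assign_gene_sets(genes, params, rng, chrom_sizes)
    targets = _coverage_targets(genes, sets, xist, params, rng, chrom_sizes)
    cov_meta = pd.DataFrame(
        [{"sample": f"{REGION_ABBREV[r]}_{s}",
          "organ": "liver" if r == "liver" else "brain",
          "region": r, "sex": s}
         for r in (*REGIONS, "liver") for s in ("F", "M")]
    ).set_index("sample")
    expr_meta = pd.DataFrame(
        [{"sample": f"{REGION_ABBREV[r]}_{s}_r{k}",
          "organ": "liver" if r == "liver" else "brain",
          "region": r, "sex": s, "replicate": f"r{k}"}
         for r in (*REGIONS, "liver") for s in ("F", "M") for k in (1, 2)]
    ).set_index("sample")
    return SyntheticTruth(params, seed, chrom_sizes, genes, targets,
                          cov_meta, expr_meta, sets, xist)


def _truncnorm_lengths(n: int, params: SimulationParams,
                       rng: np.random.Generator) -> np.ndarray:
    lens = rng.normal(params.peak_len_mean, params.peak_len_sd, n)
    return np.clip(lens, params.peak_len_min, params.peak_len_max)


def _place_gene_peaks(gene: GeneModel, target: float,
                      params: SimulationParams,
                      rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Disjoint peaks inside the gene body hitting the target coverage.

    The covered bases are laid out as alternating gap/peak segments whose
    gap weights decrease 5'->3', producing the planted 3'-bias; realized
    coverage equals the target up to rounding.
    """
    L = gene.length
    needed = int(round(target * L))
    if needed < params.peak_len_min:
        return []
    needed = min(needed, L)
    n = max(1, int(round(needed / params.peak_len_mean)))
    lens = _truncnorm_lengths(n, params, rng)
    lens = np.maximum(np.round(lens * needed / lens.sum()), 1).astype(np.int64)
    lens[-1] += needed - lens.sum()  # exact total
    if lens[-1] < 1:
        lens = lens[lens > 0]
        if len(lens) == 0:
            return []
    free = L - int(lens.sum())
    # gap weights decrease linearly 5'->3' and nearly vanish at the gene end,
    # so uncovered space concentrates at the 5' end: a linear coverage gradient
    weights = np.linspace(params.three_prime_bias, 0.15, len(lens) + 1)
    gaps = np.floor(rng.dirichlet(weights * 2.0) * free).astype(np.int64)
    spans: List[Tuple[int, int]] = []
    pos = 0
    for i, plen in enumerate(lens):
        pos += int(gaps[i])
        spans.append((pos, pos + int(plen)))
        pos += int(plen)
    # 5'->3' layout: map to genomic coordinates respecting strand
    out = []
    for s, e in spans:
        if gene.span.strand == "+":
            out.append((gene.span.start + s, gene.span.start + e))
        else:
            out.append((gene.span.end - e, gene.span.end - s))
    return sorted(out)


def simulate_peaks(truth: SyntheticTruth,
                   seed: int | None = None) -> Dict[str, IntervalSet]:
    """Per-sample peak sets realizing the planted coverage targets."""
    params = truth.params
    seed = truth.seed if seed is None else seed
    peaks_by_sample: Dict[str, IntervalSet] = {}
    gene_space = {}
    for g in truth.genes:
        gene_space.setdefault(g.chrom, []).append((g.span.start, g.span.end))
    for si, sample in enumerate(truth.coverage_targets.columns):
        rng = np.random.default_rng([seed, 2, si])
        ivs: List[GenomicInterval] = []
        col = truth.coverage_targets[sample]
        for g in truth.genes:
            target = float(col.loc[g.gene_id])
            if target <= 0:
                continue
            for s, e in _place_gene_peaks(g, target, params, rng):
                ivs.append(GenomicInterval(g.chrom, s, e))
        # sparse intergenic background peaks
        chroms = list(truth.chrom_sizes.sizes)
        weights = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        placed = 0
        attempts = 0
        while placed < params.n_background_peaks and attempts < 50 * params.n_background_peaks:
            attempts += 1
            chrom = str(rng.choice(chroms, p=weights))
            plen = int(_truncnorm_lengths(1, params, rng)[0])
            start = int(rng.integers(0, truth.chrom_sizes[chrom] - plen))
            end = start + plen
            if any(s < end and start < e for s, e in gene_space.get(chrom, [])):
                continue
            ivs.append(GenomicInterval(chrom, start, end))
            placed += 1
        peaks_by_sample[sample] = IntervalSet(ivs).sorted()
    return peaks_by_sample


def simulate_counts(truth: SyntheticTruth,
                    seed: int | None = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix following the planted coverage link.

    mean count = 2^(a + b * coverage + organ shift), with housekeeping
    genes pinned at a constitutively high mean independent of coverage,
    exception classes overriding the link, and the Xist analog expressed
    only in female samples.
    """
    p = truth.params
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 3])
    gene_ids = truth.coverage_targets.index
    n = len(gene_ids)
    sets = truth.gene_sets
    hk = set(sets["housekeeping"])
    c1, c2 = set(sets["exception_class1"]), set(sets["exception_class2"])
    bspec, lspec = set(sets["brain_specific"]), set(sets["liver_specific"])
    hk_level = p.housekeeping_log2cpm + rng.normal(0, 0.15, n)  # per-gene
    counts = {}
    for sample, meta in truth.expression_meta.iterrows():
        cell = f"{REGION_ABBREV[meta['region']]}_{meta['sex']}"
        cov = truth.coverage_targets[cell].to_numpy()
        shift = p.liver_expr_shift if meta["organ"] == "liver" else 0.0
        log2mean = p.link_intercept + p.link_slope * cov + shift
        mean = np.power(2.0, log2mean)
        for i, g in enumerate(gene_ids):
            if g in hk:
                mean[i] = 2.0 ** hk_level[i]
            elif g in c1:
                mean[i] = 2.0 ** (p.link_intercept + 1.0)
            elif g in c2:
                mean[i] = 0.0
            elif g in bspec:
                mean[i] = (2.0 ** p.specific_log2cpm
                           if meta["organ"] == "brain" else 0.0)
            elif g in lspec:
                mean[i] = (2.0 ** p.specific_log2cpm
                           if meta["organ"] == "liver" else 0.0)
            elif g == truth.xist_gene:
                mean[i] = 2.0 ** p.specific_log2cpm if meta["sex"] == "F" else 0.0
        # pin the expected library size so planted levels are CPM-scale:
        # a gene's expected CPM is then its mean / library_size x 1e6,
        # independent of how much the rest of the library expresses
        lib_jitter = float(rng.lognormal(0, 0.08))
        mean *= p.library_size * lib_jitter / mean.sum()
        size = 1.0 / p.nb_dispersion
        prob = size / (size + np.maximum(mean, 1e-12))
        col = rng.negative_binomial(size, prob)
        col[mean == 0.0] = 0
        counts[sample] = col.astype(np.int64)
    counts_df = pd.DataFrame(counts, index=gene_ids)[list(truth.expression_meta.index)]
    return counts_df, truth.expression_meta.copy()


def simulate_fragments(islands: IntervalSet, chrom_sizes: ChromSizes,
                       n_control: int = 20_000, fold: float = 10.0,
                       fragment_len: int = 200,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> Tuple[IntervalSet, IntervalSet]:
    """Treatment/control fragment sets with uniform background.

    The control is uniform over the genome at the stated count; the
    treatment has the same background rate plus ``(fold - 1)x`` extra
    fragments inside the true islands. Fragments are ``fragment_len`` bp.
    """
    if rng is None:
        rng = np.random.default_rng([seed, 4])
    chroms = list(chrom_sizes.sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genome = weights.sum()
    weights /= genome

    def uniform_frags(n: int) -> List[GenomicInterval]:
        out = []
        picks = rng.choice(len(chroms), size=n, p=weights)
        for ci in picks:
            chrom = chroms[ci]
            hi = max(chrom_sizes[chrom] - fragment_len, 1)
            start = int(rng.integers(0, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(GenomicInterval(chrom, start, start + fragment_len, strand))
        return out

    ctrl = uniform_frags(n_control)
    treat = uniform_frags(n_control)
    rate = n_control / genome  # background fragments per bp
    for isl in islands:
        extra = rng.poisson((fold - 1.0) * rate * isl.length)
        for _ in range(int(extra)):
            mid = int(rng.integers(isl.start, isl.end))
            start = max(mid - fragment_len // 2, 0)
            strand = "+" if rng.random() < 0.5 else "-"
            treat.append(GenomicInterval(isl.chrom, start,
                                         start + fragment_len, strand))
    return IntervalSet(treat).sorted(), IntervalSet(ctrl).sorted()


def write_dataset(outdir: str | Path, seed: int = 0,
                  params: SimulationParams = SimulationParams()) -> SyntheticTruth:
    """Generate and write the complete dataset to ``outdir``.

    Writes: annotation.gtf, chrom.sizes, one peak BED per coverage sample,
    counts.tsv + sample_meta.tsv, gene_sets.tsv and truth TSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(params, seed)
    write_gtf_genes(truth.genes, outdir / "annotation.gtf")
    with (outdir / "chrom.sizes").open("w") as fh:
        for c, L in truth.chrom_sizes.sizes.items():
            fh.write(f"{c}\t{L}\n")
    peaks = simulate_peaks(truth)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sample, ivs in peaks.items():
        write_bed(ivs, peak_dir / f"{sample}.bed")
    counts, meta = simulate_counts(truth)
    counts.rename_axis("gene_id").to_csv(outdir / "counts.tsv", sep="\t")
    meta.rename_axis("sample").to_csv(outdir / "sample_meta.tsv", sep="\t")
    truth.coverage_meta.rename_axis("sample").to_csv(
        outdir / "coverage_meta.tsv", sep="\t")
    with (outdir / "gene_sets.tsv").open("w") as fh:
        for name, ids in truth.gene_sets.items():
            for g in ids:
                fh.write(f"{g}\t{name}\n")
    truth.coverage_targets.rename_axis("gene_id").to_csv(
        outdir / "truth_coverage_targets.tsv", sep="\t")
    return truth
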