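"""Organ-specific, sex-specific and exception-class gene calling.

Integrates the binary expression status with intragenic 5hmC coverage:

* tissue-specific genes — moderately-to-highly expressed in every sample of
  one organ and off in every sample of the other;
* sex-specific enrichment — covered in every sample of one sex and entirely
  uncovered in the other (the pattern the X-inactivation transcript shows);
* exception classes — protein-coding autosomal genes that are expressed
  without any 5hmC (class 1) or 5hmC-marked without expression (class 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Set

import pandas as pd

from hmcscan.annotation import GeneModel
from hmcscan.expression import ExpressionMatrix, TAU_MODERATE
from hmcscan.intervals import ChromSizes

__all__ = [
    "tissue_specific_genes",
    "sex_specific_enrichment",
    "expression_5hmc_exceptions",
    "SpecificityResult",
]


@dataclass
class SpecificityResult:
    """Bundled output of the three specificity scans."""

    brain_specific: Set[str] = field(default_factory=set)
    liver_specific: Set[str] = field(default_factory=set)
    sex_specific: pd.DataFrame = field(default_factory=pd.DataFrame)
    exception_class1: Set[str] = field(default_factory=set)
    exception_class2: Set[str] = field(default_factory=set)
    thresholds: dict = field(default_factory=dict)


def tissue_specific_genes(expr: ExpressionMatrix, tau_mod: float = TAU_MODERATE,
                          tau_off: float = 0.0) -> dict:
    """Organ-specific genes by an ALL-samples threshold rule.

    brain-specific: log2 CPM >= ``tau_mod`` in every brain sample AND
    < ``tau_off`` in every liver sample; liver-specific symmetric.
    """
    brain = expr.samples_of(organ="brain")
    liver = expr.samples_of(organ="liver")
    if len(brain) == 0 or len(liver) == 0:
        raise ValueError("both organs need at least one sample")
    lcpm = expr.log2cpm
    brain_on = (lcpm[brain] >= tau_mod).all(axis=1)
    brain_off = (lcpm[brain] < tau_off).all(axis=1)
    liver_on = (lcpm[liver] >= tau_mod).all(axis=1)
    liver_off = (lcpm[liver] < tau_off).all(axis=1)
    return {
        "brain_specific": set(lcpm.index[brain_on & liver_off]),
        "liver_specific": set(lcpm.index[liver_on & brain_off]),
    }


def sex_specific_enrichment(coverage: pd.DataFrame, meta: pd.DataFrame,
                            tau_cov: float = 0.0) -> pd.DataFrame:
    """Genes with strictly sex-asymmetric 5hmC enrichment.

    A gene is flagged when its intragenic coverage exceeds ``tau_cov`` (any
    overlap at the default 0) in *every* sample of one sex and is exactly 0
    in *every* sample of the other, evaluated genome-wide and per organ.
    Returns records (gene_id, scope, enriched_sex).
    """
    scopes = {"overall": coverage.columns}
    for organ in meta["organ"].unique():
        cols = meta.index[meta["organ"] == organ].intersection(coverage.columns)
        scopes[str(organ)] = cols
    records: List[dict] = []
    for scope, cols in scopes.items():
        sub_meta = meta.loc[cols]
        f_cols = sub_meta.index[sub_meta["sex"] == "F"]
        m_cols = sub_meta.index[sub_meta["sex"] == "M"]
        if len(f_cols) == 0 or len(m_cols) == 0:
            continue
        f_cov = coverage[f_cols]
        m_cov = coverage[m_cols]
        female_only = (f_cov > tau_cov).all(axis=1) & (m_cov == 0).all(axis=1)
        male_only = (m_cov > tau_cov).all(axis=1) & (f_cov == 0).all(axis=1)
        for g in coverage.index[female_only]:
            records.append({"gene_id": g, "scope": scope, "enriched_sex": "F"})
        for g in coverage.index[male_only]:
            records.append({"gene_id": g, "scope": scope, "enriched_sex": "M"})
    return pd.DataFrame(records, columns=["gene_id", "scope", "enriched_sex"])


def expression_5hmc_exceptions(expr: ExpressionMatrix, coverage: pd.DataFrame,
                               genes: Sequence[GeneModel],
                               chrom_sizes: ChromSizes,
                               tau_on: float = 0.0,
                               tau_mod: float = TAU_MODERATE,
                               tau_cov: float = 0.0) -> dict:
    """Exception classes of the coverage-expression correlation.

    Universe: protein-coding genes on autosomes (sex chromosomes excluded).
    Class 1: moderately-to-highly expressed (>= ``tau_mod``) in ALL
    expression samples AND coverage exactly 0 in ALL coverage samples.
    Class 2: below ``tau_on`` in ALL expression samples AND coverage above
    ``tau_cov`` in ALL coverage samples. The two classes are exclusive by
    construction.
    """
    universe = [
        g.gene_id for g in genes
        if g.biotype == "protein_coding" and g.chrom not in chrom_sizes.sex_chroms
    ]
    universe = [g for g in universe
                if g in expr.log2cpm.index and g in coverage.index]
    lcpm = expr.log2cpm.loc[universe]
    cov = coverage.loc[universe]
    expressed_all = (lcpm >= tau_mod).all(axis=1)
    silent_all = (lcpm < tau_on).all(axis=1)
    no_cov = (cov == 0).all(axis=1)
    high_cov = (cov > tau_cov).all(axis=1)
    class1 = set(lcpm.index[expressed_all & no_cov])
    class2 = set(lcpm.index[silent_all & high_cov])
    assert not (class1 & class2), "exception classes must be disjoint"
    return {"class1": class1, "class2": class2, "universe_size": len(universe)}
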