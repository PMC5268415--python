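"""Expression quantification: TMM normalization, log2 CPM, status flags.

Counts come in as a gene x sample integer matrix. Library-size
normalization uses the trimmed mean of M-values (TMM): per sample, log2
count-ratios against a reference sample are doubly trimmed (30% on M, 5% on
A) and precision-weighted; the resulting factors are rescaled to geometric
mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "tmm_factors",
    "log2_cpm",
    "ExpressionMatrix",
    "expression_status",
    "ExpressionStatus",
    "read_counts",
    "read_sample_meta",
]

TAU_MODERATE = 2.5  # log2 CPM threshold for "moderately to highly expressed"


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """TMM factor of one sample against the reference (log2 scale -> linear)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no nonzero genes with the reference")
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # precision weights: inverse asymptotic variance of M
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m / 2) + 1, n + 1 - (np.floor(n * trim_m / 2) + 1)
    lo_a, hi_a = np.floor(n * trim_a / 2) + 1, n + 1 - (np.floor(n * trim_a / 2) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    return float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those quantiles. Factors are rescaled so their
    geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with empty libraries: {bad}")
    q75 = counts.div(lib, axis=1).quantile(0.75)
    ref_sample = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            try:
                factors[s] = _tmm_pair(counts[s].to_numpy(), ref, trim_m, trim_a)
            except ValueError as err:
                raise ValueError(f"sample {s!r}: {err}") from err
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def log2_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
             prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        if (factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        lib = lib * factors.reindex(counts.columns)
    denom = lib + 2.0 * prior
    return np.log2((counts + prior).div(denom, axis=1) * 1e6)


@dataclass
class ExpressionMatrix:
    """Counts plus derived log2 CPM and sample metadata.

    ``meta`` is indexed by sample with columns ``organ`` (brain/liver),
    ``region`` (cerebellum/cortex/hippocampus/hypothalamus/thalamus/liver),
    ``sex`` (F/M) and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    factors: pd.Series = field(default=None)  # type: ignore[assignment]
    log2cpm: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.factors is None:
            self.factors = tmm_factors(self.counts)
        if self.log2cpm is None:
            self.log2cpm = log2_cpm(self.counts, self.factors)

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, **criteria) -> pd.Index:
        mask = pd.Series(True, index=self.meta.index)
        for key, value in criteria.items():
            mask &= self.meta[key] == value
        return self.meta.index[mask].intersection(self.counts.columns)

    @property
    def groups(self) -> pd.DataFrame:
        """Design-cell label (region, sex) per sample."""
        return self.meta.assign(
            group=self.meta["region"].astype(str) + "_" + self.meta["sex"].astype(str)
        )


@dataclass
class ExpressionStatus:
    """Binary expression flags per gene.

    ``expressed``/``moderate_high`` are gene x sample booleans at
    ``tau_on``/``tau_mod``; the ``group_*`` frames aggregate replicates
    within each design cell (region, sex) with the ALL-replicates rule by
    default.
    """

    expressed: pd.DataFrame
    moderate_high: pd.DataFrame
    group_expressed: pd.DataFrame
    group_moderate_high: pd.DataFrame
    tau_on: float
    tau_mod: float


def expression_status(expr: ExpressionMatrix, tau_on: float = 0.0,
                      tau_mod: float = TAU_MODERATE,
                      rule: Literal["all", "any"] = "all") -> ExpressionStatus:
    """Threshold the log2 CPM matrix into binary expression status.

    ``tau_mod`` is inclusive (a gene at exactly the threshold is flagged
    moderate-high). Group flags combine replicates of a design cell with
    the ALL rule (every replicate must pass) or, optionally, ANY.
    """
    expressed = expr.log2cpm >= tau_on
    moderate = expr.log2cpm >= tau_mod
    groups = expr.groups.loc[expr.samples, "group"]
    agg = "all" if rule == "all" else "any"
    group_expr = expressed.T.groupby(groups).agg(agg).T
    group_mod = moderate.T.groupby(groups).agg(agg).T
    return ExpressionStatus(expressed, moderate, group_expr, group_mod,
                            tau_on, tau_mod)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV with gene_id as the first (index) column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(np.int64)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample, organ, region, sex, replicate)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#",
                       dtype={"replicate": str})
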