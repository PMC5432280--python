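"""FPKM quantification and negative-binomial differential expression.

The differential test replaces an external tool with a defined procedure:
median-of-ratios size factors, a single method-of-moments common dispersion
(NB variance mu + d*mu^2) pooled over transcripts and conditions, an exact
conditional NB test on the normalized group sums when the total is small and
a normal approximation otherwise, Benjamini-Hochberg adjustment over the
tested set, and calls at p_adjust < 0.05 and |log2 fold change| > 1 with the
male direction meaning higher SSC mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

MALE_CONDITION = "SSC"
FEMALE_CONDITION = "FGSC"
P_ADJUST_CUTOFF = 0.05
LOG2FC_CUTOFF = 1.0
EXACT_TEST_MAX_TOTAL = 2000
PSEUDOCOUNT = 1.0


@dataclass
class ExpressionTable:
    """Fragment counts per transcript per library plus quantification metadata."""

    counts: pd.DataFrame  # transcripts x libraries, non-negative integers
    effective_length_bp: Mapping[str, float]
    conditions: Mapping[str, str]  # library_id -> SSC | FGSC
    library_size: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ConfigError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.conditions]
        if missing:
            raise ConfigError(f"libraries without condition labels: {missing}")
        colsums = self.counts.sum(axis=0)
        if self.library_size is None:
            self.library_size = colsums.to_dict()
        else:
            for lib in self.counts.columns:
                if self.library_size[lib] < colsums[lib]:
                    raise ConfigError(
                        f"library_size < column sum for library {lib}"
                    )

    def libraries(self, condition: str) -> List[str]:
        return [c for c in self.counts.columns if self.conditions[c] == condition]


@dataclass
class DifferentialResult:
    transcript_id: str
    mean_fpkm: Dict[str, float]
    log2_fold_change: float
    p_value: float
    p_adjust: float
    call: str  # male_biased | female_biased | ns


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(table: ExpressionTable) -> pd.DataFrame:
    """FPKM = count / ((effective_length/1e3) * (library_size/1e6))."""
    lengths = np.array(
        [float(table.effective_length_bp[t]) for t in table.counts.index]
    )
    if (lengths <= 0).any():
        raise ConfigError("effective lengths must be positive")
    sizes = np.array([float(table.library_size[c]) for c in table.counts.columns])
    if (sizes <= 0).any():
        raise ConfigError("zero library size")
    denom = np.outer(lengths / 1e3, sizes / 1e6)
    return pd.DataFrame(
        table.counts.values / denom,
        index=table.counts.index,
        columns=table.counts.columns,
    )


def gene_fpkm(fpkm: pd.DataFrame, gene_map: Mapping[str, str]) -> pd.DataFrame:
    """Gene-level FPKM: sum of the FPKMs of the gene's transcripts."""
    genes = pd.Index([gene_map[t] for t in fpkm.index], name="gene_id")
    return fpkm.groupby(genes).sum()


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    values = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    finite = np.isfinite(log_values).all(axis=1)
    if finite.sum() == 0:
        totals = values.sum(axis=0)
        if totals.sum() == 0:
            return pd.Series(1.0, index=counts.columns)
        sf = totals / np.exp(np.mean(np.log(totals[totals > 0])))
        return pd.Series(sf, index=counts.columns)
    ref = log_values[finite].mean(axis=1)
    sf = np.exp(np.median(log_values[finite] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def common_dispersion(
    normalized: pd.DataFrame, condition_groups: Sequence[Sequence[str]]
) -> float:
    """Method-of-moments NB dispersion pooled over transcripts and conditions.

    Uses the pooled ratio estimator sum(v - m) / sum(m^2 - v/n) over every
    transcript and condition group (v, m = within-group sample variance and
    mean of the size-factor-normalized counts), floored at a tiny positive
    value so downstream tests remain defined.
    """
    num = 0.0
    den = 0.0
    for group in condition_groups:
        sub = normalized[list(group)].values
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        # pooled ratio estimator: E[v - m] = d*mu^2 and E[m^2 - v/n] = mu^2,
        # so the summed ratio is a stable, nearly unbiased common-d estimate
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2 - v[ok] / n))
    if den <= 0:
        return 1e-8
    return max(num / den, 1e-8)


# ---------------------------------------------------------------------------
# the NB test
# ---------------------------------------------------------------------------

def _exact_conditional_p(k_obs: int, total: int, n_a: int, n_b: int, d: float) -> float:
    """Two-sided exact conditional NB test.

    Under H0 the group sums are NB with shapes n_a/d and n_b/d and a common
    success probability, so the conditional law of the first group sum given
    the total is free of the mean (negative hypergeometric).  The two-sided p
    sums every outcome no more probable than the observed one.
    """
    r_a, r_b = n_a / d, n_b / d
    k = np.arange(total + 1)
    logw = (
        gammaln(k + r_a)
        - gammaln(k + 1)
        + gammaln(total - k + r_b)
        - gammaln(total - k + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[k_obs]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _approx_p(sum_a: float, sum_b: float, n_a: int, n_b: int, d: float) -> float:
    """Normal approximation on the NB group sums for large totals."""
    mu = (sum_a + sum_b) / (n_a + n_b)
    var_a = n_a * (mu + d * mu * mu)
    var_b = n_b * (mu + d * mu * mu)
    ratio = n_a / n_b  # rescale group B to group A's replicate count
    denom = np.sqrt(var_a + ratio * ratio * var_b)
    if denom == 0:
        return 1.0
    z = (sum_a - sum_b * ratio) / denom
    return float(2 * norm.sf(abs(z)))


def differential_expression(
    table: ExpressionTable,
    p_adjust_cutoff: float = P_ADJUST_CUTOFF,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
) -> pd.DataFrame:
    """Run the NB test on every transcript of the table.

    Returns a DataFrame indexed by transcript_id with mean FPKM per condition,
    log2 fold change (SSC over FGSC, pseudocount 1 on normalized means),
    p_value, p_adjust (BH over the tested set) and the call.
    """
    libs_a = table.libraries(MALE_CONDITION)
    libs_b = table.libraries(FEMALE_CONDITION)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ConfigError("need >= 2 replicates per condition")

    sf = size_factors(table.counts)
    normalized = table.counts / sf
    d = common_dispersion(normalized, [libs_a, libs_b])
    fpkm = compute_fpkm(table)

    n_a, n_b = len(libs_a), len(libs_b)
    p_values = np.ones(len(table.counts.index))
    log2fc = np.zeros(len(table.counts.index))
    mean_a_arr = normalized[libs_a].mean(axis=1).values
    mean_b_arr = normalized[libs_b].mean(axis=1).values

    for i, tid in enumerate(table.counts.index):
        row = table.counts.loc[tid]
        if row.sum() == 0:
            p_values[i] = 1.0
            log2fc[i] = 0.0
            continue
        norm_row = normalized.loc[tid]
        sum_a = float(norm_row[libs_a].sum())
        sum_b = float(norm_row[libs_b].sum())
        k_obs = int(round(sum_a))
        total = k_obs + int(round(sum_b))
        if total <= EXACT_TEST_MAX_TOTAL:
            p_values[i] = _exact_conditional_p(k_obs, total, n_a, n_b, d)
        else:
            p_values[i] = _approx_p(sum_a, sum_b, n_a, n_b, d)
        log2fc[i] = np.log2(
            (mean_a_arr[i] + PSEUDOCOUNT) / (mean_b_arr[i] + PSEUDOCOUNT)
        )

    p_adjust = multipletests(p_values, method="fdr_bh")[1]
    calls = np.where(
        (p_adjust < p_adjust_cutoff) & (np.abs(log2fc) > log2fc_cutoff),
        np.where(log2fc > 0, "male_biased", "female_biased"),
        "ns",
    )
    return pd.DataFrame(
        {
            "mean_fpkm_SSC": fpkm[libs_a].mean(axis=1),
            "mean_fpkm_FGSC": fpkm[libs_b].mean(axis=1),
            "log2_fold_change": log2fc,
            "p_value": p_values,
            "p_adjust": p_adjust,
            "call": calls,
        },
        index=table.counts.index,
    )


def nb_differential_test(table: ExpressionTable, transcript_id: str) -> DifferentialResult:
    """Single-transcript view of :func:`differential_expression`."""
    df = differential_expression(table)
    if transcript_id not in df.index:
        raise ConfigError(f"unknown transcript {transcript_id}")
    row = df.loc[transcript_id]
    return DifferentialResult(
        transcript_id=transcript_id,
        mean_fpkm={
            MALE_CONDITION: float(row["mean_fpkm_SSC"]),
            FEMALE_CONDITION: float(row["mean_fpkm_FGSC"]),
        },
        log2_fold_change=float(row["log2_fold_change"]),
        p_value=float(row["p_value"]),
        p_adjust=float(row["p_adjust"]),
        call=str(row["call"]),
    )


# ---------------------------------------------------------------------------
# visualization export
# ---------------------------------------------------------------------------

def heatmap_matrix(
    fpkm: pd.DataFrame,
    results: pd.DataFrame,
    fold_change_min: float = 2.0,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Row-normalized matrix of called transcripts for heatmap export.

    Rows are called transcripts that also pass the figure thresholds (fold
    change >= 2, p < 0.05, FDR < 0.05); values are per-row z-scores of
    log2(FPKM + 1); rows are ordered by log2 fold change, descending.
    """
    mask = (
        (results["call"] != "ns")
        & (np.abs(results["log2_fold_change"]) >= np.log2(fold_change_min))
        & (results["p_value"] < p_max)
        & (results["p_adjust"] < fdr_max)
    )
    selected = results.index[mask]
    if len(selected) == 0:
        return pd.DataFrame(columns=fpkm.columns)
    order = (
        results.loc[selected, "log2_fold_change"]
        .sort_values(ascending=False, kind="mergesort")
        .index
    )
    log_vals = np.log2(fpkm.loc[order] + 1.0)
    centered = log_vals.sub(log_vals.mean(axis=1), axis=0)
    sd = log_vals.std(axis=1, ddof=1).replace(0.0, np.nan)
    return centered.div(sd, axis=0).fillna(0.0)
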