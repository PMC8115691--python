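"""Aggregation of per-dataset ASB evidence per SNP.

Per-dataset one-tailed P values for one SNP are combined with the logit
(George-Mudholkar) method, separately for the reference- and alternative-
allele direction, at two levels: per transcription factor (across cell
types) and per cell type (across TFs).  The logit method is preferred over
Fisher's because it cancels symmetric evidence (0.01 with 0.99 gives 0.5)
and over Stouffer's for robustness to extreme P values.  Aggregated P values
are Benjamini-Hochberg corrected within each (group, allele); an SNP is an
ASB when either allele's FDR is at most the significance level.

Aggregated effect sizes are weighted means of the per-dataset effect sizes
with weights -ln(p); datasets with p = 1 carry no direction information and
are excluded, and the effect size is undefined if every p equals 1.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: SNPs whose best dataset has total coverage below this are not candidates
MIN_TOTAL_COVERAGE = 20

#: clamping bounds: exact zeros are clamped, values indistinguishable from 1
#: are treated as excluded-by-rule
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def logit_combine(pvalues: Sequence[float]) -> float:
    """Combine P values with the logit method.

    The statistic is T = -sum ln(p_i / (1 - p_i)) over the k retained
    values, referred to a scaled Student-t null: T / c ~ t(5k + 4) with
    c = sqrt(k pi^2 (5k + 2) / (3 (5k + 4))).  Values equal to 1 are
    excluded first; if nothing remains the combined P value is 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("logit_combine requires at least one P value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    p = p[p < P_CEIL]
    if p.size == 0:
        return 1.0
    p = np.clip(p, P_FLOOR, P_CEIL)
    k = p.size
    t_stat = -np.sum(np.log(p) - np.log1p(-p))
    df = 5 * k + 4
    scale = math.sqrt(k * math.pi**2 * (5 * k + 2) / (3.0 * df))
    return float(stats.t.sf(t_stat / scale, df))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def aggregate_es(es_values: Sequence[float], pvalues: Sequence[float]) -> float:
    """Weighted mean effect size with weights -ln(p); NaN if all p are 1."""
    es = np.asarray(es_values, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    keep = (p < P_CEIL) & np.isfinite(es)
    if not keep.any():
        return float("nan")
    w = -np.log(np.clip(p[keep], P_FLOOR, P_CEIL))
    return float(np.average(es[keep], weights=w))


def select_candidates(scores: pd.DataFrame,
                      min_total_coverage: int = MIN_TOTAL_COVERAGE) -> pd.DataFrame:
    """Keep SNP groups whose best dataset reaches the coverage threshold.

    Grouping is by site (chrom, pos, ref, alt): observations of the same
    position with different alternative alleles are distinct candidates.
    """
    cov = scores["c_ref"] + scores["c_alt"]
    key = ["chrom", "pos", "ref_allele", "alt_allele"]
    max_cov = cov.groupby([scores[k] for k in key]).transform("max")
    return scores.loc[max_cov.values >= min_total_coverage].copy()


def aggregate(
    scores: pd.DataFrame,
    meta,
    level: str = "tf",
    fdr_level: float = 0.05,
    min_total_coverage: int = MIN_TOTAL_COVERAGE,
) -> pd.DataFrame:
    """Aggregate per-dataset ASB scores to TF- or cell-type-level calls.

    Parameters
    ----------
    scores : per-dataset table from :func:`asbkit.asb_model.score_calls`
    meta : list of DatasetMeta linking dataset_id to TF and cell type
    level : "tf" or "cell_type"
    """
    if level not in ("tf", "cell_type"):
        raise ValueError("level must be 'tf' or 'cell_type'")
    by_id = {m.dataset_id: m for m in meta}
    missing = set(scores["dataset_id"]) - set(by_id)
    if missing:
        raise KeyError(f"datasets missing from metadata: {sorted(missing)}")
    group_of = {d: (by_id[d].tf_name if level == "tf" else by_id[d].cell_type)
                for d in by_id}

    df = select_candidates(scores, min_total_coverage)
    if df.empty:
        return _empty_result(level)
    df = df.assign(group_name=df["dataset_id"].map(group_of),
                   coverage=df["c_ref"] + df["c_alt"])

    key = ["group_name", "chrom", "pos", "ref_allele", "alt_allele"]
    rows = []
    for keys, sub in df.groupby(key, sort=True):
        group_name, chrom, pos, ref, alt = keys
        snp_ids = sub["snp_id"].dropna().unique()
        rows.append({
            "chrom": chrom, "pos": pos, "ref_allele": ref, "alt_allele": alt,
            "snp_id": snp_ids[0] if len(snp_ids) else None,
            "level": level, "group_name": group_name,
            "n_datasets": sub["dataset_id"].nunique(),
            "max_total_coverage": int(sub["coverage"].max()),
            "agg_p_ref": logit_combine(sub["p_ref"].to_numpy()),
            "agg_p_alt": logit_combine(sub["p_alt"].to_numpy()),
            "es_ref": aggregate_es(sub["es_ref"], sub["p_ref"]),
            "es_alt": aggregate_es(sub["es_alt"], sub["p_alt"]),
        })
    out = pd.DataFrame(rows)
    # BH correction within each aggregation group, separately per allele
    out["fdr_ref"] = np.nan
    out["fdr_alt"] = np.nan
    for _, idx in out.groupby("group_name").groups.items():
        out.loc[idx, "fdr_ref"] = bh_fdr(out.loc[idx, "agg_p_ref"])
        out.loc[idx, "fdr_alt"] = bh_fdr(out.loc[idx, "agg_p_alt"])
    out["is_asb"] = (np.minimum(out["fdr_ref"], out["fdr_alt"]) <= fdr_level)
    return out[_RESULT_COLUMNS]


_RESULT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "snp_id", "level",
    "group_name", "n_datasets", "max_total_coverage",
    "agg_p_ref", "agg_p_alt", "fdr_ref", "fdr_alt",
    "es_ref", "es_alt", "is_asb",
]


def _empty_result(level: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=_RESULT_COLUMNS)
    df["level"] = df["level"].astype(str)
    return df
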