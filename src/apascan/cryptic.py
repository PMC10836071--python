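"""Differential last-exon usage testing and cryptic classification.

Differential usage between conditions is assessed per isoform with a
quasi-binomial GLM of isoform counts against gene-total counts: the
condition effect is tested by an F-test on the deviance difference between
the full and the covariate-only model, scaled by the Pearson dispersion of
the full fit.  Externally produced per-isoform p-value tables (e.g. from a
dedicated exon-usage GLM engine) can be ingested instead via
:func:`results_from_table`.

A *cryptic* isoform passes, in at least one dataset: BH-adjusted p < 0.05,
mean usage in control samples < 10%, and usage gain upon knockdown > 10%
(both strict).  Across datasets, isoforms are categorised from the medians
over the datasets where they were tested.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .usage import IsoformUsageMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "isoform_id",
    "gene_id",
    "p_value",
    "padj",
    "mean_usage_ctrl",
    "mean_usage_kd",
    "delta_usage",
    "dataset",
]


def _design_matrix(
    design: pd.DataFrame, condition_col: str, control: str, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(full, null) design matrices; condition coded 0=control, 1=treated."""
    cond = (design[condition_col] != control).astype(float).to_numpy()
    cols = [np.ones(len(design))]
    for cov in covariates:
        dummies = pd.get_dummies(design[cov], drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    null = np.column_stack(cols)
    full = np.column_stack(cols + [cond])
    return full, null


def _quasibinomial_f_test(
    y: np.ndarray, n: np.ndarray, full: np.ndarray, null: np.ndarray
) -> float:
    """P-value of the last column of *full* via a quasi-binomial F-test."""
    frac = y / n
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = sm.GLM(frac, full, family=sm.families.Binomial(), var_weights=n).fit()
            fit0 = sm.GLM(frac, null, family=sm.families.Binomial(), var_weights=n).fit()
    except Exception:  # separation / singular fits
        return np.nan
    df_resid = len(y) - full.shape[1]
    if df_resid <= 0:
        return np.nan
    phi = max(fit1.pearson_chi2 / df_resid, 1e-12)
    q = full.shape[1] - null.shape[1]
    f = max(fit0.deviance - fit1.deviance, 0.0) / q / phi
    return float(stats.f.sf(f, q, df_resid))


def differential_usage(
    m: IsoformUsageMatrix,
    design: pd.DataFrame,
    control: str,
    condition_col: str = "condition",
    covariates: Sequence[str] = (),
    dataset: str = "",
) -> pd.DataFrame:
    """Per-isoform differential usage between two conditions.

    *design* is indexed by sample name with a two-level ``condition_col``;
    additional categorical covariates are absorbed as strata in both the
    full and the null model.  Returns one row per tested isoform with raw
    and BH-adjusted p-values (adjusted within this dataset) and usage means
    per condition.  Isoforms with all-missing usage, or fewer than two
    informative samples per condition, are excluded and logged.
    """
    if m.usage is None:
        raise ValueError("usage not computed; call polya_usage first")
    design = design.loc[[s for s in m.sample_names if s in design.index]]
    levels = design[condition_col].unique()
    if control not in levels or len(levels) != 2:
        raise ValueError(
            f"condition column must have two levels including {control!r}; "
            f"got {sorted(levels)}"
        )
    counts_sizes = design[condition_col].value_counts()
    if (counts_sizes < 2).any():
        raise ValueError(
            f"need >= 2 samples per condition, got {counts_sizes.to_dict()}"
        )
    samples = list(design.index)
    counts = m.counts[samples]
    usage = m.usage[samples]
    gene_tot = counts.groupby(m.iso2gene).transform("sum")
    is_ctrl = (design[condition_col] == control).to_numpy()

    rows = []
    n_excluded = 0
    for iso in counts.index:
        y = counts.loc[iso].to_numpy(dtype=float)
        n = gene_tot.loc[iso].to_numpy(dtype=float)
        ok = n > 0
        if ok.sum() < 4 or (is_ctrl & ok).sum() < 2 or (~is_ctrl & ok).sum() < 2:
            n_excluded += 1
            continue
        u = usage.loc[iso].to_numpy(dtype=float)
        if np.isnan(u[ok]).all():
            n_excluded += 1
            continue
        sub = design.loc[np.asarray(samples)[ok]]
        full, null = _design_matrix(sub, condition_col, control, covariates)
        p = _quasibinomial_f_test(y[ok], n[ok], full, null)
        if np.isnan(p):
            n_excluded += 1
            continue
        mean_ctrl = float(np.nanmean(u[is_ctrl & ok]))
        mean_kd = float(np.nanmean(u[~is_ctrl & ok]))
        rows.append(
            {
                "isoform_id": iso,
                "gene_id": m.iso2gene[iso],
                "p_value": p,
                "mean_usage_ctrl": mean_ctrl,
                "mean_usage_kd": mean_kd,
                "delta_usage": mean_kd - mean_ctrl,
                "dataset": dataset,
            }
        )
    if n_excluded:
        logger.info(
            "differential_usage[%s]: %d isoforms excluded (undefined usage "
            "or too few informative samples)", dataset, n_excluded,
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = benjamini_hochberg(out["p_value"].to_numpy())
    else:
        out = pd.DataFrame(columns=RESULT_COLUMNS)
    return out[RESULT_COLUMNS]


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def results_from_table(table: pd.DataFrame, dataset: str = "") -> pd.DataFrame:
    """Adapter: ingest an externally computed per-isoform p-value table.

    Requires columns isoform_id, gene_id, p_value, mean_usage_ctrl,
    mean_usage_kd; padj is (re)computed within the table by BH.
    """
    required = ["isoform_id", "gene_id", "p_value", "mean_usage_ctrl", "mean_usage_kd"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns {missing}")
    out = table.copy()
    out["delta_usage"] = out["mean_usage_kd"] - out["mean_usage_ctrl"]
    out["padj"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["dataset"] = out.get("dataset", dataset)
    return out[RESULT_COLUMNS]


def _is_cryptic_row(r: pd.Series, cfg: PipelineConfig) -> bool:
    return (
        r["padj"] < cfg.alpha
        and r["mean_usage_ctrl"] < cfg.cryptic_max_ctrl_usage
        and r["delta_usage"] > cfg.cryptic_min_delta
    )


def classify_cryptic(
    results: Sequence[pd.DataFrame], cfg: PipelineConfig
) -> pd.DataFrame:
    """Combine per-dataset results into per-isoform cryptic calls.

    An isoform is cryptic if it passes padj < alpha, control usage < 10%
    and usage gain > 10% (strict) in at least one dataset.  The returned
    table carries per-isoform medians across the datasets where the isoform
    was tested, the set of datasets where it was significant, and the
    cross-dataset category.
    """
    combined = pd.concat([r for r in results if not r.empty], ignore_index=True)
    all_datasets = set(combined["dataset"].unique())
    rows = []
    for iso, grp in combined.groupby("isoform_id", sort=True):
        cryptic_in = {
            r["dataset"] for _, r in grp.iterrows() if _is_cryptic_row(r, cfg)
        }
        sig_up = {
            r["dataset"]
            for _, r in grp.iterrows()
            if r["padj"] < cfg.alpha and r["delta_usage"] > 0
        }
        rows.append(
            {
                "isoform_id": iso,
                "gene_id": grp["gene_id"].iloc[0],
                "is_cryptic": bool(cryptic_in),
                "datasets_tested": set(grp["dataset"]),
                "datasets_significant": {
                    r["dataset"] for _, r in grp.iterrows() if r["padj"] < cfg.alpha
                },
                "datasets_cryptic": cryptic_in,
                "datasets_sig_increase": sig_up,
                "median_ctrl_usage": float(grp["mean_usage_ctrl"].median()),
                "median_delta": float(grp["delta_usage"].median()),
                "min_padj": float(grp["padj"].min()),
            }
        )
    calls = pd.DataFrame(rows)
    return cross_dataset_categorise(calls, cfg, all_datasets)


def cross_dataset_categorise(
    calls: pd.DataFrame, cfg: PipelineConfig, all_datasets: Optional[set] = None
) -> pd.DataFrame:
    """Fill the cross-dataset category from per-isoform medians.

    * cryptic_consistent — median control usage < 10% and median usage gain
      > 10% across the datasets where the isoform was tested;
    * low_basal_nonresponsive — median control usage < 10% but median gain
      <= 10%;
    * responsive_high_basal — significant usage increase (in >= 1 dataset,
      or all datasets under ``require_all_datasets_significant``) but median
      control usage > 10%;
    * background — tested in every dataset with padj > alpha in all;
    * other — anything else (including isoforms tested nowhere).
    """
    if all_datasets is None:
        all_datasets = set().union(*calls["datasets_tested"]) if len(calls) else set()
    categories = []
    for _, r in calls.iterrows():
        tested = r["datasets_tested"]
        if not tested:
            categories.append("other")
            continue
        if cfg.require_all_datasets_significant:
            sig_increase = r["datasets_sig_increase"] == tested and bool(tested)
        else:
            sig_increase = bool(r["datasets_sig_increase"])
        if r["median_ctrl_usage"] < cfg.cryptic_max_ctrl_usage:
            if r["median_delta"] > cfg.cryptic_min_delta:
                categories.append("cryptic_consistent")
            else:
                categories.append("low_basal_nonresponsive")
        elif sig_increase and r["median_ctrl_usage"] > cfg.cryptic_max_ctrl_usage:
            categories.append("responsive_high_basal")
        elif tested == all_datasets and not r["datasets_significant"]:
            categories.append("background")
        else:
            categories.append("other")
    out = calls.copy()
    out["cross_dataset_category"] = categories
    return out


def select_background(
    results: Sequence[pd.DataFrame],
    dataset_group: Sequence[str],
    cfg: PipelineConfig,
) -> set[str]:
    """Isoforms tested in every dataset of the group with padj > alpha in all."""
    group = list(dataset_group)
    combined = pd.concat([r for r in results if not r.empty], ignore_index=True)
    combined = combined[combined["dataset"].isin(group)]
    background: set[str] = set()
    for iso, grp in combined.groupby("isoform_id"):
        if set(grp["dataset"]) == set(group) and (grp["padj"] > cfg.alpha).all():
            background.add(iso)
    return background
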