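"""Association of latent factors with survival and clinical features.

Each factor is tested against right-censored survival with a univariate Cox
proportional hazards model (Efron tie handling, Wald test), with
Benjamini-Hochberg correction across the factors; a factor whose adjusted
p-value passes the threshold is flagged as survival-associated (SAF).
Categorical clinical features are tested per factor with a Wilcoxon
rank-sum test (binary features) or Kruskal-Wallis test (more levels), BH
corrected across all factor-feature pairs. Kaplan-Meier curves on a
median split of a factor visualize the association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SurvivalTable
from .factor import FactorModel

__all__ = [
    "cox_univariate",
    "adjust_bh",
    "survival_assoc_table",
    "clinical_assoc",
    "km_median_split",
    "KmSplit",
]

log = logging.getLogger(__name__)


def cox_univariate(
    x: pd.Series, survival: SurvivalTable, ties: str = "efron"
) -> tuple[float, float, float]:
    """Univariate Cox proportional hazards fit of one covariate.

    Returns (beta, se, wald_p). A constant covariate is a degenerate case
    and returns (0, nan, 1) with a warning; zero events is an error.
    """
    df = survival.data.loc[x.index].copy()
    df["x"] = x.to_numpy(dtype=float)
    if not np.all(np.isfinite(df["x"])):
        raise ValueError("covariate contains non-finite values")
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if df["x"].std() == 0:
        warnings.warn("constant covariate: returning beta=0, p=1", stacklevel=2)
        return 0.0, float("nan"), 1.0
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="time",
        event_col="event",
        fit_options={"precision": 1e-9, "max_steps": 500},
    )
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    wald_p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, wald_p


def adjust_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def survival_assoc_table(
    model: FactorModel,
    survival: SurvivalTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-factor Cox association with BH correction across the K factors.

    Samples missing from the survival table, or with missing survival
    values, are dropped and logged; only samples present in the factor
    model are used. Returns one row per factor with beta, se, Wald
    statistic and p, BH-adjusted FDR, SAF flag, and the n used.
    """
    surv = survival.data.dropna(subset=["time", "event"])
    shared = [s for s in model.sample_ids if s in set(surv.index)]
    n_drop = len(model.sample_ids) - len(shared)
    if n_drop:
        log.info("survival association: dropped %d samples without survival", n_drop)
    sub = SurvivalTable(surv.loc[shared])
    rows = []
    for f in model.factor_scores.columns:
        beta, se, p = cox_univariate(model.factor_scores.loc[shared, f], sub)
        rows.append(
            {
                "factor": f,
                "beta": beta,
                "se": se,
                "wald": beta / se if se and np.isfinite(se) else 0.0,
                "p": p,
                "n_samples": len(shared),
                "n_events": int(sub.data["event"].sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("factor")
    out["fdr"] = adjust_bh(out["p"].to_numpy())
    out["saf"] = out["fdr"] < alpha
    return out


def clinical_assoc(model: FactorModel, clinical: pd.DataFrame) -> pd.DataFrame:
    """Factor-by-clinical-feature tests with BH across all pairs.

    Binary features use the two-sided Wilcoxon rank-sum (Mann-Whitney)
    test on factor values between the two groups; features with more
    levels use Kruskal-Wallis. Single-level features are skipped with a
    warning.
    """
    shared = [s for s in model.sample_ids if s in set(clinical.index)]
    if len(shared) < 3:
        raise ValueError("clinical association needs at least 3 shared samples")
    clin = clinical.loc[shared]
    rows = []
    for feat in clin.columns:
        levels = clin[feat].dropna().unique()
        if len(levels) < 2:
            warnings.warn(f"clinical feature {feat!r} has one level; skipped",
                          stacklevel=2)
            continue
        for f in model.factor_scores.columns:
            z = model.factor_scores.loc[shared, f]
            groups = [z[clin[feat] == lv].to_numpy(dtype=float) for lv in levels]
            if len(levels) == 2:
                test = "wilcoxon"
                stat, p = stats.mannwhitneyu(
                    groups[0], groups[1], alternative="two-sided"
                )
            else:
                test = "kruskal"
                stat, p = stats.kruskal(*groups)
            rows.append(
                {"factor": f, "feature": feat, "test": test,
                 "statistic": float(stat), "p": float(p)}
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = adjust_bh(out["p"].to_numpy())
    return out


@dataclass
class KmSplit:
    """Kaplan-Meier curves for a low/high median split of a factor."""

    groups: pd.Series  # sample -> "low" | "high"
    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, events, survival
    logrank_stat: float
    logrank_p: float


def km_median_split(x: pd.Series, survival: SurvivalTable) -> KmSplit:
    """Split samples at the factor median and estimate per-group KM curves.

    Ties at the median are assigned to the low group (deterministic). The
    two groups are compared with a two-group log-rank test.
    """
    if len(x) < 4:
        raise ValueError("median split needs at least 4 samples")
    med = float(x.median())
    low = x <= med
    if low.all() or (~low).all():
        raise ValueError("median split degenerate: one group is empty")
    groups = pd.Series(np.where(low, "low", "high"), index=x.index)
    surv = survival.data.loc[x.index]

    curves = {}
    for name in ("low", "high"):
        mask = groups == name
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time"], surv.loc[mask, "event"])
        tbl = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(dtype=float),
                "events": tbl["observed"].to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"]
                .reindex(tbl.index)
                .to_numpy(dtype=float),
            }
        )
    res = logrank_test(
        surv.loc[groups == "low", "time"],
        surv.loc[groups == "high", "time"],
        event_observed_A=surv.loc[groups == "low", "event"],
        event_observed_B=surv.loc[groups == "high", "event"],
    )
    return KmSplit(
        groups=groups,
        curves=curves,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )
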