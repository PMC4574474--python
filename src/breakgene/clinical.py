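"""Survival and enrichment analyses for subtypes and gene events.

Kaplan–Meier curves with log-rank tests compare overall survival across
groups; a Cox proportional-hazards model with a single binary covariate
estimates hazard ratios; a Bonferroni-corrected per-gene log-rank screen
tests individual breakpoint genes against outcome; Fisher exact tests
quantify enrichment of binary features (mutations, breakpoints, MSI status)
within subtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import fisher_exact

from .profiles_io import BinaryEventMatrix, ClinicalTable

__all__ = [
    "SurvivalSummary",
    "km_logrank",
    "cox_hr",
    "per_gene_survival_screen",
    "fisher_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalSummary:
    """Kaplan–Meier curves per group plus the k-group log-rank test."""

    groups: pd.Series                 # sample -> group label
    curves: dict                      # label -> DataFrame(time, survival, at_risk)
    medians: dict                     # label -> median OS (NaN if curve stays > 0.5)
    n_per_group: dict
    chi2: float
    p_value: float


def km_logrank(groups: pd.Series, clinical: ClinicalTable) -> SurvivalSummary:
    """Product-limit survival estimates per group and a k-group log-rank test.

    ``groups`` maps sample id to a group label; every group must be
    non-empty.  The median OS of a group is read from its KM curve (first
    time the estimate drops to 0.5 or below), which respects censoring.
    """
    groups = pd.Series(groups).dropna()
    table = clinical.table.loc[groups.index]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    curves, medians, n_per_group = {}, {}, {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(table.loc[mask.to_numpy(), "os_days"],
                table.loc[mask.to_numpy(), "event"], label=str(lab))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[lab] = pd.DataFrame({
            "time": surv.index.to_numpy(),
            "survival": surv.to_numpy(),
            "at_risk": at_risk.to_numpy(),
        })
        medians[lab] = float(kmf.median_survival_time_)
        n_per_group[lab] = int(mask.sum())
    res = multivariate_logrank_test(table["os_days"], groups, table["event"])
    return SurvivalSummary(groups=groups, curves=curves, medians=medians,
                           n_per_group=n_per_group,
                           chi2=float(res.test_statistic), p_value=float(res.p_value))


def cox_hr(binary_group: pd.Series, clinical: ClinicalTable) -> dict:
    """Hazard ratio of group 1 vs group 0 from a one-covariate Cox model.

    Returns ``{"hr", "ci_low", "ci_high", "p_value"}`` (95% CI).  Both
    groups must contain observed events.
    """
    binary_group = pd.Series(binary_group).dropna().astype(int)
    table = clinical.table.loc[binary_group.index]
    for side in (0, 1):
        mask = (binary_group == side).to_numpy()
        if table.loc[mask, "event"].sum() == 0:
            raise ValueError(f"group {side} has no observed events")
    df = pd.DataFrame({
        "os_days": table["os_days"].to_numpy(),
        "event": table["event"].to_numpy(),
        "group": binary_group.to_numpy(),
    })
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_days", event_col="event")
    beta = float(cph.params_["group"])
    ci = cph.confidence_intervals_.loc["group"]
    return {
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(ci.iloc[0])),
        "ci_high": float(np.exp(ci.iloc[1])),
        "p_value": float(cph.summary.loc["group", "p"]),
    }


def per_gene_survival_screen(
    gene_matrix: BinaryEventMatrix,
    clinical: ClinicalTable,
    min_carriers: int = 5,
    level: float = 0.05,
) -> pd.DataFrame:
    """Per-gene carrier-vs-non-carrier log-rank screen, Bonferroni corrected.

    Genes whose carrier or non-carrier group is smaller than
    ``min_carriers`` are skipped (reason recorded).  The adjusted p-value is
    ``min(1, p * n_tested)``.
    """
    samples = [s for s in gene_matrix.samples if s in set(clinical.samples)]
    table = clinical.table.loc[samples]
    rows = []
    for gene in gene_matrix.rows:
        carrier = gene_matrix.data.loc[gene, samples].to_numpy().astype(bool)
        n_car = int(carrier.sum())
        if n_car < min_carriers or (len(samples) - n_car) < min_carriers:
            rows.append((gene, n_car, np.nan, np.nan, False, "too_few_carriers"))
            continue
        res = multivariate_logrank_test(table["os_days"],
                                        pd.Series(carrier, index=samples),
                                        table["event"])
        rows.append((gene, n_car, float(res.p_value), np.nan, False, ""))
    df = pd.DataFrame(rows, columns=["gene", "n_carriers", "p_value",
                                     "p_adjusted", "significant", "skip_reason"])
    df = df.set_index("gene")
    tested = df["p_value"].notna()
    n_tested = int(tested.sum())
    if n_tested:
        df.loc[tested, "p_adjusted"] = np.minimum(1.0, df.loc[tested, "p_value"] * n_tested)
        df.loc[tested, "significant"] = df.loc[tested, "p_adjusted"] < level
    return df


def fisher_enrichment(
    feature: pd.Series,
    subtype_indicator: pd.Series,
    sided: str = "two",
) -> dict:
    """Fisher exact test of a binary feature against subtype membership.

    The 2×2 table is ``[[feature & in-subtype, feature & out],
    [no-feature & in, no-feature & out]]``.  ``sided`` is ``"two"`` or
    ``"one"`` (one-sided = enrichment, alternative 'greater').  Degenerate
    margins yield p = 1 with a warning.
    """
    feature = pd.Series(feature).dropna().astype(int)
    ind = pd.Series(subtype_indicator).reindex(feature.index).dropna().astype(int)
    feature = feature.loc[ind.index]
    a = int(((feature == 1) & (ind == 1)).sum())
    b = int(((feature == 1) & (ind == 0)).sum())
    c = int(((feature == 0) & (ind == 1)).sum())
    d = int(((feature == 0) & (ind == 0)).sum())
    table = np.array([[a, b], [c, d]])
    if feature.nunique() < 2 or ind.nunique() < 2:
        logger.warning("degenerate margin in Fisher table %s", table.tolist())
        return {"odds_ratio": np.nan, "p_value": 1.0, "table": table}
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    odds, p = fisher_exact(table, alternative=alternative)
    return {"odds_ratio": float(odds), "p_value": float(p), "table": table}
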