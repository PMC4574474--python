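"""Recurrence testing for breakpoint genes under a heterogeneous null.

The test proceeds in three steps:

1. A pooled logistic regression estimates, for every (gene, profile) pair,
   the baseline probability ``p_gs`` of at least one breakpoint falling in
   gene *g* of profile *s* at random, from the profile's total breakpoint
   burden, the gene's span length and its probe coverage.
2. The test statistic for a gene is the number of profiles with at least one
   breakpoint in it.  Its null distribution is the Poisson-binomial law —
   the convolution over independent profiles of Bernoulli(p_gs) variables —
   from which an exact tail p-value is computed by dynamic programming.
3. Because each gene has its own discrete null, the Benjamini–Hochberg
   step-up is replaced by a discrete variant that plugs in each hypothesis's
   attainable p-value distribution; when all nulls coincide it reduces to
   standard BH.  FDR < 0.1 is the conventional significance threshold.

The probe-level variant assumes a uniform breakpoint probability across
probes within a profile, so all probes share one null and standard BH
applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .breakpoints import GeneProbeIndex
from .profiles_io import BinaryEventMatrix

__all__ = [
    "BreakpointProbabilityModel",
    "DegenerateFitError",
    "fit_breakpoint_probability_model",
    "uniform_placement_model",
    "poisson_binomial_tail",
    "poisson_binomial_pmf",
    "gene_recurrence_test",
    "discrete_fdr",
    "probe_recurrence_test",
    "recurrence_table",
]

ALPHA_DEFAULT = 0.1


class DegenerateFitError(RuntimeError):
    """Logistic fit is not identifiable (no events, or complete separation).

    Use :func:`uniform_placement_model` as a fitting-free fallback.
    """


@dataclass
class BreakpointProbabilityModel:
    """Fitted per-(gene, profile) breakpoint probabilities.

    ``p`` is a genes × samples array of fitted probabilities in (0, 1) for
    testable genes (``n_probes > 0``); rows of untestable genes are exactly
    zero and listed in ``untestable``.
    """

    p: pd.DataFrame
    coefficients: pd.Series
    converged: bool
    log_likelihood: float
    untestable: list[str] = field(default_factory=list)
    method: str = "logistic"

    @property
    def testable_genes(self) -> list[str]:
        return [g for g in self.p.index if g not in set(self.untestable)]


def _covariates(gene_index: GeneProbeIndex, genes: pd.Index, burden: np.ndarray):
    n_probes = gene_index.n_probes.reindex(genes).to_numpy(dtype=float)
    span = gene_index.span_length.reindex(genes).to_numpy(dtype=float)
    x_gene = np.column_stack([np.log(n_probes + 1.0), np.log(span)])
    x_sample = np.log(burden + 1.0)
    return x_gene, x_sample


def fit_breakpoint_probability_model(
    gene_matrix: BinaryEventMatrix,
    gene_index: GeneProbeIndex,
    breakpoint_counts: pd.Series,
) -> BreakpointProbabilityModel:
    """Fit the pooled logistic baseline model.

    Response: 1{gene g broken in profile s}, over all (testable gene,
    profile) pairs.  Covariates: ``log(n_probes_g + 1)``,
    ``log(span_length_g)``, ``log(B_s + 1)`` with ``B_s`` the profile's
    total breakpoint count.  Genes without associated probes are untestable
    and receive ``p_gs = 0``.

    Raises
    ------
    DegenerateFitError
        If the cohort has no breakpoints at all, or the fit separates.
    """
    samples = gene_matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    genes = gene_matrix.data.index
    n_probes = gene_index.n_probes.reindex(genes)
    testable = genes[n_probes.to_numpy() > 0]
    untestable = [g for g in genes if g not in set(testable)]
    if len(testable) < 2:
        raise ValueError("need at least 2 testable genes")

    burden = breakpoint_counts.reindex(samples).to_numpy(dtype=float)
    y = gene_matrix.data.loc[testable].to_numpy(dtype=float)
    if y.sum() == 0:
        raise DegenerateFitError("cohort contains no breakpoint events")
    x_gene, x_sample = _covariates(gene_index, testable, burden)

    n_g, n_s = y.shape
    design = np.empty((n_g * n_s, 4))
    design[:, 0] = 1.0
    design[:, 1] = np.repeat(x_gene[:, 0], n_s)
    design[:, 2] = np.repeat(x_gene[:, 1], n_s)
    design[:, 3] = np.tile(x_sample, n_g)
    resp = y.ravel()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(resp, design, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # pragma: no cover - perfect separation etc.
            raise DegenerateFitError(f"logistic fit failed: {exc}") from exc
    fitted = fit.predict(design).reshape(n_g, n_s)
    if not np.all((fitted > 0) & (fitted < 1)):
        raise DegenerateFitError("fitted probabilities left (0, 1): separation suspected")

    p = pd.DataFrame(0.0, index=genes, columns=samples)
    p.loc[testable] = fitted
    coeffs = pd.Series(fit.params,
                       index=["intercept", "log_n_probes", "log_span", "log_burden"])
    return BreakpointProbabilityModel(
        p=p, coefficients=coeffs, converged=bool(fit.converged),
        log_likelihood=float(fit.llf), untestable=untestable,
    )


def uniform_placement_model(
    gene_matrix: BinaryEventMatrix,
    n_intervals_per_gene: pd.Series,
    breakpoint_counts: pd.Series,
    n_intervals_total: int,
) -> BreakpointProbabilityModel:
    """Fitting-free fallback null: uniform breakpoint placement.

    ``p_gs = 1 - (1 - B_s / N)^{n_g}`` with ``n_g`` the number of
    inter-probe intervals overlapping gene g and ``N`` the genome-wide
    interval count.  Used when the logistic fit is degenerate.
    """
    genes = gene_matrix.data.index
    samples = gene_matrix.samples
    n_g = n_intervals_per_gene.reindex(genes).fillna(0).to_numpy(dtype=float)
    b = breakpoint_counts.reindex(samples).to_numpy(dtype=float)
    rate = np.clip(b / n_intervals_total, 0.0, 1.0 - 1e-12)
    p = 1.0 - np.power.outer(1.0 - rate, n_g).T  # genes x samples
    p[n_g == 0, :] = 0.0
    untestable = [g for g, k in zip(genes, n_g) if k == 0]
    return BreakpointProbabilityModel(
        p=pd.DataFrame(p, index=genes, columns=samples),
        coefficients=pd.Series(dtype=float), converged=True,
        log_likelihood=float("nan"), untestable=untestable, method="uniform",
    )


# ---------------------------------------------------------------------------
# Poisson-binomial machinery
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by DP convolution."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for k, pi in enumerate(p):
        pmf[1:k + 2] = pmf[1:k + 2] * (1.0 - pi) + pmf[:k + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def poisson_binomial_tail(p: np.ndarray, t: int) -> float:
    """P(T >= t) for a Poisson-binomial count T = sum of Bernoulli(p_i).

    Exact via DP convolution; ``t = 0`` gives 1, ``t > len(p)`` gives 0.
    """
    p = np.asarray(p, dtype=float)
    if t <= 0:
        return 1.0
    if t > p.size:
        return 0.0
    pmf = poisson_binomial_pmf(p)
    return float(pmf[t:].sum())


def _pmf_matrix(P: np.ndarray) -> np.ndarray:
    """Row-wise Poisson-binomial pmfs: P is genes × samples, result genes × (n+1)."""
    n_genes, n = P.shape
    pmf = np.zeros((n_genes, n + 1))
    pmf[:, 0] = 1.0
    for s in range(n):
        ps = P[:, s][:, None]
        pmf[:, 1:s + 2] = pmf[:, 1:s + 2] * (1.0 - ps) + pmf[:, :s + 1] * ps
        pmf[:, 0] *= (1.0 - ps).ravel()
    return pmf


def _tails_from_pmf(pmf: np.ndarray) -> np.ndarray:
    """tails[:, k] = P(T >= k); tails[:, 0] = 1."""
    tails = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    tails[:, 0] = 1.0  # guard against rounding
    return np.clip(tails, 0.0, 1.0)


def gene_recurrence_test(
    gene_matrix: BinaryEventMatrix,
    model: BreakpointProbabilityModel,
    genes: str = "all",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-gene Poisson-binomial recurrence p-values.

    Parameters
    ----------
    genes
        ``"all"`` tests every gene the model deems testable (genes with no
        observed breakpoint enter with p-value 1 and contribute their null
        to the FDR step); ``"candidate"`` restricts to genes with at least
        one observed breakpoint.

    Returns
    -------
    table, null_tails
        ``table`` indexed by gene with columns ``t_obs``, ``prevalence``,
        ``p_value``; ``null_tails[i, k] = P0(T_i >= k)`` aligned with the
        table rows, the input to :func:`discrete_fdr`.
    """
    testable = model.testable_genes
    sub = gene_matrix.data.loc[testable]
    t_obs = sub.sum(axis=1).to_numpy()
    if genes == "candidate":
        keep = t_obs > 0
    elif genes == "all":
        keep = np.ones(len(testable), dtype=bool)
    else:
        raise ValueError(f"unknown gene selection {genes!r}")
    idx = sub.index[keep]
    t_obs = t_obs[keep]
    P = model.p.loc[idx].to_numpy()
    pmf = _pmf_matrix(P)
    tails = _tails_from_pmf(pmf)
    pvals = tails[np.arange(len(idx)), t_obs]
    table = pd.DataFrame({
        "t_obs": t_obs,
        "prevalence": t_obs / len(gene_matrix.samples),
        "p_value": pvals,
    }, index=idx)
    return table, tails


def discrete_fdr(
    p_values: np.ndarray,
    null_tails: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """BH-type step-up adjusted for discrete, per-hypothesis nulls.

    Each hypothesis's p-value takes values only on its attainable support
    ``{P0(T >= k)}``.  The estimated FDR at threshold ``t`` is
    ``FDRhat(t) = sum_g P0(P_g <= t) / max(1, #{p_g <= t})`` and
    ``q_g = min over attainable t >= p_g of FDRhat(t)``, capped at 1.
    With identical null distributions across hypotheses this reduces to the
    standard Benjamini–Hochberg correction.

    Parameters
    ----------
    p_values : observed p-values, one per hypothesis.
    null_tails : array (m, n+1); row g holds ``P0(T_g >= k)`` for k = 0..n.
    alpha : significance level for the returned flags (default 0.1).

    Returns
    -------
    q_values, significant
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.shape[0] != null_tails.shape[0]:
        raise ValueError("p_values and null_tails length mismatch")
    m = p_values.size
    if m == 0:
        return np.empty(0), np.empty(0, dtype=bool)

    # P0(P_g <= t) is a step function jumping by pmf(k) = tail(k) - tail(k+1)
    # at each attainable value tail(k); pool all jumps and cumulate.
    tails = np.asarray(null_tails, dtype=float)
    pmf = tails - np.concatenate([tails[:, 1:], np.zeros((m, 1))], axis=1)
    vals = tails.ravel()
    jumps = pmf.ravel()
    order = np.argsort(vals, kind="stable")
    vals_sorted = vals[order]
    cum = np.cumsum(jumps[order])
    # collapse ties: the numerator at a threshold includes every jump at
    # exactly that value, so read the cumulative sum at the last occurrence
    vals_u = np.unique(vals_sorted)
    last = np.searchsorted(vals_sorted, vals_u, side="right") - 1
    numer = cum[last]  # sum_g P0(P_g <= t) at t = vals_u (inclusive)

    p_sorted = np.sort(p_values)
    denom = np.searchsorted(p_sorted, vals_u, side="right")
    fdr_hat = numer / np.maximum(denom, 1)
    # step-up: minimal FDRhat over attainable thresholds >= t
    q_at = np.minimum.accumulate(fdr_hat[::-1])[::-1]
    pos = np.searchsorted(vals_u, p_values, side="left")
    pos = np.minimum(pos, vals_u.size - 1)
    q = np.minimum(q_at[pos], 1.0)
    return q, q < alpha


def probe_recurrence_test(
    probe_matrix: BinaryEventMatrix,
    breakpoint_counts: pd.Series,
    n_probes: int,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Probe-level recurrence test under a shared uniform null.

    Per profile s the probability that any given probe is a breakpoint probe
    is ``p_s = B_s / N_probes``; all probes share the resulting
    Poisson-binomial null, so standard Benjamini–Hochberg is applied.
    """
    samples = probe_matrix.samples
    b = breakpoint_counts.reindex(samples).to_numpy(dtype=float)
    if np.any(b > n_probes):
        raise ValueError("per-sample breakpoint count exceeds probe count")
    p_s = b / n_probes
    pmf = poisson_binomial_pmf(p_s)
    tails = _tails_from_pmf(pmf[None, :])[0]
    t_obs = probe_matrix.data.sum(axis=1).to_numpy()
    pvals = tails[t_obs]
    if np.all(pvals == 1.0):
        qvals = np.ones_like(pvals)
    else:
        qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "t_obs": t_obs,
        "prevalence": t_obs / len(samples),
        "p_value": pvals,
        "q_value": qvals,
        "significant": qvals < alpha,
    }, index=probe_matrix.data.index)


def recurrence_table(
    gene_matrix: BinaryEventMatrix,
    model: BreakpointProbabilityModel,
    gene_index: GeneProbeIndex | None = None,
    alpha: float = ALPHA_DEFAULT,
    genes: str = "all",
) -> pd.DataFrame:
    """Full gene-level recurrence analysis: test + discrete FDR, one table."""
    table, tails = gene_recurrence_test(gene_matrix, model, genes=genes)
    q, sig = discrete_fdr(table["p_value"].to_numpy(), tails, alpha=alpha)
    table = table.copy()
    table["q_value"] = q
    table["significant"] = sig
    if gene_index is not None:
        table.insert(0, "n_probes", gene_index.n_probes.reindex(table.index))
    return table.sort_values("p_value")
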