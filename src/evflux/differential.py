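"""Empirical-Bayes moderated t-tests with Benjamini-Hochberg control.

Per-protein variances :math:`s_g^2` (pooled residual variance across
all conditions, residual df :math:`d_g`) are assumed to follow a scaled
inverse-chi-square prior with hyper-parameters :math:`d_0` (prior df)
and :math:`s_0^2` (prior variance). The hyper-parameters are estimated
by matching the first two moments of :math:`\\log s_g^2` to the
log scaled-inv-chi-square distribution (digamma/trigamma equations).
The posterior variance

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}

replaces :math:`s_g^2` in the two-sample statistic, which then carries
:math:`d_0 + d_g` degrees of freedom. :math:`d_0 = 0` reduces to the
classical pooled t-test; :math:`d_0 = \\infty` to a z-like statistic
with fixed variance :math:`s_0^2`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .proteomics import AbundanceMatrix


@dataclass
class VariancePrior:
    """Scaled-inv-chi-square hyper-parameters for per-protein variances."""

    df: float  # d0 > 0, np.inf allowed
    var: float  # s0^2 > 0, log2^2 units

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValueError("prior df must be positive (np.inf allowed)")
        if not self.var > 0:
            raise ValueError("prior variance must be positive")


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration.

    Uses the monotone reparametrisation 1/trigamma for stable steps;
    large ``x`` means small ``y`` and vice versa.
    """
    if x <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    y = 0.5 + 1.0 / x  # exact as x -> 0, sane start elsewhere
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < tol:
            break
    return float(y)


def _residual_variances(values: np.ndarray, groups: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-condition variance and residual df per protein.

    NaN-aware: a group contributes ``n - 1`` df per protein only where
    ``n`` present values remain in that group.
    """
    n_prot = values.shape[0]
    ss = np.zeros(n_prot)
    df = np.zeros(n_prot)
    for g in np.unique(groups):
        sub = values[:, groups == g]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            total = np.nansum(sub, axis=1)
            mean = np.where(n > 0, total / np.maximum(n, 1), 0.0)
            dev = sub - mean[:, None]
            ss += np.nansum(dev * dev, axis=1)
        df += np.maximum(n - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(df > 0, ss / np.maximum(df, 1), np.nan)
    return s2, df


def fit_variance_prior(matrix: AbundanceMatrix) -> VariancePrior:
    """Estimate (d0, s0^2) from the spread of log sample variances.

    With ``e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)``, the model
    implies ``E[e_g] = log s0^2 + digamma(d0/2) - log(d0/2)`` and
    ``Var[e_g] = trigamma(d_g/2) + trigamma(d0/2)``; both are solved by
    moment matching, inverting trigamma by Newton. When the observed
    dispersion of ``e_g`` is at or below the theoretical minimum the
    prior df is reported as infinite (all variances effectively equal).
    """
    if matrix.scale != "log2":
        raise ValueError("fit_variance_prior requires a log2-scale matrix")
    s2, df = _residual_variances(matrix.intensities.to_numpy(),
                                 matrix.design.to_numpy())
    ok = (df >= 1) & np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 10:
        raise ValueError(
            f"need >= 10 proteins with residual df >= 1 and positive variance, "
            f"got {int(ok.sum())}")
    s2, df = s2[ok], df[ok]

    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        # dispersion at/below the theoretical floor: variances effectively
        # constant, prior df infinite, prior variance their plain mean
        return VariancePrior(df=np.inf, var=float(np.mean(s2)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(df=d0, var=s0sq)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    # guard the adjusted >= raw invariant against 1-ulp rounding in p*m/j
    return np.maximum(out, p)


class ModeratedTTest(BaseEstimator):
    """Moderated two-sample tests of every treatment against a control.

    scikit-learn style estimator: ``fit(X, y)`` takes a proteins x
    samples log2 matrix (ndarray or DataFrame, no missing values) and a
    sample-aligned condition label vector. Each non-control condition is
    compared with the control using the empirical-Bayes moderated t
    statistic; p-values are BH-adjusted within each comparison.

    Parameters
    ----------
    control
        Reference condition label.
    prior : VariancePrior, "estimate", or None
        ``"estimate"`` (default) fits (d0, s0^2) from the data;
        a :class:`VariancePrior` fixes them (``df=np.inf`` and ``df->0``
        limits supported, the latter via ``prior_df=0`` which bypasses
        moderation entirely).
    prior_df, prior_var
        Convenience scalar overrides used when ``prior is None``.

    Attributes
    ----------
    prior_df_, prior_var_ : float
        Hyper-parameters actually used.
    results_ : pandas.DataFrame
        One row per (protein, comparison): ``log2fc`` (treatment minus
        control), ``t``, ``df_residual``, ``df_total``, ``pvalue``,
        ``adj_pvalue``.
    """

    def __init__(self, control: str = "CTR", prior="estimate",
                 prior_df: float | None = None, prior_var: float | None = None):
        self.control = control
        self.prior = prior
        self.prior_df = prior_df
        self.prior_var = prior_var

    # -- internals --------------------------------------------------------
    def _resolve_prior(self, matrix: AbundanceMatrix) -> tuple[float, float]:
        if self.prior is None and self.prior_df is not None:
            return float(self.prior_df), float(self.prior_var or 1.0)
        if isinstance(self.prior, VariancePrior):
            return self.prior.df, self.prior.var
        if self.prior == "estimate":
            fitted = fit_variance_prior(matrix)
            return fitted.df, fitted.var
        raise ValueError(f"unrecognised prior {self.prior!r}")

    def fit(self, X, y=None, *, peptide_counts=None):
        if isinstance(X, AbundanceMatrix):
            matrix = X
        else:
            Xdf = pd.DataFrame(X)
            if y is None:
                raise ValueError("condition labels y are required")
            design = pd.Series(list(y), index=Xdf.columns)
            counts = (pd.Series(1, index=Xdf.index)
                      if peptide_counts is None else pd.Series(peptide_counts,
                                                               index=Xdf.index))
            matrix = AbundanceMatrix(intensities=Xdf, peptide_counts=counts,
                                     design=design, control=self.control,
                                     scale="log2")
        if matrix.intensities.isna().any().any():
            raise ValueError("matrix contains missing values; impute first")

        d0, s0sq = self._resolve_prior(matrix)
        self.prior_df_, self.prior_var_ = d0, s0sq

        values = matrix.intensities.to_numpy()
        groups = matrix.design.to_numpy()
        s2, dg = _residual_variances(values, groups)
        control_cols = groups == matrix.control
        if control_cols.sum() < 2:
            raise ValueError("control needs >= 2 retained replicates")
        ctrl_mean = values[:, control_cols].mean(axis=1)
        n_ctrl = int(control_cols.sum())

        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_total = np.full_like(s2, np.inf)
        elif d0 == 0:
            s2_post = s2
            df_total = dg
        else:
            s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
            df_total = d0 + dg

        rows = []
        for cond in matrix.conditions:
            if cond == matrix.control:
                continue
            cols = groups == cond
            n_c = int(cols.sum())
            if n_c < 2:
                raise ValueError(f"condition {cond!r} needs >= 2 retained replicates")
            delta = values[:, cols].mean(axis=1) - ctrl_mean
            se = np.sqrt(s2_post * (1.0 / n_c + 1.0 / n_ctrl))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
            rows.append(pd.DataFrame({
                "protein_id": matrix.intensities.index,
                "comparison": f"{cond}-vs-{matrix.control}",
                "log2fc": delta,
                "t": t,
                "df_residual": dg,
                "df_total": df_total,
                "pvalue": p,
                "adj_pvalue": bh_adjust(p),
            }))
        self.results_ = pd.concat(rows, ignore_index=True)
        return self

    def predict(self, adj_p_cut: float = 0.05, lfc_cut: float = 1.0) -> pd.DataFrame:
        """Classified volcano table at the stored thresholds."""
        return volcano_table(self.results_, adj_p_cut=adj_p_cut, lfc_cut=lfc_cut)


def moderated_ttest(matrix: AbundanceMatrix,
                    prior: VariancePrior | str = "estimate",
                    control: str | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`ModeratedTTest` for an
    :class:`AbundanceMatrix`; returns the per-protein results table."""
    if matrix.scale != "log2":
        raise ValueError("moderated_ttest requires a log2-scale matrix")
    est = ModeratedTTest(control=control or matrix.control, prior=prior)
    est.fit(matrix)
    return est.results_


def volcano_table(results: pd.DataFrame, adj_p_cut: float = 0.05,
                  lfc_cut: float = 1.0) -> pd.DataFrame:
    """Classify each protein as enriched / depleted / ns.

    ``enriched`` means adjusted p below ``adj_p_cut`` *and* log2 fold
    change above ``lfc_cut`` (treatment minus control); ``depleted`` is
    symmetric. Thresholds are recorded in ``DataFrame.attrs`` so calls
    are reproducible from the stored table.
    """
    out = results.copy()
    if len(out) == 0:
        out["call"] = pd.Series(dtype=str)
        out.attrs.update(adj_p_cut=adj_p_cut, lfc_cut=lfc_cut)
        return out
    sig = out["adj_pvalue"] < adj_p_cut
    call = np.where(sig & (out["log2fc"] > lfc_cut), "enriched",
                    np.where(sig & (out["log2fc"] < -lfc_cut), "depleted", "ns"))
    out["call"] = call
    out.attrs.update(adj_p_cut=adj_p_cut, lfc_cut=lfc_cut)
    return out


def summarize_calls(volcano: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison counts of enriched / depleted / ns proteins."""
    if len(volcano) == 0:
        return pd.DataFrame(columns=["enriched", "depleted", "ns"])
    return (volcano.pivot_table(index="comparison", columns="call",
                                values="protein_id", aggfunc="count",
                                fill_value=0)
            .reindex(columns=["enriched", "depleted", "ns"], fill_value=0))
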