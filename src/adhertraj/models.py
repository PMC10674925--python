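"""Multinomial modelling of adherence-group determinants.

Fits a maximum-likelihood multinomial logistic regression of trajectory
group membership on baseline covariates, with the high-adherence group as
the reference outcome, reporting odds ratios with Wald 95% confidence
intervals. Covariates can be screened with a forward stepwise procedure
with backward pruning, using likelihood-ratio tests at a fixed
significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MultinomialFit",
    "fit_multinomial",
    "stepwise_select",
    "report_effects",
    "plot_forest",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MultinomialFit:
    """Coefficients and Wald inference for group membership vs the reference group.

    Arrays are shaped (n_nonref_groups, n_terms) with terms ordered as
    ``const`` followed by ``covariates``.
    """

    reference_group: str
    groups: list  # non-reference outcome labels, fixed order
    covariates: list  # covariate names (excluding the constant)
    coefficients: np.ndarray  # log-odds
    standard_errors: np.ndarray
    log_likelihood: float
    n_obs: int

    @property
    def terms(self) -> list:
        return ["const"] + list(self.covariates)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.coefficients - _Z95 * self.standard_errors)
        hi = np.exp(self.coefficients + _Z95 * self.standard_errors)
        return lo, hi

    @property
    def p_values(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef(self, covariate: str, group: str) -> float:
        return float(
            self.coefficients[self.groups.index(group), self.terms.index(covariate)]
        )

    def odds_ratio(self, covariate: str, group: str) -> float:
        return float(np.exp(self.coef(covariate, group)))

    def se(self, covariate: str, group: str) -> float:
        return float(
            self.standard_errors[self.groups.index(group), self.terms.index(covariate)]
        )


def _suspect_separation(X: pd.DataFrame, groups: pd.Series) -> str:
    """Best-effort name of a covariate that perfectly separates an outcome."""
    for col in X.columns:
        values = X[col]
        if values.nunique() <= 10:  # categorical-ish
            tab = pd.crosstab(values, groups)
            if (tab == 0).any().any():
                return col
    return "unknown covariate"


def fit_multinomial(
    design: pd.DataFrame,
    groups: Sequence,
    reference: str = "high",
    maxiter: int = 500,
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit of ``groups`` on ``design`` columns.

    ``design`` holds the covariates only (a constant is added internally);
    the reference outcome's coefficients are fixed at zero. Non-reference
    outcomes are ordered alphabetically. Raises on rank-deficient designs
    and on (apparent) perfect separation, naming the offending covariate.
    """
    y = pd.Series(list(groups)).astype(str)
    present = sorted(y.unique())
    if reference not in present:
        raise ValueError(f"reference group {reference!r} absent from outcomes {present}")
    if len(present) < 2:
        raise ValueError("need at least two outcome groups to fit a multinomial model")
    nonref = [g for g in present if g != reference]
    codes = y.map({g: i for i, g in enumerate([reference] + nonref)}).to_numpy()

    X = design.copy().astype(float)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear or constant column)")

    try:
        with np.errstate(all="ignore"):
            res = sm.MNLogit(codes, exog).fit(
                method="newton", maxiter=maxiter, disp=0, tol=1e-10
            )
        bse = np.asarray(res.bse)
    except Exception as exc:  # singular Hessian, separation, ...
        raise ValueError(
            f"multinomial fit failed (possible perfect separation involving "
            f"{_suspect_separation(X, y)}): {exc}"
        ) from exc
    if not np.isfinite(bse).all() or np.abs(np.asarray(res.params)).max() > 50:
        raise ValueError(
            "multinomial fit degenerate (possible perfect separation involving "
            f"{_suspect_separation(X, y)})"
        )
    # statsmodels stores params as (n_terms, n_groups-1); transpose to group-major
    return MultinomialFit(
        reference_group=reference,
        groups=nonref,
        covariates=list(X.columns),
        coefficients=np.asarray(res.params).T,
        standard_errors=bse.T,
        log_likelihood=float(res.llf),
        n_obs=len(y),
    )


def _lr_pvalue(
    ll_full: float, ll_reduced: float, df: int
) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(stat, df))


def stepwise_select(
    design: pd.DataFrame,
    groups: Sequence,
    p_threshold: float = 0.05,
    reference: str = "high",
) -> tuple[list, MultinomialFit]:
    """Forward stepwise covariate selection with backward pruning.

    At each step the candidate with the smallest likelihood-ratio p-value is
    added if below the threshold; after each addition, any included
    covariate whose removal p-value is at or above the threshold is dropped.
    Ties break alphabetically, so the result is deterministic regardless of
    column order. May select the empty set (intercept-only model).
    """
    if design.shape[1] == 0:
        raise ValueError("no candidate covariates supplied")
    n_nonref = len(set(str(g) for g in groups)) - 1
    candidates = sorted(design.columns)
    selected: list = []

    def ll(cols: list) -> float:
        return fit_multinomial(design[cols], groups, reference=reference).log_likelihood

    current_ll = ll([])
    while True:
        changed = False
        # forward: best addition below threshold
        additions = []
        for cand in [c for c in candidates if c not in selected]:
            p = _lr_pvalue(ll(selected + [cand]), current_ll, df=n_nonref)
            additions.append((p, cand))
        if additions:
            p_best, best = min(additions)  # alphabetical tie-break via tuple order
            if p_best < p_threshold:
                selected = sorted(selected + [best])
                current_ll = ll(selected)
                changed = True
        # backward: prune anything no longer significant
        while True:
            removals = []
            for inc in selected:
                reduced = [c for c in selected if c != inc]
                p = _lr_pvalue(current_ll, ll(reduced), df=n_nonref)
                removals.append((p, inc))
            if not removals:
                break
            p_worst, worst = max(removals)
            if p_worst >= p_threshold:
                selected = [c for c in selected if c != worst]
                current_ll = ll(selected)
                changed = True
            else:
                break
        if not changed:
            break
    final = fit_multinomial(design[selected], groups, reference=reference)
    return selected, final


def report_effects(fit: MultinomialFit) -> pd.DataFrame:
    """Tidy odds-ratio table: one row per (group, covariate), constant excluded."""
    lo, hi = fit.ci95
    p = fit.p_values
    rows = []
    for gi, group in enumerate(fit.groups):
        for ci, cov in enumerate(fit.covariates):
            ti = ci + 1  # skip the constant
            rows.append(
                {
                    "group": group,
                    "covariate": cov,
                    "odds_ratio": float(fit.odds_ratios[gi, ti]),
                    "ci_low": float(lo[gi, ti]),
                    "ci_high": float(hi[gi, ti]),
                    "p_value": float(p[gi, ti]),
                }
            )
    return (
        pd.DataFrame(
            rows, columns=["group", "covariate", "odds_ratio", "ci_low", "ci_high", "p_value"]
        )
        .sort_values(["group", "covariate"])
        .reset_index(drop=True)
    )


def plot_forest(or_table: pd.DataFrame, path: str) -> None:
    """Forest plot of odds ratios with 95% CIs, one panel per outcome group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(or_table["group"].unique())
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3.4 * len(groups), 0.6 + 0.5 * or_table["covariate"].nunique()),
        sharey=True,
    )
    axes = np.atleast_1d(axes)
    for ax, group in zip(axes, groups):
        sub = or_table[or_table["group"] == group]
        ys = np.arange(len(sub))
        ax.errorbar(
            sub["odds_ratio"],
            ys,
            xerr=[sub["odds_ratio"] - sub["ci_low"], sub["ci_high"] - sub["odds_ratio"]],
            fmt="o",
            color="navy",
            capsize=2,
        )
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(ys, sub["covariate"])
        ax.set_xlabel("odds ratio (95% CI)")
        ax.set_title(f"vs {group}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
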