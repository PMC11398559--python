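"""Admission predictors of trajectory group membership.

Two stages, mirroring the study design:

1. **Univariate screening** — each declared covariate is tested against the
   group labels (one-way ANOVA for continuous, chi-squared for categorical);
   features with p below ``alpha`` become candidates.
2. **Multinomial logistic regression with forward stepwise selection** —
   starting from an intercept-only model, the candidate whose addition gives
   the smallest likelihood-ratio p-value is added while that p-value is
   below ``alpha``.  Coefficients are reported as odds ratios per natural
   unit (per year of age, per GCS point) relative to a reference group, with
   Wald confidence intervals.

The likelihood-ratio entry criterion is a design choice (the original
analysis names only "forward stepwise selection"); LRT is preferred over
Wald tests for stability at moderate sample sizes.  Multi-level categorical
features are dummy-coded against their most frequent level and enter or
leave the model as a block.  Missing covariate values are handled
complete-case per fitted model, with counts logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .associations import TestResult, chi_square_test, crosstab, one_way_anova

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenResult",
    "MNLogitModel",
    "univariate_screen",
    "build_design",
    "fit_multinomial_logit",
    "lr_test",
    "forward_stepwise",
    "odds_ratios",
]

#: |coefficient| beyond which a fit is flagged as (quasi-)separated.
SEPARATION_THRESHOLD = 30.0


@dataclass(frozen=True)
class ScreenResult:
    feature: str
    test_name: str
    statistic: float
    p_value: float
    selected: bool


@dataclass(frozen=True)
class MNLogitModel:
    """A fitted multinomial logistic regression versus a reference group.

    ``params`` has one column per non-reference group and one row per design
    column (intercept included); reference-group coefficients are fixed at
    zero and not stored.
    """

    reference_group: object
    group_levels: tuple
    feature_names: tuple[str, ...]
    params: pd.DataFrame
    bse: pd.DataFrame
    cov_params: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: int
    features: tuple[str, ...] = ()

    @property
    def n_free_params(self) -> int:
        return int(self.params.size)

    def predict_proba(self, design: pd.DataFrame) -> np.ndarray:
        """Class probabilities (columns ordered reference first)."""
        eta = design.to_numpy(dtype=float) @ self.params.to_numpy()
        eta = np.column_stack([np.zeros(len(design)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def univariate_screen(
    covariates: pd.DataFrame,
    types: Mapping[str, str],
    labels: Sequence,
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Test each declared covariate against group labels.

    Continuous features use one-way ANOVA; categorical features use the
    chi-squared test on the feature x group table.  A constant feature gets
    p = 1.0 and is never selected.  Undeclared columns do not enter.
    """
    lab = np.asarray(labels)
    results = []
    for feature, ftype in types.items():
        if ftype not in ("continuous", "categorical"):
            raise ValueError(f"feature {feature!r}: type must be continuous or categorical")
        if feature not in covariates.columns:
            raise KeyError(f"feature {feature!r} not in covariate table")
        col = covariates[feature]
        mask = col.notna()
        if (~mask).any():
            logger.info("feature %r: %d missing value(s) dropped", feature, int((~mask).sum()))
        x, g = col[mask.to_numpy()], lab[mask.to_numpy()]
        if x.nunique() <= 1:
            results.append(ScreenResult(feature, "constant", 0.0, 1.0, False))
            continue
        if ftype == "continuous":
            res = one_way_anova(x.to_numpy(dtype=float), g)
        else:
            res = chi_square_test(crosstab(g, x))
        results.append(ScreenResult(feature, res.test_name, res.statistic,
                                    res.p_value, res.p_value < alpha))
    return results


def build_design(
    covariates: pd.DataFrame,
    features: Sequence[str],
    types: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix with intercept; dummy-coding for categoricals.

    Categorical features are dummy-coded against their most frequent level;
    the returned block map lists, per feature, the design columns it owns
    (so stepwise can add/remove a multi-level feature as a block).
    """
    cols: dict[str, pd.Series] = {"const": pd.Series(1.0, index=covariates.index)}
    blocks: dict[str, list[str]] = {}
    for feature in features:
        if types[feature] == "continuous":
            cols[feature] = covariates[feature].astype(float)
            blocks[feature] = [feature]
        else:
            col = covariates[feature].astype(str)
            ref = col.value_counts().idxmax()
            blocks[feature] = []
            for level in sorted(set(col) - {ref}):
                name = f"{feature}[{level}]"
                cols[name] = (col == level).astype(float)
                blocks[feature].append(name)
    return pd.DataFrame(cols), blocks


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [str(design.columns[p]) for p in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear column(s): {sorted(bad)}")


def fit_multinomial_logit(
    design: pd.DataFrame,
    labels: Sequence,
    reference_group=None,
    features: Sequence[str] = (),
    maxiter: int = 200,
) -> MNLogitModel:
    """Maximum-likelihood multinomial logit with a fixed reference group.

    Newton-type optimization of the softmax log-likelihood with the
    reference group's coefficients pinned at zero.  Apparent separation
    (any |coefficient| above 30) is flagged as non-converged with a warning;
    estimates are still returned.  A rank-deficient design raises, naming
    the collinear columns.
    """
    lab = pd.Series(labels).reset_index(drop=True)
    design = design.reset_index(drop=True)
    if len(lab) != len(design):
        raise ValueError("labels and design must have equal length")
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise ValueError("labels must have at least 2 levels")
    if reference_group is None:
        reference_group = levels[0]
    if reference_group not in levels:
        raise ValueError(f"reference group {reference_group!r} not among labels")
    ordered = [reference_group] + [g for g in levels if g != reference_group]
    codes = lab.map({g: i for i, g in enumerate(ordered)}).to_numpy()

    K, p = len(levels), design.shape[1]
    if len(lab) <= (K - 1) * p:
        raise ValueError("too few observations for the number of free parameters")
    nonconst = design.columns[design.nunique() <= 1].difference(["const"])
    if len(nonconst):
        raise ValueError(f"constant non-intercept column(s): {list(nonconst)}")
    _check_rank(design)

    model = sm.MNLogit(codes, design.to_numpy(dtype=float))
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0, gtol=1e-8)
        except np.linalg.LinAlgError:
            # singular observed information (typically perfect separation):
            # recover estimates quasi-Newton and flag the fit
            logger.warning("Newton fit failed (singular Hessian); falling back to BFGS")
            res = model.fit(method="bfgs", maxiter=max(maxiter, 500), disp=0)
            fallback = True
    params = pd.DataFrame(
        res.params, index=design.columns,
        columns=[f"group_{g}" for g in ordered[1:]],
    )
    converged = bool(res.mle_retvals.get("converged", False)) and not fallback
    if np.abs(params.to_numpy()).max() > SEPARATION_THRESHOLD:
        logger.warning("possible separation: |coefficient| exceeds %.0f", SEPARATION_THRESHOLD)
        converged = False
    try:
        bse_arr = np.asarray(res.bse)
        cov = pd.DataFrame(res.cov_params())
    except Exception:  # covariance unavailable on a degenerate fit
        bse_arr = np.full(params.shape, np.nan)
        cov = pd.DataFrame()
    bse = pd.DataFrame(bse_arr, index=params.index, columns=params.columns)
    return MNLogitModel(
        reference_group=reference_group,
        group_levels=tuple(ordered),
        feature_names=tuple(design.columns),
        params=params,
        bse=bse,
        cov_params=cov,
        log_likelihood=float(res.llf),
        converged=converged,
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        n_obs=len(lab),
        features=tuple(features),
    )


def lr_test(full: MNLogitModel, reduced: MNLogitModel) -> TestResult:
    """Likelihood-ratio test of nested multinomial fits."""
    if not set(reduced.feature_names) <= set(full.feature_names):
        raise ValueError("reduced model's design columns must nest in the full model's")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted on different data")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        raise RuntimeError("full model has lower likelihood than the reduced model "
                           "(optimizer failure)")
    df = full.n_free_params - reduced.n_free_params
    if df == 0:
        return TestResult(0.0, (0,), 1.0, "likelihood_ratio")
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return TestResult(float(max(stat, 0.0)), (df,), p, "likelihood_ratio")


def forward_stepwise(
    covariates: pd.DataFrame,
    types: Mapping[str, str],
    candidates: Sequence[str],
    labels: Sequence,
    alpha: float = 0.05,
    reference_group=None,
) -> tuple[MNLogitModel, list[dict]]:
    """Forward stepwise selection by likelihood-ratio entry tests.

    At each step the candidate with the smallest LR p-value joins the model
    if that p-value is below ``alpha`` (ties broken by larger statistic,
    then input order); selection stops when no candidate qualifies.  Returns
    the final model and the ordered selection trace.  The procedure is fully
    deterministic given the data and candidate order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    lab = pd.Series(labels).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    mask = cov[list(candidates)].notna().all(axis=1)
    if (~mask).any():
        logger.info("forward_stepwise: %d row(s) dropped for missing covariates", int((~mask).sum()))
        cov, lab = cov[mask].reset_index(drop=True), lab[mask].reset_index(drop=True)

    def fit(selected: list[str]) -> MNLogitModel:
        design, _ = build_design(cov, selected, types)
        return fit_multinomial_logit(design, lab, reference_group, features=tuple(selected))

    selected: list[str] = []
    current = fit(selected)
    trace: list[dict] = []
    remaining = list(candidates)
    while remaining:
        best = None
        for idx, cand in enumerate(remaining):
            candidate_model = fit(selected + [cand])
            res = lr_test(candidate_model, current)
            key = (res.p_value, -res.statistic, idx)
            if best is None or key < best[0]:
                best = (key, cand, candidate_model, res)
        _, cand, model, res = best
        if res.p_value >= alpha:
            break
        selected.append(cand)
        current = model
        remaining.remove(cand)
        trace.append({"feature": cand, "statistic": res.statistic,
                      "df": res.df[0], "p_value": res.p_value})
    return current, trace


def odds_ratios(model: MNLogitModel, level: float = 0.95) -> pd.DataFrame:
    """Per-group, per-feature odds ratios with Wald confidence intervals.

    ``OR = exp(beta)``; CI endpoints are ``exp(beta +/- z * se)``.  The
    intercept row is excluded.  Non-converged models are flagged unreliable.
    """
    if not model.converged:
        logger.warning("odds ratios from a non-converged model are unreliable")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    rows = []
    for group in model.params.columns:
        for feat in model.params.index:
            if feat == "const":
                continue
            b = model.params.loc[feat, group]
            se = model.bse.loc[feat, group]
            wald_p = 2 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
            rows.append(
                {
                    "group": group,
                    "feature": feat,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                    "p_value": float(wald_p),
                    "reliable": model.converged,
                }
            )
    return pd.DataFrame(rows)
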