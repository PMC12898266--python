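"""Prediction pipeline: design matrix, subset and stepwise logistic models,
predicted death probabilities, and AUROC comparison.

The design matrix has one row per patient and one column per candidate
predictor ``<CM><Parameter>`` (13 parameters x 11 CMs = 143 candidates)
plus the binary 60-day mortality outcome and baseline covariates (age
and four comorbidity scores).  Missing parameter cells propagate as NaN
and are handled by case-wise deletion: a patient missing any variable
used by the model being fit is excluded from that fit.

Model building mirrors a development-only design: per-CM *subset*
models on the 13 parameters of one CM; a *main* model built by set-wise
stepwise logistic regression (attribute sets entered in succession,
starting with the most recent values, with one-at-a-time backward
removal of terms whose Wald p-value is no longer below ``alpha``); the
main model's predicted probability of death (PDeathLabs) per patient;
and AUROC estimation with DeLong standard errors and paired tests
against single-factor baseline models.

Because parameters whose definition requires a currently abnormal CM
(``TimeNotAtGoal``/``CtNotAtGoal``) or a multi-reading cluster
(``MaxClustDays``) are missing for most patients, case-wise deletion
over all 143 candidates would empty any realistic cohort.  The stepwise
builder therefore first drops candidate columns missing in more than
``max_missing_frac`` of rows (default 0.25, which cleanly separates the
structurally missing refractoriness columns from ordinarily missing
ones; the exclusions are reported and the threshold configurable), then
deletes case-wise over the surviving candidates once, keeping the
analysis set fixed across stages so p-values are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, rankdata

from .config import ATTRIBUTES, COVARIATE_NAMES, OUTCOME_NAME, PARAMETER_NAMES
from .tabular import derive_table
from .timeline import CM_NAMES, TargetSpec


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    targets: Mapping[str, TargetSpec],
    cms: Sequence[str] = CM_NAMES,
    time_wt_avg_on: str = "auc",
) -> pd.DataFrame:
    """Patients x (candidates + outcome + covariates) matrix.

    ``measurements`` must already be truncated at index minus blackout
    (see :func:`cmparams.tabular.truncate_frame`).  Column order is
    CM-major with attribute order within each CM.  Covariate columns
    absent from ``patients`` are simply omitted.
    """
    cms = tuple(cms)
    unknown = set(measurements["cm_name"].unique()) - set(cms)
    if unknown:
        raise ValueError(f"unknown CM names in measurements: {sorted(unknown)}")
    pats = patients.set_index("patient_id")
    params = derive_table(measurements, targets, patient_ids=pats.index,
                          cms=cms, time_wt_avg_on=time_wt_avg_on)
    out = params.copy()
    out[OUTCOME_NAME] = pats[OUTCOME_NAME]
    for cov in COVARIATE_NAMES:
        if cov in pats.columns:
            out[cov] = pats[cov]
    return out


def casewise_complete(matrix: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Rows of ``matrix`` complete (non-missing) in all named columns."""
    missing = set(columns) - set(matrix.columns)
    if missing:
        raise KeyError(f"columns not in matrix: {sorted(missing)}")
    return matrix.loc[matrix[list(columns)].notna().all(axis=1)]


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted logistic model in reporting shape (one row per term)."""

    terms: List[str]                 # predictor names, constant excluded
    coef: Dict[str, float]           # includes "const"
    se: Dict[str, float]
    p_values: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    n_used: int
    converged: bool
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Report table: Parameter, Coefficient, StdErr, pValue, CI95lo, CI95hi."""
        rows = [
            (t, self.coef[t], self.se[t], self.p_values[t], self.ci_low[t], self.ci_high[t])
            for t in self.terms + ["const"]
        ]
        return pd.DataFrame(
            rows, columns=["Parameter", "Coefficient", "StdErr", "pValue", "CI95lo", "CI95hi"]
        )

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        missing = set(self.terms) - set(matrix.columns)
        if missing:
            raise KeyError(f"matrix lacks model columns: {sorted(missing)}")
        block = matrix[self.terms]
        if block.isna().any().any():
            raise ValueError(
                "matrix rows must be case-wise complete for the model terms; "
                "apply casewise_complete first"
            )
        lp = np.full(len(matrix), self.coef["const"], dtype=np.float64)
        for t in self.terms:
            lp += self.coef[t] * block[t].to_numpy(dtype=np.float64)
        return pd.Series(expit(lp), index=matrix.index, name="p_death")


def _fit_logit(y: np.ndarray, X: pd.DataFrame, maxiter: int = 100) -> FitResult:
    """Maximum-likelihood logistic fit with explicit convergence reporting."""
    terms = list(X.columns)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # transient link overflow is benign
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, method="newton")
    except Exception as exc:  # perfect separation, singular Hessian and friends
        nan = {t: float("nan") for t in terms + ["const"]}
        return FitResult(terms, nan, dict(nan), dict(nan), dict(nan), dict(nan),
                         n_used=len(y), converged=False, message=str(exc))
    converged, message = bool(res.mle_retvals.get("converged", True)), ""
    if not converged:
        message = "optimizer did not converge"
    elif not np.isfinite(res.bse).all():
        converged, message = False, "non-finite standard errors (singular information)"
    elif np.abs(res.params).max() > 1e3:
        converged, message = False, "diverging coefficients (possible separation)"
    ci = res.conf_int()
    names = list(Xc.columns)
    return FitResult(
        terms=terms,
        coef=dict(zip(names, res.params)),
        se=dict(zip(names, res.bse)),
        p_values=dict(zip(names, res.pvalues)),
        ci_low=dict(zip(names, np.asarray(ci)[:, 0])),
        ci_high=dict(zip(names, np.asarray(ci)[:, 1])),
        n_used=len(y),
        converged=converged,
        message=message,
    )


def fit_logistic(matrix: pd.DataFrame, columns: Sequence[str]) -> FitResult:
    """Logistic fit of the outcome on ``columns`` after case-wise deletion."""
    cc = casewise_complete(matrix, list(columns) + [OUTCOME_NAME])
    if len(cc) == 0:
        raise ValueError("no complete cases for the requested columns")
    y = cc[OUTCOME_NAME].to_numpy(dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("outcome is single-class after case-wise deletion")
    return _fit_logit(y, cc[list(columns)].astype(np.float64))


# ---------------------------------------------------------------------------
# AUROC via Mann-Whitney concordance with DeLong variance
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """AUROC with DeLong standard error.

    Keeps the per-case and per-control placement values so that paired
    curve comparisons can be computed from two results on the same
    patients.
    """

    auroc: float
    se: float
    n_pos: int
    n_neg: int
    _v_pos: np.ndarray = field(repr=False, default=None)
    _v_neg: np.ndarray = field(repr=False, default=None)


def compute_auroc(scores: Sequence[float], outcomes: Sequence[int]) -> ROCResult:
    """AUROC as the Mann-Whitney concordance (ties count one half).

    Equals the probability that a randomly chosen case outranks a
    randomly chosen control.  The standard error is DeLong's, from the
    empirical variance of the placement values.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUROC undefined: need at least one case and one control")
    # midrank placements: v_pos[i] = fraction of controls below pos[i] (ties 1/2)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / n
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v_pos.mean())
    var = (np.var(v_pos, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v_neg, ddof=1) / n if n > 1 else 0.0)
    return ROCResult(auroc=auc, se=float(np.sqrt(var)), n_pos=m, n_neg=n,
                     _v_pos=v_pos, _v_neg=v_neg)


def compare_auroc(roc_a: ROCResult, roc_b: ROCResult, paired: bool = True) -> float:
    """Two-sided p-value for the difference of two AUROCs (DeLong).

    Paired comparisons require both curves to come from the same
    patients in the same order; the covariance of the placement values
    then accounts for the correlation between the curves.
    """
    diff = roc_a.auroc - roc_b.auroc
    if paired:
        if roc_a.n_pos != roc_b.n_pos or roc_a.n_neg != roc_b.n_neg:
            raise ValueError("paired comparison needs identical patient sets")
        m, n = roc_a.n_pos, roc_a.n_neg
        var = 0.0
        if m > 1:
            cov_pos = np.cov(roc_a._v_pos, roc_b._v_pos, ddof=1)
            var += (cov_pos[0, 0] + cov_pos[1, 1] - 2 * cov_pos[0, 1]) / m
        if n > 1:
            cov_neg = np.cov(roc_a._v_neg, roc_b._v_neg, ddof=1)
            var += (cov_neg[0, 0] + cov_neg[1, 1] - 2 * cov_neg[0, 1]) / n
    else:
        var = roc_a.se**2 + roc_b.se**2
    if var <= 0.0:
        return 1.0 if diff == 0.0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# subset, single-factor and stepwise models
# ---------------------------------------------------------------------------

def subset_regression(matrix: pd.DataFrame, cm_name: str
                      ) -> Tuple[FitResult, Optional[ROCResult]]:
    """Logistic model of the outcome on one CM's 13 parameters.

    Case-wise deletion over the 13 columns; the in-sample predicted
    probabilities give the subset AUROC.  Non-convergence (e.g. through
    separation) is reported in the FitResult, never silently ignored.
    """
    cols = [f"{cm_name}{p}" for p in PARAMETER_NAMES]
    fit = fit_logistic(matrix, cols)
    if not fit.converged or not np.isfinite(list(fit.coef.values())).all():
        return fit, None
    cc = casewise_complete(matrix, cols + [OUTCOME_NAME])
    probs = fit.predict(cc)
    return fit, compute_auroc(probs.to_numpy(), cc[OUTCOME_NAME].to_numpy())


def single_factor_model(matrix: pd.DataFrame, covariate_name: str
                        ) -> Tuple[FitResult, ROCResult]:
    """One-predictor logistic baseline (age or a comorbidity score) + AUROC.

    Since the predicted probability is a monotone transform of the
    covariate, the AUROC equals (up to sign of the slope) the AUROC of
    the raw covariate.
    """
    cc = casewise_complete(matrix, [covariate_name, OUTCOME_NAME])
    if cc[covariate_name].nunique() <= 1:
        raise ValueError(f"covariate {covariate_name!r} is constant: discrimination undefined")
    fit = fit_logistic(matrix, [covariate_name])
    probs = fit.predict(cc)
    return fit, compute_auroc(probs.to_numpy(), cc[OUTCOME_NAME].to_numpy())


@dataclass
class StepwiseResult:
    """Outcome of the set-wise stepwise build."""

    fit: FitResult
    retained: List[str]
    excluded_high_missing: List[str]
    n_used: int
    history: List[dict] = field(default_factory=list)


def stepwise_main_model(
    matrix: pd.DataFrame,
    attribute_order: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    cms: Sequence[str] = CM_NAMES,
    max_missing_frac: float = 0.25,
) -> StepwiseResult:
    """Set-wise stepwise logistic regression over the candidate parameters.

    Entry proceeds by attribute set, starting with the most recent
    values: all surviving columns of the next attribute are added, the
    model refit, and terms with Wald p >= ``alpha`` removed one at a
    time (largest p first, refitting after each drop) until every
    retained term is significant.  Candidate columns missing in more
    than ``max_missing_frac`` of rows are excluded up front and
    reported; case-wise deletion over the remaining candidates fixes the
    analysis set once, so n is constant across stages.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    order = list(attribute_order or ATTRIBUTES.keys())
    if sorted(order) != sorted(ATTRIBUTES.keys()):
        raise ValueError(f"attribute_order must be a permutation of {sorted(ATTRIBUTES)}")
    if order[0] != "current_control":
        raise ValueError("modeling must start with the set of most recent values")

    sets = {a: [f"{cm}{p}" for cm in cms for p in ATTRIBUTES[a]] for a in order}
    all_cands = [c for a in order for c in sets[a]]
    miss_frac = matrix[all_cands].isna().mean()
    excluded = [c for c in all_cands if miss_frac[c] > max_missing_frac]
    usable = [c for c in all_cands if c not in excluded]

    cc = casewise_complete(matrix, usable + [OUTCOME_NAME])
    if len(cc) == 0:
        raise ValueError("no complete cases over the candidate columns")
    y = cc[OUTCOME_NAME].to_numpy(dtype=np.float64)
    X = cc[usable].astype(np.float64)
    # zero-variance columns cannot enter any fit
    constant = [c for c in usable if X[c].nunique() <= 1]
    excluded = excluded + constant
    usable = [c for c in usable if c not in constant]

    model: List[str] = []
    history: List[dict] = []
    fit: Optional[FitResult] = None
    for attr in order:
        incoming = [c for c in sets[attr] if c in usable]
        if not incoming:
            history.append({"set": attr, "entered": [], "removed": [], "n_terms": len(model)})
            continue
        model = model + incoming
        fit = _fit_logit(y, X[model])
        if not fit.converged:
            raise RuntimeError(
                f"stepwise fit failed to converge after entering set {attr!r}: {fit.message}"
            )
        removed: List[str] = []
        while True:
            pvals = {t: fit.p_values[t] for t in model}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] < alpha:
                break
            model.remove(worst)
            removed.append(worst)
            if not model:
                fit = None
                break
            fit = _fit_logit(y, X[model])
            if not fit.converged:
                raise RuntimeError(
                    f"stepwise refit failed to converge while pruning set {attr!r}: {fit.message}"
                )
        history.append({"set": attr, "entered": incoming, "removed": removed,
                        "n_terms": len(model)})
    if fit is None:
        fit = _fit_logit(y, X[model]) if model else _fit_logit(y, X[[]])
    return StepwiseResult(fit=fit, retained=model, excluded_high_missing=excluded,
                          n_used=len(cc), history=history)


def predict_pdeathlabs(fit: FitResult, matrix: pd.DataFrame) -> pd.Series:
    """Predicted probability of death for each (case-wise complete) row.

    The logistic inverse link of the final model's linear predictor;
    rows must be complete for the model's terms.
    """
    return fit.predict(matrix)
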