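"""Binary logistic / probit models of neurological outcome.

The Glasgow Outcome Scale (GOS, 1-5; 1 = death) is binarized either as
survival (GOS > 1) or as favorable outcome (High, GOS >= 4, vs Low,
GOS <= 3), and modeled from clinical covariates plus orthogonal-polynomial
trend features of the CSF mediator series.  Fitting goes through
statsmodels maximum likelihood; near-separation — common at n ≈ 27 with
strong predictors — is detected and handled with a small ridge penalty so
coefficients and standard errors remain finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort

RIDGE_PENALTY = 1e-4
_PARAM_BLOWUP = 30.0  # |beta| beyond this on standardized-ish data flags separation


def binarize_gos(gos: int, rule: str = "survival") -> int:
    """Map a GOS score to a binary outcome.

    ``survival``: 1 for GOS > 1 (alive), 0 for GOS = 1 (death).
    ``low_high``: 1 for High (GOS >= 4, favorable), 0 for Low (GOS <= 3).
    """
    if rule == "survival":
        return int(gos > 1)
    if rule == "low_high":
        return int(gos >= 4)
    raise ValueError(f"unknown outcome rule {rule!r}")


@dataclass
class OutcomeModelSpec:
    link: str = "logit"  # "logit" | "probit"
    outcome_rule: str = "survival"
    terms: list[str] | None = None  # None = all feature columns
    selection: str = "none"  # "none" | "t_threshold"
    t_cut: float = 1.5

    def __post_init__(self) -> None:
        if self.link not in ("logit", "probit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.selection not in ("none", "t_threshold"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass
class OutcomeModelFit:
    link: str
    terms: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    tvalues: pd.Series  # coefficient / SE
    fitted: pd.Series  # in-sample fitted survival probabilities
    converged: bool
    separation: bool
    ridge: bool
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def split_cohort(
    cohort_or_ids, outcomes=None, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Reproducible train/test split, stratified by binary outcome.

    Test-set size is ``n - round(n * train_fraction)``, at least 1 on each
    side; test slots are allocated across the two outcome strata by largest
    remainder so the death fraction is preserved.
    """
    if isinstance(cohort_or_ids, Cohort):
        ids = cohort_or_ids.ids
        if outcomes is None:
            outcomes = [
                binarize_gos(p.gos) if p.gos is not None else 1
                for p in cohort_or_ids
            ]
    else:
        ids = list(cohort_or_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    outcomes = np.asarray(outcomes if outcomes is not None else np.zeros(n, int))
    n_test = int(np.clip(n - round(n * train_fraction), 1, n - 1))

    rng = np.random.default_rng(seed)
    strata = {c: [ids[i] for i in np.flatnonzero(outcomes == c)] for c in np.unique(outcomes)}
    quotas = {c: n_test * len(v) / n for c, v in strata.items()}
    takes = {c: int(np.floor(q)) for c, q in quotas.items()}
    shortfall = n_test - sum(takes.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - takes[c], reverse=True):
        if shortfall <= 0:
            break
        if takes[c] < len(strata[c]):
            takes[c] += 1
            shortfall -= 1
    test: list[str] = []
    for c, members in strata.items():
        members = list(members)
        rng.shuffle(members)
        test.extend(members[: takes[c]])
    test_set = set(test)
    train = [i for i in ids if i not in test_set]
    test = [i for i in ids if i in test_set]
    return train, test


def _ridge_fit(X: np.ndarray, y: np.ndarray, link: str, lam: float = RIDGE_PENALTY):
    """Penalized ML fit: minimize -loglik + lam * ||beta||^2.

    Standard errors come from the inverse of the penalized observed
    information, which stays positive definite under separation.
    """
    model = sm.Logit(y, X) if link == "logit" else sm.Probit(y, X)

    def objective(beta):
        return -model.loglike(beta) + lam * beta @ beta

    def grad(beta):
        return -model.score(beta) + 2.0 * lam * beta

    res = scipy.optimize.minimize(
        objective, np.zeros(X.shape[1]), jac=grad, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    beta = res.x
    hess = -model.hessian(beta) + 2.0 * lam * np.eye(X.shape[1])
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    fitted = model.cdf(X @ beta)
    return beta, se, fitted, bool(res.success)


def fit(
    features: pd.DataFrame,
    outcomes,
    link: str = "logit",
    ridge_on_separation: bool = True,
) -> OutcomeModelFit:
    """Maximum-likelihood binary fit with t-values (coefficient / SE).

    Complete or quasi-complete separation is flagged; with
    ``ridge_on_separation`` the model is refit under a small quadratic
    penalty (lambda = 1e-4) instead of raising.
    """
    if features.shape[0] <= features.shape[1]:
        raise ValueError(
            f"n = {features.shape[0]} rows cannot support "
            f"{features.shape[1]} terms plus intercept"
        )
    variances = features.var(axis=0)
    dead = list(variances.index[variances == 0])
    if dead:
        raise ValueError(f"zero-variance predictors: {dead}")
    y = np.asarray(outcomes, dtype=float)
    X = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")
    names = ["const", *features.columns]

    separation = False
    params = se = fitted = None
    converged = ridge = False
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            model = sm.Logit(y, X) if link == "logit" else sm.Probit(y, X)
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            if converged and np.max(np.abs(res.params)) < _PARAM_BLOWUP:
                params, se, fitted = res.params, res.bse, res.predict(X)
            else:
                separation = True
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
    if params is None:
        if not (separation and ridge_on_separation):
            raise RuntimeError("fit did not converge and ridge fallback disabled")
        with np.errstate(all="ignore"):
            params, se, fitted, converged = _ridge_fit(X, y, link)
        ridge = True

    params = pd.Series(params, index=names)
    se = pd.Series(se, index=names)
    return OutcomeModelFit(
        link=link,
        terms=list(features.columns),
        params=params,
        bse=se,
        tvalues=params / se,
        fitted=pd.Series(np.asarray(fitted), index=features.index),
        converged=converged,
        separation=separation,
        ridge=ridge,
    )


def fit_model(
    spec: OutcomeModelSpec, features: pd.DataFrame, outcomes
) -> OutcomeModelFit:
    """Fit according to an :class:`OutcomeModelSpec`: restrict to the
    spec's terms, optionally backward-eliminate at ``spec.t_cut``, and fit
    with the spec's link."""
    terms = list(features.columns) if spec.terms is None else list(spec.terms)
    missing = [t for t in terms if t not in features.columns]
    if missing:
        raise ValueError(f"spec terms not in features: {missing}")
    if spec.selection == "t_threshold":
        terms = select_terms(features[terms], outcomes, spec.link, spec.t_cut)
    return fit(features[terms], outcomes, link=spec.link)


def fit_ordinal(
    features: pd.DataFrame, gos_values, link: str = "logit"
) -> tuple[pd.Series, pd.Series, bool]:
    """Proportional-odds (ordinal logit/probit) fit of the full 5-level GOS.

    A secondary variant alongside the binary models: returns slope and
    threshold estimates with their standard errors.  GOS levels absent
    from the data are simply not assigned thresholds.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    gos = pd.Series(
        pd.Categorical(np.asarray(gos_values, dtype=int), ordered=True)
    )
    model = OrderedModel(gos, features.to_numpy(dtype=float), distr=link)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=200, disp=0)
    names = [*features.columns,
             *[f"threshold_{i}" for i in range(len(res.params) - features.shape[1])]]
    return (
        pd.Series(np.asarray(res.params), index=names),
        pd.Series(np.asarray(res.bse), index=names),
        bool(res.mle_retvals.get("converged", True)),
    )


def predict_prob(fit_result: OutcomeModelFit, features: pd.DataFrame | pd.Series) -> pd.Series:
    """Survival probability via the inverse link of the linear predictor."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    missing = [t for t in fit_result.terms if t not in features.columns]
    if missing:
        raise ValueError(f"missing model terms in features: {missing}")
    X = features[fit_result.terms].to_numpy(dtype=float)
    lp = fit_result.params["const"] + X @ fit_result.params[fit_result.terms].to_numpy()
    if fit_result.link == "logit":
        p = 1.0 / (1.0 + np.exp(-lp))
    else:
        p = scipy.stats.norm.cdf(lp)
    return pd.Series(p, index=features.index)


def select_terms(
    features: pd.DataFrame,
    outcomes,
    link: str = "logit",
    t_cut: float = 1.5,
) -> list[str]:
    """Backward elimination: drop the least-significant term until all
    |t| >= t_cut.  Ties break deterministically by column order (the later
    column is dropped).  Returns [] (intercept-only) if nothing survives.
    """
    terms = list(features.columns)
    while terms:
        fitted = fit(features[terms], outcomes, link=link)
        t_abs = fitted.tvalues[terms].abs()
        worst = t_abs.min()
        if worst >= t_cut:
            return terms
        # last column among the minimal |t| values
        victims = [t for t in terms if t_abs[t] == worst]
        terms.remove(victims[-1])
    warnings.warn("all terms eliminated; returning intercept-only model")
    return []


def screen_terms(
    features: pd.DataFrame,
    outcomes,
    blocks: list[list[str]],
    link: str = "logit",
    t_cut: float = 1.5,
) -> list[str]:
    """Marginal screening: fit each block of columns separately and pool
    the terms with |t| >= t_cut.  Remedy for candidate pools (10 clinical +
    13(d+1) trends) far larger than the cohort.
    Blocks that fail to fit (e.g. degenerate columns) are skipped.
    """
    kept: list[str] = []
    for block in blocks:
        cols = [c for c in block if c in features.columns]
        if not cols:
            continue
        sub = features[cols]
        sub = sub.loc[:, sub.var(axis=0) > 0]
        if sub.shape[1] == 0 or sub.shape[0] <= sub.shape[1]:
            continue
        try:
            f = fit(sub, outcomes, link=link)
        except (ValueError, RuntimeError):
            continue
        kept.extend(t for t in sub.columns if abs(f.tvalues[t]) >= t_cut)
    return kept


def t_table(values, ses, names=None) -> pd.DataFrame:
    """Table-style fit report (term, value, SE, t-value) with t = value/SE."""
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if names is None:
        names = [f"b{i}" for i in range(values.size)]
    return pd.DataFrame(
        {"value": values, "std_error": ses, "t_value": values / ses}, index=list(names)
    )


def fit_report(fit_result: OutcomeModelFit) -> pd.DataFrame:
    names = ["const", *fit_result.terms]
    return t_table(
        fit_result.params[names].to_numpy(), fit_result.bse[names].to_numpy(), names
    )


def evaluate(probabilities, outcomes, threshold: float = 0.5) -> dict:
    """Classification summary at a probability threshold.

    A patient is classified as surviving when probability > threshold
    (strict, so exactly 0.5 counts as non-survival).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.size == 0 or p.size != y.size:
        raise ValueError("probabilities and outcomes must be equal-length, non-empty")
    pred = (p > threshold).astype(int)
    return {
        "accuracy": float(np.mean(pred == y)),
        "n_correct": int(np.sum(pred == y)),
        "n": int(y.size),
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
        "misclassified": [int(i) for i in np.flatnonzero(pred != y)],
    }

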