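"""Cox partial likelihood, elastic-net fitting and penalty tuning.

Conventions
-----------
* Mixing parameter ``alpha`` multiplies the L1 term: ``alpha=1`` is the
  LASSO, ``alpha=0`` Ridge, ``alpha=0.5`` the Elastic Net used throughout
  the benchmark.  ``lam`` is the glmnet-scale penalty weight (partial
  log-likelihood averaged over subjects).
* Tied event times use Breslow's approximation everywhere.
* Covariates are standardised internally before penalized fitting;
  coefficients are always reported on the original scale.

Penalty tuning follows the cross-validated partial log-likelihood (cvl) of
Verweij & van Houwelingen: ``cvl(lam) = sum_k [l(b_{-k}; all) -
l(b_{-k}; without fold k)]``.  The stricter pcvl criterion subtracts a
parsimony penalty proportional to the number of active coefficients, with
the per-coefficient cost set by the cvl gain of the cvl-optimal model over
the null model (Ternes, Rotolo & Michiels 2016); its maximiser is by
construction at least as large as the cvl-optimal penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .simdata import SurvivalDataset

__all__ = [
    "CoxModel",
    "CVResult",
    "cox_partial_loglik",
    "partial_loglik_from_eta",
    "penalized_objective",
    "fit_elastic_net_cox",
    "fit_cox_refit",
    "cross_validated_loglik",
    "select_lambda_pcvl",
    "breslow_baseline",
    "predict_risk_linear",
]

DEFAULT_TOL = 1e-5  # coxnet solver tolerance; selection paths are stable at this level
DEFAULT_N_LAMBDAS = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01


@dataclass
class CoxModel:
    """A (possibly sparse) Cox model with an optional Breslow baseline."""

    coefficients: np.ndarray
    lam: float = 0.0
    alpha: float = 1.0
    baseline_times: np.ndarray | None = None
    baseline_cumhaz: np.ndarray | None = None

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients)

    def predict_linear(self, covariates: np.ndarray) -> np.ndarray:
        return np.asarray(covariates, dtype=float) @ self.coefficients

    def cumulative_hazard(self, times) -> np.ndarray:
        """Baseline cumulative hazard evaluated at ``times`` (step function)."""
        if self.baseline_times is None:
            raise ValueError("model has no baseline; call breslow_baseline first")
        idx = np.searchsorted(self.baseline_times, np.asarray(times, float), side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]

    def predict_survival(self, covariates: np.ndarray, times) -> np.ndarray:
        """S(t | z) = exp(-H0(t) * exp(b'z)); shape (n_rows, n_times)."""
        h0 = self.cumulative_hazard(times)
        eta = self.predict_linear(covariates)
        return np.exp(-np.outer(np.exp(eta), h0))

    def to_dict(self) -> dict:
        d = {
            "lambda": float(self.lam),
            "alpha": float(self.alpha),
            "coefficients": {
                int(j): float(self.coefficients[j]) for j in self.selected
            },
            "p": int(self.coefficients.size),
        }
        if self.baseline_times is not None:
            d["baseline"] = {
                "times": self.baseline_times.tolist(),
                "cumhaz": self.baseline_cumhaz.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoxModel":
        coef = np.zeros(d["p"])
        for j, v in d["coefficients"].items():
            coef[int(j)] = v
        base = d.get("baseline")
        return cls(
            coefficients=coef,
            lam=d["lambda"],
            alpha=d["alpha"],
            baseline_times=None if base is None else np.asarray(base["times"]),
            baseline_cumhaz=None if base is None else np.asarray(base["cumhaz"]),
        )


@dataclass
class CVResult:
    """Cross-validated likelihood profile along a decreasing penalty grid."""

    lambda_grid: np.ndarray
    cvl_values: np.ndarray
    active_counts: np.ndarray
    n_folds: int
    lambda_cvl: float
    lambda_pcvl: float
    alpha: float
    coef_path: np.ndarray = field(repr=False)  # shape (p, n_lambdas), full-data fit

    def coefficients_at(self, lam: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.lambda_grid - lam)))
        return self.coef_path[:, i].copy()


def partial_loglik_from_eta(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood given the linear predictor."""
    event = np.asarray(event)
    if event.sum() == 0:
        warnings.warn("no events: partial log-likelihood is an empty sum", stacklevel=2)
        return 0.0
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, float)[order]
    e = event[order]
    et = np.asarray(eta, float)[order]
    # risk set of an event at time t is {j : T_j >= t}: a suffix of the sorted order
    suffix_lse = np.logaddexp.accumulate(et[::-1])[::-1]
    first_of_tie = np.searchsorted(t, t, side="left")
    ev = e == 1
    return float(np.sum(et[ev]) - np.sum(suffix_lse[first_of_tie[ev]]))


def cox_partial_loglik(beta: np.ndarray, data: SurvivalDataset) -> float:
    """Cox partial log-likelihood l(beta) with Breslow tie handling."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.p,):
        raise ValueError(f"beta must have length p={data.p}")
    return partial_loglik_from_eta(data.covariates @ beta, data.time, data.event)


def penalized_objective(
    beta: np.ndarray, data: SurvivalDataset, lam: float, alpha: float
) -> float:
    """glmnet-scale objective: l(beta)/n - lam * (alpha*|b|_1 + (1-alpha)/2*|b|_2^2)."""
    beta = np.asarray(beta, float)
    pen = alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum()
    return cox_partial_loglik(beta, data) / data.n - lam * pen


def _surv_y(data: SurvivalDataset):
    return Surv.from_arrays(data.event.astype(bool), data.time)


def _fit_path(
    data: SurvivalDataset,
    alpha: float,
    lambda_grid: np.ndarray | None = None,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Elastic-net Cox solution path; returns (decreasing grid, coefs (p, L)).

    Covariates are standardised to unit variance here (not by the solver,
    whose own ``normalize`` rescales to unit L2 norm and thereby distorts
    the L1:L2 mix for alpha < 1); coefficients come back per original
    unit, and the penalty grid lives on the glmnet scale.
    """
    if alpha <= 0:
        raise ValueError("path fitting requires alpha > 0 (use fit_cox_refit for ridge)")
    kwargs: dict = dict(l1_ratio=alpha, normalize=False, tol=tol, fit_baseline_model=False)
    if lambda_grid is not None:
        kwargs["alphas"] = np.asarray(lambda_grid, dtype=float)
    else:
        kwargs["n_alphas"] = n_lambdas
        kwargs["alpha_min_ratio"] = lambda_min_ratio
    X = data.covariates
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    model = CoxnetSurvivalAnalysis(**kwargs)
    with warnings.catch_warnings():
        # an all-zero path is a legitimate outcome on null data
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        model.fit((X - X.mean(axis=0)) / sd, _surv_y(data))
    return np.asarray(model.alphas_), np.asarray(model.coef_) / sd[:, None]


def lambda_max(data: SurvivalDataset, alpha: float = 1.0) -> float:
    """Smallest penalty with an all-zero solution: max absolute gradient of
    the per-subject partial log-likelihood at beta=0 on unit-variance
    covariates, divided by the L1 weight (the glmnet convention, which the
    penalty grid lives on)."""
    if alpha <= 0:
        raise ValueError("lambda_max requires alpha > 0")
    X = data.covariates
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    Xo = Xs[order]
    cnt = np.arange(len(t), 0, -1)
    suffix_mean = np.cumsum(Xo[::-1], axis=0)[::-1] / cnt[:, None]
    start = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(e == 1)
    grad = (Xo[ev] - suffix_mean[start[ev]]).sum(axis=0) / data.n
    return float(np.abs(grad).max() / alpha)


def fit_elastic_net_cox(
    data: SurvivalDataset,
    lam: float,
    alpha: float,
    tol: float = DEFAULT_TOL,
    with_baseline: bool = True,
) -> CoxModel:
    """Fit a penalized Cox model at one (lam, alpha).

    ``lam=0`` or ``alpha=0`` is routed through an (optionally ridge-)
    penalized Newton-Raphson fit, since the coordinate-descent path solver
    requires a strictly positive L1 weight.
    """
    if lam < 0 or not 0 <= alpha <= 1:
        raise ValueError("need lam >= 0 and alpha in [0, 1]")
    if lam == 0 or alpha == 0:
        model = fit_cox_refit(
            data, np.arange(data.p), ridge=lam * (1 - alpha) * data.n
        )
        model.lam, model.alpha = lam, alpha
    elif lam >= lambda_max(data, alpha):
        model = CoxModel(coefficients=np.zeros(data.p), lam=lam, alpha=alpha)
    else:
        # short warm-start path from just above lambda_max down to the target
        grid = np.geomspace(lambda_max(data, alpha) * 1.05, lam, 15)
        alphas, coefs = _fit_path(data, alpha, lambda_grid=grid, tol=tol)
        if not np.isclose(alphas[-1], lam, rtol=1e-8):
            raise RuntimeError(
                f"path solver did not reach lam={lam}: stopped at {alphas[-1]} "
                f"after {len(alphas)} grid points"
            )
        model = CoxModel(coefficients=coefs[:, -1].copy(), lam=lam, alpha=alpha)
    if with_baseline:
        breslow_baseline(model, data)
    return model


def fit_cox_refit(
    data: SurvivalDataset,
    columns: np.ndarray,
    ridge: float = 0.0,
    with_baseline: bool = True,
) -> CoxModel:
    """(Ridge-)penalized Newton-Raphson Cox fit restricted to ``columns``.

    Used for unpenalized refits on small selected sets; the returned
    coefficient vector is embedded in the full length-p layout.
    """
    from lifelines import CoxPHFitter
    import pandas as pd

    columns = np.asarray(columns, dtype=int)
    coef = np.zeros(data.p)
    if columns.size > 0:
        df = pd.DataFrame(
            data.covariates[:, columns], columns=[f"g{j}" for j in columns]
        )
        df["__time"] = data.time
        df["__event"] = data.event
        cph = CoxPHFitter(penalizer=ridge / max(data.n, 1), l1_ratio=0.0)
        cph.fit(df, duration_col="__time", event_col="__event")
        coef[columns] = cph.params_.values
    model = CoxModel(coefficients=coef, lam=ridge, alpha=0.0)
    if with_baseline:
        breslow_baseline(model, data)
    return model


def _event_stratified_folds(
    data: SurvivalDataset, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Fold test-index sets, stratified by event status; one redraw on a
    degenerate draw (a fold whose complement carries no event), then failure."""
    for attempt in range(2):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        with warnings.catch_warnings():
            # fewer censored subjects than folds merely degrades stratification
            warnings.filterwarnings("ignore", message="The least populated class")
            folds = [test for _, test in skf.split(np.zeros(data.n), data.event)]
        ok = all(
            data.event.sum() - data.event[f].sum() > 0 and data.event[f].sum() > 0
            for f in folds
        )
        if ok:
            return folds
    raise RuntimeError("could not build folds with events in every part")


def cross_validated_loglik(
    data: SurvivalDataset,
    alpha: float = 1.0,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
    folds: list[np.ndarray] | None = None,
) -> CVResult:
    """Verweij-van Houwelingen cross-validated likelihood along the path.

    ``folds`` (a list of held-out index arrays) overrides the internal
    event-stratified fold draw; the likelihood itself is invariant to
    subject order given the same fold membership.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    grid, coefs = _fit_path(
        data, alpha, lambda_grid, n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio, tol=tol,
    )
    if folds is None:
        folds = _event_stratified_folds(data, n_folds, seed)
    cvl = np.zeros(len(grid))
    for test_idx in folds:
        mask = np.ones(data.n, dtype=bool)
        mask[test_idx] = False
        train = data.subset(np.flatnonzero(mask))
        g_k, coef_k = _fit_path(train, alpha, lambda_grid=grid, tol=tol)
        if len(g_k) != len(grid):  # solver truncated the path: carry last solution
            full_coef = np.zeros((data.p, len(grid)))
            pos = np.searchsorted(-grid, -g_k)
            full_coef[:, pos] = coef_k
            last = 0
            for i in range(len(grid)):
                if np.any(full_coef[:, i]) or i in set(pos):
                    last = i
                else:
                    full_coef[:, i] = full_coef[:, last]
            coef_k = full_coef
        eta_full = data.covariates @ coef_k
        eta_train = train.covariates @ coef_k
        for i in range(len(grid)):
            cvl[i] += partial_loglik_from_eta(
                eta_full[:, i], data.time, data.event
            ) - partial_loglik_from_eta(eta_train[:, i], train.time, train.event)
    active = np.count_nonzero(coefs, axis=0)
    i_cvl = int(np.argmax(cvl))  # first occurrence -> largest lam on ties
    result = CVResult(
        lambda_grid=grid,
        cvl_values=cvl,
        active_counts=active,
        n_folds=n_folds,
        lambda_cvl=float(grid[i_cvl]),
        lambda_pcvl=np.nan,
        alpha=alpha,
        coef_path=coefs,
    )
    result.lambda_pcvl = select_lambda_pcvl(result)
    return result


def select_lambda_pcvl(cv: CVResult) -> float:
    """Parsimony-penalized cvl maximiser (never below the cvl choice).

    pcvl(lam) = cvl(lam) - c * df(lam) with
    c = [cvl(lam_cvl) - cvl(lam_max)] / df(lam_cvl): the average cvl gain
    per active coefficient of the cvl-optimal model over the null end of
    the path.  Maximised over lam >= lam_cvl, ties to the largest lam.
    """
    i_cvl = int(np.argmax(cv.cvl_values))
    df_cvl = cv.active_counts[i_cvl]
    if df_cvl == 0:
        return float(cv.lambda_grid[0])
    gain = cv.cvl_values[i_cvl] - cv.cvl_values[0]
    if gain <= 0:
        return float(cv.lambda_grid[0])
    c = gain / df_cvl
    upto = slice(0, i_cvl + 1)  # grid decreasing: indices 0..i_cvl have lam >= lam_cvl
    pcvl = cv.cvl_values[upto] - c * cv.active_counts[upto]
    # parsimony contract: never more active coefficients than the cvl choice
    pcvl = np.where(cv.active_counts[upto] <= df_cvl, pcvl, -np.inf)
    return float(cv.lambda_grid[int(np.argmax(pcvl))])


def breslow_baseline(model: CoxModel, train: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard; also stored on ``model``.

    H0(t) = sum over event times s <= t of d_s / sum_{j: T_j >= s} exp(b'Z_j).
    """
    eta = model.predict_linear(train.covariates)
    order = np.argsort(train.time, kind="stable")
    t = train.time[order]
    e = train.event[order]
    w = np.exp(eta[order])
    suffix = np.cumsum(w[::-1])[::-1]
    ev_times, d_counts = np.unique(t[e == 1], return_counts=True)
    i0 = np.searchsorted(t, ev_times, side="left")
    increments = d_counts / suffix[i0]
    model.baseline_times = ev_times
    model.baseline_cumhaz = np.cumsum(increments)
    return model.baseline_times, model.baseline_cumhaz


def predict_risk_linear(model: CoxModel, covariates: np.ndarray) -> np.ndarray:
    """Linear-predictor risk score b'z per row (higher = higher hazard)."""
    return model.predict_linear(covariates)
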