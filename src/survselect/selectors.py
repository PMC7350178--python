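"""The six variable-selection strategies under comparison.

Each selector consumes a training :class:`SurvivalDataset` and returns a
:class:`SelectionResult` carrying the selected gene indices, a risk-scoring
rule for new subjects (higher score = higher hazard), a survival-probability
rule for prediction-error curves, and a method-specific diagnostics record.

Methods
-------
``lasso_cvl``   L1 Cox path, penalty by 10-fold cross-validated likelihood.
``lasso_pcvl``  Same path, penalty by the parsimony-penalized criterion.
``enet``        Elastic Net (alpha = 0.5), penalty by cvl.
``bss_enet``    Bootstrap stability selection around the Elastic Net.
``coxboost``    Component-wise likelihood boosting, steps by cvl.
``rsf``         Random survival forest with minimal-depth variable hunting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import boosting, forest
from .coxcore import (
    CoxModel,
    CVResult,
    cross_validated_loglik,
    fit_cox_refit,
    DEFAULT_LAMBDA_MIN_RATIO,
    DEFAULT_N_LAMBDAS,
    DEFAULT_TOL,
)
from .simdata import SurvivalDataset

__all__ = [
    "SelectionResult",
    "BssConfig",
    "METHODS",
    "select_lasso_cvl",
    "select_lasso_pcvl",
    "select_enet",
    "select_bss_enet",
    "select_coxboost",
    "select_rsf",
    "run_selector",
]


@dataclass
class SelectionResult:
    method: str
    selected: np.ndarray
    risk_scorer: Callable[[np.ndarray], np.ndarray]
    survival_predictor: Callable[[np.ndarray, np.ndarray], np.ndarray]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(len(self.selected))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": [int(j) for j in self.selected],
            "diagnostics": {
                k: v
                for k, v in self.diagnostics.items()
                if np.isscalar(v) or isinstance(v, (str, int, float))
            },
        }


@dataclass(frozen=True)
class BssConfig:
    """Bootstrap stability selection knobs; the inclusion threshold sigma
    must lie in [0.5, 1]."""

    n_subsamples: int = 100
    threshold: float = 0.5
    n_folds: int = 10
    n_lambdas: int = DEFAULT_N_LAMBDAS
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.n_subsamples < 2:
            raise ValueError("need at least two bootstrap subsamples")
        if not 0.5 <= self.threshold <= 1.0:
            raise ValueError("threshold sigma must lie in [0.5, 1]")


def _result_from_model(method: str, model: CoxModel, diagnostics: dict) -> SelectionResult:
    return SelectionResult(
        method=method,
        selected=model.selected.copy(),
        risk_scorer=model.predict_linear,
        survival_predictor=model.predict_survival,
        diagnostics=diagnostics,
    )


def _penalized_select(
    method: str,
    train: SurvivalDataset,
    seed: int,
    alpha: float,
    use_pcvl: bool,
    n_folds: int,
    n_lambdas: int,
    lambda_min_ratio: float,
    tol: float,
) -> SelectionResult:
    cv = cross_validated_loglik(
        train,
        alpha=alpha,
        n_folds=n_folds,
        seed=seed,
        n_lambdas=n_lambdas,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
    )
    lam = cv.lambda_pcvl if use_pcvl else cv.lambda_cvl
    model = CoxModel(coefficients=cv.coefficients_at(lam), lam=lam, alpha=alpha)
    from .coxcore import breslow_baseline

    breslow_baseline(model, train)
    diag = {
        "lambda": lam,
        "lambda_cvl": cv.lambda_cvl,
        "lambda_pcvl": cv.lambda_pcvl,
        "n_folds": n_folds,
        "cv": cv,
    }
    return _result_from_model(method, model, diag)


def select_lasso_cvl(
    train: SurvivalDataset,
    seed: int = 0,
    n_folds: int = 10,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
) -> SelectionResult:
    """LASSO with the penalty maximizing the cross-validated likelihood."""
    return _penalized_select(
        "lasso_cvl", train, seed, 1.0, False, n_folds, n_lambdas, lambda_min_ratio, tol
    )


def select_lasso_pcvl(
    train: SurvivalDataset,
    seed: int = 0,
    n_folds: int = 10,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
) -> SelectionResult:
    """LASSO with the stricter parsimony-penalized cvl criterion."""
    return _penalized_select(
        "lasso_pcvl", train, seed, 1.0, True, n_folds, n_lambdas, lambda_min_ratio, tol
    )


def select_enet(
    train: SurvivalDataset,
    seed: int = 0,
    alpha: float = 0.5,
    n_folds: int = 10,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
) -> SelectionResult:
    """Elastic Net (L1 weight alpha = 0.5) with the penalty chosen by cvl."""
    return _penalized_select(
        "enet", train, seed, alpha, False, n_folds, n_lambdas, lambda_min_ratio, tol
    )


def select_bss_enet(
    train: SurvivalDataset,
    config: BssConfig = BssConfig(),
    seed: int = 0,
    alpha: float = 0.5,
) -> SelectionResult:
    """Bootstrap stability selection around the Elastic Net.

    The Elastic Net (penalty by cvl) is run on ``n_subsamples`` bootstrap
    resamples of the training set; genes selected in a fraction >= sigma of
    the resamples form the signature, which is then refit as a Cox model
    (unpenalized when comfortably identifiable, ridge otherwise) to produce
    the risk score.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    counts = np.zeros(train.p)
    for b in range(config.n_subsamples):
        for attempt in range(2):
            idx = rng.integers(0, train.n, train.n)
            if train.event[idx].sum() > 0:
                break
        else:
            raise RuntimeError("bootstrap resample without events")
        boot = train.subset(idx)
        cv = cross_validated_loglik(
            boot,
            alpha=alpha,
            n_folds=config.n_folds,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            tol=config.tol,
        )
        counts[np.flatnonzero(cv.coefficients_at(cv.lambda_cvl))] += 1
    probs = counts / config.n_subsamples
    selected = np.flatnonzero(probs >= config.threshold)
    diag = {
        "selection_probability": probs,
        "n_subsamples": config.n_subsamples,
        "threshold": config.threshold,
        "empty_final_set": len(selected) == 0,
    }
    if len(selected) == 0:
        zero_model = CoxModel(coefficients=np.zeros(train.p))
        from .coxcore import breslow_baseline

        breslow_baseline(zero_model, train)
        return SelectionResult(
            method="bss_enet",
            selected=selected,
            risk_scorer=lambda X: np.zeros(np.asarray(X).shape[0]),
            survival_predictor=zero_model.predict_survival,
            diagnostics=diag,
        )
    if len(selected) < train.n / 5:
        model = fit_cox_refit(train, selected, ridge=0.0)
        diag["refit"] = "unpenalized"
    else:
        model = _ridge_refit_by_cvl(train, selected, seed=int(rng.integers(0, 2**31 - 1)))
        diag["refit"] = f"ridge (penalizer={model.lam:.3g})"
    return SelectionResult(
        method="bss_enet",
        selected=selected,
        risk_scorer=model.predict_linear,
        survival_predictor=model.predict_survival,
        diagnostics=diag,
    )


def _ridge_refit_by_cvl(
    train: SurvivalDataset,
    selected: np.ndarray,
    seed: int,
    grid=(0.1, 1.0, 10.0, 100.0),
    n_folds: int = 5,
) -> CoxModel:
    """Ridge refit on a large selected set; penalty picked by the
    cross-validated likelihood over a coarse grid."""
    from .coxcore import _event_stratified_folds, partial_loglik_from_eta

    folds = _event_stratified_folds(train, n_folds, seed)
    best, best_cvl = grid[0], -np.inf
    for ridge in grid:
        cvl = 0.0
        for test_idx in folds:
            mask = np.ones(train.n, dtype=bool)
            mask[test_idx] = False
            sub = train.subset(np.flatnonzero(mask))
            m = fit_cox_refit(sub, selected, ridge=ridge, with_baseline=False)
            cvl += partial_loglik_from_eta(
                m.predict_linear(train.covariates), train.time, train.event
            ) - partial_loglik_from_eta(
                m.predict_linear(sub.covariates), sub.time, sub.event
            )
        if cvl > best_cvl:
            best, best_cvl = ridge, cvl
    return fit_cox_refit(train, selected, ridge=best)


def select_coxboost(
    train: SurvivalDataset,
    seed: int = 0,
    config: boosting.BoostingConfig = boosting.BoostingConfig(),
) -> SelectionResult:
    """Component-wise likelihood boosting; steps by cvl."""
    model, diag = boosting.fit_coxboost(train, seed=seed, config=config)
    return _result_from_model("coxboost", model, diag)


def select_rsf(
    train: SurvivalDataset,
    seed: int = 0,
    config: forest.RsfConfig = forest.RsfConfig(),
) -> SelectionResult:
    """Random survival forest: variable hunting for the signature, ensemble
    cumulative hazard (out-of-bag for training subjects) for the score."""
    ss = np.random.SeedSequence(seed).spawn(2)
    selected, vh_diag = forest.variable_hunting(
        train, config=config, seed=int(ss[0].generate_state(1)[0] % 2**31)
    )
    fst = forest.SurvivalForest(
        n_trees=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
    ).fit(train, np.random.default_rng(ss[1]))
    diag = dict(vh_diag)
    diag["oob_risk_scores"] = fst.oob_risk_score(train)
    return SelectionResult(
        method="rsf",
        selected=selected,
        risk_scorer=fst.risk_score,
        survival_predictor=fst.predict_survival,
        diagnostics=diag,
    )


METHODS: dict[str, Callable] = {
    "lasso_cvl": select_lasso_cvl,
    "lasso_pcvl": select_lasso_pcvl,
    "enet": select_enet,
    "bss_enet": lambda train, seed=0, **kw: select_bss_enet(
        train, config=kw.pop("config", BssConfig()), seed=seed, **kw
    ),
    "coxboost": lambda train, seed=0, **kw: select_coxboost(
        train, seed=seed, config=kw.pop("config", boosting.BoostingConfig()), **kw
    ),
    "rsf": lambda train, seed=0, **kw: select_rsf(
        train, seed=seed, config=kw.pop("config", forest.RsfConfig()), **kw
    ),
}


def run_selector(name: str, train: SurvivalDataset, seed: int = 0, **kwargs) -> SelectionResult:
    """Dispatch a selector by name (one of :data:`METHODS`)."""
    try:
        fn = METHODS[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    return fn(train, seed=seed, **kwargs)
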