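"""Repeated training/validation split design.

The cohort is randomly split ``n_splits`` times (default 100) into a
training part of fraction f (1/2 or 2/3, round-half-up) and a validation
part.  All methods of a benchmark share the identical splits so that
between-method intersections compare selections made on the same samples.
Every selector fit sees only its split's training rows; validation rows
enter solely through scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .selectors import METHODS, SelectionResult, run_selector
from .simdata import SurvivalDataset

__all__ = ["SplitPlan", "CellRecord", "BenchmarkResult", "make_splits", "run_benchmark"]


@dataclass(frozen=True)
class SplitPlan:
    split_id: int
    train_indices: np.ndarray
    valid_indices: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        tr, va = set(self.train_indices.tolist()), set(self.valid_indices.tolist())
        if tr & va:
            raise ValueError("train and validation indices overlap")


@dataclass
class CellRecord:
    """One (split, method) outcome."""

    split_id: int
    method: str
    selected: np.ndarray | None = None
    n_selected: int = 0
    fdr: float = float("nan")
    fnr: float = float("nan")
    cindex: float = float("nan")
    ibs: float = float("nan")
    error: str | None = None
    result: SelectionResult | None = None


@dataclass
class BenchmarkResult:
    scenario: str
    methods: list[str]
    active_set: frozenset
    p: int
    records: list[CellRecord] = field(default_factory=list)
    flags: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell table: scenario, split_id, method, n_selected,
        fdr, fnr, cindex, ibs."""
        return pd.DataFrame(
            [
                {
                    "scenario": self.scenario,
                    "split_id": r.split_id,
                    "method": r.method,
                    "n_selected": r.n_selected,
                    "fdr": r.fdr,
                    "fnr": r.fnr,
                    "cindex": r.cindex,
                    "ibs": r.ibs,
                    "error": r.error,
                }
                for r in self.records
            ]
        )

    def selections(self) -> dict[str, dict[int, list[int]]]:
        out: dict[str, dict[int, list[int]]] = {m: {} for m in self.methods}
        for r in self.records:
            if r.error is None and r.selected is not None:
                out[r.method][r.split_id] = [int(j) for j in r.selected]
        return out


def make_splits(
    n: int,
    fraction: float,
    n_splits: int = 100,
    seed: int = 0,
    event: np.ndarray | None = None,
) -> list[SplitPlan]:
    """Independent uniform splits; |train| = round-half-up(f*n).

    With an ``event`` vector given, each part must contain at least one
    event; a degenerate draw is redrawn once, then the split fails.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    n_train = int(np.floor(fraction * n + 0.5))
    if not 0 < n_train < n:
        raise ValueError("fraction leaves an empty train or validation part")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    plans = []
    for s in range(n_splits):
        for attempt in range(2):
            perm = rng.permutation(n)
            train, valid = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            if event is None or (event[train].sum() > 0 and event[valid].sum() > 0):
                break
        else:
            raise RuntimeError(f"split {s}: could not place events in both parts")
        plans.append(
            SplitPlan(split_id=s, train_indices=train, valid_indices=valid,
                      fraction=fraction, seed=seed)
        )
    return plans


def _cell_seed(seed: int, split_id: int, method_index: int) -> int:
    ss = np.random.SeedSequence([seed, split_id, method_index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_benchmark(
    data: SurvivalDataset,
    methods: list[str],
    plans: list[SplitPlan],
    seed: int = 0,
    scenario: str = "",
    method_kwargs: dict[str, dict] | None = None,
    compute_performance: bool = True,
) -> BenchmarkResult:
    """Fit every method on every split's training part and score its
    validation part.

    Failures are recorded per cell rather than raised; a method failing in
    more than 10% of its cells is flagged in ``result.flags``.  Cells are
    mutually independent: each derives its own seed from
    (seed, split_id, method), so execution order cannot change results.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    method_kwargs = method_kwargs or {}
    result = BenchmarkResult(
        scenario=scenario, methods=list(methods), active_set=data.active_set, p=data.p
    )
    for plan in plans:
        train = data.subset(plan.train_indices)
        valid = data.subset(plan.valid_indices)
        for mi, method in enumerate(methods):
            rec = CellRecord(split_id=plan.split_id, method=method)
            try:
                sel = run_selector(
                    method, train,
                    seed=_cell_seed(seed, plan.split_id, mi),
                    **method_kwargs.get(method, {}),
                )
                rec.result = sel
                rec.selected = sel.selected
                rec.n_selected = sel.n_selected
                rec.fdr = _metrics.fdr(sel.selected, data.active_set)
                rec.fnr = _metrics.fnr(sel.selected, data.active_set)
                if compute_performance:
                    scores = np.asarray(sel.risk_scorer(valid.covariates), float)
                    rec.cindex = _metrics.concordance_index(
                        scores, valid.time, valid.event
                    )
                    rec.ibs = _metrics.integrated_brier(sel.survival_predictor, valid)
            except Exception as exc:  # recorded, not fatal
                rec.error = f"{type(exc).__name__}: {exc}"
            result.records.append(rec)
    for method in methods:
        cells = [r for r in result.records if r.method == method]
        failed = sum(1 for r in cells if r.error is not None)
        if cells and failed / len(cells) > 0.10:
            result.flags[method] = f"{failed}/{len(cells)} cells failed"
    return result
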