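"""Selection-quality and prognostic-performance metrics.

Selection metrics compare a selected gene set against the simulation's
active set: the false discovery rate (share of selected genes that are
inactive), the false negative rate (share of active genes missed), the
per-gene occurrence frequency over resampling splits, and pairwise
between-method intersections with the true-positive rate among the common
genes.  Undefined ratios (empty selection for FDR, empty active set for
FNR, empty intersection for the TP rate) are reported as NaN, never as 0.

Prognostic metrics score validation subjects: Harrell's concordance index
on the risk scores and the integrated Brier score (IBS) of the predicted
survival curves, censoring-weighted by the Kaplan-Meier estimate of the
censoring distribution on the validation set (IPCW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sksurv.metrics import concordance_index_censored

from .simdata import SurvivalDataset

__all__ = [
    "fdr",
    "fnr",
    "occurrence_frequency",
    "summarize_frequencies",
    "pairwise_intersection",
    "concordance_index",
    "integrated_brier",
    "MetricTable",
    "aggregate_tables",
    "med_min_max",
]


def _as_set(indices) -> set:
    return {int(i) for i in indices}


def fdr(selected, active) -> float:
    """|selected \\ active| / |selected|; NaN when nothing was selected."""
    sel, act = _as_set(selected), _as_set(active)
    if not sel:
        return float("nan")
    return len(sel - act) / len(sel)


def fnr(selected, active) -> float:
    """|active \\ selected| / |active|; NaN when there is no active set."""
    sel, act = _as_set(selected), _as_set(active)
    if not act:
        return float("nan")
    return len(act - sel) / len(act)


def occurrence_frequency(selections: Sequence[Iterable], p: int) -> np.ndarray:
    """Per-gene selection percentage (0-100) over resampling splits."""
    if len(selections) == 0:
        raise ValueError("need at least one selection set")
    counts = np.zeros(p)
    for sel in selections:
        for j in _as_set(sel):
            counts[j] += 1
    return 100.0 * counts / len(selections)


def med_min_max(values) -> tuple[float, float, float]:
    v = np.asarray([x for x in values if not np.isnan(x)], dtype=float)
    if v.size == 0:
        return (float("nan"),) * 3
    return float(np.median(v)), float(v.min()), float(v.max())


def summarize_frequencies(
    frequencies: np.ndarray, active
) -> dict[str, tuple[float, float, float]]:
    """med (min-max) of occurrence frequencies, split into true-positive and
    false-positive genes; genes never selected are excluded."""
    act = _as_set(active)
    ever = np.flatnonzero(frequencies > 0)
    tp = [frequencies[j] for j in ever if j in act]
    fp = [frequencies[j] for j in ever if j not in act]
    return {"tp": med_min_max(tp), "fp": med_min_max(fp)}


def pairwise_intersection(sel_a, sel_b, active) -> tuple[int, float]:
    """(|A∩B|, TP rate among the common genes); the rate is NaN when the
    intersection is empty."""
    a, b, act = _as_set(sel_a), _as_set(sel_b), _as_set(active)
    common = a & b
    if not common:
        return 0, float("nan")
    return len(common), len(common & act) / len(common)


def concordance_index(scores, time, event) -> float:
    """Harrell's C over usable pairs; ties in the score get half credit.

    NaN when no pair is usable (e.g. all subjects censored).
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if scores.shape != time.shape or time.shape != event.shape:
        raise ValueError("scores, time and event must have equal length")
    try:
        c, *_ = concordance_index_censored(event, time, scores)
    except Exception:
        return float("nan")
    return float(c)


def _censoring_km(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the censoring survival G(t).

    Censorings are the 'events'; at tied times, deaths are conventionally
    taken to precede censorings, so censored subjects at t are still at
    risk for G just before t.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    cens = 1 - event[order]
    uniq = np.unique(t)
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d_cens = np.array([int(cens[(t == u)].sum()) for u in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(at_risk > 0, 1.0 - d_cens / at_risk, 1.0)
    return uniq, np.cumprod(factors)


def _eval_step(times: np.ndarray, values: np.ndarray, at: np.ndarray, left: bool = False) -> np.ndarray:
    """Right-continuous step lookup; ``left=True`` gives the left limit."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, at, side=side) - 1
    padded = np.concatenate([[1.0], values])
    return padded[idx + 1]


def integrated_brier(
    survival_predictor: Callable[[np.ndarray, np.ndarray], np.ndarray],
    valid: SurvivalDataset,
    tau: float | None = None,
) -> float:
    """IPCW integrated Brier score on the validation set.

    BS(t) averages, over subjects, the squared error between the predicted
    survival probability S(t|z_i) and the observed status, weighting
    subjects with an observed event before t by 1/G(T_i-) and subjects
    still at risk by 1/G(t), where G is the censoring Kaplan-Meier on the
    validation set.  IBS = (1/tau) * integral of BS over [0, tau] by the
    trapezoid rule on the event-time grid.  When G reaches 0 before tau,
    tau is truncated with a warning.
    """
    time, event = valid.time, valid.event
    if tau is None:
        tau = float(np.quantile(time, 0.8))
    g_times, g_vals = _censoring_km(time, event)
    positive = g_vals > 0
    if not positive.all():
        g_zero_at = g_times[~positive][0]
        if g_zero_at <= tau:
            warnings.warn(
                f"censoring survival reaches 0 at t={g_zero_at:.4g}; truncating "
                f"the IBS horizon from {tau:.4g}",
                stacklevel=2,
            )
            tau = float(g_zero_at) - 1e-12
    grid = np.unique(np.concatenate([[0.0], np.unique(time[event == 1]), [tau]]))
    grid = grid[grid <= tau]
    S = survival_predictor(valid.covariates, grid)  # (n, len(grid))
    g_at_T_left = _eval_step(g_times, g_vals, time, left=True)
    g_at_grid = _eval_step(g_times, g_vals, grid)
    n = valid.n
    bs = np.zeros(len(grid))
    for k, t in enumerate(grid):
        died = (time <= t) & (event == 1)
        alive = time > t
        contrib = np.zeros(n)
        contrib[died] = (S[died, k] ** 2) / g_at_T_left[died]
        contrib[alive] = ((1.0 - S[alive, k]) ** 2) / g_at_grid[k]
        bs[k] = contrib.sum() / n
    if tau <= 0:
        return float("nan")
    return float(np.trapezoid(bs, grid) / tau)


@dataclass
class MetricTable:
    """Aggregated med (min-max) summaries over splits, per method.

    ``counts``/``performance`` are wide DataFrames keyed by method;
    ``intersections`` holds the between-method overlap matrix records.
    """

    counts: pd.DataFrame
    error_rates: pd.DataFrame
    frequencies: pd.DataFrame
    performance: pd.DataFrame
    intersections: pd.DataFrame

    @staticmethod
    def format_mmm(m: float, lo: float, hi: float, digits: int = 0) -> str:
        if np.isnan(m):
            return "."
        if digits == 0:
            return f"{m:.0f} ({lo:.0f}-{hi:.0f})"
        return f"{m:.{digits}g} ({lo:.{digits}g}-{hi:.{digits}g})"


def aggregate_tables(result) -> MetricTable:
    """Aggregate a :class:`~survselect.harness.BenchmarkResult` into the
    benchmark's summary tables (median with min-max envelopes)."""
    active = result.active_set
    methods = result.methods
    records = result.records
    splits = sorted({r.split_id for r in records})

    count_rows, err_rows, freq_rows, perf_rows = [], [], [], []
    for m in methods:
        cells = [r for r in records if r.method == m and r.error is None]
        n_sel = [r.n_selected for r in cells]
        med, lo, hi = med_min_max(n_sel)
        count_rows.append(
            {"method": m, "median": med, "min": lo, "max": hi,
             "formatted": MetricTable.format_mmm(med, lo, hi)}
        )
        fdr_med = med_min_max([r.fdr for r in cells])[0]
        fnr_med = med_min_max([r.fnr for r in cells])[0]
        err_rows.append({"method": m, "fdr": fdr_med, "fnr": fnr_med})
        if cells:
            freqs = occurrence_frequency([r.selected for r in cells], result.p)
            summary = summarize_frequencies(freqs, active)
        else:
            summary = {"tp": (np.nan,) * 3, "fp": (np.nan,) * 3}
        freq_rows.append(
            {
                "method": m,
                "tp_median": summary["tp"][0], "tp_min": summary["tp"][1],
                "tp_max": summary["tp"][2],
                "fp_median": summary["fp"][0], "fp_min": summary["fp"][1],
                "fp_max": summary["fp"][2],
            }
        )
        c_mmm = med_min_max([r.cindex for r in cells])
        i_mmm = med_min_max([r.ibs for r in cells])
        perf_rows.append(
            {"method": m, "cindex_median": c_mmm[0], "cindex_min": c_mmm[1],
             "cindex_max": c_mmm[2], "ibs_median": i_mmm[0], "ibs_min": i_mmm[1],
             "ibs_max": i_mmm[2]}
        )

    inter_rows = []
    by_cell = {(r.split_id, r.method): r for r in records if r.error is None}
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            counts, rates = [], []
            for s in splits:
                ra, rb = by_cell.get((s, ma)), by_cell.get((s, mb))
                if ra is None or rb is None:
                    continue
                c, t = pairwise_intersection(ra.selected, rb.selected, active)
                counts.append(float(c))
                rates.append(t)
            cm, cl, ch = med_min_max(counts)
            tm, tl, th = med_min_max(rates)
            inter_rows.append(
                {"method_a": ma, "method_b": mb,
                 "count_median": cm, "count_min": cl, "count_max": ch,
                 "tp_rate_median": tm, "tp_rate_min": tl, "tp_rate_max": th}
            )

    return MetricTable(
        counts=pd.DataFrame(count_rows),
        error_rates=pd.DataFrame(err_rows),
        frequencies=pd.DataFrame(freq_rows),
        performance=pd.DataFrame(perf_rows),
        intersections=pd.DataFrame(inter_rows),
    )
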