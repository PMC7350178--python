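"""Reading and writing expression + survival tables.

The on-disk layout is a delimited table with a ``time`` column, a 0/1
``status`` column and one column per gene (``g0001`` ... style names).
Simulated datasets round-trip through the same layout with a sidecar JSON
recording the scenario parameters, the seed and the active set.

Real expression matrices are prefiltered on the interquartile range to
drop probes with low variance across samples.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import SimulationScenario, SurvivalDataset

__all__ = [
    "iqr_prefilter",
    "load_expression_survival",
    "write_dataset",
    "read_dataset",
]


def iqr_prefilter(
    expression: np.ndarray, threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Keep columns whose interquartile range strictly exceeds ``threshold``.

    Quantiles use linear interpolation (type 7).  Raises if every column
    would be removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    expression = np.asarray(expression, dtype=float)
    q75, q25 = np.percentile(expression, [75, 25], axis=0)
    kept = np.flatnonzero(q75 - q25 > threshold)
    if kept.size == 0:
        raise ValueError("IQR prefilter removed every column")
    return expression[:, kept], kept


def load_expression_survival(path: str | Path, sep: str = ",") -> SurvivalDataset:
    """Load a delimited expression + survival table.

    Requires ``time`` and ``status`` columns followed by gene columns;
    rejects non-numeric cells (with coordinates), non-positive times and
    status values outside {0, 1}.
    """
    df = pd.read_csv(path, sep=sep)
    for col in ("time", "status"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    gene_cols = [c for c in df.columns if c not in ("time", "status")]
    bad = df[["time", "status", *gene_cols]].apply(
        pd.to_numeric, errors="coerce"
    )
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at row {r}, column {bad.columns[c]!r}"
        )
    time = bad["time"].to_numpy(float)
    status = bad["status"].to_numpy(float)
    if np.any(time <= 0):
        raise ValueError(
            f"non-positive time at row {int(np.flatnonzero(time <= 0)[0])}"
        )
    if not np.isin(status, (0.0, 1.0)).all():
        raise ValueError(
            f"status outside {{0,1}} at row "
            f"{int(np.flatnonzero(~np.isin(status, (0.0, 1.0)))[0])}"
        )
    return SurvivalDataset(
        covariates=bad[gene_cols].to_numpy(float),
        time=time,
        event=status.astype(int),
    )


def _gene_names(p: int) -> list[str]:
    width = max(4, len(str(p)))
    return [f"g{j + 1:0{width}d}" for j in range(p)]


def write_dataset(
    data: SurvivalDataset,
    path: str | Path,
    scenario: SimulationScenario | None = None,
    sep: str = ",",
) -> None:
    """Write ``time,status,g0001...`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(data.covariates, columns=_gene_names(data.p))
    df.insert(0, "status", data.event)
    df.insert(0, "time", data.time)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    sidecar = {
        "active_set": sorted(int(j) for j in data.active_set),
        "beta_true": None
        if data.beta_true is None
        else {int(j): float(data.beta_true[j]) for j in np.flatnonzero(data.beta_true)},
        "p": int(data.p),
        "scenario": None if scenario is None else dataclasses.asdict(scenario),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(path: str | Path, sep: str = ",") -> SurvivalDataset:
    """Inverse of :func:`write_dataset`; restores the ground truth when the
    sidecar JSON is present."""
    path = Path(path)
    data = load_expression_survival(path, sep=sep)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        beta = None
        if sidecar.get("beta_true") is not None:
            beta = np.zeros(sidecar["p"])
            for j, v in sidecar["beta_true"].items():
                beta[int(j)] = v
        data = SurvivalDataset(
            covariates=data.covariates,
            time=data.time,
            event=data.event,
            active_set=frozenset(sidecar.get("active_set", [])),
            beta_true=beta,
        )
    return data
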