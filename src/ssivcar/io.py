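"""Dataset and configuration I/O.

Datasets travel as comma-delimited text with a header (columns y, x1..xd,
u1..um by default); unit identity is positional — row i of the dataset is
row/column i of the weight matrix.  Simulation designs can be loaded from
YAML with schema validation (unknown keys are rejected).
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .simulate import Dataset, SimulationDesign
from .weights import WeightMatrix

__all__ = ["read_dataset", "write_dataset", "load_design", "fit_to_dict"]

_DESIGN_KEYS = {"region", "h", "n_disk", "disk_radius", "knn_k", "alpha",
                "beta", "covariate_law", "sigma2"}


def read_dataset(path, y_col: str = "y", x_cols=None, u_cols=None,
                 w: WeightMatrix | None = None) -> Dataset:
    """Read a delimited dataset; rows in file order define unit indices.

    Column groups default to every ``x*`` / ``u*`` column in file order.
    Raises KeyError naming any missing column and ValueError on non-numeric
    cells or a size mismatch with an attached weight matrix.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if x_cols is None:
        x_cols = [c for c in df.columns if c.startswith("x") and c != y_col]
    if u_cols is None:
        u_cols = [c for c in df.columns if c.startswith("u")]
    for col in [y_col, *x_cols, *u_cols]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"column {col!r} contains non-numeric values")
    n = len(df)
    if w is not None and w.n != n:
        raise ValueError(f"dataset has {n} rows but weight matrix is {w.n}×{w.n}")
    wm = w if w is not None else WeightMatrix(np.zeros((n, n)))
    return Dataset(y=df[y_col].to_numpy(float),
                   x=df[list(x_cols)].to_numpy(float),
                   u=df[list(u_cols)].to_numpy(float), w=wm)


def write_dataset(data: Dataset, path) -> None:
    """Write y, x1..xd, u1..um as CSV (shortest-repr floats round-trip exactly)."""
    cols = {"y": data.y}
    for j in range(data.x.shape[1]):
        cols[f"x{j + 1}"] = data.x[:, j]
    for j in range(data.u.shape[1]):
        cols[f"u{j + 1}"] = data.u[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_design(path) -> SimulationDesign:
    """Load a SimulationDesign from YAML; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _DESIGN_KEYS
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    for key in ("alpha", "beta"):
        if key in raw:
            raw[key] = np.asarray(raw[key], dtype=float)
    return SimulationDesign(**raw)


def fit_to_dict(fitted) -> dict:
    """JSON-serializable summary of an SSIVCAR fit (schema version 1)."""
    return {
        "schema_version": 1,
        "alpha": fitted.alpha.tolist(),
        "beta": fitted.beta.tolist(),
        "delta": fitted.delta.tolist(),
        "knots": fitted.basis.knots.tolist(),
        "spline_order": fitted.basis.order,
        "sigma2": fitted.sigma2,
        "loss": fitted.loss,
        "iterations": fitted.iterations,
        "converged": fitted.converged,
    }
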