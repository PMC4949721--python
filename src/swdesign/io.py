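"""Reading and writing designs, variance configs and curve tables.

Design matrices travel as plain CSV: one row per cluster, comma-separated
0/1 entries, with an optional header row of time labels.  Variance
specifications are flat YAML/JSON key-value files accepting any one of
three equivalent parameterizations: the individual-level components
(eta_C, eta_S, eta_ST, eta_CT, m, sigma1_sq), the cluster-period-mean
model (rho, sigma_sq, T), or the cluster-mean correlation (R) directly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import SteppedDesign, coefficients
from .families import DesignFamilySpec, closed_form_coefficients
from .variance import VarianceComponents, ClusterMeanModel, cluster_mean_model

__all__ = [
    "read_design",
    "write_design",
    "load_variance_config",
    "precision_ratio_curve",
]


def read_design(path, strict: bool = False, name: str | None = None) -> SteppedDesign:
    """Read a K x T design matrix from CSV.

    Entries must be 0 or 1; a first row containing anything else is
    treated as a header of time labels and skipped.  With ``strict=True``
    the rows must be nondecreasing (irreversibility).
    """
    path = Path(path)
    rows = []
    with path.open(newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh)):
            rec = [tok.strip() for tok in rec if tok.strip() != ""]
            if not rec:
                continue
            if lineno == 0 and not all(tok in {"0", "1"} for tok in rec):
                continue  # header row of time labels
            if not all(tok in {"0", "1"} for tok in rec):
                raise ValueError(f"{path}: non-binary entry in row {lineno + 1}")
            rows.append([int(tok) for tok in rec])
    if not rows:
        raise ValueError(f"{path}: no design rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    d = SteppedDesign(np.array(rows, dtype=int), name=name or path.stem)
    if strict and not d.is_monotone():
        raise ValueError(f"{path}: rows violate the irreversibility constraint")
    return d


def write_design(d: SteppedDesign, path, header: bool = False) -> None:
    """Write a design as CSV (optionally with a time-label header row)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow([f"t{j + 1}" for j in range(d.T)])
        for row in d.J:
            w.writerow([int(v) for v in row])


_VC_KEYS = {"eta_C", "eta_S", "eta_ST", "eta_CT", "m"}


def load_variance_config(path):
    """Load a variance specification from flat YAML/JSON.

    Returns a :class:`VarianceComponents`, a :class:`ClusterMeanModel`, or
    a bare CMC float, depending on which of the three parameterizations
    the file uses.  Mixing parameterizations is rejected.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a flat mapping")
    keys = set(cfg)
    has_vc = bool(keys & _VC_KEYS)
    has_rho = "rho" in keys
    has_R = "R" in keys
    if has_vc + has_rho + has_R != 1:
        raise ValueError(f"{path}: supply exactly one of the variance-component, "
                         "(rho, sigma_sq, T), or R parameterizations")
    if has_vc:
        return VarianceComponents(
            eta_C=float(cfg.get("eta_C", 0.0)),
            eta_S=float(cfg.get("eta_S", 0.0)),
            eta_ST=float(cfg.get("eta_ST", 0.0)),
            eta_CT=float(cfg.get("eta_CT", 0.0)),
            m=int(cfg["m"]),
            sigma1_sq=float(cfg.get("sigma1_sq", 1.0)),
        )
    if has_rho:
        return ClusterMeanModel.from_rho(
            T=int(cfg["T"]), rho=float(cfg["rho"]),
            sigma_sq=float(cfg.get("sigma_sq", 1.0)))
    R = float(cfg["R"])
    if not (0 <= R <= 1):
        raise ValueError(f"{path}: R must lie in [0, 1]")
    return R


def precision_ratio_curve(designs: Sequence, R_grid: Sequence) -> pd.DataFrame:
    """Efficiency-vs-CMC table for plotting precision-ratio curves.

    ``designs`` may mix explicit matrices and family specs.  Returns a
    long-format frame with columns (R, design, rel_eff) where rel_eff is
    the precision relative to the cross-over design, 4(a - bR).
    """
    rows = []
    for d in designs:
        if isinstance(d, SteppedDesign):
            c, label = coefficients(d), d.name or "design"
        elif isinstance(d, DesignFamilySpec):
            c, label = closed_form_coefficients(d), d.label
        else:
            raise TypeError("designs must be SteppedDesign or DesignFamilySpec")
        for R in R_grid:
            rows.append({"R": float(R), "design": label,
                         "rel_eff": float(4 * c.precision_factor(R))})
    return pd.DataFrame(rows)
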