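"""CSV/YAML input and output for every pipeline stage.

Viability is always expressed in percent of untreated control at the file
boundary; inhibition fractions are internal only.  Numeric output is fixed
at 6 significant digits so result tables are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bliss import BlissResult, DoseMatrix
from .design import CodedDesign, DoseDesign
from .dose_response import DoseResponseData, DoseResponseSummary, DrugSpec, ScreenDoses
from .errors import InputError
from .qpop import (
    ModelDiagnostics,
    PairScore,
    QuadraticModel,
    ScreenMeasurements,
    SurfaceMap,
    term_names,
)

__all__ = [
    "FMT",
    "read_panel",
    "read_dose_response_table",
    "write_design_table",
    "read_design_table",
    "write_screen_table",
    "read_screen_table",
    "write_summary_table",
    "write_coefficients_table",
    "write_diagnostics_table",
    "write_pair_table",
    "write_surface_table",
    "write_matrix_table",
    "read_matrix_table",
    "write_bliss_summary",
]

FMT = "%.6g"


def _fmt(x: float) -> str:
    return FMT % x


def read_panel(path: str | Path) -> list[DrugSpec]:
    """Drug panel config (YAML or JSON): name, dose unit, optional cmax."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    drugs = raw["drugs"] if isinstance(raw, dict) else raw
    specs = []
    for entry in drugs:
        specs.append(
            DrugSpec(
                name=str(entry["name"]),
                dose_unit=str(entry.get("dose_unit", "uM")),
                cmax=None if entry.get("cmax") in (None, "", "ND") else float(entry["cmax"]),
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise InputError("duplicate drug names in panel")
    return specs


def read_dose_response_table(path: str | Path, panel: Sequence[DrugSpec]) -> dict[str, DoseResponseData]:
    """Long-format monotherapy table: drug, dose, viability, replicate."""
    df = pd.read_csv(path)
    required = {"drug", "dose", "viability", "replicate"}
    if missing := required - set(df.columns):
        raise InputError(f"monotherapy table missing columns: {sorted(missing)}")
    by_name = {s.name: s for s in panel}
    if unknown := set(df["drug"]) - set(by_name):
        raise InputError(f"drugs absent from panel: {sorted(unknown)}")
    out = {}
    for name, sub in df.groupby("drug"):
        out[str(name)] = DoseResponseData(
            drug=by_name[str(name)],
            doses=sub["dose"].to_numpy(float),
            viability=sub["viability"].to_numpy(float),
            replicate=sub["replicate"].to_numpy(int),
        )
    return out


def write_design_table(path: str | Path, design: CodedDesign, doses: DoseDesign | None = None) -> None:
    rows = {"run": np.arange(1, design.n_runs + 1), "part": design.part}
    for c, name in enumerate(design.factor_names):
        rows[name] = design.runs[:, c]
    df = pd.DataFrame(rows)
    if doses is not None:
        for c, name in enumerate(design.factor_names):
            df[f"dose_{name}"] = [_fmt(v) for v in doses.runs[:, c]]
    df.to_csv(path, index=False)


def read_design_table(path: str | Path) -> CodedDesign:
    df = pd.read_csv(path)
    if "run" not in df.columns or "part" not in df.columns:
        raise InputError("design table must have 'run' and 'part' columns")
    factor_cols = [c for c in df.columns if c not in ("run", "part") and not c.startswith("dose_")]
    runs = df[factor_cols].to_numpy()
    if not np.all(np.isin(runs, (-1, 0, 1))):
        raise InputError("design table levels must lie in {-1, 0, +1}")
    return CodedDesign(runs.astype(np.int8), df["part"].to_numpy(str), tuple(factor_cols))


def write_screen_table(path: str | Path, screen: ScreenMeasurements) -> None:
    rows = []
    for r, reps in enumerate(screen.viabilities, start=1):
        for rep, v in enumerate(reps, start=1):
            rows.append((r, rep, _fmt(v)))
    pd.DataFrame(rows, columns=["run", "replicate", "viability"]).to_csv(path, index=False)


def read_screen_table(path: str | Path, design: CodedDesign) -> ScreenMeasurements:
    """Screen results (run, replicate, viability) joined to the design."""
    df = pd.read_csv(path)
    required = {"run", "replicate", "viability"}
    if missing := required - set(df.columns):
        raise InputError(f"screen table missing columns: {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["viability"]):
        bad = df.index[pd.to_numeric(df["viability"], errors="coerce").isna()]
        raise InputError(f"non-numeric viability at table rows {list(bad + 2)}")
    dup = df.duplicated(subset=["run", "replicate"])
    if dup.any():
        raise InputError(f"duplicate (run, replicate) rows at table rows {list(df.index[dup] + 2)}")
    run_ids = set(df["run"])
    expected = set(range(1, design.n_runs + 1))
    if stray := run_ids - expected:
        raise InputError(f"run ids absent from design: {sorted(stray)}")
    if absent := expected - run_ids:
        raise InputError(f"design runs without measurements: {sorted(absent)}")
    viabilities = [
        df.loc[df["run"] == r, "viability"].to_numpy(float) for r in range(1, design.n_runs + 1)
    ]
    return ScreenMeasurements(design=design, viabilities=viabilities)


def write_summary_table(
    path: str | Path,
    summaries: Sequence[DoseResponseSummary],
    screen_doses: Sequence[ScreenDoses | None],
) -> None:
    rows = []
    for summ, sd in zip(summaries, screen_doses):
        ic = {x: summ.ic_values.get(x) for x in (15, 30, 50)}
        rows.append(
            {
                "drug": summ.drug.name,
                "ic15": "ND" if ic[15] is None else _fmt(ic[15]),
                "ic30": "ND" if ic[30] is None else _fmt(ic[30]),
                "ic50": "ND" if ic[50] is None else _fmt(ic[50]),
                "auc": _fmt(summ.auc),
                "r2": _fmt(summ.fit.r2),
                "rule_used": "" if sd is None else sd.rule_used,
                "low": "" if sd is None else _fmt(sd.low),
                "high": "" if sd is None else _fmt(sd.high),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_coefficients_table(path: str | Path, model: QuadraticModel) -> None:
    se = np.sqrt(np.diag(model.coef_cov))
    pd.DataFrame(
        {
            "term": term_names(model.factor_names),
            "coefficient": [_fmt(c) for c in model.coef],
            "std_error": [_fmt(s) for s in se],
        }
    ).to_csv(path, index=False)


def write_diagnostics_table(path: str | Path, diag: ModelDiagnostics) -> None:
    df = pd.DataFrame(
        {
            "term": diag.term_names,
            "partial_F": [_fmt(f) for f in diag.f_stats],
            "p_value": [_fmt(p) for p in diag.p_values],
        }
    )
    df["r2"] = _fmt(diag.r2)
    df["adj_r2"] = _fmt(diag.adj_r2)
    df.to_csv(path, index=False)


def write_pair_table(path: str | Path, banded: Sequence[PairScore]) -> None:
    pd.DataFrame(
        {
            "drug_a": [s.pair[0] for s in banded],
            "drug_b": [s.pair[1] for s in banded],
            "gmean_viability": [_fmt(s.gmean_viability) for s in banded],
            "percentile_band": [s.percentile_band for s in banded],
        }
    ).to_csv(path, index=False)


def write_surface_table(path: str | Path, surf: SurfaceMap) -> None:
    rows = []
    for a, xi in enumerate(surf.axis_i):
        for b, xj in enumerate(surf.axis_j):
            rows.append((_fmt(xi), _fmt(xj), _fmt(surf.surface[a, b])))
    pd.DataFrame(rows, columns=[surf.pair[0], surf.pair[1], "predicted_viability"]).to_csv(
        path, index=False
    )


def write_matrix_table(path: str | Path, matrix: DoseMatrix) -> None:
    rows = []
    for a, da in enumerate(matrix.doses_a):
        for b, db in enumerate(matrix.doses_b):
            rows.append((_fmt(da), _fmt(db), _fmt(matrix.viability[a, b])))
    pd.DataFrame(rows, columns=["dose_a", "dose_b", "viability"]).to_csv(path, index=False)


def read_matrix_table(path: str | Path, drug_a: str = "drug_a", drug_b: str = "drug_b") -> DoseMatrix:
    """Long-format checkerboard (dose_a, dose_b, viability[, replicate])."""
    df = pd.read_csv(path)
    required = {"dose_a", "dose_b", "viability"}
    if missing := required - set(df.columns):
        raise InputError(f"matrix table missing columns: {sorted(missing)}")
    agg = df.groupby(["dose_a", "dose_b"])["viability"].mean().reset_index()
    doses_a = np.sort(agg["dose_a"].unique())
    doses_b = np.sort(agg["dose_b"].unique())
    grid = np.full((doses_a.size, doses_b.size), np.nan)
    ia = {d: i for i, d in enumerate(doses_a)}
    ib = {d: i for i, d in enumerate(doses_b)}
    for _, row in agg.iterrows():
        grid[ia[row["dose_a"]], ib[row["dose_b"]]] = row["viability"]
    return DoseMatrix(drug_a=drug_a, drug_b=drug_b, doses_a=doses_a, doses_b=doses_b, viability=grid)


def write_bliss_summary(path: str | Path, results: Sequence[BlissResult]) -> None:
    pd.DataFrame(
        {
            "drug_a": [r.drug_a for r in results],
            "drug_b": [r.drug_b for r in results],
            "mean_delta": [_fmt(r.mean_delta) for r in results],
            "ci95": [_fmt(r.ci95) for r in results],
            "n_cells": [r.n_cells for r in results],
            "classification": [r.classification for r in results],
        }
    ).to_csv(path, index=False)
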