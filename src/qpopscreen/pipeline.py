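"""End-to-end screen analysis: dose-response -> design -> model -> ranking -> synergy.

``run_qpop_pipeline`` drives every stage from a single validated
:class:`RunConfig`, writes all result tables into the output directory in a
deterministic 6-significant-digit CSV dialect, serialises the config next
to them for provenance, and logs every data-driven decision (dose-rule
fallbacks, non-determined ICx values, prediction clamps).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as qio
from .bliss import analyze_bliss
from .design import build_oacd, map_coded_to_doses, verify_oa_strength, verify_resolution
from .dose_response import select_screen_doses, summarize_dose_response
from .errors import InputError, QPOPError
from .qpop import (
    band_sizes,
    f_test_parameters,
    fit_quadratic,
    response_surface,
    score_two_drug_pairs,
    stratify_percentiles,
)
from .simulate import (
    HillParams,
    SyntheticDrug,
    SyntheticTruth,
    default_truth,
    simulate_dose_matrix,
    simulate_single_drug,
    simulate_screen,
)
from .dose_response import DrugSpec

__all__ = ["RunConfig", "PipelineResult", "run_qpop_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    noise_sd: float = 5.0
    replicates: int = 3
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    panel: list[dict[str, Any]] | None = None      # None -> built-in 10-drug panel
    screen_table: str | None = None                # measured screen CSV, else simulate
    pair_cells: str = "combination"
    surface_grid: int = 21
    checkerboard_doses: int = 5
    mono_doses: int = 9

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(raw) - known:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise InputError("config must set 'outdir'")
        inter = {}
        for entry in raw.get("interactions", []):
            if isinstance(entry, Mapping):
                a, b = entry["pair"]
                inter[(str(a), str(b))] = float(entry["tau"])
            else:
                (a, b), tau = entry
                inter[(str(a), str(b))] = float(tau)
        cfg = cls(**{**{k: v for k, v in raw.items() if k != "interactions"},
                     "interactions": inter})
        if cfg.replicates < 1:
            raise InputError("replicates must be >= 1")
        if cfg.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if cfg.pair_cells not in ("combination", "active"):
            raise InputError(f"pair_cells must be 'combination' or 'active', got {cfg.pair_cells!r}")
        if not (2 <= cfg.checkerboard_doses <= 12):
            raise InputError("checkerboard_doses must be in 2..12")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["interactions"] = [
            {"pair": list(pair), "tau": tau} for pair, tau in self.interactions.items()
        ]
        return d


@dataclass
class PipelineResult:
    """Paths of the tables a pipeline run produced, plus the key objects."""

    outdir: Path
    tables: dict[str, Path]
    truth: SyntheticTruth | None
    banded: list
    bliss: list
    log: list[str]


def _truth_from_config(cfg: RunConfig) -> SyntheticTruth:
    if cfg.panel is None:
        truth = default_truth(seed=cfg.seed, noise_sd=cfg.noise_sd, replicates=cfg.replicates)
    else:
        drugs = []
        for entry in cfg.panel:
            spec = DrugSpec(
                name=str(entry["name"]),
                dose_unit=str(entry.get("dose_unit", "uM")),
                cmax=None if entry.get("cmax") is None else float(entry["cmax"]),
            )
            curve = HillParams(
                top=float(entry.get("top", 100.0)),
                bottom=float(entry.get("bottom", 0.0)),
                hill=float(entry.get("hill", 1.0)),
                ec50=float(entry.get("ec50", 1.0)),
            )
            drugs.append(SyntheticDrug(spec=spec, curve=curve))
        truth = SyntheticTruth(
            drugs=tuple(drugs), noise_sd=cfg.noise_sd, replicates=cfg.replicates, seed=cfg.seed
        )
    names = truth.names
    indexed = {}
    for (a, b), tau in cfg.interactions.items():
        if a not in names or b not in names:
            raise InputError(f"interaction pair ({a}, {b}) names drugs absent from the panel")
        indexed[(names.index(a), names.index(b))] = tau
    return dataclasses.replace(truth, interactions=indexed)


def run_qpop_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the result bundle into ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    tables: dict[str, Path] = {}

    def emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(path, *args)
        tables[name.split(".")[0]] = path
        return path

    stage = "config"
    try:
        truth = _truth_from_config(config)
        (out / "config.json").write_text(json.dumps(config.to_jsonable(), indent=2) + "\n")

        # --- monotherapy dose-response and screening-dose selection -------
        stage = "dose_response"
        summaries, screen_doses = [], []
        for idx, drug in enumerate(truth.drugs):
            lo = drug.curve.ec50 / 100.0
            doses = np.geomspace(lo, drug.curve.ec50 * 100.0, config.mono_doses)
            data = simulate_single_drug(truth, idx, doses)
            summ = summarize_dose_response(data)
            for x, v in summ.ic_values.items():
                if v is None:
                    log.append(f"dose_response: {drug.spec.name} IC{x} not determined")
            sd = select_screen_doses(summ)
            if sd.rule_used == "CMAX_FRACTION":
                log.append(
                    f"dose_response: {drug.spec.name} screen doses from 10%/20% Cmax "
                    f"(IC50 unattainable or above Cmax)"
                )
            summaries.append(summ)
            screen_doses.append(sd)
        emit("dose_response_summary.csv", qio.write_summary_table, summaries, screen_doses)

        # --- composite design --------------------------------------------
        stage = "design"
        design = build_oacd(len(truth.drugs), truth.names)
        res = verify_resolution(design.subset("FF"))
        oa_ok = verify_oa_strength(design.subset("OA")).passed
        log.append(f"design: {design.n_runs} runs, FF resolution {res}, OA strength-2 pass={oa_ok}")
        dose_design = map_coded_to_doses(design, {sd.drug.name: sd for sd in screen_doses})
        emit("design.csv", qio.write_design_table, design, dose_design)

        # --- screen measurements and quadratic model ---------------------
        stage = "screen"
        if config.screen_table is not None:
            screen = qio.read_screen_table(config.screen_table, design)
        else:
            screen = simulate_screen(truth, dose_design)
            emit("screen.csv", qio.write_screen_table, screen)

        stage = "model"
        model = fit_quadratic(screen)
        diag = f_test_parameters(model, screen)
        log.append(f"model: adj_r2={diag.adj_r2:.4f} over {model.residual_df} residual df")
        emit("coefficients.csv", qio.write_coefficients_table, model)
        emit("diagnostics.csv", qio.write_diagnostics_table, diag)

        # --- pair ranking and surfaces ------------------------------------
        stage = "ranking"
        scores = score_two_drug_pairs(model, cells=config.pair_cells)
        banded = stratify_percentiles(scores)
        log.append(f"ranking: band sizes {band_sizes(banded)}")
        emit("pair_bands.csv", qio.write_pair_table, banded)
        top_band = [s for s in banded if s.percentile_band == "75-100"]
        for s in top_band[:3]:
            surf = response_surface(
                model,
                s.indices,
                grid_size=config.surface_grid,
                screen_doses=(screen_doses[s.indices[0]], screen_doses[s.indices[1]]),
            )
            emit(f"surface_{s.pair[0]}_{s.pair[1]}.csv", qio.write_surface_table, surf)

        # --- Bliss validation of the top-ranked pair ----------------------
        stage = "bliss"
        bliss_results = []
        best = banded[0]
        i, j = best.indices
        da = np.concatenate([[0.0], np.geomspace(
            screen_doses[i].low / 4, screen_doses[i].high * 4, config.checkerboard_doses)])
        db = np.concatenate([[0.0], np.geomspace(
            screen_doses[j].low / 4, screen_doses[j].high * 4, config.checkerboard_doses)])
        matrix = simulate_dose_matrix(truth, (i, j), da, db)
        result = analyze_bliss(matrix)
        bliss_results.append(result)
        log.append(
            f"bliss: {result.drug_a}+{result.drug_b} mean delta {result.mean_delta:.3f} "
            f"+/- {result.ci95:.3f} ({result.classification})"
        )
        emit(f"delta_{result.drug_a}_{result.drug_b}.csv", qio.write_matrix_table, matrix)
        emit("bliss_summary.csv", qio.write_bliss_summary, bliss_results)
    except QPOPError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(
        outdir=out,
        tables=tables,
        truth=truth if config.screen_table is None else None,
        banded=banded,
        bliss=bliss_results,
        log=log,
    )
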