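"""Monotherapy dose-response analysis.

Fits four-parameter logistic (4PL) viability curves to percent-of-control
readouts, interpolates ICx doses and normalised AUC, and applies the
screening-dose rule used to set the two nonzero concentrations of each drug
in a combination screen: IC15/IC30 from the fitted curve when the IC50 is
clinically attainable, otherwise 10%/20% of the drug's maximum serum
concentration (Cmax).

The 4PL model on the percent-viability scale is

    v(d) = bottom + (top - bottom) / (1 + (d / ec50)**hill)

with ``hill > 0`` so viability is non-increasing in dose.  ICx values are
defined on the absolute percent-of-control scale (the dose where
``v = 100 - x``); a curve whose plateau never crosses that level yields
"not determined", mirroring how screening panels report drugs that fail to
reach 50% inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, InputError, UnresolvableDoseError

__all__ = [
    "DrugSpec",
    "DoseResponseData",
    "FourPLFit",
    "DoseResponseSummary",
    "ScreenDoses",
    "four_pl",
    "fit_four_pl",
    "interpolate_icx",
    "compute_auc",
    "summarize_dose_response",
    "select_screen_doses",
]

#: minimum number of distinct nonzero doses required for a 4PL fit
MIN_DOSES_FIT = 5


@dataclass(frozen=True)
class DrugSpec:
    """Identity and clinical context of one drug in the panel."""

    name: str
    dose_unit: str = "uM"
    cmax: float | None = None

    def __post_init__(self) -> None:
        if self.cmax is not None and not self.cmax > 0:
            raise InputError(f"cmax for {self.name!r} must be positive, got {self.cmax}")


@dataclass
class DoseResponseData:
    """Replicate-level monotherapy viability measurements for one drug.

    ``doses`` are in the drug's dose unit, ``viability`` in percent of the
    untreated control, and ``replicate`` is an integer replicate index.
    """

    drug: DrugSpec
    doses: np.ndarray
    viability: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if not (self.doses.shape == self.viability.shape == self.replicate.shape):
            raise InputError("doses, viability and replicate must be equal-length")
        if np.any(self.doses < 0):
            raise InputError("doses must be non-negative")
        if not np.all(np.isfinite(self.viability)):
            raise InputError("viabilities must be finite")

    def replicate_means(self, nonzero_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Mean viability per distinct dose, sorted ascending by dose."""
        mask = self.doses > 0 if nonzero_only else np.ones_like(self.doses, dtype=bool)
        doses = np.unique(self.doses[mask])
        means = np.array([self.viability[mask][self.doses[mask] == d].mean() for d in doses])
        return doses, means


@dataclass(frozen=True)
class FourPLFit:
    """Fitted four-parameter logistic curve with convergence diagnostics."""

    top: float
    bottom: float
    hill: float
    ec50: float
    converged: bool
    rss: float
    r2: float

    def predict(self, dose):
        return four_pl(np.asarray(dose, dtype=float), self.top, self.bottom, self.hill, self.ec50)


@dataclass(frozen=True)
class ScreenDoses:
    """The two nonzero screening concentrations chosen for one drug."""

    drug: DrugSpec
    low: float
    high: float
    rule_used: str  # "ICX" or "CMAX_FRACTION"

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise InputError(
                f"screen doses for {self.drug.name!r} must satisfy 0 < low < high, "
                f"got ({self.low}, {self.high})"
            )


@dataclass
class DoseResponseSummary:
    """ICx doses, normalised AUC and the underlying 4PL fit for one drug.

    ``ic_values`` maps an inhibition percentage x to the interpolated dose,
    or ``None`` when the fitted curve never reaches ``100 - x`` percent
    viability ("not determined").
    """

    drug: DrugSpec
    ic_values: dict[int, float | None]
    auc: float
    fit: FourPLFit = field(repr=False)


def four_pl(dose, top: float, bottom: float, hill: float, ec50: float):
    """Four-parameter logistic viability curve, vectorised over dose."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
        out = bottom + (top - bottom) / (1.0 + ratio**hill)
    return np.where(dose > 0, out, float(top))


def _log_four_pl(logd, top, bottom, hill, logec50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logec50)))


def fit_four_pl(
    data: DoseResponseData,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FourPLFit:
    """Fit the 4PL model to replicate-level points by least squares.

    The optimisation runs in log10-dose space, which is where sigmoidal
    viability curves are close to symmetric.  Zero-dose points anchor the
    control scale during simulation but are excluded here (log of zero).
    ``bounds`` may override the default parameter box per parameter name
    (``top``, ``bottom``, ``hill``, ``ec50``).
    """
    mask = data.doses > 0
    doses = data.doses[mask]
    viab = data.viability[mask]
    if np.unique(doses).size < MIN_DOSES_FIT:
        raise InputError(
            f"need at least {MIN_DOSES_FIT} distinct nonzero doses, got {np.unique(doses).size}"
        )
    if np.ptp(data.viability) == 0:
        raise DegenerateFitError("all viabilities identical; no dose effect to fit")

    dmin, dmax = doses.min(), doses.max()
    box = {
        "top": (50.0, 150.0),
        "bottom": (-10.0, 100.0),
        "hill": (0.1, 10.0),
        "ec50": (dmin / 100.0, dmax * 100.0),
    }
    if bounds:
        box.update({k: tuple(v) for k, v in bounds.items()})

    logd = np.log10(doses)
    lo = np.array([box["top"][0], box["bottom"][0], box["hill"][0], np.log10(box["ec50"][0])])
    hi = np.array([box["top"][1], box["bottom"][1], box["hill"][1], np.log10(box["ec50"][1])])

    # data-driven initial guesses; a small hill-slope multistart guards
    # against the flat local optima the logistic is prone to
    order = np.argsort(logd)
    top0 = float(np.clip(viab[order][: max(1, len(viab) // 4)].mean(), *box["top"]))
    bot0 = float(np.clip(viab[order][-max(1, len(viab) // 4):].mean(), *box["bottom"]))
    mid = (top0 + bot0) / 2.0
    ud, um = data.replicate_means()
    ec0 = float(ud[np.argmin(np.abs(um - mid))])

    best = None
    for h0 in (1.0, 0.5, 2.0, 4.0):
        p0 = np.clip(
            [top0, min(bot0, top0 - 1e-6), h0, np.log10(ec0)], lo + 1e-9, hi - 1e-9
        )
        try:
            popt, _ = curve_fit(
                _log_four_pl, logd, viab, p0=p0, bounds=(lo, hi),
                maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_log_four_pl(logd, *popt) - viab) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, False, np.inf, -np.inf)

    popt, rss = best
    top, bottom, hill, logec50 = popt
    # flag fits pinned to the parameter box as non-converged
    at_bound = bool(np.any(np.isclose(popt, lo, atol=1e-8)) or np.any(np.isclose(popt, hi, atol=1e-8)))
    increasing = bottom > top  # dose-stimulated "curve"; report but flag
    if increasing:
        top, bottom = bottom, top
    ec50 = float(10.0**logec50)
    fit = FourPLFit(float(top), float(bottom), float(hill), ec50, not (at_bound or increasing), rss, 0.0)

    # r2 against replicate-mean points, as plate summaries are reported
    pred = fit.predict(ud)
    ss_res = float(np.sum((um - pred) ** 2))
    ss_tot = float(np.sum((um - um.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return FourPLFit(fit.top, fit.bottom, fit.hill, fit.ec50, fit.converged, rss, r2)


def fit_four_pl_per_replicate(data: DoseResponseData, **kwargs) -> list[FourPLFit]:
    """Refit the 4PL independently per replicate (mean +/- SD reporting)."""
    fits = []
    for rep in np.unique(data.replicate):
        mask = data.replicate == rep
        sub = DoseResponseData(data.drug, data.doses[mask], data.viability[mask], data.replicate[mask])
        fits.append(fit_four_pl(sub, **kwargs))
    return fits


def interpolate_icx(fit: FourPLFit, x: float) -> float | None:
    """Dose giving x% inhibition (viability ``100 - x``), or None if unreachable.

    The inversion uses the absolute percent-of-control scale: a curve whose
    asymptotes do not bracket ``100 - x`` has no ICx ("not determined").
    """
    if not (0 < x < 100):
        raise InputError(f"inhibition percent x must lie in (0, 100), got {x}")
    if not fit.converged:
        raise InputError("4PL fit did not converge; ICx interpolation is unreliable")
    target = 100.0 - x
    if not (fit.bottom < target < fit.top):
        return None
    ratio = (fit.top - target) / (target - fit.bottom)
    return float(fit.ec50 * ratio ** (1.0 / fit.hill))


def compute_auc(data: DoseResponseData) -> float:
    """Normalised area under the viability curve over the tested log-dose range.

    Trapezoidal integral of replicate-mean viability/100 against log10(dose),
    divided by the log10-dose span, so a fully resistant drug scores 1 and a
    fully lethal one 0.  Zero-dose points are excluded.
    """
    doses, means = data.replicate_means()
    if doses.size < 2:
        raise InputError("AUC needs at least 2 distinct nonzero doses")
    logd = np.log10(doses)
    return float(np.trapezoid(means / 100.0, logd) / (logd[-1] - logd[0]))


def summarize_dose_response(
    data: DoseResponseData,
    ic_levels: Sequence[int] = (15, 30, 50),
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> DoseResponseSummary:
    """Fit, interpolate the requested ICx levels and compute AUC for one drug."""
    fit = fit_four_pl(data, bounds=bounds)
    ic = {int(x): (interpolate_icx(fit, x) if fit.converged else None) for x in ic_levels}
    return DoseResponseSummary(drug=data.drug, ic_values=ic, auc=compute_auc(data), fit=fit)


def select_screen_doses(summary: DoseResponseSummary, drug: DrugSpec | None = None) -> ScreenDoses:
    """Choose the two screening concentrations for one drug.

    Primary rule (``ICX``): low = IC15, high = IC30, used when IC15/IC30/IC50
    are all determined and the IC50 does not exceed the drug's Cmax (or no
    Cmax is on record).  Fallback rule (``CMAX_FRACTION``): low = 0.1*Cmax,
    high = 0.2*Cmax, keeping the screen within clinically attainable
    exposures when the curve-derived IC50 is unattainable or undefined.
    """
    drug = drug or summary.drug
    ic15 = summary.ic_values.get(15)
    ic30 = summary.ic_values.get(30)
    ic50 = summary.ic_values.get(50)
    icx_ok = all(v is not None for v in (ic15, ic30, ic50))
    if icx_ok and (drug.cmax is None or ic50 <= drug.cmax):
        return ScreenDoses(drug=drug, low=float(ic15), high=float(ic30), rule_used="ICX")
    if drug.cmax is not None:
        return ScreenDoses(
            drug=drug, low=0.1 * drug.cmax, high=0.2 * drug.cmax, rule_used="CMAX_FRACTION"
        )
    raise UnresolvableDoseError(
        f"{drug.name!r}: ICx not determined and no Cmax available to fall back on"
    )
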