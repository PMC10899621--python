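"""Bliss-independence synergy scoring over dose checkerboards.

Viabilities (percent of untreated control) measured on a two-drug dose
matrix are converted to inhibition fractions f = 1 - v / v(0,0), clipped to
[0, 1].  For each combination cell with both doses positive, the Bliss
expectation from the monotherapy anchors is

    E = f_a + f_b - f_a * f_b

and the excess inhibition delta = (f_obs - E) * 100, in percentage points.
The matrix is summarised by the arithmetic mean of delta over all defined
combination cells with a t-based 95% confidence half-width, and classified
as additive when -10 < mean delta < 10, synergistic at >= +10 and
antagonistic at <= -10 (the boundary itself counts as non-additive, since
the additive range is stated strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "DoseMatrix",
    "BlissResult",
    "normalize_viability",
    "bliss_delta_matrix",
    "summarize_bliss",
    "classify_interaction",
    "analyze_bliss",
]

ADDITIVE_LIMIT = 10.0


@dataclass
class DoseMatrix:
    """Replicate-aggregated viability checkerboard for one drug pair.

    ``doses_a`` index the rows and ``doses_b`` the columns; both are
    strictly increasing and include 0, so the (0, 0) cell is the untreated
    control anchor and the zero-dose row/column are the monotherapy
    anchors.  Undefined cells may be NaN.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for doses, name in ((self.doses_a, "doses_a"), (self.doses_b, "doses_b")):
            if np.any(np.diff(doses) <= 0):
                raise InputError(f"{name} must be strictly increasing")
            if doses[0] != 0:
                raise InputError(f"{name} must include dose 0 (control / monotherapy anchor)")
        if self.viability.shape != (self.doses_a.size, self.doses_b.size):
            raise InputError(
                f"viability shape {self.viability.shape} does not match dose grid "
                f"({self.doses_a.size}, {self.doses_b.size})"
            )

    def transpose(self) -> "DoseMatrix":
        return DoseMatrix(self.drug_b, self.drug_a, self.doses_b, self.doses_a, self.viability.T)


@dataclass(frozen=True)
class BlissResult:
    """Per-cell Bliss delta with summary statistics and interaction class."""

    drug_a: str
    drug_b: str
    doses_a: np.ndarray         # positive doses only
    doses_b: np.ndarray
    delta: np.ndarray           # (len(doses_a), len(doses_b)), NaN where undefined
    mean_delta: float
    ci95: float
    classification: str
    n_cells: int


def normalize_viability(matrix: DoseMatrix) -> np.ndarray:
    """Inhibition fractions f = 1 - v / v(0,0), clipped to [0, 1]."""
    control = matrix.viability[0, 0]
    if not np.isfinite(control) or control <= 0:
        raise InputError("control cell (0, 0) missing or non-positive")
    return np.clip(1.0 - matrix.viability / control, 0.0, 1.0)


def bliss_delta_matrix(matrix: DoseMatrix) -> np.ndarray:
    """Per-cell Bliss excess inhibition (percentage points).

    Returns a matrix over the positive-dose cells; a cell whose monotherapy
    anchor (its row or column at dose zero) is undefined is reported NaN
    and excluded from any downstream summary.
    """
    f = normalize_viability(matrix)
    fa = f[1:, 0]               # monotherapy inhibition of drug A at each dose
    fb = f[0, 1:]
    f_obs = f[1:, 1:]
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    delta = (f_obs - expected) * 100.0
    delta = np.where(np.isfinite(fa)[:, None] & np.isfinite(fb)[None, :], delta, np.nan)
    return delta


def summarize_bliss(delta: np.ndarray) -> tuple[float, float]:
    """Mean delta over defined combination cells with t-based 95% half-width."""
    vals = np.asarray(delta, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n < 2:
        raise InputError(f"Bliss summary needs >= 2 defined combination cells, got {n}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    ci95 = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return mean, ci95


def classify_interaction(mean_delta: float) -> str:
    """Interaction class from the mean delta; |delta| = 10 is non-additive."""
    if not np.isfinite(mean_delta):
        raise InputError("mean delta must be finite")
    if mean_delta >= ADDITIVE_LIMIT:
        return "synergistic"
    if mean_delta <= -ADDITIVE_LIMIT:
        return "antagonistic"
    return "additive"


def analyze_bliss(matrix: DoseMatrix) -> BlissResult:
    """Full Bliss analysis of one checkerboard: delta matrix, summary, class."""
    delta = bliss_delta_matrix(matrix)
    mean, ci95 = summarize_bliss(delta)
    return BlissResult(
        drug_a=matrix.drug_a,
        drug_b=matrix.drug_b,
        doses_a=matrix.doses_a[1:],
        doses_b=matrix.doses_b[1:],
        delta=delta,
        mean_delta=mean,
        ci95=ci95,
        classification=classify_interaction(mean),
        n_cells=int(np.isfinite(delta).sum()),
    )
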