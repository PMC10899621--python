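"""Second-order viability modelling and combination ranking.

Screen viabilities measured over an orthogonal-array composite design are
fitted by ordinary least squares to the full quadratic response surface in
coded drug levels x_i in {-1, 0, +1}:

    y = b0 + sum_i bL_i x_i + sum_i bQ_i x_i^2 + sum_{i<j} bI_ij x_i x_j

(66 coefficients for a 10-drug panel).  The fitted surface is projected
over the full 3^k search space, every unordered drug pair is scored by the
geometric mean of its projected viabilities with all other drugs absent,
and pairs are stratified into four effectiveness percentile bands (the
polygonogram).  Per-coefficient partial F tests and the adjusted R^2 serve
as fidelity diagnostics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .design import CodedDesign
from .errors import InputError, InsufficientDataError, SearchSpaceError, SingularDesignError

__all__ = [
    "ScreenMeasurements",
    "QuadraticModel",
    "ModelDiagnostics",
    "ProjectionGrid",
    "PairScore",
    "SurfaceMap",
    "BANDS",
    "term_names",
    "build_model_matrix",
    "fit_quadratic",
    "f_test_parameters",
    "project_search_space",
    "score_two_drug_pairs",
    "stratify_percentiles",
    "band_sizes",
    "response_surface",
]

#: geometric-mean clamp: fitted quadratics can predict <= 0 viability
GMEAN_EPS = 1e-6

#: effectiveness percentile bands, most effective first
BANDS = ("75-100", "50-75", "25-50", "0-25")

#: largest k for which the full 3^k grid is enumerated
MAX_FULL_GRID_K = 12


@dataclass
class ScreenMeasurements:
    """Replicate viabilities (percent of untreated control) per design run."""

    design: CodedDesign
    viabilities: list[np.ndarray]      # one array of replicates per run

    def __post_init__(self) -> None:
        self.viabilities = [np.atleast_1d(np.asarray(v, dtype=float)) for v in self.viabilities]
        if len(self.viabilities) != self.design.n_runs:
            raise InputError(
                f"{len(self.viabilities)} viability records for {self.design.n_runs} design runs"
            )
        for r, v in enumerate(self.viabilities):
            if v.size < 1 or not np.all(np.isfinite(v)):
                raise InputError(f"run {r}: replicate viabilities must be non-empty and finite")

    @property
    def run_means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.viabilities])


@dataclass(frozen=True)
class QuadraticModel:
    """OLS-fitted second-order model on coded levels, with covariance."""

    k: int
    coef: np.ndarray            # (p,) ordered [1, x, x^2, x_i x_j i<j]
    coef_cov: np.ndarray        # (p, p)
    residual_df: int
    sigma2: float
    factor_names: tuple[str, ...]

    @property
    def beta0(self) -> float:
        return float(self.coef[0])

    @property
    def beta_lin(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k]

    @property
    def beta_quad(self) -> np.ndarray:
        return self.coef[1 + self.k : 1 + 2 * self.k]

    @property
    def beta_int(self) -> dict[tuple[int, int], float]:
        pairs = list(itertools.combinations(range(self.k), 2))
        return {p: float(c) for p, c in zip(pairs, self.coef[1 + 2 * self.k :])}

    def predict(self, levels: np.ndarray) -> np.ndarray:
        """Evaluate the surface at arbitrary (possibly fractional) levels."""
        return _expand(np.atleast_2d(np.asarray(levels, dtype=float))) @ self.coef


@dataclass(frozen=True)
class ModelDiagnostics:
    """Per-coefficient partial F tests plus global fit statistics."""

    f_stats: np.ndarray         # (p,)
    p_values: np.ndarray        # (p,)
    r2: float
    adj_r2: float
    exact_fit: bool             # zero residual variance; F reported infinite
    term_names: tuple[str, ...]


@dataclass(frozen=True)
class ProjectionGrid:
    """Predicted viability over an enumerated region of the coded space."""

    combos: np.ndarray          # (m, k) int8
    predicted: np.ndarray       # (m,)
    subset_tag: str | None = None

    def sorted(self) -> "ProjectionGrid":
        order = np.argsort(self.predicted, kind="stable")
        return ProjectionGrid(self.combos[order], self.predicted[order], self.subset_tag)


@dataclass(frozen=True)
class PairScore:
    """Geometric-mean projected viability of one unordered drug pair."""

    pair: tuple[str, str]
    indices: tuple[int, int]
    gmean_viability: float
    percentile_band: str | None = None   # one of BANDS once stratified


@dataclass(frozen=True)
class SurfaceMap:
    """Model surface over a two-drug coded grid, all other drugs absent."""

    pair: tuple[str, str]
    indices: tuple[int, int]
    axis_i: np.ndarray
    axis_j: np.ndarray
    surface: np.ndarray         # (len(axis_i), len(axis_j))
    dose_axis_i: np.ndarray | None = None
    dose_axis_j: np.ndarray | None = None


def term_names(factor_names: Sequence[str]) -> tuple[str, ...]:
    """Column labels in model-matrix order."""
    names = list(factor_names)
    out = ["intercept"]
    out += names
    out += [f"{n}^2" for n in names]
    out += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    return tuple(out)


def _expand(levels: np.ndarray) -> np.ndarray:
    n, k = levels.shape
    cols = [np.ones(n)]
    cols.extend(levels[:, i] for i in range(k))
    cols.extend(levels[:, i] ** 2 for i in range(k))
    cols.extend(levels[:, i] * levels[:, j] for i, j in itertools.combinations(range(k), 2))
    return np.column_stack(cols)


def n_terms(k: int) -> int:
    return 1 + 2 * k + k * (k - 1) // 2


def build_model_matrix(design: CodedDesign | np.ndarray) -> np.ndarray:
    """Second-order model matrix [1, x_i, x_i^2, x_i x_j (i<j)] of a coded design."""
    runs = design.runs if isinstance(design, CodedDesign) else np.asarray(design)
    runs = np.atleast_2d(runs)
    if not np.all(np.isin(runs, (-1, 0, 1))):
        raise InputError("coded design levels must lie in {-1, 0, +1}")
    return _expand(runs.astype(float))


def fit_quadratic(screen: ScreenMeasurements) -> QuadraticModel:
    """OLS fit of the full quadratic model to per-run mean viabilities."""
    X = build_model_matrix(screen.design)
    y = screen.run_means
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"{n} runs cannot identify {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        dependent = [term_names(screen.design.factor_names)[i] for i in sorted(piv[rank:])]
        raise SingularDesignError(
            f"model matrix rank {rank} < {p}; dependent columns: {', '.join(dependent)}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return QuadraticModel(
        k=screen.design.k,
        coef=coef,
        coef_cov=sigma2 * xtx_inv,
        residual_df=df,
        sigma2=sigma2,
        factor_names=screen.design.factor_names,
    )


def f_test_parameters(model: QuadraticModel, screen: ScreenMeasurements) -> ModelDiagnostics:
    """Partial (extra-sum-of-squares) F test for each coefficient.

    Dropping a single column from the full model gives F on (1, residual_df)
    degrees of freedom, identical to the squared t statistic
    ``(beta_j / se_j)^2``, which is how it is computed here.  An exact fit
    (zero residual variance) reports infinite F with p = 0 and is flagged.
    """
    if model.residual_df < 1:
        raise InsufficientDataError("no residual degrees of freedom for F tests")
    y = screen.run_means
    X = build_model_matrix(screen.design)
    pred = X @ model.coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = X.shape
    exact = math.isclose(ss_res, 0.0, abs_tol=1e-12 * max(ss_tot, 1.0))
    se = np.sqrt(np.diag(model.coef_cov))
    if exact:
        f = np.full(p, np.inf)
        pvals = np.zeros(p)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (model.coef / se) ** 2
        pvals = stats.f.sf(f, 1, model.residual_df)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / model.residual_df
    return ModelDiagnostics(
        f_stats=f,
        p_values=pvals,
        r2=r2,
        adj_r2=adj_r2,
        exact_fit=exact,
        term_names=term_names(model.factor_names),
    )


def project_search_space(
    model: QuadraticModel,
    subset: int | None = None,
    chunk: int = 100_000,
) -> ProjectionGrid:
    """Predict viability for every coded combination in the search space.

    ``subset=m`` restricts the enumeration to combinations with exactly m
    drugs active (level 0 or +1) and the rest absent (-1); otherwise the
    full 3^k grid is enumerated (guarded for k <= 12).
    """
    k = model.k
    if subset is None:
        if k > MAX_FULL_GRID_K:
            raise SearchSpaceError(
                f"3^{k} combinations is too large to enumerate; use subset=m"
            )
        combos = np.array(list(itertools.product((-1, 0, 1), repeat=k)), dtype=np.int8)
        tag = None
    else:
        if not (0 <= subset <= k):
            raise InputError(f"subset must be in 0..{k}, got {subset}")
        rows = []
        for active in itertools.combinations(range(k), subset):
            for levels in itertools.product((0, 1), repeat=subset):
                row = np.full(k, -1, dtype=np.int8)
                row[list(active)] = levels
                rows.append(row)
        combos = np.array(rows, dtype=np.int8)
        tag = f"exactly-{subset}-active"
    predicted = np.empty(combos.shape[0])
    for start in range(0, combos.shape[0], chunk):
        block = combos[start : start + chunk]
        predicted[start : start + block.shape[0]] = model.predict(block)
    return ProjectionGrid(combos=combos, predicted=predicted, subset_tag=tag)


def _pair_cells(i: int, j: int, k: int, cells: str) -> np.ndarray:
    if cells == "combination":
        grid = [(0, 0), (0, 1), (1, 0), (1, 1)]
    elif cells == "active":
        grid = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (-1, -1)]
    else:
        raise InputError(f"unknown cell convention {cells!r}")
    rows = np.full((len(grid), k), -1, dtype=np.int8)
    for r, (a, b) in enumerate(grid):
        rows[r, i] = a
        rows[r, j] = b
    return rows


def score_two_drug_pairs(
    model: QuadraticModel,
    cells: Literal["combination", "active"] = "combination",
) -> list[PairScore]:
    """Geometric-mean projected viability for every unordered drug pair.

    The default convention evaluates the four {low, high}^2 combination
    cells of the pair with every other drug absent; ``cells="active"``
    widens this to all eight cells where only that pair is present,
    including single-agent cells.  Predictions are clamped at ``GMEAN_EPS``
    before taking logs.
    """
    if model.k < 2:
        raise InputError("pair scoring needs at least two drugs")
    scores = []
    for i, j in itertools.combinations(range(model.k), 2):
        pred = model.predict(_pair_cells(i, j, model.k, cells))
        pred = np.maximum(pred, GMEAN_EPS)
        gmean = float(np.exp(np.mean(np.log(pred))))
        scores.append(
            PairScore(
                pair=(model.factor_names[i], model.factor_names[j]),
                indices=(i, j),
                gmean_viability=gmean,
            )
        )
    return scores


def stratify_percentiles(scores: Sequence[PairScore]) -> list[PairScore]:
    """Assign each pair to one of four effectiveness percentile bands.

    Pairs are ranked by ascending geometric-mean viability (lower viability
    = more effective), ties broken lexicographically by pair name; rank r
    of n maps to band ``floor(4 * (r - 1) / n)``, so the most-effective
    band takes the 75-100th effectiveness percentile.  For 45 pairs the
    band sizes are 12/11/11/11.
    """
    if len(scores) < 4:
        raise InputError("percentile banding needs at least 4 pairs")
    n = len(scores)
    ranked = sorted(scores, key=lambda s: (s.gmean_viability, s.pair))
    return [
        replace(s, percentile_band=BANDS[min(3, (4 * r) // n)])
        for r, s in enumerate(ranked)
    ]


def band_sizes(banded: Sequence[PairScore]) -> dict[str, int]:
    return {b: sum(1 for s in banded if s.percentile_band == b) for b in BANDS}


def response_surface(
    model: QuadraticModel,
    pair: tuple[int, int] | tuple[str, str],
    grid_size: int = 21,
    screen_doses: tuple | None = None,
) -> SurfaceMap:
    """Model surface over a uniform coded grid [-1, +1]^2 for one pair.

    All other drugs are fixed at -1 (absent).  If ``screen_doses`` (a pair
    of ScreenDoses) is given, dose axes are attached by linear decoding of
    the coded axis between 0 (at -1) and high (at +1).
    """
    if isinstance(pair[0], str):
        try:
            i, j = (model.factor_names.index(p) for p in pair)
        except ValueError as exc:
            raise InputError(str(exc)) from None
    else:
        i, j = pair
    if not (0 <= i < model.k and 0 <= j < model.k and i != j):
        raise InputError(f"pair indices {pair} out of range for k={model.k}")
    axis = np.linspace(-1.0, 1.0, grid_size)
    levels = np.full((grid_size * grid_size, model.k), -1.0)
    gi, gj = np.meshgrid(axis, axis, indexing="ij")
    levels[:, i] = gi.ravel()
    levels[:, j] = gj.ravel()
    surface = model.predict(levels).reshape(grid_size, grid_size)
    dose_i = dose_j = None
    if screen_doses is not None:
        sd_i, sd_j = screen_doses
        dose_i = np.interp(axis, [-1, 0, 1], [0.0, sd_i.low, sd_i.high])
        dose_j = np.interp(axis, [-1, 0, 1], [0.0, sd_j.low, sd_j.high])
    return SurfaceMap(
        pair=(model.factor_names[i], model.factor_names[j]),
        indices=(i, j),
        axis_i=axis,
        axis_j=axis,
        surface=surface,
        dose_axis_i=dose_i,
        dose_axis_j=dose_j,
    )
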