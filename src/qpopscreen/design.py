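"""Orthogonal-array composite designs (OACD) for combination screens.

An OACD stacks a two-level fractional factorial (FF) of resolution >= IV on
top of a three-level strength-2 orthogonal array (OA), giving a run set that
supports a full second-order polynomial model in far fewer wells than a
3^k factorial.  For a 10-drug panel this is the 64-run 2^(10-4) fractional
factorial plus the 27-run L27(3^13) array restricted to 10 columns: 91
combinations in total.

Coded levels follow the screening convention: -1 = drug absent, 0 = low
dose, +1 = high dose.  FF rows use only the {-1, +1} extremes; OA rows use
all three levels.

The FF generators are catalogued as subsets of the basic factors with odd
cardinality >= 3.  Distinct odd generator words guarantee every word of the
defining contrast subgroup has even length >= 4, i.e. resolution >= IV;
the resolution is nonetheless re-verified from the realised run matrix at
construction time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dose_response import ScreenDoses
from .errors import InputError, UnsupportedSizeError

__all__ = [
    "CodedDesign",
    "DoseDesign",
    "OAStrengthReport",
    "build_two_level_ff",
    "build_three_level_oa",
    "build_oacd",
    "verify_resolution",
    "verify_oa_strength",
    "map_coded_to_doses",
]


@dataclass(frozen=True)
class CodedDesign:
    """A run matrix in coded levels {-1, 0, +1} with per-row part labels."""

    runs: np.ndarray                      # (n_runs, k) int8
    part: np.ndarray                      # (n_runs,) "FF" or "OA"
    factor_names: tuple[str, ...]
    generators: tuple[tuple[int, ...], ...] = ()   # FF generator words (1-based basic factors)

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def k(self) -> int:
        return self.runs.shape[1]

    def subset(self, part: str) -> "CodedDesign":
        mask = self.part == part
        return CodedDesign(self.runs[mask], self.part[mask], self.factor_names, self.generators)


@dataclass(frozen=True)
class DoseDesign:
    """A design decoded to actual concentrations."""

    runs: np.ndarray                      # (n_runs, k) float doses
    mapping: tuple[ScreenDoses, ...]      # per-factor decoding used
    design: CodedDesign


@dataclass(frozen=True)
class OAStrengthReport:
    """Outcome of a brute-force strength check on a level matrix."""

    passed: bool
    strength: int
    failures: tuple[tuple[int, int], ...]  # offending column pairs


def _default_names(k: int) -> tuple[str, ...]:
    return tuple(f"drug{i + 1:02d}" for i in range(k))


# number of basic factors q and generator subsets (1-based basic factor
# indices, odd size >= 3) for each supported k; the k=10 entry is the
# 64-run 2^(10-4) member so the composite totals 91 runs
_FF_CATALOG: dict[int, tuple[int, tuple[tuple[int, ...], ...]]] = {
    4: (3, ((1, 2, 3),)),
    5: (4, ((1, 2, 3, 4),)),          # even word of length 5: resolution V
    6: (4, ((1, 2, 3), (2, 3, 4))),
    7: (4, ((1, 2, 3), (2, 3, 4), (1, 3, 4))),
    8: (4, ((2, 3, 4), (1, 3, 4), (1, 2, 3), (1, 2, 4))),
    9: (5, ((1, 2, 3), (1, 4, 5), (2, 3, 4), (3, 4, 5))),
    10: (6, ((1, 2, 3), (1, 4, 5), (2, 4, 6), (3, 5, 6))),
    11: (6, ((1, 2, 3), (1, 4, 5), (2, 4, 6), (3, 5, 6), (2, 3, 5))),
    12: (6, ((1, 2, 3), (1, 4, 5), (2, 4, 6), (3, 5, 6), (2, 3, 5), (1, 3, 6))),
}


def build_two_level_ff(k: int, factor_names: Sequence[str] | None = None) -> CodedDesign:
    """Two-level fractional factorial of resolution >= IV for ``k`` factors.

    Returns the catalogued 2^(k-p) design with levels {-1, +1}; the
    resolution is re-derived from the realised runs and asserted >= IV.
    """
    if k not in _FF_CATALOG:
        raise UnsupportedSizeError(
            f"no fractional-factorial catalogue entry for k={k} (supported: 4..12)"
        )
    q, generators = _FF_CATALOG[k]
    base = np.array(list(itertools.product([-1, 1], repeat=q)), dtype=np.int8)
    cols = [base[:, j] for j in range(q)]
    for word in generators:
        col = np.prod([base[:, j - 1] for j in word], axis=0).astype(np.int8)
        cols.append(col)
    runs = np.column_stack(cols)
    names = tuple(factor_names) if factor_names else _default_names(k)
    if len(names) != k:
        raise InputError(f"expected {k} factor names, got {len(names)}")
    design = CodedDesign(runs, np.full(runs.shape[0], "FF"), names, tuple(generators))
    res = verify_resolution(design)
    if res < 4:
        raise UnsupportedSizeError(f"catalogue entry for k={k} verified at resolution {res} < IV")
    return design


# the 13 column-generating vectors of L27(3^13): one representative per
# projective point of GF(3)^3, basic columns first
_L27_VECTORS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 2, 0), (1, 0, 1), (1, 0, 2),
    (0, 1, 1), (0, 1, 2),
    (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
)


def build_three_level_oa(k: int, factor_names: Sequence[str] | None = None) -> CodedDesign:
    """First ``k`` columns of the L27(3^13) orthogonal array, strength 2.

    Columns are linear forms over GF(3) of the three base-3 digits of the
    run index; levels {0, 1, 2} are recoded to {-1, 0, +1}.
    """
    if not (1 <= k <= 13):
        raise UnsupportedSizeError(f"L27 provides at most 13 columns, requested {k}")
    digits = np.array([(n // 9, (n // 3) % 3, n % 3) for n in range(27)])
    cols = [(digits @ np.array(v)) % 3 for v in _L27_VECTORS[:k]]
    runs = (np.column_stack(cols) - 1).astype(np.int8)
    names = tuple(factor_names) if factor_names else _default_names(k)
    if len(names) != k:
        raise InputError(f"expected {k} factor names, got {len(names)}")
    return CodedDesign(runs, np.full(27, "OA"), names)


def build_oacd(k: int, factor_names: Sequence[str] | None = None) -> CodedDesign:
    """Stack the resolution-IV FF part on the L27 OA part for ``k`` factors."""
    ff = build_two_level_ff(k, factor_names)
    oa = build_three_level_oa(k, factor_names)
    return CodedDesign(
        np.vstack([ff.runs, oa.runs]),
        np.concatenate([ff.part, oa.part]),
        ff.factor_names,
        ff.generators,
    )


def verify_resolution(design: CodedDesign) -> float:
    """Resolution of a two-level design from its defining contrast subgroup.

    Tests every nonempty factor subset for a constant run-wise product; the
    resolution is the smallest such subset size.  A full factorial has no
    defining words and reports ``math.inf`` (unbounded).
    """
    runs = design.runs
    if not np.all(np.isin(runs, (-1, 1))):
        raise InputError("resolution is defined for two-level (+/-1) designs only")
    k = runs.shape[1]
    bits = (runs == 1).astype(np.uint8)
    best = math.inf
    for size in range(1, k + 1):
        if size >= best:
            break
        for subset in itertools.combinations(range(k), size):
            parity = bits[:, subset].sum(axis=1) % 2
            if parity.min() == parity.max():
                best = size
                break
    return best


def verify_oa_strength(design: CodedDesign, strength: int = 2) -> OAStrengthReport:
    """Brute-force strength-2 check: every ordered level pair equally often.

    A single column passes vacuously.  Failures name the offending column
    pairs.  Only ``strength=2`` is implemented (the property the composite
    design relies on).
    """
    if strength != 2:
        raise InputError("only strength-2 verification is implemented")
    runs = design.runs
    n, k = runs.shape
    if n == 0:
        raise InputError("empty design")
    failures = []
    expected = n / 9.0
    for i, j in itertools.combinations(range(k), 2):
        ok = True
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                count = int(np.sum((runs[:, i] == a) & (runs[:, j] == b)))
                if count != expected:
                    ok = False
        if not ok:
            failures.append((i, j))
    return OAStrengthReport(passed=not failures, strength=2, failures=tuple(failures))


def map_coded_to_doses(
    design: CodedDesign, doses: Mapping[str, ScreenDoses] | Sequence[ScreenDoses]
) -> DoseDesign:
    """Decode coded levels to concentrations: -1 -> 0, 0 -> low, +1 -> high."""
    if isinstance(doses, Mapping):
        try:
            per_factor = tuple(doses[name] for name in design.factor_names)
        except KeyError as exc:
            raise InputError(f"no screen doses supplied for factor {exc.args[0]!r}") from None
    else:
        per_factor = tuple(doses)
        if len(per_factor) != design.k:
            raise InputError(f"expected {design.k} dose mappings, got {len(per_factor)}")
    levels = np.array([[0.0, sd.low, sd.high] for sd in per_factor])  # [factor, level+1]
    idx = design.runs.astype(int) + 1
    runs = np.empty(idx.shape, dtype=float)
    for c in range(design.k):
        runs[:, c] = levels[c, idx[:, c]]
    return DoseDesign(runs=runs, mapping=per_factor, design=design)
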