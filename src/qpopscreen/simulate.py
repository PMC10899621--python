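"""Synthetic organoid-screen generator with known ground truth.

Emulates the three data layers the analysis pipeline consumes — monotherapy
dose-response plates, composite-design combination screens, and validation
checkerboards — from an explicit generative truth:

* each drug inhibits via its own 4PL (Hill) curve, so single-agent survival
  is ``s_i(d) = v_i(d) / 100``;
* a combination survives as the Bliss product of single-agent survivals,
  multiplied by ``(1 - tau_ij)`` for every active pair with a planted
  interaction: ``S = prod_i s_i(d_i) * prod_{i<j active} (1 - tau_ij)``.
  With all tau = 0 the generator satisfies Bliss independence exactly;
  tau > 0 plants synergy (excess kill), tau < 0 antagonism;
* measured viability is 100 * S plus Gaussian plate noise on the percent
  scale, truncated to [0, 120] (mild apparent growth stimulation allowed).

All randomness flows from the truth's single seed; repeated calls with the
same truth are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bliss import DoseMatrix
from .design import DoseDesign
from .dose_response import DoseResponseData, DrugSpec, four_pl
from .errors import InputError
from .qpop import ScreenMeasurements

__all__ = [
    "HillParams",
    "SyntheticDrug",
    "SyntheticTruth",
    "default_truth",
    "true_screen_doses",
    "simulate_single_drug",
    "simulate_combination_truth",
    "simulate_screen",
    "simulate_dose_matrix",
]

# per-operation RNG stream salts so the three generators draw independent,
# individually reproducible streams from one seed
_SALT_MONO, _SALT_SCREEN, _SALT_MATRIX = 101, 202, 303


@dataclass(frozen=True)
class HillParams:
    """True 4PL parameters of one drug's viability curve (percent scale)."""

    top: float = 100.0
    bottom: float = 0.0
    hill: float = 1.0
    ec50: float = 1.0

    def viability(self, dose) -> np.ndarray:
        return four_pl(dose, self.top, self.bottom, self.hill, self.ec50)

    def survival(self, dose) -> np.ndarray:
        return self.viability(dose) / 100.0

    def ic(self, x: float) -> float | None:
        """Closed-form dose at x% inhibition on the absolute scale."""
        target = 100.0 - x
        if not (self.bottom < target < self.top):
            return None
        return float(self.ec50 * ((self.top - target) / (target - self.bottom)) ** (1.0 / self.hill))


@dataclass(frozen=True)
class SyntheticDrug:
    spec: DrugSpec
    curve: HillParams


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters for one synthetic screen."""

    drugs: tuple[SyntheticDrug, ...]
    interactions: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sd: float = 5.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.drugs = tuple(self.drugs)
        self.interactions = {
            (min(i, j), max(i, j)): float(t) for (i, j), t in self.interactions.items()
        }
        for (i, j), tau in self.interactions.items():
            if i == j or not (0 <= i < len(self.drugs) and 0 <= j < len(self.drugs)):
                raise InputError(f"interaction pair ({i}, {j}) out of range")
            if not (-0.5 <= tau <= 0.5):
                raise InputError(f"interaction strength tau must lie in [-0.5, 0.5], got {tau}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.spec.name for d in self.drugs)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


#: a realistic 10-drug metastatic-CRC screening panel: five standard-of-care
#: agents, two PRMT inhibitors and three epigenetic drugs.  Cmax (uM) is the
#: maximum clinically attainable serum concentration from published
#: pharmacokinetics (TP-064 has none established); true IC50s (= ec50, as
#: top = 100 and bottom = 0) follow the magnitudes typical of organoid
#: screens with these agents, so half the panel has IC50 > Cmax and screens
#: at the 10%/20% Cmax fallback doses, where it is nearly inert.
#: Leucovorin is a shallow partial inhibitor (bottom 75%): none of its ICx
#: values is determined, which also forces the Cmax fallback.
#: Drugs whose screen doses come from the ICx rule (the pharmacologically
#: active factors) are listed first, assigning them to the basic columns of
#: the fractional factorial — the standard design-of-experiments practice
#: of giving the factors expected to be most active the most cleanly
#: aliased columns.
#: columns: name, cmax, ec50, hill, bottom
PANEL_10 = (
    ("sn38", 0.143, 0.142, 1.3, 0.0),
    ("regorafenib", 8.08, 5.58, 1.5, 0.0),
    ("fluorouracil", 426.0, 53.2, 1.2, 0.0),
    ("tp064", None, 19.5, 1.2, 0.0),
    ("vorinostat", 1.2, 1.19, 1.4, 0.0),
    ("oxaliplatin", 4.96, 25.3, 1.1, 0.0),
    ("leucovorin", 2.86, 5.0, 1.0, 75.0),
    ("pemrametostat", 3.54, 123.8, 0.9, 0.0),
    ("decitabine", 0.323, 113.6, 0.8, 0.0),
    ("entinostat", 0.19, 4.8, 1.0, 0.0),
)


def default_truth(
    seed: int = 0,
    noise_sd: float = 5.0,
    replicates: int = 3,
    interactions: Mapping[tuple[int, int], float] | None = None,
) -> SyntheticTruth:
    """The default 10-drug synthetic screen with the clinically anchored panel.

    The dose-response curves are fixed (the panel defines the biology);
    the seed drives plate noise and any replicate-level variation.
    """
    drugs = tuple(
        SyntheticDrug(
            spec=DrugSpec(name=name, cmax=cmax),
            curve=HillParams(top=100.0, bottom=bottom, hill=hill, ec50=ec50),
        )
        for name, cmax, ec50, hill, bottom in PANEL_10
    )
    return SyntheticTruth(
        drugs=drugs,
        interactions=dict(interactions or {}),
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
    )


def true_screen_doses(truth: SyntheticTruth) -> dict[str, "ScreenDoses"]:
    """Screen doses from the *true* curves via the selection rule.

    Applies the same decision as :func:`~qpopscreen.dose_response.select_screen_doses`
    but on closed-form ICx values, bypassing curve fitting: the generative
    analogue used when simulating a screen directly from a truth object.
    """
    from .dose_response import ScreenDoses

    out: dict[str, ScreenDoses] = {}
    for drug in truth.drugs:
        ic15, ic30, ic50 = (drug.curve.ic(x) for x in (15, 30, 50))
        cmax = drug.spec.cmax
        determined = all(v is not None for v in (ic15, ic30, ic50))
        if determined and (cmax is None or ic50 <= cmax):
            out[drug.spec.name] = ScreenDoses(drug=drug.spec, low=ic15, high=ic30, rule_used="ICX")
        elif cmax is not None:
            out[drug.spec.name] = ScreenDoses(
                drug=drug.spec, low=0.1 * cmax, high=0.2 * cmax, rule_used="CMAX_FRACTION"
            )
        else:
            raise InputError(
                f"{drug.spec.name!r}: no ICx and no Cmax; cannot assign screen doses"
            )
    return out


def _noisy(values: np.ndarray, truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    noisy = values + rng.normal(0.0, truth.noise_sd, size=values.shape) if truth.noise_sd > 0 else values.copy()
    return np.clip(noisy, 0.0, 120.0)


def simulate_single_drug(
    truth: SyntheticTruth,
    drug: int | str,
    doses: Sequence[float],
    rng: np.random.Generator | None = None,
) -> DoseResponseData:
    """Replicate monotherapy viabilities on the drug's true 4PL curve."""
    idx = truth.index(drug) if isinstance(drug, str) else drug
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise InputError("doses must be non-negative")
    rng = rng or truth.rng(_SALT_MONO + idx)
    d_all, v_all, r_all = [], [], []
    clean = truth.drugs[idx].curve.viability(doses)
    for rep in range(truth.replicates):
        d_all.append(doses)
        v_all.append(_noisy(clean, truth, rng))
        r_all.append(np.full(doses.size, rep))
    return DoseResponseData(
        drug=truth.drugs[idx].spec,
        doses=np.concatenate(d_all),
        viability=np.concatenate(v_all),
        replicate=np.concatenate(r_all),
    )


def simulate_combination_truth(truth: SyntheticTruth, dose_vector: Sequence[float]) -> float:
    """Noiseless viability of one combination under the generative model."""
    doses = np.asarray(dose_vector, dtype=float)
    if doses.size != len(truth.drugs):
        raise InputError(f"expected {len(truth.drugs)} doses, got {doses.size}")
    survival = 1.0
    for i, d in enumerate(doses):
        if d > 0:
            survival *= float(truth.drugs[i].curve.survival(d))
    active = np.flatnonzero(doses > 0)
    for (i, j), tau in truth.interactions.items():
        if i in active and j in active:
            survival *= 1.0 - tau
    return float(np.clip(100.0 * survival, 0.0, 120.0))


def simulate_screen(
    truth: SyntheticTruth,
    design: DoseDesign,
    rng: np.random.Generator | None = None,
) -> ScreenMeasurements:
    """Replicate viabilities for every run of a decoded combination design."""
    rng = rng or truth.rng(_SALT_SCREEN)
    clean = np.array([simulate_combination_truth(truth, row) for row in design.runs])
    viabilities = [
        _noisy(np.full(truth.replicates, v), truth, rng) for v in clean
    ]
    return ScreenMeasurements(design=design.design, viabilities=viabilities)


def simulate_dose_matrix(
    truth: SyntheticTruth,
    pair: tuple[int | str, int | str],
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    rng: np.random.Generator | None = None,
) -> DoseMatrix:
    """Replicate-averaged checkerboard for one drug pair.

    With all tau = 0 and zero noise the returned matrix satisfies Bliss
    independence exactly, by construction.
    """
    i = truth.index(pair[0]) if isinstance(pair[0], str) else pair[0]
    j = truth.index(pair[1]) if isinstance(pair[1], str) else pair[1]
    rng = rng or truth.rng(_SALT_MATRIX)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    k = len(truth.drugs)
    clean = np.empty((doses_a.size, doses_b.size))
    for r, da in enumerate(doses_a):
        for c, db in enumerate(doses_b):
            vec = np.zeros(k)
            vec[i], vec[j] = da, db
            clean[r, c] = simulate_combination_truth(truth, vec)
    reps = np.stack([_noisy(clean, truth, rng) for _ in range(truth.replicates)])
    return DoseMatrix(
        drug_a=truth.drugs[i].spec.name,
        drug_b=truth.drugs[j].spec.name,
        doses_a=doses_a,
        doses_b=doses_b,
        viability=reps.mean(axis=0),
    )
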