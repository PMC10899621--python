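# Methods

## Dose-response stage

Monotherapy curves are fitted by unweighted nonlinear least squares to the
four-parameter logistic in log10-dose space, pooling replicate-level
points (an option refits per replicate for mean ± SD reporting). The
parameter box defaults to top ∈ [50, 150] %, bottom ∈ [−10, 100] %,
hill ∈ [0.1, 10], EC50 ∈ [min dose/100, max dose·100]; a fit pinned to the
box, or one that comes back increasing in dose, is flagged non-converged.
A short hill-slope multistart (h₀ ∈ {1, 0.5, 2, 4}) guards against the
flat local optima the logistic is prone to; with tight solver tolerances
this recovers noise-free curves to better than 1e−6 relative error.
R² is reported against replicate-mean points.

ICx is inverted on the absolute percent-of-control scale (v = 100 − x),
not relative to the fitted asymptotes. The absolute convention is what
makes "not determined" possible for shallow curves — a partial inhibitor
whose plateau never crosses 50% viability has no IC50 — which is exactly
how screening panels report such drugs. Zero-dose wells anchor the
control scale but are excluded from log-dose fitting and from the AUC
integral (log 0 is undefined); AUC is the trapezoidal mean of
viability/100 over the tested log10-dose range, so 1 means fully
resistant over the range tested.

Screening doses per drug: (IC15, IC30) when IC15/IC30/IC50 are all
determined and IC50 ≤ C_max (or no C_max is on record); otherwise
(0.1·C_max, 0.2·C_max), keeping the screen within clinically attainable
exposure. If neither rule applies (no ICx and no C_max) the drug is
rejected rather than guessed at.

## Composite design

The OACD stacks a two-level resolution-IV fractional factorial (FF) on
the L27(3^13) orthogonal array. The FF catalogue is built by the
odd-subset construction: with q basic factors, each added factor is the
product of a distinct odd-cardinality (≥3) subset of them. Distinct odd
generator words make every word of the defining contrast subgroup even
with length ≥ 4, i.e. resolution ≥ IV by construction; the resolution is
nonetheless re-derived from the realised runs (brute force over all
factor subsets with constant run-wise product) each time a design is
built, so a catalogue error cannot pass silently. For k = 10 the FF is
the 64-run 2^(10−4) member — not the minimal 32-run resolution-IV design —
so that the composite totals 64 + 27 = 91 runs with no centre point, and
the full 66-column second-order model matrix on it has rank 66 (asserted
in the tests). The L27 columns are linear forms over GF(3) of the three
base-3 digits of the run index, one representative per projective point,
basic columns first; strength 2 is verified by exhaustive pair counting.

Coded levels decode as −1 → dose 0 (absent), 0 → low, +1 → high. FF rows
therefore use only {absent, high}; OA rows use all three levels, which is
where the nine mid-level (low-dose) runs per drug come from.

## Quadratic model, ranking, surfaces

The regression is OLS on per-run replicate means against the coded
levels, never against raw concentrations — the response-surface
convention; dose decoding is presentation-only. Partial F per coefficient
is computed as the squared t statistic (identical to the
extra-sum-of-squares F on (1, n−p) df); an exact fit (zero residual
variance) reports infinite F and is flagged rather than erroring.
Adjusted R² uses 1 − (1 − R²)(n − 1)/(n − p − 1). With 91 runs and 66
coefficients there are 25 residual degrees of freedom — enough for
calibrated inference (the acceptance suite checks test size within
[3, 7]% at α = 0.05 and CI coverage within [90, 99]%), but diagnostics,
not term selection: the full model is always projected.

Pair scores are geometric means of the model's predictions over the four
{low, high}² cells of the pair with all other drugs absent. This is the
minimal reading of "all two-drug combinations" that ranks pairs; an
option (`cells="active"`) widens the set to all eight cells where only
that pair is present, including single-agent cells. Predictions are
clamped at 1e−6 before the log-mean since a fitted quadratic can predict
non-positive viability. Banding is computed on ranks, not score values:
pairs sorted by ascending geometric-mean viability (ties broken
lexicographically by name), rank r of n mapping to band
floor(4(r−1)/n) — for 45 pairs, 12/11/11/11 from most to least effective.

One caveat worth stating explicitly: under −1/0/+1 coding, a bare
interaction coefficient β_ij·x_i·x_j is *not* combination-specific — it
contributes equally at (−1, −1), when neither drug is present.
Combination-localised synergy corresponds to the block
−c(x_i+1)(x_j+1)/4, which spreads over the intercept, two linear terms
and the interaction term. The test suite constructs hand-built models
this way; users inspecting raw coefficients should keep it in mind.

## Bliss scoring

Inhibition fractions are clipped to [0, 1] before the Bliss expectation
(probabilities), so growth stimulation above control counts as zero
inhibition. δ is computed per combination cell from the monotherapy
anchors in the same matrix; cells whose anchor is missing are excluded,
not imputed. The summary is the arithmetic mean over defined combination
cells with a t-interval half-width; replicate-level bootstrap is not
implemented (cells, not replicates, are the unit, matching how synergy
maps are reported). Classification treats |δ| = 10 as non-additive since
the additive range is stated strictly as −10 < δ < 10. No smoothing or
outlier correction is applied, so scores from engines that smooth the
surface will not be bit-identical on the same matrix.

## Synthetic generator

The generator emulates three layers of a real organoid screen: (i)
monotherapy plates — 4PL viability plus Gaussian noise on the percent
scale, truncated to [0, 120] (mild apparent growth stimulation allowed);
(ii) combination screens — survival is the Bliss product of single-agent
survivals times (1 − τ_ij) for every planted pair interaction, τ ∈
[−0.5, 0.5], so τ = 0 is exact Bliss independence by construction and
τ > 0 plants excess kill; (iii) validation checkerboards from the same
generative rule. All randomness derives from one explicit seed through
salted, per-operation streams; identical truth objects reproduce
datasets bit for bit.

Default conditions: noise SD 5 percentage points, 3 replicates — typical
of CellTiter-Glo organoid plates — and a fixed 10-drug metastatic-CRC
panel (five standard-of-care agents, two PRMT inhibitors, three
epigenetic drugs) whose true IC50/C_max magnitudes follow published
values for these agents. That anchoring has a consequence worth keeping:
half the panel has IC50 above C_max (decitabine dramatically so) and
therefore screens at the nearly-inert 10%/20% C_max fallback doses, while
leucovorin is a shallow partial inhibitor (bottom 75%) with no
determined ICx at all. Potent (ICx-rule) drugs are listed first, which
assigns them to the basic FF columns — the usual design-of-experiments
practice of giving the factors expected to be most active the most
cleanly aliased columns.

What the generator does *not* emulate: growth-rate differences between
lines (no GR-style correction), PK/PD or sequential dosing,
tumour-microenvironment effects, plate-position artefacts, and
replicate-level curve heterogeneity. Passing tests therefore demonstrate
that the analysis chain recovers a truth of the assumed structure at
realistic noise, not that the modelling assumptions hold for any given
patient screen.

## Numerical and testing choices

The quadratic model is a viability-scale approximation to the
multiplicative (log-scale) generative truth, so two facts shape the
tests. First, Bliss independence itself induces genuine positive
viability-scale cross terms (+f_a·f_b), so under an all-τ-zero truth the
fitted interaction coefficients are *not* centred at zero; the
calibration test instead checks unbiasedness against the noise-free
projection of the same truth. Second, lack of fit of the product
structure aliases into second-order terms through the resolution-IV
fraction, so planted-pair recovery depends on where the pair sits in the
alias structure. The end-to-end check plants τ = 0.4 on the two leading
basic-column drugs (regorafenib + SN-38, the kind of combination such
screens surface for validation) and recovers it in ≥ 95 of 100 seeded
screens; pairs on heavily aliased columns recover at lower rates — a real
limitation of 91-run screens, not of the implementation.

Problem sizes in the test and acceptance suites — 50 noise-free recovery
draws, 1000 simulations for test size, 200 for CI coverage, 100 seeded
end-to-end screens, 25 Hypothesis/oracle draws for the Bliss properties —
were chosen to give stable Monte-Carlo margins at interactive runtimes
(the whole suite runs in seconds on one core). Output tables print 6
significant digits, which makes pipeline reruns byte-identical and is the
precision asserted by the golden-file determinism test.
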