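# Methods

## The FRAP model

Recovery after photobleaching a short membrane segment is modeled as free
one-dimensional diffusion of the tagged protein along the membrane, with an
immobile complement. The fitted quantity is the post-bleach recovery
re-expressed relative to the first post-bleach value,

    R(t) = (F_rel(t) − F_rel(t0)) / (1 − F_rel(t0)),

which removes the bleach depth and makes mobile fractions comparable across
bleach depths. The default model form is

    R(t) = F_m · (1 − (1 + t/τ_D)^(−1/2)),

with R(0) = 0, R(∞) = F_m and t_1/2 = 3 τ_D. This is the exact recovery of
a Gaussian bleach profile read out with a matched Gaussian weight under 1-D
diffusion: if the bleach removes fluorophores with profile
exp(−x²/2σ²) and the signal is the σ-weighted mean of the concentration,
then the bleached component decays as (1 + Dt/σ²)^(−1/2), i.e. τ_D = σ²/D.
Alternative forms can be slotted into `frap_fit.MODEL_REGISTRY`; all
downstream code (fitting, half time, classification) is model-agnostic.

Assumptions: instantaneous bleach, no exchange between mobile and immobile
pools on the recording timescale, no reaction/binding kinetics (a pure
transport model), 1-D geometry (the membrane is long compared to the
diffusion length).

## Fitting, uncertainty and the `extrapolated` flag

`fit_recovery` runs bounded nonlinear least squares (`scipy`
trust-region-reflective) over (τ_D, F_m) with F_m ∈ [0, 1] and
τ_D ∈ [Δt/10, 10⁴·window], multi-started from 8 log-spaced τ_D values; the
best SSE wins and ties break toward the smaller τ_D for determinism.
Uncertainty comes from a seeded residual bootstrap (percentile intervals,
200 resamples by default in the examples).

A recording of finite length cannot pin down characteristic times much
longer than itself: estimates then slide along a ridge where only
F_m/τ_D (the initial slope) is constrained. The `extrapolated` flag marks
such fits. It is set when the fitted τ_D exceeds the observation window,
and also when a profile F-test (α = 0.05) cannot reject the best fit
constrained to τ_D ≥ window — i.e. the data are consistent with a
characteristic time beyond the recording, so the reported τ_D is an
extrapolation. Both arms of that test include a small nuisance offset
absorbing the noise of the single-sample bleach-depth anchor in the
R-transform; without it, anchor noise masquerades as an instant recovery
component and biases the test. On simulated wild-type-like curves
(τ_D ≈ 3× the window, acquisition noise 0.02) the flag fires on ~98% of
replicates while fast mutant-like regimes are never flagged.

For the same reason, point estimates of (τ_D, F_m) for flagged fits should
not be averaged or compared across genotypes; the flag rate and the modeled
recovery within the window are the meaningful summaries there.

## Normalization conventions

`normalize_curve` uses full-scale normalization
F_rel(t) = (I(t) − B) / (Ī_pre − B) with the pre-bleach mean set to 1.
If an unbleached reference ROI series is supplied, each sample is divided by
the identically-normalized reference, cancelling multiplicative photofading
exactly (the simulator's global exponential fade is removed to ~1e-6).
Static additive structure in the ROI (background tissue signal) cancels in
the R-transform without any correction.

## The synthetic-data generators

The generators emulate the acquisition conditions of embryonic epidermis
FRAP: a bleached membrane segment of ~3 µm, two pre-bleach frames, one
frame every 30 s for 10 min (slow regime) or every 4 s for 3 min (fast
regime), additive Gaussian noise of sd 0.02 on normalized intensity,
optional global photofading and rigid frame-to-frame specimen drift, and an
immobile component so fluorescence never recovers fully.

The image-level simulator evolves the mobile species by an explicit
finite-difference scheme on a 1-px membrane line (sub-stepped so the
stability number D·Δt/Δx² stays ≤ 0.25 — never silent divergence), renders
with a Gaussian PSF, adds a static smooth tissue texture (which both gives
registration 2-D structure to lock onto and cancels in the R-transform),
applies drift on a padded canvas (so drifted frames show real scene content
at their borders, not a constant fill) and adds noise. The bleach is
modeled as a Gaussian profile with σ = bleach_len/2 — physically, the
profile of a focused bleaching spot; mathematically, the profile for which
the default closed form is exact, making the PDE-vs-analytic consistency
check a pure test of the numerics (agreement ≲0.1% sup-norm; a step-profile
bleach with a uniform ROI readout deviates ~5% from the closed form by
shape, not by numerical error). `gaussian_readout` builds the matched
extraction weights, deflating the weight σ by the PSF width so the
effective readout profile equals the bleach profile.

What the generators do not emulate: optics-accurate confocal imaging, 2-D/3-D
diffusion, bleaching during acquisition, a measured bleach-depth profile,
non-rigid tissue deformation, and detector-specific noise (Poisson,
read-out). Passing tests therefore certify the analysis chain against the
stated model of the data, not against every property of real embryo movies.

The dye-image generator pins saturated regions exactly at the detector
ceiling 2^bit_depth − 1 and records the mean of non-saturated ROI pixels as
ground truth. The group-table generator draws i.i.d. Gaussian per-embryo
readouts.

## Statistics

One-way ANOVA uses the standard SSB/SSW decomposition (`scipy.stats`).
The SNK post-hoc orders the group means and steps down from the full range:
a range of r ordered means is significant when
q = (max − min)/√(MSW/n) exceeds the studentized-range quantile
q(α, r, df_within); a non-significant range seals all its sub-ranges.
Quantiles come from the numerical studentized-range distribution
(`scipy.stats.studentized_range`), valid for any df — no lookup tables.
Equal group sizes are assumed; otherwise the harmonic mean n is substituted
and flagged. Under a complete null the first (full-range) gate makes the
family-wise error ≤ α by construction; simulation at k = 4, n = 10
reproduces this (~4.8% at α = 0.05 over 2000 replicates).

Saturation exclusion uses threshold ≥ 2^bit_depth − 1 with a 1-px square
dilation (8-neighborhood) as a bloom margin; only intensity-based exclusion
is implemented — ROIs are supplied, never segmented.

## Sequence comparison

Pairwise global alignment uses BLOSUM62 with affine gap penalties
(open 10, extend 0.1, terminal gaps penalized; Biopython's deterministic
traceback). Percent identity and percent similarity (identical or within
one of the strong groups STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW)
are reported under two denominator conventions — gapped alignment length
and shorter-sequence length; the family percentages quoted by this package
use the shorter-sequence convention. Trees are neighbor-joining on
p-distances (1 − identical/aligned columns) with taxa sorted
lexicographically so the result is input-order invariant. The hydropathy
scan is a 19-residue Kyte–Doolittle window with threshold 1.6, the classic
setting for membrane-spanning helices.

The bundled tetraspan family is a synthetic stand-in
(`synthetic_tetraspan_family`): random sequences carrying the family's
documented divergence structure — founders of 169 aa and 258 aa, a close
paralog at 23% identity, 15% strong-group similarity between the founders,
and ~60%-identity orthologs of each founder. Mismatch residues are chosen
to share no strong group with the original while scoring ≥ 0 in BLOSUM62,
which makes the planted alignment the optimal one, so the de-novo
identity readout recovers the planted 23% exactly. At 15% similarity the
optimal alignment of any pair is inherently non-unique (far below the
twilight zone), so the founder-pair similarity is defined on the generating
alignment, which the generator emits as ground truth; a de-novo re-alignment
of such a pair can legitimately report a different figure, which is exactly
the convention-dependence such percentages carry in practice.

## Numerical choices and degenerate inputs

* Registration: integer offset by masked normalized cross-correlation
  (correct under partial frame overlap), sub-pixel residual by upsampled
  (10×) phase cross-correlation on the overlapping crop; flat frames get
  zero shift and a `degenerate` flag; border pixels filled during
  re-alignment are masked out of extraction.
* Normalization errors on non-physical inputs (background ≥ pre-bleach
  mean); extraction errors when an ROI is empty or fully masked
  ("unquantifiable image" for fully saturated dye ROIs).
* Half time is found by bracketing + Brent root-finding (any registered
  model); for the default model it equals 3 τ_D to ~1e-9.
* ANOVA with all values identical is an error (F undefined); SNK with zero
  within-group variance likewise.
* All simulators are bit-reproducible given (params, seed); every stochastic
  routine takes an explicit seed.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use 100 noisy replicates per FRAP
regime, 2000 null replicates for the SNK family-wise error, a 500×500
grid-search oracle on 5 instances, 50 exhaustively-enumerated alignment
pairs of length ≤ 8, and a 40 µm membrane at 0.05 µm/px for the
PDE-consistency check — sizes chosen so the full evidence chain recomputes
in about a minute on a single CPU.

## Known limitations

* The recovery model is transport-only; binding-dominated FRAP would need a
  reaction-diffusion model (out of scope, registry-extensible).
* The exact normalization and fit equation used by any particular published
  dataset may differ in detail (e.g. a published ~10% recovery at 10 min
  versus ~4% predicted by this model at τ_D = 29.5 min, F_m = 0.29); the
  model registry exists precisely so an alternative closed form can be
  substituted without touching the pipeline.
* Progressive multiple alignment is approximated by pairwise alignments for
  percentages and distances; no bootstrap support values on trees.
* Overexposure exclusion is purely intensity-based; structures that are
  bright but unsaturated are not excluded.
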