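# Methods

This note documents the models, numerical choices and limitations of
hdxkit in one place. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Input model and deconvolution

The cluster CSV carries 15 columns (protein, start, end, sequence,
modification, fragment, max_uptake, mono_mass, state, exposure, file,
charge, rt, intensity, centroid), one row per charge-state observation
of one species in one state/time/file. Exposure times are converted to
seconds on input from a user-declared unit (ms, s, min).

Charge deconvolution: neutral mass per observation is
`centroid·z − z·m_proton` with m_proton = 1.007276466 Da; the
species-level neutral mass is the intensity-weighted mean over charge
states. Uptake is the neutral mass minus the undeuterated reference.
The reference is taken from time-0 control rows when present,
otherwise from the theoretical monoisotopic-mass column with a logged
warning. Negative uptake after subtraction is *retained* by default:
clamping at zero would bias the replicate SDs that feed the global
significance thresholds (a clamp option exists for display purposes).

Replicates are assigned lexicographically by file name within each
(state, time) group, matching the `file_01, file_02, …` convention; an
explicit `file,state,replicate` mapping overrides this and collisions
or unknown files are errors. Missing replicates at individual time
points are tolerated and reported.

## Kinetic model

Uptake is fitted with `D(t) = Σᵢ Nᵢ(1 − exp(−(kᵢ t)^{βᵢ}))`. The
`(k·t)^β` placement is used (the β∈(0,1] constraint makes it the
natural stretched-exponential form); the alternative `k·t^β` placement
is not offered. Bounds: k > 0, β ∈ (0, 1] (inclusive upper bound — a
simple exponential is the β→1 limit), Nᵢ ≥ 0 with ΣNᵢ ≤ N_max. With
one phase after back-exchange correction, N is fixed at N_max.
Replicates are pooled as individual (time, uptake) points.

Phase-count selection maximizes adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1); ties within 1e-12 break toward fewer
phases, so extra phases are never selected when a simpler model
already reproduces the data.

Numerics: multi-start nonlinear least squares. k is initialized at the
geometric mean of 1/t over observed times, β at {0.5, 0.8, 1.0}, N at
the maximum observed uptake; the best residual wins. Single-phase fits
use variable projection (N has a closed-form optimum for fixed (k, β))
and a small box-projected Levenberg–Marquardt over (log₁₀k, β), which
is the hot path when thousands of replicate-combination refits are
needed; multi-phase fits use scipy's bounded trust-region solver with
amplitudes in a nested-fraction parametrization that enforces
ΣN ≤ N_max without explicit constraints. Degenerate constant data get
amplitude ≈ 0.

PCHIP interpolation is available for sparse or non-equilibrium data;
it carries no (k, β) and every downstream operation needing a rate
(empirical adjustment, protection factors) rejects interpolation fits
with a typed error.

## Area under the uptake curve

HDX_Area integrates the fitted curve over the user window, truncated
at the plateau time X_plat — the earliest t with
D(t) ≥ 0.99·ΣN (fraction configurable). Truncation prevents real
differences from being diluted when the window extends far past full
exchange. X_plat is closed-form for one phase and bisected for
multi-phase fits; if the plateau is not reached within 10× the last
observed time, X_plat is undefined and the full window is used.

Integration is linear-time by default (Da·s); a log₁₀-time option
(Da·decades) weights the decades of an HDX time course evenly.
Stretched-exponential areas use 192-point Gauss–Legendre quadrature on
the log-time axis (agrees with the closed form for β = 1 to ~1e-13
relative; adaptive quadrature is used when the window starts at 0);
interpolation areas use the exact antiderivative of the spline.

## Corrections

*Back-exchange*: corrected uptake = measured × N_max/maxD, applied to
uptake values before fitting. maxD comes from an experimental
maximal-deuteration control, or from the species' own fitted plateau
(ΣNᵢ) — the latter only for species that fully exchange within the
window (an error otherwise). maxD beyond N_max by more than 10% is
rejected.

*pH clock*: labeling times are multiplied by `10^(pH_exp − pH_ref)`,
i.e. a state labeled at higher pH has exchanged as if for
proportionally longer on the reference-pH clock (base-catalyzed
regime). Outside pH 5–10 the factor is not applicable and an error is
raised (warning in permissive mode). The sign convention is covered by
a composition unit test (a→b then b→c equals a→c).

*Empirical adjustment*: deliberately phenomenological. The reference
peptide (bradykinin RPPGFSPFR by default — random coil in water, so
its exchange reflects solution chemistry only) is fitted single-phase
per state after back-exchange correction; factors
f_k = k_ref/k_state and f_β = β_ref/β_state are ratios, multiplied
onto every phase of every fit of the protein of interest. β products
above 1 are clipped to 1 with a warning. Applying the factors to the
reference peptide itself collapses all states onto the reference curve
exactly, which is the package's acceptance check. Only single-phase
fits are accepted for calibration.

## Intrinsic rates and protection factors

Per-amide intrinsic rates follow the reference-rate/neighbor-factor
model of Bai et al. (Proteins 1993, with the Connelly 1993 acid-side
update), as embedded in `hdxkit/_bai.py` with provenance notes:
`k_int = k_A F_A [D⁺] + k_B F_B [OD⁻] + k_W F_W`, with log-additive
side-chain λ/ρ factors, N-/C-terminal contributions, Arrhenius
temperature scaling (Ea = 14/17/19 kcal/mol) and pK(D₂O) = 15.05.
Asp/Glu/His factors are blended by Henderson–Hasselbalch ionization at
the working pD (pKa 4.48/4.93/7.42). The pD correction
(pD = pH_read + 0.4) is an explicit flag, off by default. The
N-terminal residue and prolines have no defined rate.

A peptide-level k_int is obtained by *fitting* the simulated
multi-residue curve `Σⱼ(1 − e^{−k_j t})` with one stretched phase
(N fixed at the residue count) on a log-spaced grid spanning the full
dynamic range of the rates — not by averaging rates. Homogeneous rates
give β = 1 exactly; heterogeneity stretches the fit. For c/z
fragments, rates are computed over the covered interval with the
parent peptide providing neighbor context.

Protection factor: P_f = k_int/k_obs (single-phase experimental fits
only). Because both k_int and k_obs come through the same fitting
funnel, recovered P_f on synthetic data with uniform per-residue
protection P is accurate to ~15% over P ∈ {1, 10, 100} (β-stretching
causes a bounded bias); this tolerance is asserted in the tests. The
default reporting cutoff discards species with ln(P_f) ≥ 10, the upper
limit of quantification set by practical labeling windows.

## Hybrid significance testing

Fitted metrics (area, k_obs, P_f) have no direct per-replicate value,
so replicate-level distributions are built by refitting combinations:

1. *per_replicate* — one fit per replicate index (times with a missing
   replicate are skipped for that index);
2. *random* — n fits, each drawing a random replicate per time point;
3. *bootstrap* — s assignments sampled uniformly with replacement from
   all time→replicate assignments are fitted (s defaults to 100;
   bulk validation runs use s = 20 to keep refit counts at desk
   scale), then B = 10 000 bootstrap resamples of the fitted values
   are drawn and each resample's mean recorded.

The *uptake* metric instead reads the experimental points directly.
All random draws are seeded and the seed recorded in outputs.

Global thresholds (value is the minimum |Δ| for significance):

* *sd_ci* — pooled variance = mean of per-species sample variances
  across species and states; threshold `z · sqrt(s²/n_a + s²/n_b)`.
* *pairwise_ci* — all within-state pairwise replicate differences
  pooled across species (pairwise rather than vs-the-mean so outliers
  cannot shift the center, which is zero by construction); a zero-mean
  normal is fitted (sd = sqrt(mean(d²))) and the threshold is z·sd.
  Defined only for distributions 1 and 2.
* *bootstrap_ci* — bootstrap means, centered per species on the
  species' own overall mean, pooled across species; threshold = upper
  bound of the two-sided percentile interval. Centering makes the pool
  a null distribution, so noise-free data give a threshold of exactly
  zero; the uncentered alternative would not. Note the spread of
  resample means scales like σ/√s, so this threshold is systematically
  the smallest of the three — see Limitations.

Thresholds use the normal quantile z (not t): the pooled difference
population is large. "Upper limit of the two-sided CI" means
z₀.₉₇₅·sd at 95% confidence. Optional outlier removal before
thresholding offers mean (3 SD), median (3 scaled MAD), quartiles
(1.5 IQR), iterative Grubbs (α=0.05)
and generalized ESD (α=0.05, at most ⌈10%⌉ outliers); the scaled-MAD
uses the normal-consistency constant 1/(√2·erfc⁻¹(3/2)) ≈ 1.4826.

Welch's t test with Satterthwaite degrees of freedom runs per species
on the replicate-level samples (for bootstrap thresholds the t test
still uses per-replicate fits — testing B resample means against each
other would fabricate sample size). Zero-variance degenerate groups
get p = 1 (equal means) or p = 0 (unequal) by convention, logged.

A difference is significant iff |Δ| **strictly** exceeds the global
threshold **and** p < α. No further multiple-testing correction is
applied; the global threshold is the guard against the
low-replicate-t-test false-positive flood.

## Resolution merging and flattening

Every species' covered interval (c_n: first n residues of its peptide;
z_n: last n) contributes its boundaries as cut points; the atomic
intervals between consecutive cuts within covered stretches are the
finest resolvable segments. This is verified in tests against a
brute-force oracle that groups residues by identical covering-species
sets. Adding species can only refine the partition. Coordinates are
1-based inclusive throughout.

Flattening divides a species' value by its exchangeable-hydrogen count
q (default: the input max_uptake column, mirrored rather than
recomputed to avoid convention drift) and assigns the quotient to each
covered residue. Prolines carry no amide and are fixed at 0; each
species' N-terminal residue likewise (quench-time back-exchange).
Residues covered by several species get the unweighted mean of the
informative contributions — contributions that are structural zeros
for one species (its N-terminal position) do not dilute another
species' measurement. Uncovered residues are missing, never 0.
Consecutive-fragment subtraction (c_{n+1} − c_n) is intentionally not
implemented: differencing adjacent noisy fragments amplifies error
beyond usefulness.

## Synthetic data

The generator simulates independent first-order exchange per residue
(log-uniform rates, 10⁻³–1 s⁻¹ by default, over a 140-residue protein
with ~5% prolines), aggregates over each species' exchangeable
residues, applies a back-exchange loss fraction, converts to two
charge-state centroid rows per species with intensity-weighted
deconvolution in mind, and adds Gaussian replicate noise (σ = 0.05 Da
default; an optional log-normal per-species dispersion models
intensity-dependent precision, off by default). Time-0 control rows
are written noise-free, fixing the undeuterated reference exactly.
Solution states can rescale all rates (salt effects), protect residue
regions by a factor (binding/structure), and carry distinct reference-
peptide (k, β) for calibration tests. The same seed yields
byte-identical CSVs.

What it does **not** emulate: correlated within-replicate drift,
intensity-dependent centroid error per charge state, EX1 bimodality,
peptide carry-over, or deviations of real disordered proteins from the
Bai rate model. Passing tests therefore demonstrate correctness of the
computations, not robustness to every artifact of real data.

Null experiments split one state's replicates into disjoint
pseudo-groups (4 replicates → 3 pairings of two groups of two),
relabeled as pseudo-states.

## Problem sizes used in validation

The automated validation suite runs at desk scale, chosen so the whole
suite stays in the minutes range: null false-positive control at 100
species × 4 replicates × 20 seeded runs with bootstrap s = 20;
parameter recovery at 100 simulations of 7 time points × 3 replicates;
oracle equivalence on 50 random coverage maps; end-to-end effect
detection at 25 peptides over a 100-residue protein.

## Known limitations

* The hybrid criterion does not guarantee zero false positives: with
  ~100 species the expected number of null species passing both
  hurdles at 95%/α=0.05 is of order 0.1–1 per comparison (the t test
  at n = 2–3 only partially suppresses threshold exceedances), and the
  bootstrap threshold's σ/√s scale makes it the most permissive of the
  three. The corresponding acceptance test records this honestly
  rather than relaxing the check; for stringent control use
  sd_ci at 99% with α = 0.01.
* Per-phase amplitudes in multi-phase fits are free (ΣN ≤ N_max), not
  equal fractions; multi-phase (k, β) are not used for protection
  factors.
* The empirical calibration is only meaningful for unstructured
  reference species and has no mechanistic interpretation.
* Site-resolved deconvolution of overlapping peptides into independent
  per-residue estimates (a linear inverse problem) is out of scope;
  flattening averages, it does not deconvolve.
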