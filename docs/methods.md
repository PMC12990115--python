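# Methods

This note documents the models and estimators implemented in `fretloop`,
the defaults chosen where the underlying methods leave parameters open,
and what the synthetic-data generators do and do not emulate.

## Geometric observables

The donor–acceptor end-to-end distance *R*<sub>ee</sub> is the Euclidean
distance between the midpoint of the Trp indole fusion bond and the
midpoint of the Dbo diazo group; the backbone extension
*R*<sub>CαCα</sub> is the distance between the terminal-residue Cα atoms;
*R*<sub>g</sub> is the mass-weighted radius of gyration about the center
of mass. All lengths are nm and times ps; Å-based trajectory formats are
converted on ingestion. Distances are computed on unwrapped coordinates
with no minimum-image convention — the intended systems are short
peptides whose intramolecular distances are far below half the box, so
periodic wrap-around cannot occur for correctly unwrapped input.

The orientational factor is the standard Förster expression

κ² = (cos θ<sub>T</sub> − 3 cos θ<sub>D</sub> cos θ<sub>A</sub>)²,

with θ<sub>D</sub>, θ<sub>A</sub> the angles of the donor and acceptor
transition dipoles to the separation vector and θ<sub>T</sub> the angle
between the dipoles. This form is bounded by [0, 4], is even under
inversion of either dipole (so the sign convention of the two-atom dipole
pairs is immaterial), and averages to 2/3 over isotropic orientations —
all three properties are tested. Transition-dipole directions are
user-specified atom pairs in the label map, since the precise dipole
atoms depend on the chromophore model in use.

## Distance-distribution model

*P*(*R*) = Σ<sub>j=1..3</sub> *A*<sub>j</sub> *R*²
exp[−½((*R* − *r*<sub>j</sub>⁰)/σ<sub>j</sub>)²].

The *R*² prefactor is the polymer end-to-end Jacobian weighting; it skews
each Gaussian toward larger distances, which matters most in the
short-distance contact region probed by quenching. Three components are
the default because flexible Gly/Ser-rich chains show multimodal
distributions whose short-distance shoulder a two-component model visibly
misses; rigid, single-peaked chains are adequately fit with one.

Fitting details (the literature on this model rarely states them; these
are this package's choices): the empirical density is a
Freedman–Diaconis-binned, density-normalized histogram; the summed model
density is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`) with bounds *r*⁰ ∈ (0, max sample],
σ ∈ [10⁻³, sample range]; 10 multi-starts are seeded from histogram peak
detection (peaks padded with sample quantiles when fewer peaks than
components are visible) plus seeded random perturbations, and the
lowest-residual solution is kept. Components are reported sorted by
center (ties by width) so results are deterministic. On 5·10⁴ synthetic
samples the centers and widths are recovered to well within 0.03 nm.

## Free-energy landscape

ΔF(*R*<sub>g</sub>, SASA) = −*RT* ln(*n*/*N*) on a 50 × 50 occupancy grid
spanning the data ranges, with R = 8.314 J mol⁻¹ K⁻¹ and T = 300 K by
default. Cells never visited are masked rather than assigned an infinite
sentinel, so downstream statistics and plotting can ignore them without
special-casing. SASA is consumed as a precomputed input column; the
package does not compute solvent-accessible areas.

## Block averaging

For geometrically spaced block sizes *b* the series is cut into ⌊n/b⌋
full blocks and error(*b*) = std(block means, ddof = 1)/√(n_blocks). The
reported error is read at the largest block size that still leaves at
least four blocks — a plateau proxy appropriate when the correlation
time is well below a quarter of the series length. With only four blocks
at that size the error estimate itself carries χ²₃-level noise, which is
why recovery tests use two-error bands.

## Clustering

Pairwise structural similarity is the positional RMSD after optimal
least-squares superposition (Kabsch via SVD, reflection-corrected, with
the residual computed explicitly after rotation to avoid the catastrophic
cancellation of the E₀ − 2Σs form). Whether the original greedy
neighbor-count method superposed structures is not always stated in
applications; superposition is adopted here as the common practice.
Clustering is the greedy neighbor-count scheme: repeatedly extract the
structure with the most neighbors within the cutoff (itself included) as
a center, assign and remove its neighbors. Ties in neighbor count break
toward the lower structure index, making the partition deterministic;
populations are non-increasing by construction, and cluster ids follow
extraction order. The implementation is verified against an exhaustive
from-scratch reference on 200 random structures. A cutoff of 0.2–0.35 nm
over non-hydrogen atoms is the useful range for short peptides; 0.25 nm
is the pipeline default, with the sampling stride exposed.

## Contact kinetics

Traces are prefiltered with a Savitzky–Golay filter before contact
detection (default window 51 frames, polynomial order 3, both
configurable): the filter removes sub-window noise that would register
spurious sink crossings while preserving the slower crossings carrying
the kinetics. Short traces need a proportionally smaller window — a
51-frame window on a few-hundred-frame trace averages over the
correlation time and erases the crossings. Smoothing is applied to
contact detection only, not to ensemble averages.

A contact event occurs at sample *i* when *R*<sub>ee</sub>(t<sub>i−1</sub>)
> *r* and *R*<sub>ee</sub>(t<sub>i</sub>) ≤ *r*; intercontact intervals
Δ<sub>k</sub> are the times between successive events (between any two
events the trace has necessarily re-escaped above *r*). No additional
debouncing beyond smoothing is applied. The mean first-contact time is

*T* = ⟨Δ²⟩ / (2⟨Δ⟩),

the mean waiting time between contacts of a diffusion-limited process;
by Cauchy–Schwarz *T* ≥ ⟨Δ⟩/2 always. Its standard error is propagated
by the delta method from the joint sampling covariance of (⟨Δ⟩, ⟨Δ²⟩),
treating intervals as independent; it agrees with a bootstrap to ~10% on
exponential intervals.

Simple point-charge water underestimates the real (here: heavy water)
shear viscosity, so simulated diffusive times are rescaled by
f = η<sub>target</sub>/η<sub>model</sub> (Kramers-type linear scaling;
1.10/0.445 mPa·s gives f = 2.472). Uncertainties scale by the same
factor. The sink radius is optimized by grid search over 0.40–0.55 nm in
0.001 nm steps (bracketing the physically expected chromophore contact
range and matching the precision at which optimized radii are reported),
minimizing |T<sup>corr</sup>(r) − T<sub>exp</sub>|/T<sub>exp</sub>; ties
break toward the smaller radius and a minimum at either grid end is
flagged, since the true optimum may lie outside the search window.

## Time-series indicators

**ACF.** Mean-subtracted, variance-normalized autocorrelation via
zero-padded FFT with the biased (divide-by-N) normalization, which keeps
the estimator positive semidefinite. τ₀ is the first zero crossing
(linearly interpolated between lags); τ<sub>corr</sub> is the trapezoidal
integral of C up to τ₀, including the triangle to the interpolated
crossing. When C never crosses zero within the available lags the
integral runs to the maximum lag and the result is flagged.

**Hurst exponent.** Classical rescaled-range analysis: for
logarithmically spaced window sizes n ∈ [16, N/4] (12 sizes by default)
the series is tiled with disjoint windows, R is the range of cumulative
mean-subtracted deviations and S the window standard deviation, and H is
the log–log slope of mean R/S versus n. The estimator carries the known
small upward bias near H = 0.5 (≈ +0.03 at n = 2¹⁶), within the ±0.07
recovery band used in the tests.

**Spectral exponent.** Welch PSD with Hann windows and 50% overlap
(default segment 1024 samples). α is the negative log–log slope fitted
over the upper half of the log-frequency span after excluding the DC bin
and all frequencies above a quarter of Nyquist. The Nyquist-side cap is a
deliberate numerical choice: a sampled diffusive signal has the discrete
spectrum S(f) ∝ 1/(4 sin²(π f dt)), which bends below the continuous f⁻²
law near Nyquist and would bias α low by ~0.3 for Brownian-type signals.
Both the fit fraction and the cap are configurable. Noise classes: white
for α < 0.5, 1/f for 0.5 ≤ α < 1.5, Brownian for α ≥ 1.5 (the regimes are
conventionally quoted as α ≈ 0/1/2; the midpoint boundaries make the
classification total and deterministic).

## NEMD shear viscosity

For a cosine acceleration field a(x) = A cos(kx), k = 2π/L<sub>x</sub>,
the steady Navier–Stokes balance gives a velocity-profile amplitude
V = ρA/(ηk²), hence 1/η = V k²/(ρA) per fitted profile. V is a single
cosine-basis linear projection. With A in nm ps⁻², V in nm ps⁻¹,
L<sub>x</sub> in nm and ρ in kg m⁻³, the conversion factor to SI is 10⁶,
yielding 1/η in m s kg⁻¹ (checked against a hand-converted constant in
the tests). η is the reciprocal of the time-averaged inverse viscosity,
with the block-averaged error of the mean propagated through the
reciprocal. Defaults A = 0.025 nm ps⁻², L<sub>x</sub> = 5.0 nm, and
ρ = 972 kg m⁻³ (a typical simple-point-charge water density) for the
synthetic fixtures.

## Synthetic data: what it does and does not show

Each analysis stage has a generator with the answer built in:

* **Ornstein–Uhlenbeck traces** (exact discretization; defaults mean
  0.9 nm, stationary std 0.2 nm, relaxation time 100 ps — the scale of
  flexible-peptide *R*<sub>ee</sub> fluctuations) stand in for distance
  time series in kinetics and ACF tests. Positivity is enforced by a
  10⁻³ nm floor rather than reflecting dynamics; clipping is rare at the
  default parameterization and the clip count is reported.
* **Fractional Gaussian noise** by circulant-embedding synthesis is exact
  for its target autocovariance and grounds the Hurst tests.
* **Power-law noise** by spectral synthesis with random phases grounds
  the spectral-exponent tests.
* **Mixture samples** by rejection sampling from the R²-weighted density
  ground the distribution fit.
* **Isotropic dipole triplets** give the κ² ensemble average its 2/3
  oracle.
* **The bead chain** (overdamped Euler–Maruyama, stiff harmonic bonds,
  cosine angular stiffness, kT = 1) is deliberately schematic: no
  excluded volume, no solvent, no chemistry. Low stiffness yields a
  flexible coil, high stiffness an extended rod, reproducing the
  flexible-versus-rigid contrast qualitatively. It exists to exercise the
  geometry → clustering → landscape → report path end to end.
* **Velocity profiles** invert the same closed form the analysis solves,
  so the noiseless round trip is exact by construction; the noisy case
  tests the fit-error propagation.

Passing these tests shows the estimators are correct on processes with
the assumed statistical structure (stationary, Gaussian, known spectra).
It does not validate force fields, sampling convergence, or any claim
about real peptides: microsecond trajectories have multi-scale
correlations, nonstationarity from rare transitions, and bounded
distances that none of the generators reproduce quantitatively.

## Problem sizes and numerical tolerances

Recovery tests use 10⁶ orientations for κ², 10⁵ intervals for the MFCT
estimator, 2¹⁶ samples for Hurst/spectral recovery, 5·10⁴ samples for
the mixture fit, 200 structures for the clustering cross-check, and
2·10⁵-point traces for sink-radius optimization — sizes at which the
estimators' sampling error is comfortably below the documented recovery
bands while the whole suite runs in well under a minute. Degenerate
inputs (constant traces, zero variance, zero total mass, fewer than two
intervals, empty histogram cells) raise explicit `ValueError`s rather
than propagating NaNs; equality guards on constant input use exact
range checks (`ptp == 0`) because floating-point means of identical
values need not be exact.

## Known limitations

* The MFCT uncertainty assumes independent intervals; strongly correlated
  successive loop closures would need a blocked or batch-means variant.
* The R/S Hurst estimator is biased upward near H = 0.5 at moderate
  sample sizes; detrended fluctuation analysis or wavelet estimators
  (out of scope) reduce that bias.
* Sink-radius optimization is a grid search; the objective is cheap, so
  no derivative-based refinement is provided and the resolution equals
  the grid step.
* The greedy clustering computes the full O(N²) RMSD matrix; for the
  intended ~10⁴-conformation use case at 100 ps stride this is the
  standard cost, but no neighbor-list acceleration is implemented.
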