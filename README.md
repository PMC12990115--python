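# fretloop

Ensemble, kinetic, and spectral analysis of FRET-labeled peptide
trajectories.

Short flexible peptides — Gly/Ser-rich linkers, polyproline rulers, and
other intrinsically disordered segments — are routinely characterized by
combining time-resolved Förster resonance energy transfer (FRET)
measurements with molecular dynamics simulations. A donor (typically the
Trp indole) and an acceptor (such as the Dbo diazo fluorophore) report on
the end-to-end distance *R*<sub>ee</sub>(*t*) and on intrachain contact
formation. `fretloop` implements the full downstream analysis of such
trajectories for computational biophysicists who want to compare
simulated ensembles and kinetics with FRET observables:

* **Geometry** — per-frame *R*<sub>ee</sub> (indole-bond midpoint to
  diazo-group midpoint), terminal Cα–Cα distance, mass-weighted
  *R*<sub>g</sub>, and the orientational factor
  κ² = (cos θ<sub>T</sub> − 3 cos θ<sub>D</sub> cos θ<sub>A</sub>)²,
  whose isotropic dynamic average is 2/3.
* **Distance distributions** — fits of
  *P*(*R*) = Σ<sub>j</sub> *A*<sub>j</sub> *R*² exp[−½((*R* −
  *r*<sub>j</sub>⁰)/σ<sub>j</sub>)²], the three-component skewed-Gaussian
  model standard for flexible-chain FRET distributions.
* **Landscapes and clustering** — Boltzmann inversion
  ΔF = −*RT* ln(*n*/*N*) over an (*R*<sub>g</sub>, SASA) grid, and greedy
  RMSD neighbor-count (GROMOS-style) clustering with cumulative-cluster
  convergence curves.
* **Looping kinetics** — first-contact-time detection (downward crossings
  of a sink radius *r* on Savitzky–Golay-smoothed traces), the mean
  first-contact time *T* = ⟨Δ²⟩/(2⟨Δ⟩) over intercontact intervals Δ, a
  Kramers-type viscosity correction
  *T*<sup>corr</sup> = *T* · η<sub>target</sub>/η<sub>model</sub>, and
  sink-radius optimization against experimental MFCTs.
* **Time-series indicators** — FFT autocorrelation with integrated
  correlation time τ<sub>corr</sub> = ∫₀^τ₀ C(τ) dτ, the Hurst exponent
  from rescaled-range analysis R(n)/S(n) = c·n^H, Welch power spectra
  with power-law exponent α (S(f) ∝ f^−α, classified white / 1/f /
  Brownian), and zero-lag cross-correlations.
* **NEMD viscosity** — extraction of the solvent shear viscosity from
  periodic cosine-perturbation velocity profiles,
  1/η = *V k*²/(ρ*A*), with block-averaged uncertainties.
* **Synthetic data** — generators with known ground truth
  (Ornstein–Uhlenbeck traces, fractional Gaussian noise, 1/f^α noise,
  mixture samples, isotropic dipoles, a toy bead chain, cosine velocity
  profiles) so every stage is testable without microsecond MD output.

## Worked example

Generate a synthetic end-to-end distance trace (an Ornstein–Uhlenbeck
process, mean 0.9 nm, 200 000 samples at 1 ps) and analyze its looping
kinetics against a target MFCT of 5.28 ns with the D₂O/SPC viscosity
pair:

```sh
fretloop --seed 3 synth --kind ou_trace --n 200000 --out ree.csv
fretloop kinetics ree.csv --optimize 5.28
```

```json
{
  "T_md_corr_ns": 5.279276596495625,
  "T_md_ns": 2.1357073504005024,
  "at_boundary": false,
  "factor": 2.471910112359551,
  "percent_error": 0.013700823946505628,
  "r_opt_nm": 0.5,
  "sigma_corr_ns": 0.5131983412415732
}
```

The sink radius that best reproduces the target is 0.50 nm; at that
radius the uncorrected simulated MFCT is 2.14 ns, which the viscosity
factor f = η_D₂O/η_SPC = 1.10/0.445 = 2.472 rescales to 5.28 ns, 0.014%
from the target; the propagated statistical uncertainty is 0.51 ns. The
same trace's dynamical indicators:

```sh
fretloop spectra ree.csv --segment-length 2048
```

```json
{
  "alpha": 1.9830538148174144,
  "hurst": 0.795258412168147,
  "noise_class": "brownian",
  "tau0_ps": 388.4452252304641,
  "tau_corr_ps": 92.91807339103937
}
```

An integrated correlation time of 93 ps (the generator's relaxation time
is 100 ps), strong persistence (H ≈ 0.8), and an α ≈ 2 Brownian spectrum,
as expected for diffusive distance fluctuations sampled well below their
correlation time.

The same operations are available as library calls
(`fretloop.detect_contacts`, `fretloop.mfct`,
`fretloop.optimize_sink_radius`, `fretloop.hurst_rs`, ...); the
`fretloop report` subcommand runs the whole per-peptide pipeline from a
JSON config and emits a single report with structure, distribution-fit,
clustering, kinetics, and time-series blocks.

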