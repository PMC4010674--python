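# Methods

## Model

The generative model couples a four-population canonical microcircuit —
spiny stellate (1), inhibitory interneurons (2), deep pyramidal (3),
superficial pyramidal (4) — across a periodic one-dimensional cortical
patch of length ℓ = 25 mm.  Depolarisation obeys the delayed integro-
differential field equation given in the README; the package works
throughout with its linearisation about the zero fixed point, so all
spectral predictions are exact for the linearised dynamics and
approximations for the full sigmoid system.

Conventions.  Internal units are milliseconds and millimetres; ω = 2πf/1000
rad/ms for f in Hz, wavenumbers k_n = 2πn/ℓ rad/mm.  The Fourier convention
is e^{+iωt} synthesis, under which time derivatives map to +iω and the
delayed-kernel transform is D(k, ω) = α(c + iυω)/((c + iυω)² + k²); the
conjugate convention would flip every sign of iω coherently and leave all
spectra unchanged.  Hermitian symmetry T(k, −ω) = T(k, ω)* holds by
construction and guarantees real non-negative predicted auto-spectra.

Two independent routes compute T(k, ω): a direct 4×4 complex solve of the
linearised system, and a closed-form elimination

    P_a = κ_a² + 2iωκ_a − ω² + κ_a γ D_aa,      R_ab = γ²κ_aκ_b D_ab D_ba,
    W  = P₄(P₁P₂P₃ + P₁R₂₃ + P₃R₁₂) + R₁₄(P₂P₃ + R₂₃),
    T₁ = κ₁P₄(P₂P₃+R₂₃)/W,   T₂ = κ₁κ₂γD₂₁P₃P₄/W,
    T₃ = −κ₁κ₂κ₃γ²D₂₁D₃₂P₄/W,  T₄ = κ₁κ₄γD₄₁(P₂P₃+R₂₃)/W,

derived by Cramer elimination from the same operator.  The matrix route is
the reference; the vectorised closed form is the production path, and their
equivalence (≤10⁻⁸ relative over ±3 prior SD) is a standing test.

## Sign pattern and priors

The connectivity kernel's sign pattern is structural: self-connections are
inhibitory, projections from the interneuron population are inhibitory, the
superficial-pyramidal → spiny-stellate edge is inhibitory-signed, and the
remaining edges are excitatory.  The ten coupling strengths α_ab and decays
c_ab are stored positive.

Prior means: κ = (1/2, 1/35, 1/35, 1/2) ms⁻¹; c_ab = 0.6 mm⁻¹ between
populations and 2 mm⁻¹ for self-connections; sigmoid (r, η) = (0.54, 0);
conduction speed 0.3 m/s; electrode centres near the middle of the patch at
ℓ/8 spacing, lead-field dispersions ℓ/16; population mixing weights
Q = (0.2, 0, 0.2, 0.6).  The published table of connection amplitudes lists
ten parameter names against eight printed values with an uncertain scale
annotation; this package maps the printed values in order
(α₁₁, α₁₄, α₁₂, α₂₂, α₂₁, α₂₃, α₃₃, α₄₁) = (108, 45, 1.89, 162, 18, 4536,
18, 9) and recycles the final pair for (α₃₂, α₄₄) = (18, 9).  The scale was
fixed by a physical constraint rather than the ambiguous annotation: at
these values the prior-mean transfer function |T₄(0, ω)|² has an interior
resonance near 76 Hz, whereas a 10³-fold larger scale is overdamped with no
spectral peak anywhere in the band of interest.  The mapping is exposed in
the configuration schema and archived with every run.  The large printed
α₂₃ is internally consistent: loop gains enter as γ²κ_aκ_b α_ab α_ba, and
κ₂κ₃ = 1/1225 brings the slow interneuron/deep loop to the same order as
the fast stellate/superficial loop.

All scale parameters are optimised as log-normal multipliers of their prior
means, θ = θ̄ e^ϑ with ϑ ~ N(0, σ²): σ² = 1/16 for couplings, decays,
dispersions, mixing weights and noise amplitudes; 1/64 for rate constants,
conduction speed and electrode centres (tighter, since these are strongly
informed by physiology and geometry).  η (prior mean 0) and the interneuron
mixing weight q₂ = 0 are fixed.  Contrast sensitivities β are additive free
parameters with N(0, 1/16) priors.

## Observation model

Each electrode integrates the patch through a unit-mass Gaussian lead field
of width φ; its Fourier factor is e^{−2π²φ²κ²} in cyclic wavenumber κ
(equivalently e^{−φ²k²/2} on the angular grid).  Bipolar sites difference
two electrodes, which removes the spatially uniform k = 0 mode exactly —
the montage's common-mode rejection.  Input noise is spatially white with
per-mode one-sided density g_u(f) = α_u + β_u/f (the coloured exponent is
configurable); channel noise has the same white-plus-1/f form per site on
the auto-spectra plus an optional common component on every entry, a
superset that nests both readings of where channel noise enters.
Predictions sum 2N+1 wavenumbers; N = 32 by default, and doubling N changes
predictions by < 10⁻⁶ relative (a standing test), because the lead-field
factor suppresses high modes.

The neural-mass restriction evaluates the same microcircuit at k = 0 only.
Because the bipolar lead-field difference vanishes identically at k = 0,
the point-source variant replaces the spatial observation model with one
free log-normal gain per site and fixes all spatial parameters (decays,
conduction speed, centres, dispersions) at their prior means; it has
strictly fewer free parameters than the field variant and is invariant to
electrode centres.

## Dynamical stability versus spectral finiteness

The analytic CSD formula evaluates the resolvent on the real frequency
axis and is finite whether or not the delayed dynamical system is stable.
These are different properties: a Nyquist winding-number screen
(`stability_screen`) counts unstable characteristic roots per spatial mode.
At the prior means the dynamics are supercritical (winding 4): with
κ₂ = κ₃ = 1/35 ms⁻¹, any appreciable interneuron↔deep coupling exceeds the
loop-gain bound ≈ 4κ⁴, and the fast stellate↔superficial loop at the prior
amplitudes is also ≈2.3× supercritical.  Spectral fitting is unaffected —
the model is used as a stationary filter parameterisation, as in spectral
DCM practice — but time-domain simulation requires a stable configuration.
The documented **simulation reference configuration** (prior means with
α₁₁, α₄₄ × 0.3, α₁₄, α₄₁ × 0.4 and the six slow-population couplings
× 10⁻⁴) has winding 0 at every mode and an interior |T₄(0, ω)|² resonance
near 48 Hz; all simulator-versus-analytic comparisons run there.

## Time-domain simulator

The field equation is integrated on a 128-point ring (dx ≈ 0.195 mm).  Per
population, the homogeneous critically damped operator is advanced with its
exact 2×2 matrix exponential; coupling and noise are held constant within a
step.  Kernel weights are exact cell integrals of the exponential kernel
(pointwise sampling biases the cusped c = 2 mm⁻¹ self-kernels by a few
percent).  Conduction delays |x−x′|υ are realised by fractional-delay
linear interpolation into a circular history buffer, with the half-step
offset that makes the piecewise-constant forcing a midpoint rule; with
these choices dt = 0.25 ms and dt = 0.1 ms give statistically identical
spectra, and dt = 0.25 ms is the working default for long runs (the
simulate API default remains 0.1 ms for conservative exploratory use).
Spatially and temporally white input drives the stellate population with
per-(site, step) variance σ² = g_u X/(2 dt) so that every spatial mode
carries one-sided density g_u, matching the analytic input convention.
Output is decimated to 1 kHz; sensor series apply the identical lead-field/
montage model in mode space.  A nonlinear mode substitutes the
baseline-subtracted sigmoid for the linear gain and exists for exploration;
all oracle comparisons use the linearised mode, which the analytic model
describes exactly.  The first second of every run is discarded as burn-in.

Agreement statistics.  Welch cross-spectra (Hann taper, 500 ms segments,
50 % overlap) of simulated site series are compared with `predict_csd` over
20–90 Hz.  The full-matrix relative L2 error has an irreducible sampling
floor ≈ √(Σ G_ii G_jj / n_eff)/‖G‖, ≈ 5.8 % for 512 × 500 ms epochs at the
reference configuration's inter-site coherence; the standing validation
uses 1024 epochs (floor ≈ 4 %, measured 0.040, with auto-spectra agreeing
to 0.025).  This is an estimator-variance property, not a model bias: the
bias component, measured by seed-averaging, is below 1 %.

## Synthetic study design

The generator emulates the nine-contrast experiment: conditions 0, 5, 10,
16, 23, 32, 44, 60, 82 % contrast (covariate u = percent/100; a log-
intensity coding is available), four bipolar sites from eight electrodes on
the 25 mm patch, spectra on 24 frequencies spanning 4–90 Hz for inversion
studies.  Finite-epoch estimation noise is emulated by drawing each
site×site matrix from a complex Wishart distribution with dof = the epoch
count — this preserves Hermitian positive semidefiniteness and matches
averaged-periodogram statistics, unlike additive Gaussian noise.

The default ground truth sets base deviations α₁₄, α₄₁ × e^{−0.85},
α₄₄ × e^{−0.15}, c₄₁ × e^{0.1} (placing the zero-contrast gamma peak at
48 Hz) and sensitivities β(α₁₄) = β(α₄₁) = +0.5, β(α₄₄) = −0.5.  The
pattern concentrates contrast effects on the connections to and from the
superficial pyramidal population, with disinhibition of its self-
connection; its net forward effect is a monotone 48 → 57 Hz peak shift
with rising gamma power across the contrast range.  A single negative
α₄₄ sensitivity alone would raise power but lower the peak frequency, since
α₄₄ enters P₄ as a positive restoring term — the frequency shift requires
the accompanying coupling increase, which is why the generating pattern
modulates all three parameters.

What passing tests show — and do not.  The synthetic data share the real
data's dimensionality, spectral support, Hermitian/Wishart sampling
structure and contrast design, but they are generated by the model being
fitted: recovery results demonstrate internal consistency and
identifiability at study scale, not robustness to model mismatch,
non-stationarity, line noise or artefacts, which real ECoG would add.

## Inversion

Variational Laplace with a Gaussian fixed-form posterior on the packed
log-parameters.  Jacobians by central differences (step 10⁻³ on the log
scale); Levenberg–Marquardt damping (initial 1, ×4 on rejection, ×½ on
acceptance); observation precision e^λ shared across the vectorised real/
imaginary data with a Gaussian hyperprior on λ (mean matched to the sample
variance of the data vector, variance 1/16) updated by Newton steps inside
each iteration; convergence after four consecutive accepted improvements
below 0.01 nats or 128 iterations (the recovery studies cap at 32–48).
Accepted iterations never decrease F, which doubles as the log-evidence
approximation for fixed-effects model comparison: one joint fit across all
conditions per model, the joint likelihood factorising over conditions.

Recovery studies (desk-scale sizes, stated here as the package's own
choices): 24 frequencies, 16 wavenumber pairs, and a compact free set — the
ten couplings, c₄₁, input/channel noise amplitudes, plus each model's
sensitivities (site gains for the mass variant).  Parameter recovery uses
256 epochs and ten seeds; model recovery among {G, L, E, null} uses 512
epochs (the G-versus-E contrast is intrinsically weak because α₄₄ and c₄₄
act nearly identically at k ≈ 0, distinguishable only through the
k-dependence of D₄₄); the field-versus-mass study uses 256 epochs.

## Known limitations

One-dimensional patch (the radially symmetric 2-D reading of the receptive
field remains open); linearisation about zero with no fixed-point search;
shared isotropic noise precision rather than frequency-resolved λ; the
α-table reading documented above; no real-data preprocessing (artefact
rejection, line-noise removal, site selection) — re-analysis of the
original recordings is out of scope.
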