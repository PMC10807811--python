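# Methods

## Physical model

### Relaxation of shallow NV centers under a planar Gd³⁺ bath

Each NV center sits a depth d below the diamond surface (default d = 5 nm,
matching the nominal implantation depth; an optional truncated-Gaussian
depth model with sd 2 nm emulates straggle and is off by default). Gd³⁺
labels form a planar Poisson point process of density σ = 9000/μm² at height
h above the surface. The longitudinal relaxation rate of one NV under one
bath configuration is modelled as

    Γ(h) = Γ_int + C · Σ_i w(θ_i) / r_i⁶,

summing ions within a 50 nm lateral cutoff (the 100-nm interaction circle);
r_i is the 3-D NV–ion distance with vertical separation h + d. The r⁻⁶ form
is the variance scaling of a fluctuating point magnetic dipole; the angular
weight w is 1 by default (isotropic). An optional `secular` model uses
w(θ) = (5 − 3cos²θ)/4 — the transverse-field fraction of an isotropically
fluctuating dipole relative to the NV axis, normalized to unit spherical
average — but is off by default because the ensemble averages over four
crystallographic axes largely wash out the anisotropy. No spin-Hamiltonian
dynamics, Gd correlation-time physics, or field-dependent spectra are
modelled; the aggregate distance scaling emerges from the geometry.

NV orientations are drawn uniformly from the four ⟨111⟩ axes of a [100]-cut
crystal ([-111], [1-11], [11-1], [-1-1-1]). They matter only under the
secular weight.

### Pixel decay curves and the stretched exponential

Each NV decays single-exponentially, I_i(τ) = a·e^{−Γ_i τ} + c. A camera
pixel images a 600 × 600 nm² patch (≈360 NVs at 1000/μm²); the pixel trace
is the normalized sum of its NV curves. Because each NV sees a different
local bath, the summed curve is sub-exponential and is summarized by fitting

    I(τ) = a · exp(−(τ/T)^b) + c,     b ∈ [0.3, 2].

Stretching arises *only* from ensemble heterogeneity: single-NV pixels or
artificially equalized rates fit with b = 1 (tested).

### Expected pixel curve (exact bath average)

For a Poisson plane the configuration average of the bath factor has a
closed form (characteristic functional of the Poisson process):

    E(t) = exp( −σ ∫₀^{R²} π (1 − e^{−C t/(u+H²)³}) du ),   H = h + d,

so the expected pixel trace a·e^{−Γ_int t}·E(t) + c — and hence its
stretched-exponential fit T(h) — is deterministic. The Monte Carlo pixel
simulation converges on it as replicates grow (tested at 4σ). The integral
is evaluated with adaptive quadrature on the u = ρ² substitution.

### Two-anchor calibration of the absolute constants

The per-ion coupling C and intrinsic rate Γ_int are not printed anywhere;
they are pinned by requiring the *fitted* pixel T₁ of the expected curve to
equal the working-range endpoints:

    T(h = 0.3 nm) = 391 μs,   T(h = 6 nm) = 795 μs.

A linear solve on the closed-form mean rate (Γ(h) = Γ_int + C·σπ/2·[H⁻⁴ −
(H²+R²)⁻²]) provides the starting point; a 2-D root find (log-parametrized,
`scipy.optimize.root`) on the expected-curve fit finishes the job. The
mean-rate solution alone is *not* sufficient: bath-rate heterogeneity across
NVs is large (relative sd ≈ 100% at h = 0.3 nm), so the fitted stretched T
of the summed curve deviates from 1/⟨Γ⟩ by ≈13% at the low anchor.
Calibrating on the expected-curve fit makes the default calibration table
exact at the anchors by construction, with the Monte Carlo agreeing within
sampling error (calibrated values: C ≈ 103.5 μs⁻¹·nm⁶, Γ_int ≈ 1.159 ×
10⁻³ μs⁻¹, i.e. intrinsic T₁ ≈ 863 μs). Whether 391/795 μs correspond
exactly to the 0.3/6 nm scan endpoints is an interpretation; it is adopted
here as the anchor convention.

The default calibration table (`calibration_curve(method="analytic")`) scans
the deterministic T(h) on a 20-point grid over 0.3–6 nm; `monte_carlo` mode
instead averages replicate pixel simulations and reports mean ± sd. Both are
interpolated with monotone PCHIP, forward and inverse; the constructor
rejects non-monotone tables (a Monte Carlo scan at too few replicates) with
instructions to raise the replicate count.

## Tether mechanics

Marko–Siggia interpolation of the worm-like chain,

    F(x) = (k_BT/L_p) [ 1/(4(1−x/L_c)²) − 1/4 + x/L_c ],

with defaults L_c = 7.98 nm, L_p = 0.38 nm, T = 298 K (k_BT = 4.114 pN·nm).
These defaults reproduce the worked values of the sensor's band: F(3.5 nm) ≈
10.6 pN and F(5.5 nm) ≈ 32.8 pN, i.e. ~10 pN and ~30 pN. The persistence
length is a reverse-engineered working assumption (a measured L_p for the
exact construct is not available), as are the per-monomer contour constants
0.273–0.352 nm that map MW ≈ 1000 g/mol to the 6.20–7.98 nm contour-length
band. An optional enthalpic stretch modulus K₀ (extensible WLC, substitution
x/L_c → x/L_c − F/K₀ solved self-consistently by bracketed root finding) is
available; K₀ → ∞ recovers the inextensible law exactly. The inverse
x(F) is computed by `brentq` on [0, L_c) and round-trips to better than
10⁻⁶ relative.

## T₁ map extraction

The off/on division is computed per bin after averaging frames over the bin
(averaging before division amplifies noise less than dividing pixel-wise and
averaging ratios). Zero-denominator delays become flagged missing points.
The per-bin stretched-exponential fit uses trust-region least squares
(`scipy.optimize.least_squares`, trf, ftol = xtol = 10⁻¹², max 2000
evaluations) with bounds a ≥ 0, T ∈ [10⁻³ τ_min, 10³ τ_max], b ∈ [0.3, 2],
initialized from a log–log linear regression of the decay; if the first
attempt fails or leaves a large residual, a log-spaced multistart on T
retries. Failed or boundary-pinned fits are flagged, never silently
accepted. Degenerate (constant) traces flag non-convergence; traces with
fewer than 5 valid points or spanning less than a decade in τ are input
errors.

Two optional constraints exist: `fix_b` (e.g. 1.0) for data known to be
single-rate, and `fix_c` for data whose division baseline is known by
construction. A Cramér–Rao analysis at the default synthetic conditions
(10⁵ counts/pixel/frame, a = 0.1, 24 delays) gives sd(T) ≈ 78 μs at the top
of the working range for the floating-(a, T, c) fit — the c–T correlation
dominates — dropping to ≈ 45 μs with the baseline fixed. Matched-model
reconstructions of synthetic single-rate stacks therefore fix b = 1 and
c = 1; measured data default to floating b (whether the instrument pipeline
fixes b is not documented; the flag covers both conventions).

Default τ schedule: 24 points log-spaced over 1 μs – 3 ms, chosen to bracket
the full 391–863 μs range of observable T₁ with margin on both sides.

## Force reconstruction and classification

T₁ → height by the inverse PCHIP of the calibration table; out-of-range T₁
is clamped to the boundary and flagged rather than extrapolated (the Monte
Carlo calibration has no support outside its scan). Extension convention:
x = h − h₀ with h₀ = 0 by default — the label height is identified with the
tether's vertical extension; the relaxed-coil offset is left implicit in the
calibration (the reference T₁ of 410 μs corresponds to h ≈ 0.42 nm, so a
zero-force pixel reconstructs to ≈ 0.9 pN rather than exactly 0; an explicit
h₀ can remove this if a relaxed-coil height is known).

Classes are exhaustive and exclusive: `unconverged` (failed fit),
`compressed` (T₁ < 410 μs reference — the cell pushes the tether toward the
surface; extension is reported, force is not, because the entropic force law
does not describe compression), `above_range` (T₁ above the calibrated
maximum, or extension ≥ L_c), else `in_range` with F = wlc_force(x). Note
the working range starts at 391 μs but the compressed boundary is the 410 μs
reference, so `in_range` is effectively [410, 795] μs ↔ extensions
0.42–6 nm ↔ forces ≈ 0.9–49 pN; the *sensitive* band quoted for the sensor
(~10–30 pN) is the steep part of that range, at extensions 3.5–5.5 nm.

## Synthetic experiments

The generator emulates the measurement chain, not the instrument hardware:

* **Force fields** — an elliptical or polygonal footprint with traction
  concentrated in an edge band (default band 480 nm, edge 25 pN, interior
  8 pN — an edge-dominated adhesion pattern at the scale seen in live-cell
  maps), optional polarized lobes, optional clipped Gaussian force noise.
  Masks are deterministic given the parameters; only the noise consumes the seed.
* **Forward model** — per-pixel T₁ = calibration(wlc_extension(F)); zero
  force and background sit at the 410 μs reference; forces mapping outside
  the calibrated height range are clamped and marked saturating.
* **Rendering** — with e(τ) = e^{−(τ/T₁)^b}: on(τ) = I₀(c + a(1−e)) (the
  recovery channel) and off(τ) = on(τ)·(c + a·e), so the off/on division is
  *exactly* the stretched exponential c + a·e and the noiseless round trip
  closes to fit tolerance. Real instruments' off channel is itself a decay
  and the division is only approximately stretched-exponential; this
  idealization (and the absence of PSF blur, read noise, EM gain and drift)
  is the main gap between passing synthetic tests and raw-instrument
  performance. Shot noise is per-pixel-per-frame Poisson; empirical frame
  variance matches the Poisson mean (tested at 5%). Defaults a = 0.1,
  c = 1.0, 10⁵ counts/pixel/frame are plausible desk-scale placeholders —
  the absolute fluorescence contrast of a real instrument is not documented
  — and are recorded in stack metadata.
* Every stack embeds its generating T₁/force/mask/class arrays so recovery
  tests compare against ground truth, never against re-derived quantities.

One metric convention: background pixels are generated exactly at the
reference T₁, which *is* the compressed/in-range class boundary. Any noise
makes the reconstructed side of that boundary a coin flip, so class-accuracy
metrics count a pixel whose true T₁ lies exactly on a boundary as correct
for either adjacent class.

## Numerical choices and problem sizes

* Monte Carlo oracle check: the ensemble-mean bath rate is estimated with
  10⁴ bath replicates, each averaged over 16 NVs whose cutoff discs are
  disjoint; sampling each disc's Poisson count directly is an exact thinning
  of the rectangular bath sampler (cross-checked against the literal
  sampler). A single-NV estimator has ≈ 97% per-replicate relative sd at
  h = 0.5 nm, so the ensemble averaging is what makes a 1% comparison
  meaningful at 10⁴ replicates (final se ≈ 0.24%).
* Calibration root-finding: ~0.3 s; expected-curve quadrature dominates.
* End-to-end demonstrations use 64×64 (tests) or 32×32 (examples) pixel
  fields with 24 delays; a full 64×64 reconstruction takes ~10 s per stack
  (4096 per-pixel fits).
* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical samples, maps and files.

## Known limitations

* The calibration assumes a fixed NV depth in the expected-curve average;
  the Gaussian-depth option affects only the Monte Carlo path.
* Compression (T₁ below reference) is classified but not quantified — a
  buckling/compression model is out of scope.
* Only the normal force component is reconstructed; shear is invisible to
  the height-encoded readout by construction.
* The secular angular model has no closed-form calibration path; it is
  provided for sensitivity studies via the Monte Carlo route only.
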