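# Methods

This note documents the models, default parameters, generator design and
numerical choices behind bphpkit, plus known limitations.

## 1. EMG chromatogram model (`chromatography`)

An SEC elution peak is an exponentially modified Gaussian,

```
f(V) = (amp · λ / 2) · exp(λ(μ − V) + λ²σ²/2) · erfc((μ + λσ² − V) / (√2 σ))
```

which is the convolution of a Gaussian (retention dispersion, centre μ
mL, width σ mL) with a one-sided exponential tail (rate λ per mL). The
peak integrates exactly to `amp` (area in absorbance·mL). A chromatogram
is modelled as tetramer EMG + dimer EMG + linear baseline `b + c·V`,
with the invariant `μ_tetramer < μ_dimer` (larger species elutes
earlier).

**Numerical evaluation.** The textbook form overflows whenever the
argument of `exp` is large. We evaluate piecewise in
`z = (μ + λσ² − V)/(√2 σ)`: for `z ≥ 0` as `gaussian(V) · erfcx(z)`
(scaled complementary error function, no overflow); for `z < 0` directly,
where the exponent is provably negative. This is finite for all inputs
and matches `scipy.stats.exponnorm` to 1e−8 relative.

**Fitting.** Bounded trust-region least squares (`scipy.optimize.
least_squares`, tolerances 1e−12) over all 10 parameters. Initial values
come from smoothed peak detection (Savitzky–Golay + `find_peaks`), widths
from the 60 %-height half-width, areas from trapezoidal integration split
at the inter-peak minimum, and baseline from the window edges. If the
optimum violates the elution-order invariant the two components are
swapped (with the matching Jacobian column permutation). Standard errors
are `s²(JᵀJ)⁻¹` Gauss–Newton estimates; the tetramer area-fraction SE is
obtained by the delta method on `a_T/(a_T + a_D)`.

**Defaults** (generator and tests): tetramer μ = 10.6 mL, dimer
μ = 12.1 mL, σ ≈ 0.22–0.25 mL, λ = 4 /mL, 801 points over 8–24 mL —
plausible analytical-column values giving baseline-resolved but adjacent
peaks.

## 2. Dimer⇌tetramer isotherm (`association`)

For `2 D ⇌ T` with constant `K₂ = [T]/[D]²` and total dimer-equivalent
concentration `C = [D] + 2[T]`, the tetramer mass fraction is

```
Ȳ(x) = 2(4x + 1 − √(1 + 8x)) / (8x),   x = K₂ C
```

evaluated in the cancellation-free form `4x / (4x + 1 + √(1 + 8x))`,
accurate to machine precision for all x > 0 (verified against a brentq
mass-balance solver). The exact closed-form anchors are Ȳ(1) = 0.5 and
Ȳ(16.40625) = 0.84. The inverse, `x = Ȳ / (2(1 − Ȳ)²)`, gives a direct
single-point estimator. Concentrations in mg/mL convert to molar via the
dimer molar mass (default 165 kDa; the "subunit" of association is the
intact dimer).

`DimerTetramerModel` fits log K₂ by least squares on the fractions; with
one point it uses the exact inverse. With few points and no replicate
error model the fit is labelled a descriptive trendline, not a rigorous
thermodynamic estimate.

## 3. Global dark reversion (`photokinetics`)

Absorbance at wavelength w and time t:

```
A(w, t) = a₁(w)·e^{−k₁t} + a₂(w)·e^{−k₂t} + A∞(w),   k₁ > k₂
```

Rates are global across wavelengths; amplitudes and offsets are
per-wavelength linear parameters, solved by variable projection: for any
trial (k₁, k₂) the linear subproblem has a closed least-squares solution,
so the nonlinear search is 2-dimensional (in log rates). A 14-point
log-spaced grid over all rate pairs supplies the start. Agreement with a
full joint nonlinear fit is verified in the tests to 1e−6.

**Degeneracy.** If the data carry only one exponential, (k₁, k₂) is
unidentifiable. The fit collapses to a single exponential when the rates
coincide to 1e−6 relative, when adding the second exponential improves
the residual sum of squares by less than 1e−4 relative, or when the
single-exponential residual is already at numerical noise. The result is
flagged `degenerate` with k₂ = NaN.

**Standard errors** for the rates come from the full-problem Jacobian
(all 2 + 3W parameters), not the projected 2-parameter one, so the
uncertainty of the profiled amplitudes is included.

**Defaults**: 28 wavelengths over 650–785 nm (the red/far-red band
window), 200 time points over 2 h, k₁ = 3×10⁻³ s⁻¹, k₂ = 3×10⁻⁴ s⁻¹,
band amplitudes 0.04–0.12 OD — slow thermal reversion with a clear
fast/slow split and realistic signal-to-noise at 1 mOD noise.

## 4. Saturation kinetics (`kinase`)

`S(t) = ΔS(1 − e^{−kt}) + S₀` per replicate, with k shared globally
(optionally two components with k₁ > k₂). Same variable-projection
strategy: per-trace linear parameters (ΔS, S₀) are profiled; the rate
grid adapts to the observed time span (0.05/t_max to 20/t_min), which
makes the estimate exactly covariant under time-unit changes (tested to
1e−8). With `constrain_baseline=True` the t = 0 observation is
subtracted, fixing S₀ identically to the measured baseline; construction
requires a t = 0 sample. Rates are reported in 1/(time unit of the
input); units are metadata, never rescaled silently.

**Defaults**: ΔS = 100 counts, S₀ = 5, k = 4.7×10⁻³ per time unit, 25
samples over 2 h. The phosphotransfer generator produces a donor/acceptor
pair with conserved total label (donor amplitude −ΔS, acceptor +ΔS).

## 5. Structural metrics (`structure`)

- **Superposition**: Kabsch via SVD of the cross-covariance with the
  determinant sign correction, so mirror inputs still yield a proper
  rotation. Degenerate inputs (< 3 atoms, collinear sets) are rejected.
  Verified against `scipy.spatial.transform.Rotation.align_vectors` and
  a 1000-rotation brute-force oracle.
- **Rotation angle/axis**: `θ = arccos((tr R − 1)/2)`; the axis comes
  from the antisymmetric part (or the symmetric part near 180°) with a
  fixed sign convention (first nonnegative of z, y, x). Inputs are
  checked for orthogonality.
- **Domain rotation**: state B is first aligned to state A on the
  reference-domain (e.g. GAF) Cα atoms; the mobile-domain (e.g. PHY)
  rotation is then the Kabsch rotation between the two mobile-domain
  coordinate sets in that common frame. Frame-invariant by construction
  (tested to 1e−6 degree).
- **Ring-plane flip**: plane normals from SVD, oriented by Newell's
  method over the ring atom order so flips beyond 90° (e.g. ≈161°
  D-ring flips) are not folded back into [0°, 90°].
- **Marker distances** and **helix scissor angles** (PCA axes oriented
  N→C) complete the metric set. Approximate default domain windows ship
  in a versioned YAML data file and can be overridden per call.

I/O uses gemmi for PDB/mmCIF; only blank/'A' altlocs are kept (others
are logged and dropped), and the first model is used.

## 6. Synthetic generators (`simulate`)

Every generator takes a `GeneratorSpec(seed, noise, grid, truth)` and is
bit-reproducible in the seed (`numpy.random.default_rng`). Noiseless
output equals the forward model exactly, and the generating truth is
embedded in the returned object, so recovery tests are exact
round-trips. Noise models: additive Gaussian and multiplicative
(fractional) Gaussian. The equilibrium-series generator converts a
stated K₂ and concentration list into per-chromatogram peak areas via
the isotherm, with total area proportional to load. The structural
generator builds ideal α-helices (1.5 Å rise, 100°/residue) and applies
an exact rigid rotation about a stated axis/pivot, optionally with an
oriented chromophore-ring flip, returning the truth transform.

## 7. Limitations

- The isotherm assumes a two-state dimer⇌tetramer equilibrium at
  equilibrium on the column; kinetically trapped or higher-order species
  bias K₂.
- EMG deconvolution of a single-peak sample leaves the amplitude split
  between the two components unidentifiable; total area and residuals
  remain well defined (tested), and heavily overlapping peaks inflate
  the fraction SE.
- Biexponential rates closer than a factor of ~3 are weakly identified
  at realistic noise; the degeneracy guard only catches the collapsed
  limit.
- Standard errors are asymptotic Gauss–Newton estimates assuming
  homoscedastic residuals.
- Default domain windows are approximate sequence ranges; for rigorous
  structural work supply explicit selections.
- Saturation-kinetics rate units follow the input time column and are
  reported as metadata only.
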