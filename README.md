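# bphpkit

Quantitative analysis toolkit for bacterial phytochrome photoreceptor
experiments: size-exclusion chromatography (SEC) oligomer deconvolution
with a dimer⇌tetramer association isotherm, global dark-reversion
photokinetics, histidine-kinase phosphotransfer saturation kinetics, and
rigid-body structural comparison between photostates. A seeded synthetic
data module and a CLI tie the stages into reproducible pipelines.

## Scientific background

Bacteriophytochromes are red/far-red photoreceptors that interconvert
between a red-absorbing Pr state and a far-red-absorbing Pfr state when
their biliverdin chromophore photoisomerises. The photostate switch
propagates from a rotation of the chromophore D-ring pyrrole, through a
refolding sensory-module tongue, to rearrangements of the output
histidine-kinase module. Four quantitative signatures of this process
are covered here:

1. **Oligomeric equilibrium.** On SEC the protein elutes as two
   exchanging species, dimer and tetramer. Each elution peak is modelled
   as an exponentially modified Gaussian (EMG); the tetramer area
   fraction across a concentration series follows the closed-form
   dimer⇌tetramer isotherm
   `Ȳ = 2(4K₂C + 1 − √(1 + 8K₂C)) / (8K₂C)`, where `C` is total dimer
   concentration and `K₂` the dimerisation-of-dimers constant.
2. **Dark reversion.** After photoconversion, Pfr thermally reverts to
   Pr. Absorbance time courses at many wavelengths share two global
   rate constants (a fast and a slow phase) with per-wavelength
   amplitudes — a classic separable (variable-projection) problem.
3. **Phosphotransfer kinetics.** Autophosphorylation/phosphotransfer
   signals follow saturation kinetics `S(t) = ΔS(1 − e^{−kt}) + S₀`
   with a rate shared across replicates, optionally with the baseline
   pinned to the t = 0 observation.
4. **Structural metrics.** Kabsch superposition, domain-rotation angles
   measured in a reference-domain frame, oriented ring-plane flip
   angles, marker-atom distances, and helix scissor angles quantify the
   Pr → Pfr conformational change.

## Worked example

Simulate a two-species chromatogram at 0.5 % peak noise and deconvolve
it (every generator is deterministic in its seed):

```python
from bphpkit.simulate import GeneratorSpec, NoiseModel, make_chromatogram
from bphpkit.chromatography import EMGMixtureModel

chrom = make_chromatogram(GeneratorSpec(seed=11, noise=NoiseModel("gaussian", 0.004)))
res = EMGMixtureModel(chrom).fit()
print(res.summary())
```

Output:

```
EMG mixture deconvolution
  points: 801   residual RMS: 3.949e-03   converged: True
     param        value      std err
     amp_T     0.600812     0.000939
     lam_T      3.98354       0.0303
      mu_T      10.5996      0.00105
   sigma_T     0.220278     0.000764
     amp_D     0.599847     0.000942
     lam_D      3.92661         0.03
      mu_D      12.0974      0.00115
   sigma_D     0.247649     0.000896
         b    0.0103016     0.000614
         c  0.000480949     3.46e-05
  tetramer area fraction: 0.5004 +/- 0.0005
```

The generator's true area fraction is 0.5; the fit recovers it with a
propagated standard error. A kinetics fit works the same way — a Model
object wraps the data, `fit()` returns a Results object:

```python
from bphpkit.simulate import GeneratorSpec, NoiseModel, make_kinetics_trace
from bphpkit.kinase import SaturationKineticsModel

traces = [make_kinetics_trace(
    GeneratorSpec(seed=4 + i, noise=NoiseModel("multiplicative", 0.03)),
    replicate_id=f"r{i+1}") for i in range(3)]
res = SaturationKineticsModel(traces).fit()
print(res.summary())
```

```
Global saturation-kinetics fit
  components: 1   baseline constrained to t=0: False
  k  = 0.00467131 (1/time unit of input)  (SE 0.00024)
     replicate           dS           S0
            r1       99.913       5.1438
            r2       100.35       4.2813
            r3       100.04       5.6137
  residual RMS: 3.109 counts
```

(the generator's true rate is 4.7 × 10⁻³ per time unit).

## Command line

```
bphpkit simulate --stage sec --seed 7 --out-dir out/        # synthetic data + truth manifest
bphpkit fit-sec out/sec_seed7.csv --out out/report.json     # EMG deconvolution
bphpkit fit-reversion series.csv --out report.json          # global biexponential
bphpkit fit-kinase traces.csv --constrain-baseline          # saturation kinetics
bphpkit compare-structures pr.pdb pfr.pdb --out cmp.json    # rotation/flip/distances
```

All reports are deterministic JSON with a manifest recording package
version, input checksums, and the provenance (CLI flag, config file, or
default) of every parameter.

## Reproduction

```
pip install --no-build-isolation -e .[test]
python -m pytest -q tests/                                  # full suite incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs every analysis stage end to end on seeded
synthetic data and writes the recovered headline quantities (tetramer
fractions of the association titration, phosphotransfer rate, reversion
rates, domain rotation, ring flip, anchor distances) with sample sizes.
All values are computed at runtime; reruns with the same seed reproduce
them bit for bit.

## Layout

- `src/bphpkit/chromatography.py` — EMG peak model and mixture deconvolution
- `src/bphpkit/association.py` — dimer⇌tetramer isotherm and K₂ fitting
- `src/bphpkit/photokinetics.py` — global biexponential reversion, difference spectra
- `src/bphpkit/kinase.py` — saturation kinetics with shared rates
- `src/bphpkit/structure.py` — superposition and conformational metrics
- `src/bphpkit/simulate.py` — seeded synthetic generators with embedded truth
- `src/bphpkit/cli.py` — pipeline orchestration
- `docs/methods.md` — model equations, defaults, numerical choices, limitations
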