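# trsfx

Analysis toolkit for time-resolved crystallography and in crystallo
spectroscopy, exercised end-to-end on a built-in synthetic toy crystal so no
experimental data are needed.

The package implements, for triclinic P1 cells:

- **`trsfx.xtal_core`** — a minimal crystallographic engine: direct-summation
  structure factors (Cromer-Mann or single-Gaussian "toy" form factors),
  SCALEIT-style relative scaling `k exp(-B_rel/4d^2)`, SNR- and
  resolution-filtered difference amplitudes (defaults SNR > 3, low-resolution
  cut 10 Å), FFT Fourier synthesis, and observed difference electron density
  (DED) maps phased with the dark model.
- **`trsfx.ded_analysis`** — sigma thresholding, signed density integration
  within atom-selection masks (`resi 2 and name CG,OD1,ND2` grammar),
  pairwise Pearson correlation maps, and SVD of masked DED map series
  (lSV component maps / SV weights / rSV time traces) with reconvolution.
- **`trsfx.extrapolation`** — q-weighted scalar and vectorial
  structure-factor extrapolation, and occupancy estimation from the
  breakpoint of integrated residual negative density versus the
  extrapolation factor N (alpha = 2/N*).
- **`trsfx.dfocc`** — dFoCC refinement: conformer libraries from rigid
  rotations about declared side-chain axes, scoring by the Pearson
  correlation between calculated and observed DED maps, and deterministic
  coordinate-descent refinement converging at 0.1°/0.1 Å.
- **`trsfx.kinetics`** — first-order accumulation and sequential two-step
  (rise/decay) models with multi-start least-squares fitting on
  log-spaced time grids.
- **`trsfx.icos_spectra`** — crystal UV/Vis pipeline: Savitzky-Golay
  smoothing (21/3), Rayleigh `b/λ⁴` scattering correction, band integration
  (580–640 nm signal, 456–490 nm normalization), path-length-invariant
  difference traces, and two-wavelength Lambert-Beer deconvolution of
  flavin redox states.
- **`trsfx.synthetic`** — seeded generators: a 32-atom toy crystal with a
  pivotable Asn-analog side chain, partial-occupancy dark/light reflection
  datasets (complex structure-factor mixing plus fractional Gaussian noise),
  kinetic time series of datasets, and crystal absorption spectra series.
- **`trsfx.cli` / `trsfx.config`** — the `trsfx` command line and a YAML
  pipeline runner writing reproducibility manifests.

## Command line

```sh
trsfx simulate dataset --seed 1 --alpha 0.2 --noise 0.01 --out-prefix toy
trsfx ded --light toy_light.hkl --dark toy_dark.hkl --model toy_dark.pdb \
      --snr 3 --dlow 10 --out ded.ccp4
trsfx integrate --map ded.ccp4 --model toy_dark.pdb --select "resi 2" \
      --radius 2.0 --sigma 3
trsfx extrapolate --light toy_light.hkl --dark toy_dark.hkl \
      --model toy_dark.pdb --marker "resi 2" --out scan.json
trsfx dfocc --model toy_dark.pdb --dedo ded.ccp4 --axes axes.json \
      --out-pdb refined.pdb --out-json trace.json
trsfx fit --trace trace.csv --model two_step --out fit.json
trsfx pipeline --config pipeline.yaml --out manifest.json
```

Reflections travel as plain-text TSV (`.hkl`) or structure-factor mmCIF,
coordinates as PDB, maps as CCP4 mode-2, traces/spectra as CSV.

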