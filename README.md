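# dectsim

Simulation and estimation-theoretic analysis of **dual-energy MV–kV computed
tomography** — the idea of pairing the megavoltage treatment beam of a
radiotherapy linac with its kilovoltage imaging source to perform dual-energy
CT with hardware the treatment room already has.

The package is written for medical-imaging physicists who want to ask: *under
a fixed total dose, when does adding MV information beat a conventional kV
acquisition?* It provides two connected models:

1. **Single-line CRLB model.** One ray crosses a two-material object
   (ICRU soft tissue + cortical bone, mass thicknesses
   `A_j = ρ_j t_j` in g/cm²) and is measured with two dose-allocated spectra
   on an energy-integrating detector (`D(E) = E`, xenon-gas efficiency
   `η(E)` with `η ≈ 0.2` at 1 MeV). The energy-weighted compound-Poisson
   signal is approximated as Gaussian with matched moments

   ```
   λ_i  = Σ_E D(E) I_i(E) T(E) η(E)          (mean)
   σ²_i = Σ_E D²(E) I_i(E) T(E) η(E)         (variance)
   ```

   and the Fisher information for `A = (A_tissue, A_bone)` takes the
   two-term Gaussian form

   ```
   F_jk = Σ_i (1/σ²_i) ∂λ_i/∂A_j ∂λ_i/∂A_k
        + ½ Σ_i (1/σ⁴_i) ∂σ²_i/∂A_j ∂σ²_i/∂A_k .
   ```

   The Cramér–Rao lower bound `σ²_{A_j} ≥ (F⁻¹)_jj` gives the best
   achievable basis-material SNR, `SNR_j = A_j / σ_{A_j}`, which is swept
   over the dose allocation `r` (fraction of the total dose given to the
   high-energy spectrum, 1%–99% in 1% steps) and over bone thickness.

2. **Fan-beam CT model.** A polychromatic fan-beam simulator (1200 views,
   800 equiangular channels, 47° fan, exact Siddon radiological paths,
   per-energy-bin Poisson noise) images a parametric 512×512 pelvis phantom
   with an optional titanium or stainless-steel hip prosthesis. Dual-energy
   sinogram pairs are decomposed into tissue/bone mass-thickness sinograms
   by iteratively reweighted Gauss–Newton, reconstructed by equiangular
   fan-beam filtered backprojection (generalized sinc window at 80% of
   Nyquist), and combined into virtual monoenergetic images
   `VMI(E₀) = ρ₁ [μ(E₀)/ρ]₁ + ρ₂ [μ(E₀)/ρ]₂`. Dose-matched single-energy
   scans receive a two-material beam-hardening correction (4th-degree water
   polynomial in the sinogram domain plus an image-domain bone artifact
   subtraction). Image quality is scored by ROI CNR and by RMSE against the
   monoenergetic ground truth.

Five synthetic spectra are generated (80/120/140 kV bremsstrahlung with
aluminum filtration; 6 MV treatment and a "detuned" < 3 MV imaging beam),
each rescaled to deliver the same dose to the center of a 40 cm water
cylinder, so every comparison is dose-matched.

## Worked example

Sweep the dose allocation for the detuned-MV / 80 kV pair with 40 cm tissue
and 1 cm bone at 1 µGy total line dose:

```
$ dectsim sweep --pair detunedMV-80kV --t-bone 1
...
# peak tissue: r=0.89 snr=79.10
# peak bone:   r=0.83 snr=5.31
```

The tissue SNR peaks with ~90% of the dose on the MV beam: each MeV photon
deposits far more dose than a keV photon, so a dose-matched MV beam is
photon-starved and the optimum pushes most of the dose budget toward it.
The same sweep for `140kV-80kV` peaks near `r=0.51 snr=167.85` — the
diagnostic pair favors an even split and a higher absolute SNR at this bone
thickness. Repeating over bone thicknesses 1–10 cm shows the ordering
reverse at 8 cm of bone, where kV imaging starts to suffer photon
starvation and the MV pair takes over.

The CT study (scaled geometry, seed 1) reports, per phantom variant and
acquisition, the peak VMI CNR and minimum RMSE:

```python
from dectsim.pipeline import ExperimentConfig, run_model2
out = run_model2(ExperimentConfig(seed=1, scale="test"),
                 variants=("none", "steel"), include_se=False)
print(out["metrics"][["variant", "acquisition", "peak_cnr", "min_rmse_hu"]])
```

```
  variant acquisition  peak_cnr  min_rmse_hu
0    none       MV-kV      3.39        54.03
1    none       kV-kV      3.53        53.99
2   steel       MV-kV      1.55       198.88
3   steel       kV-kV      0.84       273.44
```

Without metal the kV-kV pair wins on CNR; with a steel hip prosthesis the
MV-kV pair gives both the higher CNR and the lower RMSE — the penetrating
MV beam is what survives the metal, which is the case for MV-kV dual-energy
CT as a metal-artifact strategy.

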