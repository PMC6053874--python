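# dhbpka

Acid-dissociation constants (pKa) of substituted 1,2-dihydroxybenzenes
(catechols, catecholamines and related phenolics), determined two ways and
cross-validated:

1. **Spectrophotometrically**, from UV-Vis pH-titration spectra
   (a wavelength × pH absorbance matrix), via five classical estimation
   methods behind a selection cascade: isosbestic-point intersection on
   the raw spectra, the same on Savitzky-Golay first/second wavelength
   derivatives, the zero-crossing method, the baseline-to-peak log-ratio
   fit, and a three-point closed form (Seok method).
2. **Computationally**, from a proton-exchange thermodynamic cycle that
   combines a gas-phase deprotonation free energy with continuum-solvation
   free energies (PCM / IPCM / CPCM) of every species.

The package targets anyone who needs reproducible catechol pKa values —
they control metal chelation, antioxidant/pro-oxidant behaviour and use in
advanced oxidation processes — and ships the published reference tables
for 24 compounds as fixtures, plus a synthetic titration generator so the
whole spectral pipeline is testable without a spectrophotometer.

## The models in brief

Speciation of an n-protic acid follows Henderson-Hasselbalch per step,

    pH = pKa_i + log10([base_i]/[acid_i]),

so species `s` (s protons removed) has abundance `10^(s·pH − Σ_{i≤s} pKa_i)`
up to normalisation. A titration spectrum is the Beer-Lambert mixture
`A(λ, pH) = Σ_s f_s(pH) · A_s(λ)` (+ optional Gaussian noise); every
spectral method inverts some 1-D view of this mixture. The cycle pKa is

    pKa = ΔG_sol / 1.364 − log10[H2O],        ΔG_sol = ΔG_g + ΔG_solv(A⁻)
                                              + ΔG_solv(H3O⁺) − ΔG_solv(HA)
                                              − G_solv(H2O)   [kcal/mol]

optionally minus the empirical 4.54-unit Pliego correction. Validation
pairs experimental against computed constants per dissociation (OLS r²),
and assigns the first deprotonation site from Hammett σp: electron donors
(σ < 0) acidify the hydroxyl meta to the substituent (OH_m), withdrawers
(σ > 0) the para one (OH_p).

## Worked example

```python
from dhbpka import (AcidSystem, default_species_spectra,
                    simulate_titration, run_cascade)

system = AcidSystem((8.83, 13.07))          # catechol, experimental values
series = simulate_titration(system, default_species_spectra(3),
                            noise_sd=0.0, seed=0)
report = run_cascade(series, n_dissociations=2)
for r in report.results:
    print(f"pKa{r.index} = {r.estimate.pka:.3f} via {r.estimate.method} "
          f"at {'/'.join(f'{w:.0f}' for w in r.estimate.wavelengths_nm)} nm")
```

prints

```
pKa1 = 8.831 via isosbestic_intersection at 267/289 nm
pKa2 = 13.050 via isosbestic_intersection at 285/306 nm
```

i.e. both constants are recovered from the simulated spectra by the first
cascade stage, the first one to 0.001 pH units; the second sits 0.93 units
from the top of the pH 2-14 range, so its basic plateau is never fully
reached and the estimate lands 0.02 low. The same pipeline is available
from the shell:

```bash
dhbpka simulate --preset catechol --out sim.csv
dhbpka analyze --spectra sim.csv --n-pka 2 --out report.json
dhbpka validate            # fixture tables: errors, r², site assignments
```

The numbered scripts under `analysis/` run the full set of analyses
(simulation, cascade recovery with a 100-replicate noise ensemble,
solvation-model comparison, experimental-computed correlation, Hammett
site assignment) and write their tables under `results/`.

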