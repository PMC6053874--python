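# Methods

## Scope and data model

The package determines acid-dissociation constants of 4-substituted
1,2-dihydroxybenzenes from two independent routes — UV-Vis pH titrations
and a solvation thermodynamic cycle — and runs the analyses that tie the
routes together. It consumes titration spectra (wavelength × pH
absorbance matrices, CSV) and tables of free energies (TSV, kcal/mol); it
performs no quantum chemistry itself. The published reference values for
the 24 studied compounds (experimental pKa1-3 with uncertainties,
site-resolved computed pKa with Hammett σp, and the three-compound
PCM/IPCM/CPCM benchmark) ship as packaged CSV fixtures. Where the two
source tables disagree on 4-ethylcatechol's experimental pKa1 (8.32 vs
8.29) both values are kept as printed in their respective tables.

## Speciation

Mole fractions of the n+1 protonation states follow from cumulative
Henderson-Hasselbalch quotients: species `s` has log-abundance
`s·pH − Σ_{i≤s} pKa_i`. The largest exponent is subtracted before
exponentiation, so extreme combinations (pH 14 with pKa 2) cannot
overflow; columns are normalised to sum to one. Up to four dissociations
are supported (Dopa carries four).

## Synthetic titrations

The generator emulates the study conditions: a 1 mmol/L chromophore in a
wide-range buffer titrated over pH 2.0–14.0 (default step 0.25, an
assumption — the instrument's pH spacing is not published), recorded on a
190–500 nm grid at 1 nm (covering the 194–450 nm span of the reported
analysis wavelengths). Each protonation state's pure spectrum is a sum of
Gaussian bands; the recorded matrix is the speciation-weighted mixture
plus optional i.i.d. Gaussian noise (default 0.002 AU, a small
diode-array-like figure; the source reports no noise characterisation).
The default species set shifts an 0.85 AU main band from 269 nm by
+18 nm per deprotonation at constant width, which reproduces the
qualitative red-shift of phenol → phenolate spectra and places each
consecutive-species crossing exactly on the wavelength grid; a common
far-UV shoulder adds background.

What this emulates well: isosbestic structure, overlapping transitions,
additive noise, the pH-grid resolution limit. What it does not: real band
asymmetries and vibronic structure, baseline drift, buffer absorbance,
pH-meter error, or Beer-Lambert deviations. Passing the recovery tests
therefore shows the estimators are correct and unbiased under the model's
assumptions, not that any instrument achieves those accuracies.

## Spectral estimators

All five methods reduce the matrix to one or two absorbance-vs-pH traces.

**Isosbestic intersection.** Candidate isosbestic wavelengths are interior
local minima of the across-pH standard deviation within a transition
window. The threshold adapts to the data: a candidate must lie below
max(5 × noise estimate, 2% of the window's maximum spread), the window
must carry real transition signal (max spread > 10 × noise estimate —
otherwise a pure-noise series returns "no isosbestic" and a flat series
raises a degenerate-data error), and the wavelength must carry real
absorbance (≥ 5% of the window maximum), which excludes the spuriously
flat regions outside every band. The noise estimate is a robust MAD of
second differences along pH (variance 6σ² for i.i.d. noise; the smooth
titration signal contributes little to the median). Given an isosbestic,
two monitoring wavelengths are chosen on opposite sides of the
acid-to-base difference spectrum such that the *sum* of the pure acid and
base spectra matches at the two wavelengths — the crossing of the two
traces then falls exactly at the transition midpoint, i.e. at pKa,
without assuming band symmetry. The crossing is located by linear
interpolation between bracketing pH columns; with several crossings the
one inside the active window is taken and the ambiguity recorded.

**Derivative variants.** Savitzky-Golay derivatives with respect to
wavelength (default window 7, polyorder 3; the original processing used
vendor software without published parameters) feed the same isosbestic
analysis at order 1 then 2.

**Zero-crossing.** In a derivative series, λ₁ is a wavelength where the
acid-side column is numerically zero (below 2% of that column's maximum
amplitude) and the base-side signal largest, and λ₂ the converse; each
trace then selectively monitors one species. The *magnitude* traces are
intersected: the two selective traces are proportional to
f_base·|D_b(λ₁)| and f_acid·|D_a(λ₂)| but may carry opposite signs, in
which case the signed traces would never cross.

**Baseline-to-peak.** At a wavelength whose signal grows with pH,
M = A − A_acid-limit and N = A_base-limit − A are proportional to base and
acid concentrations; log10(M/N) is fitted against pH by ordinary least
squares and pKa = −intercept/slope, the slope being left free as a
diagnostic of two-state behaviour. Limits default to the fit-range edge
columns; explicit limits may be passed. Only points where both M and N
exceed 5% of the amplitude enter the fit — near the plateaus a small
error in an estimated limit dominates the distance and its log, and this
floor is what keeps the estimate within ~0.02 pH units when a
neighbouring dissociation slightly contaminates an edge column.

**Three-point closed form (Seok).** For three (pH, A) points on one
monoprotic sigmoid, eliminating the two unknown limiting absorbances from
A(pH) = (A_HA + A_L·10^(pH−pKa))/(1 + 10^(pH−pKa)) gives
10^(pH1−pKa) as a ratio of two linear combinations of A1, A2, A3 with
coefficients in 10^a, 10^b (a = pH2−pH1, b = pH3−pH1). The implementation
was re-derived from that model and is verified in the tests against an
independent numerical three-equation solver (agreement < 1e-8 over 1000
random inputs). The expression is scale-invariant in absorbance, as are
all other estimators.

## Method cascade

Per dissociation the methods are tried in the fixed order raw isosbestic →
1st-derivative isosbestic → 2nd-derivative isosbestic → zero-crossing →
baseline-to-peak → three-point form; the first success is reported with
the reason every earlier method was skipped, and if all fail the
dissociation is reported unresolved with all reasons. Transition windows
are located from the column-to-column change rate of the whole matrix
(one peak per dissociation, boundaries at midpoints between neighbours,
snapped to the pH grid).

Two numerical refinements matter for multi-step systems:

- *Core-window gating.* The isosbestic spread test runs on the
  interquartile pH core of the window: near the window edges the
  neighbouring dissociations contribute residual fractions that inflate
  the spread at a genuine isosbestic wavelength and would veto it.
- *Two-state unmixing of the pair selection.* The window edge columns are
  only approximately pure species. After a first crossing estimate, the
  pure acid/base spectra are unmixed from two columns near the transition
  midpoint (where neighbour fractions are minimal) using two-state
  speciation factors, wavelengths that the two-state model cannot explain
  at the window edges (a third species absorbs there) are masked out of
  the pairing, and the crossing is recomputed; this iterates to
  convergence (tolerance 1e-4, ≤ 3 rounds).

With these, noiseless recovery over all fixture systems is within 0.026
pH units for every dissociation that is ≥ 2 pH units from its neighbours
and ≥ 1.5 units inside the titration range. Constants closer to pH 2 or
14 (e.g. 13.93, 2.06) cannot have their limiting plateaus established
within the published titration range and are excluded from that claim;
for catechol's second constant (13.07, 0.93 units from the top of the
grid) the cascade lands ≈ 0.02 low for this reason. Under 0.002 AU noise
the first catechol constant shows |mean bias| < 0.01 over 100 seeds
(measured ≈ 0.002, SD ≈ 0.007).

The three points for the closed form default to the 25th/50th/75th
percentile pH columns of the window; the single-wavelength methods use
the wavelength of largest absorbance increase across the window.

## Thermodynamic cycle

ΔG_sol = ΔG_g + ΔG_solv(A⁻) + ΔG_solv(H3O⁺) − ΔG_solv(HA) − G_solv(H2O),
pKa = ΔG_sol/1.364 − log10[H2O], optionally minus the 4.54 Pliego
correction. The 1.364 kcal/mol divisor is stored as the conventional
printed constant rather than recomputed, for bit-reproducibility; a
helper computes R·T·ln10 (1.3642 at 298.15 K) to validate it. The water
molarity defaults to 55.34 mol/L (pure water at 25 °C) — the source
states the −log[H2O] term without a value — and is configurable. Relative
errors are 100·|exp − calc|/exp; models are ranked by maximum error over
the benchmark compounds. Alternative conformers with/without the
intramolecular hydrogen bond are representable as extra free-energy rows
tagged `hbond`; no geometry is modelled.

## Validation analyses

Experimental and computed constants are paired per dissociation index:
both sides sorted ascending, the computed list truncated to the number of
experimental values — macroscopic constants come out of a titration in
acidity order regardless of site. r² is the plain OLS coefficient of
determination per series, computed over all compounds having that index
(the exact subset behind the published correlation figure is not stated);
no robustification is applied. Dopa's dual substituent entry ("2.31/10.2")
is parsed as two RH values.

The first deprotonation site is the hydroxyl (OH_m/OH_p) of minimum
computed pKa; a more acidic substituent proton is reported separately.
Consistency is judged against the σ-sign rule (σ<0 → OH_m, σ>0 → OH_p);
compounds without a tabulated σ are not classifiable and excluded from
consistency counts. A compound is flagged as a trend exception either
when its site contradicts the rule (4-chlorocatechol) or when its
substituent is a weak π-donor — halogens and hydroxyl are inductively
withdrawing but resonance-donating, so their σp does not predict the
deprotonation order — which additionally flags 1,2,4-benzenetriol despite
its printed σp of −0.37.

## Known limitations

- Estimates for constants within ~1.5 units of the titration-range ends
  are biased low/high because the limiting plateaus are unreachable.
- Transitions closer than ~2 pH units overlap; the cascade still reports
  values but the two-state assumptions of every method degrade.
- The cascade's method choice on synthetic spectra need not match the
  per-compound choices made on the original (undeposited) instrument
  data; the published method table is a qualitative reference only.
- The pairing rule cannot detect a computed site ordering that disagrees
  with experiment within a compound; it is a correlation device, not an
  assignment proof.
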