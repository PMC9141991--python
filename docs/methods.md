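# Methods

This note records the models implemented in `anthoredox`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The package post-processes solution-phase thermochemistry of polyprotic
antioxidants; it performs no electronic-structure calculation. A species
is one *macro* protonation state (deprotonation index 0 = flavylium
cation) of one compound in one solvent (`water` or `pentyl_ethanoate`);
tautomers/microstates are deliberately not resolved — one pKa per step,
one row per charge state. Internal energy unit is kcal/mol everywhere;
hartree (× 627.5095) and eV (× 23.060548) are converted on input via an
explicit `unit` tag, never guessed. Site labels are ASCII (`C4p` for
C4′) with a display map restoring primes.

The packaged reference tables carry per-cell provenance and a
`confidence` flag. Three kinds of defective cells exist and are kept
verbatim with an anomaly record instead of being corrected: a duplicated
molar-fraction cell (delphinidin tetra-anion, printed 0.14 where the
closed form gives ~0.00), two SET rate constants irreconcilable with the
scheme that reproduces all other cells (see Kinetics), and one
f-HAT/BDE pair whose charge-state column assignment is ambiguous in the
multi-header source layout (peonidin C5). Confidence-sensitive accessors
(`bde_map`, `fhat_map`) let callers exclude low-confidence cells;
quantitative tests run on high-confidence cells only.

## Speciation

Closed-form partition function over cumulative Henderson–Hasselbalch
exponents, with a max-exponent shift giving stability for pKa spreads of
40+ log units (property-tested on random ladders against a 50-digit
decimal oracle, agreement ≤1e−10). Temperature does not appear — the
pKa values encapsulate it — and no activity/ionic-strength corrections
are applied. The "physiological" wrapper evaluates at pH 7.40. Species
below a population threshold (default 0.1%) are pruned before reactivity
aggregation. pKa estimation from deprotonation free energies is a
user-parameterised linear model (`pka_fitted_params`); no slope/intercept
defaults are shipped because they are specific to a level of theory and
solvent model.

Reproduction tolerances: four compounds' printed molar fractions are
exactly the closed form of their printed pKa (2-decimal equality);
peonidin and petunidin were evidently evaluated from unrounded pKa, so
their rows are held to ±0.2 percentage points — the worst-case effect of
0.005-unit pKa rounding on these ladders.

## Reactivity indices and the eH-DAMA

BDE, adiabatic IP and the proton-affinity step are plain Hess sums over
supplied energies. The H-atom reference enthalpy and the solvated-proton
free energy are *conventions of the thermochemical cycle*, so they live
in `RuntimeConfig` (per solvent, overridable from YAML/JSON) rather than
as hard-coded literals; the shipped water proton value (−265.9 kcal/mol)
is the common experimental convention and the H-atom default is a
placeholder that real post-processing must pin to its own level of
theory.

μ, η, ω are computed from vertical gaps; η ≤ 0 raises (it is also the
symptom of mixed eV/kcal·mol⁻¹ inputs, which the package otherwise
cannot detect). The eH-DAMA assigns x = min-site BDE, y = ω by default —
"low both" is the favourable corner; since the convention is not
universal the axes are plain dataclass fields the caller can re-map.
Ranking sums the fractional rank of each coordinate across all points
(references included) with lexicographic (ω, BDE) tie-breaks; reference
antioxidants (Trolox, BHT, ascorbic acid) are user-supplied data points
since their vertical energies are inputs, not package knowledge.

The ring torsion is the standard atan2 formulation; the *unsigned* value
in [0°, 180°] is the public descriptor (matching how inter-ring twists
are reported), with the signed variant exposed for symmetry-aware work.
Note the signed torsion is invariant under point-order reversal and
antisymmetric under mirror reflection.

Site preference (`preferred_homolysis_site`, `bep_preferred_site`) is
argmin with a canonical tie-break order C3, C3′, C4′, C5, C5′, C7 —
ties are vanishingly rare in real data but the contract must be
deterministic.

## Mechanism thermochemistry

f-HAT, SET and SPLET proton loss are Hess sums against a named radical
partner; no vibrational or entropy corrections are applied internally
(the supplied G values define the frame — for a bulky radical like DPPH
the entropic term is *not* negligible, which is why partner
thermochemistry is data, not a constant). The ETPT second step is not
modelled: when electron transfer is downhill it drives the reaction.
Because absolute DPPH/DPPH-H free energies are effectively never
reported, `dpph_partner_from_offset` builds an effective partner from
the empirical relation ΔG_fHAT(site) = BDE(site) − 72.2 kcal/mol, the
constant offset that the packaged water tables obey to within 0.1
kcal/mol across all 56 comparable cells (itself a shipped consistency
test: per-site ΔG differences equal BDE differences within 0.15
kcal/mol, i.e. per-site TΔS terms cancel).

## Kinetics

Marcus barrier, Eyring rate, Collins–Kimball interpolation as in the
README formulas. Defaults: T = 298.15 K (back-computing the packaged
rate table from its barriers only works near 298 K, not 310 K — the
package ships a test demonstrating the ×2.3 discrepancy at body
temperature), R = 1.987204×10⁻³ kcal/(mol·K), prefactor k_BT/h ≈
6.212×10¹² s⁻¹, no tunneling, path degeneracy σ = 1. Negative
user-supplied barriers are clamped to zero with a warning (the Marcus
formula cannot produce them; a printed "0.0" barrier means diffusion
control). λ may be supplied directly or derived as ΔE_vertical − ΔG_SET.

For DPPH reproduction the diffusion limit is the empirical
k_D = 7.5×10⁹ M⁻¹s⁻¹ (the zero-barrier entry of the packaged table)
rather than a Smoluchowski estimate, because the underlying encounter
radii are unknown; `smoluchowski_kd` (Stokes–Einstein, water viscosity
8.91×10⁻⁴ Pa·s) exists for de-novo systems and gives ≈7.4×10⁹ for two
4 Å spheres, consistent with that choice. Reproduction bands: 2%
relative for barriers < 4 kcal/mol, 10% for the rest (a ±0.05 kcal/mol
rounding of a printed barrier moves an activation-controlled rate by up
to ~9%). Two printed cells — petunidin tri-anion (0.4 → 2.0×10⁹) and
petunidin-glucoside di-anion (3.3 → 4.8×10⁹) — deviate by 274% and 19%
under the scheme that reproduces all twenty other cells at any plausible
rounding of their barriers; they are flagged anomalous, excluded from
the banded check, and covered by a dedicated test asserting the
deviation is real.

The observable rate is Σ f_j·k_j over the speciation at the working pH
(fraction-weighted aggregation). Species with a population but no rate
contribute zero with a warning; rate tags absent from the speciation are
a hard error.

## Assays

The inhibition formula is implemented as the quotient
(F_s−F_c)/(F_b−F_c) — the only reading bounded by 0% (no protection) and
100% (blank-level fluorescence) and invariant under common rescaling of
the three channels. IC50/EC50 use the linear model (OLS via
`scipy.stats.linregress`, inverted at 50%) because that is the model the
assay design calls for; a 4PL sigmoid is deliberately out of scope.
Fits require a positive slope and, by default, responses that bracket
50% (extrapolation is an explicit opt-in). Responses are not clipped to
[0, 100].

## Synthetic data

Generators emulate structure, not chemistry: strictly increasing pKa
ladders (3–6 sites), per-site BDE maps with a distinguished minimum and
strict decrease per deprotonation, decreasing vertical IP, and energies
constructed so the BDE operation applied to emitted parent/radical
enthalpies reproduces the emitted map to round-off. Dose–response curves
are linear through 50% at a known true IC50 (default 3.0 µM, slope
12 %/µM over 0.5–6 µM, six points) with independent Gaussian noise
(default 2%), plus the fluorescence triples that reproduce each response
through the inhibition formula. Marcus grids span ΔG ∈ [−2λ, +λ] to
exercise both parabola branches. All draws go through NumPy's seeded
PCG64 `default_rng`, so output is reproducible across platforms.

What passing tests therefore show: the estimators are correct on data
satisfying the model assumptions (linearity, homoscedastic noise,
well-ordered ladders). What they do not show: robustness to saturating
dose–response shapes, correlated instrument drift, microstate
speciation, or solvation-model error in real quantum-chemistry input.

## Problem sizes

The property suites use 1000 random ladders for the speciation oracle,
dense (≈400-point) Marcus grids at 8 reorganization energies, 2000
randomized Collins–Kimball inputs and 100-seed IC50 recovery — sizes at
which every sampling-based check is stable run-to-run while the whole
suite stays interactive.

## Known limitations

* No microstate/tautomer resolution; no ionic-strength corrections.
* f-HAT is treated thermodynamically (BEP ranking), not with transition
  states; no tunneling or degeneracy corrections in SET rates.
* vIP/vEA/BDE inputs are taken as given; no wavefunction parsing beyond
  the CSV/JSON interchange format.
* The effective DPPH partner is a calibration, valid for comparing sites
  and species within the same frame, not an absolute thermochemistry.
* Membrane permeation and lipid-phase kinetics are out of scope; the
  lipid solvent appears only as a data tag.
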