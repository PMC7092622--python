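# Methods

## Scope and model

`acetoflux` analyses energy conservation during autotrophic growth of
*Clostridium ljungdahlii* on CO or H₂/CO₂. It is a stoichiometric
bookkeeping model, not a kinetic or genome-scale one: a single
cytoplasmic compartment, a membrane proton tally, and the ~25 reactions
of the Wood–Ljungdahl pathway (WLP), product branches
(acetate, ethanol, 2,3-butanediol, lactate) and the chemiosmotic couple
(Rnf complex + ATP synthase). Fluxes are mole-per-mole-of-product; no
growth, maintenance, or gas–liquid transfer is modelled.

### Conventions in the bundled network

- **Coefficients are exact rationals** end to end (`fractions.Fraction`;
  sympy over ℚ for the linear solves). Floating point appears only in
  thermodynamics and the synthetic-data modules. Yields such as 3/4 ATP
  are exact numbers, not rounded floats.
- **Free protons are omitted** from individual reactions, as acetogen
  pathway schemes conventionally draw them. Hydrogen therefore balances
  only modulo H⁺; carbon, oxygen and electrons must close exactly for
  every reaction (enforced by tests). Collapsed *net* reactions restore
  the free protons so they read in the charged textbook form
  (e.g. 4 H₂ + 2 CO₂ → CH₃COO⁻ + H⁺ + 2 H₂O).
- **Electron carriers are abstract conjugate pairs**; the reduced member
  carries exactly 2 electrons, recorded as pseudo-element `e` in its
  formula. Electron conservation is checked with the degree of
  reduction γ = 4C + H − 2O − 3N + 6S + 5P − charge (+ carried `e`),
  where the charge term makes γ correct for the ionic forms actually
  written (acetate⁻ carries 8 electrons, H⁺ carries 0).
- **The phosphate pool is abstract.** ATP/ADP are zero-formula energy
  tokens excluded from steady-state balancing; the net ATP row is the
  yield, not a conserved species. To keep oxygen closure exact, the
  formyl-THF synthetase step releases its phosphoryl oxygen as a
  bookkeeping water and phosphotransacetylase consumes one; the two
  cancel over every acetyl unit. CoA is a one-hydrogen thiol token so
  thioester electron counts close (the acetyl unit carries γ = 9).

## Scheme solving

A scheme preset names a feed (CO or H₂/CO₂), a product demand (the
normalization basis) and assumption flags that select active reactions.
The solver builds the balance system S·v = d over carriers,
intermediates, the non-feed gas (CO is internal on H₂/CO₂; H₂ may not
appear on CO unless evolution is enabled) and the product rows, and
solves it exactly. Uniqueness is verified (nullspace of dimension 0
after constraints); otherwise the minimum-norm solution is returned and
flagged. Infeasibility produces a Farkas certificate — an exact left
combination of balance rows no flux can satisfy — and the report names
the carrier pairs in it (e.g. removing Rnf on H₂/CO₂ names Fd and NAD).

### Wiring choices and why

The running text of gas-fermentation scheme papers rarely states the
chemiosmotic stoichiometries numerically, so these are configuration
values with defaults fixed by mutual consistency of the two headline
yields:

- **Rnf exports 2 H⁺ per Fd_red oxidized; ATP synthase consumes
  4 H⁺ per ATP.** These are the standard textbook assumptions for the
  clostridial Rnf–ATPase couple, and they are the *only* pair for which
  one parameter set reproduces both 0.75 ATP/acetate (H₂/CO₂) and
  10 ATP per (1 acetate + 1 butanediol + 4 ethanol) (CO) exactly under
  the scheme assumptions below. Both are per-preset overridable.
- **Methylene-THF reductase is electron-bifurcating** (2 NADH in, one
  pair to the methyl group, one to ferredoxin); a plain NADH variant is
  bundled but inactive.
- **Formate formation is NADPH-coupled** (formate dehydrogenase in
  complex with the NADP-specific bifurcating hydrogenase); the
  H₂-dependent CO₂-reductase wiring is available via the
  `formate-from-h2` flag as a documented variant.
- **Ethanol on CO is made by reducing acetate**: Pta/Ack (gaining
  substrate-level ATP), then AOR running reductively
  (acetate + Fd_red → acetaldehyde), then the NADPH-linked alcohol
  dehydrogenase half of AdhE. The direct acetyl-CoA → acetaldehyde route
  is kept as an optional variant (`ethanol-via-adhe`).
- **On H₂/CO₂, acetate forms through both Pta/Ack and AdhE→AOR
  (oxidative)** with equal flux. The equality is a hard constraint in
  the preset: the two routes differ by ½ ATP per unit, so without it the
  steady state is a one-parameter family and the yield is ill-defined.
  The 50/50 split is the value consistent with the 0.75 ATP/acetate
  yield under the parameters above (the general expression is
  net ATP = (p+1)/2 for Pta/Ack fraction p).
- **Futile-cycle exclusion**: AOR may not run oxidatively and
  reductively in the same scheme; the preset flags fix its direction and
  the solver rejects sign violations.
- **2,3-Butanediol** forms via reductive carboxylation of acetyl-CoA
  (PFOR), acetolactate synthase/decarboxylase, and NADH-linked
  2,3-butanediol dehydrogenase: 11 CO per butanediol, matching its
  degree of reduction (22 electrons).

With these defaults the bundled presets give (net ATP on each basis):
H2_ACETATE 3/4; CO_ACETATE 3/2; CO_BDO 3/2; CO_ACETATE_BDO 3;
CO_ETHANOL 7/4; CO_FULL 10 — and CO_FULL is exactly
CO_ACETATE + CO_BDO + 4·CO_ETHANOL by linearity.

ATP synthase flux is set by the proton balance after the solve
(exported protons / H⁺-per-ATP), never part of the internal system;
net ATP = substrate-level ATP + that chemiosmotic term.

## Thermodynamics

Overall-conversion ΔG°′ (pH 7, 25 °C, 1 M / 1 atm) is Σν·ΔGf°′ with
each net mole of H⁺ produced contributing −7·RT ln10 = −39.96 kJ.
Formation energies come from the Thauer–Jungermann–Decker (1977)
compilation (bundled file records provenance). Ferredoxin-coupled rows
are scored as ΔG°′ = −nF(E°′_acceptor − E°′_donor) with midpoints
CO₂/CO −520 mV, H⁺/H₂ −414 mV and ferredoxin −450 mV; the ferredoxin
value is the one consistent with the printed −14 and −7 kJ rows and is
flagged as inferred in the table file. The default validation tolerance
is 5 kJ, reflecting integer rounding of the printed values; at
tolerance 0 the report shows the sub-kJ rounding deviations.

## Synthetic fermentation data

The generator emulates pH-controlled fed-batch bioreactor runs: OD
follows a logistic curve to the stated peak (CO: 8.4 by 120 h; H₂/CO₂:
1.6 by 168 h) and each product follows a logistic curve to its stated
end titer (CO: ethanol 713, butanediol 188, acetate 185 mM; H₂/CO₂:
acetate 512, ethanol 42 mM), sampled every 12 h, with additive Gaussian
noise at the stated replicate spreads (clipped at zero). Product curves
share the growth rate, shifted 8 h later, so accumulation trails growth
with the same sigmoid ordering. Rates (0.12/h on CO, 0.09/h on H₂/CO₂)
and midpoints (45 h, 78 h) are chosen so the curves saturate to within
0.1 % of their caps by the stated peak time; the paper-style endpoints
are the generator's contract, kinetic realism is not. Consequences:
passing tests demonstrate endpoint and ratio fidelity and estimator
behaviour under replicate-level noise, not the ability to fit real
reactor kinetics, gas uptake, or non-monotone product curves (acetate
re-consumption, for instance, is outside the generated family).

End-product mole ratios are final-sample concentration ratios (all
titers are mM, so no conversion layer); an option uses each product's
maximum instead for non-monotone inputs. The printed CO endpoint titers
give 1 : 1.016 : 3.854 against acetate, rounding to 1:1:4.

## Expression screen

RPKM = count·10⁹/(length_bp·library_size); replicates are summarized by
the arithmetic mean of per-replicate RPKM (no dispersion statistics —
the screen is a filter, not a test). A gene passes iff
max(mean_A, mean_B) > 50 RPKM and |log₂FC| > 1, both strict. The
abundance floor uses the max so genes induced from near zero are
retained; a `both`-conditions mode is available. A pseudocount of
0.01 RPKM guards log₂ against zeros. The planted-signal generator draws
log-normal baselines, negative-binomial counts (dispersion 0.02,
3 replicates, ~2·10⁶-read libraries) and plants 4-fold changes on
baselines ≥ 100 RPKM; at these defaults recall of the planted set is
exact and the noise-only false-positive rate is below 1 %.

## Numerical and degenerate-input choices

- Exact rational pivoting (sympy Gauss–Jordan) — no tolerances anywhere
  in the flux path; determinism is structural, not seeded.
- Zero product demand solves to the all-zero flux vector and an empty
  net reaction.
- `growth_summary` resolves peak-OD ties by first attainment.
- Time-course CSV readers reject unsorted times, negative
  concentrations and missing columns with the offending line/column
  named; expression TSV readers likewise.
- Reports embed the package version, a config hash and the seed, and
  the machine-readable summary is byte-identical for identical
  config + seed (sorted keys, fixed float rounding).

## Known limitations

- The chemiosmotic parameters are consensus values, not measurements;
  changing either changes every yield (exposed as overrides for exactly
  that reason).
- Carbon/electron recovery against measured gas uptake cannot be closed
  because gas consumption is not part of the generated data.
- The screen implements thresholds only; it is not a substitute for
  dispersion-aware differential-expression inference.
- No thermodynamic feasibility constraints are imposed on fluxes; the
  thermo module scores overall conversions, not pathway steps.
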