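# Methods

## Scope and model

`phsorb` implements the equilibrium analysis chain for pH-dependent
sorption of ionizable organic pollutants to microplastics:

1. **Speciation.** Monoprotic Henderson–Hasselbalch speciation from a
   single pKa. Acids: `f_n = 1/(1+10^(pH−pKa))`; bases are interpreted
   through their conjugate-acid pKa, `f_n = 1/(1+10^(pKa−pH))`; neutral
   compounds have `f_n = 1`. The ionized fraction is stored as
   `1 − f_n`, so closure is exact in floating point. The pH domain is
   clamped to [0, 14]: the model has no meaning outside aqueous pH, and
   the experimental range is 4–10. Amphoteric behaviour and polyprotic
   speciation are not modelled; each compound's single listed pKa and
   acid/base class are taken at face value.
2. **Batch mass balance.** A single measured aqueous concentration in a
   closed batch yields `D_P = ((c0 − cw)/cw)·(V_W/m_P)`. `D_P` is
   computed per individual measurement (replicate × post-day-0 sampling
   time: 9 values per pH for the PE design, 12 for PS) and then
   aggregated. Negative single-measurement values — noise pushing `cw`
   above `c0` — are retained in aggregation and fitting; discarding them
   would bias weakly sorbing estimates upward. Only the sorbed-fraction
   report clamps negative `D_P` to zero. The <10% volume change from
   sampling is neglected (constant `V_W`), as it is within analytical
   error. The replicate CV uses the sample (n−1) standard deviation over
   the absolute mean, the conventional definition.
3. **Species fit.** `D_P = K_P,n·f_n + K_P,i·f_i` is linear in the
   coefficients, so the fit is solved as non-negative linear least
   squares (`scipy.optimize.nnls`) rather than by a generic non-linear
   solver: the optimum is identical, conditioning is better, and no
   initialization is needed. The non-negativity bound is physical.
   By default all individual `D_P` values are pooled (27 points for PE,
   36 for PS per compound), unweighted; fitting per-pH means instead is
   available as `mode="ph_mean"`. When the ionized species never
   exceeds 1% of the mixture over the design (e.g. a pKa ≈ 14 acid
   tested at pH ≤ 10), `K_P,i` is flagged indeterminate and reported
   "n.a.". A design whose neutral fraction is constant while both
   species are present raises an identifiability error.
4. **Censoring and QC.** Fitted coefficients strictly below 50 L kg⁻¹
   are rendered as the token `<5e+01` (numeric shadow retained);
   per-pH `D_P` estimates with CV > 100% carry a warning flag. The two
   rules act on different objects (fitted coefficients vs replicate
   scatter) and are applied as independent annotations.
5. **Uncertainty model.** The relative deviation between true and
   measured partition coefficient is `ε/(1+ε)·(1 + LSR/K_P)`, with ε the
   relative analytical uncertainty read as a one-sided deviation
   (literal reading of the expression). Inverted at a maximum error E:
   `K_P,min = LSR/(E(1+ε)/ε − 1)`. Defaults ε = 0.05 and E = 1.0
   reproduce the 50 L kg⁻¹ reporting threshold exactly at LSR = 10³ and
   line up with the 100% CV exclusion rule; they are the unique pair
   among the study's plotted noise levels that does so.
6. **Scenarios.** `f_diss = 1/(1 + K_OC·m_OC/V_W + K_P·m_P/V_W)` with
   presets Scenario I (plastic LSR 10³ L kg⁻¹, batch-like) and
   Scenario II (10¹⁰ L kg⁻¹, environmental), both with 10⁻⁵ kg L⁻¹
   organic carbon. Default map grids are log-spaced 10⁰–10⁷ L kg⁻¹ with
   71 points per axis, spanning all fitted plastic coefficients and
   typical K_OC ranges. Compound overlay K_OC values are a required
   user input: none are bundled, since published per-compound values
   derive from an external estimation suite.

## Synthetic study generator

The generator emulates the study design: triplicates at pH {4, 7, 10},
100 mg plastic in 100 mL (LSR 10³ L kg⁻¹), initial concentrations
5 µg L⁻¹ (50 for phenanthrene, 30 for nonylphenol — kept high because
both sorb strongly; all values stay below 1% of water solubility),
post-day-0 sampling at days {2, 4, 7} (PE) or {2, 4, 7, 11} (PS).
Equilibrium is assumed at every sampled time; the noise-free aqueous
concentration is `c0/(1 + D_P·m_P/V_W)`, which conserves mass exactly.

Noise is multiplicative on concentrations — `cw·(1 + ε·z)`, z standard
normal, default ε = 0.05, truncated below at 10⁻⁶·c0 — because ε
represents analytical (concentration) uncertainty; day-0 samples are
drawn around `c0` with the same noise. A single global seed fans out to
per-batch substreams keyed by (compound, polymer, pH, replicate) via a
CRC-32 hash into a `SeedSequence`, so adding or removing a compound
never perturbs other compounds' draws and identical inputs give
bit-identical output.

Default ground truths for the full 19-compound fixture are the bundled
fitted-coefficient tables; censored entries (no published value) are
replaced by 10 L kg⁻¹ — well below half the censoring threshold so the
simulated censoring pattern is robust to noise — and "n.a." entries by
zero.

What the generator does **not** emulate: sorption kinetics (every sample
is at equilibrium), non-linear isotherms (relevant for polystyrene at
higher concentrations), chromatographic measurement artefacts, blanks,
glassware sorption, and particle aging. Passing tests therefore
demonstrate the correctness and statistical behaviour of the analysis
chain under the linear-equilibrium assumptions, not the chemistry of any
particular real dataset.

## Numerical and reporting choices

- Fit tolerances: NNLS is exact to machine precision for this 2-column
  problem; tests verify agreement with an exhaustive step-1 grid search
  and with the closed-form normal equations on interior optima.
- `D_P` from a measurement requires `cw > 0`; zero concentration is a
  domain error, not a silent infinity.
- CV is undefined (reported absent) for fewer than two values or a zero
  mean. Censoring is strict: exactly 50 L kg⁻¹ is reported numerically.
- Machine-readable CSVs serialize numbers in scientific notation with 12
  significant digits (lossless round trips at that precision); the
  human-facing censored report table uses 6 significant digits plus
  numeric shadow columns.
- Pipeline runs are deterministic given inputs and seed: sorted
  grouping, fixed formatting, results to files, logs to stderr.

## Problem sizes in tests and the acceptance script

Monte-Carlo suites use 200 seeded studies for recovery statistics
(median relative error of `K_P,n` and `K_P,i` at ε = 5%) and 500 for the
recovery-distribution band; the grid-search oracle checks 25 random
instances on a 2001×2001 grid via the quadratic expansion of the
objective. These sizes give stable medians and percentile bands while
keeping the default suite fast.

## Known limitations

- Monoprotic speciation only; compounds with a second relevant pKa are
  approximated by their listed class.
- The censoring threshold, derived for LSR 10³ L kg⁻¹, is not rescaled
  automatically if a pipeline is run with a different batch geometry —
  set `censor_threshold` in the run configuration accordingly.
- Coefficients of species that barely appear over the tested pH range
  (maximum fraction of a few percent) are numerically defined but
  carry enormous estimation variance; the indeterminacy flag only
  triggers below 1%, so intermediate cases rely on the CV warning.
- Scenario results assume linear, reversible partitioning with a single
  organic-carbon pool; black carbon, DOM and field-observed non-linear
  `K_d` effects are out of scope.
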