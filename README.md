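# phsorb

Tools for analysing pH-dependent sorption of ionizable organic pollutants
(pharmaceuticals, pesticides, personal-care compounds) to microplastic
particles such as polyethylene (PE) and polystyrene (PS). The package is
aimed at environmental chemists who run equilibrium batch experiments and
want to go from measured aqueous concentrations to species-specific
partition coefficients, to an honest statement of how reliable those
coefficients are, and to equilibrium distribution scenarios for real
water bodies.

## The model

A compound partitions linearly between water and plastic with
coefficient `K_P = c_P / c_W` (L kg⁻¹). An ionizable compound is a
pH-dependent mixture of its neutral and ionized species, so the overall
(observable) distribution coefficient is the speciation-weighted sum

```
D_P(pH) = K_P,n · f_n(pH) + K_P,i · f_i(pH)
```

with the neutral fraction from the rearranged Henderson–Hasselbalch
equation (`f_n = 1/(1+10^(pH−pKa))` for acids, mirrored for bases) and
`f_i = 1 − f_n`. Measuring `D_P` at several pH levels and fitting this
model — linear in `(K_P,n, K_P,i)`, solved by non-negative least
squares — separates the two species' coefficients.

Batch depletion experiments can only resolve coefficients comparable to
their liquid-to-solid ratio (LSR = V_W/m_P). A first-order error budget
for relative analytical noise ε,

```
(K_P,c − K_P,m)/K_P,c = ε/(1+ε) · (1 + LSR/K_P,c),
```

inverts to the minimum reliably determinable coefficient; at ε = 5%, a
100% error bound and LSR = 10³ L kg⁻¹ that is 50 L kg⁻¹, which is where
reported coefficients are censored. Finally, the dissolved fraction in a
water body with organic carbon and microplastics as competing sorbents is

```
f_diss = 1 / (1 + K_OC·m_OC/V_W + K_P·m_P/V_W).
```

## Worked example

Simulate one triplicate batch study (pH {4, 7, 10}, LSR 10³ L kg⁻¹, 5%
analytical noise) for an acid with known ground truth and recover the
species coefficients (`examples/02_fit_species_coefficients.py`):

```
pH    mean D_P (L/kg)   CV%     n
4            927.7      9.9     9
7            110.3     57.0     9
10           105.7     37.8     9

fitted K_P,n = 1010.1 L/kg   (truth 1000)
fitted K_P,i = 103.5 L/kg   (truth 100)
```

`D_P` falls from ~930 to ~105 L kg⁻¹ as the acid deprotonates, and the
fit recovers both coefficients to within a few percent. Note the CV
rising from 10% to ~50% as sorption weakens — exactly the reliability
loss the error model predicts for `D_P` below the LSR.

The other examples cover speciation plus the <1% solubility design
screen (`01`), the reliability threshold and error map (`03`), and the
laboratory-vs-environment scenario contrast (`04`). A thin CLI mirrors
the stages (`phsorb speciate|dp|fit|uncertainty|scenario|simulate|run`).

Three data tables ship with the package: the 19-compound property table
(molecular weight, log K_OW, pKa, acid/base class, subcooled-liquid
solubility) and the published fitted-coefficient tables for PE and PS,
used as regression references for the reporting layer and as default
ground truths for the synthetic study generator.

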