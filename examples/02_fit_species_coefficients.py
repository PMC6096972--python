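"""Fit species-specific partition coefficients from a synthetic study.

Simulates one triplicate batch study (pH {4, 7, 10}, LSR 1e3 L/kg, 5%
analytical noise) for an acid with known ground truth, converts each
measured aqueous concentration to a distribution coefficient D_P, and
fits the two-species model by non-negative least squares.
"""

from phsorb import (
    BatchCondition,
    SyntheticTruth,
    aggregate_dp,
    dp_from_measurement,
    fit_species_k,
    simulate_batch,
)

TRUTH = SyntheticTruth(
    name="demo-acid", kp_n=1000.0, kp_i=100.0, pka=5.0, ion_class="acid",
    epsilon=0.05, seed=11,
)

observations = []
print("pH    mean D_P (L/kg)   CV%     n")
for ph in (4.0, 7.0, 10.0):
    cond = BatchCondition(vw=0.1, mp=1e-4, c0=5.0, ph=ph)
    batch = simulate_batch(TRUTH, cond)
    values = [
        dp_from_measurement(cond, m.cw)
        for m in batch.measurements
        if m.time_days > 0
    ]
    est = aggregate_dp(values, ph)
    observations.extend((ph, v) for v in values)
    print(f"{ph:<5g} {est.dp_mean:>12.1f} {est.cv_percent:>8.1f} {est.n_obs:>5d}")

fit = fit_species_k(observations, TRUTH.pka, TRUTH.ion_class)
print(f"\nfitted K_P,n = {fit.kp_n:.1f} L/kg   (truth {TRUTH.kp_n:g})")
print(f"fitted K_P,i = {fit.kp_i:.1f} L/kg   (truth {TRUTH.kp_i:g})")
print(
    "\nD_P falls with pH because the acid deprotonates and the ionized"
    "\nspecies sorbs ten-fold weaker; the fit disentangles the two"
    "\nspecies coefficients from the pH trend."
)
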