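"""Synthetic batch-experiment generator.

Emulates the study design end to end so fitting, censoring and the
uncertainty analysis can be exercised without any external data:
triplicate batches at pH {4, 7, 10}, liquid-to-solid ratio 1e3 L/kg
(100 mg plastic in 100 mL), initial concentrations of 5 ug/L (50 for
phenanthrene, 30 for nonylphenol), post-day-0 sampling at days {2, 4, 7}
for polyethylene and {2, 4, 7, 11} for polystyrene.

The generator assumes equilibrium at every sampled time (kinetics are out
of scope), computes the noise-free aqueous concentration from the
two-species model and the batch mass balance,

    cw = c0 / (1 + D_P(pH) * mp/vw),

and applies multiplicative Gaussian analytical noise on concentrations,
cw_obs = cw * (1 + eps*z), truncated below at 1e-6*c0 to keep
concentrations positive. Day-0 samples are drawn around c0 with the same
noise. A single global seed fans out to per-batch substreams keyed by
(compound, polymer, pH, replicate), so adding a compound never perturbs
another compound's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .batch import BatchCondition, BatchDataset, Measurement, model_dp
from .compounds import CompoundRecord, neutral_fraction
from .errors import InvalidInputError

#: Post-day-0 sampling times (days) per polymer design.
PE_TIMES: tuple[float, ...] = (2.0, 4.0, 7.0)
PS_TIMES: tuple[float, ...] = (2.0, 4.0, 7.0, 11.0)
DESIGN_TIMES = {"PE": PE_TIMES, "PS": PS_TIMES}

#: Batch pH levels and replication of the study design.
DESIGN_PHS: tuple[float, ...] = (4.0, 7.0, 10.0)
N_REPLICATES = 3

#: Batch geometry: 100 mL of solution over 100 mg of plastic.
VW_L = 0.1
MP_KG = 1e-4

#: Initial concentrations, ug/L.
DEFAULT_C0 = 5.0
SPECIAL_C0 = {"phenanthrene": 50.0, "4-nonylphenol": 30.0, "nonylphenol": 30.0}

_CW_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters for one simulated compound.

    ``epsilon`` is the relative standard deviation of the multiplicative
    analytical noise; ``seed`` the global seed the per-batch substreams
    derive from.
    """

    name: str
    kp_n: float
    kp_i: float
    pka: float | None
    ion_class: str
    epsilon: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kp_n < 0 or self.kp_i < 0:
            raise InvalidInputError("kp_n and kp_i must be >= 0")
        if self.epsilon < 0:
            raise InvalidInputError("epsilon must be >= 0")


def _substream(seed: int, *key: object) -> np.random.Generator:
    """Deterministic per-batch random stream.

    The key is hashed with CRC-32 (stable across runs and platforms) and
    combined with the global seed into a SeedSequence.
    """
    digest = zlib.crc32(repr(key).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, digest]))


def default_c0(name: str) -> float:
    """Study initial concentration (ug/L) for a compound name."""
    return SPECIAL_C0.get(name.strip().lower(), DEFAULT_C0)


def equilibrium_cw(truth: SyntheticTruth, cond: BatchCondition) -> float:
    """Noise-free equilibrium aqueous concentration, ug/L.

    Mass balance with D_P from the two-species model at the batch pH:
    cw = c0 / (1 + D_P * mp/vw). Mass is conserved exactly:
    cw*vw + (D_P*cw)*mp = c0*vw.
    """
    spec = neutral_fraction(cond.ph, truth.pka, truth.ion_class)
    dp = model_dp(truth.kp_n, truth.kp_i, spec)
    return cond.c0 / (1.0 + dp / cond.lsr)


def simulate_batch(
    truth: SyntheticTruth,
    cond: BatchCondition,
    n_replicates: int = N_REPLICATES,
    sample_times: Sequence[float] = PE_TIMES,
    *,
    stream_key: tuple = (),
) -> BatchDataset:
    """Simulate one batch condition with replicate noisy measurements.

    Each replicate gets a day-0 sample drawn around c0 and one sample per
    entry of ``sample_times`` drawn around the equilibrium concentration,
    all with multiplicative noise 1 + eps*z (z standard normal) truncated
    below at 1e-6*c0.

    Raises
    ------
    InvalidInputError
        If epsilon >= 1 (the multiplicative noise model breaks down),
        n_replicates < 1, or sample_times is empty.
    """
    if truth.epsilon >= 1.0:
        raise InvalidInputError(
            f"epsilon must be < 1 for multiplicative noise, got {truth.epsilon}"
        )
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    if len(sample_times) == 0:
        raise InvalidInputError("sample_times must be non-empty")

    floor = _CW_FLOOR_FRACTION * cond.c0
    measurements: list[Measurement] = []
    cw_eq = equilibrium_cw(truth, cond)
    for rep in range(1, n_replicates + 1):
        rng = _substream(truth.seed, *stream_key, truth.name, cond.ph, rep)
        noise = 1.0 + truth.epsilon * rng.standard_normal(1 + len(sample_times))
        cw0 = max(cond.c0 * noise[0], floor)
        measurements.append(Measurement(replicate=rep, time_days=0.0, cw=cw0))
        for t, z in zip(sample_times, noise[1:]):
            cw = max(cw_eq * z, floor)
            measurements.append(
                Measurement(replicate=rep, time_days=float(t), cw=cw)
            )
    return BatchDataset(condition=cond, measurements=tuple(measurements))


MEASUREMENT_COLUMNS = [
    "compound",
    "polymer",
    "ph",
    "replicate",
    "time_days",
    "c0_ug_per_L",
    "cw_ug_per_L",
]


def generate_study_fixture(
    compound_table: Sequence[CompoundRecord],
    truth_table: Sequence[SyntheticTruth],
    seed: int,
) -> pd.DataFrame:
    """Full synthetic measurement table emulating the study layout.

    One row per compound x polymer x pH x replicate x sampling time (the
    day-0 sample included), in the measurement CSV dialect. Truth rows
    are aligned to compound records by name; a mismatch is an error.

    The paper-style ground truths (fitted coefficients of the published
    result tables, censored entries replaced by a small sub-threshold
    value) are available via :func:`truths_from_fit_table`.
    """
    compounds = {c.name: c for c in compound_table}
    rows: list[dict] = []
    for truth in truth_table:
        if truth.name not in compounds:
            raise InvalidInputError(
                f"truth for {truth.name!r} has no matching compound record"
            )
        c0 = default_c0(truth.name)
        for polymer, times in DESIGN_TIMES.items():
            seeded = replace(truth, seed=seed)
            for ph in DESIGN_PHS:
                cond = BatchCondition(vw=VW_L, mp=MP_KG, c0=c0, ph=ph)
                ds = simulate_batch(
                    seeded,
                    cond,
                    N_REPLICATES,
                    times,
                    stream_key=(polymer,),
                )
                for m in ds.measurements:
                    rows.append(
                        {
                            "compound": truth.name,
                            "polymer": polymer,
                            "ph": ph,
                            "replicate": m.replicate,
                            "time_days": m.time_days,
                            "c0_ug_per_L": c0,
                            "cw_ug_per_L": m.cw,
                        }
                    )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


#: Stand-in truth (L/kg) for coefficients the result tables censor at
#: 50 L/kg: well below half the threshold so the simulated censoring
#: pattern is noise-robust.
CENSORED_TRUTH_VALUE = 10.0


def truths_from_fit_table(
    fit_table: pd.DataFrame,
    compound_table: Sequence[CompoundRecord],
    *,
    epsilon: float = 0.05,
    seed: int = 0,
    censored_value: float = CENSORED_TRUTH_VALUE,
) -> list[SyntheticTruth]:
    """Build ground truths from a parsed fit-report table.

    ``fit_table`` is the frame returned by :func:`phsorb.io.read_fit_table`
    (columns ``compound``, ``kp_n_value``, ``kp_i_value``, censored/na
    flags). Censored coefficients have no published value and are
    replaced by ``censored_value``; "n.a." entries by zero.
    """
    by_name = {c.name: c for c in compound_table}
    truths = []
    for row in fit_table.itertuples(index=False):
        comp = by_name.get(row.compound)
        if comp is None:
            raise InvalidInputError(
                f"fit table compound {row.compound!r} not in compound table"
            )
        kp_n = censored_value if row.kp_n_censored else row.kp_n_value
        if row.kp_i_na:
            kp_i = 0.0
        elif row.kp_i_censored:
            kp_i = censored_value
        else:
            kp_i = row.kp_i_value
        truths.append(
            SyntheticTruth(
                name=comp.name,
                kp_n=float(kp_n),
                kp_i=float(kp_i),
                pka=comp.pka,
                ion_class=comp.ion_class,
                epsilon=epsilon,
                seed=seed,
            )
        )
    return truths
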