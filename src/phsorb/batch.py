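"""Batch sorption mass balance and the two-species distribution model.

A closed batch equilibrates a water volume ``vw`` (L) holding an initial
concentration ``c0`` (ug/L) with a plastic mass ``mp`` (kg). At
equilibrium, linear partitioning defines K_P = c_P / c_W (L/kg), and the
sorbed-phase concentration follows from mass balance, so a single measured
aqueous concentration ``cw`` gives the overall distribution coefficient

    D_P = ((c0 - cw) / cw) * (vw / mp).

D_P is pH dependent for ionizable compounds and mixes the species-specific
coefficients by the speciation fractions:

    D_P(pH) = K_P,n * f_n(pH) + K_P,i * f_i(pH).

Measurement noise can push cw above c0 and make individual D_P values
negative; they are kept (dropping them would bias weakly sorbing compounds
upward) and only the sorbed-fraction report clamps at zero. Replicate
scatter is summarized by the coefficient of variation, CV% = 100 * sample
standard deviation / |mean|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .compounds import Speciation
from .errors import InvalidInputError


@dataclass(frozen=True)
class BatchCondition:
    """Physical conditions of one batch: water volume (L), plastic mass
    (kg), initial aqueous concentration (ug/L) and pH."""

    vw: float
    mp: float
    c0: float
    ph: float

    def __post_init__(self) -> None:
        for field in ("vw", "mp", "c0"):
            if not getattr(self, field) > 0:
                raise InvalidInputError(
                    f"{field} must be > 0, got {getattr(self, field)}"
                )

    @property
    def lsr(self) -> float:
        """Liquid-to-solid ratio vw/mp in L/kg."""
        return self.vw / self.mp


@dataclass(frozen=True)
class Measurement:
    """One aqueous-concentration measurement within a batch."""

    replicate: int
    time_days: float
    cw: float

    def __post_init__(self) -> None:
        if self.cw < 0:
            raise InvalidInputError(f"cw must be >= 0, got {self.cw}")
        if self.time_days < 0:
            raise InvalidInputError(f"time_days must be >= 0, got {self.time_days}")


@dataclass(frozen=True)
class BatchDataset:
    """A batch condition together with its replicate measurements."""

    condition: BatchCondition
    measurements: tuple[Measurement, ...]


@dataclass(frozen=True)
class DpEstimate:
    """Per-pH summary of individual D_P values.

    ``cv_percent`` is None when the mean is zero or there are fewer than
    two values (scatter undefined).
    """

    ph: float
    dp_mean: float
    cv_percent: float | None
    n_obs: int


def dp_from_measurement(cond: BatchCondition, cw: float) -> float:
    """Overall distribution coefficient from one aqueous measurement.

    Returns ((c0 - cw)/cw) * (vw/mp) in L/kg. Negative when noise puts
    cw above c0; returned unclamped.

    Raises
    ------
    InvalidInputError
        If cw <= 0 (the mass-balance model is undefined at zero aqueous
        concentration).
    """
    if not cw > 0:
        raise InvalidInputError(
            f"cw must be > 0 for a finite D_P, got {cw}"
        )
    return (cond.c0 - cw) / cw * cond.lsr


def aggregate_dp(values: Sequence[float], ph: float) -> DpEstimate:
    """Aggregate individual D_P values at one pH into mean, CV% and count.

    CV uses the sample (n-1) standard deviation normalized to the
    absolute mean, in percent.
    """
    if len(values) == 0:
        raise InvalidInputError("cannot aggregate an empty list of D_P values")
    n = len(values)
    mean = sum(values) / n
    if n < 2 or mean == 0.0:
        cv = None
    else:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        cv = 100.0 * math.sqrt(var) / abs(mean)
    return DpEstimate(ph=ph, dp_mean=mean, cv_percent=cv, n_obs=n)


def model_dp(kp_n: float, kp_i: float, spec: Speciation) -> float:
    """Two-species distribution coefficient K_P,n*f_n + K_P,i*f_i (L/kg).

    For neutral compounds (f_n = 1) this is K_P,n at every pH.
    """
    if kp_n < 0 or kp_i < 0:
        raise InvalidInputError(
            f"species partition coefficients must be >= 0, got ({kp_n}, {kp_i})"
        )
    return kp_n * spec.f_n + kp_i * spec.f_i


def sorbed_fraction(dp: float, lsr: float) -> float:
    """Fraction of total compound mass on the plastic at equilibrium.

    Equals dp / (dp + lsr); negative dp (a noise artifact) is reported
    as zero sorption.
    """
    if not lsr > 0:
        raise InvalidInputError(f"lsr must be > 0, got {lsr}")
    if dp <= 0:
        return 0.0
    return dp / (dp + lsr)
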