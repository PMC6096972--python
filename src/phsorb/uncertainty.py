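"""Reliability of batch-derived partition coefficients.

In a depletion batch the sorbed mass is inferred from the drop in aqueous
concentration. When the partition coefficient is small relative to the
liquid-to-solid ratio (LSR = vw/mp), that drop is tiny and analytical
noise dominates. A first-order error budget for a relative analytical
uncertainty eps gives the relative deviation between the true (calculated)
and the measured partition coefficient:

    (K_P,c - K_P,m) / K_P,c = eps/(1+eps) * (1 + (vw/mp) / K_P,c).

The expression decreases monotonically in K_P,c toward the analytical
floor eps/(1+eps), and grows without bound as K_P,c shrinks below the
LSR. Inverting it at a maximum tolerable relative error E yields the
smallest reliably determinable coefficient,

    K_P,min = LSR / (E*(1+eps)/eps - 1),

which, at eps = 5%, E = 100% and LSR = 1e3 L/kg, is 50 L/kg — the
censoring threshold used in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleError, InvalidInputError


@dataclass(frozen=True)
class ErrorModel:
    """Analytical-uncertainty model for one batch design.

    Parameters
    ----------
    epsilon : float
        Relative analytical uncertainty of a concentration measurement
        (e.g. 0.05 for 5%); must lie in (0, 1).
    vw : float
        Water volume, L.
    mp : float
        Plastic mass, kg.
    """

    epsilon: float
    vw: float
    mp: float

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise InvalidInputError(
                f"epsilon must lie in (0, 1), got {self.epsilon}"
            )
        if not (self.vw > 0 and self.mp > 0):
            raise InvalidInputError("vw and mp must be > 0")

    @property
    def lsr(self) -> float:
        return self.vw / self.mp

    @property
    def error_floor(self) -> float:
        """Limit of the relative error as K_P -> infinity: eps/(1+eps)."""
        return self.epsilon / (1.0 + self.epsilon)


def relative_error(model: ErrorModel, kp_c: float) -> float:
    """Relative deviation (K_P,c - K_P,m)/K_P,c at a true coefficient kp_c."""
    if not kp_c > 0:
        raise InvalidInputError(f"kp_c must be > 0, got {kp_c}")
    return model.error_floor * (1.0 + model.lsr / kp_c)


def min_reliable_kp(model: ErrorModel, max_error: float) -> float:
    """Smallest K_P determinable within a relative-error bound.

    Inverts the error model: K_P,min = lsr / (max_error*(1+eps)/eps - 1).
    ``relative_error`` at the returned value equals ``max_error`` exactly
    (round-trip identity).

    Raises
    ------
    InfeasibleError
        If ``max_error`` does not exceed the analytical floor
        eps/(1+eps), which no coefficient can beat.
    """
    if not max_error > 0:
        raise InvalidInputError(f"max_error must be > 0, got {max_error}")
    if max_error <= model.error_floor:
        raise InfeasibleError(
            f"max_error {max_error} is at or below the analytical floor "
            f"{model.error_floor:.6g}; unattainable at any K_P"
        )
    return model.lsr / (max_error / model.error_floor - 1.0)


def error_map(
    model: ErrorModel,
    kp_grid: Sequence[float],
    epsilons: Sequence[float],
) -> pd.DataFrame:
    """Relative-error table over a K_P grid for several analytical errors.

    Rows are indexed by K_P (L/kg), columns by epsilon; the model's own
    epsilon is superseded column by column while its LSR is kept. Suitable
    for plotting error-vs-K_P curves per epsilon.
    """
    kp = np.asarray(list(kp_grid), dtype=float)
    if kp.size == 0 or len(epsilons) == 0:
        raise InvalidInputError("kp_grid and epsilons must be non-empty")
    data = {}
    for eps in epsilons:
        m = ErrorModel(epsilon=float(eps), vw=model.vw, mp=model.mp)
        data[float(eps)] = m.error_floor * (1.0 + m.lsr / kp)
    df = pd.DataFrame(data, index=kp)
    df.index.name = "kp_L_per_kg"
    df.columns.name = "epsilon"
    return df
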