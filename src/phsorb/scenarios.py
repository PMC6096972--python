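"""Multi-sorbent equilibrium distribution in a water body.

A freshwater parcel contains two competing sorbents: natural organic
carbon at concentration m_OC/V_W and microplastic particles at loading
m_P/V_W (the reciprocal of the plastic liquid-to-solid ratio). At
equilibrium the freely dissolved fraction of a compound is

    f_diss = 1 / (1 + K_OC * m_OC/V_W + K_P * m_P/V_W),

and the OC-bound and plastic-bound fractions follow as
K_OC*(m_OC/V_W)*f_diss and K_P*(m_P/V_W)*f_diss; the three close to one.

Two presets contrast a laboratory batch with the environment, both with
1e-5 kg/L organic carbon:

* Scenario I  — plastic LSR 1e3 L/kg (the batch-experiment loading);
* Scenario II — plastic LSR 1e10 L/kg (wastewater-effluent particle
  counts). At such loadings plastics bind a negligible share of any
  compound with K_P in the measured range (<= ~1e4 L/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class ScenarioSpec:
    """Sorbent loadings of a water body.

    Parameters
    ----------
    lsr_plastic : float
        Water volume per plastic mass, L/kg (> 0).
    oc_conc : float
        Organic-carbon concentration m_OC/V_W, kg/L (>= 0).
    c0 : float
        Total (initial) concentration, ug/L; default 5.
    """

    lsr_plastic: float
    oc_conc: float
    c0: float = 5.0

    def __post_init__(self) -> None:
        if not self.lsr_plastic > 0:
            raise InvalidInputError("lsr_plastic must be > 0")
        if self.oc_conc < 0:
            raise InvalidInputError("oc_conc must be >= 0")
        if not self.c0 > 0:
            raise InvalidInputError("c0 must be > 0")


#: Laboratory-like loading: plastic LSR of the batch experiments.
SCENARIO_I = ScenarioSpec(lsr_plastic=1e3, oc_conc=1e-5)
#: Environmental loading: plastic LSR typical of WWTP effluents.
SCENARIO_II = ScenarioSpec(lsr_plastic=1e10, oc_conc=1e-5)


@dataclass(frozen=True)
class ScenarioResult:
    """Dissolved fraction and equilibrium aqueous concentration at one
    (K_OC, K_P) point."""

    koc: float
    kp: float
    f_diss: float
    cw_eq: float


def dissolved_fraction(spec: ScenarioSpec, koc: float, kp: float) -> float:
    """Freely dissolved fraction at equilibrium, in (0, 1].

    Equals 1 when both sorption terms vanish.
    """
    if koc < 0 or kp < 0:
        raise InvalidInputError(
            f"koc and kp must be >= 0, got ({koc}, {kp})"
        )
    return 1.0 / (1.0 + koc * spec.oc_conc + kp / spec.lsr_plastic)


def mass_fractions(
    spec: ScenarioSpec, koc: float, kp: float
) -> tuple[float, float, float]:
    """(dissolved, OC-bound, plastic-bound) mass fractions; sum to 1."""
    f_diss = dissolved_fraction(spec, koc, kp)
    f_oc = koc * spec.oc_conc * f_diss
    f_plastic = (kp / spec.lsr_plastic) * f_diss
    return f_diss, f_oc, f_plastic


def default_grid(lo: float = 0.0, hi: float = 7.0, n: int = 71) -> np.ndarray:
    """Log-spaced K grid (L/kg), default 10^0 .. 10^7 with 71 points —
    spans the fitted plastic coefficients and typical K_OC ranges."""
    return np.logspace(lo, hi, n)


def scenario_map(
    spec: ScenarioSpec,
    koc_grid: Sequence[float] | None = None,
    kp_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Full outer grid of dissolved fractions over (K_OC, K_P).

    Returns a long-format frame with columns ``koc``, ``kp``, ``f_diss``
    and ``cw_eq`` (= c0 * f_diss, ug/L).
    """
    koc = np.asarray(
        default_grid() if koc_grid is None else list(koc_grid), dtype=float
    )
    kp = np.asarray(
        default_grid() if kp_grid is None else list(kp_grid), dtype=float
    )
    if koc.size == 0 or kp.size == 0:
        raise InvalidInputError("grids must be non-empty")
    if np.any(koc < 0) or np.any(kp < 0):
        raise InvalidInputError("grid values must be >= 0")
    kk, pp = np.meshgrid(koc, kp, indexing="ij")
    f = 1.0 / (1.0 + kk * spec.oc_conc + pp / spec.lsr_plastic)
    return pd.DataFrame(
        {
            "koc": kk.ravel(),
            "kp": pp.ravel(),
            "f_diss": f.ravel(),
            "cw_eq": spec.c0 * f.ravel(),
        }
    )


def overlay_points(
    spec: ScenarioSpec,
    points: Iterable[tuple[str, float, float, float]],
) -> pd.DataFrame:
    """Evaluate user-supplied compound overlays on a scenario.

    ``points`` holds (name, koc, kp, ph) tuples — K_OC values are not
    bundled with the package and must come from the caller.
    """
    rows = []
    for name, koc, kp, ph in points:
        f = dissolved_fraction(spec, koc, kp)
        rows.append(
            {
                "name": name,
                "ph": ph,
                "koc": koc,
                "kp": kp,
                "f_diss": f,
                "cw_eq": spec.c0 * f,
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "ph", "koc", "kp", "f_diss", "cw_eq"]
    )


def lsr_gap(lsr_env: float, lsr_exp: float) -> float:
    """Orders of magnitude between an environmental and an experimental
    liquid-to-solid ratio: log10(lsr_env / lsr_exp)."""
    if not (lsr_env > 0 and lsr_exp > 0):
        raise InvalidInputError("both LSR values must be > 0")
    return math.log10(lsr_env / lsr_exp)
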