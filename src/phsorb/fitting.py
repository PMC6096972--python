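"""Species-specific partition coefficients by constrained least squares.

The two-species model D_P = K_P,n*f_n + K_P,i*f_i is linear in the
coefficients, so fitting it to measured D_P values across pH is a
non-negative linear least-squares problem in (K_P,n, K_P,i): the design
matrix holds the speciation fractions (f_n, f_i) per observation and the
response the per-measurement D_P values. The non-negativity bound is
physical — partition coefficients below zero are meaningless — and keeps
noisy, weakly sorbing designs from dragging K_P,i negative.

Reporting rules: coefficients below 50 L/kg are censored (rendered as a
"< 5e+01" token) because at the study's liquid-to-solid ratio smaller
values cannot be reliably determined; per-pH D_P estimates with CV > 100%
carry a warning flag. The numeric values are retained internally for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import nnls

from .batch import DpEstimate
from .compounds import neutral_fraction
from .errors import IdentifiabilityError, InvalidDesignError, InvalidInputError

#: Below this value (L/kg) a fitted coefficient is censored in reports.
CENSOR_THRESHOLD = 50.0
#: Per-pH D_P estimates with CV above this (%) carry a warning flag.
CV_FLAG_THRESHOLD = 100.0
#: A species whose maximum fraction over the design is below this is
#: unidentifiable and its coefficient is reported "n.a.".
INDETERMINACY_F_MIN = 0.01

NA_TOKEN = "n.a."


def censor_token(threshold: float = CENSOR_THRESHOLD) -> str:
    """Report token for a censored coefficient, e.g. ``"<5e+01"``."""
    return f"<{threshold:.0e}"


@dataclass
class SpeciesPartitionFit:
    """Result of fitting the two-species model to D_P observations.

    Attributes
    ----------
    kp_n, kp_i : float
        Fitted species-specific partition coefficients (L/kg), >= 0.
    rss : float
        Residual sum of squares of the fit, (L/kg)^2.
    n_points : int
        Number of (pH, D_P) observations used.
    kp_n_censored, kp_i_censored : bool
        True when the coefficient falls strictly below the censoring
        threshold (50 L/kg by default).
    kp_i_indeterminate : bool
        True when the ionized species never exceeds 1% of the mixture
        over the design, so kp_i carries no information ("n.a.").
    cv_flags : dict
        Per-pH flag (CV > 100%), filled in by :func:`censor_fit`.
    """

    kp_n: float
    kp_i: float
    rss: float
    n_points: int
    kp_n_censored: bool
    kp_i_censored: bool
    kp_i_indeterminate: bool
    cv_flags: dict[float, bool] = field(default_factory=dict)


def design_matrix(
    phs: Sequence[float], pka: float | None, ion_class: str
) -> np.ndarray:
    """(n, 2) matrix of (f_n, f_i) rows for the given pH values."""
    rows = [neutral_fraction(ph, pka, ion_class) for ph in phs]
    return np.array([[s.f_n, s.f_i] for s in rows], dtype=float)


def fit_species_k(
    observations: Sequence[tuple[float, float]],
    pka: float | None,
    ion_class: str,
    *,
    censor_threshold: float = CENSOR_THRESHOLD,
    mode: str = "pooled",
) -> SpeciesPartitionFit:
    """Fit (K_P,n, K_P,i) >= 0 to (pH, D_P) observations.

    Parameters
    ----------
    observations : sequence of (ph, dp)
        Individual D_P values; negative D_P (noise) are legal inputs.
    pka, ion_class :
        Speciation parameters of the compound; ``"neutral"`` is accepted
        (f_n = 1 everywhere, kp_i indeterminate).
    censor_threshold : float
        Censoring threshold in L/kg for the report flags.
    mode : {"pooled", "ph_mean"}
        ``"pooled"`` (default) fits all individual D_P values;
        ``"ph_mean"`` first averages D_P per pH and fits the means.

    Returns
    -------
    SpeciesPartitionFit

    Raises
    ------
    InvalidDesignError
        Fewer than two observations or fewer than two distinct pH values.
    IdentifiabilityError
        f_n is constant across the design while both species are present
        above the indeterminacy floor: only the mixture is estimable.
    """
    if mode not in ("pooled", "ph_mean"):
        raise InvalidInputError(f"unknown fit mode {mode!r}")
    obs = [(float(ph), float(dp)) for ph, dp in observations]
    if len(obs) < 2:
        raise InvalidDesignError(
            f"need >= 2 observations to fit two coefficients, got {len(obs)}"
        )
    distinct_ph = sorted({ph for ph, _ in obs})
    if len(distinct_ph) < 2:
        raise InvalidDesignError(
            f"need >= 2 distinct pH values, got {distinct_ph}"
        )

    if mode == "ph_mean":
        obs = [
            (ph, float(np.mean([dp for p, dp in obs if p == ph])))
            for ph in distinct_ph
        ]

    phs = [ph for ph, _ in obs]
    y = np.array([dp for _, dp in obs], dtype=float)
    a = design_matrix(phs, pka, ion_class)

    f_n = a[:, 0]
    f_i = a[:, 1]
    indeterminate = bool(f_i.max() < INDETERMINACY_F_MIN)
    if np.ptp(f_n) < 1e-9 and not indeterminate:
        raise IdentifiabilityError(
            "neutral fraction is identical across the design; only the "
            "mixture K_P,n*f_n + K_P,i*f_i is identifiable"
        )

    coef, rnorm = nnls(a, y)
    kp_n, kp_i = float(coef[0]), float(coef[1])
    return SpeciesPartitionFit(
        kp_n=kp_n,
        kp_i=kp_i,
        rss=float(rnorm**2),
        n_points=len(obs),
        kp_n_censored=kp_n < censor_threshold,
        kp_i_censored=kp_i < censor_threshold,
        kp_i_indeterminate=indeterminate,
    )


def format_coefficient(
    value: float,
    censored: bool,
    indeterminate: bool = False,
    *,
    threshold: float = CENSOR_THRESHOLD,
    sig: int = 6,
) -> str:
    """Render a coefficient for reports: numeric in scientific notation,
    the censor token when below threshold, or "n.a." when the species is
    absent from the design."""
    if indeterminate:
        return NA_TOKEN
    if censored:
        return censor_token(threshold)
    return f"{value:.{sig - 1}e}"


def censor_fit(
    fit: SpeciesPartitionFit,
    dp_estimates: Sequence[DpEstimate],
    *,
    censor_threshold: float = CENSOR_THRESHOLD,
    cv_flag_threshold: float = CV_FLAG_THRESHOLD,
) -> dict[str, Any]:
    """Apply the reporting rules to a fit and its per-pH D_P summaries.

    Censoring (coefficient strictly below the threshold) and the CV
    warning (per-pH CV > 100%) are independent annotations: the first
    acts on fitted coefficients, the second on measured replicate
    scatter. Numeric values are kept as shadow fields.

    Returns a JSON-ready dict with rendered tokens, numeric shadows,
    per-pH CV values and flags, n_points and rss.
    """
    kp_n_censored = fit.kp_n < censor_threshold
    kp_i_censored = fit.kp_i < censor_threshold
    cv_percent: dict[float, float | None] = {}
    cv_flags: dict[float, bool] = {}
    for est in dp_estimates:
        cv_percent[est.ph] = est.cv_percent
        cv_flags[est.ph] = (
            est.cv_percent is not None and est.cv_percent > cv_flag_threshold
        )
    fit.cv_flags = dict(cv_flags)
    fit.kp_n_censored = kp_n_censored
    fit.kp_i_censored = kp_i_censored
    return {
        "kp_n": format_coefficient(
            fit.kp_n, kp_n_censored, threshold=censor_threshold
        ),
        "kp_n_value": fit.kp_n,
        "kp_n_censored": kp_n_censored,
        "kp_i": format_coefficient(
            fit.kp_i,
            kp_i_censored,
            fit.kp_i_indeterminate,
            threshold=censor_threshold,
        ),
        "kp_i_value": fit.kp_i,
        "kp_i_censored": kp_i_censored,
        "kp_i_indeterminate": fit.kp_i_indeterminate,
        "cv_percent": cv_percent,
        "cv_flags": cv_flags,
        "n_points": fit.n_points,
        "rss": fit.rss,
    }
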