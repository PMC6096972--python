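"""Compound physico-chemical properties and acid/base speciation.

An ionizable pollutant partitions to a sorbent as a mixture of its neutral
and ionized species. The split between the two at a given pH follows from
the Henderson–Hasselbalch relation: for a monoprotic acid the neutral
(protonated) fraction is

    f_n = 1 / (1 + 10**(pH - pKa)),

and for a base (pKa of the conjugate acid) the neutral (deprotonated)
fraction is the mirror image

    f_n = 1 / (1 + 10**(pKa - pH)).

Neutral compounds have f_n = 1 at every pH. The ionized fraction is stored
as f_i = 1 - f_n so the two always sum to one exactly.

This module also carries the batch-design screen that checks an initial
concentration against the compound's (subcooled-liquid) water solubility:
keeping c0 below 1% of solubility avoids competitive sorption and
non-linear isotherm effects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InvalidInputError

ION_CLASSES = ("acid", "base", "neutral")

#: CAS registry number: 2-7 digits, 2 digits, 1 check digit.
_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's identity and sorption-relevant properties.

    Parameters
    ----------
    name : str
        Compound name (unique key across the tables).
    cas : str
        CAS registry number, ``digits-digits-digit``.
    mw : float
        Molecular weight in g/mol, > 0.
    log_kow : float
        log10 octanol-water partition coefficient of the neutral species.
    pka : float or None
        Dissociation constant; for bases the conjugate-acid pKa.
        None if and only if the compound is neutral.
    ion_class : str
        ``"acid"``, ``"base"`` or ``"neutral"``.
    ws_sub : float or None
        Subcooled-liquid water solubility in mol/L; None for compounds
        that are liquids at room temperature (no meaningful subcooled
        reference state on record).
    """

    name: str
    cas: str
    mw: float
    log_kow: float
    pka: float | None
    ion_class: str
    ws_sub: float | None = None

    def __post_init__(self) -> None:
        if self.ion_class not in ION_CLASSES:
            raise InvalidInputError(
                f"{self.name}: ion_class must be one of {ION_CLASSES}, "
                f"got {self.ion_class!r}"
            )
        if (self.pka is None) != (self.ion_class == "neutral"):
            raise InvalidInputError(
                f"{self.name}: pKa must be absent exactly for neutral "
                f"compounds (ion_class={self.ion_class!r}, pka={self.pka!r})"
            )
        if not self.mw > 0:
            raise InvalidInputError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.ws_sub is not None and not self.ws_sub > 0:
            raise InvalidInputError(
                f"{self.name}: ws_sub must be > 0 when present, got {self.ws_sub}"
            )
        if not _CAS_RE.match(self.cas):
            raise InvalidInputError(
                f"{self.name}: malformed CAS number {self.cas!r}"
            )


@dataclass(frozen=True)
class Speciation:
    """Neutral/ionized split of a compound at one pH.

    ``f_i`` is derived as ``1 - f_n`` so the closure f_n + f_i = 1 holds
    exactly in floating point.
    """

    ph: float
    f_n: float

    @property
    def f_i(self) -> float:
        return 1.0 - self.f_n


def neutral_fraction(ph: float, pka: float | None, ion_class: str) -> Speciation:
    """Henderson–Hasselbalch neutral fraction at a given pH.

    Parameters
    ----------
    ph : float
        Aqueous pH, restricted to [0, 14].
    pka : float or None
        Dissociation constant (conjugate-acid pKa for bases); may be None
        only for neutral compounds.
    ion_class : str
        ``"acid"``, ``"base"`` or ``"neutral"``.

    Returns
    -------
    Speciation

    Raises
    ------
    InvalidInputError
        If pH is outside [0, 14], the class is unknown, or pKa is missing
        for an ionizable class.
    """
    if not 0.0 <= ph <= 14.0:
        raise InvalidInputError(f"pH must lie in [0, 14], got {ph}")
    if ion_class == "neutral":
        return Speciation(ph=ph, f_n=1.0)
    if ion_class not in ("acid", "base"):
        raise InvalidInputError(f"unknown ion_class {ion_class!r}")
    if pka is None:
        raise InvalidInputError(f"pKa required for ion_class {ion_class!r}")
    if ion_class == "acid":
        f_n = 1.0 / (1.0 + 10.0 ** (ph - pka))
    else:
        f_n = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return Speciation(ph=ph, f_n=f_n)


def speciate(compound: CompoundRecord, ph: float) -> Speciation:
    """Speciation of a compound record at the given pH."""
    return neutral_fraction(ph, compound.pka, compound.ion_class)


def solubility_screen(compound: CompoundRecord, c0: float) -> float | None:
    """Ratio of an initial concentration to the compound's water solubility.

    The solubility is converted from mol/L to ug/L via the molecular
    weight (1 g = 1e6 ug), matching the concentration unit of ``c0``.
    Batch designs keep this ratio below 0.01 (1% of solubility).

    Parameters
    ----------
    compound : CompoundRecord
    c0 : float
        Initial aqueous concentration in ug/L, > 0.

    Returns
    -------
    float or None
        Dimensionless ratio c0 / solubility, or None when the compound
        has no subcooled-liquid solubility on record (room-temperature
        liquids) — a legal, flagged outcome rather than an error.
    """
    if not c0 > 0:
        raise InvalidInputError(f"c0 must be > 0, got {c0}")
    if compound.ws_sub is None:
        return None
    ws_ug_per_l = compound.ws_sub * compound.mw * 1e6
    return c0 / ws_ug_per_l
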