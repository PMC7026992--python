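"""Urea-dilution correction of bronchoalveolar lavage (BAL) measurements.

BAL recovers epithelial lining fluid (ELF) diluted by an unknown factor of
instilled saline.  Because urea equilibrates freely between blood and ELF,
the serum/BAL urea ratio estimates that dilution, giving the corrected ELF
drug concentration

    MER_ELF = MER_BAL * Urea_serum / Urea_BAL

Assay limits of quantification (LOQ): meropenem 0.5 mg/L in plasma and
0.03 mg/L in BAL; urea 3 mg/dL in plasma and 0.078 mg/dL in BAL.  A value is
quantifiable when it is at or above the LOQ (inclusive boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import CensoredResultError, InputError


@dataclass(frozen=True)
class AssaySpec:
    """One analyte's assay: LOQ, linear range, and error-SD polynomial.

    The assay SD at concentration c is ``sd_intercept + sd_proportional * c``.
    """

    analyte: str
    loq: float
    linear_lo: float
    linear_hi: float
    sd_intercept: float
    sd_proportional: float

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise InputError("loq must be > 0")
        if self.sd_proportional < 0:
            raise InputError("proportional SD coefficient must be >= 0")

    def sd(self, c: float) -> float:
        return self.sd_intercept + self.sd_proportional * c


# Defaults: SD intercept anchored at LOQ/2, 15% proportional component
# (assay precision and accuracy were <= 15% across the linear range).
PLASMA_MEROPENEM_ASSAY = AssaySpec("plasma_meropenem", 0.5, 0.5, 80.0, 0.25, 0.15)
BAL_MEROPENEM_ASSAY = AssaySpec("bal_meropenem", 0.03, 0.03, 1.0, 0.015, 0.15)
SERUM_UREA_ASSAY = AssaySpec("serum_urea", 3.0, 3.0, 300.0, 1.5, 0.15)
BAL_UREA_ASSAY = AssaySpec("bal_urea", 0.078, 0.078, 100.0, 0.039, 0.15)


def censor_loq(value: float, spec: AssaySpec) -> tuple[float, bool]:
    """Flag a measurement as below the limit of quantification.

    Returns ``(value, bloq)`` with the value preserved; ``bloq`` is True iff
    value < LOQ (a value exactly at the LOQ is quantifiable).
    """
    if value < 0:
        raise InputError("measured value must be >= 0")
    return value, value < spec.loq


@dataclass(frozen=True)
class BalSample:
    """One BAL measurement triple plus serum urea.

    mer_bal : meropenem in BAL supernatant, mg/L
    urea_ser : serum urea, mg/dL
    urea_bal : BAL urea, mg/dL
    bloq : per-analyte below-LOQ flags
    """

    mer_bal: float
    urea_ser: float
    urea_bal: float
    bloq: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.mer_bal, self.urea_ser, self.urea_bal) < 0:
            raise InputError("measured values must be >= 0")

    @property
    def dilution_factor(self) -> float:
        """Estimated BAL dilution of ELF: Urea_serum / Urea_BAL."""
        if self.urea_bal <= 0:
            raise ZeroDivisionError("urea_bal must be > 0 to estimate dilution")
        return self.urea_ser / self.urea_bal

    def is_censored(self) -> bool:
        return any(self.bloq.values())


def correct_elf(sample: BalSample) -> float:
    """ELF meropenem concentration (mg/L) from a BAL triple.

    Applies the urea dilution correction mer_bal * urea_ser / urea_bal.
    Raises CensoredResultError if any analyte is below LOQ — a censored
    sample must be handled explicitly upstream, never corrected silently.
    """
    if sample.is_censored():
        flagged = sorted(k for k, v in sample.bloq.items() if v)
        raise CensoredResultError(
            f"below-LOQ analytes {flagged}; corrected value would be unreliable"
        )
    if sample.urea_bal <= 0:
        raise ZeroDivisionError("urea_bal must be > 0")
    return sample.mer_bal * sample.urea_ser / sample.urea_bal


def correct_elf_table(df: pd.DataFrame, bloq_substitute: str = "exclude") -> pd.DataFrame:
    """Vectorized urea correction of a BAL table.

    Input columns: subject_id, mer_bal_mg_L, urea_ser_mg_dL, urea_bal_mg_dL.
    Adds ``elf_mg_L`` and per-analyte censoring flags.  Censored rows get
    NaN under the default policy ``"exclude"``; ``"loq_half"`` substitutes
    LOQ/2 for the censored analyte before correcting.
    """
    required = {"subject_id", "mer_bal_mg_L", "urea_ser_mg_dL", "urea_bal_mg_dL"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"BAL table missing columns: {sorted(missing)}")
    if bloq_substitute not in ("exclude", "loq_half"):
        raise InputError("bloq_substitute must be 'exclude' or 'loq_half'")

    out = df.copy()
    out["bloq_mer_bal"] = out["mer_bal_mg_L"] < BAL_MEROPENEM_ASSAY.loq
    out["bloq_urea_ser"] = out["urea_ser_mg_dL"] < SERUM_UREA_ASSAY.loq
    out["bloq_urea_bal"] = out["urea_bal_mg_dL"] < BAL_UREA_ASSAY.loq

    mer = out["mer_bal_mg_L"].astype(float).copy()
    ser = out["urea_ser_mg_dL"].astype(float).copy()
    bal = out["urea_bal_mg_dL"].astype(float).copy()
    if bloq_substitute == "loq_half":
        mer[out["bloq_mer_bal"]] = BAL_MEROPENEM_ASSAY.loq / 2
        ser[out["bloq_urea_ser"]] = SERUM_UREA_ASSAY.loq / 2
        bal[out["bloq_urea_bal"]] = BAL_UREA_ASSAY.loq / 2

    elf = mer * ser / bal.where(bal > 0)
    if bloq_substitute == "exclude":
        censored = out[["bloq_mer_bal", "bloq_urea_ser", "bloq_urea_bal"]].any(axis=1)
        elf[censored] = float("nan")
    out["elf_mg_L"] = elf
    return out
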