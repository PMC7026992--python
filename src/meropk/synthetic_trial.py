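"""Virtual trial generator emulating the study design.

The trial enrolled 31 critically ill patients with nosocomial pneumonia in two
continuous-infusion arms (16 on 2 g LD + 1 g/8 h, 15 on 2 g LD + 2 g/8 h).
On the third treatment day each subject contributed plasma samples
pre-infusion and at 1.5, 3, 6 and 8 h after the start of an 8-h maintenance
infusion, plus one ELF sample at 6 h obtained by bronchoalveolar lavage with
an unknown saline dilution of the recovered epithelial lining fluid.

The generator draws true structural parameters from a population sampler,
solves the exact model, reads concentrations at the design times, constructs
a BAL measurement triple (diluted meropenem, serum urea, diluted urea) with a
log-uniform dilution factor, perturbs every measurement with multiplicative
Gaussian assay noise, applies limit-of-quantification censoring, and emits
the dosing, observation and BAL tables together with the ground truth — so
estimation and diagnostics are testable without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from . import elf_bal, pk_core
from .datasets import ci_regimen
from .elf_bal import (
    BAL_MEROPENEM_ASSAY,
    BAL_UREA_ASSAY,
    PLASMA_MEROPENEM_ASSAY,
    SERUM_UREA_ASSAY,
)
from .estimation import SubjectData
from .pk_core import InfusionSchedule
from .regimen_sim import PopulationSampler, sample_population

# day-3 sampling design: the monitored maintenance infusion starts at 48 h
DAY3_START_H = 48.0
PLASMA_SAMPLE_OFFSETS_H = (0.0, 1.5, 3.0, 6.0, 8.0)  # 0 = pre-infusion trough
ELF_SAMPLE_OFFSET_H = 6.0


@dataclass(frozen=True)
class TrialDesign:
    """Study design of the two-arm continuous-infusion PK trial."""

    n_per_arm: tuple[int, ...] = (16, 15)
    arm_maintenance_mg: tuple[float, ...] = (1000.0, 2000.0)
    loading_mg: float = 2000.0
    horizon: float = 72.0
    plasma_offsets_h: tuple[float, ...] = PLASMA_SAMPLE_OFFSETS_H
    elf_offset_h: float = ELF_SAMPLE_OFFSET_H
    day3_start_h: float = DAY3_START_H
    dilution_range: tuple[float, float] = (10.0, 100.0)  # BAL dilution, log-uniform
    urea_ser_median_mg_dL: float = 40.0
    urea_ser_cv: float = 0.40
    assay_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_arm) != len(self.arm_maintenance_mg):
            raise InputError("n_per_arm and arm_maintenance_mg must align")
        if any(n < 1 for n in self.n_per_arm):
            raise InputError("each arm needs n >= 1")
        t_max = self.day3_start_h + max(max(self.plasma_offsets_h), self.elf_offset_h)
        if t_max > self.horizon:
            raise InputError("sampling times exceed the regimen horizon")

    def arm_regimen(self, arm: int) -> InfusionSchedule:
        return ci_regimen(
            self.arm_maintenance_mg[arm], ld_mg=self.loading_mg, horizon=self.horizon
        )

    def to_dict(self) -> dict:
        return {
            "n_per_arm": list(self.n_per_arm),
            "arm_maintenance_mg": list(self.arm_maintenance_mg),
            "loading_mg": self.loading_mg,
            "horizon_h": self.horizon,
            "plasma_offsets_h": list(self.plasma_offsets_h),
            "elf_offset_h": self.elf_offset_h,
            "day3_start_h": self.day3_start_h,
            "dilution_range": list(self.dilution_range),
            "urea_ser_median_mg_dL": self.urea_ser_median_mg_dL,
            "urea_ser_cv": self.urea_ser_cv,
            "assay_cv": self.assay_cv,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrialData:
    """Generated virtual-trial artifacts."""

    truth: pd.DataFrame         # per-subject true parameters, arm, dilution
    dosing: pd.DataFrame        # subject_id, start_h, duration_h, amount_mg
    observations: pd.DataFrame  # subject_id, time_h, analyte, value_mg_L, bloq
    bal: pd.DataFrame           # BAL triple per subject with censoring flags
    design: TrialDesign

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.dosing.to_csv(out / "dosing.csv", index=False)
        self.observations.to_csv(out / "obs.csv", index=False)
        self.bal.to_csv(out / "bal.csv", index=False)
        (out / "design.json").write_text(json.dumps(self.design.to_dict(), indent=2))

    def subject_datasets(self, include_elf: bool = True) -> list[SubjectData]:
        """Per-subject fitting datasets (censored rows excluded)."""
        subjects = []
        for sid, rows in self.observations.groupby("subject_id", sort=False):
            rows = rows[rows["bloq"] == 0]
            if not include_elf:
                rows = rows[rows["analyte"] != "elf"]
            if rows.empty:
                continue
            arm = int(self.truth.loc[self.truth["subject_id"] == sid, "arm"].iloc[0])
            subjects.append(
                SubjectData(
                    subject_id=str(sid),
                    schedule=self.design.arm_regimen(arm),
                    times=rows["time_h"].to_numpy(),
                    analytes=rows["analyte"].to_numpy(),
                    values=rows["value_mg_L"].to_numpy(),
                )
            )
        return subjects


def _noisy(rng: np.random.Generator, value: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative Gaussian assay noise, truncated to stay positive."""
    if cv == 0:
        return np.asarray(value, dtype=float)
    factor = 1.0 + cv * rng.standard_normal(np.shape(value))
    return np.asarray(value, dtype=float) * np.clip(factor, 0.05, None)


def generate_trial(
    design: TrialDesign, sampler: PopulationSampler | None = None
) -> TrialData:
    """Generate one virtual trial.

    Per subject: draw true parameters, solve the arm regimen, read plasma
    concentrations at the design times and the true ELF concentration at the
    BAL time; emit mer_bal = ELF/D and urea_bal = urea_serum/D for a
    log-uniform dilution D; add assay noise; censor below-LOQ values.  The
    observation table carries the urea-corrected ELF concentration computed
    from the (noisy) BAL triple — exactly what an analyst would fit.
    """
    sampler = sampler if sampler is not None else PopulationSampler()
    rng = np.random.default_rng(design.seed)

    arms = np.concatenate(
        [np.full(n, a, dtype=int) for a, n in enumerate(design.n_per_arm)]
    )
    n_total = len(arms)
    theta = sample_population(sampler, n_total, seed=int(rng.integers(2**31 - 1)))

    plasma_times = design.day3_start_h + np.asarray(design.plasma_offsets_h)
    elf_time = design.day3_start_h + design.elf_offset_h
    grid = np.unique(np.concatenate([plasma_times, [elf_time]]))

    lo, hi = design.dilution_range
    dilution = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_total))
    sigma_u = np.sqrt(np.log1p(design.urea_ser_cv**2))
    urea_ser_true = design.urea_ser_median_mg_dL * np.exp(
        sigma_u * rng.standard_normal(n_total)
    )

    truth_rows, dosing_rows, obs_rows, bal_rows = [], [], [], []
    for i in range(n_total):
        sid = f"S{i + 1:02d}"
        arm = int(arms[i])
        regimen = design.arm_regimen(arm)
        amounts = pk_core.solve_amounts(theta[i : i + 1], regimen, grid)[0]
        cp = np.clip(amounts[:, 0] / theta[i, 1], 0.0, None)
        ce = np.clip(amounts[:, 2] / theta[i, 6], 0.0, None)

        truth_rows.append(
            (sid, arm, *theta[i], dilution[i], urea_ser_true[i])
        )
        for start, dur, amt in regimen.events:
            dosing_rows.append((sid, start, dur, amt))

        # plasma observations
        cp_at = np.interp(plasma_times, grid, cp)
        cp_noisy = _noisy(rng, cp_at, design.assay_cv)
        for t, v in zip(plasma_times, cp_noisy):
            _, bloq = elf_bal.censor_loq(v, PLASMA_MEROPENEM_ASSAY)
            obs_rows.append((sid, t, "plasma", v, int(bloq)))

        # BAL triple at the ELF sampling time
        elf_true = float(np.interp(elf_time, grid, ce))
        mer_bal = _noisy(rng, elf_true / dilution[i], design.assay_cv)
        urea_ser = _noisy(rng, urea_ser_true[i], design.assay_cv)
        urea_bal = _noisy(rng, urea_ser_true[i] / dilution[i], design.assay_cv)
        _, b_mer = elf_bal.censor_loq(float(mer_bal), BAL_MEROPENEM_ASSAY)
        _, b_ser = elf_bal.censor_loq(float(urea_ser), SERUM_UREA_ASSAY)
        _, b_bal = elf_bal.censor_loq(float(urea_bal), BAL_UREA_ASSAY)
        bal_rows.append(
            (sid, elf_time, float(mer_bal), float(urea_ser), float(urea_bal),
             int(b_mer), int(b_ser), int(b_bal))
        )
        sample = elf_bal.BalSample(
            float(mer_bal), float(urea_ser), float(urea_bal),
            bloq={"mer_bal": b_mer, "urea_ser": b_ser, "urea_bal": b_bal},
        )
        if not sample.is_censored():
            obs_rows.append((sid, elf_time, "elf", elf_bal.correct_elf(sample), 0))
        else:
            obs_rows.append((sid, elf_time, "elf", float("nan"), 1))

    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "arm", *pk_core.PARAM_NAMES, "dilution", "urea_ser_mg_dL"],
    )
    dosing = pd.DataFrame(
        dosing_rows, columns=["subject_id", "start_h", "duration_h", "amount_mg"]
    )
    observations = pd.DataFrame(
        obs_rows, columns=["subject_id", "time_h", "analyte", "value_mg_L", "bloq"]
    )
    bal = pd.DataFrame(
        bal_rows,
        columns=[
            "subject_id", "time_h", "mer_bal_mg_L", "urea_ser_mg_dL",
            "urea_bal_mg_dL", "bloq_mer_bal", "bloq_urea_ser", "bloq_urea_bal",
        ],
    )
    return TrialData(truth, dosing, observations, bal, design)
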