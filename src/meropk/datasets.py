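"""Packaged reference data: published population PK parameters and regimen presets.

The reference parameter table is the final population model summary for
meropenem in critically ill patients with nosocomial pneumonia (median, mean,
95% credibility limits and SD per structural parameter).  Regimen presets
cover the continuous-infusion (CI) arms studied (2 g / 15 min loading dose
followed by 1 or 2 g per 8 h), the exploratory 3 g and 8 g CI regimens, and
4-h extended-infusion (EI) variants.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from .exceptions import InputError
from .pk_core import PARAM_NAMES, InfusionSchedule, StructuralParams

# median, mean, 95% credibility limits (lo, hi), SD
_REFERENCE_ROWS = {
    "CL":    (11.219, 12.464, 8.539, 15.589, 5.570),
    "V":     (10.143, 12.500, 8.385, 17.194, 6.929),
    "K12":   (26.696, 22.987, 23.706, 27.897, 8.072),
    "K21":   (7.601, 11.721, 3.853, 21.014, 9.730),
    "K13":   (18.539, 17.317, 13.124, 21.815, 5.611),
    "K31":   (25.614, 24.451, 23.575, 28.602, 5.892),
    "V_ELF": (19.424, 25.319, 19.321, 28.525, 10.735),
}

_REFERENCE_SHA256 = "4bd69803a690bbd8e9dd6ebfb672deb16e8b65047fbd2c9c030ad5d62b26509d"


def load_reference_parameters() -> pd.DataFrame:
    """Published population parameter summary, checksum-verified.

    Returns a DataFrame indexed by parameter name with columns
    ``median, mean, ci95_lo, ci95_hi, sd``.  Units: CL L/h; V, V_ELF L;
    rate constants 1/h.
    """
    digest = hashlib.sha256(
        json.dumps(_REFERENCE_ROWS, sort_keys=True).encode()
    ).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise RuntimeError("reference parameter table failed checksum verification")
    df = pd.DataFrame.from_dict(
        _REFERENCE_ROWS,
        orient="index",
        columns=["median", "mean", "ci95_lo", "ci95_hi", "sd"],
    )
    df.index.name = "parameter"
    return df.loc[list(PARAM_NAMES)]


def reference_median_params() -> StructuralParams:
    """StructuralParams at the published population medians."""
    ref = load_reference_parameters()
    return StructuralParams(*(ref.loc[n, "median"] for n in PARAM_NAMES))


def reference_mean_params() -> StructuralParams:
    """StructuralParams at the published population means."""
    ref = load_reference_parameters()
    return StructuralParams(*(ref.loc[n, "mean"] for n in PARAM_NAMES))


LOADING_DURATION_H = 0.25  # 2 g loading dose infused over 15 min
DOSING_INTERVAL_H = 8.0


def ci_regimen(
    maint_mg_per_interval: float,
    ld_mg: float = 2000.0,
    horizon: float = 72.0,
    interval_h: float = DOSING_INTERVAL_H,
) -> InfusionSchedule:
    """Loading dose (15 min) followed by back-to-back 8-h continuous infusions.

    Contiguous maintenance infusions are equivalent to one constant rate of
    ``maint_mg_per_interval / interval_h``.
    """
    events = [] if ld_mg == 0 else [(0.0, LOADING_DURATION_H, ld_mg)]
    t = LOADING_DURATION_H if ld_mg else 0.0
    while t < horizon:
        events.append((t, interval_h, maint_mg_per_interval))
        t += interval_h
    return InfusionSchedule(events, horizon)


def ei_regimen(
    dose_mg: float,
    infusion_h: float = 4.0,
    horizon: float = 72.0,
    interval_h: float = DOSING_INTERVAL_H,
) -> InfusionSchedule:
    """Intermittent extended infusions: ``dose_mg`` over ``infusion_h`` each interval."""
    if infusion_h > interval_h:
        raise InputError("infusion duration cannot exceed the dosing interval")
    events = []
    t = 0.0
    while t < horizon:
        events.append((t, infusion_h, dose_mg))
        t += interval_h
    return InfusionSchedule(events, horizon)


_PRESET_BUILDERS = {
    # continuous infusion arms (loading dose + CI maintenance)
    "2g_ld_1g_q8h_ci": lambda h: ci_regimen(1000.0, ld_mg=2000.0, horizon=h),
    "2g_ld_2g_q8h_ci": lambda h: ci_regimen(2000.0, ld_mg=2000.0, horizon=h),
    "3g_ld_3g_q8h_ci": lambda h: ci_regimen(3000.0, ld_mg=3000.0, horizon=h),
    "8g_q8h_ci": lambda h: ci_regimen(8000.0, ld_mg=2000.0, horizon=h),
    # 4-h extended-infusion variants
    "1g_q8h_ei4h": lambda h: ei_regimen(1000.0, horizon=h),
    "2g_q8h_ei4h": lambda h: ei_regimen(2000.0, horizon=h),
    "3g_q8h_ei4h": lambda h: ei_regimen(3000.0, horizon=h),
}


def regimen_presets() -> tuple[str, ...]:
    """Names of the packaged dosing-regimen presets."""
    return tuple(_PRESET_BUILDERS)


def load_regimen(name: str, horizon: float = 72.0) -> InfusionSchedule:
    """Build a preset regimen by name."""
    try:
        builder = _PRESET_BUILDERS[name]
    except KeyError:
        raise InputError(
            f"unknown regimen preset {name!r}; available: {', '.join(_PRESET_BUILDERS)}"
        ) from None
    return builder(horizon)


def regimen_from_frame(df: pd.DataFrame, horizon: float) -> InfusionSchedule:
    """Build a schedule from a table with columns start_h, duration_h, amount_mg."""
    required = {"start_h", "duration_h", "amount_mg"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"regimen table missing columns: {sorted(missing)}")
    rows = df.sort_values("start_h")
    events = list(zip(rows["start_h"], rows["duration_h"], rows["amount_mg"]))
    return InfusionSchedule(events, horizon)
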