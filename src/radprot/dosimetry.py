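"""Annual-dose conversion and dose-group stratification for survey-meter data.

External gamma exposure rates (μR/h, survey meter at 1 m) measured indoors and
outdoors at a subject's dwelling are combined with an indoor-occupancy factor
and converted to annual absorbed dose in mGy/y.  Subjects are then stratified
into the four dose groups used throughout the pipeline: Group I is the
normal-level natural radiation area (NLNRA) reference, Groups II-IV are
increasing high-level (HLNRA) strata.
"""

from __future__ import annotations

import pandas as pd

#: μR/h → mGy/y.  The printed study constant; its derivation is
#: 0.8763 (rad per R equivalent, scaled) × 24 h × 365 d × 1e-5.
CONVERSION_FACTOR = 0.0767

#: Dose-group cuts in mGy/y.  1.5 separates NLNRA (Group I) from HLNRA;
#: 5.0 and 14.0 separate Groups II/III/IV.
NLNRA_BOUNDARY = 1.5
GROUP_CUTS = (1.5, 5.0, 14.0)


def annual_dose(
    indoor_rate: float,
    outdoor_rate: float,
    occupancy_indoor: float,
    conversion_factor: float = CONVERSION_FACTOR,
) -> float:
    """Occupancy-weighted annual absorbed dose in mGy/y.

    dose = (indoor_rate * f + outdoor_rate * (1 - f)) * conversion_factor
    with rates in μR/h and f the fraction of time spent indoors.
    """
    if indoor_rate < 0 or outdoor_rate < 0:
        raise ValueError("exposure rates must be non-negative")
    if not 0.0 <= occupancy_indoor <= 1.0:
        raise ValueError("occupancy_indoor must lie in [0, 1]")
    f = occupancy_indoor
    return (indoor_rate * f + outdoor_rate * (1.0 - f)) * conversion_factor


def assign_group(dose: float, boundary_to_hlnra: bool = True) -> str:
    """Map an annual dose (mGy/y) to dose group I, II, III or IV.

    The 1.5 mGy/y boundary is ambiguous in the field's own usage (NLNRA is
    quoted as "≤ 1.5" and HLNRA as "≥ 1.5"); by default exactly 1.5 is
    assigned to Group II (HLNRA).  Set ``boundary_to_hlnra=False`` to keep
    1.5 in Group I.  Upper cuts are half-open: (1.5, 5.0] → II,
    (5.0, 14.0] → III, > 14.0 → IV.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    lo = GROUP_CUTS[0]
    in_group_i = dose < lo if boundary_to_hlnra else dose <= lo
    if in_group_i:
        return "I"
    if dose <= GROUP_CUTS[1]:
        return "II"
    if dose <= GROUP_CUTS[2]:
        return "III"
    return "IV"


def process_dosimetry(
    dose_table: pd.DataFrame,
    boundary_to_hlnra: bool = True,
    conversion_factor: float = CONVERSION_FACTOR,
) -> pd.DataFrame:
    """Add ``annual_dose`` and ``group`` columns to a dosimetry table.

    Expects columns ``subject, indoor_rate, outdoor_rate, occupancy_indoor``.
    """
    required = {"subject", "indoor_rate", "outdoor_rate", "occupancy_indoor"}
    missing = required - set(dose_table.columns)
    if missing:
        raise ValueError(f"dosimetry table missing columns: {sorted(missing)}")
    out = dose_table.copy()
    out["annual_dose"] = [
        annual_dose(r.indoor_rate, r.outdoor_rate, r.occupancy_indoor, conversion_factor)
        for r in out.itertuples()
    ]
    out["group"] = [assign_group(d, boundary_to_hlnra) for d in out["annual_dose"]]
    return out
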