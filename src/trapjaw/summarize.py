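"""Species-level aggregation of per-strike results.

Kinematic results are first averaged between the two synchronously striking
chelicerae of each strike (see :func:`trapjaw.kinematics.average_chelicerae`);
the per-strike values are then averaged across all strikes with equal weight
— not per individual — to give a species value, reported as mean +/- SD
(sample SD, n-1 denominator) with range and n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from trapjaw.energetics import MUSCLE_POWER_CEILING_W_PER_KG

#: StrikeSummary fields that are aggregated, with display units
SUMMARY_VARIABLES = {
    "peak_omega_rad_s": "rad/s",
    "peak_alpha_rad_s2": "rad/s^2",
    "peak_v_m_s": "m/s",
    "peak_a_m_s2": "m/s^2",
    "duration_s": "s",
    "sweep_deg": "deg",
    "E_max_J": "J",
    "P_W": "W",
    "O_W_per_kg": "W/kg",
}


@dataclass
class StrikeSummary:
    """Chelicerae-averaged scalar results for one strike."""

    specimen_id: str
    strike_id: str
    peak_omega_rad_s: float
    peak_alpha_rad_s2: float
    peak_v_m_s: float
    peak_a_m_s2: float
    duration_s: float
    sweep_deg: float
    E_max_J: float = float("nan")
    P_W: float = float("nan")
    O_W_per_kg: float = float("nan")
    smoothing_edf: float = float("nan")


@dataclass
class VariableSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int
    single_observation: bool = False   # sd undefined, reported as 0


@dataclass
class SpeciesSummary:
    """Per-variable mean +/- SD, range and n across strikes."""

    variables: dict[str, VariableSummary]
    n_strikes: int
    sd_estimator: str = "sample (n-1 denominator)"
    notes: list[str] = field(default_factory=list)


def from_profile(profile, energetics=None) -> StrikeSummary:
    """Build a StrikeSummary from an averaged KinematicProfile (+ optional energetics)."""
    s = StrikeSummary(
        specimen_id=profile.specimen_id,
        strike_id=profile.strike_id,
        peak_omega_rad_s=profile.peak_omega,
        peak_alpha_rad_s2=profile.peak_alpha,
        peak_v_m_s=profile.peak_v,
        peak_a_m_s2=profile.peak_a,
        duration_s=profile.duration_s,
        sweep_deg=math.degrees(profile.sweep_rad),
        smoothing_edf=profile.smoothing_edf,
    )
    if energetics is not None:
        s.E_max_J = energetics.E_max_J
        s.P_W = energetics.P_W
        s.O_W_per_kg = energetics.O_W_per_kg
    return s


def summarize_strikes(summaries) -> SpeciesSummary:
    """Aggregate strikes (equal weight each) into per-variable species summaries."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no strikes to summarize")
    df = strikes_to_frame(summaries)
    variables: dict[str, VariableSummary] = {}
    for var in SUMMARY_VARIABLES:
        vals = df[var].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        single = vals.size == 1
        variables[var] = VariableSummary(
            mean=float(np.mean(vals)),
            sd=0.0 if single else float(np.std(vals, ddof=1)),
            min=float(np.min(vals)),
            max=float(np.max(vals)),
            n=int(vals.size),
            single_observation=single,
        )
    return SpeciesSummary(variables=variables, n_strikes=len(summaries))


def strikes_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def species_to_frame(species: SpeciesSummary) -> pd.DataFrame:
    rows = []
    for var, vs in species.variables.items():
        rows.append(
            {
                "variable": var,
                "unit": SUMMARY_VARIABLES.get(var, ""),
                "mean": vs.mean,
                "sd": vs.sd,
                "min": vs.min,
                "max": vs.max,
                "n": vs.n,
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def report(species: SpeciesSummary, template: str = "{var}: {mean} ± {sd} {unit} ({min}–{max}), n={n}") -> str:
    """Render Results-style summary lines plus the muscle-ceiling verdict.

    Each present variable renders as "mean ± sd unit (min–max), n=…"; empty
    variables are omitted with a warning line. If mass-specific power output
    is present, a verdict line compares its mean with the ~400 W/kg ceiling
    of conventional muscle.
    """
    lines = []
    for var in SUMMARY_VARIABLES:
        if var not in species.variables:
            lines.append(f"# warning: no values for {var}; omitted")
            continue
        vs = species.variables[var]
        lines.append(
            template.format(
                var=var,
                unit=SUMMARY_VARIABLES[var],
                mean=_fmt(vs.mean),
                sd=_fmt(vs.sd),
                min=_fmt(vs.min),
                max=_fmt(vs.max),
                n=vs.n,
            )
        )
    if "O_W_per_kg" in species.variables:
        o_mean = species.variables["O_W_per_kg"].mean
        if o_mean > MUSCLE_POWER_CEILING_W_PER_KG:
            verdict = (
                f"mass-specific power output exceeds the "
                f"{MUSCLE_POWER_CEILING_W_PER_KG:.0f} W/kg limit of conventional "
                f"muscle: consistent with elastic power amplification"
            )
        else:
            verdict = (
                f"mass-specific power output does not exceed conventional muscle "
                f"power ({MUSCLE_POWER_CEILING_W_PER_KG:.0f} W/kg): no evidence of "
                f"power amplification"
            )
        lines.append(f"verdict: {verdict}")
    lines.append(f"# SD estimator: {species.sd_estimator}; strikes weighted equally")
    return "\n".join(lines)
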