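"""Rigid-rod energetics of a cheliceral strike.

Each chelicera is treated as a thin rod of uniform density rotating about a
fixed pivot at one end, giving I = (1/3) M L^2. Kinetic energy over the
strike is E(t) = (1/2) I omega(t)^2 using the smoothed angular velocity;
strike power is P = E_max / t_{E,max} with t_{E,max} measured from strike
onset (the first digitized frame); mass-specific power output is
O = P / m_muscle, compared against the ~400 W/kg ceiling of conventional
muscle to flag candidate power amplification.

Chelicera and adductor-muscle masses for sub-millimetre spiders cannot be
weighed directly; they are estimated allometrically from cheliceral length
under geometric similarity, m = c * L^exponent with exponent 3 by default.
The coefficients must be supplied by the caller — there is no defensible
universal default — and the provenance of every mass is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: conventional upper bound on the mass-specific power of muscle, W/kg;
#: outputs above it are taken as indirect evidence of elastic (spring) drive
MUSCLE_POWER_CEILING_W_PER_KG = 400.0


@dataclass
class CheliceraBody:
    """Masses and length of one chelicera with provenance of each value."""

    M_kg: float                    # chelicera (paturon) mass
    L_m: float                     # cheliceral length
    m_muscle_kg: float             # adductor muscle mass
    provenance: dict[str, str]     # per-field: "measured" | "allometric estimate"

    def __post_init__(self) -> None:
        if self.M_kg <= 0 or self.L_m <= 0 or self.m_muscle_kg <= 0:
            raise ValueError("masses and length must be positive")


@dataclass
class EnergeticsResult:
    I_kg_m2: float
    E_series_J: np.ndarray
    times_s: np.ndarray
    E_max_J: float
    t_E_max_s: float               # measured from strike onset
    P_W: float
    O_W_per_kg: float
    exceeds_muscle_limit: bool


def moment_of_inertia(M_kg: float, L_m: float) -> float:
    """Thin uniform rod rotating about one end: I = (1/3) M L^2."""
    if M_kg <= 0 or L_m <= 0:
        raise ValueError("mass and length must be positive")
    return M_kg * L_m**2 / 3.0


def kinetic_energy(I_kg_m2: float, omega_rad_s) -> np.ndarray:
    """Rotational kinetic energy E = (1/2) I omega^2, elementwise, joules."""
    if I_kg_m2 < 0:
        raise ValueError("moment of inertia must be nonnegative")
    omega = np.asarray(omega_rad_s, dtype=float)
    return 0.5 * I_kg_m2 * omega**2


def strike_power(E_series_J, times_s, t_onset: float) -> tuple[float, float, float]:
    """(E_max, t_E_max, P) with P = E_max / t_E_max and time from onset.

    Ties between equal energy maxima resolve to the earliest time. A peak at
    onset itself makes P a 0/0 and is rejected.
    """
    E = np.asarray(E_series_J, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if E.size == 0 or E.shape != t.shape:
        raise ValueError("E_series and times must be nonempty and congruent")
    if t_onset > t.min():
        raise ValueError("t_onset must not exceed the first sample time")
    i = int(np.argmax(E))          # argmax returns the earliest maximizer
    E_max = float(E[i])
    t_E_max = float(t[i] - t_onset)
    if t_E_max <= 0:
        raise ValueError("energy peak at strike onset: P = E_max / t_E_max is degenerate")
    return E_max, t_E_max, E_max / t_E_max


def mass_specific_power(P_W: float, m_muscle_kg: float) -> float:
    """Power output O = P / m, watts per kilogram of adductor muscle."""
    if m_muscle_kg <= 0:
        raise ValueError("muscle mass must be positive")
    return P_W / m_muscle_kg


def exceeds_muscle_limit(O_W_per_kg: float,
                         ceiling: float = MUSCLE_POWER_CEILING_W_PER_KG) -> bool:
    """True when the mass-specific power exceeds what conventional muscle can deliver."""
    return O_W_per_kg > ceiling


def estimate_masses(
    L_mm: float,
    c_muscle_kg_per_mm: float | None = None,
    c_chelicera_kg_per_mm: float | None = None,
    exponent: float = 3.0,
) -> CheliceraBody:
    """Allometric mass estimates m = c * L^exponent from cheliceral length.

    ``c_muscle_kg_per_mm`` and ``c_chelicera_kg_per_mm`` are the
    proportionality coefficients (kg per mm^exponent) of the adductor muscle
    and whole chelicera, typically regressed from related species measured
    directly. They have no default: supplying them is the caller's explicit,
    documented modelling choice.
    """
    if L_mm <= 0:
        raise ValueError("cheliceral length must be positive")
    if c_muscle_kg_per_mm is None or c_chelicera_kg_per_mm is None:
        raise ValueError(
            "allometric coefficients are required: pass c_muscle_kg_per_mm and "
            "c_chelicera_kg_per_mm (kg per mm^exponent), e.g. regressed from "
            "related species with directly measured masses"
        )
    return CheliceraBody(
        M_kg=c_chelicera_kg_per_mm * L_mm**exponent,
        L_m=L_mm * 1e-3,
        m_muscle_kg=c_muscle_kg_per_mm * L_mm**exponent,
        provenance={
            "M_kg": "allometric estimate",
            "L_m": "measured",
            "m_muscle_kg": "allometric estimate",
        },
    )


def compute_energetics(profile, body: CheliceraBody,
                       t_onset: float | None = None) -> EnergeticsResult:
    """Energetics of one strike from its kinematic profile and body model.

    ``profile`` is a :class:`~trapjaw.kinematics.KinematicProfile`; onset
    defaults to the profile's first time (first digitized frame).
    """
    I = moment_of_inertia(body.M_kg, body.L_m)
    E = kinetic_energy(I, profile.omega)
    onset = float(profile.times[0]) if t_onset is None else float(t_onset)
    E_max, t_E_max, P = strike_power(E, profile.times, onset)
    O = mass_specific_power(P, body.m_muscle_kg)
    return EnergeticsResult(
        I_kg_m2=I,
        E_series_J=E,
        times_s=np.asarray(profile.times, dtype=float),
        E_max_J=E_max,
        t_E_max_s=t_E_max,
        P_W=P,
        O_W_per_kg=O,
        exceeds_muscle_limit=exceeds_muscle_limit(O),
    )
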