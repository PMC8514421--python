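"""Micro-CT muscle morphometrics: side averaging, size correction, table rendering.

Tendon and fiber lengths (microns) of the seven cheliceral muscle groups are
measured on CT reconstructions of one specimen scanned with the chelicerae
closed (resting) and one scanned with them open (loaded, pre-strike). Left
and right measurements are averaged; lengths are size-corrected by the
specimen's carapace width so the two scans are comparable; clypeus thickness
is reduced to a ratio against the carapace thickness between the anterior
median eyes. Some open-specimen muscles were pulled away from the carapace
and their lengths extrapolated to its interior surface — those values carry
an ``extrapolated`` flag that propagates through averaging and rendering
(asterisks in the table).

``REFERENCE_MEASUREMENTS`` holds the published raw measurements (already
side-averaged, microns) together with the two specimens' carapace widths, as
the input data set for the table-reproduction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

#: canonical muscle set; endosternite muscles are absent in this species and
#: are represented by absent rows, never by zeros
MUSCLES = [
    "anterior medial inner",
    "anterior median outer",
    "anterior outer",
    "lateral anterior",
    "lateral posterior",
    "posterior median",
    "intercheliceral sclerite",
]

STATES = ("closed", "open")

FIELDS = ("tendon_um", "shortest_fiber_um", "longest_fiber_um")

#: carapace widths (microns) of the closed- and open-chelicerae specimens
CARAPACE_WIDTH_UM = {"closed": 500.4, "open": 495.5}

# published side-averaged raw lengths, microns:
# muscle -> state -> (tendon, shortest fiber, longest fiber); trailing bools
# flag values extrapolated to the interior carapace surface
REFERENCE_MEASUREMENTS = {
    "anterior medial inner": {
        "closed": ((140.04, False), (185.18, False), (370.45, False)),
        "open": ((156.58, False), (399.52, True), (522.22, True)),
    },
    "anterior median outer": {
        "closed": ((20.73, False), (100.52, False), (105.46, False)),
        "open": ((21.12, False), (130.01, False), (154.42, False)),
    },
    "anterior outer": {
        "closed": ((29.69, False), (113.01, False), (235.38, False)),
        "open": ((28.66, False), (236.06, False), (319.53, False)),
    },
    "lateral anterior": {
        "closed": ((33.31, False), (143.12, False), (258.94, False)),
        "open": ((33.67, False), (150.00, False), (311.41, False)),
    },
    "lateral posterior": {
        "closed": ((45.07, False), (129.79, False), (230.41, False)),
        "open": ((40.33, False), (123.20, False), (265.74, False)),
    },
    "posterior median": {
        "closed": ((91.43, False), (199.25, False), (312.83, False)),
        "open": ((64.17, False), (330.87, True), (396.70, True)),
    },
    "intercheliceral sclerite": {
        "closed": ((17.79, False), (103.13, False), (110.87, False)),
        "open": ((30.48, False), (86.21, False), (288.48, False)),
    },
}


#: published 2-decimal size-corrected ratios (the parenthetical values of the
#: reference table), kept for validation of the size-correction pipeline;
#: layout: muscle -> state -> (tendon, shortest fiber, longest fiber)
PUBLISHED_RATIOS = {
    "anterior medial inner": {"closed": (0.27, 0.37, 0.74), "open": (0.31, 0.81, 1.05)},
    "anterior median outer": {"closed": (0.04, 0.20, 0.21), "open": (0.05, 0.26, 0.31)},
    "anterior outer": {"closed": (0.06, 0.23, 0.47), "open": (0.06, 0.48, 0.64)},
    "lateral anterior": {"closed": (0.07, 0.29, 0.52), "open": (0.07, 0.30, 0.63)},
    "lateral posterior": {"closed": (0.09, 0.26, 0.46), "open": (0.08, 0.25, 0.54)},
    "posterior median": {"closed": (0.18, 0.40, 0.63), "open": (0.13, 0.67, 0.80)},
    "intercheliceral sclerite": {"closed": (0.04, 0.21, 0.22), "open": (0.06, 0.17, 0.58)},
}


@dataclass
class MuscleMeasurement:
    """Tendon and fiber lengths (microns) of one muscle in one scan state."""

    muscle_name: str
    state: str                     # "open" | "closed"
    side: str                      # "L" | "R" | "averaged"
    tendon_um: float
    shortest_fiber_um: float
    longest_fiber_um: float
    tendon_extrapolated: bool = False
    shortest_fiber_extrapolated: bool = False
    longest_fiber_extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.muscle_name not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle_name!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        for f in FIELDS:
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.shortest_fiber_um > self.longest_fiber_um:
            raise ValueError("shortest fiber exceeds longest fiber")


@dataclass
class SpecimenMorphometry:
    """Per-specimen carapace and clypeus dimensions, microns."""

    specimen_id: str
    carapace_width_um: float
    clypeus_thickness_um: float
    carapace_thickness_at_AME_um: float

    def __post_init__(self) -> None:
        for f in ("carapace_width_um", "clypeus_thickness_um", "carapace_thickness_at_AME_um"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def average_sides(left: MuscleMeasurement, right: MuscleMeasurement) -> MuscleMeasurement:
    """Arithmetic mean of left and right measurements; extrapolation flags OR-ed."""
    if (left.muscle_name, left.state) != (right.muscle_name, right.state):
        raise ValueError(
            f"cannot average {left.muscle_name}/{left.state} with "
            f"{right.muscle_name}/{right.state}"
        )
    return MuscleMeasurement(
        muscle_name=left.muscle_name,
        state=left.state,
        side="averaged",
        tendon_um=(left.tendon_um + right.tendon_um) / 2.0,
        shortest_fiber_um=(left.shortest_fiber_um + right.shortest_fiber_um) / 2.0,
        longest_fiber_um=(left.longest_fiber_um + right.longest_fiber_um) / 2.0,
        tendon_extrapolated=left.tendon_extrapolated or right.tendon_extrapolated,
        shortest_fiber_extrapolated=left.shortest_fiber_extrapolated
        or right.shortest_fiber_extrapolated,
        longest_fiber_extrapolated=left.longest_fiber_extrapolated
        or right.longest_fiber_extrapolated,
    )


def size_correct(value_um: float, carapace_width_um: float) -> float:
    """Dimensionless length / carapace-width ratio (raw, unrounded)."""
    if value_um <= 0 or carapace_width_um <= 0:
        raise ValueError("value and carapace width must be positive")
    return value_um / carapace_width_um


def round_ratio(ratio: float, decimals: int = 2) -> float:
    """Round-half-even to the table's 2-decimal display convention."""
    return round(ratio, decimals)


def clypeus_ratio(clypeus_um: float, carapace_at_AME_um: float) -> float:
    """Clypeus thickness relative to carapace thickness between the anterior median eyes."""
    if clypeus_um <= 0 or carapace_at_AME_um <= 0:
        raise ValueError("thicknesses must be positive")
    return clypeus_um / carapace_at_AME_um


def reference_measurements() -> list[MuscleMeasurement]:
    """The published side-averaged measurement set as MuscleMeasurement objects."""
    out = []
    for muscle, states in REFERENCE_MEASUREMENTS.items():
        for state, cells in states.items():
            (tend, tf), (sf, sff), (lf, lff) = cells
            out.append(
                MuscleMeasurement(
                    muscle_name=muscle,
                    state=state,
                    side="averaged",
                    tendon_um=tend,
                    shortest_fiber_um=sf,
                    longest_fiber_um=lf,
                    tendon_extrapolated=tf,
                    shortest_fiber_extrapolated=sff,
                    longest_fiber_extrapolated=lff,
                )
            )
    return out


def render_table(
    measurements: list[MuscleMeasurement],
    carapace_width_um: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Render the muscle table: raw microns and size-corrected ratios per state.

    One row per muscle; for each of tendon / shortest fiber / longest fiber
    and each chelicera state the raw length (um) and its carapace-width ratio
    (2-decimal, round-half-even) are emitted, with ``*`` marking extrapolated
    cells. Requires the complete seven-muscle set for every state present.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    if carapace_width_um is None:
        carapace_width_um = CARAPACE_WIDTH_UM
    by_key = {(m.muscle_name, m.state): m for m in measurements}
    states = sorted({m.state for m in measurements}, key=STATES.index)
    for state in states:
        missing = [mu for mu in MUSCLES if (mu, state) not in by_key]
        if missing:
            raise ValueError(f"missing muscles for state {state!r}: {missing}")
    rows = []
    for muscle in MUSCLES:
        row: dict[str, object] = {"muscle": muscle}
        for fieldname, label in zip(FIELDS, ("tendon", "shortest_fiber", "longest_fiber")):
            for state in states:
                m = by_key[(muscle, state)]
                raw = getattr(m, fieldname)
                flagged = getattr(m, fieldname.replace("_um", "") + "_extrapolated")
                ratio = round_ratio(size_correct(raw, carapace_width_um[state]))
                star = "*" if flagged else ""
                row[f"{label}_{state}_um"] = raw
                row[f"{label}_{state}_ratio"] = ratio
                row[f"{label}_{state}_display"] = f"{raw:.2f}{star} ({ratio:.2f}{star})"
        rows.append(row)
    return pd.DataFrame(rows)
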