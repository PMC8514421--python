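#!/usr/bin/env python
"""Rigid-rod energetics for every strike: energy, power, mass-specific output.

Re-runs the kinematic chain per strike to get the smoothed angular velocity
series, builds an allometric body model from each specimen's cheliceral
length (cuticle-density rod: ~4 ug chelicera, ~1.5 ug adductor muscle at
0.46 mm), and computes I, E_max, t_E,max, P = E_max / t_E,max and
O = P / m_muscle, flagging any strike whose O exceeds the 400 W/kg ceiling
of conventional muscle.
"""

import argparse
from pathlib import Path

import pandas as pd

from trapjaw.energetics import compute_energetics, estimate_masses
from trapjaw.io import read_tracks, write_results
from trapjaw.kinematics import analyze_track, average_chelicerae

# kg per mm^3; see docs/methods.md for the geometric-similarity rationale
C_CHELICERA = 4e-8
C_MUSCLE = 1.5e-8


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tracks", type=Path, default=Path("results/synthetic_strikes"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--muscle-coef", type=float, default=C_MUSCLE)
    ap.add_argument("--chelicera-coef", type=float, default=C_CHELICERA)
    args = ap.parse_args()

    rows = []
    for strike_dir in sorted(args.tracks.iterdir()):
        if not (strike_dir / "tracks.csv").exists():
            continue
        tracks = {t.side: t for t in
                  read_tracks(strike_dir / "tracks.csv", strike_dir / "config.yaml")}
        profiles = {side: analyze_track(t) for side, t in tracks.items()}
        avg = average_chelicerae(profiles.get("L"), profiles.get("R"))
        body = estimate_masses(avg.cheliceral_length_mm,
                               c_muscle_kg_per_mm=args.muscle_coef,
                               c_chelicera_kg_per_mm=args.chelicera_coef)
        res = compute_energetics(avg, body)
        rows.append(
            {
                "specimen_id": avg.specimen_id, "strike_id": avg.strike_id,
                "I_kg_m2": res.I_kg_m2, "E_max_J": res.E_max_J,
                "t_E_max_s": res.t_E_max_s, "P_W": res.P_W,
                "O_W_per_kg": res.O_W_per_kg,
                "exceeds_muscle_limit": res.exceeds_muscle_limit,
                "allometry_c_muscle": args.muscle_coef,
                "allometry_c_chelicera": args.chelicera_coef,
                "allometry_exponent": 3.0,
            }
        )
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    out_csv = args.out / "strike_energetics.csv"
    write_results(df, out_csv, units={
        "I_kg_m2": "kg m^2", "E_max_J": "J", "t_E_max_s": "s from strike onset",
        "P_W": "W", "O_W_per_kg": "W/kg",
        "allometry_c_muscle": "kg/mm^3", "allometry_c_chelicera": "kg/mm^3",
    })
    n_exceed = int(df.exceeds_muscle_limit.sum())
    print(f"wrote {out_csv} ({len(df)} strikes); "
          f"{n_exceed} exceed the 400 W/kg muscle ceiling")


if __name__ == "__main__":
    main()
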