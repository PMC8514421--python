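#!/usr/bin/env python
"""Aggregate the per-strike kinematics and energetics into a species summary.

Joins the tables from steps 02 and 03, averages all strikes with equal
weight, and prints each variable as mean +/- SD (range), n, plus the
power-amplification verdict.
"""

import argparse
from pathlib import Path

from trapjaw.io import read_results, write_results
from trapjaw.summarize import StrikeSummary, report, species_to_frame, summarize_strikes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--kinematics", type=Path, default=Path("results/strike_kinematics.csv"))
    ap.add_argument("--energetics", type=Path, default=Path("results/strike_energetics.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/species_summary.csv"))
    args = ap.parse_args()

    kin = read_results(args.kinematics)
    if args.energetics.exists():
        en = read_results(args.energetics)[
            ["specimen_id", "strike_id", "E_max_J", "P_W", "O_W_per_kg"]
        ]
        kin = kin.merge(en, on=["specimen_id", "strike_id"], how="left")
    summaries = [
        StrikeSummary(
            specimen_id=str(r.specimen_id), strike_id=str(r.strike_id),
            peak_omega_rad_s=r.peak_omega_rad_s, peak_alpha_rad_s2=r.peak_alpha_rad_s2,
            peak_v_m_s=r.peak_v_m_s, peak_a_m_s2=r.peak_a_m_s2,
            duration_s=r.duration_s, sweep_deg=r.sweep_deg,
            E_max_J=getattr(r, "E_max_J", float("nan")),
            P_W=getattr(r, "P_W", float("nan")),
            O_W_per_kg=getattr(r, "O_W_per_kg", float("nan")),
        )
        for r in kin.itertuples()
    ]
    species = summarize_strikes(summaries)
    write_results(species_to_frame(species), args.out)
    text = report(species)
    args.out.with_suffix(".txt").write_text(text + "\n")
    print(text)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
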