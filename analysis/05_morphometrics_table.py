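#!/usr/bin/env python
"""Render the size-corrected cheliceral muscle table from the reference data.

Takes the bundled side-averaged tendon/fiber lengths (microns) of the seven
cheliceral muscle groups in the open and closed specimens, size-corrects by
each specimen's carapace width, and writes the raw-plus-ratio table with
asterisks on extrapolated cells.
"""

import argparse
from pathlib import Path

from trapjaw.morphometrics import reference_measurements, render_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/muscle_table.csv"))
    args = ap.parse_args()

    table = render_table(reference_measurements())
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    display_cols = ["muscle"] + [c for c in table.columns if c.endswith("_display")]
    print(table[display_cols].to_string(index=False))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
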