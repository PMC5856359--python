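"""Regenerate the bundled standardized Gittins-index tables.

Run from the repository root:

    python scripts/make_tables.py [--discounts 0.9 0.95 0.99 0.995] [--n-max 400]

Each table is written to src/banditrials/tables/ in the plain-text format
documented in banditrials.gittins.  This is a one-off cost; the package
loads the bundled files at run time.
"""

import argparse
import pathlib
import sys
import time

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from banditrials.gittins import _table_resource_name, compute_gittins_table  # noqa: E402

DEST = pathlib.Path(__file__).resolve().parents[1] / "src" / "banditrials" / "tables"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--discounts", nargs="+", type=float, default=[0.9, 0.95, 0.99, 0.995])
    ap.add_argument("--n-max", type=int, default=400)
    ap.add_argument("--grid-points", type=int, default=801)
    args = ap.parse_args()

    DEST.mkdir(parents=True, exist_ok=True)
    for d in args.discounts:
        t0 = time.time()
        table = compute_gittins_table(d, args.n_max, grid_points=args.grid_points)
        out = DEST / _table_resource_name(d)
        table.to_file(out)
        print(f"d={d}: {len(table.n_grid)} entries -> {out} ({time.time() - t0:.0f}s)")


if __name__ == "__main__":
    main()
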