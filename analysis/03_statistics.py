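#!/usr/bin/env python
"""Statistical elaboration of the published and the simulated stress tables.

For the published scenario x weight table shipped with the package:
per-scenario means with population SD, per-kg regression slopes, Pearson
correlation against body weight, the Friedman test across scenarios
(weights as blocks) and all 21 pairwise Wilcoxon matched-pairs tests, in
both exact-enumeration and normal-approximation modes.  If a simulated
table from 02_run_grid.py exists, the same report is produced for it.
"""

import argparse
import warnings
from pathlib import Path

from cystfem.runner import load_stress_table, packaged_table1
from cystfem.stats import stats_report


def report_on(table, label: str, out_dir: Path) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exact = stats_report(table, mode="exact")
        approx = stats_report(table, mode="approx")
    print(f"\n=== {label} ===")
    print(exact.to_text())
    print(f"normal-approximation mode: all off-diagonal p < 0.03: "
          f"{approx.all_pairs_below_003} "
          f"({(approx.pairwise_p.values < 0.03).sum() // 2} of 21 pairs)")
    out_dir.mkdir(parents=True, exist_ok=True)
    exact.to_json(out_dir / f"report_{label}_exact.json")
    approx.to_json(out_dir / f"report_{label}_approx.json")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grid-table", type=Path, default=Path("results/grid/stress_table.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    report_on(packaged_table1(), "published", args.out)
    if args.grid_table.exists():
        report_on(load_stress_table(args.grid_table), "simulated", args.out)
    else:
        print(f"\n(no simulated table at {args.grid_table}; run 02_run_grid.py first)")


if __name__ == "__main__":
    main()
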