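#!/usr/bin/env python
"""The Q1-Q5 statistical battery over the per-breath tables.

Reads breaths.csv, rd.csv and ee_profiles.csv from results/tables/ and
answers: (Q1) do rate and tidal volume track PEEP, (Q2) do the aeration
compartments shift between the PEEP extremes, (Q3) does PEEP drive R/D
(Kruskal-Wallis with Dunn-Sidak post hoc), (Q4) is R/D more variable at
low PEEP (Ansari-Bradley), (Q5) how does maximal transpulmonary pressure
depend on PEEP (polynomial fits).  Writes the Tables-1-to-4-shaped CSVs
and report.json under results/tables/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from peeprd.stats_analysis import run_q_battery

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tables", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    breath_df = pd.read_csv(args.tables / "breaths.csv")
    rd_df = pd.read_csv(args.tables / "rd.csv")
    ee_df = pd.read_csv(args.tables / "ee_profiles.csv")
    rep = run_q_battery(breath_df, rd_df, ee_profile_df=ee_df)

    for name, table in rep.tables.items():
        table.to_csv(args.tables / f"{name}.csv", index=False)
    (args.tables / "report.json").write_text(json.dumps(rep.summary(), indent=1))

    q1 = rep.sections["q1"]
    print(f"Q1: RR slope {q1['rr_fit'].coefficients[0]:+.2f} bpm/cmH2O "
          f"(R2 {q1['rr_fit'].r2:.2f}); TV slope "
          f"{q1['tv_fit'].coefficients[0]:+.4f} L/cmH2O (R2 {q1['tv_fit'].r2:.2f})")
    q3 = rep.sections["q3"]
    print(f"Q3: Kruskal-Wallis (pooled) H = {q3['kw_pooled'].h:.1f}, "
          f"p = {q3['kw_pooled'].p:.3g}")
    t3 = rep.tables["q4_table3_dispersion_pairs"]
    print(f"Q4: {int(t3['h'].sum())}/{len(t3)} PEEP pairs show higher "
          f"R/D dispersion at the lower PEEP")
    q5 = rep.sections["q5"]
    for d in (1, 2, 3):
        f = q5[f"degree{d}"]
        print(f"Q5 degree {d}: coeffs {[round(float(c), 3) for c in f.coefficients]} "
              f"R2 {f.r2:.2f}")
    print(f"wrote Q tables and report.json to {args.tables}")


if __name__ == "__main__":
    main()
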