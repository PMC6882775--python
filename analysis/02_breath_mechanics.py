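#!/usr/bin/env python
"""Per-breath respiratory mechanics from the simulated tracings.

Reads the waveform CSVs written by 01_simulate_study.py, detects breaths,
fits the equation of motion per breath (transpulmonary referencing),
computes the resistive-corrected maximal transpulmonary pressure and the
EAdi statistics, and writes results/tables/breaths.csv.  Prints the pooled
drive regressions (rate and tidal volume against PEEP).
"""

import argparse
from pathlib import Path

import pandas as pd

from peeprd.pipeline import AnalysisOptions, analyze_step
from peeprd.resp_mechanics import WaveformSet
from peeprd.stats_analysis import fit_regression

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    proto = pd.read_csv(args.study / "protocol.csv")
    opts = AnalysisOptions()
    frames = []
    for _, row in proto.iterrows():
        d = args.study / row["dir"]
        waves = WaveformSet.from_csv(d / "waves.csv", eadi_path=d / "eadi.csv")
        res = analyze_step(waves, None, None, row["peep"], row["direction"], opts)
        bdf = res["breath_df"]
        bdf.insert(0, "step", int(row["step"]))
        frames.append(bdf)
    breath_df = pd.concat(frames, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    breath_df.to_csv(args.out / "breaths.csv", index=False)

    rr = fit_regression(breath_df["peep"].to_numpy(),
                        breath_df["rr_local"].to_numpy(), 1)
    tv = fit_regression(breath_df["peep"].to_numpy(),
                        breath_df["tv"].to_numpy(), 1)
    print(f"{len(breath_df)} breaths across {len(proto)} PEEP steps")
    print(f"pooled RR  = {rr.coefficients[0]:+.2f} * PEEP + "
          f"{rr.coefficients[1]:.2f}  (R2 = {rr.r2:.2f})")
    print(f"pooled TV  = {tv.coefficients[0]:+.4f} * PEEP + "
          f"{tv.coefficients[1]:.4f}  (R2 = {tv.r2:.2f})")
    print(f"wrote {args.out / 'breaths.csv'}")


if __name__ == "__main__":
    main()
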