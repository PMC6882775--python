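#!/usr/bin/env python
"""Dynamic-CT aeration and tidal recruitment/derecruitment.

Regenerates the CT phantom frames deterministically from the study config
and seed (frames are not stored on disk by default — they are ~40 MB per
step), synchronizes the CT clock against the spirometric volume, selects
end-expiratory/end-inspiratory frame pairs, and computes per-breath R/D
with its PEEP aggregates.  Writes rd.csv, ee_profiles.csv, sync.csv and
the aggregate tables under results/tables/.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from peeprd.pipeline import AnalysisOptions, _child_seeds, analyze_step
from peeprd.rd_analysis import aggregate_by_peep, rd_table
from peeprd.synthetic_data import (
    load_config_yaml,
    simulate_breathing,
    simulate_ct_sequence,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    meta = json.loads((args.study / "meta.json").read_text())
    sim, phantom = load_config_yaml(args.study / "config.yaml")
    proto = pd.read_csv(args.study / "protocol.csv")
    seeds = _child_seeds(meta["seed"], 2 * len(proto))
    opts = AnalysisOptions()
    duration = phantom.duration + 2.0

    rd_rows, ee_rows, syncs = [], [], []
    for _, row in proto.iterrows():
        k = int(row["step"])
        waves, gt = simulate_breathing(replace(sim, seed=seeds[2 * k]),
                                       row["peep"], duration)
        frames, mask, gt = simulate_ct_sequence(
            replace(phantom, seed=seeds[2 * k + 1]), waves, gt)
        res = analyze_step(waves, frames, mask, row["peep"], row["direction"], opts)
        rd_rows.extend(res["rd_rows"])
        ee_rows.extend(res["ee_rows"])
        syncs.append(res["sync"])
        del frames

    args.out.mkdir(parents=True, exist_ok=True)
    rd_df = rd_table(rd_rows)
    rd_df.to_csv(args.out / "rd.csv", index=False)
    pd.DataFrame(ee_rows).to_csv(args.out / "ee_profiles.csv", index=False)
    pd.DataFrame(syncs).to_csv(args.out / "sync.csv", index=False)
    pooled, by_dir = aggregate_by_peep(rd_df)
    pooled.to_csv(args.out / "rd_aggregates_pooled.csv", index=False)
    by_dir.to_csv(args.out / "rd_aggregates_by_direction.csv", index=False)

    print(f"{len(rd_df)} R/D breaths; sync offsets "
          f"{[round(s['offset'], 3) for s in syncs]}")
    print("pooled R/D (%eeLV) by PEEP:")
    print(pooled[["peep", "rd_pct_eelv_mean", "rd_pct_eelv_std", "n"]]
          .to_string(index=False))
    print(f"wrote tables to {args.out}")


if __name__ == "__main__":
    main()
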