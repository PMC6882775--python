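#!/usr/bin/env python
"""Generate the synthetic PEEP-ramp study.

Simulates NAVA-assisted spontaneous breathing over the 0-15-0 cmH2O PEEP
staircase (11 steps, 100 s dynamic CT acquisition per step) and writes the
200 Hz waveform CSVs, 100 Hz EAdi CSVs, configuration and ground-truth
sidecars under results/study/.  CT frames are regenerated deterministically
by later stages from the stored config and seed; pass --write-frames to
also export them as multi-page TIFF stacks.
"""

import argparse
import json
from pathlib import Path

from peeprd.pipeline import RunConfig, simulate_to_dir

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "study")
    ap.add_argument("--write-frames", action="store_true")
    ap.add_argument("--quick", action="store_true",
                    help="30 s acquisitions instead of 100 s")
    args = ap.parse_args()

    cfg = RunConfig(mode="simulate", seed=args.seed, write_frames=args.write_frames)
    if args.quick:
        cfg.phantom.duration = 30.0
    simulate_to_dir(cfg, args.out)
    (args.out / "meta.json").write_text(json.dumps(
        {"seed": args.seed, "quick": args.quick}))
    steps = sorted(p.name for p in args.out.glob("step*"))
    print(f"wrote {len(steps)} PEEP steps to {args.out}")
    for s in steps:
        print("  ", s)


if __name__ == "__main__":
    main()
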