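"""End-to-end orchestration: simulate -> analyze -> report, plus the CLI.

A *study* is one pass over the PEEP-ramp protocol.  For each step the
breathing simulator produces 200 Hz waveforms and 100 Hz EAdi, the CT
phantom renders the dynamic acquisition, and the analysis chain produces a
per-breath mechanics table, a per-breath R/D table, per-PEEP aggregates and
the Q1-Q5 statistical report.  Frames are processed per step and released,
so the full default study fits comfortably in memory.

Every run emits a provenance block (config hash, library versions, exclusion
counts) so each number in the report is traceable to a table row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breath_ct_matching import ct_gas_series, select_breath_frames, synchronize
from .ct_aeration import compute_aeration_profile, read_mask, read_tiff_frames, write_tiff_frames
from .rd_analysis import aggregate_by_peep, compute_rd, rd_table
from .resp_mechanics import WaveformSet, build_breath_table, smooth_waveforms
from .stats_analysis import run_q_battery
from .synthetic_data import (
    GroundTruth,
    PhantomConfig,
    SimConfig,
    infer_directions,
    load_config_yaml,
    save_config_yaml,
    save_ground_truth_json,
    simulate_breathing,
    simulate_ct_sequence,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "RunConfig", "StudyResult", "run_study",
           "analyze_step", "run", "cli"]


@dataclass
class AnalysisOptions:
    """Every analysis decision flag, with its recorded default."""

    pressure: str = "transpulmonary"   # equation-of-motion referencing
    hysteresis: float = 0.02           # L/s, breath-detection band
    min_tv: float = 0.01               # L, breath rejection floor
    r2_min: float = 0.8                # fit-reliability threshold
    end_exp_frac: float = 0.25         # EAdi,min window (fraction of expiration)
    eelv_denominator: str = "total"    # "total" | "gas"
    frame_method: str = "nearest-time"  # | "extremal-gas"
    alpha: float = 0.05
    smooth_window_s: float = 0.025     # s, channel denoising boxcar (0 = off)
    rd_value: str = "rd_pct_eelv"      # R/D normalization fed to Q3/Q4


@dataclass
class RunConfig:
    mode: str = "full"                 # simulate | analyze | full
    sim: SimConfig = field(default_factory=SimConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0
    wave_pad_s: float = 2.0            # waveform duration beyond CT acquisition
    write_frames: bool = False         # TIFF frame export in simulate/full mode

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim, phantom = load_config_yaml(path)
        kwargs = {}
        for key in ("mode", "seed", "wave_pad_s", "write_frames"):
            if key in doc:
                kwargs[key] = doc[key]
        if sim is not None:
            kwargs["sim"] = sim
        if phantom is not None:
            kwargs["phantom"] = phantom
        if "analysis" in doc:
            kwargs["analysis"] = AnalysisOptions(**doc["analysis"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


@dataclass
class StudyResult:
    breath_df: pd.DataFrame
    rd_df: pd.DataFrame
    ee_profile_df: pd.DataFrame
    pooled: pd.DataFrame
    by_direction: pd.DataFrame
    report: "object"                   # QBatteryReport
    sync: list[dict]
    ground_truths: list[GroundTruth]
    counts: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def analyze_step(
    waves: WaveformSet,
    frames,
    mask,
    peep: float,
    direction: str,
    opts: AnalysisOptions,
) -> dict:
    """Analyze one PEEP step: mechanics table and, when frames exist, R/D."""
    sm = smooth_waveforms(waves, opts.smooth_window_s) if opts.smooth_window_s > 0 else waves
    breath_df, breaths = build_breath_table(
        sm, peep=peep, direction=direction,
        hysteresis=opts.hysteresis, min_tv=opts.min_tv, r2_min=opts.r2_min,
        end_exp_frac=opts.end_exp_frac, pressure=opts.pressure,
    )
    out = {"breath_df": breath_df, "rd_rows": [], "ee_rows": [], "sync": None}
    if frames is None or not breaths:
        return out
    waves_v = sm.with_volume(breaths)
    ct_t, gas = ct_gas_series(frames, mask)
    sync = synchronize(ct_t, gas, waves_v.t, waves_v.volume)
    out["sync"] = {"peep": peep, "direction": direction,
                   "offset": sync.offset, "quality": sync.quality,
                   "reliable": sync.reliable}
    pairs = select_breath_frames(sync, breaths, frames, waves_v,
                                 mask=mask, method=opts.frame_method)
    for pair in pairs:
        prof_ee = compute_aeration_profile(frames[pair.ee_frame_idx], mask)
        prof_ei = compute_aeration_profile(frames[pair.ei_frame_idx], mask)
        m = compute_rd(pair, prof_ee, prof_ei, peep, direction,
                       eelv_denominator=opts.eelv_denominator)
        out["rd_rows"].append(m)
        row = prof_ee.as_row()
        row.update(breath=pair.breath_id, peep=peep, direction=direction)
        out["ee_rows"].append(row)
    return out


def run_study(
    sim_cfg: SimConfig | None = None,
    phantom_cfg: PhantomConfig | None = None,
    opts: AnalysisOptions | None = None,
    seed: int = 0,
) -> StudyResult:
    """Simulate and analyze a full PEEP-ramp study in memory."""
    sim_cfg = sim_cfg or SimConfig()
    phantom_cfg = phantom_cfg or PhantomConfig()
    opts = opts or AnalysisOptions()
    steps = infer_directions(sim_cfg.peep_sequence)
    seeds = _child_seeds(seed, 2 * len(steps))
    duration = phantom_cfg.duration + 2.0

    breath_frames, rd_rows, ee_rows, syncs, gts = [], [], [], [], []
    counts = {"steps": len(steps), "breaths_detected": 0, "breaths_flagged": 0,
              "rd_pairs": 0}
    for k, step in enumerate(steps):
        s_cfg = replace(sim_cfg, seed=seeds[2 * k])
        p_cfg = replace(phantom_cfg, seed=seeds[2 * k + 1])
        waves, gt = simulate_breathing(s_cfg, step.peep, duration)
        frames, mask, gt = simulate_ct_sequence(p_cfg, waves, gt)
        res = analyze_step(waves, frames, mask, step.peep, step.direction, opts)
        bdf = res["breath_df"]
        bdf.insert(0, "step", k)
        breath_frames.append(bdf)
        rd_rows.extend(res["rd_rows"])
        ee_rows.extend(res["ee_rows"])
        if res["sync"] is not None:
            syncs.append(res["sync"])
        gts.append(gt)
        counts["breaths_detected"] += len(bdf)
        counts["breaths_flagged"] += int((~bdf["included"]).sum()) if len(bdf) else 0
        counts["rd_pairs"] += len(res["rd_rows"])
        del frames
        logger.info("step %d (PEEP %g, %s): %d breaths, %d R/D pairs",
                    k, step.peep, step.direction, len(bdf), len(res["rd_rows"]))

    breath_df = pd.concat(breath_frames, ignore_index=True)
    rd_df = rd_table(rd_rows) if rd_rows else pd.DataFrame()
    ee_df = pd.DataFrame(ee_rows)
    if not rd_df.empty:
        pooled, by_dir = aggregate_by_peep(rd_df)
    else:
        pooled = by_dir = pd.DataFrame()
    report = run_q_battery(breath_df, rd_df, ee_profile_df=ee_df,
                           rd_value=opts.rd_value, alpha=opts.alpha)
    return StudyResult(breath_df=breath_df, rd_df=rd_df, ee_profile_df=ee_df,
                       pooled=pooled, by_direction=by_dir, report=report,
                       sync=syncs, ground_truths=gts, counts=counts)


# ---------------------------------------------------------------------------
# file-based modes
# ---------------------------------------------------------------------------

def _step_dir(root: Path, k: int, peep: float, direction: str) -> Path:
    return root / f"step{k:02d}_peep{peep:g}_{direction}"


def simulate_to_dir(cfg: RunConfig, out: Path) -> None:
    """Write the synthetic study to disk (waveform/EAdi CSVs, sidecars,
    optionally TIFF frame stacks)."""
    out.mkdir(parents=True, exist_ok=True)
    steps = infer_directions(cfg.sim.peep_sequence)
    seeds = _child_seeds(cfg.seed, 2 * len(steps))
    duration = cfg.phantom.duration + cfg.wave_pad_s
    save_config_yaml(out / "config.yaml", sim=cfg.sim, phantom=cfg.phantom)
    proto_rows = []
    for k, step in enumerate(steps):
        s_cfg = replace(cfg.sim, seed=seeds[2 * k])
        p_cfg = replace(cfg.phantom, seed=seeds[2 * k + 1])
        waves, gt = simulate_breathing(s_cfg, step.peep, duration)
        frames, mask, gt = simulate_ct_sequence(p_cfg, waves, gt)
        d = _step_dir(out, k, step.peep, step.direction)
        d.mkdir(exist_ok=True)
        waves.to_csv(d / "waves.csv", eadi_path=d / "eadi.csv")
        save_ground_truth_json(d / "ground_truth.json", gt)
        if cfg.write_frames:
            write_tiff_frames(d / "frames.tif", frames)
            import tifffile

            tifffile.imwrite(str(d / "mask.tif"), mask.mask.astype(np.uint8))
        proto_rows.append({"step": k, "peep": step.peep,
                           "direction": step.direction, "dir": d.name})
        del frames
    pd.DataFrame(proto_rows).to_csv(out / "protocol.csv", index=False)


def analyze_from_dir(cfg: RunConfig, in_dir: Path) -> StudyResult:
    """Analyze a study previously written by ``simulate_to_dir``.

    Steps without frame stacks contribute mechanics only (the CT section is
    skipped with a warning); a missing EAdi file just drops those columns.
    """
    proto = pd.read_csv(in_dir / "protocol.csv")
    breath_frames, rd_rows, ee_rows, syncs = [], [], [], []
    counts = {"steps": len(proto), "breaths_detected": 0, "breaths_flagged": 0,
              "rd_pairs": 0}
    for _, prow in proto.iterrows():
        d = in_dir / prow["dir"]
        waves = WaveformSet.from_csv(d / "waves.csv", eadi_path=d / "eadi.csv")
        frames = mask = None
        if (d / "frames.tif").exists():
            frames = read_tiff_frames(d / "frames.tif")
            mask = read_mask(d / "mask.tif")
        else:
            logger.warning("step %s: no frames found, CT section skipped", d.name)
        res = analyze_step(waves, frames, mask, prow["peep"], prow["direction"],
                           cfg.analysis)
        bdf = res["breath_df"]
        bdf.insert(0, "step", int(prow["step"]))
        breath_frames.append(bdf)
        rd_rows.extend(res["rd_rows"])
        ee_rows.extend(res["ee_rows"])
        if res["sync"] is not None:
            syncs.append(res["sync"])
        counts["breaths_detected"] += len(bdf)
        counts["breaths_flagged"] += int((~bdf["included"]).sum()) if len(bdf) else 0
        counts["rd_pairs"] += len(res["rd_rows"])

    breath_df = pd.concat(breath_frames, ignore_index=True)
    rd_df = rd_table(rd_rows) if rd_rows else pd.DataFrame()
    ee_df = pd.DataFrame(ee_rows)
    if not rd_df.empty:
        pooled, by_dir = aggregate_by_peep(rd_df)
    else:
        pooled = by_dir = pd.DataFrame()
    report = run_q_battery(breath_df, rd_df, ee_profile_df=ee_df,
                           rd_value=cfg.analysis.rd_value, alpha=cfg.analysis.alpha)
    return StudyResult(breath_df=breath_df, rd_df=rd_df, ee_profile_df=ee_df,
                       pooled=pooled, by_direction=by_dir, report=report,
                       sync=syncs, ground_truths=[], counts=counts)


def write_results(result: StudyResult, cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.breath_df.to_csv(out / "breaths.csv", index=False)
    if not result.rd_df.empty:
        result.rd_df.to_csv(out / "rd.csv", index=False)
        result.pooled.to_csv(out / "rd_aggregates_pooled.csv", index=False)
        result.by_direction.to_csv(out / "rd_aggregates_by_direction.csv", index=False)
    if not result.ee_profile_df.empty:
        result.ee_profile_df.to_csv(out / "ee_profiles.csv", index=False)
    for name, table in result.report.tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(result.report.summary(), indent=1))
    if result.sync:
        pd.DataFrame(result.sync).to_csv(out / "sync.csv", index=False)
    cfg_dict = cfg.to_dict()
    provenance = {
        "peeprd_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg_dict,
        "counts": result.counts,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))


def run(cfg: RunConfig, out: Path, in_dir: Path | None = None) -> StudyResult | None:
    """Execute one run in the configured mode; returns the result for
    analyze/full modes."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("peeprd").addHandler(fh)
    try:
        if cfg.mode == "simulate":
            simulate_to_dir(cfg, out)
            return None
        if cfg.mode == "analyze":
            if in_dir is None:
                raise ValueError("analyze mode needs an input directory")
            result = analyze_from_dir(cfg, Path(in_dir))
        elif cfg.mode == "full":
            result = run_study(cfg.sim, cfg.phantom, cfg.analysis, cfg.seed)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        write_results(result, cfg, out)
        return result
    finally:
        logging.getLogger("peeprd").removeHandler(fh)
        fh.close()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _load_cfg(config: str | None, seed: int | None, mode: str) -> RunConfig:
    cfg = RunConfig.from_yaml(config) if config else RunConfig()
    cfg.mode = mode
    if seed is not None:
        cfg.seed = seed
    return cfg


def _setup_logging(level: str) -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
def cli() -> None:
    """peeprd: synthetic PEEP-ramp studies and their breath-by-breath analysis."""


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--write-frames/--no-write-frames", default=False)
@click.option("--log-level", default="INFO")
def simulate(config, seed, out, write_frames, log_level):
    """Generate a synthetic study (waveforms, EAdi, optional CT frames)."""
    _setup_logging(log_level)
    cfg = _load_cfg(config, seed, "simulate")
    cfg.write_frames = write_frames
    run(cfg, Path(out))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--in", "in_dir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--log-level", default="INFO")
def analyze(config, in_dir, out, log_level):
    """Analyze a study directory written by `peeprd simulate`."""
    _setup_logging(log_level)
    cfg = _load_cfg(config, None, "analyze")
    run(cfg, Path(out), in_dir=Path(in_dir))


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--log-level", default="INFO")
def full(config, seed, out, log_level):
    """Simulate and analyze in one pass (in memory)."""
    _setup_logging(log_level)
    cfg = _load_cfg(config, seed, "full")
    run(cfg, Path(out))


if __name__ == "__main__":
    cli()
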