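"""Tidal recruitment/derecruitment (R/D) and end-expiratory atelectasis.

For each breath, R/D is the difference in non-aerated lung between the
end-expiratory and the end-inspiratory frame of the same breathing cycle,
in ml and in g, and normalized to the end-expiratory lung volume (eeLV)
and weight (eeLW) of the analyzed slice.  The default eeLV denominator is
the total masked slice volume (tissue plus gas); a gas-only alternative is
available.  Negative R/D (more atelectasis at end-inspiration, possible
with noisy frames) is retained and flagged rather than clipped, so the
dispersion statistics downstream are not biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breath_ct_matching import BreathFramePair
from .ct_aeration import AerationProfile

logger = logging.getLogger(__name__)

__all__ = ["RdMeasure", "compute_rd", "rd_table", "aggregate_by_peep"]

#: columns summarized by :func:`aggregate_by_peep`
RD_VALUE_COLS = (
    "rd_volume_ml", "rd_weight_g", "rd_pct_eelv", "rd_pct_eelw",
    "atelectasis_ee_ml", "atelectasis_ee_g", "atelectasis_pct_eelw",
)


@dataclass
class RdMeasure:
    breath_id: int
    peep: float
    direction: str            # "up" | "down"
    rd_volume_ml: float
    rd_weight_g: float
    rd_pct_eelv: float        # % of end-expiratory slice volume
    rd_pct_eelw: float        # % of end-expiratory slice weight
    atelectasis_ee_ml: float
    atelectasis_ee_g: float
    atelectasis_pct_eelw: float
    negative: bool            # True when rd_volume_ml < 0 (flag, not clipped)


def compute_rd(
    pair: BreathFramePair,
    profile_ee: AerationProfile,
    profile_ei: AerationProfile,
    peep: float,
    direction: str,
    eelv_denominator: str = "total",
) -> RdMeasure:
    """R/D of one breath from its end-expiratory/-inspiratory profiles.

    ``eelv_denominator``: ``"total"`` uses the full masked slice volume at
    end-expiration, ``"gas"`` the end-expiratory gas volume.
    """
    if eelv_denominator == "total":
        eelv = profile_ee.lung_volume_ml
    elif eelv_denominator == "gas":
        eelv = profile_ee.gas_volume_ml
    else:
        raise ValueError(f"unknown eeLV denominator {eelv_denominator!r}")
    eelw = profile_ee.tissue_weight_g
    if eelv <= 0 or eelw <= 0:
        raise ValueError("end-expiratory volume/weight must be positive")

    rd_ml = profile_ee.non_aerated_ml - profile_ei.non_aerated_ml
    rd_g = profile_ee.non_aerated_g - profile_ei.non_aerated_g
    return RdMeasure(
        breath_id=pair.breath_id,
        peep=peep,
        direction=direction,
        rd_volume_ml=rd_ml,
        rd_weight_g=rd_g,
        rd_pct_eelv=100.0 * rd_ml / eelv,
        rd_pct_eelw=100.0 * rd_g / eelw,
        atelectasis_ee_ml=profile_ee.non_aerated_ml,
        atelectasis_ee_g=profile_ee.non_aerated_g,
        atelectasis_pct_eelw=100.0 * profile_ee.non_aerated_g / eelw,
        negative=rd_ml < 0,
    )


def rd_table(measures: list[RdMeasure]) -> pd.DataFrame:
    """One row per breath, in the column order of :data:`RD_VALUE_COLS`."""
    return pd.DataFrame([vars(m) for m in measures])


def aggregate_by_peep(
    df: pd.DataFrame,
    value_cols: tuple[str, ...] = RD_VALUE_COLS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/sd/n summaries pooled per PEEP and split per (PEEP, direction).

    Pooling combines ascending- and descending-ramp breaths at the same
    PEEP.  The sd uses the n-1 denominator and is NaN for single-breath
    groups (the ``n`` column makes those auditable).
    """
    if df.empty:
        raise ValueError("no R/D measures to aggregate")
    cols = [c for c in value_cols if c in df.columns]

    def _agg(g: pd.core.groupby.DataFrameGroupBy) -> pd.DataFrame:
        out = g[cols].agg(["mean", "std"])
        out.columns = [f"{a}_{b}" for a, b in out.columns]
        out["n"] = g.size()
        return out.reset_index()

    pooled = _agg(df.groupby("peep"))
    by_dir = _agg(df.groupby(["peep", "direction"]))
    return pooled, by_dir
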