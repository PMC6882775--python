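"""PEEP-ramp protocol construction.

The study protocol is a symmetric staircase: PEEP rises from 0 to a peak in
fixed steps and then descends back to 0 by the same steps.  Endpoints appear
once each at the start and end of the sequence and the peak appears once,
so a 0-to-15 ramp in steps of 3 cmH2O yields 11 PEEP steps.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProtocolStep", "generate_protocol", "infer_directions"]


@dataclass(frozen=True)
class ProtocolStep:
    peep: float       # cmH2O
    direction: str    # "up" | "down"; the single peak step is tagged "up"


def generate_protocol(peep_max: float, step: float) -> list[ProtocolStep]:
    """Ordered PEEP levels of an up-then-down ramp with direction tags.

    ``peep_max`` must be a non-negative multiple of ``step``; the degenerate
    ramp ``peep_max == 0`` is a single step at PEEP 0.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if peep_max < 0:
        raise ValueError("peep_max must be non-negative")
    n = peep_max / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"peep_max ({peep_max}) must be a multiple of step ({step})"
        )
    n = int(round(n))
    up = [ProtocolStep(k * step, "up") for k in range(n + 1)]
    down = [ProtocolStep(k * step, "down") for k in range(n - 1, -1, -1)]
    return up + down


def infer_directions(peeps: list[float]) -> list[ProtocolStep]:
    """Tag a plain PEEP sequence with ramp directions (peak counts as "up")."""
    if not peeps:
        return []
    peak = max(peeps)
    steps, seen_peak = [], False
    for p in peeps:
        if not seen_peak:
            steps.append(ProtocolStep(p, "up"))
            if p == peak:
                seen_peak = True
        else:
            steps.append(ProtocolStep(p, "down"))
    return steps
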