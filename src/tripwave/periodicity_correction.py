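"""Removal of 6-bp (and 9-bp) aliasing from the triplet-periodicity track.

A tract with pure period-6 structure produces a period-3 peak as well — an
inherent property of Fourier-type transforms (a spectral line at k = N/6
implies one at N/3).  Because a period-6 comb's period-6 and aliased
period-3 responses have essentially the same amplitude, subtracting a b = 6
control track from the b = 3 track (clamping negatives to zero) removes such
false positives while leaving genuine triplet periodicity nearly untouched:
a period-3 signal has almost no b = 6 response, since the b = 6 carrier
alternates sign between successive period-3 pulses.

Subtraction happens on the tracks' common raw/calibrated scale, never after
per-track max-normalization, which would distort the amplitude ratios the
correction relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spectral_core import PSDTrack


@dataclass
class CorrectedTrack:
    """A b = 3 track with a control track subtracted and negatives clamped."""

    tp: PSDTrack
    control: PSDTrack
    values: np.ndarray
    clamp_count: int

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seq_id(self) -> str:
        return self.tp.seq_id

    @property
    def max(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0


def _check_compatible(tp: PSDTrack, control: PSDTrack) -> None:
    if len(tp) != len(control):
        raise ValueError(
            f"track length mismatch: tp has {len(tp)}, control has {len(control)}"
        )
    if (tp.params.a, tp.params.N) != (control.params.a, control.params.N):
        raise ValueError(
            "tp and control tracks must share scale a and kernel length N "
            f"(got a={tp.params.a}/{control.params.a}, N={tp.params.N}/{control.params.N})"
        )
    if tp.normalization != control.normalization or tp.normalization == "max":
        raise ValueError(
            "subtraction requires both tracks on the same raw/calibrated scale"
        )


def subtract_control(tp: PSDTrack, control: PSDTrack) -> CorrectedTrack:
    """Element-wise ``max(0, tp - control)`` with provenance retained."""
    _check_compatible(tp, control)
    diff = tp.values - control.values
    clamp_count = int(np.sum(diff < 0))
    return CorrectedTrack(tp, control, np.maximum(diff, 0.0), clamp_count)


def flag_control_regions(
    tp: PSDTrack,
    control: PSDTrack,
    min_length: int = 1,
    min_signal: float | None = None,
) -> list[tuple[int, int]]:
    """Candidate false-positive intervals: runs where the control matches tp.

    A position is flagged when it carries appreciable period-3 signal
    (``tp >= min_signal``, default 5% of the tp track's maximum — positions
    with no signal have nothing to falsify) *and* the control is at least as
    large up to a small relative tolerance (the two responses of a pure
    period-6 tract agree only to floating-point).  The tp track is left
    untouched; this is the confirmation-style use of the 6-bp control.
    Runs shorter than ``min_length`` are dropped.
    """
    _check_compatible(tp, control)
    if min_signal is None:
        min_signal = 0.05 * tp.max
    mask = (tp.values >= min_signal) & (control.values >= tp.values * (1.0 - 1e-9))
    regions: list[tuple[int, int]] = []
    start: int | None = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_length:
                regions.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_length:
        regions.append((start, len(mask)))
    return regions


def control_mode(
    tp: PSDTrack,
    control: PSDTrack,
    mode: Literal["subtract", "flag"] = "subtract",
    min_length: int = 1,
    min_signal: float | None = None,
):
    """Dispatch between subtraction and flag-only handling of the control."""
    if mode == "subtract":
        return subtract_control(tp, control)
    if mode == "flag":
        return flag_control_regions(tp, control, min_length=min_length, min_signal=min_signal)
    raise ValueError(f"unknown correction mode {mode!r}")
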