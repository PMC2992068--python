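"""In-silico frame-shift scanning: edit the sequence, re-measure the peak.

Inserting or deleting 3n+1 or 3n+2 bases inside a coding region changes the
downstream codon phase, so the upstream and downstream halves of the region
oscillate out of phase and their wavelet responses partially cancel; a 3n
edit leaves the phase (and hence the peak) essentially intact, and a second
compensatory edit that restores the net phase recovers the peak.  Scanning
an edit template across positions therefore maps the phase structure of a
region, and a grid search over single and paired deletions can point to
candidate ancient frame-shifts: an edit that *raises* the peak suggests the
region once coded in a shifted frame.

These analyses default to scale a = 2.5 rather than the boundary-calling
default of 5: the peak-amplitude statistic is integrative, and the envelope
must span the whole region of interest for a phase break anywhere in it to
register on the dominant peak.  At a = 2.5, N = 1200 the envelope std is 96
bases, wide enough for exon-sized regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .seq_encoding import IndicatorSet, NucleotideSequence, encode_indicators
from .spectral_core import SpectralParams, mwt_psd

#: Default scan parameters: wide envelope (see module docstring).
SCAN_PARAMS = SpectralParams(N=1200, a=2.5, b=3)


@dataclass(frozen=True)
class EditOperation:
    """A deletion or insertion at a fixed position (0-based)."""

    kind: Literal["delete", "insert"]
    position: int
    length: int = 1
    inserted_bases: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("edit length must be >= 1")
        if self.kind == "insert" and len(self.inserted_bases) != self.length:
            raise ValueError("inserted_bases length must equal edit length")

    @property
    def length_change(self) -> int:
        return self.length if self.kind == "insert" else -self.length


@dataclass
class MutationScanProfile:
    """Peak amplitude as a function of the scanned edit position."""

    template: str
    positions: np.ndarray
    peak_amplitude: np.ndarray
    baseline_peak: float
    region: tuple[int, int]
    params: SpectralParams

    def to_tsv(self) -> str:
        lines = ["position\tpeak_amplitude\tbaseline"]
        for p, v in zip(self.positions, self.peak_amplitude):
            lines.append(f"{p}\t{v:.6g}\t{self.baseline_peak:.6g}")
        return "\n".join(lines) + "\n"


def apply_edit(seq: NucleotideSequence, edit: EditOperation) -> NucleotideSequence:
    """Return a new sequence with the edit applied; the original is untouched."""
    res = seq.residues
    if edit.kind == "delete":
        if edit.position < 0 or edit.position + edit.length > len(res):
            raise ValueError(
                f"deletion [{edit.position}, {edit.position + edit.length}) "
                f"out of bounds for length {len(res)}"
            )
        res = res[: edit.position] + res[edit.position + edit.length :]
    else:
        if edit.position < 0 or edit.position > len(res):
            raise ValueError(f"insertion at {edit.position} out of bounds")
        res = res[: edit.position] + edit.inserted_bases + res[edit.position :]
    return NucleotideSequence(seq.id, res)


def apply_edits(seq: NucleotideSequence, edits: Sequence[EditOperation]) -> NucleotideSequence:
    """Apply edits right-to-left so earlier positions stay valid."""
    for edit in sorted(edits, key=lambda e: e.position, reverse=True):
        seq = apply_edit(seq, edit)
    return seq


def _region_peak(
    ind: IndicatorSet,
    region: tuple[int, int],
    params: SpectralParams,
    statistic: Literal["max", "mean"] = "max",
) -> float:
    track = mwt_psd(ind, params)
    lo, hi = max(0, region[0]), min(ind.length, region[1])
    window = track.values[lo:hi]
    if window.size == 0:
        return 0.0
    return float(window.max() if statistic == "max" else window.mean())


def _edited_region(region: tuple[int, int], edits: Sequence[EditOperation]) -> tuple[int, int]:
    """Map a region of interest into post-edit coordinates."""
    lo, hi = region
    for e in edits:
        if e.position < lo:
            lo += e.length_change
        if e.position < hi:
            hi += e.length_change
    return max(lo, 0), max(hi, lo + 1)


def peak_statistic(
    seq: NucleotideSequence,
    region: tuple[int, int],
    edits: Sequence[EditOperation] = (),
    params: SpectralParams = SCAN_PARAMS,
    statistic: Literal["max", "mean"] = "max",
) -> float:
    """Peak (or mean) PSD over the region of interest after applying edits.

    The region is specified in original coordinates and shifted to track
    the edits, matching the protocol of recording the maximal peak height
    over the examined region.
    """
    edited = apply_edits(seq, edits) if edits else seq
    return _region_peak(encode_indicators(edited), _edited_region(region, edits), params, statistic)


def scan_peak_amplitude(
    seq: NucleotideSequence,
    region: tuple[int, int],
    edit_template: Sequence[tuple[str, int, int]],
    positions: Sequence[int] | None = None,
    params: SpectralParams = SCAN_PARAMS,
    statistic: Literal["max", "mean"] = "max",
    inserted_base: str = "A",
) -> MutationScanProfile:
    """Slide an edit template across positions and record the peak each time.

    ``edit_template`` is a list of ``(kind, offset, length)`` triples; the
    template is anchored so that each scanned position p applies the edits
    at ``p + offset``.  Example templates: ``[("delete", 0, 1)]`` for a
    single-base deletion, ``[("delete", 0, 1), ("delete", 3, 2)]`` for a
    one-base deletion with a compensatory two-base deletion one codon
    downstream.
    """
    if positions is None:
        positions = np.arange(region[0], region[1], 3)
    positions = np.asarray(positions, dtype=int)
    baseline = peak_statistic(seq, region, (), params, statistic)
    peaks = np.empty(len(positions))
    for i, p in enumerate(positions):
        edits = [
            EditOperation(
                kind=kind,  # type: ignore[arg-type]
                position=int(p + offset),
                length=length,
                inserted_bases=inserted_base * length if kind == "insert" else "",
            )
            for kind, offset, length in edit_template
        ]
        peaks[i] = peak_statistic(seq, region, edits, params, statistic)
    name = "+".join(f"{k[:3]}{l}" for k, _, l in edit_template)
    return MutationScanProfile(name, positions, peaks, baseline, tuple(region), params)


def frameshift_recovery_search(
    seq: NucleotideSequence,
    region: tuple[int, int],
    params: SpectralParams = SCAN_PARAMS,
    max_edits: int = 1,
    stride: int = 3,
    deletion_lengths: tuple[int, ...] = (1, 2),
    top_n: int = 10,
) -> list[tuple[tuple[EditOperation, ...], float]]:
    """Grid search for deletions that *increase* the region's peak.

    Evaluates every single 1- and 2-base deletion on a ``stride`` grid over
    the region (and, for ``max_edits=2``, ordered pairs of such deletions),
    then polishes the best cell at single-base resolution.  Returns the top
    combinations ranked by peak gain over the unedited baseline; ties break
    toward smaller positions.  A peak gain >> 0 marks a candidate ancient
    frame-shift whose reversal restores the coding-phase coherence.
    """
    if max_edits not in (1, 2):
        raise ValueError("max_edits must be 1 or 2")
    lo, hi = region
    min_span = int(2 * params.b)
    if hi - lo < max(min_span, stride):
        raise ValueError("region too short to scan")
    baseline = peak_statistic(seq, region, (), params)

    def evaluate(edits: tuple[EditOperation, ...]) -> float:
        return peak_statistic(seq, region, edits, params) - baseline

    grid = list(range(lo, hi, stride))
    candidates: list[tuple[tuple[EditOperation, ...], float]] = []
    singles: dict[tuple[int, int], float] = {}
    for p in grid:
        for dlen in deletion_lengths:
            combo = (EditOperation("delete", p, dlen),)
            gain = evaluate(combo)
            singles[(p, dlen)] = gain
            candidates.append((combo, gain))

    if max_edits == 2:
        for i, p1 in enumerate(grid):
            for dlen1 in deletion_lengths:
                for p2 in grid[i + 1 :]:
                    for dlen2 in deletion_lengths:
                        combo = (
                            EditOperation("delete", p1, dlen1),
                            EditOperation("delete", p2, dlen2),
                        )
                        candidates.append((combo, evaluate(combo)))

    candidates.sort(key=lambda c: (-c[1], tuple(e.position for e in c[0])))

    # single-base polish around the best grid cell
    best_combo, _ = candidates[0]
    polished: list[tuple[tuple[EditOperation, ...], float]] = []
    offsets = range(-(stride - 1), stride)
    if len(best_combo) == 1:
        e = best_combo[0]
        for off in offsets:
            p = e.position + off
            if lo <= p < hi and off != 0:
                combo = (EditOperation("delete", p, e.length),)
                polished.append((combo, evaluate(combo)))
    else:
        e1, e2 = best_combo
        for off1 in offsets:
            for off2 in offsets:
                p1, p2 = e1.position + off1, e2.position + off2
                if (off1, off2) != (0, 0) and lo <= p1 < hi and lo <= p2 < hi and p1 < p2:
                    combo = (
                        EditOperation("delete", p1, e1.length),
                        EditOperation("delete", p2, e2.length),
                    )
                    polished.append((combo, evaluate(combo)))
    candidates.extend(polished)
    candidates.sort(key=lambda c: (-c[1], tuple(e.position for e in c[0])))
    return candidates[:top_n]
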