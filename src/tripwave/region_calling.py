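"""Threshold-based calling of triplet-periodicity regions, with coarse-to-fine
boundary refinement.

Calling is a simple thresholding of a (max-normalized) PSD track: maximal
runs of positions above the cut-off (default 0.2), with sub-threshold gaps
shorter than ``merge_gap`` bridged and runs shorter than ``min_length``
discarded.  Real tracks are rugged, so the gap bridge (default 30 bases,
~10 codons) prevents one biological region from shattering into fragments;
the length floor (default 50 bases) drops calls too short to carry a
reliable periodicity signal.

Boundary refinement implements the hybrid strategy: call with a smaller
scale (wide envelope, noise-tolerant), then re-run the transform at a larger
scale (narrow envelope, sharp transitions) on a padded sub-interval around
each call and move each boundary to the nearest threshold crossing of the
fine-scale track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .periodicity_correction import CorrectedTrack
from .seq_encoding import IndicatorSet
from .spectral_core import PSDTrack, SpectralParams, mwt_psd

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.2
DEFAULT_MIN_LENGTH = 50
DEFAULT_MERGE_GAP = 30


@dataclass(frozen=True)
class TPRegion:
    """A called triplet-periodicity interval (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    peak_value: float
    mean_value: float
    calling_threshold: float
    refined: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def _runs_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = values > threshold
    if not above.any():
        return []
    diff = np.diff(above.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))
    return list(zip(starts, ends))


def call_regions(
    track: PSDTrack | CorrectedTrack,
    threshold: float = DEFAULT_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[TPRegion]:
    """Call maximal above-threshold runs on a PSD (or corrected) track.

    The threshold is interpreted on the track's own scale; callers who want
    the conventional 0.2 cut-off should pass a max-normalized track.  A
    threshold above every value yields an empty list, not an error.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    values = np.asarray(track.values, dtype=float)
    runs = [(int(s), int(e)) for s, e in _runs_above(values, threshold)]
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    regions = [
        TPRegion(
            seq_id=track.seq_id,
            start=start,
            end=end,
            peak_value=float(values[start:end].max()),
            mean_value=float(values[start:end].mean()),
            calling_threshold=threshold,
        )
        for start, end in merged
        if end - start >= min_length
    ]
    return regions


def refine_boundaries(
    ind: IndicatorSet,
    regions: list[TPRegion],
    coarse_params: SpectralParams,
    fine_params: SpectralParams,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[TPRegion]:
    """Sharpen coarse region boundaries with a larger-scale re-run.

    For each region the fine-scale transform is computed on the region
    padded by four fine-scale envelope widths, max-normalized over that
    window, and each coarse boundary is replaced by the nearest threshold
    crossing of the fine track.  A boundary with no crossing in the window
    keeps its coarse value (with a warning).
    """
    if fine_params.a <= coarse_params.a:
        raise ValueError("fine_params.a must exceed coarse_params.a")
    pad = int(4 * fine_params.envelope_sigma) + 1
    refined: list[TPRegion] = []
    for region in regions:
        lo = max(0, region.start - pad)
        hi = min(ind.length, region.end + pad)
        sub = mwt_psd(ind[lo:hi], fine_params)
        values = sub.values / sub.values.max() if sub.values.max() > 0 else sub.values
        above = values > threshold
        diff = np.diff(above.astype(np.int8))
        rising = np.where(diff == 1)[0] + 1  # first index above threshold
        falling = np.where(diff == -1)[0] + 1  # first index back below (exclusive end)
        new_start, new_end = region.start, region.end
        if rising.size:
            new_start = lo + int(rising[np.argmin(np.abs(rising + lo - region.start))])
        else:
            log.warning(
                "no rising crossing for region %d-%d; keeping coarse start",
                region.start, region.end,
            )
        if falling.size:
            new_end = lo + int(falling[np.argmin(np.abs(falling + lo - region.end))])
        else:
            log.warning(
                "no falling crossing for region %d-%d; keeping coarse end",
                region.start, region.end,
            )
        if new_end <= new_start:  # degenerate refinement; keep coarse
            new_start, new_end = region.start, region.end
        refined.append(replace(region, start=new_start, end=new_end, refined=True))
    return refined


def regions_to_bed(regions: list[TPRegion]) -> str:
    """BED6 text for a set of called regions (score = peak value scaled to 0-1000)."""
    lines = []
    for i, r in enumerate(regions):
        score = int(round(min(max(r.peak_value, 0.0), 1.0) * 1000))
        lines.append(f"{r.seq_id}\t{r.start}\t{r.end}\tTP{i + 1}\t{score}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def regions_report(regions: list[TPRegion]) -> str:
    """Human-readable report with 1-based inclusive coordinates."""
    lines = ["# region\tstart_1based\tend_1based\tlength\tpeak\tmean\trefined"]
    for i, r in enumerate(regions):
        lines.append(
            f"TP{i + 1}\t{r.start + 1}\t{r.end}\t{r.length}"
            f"\t{r.peak_value:.6g}\t{r.mean_value:.6g}\t{r.refined}"
        )
    return "\n".join(lines) + "\n"
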