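"""Per-base period-b power spectral density by STFT and by a modified wavelet.

Both methods operate on the four binary indicator tracks of a sequence and
report, for every base position, the power at the target period ``b`` (3 for
the triplet-periodicity signal, 6 for the hexamer control):

* **STFT** — a rectangular window of length ``window`` (a multiple of ``b``)
  slides along the sequence; at each center the discrete Fourier coefficient
  at frequency index ``k = window/b`` is taken per channel and the four
  squared magnitudes are summed,

      PSD = |U_A|^2 + |U_C|^2 + |U_G|^2 + |U_T|^2,
      U[k] = sum_n u[n] exp(-2*pi*i*k*n/window).

* **MWT** — a complex Morlet-style kernel whose carrier completes exactly one
  cycle every ``b`` bases *independently of the scale parameter* ``a``,

      psi[d] = exp(-(c*a*d/N)^2 / 2) * exp(2*pi*i*d/b),   d in [-N/2, N/2],
      U(a, k) = (1/a) * sum_d u[k + d] * conj(psi[d]),

  with the same four-channel power combination.  The Gaussian envelope's
  standard deviation is ``sigma = N / (c*a)`` bases, so *larger* ``a`` means a
  *narrower* effective analysis window: sharper boundary localization, lower
  peak amplitude.  The width constant ``c`` (:data:`ENVELOPE_WIDTH_CONST`) is
  fixed at 5.0, which at the defaults (N = 1200, a = 5) gives sigma = 48
  bases — an effective +/-2 sigma window of ~192 bases, comparable to the
  180-base STFT window it is benchmarked against.

Calibrated reporting scale
--------------------------
Raw MWT power grows with the envelope area and shrinks as 1/a^4, so absolute
values are not comparable across parameter sets.  The *calibrated* scale
divides the raw PSD by four times the squared response of the kernel to an
ideal infinite period-3 comb (ones every third base) under the same
parameters.  On this scale a perfectly codon-locked sequence — all four
channels periodic with period 3 — would score ~1, a single-channel period-3
comb scores 1/4 = 0.25, and pure period-6 and period-9 combs alias to
0.25/4 ~ 0.062 and 0.25/9 ~ 0.028.  See :func:`calibration_factor`.

Edge policy: positions whose window (STFT) or whose kernel envelope mass
(MWT, >50% overhang) extends past the sequence are computed on the truncated
support and flagged in ``PSDTrack.edge``; no values are invented there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal import fftconvolve

from .seq_encoding import IndicatorSet

#: Envelope width constant c: envelope std in bases is N / (c * a).
ENVELOPE_WIDTH_CONST = 5.0

#: Kernel taps below this fraction of the peak magnitude may be dropped.
TAP_EPSILON = 1e-12


@dataclass(frozen=True)
class SpectralParams:
    """All transform knobs.

    Parameters
    ----------
    N:
        Kernel/analysis-function length in bases (taps span [-N/2, N/2]).
        Default 1200; the junction-profile analysis conventionally uses 512.
    a:
        Scale parameter, dimensionless, > 0.  Default 5.  Larger values
        narrow the envelope (sharper boundaries, lower peaks).
    b:
        Target period in bases: 3 for triplet periodicity, 6 for the
        hexamer control.
    window:
        STFT window length in bases; must be an exact multiple of ``b``.
        Default 180.
    """

    N: int = 1200
    a: float = 5.0
    b: int = 3
    window: int = 180

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"scale parameter a must be > 0, got {self.a}")
        if self.b < 2:
            raise ValueError(f"target period b must be >= 2, got {self.b}")
        if self.N < self.b:
            raise ValueError(f"kernel length N ({self.N}) must be >= b ({self.b})")
        if self.window % self.b != 0:
            raise ValueError(
                f"STFT window ({self.window}) must be a multiple of b ({self.b})"
            )

    @property
    def omega0(self) -> float:
        """Basic frequency N/b (derived, never set independently)."""
        return self.N / self.b

    @property
    def envelope_sigma(self) -> float:
        """Gaussian envelope standard deviation in bases: N / (c*a)."""
        return self.N / (ENVELOPE_WIDTH_CONST * self.a)


@dataclass
class WaveletKernel:
    """Discrete modified-Morlet kernel: ``taps[i]`` at offset ``offsets[i]``."""

    offsets: np.ndarray  # integer offsets d in [-N/2, N/2]
    taps: np.ndarray  # complex taps envelope(d) * exp(2*pi*i*d/b)
    envelope: np.ndarray  # real Gaussian part
    params: SpectralParams


@dataclass
class PSDTrack:
    """Per-base PSD values aligned to sequence coordinates.

    ``edge`` flags positions computed on a truncated support (see module
    docstring).  ``normalization`` records the value scale: ``raw``,
    ``calibrated`` (see :func:`calibration_factor`) or ``max``.
    """

    seq_id: str
    values: np.ndarray
    method: Literal["STFT", "MWT"]
    params: SpectralParams
    normalization: Literal["raw", "calibrated", "max"] = "raw"
    edge: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("PSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0


def dft_coefficient(segment: np.ndarray, N: int, k: int) -> complex:
    """Discrete Fourier coefficient ``U[k] = sum_n u[n] exp(-2*pi*i*k*n/N)``.

    Direct summation over a length-``N`` segment; serves as the brute-force
    oracle for the sliding STFT.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) != N:
        raise ValueError(f"segment length {len(segment)} != N ({N})")
    if not 0 <= k < N:
        raise ValueError(f"frequency index k = {k} out of range [0, {N})")
    n = np.arange(N)
    return complex(np.sum(segment * np.exp(-2j * np.pi * k * n / N)))


def _sliding_dft(track: np.ndarray, window: int, k: int) -> np.ndarray:
    """U[k] of every length-``window`` slice (zero-padded at the edges).

    Output index c is the window *center* c = start + window//2; with zero
    padding the edge windows are effectively truncated sums.
    """
    phasor = np.exp(-2j * np.pi * k * np.arange(window) / window)
    left = window // 2
    right = window - 1 - left
    padded = np.concatenate([np.zeros(left), track.astype(float), np.zeros(right)])
    # convolve reverses its second argument, recovering sum_n u[s+n]*phasor[n]
    return np.convolve(padded, phasor[::-1], mode="valid")


def stft_psd(ind: IndicatorSet, params: SpectralParams | None = None) -> PSDTrack:
    """Sliding-window Fourier PSD at period ``b`` for each base position.

    The window center convention is ``start + window//2`` (left-of-middle
    for even windows).  Centers whose window overhangs either end are
    computed on the truncated window and flagged.
    """
    params = params or SpectralParams()
    L = ind.length
    W = params.window
    if W > L:
        raise ValueError(f"STFT window ({W}) exceeds sequence length ({L})")
    k = W // params.b
    psd = np.zeros(L)
    for row in ind.tracks:
        psd += np.abs(_sliding_dft(row, W, k)) ** 2
    edge = np.zeros(L, dtype=bool)
    left = W // 2
    right = W - 1 - left
    edge[:left] = True
    if right:
        edge[-right:] = True
    return PSDTrack(ind.seq_id, psd, "STFT", params, "raw", edge)


def build_kernel(params: SpectralParams) -> WaveletKernel:
    """Construct the discrete modified-Morlet kernel for ``params``.

    The carrier ``exp(2*pi*i*d/b)`` is pinned to the target period and does
    not depend on ``a``; only the Gaussian envelope (std ``N/(c*a)`` bases)
    responds to the scale.  Taps whose envelope is below ``TAP_EPSILON`` of
    the peak are zeroed (they are numerically irrelevant but keep the
    offsets grid regular).
    """
    N = params.N
    d = np.arange(-(N // 2), N // 2 + 1)
    envelope = np.exp(-0.5 * (d / params.envelope_sigma) ** 2)
    envelope[envelope < TAP_EPSILON] = 0.0
    taps = envelope * np.exp(2j * np.pi * d / params.b)
    return WaveletKernel(offsets=d, taps=taps, envelope=envelope, params=params)


def _literal_kernel(params: SpectralParams) -> WaveletKernel:
    """The literal continuous-formula discretization, kept for audit.

    Envelope ``exp(-(d/a)^2/2)`` (width *grows* with ``a``) and carrier
    ``exp(i*(N/b)*(d/a))``.  This reading does not reproduce the documented
    sharper-boundary/lower-peak behaviour of larger scales and is not used
    by any pipeline; see docs/methods.md.
    """
    N = params.N
    d = np.arange(-(N // 2), N // 2 + 1)
    envelope = np.exp(-0.5 * (d / params.a) ** 2)
    envelope[envelope < TAP_EPSILON] = 0.0
    taps = envelope * np.exp(1j * params.omega0 * d / params.a)
    return WaveletKernel(offsets=d, taps=taps, envelope=envelope, params=params)


def calibration_factor(params: SpectralParams) -> float:
    """Reference power used by the calibrated reporting scale.

    Equals ``4 * |U3|^2`` where ``U3`` is the kernel's response, at its own
    center, to an infinite period-3 comb (the sum of envelope taps at
    offsets divisible by 3, times 1/a).  The factor 4 makes a fully
    codon-locked four-channel sequence score ~1 and a single-channel
    period-3 comb score 0.25.  Depends only on ``N``, ``a`` and the width
    constant — deliberately *not* on ``b``, so that tracks computed with
    b = 3 and b = 6 remain directly comparable.
    """
    N = params.N
    d = np.arange(-(N // 2), N // 2 + 1)
    envelope = np.exp(-0.5 * (d / params.envelope_sigma) ** 2)
    u3 = envelope[d % 3 == 0].sum() / params.a
    return 4.0 * u3 * u3


def mwt_psd(
    ind: IndicatorSet,
    params: SpectralParams | None = None,
    scale: Literal["raw", "calibrated"] = "calibrated",
    convention: Literal["inverse", "literal"] = "inverse",
) -> PSDTrack:
    """Modified-wavelet PSD at period ``b`` for each base position.

    For every position k the discretized transform
    ``U = (1/a) * sum_d u[k+d] * conj(psi[d])`` is evaluated per channel
    (the conjugated-kernel correlation equals a plain convolution with the
    kernel because ``psi[-d] = conj(psi[d])``) and the four squared
    magnitudes are summed.  ``scale='calibrated'`` divides by
    :func:`calibration_factor`.
    """
    params = params or SpectralParams()
    if ind.length < params.b:
        raise ValueError("sequence shorter than the target period")
    kernel = build_kernel(params) if convention == "inverse" else _literal_kernel(params)
    psd = np.zeros(ind.length)
    for row in ind.tracks:
        u = fftconvolve(row.astype(float), kernel.taps, mode="same") / params.a
        psd += np.abs(u) ** 2
    # guard against tiny negative round-off
    np.maximum(psd, 0.0, out=psd)
    if scale == "calibrated":
        psd /= calibration_factor(params)
    # flag positions where more than half the envelope mass overhangs
    mass = np.cumsum(kernel.envelope)
    total = mass[-1]
    half = len(kernel.offsets) // 2
    L = ind.length
    pos = np.arange(L)
    hi = np.minimum(half + (L - 1 - pos), len(kernel.envelope) - 1)
    lo = np.maximum(half - pos, 0)
    overlap = mass[hi] - np.where(lo > 0, mass[lo - 1], 0.0)
    edge = overlap < 0.5 * total
    return PSDTrack(ind.seq_id, psd, "MWT", params, scale, edge)


def single_track_indicators(track: np.ndarray, seq_id: str = "signal") -> IndicatorSet:
    """Wrap one binary track as an IndicatorSet with three null channels.

    Used for simulated comb signals: the four-channel PSD then reduces to
    ``|U|^2`` of the single track.
    """
    track = np.asarray(track)
    tracks = np.zeros((4, len(track)), dtype=np.uint8)
    tracks[0] = track.astype(np.uint8)
    return IndicatorSet(seq_id, tracks)


def normalize_track(track: PSDTrack, reference_max: float | None = None) -> PSDTrack:
    """Divide by ``reference_max`` (default: the track's own maximum).

    A null track is returned unchanged (still flagged ``max``); an explicit
    non-positive reference is an error.
    """
    if reference_max is not None and reference_max <= 0:
        raise ValueError(f"reference_max must be > 0, got {reference_max}")
    ref = reference_max if reference_max is not None else track.max
    values = track.values if ref == 0 else track.values / ref
    return replace(track, values=values, normalization="max")
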