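"""Deterministic generators for every simulated input class.

Four families of fixtures:

* exact-period binary combs (the canonical simulated signal: a length-900
  track with ones every p bases between positions 300 and 600, p in
  {3, 6, 9});
* codon-biased "genes": exons sampled from a per-codon-position nucleotide
  frequency table, flanked by uniform-background introns/UTRs, optionally
  with planted frame-shift edits and planted 6-bp repeat tracts;
* junction pairs: two codon-biased segments concatenated with a chosen
  reading-frame offset between them (fixtures for the splice-junction
  valley analysis);
* pure 6-bp repeat tracts (false-positive generators for the aliasing
  correction).

All generators are pure functions of (spec, seed): the same inputs always
produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_encoding import BASES, NucleotideSequence

#: Default per-codon-position nucleotide frequencies (rows: codon positions
#: 0..2; columns: A, C, G, T).  One base dominates each position (G, A, T at
#: weight 0.7), giving a strong but not degenerate triplet periodicity
#: comparable in strength to real codon bias in compact genomes.
DEFAULT_CODON_BIAS = np.array(
    [
        [0.10, 0.10, 0.70, 0.10],
        [0.70, 0.10, 0.10, 0.10],
        [0.10, 0.10, 0.10, 0.70],
    ]
)

#: Uniform background used for introns, UTRs and intergenic tracts.
UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class CombSpec:
    """An exact-period binary comb: u[n] = 1 iff s <= n <= e and (n-s) % p == 0."""

    length: int = 900
    start: int = 300
    end: int = 600
    period: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end < self.length):
            raise ValueError("comb interval must satisfy 0 <= start <= end < length")
        if self.period < 2:
            raise ValueError("comb period must be >= 2")

    @property
    def n_ones(self) -> int:
        return (self.end - self.start) // self.period + 1


def make_comb(spec: CombSpec | None = None, **kwargs) -> np.ndarray:
    """Generate the binary comb track for ``spec`` (keyword overrides allowed)."""
    if spec is None:
        spec = CombSpec(**kwargs)
    u = np.zeros(spec.length, dtype=np.uint8)
    u[np.arange(spec.start, spec.end + 1, spec.period)] = 1
    return u


@dataclass(frozen=True)
class FrameShiftPlant:
    """A deliberate frame-shift built into a generated gene.

    ``position`` is a coordinate in the *final* sequence; an insertion adds
    ``length`` copies of ``base`` there, a deletion removes ``length`` bases.
    """

    kind: str  # "insert" | "delete"
    position: int
    length: int = 1
    base: str = "A"


@dataclass
class GeneSpec:
    """Layout and composition of a synthetic gene.

    The sequence is utr5 + exon1 + intron1 + exon2 + ... + utr3; exons are
    sampled from ``codon_bias`` with the reading frame continuing across
    introns, everything else from ``background``.
    """

    exon_lengths: tuple[int, ...] = (300, 300)
    intron_lengths: tuple[int, ...] = (300,)
    utr5: int = 200
    utr3: int = 200
    codon_bias: np.ndarray = field(default_factory=lambda: DEFAULT_CODON_BIAS.copy())
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    frameshifts: tuple[FrameShiftPlant, ...] = ()
    hexamer_tracts: tuple[tuple[int, int], ...] = ()  # (start, length) in intergenic coords
    seed: int = 0

    def __post_init__(self) -> None:
        self.codon_bias = np.asarray(self.codon_bias, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.codon_bias.shape != (3, 4):
            raise ValueError("codon_bias must be a (3, 4) table")
        if np.any(self.codon_bias < 0) or not np.allclose(self.codon_bias.sum(axis=1), 1.0):
            raise ValueError("codon_bias rows must be non-negative and sum to 1")
        if not np.allclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if len(self.intron_lengths) != max(len(self.exon_lengths) - 1, 0):
            raise ValueError("need exactly one intron between consecutive exons")
        if any(l < 0 for l in self.exon_lengths + self.intron_lengths + (self.utr5, self.utr3)):
            raise ValueError("all lengths must be >= 0")


def _sample(rng: np.random.Generator, length: int, probs: np.ndarray, phase0: int = 0) -> str:
    """Sample ``length`` bases; a (3,4) table cycles codon positions from phase0."""
    if length == 0:
        return ""
    if probs.ndim == 1:
        idx = rng.choice(4, size=length, p=probs)
    else:
        idx = np.empty(length, dtype=np.int64)
        for phase in range(3):
            sel = (np.arange(length) + phase0) % 3 == phase
            idx[sel] = rng.choice(4, size=int(sel.sum()), p=probs[phase])
    return "".join(BASES[i] for i in idx)


def make_gene(spec: GeneSpec | None = None, **kwargs) -> tuple[NucleotideSequence, dict]:
    """Generate a synthetic gene and its ground-truth annotations.

    Returns the sequence plus a truth dict with 0-based half-open ``exons``,
    spliced-coordinate ``junctions``, applied ``frameshifts`` and
    ``hexamer_tracts``.
    """
    if spec is None:
        spec = GeneSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = [_sample(rng, spec.utr5, spec.background)]
    exons: list[tuple[int, int]] = []
    pos = spec.utr5
    frame = 0
    for i, elen in enumerate(spec.exon_lengths):
        parts.append(_sample(rng, elen, spec.codon_bias, phase0=frame))
        exons.append((pos, pos + elen))
        pos += elen
        frame = (frame + elen) % 3
        if i < len(spec.intron_lengths):
            ilen = spec.intron_lengths[i]
            parts.append(_sample(rng, ilen, spec.background))
            pos += ilen
    parts.append(_sample(rng, spec.utr3, spec.background))
    residues = "".join(parts)

    for start, length in spec.hexamer_tracts:
        unit = _sample(rng, 6, spec.background)
        tract = (unit * (length // 6 + 1))[:length]
        residues = residues[:start] + tract + residues[start + length :]

    for fs in spec.frameshifts:
        if fs.kind == "insert":
            residues = residues[: fs.position] + fs.base * fs.length + residues[fs.position :]
        elif fs.kind == "delete":
            residues = residues[: fs.position] + residues[fs.position + fs.length :]
        else:
            raise ValueError(f"unknown frameshift kind {fs.kind!r}")

    # junction positions in spliced (intron-free) coordinates
    junctions: list[int] = []
    acc = 0
    for elen in spec.exon_lengths[:-1]:
        acc += elen
        junctions.append(acc)

    truth = {
        "exons": exons,
        "junctions": junctions,
        "frameshifts": spec.frameshifts,
        "hexamer_tracts": spec.hexamer_tracts,
    }
    return NucleotideSequence(f"synthetic_gene_seed{spec.seed}", residues), truth


def make_junction_pair(
    bias_a: np.ndarray | None = None,
    bias_b: np.ndarray | None = None,
    phase_shift: int = 1,
    flank: int = 300,
    seed: int = 0,
) -> tuple[NucleotideSequence, int]:
    """Two codon-biased exon segments concatenated at a junction.

    The downstream segment's reading frame is offset by ``phase_shift``
    bases (0, 1 or 2) relative to the upstream one.  Returns the spliced
    sequence and the junction coordinate (0-based index of the first base
    of the downstream segment, i.e. ``flank``).
    """
    if phase_shift not in (0, 1, 2):
        raise ValueError("phase_shift must be 0, 1 or 2")
    bias_a = DEFAULT_CODON_BIAS if bias_a is None else np.asarray(bias_a, dtype=float)
    bias_b = bias_a if bias_b is None else np.asarray(bias_b, dtype=float)
    rng = np.random.default_rng(seed)
    up = _sample(rng, flank, bias_a, phase0=0)
    # continue the frame across the junction, then offset it by phase_shift
    down = _sample(rng, flank, bias_b, phase0=(flank + phase_shift) % 3)
    return NucleotideSequence(f"junction_pair_seed{seed}", up + down), flank


def make_hexamer_tract(length: int = 300, seed: int = 0, flank: int = 300) -> NucleotideSequence:
    """A uniform-background sequence carrying a pure 6-bp repeat in its middle.

    A classic false-positive generator for period-3 detection: the repeat's
    period-6 structure aliases into the period-3 band.
    """
    rng = np.random.default_rng(seed)
    unit = _sample(rng, 6, UNIFORM_BACKGROUND)
    tract = (unit * (length // 6 + 1))[:length]
    left = _sample(rng, flank, UNIFORM_BACKGROUND)
    right = _sample(rng, flank, UNIFORM_BACKGROUND)
    return NucleotideSequence(f"hexamer_tract_seed{seed}", left + tract + right)
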