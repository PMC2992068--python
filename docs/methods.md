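# Methods

## The signal

Protein-coding DNA tends to repeat nucleotide preferences with period 3:
codon structure plus codon-usage bias make, say, G more likely at the first
codon position and T at the third.  In the power spectrum of the four binary
indicator tracks (u_A, u_C, u_G, u_T — one per base, 1 where that base
occurs) this shows up as a peak at frequency 1/3 per base over coding
regions and not over introns, UTRs or intergenic sequence.  Everything in
this package is a way of measuring that peak per base position, delimiting
where it starts and stops, and interrogating how it responds to sequence
edits.

## Transforms

**STFT.**  A rectangular window of length `window` (default 180, always a
multiple of the target period b) slides along the sequence.  At each center
position the DFT coefficient at frequency index `k = window/b` is computed
per channel and the squared magnitudes summed:

    PSD = |U_A|^2 + |U_C|^2 + |U_G|^2 + |U_T|^2,
    U[k] = sum_{n=0}^{window-1} u[n] exp(-2*pi*i*k*n/window).

The center of an even window is `start + window//2` (a deterministic
left-of-middle tie-break).  The sliding computation uses a direct (not FFT)
convolution so it agrees with the brute-force summation to rounding error;
this agreement is asserted property-style in the tests.

**Modified wavelet.**  The core transform is a complex Morlet-style kernel
evaluated at integer offsets d in [-N/2, N/2] (unit step — sequences are
integer-indexed; N defaults to 1200):

    psi[d] = exp(-(d/sigma)^2 / 2) * exp(2*pi*i*d/b),    sigma = N/(c*a),
    U(a,k) = (1/a) * sum_d u[k+d] * conj(psi[d]),

with the same four-channel power combination.  Two properties define the
method:

* the carrier completes one cycle every b samples *independently of the
  scale a* — the transform always interrogates the same period, unlike a
  conventional wavelet whose frequency slides with scale (automatic
  multi-scale frequency capture is useless here because coding regions
  present period 3 at every scale);
* only the Gaussian envelope responds to a, and its width is *inversely*
  proportional to a.  Larger scales therefore mean a narrower effective
  analysis window: sharper boundary localization, lower peak amplitude,
  less noise tolerance.  A continuous-formula reading in which the envelope
  widens with a instead is retained behind `mwt_psd(...,
  convention="literal")` for audit; it does not reproduce the
  sharper-boundary/lower-peak behaviour the method relies on and is used by
  nothing else.

The width constant c = 5.0 is fixed: at the defaults (N = 1200, a = 5) it
gives sigma = 48 bases, an effective ±2σ window of ≈192 bases, deliberately
comparable to the 180-base STFT window the method is benchmarked against.
Kernel taps below 1e-12 of the peak envelope are zeroed (not configurable).

**Edge policy.**  Positions whose STFT window, or more than half of whose
MWT envelope mass, overhangs a sequence end are computed on the truncated
support and flagged in `PSDTrack.edge`.  No signal is invented at edges;
flagged values are kept so tracks stay coordinate-aligned.

## The calibrated reporting scale

Raw MWT power scales with the envelope area and as 1/a^4, so raw values are
incomparable across parameter sets.  `mwt_psd` therefore reports, by
default, raw power divided by `4 * |U3|^2`, where U3 is the kernel's
response to an ideal infinite period-3 comb under the same parameters
(`calibration_factor`).  Consequences:

* a single-channel period-3 comb scores ≈ 0.25 (one of four channels
  contributing);
* pure period-6 and period-9 combs, which alias into the period-3 band with
  1/2 and 1/3 of the comb's pulse density, score ≈ 0.25/4 ≈ 0.062 and
  0.25/9 ≈ 0.028 (the exact discrete values for the default length-900,
  active-300–600 comb are 0.2492, 0.0623, 0.0277);
* the divisor is deliberately independent of b, so b = 3 and b = 6 tracks
  computed with the same a and N are directly comparable — the aliasing
  correction depends on this.

The 1/4 and 1/9 *ratios* are normalization-free and hold on the raw scale
too.

## 6-bp aliasing correction

A pure period-6 tract produces a period-3 peak of essentially the same
amplitude as its period-6 peak (at offsets divisible by 6 both carriers are
in phase), so `corrected = max(0, PSD_b3 − PSD_b6)` removes such false
positives while reducing a genuine period-3 signal by under ~1% (the b = 6
carrier alternates sign between successive period-3 pulses and cancels).
Subtraction always happens on the common raw/calibrated scale, never after
per-track max-normalization, which would destroy the amplitude equality it
exploits.  A flag-only mode reports intervals where the control matches the
period-3 track (with a signal floor of 5% of the track maximum, since
zero-signal background trivially satisfies control ≥ tp) without altering
values.  A period-9 control is available the same way but off by default —
its aliased contribution is only 1/9, so period-9 false positives are
correspondingly rarer.

## Region calling and refinement

Regions are maximal runs above a threshold (default 0.2 on a max-normalized
track), with sub-threshold gaps under `merge_gap = 30` bases (~10 codons)
bridged and runs under `min_length = 50` bases discarded.  The gap and
length defaults are this package's choices: real tracks are rugged, and
calls much shorter than ~50 bases carry too few codons to be reliable.
Raising the threshold never widens a call.

Refinement implements the coarse-to-fine strategy: call at a smaller scale
(wide envelope, robust), then recompute the track at a larger scale on each
region padded by four fine-scale sigmas, max-normalize within that window,
and move each boundary to the nearest threshold crossing.  A missing
crossing keeps the coarse boundary and logs a warning.  On the standard
period-3 comb, calling at a = 5 places both boundaries within ~7 bases of
the truth and refining at a = 10 tightens them to ~3–4 bases.

## Frame-shift scanning

`peak_statistic` applies a set of edits, recomputes the transform, and
takes the maximum PSD over the stated region of interest (coordinates
remapped through the edits; a mean-over-region statistic is available).
The scanning analyses default to a = 2.5 (`SCAN_PARAMS`), wider than the
boundary-calling default, deliberately: the statistic is integrative, and
the envelope (sigma = 96 bases at N = 1200) must span the region for a
phase break anywhere in it to suppress the single dominant peak.  At a = 5
the two out-of-phase halves created by a central 1-base deletion are
resolved as two separate, individually coherent peaks and the regional
maximum barely drops.

Phenomenology on a 300-base comb, reproduced in the tests: an in-frame
3-base deletion changes the peak by <5% (one pulse of ~100 lost); a
mid-region 1-base deletion collapses it to ~0.32 of baseline (the halves
sit 2π/3 out of phase); a compensatory 2-base deletion one codon downstream
restores ~0.95 of baseline, and an adjacent one is exactly an in-frame
3-base deletion.  Single-base substitutions move ~1% of one channel's
amplitude and change the peak by ~1–2%.

`frameshift_recovery_search` grid-scans single 1- and 2-base deletions
(stride 3 by default; exhaustive pairs are quadratic, so paired search uses
the same stride plus a single-base polish around the best cell) and ranks
them by peak gain over baseline, ties broken toward smaller positions.  A
gain of order the baseline itself marks a candidate ancient frame-shift;
boundary-adjacent deletions can pick up a few percent of spurious gain by
shuffling flanking composition into the region, which is why gains below
~10% are noise.

## Junction profiles

Adjacent exons generally differ in codon-bias phase and composition, so the
PSD dips where the envelope straddles a junction in spliced mRNA.
`aggregate_profile` averages per-junction windows [-W, W] (junction = offset
0 = first base of the downstream exon; W default 200) across a junction
set, reporting mean and standard error per offset; all tracks use identical
parameters (this analysis conventionally uses N = 512, a = 5), so no
per-junction renormalization is applied.  Junction collection from exon
annotations enforces a minimum exon length on both sides (default 150
bases) and excludes junctions touching a first or last exon (UTR
contamination).  `trimmed_profile` deletes `trim` bases on each side of
every junction before transforming — if the valley were caused by local
sequence elements near the splice site it would vanish; a phase difference
between the exons survives any symmetric trim.

A one-base phase offset between flanks puts their carriers 2π/3 apart and
drops the mid-valley amplitude to ~1/2 (PSD to ~1/4) of the flank level.
Offsets of 1 and 2 give equal valley depth (relative phases ±2π/3 have the
same magnitude); only offset 0 is flat.

## Synthetic data

The generators (`synthetic_data`) are pure functions of (spec, seed):

* **Combs** — u[n] = 1 iff start ≤ n ≤ end and (n − start) mod p = 0; both
  endpoints may be active (for the default 300–600 interval the last pulse
  is at 600 for p ∈ {3, 6} and 597 for p = 9).  Defaults: length 900,
  active 300–600.
* **Genes** — exons sampled independently per position from a (3 × 4)
  codon-position frequency table (default: G/A/T dominant at weight 0.7 on
  positions 1/2/3), reading frame continuing across introns; introns and
  UTRs from a uniform background; optional planted frame-shift edits and
  6-bp repeat tracts.  The 0.7 weight gives a calibrated exon signal
  (~0.27) comparable to the ideal comb against a background of ~0.01,
  i.e. strong but not degenerate codon bias.
* **Junction pairs** — two codon-biased segments concatenated with the
  downstream frame offset by 0/1/2 bases (default flank 300).
* **Hexamer tracts** — a random 6-mer repeated inside uniform background.

What the generator does *not* emulate: dicodon/hexamer statistics, GC
heterogeneity, repeat families, real splice-site motifs, strand asymmetry,
or genes whose triplet signal varies along the exon.  Passing tests
demonstrate correct behaviour of the transforms and callers under clean,
first-order codon bias; on real genomes the signal-to-noise is worse and
thresholds (0.2, min_length, merge_gap) may need tuning per species.

## Numerical choices and degenerate inputs

Problem sizes throughout the suite are desk-scale by design: combs of 900
bases, genes of ~1.3 kb, 200 junction pairs of 600 bases — large enough
that envelope truncation effects are below 0.1% of peak values.  MWT uses
`scipy.signal.fftconvolve` (deterministic); STFT uses direct convolution.
Empty sequences and non-IUPAC residues are rejected at construction;
all-ambiguous input yields an all-zero track, which max-normalization
returns unchanged; a threshold above the track maximum yields zero calls; a
transcript with fewer than two exons contributes no junctions; an empty
junction set is an error.  Ambiguity codes map to 0 in all four channels
(no fractional weights).  Coordinates are 0-based half-open internally;
reports and the CLI echo 1-based inclusive.

## Known limitations

* The method measures periodicity, not coding potential: phase-locked
  repeats (satellites, some transposons) score high, and genuinely coding
  exons with weak codon bias score low.
* Exons shorter than roughly half the envelope width produce attenuated
  peaks (a ~112-base exon at a = 5 is near the detection floor).
* The calibrated scale assumes the default envelope family; changing the
  width constant would require re-deriving nothing, but comparisons across
  different c values are meaningless.
* No reading-frame assignment, ORF analysis, splice-motif (GT-AG) snapping
  or gene-model assembly is attempted.
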