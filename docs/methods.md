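# Methods

This note records the models the package implements, the parameters
that matter, and the design choices made where the method description
left room. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model

A recording is a uniformly sampled pressure series (mmHg). The working
assumption is additive structure on three time scales: macro-patterns
(tens of seconds to tens of minutes — the objects of interest), cardiac
(~1 Hz) and respiratory (~0.2–0.3 Hz) oscillations, broadband
measurement noise, and rare unphysiological spikes (sub-second, tens of
mmHg). The pipeline removes the spikes, anchors segment boundaries on a
heavily smoothed copy, and analyzes shape on the z-normalized
subsequences of the *unfiltered* artifact-removed signal, so cardiac and
respiratory content remains part of each subsequence.

## Artifact removal

**EMD.** Classical sifting: cubic-spline upper/lower envelopes through
the local extrema (first sample of a plateau run counts as the
extremum), stopping an IMF when the Cauchy criterion
Σ(h_prev − h)²/Σh_prev² < 0.2 or after 10 sifting iterations, and
stopping the decomposition when the residual has fewer than two extrema
of either kind or `max_imfs` (default 16) is reached. Envelope end
effects are suppressed by mirroring the two outermost extrema beyond
each end. IMFs plus residual reconstruct the input to floating point by
construction.

**Spike detection.** The partial reconstruction sums IMF orders
{1,2,3,4} by default; the subset is a parameter because which IMFs carry
the spikes is a property of the data. The threshold is the
Donoho–Johnstone universal threshold η_s = σ√(2 ln L) with σ the plain
(non-robust) standard deviation of g_r over all L samples, and the
natural logarithm. Samples with |g_r| > η_s are flagged.

**Mask refinement and imputation.** Before imputation, gaps shorter
than 0.5 s between flagged runs are closed (spikes last under a second,
and the partial reconstruction attenuates the interior of wide
rectangular spikes, leaving detected edges with a gap between them) and
every run is dilated by 2 samples per side to remove spike shoulders.
Flagged samples are replaced by the mean of non-flagged samples in a
**centered** 10 s window, widening (doubling) when a window holds no
donor. Imputed values depend only on donor samples, so the operation is
idempotent and leaves non-flagged samples bit-identical. The spline
envelopes of EMD ring for roughly 1–2 s around a large spike; those
shoulder samples exceed the threshold and are removed together with the
spike, which is desirable — they are artifact contamination.

## Segmentation

**Smoothing filter.** A linear-phase FIR lowpass with passband edge
0.05 Hz, stopband edge 0.1 Hz, passband ripple 0.001 dB and stopband
attenuation 60 dB (all configurable), applied with reflect padding and
'valid' convolution so the output is time-aligned and length-preserving.
The design is a Kaiser-window minimum-order fit to the ripple spec with
a 2× margin on δ: an equiripple exchange design does not converge at
this band (a transition of 0.05 Hz at fs = 100 Hz needs ≈8000 taps),
while the Kaiser design is robust at any length. Published band values
for this filter place the "passband" above the "stopband" for a
lowpass; that is read as a transposition, and the pass edge sits below
the stop edge here. The filtered signal is used **only** to place
boundaries.

**Extrema and pruning.** Interior extrema of the smoothed signal
alternate strictly; plateaus resolve to their first sample for
determinism. A minimum is removed when, against its nearest flanking
maximum in the evolving list, the time gap is under η_dur (default
1 min, typical range 0.5–2) **or** the magnitude gap is under η_mag
(default 1 mmHg, typical range 0.5–1.5). Minima are visited in time
order; after a removal the two now-adjacent maxima merge, keeping the
larger, so later candidates are judged against the merged landscape.
Minima within η_dur of the recording ends are also dropped: the filter's
edge response creates a shallow dip a few seconds into the record, and
keeping it would cut sliver subsequences shorter than the duration rule
allows anywhere else. The first and last samples are always boundaries,
so subsequences tile the recording exactly, sharing boundary samples.

**z-normalization** uses the population (divide-by-n) standard
deviation, the time-series-mining convention. Constant windows are
flagged degenerate and excluded from clustering and matching.

## Shape space and k-Shape

**Common length.** Subsequences span two orders of magnitude in
duration, so they are resampled to m = 128 points before clustering:
block-average anti-aliasing down to ≈4m samples when the input is
longer (point interpolation would fold the cardiac/respiratory/noise
power into the shape vector, where it would rival the macro-pattern
itself), then linear interpolation and re-z-normalization. Resampling
was chosen over zero-padding because padding would dominate the
correlation for short subsequences.

**SBD.** The coefficient-normalized cross-correlation over all integer
shifts w ∈ [−(m−1), m−1] is computed by FFT with next-power-of-two
padding; its contract — equality with direct shift-and-dot enumeration
to 1e-10 — is enforced by property tests and the acceptance script.
SBD = 1 − max_w NCC ∈ [0, 2]. Ties in the maximizing shift resolve to
the smallest |w|. Note one quantitative property of the zero-padded
linear correlation: shifting a z-normalized shape by s samples costs
about s·(baseline²)/m of correlation even when the alignment is
recovered exactly, so SBD grows linearly in the shift (≈0.1 at m/4 for
a compact bump) rather than staying near zero.

**Clustering.** k-Shape alternates assignment (minimum SBD, ties to the
lowest cluster index) and refinement (members aligned to the previous
centroid by their best shift; the new centroid is the principal
eigenvector of the centered alignment matrix, z-normalized, sign chosen
by positive summed correlation), for at most 100 iterations. Empty
clusters are re-seeded with the vector farthest from its assigned
centroid. Initialization is greedy k-means++-style in SBD space
(several candidates per step, keep the one minimizing total potential):
plain random-label initialization was measured to stall in local optima
that merge two shape families on a substantial fraction of seeds, and
the final SBD objective cannot arbitrate restarts because centroid
extraction is alignment-path-dependent. For the same reason the run is
repeated `n_init` = 3 times with derived seeds and the partition with
the highest mean SBD silhouette is kept. Everything is deterministic
given (data, K, seed).

**K selection** scans a window (default 5–20; the synthetic experiments
use windows matched to their menu sizes) and maximizes the mean SBD
silhouette, smallest K on ties, with per-K seeds derived from one base
seed.

## Cluster validity

Silhouette and Davies–Bouldin default to SBD, the pipeline's own metric;
Calinski–Harabasz uses Euclidean scatter in the resampled space because
a trace of scatter has no SBD analogue. 1 − DBI is reported alongside
DBI so that all three indices read "higher is better"; it can be
negative. CHI uses the standard correction (n_p − K)/(K − 1); the
variant factor (n_p − 1)/(n_p − K) that appears in some writeups is
available behind `legacy_correction=True`. Singleton clusters score
silhouette 0. The with/without-correlation-rule comparison recomputes
the indices on the retained subset only.

## Matching

Templates are cluster centroids with unique labels, stored as a
versioned JSON container (arrays in full float precision; loaders
reject unknown versions). A query is z-normalized, resampled to the
library length — "time rescaling" is this single common-length mapping,
not a multi-scale search, because templates are stored time-normalized
and SBD supplies residual shift tolerance — and the closest template by
SBD wins **iff** CC = 1 − SBD > 0.50 (configurable); otherwise
UNCLASSIFIED. Degenerate queries are UNCLASSIFIED with a reason code.
Duration accounting counts each shared boundary sample once, so percent
classified is Σ(j−i) of classified windows over the recording span.

## Synthetic data

The generator emulates what the pipeline needs to see: a baseline
(10 mmHg) carrying a minima-to-minima concatenation of macro-patterns,
cardiac (1.1 Hz, 1.5 mmHg) and respiratory (0.25 Hz, 1 mmHg) sinusoids,
white noise (sd 0.3 mmHg), and rectangular spikes of 1–50 samples
(log-uniform widths, ±50 mmHg, ~2 per hour — rare, as in practice).
Recording shapes must start and end at their minimum so ground-truth
boundaries are true local minima; the menu therefore admits
`sinusoid`, `ramp_asym` (apex at 80% — markedly asymmetric so it is
distinct from the symmetric arch in SBD), `plateau_wave` (10% smoothstep
edges), and `peak` (narrow Gaussian on a 0.2-amplitude half-sine
pedestal: with perfectly flat tails the region between patterns is a
plain of sub-η_mag wiggles whose minima the pruning cascade removes
wholesale). `ascend`, `descend` and `flat_drift` exist for shape-space
work; note `ascend` and `flat_drift` are identical after
z-normalization (both lines), so "distinct shape" sets never use both.
Defaults: one hour at 100 Hz, 4–10 min patterns of 2–10 mmHg.

What the generator does **not** emulate: pulse-wave morphology (the
cardiac component is a pure sinusoid), slow stochastic baseline wander,
posture or sleep-stage transitions, sensor drift, and pattern shapes
outside the menu. Passing tests therefore demonstrate that the pipeline
recovers known structure under controlled conditions, not that cluster
libraries learned on real patients are clinically valid.

## Study-scale choices

The fit/apply experiment uses five 2.5 h "main" recordings and two
"additional" recordings from a four-shape menu (4–10 min segments,
3–8 mmHg), η_dur = 0.5 min, η_mag = 0.75 mmHg, K selected over 4–10.
Segment durations are long relative to the smoothing filter's boundary
smear (group delay ≈49 s at the default band) so extracted windows stay
close to their generating shapes. Oracle checks run at m ≤ 32 where
enumeration is exact; cluster-recovery and K-selection experiments use
200 and 120 vectors at m = 128. These sizes keep the full suite and the
acceptance script in the tens of seconds on one CPU while leaving each
effect measured far from its pass boundary.

## Known limitations

- Boundary placement inherits the smoothing filter's smear; minima
  between patterns of very different amplitude can shift by tens of
  seconds, producing hybrid subsequences at segment joins. The
  correlation gate leaves such windows unclassified rather than
  mislabeling them, at the cost of coverage.
- The duration rule prunes genuine boundaries when a pattern's shoulder
  rises within η_dur of its boundary (e.g. short plateau waves); η_dur
  must be chosen per recording with that trade-off in mind.
- EMD has no convergence guarantee; pathological signals could yield
  fewer than four IMFs, in which case the available orders are summed.
- k-Shape optimizes a non-convex objective; restarts reduce but cannot
  eliminate local optima.
- CSV/HDF5 readers expect single-channel data; vendor binary formats
  are out of scope.
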