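# Methods

## Acquisition model

A stepped-isolation DI-MS2 measurement cycle targets one nominal mass x and
records one MS2 scan per isolation-window position. Centres are
c_i = x + start_offset + i·step for i = 0 … n−1 with
n = floor((end_offset − start_offset)/step) + 1 and the last centre clipped
to x + end_offset. Defaults (start −0.7 Th, end +0.9 Th, step 0.02 Th,
window width 1.0 Th) give 81 events per cycle. The event count follows from
the arithmetic alone and is never hardcoded for particular window widths;
offsets for wider or narrower windows are ordinary configuration values.
A small relative epsilon (1e-9) guards the floor against float rounding
when the range is an exact multiple of the step.

## Transmission and the simulator

The quadrupole/LIT band-pass is modelled as a trapezoid: transmission 1 for
|m/z − c| ≤ width/4, falling linearly to 0 at (width/2)·width_scale. The
flat-top-plus-linear-edges shape is the simplest curve with the imperfect
band-pass behaviour that drives the method; the true instrument profile is
not published, so a Gaussian alternative is selectable. Two phenomenologies
are covered:

* `shifted_bandpass` (quadrupole-like): isobars produce profiles translated
  by Δm/z / step scans;
* `widened_bandpass` (ion-trap-like): `width_scale` > 1 (optionally
  asymmetric per flank) stretches a profile so that one isobar appears
  first and disappears last. The widening is phenomenological — its
  physical origin in ion traps is unsettled — and is deliberately not
  coupled to collision energy, where the empirical link to NCE50 is known
  to be imperfect.

Per scan, each precursor deposits base_intensity · transmission, split
between the surviving precursor ion and its fragments by branching
fractions (summing to ≤ 1). Its first isotopologue sits +1.00336 Th higher
(13C spacing; abundance default 0.19, matching a ~C18 compound at nominal
mass 342) and produces the same fragments, which adds the characteristic
late-cycle contamination bump as the window approaches the isotopologue.
Shared fragments accumulate contributions from every producer. Noise is
multiplicative lognormal (exp of a zero-mean normal with sd
`noise_sd_rel`); a detection floor at `noise_floor_rel` (default 1e-4) of
the noiseless maximum drops peaks from individual scans, emulating
low-intensity dropout; blank/solvent peaks are added at constant intensity.
All randomness flows from one integer seed through one `numpy` generator.

The two-isobar preset mirrors the study conditions the package is built
around: precursors at nominal ± Δm/z/2 with Δm/z in the 0.006–0.048 range,
base intensity 1e6 (ratio configurable up to the ~20:1 imbalance of the
hardest mixture), four unshared fragments each (branching 0.08–0.25) plus
an optional shared fragment at 10%, and two constant blank peaks at 5% and
1% of the precursor base intensity.

What the simulator does not emulate: ion statistics / shot noise, AGC and
microscan effects, resolution-dependent peak merging (spectra are stick
spectra), retention of profile-mode shapes, or real fragmentation
chemistry. Passing tests on simulated data therefore demonstrate the
correctness of the processing chain and its qualitative behaviour
(degradation with Δm/z → 0, isotopologue contamination, blank removal),
not instrument-level performance.

## Deconvolution chain

1. **Template.** The seed scan is the one with maximal total ion intensity
   (TIC; the base-peak criterion is available via `seed_mode` since the
   notion of the "most intense" scan is ambiguous). It is merged with
   5 scans before and 5 after (truncated at the series boundaries) using
   greedy nearest-neighbour clustering within an absolute tolerance
   (`match_tol`, default 0.002 Th — all method tolerances are stated in
   mDa, so ppm matching is deliberately not used). Consensus m/z is the
   intensity-weighted mean, consensus intensity the mean over cluster
   members. Each scan is ground-noise filtered at 0.3% of its base peak
   before merging and the merged template again at 0.3% of the template
   base peak (the filter-then-merge order matters for peaks that are weak
   in only some scans; both cuts use ≥, so a peak exactly at the threshold
   survives). Template peaks matching a blank peak whose intensity exceeds
   1% of the blank base peak are removed; the blank match uses the same
   `match_tol` (no separate tolerance is defined by the method). Noise
   filtering precedes blank subtraction; both orders are defensible and the
   choice is visible in the code path.
2. **Intensity matrix.** Entry (p, s) is the summed intensity of scan-s
   peaks within `match_tol` of template peak p, and 0 when none — absence
   of a peak is informative of transmission, not missing-at-random, so
   zeros are kept rather than masked.
3. **Correlation.** Pearson correlation of the row profiles across scans
   (the modulation is linear co-variation, so the linear correlation is the
   natural choice). Rows with zero variance, or with fewer than 3 nonzero
   scans (Pearson needs variance to be meaningful), are undefined and
   carried as NaN — never silently zero. At least 3 scans are required.
4. **Assignment.** Every non-anchor template peak goes to the precursor
   anchor with the highest correlation (hard assignment: a shared fragment
   is given to exactly one precursor). Undefined correlations are excluded
   from the argmax; a peak undefined against every anchor lands in a
   logged unassigned pool. Exact ties are broken deterministically towards
   the anchor whose m/z is nearest the fragment's intensity-weighted
   profile centroid expressed on the isolation-centre axis (for a symmetric
   transmission curve that centroid estimates the parent's m/z); ties are
   always logged.
5. **Substitution.** If a precursor ion is absent from the template (fully
   fragmented, or unresolved), its most intense library fragment present in
   the template anchors the correlation instead, flagged `is_substitute`.

The reconstructed spectra partition the template: every template peak
appears in exactly one reconstruction or in the unassigned pool.

## Evaluation

Reconstruction and reference are aligned greedily one-to-one by ascending
mass error within 3 mDa against the reference's theoretical (formula-
derived) m/z. Recalibration removes the median relative (ppm) offset of all
matched pairs from every reconstructed peak; similarity is computed on the
recalibrated spectrum (matching the processing order of the method), with
unrecalibrated scoring available. The similarity cosine aligns peaks at
0.2 mDa; unmatched peaks contribute zero to the other vector. "Correctly
assigned" inside precision and recall is operationalised as "matches a
reference peak within the 3 mDa alignment window" (the method states no
separate tolerance for the two metrics); recall weights by reference
intensities — the numerator notation is ambiguous, and reference weighting
makes recall exactly 1 when every reference peak is recovered regardless
of intensity distortion. NCE50 linearly interpolates the first downward
crossing of 0.5 in ascending-NCE order. Profile distances take the first
and last half-maximum crossings of each max-normalised profile, rounded to
the nearest scan (half-up, to avoid banker's-rounding ties); sub-scan
interpolation is available behind a flag.

Reference libraries are cleaned on load: peaks with intensity strictly
below 0.3% of the entry's base peak are discarded (a peak exactly at 0.3%
is retained). Reference NCE is stored per entry and compared at evaluation
time, since reconstructions must be scored against references recorded at
the same collision energy.

## Numerical and I/O choices

* mzML reading and writing use a purpose-built, namespace-tolerant
  serializer/parser for centroided MS2 mzML 1.1.0 (cvParam accessions,
  base64 float32/float64 arrays, optional zlib), verified by round-trip
  tests; profile spectra are rejected with an explicit error, as
  centroiding belongs upstream (msConvert). MGF goes through pyteomics,
  MSP through matchms. A TSV scan-table dialect (columns scan_index,
  isolation_center, isolation_width, nce, mz, intensity) serves desk-scale
  fixtures.
* MSP/MGF annotation fields carry per-peak theoretical m/z as
  `observed|annotation` pairs; the annotation is either a number or an ion
  formula (resolved via pyteomics mass calculation, minus one electron
  mass for positive ions).
* All tolerances are absolute Th. Correlation values are clipped to
  [−1, 1] against float drift; the defined diagonal is exactly 1.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
the study's own scale: 81-scan cycles, two precursors, 9–11 peaks per
template. The stochastic degradation check uses 20 seeds per Δm/z
condition at 10% multiplicative noise — enough for stable means at this
effect size (the observed gap between Δm/z 0.006 and 0.048 is ~0.4 in
mean assignment accuracy). The whole suite completes in about a minute on
one CPU.

## Known limitations

* Hard argmax assignment only; no regression/mixture unmixing, by design —
  the point of the correlation score is to probe how well precursors and
  fragments co-modulate, and shared fragments are knowingly given to a
  single precursor (visible as recall < 1 for the other isobar).
* Two or more precursors closer than the template merge tolerance
  (0.002 Th default) collapse into one template peak and cannot be
  separated downstream; the method's resolution floor is the template
  tolerance, not the step size.
* No deisotoping of the template: isotopologue ions that survive the
  window appear as ordinary template peaks.
* The printed event counts of non-default plans follow strictly from
  floor(range/step)+1; configurations quoted elsewhere with counts
  inconsistent with their own offsets and step are not special-cased.
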