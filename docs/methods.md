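# Methods

## Problem setting

Spectrum clustering groups MS/MS spectra that were most likely generated by
the same analyte (same peptidoform and charge). Downstream consumers — 
spectral library builders, cluster-level database searches — need one
spectrum per cluster. `speccons` implements four reduction methods and the
statistics that quantify how well the chosen representative reflects its
cluster.

## Consensus methods

All methods operate on centroided peak lists sorted by m/z. Parameters live
in `ConsensusParams`; defaults are listed in parentheses.

**AVERAGE.** Member peak lists are concatenated and sorted; a single greedy
left-to-right pass merges each peak into the current group while its m/z is
within `merge_tolerance` (0.02 Th) of the group's running intensity-weighted
mean, otherwise a new group starts. Each group emits one peak: m/z is the
intensity-weighted mean of the group (weights = peak intensities), intensity
is the arithmetic mean over the contributing peaks. A group consisting
entirely of zero-intensity peaks falls back to an unweighted m/z mean.
The merge window, the greedy running-mean grouping, and the
per-contributing-peak intensity denominator are deliberate choices exposed
as parameters; none of them is canonical in the literature.

**BIN.** Peaks are assigned to half-open bins [k·w, (k+1)·w), w =
`bin_width` (0.02 Th), anchored at m/z 0 so the grid is reproducible across
runs and files. A bin's *occupancy* is the number of distinct members
contributing at least one peak to it (a member with two peaks in one bin
counts once — the occupancy rule is a member count, not a peak count).
Bins with occupancy/n strictly below `min_fraction` (0.25) are discarded;
a bin at exactly 25 % survives. Surviving bins emit the unweighted mean
m/z and mean intensity of their peaks — in deliberate contrast to
AVERAGE's weighted m/z. The intensity denominator is switchable
(`bin_intensity_denominator`): `"peaks"` (default) divides by the number
of contributing peaks, `"members"` by the cluster size, which downweights
bins only a minority of members support.

**MOST.** Spectra are vectorized on the `similarity_bin_width` (0.02 Th)
grid, in-bin intensities summed, optionally square-root transformed
(`intensity_transform`, default `"none"`), and normalized to unit Euclidean
norm, so the pairwise dot product lies in [0, 1]. The representative is the
member maximizing the summed similarity to all *other* members
(self-similarity excluded). Ties are broken deterministically by smallest
spectrum id (`tie_break="first_id"`); a seeded random tie-break is available
because random selection is what a naive implementation does, but
determinism is the better default for reproducible libraries.

**BEST.** The member with the best PSM score, orientation given by
`score_direction` (`"higher"`, matching raw search-engine score
conventions; `"lower"` fits e-value-like scores). Clusters with no
identified member have no valid BEST representative: the single-cluster
operation raises, and the batch driver skips and counts them so that the
same cluster set can be compared across methods.

**Consensus precursor.** The combined spectrum of AVERAGE/BIN needs
precursor values the methods themselves do not define: we use the median
member precursor m/z and the modal charge (ties to the smaller charge),
emitting a warning when members disagree on charge. Unknown charges are
propagated, never imputed.

## Evaluation statistics

A *multispectral* cluster has ≥ 2 members and a majority peptidoform: one
peptidoform carried by strictly more than 50 % of the member PSMs. The
majority is computed over identified members only — unidentified members
neither support nor dilute it — because the filter rule is phrased in terms
of matches, not spectra. Peptidoform identity means sequence plus the full
modification-site list; a `sequence_only` switch relaxes this to the bare
sequence where site-level resolution is not wanted.

Each representative of a filtered cluster receives exactly one category:
`majority` (high-quality), `minority` (matches a member but not the
majority), `novel` (matches no member — possible for AVERAGE/BIN, whose
output is not any member spectrum), or `unidentified`. Ratios are reported
over clusters with an identified representative; `high_quality` = majority
and `low_quality` = minority + novel are also reported separately because
the two low-quality modes have different causes.

Score summaries are stratified by cluster size into bins
{1}, {2}, {3}, {4}, {5}, (5,10], (10,20], (20,∞): sizes up to five are
individually resolved, and the range labels are half-open above so size 5
falls in its own bin.

Two methods' identifications are compared over the identifiers present in
both tables: `corroborative` (peptidoforms fully equal), `divergent_site`
(equal sequences, different modification sites) and `divergent_peptide`
(different sequences) partition the intersection, and the counts are
symmetric under swapping the tables.

## The simulator

`SimConfig`/`make_dataset` emulate clusters of replicate spectra of a
shared template. A template has `n_template_peaks` (40) peaks uniform in
`mz_range` (100–1500 Th) with a minimum adjacent spacing of
`min_peak_spacing` (0.04 Th, two default bin widths, so distinct template
peaks never share a bin) and log-normal intensities
(`intensity_log_mean`=6, `intensity_log_sd`=1, i.e. median ≈ 400 arbitrary
units). A replicate keeps each template peak with probability 1 −
`dropout_p` (0.1), jitters kept m/z by N(0, `mz_jitter_sd`=0.005 Th),
multiplies intensities by LogNormal(0, `intensity_cv`=0.2), and adds
`n_noise_peaks` (5) uniformly placed peaks with intensities below the
template's 25th intensity percentile — low enough that the occupancy
filter, not any intensity threshold, is what must remove them.

A fraction `contamination_fraction` of clusters (the first
round(f·n_clusters), so counts are exact) have their last member replaced
by a replicate of an independently drawn template; the contaminant's PSM
carries its own template's peptide label, producing the mixed clusters the
quality statistics are about. Member PSM scores are
100 · (similarity to own template) + N(0, 2), giving BEST a meaningful but
noisy signal. All randomness flows from the mandatory seed; identical
configurations produce byte-identical output files.

What the simulator does *not* model: fragmentation chemistry (peptide
labels are opaque strings, not theoretical fragment sets), retention time,
charge-state errors, profile-mode peaks, or score distributions of real
search engines. Consequently a contaminant replicate scores as well as a
genuine member, so BEST picks the contaminant in roughly a quarter of the
contaminated clusters — real searches penalize minority analytes more.
Passing tests demonstrate the algebra and the selection logic, not
instrument-level performance.

## Numerical choices and degenerate inputs

- Bins are anchored at 0 with half-open intervals; bin indices are
  `floor(mz / w)` in double precision.
- The occupancy discard is strict (`< min_fraction`), so 1-of-4 members is
  kept and 1-of-5 discarded.
- MOST tie detection uses an absolute tolerance of 1e-12 on the summed
  similarities before tie-breaking.
- Spectra with all-zero intensities cannot be unit-normalized; the
  similarity raises rather than guessing.
- Singleton clusters reproduce their member's peak list exactly for every
  method, *provided* the member's peaks are farther apart than the bin
  width / merge tolerance; two peaks inside one 0.02 Th bin are merged
  even in a singleton, which is the method definition, not an accident.
  Simulated noise peaks are placed uniformly, so rare collisions with a
  template peak can produce exactly this case.
- MGF output writes m/z with 4 decimal places and intensity with 4
  significant digits; round trips are exact to those precisions.

## Known limitations

The fixed BIN grid aliases peaks near bin boundaries: with m/z jitter of
0.005 Th a peak whose true position is close to a bin edge is split by the
replicates across two bins, and when the minority side clears the 25 %
occupancy filter it enters the consensus at full mean intensity. The
resulting off-grid duplicate peaks slightly depress the untransformed
binned-cosine similarity of BIN consensus spectra to their template — in
the benchmark harness (6-member pure clusters at simulator defaults) the
consensus beats the median member in about 93–96 % of clusters depending
on the seed, rather than uniformly. Square-root intensity transformation,
larger clusters, or the `"members"` intensity denominator all mitigate the
artifact; grid-free merging (AVERAGE) avoids it entirely at the cost of a
data-dependent peak grid.
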