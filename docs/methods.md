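# Methods

`gmapkit` models the computational side of pooled shRNA barcode screen
deconvolution on a dual read-out platform: a high-density barcode
microarray (GMAP, the Gene Modulation Array Platform) and direct short-read
sequencing of half-hairpin barcode amplicons. Each shRNA's 21-nt sense stem
doubles as a DNA barcode; a screen's read-out is the per-barcode abundance
change between a sample and a reference pool, expressed as log2 ratios.

## Chip manifest

The array is described as an ordered catalogue of probe classes (shRNA
barcode features in triplicate, negative and mismatch controls, hairpin
spike-ins in 25 clusters of 200, yeast barcode/ORF features, human ORF
features). The manifest model keeps, per feature, only class membership,
replicate index, optional barcode linkage, sequence and GC count — physical
coordinates and mask design are out of scope. shRNA features are the 21-nt
stem extended to 22 nt by one extra stem base; the catalogue does not fix
which end carries it, so both choices are exposed and the default appends at
the 3′ end. GC-background probes are not part of the published class table;
they are carried as an extra class `GCBG` with a configurable count
(default 33,894). When no barcode library is given, manifests are built
without sequences so that full-scale (1.06M-feature) catalogues assemble in
seconds; supplying a seed materializes random control-class sequences so GC
metadata exists downstream.

## Spike-in design

Hairpin spike-in (HSPI) candidates are screened against the shRNA feature
universe by longest shared contiguous identity, computed at every alignment
offset:

* `< 13` shared bases with every feature: retained without thermodynamic
  evaluation;
* `> 19` shared bases with any feature: eliminated outright;
* otherwise each maximal shared segment of length ≥ 13 is evaluated with a
  nearest-neighbor melting-temperature model.

Tm uses the two-state NN model with the unified perfect-match dinucleotide
parameter set, `Tm = ΔH / (ΔS + R ln(C_T/x)) − 273.15`, with the
monovalent-salt entropy correction `ΔS + 0.368·N·ln[Na+]`. Defaults:
strand concentration 50 nM (conventional oligo assay condition) and
[Na+] = 0.89 M, the NaCl concentration of the array hybridization buffer.
The parameter table ships as a JSON data file so independent
re-implementations can load identical constants. A cross-segment's Tm is
the perfect-match Tm of the shared run alone — the flanking mismatched
bases are treated as non-contributing, which is the simplest model
consistent with screening on shared-identity instances. Candidates are
admissible when their own perfect-match Tm lies inside the feature-universe
Tm envelope and every cross-segment Tm falls below the envelope minimum;
the selection score is the margin of the envelope minimum above the worst
cross-segment Tm (floored at 0 °C when there are no cross segments) minus
the distance of the candidate's Tm from the envelope midpoint, with
lexicographic tie-break for determinism. Secondary-structure screening and
full mismatch thermodynamics are out of scope.

## Array pipeline

Processing order: GC-matched background subtraction on features, replicate
median per barcode, log2, then cyclic-loess normalization across arrays.

* **GC-background correction** subtracts, from every non-background
  feature, the median intensity of background probes with the same GC
  count; a missing GC bin falls back to the nearest available bin. Results
  are floored at 1.0 intensity unit so log2 signals stay ≥ 0 and finite
  while preserving rank.
* **Replicate summarization** is the median of the (typically three)
  replicate features per barcode — robust to a single bright outlier.
* **Cyclic loess** iterates over array pairs, fits a local-linear
  (lowess, span 0.4, at most 3 cycles, tolerance 1e-3) trend to the MA
  plot and removes half of it from each array, conserving the pairwise
  total log2 signal. The method assumes most barcodes are unchanged at
  every intensity, which holds for replicate hybridizations of one sample
  but *not* for sample-vs-reference pairs containing diluted subpools (a
  diluted subpool occupies its own intensity stratum and would be
  normalized away). The pipeline therefore applies loess only within
  replicate groups and takes between-condition ratios afterwards.
* **Detection threshold** is mean + z·SD (sample SD, z = 1.96 by default,
  the 95% confidence limit) of the log2 background signal; signals at or
  above it are retained.
* **Ratios** are per-barcode log2 differences (sample − reference) with
  subpool labels attached; missing barcodes are dropped and logged.
  Optional centering subtracts the median of all ratios or of a designated
  (undiluted) subpool; see below.
* **Subpool summaries** report count, median, IQR and a mode estimated as
  the argmax of a Gaussian KDE on a fixed 0.01-log2-unit grid; subpools
  with fewer than 10 members get a flagged, median-only summary.
* **Cross-hybridization rate** is the fraction of off-pool barcode
  features (minus a configurable exclusion set of sequences shared with
  the hybridized pool) at or above the detection threshold, reported
  half-even-rounded to two decimals.

## Sequencing pipeline

The matcher re-expresses the original alignment-based rule (MAQ mapping
quality ≥ 50 against a synthetic chromosome) as its stated effective
criterion: at most one mismatch over the 21-nt stem, with reads mismatching
at the first nucleotide removed. The 22nd read base is ignored for
matching. Implementation is an exact-dictionary lookup followed, on miss,
by enumeration of the 60 one-substitution neighbors at positions 2–21; a
unit test proves equivalence with a literal all-pairs Hamming scan. Reads
equidistant from two distinct barcode sequences are discarded as unmapped
(avoiding false assignment); reads matching a sequence duplicated under
several barcode IDs count once for each ID. Reverse-complement matching is
off by default (reads are primed from a fixed strand) but exposed.

Run summaries conserve `mapped + unmapped = reads passed filter`; the
unmapped percentage is half-even-rounded to two decimals. Quartiles and
the mean are computed over barcodes with at least one assigned read
(quartiles by linear interpolation); `uncounted` is the number of expected
barcodes with zero reads. Counts are log2-transformed with a configurable
pseudocount, after dropping barcodes below a minimum read count (default
16). Detection accounting divides detected distinct sequences by the
distinct-sequence denominator: total IDs minus the number of sequences
duplicated across IDs.

The synthetic chromosome builder interleaves barcode stems with 79-nt
random spacers (`spacer + Σ(barcode + spacer)`), recording each barcode's
offset; it is deterministic per seed.

## Simulator

The simulator regenerates the dilution-pool study designs: an even pool;
separate pools with one ~10.6% subset diluted 4-, 16- or 64-fold; a mixed
pool with four subsets (~10.7% each) diluted 2/5/10/20-fold; and a 90k-style
reference/dilution pair with four ~3.9% subsets. One design's dilution
factors are printed inconsistently across the source material (2/4/10/20 in
one place, 2/5/10/20 in the analyzed figure); the default follows the
analyzed figure and factors are fully configurable. Desk-scale defaults are
a 5,000-barcode library with subset sizes scaled proportionally from the
published pool layouts (8,300/78,432 etc.) and 2×10⁶ reads per run — sizes
chosen so every stage of the toolkit is exercised end to end on a laptop;
full 78k/90k dimensions are plain parameters.

* **Array signal** follows a saturating response `I = B + A·c/(c+K)` with
  per-feature lognormal noise (log2-scale SD σ, default 0.25). The
  saturating form is the simplest mechanism that reproduces the platform's
  observed behavior: diluted subpools appear *compressed* (|log2 drop| <
  log2 d) while remaining resolvable and ordered. Defaults A = 30,000,
  K = 1 (so the undiluted concentration sits at half-saturation, the
  compressive regime), B = 120.
* **Sequencing reads** are multinomial over barcodes proportional to
  abundance, each read the 21-mer stem plus one layout base, with
  substitution-only errors (default 0.1%/base; half-hairpin amplicons are
  fixed-length, so indels are not modeled), constant quality lines, and a
  truth count table. Read counts always sum to the requested total.
* **Infection bottleneck**: total integrations are Poisson at
  `n_cells × MOI` (default MOI 0.35, mid-range of the screening protocol)
  and allocated multinomially by concentration.

What the simulator does *not* emulate: PCR amplification bias, cruciform
formation, flow-cell cluster effects, spatial array artifacts, selection
dynamics, and sequence-dependent hybridization efficiency. Passing tests
therefore demonstrate the pipelines' statistical correctness under the
generative model, not robustness to those real-data artifacts.

### Ratio centering

With fixed sequencing depth, raw count ratios against an even run carry a
constant offset `log2(mass_even / mass_dilution)` because dilution reduces
the pool's total concentration mass and the sequencer renormalizes. At
desk scale this offset is ≈ 0.59 log2 units for the mixed 2–20x design.
The published presentation centers the undiluted (1x) population at zero,
so the pipeline's dilution analyses center ratios on the undiluted
subpool's median (`center="1x"`); with that centering the subpool medians
recover −log2(d) within ±0.15 at 2×10⁶ reads. Whole-set median centering
is also available but is biased by a few hundredths of a log2 unit when
diluted subpools make up a large minority of the library.

## Numerical choices

* Percent reporting uses numpy's half-even rounding; trailing zeros drop
  naturally (0.4983 → 0.5, 0.2840 → 0.28).
* Sample (n−1) standard deviation in the background threshold.
* KDE bandwidth defaults to Scott's rule; degenerate (zero-variance)
  subpools short-circuit to the constant value.
* All simulators take explicit integer seeds and are bit-reproducible;
  end-to-end runs re-derive stage seeds from the config seed, so identical
  configs give byte-identical output files (outputs embed tool version,
  run id, seed and a config hash, never timestamps).
* Spearman correlation uses average ranks, which matters for count data
  with ties near the detection floor.

## Known limitations

* The cross-hybridization exclusion set (features identical between two
  species' pools) cannot be derived without the original library tables;
  it is a caller-supplied set.
* The per-run "mean reads per barcode" statistic is defined here as the
  mean over barcodes with ≥ 1 read; other averaging populations give
  slightly different values.
* Loess normalization of arrays whose majority of barcodes genuinely
  changed would remove signal; the pipeline leaves cross-condition
  normalization to the ratio-centering step by design.
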