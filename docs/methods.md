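# Methods

## Scope and model

`coithresh` implements the distance–threshold approach to species
delimitation on COI barcodes. Its working assumption is the *barcoding gap*:
within a genus, conspecific sequences are separated by smaller genetic
distances than heterospecific ones, so a single distance threshold can
recover the species partition. The package quantifies when that assumption
holds (distance summaries, error scans, density dips) and what happens when
it does not (SPLIT/MERGE/MIXTURE outcomes, overestimation ratios).

## Distances

The K2P distance d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) is computed per pair
under **pairwise deletion**: any site where either sequence carries a
non-ACGT symbol (gap, N, IUPAC ambiguity) is excluded from that pair only.
Ambiguity codes are never counted as matches or mismatches; the original
toolchain's behaviour on them is not documented, and pairwise deletion is
the least-assumption choice. Transitions are A↔G and C↔T; everything else
among ACGT is a transversion.

A pair's distance is **undefined** when zero sites are comparable or when a
logarithm argument is ≤ 0 (saturation). Undefined is a first-class state —
`None` for scalars, NaN behind an explicit mask in `DistanceMatrix` — so the
"species with an NA distance" filter is an explicit, testable rule rather
than NaN propagation. The implementation was cross-checked against an
independent reference distance routine on random pairs (agreement to 1e-16;
identical undefined cells) and is tested against the closed form at 1e-12.

Distances are kept at full float precision; rounding happens only in report
files.

## Filter cascade

Stage order at species level: identification to species level →
open-nomenclature keywords → marker code → minimum 3 sequences per species →
100-sequence subsample cap → gap-bearing sequence removal → minimum-count
re-check → stop-codon screen → undefined-distance screen → 95th-percentile
screen on maximum intraspecific distance. Notes on the individually
debatable points, each exposed as configuration:

* **Keyword matching is token-based** (whitespace/period-delimited,
  lowercased), so "Cfa albipes" survives while "Apis cf. mellifera" does
  not; substring matching would silently delete legitimate names.
* **"Leads to insertions or deletions"** is operationalised as "contains a
  gap character in the alignment"; gap-only columns are excised first.
  Realignment after removal is out of scope — synthetic inputs are generated
  pre-aligned, and external inputs are assumed aligned.
* The **minimum-count rule is re-applied after gap removal** because that
  removal can shrink a species below three sequences; without the re-check
  the cascade's postcondition (≥3 usable sequences per surviving species)
  would not hold.
* **Stop-codon screen**: for each of the three forward frames, stop codons
  under the invertebrate mitochondrial code (table 5; TGA encodes Trp) are
  summed over all sequences of the species, the final incomplete codon
  ignored; the frame with the minimal total is taken as the species' reading
  frame and the species is dropped iff that minimum is positive. This avoids
  assuming the alignment starts in-frame.
* **Quantile screen**: the cutoff is the type-7 (linear-interpolation)
  quantile — the default of the statistical environment this analysis style
  comes from — computed over all species' maxima; species strictly above it
  are dropped, species exactly at it retained. The estimator is
  configurable because results are sensitive to it at small n. The rule is
  deliberately *not* idempotent (recomputing the quantile on survivors would
  keep trimming), which is why it sits last.
* **Subsampling** above the 100-record cap draws without replacement from
  the species' sorted record ids with a per-species stream derived from
  (global seed, species name), so the selection is independent of dataset
  ordering.

Genus-level preparation removes **both** members of every congeneric species
pair at interspecific distance zero (the literal reading of the source
rule; removing one of the two would require an arbitrary choice of victim),
then genera with fewer than three species, then families with a single
genus.

## Clustering

Single linkage: records are linked when their distance is strictly below
the threshold, MOTUs are the connected components. Strict `<` (rather than
`≤`) is the decisive boundary choice: the mininter threshold is defined as
the minimum congeneric interspecific distance minus 1e-8 precisely so that
the pair attaining the minimum stays separate, and that correction is only
meaningful under strict comparison. The comparison operator is exposed as a
switch, and the test suite demonstrates that `≤` without the correction
violates purity. MOTU ids are consecutive integers ordered by each MOTU's
lexicographically smallest member, making partitions reproducible.

## Threshold selection

* **localMinima**: Gaussian KDE with the rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated at 512 points spanning
  [min − 3·bw, max + 3·bw]; interior grid points strictly lower than both
  neighbours are local minima and the first is the threshold. These are the
  defaults of the density routine this analysis style traditionally uses,
  and the implementation reproduces that routine's output to full precision
  on a frozen reference sample (tests/data/density_sample.tsv). A genus with
  a unimodal density is reported NOT-EVALUABLE for this method rather than
  silently falling back to a fixed threshold.
* **opt**: every grid threshold (default 0.001–0.2 step 0.001; thresholds
  generated by index, not accumulation, to avoid float drift) is scored by
  cumulative identification error; the optimum is the arithmetic mean of
  *all* tied minimisers. Per record at threshold t, with M the set of other
  records at distance < t: empty M is a true negative if the record's
  species is a singleton, else a false negative; non-empty M is a true
  positive if all neighbours are conspecific, else a false positive. The
  four categories are exhaustive and mutually exclusive (they sum to n at
  every threshold). This taxonomy is a reconstruction — the original
  optimiser's exact definitions are not restated in the literature this
  follows — and is the implemented contract, validated against an
  independently coded per-record oracle.
* **mininter**: minimum congeneric interspecific distance − 1e-8; inputs at
  or below the correction are an error.

## Synthetic data generator

Per genus, a random in-frame coding ancestor (no internal stops under table
5) is evolved along a star phylogeny — genus root → species ancestors →
individuals — by the jump chain of the K2P process: the number of mutation
events on a branch of expected divergence d over L sites is Poisson(d·L),
each event is a transition with probability κ/(κ+2) (default κ = 4, typical
of insect mitochondrial coding sequence), and events creating an internal
stop codon are rejected and redrawn. Branch lengths place the expected
conspecific pairwise divergence at the intraspecific target (default 0.005)
and the expected congeneric heterospecific divergence at the interspecific
target (default 0.06): individuals sit intra/2 from their species ancestor
and species ancestors (inter − intra)/2 from the genus root. Because the
generator's event count is the K2P expectation, targets are on the same
scale as measured K2P distances; calibration is verified in the tests
(realized mean intraspecific distance within three Monte-Carlo standard
errors of the target).

Default study conditions are ten genera of four species with eight
sequences of length 600. Defect injection adds, at configurable rates, the
five defect classes the filters exist for — gap-bearing sequences, forced
internal stop codons, "cf." renames, truncation below three records, and
congeneric pairs with identical sequences — with a manifest naming the
filter stage expected to remove each item, at the granularity that stage
drops (record ids or species names). Gap injection is capped so a species
never falls below three gapless records, keeping defect accounting exact.

What the generator does **not** emulate: rate variation among sites and
lineages, indel evolution (gaps exist only as injected defects), coalescent
genealogies within species, codon-usage or selection effects, mislabelled
or chimeric sequences, and geographic population structure. Passing tests
therefore show the machinery is correct and calibrated under the stated
model — not that real Insecta data have clean barcoding gaps; on real data
the interesting output is exactly the per-genus disagreement between
methods.

## Pipeline and determinism

`run_all` chains simulation (optional) → cascade → species-level summaries
(per-species maxima, per-order histograms at class interval 0.01,
proportions above 1/2/3%, fixed-threshold cluster counts and
multi-cluster-species counts) → genus preparation → the method comparison
(fixed thresholds plus the three flexible methods, per-genus evaluations,
unweighted per-method means over evaluable genera) → the cutoff-subset
cluster-count table. In that table, per-species congeneric minima are
computed once on the full genus before subsetting; a cutoff that leaves a
genus with fewer than two species drops the genus from that row entirely so
the species count and every MOTU column cover the same record set, and the
mininter threshold is recomputed on the retained submatrix.

All outputs are TSV with a fixed float format; the JSON manifest records
the full configuration, per-stage counts and SHA-256 digests of every file.
One seed drives simulation, defect injection and subsampling, so identical
configuration and seed give byte-identical runs (tested). Distance matrices
are recomputed rather than cached on disk: at the problem sizes the package
targets (hundreds of records per group) they cost milliseconds, and a
content-addressed cache would only add state to keep consistent. Order
pooling of small orders into an "Others" group is available
(`min_species_per_order`) and off by default, since at simulation scale it
would pool everything.

The bundled runs and the acceptance script use the default study conditions
(ten genera, 320 records); these sizes keep every property crisp —
realized gaps, exact manifest accounting — while the implementation itself
is vectorised and handles the 100-record-per-species cap the subsampler
exists for.

## Known limitations

* Alignment is out of scope; inputs must be pre-aligned per group
  (equal-length sequences), and the gap filter assumes that.
* Only K2P and p-distances are offered; no ML distances or rate-variation
  models.
* The identification-error taxonomy is a reconstruction (see above); other
  reasonable definitions would shift `opt` thresholds slightly.
* Average match ratios are unweighted means over genera; genera with many
  species count the same as genera with three.
* The mininter method requires at least two species per genus and a
  non-zero minimum — guaranteed after genus preparation, but not for
  arbitrary user-supplied partitions of the data.
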