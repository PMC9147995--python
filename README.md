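# coithresh

Threshold-based species delimitation on COI barcode data: quality filtering
of BOLD-style specimen tables, Kimura two-parameter (K2P) genetic distances,
single-linkage clustering into molecular operational taxonomic units (MOTUs),
flexible clustering-threshold selection, and congruence scoring of MOTUs
against morphological taxonomy — plus a calibrated synthetic barcode-data
generator so every stage can be exercised and validated without touching any
external database.

The package is aimed at researchers who delimit or identify species from
COI-5P barcodes and want the whole distance-threshold workflow — the same
analysis usually stitched together from `ape`, `spider` and ad hoc scripts —
as one tested, deterministic Python library.

## The analysis

**Distances.** For two aligned sequences, sites where either member carries
anything other than A/C/G/T are excluded (pairwise deletion). With *P* the
transition proportion and *Q* the transversion proportion over the compared
sites, the K2P distance is

> d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

A distance is **undefined** (a first-class state, not a sentinel) when no
site is comparable or a logarithm argument is non-positive; the quality
filters act on exactly this state. The uncorrected p-distance is available
as an alternative model.

**Filtering.** The species-level cascade drops records not identified to
species level; open-nomenclature names ("aff", "cf", "nr", "spp" as name
tokens); wrong marker codes; species with <3 records; surplus records beyond
a 100-sequence cap (seeded subsampling); gap-bearing sequences; species with
internal stop codons in their best reading frame (invertebrate mitochondrial
code, where TGA = Trp); species with any undefined distance; and species
whose maximum intraspecific distance exceeds the 95th percentile across
species. Genus-level preparation then removes zero-distance congeneric
species pairs, genera with <3 species, and single-genus families. Every
stage reports its removals.

**Clustering.** Records share a MOTU iff connected through pairwise
distances strictly below the threshold (single linkage / connected
components). Fixed thresholds default to 1%, 2%, 2.2% and 3%.

**Flexible thresholds**, derived per genus:

* `localMinima` — first interior dip of a Gaussian kernel density estimate
  over all pairwise distances (the barcoding gap); not applicable when the
  density is unimodal;
* `opt` — grid search (0.001–0.2, step 0.001) minimising cumulative
  identification error (false positives + false negatives), mean of tied
  optima;
* `mininter` — the minimum congeneric interspecific distance minus 1e-8, so
  strict-< clustering keeps the closest heterospecific pair apart.

**Evaluation.** MOTUs are scored against taxonomy by the match ratio
2·N<sub>match</sub>/(N<sub>delimited</sub> + N<sub>morph</sub>) and per
species as MATCH / SPLIT / MERGE / MIXTURE; summary tables cover histograms
of maximum intraspecific distances (class interval 0.01), proportions above
cutoffs, overestimation ratios and cluster counts over
minimum-interspecific-distance subsets.

## Worked example

`python examples/threshold_methods.py` simulates one genus (5 species × 10
sequences, expected intraspecific divergence 0.005, interspecific 0.06) and
compares the three flexible thresholds:

```
genus with 5 species, 50 sequences
realized max intraspecific K2P: 0.0118
realized min interspecific K2P: 0.0466

localMinima  t=0.028969  MOTUs=5  match_ratio=1.0000  outcomes=['MATCH']
opt          t=0.026500  MOTUs=5  match_ratio=1.0000  outcomes=['MATCH']
mininter     t=0.046556  MOTUs=5  match_ratio=1.0000  outcomes=['MATCH']
```

All three thresholds land inside the realized barcoding gap
(0.0118, 0.0466), so clustering recovers the five true species exactly: five
MOTUs, every species a MATCH, match ratio 1. The other examples cover the
distance matrix and its undefined state (`k2p_distances.py`), the filter
cascade against an injection manifest (`filter_cascade.py`) and a full run
with all reports (`full_pipeline.py`).

A thin CLI wraps the same functions:

```bash
coithresh simulate --out-dir sim/ --seed 1
coithresh filter --in sim/simulated.tsv --out filtered.tsv --report report.tsv
coithresh convert --in filtered.tsv --out-dir fasta/ --group-by species
coithresh run --config run.yaml
```

## Layout

```
src/coithresh/      bold_io, filtering, distances, clustering, thresholds,
                    evaluation, simulate, pipeline, cli
examples/           one short narrative script per capability
tests/              unit, property and end-to-end suites (pytest)
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
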