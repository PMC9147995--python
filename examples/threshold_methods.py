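"""Comparing threshold-selection methods on one simulated genus.

Generates a genus with a clear barcoding gap, derives a clustering threshold
three ways — the first dip of the distance-density estimate (localMinima),
the error-minimising grid search (opt), and the minimum congeneric
interspecific distance minus 1e-8 (mininter) — then clusters at each and
scores the MOTUs against the true species with the match ratio.
"""

from coithresh import (
    SimulationConfig,
    distance_matrix,
    evaluate_genus,
    generate_dataset,
    local_minima_thresholds,
    min_interspecific_congeneric,
    mininter_threshold,
    select_local_minima,
    thresh_opt,
    threshold_cluster,
)

config = SimulationConfig(
    n_genera=1, species_per_genus=5, sequences_per_species=10,
    intra_divergence=0.005, inter_divergence=0.06, seed=8,
)
dataset, truth = generate_dataset(config)
records = dataset.records
matrix = distance_matrix([(r.record_id, r.sequence) for r in records])
species_of = {r.record_id: r.species_name for r in records}

row = truth.genera.iloc[0]
print(f"genus with {row['n_species']} species, {len(records)} sequences")
print(f"realized max intraspecific K2P: {row['max_intra']:.4f}")
print(f"realized min interspecific K2P: {row['min_inter']:.4f}\n")

dip = select_local_minima(local_minima_thresholds(matrix.off_diagonal()))
opt, scan = thresh_opt(matrix, species_of)
min_inter, _ = min_interspecific_congeneric(matrix, species_of)

for method, threshold in (
    ("localMinima", dip),
    ("opt", opt),
    ("mininter", mininter_threshold(min_inter)),
):
    partition = threshold_cluster(matrix, threshold)
    ev = evaluate_genus(row["genus"], method, threshold, partition, species_of)
    print(
        f"{method:<12} t={threshold:.6f}  MOTUs={ev.n_delimited}  "
        f"match_ratio={ev.match_ratio:.4f}  outcomes="
        f"{sorted(set(ev.species_outcomes.values()))}"
    )

print("\nAll three thresholds fall inside the barcoding gap, so each method")
print("recovers the true species exactly (match ratio 1, all MATCH). The")
print("optimiser's zero-error run spans the gap; its mean sits mid-gap.")
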