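"""The quality-filter cascade on defect-injected synthetic data.

Generates a BOLD-like dataset, injects one defect class per filter rule
(gap-bearing sequences, internal stop codons, "cf." names, under-sampled
species, zero-distance congeneric pairs), runs the species-level cascade and
prints the per-stage accounting next to the injection manifest.
"""

from coithresh import (
    FilterConfig,
    SimulationConfig,
    generate_dataset,
    inject_defects,
    prepare_genus_level,
    run_filter_cascade,
)

config = SimulationConfig(
    n_genera=9,
    species_per_genus=4,
    sequences_per_species=6,
    p_gap_record=0.05,
    p_stop_species=0.05,
    p_ambiguous_name_species=0.05,
    p_undersampled_species=0.05,
    p_zero_pair_genus=0.15,
    seed=42,
)
dataset, _truth = generate_dataset(config)
dataset, manifest = inject_defects(dataset, config)
print(f"simulated {len(dataset)} records; injected defects by stage:")
print(manifest.groupby(["expected_stage", "defect"]).size().to_string(), "\n")

filtered, report = run_filter_cascade(dataset, FilterConfig())
print(report.to_frame()[["stage", "records_in", "records_out", "n_dropped"]]
      .to_string(index=False))

prepared, prep_report = prepare_genus_level(filtered)
print("\ngenus-level preparation:")
print(prep_report.to_frame()[["stage", "records_in", "records_out", "n_dropped"]]
      .to_string(index=False))
print("\nEach injected defect is removed at exactly the stage built for it;")
print("the quantile stage additionally trims the species with the largest")
print("maximum intraspecific distances (a data-driven rule, not a defect).")
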