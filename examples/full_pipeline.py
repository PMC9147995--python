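"""One full pipeline run: simulate → filter → species level → genus level.

Writes all reports to ./coithresh_example_run/ and prints the genus-level
method comparison: per method, the average match ratio across genera and
the totals of the four species-outcome categories.
"""

import pandas as pd

from coithresh import RunConfig, SimulationConfig, run_all

config = RunConfig(
    simulation=SimulationConfig(
        p_gap_record=0.05,
        p_ambiguous_name_species=0.05,
        p_zero_pair_genus=0.2,
    ),
    out_dir="coithresh_example_run",
    seed=1,
)
manifest = run_all(config)
print(f"wrote {len(manifest['outputs'])} reports to {config.out_dir}\n")

methods = pd.read_csv(f"{config.out_dir}/genus_methods.tsv", sep="\t")
print(methods[["method", "n_evaluable", "mean_match_ratio",
               "MATCH", "SPLIT", "MERGE", "MIXTURE"]].to_string(index=False))
print("\nFlexible thresholds (localMinima, mininter, opt) score a perfect")
print("match ratio on this clean-gap simulation; the 1% fixed threshold")
print("sits below some realized intraspecific variation and SPLITs species.")
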