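"""End-to-end orchestration of the species- and genus-level analyses.

``run_all`` chains: (optional) simulation with defect injection → quality
filter cascade → species-level summaries (maximum intraspecific distances,
histograms, fixed-threshold clustering) → genus-level preparation and the
method comparison (fixed thresholds vs local-minima, error-minimising and
minimum-interspecific thresholds, scored by match ratio and species-outcome
categories) → the cutoff-subset cluster-count report.  All outputs are TSV;
a JSON manifest records the configuration, per-stage counts and a SHA-256
digest of every written file, so identical configuration and seed give
byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bold_io import SequenceDataset, read_bold_tsv, write_bold_tsv
from .clustering import cluster_count, multi_cluster_species, threshold_cluster
from .distances import distance_matrix, max_intraspecific, min_interspecific_congeneric
from .errors import ConfigurationError, DataError
from .evaluation import (
    CATEGORIES,
    GenusData,
    evaluate_genus,
    frequency_distribution,
    mininter_subset_report,
    proportion_above,
)
from .filtering import FilterConfig, prepare_genus_level, run_filter_cascade
from .simulate import SimulationConfig, generate_dataset, inject_defects
from .thresholds import (
    ThresholdGrid,
    local_minima_thresholds,
    mininter_threshold,
    select_local_minima,
    thresh_opt,
)

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one full analysis run."""

    input_tsv: str | None = None
    simulation: SimulationConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    model: str = "K2P"
    fixed_thresholds: tuple[float, ...] = (0.01, 0.02, 0.022, 0.03)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    cutoffs: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.11, 0.01), 2))
    proportion_cutoffs: tuple[float, ...] = (0.01, 0.02, 0.03)
    min_species_per_order: int = 0
    out_dir: str = "coithresh_run"
    seed: int = 0
    comparison: str = "lt"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.fixed_thresholds):
            raise ConfigurationError("fixed thresholds must be positive")
        if self.input_tsv is None and self.simulation is None:
            raise ConfigurationError("either input_tsv or simulation must be set")


def _write(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return path


def _species_matrices(dataset: SequenceDataset, model: str) -> dict:
    return {
        sp: distance_matrix([(r.record_id, r.sequence) for r in recs], model)
        for sp, recs in dataset.by_species().items()
    }


def run_species_level(
    dataset: SequenceDataset, config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Species-level summaries of a filtered dataset.

    Returns tables: ``species`` (per-species maximum intraspecific distance),
    ``order_histograms`` (class interval 0.01 per order), ``proportions``
    (fraction of species above each cutoff, overall and per order) and
    ``species_clustering`` (per fixed threshold: total clusters over
    per-species clusterings and the number of species split into ≥2 MOTUs).
    """
    if not dataset.records:
        raise DataError("empty dataset after filtering; nothing to analyse")
    matrices = _species_matrices(dataset, config.model)
    rows = []
    for sp, recs in dataset.by_species().items():
        rows.append(
            {
                "species": sp,
                "genus": recs[0].genus_name,
                "order": recs[0].order_name,
                "n_records": len(recs),
                "max_intra": max_intraspecific(matrices[sp]),
            }
        )
    species_table = pd.DataFrame(rows).sort_values("species", ignore_index=True)

    counts = species_table.groupby("order")["species"].count()
    pooled = species_table["order"].where(
        species_table["order"].map(counts) >= config.min_species_per_order, "Others"
    )
    species_table = species_table.assign(order_group=pooled)

    hist_frames = []
    for order, group in species_table.groupby("order_group"):
        hist = frequency_distribution(group["max_intra"].to_numpy())
        hist.insert(0, "order", order)
        hist_frames.append(hist)
    order_hist = pd.concat(hist_frames, ignore_index=True)

    prop_rows = []
    for cutoff in config.proportion_cutoffs:
        prop_rows.append(
            {
                "order": "ALL",
                "cutoff": cutoff,
                "proportion_above": proportion_above(
                    species_table["max_intra"].to_numpy(), cutoff
                ),
            }
        )
        for order, group in species_table.groupby("order_group"):
            prop_rows.append(
                {
                    "order": order,
                    "cutoff": cutoff,
                    "proportion_above": proportion_above(
                        group["max_intra"].to_numpy(), cutoff
                    ),
                }
            )
    proportions = pd.DataFrame(prop_rows)

    clust_rows = []
    for t in config.fixed_thresholds:
        partitions = {
            sp: threshold_cluster(matrices[sp], t, config.comparison)
            for sp in species_table["species"]
        }
        clust_rows.append(
            {
                "threshold": t,
                "n_species": len(partitions),
                "total_clusters": sum(cluster_count(p) for p in partitions.values()),
                "multi_cluster_species": multi_cluster_species(partitions),
            }
        )
    clustering = pd.DataFrame(clust_rows)

    return {
        "species": species_table,
        "order_histograms": order_hist,
        "proportions": proportions,
        "species_clustering": clustering,
    }


def _genus_bundles(dataset: SequenceDataset, model: str) -> list[GenusData]:
    bundles = []
    for genus, recs in sorted(dataset.by_genus().items()):
        matrix = distance_matrix([(r.record_id, r.sequence) for r in recs], model)
        species_of = {r.record_id: r.species_name for r in recs}
        bundles.append(GenusData(genus, matrix, species_of))
    return bundles


def run_genus_level(
    dataset: SequenceDataset, config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Genus-level method comparison on a dataset that passed the cascade.

    Returns tables: ``genus_prep_report`` (the preparation filters),
    ``genus_distances`` (per genus: maximum intraspecific and minimum
    interspecific distance), ``per_genus`` (one row per genus × method with
    threshold, match ratio and category counts; a genus where the
    local-minima method finds no dip is marked not evaluable), ``methods``
    (per-method averages and category totals) and ``subset_report`` (the
    cutoff-subset cluster counts).
    """
    prepared, prep_report = prepare_genus_level(dataset, config.filter, config.model)
    if not prepared.records:
        raise DataError("no genera left after genus-level preparation")
    bundles = _genus_bundles(prepared, config.model)

    genus_rows = []
    per_genus_rows = []
    for g in bundles:
        min_inter, _ = min_interspecific_congeneric(g.matrix, g.species_of)
        intra_max = 0.0
        for sp in sorted(set(g.species_of.values())):
            labels = [lab for lab in g.matrix.labels if g.species_of[lab] == sp]
            if len(labels) >= 2:
                intra_max = max(intra_max, max_intraspecific(g.matrix.submatrix(labels)))
        genus_rows.append(
            {"genus": g.genus, "n_species": len(set(g.species_of.values())),
             "n_records": g.matrix.n, "max_intra": intra_max, "min_inter": min_inter}
        )

        methods: list[tuple[str, float | None]] = [
            (f"fixed_{t:g}", t) for t in config.fixed_thresholds
        ]
        candidates = local_minima_thresholds(g.matrix.off_diagonal())
        methods.append(("localMinima", select_local_minima(candidates)))
        methods.append(("mininter", mininter_threshold(min_inter)))
        opt, _scan = thresh_opt(g.matrix, g.species_of, config.grid, config.comparison)
        methods.append(("opt", opt))

        for method, threshold in methods:
            if threshold is None:
                per_genus_rows.append(
                    {"genus": g.genus, "method": method, "threshold": np.nan,
                     "evaluable": False, "n_morph": len(set(g.species_of.values())),
                     "n_delimited": np.nan, "n_match": np.nan, "match_ratio": np.nan,
                     **dict.fromkeys(CATEGORIES, np.nan)}
                )
                continue
            partition = threshold_cluster(g.matrix, threshold, config.comparison)
            ev = evaluate_genus(g.genus, method, threshold, partition, g.species_of)
            per_genus_rows.append(
                {"genus": g.genus, "method": method, "threshold": threshold,
                 "evaluable": True, "n_morph": ev.n_morph,
                 "n_delimited": ev.n_delimited, "n_match": ev.n_match,
                 "match_ratio": ev.match_ratio, **ev.category_counts}
            )

    per_genus = pd.DataFrame(per_genus_rows)
    method_rows = []
    for method, group in per_genus.groupby("method", sort=False):
        evaluable = group[group["evaluable"]]
        method_rows.append(
            {
                "method": method,
                "n_genera": len(group),
                "n_evaluable": len(evaluable),
                "mean_match_ratio": float(evaluable["match_ratio"].mean()),
                "total_species": int(evaluable["n_morph"].sum()),
                "total_clusters": int(evaluable["n_delimited"].sum()),
                **{c: int(evaluable[c].sum()) for c in CATEGORIES},
            }
        )
    methods_table = pd.DataFrame(method_rows)

    subset = mininter_subset_report(
        bundles, config.cutoffs, config.fixed_thresholds, config.comparison
    )
    return {
        "genus_prep_report": prep_report.to_frame(),
        "genus_distances": pd.DataFrame(genus_rows),
        "per_genus": per_genus,
        "methods": methods_table,
        "subset_report": subset,
    }


def _config_dict(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    return encode(config)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write all reports under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``): the full
    configuration, per-stage record counts, and a SHA-256 digest of every
    output file.  Identical configuration and seed yield byte-identical
    outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        dataset, truth = generate_dataset(sim)
        dataset, manifest_df = inject_defects(dataset, sim)
        outputs["simulated.tsv"] = write_bold_tsv(dataset, out_dir / "simulated.tsv")
        outputs["ground_truth.tsv"] = out_dir / "ground_truth.tsv"
        _write(truth.records, outputs["ground_truth.tsv"])
        outputs["defect_manifest.tsv"] = _write(
            manifest_df, out_dir / "defect_manifest.tsv"
        )
    else:
        dataset = read_bold_tsv(config.input_tsv)

    filter_config = dataclasses.replace(config.filter, subsample_seed=config.seed)
    filtered, report = run_filter_cascade(dataset, filter_config, config.model)
    outputs["filter_report.tsv"] = _write(
        report.to_frame(), out_dir / "filter_report.tsv"
    )
    outputs["filtered.tsv"] = write_bold_tsv(filtered, out_dir / "filtered.tsv")

    species_tables = run_species_level(filtered, config)
    for name, frame in species_tables.items():
        outputs[f"species_{name}.tsv"] = _write(frame, out_dir / f"species_{name}.tsv")

    genus_tables = run_genus_level(filtered, config)
    for name, frame in genus_tables.items():
        outputs[f"genus_{name}.tsv"] = _write(frame, out_dir / f"genus_{name}.tsv")

    digests = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(outputs.items())
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stage_counts": {
            s.name: {"records_in": s.records_in, "records_out": s.records_out}
            for s in report.stages
        },
        "outputs": digests,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
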