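"""Synthetic BOLD-like barcode datasets with controlled divergence.

The generator emulates the statistical structure a threshold-based
delimitation study assumes: genera containing several species, each species
with several aligned, equal-length, gapless COI-5P-like coding sequences;
conspecific sequences are similar, congeneric heterospecific sequences are
more divergent.  Per genus a random in-frame ancestral coding sequence
(no internal stop codons under the chosen genetic code) is evolved along a
star phylogeny: genus root → species ancestors → individuals, under a
two-rate substitution process in which a mutation event is a transition with
probability κ/(κ+2) and each transversion with probability 1/(κ+2) — the
jump chain of the Kimura two-parameter model, so divergence targets are on
the same scale as measured K2P distances.  The number of events on a branch
of expected divergence *d* over *L* sites is Poisson(d·L); events that would
create an internal stop codon in the coding frame are rejected and redrawn.

Branch lengths are set so that the expected pairwise distance between
conspecific individuals equals the intraspecific target and between
congeneric heterospecific individuals the interspecific target.

``inject_defects`` adds the defect classes the quality filters exist for —
gap-bearing sequences, forced internal stop codons, "cf."-style names,
under-sampled species, and congeneric species pairs with identical sequences
— together with a manifest naming the filter stage expected to remove each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .bold_io import SequenceDataset, SequenceRecord
from .distances import distance_matrix, max_intraspecific, min_interspecific_congeneric
from .errors import ConfigurationError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Per base code, its two transversion partners (opposite parity).
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Divergence targets are expected substitutions per site (the scale of the
    K2P distance).  Defaults describe a clean, well-separated scenario: ten
    genera of four species with eight sequences each, tight conspecific
    variation (0.005) against clear congeneric divergence (0.06), and a
    transition/transversion rate ratio κ = 4, typical of insect mitochondrial
    coding sequence.  Defect rates default to zero; the species-level rates
    must sum to at most 1 because a species receives at most one defect.
    """

    n_genera: int = 10
    species_per_genus: int | tuple[int, int] = 4
    sequences_per_species: int | tuple[int, int] = 8
    sequence_length: int = 600
    intra_divergence: float = 0.005
    inter_divergence: float = 0.06
    kappa: float = 4.0
    genetic_code: int = 5
    genera_per_family: int = 3
    families_per_order: int = 2
    marker: str = "COI-5P"
    p_gap_record: float = 0.0
    p_stop_species: float = 0.0
    p_ambiguous_name_species: float = 0.0
    p_undersampled_species: float = 0.0
    p_zero_pair_genus: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence_length % 3:
            raise ConfigurationError("sequence_length must be a codon multiple")
        if not (0 < self.intra_divergence < 0.5 and 0 < self.inter_divergence < 0.5):
            raise ConfigurationError("divergence targets must lie in (0, 0.5)")
        if self.intra_divergence >= self.inter_divergence:
            raise ConfigurationError(
                "intraspecific divergence must be below interspecific divergence"
            )
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        species_rates = (
            self.p_stop_species
            + self.p_ambiguous_name_species
            + self.p_undersampled_species
        )
        rates = (
            species_rates, self.p_gap_record, self.p_zero_pair_genus,
        )
        if any(r < 0 for r in rates) or species_rates > 1 or any(r > 1 for r in rates):
            raise ConfigurationError("defect rates must be probabilities; the "
                                     "species-level rates must sum to ≤ 1")

    def _resolve(self, value: int | tuple[int, int], rng: np.random.Generator) -> int:
        if isinstance(value, tuple):
            lo, hi = value
            return int(rng.integers(lo, hi + 1))
        return int(value)


@dataclass
class GroundTruth:
    """True taxonomy and realized divergence of a generated dataset."""

    records: pd.DataFrame
    species: pd.DataFrame  # species, genus, n_records, max_intra
    genera: pd.DataFrame  # genus, n_species, min_inter, max_intra

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _stop_codon_codes(genetic_code: int) -> set[tuple[int, int, int]]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    code = {b: i for i, b in enumerate("ACGT")}
    return {tuple(code[b] for b in codon) for codon in table.stop_codons}


def _random_coding_sequence(
    length: int, stops: set[tuple[int, int, int]], rng: np.random.Generator
) -> np.ndarray:
    allowed = [
        (a, b, c)
        for a in range(4) for b in range(4) for c in range(4)
        if (a, b, c) not in stops
    ]
    picks = rng.integers(0, len(allowed), size=length // 3)
    return np.array([base for i in picks for base in allowed[i]], dtype=np.uint8)


def _evolve(
    parent: np.ndarray,
    branch_divergence: float,
    kappa: float,
    stops: set[tuple[int, int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of the stop-avoiding K2P jump process."""
    child = parent.copy()
    length = child.size
    p_transition = kappa / (kappa + 2.0)
    n_events = rng.poisson(branch_divergence * length)
    for _ in range(n_events):
        for _attempt in range(100):
            site = int(rng.integers(length))
            base = int(child[site])
            if rng.random() < p_transition:
                new = base ^ 2  # A<->G, C<->T under the 0..3 coding
            else:
                new = int(_TRANSVERSIONS[base][int(rng.integers(2))])
            codon_start = 3 * (site // 3)
            codon = list(child[codon_start : codon_start + 3])
            codon[site - codon_start] = new
            if tuple(codon) not in stops:
                child[site] = new
                break
    return child


def _decode(encoded: np.ndarray) -> str:
    return _BASES[encoded].tobytes().decode("ascii")


def generate_dataset(config: SimulationConfig) -> tuple[SequenceDataset, GroundTruth]:
    """Generate a clean (defect-free) dataset plus its ground truth.

    Fully deterministic given ``config.seed``.  The ground truth carries the
    true taxonomy of every record and the realized (K2P-measured) maximum
    intraspecific distance per species and minimum congeneric interspecific
    distance per genus, so tests never re-derive truth from names.
    """
    rng = np.random.default_rng(config.seed)
    stops = _stop_codon_codes(config.genetic_code)
    records: list[SequenceRecord] = []
    truth_rows = []
    counter = 0
    genera_per_order = config.genera_per_family * config.families_per_order
    for g in range(config.n_genera):
        order = f"Ordale{g // genera_per_order + 1:02d}"
        family = f"Famulidae{g // config.genera_per_family + 1:02d}"
        genus = f"Genulus{g + 1:03d}"
        root = _random_coding_sequence(config.sequence_length, stops, rng)
        n_species = config._resolve(config.species_per_genus, rng)
        species_branch = (config.inter_divergence - config.intra_divergence) / 2.0
        for s in range(n_species):
            species = f"{genus} simulans{s + 1:02d}"
            ancestor = _evolve(root, species_branch, config.kappa, stops, rng)
            n_seqs = config._resolve(config.sequences_per_species, rng)
            for _ in range(n_seqs):
                tip = _evolve(
                    ancestor, config.intra_divergence / 2.0, config.kappa, stops, rng
                )
                counter += 1
                rid = f"SYN{counter:06d}"
                records.append(
                    SequenceRecord(
                        record_id=rid,
                        species_name=species,
                        genus_name=genus,
                        family_name=family,
                        order_name=order,
                        marker=config.marker,
                        sequence=_decode(tip),
                    )
                )
                truth_rows.append(
                    {"record_id": rid, "order": order, "family": family,
                     "genus": genus, "species": species}
                )
    dataset = SequenceDataset(records, provenance=f"simulated(seed={config.seed})")
    truth = _measure_truth(dataset, pd.DataFrame(truth_rows))
    return dataset, truth


def _measure_truth(dataset: SequenceDataset, record_table: pd.DataFrame) -> GroundTruth:
    species_rows = []
    for species, recs in dataset.by_species().items():
        matrix = distance_matrix([(r.record_id, r.sequence) for r in recs])
        species_rows.append(
            {
                "species": species,
                "genus": recs[0].genus_name,
                "n_records": len(recs),
                "max_intra": max_intraspecific(matrix),
            }
        )
    species_table = pd.DataFrame(species_rows)
    genus_rows = []
    for genus, recs in dataset.by_genus().items():
        species_of = {r.record_id: r.species_name for r in recs}
        matrix = distance_matrix([(r.record_id, r.sequence) for r in recs])
        min_inter, _ = min_interspecific_congeneric(matrix, species_of)
        sub = species_table[species_table["genus"] == genus]
        genus_rows.append(
            {
                "genus": genus,
                "n_species": len(set(species_of.values())),
                "min_inter": min_inter,
                "max_intra": float(sub["max_intra"].max()),
            }
        )
    return GroundTruth(record_table, species_table, pd.DataFrame(genus_rows))


def inject_defects(
    dataset: SequenceDataset, config: SimulationConfig
) -> tuple[SequenceDataset, pd.DataFrame]:
    """Add filterable defects per the configured rates; return the manifest.

    The manifest has one row per removable item — granularity matching what
    the expected filter stage drops (record ids for record-level stages,
    species names for species-level stages) — with columns ``defect``,
    ``expected_stage`` and ``target``.
    """
    rng = np.random.default_rng([config.seed, 7919])
    stops = _stop_codon_codes(config.genetic_code)
    stop_strings = sorted(
        "".join("ACGT"[c] for c in codon) for codon in stops
    )
    by_id = {r.record_id: r for r in dataset}
    removed_ids: set[str] = set()
    manifest_rows: list[dict[str, str]] = []
    defected_species: set[str] = set()

    species_groups = dataset.by_species()
    genus_species: dict[str, list[str]] = {}
    for sp, recs in species_groups.items():
        genus_species.setdefault(recs[0].genus_name, []).append(sp)

    # Zero-distance congeneric pairs: one species' sequences copied over
    # another's, making their interspecific minimum exactly zero.
    for genus in sorted(genus_species):
        pool = sorted(genus_species[genus])
        if len(pool) < 2 or rng.random() >= config.p_zero_pair_genus:
            continue
        donor, receiver = (
            pool[i] for i in rng.choice(len(pool), size=2, replace=False)
        )
        donor_seqs = [r.sequence for r in species_groups[donor]]
        for i, rec in enumerate(species_groups[receiver]):
            by_id[rec.record_id] = rec.with_sequence(donor_seqs[i % len(donor_seqs)])
        defected_species.update({donor, receiver})
        for sp in (donor, receiver):
            manifest_rows.append(
                {"defect": "zero_distance_pair",
                 "expected_stage": "zero_interspecific", "target": sp}
            )

    # Species-level defects: at most one per species.
    for species in sorted(species_groups):
        if species in defected_species:
            continue
        recs = species_groups[species]
        u = rng.random()
        if u < config.p_stop_species:
            victim = recs[0]
            codon_index = int(rng.integers(1, len(victim.sequence) // 3 - 1))
            stop = stop_strings[int(rng.integers(len(stop_strings)))]
            seq = victim.sequence
            seq = seq[: 3 * codon_index] + stop + seq[3 * codon_index + 3 :]
            by_id[victim.record_id] = victim.with_sequence(seq)
            defected_species.add(species)
            manifest_rows.append(
                {"defect": "internal_stop_codon",
                 "expected_stage": "stop_codons", "target": species}
            )
        elif u < config.p_stop_species + config.p_ambiguous_name_species:
            genus, epithet = species.split(" ", 1)
            new_name = f"{genus} cf. {epithet}"
            for rec in recs:
                by_id[rec.record_id] = by_id[rec.record_id].with_species(new_name)
                manifest_rows.append(
                    {"defect": "ambiguous_name",
                     "expected_stage": "ambiguous_names", "target": rec.record_id}
                )
            defected_species.add(species)
        elif u < (config.p_stop_species + config.p_ambiguous_name_species
                  + config.p_undersampled_species):
            for rec in recs[2:]:
                removed_ids.add(rec.record_id)
            defected_species.add(species)
            manifest_rows.append(
                {"defect": "undersampled_species",
                 "expected_stage": "min_sequences", "target": species}
            )

    # Gap-bearing sequences inside otherwise clean, well-sampled species;
    # capped so the species never drops below three gapless records.
    for species in sorted(species_groups):
        if species in defected_species:
            continue
        recs = species_groups[species]
        budget = len(recs) - 3
        for rec in recs:
            if budget <= 0:
                break
            if rng.random() < config.p_gap_record:
                pos = int(rng.integers(len(rec.sequence)))
                seq = rec.sequence[:pos] + "-" + rec.sequence[pos + 1 :]
                by_id[rec.record_id] = by_id[rec.record_id].with_sequence(seq)
                budget -= 1
                manifest_rows.append(
                    {"defect": "gap_bearing_sequence",
                     "expected_stage": "gap_inducers", "target": rec.record_id}
                )

    new_records = [
        by_id[r.record_id] for r in dataset if r.record_id not in removed_ids
    ]
    manifest = pd.DataFrame(
        manifest_rows, columns=["defect", "expected_stage", "target"]
    )
    out = dataset.replace_records(new_records)
    out.provenance = dataset.provenance + "+defects"
    return out, manifest
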