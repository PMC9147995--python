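"""Quality-filter cascade for barcode datasets.

Species-level cascade, applied in order: drop records not identified to
species level; drop open-nomenclature names ("aff", "cf", "nr", "spp" as
name tokens); keep only the required marker; drop species with fewer than
three records; subsample species above the record cap; remove gap-bearing
sequences from each species alignment (re-checking the minimum-record rule
afterwards); drop species with internal stop codons in their best reading
frame; drop species with any undefined pairwise distance; drop species whose
maximum intraspecific distance exceeds the 95th-percentile value across
species.  Every stage is independently callable and every removal is listed
in a :class:`FilterReport`.

Genus-level preparation, applied to a dataset that already passed the
species-level cascade: remove both members of every congeneric species pair
at interspecific distance zero, then genera with fewer than three species,
then families with a single genus.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .bold_io import SequenceDataset, SequenceRecord
from .distances import distance_matrix, max_intraspecific, min_interspecific_congeneric
from .errors import ConfigurationError, DataError

_SP_EPITHET = re.compile(r"sp\.?\d*$")


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the species- and genus-level filter cascades."""

    exclusion_keywords: frozenset[str] = frozenset({"aff", "cf", "nr", "spp"})
    required_marker: str = "COI-5P"
    min_sequences_per_species: int = 3
    subsample_cap: int = 100
    subsample_seed: int = 0
    genetic_code: int = 5  # invertebrate mitochondrial
    quantile_cutoff: float = 0.95
    quantile_method: str = "linear"  # numpy name for the type-7 estimator
    min_species_per_genus: int = 3
    min_genera_per_family: int = 2

    def __post_init__(self) -> None:
        if self.min_sequences_per_species < 2:
            raise ConfigurationError("min_sequences_per_species must be ≥ 2")
        if not 0 < self.quantile_cutoff < 1:
            raise ConfigurationError("quantile_cutoff must be in (0, 1)")
        if self.subsample_cap < self.min_sequences_per_species:
            raise ConfigurationError("subsample_cap must be ≥ min_sequences_per_species")
        if not self.exclusion_keywords:
            raise ConfigurationError("exclusion_keywords must be non-empty")


@dataclass(frozen=True)
class FilterStage:
    """One cascade stage's before/after counts and removed identifiers."""

    name: str
    records_in: int
    records_out: int
    species_in: int
    species_out: int
    dropped: tuple[str, ...]


@dataclass
class FilterReport:
    """Ordered stage records; consecutive stages must agree on counts."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, before: SequenceDataset, after: SequenceDataset,
            dropped: Iterable[str]) -> None:
        self.stages.append(
            FilterStage(
                name=name,
                records_in=len(before),
                records_out=len(after),
                species_in=len(before.by_species()),
                species_out=len(after.by_species()),
                dropped=tuple(dropped),
            )
        )

    def stage(self, name: str) -> FilterStage:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "records_in": [s.records_in for s in self.stages],
                "records_out": [s.records_out for s in self.stages],
                "species_in": [s.species_in for s in self.stages],
                "species_out": [s.species_out for s in self.stages],
                "n_dropped": [len(s.dropped) for s in self.stages],
                "dropped": [";".join(s.dropped) for s in self.stages],
            }
        )


def filter_species_level_identification(dataset: SequenceDataset) -> SequenceDataset:
    """Remove records not identified to species level.

    Removed: empty names, genus-only names, and epithets of the form "sp.",
    "sp" or "sp." followed by numerals.
    """
    kept = []
    for rec in dataset:
        tokens = rec.species_name.split()
        if len(tokens) < 2:
            continue
        if _SP_EPITHET.fullmatch(tokens[1].lower()):
            continue
        kept.append(rec)
    return dataset.replace_records(kept)


def filter_ambiguous_names(
    dataset: SequenceDataset, keywords: Iterable[str] = FilterConfig().exclusion_keywords
) -> SequenceDataset:
    """Remove records whose species name carries an open-nomenclature keyword.

    Matching is token-based (whitespace or period delimited, lowercased), not
    substring-based, so "Cfa albipes" survives while "Apis cf. mellifera"
    does not.
    """
    kw = {k.lower() for k in keywords}
    if not kw:
        raise ConfigurationError("keywords must be non-empty")
    kept = []
    for rec in dataset:
        tokens = [t for t in re.split(r"[\s.]+", rec.species_name.lower()) if t]
        if any(t in kw for t in tokens):
            continue
        kept.append(rec)
    return dataset.replace_records(kept)


def filter_marker(dataset: SequenceDataset, required_marker: str = "COI-5P") -> SequenceDataset:
    """Keep only records whose marker code matches exactly (case-sensitive)."""
    return dataset.replace_records(r for r in dataset if r.marker == required_marker)


def filter_min_sequences(dataset: SequenceDataset, n: int = 3) -> SequenceDataset:
    """Remove species represented by fewer than ``n`` records."""
    groups = dataset.by_species()
    keep = {sp for sp, recs in groups.items() if len(recs) >= n}
    return dataset.replace_records(r for r in dataset if r.species_name in keep)


def _species_rng(seed: int, species_name: str) -> np.random.Generator:
    # Per-species stream derived from (seed, species name) so the selection
    # does not depend on dataset ordering or on other species.
    digest = hashlib.sha256(species_name.encode("utf-8")).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "little")])


def subsample_species(
    dataset: SequenceDataset, cap: int = 100, seed: int = 0
) -> SequenceDataset:
    """Reduce species above ``cap`` records to exactly ``cap`` by uniform
    sampling without replacement; deterministic given (seed, species name)."""
    if cap < 1:
        raise ConfigurationError("subsample cap must be ≥ 1")
    keep_ids: set[str] = set()
    for species, recs in dataset.by_species().items():
        ids = sorted(r.record_id for r in recs)
        if len(ids) > cap:
            rng = _species_rng(seed, species)
            ids = list(rng.choice(ids, size=cap, replace=False))
        keep_ids.update(ids)
    return dataset.replace_records(r for r in dataset if r.record_id in keep_ids)


def remove_gap_inducers(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[str]]:
    """Drop gap-bearing sequences from one species alignment.

    Columns that are gap-only across the alignment are excised first (they
    carry no signal), then every sequence still containing ``-`` is removed.
    Returns (kept records with gapless sequences, removed record ids).
    Unequal sequence lengths are a data error.
    """
    if not records:
        return [], []
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise DataError(f"unaligned species alignment: lengths {sorted(lengths)}")
    array = np.array([list(r.sequence) for r in records])
    gap_only = (array == "-").all(axis=0)
    if gap_only.any():
        array = array[:, ~gap_only]
    has_gap = (array == "-").any(axis=1)
    kept, removed = [], []
    for rec, row, gapped in zip(records, array, has_gap):
        if gapped:
            removed.append(rec.record_id)
        else:
            kept.append(rec.with_sequence("".join(row)))
    return kept, removed


def _stop_codons(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def count_stop_codons(sequence: str, frame: int, stops: frozenset[str]) -> int:
    """Stop codons among the complete codons of one reading frame."""
    return sum(
        1
        for i in range(frame, len(sequence) - 2, 3)
        if sequence[i : i + 3] in stops
    )


def filter_stop_codons(
    records: Sequence[SequenceRecord], genetic_code: int = 5
) -> bool:
    """Keep/drop decision for one species based on internal stop codons.

    For each of the three forward reading frames the stop codons are summed
    over all sequences (the final incomplete codon is ignored); the frame
    with the minimum total is taken as the species' reading frame.  The
    species is kept iff that minimum is zero.
    """
    stops = _stop_codons(genetic_code)
    totals = [
        sum(count_stop_codons(r.sequence, frame, stops) for r in records)
        for frame in range(3)
    ]
    return min(totals) == 0


def filter_quantile_outliers(
    per_species_max_intra: dict[str, float],
    q: float = 0.95,
    method: str = "linear",
) -> set[str]:
    """Retain species whose maximum intraspecific distance does not exceed the
    q-quantile of those maxima (computed over all species; equality retained)."""
    if not per_species_max_intra:
        raise DataError("empty species → distance mapping")
    values = np.array(list(per_species_max_intra.values()))
    cutoff = float(np.quantile(values, q, method=method))
    return {sp for sp, v in per_species_max_intra.items() if v <= cutoff}


def _drop_species(dataset: SequenceDataset, species: set[str]) -> SequenceDataset:
    return dataset.replace_records(r for r in dataset if r.species_name not in species)


def run_filter_cascade(
    dataset: SequenceDataset,
    config: FilterConfig = FilterConfig(),
    model: str = "K2P",
) -> tuple[SequenceDataset, FilterReport]:
    """Apply the full species-level cascade; every stage is reported.

    After the cascade every surviving species has at least
    ``min_sequences_per_species`` gapless, stop-codon-free, equal-length
    sequences with all pairwise distances defined, and no species exceeds the
    quantile cutoff on maximum intraspecific distance.
    """
    report = FilterReport()

    def record_stage(name: str, before: SequenceDataset, after: SequenceDataset,
                     by_species: bool = False) -> SequenceDataset:
        if by_species:
            gone = set(before.by_species()) - set(after.by_species())
            dropped = sorted(gone)
        else:
            dropped = sorted(
                {r.record_id for r in before} - {r.record_id for r in after}
            )
        report.add(name, before, after, dropped)
        return after

    current = dataset
    current = record_stage(
        "species_level_identification", current,
        filter_species_level_identification(current))
    current = record_stage(
        "ambiguous_names", current,
        filter_ambiguous_names(current, config.exclusion_keywords))
    current = record_stage(
        "marker", current, filter_marker(current, config.required_marker))
    current = record_stage(
        "min_sequences", current,
        filter_min_sequences(current, config.min_sequences_per_species),
        by_species=True)
    current = record_stage(
        "subsample", current,
        subsample_species(current, config.subsample_cap, config.subsample_seed))

    # Gap-bearing sequences, per species alignment.
    kept_records: list[SequenceRecord] = []
    gap_removed: list[str] = []
    for recs in current.by_species().values():
        kept, removed = remove_gap_inducers(recs)
        kept_records.extend(kept)
        gap_removed.extend(removed)
    after_gaps = current.replace_records(kept_records)
    report.add("gap_inducers", current, after_gaps, sorted(gap_removed))
    current = after_gaps

    current = record_stage(
        "min_sequences_after_gaps", current,
        filter_min_sequences(current, config.min_sequences_per_species),
        by_species=True)

    stop_drop = {
        sp for sp, recs in current.by_species().items()
        if not filter_stop_codons(recs, config.genetic_code)
    }
    current = record_stage(
        "stop_codons", current, _drop_species(current, stop_drop), by_species=True)

    matrices = {
        sp: distance_matrix([(r.record_id, r.sequence) for r in recs], model)
        for sp, recs in current.by_species().items()
    }
    na_drop = {sp for sp, m in matrices.items() if m.has_undefined}
    current = record_stage(
        "undefined_distances", current, _drop_species(current, na_drop), by_species=True)

    max_intra = {
        sp: max_intraspecific(matrices[sp])
        for sp in current.by_species()
    }
    if max_intra:
        retained = filter_quantile_outliers(
            max_intra, config.quantile_cutoff, config.quantile_method)
        quantile_drop = set(max_intra) - retained
    else:
        quantile_drop = set()
    current = record_stage(
        "quantile_outliers", current, _drop_species(current, quantile_drop),
        by_species=True)

    return current, report


def filter_undefined_distances(matrix) -> bool:
    """Keep/drop decision for one species: keep iff no pairwise distance is
    undefined."""
    return not matrix.has_undefined


def prepare_genus_level(
    dataset: SequenceDataset,
    config: FilterConfig = FilterConfig(),
    model: str = "K2P",
) -> tuple[SequenceDataset, FilterReport]:
    """Genus-level preparation filters (run after the species-level cascade).

    Removes both members of every congeneric species pair at interspecific
    distance zero, then genera with fewer than ``min_species_per_genus``
    species, then families with fewer than ``min_genera_per_family`` genera.
    """
    report = FilterReport()

    zero_species: set[str] = set()
    for recs in dataset.by_genus().values():
        species_of = {r.record_id: r.species_name for r in recs}
        if len(set(species_of.values())) < 2:
            continue
        matrix = distance_matrix([(r.record_id, r.sequence) for r in recs], model)
        _, per_species = min_interspecific_congeneric(matrix, species_of)
        zero_species.update(sp for sp, d in per_species.items() if d == 0.0)
    after_zero = _drop_species(dataset, zero_species)
    report.add("zero_interspecific", dataset, after_zero, sorted(zero_species))
    current = after_zero

    genus_species = {
        genus: {r.species_name for r in recs}
        for genus, recs in current.by_genus().items()
    }
    small_genera = {
        g for g, sps in genus_species.items()
        if len(sps) < config.min_species_per_genus
    }
    after_genera = current.replace_records(
        r for r in current if r.genus_name not in small_genera)
    report.add("min_species_per_genus", current, after_genera, sorted(small_genera))
    current = after_genera

    family_genera: dict[str, set[str]] = {}
    for r in current:
        family_genera.setdefault(r.family_name, set()).add(r.genus_name)
    small_families = {
        f for f, genera in family_genera.items()
        if len(genera) < config.min_genera_per_family
    }
    after_families = current.replace_records(
        r for r in current if r.family_name not in small_families)
    report.add("single_genus_families", current, after_families, sorted(small_families))
    return after_families, report
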