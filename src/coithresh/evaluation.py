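"""Congruence between MOTU partitions and morphological taxonomy.

The headline statistic is the match ratio

    match_ratio = 2 · Nmatch / (Ndelimited + Nmorph)

where Nmorph is the number of morphologically defined species in the genus,
Ndelimited the number of MOTUs the method produced, and Nmatch the number of
MOTUs whose member set coincides exactly with the member set of one species.
The ratio is 1 iff the two partitions are identical.

Per species the outcome is one of four categories: MATCH (the species is one
MOTU containing nothing else), SPLIT (spread over several MOTUs, each pure),
MERGE (one MOTU shared with other species) and MIXTURE (spread over several
MOTUs, at least one shared).  The categories are exhaustive and mutually
exclusive, so their counts sum to Nmorph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Partition, cluster_count, species_motu_sets, threshold_cluster
from .distances import DistanceMatrix, min_interspecific_congeneric
from .errors import DataError
from .thresholds import mininter_threshold

CATEGORIES = ("MATCH", "SPLIT", "MERGE", "MIXTURE")


@dataclass(frozen=True)
class GenusEvaluation:
    """Delimitation outcome of one method on one genus."""

    genus: str
    method: str
    threshold: float | None
    n_morph: int
    n_delimited: int
    n_match: int
    match_ratio: float
    species_outcomes: Mapping[str, str]

    @property
    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for cat in self.species_outcomes.values():
            counts[cat] += 1
        return counts


def match_ratio(
    partition: Partition, species_of: Mapping[str, str]
) -> tuple[int, int, int, float]:
    """(Nmatch, Ndelimited, Nmorph, 2·Nmatch/(Ndelimited+Nmorph))."""
    if set(partition.assignment) != set(species_of):
        raise DataError("partition does not cover exactly the labeled records")
    species_sets = {}
    for rid, sp in species_of.items():
        species_sets.setdefault(sp, set()).add(rid)
    species_sets = {sp: frozenset(m) for sp, m in species_sets.items()}
    motu_sets = partition.member_sets()
    n_match = len(motu_sets & set(species_sets.values()))
    n_delimited = len(motu_sets)
    n_morph = len(species_sets)
    return n_match, n_delimited, n_morph, 2.0 * n_match / (n_delimited + n_morph)


def classify_species_outcomes(
    partition: Partition, species_of: Mapping[str, str]
) -> dict[str, str]:
    """Per-species MATCH/SPLIT/MERGE/MIXTURE classification."""
    occupancy = species_motu_sets(partition, species_of)
    motus = partition.motus()
    purity = {
        motu: len({species_of[rid] for rid in members}) == 1
        for motu, members in motus.items()
    }
    outcomes: dict[str, str] = {}
    for sp, motu_ids in occupancy.items():
        all_pure = all(purity[m] for m in motu_ids)
        if len(motu_ids) == 1:
            outcomes[sp] = "MATCH" if all_pure else "MERGE"
        else:
            outcomes[sp] = "SPLIT" if all_pure else "MIXTURE"
    return outcomes


def evaluate_genus(
    genus: str,
    method: str,
    threshold: float | None,
    partition: Partition,
    species_of: Mapping[str, str],
) -> GenusEvaluation:
    n_match, n_delim, n_morph, ratio = match_ratio(partition, species_of)
    return GenusEvaluation(
        genus=genus,
        method=method,
        threshold=threshold,
        n_morph=n_morph,
        n_delimited=n_delim,
        n_match=n_match,
        match_ratio=ratio,
        species_outcomes=classify_species_outcomes(partition, species_of),
    )


def overestimation_ratio(n_clusters: int, n_species: int) -> float:
    """(clusters − species)/species as a fraction; negative when clustering
    lumps more than taxonomy."""
    if n_species <= 0:
        raise DataError("n_species must be positive")
    return (n_clusters - n_species) / n_species


def frequency_distribution(
    values: Sequence[float] | np.ndarray, bin_width: float = 0.01
) -> pd.DataFrame:
    """Histogram table with left-closed right-open bins of fixed width.

    A value sitting exactly on a bin edge goes to the higher bin.  Columns:
    ``bin_low``, ``bin_high``, ``count``, ``frequency``; counts sum to the
    number of values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count", "frequency"])
    index = np.floor(x / bin_width + 1e-12).astype(int)
    top = int(index.max())
    counts = np.bincount(index, minlength=top + 1)
    return pd.DataFrame(
        {
            "bin_low": np.arange(top + 1) * bin_width,
            "bin_high": np.arange(1, top + 2) * bin_width,
            "count": counts,
            "frequency": counts / x.size,
        }
    )


def proportion_above(values: Sequence[float] | np.ndarray, cutoff: float) -> float:
    """Fraction of values strictly greater than the cutoff."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DataError("proportion_above needs at least one value")
    return float((x > cutoff).sum() / x.size)


@dataclass(frozen=True)
class GenusData:
    """A genus ready for clustering: its matrix and record → species map."""

    genus: str
    matrix: DistanceMatrix
    species_of: Mapping[str, str]


def mininter_subset_report(
    genera: Iterable[GenusData],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.0, 0.11, 0.01), 2)),
    fixed_thresholds: Sequence[float] = (0.01, 0.02, 0.022, 0.03),
    comparison: str = "lt",
) -> pd.DataFrame:
    """Cluster-count report over subsets defined by minimum-interspecific cutoffs.

    Per-species congeneric minimum distances are computed once on the full
    genera.  For each cutoff *c*, species whose minimum is ≥ *c* are
    retained; genera left with fewer than two species are dropped from that
    row so the minimum-interspecific column stays defined on the same record
    set as the fixed-threshold columns.  Each retained genus is re-clustered
    at every fixed threshold and at its (recomputed) minimum interspecific
    distance minus the 1e-8 correction.  Output columns: ``cutoff``, ``SN``
    (species number), per threshold the MOTU count ``M_<t>`` and the
    overestimation percentage ``pct_<t>`` (rounded to the nearest integer),
    and the same pair for the minimum-interspecific threshold.
    """
    genera = list(genera)
    minima: list[dict[str, float]] = []
    for g in genera:
        _, per_species = min_interspecific_congeneric(g.matrix, g.species_of)
        minima.append(per_species)
    rows = []
    for cutoff in cutoffs:
        sn = 0
        motu_counts = {f"{t:g}": 0 for t in fixed_thresholds}
        motu_counts["mininter"] = 0
        for g, per_species in zip(genera, minima):
            retained = {sp for sp, d in per_species.items() if d >= cutoff}
            if len(retained) < 2:
                continue
            labels = [lab for lab in g.matrix.labels if g.species_of[lab] in retained]
            sub = g.matrix.submatrix(labels)
            sub_species = {lab: g.species_of[lab] for lab in labels}
            sn += len(retained)
            for t in fixed_thresholds:
                motu_counts[f"{t:g}"] += cluster_count(
                    threshold_cluster(sub, t, comparison)
                )
            sub_min, _ = min_interspecific_congeneric(sub, sub_species)
            motu_counts["mininter"] += cluster_count(
                threshold_cluster(sub, mininter_threshold(sub_min), comparison)
            )
        row: dict[str, float | int] = {"cutoff": cutoff, "SN": sn}
        for key, count in motu_counts.items():
            row[f"M_{key}"] = count
            row[f"pct_{key}"] = (
                round(100.0 * overestimation_ratio(count, sn)) if sn else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
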