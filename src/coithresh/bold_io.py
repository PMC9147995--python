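"""Reading and writing BOLD-style specimen tables and FASTA files.

The central containers are :class:`SequenceRecord` (one specimen: identifier,
taxonomy, marker code, aligned nucleotide string) and :class:`SequenceDataset`
(an ordered record collection with grouping accessors by species and genus).
TSV input follows the public BOLD specimen export: tab-separated, UTF-8, a
header row with ``processid``, ``order_name``, ``family_name``, ``genus_name``,
``species_name``, ``markercode`` and ``nucleotides`` columns; a column map lets
callers rename any of those roles. FASTA headers carry the same fields as
pipe-delimited tokens so that a write/read round trip preserves the taxonomy.
"""

from __future__ import annotations

import re
from collections import Counter, OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import ConfigurationError, DataError

#: IUPAC nucleotide alphabet, ambiguity codes included, plus the alignment gap.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")

#: Default mapping from logical roles to BOLD specimen-export column names.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "record_id": "processid",
    "order": "order_name",
    "family": "family_name",
    "genus": "genus_name",
    "species": "species_name",
    "marker": "markercode",
    "sequence": "nucleotides",
}

_FASTA_DELIMITER = "|"


@dataclass(frozen=True)
class SequenceRecord:
    """One specimen record: identity, taxonomy, marker and sequence.

    The sequence is stored uppercase; letters outside the IUPAC nucleotide
    alphabet (gap ``-`` included) raise :class:`~coithresh.errors.DataError`.
    ``species_name`` is the name as printed in the source, which may be a
    binomial, a trinomial or an open-nomenclature form — the filtering module
    is what decides which of those survive.
    """

    record_id: str
    species_name: str
    genus_name: str = ""
    family_name: str = ""
    order_name: str = ""
    marker: str = "COI-5P"
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise DataError("record_id must be non-empty")
        seq = re.sub(r"\s+", "", self.sequence).upper()
        if not seq:
            raise DataError(f"record {self.record_id!r}: empty sequence")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise DataError(
                f"record {self.record_id!r}: non-IUPAC symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def with_sequence(self, sequence: str) -> "SequenceRecord":
        return replace(self, sequence=sequence)

    def with_species(self, species_name: str) -> "SequenceRecord":
        return replace(self, species_name=species_name)


@dataclass
class SequenceDataset:
    """An ordered collection of :class:`SequenceRecord` with a provenance tag.

    Grouping accessors return dicts keyed by species (full printed name) or
    genus; together the groups partition the records.  ``load_report`` carries
    per-category drop counts from the reader that produced the dataset.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    provenance: str = ""
    load_report: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def replace_records(self, records: Iterable[SequenceRecord]) -> "SequenceDataset":
        """A new dataset with the same provenance but different records."""
        return SequenceDataset(list(records), provenance=self.provenance)

    def by_species(self) -> "OrderedDict[str, list[SequenceRecord]]":
        groups: OrderedDict[str, list[SequenceRecord]] = OrderedDict()
        for rec in self.records:
            groups.setdefault(rec.species_name, []).append(rec)
        return groups

    def by_genus(self) -> "OrderedDict[str, list[SequenceRecord]]":
        groups: OrderedDict[str, list[SequenceRecord]] = OrderedDict()
        for rec in self.records:
            groups.setdefault(rec.genus_name, []).append(rec)
        return groups

    def species_names(self) -> list[str]:
        return list(self.by_species())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "processid": [r.record_id for r in self.records],
                "order_name": [r.order_name for r in self.records],
                "family_name": [r.family_name for r in self.records],
                "genus_name": [r.genus_name for r in self.records],
                "species_name": [r.species_name for r in self.records],
                "markercode": [r.marker for r in self.records],
                "nucleotides": [r.sequence for r in self.records],
            }
        )


def _check_unique_ids(records: list[SequenceRecord]) -> None:
    counts = Counter(r.record_id for r in records)
    dupes = sorted(rid for rid, n in counts.items() if n > 1)
    if dupes:
        raise DataError(f"duplicate record ids: {dupes}")


def read_bold_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SequenceDataset:
    """Read a BOLD-style tab-separated specimen table.

    ``column_map`` overrides entries of :data:`DEFAULT_COLUMN_MAP` (role →
    column name).  Rows whose sequence cell is empty are dropped and counted
    in the dataset's ``load_report`` under ``dropped_empty_sequence``.
    """
    path = Path(path)
    roles = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        roles.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for role, column in roles.items():
        if column not in table.columns:
            raise ConfigurationError(
                f"required role {role!r} not found: no column {column!r} in {path.name}"
            )
    rows_in = len(table)
    seq_col = roles["sequence"]
    empty = table[seq_col].str.strip() == ""
    table = table[~empty]
    records = [
        SequenceRecord(
            record_id=row[roles["record_id"]],
            order_name=row[roles["order"]],
            family_name=row[roles["family"]],
            genus_name=row[roles["genus"]],
            species_name=row[roles["species"]],
            marker=row[roles["marker"]],
            sequence=row[seq_col],
        )
        for row in table.to_dict("records")
    ]
    _check_unique_ids(records)
    dataset = SequenceDataset(records, provenance=str(path))
    dataset.load_report = {
        "rows_in": rows_in,
        "records_out": len(records),
        "dropped_empty_sequence": int(empty.sum()),
    }
    return dataset


def write_bold_tsv(dataset: SequenceDataset, path: str | Path) -> Path:
    """Write the dataset as a BOLD-style TSV (default column names)."""
    path = Path(path)
    dataset.to_frame().to_csv(path, sep="\t", index=False)
    return path


def _parse_fasta_header(header: str) -> SequenceRecord | None:
    """Split a pipe-delimited header into record fields (sequence added later).

    Accepts the five-field form ``id|order|family|binomial|marker`` written by
    :func:`write_fasta` and the short form ``id|binomial|marker``; in the short
    form the genus is the first token of the binomial.
    """
    parts = [p.strip() for p in header.split(_FASTA_DELIMITER)]
    if len(parts) == 5:
        rid, order, family, species, marker = parts
        genus = species.split()[0] if species.split() else ""
        return SequenceRecord(rid, species, genus, family, order, marker, "N")
    if len(parts) == 3:
        rid, species, marker = parts
        genus = species.split()[0] if species.split() else ""
        return SequenceRecord(rid, species, genus, "", "", marker, "N")
    return None


def read_fasta(path: str | Path) -> SequenceDataset:
    """Read a FASTA file whose headers follow the pipe-delimited convention."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        stub = _parse_fasta_header(bio_rec.description)
        if stub is None:
            raise DataError(
                f"unparseable FASTA header (expected pipe-delimited fields): "
                f"{bio_rec.description!r}"
            )
        records.append(stub.with_sequence(str(bio_rec.seq)))
    _check_unique_ids(records)
    return SequenceDataset(records, provenance=str(path))


def sanitize_filename(name: str) -> str:
    """Species/genus name → deterministic, filesystem-safe file stem."""
    stem = re.sub(r"\s+", "_", name.strip())
    stem = re.sub(r"[^A-Za-z0-9_\-]", "", stem)
    return stem or "unnamed"


def _to_bio(rec: SequenceRecord) -> BioSeqRecord:
    header = _FASTA_DELIMITER.join(
        [rec.record_id, rec.order_name, rec.family_name, rec.species_name, rec.marker]
    )
    return BioSeqRecord(Seq(rec.sequence), id=header, description="")


def write_fasta(
    dataset: SequenceDataset,
    path: str | Path,
    grouping: str = "none",
) -> dict[str, Path]:
    """Write the dataset to FASTA.

    ``grouping='none'`` writes one file at ``path``; ``'per-species'`` or
    ``'per-genus'`` treat ``path`` as a directory and write one file per group
    with sanitized names (collisions get a numeric suffix).  Returns a mapping
    group name → written path (key ``''`` for the ungrouped file).
    """
    if not dataset.records:
        raise DataError("refusing to write an empty dataset")
    path = Path(path)
    if grouping == "none":
        with open(path, "w") as handle:
            SeqIO.write([_to_bio(r) for r in dataset], handle, "fasta")
        return {"": path}
    if grouping not in ("per-species", "per-genus"):
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    groups = dataset.by_species() if grouping == "per-species" else dataset.by_genus()
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    used: dict[str, int] = {}
    for name, records in groups.items():
        stem = sanitize_filename(name)
        n_seen = used.get(stem, 0)
        used[stem] = n_seen + 1
        if n_seen:
            stem = f"{stem}_{n_seen + 1}"
        target = path / f"{stem}.fasta"
        with open(target, "w") as handle:
            SeqIO.write([_to_bio(r) for r in records], handle, "fasta")
        written[name] = target
    return written
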