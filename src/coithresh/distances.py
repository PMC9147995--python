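"""Pairwise genetic distances with pairwise deletion.

Two models are offered: the Kimura two-parameter (K2P) distance, which
corrects for multiple hits while distinguishing transitions (A↔G, C↔T) from
transversions, and the uncorrected p-distance.  For a pair of aligned
sequences, sites where either member carries anything other than A, C, G or T
(gaps, Ns, IUPAC ambiguity codes) are excluded — pairwise deletion.  With
``P`` the transition proportion and ``Q`` the transversion proportion over the
compared sites, the K2P distance is

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

A distance is *undefined* — a first-class state, returned as ``None`` for
scalars and stored as NaN behind an explicit mask in matrices — when no site
is comparable or when a logarithm argument is non-positive (saturation).  The
"NA" filter in the quality cascade acts on exactly this state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _base in enumerate(b"ACGT"):
    _ENCODE[_base] = _i
# With A=0, C=1, G=2, T=3 the purines are even and the pyrimidines odd, so a
# substitution is a transition iff both codes share parity.


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes; non-ACGT symbols become 255."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def pair_site_counts(ea: np.ndarray, eb: np.ndarray) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    diff = valid & (ea != eb)
    transitions = int((diff & ((ea & 1) == (eb & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return n, transitions, transversions


def k2p_from_counts(n: int, transitions: int, transversions: int) -> float | None:
    """K2P distance from site counts, or ``None`` where the formula is undefined."""
    if n == 0:
        return None
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> float | None:
    """K2P distance between two equal-length aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise DataError(
            f"unaligned input: sequence lengths differ ({len(seq_a)} vs {len(seq_b)})"
        )
    return k2p_from_counts(*pair_site_counts(encode_sequence(seq_a), encode_sequence(seq_b)))


def p_distance(seq_a: str, seq_b: str) -> float | None:
    """Proportion of mismatched sites under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise DataError(
            f"unaligned input: sequence lengths differ ({len(seq_a)} vs {len(seq_b)})"
        )
    n, ts, tv = pair_site_counts(encode_sequence(seq_a), encode_sequence(seq_b))
    if n == 0:
        return None
    return (ts + tv) / n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled distance matrix with an explicit undefined state.

    ``values`` holds NaN wherever a pair is undefined; the diagonal is always
    zero and defined.  Labels keep the order the sequences were supplied in.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    model: str = "K2P"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("distance matrix shape does not match its labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def value(self, label_a: str, label_b: str) -> float | None:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        v = self.values[i, j]
        return None if np.isnan(v) else float(v)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle values (NaN included), one entry per unordered pair."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.model)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))
        frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, model: str = "K2P") -> "DistanceMatrix":
        """Read a labeled square TSV; a PHYLIP-style square matrix (leading
        count line, whitespace-separated) is also accepted."""
        path = Path(path)
        first = path.read_text().splitlines()[0].split()
        if len(first) == 1 and first[0].isdigit():
            frame = pd.read_csv(
                path, sep=r"\s+", skiprows=1, header=None, index_col=0, na_values=["NA"]
            )
            frame.columns = list(frame.index)
        else:
            frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        values = frame.to_numpy(dtype=float)
        return cls(tuple(str(x) for x in frame.index), values, model)


def distance_matrix(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    model: str = "K2P",
) -> DistanceMatrix:
    """All pairwise distances among labeled, equal-length aligned sequences."""
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise DataError("cannot build a distance matrix from zero sequences")
    labels = tuple(label for label, _ in items)
    lengths = {len(seq) for _, seq in items}
    if len(lengths) > 1:
        raise DataError(f"unaligned input: sequence lengths {sorted(lengths)}")
    if model not in ("K2P", "p"):
        raise DataError(f"unknown distance model {model!r}")
    encoded = [encode_sequence(seq) for _, seq in items]
    n = len(items)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            sites, ts, tv = pair_site_counts(encoded[i], encoded[j])
            if model == "K2P":
                d = k2p_from_counts(sites, ts, tv)
            else:
                d = None if sites == 0 else (ts + tv) / sites
            values[i, j] = values[j, i] = np.nan if d is None else d
    return DistanceMatrix(labels, values, model)


def max_intraspecific(matrix: DistanceMatrix) -> float:
    """Maximum pairwise distance within one species' matrix.

    Requires at least two records and no undefined cells.
    """
    if matrix.n < 2:
        raise DataError("max_intraspecific needs at least two records")
    off = matrix.off_diagonal()
    if np.isnan(off).any():
        raise DataError("undefined distances present; filter the species first")
    return float(off.max())


def min_interspecific_congeneric(
    matrix: DistanceMatrix, species_of: Mapping[str, str]
) -> tuple[float, dict[str, float]]:
    """Minimum heterospecific distance within a genus.

    Returns the per-genus minimum and, per species, the minimum distance to
    any congeneric heterospecific record.  The genus value equals the minimum
    of the per-species values.  Requires ≥2 species and defined heterospecific
    distances.
    """
    species = np.array([species_of[lab] for lab in matrix.labels])
    if len(set(species)) < 2:
        raise DataError("min_interspecific_congeneric needs at least two species")
    hetero = species[:, None] != species[None, :]
    vals = matrix.values
    if np.isnan(vals[hetero]).any():
        raise DataError("undefined heterospecific distances; filter the genus first")
    per_species: dict[str, float] = {}
    for sp in sorted(set(species)):
        rows = species == sp
        per_species[sp] = float(vals[np.ix_(rows, ~rows)].min())
    return min(per_species.values()), per_species
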