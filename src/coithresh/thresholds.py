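"""Flexible threshold selection for distance-based species delimitation.

Three strategies, each producing a clustering threshold for one genus:

* **local minima** — a Gaussian kernel density estimate over all pairwise
  distances of the genus; a dip (interior local minimum) marks the transition
  between intra- and interspecific distances (the barcoding gap).  The first
  local minimum is the threshold; a unimodal density means the method is not
  applicable to that genus.
* **error-minimising grid search** — every threshold on a fixed grid is
  scored by cumulative identification error (false positives + false
  negatives); the optimum is the mean of all thresholds attaining the
  minimum.
* **minimum interspecific** — the smallest congeneric heterospecific distance
  minus a 1e-8 correction, so that strict-``<`` clustering keeps the closest
  heterospecific pair apart.

The identification-error taxonomy per record, at threshold *t*: let *M* be
the set of other records at distance < *t* (its neighbourhood).  An empty
*M* is a true negative when the record's species has no other member in the
data, otherwise a false negative (a conspecific exists but is not found).  A
non-empty *M* is a true positive when every neighbour is conspecific,
otherwise a false positive.  The four categories are exhaustive and mutually
exclusive, so they sum to the number of records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import DataError

#: Correction subtracted from the minimum interspecific distance so that
#: strict-< clustering separates the pair attaining the minimum.
MININTER_CORRECTION = 1e-8


@dataclass(frozen=True)
class ThresholdGrid:
    """Evenly spaced candidate thresholds, generated by index to avoid
    floating-point accumulation drift."""

    start: float = 0.001
    stop: float = 0.2
    step: float = 0.001

    def __post_init__(self) -> None:
        if not (self.start > 0 and self.step > 0 and self.stop >= self.start):
            raise DataError(
                f"invalid grid: start={self.start}, stop={self.stop}, step={self.step}"
            )

    def thresholds(self) -> np.ndarray:
        k = int(np.floor((self.stop - self.start) / self.step + 1e-9))
        return self.start + np.arange(k + 1) * self.step


@dataclass(frozen=True)
class ScanRow:
    """Identification-error counts at one threshold."""

    threshold: float
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int

    @property
    def cumulative_error(self) -> int:
        return self.false_positives + self.false_negatives

    @property
    def total(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.false_negatives
            + self.true_negatives
        )


@dataclass(frozen=True)
class ThresholdScan:
    """Rows of a grid scan, exportable as a tidy table."""

    rows: tuple[ScanRow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [r.threshold for r in self.rows],
                "true_positives": [r.true_positives for r in self.rows],
                "false_positives": [r.false_positives for r in self.rows],
                "false_negatives": [r.false_negatives for r in self.rows],
                "true_negatives": [r.true_negatives for r in self.rows],
                "cumulative_error": [r.cumulative_error for r in self.rows],
            }
        )


def rule_of_thumb_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9·min(sd, IQR/1.34)·n^(-1/5).

    Falls back (sd, then |x₁|, then 1) when the spread is degenerate, so the
    bandwidth is always positive.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    lo = min(sd, (q75 - q25) / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def local_minima_thresholds(
    distance_values: Sequence[float] | np.ndarray,
    *,
    bandwidth: float | None = None,
    n_points: int = 512,
    cut: float = 3.0,
) -> list[float]:
    """Candidate thresholds at the dips of the distance-density estimate.

    A Gaussian KDE is evaluated on ``n_points`` equally spaced points spanning
    [min − cut·bw, max + cut·bw]; grid points strictly lower than both
    neighbours are local minima, returned in increasing order (possibly
    empty when the density is unimodal).
    """
    x = np.asarray(distance_values, dtype=float)
    if x.size < 2:
        raise DataError("local minima need at least two distance values")
    bw = rule_of_thumb_bandwidth(x) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise DataError("bandwidth must be positive")
    grid = np.linspace(x.min() - cut * bw, x.max() + cut * bw, n_points)
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    interior = (density[1:-1] < density[:-2]) & (density[1:-1] < density[2:])
    return [float(g) for g in grid[1:-1][interior]]


def select_local_minima(candidates: Sequence[float]) -> float | None:
    """The first (smallest) local minimum, or ``None`` when there is none.

    ``None`` propagates through reports as "method not applicable to this
    genus"."""
    return float(candidates[0]) if candidates else None


def identification_errors(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    threshold: float,
    comparison: str = "lt",
) -> ScanRow:
    """Score one threshold against the taxonomy (see module docstring)."""
    if matrix.has_undefined:
        raise DataError("undefined distances present; filter before scoring")
    species = np.array([species_of[lab] for lab in matrix.labels])
    if comparison == "lt":
        below = matrix.values < threshold
    elif comparison == "le":
        below = matrix.values <= threshold
    else:
        raise DataError(f"unknown comparison {comparison!r}")
    np.fill_diagonal(below, False)
    counts = Counter(species)
    singleton = np.array([counts[sp] == 1 for sp in species])
    conspecific = species[:, None] == species[None, :]
    has_neighbour = below.any(axis=1)
    impure = (below & ~conspecific).any(axis=1)
    tp = int((has_neighbour & ~impure).sum())
    fp = int((has_neighbour & impure).sum())
    tn = int((~has_neighbour & singleton).sum())
    fn = int((~has_neighbour & ~singleton).sum())
    return ScanRow(float(threshold), tp, fp, fn, tn)


def thresh_opt(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    grid: ThresholdGrid = ThresholdGrid(),
    comparison: str = "lt",
) -> tuple[float, ThresholdScan]:
    """Grid-search the threshold minimising cumulative identification error.

    Every grid threshold is scored; the optimum is the arithmetic mean of all
    thresholds attaining the minimal cumulative error (so a broad flat
    optimum lands mid-gap).  Returns the optimum and the full scan.
    """
    rows = tuple(
        identification_errors(matrix, species_of, t, comparison)
        for t in grid.thresholds()
    )
    errors = np.array([r.cumulative_error for r in rows])
    tied = [r.threshold for r, e in zip(rows, errors) if e == errors.min()]
    return float(np.mean(tied)), ThresholdScan(rows)


def mininter_threshold(
    min_interspecific: float, correction: float = MININTER_CORRECTION
) -> float:
    """Clustering threshold just below the minimum interspecific distance."""
    if min_interspecific <= correction:
        raise DataError(
            f"minimum interspecific distance {min_interspecific} is not above the "
            f"correction {correction}"
        )
    return min_interspecific - correction
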