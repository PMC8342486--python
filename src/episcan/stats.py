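"""Gini-purity association statistics for genotype-combination tables.

Two statistics are computed for every SNV tuple:

* beta — the combined association power: the count-weighted mean
  purity of the contingency-table rows, where the purity of a set with
  x cases and y controls is (x^2 + y^2) / (x + y)^2.  beta lies in
  [0.5, 1] and never decreases when an SNV is added to the tuple.
* alpha — the interaction effect size: beta of the full m-tuple minus
  the maximum beta over its (m-1)-subsets.  alpha isolates the gain in
  association power that appears only when all m SNVs are considered
  together; for a single SNV the baseline is the purity of the whole
  cohort.

Because every (m-1)-subset beta is shared by many m-tuples, an
exhaustive alpha scan first fills a dense cache of all lower-order
betas.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .counting import ContingencyTable, combine_bytes, _histogram_column
from .genotype_io import EncodedCohort

#: slack for floating-point violations of beta monotonicity; anything
#: more negative signals a counting bug and raises
ALPHA_CLAMP_TOL = 1e-12


class StatsError(ValueError):
    """Invalid statistic input or internal inconsistency."""


@dataclass(frozen=True)
class AssociationResult:
    """beta and alpha for one SNV tuple (indices in matrix column order)."""

    snv_tuple: tuple[int, ...]
    beta: float
    alpha: float

    @property
    def order(self) -> int:
        return len(self.snv_tuple)


def purity(x: float, y: float) -> float:
    """Gini-based purity (x^2 + y^2) / (x + y)^2 of a set with x cases
    and y controls; 0.5 = maximally mixed, 1 = single-cohort.  The
    empty set returns 0 (it carries zero weight in beta)."""
    if x < 0 or y < 0:
        raise StatsError(f"negative count: ({x}, {y})")
    total = x + y
    if total == 0:
        return 0.0
    return (x * x + y * y) / (total * total)


def beta_from_counts(case_counts: np.ndarray, control_counts: np.ndarray) -> float:
    """Weighted-mean purity over rows given the two count columns."""
    x = np.asarray(case_counts, dtype=np.float64)
    y = np.asarray(control_counts, dtype=np.float64)
    totals = x + y
    n = totals.sum()
    if n == 0:
        raise StatsError("empty cohort: all-zero contingency table")
    occupied = totals > 0
    t = totals[occupied]
    # weight (t/n) times purity (x^2+y^2)/t^2, rewritten via
    # (x^2+y^2)/t^2 = 1/2 + ((x-y)/t)^2 / 2 so that beta >= 1/2 holds
    # exactly even in floating point (sum of non-negative terms)
    d = (x[occupied] - y[occupied]) / t
    return min(1.0, 0.5 + 0.5 * float((t / n) @ (d * d)))


def beta_from_table(table: ContingencyTable) -> float:
    """Combined association power of a contingency table.

    Each row contributes weight * purity with weight (x_i + y_i)/n;
    empty rows contribute nothing.
    """
    return beta_from_counts(table.case_counts, table.control_counts)


def beta_zero(n_cases: int, n_controls: int) -> float:
    """Baseline beta: purity of the set holding all samples."""
    if n_cases + n_controls == 0:
        raise StatsError("empty phenotype")
    return purity(n_cases, n_controls)


def alpha_from_betas(beta_m: float, subset_betas: np.ndarray | list[float]) -> float:
    """Interaction effect size: beta_m minus the best (m-1)-subset beta.

    Only the immediate subsets are needed: their maximum dominates the
    beta of every smaller subset (beta is monotone under adding SNVs).
    For m = 1, ``subset_betas`` holds the single whole-cohort baseline.
    Tiny negative differences are floating-point noise and clamp to 0;
    larger ones indicate inconsistent inputs and raise.
    """
    subset_betas = np.asarray(subset_betas, dtype=np.float64)
    if subset_betas.size == 0:
        raise StatsError("at least one subset beta required")
    alpha = beta_m - float(subset_betas.max())
    if alpha < 0:
        if alpha < -ALPHA_CLAMP_TOL:
            raise StatsError(
                f"beta monotonicity violated by {alpha:.3e}: "
                "inconsistent contingency counts"
            )
        alpha = 0.0
    return alpha


class BetaCache:
    """Dense store of beta for every (m-1)-subset of SNVs.

    ``order`` 0 holds the single whole-cohort baseline; order k >= 1
    uses a k-dimensional array indexed by the sorted SNV tuple (cells
    off the sorted simplex stay NaN — memory-redundant but O(1) to
    read, which matters because each subset beta is read once per
    containing tuple).
    """

    def __init__(self, order: int, n_snvs: int):
        if order < 0:
            raise StatsError("cache order must be >= 0")
        self.order = order
        self.n_snvs = n_snvs
        if order == 0:
            self._store = np.full((), np.nan)
        else:
            self._store = np.full((n_snvs,) * order, np.nan)

    def put(self, snv_tuple: tuple[int, ...], beta: float) -> None:
        if len(snv_tuple) != self.order:
            raise StatsError(
                f"cache holds order-{self.order} tuples, got {snv_tuple}"
            )
        self._store[tuple(sorted(snv_tuple))] = beta

    def get(self, snv_tuple: tuple[int, ...]) -> float:
        if len(snv_tuple) != self.order:
            raise StatsError(
                f"cache holds order-{self.order} tuples, got {snv_tuple}"
            )
        value = float(self._store[tuple(sorted(snv_tuple))])
        if np.isnan(value):
            raise StatsError(f"beta not cached for tuple {snv_tuple}")
        return value

    def subset_betas(self, snv_tuple: tuple[int, ...]) -> np.ndarray:
        """Betas of all (order+1 choose order) immediate subsets of a tuple."""
        if self.order == 0:
            return np.array([float(self._store)])
        return np.array(
            [self.get(sub) for sub in combinations(sorted(snv_tuple), self.order)]
        )


def tuple_beta(
    case: EncodedCohort, control: EncodedCohort, snv_tuple: tuple[int, ...]
) -> float:
    """beta of one tuple via the combined-byte histogram (no table object).

    beta is invariant under tuple permutation, so the tuple is
    canonicalized to sorted order first: this makes the value
    bit-identical no matter how the caller orders the SNVs (a
    different slot assignment permutes rows and hence the float
    summation order).
    """
    snv_tuple = tuple(sorted(snv_tuple))
    m = len(snv_tuple)
    x = _histogram_column(combine_bytes(case, snv_tuple), m)
    y = _histogram_column(combine_bytes(control, snv_tuple), m)
    return beta_from_counts(x, y)


def build_beta_cache(
    case: EncodedCohort, control: EncodedCohort, order: int
) -> BetaCache:
    """Compute beta for every ``order``-tuple of SNVs once, up front."""
    if order > case.n_snvs:
        raise StatsError(
            f"cache order {order} exceeds the {case.n_snvs} available SNVs"
        )
    cache = BetaCache(order=order, n_snvs=case.n_snvs)
    if order == 0:
        cache._store = np.array(float(beta_zero(case.s, control.s)))
        return cache
    for snv_tuple in combinations(range(case.n_snvs), order):
        cache.put(snv_tuple, tuple_beta(case, control, snv_tuple))
    return cache


def tuple_statistics(
    case: EncodedCohort,
    control: EncodedCohort,
    snv_tuple: tuple[int, ...],
    lower_cache: BetaCache,
) -> AssociationResult:
    """beta and alpha for one tuple, using the (m-1)-order beta cache."""
    beta = tuple_beta(case, control, snv_tuple)
    alpha = alpha_from_betas(beta, lower_cache.subset_betas(snv_tuple))
    return AssociationResult(snv_tuple=tuple(snv_tuple), beta=beta, alpha=alpha)
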