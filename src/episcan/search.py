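"""Exhaustive enumeration of m-SNV tuples (m = 1..4) with ranked output.

Every tuple of each requested order is tested exactly once.  Work is
split into balanced index ranges over the combination space using the
combinatorial number system (colex unranking), so the result is
byte-identical for any worker count.  Output ordering is canonical:
chosen metric descending, ties broken by the lexicographic tuple of
SNV ids.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from math import comb

import pandas as pd

from .counting import MAX_ORDER
from .genotype_io import EncodedCohort
from .stats import (
    AssociationResult,
    BetaCache,
    build_beta_cache,
    tuple_statistics,
)


class SearchError(ValueError):
    """Invalid search configuration."""


def combination_count(n: int, m: int) -> int:
    """Number of m-SNV tuples among n SNVs: the binomial coefficient."""
    if m <= 0:
        raise SearchError(f"order must be positive, got {m}")
    if m > n:
        raise SearchError(f"order {m} exceeds {n} SNVs")
    return comb(n, m)


def unrank_colex(rank: int, m: int) -> tuple[int, ...]:
    """Tuple at position ``rank`` in colex order over m-combinations.

    Colex rank of (c_1 < ... < c_m) is sum_i C(c_i, i); the inverse is
    found greedily from the largest element down.  Any fixed bijection
    would do for partitioning — this one needs no knowledge of n.
    """
    out = []
    for i in range(m, 0, -1):
        c = i - 1
        while comb(c + 1, i) <= rank:
            c += 1
        out.append(c)
        rank -= comb(c, i)
    return tuple(reversed(out))


def partition_combinations(n: int, m: int, workers: int) -> list[range]:
    """Split [0, C(n, m)) into ``workers`` ranges of near-equal size.

    Sizes differ by at most one; empty trailing ranges are possible
    when workers exceeds the number of combinations.
    """
    if workers < 1:
        raise SearchError(f"workers must be >= 1, got {workers}")
    total = combination_count(n, m)
    base, extra = divmod(total, workers)
    ranges, start = [], 0
    for w in range(workers):
        size = base + (1 if w < extra else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


@dataclass(frozen=True)
class SearchConfig:
    """What to scan and how to rank/limit the output."""

    orders: tuple[int, ...] = (2,)
    metric: str = "alpha"  # "alpha" or "beta"
    top_k: int | None = None
    threshold: float | None = None
    workers: int = 1

    def __post_init__(self) -> None:
        if not self.orders:
            raise SearchError("at least one order required")
        if any(not 1 <= o <= MAX_ORDER for o in self.orders):
            raise SearchError(f"orders must be within 1..{MAX_ORDER}")
        if self.metric not in ("alpha", "beta"):
            raise SearchError(f"metric must be 'alpha' or 'beta', got {self.metric!r}")
        if self.workers < 1:
            raise SearchError("workers must be >= 1")


@dataclass(frozen=True)
class BestRecord:
    """Per-SNV best partner tuples: for each order, the tuple containing
    this SNV with the highest alpha."""

    snv: int
    best: dict[int, AssociationResult] = field(default_factory=dict)


def _metric_value(result: AssociationResult, metric: str) -> float:
    return result.alpha if metric == "alpha" else result.beta


def _sort_key(result: AssociationResult, metric: str, snv_ids: tuple[str, ...]):
    ids = tuple(snv_ids[i] for i in result.snv_tuple)
    return (-_metric_value(result, metric), ids)


def _scan_range(
    case: EncodedCohort,
    control: EncodedCohort,
    order: int,
    index_range: range,
    cache: BetaCache,
) -> list[AssociationResult]:
    return [
        tuple_statistics(case, control, unrank_colex(r, order), cache)
        for r in index_range
    ]


def exhaustive_search(
    case: EncodedCohort,
    control: EncodedCohort,
    config: SearchConfig,
    snv_ids: tuple[str, ...] | None = None,
) -> dict[int, list[AssociationResult]]:
    """Test every tuple of every requested order; return ranked results.

    For each order m the (m-1)-order beta cache is built first, so the
    alpha of each tuple costs one counting pass plus m cache reads.
    ``top_k``/``threshold`` limit the returned list after ranking.
    """
    n = case.n_snvs
    if control.n_snvs != n:
        raise SearchError("case and control cohorts disagree on SNV count")
    if max(config.orders) > n:
        raise SearchError(f"order {max(config.orders)} exceeds {n} SNVs")
    ids = snv_ids if snv_ids is not None else tuple(str(i) for i in range(n))
    results: dict[int, list[AssociationResult]] = {}
    for order in sorted(config.orders):
        cache = build_beta_cache(case, control, order - 1)
        ranges = partition_combinations(n, order, config.workers)
        if config.workers == 1:
            chunks = [_scan_range(case, control, order, ranges[0], cache)]
        else:
            with ThreadPoolExecutor(max_workers=config.workers) as pool:
                chunks = list(
                    pool.map(
                        lambda rg: _scan_range(case, control, order, rg, cache),
                        ranges,
                    )
                )
        flat = [res for chunk in chunks for res in chunk]
        flat.sort(key=lambda res: _sort_key(res, config.metric, ids))
        if config.threshold is not None:
            flat = [
                res for res in flat
                if _metric_value(res, config.metric) >= config.threshold
            ]
        if config.top_k is not None:
            flat = flat[: config.top_k]
        results[order] = flat
    return results


def best_mode(
    case: EncodedCohort,
    control: EncodedCohort,
    orders: tuple[int, ...] = (2, 3, 4),
    snv_ids: tuple[str, ...] | None = None,
) -> list[BestRecord]:
    """For every SNV, the tuple of each order containing it with the
    highest alpha (ties broken by lexicographic partner ids)."""
    if any(not 2 <= o <= MAX_ORDER for o in orders):
        raise SearchError("best mode covers orders 2..4")
    n = case.n_snvs
    ids = snv_ids if snv_ids is not None else tuple(str(i) for i in range(n))
    best: dict[int, dict[int, AssociationResult]] = {s: {} for s in range(n)}
    for order in sorted(orders):
        if order > n:
            raise SearchError(f"order {order} exceeds {n} SNVs")
        cache = build_beta_cache(case, control, order - 1)
        for rank in range(combination_count(n, order)):
            snv_tuple = unrank_colex(rank, order)
            res = tuple_statistics(case, control, snv_tuple, cache)
            for snv in snv_tuple:
                cur = best[snv].get(order)
                if cur is None or _sort_key(res, "alpha", ids) < _sort_key(
                    cur, "alpha", ids
                ):
                    best[snv][order] = res
    return [BestRecord(snv=s, best=best[s]) for s in range(n)]


def results_to_frame(
    results: list[AssociationResult], snv_ids: tuple[str, ...]
) -> pd.DataFrame:
    """Ranked results as a table: SNV_1..SNV_m, BETA, ALPHA."""
    if not results:
        return pd.DataFrame(columns=["BETA", "ALPHA"])
    m = results[0].order
    if any(r.order != m for r in results):
        raise SearchError("mixed orders in one result table")
    data = {
        f"SNV_{j + 1}": [snv_ids[r.snv_tuple[j]] for r in results]
        for j in range(m)
    }
    data["BETA"] = [r.beta for r in results]
    data["ALPHA"] = [r.alpha for r in results]
    return pd.DataFrame(data)


def best_to_frame(
    records: list[BestRecord], snv_ids: tuple[str, ...]
) -> pd.DataFrame:
    """Best-mode records as a table: SNV, ORDER, PARTNERS, ALPHA."""
    rows = []
    for rec in records:
        for order in sorted(rec.best):
            res = rec.best[order]
            partners = ",".join(
                snv_ids[i] for i in res.snv_tuple if i != rec.snv
            )
            rows.append(
                {
                    "SNV": snv_ids[rec.snv],
                    "ORDER": order,
                    "PARTNERS": partners,
                    "ALPHA": res.alpha,
                }
            )
    return pd.DataFrame(rows, columns=["SNV", "ORDER", "PARTNERS", "ALPHA"])
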