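"""Exhaustive tuple enumeration, ranking, best mode and partitioning."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from episcan.counting import count_naive
from episcan.genotype_io import GenotypeMatrix, encode_cohorts
from episcan.search import (
    SearchConfig,
    SearchError,
    best_mode,
    best_to_frame,
    combination_count,
    exhaustive_search,
    partition_combinations,
    results_to_frame,
    unrank_colex,
)
from episcan.simulate import simulate_dataset, xor_model
from episcan.stats import beta_from_table, build_beta_cache, tuple_statistics

from conftest import random_dataset


class TestCombinatorics:
    @pytest.mark.parametrize(
        "n,m,expected",
        [
            (1000, 2, 499_500),
            (1000, 3, 166_167_000),
            (1000, 4, 41_417_124_750),
            (100, 1, 100),
            (100, 2, 4950),
            (100, 3, 161_700),
        ],
    )
    def test_search_space_sizes(self, n, m, expected):
        assert combination_count(n, m) == expected

    def test_invalid_orders(self):
        with pytest.raises(SearchError):
            combination_count(3, 5)
        with pytest.raises(SearchError):
            combination_count(3, 0)

    @pytest.mark.parametrize("n,m", [(6, 2), (7, 3), (6, 4)])
    def test_unrank_is_a_bijection(self, n, m):
        seen = [unrank_colex(r, m) for r in range(comb(n, m))]
        assert sorted(seen) == sorted(combinations(range(n), m))
        # colex order: sorted by reversed tuple
        assert seen == sorted(seen, key=lambda t: t[::-1])


class TestPartitioning:
    def test_balanced_split(self):
        ranges = partition_combinations(5, 2, 3)  # C=10 -> 4,3,3
        assert [len(r) for r in ranges] == [4, 3, 3]
        assert ranges[0].start == 0 and ranges[-1].stop == 10

    def test_single_worker_identity(self):
        (rg,) = partition_combinations(6, 3, 1)
        assert rg == range(0, 20)

    def test_union_covers_everything(self):
        ranges = partition_combinations(30, 3, 7)
        flat = [i for rg in ranges for i in rg]
        assert flat == list(range(comb(30, 3)))


class TestExhaustiveSearch:
    def test_top_k_contract(self, rng):
        matrix, pheno = random_dataset(rng, 100, 10)
        case, control = encode_cohorts(matrix, pheno)
        res = exhaustive_search(
            case, control, SearchConfig(orders=(2,), top_k=3), matrix.snv_ids
        )[2]
        assert len(res) == 3
        assert res[0].alpha >= res[1].alpha >= res[2].alpha

    def test_completeness_and_order1_oracle(self, rng):
        matrix, pheno = random_dataset(rng, 150, 8)
        case, control = encode_cohorts(matrix, pheno)
        out = exhaustive_search(
            case, control, SearchConfig(orders=(1, 2)), matrix.snv_ids
        )
        assert len(out[1]) == 8 and len(out[2]) == comb(8, 2)
        by_snv = {r.snv_tuple[0]: r.beta for r in out[1]}
        for snv in range(8):
            expected = beta_from_table(count_naive(matrix, pheno, (snv,)))
            assert by_snv[snv] == pytest.approx(expected)

    def test_planted_pair_ranked_first(self):
        ds = simulate_dataset(
            xor_model(), n_cases=1000, n_controls=1000, n_snvs=20, seed=5
        )
        case, control = encode_cohorts(ds.matrix, ds.phenotype)
        res = exhaustive_search(
            case, control, SearchConfig(orders=(2,), top_k=1), ds.matrix.snv_ids
        )[2]
        assert tuple(sorted(res[0].snv_tuple)) == ds.truth[0]

    def test_worker_count_invariance(self, rng):
        matrix, pheno = random_dataset(rng, 80, 9)
        case, control = encode_cohorts(matrix, pheno)
        outputs = []
        for workers in (1, 2, 8):
            res = exhaustive_search(
                case, control,
                SearchConfig(orders=(3,), workers=workers),
                matrix.snv_ids,
            )[3]
            outputs.append(
                results_to_frame(res, matrix.snv_ids).to_csv(sep="\t")
            )
        assert outputs[0] == outputs[1] == outputs[2]

    def test_rank_stability_under_column_permutation(self, rng):
        matrix, pheno = random_dataset(rng, 90, 6)
        perm = rng.permutation(6)
        shuffled = GenotypeMatrix(
            snv_ids=tuple(matrix.snv_ids[i] for i in perm),
            genotypes=matrix.genotypes[:, perm],
        )
        def result_set(mat):
            case, control = encode_cohorts(mat, pheno)
            res = exhaustive_search(
                case, control, SearchConfig(orders=(2,)), mat.snv_ids
            )[2]
            return {
                (tuple(sorted(mat.snv_ids[i] for i in r.snv_tuple)),
                 round(r.beta, 12), round(r.alpha, 12))
                for r in res
            }
        assert result_set(matrix) == result_set(shuffled)

    def test_threshold_filter(self, rng):
        matrix, pheno = random_dataset(rng, 100, 6)
        case, control = encode_cohorts(matrix, pheno)
        config = SearchConfig(orders=(2,), metric="beta", threshold=0.51)
        res = exhaustive_search(case, control, config, matrix.snv_ids)[2]
        assert all(r.beta >= 0.51 for r in res)

    def test_config_validation(self):
        with pytest.raises(SearchError):
            SearchConfig(orders=())
        with pytest.raises(SearchError):
            SearchConfig(orders=(5,))
        with pytest.raises(SearchError):
            SearchConfig(orders=(2,), metric="gamma")


class TestBestMode:
    def test_matches_brute_force(self, rng):
        matrix, pheno = random_dataset(rng, 120, 5)
        case, control = encode_cohorts(matrix, pheno)
        records = best_mode(case, control, orders=(2,), snv_ids=matrix.snv_ids)
        cache = build_beta_cache(case, control, 1)
        for rec in records:
            best = max(
                (
                    tuple_statistics(case, control, tuple(sorted((rec.snv, o))), cache)
                    for o in range(5) if o != rec.snv
                ),
                key=lambda r: r.alpha,
            )
            assert rec.best[2].alpha == pytest.approx(best.alpha)

    def test_dominating_pair_shared(self):
        ds = simulate_dataset(
            xor_model(), n_cases=600, n_controls=600, n_snvs=5, seed=7
        )
        case, control = encode_cohorts(ds.matrix, ds.phenotype)
        records = best_mode(case, control, orders=(2,), snv_ids=ds.matrix.snv_ids)
        i, j = ds.truth[0]
        assert tuple(sorted(records[i].best[2].snv_tuple)) == ds.truth[0]
        assert tuple(sorted(records[j].best[2].snv_tuple)) == ds.truth[0]

    def test_constant_snvs_give_zero_alpha(self):
        geno = np.zeros((40, 3), dtype=np.uint8)
        matrix = GenotypeMatrix(snv_ids=("a", "b", "c"), genotypes=geno)
        pheno = np.array([1] * 20 + [0] * 20, dtype=np.uint8)
        from episcan.genotype_io import PhenotypeVector

        case, control = encode_cohorts(matrix, PhenotypeVector(labels=pheno))
        records = best_mode(case, control, orders=(2,), snv_ids=matrix.snv_ids)
        assert all(rec.best[2].alpha == 0.0 for rec in records)

    def test_frame_layout(self, rng):
        matrix, pheno = random_dataset(rng, 60, 4)
        case, control = encode_cohorts(matrix, pheno)
        records = best_mode(case, control, orders=(2, 3), snv_ids=matrix.snv_ids)
        frame = best_to_frame(records, matrix.snv_ids)
        assert list(frame.columns) == ["SNV", "ORDER", "PARTNERS", "ALPHA"]
        assert len(frame) == 8  # 4 SNVs x 2 orders
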