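"""Penetrance-model simulation, fixtures and detection power."""

import numpy as np
import pytest
from scipy import stats as sps

from episcan.counting import count_1vector
from episcan.genotype_io import encode_cohorts, read_genotype_table, write_genotype_table
from episcan.search import SearchConfig, exhaustive_search
from episcan.simulate import (
    PenetranceModel,
    SimulationError,
    detection_power,
    flat_model,
    hwe_probabilities,
    make_e123_dataset,
    marginal_model,
    parity3_model,
    simulate_dataset,
    table1_fixture,
    threshold_model,
    xor_model,
)
from episcan.stats import build_beta_cache, tuple_statistics


class TestModels:
    def test_validation(self):
        with pytest.raises(SimulationError, match="MAF"):
            PenetranceModel(m=1, mafs=(0.7,), penetrance=np.full(3, 0.5))
        with pytest.raises(SimulationError, match="3\\^2"):
            PenetranceModel(m=2, mafs=(0.1, 0.1), penetrance=np.full(3, 0.5))
        with pytest.raises(SimulationError, match="\\[0, 1\\]"):
            PenetranceModel(m=1, mafs=(0.1,), penetrance=np.array([0, 0.5, 1.2]))

    def test_xor_has_no_marginal_penetrance(self):
        model = xor_model(maf=0.5)
        pen = model.penetrance.reshape(3, 3)  # [g2, g1] little-endian
        hwe = hwe_probabilities(0.5)
        marg1 = pen.T @ hwe
        marg2 = pen @ hwe
        assert np.allclose(marg1, 0.5) and np.allclose(marg2, 0.5)

    def test_parity3_has_no_pairwise_penetrance(self):
        pen = parity3_model(maf=0.5).penetrance.reshape(3, 3, 3)
        hwe = hwe_probabilities(0.5)
        # marginalising out any one SNV leaves a flat table
        for axis in range(3):
            assert np.allclose(np.tensordot(pen, hwe, axes=([axis], [0])), 0.5)

    def test_json_round_trip(self, tmp_path):
        model = threshold_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PenetranceModel.from_json(path)
        assert back.m == model.m and back.mafs == model.mafs
        assert np.array_equal(back.penetrance, model.penetrance)


class TestSimulateDataset:
    def test_exact_cohort_sizes_and_truth(self):
        ds = simulate_dataset(
            xor_model(), n_cases=120, n_controls=80, n_snvs=12, seed=3
        )
        assert ds.phenotype.n_cases == 120
        assert ds.phenotype.n_controls == 80
        assert ds.matrix.n_snvs == 12
        (pair,) = ds.truth
        assert len(pair) == 2 and all(0 <= i < 12 for i in pair)

    def test_seeded_determinism(self):
        a = simulate_dataset(xor_model(), 50, 50, 8, seed=77)
        b = simulate_dataset(xor_model(), 50, 50, 8, seed=77)
        assert np.array_equal(a.matrix.genotypes, b.matrix.genotypes)
        assert np.array_equal(a.phenotype.labels, b.phenotype.labels)
        assert a.truth == b.truth

    def test_unattainable_cases_error(self):
        zero = PenetranceModel(
            m=1, mafs=(0.3,), penetrance=np.zeros(3), label="zero"
        )
        with pytest.raises(SimulationError, match="rejection sampling"):
            simulate_dataset(zero, n_cases=10, n_controls=10, n_snvs=3, seed=1)

    def test_hwe_at_noise_snvs(self):
        ds = simulate_dataset(
            flat_model(), n_cases=2000, n_controls=2000, n_snvs=6, seed=13,
            noise_maf_range=(0.3, 0.3),
        )
        noise = [i for i in range(6) if i not in ds.truth[0]]
        expected = hwe_probabilities(0.3)
        for snv in noise:
            observed = np.bincount(ds.matrix.genotypes[:, snv], minlength=3)
            assert sps.chisquare(observed, expected * 4000).pvalue > 1e-4

    def test_flat_penetrance_truth_blends_in(self):
        """Under a flat model the planted pair's alpha is statistically
        indistinguishable from a noise pair's."""
        planted, noise = [], []
        for seed in range(30):
            ds = simulate_dataset(flat_model(), 100, 100, 6, seed=seed)
            case, control = encode_cohorts(ds.matrix, ds.phenotype)
            cache = build_beta_cache(case, control, 1)
            planted.append(
                tuple_statistics(case, control, ds.truth[0], cache).alpha
            )
            noise_pair = tuple(sorted(set(range(6)) - set(ds.truth[0]))[:2])
            noise.append(
                tuple_statistics(case, control, noise_pair, cache).alpha
            )
        assert sps.mannwhitneyu(planted, noise).pvalue > 0.01


class TestDetectionPower:
    def test_fully_penetrant_model(self):
        power = detection_power(
            [xor_model()], n_datasets=5, n_cases=300, n_controls=300,
            n_snvs=20, seed=5,
        )
        assert power["xor(maf=0.5)"] == 1.0

    def test_power_monotone_in_sample_size(self):
        model = xor_model(high=0.62, low=0.38)
        powers = [
            detection_power(
                [model], n_datasets=12, n_cases=n // 2, n_controls=n // 2,
                n_snvs=30, seed=17,
            )[model.label]
            for n in (200, 1000, 2000)
        ]
        assert powers[2] >= powers[0]
        assert powers[2] > 0.5
        assert powers[1] >= powers[0] - 0.1


class TestTable1Fixture:
    def test_documented_cell_and_sums(self):
        matrix, pheno = table1_fixture()
        case, control = encode_cohorts(matrix, pheno)
        table = count_1vector(case, control, (0, 1))
        assert table.cell((1, 1)) == (34, 46)
        assert pheno.n_cases == 34 + 8 * 10 == 114
        assert pheno.n_controls == 46 + 8 * 10 == 126

    def test_round_trips_through_table_io(self, tmp_path):
        matrix, pheno = table1_fixture()
        path = tmp_path / "fixture.tsv"
        write_genotype_table(path, matrix, pheno)
        back_m, back_p = read_genotype_table(path)
        assert np.array_equal(back_m.genotypes, matrix.genotypes)
        assert np.array_equal(back_p.labels, pheno.labels)


class TestE123:
    def test_each_truth_tops_its_order(self):
        ds = make_e123_dataset(
            n_snvs=50, n_cases=600, n_controls=600, seed=29
        )
        case, control = encode_cohorts(ds.matrix, ds.phenotype)
        out = exhaustive_search(
            case, control,
            SearchConfig(orders=(1, 2, 3), top_k=1),
            ds.matrix.snv_ids,
        )
        single, pair, triplet = ds.truth
        assert out[1][0].snv_tuple == single
        assert tuple(sorted(out[2][0].snv_tuple)) == pair
        assert tuple(sorted(out[3][0].snv_tuple)) == triplet

    def test_determinism(self):
        a = make_e123_dataset(n_snvs=20, n_cases=50, n_controls=50, seed=4)
        b = make_e123_dataset(n_snvs=20, n_cases=50, n_controls=50, seed=4)
        assert np.array_equal(a.matrix.genotypes, b.matrix.genotypes)
        assert a.truth == b.truth
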