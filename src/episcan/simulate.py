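"""Penetrance-model simulation of case/control genotype data.

Simulated datasets plant a known m-SNV interaction among noise SNVs so
that detection power (how often an exhaustive scan ranks the planted
tuple first) can be measured against ground truth:

* truth-SNV genotypes are drawn per locus under Hardy-Weinberg
  equilibrium from the model's minor-allele frequencies;
* disease status is Bernoulli with probability given by the model's
  penetrance table entry for the sample's genotype combination;
* sampling is rejected/continued until the requested numbers of cases
  and controls are reached exactly;
* noise SNVs are Hardy-Weinberg draws independent of the phenotype,
  and the truth columns are placed at seeded random positions.

The built-in model library covers the canonical simulation regimes:
strict-and-pure interactions with no marginal effects (2-SNV XOR,
3-SNV parity), a threshold model with marginal effects, a purely
marginal single-SNV model, and a flat (null) model.  A deterministic
two-SNV fixture with a documented contingency table is also provided
for exact counting checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .counting import decode_row
from .genotype_io import GenotypeMatrix, PhenotypeVector

#: rejection-sampling cap: give up after drawing this many times the
#: requested number of samples
REJECTION_CAP_FACTOR = 100


class SimulationError(ValueError):
    """Unattainable simulation request."""


@dataclass(frozen=True)
class PenetranceModel:
    """m interacting SNVs: MAFs plus a 3^m disease-probability table.

    ``penetrance[r]`` is P(case | genotype combination r) with r the
    little-endian base-3 encoding of the m genotypes.
    """

    m: int
    mafs: tuple[float, ...]
    penetrance: np.ndarray  # (3**m,) floats in [0, 1]
    label: str = ""

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=np.float64)
        if len(self.mafs) != self.m:
            raise SimulationError(f"need {self.m} MAFs, got {len(self.mafs)}")
        if any(not 0 < f <= 0.5 for f in self.mafs):
            raise SimulationError("MAFs must lie in (0, 0.5]")
        if pen.shape != (3 ** self.m,):
            raise SimulationError(
                f"penetrance table must have 3^{self.m} = {3 ** self.m} entries"
            )
        if (pen < 0).any() or (pen > 1).any():
            raise SimulationError("penetrance values must lie in [0, 1]")
        object.__setattr__(self, "penetrance", pen)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "label": self.label,
                    "mafs": list(self.mafs),
                    "penetrance": self.penetrance.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PenetranceModel":
        spec = json.loads(Path(path).read_text())
        mafs = tuple(float(f) for f in spec["mafs"])
        return cls(
            m=len(mafs),
            mafs=mafs,
            penetrance=np.asarray(spec["penetrance"], dtype=np.float64),
            label=str(spec.get("label", Path(path).stem)),
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """Genotypes + phenotype + the planted truth tuples (SNV indices)."""

    matrix: GenotypeMatrix
    phenotype: PhenotypeVector
    truth: tuple[tuple[int, ...], ...]
    seed: int = 0


# ---------------------------------------------------------------------------
# model library
# ---------------------------------------------------------------------------

def xor_model(
    maf: float = 0.5, high: float = 1.0, low: float = 0.0
) -> PenetranceModel:
    """Strict-and-pure 2-SNV interaction: penetrance ``high`` where the
    two genotype codes have odd sum, ``low`` elsewhere.  At MAF 0.5
    every marginal penetrance is (high+low)/2, so neither SNV alone
    carries any association."""
    pen = np.array(
        [high if sum(decode_row(r, 2)) % 2 else low for r in range(9)]
    )
    return PenetranceModel(
        m=2, mafs=(maf, maf), penetrance=pen, label=f"xor(maf={maf})"
    )


def parity3_model(
    maf: float = 0.5, high: float = 1.0, low: float = 0.0
) -> PenetranceModel:
    """Strict-and-pure 3-SNV interaction: penetrance depends only on
    the parity of the summed genotype codes; no single SNV or pair is
    informative at MAF 0.5."""
    pen = np.array(
        [high if sum(decode_row(r, 3)) % 2 else low for r in range(27)]
    )
    return PenetranceModel(
        m=3, mafs=(maf,) * 3, penetrance=pen, label=f"parity3(maf={maf})"
    )


def threshold_model(
    maf: float = 0.3, high: float = 0.8, low: float = 0.1
) -> PenetranceModel:
    """2-SNV model with marginal effects: elevated risk whenever both
    SNVs carry at least one alternate allele."""
    pen = np.array(
        [
            high if min(decode_row(r, 2)) >= 1 else low
            for r in range(9)
        ]
    )
    return PenetranceModel(
        m=2, mafs=(maf, maf), penetrance=pen, label=f"threshold(maf={maf})"
    )


def marginal_model(
    maf: float = 0.3, base: float = 0.1, slope: float = 0.3
) -> PenetranceModel:
    """Single-SNV additive risk: penetrance base + slope * genotype code."""
    pen = np.clip(base + slope * np.arange(3), 0.0, 1.0)
    return PenetranceModel(
        m=1, mafs=(maf,), penetrance=pen, label=f"marginal(maf={maf})"
    )


def flat_model(m: int = 2, maf: float = 0.5, rate: float = 0.5) -> PenetranceModel:
    """Null model: constant penetrance, no genotype-phenotype link."""
    return PenetranceModel(
        m=m,
        mafs=(maf,) * m,
        penetrance=np.full(3 ** m, rate),
        label=f"flat(m={m})",
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def hwe_probabilities(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-f)^2, 2f(1-f), f^2)."""
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf * maf])


def _draw_hwe(rng: np.random.Generator, mafs, size: int) -> np.ndarray:
    """(size, len(mafs)) genotype codes drawn independently per locus."""
    cols = [
        rng.choice(3, size=size, p=hwe_probabilities(f)) for f in mafs
    ]
    return np.stack(cols, axis=1).astype(np.uint8)


def _sample_truth_block(
    rng: np.random.Generator,
    mafs: tuple[float, ...],
    case_probability,
    n_cases: int,
    n_controls: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample truth genotypes to exact cohort sizes.

    ``case_probability`` maps a (batch, t) genotype block to per-sample
    disease probabilities.  Returns (genotypes, labels) with cases
    first, then controls, each cohort in draw order.
    """
    n_total = n_cases + n_controls
    batch = max(n_total, 256)
    got_case: list[np.ndarray] = []
    got_ctrl: list[np.ndarray] = []
    need_case, need_ctrl = n_cases, n_controls
    drawn = 0
    while need_case > 0 or need_ctrl > 0:
        if drawn > REJECTION_CAP_FACTOR * n_total:
            raise SimulationError(
                "rejection sampling exhausted: the penetrance model cannot "
                f"produce {n_cases} cases and {n_controls} controls "
                f"within {REJECTION_CAP_FACTOR}x oversampling"
            )
        geno = _draw_hwe(rng, mafs, batch)
        drawn += batch
        p = np.asarray(case_probability(geno), dtype=np.float64)
        is_case = rng.random(batch) < p
        if need_case > 0:
            got_case.append(geno[is_case][:need_case])
            need_case -= got_case[-1].shape[0]
        if need_ctrl > 0:
            got_ctrl.append(geno[~is_case][:need_ctrl])
            need_ctrl -= got_ctrl[-1].shape[0]
    geno = np.concatenate(got_case + got_ctrl)
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.uint8), np.zeros(n_controls, dtype=np.uint8)]
    )
    return geno, labels


def _assemble(
    rng: np.random.Generator,
    truth_geno: np.ndarray,
    labels: np.ndarray,
    truth_groups: tuple[tuple[int, ...], ...],
    n_snvs: int,
    noise_maf_range: tuple[float, float],
    seed: int,
) -> SimulatedDataset:
    """Scatter truth columns among noise columns and shuffle samples."""
    n_total = truth_geno.shape[0]
    t = truth_geno.shape[1]
    if n_snvs < t:
        raise SimulationError(f"n_snvs={n_snvs} < {t} truth SNVs")
    lo, hi = noise_maf_range
    noise_mafs = rng.uniform(lo, hi, size=n_snvs - t)
    noise = _draw_hwe(rng, noise_mafs, n_total)
    positions = rng.choice(n_snvs, size=t, replace=False)
    geno = np.empty((n_total, n_snvs), dtype=np.uint8)
    noise_positions = np.setdiff1d(np.arange(n_snvs), positions)
    geno[:, positions] = truth_geno
    geno[:, noise_positions] = noise
    order = rng.permutation(n_total)
    geno = geno[order]
    labels = labels[order]
    truth = tuple(
        tuple(sorted(int(positions[i]) for i in group)) for group in truth_groups
    )
    matrix = GenotypeMatrix(
        snv_ids=tuple(f"snv{i}" for i in range(n_snvs)),
        genotypes=geno,
        sample_ids=tuple(f"S{i}" for i in range(n_total)),
    )
    return SimulatedDataset(
        matrix=matrix,
        phenotype=PhenotypeVector(labels=labels),
        truth=truth,
        seed=seed,
    )


def simulate_dataset(
    model: PenetranceModel,
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_snvs: int = 100,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> SimulatedDataset:
    """One case/control dataset with the model's interaction planted.

    Defaults mirror the standard detection-power protocol: 100 SNVs,
    1000 cases and 1000 controls per dataset.
    """
    rng = np.random.default_rng(seed)
    truth_geno, labels = _sample_truth_block(
        rng,
        model.mafs,
        lambda g: model.penetrance[
            (g.astype(np.int64) @ (3 ** np.arange(model.m)))
        ],
        n_cases,
        n_controls,
    )
    return _assemble(
        rng,
        truth_geno,
        labels,
        (tuple(range(model.m)),),
        n_snvs,
        noise_maf_range,
        seed,
    )


def detection_power(
    models,
    n_datasets: int = 100,
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_snvs: int = 100,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    metric: str = "alpha",
    seed: int = 0,
) -> dict[str, float]:
    """Detection power per model: the fraction of replicate datasets in
    which the planted tuple attains rank 1 at its order (anything
    ranked above the truth counts as a false positive)."""
    from .genotype_io import encode_cohorts
    from .search import SearchConfig, exhaustive_search

    rng = np.random.default_rng(seed)
    powers: dict[str, float] = {}
    for model in models:
        hits = 0
        for _ in range(n_datasets):
            ds_seed = int(rng.integers(0, 2 ** 31 - 1))
            ds = simulate_dataset(
                model, n_cases, n_controls, n_snvs, noise_maf_range, ds_seed
            )
            case, control = encode_cohorts(ds.matrix, ds.phenotype)
            top = exhaustive_search(
                case,
                control,
                SearchConfig(orders=(model.m,), metric=metric, top_k=1),
                ds.matrix.snv_ids,
            )[model.m]
            if top and tuple(sorted(top[0].snv_tuple)) == ds.truth[0]:
                hits += 1
        powers[model.label] = hits / n_datasets
    return powers


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

#: (case, control) filler counts for the 8 non-heterozygous/heterozygous
#: cells of the two-SNV fixture
_FIXTURE_FILLER = (10, 10)
#: the documented double-heterozygote cell of the fixture
_FIXTURE_HET_HET = (34, 46)


def table1_fixture() -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Deterministic two-SNV dataset with a fully documented 9 x 2
    contingency table.

    SNVs are named A and B.  Exactly 34 cases and 46 controls are
    heterozygous at both SNVs; every other genotype combination holds
    10 cases and 10 controls, giving 114 cases and 126 controls in
    total.  Construction is fixed (cells in row order, cases before
    controls) so byte-level counting paths can be checked exactly.
    """
    geno_rows: list[tuple[int, int]] = []
    labels: list[int] = []
    for row in range(9):
        g = decode_row(row, 2)
        n_case, n_ctrl = (
            _FIXTURE_HET_HET if g == (1, 1) else _FIXTURE_FILLER
        )
        geno_rows.extend([g] * (n_case + n_ctrl))
        labels.extend([1] * n_case + [0] * n_ctrl)
    matrix = GenotypeMatrix(
        snv_ids=("A", "B"),
        genotypes=np.array(geno_rows, dtype=np.uint8),
        sample_ids=tuple(f"S{i}" for i in range(len(labels))),
    )
    return matrix, PhenotypeVector(labels=np.array(labels, dtype=np.uint8))


def make_e123_dataset(
    n_snvs: int = 100,
    n_cases: int = 1000,
    n_controls: int = 1000,
    effect_single: float = 0.25,
    effect_pair: float = 0.5,
    effect_triplet: float = 0.5,
    base_rate: float = 0.1,
    maf: float = 0.5,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> SimulatedDataset:
    """Multi-truth dataset: the phenotype combines a marginal effect at
    one SNV (A), a pure pairwise interaction (B-C, XOR-type) and a pure
    triplet interaction (D-E-F, parity-type).

    P(case) = base + effect_single * g_A / 2
            + effect_pair * parity(g_B + g_C)
            + effect_triplet * parity(g_D + g_E + g_F), clipped to [0, 1].

    ``truth`` lists the three planted tuples in that order.
    """

    def prob(geno: np.ndarray) -> np.ndarray:
        g = geno.astype(np.float64)
        p = (
            base_rate
            + effect_single * g[:, 0] / 2.0
            + effect_pair * ((g[:, 1] + g[:, 2]) % 2)
            + effect_triplet * ((g[:, 3] + g[:, 4] + g[:, 5]) % 2)
        )
        return np.clip(p, 0.0, 1.0)

    rng = np.random.default_rng(seed)
    truth_geno, labels = _sample_truth_block(
        rng, (maf,) * 6, prob, n_cases, n_controls
    )
    return _assemble(
        rng,
        truth_geno,
        labels,
        ((0,), (1, 2), (3, 4, 5)),
        n_snvs,
        noise_maf_range,
        seed,
    )
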