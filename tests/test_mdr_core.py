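"""MDR statistic: binarisation, cell tables, risk pooling, chi-square, CV."""

import numpy as np
import pytest
from scipy import stats

from episcan import mdr_core, simdata
from episcan.mdr_core import (
    HIGH,
    LOW,
    EMPTY,
    DegeneratePhenotypeError,
    RiskAssignment,
    SampleSizeError,
    TwoLocusTable,
    binarize_phenotype,
    build_two_locus_table,
    classify_cells,
    cv_mean_chi_square,
    pooled_chi_square,
)
from episcan.pairscan import _chunk_chi_square


def pheno_of(values):
    return simdata.PhenotypeSet("E", {f"L{i}": v for i, v in enumerate(values)})


def table_of(cells):
    cases = np.zeros((3, 3), dtype=np.int64)
    controls = np.zeros((3, 3), dtype=np.int64)
    for (a, b), (nc, nn) in cells.items():
        cases[a, b], controls[a, b] = nc, nn
    return TwoLocusTable(cases, controls)


class TestBinarize:
    def test_median_split_one_to_ten(self):
        labels = binarize_phenotype(pheno_of(range(1, 11)))
        assert labels.n_case == 5 and labels.n_control == 5

    def test_ties_at_median_go_to_control(self):
        labels = binarize_phenotype(pheno_of([1, 1, 1, 2]))
        assert labels.n_case == 1 and labels.n_control == 3

    def test_all_identical_rejected(self):
        with pytest.raises(DegeneratePhenotypeError):
            binarize_phenotype(pheno_of([20.0] * 6))

    def test_too_few_values_rejected(self):
        with pytest.raises(SampleSizeError):
            binarize_phenotype(pheno_of([1, 2, 3]))

    def test_location_shift_invariance(self):
        vals = [1.0, 4.0, 2.5, 3.0, 9.0, 0.5]
        a = binarize_phenotype(pheno_of(vals))
        b = binarize_phenotype(pheno_of([v + 123.4 for v in vals]))
        assert a.is_case == b.is_case

    def test_mean_rule(self):
        labels = binarize_phenotype(pheno_of([0, 0, 0, 4]), rule="mean")  # mean 1
        assert labels.n_case == 1 and labels.n_control == 3


class TestTwoLocusTable:
    def make_pop(self, genotypes):
        n = len(genotypes)
        return simdata.RILPopulation(
            tuple(f"L{i}" for i in range(n)), ("ma", "mb"), np.array(genotypes, dtype=np.int8)
        )

    def test_direct_tally(self):
        pop = self.make_pop([(0, 0), (0, 2), (2, 0), (2, 2)])
        labels = mdr_core.BinaryPhenotype(
            {"L0": True, "L1": False, "L2": False, "L3": True}
        )
        t = build_two_locus_table(pop, "ma", "mb", labels)
        assert t.cases[0, 0] == 1 and t.controls[0, 2] == 1
        assert t.controls[2, 0] == 1 and t.cases[2, 2] == 1
        assert t.excluded == 0

    def test_conservation_and_missing(self):
        pop = self.make_pop([(0, 0), (-1, 2), (2, 0), (2, 2), (1, 1)])
        labels = mdr_core.BinaryPhenotype({f"L{i}": i % 2 == 0 for i in range(5)})
        t = build_two_locus_table(pop, "ma", "mb", labels)
        assert t.excluded == 1
        assert t.totals.sum() + t.excluded == 5
        assert t.cases[1, 1] == 1  # heterozygous cell is a real cell

    def test_same_marker_rejected(self):
        pop = self.make_pop([(0, 0), (2, 2)])
        with pytest.raises(ValueError):
            build_two_locus_table(pop, "ma", "ma", mdr_core.BinaryPhenotype({"L0": True, "L1": False}))


class TestClassify:
    def test_ratio_comparison(self):
        t = table_of({(0, 0): (10, 2), (2, 2): (2, 10)})  # T = 1
        risk = classify_cells(t)
        assert risk.status[0, 0] == HIGH
        assert risk.status[2, 2] == LOW
        assert risk.status[1, 1] == EMPTY
        assert risk.threshold == 1.0

    def test_case_only_cell_is_high(self):
        t = table_of({(0, 0): (5, 0), (2, 2): (3, 7)})
        assert classify_cells(t).status[0, 0] == HIGH

    def test_boundary_ratio_goes_high(self):
        t = table_of({(0, 0): (4, 2), (0, 2): (2, 1), (2, 2): (6, 3)})  # all ratios == T
        risk = classify_cells(t)
        occupied = t.totals > 0
        assert (risk.status[occupied] == HIGH).all()

    def test_empty_table_rejected(self):
        with pytest.raises(mdr_core.EmptyTableError):
            classify_cells(table_of({}))


class TestPooledChiSquare:
    def test_strong_association(self):
        t = table_of({(0, 0): (30, 10), (2, 2): (10, 30)})
        stat = pooled_chi_square(t, classify_cells(t))
        assert stat.chi_square == pytest.approx(20.0)
        assert stat.p_value == pytest.approx(7.744e-6, rel=1e-3)

    def test_independence_gives_zero(self):
        t = table_of({(0, 0): (10, 10), (2, 2): (10, 10)})
        stat = pooled_chi_square(t, classify_cells(t))
        assert stat.chi_square == pytest.approx(0.0)
        assert stat.p_value == 1.0

    def test_zero_margin_undefined(self):
        # every cell high -> low margin empty
        t = table_of({(0, 0): (10, 1), (2, 2): (20, 2)})
        stat = pooled_chi_square(t, classify_cells(t))
        assert not stat.defined and stat.p_value == 1.0

    def test_closed_form_matches_observed_expected_sum(self):
        """n(ad-bc)^2/margins == four-term sum of (O-E)^2/E on random tables."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            cells = {
                (a, b): (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                for a in (0, 2)
                for b in (0, 2)
            }
            t = table_of(cells)
            try:
                risk = classify_cells(t)
            except (mdr_core.EmptyTableError, mdr_core.ZeroMarginError):
                continue
            stat = pooled_chi_square(t, risk)
            pooled = mdr_core.pool_counts(t, risk)
            if pooled.sum(axis=0).min() == 0 or pooled.sum(axis=1).min() == 0:
                assert not stat.defined
                continue
            expected = np.outer(pooled.sum(axis=1), pooled.sum(axis=0)) / pooled.sum()
            oe = ((pooled - expected) ** 2 / expected).sum()
            assert stat.chi_square == pytest.approx(oe, abs=1e-8)
            # and against scipy's uncorrected 2x2 test
            chi_sp, p_sp = stats.chi2_contingency(pooled, correction=False)[:2]
            assert stat.chi_square == pytest.approx(chi_sp, abs=1e-8)
            assert stat.p_value == pytest.approx(p_sp, abs=1e-10)

    def test_marker_swap_symmetry(self, pop147, noise_pheno):
        labels = binarize_phenotype(noise_pheno)
        ma, mb = pop147.marker_ids[1], pop147.marker_ids[6]
        t_ab = build_two_locus_table(pop147, ma, mb, labels)
        t_ba = build_two_locus_table(pop147, mb, ma, labels)
        s_ab = pooled_chi_square(t_ab, classify_cells(t_ab))
        s_ba = pooled_chi_square(t_ba, classify_cells(t_ba))
        assert s_ab.chi_square == pytest.approx(s_ba.chi_square, abs=1e-12)


class TestCrossValidation:
    def xor_setup(self, n=100):
        rng = np.random.default_rng(1)
        geno = rng.choice(np.array([0, 2], dtype=np.int8), size=(n, 2))
        pop = simdata.RILPopulation(
            tuple(f"L{i}" for i in range(n)), ("ma", "mb"), geno
        )
        is_case = {
            l: bool(geno[i, 0] == geno[i, 1]) for i, l in enumerate(pop.line_ids)
        }
        return pop, mdr_core.BinaryPhenotype(is_case)

    def test_separating_pair_survives_held_out_evaluation(self):
        pop, labels = self.xor_setup()
        t = build_two_locus_table(pop, "ma", "mb", labels)
        full = pooled_chi_square(t, classify_cells(t)).chi_square
        cv = cv_mean_chi_square(pop, "ma", "mb", labels, seed=0)
        assert cv == pytest.approx(full, rel=0.10)

    def test_overfitting_penalised_under_null(self):
        """With permuted labels the held-out statistic drops below full-data."""
        rng = np.random.default_rng(3)
        pop, labels = self.xor_setup()
        diffs = []
        for s in range(25):
            perm = rng.permutation(list(labels.is_case.values()))
            null_labels = mdr_core.BinaryPhenotype(
                dict(zip(labels.is_case, (bool(v) for v in perm)))
            )
            t = build_two_locus_table(pop, "ma", "mb", null_labels)
            full = pooled_chi_square(t, classify_cells(t)).chi_square
            cv = cv_mean_chi_square(pop, "ma", "mb", null_labels, seed=s)
            diffs.append(full - cv)
        assert np.mean(diffs) > 0

    def test_determinism(self, pop147, noise_pheno):
        labels = binarize_phenotype(noise_pheno)
        ma, mb = pop147.marker_ids[0], pop147.marker_ids[7]
        a = cv_mean_chi_square(pop147, ma, mb, labels, seed=9)
        b = cv_mean_chi_square(pop147, ma, mb, labels, seed=9)
        assert a == b


def test_null_distribution_regression():
    """Empirical null quantiles of the adaptive statistic (10,000 unlinked
    pairs, n=147, balanced split): heavier-tailed than chi-square(1), frozen
    as a regression fixture."""
    rng = np.random.default_rng(777)
    n, npairs = 147, 10_000
    G = rng.choice(np.array([0, 2], dtype=np.int8), size=(n, 2 * npairs))
    case = np.zeros(n, dtype=bool)
    case[:73] = True
    ia = np.arange(0, 2 * npairs, 2)
    chi = np.concatenate(
        [
            _chunk_chi_square(G, case, ia[s : s + 2000], ia[s : s + 2000] + 1)
            for s in range(0, npairs, 2000)
        ]
    )
    frozen = {0.5: 1.964717, 0.9: 5.204103, 0.99: 9.514867, 0.999: 12.870074}
    for q, expected in frozen.items():
        assert np.quantile(chi, q) == pytest.approx(expected, rel=1e-5)
        # data-adaptive pooling inflates the statistic above chi-square(1)
        assert np.quantile(chi, q) > stats.chi2.ppf(q, 1)
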