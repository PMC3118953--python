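import itertools

import numpy as np
import pytest
from scipy.stats import norm

from causal_gwas import (
    SimulationSpec,
    auc,
    delong_ci,
    generate_dataset,
    robustness,
    roc_report,
    stratified_split,
)

from conftest import make_dataset


def auc_pairs(scores, labels):
    """Exhaustive case/control pair counting (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c, d in itertools.product(cases, controls):
        total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestStratifiedSplit:
    def test_balanced_small_fixture(self):
        ds = make_dataset(np.zeros((18, 1)), phenotype=[1] * 9 + [0] * 9)
        train, test = stratified_split(ds, 2 / 3, seed=0)
        assert int(train.phenotype.sum()) == 6 and train.n_subjects == 12
        assert int(test.phenotype.sum()) == 3 and test.n_subjects == 6

    def test_partition_and_determinism(self):
        ds = make_dataset(
            np.zeros((40, 1)), phenotype=[1] * 15 + [0] * 25
        )
        t1a, s1a = stratified_split(ds, seed=1)
        t1b, s1b = stratified_split(ds, seed=1)
        t2, _ = stratified_split(ds, seed=2)
        assert t1a.subject_ids == t1b.subject_ids
        assert t1a.subject_ids != t2.subject_ids
        assert sorted(t1a.subject_ids + s1a.subject_ids) == sorted(ds.subject_ids)

    def test_train_ratio_within_one_subject_of_full_ratio(self):
        pheno = np.array([1] * 437 + [0] * 563)
        ds = make_dataset(np.zeros((1000, 1)), phenotype=pheno)
        train, _ = stratified_split(ds, 2 / 3, seed=3)
        full_ratio = 437 / 1000
        train_cases = int(train.phenotype.sum())
        assert abs(train_cases - full_ratio * train.n_subjects) <= 1.0

    def test_missing_stratum_errors(self):
        ds = make_dataset(np.zeros((4, 1)))
        with pytest.raises(ValueError):
            stratified_split(ds, seed=0)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_small_example_matches_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(auc_pairs(scores, labels))

    def test_random_scores_match_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(auc_pairs(scores, labels))

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(40) / 40.0
        labels = np.array([0, 1] * 20)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_perfect_separation_collapses_to_one(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.05]
        labels = [1, 1, 1, 0, 0, 0]
        lo, hi = delong_ci(scores, labels)
        assert (lo, hi) == (1.0, 1.0)

    def test_symmetric_about_auc_before_truncation(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60) + np.array([0, 1] * 30)
        labels = np.array([0, 1] * 30)
        a = auc(scores, labels)
        lo, hi = delong_ci(scores, labels)
        if 0.0 < lo and hi < 1.0:
            assert (hi - a) == pytest.approx(a - lo, abs=1e-12)

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(3)

        def width(n):
            labels = np.array([0, 1] * (n // 2))
            scores = rng.normal(size=n) + labels
            lo, hi = delong_ci(scores, labels)
            return hi - lo

        assert width(1000) < width(100)

    def test_coverage_of_true_auc_binormal(self):
        # cases ~ N(mu, 1), controls ~ N(0, 1): true AUC = Phi(mu/sqrt(2))
        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(4)
        covered = 0
        reps = 300
        for _ in range(reps):
            cases = rng.normal(mu, 1, 100)
            controls = rng.normal(0, 1, 100)
            scores = np.concatenate([cases, controls])
            labels = np.array([1] * 100 + [0] * 100)
            lo, hi = delong_ci(scores, labels)
            covered += lo <= true_auc <= hi
        assert 0.93 - 0.03 <= covered / reps <= 0.97 + 0.03

    def test_roc_report_curve_endpoints(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1] * 40)
        scores = rng.normal(size=80) + labels
        rep = roc_report(scores, labels)
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert rep.fpr[0] == 0.0 and rep.tpr[0] == 0.0
        assert rep.fpr[-1] == 1.0 and rep.tpr[-1] == 1.0
        assert (np.diff(rep.tpr) >= 0).all()


class TestRobustness:
    def test_single_split_reduces_to_holdout(self):
        spec = SimulationSpec(
            n_cases=200, n_controls=200, n_snps=20, ld_block_size=1,
            causal_snps=((4, 1.3),), seed=17,
        )
        ds, _ = generate_dataset(spec)
        rep = robustness(
            ds, n_splits=1, lambda_grid=[1e-4], gamma_grid=[0.2],
            cv_folds=3, seed=5,
        )
        assert len(rep.split_aucs) == 1
        assert not rep.failures
        assert rep.selection_frequency["rs000005"] == 1.0

    def test_duplicate_pair_multiplicity_in_selection(self):
        spec = SimulationSpec(
            n_cases=400, n_controls=400, n_snps=20, ld_block_size=1,
            causal_snps=((4, 1.3), (12, 1.1)), duplicate_pairs=((4, 9),), seed=19,
        )
        ds, _ = generate_dataset(spec)
        rep = robustness(
            ds, n_splits=20, lambda_grid=[1e-4], gamma_grid=[0.2],
            cv_folds=3, seed=7,
        )
        f = rep.selection_frequency
        # both copies appear (multiplicity); jointly at least as often as
        # the non-duplicated causal SNP
        assert f["rs000005"] > 0 and f["rs000010"] > 0
        assert f["rs000005"] + f["rs000010"] >= f["rs000013"]

    def test_bit_reproducible_under_fixed_seed(self):
        spec = SimulationSpec(
            n_cases=150, n_controls=150, n_snps=15, ld_block_size=1,
            causal_snps=((3, 1.3),), seed=23,
        )
        ds, _ = generate_dataset(spec)
        kwargs = dict(n_splits=3, lambda_grid=[1e-4], gamma_grid=[0.2],
                      cv_folds=3, seed=11)
        assert robustness(ds, **kwargs).to_json_dict() == robustness(
            ds, **kwargs
        ).to_json_dict()
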