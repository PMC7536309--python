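"""Nested cross-validation machinery: partitions, model selection, rDCV."""

from itertools import product

import numpy as np
import pytest

from socovsel import (
    RdcvConfig,
    SyntheticConfig,
    fit_so_covsel,
    generate,
    inner_select,
    make_partition,
    permutation_test,
    run_dcv,
    run_rdcv,
)
from socovsel.model import fit_lda
from socovsel.preprocessing import scale_matrices
from socovsel.validation import _grid_search

REDUCED = dict(complexity_max=2, candidate_orders=((0, 1, 2),))


class TestMakePartition:
    def test_k_equals_n_gives_singletons(self, rng):
        labels = np.array([1] * 11 + [0] * 10)
        assign = make_partition(21, 21, labels, rng)
        assert sorted(np.bincount(assign, minlength=21)) == [1] * 21

    def test_balanced_stratification(self, rng):
        labels = np.array([1, 0] * 10)
        assign = make_partition(20, 5, labels, rng)
        for g in range(5):
            members = labels[assign == g]
            assert len(members) == 4
            assert members.sum() == 2

    def test_sizes_differ_by_at_most_one(self, rng):
        for n, k in [(21, 5), (17, 4), (9, 2)]:
            labels = (np.arange(n) % 2).astype(int)
            sizes = np.bincount(make_partition(n, k, labels, rng), minlength=k)
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic_given_seed(self):
        labels = np.array([1] * 6 + [0] * 6)
        a = make_partition(12, 3, labels, np.random.default_rng(4))
        b = make_partition(12, 3, labels, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_raises(self, rng):
        with pytest.raises(ValueError, match="k="):
            make_partition(5, 6, np.array([0, 1, 0, 1, 0]), rng)


def naive_grid_search(blocks, y, cfg, rng):
    """Point-by-point evaluation of the (order x complexity) grid with the
    canonical fitting path; the oracle the fast tree search must match."""
    n = len(y)
    k = min(cfg.n_inner_groups, n)
    assign = make_partition(n, k, y, rng)
    folds = []
    for g in range(k):
        te, tr = np.flatnonzero(assign == g), np.flatnonzero(assign != g)
        if len(np.unique(y[tr])) < 2:
            continue
        if cfg.scaling == "fold":
            btr, bte = scale_matrices([b[tr] for b in blocks], [b[te] for b in blocks])
        else:
            btr, bte = [b[tr] for b in blocks], [b[te] for b in blocks]
        folds.append((btr, y[tr], bte, y[te]))
    best_key, best = None, None
    for oi, order in enumerate(cfg.orders(len(blocks))):
        widths = [blocks[i].shape[1] for i in order]
        ranges = [range(cfg.complexity_min, min(cfg.complexity_max, w) + 1) for w in widths]
        for comp in product(*ranges):
            if sum(comp) == 0:
                continue
            err = 0
            for btr, ytr, bte, yte in folds:
                m = fit_so_covsel([btr[i] for i in order], ytr, comp, priors=cfg.priors)
                err += int((m.classify([bte[i] for i in order]) != yte).sum())
            key = (err, sum(comp), oi, comp)
            if best_key is None or key < best_key:
                best_key, best = key, (order, comp)
    return best


class TestInnerSelect:
    def test_tree_search_matches_naive_grid_evaluation(self):
        """The fast prefix-tree enumeration is exactly the exhaustive grid."""
        rng0 = np.random.default_rng(42)
        for trial in range(10):
            y = np.array([1.0] * 7 + [0.0] * 7)
            blocks = [rng0.standard_normal((14, w)) for w in (5, 4, 3)]
            blocks[0][:, 0] += 1.5 * y
            blocks[1][:, 1] += 1.0 * y
            cfg = RdcvConfig(n_inner_groups=3, complexity_max=2, base_seed=0)
            seed = 100 + trial
            fast = _grid_search(blocks, y, cfg, np.random.default_rng(seed))
            slow = naive_grid_search(blocks, y, cfg, np.random.default_rng(seed))
            assert fast == slow, f"trial {trial}"

    def test_informative_variable_complexity_preferred(self):
        """Single block where only one variable matters: large effect sizes
        drive the inner loop to complexity 1 in a majority of seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([1.0] * 8 + [0.0] * 8)
            X = rng.standard_normal((16, 6))
            X[:, 0] += 3.0 * y
            cfg = RdcvConfig(n_inner_groups=4, complexity_max=2, base_seed=0)
            _, comp = _grid_search([X], y, cfg, np.random.default_rng(seed))
            wins += comp == (1,)
        assert wins > 10

    def test_degenerate_grid_returns_single_entry(self, default_dataset, rng):
        ds, _ = default_dataset
        cfg = RdcvConfig(
            complexity_min=2, complexity_max=2, candidate_orders=((2, 1, 0),)
        )
        order, comp = inner_select(ds, cfg, rng)
        assert order == ("mdv", "inflammation", "amino_acids")
        assert comp == (2, 2, 2)

    def test_all_noise_tie_breaks_to_fewest_variables(self):
        rng = np.random.default_rng(77)
        y = np.array([1.0] * 6 + [0.0] * 6)
        blocks = [rng.standard_normal((12, 4)), rng.standard_normal((12, 3))]
        cfg = RdcvConfig(n_inner_groups=3, complexity_max=3, base_seed=0)
        _, comp = _grid_search(blocks, y, cfg, np.random.default_rng(3))
        # pure noise: nothing beats the smallest admissible models reliably;
        # the chosen tuple can never be dominated in size by an equal-error one
        assert sum(comp) <= 4


class TestRunDcv:
    def test_each_sample_predicted_once_and_21_models(self, default_dataset, rng):
        ds, _ = default_dataset
        run = run_dcv(ds, RdcvConfig(**REDUCED), rng)
        assert len(run.orders) == 21
        assert len(run.y_pred) == ds.n_samples
        assert set(run.y_pred).issubset({0, 1})

    def test_strongly_separated_data_near_perfect_accuracy(self):
        """At a 4-SD planted shift almost every held-out sample is classified
        correctly; residual errors come from single-variable outer models
        meeting per-variable outliers."""
        accs = [
            run_dcv(
                generate(SyntheticConfig(seed=s, effect_size=4.0))[0],
                RdcvConfig(**REDUCED),
                np.random.default_rng(s),
            ).accuracy
            for s in range(10, 14)
        ]
        assert min(accs) >= 0.85
        assert np.mean(accs) >= 0.9

    def test_label_permutation_gives_chance_accuracy(self):
        accs = []
        for seed in range(20):
            ds, _ = generate(SyntheticConfig(seed=seed, effect_size=2.0))
            rng = np.random.default_rng(seed)
            ds.y = rng.permutation(ds.y)
            accs.append(run_dcv(ds, RdcvConfig(**REDUCED), rng).accuracy)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_heldout_sample_cannot_influence_its_model(self, default_dataset):
        """Outer-loop hygiene: perturbing a sample's analyte values must not
        change the selections of the model that predicts it (fold scaling)."""
        ds, _ = default_dataset
        cfg = RdcvConfig(**REDUCED)
        run1 = run_dcv(ds, cfg, np.random.default_rng(0))
        tampered = ds.copy()
        i = 4
        for b in tampered.blocks:
            b.data.iloc[i] = b.data.iloc[i] * 7.7 + 3.0
        run2 = run_dcv(tampered, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(run1.outer_assignment, run2.outer_assignment)
        seg = int(run1.outer_assignment[i])
        assert run1.orders[seg] == run2.orders[seg]
        assert run1.complexities[seg] == run2.complexities[seg]
        assert run1.selected[seg] == run2.selected[seg]


class TestRunRdcv:
    def test_total_model_count_and_frequency_conservation(self, default_dataset):
        ds, _ = default_dataset
        cfg = RdcvConfig(n_repetitions=3, **REDUCED)
        s = run_rdcv(ds, cfg)
        assert s.total_models == 3 * 21
        total_selected = sum(len(m["selected"]) for m in s.per_model)
        assert sum(s.selection_frequency.values()) == total_selected
        assert max(s.selection_frequency.values()) <= s.total_models

    def test_bit_identical_reproducibility(self, default_dataset):
        ds, _ = default_dataset
        cfg = RdcvConfig(n_repetitions=2, base_seed=9, **REDUCED)
        a, b = run_rdcv(ds, cfg), run_rdcv(ds, cfg)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.selection_frequency == b.selection_frequency
        assert a.modal_order == b.modal_order
        assert a.modal_complexity == b.modal_complexity
        assert a.per_model == b.per_model

    def test_planted_markers_dominate_aggregate_frequency(self):
        """Across base seeds, the five planted analytes collect more outer-model
        selections than any decoy: the pipeline's parameter-recovery property."""
        from collections import Counter

        total = Counter()
        truth = None
        for seed in range(1, 11):
            ds, truth = generate(SyntheticConfig(seed=seed, effect_size=2.0))
            s = run_rdcv(ds, RdcvConfig(n_repetitions=10, base_seed=seed, **REDUCED))
            total.update(s.selection_frequency)
        planted = {a for v in truth.planted.values() for a in v}
        top5 = {a for a, _ in sorted(total.items(), key=lambda kv: -kv[1])[:5]}
        assert top5 == planted


class TestPermutationTest:
    def test_add_one_rule_floor(self, default_dataset, rng):
        ds, _ = generate(SyntheticConfig(seed=11, effect_size=4.0))
        cfg = RdcvConfig(n_repetitions=1, base_seed=0, **REDUCED)
        res = permutation_test(ds, cfg, 9, rng)
        assert res.p_value >= 1 / 10
        assert len(res.null) == 9

    def test_strong_signal_rejects_at_floor(self):
        ds, _ = generate(SyntheticConfig(seed=11, effect_size=3.0))
        cfg = RdcvConfig(n_repetitions=1, base_seed=0, **REDUCED)
        res = permutation_test(ds, cfg, 19, np.random.default_rng(1))
        assert res.p_value == pytest.approx(1 / 20)

    def test_observed_below_null_gives_p_one_region(self, rng):
        """With a caller-supplied observed statistic below every null draw the
        add-one rule yields p = 1."""
        ds, _ = generate(SyntheticConfig(seed=2, effect_size=0.0))
        cfg = RdcvConfig(n_repetitions=1, base_seed=0, **REDUCED)
        res = permutation_test(ds, cfg, 5, rng, observed=-1.0)
        assert res.p_value == 1.0
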