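"""Split bookkeeping, cumulative training, subsampling, metrics, and the factorial run."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ribofit as rf
from ribofit.evaluation import _round_half_up, derive_seed, table1_counts


def synthetic_binned_table(ref, bin_sizes, seed=0):
    """A table with prescribed per-order bin sizes (orders are dict keys)."""
    rng = np.random.default_rng(seed)
    singles = rf.enumerate_single_mutants(ref)
    rows = []
    for order, size in bin_sizes.items():
        made = set()
        attempts = 0
        while len(made) < size and attempts < 100 * size:
            attempts += 1
            if order == 0:
                made.add("WT")
                continue
            idx = rng.choice(len(singles), order, replace=False)
            muts = tuple(singles[i].mutations[0] for i in idx)
            if len({m.position for m in muts}) != order:
                continue
            made.add(str(rf.Genotype(muts)))
        assert len(made) == size, f"could not build bin {order}"
        for label in sorted(made):
            rows.append(
                {
                    "genotype": label, "order": order, "cleaved": 1,
                    "uncleaved": 1, "total": 2,
                    "fraction_cleaved": float(rng.random()),
                }
            )
    return rf.ActivityTable(pd.DataFrame(rows), ref)


class TestSplitByOrder:
    def test_exact_division_bin(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 1: 50, 3: 100})
        split = rf.split_by_order(table, 0.2, seed=1)
        assert len(split.test[3]) == 20 and len(split.train[3]) == 80

    def test_orders_up_to_two_fully_in_training(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 1: 207, 2: 300, 3: 50})
        split = rf.split_by_order(table, 0.2, seed=2)
        assert len(split.train[1]) == 207 and split.test[1] == []
        assert len(split.train[2]) == 300 and split.test[2] == []
        assert len(split.train[0]) == 1

    def test_round_half_up_rule(self, ref69):
        # 518 * 0.2 = 103.6 -> 104
        table = synthetic_binned_table(ref69, {0: 1, 3: 518})
        split = rf.split_by_order(table, 0.2, seed=3)
        assert len(split.test[3]) == 104
        assert len(split.train[3]) == 414
        assert _round_half_up(103.5) == 104 and _round_half_up(103.4) == 103

    def test_conservation_per_bin(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 3: 77, 4: 33, 5: 13})
        split = rf.split_by_order(table, 0.2, seed=4)
        for order, size in {3: 77, 4: 33, 5: 13}.items():
            assert len(split.train[order]) + len(split.test[order]) == size
            assert not set(split.train[order]) & set(split.test[order])

    def test_different_seeds_differ_but_both_valid(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 3: 5})
        a = rf.split_by_order(table, 0.2, seed=5)
        b = rf.split_by_order(table, 0.2, seed=6)
        assert len(a.test[3]) == len(b.test[3]) == 1
        # with only 5 members, some seed pair differs; these two were chosen to
        assert a.test[3] != b.test[3]

    def test_tiny_bin_warns_and_trains(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 3: 1})
        with pytest.warns(UserWarning):
            split = rf.split_by_order(table, 0.2, seed=7)
        assert split.test[3] == [] and len(split.train[3]) == 1

    def test_split_persistence_round_trip(self, ref69, tmp_path):
        table = synthetic_binned_table(ref69, {0: 1, 3: 40, 4: 17})
        split = rf.split_by_order(table, 0.2, seed=8)
        split.to_json(tmp_path / "split.json")
        back = rf.BinnedSplit.from_json(tmp_path / "split.json")
        assert back.train == split.train and back.test == split.test

    def test_table1_layout(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 1: 30, 2: 40, 3: 50})
        split = rf.split_by_order(table, 0.2, seed=9)
        t1 = table1_counts(split)
        assert list(t1.columns) == ["No. of mutations", "Training", "Testing"]
        assert t1.loc[t1["No. of mutations"] == 1, "Testing"].iloc[0] == "—"
        assert t1.loc[t1["No. of mutations"] == 3, "Testing"].iloc[0] == 10
        assert 0 not in t1["No. of mutations"].values


class TestCumulativeTraining:
    def test_counts_match_per_bin_bookkeeping(self, ref69):
        sizes = {0: 1, 1: 20, 2: 30, 3: 40, 4: 25}
        table = synthetic_binned_table(ref69, sizes)
        split = rf.split_by_order(table, 0.2, seed=10)
        for k in (1, 2, 3, 4):
            data = rf.build_cumulative_training(split, table, k)
            expected = 1 + sum(len(split.train[o]) for o in range(1, k + 1))
            assert len(data) == expected

    def test_nesting(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 1: 10, 2: 20, 3: 30, 4: 12})
        split = rf.split_by_order(table, 0.2, seed=11)
        prev = set()
        for k in (1, 2, 3, 4):
            keys = set(rf.build_cumulative_training(split, table, k).keys)
            assert prev <= keys
            prev = keys

    def test_excessive_max_order_clamps_with_warning(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 1: 10, 3: 20})
        split = rf.split_by_order(table, 0.2, seed=12)
        with pytest.warns(UserWarning):
            data = rf.build_cumulative_training(split, table, 99)
        assert len(data) == 1 + 10 + len(split.train[3])


class TestSubsampling:
    @pytest.fixture()
    def data(self, ref69):
        table = synthetic_binned_table(ref69, {0: 1, 3: 999})
        return rf.encode_dataset(table)

    def test_full_fraction_is_identity(self, data):
        sub = rf.subsample_training(data, 1.0, seed=0)
        assert sub.keys == data.keys

    def test_exact_rounding(self, data):
        assert len(rf.subsample_training(data, 0.1, seed=1)) == 100

    def test_replicates_differ_in_membership_not_size(self, data):
        a = rf.subsample_training(data, 0.01, seed=2)
        b = rf.subsample_training(data, 0.01, seed=3)
        assert len(a) == len(b) == 10
        assert set(a.keys) != set(b.keys)

    def test_too_small_subsample_errors(self, data):
        with pytest.raises(ValueError):
            rf.subsample_training(data, 0.001, seed=4)

    def test_spec_replicate_rule(self):
        spec = rf.SubsampleSpec()
        assert spec.fractions == (0.6, 0.4, 0.2, 0.1, 0.01)
        assert spec.replicates_for(0.01) == 5
        assert spec.replicates_for(0.6) == 1


class TestMetrics:
    def test_perfect_prediction(self):
        obs = [0.1, 0.4, 0.9, 0.2]
        m = rf.compute_metrics(obs, obs)
        assert m["pearson_r"] == pytest.approx(1.0)
        assert m["mse"] == 0.0
        assert m["r_squared"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        obs = np.array([0.1, 0.4, 0.9, 0.2])
        m = rf.compute_metrics(-obs + 1, obs)
        assert m["pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        m = rf.compute_metrics([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert math.isnan(m["pearson_r"]) and m["degenerate_variance"]

    @given(st.integers(0, 500))
    def test_matches_textbook_formulas(self, seed):
        """Independent recomputation from the definitional formulas, to 1e-12."""
        rng = np.random.default_rng(seed)
        p, o = rng.random(50), rng.random(50)
        m = rf.compute_metrics(p, o)
        pm, om = p.mean(), o.mean()
        r_direct = float(
            np.sum((p - pm) * (o - om))
            / math.sqrt(np.sum((p - pm) ** 2) * np.sum((o - om) ** 2))
        )
        mse_direct = float(sum((x - y) ** 2 for x, y in zip(p, o)) / 50)
        assert abs(m["pearson_r"] - r_direct) < 1e-12
        assert abs(m["mse"] - mse_direct) < 1e-12
        assert abs(m["r_squared"] - r_direct**2) < 1e-12
        cod_direct = 1 - np.sum((p - o) ** 2) / np.sum((o - om) ** 2)
        assert abs(m["r_squared_cod"] - cod_direct) < 1e-12


class TestDeriveSeed:
    def test_deterministic_and_tag_sensitive(self):
        assert derive_seed(1, "split") == derive_seed(1, "split")
        assert derive_seed(1, "split") != derive_seed(1, "model")
        assert derive_seed(1, "split") != derive_seed(2, "split")
        assert 0 <= derive_seed(123, "x", 4, 0.2) < 2**31


class TestRunPredictionExperiment:
    @pytest.fixture(scope="class")
    def table(self, trend_fixture):
        return trend_fixture["table"]

    def test_factorial_record_count(self, table):
        metrics = rf.run_prediction_experiment(
            table, ["random_forest"], max_orders=[2], test_orders=[4, 5, 6],
            base_seed=1,
        )
        assert len(metrics) == 3
        assert set(metrics["test_order"]) == {4, 5, 6}

    def test_rerun_is_identical(self, table, tmp_path):
        kw = dict(
            model_kinds=["random_forest"], max_orders=[2], test_orders=[5],
            base_seed=2,
        )
        a = rf.run_prediction_experiment(table, **kw)
        b = rf.run_prediction_experiment(table, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_test_sets_identical_across_models_and_training(self, table, tmp_path):
        rf.run_prediction_experiment(
            table, ["random_forest", "linear"], max_orders=[2, 3], test_orders=[5],
            base_seed=3, out_dir=tmp_path,
        )
        preds = sorted(tmp_path.glob("pred_*_test5.tsv"))
        assert len(preds) == 4
        reference_bytes = None
        for p in preds:
            frame = pd.read_csv(p, sep="\t")
            blob = "\n".join(frame["genotype"]) + "|" + "\n".join(
                f"{v:.12g}" for v in frame["observed"]
            )
            if reference_bytes is None:
                reference_bytes = blob
            assert blob == reference_bytes

    def test_outputs_written(self, table, tmp_path):
        rf.run_prediction_experiment(
            table, ["random_forest"], max_orders=[2], test_orders=[5],
            base_seed=4, out_dir=tmp_path,
        )
        assert (tmp_path / "split.json").exists()
        assert (tmp_path / "table1_counts.tsv").exists()
        assert (tmp_path / "metrics.tsv").exists()

    def test_subsample_replicate_records(self, table):
        spec = rf.SubsampleSpec(fractions=(0.5, 0.1), smallest_fraction_replicates=3)
        metrics = rf.run_prediction_experiment(
            table, ["random_forest"], max_orders=[3], test_orders=[5],
            subsample_spec=spec, base_seed=5,
        )
        assert len(metrics) == 1 + 3  # one at 0.5, three replicates at 0.1
        reps = metrics.loc[metrics["subsample_fraction"] == 0.1]
        assert sorted(reps["replicate"]) == [0, 1, 2]
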