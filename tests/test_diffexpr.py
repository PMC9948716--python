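import numpy as np
import pandas as pd
import pytest

from dualstress import (
    DataValidationError,
    adjust_fdr,
    classify_degs,
    compute_delta_lfc,
    compute_lfc,
    differential_expression,
    select_trend_genes,
    summarize_degs,
)
from dualstress import test_differential as run_group_tests
from dualstress.diffexpr import overlap_row
from dualstress.io import STRESS_TIMES
from dualstress.normalize import NormalizedMatrix
from conftest import make_sample_table, matrix_from_group_means


def flat_means(value):
    return {
        (strain, time): np.asarray(value, dtype=float)
        for strain in ("stressA", "stressB")
        for time in ("control", "early", "middle", "late")
    }


class TestComputeLfc:
    def test_hand_computed_value(self, toy_samples):
        means = flat_means([100.0])
        means[("stressA", "early")] = np.array([400.0])
        norm = matrix_from_group_means(means, ["g"])
        lfc = compute_lfc(norm, toy_samples, pseudocount=0.5)
        assert lfc.loc[("g", "stressA", "early"), "lfc"] == pytest.approx(
            np.log2(400.5 / 100.5)
        )
        assert lfc.loc[("g", "stressA", "early"), "lfc"] == pytest.approx(1.995, abs=5e-4)

    def test_identical_means_give_zero(self, toy_samples):
        norm = matrix_from_group_means(flat_means([50.0, 7.0]), ["g0", "g1"])
        lfc = compute_lfc(norm, toy_samples)
        assert lfc["lfc"].to_numpy() == pytest.approx(0.0)

    def test_strain_scale_equivariance_without_pseudocount(self, toy_samples):
        rng = np.random.default_rng(5)
        base = rng.uniform(10, 1000, 8)
        means = {
            (strain, time): base * rng.uniform(0.5, 2)
            for strain in ("stressA", "stressB")
            for time in ("control", "early", "middle", "late")
        }
        norm1 = matrix_from_group_means(means, [f"g{i}" for i in range(8)])
        scaled = {
            key: (vals * 7.0 if key[0] == "stressA" else vals)
            for key, vals in means.items()
        }
        norm2 = matrix_from_group_means(scaled, [f"g{i}" for i in range(8)])
        lfc1 = compute_lfc(norm1, toy_samples, pseudocount=0.0)
        lfc2 = compute_lfc(norm2, toy_samples, pseudocount=0.0)
        assert lfc2["lfc"].to_numpy() == pytest.approx(lfc1["lfc"].to_numpy())


class TestDifferentialTest:
    def _norm(self, a_vals, ctrl_vals, toy):
        # distinct replicate values per group; other cells neutral
        data = {}
        for _, row in toy.data.iterrows():
            strain, time, rep = row["strain"], row["time"], row["replicate"]
            if strain == "stressA" and time == "early":
                value = a_vals[rep - 1]
            elif strain == "stressA" and time == "control":
                value = ctrl_vals[rep - 1]
            else:
                value = 100.0
            data[row["sample_id"]] = [value]
        return NormalizedMatrix(pd.DataFrame(data, index=["g"]))

    def test_identical_groups_give_p_one(self):
        samples = make_sample_table(replicates=3)
        norm = self._norm([4, 4, 4], [4, 4, 4], samples)
        p = run_group_tests(norm, samples)
        assert p.loc[("g", "stressA", "early"), "p_value"] == 1.0

    def test_zero_variance_separation_gives_minimal_p(self):
        samples = make_sample_table(replicates=3)
        norm = self._norm([8, 8, 8], [4, 4, 4], samples)
        p = run_group_tests(norm, samples)
        assert 0 < p.loc[("g", "stressA", "early"), "p_value"] < 1e-300

    @pytest.mark.parametrize("var_policy", ["pooled", "welch"])
    def test_matches_scipy_reference(self, var_policy):
        from scipy import stats

        samples = make_sample_table(replicates=3)
        rng = np.random.default_rng(11)
        norm = NormalizedMatrix(
            pd.DataFrame(
                rng.uniform(50, 500, (20, 24)),
                index=[f"g{i}" for i in range(20)],
                columns=samples.sample_ids,
            )
        )
        table = run_group_tests(norm, samples, pseudocount=0.5, var_policy=var_policy)
        log = np.log2(norm.data + 0.5)
        for strain in ("stressA", "stressB"):
            ctrl = log[samples.samples_for(strain, "control")]
            for time in STRESS_TIMES:
                grp = log[samples.samples_for(strain, time)]
                expected = stats.ttest_ind(
                    grp, ctrl, axis=1, equal_var=(var_policy == "pooled")
                ).pvalue
                got = [
                    table.loc[(g, strain, time), "p_value"] for g in norm.gene_ids
                ]
                assert got == pytest.approx(expected.tolist())

    def test_single_replicate_group_is_error(self):
        samples = make_sample_table(replicates=1)
        norm = NormalizedMatrix(
            pd.DataFrame(
                np.ones((2, 8)),
                index=["g0", "g1"],
                columns=samples.sample_ids,
            )
        )
        with pytest.raises(DataValidationError, match="control"):
            run_group_tests(norm, samples)


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        assert adjust_fdr([0.2]).tolist() == [0.2]

    def test_all_ones_stay_one(self):
        assert adjust_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        assert np.all(adjust_fdr(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            adjust_fdr([0.5, 1.2])


def lfc_frame(records):
    idx = pd.MultiIndex.from_tuples(
        [(r[0], r[1], r[2]) for r in records], names=["gene", "strain", "time"]
    )
    return pd.DataFrame(
        {"lfc": [r[3] for r in records], "fdr": [r[4] for r in records]}, index=idx
    )


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.0, 0.049, "up"),  # |lfc| threshold inclusive
            (-0.99, 0.001, "none"),  # below threshold despite tiny FDR
            (-1.5, 0.05, "none"),  # FDR strictly below alpha required
            (-1.0, 0.049, "down"),
        ],
    )
    def test_thresholds(self, lfc, fdr, expected):
        table = lfc_frame([("g", "stressA", "early", lfc, fdr)])
        calls = classify_degs(table)
        assert calls.loc[("g", "stressA", "early"), "call"] == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        records = [
            (f"g{i}", "stressA", "early", rng.normal(0, 2), rng.uniform())
            for i in range(200)
        ]
        table = lfc_frame(records)
        loose = set((classify_degs(table, 1.0, 0.05)["call"] != "none").pipe(lambda s: s.index[s]))
        tighter_lfc = set((classify_degs(table, 1.5, 0.05)["call"] != "none").pipe(lambda s: s.index[s]))
        tighter_alpha = set((classify_degs(table, 1.0, 0.01)["call"] != "none").pipe(lambda s: s.index[s]))
        assert tighter_lfc <= loose
        assert tighter_alpha <= loose


def calls_frame(entries):
    """entries: dict (gene, strain, time) -> call; missing combos are 'none'."""
    genes = sorted({g for g, _, _ in entries})
    rows = []
    for g in genes:
        for s in ("stressA", "stressB"):
            for t in STRESS_TIMES:
                rows.append((g, s, t, entries.get((g, s, t), "none")))
    idx = pd.MultiIndex.from_tuples(
        [(g, s, t) for g, s, t, _ in rows], names=["gene", "strain", "time"]
    )
    return pd.DataFrame({"call": [c for *_, c in rows]}, index=idx)


class TestSummarizeDegs:
    def test_simple_overlap_counts(self):
        entries = {
            ("g1", "stressA", "early"): "up",
            ("g2", "stressA", "early"): "up",
            ("g2", "stressB", "early"): "up",
            ("g3", "stressB", "early"): "down",
        }
        summary = summarize_degs(calls_frame(entries), universe_size=100)
        row = summary.table.loc[("early", "total")]
        assert (row["n_a_only"], row["n_both"], row["n_b_only"], row["n_all"]) == (
            1,
            1,
            1,
            3,
        )
        assert row["f_all"] == 3.0

    def test_additivity_holds_on_random_calls(self):
        rng = np.random.default_rng(2)
        entries = {}
        for i in range(300):
            for s in ("stressA", "stressB"):
                for t in STRESS_TIMES:
                    entries[(f"g{i:03d}", s, t)] = rng.choice(
                        ["up", "down", "none"], p=[0.2, 0.2, 0.6]
                    )
        summary = summarize_degs(calls_frame(entries), universe_size=300)
        for _, row in summary.table.iterrows():
            assert row["n_all"] == row["n_a_only"] + row["n_both"] + row["n_b_only"]

    def test_discordant_convention(self):
        # g1 is up in stressA and down in stressB at early
        entries = {
            ("g1", "stressA", "early"): "up",
            ("g1", "stressB", "early"): "down",
        }
        summary = summarize_degs(calls_frame(entries), universe_size=10)
        assert summary.discordant["early"] == 1
        total = summary.table.loc[("early", "total")]
        up = summary.table.loc[("early", "up")]
        down = summary.table.loc[("early", "down")]
        assert total["n_both"] == 1
        assert up["n_both"] == 0 and down["n_both"] == 0
        assert up["n_a_only"] == 1  # per its direction in stressA
        assert down["n_b_only"] == 1

    def test_persistent_requires_all_three_times(self):
        entries = {}
        for t in STRESS_TIMES:
            entries[("g1", "stressA", t)] = "down"
        entries[("g2", "stressA", "early")] = "down"
        summary = summarize_degs(calls_frame(entries), universe_size=50)
        persistent = summary.table.loc[("persistent", "total")]
        assert persistent["n_a_only"] == 1 and persistent["n_all"] == 1

    def test_no_degs_all_zero(self):
        summary = summarize_degs(calls_frame({("g1", "stressA", "early"): "none"}), 10)
        assert (summary.table[["n_a_only", "n_both", "n_b_only", "n_all"]] == 0).all().all()
        assert (summary.table[["f_a_only", "f_both", "f_b_only", "f_all"]] == 0.0).all().all()

    def test_universe_smaller_than_called_genes_is_error(self):
        entries = {(f"g{i}", "stressA", "early"): "none" for i in range(5)}
        with pytest.raises(DataValidationError, match="universe"):
            summarize_degs(calls_frame(entries), universe_size=3)

    def test_overlap_row_arithmetic(self):
        row = overlap_row(334, 223, 104, 5348)
        assert row["n_all"] == 661
        assert (row["f_a_only"], row["f_both"], row["f_b_only"], row["f_all"]) == (
            6.2,
            4.2,
            1.9,
            12.4,
        )


class TestTrends:
    def test_delta_and_selection(self):
        records = [
            ("g1", "stressA", "early", -0.4, 0.5),
            ("g1", "stressA", "middle", 0.1, 0.5),
            ("g1", "stressA", "late", 0.8, 0.5),
            ("g2", "stressA", "early", 0.3, 0.5),
            ("g2", "stressA", "middle", 0.3, 0.5),
            ("g2", "stressA", "late", 0.3, 0.5),
        ]
        table = lfc_frame(records)
        delta = compute_delta_lfc(table)
        assert delta.loc[("g1", "stressA"), "delta"] == pytest.approx(1.2)
        assert delta.loc[("g2", "stressA"), "delta"] == 0.0
        selected = select_trend_genes(delta, threshold=1.0)
        assert selected == {"stressA": ["g1"]}

    def test_opposite_trend_recovery(self, default_sim):
        from dualstress import compute_size_factors, filter_by_min_count, normalize

        _, counts, samples, _, truth = default_sim
        sf = compute_size_factors(counts)
        filtered = filter_by_min_count(counts, samples, 50)
        norm = normalize(filtered, sf)
        table = differential_expression(norm, samples)
        delta = compute_delta_lfc(table)
        selected = select_trend_genes(delta, threshold=1.0)
        kept = set(filtered.gene_ids)
        planted = [
            g for g in truth.index[truth["class"] == "opposite_trend"] if g in kept
        ]
        in_a = set(selected["stressA"])
        in_b = set(selected["stressB"])
        both = [g for g in planted if g in in_a and g in in_b]
        assert len(both) / len(planted) >= 0.95
        wide = delta["delta"].unstack("strain")
        signs = np.sign(wide.loc[both])
        assert (signs["stressA"] == -signs["stressB"]).mean() == 1.0
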