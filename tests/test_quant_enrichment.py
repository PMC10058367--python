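import numpy as np
import pandas as pd
import pytest

from anemotox.io_formats import MISSING, PipelineConfig, QuantTable
from anemotox.quant_enrichment import (
    category_composition,
    enrichment_call,
    group_means_with_replacement,
    impute,
    normalize,
    presence_filter,
    run_quant,
)


def make_table(rows: dict, layout={"tentacle": 3, "mucus": 3}) -> QuantTable:
    columns = pd.MultiIndex.from_tuples(
        [(g, s) for g in layout for s in range(1, layout[g] + 1)],
        names=["group", "sample"],
    )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = columns
    df.index.name = "feature_id"
    return QuantTable(df.astype(float), dict(layout))


class TestImpute:
    def test_missing_goes_to_floor_via_zero(self, cfg):
        table = make_table({"P1": [MISSING, 0.0, 5.0, 1.0, 2.0, 3.0]})
        out = impute(table, cfg)
        assert out.values.loc["P1", ("tentacle", 1)] == cfg.imputation_floor
        assert out.values.loc["P1", ("tentacle", 2)] == cfg.imputation_floor
        assert out.values.loc["P1", ("tentacle", 3)] == 5.0
        assert out.imputed.loc["P1", ("tentacle", 1)]
        assert out.imputed.loc["P1", ("tentacle", 2)]
        assert not out.imputed.loc["P1", ("tentacle", 3)]

    def test_fully_observed_row_unchanged(self, cfg):
        table = make_table({"P1": [1, 2, 3, 4, 5, 6]})
        out = impute(table, cfg)
        assert (out.values.loc["P1"] == table.values.loc["P1"]).all()
        assert not out.imputed.loc["P1"].any()

    def test_idempotent(self, cfg):
        table = make_table({"P1": [MISSING, 0.0, 5.0, 1.0, MISSING, 3.0]})
        once = impute(table, cfg)
        twice = impute(once, cfg)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_frame_equal(once.imputed, twice.imputed)


class TestNormalize:
    def test_total_area_factors(self, cfg):
        layout = {"tentacle": 1, "mucus": 1}
        table = impute(make_table({"P1": [4, 12], "P2": [6, 18]}, layout), cfg)
        out = normalize(table)
        sums = out.values.sum(axis=0)
        assert sums.iloc[0] == pytest.approx(sums.iloc[1])
        assert sums.iloc[0] == pytest.approx(20.0)  # grand mean of 10 and 30

    def test_none_is_identity(self, cfg):
        table = impute(make_table({"P1": [1, 2, 3, 4, 5, 6]}), cfg)
        pd.testing.assert_frame_equal(normalize(table, "none").values, table.values)

    def test_preserves_within_sample_rank_order(self, cfg):
        table = impute(make_table({"P1": [5, 1, 1, 1, 1, 1],
                                   "P2": [2, 9, 1, 1, 1, 1]}), cfg)
        out = normalize(table)
        col = ("tentacle", 1)
        assert (out.values[col].rank() == table.values[col].rank()).all()

    def test_zero_sum_sample_is_an_error(self):
        # an unimputed table can still carry an all-zero sample column
        table = make_table({"P1": [0, 1, 1, 1, 1, 1]})
        with pytest.raises(ValueError, match="zero total"):
            normalize(table)


class TestPresenceFilter:
    def test_two_of_three_in_one_group_retains(self):
        table = make_table({"P1": [5, MISSING, 3, MISSING, MISSING, MISSING]})
        assert presence_filter(table) == ["P1"]

    def test_insufficient_detection_drops(self):
        table = make_table({"P1": [MISSING, MISSING, 7, MISSING, 0, MISSING]})
        assert presence_filter(table) == []

    def test_zero_counts_as_not_detected(self):
        table = make_table({"P1": [0, 0, 7, MISSING, MISSING, MISSING]})
        assert presence_filter(table) == []

    def test_monotone_in_added_observations(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            vals = [
                MISSING if rng.random() < 0.5 else float(rng.integers(1, 9))
                for _ in range(6)
            ]
            before = presence_filter(make_table({"P1": vals}))
            j = int(rng.integers(6))
            improved = list(vals)
            improved[j] = 5.0
            after = presence_filter(make_table({"P1": improved}))
            assert set(before) <= set(after)

    def test_synthetic_known_presence_patterns(self):
        """The filter retains exactly the subset designed to pass."""
        rows = {
            "keep_t": [1, 2, MISSING, MISSING, MISSING, MISSING],
            "keep_m": [MISSING, MISSING, MISSING, 1, MISSING, 2],
            "keep_both": [1, 1, 1, 1, 1, 1],
            "drop_single": [1, MISSING, MISSING, MISSING, 1, MISSING],
            "drop_zero": [0, 0, 0, 0, 0, 0],
        }
        assert presence_filter(make_table(rows)) == ["keep_t", "keep_m", "keep_both"]


class TestGroupMeans:
    def test_imputed_cell_replaced_by_observed_mean(self, cfg):
        table = impute(make_table({"P1": [MISSING, 2, 4, 1, 1, 1]}), cfg)
        pq = group_means_with_replacement(table, cfg)["P1"]
        assert pq.final[("tentacle", 1)] == pytest.approx(3.0)
        assert pq.group_means["tentacle"] == pytest.approx(3.0)

    def test_all_imputed_group_stays_at_floor(self, cfg):
        table = impute(make_table({"P1": [MISSING, MISSING, MISSING, 1, 2, 3]}), cfg)
        pq = group_means_with_replacement(table, cfg)["P1"]
        assert pq.group_means["tentacle"] == pytest.approx(cfg.imputation_floor)
        assert pq.exclusive

    def test_no_imputation_gives_arithmetic_mean(self, cfg):
        table = impute(make_table({"P1": [2, 4, 6, 1, 1, 1]}), cfg)
        pq = group_means_with_replacement(table, cfg)["P1"]
        assert pq.group_means["tentacle"] == pytest.approx(4.0)
        assert pq.n_imputed == 0


class TestEnrichmentCall:
    def _call(self, row, cfg):
        table = impute(make_table(row), cfg)
        pq = group_means_with_replacement(table, cfg)[list(row)[0]]
        return enrichment_call(pq), pq

    def test_published_mucus_enriched_peptide(self, cfg):
        # DCRGKHCQTGPFGD: mucus 9.06E+09 vs tentacle 4.84E+08 (1+1 design)
        layout = {"tentacle": 1, "mucus": 1}
        table = impute(make_table({"m01": [4.84e8, 9.06e9]}, layout), cfg)
        pq = group_means_with_replacement(table, cfg)["m01"]
        assert enrichment_call(pq) == "mucus"

    def test_published_tentacle_exclusive_peptide(self, cfg):
        # Histone H2B fragment: mucus "-" vs tentacle 3.99E+08
        layout = {"tentacle": 1, "mucus": 1}
        table = impute(make_table({"t02": [3.99e8, MISSING]}, layout), cfg)
        pq = group_means_with_replacement(table, cfg)["t02"]
        assert enrichment_call(pq) == "tentacle"
        assert pq.exclusive

    def test_equal_means_tie(self, cfg):
        call, _ = self._call({"P1": [2, 2, 2, 2, 2, 2]}, cfg)
        assert call == "tie"


class TestPipeline:
    def test_deterministic_byte_identical_outputs(self, tmp_path, cfg):
        from anemotox.synthetic_data import SimulationConfig, simulate_quant_table

        table, _ = simulate_quant_table(SimulationConfig(seed=8))
        outputs = []
        for run in range(2):
            df, _ = run_quant(table, cfg)
            path = tmp_path / f"run{run}.tsv"
            df.to_csv(path, sep="\t", index=False)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_planted_tenfold_direction_recovered(self):
        """>= 95% direction agreement at 10-fold planting, 20% missingness,
        300 features (seeded)."""
        from anemotox.synthetic_data import SimulationConfig, simulate_quant_table

        table, truth = simulate_quant_table(SimulationConfig(seed=8))
        df, _ = run_quant(table)
        merged = df.set_index("feature_id").join(
            truth.set_index("feature_id"), rsuffix="_truth"
        )
        agreement = (merged["enrichment"] == merged["direction"]).mean()
        assert agreement >= 0.95


class TestCategoryComposition:
    def test_single_category_counts(self):
        table = category_composition(
            {"a": ["enzyme"], "b": ["enzyme"], "c": ["toxin"], "d": ["structural"]}
        )
        assert table.loc[table.category == "enzyme", "percent"].item() == 50.0

    def test_empty_known_set(self):
        assert category_composition({}).empty

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(43)
        cats = {f"f{i}": [rng.choice(["a", "b", "c"])] for i in range(37)}
        table = category_composition(cats)
        # each category can lose/gain up to 0.05 to half-up rounding
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.05 * len(table))
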