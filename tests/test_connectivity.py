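import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxlineage.connectivity import (build_connection_matrix, input_fraction_by_group,
                                    normalize_to_max, pairwise_strength_ecdf,
                                    source_exclusivity, synapse_weight_by_upstream,
                                    tbar_counts, upstream_totals)
from cxlineage.io import validate_connector_table


def table(rows):
    return validate_connector_table(pd.DataFrame(
        rows, columns=["synapse_id", "pre_neuron", "post_neuron", "kind",
                       "x", "y", "z", "compartment", "weight"]))


def random_table(rng, n=500, neurons=8, regions=("EB", "PB", "SMP")):
    return validate_connector_table(pd.DataFrame({
        "synapse_id": np.arange(n),
        "pre_neuron": rng.integers(1, neurons + 1, n),
        "post_neuron": rng.integers(1, neurons + 1, n),
        "kind": rng.choice(["TBAR", "PSD"], n),
        "x": 0.0, "y": 0.0, "z": 0.0,
        "compartment": rng.choice(regions, n),
        "weight": rng.integers(1, 4, n),
    }))


class TestConnectionMatrix:
    def test_small_example(self):
        rows = [(i, 1, 10, "TBAR", 0, 0, 0, "EB", 1) for i in range(10)] \
            + [(20 + i, 1, 11, "TBAR", 0, 0, 0, "EB", 1) for i in range(5)] \
            + [(40 + i, 2, 11, "TBAR", 0, 0, 0, "EB", 1) for i in range(20)]
        m = build_connection_matrix(table(rows), {1: "A", 2: "B"},
                                    {10: "X", 11: "Y"})
        assert m.to_numpy().tolist() == [[10, 5], [0, 20]]

    def test_region_filter_preserves_labels(self):
        rows = [(1, 1, 10, "TBAR", 0, 0, 0, "EB", 1)]
        m = build_connection_matrix(table(rows), {1: "A"}, {10: "X"},
                                    region="PB")
        assert m.shape == (1, 1) and m.loc["A", "X"] == 0

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(17)
        conn = random_table(rng)
        src = {n: f"s{n % 3}" for n in range(1, 9)}
        tgt = {n: f"t{n % 2}" for n in range(1, 9)}
        m = build_connection_matrix(conn, src, tgt, region="EB")
        for s in m.index:
            for t in m.columns:
                expected = 0
                for _, row in conn.iterrows():
                    if row["compartment"] == "EB" and src[row["pre_neuron"]] == s \
                            and tgt[row["post_neuron"]] == t:
                        expected += row["weight"]
                assert m.loc[s, t] == expected

    def test_conservation_of_totals(self):
        rng = np.random.default_rng(3)
        conn = random_table(rng)
        src = {n: "a" for n in range(1, 9)}
        m = build_connection_matrix(conn, src, src)
        assert m.to_numpy().sum() == conn["weight"].sum()
        m_eb = build_connection_matrix(conn, src, src, region="EB")
        assert m_eb.to_numpy().sum() == conn.loc[
            conn["compartment"] == "EB", "weight"].sum()


class TestNormalizeToMax:
    def test_example(self):
        m = pd.DataFrame([[10, 5], [0, 20]])
        out = normalize_to_max(m)
        assert out.to_numpy().tolist() == [[0.5, 0.25], [0.0, 1.0]]

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="no positive"):
            out = normalize_to_max(pd.DataFrame([[0, 0]]))
        assert (out.to_numpy() == 0).all()

    def test_commutes_with_permutation(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 50, (4, 5)))
        perm = rng.permutation(4)
        a = normalize_to_max(m).iloc[perm]
        b = normalize_to_max(m.iloc[perm])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10 ** 6),
                    min_size=1, max_size=30).filter(lambda v: max(v) > 0),
           st.integers(min_value=1, max_value=1000))
    def test_scale_invariant_with_unit_max(self, values, scale):
        m = pd.DataFrame({"t": values})
        out = normalize_to_max(m)
        assert out.to_numpy().max() == pytest.approx(1.0)
        np.testing.assert_allclose(normalize_to_max(m * scale).to_numpy(),
                                   out.to_numpy())


class TestInputFractions:
    def test_thirty_seventy(self):
        rows = [(i, 1, 10, "PSD", 0, 0, 0, "SMP", 1) for i in range(30)] \
            + [(50 + i, 1, 11, "PSD", 0, 0, 0, "SMP", 1) for i in range(70)]
        fr = input_fraction_by_group(table(rows), {10: "G1", 11: "G2"})
        assert fr["G1"] == pytest.approx(0.30)
        assert fr["G2"] == pytest.approx(0.70)
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_excluding_all_regions_warns(self):
        rows = [(1, 1, 10, "PSD", 0, 0, 0, "EB", 1)]
        with pytest.warns(UserWarning, match="no synapses"):
            fr = input_fraction_by_group(table(rows), {10: "G"},
                                         exclude_regions={"EB"})
        assert fr.isna().all()

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        conn = random_table(rng)
        fr = input_fraction_by_group(conn, {n: f"g{n % 3}" for n in range(1, 9)},
                                     exclude_regions={"EB"})
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)


class TestTbarCounts:
    def test_psds_excluded(self):
        rows = [(i, 1, 9, "TBAR", 0, 0, 0, "PB", 1) for i in range(12)] \
            + [(50 + i, 1, 9, "PSD", 0, 0, 0, "PB", 1) for i in range(30)]
        counts = tbar_counts(table(rows), {1}, "PB")
        assert counts[1] == 12

    def test_absent_neuron_counts_zero(self):
        rows = [(1, 1, 9, "TBAR", 0, 0, 0, "PB", 1)]
        counts = tbar_counts(table(rows), {1, 2}, "PB")
        assert counts[2] == 0

    def test_matches_filter_and_count(self):
        rng = np.random.default_rng(11)
        conn = random_table(rng)
        counts = tbar_counts(conn, set(range(1, 9)), "PB")
        for n in range(1, 9):
            expected = conn[(conn["kind"] == "TBAR") & (conn["pre_neuron"] == n)
                            & (conn["compartment"] == "PB")]["weight"].sum()
            assert counts[n] == expected


class TestPairwiseEcdf:
    def test_strengths_1_1_4(self):
        rows = [(1, 1, 10, "TBAR", 0, 0, 0, "PB", 1),
                (2, 2, 10, "TBAR", 0, 0, 0, "PB", 1)] \
            + [(10 + i, 1, 11, "TBAR", 0, 0, 0, "PB", 1) for i in range(4)]
        e = pairwise_strength_ecdf(table(rows), {1, 2}, "PB")
        assert e.set_index("strength")["F"][1] == pytest.approx(2 / 3)
        assert e.set_index("strength")["F"][4] == pytest.approx(1.0)

    def test_single_pair_step(self):
        rows = [(1, 1, 10, "TBAR", 0, 0, 0, "PB", 3)]
        e = pairwise_strength_ecdf(table(rows), {1}, "PB")
        assert e["F"].tolist() == [1.0]

    def test_empty_flagged(self):
        rows = [(1, 1, 10, "TBAR", 0, 0, 0, "EB", 1)]
        with pytest.warns(UserWarning, match="no connection pairs"):
            e = pairwise_strength_ecdf(table(rows), {1}, "PB")
        assert e.empty

    def test_monotone_ends_at_one_matches_brute_force(self):
        rng = np.random.default_rng(21)
        conn = random_table(rng)
        e = pairwise_strength_ecdf(conn, set(range(1, 9)), "EB")
        assert (np.diff(e["F"]) > 0).all()
        assert e["F"].iloc[-1] == pytest.approx(1.0)
        # sort-based brute force
        sub = conn[(conn["compartment"] == "EB")]
        strengths = sorted(sub.groupby(["pre_neuron", "post_neuron"])["weight"]
                           .sum().tolist())
        for _, row in e.iterrows():
            expected = sum(1 for s in strengths if s <= row["strength"]) / len(strengths)
            assert row["F"] == pytest.approx(expected)


class TestSourceExclusivity:
    PART = {"TuBu_s": "DALcl1d", "TuBu_a": "DALcl1d", "TuBu_i": "DALcl2d"}

    def test_exclusive_column(self):
        m = pd.DataFrame({"ER1": [40, 0, 0]},
                         index=["TuBu_s", "TuBu_a", "TuBu_i"])
        assert source_exclusivity(m, self.PART)["ER1"] == 1.0

    def test_mixed_column(self):
        m = pd.DataFrame({"ER1": [30, 0, 10]},
                         index=["TuBu_s", "TuBu_a", "TuBu_i"])
        assert source_exclusivity(m, self.PART)["ER1"] == pytest.approx(0.75)

    def test_zero_column_is_na(self):
        m = pd.DataFrame({"ER1": [0, 0, 0]},
                         index=["TuBu_s", "TuBu_a", "TuBu_i"])
        assert np.isnan(source_exclusivity(m, self.PART)["ER1"])


class TestUpstreamShading:
    def test_max_and_half_max(self):
        rows = [(i, 1, 5, "TBAR", 0, 0, 0, "BUs", 1) for i in range(10)] \
            + [(20 + i, 1, 6, "TBAR", 0, 0, 0, "BUs", 1) for i in range(5)]
        totals = upstream_totals(table(rows), {1})
        out = table([(100, 5, 9, "TBAR", 0, 0, 0, "EBa", 1),
                     (101, 6, 9, "TBAR", 0, 0, 0, "EBa", 1)])
        shaded = synapse_weight_by_upstream(out, totals)
        w = shaded.set_index("pre_neuron")["shade_weight"]
        assert w[5] == pytest.approx(1.0)
        assert w[6] == pytest.approx(0.5)

    def test_missing_upstream_flagged_zero(self):
        totals = pd.Series({5: 10})
        out = table([(1, 7, 9, "TBAR", 0, 0, 0, "EBa", 1)])
        shaded = synapse_weight_by_upstream(out, totals)
        assert shaded["shade_weight"].iloc[0] == 0.0
        assert shaded["no_upstream"].iloc[0]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        conn = random_table(rng, n=200)
        totals = upstream_totals(conn, {1, 2, 3})
        out = conn[conn["pre_neuron"].isin({4, 5})]
        a = synapse_weight_by_upstream(out, totals)
        b = synapse_weight_by_upstream(out.sample(frac=1, random_state=0), totals)
        merged = a.set_index("synapse_id")["shade_weight"]
        for sid, w in b.set_index("synapse_id")["shade_weight"].items():
            assert merged[sid] == w
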