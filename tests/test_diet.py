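import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophimix import diet


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["stomach_id", "predator_group", "prey_taxon", "prey_category",
                 "digestion_level", "weight", "method"],
    )


class TestGroupToCategory:
    def test_scarinae_split_on_and_off(self):
        rec = _records([("s1", "g", "Scarus ghobban", None, 2, 1.0, "visual")])
        on = diet.group_to_category(rec, labridae_split=True)
        assert on["prey_category"].iloc[0] == "Labridae (Scarinae)"
        off = diet.group_to_category(rec, labridae_split=False)
        assert off["prey_category"].iloc[0] == "Labridae"

    def test_crustacean_prey_grouped_to_crustacea(self):
        rec = _records([("s1", "g", "Alpheus sp.", None, 3, np.nan, "visual")])
        out = diet.group_to_category(rec)
        assert out["prey_category"].iloc[0] == "Crustacea"

    def test_unknown_taxon_routed_and_reported(self):
        rec = _records([("s1", "g", "Mystery fish", None, 3, np.nan, "visual")])
        out = diet.group_to_category(rec)
        assert out["prey_category"].iloc[0] == "Unknown"
        assert out.attrs["unknown_taxa"] == ["Mystery fish"]


class TestComputeIndices:
    def test_single_category_single_stomach_all_100(self):
        rec = _records([("s1", "g", "x", "Caesionidae", 1, 2.5, "visual")])
        out = diet.compute_indices(rec)
        row = out.loc["Caesionidae"]
        assert row["percent_N"] == row["percent_O"] == 100.0
        assert row["percent_W"] == row["percent_IRI"] == 100.0

    def test_percent_sums(self, table2_records):
        out = diet.compute_indices(table2_records)
        assert out["percent_N"].sum() == pytest.approx(100.0, abs=0.1)
        # %O has no sum constraint but each entry is a valid percentage
        assert (out["percent_O"] <= 100.0).all()

    def test_table2_percent_n_and_o_rows(self, table2_records):
        """Item counts k over 38 give %N = 100k/38; occurrences over 31
        stomachs give %O = 100k/31 — matching the published table."""
        out = diet.compute_indices(table2_records).round(1)
        expected_n = {
            "Caesionidae": 26.3, "Labridae": 23.7, "Pomacentridae": 23.7,
            "Labridae (Scarinae)": 5.3, "Acanthuridae": 2.6, "Serranidae": 5.3,
            "Siganidae": 2.6, "Crustacea": 5.3, "Gobiidae": 2.6, "Apogonidae": 2.6,
        }
        expected_o = {
            "Caesionidae": 32.3, "Labridae": 25.8, "Pomacentridae": 19.4,
            "Labridae (Scarinae)": 6.5, "Acanthuridae": 3.2, "Serranidae": 6.5,
            "Siganidae": 3.2, "Crustacea": 6.5, "Gobiidae": 3.2, "Apogonidae": 3.2,
        }
        for fam, v in expected_n.items():
            assert out.loc[fam, "percent_N"] == v
        for fam, v in expected_o.items():
            assert out.loc[fam, "percent_O"] == v
        assert out.attrs["n_items"] == 38
        assert out.attrs["n_stomachs_with_identifiable_prey"] == 31

    def test_no_weighed_records_warns_and_drops_w_iri(self, table2_records):
        with pytest.warns(UserWarning, match="%W and %IRI unavailable"):
            out = diet.compute_indices(table2_records)
        assert out["percent_W"].isna().all()
        assert out["percent_IRI"].isna().all()
        assert out["percent_N"].notna().all()

    def test_iri_formula_on_weighted_records(self):
        rec = _records(
            [
                ("s1", "g", "a", "A", 1, 3.0, "visual"),
                ("s1", "g", "b", "B", 2, 1.0, "visual"),
                ("s2", "g", "a", "A", 1, 2.0, "visual"),
            ]
        )
        out = diet.compute_indices(rec)
        # A: %N=2/3, %O=2/2, %W=5/6 ; B: %N=1/3, %O=1/2, %W=1/6
        iri_a = (200 / 3 + 500 / 6) * 100.0
        iri_b = (100 / 3 + 100 / 6) * 50.0
        assert out.loc["A", "percent_IRI"] == pytest.approx(100 * iri_a / (iri_a + iri_b))

    def test_unidentifiable_records_excluded_from_bases(self):
        rec = _records(
            [
                ("s1", "g", "a", "A", 1, 1.0, "visual"),
                ("s2", "g", "??", "Unknown", 4, np.nan, "visual"),
            ]
        )
        out = diet.compute_indices(rec)
        assert out.attrs["n_stomachs_with_identifiable_prey"] == 1
        assert "Unknown" not in out.index


class TestComposition:
    def test_two_equal_counts(self):
        comp = diet.composition_from_counts({"A": 1, "B": 1})
        assert comp["A"] == comp["B"] == 0.5

    def test_lumping_below_threshold_into_others(self):
        comp = diet.composition_from_counts(
            {"A": 60, "B": 36, "C": 4}, lump_threshold=0.05
        )
        assert "C" not in comp.index
        assert comp["Others"] == pytest.approx(0.04)
        assert comp.sum() == pytest.approx(1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            diet.composition_from_counts({})

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8).filter(
            lambda c: sum(c) > 0
        ),
        thr=st.floats(min_value=0.01, max_value=0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_lumping_preserves_total(self, counts, thr):
        data = {f"c{i}": c for i, c in enumerate(counts)}
        comp = diet.composition_from_counts(data, lump_threshold=thr)
        assert comp.sum() == pytest.approx(1.0)


class TestAccumulationCurve:
    def test_identical_stomachs_constant_curve(self):
        pres = pd.DataFrame(np.ones((5, 1), dtype=int))
        out = diet.accumulation_curve(pres, n_permutations=20, seed=0)
        np.testing.assert_allclose(out["mean_new_taxa"], 1.0)

    def test_unique_families_identity_line(self):
        pres = pd.DataFrame(np.eye(6, dtype=int))
        out = diet.accumulation_curve(pres, n_permutations=20, seed=0)
        np.testing.assert_allclose(out["mean_new_taxa"], np.arange(1, 7))

    def test_matches_exact_order_enumeration(self):
        # 3 stomachs: {A}, {A,B}, {B} — exact expectation by enumerating 3! orders
        pres = pd.DataFrame(
            [[1, 0], [1, 1], [0, 1]], index=["s1", "s2", "s3"], columns=["A", "B"]
        )
        mat = pres.to_numpy(dtype=bool)
        n = 3
        exact = np.zeros(n)
        orders = list(itertools.permutations(range(n)))
        for order in orders:
            seen = np.cumsum(mat[list(order)], axis=0) > 0
            exact += seen.sum(axis=1)
        exact /= len(orders)
        out = diet.accumulation_curve(pres, n_permutations=4000, seed=1)
        # Monte-Carlo error at B=4000 permutations: 3 sigma < 0.03
        np.testing.assert_allclose(out["mean_new_taxa"], exact, atol=0.03)

    def test_curve_nondecreasing_and_bounded(self, scenario):
        from trophimix import synthetic

        rec = synthetic.simulate_stomachs(scenario, 40)
        pres = diet.presence_matrix(rec)
        out = diet.accumulation_curve(pres, n_permutations=100, seed=2)
        m = out["mean_new_taxa"].to_numpy()
        assert (np.diff(m) >= -1e-12).all()
        assert m[-1] == pres.shape[1]  # reaches total distinct families
        # bounded by the total family count and by the richest possible
        # prefix (k stomachs can expose at most k * max-families-per-stomach)
        per_stomach_max = pres.sum(axis=1).max()
        assert (m <= pres.shape[1] + 1e-12).all()
        assert (m <= out["k"] * per_stomach_max + 1e-12).all()

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            diet.accumulation_curve(pd.DataFrame([[1]]), n_permutations=0)
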