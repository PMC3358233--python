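import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

import reference_cube as rc
from immunomart.errors import QueryError
from immunomart.olap import (ALL, CubeQuery, aggregate, compute_measures,
                             drill_down, drill_through, export_pivot,
                             import_pivot_csv, pivot_to_json_obj,
                             validate_pivot_json)
from immunomart.warehouse import (AliquotFact, AnalyteRecord, PersonRecord,
                                  SampleRecord, SourceRecord, create_store)


@pytest.fixture()
def tiny_store():
    """20 hand-placed facts: 2 analytes x 2 genders x mixed units."""
    store = create_store(":memory:")
    p_m = store.upsert_person(PersonRecord("P1", gender="male"))
    p_f = store.upsert_person(PersonRecord("P2", gender="female"))
    s_m = store.upsert_sample(SampleRecord("S1", day=0), person_key=p_m)
    s_f = store.upsert_sample(SampleRecord("S2", day=7), person_key=p_f)
    src = store.insert_source(SourceRecord(
        "b.csv", "h", "2011-01-01", "Human Luminex 51plex", lot="H51-1"))
    a1 = store.upsert_analyte(AnalyteRecord("IL-6", "luminex"))
    a2 = store.upsert_analyte(AnalyteRecord("VEGF", "luminex"))
    facts = []
    vals = iter(range(1, 21))
    for akey, units in ((a1, "MFI"), (a2, "MFI")):
        for skey in (s_m, s_f):
            for i in range(5):
                v = next(vals)
                facts.append(AliquotFact(
                    f"ALQ{akey}-{skey}-{i}", akey, src, float(v), units,
                    sample_key=skey, tissue="cryopreserved serum"))
    store.insert_facts(facts)
    yield store
    store.close()


class TestComputeMeasures:
    def test_empty_multiset(self):
        out = compute_measures([])
        assert out["n"] == 0
        assert all(out[m] is None for m in
                   ("mean", "median", "min", "max", "sd", "cv"))

    def test_two_point_symmetry(self):
        out = compute_measures([2, 4])
        assert (out["mean"], out["median"], out["min"], out["max"]) == \
            (3, 3, 2, 4)

    def test_even_median_is_mean_of_central_pair(self):
        assert compute_measures([1, 2, 10, 100])["median"] == 6.0

    def test_sd_needs_two_values_cv_needs_nonzero_mean(self):
        assert compute_measures([5.0])["sd"] is None
        assert compute_measures([-1.0, 1.0])["cv"] is None

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6, width=32,
                              allow_nan=False), min_size=1, max_size=1000))
    def test_matches_naive_reference(self, values):
        got = compute_measures(values)
        want = rc.reference_measures(values)
        assert got["n"] == want["n"]
        for m in ("mean", "median", "min", "max", "sd"):
            if want[m] is None:
                assert got[m] is None
            else:
                assert got[m] == pytest.approx(want[m], rel=1e-9, abs=1e-12)


class TestAggregate:
    def test_single_fact_single_cell(self, mem_store):
        p = mem_store.upsert_person(PersonRecord("P1", gender="female"))
        s = mem_store.upsert_sample(SampleRecord("S1"), person_key=p)
        src = mem_store.insert_source(SourceRecord(
            "b.csv", "h", "2011", "MSD 4plex"))
        a = mem_store.upsert_analyte(AnalyteRecord("IL-6", "msd"))
        mem_store.insert_facts(
            [AliquotFact("A1", a, src, 42.0, "pg/ml", sample_key=s)])
        result = aggregate(mem_store, CubeQuery(rows=["Gender"]))
        cell = result.cell(("female", "pg/ml"), ())
        assert cell["n"] == 1 and cell["mean"] == 42.0

    def test_cells_match_flat_reference(self, tiny_store, tmp_path):
        frame = rc.reference_frame(tiny_store, tmp_path)
        q = CubeQuery(rows=["Analyte"], columns=["Gender"],
                      measures=list(rc.reference_measures([])))
        q.measures = ["n", "mean", "median", "min", "max", "sd", "cv"]
        result = aggregate(tiny_store, q)
        assert rc.assert_cells_match(result, frame) > 4

    def test_filters_restrict_and_conserve(self, tiny_store):
        full = aggregate(tiny_store, CubeQuery(rows=["Analyte"]))
        filt = aggregate(tiny_store, CubeQuery(
            rows=["Analyte"], filters=[("Gender", ["female"])]))
        n_full = full.cell((ALL, "MFI"), ())["n"]
        n_f = filt.cell((ALL, "MFI"), ())["n"]
        assert n_full == 20 and n_f == 10

    def test_filter_axis_commutation(self, tiny_store):
        filtered = aggregate(tiny_store, CubeQuery(
            rows=["Analyte"], filters=[("Gender", ["female"])]))
        axed = aggregate(tiny_store, CubeQuery(rows=["Analyte"],
                                               columns=["Gender"]))
        for rt in filtered.leaf_rows():
            a = filtered.cell(rt, ())
            b = axed.cell(rt, ("female",))
            assert a["n"] == b["n"] and a["mean"] == b["mean"]

    def test_unmapped_facts_surface_as_member(self, tiny_store):
        src = tiny_store.execute(
            "SELECT source_key FROM source").fetchone()[0]
        a = tiny_store.upsert_analyte(AnalyteRecord("TNF", "luminex"))
        tiny_store.insert_facts(
            [AliquotFact("LOOSE", a, src, 7.0, "MFI")])  # no sample
        result = aggregate(tiny_store, CubeQuery(rows=["Gender"]))
        cell = result.cell(("(unmapped)", "MFI"), ())
        assert cell["n"] == 1

    def test_units_never_pooled(self, tiny_store):
        src = tiny_store.execute("SELECT source_key FROM source").fetchone()[0]
        a = tiny_store.execute(
            "SELECT analyte_key FROM analyte WHERE analyte_name='IL-6'"
        ).fetchone()[0]
        tiny_store.insert_facts(
            [AliquotFact("PGML", a, src, 3.0, "pg/ml", stim="IL-6")])
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"]))
        # even the roll-up rows carry a concrete units member
        for rt, ct in result.cells:
            detail = drill_through(tiny_store, result, rt, ct)
            assert detail["Units"].nunique() == 1

    def test_unknown_level_and_member_rejected(self, tiny_store):
        with pytest.raises(QueryError):
            aggregate(tiny_store, CubeQuery(rows=["Flavor"]))
        with pytest.raises(QueryError):
            aggregate(tiny_store, CubeQuery(
                rows=["Analyte"], filters=[("Gender", ["robot"])]))
        with pytest.raises(QueryError):
            aggregate(tiny_store, CubeQuery(rows=["Gender"],
                                            columns=["Gender"]))

    def test_invariant_min_le_median_le_max(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(
            rows=["Analyte", "Gender"], measures=["n", "median", "min",
                                                  "max"]))
        for cell in result.cells.values():
            if cell["n"] >= 1:
                assert cell["min"] <= cell["median"] <= cell["max"]


class TestRollup:
    def test_child_counts_sum_to_parent(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte", "Gender"]))
        for units in ("MFI",):
            parent = result.cell((ALL, ALL, units), ())["n"]
            leaves = [c["n"] for (rt, _), c in result.cells.items()
                      if rt[0] != ALL and rt[1] != ALL and rt[2] == units]
            assert parent == sum(leaves)

    def test_parent_mean_is_weighted_child_mean(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte", "Gender"]))
        parent = result.cell((ALL, ALL, "MFI"), ())
        num = den = 0.0
        for (rt, _), c in result.cells.items():
            if rt[0] != ALL and rt[1] != ALL and rt[2] == "MFI":
                num += c["n"] * c["mean"]
                den += c["n"]
        assert parent["mean"] == pytest.approx(num / den, rel=1e-12)

    def test_drill_down_appends_child_level(self, tiny_store):
        top = aggregate(tiny_store, CubeQuery(rows=["Assay"]))
        down = drill_down(tiny_store, top, "rows", "Human Luminex 51plex")
        assert down.query.rows == ["Assay", "Analyte"]
        analytes = {rt[1] for rt in down.leaf_rows()}
        assert analytes == {"IL-6", "VEGF"}
        # parent subtotal retained
        assert down.cell(("Human Luminex 51plex", ALL, "MFI"), ()) is not None

    def test_drill_down_leaf_is_noop_with_notice(self, tiny_store):
        res = aggregate(tiny_store, CubeQuery(rows=["Gender"]))
        out = drill_down(tiny_store, res, "rows", "female")
        assert out.notice is not None


class TestDrillThrough:
    def test_row_count_equals_cell_n(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"],
                                                 columns=["Gender"]))
        for (rt, ct), cell in result.cells.items():
            detail = drill_through(tiny_store, result, rt, ct)
            assert len(detail) == cell["n"]

    def test_reaggregation_reproduces_mean_bit_exact(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"],
                                                 columns=["Gender"]))
        for (rt, ct), cell in result.cells.items():
            detail = drill_through(tiny_store, result, rt, ct)
            assert compute_measures(detail["readout"])["mean"] == cell["mean"]

    def test_empty_cell_gives_empty_table(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"]))
        with pytest.raises(QueryError):
            drill_through(tiny_store, result, ("nonexistent", "MFI"), ())

    def test_detail_carries_context_columns(self, tiny_store):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"]))
        detail = drill_through(tiny_store, result,
                               result.leaf_rows()[0], ())
        for col in ("person_id_ext", "sample_id_ext", "Day", "readout",
                    "Units", "Lot", "Document"):
            assert col in detail.columns


class TestExport:
    def test_csv_round_trip(self, tiny_store, tmp_path):
        result = aggregate(tiny_store, CubeQuery(
            rows=["Analyte"], columns=["Gender"],
            measures=["n", "mean", "median", "min", "max"]))
        p = tmp_path / "pivot.csv"
        export_pivot(result, p, format="csv")
        cells = import_pivot_csv(p, n_row_levels=len(result.row_levels))
        for (rt, ct), cell in result.cells.items():
            for m in ("n", "mean", "median", "min", "max"):
                assert cells[(rt, ct)][m] == cell[m]

    def test_json_export_validates_against_schema(self, tiny_store,
                                                  tmp_path):
        result = aggregate(tiny_store, CubeQuery(rows=["Analyte"],
                                                 columns=["Gender"]))
        p = tmp_path / "pivot.json"
        export_pivot(result, p, format="json")
        obj = json.loads(p.read_text())
        validate_pivot_json(obj)  # raises on violation
        bad = dict(obj)
        bad.pop("cells")
        with pytest.raises(QueryError, match="cells"):
            validate_pivot_json(bad)

    def test_single_cell_pivot_exports_one_data_row(self, mem_store,
                                                    tmp_path):
        src = mem_store.insert_source(SourceRecord(
            "b.csv", "h", "2011", "MSD 4plex"))
        a = mem_store.upsert_analyte(AnalyteRecord("IL-6", "msd"))
        mem_store.insert_facts([AliquotFact("A1", a, src, 1.0, "pg/ml")])
        result = aggregate(mem_store, CubeQuery(rows=["Units"]))
        p = tmp_path / "one.csv"
        export_pivot(result, p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 2  # header + 1 data row

    def test_query_json_round_trip(self):
        q = CubeQuery(rows=["Analyte"], columns=["Gender"],
                      filters=[("Day", ["0", "7"])], measures=["n", "mean"])
        q2 = CubeQuery.from_dict(json.loads(q.to_json()))
        assert q2.to_dict() == q.to_dict()


class TestOracleBattery:
    def test_random_stores_random_queries_match_reference(self, tmp_path):
        rng = np.random.default_rng(2026)
        for trial in range(5):
            store = rc.random_store(rng, n_facts=int(rng.integers(50, 300)))
            d = tmp_path / f"t{trial}"
            d.mkdir()
            frame = rc.reference_frame(store, d)
            for _ in range(3):
                q = rc.random_query(rng, frame)
                result = aggregate(store, q)
                rc.assert_cells_match(result, frame)
            store.close()
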