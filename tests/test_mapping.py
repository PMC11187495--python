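from datetime import date

import pytest

from ddiconcord.codes import CodeSystem, validate_code
from ddiconcord.mapping import (
    Category,
    ConflictReport,
    CrosswalkRow,
    KeggDrugRecord,
    NdcRxcuiLink,
    RxcuiDrugbankLink,
    Scope,
    SchemaError,
    VerificationStatus,
    build_yj_rxcui,
    build_yj_rxcui_db,
    detect_ingredient_mismatch,
    filter_allergen_extracts,
    load_kegg_drug_table,
    normalize_ingredient_name,
    resolve_ndc_to_rxcui,
    resolve_rxcui_to_drugbank,
)


def _code(system, value):
    return validate_code(system, value)


def _record(d, yjs, ndcs, name="atorvastatin", category=Category.STANDARD):
    return KeggDrugRecord(
        d_number=_code(CodeSystem.KEGG_D, d),
        yj_codes=frozenset(_code(CodeSystem.YJ, y) for y in yjs),
        ndcs=frozenset(_code(CodeSystem.NDC, n) for n in ndcs),
        category=category,
        ingredient_name=name,
    )


def _link(ndc, rxcui, active=True, name="atorvastatin", inact=None):
    return NdcRxcuiLink(
        ndc=_code(CodeSystem.NDC, ndc),
        rxcui=_code(CodeSystem.RXCUI, rxcui),
        active=active,
        inactivation_date=inact,
        ingredient_name=name,
    )


# A recycled NDC whose history carries an active statin link and an
# inactivated anticonvulsant link.
RECYCLED_NDC_LINKS = [
    _link("71335-1641", "83367", active=True, name="atorvastatin"),
    _link("71335-1641", "25480", active=False, name="gabapentin",
          inact=date(2020, 9, 1)),
]


class TestNdcHistory:
    def test_inactive_links_excluded(self):
        ndc = _code(CodeSystem.NDC, "71335-1641")
        got = resolve_ndc_to_rxcui(ndc, RECYCLED_NDC_LINKS)
        assert {c.value for c in got} == {"83367"}

    def test_absent_ndc_resolves_empty(self):
        got = resolve_ndc_to_rxcui(_code(CodeSystem.NDC, "99999-0001"), RECYCLED_NDC_LINKS)
        assert got == frozenset()

    def test_two_active_links_both_returned_and_flagged(self):
        links = [
            _link("55555-0001", "100", name="a"),
            _link("55555-0001", "200", name="b"),
        ]
        report = ConflictReport()
        got = resolve_ndc_to_rxcui(_code(CodeSystem.NDC, "55555-0001"), links, report)
        assert {c.value for c in got} == {"100", "200"}
        assert len(report.multi_rxcui_ndcs) == 1


class TestAllergenFilter:
    def test_allergen_records_removed(self):
        recs = [
            _record("D00001", ["1000000A0001"], []),
            _record("D00002", ["1000001A0001"], [], category=Category.ALLERGEN_EXTRACT),
            _record("D00003", ["1000002A0001"], []),
        ]
        kept = filter_allergen_extracts(recs)
        assert [r.d_number.value for r in kept] == ["D00001", "D00003"]
        assert filter_allergen_extracts(kept) == kept  # identity on clean input
        assert filter_allergen_extracts(
            [recs[1]]
        ) == []


class TestIngredientMismatch:
    def test_cross_ingredient_edge_flagged(self):
        # a mononitrate entry whose NDC resolves to a beta blocker
        rec = _record("D00630", ["1000000A0001"], ["17478-189"],
                      name="isosorbide mononitrate")
        links = [_link("17478-189", "10600", name="timolol")]
        report = detect_ingredient_mismatch([rec], links)
        assert len(report.ingredient_mismatches) == 1
        d, ndc, kegg_name, rx_name = report.ingredient_mismatches[0]
        assert d.value == "D00630" and ndc.value == "174780189"

    @pytest.mark.parametrize("kegg_name, rx_name", [
        ("Timolol", "timolol"),                    # case only
        ("metoprolol tartrate", "metoprolol"),     # salt token stripped
        ("timolol", "timolol"),
    ])
    def test_equivalent_notations_not_flagged(self, kegg_name, rx_name):
        rec = _record("D00001", ["1000000A0001"], ["17478-189"], name=kegg_name)
        links = [_link("17478-189", "10600", name=rx_name)]
        report = detect_ingredient_mismatch([rec], links)
        assert report.ingredient_mismatches == []

    def test_salt_list_is_conservative(self):
        # 'mononitrate' is ingredient identity, not a listed salt token
        assert normalize_ingredient_name("isosorbide mononitrate") == "isosorbide mononitrate"
        assert normalize_ingredient_name("Metoprolol Tartrate") == "metoprolol"


class TestBuildYjRxcui:
    def test_basic_row_and_inactive_only_record(self):
        rec_ok = _record("D00001", ["1000000A0001"], ["71335-1641"])
        rec_dead = _record("D00002", ["1000001A0001"], ["22222-0001"], name="gabapentin")
        links = RECYCLED_NDC_LINKS + [
            _link("22222-0001", "25480", active=False, name="gabapentin",
                  inact=date(2020, 9, 1)),
        ]
        rows = build_yj_rxcui([rec_ok, rec_dead], links)
        assert [(r.yj.value, r.rxcui.value) for r in rows] == [("1000000A0001", "83367")]
        assert rows[0].verification_status is VerificationStatus.UNVERIFIED

    def test_mismatched_edge_yields_inaccurate_row(self):
        rec = _record("D00630", ["1000000A0001"], ["17478-189"],
                      name="isosorbide mononitrate")
        links = [_link("17478-189", "10600", name="timolol")]
        rows = build_yj_rxcui([rec], links)
        assert len(rows) == 1
        assert rows[0].verification_status is VerificationStatus.INACCURATE

    def test_monotone_in_active_links(self):
        rec = _record("D00001", ["1000000A0001", "1000000B0001"], ["71335-1641", "33333-0001"])
        base_links = [_link("71335-1641", "83367")]
        rows_before = {(r.yj.value, r.rxcui.value) for r in build_yj_rxcui([rec], base_links)}
        more_links = base_links + [_link("33333-0001", "25480", name="atorvastatin")]
        rows_after = {(r.yj.value, r.rxcui.value) for r in build_yj_rxcui([rec], more_links)}
        assert rows_before <= rows_after

    def test_no_crosswalk_row_references_inactive_link(self, small_bundle, run_pipeline):
        """Audit on a whole synthetic bundle: every (yj, rxcui) row is backed
        by at least one active link."""
        art, _ = run_pipeline(small_bundle)
        active = {
            (l.ndc.value, l.rxcui.value) for l in art["links"] if l.active
        }
        ndc_by_yj = {}
        for rec in art["records"]:
            for yj in rec.yj_codes:
                ndc_by_yj.setdefault(yj.value, set()).update(n.value for n in rec.ndcs)
        for row in art["crosswalk"]:
            assert any(
                (ndc, row.rxcui.value) in active
                for ndc in ndc_by_yj.get(row.yj.value, ())
            )


class TestResolveDrugbank:
    def _link(self, rxcui, dbid, rx_name, db_name):
        return RxcuiDrugbankLink(
            rxcui=_code(CodeSystem.RXCUI, rxcui),
            drugbank_id=_code(CodeSystem.DRUGBANK, dbid),
            name_rxnorm=rx_name,
            name_drugbank=db_name,
        )

    def test_single_candidate_maps_directly(self):
        resolved, flagged = resolve_rxcui_to_drugbank(
            [self._link("83367", "DB01076", "atorvastatin", "atorvastatin")]
        )
        assert resolved["83367"].value == "DB01076"
        assert flagged == []

    def test_one_to_two_resolves_by_name_match(self):
        links = [
            self._link("83367", "DB91076", "atorvastatin", "atorvastatin calcium variant"),
            self._link("83367", "DB01076", "atorvastatin", "atorvastatin"),
        ]
        resolved, flagged = resolve_rxcui_to_drugbank(links)
        assert resolved["83367"].value == "DB01076"
        assert flagged == []

    def test_undecidable_tie_keeps_smallest_and_flags(self):
        report = ConflictReport()
        links = [
            self._link("83367", "DB91076", "atorvastatin", "atorvastatin"),
            self._link("83367", "DB01076", "atorvastatin", "atorvastatin"),
        ]
        resolved, flagged = resolve_rxcui_to_drugbank(links, report=report)
        assert resolved["83367"].value == "DB01076"
        assert [c.value for c in flagged] == ["83367"]
        assert len(report.drugbank_ties) == 1

    def test_output_is_functional(self, small_bundle):
        from ddiconcord.mapping import load_rxcui_drugbank_table  # noqa: F401
        links = [
            self._link(str(100 + i), f"DB{10000 + i:05d}", f"n{i}", f"n{i}")
            for i in range(20)
        ] + [self._link("105", "DB99999", "n5", "other")]
        resolved, _ = resolve_rxcui_to_drugbank(links)
        assert len(resolved) == 20  # one entry per rxcui


class TestBuildYjRxcuiDb:
    def _rows(self):
        return [
            CrosswalkRow(_code(CodeSystem.YJ, "1000000A0001"), _code(CodeSystem.RXCUI, "100")),
            CrosswalkRow(_code(CodeSystem.YJ, "1000001A0001"), _code(CodeSystem.RXCUI, "200")),
            CrosswalkRow(_code(CodeSystem.YJ, "1000002A0001"), _code(CodeSystem.RXCUI, "300")),
        ]

    def test_scope_filter_keeps_oral_and_injectable(self):
        scope = {"1000000A0001": Scope.ORAL, "1000001A0001": Scope.INJECTABLE,
                 "1000002A0001": Scope.OTHER}
        db_map = {"100": _code(CodeSystem.DRUGBANK, "DB00001"),
                  "200": _code(CodeSystem.DRUGBANK, "DB00002"),
                  "300": _code(CodeSystem.DRUGBANK, "DB00003")}
        out = build_yj_rxcui_db(self._rows(), db_map, scope)
        assert [r.yj.value for r in out] == ["1000000A0001", "1000001A0001"]

    def test_inaccurate_rows_dropped_unless_included(self):
        rows = self._rows()
        rows[0].verification_status = VerificationStatus.INACCURATE
        scope = {r.yj.value: Scope.ORAL for r in rows}
        out = build_yj_rxcui_db(rows, {}, scope)
        assert all(r.verification_status is not VerificationStatus.INACCURATE for r in out)
        out_incl = build_yj_rxcui_db(rows, {}, scope, include_inaccurate=True)
        assert len(out_incl) == len(rows)

    def test_unresolved_rxcui_kept_with_null_id(self):
        rows = self._rows()[:1]
        scope = {"1000000A0001": Scope.ORAL}
        report = ConflictReport()
        out = build_yj_rxcui_db(rows, {}, scope, report=report)
        assert out[0].drugbank_id is None
        assert [c.value for c in report.unresolved_drugbank] == ["100"]


class TestLoaders:
    def test_kegg_loader_roundtrip(self, tmp_path):
        p = tmp_path / "kegg_drug.tsv"
        p.write_text(
            "d_number\tyj_code\tndc\tcategory\tingredient_name\n"
            "D00001\t1000000A0001\t71335-1641\tSTANDARD\tatorvastatin\n"
            "D00001\t1000000B0001\t\tSTANDARD\tatorvastatin\n"
            "D00002\t\t\tALLERGEN_EXTRACT\tpollen extract\n"
        )
        recs = load_kegg_drug_table(p)
        assert len(recs) == 2
        first = next(r for r in recs if r.d_number.value == "D00001")
        assert len(first.yj_codes) == 2 and len(first.ndcs) == 1

    def test_malformed_code_error_names_row(self, tmp_path):
        p = tmp_path / "kegg_drug.tsv"
        p.write_text(
            "d_number\tyj_code\tndc\tcategory\tingredient_name\n"
            "D00001\tTOOSHORT\t\tSTANDARD\tx\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            load_kegg_drug_table(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "kegg_drug.tsv"
        p.write_text("d_number\tyj_code\n")
        with pytest.raises(SchemaError, match="ndc"):
            load_kegg_drug_table(p)

    def test_empty_file_with_header_loads_empty(self, tmp_path):
        p = tmp_path / "kegg_drug.tsv"
        p.write_text("d_number\tyj_code\tndc\tcategory\tingredient_name\n")
        assert load_kegg_drug_table(p) == []
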