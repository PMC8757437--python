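"""Parsing and evaluation of the metastatement language."""

import math

import pytest

from confmeta.metastatement import (
    Binary,
    Call,
    Compare,
    KeyExtract,
    KeyIndex,
    Literal,
    MetaRef,
    Slice,
    StatementError,
    evaluate,
    parse_statement,
    regex_subtract,
    slice_by_value,
    unparse,
)
from confmeta.sdf_core import ABSENT, Atom, ConformationRecord, Ensemble, MetaValue, Molfile
from tests import oracles


def make_ensemble(groups: dict[str, list[dict]]) -> Ensemble:
    """Build a minimal one-atom-per-record ensemble with given metadata."""
    records = []
    for name, confs in groups.items():
        for meta in confs:
            mol = Molfile(
                name,
                ["", ""],
                "  1  0  0  0  0  0  0  0  0  0999 V2000",
                [Atom(1, "C", 0.0, 0.0, 0.0,
                      "    0.0000    0.0000    0.0000 C   0")],
                [],
                ["M  END"],
            )
            mvs = {k: MetaValue.of(v, k) for k, v in meta.items()}
            records.append(ConformationRecord(mol, mvs, name, 0))
    return Ensemble(records)


class TestParsing:
    def test_normalization_statement_ast(self):
        ast = parse_statement("score/mmax(score)")
        assert ast == Binary("/", MetaRef("score"), Call("mmax", [MetaRef("score")]))

    def test_slice_statement_ast(self):
        assert parse_statement("glutadist(≤2.5)") == Slice(MetaRef("glutadist"), "≤", 2.5)
        # ASCII digraph synonym
        assert parse_statement("glutadist(<=2.5)") == Slice(MetaRef("glutadist"), "≤", 2.5)

    def test_key_extract_and_index_ast(self):
        assert parse_statement("close_atoms{}") == KeyExtract(MetaRef("close_atoms"))
        assert parse_statement("atom_types(close_atom_nums)") == KeyIndex(
            MetaRef("atom_types"), MetaRef("close_atom_nums")
        )

    def test_precedence(self):
        ast = parse_statement("-a*b+c")
        assert isinstance(ast, Binary) and ast.op == "+"
        ast = parse_statement("a+b<=c*d")
        assert isinstance(ast, Compare) and ast.op == "≤"

    def test_quoted_forms(self):
        assert parse_statement('"odd name"') == MetaRef("odd name")
        assert parse_statement("'lit'") == Literal("lit")

    @pytest.mark.parametrize("bad", ["(a+b", "a+", "a{", "", "a ? b", "pow(a"])
    def test_syntax_errors_carry_offset(self, bad):
        with pytest.raises(StatementError):
            parse_statement(bad)

    @pytest.mark.parametrize(
        "text",
        [
            "score/mmax(score)",
            "glutadist(≤2.5)",
            "close_atoms{}",
            "atom_types(close_atom_nums)",
            "9-log10(IC50_nM)",
            "mrank(TOTAL_SCORE)<=0.3*mcount()",
            "a&b|c",
            "-x*(y+2.5)/pow(z,2)",
            "plants_id-'_entry_x'",
            '"odd name"(=O.3)',
        ],
    )
    def test_parse_unparse_parse_is_identity(self, text):
        ast = parse_statement(text)
        assert parse_statement(unparse(ast)) == ast


class TestArithmetic:
    def test_literal_broadcasts_to_every_record(self):
        ens = make_ensemble({"A": [{}, {}], "B": [{}]})
        assert evaluate("2.5", ens) == [2.5, 2.5, 2.5]

    def test_dict_scalar_division(self):
        ens = make_ensemble({"A": [{"d": {1: 4.0, 2: 6.0}}]})
        assert evaluate("d/2", ens) == [{1: 2.0, 2: 3.0}]

    def test_dict_dict_inner_join(self):
        ens = make_ensemble({"A": [{"a": {1: 4.0, 2: 6.0, 3: 1.0}, "b": {2: 2.0, 3: 4.0, 9: 5.0}}]})
        assert evaluate("a+b", ens) == [{2: 8.0, 3: 5.0}]

    def test_division_by_zero_is_absent_not_crash(self):
        ens = make_ensemble({"A": [{"x": 1.0, "y": 0.0}], "B": [{"x": 1.0, "y": 2.0}]})
        assert evaluate("x/y", ens) == [ABSENT, 0.5]

    def test_string_plus_concatenates_and_other_ops_absent(self):
        ens = make_ensemble({"A": [{"s": "ab", "t": "cd"}]})
        assert evaluate("s+t", ens) == ["abcd"]
        assert evaluate("s*t", ens) == [ABSENT]
        assert evaluate("s*2", ens) == [ABSENT]

    def test_elementwise_matches_oracle_on_random_values(self):
        import numpy as np

        rng = np.random.default_rng(42)
        for _ in range(200):
            kind_a, kind_b = rng.integers(0, 3, size=2)
            if {kind_a, kind_b} == {1, 2}:  # dict-with-list has no defined join
                continue

            def mk(kind):
                n = int(rng.integers(1, 6))
                vals = [float(v) for v in rng.uniform(-5, 5, size=n)]
                if kind == 0:
                    return vals[0]
                if kind == 1:
                    return vals
                return {int(k): v for k, v in zip(rng.choice(20, n, replace=False), vals)}

            a, b = mk(kind_a), mk(kind_b)
            op = ["+", "-", "*", "/"][int(rng.integers(0, 4))]
            ens = make_ensemble({"A": [{"a": a, "b": b}]})
            got = evaluate(f"a{op}b", ens)[0]
            want = oracles.elementwise_oracle(op, a, b)
            if want is None:
                assert got is ABSENT
            elif isinstance(want, dict):
                assert got.keys() == want.keys()
                for k in want:
                    assert got[k] == pytest.approx(want[k])
            else:
                assert got == pytest.approx(want)


class TestAbsentPropagation:
    def test_missing_meta_makes_whole_statement_absent(self):
        ens = make_ensemble({"A": [{"x": 1.0}, {}]})
        assert evaluate("x+1", ens) == [2.0, ABSENT]
        assert evaluate("log10(x)+mmax(x)", ens)[1] is ABSENT

    def test_absent_monotonicity(self):
        full = make_ensemble({"A": [{"x": 2.0, "y": 3.0}]})
        poorer = make_ensemble({"A": [{"x": 2.0}]})
        for stmt in ["x+y", "y/mmax(y)", "x*y", "pow(x,y)"]:
            if evaluate(stmt, full)[0] is ABSENT:
                assert evaluate(stmt, poorer)[0] is ABSENT

    def test_logic_presence_semantics(self):
        ens = make_ensemble({"A": [{"x": 0.0, "y": 1.0}, {"y": 1.0}]})
        # present 0.0 is still a value: & keeps it, ABSENT side kills &
        assert evaluate("x&y", ens) == [0.0, ABSENT]
        assert evaluate("x|y", ens) == [0.0, 1.0]


class TestAggregates:
    def test_group_max_normalization(self, full_fixture):
        from confmeta import dataio
        from confmeta.sdf_core import parse_sdfile
        from confmeta.select_transform import rename_records, store_header_as_meta

        ens = parse_sdfile(full_fixture.sdf_text)
        ens = dataio.import_csv(ens, dataio.CsvTable.parse(full_fixture.ranking_csv))
        ens = dataio.import_csv(ens, dataio.CsvTable.parse(full_fixture.corresponding_names_csv))
        ens = rename_records(ens, "OLD_LIGAND_DESCRIPTION")
        res = evaluate("TOTAL_SCORE/mmax(TOTAL_SCORE)", ens)
        assert all(v is not ABSENT and 0 < v <= 1.0 for v in res)
        per_group_max: dict[str, float] = {}
        for rec, v in zip(ens.records, res):
            per_group_max[rec.group_key] = max(per_group_max.get(rec.group_key, 0.0), v)
        assert len(per_group_max) == 99
        assert all(m == 1.0 for m in per_group_max.values())

    def test_mmax_on_singleton_group_is_own_value(self):
        ens = make_ensemble({"A": [{"x": 3.5}]})
        assert evaluate("mmax(x)", ens) == [3.5]

    def test_file_and_group_scope_agree_on_one_group(self):
        ens = make_ensemble({"A": [{"x": 1.0}, {"x": 5.0}, {"x": 3.0}]})
        assert evaluate("max(x)", ens) == evaluate("mmax(x)", ens) == [5.0] * 3

    def test_all_absent_input_is_absent(self):
        ens = make_ensemble({"A": [{}, {}]})
        assert evaluate("mavg(x)", ens) == [ABSENT, ABSENT]

    @pytest.mark.parametrize("name", ["max", "min", "avg", "sum", "mmax", "mmin", "mavg", "msum"])
    def test_aggregates_match_oracle(self, name):
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(25):
            groups = {}
            for g in range(int(rng.integers(1, 5))):
                confs = []
                for _ in range(int(rng.integers(1, 6))):
                    kind = int(rng.integers(0, 4))
                    if kind == 0:
                        confs.append({})  # absent
                    elif kind == 1:
                        confs.append({"x": float(rng.uniform(-10, 10))})
                    elif kind == 2:
                        confs.append({"x": [float(v) for v in rng.uniform(-10, 10, 3)]})
                    else:
                        confs.append({"x": {i + 1: float(v) for i, v in enumerate(rng.uniform(-10, 10, 3))}})
                groups[f"G{g}"] = confs
            ens = make_ensemble(groups)
            got = evaluate(f"{name}(x)", ens)
            per_record = [
                None if "x" not in rec.meta else
                (rec.meta["x"].payload if not isinstance(rec.meta["x"].payload, (list, dict))
                 else rec.meta["x"].payload)
                for rec in ens.records
            ]
            want = oracles.aggregate_oracle(name, per_record, [r.group_key for r in ens.records])
            for g, w in zip(got, want):
                if w is None:
                    assert g is ABSENT
                else:
                    assert g == pytest.approx(w)


class TestSliceAndKeys:
    def test_dict_slice(self):
        assert slice_by_value({3: 2.41, 9: 2.62, 15: 1.97}, "≤", 2.5) == {3: 2.41, 15: 1.97}

    def test_single_failing_slice_is_absent(self):
        assert slice_by_value(3.0, "≤", 2.5) is ABSENT

    def test_pass_all_threshold_is_identity(self):
        d = {1: 5.0, 2: -3.0, 3: 0.0}
        assert slice_by_value(d, "≤", 1e18) == d
        assert slice_by_value(d, ">", 1e18) is ABSENT

    def test_string_equality_slice(self):
        d = {1: "C", 3: "O", 7: "H"}
        assert slice_by_value(d, "=", "O") == {3: "O"}
        assert slice_by_value(d, "≠", "H") == {1: "C", 3: "O"}

    def test_key_extract(self):
        ens = make_ensemble({"A": [{"d": {3: 2.41, 15: 1.97}}, {"d": {8: 1.0}}]})
        assert evaluate("d{}", ens) == [[3, 15], [8]]

    def test_key_extract_non_dict_is_absent(self):
        ens = make_ensemble({"A": [{"d": 5.0}]})
        assert evaluate("d{}", ens) == [ABSENT]

    def test_key_index_restriction(self):
        ens = make_ensemble(
            {"A": [{"types": {1: "C", 3: "O", 7: "H"}, "keys": [3, 7, 99]}]}
        )
        assert evaluate("types(keys)", ens) == [{3: "O", 7: "H"}]

    def test_key_index_empty_is_absent(self):
        ens = make_ensemble({"A": [{"types": {1: "C"}, "keys": [5]}]})
        assert evaluate("types(keys)", ens) == [ABSENT]

    def test_slice_matches_oracle_random(self):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(1, 8))
            d = {int(k) + 1: float(v) for k, v in enumerate(rng.uniform(0, 5, n))}
            op = ["<", "≤", ">", "≥", "=", "≠"][int(rng.integers(0, 6))]
            thr = float(rng.uniform(0, 5))
            got = slice_by_value(dict(d), op, thr)
            want = oracles.slice_oracle(d, op, thr)
            assert (got is ABSENT) == (want is None)
            if want is not None:
                assert got == want


class TestStrings:
    def test_docking_suffix_removal(self):
        assert (
            regex_subtract("CHEMBL100231_entry_00042_conf_01", r"_entry_\d+_conf_\d+")
            == "CHEMBL100231"
        )

    def test_no_match_is_identity(self):
        assert regex_subtract("abc", "z+") == "abc"

    def test_all_matches_removed(self):
        assert regex_subtract("abcabc", "b") == "acac"

    def test_invalid_regex_is_statement_error(self):
        with pytest.raises(StatementError, match="regular expression"):
            regex_subtract("abc", "(")

    def test_matches_independent_splice_oracle(self):
        cases = [
            ("aaabbbccc", "b+"),
            ("x1y22z333", r"\d+"),
            ("CHEMBLSYN5_entry_00123_conf_09", r"_entry_\d+_conf_\d+"),
            ("no-digits", r"\d"),
        ]
        for s, pat in cases:
            assert regex_subtract(s, pat) == oracles.regex_subtract_oracle(s, pat)


class TestAtomAccess:
    def test_confcol_elements_and_coordinates(self, tiny_ens):
        from confmeta.geometry import IgnoreList

        res = evaluate("confcol(4)", tiny_ens, ignore=IgnoreList.none())
        assert res[0] == {1: "O", 2: "H", 3: "H"}
        xs = evaluate("confcol(1)", tiny_ens, ignore=IgnoreList.none())
        assert xs[0] == {1: 0.0, 2: 0.96, 3: -0.24}
        assert xs[1] == {1: 1.0, 2: 2.54, 3: 3.1}

    def test_confcol_honors_ignore_list(self, tiny_ens):
        res = evaluate("confcol(4)", tiny_ens)  # default ignore = {"H"}
        assert res[0] == {1: "O"}

    def test_confcol_out_of_range_is_statement_error(self, tiny_ens):
        with pytest.raises(StatementError, match="out of range"):
            evaluate("confcol(99)", tiny_ens)

    def test_dist_builtin_equals_geometry(self, tiny_ens):
        from confmeta.geometry import IgnoreList, distances_to_point

        res = evaluate("dist(1.0,2.0,3.0)", tiny_ens, ignore=IgnoreList.none())
        for rec, got in zip(tiny_ens.records, res):
            want = distances_to_point(rec, (1.0, 2.0, 3.0), IgnoreList.none())
            assert got == pytest.approx(want)


class TestMath:
    def test_pic50_of_one_nanomolar_is_nine(self):
        ens = make_ensemble({"A": [{"IC50_nM": 1}]})
        assert evaluate("9-log10(IC50_nM)", ens) == [9.0]

    @pytest.mark.parametrize(
        "stmt,val",
        [("log10(1)", 0.0), ("log10(1000)", 3.0), ("sqrt(9)", 3.0), ("abs(-2)", 2), ("pow(2,10)", 1024)],
    )
    def test_math_builtins(self, stmt, val):
        ens = make_ensemble({"A": [{}]})
        assert evaluate(stmt, ens) == [val]

    def test_log_of_nonpositive_is_absent(self):
        ens = make_ensemble({"A": [{"x": -1.0}]})
        assert evaluate("log10(x)", ens) == [ABSENT]
        assert evaluate("ln(0)", ens) == [ABSENT]

    def test_elementwise_over_dict(self):
        ens = make_ensemble({"A": [{"d": {1: 1.0, 2: 100.0}}]})
        assert evaluate("log10(d)", ens) == [{1: 0.0, 2: 2.0}]

    def test_arity_mismatch_is_error(self):
        with pytest.raises(StatementError, match="argument"):
            evaluate("log10(1,2)", make_ensemble({"A": [{}]}))


class TestRanks:
    def test_rank_ordering(self):
        ens = make_ensemble({"A": [{"s": 5.0}, {"s": 3.0}, {"s": 4.0}]})
        assert evaluate("mrank(s)", ens) == [3, 1, 2]

    def test_singleton_group(self):
        ens = make_ensemble({"A": [{"s": 9.9}]})
        assert evaluate("mrank(s)", ens) == [1]
        assert evaluate("mcount()", ens) == [1]

    def test_best_30_percent_cut(self):
        ens = make_ensemble({"A": [{"s": float(i)} for i in range(10)]})
        from confmeta.select_transform import filter_records

        out = filter_records(ens, "mrank(s)<=0.3*mcount()")
        assert len(out) == 3
        assert [r.meta["s"].payload for r in out] == [0.0, 1.0, 2.0]

    def test_ties_broken_by_conf_number(self):
        ens = make_ensemble({"A": [{"s": 1.0}, {"s": 1.0}, {"s": 1.0}]})
        assert evaluate("mrank(s)", ens) == [1, 2, 3]

    def test_rank_matches_oracle_random(self):
        import numpy as np

        rng = np.random.default_rng(3)
        for _ in range(50):
            groups = {
                f"G{g}": [{"s": float(rng.choice([1.0, 2.0, 3.0, 4.5]))}
                          for _ in range(int(rng.integers(1, 7)))]
                for g in range(int(rng.integers(1, 4)))
            }
            ens = make_ensemble(groups)
            got = evaluate("mrank(s)", ens)
            want = oracles.rank_oracle(
                [r.meta["s"].payload for r in ens.records],
                [r.conf_number for r in ens.records],
                [r.group_key for r in ens.records],
            )
            assert got == want
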