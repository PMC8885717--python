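import json
import random

import lxml.html
import pytest

from pubcorpus.fixtures import TableSpec, gen_table
from pubcorpus.tables import (
    TableDocument,
    build_table_json,
    classify_columns,
    grid_from_table_element,
    locate_tables,
    parse_cell,
    process_table,
    read_table_json,
    resolve_headers,
    segment_sections,
    split_subtables,
)
from conftest import run_pipeline  # noqa: F401  (shared helper import path)


def grid_of(table_html: str):
    el = lxml.html.fromstring(table_html)
    table = el if el.tag == "table" else next(iter(el.iter("table")))
    return grid_from_table_element(table)


class TestLocate:
    def test_layout_tables_are_excluded(self, fix_config):
        html = (
            "<html><body>"
            '<div class="table-box"><p class="table-title">Table 1 A</p>'
            "<table><tr><th>h</th></tr><tr><td>1</td></tr></table></div>"
            '<table class="layout"><tr><td>nav</td></tr></table>'
            '<div class="table-box"><p class="table-title">Table 2 B</p>'
            "<table><tr><th>h</th></tr><tr><td>2</td></tr></table></div>'"
            "</body></html>"
        )
        raws = locate_tables(html, fix_config, mode="inline")
        assert [r.number for r in raws] == ["1", "2"]

    def test_table_number_parsed_from_title(self, fix_config):
        html = (
            '<html><body><div class="table-box">'
            '<p class="table-title">Table 3 Clinical characteristics</p>'
            "<table><tr><th>h</th></tr></table></div></body></html>"
        )
        raws = locate_tables(html, fix_config, mode="inline")
        assert raws[0].number == "3"
        assert raws[0].title == "Table 3 Clinical characteristics"


class TestHeaders:
    def test_two_row_header_is_pipe_joined(self):
        grid = grid_of(
            "<table><thead><tr><th>Allele</th></tr><tr><th>frequency</th></tr>"
            "</thead><tbody><tr><td>0.1</td></tr></tbody></table>"
        )
        headers, body = resolve_headers(grid)
        assert headers == ["Allele|frequency"]
        assert len(body) == 1

    def test_spanning_header_replicates_per_column(self):
        grid = grid_of(
            "<table><thead>"
            '<tr><th colspan="2">Cases</th></tr>'
            "<tr><th>n</th><th>%</th></tr>"
            "</thead><tbody><tr><td>5</td><td>10</td></tr></tbody></table>"
        )
        headers, _ = resolve_headers(grid)
        assert headers == ["Cases|n", "Cases|%"]

    def test_single_header_row_is_unchanged(self):
        grid = grid_of(
            "<table><tr><th>a</th><th>b</th></tr>"
            "<tr><td>1</td><td>2</td></tr></table>"
        )
        headers, _ = resolve_headers(grid)
        assert headers == ["a", "b"]


class TestSections:
    def test_super_rows_divide_and_name_sections(self):
        grid = grid_of(
            "<table><tr><th>a</th><th>b</th></tr>"
            '<tr><td colspan="2">Men</td></tr><tr><td>1</td><td>2</td></tr>'
            '<tr><td colspan="2">Women</td></tr><tr><td>3</td><td>4</td></tr>'
            "</table>"
        )
        headers, body = resolve_headers(grid)
        sections = segment_sections(body, headers)
        assert [name for name, _ in sections] == ["Men", "Women"]
        assert [len(rows) for _, rows in sections] == [1, 1]

    def test_no_dividers_gives_one_unnamed_section(self):
        grid = grid_of(
            "<table><tr><th>a</th></tr><tr><td>1</td></tr><tr><td>2</td></tr></table>"
        )
        headers, body = resolve_headers(grid)
        sections = segment_sections(body, headers)
        assert [name for name, _ in sections] == [""]
        assert len(sections[0][1]) == 2

    def test_rowspanning_index_cell_names_its_section(self):
        # 4x3 toy grid: first-column cell spans the two "Cohort A" rows
        grid = grid_of(
            "<table><tr><th>Group</th><th>n</th><th>%</th></tr>"
            '<tr><td rowspan="2">Cohort A</td><td>1</td><td>2</td></tr>'
            "<tr><td>3</td><td>4</td></tr>"
            '<tr><td rowspan="2">Cohort B</td><td>5</td><td>6</td></tr>'
            "<tr><td>7</td><td>8</td></tr>"
            "</table>"
        )
        headers, body = resolve_headers(grid)
        sections = segment_sections(body, headers)
        assert [name for name, _ in sections] == ["Cohort A", "Cohort B"]
        assert len(sections[0][1]) == 2
        # the replicated index value stays in every covered row
        assert [row[0].flat for row in sections[0][1]] == ["Cohort A", "Cohort A"]


class TestColumnTypes:
    def body_of(self, html):
        headers, body = resolve_headers(grid_of(html))
        return body

    def test_majority_numeric_with_missing_marker(self):
        body = self.body_of(
            "<table><tr><th>x</th></tr>"
            "<tr><td>1.2</td></tr><tr><td>0.4</td></tr><tr><td>n/a</td></tr></table>"
        )
        assert classify_columns(body) == ["numerical"]

    def test_digits_plus_letters_is_mixed(self):
        body = self.body_of(
            "<table><tr><th>x</th></tr><tr><td>rs123</td></tr><tr><td>rs456</td></tr></table>"
        )
        assert classify_columns(body) == ["mixed"]

    def test_empty_column_defaults_to_textual(self):
        body = self.body_of(
            "<table><tr><th>x</th><th>y</th></tr><tr><td>1</td><td></td></tr></table>"
        )
        assert classify_columns(body) == ["numerical", "textual"]


class TestSubTables:
    def four_col_body(self, extra_row):
        html = (
            "<table><tr><th>a</th><th>b</th><th>c</th><th>d</th></tr>"
            "<tr><td>1</td><td>2</td><td>3</td><td>4</td></tr>"
            "<tr><td>5</td><td>6</td><td>7</td><td>8</td></tr>"
            f"<tr>{extra_row}</tr>"
            "<tr><td>9</td><td>10</td><td>11</td><td>12</td></tr>"
            "</table>"
        )
        headers, body = resolve_headers(grid_of(html))
        return headers, body

    def test_full_mismatch_row_starts_a_subtable(self):
        headers, body = self.four_col_body(
            "<td>OR</td><td>CI</td><td>P</td><td>Beta</td>"
        )
        types = classify_columns(body)
        blocks = split_subtables(body, types, headers)
        assert len(blocks) == 2
        assert blocks[1][0] == ["OR", "CI", "P", "Beta"]
        assert len(blocks[1][1]) == 1

    def test_exactly_half_mismatch_does_not_split(self):
        headers, body = self.four_col_body(
            "<td>OR</td><td>CI</td><td>3</td><td>4</td>"
        )
        types = classify_columns(body)
        blocks = split_subtables(body, types, headers)
        assert len(blocks) == 1

    def test_subtable_identifiers_in_scan_order(self):
        spec = TableSpec(
            seed=5,
            col_types=("numerical",) * 4,
            sub_headers=("a", "b", "c", "d"),
            sections=(("", 3),),
            subtable=(("OR", "CI", "P", "Beta"), 2),
        )
        gen = gen_table(spec)
        raws = locate_tables(gen.linked_html, fix_config_cached(), mode="linked")
        docs = [d for raw in raws for d in process_table(raw)]
        assert [d.identifier for d in docs] == ["1", "1_1"]
        assert docs[1].title == docs[0].title  # metadata copied from parent


def fix_config_cached():
    from pubcorpus.fixtures import fixture_config

    return fixture_config()


class TestParseCell:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("5 × 10<sup>−8</sup>", 5e-8),
            ("true", "true"),
            ("false", "false"),
            ("n = 10 <sup>3</sup>", "n = 10 <sup>3</sup>"),
            ("1,234", "1,234"),
            ("-3.5", -3.5),
            ("42", 42),
            ("3e-4", 3e-4),
            ("5E−8", 5e-8),
            ("2 × 10−3", 2e-3),
            ("", ""),
        ],
    )
    def test_examples(self, raw, expected):
        assert parse_cell(raw) == expected

    def test_superscript_markup_survives_in_text_cells(self):
        grid = grid_of(
            "<table><tr><th>x</th></tr><tr><td>n = 10<sup>3</sup></td></tr></table>"
        )
        cell = grid.cells[1][0]
        assert parse_cell(cell) == "n = 10 <sup>3</sup>"

    def test_numeric_agreement_with_float_oracle(self):
        rng = random.Random(0)
        minus_variants = ["-", "−", "–"]
        for _ in range(1000):
            style = rng.randrange(3)
            if style == 0:
                mant = round(rng.uniform(-99, 99), rng.randint(0, 3))
                raw, expected = repr(mant), float(mant)
            elif style == 1:
                mant, exp = rng.randint(1, 9), rng.randint(1, 20)
                sign = rng.choice(minus_variants)
                raw = f"{mant}e{sign}{exp}"
                expected = float(f"{mant}e-{exp}")
            else:
                mant, exp = rng.randint(1, 9), rng.randint(1, 20)
                sign = rng.choice(minus_variants)
                x = rng.choice(["×", "x"])
                raw = f"{mant} {x} 10{sign}{exp}"
                expected = float(mant) * 10.0 ** (-exp)
            got = parse_cell(raw)
            assert isinstance(got, (int, float)) and got == pytest.approx(expected)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        gen = gen_table(TableSpec(seed=1))
        path = tmp_path / "t_tables.json"
        build_table_json(gen.truth, path, "doc")
        doc_id, again = read_table_json(path)
        assert doc_id == "doc"
        assert [t.to_dict() for t in again] == [t.to_dict() for t in gen.truth]

    def test_duplicate_identifiers_rejected(self, tmp_path):
        doc = TableDocument(identifier="1")
        with pytest.raises(ValueError, match="duplicate"):
            build_table_json([doc, doc], tmp_path / "x.json", "doc")

    def test_no_tables_is_a_valid_file(self, tmp_path):
        path = tmp_path / "empty_tables.json"
        build_table_json([], path, "doc")
        assert read_table_json(path)[1] == []

    def test_metadata_has_three_labelled_passages(self):
        doc = TableDocument(identifier="1", title="t", caption="c", footer="f")
        labels = [t for t, _ in doc.metadata]
        assert labels == ["table title", "table caption", "table footer"]


class TestInvariants:
    def specs(self):
        return [
            TableSpec(seed=1),
            TableSpec(
                seed=2, header_depth=2, col_types=("numerical",) * 4,
                span_groups=(("Cases", 2), ("Controls", 2)),
                sub_headers=("n", "%", "n", "%"), sections=(("", 2),),
            ),
            TableSpec(seed=3, section_mode="super",
                      sections=(("", 1), ("Men", 2), ("Women", 2))),
            TableSpec(seed=4, section_mode="index",
                      col_types=("textual", "numerical", "numerical"),
                      sub_headers=("Group", "n", "%"),
                      sections=(("Cohort A", 2), ("Cohort B", 3))),
            TableSpec(seed=5, col_types=("numerical",) * 4,
                      sub_headers=("a", "b", "c", "d"),
                      subtable=(("OR", "CI", "P", "Beta"), 2),
                      sections=(("", 3),)),
        ]

    def test_row_arity_and_cell_id_uniqueness(self):
        cfg = fix_config_cached()
        for spec in self.specs():
            gen = gen_table(spec)
            raws = locate_tables(gen.linked_html, cfg, mode="linked")
            for raw in raws:
                for doc in process_table(raw):
                    n = len(doc.column_headers)
                    ids = [cid for cid, _ in doc.column_headers]
                    for _, rows in doc.sections:
                        for row in rows:
                            assert len(row) == n
                            ids.extend(cid for cid, _ in row)
                    assert len(ids) == len(set(ids))

    def test_cell_conservation(self):
        # every non-empty body cell lands exactly once as a data value, a
        # section name (divider rows) or a sub-table header
        cfg = fix_config_cached()
        for spec in self.specs():
            gen = gen_table(spec)
            raw = locate_tables(gen.linked_html, cfg, mode="linked")[0]
            headers, body = resolve_headers(raw.grid)
            source = [c.flat for row in body for c in row if c.flat]
            docs = process_table(raw)
            emitted: list[str] = []
            for doc in docs:
                for name, rows in doc.sections:
                    for row in rows:
                        for cid, value in row:
                            emitted.append(
                                value if isinstance(value, str) else None
                            )
            # count only exact string cells; numeric cells are checked by
            # count: total emitted data cells must equal body data cells
            n_divider_cells = sum(
                len(set(c.origin for c in row))
                for row in body
                if len({c.origin for c in row}) == 1 and row[0].flat
            )
            n_subheader = (
                len(spec.sub_headers) if spec.subtable is not None else 0
            )
            n_data = sum(
                len(rows) * len(doc.column_headers)
                for doc in docs
                for _, rows in doc.sections
            )
            # expanded body slots minus divider/sub-header slots
            n_body_slots = sum(len(row) for row in body)
            n_super_slots = sum(
                len(row)
                for row in body
                if len({c.origin for c in row}) == 1 and row[0].flat
            )
            assert n_data == n_body_slots - n_super_slots - n_subheader
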