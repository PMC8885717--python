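import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubcorpus.fulltext import ArticleModel, Passage
from pubcorpus.sections import (
    DPG,
    START_NODE,
    FuzzyConfig,
    SectionDigraph,
    SectionWarning,
    accumulate_digraph,
    build_dpg,
    classify_sections,
    fuzzy_ratio,
    match_fuzzy,
    match_lexical,
    normalize_header,
    predict_unmapped,
    resolve_header,
)
from oracles import count_chains, fuzzy_ratio_oracle


class TestNormalize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Materials and Methods", "materialsandmethods"),
            ("", ""),
            ("Conflict-of-Interest!", "conflictofinterest"),
        ],
    )
    def test_examples(self, text, expected):
        assert normalize_header(text) == expected

    @given(st.text(max_size=30))
    @settings(deadline=None)
    def test_stable_under_repetition(self, text):
        once = normalize_header(text)
        assert normalize_header(once) == once


class TestLexical:
    @pytest.mark.parametrize(
        "header,expected",
        [
            ("abstract", "IAO:0000315"),
            ("Experimental Procedures", "IAO:0000317"),
            ("Background", "IAO:0000316"),
            ("Zorbleflux", None),
        ],
    )
    def test_examples(self, header, expected, lexicon):
        assert match_lexical(header, lexicon) == expected


class TestFuzzy:
    def test_typographical_error_maps_to_methods(self, lexicon):
        hits = match_fuzzy("experemintal section", lexicon)
        assert hits and hits[0][0] == "IAO:0000317"
        assert hits[0][1] >= 0.8

    def test_exact_synonym_scores_one(self, lexicon):
        hits = match_fuzzy("statistical analysis", lexicon, FuzzyConfig())
        assert hits[0] == ("IAO:0000644", 1.0)

    def test_typo_score_equals_dp_oracle(self):
        a, b = "experemintalsection", "experimentalsection"
        assert fuzzy_ratio(a, b) == fuzzy_ratio_oracle(a, b)

    def test_below_threshold_returns_empty(self, lexicon):
        assert match_fuzzy("zorbleflux", lexicon) == []

    @settings(deadline=None, max_examples=400)
    @given(
        st.text(alphabet="abcdefg", max_size=25),
        st.text(alphabet="abcdefg", max_size=25),
    )
    def test_ratio_equals_oracle_for_all_short_pairs(self, a, b):
        assert fuzzy_ratio(a, b) == pytest.approx(fuzzy_ratio_oracle(a, b), abs=0)

    def test_cascade_prefers_lexical_over_fuzzy(self, lexicon):
        ids, status = resolve_header("Discussion", lexicon)
        assert status == "lexical"
        assert ids == ("IAO:0000319",)


class TestDPG:
    def test_three_headers_give_three_nodes_two_edges(self, lexicon):
        dpg = build_dpg(
            ["abstract", "introduction", "materials and methods"], lexicon
        )
        assert len(dpg.nodes) == 3
        assert len(dpg.edges) == 2

    def test_consecutive_duplicates_collapse_without_self_edge(self, lexicon):
        dpg = build_dpg(["intro", "intro", "results"], lexicon)
        assert len(dpg.nodes) == 2
        assert len(dpg.edges) == 1

    def test_empty_header_list_is_a_valid_empty_dpg(self, lexicon):
        assert build_dpg([], lexicon).nodes == []

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.sampled_from(["Intro", "intro!", "Methods", "X y", "Z"]),
                    max_size=12))
    def test_linearity_invariants(self, lexicon, headers):
        dpg = build_dpg(headers, lexicon)
        norms = [n.normalized for n in dpg.nodes]
        # no consecutive duplicates -> no self-edges in a linear chain
        assert all(a != b for a, b in zip(norms, norms[1:]))
        assert len(dpg.edges) == max(0, len(dpg.nodes) - 1)


class TestAccumulate:
    def test_same_dpg_twice_doubles_all_weights(self, lexicon):
        dpg = build_dpg(["abstract", "introduction", "methods"], lexicon)
        dg = SectionDigraph()
        accumulate_digraph(dg, dpg, lexicon)
        accumulate_digraph(dg, dpg, lexicon)
        for label in ["abstract", "introduction section", "methods section"]:
            assert dg.node_weight(label) == 2
        assert dg.edge_weight("abstract", "introduction section") == 2

    def test_chains_sharing_one_header(self, lexicon):
        dg = SectionDigraph()
        accumulate_digraph(dg, build_dpg(["introduction", "methods"], lexicon), lexicon)
        accumulate_digraph(dg, build_dpg(["abstract", "introduction"], lexicon), lexicon)
        assert dg.node_weight("introduction section") == 2
        assert dg.node_weight("abstract") == 1
        assert dg.node_weight("methods section") == 1

    def test_empty_dpg_leaves_digraph_unchanged(self, lexicon):
        dg = SectionDigraph()
        accumulate_digraph(dg, DPG(nodes=[]), lexicon)
        assert dg.n_nodes == 0

    def test_weight_conservation_per_merge(self, lexicon):
        # each merge adds exactly |nodes|+1 node-weight (the start node) and
        # |edges|+1 edge-weight (the start edge)
        dpg = build_dpg(["abstract", "introduction", "results"], lexicon)
        dg = SectionDigraph()
        accumulate_digraph(dg, dpg, lexicon)
        total_nodes = sum(dg.node_weight(n) for n in dg.graph.nodes)
        total_edges = sum(dg.edge_weight(u, v) for u, v in dg.graph.edges)
        assert total_nodes == len(dpg.nodes) + 1
        assert total_edges == len(dpg.edges) + 1

    def test_matches_counting_oracle(self, lexicon):
        plans = [
            ["abstract", "introduction", "methods", "results"],
            ["abstract", "background", "results"],
            ["introduction", "methods", "results", "discussion"],
        ]
        dg = SectionDigraph()
        chains = []
        for headers in plans:
            dpg = build_dpg(headers, lexicon)
            accumulate_digraph(dg, dpg, lexicon)
            labels = [START_NODE] + [
                lexicon.label_of(n.term_ids[0]) if n.mapped else n.normalized
                for n in dpg.nodes
            ]
            chains.append(labels)
        nodes, edges = count_chains(chains)
        assert {n: dg.node_weight(n) for n in nodes} == nodes
        assert {e: dg.edge_weight(*e) for e in edges} == edges

    def test_json_round_trip_is_exact(self, tmp_path, lexicon):
        dg = SectionDigraph()
        accumulate_digraph(
            dg, build_dpg(["abstract", "methods", "results"], lexicon), lexicon
        )
        path = tmp_path / "digraph.json"
        dg.save(path)
        again = SectionDigraph.load(path)
        assert again.to_dict() == dg.to_dict()


def manual_digraph(lexicon, heavy=10, light=2):
    """introduction -> {methods(heavy) | discussion(light)} -> results"""
    dg = SectionDigraph()
    intro = "introduction section"
    meth = "methods section"
    disc = "discussion section"
    res = "results section"
    for label, w in [(intro, heavy + light), (meth, heavy), (disc, light),
                     (res, heavy + light)]:
        dg.graph.add_node(label, weight=w)
    dg.graph.add_edge(intro, meth, weight=heavy)
    dg.graph.add_edge(meth, res, weight=heavy)
    dg.graph.add_edge(intro, disc, weight=light)
    dg.graph.add_edge(disc, res, weight=light)
    return dg


class TestPredict:
    def test_heaviest_interior_path_wins(self, lexicon):
        dg = manual_digraph(lexicon)
        dpg = build_dpg(["Introduction", "Cohort assembly", "Results"], lexicon)
        assert not dpg.nodes[1].mapped
        predicted = predict_unmapped(dpg, dg, lexicon)
        assert predicted.nodes[1].term_ids == ("IAO:0000317",)
        assert predicted.nodes[1].status == "predicted"

    def test_fully_mapped_dpg_is_returned_unchanged(self, lexicon):
        dg = manual_digraph(lexicon)
        dpg = build_dpg(["Introduction", "Methods", "Results"], lexicon)
        assert predict_unmapped(dpg, dg, lexicon) is dpg

    def test_equal_weight_paths_keep_both_terms(self, lexicon):
        dg = manual_digraph(lexicon, heavy=5, light=5)
        dpg = build_dpg(["Introduction", "Cohort assembly", "Results"], lexicon)
        predicted = predict_unmapped(dpg, dg, lexicon)
        assert set(predicted.nodes[1].term_ids) == {"IAO:0000317", "IAO:0000319"}

    def test_no_anchors_warns_and_leaves_unmapped(self, lexicon):
        dg = manual_digraph(lexicon)
        dpg = build_dpg(["Zorbleflux", "Blarg"], lexicon)
        with pytest.warns(SectionWarning):
            out = predict_unmapped(dpg, dg, lexicon)
        assert all(not n.mapped for n in out.nodes)


class TestClassify:
    def model(self, headers):
        return ArticleModel(
            document_id="d",
            passages=[Passage(text=f"p{i}", heading_path=(h,))
                      for i, h in enumerate(headers)],
        )

    def test_standard_headers_resolve_lexically(self, lexicon):
        model = self.model(
            ["Abstract", "Background", "Methods", "Results", "Discussion"]
        )
        terms = classify_sections(model, lexicon)
        ids = [t[0][1] for t in terms]
        assert ids == [
            "IAO:0000315", "IAO:0000316", "IAO:0000317",
            "IAO:0000318", "IAO:0000319",
        ]

    def test_typo_header_resolves_via_fuzzy(self, lexicon):
        model = self.model(["Introduction", "experemintal section", "Results"])
        terms = classify_sections(model, lexicon)
        assert terms[1] == [("methods section", "IAO:0000317")]

    def test_unknown_header_between_anchors_resolves_via_digraph(self, lexicon):
        dg = manual_digraph(lexicon)
        model = self.model(["Introduction", "Cohort assembly", "Results"])
        terms = classify_sections(model, lexicon, digraph=dg)
        assert terms[1] == [("methods section", "IAO:0000317")]

    def test_subheader_classified_on_its_own_before_inheriting(self, lexicon):
        model = ArticleModel(
            document_id="d",
            passages=[
                Passage(text="a", heading_path=("Methods", "Statistical Analysis")),
                Passage(text="b", heading_path=("Methods", "Cohort details")),
            ],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            terms = classify_sections(model, lexicon)
        assert terms[0] == [("statistical analysis section", "IAO:0000644")]
        assert terms[1] == [("methods section", "IAO:0000317")]

    def test_unresolvable_without_digraph_warns_and_is_empty(self, lexicon):
        model = self.model(["Zorbleflux"])
        with pytest.warns(SectionWarning):
            terms = classify_sections(model, lexicon)
        assert terms == [[]]
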