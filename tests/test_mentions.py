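import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leapfs import mentions
from leapfs._aa import THREE_TO_ONE


def keys(ms):
    return [(m.wt_code, m.position, m.mut_code) for m in ms]


class TestExtraction:
    @pytest.mark.parametrize("text,expected", [
        ("Asp104", [("ASP", 104, None)]),
        ("Asp-104 is catalytic.", [("ASP", 104, None)]),
        ("the aspartic acid 104 residue", [("ASP", 104, None)]),
        ("His—554 interacts.", [("HIS", 554, None)]),  # em dash connector
        ("cysteines at positions 6, 24, and 393",
         [("CYS", 6, None), ("CYS", 24, None), ("CYS", 393, None)]),
        ("G146A", [("GLY", 146, "ALA")]),
        ("Gly146Ala", [("GLY", 146, "ALA")]),
        ("His-554 mutated to glutamine", [("HIS", 554, "GLN")]),
        ("Asp104→Ala", [("ASP", 104, "ALA")]),  # arrow mutation
        ("mutation of Ser45 to alanine", [("SER", 45, "ALA")]),
        ("Tyr12 was replaced by phenylalanine", [("TYR", 12, "PHE")]),
    ])
    def test_normalization(self, text, expected):
        assert keys(mentions.extract_mentions(text)) == expected

    @pytest.mark.parametrize("text", [
        "Glycine is abundant.",          # bare name: no position
        "the R377 plasmid",              # bare 1-letter+digits
        "buffer at pH 7",
    ])
    def test_no_spurious_mentions(self, text):
        assert mentions.extract_mentions(text) == []

    def test_compat_mode_parenthesized_position(self):
        text = "phosphorylation of tyrosine (6) was observed"
        assert keys(mentions.extract_mentions(text)) == [("TYR", 6, None)]
        assert mentions.extract_mentions(text, strict=True) == []

    def test_compat_mode_trailing_chain_letter(self):
        text = "The catalytic residue Cys105L is conserved."
        assert keys(mentions.extract_mentions(text)) == [("CYS", 105, "LEU")]
        got = mentions.extract_mentions(text, strict=True)
        assert all(m.mut_code is None for m in got)

    def test_gene_name_lookalike_extracted_in_compat(self):
        # a documented false-positive class, not filtered by default
        assert keys(mentions.extract_mentions("binds E2F directly")) == \
            [("GLU", 2, "PHE")]

    def test_spans_match_source_text(self):
        text = "We mutated Asp104 and studied His-554 mutated to glutamine."
        for m in mentions.extract_mentions(text):
            sub = text[m.span[0]:m.span[1]]
            assert str(m.position) in sub

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(wt=st.sampled_from(sorted(THREE_TO_ONE)),
           pos=st.integers(min_value=1, max_value=99999),
           mut=st.one_of(st.none(), st.sampled_from(sorted(THREE_TO_ONE))))
    def test_canonical_form_idempotent(self, wt, pos, mut):
        if mut == wt:
            mut = None
        m = mentions.NormalizedMention(wt, pos, mut, (0, 0))
        got = mentions.extract_mentions(m.canonical_form())
        assert len(got) == 1
        assert got[0].key() == m.key()


class TestEvaluate:
    def _m(self, wt, pos, mut=None, span=(0, 0), src="d1"):
        return mentions.NormalizedMention(wt, pos, mut, span, src)

    def test_perfect_agreement(self):
        gold = [self._m("ASP", 10), self._m("GLY", 20, "ALA")]
        r = mentions.evaluate(gold, list(gold))
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_empty_predictions(self):
        r = mentions.evaluate([self._m("ASP", 10)], [])
        assert r.recall == 0.0
        assert r.precision == 0.0
        assert not r.precision_defined

    def test_mutation_requires_both_codes(self):
        gold = [self._m("GLY", 146, "ALA")]
        pred = [self._m("GLY", 146, "SER")]
        r = mentions.evaluate(gold, pred)
        assert (r.tp, r.fp, r.fn) == (0, 1, 1)

    def test_span_mode_distinguishes_offsets(self):
        gold = [self._m("ASP", 10, span=(5, 11))]
        pred = [self._m("ASP", 10, span=(7, 13))]
        assert mentions.evaluate(gold, pred, span_mode=True).tp == 0
        assert mentions.evaluate(gold, pred, span_mode=False).tp == 1

    def test_duplicate_gold_counted_once(self, caplog):
        gold = [self._m("ASP", 10), self._m("ASP", 10)]
        r = mentions.evaluate(gold, [self._m("ASP", 10)])
        assert (r.tp, r.fn) == (1, 0)

    def test_counts_arithmetic(self):
        r = mentions.prf_from_counts(454, 435, 550)
        assert (r.tp, r.fp, r.fn) == (435, 19, 115)
        assert r.precision == pytest.approx(0.958, abs=5e-4)
        assert r.recall == pytest.approx(0.791, abs=5e-4)


class TestCorpusReport:
    def _m(self, pos, src):
        return mentions.NormalizedMention("ASP", pos, None, (0, 0), src)

    def test_two_perfect_docs(self):
        gold = {"a": [self._m(1, "a")], "b": [self._m(2, "b")]}
        r = mentions.corpus_report(gold, gold)
        assert r.precision == r.recall == 1.0

    def test_planted_false_positive_rate(self):
        gold, pred = {}, {}
        for d in range(10):
            doc = f"d{d}"
            gold[doc] = [self._m(p, doc) for p in range(1, 10)]
            pred[doc] = list(gold[doc]) + [self._m(1000 + d, doc)]  # 1 FP per 10
        r = mentions.corpus_report(gold, pred)
        assert r.precision == pytest.approx(0.9, abs=1e-9)

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            mentions.corpus_report({}, {})

    def test_doc_mismatch_errors(self):
        with pytest.raises(ValueError):
            mentions.corpus_report({"a": []}, {"b": []})


class TestGoldIO:
    def test_read_normalized_tokens(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text("doc1\tW123M\tAsp104\ndoc2\tGly146Ala\n")
        gold = mentions.read_gold_mentions(p)
        assert keys(gold["doc1"]) == [("TRP", 123, "MET"), ("ASP", 104, None)]
        assert keys(gold["doc2"]) == [("GLY", 146, "ALA")]

    def test_read_span_format(self, tmp_path):
        p = tmp_path / "gold_span.tsv"
        p.write_text("doc1\t5\t11\tASP\t104\t\ndoc1\t20\t25\tGLY\t146\tALA\n")
        gold = mentions.read_gold_mentions(p, span=True)
        assert gold["doc1"][0].span == (5, 11)
        assert gold["doc1"][1].mut_code == "ALA"
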