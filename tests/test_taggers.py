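import pytest
from lxml import etree

from chemphrase.preprocess import normalize_text, tokenize
from chemphrase.taggers import (
    ACTION_FAMILIES,
    TagNamespace,
    cascade_tag,
    family_to_verb_tag,
    ingest_ner_xml,
    tag_chemicals,
    tag_pos,
    tag_regex,
)
from chemphrase.samples import SAMPLE_SENTENCE


def toks(text):
    return tokenize(normalize_text(text))


class TestChemicalNER:
    def test_single_token_compound(self):
        ents = tag_chemicals(toks("thiophenol"))
        assert len(ents) == 1
        assert ents[0].type == "CM"
        assert ents[0].surface == "thiophenol"

    def test_multi_token_lexicon_phrase(self):
        ents = tag_chemicals(toks("Potassium carbonate was added"))
        assert ents[0].surface == "Potassium carbonate"
        assert len(ents[0].token_ids) == 2

    def test_plain_verb_not_an_entity(self):
        assert tag_chemicals(toks("stirred")) == []

    def test_systematic_suffix_morphology(self):
        ents = tag_chemicals(toks("dodecanethiol reacted"))
        assert [e.surface for e in ents] == ["dodecanethiol"]

    def test_formula_recognised(self):
        ents = tag_chemicals(toks("dried MgSO4 powder"))
        assert [e.surface for e in ents] == ["MgSO4"]

    def test_locant_name_recognised(self):
        ents = tag_chemicals(toks("the 2-nitrobenzene sulfonamide"))
        assert ents and ents[0].surface == "2-nitrobenzene sulfonamide"


class TestNerXmlIngest:
    NE_BLOCK = """
    <chem-doc>
      <ne id='o1960' surface=' Potassium carbonate ' type='CM'
          confidence='0.9448241038775597 '>Potassium carbonate</ne>
      (0.63 g, 4.56 mmol) and
      <ne id='o1962' surface=' thiophenol ' type='CM'
          confidence='0.9676694757597625'>thiophenol</ne>
      were added to...
    </chem-doc>
    """

    def test_reads_printed_dialect_with_confidence(self):
        ents = ingest_ner_xml(self.NE_BLOCK)
        assert len(ents) == 2
        assert ents[0].surface == "Potassium carbonate"
        assert ents[0].confidence == pytest.approx(0.9448241038775597)
        assert ents[1].id == "o1962"

    def test_absent_confidence(self):
        ents = ingest_ner_xml("<ne id='x' surface='water' type='CM'>water</ne>")
        assert ents[0].confidence is None

    def test_no_ne_elements(self):
        assert ingest_ner_xml("<doc>nothing here</doc>") == []

    def test_malformed_xml_raises(self):
        with pytest.raises(etree.XMLSyntaxError):
            ingest_ner_xml("<ne id='x'")

    def test_alignment_to_tokens(self):
        tokens = toks(SAMPLE_SENTENCE)
        ents = ingest_ner_xml(self.NE_BLOCK, tokens)
        assert [len(e.token_ids) for e in ents] == [2, 1]
        surfaces = {t.id: t.surface for t in tokens}
        assert [surfaces[i] for i in ents[0].token_ids] == [
            "Potassium", "carbonate",
        ]

    def test_unalignable_surface_skipped(self):
        tokens = toks("nothing matches here")
        ents = ingest_ner_xml(
            "<ne id='x' surface='xenon' type='CM'>xenon</ne>", tokens
        )
        assert ents == []


class TestRegexTagger:
    @pytest.mark.parametrize(
        "word,tag",
        [
            ("mmol", "NN-MOLAR"),
            ("g", "NN-MASS"),
            ("mL", "NN-VOL"),
            ("%", "NN-PERCENT"),
            ("°C", "NN-TEMP"),
            ("overnight", "NN-TIME"),
            ("added", "VB-ADD"),
            ("stirred", "VB-STIR"),
            ("purified", "VB-PURIFY"),
            ("Synthesis", "VB-SYNTHESIZE"),
            ("oil", "NN-STATE"),
            ("mixture", "NN-MIXTURE"),
            ("solution", "NN-SOLUTION"),
            ("**82**", "CD-BOLD"),
        ],
    )
    def test_category_tags(self, word, tag):
        tagged = tag_regex(tokenize(word))
        assert tagged and tagged[0].tag == tag

    def test_unknown_token_falls_through(self):
        assert tag_regex(tokenize("xyzzy")) == []


class TestPosTagger:
    @pytest.mark.parametrize(
        "word,tag",
        [("were", "VBD"), ("and", "CC"), ("to", "TO"), ("the", "DT"),
         ("under", "IN"), ("0.63", "CD"), (".", "STOP"), ("(", "LRB"),
         ("flask", "NN"), ("products", "NNS"), ("slowly", "RB")],
    )
    def test_penn_tags(self, word, tag):
        assert tag_pos(tokenize(word))[0].tag == tag

    def test_total(self):
        tagged = tag_pos(toks("any words at all even xyzzy"))
        assert all(t.tag for t in tagged)


class TestCascade:
    def test_sample_sentence_namespaces(self):
        tagged = cascade_tag(toks(SAMPLE_SENTENCE))
        by_surface = {}
        for tt in tagged:
            by_surface.setdefault(tt.surface, tt)
        chem = {"Potassium", "carbonate", "thiophenol", "2-nitrobenzene",
                "sulfonamide"}
        regex = {"g", "mmol", "added"}
        pos = {"were", "to", "the", "and", "(", ")", ",", "0.63", "4.56"}
        for s in chem:
            assert by_surface[s].namespace is TagNamespace.CHEM, s
        for s in regex:
            assert by_surface[s].namespace is TagNamespace.REGEX, s
        for s in pos:
            assert by_surface[s].namespace is TagNamespace.POS, s

    def test_totality_and_order(self):
        tokens = toks(SAMPLE_SENTENCE)
        tagged = cascade_tag(tokens)
        assert [tt.token for tt in tagged] == tokens
        assert all(tt.tag for tt in tagged)

    def test_all_chemical_sentence_has_no_pos_tags(self):
        tagged = cascade_tag(toks("thiophenol methanol toluene"))
        assert all(tt.namespace is TagNamespace.CHEM for tt in tagged)

    def test_deterministic_fixed_point(self):
        tokens = toks(SAMPLE_SENTENCE)
        first = cascade_tag(tokens)
        second = cascade_tag(tokens)
        assert [(t.surface, t.tag) for t in first] == [
            (t.surface, t.tag) for t in second
        ]

    @pytest.mark.parametrize(
        "dialect,text",
        [
            ("positional", "the 2-nitrobenzene sulfonamide 50 was added"),
            ("markdown", "the 2-nitrobenzene sulfonamide **50** was added"),
            ("html", "the 2-nitrobenzene sulfonamide <b>50</b> was added"),
        ],
    )
    def test_bold_dialects(self, dialect, text):
        tagged = cascade_tag(toks(text), bold_dialect=dialect)
        assert any(tt.tag == "CD-BOLD" for tt in tagged)

    def test_positional_bold_not_triggered_before_unit(self):
        tagged = cascade_tag(toks("ethyl acetate 50 cm3 was added"))
        assert not any(tt.tag == "CD-BOLD" for tt in tagged)

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError):
            cascade_tag(toks("water"), bold_dialect="latex")


def test_exactly_21_action_families_with_distinct_tags():
    assert len(ACTION_FAMILIES) == 21
    tags = {family_to_verb_tag(f) for f in ACTION_FAMILIES}
    assert len(tags) == 21
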