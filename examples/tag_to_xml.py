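"""Tag and parse one sentence, emitting the phrase-tree XML.

The add-sentence is tokenised, cascade-tagged (chemical entities first,
then domain regexes, then Penn POS tags) and parsed; the tree serialises
to the XML dialect with the Add phrase wrapping the whole sentence.
"""

from chemphrase import (
    cascade_tag,
    identify_actions,
    normalize_text,
    parse_sentence,
    to_xml_string,
    tokenize,
)
from chemphrase.samples import SAMPLE_SENTENCE

tokens = tokenize(normalize_text(SAMPLE_SENTENCE))
tagged = cascade_tag(tokens)

print("tag cascade (CHEM > REGEX > POS):")
for tt in tagged:
    print(f"  {tt.surface:16s} {tt.tag:10s} [{tt.namespace.value}]")

tree = parse_sentence(tagged)
actions = identify_actions(tree)
print()
print("actions:", [a.type.name for a in actions])
print()
print(to_xml_string(tree))
# Three MOLECULE elements: the two reagents carry bracketed QUANTITY
# groups; the substrate after "to the" has none.
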