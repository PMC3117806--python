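"""Parse a full preparation paragraph: actions, quantities, roles.

Runs the bundled benzazepine preparation through the pipeline and prints
every procedural step it finds, the bracketed amounts attached to each
compound, and the inferred solvent/reactant/product roles.
"""

from chemphrase import parse_document
from chemphrase.samples import PREPARATION

doc = parse_document(PREPARATION, source_id="prep82")

print("input title:", doc.title.surface())
print()
print("procedural steps (in text order):")
for action in doc.actions:
    nested = "".join(f"  [nested {n.type.name}]" for n in action.nested)
    print(f"  {action.type.name:12s} {action.surface[:60]}...{nested}")

print()
print("bracketed amounts:")
for owner, quantities in doc.quantity_groups():
    amounts = ", ".join(
        f"{q.value:g} {q.unit or q.kind}" + (f" ×{q.repeat}" if q.repeat else "")
        for q in quantities
    )
    print(f"  {owner:45s} {amounts}")

print()
print("compound roles:")
for role in doc.roles:
    print(f"  {role.role:10s} {role.surface}  ({role.evidence or 'no rule fired'})")

# Each step line is one action phrase; the roles follow from context:
# the solvent sits after "in"/"with" in a dissolution-like step, the
# reactant carries reference 50 near the start, the product is the
# title compound 82.
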