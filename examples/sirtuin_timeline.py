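"""An evidence-driven probability trajectory with homological inference.

The hypothesis "SIRT1 regulates human life span" cannot be tested directly,
so belief in it tracks results from model organisms: a 2001 nematode study
raised it (an expert pegged it at 0.8), a 2011 failure to replicate pushed
it down, and a 2012 mouse result pushed it back up.  Each change is a new
timestamped record with its estimation method and triggering evidence — the
trajectory is append-only, so the whole argument stays auditable.
"""

from helo import EvidenceRelation, sirtuin_fixture
from helo.fixtures import SIRTUIN_H1
from helo.statements import render_infix

kb = sirtuin_fixture()
stmt = kb.statements[SIRTUIN_H1]
print(f"{stmt.id}: {render_infix(stmt.expression)}  ({stmt.free_text})\n")

print("probability trajectory:")
for r in kb.trajectory(SIRTUIN_H1):
    src = f"  <- {r.source}" if r.source else ""
    print(f"  {r.timestamp}  P={r.value:.3f}  {r.kind.value:<9} {r.method.value}{src}")

print("\nevidence on record for h1:")
for relation, items in kb.evidence_for(SIRTUIN_H1).items():
    for item in items:
        print(f"  {relation.value:<8} {item.id}: {item.description}")

print("\nhomology channels feeding h1:")
for link in kb.homology_links:
    print(f"  {link.source_statement_id} -> {link.target_statement_id} "
          f"(weight {link.weight})")

p_2001 = kb.probability_at(SIRTUIN_H1, "2010-12-31").value
p_2011 = kb.probability_at(SIRTUIN_H1, "2011-12-31").value
p_2012 = kb.probability_at(SIRTUIN_H1, "2012-12-31").value
print(f"\nP(h1): {p_2001:.3f} before 2011, {p_2011:.3f} after the refutation, "
      f"{p_2012:.3f} after the 2012 support — down then up, as the evidence arrived.")
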