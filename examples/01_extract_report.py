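"""Extract coded findings from a short imaging report.

Builds the fixture terminology, runs the extraction pipeline over a
three-sentence report, and prints every mention (with its concept code and
present/absent assertion), relation, and numeric value assignment.  The
spans are character offsets into the raw text, so each line can be traced
back to its source.
"""

import ecrfpop as ep

term = ep.build_fixture_terminology()

report = ep.Document(
    case_id="demo-1",
    doc_type="imaging_report",
    text=(
        "Ventricular septal defect was noted.\n"
        "The lesion size of ventricular septal defect is 0.6 cm.\n"
        "No atrial septal defect was found."
    ),
)

result = ep.extract(report, term)

print("Mentions (surface, category, concept, assertion):")
for m in result.mentions:
    print(f"  [{m.span.start:3d},{m.span.end:3d})  {m.surface!r:32s}"
          f" {m.category:16s} {str(m.concept_id):14s} {m.assertion}")

print("\nRelations:")
for r in result.relations:
    a, b = result.mentions[r.arg1], result.mentions[r.arg2]
    print(f"  {r.rel_type}: {a.surface!r} -> {b.surface!r}")

print("\nValue assignments:")
for v in result.value_assignments:
    obs = result.mentions[v.observable].surface
    prob = (result.mentions[v.related_problem].surface
            if v.related_problem is not None else None)
    print(f"  {obs} = {v.value} {v.unit}  (problem: {prob})")

# The negated finding is labelled absent; the affirmed defect is present and
# its measured size is tied back to it through the problem-observable link.
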