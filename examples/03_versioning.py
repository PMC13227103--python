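"""Full dialect: anchors, append-only versions, history, soft delete.

An anchor identifies a statement independently of its versions and always
resolves to the newest non-deleted version; every edit appends a version,
so the per-position editing history is fully reconstructible.
"""

from rosetta_statements import (
    IriMinter,
    ProvenanceMetadata,
    ValueBinding,
    contributors,
    create_anchor,
    make_fixtures,
    position_history,
    resolve_current,
    retrieve,
    soft_delete,
    update_statement,
)

corpus = make_fixtures(seed=0)
st = corpus.statement("ci_apple")
schema = corpus.schema_for(st)

anchor = create_anchor(st.record, schema, minter=IriMinter(seed=1))
update_statement(
    anchor, schema,
    {"MAIN_VALUE": ValueBinding.literal("241.70", "float")},
    ProvenanceMetadata(creator="editor-b", created_at="2024-01-02T00:00:00"))

current = resolve_current(anchor)
print("versions:       ", [v.version_number for v in anchor.versions])
print("current version:", current.version_number,
      "value =", current.record.values("MAIN_VALUE")[0].lexical)

for e in position_history(anchor, schema, "MAIN_VALUE"):
    flag = "changed" if e.changed else "unchanged"
    print(f"  v{e.version_number}: "
          f"{[b.display_value() for b in e.values]} ({flag}, {e.editor})")

summary = contributors(anchor)
print("contributors:   ", sorted(summary.contributors),
      "last update:", summary.last_updated)

soft_delete(anchor, "moderator", "2024-02-01T00:00:00")
view = retrieve(anchor)
print("after delete:    deleted =", view["deleted"],
      "| metadata kept =", view["metadata"].creator is not None,
      "| content =", view["content"])
# Soft delete only adds deletion metadata: provenance stays accessible
# even though the statement content is withheld.
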