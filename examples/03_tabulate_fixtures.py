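"""Tabulate the packaged survey tables into the supergroup distribution.

Loads the printed truncated/multidomain/partial-domain protein lists and
renders the phyletic distribution in "total (est)" style, exactly as the
survey summarises them.
"""

from tppplike import load_fixture_table, load_taxonomy, tabulate_distribution

taxonomy = load_taxonomy()
rows = []
for table_id in ("T2_truncated", "T3_multidomain", "T4_partial"):
    rows += [(r, r.subfamily) for r in load_fixture_table(table_id)]

table = tabulate_distribution(rows, taxonomy)
print(table.render())
print()
print(f"arthropod truncated TPPPs: {table.count('truncated', 'Arthropoda')}")
print(f"multidomain proteins total: {table.count('multidomain')}")
print(
    "Excavata partial-domain proteins:",
    table.count("partial_only", "Excavata"),
    f"({table.count('partial_only', 'Excavata', est_only=True)} as ESTs)",
)
print("-> numbers in parentheses are translated-EST records; footnoted rows stay in the counts")
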