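"""Neighbor-joining clade structure of long, truncated and short TPPPs.

On identity-derived distances, truncated TPPPs form their own clade sitting
inside/next to the long-type group, and both separate cleanly from the
short-type outparalogs - the survey's qualitative tree topology.
"""

from tppplike import SynthSpec, distance_matrix, generate_batch, is_monophyletic, nj_tree

specs = [
    SynthSpec(label, n=5, substitution_rate=0.05)
    for label in ("long_type", "truncated", "short_type")
]
records = [x.record for x in generate_batch(specs, seed=5)]
tree = nj_tree(distance_matrix(records))

truncated = {r.id for r in records if r.id.startswith("truncated")}
long_type = {r.id for r in records if r.id.startswith("long_type")}
outgroup = sorted(r.id for r in records if r.id.startswith("short_type"))[0]

print(f"{len(records)} sequences, outgroup = {outgroup}")
print("truncated TPPPs monophyletic:       ", is_monophyletic(tree, truncated, outgroup))
print("long+truncated separate from short: ", is_monophyletic(tree, truncated | long_type, outgroup))
print()
print(tree.ascii_art())
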