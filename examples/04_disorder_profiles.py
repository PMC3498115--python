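"""Predicted intrinsic disorder across the subfamilies (0.5 threshold).

The charge-hydropathy stand-in reproduces the survey's contrast: long-type
and partial-only proteins are predicted disordered, short-type and truncated
ones ordered.
"""

import numpy as np

from tppplike import SynthSpec, disorder_scores, generate_batch

batch = generate_batch(
    [SynthSpec(lbl, n=10) for lbl in
     ("long_type", "short_type", "truncated", "partial_only", "apicortin")],
    seed=3,
)
fractions: dict[str, list[float]] = {}
for rec, truth, _ in batch:
    profile = disorder_scores(rec.sequence, window=21)
    fractions.setdefault(truth.label, []).append(profile.disordered_fraction)

print("mean fraction of residues with disorder score > 0.5:")
for label in ("long_type", "short_type", "truncated", "partial_only", "apicortin"):
    print(f"  {label:<14} {np.mean(fractions[label]):.2f}")
print("-> disordered C-terminus + N-tail drive the long-type value; the core is ordered")
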