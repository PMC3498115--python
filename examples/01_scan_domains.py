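"""Locate p25alpha domain segments and the Rossmann-like motif in a sequence.

Builds the packaged domain model, assembles a noise-free long-type TPPP
(N-tail + core + partial core + extension) and re-measures its architecture
with the profile scanner.
"""

import numpy as np

from tppplike import (
    SynthSpec,
    default_model,
    detect_extension,
    find_rossmann_motifs,
    generate_class_sequence,
    scan_profile,
    synthetic_parts,
)

model = default_model()
rec, truth, _ = generate_class_sequence(
    SynthSpec("long_type"), synthetic_parts(), np.random.default_rng(0)
)
print(f"sequence {rec.id}: {len(rec)} aa ({rec.species})")

(core,) = scan_profile(rec.sequence, model, "core", 0.8)
(part,) = scan_profile(rec.sequence, model, "partial_core", 0.8)
print(f"core hit          [{core.start},{core.end})  norm={core.normalized_score:.2f} tier={core.tier}")
print(f"partial-core hit  [{part.start},{part.end})  norm={part.normalized_score:.2f} tier={part.tier}")
print(f"full domain span  {part.end - core.start} aa  (long p25alpha domains are 140-160 aa)")

(motif,) = find_rossmann_motifs(rec.sequence)
ext = detect_extension(rec.sequence, motif, model)
print(f"Rossmann motif    [{motif.start},{motif.end})  {motif.matched}")
print(f"extension         [{ext.start},{ext.end})  {len(ext)} aa right after the motif")
print("-> one complete long-type architecture; the 50 residues before the core are the N-tail")
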