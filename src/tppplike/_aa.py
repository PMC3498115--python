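"""Amino-acid constants shared across the package.

Coordinates are 0-based half-open everywhere in this package.
"""

from __future__ import annotations

import numpy as np

#: canonical 20-letter alphabet, alphabetical by one-letter code
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
#: unknown residue; scores as background (log-odds 0) in profile scans
UNKNOWN = "X"
VALID_RESIDUES = frozenset(ALPHABET + UNKNOWN)

#: non-standard codes mapped to X on input (noisy EST translations)
NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X", "*": "X"}

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: formal charge at neutral pH used by the fold-index stand-in
CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

#: conventional strong similarity groups (ClustalW-style)
SIMILARITY_GROUPS = ("ILVM", "FYW", "KRH", "DE", "ST", "NQ", "AG")


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to alphabet indices; X (and anything unknown) -> 20."""
    return np.array([AA_INDEX.get(a, 20) for a in seq], dtype=np.intp)
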