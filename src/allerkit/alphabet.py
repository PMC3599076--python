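"""The 20-letter amino-acid alphabet and residue-frequency presets.

All feature vectors, PWM columns and composition vectors in this package
index residues in the fixed alphabetical order ``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

import numpy as np

#: Standard amino acids, alphabetical one-letter order. This ordering is the
#: contract for every 20-vector in the package.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

AA_SET = frozenset(AA_ORDER)

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

#: Ambiguity codes, non-standard residues and markers that a sanitizer must
#: deal with (stripped or rejected, never silently kept).
NON_STANDARD = frozenset("BJOUXZ*-.")

#: Uniform background: every residue at 0.05.
UNIFORM_FREQS = np.full(20, 0.05)

#: Average residue frequencies of well-annotated protein databases
#: (Swiss-Prot-like composition), usable as a more realistic background for
#: motif scoring and sequence simulation.
SWISSPROT_FREQS = np.array(
    [
        0.0826,  # A
        0.0137,  # C
        0.0546,  # D
        0.0672,  # E
        0.0386,  # F
        0.0708,  # G
        0.0228,  # H
        0.0593,  # I
        0.0582,  # K
        0.0965,  # L
        0.0241,  # M
        0.0406,  # N
        0.0475,  # P
        0.0393,  # Q
        0.0553,  # R
        0.0660,  # S
        0.0535,  # T
        0.0687,  # V
        0.0110,  # W
        0.0292,  # Y
    ]
)
SWISSPROT_FREQS = SWISSPROT_FREQS / SWISSPROT_FREQS.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode a sanitized sequence as an int array over 0..19."""
    try:
        return np.fromiter((AA_INDEX[a] for a in sequence), dtype=np.int64, count=len(sequence))
    except KeyError as exc:  # pragma: no cover - guarded by sanitization
        raise ValueError(f"non-standard residue {exc} in sequence") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] for c in codes)
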