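"""Seeded synthetic-data generators.

These fixtures emulate the structure of an allergen benchmark without any
download: positive "families" share a planted word or noisy motif instance
on an i.i.d. background, and negatives are background draws, per-sequence
shuffles of the positives (same composition, destroyed order) or reversed
positives (the bias-free negative design for window-identity evaluation).
Everything is deterministic per seed, down to byte-identical FASTA output.

The generators define the study conditions for every engine test in this
package; they intentionally do not model indels, domain architecture or
phylogeny, so results on them bound what the engines can do on ideal data,
not on real proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ORDER, UNIFORM_FREQS, decode
from .records import Label, ProteinRecord, SequenceDataset

#: Keep planted elements away from sequence ends by this many residues.
PLANT_MARGIN = 5


@dataclass
class FixtureSpec:
    """Recipe for a labeled synthetic dataset.

    Each of ``n_families`` allergen families of ``family_size`` members gets
    one planted element per member: either a family-specific random word of
    ``planted_word_length`` residues or an explicit consensus from
    ``motif_consensi``, copied with per-site ``substitution_rate`` noise.
    ``negative_mode``: ``random`` draws i.i.d. background sequences,
    ``shuffled`` permutes positives (composition preserved), ``reversed``
    reverses positives.
    """

    n_families: int = 2
    family_size: int = 20
    seq_length: int = 100
    planted_word_length: int = 10
    motif_consensi: list[str] | None = None
    substitution_rate: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_FREQS.copy())
    n_negatives: int = 40
    negative_mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negative_mode not in ("random", "shuffled", "reversed"):
            raise ValueError("negative_mode must be random | shuffled | reversed")
        if not 0 <= self.substitution_rate <= 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5]")
        widths = [len(c) for c in self.motif_consensi] if self.motif_consensi else [self.planted_word_length]
        if self.motif_consensi is not None and len(self.motif_consensi) != self.n_families:
            raise ValueError("motif_consensi must list one consensus per family")
        if max(widths) + 2 * PLANT_MARGIN > self.seq_length:
            raise ValueError("planted element plus margins does not fit in seq_length")
        if self.n_families < 1 or self.family_size < 1 or self.seq_length < 1:
            raise ValueError("n_families, family_size and seq_length must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> np.ndarray:
    return rng.choice(20, size=length, p=background)


def _mutate(rng: np.random.Generator, word: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0:
        return word.copy()
    out = word.copy()
    flips = np.nonzero(rng.random(len(word)) < rate)[0]
    for i in flips:
        # substitute with a uniformly chosen *different* residue
        out[i] = (out[i] + 1 + rng.integers(19)) % 20
    return out


def generate(spec: FixtureSpec) -> SequenceDataset:
    """Generate the labeled dataset described by a :class:`FixtureSpec`."""
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    bg = bg / bg.sum()

    if spec.motif_consensi is not None:
        consensi = [np.array([AA_ORDER.index(a) for a in c], dtype=np.int64) for c in spec.motif_consensi]
    else:
        consensi = [
            rng.integers(0, 20, size=spec.planted_word_length).astype(np.int64) for _ in range(spec.n_families)
        ]

    positives: list[ProteinRecord] = []
    for f, consensus in enumerate(consensi, start=1):
        w = len(consensus)
        for i in range(1, spec.family_size + 1):
            seq = _random_sequence(rng, spec.seq_length, bg)
            start = int(rng.integers(PLANT_MARGIN, spec.seq_length - w - PLANT_MARGIN + 1))
            seq[start : start + w] = _mutate(rng, consensus, spec.substitution_rate)
            positives.append(
                ProteinRecord(
                    id=f"fam{f}_{i}",
                    sequence=decode(seq),
                    species=f"Synthfam {f}",
                    label=Label.ALLERGEN,
                )
            )

    negatives: list[ProteinRecord] = []
    if spec.negative_mode == "random":
        for i in range(1, spec.n_negatives + 1):
            seq = _random_sequence(rng, spec.seq_length, bg)
            negatives.append(ProteinRecord(id=f"neg{i}", sequence=decode(seq), label=Label.NON_ALLERGEN))
    elif spec.negative_mode == "shuffled":
        for i in range(1, spec.n_negatives + 1):
            src = positives[(i - 1) % len(positives)]
            perm = rng.permutation(len(src.sequence))
            shuffled = "".join(src.sequence[j] for j in perm)
            negatives.append(ProteinRecord(id=f"neg{i}", sequence=shuffled, label=Label.NON_ALLERGEN))
    else:  # reversed
        if spec.n_negatives > len(positives):
            raise ValueError("reversed mode cannot produce more negatives than positives")
        for i in range(1, spec.n_negatives + 1):
            src = positives[i - 1]
            negatives.append(
                ProteinRecord(id=f"{src.id}_rev", sequence=src.sequence[::-1], label=Label.NON_ALLERGEN)
            )

    return SequenceDataset(
        positives + negatives,
        provenance=f"fixture(seed={spec.seed},mode={spec.negative_mode})",
    )


def generate_composition_benchmark(
    n_per_class: int = 100,
    seq_length: int = 100,
    favored_fraction: float = 0.8,
    seed: int = 0,
) -> SequenceDataset:
    """Two classes separable by amino-acid composition alone.

    Positive sequences draw each residue from {A, L, V} with probability
    ``favored_fraction`` (uniform within the set), negatives likewise from
    {D, E, K}; remaining draws are uniform over the other 17 residues. With
    the default 0.8 the favored residues dominate every sequence, making the
    composition classes linearly separable by construction.
    """
    rng = np.random.default_rng(seed)
    sets = {"pos": ("ALV", Label.ALLERGEN), "neg": ("DEK", Label.NON_ALLERGEN)}
    records: list[ProteinRecord] = []
    for prefix, (favored, label) in sets.items():
        favored_idx = np.array([AA_ORDER.index(a) for a in favored])
        other_idx = np.array([i for i in range(20) if i not in favored_idx])
        for i in range(1, n_per_class + 1):
            use_favored = rng.random(seq_length) < favored_fraction
            seq = np.where(
                use_favored,
                favored_idx[rng.integers(0, len(favored_idx), size=seq_length)],
                other_idx[rng.integers(0, len(other_idx), size=seq_length)],
            )
            records.append(ProteinRecord(id=f"{prefix}{i}", sequence=decode(seq), label=label))
    return SequenceDataset(records, provenance=f"composition_benchmark(seed={seed})")


def rule2_boundary_pair() -> tuple[ProteinRecord, ProteinRecord]:
    """An 80-residue pair whose best local alignment is exactly 28/80 identical.

    28 evenly spread columns are W-W identities (BLOSUM62 +11); the other 52
    columns pair I in the query with L in the allergen (BLOSUM62 +2). Every
    column scores positive, so the unique optimal Smith-Waterman alignment is
    the full-length gapless one: identity 28/80 = 35.0% exactly, flipping the
    window-identity verdict at a 35% threshold under the >= convention.
    """
    query = []
    allergen = []
    acc = 0
    for _ in range(80):
        acc += 28
        if acc >= 80:  # Bresenham spread of the 28 identity columns
            acc -= 80
            query.append("W")
            allergen.append("W")
        else:
            query.append("I")
            allergen.append("L")
    q = ProteinRecord(id="boundary_query", sequence="".join(query), label=Label.UNKNOWN)
    a = ProteinRecord(id="boundary_allergen", sequence="".join(allergen), label=Label.ALLERGEN)
    return q, a
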