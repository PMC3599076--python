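"""FAO/WHO sequence-similarity rules for allergen prediction.

Rule 1 flags a query sharing an exact stretch of ``wordsize`` (default 6)
consecutive identical residues with any known allergen; a shared identical
stretch of length >= w exists iff a shared w-mer exists, so exact w-mer
lookup implements the "six or more" criterion. Rule 2 slides an 80-residue
window along the query one residue at a time and flags the query if any
window aligns to any allergen at >= 35% identity (thresholds configurable,
as are the comparison convention and the identity denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import alignment_identity
from .records import ProteinRecord, SequenceDataset, Verdict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Rule1Params:
    """Exact word-match rule parameters."""

    wordsize: int = 6

    def __post_init__(self) -> None:
        if self.wordsize < 2:
            raise ValueError("wordsize must be >= 2")


@dataclass(frozen=True)
class Rule2Params:
    """Sliding-window identity rule parameters.

    identity_denominator: ``"alignment"`` divides identical columns by the
    alignment length (BLAST convention, default); ``"window"`` divides by the
    window length. strict: require identity strictly greater than the
    threshold instead of >= (both conventions appear in published wordings
    of the 35% criterion).
    """

    window: int = 80
    step: int = 1
    identity_threshold: float = 0.35
    identity_denominator: str = "alignment"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.identity_denominator not in ("alignment", "window"):
            raise ValueError("identity_denominator must be 'alignment' or 'window'")


@dataclass(frozen=True)
class RuleHit:
    """Evidence for one rule match. Positions are 1-based inclusive."""

    query_id: str
    allergen_id: str
    rule: str  # "rule1" | "rule2"
    query_start: int
    word: str | None = None  # rule 1: the matched word
    identity: float | None = None  # rule 2: window identity


@dataclass
class WordIndex:
    """Exact w-mer index over an allergen set.

    Maps every ``wordsize``-mer occurring in any allergen to its
    (allergen_id, 1-based start) occurrences.
    """

    wordsize: int
    words: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.words.values())


def build_word_index(allergens: SequenceDataset, wordsize: int) -> WordIndex:
    """Index every wordsize-mer of every allergen sequence."""
    if wordsize < 2:
        raise ValueError("wordsize must be >= 2")
    index = WordIndex(wordsize=wordsize)
    for rec in allergens:
        if len(rec.sequence) < wordsize:
            logger.info("allergen %r shorter than wordsize %d; contributes no words", rec.id, wordsize)
            continue
        seq = rec.sequence
        for i in range(len(seq) - wordsize + 1):
            index.words.setdefault(seq[i : i + wordsize], []).append((rec.id, i + 1))
    return index


def rule1_predict(query: ProteinRecord, index: WordIndex, params: Rule1Params | None = None) -> Verdict:
    """Rule 1: positive iff the query shares an exact wordsize-mer with an allergen."""
    params = params or Rule1Params(wordsize=index.wordsize)
    if params.wordsize != index.wordsize:
        raise ValueError(f"index built with wordsize {index.wordsize}, params ask {params.wordsize}")
    w = params.wordsize
    hits: list[RuleHit] = []
    if len(query.sequence) < w:
        logger.warning("query %r shorter than wordsize %d; negative by construction", query.id, w)
        return Verdict(query.id, "rule1", False, [])
    seq = query.sequence
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        for allergen_id, _pos in index.words.get(word, ()):
            hits.append(RuleHit(query.id, allergen_id, "rule1", i + 1, word=word))
    return Verdict(query.id, "rule1", bool(hits), hits)


def rule2_max_identity(
    query: ProteinRecord,
    allergens: SequenceDataset,
    params: Rule2Params | None = None,
    exclude_self: bool = False,
) -> tuple[float, list[RuleHit]]:
    """Maximum window identity of a query against an allergen set.

    Each window (length ``min(window, len(query))``; a short query yields a
    single whole-sequence window) is locally aligned (Smith-Waterman,
    BLOSUM62, 11/1) to every allergen; returns the best identity over all
    (window, allergen) pairs plus the per-pair best hits. ``exclude_self``
    skips the allergen with the query's own id (used during evaluation).
    """
    params = params or Rule2Params()
    if len(allergens) == 0:
        raise ValueError("allergen set must be non-empty")
    seq = query.sequence
    w = min(params.window, len(seq))
    starts = range(0, len(seq) - w + 1, params.step)
    denominator = w if params.identity_denominator == "window" else None
    best = 0.0
    hits: list[RuleHit] = []
    for allergen in allergens:
        if exclude_self and allergen.id == query.id:
            continue
        pair_best = 0.0
        pair_start = 1
        for start in starts:
            window = seq[start : start + w]
            res = alignment_identity(window, allergen.sequence, mode="local", denominator=denominator)
            if res.identity > pair_best:
                pair_best, pair_start = res.identity, start + 1
        hits.append(RuleHit(query.id, allergen.id, "rule2", pair_start, identity=pair_best))
        best = max(best, pair_best)
    return best, hits


def rule2_predict(
    query: ProteinRecord,
    allergens: SequenceDataset,
    params: Rule2Params | None = None,
    exclude_self: bool = False,
) -> Verdict:
    """Rule 2: positive iff any window reaches the identity threshold."""
    params = params or Rule2Params()
    best, hits = rule2_max_identity(query, allergens, params, exclude_self=exclude_self)
    positive = best > params.identity_threshold if params.strict else best >= params.identity_threshold
    evidence = [
        h
        for h in hits
        if h.identity is not None
        and (h.identity > params.identity_threshold if params.strict else h.identity >= params.identity_threshold)
    ]
    return Verdict(query.id, "rule2", positive, evidence, score=best)


def rule_both_predict(
    query: ProteinRecord,
    index: WordIndex,
    allergens: SequenceDataset,
    r1: Rule1Params | None = None,
    r2: Rule2Params | None = None,
    mode: str = "or",
    exclude_self: bool = False,
) -> Verdict:
    """Boolean combination of rule 1 and rule 2 ("rule-both")."""
    if mode not in ("or", "and"):
        raise ValueError("mode must be 'or' or 'and'")
    v1 = rule1_predict(query, index, r1)
    v2 = rule2_predict(query, allergens, r2, exclude_self=exclude_self)
    positive = (v1.is_allergen or v2.is_allergen) if mode == "or" else (v1.is_allergen and v2.is_allergen)
    return Verdict(query.id, f"ruleboth_{mode}", positive, v1.evidence + v2.evidence, score=v2.score)
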