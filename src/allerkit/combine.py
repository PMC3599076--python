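"""Combined prediction: merge per-method verdicts into one integrated call.

The merge is a plain boolean function of the individual verdicts — ``any``
(OR, the permissive screen), ``all`` (AND, the conservative screen) or
``majority`` — and every per-method verdict and score is retained so the
integrated call is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import SequenceDataset, Verdict

COMBINATION_MODES = ("any", "all", "majority")


@dataclass
class CombinedVerdict:
    """Integrated verdict over several methods for one query."""

    query_id: str
    per_method: dict[str, Verdict]
    mode: str
    is_allergen: bool


def combine_verdicts(per_method: dict[str, list[Verdict]], mode: str = "any") -> list[CombinedVerdict]:
    """Merge per-method verdict lists (parallel over the same query set)."""
    if mode not in COMBINATION_MODES:
        raise ValueError(f"mode must be one of {COMBINATION_MODES}")
    if not per_method:
        raise ValueError("no methods to combine")
    methods = list(per_method)
    n = len(per_method[methods[0]])
    for m in methods:
        if len(per_method[m]) != n:
            raise ValueError(f"method {m!r} produced {len(per_method[m])} verdicts, expected {n}")
    combined: list[CombinedVerdict] = []
    for i in range(n):
        votes = {m: per_method[m][i] for m in methods}
        ids = {v.query_id for v in votes.values()}
        if len(ids) != 1:
            raise ValueError(f"verdicts at position {i} disagree on query id: {sorted(ids)}")
        positives = sum(v.is_allergen for v in votes.values())
        if mode == "any":
            call = positives > 0
        elif mode == "all":
            call = positives == len(methods)
        else:
            call = positives * 2 > len(methods)
        combined.append(CombinedVerdict(query_id=ids.pop(), per_method=votes, mode=mode, is_allergen=call))
    return combined


def predict_combined(
    queries: SequenceDataset,
    predictors: dict[str, object],
    mode: str = "any",
) -> list[CombinedVerdict]:
    """Run every configured predictor on the query set and merge the verdicts.

    ``predictors`` maps method name to a fitted object with a
    ``predict(SequenceDataset) -> list[Verdict]`` method. Configuration is
    validated up front: a predictor that raises on its first use aborts
    before any partial output.
    """
    if not predictors:
        raise ValueError("no methods configured")
    per_method = {name: predictor.predict(queries) for name, predictor in predictors.items()}
    return combine_verdicts(per_method, mode=mode)
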