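"""Core containers: labeled protein records, datasets and prediction verdicts."""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum

from .alphabet import AA_SET


class Label(str, Enum):
    """Class label of a protein record."""

    ALLERGEN = "allergen"
    NON_ALLERGEN = "non_allergen"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProteinRecord:
    """One identified, optionally species-annotated, labeled protein sequence.

    Parameters
    ----------
    id
        Unique identifier (FASTA header token before the first whitespace).
    sequence
        Upper-case amino-acid sequence over the standard 20-letter alphabet.
    species
        Optional source species; records without species bypass the
        same-species redundancy filter.
    label
        Class label; ``UNKNOWN`` for query sequences.
    """

    id: str
    sequence: str
    species: str | None = None
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}; "
                "sanitize on input (see read_fasta invalid= policy)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Label) -> "ProteinRecord":
        return replace(self, label=label)


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_counts(self) -> dict[Label, int]:
        counts: dict[Label, int] = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts

    def subset(self, indices: Iterable[int], provenance: str | None = None) -> "SequenceDataset":
        return SequenceDataset(
            [self.records[i] for i in indices],
            provenance=provenance if provenance is not None else self.provenance,
        )

    def filter_label(self, label: Label) -> "SequenceDataset":
        return SequenceDataset(
            [r for r in self.records if r.label is label],
            provenance=f"{self.provenance}|label={label.value}" if self.provenance else f"label={label.value}",
        )

    def relabel(self, label: Label) -> "SequenceDataset":
        return SequenceDataset([r.with_label(label) for r in self.records], provenance=self.provenance)

    @staticmethod
    def concat(datasets: Sequence["SequenceDataset"], provenance: str = "") -> "SequenceDataset":
        records = [r for ds in datasets for r in ds.records]
        return SequenceDataset(records, provenance=provenance)


@dataclass
class Verdict:
    """Outcome of one prediction method on one query.

    ``score`` is the method's graded output where one exists (rule-2 maximum
    window identity, motif combined E-value transformed to -log10, SVM
    allergen probability); rule-1 verdicts are binary and carry no score.
    ``evidence`` holds the method-specific hit objects backing the call.
    """

    query_id: str
    method: str
    is_allergen: bool
    evidence: list = field(default_factory=list)
    score: float | None = None
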