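"""FASTA I/O and dataset curation.

Implements the standard construction of an allergen benchmark: positives are
de-duplicated within species at high identity, the negative pool is purged of
anything detectably allergen-like (>= 30% local identity) or too short
(< 50 aa), negatives are sampled uniformly, and character-reversed allergens
provide the bias-free negative set for window-identity evaluation.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import alignment_identity
from .alphabet import AA_SET
from .records import Label, ProteinRecord, SequenceDataset

logger = logging.getLogger(__name__)

#: Default species extractor: UniProt-style "OS=Genus species ... XX=" header
#: field, else a tab-separated second header field.
SPECIES_RE = re.compile(r"OS=(.+?)(?:\s+[A-Z]{2}=|$)")


def _parse_species(description: str) -> str | None:
    m = SPECIES_RE.search(description)
    if m:
        return m.group(1).strip()
    parts = description.split("\t")
    if len(parts) >= 2 and parts[1].strip():
        return parts[1].strip()
    return None


def sanitize_sequence(raw: str, record_id: str, invalid: str = "strip") -> str:
    """Upper-case a raw sequence and apply the non-standard-residue policy.

    ``invalid="strip"`` drops ambiguity codes, non-standard residues, stops
    and gap characters with a warning; ``"reject"`` raises instead.
    """
    seq = raw.upper().replace(" ", "")
    bad = set(seq) - AA_SET
    if bad:
        if invalid == "reject":
            raise ValueError(f"record {record_id!r}: non-standard residues {sorted(bad)}")
        logger.warning("record %r: stripping non-standard residues %s", record_id, sorted(bad))
        seq = "".join(a for a in seq if a in AA_SET)
    return seq


def read_fasta(
    path: str | Path,
    label: Label = Label.UNKNOWN,
    invalid: str = "strip",
    species_regex: re.Pattern | None = None,
) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`.

    The header token before the first whitespace becomes the record id;
    species is parsed from the description (``OS=...`` field or tab-separated
    second column). Empty files and duplicate ids are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = sanitize_sequence(str(entry.seq), entry.id, invalid=invalid)
        if not seq:
            raise ValueError(f"record {entry.id!r} in {path}: empty sequence after sanitization")
        if species_regex is not None:
            m = species_regex.search(entry.description)
            species = m.group(1).strip() if m else None
        else:
            species = _parse_species(entry.description)
        records.append(ProteinRecord(id=entry.id, sequence=seq, species=species, label=label))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceDataset(records, provenance=str(path))


def write_fasta(ds: SequenceDataset, path: str | Path) -> None:
    """Write a dataset as 60-column-wrapped FASTA (species as ``OS=`` field)."""
    entries = []
    for rec in ds:
        description = f"OS={rec.species}" if rec.species else ""
        entries.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=description))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(entries)


@dataclass
class CurationAction:
    """One row of the curation audit trail."""

    record_id: str
    action: str  # kept | removed
    reason: str
    best_hit: str = ""
    identity: float | None = None


def write_curation_report(actions: list[CurationAction], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "action", "reason", "best_hit", "identity"])
        for a in actions:
            writer.writerow(
                [a.record_id, a.action, a.reason, a.best_hit, "" if a.identity is None else f"{a.identity:.4f}"]
            )


def redundancy_filter(
    ds: SequenceDataset,
    identity_threshold: float = 0.99,
    report: list[CurationAction] | None = None,
) -> SequenceDataset:
    """Remove near-duplicate records within each species.

    Two records are compared only when they share a species annotation;
    global (Needleman-Wunsch, BLOSUM62, 11/1) identity >= ``identity_threshold``
    marks the shorter one redundant. Within a redundant group the longest
    sequence is kept, ties broken by the lexicographically smallest id.
    Records without species are never removed.
    """
    by_species: dict[str, list[ProteinRecord]] = {}
    no_species: list[ProteinRecord] = []
    for rec in ds:
        if rec.species is None:
            no_species.append(rec)
        else:
            by_species.setdefault(rec.species, []).append(rec)

    kept_ids: set[str] = {r.id for r in no_species}
    if report is not None:
        for rec in no_species:
            report.append(CurationAction(rec.id, "kept", "no species annotation"))

    for species, group in by_species.items():
        # longest first so the group representative is the longest sequence
        ordered = sorted(group, key=lambda r: (-len(r.sequence), r.id))
        kept_group: list[ProteinRecord] = []
        for rec in ordered:
            redundant_with = None
            identity = None
            for kept in kept_group:
                res = alignment_identity(rec.sequence, kept.sequence, mode="global")
                if res.identity >= identity_threshold:
                    redundant_with, identity = kept, res.identity
                    break
            if redundant_with is None:
                kept_group.append(rec)
                kept_ids.add(rec.id)
                if report is not None:
                    report.append(CurationAction(rec.id, "kept", f"unique within {species}"))
            elif report is not None:
                report.append(
                    CurationAction(
                        rec.id,
                        "removed",
                        f"redundant within {species} (identity >= {identity_threshold:.2f})",
                        best_hit=redundant_with.id,
                        identity=identity,
                    )
                )

    return SequenceDataset(
        [r for r in ds if r.id in kept_ids],
        provenance=f"{ds.provenance}|redundancy<{identity_threshold}",
    )


def build_negative_pool(
    pool: SequenceDataset,
    allergens: SequenceDataset,
    identity_cut: float = 0.30,
    min_len: int = 50,
    min_alignment_len: int = 50,
    report: list[CurationAction] | None = None,
) -> SequenceDataset:
    """Filter a candidate pool into presumptive non-allergens.

    Removes records shorter than ``min_len`` and records whose best local
    alignment (Smith-Waterman, BLOSUM62, 11/1) to any allergen reaches
    ``identity_cut`` identity over at least ``min_alignment_len`` aligned
    columns. Survivors are relabeled ``non_allergen``.
    """
    if len(allergens) == 0:
        raise ValueError("allergen reference set must be non-empty")
    kept: list[ProteinRecord] = []
    for rec in pool:
        if len(rec.sequence) < min_len:
            if report is not None:
                report.append(CurationAction(rec.id, "removed", f"length < {min_len}"))
            continue
        hit = None
        hit_identity = None
        for allergen in allergens:
            res = alignment_identity(rec.sequence, allergen.sequence, mode="local")
            if res.length >= min_alignment_len and res.identity >= identity_cut:
                hit, hit_identity = allergen, res.identity
                break
        if hit is not None:
            if report is not None:
                report.append(
                    CurationAction(
                        rec.id,
                        "removed",
                        f"identity >= {identity_cut:.0%} with an allergen",
                        best_hit=hit.id,
                        identity=hit_identity,
                    )
                )
            continue
        kept.append(rec.with_label(Label.NON_ALLERGEN))
        if report is not None:
            report.append(CurationAction(rec.id, "kept", "passed negative-pool filters"))
    if not kept:
        logger.warning("negative pool is empty after filtering")
    return SequenceDataset(kept, provenance=f"{pool.provenance}|negpool")


def sample_negatives(pool: SequenceDataset, n: int, seed: int) -> SequenceDataset:
    """Uniform sample of ``n`` records without replacement, reproducible per seed."""
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    indices = rng.choice(len(pool), size=n, replace=False)
    return pool.subset(sorted(int(i) for i in indices), provenance=f"{pool.provenance}|sample{n}")


def reverse_dataset(ds: SequenceDataset) -> SequenceDataset:
    """Character-reverse every sequence; ids suffixed ``_rev``, labels non_allergen.

    Reversed allergens keep the length and residue composition of the
    originals while destroying any shared subsequence or alignable window,
    which makes them the unbiased negative set for similarity-based rules.
    """
    records = [
        ProteinRecord(
            id=f"{rec.id}_rev",
            sequence=rec.sequence[::-1],
            species=rec.species,
            label=Label.NON_ALLERGEN,
        )
        for rec in ds
    ]
    return SequenceDataset(records, provenance=f"{ds.provenance}|reversed")
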