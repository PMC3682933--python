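"""Reading, validating and writing barcode alignments and tabular outputs.

The central container is :class:`Alignment`, an ordered list of equal-length
:class:`SequenceRecord` objects.  Species labels (the described-species
assignment of each specimen) are parsed from FASTA headers; by default the
text before the first ``|`` is the species label and the remainder is the
record id, falling back to the whole header when no delimiter is present.

All user-facing column coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Upper-case IUPAC nucleotide codes plus the gap character.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised when records violate alignment invariants (lengths, ids, alphabet)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single aligned barcode sequence with its described-species label."""

    id: str
    species_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be non-empty")
        if not self.sequence:
            raise AlignmentError(f"record {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise AlignmentError(
                f"record {self.id!r}: illegal character {seq[pos]!r} at position {pos + 1}"
            )
        object.__setattr__(self, "sequence", seq)


class Alignment:
    """An ordered, equal-length set of sequence records.

    Parameters
    ----------
    records:
        Sequence records; all must share one length and carry unique ids.
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            offenders = self._length_offenders()
            raise AlignmentError(
                "records have unequal lengths: " + ", ".join(offenders)
            )
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise AlignmentError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        self.length: int = lengths.pop()

    def _length_offenders(self) -> list[str]:
        from collections import Counter

        counts = Counter(len(r.sequence) for r in self.records)
        majority = counts.most_common(1)[0][0]
        return [
            f"{r.id} (length {len(r.sequence)})"
            for r in self.records
            if len(r.sequence) != majority
        ] or [f"{r.id} (length {len(r.sequence)})" for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            return self.by_id()[key]
        return self.records[key]

    def by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species_label for r in self.records]

    def column(self, position: int) -> str:
        """Return the column at 1-based ``position`` as a string, one char per record."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        return "".join(r.sequence[position - 1] for r in self.records)


LabelParser = Callable[[str], tuple[str, str]]


def default_label_parser(header: str) -> tuple[str, str]:
    """Split ``species|id`` headers; whole header doubles as both when no ``|``."""
    if "|" in header:
        species, rest = header.split("|", 1)
        return species.strip(), rest.strip()
    return header.strip(), header.strip()


def regex_label_parser(pattern: str) -> LabelParser:
    """Build a parser from a regex with groups ``species`` and ``id``."""
    compiled = re.compile(pattern)

    def parse(header: str) -> tuple[str, str]:
        m = compiled.match(header)
        if m is None:
            raise AlignmentError(f"header {header!r} does not match {pattern!r}")
        return m.group("species"), m.group("id")

    return parse


def read_fasta(path: str | Path, label_parser: LabelParser = default_label_parser) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Species labels are extracted from each header by ``label_parser``
    (default: text before the first ``|``).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        species, rid = label_parser(header)
        records.append(SequenceRecord(id=rid, species_label=species, sequence=str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def strip_gap_columns(aln: Alignment) -> tuple[Alignment, dict[int, int]]:
    """Remove every column containing a gap in any record.

    Returns the gap-free alignment and the surviving-column map
    ``{new_position: original_position}`` (both 1-based) so that panel
    positions can be reported in the original coordinate system.
    """
    keep = [
        j for j in range(aln.length)
        if all(r.sequence[j] != "-" for r in aln.records)
    ]
    if not keep:
        raise AlignmentError("all columns contain gaps; nothing left after stripping")
    column_map = {new + 1: old + 1 for new, old in enumerate(keep)}
    records = [
        SequenceRecord(
            id=r.id,
            species_label=r.species_label,
            sequence="".join(r.sequence[j] for j in keep),
        )
        for r in aln.records
    ]
    return Alignment(records), column_map


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA with ``species|id`` headers."""
    write_fasta(((f"{r.species_label}|{r.id}", r.sequence) for r in aln.records), path)


def write_phylip_matrix(labels: Sequence[str], values, path: str | Path) -> None:
    """Write a square (lower+upper) PHYLIP distance matrix."""
    import numpy as np

    values = np.asarray(values, dtype=float)
    n = len(labels)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, label in enumerate(labels):
            row = " ".join(f"{values[i, j]:.6f}" for j in range(n))
            fh.write(f"{label[:30]:<32s}{row}\n")


def write_tsv(rows: Iterable[Mapping[str, object]], columns: Sequence[str], path: str | Path) -> None:
    """Write rows of dicts as a UTF-8 TSV with a header row."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def write_metadata(meta: Mapping[str, object], path: str | Path) -> None:
    """Write run metadata (seed, parameters, versions) as JSON."""
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
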