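"""IUPAC-ambiguity consensus per OTU and silent/non-silent SNP classification.

Each OTU is summarised by a strict (union) consensus: at every position the
consensus base set is the union of the member base sets, written as the
standard IUPAC ambiguity code.  Union rather than majority semantics is what
lets a diagnostic panel guarantee that an assay distinguishes taxa no matter
which member haplotype is sampled.

Silent/non-silent classification translates consensus codons under the
invertebrate mitochondrial genetic code (NCBI translation table 5 by
default): a position is non-silent when two OTUs have disjoint amino-acid
sets over all disambiguations of the codon containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable, IUPACData

from .alignment_io import Alignment

ALL_BASES = frozenset("ACGT")

#: IUPAC code -> base set (e.g. "R" -> {A, G})
CODE_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code not in ("X",)
}
#: base set -> IUPAC code
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

DEFAULT_GENETIC_CODE = 5  # invertebrate mitochondrial


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusProfile:
    """Union consensus of one OTU: IUPAC string plus per-position base sets."""

    otu_id: int | str
    consensus: str
    base_sets: list[frozenset[str]]
    n_members: int
    uninformative: list[bool]  # True where every member had a gap

    def __len__(self) -> int:
        return len(self.base_sets)


@dataclass
class ReadingFrame:
    """Reading frame chosen to minimise forced internal stop codons."""

    offset: int  # 1, 2 or 3: alignment column where the first codon starts
    genetic_code: int
    n_internal_stops: dict[int, int]  # candidate offset -> forced-stop count


def build_consensus(aln: Alignment, members: set[str] | list[str], otu_id: int | str = "consensus") -> ConsensusProfile:
    """Union (IUPAC) consensus over the given member ids.

    Per position the base set is the union of member bases, with input
    ambiguity codes expanded to their base sets.  Gaps are ignored unless
    every member has a gap, in which case the base set is {A,C,G,T} and the
    position is flagged uninformative.
    """
    members = list(members)
    if not members:
        raise ConsensusError("members must be non-empty")
    by_id = aln.by_id()
    unknown = [m for m in members if m not in by_id]
    if unknown:
        raise ConsensusError(f"unknown member ids: {unknown}")
    seqs = [by_id[m].sequence for m in members]
    base_sets: list[frozenset[str]] = []
    uninformative: list[bool] = []
    chars: list[str] = []
    for j in range(aln.length):
        bases: set[str] = set()
        for s in seqs:
            c = s[j]
            if c == "-":
                continue
            bases |= CODE_TO_BASES[c]
        if not bases:  # unanimous gap
            base_sets.append(ALL_BASES)
            uninformative.append(True)
            chars.append("N")
        else:
            fs = frozenset(bases)
            base_sets.append(fs)
            uninformative.append(False)
            chars.append(BASES_TO_CODE[fs])
    return ConsensusProfile(
        otu_id=otu_id,
        consensus="".join(chars),
        base_sets=base_sets,
        n_members=len(members),
        uninformative=uninformative,
    )


def profile_from_string(sequence: str, otu_id: int | str = "consensus") -> ConsensusProfile:
    """Wrap an existing IUPAC consensus string as a profile (n_members=1)."""
    sequence = sequence.upper().replace("U", "T")
    base_sets = []
    uninformative = []
    for c in sequence:
        if c == "-":
            base_sets.append(ALL_BASES)
            uninformative.append(True)
        else:
            base_sets.append(CODE_TO_BASES[c])
            uninformative.append(False)
    return ConsensusProfile(
        otu_id=otu_id,
        consensus=sequence.replace("-", "N"),
        base_sets=base_sets,
        n_members=1,
        uninformative=uninformative,
    )


@lru_cache(maxsize=100_000)
def _amino_acid_set(codon: tuple[frozenset, frozenset, frozenset], code_id: int) -> frozenset[str]:
    """Amino acids ('*' for stop) over all disambiguations of a codon."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    aas = set()
    for b1, b2, b3 in product(*codon):
        c = b1 + b2 + b3
        aas.add("*" if c in table.stop_codons else table.forward_table[c])
    return frozenset(aas)


def _codon_at(profile: ConsensusProfile, start0: int) -> tuple[frozenset, frozenset, frozenset]:
    return (profile.base_sets[start0], profile.base_sets[start0 + 1], profile.base_sets[start0 + 2])


def infer_frame(
    profiles: list[ConsensusProfile],
    genetic_code: int = DEFAULT_GENETIC_CODE,
) -> ReadingFrame:
    """Choose the reading frame minimising forced internal stop codons.

    For each candidate offset 1..3, codons whose every disambiguation is a
    stop are counted over all profiles (terminal codon excluded); the offset
    with the minimum count wins, ties broken by the smallest offset.
    """
    if not profiles:
        raise ConsensusError("need at least one profile")
    length = len(profiles[0])
    if length < 3:
        raise ConsensusError("alignment too short to contain a codon")
    counts: dict[int, int] = {}
    for offset in (1, 2, 3):
        total = 0
        for prof in profiles:
            starts = range(offset - 1, length - 2, 3)
            starts = list(starts)
            for s in starts[:-1]:  # internal codons only
                aas = _amino_acid_set(_codon_at(prof, s), genetic_code)
                if aas == frozenset({"*"}):
                    total += 1
        counts[offset] = total
    best = min((1, 2, 3), key=lambda o: (counts[o], o))
    return ReadingFrame(offset=best, genetic_code=genetic_code, n_internal_stops=counts)


@dataclass
class SilentCall:
    classification: str  # "silent" | "non_silent"
    warning: bool = False  # position outside any complete codon

    def __eq__(self, other):
        if isinstance(other, str):
            return self.classification == other
        return (self.classification, self.warning) == (other.classification, other.warning)


def classify_silent(
    profiles: list[ConsensusProfile],
    position: int,
    frame: ReadingFrame,
) -> SilentCall:
    """Classify the 1-based alignment ``position`` as silent or non-silent.

    Non-silent iff two OTUs have disjoint amino-acid sets for the codon
    containing the position (all disambiguations, chosen genetic code).
    Positions that fall before the frame start or in an incomplete terminal
    codon are classified silent with a warning flag.
    """
    length = len(profiles[0])
    if not 1 <= position <= length:
        raise ConsensusError(f"position {position} outside 1..{length}")
    pos0 = position - 1
    start0 = frame.offset - 1
    if pos0 < start0:
        return SilentCall("silent", warning=True)
    codon_start = start0 + 3 * ((pos0 - start0) // 3)
    if codon_start + 2 >= length:
        return SilentCall("silent", warning=True)
    aa_sets = [
        _amino_acid_set(_codon_at(p, codon_start), frame.genetic_code)
        for p in profiles
    ]
    for i in range(len(aa_sets)):
        for j in range(i + 1, len(aa_sets)):
            if not (aa_sets[i] & aa_sets[j]):
                return SilentCall("non_silent")
    return SilentCall("silent")
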