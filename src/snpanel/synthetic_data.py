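"""Synthetic barcode alignments with a planted barcode gap and ground truth.

The generator emulates the structure of a curated COI barcode compilation:
clusters of near-identical haplotypes per OTU separated by a clear gap
between within- and between-OTU distances, optional singleton species,
optional shared haplotypes between OTU pairs (mitochondrial introgression),
and codon structure under the invertebrate mitochondrial genetic code.

Generation follows a star phylogeny: a random ancestral coding sequence
(no internal stops, translation table 5) gives rise to one founder per OTU
by Poisson(length x divergence) substitutions with transition bias kappa
and codon-position weighting; members then derive from their founder by
Poisson(length x within_diversity) substitutions.  Mutations are
substitution-only; indels are out of scope since the pipeline strips gap
columns anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .alignment_io import Alignment, SequenceRecord

_BASES = np.array(list("ACGT"))
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated barcode data set.

    Defaults emulate a typical barcode compilation: a 699 bp coding
    fragment, within-OTU diversity well below between-OTU divergence
    (the barcode gap), a strong transition bias, and substitutions landing
    mostly at third codon positions.
    """

    n_otus: int = 10
    members_per_otu: int | list[int] = 5
    length: int = 699
    divergence: float = 0.08       # expected between-OTU substitutions/site
    within_diversity: float = 0.003  # expected within-OTU substitutions/site
    kappa: float = 4.0             # transition:transversion ratio
    codon_position_weights: tuple[float, float, float] = (0.1, 0.05, 0.85)
    introgression_pairs: list[tuple[int, int]] = field(default_factory=list)
    composite_species_pairs: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 1

    def member_counts(self) -> list[int]:
        if isinstance(self.members_per_otu, int):
            return [self.members_per_otu] * self.n_otus
        if len(self.members_per_otu) != self.n_otus:
            raise SimulationError("members_per_otu list must have n_otus entries")
        return list(self.members_per_otu)

    def validate(self) -> None:
        if self.length < 6 or self.length % 3 != 0:
            raise SimulationError("length must be >= 6 and divisible by 3")
        if not 0.0 < self.divergence < 1.0:
            raise SimulationError("divergence must be in (0, 1)")
        if not 0.0 <= self.within_diversity < 1.0:
            raise SimulationError("within_diversity must be in [0, 1)")
        if self.within_diversity >= self.divergence:
            raise SimulationError(
                "within_diversity must be below divergence (planted barcode gap)"
            )
        if any(c < 1 for c in self.member_counts()):
            raise SimulationError("every OTU needs at least one member")
        w = self.codon_position_weights
        if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise SimulationError("codon_position_weights must be 3 non-negative values summing to 1")
        for a, b in self.introgression_pairs:
            if not (0 <= a < self.n_otus and 0 <= b < self.n_otus) or a == b:
                raise SimulationError(f"bad introgression pair ({a}, {b})")


@dataclass
class GroundTruth:
    """Everything planted by the generator, recoverable by inspection."""

    partition: dict[str, int]           # sequence id -> true OTU (1-based)
    species_labels: dict[str, str]      # sequence id -> species label
    shared_haplotypes: list[dict]       # planted introgression events
    mutation_log: dict[str, list[tuple[int, str, str]]]  # id -> (pos, from, to)
    founders: list[str]                 # founder haplotype per OTU


def _random_coding_sequence(n_codons: int, rng: np.random.Generator, code_id: int = 5) -> np.ndarray:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(table.stop_codons)
    codon_strings = []
    for i1 in range(4):
        for i2 in range(4):
            for i3 in range(4):
                c = _BASES[i1] + _BASES[i2] + _BASES[i3]
                if c not in stops:
                    codon_strings.append((i1, i2, i3))
    picks = rng.integers(0, len(codon_strings), size=n_codons)
    out = np.empty(3 * n_codons, dtype=np.int8)
    for i, p in enumerate(picks):
        out[3 * i : 3 * i + 3] = codon_strings[p]
    return out


def _mutate(
    seq: np.ndarray,
    n_subs: int,
    rng: np.random.Generator,
    kappa: float,
    weights: tuple[float, float, float],
) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """Apply ``n_subs`` substitutions; returns new sequence and mutation log."""
    out = seq.copy()
    length = len(seq)
    site_w = np.tile(np.asarray(weights) / (length / 3), length // 3)
    p_ts = kappa / (kappa + 2.0)
    log: list[tuple[int, str, str]] = []
    if n_subs <= 0:
        return out, log
    positions = rng.choice(length, size=n_subs, replace=True, p=site_w)
    for pos in positions:
        old = int(out[pos])
        if rng.random() < p_ts:
            new = _TRANSITION[old]
        else:
            new = int(rng.choice([b for b in range(4) if b != old and b != _TRANSITION[old]]))
        out[pos] = new
        log.append((int(pos) + 1, str(_BASES[old]), str(_BASES[new])))
    return out, log


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def simulate_alignment(cfg: SimulationConfig) -> tuple[Alignment, GroundTruth]:
    """Simulate a barcode alignment with planted OTU structure.

    Deterministic given ``cfg.seed``.  Species labels equal OTU labels
    unless ``composite_species_pairs`` merges two OTUs under one label;
    ``introgression_pairs`` (a, b) copy OTU a's founder haplotype into OTU
    b's member list under OTU b's species label (a shared haplotype).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_coding_sequence(cfg.length // 3, rng)
    counts = cfg.member_counts()

    species_of_otu = {i: f"sp{i + 1:03d}" for i in range(cfg.n_otus)}
    for a, b in cfg.composite_species_pairs:
        species_of_otu[b] = species_of_otu[a]

    founders: list[np.ndarray] = []
    founder_logs: list[list[tuple[int, str, str]]] = []
    for _ in range(cfg.n_otus):
        n_subs = rng.poisson(cfg.length * cfg.divergence)
        founder, log = _mutate(ancestor, max(int(n_subs), 1), rng, cfg.kappa, cfg.codon_position_weights)
        founders.append(founder)
        founder_logs.append(log)

    records: list[SequenceRecord] = []
    partition: dict[str, int] = {}
    species_labels: dict[str, str] = {}
    mutation_log: dict[str, list[tuple[int, str, str]]] = {}
    for otu in range(cfg.n_otus):
        for m in range(counts[otu]):
            sid = f"otu{otu + 1:03d}_m{m + 1}"
            n_subs = rng.poisson(cfg.length * cfg.within_diversity)
            seq, log = _mutate(founders[otu], int(n_subs), rng, cfg.kappa, cfg.codon_position_weights)
            records.append(SequenceRecord(id=sid, species_label=species_of_otu[otu], sequence=_to_str(seq)))
            partition[sid] = otu + 1
            species_labels[sid] = species_of_otu[otu]
            mutation_log[sid] = founder_logs[otu] + log

    shared: list[dict] = []
    for a, b in cfg.introgression_pairs:
        sid = f"otu{b + 1:03d}_introg_from_otu{a + 1:03d}"
        # copy a realized member haplotype (not the founder) so the shared
        # haplotype is guaranteed to exist in the donor OTU's sample
        donor = f"otu{a + 1:03d}_m1"
        donor_seq = next(r.sequence for r in records if r.id == donor)
        records.append(SequenceRecord(id=sid, species_label=species_of_otu[b], sequence=donor_seq))
        partition[sid] = a + 1  # genetically it carries OTU a's haplotype
        species_labels[sid] = species_of_otu[b]
        mutation_log[sid] = list(mutation_log[donor])
        shared.append({
            "haplotype_of_otu": a + 1,
            "carried_by_species": species_of_otu[b],
            "native_species": species_of_otu[a],
            "sequence_id": sid,
        })

    truth = GroundTruth(
        partition=partition,
        species_labels=species_labels,
        shared_haplotypes=shared,
        mutation_log=mutation_log,
        founders=[_to_str(f) for f in founders],
    )
    return Alignment(records), truth


def simulate_candidate_pool(
    n_otus: int,
    n_positions: int,
    seed: int = 1,
    n_states_range: tuple[int, int] = (2, 4),
    skew: float = 0.6,
):
    """Generate a candidate-SNP pool directly, without an alignment.

    Emulates the state structure of a pool extracted from real consensi: at
    each position the OTUs are partitioned among 2-4 single-base states,
    with one majority state holding roughly ``skew`` of the OTUs.  Useful
    for exercising the panel search at scales (many OTUs, wide pools) that
    a 25-per-OTU extraction cap cannot reach.
    """
    from .panel_search import CandidateSNP

    rng = np.random.default_rng(seed)
    otu_ids = list(range(1, n_otus + 1))
    pool = []
    for pos in range(1, n_positions + 1):
        n_states = int(rng.integers(n_states_range[0], n_states_range[1] + 1))
        bases = rng.choice(4, size=n_states, replace=False)
        probs = np.full(n_states, (1.0 - skew) / max(n_states - 1, 1))
        probs[0] = skew if n_states > 1 else 1.0
        assign = rng.choice(n_states, size=n_otus, p=probs)
        if len(set(assign.tolist())) < 2:  # force polymorphism
            assign[int(rng.integers(n_otus))] = (assign[0] + 1) % n_states
        states = {
            otu: frozenset({str(_BASES[bases[a]])}) for otu, a in zip(otu_ids, assign)
        }
        pool.append(
            CandidateSNP(
                position=pos,
                states=states,
                degeneracy=len(set(states.values())),
                silent=bool(rng.random() < 0.8),
                sponsors=set(otu_ids),
            )
        )
    return pool


def fixture_suite() -> dict[str, dict]:
    """Small hand-checkable instances used across the test suite.

    - ``panel6``: 3 OTU consensi where pair (A,B) differs exactly at
      positions {1,2,3}, (A,C) at {4,5,6} and (B,C) at all six, so the
      minimal k=3 panel is all six positions and the minimal k=1 panel has
      size 2.
    - ``bimodal``: a simulated alignment with a wide planted barcode gap.
    - ``introgression``: zero within-OTU diversity plus one planted shared
      haplotype, giving one composite OTU and one multi-species haplotype.
    - ``additive``: a 5-leaf tree's exact additive distance matrix.
    """
    fixtures: dict[str, dict] = {}

    # panel6: A/B differ at 1-3, A/C at 4-6, B/C at 1-6; identical elsewhere
    base = "AAATTTGGG"
    seq_a = base
    seq_b = "GGG" + base[3:]
    seq_c = base[:3] + "CCC" + base[6:]
    fixtures["panel6"] = {
        "consensi": {"A": seq_a, "B": seq_b, "C": seq_c},
        "pool_positions": [1, 2, 3, 4, 5, 6],
        "min_size_k3": 6,
        "min_size_k1": 2,
    }

    cfg = SimulationConfig(n_otus=6, members_per_otu=4, length=300,
                           divergence=0.10, within_diversity=0.002, seed=42)
    fixtures["bimodal"] = {"config": cfg}

    cfg_intro = SimulationConfig(n_otus=5, members_per_otu=4, length=300,
                                 divergence=0.10, within_diversity=0.0,
                                 introgression_pairs=[(0, 1)], seed=7)
    fixtures["introgression"] = {"config": cfg_intro}

    # additive: unrooted 5-leaf tree ((L1:2,L2:3):1,(L3:4,L4:5):2,L5:6)
    labels = ["L1", "L2", "L3", "L4", "L5"]
    import numpy as _np
    dist = _np.array([
        [0, 5, 9, 10, 9],
        [0, 0, 10, 11, 10],
        [0, 0, 0, 9, 12],
        [0, 0, 0, 0, 13],
        [0, 0, 0, 0, 0],
    ], dtype=float)
    dist = dist + dist.T
    fixtures["additive"] = {"labels": labels, "matrix": dist}
    return fixtures
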