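"""Candidate SNP extraction and randomized near-minimal panel search.

A diagnostic panel is a set of alignment positions such that every pair of
OTU consensus sequences is *incompatible* (disjoint IUPAC base sets) at no
fewer than ``k`` of them.  Disjointness — rather than mere inequality — is
deliberate: it guarantees the panel separates the taxa regardless of which
underlying member haplotype is sampled, because the union consensus covers
all observed states.

Candidates are drawn per OTU: every polymorphic position at which the OTU is
incompatible with at least one other OTU is ranked (non-silent first, then
higher degeneracy, then smaller position) and the top 25 per OTU are pooled.
The search then screens random subsets of the pool at increasing sizes until
one satisfies the pairwise-k requirement; when the requested number of
trials covers the whole subset space at the current size, the screening
enumerates the subsets in lexicographic order instead of sampling, so small
instances are solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .consensus import ConsensusProfile, ReadingFrame, classify_silent


class PanelError(ValueError):
    pass


class InfeasiblePoolError(PanelError):
    """Some OTU pair has fewer than k incompatible positions in the pool."""


class PoolExhaustedError(PanelError):
    pass


def incompatible(state_a: frozenset, state_b: frozenset) -> bool:
    """True iff the two base sets are disjoint (no shared disambiguation)."""
    if not state_a or not state_b:
        raise PanelError("base sets must be non-empty")
    return not (state_a & state_b)


@dataclass
class CandidateSNP:
    """One polymorphic alignment position considered for a panel."""

    position: int  # 1-based alignment column
    states: dict  # otu_id -> frozenset of bases
    degeneracy: int  # distinct base-set states across OTUs
    silent: bool
    sponsors: set = field(default_factory=set)  # OTUs whose top-25 include it


@dataclass
class Panel:
    """A panel of positions with its pairwise OTU difference matrix."""

    positions: tuple[int, ...]
    k_target: int
    otu_ids: list
    diff_matrix: np.ndarray
    achieved_min: int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)


def extract_candidates(
    profiles: list[ConsensusProfile],
    frame: ReadingFrame | None = None,
    max_per_otu: int = 25,
    prefer_nonsilent: bool = True,
) -> list[CandidateSNP]:
    """Preference-ranked candidate pool from OTU consensus profiles.

    For each OTU, positions where it is incompatible with at least one other
    OTU are ranked by (non-silent first if ``prefer_nonsilent``, then
    degeneracy descending, then position ascending) and the top
    ``max_per_otu`` are taken; the pool is the union, sorted by position.
    Without a reading frame all positions are treated as silent, which
    reduces the ranking to degeneracy and position.
    """
    if len(profiles) < 2:
        raise PanelError("need at least 2 OTU profiles")
    length = len(profiles[0])
    otu_ids = [p.otu_id for p in profiles]
    candidates: dict[int, CandidateSNP] = {}
    for pos in range(1, length + 1):
        states = {p.otu_id: p.base_sets[pos - 1] for p in profiles}
        distinct = set(states.values())
        if len(distinct) < 2:
            continue
        silent = True
        if frame is not None:
            silent = classify_silent(profiles, pos, frame).classification == "silent"
        candidates[pos] = CandidateSNP(
            position=pos,
            states=states,
            degeneracy=len(distinct),
            silent=silent,
        )
    if not candidates:
        raise PanelError("OTUs indistinguishable: no polymorphic positions")
    pool: dict[int, CandidateSNP] = {}
    for otu in otu_ids:
        useful = [
            c
            for c in candidates.values()
            if any(
                incompatible(c.states[otu], c.states[other])
                for other in otu_ids
                if other != otu
            )
        ]
        if prefer_nonsilent:
            key = lambda c: (c.silent, -c.degeneracy, c.position)
        else:
            key = lambda c: (-c.degeneracy, c.silent, c.position)
        useful.sort(key=key)
        for c in useful[:max_per_otu]:
            entry = pool.setdefault(c.position, c)
            entry.sponsors.add(otu)
    return [pool[p] for p in sorted(pool)]


def _pair_index(otu_ids: list) -> list[tuple[int, int]]:
    return list(combinations(range(len(otu_ids)), 2))


def incompatibility_matrix(pool: list[CandidateSNP], otu_ids: list) -> np.ndarray:
    """(n_positions, n_pairs) boolean: does position separate the OTU pair."""
    pairs = _pair_index(otu_ids)
    mat = np.zeros((len(pool), len(pairs)), dtype=bool)
    for r, cand in enumerate(pool):
        for c, (i, j) in enumerate(pairs):
            mat[r, c] = incompatible(cand.states[otu_ids[i]], cand.states[otu_ids[j]])
    return mat


def pair_diffs(positions: list[int], profiles: list[ConsensusProfile]) -> np.ndarray:
    """OTU x OTU matrix of incompatibility counts over the given positions."""
    n = len(profiles)
    diff = np.zeros((n, n), dtype=int)
    for pos in positions:
        for i in range(n):
            for j in range(i + 1, n):
                if incompatible(profiles[i].base_sets[pos - 1], profiles[j].base_sets[pos - 1]):
                    diff[i, j] += 1
                    diff[j, i] += 1
    return diff


def _check_feasible(incmat: np.ndarray, pool: list[CandidateSNP], otu_ids: list, k: int) -> None:
    per_pair = incmat.sum(axis=0)
    if (per_pair >= k).all():
        return
    pairs = _pair_index(otu_ids)
    worst = int(np.argmin(per_pair))
    i, j = pairs[worst]
    raise InfeasiblePoolError(
        f"pool infeasible for k={k}: OTU pair ({otu_ids[i]!r}, {otu_ids[j]!r}) "
        f"has only {int(per_pair[worst])} incompatible positions"
    )


def _eval_subsets(incmat_u: np.ndarray, idx: np.ndarray, k: int) -> int:
    """Index (within the batch) of the first satisfying subset, or -1."""
    acc = incmat_u[idx[:, 0]].astype(np.uint16)
    for col in range(1, idx.shape[1]):
        acc += incmat_u[idx[:, col]]
    ok = acc.min(axis=1) >= k
    hits = np.flatnonzero(ok)
    return int(hits[0]) if hits.size else -1


def _make_panel(
    positions: tuple[int, ...],
    pool: list[CandidateSNP],
    otu_ids: list,
    incmat: np.ndarray,
    subset: np.ndarray,
    k: int,
    metadata: dict,
) -> Panel:
    counts = incmat[subset].sum(axis=0)
    n = len(otu_ids)
    diff = np.zeros((n, n), dtype=int)
    for c, (i, j) in enumerate(_pair_index(otu_ids)):
        diff[i, j] = diff[j, i] = int(counts[c])
    return Panel(
        positions=positions,
        k_target=k,
        otu_ids=list(otu_ids),
        diff_matrix=diff,
        achieved_min=int(counts.min()) if counts.size else 0,
        metadata=metadata,
    )


def search_panel(
    pool: list[CandidateSNP],
    k: int,
    trials: int = 1_000_000,
    start_size: int | None = None,
    seed: int = 1,
    batch_size: int = 8192,
) -> Panel:
    """Randomized screening for a near-minimal panel with min pairwise diff >= k.

    For each subset size n (starting at ``start_size``, default ``k``, growing
    by one), up to ``trials`` n-subsets of the pool are screened and the
    first subset whose minimum pairwise incompatibility count reaches ``k``
    is returned.  If C(pool, n) <= trials the subsets are enumerated
    lexicographically (exact at that size); otherwise ``trials`` uniform
    random subsets are drawn.  Deterministic given ``seed``.
    """
    if k < 1:
        raise PanelError("k must be >= 1")
    if not pool:
        raise PanelError("empty candidate pool")
    otu_ids = sorted({o for c in pool for o in c.states}, key=str)
    incmat = incompatibility_matrix(pool, otu_ids)
    _check_feasible(incmat, pool, otu_ids, k)
    incmat_u = incmat.astype(np.uint16)
    P = len(pool)
    rng = np.random.default_rng(seed)
    n = start_size if start_size is not None else k
    if n < 1:
        raise PanelError("start_size must be >= 1")
    sizes_attempted: list[int] = []
    trials_per_size: dict[int, int] = {}
    mode_per_size: dict[int, str] = {}
    while True:
        if n > P:
            raise PoolExhaustedError(
                f"pool exhausted: no satisfying panel up to size {P}"
            )
        sizes_attempted.append(n)
        space = comb(P, n)
        if space <= trials:
            mode_per_size[n] = "enumerated"
            found = None
            screened = 0
            combos = combinations(range(P), n)
            while True:
                block = []
                for _ in range(batch_size):
                    try:
                        block.append(next(combos))
                    except StopIteration:
                        break
                if not block:
                    break
                idx = np.array(block, dtype=np.intp)
                hit = _eval_subsets(incmat_u, idx, k)
                if hit >= 0:
                    screened += hit + 1
                    found = idx[hit]
                    break
                screened += len(block)
            trials_per_size[n] = screened
            if found is not None:
                subset = np.sort(found)
                meta = {
                    "seed": seed,
                    "trials": trials,
                    "sizes_attempted": sizes_attempted,
                    "trials_per_size": trials_per_size,
                    "mode_per_size": mode_per_size,
                }
                return _make_panel(
                    tuple(pool[i].position for i in subset),
                    pool, otu_ids, incmat, subset, k, meta,
                )
        else:
            mode_per_size[n] = "sampled"
            found = None
            screened = 0
            remaining = trials
            while remaining > 0:
                b = min(batch_size, remaining)
                keys = rng.random((b, P))
                idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
                hit = _eval_subsets(incmat_u, idx, k)
                if hit >= 0:
                    screened += hit + 1
                    found = idx[hit]
                    break
                screened += b
                remaining -= b
            trials_per_size[n] = screened
            if found is not None:
                subset = np.sort(found)
                meta = {
                    "seed": seed,
                    "trials": trials,
                    "sizes_attempted": sizes_attempted,
                    "trials_per_size": trials_per_size,
                    "mode_per_size": mode_per_size,
                }
                return _make_panel(
                    tuple(pool[i].position for i in subset),
                    pool, otu_ids, incmat, subset, k, meta,
                )
        n += 1


def exhaustive_min_panel(pool: list[CandidateSNP], k: int, max_pool_size: int = 20) -> Panel:
    """Exact minimal panel by exhaustive enumeration (small pools only).

    Enumerates subset sizes ascending from ``k`` and, per size, all subsets
    in lexicographic order; the first satisfying subset is therefore the
    lexicographically smallest among the minimal ones.
    """
    if len(pool) > max_pool_size:
        raise PanelError(
            f"pool size {len(pool)} exceeds exhaustive guard {max_pool_size}"
        )
    otu_ids = sorted({o for c in pool for o in c.states}, key=str)
    incmat = incompatibility_matrix(pool, otu_ids)
    _check_feasible(incmat, pool, otu_ids, k)
    P = len(pool)
    for n in range(max(k, 1), P + 1):
        for subset in combinations(range(P), n):
            counts = incmat[list(subset)].sum(axis=0)
            if counts.size == 0 or counts.min() >= k:
                meta = {"mode": "exhaustive", "size": n}
                return _make_panel(
                    tuple(pool[i].position for i in subset),
                    pool, otu_ids, incmat, np.array(subset), k, meta,
                )
    raise PoolExhaustedError("no satisfying panel exists in the pool")


def validate_panel(
    panel: Panel,
    profiles: list[ConsensusProfile],
    k: int,
    groups: dict | None = None,
) -> dict:
    """Independent recount of a panel's pairwise differences.

    Recomputes the OTU x OTU difference matrix directly from the consensus
    profiles (not from the search's precomputed incompatibility matrix) and
    reports the achieved minimum, the mean +/- sample SD of off-diagonal
    differences, within/between-group means when ``groups`` maps otu ids to
    group names, and pass/fail versus ``k``.
    """
    order = {p.otu_id: i for i, p in enumerate(profiles)}
    missing = [o for o in panel.otu_ids if o not in order]
    if missing:
        raise PanelError(f"profiles missing for OTUs {missing}")
    profs = sorted((p for p in profiles if p.otu_id in set(panel.otu_ids)), key=lambda p: str(p.otu_id))
    diff = pair_diffs(list(panel.positions), profs)
    n = len(profs)
    iu = np.triu_indices(n, k=1)
    off = diff[iu]
    achieved_min = int(off.min()) if off.size else 0
    report = {
        "achieved_min": achieved_min,
        "k_target": k,
        "passes": bool(achieved_min >= k) if off.size else False,
        "n_pairwise_comparisons": int(off.size),
        "mean_diff": float(off.mean()) if off.size else float("nan"),
        "sd_diff": float(off.std(ddof=1)) if off.size > 1 else 0.0,
        "panel_size": len(panel.positions),
    }
    if groups is not None:
        gids = [groups[p.otu_id] for p in profs]
        within, between = {}, {}
        for a, b in zip(*iu):
            ga, gb = gids[a], gids[b]
            if ga == gb:
                within.setdefault(ga, []).append(diff[a, b])
            else:
                key = tuple(sorted((str(ga), str(gb))))
                between.setdefault(key, []).append(diff[a, b])
        report["within_group_mean"] = {g: float(np.mean(v)) for g, v in within.items()}
        report["between_group_mean"] = {
            "/".join(kk): float(np.mean(v)) for kk, v in between.items()
        }
    return report
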