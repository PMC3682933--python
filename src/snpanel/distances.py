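"""Pairwise distance computation: Kimura 2-parameter and Hamming matrices.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions (purine<->purine, pyrimidine<->pyrimidine) from
transversions:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the transition and transversion proportions over comparable
sites.  A site is comparable for a pair when both characters are unambiguous
bases (pairwise deletion of gaps and ambiguity codes); ``deletion="complete"``
instead drops any column that is ambiguous in any record before computing.

Distances are computed on the substitutions/site scale; the ``percent``
view (x100) matches the scale on which delimitation thresholds are quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment

_BASES = "ACGT"
_ENCODE = {c: i for i, c in enumerate(_BASES)}
_PURINE = {"A", "G"}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class DistanceError(ValueError):
    """Base class for distance-computation failures."""


class NoComparableSitesError(DistanceError):
    """A pair of sequences shares no site where both characters are unambiguous."""


class SaturationError(DistanceError):
    """The K2P logarithm argument is non-positive; the distance is undefined."""


@dataclass
class DistanceMatrix:
    """A symmetric labelled distance matrix.

    ``saturated`` flags pairs whose K2P distance is undefined (values are NaN
    there); downstream consumers must refuse flagged matrices rather than
    silently ingest NaNs.
    """

    labels: list[str]
    values: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(self.values - self.values.T)[np.isfinite(self.values)] > 1e-12).any():
            raise DistanceError("matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DistanceError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_saturation(self) -> bool:
        return self.saturated is not None and bool(self.saturated.any())

    def percent(self) -> "DistanceMatrix":
        """The same matrix on the percent scale (1.70 means 1.70%)."""
        return DistanceMatrix(self.labels, self.values * 100.0, self.saturated)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) values in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in keep]
        sat = self.saturated[np.ix_(idx, idx)] if self.saturated is not None else None
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)], sat)


def _classify_site(c1: str, c2: str) -> str | None:
    """'ts', 'tv', 'same', or None when the site is not comparable."""
    if c1 not in _ENCODE or c2 not in _ENCODE:
        return None
    if c1 == c2:
        return "same"
    return "ts" if (c1, c2) in _TRANSITIONS else "tv"


def k2p_distance(s1: str, s2: str) -> tuple[float, float, float, int]:
    """K2P distance between two equal-length sequences.

    Returns ``(d, P, Q, n_sites)`` where P and Q are the transition and
    transversion proportions over the ``n_sites`` comparable sites.

    Raises
    ------
    NoComparableSitesError
        If no site has unambiguous bases in both sequences.
    SaturationError
        If ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    if len(s1) != len(s2):
        raise DistanceError("sequences must have equal length")
    n_sites = ts = tv = 0
    for c1, c2 in zip(s1, s2):
        kind = _classify_site(c1, c2)
        if kind is None:
            continue
        n_sites += 1
        if kind == "ts":
            ts += 1
        elif kind == "tv":
            tv += 1
    if n_sites == 0:
        raise NoComparableSitesError("no comparable sites")
    P = ts / n_sites
    Q = tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}): K2P distance undefined"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, P, Q, n_sites


def _encode(sequences: list[str]) -> np.ndarray:
    """(n, L) int8 array; unambiguous bases 0..3, everything else -1."""
    table = np.full(128, -1, dtype=np.int8)
    for c, i in _ENCODE.items():
        table[ord(c)] = i
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return table[arr].reshape(len(sequences), -1)


def _pair_counts(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Comparable-site, transition and transversion counts for all pairs.

    Uses per-base indicator matrix products so the work is a handful of BLAS
    calls rather than an O(n^2 L) Python loop.
    """
    valid = (enc >= 0).astype(np.float64)
    n_sites = valid @ valid.T
    eq = np.zeros_like(n_sites)
    for b in range(4):
        m = (enc == b).astype(np.float64)
        eq += m @ m.T
    same_class = np.zeros_like(n_sites)
    for cls in ((0, 2), (1, 3)):  # purines {A,G}, pyrimidines {C,T}
        m = ((enc == cls[0]) | (enc == cls[1])).astype(np.float64)
        same_class += m @ m.T
    ts = same_class - eq
    tv = n_sites - same_class
    return np.rint(n_sites).astype(np.int64), np.rint(ts).astype(np.int64), np.rint(tv).astype(np.int64)


def _complete_deletion(enc: np.ndarray) -> np.ndarray:
    return enc[:, (enc >= 0).all(axis=0)]


def k2p_matrix(
    aln: Alignment,
    deletion: str = "pairwise",
    on_saturation: str = "raise",
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment.

    Parameters
    ----------
    deletion:
        ``"pairwise"`` (default) excludes a site per pair when either
        character is ambiguous; ``"complete"`` drops such columns globally.
    on_saturation:
        ``"raise"`` (default) raises :class:`SaturationError` naming the first
        offending pair; ``"flag"`` records saturated pairs in the matrix's
        ``saturated`` mask with NaN values.
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 records")
    enc = _encode([r.sequence for r in aln.records])
    if deletion == "complete":
        enc = _complete_deletion(enc)
        if enc.shape[1] == 0:
            raise NoComparableSitesError("complete deletion removed every column")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n_sites, ts, tv = _pair_counts(enc)
    ids = aln.ids
    off = ~np.eye(len(ids), dtype=bool)
    if (n_sites[off] == 0).any():
        i, j = np.argwhere((n_sites == 0) & off)[0]
        raise NoComparableSitesError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_sites > 0, ts / np.maximum(n_sites, 1), 0.0)
        Q = np.where(n_sites > 0, tv / np.maximum(n_sites, 1), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        sat = ((w1 <= 0.0) | (w2 <= 0.0)) & off
        d = -0.5 * np.log(np.where(w1 > 0, w1, np.nan)) - 0.25 * np.log(
            np.where(w2 > 0, w2, np.nan)
        )
    d[~off] = 0.0
    if sat.any():
        if on_saturation == "raise":
            i, j = np.argwhere(sat)[0]
            raise SaturationError(
                f"saturated pair {ids[i]!r} vs {ids[j]!r}: K2P distance undefined"
            )
        d[sat] = np.nan
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return DistanceMatrix(list(ids), d, sat if sat.any() else None)


def hamming_matrix(sequences: list[str], labels: list[str] | None = None) -> DistanceMatrix:
    """Integer counts of differing comparable sites for all sequence pairs.

    Applies the same pairwise-deletion rule as K2P: a site counts only when
    both characters are unambiguous bases.
    """
    if len(sequences) < 2:
        raise DistanceError("need at least 2 sequences")
    if len({len(s) for s in sequences}) != 1:
        raise DistanceError("sequences must have equal length")
    labels = labels if labels is not None else [str(i) for i in range(len(sequences))]
    enc = _encode(sequences)
    n_sites, ts, tv = _pair_counts(enc)
    off = ~np.eye(len(sequences), dtype=bool)
    if (n_sites[off] == 0).any():
        i, j = np.argwhere((n_sites == 0) & off)[0]
        raise NoComparableSitesError(
            f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
        )
    diff = (ts + tv).astype(float)
    np.fill_diagonal(diff, 0.0)
    return DistanceMatrix(list(labels), diff)


def hamming_pair(s1: str, s2: str) -> int:
    """Number of differing comparable sites between two sequences."""
    if len(s1) != len(s2):
        raise DistanceError("sequences must have equal length")
    return sum(
        1 for c1, c2 in zip(s1, s2) if _classify_site(c1, c2) in ("ts", "tv")
    )
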