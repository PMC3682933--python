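"""Barcode-gap threshold inference and threshold clustering into OTUs.

The delimitation threshold is read off the density of all pairwise genetic
distances: within-taxon distances pile up near zero, between-taxon distances
form a second mode, and the first depression ("barcode gap") between them is
taken as the transition point.  Because described species represented by a
single specimen (singletons) contribute only between-taxon distances and can
drag the depression towards zero, the inference can be run with singletons
excluded.

Sequences are then clustered at that threshold by single linkage: two
sequences share an OTU iff they are connected by a chain of pairwise
distances <= threshold (inclusive).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import gaussian_kde

from .distances import DistanceMatrix


class DelimitationError(ValueError):
    pass


class NoBarcodeGapError(DelimitationError):
    """The distance density has no interior local minimum; set a manual threshold."""


@dataclass
class ThresholdEstimate:
    """A data-driven delimitation threshold, on the percent-distance scale."""

    threshold: float
    all_local_minima: list[float]
    mode: str  # "including_singletons" | "excluding_singletons"
    n_distances_used: int


@dataclass
class OTUSummary:
    otu_id: int
    member_ids: list[str]
    species_labels: list[str]
    composite: bool      # >= 2 described species in one OTU
    split: bool          # contains a species that also occurs in another OTU
    singleton_otu: bool  # single-member OTU


@dataclass
class OTUPartition:
    """Assignment of every sequence to exactly one OTU at a stated threshold."""

    assignments: dict[str, int]
    threshold: float
    otus: list[OTUSummary]

    @property
    def n_otus(self) -> int:
        return len(self.otus)


def threshold_from_distances(
    values: np.ndarray,
    grid_points: int = 1024,
    bw_method: str = "silverman",
) -> tuple[float, list[float]]:
    """First local density minimum of a sample of (percent) distances.

    A Gaussian kernel density (Silverman's rule-of-thumb bandwidth) is
    evaluated on a ``grid_points``-point grid spanning ``[0, max(values)]``;
    interior grid points strictly lower than both neighbours are local
    minima, and the smallest-distance one is the threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise DelimitationError("no distances to analyse")
    if np.ptp(values) == 0.0:
        raise NoBarcodeGapError(
            "all distances are equal: no barcode gap detected; set a manual threshold"
        )
    try:
        kde = gaussian_kde(values, bw_method=bw_method)
    except np.linalg.LinAlgError as exc:  # degenerate sample
        raise NoBarcodeGapError(
            "degenerate distance distribution: no barcode gap detected"
        ) from exc
    grid = np.linspace(0.0, float(values.max()), grid_points)
    density = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_min = (density[interior] < density[interior - 1]) & (
        density[interior] < density[interior + 1]
    )
    minima = grid[interior[is_min]]
    if minima.size == 0:
        raise NoBarcodeGapError(
            "no barcode gap detected (unimodal distance density); "
            "set a manual threshold"
        )
    return float(minima[0]), [float(m) for m in minima]


def infer_threshold(
    dm: DistanceMatrix,
    species_labels: list[str],
    exclude_singletons: bool = False,
    grid_points: int = 1024,
) -> ThresholdEstimate:
    """Infer the delimitation threshold from a K2P distance matrix.

    ``dm`` is on the substitutions/site scale; the returned threshold is on
    the percent scale.  With ``exclude_singletons`` every sequence whose
    described species occurs exactly once is dropped before collecting the
    lower-triangle distances.
    """
    if len(species_labels) != dm.n:
        raise DelimitationError("species_labels must match matrix labels")
    if dm.has_saturation:
        raise DelimitationError(
            "matrix contains saturated pairs; resolve before threshold inference"
        )
    keep = list(dm.labels)
    if exclude_singletons:
        counts = Counter(species_labels)
        keep = [l for l, sp in zip(dm.labels, species_labels) if counts[sp] > 1]
    if len(keep) < 3:
        raise DelimitationError(
            f"only {len(keep)} sequences retained; need at least 3"
        )
    sub = dm.submatrix(keep)
    distances = sub.condensed() * 100.0
    threshold, minima = threshold_from_distances(distances, grid_points=grid_points)
    return ThresholdEstimate(
        threshold=threshold,
        all_local_minima=minima,
        mode="excluding_singletons" if exclude_singletons else "including_singletons",
        n_distances_used=int(distances.size),
    )


def cluster_otus(
    dm: DistanceMatrix,
    threshold: float,
    species_labels: list[str] | None = None,
) -> OTUPartition:
    """Single-linkage clustering at a percent threshold (inclusive <=).

    OTUs are the connected components of the graph joining pairs at distance
    <= threshold.  Component ids are canonicalized by the lexicographically
    smallest member id, numbered contiguously from 1, so the partition is
    invariant under permutation of the input order.
    """
    if threshold < 0:
        raise DelimitationError("threshold must be non-negative")
    if dm.has_saturation:
        raise DelimitationError("matrix contains saturated pairs; cannot cluster")
    if species_labels is None:
        species_labels = list(dm.labels)
    adj = (dm.values * 100.0) <= threshold
    np.fill_diagonal(adj, True)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    members: dict[int, list[int]] = {}
    for idx, c in enumerate(comp):
        members.setdefault(int(c), []).append(idx)
    # canonical order: lexicographically smallest member id
    ordered = sorted(members.values(), key=lambda idxs: min(dm.labels[i] for i in idxs))
    species_otus: dict[str, set[int]] = {}
    for otu_id, idxs in enumerate(ordered, start=1):
        for i in idxs:
            species_otus.setdefault(species_labels[i], set()).add(otu_id)
    assignments: dict[str, int] = {}
    otus: list[OTUSummary] = []
    for otu_id, idxs in enumerate(ordered, start=1):
        ids = [dm.labels[i] for i in idxs]
        sps = [species_labels[i] for i in idxs]
        for sid in ids:
            assignments[sid] = otu_id
        otus.append(
            OTUSummary(
                otu_id=otu_id,
                member_ids=ids,
                species_labels=sps,
                composite=len(set(sps)) >= 2,
                split=any(len(species_otus[sp]) >= 2 for sp in sps),
                singleton_otu=len(ids) == 1,
            )
        )
    return OTUPartition(assignments=assignments, threshold=threshold, otus=otus)


def percent_single_species(n_otus: int, n_composite: int) -> float:
    """Percentage of OTUs containing exactly one described species, 1 decimal."""
    if n_otus <= 0:
        raise DelimitationError("n_otus must be positive")
    return round(100.0 * (n_otus - n_composite) / n_otus, 1)


def summarize_partition(p: OTUPartition) -> dict:
    """Counts of OTUs, composite OTUs, split species, singletons, and the
    percentage of single-species OTUs."""
    n_composite = sum(1 for o in p.otus if o.composite)
    # a species is split iff its members span >= 2 OTUs
    split_species = {
        sp
        for sp in {s for o in p.otus for s in o.species_labels}
        if len({o.otu_id for o in p.otus if sp in o.species_labels}) >= 2
    }
    return {
        "n_otus": p.n_otus,
        "n_composite_otus": n_composite,
        "n_split_species": len(split_species),
        "n_singleton_otus": sum(1 for o in p.otus if o.singleton_otu),
        "percent_single_species_otus": percent_single_species(p.n_otus, n_composite),
        "threshold": p.threshold,
    }
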