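"""Knownness scoring for proteins and ortholog clusters.

A protein's knownness is the sum of its GO annotations weighted by evidence
code: well-characterised proteins accumulate many high-weight (experimental,
author-statement) annotations, while understudied proteins score near zero
because their annotations are few or purely electronic (IEA, weight 0).  A
cluster's knownness is the maximum over its members from the reference
species (human + 11 model organisms): one well-studied ortholog is taken to
make the whole family "known".

Because every annotation is dated by when it was first linked to the protein,
the same sum restricted to annotations up to a cut-off date yields the
historical knownness trajectory, which is non-decreasing by construction
(removed annotations are not tracked).

The "unknome" of a scored database is the set of clusters below a chosen
knownness threshold, optionally restricted to clusters conserved in required
species and in a minimum fraction of metazoan genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

from .annotation_io import (
    ASPECTS,
    DEFAULT_SCHEME,
    REFERENCE_SPECIES,
    Cluster,
    GoAnnotation,
    WeightScheme,
)

ALL_ASPECTS: frozenset[str] = frozenset(ASPECTS)


@dataclass(frozen=True)
class KnownnessRecord:
    """A computed knownness score for a protein or cluster."""

    subject_id: str
    score: float
    as_of_date: date | None = None
    scheme_name: str = "default"
    aspects_used: frozenset[str] = ALL_ASPECTS

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("knownness score cannot be negative")


@dataclass(frozen=True)
class UnknomeSelection:
    """Filter defining an unknome gene set: score at most ``max_knownness``,
    all ``required_species`` present, metazoan presence at least
    ``min_metazoan_presence``."""

    max_knownness: float
    required_species: frozenset[str] = frozenset()
    min_metazoan_presence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_metazoan_presence <= 1.0:
            raise ValueError("min_metazoan_presence must lie in [0, 1]")


def score_protein(
    annotations: Iterable[GoAnnotation],
    scheme: WeightScheme = DEFAULT_SCHEME,
    aspects_used: Iterable[str] = ALL_ASPECTS,
    include_negated: bool = False,
) -> float:
    """Sum evidence-code weights over one protein's annotations.

    Only annotations whose aspect is in ``aspects_used`` contribute
    (excluding the Component aspect is a supported option).  NOT-qualified
    annotations are excluded by default: a statement that a protein does
    *not* have a function is not evidence of known function.
    """
    aspects = frozenset(aspects_used)
    if not aspects:
        raise ValueError("aspects_used must be non-empty")
    if not aspects <= ASPECTS:
        raise ValueError(f"aspects_used must be a subset of {{P,F,C}}, got {sorted(aspects)}")
    annotations = list(annotations)
    protein_ids = {a.protein_id for a in annotations}
    if len(protein_ids) > 1:
        raise ValueError(f"annotations span multiple proteins: {sorted(protein_ids)}")
    total = 0.0
    for ann in annotations:
        if ann.negated and not include_negated:
            continue
        if ann.aspect not in aspects:
            continue
        total += scheme.weight(ann.evidence_code)
    return total


def score_cluster(
    cluster: Cluster,
    member_scores: Mapping[str, float],
    reference_species: Iterable[str] = REFERENCE_SPECIES,
) -> float:
    """Cluster knownness: the maximum member score over reference-species
    members.  Members outside the reference species are ignored; a cluster
    with no reference-species member is outside the database's scope and
    raises."""
    ref = frozenset(reference_species)
    scores = [
        float(member_scores.get(protein_id, 0.0))
        for protein_id, taxon, _symbol in cluster.members
        if taxon in ref
    ]
    if not scores:
        raise ValueError(
            f"cluster {cluster.cluster_id} has no member from the reference species"
        )
    return max(scores)


def knownness_at(
    annotations: Iterable[GoAnnotation],
    as_of: date,
    scheme: WeightScheme = DEFAULT_SCHEME,
    aspects_used: Iterable[str] = ALL_ASPECTS,
) -> float:
    """Knownness as of a given date: the score restricted to annotations
    first linked on or before ``as_of``.  Every annotation must be dated."""
    annotations = list(annotations)
    for ann in annotations:
        if ann.first_linked_date is None:
            raise ValueError(
                f"annotation {ann.protein_id}/{ann.go_term} ({ann.evidence_code}) "
                "has no date; cannot be used in a temporal query"
            )
    dated = [a for a in annotations if a.first_linked_date <= as_of]
    if not dated:
        return 0.0
    return score_protein(dated, scheme=scheme, aspects_used=aspects_used)


def knownness_timeline(
    annotations: Iterable[GoAnnotation],
    dates: Sequence[date],
    scheme: WeightScheme = DEFAULT_SCHEME,
    aspects_used: Iterable[str] = ALL_ASPECTS,
) -> list[tuple[date, float]]:
    """Evaluate :func:`knownness_at` at each date (sorted ascending)."""
    annotations = list(annotations)
    return [
        (d, knownness_at(annotations, d, scheme=scheme, aspects_used=aspects_used))
        for d in sorted(dates)
    ]


def rank_clusters(
    scored: Iterable[tuple[Cluster, float]],
    species_filter: Iterable[str] = (),
    descending: bool = False,
) -> list[tuple[Cluster, float]]:
    """Rank clusters by knownness, least-known first by default.

    Clusters lacking any of the species in ``species_filter`` are removed
    (an empty filter retains all).  Ties are broken lexicographically by
    cluster id, making the order fully deterministic.
    """
    required = frozenset(species_filter)
    kept = [(c, s) for c, s in scored if required <= c.taxa]
    kept.sort(key=lambda cs: ((-cs[1] if descending else cs[1]), cs[0].cluster_id))
    return kept


def select_unknome(
    scored: Iterable[tuple[Cluster, float]],
    selection: UnknomeSelection,
    metazoan_presence: Mapping[str, float] | None = None,
) -> set[str]:
    """Select the unknome: cluster ids passing all three predicates of
    ``selection``.  The presence table must cover every candidate whenever
    ``min_metazoan_presence`` is positive."""
    presence = metazoan_presence or {}
    chosen: set[str] = set()
    for cluster, score in scored:
        if selection.min_metazoan_presence > 0 and cluster.cluster_id not in presence:
            raise ValueError(
                f"cluster {cluster.cluster_id} missing from the metazoan presence table"
            )
        if score > selection.max_knownness:
            continue
        if not selection.required_species <= cluster.taxa:
            continue
        if presence.get(cluster.cluster_id, 0.0) < selection.min_metazoan_presence:
            continue
        chosen.add(cluster.cluster_id)
    return chosen


def fraction_below(
    scores: Mapping[str, float],
    threshold: float,
    subset_ids: Iterable[str] | None = None,
) -> float:
    """Fraction of clusters (or of ``subset_ids``) scoring at or below the
    threshold — e.g. the share of all clusters, or of clusters carrying a
    domain of unknown function, in the low-knownness tail."""
    if subset_ids is None:
        subset = set(scores)
    else:
        subset = set(subset_ids)
        extra = subset - set(scores)
        if extra:
            raise ValueError(f"subset ids not among scored clusters: {sorted(extra)[:5]}")
    if not subset:
        raise ValueError("cannot take a fraction over an empty subset")
    below = sum(1 for cid in subset if scores[cid] <= threshold)
    return below / len(subset)
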