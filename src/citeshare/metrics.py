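"""Per-article overlap metrics: recall, precision and average precision.

For a focal article with annotation set ``A`` and a citation neighborhood
whose annotated neighbors collectively carry the unique annotation set ``U``:

* recall      = |A ∩ U| / |A| — fraction of the article's annotations that
  appear in at least one neighbor;
* precision   = |A ∩ U| / |U| — fraction of the unique neighborhood
  annotations that the article itself carries;
* average precision (AP) = Σ_k P(k)·ΔR(k) over the neighborhood annotations
  ranked by document frequency, with the article's own annotations as the
  relevant set. P(k) is the precision of the top-k ranks, R(k) the fraction of
  the relevant set found in the top k, and R(0) = 0. Relevant annotations
  missing from the ranking contribute nothing, so AP ≤ recall always.

Articles with no annotations of their own or no annotated neighbors carry no
signal for these ratios; they raise :class:`ExcludedRecord`, and corpus sweeps
count them rather than emitting numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ingest import AnnotationStore, ArticleID
from .network import CitationGraph, NeighborhoodProfile, neighborhood_profile


class ExcludedRecord(ValueError):
    """Raised when an article cannot be scored (empty A or empty U)."""


def overlap(
    article_annots: Iterable[str],
    neighborhood: NeighborhoodProfile | Iterable[str],
) -> tuple[float, float, int]:
    """Return (recall, precision, n_shared) for one article.

    ``neighborhood`` may be a :class:`NeighborhoodProfile` or any iterable of
    unique neighborhood annotations. Empty article annotations or an empty
    neighborhood raise :class:`ExcludedRecord`.
    """
    a = frozenset(article_annots)
    if isinstance(neighborhood, NeighborhoodProfile):
        u = neighborhood.unique_annotations
    else:
        u = frozenset(neighborhood)
    if not a:
        raise ExcludedRecord("article has no annotations")
    if not u:
        raise ExcludedRecord("neighborhood has no annotations")
    shared = len(a & u)
    return shared / len(a), shared / len(u), shared


def rank_annotations(profile: NeighborhoodProfile) -> list[str]:
    """Rank neighborhood annotations by descending document frequency.

    Ties break by ascending annotation token, making the ranking — and hence
    AP — deterministic. The full ordering over all unique neighborhood
    annotations is returned (no cut-off).
    """
    return sorted(profile.freq, key=lambda a: (-profile.freq[a], a))


def average_precision(ranking: Sequence[str], relevant: Iterable[str]) -> float:
    """AP = Σ_{k=1}^{N} P(k)·ΔR(k) of a ranking against a relevant set.

    R's denominator is the full relevant set, so relevant items absent from
    the ranking penalize AP (AP < 1 whenever recall < 1).
    """
    rel = frozenset(relevant)
    if not rel:
        raise ExcludedRecord("relevant set is empty")
    hits = 0
    ap = 0.0
    for k, item in enumerate(ranking, start=1):
        if item in rel:
            hits += 1
            # ΔR(k) = 1/|rel| at a hit, 0 elsewhere; P(k) = hits/k.
            ap += (hits / k) / len(rel)
    return ap


def expected_average_precision(
    profile: NeighborhoodProfile,
    relevant: Iterable[str],
    max_exhaustive_group: int = 6,
    n_samples: int = 1000,
    seed: int = 0,
) -> float:
    """AP averaged over orderings of annotations tied on document frequency.

    The lexicographic tie-break in :func:`rank_annotations` is reproducible
    but arbitrary; this mode averages AP over permutations within each tie
    group instead. Groups of at most ``max_exhaustive_group`` members are
    enumerated exhaustively; larger tie structures fall back to seeded
    Monte-Carlo averaging over whole-ranking draws.
    """
    rel = frozenset(relevant)
    if not rel:
        raise ExcludedRecord("relevant set is empty")
    groups: dict[int, list[str]] = {}
    for a, f in profile.freq.items():
        groups.setdefault(f, []).append(a)
    ordered_freqs = sorted(groups, reverse=True)
    if all(len(groups[f]) <= max_exhaustive_group for f in ordered_freqs):
        total, count = 0.0, 0
        perm_sets = [list(itertools.permutations(sorted(groups[f]))) for f in ordered_freqs]
        for combo in itertools.product(*perm_sets):
            ranking = [a for block in combo for a in block]
            total += average_precision(ranking, rel)
            count += 1
        return total / count
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_samples):
        ranking = []
        for f in ordered_freqs:
            block = list(groups[f])
            rng.shuffle(block)
            ranking.extend(block)
        total += average_precision(ranking, rel)
    return total / n_samples


@dataclass
class OverlapRecord:
    """Recall/precision/AP of one article against its neighborhood."""

    focal: ArticleID
    n_annotated_neighbors: int
    n_article_annots: int
    n_neighborhood_annots: int
    n_shared: int
    recall: float
    precision: float
    ap: float

    TSV_HEADER = ("focal\tn_annotated_neighbors\tn_article_annots\t"
                  "n_neighborhood_annots\tn_shared\trecall\tprecision\tap")

    def to_tsv_row(self) -> str:
        return (f"{self.focal}\t{self.n_annotated_neighbors}\t{self.n_article_annots}\t"
                f"{self.n_neighborhood_annots}\t{self.n_shared}\t"
                f"{self.recall:.10g}\t{self.precision:.10g}\t{self.ap:.10g}")


@dataclass
class EvaluationResult:
    """Corpus evaluation output: one record per scorable target article."""

    records: list[OverlapRecord] = field(default_factory=list)
    n_targets: int = 0
    n_excluded_no_annotated_neighbors: int = 0
    n_excluded_no_own_annotations: int = 0
    mode: str = "undirected"
    degree: int = 1

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(OverlapRecord.TSV_HEADER + "\n")
            for rec in self.records:
                fh.write(rec.to_tsv_row() + "\n")

    def exclusions(self) -> dict[str, int]:
        return {
            "no_annotated_neighbors": self.n_excluded_no_annotated_neighbors,
            "no_own_annotations": self.n_excluded_no_own_annotations,
        }


def score_article(
    article_annots: Iterable[str], profile: NeighborhoodProfile
) -> OverlapRecord:
    """Compose overlap, ranking and AP into one :class:`OverlapRecord`."""
    a = frozenset(article_annots)
    recall, precision, shared = overlap(a, profile)
    ap = average_precision(rank_annotations(profile), a)
    return OverlapRecord(
        focal=profile.focal,
        n_annotated_neighbors=profile.annotated_neighbors,
        n_article_annots=len(a),
        n_neighborhood_annots=len(profile.freq),
        n_shared=shared,
        recall=recall,
        precision=precision,
        ap=ap,
    )


def evaluate_corpus(
    graph: CitationGraph,
    neighbor_store: AnnotationStore,
    target_store: AnnotationStore,
    targets: Iterable[ArticleID] | None = None,
    mode: str = "undirected",
    degree: int = 1,
) -> EvaluationResult:
    """Score every target article against its annotated citation neighbors.

    ``neighbor_store`` supplies neighborhood annotations and ``target_store``
    the articles' own (relevant) sets; they may differ, supporting
    cross-source evaluation of a gold standard against a large database.
    Targets with no annotated neighbors, or with no annotations of their own
    in the target store, are excluded and counted. Records are emitted in
    sorted target order, so identical inputs give byte-identical output.
    """
    if targets is None:
        targets = target_store.articles()
    targets = sorted(set(targets))
    result = EvaluationResult(n_targets=len(targets), mode=mode, degree=degree)
    for focal in targets:
        own = target_store.get(focal)
        if not own:
            result.n_excluded_no_own_annotations += 1
            continue
        profile = neighborhood_profile(graph, neighbor_store, focal,
                                       mode=mode, degree=degree)
        if profile.annotated_neighbors == 0 or not profile.freq:
            result.n_excluded_no_annotated_neighbors += 1
            continue
        result.records.append(score_article(own, profile))
    return result


def mean_average_precision(records: Sequence[OverlapRecord]) -> float:
    """MAP: the mean AP over a set of per-article records."""
    if not records:
        raise ExcludedRecord("no records to average")
    return float(np.mean([r.ap for r in records]))
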