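"""Tolerance-based matching of two peak lists and appear/disappear classification.

Two spectra of the same construct acquired independently show the same
cross-peak at slightly different coordinates, so peaks are paired inside a
hard per-axis tolerance box (``tol_h`` on ¹H, ``tol_n`` on ¹⁵N) using the
standard combined chemical-shift distance

    d = sqrt(Δh² + (w·Δn)²)

with the customary nitrogen weighting w ≈ 0.14.  Among the in-box candidate
pairs, the pairing is the maximum-cardinality one-to-one assignment of
minimum total combined distance (Hungarian algorithm).  Reference peaks left
unmatched are *disappearing* signals; query peaks left unmatched are
*appearing* signals — the red/blue sets of a superimposed-spectra comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .peaklist_io import Peak, PeakList

__all__ = [
    "ToleranceSpec",
    "MatchResult",
    "ChangeSet",
    "combined_distance",
    "match_peaks",
    "classify_changes",
    "subset_recapitulation",
]


@dataclass(frozen=True)
class ToleranceSpec:
    """Per-axis matching tolerances (ppm) and the ¹⁵N weight of the combined distance."""

    tol_h: float = 0.03
    tol_n: float = 0.3
    n_weight: float = 0.14

    def __post_init__(self) -> None:
        if min(self.tol_h, self.tol_n, self.n_weight) <= 0:
            raise ValueError("tolerances and n_weight must be positive")

    @property
    def combined_radius(self) -> float:
        """Largest combined distance an in-box pair can have."""
        return float(np.hypot(self.tol_h, self.n_weight * self.tol_n))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing between a reference and a query peak list.

    ``pairs`` holds ``(ref_id, query_id, combined_distance)`` triples; ids in
    ``unmatched_ref``/``unmatched_query`` complete the partition of each list.
    """

    pairs: tuple[tuple[str, str, float], ...]
    unmatched_ref: tuple[str, ...]
    unmatched_query: tuple[str, ...]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def total_cost(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


@dataclass(frozen=True)
class ChangeSet:
    """Appearing/disappearing signals of a reference-vs-query comparison."""

    appearing: tuple[Peak, ...]
    disappearing: tuple[Peak, ...]
    reference_label: str = "reference"
    query_label: str = "query"

    @property
    def n_appearing(self) -> int:
        return len(self.appearing)

    @property
    def n_disappearing(self) -> int:
        return len(self.disappearing)

    @property
    def counts(self) -> tuple[int, int]:
        return (self.n_appearing, self.n_disappearing)

    def is_empty(self) -> bool:
        return not self.appearing and not self.disappearing


def combined_distance(a: Peak, b: Peak, tol: ToleranceSpec = ToleranceSpec()) -> float:
    """Weighted Euclidean distance sqrt(Δh² + (n_weight·Δn)²) between two peaks."""
    return float(
        np.hypot(a.h_shift - b.h_shift, tol.n_weight * (a.n_shift - b.n_shift))
    )


def _in_box(a: Peak, b: Peak, tol: ToleranceSpec) -> bool:
    return (
        abs(a.h_shift - b.h_shift) <= tol.tol_h
        and abs(a.n_shift - b.n_shift) <= tol.tol_n
    )


def match_peaks(
    reference: PeakList, query: PeakList, tol: ToleranceSpec = ToleranceSpec()
) -> MatchResult:
    """Pair reference and query peaks inside the tolerance box.

    Returns the maximum-cardinality one-to-one assignment of minimum total
    combined distance over in-box candidate pairs.  Peaks are pre-sorted by id
    so ties resolve reproducibly.
    """
    ref = sorted(reference.peaks, key=lambda p: p.id)
    qry = sorted(query.peaks, key=lambda p: p.id)
    if not ref or not qry:
        return MatchResult(
            pairs=(),
            unmatched_ref=tuple(p.id for p in ref),
            unmatched_query=tuple(p.id for p in qry),
        )

    rh = np.array([p.h_shift for p in ref])
    rn = np.array([p.n_shift for p in ref])
    qh = np.array([p.h_shift for p in qry])
    qn = np.array([p.n_shift for p in qry])
    dh = np.abs(rh[:, None] - qh[None, :])
    dn = np.abs(rn[:, None] - qn[None, :])
    dist = np.hypot(dh, tol.n_weight * dn)
    in_box = (dh <= tol.tol_h) & (dn <= tol.tol_n)

    # Out-of-box pairs get a forbidden cost far above any feasible total, so the
    # assignment maximises the number of in-box pairs before minimising distance.
    forbidden = float(dist.size * (dist.max() + 1.0) + 1.0)
    cost = np.where(in_box, dist, forbidden)
    rows, cols = linear_sum_assignment(cost)

    pairs = []
    matched_r: set[int] = set()
    matched_q: set[int] = set()
    for i, j in zip(rows, cols):
        if in_box[i, j]:
            pairs.append((ref[i].id, qry[j].id, float(dist[i, j])))
            matched_r.add(i)
            matched_q.add(j)
    pairs.sort()
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_ref=tuple(ref[i].id for i in range(len(ref)) if i not in matched_r),
        unmatched_query=tuple(qry[j].id for j in range(len(qry)) if j not in matched_q),
    )


def classify_changes(
    m: MatchResult, reference: PeakList, query: PeakList
) -> ChangeSet:
    """Turn a :class:`MatchResult` into appearing/disappearing peak sets."""
    ref_ids = reference.ids()
    qry_ids = query.ids()
    for rid, qid, _ in m.pairs:
        if rid not in ref_ids or qid not in qry_ids:
            raise ValueError(
                f"match refers to unknown peak ids ({rid!r}, {qid!r}); "
                "was it produced from these lists?"
            )
    unknown = (set(m.unmatched_ref) - ref_ids) | (set(m.unmatched_query) - qry_ids)
    if unknown:
        raise ValueError(f"match refers to unknown peak ids: {sorted(unknown)[:5]}")
    return ChangeSet(
        appearing=tuple(query.by_id(i) for i in m.unmatched_query),
        disappearing=tuple(reference.by_id(i) for i in m.unmatched_ref),
        reference_label=reference.haplotype.label,
        query_label=query.haplotype.label,
    )


def compare_lists(
    reference: PeakList, query: PeakList, tol: ToleranceSpec = ToleranceSpec()
) -> ChangeSet:
    """Convenience: :func:`match_peaks` followed by :func:`classify_changes`."""
    return classify_changes(match_peaks(reference, query, tol), reference, query)


def subset_recapitulation(
    short_list: PeakList, long_list: PeakList, tol: ToleranceSpec = ToleranceSpec()
) -> tuple[float, MatchResult]:
    """Fraction of the short construct's peaks recovered in the long construct's list.

    A truncated construct that keeps its fold shows a spectrum whose peaks are
    a subset of the longer construct's; a fraction of 1.0 means every short
    peak found an in-tolerance partner.
    """
    if len(short_list) == 0:
        warnings.warn("empty short list: subset fraction defined as 1.0", stacklevel=2)
        return 1.0, match_peaks(long_list, short_list, tol)
    m = match_peaks(long_list, short_list, tol)
    return m.n_matched / len(short_list), m
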