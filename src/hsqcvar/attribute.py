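"""Combinatorial attribution of spectral changes to individual substitutions.

When a multi-SNP variant's spectrum is compared to wild type, the observed
appearing/disappearing signals are the union of its member substitutions'
signatures (the mutations perturb disjoint local environments).  Attribution
therefore peels: single-SNP comparisons give their substitution's signature
directly; for larger haplotypes, the already-attributed components are
subtracted (tolerance-matched and removed) and the remainder is credited to
the one remaining substitution.  Redundant comparisons — a haplotype all of
whose members are already attributed, or a direct variant-vs-variant
comparison spanning one extra substitution — become consistency checks whose
residual must be empty on data satisfying the independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .compare import ChangeSet, ToleranceSpec, compare_lists, match_peaks
from .peaklist_io import Peak, PeakList
from .synthetic import VariantFamily
from .variants import Haplotype, Substitution

__all__ = [
    "AttributionError",
    "ConsistencyEntry",
    "AttributionReport",
    "AdditivityRow",
    "subtract_changes",
    "attribute_all",
    "additivity_check",
]


class AttributionError(RuntimeError):
    """A substitution cannot be isolated from the provided haplotypes."""


@dataclass(frozen=True)
class ConsistencyEntry:
    """One redundant comparison: expected signature vs what was observed."""

    description: str
    expected_source: str
    observed: ChangeSet
    residual_count: int


@dataclass(frozen=True)
class AttributionReport:
    per_substitution: dict[Substitution, ChangeSet]
    consistency: tuple[ConsistencyEntry, ...]
    trace: tuple[str, ...]

    def counts(self) -> dict[Substitution, tuple[int, int]]:
        """(appearing, disappearing) per substitution."""
        return {s: cs.counts for s, cs in self.per_substitution.items()}

    def max_residual(self) -> int:
        return max((c.residual_count for c in self.consistency), default=0)


@dataclass(frozen=True)
class AdditivityRow:
    haplotype: Haplotype
    predicted: tuple[int, int]
    observed: tuple[int, int]
    discrepancy: tuple[int, int]


def _as_list(peaks: tuple[Peak, ...]) -> PeakList:
    return PeakList(peaks=peaks)


def _remove_matched(
    total: tuple[Peak, ...], component: tuple[Peak, ...], tol: ToleranceSpec
) -> tuple[Peak, ...]:
    if not total or not component:
        return total
    m = match_peaks(_as_list(total), _as_list(component), tol)
    unmatched = set(m.unmatched_ref)
    return tuple(p for p in total if p.id in unmatched)


def subtract_changes(
    total: ChangeSet,
    component: ChangeSet,
    tol: ToleranceSpec = ToleranceSpec(),
    *,
    require_same_reference: bool = True,
) -> ChangeSet:
    """Remove the component's signals (tolerance-matched) from the total.

    Both change sets must come from comparisons against the same reference
    spectrum; peaks of ``total.appearing`` matching a ``component.appearing``
    peak within tolerance are removed (min-cost matching decides ambiguous
    cases), and likewise for disappearing.
    """
    if require_same_reference and total.reference_label != component.reference_label:
        raise ValueError(
            "change sets are anchored to different references: "
            f"{total.reference_label!r} vs {component.reference_label!r}"
        )
    return replace(
        total,
        appearing=_remove_matched(total.appearing, component.appearing, tol),
        disappearing=_remove_matched(total.disappearing, component.disappearing, tol),
    )


def _symmetric_residual(
    observed: ChangeSet, expected: ChangeSet, tol: ToleranceSpec
) -> int:
    """Size of the symmetric difference between two change sets under matching."""
    residual = 0
    for obs, exp in (
        (observed.appearing, expected.appearing),
        (observed.disappearing, expected.disappearing),
    ):
        if not obs and not exp:
            continue
        m = match_peaks(_as_list(obs), _as_list(exp), tol)
        residual += len(m.unmatched_ref) + len(m.unmatched_query)
    return residual


def attribute_all(
    family: VariantFamily, tol: ToleranceSpec = ToleranceSpec()
) -> AttributionReport:
    """Attribute appearing/disappearing signals to each substitution by peeling.

    Haplotypes are processed in increasing size: singles are compared to wild
    type directly; a haplotype with exactly one unattributed substitution has
    its attributed components subtracted and the remainder credited to that
    substitution.  Haplotypes whose members are all attributed, plus every
    direct variant-vs-variant comparison differing by one attributed
    substitution, contribute consistency entries.
    """
    wt = family.wild_type
    variants = [h for h in family.haplotypes if not h.is_wild_type]
    if not variants:
        raise AttributionError("family contains only wild type; nothing to attribute")

    changes = {h: compare_lists(wt, family.lists[h], tol) for h in variants}
    attributed: dict[Substitution, ChangeSet] = {}
    consistency: list[ConsistencyEntry] = []
    trace: list[str] = []
    pending = sorted(variants, key=lambda h: (len(h), h.label))

    progress = True
    while progress and pending:
        progress = False
        still_pending = []
        for hap in pending:
            unknown = [s for s in sorted(hap.subs) if s not in attributed]
            if len(unknown) > 1:
                still_pending.append(hap)
                continue
            if not unknown:
                # redundant route: everything should subtract away
                rem = changes[hap]
                comps = []
                for s in sorted(hap.subs):
                    rem = subtract_changes(rem, attributed[s], tol)
                    comps.append(str(s))
                consistency.append(
                    ConsistencyEntry(
                        description=(
                            f"WT vs {hap.label} minus attributed "
                            f"{{{', '.join(comps)}}} should be empty"
                        ),
                        expected_source="(empty)",
                        observed=rem,
                        residual_count=rem.n_appearing + rem.n_disappearing,
                    )
                )
            else:
                sub = unknown[0]
                rem = changes[hap]
                steps = [f"WT vs {hap.label}"]
                for s in sorted(hap.subs):
                    if s == sub:
                        continue
                    rem = subtract_changes(rem, attributed[s], tol)
                    steps.append(f"minus {s}")
                attributed[sub] = rem
                trace.append(f"{sub} <- " + " ".join(steps))
            progress = True
        pending = still_pending

    if pending:
        missing = sorted(
            {s for h in pending for s in h.subs if s not in attributed}
        )
        raise AttributionError(
            f"cannot isolate substitution(s) {[str(s) for s in missing]}: no "
            "haplotype chain reduces them to a single unattributed member "
            f"(stuck haplotypes: {[h.label for h in pending]})"
        )

    # direct variant-vs-variant consistency: hap2 = hap1 + one substitution
    for i, h1 in enumerate(variants):
        for h2 in variants:
            if h1 is h2 or not h1.subs < h2.subs:
                continue
            diff = h2.subs - h1.subs
            if len(diff) != 1:
                continue
            (sub,) = diff
            direct = compare_lists(family.lists[h1], family.lists[h2], tol)
            residual = _symmetric_residual(direct, attributed[sub], tol)
            consistency.append(
                ConsistencyEntry(
                    description=(
                        f"direct {h1.label} vs {h2.label} should reproduce the "
                        f"{sub} signature"
                    ),
                    expected_source=f"attributed {sub}",
                    observed=direct,
                    residual_count=residual,
                )
            )

    return AttributionReport(
        per_substitution=attributed,
        consistency=tuple(consistency),
        trace=tuple(trace),
    )


def additivity_check(
    family: VariantFamily,
    tol: ToleranceSpec = ToleranceSpec(),
    report: AttributionReport | None = None,
) -> list[AdditivityRow]:
    """Predicted-vs-observed change counts per haplotype.

    Predicted counts are the sums of the attributed per-substitution counts;
    observed counts come from the direct WT-vs-haplotype comparison.  On data
    with disjoint (independent) planted effects every discrepancy is zero;
    overlapping effects yield nonzero discrepancies, reported without error.
    """
    if report is None:
        report = attribute_all(family, tol)
    wt = family.wild_type
    rows = []
    for hap in family.haplotypes:
        if hap.is_wild_type:
            observed = (0, 0)
        else:
            observed = compare_lists(wt, family.lists[hap], tol).counts
        predicted = (
            sum(report.per_substitution[s].n_appearing for s in hap.subs),
            sum(report.per_substitution[s].n_disappearing for s in hap.subs),
        )
        rows.append(
            AdditivityRow(
                haplotype=hap,
                predicted=predicted,
                observed=observed,
                discrepancy=(
                    observed[0] - predicted[0],
                    observed[1] - predicted[1],
                ),
            )
        )
    return rows
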