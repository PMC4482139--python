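"""Phospho-dependent 14-3-3 binding motifs, kinase consensus sites and
GSK3 priming cascades.

The built-in motif definitions are the canonical short linear consensus
strings, anchored on the phosphoacceptor (offset 0, Ser or Thr):

======  =========  ========================================================
name    consensus  constraints relative to the phosphoacceptor
======  =========  ========================================================
mode1   RXXSXP     R at −3, P at +2; 14-3-3 binding, phospho-dependent
mode2   RXXXSXXP   R at −4, P at +3; 14-3-3 binding, phospho-dependent
camk2   RXXS       R at −3; CaMK2 substrate
agc     RXXXS      R at −4; AGC-group kinase substrate (PKA/PKG/PKC)
gsk3    SXXXS      phosphorylated S/T at +4 required (priming)
======  =========  ========================================================

GSK3 phosphorylates a Ser/Thr four residues N-terminal to a pre-existing
phosphosite, so one primary phosphorylation event can walk N-terminally in
four-residue steps (e.g. S26 → S22 → S18).  :func:`propagate_priming`
iterates this rule to a fixpoint and records each site's provenance chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .variants import AMINO_ACIDS, Haplotype, Substitution

__all__ = [
    "ProteinSequence",
    "MotifDef",
    "MotifHit",
    "PhosphoPrediction",
    "BindingReport",
    "VariantImpact",
    "VariantImpactReport",
    "DEFAULT_MOTIFS",
    "MODE1_1433",
    "MODE2_1433",
    "CAMK2",
    "AGC",
    "GSK3",
    "relaxed_motifs",
    "apply_substitutions",
    "scan_motifs",
    "propagate_priming",
    "evaluate_1433_binding",
    "variant_impact",
]

_ACCEPTOR = frozenset("ST")


@dataclass(frozen=True)
class ProteinSequence:
    """A one-letter protein sequence with an optional numbering offset.

    Residue at string index ``i`` (0-based) is reported at position
    ``i + 1 + numbering_offset``, so with the default offset the 1-based
    index equals the position.
    """

    residues: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_position(self) -> int:
        return self.numbering_offset + 1

    @property
    def last_position(self) -> int:
        return self.numbering_offset + len(self.residues)

    def in_range(self, position: int) -> bool:
        return self.first_position <= position <= self.last_position

    def at(self, position: int) -> str:
        """Residue at a reported (1-based, offset-aware) position."""
        if not self.in_range(position):
            raise IndexError(
                f"position {position} outside {self.first_position}.."
                f"{self.last_position}"
            )
        return self.residues[position - self.numbering_offset - 1]


@dataclass(frozen=True)
class MotifDef:
    """A consensus motif as position constraints around the phosphoacceptor."""

    name: str
    consensus: str
    constraints: tuple[tuple[int, frozenset[str]], ...]
    phospho_dependent: bool = False
    priming_offset: Optional[int] = None

    def offsets(self) -> tuple[int, int]:
        offs = [o for o, _ in self.constraints]
        return (min(offs), max(offs))


def _mk(name: str, consensus: str, constraints: dict[int, str],
        phospho_dependent: bool = False, priming_offset: Optional[int] = None) -> MotifDef:
    return MotifDef(
        name=name,
        consensus=consensus,
        constraints=tuple(
            sorted((o, frozenset(chars)) for o, chars in constraints.items())
        ),
        phospho_dependent=phospho_dependent,
        priming_offset=priming_offset,
    )


MODE1_1433 = _mk("mode1_1433", "RXXSXP", {-3: "R", 0: "ST", 2: "P"}, phospho_dependent=True)
MODE2_1433 = _mk("mode2_1433", "RXXXSXXP", {-4: "R", 0: "ST", 3: "P"}, phospho_dependent=True)
CAMK2 = _mk("camk2", "RXXS", {-3: "R", 0: "ST"})
AGC = _mk("agc", "RXXXS", {-4: "R", 0: "ST"})
GSK3 = _mk("gsk3", "SXXXS", {0: "ST", 4: "ST"}, priming_offset=4)

DEFAULT_MOTIFS: tuple[MotifDef, ...] = (MODE2_1433, MODE1_1433, CAMK2, AGC, GSK3)

_KINASE_MOTIFS: dict[str, MotifDef] = {"camk2": CAMK2, "agc": AGC}


def relaxed_motifs() -> tuple[MotifDef, ...]:
    """14-3-3 mode definitions with the C-terminal proline made optional.

    Some characterised 14-3-3 ligands lack the consensus proline; these
    relaxed variants drop that constraint.  Not scanned by default.
    """
    return (
        _mk("mode1_1433_relaxed", "RXXS", {-3: "R", 0: "ST"}, phospho_dependent=True),
        _mk("mode2_1433_relaxed", "RXXXS", {-4: "R", 0: "ST"}, phospho_dependent=True),
    )


@dataclass(frozen=True)
class MotifHit:
    """One motif match anchored at ``phosphosite`` (reported position)."""

    motif: str
    phosphosite: int
    span: tuple[int, int]
    priming_site: Optional[int] = None
    satisfied_by_cascade: bool = False
    proline_plus1: bool = False  # GSK3's noted preference, annotation only

    @property
    def key(self) -> tuple[str, int]:
        return (self.motif, self.phosphosite)


def apply_substitutions(seq: ProteinSequence, hap: Haplotype) -> ProteinSequence:
    """Return a copy of ``seq`` with the haplotype's substitutions applied.

    Raises ValueError naming the position if a substitution's reference
    residue does not match the sequence.
    """
    residues = list(seq.residues)
    for sub in hap:
        if not seq.in_range(sub.position):
            raise ValueError(f"substitution {sub}: position outside sequence")
        idx = sub.position - seq.numbering_offset - 1
        found = residues[idx]
        if found != sub.ref_aa:
            raise ValueError(
                f"substitution {sub}: expected {sub.ref_aa} at position "
                f"{sub.position}, found {found}"
            )
        residues[idx] = sub.alt_aa
    return replace(seq, residues="".join(residues))


def scan_motifs(
    seq: ProteinSequence, motifs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """All motif matches in ``seq``; overlapping and nested hits are all kept.

    GSK3 hits here require only the sequence pattern (S/T at the acceptor and
    at +4); whether the +4 site is actually phosphorylated is resolved later
    by :func:`propagate_priming`.
    """
    hits: list[MotifHit] = []
    for motif in motifs:
        lo, hi = motif.offsets()
        for pos in range(seq.first_position - lo, seq.last_position - hi + 1):
            if all(seq.at(pos + off) in allowed for off, allowed in motif.constraints):
                proline = (
                    motif.priming_offset is not None
                    and seq.in_range(pos + 1)
                    and seq.at(pos + 1) == "P"
                )
                hits.append(
                    MotifHit(
                        motif=motif.name,
                        phosphosite=pos,
                        span=(pos + lo, pos + hi),
                        priming_site=(
                            pos + motif.priming_offset
                            if motif.priming_offset is not None
                            else None
                        ),
                        proline_plus1=proline,
                    )
                )
    hits.sort(key=lambda h: (h.phosphosite, h.motif))
    return hits


@dataclass(frozen=True)
class PhosphoPrediction:
    """Predicted phosphosites with provenance (kinase, supplied, or cascade)."""

    sites: frozenset[int]
    provenance: Mapping[int, str] = field(default_factory=dict)

    def __contains__(self, position: int) -> bool:
        return position in self.sites

    def chain(self, position: int) -> list[int]:
        """The priming chain ending at ``position``, e.g. ``[26, 22, 18]``."""
        chain = [position]
        prov = self.provenance.get(position, "")
        while prov.startswith("gsk3"):
            primer = int(prov.rsplit(" ", 1)[1])
            chain.insert(0, primer)
            prov = self.provenance.get(primer, "")
        return chain


def propagate_priming(
    seq: ProteinSequence,
    primary_kinases: Iterable[str] = ("camk2", "agc"),
    extra_phospho: Iterable[int] = (),
) -> PhosphoPrediction:
    """Predict phosphosites from primary kinase consensus hits plus the GSK3 rule.

    Starts from the acceptor positions of the selected kinase consensus
    matches and any supplied sites, then repeatedly adds every Ser/Thr whose
    +4 position is already phosphorylated, to a fixpoint.  Terminates in at
    most len(seq) iterations and is independent of iteration order.
    """
    unknown = set(primary_kinases) - set(_KINASE_MOTIFS)
    if unknown:
        raise ValueError(f"unknown primary kinases {sorted(unknown)}; "
                         f"expected from {sorted(_KINASE_MOTIFS)}")
    provenance: dict[int, str] = {}
    for name in sorted(primary_kinases):
        for hit in scan_motifs(seq, [_KINASE_MOTIFS[name]]):
            provenance.setdefault(hit.phosphosite, name)
    for pos in extra_phospho:
        provenance.setdefault(int(pos), "supplied")

    sites = set(provenance)
    changed = True
    while changed:
        changed = False
        for pos in range(seq.first_position, seq.last_position + 1):
            if pos in sites:
                continue
            if seq.at(pos) in _ACCEPTOR and (pos + 4) in sites:
                sites.add(pos)
                provenance[pos] = f"gsk3 primed by {pos + 4}"
                changed = True
    return PhosphoPrediction(sites=frozenset(sites), provenance=provenance)


@dataclass(frozen=True)
class BindingReport:
    """Phospho-satisfied 14-3-3 hits and candidate bidentate (dimer) pairs."""

    hits: tuple[MotifHit, ...]
    bidentate_pairs: tuple[tuple[int, int], ...]


def evaluate_1433_binding(
    seq: ProteinSequence,
    phospho: PhosphoPrediction | Iterable[int],
    motifs: Sequence[MotifDef] = (MODE2_1433, MODE1_1433),
) -> BindingReport:
    """Restrict 14-3-3 mode hits to phosphorylated acceptors and pair them.

    A 14-3-3 dimer has two phosphopeptide grooves, so every unordered pair of
    satisfied hits at distinct phosphosites is a candidate bidentate
    engagement.
    """
    sites = phospho.sites if isinstance(phospho, PhosphoPrediction) else frozenset(phospho)
    cascade = (
        {p for p in sites if phospho.provenance.get(p, "").startswith("gsk3")}
        if isinstance(phospho, PhosphoPrediction)
        else set()
    )
    satisfied = tuple(
        replace(h, satisfied_by_cascade=h.phosphosite in cascade)
        for h in scan_motifs(seq, motifs)
        if h.phosphosite in sites
    )
    pairs = sorted(
        {
            tuple(sorted((a.phosphosite, b.phosphosite)))
            for i, a in enumerate(satisfied)
            for b in satisfied[i + 1 :]
            if a.phosphosite != b.phosphosite
        }
    )
    return BindingReport(hits=satisfied, bidentate_pairs=tuple(pairs))


@dataclass(frozen=True)
class VariantImpact:
    """Motif gains/losses of one haplotype relative to the reference sequence."""

    haplotype: Haplotype
    hits_lost: tuple[MotifHit, ...]
    hits_gained: tuple[MotifHit, ...]
    cascade_sites_lost: tuple[int, ...]
    cascade_sites_gained: tuple[int, ...]
    pairs_lost: tuple[tuple[int, int], ...]
    pairs_gained: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class VariantImpactReport:
    """Per-haplotype motif impact; singleton haplotypes index per substitution."""

    reference: BindingReport
    impacts: tuple[VariantImpact, ...]

    @property
    def per_substitution(self) -> dict[Substitution, VariantImpact]:
        return {
            next(iter(i.haplotype.subs)): i
            for i in self.impacts
            if len(i.haplotype) == 1
        }

    def for_haplotype(self, hap: Haplotype) -> VariantImpact:
        for i in self.impacts:
            if i.haplotype == hap:
                return i
        raise KeyError(hap.label)


def _pipeline(
    seq: ProteinSequence,
    primary_kinases: Iterable[str],
    extra_phospho: Iterable[int],
) -> tuple[PhosphoPrediction, BindingReport]:
    pred = propagate_priming(seq, primary_kinases, extra_phospho)
    return pred, evaluate_1433_binding(seq, pred)


def variant_impact(
    seq: ProteinSequence,
    haps: Sequence[Haplotype],
    primary_kinases: Iterable[str] = ("camk2", "agc"),
    extra_phospho: Iterable[int] = (),
) -> VariantImpactReport:
    """Run scan → priming → 14-3-3 evaluation on the reference and each
    haplotype's edited sequence, and diff the satisfied hits, cascade sites
    and bidentate pairs."""
    primary_kinases = tuple(primary_kinases)
    extra_phospho = tuple(extra_phospho)
    ref_pred, ref_bind = _pipeline(seq, primary_kinases, extra_phospho)
    ref_keys = {h.key: h for h in ref_bind.hits}
    ref_cascade = {p for p in ref_pred.sites
                   if ref_pred.provenance.get(p, "").startswith("gsk3")}

    impacts = []
    for hap in haps:
        edited = apply_substitutions(seq, hap)
        var_pred, var_bind = _pipeline(edited, primary_kinases, extra_phospho)
        var_keys = {h.key: h for h in var_bind.hits}
        var_cascade = {p for p in var_pred.sites
                       if var_pred.provenance.get(p, "").startswith("gsk3")}
        impacts.append(
            VariantImpact(
                haplotype=hap,
                hits_lost=tuple(ref_keys[k] for k in sorted(ref_keys.keys() - var_keys)),
                hits_gained=tuple(var_keys[k] for k in sorted(var_keys.keys() - ref_keys)),
                cascade_sites_lost=tuple(sorted(ref_cascade - var_cascade)),
                cascade_sites_gained=tuple(sorted(var_cascade - ref_cascade)),
                pairs_lost=tuple(
                    sorted(set(ref_bind.bidentate_pairs) - set(var_bind.bidentate_pairs))
                ),
                pairs_gained=tuple(
                    sorted(set(var_bind.bidentate_pairs) - set(ref_bind.bidentate_pairs))
                ),
            )
        )
    return VariantImpactReport(reference=ref_bind, impacts=tuple(impacts))
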