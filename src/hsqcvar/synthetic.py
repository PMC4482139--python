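"""Synthetic peak-list families, toy sequences and toy structures.

The generator plants per-substitution spectral changes into a shared base
spectrum: each substitution removes a fixed set of base peaks (*disappearing*
signals) and adds a fixed set of new ones (*appearing* signals), and a
multi-substitution haplotype applies the union of its members' effects.
Planted effects of distinct substitutions touch disjoint peaks, modelling
mutations that are distant in the tertiary structure and perturb only their
local environment.  All peaks keep a minimum pairwise combined-shift
separation well above twice the matching tolerance, and per-spectrum
positional jitter stays well below it, so tolerance-based matching recovers
every planted change exactly — the identifiability the comparison and
attribution modules are tested against.

Everything is a pure function of (scenario, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .motifs import MotifDef, ProteinSequence
from .peaklist_io import Peak, PeakList, SpectralWindow
from .structure import Atom, CoordinateSet
from .variants import Haplotype, Substitution

__all__ = [
    "MutationEffect",
    "ScenarioSpec",
    "VariantFamily",
    "reference_scenario",
    "generate_base_peaklist",
    "generate_variant_family",
    "truncate_to_segment",
    "generate_toy_sequence",
    "generate_toy_structures",
    "CapacityError",
]

# combined-distance weight mirroring the comparison default
_N_WEIGHT = 0.14
# default per-axis matching tolerances the separation guarantee refers to
_TOL_H, _TOL_N = 0.03, 0.3
_CROWD_FRACTION = 0.4  # fraction of peaks drawn from the crowded ¹H interval


class CapacityError(RuntimeError):
    """The spectral window cannot hold the requested peaks at the separation."""


@dataclass(frozen=True)
class MutationEffect:
    """Planted spectral signature of one substitution."""

    sub: Substitution
    n_disappear: int
    n_appear: int

    def __post_init__(self) -> None:
        if self.n_disappear < 0 or self.n_appear < 0:
            raise ValueError("effect counts must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic variant-family scenario.

    ``min_separation`` (combined-distance units) must exceed twice the
    combined matching-tolerance radius and the jitter standard deviations must
    stay below a third of the per-axis tolerances; together these make
    tolerance matching of the generated lists provably unambiguous.
    """

    n_base_peaks: int = 200
    effects: tuple[MutationEffect, ...] = ()
    window: SpectralWindow = field(default_factory=SpectralWindow)
    jitter_sd_h: float = 0.005
    jitter_sd_n: float = 0.05
    min_separation: float = 0.12
    segments: tuple[tuple[int, int], ...] = ((1, 494),)
    crowded_region: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_base_peaks < 0:
            raise ValueError("n_base_peaks must be >= 0")
        combined_tol = math.hypot(_TOL_H, _N_WEIGHT * _TOL_N)
        if self.min_separation <= 2 * combined_tol:
            raise ValueError(
                f"min_separation {self.min_separation} must exceed twice the "
                f"combined matching tolerance ({2 * combined_tol:.4f})"
            )
        if self.jitter_sd_h >= _TOL_H / 3 or self.jitter_sd_n >= _TOL_N / 3:
            raise ValueError("jitter sds must be below 1/3 of the matching tolerances")
        if sum(e.n_disappear for e in self.effects) > self.n_base_peaks:
            raise ValueError("total disappearing peaks exceed the base peak count")
        subs = [e.sub for e in self.effects]
        if len(set(subs)) != len(subs):
            raise ValueError("duplicate substitution in effects")

    def effect_for(self, sub: Substitution) -> MutationEffect:
        for e in self.effects:
            if e.sub == sub:
                return e
        raise KeyError(f"no planted effect for substitution {sub}")


@dataclass(frozen=True)
class VariantFamily:
    """A family of peak lists keyed by haplotype, plus planting bookkeeping.

    ``planted`` maps each substitution to the ids of its disappearing (base)
    peaks and appearing (new) peaks; ``base`` is the unjittered base list and
    ``appear_peaks`` the unjittered appearing peaks per substitution.  These
    are ``None`` for families assembled from external files.
    """

    lists: Mapping[Haplotype, PeakList]
    scenario: ScenarioSpec
    seed: int = 0
    planted: Optional[Mapping[Substitution, tuple[tuple[str, ...], tuple[str, ...]]]] = None
    base: Optional[PeakList] = None
    appear_peaks: Optional[Mapping[Substitution, tuple[Peak, ...]]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lists", dict(self.lists))
        if Haplotype() not in self.lists:
            raise ValueError("a variant family must contain the wild-type list")

    @property
    def wild_type(self) -> PeakList:
        return self.lists[Haplotype()]

    @property
    def haplotypes(self) -> list[Haplotype]:
        return sorted(self.lists, key=lambda h: (len(h), h.label))


# ---------------------------------------------------------------------------
# scenarios


def reference_scenario() -> ScenarioSpec:
    """The fixed study scenario for the three MYLK coding SNPs.

    Plants the characteristic HSQC signal changes of the 1-494aa N-terminal
    constructs: S147P with 5 appearing / 5 disappearing signals (the largest
    single-SNP signature), P21H with 1/3 and V261A with 2/2, on a 200-peak
    base spectrum in the default window.
    """
    return ScenarioSpec(
        n_base_peaks=200,
        effects=(
            MutationEffect(Substitution.from_string("P21H"), n_disappear=3, n_appear=1),
            MutationEffect(Substitution.from_string("S147P"), n_disappear=5, n_appear=5),
            MutationEffect(Substitution.from_string("V261A"), n_disappear=2, n_appear=2),
        ),
    )


def reference_haplotypes() -> list[Haplotype]:
    """The five variant constructs examined by NMR: WT, P147, H21-P147, A261, triple."""
    p21h = Substitution.from_string("P21H")
    s147p = Substitution.from_string("S147P")
    v261a = Substitution.from_string("V261A")
    return [
        Haplotype(),
        Haplotype({s147p}),
        Haplotype({p21h, s147p}),
        Haplotype({v261a}),
        Haplotype({p21h, s147p, v261a}),
    ]


# ---------------------------------------------------------------------------
# peak-list generation


def _combined_dists(h: float, n: float, hs: np.ndarray, ns: np.ndarray) -> np.ndarray:
    return np.hypot(hs - h, _N_WEIGHT * (ns - n))


def _sample_separated(
    spec: ScenarioSpec,
    n: int,
    rng: np.random.Generator,
    existing_h: np.ndarray,
    existing_n: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``n`` in-window points keeping min_separation from
    each other and from ``existing`` points."""
    # shrink the window so later jitter cannot push peaks outside it
    margin_h = 6 * spec.jitter_sd_h
    margin_n = 6 * spec.jitter_sd_n
    (h0, h1) = spec.window.h_range
    (n0, n1) = spec.window.n_range
    h0, h1 = h0 + margin_h, h1 - margin_h
    n0, n1 = n0 + margin_n, n1 - margin_n
    n_existing = len(existing_h)
    cap = n_existing + n
    hs = np.empty(cap)
    ns = np.empty(cap)
    hs[:n_existing] = existing_h
    ns[:n_existing] = existing_n
    filled = n_existing
    max_tries = 200 * max(n, 1) + 1000
    tries = 0
    while filled < cap:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {n} peaks at separation {spec.min_separation} "
                f"after {max_tries} tries; window too crowded"
            )
        if spec.crowded_region is not None and rng.random() < _CROWD_FRACTION:
            c0, c1 = spec.crowded_region
            h = rng.uniform(max(c0, h0), min(c1, h1))
        else:
            h = rng.uniform(h0, h1)
        nshift = rng.uniform(n0, n1)
        if filled:
            d = _combined_dists(h, nshift, hs[:filled], ns[:filled])
            if d.min() < spec.min_separation:
                continue
        hs[filled] = h
        ns[filled] = nshift
        filled += 1
    return hs[n_existing:], ns[n_existing:]


def generate_base_peaklist(spec: ScenarioSpec, seed: int) -> PeakList:
    """The shared wild-type base spectrum: uniform in-window peaks with the
    scenario's minimum pairwise separation.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    hs, ns = _sample_separated(spec, spec.n_base_peaks, rng, np.empty(0), np.empty(0))
    width = len(str(max(spec.n_base_peaks, 1)))
    peaks = tuple(
        Peak(id=f"b{i + 1:0{width}d}", h_shift=float(h), n_shift=float(n))
        for i, (h, n) in enumerate(zip(hs, ns))
    )
    return PeakList(
        peaks=peaks,
        segment=spec.segments[0] if spec.segments else None,
        window=spec.window,
        source=f"synthetic base (seed={seed})",
    )


def _jitter_list(
    pl: PeakList, spec: ScenarioSpec, rng: np.random.Generator
) -> PeakList:
    # Gaussian jitter truncated at +/-2.8 sd: with sd <= 1/6 of the tolerance,
    # two independently jittered copies of a peak differ by < 0.94x the
    # per-axis tolerance, so matching recovers planted changes at every seed.
    def draw(sd: float) -> float:
        return float(np.clip(rng.normal(0.0, sd), -2.8 * sd, 2.8 * sd))

    jittered = tuple(
        replace(
            p,
            h_shift=p.h_shift + draw(spec.jitter_sd_h),
            n_shift=p.n_shift + draw(spec.jitter_sd_n),
        )
        for p in pl.peaks
    )
    return pl.with_peaks(jittered)


def generate_variant_family(
    spec: ScenarioSpec,
    haplotypes: Sequence[Haplotype],
    seed: int,
    *,
    jitter: bool = True,
) -> VariantFamily:
    """Generate one peak list per haplotype with planted per-substitution changes.

    Every substitution's disappear-set is drawn once from the base peaks and
    its appear-set placed once (respecting separation against everything),
    shared across all haplotypes carrying it; effects of distinct
    substitutions are disjoint.  Each haplotype's list then receives
    independent Gaussian jitter, modelling independently acquired spectra.
    """
    haplotypes = list(haplotypes)
    if Haplotype() not in haplotypes:
        raise ValueError("requested haplotypes must include wild type")
    needed = {s for hap in haplotypes for s in hap.subs}
    for s in sorted(needed):
        spec.effect_for(s)  # raises KeyError if missing

    ss = np.random.SeedSequence(seed)
    base_seed, effect_seed, jitter_seed = [int(c.generate_state(1)[0]) for c in ss.spawn(3)]
    base = generate_base_peaklist(spec, base_seed)

    # assign planted effects in a fixed substitution order, independent of the
    # haplotype list supplied
    eff_rng = np.random.default_rng(effect_seed)
    planted: dict[Substitution, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    free = list(range(len(base.peaks)))
    all_h = np.array([p.h_shift for p in base.peaks])
    all_n = np.array([p.n_shift for p in base.peaks])
    appear_peaks: dict[Substitution, tuple[Peak, ...]] = {}
    for eff in sorted(spec.effects, key=lambda e: e.sub):
        if eff.n_disappear > len(free):
            raise CapacityError("not enough base peaks left for disappear sets")
        idx = sorted(eff_rng.choice(len(free), size=eff.n_disappear, replace=False))
        chosen = [free[i] for i in idx]
        free = [f for f in free if f not in set(chosen)]
        dis_ids = tuple(base.peaks[i].id for i in chosen)
        hs, ns = _sample_separated(spec, eff.n_appear, eff_rng, all_h, all_n)
        all_h = np.concatenate([all_h, hs])
        all_n = np.concatenate([all_n, ns])
        apk = tuple(
            Peak(id=f"{eff.sub}_a{k + 1}", h_shift=float(h), n_shift=float(n))
            for k, (h, n) in enumerate(zip(hs, ns))
        )
        appear_peaks[eff.sub] = apk
        planted[eff.sub] = (dis_ids, tuple(p.id for p in apk))

    jit_root = np.random.SeedSequence(jitter_seed)
    lists: dict[Haplotype, PeakList] = {}
    # per-haplotype jitter seeds keyed on sorted labels: order-independent
    ordered = sorted(set(haplotypes), key=lambda h: h.label)
    jit_seeds = dict(zip(ordered, jit_root.spawn(len(ordered))))
    for hap in ordered:
        removed = {pid for s in hap.subs for pid in planted[s][0]}
        peaks = [p for p in base.peaks if p.id not in removed]
        for s in sorted(hap.subs):
            peaks.extend(appear_peaks[s])
        pl = PeakList(
            peaks=tuple(peaks),
            segment=base.segment,
            haplotype=hap,
            window=spec.window,
            source=f"synthetic {hap.label} (seed={seed})",
        )
        if jitter:
            pl = _jitter_list(pl, spec, np.random.default_rng(jit_seeds[hap]))
        lists[hap] = pl
    return VariantFamily(
        lists=lists,
        scenario=spec,
        seed=seed,
        planted=planted,
        base=base,
        appear_peaks=appear_peaks,
    )


def truncate_to_segment(
    family: VariantFamily,
    segment: tuple[int, int],
    keep_fraction: float,
    seed: int,
) -> VariantFamily:
    """Emulate a shorter construct whose spectrum is a subset of the long one.

    Keeps a shared random subset of the base peaks (round(keep_fraction ×
    n_base) of them) across all haplotypes, always retaining planted peaks of
    substitutions inside ``segment`` and dropping those of substitutions
    outside it, then applies fresh small jitter per list.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    if family.planted is None or family.base is None or family.appear_peaks is None:
        raise ValueError("truncate_to_segment needs a generated family with planting info")
    start, end = segment
    spec = family.scenario

    in_seg = {s: (start <= s.position <= end) for s in family.planted}
    mandatory = {
        pid for s, (dis, _) in family.planted.items() if in_seg[s] for pid in dis
    }
    dropped = {
        pid
        for s, (dis, app) in family.planted.items()
        if not in_seg[s]
        for pid in (*dis, *app)
    }
    base_ids = [p.id for p in family.base.peaks]
    n_keep = round(keep_fraction * len(base_ids))
    rng = np.random.default_rng(seed)
    optional = [i for i in base_ids if i not in mandatory and i not in dropped]
    n_extra = max(0, n_keep - len(mandatory))
    if n_extra > len(optional):
        warnings.warn("keep_fraction leaves fewer optional peaks than requested", stacklevel=2)
        n_extra = len(optional)
    extra = (
        {optional[i] for i in rng.choice(len(optional), size=n_extra, replace=False)}
        if n_extra
        else set()
    )
    kept_base = mandatory | extra
    kept_appear = {
        pid for s, (_, app) in family.planted.items() if in_seg[s] for pid in app
    }

    # rebuild each truncated list from the clean (unjittered) planted
    # coordinates before applying one fresh jitter, so every list stays within
    # a single jitter draw of the true peak positions
    jit_root = np.random.SeedSequence(seed)
    ordered = sorted(family.lists, key=lambda h: h.label)
    jit_seeds = dict(zip(ordered, jit_root.spawn(len(ordered))))
    new_lists: dict[Haplotype, PeakList] = {}
    for hap in ordered:
        pl = family.lists[hap]
        removed = {pid for s in hap.subs for pid in family.planted[s][0]}
        kept = [
            p for p in family.base.peaks
            if p.id in kept_base and p.id not in removed
        ]
        for s in sorted(hap.subs):
            kept.extend(p for p in family.appear_peaks[s] if p.id in kept_appear)
        short = replace(pl, peaks=tuple(kept), segment=segment,
                        source=pl.source + f" truncated to {start}-{end}")
        new_lists[hap] = _jitter_list(short, spec, np.random.default_rng(jit_seeds[hap]))

    new_planted = {
        s: (dis, app) if in_seg[s] else ((), ())
        for s, (dis, app) in family.planted.items()
    }
    base_kept = family.base.with_peaks(
        [p for p in family.base.peaks if p.id in kept_base]
    )
    return VariantFamily(
        lists=new_lists,
        scenario=spec,
        seed=seed,
        planted=new_planted,
        base=replace(base_kept, segment=segment),
        appear_peaks={
            s: (peaks if in_seg[s] else ())
            for s, peaks in family.appear_peaks.items()
        },
    )


# ---------------------------------------------------------------------------
# toy sequences


def generate_toy_sequence(
    length: int,
    planted: Iterable[tuple[MotifDef, int]] = (),
    extra_residues: Optional[Mapping[int, str]] = None,
) -> ProteinSequence:
    """A filler sequence (alternating Ala/Gly) carrying exactly the planted motifs.

    Each planted entry anchors a motif's phosphoacceptor at the given 1-based
    position; required arginines/prolines/serines are written at their
    offsets.  Conflicting constraints at a shared position raise ValueError.
    """
    constraints: dict[int, str] = {}

    def _set(pos: int, char: str, origin: str) -> None:
        if not (1 <= pos <= length):
            raise ValueError(f"{origin}: constrained position {pos} outside 1..{length}")
        if pos in constraints and constraints[pos] != char:
            raise ValueError(
                f"{origin}: conflicting constraint at {pos}: "
                f"{constraints[pos]!r} vs {char!r}"
            )
        constraints[pos] = char

    for motif, anchor in planted:
        for offset, allowed in motif.constraints:
            char = "S" if "S" in allowed else sorted(allowed)[0]
            _set(anchor + offset, char, f"{motif.name}@{anchor}")
    for pos, char in (extra_residues or {}).items():
        _set(pos, char, "extra residue")

    residues = [("A" if i % 2 == 0 else "G") for i in range(length)]
    for pos, char in constraints.items():
        residues[pos - 1] = char
    return ProteinSequence("".join(residues))


# ---------------------------------------------------------------------------
# toy structures


def generate_toy_structures(
    n_residues: int,
    perturbed_range: tuple[int, int],
    displacement_sd: float,
    seed: int,
) -> tuple[CoordinateSet, CoordinateSet]:
    """A smooth CA trace and a rigidly moved copy with local perturbation.

    The first set is an ideal-helix CA trace (2.3 Å radius, 100° twist,
    1.5 Å rise).  The second equals the first under a random rotation and
    translation, with isotropic Gaussian displacement of the given standard
    deviation added only to residues inside ``perturbed_range`` — a toy
    wild-type-vs-variant pair whose structural difference is confined to one
    loop.
    """
    start, end = perturbed_range
    if not (1 <= start <= end <= n_residues):
        raise ValueError(f"perturbed_range {perturbed_range} outside 1..{n_residues}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    theta = np.deg2rad(100.0) * t
    coords = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])

    moved = coords.copy()
    mask = (t + 1 >= start) & (t + 1 <= end)
    if displacement_sd > 0:
        moved[mask] += rng.normal(0.0, displacement_sd, size=(mask.sum(), 3))
    rot = _random_rotation(rng)
    trans = rng.normal(0.0, 10.0, size=3)
    moved = moved @ rot.T + trans

    def _as_set(xyz: np.ndarray, tag: str) -> CoordinateSet:
        return CoordinateSet(
            atoms=tuple(
                Atom(res_num=i + 1, atom_name="CA", x=float(p[0]), y=float(p[1]),
                     z=float(p[2]))
                for i, p in enumerate(xyz)
            ),
            source=f"toy trace {tag} (seed={seed})",
        )

    return _as_set(coords, "reference"), _as_set(moved, "perturbed")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
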