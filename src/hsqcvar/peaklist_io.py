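"""Reading and writing 2-D ¹H-¹⁵N peak lists.

Two text dialects are supported:

* ``sparky`` — whitespace-separated columns ``Assignment w1 w2 [intensity]``
  with ``w1`` the ¹⁵N shift and ``w2`` the ¹H shift in ppm, the common export
  convention for ¹⁵N-HSQC peak lists.  Lines starting with ``Assignment`` or
  ``#`` are treated as headers/comments.
* ``csv`` — header ``id,h_shift,n_shift,intensity,label``; the intensity and
  label columns may be empty.

Shifts are written with at least four decimal places so that a write/read
round trip is lossless at any matching tolerance used downstream.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from .variants import Haplotype

__all__ = [
    "Peak",
    "SpectralWindow",
    "PeakList",
    "PeakListParseError",
    "read_peaklist",
    "write_peaklist",
    "DIALECTS",
]

DIALECTS = ("sparky", "csv")


class PeakListParseError(ValueError):
    """A peak-list file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class Peak:
    """One ¹H-¹⁵N cross-peak.

    Parameters
    ----------
    id : str
        Opaque token, unique within a :class:`PeakList`.
    h_shift, n_shift : float
        ¹H and ¹⁵N chemical shifts in ppm.
    intensity : float, optional
        Arbitrary-unit peak height.
    label : str, optional
        Free-text assignment, e.g. ``"G12N-H"``.
    """

    id: str
    h_shift: float
    n_shift: float
    intensity: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_shift) and math.isfinite(self.n_shift)):
            raise ValueError(
                f"peak {self.id!r}: shifts must be finite, got "
                f"h={self.h_shift}, n={self.n_shift}"
            )


@dataclass(frozen=True)
class SpectralWindow:
    """Rectangular spectral window in ppm (sweep width and carrier position).

    Defaults match a typical ¹⁵N-HSQC acquisition: 14 ppm ¹H sweep centred on
    the water resonance at 4.7 ppm, 36 ppm ¹⁵N sweep centred on 118 ppm.
    """

    h_sweep: float = 14.0
    h_center: float = 4.7
    n_sweep: float = 36.0
    n_center: float = 118.0

    def __post_init__(self) -> None:
        if self.h_sweep <= 0 or self.n_sweep <= 0:
            raise ValueError("sweep widths must be positive")

    @property
    def h_range(self) -> tuple[float, float]:
        return (self.h_center - self.h_sweep / 2, self.h_center + self.h_sweep / 2)

    @property
    def n_range(self) -> tuple[float, float]:
        return (self.n_center - self.n_sweep / 2, self.n_center + self.n_sweep / 2)

    def contains(self, peak: Peak) -> bool:
        (h0, h1), (n0, n1) = self.h_range, self.n_range
        return h0 <= peak.h_shift <= h1 and n0 <= peak.n_shift <= n1


@dataclass(frozen=True)
class PeakList:
    """An ordered collection of peaks with acquisition metadata.

    ``segment`` is the 1-based inclusive residue range of the construct the
    spectrum was recorded on, e.g. ``(1, 494)``; ``haplotype`` labels the
    variant.  Peak ids must be unique.
    """

    peaks: tuple[Peak, ...]
    segment: Optional[tuple[int, int]] = None
    haplotype: Haplotype = field(default_factory=Haplotype)
    window: SpectralWindow = field(default_factory=SpectralWindow)
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peak ids: {dupes}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def by_id(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.id == peak_id:
                return p
        raise KeyError(peak_id)

    def ids(self) -> set[str]:
        return {p.id for p in self.peaks}

    def with_peaks(self, peaks: Sequence[Peak]) -> "PeakList":
        return replace(self, peaks=tuple(peaks))


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise PeakListParseError(
            f"{path}:{lineno}: non-numeric {what} {token!r}"
        ) from None


def _read_sparky(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("Assignment"):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise PeakListParseError(
                    f"{path}:{lineno}: expected 'Assignment w1 w2 [intensity]', "
                    f"got {line!r}"
                )
            label = tokens[0]
            n_shift = _parse_float(tokens[1], path, lineno, "w1 (¹⁵N) shift")
            h_shift = _parse_float(tokens[2], path, lineno, "w2 (¹H) shift")
            intensity = (
                _parse_float(tokens[3], path, lineno, "intensity")
                if len(tokens) > 3
                else None
            )
            peaks.append(
                Peak(id=label, h_shift=h_shift, n_shift=n_shift,
                     intensity=intensity, label=label)
            )
    return peaks


def _read_csv(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return peaks
        required = {"h_shift", "n_shift"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise PeakListParseError(
                f"{path}: missing required CSV columns {sorted(missing)}"
            )
        for row in reader:
            lineno = reader.line_num
            if all((v or "").strip() == "" for v in row.values()):
                continue
            peak_id = (row.get("id") or "").strip()
            label = (row.get("label") or "").strip() or None
            if not peak_id:
                peak_id = label if label else f"peak{len(peaks) + 1}"
            intensity_raw = (row.get("intensity") or "").strip()
            peaks.append(
                Peak(
                    id=peak_id,
                    h_shift=_parse_float(row["h_shift"], path, lineno, "h_shift"),
                    n_shift=_parse_float(row["n_shift"], path, lineno, "n_shift"),
                    intensity=(
                        _parse_float(intensity_raw, path, lineno, "intensity")
                        if intensity_raw
                        else None
                    ),
                    label=label,
                )
            )
    return peaks


def read_peaklist(
    path: Union[str, Path],
    dialect: str = "sparky",
    *,
    segment: Optional[tuple[int, int]] = None,
    haplotype: Optional[Haplotype] = None,
    window: Optional[SpectralWindow] = None,
) -> PeakList:
    """Read a peak list from ``path`` in the given dialect.

    One :class:`Peak` per data row; ids come from the label/id column when
    present, otherwise sequentially.  Blank lines and headers are skipped;
    any other unparseable line raises :class:`PeakListParseError` naming the
    line number.  Peaks outside the spectral window are kept with a warning.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(f"peak list not found: {path}")
    peaks = _read_sparky(path) if dialect == "sparky" else _read_csv(path)

    # sparky labels may repeat ("?"); disambiguate to keep ids unique
    seen: dict[str, int] = {}
    unique: list[Peak] = []
    for p in peaks:
        if p.id in seen:
            seen[p.id] += 1
            unique.append(replace(p, id=f"{p.id}.{seen[p.id]}"))
        else:
            seen[p.id] = 0
            unique.append(p)

    window = window if window is not None else SpectralWindow()
    outside = [p.id for p in unique if not window.contains(p)]
    if outside:
        warnings.warn(
            f"{path}: {len(outside)} peak(s) outside the spectral window "
            f"(e.g. {outside[:3]})",
            stacklevel=2,
        )
    return PeakList(
        peaks=tuple(unique),
        segment=segment,
        haplotype=haplotype if haplotype is not None else Haplotype(),
        window=window,
        source=str(path),
    )


def write_peaklist(pl: PeakList, path: Union[str, Path], dialect: str = "sparky") -> None:
    """Write ``pl`` to ``path``; the file is re-readable by :func:`read_peaklist`."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        if dialect == "sparky":
            with open(path, "w") as fh:
                fh.write(f"{'Assignment':>17s} {'w1':>10s} {'w2':>10s}\n\n")
                for p in pl.peaks:
                    label = p.label if p.label else p.id
                    line = f"{label:>17s} {p.n_shift:10.4f} {p.h_shift:10.4f}"
                    if p.intensity is not None:
                        line += f" {p.intensity:12.4e}"
                    fh.write(line + "\n")
        else:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["id", "h_shift", "n_shift", "intensity", "label"])
                for p in pl.peaks:
                    writer.writerow(
                        [
                            p.id,
                            f"{p.h_shift:.4f}",
                            f"{p.n_shift:.4f}",
                            "" if p.intensity is None else f"{p.intensity:.6g}",
                            p.label or "",
                        ]
                    )
    except OSError as exc:
        raise OSError(f"cannot write peak list to {path}: {exc}") from exc
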