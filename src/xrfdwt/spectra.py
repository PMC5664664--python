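"""Spectrum containers, energy–channel calibration and plain-text I/O.

An energy-dispersive XRF spectrum is a vector of counts indexed by
multichannel-analyzer channel.  Channel and photon energy are linearly
related through a gain (keV/channel) and an offset (keV at channel 0);
characteristic emission lines of the analyte elements are located through
this calibration and quantified over small keV bands around each line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class SpectrumParseError(ValueError):
    """A spectrum file row could not be parsed."""


class CalibrationError(ValueError):
    """Energy calibration could not be fitted or applied."""


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear channel→energy map: energy(ch) = offset + gain * ch.

    Parameters
    ----------
    gain
        keV per channel; must be positive.
    offset
        Energy in keV at channel 0.
    """

    gain: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gain > 0):
            raise CalibrationError(f"gain must be > 0, got {self.gain}")

    def energy(self, channel: float | np.ndarray) -> float | np.ndarray:
        return self.offset + self.gain * np.asarray(channel, dtype=float)

    def channel(self, energy: float | np.ndarray) -> float | np.ndarray:
        """Real-valued channel coordinate of an energy in keV."""
        return (np.asarray(energy, dtype=float) - self.offset) / self.gain

    def channel_index(self, energy: float) -> int:
        """Nearest integer channel of an energy in keV."""
        return int(round(float(self.channel(energy))))


def channel_of(cal: EnergyCalibration, energy: float) -> float:
    """Real-valued channel of ``energy`` under ``cal`` (module-level helper)."""
    return float(cal.channel(energy))


@dataclass(frozen=True)
class ElementLine:
    """A characteristic X-ray line with its quantification band.

    ``band_lo``/``band_hi`` bound the keV interval whose summed counts serve
    as the line's net intensity; the interval must bracket the line energy.
    """

    element: str
    line: str
    energy: float
    band_lo: float
    band_hi: float

    def __post_init__(self) -> None:
        if not (self.band_lo < self.energy < self.band_hi):
            raise ValueError(
                f"{self.element} {self.line}: band [{self.band_lo}, {self.band_hi}] "
                f"must bracket the line energy {self.energy}"
            )


# Characteristic lines and absorption bands of the five quantifiable soil
# heavy metals (energies in keV).  Cd, Ni and Hg are not quantifiable with
# this class of instrument and are deliberately absent.
_DEFAULT_LINES = (
    ElementLine("Cr", "Ka", 5.414, 5.399, 5.429),
    ElementLine("Cu", "Ka", 8.047, 8.032, 8.062),
    ElementLine("Zn", "Ka", 8.638, 8.623, 8.653),
    ElementLine("As", "Ka", 10.543, 10.528, 10.598),
    ElementLine("Pb", "Lb", 12.611, 12.595, 12.625),
)


@dataclass(frozen=True)
class LineTable:
    """Ordered collection of :class:`ElementLine`, unique by (element, line)."""

    lines: tuple[ElementLine, ...] = _DEFAULT_LINES

    def __post_init__(self) -> None:
        keys = [(ln.element, ln.line) for ln in self.lines]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (element, line) entries in line table")

    def __iter__(self) -> Iterator[ElementLine]:
        return iter(self.lines)

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(ln.element for ln in self.lines)

    def __getitem__(self, element: str) -> ElementLine:
        for ln in self.lines:
            if ln.element == element:
                return ln
        raise KeyError(f"element {element!r} not in line table {self.elements}")

    @classmethod
    def default(cls) -> "LineTable":
        return cls()

    @classmethod
    def from_csv(cls, path: str | Path) -> "LineTable":
        df = pd.read_csv(path)
        lines = tuple(
            ElementLine(str(r.element), str(r.line), float(r.energy_kev),
                        float(r.band_lo_kev), float(r.band_hi_kev))
            for r in df.itertuples()
        )
        return cls(lines)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(ln.element, ln.line, ln.energy, ln.band_lo, ln.band_hi) for ln in self.lines],
            columns=["element", "line", "energy_kev", "band_lo_kev", "band_hi_kev"],
        ).to_csv(path, index=False)


@dataclass
class Spectrum:
    """A channel-indexed count vector with optional calibration and metadata.

    Raw acquisitions carry non-negative integer counts; denoised or
    baseline-corrected spectra are real-valued.
    """

    counts: np.ndarray
    calibration: EnergyCalibration | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    @property
    def channels(self) -> np.ndarray:
        return np.arange(self.n_channels)

    def replace_counts(self, counts: np.ndarray) -> "Spectrum":
        """New Spectrum with the same calibration/meta and different counts."""
        return Spectrum(np.asarray(counts, dtype=float),
                        calibration=self.calibration, meta=dict(self.meta))


_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_ROW_RE = re.compile(rf"^\s*({_NUM})(?:[\s,]+({_NUM}))?\s*$")


def read_spectrum(path: str | Path, dialect: str = "auto") -> Spectrum:
    """Read a plain-text spectrum.

    Dialects: ``two_column`` (channel, counts rows, comma- or
    whitespace-delimited), ``counts_only`` (one count per row, channels
    assigned 0..N−1), or ``auto`` (inferred from the first data row).
    Lines starting with ``#`` are header comments; ``# key: value`` pairs
    are collected into ``meta``.  Negative counts are rejected: files hold
    raw acquisitions.
    """
    if dialect not in ("auto", "two_column", "counts_only"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float | None, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            m = _ROW_RE.match(line)
            if m is None:
                raise SpectrumParseError(
                    f"{path}: cannot parse line {lineno}: {line!r}")
            a, b = m.group(1), m.group(2)
            if dialect == "counts_only" and b is not None:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected a single count, got two columns")
            if dialect == "two_column" and b is None:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 'channel,counts', got one column")
            if b is None:
                rows.append((None, float(a)))
            else:
                rows.append((float(a), float(b)))
    if not rows:
        raise SpectrumParseError(f"{path}: no data rows")
    two_col = rows[0][0] is not None
    if any((r[0] is not None) != two_col for r in rows):
        raise SpectrumParseError(f"{path}: mixed one- and two-column rows")
    if two_col:
        order = np.argsort([r[0] for r in rows], kind="stable")
        counts = np.array([rows[i][1] for i in order])
    else:
        counts = np.array([r[1] for r in rows])
    if np.any(counts < 0):
        bad = int(np.flatnonzero(counts < 0)[0])
        raise ValueError(f"{path}: negative count at channel {bad}")
    return Spectrum(counts, meta=meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write ``channel,counts`` rows with ``# key: value`` meta header.

    Counts that are whole numbers are written as integers; otherwise with
    17 significant digits so that a read round-trip reproduces the values
    exactly.
    """
    path = Path(path)
    integral = bool(np.all(s.counts == np.round(s.counts)))
    with open(path, "w") as fh:
        for key, val in s.meta.items():
            fh.write(f"# {key}: {val}\n")
        for ch, c in enumerate(s.counts):
            if integral:
                fh.write(f"{ch},{int(round(c))}\n")
            else:
                fh.write(f"{ch},{c:.17g}\n")


def read_replicates(paths: Iterable[str | Path], dialect: str = "auto") -> list[Spectrum]:
    """Read several replicate spectra of the same sample."""
    return [read_spectrum(p, dialect=dialect) for p in paths]


def fit_energy_calibration(
    pairs: Iterable[tuple[float, float]] | Mapping[float, float],
) -> EnergyCalibration:
    """Least-squares fit of channel = a·energy + b over (energy keV, channel) pairs.

    Channels are the measured axis, so the regression runs channel-on-energy
    and the returned :class:`EnergyCalibration` inverts it: gain = 1/a,
    offset = −b/a.
    """
    if isinstance(pairs, Mapping):
        pairs = list(pairs.items())
    pairs = [(float(e), float(c)) for e, c in pairs]
    energies = np.array([p[0] for p in pairs])
    channels = np.array([p[1] for p in pairs])
    if len(np.unique(energies)) < 2:
        raise CalibrationError("need >= 2 pairs with distinct energies")
    a, b = np.polyfit(energies, channels, 1)
    if a <= 0:
        raise CalibrationError(f"non-increasing channel-energy relation (a={a})")
    return EnergyCalibration(gain=1.0 / a, offset=-b / a)


def band_channels(
    line: ElementLine,
    cal: EnergyCalibration,
    n_channels: int | None = None,
) -> tuple[int, int]:
    """Inclusive integer channel interval covering [band_lo, band_hi].

    Conservative coverage: floor of the lower edge, ceil of the upper edge.
    If ``n_channels`` is given, the interval must lie inside the spectrum.
    """
    lo = int(np.floor(cal.channel(line.band_lo)))
    hi = int(np.ceil(cal.channel(line.band_hi)))
    if lo > hi:  # cannot happen for a valid line/calibration, kept as a guard
        raise CalibrationError(f"degenerate band for {line.element}: ({lo}, {hi})")
    if n_channels is not None and (lo < 0 or hi >= n_channels):
        raise CalibrationError(
            f"{line.element} band channels ({lo}, {hi}) outside spectrum "
            f"of {n_channels} channels")
    return lo, hi


# (energy keV, multichannel-analyzer channel) pairs printed for the five
# default lines on the reference instrument; used to fit the default
# energy calibration.
REFERENCE_CHANNEL_PAIRS: tuple[tuple[float, float], ...] = (
    (5.414, 836.0),
    (8.047, 1243.0),
    (8.638, 1334.0),
    (10.543, 1628.0),
    (12.611, 1948.0),
)


def default_energy_calibration() -> EnergyCalibration:
    """Calibration fitted to :data:`REFERENCE_CHANNEL_PAIRS` (≈154.5 ch/keV)."""
    return fit_energy_calibration(REFERENCE_CHANNEL_PAIRS)
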