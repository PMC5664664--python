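"""Seeded generator of synthetic energy-dispersive XRF soil spectra.

The generator emulates the statistical structure the processing chain
assumes, not the physics of a particular instrument:

* a smooth continuum — exponential decay plus one broad Gaussian scatter
  hump — standing in for tube scatter background;
* one Gaussian photopeak per element line, centered at the channel of
  the line energy, with detector-like width FWHM(E) = a + b·√E and area
  linear in concentration (area = sensitivity · concentration ·
  live-time scale);
* independent Poisson counting noise per channel.

Everything is driven by a single master seed; per-spectrum child seeds
are derived with ``numpy.random.SeedSequence`` keyed by (level index,
replicate index), so whole calibration sets are bit-reproducible and any
single member can be re-drawn in isolation.

Deliberately absent (documented non-goals): escape/sum peaks, pile-up,
Compton/Rayleigh physics, matrix effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import EnergyCalibration, LineTable, Spectrum

SQRT_8LN2 = float(np.sqrt(8.0 * np.log(2.0)))  # FWHM = SQRT_8LN2 * sigma


def _default_sensitivities() -> dict[str, float]:
    # counts of peak area per mg/kg at unit live-time scale
    return {"Cr": 20.0, "Cu": 20.0, "Zn": 20.0, "As": 20.0, "Pb": 20.0}


#: Calibration concentration ranges (mg/kg) the generator targets per element.
CONCENTRATION_RANGES: dict[str, tuple[float, float]] = {
    "Cr": (32.0, 749.0),
    "Cu": (11.4, 577.0),
    "Zn": (31.0, 680.0),
    "As": (4.4, 806.0),
    "Pb": (13.4, 644.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a portable SDD instrument.

    The gain 0.006476 keV/channel places the Cr Kα line (5.414 keV) at
    channel 836 on a 4096-channel analyzer.  The continuum is smooth at
    the level-9 wavelet scale, as the baseline estimator requires of real
    tube-scatter backgrounds.
    """

    n_channels: int = 4096
    gain: float = 0.006476
    offset: float = 0.0
    lines: LineTable = field(default_factory=LineTable.default)
    sensitivities: dict = field(default_factory=_default_sensitivities)
    baseline_amplitude: float = 400.0    # counts at channel 0
    baseline_decay: float = 1500.0       # channels
    hump_amplitude: float = 150.0        # counts
    hump_center: float = 2900.0          # channels
    hump_width: float = 500.0            # channels (Gaussian sigma)
    resolution_a: float = 0.06           # keV
    resolution_b: float = 0.04           # keV per sqrt(keV)
    live_time_scale: float = 1.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        for name in ("baseline_amplitude", "hump_amplitude", "hump_width",
                     "live_time_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        e_max = self.offset + self.gain * self.n_channels
        if self.fwhm_kev(max(e_max, 0.001)) <= 0 or self.fwhm_kev(0.001) <= 0:
            raise ValueError("FWHM model must be positive over the energy range")

    @property
    def calibration(self) -> EnergyCalibration:
        return EnergyCalibration(gain=self.gain, offset=self.offset)

    def fwhm_kev(self, energy: float) -> float:
        return self.resolution_a + self.resolution_b * np.sqrt(max(energy, 0.0))


@dataclass
class SimTruth:
    """Noise-free ground truth behind a simulated spectrum."""

    clean_spectrum: np.ndarray
    baseline_component: np.ndarray
    peak_areas: dict[str, float]


def continuum(cfg: SimConfig) -> np.ndarray:
    """The noise-free continuum component on its own."""
    ch = np.arange(cfg.n_channels, dtype=float)
    base = cfg.baseline_amplitude * np.exp(-ch / cfg.baseline_decay)
    hump = cfg.hump_amplitude * np.exp(
        -0.5 * ((ch - cfg.hump_center) / cfg.hump_width) ** 2)
    return base + hump


def simulate_spectrum(concentrations: dict[str, float],
                      cfg: SimConfig = SimConfig(),
                      seed: int | np.random.Generator | None = 0,
                      ) -> tuple[Spectrum, SimTruth]:
    """One spectrum for the given element concentrations (mg/kg).

    Returns the Poisson-observed :class:`Spectrum` together with the
    :class:`SimTruth` (clean spectrum, continuum alone, injected peak
    areas).  ``seed`` may be an int or a ``numpy`` Generator.
    """
    for el, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {el}: {c}")
    ch = np.arange(cfg.n_channels, dtype=float)
    base = continuum(cfg)
    clean = base.copy()
    areas: dict[str, float] = {}
    cal = cfg.calibration
    for line in cfg.lines:
        c = float(concentrations.get(line.element, 0.0))
        area = cfg.sensitivities.get(line.element, 0.0) * c * cfg.live_time_scale
        areas[line.element] = area
        if area == 0.0:
            continue
        mu = float(cal.channel(line.energy))
        sigma = cfg.fwhm_kev(line.energy) / SQRT_8LN2 / cfg.gain  # in channels
        clean += area * np.exp(-0.5 * ((ch - mu) / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi))
    if cfg.poisson:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        observed = rng.poisson(clean).astype(float)
    else:
        observed = clean.copy()
    spec = Spectrum(observed, calibration=cal,
                    meta={"synthetic": "true",
                          **{f"conc_{el}": c for el, c in concentrations.items()}})
    return spec, SimTruth(clean_spectrum=clean, baseline_component=base,
                          peak_areas=areas)


_BLANK_KEY = 2**31 - 1  # spawn-key slot reserved for blank replicates


def _child_rng(master_seed: int, level_idx: int, rep_idx: int) -> np.random.Generator:
    # documented child-seed scheme: SeedSequence keyed by (seed, level, replicate)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(level_idx, rep_idx)))


def simulate_calibration_set(element: str, levels, replicates: int = 3,
                             cfg: SimConfig = SimConfig(), seed: int = 0,
                             ) -> list[tuple[float, list[Spectrum], SimTruth]]:
    """Replicate spectra at each concentration level of one element.

    One entry per level: (concentration, replicate spectra, shared clean
    truth).  Three replicates per level by default, matching standard
    acquisition practice.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out = []
    for i, level in enumerate(levels):
        conc = {element: float(level)}
        truth = None
        specs = []
        for r in range(replicates):
            sp, tr = simulate_spectrum(conc, cfg, seed=_child_rng(seed, i, r))
            specs.append(sp)
            truth = tr  # identical clean truth for every replicate
        out.append((float(level), specs, truth))
    return out


def default_levels(element: str, n_levels: int = 12) -> np.ndarray:
    """Equally spaced concentration levels across the element's range."""
    lo, hi = CONCENTRATION_RANGES[element]
    return np.linspace(lo, hi, n_levels)


def simulate_blanks(n: int = 11, cfg: SimConfig = SimConfig(), seed: int = 0,
                    ) -> list[Spectrum]:
    """``n`` analyte-free spectra (continuum + counting noise only)."""
    if n < 2:
        raise ValueError("need n >= 2 blank replicates")
    blanks = []
    for r in range(n):
        sp, _ = simulate_spectrum({}, cfg, seed=_child_rng(seed, _BLANK_KEY, r))
        blanks.append(sp)
    return blanks


def without_noise(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with Poisson noise disabled (clean-truth output)."""
    return replace(cfg, poisson=False)
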