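"""Orthogonal wavelet filter banks and the Mallat pyramid algorithm.

The discrete wavelet transform is computed by recursive filtering and
dyadic downsampling with a conjugate-mirror filter pair (h, g): at each
level the scaling coefficients are split into a coarser approximation
(low-pass h) and a detail block (high-pass g), and reconstruction runs
the adjoint pyramid.  The orthonormal convention is used throughout —
taps of unit Euclidean norm with Σh = √2 — so that, under periodic
boundary handling, the transform is an orthogonal map and energy is
conserved exactly.

Two boundary modes are supported:

``symmetric``
    Half-sample symmetric extension (default).  Minimizes edge artifacts
    on spectra whose ends are far from zero; block lengths follow
    ceil((N + L − 1)/2) per level.
``periodic``
    Circular extension; block lengths halve exactly (odd lengths are
    padded by repeating the last sample).  The transform is orthogonal.

The high-pass taps follow the quadrature-mirror convention
g_n = (−1)^n h_{L−1−n}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filter_taps import LOWPASS_DEC_TAPS

BOUNDARY_MODES = ("symmetric", "periodic")


class FilterLookupError(KeyError):
    """Unknown wavelet filter name."""


class LevelError(ValueError):
    """Requested decomposition level is invalid for the signal length."""


@dataclass(frozen=True)
class WaveletFilter:
    """A named orthogonal conjugate-mirror filter pair.

    ``h``/``g`` are the low/high-pass decomposition taps; ``h_rec``/``g_rec``
    the reconstruction taps (time-reversed decomposition taps, as for any
    orthogonal filter bank).
    """

    name: str
    h: np.ndarray
    g: np.ndarray
    h_rec: np.ndarray
    g_rec: np.ndarray

    @classmethod
    def from_lowpass(cls, name: str, h) -> "WaveletFilter":
        h = np.asarray(h, dtype=float)
        L = h.size
        n = np.arange(L)
        g = (-1.0) ** n * h[L - 1 - n]
        filt = cls(name=name, h=h, g=g, h_rec=h[::-1].copy(), g_rec=g[::-1].copy())
        filt.validate()
        return filt

    def __len__(self) -> int:
        return int(self.h.size)

    def validate(self, tol_sum: float = 1e-10, tol_qmf: float = 1e-12) -> None:
        """Check the filter-bank invariants; raises ``ValueError`` on failure.

        Invariants: Σh = √2, Σh² = 1, Σg = 0, the quadrature-mirror relation,
        and double-shift orthogonality Σ_n h_n h_{n+2k} = 0 for k ≠ 0.
        """
        h, g = self.h, self.g
        L = h.size
        if abs(h.sum() - np.sqrt(2.0)) > tol_sum:
            raise ValueError(f"{self.name}: sum(h) != sqrt(2)")
        if abs((h ** 2).sum() - 1.0) > tol_sum:
            raise ValueError(f"{self.name}: sum(h^2) != 1")
        if abs(g.sum()) > tol_sum:
            raise ValueError(f"{self.name}: sum(g) != 0")
        n = np.arange(L)
        if np.max(np.abs(g - (-1.0) ** n * h[L - 1 - n])) > tol_qmf:
            raise ValueError(f"{self.name}: QMF relation violated")
        for k in range(1, L // 2):
            if abs(np.dot(h[: L - 2 * k], h[2 * k:])) > tol_sum:
                raise ValueError(f"{self.name}: double-shift orthogonality fails at k={k}")


_FILTER_CACHE: dict[str, WaveletFilter] = {}


def available_filters() -> tuple[str, ...]:
    """Names of the supported filters (haar, db1–db10, sym2–sym8, coif1–coif5)."""
    return tuple(LOWPASS_DEC_TAPS)


def get_filter(name: str) -> WaveletFilter:
    """Look up a validated :class:`WaveletFilter` by name."""
    try:
        filt = _FILTER_CACHE[name]
    except KeyError:
        if name not in LOWPASS_DEC_TAPS:
            raise FilterLookupError(
                f"unknown wavelet filter {name!r}; supported: "
                + ", ".join(available_filters())) from None
        filt = WaveletFilter.from_lowpass(name, LOWPASS_DEC_TAPS[name])
        _FILTER_CACHE[name] = filt
    return filt


@dataclass
class Decomposition:
    """Multi-level DWT coefficients sufficient for exact reconstruction.

    ``details[0]`` is the finest (level-1) detail block, ``details[-1]`` the
    coarsest; ``approx`` holds the deepest-level scaling coefficients.
    ``level_lengths[j]`` records the scaling-block length entering level
    j+1 (``level_lengths[0]`` is the original signal length), which drives
    exact-length inversion under symmetric extension.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    level: int
    filter_name: str
    boundary: str
    level_lengths: list[int] = field(default_factory=list)

    @property
    def original_length(self) -> int:
        return self.level_lengths[0]

    def copy(self) -> "Decomposition":
        return Decomposition(
            approx=self.approx.copy(),
            details=[d.copy() for d in self.details],
            level=self.level,
            filter_name=self.filter_name,
            boundary=self.boundary,
            level_lengths=list(self.level_lengths),
        )


def _dwt_symmetric(x: np.ndarray, filt: WaveletFilter) -> tuple[np.ndarray, np.ndarray]:
    L = len(filt)
    ext = np.pad(x, L - 1, mode="symmetric") if L > 1 else x
    out_len = (x.size + L - 1) // 2
    ca = np.convolve(ext, filt.h)[L::2][:out_len]
    cd = np.convolve(ext, filt.g)[L::2][:out_len]
    return ca, cd


def _dwt_periodic(x: np.ndarray, filt: WaveletFilter) -> tuple[np.ndarray, np.ndarray]:
    if x.size % 2:
        x = np.append(x, x[-1])
    N = x.size
    L = len(filt)
    k = np.arange(N // 2)[:, None]
    n = np.arange(L)[None, :]
    idx = (2 * k + L // 2 - n) % N
    xi = x[idx]
    return xi @ filt.h, xi @ filt.g


def _idwt_symmetric(ca: np.ndarray, cd: np.ndarray, filt: WaveletFilter,
                    out_len: int) -> np.ndarray:
    L = len(filt)
    m = ca.size
    u = np.zeros(2 * m)
    u[::2] = ca
    v = np.zeros(2 * m)
    v[::2] = cd
    y = np.convolve(u, filt.h_rec) + np.convolve(v, filt.g_rec)
    start = max(L - 2, 0)
    full = y[start:start + 2 * m - L + 2] if L >= 2 else y
    return full[:out_len]


def _idwt_periodic(ca: np.ndarray, cd: np.ndarray, filt: WaveletFilter,
                   out_len: int) -> np.ndarray:
    # Adjoint of the forward circular operator (= inverse, by orthogonality).
    L = len(filt)
    M = 2 * ca.size
    k = np.arange(ca.size)[None, :]
    mgrid = np.arange(M)[:, None]
    t = (2 * k + L // 2 - mgrid) % M
    y = np.zeros(M)
    tt = t.astype(np.int64)
    while True:
        mask = tt < L
        if not mask.any():
            break
        hi = np.where(mask, filt.h[np.minimum(tt, L - 1)], 0.0)
        gi = np.where(mask, filt.g[np.minimum(tt, L - 1)], 0.0)
        y += hi @ ca + gi @ cd
        tt = tt + M
    return y[:out_len]


def _check_signal(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def max_level(n: int) -> int:
    """Deepest level permitted for a length-``n`` signal: floor(log2 n)."""
    return int(np.floor(np.log2(n)))


def decompose(signal, filt: WaveletFilter | str, level: int,
              boundary: str = "symmetric") -> Decomposition:
    """Mallat pyramid decomposition to depth ``level``.

    Each stage computes c_{j} = (h * c_{j+1})↓2 and d_{j} = (g * c_{j+1})↓2
    under the chosen boundary extension; the recursion is applied ``level``
    times to the approximation block.
    """
    if isinstance(filt, str):
        filt = get_filter(filt)
    x = _check_signal(signal)
    if level < 1:
        raise LevelError(f"level must be >= 1, got {level}")
    if level > max_level(x.size):
        raise LevelError(
            f"level {level} too deep for signal of length {x.size} "
            f"(max {max_level(x.size)})")
    if boundary not in BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")
    step = _dwt_symmetric if boundary == "symmetric" else _dwt_periodic
    lengths = [x.size]
    details: list[np.ndarray] = []
    c = x
    for _ in range(level):
        c, d = step(c, filt)
        details.append(d)
        lengths.append(c.size)
    return Decomposition(approx=c, details=details, level=level,
                         filter_name=filt.name, boundary=boundary,
                         level_lengths=lengths)


def reconstruct(dec: Decomposition) -> np.ndarray:
    """Inverse Mallat pyramid; exact to round-off for unmodified coefficients."""
    filt = get_filter(dec.filter_name)
    inv = _idwt_symmetric if dec.boundary == "symmetric" else _idwt_periodic
    c = dec.approx
    for j in range(dec.level - 1, -1, -1):
        d = dec.details[j]
        if d.size != c.size:
            raise ValueError(
                f"detail block at level {j + 1} has length {d.size}, "
                f"expected {c.size}")
        c = inv(c, d, filt, dec.level_lengths[j])
    return c


def approximation_at(signal, filt: WaveletFilter | str, level: int,
                     boundary: str = "symmetric") -> np.ndarray:
    """Smooth approximation a_J: reconstruct with every detail block zeroed.

    This is the scale-J low-pass component of the signal at the original
    sampling, the workhorse of the peak-peeling baseline estimator.
    """
    dec = decompose(signal, filt, level, boundary=boundary)
    for d in dec.details:
        d[:] = 0.0
    return reconstruct(dec)
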