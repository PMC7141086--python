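"""Discrete wavelet machinery: multiresolution decomposition, single-band
reconstruction, detrending and relative sub-band energies.

The multiresolution DWT splits a signal into an approximation A_J (the
coarse trend) and detail bands D_1..D_J, where D_1 is the *finest*
(highest-frequency) band.  At 25 Hz, band D_j spans roughly
25/2^(j+1) .. 25/2^j Hz, so a level-4 decomposition resolves the 1-2 s
time scale of evoked pupil dilations, while the approximation at a deep
level (default 9) captures the slow drift over minutes that must be
subtracted before any spectral reasoning about the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pywt

DEFAULT_WAVELET = "db4"
#: A_9 at 25 Hz covers frequencies below ~25/2^10 = 0.024 Hz (periods above
#: ~40 s) — the drift-over-minutes band.
DEFAULT_TREND_LEVEL = 9


@dataclass
class DwtDecomposition:
    """Coefficients of a level-J multiresolution decomposition.

    ``details[0]`` is D_1, the finest band; ``approx`` is A_J.
    """

    wavelet_name: str
    level: int
    approx: np.ndarray
    details: List[np.ndarray]  # D_1 .. D_J
    boundary_mode: str
    original_length: int

    def band(self, label: str) -> np.ndarray:
        """Coefficient vector for a band label 'A_J' / 'Aj' / 'D_j' / 'Dj'."""
        label = label.replace("_", "").upper()
        kind, j = label[0], int(label[1:])
        if kind == "A":
            if j != self.level:
                raise ValueError(f"only A_{self.level} is stored, not A_{j}")
            return self.approx
        if kind == "D" and 1 <= j <= self.level:
            return self.details[j - 1]
        raise ValueError(f"unknown band label {label!r}")


@dataclass
class BandEnergies:
    """Squared-coefficient energies per band and their normalized shares."""

    e_detail: np.ndarray  # E(D_1) .. E(D_J)
    e_approx: float
    rel_detail: np.ndarray
    rel_approx: float


def max_level(n_samples: int) -> int:
    """Deepest level for which the trace still holds >= 2^level samples."""
    return max(0, int(np.floor(np.log2(n_samples))))


def decompose(
    signal: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    level: int = 4,
    boundary_mode: str = "symmetric",
) -> DwtDecomposition:
    """Multiresolution DWT: successive low/high-pass filtering with dyadic
    downsampling, yielding A_level and D_1..D_level."""
    signal = np.asarray(signal, dtype=float)
    if level < 1:
        raise ValueError("level must be >= 1")
    if len(signal) < 2**level:
        raise ValueError(
            f"signal of {len(signal)} samples too short for level {level}; "
            f"max feasible level is {max_level(len(signal))}"
        )
    coeffs = pywt.wavedec(signal, wavelet_name, mode=boundary_mode, level=level)
    # pywt returns [A_J, D_J, ..., D_1]; store details finest-first
    details = list(reversed(coeffs[1:]))
    return DwtDecomposition(
        wavelet_name=wavelet_name,
        level=level,
        approx=coeffs[0],
        details=details,
        boundary_mode=boundary_mode,
        original_length=len(signal),
    )


def reconstruct_band(decomposition: DwtDecomposition, band: str) -> np.ndarray:
    """Partial reconstruction of the signal in one frequency sub-band.

    Inverts the transform with every other band's coefficients zeroed; the
    sum of all band reconstructions reproduces the original signal.
    """
    target = decomposition.band(band)  # validates the label
    coeffs = [np.zeros_like(decomposition.approx)] + [
        np.zeros_like(d) for d in reversed(decomposition.details)
    ]
    label = band.replace("_", "").upper()
    if label[0] == "A":
        coeffs[0] = decomposition.approx
    else:
        j = int(label[1:])
        coeffs[decomposition.level - j + 1] = target
    rec = pywt.waverec(coeffs, decomposition.wavelet_name, mode=decomposition.boundary_mode)
    return rec[: decomposition.original_length]


def reconstruct_all(decomposition: DwtDecomposition) -> np.ndarray:
    """Full inverse transform (perfect reconstruction check)."""
    coeffs = [decomposition.approx] + list(reversed(decomposition.details))
    rec = pywt.waverec(coeffs, decomposition.wavelet_name, mode=decomposition.boundary_mode)
    return rec[: decomposition.original_length]


def band_energies(decomposition: DwtDecomposition) -> BandEnergies:
    """Relative wavelet energy: each band's squared-coefficient sum divided
    by the total over all bands.  A zero-energy signal yields all zeros."""
    e_detail = np.array([float(np.sum(d**2)) for d in decomposition.details])
    e_approx = float(np.sum(decomposition.approx**2))
    total = e_detail.sum() + e_approx
    if total > 0:
        rel_detail = e_detail / total
        rel_approx = e_approx / total
    else:
        rel_detail = np.zeros_like(e_detail)
        rel_approx = 0.0
    return BandEnergies(
        e_detail=e_detail, e_approx=e_approx, rel_detail=rel_detail, rel_approx=rel_approx
    )


def detrend(
    y: np.ndarray,
    trend_level: int = DEFAULT_TREND_LEVEL,
    wavelet_name: str = DEFAULT_WAVELET,
    boundary_mode: str = "symmetric",
) -> Tuple[np.ndarray, np.ndarray]:
    """Remove the slow non-stationary trend from a signal.

    The trend is the reconstruction of the deep approximation band
    A_{trend_level}; the detrended signal is ``y - trend``.  Returns
    ``(detrended, trend)``.
    """
    y = np.asarray(y, dtype=float)
    dec = decompose(y, wavelet_name=wavelet_name, level=trend_level, boundary_mode=boundary_mode)
    trend = reconstruct_band(dec, f"A_{trend_level}")
    return y - trend, trend
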