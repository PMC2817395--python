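"""Reconstruction quality metrics.

Fourier shell correlation (FSC) with the FSC = 0.5 nominal-resolution
criterion, and the relative error RE = sum|rho_o - rho_r| / sum|rho_o| x
100% between a reference map and an amplitude-matched reconstruction,
optionally after a sharp spherical low-pass at a chosen cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import DensityVolume

__all__ = [
    "FSCCurve",
    "REProfile",
    "fsc",
    "resolution_at_threshold",
    "relative_error",
    "re_profile",
]


@dataclass
class FSCCurve:
    radii: np.ndarray  # shell radii, 1/Angstrom
    values: np.ndarray  # correlations in [-1, 1]

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class REProfile:
    cutoffs: np.ndarray  # 1/Angstrom
    values: np.ndarray  # percent

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def _shell_index(n: int) -> np.ndarray:
    """Integer shell index (radius in Fourier voxels) per 3D FFT voxel."""
    u = np.fft.fftfreq(n) * n
    uu, vv, ww = np.meshgrid(u, u, u, indexing="ij")
    return np.rint(np.sqrt(uu**2 + vv**2 + ww**2)).astype(int)


def fsc(vol_a: DensityVolume, vol_b: DensityVolume, n_shells: int | None = None) -> FSCCurve:
    """Per-shell normalized cross-correlation of two maps.

    Shells are integer-radius bins of width one Fourier voxel; shell k
    covers radius k/(N*voxel).
    """
    if vol_a.data.shape != vol_b.data.shape:
        raise ValueError("volumes must share the grid")
    if vol_a.voxel_size != vol_b.voxel_size:
        raise ValueError("volumes must share the voxel size")
    n = vol_a.n
    kmax = n_shells if n_shells is not None else n // 2
    fa = np.fft.fftn(vol_a.data)
    fb = np.fft.fftn(vol_b.data)
    k = _shell_index(n).ravel()
    cross = np.bincount(k, weights=(fa * np.conj(fb)).real.ravel())
    pa = np.bincount(k, weights=np.abs(fa.ravel()) ** 2)
    pb = np.bincount(k, weights=np.abs(fb.ravel()) ** 2)
    ks = np.arange(1, kmax + 1)
    denom = np.sqrt(pa[ks] * pb[ks])
    vals = np.divide(cross[ks], denom, out=np.zeros(len(ks)), where=denom > 0)
    return FSCCurve(radii=ks / (n * vol_a.voxel_size), values=vals)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5):
    """Nominal resolution (Angstrom) at the first downward threshold crossing.

    Linear interpolation between the bracketing shells; if the curve never
    drops below the threshold the Nyquist resolution is returned together
    with ``crossed=False``.
    """
    if len(curve.values) == 0:
        raise ValueError("empty FSC curve")
    v, r = curve.values, curve.radii
    for i in range(len(v)):
        if v[i] < threshold:
            if i == 0:
                return 1.0 / r[0], True
            t = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            r_cross = r[i - 1] + t * (r[i] - r[i - 1])
            return 1.0 / r_cross, True
    return 1.0 / r[-1], False


def _lowpass(data: np.ndarray, voxel: float, cutoff: float) -> np.ndarray:
    n = data.shape[0]
    freq = _shell_index(n) / (n * voxel)
    mask = freq <= cutoff
    return np.real(np.fft.ifftn(np.fft.fftn(data) * mask))


def relative_error(
    ref: DensityVolume, rec: DensityVolume, cutoff: float | None = None
) -> float:
    """RE (percent) between a reference and a normalized reconstruction.

    Both maps are low-passed with a sharp spherical mask at ``cutoff``
    (skipped when None); the reconstruction is then amplitude-matched to
    the reference by the least-squares scale sum(rho_o*rho_r)/sum(rho_r^2)
    before RE = sum|rho_o - rho_r| / sum|rho_o| x 100.
    """
    if ref.data.shape != rec.data.shape:
        raise ValueError("volumes must share the grid")
    if not np.any(ref.data):
        raise ValueError("all-zero reference volume")
    nyq = 1.0 / (2.0 * ref.voxel_size)
    if cutoff is not None and cutoff > nyq * (1 + 1e-9):
        raise ValueError("cutoff beyond Nyquist")
    a, b = ref.data, rec.data
    if cutoff is not None:
        a = _lowpass(a, ref.voxel_size, cutoff)
        b = _lowpass(b, rec.voxel_size, cutoff)
    denom = np.sum(b * b)
    scale = np.sum(a * b) / denom if denom > 0 else 0.0
    return float(np.sum(np.abs(a - scale * b)) / np.sum(np.abs(a)) * 100.0)


def re_profile(ref: DensityVolume, rec: DensityVolume, cutoffs) -> REProfile:
    """Relative error as a function of low-pass cutoff frequency."""
    cutoffs = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    vals = [relative_error(ref, rec, c) for c in cutoffs]
    return REProfile(cutoffs=cutoffs, values=np.array(vals))
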