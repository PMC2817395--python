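"""Synthetic octahedral phantoms and noisy projection stacks.

Stands in for PDB-derived test maps: volumes are sums of Gaussian blobs
replicated over the 24-element octahedral orbit, so they are exactly
symmetric by construction (and generically chiral, i.e. they carry odd-l
content).  Projections are real-space line integrals along the viewing
axis after rotating the volume by a ZXZ Euler triplet; optional center
offsets and additive Gaussian noise at a prescribed signal-to-noise ratio
complete the forward model.

Euler conventions
-----------------
The native convention is ZXZ with rotation matrix
``R = Rz(phi) @ Rx(theta) @ Rz(psi)`` mapping image-frame coordinates into
volume coordinates.  The ZYZ convention used by several other packages
relates to it exactly by ``(phi_zxz, theta, psi_zxz) =
(phi_zyz + pi/2, theta, psi_zyz - pi/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .basis import octahedral_rotations

__all__ = [
    "EulerTriplet",
    "DensityVolume",
    "ProjectionStack",
    "NoiseModel",
    "rotation_matrix",
    "convert_euler",
    "make_phantom",
    "random_orientations",
    "project",
    "add_noise",
    "measure_snr",
    "make_projection_stack",
]


@dataclass(frozen=True)
class EulerTriplet:
    phi: float
    theta: float
    psi: float
    convention: str = "zxz"

    def __post_init__(self):
        if self.convention not in ("zxz", "zyz"):
            raise ValueError(f"unknown Euler convention {self.convention!r}")
        if not (-1e-9 <= self.theta <= math.pi + 1e-9):
            raise ValueError("theta must lie in [0, pi]")


@dataclass
class DensityVolume:
    """Cubic voxel grid; the physical origin sits at grid index N//2."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("volume must be a cubic 3D grid")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("grid size must be even")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class ProjectionStack:
    images: np.ndarray  # (M, N, N)
    eulers: list[EulerTriplet]
    offsets: np.ndarray  # (M, 2) pixels (dx, dy)
    pixel_size: float
    snr: np.ndarray = None  # per-image S/N tag; inf = clean

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("stack must be (M, N, N)")
        self.offsets = np.asarray(self.offsets, dtype=float).reshape(-1, 2)
        if len(self.eulers) != len(self.images) or len(self.offsets) != len(
            self.images
        ):
            raise ValueError("images, eulers and offsets must have equal length")
        if np.any(np.abs(self.offsets) > self.images.shape[1] / 4):
            raise ValueError("center offsets must stay within N/4 pixels")
        if self.snr is None:
            self.snr = np.full(len(self.images), np.inf)
        self.snr = np.asarray(self.snr, dtype=float)

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class NoiseModel:
    s_over_n: float
    seed: int = 0

    def __post_init__(self):
        if not self.s_over_n > 0:
            raise ValueError("s_over_n must be positive")


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(e: EulerTriplet) -> np.ndarray:
    """3x3 rotation for a tagged Euler triplet (see module docstring)."""
    mid = _rx if e.convention == "zxz" else _ry
    return _rz(e.phi) @ mid(e.theta) @ _rz(e.psi)


def _wrap(a: float) -> float:
    return a % (2.0 * math.pi)


def convert_euler(e: EulerTriplet) -> EulerTriplet:
    """Map a ZYZ triplet to the equivalent ZXZ triplet (or back).

    (phi, theta, psi)_zyz -> (phi + pi/2, theta, psi - pi/2)_zxz; the two
    rotation matrices agree entrywise.
    """
    if e.convention == "zyz":
        return EulerTriplet(
            _wrap(e.phi + math.pi / 2), e.theta, _wrap(e.psi - math.pi / 2), "zxz"
        )
    return EulerTriplet(
        _wrap(e.phi - math.pi / 2), e.theta, _wrap(e.psi + math.pi / 2), "zyz"
    )


def make_phantom(
    n: int = 64,
    voxel: float = 2.0,
    n_blobs: int = 4,
    blob_sigma: float = 3.0,
    seed: int = 0,
    radius_frac: tuple[float, float] = (0.25, 0.35),
) -> DensityVolume:
    """Octahedrally symmetric phantom: Gaussian blobs on the 24-fold orbit.

    ``n_blobs`` generic blob positions are drawn at radii
    ``radius_frac * (n/2 * voxel)`` and replicated over the whole group, so
    the result is exactly symmetric by construction; blob amplitudes are
    random in [0.5, 1]; the map is non-negative with max normalized to 1.
    """
    if n < 32 or n % 2:
        raise ValueError("n must be even and >= 32")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    half = n / 2.0 * voxel
    lo, hi = radius_frac
    margin = 3.0 * blob_sigma
    if hi * half + margin > half:
        raise ValueError("blob centers (with 3-sigma margin) escape the grid")
    rots = octahedral_rotations()
    centers = []
    amps = []
    for _ in range(n_blobs):
        r = rng.uniform(lo, hi) * half
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        a = rng.uniform(0.5, 1.0)
        for g in rots:
            centers.append(r * (g @ v))
            amps.append(a)
    ax = (np.arange(n) - n // 2) * voxel
    vol = np.zeros((n, n, n))
    inv2s2 = 1.0 / (2.0 * blob_sigma**2)
    for c, a in zip(centers, amps):
        gx = np.exp(-((ax - c[0]) ** 2) * inv2s2)
        gy = np.exp(-((ax - c[1]) ** 2) * inv2s2)
        gz = np.exp(-((ax - c[2]) ** 2) * inv2s2)
        vol += a * np.einsum("i,j,k->ijk", gx, gy, gz)
    vol /= vol.max()
    return DensityVolume(vol, voxel)


def random_orientations(count: int, seed: int = 0) -> list[EulerTriplet]:
    """Uniform orientations: phi, psi ~ U[0, 2pi); cos(theta) ~ U[-1, 1]."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * math.pi, count)
    ct = rng.uniform(-1, 1, count)
    psi = rng.uniform(0, 2 * math.pi, count)
    return [
        EulerTriplet(p, math.acos(c), q, "zxz") for p, c, q in zip(phi, ct, psi)
    ]


def _fourier_shift_2d(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Exact periodic translation by (dx, dy) pixels via a Fourier phase ramp."""
    n = image.shape[0]
    f = np.fft.fft2(image)
    u = np.fft.fftfreq(n)
    ramp = np.exp(-2j * np.pi * (np.add.outer(u * dy, u * dx)))
    return np.real(np.fft.ifft2(f * ramp))


def project(
    vol: DensityVolume,
    e: EulerTriplet,
    offsets: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Real-space projection of the rotated volume along the viewing axis.

    The volume is resampled on the rotated grid (trilinear interpolation),
    summed along z, and translated by the center offsets (dx, dy) in pixels
    via an exact Fourier phase ramp.  Axis order of the output is (y, x).
    """
    if e.convention != "zxz":
        raise ValueError("project expects a ZXZ triplet; convert first")
    n = vol.n
    a = rotation_matrix(e)
    idx = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])
    src = a @ pts  # image-frame -> volume-frame coordinates
    coords = np.stack(
        [src[2] + n // 2, src[1] + n // 2, src[0] + n // 2]
    )  # (z, y, x) index order
    rot = ndimage.map_coordinates(vol.data, coords, order=1, mode="constant")
    img = rot.reshape(n, n, n).sum(axis=0)
    dx, dy = offsets
    if dx or dy:
        img = _fourier_shift_2d(img, dx, dy)
    return img


def measure_snr(signal: np.ndarray, noise: np.ndarray) -> float:
    """S/N = mean|signal - mean(signal)| / mean|noise|."""
    return float(
        np.mean(np.abs(signal - np.mean(signal))) / np.mean(np.abs(noise))
    )


def add_noise(image: np.ndarray, nm: NoiseModel) -> np.ndarray:
    """Add zero-mean Gaussian noise at the requested S/N.

    S/N is the ratio of the mean absolute signal fluctuation to the mean
    absolute noise; for Gaussian noise mean|n| = sigma*sqrt(2/pi), which
    fixes sigma.  Infinite S/N returns the input unchanged.
    """
    if np.ptp(image) == 0:
        raise ValueError("image has no signal variation")
    if np.isinf(nm.s_over_n):
        return image
    sig = np.mean(np.abs(image - np.mean(image)))
    sigma = sig / (nm.s_over_n * math.sqrt(2.0 / math.pi))
    rng = np.random.default_rng(nm.seed)
    return image + rng.normal(0.0, sigma, image.shape)


def make_projection_stack(
    vol: DensityVolume,
    count: int,
    s_over_n: float = np.inf,
    seed: int = 0,
    max_offset: float = 3.0,
) -> ProjectionStack:
    """Full forward model: random orientations/offsets, project, add noise."""
    eulers = random_orientations(count, seed=seed)
    rng = np.random.default_rng(seed + 1)
    offsets = rng.uniform(-max_offset, max_offset, size=(count, 2))
    images = np.empty((count, vol.n, vol.n))
    for i, (e, off) in enumerate(zip(eulers, offsets)):
        img = project(vol, e, tuple(off))
        if not np.isinf(s_over_n):
            img = add_noise(img, NoiseModel(s_over_n, seed=seed + 1000 + i))
        images[i] = img
    return ProjectionStack(
        images=images,
        eulers=eulers,
        offsets=offsets,
        pixel_size=vol.voxel_size,
        snr=np.full(count, s_over_n),
    )
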