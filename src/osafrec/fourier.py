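"""Central-section sampling and per-shell least-squares OSAF fitting.

By the central section theorem the 2D Fourier transform of a projection
equals the plane through the origin of the object's 3D transform
perpendicular to the viewing axis.  Each projection transform is therefore
resampled on rings of the FFT-native shell radii (bilinear interpolation
in the 2D plane), every ring point is mapped through the projection's
rotation to a 3D direction (Theta, Phi), and each reciprocal-space shell
collects its samples from all projections.  On a shell, the real part of F
is expanded over the even-l cosine OSAFs and the imaginary part over the
odd-l sine OSAFs; both expansions are solved by plain least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .basis import OSAFBasis, legendre_table, multiplicity
from .simulate import EulerTriplet, rotation_matrix

__all__ = [
    "FourierShellSamples",
    "ShellCoefficients",
    "transform_projection",
    "apply_center_shift",
    "sample_central_section",
    "symmetry_expand",
    "choose_lmax",
    "design_matrix",
    "fit_shell",
]


@dataclass
class FourierShellSamples:
    """Angular samples of the 3D transform on one reciprocal-space shell."""

    shell_radius: float  # 1/Angstrom
    theta: np.ndarray
    phi: np.ndarray
    values: np.ndarray  # complex F
    n_projections: int = 0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.phi = np.asarray(self.phi, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if not (len(self.theta) == len(self.phi) == len(self.values)):
            raise ValueError("theta, phi and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @staticmethod
    def concatenate(shells: list["FourierShellSamples"]) -> "FourierShellSamples":
        r = {s.shell_radius for s in shells}
        if len(r) != 1:
            raise ValueError("cannot merge samples from different shells")
        return FourierShellSamples(
            shell_radius=r.pop(),
            theta=np.concatenate([s.theta for s in shells]),
            phi=np.concatenate([s.phi for s in shells]),
            values=np.concatenate([s.values for s in shells]),
            n_projections=sum(s.n_projections for s in shells),
        )


@dataclass
class ShellCoefficients:
    """Fitted OSAF coefficients f_{l,mu}(R) on one shell, split by l parity."""

    shell_radius: float
    f_even: dict[tuple[int, int], float]
    f_odd: dict[tuple[int, int], float]
    lmax_eff: int
    residual: float = 0.0
    rank_deficient: bool = False

    def __post_init__(self):
        for (l, mu) in list(self.f_even) + list(self.f_odd):
            if mu < 1 or mu > multiplicity(l):
                raise ValueError(f"invalid (l, mu)=({l}, {mu})")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def transform_projection(image: np.ndarray, pad: int = 1) -> np.ndarray:
    """Centered 2D DFT of a square image with the object-centered phase
    convention: the zero-frequency term sits at index (P//2, P//2) and
    equals the image sum.  ``pad > 1`` zero-pads the image (centers
    aligned) for a finer reciprocal-space grid."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    n = image.shape[0]
    p = n * pad
    if pad > 1:
        big = np.zeros((p, p))
        lo = p // 2 - n // 2
        big[lo : lo + n, lo : lo + n] = image
        image = big
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def apply_center_shift(transform: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Undo a real-space translation by (dx, dy) pixels with a phase ramp
    exp(+2*pi*i*(u*dx + v*dy)/P) on the centered transform."""
    p = transform.shape[0]
    u = np.arange(p) - p // 2
    ramp = np.exp(2j * np.pi * (np.add.outer(u * dy, u * dx)) / p)
    return transform * ramp


def _default_rule(k: int) -> int:
    return max(4, 4 * k)


def sample_central_section(
    transform: np.ndarray,
    e: EulerTriplet,
    radii,
    voxel: float,
    pad: int = 1,
    n_per_shell=None,
) -> list[FourierShellSamples]:
    """Resample one projection transform on reciprocal shells.

    For shell radius R the transform is interpolated (bilinear, separately
    on real and imaginary parts) on the ring of pixel radius R*P*voxel;
    each in-plane unit vector is mapped through the projection rotation to
    its 3D direction on the central section.  The number of azimuths per
    shell follows ``n_per_shell(k)`` with k the FFT-native ring index
    (default 4k).
    """
    if e.convention != "zxz":
        raise ValueError("sample_central_section expects a ZXZ triplet")
    p = transform.shape[0]
    n = p // pad
    rule = n_per_shell or _default_rule
    a = rotation_matrix(e)
    out = []
    for r_shell in np.atleast_1d(radii):
        ring = r_shell * p * voxel  # pixel radius on the padded grid
        if ring > p // 2 - 1:
            raise ValueError(
                f"shell radius {r_shell} lies beyond the Nyquist disc"
            )
        k = int(round(r_shell * n * voxel))
        nsamp = int(rule(k))
        alpha = 2.0 * np.pi * np.arange(nsamp) / nsamp
        ca, sa = np.cos(alpha), np.sin(alpha)
        cols = p // 2 + ring * ca  # x -> column
        rows = p // 2 + ring * sa  # y -> row
        re = ndimage.map_coordinates(transform.real, [rows, cols], order=1)
        im = ndimage.map_coordinates(transform.imag, [rows, cols], order=1)
        d = a @ np.stack([ca, sa, np.zeros_like(ca)])
        theta = np.arccos(np.clip(d[2], -1.0, 1.0))
        phi = np.arctan2(d[1], d[0])
        out.append(
            FourierShellSamples(
                shell_radius=float(r_shell),
                theta=theta,
                phi=phi,
                values=re + 1j * im,
                n_projections=1,
            )
        )
    return out


def symmetry_expand(
    shell: FourierShellSamples, rotations: np.ndarray
) -> FourierShellSamples:
    """Replicate every sample direction over a set of rotations (F copied)."""
    st, ct = np.sin(shell.theta), np.cos(shell.theta)
    v = np.stack([st * np.cos(shell.phi), st * np.sin(shell.phi), ct], axis=1)
    w = np.einsum("gij,nj->gni", np.asarray(rotations), v).reshape(-1, 3)
    return FourierShellSamples(
        shell_radius=shell.shell_radius,
        theta=np.arccos(np.clip(w[:, 2], -1.0, 1.0)),
        phi=np.arctan2(w[:, 1], w[:, 0]),
        values=np.tile(shell.values, len(rotations)),
        n_projections=shell.n_projections,
    )


def _n_unknowns(lmax_eff: int) -> int:
    return sum(multiplicity(l) for l in range(lmax_eff + 1))


def choose_lmax(
    r_shell: float, r_max: float, n_samples: int, lmax_global: int
) -> int:
    """Effective angular band limit for one shell.

    The spherical-Bessel kernel j_l(2*pi*R*r) is negligible for
    l > 2*pi*R*r_max, so the band limit is min(lmax_global,
    ceil(2*pi*R*r_max) + 2), further reduced until the number of (l, mu)
    unknowns is at most half the sample count.
    """
    if r_shell <= 0 or r_max <= 0:
        raise ValueError("R and r_max must be positive")
    bound = int(np.ceil(2.0 * np.pi * r_shell * r_max)) + 2
    lm = max(
        (l for l in range(min(lmax_global, bound) + 1) if multiplicity(l) > 0 and l > 0),
        default=0,
    )
    while lm > 0 and _n_unknowns(lm) > n_samples / 2:
        lm -= 1
    return lm


def design_matrix(
    basis: OSAFBasis, lmax_eff: int, theta: np.ndarray, phi: np.ndarray
):
    """Evaluate the real OSAF forms at sample directions.

    Returns (keys_even, A_even, keys_odd, A_odd); columns follow the
    (l, mu) key lists.  All normalized Legendre factors are produced by a
    single recursion over the sample points.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    pbar = legendre_table(lmax_eff, np.cos(theta))  # (l, m, n)
    cols_e, keys_e, cols_o, keys_o = [], [], [], []
    for (l, mu) in basis.pairs(lmax=lmax_eff):
        f = basis[(l, mu)]
        col = np.zeros(len(theta))
        for m, b in f.coeffs.items():
            if l % 2 == 0:
                fac = 1.0 if m == 0 else 2.0
                col += fac * b * pbar[l, m] * np.cos(m * phi)
            else:
                col += 2.0 * b * pbar[l, m] * np.sin(m * phi)
        if l % 2 == 0:
            keys_e.append((l, mu))
            cols_e.append(col)
        else:
            keys_o.append((l, mu))
            cols_o.append(col)
    a_e = np.stack(cols_e, axis=1) if cols_e else np.zeros((len(theta), 0))
    a_o = np.stack(cols_o, axis=1) if cols_o else np.zeros((len(theta), 0))
    return keys_e, a_e, keys_o, a_o


def _solve(a: np.ndarray, b: np.ndarray, rcond: float = 1e-10):
    if a.shape[1] == 0:
        return np.zeros(0), 0.0, False
    x, _, rank, _ = np.linalg.lstsq(a, b, rcond=rcond)
    rss = float(np.sum((a @ x - b) ** 2))
    return x, rss, rank < a.shape[1]


def fit_shell(
    shell: FourierShellSamples, basis: OSAFBasis, lmax_eff: int
) -> ShellCoefficients:
    """Least-squares OSAF expansion of one shell.

    Solves two independent real problems: Re(F) against the even-l cosine
    OSAFs and Im(F) against the odd-l sine OSAFs.  Underdetermined shells
    fail explicitly; a rank-deficient design matrix yields the
    minimum-norm solution and sets ``rank_deficient``.
    """
    if lmax_eff > basis.lmax:
        raise ValueError("basis does not cover the requested band limit")
    n_unk = _n_unknowns(lmax_eff)
    if len(shell) < n_unk:
        raise ValueError(
            f"shell R={shell.shell_radius:.5g}: {len(shell)} samples cannot "
            f"constrain {n_unk} unknowns"
        )
    keys_e, a_e, keys_o, a_o = design_matrix(
        basis, lmax_eff, shell.theta, shell.phi
    )
    xe, rss_e, def_e = _solve(a_e, shell.values.real)
    xo, rss_o, def_o = _solve(a_o, shell.values.imag)
    ss = float(np.sum(shell.values.real**2) + np.sum(shell.values.imag**2))
    residual = float(np.sqrt((rss_e + rss_o) / ss)) if ss > 0 else 0.0
    return ShellCoefficients(
        shell_radius=shell.shell_radius,
        f_even=dict(zip(keys_e, xe)),
        f_odd=dict(zip(keys_o, xo)),
        lmax_eff=lmax_eff,
        residual=residual,
        rank_deficient=bool(def_e or def_o),
    )
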