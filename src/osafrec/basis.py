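"""Octahedral symmetry-adapted functions (OSAFs).

An OSAF of order ``l`` is a real linear combination of fully normalized
spherical harmonics :math:`Y_{l,m}` that is invariant under the 24 proper
rotations of the octahedral group *O*.  With the Cartesian axes along the
three 4-fold axes, only ``m ≡ 0 (mod 4)`` contributes, and the negative-m
half of the coefficient vector is fixed by ``B_{l,-m} = (-1)^{l-m} B_{l,m}``.
Even-l OSAFs are cosine series in the azimuth, odd-l OSAFs sine series.

The basis is generated recursively from three seed functions (l = 4, 6, 9)
by stretched Clebsch–Gordan coupling: combining invariant coefficient
vectors at orders ``l1`` and ``l2`` into one at ``l1 + l2`` using the
closed-form coupling coefficients for maximal total angular momentum,
followed by Gram–Schmidt orthonormalization inside each order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, sph_harm_y
from scipy.special import assoc_legendre_p_all as _legendre_all

__all__ = [
    "HarmonicCoefficients",
    "OSAFBasis",
    "multiplicity",
    "multiplicity_character_sum",
    "normalized_spherical_harmonic",
    "normalized_legendre",
    "seed_coefficients",
    "couple",
    "normalize_coefficients",
    "coefficient_inner",
    "build_basis",
    "evaluate_real",
    "evaluate_complex",
    "invariant_subspace_oracle",
    "octahedral_rotations",
]

# multiplicity of the O-invariant subspace for l = 0..11; beyond that the
# pattern repeats with period 12, gaining one function per period
_MU_TABLE = (1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 0)

_SIGN_TOL = 1e-12


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class HarmonicCoefficients:
    """Coefficient vector of one OSAF.

    ``coeffs`` maps m (0 <= m <= l, m ≡ 0 mod 4) to the real coefficient
    B_{l,m}; negative m is implied by the parity relation.  Odd-l functions
    carry no m = 0 entry (their sine form vanishes there).
    """

    l: int
    mu: int
    coeffs: Mapping[int, float]

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("order l must be >= 0")
        for m in self.coeffs:
            if m < 0 or m > self.l or m % 4 != 0:
                raise ValueError(f"invalid m={m} for l={self.l}")
        if self.l % 2 == 1 and 0 in self.coeffs:
            raise ValueError("odd-l OSAF has no m=0 coefficient")

    @property
    def parity(self) -> str:
        return "c" if self.l % 2 == 0 else "s"

    def norm_squared(self) -> float:
        return sum((1.0 if m == 0 else 2.0) * b * b for m, b in self.coeffs.items())

    def full_range(self) -> dict[int, float]:
        """Coefficients over -l..l via B_{l,-m} = (-1)^(l-m) B_{l,m}."""
        out = dict(self.coeffs)
        for m, b in self.coeffs.items():
            if m > 0:
                out[-m] = (-1.0) ** (self.l - m) * b
        return out


@dataclass(frozen=True)
class OSAFBasis:
    """All OSAFs with l <= lmax, ordered by (l, mu)."""

    lmax: int
    functions: tuple[HarmonicCoefficients, ...]

    def at_order(self, l: int) -> list[HarmonicCoefficients]:
        return [f for f in self.functions if f.l == l]

    def __getitem__(self, key: tuple[int, int]) -> HarmonicCoefficients:
        l, mu = key
        for f in self.functions:
            if f.l == l and f.mu == mu:
                return f
        raise KeyError(key)

    def pairs(self, lmax: int | None = None, parity: str | None = None):
        """(l, mu) keys present, optionally restricted by order/parity."""
        lm = self.lmax if lmax is None else lmax
        for f in self.functions:
            if f.l > lm:
                continue
            if parity == "even" and f.l % 2:
                continue
            if parity == "odd" and f.l % 2 == 0:
                continue
            yield (f.l, f.mu)


# --------------------------------------------------------------------------
# multiplicity


def multiplicity(l: int) -> int:
    """Number of independent OSAFs at order l."""
    if l < 0:
        raise ValueError("l must be >= 0")
    if l < 12:
        return _MU_TABLE[l]
    return _MU_TABLE[l % 12] + l // 12


def multiplicity_character_sum(l: int) -> int:
    """Independent oracle: average of SO(3) characters over the classes of O.

    chi_l(omega) = sin((2l+1) omega/2) / sin(omega/2); classes E, 8C3,
    6C2, 6C4, 3C2 with rotation angles 0, 2pi/3, pi, pi/2, pi.
    """
    if l < 0:
        raise ValueError("l must be >= 0")

    def chi(omega: float) -> float:
        if omega == 0.0:
            return 2 * l + 1
        return np.sin((2 * l + 1) * omega / 2.0) / np.sin(omega / 2.0)

    total = (
        chi(0.0)
        + 8 * chi(2 * np.pi / 3)
        + 6 * chi(np.pi)
        + 6 * chi(np.pi / 2)
        + 3 * chi(np.pi)
    )
    return int(round(total / 24.0))


# --------------------------------------------------------------------------
# spherical harmonics


def normalized_spherical_harmonic(l: int, m: int, theta, phi):
    """Fully normalized Y_{l,m}(theta, phi) with the Condon–Shortley phase."""
    if abs(m) > l:
        raise ValueError(f"|m|={abs(m)} exceeds l={l}")
    return sph_harm_y(l, m, theta, phi)


def normalized_legendre(l: int, m: int, costheta):
    """The normalized associated Legendre factor of Y_{l,m} (m >= 0).

    Y_{l,m}(theta, phi) = Pbar_l^m(cos theta) * exp(i m phi).
    """
    scalar = np.ndim(costheta) == 0
    out = legendre_table(l, np.atleast_1d(costheta))[l, m]
    return float(out[0]) if scalar else out


def legendre_table(lmax: int, costheta: np.ndarray) -> np.ndarray:
    """Pbar_l^m(costheta) for all 0<=m<=l<=lmax; shape (lmax+1, lmax+1, n)."""
    x = np.asarray(costheta, dtype=float)
    # norm=True gives sqrt(2pi)-scaled spherical-harmonic normalization,
    # except exactly at the poles where scipy falls back to unnormalized
    # P_l(+-1); those columns are overwritten with the closed form.
    table = _legendre_all(lmax, lmax, x, norm=True)[0][: lmax + 1, : lmax + 1]
    table = table / np.sqrt(2.0 * np.pi)
    pole = np.abs(x) == 1.0
    if np.any(pole):
        ls = np.arange(lmax + 1)
        vals = np.sqrt((2 * ls + 1) / (4.0 * np.pi))
        table[:, :, pole] = 0.0
        table[:, 0, pole] = vals[:, None] * x[pole] ** ls[:, None]
    return table


# --------------------------------------------------------------------------
# seeds and coupling


def seed_coefficients(l: int) -> HarmonicCoefficients:
    """The three seed OSAFs from which all higher orders are generated."""
    if l == 4:
        c = {0: np.sqrt(21.0) / 6.0, 4: np.sqrt(15.0 / 2.0) / 6.0}
    elif l == 6:
        c = {0: np.sqrt(2.0) / 4.0, 4: -np.sqrt(7.0) / 4.0}
    elif l == 9:
        c = {4: np.sqrt(51.0) / 12.0, 8: -np.sqrt(21.0) / 12.0}
    else:
        raise ValueError("seed OSAFs exist only for l in {4, 6, 9}")
    return HarmonicCoefficients(l=l, mu=1, coeffs=c)


def couple(b1: HarmonicCoefficients, b2: HarmonicCoefficients) -> dict[int, float]:
    """Stretched Clebsch–Gordan coupling of two OSAF coefficient vectors.

    Returns the *unnormalized* coefficient map at order l1 + l2 (m >= 0,
    multiples of 4).  The overall normalization constant is applied
    separately by :func:`normalize_coefficients`.  Factorial ratios are
    evaluated through log-gamma so the recursion stays stable to very high
    order.
    """
    l1, l2 = b1.l, b2.l
    L = l1 + l2
    f1 = b1.full_range()
    f2 = b2.full_range()
    lg_pref = gammaln(2 * l1 + 1) + gammaln(2 * l2 + 1) - gammaln(2 * L + 1)
    out: dict[int, float] = {}
    for M in range(0, L + 1, 4):
        acc = 0.0
        lg_m = gammaln(L + M + 1) + gammaln(L - M + 1)
        for m, a in f1.items():
            mm = M - m
            if abs(mm) > l2:
                continue
            b = f2.get(mm, 0.0)
            if a == 0.0 or b == 0.0:
                continue
            lg = lg_pref + lg_m - (
                gammaln(l1 + m + 1)
                + gammaln(l1 - m + 1)
                + gammaln(l2 + mm + 1)
                + gammaln(l2 - mm + 1)
            )
            acc += np.exp(0.5 * lg) * a * b
        out[M] = acc
    if L % 2 == 1:
        out.pop(0, None)
    return out


def coefficient_inner(c1: Mapping[int, float], c2: Mapping[int, float]) -> float:
    """Inner product B0*B0' + 2*sum_{m>0} Bm*Bm' (the full-range dot product)."""
    ms = set(c1) | set(c2)
    return sum(
        (1.0 if m == 0 else 2.0) * c1.get(m, 0.0) * c2.get(m, 0.0) for m in ms
    )


def normalize_coefficients(
    coeffs: Mapping[int, float], l: int, mu: int = 1
) -> HarmonicCoefficients:
    """Scale to unit coefficient norm; make the lowest-m nonzero entry positive."""
    n = np.sqrt(coefficient_inner(coeffs, coeffs))
    if n < _SIGN_TOL:
        raise ValueError(f"cannot normalize near-zero coefficient vector at l={l}")
    sign = 1.0
    for m in sorted(coeffs):
        if abs(coeffs[m]) > _SIGN_TOL * n:
            sign = 1.0 if coeffs[m] > 0 else -1.0
            break
    scaled = {m: sign * b / n for m, b in coeffs.items()}
    return HarmonicCoefficients(l=l, mu=mu, coeffs=scaled)


def _gram_schmidt(
    cand: Mapping[int, float], accepted: Iterable[HarmonicCoefficients]
) -> dict[int, float]:
    out = dict(cand)
    for f in accepted:
        p = coefficient_inner(out, f.coeffs)
        for m, b in f.coeffs.items():
            out[m] = out.get(m, 0.0) - p * b
    return out


def build_basis(lmax: int, rank_tol: float = 1e-8) -> OSAFBasis:
    """Generate every OSAF with l <= lmax by seed coupling.

    l = 0 is the constant function; the seeds l = 4, 6, 9 enter directly.
    Each higher order with nonzero multiplicity is produced by coupling all
    source pairs (l1 <= l2, l1 + l2 = l) in ascending l1 and accepting
    Gram–Schmidt survivors until the multiplicity is reached.  l = 12 uses
    the fixed convention: mu=2 is the normalized 6x6 product (its m = 12
    coefficient vanishes identically) and mu=1 the 4x8 product
    orthogonalized against it.  Fails loudly if the achievable rank at any
    order falls short of the multiplicity.
    """
    if lmax < 0:
        raise ValueError("lmax must be >= 0")
    by_l: dict[int, list[HarmonicCoefficients]] = {}
    if lmax >= 0:
        by_l[0] = [HarmonicCoefficients(l=0, mu=1, coeffs={0: 1.0})]
    for l in range(4, lmax + 1):
        nmu = multiplicity(l)
        if nmu == 0:
            continue
        if l in (4, 6, 9):
            by_l[l] = [seed_coefficients(l)]
            continue
        accepted: list[HarmonicCoefficients] = []
        if l == 12:
            seed6 = seed_coefficients(6)
            mu2 = normalize_coefficients(couple(seed6, seed6), l=12, mu=2)
            raw = couple(seed_coefficients(4), by_l[8][0])
            res = _gram_schmidt(raw, [mu2])
            mu1 = normalize_coefficients(res, l=12, mu=1)
            by_l[12] = [mu1, mu2]
            continue
        pairs = [
            (l1, l - l1)
            for l1 in range(4, l // 2 + 1)
            if l1 in by_l and (l - l1) in by_l
        ]
        for l1, l2 in pairs:
            for f1 in by_l[l1]:
                for f2 in by_l[l2]:
                    raw = couple(f1, f2)
                    scale = np.sqrt(max(coefficient_inner(raw, raw), _SIGN_TOL))
                    res = _gram_schmidt(raw, accepted)
                    if np.sqrt(coefficient_inner(res, res)) > rank_tol * scale:
                        accepted.append(
                            normalize_coefficients(res, l=l, mu=len(accepted) + 1)
                        )
                    if len(accepted) == nmu:
                        break
                if len(accepted) == nmu:
                    break
            if len(accepted) == nmu:
                break
        if len(accepted) < nmu:
            raise RuntimeError(
                f"coupling recursion reached rank {len(accepted)} < "
                f"multiplicity {nmu} at l={l}"
            )
        by_l[l] = accepted
    funcs: list[HarmonicCoefficients] = []
    for l in sorted(by_l):
        funcs.extend(by_l[l])
    return OSAFBasis(lmax=lmax, functions=tuple(funcs))


# --------------------------------------------------------------------------
# evaluation


def evaluate_real(f: HarmonicCoefficients, theta, phi):
    """Real form of an OSAF: cosine series for even l, sine series for odd l."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    x = np.cos(theta)
    out = np.zeros(np.broadcast(theta, phi).shape)
    for m, b in f.coeffs.items():
        p = normalized_legendre(f.l, m, x)
        if f.l % 2 == 0:
            fac = 1.0 if m == 0 else 2.0
            out = out + fac * b * p * np.cos(m * phi)
        else:
            out = out + 2.0 * b * p * np.sin(m * phi)
    return out


def evaluate_complex(f: HarmonicCoefficients, theta, phi):
    """Complex OSAF sum_m B_m Y_{l,m} over the full m range.

    Equals the real form for even l and i times it for odd l.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(np.broadcast(theta, phi).shape, dtype=complex)
    for m, b in f.full_range().items():
        out = out + b * sph_harm_y(f.l, m, theta, phi)
    return out


def _real_block(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Basis element multiplying B_m in evaluate_real."""
    p = normalized_legendre(l, m, np.cos(theta))
    if l % 2 == 0:
        return (1.0 if m == 0 else 2.0) * p * np.cos(m * phi)
    return 2.0 * p * np.sin(m * phi)


def _allowed_m(l: int) -> list[int]:
    start = 0 if l % 2 == 0 else 4
    return list(range(start, l + 1, 4))


def invariant_subspace_oracle(
    l: int, n_points: int = 400, seed: int = 7, tol: float = 1e-9
) -> list[HarmonicCoefficients]:
    """Independent construction of the O-invariant degree-l subspace.

    Solves numerically for all coefficient vectors over m ≡ 0 (mod 4) whose
    real form is invariant under the C3 rotation about (1,1,1); the C4
    about Z is already enforced by the m restriction, and the two rotations
    generate the whole group.  Returns an orthonormal basis (in the
    coefficient inner product); its dimension equals multiplicity(l).
    """
    if l < 0:
        raise ValueError("l must be >= 0")
    ms = _allowed_m(l)
    if not ms:
        return []
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_points, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    c3 = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    w = v @ c3.T
    th_v, ph_v = np.arccos(np.clip(v[:, 2], -1, 1)), np.arctan2(v[:, 1], v[:, 0])
    th_w, ph_w = np.arccos(np.clip(w[:, 2], -1, 1)), np.arctan2(w[:, 1], w[:, 0])
    # scale columns so the Euclidean norm matches the coefficient norm
    wts = np.array([1.0 if m == 0 else np.sqrt(2.0) for m in ms])
    a = np.stack(
        [
            (_real_block(l, m, th_v, ph_v) - _real_block(l, m, th_w, ph_w)) / wt
            for m, wt in zip(ms, wts)
        ],
        axis=1,
    )
    _, s, vt = np.linalg.svd(a, full_matrices=True)
    smax = s[0] if s.size else 0.0
    null = [
        vt[i] / wts
        for i in range(len(ms))
        if i >= len(s) or s[i] < tol * max(smax, 1.0)
    ]
    out: list[HarmonicCoefficients] = []
    for vec in null:
        cand = dict(zip(ms, vec))
        res = _gram_schmidt(cand, out)
        if coefficient_inner(res, res) > 1e-16:
            out.append(normalize_coefficients(res, l=l, mu=len(out) + 1))
    return out


# --------------------------------------------------------------------------
# the rotation group


def octahedral_rotations() -> np.ndarray:
    """The 24 proper rotations of O as a (24, 3, 3) array.

    Generated by closure from the 4-fold rotation about Z and the 3-fold
    rotation about (1,1,1); all elements are signed permutation matrices.
    """
    c4z = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=int)
    c3 = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=int)
    elems = {tuple(np.eye(3, dtype=int).ravel())}
    frontier = [np.eye(3, dtype=int)]
    while frontier:
        nxt = []
        for g in frontier:
            for h in (c4z, c3):
                p = g @ h
                key = tuple(p.ravel())
                if key not in elems:
                    elems.add(key)
                    nxt.append(p)
        frontier = nxt
    mats = np.array([np.array(k).reshape(3, 3) for k in sorted(elems)], dtype=float)
    assert mats.shape[0] == 24
    return mats
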