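# Methods

## The basis

An octahedral symmetry-adapted function (OSAF) of order `l` is the real
combination `O_{l,mu} = sum_m B_{l,m}^mu Y_{l,m}` over `m ≡ 0 (mod 4)`,
invariant under the 24 proper rotations of *O* with the Cartesian axes on
the three 4-fold axes. Fully normalized spherical harmonics with the
Condon–Shortley phase are used throughout (`Y*_{l,m} = (-1)^m Y_{l,-m}`
and `B_{l,-m} = (-1)^{l-m} B_{l,m}` then both hold). Even-`l` OSAFs
reduce to cosine series in the azimuth, odd-`l` ones to sine series; with
the convention used here (`(2 - delta_{m0}) B_m Pbar_l^m cos(m phi)` /
`2 B_m Pbar_l^m sin(m phi)` and coefficient norm
`B_0^2 + 2 sum_{m>0} B_m^2 = 1`) the real forms are orthonormal on the
sphere, which keeps the shell fits well conditioned.

The multiplicity is `mu(l) = mu(l mod 12) + floor(l/12)` with the period-12
table 1,0,0,0,1,0,1,0,1,1,1,0; it equals the character-sum average
`(1/24) sum_c n_c chi_l(omega_c)` over the classes E, 8C3, 6C2, 6C4, 3C2,
which the tests verify exactly for `l <= 200`.

Higher orders are generated from the seeds `l = 4, 6, 9` by stretched
Clebsch–Gordan coupling: the product of invariants at `l1` and `l2`
projected on total order `L = l1 + l2`. The coupling coefficient is the
standard closed form with `(2L)!` in the denominator; since the result is
explicitly renormalized (the overall gamma constant is never needed),
any constant rescaling of the kernel is immaterial. Factorial ratios go
through log-gamma, so the recursion remains stable to order ~1000.
Within each order, candidate products (ascending `l1 <= l2`) pass through
Gram–Schmidt until the multiplicity is reached; construction fails loudly
if the achievable rank falls short. Signs are fixed by making the
lowest-`m` nonzero coefficient positive. At `l = 12` a fixed convention
reproduces the published ordering: `mu = 2` is the normalized 6x6 product
(whose `m = 12` coefficient vanishes identically because no in-range
`(m, M-m)` pair exists) and `mu = 1` the 4x8 product orthogonalized
against it. For `l > 12` the `mu` labeling is basis-convention dependent;
only the spanned subspace is contractual, and an independent oracle —
the numerical null space of the C3-invariance constraint about (1,1,1)
on coefficient vectors over `m ≡ 0 (mod 4)` (C4 about Z is already
implied by the `m` restriction, and the two rotations generate the whole
group) — confirms both the dimension and the span.

Numerical notes: all coefficient algebra is double precision; the
published decimal table of low-order coefficients carries ~1e-7 rounding
in its higher rows (exact rational arithmetic gives e.g.
`B_{8,4} = sqrt(42)/24 = 0.270030862433661`), so the unit tests pin the
construction against exact closed-form values rather than the rounded
decimals. One printed `l = 12` cell (`mu = 1`, `m = 8`) is internally
inconsistent (it violates both unit norm and orthogonality; the
construction gives 0.0410768724615, an apparent misplaced decimal point)
and is never used as a target. scipy's normalized associated-Legendre
recursion (`assoc_legendre_p_all(..., norm=True)`) silently returns
unnormalized values exactly at the poles `|cos theta| = 1`; the basis
module overwrites those columns with the closed form
`sqrt((2l+1)/4pi) (cos theta)^l delta_{m0}`.

## The simulator

Phantoms replace atomic-model maps: `n_blobs` Gaussian blobs are placed
at generic positions and replicated over the full 24-element orbit, so
the volume is exactly symmetric by construction, non-negative, and max 1.
Defaults (64^3 grid, 2 Å voxels, 4 blobs of sigma 3 Å at radii 0.25–0.35
of the half-box) were chosen so the object (a) is chiral — proper
rotations only, hence genuine odd-`l` structure-factor content that
exercises the sine-OSAF path; (b) has angular bandwidth
`2 pi R c ≲ 25` at two thirds of Nyquist (blob centers `c ≤ 11` voxels),
so an `lmax = 25` expansion can represent its shells; (c) retains
measurable spectral power there (`sigma = 1.5` voxels). What the phantom
does **not** emulate: atomic-scale texture, CTF, solvent background,
non-Gaussian noise, or orientation/center errors — so passing tests show
correctness of the reconstruction operator under the stated forward
model, not robustness to the estimation errors of a real single-particle
workflow.

Orientations are uniform (`phi, psi ~ U[0, 2pi)`, `cos theta ~ U[-1,1]`)
in the native ZXZ convention with rotation matrix
`R = Rz(phi) Rx(theta) Rz(psi)` mapping image-frame to volume-frame
coordinates; the ZYZ convention maps to it exactly via
`(phi + pi/2, theta, psi - pi/2)`, and a matrix oracle pins the
handedness. Projection rotates the volume (trilinear resampling) and
sums along z; center offsets are applied as exact Fourier phase ramps so
the reconstruction-side correction inverts them exactly (fractional
shifts of a real image lose the complex Nyquist bin — irrelevant here
since sampling stays inside the Nyquist disc). Noise is zero-mean
Gaussian with `S/N = mean|I - mean I| / mean|n|` and
`mean|n| = sigma sqrt(2/pi)`; absolute averages are the only reading of a
signal-to-noise *ratio of averages* that stays finite for zero-mean
noise, and mean-subtracting the signal makes S/N independent of any
background offset.

## Fitting and inversion

Each projection transform (2x zero-padded, which quarters the bilinear
ring-interpolation error) is sampled on rings at the FFT-native shell
radii `R_k = k/(N voxel)`, `k = 1..N/2-1` (the exact Nyquist ring touches
the edge of the padded grid and is dropped), with `4k` azimuths per ring.
The per-shell band limit is `min(lmax, ceil(2 pi R r_max) + 2)` — the
argument above which `j_l` is negligible — further reduced until the
unknown count stays below half the sample count; near the origin only
`l = 0` survives. The two real least-squares systems are solved with an
SVD-based solver (rcond 1e-10; rank-deficient shells get the
minimum-norm solution plus a flag); all samples have unit weight. The
`k = 0` term enters as the mean projection DC.

Symmetry handling: because every OSAF is *exactly* invariant under the 24
rotations, replicating each sample direction over the group duplicates
design-matrix rows verbatim (same basis values, same F target), so the
least-squares solution is provably unchanged. `reconstruct` therefore
uses this implicit form by default; the literal `symmetry_expand`
operation exists, and a test asserts expanded and implicit
reconstructions agree to 1e-10. The advertised 24-fold noise averaging
is already inherent in fitting an O-invariant basis to all samples.

The radial integral `g_{l,mu}(r) = int f j_l(2 pi R r) R^2 dR` uses the
trapezoid rule on a radial grid refined 8x between shells (f linearly
interpolated, `j_l` evaluated exactly via scipy): at the box edge the
Bessel kernel advances ~pi radians per shell spacing, so quadrature on
the raw shell grid alone would be at its sampling limit; the refinement
makes the rule accurate relative to the fit error while adding no
information. Synthesis reduces the `i^l` phases (numpy forward-DFT
convention, i.e. inversion with `e^{+2 pi i K.r}`) to the real sign
sequences `(-1)^{l/2}` (even) and `(-1)^{(l+1)/2}` (odd); a direct
complex-arithmetic oracle verifies both the sign table and that the
imaginary part vanishes to machine precision. Angular factors come from
one Legendre recursion over all voxels, radial profiles from a 4N-point
fine grid with linear interpolation per voxel; voxels beyond the
half-box radius are zero.

## Metrics

FSC uses integer-radius shells of one Fourier voxel. The nominal
resolution is the linear interpolation of the first downward FSC = 0.5
crossing (Nyquist with a flag if never crossed). RE low-passes both maps
with a sharp spherical mask (bit-reproducible, unlike soft filters),
amplitude-matches the reconstruction by the least-squares scale
`sum(rho_o rho_r)/sum(rho_r^2)` — a Fourier-synthesized map's overall
scale is otherwise meaningless — then reports
`sum|rho_o - rho_r| / sum|rho_o| x 100`. RE-vs-frequency profiles are
reported from `R = 1/14.4 1/A` upward (shell 9 at the default geometry):
below the band where the object's spectral mass is fully included, RE is
dominated by a shrinking denominator and is not monotone; within the
reported range it increases with cutoff as expected.

## Problem sizes and study conditions

The acceptance checks run the full pipeline at 64^3 / 2 Å with the
default phantom, passing its true support radius (32 Å) as the
angular-band bound per shell: a noise-free round trip from 300
projections checked against FSC >= 0.95 through 2/3 Nyquist, and a noise
study from 2000 projections at S/N = 0.1, 0.5, 0.8 with fixed seeds
checking RE stability across S/N at the low-frequency anchor, RE
monotonicity over the reported cutoff range, and non-improving FSC=0.5
resolution as noise grows. With this phantom the S/N = 0.1 run retains
extra RE at the 1/14.4 1/A anchor (the blob phantom is much sparser in
the image plane than a protein map, so the image-domain S/N definition
calibrates a relatively larger noise sigma per Fourier coefficient),
while at lower cutoffs RE is essentially S/N-independent. Basis-level
checks (multiplicity to l = 200, orthonormality and 24-fold invariance
at lmax = 24, shell-coefficient recovery to 1e-8 on 5x-oversampled
noise-free shells) are exact-tolerance tests.

## Known limitations

- Orientations and centers must be known; no ab initio or refinement.
- No CTF model; noise is white Gaussian only.
- Ring resampling is bilinear in the padded 2D transform; at very high
  shells its error, not the fit, limits fidelity.
- The `mu` ordering above `l = 12` is a convention of this
  implementation; consumers should rely on the spanned subspace.
- `reconstruct` holds all shell samples in memory (~40 bytes per sample;
  ~170 MB for 2000 projections at 64^3).
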