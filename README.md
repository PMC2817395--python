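# osafrec

3D reconstruction of **octahedrally symmetric macromolecules** from 2D
projection images with known orientations, using **octahedral
symmetry-adapted functions (OSAFs)** — the cubic-harmonic analogue of the
icosahedral-harmonic methods long used for virus reconstruction.

Many protein assemblies (ferritin, small heat-shock proteins such as
DegP24 or hsp16.5) carry the 432 point symmetry of the octahedral rotation
group *O*. Expanding their structure factor over basis functions that are
themselves invariant under all 24 rotations lets every projection
constrain the whole orbit of views at once, which both regularizes the
fit and strongly suppresses noise.

## The method

An OSAF of order *l* is a real combination of fully normalized spherical
harmonics,

    O_{l,mu}(theta, phi) = sum_{m ≡ 0 (mod 4)} B^{mu}_{l,m} Y_{l,m}(theta, phi),

with the coordinate axes along the three 4-fold axes (hence *m* divisible
by 4) and `B_{l,-m} = (-1)^{l-m} B_{l,m}`. The number of independent
OSAFs at order *l* is `mu(l) = mu(l mod 12) + floor(l/12)`. All orders
are generated from the three seeds *l* = 4, 6, 9 by **stretched
Clebsch–Gordan coupling** (the closed-form coefficients for maximal total
angular momentum), followed by Gram–Schmidt orthonormalization within
each order — a recursion that is numerically stable to order ~1000 when
the factorial ratios are evaluated through log-gamma.

Reconstruction proceeds shell by shell in reciprocal space:

1. 2D-FFT each projection (object-centered phase convention), undo the
   per-image center offset with a phase ramp;
2. by the central-section theorem, resample each transform on rings of
   the FFT-native shell radii and map every ring point through the
   projection rotation to a 3D direction (Theta, Phi);
3. on each shell solve two real least-squares systems: Re F against the
   even-*l* cosine OSAFs and Im F against the odd-*l* sine OSAFs, giving
   coefficients `f_{l,mu}(R)`;
4. invert radially with spherical Bessel functions,
   `g_{l,mu}(r) = int f_{l,mu}(R) j_l(2 pi R r) R^2 dR`, and synthesize
   `rho = 4 pi [ sum_{l even} (-1)^{l/2} g O^c + sum_{l odd} (-1)^{(l+1)/2} g O^s ]`.

Quality is quantified by Fourier shell correlation (FSC, with the
FSC = 0.5 nominal-resolution criterion) and the relative error
`RE = sum|rho_o - rho_r| / sum|rho_o| x 100%` after amplitude matching,
as a function of low-pass cutoff.

Test objects are programmatically generated octahedral phantoms (Gaussian
blobs replicated over the 24-element orbit); orientations use the ZXZ
Euler convention with an exact conversion from ZYZ.

## Worked example

```python
import numpy as np
from osafrec import (make_phantom, make_projection_stack, reconstruct,
                     fsc, resolution_at_threshold, relative_error)

vol = make_phantom(n=64, voxel=2.0, n_blobs=4, blob_sigma=3.0, seed=11)
stack = make_projection_stack(vol, 300, s_over_n=np.inf, seed=42)
res = reconstruct(stack, lmax=25)

curve = fsc(vol, res.volume)
print("min FSC to 2/3 Nyquist:", curve.values[:21].min())
print("FSC=0.5 resolution (A):", resolution_at_threshold(curve)[0])
print("RE at R=1/14.4 1/A (%):", relative_error(vol, res.volume, 1/14.4))
```

prints (exact numbers depend on the seeds shown):

```
min FSC to 2/3 Nyquist: 0.9798139048357907
FSC=0.5 resolution (A): 4.617495628929413
RE at R=1/14.4 1/A (%): 7.082288790008665
```

i.e. the noise-free 300-projection reconstruction tracks the phantom
essentially perfectly through two thirds of the Nyquist band, the FSC=0.5
crossing sits at ~4.6 Å (2 Å voxels), and the low-frequency relative
error is a few percent. With noisy projections (`s_over_n=0.1/0.5/0.8`)
the low-frequency RE stays nearly constant while the attainable
resolution degrades gracefully with noise — the noise suppression that
motivates symmetry-adapted bases.

The same pipeline is scriptable from the shell:

```sh
osafrec simulate --n-projections 2000 --snr 0.5 --out stack.mrc --meta meta.tsv --phantom-out ref.mrc
osafrec reconstruct --stack stack.mrc --meta meta.tsv --lmax 25 --out rec.mrc
osafrec evaluate --ref ref.mrc --rec rec.mrc --out metrics.tsv
osafrec basis --lmax 40 --out coeffs.tsv --check
```

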