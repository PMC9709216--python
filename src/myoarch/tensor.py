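"""Structure-tensor estimation of per-voxel myocyte orientation.

For each voxel the intensity gradient ``g`` is taken by central
differences; the structure tensor is the window-aggregated sum of gradient
outer products ``J = Σ g gᵀ``. Its eigenvector ``v3`` of smallest
eigenvalue is the direction of least intensity variation — the long axis
of the locally rod-like myocyte aggregates. The eigenvalue spread yields
the fractional anisotropy of the image gradient,

    FA = sqrt(3/2) · ||λ − λ̂|| / ||λ||,   λ̂ = (λ1+λ2+λ3)/3,

which is 0 for an isotropic neighbourhood and 1 when all gradient energy
lies along a single direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "compute_gradient",
    "compute_structure_tensor",
    "eigendecompose",
    "fractional_anisotropy",
    "TensorField",
    "OrientationField",
]

# index pairs of the 6 unique components of a symmetric 3×3 tensor
_SYM = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorField:
    """Per-voxel symmetric structure tensor, stored as 6 unique components
    (xx, yy, zz, xy, xz, yz) in ``components[..., k]``."""

    components: np.ndarray  # (nx, ny, nz, 6)
    window: int

    def as_matrices(self, where: np.ndarray | None = None) -> np.ndarray:
        """Dense (N, 3, 3) tensors at ``where`` (default: all voxels)."""
        comp = self.components if where is None else self.components[where]
        comp = comp.reshape(-1, 6)
        J = np.empty((len(comp), 3, 3), dtype=comp.dtype)
        for k, (i, j) in enumerate(_SYM):
            J[:, i, j] = comp[:, k]
            J[:, j, i] = comp[:, k]
        return J


@dataclass
class OrientationField:
    """Eigen-system of the structure tensor.

    ``eigenvalues[..., k]`` holds λ_{k+1} with λ1 ≥ λ2 ≥ λ3 ≥ 0;
    ``v3`` is the unit tertiary eigenvector (myocyte long axis,
    sign-ambiguous); ``valid`` flags voxels with a well-defined axis.
    """

    eigenvalues: np.ndarray  # (nx, ny, nz, 3), descending
    v3: np.ndarray           # (nx, ny, nz, 3)
    valid: np.ndarray        # (nx, ny, nz) bool


def compute_gradient(volume: ImageVolume, *, sigma: float = 0.0,
                     ) -> np.ndarray:
    """Per-voxel intensity gradient (3, nx, ny, nz) by central differences.

    Interior voxels use ``(I(x+1) − I(x−1))/2`` per axis; image-boundary
    voxels fall back to one-sided differences. The volume must be
    isotropic (resample first); gradients are per-voxel units, which only
    scales the tensor uniformly. ``sigma`` (voxels) optionally Gaussian
    pre-smooths the intensities.
    """
    if not volume.is_isotropic:
        raise ValueError(
            f"anisotropic voxels {volume.voxel_size_um}: resample to "
            "isotropic spacing first (resample_isotropic)")
    vals = np.asarray(volume.values, dtype=np.float32)
    if not np.all(np.isfinite(vals)):
        raise ValueError("volume contains non-finite values")
    if sigma > 0:
        vals = ndimage.gaussian_filter(vals, sigma, mode="nearest")
    gx, gy, gz = np.gradient(vals, axis=(0, 1, 2))
    return np.stack([gx, gy, gz])


def compute_structure_tensor(gradients: np.ndarray, window: int = 3,
                             mask: np.ndarray | None = None) -> TensorField:
    """Windowed sum of gradient outer products.

    ``J(x) = Σ_{w ∈ window(x)} g(w) g(w)ᵀ`` over a cubic window of odd
    side ``window`` centred at x. With a mask, gradients at voxels outside
    the mask are excluded from every sum (no leakage across the
    myocardial boundary).
    """
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be odd and ≥ 1, got {window}")
    g = np.asarray(gradients)
    if g.ndim != 4 or g.shape[0] != 3:
        raise ValueError(f"gradients must have shape (3, nx, ny, nz), "
                         f"got {g.shape}")
    shape = g.shape[1:]
    if any(window > s for s in shape):
        raise ValueError(f"window {window} exceeds volume shape {shape}")
    if mask is not None:
        m = np.asarray(mask, bool).astype(np.float32)
        g = g * m[None]
    comps = np.empty(shape + (6,), dtype=np.float32)
    nwin = window**3
    for k, (i, j) in enumerate(_SYM):
        prod = g[i] * g[j]
        if window == 1:
            comps[..., k] = prod
        else:
            # uniform_filter returns window means; rescale to sums
            comps[..., k] = ndimage.uniform_filter(
                prod, size=window, mode="constant", cval=0.0) * nwin
    # the diagonal entries are sums of squares; clamp the tiny negative
    # residues the separable running-sum filter leaves at empty voxels
    np.clip(comps[..., :3], 0.0, None, out=comps[..., :3])
    return TensorField(components=comps, window=window)


def eigendecompose(tensors: TensorField, mask: np.ndarray | None = None,
                   tau: float = 0.05) -> OrientationField:
    """Sorted eigen-system of the structure tensor field.

    Voxels are flagged invalid when the tensor trace is ~0 or when
    ``λ2 − λ3 < tau·λ1`` (the tertiary axis is degenerate — e.g. an
    isotropic neighbourhood has no preferred myocyte direction).
    """
    shape = tensors.components.shape[:3]
    where = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    J = tensors.as_matrices(where).astype(np.float64)
    evals = np.zeros(shape + (3,), dtype=np.float32)
    v3 = np.zeros(shape + (3,), dtype=np.float32)
    valid = np.zeros(shape, bool)
    if J.size == 0:
        return OrientationField(evals, v3, valid)
    tr = np.trace(J, axis1=1, axis2=2)
    # tensors are Σggᵀ and hence PSD up to accumulation error; the inputs
    # are float32, so the tolerance is single-precision-scaled and
    # referenced to the largest tensor in the field
    psd_tol = 1e-5 * max(float(tr.max()), 1e-30)
    w, V = np.linalg.eigh(J)            # ascending
    if np.any(w[:, 0] < -psd_tol):
        raise ValueError("structure tensor not positive semi-definite "
                         "beyond tolerance")
    w = np.clip(w, 0.0, None)
    desc = w[:, ::-1]                   # λ1 ≥ λ2 ≥ λ3
    vecs3 = V[:, :, 0]                  # eigenvector of the smallest λ
    ok = (tr > 0) & ((desc[:, 1] - desc[:, 2]) >= tau * desc[:, 0])
    evals[where] = desc
    v3[where] = vecs3
    valid[where] = ok
    return OrientationField(eigenvalues=evals, v3=v3, valid=valid)


def fractional_anisotropy(eigenvalues: np.ndarray,
                          valid: np.ndarray | None = None,
                          atol: float = 1e-9) -> np.ndarray:
    """FA map from sorted eigenvalues (..., 3); NaN where trace is 0.

    FA = sqrt(3/2)·sqrt(Σ(λi−λ̂)²)/sqrt(Σλi²) with λ̂ the eigenvalue mean.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    scale = np.abs(lam).max() if lam.size else 0.0
    if np.any(lam < -atol * max(scale, 1.0)):
        raise ValueError("negative eigenvalues beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    if valid is not None:
        fa = np.where(np.asarray(valid, bool), fa, np.nan)
    return np.clip(fa, 0.0, 1.0)
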