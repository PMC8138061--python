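"""Diffusion-tensor fitting and the four classical scalar maps.

The single-tensor model describes the diffusion-weighted signal as

    S(g, b) = S0 * exp(-b * g^T D g)

with D a symmetric positive 3x3 tensor (mm²/s).  Taking logs makes the fit
linear: per voxel we solve

    ln S = ln S0 - b g^T D g

by ordinary least squares over the 6 unique tensor elements plus ln S0,
then eigendecompose D.  Negative eigenvalues (noise) are clamped to zero
and flagged.  Derived scalars:

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy (0 if l = 0)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIVolume

__all__ = ["TensorField", "ScalarMap", "fit_tensor", "tensor_scalars"]

_LOG_EPS = 1e-10


@dataclass
class ScalarMap:
    """A named voxelwise scalar feature."""

    values: np.ndarray
    name: str
    units: str = ""


@dataclass
class TensorField:
    """Per-voxel tensor eigensystem plus estimated S0 and fit bookkeeping."""

    eigvals: np.ndarray  # (x, y, z, 3), descending, mm^2/s
    eigvecs: np.ndarray  # (x, y, z, 3, 3); [..., :, i] pairs with eigvals[..., i]
    s0: np.ndarray  # (x, y, z)
    fit_mask: np.ndarray  # voxels that were fitted
    clamped: np.ndarray  # voxels where negative eigenvalues were clamped
    affine: np.ndarray | None = None
    voxel_size: np.ndarray | None = None

    def principal_direction(self) -> np.ndarray:
        """Unit principal eigenvector per voxel, (x, y, z, 3)."""
        return self.eigvecs[..., :, 0]


def _design_matrix(gtab) -> np.ndarray:
    b = gtab.bvals[:, None]
    g = gtab.bvecs
    return np.concatenate(
        [
            -b * g[:, [0]] ** 2,
            -b * g[:, [1]] ** 2,
            -b * g[:, [2]] ** 2,
            -2 * b * g[:, [0]] * g[:, [1]],
            -2 * b * g[:, [0]] * g[:, [2]],
            -2 * b * g[:, [1]] * g[:, [2]],
            np.ones_like(b),
        ],
        axis=1,
    )


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Log-linear ordinary-least-squares tensor fit over a mask.

    Non-positive signals are clamped to a small epsilon before the log and
    flagged through the ``clamped`` volume together with negative-eigenvalue
    voxels.
    """
    gtab = dwi.gradient_table
    if gtab.n_dirs < 6:
        raise ValueError("tensor fit requires >= 6 diffusion-weighted directions")
    if gtab.n_b0 < 1:
        raise ValueError("tensor fit requires at least one b0 volume")

    shape = dwi.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)

    A = _design_matrix(gtab)  # (N, 7)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError("singular design matrix: directions not independent")
    pinv = np.linalg.pinv(A)

    S = dwi.signal[mask]  # (V, N)
    bad_signal = S <= 0
    logS = np.log(np.clip(S, _LOG_EPS, None))
    coeffs = logS @ pinv.T  # (V, 7): Dxx Dyy Dzz Dxy Dxz Dyz lnS0

    V = coeffs.shape[0]
    D = np.empty((V, 3, 3))
    D[:, 0, 0] = coeffs[:, 0]
    D[:, 1, 1] = coeffs[:, 1]
    D[:, 2, 2] = coeffs[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = coeffs[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = coeffs[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = coeffs[:, 5]

    w, v = np.linalg.eigh(D)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped_v = (w < 0).any(axis=1) | bad_signal.any(axis=1)
    w = np.clip(w, 0.0, None)

    eigvals = np.zeros(shape + (3,))
    eigvecs = np.zeros(shape + (3, 3))
    eigvecs[..., :, :] = np.eye(3)
    s0 = np.zeros(shape)
    clamped = np.zeros(shape, dtype=bool)
    eigvals[mask] = w
    eigvecs[mask] = v
    s0[mask] = np.exp(coeffs[:, 6])
    clamped[mask] = clamped_v
    return TensorField(
        eigvals=eigvals,
        eigvecs=eigvecs,
        s0=s0,
        fit_mask=mask,
        clamped=clamped,
        affine=dwi.affine,
        voxel_size=dwi.voxel_size,
    )


def fa_from_eigvals(eigvals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues along the last axis."""
    ev = np.asarray(eigvals, dtype=float)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((3.0 / 2.0) * np.sum((ev - md) ** 2, axis=-1))
    den = np.sqrt(np.sum(ev**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(fa, 0.0, 1.0)


def tensor_scalars(tf: TensorField) -> dict[str, ScalarMap]:
    """MD, FA, AD, RD scalar maps from a fitted tensor field."""
    ev = tf.eigvals
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = ev[..., 1:].mean(axis=-1)
    fa = fa_from_eigvals(ev)
    u = "mm^2/s"
    return {
        "MD": ScalarMap(md, "MD", u),
        "FA": ScalarMap(fa, "FA", ""),
        "AD": ScalarMap(ad, "AD", u),
        "RD": ScalarMap(rd, "RD", u),
    }
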