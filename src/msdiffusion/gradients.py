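"""Gradient tables for single-shell diffusion acquisitions.

A single-shell HARDI protocol is described by a set of diffusion-sensitizing
directions at one b-value plus a few non-weighted (b=0) volumes.  The
reference acquisition emulated throughout this package is b = 1000 s/mm²,
3 b0 volumes and 45 directions at 2 mm isotropic resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = ["GradientTable", "make_gradient_table"]




@dataclass(frozen=True)
class GradientTable:
    """b-values and unit gradient directions of a diffusion acquisition.

    Parameters
    ----------
    bvals : (N,) array
        b-value per volume in s/mm².  Exactly 0 marks a b0 volume.
    bvecs : (N, 3) array
        Gradient direction per volume.  Unit norm for b > 0 entries;
        conventionally zero for b0 entries.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape != (bvecs.shape[0],):
            raise ValueError("bvals and bvecs length mismatch")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        dwi = bvals > 0
        if dwi.sum() < 6:
            raise ValueError(
                "at least 6 diffusion-weighted directions are required for "
                f"tensor identifiability, got {int(dwi.sum())}"
            )
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-unit gradient direction for a b > 0 volume")
        # renormalize only meaningfully off-unit vectors so that file
        # round trips of already-unit directions stay bit-identical
        object.__setattr__(self, "bvals", bvals)
        off = np.abs(norms - 1.0) > 1e-12
        if off.any():
            bvecs = bvecs.copy()
            rows = np.nonzero(dwi)[0][off]
            bvecs[rows] /= norms[off, None]
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def n_dirs(self) -> int:
        return int(self.dwi_mask.sum())

    def __len__(self) -> int:
        return len(self.bvals)

    # ---- FSL-dialect I/O -------------------------------------------------
    def save_fsl(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        """Write whitespace-separated bval (one row) / bvec (3 rows) files."""
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.17g")

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientTable":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            bvecs = bvecs.T  # ambiguous; FSL convention is one row per axis
        return cls(bvals=bvals, bvecs=bvecs)


def _repulsion_energy_grad(x: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """Electrostatic energy of n antipodally symmetric points and its gradient.

    Points live on the unit sphere; each point interacts with every other
    point and with every other point's antipode (1/r Coulomb terms), which
    spreads directions over the hemisphere.
    """
    p = x.reshape(n, 3)
    norms = np.linalg.norm(p, axis=1, keepdims=True)
    u = p / norms

    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    d1 = np.linalg.norm(diff, axis=2)
    d2 = np.linalg.norm(summ, axis=2)
    iu = np.triu_indices(n, k=1)
    energy = float(np.sum(1.0 / d1[iu]) + np.sum(1.0 / d2[iu]))

    np.fill_diagonal(d1, np.inf)
    np.fill_diagonal(d2, np.inf)
    # dE/du_i = -sum_j (u_i-u_j)/d1^3 - sum_j (u_i+u_j)/d2^3
    g_u = -(diff / d1[:, :, None] ** 3).sum(axis=1) - (summ / d2[:, :, None] ** 3).sum(
        axis=1
    )
    # chain rule through normalization u = p/|p|
    dot = np.sum(g_u * u, axis=1, keepdims=True)
    g_p = (g_u - dot * u) / norms
    return energy, g_p.ravel()


def make_gradient_table(
    n_dirs: int = 45,
    n_b0: int = 3,
    b: float = 1000.0,
    seed: int = 0,
) -> GradientTable:
    """Build a single-shell gradient table with repulsion-optimized directions.

    Directions are laid out by minimizing an electrostatic (Coulomb) energy
    with antipodal symmetry, the standard construction for approximately
    uniform hemisphere coverage.  The b0 volumes come first, then the
    diffusion-weighted directions.

    Parameters
    ----------
    n_dirs : int
        Number of diffusion-weighted directions (>= 6).
    n_b0 : int
        Number of b = 0 volumes.
    b : float
        Shell b-value in s/mm².
    seed : int
        Seed for the random initialization; the optimized layout is
        deterministic given the seed.
    """
    if n_dirs < 6:
        raise ValueError("n_dirs must be >= 6 for tensor identifiability")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n_dirs, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)

    res = minimize(
        _repulsion_energy_grad,
        x0.ravel(),
        args=(n_dirs,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    dirs = res.x.reshape(n_dirs, 3)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # canonical hemisphere: make the last nonzero component positive
    flip = dirs[:, 2] < 0
    flip |= (dirs[:, 2] == 0) & (dirs[:, 1] < 0)
    flip |= (dirs[:, 2] == 0) & (dirs[:, 1] == 0) & (dirs[:, 0] < 0)
    dirs[flip] *= -1.0

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs], axis=0)
    return GradientTable(bvals=bvals, bvecs=bvecs)


def min_pairwise_angle_deg(directions: np.ndarray) -> float:
    """Smallest pairwise angle (degrees, antipodally symmetric) in a set."""
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    cos = np.abs(d @ d.T)
    np.fill_diagonal(cos, 0.0)
    return float(np.degrees(np.arccos(np.clip(cos.max(), -1, 1))))
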