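"""Single-shell diffusion ODF reconstruction and the ODF-energy statistic.

The orientation distribution function (ODF) is reconstructed with the
analytic Q-ball method: the b0-normalized signal is fitted with a real,
symmetric (even-order) spherical-harmonic basis under Laplace-Beltrami
regularization, and the Funk-Radon transform is applied as a diagonal
operator on the coefficients, 2*pi*P_l(0) per harmonic degree l.

ODF energy
----------
A voxel's ODF is sampled on N directions, giving amplitudes a_1..a_N (here
min-max normalized to [0, 1] per voxel).  These "diffusion magnitudes over
all directions" are fitted with a normal distribution by maximum likelihood
(mean and population standard deviation), each amplitude is converted to
the fitted density p_i = N(a_i; mu, sigma), and the voxel energy is the sum

    E = sum_i log(p_i^2) = 2 * sum_i log p_i ,

i.e. twice the log-likelihood of the amplitudes under their own normal fit.
A tight amplitude distribution (orientationally simple voxel) yields high
densities and a high energy; a dispersed, multi-modal profile lowers it.
Because densities are not probabilities the energy's sign is unconstrained,
and rescaling all amplitudes by c > 0 shifts the energy by exactly
-2*N*log(c).  ``mode="log_of_sum"`` exposes the alternative aggregation
log(sum_i p_i^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .dti import ScalarMap
from .phantom import DWIVolume

__all__ = ["ODFField", "EnergyMap", "fit_sh_odf", "odf_energy", "real_sym_sh_basis"]


def n_coeffs(sh_order: int) -> int:
    return (sh_order + 1) * (sh_order + 2) // 2


def real_sym_sh_basis(
    sh_order: int, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Real, even-order, antipodally symmetric spherical-harmonic basis.

    Returns the design matrix B (n_directions, n_coeffs) and the harmonic
    degree l of each column.  Ordering: l ascending, m from -l to l.
    """
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    theta = np.arccos(np.clip(d[:, 2], -1, 1))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth

    cols = []
    ls = []
    for l in range(0, sh_order + 1, 2):
        # complex Y_l^m for m = 0..l evaluated once per l
        y = special.sph_harm_y(l, np.arange(0, l + 1)[:, None], theta[None, :], phi[None, :])
        for m in range(-l, l + 1):
            if m < 0:
                col = np.sqrt(2.0) * y[-m].imag
            elif m == 0:
                col = y[0].real
            else:
                col = np.sqrt(2.0) * y[m].real
            cols.append(col)
            ls.append(l)
    return np.stack(cols, axis=1), np.asarray(ls)


def _legendre0(ls: np.ndarray) -> np.ndarray:
    return special.eval_legendre(ls, 0.0)


@dataclass
class ODFField:
    """Voxelwise ODF: SH coefficients plus amplitudes on a direction set."""

    sh_coeffs: np.ndarray  # (x, y, z, n_coeffs)
    sh_order: int
    directions: np.ndarray  # (N, 3) evaluation set
    amplitudes: np.ndarray  # (x, y, z, N), raw ODF values
    fit_mask: np.ndarray

    def normalized_amplitudes(self) -> np.ndarray:
        """Per-voxel min-max normalization of the amplitudes to [0, 1].

        Voxels with a flat profile (max == min) normalize to all zeros.
        """
        a = self.amplitudes
        lo = a.min(axis=-1, keepdims=True)
        hi = a.max(axis=-1, keepdims=True)
        rng = hi - lo
        safe = np.where(rng > 0, rng, 1.0)
        return np.where(rng > 0, (a - lo) / safe, 0.0)


@dataclass
class EnergyMap(ScalarMap):
    """ODF-energy scalar map with provenance of its direction set."""

    n_directions: int = 0
    sigma_floor: float = 1e-6
    mode: str = "sum"


def fit_sh_odf(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    sh_order: int = 6,
    lambda_reg: float = 0.006,
    directions: np.ndarray | None = None,
) -> ODFField:
    """Analytic Q-ball ODF fit on the single shell.

    Per voxel the diffusion-weighted signal is normalized by the mean b0,
    projected on the even-order SH basis with Laplace-Beltrami
    regularization weight ``lambda_reg``, transformed by the Funk-Radon
    diagonal operator, and evaluated on ``directions`` (default: the
    acquisition's gradient directions).
    """
    gtab = dwi.gradient_table
    bvecs = gtab.bvecs[gtab.dwi_mask]
    if n_coeffs(sh_order) > len(bvecs):
        raise ValueError(
            f"sh_order {sh_order} needs {n_coeffs(sh_order)} coefficients but only "
            f"{len(bvecs)} directions are available"
        )
    if sh_order % 2:
        raise ValueError("sh_order must be even")
    shape = dwi.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)

    B, ls = real_sym_sh_basis(sh_order, bvecs)
    lb = (ls * (ls + 1)) ** 2  # Laplace-Beltrami penalty diagonal
    fit_op = np.linalg.solve(B.T @ B + lambda_reg * np.diag(lb), B.T)

    s0 = dwi.mean_b0()[mask]
    s0 = np.where(s0 > 0, s0, 1.0)
    signal = dwi.signal[mask][:, gtab.dwi_mask] / s0[:, None]

    coeffs = signal @ fit_op.T  # (V, n_coeffs)
    frt = 2.0 * np.pi * _legendre0(ls)
    odf_coeffs = coeffs * frt[None, :]

    if directions is None:
        directions = bvecs
    Beval, _ = real_sym_sh_basis(sh_order, directions)
    amps = odf_coeffs @ Beval.T

    sh = np.zeros(shape + (odf_coeffs.shape[1],))
    am = np.zeros(shape + (amps.shape[1],))
    sh[mask] = odf_coeffs
    am[mask] = amps
    return ODFField(
        sh_coeffs=sh,
        sh_order=sh_order,
        directions=np.asarray(directions, dtype=float),
        amplitudes=am,
        fit_mask=mask,
    )


def energy_from_amplitudes(
    amps: np.ndarray, sigma_floor: float = 1e-6, mode: str = "sum"
) -> np.ndarray:
    """ODF energy of amplitude vectors along the last axis.

    Fits a normal distribution per voxel by maximum likelihood (mean,
    population standard deviation, floored at ``sigma_floor``), evaluates
    its density p_i at every amplitude, and aggregates log(p_i^2):
    ``mode="sum"`` (default) returns sum_i log(p_i^2); ``mode="log_of_sum"``
    returns log(sum_i p_i^2).
    """
    a = np.asarray(amps, dtype=float)
    if a.shape[-1] < 10:
        raise ValueError("ODF energy requires amplitudes on >= 10 directions")
    mu = a.mean(axis=-1, keepdims=True)
    sigma = np.maximum(a.std(axis=-1, keepdims=True), sigma_floor)
    z = (a - mu) / sigma
    logp = -0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    if mode == "sum":
        return 2.0 * logp.sum(axis=-1)
    if mode == "log_of_sum":
        return special.logsumexp(2.0 * logp, axis=-1)
    raise ValueError(f"unknown mode {mode!r}")


def odf_energy(
    odf: ODFField,
    mask: np.ndarray | None = None,
    sigma_floor: float = 1e-6,
    mode: str = "sum",
) -> EnergyMap:
    """Voxelwise ODF-energy map from per-voxel normalized ODF amplitudes."""
    amps = odf.normalized_amplitudes()
    values = energy_from_amplitudes(amps, sigma_floor=sigma_floor, mode=mode)
    if mask is None:
        mask = odf.fit_mask
    values = np.where(mask, values, 0.0)
    return EnergyMap(
        values=values,
        name="ODF_energy",
        units="",
        n_directions=amps.shape[-1],
        sigma_floor=sigma_floor,
        mode=mode,
    )
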