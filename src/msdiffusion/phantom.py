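"""Synthetic single-shell DWI phantoms with known microstructure.

The phantom emulates a mirrored-hemisphere, brain-like slab: anisotropic
white-matter bundles placed symmetrically about the mid-sagittal (x) plane,
focal lesions embedded in the bundles of one hemisphere, and an isotropic
background.  The noiseless signal follows the multi-tensor model

    S(g, b) = S0 * sum_k f_k * exp(-b * g^T D_k g),

with per-voxel mixtures of diffusion tensors D_k (mm²/s) and mixture
fractions f_k summing to one.  Noise is Rician: the magnitude of the
noiseless signal perturbed by complex Gaussian noise with channel standard
deviation sigma = S0 / snr.  ``snr = inf`` yields the exact noiseless
signal, which is what the round-trip fitting tests rely on.

Lesions override the bundle microstructure inside a sphere.  Two contrast
mechanisms are supported, mirroring the two axes of lesion pathology the
downstream classification tasks probe:

* diffusivity contrast - lesion (and optionally a distinct erosion-defined
  core) carries its own tensor eigenvalues, e.g. elevated radial
  diffusivity from demyelination;
* orientation contrast - the lesion signal is a mixture of copies of the
  lesion tensor arranged on a cone about the bundle axis
  (``dispersion_deg``) and optionally a second crossing population
  (``crossing_fraction``), increasing intra-voxel orientational complexity
  while leaving the trace of the mixture unchanged.

Per-region biological variability (diffusivity scale, dispersion angle,
crossing fraction) is drawn independently for every lesion and for its
mirrored contralateral region, so ROI-level feature distributions overlap
between classes the way heterogeneous patient tissue does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import binary_erosion

from .gradients import GradientTable, make_gradient_table

__all__ = [
    "Bundle",
    "Lesion",
    "PhantomSpec",
    "CohortSpec",
    "DWIVolume",
    "simulate_dwi",
    "simulate_cohort",
]

# background (grey-matter-like) isotropic diffusivity, mm^2/s
BACKGROUND_ADC = 0.8e-3
# default white-matter bundle eigenvalues, mm^2/s
WM_EIGVALS = (1.7e-3, 0.3e-3, 0.3e-3)


def _as_eigvals(v) -> np.ndarray:
    ev = np.asarray(v, dtype=float)
    if ev.shape != (3,):
        raise ValueError("eigenvalues must be a 3-vector")
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be non-negative")
    if not (ev[0] >= ev[1] >= ev[2]):
        raise ValueError("eigenvalues must be sorted descending")
    return ev


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the x unit vector onto ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, a)
    c = float(x @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def tensor_from(axis, eigvals) -> np.ndarray:
    """3x3 diffusion tensor with principal axis ``axis`` and given eigenvalues."""
    ev = _as_eigvals(eigvals)
    R = _rotation_to(axis)
    return R @ np.diag(ev) @ R.T


def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass(frozen=True)
class Bundle:
    """Axis-aligned box of coherently oriented white matter.

    ``lo``/``hi`` are inclusive/exclusive voxel-index bounds; ``orientation``
    is the fiber axis (need not be grid-aligned); ``eigvals`` the tensor
    eigenvalues in mm²/s, descending.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    eigvals: tuple[float, float, float] = WM_EIGVALS

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        sl = tuple(slice(l, h) for l, h in zip(self.lo, self.hi))
        m[sl] = True
        return m


@dataclass(frozen=True)
class Lesion:
    """Spherical focal lesion embedded in a bundle.

    ``center`` in voxel coordinates, ``radius`` in voxels.  ``eigvals``
    replace the bundle tensor inside the sphere.  ``core_eigvals``, if set,
    apply to the erosion-defined core (all 26 neighbors inside the lesion)
    so core-vs-shell diffusivity separability is controllable.
    ``dispersion_deg`` > 0 replaces the single lesion tensor with an equal
    mixture of one axial copy plus ``n_fan`` copies on a cone of that
    half-angle about the bundle axis; ``crossing_fraction`` > 0 adds a
    second, crossing fiber population (orientational-complexity contrast).
    """

    center: tuple[float, float, float]
    radius: float
    eigvals: tuple[float, float, float] = (1.2e-3, 0.6e-3, 0.6e-3)
    core_eigvals: tuple[float, float, float] | None = None
    dispersion_deg: float = 0.0
    n_fan: int = 6
    # fraction of the mixture assigned to a second, crossing fiber
    # population tilted by crossing_angle_deg from the bundle axis
    crossing_fraction: float = 0.0
    crossing_angle_deg: float = 70.0

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        c = np.asarray(self.center, dtype=float)
        d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
        return d2 <= self.radius**2


@dataclass(frozen=True)
class PhantomSpec:
    """Complete geometric and microstructural description of one phantom."""

    grid_shape: tuple[int, int, int] = (40, 40, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bundles: tuple[Bundle, ...] = ()
    lesions: tuple[Lesion, ...] = ()
    s0: float = 1000.0
    snr: float = np.inf
    mirror_symmetric: bool = True
    background_adc: float = BACKGROUND_ADC
    # Regional biological variability, drawn once per lesion region and,
    # independently, once per mirrored contralateral region:
    # * regional_scale_sd - sd of a multiplicative jitter on all tensor
    #   eigenvalues of the region (regional diffusivity variability
    #   unrelated to the lesion contrast itself);
    # * nawm_dispersion_deg / dispersion_sd - baseline cone half-angle of
    #   normal-appearing white matter and the per-region sd of the drawn
    #   half-angle (lesion regions draw around their own dispersion_deg).
    regional_scale_sd: float = 0.0
    nawm_dispersion_deg: float = 0.0
    dispersion_sd: float = 0.0
    # per-lesion sd of the drawn crossing fraction (mirror regions never
    # receive a crossing population)
    crossing_sd: float = 0.0

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        if np.any(np.asarray(self.voxel_size) <= 0):
            raise ValueError("voxel_size must be strictly positive")
        for b in self.bundles:
            _as_eigvals(b.eigvals)
        bundle_mask = self.wm_mask()
        for les in self.lesions:
            _as_eigvals(les.eigvals)
            if les.core_eigvals is not None:
                _as_eigvals(les.core_eigvals)
            c = np.asarray(les.center)
            if np.any(c - les.radius < -0.5) or np.any(c + les.radius > shape - 0.5):
                raise ValueError(f"lesion at {les.center} extends outside the grid")
            m = les.mask(self.grid_shape)
            if not np.all(bundle_mask[m]):
                raise ValueError(f"lesion at {les.center} not fully inside a bundle")
        if self.mirror_symmetric:
            flipped = bundle_mask[::-1]
            if not np.array_equal(bundle_mask, flipped):
                raise ValueError(
                    "mirror_symmetric requires bundle geometry invariant under "
                    "the left-right (x-axis) flip"
                )

    def wm_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for b in self.bundles:
            m |= b.mask(self.grid_shape)
        return m

    # ---- JSON round trip (CLI interchange format) ------------------------
    def to_json(self, path: str | Path) -> None:
        def _tup(x):
            return list(np.asarray(x, dtype=float))

        doc = {
            "grid_shape": list(self.grid_shape),
            "voxel_size": _tup(self.voxel_size),
            "s0": self.s0,
            "snr": None if np.isinf(self.snr) else self.snr,
            "mirror_symmetric": self.mirror_symmetric,
            "background_adc": self.background_adc,
            "regional_scale_sd": self.regional_scale_sd,
            "nawm_dispersion_deg": self.nawm_dispersion_deg,
            "dispersion_sd": self.dispersion_sd,
            "crossing_sd": self.crossing_sd,
            "bundles": [
                {
                    "lo": list(b.lo),
                    "hi": list(b.hi),
                    "orientation": _tup(b.orientation),
                    "eigvals": _tup(b.eigvals),
                }
                for b in self.bundles
            ],
            "lesions": [
                {
                    "center": _tup(les.center),
                    "radius": les.radius,
                    "eigvals": _tup(les.eigvals),
                    "core_eigvals": None
                    if les.core_eigvals is None
                    else _tup(les.core_eigvals),
                    "dispersion_deg": les.dispersion_deg,
                    "n_fan": les.n_fan,
                    "crossing_fraction": les.crossing_fraction,
                    "crossing_angle_deg": les.crossing_angle_deg,
                }
                for les in self.lesions
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        doc = json.loads(Path(path).read_text())
        bundles = tuple(
            Bundle(
                lo=tuple(b["lo"]),
                hi=tuple(b["hi"]),
                orientation=tuple(b.get("orientation", (1.0, 0.0, 0.0))),
                eigvals=tuple(b.get("eigvals", WM_EIGVALS)),
            )
            for b in doc.get("bundles", [])
        )
        lesions = tuple(
            Lesion(
                center=tuple(l["center"]),
                radius=float(l["radius"]),
                eigvals=tuple(l.get("eigvals", (1.2e-3, 0.6e-3, 0.6e-3))),
                core_eigvals=None
                if l.get("core_eigvals") is None
                else tuple(l["core_eigvals"]),
                dispersion_deg=float(l.get("dispersion_deg", 0.0)),
                n_fan=int(l.get("n_fan", 6)),
                crossing_fraction=float(l.get("crossing_fraction", 0.0)),
                crossing_angle_deg=float(l.get("crossing_angle_deg", 70.0)),
            )
            for l in doc.get("lesions", [])
        )
        snr = doc.get("snr")
        return cls(
            grid_shape=tuple(doc["grid_shape"]),
            voxel_size=tuple(doc.get("voxel_size", (2.0, 2.0, 2.0))),
            bundles=bundles,
            lesions=lesions,
            s0=float(doc.get("s0", 1000.0)),
            snr=np.inf if snr is None else float(snr),
            mirror_symmetric=bool(doc.get("mirror_symmetric", True)),
            background_adc=float(doc.get("background_adc", BACKGROUND_ADC)),
            regional_scale_sd=float(doc.get("regional_scale_sd", 0.0)),
            nawm_dispersion_deg=float(doc.get("nawm_dispersion_deg", 0.0)),
            dispersion_sd=float(doc.get("dispersion_sd", 0.0)),
            crossing_sd=float(doc.get("crossing_sd", 0.0)),
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal plus voxel geometry and gradient table."""

    signal: np.ndarray  # (x, y, z, n_volumes), non-negative
    voxel_size: np.ndarray  # (3,), mm
    affine: np.ndarray  # (4, 4)
    gradient_table: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != len(self.gradient_table):
            raise ValueError("4th dimension must match gradient-table length")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def mean_b0(self) -> np.ndarray:
        """Average of the b = 0 volumes (the S0 reference image)."""
        return self.signal[..., self.gradient_table.b0_mask].mean(axis=3)

    # ---- NIfTI round trip ------------------------------------------------
    def save(self, dwi_path: str | Path, bval_path=None, bvec_path=None) -> None:
        dwi_path = Path(dwi_path)
        img = nib.Nifti1Image(self.signal.astype(np.float64), self.affine)
        img.header.set_zooms(tuple(self.voxel_size) + (1.0,))
        nib.save(img, dwi_path)
        stem = str(dwi_path).removesuffix(".gz").removesuffix(".nii")
        self.gradient_table.save_fsl(
            bval_path or stem + ".bval", bvec_path or stem + ".bvec"
        )

    @classmethod
    def load(cls, dwi_path: str | Path, bval_path=None, bvec_path=None) -> "DWIVolume":
        dwi_path = Path(dwi_path)
        img = nib.load(dwi_path)
        stem = str(dwi_path).removesuffix(".gz").removesuffix(".nii")
        gtab = GradientTable.from_fsl(
            bval_path or stem + ".bval", bvec_path or stem + ".bvec"
        )
        data = np.asarray(img.dataobj, dtype=float)
        return cls(
            signal=data,
            voxel_size=np.asarray(img.header.get_zooms()[:3]),
            affine=img.affine,
            gradient_table=gtab,
        )


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), path)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0


def default_phantom(
    lesions: tuple[Lesion, ...] = (),
    snr: float = np.inf,
    grid_shape: tuple[int, int, int] = (40, 40, 16),
    **kwargs,
) -> PhantomSpec:
    """Mirrored two-hemisphere phantom: one x-oriented bundle per hemisphere.

    The bundle pair is symmetric about the mid-sagittal plane between the
    two grid halves, so the exact left-right flip maps each bundle onto its
    contralateral homologue.
    """
    nx, ny, nz = grid_shape
    y0, y1 = int(0.15 * ny), int(0.85 * ny)
    z0, z1 = int(0.2 * nz), int(0.8 * nz)
    left = Bundle(lo=(0, y0, z0), hi=(nx // 2, y1, z1))
    right = Bundle(lo=(nx - nx // 2, y0, z0), hi=(nx, y1, z1))
    return PhantomSpec(
        grid_shape=grid_shape,
        bundles=(left, right),
        lesions=lesions,
        snr=snr,
        **kwargs,
    )


def _lesion_components(les: Lesion, axis: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """(fraction, tensor) mixture for a lesion region.

    With dispersion the mixture is a cone: one component along the bundle
    axis plus ``n_fan`` components tilted by the cone half-angle
    ``dispersion_deg`` at equally spaced azimuths, all with the lesion
    eigenvalues and equal weights.  The cone emulates Watson-like
    orientation dispersion while preserving the mixture's trace.
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    perp = np.cross(a, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(a, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    if les.dispersion_deg <= 0:
        comps = [(1.0, tensor_from(a, les.eigvals))]
    else:
        w = 1.0 / (les.n_fan + 1)
        comps = [(w, tensor_from(a, les.eigvals))]
        for i in range(les.n_fan):
            azimuth = _rodrigues(a, 2.0 * np.pi * i / les.n_fan)
            tilt = _rodrigues(azimuth @ perp, np.radians(les.dispersion_deg))
            comps.append((w, tensor_from(tilt @ a, les.eigvals)))

    f_cross = float(np.clip(les.crossing_fraction, 0.0, 0.9))
    if f_cross > 0:
        cross_axis = _rodrigues(perp, np.radians(les.crossing_angle_deg)) @ a
        comps = [(f * (1 - f_cross), D) for f, D in comps]
        comps.append((f_cross, tensor_from(cross_axis, les.eigvals)))
    return comps


def _attenuation(gtab: GradientTable, mixture: list[tuple[float, np.ndarray]]):
    """Multi-tensor attenuation S/S0 for every volume of the acquisition."""
    att = np.zeros(len(gtab))
    for f, D in mixture:
        expo = np.einsum("ni,ij,nj->n", gtab.bvecs, D, gtab.bvecs)
        att += f * np.exp(-gtab.bvals * expo)
    return att


def _core_mask(lesion_mask: np.ndarray) -> np.ndarray:
    return binary_erosion(lesion_mask, structure=np.ones((3, 3, 3), bool))


def simulate_dwi(
    spec: PhantomSpec, gtab: GradientTable, seed: int = 0
) -> tuple[DWIVolume, dict]:
    """Render the phantom into a DWI volume plus ground-truth masks.

    Returns
    -------
    dwi : DWIVolume
    truth : dict
        ``wm_mask`` (bundles), ``lesion_label_volume`` (1..K, descending
        size), ``core_truth`` and ``shell_truth`` (unions over eligible
        lesions), and ``lesion_masks`` (per-lesion boolean masks in label
        order).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    n_vol = len(gtab)

    # region-wise noiseless attenuation, later multiplied by S0
    att_vol = np.empty(shape + (n_vol,), dtype=float)
    bg = [(1.0, np.diag([spec.background_adc] * 3))]
    att_vol[:] = _attenuation(gtab, bg)

    for b in spec.bundles:
        m = b.mask(shape)
        att_vol[m] = _attenuation(gtab, [(1.0, tensor_from(b.orientation, b.eigvals))])

    # Regional biological variability: each lesion region and, independently,
    # its mirrored contralateral region draw one eigenvalue-scale factor and
    # one dispersion half-angle (core and shell of a lesion share both, so
    # intra-lesion contrast stays the designed eigenvalue difference).
    def _scale() -> float:
        if spec.regional_scale_sd <= 0:
            return 1.0
        return float(max(0.1, rng.normal(1.0, spec.regional_scale_sd)))

    def _disp(mean_deg: float) -> float:
        if spec.dispersion_sd <= 0:
            return mean_deg
        return float(max(0.0, rng.normal(mean_deg, spec.dispersion_sd)))

    regional = (
        spec.regional_scale_sd > 0
        or spec.nawm_dispersion_deg > 0
        or spec.dispersion_sd > 0
    )
    wm_mask = spec.wm_mask()
    lesion_masks_raw = []
    for les in spec.lesions:
        m = les.mask(shape)
        lesion_masks_raw.append(m)
        bundle = _bundle_at(spec, les.center)
        axis = np.asarray(bundle.orientation, dtype=float)
        s = _scale()
        d_deg = _disp(les.dispersion_deg)
        f_cross = les.crossing_fraction
        if spec.crossing_sd > 0:
            f_cross = float(max(0.0, rng.normal(f_cross, spec.crossing_sd)))
        les_drawn = replace(les, dispersion_deg=d_deg, crossing_fraction=f_cross)
        comps = [(f, s * D) for f, D in _lesion_components(les_drawn, axis)]
        att_vol[m] = _attenuation(gtab, comps)
        if les.core_eigvals is not None:
            core = _core_mask(m)
            if core.any():
                core_drawn = replace(les_drawn, eigvals=les.core_eigvals)
                core_comps = [
                    (f, s * D) for f, D in _lesion_components(core_drawn, axis)
                ]
                att_vol[core] = _attenuation(gtab, core_comps)
        # contralateral region: same bundle tissue with its own regional draws
        if regional:
            bundle_m = wm_mask & m[::-1]
            if bundle_m.any():
                b2 = _bundle_at(spec, _flip_center(les.center, shape[0]))
                nawm = Lesion(
                    center=_flip_center(les.center, shape[0]),
                    radius=les.radius,
                    eigvals=b2.eigvals,
                    dispersion_deg=_disp(spec.nawm_dispersion_deg),
                    n_fan=les.n_fan,
                )
                s2 = _scale()
                comps2 = [
                    (f, s2 * D)
                    for f, D in _lesion_components(
                        nawm, np.asarray(b2.orientation, dtype=float)
                    )
                ]
                att_vol[bundle_m] = _attenuation(gtab, comps2)

    signal = spec.s0 * att_vol

    if np.isfinite(spec.snr):
        sigma = spec.s0 / spec.snr
        n1 = rng.standard_normal(signal.shape)
        n2 = rng.standard_normal(signal.shape)
        signal = np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)

    dwi = DWIVolume(
        signal=signal,
        voxel_size=np.asarray(spec.voxel_size),
        affine=spec.affine,
        gradient_table=gtab,
    )

    # label lesions by descending size (ties: minimal (z, y, x)) to match
    # the ROI module's ordering convention
    order = sorted(
        range(len(lesion_masks_raw)),
        key=lambda i: (-int(lesion_masks_raw[i].sum()), _min_zyx(lesion_masks_raw[i])),
    )
    labels = np.zeros(shape, dtype=np.int32)
    lesion_masks = []
    for new_id, i in enumerate(order, start=1):
        labels[lesion_masks_raw[i]] = new_id
        lesion_masks.append(lesion_masks_raw[i])

    core_truth = np.zeros(shape, dtype=bool)
    shell_truth = np.zeros(shape, dtype=bool)
    for m in lesion_masks:
        core = _core_mask(m)
        if core.any():
            core_truth |= core
            shell_truth |= m & ~core

    truth = {
        "wm_mask": spec.wm_mask(),
        "lesion_label_volume": labels,
        "lesion_masks": lesion_masks,
        "core_truth": core_truth,
        "shell_truth": shell_truth,
    }
    return dwi, truth


def _min_zyx(mask: np.ndarray) -> tuple[int, int, int]:
    x, y, z = np.nonzero(mask)
    order = np.lexsort((x, y, z))
    i = order[0]
    return (int(z[i]), int(y[i]), int(x[i]))


def _flip_center(center, nx: int):
    c = np.asarray(center, dtype=float)
    return (nx - 1 - c[0], c[1], c[2])


def _bundle_at(spec: PhantomSpec, center) -> Bundle:
    c = np.asarray(center, dtype=float)
    for b in spec.bundles:
        if all(b.lo[i] <= c[i] < b.hi[i] for i in range(3)):
            return b
    raise ValueError(f"no bundle contains point {tuple(center)}")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Multi-subject cohort with high- and low-lesion-count groups.

    Group lesion-count supports must be disjoint, emulating a stratification
    that keeps only subjects clearly above / below the cohort percentiles.
    Lesions are placed in the left-hemisphere bundle only, so the exact
    left-right flip always lands in lesion-free contralateral tissue.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"high": 4, "low": 4}
    )
    count_range: dict = field(
        default_factory=lambda: {"high": (5, 6), "low": (2, 3)}
    )
    base: PhantomSpec = field(
        default_factory=lambda: default_phantom(grid_shape=(40, 40, 20))
    )
    lesion_template: Lesion = field(
        default_factory=lambda: Lesion(center=(0, 0, 0), radius=2.6)
    )
    radius_range: tuple[float, float] = (2.0, 2.8)
    # per-group multiplicative effect on lesion eigenvalues (between-subject
    # contrast); identity by default
    group_eigval_scale: dict = field(
        default_factory=lambda: {"high": 1.0, "low": 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"empty group {g!r}")
        los = {g: r[0] for g, r in self.count_range.items()}
        his = {g: r[1] for g, r in self.count_range.items()}
        if "high" in los and "low" in his and los["high"] <= his["low"]:
            pass  # disjoint iff low max < high min
        if (
            "high" in self.count_range
            and "low" in self.count_range
            and self.count_range["low"][1] >= self.count_range["high"][0]
        ):
            raise ValueError("group lesion-count supports must be disjoint")


@dataclass
class Subject:
    subject_id: str
    group: str
    lesion_count: int
    dwi: DWIVolume
    truth: dict


def _place_lesions(
    cohort: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[Lesion, ...]:
    """Seeded rejection sampling of non-overlapping lesion spheres in the
    left-hemisphere bundle."""
    spec = cohort.base
    nx = spec.grid_shape[0]
    left_bundles = [b for b in spec.bundles if b.hi[0] <= nx // 2 + 1]
    if not left_bundles:
        raise ValueError("cohort base phantom has no left-hemisphere bundle")
    lesions: list[Lesion] = []
    tries = 0
    while len(lesions) < n:
        tries += 1
        if tries > 5000:
            raise RuntimeError("could not place requested lesion count")
        b = left_bundles[rng.integers(len(left_bundles))]
        r = float(rng.uniform(*cohort.radius_range))
        lo = np.asarray(b.lo) + r + 0.6
        hi = np.asarray(b.hi) - r - 0.6
        if np.any(hi <= lo):
            continue
        c = rng.uniform(lo, hi)
        if any(
            np.linalg.norm(c - np.asarray(l2.center)) < r + l2.radius + 1.5
            for l2 in lesions
        ):
            continue
        lesions.append(replace(cohort.lesion_template, center=tuple(c), radius=r))
    return tuple(lesions)


def orientation_contrast_cohort(
    seed: int = 0,
    n_per_group: dict | None = None,
    snr: float = 40.0,
) -> CohortSpec:
    """Cohort whose lesions differ from NAWM chiefly in orientation structure.

    Normal-appearing white matter carries a baseline orientation dispersion
    (cone half-angle 26 deg, sd 8 deg across regions) and regional
    diffusivity variability (15% sd).  Lesions add three orientational
    abnormalities: stronger dispersion (40 deg), a partial crossing
    population (fraction 0.22 +/- 0.12 at 50 deg), and a modest reduction
    of the fiber components' anisotropy; the mixture trace stays within the
    regional variability, so diffusivity-based features carry little class
    signal relative to their nuisance spread.
    """
    base = default_phantom(
        grid_shape=(40, 40, 20),
        snr=snr,
        regional_scale_sd=0.15,
        nawm_dispersion_deg=26.0,
        dispersion_sd=8.0,
        crossing_sd=0.12,
    )
    tmpl = Lesion(
        center=(0, 0, 0),
        radius=2.6,
        eigvals=(1.5e-3, 0.4e-3, 0.4e-3),
        dispersion_deg=40.0,
        crossing_fraction=0.22,
        crossing_angle_deg=50.0,
    )
    return CohortSpec(
        n_per_group=n_per_group or {"high": 4, "low": 4},
        count_range={"high": (5, 6), "low": (3, 4)},
        base=base,
        lesion_template=tmpl,
        radius_range=(2.0, 2.8),
        seed=seed,
    )


def diffusivity_contrast_cohort(
    seed: int = 0,
    n_per_group: dict | None = None,
    snr: float = 40.0,
) -> CohortSpec:
    """Cohort whose lesion cores differ from shells chiefly in diffusivity.

    Lesions are large enough for the erosion core/shell split and carry a
    demyelination-like diffusivity gradient: elevated diffusivity overall
    with a further radial-weighted elevation in the core (hypocellular
    center), while orientation structure (baseline dispersion) is common to
    core and shell.
    """
    base = default_phantom(
        grid_shape=(40, 40, 20),
        snr=snr,
        regional_scale_sd=0.08,
        nawm_dispersion_deg=18.0,
        dispersion_sd=8.0,
    )
    tmpl = Lesion(
        center=(0, 0, 0),
        radius=3.4,
        eigvals=(1.6e-3, 0.45e-3, 0.45e-3),
        core_eigvals=(2.1e-3, 0.8e-3, 0.8e-3),
        dispersion_deg=18.0,
    )
    return CohortSpec(
        n_per_group=n_per_group or {"high": 3, "low": 3},
        count_range={"high": (4, 5), "low": (2, 3)},
        base=base,
        lesion_template=tmpl,
        radius_range=(3.0, 3.8),
        seed=seed,
    )


def simulate_cohort(cohort: CohortSpec) -> list[Subject]:
    """Simulate every subject of the cohort; deterministic for fixed seed."""
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    gtab = make_gradient_table(seed=cohort.seed)
    subjects: list[Subject] = []
    sid = 0
    for group in sorted(cohort.n_per_group):
        lo, hi = cohort.count_range[group]
        scale = cohort.group_eigval_scale.get(group, 1.0)
        for _ in range(cohort.n_per_group[group]):
            sid += 1
            n_lesions = int(rng.integers(lo, hi + 1))
            lesions = _place_lesions(cohort, n_lesions, rng)
            if scale != 1.0:
                lesions = tuple(
                    replace(
                        les,
                        eigvals=tuple(np.asarray(les.eigvals) * scale),
                        core_eigvals=None
                        if les.core_eigvals is None
                        else tuple(np.asarray(les.core_eigvals) * scale),
                    )
                    for les in lesions
                )
            spec = replace(cohort.base, lesions=lesions)
            subj_seed = int(rng.integers(2**31 - 1))
            dwi, truth = simulate_dwi(spec, gtab, seed=subj_seed)
            subjects.append(
                Subject(
                    subject_id=f"sub-{sid:03d}",
                    group=group,
                    lesion_count=n_lesions,
                    dwi=dwi,
                    truth=truth,
                )
            )
    return subjects
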