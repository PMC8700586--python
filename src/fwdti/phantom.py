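"""Synthetic multi-shell DWI phantom of a tumor-bearing brain slab.

The phantom plants a three-region lesion (necrotic core inside an enhancing
rim inside the total lesion) in an anisotropic background slab. Every voxel
carries a ground-truth free-water fraction f, drawn per region from a
truncated normal, and a ground-truth tissue tensor constructed exactly from
the region's target FA/MD. Signals follow the two-compartment model

    S_k = S0 * [ f * exp(-b_k * D_fw) + (1 - f) * exp(-b_k * g_k^T D g_k) ]

with the free-water diffusivity fixed at 3.0e-3 mm^2/s, optionally corrupted
by Rician noise. Two internal controls are always present: a pure-tissue
stripe (f = 0) and a pure-water block (f = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage, stats

from .dti import design_matrix, matrix_to_tensor6
from .gradients_io import DWIVolume, GradientScheme, default_scheme
from .roi_stats import ROIMaskSet

#: Diffusivity of free water at body temperature, mm^2/s.
D_FW = 3.0e-3

LABEL_BACKGROUND = 0
LABEL_NON_ENHANCING = 1
LABEL_ENHANCING = 2
LABEL_NECROTIC = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_NON_ENHANCING: "non_enhancing",
    LABEL_ENHANCING: "enhancing",
    LABEL_NECROTIC: "necrotic",
}


class PhantomValidationError(ValueError):
    """Phantom specification violates a construction constraint."""


@dataclass(frozen=True)
class RegionParams:
    """Tissue and free-water parameters of one phantom region.

    fa/md define the (constant) ground-truth tissue tensor; direction is its
    principal axis; f is drawn per voxel from N(f_mean, f_sd) truncated to
    [0, 1].
    """

    fa: float
    md: float
    direction: Tuple[float, float, float]
    f_mean: float
    f_sd: float


def _default_regions() -> Dict[str, RegionParams]:
    # Region means follow the study conditions the phantom emulates:
    # high free-water content with large spread in the necrotic core,
    # moderate in the rest of the lesion, low in normal-appearing tissue;
    # near-isotropic necrotic tissue, mildly anisotropic lesion tissue,
    # strongly anisotropic background white matter (MD 0.8e-3 mm^2/s).
    return {
        "background": RegionParams(0.70, 0.8e-3, (1.0, 0.0, 0.0), 0.05, 0.03),
        "non_enhancing": RegionParams(0.30, 0.9e-3, (0.0, 1.0, 0.0), 0.30, 0.10),
        "enhancing": RegionParams(0.27, 1.0e-3, (0.0, 0.0, 1.0), 0.30, 0.10),
        "necrotic": RegionParams(0.13, 1.2e-3, (1.0, 1.0, 0.0), 0.50, 0.15),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and acquisition of the synthetic subject.

    Three nested ellipsoids (radii in voxels, shared center) carve the lesion
    out of an elliptical brain slab; ``snr`` is S0/sigma of the Rician noise
    (``inf`` = noiseless). ``smooth_sigma_vox`` > 0 imposes spatial
    correlation on the f field (off by default: within-region f is
    independent across voxels).
    """

    grid_shape: Tuple[int, int, int] = (48, 48, 12)
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_center: Tuple[float, float, float] = (17.0, 29.0, 6.0)
    radii_total: Tuple[float, float, float] = (10.0, 9.0, 4.5)
    radii_enhancing: Tuple[float, float, float] = (6.5, 6.0, 3.0)
    radii_necrotic: Tuple[float, float, float] = (3.5, 3.0, 2.0)
    regions: Dict[str, RegionParams] = field(default_factory=_default_regions)
    with_necrotic_core: bool = True
    s0: float = 1000.0
    snr: float = 30.0
    seed: int = 0
    smooth_sigma_vox: float = 0.0
    include_controls: bool = True

    def __post_init__(self) -> None:
        for a, b in (
            (self.radii_necrotic, self.radii_enhancing),
            (self.radii_enhancing, self.radii_total),
        ):
            if not all(x < y for x, y in zip(a, b)):
                raise PhantomValidationError(
                    "region ellipsoids must be strictly nested (necrotic < enhancing < total)"
                )
        for name, rp in self.regions.items():
            if not 0.0 <= rp.fa < 1.0:
                raise PhantomValidationError(f"{name}: FA must be in [0, 1)")
            if not 0.0 < rp.md <= 3.0e-3:
                raise PhantomValidationError(f"{name}: MD must be in (0, 3.0e-3]")
        if self.snr <= 0:
            raise PhantomValidationError("snr must be positive (use inf for noiseless)")


@dataclass
class GroundTruth:
    """Planted truth of one phantom: per-voxel FW fraction, tissue tensor
    (6-component, mm^2/s) and region label code."""

    f_true: np.ndarray
    tensor_true: np.ndarray
    labels: np.ndarray

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def tensor_from_fa_md(fa: float, md: float, direction) -> np.ndarray:
    """Prolate (axially symmetric) tensor with exact FA, MD and principal axis.

    For eigenvalues (md(1+2d), md(1-d), md(1-d)) the FA relation inverts in
    closed form: d = fa / sqrt(3 - 2 fa^2). Returns a 3x3 positive-definite
    matrix (mm^2/s).
    """
    if not 0.0 <= fa < 1.0:
        raise PhantomValidationError("fa must be in [0, 1) for a prolate tensor")
    if md <= 0:
        raise PhantomValidationError("md must be positive")
    v = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise PhantomValidationError("direction must be a nonzero vector")
    v = v / norm
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam_par = md * (1.0 + 2.0 * delta)
    lam_perp = md * (1.0 - delta)
    outer = np.outer(v, v)
    return lam_par * outer + lam_perp * (np.eye(3) - outer)


def predict_signal(f, tensor, s0, scheme: GradientScheme) -> np.ndarray:
    """Two-compartment signal for one voxel (or a broadcastable stack).

    ``tensor`` may be a (..., 3, 3) matrix or (..., 6) component vector.
    Returns shape (..., K).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise PhantomValidationError("f must lie in [0, 1]")
    t = np.asarray(tensor, dtype=float)
    d6 = matrix_to_tensor6(t) if t.shape[-2:] == (3, 3) else t
    design = design_matrix(scheme.bvals, scheme.bvecs)  # (K, 6)
    bq = d6 @ design.T  # (..., K)
    a_water = np.exp(-scheme.bvals * D_FW)
    a_tissue = np.exp(-bq)
    return np.asarray(s0) * (f[..., None] * a_water + (1.0 - f[..., None]) * a_tissue)


def add_rician_noise(signals: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |signal + complex Gaussian|, std sigma per channel."""
    if sigma < 0:
        raise PhantomValidationError("sigma must be >= 0")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    e1 = rng.normal(0.0, sigma, size=signals.shape)
    e2 = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2**2)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _brain_mask(shape) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    radii = [max(n / 2.0 - 1.0, 1.0) for n in shape[:2]] + [shape[2]]
    return _ellipsoid_mask(shape, center, radii)


def _control_masks(shape, brain: np.ndarray, lesion: np.ndarray):
    """Pure-tissue stripe (f=0) and pure-water block (f=1), inside the brain
    and clear of the lesion."""
    nx, ny, nz = shape
    stripe = np.zeros(shape, dtype=bool)
    stripe[max(nx // 12, 2) : max(nx // 12, 2) + max(nx // 16, 1),
           ny // 3 : 2 * ny // 3, nz // 4 : max(3 * nz // 4, nz // 4 + 1)] = True
    block = np.zeros(shape, dtype=bool)
    block[5 * nx // 6 : 5 * nx // 6 + max(nx // 12, 1),
          2 * ny // 5 : 3 * ny // 5, nz // 3 : max(2 * nz // 3, nz // 3 + 1)] = True
    return stripe & brain & ~lesion, block & brain & ~lesion


def _sample_f(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_phantom(
    spec: PhantomSpec, scheme: Optional[GradientScheme] = None
):
    """Build one synthetic subject.

    Returns ``(dwi, scheme, masks, truth)``: the noisy 4D volume (brain mask
    attached), the acquisition scheme (default: 1 b=0 + 8 directions at each
    of b = 90, 150, 500, 1000 s/mm^2 -> 33 volumes), the ROI mask set in the
    radiological convention (total contains enhancing and necrotic), and the
    planted ground truth.
    """
    if scheme is None:
        scheme = default_scheme()
    shape = tuple(spec.grid_shape)
    rng = np.random.default_rng(spec.seed)

    brain = _brain_mask(shape)
    total = _ellipsoid_mask(shape, spec.lesion_center, spec.radii_total) & brain
    enhancing_outer = _ellipsoid_mask(shape, spec.lesion_center, spec.radii_enhancing) & brain
    necrotic = (
        _ellipsoid_mask(shape, spec.lesion_center, spec.radii_necrotic) & brain
        if spec.with_necrotic_core
        else np.zeros(shape, dtype=bool)
    )
    if not (necrotic <= enhancing_outer).all() or not (enhancing_outer <= total).all():
        raise PhantomValidationError("lesion ellipsoids do not nest on the voxel grid")
    enhancing = enhancing_outer & ~necrotic
    non_enhancing = total & ~enhancing_outer

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int16)
    labels[non_enhancing] = LABEL_NON_ENHANCING
    labels[enhancing] = LABEL_ENHANCING
    labels[necrotic] = LABEL_NECROTIC

    f_true = np.zeros(shape)
    tensor_true = np.zeros(shape + (6,))
    region_masks = {
        "background": brain & (labels == LABEL_BACKGROUND),
        "non_enhancing": non_enhancing,
        "enhancing": enhancing,
        "necrotic": necrotic,
    }
    if spec.smooth_sigma_vox > 0:
        z = rng.standard_normal(shape)
        z = ndimage.gaussian_filter(z, spec.smooth_sigma_vox)
        z /= max(z[brain].std(), 1e-12)
    else:
        z = None
    for name, m in region_masks.items():
        if not m.any():
            continue
        rp = spec.regions[name]
        if z is None:
            f_true[m] = _sample_f(rng, rp.f_mean, rp.f_sd, int(m.sum()))
        else:
            f_true[m] = np.clip(rp.f_mean + rp.f_sd * z[m], 0.0, 1.0)
        tensor_true[m] = matrix_to_tensor6(
            tensor_from_fa_md(rp.fa, rp.md, rp.direction)
        )

    if spec.include_controls:
        stripe, block = _control_masks(shape, brain, total)
        f_true[stripe] = 0.0
        f_true[block] = 1.0

    # Forward signals, vectorized over brain voxels.
    signals = np.zeros(shape + (len(scheme),))
    signals[brain] = predict_signal(f_true[brain], tensor_true[brain], spec.s0, scheme)

    if np.isfinite(spec.snr):
        sigma = spec.s0 / spec.snr
        signals = np.where(
            brain[..., None], add_rician_noise(signals, sigma, rng), signals
        )

    affine = np.diag(list(spec.voxel_size) + [1.0])
    dwi = DWIVolume(data=signals, affine=affine, mask=brain)
    masks = ROIMaskSet(total=total, enhancing=enhancing, necrotic=necrotic, brain=brain)
    truth = GroundTruth(f_true=f_true, tensor_true=tensor_true, labels=labels)
    return dwi, scheme, masks, truth


def low_grade_spec(spec: PhantomSpec) -> PhantomSpec:
    """Variant without a necrotic core (low-grade lesion profile)."""
    return replace(spec, with_necrotic_core=False)
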