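"""Single-shell diffusion-tensor fitting and tensor-derived scalar maps.

This is the conventional (non-corrected) baseline: an ordinary least-squares
log-linear tensor fit on one shell, eigen-decomposition, and the standard
fractional-anisotropy (FA) / mean-diffusivity (MD) definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gradients_io import DWIVolume, GradientScheme

#: Order of the 6 unique tensor components in flattened representations.
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


class RankDeficiencyError(ValueError):
    """Too few distinct gradient directions for a tensor fit."""


@dataclass(frozen=True)
class TensorEigen:
    """Sorted eigen-decomposition of a diffusion tensor.

    ``eigenvalues`` are descending (mm^2/s); ``eigenvectors`` columns are the
    corresponding orthonormal axes.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class ScalarMap:
    """A 3D scalar map (FA/FAt/FW unitless in [0,1]; MD in mm^2/s) with NaN
    outside the fitted mask."""

    values: np.ndarray
    map_kind: str
    affine: Optional[np.ndarray] = None

    VALID_KINDS = ("FA", "FAt", "FW", "MD")

    def __post_init__(self) -> None:
        if self.map_kind not in self.VALID_KINDS:
            raise ValueError(f"map_kind must be one of {self.VALID_KINDS}")
        self.values = np.asarray(self.values, dtype=float)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b_k * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] so that
    ``design @ d6`` gives b * g^T D g for the 6-component tensor ``d6``."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    quad = np.stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
    )
    return bvals[:, None] * quad


def tensor6_to_matrix(d6: np.ndarray) -> np.ndarray:
    """(..., 6) component vector -> (..., 3, 3) symmetric matrix."""
    d6 = np.asarray(d6, dtype=float)
    out = np.zeros(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def matrix_to_tensor6(t: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrix -> (..., 6) component vector."""
    t = np.asarray(t, dtype=float)
    return np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
        axis=-1,
    )


def _distinct_direction_count(bvecs: np.ndarray) -> int:
    """Directions distinct up to sign (the tensor model is antipodally even)."""
    seen: list[np.ndarray] = []
    for g in bvecs:
        if not any(
            np.allclose(g, h, atol=1e-6) or np.allclose(g, -h, atol=1e-6) for h in seen
        ):
            seen.append(g)
    return len(seen)


def fit_dti(
    dwi: DWIVolume,
    scheme: GradientScheme,
    shell: float = 1000.0,
    mask: Optional[np.ndarray] = None,
):
    """Ordinary least-squares single-shell tensor fit.

    Solves ln(S_k / S0) = -b_k g_k^T D g_k per voxel over the chosen shell,
    with S0 the arithmetic mean of the b=0 volumes. Voxels with any
    non-positive signal among the used volumes are excluded from the fitted
    mask (log undefined).

    Returns
    -------
    tensors : (X, Y, Z, 6) array of tensor components (mm^2/s)
    s0 : (X, Y, Z) baseline signal
    fit_mask : (X, Y, Z) bool, voxels actually fitted
    """
    sel = scheme.shell_mask(shell)
    bvecs = scheme.bvecs[sel]
    n_dir = _distinct_direction_count(bvecs)
    if n_dir < 6:
        raise RankDeficiencyError(
            f"{n_dir} distinct directions at b={shell}; >=6 required"
        )
    if not np.any(scheme.b0_mask):
        raise RankDeficiencyError("scheme has no b=0 volume")

    s0 = dwi.data[..., scheme.b0_mask].mean(axis=-1)
    signals = dwi.data[..., sel]

    fit_mask = (s0 > 0) & np.all(signals > 0, axis=-1)
    if mask is not None:
        fit_mask &= np.asarray(mask, dtype=bool)
    if dwi.mask is not None:
        fit_mask &= dwi.mask

    design = design_matrix(scheme.bvals[sel], bvecs)
    y = -np.log(signals[fit_mask] / s0[fit_mask, None])  # (n, K)
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # (6, n)

    tensors = np.zeros(dwi.shape[:3] + (6,), dtype=float)
    tensors[fit_mask] = coef.T
    return tensors, s0, fit_mask


def eig_decompose(tensor: np.ndarray) -> TensorEigen:
    """Sorted (descending) eigen-decomposition of a symmetric 3x3 tensor.

    Negative eigenvalues are retained; consumers clip where they must.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if np.max(np.abs(t - t.T)) > 1e-8:
        raise ValueError("tensor is not symmetric within 1e-8")
    w, v = np.linalg.eigh(t)
    order = np.argsort(w)[::-1]
    return TensorEigen(eigenvalues=w[order], eigenvectors=v[:, order])


def fa_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, clipped to [0, 1].

    Defined as 0 for an all-zero eigenvalue triple. Works on (..., 3) stacks.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


def md_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Mean diffusivity: the average of the three eigenvalues."""
    return np.asarray(eigenvalues, dtype=float).mean(axis=-1)


def eigenvalues_field(tensors6: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of a (..., 6) tensor-component field."""
    w = np.linalg.eigvalsh(tensor6_to_matrix(tensors6))
    return w[..., ::-1]


def fa_map(tensors6: np.ndarray, fit_mask: np.ndarray, map_kind: str = "FA",
           affine: Optional[np.ndarray] = None) -> ScalarMap:
    """FA ScalarMap from a tensor-component field; NaN outside ``fit_mask``."""
    values = np.full(tensors6.shape[:-1], np.nan)
    lam = eigenvalues_field(tensors6[fit_mask])
    values[fit_mask] = fa_from_eigenvalues(lam)
    return ScalarMap(values=values, map_kind=map_kind, affine=affine)


def md_map(tensors6: np.ndarray, fit_mask: np.ndarray,
           affine: Optional[np.ndarray] = None) -> ScalarMap:
    values = np.full(tensors6.shape[:-1], np.nan)
    values[fit_mask] = tensors6[fit_mask][:, :3].mean(axis=-1)
    return ScalarMap(values=values, map_kind="MD", affine=affine)
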