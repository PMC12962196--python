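"""Diffusion tensor estimation and scalar metrics.

The forward model is the mono-exponential single-tensor signal
``S = S0 * exp(-b g^T D g)`` with diffusivities in um^2/ms and b in s/mm^2
(so the exponent is dimensionless: 1 um^2/ms = 1e-3 mm^2/s).  Fitting is
log-linear least squares, optionally re-weighted by the squared predicted
signal (WLS), the standard variance model for log-transformed Rician
magnitude data at moderate SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import ImageStack
from .protocols import DwiProtocol, ProtocolError

B_SCALE = 1e-3  # (s/mm^2) * (um^2/ms) -> dimensionless exponent


def _design_matrix(protocol: DwiProtocol) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    b = protocol.b_values * B_SCALE
    g = protocol.gradient_directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def _tensor_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coeffs, -1, 0)
    out = np.empty(coeffs.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def tensor_from_eigensystem(eigvals, principal_axis) -> np.ndarray:
    """Build a symmetric tensor with eigenvalues ``eigvals`` (descending)
    and principal eigenvector ``principal_axis``; the two minor axes span
    the orthogonal complement (axially symmetric if lam2 == lam3)."""
    lam = np.asarray(eigvals, dtype=float)
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.column_stack([e1, e2, e3])
    return basis @ np.diag(lam) @ basis.T


def predict_dwi_signal(tensor: np.ndarray, s0: float | np.ndarray,
                       protocol: DwiProtocol) -> np.ndarray:
    """Noiseless DWI signal for each protocol volume.

    ``tensor`` is a (..., 3, 3) symmetric tensor in um^2/ms; the result has
    shape (..., n_volumes), with b=0 entries equal to ``s0`` exactly.
    """
    tensor = np.asarray(tensor, dtype=float)
    g = protocol.gradient_directions
    quad = np.einsum("vi,...ij,vj->...v", g, tensor, g)
    expo = -protocol.b_values * B_SCALE * quad
    return np.asarray(s0)[..., None] * np.exp(expo)


@dataclass
class TensorFit:
    """Voxelwise tensor fit: tensors, S0, eigensystem and QC masks."""

    tensor: np.ndarray          # (..., 3, 3), um^2/ms
    s0: np.ndarray              # (...,)
    eigenvalues: np.ndarray     # (..., 3), descending
    eigenvectors: np.ndarray    # (..., 3, 3), columns match eigenvalues
    mask: np.ndarray            # (...,) bool: voxels actually fitted
    negative_eig_mask: np.ndarray  # (...,) bool: any eigenvalue < 0 (flag, not repair)


def fit_tensor(stack: ImageStack | np.ndarray, protocol: DwiProtocol,
               method: str = "weighted", mask: np.ndarray | None = None) -> TensorFit:
    """Estimate the diffusion tensor per voxel.

    ``method`` is ``"loglinear"`` (OLS on log-signal) or ``"weighted"``
    (one-step WLS with weights equal to the squared predicted signal from
    the OLS pass).  Voxels with any nonpositive signal are excluded from
    the fit and reported through the returned mask.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if data.shape[-1] != protocol.n_volumes:
        raise ProtocolError(
            f"stack has {data.shape[-1]} volumes but protocol expects {protocol.n_volumes}"
        )
    if method not in ("loglinear", "weighted"):
        raise ValueError(f"unknown method {method!r}")

    design = _design_matrix(protocol)
    if np.linalg.matrix_rank(design) < 7:
        raise ProtocolError("rank-deficient design: fewer than 6 independent directions")

    spatial = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    fit_mask = np.all(flat > 0, axis=1)
    if mask is not None:
        fit_mask &= np.asarray(mask, bool).reshape(-1)

    coeffs = np.zeros((flat.shape[0], 7))
    if fit_mask.any():
        logs = np.log(flat[fit_mask])
        sol, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
        if method == "weighted":
            pred = design @ sol  # predicted log-signal
            w = np.exp(pred)     # weight sqrt = predicted signal
            sol = np.stack([
                np.linalg.lstsq(design * w[:, i:i + 1], logs[i] * w[:, i], rcond=None)[0]
                for i in range(sol.shape[1])
            ], axis=1)
        coeffs[fit_mask] = sol.T

    tensors = _tensor_from_coeffs(coeffs[:, 1:])
    s0 = np.exp(coeffs[:, 0]) * fit_mask
    eigvals, eigvecs = np.linalg.eigh(tensors)
    order = np.argsort(eigvals, axis=-1)[..., ::-1]
    eigvals = np.take_along_axis(eigvals, order, axis=-1)
    eigvecs = np.take_along_axis(eigvecs, order[..., None, :], axis=-1)
    neg = (eigvals < 0).any(axis=-1) & fit_mask

    return TensorFit(
        tensor=tensors.reshape(spatial + (3, 3)),
        s0=s0.reshape(spatial),
        eigenvalues=eigvals.reshape(spatial + (3,)),
        eigenvectors=eigvecs.reshape(spatial + (3, 3)),
        mask=fit_mask.reshape(spatial),
        negative_eig_mask=neg.reshape(spatial),
    )


def tensor_metrics(eigenvalues: np.ndarray) -> dict[str, np.ndarray]:
    """FA / AD / RD from sorted eigenvalues (lam1 >= lam2 >= lam3).

    FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, defined as 0 (and
    flagged via ``degenerate``) for all-zero tensors.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    degenerate = den == 0
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num),
                                  where=~degenerate)
    return {
        "FA": fa,
        "AD": lam[..., 0],
        "RD": 0.5 * (lam[..., 1] + lam[..., 2]),
        "degenerate": degenerate,
    }
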