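"""Per-voxel symmetric 3x3 tensor fields and their eigen-systems.

Used for Hessians (vesselness), structure tensors and diffusion tensors.
Tensors are stored as a ``(..., 3, 3)`` float32 array; eigen-decompositions
are done in float64.

Eigenvalues are computed with the closed-form trigonometric (Cardano) solver
for symmetric 3x3 matrices, which vectorizes over whole volumes; eigenvectors,
when needed, come from the batched LAPACK path (``numpy.linalg.eigh``).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["TensorField3D", "eigvals_sym3x3", "eigh_sym3x3"]


@dataclasses.dataclass
class TensorField3D:
    """Symmetric 3x3 tensor per voxel, shape ``spatial + (3, 3)``."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor)
        if t.ndim < 2 or t.shape[-2:] != (3, 3):
            raise ValueError(f"expected (..., 3, 3) array, got {t.shape}")
        self.tensor = t

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.tensor.shape[:-2]

    def check_symmetric(self, tol: float = 1e-6) -> None:
        dev = np.abs(self.tensor - np.swapaxes(self.tensor, -1, -2)).max()
        if dev > tol:
            raise ValueError(f"tensor field not symmetric (max asymmetry {dev:.3g})")


def eigvals_sym3x3(m: np.ndarray, check_symmetry: bool = True) -> np.ndarray:
    """Eigenvalues of symmetric 3x3 matrices, ascending, shape ``(..., 3)``.

    Closed-form trigonometric solution (numerically safe clamping of the
    acos argument). Input may be any ``(..., 3, 3)`` stack.
    """
    m = np.asarray(m, dtype=np.float64)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3), got {m.shape}")
    if check_symmetry:
        dev = np.abs(m - np.swapaxes(m, -1, -2)).max()
        if dev > 1e-6 * max(1.0, np.abs(m).max()):
            raise ValueError(f"matrix not symmetric (max asymmetry {dev:.3g})")

    a00, a11, a22 = m[..., 0, 0], m[..., 1, 1], m[..., 2, 2]
    a01, a02, a12 = m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]

    q = (a00 + a11 + a22) / 3.0
    b00, b11, b22 = a00 - q, a11 - q, a22 - q
    p2 = b00**2 + b11**2 + b22**2 + 2.0 * (a01**2 + a02**2 + a12**2)
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)

    # det((A - qI)/p) / 2, guarding p == 0 (isotropic tensors)
    safe_p = np.where(p > 0, p, 1.0)
    c00, c11, c22 = b00 / safe_p, b11 / safe_p, b22 / safe_p
    c01, c02, c12 = a01 / safe_p, a02 / safe_p, a12 / safe_p
    detb = (
        c00 * (c11 * c22 - c12**2)
        - c01 * (c01 * c22 - c12 * c02)
        + c02 * (c01 * c12 - c11 * c02)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0

    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    out = np.stack([e3, e2, e1], axis=-1)  # ascending
    return np.where(p[..., None] > 0, out, np.broadcast_to(q[..., None], out.shape))


def eigh_sym3x3(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigen-decomposition: ``(eigvals ascending (...,3), eigvecs (...,3,3))``
    with eigenvector ``[..., :, i]`` belonging to eigenvalue ``i``."""
    m = np.asarray(m, dtype=np.float64)
    w, v = np.linalg.eigh(m)
    return w, v
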