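"""Shear-free affine transforms (translation + rotation + per-axis scale).

The transform maps physical points (mm, package LPS convention) as

    T(x) = center + R @ diag(scale) @ (x - center) + translation

so ``center`` is the rotation/scale centre. By construction there is no
shear term. The class is exactly closed under composition and inversion for
isotropic scale; for anisotropic scale the result is re-decomposed via a
polar decomposition and a small residual is tolerated (the pipeline uses
isotropic scale by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError

_EULER_CONVENTION = "xyz"  # intrinsic rotations about x, then y, then z
_ORTHO_TOL = 1e-6


def _rotation_from_euler(euler_deg) -> np.ndarray:
    return Rotation.from_euler(_EULER_CONVENTION, np.asarray(euler_deg, float), degrees=True).as_matrix()


@dataclass(frozen=True)
class AffineTransform:
    translation: tuple
    rotation: np.ndarray  # 3x3 orthonormal, det +1
    scale: tuple          # per-axis, positive
    center: tuple         # mm

    def __post_init__(self):
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))
        object.__setattr__(self, "scale", tuple(float(v) for v in self.scale))
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL) or not np.isclose(
            np.linalg.det(R), 1.0, atol=_ORTHO_TOL
        ):
            raise ValidationError("rotation must be orthonormal with det +1")
        if any(s <= 0 for s in self.scale):
            raise ValidationError("scale entries must be positive")
        object.__setattr__(self, "rotation", R)

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls((0.0, 0.0, 0.0), np.eye(3), (1.0, 1.0, 1.0), center)

    @classmethod
    def from_params(cls, translation_mm, euler_deg, scale, center_mm) -> "AffineTransform":
        if np.isscalar(scale):
            scale = (float(scale),) * 3
        return cls(tuple(translation_mm), _rotation_from_euler(euler_deg), tuple(scale), tuple(center_mm))

    # -- views -------------------------------------------------------------

    @property
    def euler_deg(self) -> tuple:
        return tuple(Rotation.from_matrix(self.rotation).as_euler(_EULER_CONVENTION, degrees=True))

    @property
    def linear(self) -> np.ndarray:
        return self.rotation @ np.diag(self.scale)

    @property
    def offset(self) -> np.ndarray:
        """b such that T(x) = linear @ x + b."""
        c = np.asarray(self.center)
        return c + np.asarray(self.translation) - self.linear @ c

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            np.allclose(self.translation, 0.0, atol=tol)
            and np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.scale, 1.0, atol=tol)
        )

    # -- actions -----------------------------------------------------------

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to physical points of shape (..., 3)."""
        pts = np.asarray(pts, dtype=np.float64)
        if self.is_identity():
            return pts
        return pts @ self.linear.T + self.offset

    def decomposition_residual(self) -> float:
        """How far linear is from an exact rotation @ diag decomposition (0 here)."""
        L = self.linear
        R, S = _polar_decompose(L)
        return float(np.max(np.abs(L - R @ np.diag(S))))

    def inverse(self) -> "AffineTransform":
        Li = np.linalg.inv(self.linear)
        R, S = _polar_decompose(Li)
        b = self.offset
        c = np.asarray(self.center)
        # T^-1(x) = Li x - Li b ; re-anchor at the same center:
        # want c + R S (x - c) + t' = Li x - Li b  =>  t' = Li(c - ...) below
        t = Li @ (c - b) - c  # since R S = Li (up to residual)
        return AffineTransform(tuple(t), R, tuple(S), self.center)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self o other (apply ``other`` first)."""
        L = self.linear @ other.linear
        b = self.linear @ other.offset + self.offset
        R, S = _polar_decompose(L)
        c = np.asarray(self.center)
        t = L @ c + b - c
        return AffineTransform(tuple(t), R, tuple(S), self.center)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation),
            "euler_deg": list(self.euler_deg),
            "scale": list(self.scale),
            "center_mm": list(self.center),
            "convention": f"{_EULER_CONVENTION}-intrinsic",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        if d.get("convention", f"{_EULER_CONVENTION}-intrinsic") != f"{_EULER_CONVENTION}-intrinsic":
            raise ValidationError(f"unsupported rotation convention {d.get('convention')!r}")
        return cls.from_params(d["translation_mm"], d["euler_deg"], tuple(d["scale"]), d["center_mm"])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _polar_decompose(L: np.ndarray, tol: float = 1e-3):
    """Decompose L ~ R @ diag(S) with R a proper rotation.

    Exact when L is rotation times diagonal with isotropic diagonal; for the
    near-isotropic transforms used here the residual is negligible.
    """
    U, sv, Vt = np.linalg.svd(L)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        sv = sv.copy()
        sv[-1] *= -1.0
        R = U @ Vt
    sym = Vt.T @ np.diag(sv) @ Vt  # L = R @ sym
    S = np.clip(np.diag(sym).copy(), 1e-12, None)
    return R, S
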