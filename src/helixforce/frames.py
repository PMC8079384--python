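"""Homogeneous-transform algebra and helix/simulation coordinate frames.

Transforms follow the robotics convention: ``T`` with ``to_frame=A`` and
``from_frame=B`` (written :math:`^{A}_{B}T`) maps coordinates expressed in
frame B into frame A via ``p_A = R p_B + t``. Frame names are carried on
every transform and checked at composition time, which catches the classic
transform-direction bug early.

Each fitted helix gets a local frame whose x-axis runs along the helix axis
(N→C), whose y-axis points from the axis toward the first significant
(non-glycine) sidechain, and whose origin sits at the axis start point. A
bundle simulation frame (SIM) is anchored to the first helix's local frame by
an identity transform; every other helix keeps the relative pose it had in
the source PDB file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, FrameMismatchError, ValidationError

_ORTHO_TOL = 1e-9

PDB_FRAME = "PDB"
SIM_FRAME = "SIM"


def helix_frame_name(helix_id: int) -> str:
    return f"aH{helix_id}"


@dataclass(frozen=True)
class HomogeneousTransform:
    """A rigid transform ``p_to = R p_from + translation`` between named frames."""

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str
    to_frame: str

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValidationError("rotation matrix has det -1 (reflection)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls, from_frame: str, to_frame: str) -> "HomogeneousTransform":
        return cls(np.eye(3), np.zeros(3), from_frame, to_frame)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, from_frame: str, to_frame: str
    ) -> "HomogeneousTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4) or not np.allclose(matrix[3], [0, 0, 0, 1]):
            raise ValidationError("expected a 4x4 matrix with bottom row (0,0,0,1)")
        return cls(matrix[:3, :3], matrix[:3, 3], from_frame, to_frame)

    @property
    def matrix(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out


def compose(a: HomogeneousTransform, b: HomogeneousTransform) -> HomogeneousTransform:
    """Chain two transforms: the result maps ``b.from_frame`` into ``a.to_frame``."""
    if a.from_frame != b.to_frame:
        raise FrameMismatchError(
            f"cannot compose: left consumes frame {a.from_frame!r} but right "
            f"produces frame {b.to_frame!r}"
        )
    return HomogeneousTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        from_frame=b.from_frame,
        to_frame=a.to_frame,
    )


def invert(t: HomogeneousTransform) -> HomogeneousTransform:
    """Inverse transform (frame names swapped)."""
    rot = t.rotation.T
    return HomogeneousTransform(
        rot, -rot @ t.translation, from_frame=t.to_frame, to_frame=t.from_frame
    )


def apply(t: HomogeneousTransform, points: np.ndarray) -> np.ndarray:
    """Apply the transform to a single point (3,) or a stack of points (n, 3)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        return t.rotation @ pts + t.translation
    return pts @ t.rotation.T + t.translation


def build_helix_frame(
    geometry, first_significant_sidechain, frame_name: str = "helix"
) -> HomogeneousTransform:
    """Construct a helix's local frame from its fitted geometry.

    x̂ is the helix axis direction; ŷ points from the axis (at the foot of the
    reference sidechain's center) toward that sidechain center, orthogonalised
    against x̂ so the rotation is exactly orthonormal; ẑ = x̂ × ŷ. The origin is
    the axis start point. The returned transform maps helix-local coordinates
    into the PDB frame.
    """
    x_hat = np.asarray(geometry.direction, dtype=float)
    start = np.asarray(geometry.axis_start, dtype=float)
    center = np.asarray(first_significant_sidechain.center, dtype=float)

    foot = start + np.dot(center - start, x_hat) * x_hat
    radial = center - foot
    norm = np.linalg.norm(radial)
    if norm < 1e-6:
        raise DegenerateGeometryError(
            "reference sidechain center lies on the helix axis; frame undefined"
        )
    y_hat = radial / norm
    y_hat = y_hat - np.dot(y_hat, x_hat) * x_hat  # Gram-Schmidt against the axis
    y_hat /= np.linalg.norm(y_hat)
    z_hat = np.cross(x_hat, y_hat)
    rotation = np.column_stack([x_hat, y_hat, z_hat])
    return HomogeneousTransform(rotation, start, from_frame=frame_name, to_frame=PDB_FRAME)


@dataclass
class BundleLayout:
    """A helix bundle re-expressed in the simulation (SIM) frame.

    ``models`` are transformed copies whose coordinates, frames and sidechain
    spheres live in SIM coordinates; ``sim_from_pdb`` is the rigid transform
    that was applied. The SIM frame coincides with the first helix's local
    frame, so helix 1's axis start sits at the SIM origin and its axis runs
    along SIM x.
    """

    models: list
    sim_from_pdb: HomogeneousTransform

    @property
    def helix_ids(self) -> list[int]:
        return [m.helix_id for m in self.models]


def place_bundle(models: Sequence) -> BundleLayout:
    """Re-express a bundle of fitted helix models in the SIM frame.

    The SIM frame is defined as the first helix's local frame (the SIM←helix1
    transform is the identity); all helices keep the relative geometry they
    had in the PDB file — this is a rigid re-expression only.
    """
    if len(models) < 2:
        raise ValidationError(
            f"a bundle needs at least 2 helices, got {len(models)}"
        )
    first = models[0]
    parent = first.local_frame.to_frame  # usually PDB
    if any(m.local_frame.to_frame != parent for m in models):
        raise FrameMismatchError("bundle helices live in different parent frames")
    inv = invert(first.local_frame)
    sim_from_pdb = HomogeneousTransform(
        inv.rotation, inv.translation, from_frame=parent, to_frame=SIM_FRAME
    )
    placed = [m.transformed(sim_from_pdb) for m in models]
    return BundleLayout(models=placed, sim_from_pdb=sim_from_pdb)


def derive_linker_transform(
    frame_h1: HomogeneousTransform, frame_h2: HomogeneousTransform
) -> HomogeneousTransform:
    """Relative transform mapping helix-2 coordinates into helix-1's frame.

    Both input frames must share the same parent frame. Composing
    ``frame_h1 ∘ result`` reproduces ``frame_h2``; the result is the combined
    helix1→linker→helix2 chain (only the product of the two linker legs is
    observable, so only the product is returned).
    """
    if frame_h1.to_frame != frame_h2.to_frame:
        raise FrameMismatchError(
            f"frames have different parents: {frame_h1.to_frame!r} vs {frame_h2.to_frame!r}"
        )
    return compose(invert(frame_h1), frame_h2)
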