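"""Coarse-grained alpha-helix model fitting.

Each helix is reduced to a straight cylinder plus one sphere per sidechain:

* the backbone is represented by its Cα positions only (matrix ``M``, one row
  per residue);
* the axis direction is the first principal axis of the zero-mean Cα cloud,
  obtained by SVD of the covariance matrix ``S = BᵀB/(n−1)``;
* the axis segment runs between the orthogonal projections of the first and
  last Cα onto the fitted line, so the axis start/end/centroid are collinear
  by construction;
* the cylinder radius is the mean perpendicular Cα→axis distance;
* each sidechain is a sphere centred at the mean heavy-atom position, with
  radius equal to the mean atom→center distance (glycine: a zero-radius
  sphere at its Cα).

A local coordinate frame (x along the axis, y toward the first non-glycine
sidechain) is attached to every fitted helix; see :mod:`helixforce.frames`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import frames
from .errors import DegenerateGeometryError, ValidationError
from .pdb_io import AtomRecord, ResidueGroup

MIN_RESIDUES = 4


@dataclass(frozen=True)
class PrincipalAxisDecomposition:
    """SVD of the Cα covariance matrix, kept for inspection/diagnostics."""

    covariance: np.ndarray
    left_singular_vectors: np.ndarray
    singular_values: np.ndarray
    right_singular_vectors: np.ndarray


@dataclass(frozen=True)
class HelixGeometry:
    """Fitted cylinder geometry of one helix.

    ``axial_params`` holds the dimensionless line parameter t of each Cα
    (0 at axis_start, 1 at axis_end); multiply by ``axis_length`` for
    positions in Angstroms. ``radial_distances`` are the perpendicular
    Cα→axis distances l_i; ``radius`` is their mean.
    """

    backbone_positions: np.ndarray
    centroid: np.ndarray
    direction: np.ndarray
    axis_start: np.ndarray
    axis_end: np.ndarray
    radius: float
    axial_params: np.ndarray
    radial_distances: np.ndarray
    decomposition: PrincipalAxisDecomposition | None = None

    @property
    def n_residues(self) -> int:
        return int(self.backbone_positions.shape[0])

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(self.axis_end - self.axis_start))


@dataclass(frozen=True)
class SidechainSphere:
    """Sphere approximation of one sidechain.

    ``center`` is the mean heavy-atom position; ``sphere_radius`` the mean
    atom→center distance. ``ca_position`` is kept so shape statistics can
    normalise each instance to its own Cα. ``charge`` (integer, elementary
    charges) is None until assigned from a charge table.
    """

    residue_name: str
    residue_seq: int
    center: np.ndarray
    sphere_radius: float
    atom_count: int
    atom_positions: np.ndarray
    ca_position: np.ndarray
    charge: int | None = None


@dataclass(frozen=True)
class HelixModel:
    """A fitted helix: geometry, sidechain spheres and local frame."""

    geometry: HelixGeometry
    sidechains: tuple[SidechainSphere, ...]
    local_frame: frames.HomogeneousTransform
    helix_id: int

    def transformed(self, t: frames.HomogeneousTransform) -> "HelixModel":
        """Rigidly re-express the whole model in another frame.

        Radial distances, axial parameters and sphere radii are invariant
        under rigid motion and are copied unchanged.
        """
        geo = self.geometry
        new_geometry = replace(
            geo,
            backbone_positions=frames.apply(t, geo.backbone_positions),
            centroid=frames.apply(t, geo.centroid),
            direction=t.rotation @ geo.direction,
            axis_start=frames.apply(t, geo.axis_start),
            axis_end=frames.apply(t, geo.axis_end),
        )
        new_sidechains = tuple(
            replace(
                sc,
                center=frames.apply(t, sc.center),
                ca_position=frames.apply(t, sc.ca_position),
                atom_positions=(
                    frames.apply(t, sc.atom_positions)
                    if sc.atom_count > 0
                    else sc.atom_positions
                ),
            )
            for sc in self.sidechains
        )
        new_frame = frames.compose(t, self.local_frame)
        return HelixModel(new_geometry, new_sidechains, new_frame, self.helix_id)


def backbone_centroid(positions: np.ndarray) -> np.ndarray:
    """Mean of the Cα positions (rows of ``positions``)."""
    m = np.asarray(positions, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] == 0:
        raise ValidationError("expected a non-empty n x 3 position matrix")
    if not np.all(np.isfinite(m)):
        raise ValidationError("backbone positions must be finite")
    return m.mean(axis=0)


def principal_axis(
    positions: np.ndarray,
) -> tuple[np.ndarray, PrincipalAxisDecomposition]:
    """Principal axis of the Cα cloud via SVD of its covariance matrix.

    The covariance uses the n−1 denominator. The direction is the singular
    vector with the largest singular value, sign-fixed so it points from the
    first toward the last residue (N→C along the annotated helix).
    """
    m = np.asarray(positions, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != 3 or n < 3:
        raise ValidationError("principal axis needs at least 3 points (n x 3)")
    centroid = backbone_centroid(m)
    b = m - centroid
    cov = b.T @ b / (n - 1)
    u, s, vt = np.linalg.svd(cov)
    if s[0] < 1e-12:
        raise DegenerateGeometryError("all backbone points coincide; no axis")
    direction = u[:, 0]
    span = m[-1] - m[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    return direction, PrincipalAxisDecomposition(cov, u, s, vt)


def axis_endpoints(
    centroid: np.ndarray,
    direction: np.ndarray,
    b_first: np.ndarray,
    b_last: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis segment endpoints: orthogonal projections of the terminal Cα.

    Projecting b_first and b_last onto the fitted line guarantees that
    axis_start, the centroid and axis_end are collinear and that start/end
    sit on opposite sides of the centroid for any real helix.
    """
    centroid = np.asarray(centroid, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValidationError("direction must be a unit vector")
    start = centroid + np.dot(np.asarray(b_first, float) - centroid, direction) * direction
    end = centroid + np.dot(np.asarray(b_last, float) - centroid, direction) * direction
    return start, end


def point_on_axis(
    axis_start: np.ndarray, axis_end: np.ndarray, query: np.ndarray
) -> tuple[np.ndarray, float]:
    """Foot of the perpendicular from ``query`` to the axis line, plus its t.

    t is the dimensionless line parameter (0 at start, 1 at end; values
    outside [0, 1] are legitimate for points beyond the segment).
    """
    start = np.asarray(axis_start, dtype=float)
    end = np.asarray(axis_end, dtype=float)
    length = np.linalg.norm(end - start)
    if length < 1e-12:
        raise DegenerateGeometryError("zero-length axis")
    d_hat = (end - start) / length
    t = float(np.dot(np.asarray(query, float) - start, d_hat) / length)
    foot = start + t * (end - start)
    return foot, t


def backbone_radius(
    positions: np.ndarray, axis_start: np.ndarray, axis_end: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean and per-residue perpendicular Cα→axis distances (true norms)."""
    m = np.asarray(positions, dtype=float)
    distances = np.empty(m.shape[0])
    for i, row in enumerate(m):
        foot, _ = point_on_axis(axis_start, axis_end, row)
        distances[i] = np.linalg.norm(row - foot)
    return float(distances.mean()), distances


def sidechain_sphere(
    atoms: Sequence[AtomRecord] | np.ndarray,
    ca_position: np.ndarray,
    residue_name: str = "UNK",
    residue_seq: int = 0,
) -> SidechainSphere:
    """Sphere approximation of one sidechain's heavy atoms.

    Accepts AtomRecords or a bare (m, 3) position array. An empty atom set
    (glycine) yields a zero-radius sphere at the Cα.
    """
    ca = np.asarray(ca_position, dtype=float)
    if isinstance(atoms, np.ndarray):
        pos = atoms.reshape(-1, 3).astype(float)
    else:
        pos = (
            np.array([a.position for a in atoms], dtype=float)
            if len(atoms)
            else np.empty((0, 3))
        )
        if len(atoms):
            residue_name = atoms[0].residue_name
            residue_seq = atoms[0].residue_seq
    if pos.shape[0] == 0:
        return SidechainSphere(residue_name, residue_seq, ca.copy(), 0.0, 0, pos, ca)
    center = pos.mean(axis=0)
    radius = float(np.linalg.norm(pos - center, axis=1).mean())
    return SidechainSphere(residue_name, residue_seq, center, radius, pos.shape[0], pos, ca)


def fit_geometry(positions: np.ndarray) -> HelixGeometry:
    """Fit the straight-axis cylinder geometry to a stack of Cα positions."""
    m = np.asarray(positions, dtype=float)
    if m.shape[0] < MIN_RESIDUES:
        raise ValidationError(
            f"helix fit needs at least {MIN_RESIDUES} residues, got {m.shape[0]}"
        )
    centroid = backbone_centroid(m)
    direction, decomposition = principal_axis(m)
    start, end = axis_endpoints(centroid, direction, m[0], m[-1])
    radius, distances = backbone_radius(m, start, end)
    t_params = np.array([point_on_axis(start, end, row)[1] for row in m])
    return HelixGeometry(
        backbone_positions=m,
        centroid=centroid,
        direction=direction,
        axis_start=start,
        axis_end=end,
        radius=radius,
        axial_params=t_params,
        radial_distances=distances,
        decomposition=decomposition,
    )


def first_significant_sidechain(sidechains: Sequence[SidechainSphere]) -> SidechainSphere:
    """The lowest-numbered non-glycine sidechain (frame reference)."""
    for sc in sorted(sidechains, key=lambda s: s.residue_seq):
        if sc.residue_name != "GLY" and sc.atom_count > 0:
            return sc
    raise DegenerateGeometryError(
        "no significant (non-glycine) sidechain available for frame construction"
    )


def build_helix_model(residues: Sequence[ResidueGroup], helix_id: int) -> HelixModel:
    """Fit the full coarse-grained model for one annotated helix."""
    if len(residues) < MIN_RESIDUES:
        raise ValidationError(
            f"helix {helix_id}: needs at least {MIN_RESIDUES} residues, got {len(residues)}"
        )
    ca_positions = np.array([group.ca.position for group in residues])
    geometry = fit_geometry(ca_positions)
    sidechains = tuple(
        sidechain_sphere(
            group.sidechain_atoms,
            group.ca.position,
            residue_name=group.residue_name,
            residue_seq=group.residue_seq,
        )
        for group in residues
    )
    reference = first_significant_sidechain(sidechains)
    frame = frames.build_helix_frame(
        geometry, reference, frame_name=frames.helix_frame_name(helix_id)
    )
    return HelixModel(geometry, sidechains, frame, helix_id)


# -- serialization -----------------------------------------------------------

def model_to_dict(model: HelixModel) -> dict:
    geo = model.geometry
    return {
        "helix_id": model.helix_id,
        "geometry": {
            "backbone_positions": geo.backbone_positions.tolist(),
            "centroid": geo.centroid.tolist(),
            "direction": geo.direction.tolist(),
            "axis_start": geo.axis_start.tolist(),
            "axis_end": geo.axis_end.tolist(),
            "radius": geo.radius,
            "axial_params": geo.axial_params.tolist(),
            "radial_distances": geo.radial_distances.tolist(),
        },
        "sidechains": [
            {
                "residue_name": sc.residue_name,
                "residue_seq": sc.residue_seq,
                "center": sc.center.tolist(),
                "sphere_radius": sc.sphere_radius,
                "atom_count": sc.atom_count,
                "atom_positions": sc.atom_positions.tolist(),
                "ca_position": sc.ca_position.tolist(),
                "charge": sc.charge,
            }
            for sc in model.sidechains
        ],
        "local_frame": {
            "matrix": model.local_frame.matrix.tolist(),
            "from_frame": model.local_frame.from_frame,
            "to_frame": model.local_frame.to_frame,
        },
    }


def model_from_dict(data: dict) -> HelixModel:
    g = data["geometry"]
    geometry = HelixGeometry(
        backbone_positions=np.array(g["backbone_positions"], dtype=float),
        centroid=np.array(g["centroid"], dtype=float),
        direction=np.array(g["direction"], dtype=float),
        axis_start=np.array(g["axis_start"], dtype=float),
        axis_end=np.array(g["axis_end"], dtype=float),
        radius=float(g["radius"]),
        axial_params=np.array(g["axial_params"], dtype=float),
        radial_distances=np.array(g["radial_distances"], dtype=float),
    )
    sidechains = tuple(
        SidechainSphere(
            residue_name=s["residue_name"],
            residue_seq=int(s["residue_seq"]),
            center=np.array(s["center"], dtype=float),
            sphere_radius=float(s["sphere_radius"]),
            atom_count=int(s["atom_count"]),
            atom_positions=np.array(s["atom_positions"], dtype=float).reshape(-1, 3),
            ca_position=np.array(s["ca_position"], dtype=float),
            charge=s.get("charge"),
        )
        for s in data["sidechains"]
    )
    f = data["local_frame"]
    frame = frames.HomogeneousTransform.from_matrix(
        np.array(f["matrix"], dtype=float), f["from_frame"], f["to_frame"]
    )
    return HelixModel(geometry, sidechains, frame, int(data["helix_id"]))


def save_models(models: Sequence[HelixModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([model_to_dict(m) for m in models], indent=1) + "\n"
    )


def load_models(path: str | Path) -> list[HelixModel]:
    return [model_from_dict(d) for d in json.loads(Path(path).read_text())]
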