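"""Validation statistics for the straight-cylinder and sphere approximations.

Three families of checks quantify how well real helices match the model's
assumptions:

* **Radial profiles and skew.** For each helix, the perpendicular Cα→axis
  distance l_i is regressed on axial position (both in Å). The skew angle —
  atan(slope) in degrees — measures how much the helix width drifts along
  its length; a straight constant-width helix has skew ≈ 0. The distribution
  of skew angles across many helices summarises whether constant width is a
  fair assumption.
* **Radial histograms.** Pooled l_i values binned at fixed width with a
  moment-matched normal overlay: an unbiased, roughly symmetric distribution
  supports using the mean as the cylinder radius.
* **Sidechain shape statistics.** All instances of one residue type are
  normalised (Cα at the origin, Cα→centroid direction aligned to +x; the
  residual spin about that axis is irrelevant to distances) and pooled;
  distances from the pooled centroid summarise how sphere-like the sidechain
  cloud is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .helix_model import HelixModel


@dataclass(frozen=True)
class SkewResult:
    """OLS fit of radial distance vs axial position for one helix."""

    helix_id: int
    slope: float  # A per A
    intercept: float  # A
    skew_angle: float  # degrees, atan(slope)
    mean_radius: float  # A


@dataclass(frozen=True)
class SkewDistribution:
    """Skew angles pooled over helices with summary statistics (degrees)."""

    angles: tuple[float, ...]
    median: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class RadialHistogram:
    """Pooled radial distances binned at fixed width + moment-matched normal."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SidechainShapeStats:
    """Pooled, pose-normalised atom-distance statistics for one residue type."""

    residue_name: str
    pooled_distances: np.ndarray
    mean_distance: float
    median: float
    q1: float
    q3: float
    n_instances: int


def radial_profile(model: HelixModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (axial position Å, radial distance Å) along one helix."""
    geo = model.geometry
    return geo.axial_params * geo.axis_length, geo.radial_distances.copy()


def skew_regression(
    axial: np.ndarray, radial: np.ndarray, helix_id: int = 0
) -> SkewResult:
    """OLS line of radial distance on axial position; skew = atan(slope).

    A constant-width helix gives slope 0; decreasing width gives a negative
    slope and a negative angle.
    """
    axial = np.asarray(axial, dtype=float)
    radial = np.asarray(radial, dtype=float)
    if axial.shape[0] < 3:
        raise ValidationError("skew regression needs at least 3 residues")
    if np.ptp(axial) < 1e-12:
        slope, intercept = 0.0, float(radial.mean())
    else:
        fit = stats.linregress(axial, radial)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return SkewResult(
        helix_id=helix_id,
        slope=slope,
        intercept=intercept,
        skew_angle=float(np.degrees(np.arctan(slope))),
        mean_radius=float(radial.mean()),
    )


def skew_for_model(model: HelixModel) -> SkewResult:
    axial, radial = radial_profile(model)
    return skew_regression(axial, radial, helix_id=model.helix_id)


def skew_distribution(models: Sequence[HelixModel]) -> SkewDistribution:
    """Distribution of skew angles across helices (median/mean/sample sd)."""
    if not models:
        raise ValidationError("skew distribution needs at least one helix")
    angles = tuple(skew_for_model(m).skew_angle for m in models)
    arr = np.array(angles)
    sd = float(arr.std(ddof=1)) if len(angles) > 1 else 0.0
    return SkewDistribution(
        angles=angles,
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        sd=sd,
        n=len(angles),
    )


def radial_histogram(
    models: Sequence[HelixModel], bin_width: float = 0.1
) -> RadialHistogram:
    """Pooled Cα→axis distances binned at ``bin_width`` Å, with a normal fit.

    The normal "fit" is the moment estimator (sample mean and sd, ddof=1).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    pooled = np.concatenate([m.geometry.radial_distances for m in models]) if models else np.array([])
    if pooled.size < 2:
        raise ValidationError("radial histogram needs at least 2 pooled distances")
    low = np.floor(pooled.min() / bin_width) * bin_width
    high = np.ceil(pooled.max() / bin_width) * bin_width
    if high <= low:
        high = low + bin_width
    edges = np.arange(low, high + bin_width / 2, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    return RadialHistogram(
        bin_edges=edges,
        counts=counts,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        n=int(pooled.size),
    )


def _rotation_to_x(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +x (Rodrigues; spin is free)."""
    x = np.array([1.0, 0.0, 0.0])
    c = float(np.dot(v, x))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # antiparallel: rotate pi about z
        return np.diag([-1.0, -1.0, 1.0])
    axis = np.cross(v, x)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def sidechain_shape_stats(
    models: Sequence[HelixModel], residue_name: str
) -> SidechainShapeStats:
    """Pooled shape statistics for one residue type across all helices.

    Each instance is translated so its Cα sits at the origin and rotated so
    its Cα→centroid direction lies along +x; the pooled transformed atom
    positions are then summarised by distances from the pooled centroid.
    The unresolved spin about the alignment axis does not affect distances
    from the pooled centroid only when the cloud is axially symmetric, but it
    is the same normalisation ambiguity the sphere model itself accepts.
    """
    if residue_name == "GLY":
        raise ValidationError("glycine has no sidechain atoms to pool")
    transformed: list[np.ndarray] = []
    n_instances = 0
    for model in models:
        for sc in model.sidechains:
            if sc.residue_name != residue_name or sc.atom_count < 1:
                continue
            rel = sc.atom_positions - sc.ca_position
            v = sc.center - sc.ca_position
            norm = np.linalg.norm(v)
            rot = _rotation_to_x(v / norm) if norm > 1e-9 else np.eye(3)
            transformed.append(rel @ rot.T)
            n_instances += 1
    if n_instances == 0:
        raise ValidationError(
            f"no {residue_name} sidechain instances with atoms in the given models"
        )
    pooled = np.vstack(transformed)
    centroid = pooled.mean(axis=0)
    distances = np.linalg.norm(pooled - centroid, axis=1)
    return SidechainShapeStats(
        residue_name=residue_name,
        pooled_distances=distances,
        mean_distance=float(distances.mean()),
        median=float(np.median(distances)),
        q1=float(np.percentile(distances, 25)),
        q3=float(np.percentile(distances, 75)),
        n_instances=n_instances,
    )
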