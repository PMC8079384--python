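"""Sidechain charge assignment and static Coulomb force estimation.

Charges are integers in {−1, 0, +1} assigned per residue type at a fixed pH
(default 7.2): aspartate and glutamate carry −1, lysine and arginine +1, and
everything else — including histidine (pKa ≈ 6.0, <10 % protonated at pH
7.2), cysteine and tyrosine — is neutral. The table is overridable.

The bundle's static force is the signed scalar sum of Coulomb pair forces
F = k_e q₁q₂ / (ε_r r²) over every cross-helix sidechain pair in every
unordered helix pair (intra-helix pairs excluded), with each residue's whole
charge placed at its sidechain sphere center. Positive force is repulsive,
negative attractive. Summation order is fixed (helix pair, then donor, then
acceptor residue) so totals are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ChargeAssignmentError, ValidationError
from .frames import BundleLayout
from .helix_model import HelixModel

#: Default integer sidechain charges at pH 7.2.
DEFAULT_CHARGE_MAP: dict[str, int] = {
    "ALA": 0, "ARG": 1, "ASN": 0, "ASP": -1, "CYS": 0,
    "GLN": 0, "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0,
    "LEU": 0, "LYS": 1, "MET": 0, "PHE": 0, "PRO": 0,
    "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}


@dataclass(frozen=True)
class ChargeTable:
    """Residue-name → integer charge map at a stated pH."""

    pH: float = 7.2
    map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHARGE_MAP))

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.map.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValidationError(f"charges must be in {{-1, 0, +1}}: {bad}")

    def charge_for(self, residue_name: str) -> int:
        try:
            return self.map[residue_name]
        except KeyError:
            raise ChargeAssignmentError(
                f"no charge entry for residue {residue_name!r} (pH {self.pH} table)"
            ) from None

    def with_overrides(self, overrides: Mapping[str, int]) -> "ChargeTable":
        merged = dict(self.map)
        merged.update(overrides)
        return ChargeTable(pH=self.pH, map=merged)


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants and unit factors for the Coulomb calculation."""

    coulomb_constant: float = 8.9875517873681764e9  # N m^2 C^-2, 1/(4 pi eps0)
    elementary_charge: float = 1.602176634e-19  # C
    relative_permittivity: float = 1.0  # vacuum by default (no solvent screening)
    angstrom_to_metre: float = 1e-10
    newton_to_piconewton: float = 1e12

    def __post_init__(self) -> None:
        for name in (
            "coulomb_constant",
            "elementary_charge",
            "relative_permittivity",
            "angstrom_to_metre",
            "newton_to_piconewton",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class PairForce:
    """One cross-helix charge-pair interaction (pN, negative = attractive)."""

    helix_pair: tuple[int, int]
    residue_pair: tuple[int, int]
    distance: float
    force: float


@dataclass(frozen=True)
class BundleForceResult:
    """All pair forces plus the signed net static force for one bundle."""

    bundle_id: str
    per_pair: tuple[PairForce, ...]
    per_helix_pair_totals: dict[tuple[int, int], float]
    net_force: float
    per_helix_vector: dict[int, np.ndarray]


def coulomb_force(
    q1: int,
    q2: int,
    distance: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Coulomb force between two integer point charges, in piconewtons.

    ``distance`` is in Angstroms. Positive values are repulsive.
    """
    if distance <= 0:
        raise ValidationError(f"distance must be positive, got {distance}")
    r_m = distance * constants.angstrom_to_metre
    force_n = (
        constants.coulomb_constant
        * (q1 * constants.elementary_charge)
        * (q2 * constants.elementary_charge)
        / (constants.relative_permittivity * r_m**2)
    )
    return force_n * constants.newton_to_piconewton


def assign_charges(
    models: Sequence[HelixModel], table: ChargeTable | None = None
) -> list[HelixModel]:
    """Return copies of the models with per-sidechain integer charges set."""
    table = table if table is not None else ChargeTable()
    out = []
    for model in models:
        sidechains = tuple(
            replace(sc, charge=table.charge_for(sc.residue_name))
            for sc in model.sidechains
        )
        out.append(replace(model, sidechains=sidechains))
    return out


def bundle_static_force(
    layout: BundleLayout,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    bundle_id: str = "bundle",
) -> BundleForceResult:
    """Net static electrostatic force within a placed helix bundle.

    Iterates every unordered helix pair (a < b by list position) and every
    cross pair of charged sidechains; neutral pairs are skipped. The net
    force is the plain signed sum of the scalar pair forces. Per-helix 3D
    force vectors (sum of pair forces along the center-to-center directions)
    are also reported for inspection.
    """
    models = list(layout.models)
    if len(models) < 2:
        raise ValidationError("bundle force needs at least 2 helices")
    for model in models:
        for sc in model.sidechains:
            if sc.charge is None:
                raise ValidationError(
                    f"helix {model.helix_id} residue {sc.residue_seq}: charge "
                    "unassigned; run assign_charges first"
                )

    per_pair: list[PairForce] = []
    totals: dict[tuple[int, int], float] = {}
    vectors: dict[int, np.ndarray] = {m.helix_id: np.zeros(3) for m in models}
    net = 0.0
    for a_idx in range(len(models)):
        for b_idx in range(a_idx + 1, len(models)):
            helix_a, helix_b = models[a_idx], models[b_idx]
            key = (helix_a.helix_id, helix_b.helix_id)
            totals[key] = 0.0
            for sc_a in helix_a.sidechains:
                if sc_a.charge == 0:
                    continue
                for sc_b in helix_b.sidechains:
                    if sc_b.charge == 0:
                        continue
                    delta = sc_a.center - sc_b.center
                    distance = float(np.linalg.norm(delta))
                    if distance < 1e-6:
                        raise ValidationError(
                            f"coincident charged sidechains: helix {helix_a.helix_id} "
                            f"residue {sc_a.residue_seq} and helix {helix_b.helix_id} "
                            f"residue {sc_b.residue_seq}"
                        )
                    force = coulomb_force(sc_a.charge, sc_b.charge, distance, constants)
                    per_pair.append(PairForce(key, (sc_a.residue_seq, sc_b.residue_seq),
                                              distance, force))
                    totals[key] += force
                    net += force
                    direction = delta / distance
                    # repulsive (F > 0) pushes a away from b
                    vectors[helix_a.helix_id] += force * direction
                    vectors[helix_b.helix_id] -= force * direction
    return BundleForceResult(
        bundle_id=bundle_id,
        per_pair=tuple(per_pair),
        per_helix_pair_totals=totals,
        net_force=net,
        per_helix_vector=vectors,
    )
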