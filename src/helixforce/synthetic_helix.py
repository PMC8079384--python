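"""Ideal alpha-helix and toy-bundle generators.

These generators provide ground-truth fixtures for every downstream stage:
Cα atoms are laid out on an exact cylindrical helix (default 1.5 Å rise,
100° twist and 2.3 Å radius per residue — canonical alpha-helix values),
N/C/O backbone atoms at fixed chemically plausible offsets, and sidechain
atom clusters whose centroid sits a known radial distance outside each Cα.
Optional i.i.d. Gaussian jitter (``jitter_sd``) perturbs every emitted atom,
so axis/radius recovery can be exercised under noise; with ``jitter_sd=0``
each Cα lies exactly ``backbone_radius`` from the true axis.

Positive twist produces a right-handed helix. Generated structures can be
written to PDB format so fixtures exercise the real parser end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import ValidationError
from .pdb_io import AtomRecord, HelixAnnotation, write_helix_annotations

_SIDECHAIN_ATOM_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH"]

# Backbone N/C/O offsets from the Cα in the local (radial, tangential, axial)
# basis, Å. Values give ~1.5 Å N-CA / CA-C bonds; chemical realism is a
# non-goal, only a plausible-looking heavy-atom backbone.
_BACKBONE_OFFSETS = {
    "N": (-0.35, -1.20, -0.75),
    "C": (-0.30, 1.25, 0.65),
    "O": (-0.55, 1.40, 1.80),
}
_ELEMENTS = {"N": "N", "C": "C", "O": "O", "CA": "C"}


@dataclass(frozen=True)
class IdealHelixSpec:
    """Parameters of one generated helix; defaults are canonical values."""

    n_residues: int = 18
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    backbone_radius: float = 2.3
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sequence: tuple[str, ...] | None = None
    sidechain_distance: float = 2.5
    atoms_per_sidechain: int = 3
    jitter_sd: float = 0.0
    seed: int = 0
    chain_id: str = "A"
    helix_id: int = 1
    start_seq: int = 1

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValidationError("n_residues must be >= 4 (axis fit undefined below)")
        axis = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValidationError("axis_direction must be a unit vector")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != n_residues {self.n_residues}"
            )
        if self.atoms_per_sidechain < 1:
            raise ValidationError("atoms_per_sidechain must be >= 1")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")

    @property
    def resolved_sequence(self) -> tuple[str, ...]:
        return self.sequence if self.sequence is not None else ("ALA",) * self.n_residues


def _orthonormal_u(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to the axis (y-ish preferred)."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = ref - np.dot(ref, axis) * axis
    return u / np.linalg.norm(u)


def generate_ideal_helix(
    spec: IdealHelixSpec, _u_override: np.ndarray | None = None
) -> tuple[list[AtomRecord], HelixAnnotation]:
    """Generate one ideal helix as AtomRecords plus its annotation.

    Residue i's ideal Cα sits at ``origin + axis·rise·i + radius·(cos(iθ)·u +
    sin(iθ)·v)`` with (u, v, axis) right-handed, so positive twist gives a
    right-handed helix. Sidechain clusters (``atoms_per_sidechain`` atoms)
    are centred ``sidechain_distance`` radially outward of the ideal Cα;
    glycine entries get no sidechain atoms. All atoms receive i.i.d. Gaussian
    jitter of sd ``jitter_sd``. Deterministic per seed.
    """
    axis = np.asarray(spec.axis_direction, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    u = _u_override if _u_override is not None else _orthonormal_u(axis)
    v = np.cross(axis, u)  # (u, v, axis) right-handed
    rng = np.random.default_rng(spec.seed)
    sequence = spec.resolved_sequence

    atoms: list[AtomRecord] = []

    def emit(name: str, resname: str, seq: int, pos: np.ndarray) -> None:
        if spec.jitter_sd > 0:
            pos = pos + rng.normal(0.0, spec.jitter_sd, size=3)
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=_ELEMENTS.get(name, "C"),
                residue_name=resname,
                residue_seq=seq,
                chain_id=spec.chain_id,
                position=pos,
            )
        )

    for i in range(spec.n_residues):
        theta = np.deg2rad(spec.twist_per_residue * i)
        radial = np.cos(theta) * u + np.sin(theta) * v
        tangent = -np.sin(theta) * u + np.cos(theta) * v
        ca = origin + axis * spec.rise_per_residue * i + spec.backbone_radius * radial
        seq = spec.start_seq + i
        resname = sequence[i]
        emit("N", resname, seq, ca + _local(_BACKBONE_OFFSETS["N"], radial, tangent, axis))
        emit("CA", resname, seq, ca)
        emit("C", resname, seq, ca + _local(_BACKBONE_OFFSETS["C"], radial, tangent, axis))
        emit("O", resname, seq, ca + _local(_BACKBONE_OFFSETS["O"], radial, tangent, axis))
        if resname == "GLY":
            continue
        centroid = ca + spec.sidechain_distance * radial
        for j in range(spec.atoms_per_sidechain):
            name = _SIDECHAIN_ATOM_NAMES[j % len(_SIDECHAIN_ATOM_NAMES)]
            if j >= len(_SIDECHAIN_ATOM_NAMES):
                name = f"C{j}"
            emit(name, resname, seq, centroid)

    annotation = HelixAnnotation(
        helix_id=spec.helix_id,
        chain_id=spec.chain_id,
        start_seq=spec.start_seq,
        end_seq=spec.start_seq + spec.n_residues - 1,
    )
    return atoms, annotation


_CHARGE_RESIDUES = {1: "LYS", -1: "ASP", 0: "ALA"}


def generate_charged_pair(
    separation: float,
    charges_a: Sequence[int],
    charges_b: Sequence[int],
    seed: int = 0,
) -> tuple[list[AtomRecord], list[HelixAnnotation]]:
    """Two parallel ideal helices with prescribed per-residue charges.

    The helices run along +x with axes ``separation`` Å apart along y, phased
    so residue-0 sidechains face each other: their centroids are exactly
    ``separation − 2·(backbone_radius + sidechain_distance)`` apart at zero
    jitter. Residue types encode the requested charges via the default pH 7.2
    table (LYS → +1, ASP → −1, ALA → 0). Charge lists shorter than 4 are
    padded with neutral ALA residues so the axis fit is well-posed; padding
    residues contribute no force.
    """
    if separation <= 0:
        raise ValidationError("separation must be positive")
    for charges in (charges_a, charges_b):
        bad = [q for q in charges if q not in (-1, 0, 1)]
        if bad:
            raise ValidationError(f"charges must be in {{-1, 0, +1}}, got {bad}")
        if not charges:
            raise ValidationError("each helix needs at least one charge entry")

    def make_spec(charges: Sequence[int], helix_id: int, start_seq: int) -> IdealHelixSpec:
        seq = [_CHARGE_RESIDUES[q] for q in charges]
        seq += ["ALA"] * max(0, 4 - len(seq))
        return IdealHelixSpec(
            n_residues=len(seq),
            sequence=tuple(seq),
            atoms_per_sidechain=1,
            jitter_sd=0.0,
            seed=seed + helix_id,
            helix_id=helix_id,
            start_seq=start_seq,
        )

    spec_a = make_spec(charges_a, 1, 1)
    spec_b = replace(make_spec(charges_b, 2, 101), origin=(0.0, float(separation), 0.0))
    atoms_a, ann_a = generate_ideal_helix(spec_a, _u_override=np.array([0.0, 1.0, 0.0]))
    atoms_b, ann_b = generate_ideal_helix(spec_b, _u_override=np.array([0.0, -1.0, 0.0]))
    return atoms_a + atoms_b, [ann_a, ann_b]


def _local(
    offset: tuple[float, float, float],
    radial: np.ndarray,
    tangent: np.ndarray,
    axial: np.ndarray,
) -> np.ndarray:
    return offset[0] * radial + offset[1] * tangent + offset[2] * axial


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write AtomRecords as a single-model PDB file (via gemmi)."""
    structure = gemmi.Structure()
    model = gemmi.Model(1)
    chain_order: list[str] = []
    grouped: dict[str, list[AtomRecord]] = {}
    for atom in atoms:
        if atom.chain_id not in grouped:
            grouped[atom.chain_id] = []
            chain_order.append(atom.chain_id)
        grouped[atom.chain_id].append(atom)
    for chain_id in chain_order:
        chain = gemmi.Chain(chain_id)
        current: gemmi.Residue | None = None
        current_key: tuple[int, str] | None = None
        for atom in grouped[chain_id]:
            key = (atom.residue_seq, atom.residue_name)
            if key != current_key:
                if current is not None:
                    chain.add_residue(current)
                current = gemmi.Residue()
                current.name = atom.residue_name
                current.seqid = gemmi.SeqId(atom.residue_seq, " ")
                current.het_flag = "A"
                current_key = key
            g_atom = gemmi.Atom()
            g_atom.name = atom.atom_name
            g_atom.element = gemmi.Element(atom.element)
            g_atom.pos = gemmi.Position(*atom.position)
            current.add_atom(g_atom)
        if current is not None:
            chain.add_residue(current)
        model.add_chain(chain)
    structure.add_model(model)
    structure.write_pdb(str(path))


def write_fixture(
    atoms: Sequence[AtomRecord],
    annotations: Sequence[HelixAnnotation],
    pdb_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write a generated structure plus its annotation file."""
    write_pdb(atoms, pdb_path)
    write_helix_annotations(list(annotations), annotation_path)
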