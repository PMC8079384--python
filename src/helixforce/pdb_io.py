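"""Reading PDB structures and helix annotations.

Atoms are read from fixed-column PDB files (via gemmi) into plain
:class:`AtomRecord` objects, then grouped per residue and split into backbone
({N, CA, C, O}) and sidechain (all remaining heavy) atom sets — the raw
material for the coarse-grained helix model.

Annotation files are flat text, one helix per line::

    # helix_id  chain  start_seq  end_seq
    1  A  5   30
    2  A  33  60

Fields may be separated by whitespace or commas; ``#`` starts a comment.
Residue ranges are inclusive and use the residue sequence numbers printed in
the PDB file.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptySelectionError, ValidationError

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


@dataclass(frozen=True)
class AtomRecord:
    """One accepted heavy atom from a PDB ATOM record.

    ``position`` is the coordinate triple in Angstroms, in the global frame of
    the PDB file. ``model_index`` is 1-based (relevant for NMR ensembles).
    """

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    model_index: int = 1

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.atom_name} {self.residue_name}{self.residue_seq}: "
                "position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class HelixAnnotation:
    """Inclusive residue-sequence range of one annotated alpha-helix."""

    helix_id: int
    chain_id: str
    start_seq: int
    end_seq: int

    def __post_init__(self) -> None:
        if self.start_seq > self.end_seq:
            raise ValidationError(
                f"helix {self.helix_id}: start_seq {self.start_seq} > end_seq {self.end_seq}"
            )

    @property
    def n_residues(self) -> int:
        return self.end_seq - self.start_seq + 1


@dataclass
class ResidueGroup:
    """One residue's atoms split into backbone and sidechain sets."""

    residue_name: str
    residue_seq: int
    backbone_atoms: list[AtomRecord] = field(default_factory=list)
    sidechain_atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def ca(self) -> AtomRecord:
        for atom in self.backbone_atoms:
            if atom.atom_name == "CA":
                return atom
        raise ValidationError(
            f"residue {self.residue_name}{self.residue_seq} has no CA atom"
        )


def _accept_atom(atom: gemmi.Atom) -> bool:
    # altLoc blank or 'A' only (single-conformer model); no hydrogens.
    if atom.altloc not in ("\0", "", "A"):
        return False
    if atom.element.is_hydrogen:
        return False
    return True


def read_structure(
    path: str | Path,
    model_index: int = 1,
    chain_id: str | None = None,
) -> list[AtomRecord]:
    """Read accepted heavy atoms from one model/chain of a PDB file.

    Only ATOM records are kept: HETATM lines (waters, ligands), hydrogens and
    alternate conformers other than blank/'A' are dropped. ``model_index`` is
    1-based and defaults to the first model (NMR ensembles contribute only one
    conformer). ``chain_id=None`` selects the first chain that yields atoms.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    EmptySelectionError
        if the requested model/chain has no accepted ATOM records.
    ValidationError
        if a selected residue carries an insertion code (not supported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    structure = gemmi.read_structure(str(path))
    if model_index < 1 or model_index > len(structure):
        raise EmptySelectionError(
            f"{path.name}: model {model_index} not present ({len(structure)} model(s))"
        )
    model = structure[model_index - 1]

    records: list[AtomRecord] = []
    for chain in model:
        if chain_id is not None and chain.name != chain_id:
            continue
        chain_records: list[AtomRecord] = []
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            accepted = [a for a in residue if _accept_atom(a)]
            if not accepted:
                continue
            if residue.seqid.icode not in (" ", "", "\0"):
                raise ValidationError(
                    f"{path.name}: residue {residue.name}{residue.seqid.num}"
                    f"{residue.seqid.icode.strip()} chain {chain.name} has an "
                    "insertion code; renumber the structure first"
                )
            for atom in accepted:
                chain_records.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        model_index=model_index,
                    )
                )
        if chain_records and chain_id is None:
            # default: first chain with accepted atoms
            return chain_records
        records.extend(chain_records)
    if not records:
        raise EmptySelectionError(
            f"{path.name}: no ATOM records for model {model_index}, "
            f"chain {chain_id if chain_id is not None else '<any>'}"
        )
    return records


def read_helix_annotations(path: str | Path) -> list[HelixAnnotation]:
    """Parse a helix-annotation file; see the module docstring for the dialect.

    Returns annotations sorted by ``helix_id``. Duplicate ids, inverted ranges
    and overlapping ranges on one chain raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    annotations: list[HelixAnnotation] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace(",", " ").split()
        if len(fields) != 4:
            raise ValidationError(
                f"{path.name}:{lineno}: expected 'helix_id chain start end', got {raw!r}"
            )
        try:
            helix_id, start, end = int(fields[0]), int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise ValidationError(f"{path.name}:{lineno}: non-integer field in {raw!r}") from exc
        annotations.append(HelixAnnotation(helix_id, fields[1], start, end))

    ids = [a.helix_id for a in annotations]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path.name}: duplicate helix_id(s) {dup}")
    annotations.sort(key=lambda a: a.helix_id)
    _check_no_overlap(annotations, str(path.name))
    return annotations


def _check_no_overlap(annotations: list[HelixAnnotation], context: str) -> None:
    by_chain: dict[str, list[HelixAnnotation]] = {}
    for ann in annotations:
        by_chain.setdefault(ann.chain_id, []).append(ann)
    for chain, anns in by_chain.items():
        anns = sorted(anns, key=lambda a: a.start_seq)
        for prev, cur in zip(anns, anns[1:]):
            if cur.start_seq <= prev.end_seq:
                raise ValidationError(
                    f"{context}: helices {prev.helix_id} and {cur.helix_id} "
                    f"overlap on chain {chain}"
                )


def write_helix_annotations(annotations: list[HelixAnnotation], path: str | Path) -> None:
    """Write annotations in the flat-text dialect read_helix_annotations accepts."""
    lines = ["# helix_id  chain  start_seq  end_seq"]
    for ann in sorted(annotations, key=lambda a: a.helix_id):
        lines.append(f"{ann.helix_id}  {ann.chain_id}  {ann.start_seq}  {ann.end_seq}")
    Path(path).write_text("\n".join(lines) + "\n")


def group_residues(
    atoms: list[AtomRecord], annotation: HelixAnnotation
) -> list[ResidueGroup]:
    """Group one helix's atoms per residue and split backbone from sidechain.

    Returns one :class:`ResidueGroup` per residue sequence number in the
    annotation's inclusive range, in sequence order. Backbone atoms are those
    named N, CA, C or O; every remaining heavy atom is sidechain (glycine
    yields an empty sidechain set). A residue missing from the chain, missing
    its CA, carrying a duplicate CA, or bearing a nonstandard residue name is
    a :class:`ValidationError`.
    """
    selected: dict[int, list[AtomRecord]] = {}
    for atom in atoms:
        if atom.chain_id != annotation.chain_id:
            continue
        if annotation.start_seq <= atom.residue_seq <= annotation.end_seq:
            selected.setdefault(atom.residue_seq, []).append(atom)

    groups: list[ResidueGroup] = []
    for seq in range(annotation.start_seq, annotation.end_seq + 1):
        if seq not in selected:
            raise ValidationError(
                f"helix {annotation.helix_id}: residue {seq} (chain "
                f"{annotation.chain_id}) absent from the structure"
            )
        res_atoms = selected[seq]
        names = {a.residue_name for a in res_atoms}
        if len(names) > 1:
            raise ValidationError(
                f"helix {annotation.helix_id}: residue {seq} has conflicting "
                f"residue names {sorted(names)}"
            )
        res_name = names.pop()
        if res_name not in STANDARD_RESIDUES:
            raise ValidationError(
                f"helix {annotation.helix_id}: nonstandard residue {res_name}{seq} "
                "inside the annotated range"
            )
        backbone = [a for a in res_atoms if a.atom_name in BACKBONE_ATOM_NAMES]
        sidechain = [a for a in res_atoms if a.atom_name not in BACKBONE_ATOM_NAMES]
        n_ca = sum(1 for a in backbone if a.atom_name == "CA")
        if n_ca != 1:
            raise ValidationError(
                f"helix {annotation.helix_id}: residue {res_name}{seq} has "
                f"{n_ca} CA atoms (expected exactly 1)"
            )
        groups.append(ResidueGroup(res_name, seq, backbone, sidechain))
    return groups


def helix_annotations_from_records(path: str | Path) -> list[HelixAnnotation]:
    """Derive annotations from the HELIX records of a PDB file.

    Convenience for structures whose header already assigns secondary
    structure; only helices of at least 4 residues are returned, numbered in
    file order per chain with overlapping records merged conservatively
    (first wins).
    """
    structure = gemmi.read_structure(str(path))
    annotations: list[HelixAnnotation] = []
    next_id = 1
    for helix in structure.helices:
        chain = helix.start.chain_name
        start = helix.start.res_id.seqid.num
        end = helix.end.res_id.seqid.num
        if chain != helix.end.chain_name or end - start + 1 < 4:
            continue
        candidate = HelixAnnotation(next_id, chain, start, end)
        try:
            _check_no_overlap(annotations + [candidate], str(path))
        except ValidationError:
            continue
        annotations.append(candidate)
        next_id += 1
    return annotations


def fetch_structure(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry by 4-character accession into ``dest_dir``.

    Network convenience only; the library never requires it.
    """
    pdb_id = pdb_id.strip().lower()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise ValidationError(f"not a 4-character PDB accession: {pdb_id!r}")
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=60) as response:
        dest.write_bytes(response.read())
    return dest
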