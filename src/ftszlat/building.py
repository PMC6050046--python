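"""Construction of lateral dimers and antiparallel protofilament sheets.

The sheet-model procedure mirrors how the crystallographic observations
are turned into a bundle model: (i) pull a laterally contacting subunit
pair out of the crystal lattice (a *lateral dimer*), (ii) graft that
pairing onto a straight template protofilament by main-chain
superposition of one dimer subunit onto a template subunit, so the
partner lands laterally beside the template filament, and (iii) tile a
subunit with a longitudinal screw (along the protofilament) and a
lateral transform (across protofilaments, flipping polymerization
direction) into an antiparallel sheet — four protofilaments of six
subunits in the published model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    MAIN_CHAIN,
    RigidTransform,
    paired_coordinates,
    screw_parameters,
    superpose,
)
from .interfaces import ResidueRef
from .structure import CrystalFrame, StructureError, StructureModel, SymmetryOperator
from .symmetry import apply_symmetry, cartesian_operator

__all__ = [
    "LateralDimer",
    "SheetModel",
    "INTERFACE_FACE_RESIDUES",
    "extract_lateral_dimer",
    "graft_by_superposition",
    "assemble_sheet",
    "clash_check",
]

#: Residues (MtbFtsZ numbering) defining the two lateral faces: interface 1
#: is the S7/S10-face Arg229–Asp301 salt-bridge patch, interface 2 the
#: charge-complementary H3/H4/H5 face.
INTERFACE_FACE_RESIDUES: dict[int, frozenset[int]] = {
    1: frozenset({229, 301}),
    2: frozenset({76, 77, 83, 119, 120, 80, 87, 153}),
}


@dataclass
class LateralDimer:
    """Two laterally contacting subunits plus the transform relating them."""

    model: StructureModel  # exactly two chains
    chain_a: str
    chain_b: str
    interface_id: int
    generating_transform: RigidTransform

    @property
    def subunit_a(self):
        return self.model.chains[self.chain_a]

    @property
    def subunit_b(self):
        return self.model.chains[self.chain_b]


@dataclass
class SheetModel:
    """An assembled multi-protofilament sheet with full provenance."""

    model: StructureModel
    protofilaments: list[list[str]]  # chain ids, [protofilament][subunit]
    orientations: list[int]  # +1 / -1, alternating for antiparallel sheets
    provenance: list[list[RigidTransform]]

    def replay(self, subunit: StructureModel) -> StructureModel:
        """Re-apply the recorded transforms to ``subunit``; must reproduce the sheet."""
        out = StructureModel(metadata={"replayed": True}, cell=subunit.cell)
        for i, row in enumerate(self.provenance):
            for j, transform in enumerate(row):
                placed = subunit.transformed(transform.rotation, transform.translation)
                for cid, residues in placed.chains.items():
                    out.add_chain(f"{cid}.{i}.{j}", residues)
        return out


def _contact_score(
    xyz_a: np.ndarray, xyz_b: np.ndarray, cutoff: float
) -> int:
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), cutoff)
    return sum(len(js) for js in pairs)


def _face_coords(model: StructureModel, chain: str, face: frozenset[int] | None) -> np.ndarray:
    pts = [
        a.coords
        for _, res, a in model.iter_atoms([chain])
        if (face is None or res.seq_id in face) and not res.het
    ]
    return np.vstack(pts) if pts else np.empty((0, 3))


def extract_lateral_dimer(
    model: StructureModel,
    cell: CrystalFrame | None = None,
    interface_id: int = 1,
    face_residues: frozenset[int] | None = None,
    contact_cutoff: float = 4.5,
    max_lattice_shift: int = 1,
) -> LateralDimer:
    """Find the symmetry mate forming the named lateral interface.

    Scans all cell operators over lattice shifts in
    ``[-max_lattice_shift, max_lattice_shift]³`` and scores every
    (reference chain, mate chain) pairing by the number of inter-atomic
    contacts within ``contact_cutoff`` between the expected face residues
    (``INTERFACE_FACE_RESIDUES[interface_id]`` unless overridden; pass an
    explicit set — or None for any-face scanning — for non-FtsZ models).
    Returns the best-buried pairing as a two-chain model with the
    Cartesian generating transform.
    """
    cell = cell or model.cell
    if cell is None:
        raise StructureError("no unit cell: cannot scan symmetry mates for a lateral dimer")
    if face_residues is None and interface_id in INTERFACE_FACE_RESIDUES:
        face_residues = INTERFACE_FACE_RESIDUES[interface_id]

    ref_coords = {c: _face_coords(model, c, face_residues) for c in model.chains}
    best = None  # (score, op_idx, shift, ref_chain, mate_chain, mate_model)
    for op_idx, op in enumerate(cell.operators):
        for shift in product(range(-max_lattice_shift, max_lattice_shift + 1), repeat=3):
            if op.is_identity and shift == (0, 0, 0):
                continue
            mate = apply_symmetry(model, op, cell, shift)
            for ref_chain, ref_xyz in ref_coords.items():
                for mate_chain in mate.chains:
                    score = _contact_score(
                        ref_xyz, _face_coords(mate, mate_chain, face_residues), contact_cutoff
                    )
                    if score == 0:
                        continue
                    key = (score, -op_idx, shift, ref_chain, mate_chain)
                    if best is None or key > best[0]:
                        best = (key, op, shift, ref_chain, mate_chain, mate)
    if best is None:
        raise StructureError(
            f"no symmetry mate buries contacts on the expected face of interface {interface_id}"
        )
    _, op, shift, ref_chain, mate_chain, mate = best
    R, t = cartesian_operator(op, cell, shift)
    dimer_model = StructureModel(metadata=dict(model.metadata), cell=cell)
    dimer_model.add_chain(ref_chain, model.subset([ref_chain]).chains[ref_chain])
    partner_id = f"{mate_chain}'"
    dimer_model.add_chain(partner_id, mate.subset([mate_chain]).chains[mate_chain])
    dimer_model.metadata["lateral_dimer"] = {
        "operator": op.triplet,
        "lattice_shift": tuple(shift),
        "interface_id": interface_id,
    }
    return LateralDimer(dimer_model, ref_chain, partner_id, interface_id, RigidTransform(R, t))


def _best_offset(chain_a, chain_b) -> int:
    """Seq-id offset maximizing the number of pairable residues."""
    ids_a = [r.seq_id for r in chain_a]
    ids_b = set(r.seq_id for r in chain_b)
    counts = Counter(b - a for a in ids_a for b in ids_b)
    offset, _ = max(counts.items(), key=lambda kv: (kv[1], -abs(kv[0])))
    return offset


def graft_by_superposition(
    dimer: LateralDimer,
    template_filament: StructureModel,
    anchor_subunit: str,
    selection: tuple[str, ...] = MAIN_CHAIN,
    rmsd_warn: float = 5.0,
    min_identity: float = 0.3,
) -> StructureModel:
    """Transplant a lateral pairing onto a template protofilament.

    Superposes the dimer's subunit A onto the anchor subunit of the
    template (main-chain atoms, residues paired at the seq-id offset that
    maximizes the number of pairs — sufficient for cross-species grafts
    without a sequence aligner) and applies that transform to the whole
    dimer.  The result is the template plus the laterally paired partner;
    the superposition rmsd is recorded, with a warning above
    ``rmsd_warn`` Å (crystal-contact grafts are approximate).
    """
    if anchor_subunit not in template_filament.chains:
        raise StructureError(f"anchor subunit {anchor_subunit!r} not in template")
    chain_a = dimer.subunit_a
    anchor = template_filament.chains[anchor_subunit]
    offset = _best_offset(chain_a, anchor)
    by_id = {r.seq_id: r.name for r in anchor}
    paired = [(r.name, by_id.get(r.seq_id + offset)) for r in chain_a
              if r.seq_id + offset in by_id]
    identity = sum(a == b for a, b in paired) / max(len(paired), 1)
    if identity < min_identity:
        raise StructureError(
            f"pairing failure grafting onto {anchor_subunit!r}: residue identity "
            f"{identity:.0%} below {min_identity:.0%} at best offset {offset}"
        )
    try:
        P, Q = paired_coordinates(chain_a, anchor, selection, offset=offset)
    except StructureError as exc:
        raise StructureError(f"pairing failure grafting onto {anchor_subunit!r}: {exc}") from exc
    transform, rmsd = superpose(P, Q)

    moved = dimer.model.transformed(transform.rotation, transform.translation)
    out = template_filament.copy()
    partner_id = dimer.chain_b
    while partner_id in out.chains:
        partner_id += "'"
    out.add_chain(partner_id, moved.chains[dimer.chain_b])
    out.metadata["graft"] = {
        "anchor": anchor_subunit,
        "partner": partner_id,
        "rmsd": rmsd,
        "offset": offset,
    }
    if rmsd > rmsd_warn:
        out.metadata.setdefault("warnings", []).append(
            f"graft rmsd {rmsd:.2f} Å exceeds {rmsd_warn} Å"
        )
    return out


def clash_check(model: StructureModel, cutoff: float = 2.2) -> list[tuple]:
    """All inter-chain heavy-atom pairs closer than ``cutoff`` Å.

    Returns a deterministically ordered list of
    ``(ResidueRef, atom_name, ResidueRef, atom_name, distance)``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    refs, coords = [], []
    for cid, res, atom in model.iter_atoms():
        if atom.element.upper() == "H":
            continue
        refs.append((ResidueRef(cid, res.seq_id, res.name), atom.name))
        coords.append(atom.coords)
    if not coords:
        return []
    coords = np.vstack(coords)
    out = []
    for i, j in cKDTree(coords).query_pairs(cutoff):
        (ra, na), (rb, nb) = refs[i], refs[j]
        if ra.chain == rb.chain:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        a, b = sorted([(ra, na), (rb, nb)])
        out.append((a[0], a[1], b[0], b[1], d))
    out.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    return out


def assemble_sheet(
    subunit: StructureModel,
    longitudinal: RigidTransform,
    lateral: RigidTransform,
    n_protofilaments: int,
    n_subunits: int,
    clash_cutoff: float = 2.2,
    clash_tolerance: float = 0.005,
) -> SheetModel:
    """Tile a subunit into an antiparallel protofilament sheet.

    Subunit (i, j) — protofilament i, position j — is placed by
    ``lateral^i ∘ longitudinal^j``.  For sheets of two or more
    protofilaments the lateral transform must reverse the longitudinal
    screw axis (antiparallel alternation); orientation flags record the
    alternation.  The assembly is rejected when more than
    ``clash_tolerance`` of its atoms sit in sub-``clash_cutoff``
    inter-chain contacts.
    """
    if n_protofilaments < 1 or n_subunits < 1:
        raise StructureError("sheet dimensions must be positive")
    if n_protofilaments >= 2:
        axis = screw_parameters(longitudinal).axis
        if (lateral.rotation @ axis) @ axis >= 0:
            raise StructureError(
                "lateral transform does not flip the protofilament axis; "
                "sheet would not be antiparallel"
            )

    out = StructureModel(metadata={"generator": "assemble_sheet"}, cell=subunit.cell)
    protofilaments: list[list[str]] = []
    provenance: list[list[RigidTransform]] = []
    lat_i = RigidTransform.identity()
    for i in range(n_protofilaments):
        row_ids: list[str] = []
        row_tf: list[RigidTransform] = []
        tf = lat_i
        for j in range(n_subunits):
            placed = subunit.transformed(tf.rotation, tf.translation)
            for cid, residues in placed.chains.items():
                new_id = f"{cid}.{i}.{j}"
                out.add_chain(new_id, residues)
                row_ids.append(new_id)
            row_tf.append(tf)
            tf = tf.compose(longitudinal)
        protofilaments.append(row_ids)
        provenance.append(row_tf)
        lat_i = lat_i.compose(lateral)

    if n_protofilaments * n_subunits > 1:
        clashes = clash_check(out, clash_cutoff)
        involved = {(p[0], p[1]) for p in clashes} | {(p[2], p[3]) for p in clashes}
        if len(involved) > clash_tolerance * out.n_atoms:
            raise StructureError(
                f"sheet assembly clashes: {len(clashes)} pairs involving "
                f"{len(involved)} atoms (cutoff {clash_cutoff} Å)"
            )
    orientations = [1 if i % 2 == 0 else -1 for i in range(n_protofilaments)]
    return SheetModel(out, protofilaments, orientations, provenance)
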