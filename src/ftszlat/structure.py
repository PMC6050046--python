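"""Atomic-coordinate containers and macromolecular file I/O.

The containers are deliberately small: a structure is a mapping of chain ids
to ordered residues, each residue an ordered list of heavy atoms in an
orthogonal Cartesian frame (Å).  Crystallographic context travels alongside
as a :class:`CrystalFrame` (unit cell + symmetry operators in fractional
coordinates).  Parsing and writing of PDB/mmCIF are delegated to gemmi;
everything downstream of this module works on the plain containers.
"""

from __future__ import annotations

import math
import urllib.request
import urllib.error
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "SymmetryOperator",
    "CrystalFrame",
    "StructureError",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "fetch_rcsb",
    "P6522_TRIPLETS",
]

#: The 12 symmetry operators of space group P6_5 2 2 as coordinate triplets
#: (International Tables standard setting, screw axis along c).  Hard-coded
#: because this is the lattice the protofilament models come from; the list
#: is validated for group closure in the test suite.
P6522_TRIPLETS: tuple[str, ...] = (
    "x,y,z",
    "x-y,x,z+5/6",
    "-y,x-y,z+2/3",
    "-x,-y,z+1/2",
    "-x+y,-x,z+1/3",
    "y,-x+y,z+1/6",
    "-y,-x,-z+1/6",
    "-x,-x+y,-z+1/3",
    "-x+y,y,-z+1/2",
    "y,x,-z+2/3",
    "x,x-y,-z+5/6",
    "x-y,-y,-z",
)

#: Standard amino-acid residue names (used to separate polymer from ligand).
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Invalid structure content or usage."""


class StructureParseError(StructureError):
    """A coordinate file could not be parsed."""


@dataclass
class Atom:
    """A single (heavy) atom in the orthogonal Å frame."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    serial: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue: 3-letter code, author sequence number, ordered atoms.

    Sequence numbering follows the source entry (e.g. MtbFtsZ numbering,
    where Arg229 and Asp301 are the lateral interface-1 salt-bridge pair).
    """

    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(f"residue {self.name}{self.seq_id}: duplicate atom names")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AMINO_ACIDS

    def coords(self, atom_names: Sequence[str] | None = None) -> np.ndarray:
        sel = self.atoms if atom_names is None else [a for a in self.atoms if a.name in atom_names]
        if not sel:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in sel])


@dataclass
class SymmetryOperator:
    """A crystallographic operator ``x -> R x + t`` in fractional coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOperator":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        return cls(rot, tran)

    @property
    def triplet(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(round(v * den)) for v in row] for row in self.rotation]
        op.tran = [int(round(v * den)) for v in self.translation]
        return op.triplet()

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """Return self ∘ other (apply ``other`` first)."""
        return SymmetryOperator(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def same_mod_lattice(self, other: "SymmetryOperator", tol: float = 1e-9) -> bool:
        if not np.allclose(self.rotation, other.rotation, atol=tol):
            return False
        dt = self.translation - other.translation
        return np.allclose(dt - np.round(dt), 0.0, atol=tol)

    @property
    def is_identity(self) -> bool:
        return self.same_mod_lattice(SymmetryOperator(np.eye(3), np.zeros(3))) and np.allclose(
            self.translation, 0.0
        )


def p6522_operators() -> list[SymmetryOperator]:
    """The built-in, closure-validated P6_5 2 2 operator list."""
    return [SymmetryOperator.from_triplet(t) for t in P6522_TRIPLETS]


@dataclass
class CrystalFrame:
    """Unit cell plus symmetry operators.

    Cell edges in Å, angles in degrees.  ``orthogonalization`` maps
    fractional to Cartesian Å coordinates (PDB standard convention,
    a along x, b in the xy plane).
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    spacegroup: str = "P 1"
    operators: list[SymmetryOperator] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell edges must be positive")
        if not self.operators:
            self.operators = [SymmetryOperator(np.eye(3), np.zeros(3))]
        if abs(self.volume) < 1e-3 * self.a * self.b * self.c:
            raise StructureError("degenerate unit cell (near-zero volume)")

    @classmethod
    def p6522(cls, a: float, c: float) -> "CrystalFrame":
        return cls(a, a, c, 90.0, 90.0, 120.0, "P 65 2 2", p6522_operators())

    @property
    def orthogonalization(self) -> np.ndarray:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(0.0, 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization))

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orthogonalization.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth) @ self.fractionalization.T


@dataclass
class StructureModel:
    """Chains → residues → atoms, plus provenance metadata and cell."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    cell: CrystalFrame | None = None

    def validate(self) -> None:
        if not self.chains or not any(self.chains.values()):
            raise StructureError("structure has no residues")
        if len(set(self.chains)) != len(self.chains):
            raise StructureError("duplicate chain ids")

    # -- iteration / selection -------------------------------------------------

    def iter_atoms(
        self,
        chains: Iterable[str] | None = None,
        atom_names: Sequence[str] | None = None,
        amino_only: bool = False,
    ) -> Iterator[tuple[str, Residue, Atom]]:
        chain_ids = list(self.chains) if chains is None else list(chains)
        for cid in chain_ids:
            for res in self.chains[cid]:
                if amino_only and not res.is_amino_acid:
                    continue
                for atom in res.atoms:
                    if atom_names is not None and atom.name not in atom_names:
                        continue
                    yield cid, res, atom

    def coords(
        self,
        chains: Iterable[str] | None = None,
        atom_names: Sequence[str] | None = None,
        amino_only: bool = False,
    ) -> np.ndarray:
        pts = [a.coords for _, _, a in self.iter_atoms(chains, atom_names, amino_only)]
        return np.vstack(pts) if pts else np.empty((0, 3))

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)

    def residue(self, chain_id: str, seq_id: int) -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.seq_id == seq_id:
                return res
        raise StructureError(f"residue {chain_id}/{seq_id} not found")

    # -- construction helpers --------------------------------------------------

    def subset(self, chains: Iterable[str]) -> "StructureModel":
        chains = list(chains)
        missing = [c for c in chains if c not in self.chains]
        if missing:
            raise StructureError(f"chains not in model: {missing}")
        return StructureModel(
            {c: [_copy_residue(r) for r in self.chains[c]] for c in chains},
            dict(self.metadata),
            self.cell,
        )

    def copy(self) -> "StructureModel":
        return self.subset(self.chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A rigid-body copy: every coordinate mapped by ``R x + t``."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, _, atom in out.iter_atoms():
            atom.coords = R @ atom.coords + t
        return out

    def add_chain(self, chain_id: str, residues: list[Residue]) -> None:
        if chain_id in self.chains:
            raise StructureError(f"duplicate chain id {chain_id!r}")
        self.chains[chain_id] = residues

    def merged_with(self, other: "StructureModel") -> "StructureModel":
        out = self.copy()
        for cid, residues in other.chains.items():
            out.add_chain(cid, [_copy_residue(r) for r in residues])
        return out


def _copy_residue(res: Residue) -> Residue:
    return Residue(
        res.name,
        res.seq_id,
        [Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.serial) for a in res.atoms],
        res.het,
    )


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in {"pdb", "mmcif"}:
            raise StructureError(f"unknown format {format!r}; use 'pdb' or 'mmcif'")
        return format
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    raise StructureError(f"cannot infer format from {path.name!r}; pass format=")


def read_structure(
    path: str | Path,
    format: str | None = None,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is kept.  Alternate
    conformers are collapsed to the highest-occupancy copy so that
    downstream surface areas are single-conformer.  Hydrogens and waters
    are dropped unless requested.  Zero-occupancy atoms are dropped.
    The unit cell and symmetry operators populate ``model.cell`` when the
    file carries them.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path.name}: no coordinate model found")

    model = StructureModel(metadata={"source": str(path), "entry_id": st.name.upper()})
    gm = st[0]
    for chain in gm:
        residues: list[Residue] = []
        for gres in chain:
            if not keep_waters and gres.name in WATER_NAMES:
                continue
            # collapse altlocs: keep the highest-occupancy atom per name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.is_hydrogen() and not keep_hydrogens:
                    continue
                if ga.occ <= 0:
                    continue
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            if not best:
                continue
            atoms = [
                Atom(
                    ga.name,
                    ga.element.name,
                    np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    min(float(ga.occ), 1.0),
                    int(ga.serial),
                )
                for ga in best.values()
            ]
            residues.append(
                Residue(gres.name, gres.seqid.num, atoms, het=gres.name not in AMINO_ACIDS)
            )
        if residues:
            model.chains[chain.name] = residues

    if not model.chains:
        raise StructureParseError(f"{path.name}: no atoms found")
    model.validate()

    cell = st.cell
    if cell.a > 1.0 and cell.volume > 1.0:  # gemmi uses a 1 Å dummy cell when absent
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
        ops: list[SymmetryOperator] = []
        if sg is not None:
            for op in sg.operations():
                ops.append(
                    SymmetryOperator(
                        np.array(op.rot, dtype=float) / op.DEN,
                        np.array(op.tran, dtype=float) / op.DEN,
                    )
                )
        model.cell = CrystalFrame(
            cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma,
            st.spacegroup_hm or "P 1", ops,
        )
    return model


#: Single-character chain ids available in the PDB dialect, in fallback order.
PDB_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_structure(model: StructureModel, path: str | Path, format: str | None = None) -> Path:
    """Write the model as PDB or mmCIF; returns the path written.

    PDB output requires single-character chain ids; models with more than
    62 chains (or long ids that cannot be remapped uniquely) must go to
    mmCIF.  Any remapping applied is recorded in
    ``model.metadata['pdb_chain_map']``.
    """
    path = Path(path)
    model.validate()
    if model.n_atoms == 0:
        raise StructureError("refusing to write a model with no atoms")
    fmt = _infer_format(path, format)

    chain_ids = list(model.chains)
    if fmt == "pdb":
        if len(chain_ids) > len(PDB_CHAIN_IDS):
            raise StructureError(
                f"{len(chain_ids)} chains exceed the 62 single-character ids of the "
                "PDB dialect; write mmCIF instead"
            )
        if all(len(c) == 1 for c in chain_ids):
            chain_map = {c: c for c in chain_ids}
        else:
            chain_map = {c: PDB_CHAIN_IDS[i] for i, c in enumerate(chain_ids)}
            model.metadata["pdb_chain_map"] = dict(chain_map)
    else:
        chain_map = {c: c for c in chain_ids}

    st = gemmi.Structure()
    st.name = str(model.metadata.get("entry_id", "XXXX"))
    if model.cell is not None:
        st.cell = gemmi.UnitCell(
            model.cell.a, model.cell.b, model.cell.c,
            model.cell.alpha, model.cell.beta, model.cell.gamma,
        )
        st.spacegroup_hm = model.cell.spacegroup
    gm = gemmi.Model("1")
    serial = 0
    for cid, residues in model.chains.items():
        gchain = gemmi.Chain(chain_map[cid])
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.serial = serial
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()

    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def fetch_rcsb(entry_id: str, cache_dir: str | Path | None = None, timeout: float = 30.0) -> Path:
    """Download an mmCIF coordinate file from the RCSB PDB, with caching.

    The file lands in ``cache_dir`` (default ``~/.cache/ftszlat``) and the
    cached copy is reused on subsequent calls.  Raises ``OSError`` when the
    archive is unreachable.
    """
    entry_id = entry_id.lower()
    if len(entry_id) != 4 or not entry_id.isalnum():
        raise StructureError(f"invalid PDB entry id {entry_id!r}")
    cache = Path(cache_dir) if cache_dir is not None else Path.home() / ".cache" / "ftszlat"
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{entry_id}.cif"
    if dest.exists() and dest.stat().st_size > 0:
        return dest
    url = f"https://files.rcsb.org/download/{entry_id.upper()}.cif"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, TimeoutError, OSError) as exc:
        raise OSError(
            f"could not fetch PDB entry {entry_id.upper()} from {url}: {exc}"
        ) from exc
    dest.write_bytes(data)
    return dest
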