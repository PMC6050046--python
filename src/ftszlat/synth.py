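"""Synthetic fixtures: helical filaments, screw-symmetric crystals, planted
contact dimers and simulation configs.

Subunits are small rigid pseudo-atom clusters carrying real atom/residue
names, so that every downstream code path (superposition on main-chain
atoms, SASA, salt-bridge detection) runs exactly as it would on a real
structure, at a tiny fraction of the cost.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import (
    Atom,
    CrystalFrame,
    PDB_CHAIN_IDS,
    Residue,
    StructureError,
    StructureModel,
)
from .zring import ZRingSimConfig

__all__ = [
    "HelixSpec",
    "ContactSpec",
    "default_subunit",
    "make_helical_filament",
    "make_crystal_fixture",
    "make_contact_dimer",
    "make_sim_fixture",
]


def default_subunit(origin=(8.0, 0.0, 0.0)) -> list[Residue]:
    """A compact, asymmetric, non-coplanar 3-residue pseudo-subunit.

    Each residue carries the four main-chain atoms so superposition-based
    pitch extraction works on it; the cluster sits off the z axis (at
    ``origin``) so rotations about z displace it.
    """
    origin = np.asarray(origin, dtype=float)
    # local main-chain geometry: loosely peptide-like, deliberately asymmetric
    local = [
        ("GLY", [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.45, 0.2, 0.1)),
                 ("C", "C", (2.2, 1.3, 0.9)), ("O", "O", (2.0, 2.5, 0.7))]),
        ("ALA", [("N", "N", (3.4, 1.0, 1.5)), ("CA", "C", (4.6, 1.8, 1.8)),
                 ("C", "C", (5.3, 1.2, 3.0)), ("O", "O", (5.1, 0.0, 3.3)),
                 ("CB", "C", (5.5, 3.0, 1.3))],),
        ("SER", [("N", "N", (6.2, 2.0, 3.8)), ("CA", "C", (7.0, 1.6, 4.9)),
                 ("C", "C", (8.4, 2.2, 4.8)), ("O", "O", (8.8, 3.0, 5.7)),
                 ("OG", "O", (6.4, 2.1, 6.2))],),
    ]
    residues = []
    for i, (name, atoms) in enumerate(local, start=1):
        residues.append(
            Residue(
                name,
                i,
                [Atom(an, el, origin + np.asarray(xyz)) for an, el, xyz in atoms],
            )
        )
    return residues


@dataclass
class HelixSpec:
    """An idealized helical filament: twist (deg) and rise (Å) per subunit."""

    twist: float
    rise: float
    n_subunits: int
    subunit_template: list[Residue] | None = None
    jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.twist == 0.0:
            raise StructureError("twist = 0 defines no helix (pitch undefined)")
        if self.n_subunits < 1:
            raise StructureError("need at least one subunit")
        if self.jitter_sigma < 0:
            raise StructureError("jitter_sigma must be >= 0")

    @property
    def pitch(self) -> float:
        return self.rise * 360.0 / self.twist


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_helical_filament(spec: HelixSpec, seed: int | None = None) -> StructureModel:
    """Build a filament along z: subunit j twisted j·twist and raised j·rise.

    Optional Gaussian coordinate jitter (``spec.jitter_sigma``, Å) is
    applied independently per atom, seeded.
    """
    rng = np.random.default_rng(seed)
    template = spec.subunit_template or default_subunit()
    base = StructureModel({"T": template})
    model = StructureModel(metadata={"generator": "make_helical_filament", "seed": seed})
    for j in range(spec.n_subunits):
        R = _rot_z(j * spec.twist)
        t = np.array([0.0, 0.0, j * spec.rise])
        sub = base.transformed(R, t)
        residues = sub.chains["T"]
        if spec.jitter_sigma > 0:
            for res in residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(0.0, spec.jitter_sigma, 3)
        model.add_chain(PDB_CHAIN_IDS[j % len(PDB_CHAIN_IDS)] * (1 + j // len(PDB_CHAIN_IDS)),
                        residues)
    return model


def make_crystal_fixture(c: float, a: float = 100.5) -> tuple[StructureModel, CrystalFrame]:
    """One pseudo-subunit in a P6_5 2 2 cell whose 6-fold screw runs along c.

    Expanding the subunit with the cell's screw generator (lattice shift
    (0, 0, -1) to keep neighbours adjacent) yields a helical filament of
    rise c/6 and twist 60°, i.e. pitch exactly c.
    """
    if a <= 0 or c <= 0:
        raise StructureError("cell edges must be positive")
    cell = CrystalFrame.p6522(a, c)
    subunit = StructureModel(
        {"A": default_subunit(origin=(a / 4.0, a / 10.0, c / 20.0))},
        metadata={"generator": "make_crystal_fixture"},
        cell=cell,
    )
    return subunit, cell


#: Minimal side-chain templates: (atom, element, local xyz), tip last at x-max.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": [("N", "N", (-3.8, 0.3, 0.2)), ("CA", "C", (-2.9, -0.5, -0.5)),
            ("C", "C", (-3.2, -2.0, -0.4)), ("O", "O", (-4.2, -2.4, 0.2)),
            ("CB", "C", (-1.5, -0.2, 0.0))],
    "LEU": [("N", "N", (-4.6, 0.4, 0.3)), ("CA", "C", (-3.8, -0.4, -0.5)),
            ("C", "C", (-4.1, -1.9, -0.3)), ("O", "O", (-5.1, -2.3, 0.3)),
            ("CB", "C", (-2.4, -0.1, -0.1)), ("CG", "C", (-1.3, -0.9, -0.8)),
            ("CD1", "C", (-0.1, -0.9, 0.1)), ("CD2", "C", (-1.7, -2.3, -1.1))],
    "LYS": [("N", "N", (-6.4, 0.4, 0.3)), ("CA", "C", (-5.6, -0.4, -0.5)),
            ("C", "C", (-5.9, -1.9, -0.3)), ("O", "O", (-6.9, -2.3, 0.3)),
            ("CB", "C", (-4.2, -0.1, -0.1)), ("CG", "C", (-3.1, -0.9, -0.8)),
            ("CD", "C", (-1.7, -0.6, -0.3)), ("CE", "C", (-0.7, -1.5, -1.0)),
            ("NZ", "N", (0.0, 0.0, 0.0))],
    "ARG": [("N", "N", (-7.0, 0.4, 0.3)), ("CA", "C", (-6.2, -0.4, -0.5)),
            ("C", "C", (-6.5, -1.9, -0.3)), ("O", "O", (-7.5, -2.3, 0.3)),
            ("CB", "C", (-4.8, -0.1, -0.1)), ("CG", "C", (-3.7, -0.9, -0.8)),
            ("CD", "C", (-2.3, -0.6, -0.3)), ("NE", "N", (-1.9, 0.8, -0.6)),
            ("CZ", "C", (-0.9, 0.7, 0.2)), ("NH1", "N", (0.0, 0.0, 0.0)),
            ("NH2", "N", (-0.8, 1.7, 1.1))],
    "GLU": [("N", "N", (-5.4, 0.4, 0.3)), ("CA", "C", (-4.6, -0.4, -0.5)),
            ("C", "C", (-4.9, -1.9, -0.3)), ("O", "O", (-5.9, -2.3, 0.3)),
            ("CB", "C", (-3.2, -0.1, -0.1)), ("CG", "C", (-2.1, -0.9, -0.8)),
            ("CD", "C", (-0.9, -0.8, 0.0)), ("OE1", "O", (0.0, 0.0, 0.0)),
            ("OE2", "O", (-0.9, -1.6, 1.0))],
    "ASP": [("N", "N", (-4.3, 0.4, 0.3)), ("CA", "C", (-3.5, -0.4, -0.5)),
            ("C", "C", (-3.8, -1.9, -0.3)), ("O", "O", (-4.8, -2.3, 0.3)),
            ("CB", "C", (-2.1, -0.1, -0.1)), ("CG", "C", (-1.0, -0.9, -0.7)),
            ("OD1", "O", (0.0, 0.0, 0.0)), ("OD2", "O", (-1.1, -1.8, -1.5))],
}


@dataclass
class ContactSpec:
    """Planted inter-chain contacts: (residue A, residue B, target min distance Å)."""

    pairs: list[tuple[str, str, float]]
    spacing: float = 12.0  # Å between planted pairs along the interface
    min_clearance: float = 2.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise StructureError("need at least one planted pair")
        for ra, rb, d in self.pairs:
            if ra not in _RESIDUE_TEMPLATES or rb not in _RESIDUE_TEMPLATES:
                raise StructureError(f"no template for residue pair {ra}-{rb}")
            if d <= self.min_clearance:
                raise StructureError(
                    f"target distance {d} Å below clearance {self.min_clearance} Å"
                )


def _place_residue(name: str, seq_id: int, tip_target: np.ndarray, direction: float) -> Residue:
    """Instantiate a residue template with its tip atom at ``tip_target``.

    ``direction`` = +1 points the side chain along +x (body at -x), -1 the
    mirror (rotated 180° about z, keeping chirality-free pseudo-geometry).
    """
    template = _RESIDUE_TEMPLATES[name]
    # the tip is the template's x-extreme atom, so every other atom lies behind
    # it and the inter-residue minimum distance is exactly tip-to-tip
    tip_name = max(template, key=lambda a: a[2][0])[0]
    tip_local = dict((an, np.asarray(xyz)) for an, _, xyz in template)[tip_name]
    flip = np.diag([direction, direction, 1.0])
    atoms = []
    for an, el, xyz in template:
        pos = flip @ (np.asarray(xyz) - tip_local) + tip_target
        atoms.append(Atom(an, el, pos))
    return Residue(name, seq_id, atoms)


def make_contact_dimer(spec: ContactSpec, seed: int | None = None) -> StructureModel:
    """Two chains with each planted residue pair at its target min distance.

    Pair k sits at y = k·spacing; the A-side residue body extends to -x,
    the B side to +x, with the charged-group tip atoms facing each other
    across the gap so the minimum inter-residue distance equals the
    tip–tip distance.  Raises when the construction cannot realise every
    target (contacts closer than the clearance, or planted distances off
    by more than 0.01 Å).
    """
    chain_a: list[Residue] = []
    chain_b: list[Residue] = []
    for k, (ra, rb, d) in enumerate(spec.pairs):
        y = k * spec.spacing
        chain_a.append(_place_residue(ra, k + 1, np.array([-d / 2.0, y, 0.0]), +1.0))
        chain_b.append(_place_residue(rb, k + 1, np.array([d / 2.0, y, 0.0]), -1.0))
    model = StructureModel(
        {"A": chain_a, "B": chain_b},
        metadata={"generator": "make_contact_dimer", "seed": seed},
    )
    # verify every planted distance and the clash clearance
    for k, (ra, rb, d) in enumerate(spec.pairs):
        xa = model.chains["A"][k].coords()
        xb = model.chains["B"][k].coords()
        dmin = float(np.min(np.linalg.norm(xa[:, None] - xb[None, :], axis=-1)))
        if abs(dmin - d) > 0.01:
            raise StructureError(
                f"infeasible contact spec: pair {k} realised at {dmin:.3f} Å, wanted {d} Å"
            )
    all_a = model.coords(chains=["A"])
    all_b = model.coords(chains=["B"])
    dmat = np.linalg.norm(all_a[:, None] - all_b[None, :], axis=-1)
    floor = min(d for _, _, d in spec.pairs)
    if dmat.min() < min(spec.min_clearance, floor) - 1e-9:
        raise StructureError("infeasible contact spec: chains clash below clearance")
    return model


def make_sim_fixture(name: str) -> ZRingSimConfig:
    """Named Z-ring simulation configs.

    ``paper_default``: the study conditions (200 protofilaments × 50
    subunits, probabilities 0.01/0.99, 10,000 replicates, f = 0.4,
    T = 10 so f_c = 0.2).  ``tiny_oracle``: a 2 × 3 instance small enough
    for exact enumeration, run deep (10⁶ replicates).
    """
    if name == "paper_default":
        return ZRingSimConfig()
    if name == "tiny_oracle":
        return ZRingSimConfig(
            n_protofilaments=2,
            subunits_per_protofilament=3,
            f=0.5,
            T=1,
            n_reps=1_000_000,
        )
    raise ValueError(f"unknown simulation fixture {name!r}")
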