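"""Rigid-body superposition and helical (screw) parameters of protofilaments.

A protofilament built by a screw operation is summarised by three numbers:
the twist per subunit (deg), the rise per subunit (Å along the screw axis)
and the derived pitch, the axial distance per full turn,

    pitch = rise * 360 / twist .

The screw is recovered either from the crystal symmetry (a 6_5 screw along
c repeats every cell, so pitch = c) or from least-squares superposition of
consecutive subunits; for lattice-generated filaments the two routes must
agree, and the test suite uses that agreement as an internal check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import CrystalFrame, Residue, StructureModel, StructureError

__all__ = [
    "MAIN_CHAIN",
    "RigidTransform",
    "ScrewParameters",
    "FilamentPitchResult",
    "superpose",
    "paired_coordinates",
    "screw_parameters",
    "filament_pitch",
    "pitch_from_screw_symmetry",
]

#: Default main-chain atom selection for superposition.
MAIN_CHAIN: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (rotation then translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or not np.allclose(
            R @ R.T, np.eye(3), atol=1e-6
        ):
            raise ValueError("rotation must be proper-orthogonal (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class ScrewParameters:
    """Screw decomposition of a rigid transform.

    ``axis`` is a unit vector chosen so that ``rise >= 0``; ``angle`` is in
    degrees in (0, 180]; ``pitch = rise * 360 / angle``.
    """

    axis: np.ndarray
    angle: float
    rise: float
    point_on_axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        self.point_on_axis = np.asarray(self.point_on_axis, dtype=float).reshape(3)

    @property
    def pitch(self) -> float:
        return self.rise * 360.0 / self.angle


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of paired coordinates.

    Returns the proper-rotation transform mapping ``mobile`` onto
    ``target`` with minimum RMSD, and that RMSD (Å).  Requires at least
    three non-collinear pairs; reflections are never returned.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"paired coordinate sets required, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("mobile coordinates are collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def paired_coordinates(
    chain_a: list[Residue],
    chain_b: list[Residue],
    selection: tuple[str, ...] = MAIN_CHAIN,
    offset: int = 0,
    min_shared: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms of two chains by residue number (``seq_id_b = seq_id_a + offset``).

    Within each residue pair only atoms named in ``selection`` and present
    on both sides are paired.  Raises when fewer than ``min_shared`` of the
    smaller chain's residues can be paired, naming the first mismatch.
    """
    by_id_a = {r.seq_id: r for r in chain_a}
    by_id_b = {r.seq_id: r for r in chain_b}
    shared = sorted(set(by_id_a) & {s - offset for s in by_id_b})
    smaller = min(len(by_id_a), len(by_id_b))
    if smaller == 0 or len(shared) / smaller < min_shared:
        first_a = min(by_id_a) if by_id_a else None
        raise StructureError(
            f"chains share {len(shared)}/{smaller} residues at offset {offset} "
            f"(first mobile residue {first_a}); cannot pair"
        )
    pa, pb = [], []
    for sid in shared:
        ra, rb = by_id_a[sid], by_id_b[sid + offset]
        for name in selection:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                pa.append(aa.coords)
                pb.append(ab.coords)
    if len(pa) < 3:
        raise StructureError("fewer than 3 paired atoms after selection")
    return np.vstack(pa), np.vstack(pb)


def screw_parameters(t: RigidTransform, angle_tolerance: float = 0.1) -> ScrewParameters:
    """Decompose a rigid transform into its screw axis, twist, rise and pitch.

    The axis is the rotation's invariant direction, flipped so that the
    rise (the translation component along the axis) is non-negative.
    Near-identity rotations (twist below ``angle_tolerance`` degrees) have
    no defined screw axis and are rejected.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < angle_tolerance:
        raise ValueError(
            f"rotation angle {angle:.4g} deg below tolerance {angle_tolerance}; no screw axis"
        )
    axis = rotvec / np.linalg.norm(rotvec)
    rise = float(t.translation @ axis)
    if rise < 0:
        axis, rise = -axis, -rise
        # angle about the flipped axis is the same magnitude; convention keeps it in (0, 180]
    # point on axis: (I - R) p = t_perp, solved in the plane orthogonal to the axis
    t_perp = t.translation - (t.translation @ axis) * axis
    point, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    return ScrewParameters(axis, angle, rise, point)


@dataclass
class FilamentPitchResult:
    """Averaged screw description of a filament, with per-pair dispersion."""

    screw: ScrewParameters
    pair_pitches: list[float]
    pair_rmsds: list[float]

    @property
    def pitch(self) -> float:
        return self.screw.pitch

    @property
    def pitch_sd(self) -> float:
        return float(np.std(self.pair_pitches))


def filament_pitch(
    filament: StructureModel,
    subunit_order: list[str] | None = None,
    selection: tuple[str, ...] = MAIN_CHAIN,
) -> FilamentPitchResult:
    """Helical parameters of a filament from consecutive-subunit superposition.

    Consecutive subunits (in ``subunit_order``, default the model's chain
    order) are paired on ``selection`` atoms and superposed; the screw
    parameters are averaged over pairs after flipping all axes into the
    hemisphere of the first, and the spread of per-pair pitches is
    reported as the dispersion.
    """
    order = list(filament.chains) if subunit_order is None else subunit_order
    if len(order) < 2:
        raise StructureError("need at least 2 subunits to measure a pitch")
    screws: list[ScrewParameters] = []
    rmsds: list[float] = []
    for a, b in zip(order, order[1:]):
        P, Q = paired_coordinates(filament.chains[a], filament.chains[b], selection)
        transform, rmsd = superpose(P, Q)
        screws.append(screw_parameters(transform))
        rmsds.append(rmsd)
    ref_axis = screws[0].axis
    axes, rises = [], []
    for s in screws:
        flip = -1.0 if s.axis @ ref_axis < 0 else 1.0
        axes.append(flip * s.axis)
        rises.append(flip * s.rise)
    mean_axis = np.mean(axes, axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    mean_angle = float(np.mean([s.angle for s in screws]))
    mean_rise = float(np.mean(rises))
    if mean_rise < 0:
        mean_axis, mean_rise = -mean_axis, -mean_rise
    mean = ScrewParameters(mean_axis, mean_angle, mean_rise, screws[0].point_on_axis)
    return FilamentPitchResult(mean, [s.pitch for s in screws], rmsds)


def pitch_from_screw_symmetry(
    cell: CrystalFrame, screw_fold: int, screw_translation_fraction
) -> float:
    """Pitch of the helix generated by an n_m screw axis along c.

    A single-start n_m screw (gcd(n, m) = 1) places one subunit every
    c/n along the axis with a twist of 360/n degrees, so the helix repeats
    exactly once per cell: pitch = c.  Multi-start screws (gcd > 1) and
    folds outside the crystallographic set are rejected.
    """
    if screw_fold not in (2, 3, 4, 6):
        raise ValueError(f"unsupported screw fold {screw_fold}")
    frac = Fraction(screw_translation_fraction).limit_denominator(12)
    if frac.denominator != screw_fold or not 0 < frac.numerator < screw_fold:
        raise ValueError(
            f"translation fraction {frac} does not define a {screw_fold}-fold screw"
        )
    if math.gcd(frac.numerator, screw_fold) != 1:
        raise ValueError("multi-start screw; axial repeat is not the full-cell pitch")
    return float(cell.c)
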