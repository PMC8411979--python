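"""Base reference frames and "simple" base-pair parameters.

Each observed base gets an orthonormal frame by least-squares
superposition of the standard (Tsukuba-convention) base geometry onto
its ring atoms.  A Watson–Crick pair is then described by six *simple*
parameters expressed in a pair frame whose y axis follows the C1′–C1′
vector and whose z axis is the mean base normal:

* shear, stretch, stagger — displacement of base I relative to base J
  along the pair x, y, z axes (Å);
* buckle, propeller — the hinge decomposition of the interbase angle γ
  along x and y, so that buckle² + propeller² = γ² (degrees);
* opening — signed in-plane angle between the two y axes (degrees).

Base J is the anti-parallel partner: its y and z axes are negated
before any of the above is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .model import PURINE_RING, PYRIMIDINE_RING, Residue

__all__ = [
    "BaseFrame", "StandardBase", "SimpleParams", "HBondMeasure",
    "superpose", "base_frame", "simple_parameters", "hbond_lengths",
    "load_standard_bases", "HBOND_ATOMS", "IncompleteBaseError",
    "NotPairableError",
]

#: Watson–Crick hydrogen-bond heavy-atom pairs, purine atom first (the
#: 2 bonds of A–T / A–U and the 3 bonds of G–C).
HBOND_ATOMS: dict[str, tuple[tuple[str, str], ...]] = {
    "A-T": (("N1", "N3"), ("N6", "O4")),
    "A-U": (("N1", "N3"), ("N6", "O4")),
    "G-C": (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
}


class IncompleteBaseError(ValueError):
    """A required ring atom is missing, so no frame can be fitted."""


class NotPairableError(ValueError):
    """Base normals are anti-aligned beyond 90° after strand flipping."""


@dataclass(frozen=True)
class StandardBase:
    base: str
    ring_atom_names: tuple[str, ...]
    coords: dict[str, np.ndarray]  # all standard atoms incl. C1' and WC edge

    def ring_coords(self) -> np.ndarray:
        return np.array([self.coords[n] for n in self.ring_atom_names])


@dataclass(frozen=True)
class BaseFrame:
    origin: np.ndarray        # (3,) Å
    axes: np.ndarray          # 3×3, columns are the x, y, z unit vectors
    fit_rmsd: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axes, dtype=float)
        if not np.allclose(a.T @ a, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(a) < 0:
            raise ValueError("frame axes are left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


@dataclass(frozen=True)
class SimpleParams:
    shear: float      # Å
    stretch: float    # Å
    stagger: float    # Å
    buckle: float     # °
    propeller: float  # °
    opening: float    # °

    def as_dict(self) -> dict[str, float]:
        return {
            "shear": self.shear, "stretch": self.stretch, "stagger": self.stagger,
            "buckle": self.buckle, "propeller": self.propeller, "opening": self.opening,
        }


@dataclass(frozen=True)
class HBondMeasure:
    atom_i: str
    atom_j: str
    distance: float | None  # Å; None when an atom is missing
    missing: bool = False


def load_standard_bases() -> dict[str, StandardBase]:
    """Load the embedded Tsukuba-convention standard base coordinates."""
    bases: dict[str, dict[str, np.ndarray]] = {}
    text = resources.files("bpval.data").joinpath("standard_bases.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        base, atom, x, y, z = line.split("\t")
        bases.setdefault(base, {})[atom] = np.array([float(x), float(y), float(z)])
    out = {}
    for base, coords in bases.items():
        ring = PURINE_RING if base in ("A", "G") else PYRIMIDINE_RING
        out[base] = StandardBase(base=base, ring_atom_names=tuple(ring), coords=coords)
    return out


_STANDARD_BASES: dict[str, StandardBase] | None = None


def standard_bases() -> dict[str, StandardBase]:
    global _STANDARD_BASES
    if _STANDARD_BASES is None:
        _STANDARD_BASES = load_standard_bases()
    return _STANDARD_BASES


def superpose(reference: Sequence[np.ndarray],
              observed: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with ``observed ≈ R @ reference + t`` and
    ``R`` a proper rotation (det = +1).
    """
    ref = np.asarray(reference, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if ref.shape != obs.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be equal-length lists of 3-vectors")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    h = ref_c.T @ obs_c
    u, s, vt = np.linalg.svd(h)
    # rank-deficient cross-covariance = collinear/degenerate geometry
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = obs.mean(axis=0) - rot @ ref.mean(axis=0)
    resid = obs - (ref @ rot.T + t)
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return rot, t, rmsd


def base_frame(residue: Residue,
               standards: dict[str, StandardBase] | None = None) -> BaseFrame:
    """Fit the standard base onto the observed ring atoms.

    The returned frame is the standard reference frame carried through
    the superposition; z points to the face from which the base appears
    counter-clockwise.
    """
    standards = standards or standard_bases()
    if residue.parent_base in ("none", None):
        raise IncompleteBaseError(f"{residue.label()}: not a nucleobase")
    std = standards[residue.parent_base]
    obs = []
    for name in std.ring_atom_names:
        atom = residue.atom(name)
        if atom is None:
            raise IncompleteBaseError(f"{residue.label()}: missing ring atom {name}")
        obs.append(atom.position)
    rot, t, rmsd = superpose(std.ring_coords(), obs)
    return BaseFrame(origin=t, axes=rot, fit_rmsd=rmsd)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def simple_parameters(frame_i: BaseFrame, frame_j: BaseFrame,
                      c1_i: np.ndarray, c1_j: np.ndarray) -> SimpleParams:
    """Six simple parameters of base I relative to its anti-parallel
    partner J, in the C1′–C1′ pair frame.

    Raises :class:`NotPairableError` when the aligned base normals
    subtend more than 90°.
    """
    zi = frame_i.z
    zj = -frame_j.z            # anti-parallel alignment
    yj = -frame_j.y
    cosg = float(np.clip(zi @ zj, -1.0, 1.0))
    gamma = np.degrees(np.arccos(cosg))
    if gamma > 90.0:
        raise NotPairableError(f"interbase angle {gamma:.1f}° > 90°")

    z = _unit(zi + zj)
    y_raw = np.asarray(c1_i, dtype=float) - np.asarray(c1_j, dtype=float)
    y = y_raw - (y_raw @ z) * z
    y = _unit(y)
    x = np.cross(y, z)

    delta = frame_i.origin - frame_j.origin
    shear, stretch, stagger = float(delta @ x), float(delta @ y), float(delta @ z)

    hinge = np.cross(zj, zi)
    if np.linalg.norm(hinge) < 1e-12:
        buckle = propeller = 0.0
    else:
        a = _unit(hinge)
        buckle = gamma * float(a @ x)
        propeller = gamma * float(a @ y)

    yi_p = _unit(frame_i.y - (frame_i.y @ z) * z)
    yj_p = _unit(yj - (yj @ z) * z)
    opening = float(np.degrees(np.arctan2(np.cross(yj_p, yi_p) @ z, yj_p @ yi_p)))

    return SimpleParams(shear=shear, stretch=stretch, stagger=stagger,
                        buckle=buckle, propeller=propeller, opening=opening)


def hbond_lengths(res_i: Residue, res_j: Residue, pair_type: str,
                  bond_table: dict[str, tuple[tuple[str, str], ...]] | None = None,
                  ) -> list[HBondMeasure]:
    """Measure the standard Watson–Crick hydrogen-bond heavy-atom
    distances for a purine-first residue pair.

    A missing donor/acceptor atom yields a flagged measure, never a
    silent omission.
    """
    table = bond_table or HBOND_ATOMS
    if pair_type not in table:
        raise KeyError(f"no hydrogen-bond table for pair type {pair_type!r}")
    out: list[HBondMeasure] = []
    for name_i, name_j in table[pair_type]:
        ai, aj = res_i.atom(name_i), res_j.atom(name_j)
        if ai is None or aj is None:
            out.append(HBondMeasure(atom_i=name_i, atom_j=name_j,
                                    distance=None, missing=True))
        else:
            d = float(np.linalg.norm(ai.position - aj.position))
            out.append(HBondMeasure(atom_i=name_i, atom_j=name_j, distance=d))
    return out
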