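"""Synthetic base pairs, duplexes and mock mining collections.

The builder is the forward model of the measurement pipeline: it places
two full standard bases so that the measured simple parameters
reproduce a prescribed set.  Because the pair frame depends on the
C1′–C1′ vector, which itself moves with the bases, the placement is
solved by a small fixed-point iteration (build → measure → correct)
that converges to < 1e-9 for realistic parameter ranges.

Hydrogen-bond lengths in built pairs are emergent from the shear /
stretch placement rather than independently prescribed — the two are
geometrically coupled.  Collections that must follow prescribed
bond-length Gaussians are therefore generated at the observation-record
level (:func:`synth_records`).

All randomness flows from the seed; identical seeds give identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry
from .geometry import HBOND_ATOMS, SimpleParams, StandardBase
from .model import Atom, Residue, Structure, classify_structure
from .targets import CATEGORIES, PAIR_TYPES, TargetTable, default_targets

__all__ = ["PairSpec", "build_pair", "build_duplex", "synth_records",
           "synth_structure_collection"]

_FLIP = np.diag([1.0, -1.0, -1.0])  # anti-parallel partner: negate y and z

_DNA_COMP = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}


@dataclass(frozen=True)
class PairSpec:
    category: str = "DNA-DNA"
    pair_type: str = "G-C"
    shear: float = 0.0       # Å
    stretch: float = 0.0     # Å
    stagger: float = 0.0     # Å
    buckle: float = 0.0      # °
    propeller: float = 0.0   # °
    opening: float = 0.0     # °
    rotation: np.ndarray | None = None   # optional global rigid motion
    translation: np.ndarray | None = None
    noise_sd: float = 0.0    # Å per coordinate, Gaussian
    seed: int = 0

    def params(self) -> SimpleParams:
        return SimpleParams(shear=self.shear, stretch=self.stretch,
                            stagger=self.stagger, buckle=self.buckle,
                            propeller=self.propeller, opening=self.opening)


def _comp_ids(category: str, pair_type: str) -> tuple[str, str]:
    """Component ids for (purine, pyrimidine).  In hybrids the T strand
    is the DNA strand; otherwise the purine strand is the DNA one."""
    pu, py = pair_type.split("-")
    if category == "DNA-DNA":
        return _DNA_COMP[pu], _DNA_COMP[py]
    if category == "RNA-RNA":
        return pu, py
    if py == "T":
        return pu, _DNA_COMP[py]          # RNA purine with DNA thymine
    return _DNA_COMP[pu], py              # DNA purine with RNA pyrimidine


def _make_residue(chain: str, seq: int, comp: str, base: str,
                  rot: np.ndarray, origin: np.ndarray,
                  standards: dict[str, StandardBase]) -> Residue:
    atoms = []
    for name, xyz in standards[base].coords.items():
        element = name[0]  # N/C/O/P from PDB-convention names
        atoms.append(Atom(name=name, element=element,
                          position=rot @ xyz + origin))
    return Residue(chain_id=chain, seq_num=seq, comp_id=comp, atoms=atoms,
                   parent_base=base,
                   nucleic_class="DNA" if comp.startswith("D") else "RNA")


def _place(p: np.ndarray, spec: PairSpec,
           standards: dict[str, StandardBase]) -> Structure:
    """Build the pair for internal parameter vector p =
    (shear, stretch, stagger, buckle, propeller, opening)."""
    shear, stretch, stagger, buckle, propeller, opening = p
    gamma = float(np.hypot(buckle, propeller))
    if gamma > 1e-12:
        hinge = np.array([buckle, propeller, 0.0]) / gamma
        half = Rotation.from_rotvec(np.radians(gamma / 2) * hinge).as_matrix()
        half_inv = Rotation.from_rotvec(-np.radians(gamma / 2) * hinge).as_matrix()
    else:
        half = half_inv = np.eye(3)
    opz = Rotation.from_rotvec(np.radians(opening / 2) * np.array([0, 0, 1.0]))
    rot_i = half @ opz.as_matrix()
    rot_j = half_inv @ opz.inv().as_matrix() @ _FLIP

    delta = np.array([shear, stretch, stagger])
    origin_i, origin_j = delta / 2, -delta / 2

    comp_i, comp_j = _comp_ids(spec.category, spec.pair_type)
    pu, py = spec.pair_type.split("-")
    res_i = _make_residue("A", 1, comp_i, pu, rot_i, origin_i, standards)
    res_j = _make_residue("B", 1, comp_j, py, rot_j, origin_j, standards)
    return Structure(entry_id="synthetic-pair", residues=[res_i, res_j])


def _measure(structure: Structure) -> SimpleParams:
    res_i, res_j = structure.residues
    frame_i = geometry.base_frame(res_i)
    frame_j = geometry.base_frame(res_j)
    return geometry.simple_parameters(frame_i, frame_j,
                                      res_i.atom("C1'").position,
                                      res_j.atom("C1'").position)


def build_pair(spec: PairSpec,
               standards: dict[str, StandardBase] | None = None,
               tol: float = 1e-9, max_iter: int = 100) -> Structure:
    """Place two full bases so that the measured simple parameters equal
    the prescribed ones (to ``tol``, before noise).

    Raises for near-degenerate prescriptions (|buckle| or |propeller|
    approaching 90°), where the hinge construction is not invertible.
    """
    if max(abs(spec.buckle), abs(spec.propeller)) >= 80.0 \
            or np.hypot(spec.buckle, spec.propeller) >= 85.0:
        raise ValueError("buckle/propeller too close to 90°: pair not constructible")
    standards = standards or geometry.standard_bases()
    target = np.array([spec.shear, spec.stretch, spec.stagger,
                       spec.buckle, spec.propeller, spec.opening])
    p = target.copy()
    structure = _place(p, spec, standards)
    for _ in range(max_iter):
        m = _measure(structure)
        meas = np.array([m.shear, m.stretch, m.stagger,
                         m.buckle, m.propeller, m.opening])
        err = target - meas
        if np.max(np.abs(err)) < tol:
            break
        p = p + err
        structure = _place(p, spec, standards)
    else:
        raise RuntimeError("pair construction did not converge")

    rng = np.random.default_rng(spec.seed)
    rot = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation)
    trans = np.zeros(3) if spec.translation is None else np.asarray(spec.translation)
    out_res = []
    for res in structure.residues:
        atoms = []
        for a in res.atoms:
            pos = rot @ a.position + trans
            if spec.noise_sd > 0:
                pos = pos + rng.normal(0.0, spec.noise_sd, size=3)
            atoms.append(replace(a, position=pos))
        out_res.append(replace(res, atoms=atoms))
    return classify_structure(replace(structure, residues=out_res))


_BACKBONE_LOCAL = {  # synthetic minimal trace in the base frame, Å
    "P": np.array([-4.2, 7.6, 1.2]),
    "O5'": np.array([-3.7, 6.8, 2.2]),
    "C3'": np.array([-3.4, 6.2, -0.9]),
}


def build_duplex(n_pairs: int,
                 specs: Sequence[PairSpec] | None = None,
                 rise: float = 3.4, twist: float = 36.0,
                 seed: int = 0, backbone: bool = True) -> Structure:
    """Helical stack of ``n_pairs`` Watson–Crick pairs.

    Purines go to chain A (5′→3′ down the axis), pyrimidines to chain B
    in reverse numbering, so consecutive residues within a chain are
    spatial stacking neighbours separated by ~``rise`` along the axis.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if specs is None:
        rng = np.random.default_rng(seed)
        specs = [PairSpec(pair_type=str(rng.choice(["A-T", "G-C"])))
                 for _ in range(n_pairs)]
    if len(specs) != n_pairs:
        raise ValueError("need one PairSpec per pair")

    standards = geometry.standard_bases()
    chain_a: list[Residue] = []
    chain_b: list[Residue] = []
    for k, spec in enumerate(specs):
        pair = build_pair(replace(spec, rotation=None, translation=None,
                                  noise_sd=0.0, seed=spec.seed + k))
        rot = Rotation.from_rotvec(np.radians(k * twist) * np.array([0, 0, 1.0])
                                   ).as_matrix()
        trans = np.array([0.0, 0.0, k * rise])
        res_i, res_j = pair.residues
        frame_cache = {}
        for res, chain_id, seq in ((res_i, "A", k + 1), (res_j, "B", n_pairs - k)):
            atoms = [replace(a, position=rot @ a.position + trans) for a in res.atoms]
            if backbone:
                frame = geometry.base_frame(replace(res, atoms=atoms))
                for name, local in _BACKBONE_LOCAL.items():
                    atoms.append(Atom(name=name, element=name[0],
                                      position=frame.axes @ local + frame.origin))
            new = replace(res, chain_id=chain_id, seq_num=seq, atoms=atoms)
            (chain_a if chain_id == "A" else chain_b).append(new)
    chain_b.sort(key=lambda r: r.seq_num)

    noise = specs[0].noise_sd
    residues = chain_a + chain_b
    if noise > 0:
        rng = np.random.default_rng(specs[0].seed)
        residues = [replace(r, atoms=[replace(a, position=a.position +
                                              rng.normal(0, noise, 3))
                                      for a in r.atoms]) for r in residues]
    return classify_structure(Structure(entry_id="synthetic-duplex", residues=residues))


_CLASSES = [(c, t) for c in CATEGORIES for t in PAIR_TYPES
            if not (c in ("DNA-DNA", "RNA-RNA") and
                    t == ("A-U" if c == "DNA-DNA" else "A-T"))]


def synth_records(n_entries: int, pairs_per_entry: int = 4,
                  table: TargetTable | None = None,
                  rscc_mean: float = 0.975, rscc_sd: float = 0.01,
                  frac_bad_rscc: float = 0.0,
                  resolution_range: tuple[float, float] = (1.2, 1.6),
                  seed: int = 0):
    """Observation records drawn from the target-table Gaussians.

    Bond lengths follow the hydrogen-bond target Gaussians and the four
    validated simple parameters follow the simple-parameter target
    Gaussians of a randomly chosen pair class; RSCC and resolution are
    drawn from simple configurable models.  Returns ``(records, truth)``
    where truth maps (category, pair_type, key) → (mean, sd) actually
    used — the quantities a mining run should recover.
    """
    from .mining import ObservationRecord

    table = table or default_targets()
    hbond_entries, simple_entries = table.entries()
    truth = {(e.category, e.pair_type, e.key): (e.mean, e.sd)
             for e in hbond_entries + simple_entries}
    rng = np.random.default_rng(seed)
    records = []
    for e in range(n_entries):
        entry_id = f"syn{e:04d}"
        resolution = float(rng.uniform(*resolution_range))
        for _ in range(pairs_per_entry):
            cat, ptype = _CLASSES[rng.integers(len(_CLASSES))]
            bonds = {}
            for pu, py in HBOND_ATOMS[ptype]:
                mean, sd = table.lookup_hbond_target(cat, ptype, f"{pu}-{py}")
                bonds[f"{pu}-{py}"] = float(rng.normal(mean, sd))
            params = {}
            for key in ("shear", "stretch", "buckle", "propeller"):
                mean, sd = table.lookup_simple_target(cat, ptype, key)
                params[key] = float(rng.normal(mean, sd))
            params["stagger"] = float(rng.normal(0.0, 0.15))
            params["opening"] = float(rng.normal(0.0, 2.0))
            rsccs = []
            for _ in range(2):
                if frac_bad_rscc > 0 and rng.random() < frac_bad_rscc:
                    rsccs.append(float(rng.uniform(0.80, 0.9499)))
                else:
                    rsccs.append(min(1.0, float(rng.normal(rscc_mean, rscc_sd))))
            records.append(ObservationRecord(
                entry_id=entry_id, category=cat, pair_type=ptype,
                contains_modified=False, bonds=bonds, params=params,
                resolution=resolution, rscc_i=rsccs[0], rscc_j=rsccs[1]))
    return records, truth


def synth_structure_collection(n_entries: int, pairs_per_entry: int = 4,
                               table: TargetTable | None = None,
                               noise_sd: float = 0.0,
                               resolution_range: tuple[float, float] = (1.2, 1.6),
                               rscc_mean: float = 0.975, rscc_sd: float = 0.01,
                               seed: int = 0):
    """Mock structure collection with known true simple parameters.

    Each entry holds ``pairs_per_entry`` isolated pairs (30 Å apart, so
    detection cannot cross-link them) whose simple parameters are drawn
    from the target-table Gaussians.  Returns ``(structures, truth)``
    where truth lists the drawn parameter values per class.
    """
    table = table or default_targets()
    rng = np.random.default_rng(seed)
    structures: list[Structure] = []
    truth: dict[tuple[str, str, str], list[float]] = {}
    for e in range(n_entries):
        entry_id = f"syn{e:04d}"
        resolution = float(rng.uniform(*resolution_range))
        residues: list[Residue] = []
        rscc: dict = {}
        for k in range(pairs_per_entry):
            cat, ptype = _CLASSES[rng.integers(len(_CLASSES))]
            drawn = {}
            for key in ("shear", "stretch", "buckle", "propeller"):
                mean, sd = table.lookup_simple_target(cat, ptype, key)
                drawn[key] = float(rng.normal(mean, sd))
                truth.setdefault((cat, ptype, key), []).append(drawn[key])
            spec = PairSpec(category=cat, pair_type=ptype,
                            shear=drawn["shear"], stretch=drawn["stretch"],
                            stagger=float(rng.normal(0, 0.1)),
                            buckle=drawn["buckle"], propeller=drawn["propeller"],
                            opening=float(rng.normal(0, 1.5)),
                            translation=np.array([30.0 * k, 0.0, 0.0]),
                            noise_sd=noise_sd,
                            seed=int(rng.integers(2 ** 31)))
            pair = build_pair(spec)
            for res, chain in zip(pair.residues, ("A", "B")):
                new = replace(res, chain_id=chain, seq_num=k + 1)
                residues.append(new)
                rscc[new.key] = min(1.0, float(rng.normal(rscc_mean, rscc_sd)))
        structures.append(Structure(entry_id=entry_id, residues=residues,
                                    resolution=resolution, per_residue_rscc=rscc))
    return structures, truth
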