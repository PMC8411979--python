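"""Watson–Crick base-pair detection and classification.

Candidate detection is deliberately liberal — restraint generation must
not miss badly modelled pairs whose "hydrogen bonds" stretch past 4 Å —
and classification then keeps only anti-parallel A–T / A–U / G–C
juxtapositions with all standard donor/acceptor atoms present.

Canonical order is purine first; flipping the input order negates shear
and buckle, so reports are independent of residue order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from . import geometry
from .geometry import BaseFrame, HBondMeasure, SimpleParams
from .model import Residue, ResidueKey, Structure
from .targets import TargetTable, default_targets

__all__ = [
    "PairScreen", "BasePair", "Rejection", "find_candidate_pairs",
    "classify_pair", "canonical_order", "detect_pairs", "base_frames",
]

PURINES = ("A", "G")
WC_COMBINATIONS = ({"A", "T"}, {"A", "U"}, {"G", "C"})


@dataclass(frozen=True)
class PairScreen:
    """Detection thresholds (deliberately permissive defaults)."""
    origin_cutoff: float = 15.0        # Å, base-frame origin pre-screen
    contact_cutoff: float = 4.5        # Å, at least one inter-base N/O–N/O contact
    angle_cutoff: float = 65.0         # °, aligned interbase angle
    stagger_cutoff: float = 2.5        # Å, vertical separation


@dataclass(frozen=True)
class BasePair:
    res_i: ResidueKey              # purine, after canonical ordering
    res_j: ResidueKey
    category: str                  # DNA-DNA | RNA-RNA | DNA-RNA
    pair_type: str                 # A-T | A-U | G-C
    contains_modified: bool
    order_flipped: bool
    params: SimpleParams
    hbonds: tuple[HBondMeasure, ...]
    label_i: str = ""
    label_j: str = ""
    had_altloc: bool = False

    @property
    def pair_id(self) -> str:
        return f"{self.label_i}-{self.label_j}"


@dataclass(frozen=True)
class Rejection:
    res_i: ResidueKey
    res_j: ResidueKey
    reason: str


def base_frames(structure: Structure) -> dict[ResidueKey, BaseFrame]:
    """Frames for every usable nucleobase; unusable residues are skipped."""
    frames = {}
    for res in structure.residues:
        if res.parent_base == "none" or not res.usable:
            continue
        try:
            frames[res.key] = geometry.base_frame(res)
        except (geometry.IncompleteBaseError, ValueError):
            continue
    return frames


def _base_no_atoms(res: Residue) -> list[np.ndarray]:
    std = geometry.standard_bases().get(res.parent_base)
    if std is None:
        return []
    return [a.position for a in res.atoms
            if a.name in std.coords and a.element in ("N", "O")]


def find_candidate_pairs(structure: Structure,
                         screen: PairScreen = PairScreen(),
                         frames: dict[ResidueKey, BaseFrame] | None = None,
                         ) -> list[tuple[ResidueKey, ResidueKey]]:
    """All residue pairs whose frame origins are near and which make at
    least one inter-base N/O contact below the screen distance."""
    if frames is None:
        frames = base_frames(structure)
    residues = {r.key: r for r in structure.residues}
    keys = [k for k in frames]
    origins = np.array([frames[k].origin for k in keys]) if keys else np.zeros((0, 3))
    out: list[tuple[ResidueKey, ResidueKey]] = []
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            if np.linalg.norm(origins[a] - origins[b]) > screen.origin_cutoff:
                continue
            pts_a = _base_no_atoms(residues[keys[a]])
            pts_b = _base_no_atoms(residues[keys[b]])
            if not pts_a or not pts_b:
                continue
            d2 = ((np.asarray(pts_a)[:, None, :] - np.asarray(pts_b)[None, :, :]) ** 2
                  ).sum(axis=2)
            if d2.min() <= screen.contact_cutoff ** 2:
                out.append((keys[a], keys[b]))
    return out


def _category(class_i: str, class_j: str) -> str:
    if class_i == class_j == "DNA":
        return "DNA-DNA"
    if class_i == class_j == "RNA":
        return "RNA-RNA"
    return "DNA-RNA"


def classify_pair(candidate: tuple[ResidueKey, ResidueKey], structure: Structure,
                  screen: PairScreen = PairScreen(),
                  frames: dict[ResidueKey, BaseFrame] | None = None,
                  ) -> BasePair | Rejection:
    """Classify a candidate as a Watson–Crick pair or reject it with a
    machine-readable reason.  The result is purine-first regardless of
    the input order."""
    if frames is None:
        frames = base_frames(structure)
    key_i, key_j = candidate
    res_i, res_j = structure.residue(key_i), structure.residue(key_j)
    if res_i is None or res_j is None:
        return Rejection(key_i, key_j, "unknown-residue")

    bases = {res_i.parent_base, res_j.parent_base}
    if bases not in WC_COMBINATIONS:
        return Rejection(key_i, key_j, "non-wc-combination")

    flipped = res_i.parent_base not in PURINES
    if flipped:
        res_i, res_j = res_j, res_i
        key_i, key_j = key_j, key_i
    if key_i not in frames or key_j not in frames:
        return Rejection(key_i, key_j, "no-base-frame")
    frame_i, frame_j = frames[key_i], frames[key_j]

    cosg = float(np.clip(frame_i.z @ (-frame_j.z), -1.0, 1.0))
    gamma = np.degrees(np.arccos(cosg))
    if gamma > screen.angle_cutoff:
        return Rejection(key_i, key_j, "interbase-angle")

    c1_i, c1_j = res_i.atom("C1'"), res_j.atom("C1'")
    if c1_i is None or c1_j is None:
        return Rejection(key_i, key_j, "missing-c1'")
    try:
        params = geometry.simple_parameters(frame_i, frame_j,
                                            c1_i.position, c1_j.position)
    except geometry.NotPairableError:
        return Rejection(key_i, key_j, "interbase-angle")

    if abs(params.stagger) > screen.stagger_cutoff:
        return Rejection(key_i, key_j, "vertical-separation")

    pyrimidine = res_j.parent_base
    pair_type = {"T": "A-T", "U": "A-U", "C": "G-C"}[pyrimidine]
    hbonds = tuple(geometry.hbond_lengths(res_i, res_j, pair_type))
    if any(h.missing for h in hbonds):
        return Rejection(key_i, key_j, "missing-hbond-atoms")

    return BasePair(
        res_i=key_i, res_j=key_j,
        category=_category(res_i.nucleic_class, res_j.nucleic_class),
        pair_type=pair_type,
        contains_modified=res_i.is_modified or res_j.is_modified,
        order_flipped=flipped,
        params=params,
        hbonds=hbonds,
        label_i=res_i.label(), label_j=res_j.label(),
        had_altloc=res_i.had_altloc or res_j.had_altloc,
    )


def canonical_order(pair: BasePair, structure: Structure | None = None) -> BasePair:
    """Purine-first ordering; flipping negates shear and buckle.

    ``classify_pair`` already returns canonical pairs, so this is the
    identity on its output (idempotent by construction); it exists to
    normalize pairs deserialized from external sources.
    """
    if structure is not None:
        res_i = structure.residue(pair.res_i)
        if res_i is not None and res_i.parent_base not in PURINES:
            p = pair.params
            return replace(pair,
                           res_i=pair.res_j, res_j=pair.res_i,
                           label_i=pair.label_j, label_j=pair.label_i,
                           order_flipped=not pair.order_flipped,
                           params=replace(p, shear=-p.shear, buckle=-p.buckle))
    return pair


def _hbond_quality(pair: BasePair, targets: TargetTable) -> tuple[int, float]:
    """(satisfied bond count, mean |deviation from target mean|)."""
    satisfied = sum(1 for h in pair.hbonds
                    if h.distance is not None and h.distance <= 3.5)
    devs = []
    for h in pair.hbonds:
        if h.distance is None:
            continue
        try:
            mean, _ = targets.lookup_hbond_target(pair.category, pair.pair_type,
                                                  f"{h.atom_i}-{h.atom_j}")
        except KeyError:
            continue
        devs.append(abs(h.distance - mean))
    return satisfied, float(np.mean(devs)) if devs else float("inf")


def detect_pairs(structure: Structure, screen: PairScreen = PairScreen(),
                 targets: TargetTable | None = None,
                 ) -> tuple[list[BasePair], list[Rejection]]:
    """Full detection: candidates → classification → conflict resolution.

    Each residue ends up in at most one Watson–Crick pair; conflicting
    candidates are resolved in favour of more satisfied hydrogen bonds,
    then smaller mean deviation from the target bond lengths.
    """
    targets = targets or default_targets()
    frames = base_frames(structure)
    pairs: list[BasePair] = []
    rejections: list[Rejection] = []
    for cand in find_candidate_pairs(structure, screen, frames):
        result = classify_pair(cand, structure, screen, frames)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            pairs.append(result)

    ranked = sorted(pairs, key=lambda p: (-_hbond_quality(p, targets)[0],
                                          _hbond_quality(p, targets)[1]))
    taken: set[ResidueKey] = set()
    kept: list[BasePair] = []
    for p in ranked:
        if p.res_i in taken or p.res_j in taken:
            rejections.append(Rejection(p.res_i, p.res_j, "conflicting-pair"))
            continue
        taken.update((p.res_i, p.res_j))
        kept.append(p)
    kept.sort(key=lambda p: (p.res_i, p.res_j))
    return kept, rejections
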