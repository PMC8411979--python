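"""External refinement restraints for Watson–Crick hydrogen bonds and
base stacking.

Hydrogen-bond restraints carry the mined target/sigma per bond and are
written with weight 2; stacking restraints keep sequential bases at a
3.4 Å interplanar separation with weight 5.  Restraints are generated
only when the data resolution is worse than 1.70 Å (at or better than
that the targets still serve validation, but the data can speak for
itself); residues with alternate conformations are excluded.

The output dialect is a line-oriented text format (grammar in
docs/restraint_format.md) with one ``dist`` record per hydrogen bond
and one ``plane`` record per stacking contact; a bundled parser
round-trips it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import geometry
from .model import ResidueKey, Structure
from .pairing import BasePair, base_frames
from .targets import TargetTable, default_targets

logger = logging.getLogger(__name__)

__all__ = [
    "Restraint", "hbond_restraints", "stacking_restraints", "resolution_gate",
    "write_external_restraints", "read_external_restraints",
    "HBOND_WEIGHT", "STACKING_WEIGHT", "STACKING_TARGET", "STACKING_SIGMA",
    "RESOLUTION_GATE",
]

HBOND_WEIGHT = 2.0
STACKING_WEIGHT = 5.0
STACKING_TARGET = 3.4   # Å interplanar distance
STACKING_SIGMA = 0.2    # Å (the stacking functional is weighted separately)
RESOLUTION_GATE = 1.70  # Å; restraints only when resolution is worse than this


@dataclass(frozen=True)
class Restraint:
    kind: str                       # "distance" | "parallel_plane"
    sel_i: tuple[str, int, str, tuple[str, ...]]  # chain, seq, icode, atom names
    sel_j: tuple[str, int, str, tuple[str, ...]]
    target: float                   # Å
    sigma: float                    # Å
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("restraint sigma must be > 0")
        if self.kind == "distance":
            if len(self.sel_i[3]) != 1 or len(self.sel_j[3]) != 1:
                raise ValueError("distance restraints reference exactly 2 atoms")
        elif self.kind != "parallel_plane":
            raise ValueError(f"unknown restraint kind {self.kind!r}")


def hbond_restraints(pairs: Iterable[BasePair],
                     targets: TargetTable | None = None) -> list[Restraint]:
    """One distance restraint per standard hydrogen bond per pair,
    target/sigma from the mined table, weight 2.

    Pairs involving alternate-conformation residues are excluded; pairs
    whose class has no targets are skipped with a logged reason.
    """
    targets = targets or default_targets()
    out: list[Restraint] = []
    for pair in pairs:
        if pair.had_altloc:
            logger.info("pair %s: excluded from restraints (alternate conformations)",
                        pair.pair_id)
            continue
        if not targets.has_class(pair.category, pair.pair_type):
            logger.info("pair %s: no targets for %s %s, skipped",
                        pair.pair_id, pair.category, pair.pair_type)
            continue
        for h in pair.hbonds:
            bond = f"{h.atom_i}-{h.atom_j}"
            try:
                mean, sd = targets.lookup_hbond_target(pair.category, pair.pair_type, bond)
            except KeyError:
                continue
            ci, si, ii = pair.res_i
            cj, sj, ij = pair.res_j
            out.append(Restraint(kind="distance",
                                 sel_i=(ci, si, ii, (h.atom_i,)),
                                 sel_j=(cj, sj, ij, (h.atom_j,)),
                                 target=mean, sigma=sd, weight=HBOND_WEIGHT))
    return out


def stacking_restraints(structure: Structure,
                        pairs: Sequence[BasePair] | None = None,
                        min_sep: float = 2.5, max_sep: float = 5.0,
                        ) -> list[Restraint]:
    """Parallel-plane restraints between sequential stacked bases.

    Stacked = consecutive usable nucleotides in a chain whose base-frame
    origins are ``min_sep``–``max_sep`` Å apart along the mean base
    normal.  Interplanar target 3.4 Å, weight 5.  Residues with
    alternate conformations are excluded.
    """
    frames = base_frames(structure)
    standards = geometry.standard_bases()
    out: list[Restraint] = []
    for chain_id, residues in structure.chains().items():
        nts = [r for r in residues if r.key in frames and not r.had_altloc]
        for r1, r2 in zip(nts, nts[1:]):
            f1, f2 = frames[r1.key], frames[r2.key]
            # sequential neighbours stack with parallel normals; a pair
            # partner would be anti-parallel and is skipped here
            normal = f1.z + f2.z if f1.z @ f2.z >= 0 else f1.z - f2.z
            normal = normal / np.linalg.norm(normal)
            sep = abs(float((f2.origin - f1.origin) @ normal))
            if not min_sep <= sep <= max_sep:
                continue
            ring1 = standards[r1.parent_base].ring_atom_names
            ring2 = standards[r2.parent_base].ring_atom_names
            out.append(Restraint(kind="parallel_plane",
                                 sel_i=(r1.chain_id, r1.seq_num, r1.insertion_code, ring1),
                                 sel_j=(r2.chain_id, r2.seq_num, r2.insertion_code, ring2),
                                 target=STACKING_TARGET, sigma=STACKING_SIGMA,
                                 weight=STACKING_WEIGHT))
    return out


def resolution_gate(resolution: float | None) -> bool:
    """True (generate restraints) iff the resolution is worse than
    1.70 Å; unknown resolution defaults to True (logged)."""
    if resolution is None:
        logger.warning("resolution unknown; restraint gate defaults to open")
        return True
    return resolution > RESOLUTION_GATE


def _sel_str(sel: tuple[str, int, str, tuple[str, ...]]) -> str:
    chain, seq, icode, atoms = sel
    return f"chain {chain} resi {seq} ins {icode or '.'} atoms {','.join(atoms)}"


def _parse_sel(tokens: list[str]) -> tuple[str, int, str, tuple[str, ...]]:
    assert tokens[0] == "chain" and tokens[2] == "resi" and tokens[4] == "ins" \
        and tokens[6] == "atoms", f"bad selector: {' '.join(tokens)}"
    icode = "" if tokens[5] == "." else tokens[5]
    return tokens[1], int(tokens[3]), icode, tuple(tokens[7].split(","))


def write_external_restraints(restraints: Sequence[Restraint],
                              path: str | Path, note: str = "") -> None:
    """Write restraints in the external-restraint text dialect.

    The body is a pure function of the restraint list (no timestamps),
    so regeneration on an unchanged model is byte-identical.
    """
    lines = [
        "# bpval external restraints v1",
        f"# weights: hbond {HBOND_WEIGHT:g}, stacking {STACKING_WEIGHT:g}",
    ]
    if note:
        lines.append(f"# {note}")
    for r in sorted(restraints, key=lambda r: (r.kind, r.sel_i, r.sel_j)):
        rec = "dist" if r.kind == "distance" else "plane"
        lines.append(f"{rec} first {_sel_str(r.sel_i)} second {_sel_str(r.sel_j)} "
                     f"value {r.target:.3f} sigma {r.sigma:.3f} weight {r.weight:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_external_restraints(path: str | Path) -> list[Restraint]:
    """Parse a file written by :func:`write_external_restraints`."""
    out: list[Restraint] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        kind = {"dist": "distance", "plane": "parallel_plane"}.get(tokens[0])
        if kind is None:
            raise ValueError(f"unknown record type {tokens[0]!r}")
        i_first, i_second = tokens.index("first"), tokens.index("second")
        i_value = tokens.index("value")
        sel_i = _parse_sel(tokens[i_first + 1:i_second])
        sel_j = _parse_sel(tokens[i_second + 1:i_value])
        target = float(tokens[i_value + 1])
        sigma = float(tokens[tokens.index("sigma") + 1])
        weight = float(tokens[tokens.index("weight") + 1])
        out.append(Restraint(kind=kind, sel_i=sel_i, sel_j=sel_j,
                             target=target, sigma=sigma, weight=weight))
    return out
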