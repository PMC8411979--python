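"""Structure model I/O and nucleotide classification.

Coordinate files (PDB / mmCIF) are parsed with :mod:`gemmi`; this module
flattens them into a light residue/atom model keyed by *author* chain id,
residue number and insertion code — the numbering used in structure
papers (e.g. "B/44A", "X/57G") and in RSCC sidecar tables.

Hydrogen atoms are dropped on reading: every "hydrogen bond" downstream
is a donor/acceptor heavy-atom distance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue key = (chain_id, seq_num, insertion_code); "" for blank icode
ResidueKey = tuple[str, int, str]

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: standard polymer components and common modified nucleotides → (parent, class)
DEFAULT_PARENT_TABLE: dict[str, tuple[str, str]] = {
    "DA": ("A", "DNA"), "DC": ("C", "DNA"), "DG": ("G", "DNA"),
    "DT": ("T", "DNA"), "DU": ("U", "DNA"),
    "A": ("A", "RNA"), "C": ("C", "RNA"), "G": ("G", "RNA"), "U": ("U", "RNA"),
    # common modifications (lowercase pairing convention: a-u, G-c, ...)
    "PSU": ("U", "RNA"), "H2U": ("U", "RNA"), "4SU": ("U", "RNA"),
    "5MU": ("U", "RNA"), "OMU": ("U", "RNA"), "UR3": ("U", "RNA"),
    "1MA": ("A", "RNA"), "2MA": ("A", "RNA"), "MA6": ("A", "RNA"),
    "OMA": ("A", "RNA"), "A2M": ("A", "RNA"),
    "2MG": ("G", "RNA"), "M2G": ("G", "RNA"), "7MG": ("G", "RNA"),
    "OMG": ("G", "RNA"), "1MG": ("G", "RNA"), "G7M": ("G", "RNA"),
    "5MC": ("C", "RNA"), "OMC": ("C", "RNA"), "4OC": ("C", "RNA"),
    "5CM": ("C", "DNA"), "5HC": ("C", "DNA"), "C5M": ("C", "DNA"),
    "BRU": ("U", "DNA"), "5IU": ("U", "DNA"),
    "6MA": ("A", "DNA"), "8OG": ("G", "DNA"),
}

_STANDARD_COMPS = {"DA", "DC", "DG", "DT", "A", "C", "G", "U"}


class ParseError(ValueError):
    """Raised when a coordinate or sidecar file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å, orthogonal coordinates
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str = ""
    comp_id: str = ""
    atoms: list[Atom] = field(default_factory=list)
    nucleic_class: str = "other"      # DNA | RNA | other
    parent_base: str = "none"         # A | C | G | T | U | none
    is_modified: bool = False
    usable: bool = True               # False when required ring atoms are absent
    had_altloc: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def label(self) -> str:
        return f"{self.chain_id}/{self.seq_num}{self.insertion_code}{self.comp_id}"


@dataclass
class Structure:
    entry_id: str = ""
    residues: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    per_residue_rscc: dict[ResidueKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate residue keys in model: {sorted(dupes)}")

    def residue(self, key: ResidueKey) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out


def _from_gemmi(st: gemmi.Structure, entry_id: str) -> Structure:
    st.setup_entities()
    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                ))
            icode = res.seqid.icode.strip()
            residues.append(Residue(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=icode,
                comp_id=res.name,
                atoms=atoms,
            ))
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    structure = Structure(entry_id=entry_id or st.name.lower(), residues=residues,
                          resolution=resolution)
    return classify_structure(structure)


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    ``format`` is ``pdb``, ``mmcif`` or ``auto`` (detect from contents /
    extension).  Residues are classified on the way in.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format == "auto":
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    resolution = None
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            st = gemmi.make_structure_from_block(block)
            for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
                value = block.find_value(tag)
                if value not in (None, ".", "?"):
                    resolution = float(gemmi.cif.as_string(value) or value)
                    break
        else:
            raise ParseError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    except ParseError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with location info
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    structure = _from_gemmi(st, path.stem.lower())
    if structure.resolution is None and resolution is not None and resolution > 0:
        structure = replace(structure, resolution=resolution)
    return structure


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as mmCIF (used for synthetic fixtures)."""
    st = gemmi.Structure()
    st.name = structure.entry_id or "xxxx"
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.comp_id
        gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
        for at in res.atoms:
            ga = gemmi.Atom()
            ga.name = at.name
            ga.element = gemmi.Element(at.element)
            ga.pos = gemmi.Position(*at.position)
            ga.occ = at.occupancy
            if at.altloc:
                ga.altloc = at.altloc
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    if structure.resolution is not None:
        block = doc.sole_block()
        block.set_pair("_reflns.d_resolution_high", f"{structure.resolution:.2f}")
        block.set_pair("_refine.ls_d_res_high", f"{structure.resolution:.2f}")
    doc.write_file(str(path))


def classify_residue(residue: Residue,
                     parent_table: Mapping[str, tuple[str, str]] | None = None) -> Residue:
    """Assign ``parent_base`` / ``nucleic_class`` / ``is_modified``.

    Standard components map to themselves; listed modifications map to
    their parent base; anything else falls back to ring-atom-name
    matching (with the nucleic class inferred from the presence of O2′).
    Classification is total: unmatched residues come back as ``other``.
    """
    table = DEFAULT_PARENT_TABLE if parent_table is None else parent_table
    comp = residue.comp_id.strip().upper()
    names = residue.atom_names()

    parent, nclass, modified = "none", "other", False
    if comp in table:
        parent, nclass = table[comp]
        modified = comp not in _STANDARD_COMPS
    elif set(PURINE_RING).issubset(names) and "N9" in names:
        nclass = "RNA" if "O2'" in names else "DNA"
        if "O6" in names:
            parent = "G"
        elif "N6" in names:
            parent = "A"
        else:
            parent, nclass = "none", "other"
        modified = parent != "none"
    elif set(PYRIMIDINE_RING).issubset(names) and "N9" not in names:
        nclass = "RNA" if "O2'" in names else "DNA"
        if "N4" in names:
            parent = "C"
        elif "O4" in names:
            parent = "U" if nclass == "RNA" else "T"
        else:
            parent, nclass = "none", "other"
        modified = parent != "none"

    ring = PURINE_RING if parent in ("A", "G") else PYRIMIDINE_RING
    usable = parent != "none" and set(ring).issubset(names)
    return replace(residue, parent_base=parent, nucleic_class=nclass,
                   is_modified=modified, usable=usable)


def classify_structure(structure: Structure,
                       parent_table: Mapping[str, tuple[str, str]] | None = None) -> Structure:
    return replace(structure,
                   residues=[classify_residue(r, parent_table) for r in structure.residues])


def select_conformation(structure: Structure, policy: str = "highest_occupancy") -> Structure:
    """Collapse alternate conformations to a single-conformer view.

    ``policy`` is ``highest_occupancy`` or a single altloc id.  Residues
    that carried alternates come back with ``had_altloc`` set so that
    restraint generation can exclude them; validation still uses them.
    """
    out: list[Residue] = []
    for res in structure.residues:
        alt_ids = sorted({a.altloc for a in res.atoms if a.altloc})
        if not alt_ids:
            out.append(res)
            continue
        if policy == "highest_occupancy" or policy not in alt_ids:
            if policy != "highest_occupancy":
                logger.warning("residue %s: altloc %r absent, falling back to "
                               "highest occupancy", res.label(), policy)
            occ = {aid: sum(a.occupancy for a in res.atoms if a.altloc == aid)
                   for aid in alt_ids}
            chosen = max(alt_ids, key=lambda aid: (occ[aid], aid))
        else:
            chosen = policy
        atoms = [a for a in res.atoms if a.altloc in ("", chosen)]
        out.append(replace(res, atoms=atoms, had_altloc=True))
    return replace(structure, residues=out)


def read_rscc_table(path: str | Path) -> dict[ResidueKey, float]:
    """Read a per-residue RSCC sidecar: 4 columns (chain, seq, icode, rscc).

    '.' stands for a blank insertion code; a header line is optional.
    """
    result: dict[ResidueKey, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: row {lineno}: expected 4 columns, got {len(fields)}")
            chain, seq_s, icode, rscc_s = fields
            try:
                seq = int(seq_s)
                rscc = float(rscc_s)
            except ValueError:
                if lineno == 1:  # tolerated header
                    continue
                raise ParseError(f"{path}: row {lineno}: non-numeric field") from None
            if not -1.0 <= rscc <= 1.0:
                raise ParseError(f"{path}: row {lineno}: RSCC {rscc} outside [-1, 1]")
            key = (chain, seq, "" if icode == "." else icode)
            if key in result:
                raise ParseError(f"{path}: row {lineno}: duplicate residue key {key}")
            result[key] = rscc
    return result


def attach_rscc(structure: Structure, rscc: Mapping[ResidueKey, float]) -> Structure:
    return replace(structure, per_residue_rscc=dict(rscc))
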