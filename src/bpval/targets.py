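"""Mined target tables for Watson–Crick base-pair validation.

Two tables ship with the package: hydrogen-bond length targets (17
entries: the 2 A–T/A–U bonds and 3 G–C bonds across the DNA–DNA,
RNA–RNA and DNA–RNA categories) and simple-parameter targets (28
entries: 7 pair classes × shear/stretch/buckle/propeller).  Pairs with
modified nucleotides resolve to their natural pair's targets.

A lookup never falls back across categories: a combination absent from
the table (e.g. A–U in DNA–DNA) raises :class:`TargetLookupError`.
Re-mined tables in the same TSV format can be loaded in place of the
embedded ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "TargetEntry", "TargetTable", "TargetLookupError", "default_targets",
    "CATEGORIES", "PAIR_TYPES", "SIMPLE_PARAM_KEYS",
]

CATEGORIES = ("DNA-DNA", "RNA-RNA", "DNA-RNA")
PAIR_TYPES = ("A-T", "A-U", "G-C")
SIMPLE_PARAM_KEYS = ("shear", "stretch", "buckle", "propeller")


class TargetLookupError(KeyError):
    """No target exists for the requested (category, pair type, key)."""


@dataclass(frozen=True)
class TargetEntry:
    category: str
    pair_type: str
    key: str       # hydrogen-bond atom pair ("N1-N3") or parameter name
    mean: float    # Å or °
    sd: float      # Å or °
    count: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"target {self}: sd must be > 0")
        if self.count <= 0:
            raise ValueError(f"target {self}: count must be > 0")


def _read_tsv(text: str) -> list[TargetEntry]:
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cat, ptype, key, mean, sd, count = line.split("\t")
        entries.append(TargetEntry(category=cat, pair_type=ptype, key=key,
                                   mean=float(mean), sd=float(sd), count=int(count)))
    return entries


@dataclass(frozen=True)
class Digest:
    hbond_entries: int
    simple_entries: int
    pair_classes: int


class TargetTable:
    """Lookup of validation/restraint targets keyed by
    (category, pair type, bond-or-parameter)."""

    def __init__(self, hbond_entries: list[TargetEntry],
                 simple_entries: list[TargetEntry]) -> None:
        self._hbond = {(e.category, e.pair_type, e.key): e for e in hbond_entries}
        self._simple = {(e.category, e.pair_type, e.key): e for e in simple_entries}
        if len(self._hbond) != len(hbond_entries) or len(self._simple) != len(simple_entries):
            raise ValueError("duplicate target entries")

    @classmethod
    def from_files(cls, hbond_path: str | Path, simple_path: str | Path) -> "TargetTable":
        return cls(_read_tsv(Path(hbond_path).read_text()),
                   _read_tsv(Path(simple_path).read_text()))

    @classmethod
    def embedded(cls) -> "TargetTable":
        data = resources.files("bpval.data")
        return cls(_read_tsv(data.joinpath("hbond_targets.tsv").read_text()),
                   _read_tsv(data.joinpath("simple_targets.tsv").read_text()))

    def lookup_hbond_target(self, category: str, pair_type: str,
                            atom_pair: str) -> tuple[float, float]:
        """(mean, sd) for a hydrogen bond, e.g. ("DNA-DNA", "A-T", "N1-N3")."""
        try:
            e = self._hbond[(category, pair_type, atom_pair)]
        except KeyError:
            raise TargetLookupError(
                f"no hydrogen-bond target for ({category}, {pair_type}, {atom_pair})"
            ) from None
        return e.mean, e.sd

    def lookup_simple_target(self, category: str, pair_type: str,
                             parameter: str) -> tuple[float, float]:
        """(mean, sd) for a simple parameter, e.g. ("RNA-RNA", "A-U", "propeller")."""
        try:
            e = self._simple[(category, pair_type, parameter)]
        except KeyError:
            raise TargetLookupError(
                f"no simple-parameter target for ({category}, {pair_type}, {parameter})"
            ) from None
        return e.mean, e.sd

    def has_class(self, category: str, pair_type: str) -> bool:
        return any(k[:2] == (category, pair_type) for k in self._hbond)

    def hbond_bonds(self, category: str, pair_type: str) -> list[TargetEntry]:
        return [e for k, e in self._hbond.items() if k[:2] == (category, pair_type)]

    def entries(self) -> tuple[list[TargetEntry], list[TargetEntry]]:
        return list(self._hbond.values()), list(self._simple.values())

    def target_table_digest(self) -> Digest:
        classes = {k[:2] for k in self._hbond} | {k[:2] for k in self._simple}
        return Digest(hbond_entries=len(self._hbond),
                      simple_entries=len(self._simple),
                      pair_classes=len(classes))


_DEFAULT: TargetTable | None = None


def default_targets() -> TargetTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = TargetTable.embedded()
    return _DEFAULT
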