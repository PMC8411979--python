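"""Z scores, per-pair Z_bpG, model-level rmsZ metrics and Z_change.

Every measured quantity is standardized against its class-specific
mined target: Z = (value − mean)/sd.  Per pair, the four simple-
parameter Z scores combine into an overall base-pair geometry score
Z_bpG (root-mean-square by default); pairs with Z_bpG > 3.00 are
flagged as outliers.  Model-level quality is summarized as rmsZ over
all hydrogen bonds, rmsZ per simple parameter, and rmsZ_bpG, each with
a jackknife (leave-one-out) standard deviation.

A small bond-valence utility (Brown–Altermatt, V = Σ exp((R_o − d)/B))
supports metal-site checks like the cadmium example workflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .model import Atom, Structure
from .pairing import BasePair, PairScreen, Rejection, detect_pairs
from .targets import SIMPLE_PARAM_KEYS, TargetLookupError, TargetTable, default_targets

__all__ = [
    "zscore", "zbpg", "rmsz", "jackknife_sd", "zchange", "bond_valence",
    "validate_model", "ValidationReport", "PairRecord", "ZChange",
    "OUTLIER_THRESHOLD", "MEANINGFUL_RMSZ_BPG_CHANGE", "classify_rmsz_bpg_change",
]

OUTLIER_THRESHOLD = 3.00          # Z_bpG above this flags a base-pair outlier
SIGNIFICANT_ZCHANGE = 2.6         # |Z_change| above this is significant
MEANINGFUL_RMSZ_BPG_CHANGE = 0.5  # |Δ rmsZ_bpG| at or below this: no meaningful change


def zscore(value: float, mean: float, sd: float) -> float:
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    return (value - mean) / sd


def zbpg(z_shear: float, z_stretch: float, z_buckle: float, z_propeller: float,
         form: str = "rms") -> float:
    """Overall base-pair geometry score from the four simple-parameter Z
    scores.  ``form`` is "rms" (default) or "mean_abs"."""
    zs = np.array([z_shear, z_stretch, z_buckle, z_propeller], dtype=float)
    if not np.all(np.isfinite(zs)):
        raise ValueError("Z scores must be finite")
    if form == "rms":
        return float(np.sqrt((zs ** 2).mean()))
    if form == "mean_abs":
        return float(np.abs(zs).mean())
    raise ValueError(f"unknown Z_bpG form {form!r}")


def rmsz(values: Sequence[float]) -> float:
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("rmsZ of an empty list is undefined")
    return float(np.sqrt((vals ** 2).mean()))


def jackknife_sd(values: Sequence[float],
                 statistic: Callable[[Sequence[float]], float] = rmsz) -> float | None:
    """Leave-one-out standard deviation of ``statistic``:
    sd = sqrt(((n−1)/n) · Σ (θ_(i) − θ̄_(.))²).  None when n < 2."""
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < 2:
        return None
    theta = np.array([statistic(np.delete(vals, i)) for i in range(n)])
    return float(np.sqrt((n - 1) / n * ((theta - theta.mean()) ** 2).sum()))


@dataclass(frozen=True)
class ZChange:
    metric: str
    value_before: float
    value_after: float
    sd_before: float | None
    sd_after: float | None
    z_change: float | None
    significant: bool | None   # None = undetermined (no sd available)


def zchange(m_before: float, sd_before: float | None,
            m_after: float, sd_after: float | None,
            metric: str = "") -> ZChange:
    """Standardized change (m_before − m_after)/sqrt(sd₁² + sd₂²).

    Positive = improvement for lower-is-better metrics.  With no
    standard deviation available the significance is undetermined.
    """
    sds = [s for s in (sd_before, sd_after) if s is not None]
    if not sds:
        return ZChange(metric, m_before, m_after, sd_before, sd_after,
                       z_change=None, significant=None)
    denom = math.sqrt(sum(s * s for s in sds))
    if denom == 0:
        z = 0.0 if m_before == m_after else math.inf * math.copysign(1, m_before - m_after)
    else:
        z = (m_before - m_after) / denom
    return ZChange(metric, m_before, m_after, sd_before, sd_after,
                   z_change=z, significant=abs(z) > SIGNIFICANT_ZCHANGE)


def classify_rmsz_bpg_change(delta: float) -> str:
    """Whole-model verdict from Δ rmsZ_bpG (after − before)."""
    if delta < -MEANINGFUL_RMSZ_BPG_CHANGE:
        return "improved"
    if delta > MEANINGFUL_RMSZ_BPG_CHANGE:
        return "deteriorated"
    return "no meaningful change"


def bond_valence(center: Atom, ligands: Iterable[tuple[Atom, float]],
                 B: float = 0.37, cutoff: float = 3.0) -> float:
    """Bond-valence sum Σ exp((R_o − d)/B) over ligands within the
    coordination cutoff.  ``ligands`` is (atom, R_o) with R_o in Å."""
    total = 0.0
    for atom, r_o in ligands:
        d = float(np.linalg.norm(atom.position - center.position))
        if d <= 0:
            raise ValueError("ligand distance must be > 0")
        if d <= cutoff:
            total += math.exp((r_o - d) / B)
    return total


@dataclass
class PairRecord:
    pair: BasePair
    z_simple: dict[str, float] = field(default_factory=dict)
    z_hbonds: dict[str, float] = field(default_factory=dict)
    z_bpg: float | None = None
    outlier: bool = False
    validated: bool = True      # False when the class has no targets

    def as_dict(self) -> dict:
        return {
            "pair_id": self.pair.pair_id,
            "category": self.pair.category,
            "pair_type": self.pair.pair_type,
            "contains_modified": self.pair.contains_modified,
            "params": self.pair.params.as_dict(),
            "hbonds": {f"{h.atom_i}-{h.atom_j}": h.distance for h in self.pair.hbonds},
            "z_simple": self.z_simple,
            "z_hbonds": self.z_hbonds,
            "z_bpg": self.z_bpg,
            "outlier": self.outlier,
            "validated": self.validated,
        }


@dataclass
class ValidationReport:
    entry_id: str
    pair_records: list[PairRecord]
    rejections: list[Rejection]
    hbond_rmsz: float | None = None
    hbond_rmsz_sd: float | None = None
    simple_rmsz: dict[str, float] = field(default_factory=dict)
    simple_rmsz_sd: dict[str, float | None] = field(default_factory=dict)
    rmsz_bpg: float | None = None
    rmsz_bpg_sd: float | None = None

    @property
    def outliers(self) -> list[PairRecord]:
        return [r for r in self.pair_records if r.outlier]

    def counts(self) -> dict:
        by_class: dict[str, int] = {}
        for r in self.pair_records:
            k = f"{r.pair.category}/{r.pair.pair_type}"
            by_class[k] = by_class.get(k, 0) + 1
        reasons: dict[str, int] = {}
        for rej in self.rejections:
            reasons[rej.reason] = reasons.get(rej.reason, 0) + 1
        return {"pairs": len(self.pair_records), "by_class": by_class,
                "rejected": reasons}

    def as_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "counts": self.counts(),
            "model_metrics": {
                "hbond_rmsz": self.hbond_rmsz,
                "hbond_rmsz_sd": self.hbond_rmsz_sd,
                "simple_rmsz": self.simple_rmsz,
                "simple_rmsz_sd": self.simple_rmsz_sd,
                "rmsz_bpg": self.rmsz_bpg,
                "rmsz_bpg_sd": self.rmsz_bpg_sd,
                "percentiles": None,
            },
            "pairs": [r.as_dict() for r in self.pair_records],
            "outliers": [r.pair.pair_id for r in self.outliers],
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=1, sort_keys=True)

    def to_tsv(self) -> str:
        cols = ["pair_id", "category", "pair_type", "shear", "stretch", "stagger",
                "buckle", "propeller", "opening", "z_bpg", "outlier", "validated"]
        lines = ["\t".join(cols)]
        for r in self.pair_records:
            p = r.pair.params
            row = [r.pair.pair_id, r.pair.category, r.pair.pair_type,
                   f"{p.shear:.3f}", f"{p.stretch:.3f}", f"{p.stagger:.3f}",
                   f"{p.buckle:.3f}", f"{p.propeller:.3f}", f"{p.opening:.3f}",
                   "" if r.z_bpg is None else f"{r.z_bpg:.2f}",
                   str(r.outlier), str(r.validated)]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def validate_model(structure: Structure,
                   targets: TargetTable | None = None,
                   screen: PairScreen = PairScreen(),
                   zbpg_form: str = "rms") -> ValidationReport:
    """Detect Watson–Crick pairs and score the whole model.

    Pairs belonging to classes without mined targets (e.g. A–U in
    DNA–DNA) are reported unvalidated.  An empty model yields an empty
    report, not an error.
    """
    targets = targets or default_targets()
    pairs, rejections = detect_pairs(structure, screen, targets)

    records: list[PairRecord] = []
    all_hbond_z: list[float] = []
    per_param_z: dict[str, list[float]] = {k: [] for k in SIMPLE_PARAM_KEYS}
    zbpg_values: list[float] = []

    for pair in pairs:
        rec = PairRecord(pair=pair)
        try:
            params = pair.params.as_dict()
            for key in SIMPLE_PARAM_KEYS:
                mean, sd = targets.lookup_simple_target(pair.category, pair.pair_type, key)
                rec.z_simple[key] = zscore(params[key], mean, sd)
            for h in pair.hbonds:
                bond = f"{h.atom_i}-{h.atom_j}"
                mean, sd = targets.lookup_hbond_target(pair.category, pair.pair_type, bond)
                if h.distance is not None:
                    rec.z_hbonds[bond] = zscore(h.distance, mean, sd)
        except TargetLookupError:
            rec.validated = False
            rec.z_simple.clear()
            rec.z_hbonds.clear()
            records.append(rec)
            continue
        rec.z_bpg = zbpg(rec.z_simple["shear"], rec.z_simple["stretch"],
                         rec.z_simple["buckle"], rec.z_simple["propeller"],
                         form=zbpg_form)
        rec.outlier = rec.z_bpg > OUTLIER_THRESHOLD
        records.append(rec)
        all_hbond_z.extend(rec.z_hbonds.values())
        for key in SIMPLE_PARAM_KEYS:
            per_param_z[key].append(rec.z_simple[key])
        zbpg_values.append(rec.z_bpg)

    report = ValidationReport(entry_id=structure.entry_id,
                              pair_records=records, rejections=rejections)
    if all_hbond_z:
        report.hbond_rmsz = rmsz(all_hbond_z)
        report.hbond_rmsz_sd = jackknife_sd(all_hbond_z)
    for key, zs in per_param_z.items():
        if zs:
            report.simple_rmsz[key] = rmsz(zs)
            report.simple_rmsz_sd[key] = jackknife_sd(zs)
    if zbpg_values:
        report.rmsz_bpg = rmsz(zbpg_values)
        report.rmsz_bpg_sd = jackknife_sd(zbpg_values)
    return report
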