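"""Target mining: extract, filter, pool and aggregate base-pair
observations from an annotated structure collection.

The pipeline mirrors how the shipped target tables were derived: detect
Watson–Crick pairs, keep only those where both nucleotides have RSCC ≥
0.95 and the entry resolution is at or below the cutoff (1.60 Å by
default), canonicalize shear/buckle signs, and compute per-class
counts, means and sample standard deviations.  A Welch two-sided t-test
(p < 0.01) decides whether two samples — e.g. modified vs natural
pairs, or the same bond across categories — may be pooled.  The
resolution sweep tabulates per-class counts over cutoffs from 2.00 to
1.50 Å in 0.05 Å steps to support choosing a cutoff; the choice itself
stays with the analyst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Structure
from .pairing import PairScreen, detect_pairs
from .targets import SIMPLE_PARAM_KEYS, TargetEntry, TargetTable

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationRecord", "MiningConfig", "extract_observations",
    "filter_observations", "aggregate_targets", "pool_test", "PoolResult",
    "resolution_sweep", "write_records", "read_records", "tables_from_aggregate",
]

_PARAM_COLS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")


@dataclass(frozen=True)
class ObservationRecord:
    entry_id: str
    category: str
    pair_type: str
    contains_modified: bool
    bonds: dict[str, float]       # atom-pair key → distance, Å
    params: dict[str, float]      # simple parameters (canonical signs)
    resolution: float
    rscc_i: float | None = None
    rscc_j: float | None = None


@dataclass(frozen=True)
class MiningConfig:
    rscc_min: float = 0.95
    resolution_max: float = 1.60       # Å
    alpha: float = 0.01
    sweep_start: float = 2.00          # Å, sweep runs descending
    sweep_stop: float = 1.50
    sweep_step: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sweep_start < self.sweep_stop:
            raise ValueError("sweep must run from a loose to a tight cutoff")

    def sweep_cutoffs(self) -> list[float]:
        n = int(round((self.sweep_start - self.sweep_stop) / self.sweep_step))
        return [round(self.sweep_start - i * self.sweep_step, 10) for i in range(n + 1)]


def extract_observations(structures: Iterable[Structure],
                         screen: PairScreen = PairScreen(),
                         ) -> list[ObservationRecord]:
    """One record per detected Watson–Crick pair with complete standard
    hydrogen bonds; entries without a resolution are skipped (logged)."""
    records: list[ObservationRecord] = []
    for structure in structures:
        if structure.resolution is None:
            logger.warning("entry %s: no resolution, skipped", structure.entry_id)
            continue
        try:
            pairs, _ = detect_pairs(structure, screen)
        except Exception as exc:  # per-entry failure must not kill the run
            logger.error("entry %s: extraction failed: %s", structure.entry_id, exc)
            continue
        for pair in pairs:
            if any(h.missing or h.distance is None for h in pair.hbonds):
                continue
            records.append(ObservationRecord(
                entry_id=structure.entry_id,
                category=pair.category,
                pair_type=pair.pair_type,
                contains_modified=pair.contains_modified,
                bonds={f"{h.atom_i}-{h.atom_j}": h.distance for h in pair.hbonds},
                params=pair.params.as_dict(),
                resolution=structure.resolution,
                rscc_i=structure.per_residue_rscc.get(pair.res_i),
                rscc_j=structure.per_residue_rscc.get(pair.res_j),
            ))
    return records


def filter_observations(records: Sequence[ObservationRecord],
                        config: MiningConfig = MiningConfig(),
                        ) -> list[ObservationRecord]:
    """Keep records with both RSCC ≥ rscc_min and resolution ≤
    resolution_max; records without RSCC annotation are dropped."""
    return [r for r in records
            if r.rscc_i is not None and r.rscc_j is not None
            and r.rscc_i >= config.rscc_min and r.rscc_j >= config.rscc_min
            and r.resolution <= config.resolution_max]


def aggregate_targets(records: Sequence[ObservationRecord],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class counts, means and sample (n−1) standard deviations.

    Returns ``(hbond_table, simple_table)`` in the target-table column
    layout (category, pair_type, key, mean, sd, count).  Empty cells are
    simply absent; single-observation cells carry sd = NaN.  Only the
    four validated parameters (shear, stretch, buckle, propeller) are
    aggregated.
    """
    bond_rows, param_rows = [], []
    for r in records:
        for key, d in r.bonds.items():
            bond_rows.append((r.category, r.pair_type, key, d))
        for key in SIMPLE_PARAM_KEYS:
            param_rows.append((r.category, r.pair_type, key, r.params[key]))

    def agg(rows: list) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame(columns=["category", "pair_type", "key",
                                         "mean", "sd", "count"])
        df = pd.DataFrame(rows, columns=["category", "pair_type", "key", "value"])
        out = (df.groupby(["category", "pair_type", "key"], sort=True)["value"]
                 .agg(mean="mean", sd="std", count="count").reset_index())
        out["count"] = out["count"].astype(int)
        return out

    return agg(bond_rows), agg(param_rows)


def tables_from_aggregate(hbond_table: pd.DataFrame,
                          simple_table: pd.DataFrame) -> TargetTable:
    """Turn aggregated mining output into a loadable TargetTable
    (rows with fewer than 2 observations are dropped: no sd)."""
    def entries(df: pd.DataFrame) -> list[TargetEntry]:
        out = []
        for row in df.itertuples():
            if row.count < 2 or not np.isfinite(row.sd) or row.sd <= 0:
                continue
            out.append(TargetEntry(category=row.category, pair_type=row.pair_type,
                                   key=row.key, mean=float(row.mean),
                                   sd=float(row.sd), count=int(row.count)))
        return out
    return TargetTable(entries(hbond_table), entries(simple_table))


@dataclass(frozen=True)
class PoolResult:
    poolable: bool | None    # None = undetermined (n < 2 on either side)
    p_value: float | None


def pool_test(sample_a: Sequence[float], sample_b: Sequence[float],
              alpha: float = 0.01) -> PoolResult:
    """Welch (unequal-variance) two-sided t-test; the samples are
    distinct — not poolable — iff p < alpha."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return PoolResult(poolable=None, p_value=None)
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return PoolResult(poolable=bool(p >= alpha), p_value=p)


def resolution_sweep(records: Sequence[ObservationRecord],
                     config: MiningConfig = MiningConfig()) -> pd.DataFrame:
    """Per-class pair counts at each resolution cutoff of the sweep.

    One row per cutoff with a column per (category, pair_type) class and
    a total; counts are monotone non-increasing as the cutoff tightens.
    """
    rows = []
    for cutoff in config.sweep_cutoffs():
        kept = filter_observations(
            records, MiningConfig(rscc_min=config.rscc_min, resolution_max=cutoff,
                                  alpha=config.alpha))
        row: dict[str, float] = {"cutoff": cutoff, "total": len(kept)}
        for r in kept:
            col = f"{r.category}/{r.pair_type}"
            row[col] = row.get(col, 0) + 1
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0)
    count_cols = [c for c in df.columns if c != "cutoff"]
    df[count_cols] = df[count_cols].astype(int)
    return df


_TSV_COLS = ["entry_id", "category", "pair_type", "contains_modified",
             "resolution", "rscc_i", "rscc_j", *_PARAM_COLS, "bonds"]


def write_records(records: Sequence[ObservationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        bonds = ";".join(f"{k}={v:.4f}" for k, v in sorted(r.bonds.items()))
        rows.append([r.entry_id, r.category, r.pair_type, int(r.contains_modified),
                     r.resolution, r.rscc_i, r.rscc_j,
                     *[r.params.get(c, np.nan) for c in _PARAM_COLS], bonds])
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[ObservationRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        bonds = {}
        if isinstance(row.bonds, str) and row.bonds:
            for item in row.bonds.split(";"):
                k, v = item.split("=")
                bonds[k] = float(v)
        params = {c: float(getattr(row, c)) for c in _PARAM_COLS
                  if np.isfinite(getattr(row, c))}
        records.append(ObservationRecord(
            entry_id=str(row.entry_id), category=row.category,
            pair_type=row.pair_type, contains_modified=bool(row.contains_modified),
            bonds=bonds, params=params, resolution=float(row.resolution),
            rscc_i=None if pd.isna(row.rscc_i) else float(row.rscc_i),
            rscc_j=None if pd.isna(row.rscc_j) else float(row.rscc_j)))
    return records
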