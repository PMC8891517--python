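"""Screening analytics over %ADS tables.

A screen produces one %ADS value per peptide sequence (tagged with the
simulation time it came from).  The design rules are derived from summary
statistics over these tables: per-amino-acid presence averages and spreads,
terminal-versus-interior positional preference, threshold counts, top and
bottom rankings, and paired comparisons between screening timescales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_space import CANONICAL_RESIDUES, validate_sequence

__all__ = [
    "AdsTable",
    "AdsTableError",
    "load_ads_table",
    "aa_presence_stats",
    "positional_preference",
    "PositionalPreference",
    "count_above",
    "rank",
    "compare_timescales",
]


class AdsTableError(ValueError):
    """A %ADS table failed validation."""


@dataclass
class AdsTable:
    """Sequences with their %ADS values and a simulation-time tag.

    Wraps a DataFrame with columns ``sequence``, ``percent_ads``,
    ``time_tag``.  Within one time tag sequences are unique, %ADS lies in
    [0, 100], and all sequences share one length.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sequence", "percent_ads", "time_tag"}
        missing = required - set(self.df.columns)
        if missing:
            raise AdsTableError(f"missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        problems = []
        for i, seq in df["sequence"].items():
            try:
                validate_sequence(seq)
            except ValueError as exc:
                problems.append(f"row {i}: {exc}")
        ads = pd.to_numeric(df["percent_ads"], errors="coerce")
        for i in df.index[ads.isna() | (ads < 0) | (ads > 100)]:
            problems.append(f"row {i}: percent_ads {df.at[i, 'percent_ads']!r} outside [0, 100]")
        for i in df.index[df.duplicated(subset=["sequence", "time_tag"], keep="first")]:
            problems.append(f"row {i}: duplicate sequence {df.at[i, 'sequence']!r}")
        if not problems and df["sequence"].str.len().nunique() > 1:
            problems.append("sequences do not share a single length")
        if problems:
            raise AdsTableError("; ".join(problems))
        df["percent_ads"] = ads
        self.df = df

    @classmethod
    def from_records(
        cls, records: Mapping[str, float] | Sequence[tuple], time_tag: str = "100ns"
    ) -> "AdsTable":
        items = records.items() if isinstance(records, Mapping) else records
        rows = [(s, v, time_tag) for s, v in items]
        return cls(pd.DataFrame(rows, columns=["sequence", "percent_ads", "time_tag"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sequences(self) -> pd.Series:
        return self.df["sequence"]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def load_ads_table(
    path: str | Path,
    fmt: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
    time_tag: Optional[str] = None,
    sheet: int | str = 0,
) -> AdsTable:
    """Read a %ADS table from CSV or XLSX and validate it.

    ``column_map`` maps file column names to the canonical ``sequence`` /
    ``percent_ads`` / ``time_tag`` names; ``time_tag`` supplies a constant
    tag for files without one.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        raw = pd.read_csv(path)
    elif fmt == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    if "time_tag" not in raw.columns:
        raw["time_tag"] = time_tag if time_tag is not None else "100ns"
    keep = [c for c in ("sequence", "percent_ads", "time_tag") if c in raw.columns]
    return AdsTable(raw[keep].copy())


def aa_presence_stats(table: AdsTable, ddof: int = 1, weighted: bool = False) -> pd.DataFrame:
    """Per-amino-acid presence statistics, sorted by mean %ADS descending.

    For each amino acid that occurs in at least one sequence: the mean and
    standard deviation of %ADS over all sequences *containing* it (each
    sequence counted once regardless of multiplicity — set
    ``weighted=True`` to weight by occurrence count), plus its prevalence
    (percentage of table sequences containing it).  ``ddof=1`` gives the
    sample standard deviation; ``ddof=0`` the population one.
    """
    if len(table) == 0:
        raise AdsTableError("cannot summarise an empty table")
    seqs = table.df["sequence"].to_numpy()
    ads = table.df["percent_ads"].to_numpy(float)
    rows = []
    for aa in CANONICAL_RESIDUES:
        counts = np.array([s.count(aa) for s in seqs])
        present = counts > 0
        n_seq = int(present.sum())
        if n_seq == 0:
            continue
        if weighted:
            w = counts[present].astype(float)
            mean = float(np.average(ads[present], weights=w))
            var = float(np.average((ads[present] - mean) ** 2, weights=w))
            if ddof and n_seq > 1:
                var *= n_seq / (n_seq - ddof)
            sd = float(np.sqrt(var))
        else:
            mean = float(ads[present].mean())
            sd = float(ads[present].std(ddof=ddof)) if n_seq > ddof else 0.0
        rows.append(
            {
                "aa": aa,
                "mean_ads": mean,
                "sd_ads": sd,
                "prevalence_pct": 100.0 * n_seq / len(table),
                "n_sequences": n_seq,
            }
        )
    out = pd.DataFrame(rows).set_index("aa")
    return out.sort_values("mean_ads", ascending=False)


@dataclass
class PositionalPreference:
    """Terminal-versus-interior %ADS split for one amino acid."""

    aa: str
    terminal_mean: float
    middle_mean: float
    n_terminal: int
    n_middle: int

    @property
    def empty(self) -> bool:
        return self.n_terminal + self.n_middle == 0


def positional_preference(table: AdsTable, aa: str) -> PositionalPreference:
    """Mean %ADS of sequences holding ``aa`` terminally vs only internally.

    A sequence with ``aa`` both at a terminus and inside is assigned to the
    terminal class.  Empty classes yield NaN means; if the amino acid is
    absent altogether the result is flagged empty and a warning issued.
    """
    if aa not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue code {aa!r}")
    seqs = table.df["sequence"]
    ads = table.df["percent_ads"]
    terminal = (seqs.str[0] == aa) | (seqs.str[-1] == aa)
    middle = seqs.str.slice(1, -1).str.contains(aa, regex=False) & ~terminal
    if not (terminal.any() or middle.any()):
        warnings.warn(f"{aa!r} does not occur in the table")
    return PositionalPreference(
        aa=aa,
        terminal_mean=float(ads[terminal].mean()) if terminal.any() else float("nan"),
        middle_mean=float(ads[middle].mean()) if middle.any() else float("nan"),
        n_terminal=int(terminal.sum()),
        n_middle=int(middle.sum()),
    )


def count_above(table: AdsTable, threshold: float) -> int:
    """Number of sequences with %ADS strictly greater than ``threshold``."""
    return int((table.df["percent_ads"] > threshold).sum())


def rank(table: AdsTable, k: int, direction: str = "top") -> pd.DataFrame:
    """The ``k`` best (or worst) sequences by %ADS.

    Ties are broken lexicographically by sequence, so the ordering is
    deterministic.  ``k`` larger than the table is truncated with a warning.
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if k > len(table):
        warnings.warn(f"k={k} exceeds table size {len(table)}; truncating")
        k = len(table)
    df = table.df.sort_values(
        ["percent_ads", "sequence"],
        ascending=[direction == "bottom", True],
        kind="mergesort",
    )
    return df[["sequence", "percent_ads"]].head(k).reset_index(drop=True)


def compare_timescales(table_a: AdsTable, table_b: AdsTable) -> pd.DataFrame:
    """Pair two screens of the same sequences run at different timescales.

    Inner-joins on sequence and reports ``delta = b - a`` together with a
    ``crossed_50`` flag marking sequences below 50% in the short screen that
    reach 50% in the long one — the interesting exceptions when a short
    screen is used to discard candidates.
    """
    merged = pd.merge(
        table_a.df[["sequence", "percent_ads"]],
        table_b.df[["sequence", "percent_ads"]],
        on="sequence",
        suffixes=("_a", "_b"),
    )
    if merged.empty:
        raise ValueError("the two tables share no sequences")
    merged["delta"] = merged["percent_ads_b"] - merged["percent_ads_a"]
    merged["crossed_50"] = (merged["percent_ads_a"] < 50.0) & (merged["percent_ads_b"] >= 50.0)
    return merged.sort_values("percent_ads_a", ascending=False).reset_index(drop=True)
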