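"""TRAP quartile construction, DEG filtration, ranked binning, symbol mapping."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CresigError, TrapList, validate_deg_table

log = logging.getLogger(__name__)


@dataclass
class BinProfile:
    """Per-bin summaries of a ranked transcriptome.

    ``table`` columns: bin (1-based), section, n, median_logFC, median_p_adj,
    q1_count.  ``assignments`` maps gene -> bin index (every gene in exactly
    one bin).
    """

    table: pd.DataFrame
    assignments: pd.Series


def build_q1(trap: TrapList, quartile: int = 1) -> set[str]:
    """Genes in the requested abundance quartile (1 = most abundant).

    Quartile boundaries use ceil(G/4); ties on abundance are already broken
    by gene symbol inside :class:`TrapList`.
    """
    if not 1 <= quartile <= 4:
        raise CresigError("quartile must be in 1..4")
    g = len(trap)
    if g == 0:
        raise CresigError("empty TRAP list")
    size = math.ceil(g / 4)
    lo, hi = (quartile - 1) * size, min(quartile * size, g)
    return set(trap.table["gene"].iloc[lo:hi])


def average_trap_profiles(traps: list[TrapList]) -> TrapList:
    """Arithmetic per-gene mean of abundances over the lists containing the gene."""
    if len(traps) < 2:
        raise CresigError("averaging needs >=2 TRAP lists")
    frames = [t.table[["gene", "abundance"]] for t in traps]
    merged = pd.concat(frames, ignore_index=True)
    mean = merged.groupby("gene", as_index=False)["abundance"].mean()
    return TrapList(mean)


def filter_by_set(degs: pd.DataFrame, keep: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a DEG table into (kept, rest) by gene-set membership."""
    degs = validate_deg_table(degs)
    mask = degs["gene"].isin(keep)
    kept = degs[mask].reset_index(drop=True)
    rest = degs[~mask].reset_index(drop=True)
    return kept, rest


def rank_transcriptome(degs: pd.DataFrame, key: str = "t_mod") -> pd.DataFrame:
    """Order the whole transcriptome: UP genes first by decreasing statistic,
    then DOWN genes ending with the most significant down-regulation.

    With a signed statistic this is a single descending sort; ties are broken
    by gene symbol for determinism.
    """
    degs = validate_deg_table(degs)
    out = degs.sort_values([key, "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def bin_profile(ranked: pd.DataFrame, bin_size: int, q1: set[str]) -> BinProfile:
    """Summarize consecutive rank-order bins of ``bin_size`` genes.

    Per bin: median logFC, median adjusted p, count of Q1-TRAP members and a
    section label (majority direction).  A final short bin is retained so
    that bin counts always sum to the input size.
    """
    if bin_size < 2:
        raise CresigError("bin_size must be >= 2")
    ranked = validate_deg_table(ranked)
    n = len(ranked)
    if n == 0:
        raise CresigError("cannot bin an empty table")
    if bin_size > n:
        log.warning("bin_size %d > %d genes; using a single bin", bin_size, n)
        bin_size = n
    idx = np.arange(n) // bin_size + 1
    rows = []
    for b, chunk in ranked.groupby(idx, sort=True):
        n_up = int((chunk["direction"] == "UP").sum())
        rows.append(
            {
                "bin": int(b),
                "section": "UP" if n_up * 2 >= len(chunk) else "DOWN",
                "n": len(chunk),
                "median_logFC": float(chunk["logFC"].median()),
                "median_p_adj": float(chunk["p_adj"].median()),
                "q1_count": int(chunk["gene"].isin(q1).sum()),
            }
        )
    assignments = pd.Series(idx, index=ranked["gene"].to_numpy(), name="bin")
    return BinProfile(pd.DataFrame(rows), assignments)


def write_bin_profile(profile: BinProfile, path) -> None:
    cols = ["bin", "section", "n", "median_logFC", "median_p_adj", "q1_count"]
    profile.table[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


def map_symbols(table: pd.DataFrame, mapping: dict[str, str], key: str = "gene") -> pd.DataFrame:
    """Translate gene identifiers through a mapping table.

    Unmapped rows are dropped (and counted in the log).  Many-to-one
    collisions keep the row with the largest |t_mod| when present, otherwise
    the first occurrence after a stable sort on the new symbol.
    """
    t = table.copy()
    t["__new"] = t[key].map(mapping)
    n_dropped = int(t["__new"].isna().sum())
    if n_dropped:
        log.info("map_symbols: dropped %d unmapped rows", n_dropped)
    t = t.dropna(subset=["__new"])
    if "t_mod" in t.columns:
        t["__abs_t"] = t["t_mod"].abs()
        t = t.sort_values(["__new", "__abs_t", key], ascending=[True, False, True], kind="mergesort")
        t = t.drop(columns="__abs_t")
    else:
        t = t.sort_values(["__new", key], kind="mergesort")
    t = t.drop_duplicates(subset="__new", keep="first")
    t = t.drop(columns=key).rename(columns={"__new": key})
    cols = [key] + [c for c in table.columns if c != key]
    return t[cols].reset_index(drop=True)
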