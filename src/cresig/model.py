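"""Shared domain types used across the pipeline stages.

Tabular data is held in :class:`pandas.DataFrame` / :class:`pandas.Series`
containers wrapped by light validating dataclasses, so every stage can rely
on the invariants being checked once at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed column order of differential-expression tables on disk.
DEG_COLUMNS = ["gene", "logFC", "t_mod", "p_raw", "p_adj", "direction", "mean_expr"]


class CresigError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes x samples, with condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    conditions
        Series mapping sample id -> condition label; must cover every sample.
    """

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise CresigError(f"duplicate gene ids: {list(dupes[:5])}")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise CresigError(f"samples without condition label: {sorted(missing)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CresigError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise CresigError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        hits = [s for s in self.values.columns if self.conditions[s] == condition]
        if not hits:
            raise CresigError(f"no samples with condition {condition!r}")
        return hits


@dataclass
class TrapList:
    """Cell-type abundance list (TRAP-style), ranked by descending abundance.

    ``table`` has columns ``gene`` and ``abundance``; a dense ``rank`` column
    (1 = most abundant) is computed on construction.  Ties on abundance are
    broken by lexicographic gene symbol so ranking is deterministic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not {"gene", "abundance"}.issubset(t.columns):
            raise CresigError("TrapList needs 'gene' and 'abundance' columns")
        if t["gene"].duplicated().any():
            raise CresigError("duplicate genes in TRAP list")
        ab = t["abundance"].to_numpy(dtype=float)
        if not np.isfinite(ab).all():
            raise CresigError("TRAP abundances must be finite")
        if (ab < 0).any():
            raise CresigError("TRAP abundances must be nonnegative")
        t = t.sort_values(["abundance", "gene"], ascending=[False, True], kind="mergesort")
        t = t.reset_index(drop=True)
        t["rank"] = np.arange(1, len(t) + 1)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, GSEA sets, registries, quartile lists)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise CresigError(f"gene set {name!r} is empty")
        self.descriptions = {n: self.descriptions.get(n, "") for n in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class RunConfig:
    """Pipeline-wide analysis parameters with study defaults."""

    alpha: float = 0.05
    adjust_method: str = "BH"  # 'none' or 'BH'
    bin_size: int = 250
    promoter_window: tuple[int, int] = (-450, 50)
    gsea_n_perm: int = 1000
    gsea_exponent: float = 1.0
    go_min_genes: int = 3
    go_min_pct: float = 2.0
    go_kappa_threshold: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise CresigError("alpha must be in (0,1)")
        if self.adjust_method not in ("none", "BH"):
            raise CresigError("adjust_method must be 'none' or 'BH'")
        if self.bin_size < 2:
            raise CresigError("bin_size must be >= 2")
        if self.gsea_n_perm < 100:
            raise CresigError("gsea_n_perm must be >= 100")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "adjust_method": self.adjust_method,
            "bin_size": self.bin_size,
            "promoter_window": list(self.promoter_window),
            "gsea_n_perm": self.gsea_n_perm,
            "gsea_exponent": self.gsea_exponent,
            "go_min_genes": self.go_min_genes,
            "go_min_pct": self.go_min_pct,
            "go_kappa_threshold": self.go_kappa_threshold,
            "seed": self.seed,
        }


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check DEG-table invariants and return the table in canonical column order.

    Invariants: one row per gene; direction is 'UP' iff logFC > 0;
    p_adj >= p_raw; probabilities in [0, 1].
    """
    missing = [c for c in DEG_COLUMNS if c not in table.columns]
    if missing:
        raise CresigError(f"DEG table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].unique()
        raise CresigError(f"duplicate genes in DEG table: {list(dupes[:5])}")
    up = table["direction"] == "UP"
    if not (up == (table["logFC"] > 0)).all():
        raise CresigError("direction must be UP iff logFC > 0")
    for col in ("p_raw", "p_adj"):
        p = table[col].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise CresigError(f"{col} out of [0,1]")
    if (table["p_adj"].to_numpy() < table["p_raw"].to_numpy() - 1e-12).any():
        raise CresigError("p_adj must be >= p_raw")
    extra = [c for c in table.columns if c not in DEG_COLUMNS]
    return table[DEG_COLUMNS + extra]


def require_mapping(conditions: Mapping[str, str], samples) -> pd.Series:
    """Build a condition Series, erroring on unknown samples in the map."""
    unknown = set(conditions) - set(samples)
    if unknown:
        raise CresigError(f"condition map names unknown samples: {sorted(unknown)}")
    return pd.Series(dict(conditions))
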