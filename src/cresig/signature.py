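"""Multi-condition core-signature extraction and cross-cell-type comparison.

The headline cascade: genes significant in every condition (within the TRAP
first quartile), then up-regulated in every condition, then cross-referenced
against a CRE-target registry, ranked by average log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model import CresigError, validate_deg_table


@dataclass
class CoreSignature:
    """Ordered core genes with per-condition fold changes and provenance flags.

    ``table`` columns: gene, logFC_<cond> per condition, avg_fc, in_registry,
    q1_trap, category (optional).  ``counts`` records the cascade sizes:
    shared (significant in all), up_in_all, in_registry.
    """

    table: pd.DataFrame
    conditions: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class OverlapReport:
    regions: dict[str, int]
    percentages: dict[str, float]  # "A|B" -> % of A's genes found in B
    pearson: dict[str, float] = field(default_factory=dict)


def venn_overlap(sets: dict[str, set[str]]) -> OverlapReport:
    """Exact Venn region counts and directional overlap percentages for 2-3 sets.

    Region keys are '+'-joined sorted subset names (e.g. 'A+B' holds genes in
    A and B but no other set); percentage key 'A|B' is 100*|A∩B|/|A|.
    """
    if not 2 <= len(sets) <= 3:
        raise CresigError("venn_overlap supports 2 or 3 sets")
    for name, s in sets.items():
        if not s:
            raise CresigError(f"set {name!r} is empty")
    names = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions["+".join(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    percentages = {}
    for a in names:
        for b in names:
            if a != b:
                percentages[f"{a}|{b}"] = 100.0 * len(sets[a] & sets[b]) / len(sets[a])
    return OverlapReport(regions, percentages)


def pearson_logfc(a: pd.DataFrame, b: pd.DataFrame, universe: set[str] | None = None) -> float:
    """Pearson correlation of logFC between two DEG tables over shared genes."""
    a = validate_deg_table(a)
    b = validate_deg_table(b)
    fa = a.set_index("gene")["logFC"]
    fb = b.set_index("gene")["logFC"]
    shared = fa.index.intersection(fb.index)
    if universe is not None:
        shared = shared.intersection(pd.Index(sorted(universe)))
    if len(shared) < 3:
        raise CresigError("Pearson correlation needs >=3 shared genes")
    x = fa.loc[shared].to_numpy(dtype=float)
    y = fb.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise CresigError("zero variance in logFC; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def extract_core(
    deg_tables: dict[str, pd.DataFrame],
    q1: set[str],
    registry: set[str],
    q1_first: bool = True,
) -> CoreSignature:
    """Intersect per-condition DEG lists, keep genes UP everywhere, flag by
    registry membership, and rank by descending average log2 fold change.

    With ``q1_first`` (default) the intersection is taken over Q1-filtered
    lists; otherwise over the raw DEG lists, with the Q1 flag still reported.
    The cascade counts (shared / up_in_all / in_registry) mirror the
    intermediate list sizes.
    """
    if len(deg_tables) < 2:
        raise CresigError("core extraction needs >=2 condition tables")
    conditions = sorted(deg_tables)
    per_cond: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        t = validate_deg_table(deg_tables[cond])
        per_cond[cond] = t.set_index("gene")
    gene_sets = []
    for cond in conditions:
        genes = set(per_cond[cond].index)
        if q1_first:
            genes &= q1
        gene_sets.append(genes)
    shared = set.intersection(*gene_sets)
    up_in_all = {
        g for g in shared if all(per_cond[c].at[g, "logFC"] > 0 for c in conditions)
    }
    in_registry = up_in_all & registry
    rows = []
    for g in sorted(up_in_all):
        fcs = {f"logFC_{c}": float(per_cond[c].at[g, "logFC"]) for c in conditions}
        rows.append(
            {
                "gene": g,
                **fcs,
                "avg_fc": float(np.mean(list(fcs.values()))),
                "in_registry": g in registry,
                "q1_trap": g in q1,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", *(f"logFC_{c}" for c in conditions), "avg_fc", "in_registry", "q1_trap"],
    )
    if len(table):
        table = table.sort_values(["avg_fc", "gene"], ascending=[False, True], kind="mergesort")
        table = table.reset_index(drop=True)
    counts = {
        "shared": len(shared),
        "up_in_all": len(up_in_all),
        "in_registry": len(in_registry),
    }
    return CoreSignature(table, conditions, counts)


def compare_cell_signatures(
    sig_a: CoreSignature,
    sig_b: CoreSignature,
    categories: dict[str, str] | None = None,
) -> dict:
    """Shared genes between two cell-type signatures plus optional category mix.

    With a gene->category map, per-signature category percentages are
    reported (genes without a category count as 'unassigned').
    """
    a, b = set(sig_a.genes), set(sig_b.genes)
    out: dict = {"shared": sorted(a & b), "n_shared": len(a & b)}
    if categories is not None:
        for label, genes in (("a", sig_a.genes), ("b", sig_b.genes)):
            if genes:
                cats = pd.Series([categories.get(g, "unassigned") for g in genes])
                out[f"category_pct_{label}"] = (
                    (cats.value_counts() / len(genes) * 100.0).to_dict()
                )
            else:
                out[f"category_pct_{label}"] = {}
    return out


def curated_function_screen(
    deg_tables: dict[str, pd.DataFrame],
    function_lists: dict[str, set[str]],
) -> pd.DataFrame:
    """Presence matrix of curated function-list genes across DEG conditions.

    One row per (function, gene) pair where the gene is a DEG in at least one
    condition; boolean column per condition plus a 'core' column (DEG in all).
    """
    conditions = sorted(deg_tables)
    deg_sets = {c: set(validate_deg_table(t)["gene"]) for c, t in deg_tables.items()}
    rows = []
    for fname in sorted(function_lists):
        for g in sorted(function_lists[fname]):
            present = {c: g in deg_sets[c] for c in conditions}
            if any(present.values()):
                rows.append(
                    {"function": fname, "gene": g, **present, "core": all(present.values())}
                )
    return pd.DataFrame(rows, columns=["function", "gene", *conditions, "core"])


def write_signature(sig: CoreSignature, path) -> None:
    sig.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_signature(path, conditions: list[str] | None = None) -> CoreSignature:
    table = pd.read_csv(path, sep="\t", comment="#")
    conds = conditions or [c[len("logFC_"):] for c in table.columns if c.startswith("logFC_")]
    counts = {
        "shared": len(table),
        "up_in_all": len(table),
        "in_registry": int(table["in_registry"].sum()) if "in_registry" in table else 0,
    }
    return CoreSignature(table, conds, counts)
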