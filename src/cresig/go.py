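"""Term-level enrichment/depletion: two-sided hypergeometric test with
Bonferroni correction, term-selection filters and kappa-based term grouping."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CresigError, GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class GoConfig:
    min_genes: int = 3
    min_pct: float = 2.0  # percent of term size that must be query hits
    kappa_threshold: float = 0.5
    min_group: int = 2
    merge_share: float = 50.0  # percent shared genes required to merge groups


def hypergeom_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided hypergeometric p by tail doubling, capped at 1.

    X ~ Hypergeometric(N population, K marked, n drawn);
    p = min(1, 2*min(P(X >= k), P(X <= k))).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise CresigError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    dist = stats.hypergeom(N, K, n)
    upper = float(dist.sf(k - 1))
    lower = float(dist.cdf(k))
    return min(1.0, 2.0 * min(upper, lower))


def term_filters(
    terms: GeneSetCollection,
    query: set[str],
    min_genes: int = 3,
    min_pct: float = 2.0,
) -> list[str]:
    """Terms with >= min_genes query hits that are >= min_pct % of term size."""
    eligible = []
    for name, members in terms.items():
        hits = len(members & query)
        if hits >= min_genes and hits * 100.0 >= min_pct * len(members):
            eligible.append(name)
    return eligible


def cohen_kappa(a: set[str], b: set[str], universe: set[str]) -> float:
    """Cohen's kappa of two membership indicators over the universe."""
    if not a or not b:
        raise CresigError("kappa needs non-empty memberships")
    n = len(universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pa1 = (n11 + n10) / n
    pb1 = (n11 + n01) / n
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_matrix(terms: GeneSetCollection, names: list[str], universe: set[str]) -> pd.DataFrame:
    """Pairwise kappa over the given term names (symmetric, unit diagonal)."""
    mat = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mat[i, j] = mat[j, i] = cohen_kappa(terms[names[i]], terms[names[j]], universe)
    return pd.DataFrame(mat, index=names, columns=names)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def kappa_grouping(
    terms: GeneSetCollection,
    names: list[str],
    universe: set[str],
    threshold: float = 0.5,
    min_group: int = 2,
    merge_share: float = 50.0,
) -> dict[str, int]:
    """Group terms by membership agreement.

    Single-linkage components over term pairs with kappa >= threshold; groups
    are then iteratively merged while any pair shares >= merge_share percent
    of the smaller group's genes.  Terms left in components smaller than
    ``min_group`` stay as singleton groups.
    """
    if not names:
        return {}
    km = kappa_matrix(terms, names, universe)
    uf = _UnionFind(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if km.iat[i, j] >= threshold:
                uf.union(i, j)
    comps: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        comps.setdefault(uf.find(i), []).append(name)
    groups = list(comps.values())

    def genes_of(group: list[str]) -> set[str]:
        out: set[str] = set()
        for t in group:
            out |= terms[t]
        return out

    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = genes_of(groups[i]), genes_of(groups[j])
                share = 100.0 * len(gi & gj) / min(len(gi), len(gj))
                if share >= merge_share and len(groups[i]) >= min_group and len(groups[j]) >= min_group:
                    groups[i] = groups[i] + groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    assignment: dict[str, int] = {}
    for gid, group in enumerate(sorted(groups, key=lambda g: sorted(g)[0]), start=1):
        for t in group:
            assignment[t] = gid
    return assignment


def run_go(
    query_up: set[str],
    query_down: set[str],
    terms: GeneSetCollection,
    universe: set[str],
    cfg: GoConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Enrichment of UP and DOWN query lists, run independently per direction.

    Per direction: term filters -> two-sided hypergeometric tests ->
    Bonferroni over the tested terms -> kappa grouping of the tested terms.
    Output frames carry -log10(p_bonf) for heatmap export.
    """
    cfg = cfg or GoConfig()
    out: dict[str, pd.DataFrame] = {}
    for label, query in (("UP", query_up), ("DOWN", query_down)):
        query = query & universe
        if not query:
            out[label] = pd.DataFrame(
                columns=["term", "k", "K", "n", "N", "p_two", "p_bonf",
                         "neg_log10_p_bonf", "direction", "group_id"]
            )
            continue
        eligible = term_filters(terms, query, cfg.min_genes, cfg.min_pct)
        n_tests = len(eligible)
        rows = []
        for name in eligible:
            members = terms[name] & universe
            k, K, n, N = len(members & query), len(members), len(query), len(universe)
            p_two = hypergeom_two_sided(k, K, n, N)
            rows.append(
                {
                    "term": name,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_two": p_two,
                    "p_bonf": min(1.0, p_two * n_tests),
                    "direction": "enriched" if k * N > n * K else "depleted",
                }
            )
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["neg_log10_p_bonf"] = -np.log10(frame["p_bonf"].clip(lower=1e-300))
            groups = kappa_grouping(
                terms, eligible, universe, cfg.kappa_threshold, cfg.min_group, cfg.merge_share
            )
            frame["group_id"] = frame["term"].map(groups)
            frame = frame.sort_values("p_two", kind="mergesort").reset_index(drop=True)
        out[label] = frame
    return out
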