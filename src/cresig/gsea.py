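"""Pre-ranked gene-set enrichment: weighted running-sum ES, gene-set
permutation null, sign-matched NES and add-one nominal p-values."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CresigError, GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes with signed scores, sorted descending (ties broken by symbol)."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if genes.size != scores.size:
            raise CresigError("genes and scores must have equal length")
        if len(set(genes)) != genes.size:
            raise CresigError("duplicate genes in ranked list")
        if not np.isfinite(scores).all():
            raise CresigError("ranked scores must be finite")
        order = np.lexsort((genes, -scores))
        self.genes = genes[order]
        self.scores = scores[order]

    def __len__(self) -> int:
        return self.genes.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankedList":
        return cls(df["gene"].to_numpy(), df["score"].to_numpy())


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    nom_p: float
    n_perm: int
    peak_rank: int
    leading_edge: list[str] = field(default_factory=list)


def _hit_mask(ranked: RankedList, gene_set: set[str]) -> np.ndarray:
    mask = np.isin(ranked.genes, list(gene_set))
    return mask


def _running_sum(scores: np.ndarray, hits: np.ndarray, exponent: float) -> np.ndarray:
    n = scores.size
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise CresigError("gene set has no genes in the ranked list")
    if n_hits == n:
        raise CresigError("gene set covers the entire ranked list")
    weights = np.abs(scores) ** exponent
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hits) / float(n - n_hits)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set: set[str], exponent: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted Kolmogorov-Smirnov-style enrichment score.

    Hits advance the running sum by |score|^exponent (normalized over hits);
    misses retreat by 1/(N - N_hits).  The ES is the extremum of largest
    absolute deviation, signed.  Returns (ES, running sum, peak rank).
    """
    hits = _hit_mask(ranked, gene_set)
    run = _running_sum(ranked.scores, hits, exponent)
    peak = int(np.abs(run).argmax())
    return float(run[peak]), run, peak


def leading_edge(ranked: RankedList, gene_set: set[str], exponent: float = 1.0) -> list[str]:
    """Hit genes at or before (after, for negative ES) the running-sum peak."""
    hits = _hit_mask(ranked, gene_set)
    run = _running_sum(ranked.scores, hits, exponent)
    peak = int(np.abs(run).argmax())
    if run[peak] >= 0:
        sel = hits[: peak + 1]
        return list(ranked.genes[: peak + 1][sel])
    sel = hits[peak:]
    return list(ranked.genes[peak:][sel])


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int,
    seed: int,
    exponent: float = 1.0,
) -> np.ndarray:
    """ES of ``n_perm`` random gene sets of ``set_size`` (sampled w/o replacement)."""
    n = len(ranked)
    if not 1 <= set_size < n:
        raise CresigError("set_size must be in [1, N)")
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** exponent
    miss_step = -1.0 / (n - set_size)
    out = np.empty(n_perm)
    steps = np.full(n, miss_step)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        w = weights[idx]
        total = w.sum()
        steps_i = steps.copy()
        if total > 0:
            steps_i[idx] = w / total
        else:
            steps_i[idx] = 1.0 / set_size
        run = np.cumsum(steps_i)
        out[i] = run[np.abs(run).argmax()]
    return out


def nes_and_pvalue(es: float, null_es: np.ndarray) -> tuple[float, float]:
    """Sign-matched normalization and add-one nominal p.

    NES = ES / mean(|null ES of same sign|); nominal p uses the add-one rule
    over the same-sign null values.
    """
    null_es = np.asarray(null_es, dtype=float)
    same = null_es > 0 if es >= 0 else null_es < 0
    m = int(same.sum())
    if m == 0:
        raise CresigError("no same-sign null ES values; increase n_perm")
    denom = np.abs(null_es[same]).mean()
    nes = es / denom
    nom_p = (1.0 + int((np.abs(null_es[same]) >= abs(es)).sum())) / (1.0 + m)
    return float(nes), float(nom_p)


def run_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    exponent: float = 1.0,
) -> list[GseaResult]:
    """Score every set in the collection against one pre-ranked list.

    Set members missing from the ranked list are dropped (and counted in the
    log); null distributions are shared between sets of equal effective size.
    """
    if seed is None:
        raise CresigError("run_gsea requires an explicit seed")
    in_list = set(ranked.genes.tolist())
    null_cache: dict[int, np.ndarray] = {}
    results = []
    for name in collection.names():
        members = collection[name] & in_list
        dropped = len(collection[name]) - len(members)
        if dropped:
            log.info("gsea: set %r drops %d genes absent from the ranked list", name, dropped)
        if not members:
            log.warning("gsea: set %r has no overlap with the ranked list; skipped", name)
            continue
        es, _, peak = enrichment_score(ranked, members, exponent)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = permutation_null(ranked, size, n_perm, seed, exponent)
        nes, nom_p = nes_and_pvalue(es, null_cache[size])
        results.append(
            GseaResult(
                set_name=name,
                es=es,
                nes=nes,
                nom_p=nom_p,
                n_perm=n_perm,
                peak_rank=peak,
                leading_edge=leading_edge(ranked, members, exponent),
            )
        )
    return results


def results_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "ES": r.es,
                "NES": r.nes,
                "nom_p": r.nom_p,
                "n_perm": r.n_perm,
                "peak_rank": r.peak_rank,
                "leading_edge_size": len(r.leading_edge),
            }
            for r in results
        ]
    )
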