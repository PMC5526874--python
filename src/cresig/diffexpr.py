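"""Two-group contrasts with empirical-Bayes variance moderation.

The per-gene pipeline is: pooled two-sample statistics -> method-of-moments
estimation of the variance prior (d0, s0^2) on the log residual variances ->
posterior (shrunk) variances -> moderated t with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .model import CresigError, ExpressionMatrix, validate_deg_table


@dataclass
class GeneLevelStats:
    """Ordinary per-gene statistics for one two-group contrast.

    ``table`` columns: gene, logFC, s2, df, v, mean_expr, s2_floored.
    ``v`` is the unscaled variance factor 1/n_t + 1/n_c of the mean difference.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]


@dataclass
class ModeratedStats:
    """Posterior statistics after empirical-Bayes shrinkage."""

    table: pd.DataFrame  # adds s2_post, t_mod, p_raw, df_total
    d0: float
    s0_sq: float
    contrast: tuple[str, str]


def fit_group_contrast(expr: ExpressionMatrix, treated: str, control: str) -> GeneLevelStats:
    """Per-gene mean difference and pooled within-group variance.

    logFC = mean(treated) - mean(control); s2 pools both groups with
    df = n_t + n_c - 2.  Both groups need >= 2 samples.
    """
    t_cols = expr.samples_of(treated)
    c_cols = expr.samples_of(control)
    n_t, n_c = len(t_cols), len(c_cols)
    if n_t < 2 or n_c < 2:
        raise CresigError(
            f"each group needs >=2 samples (got {treated}:{n_t}, {control}:{n_c})"
        )
    tv = expr.values[t_cols].to_numpy(dtype=float)
    cv = expr.values[c_cols].to_numpy(dtype=float)
    logfc = tv.mean(axis=1) - cv.mean(axis=1)
    ss = ((tv - tv.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (cv - cv.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n_t + n_c - 2
    s2 = ss / df
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "logFC": logfc,
            "s2": s2,
            "df": float(df),
            "v": 1.0 / n_t + 1.0 / n_c,
            "mean_expr": np.concatenate([tv, cv], axis=1).mean(axis=1),
            "s2_floored": False,
        }
    ).reset_index(drop=True)
    return GeneLevelStats(table, (treated, control))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, limma-style)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for residual variances.

    Works on e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2): its mean and
    excess variance over trigamma(d_g/2) identify s0^2 and d0.  A non-positive
    excess variance yields d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if s2.size < 2 or np.all(s2 <= 0):
        raise CresigError("variance prior needs a population of positive variances")
    if np.allclose(s2, s2[0]):
        # no spread in the sample variances: shrink completely to the common value
        return np.inf, float(s2[0])
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1)
    excess = evar - np.mean(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    else:
        half_d0 = _trigamma_inverse(float(excess))
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s0_sq


def empirical_bayes_moderate(
    stats_in: GeneLevelStats,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedStats:
    """Shrink per-gene variances toward the prior and compute moderated t.

    s2_post = (d0*s0^2 + d_g*s2_g) / (d0 + d_g); t_mod = logFC/sqrt(s2_post*v);
    two-sided p from Student t with d0 + d_g df (normal when d0 is infinite).
    Hyperparameters are estimated unless supplied (d0=0 gives the ordinary t).

    Genes with s2 == 0 are floored to the smallest positive s2 before
    moderation and flagged in the ``s2_floored`` column.
    """
    table = stats_in.table.copy()
    if len(table) < 30 and d0 is None:
        raise CresigError("hyperparameter estimation needs >=30 genes")
    s2 = table["s2"].to_numpy(dtype=float).copy()
    df = table["df"].to_numpy(dtype=float)
    zero = s2 <= 0
    if zero.all():
        raise CresigError("all residual variances are zero; moderation is degenerate")
    if zero.any():
        s2[zero] = s2[~zero].min()
        table["s2_floored"] = zero
        table["s2"] = s2
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_variance_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    t_mod = table["logFC"].to_numpy() / np.sqrt(s2_post * table["v"].to_numpy())
    with np.errstate(invalid="ignore"):
        p_raw = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t_mod)),
            2.0 * stats.t.sf(np.abs(t_mod), df_total),
        )
    table["s2_post"] = s2_post
    table["t_mod"] = t_mod
    table["p_raw"] = p_raw
    table["df_total"] = df_total
    return ModeratedStats(table, float(d0), float(s0_sq), stats_in.contrast)


def call_degs(mstats: ModeratedStats, alpha: float = 0.05, adjust: str = "BH") -> pd.DataFrame:
    """Call differentially expressed genes at ``alpha`` on (adjusted) p-values.

    Returns a DEG table restricted to significant genes, with UP/DOWN from
    the sign of logFC and both raw and adjusted p retained.
    """
    if not 0.0 < alpha < 1.0:
        raise CresigError("alpha must be in (0,1)")
    if adjust not in ("none", "BH"):
        raise CresigError("adjust must be 'none' or 'BH'")
    t = mstats.table
    p_raw = t["p_raw"].to_numpy(dtype=float)
    if adjust == "BH":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    else:
        p_adj = p_raw.copy()
    full = pd.DataFrame(
        {
            "gene": t["gene"],
            "logFC": t["logFC"],
            "t_mod": t["t_mod"],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(t["logFC"] > 0, "UP", "DOWN"),
            "mean_expr": t["mean_expr"],
        }
    )
    crit = p_adj if adjust == "BH" else p_raw
    out = full[crit < alpha].reset_index(drop=True)
    return validate_deg_table(out)


def full_deg_table(mstats: ModeratedStats, adjust: str = "BH") -> pd.DataFrame:
    """All genes as a DEG table (no significance cut) — input for ranking/bins."""
    t = mstats.table
    p_raw = t["p_raw"].to_numpy(dtype=float)
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if adjust == "BH" else p_raw.copy()
    out = pd.DataFrame(
        {
            "gene": t["gene"],
            "logFC": t["logFC"],
            "t_mod": t["t_mod"],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(t["logFC"] > 0, "UP", "DOWN"),
            "mean_expr": t["mean_expr"],
        }
    )
    return validate_deg_table(out)


def collapse_probes(table: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene, keeping max |t_mod|.

    Probes missing from the map are dropped.  Ties on |t_mod| keep the
    lexicographically smallest probe id for determinism.
    """
    t = table.copy()
    t["__sym"] = t["gene"].map(probe_to_gene)
    t = t.dropna(subset=["__sym"])
    t["__abs_t"] = t["t_mod"].abs()
    t = t.sort_values(["__sym", "__abs_t", "gene"], ascending=[True, False, True], kind="mergesort")
    t = t.drop_duplicates(subset="__sym", keep="first")
    t = t.drop(columns=["gene", "__abs_t"]).rename(columns={"__sym": "gene"})
    return validate_deg_table(t.reset_index(drop=True))
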