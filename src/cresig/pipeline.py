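"""High-level orchestration: chain the stages end-to-end on in-memory objects.

The CLI wraps these helpers with file IO; tests and the simulator's
recovery scoring call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import call_degs, empirical_bayes_moderate, fit_group_contrast, full_deg_table
from .model import ExpressionMatrix, RunConfig
from .signature import CoreSignature, extract_core
from .simulate import STIMULI, SyntheticStudy
from .trap import build_q1


def run_de(
    expr: ExpressionMatrix,
    treated: str,
    control: str,
    alpha: float = 0.05,
    adjust: str = "BH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit, moderate and call one contrast.

    Returns ``(full_table, deg_table)``: all genes with statistics, and the
    significant subset.
    """
    stats = fit_group_contrast(expr, treated, control)
    mstats = empirical_bayes_moderate(stats)
    return full_deg_table(mstats, adjust), call_degs(mstats, alpha, adjust)


@dataclass
class StudyResult:
    full_tables: dict[str, pd.DataFrame]
    deg_tables: dict[str, pd.DataFrame]
    q1: set[str]
    signature: CoreSignature = None


def run_study_pipeline(study: SyntheticStudy, cfg: RunConfig | None = None) -> StudyResult:
    """Differential expression per stimulus -> Q1-TRAP -> core signature."""
    cfg = cfg or RunConfig()
    full_tables: dict[str, pd.DataFrame] = {}
    deg_tables: dict[str, pd.DataFrame] = {}
    for stim, ctrl in STIMULI.items():
        full, degs = run_de(study.expression[stim], stim, ctrl, cfg.alpha, cfg.adjust_method)
        full_tables[stim] = full
        deg_tables[stim] = degs
    q1 = build_q1(study.trap, 1)
    signature = extract_core(deg_tables, q1, study.registry)
    return StudyResult(full_tables, deg_tables, q1, signature)
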