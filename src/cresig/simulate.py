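"""Synthetic study generator with planted ground truth.

Produces everything the pipeline consumes — three stimulus expression
matrices with replicate noise, promoter FASTA with planted CRE sites, a
TRAP-style abundance list enriched for the planted regulon, a CRE-target
registry, GO-like gene sets, and an "in vivo" ranked list — so every stage
of the analysis has a recoverable truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .model import CresigError, ExpressionMatrix, GeneSetCollection, TrapList
from .motif import PWM, default_cre_pwm

#: stimulus -> control condition label
STIMULI = {"FSK": "CT", "NE": "CT", "VP16": "Null"}


@dataclass
class SimulationConfig:
    n_genes: int = 5000
    n_core: int = 100
    n_specific: int = 150  # per-stimulus extra UP genes
    n_down: int = 150  # per-stimulus DOWN genes
    delta: float = 1.0  # log2 effect size
    sigma: float = 0.25  # replicate noise sd (log2)
    n_reps: int = 3
    promoter_len: int = 500
    gc: float = 0.5
    q1_enrich: float = 0.9  # P(core gene lands in TRAP Q1)
    registry_fpr: float = 0.02  # fraction of non-core genes in the registry
    decoy_motif_rate: float = 0.0  # fraction of non-core genes given a motif
    invivo_shift: float = 2.0
    baseline_mean: float = 8.0  # log2 baseline location
    baseline_sd: float = 1.5  # log2 baseline spread (=> log-normal abundance)
    n_random_terms: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CresigError("SimulationConfig requires an explicit seed")
        if self.n_core + 3 * (self.n_specific + self.n_down) > self.n_genes:
            raise CresigError("planted genes exceed n_genes")
        if self.delta < 0 or self.sigma <= 0:
            raise CresigError("delta must be >=0 and sigma > 0")
        for name in ("q1_enrich", "registry_fpr", "gc", "decoy_motif_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CresigError(f"{name} must be in [0,1]")
        if self.n_core > math.ceil(self.n_genes / 4):
            raise CresigError("n_core exceeds the size of the first quartile")


@dataclass
class TruthTable:
    """Planted labels per gene: core / specific:<stim> / down:<stim> / null,
    plus flags filled in by the downstream generators."""

    table: pd.DataFrame  # index: gene; columns: label, motif_planted, trap_q1, registry_member

    @property
    def core_genes(self) -> set[str]:
        return set(self.table.index[self.table["label"] == "core"])

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.table.index[self.table["label"] == label])


@dataclass
class SyntheticStudy:
    cfg: SimulationConfig
    truth: TruthTable
    expression: dict[str, ExpressionMatrix]  # stimulus -> matrix (treated+control)
    promoters: dict[str, str]
    pwm: PWM
    trap: TrapList
    registry: set[str]
    invivo: pd.DataFrame  # columns gene, score (RNK)
    go_sets: GeneSetCollection = None


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def assign_labels(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    core_genes: list[str] | None = None,
) -> TruthTable:
    """Assign planted labels; an explicit core list pins the regulon (used to
    build a second cell type with a controlled overlap)."""
    genes = _gene_names(cfg.n_genes)
    labels = pd.Series("null", index=pd.Index(genes, name="gene"), name="label", dtype=object)
    if core_genes is None:
        order = rng.permutation(genes)
        core = list(order[: cfg.n_core])
    else:
        if len(core_genes) != cfg.n_core:
            raise CresigError("explicit core list must have n_core genes")
        core = list(core_genes)
        order = rng.permutation([g for g in genes if g not in set(core)])
    labels.loc[core] = "core"
    pool = [g for g in order if labels[g] == "null"]
    pos = 0
    for stim in STIMULI:
        for kind, count in (("specific", cfg.n_specific), ("down", cfg.n_down)):
            chunk = pool[pos : pos + count]
            pos += count
            labels.loc[chunk] = f"{kind}:{stim}"
    table = labels.to_frame()
    table["motif_planted"] = False
    table["trap_q1"] = False
    table["registry_member"] = False
    return TruthTable(table)


def simulate_expression(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> dict[str, ExpressionMatrix]:
    """One expression matrix per stimulus (treated + its control samples).

    Per-gene baseline mu_g ~ Normal(baseline_mean, baseline_sd) in log2
    (log-normal abundance); replicate values add Normal(0, sigma) noise;
    planted genes are shifted by +/- delta in their stimulus condition.
    """
    if cfg.n_reps < 2:
        raise CresigError("n_reps must be >= 2 (within-group variance undefined)")
    genes = list(truth.table.index)
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    labels = truth.table["label"]
    core_mask = (labels == "core").to_numpy()
    out: dict[str, ExpressionMatrix] = {}
    for stim, ctrl in STIMULI.items():
        shift = np.zeros(len(genes))
        shift[core_mask] = cfg.delta
        shift[(labels == f"specific:{stim}").to_numpy()] = cfg.delta
        shift[(labels == f"down:{stim}").to_numpy()] = -cfg.delta
        cols, names, conds = [], [], {}
        for rep in range(1, cfg.n_reps + 1):
            cols.append(mu + rng.normal(0.0, cfg.sigma, size=len(genes)))
            names.append(f"{ctrl}_{stim}_{rep}")
            conds[names[-1]] = ctrl
        for rep in range(1, cfg.n_reps + 1):
            cols.append(mu + shift + rng.normal(0.0, cfg.sigma, size=len(genes)))
            names.append(f"{stim}_{rep}")
            conds[names[-1]] = stim
        values = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=names)
        out[stim] = ExpressionMatrix(values, pd.Series(conds))
    return out


def simulate_promoters(
    cfg: SimulationConfig,
    truth: TruthTable,
    rng: np.random.Generator,
    pwm: PWM | None = None,
) -> tuple[dict[str, str], PWM]:
    """iid-background promoters; motif-planted genes get one PWM-sampled site
    at a uniform random position on a uniform random strand.

    Motif-planted = all core genes plus a ``decoy_motif_rate`` fraction of
    the others; the flag is recorded in the truth table.
    """
    pwm = pwm or default_cre_pwm()
    if cfg.promoter_len < pwm.width + 10:
        raise CresigError("promoter_len must be >= PWM width + 10")
    comp = str.maketrans("ACGT", "TGCA")
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    genes = list(truth.table.index)
    planted = truth.table["label"] == "core"
    if cfg.decoy_motif_rate > 0:
        decoys = rng.random(len(genes)) < cfg.decoy_motif_rate
        planted = planted | (pd.Series(decoys, index=truth.table.index) & ~planted)
    truth.table["motif_planted"] = planted
    bases = np.array(list("ACGT"))
    draws = rng.choice(4, size=(len(genes), cfg.promoter_len), p=p)
    out: dict[str, str] = {}
    for i, g in enumerate(genes):
        seq = "".join(bases[draws[i]])
        if planted[g]:
            site = pwm.sample_site(rng)
            if rng.random() < 0.5:
                site = site.translate(comp)[::-1]
            pos = int(rng.integers(0, cfg.promoter_len - pwm.width + 1))
            seq = seq[:pos] + site + seq[pos + pwm.width :]
        out[g] = seq
    return out, pwm


def simulate_trap(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> TrapList:
    """Abundance list whose first quartile contains each core gene with
    probability ``q1_enrich``; all other placements are uniform."""
    genes = list(truth.table.index)
    g = len(genes)
    q1_size = math.ceil(g / 4)
    values = np.sort(np.exp(rng.normal(cfg.baseline_mean * np.log(2), cfg.baseline_sd * np.log(2), size=g)))[::-1]
    core = sorted(truth.core_genes)
    in_q1 = rng.random(len(core)) < cfg.q1_enrich
    q1_slots = list(rng.permutation(q1_size))
    rest_slots = list(rng.permutation(np.arange(q1_size, g)))
    slot_of: dict[str, int] = {}
    for gene, hit in zip(core, in_q1):
        slot_of[gene] = q1_slots.pop() if hit else rest_slots.pop()
    free = sorted(set(range(g)) - set(slot_of.values()))
    others = [gn for gn in genes if gn not in slot_of]
    for gene, slot in zip(others, rng.permutation(free)):
        slot_of[gene] = int(slot)
    abundance = {gene: values[slot] for gene, slot in slot_of.items()}
    table = pd.DataFrame({"gene": genes, "abundance": [abundance[gn] for gn in genes]})
    trap = TrapList(table)
    q1_genes = set(trap.table["gene"].iloc[:q1_size])
    truth.table["trap_q1"] = truth.table.index.isin(q1_genes)
    return trap


def simulate_registry(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> set[str]:
    """CRE-target registry: every core gene plus a false-positive fraction."""
    core = truth.core_genes
    others = [g for g in truth.table.index if g not in core]
    extra = {g for g in others if rng.random() < cfg.registry_fpr}
    registry = core | extra
    truth.table["registry_member"] = truth.table.index.isin(registry)
    return registry


def simulate_invivo_ranked(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Ranked 'in vivo' list: null scores ~ N(0,1), core ~ N(shift,1)."""
    genes = list(truth.table.index)
    scores = rng.normal(0.0, 1.0, size=len(genes))
    scores[(truth.table["label"] == "core").to_numpy()] += cfg.invivo_shift
    df = pd.DataFrame({"gene": genes, "score": scores})
    return df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def simulate_go_sets(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> GeneSetCollection:
    """GO-like collection: one term per planted label group plus random terms."""
    genes = np.array(truth.table.index)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for label in sorted(truth.table["label"].unique()):
        members = truth.genes_with_label(label)
        if label != "null" and members:
            name = "TERM_" + label.replace(":", "_").upper()
            sets[name] = set(members)
            descriptions[name] = f"planted {label} genes"
    for i in range(cfg.n_random_terms):
        size = int(rng.integers(10, 51))
        name = f"TERM_RANDOM_{i + 1:03d}"
        sets[name] = set(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "random term"
    return GeneSetCollection(sets, descriptions)


def simulate_study(cfg: SimulationConfig, core_genes: list[str] | None = None) -> SyntheticStudy:
    """Generate the full synthetic study deterministically from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    truth = assign_labels(cfg, rng, core_genes)
    expression = simulate_expression(cfg, truth, rng)
    promoters, pwm = simulate_promoters(cfg, truth, rng)
    trap = simulate_trap(cfg, truth, rng)
    registry = simulate_registry(cfg, truth, rng)
    invivo = simulate_invivo_ranked(cfg, truth, rng)
    go_sets = simulate_go_sets(cfg, truth, rng)
    return SyntheticStudy(cfg, truth, expression, promoters, pwm, trap, registry, invivo, go_sets)


def simulate_paired_cell_types(
    cfg: SimulationConfig, overlap: int = 2
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Two cell-type studies over the same gene universe whose planted
    regulons share exactly ``overlap`` genes (second study seeded at seed+1)."""
    if overlap > cfg.n_core:
        raise CresigError("overlap cannot exceed n_core")
    study_a = simulate_study(cfg)
    rng = np.random.default_rng(cfg.seed + 10_000_019)
    core_a = sorted(study_a.truth.core_genes)
    shared = list(rng.choice(core_a, size=overlap, replace=False))
    null_a = sorted(study_a.truth.genes_with_label("null"))
    fresh = list(rng.choice(null_a, size=cfg.n_core - overlap, replace=False))
    cfg_b = replace(cfg, seed=cfg.seed + 1)
    study_b = simulate_study(cfg_b, core_genes=shared + fresh)
    return study_a, study_b


def recovery_metrics(called, truth: TruthTable) -> tuple[float, float]:
    """Precision and recall of a called gene list against the planted core."""
    called = set(called)
    core = truth.core_genes
    tp = len(called & core)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(core) if core else 0.0
    return precision, recall


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study as a drop-in input directory for the CLI pipeline."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stim, expr in study.expression.items():
        cio.write_expression(expr, out / f"expr_{stim}.tsv", out / f"conditions_{stim}.tsv")
    cio.write_fasta(study.promoters, out / "promoters.fasta")
    cio.write_pwm_jaspar(study.pwm, out / "cre_motif.pfm")
    cio.write_trap(study.trap, out / "trap.tsv")
    cio.write_gene_list(sorted(study.registry), out / "registry.txt")
    cio.write_gene_list(list(study.truth.table.index), out / "universe.txt")
    cio.write_rnk(study.invivo, out / "invivo.rnk")
    cio.write_gmt(study.go_sets, out / "go_sets.gmt")
    truth = study.truth.table.reset_index()
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "sim_config.json").write_text(json.dumps(asdict(study.cfg), indent=2) + "\n")
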