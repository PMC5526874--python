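"""File readers and writers for every format the pipeline touches.

All tabular formats are plain TSV ('.' decimal, '#' comments ignored);
gene sets use standard GMT; motif matrices use JASPAR pfm or TRANSFAC
blocks (parsed with Biopython); promoters are FASTA keyed by gene symbol;
ranked lists use two-column RNK.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DEG_COLUMNS,
    CresigError,
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    TrapList,
    require_mapping,
    validate_deg_table,
)

_TSV_KW = dict(sep="\t", comment="#")


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(path, condition_map) -> ExpressionMatrix:
    """Read a genes x samples log2 TSV plus a two-column sample->condition map."""
    try:
        df = pd.read_csv(path, index_col=0, **_TSV_KW)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise CresigError(f"cannot parse expression matrix {path}: {exc}") from exc
    bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        raise CresigError(f"non-numeric cell in {path} at gene {row!r}, sample {col!r}")
    cond = read_condition_map(condition_map)
    return ExpressionMatrix(df, require_mapping(cond, df.columns))


def write_expression(expr: ExpressionMatrix, path, condition_path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.12g")
    cond = expr.conditions.loc[expr.values.columns]
    cond.rename("condition").rename_axis("sample").to_csv(condition_path, sep="\t")


def read_condition_map(path) -> dict[str, str]:
    df = pd.read_csv(path, **_TSV_KW, dtype=str)
    if df.shape[1] < 2:
        raise CresigError(f"condition map {path} needs two columns (sample, condition)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes...."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CresigError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            members = {g for g in fields[2:] if g}
            if not members:
                raise CresigError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise CresigError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions) if sets else GeneSetCollection({}, {})


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# motif matrices

def read_pwm(path, format: str = "jaspar"):
    """Read a count matrix in JASPAR pfm or TRANSFAC format -> PWM.

    Returns the first motif in the file; multi-motif files can be read with
    :func:`read_pwms`.
    """
    return read_pwms(path, format)[0]


def read_pwms(path, format: str = "jaspar") -> list:
    from .motif import PWM  # local import to avoid a cycle

    fmt = format.lower()
    if fmt not in ("jaspar", "transfac"):
        raise CresigError(f"unknown PWM format {format!r}")
    with open(path) as fh:
        try:
            records = list(motifs.parse(fh, fmt, strict=False))
        except Exception as exc:
            raise CresigError(f"cannot parse {fmt} matrix {path}: {exc}") from exc
    if not records:
        raise CresigError(f"no motifs found in {path}")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        if counts.shape[1] < 1:
            raise CresigError(f"zero-width matrix in {path}")
        if (counts < 0).any():
            raise CresigError(f"negative counts in {path}")
        name = getattr(rec, "name", None) or getattr(rec, "matrix_id", None) or "motif"
        out.append(PWM(counts=counts, name=str(name)))
    return out


def write_pwm_jaspar(pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for base, row in zip("ACGT", pwm.counts):
            fh.write(f"{base} [ " + " ".join(f"{v:.6g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# DEG tables / TRAP lists / ranked lists / mappings

def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_TSV_KW)
    return validate_deg_table(df)


def write_deg_table(table: pd.DataFrame, path) -> None:
    validate_deg_table(table).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trap(path) -> TrapList:
    df = pd.read_csv(path, **_TSV_KW)
    if df.shape[1] < 2:
        raise CresigError(f"TRAP list {path} needs (gene, abundance) columns")
    df = df.rename(columns={df.columns[0]: "gene", df.columns[1]: "abundance"})
    return TrapList(df[["gene", "abundance"]])


def write_trap(trap: TrapList, path) -> None:
    trap.table[["gene", "abundance"]].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_rnk(path) -> pd.DataFrame:
    """Read a two-column RNK file into a (gene, score) frame sorted by score."""
    df = pd.read_csv(path, header=None, names=["gene", "score"], **_TSV_KW)
    if df["gene"].duplicated().any():
        raise CresigError(f"duplicate genes in RNK file {path}")
    return df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False, float_format="%.12g")


def read_mapping(path) -> dict[str, str]:
    """Two-column symbol mapping table (source -> target)."""
    df = pd.read_csv(path, **_TSV_KW, dtype=str)
    if df.shape[1] < 2:
        raise CresigError(f"mapping table {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gene_list(path) -> list[str]:
    """One gene symbol per line (flat registry / category lists)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# FASTA promoters

def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise CresigError(f"duplicate FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# config / run summaries

def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "promoter_window" in raw:
        raw["promoter_window"] = tuple(raw["promoter_window"])
    return RunConfig(**raw)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_summary(path, **payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
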