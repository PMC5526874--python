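"""PWM promoter scanning and CRE-site over-representation statistics.

Each promoter gets a single best-site score: the maximum log-odds over all
windows on both strands, min-max normalized to [0,1] against the matrix's
achievable score range.  Gene-set over-representation is a one-sample z-test
of the set's mean best score against the promoter universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import CresigError
from .trap import BinProfile

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
#: complement permutation of ACGT rows (N maps to itself)
_COMPLEMENT = np.array([3, 2, 1, 0, 4])

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes (4 = N)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise CresigError(f"invalid base {exc.args[0]!r} in sequence") from exc


@dataclass
class PWM:
    """Position count matrix with pseudocount and background model.

    ``counts`` is 4 x width in A,C,G,T row order.  The pseudocount added to
    each cell defaults to ``pseudocount_frac`` times the column total, which
    keeps log-odds finite for zero counts.
    """

    counts: np.ndarray
    name: str = "motif"
    pseudocount_frac: float = 0.01
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise CresigError("PWM counts must be a 4 x width matrix (A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise CresigError("zero-width PWM")
        if (self.counts < 0).any():
            raise CresigError("PWM counts must be nonnegative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise CresigError("background must be 4 positive probabilities summing to 1")
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            raise CresigError("every PWM column needs positive total count")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        pc = self.pseudocount_frac * totals
        return (self.counts + pc) / (totals + 4 * pc)

    def log_odds(self) -> np.ndarray:
        """5 x width log2(freq/background) lookup table; N rows score 0."""
        lo = np.log2(self.frequencies() / np.asarray(self.background)[:, None])
        return np.vstack([lo, np.zeros((1, self.width))])

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds()[:4]
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site with per-column base probabilities from the counts."""
        freqs = self.frequencies()
        return "".join(rng.choice(list("ACGT"), p=freqs[:, j] / freqs[:, j].sum()) for j in range(self.width))


def default_cre_pwm() -> PWM:
    """A palindromic CRE-like (TGACGTCA) count matrix used by the simulator."""
    consensus = "TGACGTCA"
    counts = np.full((4, len(consensus)), 2.0)
    for j, b in enumerate(consensus):
        counts[_BASE_INDEX[b], j] = 94.0
    return PWM(counts, name="CRE")


def _window_scores(codes: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Scores of all forward-strand windows for one encoded sequence."""
    w = lut.shape[1]
    n_win = codes.size - w + 1
    out = np.zeros(n_win)
    for j in range(w):
        out += lut[codes[j : j + n_win], j]
    return out


def best_site_score(pwm: PWM, seq: str) -> tuple[float, int, str]:
    """Best normalized site score over all windows and both strands.

    Returns ``(score, position, strand)`` where position is the window start
    on the forward sequence.  Scores are min-max normalized so that the PWM
    consensus scores 1.0 and the worst possible window scores 0.0.
    """
    if len(seq) < pwm.width:
        raise CresigError(f"sequence shorter than PWM width {pwm.width}")
    codes = encode(seq)
    lut = pwm.log_odds()
    # reverse strand == scanning with the reverse-complemented matrix
    lut_rc = lut[_COMPLEMENT][:, ::-1]
    fwd = _window_scores(codes, lut)
    rev = _window_scores(codes, lut_rc)
    lo, hi = pwm.score_range()
    span = hi - lo if hi > lo else 1.0
    i_f, i_r = int(fwd.argmax()), int(rev.argmax())
    if fwd[i_f] >= rev[i_r]:
        raw, pos, strand = fwd[i_f], i_f, "+"
    else:
        raw, pos, strand = rev[i_r], i_r, "-"
    return float((raw - lo) / span), pos, strand


def score_promoters(pwm: PWM, promoters: dict[str, str]) -> pd.DataFrame:
    """Best-site scores for a promoter set.

    Returns a frame with columns gene, best_score, best_position, best_strand.
    """
    rows = []
    for gene, seq in promoters.items():
        score, pos, strand = best_site_score(pwm, seq)
        rows.append({"gene": gene, "best_score": score, "best_position": pos, "best_strand": strand})
    return pd.DataFrame(rows)


def zscore_overrepresentation(set_scores: np.ndarray, bg_scores: np.ndarray) -> tuple[float, float]:
    """One-sample z of the set mean against the universe score distribution.

    z = (mean_set - mean_bg) / (sd_bg / sqrt(|set|)); p is the upper tail of
    the standard normal (over-representation only).
    """
    set_scores = np.asarray(set_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    if set_scores.size < 2:
        raise CresigError("gene set needs >=2 scored promoters")
    sd = bg_scores.std(ddof=0)
    if sd == 0:
        raise CresigError("degenerate universe: zero score variance")
    z = (set_scores.mean() - bg_scores.mean()) / (sd / np.sqrt(set_scores.size))
    return float(z), float(stats.norm.sf(z))


def binned_motif_profile(bins: BinProfile, scores: pd.DataFrame) -> pd.DataFrame:
    """Over-representation test of each rank-order bin against the universe.

    Bins with fewer than 2 scored genes are skipped with a warning.  Returns
    a frame with columns bin, n, z, p.
    """
    score_of = scores.set_index("gene")["best_score"]
    universe = score_of.to_numpy()
    rows = []
    for b in sorted(bins.assignments.unique()):
        genes = bins.assignments.index[bins.assignments == b]
        vals = score_of.reindex(genes).dropna().to_numpy()
        if vals.size < 2:
            log.warning("bin %s has <2 scored genes; skipped", b)
            continue
        z, p = zscore_overrepresentation(vals, universe)
        rows.append({"bin": int(b), "n": int(vals.size), "z": z, "p": p})
    return pd.DataFrame(rows)


def compare_partitions(scores: pd.DataFrame, partitions: dict[str, set[str]]) -> pd.DataFrame:
    """One over-representation test per named gene-set partition."""
    score_of = scores.set_index("gene")["best_score"]
    universe = score_of.to_numpy()
    rows = []
    for name, genes in partitions.items():
        vals = score_of.reindex(sorted(genes)).dropna().to_numpy()
        if vals.size < 2:
            log.warning("partition %r has <2 scored genes; skipped", name)
            continue
        z, p = zscore_overrepresentation(vals, universe)
        rows.append({"partition": name, "n": int(vals.size), "z": z, "p": p})
    return pd.DataFrame(rows)


def extract_promoter_windows(
    genome: dict[str, str],
    coords: pd.DataFrame,
    window: tuple[int, int] = (-450, 50),
) -> dict[str, str]:
    """Slice promoter windows around transcription starts from a genome FASTA.

    ``coords`` needs columns gene, chrom, tss (0-based), strand.  The window
    (upstream, downstream) is relative to the TSS in transcription direction;
    minus-strand promoters are reverse-complemented.  Windows falling off a
    contig are clipped.
    """
    up, down = window
    comp = str.maketrans("ACGTN", "TGCAN")
    out: dict[str, str] = {}
    for row in coords.itertuples(index=False):
        seq = genome[row.chrom].upper()
        if row.strand == "+":
            start, end = row.tss + up, row.tss + down
            piece = seq[max(0, start) : max(0, end)]
        else:
            start, end = row.tss - down, row.tss - up
            piece = seq[max(0, start) : max(0, end)].translate(comp)[::-1]
        out[row.gene] = piece
    return out
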