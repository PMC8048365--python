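"""PWM scanning and motif enrichment between peak sequence sets.

A transparent known-motif pipeline: log2-odds scanning of each PWM over
both strands with a fraction-of-maximum score threshold, then a
one-sided Fisher exact test on the 2x2 table of peaks containing at
least one hit in the foreground vs background set.  Simpler than suite
tools like HOMER (no GC matching, no background model calibration), but
fully deterministic and self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ParseError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValidationError(f"PWM {self.name}: matrix must be 4 x L")
        if self.length < 4:
            raise ValidationError(f"PWM {self.name}: length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds lookup; the extra row scores N as 0."""
        lo = np.log2(np.clip(self.matrix, 1e-9, None) / self.background[:, None])
        return np.vstack([lo, np.zeros(self.length)])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.background[::-1])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every length-L window of an encoded sequence."""
    length = log_odds.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(idx, length)
    return log_odds[windows, np.arange(length)].sum(axis=1)


def scan_pwm(seq: str, pwm: PWM,
             score_frac: float = 0.8) -> list[tuple[int, str, float]]:
    """All (position, strand, score) hits of the PWM in the sequence.

    Positions are 0-based starts of the L-window on the forward strand;
    a '-' strand hit means the window's reverse complement matches.  A
    sequence shorter than the motif yields no hits.  Hit threshold is
    ``score_frac`` times the maximum attainable score.
    """
    idx = encode(seq)
    if len(idx) < pwm.length:
        return []
    threshold = score_frac * pwm.max_score
    fwd = _window_scores(idx, pwm.log_odds)
    rev = _window_scores(idx, pwm.reverse_complement().log_odds)
    hits = [(int(pos), "+", float(s)) for pos, s in enumerate(fwd)
            if s >= threshold]
    hits += [(int(pos), "-", float(s)) for pos, s in enumerate(rev)
             if s >= threshold]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _has_hit(seqs: Sequence[str], pwm: PWM, score_frac: float) -> int:
    threshold = score_frac * pwm.max_score
    lo_f, lo_r = pwm.log_odds, pwm.reverse_complement().log_odds
    count = 0
    for seq in seqs:
        idx = encode(seq)
        if len(idx) < pwm.length:
            continue
        if (_window_scores(idx, lo_f).max() >= threshold
                or _window_scores(idx, lo_r).max() >= threshold):
            count += 1
    return count


def motif_enrichment(fg_seqs: Mapping[str, str] | Sequence[str],
                     bg_seqs: Mapping[str, str] | Sequence[str],
                     pwms: Sequence[PWM],
                     score_frac: float = 0.8) -> pd.DataFrame:
    """Rank PWMs by foreground-vs-background hit enrichment.

    Per PWM the unit of counting is "peak with >= 1 hit"; p is the
    one-sided Fisher exact test (enrichment in foreground), q is BH
    across PWMs, rank is 1-based by ascending p with ties broken by
    name.  The odds ratio uses the Haldane-Anscombe 0.5 correction so
    it is finite (and exactly 1 for identical tables).
    """
    fg = list(fg_seqs.values()) if isinstance(fg_seqs, Mapping) else list(fg_seqs)
    bg = list(bg_seqs.values()) if isinstance(bg_seqs, Mapping) else list(bg_seqs)
    if not fg or not bg:
        raise ValidationError("foreground and background sets must be nonempty")
    rows = []
    for pwm in pwms:
        fg_hits = _has_hit(fg, pwm, score_frac)
        bg_hits = _has_hit(bg, pwm, score_frac)
        table = [[fg_hits, len(fg) - fg_hits], [bg_hits, len(bg) - bg_hits]]
        _, p = stats.fisher_exact(table, alternative="greater")
        orat = ((fg_hits + 0.5) * (len(bg) - bg_hits + 0.5)
                / ((len(fg) - fg_hits + 0.5) * (bg_hits + 0.5)))
        rows.append((pwm.name, fg_hits, len(fg), bg_hits, len(bg),
                     float(orat), float(p)))
    df = pd.DataFrame(rows, columns=["pwm", "fg_hits", "fg_total", "bg_hits",
                                     "bg_total", "odds_ratio", "p"])
    from .diffexp import bh_adjust
    df["q"] = bh_adjust(df["p"])
    df = df.sort_values(["p", "pwm"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# JASPAR-style IO
# ---------------------------------------------------------------------------

def write_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row, base in zip(pwm.matrix, BASES):
                body = "  ".join(f"{x:.6f}" for x in row)
                fh.write(f"{base}  [ {body} ]\n")


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-style 4-row matrices; counts are normalised per column."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise ParseError(f"{path}: not a JASPAR motif file ({exc})") from exc
    out = []
    for rec in records:
        counts = np.array([list(rec.counts[b]) for b in BASES], dtype=float)
        colsums = counts.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValidationError(f"{path}: motif {rec.name} has a zero column")
        out.append(PWM(str(rec.name), counts / colsums))
    return out
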