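"""Local Hi-C map reconstruction across structural-variant breakpoints.

Given the intra-chromosomal matrices of the two partner chromosomes and
(optionally) their inter-chromosomal block, ``stitch_map`` assembles the
contact map of the derivative locus around a known breakpoint: the two
retained flanks become the diagonal blocks and the translocation's trans
contacts become the off-diagonal block.  When no trans matrix is
available the cross block is filled with the distance-decay expectation
evaluated at the derivative-coordinate distance, which is the expected
signal if the junction behaved like ordinary intra-chromosomal sequence.
Breakpoint discovery is out of scope: breakpoints are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ContactMatrix, ValidationError

SIDES = ("left", "right")


@dataclass(frozen=True)
class Breakpoint:
    """A two-partner junction; ``side`` names the retained segment."""

    chrom_a: str
    pos_a: int
    side_a: str
    chrom_b: str
    pos_b: int
    side_b: str
    flank: int = 100          # bins kept on each side of the junction

    def __post_init__(self) -> None:
        if self.side_a not in SIDES or self.side_b not in SIDES:
            raise ValidationError("breakpoint sides must be 'left' or 'right'")
        if self.flank < 1:
            raise ValidationError("flank must be >= 1 bin")
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValidationError("breakpoint positions must be non-negative")


def read_breakpoints_tsv(path: str | Path, flank: int = 100) -> list[Breakpoint]:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom_a", "pos_a", "side_a", "chrom_b", "pos_b", "side_b"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: breakpoint TSV needs columns {sorted(need)}")
    return [Breakpoint(str(r.chrom_a), int(r.pos_a), str(r.side_a),
                       str(r.chrom_b), int(r.pos_b), str(r.side_b),
                       int(getattr(r, "flank", flank)))
            for r in df.itertuples()]


def decay_curve(intra: ContactMatrix) -> np.ndarray:
    """Mean contact count per diagonal distance (genome-wide expected)."""
    values = intra.values
    n, m = values.shape
    if n != m:
        raise ValidationError("decay_curve requires a square intra matrix")
    return np.array([values.diagonal(d).mean() for d in range(n)])


def _flank_bins(pos_bin: int, side: str, n_bins: int, flank: int,
                label: str) -> np.ndarray:
    """Bin indices of the retained flank, ordered toward the junction for
    the A partner (callers reverse for B)."""
    if side == "left":
        if pos_bin - flank < 0:
            raise ValidationError(
                f"flank {flank} exceeds retained left segment of {label} "
                f"(breakpoint bin {pos_bin})")
        return np.arange(pos_bin - flank, pos_bin)
    if pos_bin + flank > n_bins:
        raise ValidationError(
            f"flank {flank} exceeds retained right segment of {label} "
            f"(breakpoint bin {pos_bin}, {n_bins} bins)")
    return np.arange(pos_bin + flank - 1, pos_bin - 1, -1)


def stitch_map(intra_a: ContactMatrix, intra_b: ContactMatrix,
               trans_ab: ContactMatrix | None, bp: Breakpoint) -> ContactMatrix:
    """Reconstruct the (2*flank) x (2*flank) map around a junction.

    Output rows/cols run along the derivative locus: the A flank ends at
    the junction (index flank-1), the B flank starts at it (index
    flank).  Pure-source blocks are bit-exact copies; the cross block
    comes from ``trans_ab`` when supplied, otherwise from the decay
    expectation of ``intra_a``.
    """
    res = intra_a.resolution
    if intra_b.resolution != res or (trans_ab is not None
                                     and trans_ab.resolution != res):
        raise ValidationError("resolution mismatch between input matrices")
    f = bp.flank
    ia = _flank_bins(bp.pos_a // res, bp.side_a, intra_a.n_bins, f, bp.chrom_a)
    # B flank runs away from the junction: reverse the toward-junction order
    ib = _flank_bins(bp.pos_b // res, bp.side_b, intra_b.n_bins, f,
                     bp.chrom_b)[::-1]
    out = np.zeros((2 * f, 2 * f))
    out[:f, :f] = intra_a.values[np.ix_(ia, ia)]
    out[f:, f:] = intra_b.values[np.ix_(ib, ib)]
    if trans_ab is not None:
        tv = trans_ab.values
        if trans_ab.chrom_a == bp.chrom_b and trans_ab.chrom_b == bp.chrom_a:
            tv = tv.T
        elif not (trans_ab.chrom_a == bp.chrom_a
                  and trans_ab.chrom_b == bp.chrom_b):
            raise ValidationError(
                f"trans matrix is {trans_ab.chrom_a} x {trans_ab.chrom_b}, "
                f"breakpoint joins {bp.chrom_a} and {bp.chrom_b}")
        cross = tv[np.ix_(ia, ib)]
    else:
        curve = decay_curve(intra_a)
        i_idx, j_idx = np.meshgrid(np.arange(f), np.arange(f, 2 * f),
                                   indexing="ij")
        d = np.minimum(j_idx - i_idx, len(curve) - 1)
        cross = curve[d]
    out[:f, f:] = cross
    out[f:, :f] = cross.T
    out = (out + out.T) / 2.0          # exact for already-symmetric blocks
    return ContactMatrix(
        chrom_a=f"der({bp.chrom_a},{bp.chrom_b})",
        chrom_b=f"der({bp.chrom_a},{bp.chrom_b})",
        resolution=res, values=out)
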