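"""Domain types, interval arithmetic, and plain-text readers/writers.

All genomic coordinates are 0-based half-open (BED convention).  Loop
anchors are stored as bin indices at a fixed resolution and converted to
base-pair intervals only on output, so a single coordinate convention
flows through every downstream module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# intervals and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, optionally carrying BED name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be +/- ({self.gene_id})")
        if self.tss < 0:
            raise ValidationError(f"negative TSS for {self.gene_id}")

    @property
    def tss_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tss, self.tss + 1, self.strand)


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    group: str
    replicate_of: str | None = None


def samples_of(design: Sequence[SampleDesign], group: str) -> list[str]:
    return [s.sample_id for s in design if s.group == group]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

class ActivityMatrix:
    """Features x samples numeric matrix (log-scale signal or expression).

    Thin validated wrapper around a pandas DataFrame: unique ids, no
    missing values, everything finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValidationError("duplicate feature ids in activity matrix")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in activity matrix")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("activity matrix is not numeric")
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("activity matrix contains missing/non-finite values")
        self.data = data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        # repr is the shortest representation that round-trips exactly
        self.data.to_csv(path, sep="\t", index_label="feature_id",
                         float_format=lambda x: repr(float(x)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."],
                         keep_default_na=True, float_precision="round_trip")
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)][:5].tolist()
            raise ParseError(f"{path}: missing values not allowed (e.g. rows {bad})")
        return cls(df)


@dataclass
class ContactMatrix:
    """Binned contact-count matrix for one chromosome pair."""

    chrom_a: str
    chrom_b: str
    resolution: int
    values: np.ndarray
    offset_a: int = 0
    offset_b: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")
        if self.values.ndim != 2:
            raise ValidationError("contact matrix must be 2-dimensional")
        if np.any(self.values < 0):
            raise ValidationError("contact counts must be non-negative")
        if self.is_intra:
            n, m = self.values.shape
            if n != m:
                raise ValidationError("intra-chromosomal matrix must be square")
            if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-9):
                raise ValidationError("intra-chromosomal matrix must be symmetric")

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b and self.offset_a == self.offset_b

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def write_contact_matrix(cm: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom_a\t{cm.chrom_a}\n#chrom_b\t{cm.chrom_b}\n")
        fh.write(f"#resolution\t{cm.resolution}\n")
        fh.write(f"#offset_a\t{cm.offset_a}\n#offset_b\t{cm.offset_b}\n")
        np.savetxt(fh, cm.values, fmt="%.17g", delimiter="\t")


def read_contact_matrix(path: str | Path) -> ContactMatrix:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                try:
                    key, value = line[1:].rstrip("\n").split("\t")
                except ValueError as exc:
                    raise ParseError(f"{path}: malformed header line {line!r}") from exc
                meta[key] = value
            else:
                body.write(line)
    body.seek(0)
    for key in ("chrom_a", "chrom_b", "resolution"):
        if key not in meta:
            raise ParseError(f"{path}: missing #{key} header")
    values = np.loadtxt(body, delimiter="\t", ndmin=2)
    return ContactMatrix(
        chrom_a=meta["chrom_a"],
        chrom_b=meta["chrom_b"],
        resolution=int(meta["resolution"]),
        values=values,
        offset_a=int(meta.get("offset_a", 0)),
        offset_b=int(meta.get("offset_b", 0)),
    )


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

@dataclass
class Loop:
    """A chromatin loop: two resolution-aligned anchor bins plus per-sample
    loop-probability scores (e.g. from a machine-learning loop caller)."""

    chrom_a: str
    bin_a: int
    chrom_b: str
    bin_b: int
    resolution: int
    probs: dict[str, float] = field(default_factory=dict)
    category: str | None = None
    subtype_call: str | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValidationError("loop resolution must be positive")
        if self.bin_a < 0 or self.bin_b < 0:
            raise ValidationError("negative anchor bin")
        for sid, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} for {sid} outside [0, 1]")
        if (self.chrom_b, self.bin_b) < (self.chrom_a, self.bin_a):
            self.chrom_a, self.chrom_b = self.chrom_b, self.chrom_a
            self.bin_a, self.bin_b = self.bin_b, self.bin_a

    @property
    def anchor1(self) -> GenomicInterval:
        r = self.resolution
        return GenomicInterval(self.chrom_a, self.bin_a * r, (self.bin_a + 1) * r)

    @property
    def anchor2(self) -> GenomicInterval:
        r = self.resolution
        return GenomicInterval(self.chrom_b, self.bin_b * r, (self.bin_b + 1) * r)

    def key(self) -> tuple[str, int, str, int]:
        return (self.chrom_a, self.bin_a, self.chrom_b, self.bin_b)


def read_loops_bedpe(path: str | Path, sample_ids: Sequence[str],
                     resolution: int) -> list[Loop]:
    """Read loops from BEDPE with one probability column per sample.

    Anchors are snapped to resolution-aligned bins and the two anchors
    are put in canonical (chrom, bin) order.  Extra trailing columns
    named ``category`` / ``subtype`` in the header are restored.
    """
    loops: list[Loop] = []
    n_required = 6 + len(sample_ids)
    header_extra: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                cols = line[1:].split("\t")
                header_extra = cols[n_required:]
                continue
            fields = line.split("\t")
            if len(fields) < n_required:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {n_required} columns, "
                    f"got {len(fields)}"
                )
            try:
                c1, s1, e1, c2, s2, e2 = fields[0], int(fields[1]), int(fields[2]), \
                    fields[3], int(fields[4]), int(fields[5])
                probs = [float(x) for x in fields[6:n_required]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})") from exc
            for (s, e) in ((s1, e1), (s2, e2)):
                if e - s != resolution:
                    raise ValidationError(
                        f"{path}:{lineno}: anchor width {e - s} != resolution "
                        f"{resolution}"
                    )
            for p in probs:
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: probability {p} outside [0, 1]"
                    )
            loop = Loop(c1, s1 // resolution, c2, s2 // resolution, resolution,
                        probs=dict(zip(sample_ids, probs)))
            extra = fields[n_required:]
            for name, value in zip(header_extra, extra):
                if name == "category":
                    loop.category = value
                elif name == "subtype":
                    loop.subtype_call = value
            loops.append(loop)
    return loops


def write_loops_bedpe(loops: Iterable[Loop], sample_ids: Sequence[str],
                      path: str | Path, with_annotation: bool = False) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    cols += [f"prob_{s}" for s in sample_ids]
    if with_annotation:
        cols += ["category", "subtype"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for lp in loops:
            r = lp.resolution
            row = [lp.chrom_a, lp.bin_a * r, (lp.bin_a + 1) * r,
                   lp.chrom_b, lp.bin_b * r, (lp.bin_b + 1) * r]
            row += [repr(float(lp.probs[s])) for s in sample_ids]
            if with_annotation:
                row += [lp.category or "None", lp.subtype_call or "unassigned"]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# BED / tables
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; preserves input order, validates every interval."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated "
                                 f"columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [iv.name if iv.name is not None else ".",
                           repr(float(iv.score)) if iv.score is not None else ".",
                           iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_genes_tsv(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: gene table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return [GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples()]


def write_genes_tsv(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    df = pd.DataFrame([(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
                      columns=["gene_id", "chrom", "tss", "strand"])
    df.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ParseError(f"{path}: design table needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    out = []
    for r in df.itertuples():
        rep = getattr(r, "replicate_of", None)
        rep = None if rep is None or (isinstance(rep, float) and np.isnan(rep)) else str(rep)
        out.append(SampleDesign(str(r.sample_id), str(r.group), rep))
    return out


def write_design_tsv(design: Iterable[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.group, s.replicate_of if s.replicate_of else "")
         for s in design],
        columns=["sample_id", "group", "replicate_of"])
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
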