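"""Domain types and file I/O shared by every pipeline stage.

Coordinates are 1-based inclusive throughout (the GFF/GTF convention of the
input files); lengths are ``end - start + 1``.  Long non-coding RNAs must be
at least 200 nt, the defining length cutoff for the class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "LNCRNA_MIN_LENGTH",
    "TREATMENTS",
    "GenomicFeature",
    "SampleInfo",
    "ExpressionMatrix",
    "ValidationError",
    "AnnotationParseError",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
]

logger = logging.getLogger(__name__)

#: minimum lncRNA length in nt
LNCRNA_MIN_LENGTH = 200

#: the four treatments of the repeated-dehydration design: control, first
#: dehydration, first recovery, second dehydration
TREATMENTS = ("C1", "D1", "R1", "D2")

FEATURE_KINDS = ("gene", "lncRNA")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class AnnotationParseError(ValueError):
    """A GFF3/GTF line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicFeature:
    """One gene or lncRNA locus.

    Parameters
    ----------
    feature_id
        Unique identifier within a dataset.
    chrom
        Chromosome name (case-sensitive).
    start, end
        1-based inclusive coordinates, ``start <= end``.
    strand
        ``"+"`` or ``"-"``; strandless records are not representable because
        antisense logic is meaningless without a strand.
    kind
        ``"gene"`` or ``"lncRNA"``.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValidationError("feature_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.feature_id}: invalid coordinates "
                f"[{self.start}, {self.end}] (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.feature_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"{self.feature_id}: kind must be one of {FEATURE_KINDS}, got {self.kind!r}"
            )
        if self.kind == "lncRNA" and self.length < LNCRNA_MIN_LENGTH:
            raise ValidationError(
                f"{self.feature_id}: lncRNA length {self.length} < {LNCRNA_MIN_LENGTH} nt"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: a (treatment, replicate) pair."""

    sample_id: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"{self.sample_id}: treatment must be one of {TREATMENTS}, "
                f"got {self.treatment!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")


def validate_design(samples: Sequence[SampleInfo], require_r1: bool = False) -> None:
    """Check sample-design invariants: unique (treatment, replicate) pairs and
    presence of the mandatory treatments C1, D1, D2 (R1 is optional)."""
    pairs = [(s.treatment, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate (treatment, replicate) pairs in design")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_ids in design")
    present = {s.treatment for s in samples}
    required = {"C1", "D1", "D2"} | ({"R1"} if require_r1 else set())
    missing = required - present
    if missing:
        raise ValidationError(f"design is missing treatments: {sorted(missing)}")


@dataclass
class ExpressionMatrix:
    """Features x samples FPKM table with treatment/replicate metadata.

    ``values`` is a DataFrame indexed by feature_id with one column per
    sample_id, in the order of ``samples``.  All values must be finite and
    non-negative (FPKM are accepted as given; no re-normalization).
    """

    samples: list[SampleInfo]
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_design(self.samples)
        expected = [s.sample_id for s in self.samples]
        if list(self.values.columns) != expected:
            raise ValidationError(
                "expression columns do not match the design sample order"
            )
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature_ids in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def treatment_values(self, treatment: str) -> pd.DataFrame:
        """Sub-matrix of all replicates of one treatment (columns ordered by
        replicate number)."""
        cols = [s.sample_id for s in sorted(
            (s for s in self.samples if s.treatment == treatment),
            key=lambda s: s.replicate,
        )]
        if not cols:
            raise ValidationError(f"treatment {treatment!r} absent from design")
        return self.values[cols]


# ---------------------------------------------------------------------------
# annotation I/O

def read_annotation(
    path: str | Path,
    kind_map: Mapping[str, str],
    id_keys: Sequence[str] = ("ID", "gene_id", "transcript_id"),
) -> list[GenomicFeature]:
    """Read gene/lncRNA loci from a GFF3 or GTF file.

    ``kind_map`` maps source feature types (column 3) to ``"gene"`` or
    ``"lncRNA"``; records whose type is not in the map are skipped (a count
    is logged).  Coordinates are passed through verbatim.  Strandless
    records and duplicate IDs are rejected.
    """
    features: list[GenomicFeature] = []
    seen: set[str] = set()
    skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                rec = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationParseError(str(exc), lineno) from exc
            if rec.featuretype not in kind_map:
                skipped += 1
                continue
            kind = kind_map[rec.featuretype]
            if rec.end < rec.start:
                raise AnnotationParseError(
                    f"end {rec.end} < start {rec.start}", lineno
                )
            if rec.strand not in ("+", "-"):
                raise AnnotationParseError(
                    f"record without strand (got {rec.strand!r}); strandless "
                    "records are rejected", lineno
                )
            fid = None
            for key in id_keys:
                if key in rec.attributes:
                    fid = rec.attributes[key][0]
                    break
            if fid is None:
                raise AnnotationParseError(
                    f"no ID attribute among {tuple(id_keys)}", lineno
                )
            if fid in seen:
                raise ValidationError(f"duplicate feature ID {fid!r}")
            seen.add(fid)
            features.append(
                GenomicFeature(fid, rec.seqid, rec.start, rec.end, rec.strand, kind)
            )
    if skipped:
        logger.info("read_annotation: skipped %d records with unmapped types", skipped)
    return features


def write_annotation(features: Iterable[GenomicFeature], path: str | Path) -> None:
    """Write features as GFF3 (type column = kind, ``ID=`` attribute)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tlncmem\t{f.kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# expression I/O

def read_expression(path: str | Path, design: Sequence[SampleInfo]) -> ExpressionMatrix:
    """Read a tab-delimited FPKM table (first column ``feature_id``, one
    column per sample) and align it to ``design`` order.

    Missing samples, non-numeric cells and negative values are errors; the
    result is independent of the input column order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "feature_id":
        raise ValidationError(
            f"first column must be 'feature_id', got {df.columns[0]!r}"
        )
    df = df.set_index("feature_id")
    missing = [s.sample_id for s in design if s.sample_id not in df.columns]
    if missing:
        raise ValidationError(f"samples in design absent from header: {missing}")
    df = df[[s.sample_id for s in design]]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        row, col = bad[bad].index[0]
        raise ValidationError(
            f"non-numeric expression value at feature {row!r}, sample {col!r}"
        )
    return ExpressionMatrix(samples=list(design), values=numeric.astype(float))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
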