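"""CNV parsing, quality filtering, gene annotation and stratification.

Coordinates: the PLINK-style .cnv dialect is 1-based inclusive on both
ends; all interval arithmetic here happens on 0-based half-open intervals
after conversion at the parse boundary.  Length is defined on the input
convention, end - start + 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "DELETION",
    "DUPLICATION",
    "CNVRecord",
    "AnnotatedCNV",
    "read_cnv_file",
    "write_cnv_file",
    "filter_cnvs",
    "annotate_cnvs",
    "stratify_by_type",
    "GeneIndex",
    "MIN_LENGTH_BP",
    "MIN_PROBES",
]

DELETION = "deletion"
DUPLICATION = "duplication"

#: reliability filter defaults: CNVs at least 100 kb covered by >= 15 probes
MIN_LENGTH_BP = 100_000
MIN_PROBES = 15

_TYPE_CODES = {1: DELETION, 3: DUPLICATION}
_CODE_OF = {DELETION: 1, DUPLICATION: 3}


@dataclass(frozen=True)
class CNVRecord:
    """One CNV call, coordinates 1-based inclusive as read from file."""

    subject_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    n_probes: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"CNV start {self.start} > end {self.end} "
                f"({self.subject_id} {self.chrom})")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.cnv_type not in (DELETION, DUPLICATION):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class AnnotatedCNV:
    cnv: CNVRecord
    genes_hit: frozenset[str]


class CNVParseError(ValueError):
    pass


def read_cnv_file(path, strict: bool = True) -> list[CNVRecord]:
    """Parse the PLINK-style .cnv dialect.

    Columns: FID IID CHR BP1 BP2 TYPE SCORE SITES, whitespace-delimited,
    optional header.  TYPE 1 = deletion, 3 = duplication.  In strict mode
    any malformed line aborts with a line-numbered error; in lenient mode
    malformed lines are skipped and logged.
    """
    records: list[CNVRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if lineno == 1 and fields[0].upper() == "FID":
                continue  # header
            try:
                if len(fields) < 8:
                    raise CNVParseError(f"expected 8 fields, got {len(fields)}")
                _fid, iid, chrom, bp1, bp2, type_code, _score, sites = \
                    fields[:8]
                code = int(type_code)
                if code not in _TYPE_CODES:
                    raise CNVParseError(f"unknown TYPE code {code}")
                rec = CNVRecord(
                    subject_id=iid,
                    chrom=chrom if chrom.startswith("chr") else "chr" + chrom,
                    start=int(bp1), end=int(bp2),
                    cnv_type=_TYPE_CODES[code], n_probes=int(sites))
            except (ValueError, CNVParseError) as exc:
                msg = f"{path}:{lineno}: {exc}"
                if strict:
                    raise CNVParseError(msg) from exc
                logger.warning("skipping malformed CNV line %s", msg)
                n_skipped += 1
                continue
            records.append(rec)
    if n_skipped:
        logger.info("read_cnv_file: skipped %d malformed lines", n_skipped)
    return records


def write_cnv_file(records: list[CNVRecord], path, fid_map=None) -> None:
    """Write records in the .cnv dialect (FID defaults to the subject id)."""
    with open(path, "w") as fh:
        fh.write("FID IID CHR BP1 BP2 TYPE SCORE SITES\n")
        for r in records:
            fid = fid_map.get(r.subject_id, r.subject_id) if fid_map \
                else r.subject_id
            chrom = r.chrom[3:] if r.chrom.startswith("chr") else r.chrom
            fh.write(f"{fid} {r.subject_id} {chrom} {r.start} {r.end} "
                     f"{_CODE_OF[r.cnv_type]} 0 {r.n_probes}\n")


def filter_cnvs(records: list[CNVRecord],
                min_length: int = MIN_LENGTH_BP,
                min_probes: int = MIN_PROBES) -> list[CNVRecord]:
    """Apply the reliability filter: length >= min_length (inclusive) and
    probe support >= min_probes (inclusive)."""
    kept, short, sparse = [], 0, 0
    for r in records:
        if r.length < min_length:
            short += 1
        elif r.n_probes < min_probes:
            sparse += 1
        else:
            kept.append(r)
    if short or sparse:
        logger.info("filter_cnvs: removed %d below %d bp, %d below %d "
                    "probes; retained %d of %d",
                    short, min_length, sparse, min_probes,
                    len(kept), len(records))
    return kept


class GeneIndex:
    """Per-chromosome interval index over gene annotation (0-based
    half-open intervals)."""

    def __init__(self, genes):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id)
        self._warned: set[str] = set()
        self.universe = frozenset(g.gene_id for g in genes)

    def overlapping(self, chrom: str, start0: int, end0: int,
                    min_overlap_frac: float = 0.0) -> frozenset[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from gene annotation",
                               chrom)
                self._warned.add(chrom)
            return frozenset()
        hits = tree.overlap(start0, end0)
        if min_overlap_frac > 0.0:
            span = end0 - start0
            hits = {iv for iv in hits
                    if (min(iv.end, end0) - max(iv.begin, start0))
                    >= min_overlap_frac * span}
        return frozenset(iv.data for iv in hits)


def annotate_cnvs(records: list[CNVRecord], gene_index: GeneIndex,
                  min_overlap_frac: float = 0.0) -> list[AnnotatedCNV]:
    """Attach every gene sharing at least one base with each CNV.

    ``min_overlap_frac`` optionally requires the shared span to cover that
    fraction of the CNV; the default of 0 means any overlap counts.
    """
    out = []
    for r in records:
        s0, e0 = r.interval0
        out.append(AnnotatedCNV(r, gene_index.overlapping(
            r.chrom, s0, e0, min_overlap_frac)))
    return out


def stratify_by_type(records, which: str = "all"):
    """Filtered view of CNV (or annotated-CNV) records by type."""
    if which == "all":
        return list(records)
    if which not in (DELETION, DUPLICATION):
        raise ValueError(f"unknown stratum {which!r}")

    def type_of(r):
        return r.cnv.cnv_type if isinstance(r, AnnotatedCNV) else r.cnv_type

    out = [r for r in records if type_of(r) == which]
    if records and not out:
        warnings.warn(f"stratum {which!r} is empty", UserWarning,
                      stacklevel=2)
    return out
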