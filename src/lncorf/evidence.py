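"""Mapping translational evidence tracks onto called ORFs.

Four record-level evidence kinds are handled here:

* Ribo-seq intervals — a record supports an ORF when at least 90% of the
  record lies inside the ORF (the coverage-fraction convention of
  ``bedtools intersect -f 0.90``, computed on the record side);
* translation initiation sites (TIS) — point evidence inside the ORF;
* m6A sites — point evidence in the ORF-relative 3' UTR, i.e. strictly
  downstream of the ORF's stop codon, deduplicated across merged sources;
* Pfam domain hits — retained when the hmmsearch e-value is < 1e-4.

Coding-potential probabilities (CPAT, CPC2) arrive as per-transcript tables
and are passed through unchanged.

All coordinates are 1-based inclusive transcript coordinates in memory; the
on-disk track dialect is BED-like (0-based half-open) and is converted on
read.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .orf import OrfCall

TRACK_KINDS = ("riboseq", "tis", "m6a")
EVIDENCE_KINDS = ("cpat", "cpc2", "m6a", "pfam", "riboseq", "tis")

DEFAULT_MIN_FRACTION = 0.90
DEFAULT_MAX_EVALUE = 1e-4


@dataclass(frozen=True)
class EvidenceRecord:
    """One evidence datum on a transcript (1-based inclusive interval)."""

    track_kind: str
    transcript_id: str
    start: int
    end: int
    sample_id: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.track_kind not in TRACK_KINDS:
            raise ValidationError(f"unknown track kind {self.track_kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid evidence interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit on a predicted peptide."""

    peptide_id: str
    domain_name: str
    e_value: float

    def __post_init__(self) -> None:
        if not (self.e_value > 0) or math.isnan(self.e_value):
            raise ValidationError(
                f"e-value must be positive, got {self.e_value!r} for {self.peptide_id!r}"
            )


@dataclass(frozen=True)
class CodingScoreRecord:
    """Coding probability of one transcript from one predictor."""

    transcript_id: str
    tool: str
    probability: float

    def __post_init__(self) -> None:
        if self.tool not in ("cpat", "cpc2"):
            raise ValidationError(f"tool must be 'cpat' or 'cpc2', got {self.tool!r}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"coding probability must be in [0, 1], got {self.probability}"
            )


def _check_track(orf: OrfCall, records: Sequence[EvidenceRecord], kind: str) -> None:
    for rec in records:
        if rec.transcript_id != orf.transcript_id:
            raise ValidationError(
                f"{kind} record on transcript {rec.transcript_id!r} passed to an "
                f"ORF of transcript {orf.transcript_id!r}"
            )


def _tree(records: Sequence[EvidenceRecord]) -> IntervalTree:
    # intervaltree uses half-open intervals; store [start, end+1). The tree
    # is a set, so the payload carries the record index to keep duplicate
    # records distinct — every record is one hit, however often repeated.
    return IntervalTree.from_tuples(
        (r.start, r.end + 1, (i, r)) for i, r in enumerate(records)
    )


def count_riboseq_hits(
    orf: OrfCall,
    records: Sequence[EvidenceRecord],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    strict_gt: bool = False,
) -> int:
    """Number of Ribo-seq records covered by the ORF at >= ``min_fraction``.

    The fraction is overlap length divided by the record's own length
    (``bedtools -f`` on the query side). ``strict_gt`` switches the test
    from >= to a literal >.
    """
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must be in (0, 1]")
    _check_track(orf, records, "riboseq")
    count = 0
    for iv in _tree(records).overlap(orf.start, orf.end + 1):
        rec: EvidenceRecord = iv.data[1]
        overlap = min(rec.end, orf.end) - max(rec.start, orf.start) + 1
        fraction = overlap / rec.length
        if (fraction > min_fraction) if strict_gt else (fraction >= min_fraction):
            count += 1
    return count


def count_tis_hits(
    orf: OrfCall,
    records: Sequence[EvidenceRecord],
    start_window: Optional[int] = None,
) -> int:
    """Number of TIS positions inside the ORF interval (inclusive ends).

    With ``start_window`` = w, only positions within ``[start, start + w]``
    count, for stricter initiation-site matching.
    """
    _check_track(orf, records, "tis")
    hi = orf.end if start_window is None else min(orf.end, orf.start + start_window)
    tree = _tree(records)
    count = 0
    for iv in tree.overlap(orf.start, hi + 1):
        rec: EvidenceRecord = iv.data[1]
        if orf.start <= rec.start <= hi:
            count += 1
    return count


def count_m6a_hits(
    orf: OrfCall,
    transcript,
    records: Sequence[EvidenceRecord],
    utr_start: Optional[int] = None,
) -> int:
    """Number of distinct m6A positions in the ORF-relative 3' UTR.

    The 3' UTR of an ORF is the half-open region ``(orf.end,
    transcript_length]``. Positions reported by multiple merged sources are
    deduplicated by (transcript, position) before counting. ``transcript``
    may be a :class:`~lncorf.sequences.Transcript` or its length in nt.
    ``utr_start`` overrides the region's left boundary, e.g. with the stop
    position of the most 3' ORF for a per-transcript UTR definition.
    """
    transcript_length = transcript if isinstance(transcript, int) else transcript.length
    if orf.end > transcript_length:
        raise ValidationError(
            f"ORF end {orf.end} beyond transcript length {transcript_length}"
        )
    _check_track(orf, records, "m6a")
    boundary = orf.end if utr_start is None else utr_start
    positions = {
        rec.start
        for rec in records
        if boundary < rec.start <= transcript_length
    }
    return len(positions)


def filter_domain_hits(
    hits: Iterable[DomainHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> List[DomainHit]:
    """Retain domain hits with e-value strictly below the cutoff (default 1e-4)."""
    return [h for h in hits if h.e_value < max_evalue]


def count_domain_hits(
    peptide_id: str, hits: Iterable[DomainHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> int:
    """Number of retained Pfam hits for one peptide."""
    return sum(1 for h in filter_domain_hits(hits, max_evalue) if h.peptide_id == peptide_id)


def lookup_coding_probability(
    transcript_id: str, table: Sequence[CodingScoreRecord], tool: str
) -> Optional[float]:
    """Coding probability for (transcript, tool), or None when absent.

    Duplicate rows with conflicting probabilities raise
    :class:`ValidationError`; exact duplicates are tolerated.
    """
    values = {
        r.probability
        for r in table
        if r.transcript_id == transcript_id and r.tool == tool
    }
    if len(values) > 1:
        raise ValidationError(
            f"conflicting {tool} probabilities for {transcript_id!r}: {sorted(values)}"
        )
    return values.pop() if values else None


# ---------------------------------------------------------------------------
# readers / writers

def read_evidence_track(path: str | os.PathLike, track_kind: Optional[str] = None) -> List[EvidenceRecord]:
    """Read a 6-column BED-like evidence track.

    Columns: transcript_id, start (0-based), end (half-open), sample_id,
    score, track_kind. Coordinates are converted to 1-based inclusive.
    ``track_kind``, when given, validates that the file carries one kind.
    """
    records: List[EvidenceRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            tid, start0, end, sample_id, _score, kind = fields[:6]
            if track_kind is not None and kind != track_kind:
                raise ValidationError(
                    f"{path}:{lineno}: track kind {kind!r} in a {track_kind!r} track"
                )
            records.append(
                EvidenceRecord(
                    track_kind=kind,
                    transcript_id=tid,
                    start=int(start0) + 1,
                    end=int(end),
                    sample_id=sample_id or None,
                )
            )
    return records


def write_evidence_track(records: Iterable[EvidenceRecord], path: str | os.PathLike) -> None:
    """Write records in the on-disk BED-like dialect (0-based half-open)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.start - 1}\t{r.end}\t{r.sample_id or '.'}\t0\t{r.track_kind}\n"
            )


def read_domain_table(path: str | os.PathLike) -> List[DomainHit]:
    """Read a TSV of (peptide_id, domain_name, e_value), header optional."""
    hits: List[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "peptide_id":
                continue
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            hits.append(DomainHit(fields[0], fields[1], float(fields[2])))
    return hits


def read_hmmsearch_tblout(path: str | os.PathLike) -> List[DomainHit]:
    """Parse hmmsearch ``--tblout`` output into domain hits.

    Uses the full-sequence e-value (column 5) and the query/profile name
    (column 3) as the domain name.
    """
    hits: List[DomainHit] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 5:
                continue
            hits.append(DomainHit(peptide_id=fields[0], domain_name=fields[2],
                                  e_value=float(fields[4])))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("peptide_id\tdomain_name\te_value\n")
        for h in hits:
            fh.write(f"{h.peptide_id}\t{h.domain_name}\t{h.e_value:g}\n")


def read_coding_scores(path: str | os.PathLike) -> List[CodingScoreRecord]:
    """Read a TSV of (transcript_id, tool, probability), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["transcript_id", "tool", "probability"], dtype=str)
    df = df[df["transcript_id"] != "transcript_id"]
    records = [
        CodingScoreRecord(row.transcript_id, row.tool, float(row.probability))
        for row in df.itertuples(index=False)
    ]
    # fail fast on conflicting duplicates
    seen: Dict[tuple, float] = {}
    for r in records:
        key = (r.transcript_id, r.tool)
        if key in seen and seen[key] != r.probability:
            raise ValidationError(
                f"conflicting {r.tool} probabilities for {r.transcript_id!r}"
            )
        seen[key] = r.probability
    return records


def write_coding_scores(records: Iterable[CodingScoreRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttool\tprobability\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.tool}\t{r.probability:g}\n")
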