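"""ORF calling on lncRNA transcripts.

The caller enumerates maximal start-codon -> stop-codon spans in up to six
reading frames, accepting either ATG only or ATG plus the nine near-cognate
start codons (single-nucleotide neighbours of ATG). Overlapping calls are
resolved by keeping the longest ORF, judged on forward-strand nucleotide
intervals across all frames and strands.

Coordinates are 1-based inclusive on the forward transcript, with the stop
codon included in the reported interval, so a complete ORF of ``n`` amino
acids spans ``3 * (n + 1)`` nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

from .errors import ValidationError
from .sequences import STOP_CODONS, Transcript, reverse_complement, translate

#: ATG plus its nine single-substitution neighbours, the near-cognate set
#: conventionally used for non-ATG translation initiation.
NEAR_COGNATE_STARTS = frozenset(
    {"ATG", "CTG", "GTG", "TTG", "ACG", "AAG", "AGG", "ATA", "ATC", "ATT"}
)
ATG_ONLY = frozenset({"ATG"})

START_MODES = {"atg": ATG_ONLY, "near_cognate": NEAR_COGNATE_STARTS}


@dataclass(frozen=True)
class OrfParams:
    """Parameters of the ORF caller.

    min_peptide_len
        Minimum peptide length in amino acids (default 10).
    start_mode
        ``"near_cognate"`` (default) or ``"atg"``.
    frames
        6 for both strands (default) or 3 for the sense strand only.
    require_stop
        Drop spans lacking an in-frame stop codon (default True).
    """

    min_peptide_len: int = 10
    start_mode: str = "near_cognate"
    frames: int = 6
    require_stop: bool = True

    def __post_init__(self) -> None:
        if self.min_peptide_len < 1:
            raise ValidationError("min_peptide_len must be >= 1")
        if self.start_mode not in START_MODES:
            raise ValidationError(
                f"start_mode must be one of {sorted(START_MODES)}, got {self.start_mode!r}"
            )
        if self.frames not in (3, 6):
            raise ValidationError("frames must be 3 or 6")

    @property
    def start_codons(self) -> frozenset[str]:
        return START_MODES[self.start_mode]


@dataclass(frozen=True)
class OrfCall:
    """One called ORF in forward transcript coordinates (1-based inclusive)."""

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    start_codon: str
    peptide: str
    complete: bool

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(f"invalid interval [{self.start}, {self.end}]")
        if self.nt_length % 3 != 0:
            raise ValidationError("ORF nucleotide length must be divisible by 3")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1

    @property
    def aa_length(self) -> int:
        return len(self.peptide)

    def overlaps(self, other: "OrfCall") -> bool:
        """True if forward-coordinate intervals intersect (any strand/frame)."""
        return self.start <= other.end and other.start <= self.end


def _scan_frame(seq: str, frame: int, starts: frozenset[str]) -> List[tuple[int, int]]:
    """Maximal ORF spans (0-based inclusive codon-aligned intervals) in one frame.

    A span runs from the earliest start codon after the previous in-frame
    stop to the stop codon terminating it (stop included). Spans without a
    terminating stop run to the last full codon and are flagged by end < 0
    encoding; here we return (start_idx, stop_idx) with stop_idx = index of
    the stop codon's last base, or -1 when the span is incomplete.
    """
    spans: List[tuple[int, int]] = []
    pending_start: int | None = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if pending_start is not None:
                spans.append((pending_start, i + 2))
                pending_start = None
        elif pending_start is None and codon in starts:
            pending_start = i
        i += 3
    if pending_start is not None:
        spans.append((pending_start, -1))
    return spans


def find_orfs(transcript: Transcript, params: OrfParams | None = None) -> List[OrfCall]:
    """Enumerate candidate ORFs on a transcript.

    Returns every maximal start->stop span in the selected frames whose
    peptide is at least ``params.min_peptide_len`` amino acids. With
    ``require_stop`` (default), spans lacking an in-frame stop are dropped;
    otherwise they are emitted as incomplete calls ending at the last full
    codon. Minus-strand calls report start/end converted back to forward
    coordinates. Results are sorted by (start, end, strand, frame).
    """
    params = params or OrfParams()
    calls: List[OrfCall] = []
    strands = ["+", "-"] if params.frames == 6 else ["+"]
    length = len(transcript.sequence)
    for strand in strands:
        seq = transcript.sequence if strand == "+" else reverse_complement(transcript.sequence)
        for frame in range(3):
            for s0, e0 in _scan_frame(seq, frame, params.start_codons):
                complete = e0 >= 0
                if not complete:
                    if params.require_stop:
                        continue
                    # trim to the last full codon in this frame
                    e0 = frame + ((length - frame) // 3) * 3 - 1
                    if e0 < s0 + 2:
                        continue
                nt = seq[s0 : e0 + 1]
                peptide = translate(nt, require_stop=False)
                if len(peptide) < params.min_peptide_len:
                    continue
                if strand == "+":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = length - e0, length - s0
                calls.append(
                    OrfCall(
                        transcript_id=transcript.id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        start_codon=nt[:3],
                        peptide=peptide,
                        complete=complete,
                    )
                )
    calls.sort(key=lambda c: (c.start, c.end, c.strand, c.frame))
    return calls


def _selection_key(call: OrfCall) -> tuple:
    # longest first; ties: smaller start, '+' before '-', smaller frame
    return (-call.nt_length, call.start, 0 if call.strand == "+" else 1, call.frame)


def select_longest_nonoverlapping(orfs: Sequence[OrfCall]) -> List[OrfCall]:
    """Resolve overlaps by greedily keeping the longest ORF.

    Candidates are visited in descending nucleotide length (ties broken by
    smaller start, then ``+`` before ``-``, then smaller frame); a candidate
    is kept iff its forward-coordinate interval intersects no already-kept
    interval, regardless of strand or frame. The result is sorted by start
    and its intervals are pairwise disjoint. All calls must share one
    transcript.
    """
    if not orfs:
        return []
    ids = {o.transcript_id for o in orfs}
    if len(ids) > 1:
        raise ValidationError(f"mixed transcript ids in selection: {sorted(ids)}")
    kept: List[OrfCall] = []
    for cand in sorted(orfs, key=_selection_key):
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept


def call_orfs(transcript: Transcript, params: OrfParams | None = None,
              keep: str = "longest-nonoverlapping") -> List[OrfCall]:
    """Convenience wrapper: enumerate then optionally resolve overlaps."""
    calls = find_orfs(transcript, params)
    if keep == "all":
        return calls
    if keep == "longest-nonoverlapping":
        return select_longest_nonoverlapping(calls)
    raise ValidationError(f"unknown keep policy {keep!r}")


def orf_id(call: OrfCall, index: int) -> str:
    """Report id for the ``index``-th (1-based) selected ORF of a transcript."""
    return f"{call.transcript_id}_ORF-{index}"
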