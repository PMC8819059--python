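"""End-to-end pipeline: ORF calling -> evidence mapping -> scoring -> HCP.

Evidence inputs are all optional; a missing track marks that kind as not
assayed for every peptide, mirroring how per-species evidence availability
varies in practice. The run is deterministic for fixed inputs and
configuration.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError
from .evidence import (
    CodingScoreRecord,
    DomainHit,
    EvidenceRecord,
    count_domain_hits,
    count_m6a_hits,
    count_riboseq_hits,
    count_tis_hits,
    lookup_coding_probability,
    read_coding_scores,
    read_domain_table,
    read_evidence_track,
)
from .orf import OrfCall, OrfParams, call_orfs, orf_id
from .scoring import (
    DEFAULT_CODING_THRESHOLD,
    EvidenceSummary,
    HcpRuleSet,
    PeptideScore,
    score_cohort,
)
from .sequences import Transcript, read_fasta, write_peptides_fasta

logger = logging.getLogger("lncorf")

REPORT_COLUMNS = [
    "peptide_id", "transcript_id", "species", "start", "end", "strand", "frame",
    "start_codon", "nt_length", "aa_length", "complete",
    "hits_riboseq", "hits_tis", "hits_m6a", "hits_pfam",
    "cpat_probability", "cpc2_probability",
    "s_cpat", "s_cpc2", "s_m6a", "s_pfam", "s_riboseq", "s_tis",
    "composite", "n_evidence_types", "is_hcp", "peptide",
]


@dataclass
class RunConfig:
    """All inputs, outputs and parameters of one pipeline run."""

    fasta: str
    species: str = "unknown"
    riboseq_track: Optional[str] = None
    tis_track: Optional[str] = None
    m6a_track: Optional[str] = None
    coding_table: Optional[str] = None
    domain_table: Optional[str] = None
    out_report: Optional[str] = None
    out_peptides: Optional[str] = None
    orf_params: OrfParams = field(default_factory=OrfParams)
    keep: str = "longest-nonoverlapping"
    min_fraction: float = 0.90
    strict_fraction: bool = False
    tis_window: Optional[int] = None
    m6a_mode: str = "per_orf"
    max_evalue: float = 1e-4
    score_mode: str = "median_normalized"
    median_policy: str = "nonzero_only"
    coding_threshold: float = DEFAULT_CODING_THRESHOLD
    clamp: bool = False
    hcp_overrides: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m6a_mode not in ("per_orf", "per_transcript"):
            raise ConfigurationError(f"unknown m6a_mode {self.m6a_mode!r}")
        if self.keep not in ("all", "longest-nonoverlapping"):
            raise ConfigurationError(f"unknown keep policy {self.keep!r}")


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _by_transcript(records: Sequence[EvidenceRecord]) -> Dict[str, List[EvidenceRecord]]:
    grouped: Dict[str, List[EvidenceRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.transcript_id, []).append(rec)
    return grouped


def map_evidence(
    transcripts: Sequence[Transcript],
    selected: Dict[str, List[OrfCall]],
    config: RunConfig,
    riboseq: Optional[Sequence[EvidenceRecord]] = None,
    tis: Optional[Sequence[EvidenceRecord]] = None,
    m6a: Optional[Sequence[EvidenceRecord]] = None,
    domains: Optional[Sequence[DomainHit]] = None,
    coding: Optional[Sequence[CodingScoreRecord]] = None,
) -> List[EvidenceSummary]:
    """Build per-peptide evidence summaries for the selected ORFs.

    ``None`` for a track means the evidence kind was not assayed; an empty
    list means it was assayed and produced nothing.
    """
    availability = {
        "riboseq": "available" if riboseq is not None else "not_assayed",
        "tis": "available" if tis is not None else "not_assayed",
        "m6a": "available" if m6a is not None else "not_assayed",
        "pfam": "available" if domains is not None else "not_assayed",
        "cpat": "available" if coding is not None else "not_assayed",
        "cpc2": "available" if coding is not None else "not_assayed",
    }
    rs_by_t = _by_transcript(riboseq or [])
    tis_by_t = _by_transcript(tis or [])
    m6a_by_t = _by_transcript(m6a or [])
    summaries: List[EvidenceSummary] = []
    for transcript in transcripts:
        calls = selected.get(transcript.id, [])
        utr_start = max((c.end for c in calls), default=None)
        for idx, call in enumerate(calls, start=1):
            pid = orf_id(call, idx)
            hits = {
                "riboseq": count_riboseq_hits(
                    call, rs_by_t.get(transcript.id, []),
                    config.min_fraction, config.strict_fraction,
                ),
                "tis": count_tis_hits(
                    call, tis_by_t.get(transcript.id, []), config.tis_window
                ),
                "m6a": count_m6a_hits(
                    call, transcript, m6a_by_t.get(transcript.id, []),
                    utr_start=utr_start if config.m6a_mode == "per_transcript" else None,
                ),
                "pfam": count_domain_hits(pid, domains or [], config.max_evalue),
            }
            summaries.append(
                EvidenceSummary(
                    peptide_id=pid,
                    species=config.species,
                    hits=hits,
                    cpat_probability=lookup_coding_probability(
                        transcript.id, coding or [], "cpat"
                    ),
                    cpc2_probability=lookup_coding_probability(
                        transcript.id, coding or [], "cpc2"
                    ),
                    availability=dict(availability),
                )
            )
    return summaries


def build_report(
    transcripts: Sequence[Transcript],
    selected: Dict[str, List[OrfCall]],
    summaries: Sequence[EvidenceSummary],
    scores: Sequence[PeptideScore],
    species: str,
) -> pd.DataFrame:
    """Assemble the per-peptide report table."""
    by_pid_summary = {s.peptide_id: s for s in summaries}
    by_pid_score = {s.peptide_id: s for s in scores}
    rows = []
    for transcript in transcripts:
        for idx, call in enumerate(selected.get(transcript.id, []), start=1):
            pid = orf_id(call, idx)
            summ = by_pid_summary[pid]
            sc = by_pid_score[pid]
            rows.append({
                "peptide_id": pid,
                "transcript_id": transcript.id,
                "species": species,
                "start": call.start,
                "end": call.end,
                "strand": call.strand,
                "frame": call.frame,
                "start_codon": call.start_codon,
                "nt_length": call.nt_length,
                "aa_length": call.aa_length,
                "complete": call.complete,
                "hits_riboseq": summ.hits["riboseq"],
                "hits_tis": summ.hits["tis"],
                "hits_m6a": summ.hits["m6a"],
                "hits_pfam": summ.hits["pfam"],
                "cpat_probability": summ.cpat_probability,
                "cpc2_probability": summ.cpc2_probability,
                "s_cpat": sc.s_cpat,
                "s_cpc2": sc.s_cpc2,
                "s_m6a": sc.s_m6a,
                "s_pfam": sc.s_pfam,
                "s_riboseq": sc.s_riboseq,
                "s_tis": sc.s_tis,
                "composite": sc.composite,
                "n_evidence_types": sc.n_evidence_types,
                "is_hcp": sc.is_hcp,
                "peptide": call.peptide,
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and return the report table.

    Writes the report TSV and peptide FASTA when output paths are set.
    An empty ORF set is a success with an empty report.
    """
    for label, path in (
        ("fasta", config.fasta),
        ("riboseq", config.riboseq_track), ("tis", config.tis_track),
        ("m6a", config.m6a_track), ("coding", config.coding_table),
        ("pfam", config.domain_table),
    ):
        if path is not None:
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} input not found: {path}")
            logger.info("input %s: %s (md5 %s)", label, path, _checksum(path))

    transcripts = read_fasta(config.fasta, species=config.species)
    logger.info("loaded %d transcripts (species=%s)", len(transcripts), config.species)

    selected: Dict[str, List[OrfCall]] = {}
    n_calls = 0
    for transcript in transcripts:
        calls = call_orfs(transcript, config.orf_params, keep=config.keep)
        selected[transcript.id] = calls
        n_calls += len(calls)
    logger.info("called %d ORFs (%s, min %d aa, keep=%s)", n_calls,
                config.orf_params.start_mode, config.orf_params.min_peptide_len,
                config.keep)
    if n_calls == 0:
        logger.warning("no ORFs called; report will be empty")

    riboseq = read_evidence_track(config.riboseq_track, "riboseq") if config.riboseq_track else None
    tis = read_evidence_track(config.tis_track, "tis") if config.tis_track else None
    m6a = read_evidence_track(config.m6a_track, "m6a") if config.m6a_track else None
    coding = read_coding_scores(config.coding_table) if config.coding_table else None
    domains = read_domain_table(config.domain_table) if config.domain_table else None
    for label, track in (("riboseq", riboseq), ("tis", tis), ("m6a", m6a)):
        if track is None:
            logger.info("track %s: not assayed", label)
        else:
            logger.info("track %s: %d records", label, len(track))

    summaries = map_evidence(
        transcripts, selected, config,
        riboseq=riboseq, tis=tis, m6a=m6a, domains=domains, coding=coding,
    )
    rules = HcpRuleSet.paper_defaults().with_overrides(config.hcp_overrides)
    scores = score_cohort(
        summaries, mode=config.score_mode, policy=config.median_policy,
        rules=rules, coding_threshold=config.coding_threshold, clamp=config.clamp,
    )
    report = build_report(transcripts, selected, summaries, scores, config.species)
    logger.info("scored %d peptides, %d HCPs", len(report),
                int(report["is_hcp"].sum()) if len(report) else 0)

    if config.out_report:
        report.to_csv(config.out_report, sep="\t", index=False, float_format="%.6g")
        logger.info("wrote report to %s", config.out_report)
    if config.out_peptides:
        peptides = [
            (row.peptide_id, row.peptide) for row in report.itertuples(index=False)
        ]
        write_peptides_fasta(peptides, config.out_peptides)
        logger.info("wrote %d peptides to %s", len(peptides), config.out_peptides)
    return report
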