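"""Deterministic synthetic transcripts and evidence tracks with known truth.

The generator plants ORFs of known coordinates and peptides into stop-rich
background sequence, then draws evidence records that either satisfy each
mapping rule by construction (true hits) or violate it by a wide margin
(background), so every downstream count can be checked against the recorded
truth exactly.

Background sequence interleaves short random stretches with the 12-mer
``TTAATTAATTAA``, which carries a TAA stop in all three frames and is its
own reverse complement, so it stops reading frames on both strands. With
random stretches capped at 6 nt, no background region can host a stop-free
span of 33 nt, hence no complete ORF of >= 10 amino acids; planted ORFs are
therefore the longest calls in their neighbourhood by construction. Codon
choices inside a planted ORF are resampled until no overlapping
foreign-frame ORF matches its length, which makes planted-ORF recovery by
the caller exact.

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .evidence import (
    CodingScoreRecord,
    DomainHit,
    EvidenceRecord,
    write_coding_scores,
    write_domain_table,
    write_evidence_track,
)
from .sequences import STOP_CODONS, Transcript, reverse_complement, translate, write_fasta

#: stops in all three frames, and its own reverse complement
STOP_BLOCK = "TTAATTAATTAA"
_MIN_GAP = 30
_NT = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``evidence_rates`` are expected (Poisson) true-hit counts per planted
    ORF and kind; ``background_rate`` is the expected number of
    rule-violating records per kilobase of transcript for each track.
    """

    n_transcripts: int = 50
    length_range: Tuple[int, int] = (300, 2000)
    gc_content: float = 0.5
    planted_orfs_per_transcript: int = 1
    planted_aa_range: Tuple[int, int] = (10, 200)
    evidence_rates: Dict[str, float] = field(
        default_factory=lambda: {"riboseq": 3.0, "tis": 1.0, "m6a": 2.0, "pfam": 1.0}
    )
    background_rate: float = 1.0
    coding_probability_range: Tuple[float, float] = (0.0, 1.0)
    start_codon: str = "ATG"
    species: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0 or self.planted_orfs_per_transcript < 0:
            raise ConfigurationError("counts must be non-negative")
        if not (0 < self.gc_content < 1):
            raise ConfigurationError("gc_content must be in (0, 1)")
        lo, hi = self.planted_aa_range
        if not (10 <= lo <= hi <= 500):
            raise ConfigurationError("planted_aa_range must lie within [10, 500]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ConfigurationError("invalid length_range")
        for kind, rate in self.evidence_rates.items():
            if rate < 0:
                raise ConfigurationError(f"negative evidence rate for {kind}")


@dataclass(frozen=True)
class PlantedOrf:
    """Ground truth for one planted ORF."""

    transcript_id: str
    index: int  # 1-based, by position on the transcript
    start: int
    end: int
    peptide: str

    @property
    def peptide_id(self) -> str:
        return f"{self.transcript_id}_ORF-{self.index}"

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthTable:
    """Planted ORFs plus, after evidence simulation, their true hit counts."""

    orfs: List[PlantedOrf]
    transcript_lengths: Dict[str, int]
    hit_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    coding_probabilities: Dict[str, Dict[str, float]] = field(default_factory=dict)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[rng.choice(4, size=n, p=p)])


def _gap(rng: np.random.Generator, n: int, gc: float) -> str:
    """Stop-rich filler of exactly ``n`` nt ending in a full stop block."""
    if n < len(STOP_BLOCK):
        raise ConfigurationError(f"gap of {n} nt cannot hold a stop block")
    filler = []
    total = 0
    while total < n - len(STOP_BLOCK):
        chunk = STOP_BLOCK + _random_nt(rng, int(rng.integers(0, 7)), gc)
        filler.append(chunk)
        total += len(chunk)
    return ("".join(filler))[: n - len(STOP_BLOCK)] + STOP_BLOCK


def _complete_span_lengths(seq: str, exclude: Optional[Tuple[str, int]] = None) -> List[int]:
    """Nucleotide lengths of maximal complete ORF spans in all six frames.

    Start codons are the full near-cognate set, the widest the caller can
    use. ``exclude`` skips the span at (strand, 0-based start) — the
    planted ORF itself during construction checks.
    """
    from .orf import NEAR_COGNATE_STARTS  # local import to avoid a cycle at module load

    lengths: List[int] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            pending = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if pending is not None:
                        if exclude is None or (strand, pending) != exclude:
                            lengths.append(i + 3 - pending)
                        pending = None
                elif pending is None and codon in NEAR_COGNATE_STARTS:
                    pending = i
    return lengths


def _planted_orf_nt(rng: np.random.Generator, aa: int, start_codon: str,
                    max_tries: int = 200) -> str:
    """Nucleotide sequence of a planted ORF (start + aa-1 codons + stop).

    Codons are resampled until, within the ORF flanked by stop blocks, no
    foreign-frame complete ORF reaches the planted length, so the planted
    call always wins longest-ORF selection.
    """
    stops = sorted(STOP_CODONS)
    for _ in range(max_tries):
        body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=aa - 1)]
        nt = start_codon + "".join(body) + stops[int(rng.integers(0, 3))]
        flanked = STOP_BLOCK + nt + STOP_BLOCK
        foreign = _complete_span_lengths(flanked, exclude=("+", len(STOP_BLOCK)))
        if not foreign or max(foreign) < len(nt):
            return nt
    raise ConfigurationError(
        f"could not construct an unambiguous planted ORF of {aa} aa"
    )


def simulate_transcripts(config: SimulationConfig) -> Tuple[List[Transcript], TruthTable]:
    """Generate transcripts with planted ORFs at recorded coordinates."""
    rng = np.random.default_rng([config.seed, 0])
    transcripts: List[Transcript] = []
    orfs: List[PlantedOrf] = []
    lengths: Dict[str, int] = {}
    lo, hi = config.length_range
    k = config.planted_orfs_per_transcript
    for t in range(config.n_transcripts):
        tid = f"SYN{t + 1:05d}"
        aa_sizes = [
            int(rng.integers(config.planted_aa_range[0], config.planted_aa_range[1] + 1))
            for _ in range(k)
        ]
        orf_nts = [
            _planted_orf_nt(rng, aa, config.start_codon) for aa in aa_sizes
        ]
        required = sum(len(s) for s in orf_nts) + (k + 1) * _MIN_GAP
        if required > hi:
            raise ConfigurationError(
                f"planted ORFs need {required} nt but length_range caps at {hi}"
            )
        length = int(rng.integers(max(required, lo), hi + 1))
        extra = length - required
        alloc = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1))) if k >= 0 else []
        gap_sizes = [_MIN_GAP + int(a) for a in alloc]
        parts: List[str] = []
        pos = 0
        for i, orf_nt in enumerate(orf_nts):
            gap = _gap(rng, gap_sizes[i], config.gc_content)
            parts.append(gap)
            pos += len(gap)
            start = pos + 1
            parts.append(orf_nt)
            pos += len(orf_nt)
            orfs.append(
                PlantedOrf(
                    transcript_id=tid,
                    index=i + 1,
                    start=start,
                    end=pos,
                    peptide=translate(orf_nt),
                )
            )
        parts.append(_gap(rng, gap_sizes[k], config.gc_content))
        sequence = "".join(parts)
        assert len(sequence) == length
        transcripts.append(Transcript(id=tid, sequence=sequence, species=config.species))
        lengths[tid] = length
    return transcripts, TruthTable(orfs=orfs, transcript_lengths=lengths)


@dataclass
class SimulatedEvidence:
    """Evidence tracks and tables drawn for one truth table."""

    riboseq: List[EvidenceRecord]
    tis: List[EvidenceRecord]
    m6a: List[EvidenceRecord]
    domain_hits: List[DomainHit]
    coding_scores: List[CodingScoreRecord]


def _gap_regions(truth: TruthTable, tid: str) -> List[Tuple[int, int]]:
    """Maximal intervals of ``tid`` outside every planted ORF (1-based incl.)."""
    length = truth.transcript_lengths[tid]
    planted = sorted(
        (o.start, o.end) for o in truth.orfs if o.transcript_id == tid
    )
    regions = []
    prev = 1
    for s, e in planted:
        if s > prev:
            regions.append((prev, s - 1))
        prev = e + 1
    if prev <= length:
        regions.append((prev, length))
    return regions


def simulate_evidence(truth: TruthTable, config: SimulationConfig) -> SimulatedEvidence:
    """Draw evidence records with known per-ORF qualifying counts.

    True hits satisfy each mapping rule by construction: Ribo-seq records
    lie fully inside their ORF (coverage fraction 1), TIS points fall
    inside the ORF, m6A sites strictly downstream, and Pfam e-values below
    1e-5. Background records violate the rules by margin: Ribo-seq either
    fully outside all ORFs or with at most half the record inside, TIS and
    m6A points where no rule admits them, Pfam e-values above 1.25e-4.
    Fills ``truth.hit_counts`` and ``truth.coding_probabilities`` in place.
    """
    rng = np.random.default_rng([config.seed, 1])
    riboseq: List[EvidenceRecord] = []
    tis: List[EvidenceRecord] = []
    m6a_positions: Dict[str, set] = {tid: set() for tid in truth.transcript_lengths}
    bg_m6a: Dict[str, set] = {tid: set() for tid in truth.transcript_lengths}
    domain_hits: List[DomainHit] = []
    coding: List[CodingScoreRecord] = []
    rates = config.evidence_rates

    for orf in truth.orfs:
        counts = {"riboseq": 0, "tis": 0, "m6a": 0, "pfam": 0}
        tid = orf.transcript_id
        tlen = truth.transcript_lengths[tid]
        # Ribo-seq: intervals fully inside the ORF
        for _ in range(int(rng.poisson(rates.get("riboseq", 0.0)))):
            rec_len = min(int(rng.integers(15, 36)), orf.nt_length)
            s = int(rng.integers(orf.start, orf.end - rec_len + 2))
            riboseq.append(EvidenceRecord("riboseq", tid, s, s + rec_len - 1,
                                          sample_id=f"rs{len(riboseq) + 1}"))
            counts["riboseq"] += 1
        # TIS: points inside the ORF
        for _ in range(int(rng.poisson(rates.get("tis", 0.0)))):
            p = int(rng.integers(orf.start, orf.end + 1))
            tis.append(EvidenceRecord("tis", tid, p, p, sample_id=f"tis{len(tis) + 1}"))
        # m6A: distinct positions strictly downstream of the stop codon
        utr_size = tlen - orf.end
        n_m6a = min(int(rng.poisson(rates.get("m6a", 0.0))), utr_size)
        if n_m6a > 0:
            offs = rng.choice(utr_size, size=n_m6a, replace=False)
            for off in sorted(int(o) for o in offs):
                m6a_positions[tid].add(orf.end + 1 + off)
        # Pfam: true hits comfortably below the e-value cutoff
        for d in range(int(rng.poisson(rates.get("pfam", 0.0)))):
            e = 10.0 ** rng.uniform(-12.0, -5.0)
            domain_hits.append(DomainHit(orf.peptide_id, f"DOM{d + 1}", float(e)))
            counts["pfam"] += 1
        truth.hit_counts[orf.peptide_id] = counts

    # per-ORF truth recomputed for position-based kinds from the final site sets
    for orf in truth.orfs:
        tid = orf.transcript_id
        truth.hit_counts[orf.peptide_id]["tis"] = sum(
            1 for r in tis
            if r.transcript_id == tid and orf.start <= r.start <= orf.end
        )
        truth.hit_counts[orf.peptide_id]["m6a"] = sum(
            1 for p in m6a_positions[tid] if p > orf.end
        )

    # background records, placed to fail every mapping rule by margin
    for tid, tlen in truth.transcript_lengths.items():
        n_bg = int(rng.poisson(config.background_rate * tlen / 1000.0))
        gaps = [g for g in _gap_regions(truth, tid) if g[1] - g[0] + 1 >= 20]
        planted = sorted(
            (o.start, o.end) for o in truth.orfs if o.transcript_id == tid
        )
        first_end = planted[0][1] if planted else tlen
        for b in range(n_bg):
            if gaps:
                lo_g, hi_g = gaps[int(rng.integers(0, len(gaps)))]
                rec_len = int(rng.integers(10, 21))
                s = int(rng.integers(lo_g, hi_g - rec_len + 2))
                riboseq.append(EvidenceRecord("riboseq", tid, s, min(s + rec_len - 1, hi_g),
                                              sample_id=f"bg_rs{tid}_{b}"))
                p = int(rng.integers(lo_g, hi_g + 1))
                tis.append(EvidenceRecord("tis", tid, p, p, sample_id=f"bg_tis{tid}_{b}"))
            # m6A background stays upstream of every ORF's stop codon
            if first_end > 1:
                bg_m6a[tid].add(int(rng.integers(1, first_end)))
        # straddling Ribo-seq background: well under half the record inside
        if planted and n_bg > 0:
            s0, _e0 = planted[0]
            if s0 > 20:
                riboseq.append(EvidenceRecord("riboseq", tid, s0 - 14, s0 + 5,
                                              sample_id=f"bg_straddle_{tid}"))

    # materialize m6A records; true and background sites share one dedup space
    m6a: List[EvidenceRecord] = []
    for tid in truth.transcript_lengths:
        for pos in sorted(m6a_positions[tid] | bg_m6a[tid]):
            m6a.append(EvidenceRecord("m6a", tid, pos, pos, sample_id="m6a"))

    # background Pfam hits above the cutoff, attached to real peptides
    for orf in truth.orfs:
        if config.background_rate > 0 and rng.random() < 0.3:
            e = 10.0 ** rng.uniform(-3.9, -0.3)
            domain_hits.append(DomainHit(orf.peptide_id, "BGDOM", float(e)))

    lo_p, hi_p = config.coding_probability_range
    for tid in truth.transcript_lengths:
        cpat = float(rng.uniform(lo_p, hi_p))
        cpc2 = float(rng.uniform(lo_p, hi_p))
        truth.coding_probabilities[tid] = {"cpat": cpat, "cpc2": cpc2}
        coding.append(CodingScoreRecord(tid, "cpat", round(cpat, 6)))
        coding.append(CodingScoreRecord(tid, "cpc2", round(cpc2, 6)))

    return SimulatedEvidence(
        riboseq=riboseq, tis=tis, m6a=m6a,
        domain_hits=domain_hits, coding_scores=coding,
    )


def write_truth_table(truth: TruthTable, path: str | os.PathLike) -> None:
    cols = ["peptide_id", "transcript_id", "start", "end", "peptide",
            "riboseq", "tis", "m6a", "pfam", "cpat", "cpc2"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for orf in truth.orfs:
            counts = truth.hit_counts.get(orf.peptide_id, {})
            probs = truth.coding_probabilities.get(orf.transcript_id, {})
            row = [
                orf.peptide_id, orf.transcript_id, str(orf.start), str(orf.end),
                orf.peptide,
                *(str(counts.get(k, 0)) for k in ("riboseq", "tis", "m6a", "pfam")),
                *(f"{probs.get(k, 0.0):.6f}" for k in ("cpat", "cpc2")),
            ]
            fh.write("\t".join(row) + "\n")


def write_simulation(config: SimulationConfig, outdir: str | os.PathLike) -> Dict[str, str]:
    """Run the full simulation and write every artefact to ``outdir``.

    Returns a mapping from artefact name to file path. Running twice with
    the same configuration produces byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    transcripts, truth = simulate_transcripts(config)
    evidence = simulate_evidence(truth, config)
    paths = {
        "transcripts": os.path.join(outdir, "transcripts.fasta"),
        "riboseq": os.path.join(outdir, "riboseq.tsv"),
        "tis": os.path.join(outdir, "tis.tsv"),
        "m6a": os.path.join(outdir, "m6a.tsv"),
        "coding_scores": os.path.join(outdir, "coding_scores.tsv"),
        "domain_hits": os.path.join(outdir, "domain_hits.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    write_fasta(transcripts, paths["transcripts"])
    write_evidence_track(evidence.riboseq, paths["riboseq"])
    write_evidence_track(evidence.tis, paths["tis"])
    write_evidence_track(evidence.m6a, paths["m6a"])
    write_coding_scores(evidence.coding_scores, paths["coding_scores"])
    write_domain_table(evidence.domain_hits, paths["domain_hits"])
    write_truth_table(truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "n_transcripts": config.n_transcripts,
                "length_range": list(config.length_range),
                "gc_content": config.gc_content,
                "planted_orfs_per_transcript": config.planted_orfs_per_transcript,
                "planted_aa_range": list(config.planted_aa_range),
                "evidence_rates": dict(config.evidence_rates),
                "background_rate": config.background_rate,
                "coding_probability_range": list(config.coding_probability_range),
                "start_codon": config.start_codon,
                "species": config.species,
                "seed": config.seed,
            },
            fh, sort_keys=True,
        )
    return paths
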