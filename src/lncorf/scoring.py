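"""Peptide-encoding scores and high-confidence peptide (HCP) classification.

Each predicted peptide accumulates up to six lines of evidence: CPAT and
CPC2 coding probabilities, and hit counts for m6A, Pfam, Ribo-seq and TIS.
The composite peptide-encoding score is the sum of six per-evidence scores:

    Score = S(CPAT) + S(CPC2) + S(m6A) + S(Pfam) + S(Ribo-seq) + S(TIS)

where S(CPAT) and S(CPC2) pass the coding probabilities through unchanged,
and each count-based kind is normalized by the cohort median of its hit
counts:

    S(kind) = Hits(kind) / Median(kind)        for m6A, Pfam, TIS
    S(Ribo-seq) = 5 * Hits(Ribo-seq) / Median(Ribo-seq)

the factor 5 up-weighting direct ribosome-occupancy evidence. An alternative
``binary`` mode scores each count-based kind 1 when at least one record
mapped and 0 otherwise. A peptide with zero hits scores 0 in either mode.

The cohort is all scored peptides of one species in the current run; by
default the median is taken over peptides with at least one hit
(``nonzero_only``), which keeps the denominator positive in sparse tracks.

HCP rules are species-specific: human and mouse require Ribo-seq evidence;
A. thaliana, C. elegans, fruit fly, rat, yeast and zebrafish require at
least 4 supporting evidence types; every other species at least 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median as _median
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .errors import ConfigurationError, ValidationError

COUNT_KINDS = ("m6a", "pfam", "riboseq", "tis")
ALL_KINDS = ("cpat", "cpc2") + COUNT_KINDS

RIBOSEQ_WEIGHT = 5.0
DEFAULT_CODING_THRESHOLD = 0.5

#: additive tolerance for the composite-sum invariant
COMPOSITE_ATOL = 1e-9


def normalize_species(name: str) -> str:
    """Canonical lower-case underscore species label, resolving common aliases."""
    key = name.strip().lower().replace(" ", "_").replace(".", "")
    aliases = {
        "homo_sapiens": "human",
        "hsapiens": "human",
        "mus_musculus": "mouse",
        "mmusculus": "mouse",
        "arabidopsis": "arabidopsis_thaliana",
        "a_thaliana": "arabidopsis_thaliana",
        "athaliana": "arabidopsis_thaliana",
        "c_elegans": "caenorhabditis_elegans",
        "celegans": "caenorhabditis_elegans",
        "drosophila": "fruit_fly",
        "drosophila_melanogaster": "fruit_fly",
        "fruitfly": "fruit_fly",
        "rattus_norvegicus": "rat",
        "saccharomyces_cerevisiae": "yeast",
        "danio_rerio": "zebrafish",
    }
    return aliases.get(key, key)


@dataclass
class EvidenceSummary:
    """Per-peptide evidence: hit counts, coding probabilities, availability.

    ``availability`` marks evidence kinds that were never assayed for this
    species (the N/A cells of a per-species evidence matrix); unavailable
    kinds contribute 0 to the composite and never count as support.
    """

    peptide_id: str
    species: str
    hits: Dict[str, int] = field(default_factory=dict)
    cpat_probability: Optional[float] = None
    cpc2_probability: Optional[float] = None
    availability: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in COUNT_KINDS:
            self.hits.setdefault(kind, 0)
        for kind, n in self.hits.items():
            if kind not in COUNT_KINDS:
                raise ValidationError(f"unknown hit kind {kind!r}")
            if n < 0:
                raise ValidationError(f"negative hit count for {kind}: {n}")
        for p, label in ((self.cpat_probability, "cpat"), (self.cpc2_probability, "cpc2")):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValidationError(f"{label} probability {p} outside [0, 1]")
        for kind in ALL_KINDS:
            self.availability.setdefault(kind, "available")

    def is_available(self, kind: str) -> bool:
        return self.availability.get(kind, "available") == "available"


@dataclass(frozen=True)
class CohortStats:
    """Per-species medians of evidence hit counts (score denominators)."""

    species: str
    median: Mapping[str, Optional[float]]
    policy: str = "nonzero_only"


@dataclass(frozen=True)
class PeptideScore:
    """Per-evidence scores, their sum, and the HCP call for one peptide."""

    peptide_id: str
    s_cpat: float
    s_cpc2: float
    s_m6a: float
    s_pfam: float
    s_riboseq: float
    s_tis: float
    composite: float
    n_evidence_types: int
    is_hcp: bool

    def components(self) -> Dict[str, float]:
        return {
            "cpat": self.s_cpat,
            "cpc2": self.s_cpc2,
            "m6a": self.s_m6a,
            "pfam": self.s_pfam,
            "riboseq": self.s_riboseq,
            "tis": self.s_tis,
        }


@dataclass(frozen=True)
class HcpRule:
    """Either a Ribo-seq requirement or a minimum evidence-type count."""

    riboseq_required: bool = False
    min_evidence: Optional[int] = None


@dataclass(frozen=True)
class HcpRuleSet:
    """Species -> HCP rule resolution with a default for unlisted species."""

    rules: Mapping[str, HcpRule]
    default: Optional[HcpRule]

    @classmethod
    def paper_defaults(cls) -> "HcpRuleSet":
        riboseq = HcpRule(riboseq_required=True)
        four = HcpRule(min_evidence=4)
        rules = {"human": riboseq, "mouse": riboseq}
        for sp in ("arabidopsis_thaliana", "caenorhabditis_elegans", "fruit_fly",
                   "rat", "yeast", "zebrafish"):
            rules[sp] = four
        return cls(rules=rules, default=HcpRule(min_evidence=3))

    def resolve(self, species: str) -> HcpRule:
        rule = self.rules.get(normalize_species(species), self.default)
        if rule is None:
            raise ConfigurationError(f"no HCP rule for species {species!r}")
        return rule

    def with_overrides(self, overrides: Mapping[str, Mapping]) -> "HcpRuleSet":
        """New rule set with per-species overrides, e.g. {"chicken": {"min_evidence": 2}}."""
        rules = dict(self.rules)
        default = self.default
        for species, spec in overrides.items():
            rule = HcpRule(
                riboseq_required=bool(spec.get("riboseq_required", False)),
                min_evidence=spec.get("min_evidence"),
            )
            if species == "default":
                default = rule
            else:
                rules[normalize_species(species)] = rule
        return HcpRuleSet(rules=rules, default=default)


def cohort_median(hit_counts: Iterable[int], policy: str = "nonzero_only") -> Optional[float]:
    """Median hit count used as the score denominator, or None when undefined.

    ``nonzero_only`` (default) takes the median over peptides with at least
    one hit, undefined when no peptide has any. ``all_peptides`` takes the
    median over every peptide, undefined when that median is 0.
    """
    counts = list(hit_counts)
    if policy == "nonzero_only":
        nonzero = [c for c in counts if c >= 1]
        return float(_median(nonzero)) if nonzero else None
    if policy == "all_peptides":
        if not counts:
            return None
        m = float(_median(counts))
        return m if m > 0 else None
    raise ValidationError(f"unknown median policy {policy!r}")


def compute_cohort_stats(
    summaries: Sequence[EvidenceSummary], species: str, policy: str = "nonzero_only"
) -> CohortStats:
    """Medians over all peptides of one species in the current run."""
    cohort = [s for s in summaries if normalize_species(s.species) == normalize_species(species)]
    medians = {
        kind: cohort_median((s.hits[kind] for s in cohort), policy)
        for kind in COUNT_KINDS
    }
    return CohortStats(species=species, median=medians, policy=policy)


def evidence_score(
    kind: str,
    hits: int,
    median: Optional[float],
    mode: str = "median_normalized",
    clamp: bool = False,
) -> float:
    """Score one count-based evidence kind for one peptide.

    ``median_normalized`` (default): hits / median, times 5 for Ribo-seq;
    0 when hits is 0 or the median is undefined. ``binary``: 1 if any hit
    mapped, else 0. ``clamp`` caps the normalized score at 1.
    """
    if kind not in COUNT_KINDS:
        raise ValidationError(f"unknown evidence kind {kind!r}")
    if hits < 0:
        raise ValidationError(f"negative hit count {hits}")
    if mode == "binary":
        return 1.0 if hits > 0 else 0.0
    if mode != "median_normalized":
        raise ValidationError(f"unknown scoring mode {mode!r}")
    if hits == 0 or median is None:
        return 0.0
    score = hits / median
    if kind == "riboseq":
        score *= RIBOSEQ_WEIGHT
    if clamp:
        score = min(score, 1.0)
    return score


def count_evidence_types(
    summary: EvidenceSummary, coding_threshold: float = DEFAULT_CODING_THRESHOLD
) -> int:
    """Number of evidence kinds supporting a peptide.

    A count-based kind supports when hits > 0; CPAT/CPC2 support when their
    coding probability is at or above ``coding_threshold``. Kinds not
    assayed for the species never count.
    """
    n = sum(
        1 for kind in COUNT_KINDS
        if summary.is_available(kind) and summary.hits[kind] > 0
    )
    for prob, kind in ((summary.cpat_probability, "cpat"), (summary.cpc2_probability, "cpc2")):
        if summary.is_available(kind) and prob is not None and prob >= coding_threshold:
            n += 1
    return n


def classify_hcp(
    summary: EvidenceSummary,
    rules: Optional[HcpRuleSet] = None,
    coding_threshold: float = DEFAULT_CODING_THRESHOLD,
) -> bool:
    """Apply the species-specific high-confidence peptide rule."""
    rules = rules or HcpRuleSet.paper_defaults()
    rule = rules.resolve(summary.species)
    if rule.riboseq_required:
        return summary.hits["riboseq"] > 0
    if rule.min_evidence is None:
        raise ConfigurationError(
            f"rule for species {summary.species!r} defines neither a Ribo-seq "
            "requirement nor a minimum evidence count"
        )
    return count_evidence_types(summary, coding_threshold) >= rule.min_evidence


def composite_score(
    summary: EvidenceSummary,
    stats: CohortStats,
    mode: str = "median_normalized",
    rules: Optional[HcpRuleSet] = None,
    coding_threshold: float = DEFAULT_CODING_THRESHOLD,
    clamp: bool = False,
) -> PeptideScore:
    """Compute all six per-evidence scores and their sum for one peptide."""
    if normalize_species(summary.species) != normalize_species(stats.species):
        raise ValidationError(
            f"species mismatch: summary {summary.species!r} vs stats {stats.species!r}"
        )
    s_cpat = (
        summary.cpat_probability
        if summary.is_available("cpat") and summary.cpat_probability is not None
        else 0.0
    )
    s_cpc2 = (
        summary.cpc2_probability
        if summary.is_available("cpc2") and summary.cpc2_probability is not None
        else 0.0
    )
    count_scores = {}
    for kind in COUNT_KINDS:
        if not summary.is_available(kind):
            count_scores[kind] = 0.0
        else:
            count_scores[kind] = evidence_score(
                kind, summary.hits[kind], stats.median[kind], mode=mode, clamp=clamp
            )
    components = [s_cpat, s_cpc2] + [count_scores[k] for k in COUNT_KINDS]
    return PeptideScore(
        peptide_id=summary.peptide_id,
        s_cpat=s_cpat,
        s_cpc2=s_cpc2,
        s_m6a=count_scores["m6a"],
        s_pfam=count_scores["pfam"],
        s_riboseq=count_scores["riboseq"],
        s_tis=count_scores["tis"],
        composite=sum(components),
        n_evidence_types=count_evidence_types(summary, coding_threshold),
        is_hcp=classify_hcp(summary, rules, coding_threshold),
    )


def score_cohort(
    summaries: Sequence[EvidenceSummary],
    mode: str = "median_normalized",
    policy: str = "nonzero_only",
    rules: Optional[HcpRuleSet] = None,
    coding_threshold: float = DEFAULT_CODING_THRESHOLD,
    clamp: bool = False,
) -> List[PeptideScore]:
    """Score every peptide, computing per-species cohort medians internally."""
    stats_by_species: Dict[str, CohortStats] = {}
    scores: List[PeptideScore] = []
    for summary in summaries:
        sp = normalize_species(summary.species)
        if sp not in stats_by_species:
            stats_by_species[sp] = compute_cohort_stats(summaries, summary.species, policy)
        scores.append(
            composite_score(
                summary, stats_by_species[sp], mode=mode, rules=rules,
                coding_threshold=coding_threshold, clamp=clamp,
            )
        )
    return scores
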