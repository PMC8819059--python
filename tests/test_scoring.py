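"""Per-evidence scores, cohort medians, composite sums, and HCP rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncorf import (
    CohortStats,
    EvidenceSummary,
    HcpRuleSet,
    ValidationError,
    classify_hcp,
    cohort_median,
    composite_score,
    count_evidence_types,
    evidence_score,
    score_cohort,
)


def summary(species="human", hits=None, cpat=None, cpc2=None, availability=None):
    return EvidenceSummary(
        peptide_id="p1", species=species, hits=dict(hits or {}),
        cpat_probability=cpat, cpc2_probability=cpc2,
        availability=dict(availability or {}),
    )


def stats(species="human", **medians):
    med = {k: None for k in ("m6a", "pfam", "riboseq", "tis")}
    med.update(medians)
    return CohortStats(species=species, median=med)


class TestCohortMedian:
    def test_all_zero_is_undefined(self):
        assert cohort_median([0, 0, 0]) is None
        assert cohort_median([]) is None

    def test_nonzero_only_policy(self):
        assert cohort_median([0, 2, 4, 6], "nonzero_only") == 4

    def test_all_peptides_policy(self):
        assert cohort_median([0, 2, 4, 6], "all_peptides") == 3
        assert cohort_median([0, 0, 0, 1], "all_peptides") is None


class TestEvidenceScore:
    def test_riboseq_at_median_scores_five(self):
        for m in (1.0, 4.0, 77.0):
            assert evidence_score("riboseq", int(m), m) == pytest.approx(5.0)

    def test_zero_hits_score_zero_in_any_mode(self):
        for kind in ("m6a", "pfam", "riboseq", "tis"):
            assert evidence_score(kind, 0, 3.0) == 0.0
            assert evidence_score(kind, 0, 3.0, mode="binary") == 0.0

    def test_quotient_formula(self):
        assert evidence_score("m6a", 3, 2.0) == pytest.approx(1.5)

    def test_binary_mode_is_presence_absence(self):
        assert evidence_score("tis", 7, None, mode="binary") == 1.0
        assert evidence_score("tis", 0, None, mode="binary") == 0.0

    def test_undefined_median_scores_zero(self):
        assert evidence_score("pfam", 4, None) == 0.0

    def test_negative_hits_rejected(self):
        with pytest.raises(ValidationError):
            evidence_score("tis", -1, 2.0)

    def test_clamp_caps_at_one(self):
        assert evidence_score("m6a", 10, 2.0, clamp=True) == 1.0

    @given(st.integers(0, 50), st.floats(0.5, 20.0))
    @settings(deadline=None, derandomize=True)
    def test_riboseq_is_five_times_any_other_kind(self, hits, median):
        assert evidence_score("riboseq", hits, median) == pytest.approx(
            5 * evidence_score("m6a", hits, median)
        )

    @given(st.integers(0, 50), st.floats(0.5, 20.0))
    @settings(deadline=None, derandomize=True)
    def test_linear_in_hits_and_binary_in_unit_set(self, hits, median):
        s1 = evidence_score("tis", hits, median)
        s2 = evidence_score("tis", 2 * hits, median)
        assert s2 == pytest.approx(2 * s1)
        assert evidence_score("tis", hits, median, mode="binary") in (0.0, 1.0)


class TestCompositeScore:
    def test_empty_evidence_gives_zero(self):
        sc = composite_score(summary(), stats())
        assert sc.composite == 0.0 and sc.n_evidence_types == 0

    def test_worked_example_probability_pass_through(self):
        """CPAT 0.286 + CPC2 0.209 with no mapped hits sums to 0.495."""
        sc = composite_score(summary(cpat=0.286, cpc2=0.209), stats())
        assert sc.s_cpat == pytest.approx(0.286)
        assert sc.s_cpc2 == pytest.approx(0.209)
        assert sc.composite == pytest.approx(0.495)

    def test_single_riboseq_term(self):
        sc = composite_score(summary(hits={"riboseq": 4}), stats(riboseq=4.0))
        assert sc.composite == pytest.approx(5.0)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            composite_score(summary(species="rat"), stats(species="human"))

    def test_composite_is_additive_in_components(self):
        st_ = stats(riboseq=2.0, m6a=1.0, tis=3.0, pfam=1.0)
        full = composite_score(
            summary(hits={"riboseq": 2, "m6a": 3, "tis": 3, "pfam": 1},
                    cpat=0.7, cpc2=0.4), st_)
        without_m6a = composite_score(
            summary(hits={"riboseq": 2, "m6a": 0, "tis": 3, "pfam": 1},
                    cpat=0.7, cpc2=0.4), st_)
        assert full.composite - without_m6a.composite == pytest.approx(full.s_m6a)
        assert full.composite == pytest.approx(
            sum(full.components().values()), abs=1e-9
        )

    def test_not_assayed_kind_contributes_nothing(self):
        sc = composite_score(
            summary(hits={"riboseq": 5}, cpat=0.9,
                    availability={"riboseq": "not_assayed", "cpat": "not_assayed"}),
            stats(riboseq=2.0),
        )
        assert sc.s_riboseq == 0.0 and sc.s_cpat == 0.0
        assert sc.n_evidence_types == 0


class TestEvidenceTypeCounting:
    def test_empty_summary_counts_zero(self):
        assert count_evidence_types(summary()) == 0

    def test_threshold_rule_for_coding_tools(self):
        s = summary(hits={"riboseq": 3, "tis": 1}, cpat=0.7, cpc2=0.2)
        assert count_evidence_types(s) == 3
        assert count_evidence_types(s, coding_threshold=0.1) == 4

    def test_all_six_supporting(self):
        s = summary(hits={"riboseq": 1, "tis": 1, "m6a": 1, "pfam": 1},
                    cpat=0.9, cpc2=0.9)
        assert count_evidence_types(s) == 6


class TestHcpRules:
    RULES = HcpRuleSet.paper_defaults()

    def test_human_needs_only_riboseq(self):
        assert classify_hcp(summary(hits={"riboseq": 1}), self.RULES)
        assert not classify_hcp(
            summary(hits={"tis": 5, "m6a": 5, "pfam": 5}, cpat=1.0, cpc2=1.0),
            self.RULES,
        )

    def test_rat_needs_four_evidence_types(self):
        four = summary("rat", hits={"riboseq": 1, "tis": 1, "m6a": 1}, cpat=0.8)
        three = summary("rat", hits={"riboseq": 1, "tis": 1, "m6a": 1})
        assert classify_hcp(four, self.RULES)
        assert not classify_hcp(three, self.RULES)

    def test_other_species_need_three(self):
        chicken = summary("chicken", hits={"riboseq": 1, "tis": 1}, cpat=0.6)
        assert classify_hcp(chicken, self.RULES)
        assert not classify_hcp(summary("chicken", hits={"riboseq": 1, "tis": 1}),
                                self.RULES)

    def test_species_aliases_resolve(self):
        assert classify_hcp(summary("Homo sapiens", hits={"riboseq": 2}), self.RULES)
        assert not classify_hcp(summary("Danio rerio", hits={"riboseq": 1}), self.RULES)

    def test_overrides(self):
        rules = self.RULES.with_overrides({"chicken": {"min_evidence": 1}})
        assert classify_hcp(summary("chicken", hits={"tis": 1}), rules)

    @given(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3))
    @settings(deadline=None, derandomize=True)
    def test_monotone_adding_evidence_never_revokes_hcp(self, a, b, c, d):
        base = summary("rat", hits={"riboseq": a, "tis": b, "m6a": c, "pfam": d})
        more = summary("rat", hits={"riboseq": a + 1, "tis": b, "m6a": c, "pfam": d},
                       cpat=0.9)
        if classify_hcp(base, self.RULES):
            assert classify_hcp(more, self.RULES)


class TestCohortScoring:
    def test_matches_spreadsheet_style_oracle(self):
        """Row-for-row agreement with an independently coded recomputation."""
        rng = np.random.default_rng(42)
        summaries = []
        for i in range(40):
            summaries.append(EvidenceSummary(
                peptide_id=f"p{i}", species="human",
                hits={k: int(rng.poisson(2)) for k in ("m6a", "pfam", "riboseq", "tis")},
                cpat_probability=float(rng.uniform(0, 1)),
                cpc2_probability=float(rng.uniform(0, 1)),
            ))
        scores = {s.peptide_id: s for s in score_cohort(summaries)}

        # independent oracle: plain medians and arithmetic
        import statistics
        med = {}
        for kind in ("m6a", "pfam", "riboseq", "tis"):
            nz = [s.hits[kind] for s in summaries if s.hits[kind] > 0]
            med[kind] = statistics.median(nz) if nz else None
        for s in summaries:
            expected = s.cpat_probability + s.cpc2_probability
            for kind in ("m6a", "pfam", "riboseq", "tis"):
                if s.hits[kind] > 0 and med[kind]:
                    term = s.hits[kind] / med[kind]
                    expected += 5 * term if kind == "riboseq" else term
            assert scores[s.peptide_id].composite == pytest.approx(expected)

    def test_binary_mode_scores_lie_in_unit_set(self):
        summaries = [
            EvidenceSummary(peptide_id=f"p{i}", species="rat",
                            hits={"riboseq": i % 3, "tis": i % 2, "m6a": 0, "pfam": 1})
            for i in range(10)
        ]
        for sc in score_cohort(summaries, mode="binary"):
            for kind, value in sc.components().items():
                if kind not in ("cpat", "cpc2"):
                    assert value in (0.0, 1.0)
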