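import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosite.digest import map_psm
from phosite.io import Modification, ProteinRecord, PsmRecord
from phosite.sites import (
    FilterConfig,
    SiteEvidence,
    collect_site_evidence,
    color_bin,
    detect_and_classify,
    mean_phospho_psms,
    replicate_passes,
    site_count_report,
    summaries_to_frame,
)

from oracles import brute_force_site_analysis


def _evidence(position=32, residue="S", condition="DMSO", replicate=1,
              count=2, prob=98.0):
    return SiteEvidence(
        protein_accession="P1",
        position=position,
        residue=residue,
        condition=condition,
        replicate=replicate,
        phospho_psm_count=count,
        best_localization_probability=prob,
    )


class TestReplicatePasses:
    @pytest.mark.parametrize(
        "count,prob,expected",
        [
            (2, 98.0, True),    # the canonical passing replicate
            (1, 99.0, False),   # below count threshold
            (5, 75.0, False),   # confidence is a strict inequality
            (5, 75.01, True),
            (2, 0.0, False),
        ],
    )
    def test_filter(self, count, prob, expected):
        ev = _evidence(count=count, prob=prob)
        assert replicate_passes(ev, FilterConfig()) is expected

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            FilterConfig(confidence_threshold=0)
        with pytest.raises(ValueError):
            FilterConfig(min_phospho_psms=0)


class TestMeanPhosphoPsms:
    @pytest.mark.parametrize(
        "counts,expected",
        [((2,), 2 / 3), ((17, 17, 17), 17.0), ((2, 3), 5 / 3), ((), 0.0)],
    )
    def test_divides_by_design_replicates(self, counts, expected):
        assert mean_phospho_psms(counts, 3) == pytest.approx(expected)

    def test_two_dp_rendering(self):
        assert f"{mean_phospho_psms((2,), 3):.2f}" == "0.67"
        assert f"{mean_phospho_psms((2, 3), 3):.2f}" == "1.67"


class TestColorBin:
    @pytest.mark.parametrize(
        "mean,expected",
        [(0.67, "gray"), (4.99, "gray"), (5.0, "blue"), (10.0, "blue"),
         (10.01, "coral"), (17.0, "coral"), (0.0, "gray")],
    )
    def test_bins(self, mean, expected):
        assert color_bin(mean) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            color_bin(-0.1)


class TestCollectSiteEvidence:
    def _mapped(self, protein, peptide, mods, condition, replicate, sid):
        psm = PsmRecord(sid, condition, replicate, protein.accession, peptide,
                        tuple(mods))
        return map_psm(psm, protein)

    def test_counts_distinct_psms(self, design):
        protein = ProteinRecord("P1", "MKRGSK")
        mapped = [
            self._mapped(protein, "GSK", [Modification(2, "S", "Phospho", 95.0 + i)],
                         "nocodazole", 1, f"s{i}")
            for i in range(3)
        ]
        (ev,) = collect_site_evidence(mapped, design)
        assert ev.position == 5 and ev.condition == "nocodazole"
        assert ev.phospho_psm_count == 3
        assert ev.best_localization_probability == 97.0  # max over PSMs

    def test_doubly_phosphorylated_peptide_counts_each_site_once(self, design):
        protein = ProteinRecord("P1", "MKRGSTK")
        mods = [Modification(2, "S", "Phospho", 90.0),
                Modification(3, "T", "Phospho", 80.0)]
        mapped = [self._mapped(protein, "GSTK", mods, "DMSO", 1, "s1")]
        evidence = collect_site_evidence(mapped, design)
        assert [(e.position, e.phospho_psm_count) for e in evidence] == [(5, 1), (6, 1)]

    def test_oxidation_ignored(self, design):
        protein = ProteinRecord("P1", "MKRGSK")
        mapped = [self._mapped(protein, "MK", [Modification(1, "M", "Oxidation", 100.0)],
                               "DMSO", 1, "s1")]
        assert collect_site_evidence(mapped, design) == []

    def test_no_phospho_gives_empty(self, design):
        protein = ProteinRecord("P1", "MKRGSK")
        mapped = [self._mapped(protein, "GSK", [], "DMSO", 1, "s1")]
        assert collect_site_evidence(mapped, design) == []


class TestDetectAndClassify:
    def _site(self, position, passing_by_condition, design, count=3, prob=99.0):
        """Evidence rows giving `passing_by_condition[cond]` passing replicates."""
        rows = []
        for cond, n_pass in passing_by_condition.items():
            for rep in range(1, n_pass + 1):
                rows.append(_evidence(position=position, condition=cond,
                                      replicate=rep, count=count, prob=prob))
        return rows

    def test_shared_all(self, design):
        ev = self._site(10, {c: 1 for c in design.conditions}, design)
        (s,) = detect_and_classify(ev, design)
        assert s.category == "shared_all"

    def test_mitotic_shared(self, design):
        ev = self._site(10, {c: 2 for c in design.mitotic_conditions}, design)
        (s,) = detect_and_classify(ev, design)
        assert s.category == "mitotic_shared"

    def test_unique_starred_needs_two_passing_replicates(self, design):
        (s,) = detect_and_classify(self._site(10, {"STLC": 2}, design), design)
        assert s.category == "unique_starred"
        (s,) = detect_and_classify(self._site(10, {"STLC": 1}, design), design)
        assert s.category == "other"

    def test_failing_sites_are_not_detected(self, design):
        ev = [_evidence(count=1, prob=99.0), _evidence(replicate=2, count=9, prob=60.0)]
        assert detect_and_classify(ev, design) == []

    def test_mean_includes_missing_replicates_and_ignores_filter(self, design):
        ev = [_evidence(position=1831, condition="nocodazole", replicate=2,
                        count=2, prob=50.0)]
        # prob 50 fails the filter in that replicate...
        assert detect_and_classify(ev, design) == []
        # ...but a passing site's mean still uses raw counts over all replicates
        ev.append(_evidence(position=1831, condition="STLC", replicate=1,
                            count=8, prob=99.0))
        ev.append(_evidence(position=1831, condition="STLC", replicate=2,
                            count=8, prob=99.0))
        ev.append(_evidence(position=1831, condition="STLC", replicate=3,
                            count=8, prob=99.0))
        (s,) = detect_and_classify(ev, design)
        assert s.per_condition["nocodazole"].mean_phospho_psms == pytest.approx(2 / 3)
        assert s.per_condition["STLC"].mean_phospho_psms == pytest.approx(8.0)
        assert not s.per_condition["nocodazole"].detected


class TestSiteCountReport:
    def test_hand_counted(self, design):
        a = design.conditions[0]
        ev = []
        helper = TestDetectAndClassify()
        ev += helper._site(1, {a: 2}, design)
        ev += helper._site(2, {a: 2}, design)
        ev += helper._site(3, {c: 1 for c in design.conditions}, design)
        summaries = detect_and_classify(ev, design)
        report = site_count_report(summaries, design)
        assert report["per_condition"][a] == 3
        assert all(report["per_condition"][c] == 1 for c in design.conditions[1:])
        assert report["union"] == 3 and report["shared_all"] == 1
        # sites 1 and 2 pass in >=2 replicates of the reference only
        assert report["unique_starred"] == 2

    def test_empty(self, design):
        report = site_count_report([], design)
        assert report["union"] == 0
        assert set(report["per_condition"].values()) == {0}

    def test_categories_partition_union(self, design):
        rng = np.random.default_rng(5)
        ev = _random_evidence(rng, design)
        summaries = detect_and_classify(ev, design)
        report = site_count_report(summaries, design)
        assert (
            report["shared_all"] + report["mitotic_shared"]
            + report["unique_starred"] + report["other"]
        ) == report["union"]
        for c in design.conditions:
            assert report["per_condition"][c] <= report["union"]


def _random_evidence(rng, design, n_sites=20):
    evidence = []
    for pos in rng.choice(np.arange(1, 200), size=n_sites, replace=False):
        residue = rng.choice(list("STY"))
        for cond in design.conditions:
            for rep in design.replicates:
                if rng.random() < 0.4:
                    evidence.append(
                        SiteEvidence(
                            protein_accession="P1",
                            position=int(pos),
                            residue=str(residue),
                            condition=cond,
                            replicate=rep,
                            phospho_psm_count=int(rng.integers(1, 6)),
                            best_localization_probability=float(
                                np.round(rng.uniform(0, 100), 1)
                            ),
                        )
                    )
    return evidence


class TestOracleAgreement:
    def test_matches_independent_recount(self, design):
        """Detection, means and categories agree with a brute-force recount."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            evidence = _random_evidence(rng, design)
            summaries = detect_and_classify(evidence, design)
            rows = [
                {
                    "position": e.position, "residue": e.residue,
                    "condition": e.condition, "replicate": e.replicate,
                    "count": e.phospho_psm_count,
                    "best_prob": e.best_localization_probability,
                }
                for e in evidence
            ]
            oracle = brute_force_site_analysis(
                rows, list(design.conditions), design.reference,
                design.replicates_per_condition,
            )
            assert {(s.position, s.residue) for s in summaries} == set(oracle["sites"])
            for s in summaries:
                expected = oracle["sites"][(s.position, s.residue)]
                assert s.category == expected["category"]
                for cond in design.conditions:
                    assert s.per_condition[cond].mean_phospho_psms == pytest.approx(
                        expected["per_cond"][cond]["mean"]
                    )
            assert site_count_report(summaries, design) == oracle["report"]


class TestFilterMonotonicity:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), confidence=st.floats(50, 99),
           min_psms=st.integers(1, 5))
    def test_tightening_never_increases_counts(self, design, seed, confidence, min_psms):
        rng = np.random.default_rng(seed)
        evidence = _random_evidence(rng, design, n_sites=10)
        loose = FilterConfig(confidence_threshold=confidence, min_phospho_psms=min_psms)
        tight = FilterConfig(confidence_threshold=confidence + 10,
                             min_phospho_psms=min_psms + 1)
        report_loose = site_count_report(detect_and_classify(evidence, design, loose), design)
        report_tight = site_count_report(detect_and_classify(evidence, design, tight), design)
        assert report_tight["union"] <= report_loose["union"]
        for c in design.conditions:
            assert report_tight["per_condition"][c] <= report_loose["per_condition"][c]


class TestSummariesToFrame:
    def test_layout(self, design):
        helper = TestDetectAndClassify()
        ev = helper._site(10, {c: 1 for c in design.conditions}, design)
        frame = summaries_to_frame(detect_and_classify(ev, design), design)
        assert list(frame.columns[:2]) == ["position", "residue"]
        assert f"{design.conditions[0]}_color_bin" in frame.columns
        assert frame.loc[0, "category"] == "shared_all"
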