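import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from promiscuity import (assay_coverage, category_summary, classify_family_scope,
                         count_targets, mixture_identity, promiscuity_summary)
from promiscuity.stats import drug_target_counts, screen_target_counts

from _naive import naive_assay_coverage, naive_counts, naive_scope, naive_summary


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "target_family"])


class TestCountTargets:
    def test_duplicate_targets_counted_once(self):
        pairs = pairs_frame([("c1", "A", "GPCR_A"), ("c1", "B", "GPCR_A"),
                             ("c1", "B", "GPCR_A")])
        counts = count_targets(pairs)
        assert counts["n_targets"].tolist() == [2]

    def test_empty_pairs_empty_counts(self):
        assert len(count_targets(pairs_frame([]))) == 0

    def test_counts_match_brute_force(self, rng):
        rows = [(f"c{i}", f"t{t}", "GPCR_A")
                for i in range(4)
                for t in rng.choice(20, size=rng.integers(1, 7), replace=False)]
        counts = count_targets(pairs_frame(rows))
        expected = naive_counts((c, t) for c, t, _ in rows)
        assert dict(zip(counts["compound_id"], counts["n_targets"])) == expected


class TestPromiscuitySummary:
    def test_hand_arithmetic(self):
        s = promiscuity_summary(np.array([1, 1, 1, 2, 3]))
        assert s.avg_all == pytest.approx(1.6)
        assert s.p_ge2 == pytest.approx(0.4)
        assert s.p_gt5 == 0.0
        assert s.avg_promiscuous == pytest.approx(2.5)
        assert s.median_promiscuous == pytest.approx(2.5)

    def test_all_single_target_promiscuous_fields_undefined(self):
        s = promiscuity_summary(np.array([1, 1, 1]))
        assert s.avg_all == 1.0
        assert s.p_ge2 == 0.0
        assert math.isnan(s.avg_promiscuous)
        assert math.isnan(s.median_promiscuous)

    def test_empty_input_yields_empty_summary(self):
        s = promiscuity_summary(np.array([], dtype=int))
        assert s.is_empty
        assert math.isnan(s.avg_all)

    def test_even_sized_median_is_mean_of_middle_two(self):
        s = promiscuity_summary(np.array([2, 3, 5, 8]))
        assert s.median_promiscuous == pytest.approx(4.0)

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 1001))
            counts = rng.choice(np.arange(1, 13), size=n,
                                p=np.ones(12) / 12)
            s = promiscuity_summary(counts)
            expected = naive_summary(counts.tolist())
            assert s.n_compounds == expected["n_compounds"]
            assert s.avg_all == pytest.approx(expected["avg_all"], abs=0)
            assert s.p_ge2 == pytest.approx(expected["p_ge2"], abs=0)
            assert s.p_gt5 == pytest.approx(expected["p_gt5"], abs=0)
            assert s.avg_promiscuous == pytest.approx(expected["avg_promiscuous"], nan_ok=True)
            assert s.median_promiscuous == pytest.approx(expected["median_promiscuous"], nan_ok=True)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(counts=st.lists(st.integers(1, 12), min_size=1, max_size=60),
           extra=st.integers(0, 30))
    def test_adding_a_target_annotation_is_monotone(self, counts, extra):
        before = promiscuity_summary(np.array(counts))
        bumped = list(counts)
        bumped[extra % len(bumped)] += 1
        after = promiscuity_summary(np.array(bumped))
        assert after.avg_all >= before.avg_all
        assert after.p_ge2 >= before.p_ge2
        assert after.p_gt5 >= before.p_gt5

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(counts=st.lists(st.integers(1, 12), min_size=1, max_size=60))
    def test_mixture_identity_and_ordering_invariants(self, counts):
        s = promiscuity_summary(np.array(counts))
        assert s.p_gt5 <= s.p_ge2 <= 1.0
        if s.p_ge2 > 0:
            prom = [c for c in counts if c >= 2]
            assert min(prom) <= s.median_promiscuous <= max(prom)
            recon = mixture_identity(s.p_ge2, s.avg_promiscuous)
        else:
            recon = mixture_identity(s.p_ge2, math.nan)
        assert abs(s.avg_all - recon) < 1e-12


class TestMixtureIdentity:
    def test_reconstructs_printed_overall_average(self):
        # probability 37.9%, promiscuous-only average 2.9 -> 1.7201 -> 1.7
        avg = mixture_identity(0.379, 2.9)
        assert avg == pytest.approx(1.7201)
        assert round(avg, 1) == 1.7

    def test_degenerate_probabilities(self):
        assert mixture_identity(0.0, math.nan) == 1.0
        assert mixture_identity(1.0, 3.0) == 3.0

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            mixture_identity(0.5, 1.5)
        with pytest.raises(ValueError):
            mixture_identity(1.2, 3.0)


class TestFamilyScope:
    def test_labels(self):
        counts = count_targets(pairs_frame([
            ("c1", "A", "GPCR_A"), ("c1", "B", "GPCR_A"), ("c1", "C", "GPCR_A"),
            ("c2", "A", "GPCR_A"),
            ("c3", "A", "GPCR_A"), ("c3", "K", "kinase"),
        ]))
        labels, breakdown = classify_family_scope(counts)
        assert labels["c1"] == "intra_family"
        assert labels["c2"] == "single"
        assert labels["c3"] == "cross_family"
        assert breakdown.frac_single + breakdown.frac_intra_family \
            + breakdown.frac_cross_family == pytest.approx(1.0, abs=1e-12)

    def test_missing_family_label_rejected(self):
        counts = count_targets(pairs_frame([("c1", "A", np.nan), ("c1", "B", "GPCR_A")]))
        with pytest.raises(ValueError, match="c1"):
            classify_family_scope(counts)

    def test_fractions_match_brute_force(self, rng):
        fams = ["GPCR_A", "kinase", "protease"]
        rows = []
        per_compound = {}
        for i in range(10):
            k = int(rng.integers(1, 5))
            chosen = [fams[rng.integers(0, 3)] for _ in range(k)]
            per_compound[f"c{i}"] = chosen
            rows += [(f"c{i}", f"{f}_t{j}", f) for j, f in enumerate(chosen)]
        counts = count_targets(pairs_frame(rows))
        _, breakdown = classify_family_scope(counts)
        _, (fs, fi, fc) = naive_scope(per_compound)
        assert breakdown.frac_single == pytest.approx(fs)
        assert breakdown.frac_intra_family == pytest.approx(fi)
        assert breakdown.frac_cross_family == pytest.approx(fc)


class TestCategorySummary:
    def drugs_frame(self, rows):
        return pd.DataFrame(rows, columns=["drug_id", "drug_status", "target_id"])

    def outcomes_frame(self, rows):
        return pd.DataFrame(rows, columns=["compound_id", "assay_id", "target_id", "outcome"])

    def test_drug_with_six_targets_promiscuous_under_all_thresholds(self):
        drugs = self.drugs_frame([("d1", "approved", f"t{i}") for i in range(6)])
        s = category_summary(drugs, "approved")
        assert s.avg_all == 6.0
        assert s.p_ge2 == 1.0
        assert s.median_promiscuous == 6.0  # median threshold 5 for approved

    def test_screen_counts_use_distinct_active_targets(self):
        outcomes = self.outcomes_frame([
            ("c1", "a1", "t1", "active"),
            ("c1", "a2", "t1", "active"),
            ("c1", "a3", "t2", "active"),
            ("c1", "a4", "t3", "inactive"),
        ])
        counts = screen_target_counts(outcomes)
        assert counts["n_targets"].tolist() == [2]

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            category_summary(self.drugs_frame([]), "repurposed")

    def test_drug_summary_matches_brute_force(self, rng):
        rows = []
        truth = {}
        for i in range(20):
            k = int(rng.integers(1, 9))
            targets = rng.choice(40, size=k, replace=False)
            truth[f"d{i}"] = k
            rows += [(f"d{i}", "experimental", f"t{t}") for t in targets]
        drugs = self.drugs_frame(rows)
        s = category_summary(drugs, "experimental")
        expected = naive_summary(list(truth.values()), threshold=2, median_threshold=2)
        assert s.avg_all == pytest.approx(expected["avg_all"])
        assert s.p_ge2 == pytest.approx(expected["p_ge2"])
        assert s.avg_promiscuous == pytest.approx(expected["avg_promiscuous"])
        assert s.median_promiscuous == pytest.approx(expected["median_promiscuous"])


class TestAssayCoverage:
    def outcomes(self, rows):
        return pd.DataFrame(rows, columns=["compound_id", "assay_id", "target_id", "outcome"])

    def test_strictly_more_than_threshold(self):
        rows51 = [("c1", f"a{i}", "t1", "inactive") for i in range(50)] \
            + [("c1", "a50", "t1", "active")]
        assert assay_coverage(self.outcomes(rows51)) == 1.0
        rows50 = [("c1", f"a{i}", "t1", "inactive") for i in range(49)] \
            + [("c1", "a49", "t1", "active")]
        assert assay_coverage(self.outcomes(rows50)) == 0.0

    def test_matches_brute_force(self, rng):
        rows = []
        for i in range(30):
            n_assays = int(rng.integers(1, 80))
            for a in range(n_assays):
                outcome = "active" if rng.random() < 0.1 else "inactive"
                rows.append((f"c{i}", f"a{a}", f"t{a % 7}", outcome))
        df = self.outcomes(rows)
        expected = naive_assay_coverage((c, a, o) for c, a, _, o in rows)
        got = assay_coverage(df)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)
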