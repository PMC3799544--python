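import math

import numpy as np
import pandas as pd
import pytest

from promiscuity import (assign_mw_bin, count_targets, default_mw_bins, mixture_identity,
                         promiscuity_summary, stratify_by_family, stratify_by_mw)
from promiscuity.stratification import MWBin, validate_bins

from _naive import naive_summary


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "target_family"])


def meta_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "mw", "category"])


class TestMWBins:
    @pytest.mark.parametrize("mw, label", [
        (150.0, "≤ 200"),
        (200.0, "≤ 200"),        # boundary goes to the lower-labelled bin
        (200.1, "(200, 300)"),
        (300.0, "(200, 300)"),
        (700.0, "(600, 700)"),
        (700.5, "> 700"),
        (5000.0, "> 700"),
    ])
    def test_boundary_convention(self, mw, label):
        assert assign_mw_bin(mw) == label

    def test_non_positive_mw_rejected(self):
        with pytest.raises(ValueError):
            assign_mw_bin(0.0)

    def test_default_bins_partition_positive_reals(self):
        bins = validate_bins(default_mw_bins())
        assert len(bins) == 7
        for mw in (0.1, 200.0, 200.00001, 450.0, 699.99, 700.0, 1e6):
            assert sum(b.contains(mw) for b in bins) == 1

    def test_non_abutting_bins_rejected(self):
        bad = (MWBin("≤ 200", -math.inf, 200.0), MWBin("> 300", 300.0, math.inf))
        with pytest.raises(ValueError, match="abut"):
            validate_bins(bad)


class TestStratifyByFamily:
    def test_cross_family_targets_ignored(self):
        pairs = pairs_frame([
            ("c1", "G1", "GPCR_A"), ("c1", "G2", "GPCR_A"), ("c1", "K1", "kinase"),
        ])
        fs = stratify_by_family(pairs, "GPCR_A")
        assert fs.n_compounds == 1
        assert fs.summary.avg_all == 2.0  # kinase target not counted
        assert stratify_by_family(pairs, "kinase").summary.avg_all == 1.0

    def test_absent_family_gives_empty_summary(self):
        fs = stratify_by_family(pairs_frame([("c1", "G1", "GPCR_A")]), "protease")
        assert fs.n_compounds == 0
        assert fs.summary.is_empty

    def test_restriction_never_increases_counts(self, rng):
        fams = ["GPCR_A", "kinase", "protease"]
        rows = []
        for i in range(30):
            k = int(rng.integers(1, 6))
            for j in range(k):
                f = fams[rng.integers(0, 3)]
                rows.append((f"c{i}", f"{f}_t{rng.integers(0, 10)}", f))
        pairs = pairs_frame(rows).drop_duplicates(["compound_id", "target_id"])
        unrestricted = dict(zip(*count_targets(pairs)[["compound_id", "n_targets"]]
                                .T.to_numpy()))
        for f in fams:
            sub = pairs.loc[pairs["target_family"] == f]
            for cid, n in count_targets(sub)[["compound_id", "n_targets"]].to_numpy():
                assert n <= unrestricted[cid]

    def test_summary_matches_brute_force_restriction(self, rng):
        fams = ["GPCR_A", "kinase"]
        rows = []
        for i in range(40):
            k = int(rng.integers(1, 6))
            for j in range(k):
                f = fams[rng.integers(0, 2)]
                rows.append((f"c{i}", f"{f}_t{rng.integers(0, 8)}", f))
        pairs = pairs_frame(rows).drop_duplicates(["compound_id", "target_id"])
        for f in fams:
            fs = stratify_by_family(pairs, f)
            counts = {}
            for cid, tid, fam in pairs.itertuples(index=False):
                if fam == f:
                    counts.setdefault(cid, set()).add(tid)
            expected = naive_summary([len(v) for v in counts.values()])
            assert fs.n_compounds == expected["n_compounds"]
            assert fs.summary.avg_all == pytest.approx(expected["avg_all"])
            assert fs.summary.p_ge2 == pytest.approx(expected["p_ge2"])
            assert fs.summary.avg_promiscuous == pytest.approx(
                expected["avg_promiscuous"], nan_ok=True)


class TestStratifyByMW:
    def test_each_compound_in_exactly_one_bin(self):
        counts = count_targets(pairs_frame([("c1", "t1", "GPCR_A"),
                                            ("c2", "t1", "GPCR_A"),
                                            ("c2", "t2", "GPCR_A")]))
        meta = meta_frame([("c1", 150.0, "bioactive"), ("c2", 650.0, "bioactive")])
        by_bin = stratify_by_mw(counts, meta)
        assert by_bin["≤ 200"].n_compounds == 1
        assert by_bin["(600, 700)"].n_compounds == 1
        assert sum(s.n_compounds for s in by_bin.values()) == 2

    def test_missing_mw_excluded_with_warning(self, caplog):
        counts = count_targets(pairs_frame([("c1", "t1", "GPCR_A"),
                                            ("c2", "t1", "GPCR_A")]))
        meta = meta_frame([("c1", None, "bioactive"), ("c2", None, "bioactive")])
        with caplog.at_level("WARNING", logger="promiscuity"):
            by_bin = stratify_by_mw(counts, meta)
        assert all(s.is_empty for s in by_bin.values())
        assert any("without MW" in r.message for r in caplog.records)

    def test_per_bin_summaries_match_brute_force(self, rng):
        rows = []
        mws = {}
        for i in range(60):
            k = int(rng.integers(1, 7))
            rows += [(f"c{i}", f"t{t}", "GPCR_A")
                     for t in rng.choice(30, size=k, replace=False)]
            mws[f"c{i}"] = float(rng.uniform(100, 900))
        counts = count_targets(pairs_frame(rows))
        meta = meta_frame([(c, mw, "bioactive") for c, mw in mws.items()])
        by_bin = stratify_by_mw(counts, meta)
        truth = dict(zip(counts["compound_id"], counts["n_targets"]))
        for label, s in by_bin.items():
            members = [truth[c] for c, mw in mws.items() if assign_mw_bin(mw) == label]
            if not members:
                assert s.is_empty
                continue
            expected = naive_summary(members)
            assert s.n_compounds == expected["n_compounds"]
            assert s.avg_all == pytest.approx(expected["avg_all"])
            assert s.p_gt5 == pytest.approx(expected["p_gt5"])

    def test_mixture_identity_holds_within_every_bin(self, rng):
        rows = []
        mws = []
        for i in range(80):
            k = int(rng.integers(1, 5))
            rows += [(f"c{i}", f"t{t}", "GPCR_A") for t in range(k)]
            mws.append((f"c{i}", float(rng.uniform(100, 900)), "bioactive"))
        by_bin = stratify_by_mw(count_targets(pairs_frame(rows)), meta_frame(mws))
        for s in by_bin.values():
            if s.is_empty:
                continue
            recon = mixture_identity(s.p_ge2, s.avg_promiscuous if s.p_ge2 else math.nan)
            assert abs(s.avg_all - recon) < 1e-12
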