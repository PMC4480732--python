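"""Likelihood-ratio calibration, composite scoring, ROC/cutoff and subnetworks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pimnet import (
    ChannelSpec,
    EvidenceChannel,
    NaiveBayesPPI,
    ReferenceSets,
    SimConfig,
    combine_lrs,
    compute_channel_lr,
    extract_subnetwork,
    gen_reference_and_evidence,
    make_pair,
    posterior_odds,
    roc_and_tpfp,
    select_cutoff,
)
from pimnet.bayes import LikelihoodTable

from conftest import binary_channel


class TestChannelLR:
    def test_raw_rate_ratio(self, tiny_refs):
        # 3 of 4 PRS hit, 2 of 8 NRS hit, no smoothing: TPR .75, FPR .25, LR 3
        hits = list(sorted(tiny_refs.prs))[:3] + list(sorted(tiny_refs.nrs))[:2]
        (entry,) = compute_channel_lr(binary_channel("c", hits), tiny_refs, 0.0)
        assert entry.tpr == pytest.approx(0.75)
        assert entry.fpr == pytest.approx(0.25)
        assert entry.lr == pytest.approx(3.0)

    def test_equal_rates_give_unit_lr(self, tiny_refs):
        hits = list(sorted(tiny_refs.prs))[:2] + list(sorted(tiny_refs.nrs))[:4]
        (entry,) = compute_channel_lr(binary_channel("c", hits), tiny_refs, 0.0)
        assert entry.lr == pytest.approx(1.0)

    def test_smoothing_keeps_zero_fpr_finite(self, tiny_refs):
        # 2/4 PRS, 0/8 NRS, alpha .5: TPR .5, FPR .5/9, LR 9
        hits = list(sorted(tiny_refs.prs))[:2]
        (entry,) = compute_channel_lr(binary_channel("c", hits), tiny_refs, 0.5)
        assert entry.tpr == pytest.approx(0.5)
        assert entry.fpr == pytest.approx(0.5 / 9)
        assert entry.lr == pytest.approx(9.0)

    def test_unsmoothed_zero_fpr_raises(self, tiny_refs):
        hits = list(sorted(tiny_refs.prs))[:2]
        with pytest.raises(ZeroDivisionError):
            compute_channel_lr(binary_channel("c", hits), tiny_refs, 0.0)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSets(frozenset(), frozenset(), "Ran").validate_nonempty()


class TestComposite:
    def test_product_and_neutral_missing(self):
        table = LikelihoodTable()
        p = make_pair("X", "Y")
        ch1 = binary_channel("a", [p])
        ch2 = binary_channel("b", [p])
        from pimnet.bayes import LikelihoodEntry

        table.add(LikelihoodEntry("a", 1, 0.5, 0.25, 2.0))
        table.add(LikelihoodEntry("b", 1, 0.6, 0.2, 3.0))
        assert combine_lrs(p, [ch1, ch2], table) == pytest.approx(6.0)
        # pair unseen by both channels -> neutral 1.0
        q = make_pair("X", "Z")
        assert combine_lrs(q, [ch1, ch2], table) == pytest.approx(1.0)
        # single channel passes through
        assert combine_lrs(p, [ch2], table) == pytest.approx(3.0)

    def test_posterior_odds(self):
        assert posterior_odds(0.001, 6.0) == pytest.approx(0.006)
        assert posterior_odds(0.01, 9.0) == pytest.approx(0.09)
        assert posterior_odds(0.37, 1.0) == pytest.approx(0.37)
        with pytest.raises(ValueError):
            posterior_odds(0.0, 2.0)

    @given(
        lr1=st.floats(0.1, 50), lr2=st.floats(0.1, 50), prior=st.floats(1e-4, 10)
    )
    @settings(max_examples=50, deadline=None)
    def test_posterior_monotone_in_lr(self, lr1, lr2, prior):
        lo, hi = sorted([lr1, lr2])
        if lo == hi:
            return
        assert posterior_odds(prior, lo) < posterior_odds(prior, hi)


class TestBruteForceOracle:
    def test_composite_and_edges_match_exhaustive_recomputation(self):
        """On a small universe the pipeline must equal a from-scratch product
        of per-channel smoothed rate ratios."""
        cfg = SimConfig(
            seed=9, universe_size=12, n_prs=20, n_nrs=20, nrs_variant="Ran",
            n_unknown_pairs=10,
            channel_specs=(
                ChannelSpec("c1", 4.0, 0.5),
                ChannelSpec("c2", 2.0, 0.6),
            ),
        )
        refs, channels = gen_reference_and_evidence(cfg)
        alpha = 0.5
        res = NaiveBayesPPI(channels, refs, alpha=alpha).fit()

        # independent brute force from the raw flags
        lr_of = {}
        for ch in channels:
            tp = sum(1 for p in refs.prs if ch.values.get(p) == 1)
            fp = sum(1 for p in refs.nrs if ch.values.get(p) == 1)
            tpr = (tp + alpha) / (len(refs.prs) + 2 * alpha)
            fpr = (fp + alpha) / (len(refs.nrs) + 2 * alpha)
            lr_of[ch.name] = tpr / fpr
        for _, row in res.scores.iterrows():
            p = make_pair(row["protein_a"], row["protein_b"])
            expected = 1.0
            for ch in channels:
                if ch.values.get(p) == 1:
                    expected *= lr_of[ch.name]
            assert row["composite_lr"] == pytest.approx(expected)
        # edge sets: strict inequality at the cutoff
        for cutoff in (0.5, 1.0, 2.0):
            brute = {
                make_pair(a, b)
                for a, b, s in zip(
                    res.scores["protein_a"], res.scores["protein_b"],
                    res.scores["composite_lr"],
                )
                if s > cutoff
            }
            assert res.predict_edges(cutoff) == brute


class TestRocAndCutoff:
    def test_tp_fp_counting(self):
        curve = roc_and_tpfp([5, 4], [3, 2, 1], cutoffs=[2.5])
        row = curve.points.iloc[0]
        assert (row["tp"], row["fp"]) == (2, 1)
        assert row["tpfp"] == pytest.approx(2.0)

    def test_zero_fp_yields_inf_marker(self):
        curve = roc_and_tpfp([5, 4], [3, 2, 1], cutoffs=[3.5])
        assert math.isinf(curve.points["tpfp"].iloc[0])

    def test_separated_scores_auc_one(self):
        curve = roc_and_tpfp([10, 9, 8], [3, 2, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_auc_matches_sklearn(self):
        """Own trapezoid AUC cross-checked against an independent ROC routine."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        prs = rng.normal(1.0, 1.0, 200)
        nrs = rng.normal(0.0, 1.0, 200)
        curve = roc_and_tpfp(prs, nrs)
        ref = roc_auc_score([1] * 200 + [0] * 200, np.concatenate([prs, nrs]))
        assert curve.auc == pytest.approx(ref, abs=1e-6)

    def test_select_cutoff_scan_and_errors(self):
        import pandas as pd
        from pimnet.bayes import RocCurve

        pts = pd.DataFrame(
            {"cutoff": [1, 2, 3, 4], "tp": [4] * 4, "fp": [4, 2, 1, 0],
             "tpr": [1] * 4, "fpr": [1, 0.5, 0.25, 0],
             "tpfp": [1.0, 2.0, 4.0, 8.0]}
        )
        curve = RocCurve(points=pts, auc=1.0)
        assert select_cutoff(curve, 4) == 3
        assert select_cutoff(curve, 0.5) == 1
        with pytest.raises(ValueError, match="best attained"):
            select_cutoff(curve, 100)

    def test_edges_antitone_in_cutoff(self):
        cfg = SimConfig(seed=4, universe_size=30, n_prs=50, n_nrs=50)
        refs, channels = gen_reference_and_evidence(cfg)
        res = NaiveBayesPPI(channels, refs).fit()
        cutoffs = sorted(res.scores["composite_lr"].unique())
        prev = None
        for c in cutoffs:
            edges = res.predict_edges(c)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_predict_edges_boundaries(self):
        cfg = SimConfig(seed=4, universe_size=20, n_prs=30, n_nrs=30)
        refs, channels = gen_reference_and_evidence(cfg)
        res = NaiveBayesPPI(channels, refs).fit()
        assert res.predict_edges(res.scores["composite_lr"].max()) == set()
        assert len(res.predict_edges(0.0)) == len(res.scores)


class TestCalibrationRecovery:
    def test_estimated_lr_within_15pct_at_5000(self):
        cfg = SimConfig(
            seed=13, universe_size=200, n_prs=5000, n_nrs=5000,
            nrs_variant="Ran", n_unknown_pairs=0,
        )
        refs, channels = gen_reference_and_evidence(cfg)
        res = NaiveBayesPPI(channels, refs).fit()
        lrs = res.likelihoods.to_frame().set_index("channel")["lr"]
        for spec in cfg.channel_specs:
            assert abs(lrs[spec.name] / spec.target_lr - 1) < 0.15

    def test_variant_agnostic_downstream(self):
        """Loc and Ran runs differ only in NRS membership; scoring machinery
        behaves identically."""
        for variant in ("Loc", "Ran"):
            cfg = SimConfig(seed=21, nrs_variant=variant, universe_size=60,
                            n_prs=100, n_nrs=100)
            refs, channels = gen_reference_and_evidence(cfg)
            res = NaiveBayesPPI(channels, refs).fit()
            assert res.roc().auc > 0.6  # informative channels separate either way


class TestSubnetwork:
    def test_degrees_and_shared_neighbors(self):
        edges = [make_pair("P1", "X"), make_pair("P1", "Y"), make_pair("P2", "X")]
        sn = extract_subnetwork(edges, ["P1", "P2"])
        assert sn.degrees == {"P1": 2, "P2": 1}
        assert sn.shared_neighbors == ["X"]

    def test_absent_seed_warns_and_is_empty(self):
        edges = [make_pair("P1", "X")]
        with pytest.warns(UserWarning, match="absent"):
            sn = extract_subnetwork(edges, ["P1", "P9"])
        assert sn.neighbors["P9"] == []
        assert sn.degrees["P9"] == 0

    def test_tag_filter(self):
        edges = [make_pair("P1", "X"), make_pair("P1", "Y")]
        sn = extract_subnetwork(edges, ["P1"], {"X": "apoptosis"}, "apoptosis")
        assert sn.tag_filtered["P1"] == ["X"]

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            make_pair("A", "A")
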