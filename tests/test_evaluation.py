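"""Evaluation statistics: windows, variance explained, collation,
calibration, B-reduction summaries, deleterious-rate accounting."""

import numpy as np
import pandas as pd
import pytest

from linkedsel import (
    FitConfig,
    FitResult,
    PolymorphismTable,
    PredictionTrack,
    SelectionGrid,
    ThetaParams,
    b_reduction_summary,
    calibration_curve,
    collate_by_distance,
    deleterious_rate_report,
    variance_explained,
    windowed_diversity,
)
from linkedsel.genome_io import SubstitutionSet
from tests.test_bgs import uniform_map


def make_track(pos, pi=None, B=None, S=None, pi0=None, m=None):
    n = len(pos)
    return PredictionTrack(
        chrom=np.full(n, "chr1"),
        pos=np.asarray(pos, dtype=np.int64),
        pi=np.asarray(pi if pi is not None else np.full(n, 1e-3)),
        B=np.asarray(B if B is not None else np.ones(n)),
        S=np.asarray(S if S is not None else np.zeros(n)),
        pi0=np.asarray(pi0 if pi0 is not None else np.full(n, 1.1e-3)),
        m=np.asarray(m if m is not None else np.ones(n)),
    )


def make_table(pos, h, n=216):
    C = n * (n - 1) // 2
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.asarray(pos, dtype=np.int64),
            "n": n,
            "k": 0,
            "h": np.asarray(h, dtype=np.int64),
        }
    )
    return PolymorphismTable(sites=df)


class TestWindowedDiversity:
    def test_uniform_genome_normalises_to_one(self):
        pos = np.arange(1000, 3_000_000, 1000)
        table = make_table(pos, np.full(len(pos), 23))
        track = make_track(pos)
        ws = windowed_diversity(table, track, 1_000_000, 0)
        assert np.allclose(ws.windows["obs"], 1.0)
        assert np.allclose(ws.windows["pred"], 1.0)

    def test_window_count_with_overlap(self):
        # 3 Mb of sites, 1 Mb windows with 0.5 Mb overlap -> 5 full windows
        pos = np.arange(1000, 3_000_001, 1000)
        table = make_table(pos, np.full(len(pos), 23))
        ws = windowed_diversity(table, make_track(pos), 1_000_000, 500_000)
        assert len(ws.windows) == 5
        assert ws.windows["start"].iloc[-1] == 2_000_000

    def test_empty_windows_dropped(self):
        pos = np.concatenate([np.arange(1000, 900_000, 1000),
                              np.arange(2_100_000, 3_000_001, 1000)])
        table = make_table(pos, np.full(len(pos), 23))
        with pytest.warns(UserWarning, match="dropped"):
            ws = windowed_diversity(
                table, make_track(pos), 1_000_000, 0, min_sites=10
            )
        assert ws.n_dropped == 1
        assert len(ws.windows) == 2

    def test_overlap_validation(self):
        pos = np.arange(1000, 100_000, 1000)
        table = make_table(pos, np.full(len(pos), 23))
        with pytest.raises(ValueError):
            windowed_diversity(table, make_track(pos), 1_000_000, 1_000_000)


class TestVarianceExplained:
    def _series(self, obs, pred):
        pos = np.arange(1000, len(obs) * 1_000_000, 1000)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(obs)) * 1_000_000,
                "end": (np.arange(len(obs)) + 1) * 1_000_000,
                "obs": obs,
                "pred": pred,
                "n_sites": 100,
            }
        )
        from linkedsel.evaluation import WindowSeries

        return WindowSeries(df, 1_000_000, 0)

    def test_perfect_prediction(self):
        obs = np.array([0.8, 1.0, 1.2, 0.9, 1.1])
        ve = variance_explained({1_000_000: self._series(obs, obs.copy())})
        assert ve["r2"][0] == pytest.approx(1.0)

    def test_constant_prediction_zero(self):
        obs = np.array([0.8, 1.0, 1.2, 0.9, 1.1])
        ve = variance_explained({1_000_000: self._series(obs, np.full(5, obs.mean()))})
        assert ve["r2"][0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_windows(self):
        with pytest.raises(ValueError, match=">= 3"):
            variance_explained({1_000_000: self._series(np.ones(2), np.ones(2))})

    def test_overlapping_windows_rejected(self):
        s = self._series(np.ones(5), np.ones(5))
        s.overlap_bp = 500_000
        with pytest.raises(ValueError, match="non-overlapping"):
            variance_explained({1_000_000: s})


class TestCollate:
    def test_bin_assignment_uniform_map(self):
        # single feature on a 1 cM/Mb map: bin index = floor(d_cm / 0.005)
        gmap = uniform_map(2_000_000)
        feature = SubstitutionSet(
            sites=pd.DataFrame(
                {"chrom": ["chr1"], "pos": [1_000_000], "class_label": ["nonsynonymous"]}
            )
        )
        pos = np.array([1_000_000, 1_002_000, 1_007_000, 1_792_000, 1_900_000])
        # d_cm = 0, .002, .007, .792, .9 -> bins 0, 0, 1, 158, beyond
        table = make_table(pos, np.full(len(pos), 23))
        prof = collate_by_distance(table, make_track(pos), feature, gmap)
        counts = prof.bins["n_sites"].to_numpy()
        assert counts[0] == 2 and counts[1] == 1 and counts[158] == 1
        assert prof.n_beyond == 1
        assert len(prof.bins) == 160

    def test_pred_profile_rises_with_distance(self, small_genome, small_data):
        genome, bundle, _ = small_genome
        track = make_track(
            genome.neutral_pos, pi=bundle.pi, B=bundle.B, pi0=bundle.pi0, m=genome.m
        )
        prof = collate_by_distance(
            small_data, track, genome.substitutions, genome.gmap, n_bins=40
        )
        pred = prof.bins["pred"].dropna().to_numpy()
        # BGS-only truth: predicted diversity increases away from features
        # (substitutions cluster in constrained blocks); monotone trend test
        assert np.corrcoef(np.arange(len(pred)), pred)[0, 1] > 0.5
        assert pred[0] < pred[-10:].mean()

    def test_no_features_rejected(self, small_genome, small_data):
        genome, _, _ = small_genome
        empty = SubstitutionSet(
            sites=pd.DataFrame(columns=["chrom", "pos", "class_label"])
        )
        track = make_track(genome.neutral_pos, m=genome.m)
        with pytest.raises(ValueError):
            collate_by_distance(small_data, track, empty, genome.gmap)


class TestCalibration:
    def test_perfect_model_identity_line(self):
        rng = np.random.default_rng(0)
        n = 20_000
        pos = np.arange(1, n + 1) * 100
        B = rng.uniform(0.6, 1.0, size=n)
        pi0 = 1.1e-3
        pi = pi0 * B
        nC = 2000
        C = nC * (nC - 1) // 2
        h = np.round(C * pi).astype(int)  # noise-free pairs
        table = make_table(pos, h, n=nC)
        track = make_track(pos, pi=pi, B=B, pi0=np.full(n, pi0))
        cal = calibration_curve(table, track, pi0, loess_bins=500)
        assert cal.slope == pytest.approx(1.0, abs=0.01)
        assert cal.r2 > 0.999
        assert cal.pooled_lowest is not None
        assert len(cal.loess) == 500

    def test_group_lowest_zero_no_pooled_point(self):
        pos = np.arange(1, 1001) * 100
        table = make_table(pos, np.full(1000, 23))
        track = make_track(pos, B=np.linspace(0.5, 1, 1000))
        cal = calibration_curve(table, track, 1e-3, n_bins=10, group_lowest=0,
                                loess_bins=0)
        assert cal.pooled_lowest is None

    def test_more_bins_than_sites_rejected(self):
        pos = np.arange(1, 51) * 100
        table = make_table(pos, np.full(50, 23))
        with pytest.raises(ValueError):
            calibration_curve(table, make_track(pos), 1e-3, n_bins=100)


class TestBReduction:
    def test_no_selection(self):
        pos = np.arange(1, 1001) * 100
        summary = b_reduction_summary(make_track(pos, B=np.ones(1000)))
        assert summary["mean_reduction"] == 0.0
        assert all(d == 0.0 for d in summary["decile_reductions"])

    def test_constant_track(self):
        pos = np.arange(1, 1001) * 100
        summary = b_reduction_summary(make_track(pos, B=np.full(1000, 0.83)))
        assert summary["mean_reduction"] == pytest.approx(0.17, abs=1e-12)
        assert summary["most_affected_decile"] == pytest.approx(0.17, abs=1e-12)

    def test_matches_direct_computation_on_truth(self, small_genome):
        genome, bundle, _ = small_genome
        track = make_track(genome.neutral_pos, B=bundle.B)
        summary = b_reduction_summary(track, exclude_top_bins_pct=0)
        assert summary["mean_reduction"] == pytest.approx(1 - bundle.B.mean(), rel=1e-12)
        B_sorted = np.sort(bundle.B)
        n = len(B_sorted)
        assert summary["most_affected_decile"] == pytest.approx(
            1 - B_sorted[: n // 10].mean(), abs=1e-3
        )

    def test_top_bins_excluded(self):
        pos = np.arange(1, 1001) * 100
        B = np.linspace(0.5, 1.0, 1000)
        summary = b_reduction_summary(make_track(pos, B=B), exclude_top_bins_pct=2)
        assert summary["n_excluded"] == 20
        assert summary["least_affected_decile"] > 0.0


class TestDeleteriousRateReport:
    def _fit_result(self, U):
        theta = ThetaParams(ne=2e4, U=U)
        return FitResult(
            theta_hat=theta, loglik=-1.0, n_sites=100, n_pairs=1e6,
            converged=True, starts=[], config=FitConfig(),
            bgs_classes=list(U),
        )

    def test_ratio_range(self):
        fr = self._fit_result({"conserved": np.full(6, 7e-9 / 6)})
        rep = deleterious_rate_report(fr, {"conserved": 1000})
        c = rep["classes"]["conserved"]
        assert c["ratio_lower"] == pytest.approx(7e-9 / 1.51e-8, rel=1e-6)
        assert c["ratio_upper"] == pytest.approx(7e-9 / 1.29e-8, rel=1e-6)
        assert not c["exceeds_bound"]

    def test_shares_weighted_by_class_size(self):
        U = {"a": np.array([1e-9]), "b": np.array([1e-9])}
        fr = self._fit_result(U)
        rep = deleterious_rate_report(fr, {"a": 100, "b": 400})
        assert rep["classes"]["a"]["share_of_deleterious_input"] == pytest.approx(0.2)
        assert rep["classes"]["b"]["share_of_deleterious_input"] == pytest.approx(0.8)

    def test_zero_rate_flagged(self):
        fr = self._fit_result({"a": np.zeros(3)})
        rep = deleterious_rate_report(fr, {"a": 100})
        assert rep["flag"] == "no deleterious input"

    def test_missing_site_count(self):
        fr = self._fit_result({"a": np.array([1e-9])})
        with pytest.raises(ValueError, match="site count"):
            deleterious_rate_report(fr, {})
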