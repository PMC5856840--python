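"""Snapshot-ensemble prediction: sampling, filtering, fractions, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coatkit import (
    CalibrationScale,
    DetectionLimit,
    SnapshotEnsemble,
    TransitionRule,
    apply_detection_limit,
    compare_distributions,
    intensity_to_area,
    morphology_fractions,
    predict_event,
    predict_stalled_morphology,
    sample_snapshots,
)
from coatkit.ensemble import EventPrediction
from coatkit.growth import MorphologyTimeline


def _toy_prediction(track_id, t_nuc, t_tr, t_sc, rule=None, area=2000.0):
    rule = rule or TransitionRule()
    t_dome_end = t_tr + rule.dome_fraction * (t_sc - t_tr)
    tl = MorphologyTimeline(t_nuc, t_tr, t_dome_end, t_sc)
    const = lambda t: np.full(np.shape(np.asarray(t)), area)
    return EventPrediction(track_id=track_id, timeline=tl, projected_area=const, surface=const)


class TestIntensityToArea:
    def test_linear_and_round_trip(self):
        scale = CalibrationScale(2.5)
        assert intensity_to_area(0.0, scale) == 0.0
        assert intensity_to_area(5.0, scale) == pytest.approx(2.0)
        x = np.array([1.0, 10.0, 100.0])
        assert np.allclose(intensity_to_area(x, scale) * scale.intensity_per_area, x)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            CalibrationScale(0.0)


class TestSampleSnapshots:
    def test_single_all_flat_track(self):
        pred = _toy_prediction("a", 0.0, 60.0, 60.0)
        ens = sample_snapshots([pred], n_samples=500, seed=1)
        assert (ens.records["morphology"] == "flat").all()

    def test_curved_phase_dome_fraction(self):
        """Sampling restricted to the curved phase yields the rule's dome
        fraction (40%) within binomial error."""
        rule = TransitionRule()
        pred = _toy_prediction("a", 0.0, 30.0, 60.0, rule)
        ens = sample_snapshots([pred], n_samples=100_000, seed=2, restrict="curved")
        dome = (ens.records["morphology"] == "dome").mean()
        # 99.9% binomial CI half-width at n=1e5, p=0.4
        assert abs(dome - rule.dome_fraction) < 3.3 * np.sqrt(0.4 * 0.6 / 100_000)

    def test_three_track_toy_matches_enumeration(self):
        """Lifetime-weighted sampling reproduces exhaustive time-grid
        enumeration of morphology fractions on a hand-built toy."""
        rule = TransitionRule()
        preds = [
            _toy_prediction("a", 0.0, 40.0, 50.0, rule),
            _toy_prediction("b", 0.0, 10.0, 100.0, rule),
            _toy_prediction("c", 0.0, 25.0, 25.0, rule),
        ]
        # enumeration on a fixed-step grid: frame pooling weights each track
        # by its lifetime, so the grid step must be common to all tracks
        labels = []
        for p in preds:
            t = np.arange(p.timeline.t_nucleation, p.timeline.t_scission, 0.001)
            labels.append(p.morphology(t))
        enum = pd.Series(np.concatenate(labels)).value_counts(normalize=True)
        ens = sample_snapshots(preds, n_samples=200_000, seed=3)
        sampled = ens.records["morphology"].value_counts(normalize=True)
        for m in ("flat", "dome", "pit"):
            assert sampled.get(m, 0.0) == pytest.approx(enum.get(m, 0.0), abs=0.01)

    def test_seed_reproducible(self):
        pred = _toy_prediction("a", 0.0, 30.0, 60.0)
        e1 = sample_snapshots([pred], n_samples=100, seed=9)
        e2 = sample_snapshots([pred], n_samples=100, seed=9)
        pd.testing.assert_frame_equal(e1.records, e2.records)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sample_snapshots([], n_samples=10, seed=0)


class TestDetectionLimit:
    def _ensemble(self, areas, morph="flat"):
        return SnapshotEnsemble(
            records=pd.DataFrame(
                {"morphology": [morph] * len(areas), "projected_area_nm2": areas}
            )
        )

    def test_zero_limit_is_identity(self):
        ens = self._ensemble([500.0, 1500.0, 2500.0])
        out = apply_detection_limit(ens, DetectionLimit(0.0))
        assert len(out) == 3
        assert out.meta["n_removed_below_limit"] == 0

    def test_toy_filtering(self):
        ens = self._ensemble([500.0, 1500.0, 2500.0])
        out = apply_detection_limit(ens, DetectionLimit(1000.0))
        assert len(out) == 2
        assert out.meta["n_removed_below_limit"] == 1

    def test_removed_fraction_equals_empirical_cdf(self):
        rng = np.random.default_rng(4)
        areas = rng.lognormal(np.log(2000), 0.6, 2000)
        limit = 1500.0
        ens = self._ensemble(list(areas))
        out = apply_detection_limit(ens, DetectionLimit(limit))
        removed = out.meta["n_removed_below_limit"] / len(areas)
        assert removed == pytest.approx(np.mean(areas < limit), abs=1e-12)

    def test_commutes_with_morphology_labelling(self):
        rng = np.random.default_rng(5)
        n = 500
        df = pd.DataFrame(
            {
                "morphology": rng.choice(["flat", "dome", "pit"], n),
                "projected_area_nm2": rng.lognormal(np.log(2000), 0.5, n),
            }
        )
        filtered = apply_detection_limit(SnapshotEnsemble(records=df), DetectionLimit(1800.0))
        manual = df[df["projected_area_nm2"] >= 1800.0]
        assert filtered.records["morphology"].value_counts().to_dict() == (
            manual["morphology"].value_counts().to_dict()
        )


class TestMorphologyFractions:
    def test_all_flat_and_equal_thirds(self):
        all_flat = SnapshotEnsemble(
            records=pd.DataFrame({"morphology": ["flat"] * 10, "projected_area_nm2": 1.0})
        )
        f = morphology_fractions(all_flat)
        assert f.fractions == {"flat": 100.0, "dome": 0.0, "pit": 0.0}
        thirds = SnapshotEnsemble(
            records=pd.DataFrame(
                {"morphology": ["flat", "dome", "pit"] * 5, "projected_area_nm2": 1.0}
            )
        )
        f = morphology_fractions(thirds)
        for v in f.fractions.values():
            assert v == pytest.approx(100.0 / 3.0)

    def test_grouped_sd_matches_brute_force(self):
        rng = np.random.default_rng(6)
        n = 600
        df = pd.DataFrame(
            {
                "morphology": rng.choice(["flat", "dome", "pit"], n, p=[0.5, 0.2, 0.3]),
                "projected_area_nm2": 1.0,
                "group": rng.choice(["m0", "m1", "m2"], n),
            }
        )
        f = morphology_fractions(SnapshotEnsemble(records=df), group_key="group")
        for m in ("flat", "dome", "pit"):
            per_group = [
                100.0 * (sub["morphology"] == m).mean() for _, sub in df.groupby("group")
            ]
            assert f.group_mean[m] == pytest.approx(np.mean(per_group), rel=1e-12)
            assert f.group_sd[m] == pytest.approx(np.std(per_group, ddof=1), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            morphology_fractions(
                SnapshotEnsemble(records=pd.DataFrame(columns=["morphology", "projected_area_nm2"]))
            )


class TestCompareDistributions:
    def test_identical_samples_degenerate_convention(self):
        out = compare_distributions([1.0, 1.0, 1.0], [1.0, 1.0])
        assert out["t"] == 0.0 and out["p_value"] == 1.0

    def test_matches_hand_computed_welch(self):
        """Welch's statistic and p-value from the explicit formula with
        Welch-Satterthwaite degrees of freedom, to 1e-10."""
        rng = np.random.default_rng(7)
        a = rng.normal(10.0, 2.0, 40)
        b = rng.normal(11.0, 3.5, 55)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df_hand)
        out = compare_distributions(a, b)
        assert out["t"] == pytest.approx(t_hand, abs=1e-10)
        assert out["p_value"] == pytest.approx(p_hand, abs=1e-10)

    def test_percentile_whiskers_match_order_statistics(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(7, 0.5, 300)
        out = compare_distributions(a, a + 1.0)
        assert out["predicted"]["p10"] == pytest.approx(np.percentile(a, 10))
        assert out["predicted"]["p90"] == pytest.approx(np.percentile(a, 90))
        assert out["predicted"]["median"] == pytest.approx(np.median(a))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [1.0, 2.0])


class TestPredictStalledMorphology:
    def test_all_below_threshold_all_flat(self, rule):
        from coatkit import fit_flat_model
        from coatkit.growth import FlatGrowthParams
        from coatkit.tracks import IntensityTrack
        from coatkit.growth import constant_area_curve

        t = 3.0 * np.arange(40)
        p = FlatGrowthParams.from_plateau(100.0, 10.0, 6.0)
        y = np.asarray(constant_area_curve(p, t))
        tracks = [
            IntensityTrack(f"t{i}", t, y, clc=y.copy(), condition="shock", shock_onset=0.0)
            for i in range(5)
        ]
        fits = [fit_flat_model(tr, "ap2") for tr in tracks]
        frac, labels = predict_stalled_morphology(tracks, fits, rule, seed=0)
        assert frac.fractions["flat"] == 100.0
        assert (labels["morphology"] == "flat").all()

    def test_five_track_enumeration(self, rule):
        """Crossed tracks split dome:pit per rule; uncrossed count flat —
        checked against direct enumeration of the crossing outcomes."""
        from coatkit import fit_flat_model
        from coatkit.growth import FlatGrowthParams, constant_area_curve

        from coatkit.tracks import IntensityTrack, transition_time_threshold

        t = 3.0 * np.arange(40)
        p = FlatGrowthParams.from_plateau(100.0, 10.0, 6.0)
        y = np.asarray(constant_area_curve(p, t))
        tracks = []
        for i in range(5):
            clc = y.copy()
            if i < 2:  # two tracks acquire a sustained 10% excess late
                clc[30:] = y[30:] * 1.10
            tracks.append(
                IntensityTrack(f"t{i}", t, y, clc=clc, condition="shock", shock_onset=0.0)
            )
        fits = [fit_flat_model(tr, "ap2") for tr in tracks]
        crossings = [
            transition_time_threshold(tr, f, delta=0.05) for tr, f in zip(tracks, fits)
        ]
        assert sum(c is not None for c in crossings) == 2
        frac, labels = predict_stalled_morphology(tracks, fits, rule, seed=0)
        assert frac.fractions["flat"] == pytest.approx(60.0)
        assert set(labels.loc[labels["t_cross"].notna(), "morphology"]) <= {"dome", "pit"}


class TestPredictEvent:
    def test_constant_area_fit_projection_halves_to_sphere(self, noiseless_tracks, rule):
        from coatkit import fit_flat_model

        tracks, _ = noiseless_tracks
        fit = fit_flat_model(tracks[0], "clc")
        pred = predict_event(fit, rule, theta_max=np.pi)
        tl = pred.timeline
        s = fit.flat.a_max
        # just after the transition the silhouette equals the flat area;
        # at scission (full sphere) it is a quarter of the surface
        early = float(pred.projected_area(tl.t_transition + 1e-9))
        late = float(pred.projected_area(tl.t_scission))
        assert early == pytest.approx(s, rel=0.06)
        assert late == pytest.approx(s / 4.0, rel=1e-6)

    def test_two_phase_fit_projection_drops_at_transition(
        self, two_phase_tracks_noiseless, rule
    ):
        """Fixed-tip-radius bending keeps the surface continuous but the
        silhouette drops sharply at the flat-to-curved transition; within
        each phase the projected area is smooth and positive."""
        from coatkit import fit_two_phase_model

        tracks, _ = two_phase_tracks_noiseless
        fit = fit_two_phase_model(tracks[0], rule)
        pred = predict_event(fit, rule)
        tl = pred.timeline
        t_tr = tl.t_transition
        before = float(pred.projected_area(t_tr - 1e-6))
        after = float(pred.projected_area(t_tr + 1e-6))
        assert after < before  # bending shrinks the TEM footprint
        for lo, hi in ((tl.t_nucleation + 0.1, t_tr - 1e-6), (t_tr + 1e-6, tl.t_scission)):
            t = np.linspace(lo, hi, 300)
            area = pred.projected_area(t)
            assert np.all(area > 0)
            assert np.abs(np.diff(area)).max() / np.max(area) < 0.05
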