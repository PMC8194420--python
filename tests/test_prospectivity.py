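"""Predictive-cluster selection, binarization, and classifier scoring.

The confusion-matrix cells TP=15, FP=12, FN=2, TN=62 and the five metric
values (accuracy 84.6%, precision 55.56%, NPV 96.88%, sensitivity 88.24%,
specificity 83.78%) form the reference scoring example used throughout.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fossilscout.clustering import ClusterModel
from fossilscout.prospectivity import (
    ConfusionMatrix,
    ProspectivityError,
    binarize,
    classification_metrics,
    confusion_matrix,
    predictive_area_stats,
    select_predictive_cluster,
)
from fossilscout.raster_io import SiteCatalog, SiteRecord, SpectralScene, site_to_pixel


def make_model(labels: np.ndarray, k: int, centroids=None, bands=()) -> ClusterModel:
    if centroids is None:
        centroids = np.zeros((k, max(1, len(bands))))
    return ClusterModel(
        centroids=np.asarray(centroids, dtype=float),
        labels=labels,
        k=k,
        wcss=0.0,
        wcss_trace=(0.0,),
        n_iter=1,
        converged=True,
        seed_used=0,
        bands=tuple(bands),
    )


def make_scene(n_rows, n_cols, n_bands=1) -> SpectralScene:
    return SpectralScene(
        values=np.zeros((n_rows, n_cols, n_bands)),
        bands=tuple(f"b{i}" for i in range(n_bands)),
        origin_easting=0.0,
        origin_northing=n_rows * 30.0,
        pixel_size=30.0,
    )


def record(site_id, scene, row, col, category="vertebrate_invertebrate", verifiable=True):
    return SiteRecord(
        site_id=site_id,
        easting=scene.origin_easting + col * 30.0 + 15.0,
        northing=scene.origin_northing - row * 30.0 - 15.0,
        category=category,
        verifiable=verifiable,
    )


class TestSelectPredictiveCluster:
    def test_all_sites_in_one_cluster(self):
        scene = make_scene(4, 4)
        labels = np.full((4, 4), 2)
        labels[0, 0] = 1
        model = make_model(labels, k=2)
        catalog = SiteCatalog(
            tuple(record(f"S{i}", scene, 1 + i % 3, 2) for i in range(5))
        )
        chosen, tally = select_predictive_cluster(model, catalog, scene)
        assert chosen == 2
        assert tally == {1: 0, 2: 5}

    def test_majority_cluster_wins_15_of_17(self):
        scene = make_scene(6, 6)
        labels = np.ones((6, 6), dtype=int)
        labels[5, :] = 2
        labels[4, :] = 3
        model = make_model(labels, k=3)
        recs = [record(f"S{i}", scene, i % 4, i % 6) for i in range(15)]
        recs.append(record("S15", scene, 5, 0))
        recs.append(record("S16", scene, 4, 1))
        chosen, tally = select_predictive_cluster(model, SiteCatalog(tuple(recs)), scene)
        assert chosen == 1
        assert tally == {1: 15, 2: 1, 3: 1}

    def test_tie_breaks_to_higher_nir_centroid(self):
        scene = make_scene(2, 4, n_bands=2)
        labels = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
        centroids = np.array([[0.5, 0.24], [0.5, 0.31]])
        model = make_model(labels, k=2, centroids=centroids, bands=("red", "nir"))
        recs = [
            record("A", scene, 0, 0),
            record("B", scene, 0, 1),
            record("C", scene, 0, 2),
            record("D", scene, 1, 3),
        ]
        chosen, tally = select_predictive_cluster(model, SiteCatalog(tuple(recs)), scene)
        assert tally == {1: 2, 2: 2}
        assert chosen == 2  # NIR 0.31 > 0.24

    def test_no_in_scene_sites_errors(self):
        scene = make_scene(2, 2)
        model = make_model(np.ones((2, 2), dtype=int), k=1)
        catalog = SiteCatalog(
            (SiteRecord("far", 1e7, 1e7, "invertebrate"),)
        )
        with pytest.raises(ProspectivityError):
            select_predictive_cluster(model, catalog, scene)

    def test_non_verifiable_and_non_fossil_ignored_in_tally(self):
        scene = make_scene(3, 3)
        model = make_model(np.full((3, 3), 1), k=2)
        catalog = SiteCatalog(
            (
                record("na", scene, 0, 0, verifiable=False),
                record("neg", scene, 1, 1, category="non_locality"),
                record("ok", scene, 2, 2),
            )
        )
        _, tally = select_predictive_cluster(model, catalog, scene)
        assert tally == {1: 1, 2: 0}


class TestBinarize:
    def test_all_positive(self):
        model = make_model(np.ones((3, 3), dtype=int), k=1)
        pmap = binarize(model, 1)
        assert pmap.n_positive_pixels == pmap.n_total_pixels == 9

    def test_none_positive(self):
        model = make_model(np.full((3, 3), 2), k=2)
        pmap = binarize(model, 1)
        assert pmap.n_positive_pixels == 0

    def test_1795_of_40000(self):
        labels = np.full(40_000, 2)
        labels[:1795] = 1
        rng = np.random.default_rng(0)
        rng.shuffle(labels)
        model = make_model(labels.reshape(200, 200), k=2)
        pmap = binarize(model, 1)
        assert pmap.n_positive_pixels == 1795
        assert pmap.n_total_pixels == 40_000

    def test_bad_cluster_id(self):
        model = make_model(np.ones((2, 2), dtype=int), k=2)
        with pytest.raises(ProspectivityError):
            binarize(model, 3)


class TestConfusionMatrix:
    def test_reference_scoring_example(self):
        """15/17 fossil sites and 12/74 non-localities on positive pixels."""
        scene = make_scene(20, 20)
        labels = np.full((20, 20), 2)
        labels[:5, :] = 1  # rows 0-4 positive
        model = make_model(labels, k=2)
        pmap = binarize(model, 1)
        recs = []
        for i in range(17):
            row = i % 5 if i < 15 else 10 + i % 5
            recs.append(record(f"F{i}", scene, row, i % 20))
        for i in range(74):
            row = i % 5 if i < 12 else 10 + i % 8
            recs.append(record(f"N{i}", scene, row, (3 + i) % 20, category="non_locality"))
        cm, excluded = confusion_matrix(pmap, SiteCatalog(tuple(recs)), scene)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (15, 12, 2, 62)
        assert excluded == []

    def test_empty_positive_map(self):
        scene = make_scene(3, 3)
        model = make_model(np.full((3, 3), 2), k=2)
        pmap = binarize(model, 1)
        recs = (record("F", scene, 0, 0), record("N", scene, 1, 1, category="non_locality"))
        cm, _ = confusion_matrix(pmap, SiteCatalog(recs), scene)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 1, 1)

    def test_outside_and_na_records_excluded(self):
        scene = make_scene(3, 3)
        model = make_model(np.ones((3, 3), dtype=int), k=1)
        pmap = binarize(model, 1)
        recs = (
            record("in", scene, 0, 0),
            SiteRecord("out", 1e7, 1e7, "fossil_wood"),
            record("na", scene, 1, 1, verifiable=False),
        )
        cm, excluded = confusion_matrix(pmap, SiteCatalog(recs), scene)
        assert cm.n_scored == 1
        assert excluded == ["out"]

    def test_zero_scorable_errors(self):
        scene = make_scene(2, 2)
        model = make_model(np.ones((2, 2), dtype=int), k=1)
        pmap = binarize(model, 1)
        catalog = SiteCatalog((record("na", scene, 0, 0, verifiable=False),))
        with pytest.raises(ProspectivityError):
            confusion_matrix(pmap, catalog, scene)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_tally(self, seed):
        """Matrix equals a direct per-record loop on random planted data."""
        rng = np.random.default_rng(seed)
        scene = make_scene(10, 10)
        labels = rng.integers(1, 4, size=(10, 10))
        model = make_model(labels, k=3)
        pmap = binarize(model, 1)
        recs = []
        for i in range(rng.integers(2, 30)):
            cat = "vertebrate_invertebrate" if rng.random() < 0.5 else "non_locality"
            recs.append(
                record(f"S{i}", scene, rng.integers(10), rng.integers(10), category=cat)
            )
        catalog = SiteCatalog(tuple(recs))
        cm, _ = confusion_matrix(pmap, catalog, scene)
        tp = fp = fn = tn = 0
        for rec in recs:
            r, c = site_to_pixel(rec, scene)
            pos = labels[r, c] == 1
            if rec.fossil_bearing:
                tp += pos
                fn += not pos
            else:
                fp += pos
                tn += not pos
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        assert cm.tp + cm.fn == sum(r.fossil_bearing for r in recs)
        assert cm.fp + cm.tn == sum(not r.fossil_bearing for r in recs)


class TestClassificationMetrics:
    def test_reference_metric_values(self):
        report = classification_metrics(ConfusionMatrix(tp=15, fp=12, fn=2, tn=62))
        assert report.accuracy == pytest.approx(0.846, abs=5e-4)
        assert report.precision == pytest.approx(0.5556, abs=5e-5)
        assert report.npv == pytest.approx(0.9688, abs=5e-5)
        assert report.sensitivity == pytest.approx(0.8824, abs=5e-5)
        assert report.specificity == pytest.approx(0.8378, abs=5e-5)
        pct = report.as_percentages()
        assert pct["accuracy"] == 84.62
        assert pct["precision"] == 55.56
        assert pct["npv"] == 96.88
        assert pct["sensitivity"] == 88.24
        assert pct["specificity"] == 83.78

    def test_perfect_matrix(self):
        report = classification_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=7))
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_undefined_precision_when_no_positive_predictions(self):
        report = classification_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=4))
        assert np.isnan(report.precision)
        assert np.isfinite(report.accuracy)
        assert np.isfinite(report.specificity)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 40),
        fp=st.integers(0, 40),
        fn=st.integers(0, 40),
        tn=st.integers(0, 40),
    )
    def test_closed_forms(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        report = classification_metrics(ConfusionMatrix(tp, fp, fn, tn))
        if tp + fn:
            assert report.sensitivity == pytest.approx(tp / (tp + fn))
        else:
            assert np.isnan(report.sensitivity)
        if tn + fp:
            assert report.specificity == pytest.approx(tn / (tn + fp))
        else:
            assert np.isnan(report.specificity)
        assert report.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))


class TestAreaStats:
    def test_paper_scale_area(self):
        labels = np.full(40_000, 2)
        labels[:1795] = 1
        model = make_model(labels.reshape(200, 200), k=2)
        stats = predictive_area_stats(binarize(model, 1), 30.0)
        assert stats["fraction"] * 100 == pytest.approx(4.4875)
        assert round(stats["fraction"] * 100, 2) == 4.49
        assert stats["area_km2"] == pytest.approx(1.6155)

    def test_zero_positives(self):
        model = make_model(np.full((4, 4), 2), k=2)
        stats = predictive_area_stats(binarize(model, 1), 30.0)
        assert stats["fraction"] == 0.0
        assert stats["area_km2"] == 0.0

    def test_all_positives(self):
        model = make_model(np.ones((4, 4), dtype=int), k=1)
        stats = predictive_area_stats(binarize(model, 1), 30.0)
        assert stats["fraction"] == 1.0
        assert stats["area_km2"] == pytest.approx(16 * 900 / 1e6)
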