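"""Stimulus selection: clustering, labelling, pre-screen, group picks,
and session sampling."""

import numpy as np
import pytest

from feelpix.emotions import BASIC_EMOTIONS, EMOTIONS
from feelpix.stimulus_selection import (
    ClusterModel,
    EmotionClusterMap,
    RatingsTable,
    build_stimulus_set,
    cluster_images,
    label_clusters,
    prescreen,
    sample_session,
    select_for_emotion,
    select_neutral,
    valence_band,
)
from feelpix.synthetic_data import DEFAULT_CENTROIDS

from conftest import make_ratings_df


class TestClusterImages:
    def test_k_equals_n_gives_singletons(self):
        table = RatingsTable(make_ratings_df([
            {"valence_mean": 2.0, "arousal_mean": 7.0},
            {"valence_mean": 5.0, "arousal_mean": 3.0},
            {"valence_mean": 8.0, "arousal_mean": 7.0},
        ]))
        model = cluster_images(table, k=3, seed=0)
        assert len(set(model.assignment.values())) == 3
        points = table.valence_arousal()
        for img, cluster in model.assignment.items():
            row = table.image_ids.index(img)
            assert np.allclose(model.centroids[cluster], points[row])

    @pytest.mark.parametrize("seed", [0, 1, 17, 99])
    def test_recovers_well_separated_blobs_any_seed(self, seed):
        """Tight blobs at the macro centroids are recovered exactly; the
        oracle is brute-force nearest-generating-centroid assignment."""
        rng = np.random.default_rng(42)
        centroids = list(DEFAULT_CENTROIDS.values())
        rows, truth = [], []
        for g, (v, a) in enumerate(centroids):
            for _ in range(20):
                rows.append({
                    "valence_mean": float(np.clip(rng.normal(v, 0.2), 1, 9)),
                    "arousal_mean": float(np.clip(rng.normal(a, 0.2), 1, 9)),
                })
                truth.append(g)
        table = RatingsTable(make_ratings_df(rows))
        points = table.valence_arousal()
        oracle = np.argmin(
            np.linalg.norm(points[:, None, :] - np.array(centroids)[None], axis=2),
            axis=1,
        )
        assert (oracle == truth).all()  # blobs tight enough to be unambiguous
        model = cluster_images(table, k=3, seed=seed)
        fitted = np.array([model.assignment[i] for i in table.image_ids])
        # same partition up to cluster relabelling
        mapping = {}
        for f, o in zip(fitted, oracle):
            mapping.setdefault(f, o)
            assert mapping[f] == o

    def test_invalid_inputs(self):
        table = RatingsTable(make_ratings_df([{}, {}]))
        with pytest.raises(ValueError):
            cluster_images(table, k=0)
        with pytest.raises(ValueError, match="insufficient data"):
            cluster_images(table, k=3)
        with pytest.raises(ValueError, match="NaN"):
            RatingsTable(make_ratings_df([{"valence_mean": float("nan")}]))


class TestLabelClusters:
    def _model_for(self, table, assignment):
        ids = table.image_ids
        k = max(assignment) + 1
        return ClusterModel(k=k, assignment=dict(zip(ids, assignment)),
                            centroids=np.zeros((k, 2)))

    def test_majority_membership(self):
        table = RatingsTable(make_ratings_df(
            [{"valence_mean": v} for v in (2.0, 3.5, 4.5)]))
        model = label_clusters(self._model_for(table, [0, 0, 0]), table)
        assert model.labels == {0: "negative"}

    def test_unanimous_band(self):
        table = RatingsTable(make_ratings_df(
            [{"valence_mean": 5.0}, {"valence_mean": 5.0}]))
        model = label_clusters(self._model_for(table, [0, 0]), table)
        assert model.labels == {0: "neutral"}

    def test_tie_broken_by_mean_valence_band(self):
        table = RatingsTable(make_ratings_df(
            [{"valence_mean": 3.9}, {"valence_mean": 4.1}]))
        model = label_clusters(self._model_for(table, [0, 0]), table)
        assert model.labels == {0: "neutral"}  # mean 4.0 falls in [4, 6)

    def test_empty_cluster_errors(self):
        table = RatingsTable(make_ratings_df([{"valence_mean": 3.0}]))
        model = ClusterModel(k=2, assignment={table.image_ids[0]: 0},
                             centroids=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            label_clusters(model, table)

    def test_band_boundaries_are_half_open(self):
        assert valence_band(3.999) == "negative"
        assert valence_band(4.0) == "neutral"
        assert valence_band(6.0) == "positive"


class TestPrescreen:
    def test_strictly_greater_removed(self):
        table = RatingsTable(make_ratings_df([
            {"int_disgust": 4.5}, {"int_disgust": 4.0}, {"int_disgust": 1.0},
        ]))
        out = prescreen(table)
        assert len(out) == 2
        assert (out.df["int_disgust"] <= 4.0).all()

    def test_empty_table_passes_through(self):
        table = RatingsTable(make_ratings_df([{"int_disgust": 5.0}]))
        once = prescreen(table)
        assert len(once) == 0
        assert len(prescreen(once)) == 0

    def test_idempotent(self, ratings_table):
        once = prescreen(ratings_table)
        twice = prescreen(once)
        assert once.image_ids == twice.image_ids


class TestSelectForEmotion:
    def _setup(self, rows, labels_emotion="fear"):
        table = RatingsTable(make_ratings_df(rows))
        model = ClusterModel(
            k=1, assignment={i: 0 for i in table.image_ids},
            centroids=np.zeros((1, 2)), labels={0: "negative"})
        return table, model

    def test_descending_intensity_ties_by_id(self):
        rows = [
            {"image_id": "a", "labels": {"fear"}, "int_fear": 5.1},
            {"image_id": "b", "labels": {"fear"}, "int_fear": 6.2},
            {"image_id": "c", "labels": {"fear"}, "int_fear": 3.3},
            {"image_id": "d", "labels": {"fear"}, "int_fear": 6.2},
        ]
        table, model = self._setup(rows)
        assert select_for_emotion(table, "fear", model, n=2) == ["b", "d"]

    def test_n_zero_returns_empty(self):
        table, model = self._setup([{"labels": {"fear"}, "int_fear": 5.0}])
        assert select_for_emotion(table, "fear", model, n=0) == []

    def test_exact_candidate_count_returns_all(self):
        rows = [{"image_id": f"x{i}", "labels": {"fear"}, "int_fear": 2.0 + i * 0.1}
                for i in range(10)]
        table, model = self._setup(rows)
        picked = select_for_emotion(table, "fear", model, n=10)
        assert sorted(picked) == sorted(table.image_ids)

    def test_insufficient_candidates_names_emotion(self):
        table, model = self._setup([{"labels": {"fear"}, "int_fear": 5.0}])
        with pytest.raises(ValueError, match="fear"):
            select_for_emotion(table, "fear", model, n=2)

    def test_requires_discrete_label_and_intensities_non_increasing(self, ratings_table):
        screened = prescreen(ratings_table)
        model = label_clusters(cluster_images(screened, k=3, seed=0), screened)
        for emotion in BASIC_EMOTIONS:
            picked = select_for_emotion(screened, emotion, model, n=10)
            rows = screened.df.set_index("image_id").loc[picked]
            assert all(emotion in labels for labels in rows["labels"])
            intensities = rows[f"int_{emotion}"].to_numpy()
            assert (np.diff(intensities) <= 1e-12).all()


class TestSelectNeutral:
    def _setup(self, rows):
        table = RatingsTable(make_ratings_df(rows))
        model = ClusterModel(
            k=1, assignment={i: 0 for i in table.image_ids},
            centroids=np.zeros((1, 2)), labels={0: "neutral"})
        return table, model

    def test_ascending_arousal(self):
        all_six = set(BASIC_EMOTIONS)
        rows = [
            {"image_id": "p", "labels": all_six, "arousal_mean": 2.1},
            {"image_id": "q", "labels": all_six, "arousal_mean": 1.8},
            {"image_id": "r", "labels": all_six, "arousal_mean": 3.0},
        ]
        table, model = self._setup(rows)
        assert select_neutral(table, model, n=2) == ["q", "p"]

    def test_requires_all_six_labels(self):
        rows = [
            {"image_id": "full", "labels": set(BASIC_EMOTIONS), "arousal_mean": 2.0},
            {"image_id": "nosad", "labels": set(BASIC_EMOTIONS) - {"sad"},
             "arousal_mean": 1.0},
        ]
        table, model = self._setup(rows)
        assert select_neutral(table, model, n=1) == ["full"]
        with pytest.raises(ValueError, match="neutral"):
            select_neutral(table, model, n=2)

    def test_n_zero(self):
        table, model = self._setup([{"labels": set(BASIC_EMOTIONS)}])
        assert select_neutral(table, model, n=0) == []


class TestBuildStimulusSet:
    def test_seventy_unique_ids_from_generator_table(self, ratings_table):
        stimulus_set = build_stimulus_set(ratings_table, seed=3)
        ids = stimulus_set.all_ids
        assert len(ids) == 70
        assert len(set(ids)) == 70
        assert set(stimulus_set.groups) == set(EMOTIONS)
        assert all(len(g) == 10 for g in stimulus_set.groups.values())
        assert set(ids) <= set(ratings_table.image_ids)

    def test_scales_to_one_per_group(self, ratings_table):
        stimulus_set = build_stimulus_set(ratings_table, seed=3, n_per_group=1)
        assert len(set(stimulus_set.all_ids)) == 7

    def test_prescreen_can_starve_disgust(self):
        """If every disgust-labelled image is too disgusting, the disgust
        group cannot be filled and the error names the emotion."""
        rng = np.random.default_rng(0)
        rows = []
        for v, a, labels, inten in [
            (2.7, 6.9, {"anger"}, "int_anger"),
            (2.7, 6.9, {"fear"}, "int_fear"),
            (2.7, 6.9, {"sad"}, "int_sad"),
            (8.0, 6.9, {"happy"}, "int_happy"),
            (6.6, 7.7, {"surprise"}, "int_surprise"),
        ]:
            for _ in range(12):
                rows.append({
                    "valence_mean": v + rng.normal(0, 0.1),
                    "arousal_mean": a + rng.normal(0, 0.1),
                    "labels": labels, inten: 6.0,
                })
        for _ in range(12):  # neutral-eligible
            rows.append({"valence_mean": 5.0 + rng.normal(0, 0.1),
                         "arousal_mean": 2.5 + rng.normal(0, 0.1),
                         "labels": set(BASIC_EMOTIONS)})
        for _ in range(12):  # all disgust candidates fail the pre-screen
            rows.append({"valence_mean": 2.7 + rng.normal(0, 0.1),
                         "arousal_mean": 6.9 + rng.normal(0, 0.1),
                         "labels": {"disgust"}, "int_disgust": 5.5})
        table = RatingsTable(make_ratings_df(rows))
        with pytest.raises(ValueError, match="disgust"):
            build_stimulus_set(table, seed=0)


class TestSampleSession:
    def test_one_per_emotion_is_always_valid(self, ratings_table):
        stimulus_set = build_stimulus_set(ratings_table, seed=3)
        session = sample_session(stimulus_set, per_emotion=1, seed=0)
        assert len(session.items) == 7
        assert len({e for _, e in session.items}) == 7

    def test_session_invariants_over_many_seeds(self, ratings_table):
        stimulus_set = build_stimulus_set(ratings_table, seed=3)
        for seed in range(100):
            session = sample_session(stimulus_set, per_emotion=5, seed=seed)
            assert len(session.items) == 35
            counts = {}
            for image_id, emotion in session.items:
                counts[emotion] = counts.get(emotion, 0) + 1
                assert image_id in stimulus_set.groups[emotion]
            assert all(counts[e] == 5 for e in EMOTIONS)
            adjacent = sum(a == b for (_, a), (_, b)
                           in zip(session.items, session.items[1:]))
            assert adjacent == 0

    def test_sessions_vary_with_seed(self, ratings_table):
        stimulus_set = build_stimulus_set(ratings_table, seed=3)
        a = sample_session(stimulus_set, seed=0)
        b = sample_session(stimulus_set, seed=1)
        assert a.items != b.items
        assert a.items == sample_session(stimulus_set, seed=0).items

    def test_single_group_is_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            sample_session({"happy": ["a", "b", "c"]}, per_emotion=2, seed=0)


def test_ratings_csv_round_trip(tmp_path, ratings_table):
    path = tmp_path / "ratings.csv"
    ratings_table.to_csv(path)
    back = RatingsTable.from_csv(path)
    assert back.image_ids == ratings_table.image_ids
    assert np.allclose(back.valence_arousal(), ratings_table.valence_arousal())
    assert list(back.df["labels"]) == list(ratings_table.df["labels"])


def test_cluster_map_requires_full_coverage():
    with pytest.raises(ValueError, match="surprise"):
        EmotionClusterMap(targets={e: frozenset({"negative"})
                                   for e in EMOTIONS if e != "surprise"})
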