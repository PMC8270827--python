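"""The three predictors: cutoff geometry, kNN vote, decision maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stonect import (
    CutoffConfig,
    KnnConfig,
    StoneLabel,
    TrainingSet,
    ValidationError,
    classify_cutoff,
    classify_knn,
    classify_maxhu,
    decision_map,
    knn_ua_fraction,
)


@pytest.mark.parametrize(
    "max_hu, pp_lapl, expected",
    [
        (693.0, 98.0, StoneLabel.UA),  # published UA worked example
        (1398.0, 182.0, StoneLabel.NON_UA),  # published non-UA worked example
        (999.0, 195.0, StoneLabel.NON_UA),  # on the ppLapl line -> non-UA
        (1000.0, 0.0, StoneLabel.NON_UA),  # on the maxHU line -> non-UA
        (999.0, 194.9, StoneLabel.UA),
    ],
)
def test_cutoff_rule(max_hu, pp_lapl, expected):
    assert classify_cutoff((max_hu, pp_lapl)) is expected


@pytest.mark.parametrize(
    "max_hu, expected",
    [(693.0, StoneLabel.UA), (745.0, StoneLabel.NON_UA), (1398.0, StoneLabel.NON_UA),
     (744.9, StoneLabel.UA)],
)
def test_maxhu_rule(max_hu, expected):
    assert classify_maxhu(max_hu) is expected


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    mh=st.floats(0, 2000), pl=st.floats(0, 600),
    dmh=st.floats(0, 500), dpl=st.floats(0, 200),
)
def test_cutoff_monotone(mh, pl, dmh, dpl):
    """Raising either feature can never flip a non-UA call back to UA."""
    if classify_cutoff((mh, pl)) is StoneLabel.NON_UA:
        assert classify_cutoff((mh + dmh, pl + dpl)) is StoneLabel.NON_UA


def test_maxhu_ua_implies_cutoff_ua_below_pplapl_line():
    """With printed defaults (745 < 1000), a maxHU-UA stone with ppLapl < 195
    is also cutoff-UA."""
    for mh in (200.0, 500.0, 744.9):
        for pl in (0.0, 100.0, 194.9):
            if classify_maxhu(mh) is StoneLabel.UA:
                assert classify_cutoff((mh, pl)) is StoneLabel.UA


def test_invalid_configs_rejected():
    with pytest.raises(ValidationError):
        CutoffConfig(pp_lapl_cut=0.0)
    with pytest.raises(ValidationError):
        KnnConfig(k=4)
    with pytest.raises(ValidationError):
        KnnConfig(k=-3)


# ------------------------------------------------------------------- kNN
def knn_oracle(mh, pl, train: TrainingSet, k: int) -> StoneLabel:
    """Sort all distances (insertion order breaks ties), vote among first k."""
    d2 = [
        ((train.max_hu[i] - mh) ** 2 + (train.pp_lapl[i] - pl) ** 2, i)
        for i in range(len(train))
    ]
    d2.sort()
    votes = [train.labels[i] for _, i in d2[:k]]
    n_ua = sum(v is StoneLabel.UA for v in votes)
    return StoneLabel.UA if n_ua > k / 2 else StoneLabel.NON_UA


def test_unanimous_training_set_rejected_but_vote_is_trivial():
    """A one-class training set violates the contract; with a single opposite
    point far away, any nearby query follows the dominant class."""
    with pytest.raises(ValidationError):
        TrainingSet(max_hu=np.full(9, 500.0), pp_lapl=np.full(9, 100.0),
                    labels=[StoneLabel.UA] * 9)
    train = TrainingSet(
        max_hu=np.r_[np.full(9, 500.0), 1e6],
        pp_lapl=np.r_[np.full(9, 100.0), 1e6],
        labels=[StoneLabel.UA] * 9 + [StoneLabel.NON_UA],
    )
    assert classify_knn((450.0, 90.0), train) is StoneLabel.UA


def test_knn_matches_full_sort_oracle(cutoff_labeled_train, rng):
    for _ in range(200):
        mh, pl = rng.uniform(0, 2000), rng.uniform(0, 600)
        assert classify_knn((mh, pl), cutoff_labeled_train) is knn_oracle(
            mh, pl, cutoff_labeled_train, 9
        )


def test_knn_matches_sklearn_without_ties(cutoff_labeled_train, rng):
    """Independent cross-check against an off-the-shelf kNN on tie-free data."""
    from sklearn.neighbors import KNeighborsClassifier

    X = np.column_stack([cutoff_labeled_train.max_hu, cutoff_labeled_train.pp_lapl])
    y = np.array([l.value for l in cutoff_labeled_train.labels])
    ref = KNeighborsClassifier(n_neighbors=9).fit(X, y)
    queries = np.column_stack([rng.uniform(0, 2000, 100), rng.uniform(0, 600, 100)])
    mine = [classify_knn(tuple(q), cutoff_labeled_train).value for q in queries]
    assert mine == list(ref.predict(queries))


def test_knn_k1_returns_label_of_identical_training_point(cutoff_labeled_train):
    i = 17
    q = (cutoff_labeled_train.max_hu[i], cutoff_labeled_train.pp_lapl[i])
    assert classify_knn(q, cutoff_labeled_train, KnnConfig(k=1)) is cutoff_labeled_train.labels[i]


def test_knn_deep_inside_ua_rectangle(cutoff_labeled_train):
    assert classify_knn((400.0, 80.0), cutoff_labeled_train) is StoneLabel.UA
    assert knn_ua_fraction((400.0, 80.0), cutoff_labeled_train) == 1.0


def test_knn_distance_tie_broken_by_insertion_order():
    # query equidistant from two opposite-label points at the k-th rank
    train = TrainingSet(
        max_hu=[0.0, 0.0, 10.0, -10.0],
        pp_lapl=[1.0, -1.0, 0.0, 0.0],
        labels=[StoneLabel.UA, StoneLabel.NON_UA, StoneLabel.UA, StoneLabel.NON_UA],
    )
    # k=3: the two distance-1 points enter; of the distance-10 tie the
    # earlier-inserted (index 2, UA) wins -> vote 2 UA vs 1 non-UA.
    assert classify_knn((0.0, 0.0), train, KnnConfig(k=3)) is StoneLabel.UA


def test_knn_requires_enough_training_points(cutoff_labeled_train):
    with pytest.raises(ValidationError):
        classify_knn((500.0, 100.0), cutoff_labeled_train, KnnConfig(k=201))


def test_knn_standardized_distances_still_vote_sensibly(cutoff_labeled_train):
    cfg = KnnConfig(k=9, standardize=True)
    assert classify_knn((400.0, 80.0), cutoff_labeled_train, cfg) is StoneLabel.UA
    assert classify_knn((1600.0, 400.0), cutoff_labeled_train, cfg) is StoneLabel.NON_UA


# --------------------------------------------------------------- decision map
def test_cutoff_decision_map_is_exact_rectangle():
    mh = np.arange(0, 2001, 100, dtype=float)
    pl = np.arange(0, 601, 50, dtype=float)
    grid = decision_map(classify_cutoff, mh, pl)
    for i, x in enumerate(mh):
        for j, y in enumerate(pl):
            expect = StoneLabel.UA if (x < 1000 and y < 195) else StoneLabel.NON_UA
            assert grid[i, j] is expect


def test_single_point_grid_equals_direct_call():
    grid = decision_map(classify_cutoff, [693.0], [98.0])
    assert grid.shape == (1, 1) and grid[0, 0] is classify_cutoff((693.0, 98.0))


def test_knn_map_agrees_with_cutoff_away_from_lines(cutoff_labeled_train):
    """On a cutoff-labelled surrogate set, kNN recovers the rectangle except
    near the cutoff lines."""
    mh = np.arange(50, 2000, 75, dtype=float)
    pl = np.arange(10, 590, 25, dtype=float)
    far_mh = np.abs(mh - 1000) >= 50
    far_pl = np.abs(pl - 195) >= 50
    grid = decision_map(
        lambda p: classify_knn(p, cutoff_labeled_train), mh, pl
    )
    agree = total = 0
    for i, x in enumerate(mh):
        for j, y in enumerate(pl):
            if not (far_mh[i] and far_pl[j]):
                continue
            total += 1
            agree += grid[i, j] is classify_cutoff((x, y))
    assert total > 100
    assert agree / total >= 0.95


def test_empty_grid_rejected():
    with pytest.raises(ValidationError):
        decision_map(classify_cutoff, [], [1.0])


# --------------------------------------------------------------- training set
def test_training_set_csv_round_trip(tmp_path, cutoff_labeled_train):
    path = tmp_path / "train.csv"
    cutoff_labeled_train.to_csv(path)
    back = TrainingSet.from_csv(path)
    assert np.allclose(back.max_hu, cutoff_labeled_train.max_hu)
    assert np.allclose(back.pp_lapl, cutoff_labeled_train.pp_lapl)
    assert list(back.labels) == list(cutoff_labeled_train.labels)


def test_training_set_rejects_mixed_labels():
    with pytest.raises(ValidationError):
        TrainingSet(max_hu=[1.0, 2.0], pp_lapl=[1.0, 2.0],
                    labels=[StoneLabel.UA, StoneLabel.MIXED])
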