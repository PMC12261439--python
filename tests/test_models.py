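"""Labeling, chromosome split, forest training and per-cell scoring."""

import numpy as np
import pandas as pd
import pytest

from beaver import (
    FragmentIndex,
    ModelBundle,
    SearchParams,
    cell_feature_matrix,
    filter_general,
    general_feature_matrix,
    label_general,
    label_specific,
    score_cells,
    search_all,
    split_by_chromosome,
    train_general,
    train_specific,
)
from beaver.features import GENERAL_NAMES
from beaver.fragment_graph import build_graph, connected_components



def _candidates(assemblies):
    index = FragmentIndex(assemblies)
    comps = connected_components(build_graph(assemblies))
    return search_all(comps, SearchParams(), index), index


class TestLabeling:
    def test_general_union_semantics(self, small_fixture):
        cands, _ = _candidates(small_fixture.assemblies)
        union = set().union(*small_fixture.per_cell_truth.values())
        labels = label_general(cands, union)
        assert set(labels) <= {0, 1}
        for path, lab in zip(cands, labels):
            assert lab == (1 if path.chain in union else 0)
        assert labels.sum() > 0  # planted chains are recoverable

    def test_empty_truth_warns_all_zero(self, small_fixture):
        cands, _ = _candidates(small_fixture.assemblies)
        with pytest.warns(UserWarning, match="empty ground truth"):
            labels = label_general(cands[:5], set())
        assert labels.sum() == 0

    def test_specific_per_cell_semantics(self, small_fixture):
        cands, index = _candidates(small_fixture.assemblies)
        pairs = [(p, c) for p in cands[:50] for c in index.cells]
        labels = label_specific(pairs, small_fixture.per_cell_truth)
        expected_positives = sum(
            1 for p, c in pairs
            if p.chain in small_fixture.per_cell_truth[c]
        )
        assert labels.sum() == expected_positives

    def test_unknown_cell_labeled_zero_with_warning(self, small_fixture):
        cands, _ = _candidates(small_fixture.assemblies)
        with pytest.warns(UserWarning, match="absent from truth"):
            labels = label_specific(
                [(cands[0], "no_such_cell")], small_fixture.per_cell_truth
            )
        assert labels.tolist() == [0]


class TestSplit:
    def test_partition_disjoint_exhaustive(self):
        chroms = ["3", "12", "chr5", "chr17", "1"]
        train, test = split_by_chromosome(chroms)
        assert (train & test).sum() == 0
        assert (train | test).all()
        assert train.tolist() == [True, False, True, False, True]

    def test_all_held_out_warns(self):
        with pytest.warns(UserWarning, match="no examples"):
            train, test = split_by_chromosome(["20", "21"])
        assert not train.any() and test.all()


def _toy_tables(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 30)) + y[:, None] * 3.0  # cleanly separable
    return pd.DataFrame(X, columns=GENERAL_NAMES), y


class TestForests:
    def test_separable_features_fit_perfectly(self):
        X, y = _toy_tables()
        model = train_general(X, y, seed=0)
        from sklearn.metrics import roc_auc_score
        probs = model.predict_proba(X.to_numpy())[:, 1]
        assert roc_auc_score(y, probs) == 1.0

    def test_identical_features_predict_class_prior(self):
        y = np.array([1] * 30 + [0] * 70)
        X = pd.DataFrame(np.zeros((100, 30)), columns=GENERAL_NAMES)
        model = train_general(X, y, seed=0)
        prob = model.predict_proba(np.zeros((1, 30)))[0, 1]
        assert prob == pytest.approx(0.3, abs=0.05)

    def test_same_seed_same_predictions(self):
        X, y = _toy_tables(seed=3)
        p1 = train_general(X, y, seed=9).predict_proba(X.to_numpy())
        p2 = train_general(X, y, seed=9).predict_proba(X.to_numpy())
        assert np.array_equal(p1, p2)

    def test_single_class_refused(self):
        X, _ = _toy_tables()
        with pytest.raises(ValueError, match="single class"):
            train_general(X, np.zeros(len(X), dtype=int), seed=0)

    def test_schema_mismatch_refused(self):
        X, y = _toy_tables()
        wrong = X.rename(columns={GENERAL_NAMES[0]: "mystery"})
        with pytest.raises(ValueError, match="schema"):
            train_general(wrong, y)
        with pytest.raises(ValueError, match="schema"):
            train_specific(X, y)


class TestFilterGeneral:
    def _paths(self, small_fixture):
        cands, _ = _candidates(small_fixture.assemblies)
        return cands[:3]

    def test_boundary_kept_at_threshold(self, small_fixture):
        paths = self._paths(small_fixture)
        kept, scores = filter_general(
            paths, np.array([0.1, 0.2, 0.9]), theta=0.2
        )
        assert [p.id for p in kept] == [paths[1].id, paths[2].id]
        assert scores.tolist() == [0.2, 0.9]

    def test_extreme_thresholds(self, small_fixture):
        paths = self._paths(small_fixture)
        scores = np.array([0.1, 0.2, 0.9])
        assert len(filter_general(paths, scores, theta=0.0)[0]) == 3
        assert len(filter_general(paths, scores, theta=1.0 + 1e-9)[0]) == 0

    def test_raising_theta_is_monotone(self, small_fixture):
        cands, _ = _candidates(small_fixture.assemblies)
        rng = np.random.default_rng(0)
        scores = rng.random(len(cands))
        prev = None
        for theta in (0.0, 0.2, 0.5, 0.8, 1.0):
            kept = {p.id for p in filter_general(cands, scores, theta)[0]}
            if prev is not None:
                assert kept <= prev
            prev = kept


@pytest.fixture(scope="module")
def trained(small_fixture):
    cands, index = _candidates(small_fixture.assemblies)
    pairs_X = cell_feature_matrix(cands, index)
    by_id = {p.id: p for p in cands}
    pairs = [(by_id[cid], cell) for cid, cell in pairs_X.index]
    labels = label_specific(pairs, small_fixture.per_cell_truth)
    model = train_specific(pairs_X, labels, seed=0)
    return cands, index, model, pairs_X, labels


class TestScoreCells:
    def test_pair_count_at_least_candidate_count(self, trained):
        cands, _index, _m, pairs_X, _labels = trained
        with_pairs = {cid for cid, _ in pairs_X.index}
        assert with_pairs == {p.id for p in cands}
        assert len(pairs_X) >= len(cands)

    def test_true_pairs_score_higher_on_held_out_chroms(self, trained):
        cands, _index, model, pairs_X, labels = trained
        by_id = {p.id: p for p in cands}
        held = np.array([
            by_id[cid].chrom not in {str(i) for i in range(1, 10)}
            for cid, _ in pairs_X.index
        ])
        probs = model.predict_proba(pairs_X.to_numpy())[:, 1]
        pos, neg = probs[held & (labels == 1)], probs[held & (labels == 0)]
        assert len(pos) and len(neg)
        assert pos.mean() > neg.mean()

    def test_tau_zero_emits_every_eligible_pair(self, trained):
        cands, index, model, pairs_X, _labels = trained
        scored, table = score_cells(cands, index, model, tau=0.0,
                                    pair_features=pairs_X)
        emitted = sum(len(a.transcripts) for a in scored.values())
        assert emitted == len(pairs_X) == len(table)

    def test_raising_tau_is_monotone_and_cell_specific(self, trained):
        cands, index, model, pairs_X, _labels = trained
        prev = None
        for tau in (0.0, 0.3, 0.6, 0.9):
            scored, _ = score_cells(cands, index, model, tau=tau,
                                    pair_features=pairs_X)
            sets = {
                cell: {(t.id, t.chrom) for t in a.transcripts}
                for cell, a in scored.items()
            }
            if prev is not None:
                assert all(sets[c] <= prev[c] for c in sets)
            prev = sets
        # per-cell outputs differ across cells at a mid threshold
        scored, _ = score_cells(cands, index, model, tau=0.5,
                                pair_features=pairs_X)
        distinct = {
            frozenset(t.id for t in a.transcripts)
            for a in scored.values()
        }
        assert len(distinct) > 1


def test_bundle_round_trip(tmp_path, small_fixture):
    cands, index = _candidates(small_fixture.assemblies)
    union = set().union(*small_fixture.per_cell_truth.values())
    X = general_feature_matrix(cands, index)
    y = label_general(cands, union)
    general = train_general(X, y, seed=1)
    pairs_X = cell_feature_matrix(cands, index)
    by_id = {p.id: p for p in cands}
    pairs = [(by_id[cid], cell) for cid, cell in pairs_X.index]
    specific = train_specific(
        pairs_X, label_specific(pairs, small_fixture.per_cell_truth), seed=1
    )
    bundle = ModelBundle(general=general, specific=specific, seed=1)
    bundle.save(tmp_path / "model.bundle")
    loaded = ModelBundle.load(tmp_path / "model.bundle")
    assert loaded.theta == bundle.theta
    assert np.array_equal(
        loaded.general.predict_proba(X.to_numpy()),
        general.predict_proba(X.to_numpy()),
    )
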