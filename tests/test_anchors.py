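"""Anchor selection: k-means response anchors and adaptive structure sets."""

import numpy as np
import pytest

from adaptor import (
    AnchorConfig,
    AnchorSets,
    early_stop_check,
    fit_adaptor,
    select_initial_structure_anchors,
    select_response_anchors,
)
from adaptor.anchors import AnchorConfigError, rank_by_absolute_error


class TestResponseAnchors:
    def test_kr_equals_n_selects_everything(self):
        ids = [f"m{i}" for i in range(10)]
        resp = np.arange(10, dtype=float)
        chosen = select_response_anchors(resp, ids, Kr=10, seed=0)
        assert sorted(chosen) == sorted(ids)

    def test_separated_clusters_pick_one_anchor_each(self):
        resp = np.array([0.0] * 5 + [10.0] * 5)
        ids = [f"m{i}" for i in range(10)]
        chosen = select_response_anchors(resp, ids, Kr=2, seed=0)
        values = sorted(resp[ids.index(c)] for c in chosen)
        assert values == [0.0, 10.0]

    def test_anchors_cover_the_response_range(self, rng):
        """k-means anchors spread across the observed response range."""
        resp = rng.uniform(4, 8, size=200)
        ids = [f"m{i}" for i in range(200)]
        chosen = select_response_anchors(resp, ids, Kr=10, seed=1)
        anchor_resp = np.array([resp[ids.index(c)] for c in chosen])
        covered = anchor_resp.max() - anchor_resp.min()
        assert covered >= 0.8 * (resp.max() - resp.min())

    def test_deterministic_given_seed(self, rng):
        resp = rng.normal(6, 1, size=50)
        ids = [f"m{i}" for i in range(50)]
        a = select_response_anchors(resp, ids, Kr=5, seed=3)
        b = select_response_anchors(resp, ids, Kr=5, seed=3)
        assert a == b

    def test_kr_larger_than_n_rejected(self):
        with pytest.raises(AnchorConfigError):
            select_response_anchors(np.arange(3.0), ["a", "b", "c"], Kr=4)


class TestStructureAnchors:
    def test_default_fraction_at_n500_gives_75(self):
        cfg = AnchorConfig()
        assert cfg.ka_for(500) == 75

    def test_full_fraction_returns_everything(self):
        ids = [f"m{i}" for i in range(20)]
        assert sorted(select_initial_structure_anchors(ids, 20, seed=0)) == sorted(ids)

    def test_same_seed_same_subset(self):
        ids = [f"m{i}" for i in range(100)]
        assert select_initial_structure_anchors(
            ids, 15, seed=9
        ) == select_initial_structure_anchors(ids, 15, seed=9)

    def test_oversized_request_rejected(self):
        with pytest.raises(AnchorConfigError):
            select_initial_structure_anchors(["a"], 2)

    def test_error_ranking_breaks_ties_by_id(self):
        ids = ["b", "a", "c"]
        errs = np.array([1.0, 1.0, 0.5])
        assert rank_by_absolute_error(ids, errs, 2) == ["a", "b"]


class TestEarlyStop:
    @pytest.mark.parametrize(
        "history,min_delta,patience,expected",
        [
            ((0.9, 0.7, 0.5), 0.01, 2, False),  # still improving
            ((0.7, 0.699, 0.6989), 0.01, 2, True),  # two stalls
            ((0.7,), 0.01, 2, False),  # insufficient evidence
            ((0.9, 0.7, 0.699), 0.01, 2, False),  # only one stall so far
        ],
    )
    def test_stall_detection(self, history, min_delta, patience, expected):
        assert early_stop_check(history, min_delta, patience) is expected

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            early_stop_check([])


class TestAdaptiveFit:
    def test_anchor_sets_nested_with_exact_arithmetic(self, synth300):
        """|S_p| = p*Ka and S_{p-1} ⊂ S_p for every step."""
        cfg = AnchorConfig(anchor_fraction=0.15, P=4, seed=0)
        model = fit_adaptor(synth300, cfg)
        ka = cfg.ka_for(300)
        sets = model.anchor_sets.structure_sets
        assert len(sets) == 4
        prev = set()
        for p, ids in enumerate(sets, start=1):
            assert len(ids) == p * ka
            assert prev <= set(ids)
            prev = set(ids)
        assert len(sets[-1]) == round(0.6 * 300)

    def test_new_anchors_disjoint_from_previous_set(self, synth300):
        model = fit_adaptor(synth300, AnchorConfig(P=3, seed=1))
        sets = model.anchor_sets.structure_sets
        for p in range(1, len(sets)):
            added = set(sets[p]) - set(sets[p - 1])
            assert added and added.isdisjoint(set(sets[p - 1]))

    def test_deterministic_given_seed(self, synth300):
        a = fit_adaptor(synth300, AnchorConfig(seed=5))
        b = fit_adaptor(synth300, AnchorConfig(seed=5))
        assert a.anchor_sets.structure_sets == b.anchor_sets.structure_sets
        assert np.array_equal(a.model.W, b.model.W)

    def test_single_step_equals_plain_random_anchor_fit(self, synth300):
        m1 = fit_adaptor(synth300, AnchorConfig(P=1, seed=2))
        m4 = fit_adaptor(synth300, AnchorConfig(P=4, seed=2))
        assert m1.anchor_sets.structure_sets[0] == m4.anchor_sets.structure_sets[0]
        assert np.array_equal(m1.model.W, m4.step_models[0].W)

    def test_second_model_fixes_first_model_failures(self, synth300):
        """Mean absolute error on the worst-predicted samples drops after
        they are added as anchors."""
        model = fit_adaptor(synth300, AnchorConfig(P=2, seed=3))
        s1, s2 = model.anchor_sets.structure_sets
        s_star = sorted(set(s2) - set(s1))
        sub = synth300.subset(s_star)
        err1 = np.abs(sub.responses - model.predict(sub, model=model.step_models[0]))
        err2 = np.abs(sub.responses - model.predict(sub, model=model.step_models[1]))
        assert err2.mean() < err1.mean()

    def test_infeasible_config_rejected_before_fitting(self, synth300):
        cfg = AnchorConfig(anchor_fraction=0.3, P=4)  # P*Ka = 1.2*N
        with pytest.raises(AnchorConfigError, match="exceeds"):
            fit_adaptor(synth300, cfg)

    def test_early_stopping_requires_validation_split(self, synth300):
        cfg = AnchorConfig(early_stopping=True, val_fraction=0.0, seed=0)
        with pytest.raises(AnchorConfigError, match="validation"):
            fit_adaptor(synth300, cfg)

    def test_early_stopping_can_shorten_the_run(self, synth300):
        """With an extreme min_delta every improvement counts as a stall,
        so the loop must stop after patience+1 steps."""
        cfg = AnchorConfig(
            anchor_fraction=0.1,
            P=6,
            early_stopping=True,
            min_delta=10.0,
            patience=2,
            seed=0,
        )
        model = fit_adaptor(synth300, cfg)
        assert len(model.step_models) == 3

    def test_model_archive_round_trip(self, synth300, tmp_path):
        from adaptor.model import AdapToRModel

        model = fit_adaptor(synth300, AnchorConfig(P=2, seed=4))
        path = tmp_path / "model.json"
        model.save(path)
        back = AdapToRModel.load(path)
        assert np.array_equal(back.model.W, model.model.W)
        assert back.anchor_sets.structure_sets == model.anchor_sets.structure_sets
        test = synth300.subset(synth300.ids[:20])
        assert np.allclose(back.predict(test), model.predict(test))


class TestAnchorSetsInvariants:
    def test_non_nested_sets_rejected(self):
        with pytest.raises(ValueError, match="contain"):
            AnchorSets(structure_sets=[["a", "b"], ["a", "c"]], response_ids=["a"])

    def test_duplicate_response_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AnchorSets(structure_sets=[["a"]], response_ids=["a", "a"])
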