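"""Label policy, annotation resolution, agreement, rounds and summaries."""

import numpy as np
import pytest

from lipal import campaign
from lipal.campaign import (
    AnnotationRecord,
    CampaignState,
    LabelingPolicy,
    SelectionConfig,
    agreement_rate,
    apply_label_policy,
    campaign_summary,
    resolve_annotations,
    run_round,
)
from lipal.model import EnsembleConfig


class TestLabelPolicy:
    @pytest.mark.parametrize("steps,expected", [(14, 1), (15, 0), (0, 1), (1, 1), (40, 0)])
    def test_strictly_fewer_than_k(self, steps, expected):
        assert apply_label_policy(steps, LabelingPolicy(k=15)) == expected

    def test_monotone_in_steps(self):
        labels = [apply_label_policy(s) for s in range(0, 40)]
        assert labels == sorted(labels, reverse=True)

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            apply_label_policy(-1)


def _ann(mol, annotator, label=None, steps=None, comment=""):
    return AnnotationRecord(
        molecule_id=mol, annotator_id=annotator, label=label, estimated_steps=steps,
        comment=comment,
    )


class TestResolveAnnotations:
    def test_single_annotator_stands(self):
        res = resolve_annotations([_ann("m1", "a", label=1)])
        assert res.final_labels == {"m1": 1} and not res.conflicts

    def test_majority_of_three_wins_and_is_flagged(self):
        res = resolve_annotations(
            [_ann("m1", "a", label=1), _ann("m1", "b", label=1), _ann("m1", "c", label=0)]
        )
        assert res.final_labels == {"m1": 1}
        assert "m1" in res.flagged and "m1" not in res.conflicts

    def test_two_way_tie_goes_to_conflict_list(self):
        res = resolve_annotations([_ann("m1", "a", label=1), _ann("m1", "b", label=0)])
        assert "m1" not in res.final_labels and res.conflicts == ["m1"]

    def test_skips_ignored(self):
        res = resolve_annotations([_ann("m1", "a"), _ann("m1", "b", label=0)])
        assert res.final_labels == {"m1": 0}

    def test_step_counts_resolve_through_policy(self):
        res = resolve_annotations([_ann("m1", "a", steps=12)], policy=LabelingPolicy(k=15))
        assert res.final_labels == {"m1": 1}

    def test_explicit_label_beats_conflicting_steps_and_flags(self):
        res = resolve_annotations([_ann("m1", "a", label=0, steps=3)])
        assert res.final_labels == {"m1": 0} and "m1" in res.flagged


class TestAgreementRate:
    def test_campaign_scale_worked_example(self):
        """23 double- plus 7 triple-annotated molecules with one disagreement."""
        records = []
        for i in range(23):
            records += [_ann(f"d{i}", "a", label=1), _ann(f"d{i}", "b", label=1)]
        for i in range(7):
            records += [
                _ann(f"t{i}", "a", label=0), _ann(f"t{i}", "b", label=0),
                _ann(f"t{i}", "c", label=0),
            ]
        records[1] = _ann("d0", "b", label=0)  # the single disagreement
        rep = agreement_rate(records)
        assert (rep.n_redundant, rep.n_disagreeing) == (30, 1)
        assert rep.percent_agreement == pytest.approx(96.7, abs=0.05)

    def test_all_identical_is_full_agreement(self):
        records = [_ann("m", "a", label=1), _ann("m", "b", label=1)]
        assert agreement_rate(records).percent_agreement == 100.0

    def test_all_disagreeing_is_zero(self):
        records = [
            _ann("m1", "a", label=1), _ann("m1", "b", label=0),
            _ann("m2", "a", label=0), _ann("m2", "b", label=1),
        ]
        assert agreement_rate(records).percent_agreement == 0.0

    def test_no_redundancy_reports_absent(self):
        assert agreement_rate([_ann("m", "a", label=1)]).percent_agreement is None


def _toy_state_and_features(n_pool=40, n_labeled=12, seed=0):
    rng = np.random.default_rng(seed)
    features, labeled, pool = {}, {}, {}
    for i in range(n_labeled + n_pool):
        x = rng.poisson(1.0, 24).astype(float)
        x[0] = rng.integers(0, 2) * 5
        features[f"m{i:03d}"] = x
        if i < n_labeled:
            labeled[f"m{i:03d}"] = int(x[0] > 2)
        else:
            pool[f"m{i:03d}"] = "comb" if i % 2 else "llm1"
    # ensure both classes in the seed set
    labeled["m000"], labeled["m001"] = 0, 1
    return CampaignState(labeled=labeled, pool=pool), features


class TestRunRound:
    def test_selection_is_disjoint_from_labeled(self):
        state, features = _toy_state_and_features()
        labeled_before = set(state.labeled)
        state, batch, selected = run_round(
            state, features,
            ensemble_config=EnsembleConfig(n_members=3, n_draws=12, n_iterations=30),
            selection=SelectionConfig(batch_size=10, seed=0),
            labeler=lambda mol: 1,
        )
        assert len(selected) == 10
        assert not set(selected) & labeled_before

    def test_tiny_pool_exhaustive_matches_brute_force(self):
        from lipal import acquisition as acq
        from lipal.model import EnsembleClassifier

        state, features = _toy_state_and_features(n_pool=8)
        cfg = EnsembleConfig(n_members=3, n_draws=12, n_iterations=30, base_seed=0)
        pool_ids = sorted(state.pool)
        labeled_ids = sorted(state.labeled)
        y = np.array([state.labeled[i] for i in labeled_ids])
        X_l = np.vstack([features[i] for i in labeled_ids])
        fitted = EnsembleClassifier(y, X_l, config=cfg).fit()
        matrix = acq.build_entropy_matrix(
            fitted.posterior_draws(np.vstack([features[i] for i in pool_ids]))
        )
        import itertools

        brute = max(
            itertools.combinations(range(8), 3),
            key=lambda c: acq.acquisition(matrix, acq.Batch(indices=c)),
        )
        _, batch, _ = run_round(
            state, features, ensemble_config=cfg,
            selection=SelectionConfig(batch_size=3, method="exhaustive"),
        )
        assert batch.indices == tuple(sorted(brute))

    def test_partial_labeling_recorded_in_history(self):
        state, features = _toy_state_and_features()
        answered = iter([1, 1, 0, None, 1, None, 0, 1, 1, None])
        state, _, selected = run_round(
            state, features,
            ensemble_config=EnsembleConfig(n_members=3, n_draws=12, n_iterations=30),
            selection=SelectionConfig(batch_size=10),
            labeler=lambda mol: next(answered),
        )
        row = state.history[-1]
        assert row.n_labeled == 7
        assert len(row.selected) - row.n_labeled == 3
        assert row.n_positive + row.n_negative == row.n_labeled

    def test_single_class_seed_set_rejected(self):
        state, features = _toy_state_and_features()
        for k in state.labeled:
            state.labeled[k] = 1
        with pytest.raises(ValueError, match="seed set"):
            run_round(state, features)

    def test_rounds_shrink_pool(self):
        state, features = _toy_state_and_features()
        cfg = EnsembleConfig(n_members=3, n_draws=12, n_iterations=30)
        for _ in range(3):
            before = len(state.pool)
            state, _, selected = run_round(
                state, features, ensemble_config=cfg,
                selection=SelectionConfig(batch_size=8),
                labeler=lambda mol: 0 if hash(mol) % 3 else 1,
            )
            assert len(state.pool) == before - len(selected)


class TestCampaignSummaryAndState:
    def _campaign_state(self):
        labeled = {f"i{i}": int(i < 76) for i in range(160)}  # 76 pos / 84 neg
        state = CampaignState(labeled=labeled, pool={})
        batches = [(20, 10, 18, 2, "comb"), (16, 14, 15, 1, "llm1"), (19, 11, 12, 7, "llm1"),
                   (20, 10, 13, 7, "llm2"), (22, 8, 21, 1, "llm2")]
        mol = 0
        for r, (lab, unlab, pos, neg, tag) in enumerate(batches, start=1):
            selected = []
            for j in range(lab + unlab):
                selected.append(f"al{mol}")
                if j < lab:
                    state.labeled[f"al{mol}"] = int(j < pos)
                mol += 1
            state.history.append(
                campaign.RoundRecord(
                    round=r, selected=selected, n_labeled=lab,
                    n_positive=pos, n_negative=neg, pool_tag=tag,
                )
            )
        return state

    def test_stage_totals_reproduce_campaign_shape(self):
        """160 initial (76/84) + 97 AL labels (79/18) -> 257 / 155 / 102."""
        tables = campaign_summary(self._campaign_state())
        total = tables["stages"].set_index("stage").loc["total data set"]
        assert (total["samples"], total["positive"], total["negative"]) == (257, 155, 102)
        al = tables["stages"].set_index("stage").loc["active learning part"]
        assert (al["samples"], al["positive"], al["negative"]) == (97, 79, 18)

    def test_batch_rows_sum_to_al_total(self):
        tables = campaign_summary(self._campaign_state())
        assert tables["batches"]["labeled"].tolist() == [20, 16, 19, 20, 22]
        assert tables["batches"]["labeled"].sum() == 97
        rows = tables["batches"]
        assert ((rows["positive"] + rows["negative"]) == rows["labeled"]).all()

    def test_empty_campaign_has_zero_rows(self):
        tables = campaign_summary(CampaignState())
        assert tables["stages"].empty and tables["batches"].empty

    def test_state_json_roundtrip(self, tmp_path):
        state = self._campaign_state()
        path = tmp_path / "state.json"
        state.to_json(path)
        back = CampaignState.from_json(path)
        assert back.labeled == state.labeled
        assert back.history[-1].pool_tag == state.history[-1].pool_tag

    def test_overlapping_state_rejected(self):
        with pytest.raises(ValueError):
            CampaignState(labeled={"m": 1}, pool={"m": "comb"})


class TestAnnotationCsv:
    def test_roundtrip(self, tmp_path):
        records = [
            _ann("m1", "a", label=1, steps=4, comment="easy ester"),
            _ann("m2", "b", label=0),
            _ann("m3", "c"),
        ]
        path = tmp_path / "ann.csv"
        campaign.write_annotations_csv(records, path)
        back = campaign.read_annotations_csv(path)
        assert [r.molecule_id for r in back] == ["m1", "m2", "m3"]
        assert back[0].label == 1 and back[0].estimated_steps == 4
        assert back[2].skipped
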