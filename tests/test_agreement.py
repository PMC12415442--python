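"""Kappa, simple agreement, majority vote and leave-one-out analysis."""

import numpy as np
import pandas as pd
import pytest

from luadgrade import (
    RaterPanel,
    cohen_kappa,
    consensus_summary,
    leave_one_out,
    majority_vote,
    pairwise_kappa,
    simple_agreement,
)
from luadgrade.patterns import SEVERITY_ORDER

from .oracles import oracle_kappa


def panel_from_columns(cols, ai=()):
    df = pd.DataFrame(cols)
    df.index = [f"item_{i}" for i in range(len(df))]
    return RaterPanel(ratings=df, ai_raters=frozenset(ai))


class TestCohenKappa:
    def test_perfect_agreement(self):
        v = ["lepidic", "acinar", "solid", "acinar"]
        assert cohen_kappa(v, v) == pytest.approx(1.0)
        assert cohen_kappa(v, v, weighting="equal") == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        # p_o = 0.75, p_e = 0.5 -> kappa 0.5
        a = ["acinar", "acinar", "solid", "solid"]
        b = ["acinar", "solid", "solid", "solid"]
        assert cohen_kappa(a, b) == pytest.approx(0.5)

    def test_chance_level_near_zero(self, rng):
        cats = list(SEVERITY_ORDER)
        a = rng.choice(cats, size=20_000)
        b = rng.choice(cats, size=20_000)
        assert cohen_kappa(a, b) == pytest.approx(0.0, abs=0.02)
        assert cohen_kappa(a, b, weighting="equal") == pytest.approx(0.0, abs=0.02)

    def test_single_shared_category_convention(self):
        assert cohen_kappa(["solid"] * 5, ["solid"] * 5) == 1.0

    def test_missing_pairs_dropped(self):
        a = ["acinar", None, "solid"]
        b = ["acinar", "solid", "solid"]
        assert simple_agreement(a, b) == 1.0
        assert cohen_kappa(a, b) == 1.0

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([None, "solid"], ["acinar", None])

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        cats = list(SEVERITY_ORDER)
        for _ in range(5):
            a = rng.choice(cats[:4], size=300)
            b = np.where(rng.random(300) < 0.6, a, rng.choice(cats, size=300))
            assert cohen_kappa(a, b) == pytest.approx(oracle_kappa(a, b))
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )
            assert cohen_kappa(a, b, weighting="equal") == pytest.approx(
                cohen_kappa_score(a, b, labels=cats, weights="linear"), abs=1e-12
            )

    def test_unweighted_invariant_under_relabelling(self, rng):
        cats = list(SEVERITY_ORDER)
        a = rng.choice(cats, size=500)
        b = np.where(rng.random(500) < 0.5, a, rng.choice(cats, size=500))
        perm = dict(zip(cats, rng.permutation(cats)))
        k1 = cohen_kappa(a, b)
        k2 = cohen_kappa([perm[x] for x in a], [perm[x] for x in b])
        assert k1 == pytest.approx(k2)

    def test_po_recovery_identity(self, rng):
        # simple agreement = kappa*(1-p_e) + p_e by construction
        cats = list(SEVERITY_ORDER)
        a = rng.choice(cats, size=400)
        b = np.where(rng.random(400) < 0.5, a, rng.choice(cats, size=400))
        k = len(cats)
        n = len(a)
        pa = np.bincount([cats.index(x) for x in a], minlength=k) / n
        pb = np.bincount([cats.index(x) for x in b], minlength=k) / n
        p_e = float(pa @ pb)
        assert simple_agreement(a, b) == pytest.approx(
            cohen_kappa(a, b) * (1 - p_e) + p_e
        )


class TestPairwiseKappa:
    def test_identical_raters(self):
        col = ["acinar", "solid", "lepidic", "acinar"]
        panel = panel_from_columns({"r1": col, "r2": col, "r3": col})
        mat, avg, _ = pairwise_kappa(panel)
        assert (mat.to_numpy() == 1.0).all()
        assert (avg == 1.0).all()

    def test_random_rater_near_zero(self, rng):
        cats = list(SEVERITY_ORDER)
        base = rng.choice(cats, size=5000)
        panel = panel_from_columns(
            {"r1": base, "r2": base, "r3": rng.choice(cats, size=5000)}
        )
        mat, avg, _ = pairwise_kappa(panel, weighting="none")
        assert avg["r3"] == pytest.approx(0.0, abs=0.03)
        assert mat.loc["r1", "r2"] == pytest.approx(1.0)
        # r1's average blends one perfect and one chance-level partner
        assert avg["r1"] == pytest.approx(0.5, abs=0.03)

    def test_all_missing_rater_excluded_with_warning(self):
        panel = panel_from_columns(
            {"r1": ["acinar", "solid"], "r2": ["acinar", "solid"], "r3": [None, None]}
        )
        with pytest.warns(UserWarning, match="r3"):
            mat, avg, _ = pairwise_kappa(panel)
        assert "r3" not in mat.columns

    def test_ai_excluded_average_uses_pathologist_partners_only(self):
        panel = panel_from_columns(
            {"p1": ["acinar", "solid", "lepidic"],
             "p2": ["acinar", "solid", "lepidic"],
             "ai": ["acinar", "solid", "acinar"]},
            ai=("ai",),
        )
        _, _, avg_vs_path = pairwise_kappa(panel, weighting="none")
        # p1's pathologist-only average excludes the ai column entirely
        assert avg_vs_path["p1"] == pytest.approx(1.0)


class TestMajorityVote:
    def test_unanimous_13(self):
        panel = panel_from_columns({f"r{i}": ["solid"] * 2 for i in range(13)})
        votes = majority_vote(panel)
        assert all(v.consensus and v.counts["solid"] == 13 for v in votes)

    def test_no_consensus_6_4_3(self):
        labels = ["acinar"] * 6 + ["papillary"] * 4 + ["solid"] * 3
        panel = panel_from_columns({f"r{i}": [labels[i]] for i in range(13)})
        (v,) = majority_vote(panel, consensus_min=7)
        assert not v.consensus
        assert v.mv1 == "acinar" and v.mv2 == "papillary"
        assert v.n_distinct == 3

    def test_consensus_at_exactly_7(self):
        labels = ["acinar"] * 7 + ["solid"] * 6
        panel = panel_from_columns({f"r{i}": [labels[i]] for i in range(13)})
        (v,) = majority_vote(panel, consensus_min=7)
        assert v.consensus and v.mv1 == "acinar" and v.mv2 == "solid"

    def test_modal_tie_flagged_severity_break(self):
        labels = ["acinar"] * 5 + ["solid"] * 5 + ["lepidic"] * 3
        panel = panel_from_columns({f"r{i}": [labels[i]] for i in range(13)})
        (v,) = majority_vote(panel)
        assert v.tie and not v.consensus and v.mv1 == "solid"

    def test_ai_votes_never_counted(self):
        cols = {f"p{i}": ["acinar"] for i in range(7)} | {"ai": ["solid"]}
        panel = panel_from_columns(cols, ai=("ai",))
        (v,) = majority_vote(panel)
        assert "solid" not in v.counts and v.counts["acinar"] == 7

    def test_counts_sum_to_nonmissing(self, rng):
        cats = list(SEVERITY_ORDER)
        data = {f"r{i}": rng.choice(cats + [None], size=50) for i in range(9)}
        panel = panel_from_columns(data)
        for v, (item, row) in zip(majority_vote(panel), panel.ratings.iterrows()):
            assert sum(v.counts.values()) == row.notna().sum()

    def test_consensus_monotone_in_min(self, rng):
        cats = list(SEVERITY_ORDER)
        data = {f"r{i}": rng.choice(cats, size=80) for i in range(13)}
        panel = panel_from_columns(data)
        cons = {
            m: {v.item for v in majority_vote(panel, consensus_min=m) if v.consensus}
            for m in (5, 7, 9, 11)
        }
        assert cons[11] <= cons[9] <= cons[7] <= cons[5]

    def test_consensus_summary_counts(self, rng):
        cats = list(SEVERITY_ORDER)
        data = {f"r{i}": rng.choice(cats, size=60) for i in range(13)}
        panel = panel_from_columns(data)
        votes = majority_vote(panel)
        s = consensus_summary(votes)
        assert s["n_items"] == 60
        assert s["n_consensus"] + s["n_no_consensus"] == 60
        assert s["n_consensus"] == sum(v.consensus for v in votes)


class TestLeaveOneOut:
    def test_identical_raters_give_one(self):
        col = ["acinar", "solid", "lepidic"] * 4
        panel = panel_from_columns({f"r{i}": col for i in range(5)})
        for r in panel.raters:
            res = leave_one_out(panel, r)
            assert res["kappa"] == pytest.approx(1.0)
            assert res["simple_agreement"] == 1.0

    def test_target_matching_majority_ignores_noise(self, rng):
        cats = list(SEVERITY_ORDER)
        truth = rng.choice(cats, size=200)
        cols = {f"r{i}": truth.copy() for i in range(6)}
        cols["noisy"] = rng.choice(cats, size=200)
        cols["target"] = truth.copy()
        panel = panel_from_columns(cols)
        res = leave_one_out(panel, "target")
        assert res["kappa"] == pytest.approx(1.0)

    def test_ai_excluded_by_default(self):
        col = ["acinar", "solid"] * 3
        panel = panel_from_columns(
            {"p1": col, "p2": col, "p3": col, "ai": ["solid"] * 6}, ai=("ai",)
        )
        res = leave_one_out(panel, "p1")
        assert res["kappa"] == pytest.approx(1.0)  # ai never joins the vote

    def test_target_in_exclusion_rejected(self):
        panel = panel_from_columns({"r1": ["acinar"], "r2": ["acinar"], "r3": ["acinar"]})
        with pytest.raises(ValueError):
            leave_one_out(panel, "r1", exclude=frozenset({"r1"}))
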