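"""Trait ingestion, dichotomization, screening and summary frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dentabc import trait_data as td
from dentabc.trait_data import TraitDefinition, TraitObservationMatrix


def _defs():
    return [
        TraitDefinition("A", "molar", "M1", ("M1", "M2"), breakpoint=2),
        TraitDefinition("B", "incisor", "I1", ("I1", "I2"), breakpoint=1),
    ]


class TestDichotomize:
    def test_breakpoint_rule_and_missingness(self):
        grades = pd.DataFrame(
            {"A:M1": [0, 2, 3, np.nan], "B:I1": [0, 1, np.nan, 4]},
            index=list("wxyz"),
        )
        out = td.dichotomize_scores(grades, _defs())
        # grade 0 with breakpoint 2 -> absent; >= breakpoint -> present
        assert out.loc["w", "A:M1"] == 0.0
        assert out.loc["x", "A:M1"] == 1.0
        # missing grades stay missing, never imputed
        assert np.isnan(out.loc["z", "A:M1"])
        assert np.isnan(out.loc["y", "B:I1"])

    def test_presence_counts_match_hand_tally(self):
        # 5 specimens, breakpoints {2, 1}: exhaustive manual tally
        grades = pd.DataFrame(
            {"A:M1": [0, 1, 2, 3, 5], "B:I1": [0, 0, 1, 1, np.nan]}
        )
        out = td.dichotomize_scores(grades, _defs())
        assert out["A:M1"].sum() == 3  # grades 2,3,5 >= 2
        assert out["B:I1"].sum() == 2  # grades 1,1 >= 1

    def test_rejects_unknown_trait_and_negative_grade(self):
        with pytest.raises(KeyError):
            td.dichotomize_scores(pd.DataFrame({"ZZ:M1": [1]}), _defs())
        with pytest.raises(ValueError):
            td.dichotomize_scores(pd.DataFrame({"A:M1": [-1]}), _defs())


class TestKeyToothReduction:
    def test_key_vs_modified_key(self):
        binary = pd.DataFrame(
            {
                "A:M1": [1.0, np.nan],
                "A:M2": [0.0, 1.0],
            }
        )
        key = td.reduce_to_key_teeth(binary, _defs()[:1], mode="key")
        mod = td.reduce_to_key_teeth(binary, _defs()[:1], mode="modified_key")
        # key tooth present -> its score used in both modes
        assert key.loc[0, "A"] == 1.0 and mod.loc[0, "A"] == 1.0
        # key tooth missing -> substitute only under modified_key
        assert np.isnan(key.loc[1, "A"])
        assert mod.loc[1, "A"] == 1.0

    def test_modified_key_strictly_increases_coverage(self, rng):
        defs = [
            TraitDefinition(f"T{i}", "molar", "M1", ("M1", "M2"), 1)
            for i in range(10)
        ]
        cols = {}
        for d in defs:
            key_missing = rng.random(200) < 0.3
            cols[f"{d.trait_id}:M1"] = np.where(key_missing, np.nan, 1.0)
            cols[f"{d.trait_id}:M2"] = np.ones(200)
        binary = pd.DataFrame(cols)
        key = td.reduce_to_key_teeth(binary, defs, mode="key")
        mod = td.reduce_to_key_teeth(binary, defs, mode="modified_key")
        assert (
            mod.notna().sum(axis=1).mean() > key.notna().sum(axis=1).mean()
        )

    def test_empty_substitute_order_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            TraitDefinition("A", "molar", "M1", (), 1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            td.reduce_to_key_teeth(pd.DataFrame({"A:M1": [1.0]}), _defs(), "x")


class TestTetrachoric:
    def test_independence_table_gives_zero(self):
        r, p = td.tetrachoric_2x2(np.array([[25, 25], [25, 25]]))
        assert abs(r) < 1e-3
        assert p > 0.9

    def test_perfect_association_near_plus_one(self):
        r, _ = td.tetrachoric_2x2(np.array([[30, 0], [0, 30]]))
        assert r > 0.9  # zero-cell corrected, near the +1 boundary

    def test_matches_grid_search_oracle(self):
        table = np.array([[40, 10], [10, 40]], float)
        r_hat, p = td.tetrachoric_2x2(table)
        # independent oracle: brute-force likelihood maximization on a grid
        n = table.sum()
        h = stats.norm.ppf(table[0].sum() / n)
        k = stats.norm.ppf(table[:, 0].sum() / n)
        grid = np.linspace(-0.99, 0.99, 397)
        best = None
        for r in grid:
            p00 = stats.multivariate_normal(
                mean=[0, 0], cov=[[1, r], [r, 1]]
            ).cdf([h, k])
            probs = np.clip(
                np.array(
                    [
                        [p00, stats.norm.cdf(h) - p00],
                        [stats.norm.cdf(k) - p00,
                         1 - stats.norm.cdf(h) - stats.norm.cdf(k) + p00],
                    ]
                ),
                1e-12,
                None,
            )
            ll = (table * np.log(probs)).sum()
            if best is None or ll > best[1]:
                best = (r, ll)
        assert abs(r_hat - best[0]) < 0.01
        assert p < 0.01  # clearly associated

    def test_matrix_shape_and_sparse_pair_flagging(self):
        scores = pd.DataFrame(
            {
                "A": [0, 1, 0, 1, 1, 0],
                "B": [0, 1, 1, 1, 0, 0],
                "C": [np.nan] * 5 + [1.0],  # <2 joint observations with others
            }
        )
        m = TraitObservationMatrix(
            scores,
            pd.DataFrame(
                {"country": ["Spain"] * 6, "latitude": 0.0, "longitude": 0.0,
                 "age_mean": 20.0},
                index=scores.index,
            ),
        )
        r, p = td.tetrachoric_matrix(m)
        assert (np.diag(r) == 1).all()
        assert r.loc["A", "B"] == r.loc["B", "A"]
        assert np.isnan(r.loc["A", "C"]) and np.isnan(p.loc["A", "C"])

    def test_false_positive_rate_on_independent_traits(self, rng):
        # independent traits: significant-pair fraction <= alpha + 3 SE
        n_traits, n_spec, alpha = 10, 250, 0.05
        scores = pd.DataFrame(
            rng.random((n_spec, n_traits)) < rng.uniform(0.3, 0.7, n_traits),
            columns=[f"T{i}" for i in range(n_traits)],
            dtype=float,
        )
        _, p = td.tetrachoric_matrix(scores)
        iu = np.triu_indices(n_traits, 1)
        pv = p.to_numpy()[iu]
        frac = np.mean(pv < alpha)
        n_pairs = len(pv)
        assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_pairs)


class TestBHFilter:
    def test_hand_worked_example(self):
        # 0.01 <= 0.0167, 0.02 <= 0.0333, 0.04 <= 0.05: all significant
        assert td.bh_filter([0.01, 0.02, 0.04], alpha=0.05) == [0, 1, 2]

    def test_all_ones_empty(self):
        assert td.bh_filter([1.0, 1.0, 1.0], alpha=0.05) == []

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            td.bh_filter([0.5], alpha=0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.001, 1.0), min_size=2, max_size=15),
        st.integers(0, 14),
    )
    def test_monotone_in_pvalues(self, pvals, idx):
        """Lowering any single p-value never shrinks the significant set."""
        idx = idx % len(pvals)
        before = set(td.bh_filter(pvals, 0.05))
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2
        after = set(td.bh_filter(lowered, 0.05))
        assert before <= after


class TestGroupAssignment:
    def test_period_and_region_examples(self, toy_matrix):
        labels = td.assign_groups(toy_matrix.metadata)
        assert labels.loc["S0", "period"] == "MPG"      # 30 ka
        assert labels.loc["S0", "region"] == "West"     # Spain
        assert labels.loc["S3", "region"] == "East"     # Italy
        assert labels.loc["S2", "period"] == "LPG"      # 20 ka
        assert labels.loc["S4", "period"] == "LG&EH"    # 10 ka

    def test_boundary_ties_go_to_older_period(self):
        meta = pd.DataFrame(
            {"country": ["Spain", "Spain"], "age_mean": [28.0, 14.7]},
            index=["a", "b"],
        )
        labels = td.assign_groups(meta)
        assert labels.loc["a", "period"] == "MPG"
        assert labels.loc["b", "period"] == "LPG"

    def test_out_of_window_excluded_with_warning(self):
        meta = pd.DataFrame(
            {"country": ["Spain", "Spain"], "age_mean": [60.0, 20.0]},
            index=["a", "b"],
        )
        with pytest.warns(UserWarning, match="study window"):
            labels = td.assign_groups(meta)
        assert list(labels.index) == ["b"]

    def test_unmapped_country_raises_naming_it(self):
        meta = pd.DataFrame({"country": ["Atlantis"], "age_mean": [20.0]},
                            index=["a"])
        with pytest.raises(KeyError, match="Atlantis"):
            td.assign_groups(meta)

    def test_longitude_fallback_only_when_enabled(self):
        meta = pd.DataFrame(
            {"country": [None], "age_mean": [20.0], "longitude": [5.0]},
            index=["a"],
        )
        with pytest.raises(KeyError):
            td.assign_groups(meta)
        labels = td.assign_groups(meta, longitude_fallback=True)
        assert labels.loc["a", "region"] == "West"


class TestSummarize:
    def test_polarity_orientation(self):
        scores = pd.DataFrame({"A": [1.0, 1.0, 1.0, 0.0]},
                              index=list("wxyz"))
        meta = pd.DataFrame(
            {"country": ["Spain"] * 4, "age_mean": [30.0] * 4},
            index=scores.index,
        )
        m = TraitObservationMatrix(scores, meta)
        labels = td.assign_groups(meta)
        # 3 of 4 present; ancestral=absence -> derived frequency 0.75
        g1 = td.summarize_frequencies(m, labels, {"A": "absence"})
        assert g1.table.loc[("A", "West", "MPG"), "freq_derived"] == 0.75
        # same cell, ancestral=presence -> complement
        g2 = td.summarize_frequencies(m, labels, {"A": "presence"})
        assert g2.table.loc[("A", "West", "MPG"), "freq_derived"] == 0.25

    def test_empty_cells_masked_and_absent_from_vector(self, toy_matrix):
        labels = td.assign_groups(toy_matrix.metadata)
        gft = td.summarize_frequencies(
            toy_matrix, labels, {"C6": "absence", "SHOV": "presence"}
        )
        layout = gft.layout()
        assert ("C6", ("West", "MPG")) in layout
        # no West LG&EH C6 observations in the fixture? S4..S6: S6 Germany 10ka C6=1
        mask = gft.mask()
        for cell in mask:
            assert cell not in layout
        assert len(gft.flat_vector()) == len(layout)

    def test_unset_polarity_rejected(self, toy_matrix):
        labels = td.assign_groups(toy_matrix.metadata)
        with pytest.raises(ValueError, match="polarity"):
            td.summarize_frequencies(toy_matrix, labels, {"C6": "absence"})

    def test_round_trip_matches_brute_force_tally(self, rng):
        # dichotomize -> reduce -> summarize equals an exhaustive tally
        defs = [TraitDefinition("A", "molar", "M1", ("M1", "M2"), 2,
                                polarity="absence")]
        n = 40
        grades = pd.DataFrame(
            {
                "A:M1": rng.choice([0, 1, 2, 3, np.nan], n),
                "A:M2": rng.choice([0, 1, 2, 3, np.nan], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {
                "country": rng.choice(["Spain", "Italy"], n),
                "age_mean": rng.choice([30.0, 20.0, 10.0], n),
            },
            index=grades.index,
        )
        binary = td.dichotomize_scores(grades, defs)
        reduced = td.reduce_to_key_teeth(binary, defs, mode="modified_key")
        keep = reduced.notna().any(axis=1)
        m = TraitObservationMatrix(reduced[keep], meta[keep])
        labels = td.assign_groups(m.metadata)
        gft = td.summarize_frequencies(m, labels, {"A": "absence"})
        # brute force: per specimen, first non-missing of M1, M2 >= 2
        for (trait, region, period), row in gft.table.iterrows():
            n_obs = n_pres = 0
            for sid in grades.index:
                g1, g2 = grades.loc[sid, "A:M1"], grades.loc[sid, "A:M2"]
                val = g1 if not np.isnan(g1) else g2
                if np.isnan(val):
                    continue
                reg = "West" if meta.loc[sid, "country"] == "Spain" else "East"
                per = {30.0: "MPG", 20.0: "LPG", 10.0: "LG&EH"}[
                    meta.loc[sid, "age_mean"]
                ]
                if (reg, per) == (region, period):
                    n_obs += 1
                    n_pres += val >= 2
            assert row["n_observed"] == n_obs
            assert row["n_present"] == n_pres

    def test_vector_invariant_under_specimen_permutation(self, toy_matrix, rng):
        labels = td.assign_groups(toy_matrix.metadata)
        pol = {"C6": "absence", "SHOV": "presence"}
        v1 = td.summarize_frequencies(toy_matrix, labels, pol).flat_vector()
        order = rng.permutation(toy_matrix.scores.index)
        shuffled = TraitObservationMatrix(
            toy_matrix.scores.loc[order], toy_matrix.metadata.loc[order]
        )
        labels2 = td.assign_groups(shuffled.metadata)
        v2 = td.summarize_frequencies(shuffled, labels2, pol).flat_vector()
        assert np.array_equal(v1, v2, equal_nan=True)
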