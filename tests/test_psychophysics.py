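"""Analysis pipeline: aggregation, correlation, ANOVA, binomial criterion
and preference maps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from presbysim.corrections import build_catalog, preference_subset, standard_profiles
from presbysim.observer import ObserverParams, default_cohort, run_experiment
from presbysim.psychophysics import (
    AnalysisError,
    PreferenceCell,
    anova_scores,
    bernoulli_tail,
    classify_preference,
    correlate_energy,
    preference_map,
    summarize_scores,
)


def _toy_catalog():
    return [c for c in build_catalog() if c.label in ("F+F", "F+N")]


def _toy_scores():
    rows = []
    data = {
        # (subject, correction, distance): (rep1, rep2)
        ("S1", "F+F", "far"): (4.0, 5.0),
        ("S2", "F+F", "far"): (3.0, 3.0),
        ("S1", "F+F", "near"): (1.0, 2.0),
        ("S2", "F+F", "near"): (0.0, 1.0),
        ("S1", "F+N", "far"): (5.0, 5.0),
        ("S2", "F+N", "far"): (4.0, 5.0),
        ("S1", "F+N", "near"): (4.0, 4.0),
        ("S2", "F+N", "near"): (5.0, 4.0),
    }
    for (s, c, d), reps in data.items():
        for i, score in enumerate(reps, start=1):
            rows.append(
                {"subject": s, "correction": c, "distance": d, "repetition": i, "score": score}
            )
    return pd.DataFrame(rows)


class TestSummarizeScores:
    def test_constant_table(self):
        table = _toy_scores().assign(score=3.0)
        summary = summarize_scores(table, _toy_catalog())
        cd = summary.by_correction_distance
        assert (cd["mean_score"] == 3.0).all()
        assert (cd["sd_repetitions"] == 0.0).all()
        assert (cd["sd_subjects"] == 0.0).all()

    def test_toy_table_against_hand_computation(self):
        """Frozen means/SDs computed independently by hand for the 2-subject
        toy table."""
        summary = summarize_scores(_toy_scores(), _toy_catalog())
        cd = summary.by_correction_distance.set_index(["correction", "distance"])
        assert cd.loc[("F+F", "far"), "mean_score"] == pytest.approx(3.75)
        assert cd.loc[("F+F", "far"), "sd_repetitions"] == pytest.approx(
            (math.sqrt(0.5) + 0.0) / 2
        )
        assert cd.loc[("F+F", "far"), "sd_subjects"] == pytest.approx(
            np.std([4.5, 3.0], ddof=1)
        )
        assert cd.loc[("F+N", "near"), "mean_score"] == pytest.approx(4.25)
        fam = summary.by_family.set_index("family")
        assert fam.loc["monofocal", "far_near_diff"] == pytest.approx(2.75)
        assert fam.loc["monofocal", "far_near_mean"] == pytest.approx(2.375)
        assert fam.loc["monovision", "far_near_diff"] == pytest.approx(0.5)
        assert fam.loc["monovision", "far_near_mean"] == pytest.approx(4.5)

    def test_noiseless_monofocal_imbalance(self):
        """A noiseless table with F+F far=5/near=0 contributes a 5.0 PS
        far-near difference to the monofocal family."""
        table = _toy_scores()
        table.loc[(table.correction == "F+F") & (table.distance == "far"), "score"] = 5.0
        table.loc[(table.correction == "F+F") & (table.distance == "near"), "score"] = 0.0
        fam = summarize_scores(table, _toy_catalog()).by_family.set_index("family")
        assert fam.loc["monofocal", "far_near_diff"] == pytest.approx(5.0)

    def test_missing_cells_reported(self):
        table = _toy_scores()
        table = table[~((table.correction == "F+N") & (table.distance == "near"))]
        with pytest.raises(AnalysisError, match="F\\+N/near"):
            summarize_scores(table, _toy_catalog())


class TestCorrelateEnergy:
    def test_linear_noiseless_observer_gives_r_one(self):
        """Scores exactly linear in energy: r = 1 to machine precision."""
        catalog = build_catalog()
        cohort = [
            ObserverParams(subject_id="T1", gain=5.0, bias=0.0,
                           score_noise_sd=0.0, choice_noise_sd=0.0, seed=2)
        ]
        scores, _ = run_experiment(
            cohort, catalog, None, None, quality_source="energy", energy_mode="mean"
        )
        r, p = correlate_energy(scores, catalog, mode="mean")
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_noisy_linear_observer_strong_correlation(self):
        """With 0.45 SD repetition noise over 8 x 17 x 3 points the energy
        correlation stays strong and highly significant."""
        catalog = build_catalog()
        scores, _ = run_experiment(
            default_cohort(8, base_seed=5), catalog, None, None,
            quality_source="energy", energy_mode="mean",
        )
        r, p = correlate_energy(scores, catalog, mode="mean")
        assert r > 0.5
        assert p < 1e-4

    def test_constant_scores_rejected(self):
        catalog = _toy_catalog()
        table = _toy_scores().assign(score=2.0)
        with pytest.raises(AnalysisError, match="zero variance"):
            correlate_energy(table, catalog)

    def test_agrees_with_direct_pearson(self, catalog, study_tables):
        """Cross-check against scipy.stats.pearsonr applied to the raw
        per-subject means."""
        from presbysim.corrections import binocular_energy, viewing_targets

        scores, _ = study_tables
        r, _ = correlate_energy(scores, catalog, mode="better_eye")
        targets = viewing_targets("nominal")
        sub = scores[scores.distance.isin(targets)]
        means = sub.groupby(["subject", "correction", "distance"])["score"].mean().reset_index()
        energies = {
            (c.label, t): binocular_energy(c, targets[t], mode="better_eye")
            for c in catalog for t in targets
        }
        x = [energies[(row.correction, row.distance)] for row in means.itertuples()]
        expected = stats.pearsonr(x, means["score"]).statistic
        assert r == pytest.approx(expected, abs=1e-12)


class TestAnova:
    def test_degrees_of_freedom_on_full_design(self, study_tables):
        scores, _ = study_tables
        table = anova_scores(scores)
        assert table.loc["subject", "df"] == 7
        assert table.loc["correction", "df"] == 16
        assert table.loc["distance", "df"] == 2

    def test_constant_scores_give_zero_F(self):
        table = _toy_scores().assign(score=1.0)
        out = anova_scores(table)
        assert (out.loc[["subject", "correction", "distance"], "F"] == 0.0).all()

    def test_toy_sums_of_squares_match_hand_formula(self):
        """Balanced 2 x 2 x 2 design: type-II main-effect SS equal the
        textbook between-level formulas computed directly."""
        rng = np.random.default_rng(12)
        rows = []
        for s, c, d in itertools.product(("S1", "S2"), ("F+F", "F+N"), ("far", "near")):
            rows.append({"subject": s, "correction": c, "distance": d,
                         "repetition": 1, "score": float(rng.integers(0, 6))})
        table = pd.DataFrame(rows)
        out = anova_scores(table)
        grand = table["score"].mean()
        for factor in ("subject", "correction", "distance"):
            ss_hand = sum(
                len(g) * (g["score"].mean() - grand) ** 2
                for _, g in table.groupby(factor)
            )
            assert out.loc[factor, "sum_sq"] == pytest.approx(ss_hand, abs=1e-9)

    def test_ss_decomposition(self, study_tables):
        """Total SS = factor SS + residual SS on the balanced design."""
        scores, _ = study_tables
        sub = scores[scores.distance.isin(("far", "intermediate", "near"))]
        out = anova_scores(scores)
        total = float(((sub["score"] - sub["score"].mean()) ** 2).sum())
        assert out["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_unbalanced_table_rejected(self):
        table = _toy_scores().iloc[:-1]
        with pytest.raises(AnalysisError, match="unbalanced"):
            anova_scores(table)


class TestBernoulliCriterion:
    @pytest.mark.parametrize(
        "positives, expected",
        [(6, 1 / 64), (5, 7 / 64), (0, 1.0)],
    )
    def test_exact_tails_n6(self, positives, expected):
        assert bernoulli_tail(positives, 6) == pytest.approx(expected, abs=0)

    @pytest.mark.parametrize("n", [1, 3, 6, 9, 12])
    def test_tail_matches_brute_force_enumeration(self, n):
        """Enumerate all 2^n equiprobable outcome sequences."""
        for k in range(n + 1):
            count = sum(
                1 for outcome in itertools.product((0, 1), repeat=n)
                if sum(outcome) >= k
            )
            assert bernoulli_tail(k, n) == count / 2**n

    def test_tail_matches_scipy_binomial(self):
        for n in (6, 48):
            for k in range(0, n + 1, max(1, n // 8)):
                assert bernoulli_tail(k, n) == pytest.approx(
                    stats.binom.sf(k - 1, n, 0.5), rel=1e-12
                )

    def test_invalid_counts_rejected(self):
        with pytest.raises(AnalysisError):
            bernoulli_tail(7, 6)
        with pytest.raises(AnalysisError):
            bernoulli_tail(-1, 6)

    @pytest.mark.parametrize(
        "positives, expected",
        [
            (6, "preferred"), (5, "preferred"), (4, "neutral"), (3, "neutral"),
            (2, "neutral"), (1, "rejected"), (0, "rejected"),
        ],
    )
    def test_count_rule_all_seven_counts(self, positives, expected):
        assert classify_preference(positives, 6) == expected

    @settings(derandomize=True, max_examples=60)
    @given(n=st.integers(1, 30))
    def test_classification_monotone_in_positives(self, n):
        order = {"rejected": 0, "neutral": 1, "preferred": 2}
        levels = [order[classify_preference(k, n)] for k in range(n + 1)]
        assert levels == sorted(levels)


class TestPreferenceMap:
    @staticmethod
    def _choices_from(picker, subjects=1, reps=6, seed=0):
        from presbysim.corrections import all_pairs

        rng = np.random.default_rng(seed)
        rows = []
        for s in range(subjects):
            for a, b in all_pairs():
                for rep in range(1, reps + 1):
                    rows.append(
                        {"subject": f"S{s + 1}", "correction_a": a, "correction_b": b,
                         "repetition": rep, "chosen": picker(a, b, rng)}
                    )
        return pd.DataFrame(rows)

    def test_deterministic_monovision_fan(self):
        """An observer that always picks F+N marks the F+N row preferred
        against every other correction."""
        table = self._choices_from(lambda a, b, rng: "F+N" if "F+N" in (a, b) else a)
        maps = preference_map(table)
        i = maps.labels.index("F+N")
        for j, label in enumerate(maps.labels):
            if label == "F+N":
                continue
            assert maps.positives["S1"][i, j] == 6
            assert maps.cells["S1"][("F+N", label)].classification == "preferred"
        assert maps.preferred_percent["F+N"] == pytest.approx(100.0)

    def test_antisymmetry(self):
        table = self._choices_from(lambda a, b, rng: a if rng.random() < 0.5 else b, subjects=3)
        maps = preference_map(table)
        for mat in maps.positives.values():
            off_diag = ~np.eye(len(maps.labels), dtype=bool)
            pair_mask = (mat + mat.T) > 0
            assert np.all((mat + mat.T)[off_diag & pair_mask] == 6)

    def test_random_chooser_preferred_rate_matches_binomial(self):
        """For a fair coin, a cell is 'preferred' with probability
        P(X >= 5 | 6, 1/2) = 7/64; check over many simulated subjects."""
        table = self._choices_from(
            lambda a, b, rng: a if rng.random() < 0.5 else b, subjects=250, seed=42
        )
        maps = preference_map(table)
        rate = np.mean([
            cell.classification == "preferred"
            for cells in maps.cells.values()
            for cell in cells.values()
        ])
        expected = 7 / 64
        se = math.sqrt(expected * (1 - expected) / (250 * 72))
        assert rate == pytest.approx(expected, abs=4 * se)

    def test_pooled_map_uses_summed_counts(self):
        """Pooled cells aggregate counts over subjects (n = 6 x subjects)
        and classify with the proportional thresholds."""
        table = self._choices_from(lambda a, b, rng: a, subjects=4)
        maps = preference_map(table)
        for (row, col), cell in maps.pooled_cells.items():
            assert cell.n == 24
            expected = sum(
                maps.cells[s][(row, col)].positives for s in maps.positives
            )
            assert cell.positives == expected

    def test_incomplete_pairs_rejected(self):
        table = self._choices_from(lambda a, b, rng: a).iloc[:-1]
        with pytest.raises(AnalysisError, match="incomplete"):
            preference_map(table)


def test_preference_cell_consistency():
    cell = PreferenceCell("A", "B", 5, 6)
    assert cell.classification == "preferred"
    assert cell.tail_probability == pytest.approx(7 / 64)
    with pytest.raises(AnalysisError):
        PreferenceCell("A", "B", 3, 6, classification="preferred")
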