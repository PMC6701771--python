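"""Analysis pipeline: score aggregation, energy-score correlation, factorial
ANOVA, and pairwise preference maps with the exact binomial criterion.

The preference criterion follows the operational count rule of the protocol:
with 6 presentations per pair, 5 or 6 wins flag a correction as significantly
preferred and 0 or 1 as significantly rejected.  The exact one-sided binomial
tail P(X >= k | n, p = 1/2) is reported alongside each cell (for k = 5 of 6
it is 7/64 ~ 0.109).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import corrections as corr
from .observer import DISTANCES

__all__ = [
    "ScoreSummary",
    "PreferenceCell",
    "PreferenceMaps",
    "summarize_scores",
    "correlate_energy",
    "anova_scores",
    "bernoulli_tail",
    "classify_preference",
    "preference_map",
    "render_preference_map",
]


class AnalysisError(ValueError):
    """Raised for incomplete, unbalanced or degenerate input tables."""


# ---------------------------------------------------------------------------
# score aggregation


@dataclass
class ScoreSummary:
    """Aggregated perceptual scores.

    ``by_correction_distance``: per correction x distance — grand mean
    (of per-subject repetition means), SD across repetitions (average of
    per-subject repetition SDs) and SD across subjects (of subject means).
    ``by_family``: per family — mean |far - near| score difference and mean
    (far + near)/2 score over the family's corrections.
    """

    by_correction_distance: pd.DataFrame
    by_family: pd.DataFrame


def _check_complete(table: pd.DataFrame, catalog, distances) -> None:
    need = {c.label for c in catalog}
    missing = []
    for label in sorted(need):
        for d in distances:
            sub = table[(table["correction"] == label) & (table["distance"] == d)]
            if sub.empty:
                missing.append(f"{label}/{d}")
    if missing:
        raise AnalysisError(f"missing score cells: {', '.join(missing)}")


def summarize_scores(table: pd.DataFrame, catalog: list[corr.BinocularCorrection]) -> ScoreSummary:
    """Aggregate a tidy ScoreTable: repetition means per subject first, then
    across-subject statistics, then family-level far/near aggregates."""
    distances = sorted(table["distance"].unique())
    _check_complete(table, catalog, distances)
    per_subject = (
        table.groupby(["correction", "distance", "subject"])["score"]
        .agg(["mean", "std"])
        .rename(columns={"mean": "subj_mean", "std": "subj_rep_sd"})
        .reset_index()
    )
    by_cd = (
        per_subject.groupby(["correction", "distance"])
        .agg(
            mean_score=("subj_mean", "mean"),
            sd_repetitions=("subj_rep_sd", "mean"),
            sd_subjects=("subj_mean", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        )
        .reset_index()
    )
    families = {c.label: c.family for c in catalog}
    cd = by_cd.pivot(index="correction", columns="distance", values="mean_score")
    fam_rows = []
    for family in sorted(set(families.values())):
        labels = [l for l, f in families.items() if f == family]
        diffs = [abs(cd.loc[l, "far"] - cd.loc[l, "near"]) for l in labels]
        means = [(cd.loc[l, "far"] + cd.loc[l, "near"]) / 2.0 for l in labels]
        fam_rows.append(
            {
                "family": family,
                "n_corrections": len(labels),
                "far_near_diff": float(np.mean(diffs)),
                "far_near_mean": float(np.mean(means)),
            }
        )
    return ScoreSummary(
        by_correction_distance=by_cd, by_family=pd.DataFrame(fam_rows)
    )


# ---------------------------------------------------------------------------
# energy-score correlation


def correlate_energy(
    table: pd.DataFrame,
    catalog: list[corr.BinocularCorrection],
    mode: str = "mean",
    tolerance: float = corr.DEFAULT_TOLERANCE,
    demand_mode: str = "nominal",
) -> tuple[float, float]:
    """Pearson correlation between per-subject mean scores and energy in
    focus over all (subject, correction, distance) triples.

    Returns ``(r, p)`` with a two-sided p-value from the t transform.
    """
    sub = table[table["distance"].isin(DISTANCES)]
    targets = corr.viewing_targets(demand_mode)
    energy = {
        (c.label, t): corr.binocular_energy(c, targets[t], mode=mode, tolerance=tolerance)
        for c in catalog
        for t in DISTANCES
    }
    means = (
        sub.groupby(["subject", "correction", "distance"])["score"].mean().reset_index()
    )
    if len(means) < 3:
        raise AnalysisError("need at least 3 (subject, correction, distance) points")
    x = np.array([energy[(r.correction, r.distance)] for r in means.itertuples()])
    y = means["score"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# factorial ANOVA


def anova_scores(table: pd.DataFrame, include_interactions: bool = False) -> pd.DataFrame:
    """Fixed-effects main-effects ANOVA of score on subject, correction and
    distance (type II sums of squares) over the balanced factorial design.

    Returns a DataFrame indexed by factor with ``df``, ``sum_sq``, ``F`` and
    ``p`` columns plus a ``residual`` row.  Zero-variance factors report
    F = 0, p = 1 rather than the 0/0 indeterminate form.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    sub = table[table["distance"].isin(DISTANCES)].copy()
    counts = sub.groupby(["subject", "correction", "distance"]).size()
    if counts.empty:
        raise AnalysisError("empty score table")
    if counts.nunique() != 1 or len(counts) != (
        sub["subject"].nunique() * sub["correction"].nunique() * sub["distance"].nunique()
    ):
        raise AnalysisError("unbalanced factorial table: equal cell counts required")
    formula = "score ~ C(subject) + C(correction) + C(distance)"
    if include_interactions:
        formula += " + C(correction):C(distance)"
    fit = ols(formula, data=sub).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(subject)": "subject",
        "C(correction)": "correction",
        "C(distance)": "distance",
        "C(correction):C(distance)": "correction:distance",
        "Residual": "residual",
    }
    an = an.rename(index=rename)
    out = pd.DataFrame(
        {
            "df": an["df"].astype(int),
            "sum_sq": an["sum_sq"],
            "F": an["F"],
            "p": an["PR(>F)"],
        }
    )
    degenerate = out["sum_sq"] < 1e-12
    out.loc[degenerate & (out.index != "residual"), "F"] = 0.0
    out.loc[degenerate & (out.index != "residual"), "p"] = 1.0
    out.loc["residual", ["F", "p"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# exact binomial preference criterion


def bernoulli_tail(positives: int, n: int) -> float:
    """Exact one-sided upper tail P(X >= positives) for X ~ Binomial(n, 1/2).

    Computed by direct enumeration of binomial coefficients; exact in float
    for protocol-sized n.
    """
    if not (isinstance(positives, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise AnalysisError("counts must be integers")
    if n < 1 or not 0 <= positives <= n:
        raise AnalysisError(f"invalid counts: {positives} of {n}")
    return sum(math.comb(n, k) for k in range(positives, n + 1)) / 2**n


def classify_preference(positives: int, n: int = 6) -> str:
    """Operational count rule: >= 5 of 6 preferred, <= 1 of 6 rejected,
    otherwise neutral; generalized to ceil(5n/6) / floor(n/6) for pooled
    counts."""
    bernoulli_tail(positives, n)  # validates counts
    hi = math.ceil(5 * n / 6)
    lo = math.floor(n / 6)
    if positives >= hi:
        return "preferred"
    if positives <= lo:
        return "rejected"
    return "neutral"


@dataclass(frozen=True)
class PreferenceCell:
    """One cell of a pairwise preference map: how often the row correction
    beat the column correction."""

    correction_row: str
    correction_col: str
    positives: int
    n: int
    classification: str = ""
    tail_probability: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        tail = bernoulli_tail(self.positives, self.n)
        cls = classify_preference(self.positives, self.n)
        if self.classification == "":
            object.__setattr__(self, "classification", cls)
        elif self.classification != cls:
            raise AnalysisError(
                f"classification '{self.classification}' inconsistent with counts"
            )
        if math.isnan(self.tail_probability):
            object.__setattr__(self, "tail_probability", tail)


@dataclass
class PreferenceMaps:
    """Per-subject and pooled pairwise preference maps.

    ``positives[s][i, j]`` counts how often correction ``labels[i]`` beat
    ``labels[j]`` for subject ``s`` (diagonal unused); antisymmetric in the
    sense ``positives[i, j] + positives[j, i] = n_repetitions``.  The pooled
    map classifies summed counts with the generalized thresholds.
    ``preferred_percent`` gives, per correction, the percentage of its
    per-subject comparisons classified as preferred.
    """

    labels: list[str]
    n_repetitions: int
    positives: dict[str, np.ndarray]
    cells: dict[str, dict[tuple[str, str], PreferenceCell]]
    pooled_positives: np.ndarray
    pooled_cells: dict[tuple[str, str], PreferenceCell]
    preferred_percent: pd.Series


def preference_map(
    table: pd.DataFrame, subset: list[corr.BinocularCorrection] | None = None
) -> PreferenceMaps:
    """Build per-subject and pooled preference maps from a tidy ChoiceTable."""
    subset = subset if subset is not None else corr.preference_subset()
    labels = [c.label for c in subset]
    index = {l: i for i, l in enumerate(labels)}
    pairs = corr.all_pairs(subset)
    subjects = sorted(table["subject"].unique())
    reps_per_pair = None
    positives: dict[str, np.ndarray] = {}
    cells: dict[str, dict[tuple[str, str], PreferenceCell]] = {}
    incomplete = []
    for s in subjects:
        sub = table[table["subject"] == s]
        mat = np.zeros((len(labels), len(labels)), dtype=int)
        cell_map = {}
        for a, b in pairs:
            rows = sub[
                ((sub["correction_a"] == a) & (sub["correction_b"] == b))
                | ((sub["correction_a"] == b) & (sub["correction_b"] == a))
            ]
            if rows.empty:
                incomplete.append(f"{s}:{a} vs {b}")
                continue
            n = len(rows)
            if reps_per_pair is None:
                reps_per_pair = n
            elif n != reps_per_pair:
                incomplete.append(f"{s}:{a} vs {b} ({n} of {reps_per_pair} choices)")
                continue
            wins_a = int((rows["chosen"] == a).sum())
            mat[index[a], index[b]] = wins_a
            mat[index[b], index[a]] = n - wins_a
            cell_map[(a, b)] = PreferenceCell(a, b, wins_a, n)
            cell_map[(b, a)] = PreferenceCell(b, a, n - wins_a, n)
        positives[s] = mat
        cells[s] = cell_map
    if incomplete:
        raise AnalysisError(f"incomplete pairs: {', '.join(incomplete[:8])}")
    if reps_per_pair is None:
        raise AnalysisError("choice table holds no protocol pairs")
    pooled = sum(positives.values())
    pooled_n = reps_per_pair * len(subjects)
    pooled_cells = {}
    for a, b in pairs:
        pooled_cells[(a, b)] = PreferenceCell(a, b, int(pooled[index[a], index[b]]), pooled_n)
        pooled_cells[(b, a)] = PreferenceCell(b, a, int(pooled[index[b], index[a]]), pooled_n)
    pref_counts = {l: 0 for l in labels}
    total_counts = {l: 0 for l in labels}
    for s in subjects:
        for (a, b), cell in cells[s].items():
            total_counts[a] += 1
            if cell.classification == "preferred":
                pref_counts[a] += 1
    preferred_percent = pd.Series(
        {l: 100.0 * pref_counts[l] / total_counts[l] for l in labels}, name="preferred_percent"
    )
    return PreferenceMaps(
        labels=labels,
        n_repetitions=reps_per_pair,
        positives=positives,
        cells=cells,
        pooled_positives=pooled,
        pooled_cells=pooled_cells,
        preferred_percent=preferred_percent,
    )


_CLASS_COLORS = {"preferred": "#2ca02c", "rejected": "#d62728", "neutral": "#9e9e9e"}


def render_preference_map(maps: PreferenceMaps, path, subject: str | None = None) -> None:
    """Render one preference map (a subject's, or pooled) as a dot-matrix
    heatmap: green = row preferred over column, red = rejected, gray =
    neutral."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = maps.pooled_cells if subject is None else maps.cells[subject]
    k = len(maps.labels)
    fig, ax = plt.subplots(figsize=(0.6 * k + 2, 0.6 * k + 2))
    for (a, b), cell in cells.items():
        i, j = maps.labels.index(a), maps.labels.index(b)
        if i == j:
            continue
        ax.scatter(j, k - 1 - i, s=360, color=_CLASS_COLORS[cell.classification])
    ax.set_xticks(range(k), maps.labels, rotation=45, ha="right")
    ax.set_yticks(range(k), maps.labels[::-1])
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    title = "pooled" if subject is None else subject
    ax.set_title(f"Pairwise preference map ({title})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
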