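"""Synthetic observers: perceptual scores and 2AFC choices with subject
structure.

Each observer maps objective binocular image quality to a 0-5 perceptual
score through a linear transducer (gain, bias) plus Gaussian repetition
noise, and makes two-alternative forced choices by comparing noisy
distance-weighted utilities.  Subject heterogeneity (gain, bias, distance
weights) emulates the consistent inter-subject differences real cohorts
show; repetition noise defaults to an intra-subject SD of 0.45 score units.

Every subject owns an independent seeded random stream, so cohorts are
reproducible and subjects statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import corrections as corr
from . import retina
from .optics import OpticalConfig
from .scene import SceneStack

__all__ = [
    "ObserverParams",
    "default_cohort",
    "score_trial",
    "choose_2afc",
    "compute_quality_table",
    "run_experiment",
    "SCORE_COLUMNS",
    "CHOICE_COLUMNS",
]

SCORE_COLUMNS = ("subject", "correction", "distance", "repetition", "score")
CHOICE_COLUMNS = ("subject", "correction_a", "correction_b", "repetition", "chosen")

SCORE_MAX = 5.0
DISTANCES = ("far", "intermediate", "near")

#: Intra-subject repetition SD of perceptual scores (score units).
DEFAULT_SCORE_NOISE_SD = 0.45


class ObserverError(ValueError):
    """Raised for invalid observer parameters or incomplete inputs."""


@dataclass(frozen=True)
class ObserverParams:
    """One synthetic subject.

    ``gain``/``bias`` map quality in [0, 1] to score units; ``score_noise_sd``
    is the repetition noise of scoring; ``choice_noise_sd`` is the trial noise
    of each interval's utility in a 2AFC (quality units); ``distance_weights``
    weight far/intermediate/near when judging the whole scene.
    """

    subject_id: str
    gain: float = 5.0
    bias: float = 0.0
    score_noise_sd: float = DEFAULT_SCORE_NOISE_SD
    choice_noise_sd: float = 0.09
    distance_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_noise_sd < 0 or self.choice_noise_sd < 0:
            raise ObserverError("noise SDs must be >= 0")
        w = np.asarray(self.distance_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ObserverError(
                f"distance_weights must be 3 nonnegative values summing to 1, got {self.distance_weights}"
            )

    def weight(self, distance: str) -> float:
        return dict(zip(DISTANCES, self.distance_weights))[distance]


def default_cohort(n_subjects: int = 8, base_seed: int = 0) -> list[ObserverParams]:
    """A reproducible cohort of ``n_subjects`` with dispersed parameters.

    Gains and biases scatter around a transducer (gain 4.0, bias 0.5) whose
    response to the best and worst stimuli sits about one noise SD inside
    the 0/5 rails, so the clamped repetition noise realizes close to its
    configured SD; the distance weights are drawn from a Dirichlet prior,
    giving each subject a stable idiosyncratic emphasis on
    far/intermediate/near — the analogue of consistent subject-dependent
    judgments in real cohorts.
    """
    if n_subjects < 1:
        raise ObserverError("cohort must have at least one subject")
    rng = np.random.default_rng(base_seed)
    cohort = []
    for i in range(n_subjects):
        gain = float(np.clip(rng.normal(4.0, 0.25), 3.4, 4.6))
        bias = float(np.clip(rng.normal(0.5, 0.1), 0.25, 0.75))
        weights = rng.dirichlet([6.0, 4.0, 6.0])
        cohort.append(
            ObserverParams(
                subject_id=f"S{i + 1}",
                gain=gain,
                bias=bias,
                distance_weights=tuple(weights),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return cohort


def score_trial(
    params: ObserverParams,
    correction_label: str,
    distance: str,
    quality: float,
    rng: np.random.Generator,
) -> dict:
    """One scoring trial: ``clamp(gain * quality + bias + noise, 0, 5)``."""
    if not 0.0 <= quality <= 1.0:
        raise ObserverError(f"quality must be in [0, 1], got {quality}")
    noise = rng.normal(0.0, params.score_noise_sd) if params.score_noise_sd > 0 else 0.0
    score = min(max(params.gain * quality + params.bias + noise, 0.0), SCORE_MAX)
    return {
        "subject": params.subject_id,
        "correction": correction_label,
        "distance": distance,
        "score": float(score),
    }


def _decide(delta_utility: float, noise: float) -> str:
    """Deterministic 2AFC decision given the utility difference and the
    realized noise; antisymmetric: flipping both signs flips the choice."""
    return "A" if delta_utility + noise > 0 else "B"


def choose_2afc(
    params: ObserverParams,
    utility_a: float,
    utility_b: float,
    rng: np.random.Generator,
) -> str:
    """Pick 'A' or 'B'; the two intervals carry independent Gaussian noise,
    so the effective comparison noise has SD ``choice_noise_sd * sqrt(2)``
    and P(choose A) follows a cumulative-normal psychometric function of
    the utility difference."""
    sd = params.choice_noise_sd * math.sqrt(2.0)
    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    return _decide(utility_a - utility_b, noise)


def compute_quality_table(
    scene: SceneStack,
    catalog: list[corr.BinocularCorrection],
    config: OpticalConfig,
    *,
    binocular_rule: str = "better_eye",
    metric: str = "contrast",
    demand_mode: str = "nominal",
) -> dict[tuple[str, str], float]:
    """Binocular quality for every (correction label, distance).

    Each unique monocular profile is simulated once per distance; the
    binocular value combines the two eyes under ``binocular_rule``.
    """
    targets = corr.viewing_targets(demand_mode)
    profiles = {}
    for c in catalog:
        profiles[c.dominant.label] = c.dominant
        profiles[c.nondominant.label] = c.nondominant
    eye_quality: dict[tuple[str, str], retina.QualityScore] = {}
    for tname, target in targets.items():
        plane = scene.planes[tname]
        mask = scene.region_masks[tname]
        ref = retina.diffraction_limited_image(plane, target, config)
        for plabel, profile in profiles.items():
            img = retina.simulate_eye(plane, profile, target, config)
            eye_quality[(plabel, tname)] = retina.image_quality(
                img, ref, metric=metric, mask=mask
            )
    table = {}
    for c in catalog:
        for tname in targets:
            q = retina.binocular_quality(
                eye_quality[(c.dominant.label, tname)],
                eye_quality[(c.nondominant.label, tname)],
                rule=binocular_rule,
            )
            table[(c.label, tname)] = q.value
    return table


def energy_quality_table(
    catalog: list[corr.BinocularCorrection],
    *,
    energy_mode: str = "mean",
    tolerance: float = corr.DEFAULT_TOLERANCE,
    demand_mode: str = "nominal",
) -> dict[tuple[str, str], float]:
    """Quality surrogate taken directly from energy in focus (scaled to
    [0, 1]); used for structure-recovery checks against the analysis chain."""
    targets = corr.viewing_targets(demand_mode)
    return {
        (c.label, tname): corr.binocular_energy(c, t, mode=energy_mode, tolerance=tolerance) / 100.0
        for c in catalog
        for tname, t in targets.items()
    }


def _overall_quality(
    params: ObserverParams, quality: dict[tuple[str, str], float], label: str
) -> float:
    return sum(
        params.weight(d) * quality[(label, d)] for d in DISTANCES
    )


def run_experiment(
    cohort: list[ObserverParams],
    catalog: list[corr.BinocularCorrection],
    scene: SceneStack | None,
    config: OpticalConfig | None,
    *,
    subset: list[corr.BinocularCorrection] | None = None,
    score_repetitions: int = 3,
    choice_repetitions: int = 6,
    binocular_rule: str = "better_eye",
    metric: str = "contrast",
    demand_mode: str = "nominal",
    quality_source: str = "image",
    energy_mode: str = "mean",
    tolerance: float = corr.DEFAULT_TOLERANCE,
    quality: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full scoring + preference protocol on a synthetic cohort.

    Scoring covers every catalog correction at far, intermediate, near and
    overall (``score_repetitions`` times each, order shuffled per subject);
    preferences cover all unordered pairs of the ``subset`` (default: the
    9-correction far-dominant subset), ``choice_repetitions`` times each.

    ``quality_source`` selects the objective correlate driving the observer:
    ``image`` simulates retinal images (requires ``scene`` and ``config``),
    ``energy`` uses energy in focus directly.  A precomputed ``quality``
    table overrides both.

    Returns tidy (ScoreTable, ChoiceTable) DataFrames.
    """
    if not cohort:
        raise ObserverError("cohort must be non-empty")
    if quality is None:
        if quality_source == "image":
            if scene is None or config is None:
                raise ObserverError("image quality source needs a scene and a config")
            quality = compute_quality_table(
                scene, catalog, config,
                binocular_rule=binocular_rule, metric=metric, demand_mode=demand_mode,
            )
        elif quality_source == "energy":
            quality = energy_quality_table(
                catalog, energy_mode=energy_mode, tolerance=tolerance, demand_mode=demand_mode
            )
        else:
            raise ObserverError(f"unknown quality_source '{quality_source}'")
    missing = [
        (c.label, d) for c in catalog for d in DISTANCES if (c.label, d) not in quality
    ]
    if missing:
        raise ObserverError(f"quality table incomplete, missing {missing[:5]}...")

    if subset is None:
        subset = corr.preference_subset()
    pairs = corr.all_pairs(subset)

    score_rows, choice_rows = [], []
    for params in cohort:
        rng = np.random.default_rng(params.seed)
        cells = [
            (c.label, d, rep)
            for rep in range(1, score_repetitions + 1)
            for c in catalog
            for d in (*DISTANCES, "overall")
        ]
        order = rng.permutation(len(cells))
        for idx in order:
            label, distance, rep = cells[idx]
            q = (
                _overall_quality(params, quality, label)
                if distance == "overall"
                else quality[(label, distance)]
            )
            row = score_trial(params, label, distance, q, rng)
            row["repetition"] = rep
            score_rows.append(row)
        trials = [
            (a, b, rep)
            for rep in range(1, choice_repetitions + 1)
            for a, b in pairs
        ]
        order = rng.permutation(len(trials))
        for idx in order:
            a, b, rep = trials[idx]
            ua = _overall_quality(params, quality, a)
            ub = _overall_quality(params, quality, b)
            chosen = choose_2afc(params, ua, ub, rng)
            choice_rows.append(
                {
                    "subject": params.subject_id,
                    "correction_a": a,
                    "correction_b": b,
                    "repetition": rep,
                    "chosen": a if chosen == "A" else b,
                }
            )
    scores = pd.DataFrame(score_rows, columns=list(SCORE_COLUMNS))
    choices = pd.DataFrame(choice_rows, columns=list(CHOICE_COLUMNS))
    return scores, choices


def reseeded(cohort: list[ObserverParams], base_seed: int) -> list[ObserverParams]:
    """Same cohort parameters under a fresh family of per-subject seeds."""
    rng = np.random.default_rng(base_seed)
    return [
        replace(p, seed=int(rng.integers(2**31 - 1))) for p in cohort
    ]
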