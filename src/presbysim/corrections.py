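"""Temporal-multiplexing correction profiles and energy-in-focus accounting.

A tunable lens cycling faster than flicker fusion delivers a mixture of focus
states; the dwell fraction at each state is the fraction of optical energy at
that focus.  A :class:`TemporalPowerProfile` encodes one eye's correction as
(add power, dwell fraction) pairs, and a :class:`BinocularCorrection` pairs a
dominant- and a non-dominant-eye profile.

The standard catalog holds 17 binocular corrections: three monofocals (far,
intermediate, near adds of 0, +1.5, +3 D), four simultaneous-vision
combinations of a 50/50 bifocal (2SV) and a 50/20/30 trifocal (3SV), two
monovisions and eight modified monovisions.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

__all__ = [
    "FocusState",
    "TemporalPowerProfile",
    "BinocularCorrection",
    "ViewingTarget",
    "standard_profiles",
    "viewing_targets",
    "build_catalog",
    "preference_subset",
    "residual_defocus",
    "energy_in_focus",
    "binocular_energy",
    "profile_to_dict",
    "profile_from_dict",
]

DWELL_TOL = 1e-9
POWER_RANGE = (-10.0, 10.0)

#: Default in-focus window (diopters); a typical ocular depth of focus.
DEFAULT_TOLERANCE = 0.35

FAR_DISTANCE_M = 4.0
INTERMEDIATE_DISTANCE_M = 0.66
NEAR_DISTANCE_M = 0.33


class CorrectionError(ValueError):
    """Raised for invalid profiles, catalogs or accounting parameters."""


@dataclass(frozen=True)
class FocusState:
    """One focus state: add power (D, relative to far best focus) and the
    dwell fraction of cycle time (hence optical energy) spent there."""

    add_power: float
    dwell_fraction: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.add_power) and math.isfinite(self.dwell_fraction)):
            raise CorrectionError("focus state fields must be finite")
        if self.dwell_fraction < 0:
            raise CorrectionError(f"dwell_fraction must be >= 0, got {self.dwell_fraction}")
        if not (POWER_RANGE[0] <= self.add_power <= POWER_RANGE[1]):
            raise CorrectionError(
                f"add_power {self.add_power} D outside tunable range {POWER_RANGE}"
            )


@dataclass(frozen=True)
class TemporalPowerProfile:
    """Ordered focus states of one eye's temporally multiplexed correction."""

    label: str
    states: tuple[FocusState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise CorrectionError("profile needs at least one focus state")
        object.__setattr__(self, "states", tuple(self.states))
        total = sum(s.dwell_fraction for s in self.states)
        if abs(total - 1.0) > DWELL_TOL:
            raise CorrectionError(
                f"dwell fractions of '{self.label}' sum to {total}, expected 1"
            )
        adds = [s.add_power for s in self.states]
        if len(set(adds)) != len(adds):
            raise CorrectionError(f"profile '{self.label}' repeats an add power")

    @property
    def is_monofocal(self) -> bool:
        return len(self.states) == 1


@dataclass(frozen=True)
class ViewingTarget:
    """A viewing distance with its dioptric demand on the correction."""

    name: str
    distance: float
    demand: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise CorrectionError(f"distance must be positive, got {self.distance}")
        if self.demand < 0:
            raise CorrectionError(f"demand must be >= 0, got {self.demand}")


@dataclass(frozen=True)
class BinocularCorrection:
    """Labeled pair of profiles; first label token is the dominant eye."""

    label: str
    dominant: TemporalPowerProfile
    nondominant: TemporalPowerProfile
    family: str = field(default="")

    def __post_init__(self) -> None:
        expected = f"{self.dominant.label}+{self.nondominant.label}"
        if self.label != expected:
            raise CorrectionError(
                f"label '{self.label}' inconsistent with profiles '{expected}'"
            )
        fam = classify_family(self.dominant, self.nondominant)
        if self.family == "":
            object.__setattr__(self, "family", fam)
        elif self.family != fam:
            raise CorrectionError(
                f"family '{self.family}' inconsistent with derived '{fam}'"
            )


def classify_family(dom: TemporalPowerProfile, nond: TemporalPowerProfile) -> str:
    """Derive the correction family from the two profiles."""
    if dom.is_monofocal and nond.is_monofocal:
        if dom.states[0].add_power == nond.states[0].add_power:
            return "monofocal"
        return "monovision"
    if not dom.is_monofocal and not nond.is_monofocal:
        return "simultaneous"
    return "modified_monovision"


def standard_profiles() -> dict[str, TemporalPowerProfile]:
    """The five monocular profiles the catalog is built from.

    F/I/N are static foci at 0 / +1.5 / +3 D; 2SV splits the energy 50% far,
    50% near; 3SV splits it 50% far, 20% intermediate, 30% near.
    """
    return {
        "F": TemporalPowerProfile("F", (FocusState(0.0, 1.0),)),
        "I": TemporalPowerProfile("I", (FocusState(1.5, 1.0),)),
        "N": TemporalPowerProfile("N", (FocusState(3.0, 1.0),)),
        "2SV": TemporalPowerProfile(
            "2SV", (FocusState(0.0, 0.5), FocusState(3.0, 0.5))
        ),
        "3SV": TemporalPowerProfile(
            "3SV",
            (FocusState(0.0, 0.5), FocusState(1.5, 0.2), FocusState(3.0, 0.3)),
        ),
    }


def viewing_targets(mode: str = "nominal") -> dict[str, ViewingTarget]:
    """The three viewing distances (4 m, 66 cm, 33 cm) with their demands.

    ``nominal`` assigns the demands the device's adds were chosen for
    (0 / 1.5 / 3 D), absorbing the 0.25 D far vergence into the subjective
    best focus; ``exact`` uses ``1/distance - 1/4`` relative to the far
    plane.
    """
    if mode == "nominal":
        demands = {"far": 0.0, "intermediate": 1.5, "near": 3.0}
    elif mode == "exact":
        demands = {
            "far": 0.0,
            "intermediate": 1.0 / INTERMEDIATE_DISTANCE_M - 1.0 / FAR_DISTANCE_M,
            "near": 1.0 / NEAR_DISTANCE_M - 1.0 / FAR_DISTANCE_M,
        }
    else:
        raise CorrectionError(f"unknown demand mode '{mode}'")
    distances = {
        "far": FAR_DISTANCE_M,
        "intermediate": INTERMEDIATE_DISTANCE_M,
        "near": NEAR_DISTANCE_M,
    }
    return {
        name: ViewingTarget(name, distances[name], demands[name]) for name in distances
    }


#: Catalog order: 3 monofocal, 4 simultaneous vision, 2 monovision,
#: 8 modified monovision.
CATALOG_LABELS = (
    "F+F", "I+I", "N+N",
    "2SV+2SV", "3SV+3SV", "2SV+3SV", "3SV+2SV",
    "F+N", "N+F",
    "F+2SV", "F+3SV", "2SV+N", "3SV+N",
    "2SV+F", "3SV+F", "N+2SV", "N+3SV",
)

#: Corrections compared pairwise; the dominant eye is always corrected
#: for far in this subset.
PREFERENCE_LABELS = (
    "3SV+3SV", "2SV+2SV", "2SV+3SV", "3SV+2SV",
    "F+N", "F+2SV", "F+3SV", "2SV+N", "3SV+N",
)


def _from_label(label: str, profiles: dict[str, TemporalPowerProfile]) -> BinocularCorrection:
    try:
        dom_label, nond_label = label.split("+")
        dom, nond = profiles[dom_label], profiles[nond_label]
    except (ValueError, KeyError) as exc:
        raise CorrectionError(f"cannot resolve correction label '{label}'") from exc
    return BinocularCorrection(label=label, dominant=dom, nondominant=nond)


def build_catalog() -> list[BinocularCorrection]:
    """The 17 binocular corrections of the standard protocol."""
    profiles = standard_profiles()
    return [_from_label(label, profiles) for label in CATALOG_LABELS]


def preference_subset() -> list[BinocularCorrection]:
    """The 9 corrections entering pairwise preference comparisons."""
    profiles = standard_profiles()
    return [_from_label(label, profiles) for label in PREFERENCE_LABELS]


def all_pairs(subset: list[BinocularCorrection] | None = None) -> list[tuple[str, str]]:
    """The unordered correction pairs of the preference protocol (36)."""
    labels = [c.label for c in (subset if subset is not None else preference_subset())]
    return list(itertools.combinations(labels, 2))


def residual_defocus(profile: TemporalPowerProfile, target: ViewingTarget) -> list[float]:
    """Per-state residual defocus ``demand - add_power`` in diopters."""
    return [target.demand - s.add_power for s in profile.states]


def energy_in_focus(
    profile: TemporalPowerProfile,
    target: ViewingTarget,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Percent of the profile's energy within ``tolerance`` D of focus."""
    if not (math.isfinite(tolerance) and tolerance > 0):
        raise CorrectionError(f"tolerance must be positive, got {tolerance}")
    residuals = residual_defocus(profile, target)
    share = sum(
        s.dwell_fraction
        for s, r in zip(profile.states, residuals)
        if abs(r) <= tolerance
    )
    return 100.0 * share


def binocular_energy(
    correction: BinocularCorrection,
    target: ViewingTarget,
    mode: str = "mean",
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Combine the two eyes' energy in focus: mean, better eye, or dominant."""
    e_dom = energy_in_focus(correction.dominant, target, tolerance)
    e_nond = energy_in_focus(correction.nondominant, target, tolerance)
    if mode == "mean":
        return 0.5 * (e_dom + e_nond)
    if mode == "better_eye":
        return max(e_dom, e_nond)
    if mode == "dominant_eye":
        return e_dom
    raise CorrectionError(f"unknown binocular energy mode '{mode}'")


def profile_to_dict(profile: TemporalPowerProfile) -> dict:
    return {
        "label": profile.label,
        "states": [
            {"add": s.add_power, "dwell": s.dwell_fraction} for s in profile.states
        ],
    }


def profile_from_dict(data: dict) -> TemporalPowerProfile:
    try:
        states = tuple(
            FocusState(float(s["add"]), float(s["dwell"])) for s in data["states"]
        )
        return TemporalPowerProfile(str(data["label"]), states)
    except (KeyError, TypeError) as exc:
        raise CorrectionError(f"malformed profile spec: {data!r}") from exc


def save_catalog(catalog: list[BinocularCorrection], path) -> None:
    payload = [
        {
            "label": c.label,
            "family": c.family,
            "dominant": profile_to_dict(c.dominant),
            "nondominant": profile_to_dict(c.nondominant),
        }
        for c in catalog
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_catalog(path) -> list[BinocularCorrection]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        BinocularCorrection(
            label=item["label"],
            dominant=profile_from_dict(item["dominant"]),
            nondominant=profile_from_dict(item["nondominant"]),
            family=item.get("family", ""),
        )
        for item in payload
    ]
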