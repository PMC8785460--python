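"""Classification of penalty vectors into the visual pattern taxonomy.

The hexagon shapes recur as a small set of clinically meaningful patterns:
optimal control (square / semi-circle on the right half), optimal support
(round ring or bow tie), directional spikes for over/under ventilation,
over/under support and over/under oxygenation, an over-support triad
(support + pressure + oxygen all elevated), and over-ventilation combined
with hypoxia.  Classification is a decision list over the penalty vector,
evaluated in a documented priority order (combined patterns before single
spikes), using an "elevated" threshold at the green band boundary and a
relative dominance ratio so that rescaling all penalties never turns one
spike into a different spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import DomainError
from .physiology import CONTROL_MODES
from .preferences import PenaltyVector


class PatternLabel(str, Enum):
    OPTIMAL_CONTROL = "OPTIMAL_CONTROL"
    OPTIMAL_SUPPORT_ROUND = "OPTIMAL_SUPPORT_ROUND"
    OPTIMAL_SUPPORT_BOWTIE = "OPTIMAL_SUPPORT_BOWTIE"
    OVERVENTILATION = "OVERVENTILATION"
    OVERVENTILATION_WITH_HYPOXIA = "OVERVENTILATION_WITH_HYPOXIA"
    UNDERVENTILATION = "UNDERVENTILATION"
    OVERSUPPORT = "OVERSUPPORT"
    UNDERSUPPORT = "UNDERSUPPORT"
    OVERSUPPORT_TRIAD = "OVERSUPPORT_TRIAD"
    OVEROXYGENATION = "OVEROXYGENATION"
    UNDEROXYGENATION = "UNDEROXYGENATION"
    UNCLASSIFIED = "UNCLASSIFIED"


#: single-spike label per dominant axis (direction fixed by the axis layout)
SPIKE_LABELS = {
    "lung_trauma": PatternLabel.OVERVENTILATION,          # upward spike
    "acidosis": PatternLabel.UNDERVENTILATION,            # downward spike
    "muscle_atrophy": PatternLabel.OVERSUPPORT,           # left-upward spike
    "respiratory_stress": PatternLabel.UNDERSUPPORT,      # left-downward spike
    "oxygen_toxicity": PatternLabel.OVEROXYGENATION,      # right-upward spike
    "low_oxygenation": PatternLabel.UNDEROXYGENATION,     # right-downward spike
}

_CENTER_AXES = ("lung_trauma", "acidosis")
_LEFT_AXES = ("muscle_atrophy", "respiratory_stress")
_RIGHT_AXES = ("oxygen_toxicity", "low_oxygenation")


@dataclass(frozen=True)
class PatternConfig:
    elevated: float = 1.0 / 3.0        # yellow band boundary
    dominance: float = 2.0             # spike: max >= dominance * next highest
    bowtie_center_ratio: float = 0.5   # center << wings
    bowtie_wing_min: float = 0.15      # wings must be visible


DEFAULT_PATTERN_CONFIG = PatternConfig()


@dataclass(frozen=True)
class Classification:
    label: PatternLabel
    dominant_axes: tuple
    confidence: float                  # margin of the decisive rule


def classify(pv: PenaltyVector,
             config: PatternConfig = DEFAULT_PATTERN_CONFIG) -> Classification:
    """Assign exactly one pattern label to a penalty vector.

    Priority order: (1) over-support triad; (2) over-ventilation with
    hypoxia; (3) single dominant spike; (4) balanced ventilation trade-off
    (both center axes elevated, neither dominant: the permissive-hypercapnia
    optimum); (5) all-below-elevated optimal shapes; else unclassified.
    """
    vals = pv.active_values()
    thr = config.elevated
    elevated = {a for a, v in vals.items() if v > thr}
    in_control = pv.mode in CONTROL_MODES

    # (1) over support + elevated pressure + over oxygenation: quadrilateral
    # above the left, center and right upward axes
    triad = ("muscle_atrophy", "lung_trauma", "oxygen_toxicity")
    if not in_control and all(a in elevated for a in triad):
        margin = min(vals[a] for a in triad) - thr
        return Classification(PatternLabel.OVERSUPPORT_TRIAD, triad, margin)

    # (2) over ventilation with hypoxia: spikes upward and to the lower right
    duo = ("lung_trauma", "low_oxygenation")
    if all(a in elevated for a in duo):
        margin = min(vals[a] for a in duo) - thr
        return Classification(PatternLabel.OVERVENTILATION_WITH_HYPOXIA, duo, margin)

    # (3) single dominant spike
    ordered = sorted(vals, key=lambda a: vals[a], reverse=True)
    top, top_v = ordered[0], vals[ordered[0]]
    second_v = vals[ordered[1]] if len(ordered) > 1 else 0.0
    if top_v > thr and top_v >= config.dominance * second_v:
        return Classification(SPIKE_LABELS[top], (top,),
                              top_v - config.dominance * second_v)

    def optimal(margin: float) -> Classification:
        if in_control:
            return Classification(PatternLabel.OPTIMAL_CONTROL, (), margin)
        left = max(vals[a] for a in _LEFT_AXES)
        right = max(vals[a] for a in _RIGHT_AXES)
        center = max(vals[a] for a in _CENTER_AXES)
        wings = min(left, right)
        if wings >= config.bowtie_wing_min and center < config.bowtie_center_ratio * wings:
            return Classification(PatternLabel.OPTIMAL_SUPPORT_BOWTIE,
                                  _LEFT_AXES + _RIGHT_AXES, margin)
        return Classification(PatternLabel.OPTIMAL_SUPPORT_ROUND, (), margin)

    # (4) balanced center pair: pressure/pH trade-off achieved despite
    # abnormal values on both (permissive hypercapnia)
    center_vals = [vals[a] for a in _CENTER_AXES if a in vals]
    if (elevated and elevated <= set(_CENTER_AXES) and len(elevated) == 2
            and max(center_vals) < config.dominance * min(center_vals)):
        return Classification(optimal(min(center_vals) - thr).label,
                              _CENTER_AXES, min(center_vals) - thr)

    # (5) everything in balance below the elevated threshold
    if not elevated:
        return optimal(thr - max(vals.values()))

    return Classification(PatternLabel.UNCLASSIFIED, tuple(sorted(elevated)), 0.0)


def classify_trajectory(trajectory,
                        config: PatternConfig = DEFAULT_PATTERN_CONFIG) -> list:
    """One classification per trajectory record, in chronological order."""
    steps = getattr(trajectory, "steps", trajectory)
    if len(steps) == 0:
        raise DomainError("cannot classify an empty trajectory")
    return [classify(s.penalties, config) for s in steps]
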