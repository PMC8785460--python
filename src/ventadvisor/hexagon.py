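"""Hexagon glyph geometry and deterministic SVG rendering.

Each of the six competing goals is a vertical axis anchored on one of three
columns: the left column carries the support axes (muscle atrophy up,
respiratory stress down), the center column the ventilation axes (lung
trauma up, acidosis down) and the right column the oxygenation axes (oxygen
toxicity up, low oxygenation down).  "Up" always means "too much" harms.
Control modes deactivate the left column, so the symbol fills only the right
hand side of the hexagon.

The current (blue) and advised/simulated (grey) penalty polygons share one
axis scale, chosen from the severity band of the current vector: an
all-green vector is magnified so the axis spans the green range only, while
yellow and red vectors are progressively compressed - a smaller drawn area
on a red hexagon can therefore be a higher penalty than a larger area on a
rescaled green one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DomainError
from .physiology import Mode
from .preferences import (AXES, DEFAULT_PENALTY_CONFIG, PenaltyConfig,
                          PenaltyVector, SeverityBand, active_mask_for_mode,
                          severity)


@dataclass(frozen=True)
class HexagonConfig:
    """Geometry and color constants of the glyph."""

    min_offset: float = 0.08           # zero-penalty shapes stay visible
    scale_green: float = 3.0           # axis magnification per severity band
    scale_yellow: float = 1.5
    scale_red: float = 0.7
    color_current: str = "#1f62b4"     # blue symbol: current settings
    color_advised: str = "#8a8a8a"     # grey symbol: advice / simulation
    color_green: str = "#c8e6c9"
    color_yellow: str = "#fff3b0"
    color_red: str = "#f4b6b6"

    def band_color(self, band: SeverityBand) -> str:
        return {SeverityBand.GREEN: self.color_green,
                SeverityBand.YELLOW: self.color_yellow,
                SeverityBand.RED: self.color_red}[band]

    def band_scale(self, band: SeverityBand) -> float:
        return {SeverityBand.GREEN: self.scale_green,
                SeverityBand.YELLOW: self.scale_yellow,
                SeverityBand.RED: self.scale_red}[band]


DEFAULT_HEXAGON_CONFIG = HexagonConfig()

# goal -> (column x, direction); order matches preferences.AXES, which walks
# the hexagon left-up, center-up, right-up, right-down, center-down, left-down
_AXIS_GEOMETRY = {
    "muscle_atrophy": (-1.0, +1.0),
    "lung_trauma": (0.0, +1.0),
    "oxygen_toxicity": (+1.0, +1.0),
    "low_oxygenation": (+1.0, -1.0),
    "acidosis": (0.0, -1.0),
    "respiratory_stress": (-1.0, -1.0),
}

# fixed decorative outline of the hexagon frame
_OUTLINE = ((-1.0, 1.1), (0.0, 1.25), (1.0, 1.1), (1.0, -1.1), (0.0, -1.25),
            (-1.0, -1.1))


@dataclass(frozen=True)
class Axis:
    goal: str
    x: float
    direction: float   # +1 up ("too much" harms), -1 down ("too little")
    column: str        # left / center / right
    active: bool


@dataclass(frozen=True)
class AxisLayout:
    axes: tuple

    def active_axes(self) -> tuple:
        return tuple(a for a in self.axes if a.active)

    def __iter__(self):
        return iter(self.axes)


def layout(mode: Mode) -> AxisLayout:
    """Axis geometry for a mode; control modes deactivate the left column."""
    mask = active_mask_for_mode(mode)
    axes = []
    for goal in AXES:
        x, direction = _AXIS_GEOMETRY[goal]
        column = {-1.0: "left", 0.0: "center", 1.0: "right"}[x]
        axes.append(Axis(goal=goal, x=x, direction=direction, column=column,
                         active=mask[goal]))
    return AxisLayout(axes=tuple(axes))


def axis_scale(pv: PenaltyVector, config: HexagonConfig = DEFAULT_HEXAGON_CONFIG,
               penalty_config: PenaltyConfig = DEFAULT_PENALTY_CONFIG) -> float:
    """Axis magnification from the severity band of the vector's maximum."""
    return config.band_scale(severity(pv, penalty_config))


def drawn_length(penalty: float, scale: float,
                 config: HexagonConfig = DEFAULT_HEXAGON_CONFIG) -> float:
    """Length of an axis segment: minimum offset plus penalty times scale."""
    return config.min_offset + penalty * scale


@dataclass(frozen=True)
class HexagonScene:
    """Renderable decision-space glyph."""

    layout: AxisLayout
    current_polygon: tuple            # ((x, y), ...) over active axes, in order
    advised_polygon: Optional[tuple]
    background_band: SeverityBand
    axis_scale: float
    corner_values: Optional[dict]     # goal -> physiological readout string


def compose(current_pv: PenaltyVector, advised_pv: Optional[PenaltyVector] = None,
            corner_values: Optional[dict] = None,
            config: HexagonConfig = DEFAULT_HEXAGON_CONFIG,
            penalty_config: PenaltyConfig = DEFAULT_PENALTY_CONFIG) -> HexagonScene:
    """Place the current (and optionally advised) polygons on the hexagon.

    Both polygons share the scale derived from the current vector's severity.
    """
    if advised_pv is not None and advised_pv.active != current_pv.active:
        raise DomainError("current and advised vectors have different axis masks")
    lay = layout(current_pv.mode)
    scale = axis_scale(current_pv, config, penalty_config)

    def polygon(pv):
        return tuple(
            (axis.x, axis.direction * drawn_length(pv.values[axis.goal], scale, config))
            for axis in lay.active_axes())

    return HexagonScene(
        layout=lay,
        current_polygon=polygon(current_pv),
        advised_polygon=polygon(advised_pv) if advised_pv is not None else None,
        background_band=severity(current_pv, penalty_config),
        axis_scale=scale,
        corner_values=dict(corner_values) if corner_values else None,
    )


def penalties_from_scene(scene: HexagonScene,
                         config: HexagonConfig = DEFAULT_HEXAGON_CONFIG) -> dict:
    """Invert the geometry: recover active-axis penalties from the vertices."""
    out = {}
    for axis, (x, y) in zip(scene.layout.active_axes(), scene.current_polygon):
        out[axis.goal] = (abs(y) - config.min_offset) / scene.axis_scale
    return out


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _svg_polygon(points, fill, stroke, opacity="1.0", width=0.03):
    pts = " ".join(f"{_fmt(x)},{_fmt(-y)}" for x, y in points)  # y up -> SVG y down
    return (f'<polygon points="{pts}" fill="{fill}" fill-opacity="{opacity}" '
            f'stroke="{stroke}" stroke-width="{_fmt(width)}" />')


def _glyph_fragment(scene: HexagonScene, config: HexagonConfig) -> list[str]:
    parts = [_svg_polygon(_OUTLINE, config.band_color(scene.background_band),
                          "#555555")]
    for axis in scene.layout.active_axes():
        tip = axis.direction * 1.2
        parts.append(f'<line x1="{_fmt(axis.x)}" y1="0.000000" x2="{_fmt(axis.x)}" '
                     f'y2="{_fmt(-tip)}" stroke="#777777" stroke-width="0.015000" />')
    if scene.advised_polygon is not None:
        parts.append(_svg_polygon(scene.advised_polygon, config.color_advised,
                                  config.color_advised, opacity="0.45"))
    parts.append(_svg_polygon(scene.current_polygon, config.color_current,
                              config.color_current, opacity="0.55"))
    if scene.corner_values:
        for axis in scene.layout.active_axes():
            text = scene.corner_values.get(axis.goal)
            if text is None:
                continue
            y = -(axis.direction * 1.32)
            parts.append(f'<text x="{_fmt(axis.x)}" y="{_fmt(y)}" font-size="0.1" '
                         f'text-anchor="middle">{text}</text>')
    return parts


def render_svg(scene: HexagonScene, path=None,
               config: HexagonConfig = DEFAULT_HEXAGON_CONFIG) -> str:
    """Render one scene as a deterministic standalone SVG document."""
    body = "\n".join(_glyph_fragment(scene, config))
    doc = ('<svg xmlns="http://www.w3.org/2000/svg" viewBox="-1.6 -1.5 3.2 3.0" '
           'width="320" height="300">\n' + body + "\n</svg>\n")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc


def render_history(trajectory, path=None, advised=True, shared_scale=True,
                   config: HexagonConfig = DEFAULT_HEXAGON_CONFIG,
                   penalty_config: PenaltyConfig = DEFAULT_PENALTY_CONFIG) -> str:
    """Render a trajectory as one SVG with one glyph per record, in time order.

    With ``shared_scale`` the magnification of the severest record is applied
    to every glyph so shapes are directly comparable across time.
    """
    steps = getattr(trajectory, "steps", trajectory)
    if len(steps) == 0:
        raise DomainError("cannot render an empty trajectory")
    scenes = []
    for s in steps:
        advised_pv = s.advice.predicted if (advised and not s.advice.is_null) else None
        scenes.append(compose(s.penalties, advised_pv, None, config, penalty_config))
    if shared_scale:
        common = min(sc.axis_scale for sc in scenes)
        scenes = [HexagonScene(sc.layout,
                               _rescale(sc.current_polygon, sc.axis_scale, common, config),
                               _rescale(sc.advised_polygon, sc.axis_scale, common, config),
                               sc.background_band, common, sc.corner_values)
                  for sc in scenes]
    width = 3.4
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'viewBox="-1.6 -1.5 {_fmt(width * len(scenes))} 3.0" '
             f'width="{320 * len(scenes)}" height="300">']
    for i, sc in enumerate(scenes):
        parts.append(f'<g transform="translate({_fmt(i * width)} 0)">')
        parts.extend(_glyph_fragment(sc, config))
        parts.append("</g>")
    parts.append("</svg>")
    doc = "\n".join(parts) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc)
    return doc


def _rescale(polygon, old_scale, new_scale, config: HexagonConfig):
    if polygon is None:
        return None
    out = []
    for x, y in polygon:
        sign = 1.0 if y >= 0 else -1.0
        penalty = (abs(y) - config.min_offset) / old_scale
        out.append((x, sign * drawn_length(penalty, new_scale, config)))
    return tuple(out)
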