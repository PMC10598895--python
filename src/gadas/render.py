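"""Deterministic SVG rendering of laryngoscopy scenes.

The drawing is plain SVG assembled from formatted strings: identical scenes
yield byte-identical documents, which the test-suite asserts.  A shared
:class:`Viewport` renders several scenes at one scale for side-by-side
comparison figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import Scene
from .sightline import VisibilityResult

_F = "{:.3f}"


@dataclass(frozen=True)
class Viewport:
    """Affine map from scene mm-coordinates to SVG pixels (y flipped)."""

    min_x: float
    max_y: float
    scale: float
    pad: float
    width: float
    height: float

    @classmethod
    def for_scenes(cls, scenes: list[Scene], scale: float = 3.0, pad: float = 20.0) -> "Viewport":
        pts = np.vstack(
            [
                np.vstack(
                    [
                        s.upper_incisor_apex,
                        s.lower_incisor_apex,
                        s.gnathion,
                        s.tmj_condyle,
                        s.hyoid,
                        s.glottis_anterior,
                        s.glottis_posterior,
                        s.posterior_pharyngeal_wall,
                        s.tongue_outline,
                    ]
                )
                for s in scenes
            ]
        )
        min_x, min_y = pts.min(axis=0)
        max_x, max_y = pts.max(axis=0)
        return cls(
            min_x=float(min_x),
            max_y=float(max_y),
            scale=scale,
            pad=pad,
            width=float((max_x - min_x) * scale + 2 * pad),
            height=float((max_y - min_y) * scale + 2 * pad),
        )

    def to_px(self, p: np.ndarray) -> tuple[float, float]:
        return (
            (float(p[0]) - self.min_x) * self.scale + self.pad,
            (self.max_y - float(p[1])) * self.scale + self.pad,
        )

    @property
    def params(self) -> str:
        return " ".join(_F.format(v) for v in (self.min_x, self.max_y, self.scale, self.pad))


def _poly(viewport: Viewport, pts: np.ndarray, style: str, close: bool = False) -> str:
    coords = " ".join(
        f"{_F.format(x)},{_F.format(y)}" for x, y in (viewport.to_px(p) for p in pts)
    )
    tag = "polygon" if close else "polyline"
    return f'<{tag} points="{coords}" {style}/>'


def _line(viewport: Viewport, a: np.ndarray, b: np.ndarray, style: str) -> str:
    x1, y1 = viewport.to_px(a)
    x2, y2 = viewport.to_px(b)
    return (
        f'<line x1="{_F.format(x1)}" y1="{_F.format(y1)}" '
        f'x2="{_F.format(x2)}" y2="{_F.format(y2)}" {style}/>'
    )


def _dot(viewport: Viewport, p: np.ndarray, r: float, fill: str) -> str:
    x, y = viewport.to_px(p)
    return f'<circle cx="{_F.format(x)}" cy="{_F.format(y)}" r="{_F.format(r)}" fill="{fill}"/>'


def render_scene(scene: Scene, result: VisibilityResult, viewport: Viewport | None = None) -> str:
    """Render one transformed scene with its limiting ray and V annotation."""
    vp = viewport or Viewport.for_scenes([scene])
    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_F.format(vp.width)}" '
        f'height="{_F.format(vp.height)}">'
    )
    parts.append(f'<g data-viewport="{vp.params}">')
    parts.append(
        _poly(vp, scene.posterior_pharyngeal_wall, 'fill="none" stroke="#888" stroke-width="2"')
    )
    mandible = np.vstack([scene.tmj_condyle, scene.lower_incisor_apex, scene.gnathion])
    parts.append(_poly(vp, mandible, 'fill="none" stroke="#444" stroke-width="2"'))
    parts.append(
        _poly(vp, scene.tongue_outline, 'fill="#f2c4c4" stroke="#c66" stroke-width="1"', close=True)
    )
    # limiting ray, drawn well past the glottis
    ray = result.limiting_ray
    far = ray.origin + ray.direction * 250.0
    parts.append(_line(vp, ray.origin, far, 'stroke="#2a7" stroke-width="1" stroke-dasharray="4 2"'))
    # glottal segment with the visible posterior span highlighted
    a, p = scene.glottis_anterior, scene.glottis_posterior
    parts.append(_line(vp, a, p, 'stroke="#06c" stroke-width="3"'))
    v = result.visibility_mm
    if v > 0:
        span = float(np.linalg.norm(p - a))
        x = p + (a - p) * min(v, span) / span
        parts.append(_line(vp, x, p, 'stroke="#f80" stroke-width="3"'))
    for lm, color in (
        (scene.upper_incisor_apex, "#000"),
        (scene.lower_incisor_apex, "#000"),
        (scene.gnathion, "#444"),
        (scene.tmj_condyle, "#444"),
        (scene.hyoid, "#06c"),
        (scene.thyroid_notch, "#06c"),
    ):
        parts.append(_dot(vp, lm, 2.5, color))
    ox, oy = vp.to_px(scene.upper_incisor_apex)
    parts.append(
        f'<text x="{_F.format(ox + 6.0)}" y="{_F.format(oy - 6.0)}" '
        f'font-family="monospace" font-size="12">V = {result.visibility_rounded:.1f} mm</text>'
    )
    parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
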