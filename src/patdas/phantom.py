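"""Numerical phantoms: collections of uniform circular absorbers.

A phantom is a set of disc sources, each defined by centre, radius and
initial-pressure amplitude. Complex shapes (triangle edges, vessel trees)
are approximated by dense chains of small discs, which keeps the forward
model closed-form while reproducing the target topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ValidationError

#: Half-extent of the reconstruction field of view the shaped phantoms are
#: required to fit inside (the standard 250 px x 0.1 mm/px grid => 2.5 cm).
FOV_HALF_EXTENT = 12.5e-3


@dataclass(frozen=True)
class Phantom:
    """Initial-pressure distribution as uniform disc sources.

    ``sources`` is a sequence of ``(cx, cy, radius, amplitude)`` tuples in SI
    units (metres; amplitude in arbitrary initial-pressure units).
    """

    sources: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.sources) == 0:
            raise ValidationError("phantom must contain at least one source")
        for cx, cy, radius, amplitude in self.sources:
            if not (radius > 0):
                raise ValidationError(f"source radius must be > 0, got {radius}")
            if not np.isfinite(amplitude):
                raise ValidationError("source amplitude must be finite")
            if not (np.isfinite(cx) and np.isfinite(cy)):
                raise ValidationError("source centre must be finite")

    def as_array(self) -> np.ndarray:
        """Sources as an (n, 4) array of columns cx, cy, radius, amplitude."""
        return np.asarray(self.sources, dtype=np.float64)

    def scaled(self, factor: float) -> "Phantom":
        """Same geometry with every amplitude multiplied by ``factor``."""
        return Phantom(
            tuple((cx, cy, r, a * factor) for cx, cy, r, a in self.sources)
        )


def _check_fov(sources: list[tuple[float, float, float, float]]) -> None:
    for cx, cy, r, _ in sources:
        if max(abs(cx), abs(cy)) + r > FOV_HALF_EXTENT:
            raise ValidationError(
                f"source at ({cx * 1e3:.2f}, {cy * 1e3:.2f}) mm falls outside the "
                f"{2 * FOV_HALF_EXTENT * 1e2:.1f} cm field of view"
            )


def make_point_phantom(
    spacing: float = 5e-3, point_radius: float = 0.5e-3, amplitude: float = 1.0
) -> Phantom:
    """Five point targets: one at the scan centre, four at distance ``spacing``.

    The four outer points sit on the +/-x and +/-y axes, so adjacent points
    are ``spacing`` apart and the centroid is the origin.
    """
    if not (spacing > 0):
        raise ValidationError(f"spacing must be > 0, got {spacing}")
    if not (point_radius > 0):
        raise ValidationError(f"point_radius must be > 0, got {point_radius}")
    centers = [(0.0, 0.0), (spacing, 0.0), (-spacing, 0.0), (0.0, spacing), (0.0, -spacing)]
    return Phantom(tuple((cx, cy, point_radius, amplitude) for cx, cy in centers))


def _disc_chain(
    p0: np.ndarray, p1: np.ndarray, line_radius: float, amplitude: float
) -> list[tuple[float, float, float, float]]:
    """Discs of radius ``line_radius`` along segment p0->p1, step <= line_radius."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(np.ceil(length / line_radius)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    return [
        (float(p[0]), float(p[1]), line_radius, amplitude)
        for p in (p0[None, :] + ts[:, None] * (p1 - p0)[None, :])
    ]


def make_triangle_phantom(
    side: float = 10e-3, line_radius: float = 0.3e-3, amplitude: float = 1.0
) -> Phantom:
    """Isosceles triangle outline drawn with chains of small discs.

    The base (length ``side``) is horizontal and the apex sits above it at a
    height of ``side``, with the centroid at the origin. Edge discretisation
    uses a step no larger than ``line_radius``, so consecutive discs overlap.
    """
    if not (side > 0):
        raise ValidationError(f"side must be > 0, got {side}")
    if not (line_radius > 0):
        raise ValidationError(f"line_radius must be > 0, got {line_radius}")
    height = side
    # Vertices before centring: base endpoints and apex.
    verts = np.array(
        [[-side / 2, 0.0], [side / 2, 0.0], [0.0, height]], dtype=np.float64
    )
    verts -= verts.mean(axis=0)
    sources: list[tuple[float, float, float, float]] = []
    for a, b in ((0, 1), (1, 2), (2, 0)):
        sources.extend(_disc_chain(verts[a], verts[b], line_radius, amplitude))
    _check_fov(sources)
    return Phantom(tuple(sources))


# Control polylines (mm) sketching rat-brain venous sinuses: a midline
# sagittal sinus plus two transverse sinuses and four cortical branches.
_VESSEL_POLYLINES_MM: tuple[tuple[tuple[float, float], ...], ...] = (
    # superior sagittal sinus, slightly curved midline vessel
    ((0.0, -9.0), (0.3, -4.5), (0.0, 0.0), (-0.3, 4.5), (0.0, 8.5)),
    # left transverse sinus
    ((0.0, 6.5), (-3.0, 7.2), (-6.0, 6.3), (-8.5, 4.0)),
    # right transverse sinus
    ((0.0, 6.5), (3.0, 7.2), (6.0, 6.3), (8.5, 4.0)),
    # cortical branches
    ((0.0, 2.0), (-3.5, 3.0), (-6.0, 1.5)),
    ((0.0, 2.0), (3.5, 3.0), (6.0, 1.5)),
    ((0.0, -4.0), (-3.0, -5.5), (-5.0, -8.0)),
    ((0.0, -4.0), (3.0, -5.5), (5.0, -8.0)),
)


def make_vessel_phantom(
    seed: int = 0, line_radius: float = 0.3e-3, amplitude: float = 1.0
) -> Phantom:
    """Branching vessel-tree phantom mimicking rat-brain venous sinuses.

    Fixed polylines trace a midline sagittal sinus, two transverse sinuses
    and four cortical branches; each is drawn as a chain of overlapping
    discs. ``seed`` drives a small (<= 0.15 mm) deterministic jitter of the
    control points so different seeds give distinct but topologically
    identical vasculature; the same seed always returns the same phantom.
    """
    rng = np.random.default_rng(seed)
    sources: list[tuple[float, float, float, float]] = []
    for polyline in _VESSEL_POLYLINES_MM:
        pts = np.asarray(polyline, dtype=np.float64) * 1e-3
        pts = pts + rng.uniform(-0.15e-3, 0.15e-3, size=pts.shape)
        for a, b in zip(pts[:-1], pts[1:]):
            sources.extend(_disc_chain(a, b, line_radius, amplitude))
    _check_fov(sources)
    return Phantom(tuple(sources))


def write_phantom(phantom: Phantom, path: str | Path) -> None:
    """Write a phantom as plain text: one ``cx cy radius amplitude`` line per
    source, SI units."""
    lines = ["# patdas phantom: cx_m cy_m radius_m amplitude"]
    for cx, cy, r, a in phantom.sources:
        lines.append(f"{cx!r} {cy!r} {r!r} {a!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phantom(path: str | Path) -> Phantom:
    """Read a phantom from the plain-text format of :func:`write_phantom`."""
    sources = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValidationError(
                f"{path}:{lineno}: expected 4 fields (cx cy radius amplitude), "
                f"got {len(fields)}"
            )
        sources.append(tuple(float(f) for f in fields))
    if not sources:
        raise ValidationError(f"{path}: no sources found")
    return Phantom(tuple(sources))
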