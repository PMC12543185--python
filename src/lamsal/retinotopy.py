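"""pRF coordinate correction and visual-field back-projection.

Atlas pRF coordinates are linearly rescaled so that the localizer-peak
vertex (Am, Em) lands exactly on the screen location of the foreground bars
(polar angle 127.88 deg, eccentricity 4.28 deg); angles above Am are mapped
by the complementary linear segment so 0 and 180 deg stay fixed. Depth
responses are then back-projected into the visual field by summing each
node's response-weighted isotropic Gaussian pRF image, and all depths are
divided by the single maximum across depths.

Angle convention: polar angle is measured within each hemisphere from the
upper vertical meridian (0 deg) to the lower vertical meridian (180 deg);
left-hemisphere nodes project to the right visual hemifield and vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = [
    "FOREGROUND_ANGLE",
    "FOREGROUND_ECC",
    "GridSpec",
    "FieldMap",
    "correct_prf",
    "node_center",
    "node_prf_image",
    "reconstruct_field_map",
    "average_field_maps",
]

#: Screen location of the foreground bars in corrected pRF coordinates.
FOREGROUND_ANGLE = 127.88  # degrees from the upper vertical meridian
FOREGROUND_ECC = 4.28      # degrees of eccentricity


def correct_prf(A, E, Am: float, Em: float,
                anchor_angle: float = FOREGROUND_ANGLE,
                anchor_ecc: float = FOREGROUND_ECC):
    """Piecewise-linear pRF coordinate correction.

    Maps the localizer-peak coordinates (Am, Em) onto the foreground's
    screen location: ``Ac = A / Am * anchor_angle`` for ``A <= Am`` and the
    complementary segment ``180 - (180 - A)/(180 - Am) * (180 - anchor_angle)``
    above; ``Ec = E / Em * anchor_ecc``. Continuous at Am, strictly
    increasing in A, with fixed points at 0 and 180 degrees.
    """
    if not (0.0 < Am < 180.0):
        raise InvalidArgumentError("Am must lie strictly inside (0, 180)")
    if Em <= 0:
        raise InvalidArgumentError("Em must be positive")
    A = np.asarray(A, dtype=float)
    E = np.asarray(E, dtype=float)
    if (A < 0).any() or (A > 180).any():
        raise InvalidArgumentError("A must lie in [0, 180] degrees")
    if (E < 0).any():
        raise InvalidArgumentError("E must be non-negative")
    low = A / Am * anchor_angle
    high = 180.0 - (180.0 - A) / (180.0 - Am) * (180.0 - anchor_angle)
    Ac = np.where(A <= Am, low, high)
    Ec = E / Em * anchor_ecc
    if Ac.ndim == 0:
        return float(Ac), float(Ec)
    return Ac, Ec


@dataclass(frozen=True)
class GridSpec:
    """Regular visual-field grid (degrees); default covers the lower field."""

    x_min: float = -8.0
    x_max: float = 8.0
    y_min: float = -8.0
    y_max: float = 0.0
    step: float = 0.1

    @property
    def xs(self) -> np.ndarray:
        return np.arange(self.x_min, self.x_max + self.step / 2, self.step)

    @property
    def ys(self) -> np.ndarray:
        return np.arange(self.y_min, self.y_max + self.step / 2, self.step)

    def mesh(self):
        return np.meshgrid(self.xs, self.ys)

    @property
    def cell_area(self) -> float:
        return self.step**2


def node_center(Ac: float, Ec: float, hemisphere: str):
    """Cartesian visual-field center of a corrected node.

    Angle 0 = upper vertical meridian, 180 = lower vertical; the horizontal
    offset points into the hemifield contralateral to the node's hemisphere.
    """
    if hemisphere not in ("left", "right"):
        raise InvalidArgumentError("hemisphere must be 'left' or 'right'")
    sign = 1.0 if hemisphere == "left" else -1.0
    rad = np.deg2rad(Ac)
    return sign * Ec * np.sin(rad), Ec * np.cos(rad)


def node_prf_image(Ac: float, Ec: float, sigma: float, hemisphere: str,
                   grid: GridSpec = GridSpec(),
                   warn_truncated: bool = True) -> np.ndarray:
    """Unit-volume isotropic Gaussian pRF image on the grid.

    The Gaussian density integrates to ~1 over the grid when the center lies
    well inside the extent; if the center falls outside, a warning reports
    the truncated mass.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be positive")
    x0, y0 = node_center(Ac, Ec, hemisphere)
    X, Y = grid.mesh()
    img = np.exp(-((X - x0)**2 + (Y - y0)**2) / (2.0 * sigma**2)) \
        / (2.0 * np.pi * sigma**2)
    outside = not (grid.x_min <= x0 <= grid.x_max and grid.y_min <= y0 <= grid.y_max)
    if warn_truncated and outside:
        mass = img.sum() * grid.cell_area
        warnings.warn(f"pRF center ({x0:.2f}, {y0:.2f}) outside the grid; "
                      f"truncated mass {1.0 - mass:.3f}", stacklevel=2)
    return img


@dataclass(frozen=True)
class FieldMap:
    """Back-projected visual-field maps per cortical depth."""

    maps: dict                 # depth -> 2-D array (ny, nx)
    grid: GridSpec
    normalization: float       # the pre-normalization across-depth maximum
    n_subjects: int = 1

    def peak_location(self, depth: str):
        m = self.maps[depth]
        iy, ix = np.unravel_index(np.argmax(m), m.shape)
        return float(self.grid.xs[ix]), float(self.grid.ys[iy])


def reconstruct_field_map(responses, nodes: pd.DataFrame,
                          grid: GridSpec = GridSpec(),
                          depth_key: str = "depth") -> FieldMap:
    """Back-project node responses into visual-field maps per depth.

    ``nodes`` must carry corrected coordinates (columns ``Ac``, ``Ec``),
    ``sigma``, ``hemisphere`` and a depth label column; ``responses`` is a
    per-node scalar aligned with the table. Per depth, the map is the
    response-weighted sum of node pRF images; all depths are divided by the
    single maximum across depths (skipped with a warning if all responses
    are zero).
    """
    responses = np.asarray(responses, dtype=float)
    if len(nodes) == 0:
        raise InvalidArgumentError("empty node set")
    if responses.size != len(nodes):
        raise InvalidArgumentError("responses and nodes must be aligned")
    maps = {}
    for depth in nodes[depth_key].unique():
        sub = nodes[nodes[depth_key] == depth]
        acc = np.zeros((grid.ys.size, grid.xs.size))
        for i, row in sub.iterrows():
            r = responses[nodes.index.get_loc(i)]
            if r == 0:
                continue
            acc += r * node_prf_image(row["Ac"], row["Ec"], row["sigma"],
                                      row["hemisphere"], grid,
                                      warn_truncated=False)
        maps[depth] = acc
    peak = max(m.max() for m in maps.values())
    if peak <= 0:
        warnings.warn("all-zero responses; normalization skipped", stacklevel=2)
        return FieldMap(maps, grid, 0.0)
    return FieldMap({d: m / peak for d, m in maps.items()}, grid, float(peak))


def average_field_maps(field_maps) -> FieldMap:
    """Average already-normalized subject maps (group map)."""
    field_maps = list(field_maps)
    if not field_maps:
        raise InvalidArgumentError("no field maps supplied")
    depths = field_maps[0].maps.keys()
    maps = {d: np.mean([fm.maps[d] for fm in field_maps], axis=0) for d in depths}
    return FieldMap(maps, field_maps[0].grid,
                    float(np.mean([fm.normalization for fm in field_maps])),
                    n_subjects=len(field_maps))
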