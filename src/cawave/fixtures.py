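"""Deterministic small-scale assets for tests and demos.

All fixtures are generated programmatically; identical specs produce
bit-identical objects.  ``tube_small`` and ``bif_mini`` are desk-scale
meshes, ``tube_demo`` the larger tube used for wave-propagation demos, and
``analytic_wave`` a closed-form travelling-wave kymograph used as the
oracle for the wave metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import SpaceTimeMap
from .geometry import GeometrySpec, BifurcationMesh, build_tube, \
    build_bifurcation, tile_cells

__all__ = ["FixtureSpec", "make_fixture"]

_KINDS = ("tube_small", "tube_demo", "bif_mini", "analytic_wave")


@dataclass
class FixtureSpec:
    """Recipe for one deterministic fixture."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; choose from {_KINDS}")


def _tube(quads_axial: int, quads_circ: int, diameter: float
          ) -> BifurcationMesh:
    spec = GeometrySpec(branch_length=quads_axial * 0.26, diameter=diameter,
                        quads_axial=quads_axial, quads_circ=quads_circ)
    return tile_cells(build_tube(spec))


def make_fixture(spec: FixtureSpec | str, **params):
    """Build a fixture; string kinds accept parameter overrides directly."""
    if isinstance(spec, str):
        spec = FixtureSpec(kind=spec, params=params)
    p = dict(spec.params)
    if spec.kind == "tube_small":
        # 4 x 4 quads = 16 domains, 1280 EC + 3328 SMC = 4608 cells
        return _tube(p.get("quads_axial", 4), p.get("quads_circ", 4),
                     p.get("diameter", 4 * 0.2 / np.pi))
    if spec.kind == "tube_demo":
        # 60 x 20 quads = 1200 domains, ~345k cells
        return _tube(p.get("quads_axial", 60), p.get("quads_circ", 20),
                     p.get("diameter", 20 * 0.2 / np.pi))
    if spec.kind == "bif_mini":
        g = GeometrySpec(branch_length=p.get("quads_axial", 10) * 0.26,
                         diameter=p.get("diameter", 4 * 0.2 / np.pi),
                         branch_angle=p.get("branch_angle", 30.0),
                         quads_axial=p.get("quads_axial", 10),
                         quads_circ=p.get("quads_circ", 4))
        return tile_cells(build_bifurcation(g))
    # analytic_wave: ca(x, t) = offset + A sin(k x + omega t)
    nx = p.get("n_positions", 60)
    nt = p.get("n_times", 400)
    length = p.get("length", 6.0)              # mm
    tmax = p.get("duration", 200.0)            # s
    amp = p.get("amplitude", 0.2)              # uM
    offset = p.get("offset", 0.4)              # uM
    wavelength = p.get("wavelength", 2.0)      # mm
    period = p.get("period", 20.0)             # s
    x = np.linspace(0.0, length, nx)
    t = np.linspace(0.0, tmax, nt)
    k = 2.0 * np.pi / wavelength
    omega = 2.0 * np.pi / period
    values = offset + amp * np.sin(k * x[:, None] + omega * t[None, :])
    return SpaceTimeMap(positions=x, times=t, values=values)
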