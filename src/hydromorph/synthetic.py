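"""Synthetic fused-sphere solutes and shape-scaling experiments.

Generators for the controlled geometries used throughout the test suite and
in the shape studies: single smooth spheres, sphere pairs in contact,
hexagonally packed single-layer discs (and stacks of two), self-avoiding
sphere chains, and hollow shells enclosing a sealed cavity.  All generators
are deterministic for a fixed seed.

The shape experiments probe how the water-entropy gain on association
scales with solute size: for two large smooth spheres of diameter ``dL``
brought into contact the gain grows linearly in ``dL/dS``, while stacking
two discs of surface diameter ``D`` gains entropy in proportion to
``(D/dS)^2``.  Only these scaling exponents are calibration-independent;
absolute gains depend on the morphometric coefficients supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_DS
from .geometry import ProbeSpec, SoluteBody, accessible_measures
from .morphometric import MACoefficients, hydration_entropy

__all__ = [
    "ShapeSpec",
    "make_shape",
    "disc_stack",
    "sphere_pair_bound",
    "shape_scaling_experiment",
    "hex_disc_count",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Specification of a synthetic fused-sphere solute.

    ``kind`` is one of ``sphere | sphere_pair | disc | chain | shell``.
    ``dL`` is a sphere diameter, ``D`` a disc/shell span, ``thickness`` a
    shell wall allowance, ``separation`` a surface-to-surface gap for
    ``sphere_pair`` (0 = contact), and ``atom_diameter`` the size of the
    constituent spheres for composite bodies.
    """

    kind: str
    dL: float | None = None
    D: float | None = None
    thickness: float | None = None
    n_atoms: int | None = None
    atom_diameter: float = DEFAULT_DS
    separation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("sphere", "sphere_pair", "disc", "chain", "shell"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for val in (self.dL, self.D, self.thickness):
            if val is not None and val <= 0:
                raise ValueError("shape sizes must be positive")
        if self.atom_diameter <= 0:
            raise ValueError("atom diameter must be positive")
        if self.thickness is not None and self.D is not None and self.thickness > self.D:
            raise ValueError("inconsistent shape sizes: thickness exceeds span")


def _hex_lattice(span: float, a: float) -> np.ndarray:
    """Hexagonal lattice points with spacing ``a`` inside radius span/2."""
    r_max = span / 2.0
    pts = []
    jmax = int(np.ceil(r_max / (a * np.sqrt(3) / 2))) + 1
    imax = int(np.ceil(r_max / a)) + 1
    for j in range(-jmax, jmax + 1):
        y = j * a * np.sqrt(3) / 2.0
        for i in range(-imax, imax + 1):
            x = (i + 0.5 * (j % 2)) * a
            if x * x + y * y <= r_max * r_max + 1e-9:
                pts.append((x, y, 0.0))
    return np.array(pts)


def hex_disc_count(D: float, atom_diameter: float) -> int:
    """Atom count of a hexagonally packed disc spanning ``D`` (lattice census)."""
    return len(_hex_lattice(D - atom_diameter, atom_diameter))


def make_shape(spec: ShapeSpec) -> SoluteBody:
    """Build the fused-sphere body described by ``spec`` (seed-deterministic)."""
    a = spec.atom_diameter
    if spec.kind == "sphere":
        if spec.dL is None:
            raise ValueError("sphere requires dL")
        return SoluteBody(np.zeros((1, 3)), np.array([spec.dL]), label=f"sphere-{spec.dL:g}")
    if spec.kind == "sphere_pair":
        if spec.dL is None:
            raise ValueError("sphere_pair requires dL")
        gap = spec.dL + spec.separation
        centers = np.array([[0.0, 0.0, 0.0], [gap, 0.0, 0.0]])
        return SoluteBody(centers, np.full(2, spec.dL),
                          label=f"sphere-pair-{spec.dL:g}@{spec.separation:g}")
    if spec.kind == "disc":
        if spec.D is None:
            raise ValueError("disc requires D")
        pts = _hex_lattice(spec.D - a, a)
        return SoluteBody(pts, np.full(len(pts), a), label=f"disc-{spec.D:g}")
    if spec.kind == "chain":
        n = spec.n_atoms or 10
        rng = np.random.default_rng(spec.seed)
        pts = [np.zeros(3)]
        while len(pts) < n:
            v = rng.normal(size=3)
            cand = pts[-1] + a * v / np.linalg.norm(v)
            # self-avoidance: no overlap with non-adjacent beads
            if all(np.linalg.norm(cand - p) >= a * 0.999 for p in pts[:-1]):
                pts.append(cand)
        pts = np.array(pts)
        return SoluteBody(pts, np.full(n, a), label=f"chain-{n}")
    if spec.kind == "shell":
        if spec.D is None:
            raise ValueError("shell requires D")
        # beads on a sphere of diameter D, spaced tightly enough that the
        # accessible shells fuse into a watertight wall around the cavity
        r_shell = spec.D / 2.0
        n = max(12, int(np.ceil(4.0 * np.pi * r_shell**2 / (0.5 * a) ** 2)))
        i = np.arange(n) + 0.5
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - 2.0 * i / n
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        pts = r_shell * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        return SoluteBody(pts, np.full(n, a), label=f"shell-{spec.D:g}")
    raise AssertionError


def sphere_pair_bound(dL: float) -> tuple[SoluteBody, SoluteBody, SoluteBody]:
    """(complex, part, part) for two smooth spheres of diameter dL in contact."""
    bound = make_shape(ShapeSpec("sphere_pair", dL=dL, separation=0.0))
    single = make_shape(ShapeSpec("sphere", dL=dL))
    return bound, single, single


def disc_stack(D: float, atom_diameter: float = DEFAULT_DS
               ) -> tuple[SoluteBody, SoluteBody, SoluteBody]:
    """(stack, disc, disc) for two hexagonal discs stacked in contact."""
    disc = make_shape(ShapeSpec("disc", D=D, atom_diameter=atom_diameter))
    top = SoluteBody(disc.centers + np.array([0.0, 0.0, atom_diameter]),
                     disc.diameters, label=disc.label + "-top")
    stack = disc + top
    stack.label = f"disc-stack-{D:g}"
    return stack, disc, top


def shape_scaling_experiment(kind: str, sizes, coeffs: MACoefficients,
                             probe: ProbeSpec = ProbeSpec(),
                             resolution: float = 0.25) -> dict:
    """Water-entropy gain on contact/stacking versus solute size.

    For each size the gain ``Delta S_VH / k_B = S(bound) - 2 S(part)`` is
    evaluated through the geometry engine and the supplied coefficients; a
    log-log regression of gain against size gives the scaling exponent.

    Returns a dict with ``sizes``, ``gains`` (k_B) and ``exponent``.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if len(sizes) < 4:
        raise ValueError("need >= 4 sizes for a scaling exponent")
    if kind not in ("sphere_pair", "disc_stack"):
        raise ValueError(f"unknown experiment kind {kind!r}")
    gains = []
    for size in sizes:
        if kind == "sphere_pair":
            bound, p1, p2 = sphere_pair_bound(size)
        else:
            bound, p1, p2 = disc_stack(size)
        s_bound = hydration_entropy(accessible_measures(bound, probe, resolution), coeffs)
        s_p1 = hydration_entropy(accessible_measures(p1, probe, resolution), coeffs)
        s_p2 = s_p1 if kind == "sphere_pair" else hydration_entropy(
            accessible_measures(p2, probe, resolution), coeffs)
        gains.append(s_bound - s_p1 - s_p2)
    gains = np.array(gains)
    if np.all(gains > 0):
        exponent = float(np.polyfit(np.log(sizes), np.log(gains), 1)[0])
    else:
        exponent = float("nan")
    return {"sizes": sizes, "gains": gains, "exponent": exponent}
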