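"""Molecular-mechanics conformational-energy components.

The conformational energy of an isolated solute decomposes as
``E_C = E_B + E_LJ + E_ES``: bonded (bond-stretch, angle-bend, torsion)
terms, Lennard-Jones pair interactions and Coulomb pair interactions.
Systems are treated at infinite dilution: no distance cutoff, no periodic
boundary, no lattice summation.  Lorentz-Berthelot combining (arithmetic
sigma, geometric epsilon) is used for unlike pairs, and intramolecular
nonbonded sums honour an exclusion/scaling list (Amber-style: 1-2 and 1-3
excluded, 1-4 scaled by 1/1.2 for electrostatics and 1/2 for LJ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .constants import COULOMB_K

__all__ = [
    "ChargedAtom",
    "MolecularSystem",
    "EnergyComponents",
    "pair_lj",
    "intermolecular_energy",
    "conformational_energy",
    "SCALE_ES_14",
    "SCALE_LJ_14",
]

#: Amber-convention 1-4 scale factors (configurable per exclusion entry).
SCALE_ES_14 = 1.0 / 1.2
SCALE_LJ_14 = 0.5


@dataclass(frozen=True)
class ChargedAtom:
    """An atom carrying LJ parameters and a partial charge."""

    center: np.ndarray
    sigma: float
    epsilon: float
    charge: float
    name: str = ""
    residue: str = ""

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("atom center must be a finite 3-vector")
        object.__setattr__(self, "center", c)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


class BondTerm(NamedTuple):
    i: int
    j: int
    k_r: float   # kcal/mol/Å^2
    r0: float    # Å


class AngleTerm(NamedTuple):
    i: int
    j: int
    k: int
    k_theta: float  # kcal/mol/rad^2
    theta0: float   # degrees


class TorsionTerm(NamedTuple):
    i: int
    j: int
    k: int
    l: int
    barrier: float    # kcal/mol (V_n / 2)
    periodicity: int
    phase: float      # degrees


@dataclass
class MolecularSystem:
    """Array-backed molecular system for nonbonded/bonded energy evaluation.

    ``exclusions`` maps ordered index pairs ``(i, j)``, ``i < j``, to
    ``(scale_lj, scale_es)`` factors in [0, 1]; a factor of 0 removes the
    pair (1-2/1-3 neighbours), fractional factors implement 1-4 scaling.
    ``bonded_terms`` is optional; without it ``E_B`` is reported as absent.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    charges: np.ndarray
    names: list[str] = field(default_factory=list)
    residues: list[str] = field(default_factory=list)
    exclusions: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    bonded_terms: list | None = None
    label: str = ""

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        n = self.centers.shape[0]
        self.sigmas = np.broadcast_to(np.asarray(self.sigmas, dtype=float), (n,)).copy()
        self.epsilons = np.broadcast_to(np.asarray(self.epsilons, dtype=float), (n,)).copy()
        self.charges = np.broadcast_to(np.asarray(self.charges, dtype=float), (n,)).copy()
        if not self.names:
            self.names = [""] * n
        if not self.residues:
            self.residues = [""] * n
        for (i, j), (slj, ses) in self.exclusions.items():
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"exclusion pair ({i}, {j}) references invalid atoms")
            if not (0.0 <= slj <= 1.0 and 0.0 <= ses <= 1.0):
                raise ValueError("exclusion scale factors must lie in [0, 1]")

    @classmethod
    def from_atoms(cls, atoms: Iterable[ChargedAtom], **kw) -> "MolecularSystem":
        atoms = list(atoms)
        return cls(
            centers=np.array([a.center for a in atoms]),
            sigmas=np.array([a.sigma for a in atoms]),
            epsilons=np.array([a.epsilon for a in atoms]),
            charges=np.array([a.charge for a in atoms]),
            names=[a.name for a in atoms],
            residues=[a.residue for a in atoms],
            **kw,
        )

    def __len__(self) -> int:
        return self.centers.shape[0]

    def combined_with(self, other: "MolecularSystem", label: str = "") -> "MolecularSystem":
        """Concatenate two systems (exclusions re-indexed; no cross exclusions)."""
        n = len(self)
        excl = dict(self.exclusions)
        for (i, j), s in other.exclusions.items():
            excl[(i + n, j + n)] = s
        bonded = None
        if self.bonded_terms is not None or other.bonded_terms is not None:
            bonded = list(self.bonded_terms or [])
            for t in other.bonded_terms or []:
                idx = [x + n for x in t[: len(t) - _n_params(t)]]
                bonded.append(type(t)(*idx, *t[len(idx):]))
        return MolecularSystem(
            centers=np.vstack([self.centers, other.centers]),
            sigmas=np.concatenate([self.sigmas, other.sigmas]),
            epsilons=np.concatenate([self.epsilons, other.epsilons]),
            charges=np.concatenate([self.charges, other.charges]),
            names=self.names + other.names,
            residues=self.residues + other.residues,
            exclusions=excl,
            bonded_terms=bonded,
            label=label or f"{self.label}+{other.label}",
        )


def _n_params(term) -> int:
    return {BondTerm: 2, AngleTerm: 2, TorsionTerm: 3}[type(term)]


class EnergyComponents(NamedTuple):
    """(E_B, E_LJ, E_ES) in kcal/mol; ``E_B`` is None when no bonded terms."""

    E_B: float | None
    E_LJ: float
    E_ES: float


def pair_lj(r: float, sigma_ij: float, epsilon_ij: float) -> float:
    """Lennard-Jones pair energy ``4 eps [(sigma/r)^12 - (sigma/r)^6]``."""
    if r <= 0:
        raise ValueError("coincident atoms: r must be positive")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


def _pair_matrices(A: MolecularSystem, B: MolecularSystem):
    diff = A.centers[:, None, :] - B.centers[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    sig = 0.5 * (A.sigmas[:, None] + B.sigmas[None, :])
    eps = np.sqrt(A.epsilons[:, None] * B.epsilons[None, :])
    qq = A.charges[:, None] * B.charges[None, :]
    return r, sig, eps, qq


def intermolecular_energy(A: MolecularSystem, B: MolecularSystem) -> tuple[float, float]:
    """Full inter-system (E_LJ, E_ES) double sum, kcal/mol, no cutoff.

    This is exactly the path-I interaction gain: for a complex whose parts
    keep their bound coordinates, ``E(complex) - E(A) - E(B)`` equals this
    pair sum, component by component.
    """
    r, sig, eps, qq = _pair_matrices(A, B)
    if np.any(r <= 0.0):
        raise ValueError("coincident atoms across systems")
    sr6 = (sig / r) ** 6
    e_lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    e_es = float(COULOMB_K * np.sum(qq / r))
    return e_lj, e_es


def _bonded_energy(S: MolecularSystem) -> float:
    x = S.centers
    e = 0.0
    for t in S.bonded_terms:
        if isinstance(t, BondTerm):
            r = np.linalg.norm(x[t.j] - x[t.i])
            e += t.k_r * (r - t.r0) ** 2
        elif isinstance(t, AngleTerm):
            v1 = x[t.i] - x[t.j]
            v2 = x[t.k] - x[t.j]
            cosang = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
            e += t.k_theta * (math.acos(cosang) - math.radians(t.theta0)) ** 2
        elif isinstance(t, TorsionTerm):
            b1 = x[t.j] - x[t.i]
            b2 = x[t.k] - x[t.j]
            b3 = x[t.l] - x[t.k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2))
            phi = math.atan2(m1 @ n2, n1 @ n2)
            e += t.barrier * (1.0 + math.cos(t.periodicity * phi - math.radians(t.phase)))
        else:
            raise ValueError(f"missing parameters for bonded term {t!r}")
    return e


def conformational_energy(S: MolecularSystem) -> EnergyComponents:
    """Intramolecular (E_B, E_LJ, E_ES) with exclusions and 1-4 scaling.

    All unordered atom pairs are summed; pairs present in ``S.exclusions``
    are multiplied by their (scale_lj, scale_es) factors.  ``E_B`` is
    evaluated from ``bonded_terms`` when present, else reported as ``None``.
    """
    n = len(S)
    if n < 2:
        eb = _bonded_energy(S) if S.bonded_terms is not None else None
        return EnergyComponents(eb, 0.0, 0.0)
    r, sig, eps, qq = _pair_matrices(S, S)
    iu, ju = np.triu_indices(n, k=1)
    rr = r[iu, ju]
    if np.any(rr <= 0.0):
        raise ValueError("coincident atoms: zero interatomic distance")
    s_lj = np.ones(len(iu))
    s_es = np.ones(len(iu))
    for (i, j), (slj, ses) in S.exclusions.items():
        a, b = (i, j) if i < j else (j, i)
        k = np.flatnonzero((iu == a) & (ju == b))
        s_lj[k] = slj
        s_es[k] = ses
    sr6 = (sig[iu, ju] / rr) ** 6
    e_lj = float(np.sum(s_lj * 4.0 * eps[iu, ju] * (sr6 * sr6 - sr6)))
    e_es = float(COULOMB_K * np.sum(s_es * qq[iu, ju] / rr))
    e_b = _bonded_energy(S) if S.bonded_terms is not None else None
    return EnergyComponents(e_b, e_lj, e_es)
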