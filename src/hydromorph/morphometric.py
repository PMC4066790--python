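"""Morphometric form of the hydration entropy and its hard-sphere calibration.

The hydration entropy of a solute under isochoric insertion is expressed as
a linear combination of the four Minkowski measures of its water-accessible
body::

    S_VH / k_B = C1 * V_ex + C2 * A + C3 * X + C4 * Y

The four coefficients depend only on the solvent.  They are calibrated by a
least-squares fit of the same form to the hydration entropies of spherical
solutes over a range of diameters ``d_U`` (for a sphere the measures reduce
to ``4 pi R^3 / 3, 4 pi R^2, 4 pi R, 4 pi`` with ``R = (d_U + d_S)/2``).

As the bundled calibration source this module provides the scaled-particle
theory (SPT) hydration entropy of a hard-sphere solute in a hard-sphere
solvent.  For a hard-sphere fluid the insertion work is purely entropic, so
``S_VH / k_B = -beta W(R)`` with ``W`` the cavity-creation work.  SPT gives
``beta W`` exactly as ``-ln(1 - eta (2R/dS)^3)`` for ``R <= dS/2`` and as a
cubic polynomial in ``R`` beyond, matched in value and slope at ``R = dS/2``
and anchored at large ``R`` by the SPT (Percus-Yevick compressibility)
pressure.  An SPT-generated table is therefore *exactly* cubic in ``R`` and
the fit recovers it to round-off.

Coefficients calibrated this way describe a simple hard-sphere solvent, not
a multipolar water model; users with externally calibrated coefficients can
supply them directly (see :class:`MACoefficients`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_DS, DEFAULT_ETA, DEFAULT_T, RHO_WATER
from .geometry import MorphoMeasures

__all__ = [
    "MACoefficients",
    "HardSphereEntropyTable",
    "spt_hs_entropy",
    "spt_table",
    "fit_ma_coefficients",
    "hydration_entropy",
]


@dataclass(frozen=True)
class MACoefficients:
    """Morphometric coefficients (C1: Å^-3, C2: Å^-2, C3: Å^-1, C4: 1).

    For a physically meaningful dense solvent ``C1 < 0``: creating excluded
    volume always costs solvent entropy.  ``provenance`` records where the
    values came from (a fit, or "config" for user-supplied numbers).
    """

    C1: float
    C2: float
    C3: float
    C4: float
    provenance: str = "config"
    residual_rms: float = float("nan")

    def __post_init__(self):
        vals = (self.C1, self.C2, self.C3, self.C4)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.C1, self.C2, self.C3, self.C4])


@dataclass
class HardSphereEntropyTable:
    """Hydration entropies of hard-sphere solutes used to fit C1..C4.

    ``dU`` are solute hard-sphere diameters (Å) and ``s`` the corresponding
    ``S_VH / k_B`` values; ``dS``, ``T`` and ``rho_S`` document the solvent
    state the entropies refer to.
    """

    dU: np.ndarray
    s: np.ndarray
    dS: float = DEFAULT_DS
    T: float = DEFAULT_T
    rho_S: float = RHO_WATER

    def __post_init__(self):
        self.dU = np.atleast_1d(np.asarray(self.dU, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if self.dU.shape != self.s.shape:
            raise ValueError("dU and s must have matching shapes")
        if np.any(self.dU < 0):
            raise ValueError("solute diameters must be non-negative")
        if len(np.unique(self.dU)) < 4:
            raise ValueError("underdetermined fit: need >= 4 distinct solute diameters")


def _spt_beta_w(R: np.ndarray, eta: float) -> np.ndarray:
    """SPT work (in k_B T) of creating a cavity of center-exclusion radius R.

    ``R`` is in units of the solvent diameter.  Exact logarithmic branch for
    R <= 1/2; matched cubic with the SPT/PY pressure beyond.
    """
    R = np.asarray(R, dtype=float)
    one = 1.0 - eta
    # cubic-branch coefficients from the matching conditions at R = 1/2
    A = -3.0 * eta * (1.0 + eta) / one**3
    B = 3.0 * eta**2 / one**3
    bp_term = 8.0 * eta * (1.0 + eta + eta * eta) / one**3  # (4 pi / 3) beta P
    small = R <= 0.5
    out = np.empty_like(R)
    with np.errstate(invalid="ignore"):
        out[small] = -np.log(1.0 - 8.0 * eta * R[small] ** 3)
    Rb = R[~small]
    out[~small] = (
        -np.log(one)
        + bp_term * (Rb**3 - 0.125)
        + 6.0 * eta * A * (Rb**2 - 0.25)
        + 6.0 * eta * B * (Rb - 0.5)
    )
    return out


def spt_hs_entropy(dU, dS: float = DEFAULT_DS, eta: float = DEFAULT_ETA):
    """Hydration entropy ``S_VH / k_B`` of a hard-sphere solute, from SPT.

    Parameters
    ----------
    dU
        Solute hard-sphere diameter in Å (scalar or array, >= 0).
    dS
        Solvent hard-sphere diameter in Å.
    eta
        Solvent packing fraction, in (0, 0.74).  The default matches water's
        number density 0.0333 Å^-3 at ``dS`` = 2.8 Å.

    Returns
    -------
    ``-beta W(R)`` with ``R = (dU + dS)/2``: negative (insertion restricts
    the solvent's configurational freedom).  At ``dU = 0`` the exact
    point-solute value ``ln(1 - eta)`` is recovered.
    """
    if not (0.0 < eta < 0.74):
        raise ValueError("unphysical packing fraction: eta must be in (0, 0.74)")
    dU_arr = np.asarray(dU, dtype=float)
    if np.any(dU_arr < 0):
        raise ValueError("solute diameter must be non-negative")
    if dS <= 0:
        raise ValueError("solvent diameter must be positive")
    R = (dU_arr + dS) / (2.0 * dS)
    out = -_spt_beta_w(R, eta)
    return float(out) if np.isscalar(dU) or dU_arr.ndim == 0 else out


def spt_table(dU_grid: np.ndarray | None = None, dS: float = DEFAULT_DS,
              eta: float = DEFAULT_ETA, T: float = DEFAULT_T) -> HardSphereEntropyTable:
    """SPT-generated calibration table over a solute-diameter grid.

    The default grid spans 0.1 to 10 water diameters (40 points), wide enough
    to separate the four geometric basis functions cleanly.
    """
    if dU_grid is None:
        dU_grid = np.linspace(0.1 * dS, 10.0 * dS, 40)
    dU_grid = np.asarray(dU_grid, dtype=float)
    rho = 6.0 * eta / (np.pi * dS**3)
    return HardSphereEntropyTable(dU=dU_grid, s=spt_hs_entropy(dU_grid, dS, eta),
                                  dS=dS, T=T, rho_S=rho)


def fit_ma_coefficients(table: HardSphereEntropyTable) -> MACoefficients:
    """Least-squares fit of the morphometric form to a hard-sphere table.

    Solves ``s_i = C1 (4 pi R_i^3 / 3) + C2 (4 pi R_i^2) + C3 (4 pi R_i)
    + C4 (4 pi)`` with ``R_i = (dU_i + dS)/2`` by ordinary least squares and
    stores the residual RMS on the returned coefficients.
    """
    R = (table.dU + table.dS) / 2.0
    design = np.column_stack([
        4.0 * np.pi * R**3 / 3.0,
        4.0 * np.pi * R**2,
        4.0 * np.pi * R,
        4.0 * np.pi * np.ones_like(R),
    ])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("underdetermined fit: design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(design, table.s, rcond=None)
    resid = table.s - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return MACoefficients(*map(float, coef),
                          provenance=f"fit:n={len(table.dU)},dS={table.dS},T={table.T}",
                          residual_rms=rms)


def hydration_entropy(measures: MorphoMeasures, coeffs: MACoefficients) -> float:
    """``S_VH / k_B`` of a solute from its measures and the coefficients."""
    return float(coeffs.as_array() @ measures.as_array())
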