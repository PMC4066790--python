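"""Binding free-energy function and its three-path decomposition.

For a solute at infinite dilution define the free-energy function

    G = E_B + (E_LJ + eps_VH,LJ) + (E_ES + eps_VH,ES) - T S_C - T S_VH

where the bracketed sums are the LJ and electrostatic components of the
total energy, ``S_C`` the solute conformational entropy and ``S_VH`` the
(isochoric) hydration entropy.  Binding of a rigid receptor R and a peptide
P that folds upon binding is decomposed along three paths:

* path I: the bound partners are simply separated without structural change;
* path III: the isolated peptide goes from its random-coil ensemble to the
  bound compact structure;
* path II = I + III: the physically realised binding, with the additivity
  ``Delta^II X = Delta^I X + Delta^III X`` holding component by component.

Entropic quantities are carried as ``T*S`` in kcal/mol at the stated
temperature (so tables read directly in energy units); helpers convert to
``k_B`` units via ``k_B T = R T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .constants import (
    ALPHA_WATER,
    DEFAULT_DS,
    DEFAULT_T,
    KAPPA_T_WATER,
    KB_J,
    R_KCAL,
)

__all__ = [
    "SpeciesThermo",
    "PathResult",
    "WaterProperties",
    "FitterInput",
    "free_energy",
    "path_delta",
    "path2_from_additivity",
    "fitter_conf_entropy",
    "isochoric_to_isobaric",
    "isobaric_correction",
    "kd_to_binding_free_energy",
    "ensemble_summary",
    "EnsembleSummary",
]

_COMPONENTS = ("E_B", "E_LJ", "E_ES", "eps_VH_LJ", "eps_VH_ES", "TS_VH", "TS_C")


@dataclass(frozen=True)
class SpeciesThermo:
    """Per-species thermodynamic components, kcal/mol at temperature ``T``.

    ``TS_VH`` stores ``T * S_VH`` (so the hydration-entropy contribution to
    ``G`` is ``-TS_VH``); likewise ``TS_C`` for the conformational entropy.
    ``E_B`` and ``TS_C`` are optional — when ``None`` they contribute zero
    and downstream results carry an explicit omission flag.
    """

    label: str
    E_LJ: float
    E_ES: float
    eps_VH_LJ: float
    eps_VH_ES: float
    TS_VH: float
    E_B: float | None = None
    TS_C: float | None = None
    T: float = DEFAULT_T

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        for name in _COMPONENTS:
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"component {name} must be finite")

    def s_vh_kB(self) -> float:
        """S_VH in units of k_B (uses k_B T = R T at the stored T)."""
        return self.TS_VH / (R_KCAL * self.T)


def free_energy(s: SpeciesThermo) -> float:
    """G = E_B + (E_LJ + eps_VH,LJ) + (E_ES + eps_VH,ES) - TS_C - TS_VH.

    Absent optional components (``E_B``, ``TS_C``) contribute zero.
    """
    e_b = s.E_B or 0.0
    ts_c = s.TS_C or 0.0
    return (e_b + s.E_LJ + s.eps_VH_LJ + s.E_ES + s.eps_VH_ES) - ts_c - s.TS_VH


@dataclass(frozen=True)
class PathResult:
    """Delta-components of the free-energy function along one path, kcal/mol.

    Internal identities (these are definitions, not approximations)::

        d_LJ_component = dE_LJ + dEps_LJ
        d_ES_component = dE_ES + dEps_ES
        dE_total       = dE_B + d_LJ_component + d_ES_component
        dG             = dE_total + mTdS_VH + mTdS_C

    ``mTdS_VH`` is ``-T Delta S_VH`` (negative when water entropy is
    gained); ``s_c_omitted`` flags results where no conformational-entropy
    term was available and ``mTdS_C`` was taken as zero.
    """

    path_id: str
    model_label: str
    dG: float
    dE_total: float
    mTdS_VH: float
    dE_B: float
    d_LJ_component: float
    d_ES_component: float
    dE_LJ: float
    dEps_LJ: float
    dE_ES: float
    dEps_ES: float
    mTdS_C: float = 0.0
    s_c_omitted: bool = True

    def __post_init__(self):
        if self.path_id not in ("I", "II", "III"):
            raise ValueError("path_id must be 'I', 'II' or 'III'")

    def validate(self, tol: float = 1e-9) -> None:
        """Assert the defining identities to ``tol`` (raises on violation)."""
        checks = {
            "d_LJ_component": self.dE_LJ + self.dEps_LJ - self.d_LJ_component,
            "d_ES_component": self.dE_ES + self.dEps_ES - self.d_ES_component,
            "dE_total": self.dE_B + self.d_LJ_component + self.d_ES_component - self.dE_total,
            "dG": self.dE_total + self.mTdS_VH + self.mTdS_C - self.dG,
        }
        for name, err in checks.items():
            if abs(err) > tol:
                raise AssertionError(f"identity violated for {name}: {err:g}")


def path_delta(complex_s: SpeciesThermo, parts: Sequence[SpeciesThermo],
               path_id: str, model_label: str | None = None) -> PathResult:
    """Componentwise ``complex - sum(parts)`` for one path.

    For path I (rigid separation) ``Delta E_B`` and ``Delta S_C`` are zero
    by construction and are forced to zero regardless of the inputs.
    ``model_label`` names the structural model the result belongs to
    (default: the label of ``complex_s``); path-I and path-III results can
    only be combined into a path-II result when their labels agree.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("empty parts")

    def delta(name):
        vals = [getattr(complex_s, name)] + [getattr(p, name) for p in parts]
        if any(v is None for v in vals):
            return None
        return vals[0] - sum(vals[1:])

    d_e_lj = delta("E_LJ")
    d_eps_lj = delta("eps_VH_LJ")
    d_e_es = delta("E_ES")
    d_eps_es = delta("eps_VH_ES")
    m_tds_vh = -delta("TS_VH")
    if path_id == "I":
        d_e_b, m_tds_c = 0.0, 0.0
        s_c_omitted = False
    else:
        d_e_b = delta("E_B") or 0.0
        d_ts_c = delta("TS_C")
        s_c_omitted = d_ts_c is None
        m_tds_c = 0.0 if s_c_omitted else -d_ts_c
    d_lj = d_e_lj + d_eps_lj
    d_es = d_e_es + d_eps_es
    d_e_total = d_e_b + d_lj + d_es
    return PathResult(
        path_id=path_id,
        model_label=model_label if model_label is not None else complex_s.label,
        dG=d_e_total + m_tds_vh + m_tds_c,
        dE_total=d_e_total,
        mTdS_VH=m_tds_vh,
        dE_B=d_e_b,
        d_LJ_component=d_lj,
        d_ES_component=d_es,
        dE_LJ=d_e_lj,
        dEps_LJ=d_eps_lj,
        dE_ES=d_e_es,
        dEps_ES=d_eps_es,
        mTdS_C=m_tds_c,
        s_c_omitted=s_c_omitted,
    )


def path2_from_additivity(p1: PathResult, p3: PathResult) -> PathResult:
    """Path II result from ``Delta^II = Delta^I + Delta^III`` (componentwise)."""
    if p1.path_id != "I" or p3.path_id != "III":
        raise ValueError("additivity needs a path-I and a path-III result")
    if p1.model_label != p3.model_label:
        raise ValueError(
            f"label mismatch: {p1.model_label!r} vs {p3.model_label!r}")
    return PathResult(
        path_id="II",
        model_label=p1.model_label,
        dG=p1.dG + p3.dG,
        dE_total=p1.dE_total + p3.dE_total,
        mTdS_VH=p1.mTdS_VH + p3.mTdS_VH,
        dE_B=p1.dE_B + p3.dE_B,
        d_LJ_component=p1.d_LJ_component + p3.d_LJ_component,
        d_ES_component=p1.d_ES_component + p3.d_ES_component,
        dE_LJ=p1.dE_LJ + p3.dE_LJ,
        dEps_LJ=p1.dEps_LJ + p3.dEps_LJ,
        dE_ES=p1.dE_ES + p3.dE_ES,
        dEps_ES=p1.dEps_ES + p3.dEps_ES,
        mTdS_C=p1.mTdS_C + p3.mTdS_C,
        s_c_omitted=p1.s_c_omitted or p3.s_c_omitted,
    )


@dataclass(frozen=True)
class WaterProperties:
    """Pure-water properties for the isochoric -> isobaric conversion.

    Defaults are the standard experimental values at 298 K: isobaric
    thermal expansion ``alpha`` = 2.57e-4 K^-1 and isothermal
    compressibility ``kappa_T`` = 4.52e-10 Pa^-1.
    """

    alpha: float = ALPHA_WATER
    kappa_T: float = KAPPA_T_WATER
    T: float = DEFAULT_T
    dS: float = DEFAULT_DS

    def __post_init__(self):
        if min(self.alpha, self.kappa_T, self.T, self.dS) <= 0:
            raise ValueError("water properties must all be positive")

    def alpha_star_over_kappa_star(self) -> float:
        """Dimensionless ratio alpha* / kappa_T* = alpha dS^3 / (kappa_T k_B)."""
        ds3_m3 = (self.dS * 1e-10) ** 3
        return self.alpha * ds3_m3 / (self.kappa_T * KB_J)


def isobaric_correction(w: WaterProperties = WaterProperties()) -> float:
    """``k_B T (alpha*/kappa_T*)`` in kcal/mol per unit ``dV_PH/dS^3``."""
    return R_KCAL * w.T * w.alpha_star_over_kappa_star()


def isochoric_to_isobaric(dEps_VH: float, dS_VH_kB: float, dV_PH_dS3: float,
                          w: WaterProperties = WaterProperties()) -> tuple[float, float]:
    """Convert isochoric hydration changes to isobaric ones.

    Parameters
    ----------
    dEps_VH
        Change of the isochoric hydration energy, kcal/mol.
    dS_VH_kB
        Change of the isochoric hydration entropy, in k_B units.
    dV_PH_dS3
        System-volume change in units of ``dS^3``.
    w
        Pure-water properties (``alpha* = alpha T``,
        ``kappa_T* = kappa_T k_B T / dS^3``).

    Returns
    -------
    ``(dH, dS_PH_kB)``: hydration-enthalpy change in kcal/mol and isobaric
    hydration-entropy change in k_B.  The hydration free-energy change
    ``dMu_H = dEps_VH - T dS_VH = dH - T dS_PH`` is invariant under the
    conversion (exactly, by construction).
    """
    ratio = w.alpha_star_over_kappa_star()
    corr_kcal = R_KCAL * w.T * ratio * dV_PH_dS3
    return dEps_VH + corr_kcal, dS_VH_kB + ratio * dV_PH_dS3


def kd_to_binding_free_energy(kD: float, T: float = DEFAULT_T) -> float:
    """Binding free energy from a dissociation constant: ``R T ln(kD/1M)``.

    Negative for sub-molar ``kD``, i.e. the sign of the reported binding
    free energy of a favourable binder.  (The frequently quoted expression
    ``-RT ln kD`` gives the opposite, positive sign for ``kD < 1 M``; this
    function follows the reported-value convention.)  Standard state 1 mol/l,
    unit activity coefficient.
    """
    if kD <= 0:
        raise ValueError("dissociation constant must be positive")
    return R_KCAL * T * float(np.log(kD))


@dataclass(frozen=True)
class FitterInput:
    """Inputs for the residue-wise conformational-entropy estimate.

    ``observations`` are ``(T, r_u, r_f)`` triples: temperature and the
    free-motion radius parameters of the unfolded and folded states from
    incoherent neutron scattering; the loss per residue is
    ``-3 k_B ln(r_u/r_f)`` evaluated at ``T_target`` after a linear fit of
    each radius against temperature.
    """

    N_r: int
    observations: tuple
    T_target: float = DEFAULT_T

    def __post_init__(self):
        obs = tuple(tuple(map(float, o)) for o in self.observations)
        object.__setattr__(self, "observations", obs)
        if self.N_r <= 0:
            raise ValueError("residue count must be positive")
        if len(obs) < 2:
            raise ValueError("need >= 2 observation temperatures for the linear fit")
        if any(o[1] <= 0 or o[2] <= 0 for o in obs):
            raise ValueError("unphysical radii: radius parameters must be positive")


def fitter_conf_entropy(f: FitterInput) -> float:
    """Conformational-entropy loss ``-T dS_C = 3 k_B T N_r ln(r_u/r_f)``, kcal/mol.

    ``r_u`` and ``r_f`` are first fitted linearly against temperature and
    evaluated at ``T_target``.  Positive when the unfolded state explores a
    larger free-motion radius than the folded one.
    """
    obs = np.array(f.observations)
    temps, ru, rf = obs[:, 0], obs[:, 1], obs[:, 2]
    ru_t = np.polyval(np.polyfit(temps, ru, 1), f.T_target)
    rf_t = np.polyval(np.polyfit(temps, rf, 1), f.T_target)
    if ru_t <= 0 or rf_t <= 0:
        raise ValueError("unphysical radii: extrapolated radius is non-positive")
    return 3.0 * R_KCAL * f.T_target * f.N_r * float(np.log(ru_t / rf_t))


class EnsembleSummary(NamedTuple):
    mean: float
    min: float
    max: float
    ranking: list[str]  # model labels, ascending dG (+shift)


def ensemble_summary(results: Iterable[PathResult], shift: float = 0.0) -> EnsembleSummary:
    """Mean/min/max of ``dG + shift`` over models, with ascending ranking.

    ``shift`` is typically the omitted ``-T dS_C`` contribution added back
    when comparing against an experimental binding free energy.
    """
    results = list(results)
    if not results:
        raise ValueError("empty ensemble")
    vals = np.array([r.dG + shift for r in results])
    order = np.argsort(vals, kind="stable")
    return EnsembleSummary(
        mean=float(vals.mean()),
        min=float(vals.min()),
        max=float(vals.max()),
        ranking=[results[k].model_label for k in order],
    )
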