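"""Random-coil peptide ensembles for unstructured reference states.

A disordered peptide state is modelled as an ensemble of conformers built
by drawing backbone dihedrals (Phi, Psi) uniformly from the sterically
allowed regions of the Ramachandran map, rebuilding Cartesian coordinates
from fixed ideal internal coordinates, and discarding conformers with
atomic overlaps.  The ensemble average of the per-conformer thermodynamic
components then defines the reference state of the unbound peptide.

Allowed regions (degrees):

* generic residues: Phi in [-180, -30]; Psi in [-180, -150] u [-90, 180];
* glycine: Phi in [-180, -30] u [30, 180]; Psi in [-180, 180];
* proline: fixed at (Phi, Psi) = (-65, 180).

Sampling is uniform over the union of a residue's intervals (mass
proportional to interval length).  Backbone geometry uses ideal values
(N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, omega = 180°); a CB pseudo
side chain is carried rigidly for all residues except glycine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .paths import SpeciesThermo

__all__ = [
    "DihedralRanges",
    "PeptideConformer",
    "ClashReport",
    "P16_SEQUENCE",
    "build_template",
    "sample_random_coil",
    "measure_dihedrals",
    "clash_filter",
    "ensemble_reference_state",
]

#: The 12-residue prion-protein fragment that folds upon binding the R12
#: RNA aptamer (one-letter code).
P16_SEQUENCE = "GQWNKPSKPKTN"

# ideal backbone internal coordinates (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.229
B_CA_CB = 1.530
A_N_CA_C = 111.2
A_CA_C_N = 116.6
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.5
T_OMEGA = 180.0
T_CB = -122.6  # torsion C(i)-N(i)-CA(i)-CB(i): L-amino-acid branch

#: Hard-sphere diameters (LJ sigma, Å) for the heavy-atom types emitted by
#: the builder; used by the default clash criterion and the geometry bridge.
ATOM_SIGMA = {"N": 3.25, "CA": 3.40, "C": 3.40, "O": 2.96, "CB": 3.40}


@dataclass(frozen=True)
class DihedralRanges:
    """Allowed (Phi, Psi) intervals per residue class, degrees.

    Intervals are closed ``(lo, hi)`` pairs inside [-180, 180]; a residue
    type's set of intervals is a union, sampled with mass proportional to
    length.  Proline is pinned to a single point.
    """

    generic_phi: tuple = ((-180.0, -30.0),)
    generic_psi: tuple = ((-180.0, -150.0), (-90.0, 180.0))
    gly_phi: tuple = ((-180.0, -30.0), (30.0, 180.0))
    gly_psi: tuple = ((-180.0, 180.0),)
    pro_phi: float = -65.0
    pro_psi: float = 180.0

    def __post_init__(self):
        for ivs in (self.generic_phi, self.generic_psi, self.gly_phi, self.gly_psi):
            for lo, hi in ivs:
                if not (-180.0 <= lo < hi <= 180.0):
                    raise ValueError(f"invalid dihedral interval ({lo}, {hi})")

    def intervals(self, aa: str, which: str):
        """Allowed intervals for residue ``aa`` ('phi' or 'psi'); None for Pro."""
        if aa == "P":
            return None
        if aa == "G":
            return self.gly_phi if which == "phi" else self.gly_psi
        return self.generic_phi if which == "phi" else self.generic_psi

    def contains(self, aa: str, which: str, value: float, tol: float = 1e-9) -> bool:
        if aa == "P":
            target = self.pro_phi if which == "phi" else self.pro_psi
            return abs(value - target) <= tol or abs(abs(value - target) - 360.0) <= tol
        return any(lo - tol <= value <= hi + tol for lo, hi in self.intervals(aa, which))


@dataclass
class PeptideConformer:
    """A peptide conformer: sequence, atoms, coordinates and its dihedrals.

    ``atom_names``/``atom_res`` give the atom type and residue index of each
    row of ``coordinates``; ``dihedrals`` holds the (Phi, Psi) pair used to
    build each residue (Phi of the first residue and Psi of the last have no
    geometric counterpart through the chain but Psi still orients the
    terminal carbonyl oxygen).
    """

    sequence: str
    atom_names: list[str]
    atom_res: np.ndarray
    coordinates: np.ndarray
    dihedrals: np.ndarray  # (n_res, 2) degrees
    seed: int | None = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.atom_names)

    def backbone_index(self, res: int, name: str) -> int:
        for k, (nm, ri) in enumerate(zip(self.atom_names, self.atom_res)):
            if ri == res and nm == name:
                return k
        raise KeyError(f"residue {res} missing backbone atom {name}")

    def sigmas(self) -> np.ndarray:
        return np.array([ATOM_SIGMA[n] for n in self.atom_names])


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear frame; pick any perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build(sequence: str, dihedrals: np.ndarray, seed: int | None = None,
           label: str = "") -> PeptideConformer:
    """Rebuild Cartesian coordinates from (Phi, Psi) and ideal geometry."""
    names: list[str] = []
    res_of: list[int] = []
    coords: list[np.ndarray] = []
    n_prev = ca_prev = c_prev = None
    for i, aa in enumerate(sequence):
        phi, psi = dihedrals[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([B_N_CA, 0.0, 0.0])
            ang = math.radians(A_N_CA_C)
            c = ca + np.array([-B_CA_C * math.cos(ang), B_CA_C * math.sin(ang), 0.0])
        else:
            # N(i): torsion psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
            n = _place(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, dihedrals[i - 1][1])
            # CA(i): omega about CA(i-1)-C(i-1)-N(i)
            ca = _place(ca_prev, c_prev, n, B_N_CA, A_C_N_CA, T_OMEGA)
            # C(i): phi(i) about C(i-1)-N(i)-CA(i)
            c = _place(c_prev, n, ca, B_CA_C, A_N_CA_C, phi)
        for nm, xyz in (("N", n), ("CA", ca), ("C", c)):
            names.append(nm)
            res_of.append(i)
            coords.append(xyz)
        # carbonyl O: anti to the next N, i.e. torsion psi + 180 about N-CA-C
        o = _place(n, ca, c, B_C_O, A_CA_C_O, psi + 180.0)
        names.append("O")
        res_of.append(i)
        coords.append(o)
        if aa != "G":
            cb = _place(c, n, ca, B_CA_CB, A_N_CA_CB, T_CB)
            names.append("CB")
            res_of.append(i)
            coords.append(cb)
        n_prev, ca_prev, c_prev = n, ca, c
    return PeptideConformer(
        sequence=sequence,
        atom_names=names,
        atom_res=np.array(res_of),
        coordinates=np.array(coords),
        dihedrals=np.array(dihedrals, dtype=float),
        seed=seed,
        label=label,
    )


def build_template(sequence: str = P16_SEQUENCE) -> PeptideConformer:
    """Extended-chain template: (Phi, Psi) = (-135, 135), proline pinned."""
    dih = np.array([
        (-65.0, 180.0) if aa == "P" else (-135.0, 135.0) for aa in sequence
    ])
    return _build(sequence, dih, label="template")


def _sample_union(rng: np.random.Generator, intervals) -> float:
    lengths = np.array([hi - lo for lo, hi in intervals])
    k = rng.choice(len(intervals), p=lengths / lengths.sum())
    lo, hi = intervals[k]
    return float(rng.uniform(lo, hi))


def sample_random_coil(template: PeptideConformer,
                       ranges: DihedralRanges = DihedralRanges(),
                       seed: int = 0) -> PeptideConformer:
    """Draw one random-coil conformer from the allowed dihedral regions.

    Dihedrals are drawn uniformly over each residue's union of intervals
    (probability proportional to interval length); proline is fixed at its
    pinned values.  Coordinates are rebuilt from the ideal internal
    coordinates; the draw is deterministic for a fixed seed.
    """
    for i in range(len(template.sequence)):
        for nm in ("N", "CA", "C"):
            template.backbone_index(i, nm)  # raises naming the residue if absent
    rng = np.random.default_rng(seed)
    dih = np.empty((len(template.sequence), 2))
    for i, aa in enumerate(template.sequence):
        if aa == "P":
            dih[i] = (ranges.pro_phi, ranges.pro_psi)
        else:
            dih[i, 0] = _sample_union(rng, ranges.intervals(aa, "phi"))
            dih[i, 1] = _sample_union(rng, ranges.intervals(aa, "psi"))
    return _build(template.sequence, dih, seed=seed, label=f"coil-{seed}")


def _torsion(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(m1 @ n2, n1 @ n2))


def measure_dihedrals(c: PeptideConformer) -> np.ndarray:
    """(Phi, Psi) per residue measured from coordinates (NaN where undefined,
    except the terminal Psi which is recovered through the carbonyl O)."""
    n_res = len(c.sequence)
    out = np.full((n_res, 2), np.nan)
    xyz = c.coordinates
    idx = c.backbone_index
    for i in range(n_res):
        if i > 0:
            out[i, 0] = _torsion(xyz[idx(i - 1, "C")], xyz[idx(i, "N")],
                                 xyz[idx(i, "CA")], xyz[idx(i, "C")])
        if i < n_res - 1:
            out[i, 1] = _torsion(xyz[idx(i, "N")], xyz[idx(i, "CA")],
                                 xyz[idx(i, "C")], xyz[idx(i + 1, "N")])
        else:
            psi_o = _torsion(xyz[idx(i, "N")], xyz[idx(i, "CA")],
                             xyz[idx(i, "C")], xyz[idx(i, "O")])
            out[i, 1] = ((psi_o - 180.0) + 180.0) % 360.0 - 180.0
    return out


def _bond_graph(c: PeptideConformer) -> list[tuple[int, int]]:
    bonds = []
    for i in range(len(c.sequence)):
        n, ca, cc, o = (c.backbone_index(i, x) for x in ("N", "CA", "C", "O"))
        bonds += [(n, ca), (ca, cc), (cc, o)]
        if c.sequence[i] != "G":
            bonds.append((ca, c.backbone_index(i, "CB")))
        if i + 1 < len(c.sequence):
            bonds.append((cc, c.backbone_index(i + 1, "N")))
    return bonds


def _graph_distances(n_atoms: int, bonds, cutoff: int = 4) -> np.ndarray:
    """All-pairs bond-graph distances up to ``cutoff`` (BFS; inf beyond)."""
    adj = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full((n_atoms, n_atoms), np.inf)
    for s in range(n_atoms):
        dist[s, s] = 0
        frontier = [s]
        for depth in range(1, cutoff + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s, v] == np.inf:
                        dist[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return dist


@dataclass
class ClashReport:
    """Retention report of :func:`clash_filter`."""

    n_input: int
    n_retained: int
    rejected: list[tuple[str, tuple[int, int], float]]  # label, atom pair, distance


def clash_filter(ensemble: Sequence[PeptideConformer],
                 min_distance_factor: float = 0.6,
                 energy_threshold: float | None = None,
                 epsilon: float = 0.1) -> tuple[list[PeptideConformer], ClashReport]:
    """Discard conformers with overlapping non-bonded atoms.

    Default criterion: reject a conformer if any heavy-atom pair separated
    by more than three bonds is closer than
    ``min_distance_factor * (sigma_i + sigma_j)/2``.  Alternatively, with
    ``energy_threshold`` set, a conformer is rejected when its nonbonded LJ
    energy (well depth ``epsilon`` kcal/mol for every atom) exceeds the
    threshold — the energy reading of "divergently high LJ energy".
    """
    retained: list[PeptideConformer] = []
    rejected: list[tuple[str, tuple[int, int], float]] = []
    for conf in ensemble:
        sig = conf.sigmas()
        dist_g = _graph_distances(len(conf), _bond_graph(conf))
        diff = conf.coordinates[:, None, :] - conf.coordinates[None, :, :]
        r = np.sqrt((diff**2).sum(-1))
        iu, ju = np.triu_indices(len(conf), k=1)
        nb = dist_g[iu, ju] > 3
        ok = True
        worst: tuple[int, int] | None = None
        if energy_threshold is None:
            thresh = min_distance_factor * 0.5 * (sig[iu] + sig[ju])
            bad = nb & (r[iu, ju] < thresh)
            if bad.any():
                ok = False
                k = np.flatnonzero(bad)[np.argmin(r[iu, ju][np.flatnonzero(bad)])]
                worst = (int(iu[k]), int(ju[k]))
                rejected.append((conf.label, worst, float(r[iu, ju][k])))
        else:
            sij = 0.5 * (sig[iu] + sig[ju])
            sr6 = (sij[nb] / r[iu, ju][nb]) ** 6
            e = float(np.sum(4.0 * epsilon * (sr6**2 - sr6)))
            if not np.isfinite(e) or e > energy_threshold:
                ok = False
                k = np.flatnonzero(nb)[np.argmin(r[iu, ju][nb])]
                rejected.append((conf.label, (int(iu[k]), int(ju[k])),
                                 float(r[iu, ju][k])))
        if ok:
            retained.append(conf)
    return retained, ClashReport(len(ensemble), len(retained), rejected)


def ensemble_reference_state(thermos: Sequence[SpeciesThermo],
                             label: str = "random-coil reference") -> SpeciesThermo:
    """Arithmetic mean of each component over a retained ensemble.

    Optional components (``E_B``, ``TS_C``) are averaged when present on
    every member and omitted otherwise.
    """
    thermos = list(thermos)
    if not thermos:
        raise ValueError("empty ensemble")
    T = thermos[0].T

    def mean_of(name):
        vals = [getattr(t, name) for t in thermos]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    return SpeciesThermo(
        label=label,
        E_LJ=mean_of("E_LJ"),
        E_ES=mean_of("E_ES"),
        eps_VH_LJ=mean_of("eps_VH_LJ"),
        eps_VH_ES=mean_of("eps_VH_ES"),
        TS_VH=mean_of("TS_VH"),
        E_B=mean_of("E_B"),
        TS_C=mean_of("TS_C"),
        T=T,
    )
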