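"""Structure, parameter and table IO plus run configuration.

Structures are read with Biopython (PDB and PQR); parameter tables are TSV
files keyed by residue and atom name.  The same atom ordering feeds both
views of a molecule: the charged-atom view for energies and the
fused-sphere view for geometry.

PQR radius columns are ambiguous across generators: the column may hold
``sigma/2`` or ``Rmin/2``.  The interpretation is an explicit switch; with
``rmin/2`` the conversion ``sigma = 2 * (Rmin/2) / 2^(1/6)`` is applied and
logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_DS, DEFAULT_ETA, DEFAULT_T
from .energetics import MolecularSystem, SCALE_ES_14, SCALE_LJ_14
from .geometry import SoluteBody
from .conformers import PeptideConformer
from .paths import PathResult, SpeciesThermo

logger = logging.getLogger("hydromorph")

__all__ = [
    "RunConfig",
    "load_config",
    "read_structure",
    "read_parameter_table",
    "write_measures_tsv",
    "write_path_table",
    "read_path_table",
    "write_species_tsv",
    "read_species_tsv",
    "write_ensemble_pdb",
    "write_body_pdb",
]


@dataclass
class RunConfig:
    """Run-wide physical and numerical settings (all units Å, K, kcal/mol)."""

    probe_dS: float = DEFAULT_DS
    solvent_eta: float = DEFAULT_ETA
    temperature: float = DEFAULT_T
    resolution: float = 0.25
    coefficients: dict | None = None     # optional {C1..C4} override
    scale_es_14: float = SCALE_ES_14
    scale_lj_14: float = SCALE_LJ_14
    clash_factor: float = 0.6
    pqr_radius_convention: str = "sigma/2"   # or "rmin/2"
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        for name in ("probe_dS", "solvent_eta", "temperature", "resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pqr_radius_convention not in ("sigma/2", "rmin/2"):
            raise ValueError("pqr_radius_convention must be 'sigma/2' or 'rmin/2'")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log_provenance(self) -> None:
        logger.info("config %s seed=%d resolution=%.3g coefficients=%s",
                    self.config_hash(), self.seed, self.resolution,
                    "config" if self.coefficients else "fit")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns residue, atom, sigma, epsilon, charge.

    A row with residue ``*`` acts as a fallback for any residue with a
    matching atom name.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue", "atom", "sigma", "epsilon", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def _lookup_params(df: pd.DataFrame | None, residue: str, atom: str):
    if df is None:
        return None
    hit = df[(df["residue"] == residue) & (df["atom"] == atom)]
    if hit.empty:
        hit = df[(df["residue"] == "*") & (df["atom"] == atom)]
    if hit.empty:
        return None
    row = hit.iloc[0]
    return float(row["sigma"]), float(row["epsilon"]), float(row["charge"])


def read_structure(path: str | Path, fmt: str | None = None,
                   params: pd.DataFrame | str | Path | None = None,
                   model: int | None = None,
                   chains: Sequence[str] | None = None,
                   radius_convention: str = "sigma/2",
                   ) -> tuple[MolecularSystem, SoluteBody]:
    """Read a structure into its energy and geometry views.

    Parameters
    ----------
    path, fmt
        Input file; ``fmt`` is ``"pdb"`` or ``"pqr"`` (inferred from the
        suffix when omitted).
    params
        Parameter table (or its path) resolving ``(residue, atom) ->
        (sigma, epsilon, charge)``.  Required for PDB input; optional for
        PQR, whose own charge/radius columns are used otherwise (with
        ``epsilon = 0``).
    model, chains
        Restrict to one model and/or a set of chain identifiers.
    radius_convention
        How to read a PQR radius column: ``"sigma/2"`` (default) or
        ``"rmin/2"`` (converted to sigma and logged).

    Returns
    -------
    ``(MolecularSystem, SoluteBody)`` over the identical atom ordering.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "pqr"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    if isinstance(params, (str, Path)):
        params = read_parameter_table(params)

    parser = PDBParser(QUIET=True, is_pqr=(fmt == "pqr"))
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if model is not None:
        models = [m for m in models if m.id == model - 1 or m.serial_num == model]
        if not models:
            raise ValueError(f"empty selection: model {model} not present")
    sel = models[:1] if model is not None else models[:1]  # first (or chosen) model

    centers, sigmas, epsilons, charges, names, residues = [], [], [], [], [], []
    unresolved = []
    for m in sel:
        for chain in m:
            if chains is not None and chain.id not in chains:
                continue
            for res in chain:
                for atom in res:
                    resname = res.get_resname().strip()
                    aname = atom.get_name().strip()
                    looked = _lookup_params(params, resname, aname)
                    if looked is not None:
                        sig, eps, q = looked
                    elif fmt == "pqr":
                        radius = float(atom.get_radius())
                        if radius_convention == "rmin/2":
                            sig = 2.0 * radius / 2 ** (1.0 / 6.0)
                            logger.info("converted Rmin/2=%.3f to sigma=%.3f for %s/%s",
                                        radius, sig, resname, aname)
                        else:
                            sig = 2.0 * radius
                        eps, q = 0.0, float(atom.get_charge())
                    else:
                        unresolved.append(f"{resname}/{aname}")
                        continue
                    centers.append(atom.get_coord().astype(float))
                    sigmas.append(sig)
                    epsilons.append(eps)
                    charges.append(q)
                    names.append(aname)
                    residues.append(resname)
    if unresolved:
        raise ValueError("unresolvable atom types: " + ", ".join(sorted(set(unresolved))))
    if not centers:
        raise ValueError("empty selection")
    system = MolecularSystem(
        centers=np.array(centers), sigmas=np.array(sigmas),
        epsilons=np.array(epsilons), charges=np.array(charges),
        names=names, residues=residues, label=path.stem,
    )
    body = SoluteBody(system.centers, system.sigmas.copy(), label=path.stem)
    return system, body


_MEASURE_COLS = ["label", "V_ex_A3", "A_A2", "X_A", "Y", "resolution_A"]


def write_measures_tsv(rows: Sequence[tuple], path: str | Path) -> None:
    """Rows of (label, MorphoMeasures, resolution) -> TSV."""
    recs = [
        {"label": label, "V_ex_A3": m.V_ex, "A_A2": m.A, "X_A": m.X, "Y": m.Y,
         "resolution_A": res}
        for label, m, res in rows
    ]
    pd.DataFrame(recs, columns=_MEASURE_COLS).to_csv(path, sep="\t", index=False,
                                                     float_format="%.6g")


_PATH_COLS = ["model", "dG", "dE_total", "mTdS_VH", "dE_B", "d_LJ_component",
              "d_ES_component", "dE_LJ", "dEps_LJ", "dE_ES", "dEps_ES",
              "mTdS_C", "path", "S_C_flag"]


def write_path_table(results: Sequence[PathResult], path: str | Path) -> None:
    """Write path results at 2-decimal precision, table-style column order."""
    if not results:
        raise ValueError("no results to write")
    recs = []
    for r in results:
        recs.append({
            "model": r.model_label, "dG": r.dG, "dE_total": r.dE_total,
            "mTdS_VH": r.mTdS_VH, "dE_B": r.dE_B,
            "d_LJ_component": r.d_LJ_component, "d_ES_component": r.d_ES_component,
            "dE_LJ": r.dE_LJ, "dEps_LJ": r.dEps_LJ, "dE_ES": r.dE_ES,
            "dEps_ES": r.dEps_ES, "mTdS_C": r.mTdS_C, "path": r.path_id,
            "S_C_flag": "S_C omitted" if r.s_c_omitted else "S_C included",
        })
    pd.DataFrame(recs, columns=_PATH_COLS).to_csv(path, sep="\t", index=False,
                                                  float_format="%.2f")


def read_path_table(path: str | Path) -> list[PathResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(PathResult(
            path_id=str(row["path"]), model_label=str(row["model"]),
            dG=row["dG"], dE_total=row["dE_total"], mTdS_VH=row["mTdS_VH"],
            dE_B=row["dE_B"], d_LJ_component=row["d_LJ_component"],
            d_ES_component=row["d_ES_component"], dE_LJ=row["dE_LJ"],
            dEps_LJ=row["dEps_LJ"], dE_ES=row["dE_ES"], dEps_ES=row["dEps_ES"],
            mTdS_C=row["mTdS_C"], s_c_omitted=(row["S_C_flag"] == "S_C omitted"),
        ))
    return out


_SPECIES_COLS = ["label", "E_B", "E_LJ", "E_ES", "eps_VH_LJ", "eps_VH_ES",
                 "TS_VH", "TS_C", "T"]


def write_species_tsv(species: Sequence[SpeciesThermo], path: str | Path) -> None:
    recs = [{c: getattr(s, c if c != "label" else "label") for c in _SPECIES_COLS}
            for s in species]
    pd.DataFrame(recs, columns=_SPECIES_COLS).to_csv(path, sep="\t", index=False)


def read_species_tsv(path: str | Path) -> list[SpeciesThermo]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kw = {c: row[c] for c in _SPECIES_COLS if c not in ("label",)}
        kw = {k: (None if pd.isna(v) else float(v)) for k, v in kw.items()}
        out.append(SpeciesThermo(label=str(row["label"]), **kw))
    return out


def _conformer_to_biopdb(conformers: Sequence[PeptideConformer]):
    from Bio.PDB.StructureBuilder import StructureBuilder

    three = {"G": "GLY", "Q": "GLN", "W": "TRP", "N": "ASN", "K": "LYS",
             "P": "PRO", "S": "SER", "T": "THR", "A": "ALA", "V": "VAL",
             "L": "LEU", "I": "ILE", "F": "PHE", "Y": "TYR", "D": "ASP",
             "E": "GLU", "R": "ARG", "H": "HIS", "M": "MET", "C": "CYS"}
    sb = StructureBuilder()
    sb.init_structure("ens")
    for mi, conf in enumerate(conformers):
        sb.init_model(mi)
        sb.init_chain("A")
        sb.init_seg("    ")
        current = -1
        serial = 1
        for k, (nm, ri) in enumerate(zip(conf.atom_names, conf.atom_res)):
            if ri != current:
                sb.init_residue(three[conf.sequence[ri]], " ", int(ri) + 1, " ")
                current = ri
            sb.init_atom(nm, conf.coordinates[k].astype("float32"), 0.0, 1.0,
                         " ", nm, serial, element=nm[0])
            serial += 1
    return sb.get_structure()


def write_ensemble_pdb(conformers: Sequence[PeptideConformer], path: str | Path) -> None:
    """Write a conformer ensemble as a multi-model PDB file."""
    from Bio.PDB import PDBIO

    io = PDBIO()
    io.set_structure(_conformer_to_biopdb(conformers))
    io.save(str(path))


def write_body_pdb(body: SoluteBody, path: str | Path,
                   sidecar_tsv: str | Path | None = None) -> None:
    """Write a fused-sphere body as PDB pseudo-atoms (+ diameter sidecar TSV)."""
    with open(path, "w") as fh:
        for k, (c, d) in enumerate(zip(body.centers, body.diameters), start=1):
            fh.write(
                f"ATOM  {k:5d}  C   SPH A{min(k, 9999):4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}\n")
        fh.write("END\n")
    if sidecar_tsv is not None:
        pd.DataFrame({"atom": np.arange(1, len(body) + 1),
                      "diameter_A": body.diameters}).to_csv(
            sidecar_tsv, sep="\t", index=False)
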