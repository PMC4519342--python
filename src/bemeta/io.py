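"""Readers and writers for the pipeline's text formats.

PDB structures go through biotite; everything else is plain whitespace or CSV
text in the conventions of the metadynamics ecosystem (COLVAR / HILLS files
with ``#! FIELDS`` headers) and of shift-prediction tables.  All writers can
embed a provenance block (config hash, seed, package version) as comment
lines, and every reader/writer pair round-trips exactly on the values it
writes (floats are emitted with 17 significant digits).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import constants as c
from .bias import Hill
from .cv import BackboneStructure
from .fes import FreeEnergySurface, GridSpec
from .reweight import FrameObservation

_FLOAT_FMT = "%.17g"


def provenance_lines(provenance: dict = None) -> list[str]:
    if not provenance:
        return []
    return [f"# provenance {k}: {v}" for k, v in provenance.items()]


def config_hash(mapping: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = repr(sorted((str(k), str(v)) for k, v in mapping.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# --- PDB ----------------------------------------------------------------------

_BACKBONE_SET = ("N", "CA", "C", "O", "CB")


def read_pdb(path) -> list[BackboneStructure]:
    """Backbone structures (one per model), coordinates converted to nm."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, coords in Angstrom
    structures = []
    for model in stack:
        res_ids = np.unique(model.res_id)
        residues = []
        for rid in res_ids:
            sel = model[(model.res_id == rid)]
            atoms = {}
            for name in _BACKBONE_SET:
                hit = sel[sel.atom_name == name]
                if len(hit) > 0:
                    atoms[name] = hit.coord[0] * c.ANGSTROM_TO_NM
            residues.append(atoms)
        structures.append(BackboneStructure(res_ids, residues))
    return structures


def write_pdb(structures, path, res_names=None) -> None:
    """Write backbone structures as PDB models (nm converted to Angstrom)."""
    structures = [structures] if isinstance(structures, BackboneStructure) else list(structures)
    first = structures[0]
    n_atoms = sum(len(res) for res in first.atom_coords)

    def make_array(s: BackboneStructure):
        arr = struc.AtomArray(n_atoms)
        k = 0
        for rid, res in zip(s.residue_ids, s.atom_coords):
            for name in _BACKBONE_SET:
                if name not in res:
                    continue
                arr.coord[k] = res[name] / c.ANGSTROM_TO_NM
                arr.chain_id[k] = "A"
                arr.res_id[k] = rid
                arr.res_name[k] = (
                    res_names[rid - 1] if res_names is not None else "ALA"
                )
                arr.atom_name[k] = name
                arr.element[k] = name[0]
                k += 1
        return arr

    stack = struc.stack([make_array(s) for s in structures])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --- COLVAR -------------------------------------------------------------------


def write_colvar(frames, path, fields=("time", "alpha_rmsd", "beta_rmsd"), provenance=None):
    """Whitespace table of per-frame CV values with a ``#! FIELDS`` header."""
    lines = ["#! FIELDS " + " ".join(fields)]
    lines += provenance_lines(provenance)
    for f in frames:
        row = [f.time, *f.cv]
        lines.append(" ".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path) -> list[FrameObservation]:
    fields, rows = _read_plumed_table(path)
    if fields[0] != "time":
        raise ValueError("COLVAR file must start with a time column")
    return [FrameObservation(time=r[0], cv=tuple(r[1:])) for r in rows]


def _read_plumed_table(path):
    fields, rows = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#! FIELDS"):
            fields = line.split()[2:]
        elif line.startswith("#"):
            continue
        else:
            rows.append([float(tok) for tok in line.split()])
    if fields is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    return fields, rows


# --- HILLS --------------------------------------------------------------------


def write_hills(hills, path, cv_names=("alpha", "beta"), provenance=None):
    """PLUMED-style hill log; dimensionality inferred from the first hill."""
    hills = list(hills)
    if not hills:
        raise ValueError("no hills to write")
    dim = hills[0].dim
    names = list(cv_names[:dim])
    fields = (
        ["time"]
        + [f"center_{n}" for n in names]
        + [f"sigma_{n}" for n in names]
        + ["height"]
    )
    lines = ["#! FIELDS " + " ".join(fields)]
    lines += provenance_lines(provenance)
    for h in hills:
        row = [h.time, *h.center, *h.sigma, h.height]
        lines.append(" ".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path) -> list[Hill]:
    fields, rows = _read_plumed_table(path)
    n_center = sum(1 for f in fields if f.startswith("center_"))
    hills = []
    for r in rows:
        t = r[0]
        center = tuple(r[1 : 1 + n_center])
        sigma = tuple(r[1 + n_center : 1 + 2 * n_center])
        height = r[1 + 2 * n_center]
        hills.append(Hill(center, height, sigma, time=t))
    return hills


# --- free-energy surface ------------------------------------------------------


def write_fes(fes: FreeEnergySurface, path, provenance=None):
    """Row-major table: one row per node with coordinates, F (kT), visited."""
    axes = fes.grid.axes()
    lines = ["#! FIELDS " + " ".join(
        (["alpha", "beta"] if fes.grid.dim == 2 else ["alpha"]) + ["free_energy_kT", "visited"]
    )]
    lines += provenance_lines(provenance)
    lines.append(f"# temperature_K {fes.temperature_k}")
    vals_kt = fes.values_kt
    it = np.ndindex(*fes.grid.n_nodes)
    for idx in it:
        coords = [axes[d][idx[d]] for d in range(fes.grid.dim)]
        lines.append(
            " ".join(_FLOAT_FMT % v for v in coords)
            + " " + (_FLOAT_FMT % vals_kt[idx])
            + f" {int(fes.visited[idx])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path) -> FreeEnergySurface:
    fields, rows = _read_plumed_table(path)
    temperature = c.DEFAULT_TEMPERATURE_K
    for line in Path(path).read_text().splitlines():
        if line.startswith("# temperature_K"):
            temperature = float(line.split()[-1])
    dim = len(fields) - 2
    arr = np.asarray(rows)
    axes = [np.unique(arr[:, d]) for d in range(dim)]
    n_nodes = tuple(len(a) for a in axes)
    grid = GridSpec(
        tuple(a[0] for a in axes), tuple(a[-1] for a in axes), n_nodes
    )
    values = arr[:, dim].reshape(n_nodes) * c.kT(temperature)
    visited = arr[:, dim + 1].reshape(n_nodes).astype(bool)
    return FreeEnergySurface(grid, values, visited, temperature)


# --- chemical-shift tables ----------------------------------------------------


def write_shift_table(shifts: dict, path, resnames=None, provenance=None):
    """Columnar per-frame shift table (resid, resname, atom, shift_ppm)."""
    lines = ["# resid resname atom shift_ppm"] + provenance_lines(provenance)
    for atom in sorted(shifts):
        vals = np.asarray(shifts[atom], float)
        for i, v in enumerate(vals):
            rn = resnames[i] if resnames is not None else "XXX"
            lines.append(f"{i + 1} {rn} {atom} " + (_FLOAT_FMT % v))
    Path(path).write_text("\n".join(lines) + "\n")


def read_shift_table(path) -> dict:
    """Shift table back to atom -> per-residue array (aliases normalised)."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resid, _resname, atom, val = line.split()
        atom = c.ATOM_ALIASES.get(atom, atom)
        records.append((int(resid), atom, float(val)))
    df = pd.DataFrame(records, columns=["resid", "atom", "shift"])
    out = {}
    for atom, grp in df.groupby("atom"):
        grp = grp.sort_values("resid")
        out[atom] = grp["shift"].to_numpy()
    return out


def write_shift_manifest(entries, path):
    """Map per-frame shift files to trajectory times: 'time_ps  filename'."""
    lines = ["# time_ps filename"]
    for t, fname in entries:
        lines.append(f"{_FLOAT_FMT % t} {fname}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shift_manifest(path):
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        t, fname = line.split()
        entries.append((float(t), fname))
    return entries


# --- DSSP strings -------------------------------------------------------------


def write_ss_strings(ss_strings, path, provenance=None):
    lines = ["# one DSSP string per frame"] + provenance_lines(provenance)
    lines += list(ss_strings)
    Path(path).write_text("\n".join(lines) + "\n")


def read_ss_strings(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        out.append(line.strip())
    return out


# --- experimental shifts + temperature coefficients ---------------------------


def write_experimental_csv(df: pd.DataFrame, path):
    """CSV with columns resid, atom, shift_ppm, coeff_ppb_per_K."""
    df.to_csv(path, index=False)


def read_experimental_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"resid", "atom", "shift_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"experimental CSV needs columns {sorted(required)}")
    df["atom"] = df["atom"].map(lambda a: c.ATOM_ALIASES.get(a, a))
    return df
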