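"""Reading search outputs, re-optimization results, and writing job inputs.

The conformational-search side speaks multi-record SDF (V2000): one record
per conformer with the FF energy stored as a record property.  Different
search engines use different property keys and units, so the reader takes a
key name but can also auto-detect, and treats raw energies with magnitude
above 100 as Hartree (typical electronic-structure totals) and anything
else as kcal/mol.

The re-optimization side reads a folder of quantum-chemistry text outputs.
Two dialects are supported: ``gaussian`` (final standard-orientation block
plus thermochemistry summary lines) and ``xyz`` (XYZ file with the energy
on the comment line).  Filenames map to priority rank by natural sort
unless an explicit manifest is given.
"""

from __future__ import annotations

import csv
import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .ensemble import (
    HARTREE_TO_KCAL,
    ConformerEnsemble,
    EnsembleMismatchError,
    OptimizedResult,
)

# property keys commonly used for the search energy, tried in order when no
# explicit name is given
_ENERGY_KEY_CANDIDATES = (
    "r_mmod_Potential_Energy-MMFF94",
    "r_mmod_Potential_Energy-MMFF94s",
    "energy",
    "Energy",
    "E",
    "total energy / Eh",
)


def natural_sort_key(name: str) -> tuple:
    """Sort key that orders embedded integers numerically (conf_2 < conf_10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _record_energy(mol: Chem.Mol, key: str | None, record: int) -> float:
    if key is not None:
        if not mol.HasProp(key):
            raise ValueError(
                f"record {record}: energy property {key!r} missing")
        raw = mol.GetProp(key)
        try:
            return float(raw.split()[0])
        except ValueError as exc:
            raise ValueError(
                f"record {record}: energy property {key!r} "
                f"unparsable: {raw!r}") from exc
    for cand in _ENERGY_KEY_CANDIDATES:
        if mol.HasProp(cand):
            return _record_energy(mol, cand, record)
    # last resort: any property whose name mentions energy and parses
    for name in mol.GetPropNames():
        if "energy" in name.lower():
            try:
                return float(mol.GetProp(name).split()[0])
            except ValueError:
                continue
    raise ValueError(f"record {record}: no energy property found")


def read_ensemble(
    path: str | Path,
    energy_property_name: str | None = None,
    units: str = "auto",
) -> ConformerEnsemble:
    """Read a multi-record SDF into an energy-sorted :class:`ConformerEnsemble`.

    Parameters
    ----------
    path
        SDF file with one record per conformer, identical atom order across
        records.
    energy_property_name
        SDF property key holding the FF energy.  ``None`` scans common keys.
    units
        ``"auto"`` (magnitude heuristic), ``"hartree"`` or ``"kcal/mol"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = [m for m in supplier]
    if not mols or any(m is None for m in mols):
        bad = [i for i, m in enumerate(mols) if m is None]
        raise ValueError(
            f"unreadable SDF records {bad} in {path}" if mols
            else f"no records in {path}")

    ref_elems = [a.GetSymbol() for a in mols[0].GetAtoms()]
    energies = []
    coords = []
    for k, m in enumerate(mols):
        elems = [a.GetSymbol() for a in m.GetAtoms()]
        if elems != ref_elems:
            raise EnsembleMismatchError(
                f"record {k} atom sequence differs from record 0")
        energies.append(_record_energy(m, energy_property_name, k))
        coords.append(m.GetConformer().GetPositions())
    energies = np.asarray(energies, dtype=float)

    if units == "auto":
        # electronic-structure totals are O(100+) Hartree in magnitude;
        # FF energies in kcal/mol rarely reach that for window-filtered sets
        is_hartree = bool(np.median(np.abs(energies)) >= 100)
    elif units in ("hartree", "Hartree"):
        is_hartree = True
    elif units in ("kcal/mol", "kcal"):
        is_hartree = False
    else:
        raise ValueError(f"unknown units {units!r}")

    rel = energies - energies.min()
    if is_hartree:
        rel = rel * HARTREE_TO_KCAL
    order = np.argsort(rel, kind="stable")  # ties keep record order
    graph_mol = Chem.Mol(mols[0])
    graph_mol.RemoveAllConformers()
    return ConformerEnsemble(
        graph_mol,
        np.stack([coords[i] for i in order]),
        rel[order],
    )


def apply_energy_window(
    ens: ConformerEnsemble, window: float = 10.0
) -> ConformerEnsemble:
    """Drop conformers more than ``window`` kcal/mol above the FF minimum.

    The default window of 10 kcal/mol is the conventional cutoff beyond
    which conformers carry negligible Boltzmann weight at room temperature.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    keep = np.flatnonzero(ens.u_ff <= window)
    if len(keep) == ens.m:
        return ens
    return ens.subset(keep)


def write_ensemble_sdf(
    ens: ConformerEnsemble,
    path: str | Path,
    order: Sequence[int] | None = None,
    energy_property_name: str = "energy",
) -> None:
    """Write the ensemble (optionally reordered) as a multi-record SDF."""
    order = range(ens.m) if order is None else order
    writer = Chem.SDWriter(str(path))
    try:
        for idx in order:
            m = ens.conformer_mol(int(idx))
            m.SetProp(energy_property_name, f"{ens.u_ff[int(idx)]:.6f}")
            m.SetProp("_Name", f"conformer_{int(idx)}")
            writer.write(m)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# re-optimization outputs


def _parse_gaussian(text: str) -> tuple[np.ndarray, list[str], dict, bool]:
    """Extract the last geometry block and thermochemistry from a text log."""
    geom_blocks = re.findall(
        r"(?:Standard|Input) orientation:.*?-{10,}\n.*?-{10,}\n(.*?)\n\s*-{10,}",
        text, re.S)
    if not geom_blocks:
        raise ValueError("no geometry block found")
    symbols, xyz = [], []
    pt = Chem.GetPeriodicTable()
    for line in geom_blocks[-1].strip().splitlines():
        f = line.split()
        if len(f) < 6:
            continue
        symbols.append(pt.GetElementSymbol(int(f[1])))
        xyz.append([float(f[3]), float(f[4]), float(f[5])])
    energies = {}
    m = re.findall(r"Sum of electronic and thermal Free Energies=\s*(-?\d+\.\d+)", text)
    if m:
        energies["g"] = float(m[-1])
    m = re.findall(r"Sum of electronic and thermal Enthalpies=\s*(-?\d+\.\d+)", text)
    if m:
        energies["h"] = float(m[-1])
    m = re.findall(r"SCF Done:\s+E\(\S+\)\s*=\s*(-?\d+\.\d+)", text)
    if m:
        energies["scf"] = float(m[-1])
    converged = "Normal termination" in text
    return np.asarray(xyz), symbols, energies, converged


def _parse_xyz(text: str) -> tuple[np.ndarray, list[str], dict, bool]:
    lines = text.strip().splitlines()
    n = int(lines[0].split()[0])
    comment = lines[1]
    m = re.search(r"(-?\d+\.\d+)", comment)
    energies = {"g": float(m.group(1))} if m else {}
    symbols, xyz = [], []
    for line in lines[2:2 + n]:
        f = line.split()
        symbols.append(f[0])
        xyz.append([float(f[1]), float(f[2]), float(f[3])])
    return np.asarray(xyz), symbols, energies, True


_DIALECTS = {"gaussian": _parse_gaussian, "xyz": _parse_xyz}
_DIALECT_SUFFIX = {"gaussian": (".log", ".out"), "xyz": (".xyz",)}


def read_manifest(path: str | Path) -> dict[int, int]:
    """Read a rank→source_index manifest CSV (columns rank, source_index)."""
    mapping = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mapping[int(row["rank"])] = int(row["source_index"])
    return mapping


def read_optimized_results(
    folder: str | Path,
    dialect: str = "gaussian",
    manifest: str | Path | dict[int, int] | None = None,
    priority_order: Sequence[int] | None = None,
    energy_key: str = "g",
) -> list[OptimizedResult]:
    """Read a folder of re-optimization outputs in priority order.

    Files are ordered by natural sort of their names, which by convention
    equals the priority rank in which the jobs were written.  ``manifest``
    or ``priority_order`` maps rank to the source conformer index in the FF
    ensemble; with neither, the source index defaults to the rank itself.

    Converged results are re-zeroed to the batch minimum and converted from
    Hartree to kcal/mol.  Unparsable files are skipped with a warning;
    non-converged jobs are retained, flagged, and excluded from the energy
    zeroing.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(folder)
    parse = _DIALECTS[dialect]
    files = sorted(
        (p for p in folder.iterdir()
         if p.suffix.lower() in _DIALECT_SUFFIX[dialect]),
        key=lambda p: natural_sort_key(p.name))
    if not files:
        raise ValueError(f"no {dialect} outputs in {folder}")
    if isinstance(manifest, (str, Path)):
        manifest = read_manifest(manifest)

    results: list[OptimizedResult] = []
    raw: list[float] = []
    for rank, f in enumerate(files):
        try:
            xyz, _symbols, energies, converged = parse(f.read_text())
        except (ValueError, IndexError) as exc:
            warnings.warn(f"skipping unparsable output {f.name}: {exc}")
            continue
        if manifest is not None:
            source = manifest[rank]
        elif priority_order is not None:
            source = int(priority_order[rank])
        else:
            source = rank
        e = energies.get(energy_key, energies.get("g", energies.get("scf")))
        if converged and e is None:
            warnings.warn(f"{f.name}: no energy found, marking non-converged")
            converged = False
        results.append(OptimizedResult(
            source_index=source,
            coordinates=xyz,
            g_rel=float(e) if e is not None else float("nan"),
            converged=converged,
        ))
        if converged:
            raw.append(float(e))
    if not results:
        raise ValueError(f"no parsable outputs in {folder}")
    if raw:
        e_min = min(raw)
        for r in results:
            if r.converged:
                r.g_rel = (r.g_rel - e_min) * HARTREE_TO_KCAL
    return results


def write_job_inputs(
    ens: ConformerEnsemble,
    priority,
    template: str,
    out_dir: str | Path,
    extension: str = ".com",
) -> int:
    """Write one job-input file per conformer, named by zero-padded rank.

    ``template`` must contain a ``{coordinates}`` placeholder; it may also
    use ``{rank}`` and ``{conformer}``.  Returns the number of files
    written.  A rank/source manifest CSV is written alongside the inputs.
    """
    if "{coordinates}" not in template:
        raise ValueError("template lacks a {coordinates} placeholder")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = getattr(priority, "order", priority)
    width = max(2, len(str(len(order))))
    symbols = [a.GetSymbol() for a in ens.mol.GetAtoms()]
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "source_index", "filename"])
        for rank, conf_idx in enumerate(order):
            conf_idx = int(conf_idx)
            coord_lines = "\n".join(
                f"{s:<3s} {x:14.6f} {y:14.6f} {z:14.6f}"
                for s, (x, y, z) in zip(symbols, ens.coords[conf_idx]))
            name = f"conf_{rank + 1:0{width}d}{extension}"
            (out_dir / name).write_text(template.format(
                coordinates=coord_lines, rank=rank + 1, conformer=conf_idx))
            w.writerow([rank, conf_idx, name])
    return len(order)


def write_priority_csv(ens: ConformerEnsemble, priority, path: str | Path) -> None:
    """Write a priority list as CSV (rank, conformer_index, u_ff, method, params)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "conformer_index", "u_ff_kcal_mol",
                    "method", "params"])
        params = getattr(priority, "params", {})
        method = getattr(priority, "method", "unknown")
        for rank, idx in enumerate(priority.order):
            w.writerow([rank + 1, int(idx), f"{ens.u_ff[int(idx)]:.4f}",
                        method, ";".join(f"{k}={v}" for k, v in params.items())])
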