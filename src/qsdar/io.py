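"""Flat-file plumbing: peak-list CSV/JSON, feature matrices, SDF export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Peak, PeakList

__all__ = ["peaklists_from_frame", "load_peaks_csv", "load_peaks_json",
           "save_peaks_json", "load_feature_csv", "export_sdf"]


def _parse_j(field) -> tuple[float, ...]:
    if field is None or (isinstance(field, float) and np.isnan(field)):
        return ()
    s = str(field).strip()
    return tuple(float(x) for x in s.split(";") if x) if s else ()


def peaklists_from_frame(frame: pd.DataFrame) -> list[PeakList]:
    """Long-format table (id, shift_ppm, j_hz, n_protons[, atom_type]) ->
    one PeakList per id, in first-appearance order."""
    out: dict[str, list[Peak]] = {}
    has_atom = "atom_type" in frame.columns
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.id), []).append(Peak(
            shift=float(row.shift_ppm),
            couplings=_parse_j(getattr(row, "j_hz", None)),
            n_protons=int(getattr(row, "n_protons", 1)),
            atom_type=str(row.atom_type) if has_atom else "H"))
    return [PeakList(molecule_id=k, peaks=tuple(v)) for k, v in out.items()]


def load_peaks_csv(path) -> list[PeakList]:
    return peaklists_from_frame(pd.read_csv(path))


def load_peaks_json(path) -> list[PeakList]:
    """JSON: {"<id>": [{"shift": ..., "couplings": [...], "n_protons": ...,
    "atom_type": "H"}, ...], ...}"""
    data = json.loads(Path(path).read_text())
    out = []
    for mol_id, peaks in data.items():
        out.append(PeakList(molecule_id=mol_id, peaks=tuple(
            Peak(shift=float(p["shift"]),
                 couplings=tuple(float(j) for j in p.get("couplings", ())),
                 n_protons=int(p.get("n_protons", 1)),
                 atom_type=str(p.get("atom_type", "H"))) for p in peaks)))
    return out


def save_peaks_json(peaklists: list[PeakList], path) -> None:
    data = {pl.molecule_id: [
        {"shift": p.shift, "couplings": list(p.couplings),
         "n_protons": p.n_protons, "atom_type": p.atom_type}
        for p in pl.peaks] for pl in peaklists}
    Path(path).write_text(json.dumps(data, indent=1))


def load_feature_csv(path):
    """Feature CSV with an id column -> (ids, X, feature_names)."""
    frame = pd.read_csv(path)
    if "id" not in frame.columns:
        raise ValueError(f"feature file {path} lacks an 'id' column")
    cols = [c for c in frame.columns if c != "id"]
    return (frame["id"].astype(str).tolist(),
            frame[cols].to_numpy(dtype=float), cols)


def export_sdf(records, path) -> int:
    """Write molecule records (with conformers where present) to an SDF file.

    Returns the number of molecules written.
    """
    from rdkit import Chem

    n = 0
    with Chem.SDWriter(str(path)) as writer:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:
                continue
            if rec.conformer is not None:
                mol = Chem.AddHs(mol)
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(np.asarray(rec.conformer)):
                    conf.SetAtomPosition(i, (float(x), float(y), float(z)))
                mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", rec.id)
            mol.SetProp("source_class", rec.source_class)
            writer.write(mol)
            n += 1
    return n
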