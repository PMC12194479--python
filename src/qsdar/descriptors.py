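"""Fingerprints, molecular descriptor blocks and drug-likeness flags.

All structure handling goes through RDKit.  The block-length registry records
what the toolkit actually produces; the 1D&2D block in particular is "the
toolkit's full standard descriptor list" and its length is metadata rather
than a contract.  The quantum block is filled from synthetic frontier-orbital
stubs — surrogate-model DFT properties are outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FingerprintVector",
    "DescriptorBlock",
    "FeaturizationError",
    "FINGERPRINT_LENGTHS",
    "BLOCK_LENGTHS",
    "compute_fingerprint",
    "compute_descriptor_block",
    "heavy_atom_mol_wt",
    "drug_likeness_flags",
    "fingerprint_matrix",
]

FINGERPRINT_LENGTHS = {"maccs166": 166, "circular1024": 1024, "path2048": 2048}

#: Fixed block lengths; ``oneD_twoD`` is the toolkit's standard list and its
#: length is recorded here from the installed version.
BLOCK_LENGTHS = {
    "oneD_twoD": len(Descriptors._descList),
    "autocorr3D": 80,
    "getaway": 273,
    "rdf": 210,
    "quantum": 5,
}

#: Inclusive drug-likeness ranges: heavy-atom MW and logP (Ghose), NP-likeness.
GHOSE_MW_RANGE = (160.0, 480.0)
GHOSE_LOGP_RANGE = (-0.4, 5.6)
NPL_RANGE = (-1.0, 1.0)


class FeaturizationError(ValueError):
    """Raised when a structure cannot be parsed or featurized."""


@dataclass(frozen=True)
class FingerprintVector:
    kind: str
    bits: np.ndarray  # uint8 0/1 vector of the stated length

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        expected = FINGERPRINT_LENGTHS.get(self.kind)
        if expected is None:
            raise ValueError(f"unknown fingerprint kind: {self.kind!r}")
        if bits.shape != (expected,):
            raise ValueError(
                f"{self.kind} fingerprint must have length {expected}, got {bits.shape}")

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


@dataclass(frozen=True)
class DescriptorBlock:
    family: str
    values: np.ndarray
    names: tuple[str, ...]
    imputed: tuple[bool, ...] = ()  # per-column: was NaN/inf replaced by 0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names lengths differ")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("descriptor block contains non-finite values after imputation")


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    smiles = getattr(mol_or_smiles, "smiles", mol_or_smiles)
    if not isinstance(smiles, str) or not smiles:
        raise FeaturizationError(f"empty or invalid structure input: {mol_or_smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_RDKIT_FP = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)


def compute_fingerprint(mol_or_smiles, kind: str) -> FingerprintVector:
    """Binary fingerprint of the stated length.

    ``maccs166`` is the 166-key MACCS set (the toolkit's unused bit 0 is
    dropped); ``circular1024`` is a radius-2 circular (Morgan) fingerprint;
    ``path2048`` is the toolkit's path-based fingerprint.  Identical canonical
    structures give identical bits.
    """
    mol = _as_mol(mol_or_smiles)
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError("structure has no atoms")
    if kind == "maccs166":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(167, dtype=np.uint8)
        bits[list(fp.GetOnBits())] = 1
        return FingerprintVector(kind, bits[1:])
    if kind == "circular1024":
        return FingerprintVector(kind, np.array(_MORGAN.GetFingerprint(mol)))
    if kind == "path2048":
        return FingerprintVector(kind, np.array(_RDKIT_FP.GetFingerprint(mol)))
    raise ValueError(f"unknown fingerprint kind: {kind!r}")


def _with_conformer(mol_or_record) -> Chem.Mol:
    """Molecule with an explicit 3D conformer, from a record or an embedded Mol."""
    conf = getattr(mol_or_record, "conformer", None)
    if conf is not None:
        mol = Chem.AddHs(_as_mol(mol_or_record))
        coords = np.asarray(conf, dtype=float)
        if coords.shape != (mol.GetNumAtoms(), 3):
            raise FeaturizationError(
                f"conformer shape {coords.shape} does not match "
                f"{mol.GetNumAtoms()} atoms (H included)")
        c = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(coords):
            c.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.AddConformer(c, assignId=True)
        return mol
    mol = _as_mol(mol_or_record)
    if isinstance(mol_or_record, Chem.Mol) and mol.GetNumConformers() > 0:
        return mol
    raise FeaturizationError(
        "3D descriptor families require a conformer on the record")


def compute_descriptor_block(mol_or_record, family: str,
                             quantum_stub=None) -> DescriptorBlock:
    """Numeric descriptor vector of the family's fixed length.

    NaN or infinite columns are imputed to 0 and flagged per column.  3D
    families (``autocorr3D``, ``getaway``, ``rdf``) require a conformer;
    ``quantum`` reads the supplied stub object.
    """
    if family == "quantum":
        if quantum_stub is None:
            quantum_stub = getattr(mol_or_record, "quantum", None)
        if quantum_stub is None:
            raise FeaturizationError("quantum family requires a QuantumDescriptorStub")
        names = ("e_homo_ev", "e_lumo_ev", "gap_ev", "dm_nbo_debye", "dm_dft_debye")
        values = np.array([quantum_stub.e_homo, quantum_stub.e_lumo,
                           quantum_stub.gap, quantum_stub.dm_nbo,
                           quantum_stub.dm_dft])
    elif family == "oneD_twoD":
        mol = _as_mol(mol_or_smiles=mol_or_record)
        names, values = [], []
        for name, fn in Descriptors._descList:
            try:
                values.append(float(fn(mol)))
            except Exception:
                values.append(np.nan)
            names.append(name)
        names, values = tuple(names), np.array(values)
    elif family in ("autocorr3D", "getaway", "rdf"):
        mol = _with_conformer(mol_or_record)
        fn = {"autocorr3D": rdMolDescriptors.CalcAUTOCORR3D,
              "getaway": rdMolDescriptors.CalcGETAWAY,
              "rdf": rdMolDescriptors.CalcRDF}[family]
        values = np.asarray(fn(mol), dtype=float)
        names = tuple(f"{family}_{i:03d}" for i in range(len(values)))
    else:
        raise ValueError(f"unknown descriptor family: {family!r}")

    values = np.asarray(values, dtype=float)
    expected = BLOCK_LENGTHS[family]
    if values.shape != (expected,):
        raise FeaturizationError(
            f"{family} block produced {values.shape}, expected length {expected}")
    bad = ~np.isfinite(values)
    values = np.where(bad, 0.0, values)
    return DescriptorBlock(family=family, values=values, names=tuple(names),
                           imputed=tuple(bool(b) for b in bad))


def heavy_atom_mol_wt(mol_or_smiles) -> float:
    """Molecular weight summed over non-hydrogen atoms (Da)."""
    return float(Descriptors.HeavyAtomMolWt(_as_mol(mol_or_smiles)))


def drug_likeness_flags(heavy_mw: float, logp: float, npl: float):
    """Inclusive range checks: Ghose heavy-atom MW 160–480 Da, Ghose logP
    −0.4–5.6, NP-likeness −1–1.  Returns (ghose_mw, ghose_logp, npl_in_range)."""
    for name, v in (("heavy_mw", heavy_mw), ("logp", logp), ("npl", npl)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing or non-finite attribute: {name}")
    return (GHOSE_MW_RANGE[0] <= heavy_mw <= GHOSE_MW_RANGE[1],
            GHOSE_LOGP_RANGE[0] <= logp <= GHOSE_LOGP_RANGE[1],
            NPL_RANGE[0] <= npl <= NPL_RANGE[1])


def fingerprint_matrix(smiles_list, kind: str):
    """Fingerprints for many structures; failures are collected, not raised.

    Returns (list of FingerprintVector | None, list of (index, message)).
    """
    fps, failures = [], []
    for i, smi in enumerate(smiles_list):
        try:
            fps.append(compute_fingerprint(smi, kind))
        except FeaturizationError as exc:
            fps.append(None)
            failures.append((i, str(exc)))
    return fps, failures
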