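"""Synthetic benchmark generator for the screening pipeline.

Emulates the statistical structure of a docked natural-product library so that
every downstream stage (sanitation, activity proxy, spectral encoding, model
training, applicability domain) is testable without external data:

* a binary activity class with a configurable prevalence (default 40%,
  matching a library where roughly two in five members dock below the 10 µM
  equivalent);
* class-conditional pIC50 values from truncated normals (actives centred at
  6.0, inactives at 4.0, sd 0.8, truncated at the 10 µM boundary pIC50 = 5 so
  class and potency never disagree);
* docking free energies ΔG_B tied to pIC50 through the thermodynamic constant
  ln(10)·R·T with additive Gaussian noise, clipped to the plausible
  [−20, −2] kcal/mol window;
* ¹H peak lists whose chemical-shift region occupancy (aliphatic /
  heteroatom-adjacent / aromatic) carries a learnable activity signal scaled
  by ``spectral_signal_strength``, plus uniform decoy peaks;
* real RDKit-parseable structures drawn from a bundled scaffold enumeration,
  with physchem attributes computed from the structures themselves.

One global seed derives per-stage seeds by fixed offsets, so the same config
always produces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import scaffolds
from .activity import PIC50_KCAL, classify_activity
from .spectra import Peak, PeakList

__all__ = [
    "SyntheticConfig",
    "MoleculeRecord",
    "QuantumDescriptorStub",
    "LibraryEntry",
    "generate_library",
    "generate_calibration_set",
    "split_train_test",
    "library_to_frame",
    "peaklists_to_frame",
]

# Fixed per-stage seed offsets (all stages derive from the one global seed).
_SEED_CLASS = 11
_SEED_PIC50 = 23
_SEED_DG = 37
_SEED_PEAKS = 41
_SEED_STRUCT = 53
_SEED_QM = 67

#: Latent potency mixture: class-conditional means/sd of true pIC50.
ACTIVE_MEAN, INACTIVE_MEAN, PIC50_SD = 6.0, 4.0, 0.8

#: Chemical-shift regions (ppm) and their baseline sampling probabilities.
REGIONS = {
    "aliphatic": (0.5, 3.0),
    "heteroatom": (3.0, 5.5),
    "aromatic": (6.5, 8.5),
}
_BASE_PROBS = {"aliphatic": 0.55, "heteroatom": 0.30, "aromatic": 0.15}
_DECOY_PROB = 0.10  # uniform-anywhere decoy peaks, class-independent

_SOURCE_CLASSES = ("unclassified", "plant", "fungi", "marine", "bacteria")
_SOURCE_PROBS = (0.78, 0.14, 0.04, 0.03, 0.01)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic library."""

    n_molecules: int = 5000
    active_fraction: float = 0.40
    target_calibration_r: float = 0.32
    noise_sd_dg: float = 3.2  # kcal/mol; reproduces a weak (~0.3) pIC50/ΔG correlation
    spectral_signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("active_fraction", "target_calibration_r",
                     "noise_sd_dg", "spectral_signal_strength"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.n_molecules < 0:
            raise ValueError(f"n_molecules must be >= 0, got {self.n_molecules}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError(
                f"active_fraction must be in [0, 1], got {self.active_fraction}")
        if not abs(self.target_calibration_r) < 1:
            raise ValueError(
                f"|target_calibration_r| must be < 1, got {self.target_calibration_r}")
        if self.noise_sd_dg < 0:
            raise ValueError(f"noise_sd_dg must be >= 0, got {self.noise_sd_dg}")
        if self.spectral_signal_strength < 0:
            raise ValueError(
                f"spectral_signal_strength must be >= 0, got {self.spectral_signal_strength}")


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles: str
    source_class: str
    heavy_atom_mol_wt: float  # Da, hydrogens ignored
    mol_logp: float
    np_likeness: float
    conformer: np.ndarray | None = None  # optional (n_atoms, 3) Angstrom coords


@dataclass(frozen=True)
class QuantumDescriptorStub:
    """Synthetic frontier-orbital/dipole descriptors (eV, Debye)."""

    e_homo: float
    e_lumo: float
    gap: float
    dm_nbo: float
    dm_dft: float


@dataclass(frozen=True)
class LibraryEntry:
    molecule: MoleculeRecord
    peaks: PeakList
    delta_g: float  # kcal/mol, always within [-20, -2]
    activity_class: str  # ground-truth class label
    true_pic50: float
    quantum: QuantumDescriptorStub


def _region_probs(active: bool, signal: float) -> np.ndarray:
    """Per-peak region probabilities; actives get extra aromatic mass."""
    p_arom = _BASE_PROBS["aromatic"]
    if active:
        p_arom = min(p_arom + 0.25 * signal, 0.85)
    rest = 1.0 - _DECOY_PROB - p_arom
    base_rest = _BASE_PROBS["aliphatic"] + _BASE_PROBS["heteroatom"]
    return np.array([
        _BASE_PROBS["aliphatic"] * rest / base_rest,
        _BASE_PROBS["heteroatom"] * rest / base_rest,
        p_arom,
        _DECOY_PROB,
    ])


def _sample_peaklist(rng: np.random.Generator, mol_id: str, active: bool,
                     signal: float) -> PeakList:
    n_peaks = int(rng.integers(5, 26))
    probs = _region_probs(active, signal)
    regions = list(REGIONS) + ["decoy"]
    peaks = []
    for _ in range(n_peaks):
        region = regions[rng.choice(4, p=probs)]
        if region == "decoy":
            shift = rng.uniform(0.0, 10.0)
        else:
            lo, hi = REGIONS[region]
            shift = rng.uniform(lo, hi)
        n_j = int(rng.integers(0, 4))
        if region == "aromatic":
            couplings = tuple(rng.uniform(6.0, 9.0, size=n_j))  # ortho-range J
        else:
            couplings = tuple(rng.uniform(0.0, 18.0, size=n_j))
        peaks.append(Peak(shift=float(shift), couplings=couplings,
                          n_protons=int(rng.integers(1, 4))))
    return PeakList(molecule_id=mol_id, peaks=tuple(peaks))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_library(config: SyntheticConfig,
                     conformers: bool = False) -> list[LibraryEntry]:
    """Generate a synthetic screening library under the configured conditions.

    The class assignment is an exact stratified draw (round(n·active_fraction)
    actives, shuffled), so the realised prevalence is always within one
    molecule of the target.  With ``conformers=True`` each structure also gets
    an embedded 3D conformer (slower; needed only for 3D descriptor work).
    """
    n = config.n_molecules
    if n == 0:
        return []
    s = config.seed
    rng_class = np.random.default_rng(s + _SEED_CLASS)
    rng_pic50 = np.random.default_rng(s + _SEED_PIC50)
    rng_dg = np.random.default_rng(s + _SEED_DG)
    rng_peaks = np.random.default_rng(s + _SEED_PEAKS)
    rng_struct = np.random.default_rng(s + _SEED_STRUCT)
    rng_qm = np.random.default_rng(s + _SEED_QM)

    n_active = int(round(n * config.active_fraction))
    active = np.zeros(n, dtype=bool)
    active[:n_active] = True
    rng_class.shuffle(active)

    pic50 = np.empty(n)
    if n_active:
        pic50[active] = _truncnorm(rng_pic50, ACTIVE_MEAN, PIC50_SD, 5.0, np.inf,
                                   n_active)
    if n - n_active:
        pic50[~active] = _truncnorm(rng_pic50, INACTIVE_MEAN, PIC50_SD, -np.inf,
                                    np.nextafter(5.0, -np.inf), n - n_active)

    dg = -PIC50_KCAL * pic50 + config.noise_sd_dg * rng_dg.standard_normal(n)
    dg = np.clip(dg, -20.0, -2.0)

    variant = rng_struct.integers(0, scaffolds.n_variants(), size=n)
    source = rng_struct.choice(len(_SOURCE_CLASSES), size=n, p=_SOURCE_PROBS)
    npl = rng_struct.normal(0.4, 0.9, size=n)

    from rdkit import Chem
    from rdkit.Chem import AllChem, Crippen, Descriptors

    entries: list[LibraryEntry] = []
    width = max(6, len(str(n)))
    for i in range(n):
        smiles = scaffolds.enumerate_smiles(int(variant[i]))
        mol = Chem.MolFromSmiles(smiles)
        conf = None
        if conformers:
            molh = Chem.AddHs(mol)
            if AllChem.EmbedMolecule(molh, randomSeed=int(s + i)) == 0:
                AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
                conf = molh.GetConformer().GetPositions().copy()
        mol_id = f"SYN{i:0{width}d}"
        record = MoleculeRecord(
            id=mol_id,
            smiles=smiles,
            source_class=_SOURCE_CLASSES[int(source[i])],
            heavy_atom_mol_wt=float(Descriptors.HeavyAtomMolWt(mol)),
            mol_logp=float(Crippen.MolLogP(mol)),
            np_likeness=float(npl[i]),
            conformer=conf,
        )
        e_homo = float(rng_qm.normal(-6.5, 0.5))
        e_lumo = e_homo + float(abs(rng_qm.normal(4.5, 1.0))) + 0.1
        dm = float(abs(rng_qm.normal(3.0, 1.5)))
        quantum = QuantumDescriptorStub(
            e_homo=e_homo, e_lumo=e_lumo, gap=e_lumo - e_homo,
            dm_nbo=dm, dm_dft=float(abs(dm + rng_qm.normal(0.0, 0.4))))
        entries.append(LibraryEntry(
            molecule=record,
            peaks=_sample_peaklist(rng_peaks, mol_id, bool(active[i]),
                                   config.spectral_signal_strength),
            delta_g=float(dg[i]),
            activity_class=str(classify_activity(float(pic50[i]))),
            true_pic50=float(pic50[i]),
            quantum=quantum,
        ))
    return entries


def generate_calibration_set(n: int, target_r: float = 0.32,
                             seed: int = 0) -> pd.DataFrame:
    """Bivariate (experimental pIC50, ΔG_B) sample with tunable correlation.

    Emulates a literature calibration set of known actives.  pIC50 is drawn
    from the active component N(6.0, 0.8); ΔG_B has a Gaussian spread of
    1.5 kcal/mol about the thermodynamic mean and a population Pearson
    correlation with pIC50 of −|target_r| (stronger binding, i.e. more
    negative energy, accompanies higher potency).  Returned ΔG_B is clipped
    to the plausible [−20, −2] window.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 calibration pairs, got {n}")
    if not np.isfinite(target_r) or not abs(target_r) < 1:
        raise ValueError(f"|target_r| must be < 1, got {target_r}")
    rng = np.random.default_rng(seed)
    rho = -abs(target_r)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    pic50 = ACTIVE_MEAN + PIC50_SD * z1
    dg = -PIC50_KCAL * ACTIVE_MEAN + 1.5 * z2
    return pd.DataFrame({
        "pic50_exp": pic50,
        "dg_kcal_mol": np.clip(dg, -20.0, -2.0),
    })


def split_train_test(library: list, test_ratio: float, seed: int = 0):
    """Random, disjoint, exhaustive train/test partition.

    ``|test| = round(N · test_ratio)`` (half-up), membership determined by the
    seed alone.
    """
    if not 0.0 < test_ratio < 1.0:
        raise ValueError(f"test_ratio must be in (0, 1), got {test_ratio}")
    n = len(library)
    if n == 0:
        raise ValueError("cannot split an empty library")
    n_test = int(math.floor(n * test_ratio + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [library[i] for i in range(n) if i not in test_idx]
    test = [library[i] for i in range(n) if i in test_idx]
    return train, test


def library_to_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    """One row per molecule: id, smiles, source, ΔG, true pIC50, class."""
    return pd.DataFrame([{
        "id": e.molecule.id,
        "smiles": e.molecule.smiles,
        "source_class": e.molecule.source_class,
        "heavy_atom_mol_wt": e.molecule.heavy_atom_mol_wt,
        "mol_logp": e.molecule.mol_logp,
        "np_likeness": e.molecule.np_likeness,
        "dg_kcal_mol": e.delta_g,
        "true_pic50": e.true_pic50,
        "class": e.activity_class,
    } for e in entries])


def peaklists_to_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    """Long-format peak table: id, shift_ppm, j_hz (';'-joined), n_protons."""
    rows = []
    for e in entries:
        for p in e.peaks.peaks:
            rows.append({
                "id": e.molecule.id,
                "shift_ppm": p.shift,
                "j_hz": ";".join(f"{j:.4f}" for j in p.couplings),
                "n_protons": p.n_protons,
                "atom_type": p.atom_type,
            })
    return pd.DataFrame(rows)
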