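"""Bundled natural-product-like scaffolds for the synthetic library.

Each scaffold SMILES carries a single attachment point written as ``[*:1]``;
:func:`enumerate_smiles` grafts a substituent fragment onto it, giving a few
hundred distinct, chemically valid structures (coumarins, flavonoids, indole
and quinoline alkaloid cores, terpenoid rings, simple glycosides, quinones,
biphenyls, ...) without shipping a structure database.  The enumeration is for
realism of the structure-handling code paths, not a model of any database's
chemical-space distribution.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

__all__ = ["SCAFFOLDS", "SUBSTITUENTS", "n_variants", "enumerate_smiles"]

SCAFFOLDS: tuple[str, ...] = (
    "O=c1oc2ccccc2cc1[*:1]",              # coumarin, 3-substituted
    "O=c1cc(-[*:1])oc2ccccc12",           # chromone / flavone core
    "[*:1]c1c[nH]c2ccccc12",              # 3-substituted indole
    "O=C1CC(c2ccc([*:1])cc2)Oc2ccccc21",  # flavanone
    "[*:1]c1ccc2ncccc2c1",                # quinoline
    "OCC1OC(O[*:1])C(O)C(O)C1O",          # pyranose O-glycoside
    "O=C1CCC2CCCCC2C1[*:1]",              # decalone (terpenoid-like)
    "CC1CCC(C(C)C)CC1[*:1]",              # p-menthane monoterpene
    "O=C1C=C([*:1])C(=O)c2ccccc21",       # 1,4-naphthoquinone
    "O=C(/C=C/c1ccccc1)c1ccc([*:1])cc1",  # chalcone
    "[*:1]c1cc2ccccc2o1",                 # benzofuran
    "[*:1]c1ccncc1",                      # pyridine
    "[*:1]c1ncccn1",                      # pyrimidine
    "[*:1]c1cnc[nH]1",                    # imidazole
    "[*:1]c1ccc[nH]1",                    # pyrrole
    "O=C1OC([*:1])C=C1",                  # butenolide
    "O=C1OC([*:1])CCCCC1",                # medium-ring lactone
    "O=c1c2ccccc2oc2ccc([*:1])cc12",      # xanthone
    "[*:1]c1ccc2c(c1)[nH]c1ccccc12",      # carbazole
    "[*:1]c1cccs1",                       # thiophene
    "CN1CCCCC1[*:1]",                     # N-methylpiperidine alkaloid
    "O=c1c(-c2ccc([*:1])cc2)coc2ccccc12", # isoflavone
    "O=C1c2ccccc2C(=O)c2cc([*:1])ccc21",  # anthraquinone
    "[*:1]c1ccc(/C=C/c2ccccc2)cc1",       # stilbene
    "O=C(O)c1ccc(O)c([*:1])c1",           # hydroxybenzoic acid
    "COC(=O)/C=C/c1ccc([*:1])cc1",        # cinnamate ester
    "CC1=CCC([*:1])CC1",                  # cyclohexene terpene fragment
    "CC1(C)C2CCC1([*:1])CC2",             # pinane-type bicyclic
    "OCC1OC([*:1])C(O)C1O",               # furanose glycoside
    "COc1ccc([*:1])cc1O",                 # guaiacol (lignan fragment)
    "[*:1]c1ccc2ccccc2c1",                # naphthalene
    "[*:1]c1ccc(-c2ccccc2)cc1",           # biphenyl
    "[*:1]c1ccc2c(c1)OCO2",               # benzodioxole
    "O=c1[nH]c([*:1])nc2ccccc12",         # quinazolin-4(3H)-one
    "C1OC(c2ccccc2)C([*:1])C1",           # tetrahydrofuran lignan core
    "C1CCN2CCCC2C1[*:1]",                 # indolizidine
)

SUBSTITUENTS: tuple[str, ...] = (
    "[*:1]C",            # methyl
    "[*:1]O",            # hydroxy
    "[*:1]CC",           # ethyl
    "[*:1]OC",           # methoxy
    "[*:1]Cl",           # chloro (halogenated NPs)
    "[*:1]Br",           # bromo (marine NPs)
    "[*:1]N",            # amino
    "[*:1]CC=C(C)C",     # prenyl
    "[*:1]C(C)=O",       # acetyl
    "[*:1]C(=O)O",       # carboxy
    "[*:1]c1ccccc1",     # phenyl
    "[*:1]CO",           # hydroxymethyl
    "[*:1]C(C)C",        # isopropyl
)


def n_variants() -> int:
    return len(SCAFFOLDS) * len(SUBSTITUENTS)


@lru_cache(maxsize=None)
def enumerate_smiles(index: int) -> str:
    """Canonical SMILES for variant ``index`` (scaffold-major enumeration)."""
    index = index % n_variants()
    scaffold = SCAFFOLDS[index % len(SCAFFOLDS)]
    sub = SUBSTITUENTS[index // len(SCAFFOLDS)]
    combined = Chem.MolFromSmiles(f"{scaffold}.{sub}")
    if combined is None:  # pragma: no cover - scaffold list is validated in tests
        raise ValueError(f"invalid scaffold/substituent pair: {scaffold} + {sub}")
    mol = Chem.molzip(combined)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
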