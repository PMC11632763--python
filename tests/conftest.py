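"""Shared fixtures: random molecule builder and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from bbbcliques.simulate import GeneratorSpec, generate_dataset

# ring systems spanning plain, heteroaromatic, fused and bridged cases
RING_LIBRARY = [
    "C1CCCC1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1COCCN1",
    "C1CNC1",
    "C1CCOCC1",
    "c1ccccc1",
    "c1ccncc1",
    "c1nnn[nH]1",
    "C1CSCN1",
    "C1=CCC=CC1",
    "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "C1CC2CCC1CC2",
    "C1CC2(CC1)CC2",
]

CHAIN_LIBRARY = ["CCO", "CC(=O)O", "CCN", "CCCC", "CC(C)C", "CCS", "FC(F)F", "CC#N", "C=CC=O"]

SUBSTITUENTS = [("C", 1), ("F", 1), ("O", 1), ("N", 2), ("Cl", 1)]


def random_molecule(rng: np.random.Generator, max_heavy: int = 20) -> str:
    """A random valid SMILES of at most ``max_heavy`` heavy atoms."""
    if rng.uniform() < 0.3:
        return str(rng.choice(CHAIN_LIBRARY))
    base = str(rng.choice(RING_LIBRARY))
    mol = Chem.RWMol(Chem.MolFromSmiles(base))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    n_sub = int(rng.integers(0, 4))
    for _ in range(n_sub):
        if mol.GetNumAtoms() >= max_heavy:
            break
        mol.UpdatePropertyCache(strict=False)
        symbol, order = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() >= order
        ]
        if not sites:
            continue
        site = int(rng.choice(sites))
        idx = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(site, idx, Chem.BondType.SINGLE if order == 1 else Chem.BondType.DOUBLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return base
    return Chem.MolToSmiles(out)


@pytest.fixture(scope="session")
def random_smiles_200():
    rng = np.random.default_rng(20240901)
    return [random_molecule(rng) for _ in range(200)]


@pytest.fixture(scope="session")
def small_dataset():
    """500-molecule synthetic dataset with its analytic marginals."""
    return generate_dataset(GeneratorSpec(n_molecules=500, seed=11))


@pytest.fixture(scope="session")
def tiny_tsv(tmp_path_factory):
    """A 4-row table in the native column layout, one row unparseable."""
    path = tmp_path_factory.mktemp("data") / "tiny.tsv"
    rows = [
        "compound_name\tSMILES\tInChI\tBBB+/BBB-\tgroup\tlogBB",
        "ethanol\tCCO\t\tBBB+\tA\t-0.5",
        "fluoromethane\tCF\t\tyes\tB\t",
        "bad\tnot_a_smiles\t\tno\tC\t",
        "azetidine\tC1CNC1\t\tBBB-\tD\t-1.2",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
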