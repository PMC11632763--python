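"""Synthetic molecule tables with planted clique -> permeability structure.

The generator assembles simple "decorated ring" molecules: one ring
building block (cyclopentane, piperidine, morpholine, azetidine,
tetrahydropyran by default) decorated with up to three distinct
substituent bond blocks (methyl, fluoro, hydroxyl, exocyclic imine),
each on its own ring carbon.  The chemistry is deliberately minimal so
that the clique decomposition recovers exactly the planted blocks,
making clique-level ground truth exact.

The permeability label is Bernoulli with

    logit = beta0 + sum_c beta_c * [block c present],

so every block's marginal P(y=1 | block present) has a closed form,
computed by :func:`analytic_marginals` through exhaustive enumeration of
the finite composition space (no simulation).  An optional log BB value
(emitted for a "grade A" subset of rows) is a noisy monotone function
of the planted logit, giving the exploratory-analysis code a real
signal to find.  Output uses the B3DB column layout, so generated files
round-trip through :func:`bbbcliques.data.read_table` unchanged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .data import Dataset, MoleculeRecord

__all__ = ["GeneratorSpec", "generate_dataset", "analytic_marginals", "BOND_BLOCKS"]

#: Substituent bond blocks: clique string -> (atom symbol, bond order).
BOND_BLOCKS: dict[str, tuple[str, int]] = {
    "CC": ("C", 1),  # methyl
    "CF": ("F", 1),  # fluoro
    "CO": ("O", 1),  # hydroxyl
    "C=N": ("N", 2),  # exocyclic imine
}

_DEFAULT_RING_EFFECTS = {
    "C1CCCC1": 4.0,  # cyclopentane
    "C1CCNCC1": 3.0,  # piperidine
    "C1COCCN1": 2.0,  # morpholine
    "C1CNC1": -4.0,  # azetidine
    "C1CCOCC1": -2.0,  # tetrahydropyran
}
_DEFAULT_BOND_EFFECTS = {"CF": 4.0, "CC": 1.0, "CO": -1.0, "C=N": -3.0}


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``effect_log_odds`` maps each building block (ring or substituent
    clique string) to its additive log-odds effect beta_c on the
    permeability label.  If ``intercept`` is None it is calibrated by
    bisection so the population positive rate equals ``imbalance``
    (default 0.64, the rough positive fraction of the curated BBB
    database the dialect emulates).  ``max_substituents`` distinct bond
    blocks are drawn per molecule, the count uniform on
    0..max_substituents.
    """

    n_molecules: int = 2000
    ring_blocks: tuple[str, ...] = tuple(_DEFAULT_RING_EFFECTS)
    bond_blocks: tuple[str, ...] = tuple(_DEFAULT_BOND_EFFECTS)
    effect_log_odds: dict[str, float] = field(
        default_factory=lambda: {**_DEFAULT_RING_EFFECTS, **_DEFAULT_BOND_EFFECTS}
    )
    intercept: float | None = None
    imbalance: float = 0.64
    max_substituents: int = 3
    seed: int = 0
    log_bb_fraction: float = 0.15
    log_bb_scale: float = 0.5  # log BB = -1 + scale * logit + noise
    log_bb_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for b in self.bond_blocks:
            if b not in BOND_BLOCKS:
                raise ValueError(f"unknown bond block {b!r}; known: {sorted(BOND_BLOCKS)}")
        for r in self.ring_blocks:
            if Chem.MolFromSmiles(r) is None:
                raise ValueError(f"ring block {r!r} does not parse")
        if not 0 < self.imbalance < 1:
            raise ValueError("imbalance must be in (0, 1)")


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _attachment_sites(ring_smiles: str) -> list[int]:
    """Indices of ring carbons able to take a substituent (free valence >= 1)."""
    mol = Chem.MolFromSmiles(ring_smiles)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "C" and atom.GetTotalNumHs() >= 1:
            sites.append(atom.GetIdx())
    return sites


def _feasible(ring: str, subset: tuple[str, ...]) -> bool:
    """Can ``subset`` of bond blocks be placed on distinct carbons of ``ring``?"""
    mol = Chem.MolFromSmiles(ring)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    free = sorted(
        (a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1),
        reverse=True,
    )
    need = sorted((BOND_BLOCKS[b][1] for b in subset), reverse=True)
    if len(need) > len(free):
        return False
    # greedy: largest valence demand onto largest free valence
    return all(n <= f for n, f in zip(need, free))


def _compositions(spec: GeneratorSpec) -> list[tuple[float, str, tuple[str, ...]]]:
    """Enumerate (probability, ring, substituent subset) over the finite space.

    A molecule is drawn as: ring uniform over ring blocks; substituent
    count uniform over the sizes feasible for that ring (0..max);
    subset uniform over the feasible subsets of that size.
    """
    out = []
    p_ring = 1.0 / len(spec.ring_blocks)
    for ring in spec.ring_blocks:
        by_size: dict[int, list[tuple[str, ...]]] = {}
        for s in range(spec.max_substituents + 1):
            subs = [c for c in itertools.combinations(spec.bond_blocks, s) if _feasible(ring, c)]
            if subs:
                by_size[s] = subs
        p_size = 1.0 / len(by_size)
        for s, subs in by_size.items():
            for sub in subs:
                out.append((p_ring * p_size / len(subs), ring, sub))
    return out


def _logit(spec: GeneratorSpec, intercept: float, ring: str, subset: tuple[str, ...]) -> float:
    eff = spec.effect_log_odds
    return intercept + eff.get(ring, 0.0) + sum(eff.get(b, 0.0) for b in subset)


def calibrated_intercept(spec: GeneratorSpec) -> float:
    """Intercept giving the target positive rate (bisection on the exact rate)."""
    if spec.intercept is not None:
        return spec.intercept
    comps = _compositions(spec)

    def rate(b0: float) -> float:
        return sum(p * _sigmoid(_logit(spec, b0, r, s)) for p, r, s in comps)

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if rate(mid) < spec.imbalance:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def analytic_marginals(spec: GeneratorSpec) -> dict[str, float]:
    """Exact P(y=1 | block present) per building block, by enumeration."""
    b0 = calibrated_intercept(spec)
    comps = _compositions(spec)
    marg: dict[str, float] = {}
    for block in list(spec.ring_blocks) + list(spec.bond_blocks):
        num = den = 0.0
        for p, ring, sub in comps:
            if block == ring or block in sub:
                den += p
                num += p * _sigmoid(_logit(spec, b0, ring, sub))
        if den > 0:
            marg[block] = num / den
    return marg


def _assemble(ring: str, subset: tuple[str, ...], rng: np.random.Generator) -> str:
    """Attach each substituent to its own randomly chosen ring carbon."""
    mol = Chem.RWMol(Chem.MolFromSmiles(ring))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    # place double-bond substituents first so valence-2 sites are not used up
    order = sorted(subset, key=lambda b: -BOND_BLOCKS[b][1])
    used: set[int] = set()
    for block in order:
        symbol, bond_order = BOND_BLOCKS[block]
        mol.UpdatePropertyCache(strict=False)
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C"
            and a.GetIdx() not in used
            and a.GetTotalNumHs() >= bond_order
            and a.IsInRing()
        ]
        if not sites:
            raise RuntimeError(f"unsatisfiable attachment: {block} on {ring} with {subset}")
        site = int(rng.choice(sites))
        used.add(site)
        new_idx = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(site, new_idx, Chem.BondType.SINGLE if bond_order == 1 else Chem.BondType.DOUBLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_dataset(spec: GeneratorSpec) -> tuple[Dataset, dict[str, float]]:
    """Draw a synthetic dataset and return it with its ground-truth marginals.

    Every row carries a valid SMILES, a BBB+/BBB- label, a quality
    grade, and (for a random ``log_bb_fraction`` of rows, flagged grade
    A) a log BB value generated as ``-1 + log_bb_scale * logit + noise``
    so that higher planted permeability log-odds mean higher log BB.
    """
    rng = np.random.default_rng(spec.seed)
    b0 = calibrated_intercept(spec)
    comps = _compositions(spec)
    probs = np.array([p for p, _, _ in comps])
    probs = probs / probs.sum()

    records: list[MoleculeRecord] = []
    for i in range(spec.n_molecules):
        idx = rng.choice(len(comps), p=probs)
        _, ring, subset = comps[idx]
        smiles = _assemble(ring, subset, rng)
        z = _logit(spec, b0, ring, subset)
        label = int(rng.uniform() < _sigmoid(z))
        has_lbb = rng.uniform() < spec.log_bb_fraction
        lbb = None
        grade = "A" if has_lbb else str(rng.choice(["B", "C", "D"], p=[0.5, 0.4, 0.1]))
        if has_lbb:
            lbb = float(-1.0 + spec.log_bb_scale * z + rng.normal(0.0, spec.log_bb_noise_sd))
        records.append(
            MoleculeRecord(
                row_index=i,
                name=f"synthetic-{i:05d}",
                smiles=smiles,
                canonical_smiles=Chem.MolToSmiles(Chem.MolFromSmiles(smiles)),
                label=label,
                log_bb=round(lbb, 4) if lbb is not None else None,
                quality_grade=grade,
                inchi="",
            )
        )
    dataset = Dataset(records=records, source=f"<synthetic seed={spec.seed}>")
    return dataset, analytic_marginals(spec)
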