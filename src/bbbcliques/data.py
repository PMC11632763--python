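"""Reading, writing and exploring BBB-permeability molecule tables.

The on-disk dialect is the B3DB one: a tab-separated table with a header
row carrying, by default, molecule name, SMILES, InChI, a yes/no
permeability label, a curation quality grade (A-D) and, where available,
a numeric log BB value (log10 of the brain-to-blood concentration
ratio).  Everything downstream works on :class:`Dataset`, an ordered
collection of :class:`MoleculeRecord`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from scipy import stats

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "Dataset",
    "DEFAULT_COLUMN_MAP",
    "POSITIVE_LABELS",
    "NEGATIVE_LABELS",
    "read_table",
    "write_table",
    "canonicalize",
    "log_bb",
    "molecular_weight",
    "clogp",
    "pearson",
    "eda_summary",
    "EDASummary",
]

#: Accepted spellings of the binary permeability label (case-insensitive).
POSITIVE_LABELS = frozenset({"bbb+", "yes", "1", "true"})
NEGATIVE_LABELS = frozenset({"bbb-", "no", "0", "false"})

#: Column names of the native B3DB layout, in file order.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "name": "compound_name",
    "smiles": "SMILES",
    "inchi": "InChI",
    "label": "BBB+/BBB-",
    "grade": "group",
    "log_bb": "logBB",
}

_GRADES = frozenset("ABCD")


@dataclass
class MoleculeRecord:
    """One parsed molecule with its permeability annotation."""

    row_index: int
    name: str
    smiles: str
    canonical_smiles: str
    label: int | None = None
    log_bb: float | None = None
    quality_grade: str | None = None
    inchi: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.quality_grade is not None and self.quality_grade not in _GRADES:
            raise ValueError(f"quality grade must be one of A-D, got {self.quality_grade!r}")


@dataclass
class Dataset:
    """Ordered collection of molecule records plus provenance."""

    records: list[MoleculeRecord]
    source: str = "<memory>"
    column_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        """Labels of the labelled records, in record order."""
        return np.array([r.label for r in self.records if r.label is not None], dtype=int)

    def labelled(self) -> "Dataset":
        recs = [r for r in self.records if r.label is not None]
        return Dataset(records=recs, source=self.source, column_map=self.column_map)

    def to_frame(self) -> pd.DataFrame:
        cm = self.column_map
        rows = []
        for r in self.records:
            rows.append(
                {
                    cm["name"]: r.name,
                    cm["smiles"]: r.smiles,
                    cm["inchi"]: r.inchi if r.inchi is not None else "",
                    cm["label"]: {1: "BBB+", 0: "BBB-"}.get(r.label, ""),
                    cm["grade"]: r.quality_grade if r.quality_grade is not None else "",
                    cm["log_bb"]: r.log_bb if r.log_bb is not None else "",
                }
            )
        return pd.DataFrame(rows)


def _parse_label(raw: object) -> int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text == "":
        return None
    if text in POSITIVE_LABELS:
        return 1
    if text in NEGATIVE_LABELS:
        return 0
    raise ValueError(f"unrecognized permeability label {raw!r}")


def canonicalize(smiles: str) -> str:
    """Canonical SMILES with stereochemistry stripped.

    Two SMILES spellings of the same molecular graph (atom reordering,
    ring-numbering rotation, cis/trans or R/S marks) map to one string,
    so identical molecules written differently share clique fragments.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable or empty SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def read_table(
    path: str,
    column_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a tab-separated molecule table into a :class:`Dataset`.

    ``column_map`` maps the logical field names (``smiles``, ``label``,
    and optionally ``name``, ``inchi``, ``grade``, ``log_bb``) to the
    file's header names; it defaults to the native B3DB layout.  Rows
    whose SMILES fails to parse are dropped, counted in
    ``Dataset.n_excluded`` and logged — never silently discarded.
    """
    cm = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cm.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty input table: {path}")
    for key in ("smiles", "label"):
        if cm[key] not in df.columns:
            raise KeyError(f"mapped column {cm[key]!r} (for {key!r}) not in header {list(df.columns)}")

    records: list[MoleculeRecord] = []
    n_excluded = 0
    for _, row in df.iterrows():
        smi = row[cm["smiles"]]
        try:
            canonical = canonicalize(str(smi))
        except ValueError:
            n_excluded += 1
            logger.warning("dropping row with unparseable SMILES %r", smi)
            continue
        label = _parse_label(row[cm["label"]])
        grade = None
        if cm.get("grade") in df.columns:
            g = row[cm["grade"]]
            if isinstance(g, str) and g.strip():
                grade = g.strip().upper()
        lbb = None
        if cm.get("log_bb") in df.columns:
            v = row[cm["log_bb"]]
            if isinstance(v, str) and v.strip():
                lbb = float(v)
        name = ""
        if cm.get("name") in df.columns and isinstance(row[cm["name"]], str):
            name = row[cm["name"]]
        inchi = None
        if cm.get("inchi") in df.columns and isinstance(row[cm["inchi"]], str):
            inchi = row[cm["inchi"]]
        records.append(
            MoleculeRecord(
                row_index=len(records),
                name=name,
                smiles=str(smi),
                canonical_smiles=canonical,
                label=label,
                log_bb=lbb,
                quality_grade=grade,
                inchi=inchi,
            )
        )
    if n_excluded:
        logger.warning("excluded %d rows with unparseable SMILES", n_excluded)
    return Dataset(records=records, source=str(path), column_map=cm, n_excluded=n_excluded)


def write_table(dataset: Dataset, path: str) -> None:
    """Write a dataset back to its tab-separated dialect."""
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def log_bb(c_brain: float, c_blood: float) -> float:
    """log BB = log10(C_brain / C_blood), the brain-to-blood partition.

    B3DB classifies molecules with log BB >= -1 as permeable (BBB+).
    Both concentrations must be strictly positive and in the same units.
    """
    if c_brain <= 0 or c_blood <= 0:
        raise ValueError("concentrations must be strictly positive")
    return math.log10(c_brain / c_blood)


def _mol_from(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable or empty SMILES: {smiles!r}")
    return mol


def molecular_weight(smiles_or_record: "str | MoleculeRecord") -> float:
    """Average-atomic-mass molecular weight in g/mol, implicit H included."""
    smi = smiles_or_record.canonical_smiles if isinstance(smiles_or_record, MoleculeRecord) else smiles_or_record
    return Descriptors.MolWt(_mol_from(smi))


def clogp(structure: str) -> float:
    """Wildman-Crippen atomic-contribution log P.

    Applies to whole molecules and, as a qualitative lipophilicity
    indicator only, to isolated fragment strings.
    """
    return Crippen.MolLogP(_mol_from(structure))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class EDASummary:
    """Exploratory summary of a labelled dataset (per-class MW / clogP)."""

    per_class_mw: dict[int, np.ndarray]
    per_class_clogp: dict[int, np.ndarray]
    ranges: dict[str, tuple[float, float]]  # keys like "mw/1"
    kde_grids: dict[str, np.ndarray]
    kde_densities: dict[str, np.ndarray | None]
    degenerate: dict[str, bool]
    correlations: pd.DataFrame  # feature x class table of PCC vs log BB
    n_with_log_bb: int

    def correlation_table(self) -> pd.DataFrame:
        return self.correlations


def eda_summary(dataset: Dataset, grid_size: int = 256) -> EDASummary:
    """Per-class molecular-weight and clogP distributions plus log BB correlations.

    For each class (BBB+ = 1, BBB- = 0) the summary holds the raw MW and
    clogP samples, their [min, max] ranges, and a Gaussian kernel density
    estimate (Scott's bandwidth) on a ``grid_size``-point grid.  The
    correlation table gives the Pearson correlation of MW and clogP with
    log BB within each class, over the records for which a log BB value
    is present; records lacking log BB still contribute to the KDEs.
    """
    labelled = [r for r in dataset.records if r.label is not None]
    if not labelled:
        raise ValueError("no labelled records")

    per_mw: dict[int, np.ndarray] = {}
    per_lp: dict[int, np.ndarray] = {}
    ranges: dict[str, tuple[float, float]] = {}
    grids: dict[str, np.ndarray] = {}
    dens: dict[str, np.ndarray | None] = {}
    degen: dict[str, bool] = {}

    values = {
        r.row_index: (molecular_weight(r.canonical_smiles), clogp(r.canonical_smiles))
        for r in labelled
    }
    for cls in (0, 1):
        recs = [r for r in labelled if r.label == cls]
        mw = np.array([values[r.row_index][0] for r in recs])
        lp = np.array([values[r.row_index][1] for r in recs])
        per_mw[cls] = mw
        per_lp[cls] = lp
        for key, arr in ((f"mw/{cls}", mw), (f"clogp/{cls}", lp)):
            if arr.size == 0:
                continue
            lo, hi = float(arr.min()), float(arr.max())
            ranges[key] = (lo, hi)
            is_degen = arr.size < 2 or lo == hi
            degen[key] = is_degen
            pad = 0.05 * (hi - lo) if hi > lo else 1.0
            grid = np.linspace(lo - pad, hi + pad, grid_size)
            grids[key] = grid
            if is_degen:
                dens[key] = None
            else:
                dens[key] = stats.gaussian_kde(arr, bw_method="scott")(grid)

    rows = []
    n_lbb = 0
    for cls in (0, 1):
        recs = [r for r in labelled if r.label == cls and r.log_bb is not None]
        n_lbb += len(recs)
        lbb = np.array([r.log_bb for r in recs], dtype=float)
        for feat, getter in (("molecular weight", 0), ("clogp", 1)):
            feat_vals = np.array([values[r.row_index][getter] for r in recs])
            if len(recs) >= 3 and np.ptp(feat_vals) > 0 and np.ptp(lbb) > 0:
                r_val = pearson(feat_vals, lbb)
            else:
                r_val = float("nan")
            rows.append({"feature": feat, "class": "BBB+" if cls else "BBB-", "pcc_vs_log_bb": r_val})
    corr = pd.DataFrame(rows)
    return EDASummary(
        per_class_mw=per_mw,
        per_class_clogp=per_lp,
        ranges=ranges,
        kde_grids=grids,
        kde_densities=dens,
        degenerate=degen,
        correlations=corr,
        n_with_log_bb=n_lbb,
    )
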