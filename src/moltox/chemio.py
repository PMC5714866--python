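"""Molecule input/output and packaged reference tables.

Molecules enter the pipeline either as V2000 SDF files or as delimited
SMILES tables. Every record is sanitized (valence check) on the way in;
records that fail are *reported*, never silently dropped, because corpus
shrinkage must be auditable. Multi-fragment records (salts) keep the
largest covalent fragment by default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

SourceLabel = Literal["toxin", "nontoxin", "unlabeled"]


class MoleculeIOError(ValueError):
    """Raised when an input file yields no usable molecules."""


@dataclass
class Molecule:
    """A sanitized chemical structure with provenance.

    Attributes
    ----------
    id : str
        Unique identifier within a dataset.
    name : str
        Human-readable name (may equal ``id``).
    smiles : str
        Canonical isomeric SMILES of the sanitized structure.
    source_label : {"toxin", "nontoxin", "unlabeled"}
    """

    id: str
    name: str
    smiles: str
    source_label: SourceLabel = "unlabeled"
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        """The underlying RDKit molecule (lazily re-parsed)."""
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol

    @classmethod
    def from_rdkit(
        cls,
        mol: Chem.Mol,
        id: str,
        name: str | None = None,
        source_label: SourceLabel = "unlabeled",
        keep_largest_fragment: bool = True,
    ) -> "Molecule":
        if keep_largest_fragment:
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
            if len(frags) > 1:
                mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        return cls(
            id=id,
            name=name if name is not None else id,
            smiles=Chem.MolToSmiles(mol),
            source_label=source_label,
            _mol=mol,
        )


@dataclass(frozen=True)
class ParseFailure:
    """One unparsable input record, kept for reporting."""

    index: int
    reason: str


@dataclass(frozen=True)
class BlindPair:
    """An (observed, predicted) pair from a held-out evaluation table."""

    molecule_name: str
    observed: float
    predicted: float


def _unique_ids(mols: Iterable[Molecule]) -> None:
    seen: set[str] = set()
    for m in mols:
        if m.id in seen:
            raise MoleculeIOError(f"duplicate molecule id: {m.id!r}")
        seen.add(m.id)


def read_sdf(
    path: str | Path,
    source_label: SourceLabel = "unlabeled",
    keep_largest_fragment: bool = True,
    return_failures: bool = False,
):
    """Read a V2000 SDF file into sanitized :class:`Molecule` records.

    Parameters
    ----------
    path : path to an existing SDF file.
    return_failures : when True also return the list of
        :class:`ParseFailure` for records RDKit could not sanitize.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MoleculeIOError
        If the file contains zero parsable records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:  # RDKit refuses empty files at construction
        raise MoleculeIOError(f"{path}: zero parsable records") from exc
    mols: list[Molecule] = []
    failures: list[ParseFailure] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            failures.append(ParseFailure(i, "record failed parsing/sanitization"))
            logger.warning("SDF record %d in %s excluded: sanitization failed", i, path)
            continue
        rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        rid = rid or f"record{i}"
        mols.append(
            Molecule.from_rdkit(
                mol, id=rid, source_label=source_label,
                keep_largest_fragment=keep_largest_fragment,
            )
        )
    if not mols:
        raise MoleculeIOError(f"{path}: zero parsable records")
    _unique_ids(mols)
    if return_failures:
        return mols, failures
    return mols


def read_smiles_table(
    path: str | Path,
    sep: str | None = None,
    keep_largest_fragment: bool = True,
    return_failures: bool = False,
):
    """Read a delimited table with ``id`` and ``smiles`` columns.

    An optional ``label`` column maps onto ``source_label`` (values
    ``toxin`` / ``nontoxin``). Invalid SMILES rows are reported with their
    row number; duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise MoleculeIOError(f"{path}: missing required column {col!r}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise MoleculeIOError(f"duplicate molecule id: {dup.iloc[0]!r}")
    mols: list[Molecule] = []
    failures: list[ParseFailure] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        mol = Chem.MolFromSmiles(str(row.smiles))
        if mol is None:
            failures.append(ParseFailure(row_no, f"invalid SMILES {row.smiles!r}"))
            logger.warning("%s row %d excluded: invalid SMILES", path, row_no)
            continue
        label = getattr(row, "label", "unlabeled") or "unlabeled"
        if label not in ("toxin", "nontoxin", "unlabeled"):
            label = "unlabeled"
        mols.append(
            Molecule.from_rdkit(
                mol, id=str(row.id), source_label=label,
                keep_largest_fragment=keep_largest_fragment,
            )
        )
    if not mols:
        raise MoleculeIOError(f"{path}: zero parsable records")
    if return_failures:
        return mols, failures
    return mols


def write_smiles_table(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as a CSV with id, smiles and label columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "label"])
        for m in mols:
            w.writerow([m.id, m.smiles, m.source_label])


_BLIND_FILES = {"LogS": "logs_blind.csv", "LogP": "logp_blind.csv"}
_GRID_FILES = {"descriptor": "descriptor_grid.csv", "fingerprint": "fingerprint_grid.csv"}


def load_blind_fixture(target: str) -> list[BlindPair]:
    """Packaged blind-set (observed, predicted) pairs.

    ``target`` is ``"LogS"`` (90 aqueous-solubility pairs) or ``"LogP"``
    (18 caco-2 permeability pairs), both on the log10 scale.
    """
    if target not in _BLIND_FILES:
        raise ValueError(f"unknown blind-set target {target!r}; use 'LogS' or 'LogP'")
    with resources.files("moltox.data").joinpath(_BLIND_FILES[target]).open() as fh:
        df = pd.read_csv(fh)
    return [
        BlindPair(r["name"], float(r["observed"]), float(r["predicted"]))
        for _, r in df.iterrows()
    ]


def load_grid_reference(kind: str) -> pd.DataFrame:
    """Published random-forest grid performance rows.

    ``kind`` is ``"descriptor"`` (top-k descriptor subsets) or
    ``"fingerprint"`` (top-percent fingerprint subsets). Columns:
    subset, mtry, sensitivity, specificity, precision, accuracy, mcc.
    """
    if kind not in _GRID_FILES:
        raise ValueError(f"unknown grid reference {kind!r}")
    with resources.files("moltox.data").joinpath(_GRID_FILES[kind]).open() as fh:
        return pd.read_csv(fh)
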