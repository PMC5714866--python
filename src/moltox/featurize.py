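"""Molecular featurization: composition, descriptors, fingerprints, tables.

Three feature layers feed the downstream models:

* elemental composition — per-element atom counts, used to contrast toxin
  and non-toxin chemistry (toxins are enriched in halogens);
* 1D/2D molecular descriptors — numeric physicochemical summaries
  (molecular weight, TPSA, ring counts, ...) from the RDKit registry;
* binary substructure fingerprints — concatenated fixed-width bit
  families, each bit flagging a structural fragment.

Feature tables apply a strict column-exclusion rule: any feature that is
incomputable for at least one molecule is dropped (and logged) so that no
missing values reach the learners.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.model_selection import train_test_split

from .chemio import Molecule

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # toxin
NEGATIVE_LABEL = 0  # nontoxin


# --------------------------------------------------------------------------
# elemental composition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomCompositionProfile:
    """Per-element atom counts for one molecule."""

    counts: Mapping[str, int]
    include_hydrogens: bool

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)


def atom_composition(mol: Molecule, include_h: bool = True) -> AtomCompositionProfile:
    """Count atoms per element; implicit hydrogens included when asked."""
    counts: Counter[str] = Counter()
    h = 0
    for atom in mol.mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        h += atom.GetTotalNumHs()
    if include_h:
        counts["H"] += h
        if counts["H"] == 0:
            del counts["H"]
    return AtomCompositionProfile(dict(counts), include_h)


def compare_composition(
    set_a: Sequence[Molecule],
    set_b: Sequence[Molecule],
    include_h: bool = True,
    names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-element mean count and presence fraction for two molecule sets.

    Returns a DataFrame indexed by element with columns
    ``mean_<name>``, ``presence_<name>`` for each set.
    """
    if not set_a or not set_b:
        raise ValueError("both molecule sets must be non-empty")
    profs = {
        name: [atom_composition(m, include_h) for m in mols]
        for name, mols in zip(names, (set_a, set_b))
    }
    elements = sorted({e for ps in profs.values() for p in ps for e in p.counts})
    out = {}
    for name, ps in profs.items():
        out[f"mean_{name}"] = [np.mean([p[e] for p in ps]) for e in elements]
        out[f"presence_{name}"] = [np.mean([p[e] > 0 for p in ps]) for e in elements]
    return pd.DataFrame(out, index=pd.Index(elements, name="element"))


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

# Descriptors that are incomputable for part of typical corpora (partial
# charges fail on unparametrized atoms; Ipc overflows on large molecules)
# are excluded from the default registry up front.
DEFAULT_DESCRIPTOR_EXCLUSIONS = (
    "MinPartialCharge",
    "MaxPartialCharge",
    "MaxAbsPartialCharge",
    "Ipc",
)

_ALL_DESCRIPTORS: dict[str, Callable] = dict(Descriptors.descList)

DESCRIPTOR_REGISTRIES: dict[str, tuple[str, ...]] = {
    "rdkit-2d": tuple(
        n for n in _ALL_DESCRIPTORS if n not in DEFAULT_DESCRIPTOR_EXCLUSIONS
    ),
    "rdkit-2d-full": tuple(_ALL_DESCRIPTORS),
}


@dataclass(frozen=True)
class DescriptorVector:
    """Named descriptor values; incomputable entries hold NaN."""

    values: Mapping[str, float]
    registry: str


def compute_descriptors(mol: Molecule, registry: str = "rdkit-2d") -> DescriptorVector:
    """Evaluate every descriptor in ``registry`` for one molecule.

    A descriptor whose computation raises, or returns a non-finite value,
    is recorded as NaN (the missing-marker) instead of propagating an
    exception; the table builder later excludes such columns.
    """
    if registry not in DESCRIPTOR_REGISTRIES:
        raise KeyError(f"unknown descriptor registry {registry!r}")
    values: dict[str, float] = {}
    for name in DESCRIPTOR_REGISTRIES[registry]:
        try:
            v = float(_ALL_DESCRIPTORS[name](mol.mol))
        except Exception:
            v = math.nan
        values[name] = v if math.isfinite(v) else math.nan
    return DescriptorVector(values, registry)


# --------------------------------------------------------------------------
# fingerprints
# --------------------------------------------------------------------------

def _maccs(mol: Chem.Mol) -> np.ndarray:
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits (bit 0 unused by convention)
    return np.frombuffer(bytes(bv.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")


def _generator_family(factory) -> Callable[[Chem.Mol], np.ndarray]:
    gen = factory()

    def compute(mol: Chem.Mol) -> np.ndarray:
        return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)

    return compute


def _pattern(mol: Chem.Mol) -> np.ndarray:
    bv = Chem.PatternFingerprint(mol, fpSize=1024)
    arr = np.zeros(1024, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


FINGERPRINT_FAMILIES: dict[str, tuple[int, Callable[[Chem.Mol], np.ndarray]]] = {
    "maccs": (167, _maccs),
    "morgan2": (
        1024,
        _generator_family(
            lambda: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        ),
    ),
    "rdkit_path": (
        1024,
        _generator_family(lambda: rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=1024)),
    ),
    "atom_pair": (
        1024,
        _generator_family(lambda: rdFingerprintGenerator.GetAtomPairGenerator(fpSize=1024)),
    ),
    "torsion": (
        1024,
        _generator_family(
            lambda: rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=1024)
        ),
    ),
    "pattern": (1024, _pattern),
}

DEFAULT_FINGERPRINT_FAMILIES = tuple(FINGERPRINT_FAMILIES)


def fingerprint_width(families: Sequence[str] = DEFAULT_FINGERPRINT_FAMILIES) -> int:
    """Total bit width of a family configuration."""
    return sum(FINGERPRINT_FAMILIES[f][0] for f in families)


@dataclass(frozen=True)
class FingerprintVector:
    """Concatenated binary fingerprint with per-bit family provenance."""

    bits: np.ndarray
    index: tuple[tuple[str, int], ...]  # (family, bit-within-family)

    def __post_init__(self):
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")

    @property
    def names(self) -> list[str]:
        return [f"{fam}:{i}" for fam, i in self.index]


def compute_fingerprints(
    mol: Molecule, families: Sequence[str] = DEFAULT_FINGERPRINT_FAMILIES
) -> FingerprintVector:
    """Concatenate the configured fingerprint families for one molecule."""
    blocks: list[np.ndarray] = []
    index: list[tuple[str, int]] = []
    for fam in families:
        if fam not in FINGERPRINT_FAMILIES:
            raise KeyError(f"unknown fingerprint family {fam!r}")
        width, fn = FINGERPRINT_FAMILIES[fam]
        arr = fn(mol.mol)
        if arr.size != width:
            raise RuntimeError(f"family {fam} produced {arr.size} bits, expected {width}")
        blocks.append(arr.astype(np.uint8))
        index.extend((fam, i) for i in range(width))
    return FingerprintVector(np.concatenate(blocks), tuple(index))


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 0 when both are all-zero."""
    if a.bits.size != b.bits.size or a.index != b.index:
        raise ValueError("fingerprints have mismatched family configurations")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    return inter / union if union else 0.0


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Molecules × features matrix with column kinds and optional labels.

    ``X`` is a float DataFrame indexed by molecule id; ``kinds`` maps each
    column to ``"descriptor"`` or ``"fingerprint"``; ``labels`` (optional)
    is either a binary class series (1 = toxin) or a real-valued
    regression target aligned with ``X``.
    """

    X: pd.DataFrame
    kinds: dict[str, str]
    labels: pd.Series | None = None
    dropped_columns: dict[str, str] = field(default_factory=dict)
    dropped_rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.X.index.has_duplicates:
            raise ValueError("row ids must be unique")
        if self.labels is not None:
            self.labels = self.labels.loc[self.X.index]

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        return FeatureTable(
            self.X[list(names)].copy(),
            {n: self.kinds[n] for n in names},
            None if self.labels is None else self.labels.copy(),
        )

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            self.X.loc[list(ids)].copy(),
            dict(self.kinds),
            None if self.labels is None else self.labels.loc[list(ids)].copy(),
        )

    def drop_missing(self) -> "FeatureTable":
        """Apply the exclusion rule: drop all-missing rows, then any
        column with a remaining missing value. Idempotent."""
        X = self.X.copy()
        dropped_rows = {
            str(rid): "no computable features" for rid in X.index[X.isna().all(axis=1)]
        }
        X = X.loc[X.notna().any(axis=1)]
        dropped_cols = {str(c): "missing value(s)" for c in X.columns[X.isna().any()]}
        X = X.loc[:, X.notna().all()]
        if X.shape[1] == 0:
            raise ValueError("exclusion rule dropped every column")
        for c, why in dropped_cols.items():
            logger.info("excluded feature %s: %s", c, why)
        for r, why in dropped_rows.items():
            logger.info("excluded molecule %s: %s", r, why)
        labels = None if self.labels is None else self.labels.loc[X.index]
        return FeatureTable(
            X, {c: self.kinds[c] for c in X.columns}, labels,
            dropped_columns=dropped_cols, dropped_rows=dropped_rows,
        )

    # -- persistence (CSV + JSON sidecar) ---------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = self.X.copy()
        if self.labels is not None:
            df.insert(0, "__label__", self.labels)
        df.to_csv(path, index_label="id")
        sidecar = {
            "columns": [{"name": c, "kind": self.kinds[c]} for c in self.X.columns],
            "has_labels": self.labels is not None,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        df = pd.read_csv(path, index_col="id")
        df.index = df.index.astype(str)
        labels = None
        if meta["has_labels"]:
            labels = df.pop("__label__")
        kinds = {c["name"]: c["kind"] for c in meta["columns"]}
        return cls(df, kinds, labels)


def build_feature_table(
    mols: Sequence[Molecule],
    labels: Mapping[str, float] | Sequence[float] | None = None,
    kinds: Iterable[str] = ("descriptor", "fingerprint"),
    descriptor_registry: str = "rdkit-2d",
    fingerprint_families: Sequence[str] = DEFAULT_FINGERPRINT_FAMILIES,
) -> FeatureTable:
    """Featurize molecules into a labeled table, applying the exclusion rule.

    ``labels`` may be an explicit mapping/sequence; when omitted, binary
    labels are derived from each molecule's ``source_label`` if any
    molecule carries one. Columns with missing values across the set are
    dropped and logged; rows with zero computable features likewise.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecules to build a table")
    kinds = set(kinds)
    if not kinds <= {"descriptor", "fingerprint"}:
        raise ValueError(f"unknown feature kinds: {kinds}")
    rows: list[dict[str, float]] = []
    kind_map: dict[str, str] = {}
    for m in mols:
        row: dict[str, float] = {}
        if "descriptor" in kinds:
            dv = compute_descriptors(m, descriptor_registry)
            row.update(dv.values)
            kind_map.update({n: "descriptor" for n in dv.values})
        if "fingerprint" in kinds:
            fv = compute_fingerprints(m, fingerprint_families)
            row.update(zip(fv.names, fv.bits.astype(float)))
            kind_map.update({n: "fingerprint" for n in fv.names})
        rows.append(row)
    X = pd.DataFrame(rows, index=pd.Index([m.id for m in mols], name="id"), dtype=float)
    lab: pd.Series | None = None
    if labels is not None:
        if isinstance(labels, Mapping):
            lab = pd.Series({m.id: labels[m.id] for m in mols})
        else:
            lab = pd.Series(list(labels), index=X.index)
    elif any(m.source_label != "unlabeled" for m in mols):
        lab = pd.Series(
            [POSITIVE_LABEL if m.source_label == "toxin" else NEGATIVE_LABEL for m in mols],
            index=X.index,
        )
    return FeatureTable(X, kind_map, lab).drop_missing()


# --------------------------------------------------------------------------
# train/test splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    """A reproducible train/test partition of row ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test overlap")


def split_dataset(table: FeatureTable, ratio: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Random train/test split with train size ``round(ratio * n)``.

    Stratified by class when the table carries binary labels, preserving
    the class ratio in both partitions; reproducible under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = np.asarray(table.X.index)
    n_train = int(round(ratio * len(ids)))
    stratify = None
    if table.labels is not None and table.labels.nunique() == 2:
        stratify = table.labels.values
        if pd.Series(stratify).value_counts().min() < 2:
            raise ValueError("each class needs >= 2 members for stratified splitting")
    train, test = train_test_split(
        ids, train_size=n_train, stratify=stratify, random_state=seed
    )
    return DatasetSplit(tuple(map(str, train)), tuple(map(str, test)), ratio, seed)
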