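"""Synthetic planted-signal data so every pipeline stage is testable
without external corpora.

Classification tables plant a known set of informative features:
continuous ("descriptor-like") informative features shift their class
means by ``effect_size * noise_sd``; binary ("fingerprint-like") bits
shift their on-probability by ``effect_size`` over a sparse base rate.
Noise features are class-independent. A small packaged molecule panel
spans halogenated (toxin-like) and CHNOP (metabolite-like) chemistry for
hand-checkable featurization tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .chemio import Molecule
from .featurize import FeatureTable

BINARY_BASE_RATE = 0.1  # sparse substructure bits

# class imbalance default mirrors a ~2.25:1 toxin:non-toxin corpus
DEFAULT_N_POS = 225
DEFAULT_N_NEG = 100


@dataclass(frozen=True)
class PlantedSpec:
    """Generator settings for a planted-signal classification table."""

    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    n_informative: int = 20
    n_noise: int = 980
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_informative, self.n_noise) < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if self.n_pos + self.n_neg < 1:
            raise ValueError("degenerate spec: zero rows")


FeatureKind = Literal["continuous", "binary", "mixed"]


def make_classification_table(
    spec: PlantedSpec, feature_kind: FeatureKind = "continuous"
) -> tuple[FeatureTable, list[str]]:
    """Generate a labeled table plus the ground-truth informative names.

    Continuous informative features: class means 0 vs
    ``effect_size * noise_sd``, common sd ``noise_sd``. Binary
    informative bits: on-probability ``BINARY_BASE_RATE`` in non-toxins
    vs ``BINARY_BASE_RATE + effect_size`` (clipped to [0, 1]) in toxins.
    Bit-reproducible under (spec.seed, spec).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    y = np.array([1] * spec.n_pos + [0] * spec.n_neg)

    def continuous_block(n_feat: int, informative: bool) -> np.ndarray:
        x = rng.normal(0.0, spec.noise_sd, size=(n, n_feat))
        if informative:
            x[y == 1] += spec.effect_size * spec.noise_sd
        return x

    def binary_block(n_feat: int, informative: bool) -> np.ndarray:
        p_neg = BINARY_BASE_RATE
        p_pos = min(1.0, p_neg + spec.effect_size) if informative else p_neg
        p = np.where(y == 1, p_pos, p_neg)[:, None]
        return (rng.random((n, n_feat)) < p).astype(float)

    if feature_kind == "continuous":
        blocks = [("desc_inf", "descriptor", continuous_block(spec.n_informative, True)),
                  ("desc_noise", "descriptor", continuous_block(spec.n_noise, False))]
    elif feature_kind == "binary":
        blocks = [("bit_inf", "fingerprint", binary_block(spec.n_informative, True)),
                  ("bit_noise", "fingerprint", binary_block(spec.n_noise, False))]
    elif feature_kind == "mixed":
        ni_c = spec.n_informative // 2
        nn_c = spec.n_noise // 2
        blocks = [
            ("desc_inf", "descriptor", continuous_block(ni_c, True)),
            ("bit_inf", "fingerprint", binary_block(spec.n_informative - ni_c, True)),
            ("desc_noise", "descriptor", continuous_block(nn_c, False)),
            ("bit_noise", "fingerprint", binary_block(spec.n_noise - nn_c, False)),
        ]
    else:
        raise ValueError(f"unknown feature_kind {feature_kind!r}")

    cols, kinds, mats = [], {}, []
    informative: list[str] = []
    for prefix, kind, mat in blocks:
        names = [f"{prefix}_{i:04d}" for i in range(mat.shape[1])]
        cols.extend(names)
        kinds.update({nm: kind for nm in names})
        mats.append(mat)
        if "inf" in prefix:
            informative.extend(names)
    X = pd.DataFrame(
        np.hstack(mats) if mats else np.empty((n, 0)),
        columns=cols,
        index=pd.Index([f"m{i:05d}" for i in range(n)], name="id"),
    )
    labels = pd.Series(y, index=X.index)
    return FeatureTable(X, kinds, labels), informative


def make_regression_table(
    n: int,
    coefficients: Sequence[float],
    intercept: float = 0.0,
    n_noise: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Linear-model table: target = X @ coefficients + intercept + noise.

    The first ``len(coefficients)`` columns are the true predictors
    (standard normal), followed by ``n_noise`` irrelevant columns; the
    Gaussian target noise has sd ``noise_sd``. Returns the table (target
    in ``labels``) and the generating parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coefficients = np.asarray(coefficients, dtype=float)
    p_true = len(coefficients)
    X = rng.normal(size=(n, p_true + n_noise))
    y = X[:, :p_true] @ coefficients + intercept + rng.normal(0.0, noise_sd, size=n)
    names = [f"x_true_{i:02d}" for i in range(p_true)] + [
        f"x_noise_{i:02d}" for i in range(n_noise)
    ]
    table = FeatureTable(
        pd.DataFrame(X, columns=names,
                     index=pd.Index([f"m{i:05d}" for i in range(n)], name="id")),
        {nm: "descriptor" for nm in names},
        pd.Series(y, index=[f"m{i:05d}" for i in range(n)]),
    )
    params = {
        "coefficients": dict(zip(names[:p_true], coefficients)),
        "intercept": float(intercept),
        "noise_sd": float(noise_sd),
        "true_features": names[:p_true],
    }
    return table, params


# hand-verifiable structures: halogenated, toxin-like chemistry vs
# CHNOP(S) metabolite-like chemistry
_PANEL = [
    # (id, name, SMILES, label)
    ("ddt", "DDT", "Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl", "toxin"),
    ("dicofol", "Dicofol", "OC(c1ccc(Cl)cc1)(c1ccc(Cl)cc1)C(Cl)(Cl)Cl", "toxin"),
    ("tcb", "1,2,4-Trichlorobenzene", "Clc1ccc(Cl)c(Cl)c1", "toxin"),
    ("hcbd", "Hexachlorobutadiene", "ClC(Cl)=C(Cl)C(Cl)=C(Cl)Cl", "toxin"),
    ("vinyl_chloride", "Vinyl chloride", "C=CCl", "toxin"),
    ("bromopropane", "1-Bromopropane", "CCCBr", "toxin"),
    ("chloroform", "Chloroform", "ClC(Cl)Cl", "toxin"),
    ("dbcp", "1,2-Dibromo-3-chloropropane", "BrCC(Br)CCl", "toxin"),
    ("pcp", "Pentachlorophenol", "Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl", "toxin"),
    ("halothane", "Halothane", "FC(F)(F)C(Cl)Br", "toxin"),
    ("pyrene", "Pyrene", "c1cc2ccc3cccc4ccc(c1)c2c34", "toxin"),
    ("styrene", "Styrene", "C=Cc1ccccc1", "toxin"),
    ("fructose", "D-Fructose", "OCC(=O)C(O)C(O)C(O)CO", "nontoxin"),
    ("glucose", "D-Glucose", "OCC1OC(O)C(O)C(O)C1O", "nontoxin"),
    ("succinate", "Succinic acid", "OC(=O)CCC(=O)O", "nontoxin"),
    ("adenine", "Adenine", "Nc1ncnc2[nH]cnc12", "nontoxin"),
    ("glycine", "Glycine", "NCC(=O)O", "nontoxin"),
    ("tryptophan", "L-Tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O", "nontoxin"),
    ("cholate", "Cholic acid", "C[C@H](CCC(=O)O)[C@H]1CC[C@H]2[C@@H]3[C@H](O)C[C@@H]4C[C@H](O)CC[C@]4(C)[C@H]3C[C@H](O)[C@]12C", "nontoxin"),
    ("glycerol_3p", "Glycerol 3-phosphate", "OCC(O)COP(=O)(O)O", "nontoxin"),
]


def toy_molecule_panel() -> list[Molecule]:
    """Twenty packaged small molecules with hand-verifiable compositions.

    Halogen-bearing entries carry the toxin label, CHNOP(S) metabolites
    the nontoxin label, mirroring the compositional contrast between the
    two chemistries.
    """
    from rdkit import Chem

    mols = []
    for mid, name, smi, label in _PANEL:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - panel is fixed and valid
            raise RuntimeError(f"panel SMILES failed to parse: {name}")
        mols.append(Molecule.from_rdkit(mol, id=mid, name=name, source_label=label))
    return mols
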