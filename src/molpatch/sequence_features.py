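"""Sequence-only features and the regression harness for hydrophobicity prediction.

Three model families predict THSA/RHSA/LHP from sequence-derived inputs:

TFM  three-feature model: sequence length, hydrophobic residue count,
     hydrophilic residue count.
GFM  global-feature model: 31 features (20 amino-acid counts, length,
     entropy, hydrophobic count, polar count, molecular weight,
     aromaticity, instability index, gravy, buried fraction, isoelectric
     point, molar extinction coefficient).
NBM  model over per-residue-accessibility-derived predicted THSA and RHSA
     (for LHP, whose surface adjacency is invisible to per-residue
     predictors).

The harness reproduces a nested validation scheme: an 80/20 train/test
split, with the training part split 2/3 cross-validation pool (k-fold
grid search) and 1/3 validation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold

from .structure_io import HYDROPHOBIC_RESIDUES, STANDARD_AA

AA_ORDER = sorted(STANDARD_AA)

#: Residues counted as buried-propensity (aliphatic/sulfur hydrophobics;
#: the aromatic W and Y are surface-active and excluded).
BURIED_RESIDUES = frozenset("ACFILMV")

GFM_FEATURES = (
    [f"count_{aa}" for aa in AA_ORDER]
    + [
        "length",
        "entropy",
        "hydrophobic_count",
        "polar_count",
        "molecular_weight",
        "aromaticity",
        "instability_index",
        "gravy",
        "buried_fraction",
        "isoelectric_point",
        "extinction_coefficient",
    ]
)

TFM_FEATURES = ["length", "hydrophobic_count", "hydrophilic_count"]
NBM_FEATURES = ["thsa_pred", "rhsa_pred"]


@dataclass(frozen=True)
class SequenceFeatures:
    length: int
    aa_counts: dict[str, int]
    hydrophobic_count: int
    polar_count: int
    entropy: float                 # bits, over the 20-letter distribution
    molecular_weight: float        # Da
    aromaticity: float             # frequency of F+W+Y
    instability_index: float
    gravy: float                   # mean Kyte-Doolittle
    buried_fraction: float
    isoelectric_point: float
    extinction_coefficient: float  # M^-1 cm^-1, all Cys assumed paired

    @property
    def hydrophilic_count(self) -> int:
        return self.polar_count

    def to_dict(self) -> dict[str, float]:
        d = {f"count_{aa}": self.aa_counts.get(aa, 0) for aa in AA_ORDER}
        d.update(
            length=self.length,
            entropy=self.entropy,
            hydrophobic_count=self.hydrophobic_count,
            polar_count=self.polar_count,
            hydrophilic_count=self.polar_count,
            molecular_weight=self.molecular_weight,
            aromaticity=self.aromaticity,
            instability_index=self.instability_index,
            gravy=self.gravy,
            buried_fraction=self.buried_fraction,
            isoelectric_point=self.isoelectric_point,
            extinction_coefficient=self.extinction_coefficient,
        )
        return d


def shannon_entropy(counts: Counter, total: int) -> float:
    """Shannon entropy (bits) of the amino-acid frequency distribution."""
    h = 0.0
    for c in counts.values():
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def extract_features(sequence: str) -> SequenceFeatures:
    """Compute all global sequence features for one amino-acid string.

    ``X`` is tolerated: it contributes to length and counts of nothing,
    and is excluded from scale-based features (gravy, MW, pI, ...).
    """
    sequence = sequence.upper().strip("*")
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - STANDARD_AA - {"X"}
    if bad:
        raise ValueError(f"invalid residue code(s): {sorted(bad)}")

    counts = Counter(c for c in sequence if c in STANDARD_AA)
    length = len(sequence)
    n_std = sum(counts.values())
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    hydrophobic = sum(counts[aa] for aa in HYDROPHOBIC_RESIDUES)

    clean = "".join(c for c in sequence if c in STANDARD_AA)
    pa = ProteinAnalysis(clean)
    ext_reduced, ext_cystines = pa.molar_extinction_coefficient()

    return SequenceFeatures(
        length=length,
        aa_counts=dict(counts),
        hydrophobic_count=hydrophobic,
        polar_count=length - hydrophobic,
        entropy=shannon_entropy(counts, n_std),
        molecular_weight=pa.molecular_weight(),
        aromaticity=pa.aromaticity(),
        instability_index=pa.instability_index(),
        gravy=pa.gravy(),
        buried_fraction=sum(counts[aa] for aa in BURIED_RESIDUES) / n_std,
        isoelectric_point=pa.isoelectric_point(),
        extinction_coefficient=ext_cystines,
    )


def features_frame(sequences: dict[str, str]) -> pd.DataFrame:
    """Feature table (one row per sequence id) for a dict of sequences."""
    rows = {sid: extract_features(seq).to_dict() for sid, seq in sequences.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ModelSpec:
    """Which features feed which target, and with which estimator."""

    name: str                          # "TFM" | "GFM" | "NBM"
    target: str                        # "THSA" | "RHSA" | "LHP"
    regressor: Optional[BaseEstimator] = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        defaults = {"TFM": TFM_FEATURES, "GFM": GFM_FEATURES, "NBM": NBM_FEATURES}
        if self.name not in defaults:
            raise ValueError(f"unknown model {self.name!r}")
        if not self.feature_names:
            self.feature_names = list(defaults[self.name])

    def make_regressor(self, seed: int = 0) -> BaseEstimator:
        if self.regressor is not None:
            est = clone(self.regressor)
            if "random_state" in est.get_params():
                est.set_params(random_state=seed)
            return est
        # Defaults per family: a linear rule model for the 3-feature
        # setting, boosted trees for the wide global-feature setting, and
        # a random forest for the accessibility-derived features.
        if self.name == "TFM":
            return LinearRegression()
        if self.name == "GFM":
            return GradientBoostingRegressor(random_state=seed)
        return RandomForestRegressor(n_estimators=200, random_state=seed)


@dataclass(frozen=True)
class DataSplit:
    train_idx: np.ndarray       # full 80% training portion
    test_idx: np.ndarray        # held-out 20%
    cv_pool_idx: np.ndarray     # 2/3 of train, used for k-fold grid search
    validation_idx: np.ndarray  # remaining 1/3 of train
    n_folds: int


def split_and_validate(
    data: pd.DataFrame, seed: int, n_folds: int = 5, test_fraction: float = 0.2
) -> DataSplit:
    """Disjoint, exhaustive 80/20 split with an inner 2/3 CV-pool / 1/3 validation split."""
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 rows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    n_val = int(round(len(train_idx) / 3))
    inner = rng.permutation(train_idx)
    validation_idx = np.sort(inner[:n_val])
    cv_pool_idx = np.sort(inner[n_val:])
    return DataSplit(
        train_idx=train_idx,
        test_idx=test_idx,
        cv_pool_idx=cv_pool_idx,
        validation_idx=validation_idx,
        n_folds=n_folds,
    )


#: Small default hyperparameter grids, searched on R^2.
DEFAULT_GRIDS: dict[str, dict] = {
    "TFM": {},
    "GFM": {"n_estimators": [100, 300], "max_depth": [2, 3]},
    "NBM": {"max_depth": [None, 8], "min_samples_leaf": [1, 5]},
}


def fit_model(
    spec: ModelSpec,
    train: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 5,
    param_grid: dict | None = None,
) -> BaseEstimator:
    """Fit the spec's regressor on a feature/target table.

    ``train`` must contain every feature column plus the target column.
    When a non-empty hyperparameter grid applies, it is searched with
    k-fold cross-validated grid search optimising R^2.
    """
    missing = set(spec.feature_names) | {spec.target}
    missing -= set(train.columns)
    if missing:
        raise ValueError(f"training table missing column(s): {sorted(missing)}")
    X = train[spec.feature_names].to_numpy(dtype=float)
    y = train[spec.target].to_numpy(dtype=float)
    est = spec.make_regressor(seed)
    grid = DEFAULT_GRIDS.get(spec.name, {}) if param_grid is None else param_grid
    if grid:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="r2")
        search.fit(X, y)
        return search.best_estimator_
    est.fit(X, y)
    return est


def predict(model: BaseEstimator, spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    return model.predict(data[spec.feature_names].to_numpy(dtype=float))
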