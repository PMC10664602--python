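"""Random-forest activity scorer over circular fingerprints.

Early-stage compounds are labelled active/inactive by their mean potency,
a forest is fit on a stratified 70/30 split, and the active-class
probability is the score used to rank generated compounds and to diagnose
the alpha/beta/gamma regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split

from .chem_io import InvalidMoleculeError, MoleculeRecord

ECFP6_RADIUS = 3
ECFP6_BITS = 1024
TEST_FRACTION = 0.3
N_TREES = 100
MAX_DEPTH = 20

_FORMAT_VERSION = 1


def ecfp6_features(
    smiles_canonical: str, n_bits: int = ECFP6_BITS
) -> np.ndarray:
    """Binary circular fingerprint, radius 3, folded to ``n_bits``."""
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles_canonical!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=ECFP6_RADIUS, fpSize=n_bits
    )
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def feature_matrix(smiles: Sequence[str], n_bits: int = ECFP6_BITS) -> np.ndarray:
    return np.stack([ecfp6_features(s, n_bits) for s in smiles])


def label_by_mean_activity(early_records: Sequence[MoleculeRecord]) -> np.ndarray:
    """1 = pXC50 strictly above the early-stage mean, else 0."""
    if len(early_records) < 2:
        raise ValueError("need at least 2 records to label by mean activity")
    pxc = np.array([r.pxc50 for r in early_records], dtype=np.float64)
    labels = (pxc > pxc.mean()).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            "mean-activity labelling produced a single class; "
            "the scorer is untrainable on this set"
        )
    return labels


@dataclass
class ScorerModel:
    """Fitted forest plus the descriptor/split configuration that made it."""

    forest: RandomForestClassifier
    n_bits: int
    radius: int
    seed: int
    training_mean_pxc50: float
    balanced_accuracy_test: float
    split: tuple[float, float] = (1 - TEST_FRACTION, TEST_FRACTION)
    stratified: bool = True
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": _FORMAT_VERSION,
                "forest": self.forest,
                "n_bits": self.n_bits,
                "radius": self.radius,
                "seed": self.seed,
                "training_mean_pxc50": self.training_mean_pxc50,
                "balanced_accuracy_test": self.balanced_accuracy_test,
                "split": self.split,
                "stratified": self.stratified,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ScorerModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported scorer file version in {path}")
        blob.pop("format_version")
        return cls(**blob)


def train(
    early_records: Sequence[MoleculeRecord],
    seed: int,
    *,
    n_bits: int = ECFP6_BITS,
    features: np.ndarray | None = None,
) -> ScorerModel:
    """Fit the scorer on early-stage compounds.

    A stratified 70/30 split with the given seed yields held-out balanced
    accuracy; the forest itself uses the same seed. ``features`` overrides
    the fingerprint matrix (used by tests with synthetic descriptors).
    """
    if len(early_records) < 20:
        raise ValueError("need at least 20 records to train the scorer")
    y = label_by_mean_activity(early_records)
    X = (
        features
        if features is not None
        else feature_matrix([r.smiles_canonical for r in early_records], n_bits)
    )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=TEST_FRACTION, random_state=seed, stratify=y
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("class starvation after the 70/30 split")
    forest = RandomForestClassifier(
        n_estimators=N_TREES, max_depth=MAX_DEPTH, random_state=seed
    )
    forest.fit(X_tr, y_tr)
    bal_acc = balanced_accuracy_score(y_te, forest.predict(X_te))
    return ScorerModel(
        forest=forest,
        n_bits=X.shape[1],
        radius=ECFP6_RADIUS,
        seed=seed,
        training_mean_pxc50=float(
            np.mean([r.pxc50 for r in early_records])
        ),
        balanced_accuracy_test=float(bal_acc),
    )


def score(model: ScorerModel, smiles_list: Sequence[str]) -> np.ndarray:
    """Active-class probability per molecule; NaN flags unparseable SMILES."""
    out = np.full(len(smiles_list), np.nan)
    feats, idx = [], []
    for i, smi in enumerate(smiles_list):
        try:
            feats.append(ecfp6_features(smi, model.n_bits))
            idx.append(i)
        except InvalidMoleculeError:
            continue
    if feats:
        proba = model.forest.predict_proba(np.stack(feats))
        active_col = list(model.forest.classes_).index(1)
        out[idx] = proba[:, active_col]
    return out


def region_scores(model: ScorerModel, labelled_dataset) -> pd.DataFrame:
    """Score-distribution summary per region (alpha, beta, gamma).

    Empty regions are absent from the table.
    """
    rows = []
    for region in ("alpha", "beta", "gamma"):
        smiles = labelled_dataset.region_smiles(region)
        if not smiles:
            continue
        s = score(model, smiles)
        s = s[~np.isnan(s)]
        rows.append(
            {
                "region": region,
                "n": int(len(s)),
                "mean": float(np.mean(s)),
                "median": float(np.median(s)),
                "q25": float(np.percentile(s, 25)),
                "q75": float(np.percentile(s, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n", "mean", "median", "q25", "q75"])
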