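"""Independent brute-force oracles, deliberately coded apart from retroval.

These re-derive expected values with plain loops, covariance
eigendecomposition and explicit set arithmetic so the package's
implementations can be checked against a second route.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


def oracle_canonical(smiles: str) -> str | None:
    """Plain RDKit canonicalization (single-fragment inputs only)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def oracle_metric_funnel(generated, novelty_ref, redis_ref):
    """Loop-based recomputation of the four count metrics."""
    n_gen = len(generated)
    valid = []
    for smi in generated:
        can = oracle_canonical(smi)
        if can is not None:
            valid.append(can)
    n_val = len(valid)
    seen, unique = set(), []
    for can in valid:
        if can not in seen:
            seen.add(can)
            unique.append(can)
    n_uni = len(unique)
    ref = set(novelty_ref)
    n_unk = 0
    for can in unique:
        if can not in ref:
            n_unk += 1
    redis = set(redis_ref)
    n_redis = 0
    for can in set(unique):
        if can in redis:
            n_redis += 1
    return {
        "n_gen": n_gen,
        "n_val": n_val,
        "n_uni": n_uni,
        "n_unk": n_unk,
        "n_redis": n_redis,
        "validity_pct": 100.0 * n_val / n_gen,
        "uniqueness_pct": 100.0 * n_uni / n_val if n_val else 0.0,
        "novelty_pct": 100.0 * n_unk / n_uni if n_uni else 0.0,
        "rediscovery_pct": 100.0 * n_redis / n_gen,
    }


def oracle_pca_scores(X, n_components, standardize=False):
    """PCA scores via covariance eigendecomposition (not SVD)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / len(X)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:n_components]
    scores = Xc @ v[:, order]
    if standardize:
        scores = scores / scores.std(axis=0, ddof=0)
    return scores


def oracle_pseudotime_distances(fingerprints, pxc50, standardize_scores=True):
    """Two-stage PCA + anchored Euclidean distance, independent route."""
    s1 = oracle_pca_scores(fingerprints, 3, standardize=standardize_scores)
    s2 = oracle_pca_scores(np.column_stack([s1, pxc50]), 3)
    anchor = int(np.argmin(pxc50))
    return np.linalg.norm(s2 - s2[anchor], axis=1), anchor


def oracle_tanimoto(smiles_a, smiles_b, radius=2, n_bits=2048):
    """|intersection| / |union| over explicit Morgan on-bit sets."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = []
    for smi in (smiles_a, smiles_b):
        mol = Chem.MolFromSmiles(smi)
        bits.append(set(gen.GetFingerprint(mol).GetOnBits()))
    a, b = bits
    return len(a & b) / len(a | b)


def oracle_asnn(query, reference, radius=2, n_bits=2048):
    """Mean over queries of the max pairwise oracle Tanimoto."""
    return float(
        np.mean(
            [
                max(oracle_tanimoto(q, r, radius, n_bits) for r in reference)
                for q in query
            ]
        )
    )
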