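"""Pseudo-time ordering of undated project datasets.

Fingerprints are reduced by PCA to 3 components, the potency column is
appended, a second PCA to 3 components follows, and each compound's
Euclidean distance to the least-potent compound in that final score space
defines the pseudo-time axis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import InvalidMoleculeError, MoleculeRecord

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class PseudoTimeMap:
    """Distances and induced ordering along the pseudo-time axis."""

    distances: np.ndarray  # (n,) non-negative
    order: np.ndarray  # permutation of 0..n-1, ascending distance
    anchor_index: int
    pc_scores_stage1: np.ndarray  # (n, 3)
    pc_scores_stage2: np.ndarray  # (n, 3)


def structural_fingerprint(
    smiles_canonical: str, n_bits: int = 1024, max_path: int = 7
) -> np.ndarray:
    """Hashed linear-path (RDKit topological) fingerprint as a 0/1 vector.

    Stands in for a proprietary fragment fingerprint; only determinism and
    structural sensitivity matter downstream, not the exact bit definition.
    """
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles_canonical!r}")
    arr = np.zeros(n_bits, dtype=np.float64)
    fp = Chem.RDKFingerprint(mol, maxPath=max_path, fpSize=n_bits)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    # length-0 paths (single atoms) so bond-less molecules are non-empty
    for atom in mol.GetAtoms():
        key = f"{atom.GetSymbol()}:{int(atom.GetIsAromatic())}".encode()
        arr[zlib.crc32(key) % n_bits] = 1.0
    return arr


def pca_scores(
    matrix: np.ndarray, n_components: int = 3, standardize_scores: bool = False
) -> np.ndarray:
    """Principal-component scores via SVD of the centered data.

    Components are ordered by decreasing singular value; with
    ``standardize_scores`` each score column is rescaled to unit variance.
    Deterministic up to column sign (distances downstream are sign
    invariant).

    Raises
    ------
    ValueError
        If fewer than 2 rows, or the centered matrix has rank below
        ``n_components``.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(s[0], 1.0)))
    if rank < n_components:
        raise ValueError(
            f"rank-deficient data: rank {rank} < {n_components} requested "
            "components (identical or collinear rows?)"
        )
    scores = u[:, :n_components] * s[:n_components]
    if standardize_scores:
        scores = scores / scores.std(axis=0, ddof=0)
    return scores


def pseudo_time_order(
    records: Sequence[MoleculeRecord],
    *,
    fp_bits: int = 1024,
    fp_max_path: int = 7,
    standardize_scores: bool = True,
    standardize_pxc50: bool = False,
    fingerprints: np.ndarray | None = None,
) -> PseudoTimeMap:
    """Order records along the pseudo-time axis.

    Stage 1: PCA(3) on structural fingerprints (score columns standardized
    to unit variance by default, so the appended potency is not drowned out
    by arbitrary score scales). Stage 2: PCA(3) on the 4-column matrix of
    stage-1 scores plus pXC50. Distances are Euclidean in stage-2 space to
    the record with the lowest pXC50 (ties broken by smallest source_row).
    """
    if len(records) < 4:
        raise ValueError("pseudo-time ordering needs at least 4 records")
    pxc50 = np.array([r.pxc50 for r in records], dtype=np.float64)
    if not np.all(np.isfinite(pxc50)):
        raise ValueError("all records need finite pXC50")
    if fingerprints is not None:
        fps = np.asarray(fingerprints, dtype=np.float64)
        if fps.shape[0] != len(records):
            raise ValueError("fingerprint matrix does not match record count")
    else:
        fps = np.stack(
            [
                structural_fingerprint(r.smiles_canonical, fp_bits, fp_max_path)
                for r in records
            ]
        )
    stage1 = pca_scores(fps, 3, standardize_scores=standardize_scores)
    act = pxc50.copy()
    if standardize_pxc50:
        sd = act.std(ddof=0)
        if sd == 0:
            raise ValueError("constant pXC50 cannot be standardized")
        act = (act - act.mean()) / sd
    stage2 = pca_scores(np.column_stack([stage1, act]), 3)

    # anchor: lowest pXC50; ties -> smallest source_row
    anchor = min(
        range(len(records)), key=lambda i: (pxc50[i], records[i].source_row)
    )
    dist = np.linalg.norm(stage2 - stage2[anchor], axis=1)
    src = np.array([r.source_row for r in records])
    order = np.lexsort((src, dist))
    return PseudoTimeMap(
        distances=dist,
        order=order,
        anchor_index=anchor,
        pc_scores_stage1=stage1,
        pc_scores_stage2=stage2,
    )
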