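"""Generation metrics: validity, uniqueness, novelty, rediscovery, aSNN.

Counts follow the evaluation funnel

    n_gen >= n_val >= n_uni >= n_unk

with validity% = 100*n_val/n_gen, uniqueness% = 100*n_uni/n_val,
novelty% = 100*n_unk/n_uni and rediscovery% = 100*n_redis/n_gen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import standardize, InvalidMoleculeError

DEFAULT_ASNN_RADIUS = 2
DEFAULT_ASNN_BITS = 2048
#: reporting annotation only — similarity above this is conventionally
#: considered "similar"; it never filters any computation
ASNN_SIMILAR_CUTOFF = 0.3


@dataclass
class GenerationReport:
    """Counts and percentage metrics for one evaluated generated set."""

    n_gen: int
    n_val: int
    n_uni: int
    n_unk: int
    n_redis: int
    validity_pct: float
    uniqueness_pct: float
    novelty_pct: float
    rediscovery_pct: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ASNNTable:
    """aSNN of a generated set against (stage, activity class) strata."""

    entries: dict  # (stage, activity_class) -> asnn value
    n_reference: dict  # (stage, activity_class) -> reference subset size
    cutoff: float = ASNN_SIMILAR_CUTOFF

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s,
                "activity_class": c,
                "asnn": v,
                "n_reference": self.n_reference[(s, c)],
            }
            for (s, c), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["stage", "activity_class", "asnn", "n_reference"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 2)


def validity(generated_raw: Sequence[str]) -> tuple[int, float, list[str]]:
    """Count parseable+sanitizable SMILES.

    Returns (n_val, percentage, canonical forms of the valid subset in
    input order).
    """
    if len(generated_raw) == 0:
        raise ValueError("empty generated set")
    valid_canonical = []
    for smi in generated_raw:
        try:
            valid_canonical.append(standardize(smi))
        except InvalidMoleculeError:
            continue
    n_val = len(valid_canonical)
    return n_val, _pct(n_val, len(generated_raw)), valid_canonical


def uniqueness(
    valid_canonical: Sequence[str],
) -> tuple[int, float, list[str]]:
    """De-duplicate canonical SMILES, first occurrence kept."""
    if len(valid_canonical) == 0:
        raise ValueError("empty valid set")
    unique = list(dict.fromkeys(valid_canonical))
    return len(unique), _pct(len(unique), len(valid_canonical)), unique


def novelty(
    unique_canonical: Sequence[str],
    reference_training_canonical: Iterable[str],
) -> tuple[int, float]:
    """Fraction of unique compounds absent from the training reference."""
    if len(unique_canonical) == 0:
        raise ValueError("empty unique set")
    ref = set(reference_training_canonical)
    n_unk = sum(1 for s in unique_canonical if s not in ref)
    return n_unk, _pct(n_unk, len(unique_canonical))


def rediscovery(
    generated_raw: Sequence[str],
    reference_actives_canonical: Iterable[str],
) -> tuple[int, float]:
    """Exact-structure matches to the known-active reference.

    Matching is by canonical non-isomeric SMILES over the de-duplicated
    valid generated compounds, so each reference compound counts at most
    once. The denominator is the size of the evaluated generated list.
    """
    if len(generated_raw) == 0:
        raise ValueError("empty generated set")
    ref = set(reference_actives_canonical)
    if not ref:
        warnings.warn("empty rediscovery reference; reporting 0%", stacklevel=2)
        return 0, 0.0
    _, _, valid_canonical = validity(generated_raw)
    unique = set(valid_canonical)
    n_redis = len(unique & ref)
    return n_redis, _pct(n_redis, len(generated_raw))


def evaluate_generated(
    generated_raw: Sequence[str],
    novelty_reference: Iterable[str],
    rediscovery_reference: Iterable[str],
) -> GenerationReport:
    """Full metric funnel for one generated set."""
    n_gen = len(generated_raw)
    n_val, val_pct, valid_canonical = validity(generated_raw)
    if n_val == 0:
        return GenerationReport(n_gen, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)
    n_uni, uni_pct, unique = uniqueness(valid_canonical)
    n_unk, unk_pct = novelty(unique, novelty_reference)
    n_redis, redis_pct = rediscovery(generated_raw, rediscovery_reference)
    return GenerationReport(
        n_gen=n_gen,
        n_val=n_val,
        n_uni=n_uni,
        n_unk=n_unk,
        n_redis=n_redis,
        validity_pct=val_pct,
        uniqueness_pct=uni_pct,
        novelty_pct=unk_pct,
        rediscovery_pct=redis_pct,
    )


def _morgan_fps(smiles: Sequence[str], radius: int, n_bits: int) -> list:
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits
    )
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InvalidMoleculeError(f"unparseable SMILES: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def asnn(
    query_canonical: Sequence[str],
    reference_canonical: Sequence[str],
    radius: int = DEFAULT_ASNN_RADIUS,
    n_bits: int = DEFAULT_ASNN_BITS,
) -> float:
    """Average single-nearest-neighbour Tanimoto similarity.

    Directional: mean over query molecules of the maximum Tanimoto
    similarity of circular (Morgan) fingerprints against the reference set.
    """
    if len(query_canonical) == 0 or len(reference_canonical) == 0:
        raise ValueError("aSNN needs non-empty query and reference sets")
    q_fps = _morgan_fps(query_canonical, radius, n_bits)
    r_fps = _morgan_fps(reference_canonical, radius, n_bits)
    best = [
        max(DataStructs.BulkTanimotoSimilarity(q, r_fps)) for q in q_fps
    ]
    return float(np.mean(best))


def stratified_asnn(
    generated_canonical: Sequence[str],
    labelled_dataset,
    radius: int = DEFAULT_ASNN_RADIUS,
    n_bits: int = DEFAULT_ASNN_BITS,
) -> ASNNTable:
    """aSNN against each populated (middle/late stage, activity class) cell.

    Cells with no reference members are absent from the table, never
    reported as 0.
    """
    from .stratify import ACTIVITY_CLASSES

    entries: dict = {}
    n_ref: dict = {}
    any_cell = False
    for stage in ("middle", "late"):
        for cls in ACTIVITY_CLASSES:
            subset = labelled_dataset.stage_class_records(stage, cls)
            if not subset:
                continue
            any_cell = True
            ref = [r.smiles_canonical for r in subset]
            entries[(stage, cls)] = asnn(
                generated_canonical, ref, radius=radius, n_bits=n_bits
            )
            n_ref[(stage, cls)] = len(ref)
    if not any_cell:
        raise ValueError("dataset has no middle/late-stage records")
    return ASNNTable(entries=entries, n_reference=n_ref)


def top_k_by_score(
    generated: Sequence[str], scores: Sequence[float], k: int
) -> list[str]:
    """The k highest-scored entries; ties keep original order (stable)."""
    if len(generated) != len(scores):
        raise ValueError("scores must align with generated entries")
    if k > len(generated):
        raise ValueError(f"k={k} exceeds set size {len(generated)}")
    order = sorted(
        range(len(generated)), key=lambda i: (-float(scores[i]), i)
    )
    return [generated[i] for i in order[:k]]
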