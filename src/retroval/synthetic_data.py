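"""Synthetic drug-discovery projects with controllable chemistry drift.

A project is a time-ordered congeneric series whose potency rises with
time. Compounds are built from two structurally distinct template series
(a *founding* series and a *drift* series) decorated with substituent
fragments, and the regime decides which series the middle/late-stage
compounds come from:

``public_like``
    middle/late actives stay on the founding series (the one the early
    actives belong to) while middle/late weak compounds come from the
    drift series — so early actives resemble late actives more than late
    inactives, aSNN(alpha, gamma) > aSNN(alpha, beta).

``inhouse_like``
    the converse: chemistry moves on, middle/late actives come from the
    drift series while weak middle/late compounds remain near the founding
    chemistry — aSNN(alpha, beta) > aSNN(alpha, gamma).

Potency model (documented so the regime-separation oracle is auditable)::

    pXC50(t) = base + slope * t/(n-1) + effect(substituents) + noise
               - setback (with probability p_setback, middle/late only)

with Gaussian noise and a positive "setback" excursion standing in for
failed analogs; the setback keeps the beta region populated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import baseline_generator
from .chem_io import (
    MoleculeRecord,
    standardize,
    write_generated_set,
    write_records,
)
from .stratify import ActivityThresholds

# Founding series: arylamide; drift series: aliphatic piperazine diamide.
# Structurally distant (low Tanimoto between series, high within).
DEFAULT_TEMPLATES = (
    "O=C(Nc1ccc({R0})cc1)c1ccccc1{R1}",
    "O=C(C{R0})N1CCN(C(=O)C{R1})CC1",
)

DEFAULT_SUBSTITUENTS = (
    "C",
    "CC",
    "CCC",
    "O",
    "OC",
    "N",
    "Cl",
    "F",
    "C(F)(F)F",
    "N(C)C",
    "OCC",
    "C#N",
)

_MIN_PER_CLASS = 5
_MAX_ATTEMPTS = 20


@dataclass(frozen=True)
class SyntheticProjectSpec:
    """Parameters of one simulated project."""

    n_compounds: int = 200
    templates: tuple[str, str] = DEFAULT_TEMPLATES
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    regime: str = "public_like"
    base_pxc50: float = 4.6
    drift_slope: float = 4.4
    noise_sd: float = 0.4
    p_setback: float = 0.3
    setback_mean: float = 1.8
    setback_sd: float = 0.5
    thresholds: ActivityThresholds = field(default_factory=ActivityThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("public_like", "inhouse_like"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_compounds < 40:
            raise ValueError("need n_compounds >= 40 for stage/region viability")
        # fail fast on templates that cannot instantiate
        for tmpl in self.templates:
            n_sites = _n_sites(tmpl)
            if n_sites < 1:
                raise ValueError(f"template without substitution sites: {tmpl!r}")
            for sub in self.substituents:
                _instantiate(tmpl, (sub,) * n_sites)


def _n_sites(template: str) -> int:
    n = 0
    while f"{{R{n}}}" in template:
        n += 1
    return n


def _instantiate(template: str, subs: tuple[str, ...]) -> str:
    smi = template
    for i, sub in enumerate(subs):
        smi = smi.replace(f"{{R{i}}}", sub)
    try:
        return standardize(smi)
    except Exception as exc:
        raise ValueError(
            f"template {template!r} with substituents {subs} produced an "
            f"unparseable SMILES: {exc}"
        ) from exc


def enumerate_library(
    templates,
    substituents,
    max_products: int | None = None,
    seed: int = 0,
) -> list[str]:
    """All (or a seeded sample of) substituted products, canonical, unique."""
    products: dict[str, None] = {}
    for tmpl in templates:
        n_sites = _n_sites(tmpl)
        if n_sites < 1:
            raise ValueError(f"template without substitution sites: {tmpl!r}")
        for combo in itertools.product(substituents, repeat=n_sites):
            products[_instantiate(tmpl, combo)] = None
    out = list(products)
    if max_products is not None and len(out) > max_products:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(out), size=max_products, replace=False))
        out = [out[i] for i in idx]
    return out


def _substituent_effect(substituents, combo_indices) -> float:
    # deterministic small SAR effect per fragment, centred near 0
    return sum(((i % 5) - 2) * 0.08 for i in combo_indices)


def simulate_project(spec: SyntheticProjectSpec) -> list[MoleculeRecord]:
    """Simulate one project; deterministic for a given spec (incl. seed).

    Dates are integer day offsets (one compound per day). All four
    activity classes carry at least 5 compounds; the simulation is
    resampled with derived seeds a bounded number of times, else it fails.
    """
    for attempt in range(_MAX_ATTEMPTS):
        records = _simulate_once(spec, spec.seed + 100_003 * attempt)
        if records is not None:
            return records
    raise ValueError(
        f"spec infeasible: could not populate all activity classes with "
        f">= {_MIN_PER_CLASS} compounds in {_MAX_ATTEMPTS} attempts"
    )


def _simulate_once(spec, seed) -> list[MoleculeRecord] | None:
    rng = np.random.default_rng(seed)
    n = spec.n_compounds
    thr = spec.thresholds
    founding, drifted = spec.templates
    records = []
    class_counts = {"low": 0, "middle": 0, "high": 0, "ultra_high": 0}
    for t in range(n):
        frac = t / (n - 1)
        noise = rng.normal(0.0, spec.noise_sd)
        pxc50 = spec.base_pxc50 + spec.drift_slope * frac + noise
        is_early = frac < 0.5
        if not is_early and rng.random() < spec.p_setback:
            pxc50 -= abs(rng.normal(spec.setback_mean, spec.setback_sd))
        potent = pxc50 >= thr.t_mid_high
        if is_early:
            template = founding
        elif spec.regime == "public_like":
            template = founding if potent else drifted
        else:  # inhouse_like
            template = drifted if potent else founding
        n_sites = _n_sites(template)
        combo_idx = tuple(
            int(rng.integers(len(spec.substituents))) for _ in range(n_sites)
        )
        pxc50 += _substituent_effect(spec.substituents, combo_idx)
        smiles = _instantiate(
            template, tuple(spec.substituents[i] for i in combo_idx)
        )
        if pxc50 < thr.t_low_mid:
            class_counts["low"] += 1
        elif pxc50 < thr.t_mid_high:
            class_counts["middle"] += 1
        elif pxc50 < thr.t_high_ultra:
            class_counts["high"] += 1
        else:
            class_counts["ultra_high"] += 1
        records.append(
            MoleculeRecord(
                id=f"syn{t:04d}",
                smiles_raw=smiles,
                smiles_canonical=smiles,
                pxc50=round(float(pxc50), 4),
                date=t,
                source_row=t,
            )
        )
    if min(class_counts.values()) < _MIN_PER_CLASS:
        return None
    return records


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write everything needed to run the full pipeline offline.

    Produces a public-like project, an in-house-like project, a
    pretraining corpus (the enumerated library superset) and a reference
    generated set sampled from a Markov model fit on that corpus.
    Regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "public_project": out_dir / "project_public_like.csv",
        "inhouse_project": out_dir / "project_inhouse_like.csv",
        "pretraining_corpus": out_dir / "pretraining_corpus.smi",
        "generated_set": out_dir / "generated_reference.smi",
    }
    public = simulate_project(
        SyntheticProjectSpec(regime="public_like", seed=seed)
    )
    inhouse = simulate_project(
        SyntheticProjectSpec(regime="inhouse_like", seed=seed + 1)
    )
    write_records(public, paths["public_project"])
    write_records(inhouse, paths["inhouse_project"])

    corpus = enumerate_library(DEFAULT_TEMPLATES, DEFAULT_SUBSTITUENTS)
    write_generated_set(corpus, paths["pretraining_corpus"])

    model = baseline_generator.MarkovSmilesModel(order=3).fit(corpus)
    sampled = model.sample(1000, seed=seed)
    write_generated_set(sampled, paths["generated_set"])
    return paths
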