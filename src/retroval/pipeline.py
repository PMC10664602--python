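"""End-to-end orchestration: configuration, stage runners, manifest.

Every artifact a run writes is listed in ``manifest.json`` together with
its SHA-256 hash and the full configuration, so any reported number can be
traced back to the config and seeds that produced it. No timestamps are
written anywhere: two runs with the same config produce byte-identical
artifacts and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (
    activity_scorer,
    baseline_generator,
    chem_io,
    cluster_predictivity,
    metrics,
    pseudotime,
    stratify,
    synthetic_data,
)


@dataclass
class RunConfig:
    """All knobs of a retrospective-evaluation run."""

    project_table: str = ""
    generated_sets: tuple[str, ...] = ()
    pretraining_corpus: str = ""
    out_dir: str = "retroval_out"
    column_map: dict = field(default_factory=dict)

    thresholds: tuple[float, float, float] = (6.0, 7.0, 8.0)
    stage_mode: str = "pseudo_time"
    stage_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    stage_cutpoints: tuple = ()
    focus_rule: str = "above_mean_early"

    pseudotime_fp_bits: int = 1024
    pseudotime_fp_max_path: int = 7
    pca_standardize_scores: bool = True
    pca_standardize_pxc50: bool = False
    asnn_radius: int = 2
    asnn_bits: int = 2048

    seed_scorer: int = 17
    seed_kmeans: int = 23
    seed_generator: int = 29
    seed_simulator: int = 31

    top_k: tuple[int, ...] = (100, 500)
    novelty_reference: str = "union"  # union | pretraining | focus
    kmeans_k: int = 10

    generator_order: int = 3
    generator_smoothing: float = 0.01
    generator_lambda: float = 0.7
    n_samples: int = 5000
    sample_max_len: int = 120

    def __post_init__(self) -> None:
        for name in ("generated_sets", "thresholds", "stage_fractions",
                     "stage_cutpoints", "top_k"):
            setattr(self, name, tuple(getattr(self, name)))

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived objects -------------------------------------------------

    def activity_thresholds(self) -> stratify.ActivityThresholds:
        t1, t2, t3 = self.thresholds
        return stratify.ActivityThresholds(t1, t2, t3)

    def stage_config(self) -> stratify.StageConfig:
        return stratify.StageConfig(
            mode=self.stage_mode,
            fractions=tuple(self.stage_fractions),
            cutpoints=tuple(self.stage_cutpoints),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


class PipelineRun:
    """Stateful runner accumulating artifacts for the manifest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, Path] = {}
        self.labelled: stratify.LabelledDataset | None = None
        self.focus_records = None
        self.scorer: activity_scorer.ScorerModel | None = None
        self.prior: baseline_generator.MarkovSmilesModel | None = None
        self.focused: baseline_generator.MarkovSmilesModel | None = None
        self.corpus: list[str] | None = None

    def _register(self, name: str, path: Path) -> Path:
        self.artifacts[name] = path
        return path

    # -- stages ----------------------------------------------------------

    def load_project(self) -> list[chem_io.MoleculeRecord]:
        cfg = self.config
        if not cfg.project_table:
            raise ValueError("config has no project_table")
        path = Path(cfg.project_table)
        if path.suffix.lower() == ".csv":
            import pandas as pd

            header = list(pd.read_csv(path, nrows=0).columns)
            if header == list(chem_io.TABLE_COLUMNS):
                # already-normalized project CSV
                records = chem_io.load_records(path)
                self.load_report = chem_io.LoadReport(
                    n_rows=len(records), n_loaded=len(records)
                )
                return records
        records, report = chem_io.load_project_table(
            path, cfg.column_map or None
        )
        self.load_report = report
        return records

    def characterize(self) -> dict:
        """Label the project and report region sizes and region aSNN."""
        cfg = self.config
        records = self.load_project()
        ptm = None
        if cfg.stage_mode == "pseudo_time":
            ptm = pseudotime.pseudo_time_order(
                records,
                fp_bits=cfg.pseudotime_fp_bits,
                fp_max_path=cfg.pseudotime_fp_max_path,
                standardize_scores=cfg.pca_standardize_scores,
                standardize_pxc50=cfg.pca_standardize_pxc50,
            )
            import pandas as pd

            pseudo = pd.DataFrame(
                {
                    "id": [r.id for r in records],
                    "distance": ptm.distances,
                    "pseudo_rank": np.argsort(ptm.order, kind="stable"),
                }
            )
            pseudo.to_csv(
                self._register("pseudotime", self.out_dir / "pseudotime.csv"),
                index=False,
            )
        self.labelled = stratify.label_dataset(
            records,
            thresholds=cfg.activity_thresholds(),
            stage_config=cfg.stage_config(),
            pseudo_time_map=ptm,
        )
        self.labelled.to_csv(
            self._register("labelled", self.out_dir / "labelled.csv")
        )
        sizes = {
            region: len(self.labelled.region_records(region))
            for region in stratify.REGIONS
        }
        pair_asnn = {}
        for a, b in (("alpha", "beta"), ("alpha", "gamma"), ("beta", "gamma")):
            if sizes[a] and sizes[b]:
                pair_asnn[f"{a}-{b}"] = stratify.region_asnn(
                    self.labelled, a, b,
                    radius=cfg.asnn_radius, n_bits=cfg.asnn_bits,
                )
        report = {
            "n_records": len(self.labelled),
            "n_dropped_rows": self.load_report.n_dropped,
            "region_sizes": sizes,
            "stage_sizes": {
                s: self.labelled.stage.count(s) for s in stratify.STAGES
            },
            "region_asnn": pair_asnn,
            "stage_mode": cfg.stage_mode,
        }
        _write_json(
            report,
            self._register(
                "characterization", self.out_dir / "characterization.json"
            ),
        )
        return report

    def build_focus(self):
        if self.labelled is None:
            self.characterize()
        self.focus_records = stratify.focus_set(
            self.labelled, self.config.focus_rule
        )
        chem_io.write_generated_set(
            [r.smiles_canonical for r in self.focus_records],
            self._register("focus_set", self.out_dir / "focus_set.smi"),
        )
        return self.focus_records

    def train_scorer(self) -> activity_scorer.ScorerModel:
        if self.labelled is None:
            self.characterize()
        early = [
            r
            for r, s in zip(self.labelled.records, self.labelled.stage)
            if s == "early"
        ]
        self.scorer = activity_scorer.train(early, self.config.seed_scorer)
        self.scorer.save(self.out_dir / "scorer_model.joblib")
        _write_json(
            {
                "balanced_accuracy_test": self.scorer.balanced_accuracy_test,
                "training_mean_pxc50": self.scorer.training_mean_pxc50,
                "n_training": len(early),
                "seed": self.config.seed_scorer,
                "descriptor": {"radius": self.scorer.radius,
                               "n_bits": self.scorer.n_bits},
            },
            self._register(
                "scorer_summary", self.out_dir / "scorer_summary.json"
            ),
        )
        return self.scorer

    def _load_corpus(self) -> list[str]:
        if self.corpus is None:
            if self.config.pretraining_corpus:
                smiles, _ = chem_io.load_generated_set(
                    self.config.pretraining_corpus
                )
                self.corpus = smiles
            else:
                self.corpus = synthetic_data.enumerate_library(
                    synthetic_data.DEFAULT_TEMPLATES,
                    synthetic_data.DEFAULT_SUBSTITUENTS,
                )
        return self.corpus

    def build_generator(self) -> list[str]:
        """Fit prior + focused models and sample the generated set."""
        cfg = self.config
        if self.focus_records is None:
            self.build_focus()
        corpus = self._load_corpus()
        self.prior = baseline_generator.MarkovSmilesModel(
            cfg.generator_order, cfg.generator_smoothing
        ).fit(corpus)
        self.focused = self.prior.focus(
            [r.smiles_canonical for r in self.focus_records],
            cfg.generator_lambda,
        )
        self.focused.save(self.out_dir / "generator_model.json")
        sampled = self.focused.sample(
            cfg.n_samples, max_len=cfg.sample_max_len, seed=cfg.seed_generator
        )
        chem_io.write_generated_set(
            sampled, self._register("generated", self.out_dir / "generated.smi")
        )
        return sampled

    def _novelty_reference(self) -> set[str]:
        cfg = self.config
        focus = {r.smiles_canonical for r in self.focus_records or ()}
        corpus = set(self._load_corpus())
        if cfg.novelty_reference == "pretraining":
            return corpus
        if cfg.novelty_reference == "focus":
            return focus
        return corpus | focus

    def evaluate(self, generated_raw, scores=None, name="generated") -> dict:
        """Metric funnel + stratified aSNN for the full set and top-k cuts."""
        cfg = self.config
        if self.labelled is None:
            self.characterize()
        if self.focus_records is None:
            self.build_focus()
        gamma = self.labelled.region_smiles("gamma")
        novelty_ref = self._novelty_reference()

        cuts: dict[str, list[str]] = {"full": list(generated_raw)}
        if scores is not None:
            ranked_scores = np.asarray(scores, dtype=float)
            ranked_scores = np.where(
                np.isnan(ranked_scores), -np.inf, ranked_scores
            )
            for k in cfg.top_k:
                if k <= len(generated_raw):
                    cuts[f"top{k}"] = metrics.top_k_by_score(
                        list(generated_raw), ranked_scores, k
                    )
        out = {}
        for cut_name, subset in cuts.items():
            report = metrics.evaluate_generated(subset, novelty_ref, gamma)
            _write_json(
                report.to_dict(),
                self._register(
                    f"{name}_{cut_name}_report",
                    self.out_dir / f"{name}_{cut_name}_report.json",
                ),
            )
            _, _, valid_canonical = metrics.validity(subset)
            if valid_canonical:
                table = metrics.stratified_asnn(
                    valid_canonical,
                    self.labelled,
                    radius=cfg.asnn_radius,
                    n_bits=cfg.asnn_bits,
                )
                table.to_csv(
                    self._register(
                        f"{name}_{cut_name}_asnn",
                        self.out_dir / f"{name}_{cut_name}_asnn.csv",
                    )
                )
                out[cut_name] = {
                    "report": report.to_dict(),
                    "asnn": {
                        f"{s}:{c}": v for (s, c), v in table.entries.items()
                    },
                }
            else:
                out[cut_name] = {"report": report.to_dict(), "asnn": {}}
        return out

    def cluster(self) -> dict:
        cfg = self.config
        if self.labelled is None:
            self.characterize()
        results = cluster_predictivity.analyze_clusters(
            self.labelled, k=cfg.kmeans_k, seed=cfg.seed_kmeans
        )
        cluster_predictivity.predictivity_table(results).to_csv(
            self._register("clusters", self.out_dir / "clusters.csv"),
            index=False,
        )
        summary = cluster_predictivity.predictivity_summary(results)
        summary["seed"] = cfg.seed_kmeans
        summary["k"] = cfg.kmeans_k
        _write_json(
            summary,
            self._register(
                "cluster_summary", self.out_dir / "cluster_summary.json"
            ),
        )
        return summary

    def nll_summary(self):
        if self.focused is None:
            self.build_generator()
        df = baseline_generator.region_nll_summary(
            {"prior": self.prior, "focused": self.focused}, self.labelled
        )
        df.to_csv(
            self._register("region_nll", self.out_dir / "region_nll.csv"),
            index=False,
        )
        return df

    def region_scores(self):
        if self.scorer is None:
            self.train_scorer()
        df = activity_scorer.region_scores(self.scorer, self.labelled)
        df.to_csv(
            self._register(
                "region_scores", self.out_dir / "region_scores.csv"
            ),
            index=False,
        )
        return df

    def write_manifest(self) -> Path:
        manifest = {
            "config": self.config.to_dict(),
            "artifacts": {
                name: {
                    "path": str(path.relative_to(self.out_dir)),
                    "sha256": _sha256(path),
                }
                for name, path in sorted(self.artifacts.items())
            },
        }
        path = self.out_dir / "manifest.json"
        _write_json(manifest, path)
        return path


def run_characterize(config: RunConfig) -> dict:
    run = PipelineRun(config)
    report = run.characterize()
    run.write_manifest()
    return report


def run_evaluate(config: RunConfig, generated_path: str, name=None) -> dict:
    run = PipelineRun(config)
    run.characterize()
    run.build_focus()
    smiles, scores = chem_io.load_generated_set(generated_path)
    if scores is None and config.top_k:
        run.train_scorer()
        scores = activity_scorer.score(run.scorer, smiles)
    name = name or Path(generated_path).stem
    out = run.evaluate(smiles, scores, name=name)
    run.write_manifest()
    return out


def run_full(config: RunConfig) -> Path:
    """Execute every stage and return the manifest path.

    Any stage failure aborts with the stage name; artifacts produced so
    far are retained next to a FAILED marker naming the stage.
    """
    run = PipelineRun(config)
    stages = [
        ("characterize", run.characterize),
        ("focus", run.build_focus),
        ("train_scorer", run.train_scorer),
        ("generate", run.build_generator),
        ("evaluate", None),  # handled below, needs the samples
        ("cluster", run.cluster),
        ("nll", run.nll_summary),
        ("region_scores", run.region_scores),
    ]
    sampled = None
    for name, fn in stages:
        try:
            if name == "generate":
                sampled = fn()
            elif name == "evaluate":
                scores = activity_scorer.score(run.scorer, sampled)
                run.evaluate(sampled, scores, name="generated")
            else:
                fn()
        except Exception as exc:
            marker = run.out_dir / "FAILED"
            marker.write_text(f"stage {name} failed: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return run.write_manifest()
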