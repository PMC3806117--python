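"""End-to-end orchestration: generate -> preprocess -> features -> train -> evaluate.

A run is fully described by a :class:`PipelineConfig` (serializable to and
from YAML) and a seed; the persisted report contains the feature table,
four confusion matrices (two classifiers x train/test), the derived metric
reports, and a manifest echoing the configuration, so a run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anfis import AnfisConfig, AnfisModel, train_anfis
from .core import CLASSES, FeatureVector, features_to_arrays
from .evaluation import ConfusionMatrix, MetricReport, confusion, make_split, metrics
from .features import FeatureConfig, extract_features
from .fixtures import load_paper_fixtures
from .io import features_to_frame
from .preprocess import segments_to_parts
from .svm import OvaSvmModel, SvmConfig, train_ova_svm
from .synthetic import DatasetDesign, SynthesisConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "scale_design", "run_pipeline", "verify_tables"]


def scale_design(design: DatasetDesign, factor: float) -> DatasetDesign:
    """Shrink (or grow) a design's counts by ``factor``; nonzero cells keep >= 1."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    rows = [
        (s, l, 0 if c == 0 else max(1, int(round(c * factor))))
        for s, l, c in design.rows
    ]
    return DatasetDesign(rows)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one experiment run (except the seed)."""

    experiment: str = "II"  # "I" (shared subjects) or "II" (disjoint subjects)
    design: str = "table3"  # "table2" | "table3"
    design_scale: float = 1.0
    duration_range_s: tuple[float, float] = (0.5, 2.0)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    anfis: AnfisConfig = field(default_factory=AnfisConfig)

    def __post_init__(self) -> None:
        if self.experiment not in ("I", "II"):
            raise ValueError("experiment must be 'I' or 'II'")
        if self.design not in ("table2", "table3"):
            raise ValueError("design must be 'table2' or 'table3'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("synthesis", SynthesisConfig),
            ("features", FeatureConfig),
            ("svm", SvmConfig),
            ("anfis", AnfisConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "duration_range_s" in kwargs:
            kwargs["duration_range_s"] = tuple(kwargs["duration_range_s"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"]["fit_range"] = list(self.features.fit_range)
        return d


@dataclass
class RunReport:
    """All artefacts of one pipeline run."""

    config: PipelineConfig
    seed: int
    features_train: list[FeatureVector]
    features_test: list[FeatureVector]
    confusions: dict[tuple[str, str], ConfusionMatrix]  # (classifier, phase)
    reports: dict[tuple[str, str], MetricReport]
    svm_model: OvaSvmModel
    anfis_model: AnfisModel

    def accuracy(self, classifier: str, phase: str) -> float:
        return self.reports[(classifier, phase)].total_accuracy_pct

    def manifest(self) -> dict:
        return {
            "package_version": __version__,
            "python_version": platform.python_version(),
            "numpy_version": np.__version__,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "n_train_parts": len(self.features_train),
            "n_test_parts": len(self.features_test),
        }

    def write(self, outdir: str | Path) -> Path:
        """Persist feature tables, confusion matrices, metrics and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        features_to_frame(self.features_train).to_csv(outdir / "features_train.csv", index=False)
        features_to_frame(self.features_test).to_csv(outdir / "features_test.csv", index=False)
        def _clean(d: dict[str, float]) -> dict[str, float | None]:
            # undefined (NaN) metrics become null so the file stays strict JSON
            return {k: (None if not np.isfinite(v) else v) for k, v in d.items()}

        summary: dict[str, dict] = {}
        for (clf, phase), cm in self.confusions.items():
            rep = self.reports[(clf, phase)]
            cm_df = cm.to_frame()
            cm_df.insert(0, "n_parts", cm.row_totals)
            cm_df["sensitivity_pct"] = [rep.sensitivity_pct[c] for c in cm.labels]
            cm_df["ppv_pct"] = [rep.ppv_pct[c] for c in cm.labels]
            cm_df.to_csv(outdir / f"confusion_{clf}_{phase}.csv")
            summary[f"{clf}_{phase}"] = {
                "total_accuracy_pct": rep.total_accuracy_pct,
                "sensitivity_pct": _clean(rep.sensitivity_pct),
                "ppv_pct": _clean(rep.ppv_pct),
            }
        (outdir / "metrics.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True)
        )
        return outdir


def _design_and_split(config: PipelineConfig):
    fixtures = load_paper_fixtures()
    if config.design == "table2":
        design = fixtures.experiment1_design()
        test_subjects = None
    else:
        design = fixtures.experiment2_design()
        test_subjects = fixtures.experiment2_test_subjects()
    if config.design_scale != 1.0:
        design = scale_design(design, config.design_scale)
    if config.experiment == "II" and test_subjects is None:
        raise ValueError("Experiment II needs the table3 design (disjoint subject sides)")
    return design, test_subjects


def run_pipeline(config: PipelineConfig, seed: int) -> RunReport:
    """Execute the full experiment and return the in-memory report."""

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    try:
        stage("generate")
        design, test_subjects = _design_and_split(config)
        segments = generate_dataset(
            design, seed, duration_range_s=config.duration_range_s, config=config.synthesis
        )
        stage("split")
        split = make_split(segments, config.experiment, test_subjects=test_subjects)
        stage("preprocess+extract")
        feats = {}
        for phase, segs in (("train", split.train(segments)), ("test", split.test(segments))):
            parts = segments_to_parts(segs)
            feats[phase] = extract_features(parts, config.features)
        stage("train classifiers")
        X_train, y_train = features_to_arrays(feats["train"])
        svm_model = train_ova_svm((X_train, y_train), config.svm)
        anfis_model = train_anfis((X_train, y_train), config=config.anfis)
        stage("evaluate")
        confusions: dict[tuple[str, str], ConfusionMatrix] = {}
        reports: dict[tuple[str, str], MetricReport] = {}
        for phase in ("train", "test"):
            X, y = features_to_arrays(feats[phase])
            for clf, model in (("svm", svm_model), ("anfis", anfis_model)):
                cm = confusion(y, model.predict(X))
                confusions[(clf, phase)] = cm
                reports[(clf, phase)] = metrics(cm)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    return RunReport(
        config=config,
        seed=seed,
        features_train=feats["train"],
        features_test=feats["test"],
        confusions=confusions,
        reports=reports,
        svm_model=svm_model,
        anfis_model=anfis_model,
    )


def verify_tables(tolerance: float = 0.01) -> pd.DataFrame:
    """Recompute every printed metric cell from the shipped confusion matrices.

    Returns one row per (table, block, metric cell) with the printed value,
    the recomputed value, and a pass flag at ``tolerance`` (absolute
    percentage points, after rounding to two decimals).
    """
    fixtures = load_paper_fixtures()
    rows = []
    for (table, block), blk in sorted(fixtures.blocks.items()):
        rep = metrics(blk.matrix)
        cells = [("total_accuracy", None, blk.printed_total_accuracy_pct, rep.total_accuracy_pct)]
        for c in CLASSES:
            cells.append(("sensitivity", c, blk.printed_sensitivity_pct[c], rep.sensitivity_pct[c]))
            cells.append(("ppv", c, blk.printed_ppv_pct[c], rep.ppv_pct[c]))
        for metric_name, cls, printed, computed in cells:
            rows.append(
                {
                    "table": table,
                    "block": block,
                    "metric": metric_name,
                    "class": cls or "",
                    "printed": printed,
                    "computed": round(computed, 2),
                    "ok": abs(round(computed, 2) - printed) <= tolerance + 1e-9,
                }
            )
    return pd.DataFrame(rows)
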