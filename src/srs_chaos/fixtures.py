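"""Typed access to the published worked-example tables shipped with the package.

The package ships six small CSV fixtures transcribing the published
experiment designs and result tables of the clinical study this pipeline
mirrors:

* ``table2.csv`` — Experiment I per-subject segment counts (12 subjects,
  first-half/second-half split; 672 training / 668 test segments).
* ``table3.csv`` — Experiment II per-subject counts (6 training subjects,
  553 segments; 6 test subjects, 787 segments).
* ``table4a/4b.csv`` — Experiment I confusion matrices with printed
  sensitivity/PPV/total-accuracy cells (M-SVM / ANFIS).
* ``table5a/5b.csv`` — the same for Experiment II.

These are worked-example inputs for validating the metric engine and the
dataset bookkeeping; they are not training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CLASSES
from .evaluation import ConfusionMatrix
from .synthetic import DatasetDesign

__all__ = ["PrintedBlock", "PaperFixtures", "load_paper_fixtures"]

_TABLE_FILES = ("table2.csv", "table3.csv", "table4a.csv", "table4b.csv", "table5a.csv", "table5b.csv")


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("srs_chaos.data").joinpath(name)
    try:
        with ref.open("r") as fh:
            return pd.read_csv(fh)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"missing fixture file {name!r} in srs_chaos/data") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"corrupt fixture file {name!r}: {exc}") from exc


@dataclass
class PrintedBlock:
    """One training or test block of a printed result table."""

    table: str  # "4a" | "4b" | "5a" | "5b"
    block: str  # "training" | "test"
    matrix: ConfusionMatrix
    printed_sensitivity_pct: dict[str, float]
    printed_ppv_pct: dict[str, float]
    printed_total_accuracy_pct: float


@dataclass
class PaperFixtures:
    """All published tables, typed."""

    #: Experiment I design: (subject, phase) -> per-class counts
    experiment1_counts: pd.DataFrame
    #: Experiment II design: (subject, side) -> per-class counts
    experiment2_counts: pd.DataFrame
    #: "4a"/"4b"/"5a"/"5b" x "training"/"test" -> PrintedBlock
    blocks: dict[tuple[str, str], PrintedBlock]

    # -- designs -----------------------------------------------------------
    def experiment1_design(self) -> DatasetDesign:
        """Combined (train + test) per-subject counts for Experiment I generation."""
        rows = []
        totals = self.experiment1_counts.groupby("subject", sort=False)[list(CLASSES)].sum()
        for subject, row in totals.iterrows():
            for label in CLASSES:
                rows.append((str(subject), label, int(row[label])))
        return DatasetDesign(rows)

    def experiment1_phase_design(self, phase: str) -> DatasetDesign:
        sel = self.experiment1_counts[self.experiment1_counts["phase"] == phase]
        if sel.empty:
            raise ValueError(f"unknown phase {phase!r}")
        rows = [
            (str(r["subject"]), label, int(r[label]))
            for _, r in sel.iterrows()
            for label in CLASSES
        ]
        return DatasetDesign(rows)

    def experiment2_design(self, side: str | None = None) -> DatasetDesign:
        sel = self.experiment2_counts
        if side is not None:
            sel = sel[sel["side"] == side]
            if sel.empty:
                raise ValueError(f"unknown side {side!r}")
        rows = [
            (str(r["subject"]), label, int(r[label]))
            for _, r in sel.iterrows()
            for label in CLASSES
        ]
        return DatasetDesign(rows)

    def experiment2_test_subjects(self) -> set[str]:
        sel = self.experiment2_counts
        return set(sel[sel["side"] == "test"]["subject"].astype(str))


def _parse_result_table(name: str, table: str) -> dict[tuple[str, str], PrintedBlock]:
    df = _read_fixture(name)
    blocks: dict[tuple[str, str], PrintedBlock] = {}
    for block_name, sub in df.groupby("block", sort=False):
        sub = sub.set_index("true_class").loc[list(CLASSES)]
        counts = sub[list(CLASSES)].to_numpy(dtype=int)
        row_sums = counts.sum(axis=1)
        printed_n = sub["n_parts"].to_numpy(dtype=int)
        if not np.array_equal(row_sums, printed_n):
            raise ValueError(
                f"corrupt fixture {name!r}: row sums {row_sums.tolist()} do not match "
                f"printed part counts {printed_n.tolist()} in block {block_name!r}"
            )
        total_acc = float(sub["total_accuracy_pct"].dropna().iloc[0])
        blocks[(table, str(block_name))] = PrintedBlock(
            table=table,
            block=str(block_name),
            matrix=ConfusionMatrix(counts),
            printed_sensitivity_pct=dict(zip(CLASSES, sub["sensitivity_pct"].astype(float))),
            printed_ppv_pct=dict(zip(CLASSES, sub["ppv_pct"].astype(float))),
            printed_total_accuracy_pct=total_acc,
        )
    return blocks


def load_paper_fixtures() -> PaperFixtures:
    """Load every shipped table; raises naming the file if one is missing/corrupt."""
    exp1 = _read_fixture("table2.csv")
    exp2 = _read_fixture("table3.csv")
    for df, name, col in ((exp1, "table2.csv", "phase"), (exp2, "table3.csv", "side")):
        missing = {col, "subject", *CLASSES} - set(df.columns)
        if missing:
            raise ValueError(f"corrupt fixture {name!r}: missing columns {sorted(missing)}")
    blocks: dict[tuple[str, str], PrintedBlock] = {}
    for name, table in (
        ("table4a.csv", "4a"),
        ("table4b.csv", "4b"),
        ("table5a.csv", "5a"),
        ("table5b.csv", "5b"),
    ):
        blocks.update(_parse_result_table(name, table))
    return PaperFixtures(experiment1_counts=exp1, experiment2_counts=exp2, blocks=blocks)
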