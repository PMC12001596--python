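"""Ground-truth categorization and performance metrics for simulation runs.

Because pathways overlap, injecting an effect into k selected pathways
also makes some metabolites of *other* pathways differential.  Pathways
therefore fall into three categories:

* **differential** — explicitly selected for injection (clean positives);
* **overlapping** — not selected but sharing at least one target
  metabolite (no clean ground-truth label);
* **non_differential** — containing no target metabolite (clean negatives).

Confusion counts (TP/FP/FN/TN) are computed only over the two clean
categories; overlapping pathways are tallied separately as positive or
negative calls, and their fraction of differential members supports the
plausibility analysis of those calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PathwaySet


@dataclass
class PathwayTruth:
    differential: frozenset[str]
    overlapping: frozenset[str]
    non_differential: frozenset[str]

    def __post_init__(self) -> None:
        if self.differential & self.overlapping:
            raise ValueError("differential and overlapping sets intersect")

    @property
    def all_pathways(self) -> frozenset[str]:
        return self.differential | self.overlapping | self.non_differential


@dataclass
class EvalReport:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    pos_overlap: int = 0
    neg_overlap: int = 0

    @property
    def ppv(self) -> float:
        """Precision over clean categories; NA when nothing is positive."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    def __add__(self, other: "EvalReport") -> "EvalReport":
        return EvalReport(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
            self.pos_overlap + other.pos_overlap,
            self.neg_overlap + other.neg_overlap,
        )


def categorize(
    ps: PathwaySet,
    selected: frozenset[str] | set[str] | list[str],
    target_metabolites: frozenset[str] | set[str],
) -> PathwayTruth:
    """Partition pathways into differential / overlapping / non-differential."""
    selected = frozenset(selected)
    unknown = selected - frozenset(ps.ids)
    if unknown:
        raise ValueError(f"selected pathway(s) not in set: {sorted(unknown)}")
    targets = frozenset(target_metabolites)
    overlapping = frozenset(
        pid for pid in ps.ids
        if pid not in selected and ps[pid] & targets
    )
    non_diff = frozenset(ps.ids) - selected - overlapping
    return PathwayTruth(selected, overlapping, non_diff)


def confusion(
    results: pd.DataFrame,
    truth: PathwayTruth,
    alpha: float = 0.05,
    pvalue_column: str = "adj_p",
) -> EvalReport:
    """Count calls per category at threshold ``alpha``.

    ``results`` needs ``pathway_id`` and the chosen p-value column (one
    effect at a time).  Unknown pathways raise; missing pathways simply
    do not contribute (skipped pathways count as not-called).
    """
    report = EvalReport()
    seen = set()
    for _, row in results.iterrows():
        pid = row["pathway_id"]
        if pid not in truth.all_pathways:
            raise ValueError(f"pathway '{pid}' not categorized")
        if pid in seen:
            raise ValueError(f"duplicate result row for pathway '{pid}'")
        seen.add(pid)
        p = row[pvalue_column]
        positive = bool(np.isfinite(p) and p < alpha)
        if pid in truth.differential:
            report.tp += positive
            report.fn += not positive
        elif pid in truth.overlapping:
            report.pos_overlap += positive
            report.neg_overlap += not positive
        else:
            report.fp += positive
            report.tn += not positive
    # pathways absent from results (skipped) count as negative calls
    for pid in truth.all_pathways - seen:
        if pid in truth.differential:
            report.fn += 1
        elif pid in truth.overlapping:
            report.neg_overlap += 1
        else:
            report.tn += 1
    return report


def overlap_diff_fraction(
    ps: PathwaySet,
    truth: PathwayTruth,
    target_metabolites: frozenset[str] | set[str],
) -> pd.Series:
    """Fraction of differential members per overlapping pathway.

    Can reach 1.0 when an overlapping pathway is entirely contained in a
    differential one.
    """
    targets = frozenset(target_metabolites)
    out = {
        pid: len(ps[pid] & targets) / len(ps[pid])
        for pid in sorted(truth.overlapping)
    }
    return pd.Series(out, dtype=float, name="diff_metab_fraction")
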