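"""Core data containers and file I/O.

The two central objects are :class:`QuantTable` — a samples × metabolites
matrix of nonnegative metabolite quantifications joined to a longitudinal
sample design (individual, time, condition) — and :class:`PathwaySet`, a
collection of named, possibly overlapping metabolite sets.

Quantifications are relative abundances (e.g. NMR-derived) and are used as
provided: no log transform, no missing values.  The design may be
incomplete (an individual may miss a time point) but every observation is
keyed by a unique (individual, time) pair and each individual belongs to
exactly one condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("individual", "time", "condition")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _as_ordered_time(values: pd.Series) -> pd.Categorical:
    """Time levels ordered numerically when possible, else lexically."""
    levels = pd.unique(values.astype(str))
    try:
        order = sorted(levels, key=float)
    except ValueError:
        order = sorted(levels)
    return pd.Categorical(values.astype(str), categories=order, ordered=True)


@dataclass
class QuantTable:
    """Samples × metabolites quantification matrix with its design.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id, one column per metabolite,
        nonnegative reals, no missing entries.
    design
        DataFrame indexed by sample_id with columns ``individual``,
        ``time`` (ordered categorical) and ``condition``.

    Rows are canonicalized to time-major order: all individuals at the
    first time level, then the second, and so on; within a time level,
    individuals are sorted.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()
        self._canonicalize()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        v, d = self.values, self.design
        if not v.index.equals(d.index):
            missing = v.index.symmetric_difference(d.index).tolist()
            raise ValidationError(
                f"values and design sample_ids differ: {missing[:5]}"
            )
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metabolite ids: {dups[:5]}")
        if v.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, c in zip(*np.where(v.isna().to_numpy()))
            ]
            named = [
                f"({v.index[i]}, {v.columns[j]})"
                for i, j in zip(*np.where(v.isna().to_numpy()))
            ][:5]
            del cells
            raise ValidationError(f"missing quantifications at cells {named}")
        if (v.to_numpy() < 0).any():
            raise ValidationError("negative quantifications present")
        for col in DESIGN_COLUMNS:
            if col not in d.columns:
                raise ValidationError(f"design missing column '{col}'")
        if d[list(DESIGN_COLUMNS)].isna().any().any():
            raise ValidationError("missing entries in design")
        dup = d.duplicated(subset=["individual", "time"])
        if dup.any():
            pairs = d.loc[dup, ["individual", "time"]].astype(str).agg(
                "/".join, axis=1
            ).tolist()
            raise ValidationError(
                f"duplicate (individual, time) observations: {pairs[:5]}"
            )
        n_cond = d.groupby("individual", observed=True)["condition"].nunique()
        bad = n_cond[n_cond > 1].index.tolist()
        if bad:
            raise ValidationError(
                f"inconsistent condition for individuals {bad[:5]}"
            )

    def _canonicalize(self) -> None:
        d = self.design.copy()
        if not isinstance(d["time"].dtype, pd.CategoricalDtype):
            d["time"] = _as_ordered_time(d["time"])
        d["individual"] = d["individual"].astype(str)
        d["condition"] = d["condition"].astype(str)
        order = d.sort_values(
            ["time", "individual"], kind="mergesort"
        ).index
        self.design = d.loc[order]
        self.values = self.values.loc[order].astype(float)

    # -- convenience ---------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def n_individuals(self) -> int:
        return self.design["individual"].nunique()

    @property
    def time_levels(self) -> list[str]:
        return list(self.design["time"].cat.categories)

    @property
    def condition_levels(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def with_values(self, values: pd.DataFrame) -> "QuantTable":
        """New table with replaced values, same design."""
        return QuantTable(values.loc[self.sample_ids], self.design.copy())

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.design.copy())


@dataclass
class PathwaySet:
    """Named, possibly overlapping sets of metabolite ids."""

    pathways: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id]

    def items(self):
        return self.pathways.items()

    @property
    def ids(self) -> list[str]:
        return list(self.pathways)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.pathways.items()}

    def largest(self) -> str:
        """Id of the largest pathway (ties broken by id)."""
        return max(self.pathways, key=lambda k: (len(self.pathways[k]), k))

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return frozenset(out)


@dataclass
class EffectTestResult:
    """One pathway × effect test outcome.

    ``component_pvalues`` holds the per-score-column mixed-model LRT
    p-values (length ``n_components``); ``simes_p`` aggregates them into a
    single pathway p-value and ``adj_p`` is the BH-adjusted value across
    all tested pathways for the same effect.
    """

    pathway_id: str
    effect: str
    component_pvalues: np.ndarray
    simes_p: float
    adj_p: float
    n_components: int
    n_metabolites: int
    not_recommended: bool = False


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

def read_quant_table(values_path: str | Path, design_path: str | Path) -> QuantTable:
    """Read a quantification TSV and a design TSV, join on sample_id.

    The values file has a ``sample_id`` first column and one column per
    metabolite.  The design file has columns ``sample_id``, ``individual``,
    ``time``, ``condition``.
    """
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id", dtype=str)
    return QuantTable(values, design)


def write_quant_table(
    qt: QuantTable, values_path: str | Path, design_path: str | Path
) -> None:
    qt.values.to_csv(values_path, sep="\t", index_label="sample_id")
    qt.design[list(DESIGN_COLUMNS)].to_csv(
        design_path, sep="\t", index_label="sample_id"
    )


def read_pathways(path: str | Path, format: str = "gmt") -> PathwaySet:
    """Read a pathway membership file.

    ``gmt``: one line per pathway, tab-separated
    ``pathway_id<TAB>description<TAB>member1<TAB>member2...``.
    ``long_tsv``: two-column (pathway_id, metabolite_id) pairs with header.

    Members absent from any particular quantification table are kept;
    filtering against a metabolite universe happens at test time.
    """
    path = Path(path)
    if format == "gmt":
        pathways: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3 or not parts[2:]:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs id, description "
                        "and at least one member"
                    )
                pid, desc, members = parts[0], parts[1], parts[2:]
                members = [m for m in members if m]
                if not members:
                    raise ValidationError(f"{path}:{lineno}: empty pathway {pid}")
                if pid in pathways:
                    raise ValidationError(f"duplicate pathway_id '{pid}'")
                pathways[pid] = frozenset(members)
                descriptions[pid] = desc
        return PathwaySet(pathways, descriptions)
    if format == "long_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("long format needs two columns")
        pid_col, met_col = df.columns[:2]
        pathways = {}
        for pid, grp in df.groupby(pid_col, sort=False):
            members = frozenset(grp[met_col])
            if not members:
                raise ValidationError(f"empty pathway {pid}")
            pathways[str(pid)] = members
        return PathwaySet(pathways)
    raise ValueError(f"unknown pathway format '{format}'")


def write_pathways_gmt(ps: PathwaySet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, members in ps.items():
            desc = ps.descriptions.get(pid, "")
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def filter_pathways(
    ps: PathwaySet, qt: QuantTable, min_size: int = 2
) -> PathwaySet:
    """Restrict pathways to quantified metabolites; drop the too-small.

    Each pathway is intersected with the metabolite columns of ``qt``;
    pathways left with fewer than ``min_size`` members are dropped (the
    method needs at least two quantified metabolites per pathway).
    Idempotent.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    quantified = frozenset(qt.metabolites)
    kept: dict[str, frozenset[str]] = {}
    dropped: list[str] = []
    for pid, members in ps.items():
        surviving = members & quantified
        if len(surviving) >= min_size:
            kept[pid] = surviving
        else:
            dropped.append(pid)
    if dropped:
        logger.info(
            "filter_pathways dropped %d pathway(s) with < %d quantified "
            "metabolites: %s",
            len(dropped), min_size, ", ".join(dropped[:10]),
        )
    descriptions = {k: ps.descriptions[k] for k in kept if k in ps.descriptions}
    return PathwaySet(kept, descriptions)


def results_to_frame(results: Iterable[EffectTestResult], alpha: float = 0.05) -> pd.DataFrame:
    """Flatten test results into the output TSV schema."""
    rows = []
    max_comp = 0
    results = list(results)
    for r in results:
        max_comp = max(max_comp, r.n_components)
    for r in results:
        row: dict[str, object] = {
            "pathway_id": r.pathway_id,
            "effect": r.effect,
            "n_metabolites": r.n_metabolites,
            "n_components": r.n_components,
        }
        for j in range(max_comp):
            row[f"comp_p_{j + 1}"] = (
                r.component_pvalues[j] if j < r.n_components else np.nan
            )
        row["simes_p"] = r.simes_p
        row["adj_p"] = r.adj_p
        row["significant"] = bool(r.adj_p < alpha) if np.isfinite(r.adj_p) else False
        row["not_recommended"] = r.not_recommended
        rows.append(row)
    return pd.DataFrame(rows)
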