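"""Semi-synthetic dataset construction from a base quantification table.

Three families of transforms, mirroring the standard benchmark design for
longitudinal pathway tests:

* **Null transforms** — erase the effect under test while leaving the rest
  of the data structure intact: condition labels are permuted between
  individuals (values untouched), or later time points are replaced by
  each individual's first-time measurements plus Gaussian noise.
* **Effect injection** — multiply the quantifications of the metabolites
  in k randomly selected pathways by condition-specific factors gamma_d
  (condition effect) or rebuild them from the first-time block scaled by
  time-specific factors gamma_t plus noise (time effect).
* **VSize designs** — inject the effect into only p-tilde members of the
  largest pathway (k-1 further pathways fully injected) to probe how many
  differential metabolites a pathway needs before it is detected.

The noise variance follows the benchmark convention sigma_b^2 =
noise_factor * (max - min) of the pre-noise matrix; noised values are
floored at 0 to keep quantifications nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import PathwaySet, QuantTable

logger = logging.getLogger(__name__)

#: Condition effect-size factors per scenario (treated condition; the
#: control condition always keeps gamma = 1).
CONDITION_SCENARIOS: dict[int, float] = {1: 10.0, 2: 3.0, 3: 2.0}

#: Time effect-size factors per scenario for a 3-time-point design,
#: ordered (t1, t2, t3); the first time point always keeps gamma = 1.
TIME_SCENARIOS: dict[int, tuple[float, float, float]] = {
    1: (1.0, 5.0, 10.0),
    2: (1.0, 2.0, 3.0),
    3: (1.0, 1.5, 2.0),
    4: (1.0, 1.2, 1.5),
}


@dataclass
class ScenarioSpec:
    """Recipe for one simulated dataset family."""

    effect: str                                 # condition | time | condition_time
    mode: str = "H1"                            # H0 | H1 | VSize
    gamma_d: Mapping[str, float] | None = None  # condition -> factor
    gamma_t: Mapping[str, float] | None = None  # time level -> factor
    k: int = 3
    p_tilde: int | None = None                  # VSize only
    noise_factor: float = 0.05
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect not in ("condition", "time", "condition_time"):
            raise ValueError(f"unknown effect '{self.effect}'")
        if self.mode not in ("H0", "H1", "VSize"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for g in (self.gamma_d, self.gamma_t):
            if g is not None and any(v <= 0 for v in g.values()):
                raise ValueError("gamma factors must be positive")


# ---------------------------------------------------------------------
# Null transforms
# ---------------------------------------------------------------------

def permute_condition(qt: QuantTable, seed: int | np.random.Generator = 0) -> QuantTable:
    """Permute condition labels among individuals (values untouched).

    Each individual keeps a single label and the label multiset over
    individuals is preserved, so the within-individual correlation
    structure — and any time effect — survives the permutation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cond_by_ind = (
        qt.design.groupby("individual", observed=True)["condition"].first()
    )
    if cond_by_ind.nunique() < 2:
        logger.warning("single condition; permutation is a no-op")
        return qt.copy()
    individuals = cond_by_ind.index.to_numpy()
    permuted = rng.permutation(cond_by_ind.to_numpy())
    new_map = dict(zip(individuals, permuted))
    design = qt.design.copy()
    design["condition"] = design["individual"].map(new_map)
    return QuantTable(qt.values.copy(), design)


def _first_time_block(qt: QuantTable) -> np.ndarray:
    """Matrix S: each row replaced by its individual's first-time row."""
    t1 = qt.time_levels[0]
    first = qt.design["time"] == t1
    missing = set(qt.design["individual"]) - set(
        qt.design.loc[first, "individual"]
    )
    if missing:
        raise ValueError(
            f"individual(s) missing the first time point: {sorted(missing)[:5]}"
        )
    first_rows = qt.values.loc[first].set_axis(
        qt.design.loc[first, "individual"], axis=0
    )
    S = first_rows.loc[qt.design["individual"]].to_numpy(dtype=float)
    return S


def _noise_sd(M: np.ndarray, noise_factor: float) -> float:
    """sigma_b from sigma_b^2 = noise_factor * (max(M) - min(M))."""
    var = noise_factor * float(M.max() - M.min())
    return float(np.sqrt(max(var, 0.0)))


def erase_time(
    qt: QuantTable,
    noise_factor: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> QuantTable:
    """Null transform for the time effect.

    Every later-time row is replaced by that individual's first-time row;
    iid Gaussian noise with variance noise_factor * range(pre-noise
    matrix) is then added to all rows, and negatives are floored at 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    S = _first_time_block(qt)
    sd = _noise_sd(S, noise_factor)
    noisy = S + rng.normal(0.0, sd, size=S.shape) if sd > 0 else S.copy()
    noisy = np.maximum(noisy, 0.0)
    values = pd.DataFrame(noisy, index=qt.sample_ids, columns=qt.metabolites)
    return qt.with_values(values)


# ---------------------------------------------------------------------
# Effect injection
# ---------------------------------------------------------------------

def _check_levels(mapping: Mapping[str, float], levels: list[str], what: str) -> dict[str, float]:
    m = {str(k): float(v) for k, v in mapping.items()}
    unknown = set(m) - set(levels)
    if unknown:
        raise ValueError(f"unknown {what} key(s) in gamma: {sorted(unknown)}")
    missing = set(levels) - set(m)
    if missing:
        raise ValueError(f"gamma missing {what} level(s): {sorted(missing)}")
    return m


def inject_condition_effect(
    qt: QuantTable,
    target_metabolites: frozenset[str] | set[str],
    gamma_d: Mapping[str, float],
) -> QuantTable:
    """Multiply target-metabolite quantifications by the condition factor.

    X~_ij = X_ij * gamma_{d(i)} for target metabolites j, all rows;
    non-target columns are bit-identical to the input.
    """
    gamma = _check_levels(gamma_d, qt.condition_levels, "condition")
    targets = [m for m in qt.metabolites if m in set(target_metabolites)]
    absent = set(target_metabolites) - set(qt.metabolites)
    if absent:
        raise ValueError(f"target metabolite(s) not quantified: {sorted(absent)[:5]}")
    factors = qt.design["condition"].map(gamma).to_numpy(dtype=float)
    values = qt.values.copy()
    values[targets] = values[targets].to_numpy() * factors[:, None]
    return qt.with_values(values)


def inject_time_effect(
    qt: QuantTable,
    target_metabolites: frozenset[str] | set[str],
    gamma_t: Mapping[str, float],
    noise_factor: float = 0.05,
    seed: int | np.random.Generator = 0,
    nontargets: str = "noise",
) -> QuantTable:
    """Rebuild target metabolites from the first-time block with time factors.

    For target metabolites j: X~_ij = S_ij * gamma_{t(i)} + b_ij, where S
    repeats each individual's first-time row at every time point and b is
    iid Gaussian with variance noise_factor * range(S * gamma) over the
    target columns.  Non-target metabolites are rebuilt as S + same-law
    noise so that only target pathways carry time signal
    (``nontargets="keep"`` leaves them untouched instead).
    """
    if nontargets not in ("noise", "keep"):
        raise ValueError("nontargets must be 'noise' or 'keep'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gamma = _check_levels(gamma_t, qt.time_levels, "time")
    targets = [m for m in qt.metabolites if m in set(target_metabolites)]
    absent = set(target_metabolites) - set(qt.metabolites)
    if absent:
        raise ValueError(f"target metabolite(s) not quantified: {sorted(absent)[:5]}")

    S = _first_time_block(qt)
    t_factors = qt.design["time"].astype(str).map(gamma).to_numpy(dtype=float)
    cols = qt.metabolites.get_indexer(targets)
    scaled = S[:, cols] * t_factors[:, None]
    sd = _noise_sd(scaled, noise_factor)

    new = qt.values.to_numpy(dtype=float).copy()
    new[:, cols] = scaled
    if nontargets == "noise":
        non_cols = np.setdiff1d(np.arange(new.shape[1]), cols)
        new[:, non_cols] = S[:, non_cols]
        noise = rng.normal(0.0, sd, size=new.shape) if sd > 0 else 0.0
        new = new + noise
    else:
        if sd > 0:
            new[:, cols] = scaled + rng.normal(0.0, sd, size=scaled.shape)
    new = np.maximum(new, 0.0)
    values = pd.DataFrame(new, index=qt.sample_ids, columns=qt.metabolites)
    return qt.with_values(values)


# ---------------------------------------------------------------------
# Dataset builders
# ---------------------------------------------------------------------

def _default_gammas(qt: QuantTable, spec: ScenarioSpec) -> tuple[dict, dict]:
    gamma_d = dict(spec.gamma_d) if spec.gamma_d else None
    gamma_t = dict(spec.gamma_t) if spec.gamma_t else None
    if spec.effect in ("condition", "condition_time") and gamma_d is None:
        levels = qt.condition_levels
        gamma_d = {levels[0]: 1.0, **{l: CONDITION_SCENARIOS[1] for l in levels[1:]}}
    if spec.effect in ("time", "condition_time") and gamma_t is None:
        levels = qt.time_levels
        factors = TIME_SCENARIOS[1]
        gamma_t = {l: factors[min(i, len(factors) - 1)] for i, l in enumerate(levels)}
    return gamma_d or {}, gamma_t or {}


def _inject(
    qt: QuantTable,
    targets: frozenset[str],
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> QuantTable:
    gamma_d, gamma_t = _default_gammas(qt, spec)
    out = qt
    if spec.effect in ("time", "condition_time"):
        out = inject_time_effect(
            out, targets, gamma_t, noise_factor=spec.noise_factor, seed=rng
        )
    if spec.effect in ("condition", "condition_time"):
        out = inject_condition_effect(out, targets, gamma_d)
    return out


def make_h0_dataset(qt: QuantTable, spec: ScenarioSpec) -> QuantTable:
    """Null dataset for the requested effect."""
    rng = np.random.default_rng(spec.seed)
    out = qt
    if spec.effect in ("condition", "condition_time"):
        out = permute_condition(out, rng)
    if spec.effect in ("time", "condition_time"):
        out = erase_time(out, noise_factor=spec.noise_factor, seed=rng)
    return out


def make_h1_dataset(
    qt: QuantTable, ps: PathwaySet, spec: ScenarioSpec
) -> tuple[QuantTable, dict]:
    """Inject the effect into k randomly selected pathways.

    Returns the transformed table and a ground-truth record with the
    selected pathway ids and the union of their member metabolites.
    """
    if spec.k > len(ps):
        raise ValueError(f"k={spec.k} exceeds number of pathways ({len(ps)})")
    rng = np.random.default_rng(spec.seed)
    selected = sorted(rng.choice(ps.ids, size=spec.k, replace=False).tolist())
    targets = frozenset().union(*(ps[p] for p in selected)) & frozenset(qt.metabolites)
    out = _inject(qt, targets, spec, rng)
    truth = {
        "mode": "H1",
        "effect": spec.effect,
        "selected_pathways": selected,
        "target_metabolites": sorted(targets),
    }
    return out, truth


def make_vsize_dataset(
    qt: QuantTable, ps: PathwaySet, spec: ScenarioSpec
) -> tuple[QuantTable, dict]:
    """Variable-size design: inject p-tilde members of the largest pathway.

    The largest pathway receives the effect in only ``spec.p_tilde`` of
    its members (drawn at random); k-1 further pathways, drawn from the
    rest, are injected in full with the same process.
    """
    big = ps.largest()
    big_members = sorted(frozenset(ps[big]) & frozenset(qt.metabolites))
    if spec.p_tilde is None or not 1 <= spec.p_tilde <= len(big_members):
        raise ValueError(
            f"p_tilde must be in [1, {len(big_members)}], got {spec.p_tilde}"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = sorted(
        rng.choice(big_members, size=spec.p_tilde, replace=False).tolist()
    )
    others_pool = [p for p in ps.ids if p != big]
    n_others = min(spec.k - 1, len(others_pool))
    others = sorted(rng.choice(others_pool, size=n_others, replace=False).tolist())
    targets = frozenset(chosen)
    if others:
        targets |= frozenset().union(*(ps[p] for p in others)) & frozenset(
            qt.metabolites
        )
    out = _inject(qt, targets, spec, rng)
    truth = {
        "mode": "VSize",
        "effect": spec.effect,
        "p_tilde": spec.p_tilde,
        "vsize_pathway": big,
        "vsize_members": chosen,
        "selected_pathways": [big, *others],
        "target_metabolites": sorted(targets),
    }
    return out, truth
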