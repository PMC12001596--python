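"""Fully synthetic base datasets with realistic pathway structure.

The generator produces a *null* longitudinal metabolomics dataset — no
condition and no time effect — whose structure mimics a small rodent
feces NMR study: ~16 individuals split over 2 conditions, 3 time points,
~120 quantified metabolites, and ~40 overlapping pathways of size 2–32
with mean size ≈ 6 and, over the metabolites that appear in at least one
pathway, mean membership ≈ 4.  (Those two targets are only jointly
satisfiable when part of the metabolite universe lies outside all
pathways, which is exactly what real KEGG annotations look like.)

Quantifications are log-normal: for metabolite j, individual i, time t,

    log X_ijt = mu_j + u_i + c_{i, home(j), t} + e_ijt

with u_i an individual offset shared by all metabolites, c a fluctuation
shared by all metabolites whose *home* pathway is the same (inducing a
within-pathway correlation ``pathway_corr`` on the log scale), and e iid
noise.  A metabolite's home pathway is the first pathway (in sorted id
order) that contains it; metabolites outside all pathways get a private
fluctuation of the same variance so every metabolite has the same
marginal variance.  Exponentiation keeps quantifications positive, and
multiplicative condition effects injected later act additively on the
log scale — matching the model the pathway tests assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PathwaySet, QuantTable


@dataclass
class GeneratorSpec:
    n_individuals: int = 16
    n_conditions: int = 2
    T: int = 3
    n_metabolites: int = 120
    n_pathways: int = 40
    size_range: tuple[int, int] = (2, 32)
    target_mean_size: float = 6.0
    target_mean_membership: float = 4.0
    individual_sd: float = 0.1
    pathway_corr: float = 0.3
    resid_sd: float = 0.25
    baseline_log_mean_range: tuple[float, float] = (0.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.T, self.n_metabolites, self.n_pathways) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.pathway_corr < 1:
            raise ValueError("pathway_corr must be in [0, 1)")
        if self.size_range[0] < 2 or self.size_range[1] < self.size_range[0]:
            raise ValueError("invalid size_range")


def _metabolite_ids(n: int) -> list[str]:
    return [f"met{j + 1:03d}" for j in range(n)]


def generate_pathways(spec: GeneratorSpec) -> PathwaySet:
    """Sample an overlapping pathway membership structure.

    Pathway sizes are drawn around ``target_mean_size`` (one pathway is
    pinned at the maximum size so variable-size experiments have a large
    target), and members are drawn from a restricted pool of metabolites
    sized so that the mean per-covered-metabolite membership lands near
    ``target_mean_membership``.
    """
    lo, hi = spec.size_range
    if hi > spec.n_metabolites:
        raise ValueError("maximum pathway size exceeds metabolite universe")
    if spec.target_mean_membership > spec.n_pathways:
        raise ValueError("mean membership target exceeds number of pathways")
    rng = np.random.default_rng(spec.seed)
    mets = np.array(_metabolite_ids(spec.n_metabolites))

    sizes = np.clip(
        lo + rng.poisson(max(spec.target_mean_size - lo, 0.1), spec.n_pathways),
        lo, hi,
    )
    sizes[0] = hi  # guarantee one maximum-size pathway

    pool_size = int(round(sizes.sum() / spec.target_mean_membership))
    pool_size = min(max(pool_size, hi), spec.n_metabolites)
    pool = rng.choice(mets, size=pool_size, replace=False)

    pathways: dict[str, frozenset[str]] = {}
    # draw with mild preference for already-used metabolites kept uniform:
    # uniform draws from a small pool already create heavy overlap
    for p, size in enumerate(sizes):
        members = rng.choice(pool, size=int(size), replace=False)
        pathways[f"pw{p + 1:03d}"] = frozenset(members.tolist())
    return PathwaySet(pathways)


def home_pathways(ps: PathwaySet, metabolites: list[str]) -> dict[str, str | None]:
    """First pathway (sorted id order) containing each metabolite, or None."""
    homes: dict[str, str | None] = {m: None for m in metabolites}
    for pid in sorted(ps.ids):
        for m in ps[pid]:
            if m in homes and homes[m] is None:
                homes[m] = pid
    return homes


def generate_base(
    spec: GeneratorSpec, ps: PathwaySet | None = None
) -> QuantTable:
    """Generate a null base quantification table.

    If a PathwaySet is given, its membership defines the within-pathway
    correlation groups; otherwise every metabolite gets an independent
    fluctuation (zero within-pathway correlation).
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from pathway draw
    mets = _metabolite_ids(spec.n_metabolites)
    n, T = spec.n_individuals, spec.T

    individuals = [f"ind{i + 1:02d}" for i in range(n)]
    conditions = [
        f"cond{(i * spec.n_conditions) // n + 1}" for i in range(n)
    ]
    times = [f"t{t + 1}" for t in range(T)]

    mu = rng.uniform(*spec.baseline_log_mean_range, size=spec.n_metabolites)
    u = rng.normal(0.0, spec.individual_sd, size=n)

    # shared-fluctuation variance chosen so that the within-group log-scale
    # correlation (sigma_u^2 + sigma_c^2) / (total) equals pathway_corr
    rho = spec.pathway_corr
    s_e2 = spec.resid_sd**2
    s_u2 = spec.individual_sd**2
    s_c2 = max(rho * s_e2 / (1.0 - rho) - s_u2, 0.0) if rho > 0 else 0.0
    s_c = float(np.sqrt(s_c2))

    homes = home_pathways(ps, mets) if ps is not None else {m: None for m in mets}
    group_of: dict[str, int] = {}
    next_group = 0
    group_idx = np.empty(spec.n_metabolites, dtype=int)
    for j, m in enumerate(mets):
        key = homes[m] if homes[m] is not None else f"__solo_{m}"
        if key not in group_of:
            group_of[key] = next_group
            next_group += 1
        group_idx[j] = group_of[key]

    rows = []
    index = []
    design_rows = []
    c_all = rng.normal(0.0, s_c, size=(n, T, next_group))
    for t_i, t in enumerate(times):
        for i, ind in enumerate(individuals):
            e = rng.normal(0.0, spec.resid_sd, size=spec.n_metabolites)
            log_x = mu + u[i] + c_all[i, t_i, group_idx] + e
            rows.append(np.exp(log_x))
            sid = f"{ind}_{t}"
            index.append(sid)
            design_rows.append((sid, ind, t, conditions[i]))
    values = pd.DataFrame(np.asarray(rows), index=index, columns=mets)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "individual", "time", "condition"]
    ).set_index("sample_id")
    return QuantTable(values, design)


def generate_dataset(spec: GeneratorSpec) -> tuple[QuantTable, PathwaySet]:
    """Convenience: pathways plus a correlated base table from one spec."""
    ps = generate_pathways(spec)
    qt = generate_base(spec, ps)
    return qt, ps
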