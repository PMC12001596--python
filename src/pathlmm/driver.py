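"""Pathway-level testing pipeline.

For each pathway: extract a score matrix (PCA or MFA variant), run one
mixed-model likelihood-ratio test per score column and per fixed effect,
aggregate the per-component p-values with the Simes procedure into a
single pathway p-value, and finally BH-adjust across pathways separately
for each effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EffectTestResult, PathwaySet, QuantTable
from .factorize import PathwaySkip, pathway_scores_mfa, pathway_scores_pca
from .lmm import lrt_effect

logger = logging.getLogger(__name__)


@dataclass
class PhoenicsConfig:
    """Configuration of the pathway-testing pipeline.

    ``effects`` defines F, the number of fixed effects, which is also the
    number of principal components retained per pathway.
    """

    method: str = "pca"                       # "pca" | "mfa"
    effects: tuple[str, ...] = ("time", "condition")
    alpha: float = 0.05
    min_pathway_size: int = 2
    mfa_block_var: str = "time"
    mfa_weight: str = "inv_sqrt_lambda1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("pca", "mfa"):
            raise ValueError(f"unknown method '{self.method}'")
        if not self.effects:
            raise ValueError("effects must be nonempty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method == "mfa" and self.mfa_block_var not in self.effects:
            raise ValueError("mfa_block_var must be one of the effects")

    @property
    def F(self) -> int:
        return len(self.effects)


def simes(pvals: np.ndarray | list[float]) -> float:
    """Simes combination: min over j of m * p_(j) / j, clipped to [0, 1].

    Controls the type-I error of the intersection null over the component
    hypotheses under independence or positive dependence.  NA components
    are removed (with m reduced accordingly); an empty vector gives NA.
    """
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        logger.warning("NA component p-values removed before Simes")
        p = p[~np.isnan(p)]
    m = p.size
    if m == 0:
        return np.nan
    p_sorted = np.sort(p)
    ranks = np.arange(1, m + 1)
    return float(min(np.min(m * p_sorted / ranks), 1.0))


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NAs pass through.

    Adjusted values are monotone non-decreasing in the rank of the raw
    p-value and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    scaled = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def phoenics_test(
    qt: QuantTable,
    ps: PathwaySet,
    cfg: PhoenicsConfig | None = None,
) -> tuple[list[EffectTestResult], pd.DataFrame]:
    """Run the full pathway-testing pipeline.

    Returns the per-(pathway, effect) results and a skip report
    (pathway_id, reason) for pathways that could not be scored.  Pathways
    are expected to be pre-filtered to >= 2 quantified metabolites; any
    that degenerate below that at scoring time are skipped and reported.

    When the MFA variant is used with blocks defined by an effect that is
    itself being tested (typically time), the corresponding result rows
    carry ``not_recommended=True``: the partial analyses erase
    between-block differences, so that test has essentially no power.
    """
    cfg = cfg or PhoenicsConfig()
    results_by_effect: dict[str, list[EffectTestResult]] = {
        e: [] for e in cfg.effects
    }
    skipped: list[tuple[str, str]] = []

    for pid in ps.ids:
        members = ps[pid]
        try:
            if cfg.method == "pca":
                block = pathway_scores_pca(qt, members, cfg.F, pathway_id=pid)
            else:
                block = pathway_scores_mfa(
                    qt, members, cfg.F,
                    block_var=cfg.mfa_block_var,
                    pathway_id=pid,
                    weight=cfg.mfa_weight,
                )
        except PathwaySkip as exc:
            logger.warning("skipping pathway %s: %s", pid, exc.reason)
            skipped.append((pid, exc.reason))
            continue

        for effect in cfg.effects:
            comp_p = np.array([
                lrt_effect(block.scores[:, j], qt.design, cfg.effects, effect).pvalue
                for j in range(block.n_components)
            ])
            results_by_effect[effect].append(
                EffectTestResult(
                    pathway_id=pid,
                    effect=effect,
                    component_pvalues=comp_p,
                    simes_p=simes(comp_p),
                    adj_p=np.nan,  # filled after BH below
                    n_components=block.n_components,
                    n_metabolites=len(block.members),
                    not_recommended=(
                        cfg.method == "mfa" and effect == cfg.mfa_block_var
                    ),
                )
            )

    # BH across pathways, separately per effect
    results: list[EffectTestResult] = []
    for effect in cfg.effects:
        rows = results_by_effect[effect]
        adj = bh_adjust([r.simes_p for r in rows])
        for r, a in zip(rows, adj):
            r.adj_p = float(a) if np.isfinite(a) else np.nan
            results.append(r)

    skip_report = pd.DataFrame(skipped, columns=["pathway_id", "reason"])
    return results, skip_report
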