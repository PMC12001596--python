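"""Over-representation analysis (ORA) comparator.

The classical two-step pathway approach: test every metabolite
individually with the same random-intercept mixed model used by the
pathway pipeline, call metabolites significant at ``metab_alpha``
(BH-adjusted by default; raw under null-simulation runs, where BH would
filter out everything), then test each pathway for over-representation
of significant metabolites against a background set with a one-sided
Fisher exact (hypergeometric tail) test, and BH-adjust across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import PathwaySet, QuantTable
from .driver import bh_adjust
from .lmm import lrt_effect

logger = logging.getLogger(__name__)


@dataclass
class OraConfig:
    background: frozenset[str] | None = None  # default: quantified metabolites
    metab_alpha: float = 0.05
    adjust_metabolites: bool = True
    alpha: float = 0.05


def metabolite_tests(
    qt: QuantTable,
    effect: str,
    effects: tuple[str, ...] = ("time", "condition"),
) -> pd.Series:
    """Per-metabolite mixed-model LRT p-values for one fixed effect.

    Constant metabolites get an NA p-value.
    """
    if effect not in effects:
        raise ValueError(f"effect '{effect}' not among {effects}")
    pvals = {}
    vals = qt.values
    for met in qt.metabolites:
        y = vals[met].to_numpy()
        if np.std(y) == 0:
            pvals[met] = np.nan
            continue
        pvals[met] = lrt_effect(y, qt.design, effects, effect).pvalue
    return pd.Series(pvals, name=f"p_{effect}")


def fisher_ora(
    significant: frozenset[str] | set[str],
    pathway: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
) -> float:
    """One-sided over-representation p-value.

    Hypergeometric upper tail P(X >= |significant ∩ pathway|) drawing
    n = |pathway| from a background of N metabolites of which
    K = |significant| are significant.
    """
    if not background:
        raise ValueError("empty background set")
    if not set(pathway) <= set(background):
        raise ValueError("pathway not contained in background")
    if not set(significant) <= set(background):
        raise ValueError("significant set not contained in background")
    N = len(background)
    K = len(set(significant))
    n = len(set(pathway))
    x = len(set(significant) & set(pathway))
    # sf(x-1) = P(X >= x)
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def ora_test(
    qt: QuantTable,
    ps: PathwaySet,
    effect: str,
    cfg: OraConfig | None = None,
    effects: tuple[str, ...] = ("time", "condition"),
    metabolite_pvalues: pd.Series | None = None,
) -> pd.DataFrame:
    """Pathway-level ORA for one effect.

    Returns a frame with per-pathway Fisher p (``fisher_p``), BH-adjusted
    value across pathways (``adj_p``), the fraction of individually
    significant member metabolites, and the significance call at
    ``cfg.alpha``.  ``metabolite_pvalues`` can be supplied to reuse
    per-metabolite tests across calls.
    """
    cfg = cfg or OraConfig()
    if metabolite_pvalues is None:
        metabolite_pvalues = metabolite_tests(qt, effect, effects)
    pv = metabolite_pvalues.dropna()
    if cfg.adjust_metabolites:
        adj = pd.Series(bh_adjust(pv.to_numpy()), index=pv.index)
    else:
        adj = pv
    significant = frozenset(adj.index[adj < cfg.metab_alpha])

    background = cfg.background or frozenset(qt.metabolites)
    # metabolites with NA p carry no call: exclude from both sets
    na_mets = frozenset(metabolite_pvalues.index[metabolite_pvalues.isna()])
    background = frozenset(background) - na_mets

    rows = []
    for pid in ps.ids:
        members = frozenset(ps[pid]) & background
        p = fisher_ora(significant & background, members, background)
        frac = len(members & significant) / len(members) if members else np.nan
        rows.append({
            "pathway_id": pid,
            "effect": effect,
            "n_metabolites": len(members),
            "fisher_p": p,
            "pct_significant_metabolites": 100.0 * frac,
        })
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["fisher_p"].to_numpy())
    out["significant"] = out["adj_p"] < cfg.alpha
    return out
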