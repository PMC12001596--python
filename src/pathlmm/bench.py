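"""Replicated simulation benchmarks: type-I error, power, variable-size power.

These routines wire together the synthetic generator, the semi-synthetic
transforms, the pathway tests and the evaluation metrics into the three
standard experiments: positive rate under the null (type-I error), the
sensitivity under effect injection (power), and detection of the largest
pathway as a function of how many of its members are differential.

Conventions, fixed across the package: type-I experiments threshold the
*raw* pathway p-values (Simes p for the factor-score methods, Fisher p
with raw metabolite p-values for ORA) at the nominal level, because BH
under a global null filters out everything; power experiments threshold
the BH-adjusted values.  Replicate r of an experiment with base seed s
uses seed s + r everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .data import PathwaySet, QuantTable, filter_pathways, results_to_frame
from .driver import PhoenicsConfig, phoenics_test
from .evaluate import EvalReport, categorize, confusion
from .ora import OraConfig, ora_test
from .simulate import ScenarioSpec, make_h0_dataset, make_h1_dataset, make_vsize_dataset
from .synthgen import GeneratorSpec, generate_dataset

logger = logging.getLogger(__name__)

METHODS = ("pca", "mfa", "ora")


def _raw_pvalues(
    qt: QuantTable, ps: PathwaySet, effect: str, method: str
) -> pd.Series:
    """Raw pathway p-values for one method and effect."""
    if method in ("pca", "mfa"):
        cfg = PhoenicsConfig(method=method)
        results, _ = phoenics_test(qt, ps, cfg)
        frame = results_to_frame(results)
        sub = frame[frame["effect"] == effect]
        return sub.set_index("pathway_id")["simes_p"]
    if method == "ora":
        out = ora_test(
            qt, ps, effect, OraConfig(adjust_metabolites=False)
        )
        return out.set_index("pathway_id")["fisher_p"]
    raise ValueError(f"unknown method '{method}'")


def _adjusted_pvalues(
    qt: QuantTable, ps: PathwaySet, effect: str, method: str
) -> pd.DataFrame:
    """Per-pathway BH-adjusted p-values (column 'adj_p')."""
    if method in ("pca", "mfa"):
        cfg = PhoenicsConfig(method=method)
        results, _ = phoenics_test(qt, ps, cfg)
        frame = results_to_frame(results)
        return frame[frame["effect"] == effect][["pathway_id", "adj_p"]]
    if method == "ora":
        out = ora_test(qt, ps, effect, OraConfig(adjust_metabolites=True))
        return out[["pathway_id", "adj_p"]]
    raise ValueError(f"unknown method '{method}'")


def h0_positive_rates(
    effect: str,
    methods: tuple[str, ...] = METHODS,
    n_reps: int = 20,
    base_seed: int = 1,
    alpha: float = 0.05,
    gen_spec: GeneratorSpec | None = None,
    noise_factor: float = 0.05,
) -> dict[str, list[float]]:
    """Per-replicate fraction of raw pathway p-values below ``alpha``
    under the null transform for ``effect``.

    Each replicate draws a fresh synthetic base (seed = base_seed + r),
    erases the tested effect, and runs every requested method.
    """
    rates: dict[str, list[float]] = {m: [] for m in methods}
    for r in range(n_reps):
        seed = base_seed + r
        spec = replace(gen_spec or GeneratorSpec(), seed=seed)
        qt, ps = generate_dataset(spec)
        ps = filter_pathways(ps, qt)
        null_qt = make_h0_dataset(
            qt,
            ScenarioSpec(
                effect=effect, mode="H0", seed=seed, noise_factor=noise_factor
            ),
        )
        for method in methods:
            pv = _raw_pvalues(null_qt, ps, effect, method).dropna()
            rates[method].append(float((pv < alpha).mean()))
    return rates


def h1_confusion(
    scenario: ScenarioSpec,
    method: str,
    n_reps: int = 20,
    base_seed: int = 1,
    alpha: float = 0.05,
    gen_spec: GeneratorSpec | None = None,
) -> EvalReport:
    """Summed confusion counts over replicated effect-injection runs.

    Counts are accumulated over replicates and PPV/sensitivity are then
    computed on the totals.
    """
    total = EvalReport()
    test_effect = {
        "condition": "condition", "time": "time", "condition_time": "condition",
    }[scenario.effect]
    for r in range(n_reps):
        seed = base_seed + r
        spec = replace(gen_spec or GeneratorSpec(), seed=seed)
        qt, ps = generate_dataset(spec)
        ps = filter_pathways(ps, qt)
        h1_qt, truth_rec = make_h1_dataset(
            qt, ps, replace(scenario, seed=seed)
        )
        truth = categorize(
            ps, truth_rec["selected_pathways"], truth_rec["target_metabolites"]
        )
        frame = _adjusted_pvalues(h1_qt, ps, test_effect, method)
        total = total + confusion(frame, truth, alpha=alpha)
    return total


def vsize_detection_rate(
    p_tilde: int,
    scenario: ScenarioSpec,
    method: str = "pca",
    n_reps: int = 10,
    base_seed: int = 1,
    alpha: float = 0.05,
    gen_spec: GeneratorSpec | None = None,
) -> float:
    """Fraction of replicates in which the largest pathway is detected
    (BH-adjusted p < alpha) when only ``p_tilde`` of its members carry
    the injected effect.
    """
    hits = 0
    test_effect = "condition" if scenario.effect != "time" else "time"
    for r in range(n_reps):
        seed = base_seed + r
        spec = replace(gen_spec or GeneratorSpec(), seed=seed)
        qt, ps = generate_dataset(spec)
        ps = filter_pathways(ps, qt)
        vs_qt, truth_rec = make_vsize_dataset(
            qt, ps, replace(scenario, mode="VSize", p_tilde=p_tilde, seed=seed)
        )
        frame = _adjusted_pvalues(vs_qt, ps, test_effect, method)
        row = frame[frame["pathway_id"] == truth_rec["vsize_pathway"]]
        if len(row) and np.isfinite(row["adj_p"].iloc[0]):
            hits += int(row["adj_p"].iloc[0] < alpha)
    return hits / n_reps


def null_base_positive_rates(
    methods: tuple[str, ...] = ("pca",),
    effects: tuple[str, ...] = ("time", "condition"),
    n_reps: int = 20,
    base_seed: int = 1,
    alpha: float = 0.05,
    gen_spec: GeneratorSpec | None = None,
) -> dict[tuple[str, str], list[float]]:
    """Raw positive rates on the *untransformed* null base, per
    (method, effect) — the generator's own calibration check."""
    rates: dict[tuple[str, str], list[float]] = {
        (m, e): [] for m in methods for e in effects
    }
    for r in range(n_reps):
        seed = base_seed + r
        spec = replace(gen_spec or GeneratorSpec(), seed=seed)
        qt, ps = generate_dataset(spec)
        ps = filter_pathways(ps, qt)
        for method in methods:
            for effect in effects:
                pv = _raw_pvalues(qt, ps, effect, method).dropna()
                rates[(method, effect)].append(float((pv < alpha).mean()))
    return rates
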