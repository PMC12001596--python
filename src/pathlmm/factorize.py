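"""Per-pathway dimension reduction: global PCA and the MFA partial-PCA variant.

For each pathway the quantification submatrix Z_l (observations × member
metabolites) is standardized and reduced to a small score matrix A_l whose
columns feed the mixed models.  Two reductions are available:

* ``pca`` — one PCA on the full Z_l; the scores of the first m* components
  are kept.
* ``mfa`` — the first step of Multiple Factor Analysis: Z_l is split into
  one block per time point, each block gets its own PCA, each block's
  scores are divided by the square root of the block's first eigenvalue
  (so every block contributes comparably), and the weighted block scores
  are stacked back in observation order.  Because each block is analyzed
  independently, between-time mean differences are erased, which is why
  this variant should not be used to test the effect that defines the
  blocks.

m* defaults to the number of fixed effects F, capped by the number of
usable metabolites in the pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import QuantTable

logger = logging.getLogger(__name__)


class PathwaySkip(Exception):
    """A pathway cannot be scored (too few usable metabolites, degenerate block)."""

    def __init__(self, pathway_id: str, reason: str):
        self.pathway_id = pathway_id
        self.reason = reason
        super().__init__(f"{pathway_id}: {reason}")


@dataclass
class ScoreBlock:
    """Score matrix A_l for one pathway, row-aligned to the QuantTable."""

    pathway_id: str
    scores: np.ndarray          # (N_obs, m*)
    eigenvalues: np.ndarray     # descending, nonnegative
    loadings: np.ndarray        # (|members|, m*), unit-norm columns
    method: str                 # "pca" | "mfa"
    members: list[str]
    block_weights: np.ndarray | None = None  # (T,) for mfa

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def standardize_columns(
    Z: np.ndarray, center: bool = True, scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; return (standardized, zero-variance mask).

    Standard deviations use ddof=1.  Zero-variance columns are left
    centered-only and flagged; the caller drops them before PCA.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    out = Z.copy()
    if center:
        out = out - out.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    zero_var = sd == 0
    if scale:
        nz = ~zero_var
        out[:, nz] = out[:, nz] / sd[nz]
    return out, zero_var


def _svd_pca(Z: np.ndarray, n_comp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a column-standardized matrix via SVD.

    Returns (scores, eigenvalues, loadings) with var(scores_j) ==
    eigenvalue_j (ddof=1) and a deterministic sign convention: each
    loading column is flipped so its largest-magnitude entry is positive.
    """
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_comp > rank:
        logger.warning(
            "requested %d components but rank is %d; truncating", n_comp, rank
        )
        n_comp = max(rank, 1)
    loadings = Vt[:n_comp].T
    scores = U[:, :n_comp] * s[:n_comp]
    # sign convention: largest-|.| loading entry positive
    for j in range(n_comp):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, eig[:n_comp], loadings


def pca_scores(
    Z: np.ndarray, n_comp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-``n_comp`` principal-component scores of a standardized matrix."""
    Z = np.asarray(Z, dtype=float)
    if n_comp > min(Z.shape[0] - 1, Z.shape[1]):
        raise ValueError("n_comp exceeds min(rows - 1, cols)")
    return _svd_pca(Z, n_comp)


def _usable_submatrix(
    qt: QuantTable, pathway: frozenset[str] | set[str], pathway_id: str
) -> tuple[np.ndarray, list[str]]:
    members = sorted(m for m in pathway if m in qt.metabolites)
    if len(members) < 2:
        raise PathwaySkip(pathway_id, "fewer than 2 quantified metabolites")
    Z = qt.values[members].to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise PathwaySkip(
            pathway_id, "fewer than 2 non-constant quantified metabolites"
        )
    if not keep.all():
        dropped = [m for m, k in zip(members, keep) if not k]
        logger.warning(
            "pathway %s: dropping zero-variance metabolite(s) %s",
            pathway_id, dropped,
        )
        members = [m for m, k in zip(members, keep) if k]
        Z = Z[:, keep]
    return Z, members


def pathway_scores_pca(
    qt: QuantTable,
    pathway: frozenset[str] | set[str],
    F: int,
    pathway_id: str = "",
) -> ScoreBlock:
    """Global-PCA score block: m* = min(F, #usable metabolites) components."""
    Z, members = _usable_submatrix(qt, pathway, pathway_id)
    Zs, _ = standardize_columns(Z)
    m_star = min(F, len(members), Z.shape[0] - 1)
    scores, eig, load = pca_scores(Zs, m_star)
    return ScoreBlock(pathway_id, scores, eig, load, "pca", members)


def pathway_scores_mfa(
    qt: QuantTable,
    pathway: frozenset[str] | set[str],
    F: int,
    block_var: str = "time",
    pathway_id: str = "",
    weight: str = "inv_sqrt_lambda1",
) -> ScoreBlock:
    """MFA partial-PCA score block with per-time-point blocks.

    Each block is standardized and analyzed on its own; block scores are
    rescaled by the block weight (1/sqrt(lambda1) by default, 1/lambda1
    with ``weight="inv_lambda1"``) and sign-aligned to the global-PCA
    loadings before stacking, since PCA signs are arbitrary per block.
    """
    if weight not in ("inv_sqrt_lambda1", "inv_lambda1"):
        raise ValueError(f"unknown MFA weight '{weight}'")
    Z, members = _usable_submatrix(qt, pathway, pathway_id)
    blocks = qt.design[block_var]
    if isinstance(blocks.dtype, pd.CategoricalDtype):
        levels = [l for l in blocks.cat.categories if (blocks == l).any()]
    else:
        levels = sorted(blocks.unique())
    if len(levels) < 1:
        raise PathwaySkip(pathway_id, f"no levels in block variable {block_var}")

    # reference loadings from the global PCA for cross-block sign alignment
    Zs_global, _ = standardize_columns(Z)
    min_block = min(int((blocks == l).sum()) for l in levels)
    if min_block < 3:
        raise PathwaySkip(
            pathway_id, f"block too small ({min_block} rows) in {block_var}"
        )
    m_star = min(F, len(members), min_block - 1)
    _, _, ref_load = pca_scores(Zs_global, m_star)
    m_star = ref_load.shape[1]

    N = Z.shape[0]
    stacked = np.full((N, m_star), np.nan)
    weights = np.empty(len(levels))
    first_eigs = []
    for b, level in enumerate(levels):
        mask = (blocks == level).to_numpy()
        Zb = Z[mask]
        sd = Zb.std(axis=0, ddof=1)
        if (sd == 0).any():
            # constant within this block only: keep the column centered,
            # unscaled, to avoid 0/0; it contributes nothing to variance
            Zb_s = Zb - Zb.mean(axis=0)
            nz = sd > 0
            Zb_s[:, nz] = Zb_s[:, nz] / sd[nz]
        else:
            Zb_s, _ = standardize_columns(Zb)
        k = min(m_star, Zb.shape[0] - 1, Zb.shape[1])
        sc, eig, load = _svd_pca(Zb_s, k)
        if eig[0] <= 0:
            raise PathwaySkip(
                pathway_id, f"zero first eigenvalue in block {level}"
            )
        if sc.shape[1] < m_star:
            raise PathwaySkip(
                pathway_id, f"rank-deficient block {level}"
            )
        w = eig[0] ** -0.5 if weight == "inv_sqrt_lambda1" else 1.0 / eig[0]
        first_eigs.append(eig[0])
        weights[b] = w
        # align each partial component with the global loading direction
        for j in range(m_star):
            if float(load[:, j] @ ref_load[:, j]) < 0:
                sc[:, j] = -sc[:, j]
                load[:, j] = -load[:, j]
        stacked[mask] = sc * w
    eig_out = np.asarray(first_eigs, dtype=float)
    return ScoreBlock(
        pathway_id, stacked, eig_out, ref_load, "mfa", members,
        block_weights=weights,
    )
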