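"""Association statistics between binary presence/absence vectors.

Genome-genome and trait-trait similarity is the phi coefficient (Pearson r
on dichotomous variables).  Significance of a pair uses the identity
chi2 = n * phi^2 with one degree of freedom, corrected for multiple testing
with Benjamini-Hochberg.  For trait clustering, negative correlations are
thresholded to zero so clustering is driven by positive association only,
and non-significant pairs (adjusted p >= alpha) are zeroed as well.
Genome similarities are passed through unthresholded; negative genome
pairs are legal and merely counted in the provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import TraitMatrix, ValidationError

__all__ = [
    "phi",
    "pair_significance",
    "bh_adjust",
    "phi_matrix",
    "SimilarityMatrix",
    "build_similarity",
]


def _counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return n11, n10, n01, n00


def phi(x: Sequence[int], y: Sequence[int]) -> float:
    """Phi coefficient of two binary vectors.

    ``(n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)``; returns 0.0 when
    any margin is zero (degenerate table, see :func:`pair_significance`).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("phi needs vectors of length >= 2")
    n11, n10, n01, n00 = _counts(x, y)
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def pair_significance(x: Sequence[int], y: Sequence[int]) -> tuple[float, float, float]:
    """(phi, chi-square, p) for one pair; chi2 = n * phi^2, df = 1.

    Degenerate margins yield (0, 0, 1).  No continuity correction is
    applied, preserving the n*phi^2 identity.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    r = phi(x, y)
    n11, n10, n01, n00 = _counts(x, y)
    if min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0:
        return 0.0, 0.0, 1.0
    chi2 = x.size * r * r
    return r, chi2, float(stats.chi2.sf(chi2, df=1))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def phi_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise phi over the columns of a binary matrix (Pearson r)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values.astype(float), rowvar=False)
    return np.atleast_2d(r)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over genomes or traits.

    ``values`` holds the similarities actually fed to clustering (after any
    thresholding); ``raw`` keeps the unthresholded phi matrix so summaries
    such as mean within-cluster r stay meaningful.  ``pairs`` is the long
    table of tested pairs with phi, chi2, p and adjusted p.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    raw: np.ndarray | None = None
    pairs: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)


def _drop_constant(values: np.ndarray, ids: list[str], what: str) -> tuple[np.ndarray, list[str]]:
    keep = values.std(axis=0) > 0
    if not keep.all():
        dropped = [i for i, k in zip(ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant {what}(s) before correlation: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            UserWarning,
        )
    return values[:, keep], [i for i, k in zip(ids, keep) if k]


def build_similarity(
    matrix: TraitMatrix,
    kind: str,
    alpha: float = 0.05,
    fdr_family: str = "positive",
) -> SimilarityMatrix:
    """Build the genome or trait similarity matrix from a trait matrix.

    kind="trait"
        Phi over trait columns; negative pairs zeroed; remaining pairs
        chi-square tested and BH-adjusted over the upper triangle, pairs
        with adjusted p >= alpha zeroed.  ``fdr_family`` chooses whether
        the BH family is the positive pairs only (default) or all pairs
        ("all", adjusted before sign-thresholding).
    kind="genome"
        Phi over genome rows, no thresholding; the number of negative
        entries is recorded in provenance.
    """
    if kind not in ("genome", "trait"):
        raise ValidationError(f"kind must be 'genome' or 'trait', got {kind!r}")
    if fdr_family not in ("positive", "all"):
        raise ValidationError("fdr_family must be 'positive' or 'all'")
    if kind == "genome":
        data = matrix.values.T  # columns become genomes
        ids = list(matrix.genomes)
        what = "genome"
    else:
        data = matrix.values
        ids = list(matrix.traits)
        what = "trait"
    if len(ids) < 2:
        raise ValidationError("need >= 2 items to correlate")
    data, ids = _drop_constant(data, ids, what)
    if len(ids) < 2:
        raise ValidationError("fewer than 2 non-constant items remain")

    n_obs = data.shape[0]
    raw = phi_matrix(data)
    np.fill_diagonal(raw, np.nan)  # preference set later by clustering

    if kind == "genome":
        values = raw.copy()
        return SimilarityMatrix(
            ids=ids, values=values, kind=kind, raw=raw,
            provenance={
                "alpha": None,
                "thresholding": "none",
                "n_negative_pairs": int((raw[np.triu_indices(len(ids), 1)] < 0).sum()),
            },
        )

    iu, ju = np.triu_indices(len(ids), 1)
    r = raw[iu, ju]
    chi2 = n_obs * r * r
    p = stats.chi2.sf(chi2, df=1)

    if fdr_family == "positive":
        family = r > 0
    else:
        family = np.ones_like(r, dtype=bool)
    p_adj = np.full_like(p, np.nan)
    if family.any():
        p_adj[family] = bh_adjust(p[family])
    retained = family & (r > 0) & (p_adj < alpha)

    values = np.zeros_like(raw)
    values[iu[retained], ju[retained]] = r[retained]
    values += values.T
    np.fill_diagonal(values, np.nan)

    pairs = pd.DataFrame(
        {
            "item_a": np.asarray(ids)[iu],
            "item_b": np.asarray(ids)[ju],
            "phi": r,
            "chi2": chi2,
            "p": p,
            "p_adj": p_adj,
            "retained": retained,
        }
    )
    return SimilarityMatrix(
        ids=ids, values=values, kind=kind, raw=raw, pairs=pairs,
        provenance={
            "alpha": alpha,
            "thresholding": f"negatives zeroed; FDR family={fdr_family}",
            "n_retained_pairs": int(retained.sum()),
            "n_tested_pairs": int(family.sum()),
        },
    )
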