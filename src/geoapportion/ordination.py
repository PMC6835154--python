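"""Redundancy analysis: constrained ordination of community composition.

The community matrix is transformed (Hellinger by default), column
centered, regressed on standardized constraints, and the fitted values
eigendecomposed. The constrained variance percentage is the trace ratio
of fitted to total community variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSFORMS = ("hellinger", "proportion", "none")


class CollinearityError(ValueError):
    """Constraint matrix is rank-deficient after centering."""


@dataclass
class RdaResult:
    """Outcome of a redundancy analysis.

    ``otu_loadings`` are correlations of (transformed, centered) OTU
    columns with the site scores on each constrained axis, not raw
    eigenvector weights.
    """

    constrained_variance_pct: float
    axis_eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    otu_loadings: pd.DataFrame
    constraint_names: tuple[str, ...]
    transform: str

    def __post_init__(self) -> None:
        if not -1e-9 <= self.constrained_variance_pct <= 100 + 1e-9:
            raise ValueError("constrained variance percent out of [0, 100]")


def _transform_community(community: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}, got {transform!r}")
    if transform == "none":
        return community.astype(float)
    if (community.values < 0).any():
        raise ValueError("community counts must be non-negative")
    totals = community.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("samples with zero total reads cannot be transformed")
    rel = community.div(totals, axis=0)
    if transform == "hellinger":
        return np.sqrt(rel)
    return rel


def rda(
    community: pd.DataFrame,
    constraints: pd.DataFrame,
    transform: str = "hellinger",
) -> RdaResult:
    """Constrained ordination of ``community`` (samples x OTUs) on ``constraints``.

    Constraints are standardized to zero mean and unit variance so
    differently scaled variables are commensurable. Constant OTU columns
    are dropped with a warning; a rank-deficient constraint matrix raises
    :class:`CollinearityError`.
    """
    if not community.index.equals(constraints.index):
        constraints = constraints.loc[community.index]
    n, k = constraints.shape
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {n}")

    Yt = _transform_community(community, transform)
    const_cols = Yt.columns[Yt.std(axis=0, ddof=0) == 0]
    if len(const_cols):
        warnings.warn(f"dropping constant OTU columns: {list(const_cols)}", stacklevel=2)
        Yt = Yt.drop(columns=const_cols)
    Y = Yt.values - Yt.values.mean(axis=0)

    Xraw = constraints.values.astype(float)
    Xc = Xraw - Xraw.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [constraints.columns[i] for i in np.flatnonzero(sd == 0)]
        raise CollinearityError(f"constant constraints: {bad}")
    X = Xc / sd
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError("constraints are collinear after centering")

    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ coef

    # SVD of the fitted matrix yields the constrained axes directly
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = S**2 / (n - 1)
    keep = eig > max(eig[0], 1.0) * 1e-12 if eig.size else np.array([], dtype=bool)
    keep &= np.arange(eig.size) < k
    eig = eig[keep]
    n_axes = int(keep.sum())

    scores = (U[:, keep] * S[keep])  # sample scores on constrained axes
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    site_scores = pd.DataFrame(scores, index=community.index, columns=axes)

    # loadings = correlation of each OTU column with each axis score
    loadings = np.zeros((Y.shape[1], n_axes))
    y_sd = Y.std(axis=0, ddof=0)
    for a in range(n_axes):
        s = scores[:, a]
        s_sd = s.std(ddof=0)
        cov = (Y * (s - s.mean())[:, None]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings[:, a] = np.where(y_sd > 0, cov / (y_sd * s_sd), 0.0)
    otu_loadings = pd.DataFrame(loadings, index=Yt.columns, columns=axes)

    total_var = float((Y**2).sum())
    fitted_var = float((Yhat**2).sum())
    pct = 100.0 * fitted_var / total_var if total_var > 0 else 0.0

    return RdaResult(
        constrained_variance_pct=min(pct, 100.0),
        axis_eigenvalues=eig,
        site_scores=site_scores,
        otu_loadings=otu_loadings,
        constraint_names=tuple(constraints.columns),
        transform=transform,
    )


def top_loadings(result: RdaResult, n: int = 10, axis: int = 1) -> pd.Series:
    """The ``n`` OTUs with the strongest absolute loading on one axis.

    Returns signed loadings, ranked by |loading| descending with ties
    broken by OTU id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= axis <= result.otu_loadings.shape[1]:
        raise ValueError(f"axis {axis} out of range (1..{result.otu_loadings.shape[1]})")
    col = result.otu_loadings.iloc[:, axis - 1]
    order = sorted(col.index, key=lambda o: (-abs(col[o]), str(o)))
    return col.loc[order[: min(n, len(order))]]
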