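"""COVID-exposure scores via principal component analysis.

Three exposure dimensions are summarized, each from its own item block:
susceptibility (how badly infection would hit: age, five comorbidity flags,
self-rated poor health), vulnerability (the likelihood of getting infected:
factors preventing full quarantine compliance) and behavioural response
(contacting doctors or authorities, seeking a test). Items are standardized,
the correlation matrix is eigendecomposed, components with eigenvalue above
one are retained (Kaiser criterion), and the first component — oriented so it
increases with exposure — is min-max rescaled onto [0.25, 1] to be comparable
with the stress index. Sampling adequacy is assessed with the
Kaiser-Meyer-Olkin statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BEHAVIOUR_COLUMNS, COMORBIDITY_COLUMNS, VULNERABILITY_COLUMNS

#: Default item blocks per dimension, with the anchor item whose first-component
#: loading is constrained positive (fixing the "increasing in exposure" sign).
ITEM_BLOCKS: dict[str, tuple[str, ...]] = {
    "susceptibility": ("age",) + COMORBIDITY_COLUMNS + ("poor_health",),
    "vulnerability": VULNERABILITY_COLUMNS,
    "behaviour": BEHAVIOUR_COLUMNS,
}

ANCHOR_ITEMS: dict[str, str] = {
    "susceptibility": "poor_health",
    "vulnerability": "vuln_work",
    "behaviour": "sought_test",
}


class AdequacyError(ValueError):
    """Raised when the item correlation matrix is unusable (e.g. singular)."""


@dataclass
class ExposureScore:
    dimension: str
    scores: pd.Series  # per respondent, on [0.25, 1]
    kmo: float
    eigenvalues: np.ndarray  # descending; sums to the number of items
    variance_explained: float  # of component 1
    loadings: pd.Series  # first eigenvector
    n_retained: int  # components with eigenvalue > 1
    weak_first_component: bool  # first eigenvalue <= 1


def _correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise AdequacyError("constant item column; remove it before PCA")
    return np.corrcoef(X, rowvar=False)


def kmo_statistic(items: pd.DataFrame | np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal pairs,
    where r are raw correlations and q are anti-image partial correlations
    obtained from the inverse correlation matrix
    (q_ij = -s_ij / sqrt(s_ii s_jj) with S = R^-1). Values near 1 indicate the
    items share enough common variance for factor/PCA summarization.
    """
    X = np.asarray(items, dtype=float)
    if X.shape[1] < 3:
        raise AdequacyError("KMO needs at least three variables")
    R = _correlation(X)
    if np.linalg.cond(R) > 1e10:
        raise AdequacyError(
            "correlation matrix is singular or near-singular; "
            "remove redundant variables"
        )
    S = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    Q = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def pca_exposure_score(
    items: pd.DataFrame, dimension: str, anchor: str | None = None
) -> ExposureScore:
    """First-principal-component exposure score on the [0.25, 1] scale.

    PCA is run on the item correlation matrix (items standardized), so the
    score is invariant, up to its final rescaling, to affine changes of any
    item's units. The first eigenvector is oriented so the anchor item loads
    positively, and the resulting linear combination is min-max rescaled to
    [0.25, 1] over the sample.
    """
    cols = list(items.columns)
    X = items.dropna().to_numpy(dtype=float)
    R = _correlation(X)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    v1 = eigvec[:, 0]
    anchor = anchor or ANCHOR_ITEMS.get(dimension, cols[0])
    a = cols.index(anchor)
    pivot = v1[a] if v1[a] != 0 else v1[np.argmax(np.abs(v1))]
    if pivot < 0:
        v1 = -v1
    n_retained = int(np.sum(eigval > 1.0))
    weak = bool(eigval[0] <= 1.0)
    if weak:
        warnings.warn(
            f"{dimension}: first eigenvalue {eigval[0]:.3f} <= 1; "
            "score produced from component 1 anyway",
            stacklevel=2,
        )
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    raw = Z @ v1
    lo, hi = raw.min(), raw.max()
    scaled = 0.25 + 0.75 * (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.25)
    try:
        kmo = kmo_statistic(X)
    except AdequacyError:
        # degenerate (e.g. rank-1) correlation matrix: PCA is still defined
        kmo = float("nan")
    return ExposureScore(
        dimension=dimension,
        scores=pd.Series(scaled, index=items.dropna().index, name=f"{dimension}_score"),
        kmo=kmo,
        eigenvalues=eigval,
        variance_explained=float(eigval[0] / len(cols)),
        loadings=pd.Series(v1, index=cols, name="loading"),
        n_retained=n_retained,
        weak_first_component=weak,
    )


def score_all(data: pd.DataFrame) -> dict[str, ExposureScore]:
    """Score the three exposure dimensions from their default item blocks."""
    return {
        dim: pca_exposure_score(data.loc[:, list(cols)], dim)
        for dim, cols in ITEM_BLOCKS.items()
    }
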