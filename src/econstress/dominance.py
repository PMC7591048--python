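"""Empirical-CDF comparison and first-order stochastic dominance.

All four indices (predicted stress and the three exposure scores) live on
[0.25, 1], so their distributions can be compared directly: index A
first-order stochastically dominates (FOSD) index B when
F_A(x) <= F_B(x) for every x — A puts at least as much mass on high values
everywhere. The check is descriptive (no inferential test): both empirical
CDFs are step functions, so the supremum of F_A - F_B is attained on the
union of the two samples' jump points, which is the evaluation grid used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmptySampleError(ValueError):
    pass


class ECDF:
    """Right-continuous empirical CDF: F(x) = (# values <= x) / n."""

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise EmptySampleError("ECDF needs at least one value")
        self._sorted = np.sort(arr)
        self.n = arr.size

    def __call__(self, x):
        return np.searchsorted(self._sorted, x, side="right") / self.n


def ecdf(values) -> ECDF:
    """Build the empirical CDF step function for a sample."""
    return ECDF(values)


@dataclass(frozen=True)
class DominanceResult:
    pair: tuple[str, str]
    holds: bool  # a FOSD b within tolerance eps
    max_violation: float  # largest positive excess of F_a over F_b on the grid
    eps: float
    grid: np.ndarray


def fosd_check(
    a_values,
    b_values,
    eps: float = 0.01,
    grid=None,
    names: tuple[str, str] = ("a", "b"),
) -> DominanceResult:
    """Does sample ``a`` first-order stochastically dominate sample ``b``?

    Evaluates F_a - F_b on the union of both samples' points (plus any extra
    grid supplied) and reports the largest positive excess; dominance holds
    when F_a(x) <= F_b(x) + eps everywhere. The small tolerance eps lets
    near-coincident CDFs count as weak dominance, with the actual excess
    recorded in ``max_violation``.
    """
    F_a, F_b = ecdf(a_values), ecdf(b_values)
    pts = np.concatenate([F_a._sorted, F_b._sorted])
    if grid is not None:
        pts = np.concatenate([pts, np.asarray(grid, dtype=float)])
    pts = np.unique(pts)
    diff = F_a(pts) - F_b(pts)
    max_violation = float(max(0.0, diff.max()))
    return DominanceResult(
        pair=names,
        holds=bool(max_violation <= eps),
        max_violation=max_violation,
        eps=eps,
        grid=pts,
    )


def plot_cdfs(samples: dict[str, np.ndarray], path=None):
    """Overlay the empirical CDFs of the named index samples.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, values in samples.items():
        F = ecdf(values)
        grid = np.linspace(0.2, 1.0, 400)
        ax.plot(grid, F(grid), label=name, drawstyle="steps-post")
    ax.set_xlabel("index value x")
    ax.set_ylabel("P(index ≤ x)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
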