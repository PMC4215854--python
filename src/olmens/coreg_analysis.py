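"""Conductance co-regulation analysis.

Implements clutter-based dimension reordering (CBDR): the grid of models is
rendered as a nested two-dimensional "dimensional stack" image of distance
values, and the parameter ordering minimizing image clutter (sum of
squared adjacent-pixel differences; the squared form is needed so that
smooth additive structure scores lower than fragmented layouts) is
sought.  Parameters early in the
optimal ordering (outermost blocks) are those to which the distance is most
sensitive ("high-order").  Pairwise conductance histograms over a retained
subset are then classified as no-interaction, local preference, or
co-regulation; a quantitative ridge score (count-weighted rank correlation
between the two parameters' grid levels) backs the classification so the
outcome is assertable rather than purely visual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StackOrder", "ConductanceHistogram", "InteractionResult",
    "stack_image", "clutter_score", "cbdr_order", "conductance_histogram",
    "classify_interaction", "coreg_screen",
    "RIDGE_THRESHOLD", "PEAK_THRESHOLD",
]

RIDGE_THRESHOLD = 0.4   # |weighted rank correlation| for co-regulation
PEAK_THRESHOLD = 2.0    # dominant-cell share relative to uniform


@dataclass(frozen=True)
class StackOrder:
    """Parameter ordering (highest-order first) with its clutter score."""

    order: tuple[str, ...]
    clutter: float


@dataclass
class ConductanceHistogram:
    """2-D count matrix of subset members over a parameter pair's levels."""

    param_a: str
    param_b: str
    levels_a: tuple[float, ...]
    levels_b: tuple[float, ...]
    counts: np.ndarray          # (len_a, len_b)
    subset_size: int

    @property
    def percent(self) -> np.ndarray:
        """Counts as a percentage of the subset (sums to 100)."""
        tot = self.counts.sum()
        return (self.counts / tot * 100.0) if tot > 0 \
            else np.zeros_like(self.counts, float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.levels_a),
                            columns=list(self.levels_b))


@dataclass(frozen=True)
class InteractionResult:
    param_a: str
    param_b: str
    label: str        # 'co-regulation' | 'local-preference' | 'no-interaction'
    ridge_score: float


# ---------------------------------------------------------------------------
# Dimensional stacking
# ---------------------------------------------------------------------------

def _axis_split(order):
    """Nest the first half of the ordering on x, the rest on y."""
    h = (len(order) + 1) // 2
    return tuple(order[:h]), tuple(order[h:])


def stack_image(coords: pd.DataFrame, values: np.ndarray,
                order: tuple[str, ...], levels: dict[str, int],
                background: float | None = None) -> np.ndarray:
    """Render the grid as a nested 2-D image for a given parameter order.

    ``coords`` holds one row per model with integer level indices per
    parameter; ``values`` is the pixel value per model (NaN = not in the
    subset, painted with ``background``).
    """
    xs, ys = _axis_split(order)
    values = np.asarray(values, float)

    def mixed_radix(params):
        idx = np.zeros(len(coords), np.int64)
        size = 1
        for p in params:       # first param = most significant
            idx = idx * levels[p] + coords[p].to_numpy()
            size *= levels[p]
        return idx, size

    ix, nx = mixed_radix(xs)
    iy, ny = mixed_radix(ys) if ys else (np.zeros(len(coords), np.int64), 1)
    img = np.full((ny, nx), np.nan)
    img[iy, ix] = values
    if background is None:
        finite = values[np.isfinite(values)]
        background = float(finite.max()) * 1.05 + 1e-9 if len(finite) else 0.0
    img[~np.isfinite(img)] = background
    return img


def clutter_score(img: np.ndarray) -> float:
    """Sum of squared differences between horizontally and vertically
    adjacent pixels (lower = smoother = better-organized stack)."""
    return float((np.diff(img, axis=0) ** 2).sum()
                 + (np.diff(img, axis=1) ** 2).sum())


def cbdr_order(coords: pd.DataFrame, values: np.ndarray,
               params: list[str] | None = None,
               levels: dict[str, int] | None = None,
               exhaustive_max: int = 6) -> StackOrder:
    """Find the parameter ordering minimizing stack-image clutter.

    Exhaustive search for up to ``exhaustive_max`` parameters; greedy
    insertion beyond.  Deterministic: candidates are visited in decreasing
    main-effect-sensitivity order (ties by name) and only strictly better
    clutter replaces the incumbent; because the stack's two axes are
    interchangeable, many orderings tie on clutter, and this visit order
    resolves ties toward sensitivity-first (name-sorted when the values
    are constant).
    """
    if params is None:
        params = [c for c in coords.columns if c != "model_id"]
    for p in params:
        if p not in coords.columns:
            raise KeyError(f"model coordinates missing parameter {p!r}")
    if levels is None:
        levels = {p: int(coords[p].max()) + 1 for p in params}
    values = np.asarray(values, float)

    # main-effect sensitivity: between-level variance of the mean value
    finite = np.isfinite(values)
    sens = {}
    for p in params:
        if finite.any():
            lv = coords[p].to_numpy()[finite]
            v = values[finite]
            means = np.array([v[lv == i].mean() if np.any(lv == i) else 0.0
                              for i in range(levels[p])])
            sens[p] = float(np.var(means))
        else:
            sens[p] = 0.0
    params = sorted(params, key=lambda p: (-sens[p], p))

    def score(order):
        return clutter_score(stack_image(coords, values, order, levels))

    if len(params) <= exhaustive_max:
        best, best_c = None, np.inf
        for perm in itertools.permutations(params):
            c = score(perm)
            if c < best_c - 1e-12:
                best, best_c = perm, c
        return StackOrder(order=tuple(best), clutter=best_c)

    # greedy insertion in sensitivity order; ties keep the newcomer last
    order: list[str] = [params[0]]
    for p in params[1:]:
        best_pos, best_c = len(order), np.inf
        for pos in range(len(order), -1, -1):
            cand = order[:pos] + [p] + order[pos:]
            c = score(tuple(cand))
            if c < best_c - 1e-12:
                best_pos, best_c = pos, c
        order.insert(best_pos, p)
    return StackOrder(order=tuple(order), clutter=score(tuple(order)))


# ---------------------------------------------------------------------------
# Pairwise conductance histograms and interaction classification
# ---------------------------------------------------------------------------

def conductance_histogram(members: pd.DataFrame, param_a: str, param_b: str,
                          grid_values: dict[str, tuple[float, ...]]
                          ) -> ConductanceHistogram:
    """Count subset members per (value_a, value_b) grid cell."""
    for p in (param_a, param_b):
        if p not in grid_values:
            raise KeyError(f"parameter {p!r} not in the grid design")
    la = tuple(grid_values[param_a])
    lb = tuple(grid_values[param_b])
    counts = np.zeros((len(la), len(lb)), int)
    if len(members):
        ia = np.searchsorted(la, members[param_a].to_numpy())
        ib = np.searchsorted(lb, members[param_b].to_numpy())
        np.add.at(counts, (ia, ib), 1)
    return ConductanceHistogram(param_a, param_b, la, lb, counts,
                                subset_size=len(members))


def _weighted_rank_corr(counts: np.ndarray) -> float:
    """Count-weighted correlation of the two parameters' level ranks."""
    na, nb = counts.shape
    w = counts.astype(float)
    tot = w.sum()
    if tot == 0:
        return 0.0
    ia, ib = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    ma = (w * ia).sum() / tot
    mb = (w * ib).sum() / tot
    va = (w * (ia - ma) ** 2).sum() / tot
    vb = (w * (ib - mb) ** 2).sum() / tot
    if va <= 0 or vb <= 0:
        return 0.0
    cov = (w * (ia - ma) * (ib - mb)).sum() / tot
    return float(cov / np.sqrt(va * vb))


def _modes_monotone(counts: np.ndarray, direction: float) -> bool:
    """Are the per-row conditional modes monotone in the score's direction?"""
    modes = []
    for row in counts:
        if row.sum() == 0:
            continue
        modes.append(int(np.argmax(row)))
    if len(modes) < 2:
        return False
    d = np.diff(modes)
    return bool(np.all(d >= 0) if direction >= 0 else np.all(d <= 0))


def classify_interaction(h: ConductanceHistogram,
                         ridge_threshold: float = RIDGE_THRESHOLD,
                         peak_threshold: float = PEAK_THRESHOLD
                         ) -> InteractionResult:
    """Label a pairwise histogram.

    co-regulation: |ridge score| >= threshold with monotone conditional
    modes; local preference: a dominant cell holding >= peak_threshold x
    the uniform share, without the monotone ridge; otherwise no clear
    interaction.  The score is always reported alongside the label.
    """
    na, nb = h.counts.shape
    if na < 2 or nb < 2:
        raise ValueError(
            f"degenerate {na}x{nb} histogram: interactions incomparable")
    score = _weighted_rank_corr(h.counts)
    tot = h.counts.sum()
    label = "no-interaction"
    if abs(score) >= ridge_threshold and _modes_monotone(h.counts, score):
        label = "co-regulation"
    elif tot > 0:
        share = h.counts.max() / tot
        if share >= peak_threshold / (na * nb):
            label = "local-preference"
    return InteractionResult(h.param_a, h.param_b, label, score)


def coreg_screen(members: pd.DataFrame, order: StackOrder,
                 grid_values: dict[str, tuple[float, ...]],
                 n_high: int = 5, control: str | None = "AHP",
                 ridge_threshold: float = RIDGE_THRESHOLD
                 ) -> list[InteractionResult]:
    """Classify all pairs among the high-order parameters (top ``n_high``
    of the stack order) plus one boundary control parameter; sorted by
    |ridge score| descending."""
    varied = [p for p in order.order
              if p in grid_values and len(grid_values[p]) >= 2]
    high = varied[:n_high]
    if control and control in grid_values and control not in high \
            and len(grid_values[control]) >= 2:
        high = high + [control]
    results = []
    for a, b in itertools.combinations(high, 2):
        hist = conductance_histogram(members, a, b, grid_values)
        results.append(classify_interaction(
            hist, ridge_threshold=ridge_threshold))
    results.sort(key=lambda r: (-abs(r.ridge_score), r.param_a, r.param_b))
    return results


# ---------------------------------------------------------------------------
# Figure export
# ---------------------------------------------------------------------------

def save_stack_figure(img: np.ndarray, path, title: str = ""):
    """Render a dimensional-stack image to PNG (and the matrix to CSV)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(img, origin="lower", aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="distance")
    ax.set_title(title or "dimensional stack")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    np.savetxt(str(path) + ".csv", img, delimiter=",")


def save_histogram_figure(h: ConductanceHistogram, path):
    """Render a pairwise conductance histogram to PNG (+ CSV matrix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(h.percent, origin="lower", cmap="magma", aspect="auto")
    ax.set_xticks(range(len(h.levels_b)), [f"{x:g}" for x in h.levels_b])
    ax.set_yticks(range(len(h.levels_a)), [f"{x:g}" for x in h.levels_a])
    ax.set_xlabel(f"{h.param_b} (pS/um^2)")
    ax.set_ylabel(f"{h.param_a} (pS/um^2)")
    fig.colorbar(im, ax=ax, label="% of subset")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    h.to_frame().to_csv(str(path) + ".csv")
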