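"""Hyperparameter procedures: lambda tuning to a target edge density,
model-order sweep with an elbow rule, subgraph normalization/thresholding,
and triage of non-specific (pre-ictally active) components."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import BTNDConfig, Decomposition, FusedLassoParams, SubgraphSet, fit
from .types import MultiSeizureDataset

logger = logging.getLogger(__name__)

DEFAULT_TARGET_DENSITY = 0.2
DEFAULT_THRESHOLD = 0.2
DEFAULT_K_MIN = 3
DEFAULT_K_MAX = 10


def edge_density(F: SubgraphSet) -> float:
    """Fraction of edges with nonzero weight in at least one component."""
    return float(np.mean(F.weights.any(axis=1)))


def _lambda_upper_bound(X: MultiSeizureDataset, zeta: list[float]) -> float:
    # gradient bound: with every ||v||_2 <= 1, each entry of
    # sum_s zeta_s X_s V_s is at most sum_s zeta_s ||x_l{s}||_2, so this
    # lambda zeroes F at the first subgraph update.
    row_norm = np.zeros(X.L)
    for z, fc in zip(zeta, X.seizures):
        row_norm += z * np.linalg.norm(fc.values, axis=1)
    return 2.0 * X.S * float(row_norm.max())


def tune_lambda(
    X: MultiSeizureDataset,
    config: BTNDConfig,
    target_density: float = DEFAULT_TARGET_DENSITY,
    max_steps: int = 20,
    density_tol: float = 0.05,
) -> tuple[float, Decomposition]:
    """Bisect lambda until the fitted subgraphs use ~``target_density`` of edges.

    Follows the lambda = gamma coupling: each trial fit uses the candidate
    lambda both as the subgraph-sparsity weight and as the base activation
    sparsity weight.  Stops when the achieved density is within
    ``density_tol`` of the target or after ``max_steps`` bisections
    (returning the closest trial).
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must lie in (0, 1)")
    if all(not fc.values.any() for fc in X.seizures):
        raise ValueError("cannot tune lambda on all-zero data")
    cfg0 = config.resolved(X)

    def fit_at(lam: float) -> Decomposition:
        cfg = replace(
            cfg0,
            lam=lam,
            base_fused=FusedLassoParams(gamma=lam, eta=cfg0.base_fused.eta),
            per_seizure_fused=None,
        )
        return fit(X, cfg)

    lo, hi = 0.0, _lambda_upper_bound(X, cfg0.zeta)
    best: tuple[float, float, Decomposition] | None = None  # (gap, lam, fit)
    trace: list[tuple[float, float]] = []
    for _ in range(max_steps):
        lam = 0.5 * (lo + hi)
        dec = fit_at(lam)
        density = edge_density(dec.subgraphs)
        trace.append((lam, density))
        gap = abs(density - target_density)
        if best is None or gap < best[0]:
            best = (gap, lam, dec)
        if gap <= density_tol:
            break
        if density > target_density:
            lo = lam
        else:
            hi = lam
    assert best is not None
    logger.info("tune_lambda: lambda=%.4g achieved density %.3f",
                best[1], edge_density(best[2].subgraphs))
    return best[1], best[2]


@dataclass
class KSweepResult:
    """Reconstruction error versus model order, with the elbow choice."""

    k_values: list[int]
    errors: list[float]
    decompositions: dict[int, Decomposition]
    selected_k: int


def sweep_k(
    X: MultiSeizureDataset,
    config: BTNDConfig,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
) -> KSweepResult:
    """Fit every K in ``k_min..k_max`` and pick the elbow of the error curve.

    The error recorded per K is the zeta-weighted relative Frobenius
    reconstruction error of the best restart.
    """
    if k_min < 1 or k_max > X.L or k_min > k_max:
        raise ValueError(f"invalid K range {k_min}..{k_max} for L={X.L}")
    k_values, errors, decs = [], [], {}
    for K in range(k_min, k_max + 1):
        try:
            dec = fit(X, replace(config, K=K))
        except Exception:
            logger.exception("fit failed for K=%d; skipping", K)
            continue
        k_values.append(K)
        errors.append(dec.relative_error(X))
        decs[K] = dec
    if len(k_values) < 3:
        raise RuntimeError("fewer than 3 successful fits; cannot place an elbow")
    selected = elbow_select(k_values, errors)
    return KSweepResult(
        k_values=k_values, errors=errors, decompositions=decs, selected_k=selected
    )


def elbow_select(k_values: list[int], errors: list[float]) -> int:
    """Pick the K at the elbow of the error curve.

    The elbow is the point of maximal perpendicular distance from the
    chord joining the first and last points of the curve, after min-max
    normalization of both axes (which makes the choice invariant to affine
    rescaling of the error axis).  Ties resolve to the smaller K; a curve
    with no elbow (monotone increasing, or perfectly linear) returns
    ``k_min`` with a warning.
    """
    if len(k_values) < 3:
        raise ValueError("need at least 3 points to place an elbow")
    k = np.asarray(k_values, dtype=float)
    e = np.asarray(errors, dtype=float)
    if np.all(np.diff(e) >= 0) and e[-1] > e[0]:
        warnings.warn("error curve increases with K; no elbow, returning k_min")
        return k_values[0]
    x = (k - k[0]) / (k[-1] - k[0])
    span = e.max() - e.min()
    y = (e - e.min()) / span if span > 0 else np.zeros_like(e)
    # distance from (x, y) to the chord between the first and last points
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist /= np.hypot(x1 - x0, y1 - y0)
    if dist.max() <= 1e-12:
        warnings.warn("error curve is linear; no elbow, returning k_min")
        return k_values[0]
    return k_values[int(np.argmax(dist))]


@dataclass
class SubgraphReport:
    """Normalized, thresholded subgraphs ready for interpretation.

    ``retained_edges[k]`` lists ``(edge_l, weight)`` pairs in descending
    weight order; ``zero_components`` flags columns that were all-zero
    before normalization.
    """

    normalized_weights: np.ndarray
    retained_edges: list[list[tuple[int, float]]]
    zero_components: list[bool]
    threshold: float


def normalize_and_threshold(
    F: SubgraphSet, threshold: float = DEFAULT_THRESHOLD
) -> SubgraphReport:
    """Scale each subgraph to max weight 1, then drop edges below ``threshold``.

    All-zero components are kept as all-zero and flagged.  The operation
    is idempotent: renormalizing a reported matrix changes nothing.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    W = F.weights.copy()
    zero_components = []
    retained: list[list[tuple[int, float]]] = []
    for k in range(W.shape[1]):
        peak = W[:, k].max()
        if peak <= 0:
            zero_components.append(True)
            retained.append([])
            continue
        zero_components.append(False)
        W[:, k] /= peak
        W[W[:, k] < threshold, k] = 0.0
        order = np.argsort(-W[:, k], kind="stable")
        retained.append(
            [(int(l), float(W[l, k])) for l in order if W[l, k] > 0]
        )
    return SubgraphReport(
        normalized_weights=W,
        retained_edges=retained,
        zero_components=zero_components,
        threshold=threshold,
    )


def flag_nonspecific(
    decomposition: Decomposition,
    preictal_windows: int | list[int],
    ratio: float = 0.5,
) -> list[bool]:
    """Flag components that are as active before seizure onset as during it.

    A component is non-specific when, in *every* seizure, its mean
    activation over the pre-ictal windows is at least ``ratio`` times its
    mean activation over the remaining (ictal) windows.  Components with
    all-zero activations are flagged (vacuously pre-ictal).
    """
    S = len(decomposition.activations)
    pre = (
        list(preictal_windows)
        if isinstance(preictal_windows, (list, tuple))
        else [int(preictal_windows)] * S
    )
    if len(pre) != S:
        raise ValueError("need one pre-ictal window count per seizure")
    for p, act in zip(pre, decomposition.activations):
        if not 0 < p < act.T:
            raise ValueError(
                f"pre-ictal window count {p} must lie in 1..{act.T - 1}"
            )
    K = decomposition.subgraphs.K
    flags = []
    for k in range(K):
        nonspecific = True
        for p, act in zip(pre, decomposition.activations):
            v = act.values[:, k]
            pre_mean = float(v[:p].mean())
            ictal_mean = float(v[p:].mean())
            if pre_mean < ratio * ictal_mean:
                nonspecific = False
                break
        flags.append(nonspecific)
    return flags
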