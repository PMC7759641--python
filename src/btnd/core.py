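"""Joint non-negative factorization of multi-seizure FC matrices.

Each seizure's edge-by-window matrix ``X{s}`` is approximated as
``F @ V{s}.T`` with a single non-negative, sparse subgraph matrix ``F``
(L edges x K components) shared across seizures and per-seizure
non-negative activation profiles ``V{s}`` (T(s) windows x K).  The fitted
objective is

    sum_s zeta_s * ||X{s} - F V{s}^T||_F^2  +  (lambda / S) * sum |F|,

subject to F >= 0, V{s} >= 0 and, for every activation column v, the
sparsity+compactness budget

    C(v; gamma, eta) = gamma*sum|v_t| + eta*sum|v_{t+1}-v_t| + sum v_t^2 <= 1.

The l1 term makes each column of v sparse, the total-variation term makes
it piecewise constant (compact activation periods), and the quadratic term
pins the scale of the activations so that magnitude lives in F.

Optimization is block-coordinate descent with multiple random restarts:
the F block is a row-separable non-negative lasso solved by coordinate
descent with soft-thresholding, and each V column is solved by a
Lagrangian bisection on the fused-lasso budget (penalized prox, then
bisect the multiplier to the constraint boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._tv import fused_lasso_nonneg_prox
from .types import EdgeIndex, FCSeries, MultiSeizureDataset

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 20
DEFAULT_ETA = 0.2
DEFAULT_MAX_ITER = 500
DEFAULT_REL_TOL = 1e-5

_FEAS_TOL = 1e-6          # allowed constraint overshoot at convergence
_BISECT_BAND = 1e-3       # bisection stops when C(v) in [1 - band, 1]


@dataclass(frozen=True)
class FusedLassoParams:
    """Weights of the activation budget: gamma (sparsity), eta (compactness)."""

    gamma: float = 0.0
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.eta < 0:
            raise ValueError("gamma and eta must be non-negative")


@dataclass
class BTNDConfig:
    """Hyperparameters of one decomposition run.

    ``zeta`` and ``per_seizure_fused`` may be left ``None``; they are then
    derived from the data (energy balancing) and from the base fused-lasso
    weights (duration adaptation) when the fit starts.
    """

    K: int
    lam: float = 0.0
    base_fused: FusedLassoParams = field(default_factory=FusedLassoParams)
    per_seizure_fused: list[FusedLassoParams] | None = None
    zeta: list[float] | None = None
    n_restarts: int = DEFAULT_N_RESTARTS
    max_iter: int = DEFAULT_MAX_ITER
    rel_tol: float = DEFAULT_REL_TOL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.zeta is not None and any(z <= 0 for z in self.zeta):
            raise ValueError("all zeta weights must be positive")

    def resolved(self, X: MultiSeizureDataset) -> "BTNDConfig":
        """Fill in data-derived zeta and per-seizure fused-lasso weights."""
        zeta = self.zeta if self.zeta is not None else compute_zeta(X)
        fused = (
            self.per_seizure_fused
            if self.per_seizure_fused is not None
            else adapt_fused_params(self.base_fused, X.durations)
        )
        if len(zeta) != X.S or len(fused) != X.S:
            raise ValueError("zeta / fused-lasso lists must have one entry per seizure")
        return replace(self, zeta=list(zeta), per_seizure_fused=list(fused))


@dataclass
class SubgraphSet:
    """Non-negative edge-weight matrix F: one column per subgraph."""

    weights: np.ndarray
    edge_index: EdgeIndex

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be L x K")
        if self.weights.shape[0] != self.edge_index.L:
            raise ValueError("row count must match the edge index")
        if not np.all(np.isfinite(self.weights)) or self.weights.min() < 0:
            raise ValueError("weights must be finite and non-negative")

    @property
    def L(self) -> int:
        return self.weights.shape[0]

    @property
    def K(self) -> int:
        return self.weights.shape[1]


@dataclass
class ActivationProfiles:
    """Non-negative activation time courses V{s} for one seizure (T x K)."""

    values: np.ndarray
    seizure_id: str = ""
    zeroed_components: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be T x K")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("activations must be finite and non-negative")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class Decomposition:
    """A fitted model: shared subgraphs, per-seizure activations, provenance."""

    subgraphs: SubgraphSet
    activations: list[ActivationProfiles]
    config: BTNDConfig
    objective_trace: list[float]
    restart_objectives: list[float]
    selected_restart: int

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]

    def reconstruction(self, s: int) -> np.ndarray:
        return self.subgraphs.weights @ self.activations[s].values.T

    def relative_error(self, X: MultiSeizureDataset) -> float:
        """zeta-weighted relative Frobenius reconstruction error."""
        zeta = self.config.zeta
        num = sum(
            z * np.sum((fc.values - self.reconstruction(s)) ** 2)
            for s, (fc, z) in enumerate(zip(X.seizures, zeta))
        )
        den = sum(z * np.sum(fc.values**2) for fc, z in zip(X.seizures, zeta))
        return float(np.sqrt(num / den))


def constraint_value(v: np.ndarray, params: FusedLassoParams) -> float:
    """Activation budget C(v) = gamma*sum|v| + eta*TV(v) + sum v^2."""
    v = np.asarray(v, dtype=float)
    return float(
        params.gamma * np.sum(np.abs(v))
        + params.eta * np.sum(np.abs(np.diff(v)))
        + np.sum(v * v)
    )


def objective(
    F: SubgraphSet,
    V: list[ActivationProfiles],
    X: MultiSeizureDataset,
    config: BTNDConfig,
) -> float:
    """Penalized data-fit value (the constraints are not added as penalties)."""
    if len(V) != X.S:
        raise ValueError(f"{len(V)} activation sets for {X.S} seizures")
    cfg = config.resolved(X)
    total = 0.0
    for s, fc in enumerate(X.seizures):
        if V[s].K != F.K or V[s].T != fc.T or F.L != fc.L:
            raise ValueError(f"shape mismatch at seizure {s}")
        resid = fc.values - F.weights @ V[s].values.T
        total += cfg.zeta[s] * float(np.sum(resid * resid))
    total += config.lam / X.S * float(np.sum(np.abs(F.weights)))
    return total


def compute_zeta(X: MultiSeizureDataset) -> list[float]:
    """Energy-balancing seizure weights: zeta_s = 1 / ||X{s}||_F^2."""
    zeta = []
    for fc in X.seizures:
        energy = float(np.sum(fc.values**2))
        if energy <= 0:
            raise ValueError(f"seizure {fc.seizure_id!r} has zero energy")
        zeta.append(1.0 / energy)
    return zeta


def adapt_fused_params(
    base: FusedLassoParams, durations: list[int]
) -> list[FusedLassoParams]:
    """Scale gamma and eta per seizure by sqrt(T_ref / T(s)), T_ref = median.

    Longer seizures get proportionally smaller weights so that the l1 and
    total-variation budgets stay comparable per unit of ||v||_2 across
    durations; equal durations return the base weights unchanged.
    """
    if any(T < 2 for T in durations):
        raise ValueError("every seizure needs at least 2 windows")
    t_ref = float(np.median(durations))
    return [
        FusedLassoParams(
            gamma=base.gamma * np.sqrt(t_ref / T),
            eta=base.eta * np.sqrt(t_ref / T),
        )
        for T in durations
    ]


def _subgraph_normal_matrices(
    V: list[ActivationProfiles], X: MultiSeizureDataset, zeta: list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """A = sum_s zeta_s V_s^T V_s (K x K); B = sum_s zeta_s X_s V_s (L x K)."""
    K = V[0].K
    A = np.zeros((K, K))
    B = np.zeros((X.L, K))
    for s, fc in enumerate(X.seizures):
        A += zeta[s] * V[s].values.T @ V[s].values
        B += zeta[s] * fc.values @ V[s].values
    return A, B


def update_subgraphs(
    F: SubgraphSet,
    V: list[ActivationProfiles],
    X: MultiSeizureDataset,
    config: BTNDConfig,
    n_sweeps: int = 100,
    tol: float = 1e-12,
) -> SubgraphSet:
    """Minimize the objective over F with the activations held fixed.

    The subproblem is a row-separable non-negative lasso; coordinate
    descent with soft-thresholding drives entries below lambda/(2S) (on
    the gradient scale) to exact zeros.
    """
    cfg = config.resolved(X)
    A, B = _subgraph_normal_matrices(V, X, cfg.zeta)
    thr = config.lam / (2.0 * X.S)
    W = F.weights.copy()
    diag = np.diag(A).copy()
    dead = diag <= 1e-15 * max(diag.max(), 1.0)
    scale = float(np.abs(W).max()) or 1.0
    for _ in range(n_sweeps):
        delta = 0.0
        for k in range(W.shape[1]):
            if dead[k]:
                # data term does not involve this column; the l1 term zeroes it
                delta = max(delta, float(np.abs(W[:, k]).max()))
                W[:, k] = 0.0
                continue
            g = B[:, k] - W @ A[:, k] + W[:, k] * diag[k]
            new = np.maximum(0.0, g - thr) / diag[k]
            delta = max(delta, float(np.abs(new - W[:, k]).max()))
            W[:, k] = new
        if delta <= tol * scale:
            break
    return SubgraphSet(weights=W, edge_index=F.edge_index)


def _update_activation_column(
    b: np.ndarray, a: float, params: FusedLassoParams
) -> np.ndarray:
    """Minimize a*||v||^2 - 2 b.v over v >= 0 with C(v; params) <= 1.

    Solved in penalized form: for multiplier mu the minimizer is the
    fused-lasso prox of b/(a+mu); mu is bisected until C(v) hits the
    budget boundary (or the unconstrained minimizer is already feasible).
    """

    def solve(mu: float) -> np.ndarray:
        denom = a + mu
        return fused_lasso_nonneg_prox(
            b / denom,
            l1=mu * params.gamma / (2.0 * denom),
            tv=mu * params.eta / (2.0 * denom),
        )

    v0 = np.maximum(b, 0.0) / a
    if constraint_value(v0, params) <= 1.0:
        return v0
    lo, hi = 0.0, max(a, 1.0)
    while constraint_value(solve(hi), params) > 1.0:
        hi *= 2.0
        if hi > 1e16:  # pragma: no cover - defensive
            return np.zeros_like(b)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        c = constraint_value(solve(mid), params)
        if c > 1.0:
            lo = mid
        else:
            hi = mid
            if c >= 1.0 - _BISECT_BAND:
                break
    return solve(hi)


def update_activations(
    V_s: ActivationProfiles,
    F: SubgraphSet,
    X_s: FCSeries,
    params: FusedLassoParams,
) -> ActivationProfiles:
    """Column-wise update of one seizure's activations with F fixed.

    Each returned column is non-negative, satisfies the fused-lasso budget,
    and never fits the data worse than the column it replaces (a column is
    kept unchanged if the bisection tolerance would degrade it).  Columns
    matched to an all-zero subgraph are set to zero.
    """
    W = F.weights
    Vv = V_s.values.copy()
    G = W.T @ W                      # K x K
    H = W.T @ X_s.values             # K x T
    diag = np.diag(G)
    zeroed: list[int] = []
    for k in range(Vv.shape[1]):
        a = float(diag[k])
        if a <= 1e-15 * max(float(diag.max()), 1.0):
            zeroed.append(k)
            logger.debug("subgraph %d is all-zero; activation column zeroed", k)
            Vv[:, k] = 0.0
            continue
        b = H[k] - Vv @ G[:, k] + Vv[:, k] * a
        new = _update_activation_column(b, a, params)
        # data-fit change for this column: a||v||^2 - 2 b.v
        old_fit = a * float(Vv[:, k] @ Vv[:, k]) - 2.0 * float(b @ Vv[:, k])
        new_fit = a * float(new @ new) - 2.0 * float(b @ new)
        if new_fit <= old_fit:
            Vv[:, k] = new
    return ActivationProfiles(
        values=Vv, seizure_id=V_s.seizure_id, zeroed_components=zeroed
    )


def _feasible_scale(v: np.ndarray, params: FusedLassoParams) -> np.ndarray:
    """Rescale v onto the budget boundary: alpha solves a*alpha^2 + b*alpha = 1."""
    quad = float(np.sum(v * v))
    lin = params.gamma * float(np.sum(np.abs(v))) + params.eta * float(
        np.sum(np.abs(np.diff(v)))
    )
    if quad <= 0 and lin <= 0:
        return v
    if quad <= 0:
        return v / lin
    alpha = (-lin + np.sqrt(lin * lin + 4.0 * quad)) / (2.0 * quad)
    return v * alpha


def fit_single(
    X: MultiSeizureDataset, config: BTNDConfig, restart_seed: int
) -> Decomposition:
    """One run of alternating block updates from a random initialization."""
    cfg = config.resolved(X)
    if cfg.K > X.L:
        raise ValueError(f"K={cfg.K} exceeds the number of edges L={X.L}")
    if any(T < 2 for T in X.durations):
        raise ValueError("every seizure needs at least 2 windows")
    rng = np.random.default_rng(restart_seed)
    F = SubgraphSet(
        weights=rng.uniform(size=(X.L, cfg.K)), edge_index=X.edge_index
    )
    V = []
    for s, fc in enumerate(X.seizures):
        Vv = rng.uniform(size=(fc.T, cfg.K))
        for k in range(cfg.K):
            Vv[:, k] = _feasible_scale(Vv[:, k], cfg.per_seizure_fused[s])
        V.append(ActivationProfiles(values=Vv, seizure_id=fc.seizure_id))

    trace = [objective(F, V, X, cfg)]
    for _ in range(cfg.max_iter):
        F = update_subgraphs(F, V, X, cfg)
        V = [
            update_activations(V[s], F, X.seizures[s], cfg.per_seizure_fused[s])
            for s in range(X.S)
        ]
        obj = objective(F, V, X, cfg)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective became non-finite at iteration {len(trace)}"
            )
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= cfg.rel_tol * max(abs(prev), 1e-30):
            break
    return Decomposition(
        subgraphs=F,
        activations=V,
        config=cfg,
        objective_trace=trace,
        restart_objectives=[trace[-1]],
        selected_restart=0,
    )


def fit(X: MultiSeizureDataset, config: BTNDConfig) -> Decomposition:
    """Multi-restart fit; returns the restart with the smallest objective.

    Restart seeds are derived deterministically from ``config.seed``; ties
    in the final objective resolve to the lowest restart index.
    """
    cfg = config.resolved(X)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_restarts)
    runs = [fit_single(X, cfg, int(s) % (2**31)) for s in seeds]
    finals = [r.objective_trace[-1] for r in runs]
    best = int(np.argmin(finals))
    chosen = runs[best]
    return Decomposition(
        subgraphs=chosen.subgraphs,
        activations=chosen.activations,
        config=cfg,
        objective_trace=chosen.objective_trace,
        restart_objectives=finals,
        selected_restart=best,
    )
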