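"""Masked, graph-regularized nonnegative Tucker decomposition.

Fits T ≈ ⟦G; Ay, Ax, Ag⟧ by minimizing

    F(G, Ay, Ax, Ag) = ½‖M ⊙ (T − T̂)‖²_F + (λ/2)·vec(T̂)ᵀ L_c vec(T̂)

subject to nonnegativity of every block, where T̂ is the Tucker
reconstruction, M a binary mask selecting observed entries, and L_c the
Kronecker-sum Laplacian of the Cartesian product of the two spatial chain
graphs and the gene network.  Each block is updated in turn — Ay, Ax, Ag,
then the core — with a multiplicative rule built from the positive and
negative parts of that block's gradient, which preserves nonnegativity and
does not increase the objective.  After every sweep the factor columns are
rescaled to sum to one, with the scales absorbed into the core, leaving the
reconstruction unchanged but making core magnitudes comparable across
multiway interactions.

The gradients are evaluated through the Tucker structure: the data term
uses contractions of M⊙T̂ and M⊙T with the fixed factors, and the
regularizer acts on one factor at a time through its mode's Laplacian with
the remaining modes entering only via r×r Gram matrices — the product
Laplacian is never formed.  The positive/negative split follows the
degree/adjacency split L = D − W of each Laplacian and the M⊙T̂ / M⊙T
split of the data residual, so both parts are elementwise nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionTensor, MaskTensor
from .graphs import GraphSet, UndirectedGraph, build_graph_set
from .tensor_algebra import nmode_product, tucker_reconstruct, unfold

logger = logging.getLogger(__name__)

__all__ = [
    "TuckerModel",
    "FitConfig",
    "FitResult",
    "objective",
    "normalize",
    "fit",
    "impute",
    "factor_gradient_parts",
    "core_gradient_parts",
    "mu_update_factor",
    "mu_update_core",
]


@dataclass
class TuckerModel:
    """Nonnegative Tucker model: core (ry, rx, rg) and factors
    Ay (ny, ry), Ax (nx, rx), Ag (ng, rg)."""

    core: np.ndarray
    ay: np.ndarray
    ax: np.ndarray
    ag: np.ndarray

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ag = np.asarray(self.ag, dtype=float)
        ry, rx, rg = self.core.shape
        if self.ay.shape[1] != ry or self.ax.shape[1] != rx or self.ag.shape[1] != rg:
            raise ValueError("factor column counts must match the core shape")
        for name, block in self.blocks().items():
            if block.size and block.min() < 0:
                raise ValueError(f"block {name} has negative entries")

    @property
    def rank(self) -> tuple[int, int, int]:
        return self.core.shape  # type: ignore[return-value]

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.ay.shape[0], self.ax.shape[0], self.ag.shape[0])

    def factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.ay, self.ax, self.ag)

    def blocks(self) -> dict[str, np.ndarray]:
        return {"core": self.core, "ay": self.ay, "ax": self.ax, "ag": self.ag}

    def reconstruct(self) -> np.ndarray:
        return tucker_reconstruct(self.core, self.ay, self.ax, self.ag)

    def copy(self) -> "TuckerModel":
        return TuckerModel(
            self.core.copy(), self.ay.copy(), self.ax.copy(), self.ag.copy()
        )


@dataclass
class FitConfig:
    """Hyperparameters of a fit.

    lambda_ is the regularization strength λ; tol applies to the relative
    change of the total objective between sweeps; eps guards multiplicative
    denominators against 0/0.
    """

    rank: tuple[int, int, int] = (50, 50, 50)
    lambda_: float = 0.1
    max_iter: int = 5000
    tol: float = 1e-4
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.rank):
            raise ValueError("every rank component must be >= 1")
        if self.lambda_ < 0:
            raise ValueError("lambda must be nonnegative")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")


@dataclass
class FitResult:
    model: TuckerModel
    objective_trace: list[tuple[float, float, float]]
    n_iter: int
    converged: bool
    config: FitConfig | None = None


def _as_array(t) -> np.ndarray:
    return t.values if hasattr(t, "values") else np.asarray(t, dtype=float)


# ---------------------------------------------------------------------------
# objective


def _gram_regularizer_terms(model: TuckerModel, gs: GraphSet) -> float:
    """vec(T̂)ᵀ L_c vec(T̂) through the Tucker structure (no full tensor)."""
    core, factors = model.core, model.factors()
    grams = [a.T @ a for a in factors]
    total = 0.0
    for mode, lap in enumerate(gs.laplacians()):
        a = factors[mode]
        lap_gram = a.T @ (lap @ a)
        mats = list(grams)
        mats[mode] = np.eye(core.shape[mode])
        h = core
        for m, g in enumerate(mats):
            if m != mode:
                h = nmode_product(h, g, m)
        hh = unfold(h, mode) @ unfold(core, mode).T
        total += float(np.sum(lap_gram * hh.T))
    return max(total, 0.0)


def objective(
    t, m, model: TuckerModel, gs: GraphSet, lambda_: float
) -> tuple[float, float, float]:
    """Return (F1, F2, total) with F1 = ½‖M⊙(T−T̂)‖², F2 = ½·vecᵀL_c vec,
    total = F1 + λ·F2."""
    tv, mv = _as_array(t), _as_array(m)
    if tv.shape != mv.shape or tv.shape != model.shape:
        raise ValueError("tensor, mask and model shapes must agree")
    that = model.reconstruct()
    f1 = 0.5 * float(np.sum((mv * (tv - that)) ** 2))
    f2 = 0.5 * _gram_regularizer_terms(model, gs)
    total = f1 + lambda_ * f2
    if not np.isfinite(total):
        raise FloatingPointError("objective is not finite")
    return (f1, f2, total)


# ---------------------------------------------------------------------------
# gradients, split into elementwise-nonnegative positive/negative parts


def _contract_others(x: np.ndarray, factors, skip: int) -> np.ndarray:
    """Contract every mode but ``skip`` of x with the matching factor
    transpose."""
    out = x
    for mode, a in enumerate(factors):
        if mode != skip:
            out = nmode_product(out, a.T, mode)
    return out


def factor_gradient_parts(
    t, m, model: TuckerModel, gs: GraphSet, mode: int, that: np.ndarray | None = None
):
    """Gradient of (F1, F2) w.r.t. the factor of ``mode``, as
    (dF1_pos, dF1_neg, dF2_pos, dF2_neg), all elementwise >= 0."""
    tv, mv = _as_array(t), _as_array(m)
    factors = model.factors()
    core = model.core
    if that is None:
        that = model.reconstruct()

    core_unf_t = unfold(core, mode).T
    d_pos = unfold(_contract_others(mv * that, factors, mode), mode) @ core_unf_t
    d_neg = unfold(_contract_others(mv * tv, factors, mode), mode) @ core_unf_t

    grams = [a.T @ a for a in factors]
    parts = gs.degree_adjacency_parts()
    a_mode = factors[mode]

    def core_quad(mats) -> np.ndarray:
        h = core
        for mm, g in enumerate(mats):
            if mm != mode and g is not None:
                h = nmode_product(h, g, mm)
        return unfold(h, mode) @ core_unf_t

    r_pos = np.zeros_like(a_mode)
    r_neg = np.zeros_like(a_mode)
    for other in range(3):
        dmat, wmat = parts[other]
        if other == mode:
            h = core_quad([g if i != mode else None for i, g in enumerate(grams)])
            r_pos += (dmat @ a_mode) @ h
            r_neg += (wmat @ a_mode) @ h
        else:
            mats_d = list(grams)
            mats_d[other] = factors[other].T @ (dmat @ factors[other])
            mats_w = list(grams)
            mats_w[other] = factors[other].T @ (wmat @ factors[other])
            r_pos += a_mode @ core_quad(mats_d)
            r_neg += a_mode @ core_quad(mats_w)
    return d_pos, d_neg, r_pos, r_neg


def core_gradient_parts(
    t, m, model: TuckerModel, gs: GraphSet, that: np.ndarray | None = None
):
    """Gradient of (F1, F2) w.r.t. the core, split as for the factors."""
    tv, mv = _as_array(t), _as_array(m)
    factors = model.factors()
    if that is None:
        that = model.reconstruct()

    d_pos = _contract_others(mv * that, factors, skip=-1)
    d_neg = _contract_others(mv * tv, factors, skip=-1)

    grams = [a.T @ a for a in factors]
    parts = gs.degree_adjacency_parts()
    r_pos = np.zeros_like(model.core)
    r_neg = np.zeros_like(model.core)
    for mode in range(3):
        dmat, wmat = parts[mode]
        mats_d = list(grams)
        mats_d[mode] = factors[mode].T @ (dmat @ factors[mode])
        mats_w = list(grams)
        mats_w[mode] = factors[mode].T @ (wmat @ factors[mode])
        hd = hw = model.core
        for mm in range(3):
            hd = nmode_product(hd, mats_d[mm], mm)
            hw = nmode_product(hw, mats_w[mm], mm)
        r_pos += hd
        r_neg += hw
    return d_pos, d_neg, r_pos, r_neg


def _mu_ratio(pos, neg, lam_pos, lam_neg, lambda_: float, eps: float) -> np.ndarray:
    num = neg + lambda_ * lam_neg
    den = pos + lambda_ * lam_pos + eps
    ratio = num / den
    if not np.isfinite(ratio).all():
        raise FloatingPointError("non-finite multiplicative ratio")
    return ratio


def mu_update_factor(
    t, m, model: TuckerModel, gs: GraphSet, mode: int, lambda_: float, eps: float = 1e-12
) -> np.ndarray:
    """One multiplicative update of the factor of ``mode`` with every other
    block fixed.  Entries at exactly zero stay zero."""
    d_pos, d_neg, r_pos, r_neg = factor_gradient_parts(t, m, model, gs, mode)
    a = model.factors()[mode]
    return a * _mu_ratio(d_pos, d_neg, r_pos, r_neg, lambda_, eps)


def mu_update_core(
    t, m, model: TuckerModel, gs: GraphSet, lambda_: float, eps: float = 1e-12
) -> np.ndarray:
    """One multiplicative update of the (vectorized) core."""
    d_pos, d_neg, r_pos, r_neg = core_gradient_parts(t, m, model, gs)
    return model.core * _mu_ratio(d_pos, d_neg, r_pos, r_neg, lambda_, eps)


# ---------------------------------------------------------------------------
# normalization


def normalize(model: TuckerModel) -> TuckerModel:
    """Rescale every factor column to sum to 1, absorbing the scales into
    the core; the reconstruction is unchanged.  Zero columns are left as
    zeros with scale 1 (a dead component is a legitimate outcome)."""
    scales = []
    new_factors = []
    for a in model.factors():
        s = a.sum(axis=0)
        zero = s <= 0
        if zero.any():
            logger.warning("normalize: %d zero factor column(s) left as-is", zero.sum())
        safe = np.where(zero, 1.0, s)
        new_factors.append(a / safe)
        scales.append(safe)
    u, v, w = scales
    core = model.core * u[:, None, None] * v[None, :, None] * w[None, None, :]
    return TuckerModel(core, *new_factors)


# ---------------------------------------------------------------------------
# fitting


def fit(
    t,
    m,
    network: UndirectedGraph | None = None,
    config: FitConfig | None = None,
    graph_set: GraphSet | None = None,
) -> FitResult:
    """Run the block multiplicative-update fit.

    Parameters
    ----------
    t, m : ExpressionTensor / MaskTensor (or plain arrays) of equal shape.
    network : gene graph aligned to the gene axis; ignored when
        ``graph_set`` is given, edgeless if both are None.
    config : rank, λ, iteration budget, tolerance and seed.

    All blocks are initialized i.i.d. uniform(0, 1) from ``config.seed``.
    Each sweep updates Ay, Ax, Ag, then the core, then renormalizes; the
    run stops when the relative objective change drops below ``config.tol``
    or after ``config.max_iter`` sweeps.
    """
    cfg = config or FitConfig()
    tv, mv = _as_array(t), _as_array(m)
    if tv.shape != mv.shape:
        raise ValueError("tensor and mask shapes differ")
    ny, nx, ng = tv.shape
    ry, rx, rg = cfg.rank
    if ry > ny or rx > nx or rg > ng:
        raise ValueError(f"rank {cfg.rank} exceeds tensor shape {tv.shape}")

    gs = graph_set if graph_set is not None else build_graph_set(tv.shape, network)

    rng = np.random.default_rng(cfg.seed)
    model = TuckerModel(
        core=rng.uniform(size=(ry, rx, rg)),
        ay=rng.uniform(size=(ny, ry)),
        ax=rng.uniform(size=(nx, rx)),
        ag=rng.uniform(size=(ng, rg)),
    )

    trace: list[tuple[float, float, float]] = []
    prev_total: float | None = None
    converged = False
    n_iter = 0
    for it in range(cfg.max_iter):
        for mode in range(3):
            new_a = mu_update_factor(tv, mv, model, gs, mode, cfg.lambda_, cfg.eps)
            if mode == 0:
                model.ay = new_a
            elif mode == 1:
                model.ax = new_a
            else:
                model.ag = new_a
        model.core = mu_update_core(tv, mv, model, gs, cfg.lambda_, cfg.eps)
        model = normalize(model)

        f1, f2, total = objective(tv, mv, model, gs, cfg.lambda_)
        trace.append((f1, f2, total))
        n_iter = it + 1
        if it % 100 == 0:
            logger.info(
                "iter %d: F1=%.6g F2=%.6g total=%.6g", it, f1, f2, total
            )
        if prev_total is not None:
            residual = abs(total - prev_total) / max(prev_total, 1.0)
            if residual < cfg.tol:
                converged = True
                break
        prev_total = total

    return FitResult(
        model=model,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        config=cfg,
    )


def impute(model: TuckerModel) -> np.ndarray:
    """Full reconstruction T̂; callers select held-out entries to score."""
    return model.reconstruct()
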