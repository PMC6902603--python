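"""No-U-Turn Sampler with dual-averaging step-size adaptation.

Each iteration refreshes the momentum, draws a slice variable
``u ~ Uniform(0, exp(log f(theta) - p'M^{-1}p / 2))`` (held in log scale),
and doubles a leapfrog trajectory randomly forwards/backwards until either
the U-turn criterion ``(theta+ - theta-)'p- < 0 or (theta- - theta+)'p+ < 0``
fires or the slice is violated catastrophically (divergence).  Proposals move
between doubling halves with the memory-efficient transition kernel ``T``
(accept the new half with probability ``|C_new| / |C_old|``, then pick a
valid state of the new half uniformly).  The per-iteration acceptance
statistic ``alpha_j`` — the mean Metropolis ratio over the states explored
during the final doubling — drives dual averaging of ``log epsilon`` towards
a target acceptance ``delta`` during warm-up; afterwards ``epsilon`` is
frozen at the averaged value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .diagnostics import SampleStore
from .hmc import DIVERGENCE_THRESHOLD, DivergenceSignal, initial_theta, kinetic_energy
from .hmc import _assemble_store
from .model import ModelData, make_target
from .pedigree import RelationshipFactor


@dataclass(frozen=True)
class NUTSConfig:
    n_iter: int = 10000
    warmup: int = 1000
    delta: float = 0.6
    max_tree_depth: int = 10
    seed: int = 0
    adapt_mass: bool = False
    epsilon: float | None = None  # fixed step size; disables adaptation

    def __post_init__(self):
        if not 0 <= self.warmup < self.n_iter:
            raise ValueError("need 0 <= warmup < n_iter")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")


class _Node(NamedTuple):
    """One phase-space point with cached log density and gradient."""

    theta: np.ndarray
    p: np.ndarray
    logp: float
    grad: np.ndarray


@dataclass
class TreeState:
    """Summary of a (sub)tree built by the doubling process."""

    minus: _Node
    plus: _Node
    proposal: _Node | None
    proposal_joint: float
    n_valid: int
    stop: bool
    alpha_sum: float
    n_alpha: int
    divergent: bool = False
    n_leapfrog: int = 0


@dataclass(frozen=True)
class DualAveragingState:
    """State of the printed step-size recursions.

    ``log eps_{j+1} = mu - (sqrt(j)/gamma) * (1/(j+j0)) * sum_i (delta - alpha_i)``
    ``log eps_bar_{j+1} = eta_j log eps_{j+1} + (1 - eta_j) log eps_bar_j``
    with ``eta_j = j^-kappa``.  After warm-up the sampler freezes epsilon at
    ``exp(log_eps_bar)``.
    """

    mu: float
    log_eps: float
    log_eps_bar: float = 0.0
    shrink_sum: float = 0.0  # running sum of (delta - alpha_i)
    j: int = 0
    gamma: float = 0.05
    j0: float = 10.0
    kappa: float = 0.75
    delta: float = 0.6

    @property
    def h_bar(self) -> float:
        """Running average of (delta - alpha): shrink_sum / (j + j0)."""
        return self.shrink_sum / (self.j + self.j0)

    @property
    def epsilon(self) -> float:
        return float(np.exp(self.log_eps))

    @property
    def epsilon_frozen(self) -> float:
        return float(np.exp(self.log_eps_bar))


def dual_averaging_update(da: DualAveragingState, alpha_j: float) -> DualAveragingState:
    """One warm-up update of the three printed recursions."""
    j = da.j + 1
    s = da.shrink_sum + (da.delta - alpha_j)
    log_eps = da.mu - np.sqrt(j) / da.gamma * s / (j + da.j0)
    eta = j ** (-da.kappa)
    log_eps_bar = eta * log_eps + (1.0 - eta) * da.log_eps_bar
    return replace(da, log_eps=log_eps, log_eps_bar=log_eps_bar, shrink_sum=s, j=j)


def draw_slice(joint_logp: float, rng: np.random.Generator) -> float:
    """log u with u ~ Uniform(0, exp(joint_logp)), kept in log scale.

    ``log u = joint + log U(0,1)`` never under/overflows where the direct
    scale would.
    """
    return joint_logp + np.log(rng.uniform())


def uturn_stop(
    theta_plus: np.ndarray,
    theta_minus: np.ndarray,
    p_plus: np.ndarray,
    p_minus: np.ndarray,
) -> bool:
    """True iff the trajectory has begun doubling back on itself:
    ``(theta+ - theta-)'p- < 0`` or ``(theta+ - theta-)'p+ < 0``."""
    dtheta = theta_plus - theta_minus
    return bool(dtheta @ p_minus < 0.0 or dtheta @ p_plus < 0.0)


def transition_select(n_old: int, n_new: int, rng: np.random.Generator) -> bool:
    """Kernel T: move to the new subtree with probability min(1, n_new/n_old)."""
    if n_new <= 0:
        return False
    if n_new >= n_old:
        return True
    return bool(rng.uniform() < n_new / n_old)


def accept_statistic(tree: TreeState) -> float:
    """alpha_j: mean Metropolis ratio over the states of the final doubling."""
    return tree.alpha_sum / max(tree.n_alpha, 1)


def _leapfrog_one(target, node: _Node, eps: float, v: int, m_inv) -> _Node:
    """Single leapfrog step of signed size v*eps from a cached node."""
    p = node.p + 0.5 * v * eps * node.grad
    theta = node.theta + v * eps * (p * m_inv if m_inv is not None else p)
    logp, grad = target(theta)
    if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
        raise DivergenceSignal(theta, p)
    p = p + 0.5 * v * eps * grad
    return _Node(theta, p, float(logp), grad)


def build_tree(
    target: Callable,
    node: _Node,
    log_u: float,
    v: int,
    depth: int,
    eps: float,
    joint0: float,
    rng: np.random.Generator,
    m_diag: np.ndarray | None = None,
) -> TreeState:
    """Recursive doubling: a depth-k tree is two depth-(k-1) subtrees.

    The U-turn check runs at every merge (required for a correct stopping
    rule, not only at the outermost doubling); a state enters the candidate
    set when ``u <= exp(log f(theta) - p'M^{-1}p/2)``, and a slice violation
    by more than ``DIVERGENCE_THRESHOLD`` nats stops the trajectory as
    divergent.  Memory is O(depth): only boundary nodes and summaries live
    per recursion level.
    """
    m_inv = 1.0 / m_diag if m_diag is not None else None
    if depth == 0:
        try:
            new = _leapfrog_one(target, node, eps, v, m_inv)
        except DivergenceSignal:
            return TreeState(
                minus=node, plus=node, proposal=None, proposal_joint=-np.inf,
                n_valid=0, stop=True, alpha_sum=0.0, n_alpha=1,
                divergent=True, n_leapfrog=1,
            )
        joint = new.logp - kinetic_energy(new.p, m_diag)
        valid = log_u <= joint
        divergent = (log_u - joint) > DIVERGENCE_THRESHOLD
        return TreeState(
            minus=new, plus=new,
            proposal=new if valid else None,
            proposal_joint=joint if valid else -np.inf,
            n_valid=int(valid), stop=divergent,
            alpha_sum=float(min(1.0, np.exp(min(joint - joint0, 0.0)))),
            n_alpha=1, divergent=divergent, n_leapfrog=1,
        )
    first = build_tree(target, node, log_u, v, depth - 1, eps, joint0, rng, m_diag)
    if first.stop:
        return first
    outer = first.plus if v == 1 else first.minus
    second = build_tree(target, outer, log_u, v, depth - 1, eps, joint0, rng, m_diag)
    n_total = first.n_valid + second.n_valid
    proposal, joint = first.proposal, first.proposal_joint
    if second.n_valid > 0 and not second.stop:
        if n_total > 0 and rng.uniform() < second.n_valid / n_total:
            proposal, joint = second.proposal, second.proposal_joint
    minus = first.minus if v == 1 else second.minus
    plus = second.plus if v == 1 else first.plus
    stop = second.stop or uturn_stop(plus.theta, minus.theta, plus.p, minus.p)
    return TreeState(
        minus=minus, plus=plus, proposal=proposal, proposal_joint=joint,
        n_valid=n_total, stop=stop,
        alpha_sum=first.alpha_sum + second.alpha_sum,
        n_alpha=first.n_alpha + second.n_alpha,
        divergent=first.divergent or second.divergent,
        n_leapfrog=first.n_leapfrog + second.n_leapfrog,
    )


class _IterationResult(NamedTuple):
    node: _Node
    alpha: float
    depth: int
    divergent: bool
    depth_capped: bool
    n_leapfrog: int
    slice_ok: bool


def _nuts_iteration(
    target, node: _Node, eps: float, rng, m_diag, max_depth
) -> _IterationResult:
    dim = len(node.theta)
    scale = np.sqrt(m_diag) if m_diag is not None else 1.0
    p0 = rng.standard_normal(dim) * scale
    start = _Node(node.theta, p0, node.logp, node.grad)
    joint0 = node.logp - kinetic_energy(p0, m_diag)
    log_u = draw_slice(joint0, rng)
    minus = plus = start
    proposal, proposal_joint = start, joint0
    n_old = 1
    depth = 0
    stop = False
    alpha = 1.0
    divergent = False
    n_leap = 0
    while not stop and depth < max_depth:
        v = 1 if rng.uniform() < 0.5 else -1
        root = plus if v == 1 else minus
        tree = build_tree(target, root, log_u, v, depth, eps, joint0, rng, m_diag)
        if v == 1:
            plus = tree.plus
        else:
            minus = tree.minus
        if not tree.stop and tree.n_valid > 0:
            if transition_select(n_old, tree.n_valid, rng):
                proposal, proposal_joint = tree.proposal, tree.proposal_joint
        n_old += tree.n_valid
        alpha = accept_statistic(tree)  # statistic of the final doubling
        divergent = divergent or tree.divergent
        n_leap += tree.n_leapfrog
        stop = tree.stop or uturn_stop(plus.theta, minus.theta, plus.p, minus.p)
        depth += 1
    return _IterationResult(
        node=_Node(proposal.theta, proposal.p, proposal.logp, proposal.grad),
        alpha=float(alpha),
        depth=depth,
        divergent=divergent,
        depth_capped=depth >= max_depth and not stop,
        n_leapfrog=n_leap,
        slice_ok=bool(log_u <= proposal_joint),
    )


def find_reasonable_epsilon(
    target, theta: np.ndarray, rng: np.random.Generator,
    m_diag: np.ndarray | None = None,
) -> float:
    """Coarse doubling/halving search for a step size with Metropolis ratio
    about 0.5 after a single leapfrog step from the initial state."""
    eps = 1.0
    dim = len(theta)
    scale = np.sqrt(m_diag) if m_diag is not None else 1.0
    m_inv = 1.0 / m_diag if m_diag is not None else None
    logp, grad = target(theta)
    p0 = rng.standard_normal(dim) * scale
    joint0 = logp - kinetic_energy(p0, m_diag)
    node = _Node(theta, p0, logp, grad)

    def log_ratio(eps):
        try:
            new = _leapfrog_one(target, node, eps, 1, m_inv)
        except DivergenceSignal:
            return -np.inf
        return (new.logp - kinetic_energy(new.p, m_diag)) - joint0

    r = log_ratio(eps)
    direction = 1 if r > np.log(0.5) else -1
    for _ in range(64):
        eps = eps * (2.0 ** direction)
        r = log_ratio(eps)
        if direction == 1 and not r > np.log(0.5):
            break
        if direction == -1 and not r < np.log(0.5):
            break
        if eps < 1e-10 or eps > 1e7:
            break
    return eps


def nuts_sample(
    target: Callable,
    theta0: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    delta: float = 0.6,
    max_tree_depth: int = 10,
    m_diag: np.ndarray | None = None,
    adapt_mass: bool = False,
    epsilon: float | None = None,
    keep: Callable | None = None,
) -> dict:
    """Generic NUTS driver for any ``target(theta) -> (logp, grad)``.

    Returns kept draws (``thetas`` unless a ``keep`` callback consumes them)
    and per-iteration bookkeeping: adapted ``eps_trace``, tree depths,
    divergence flags and acceptance statistics.
    """
    theta0 = np.asarray(theta0, dtype=float)
    logp, grad = target(theta0)
    node = _Node(theta0, np.zeros_like(theta0), float(logp), grad)
    if epsilon is not None:
        eps = float(epsilon)
        da = None
    else:
        eps = find_reasonable_epsilon(target, theta0, rng, m_diag)
        da = DualAveragingState(
            mu=float(np.log(10.0 * eps)), log_eps=float(np.log(eps)), delta=delta
        )
    # expanding windows; the final (longest) one dominates the estimate, and
    # a Stan-style shrinkage toward unit variance regularizes short windows
    mass_windows = (
        {int(warmup * f) for f in (0.2, 0.45, 0.85)} if adapt_mass and warmup else set()
    )
    window_draws: list[np.ndarray] = []
    kept_thetas = [] if keep is None else None
    depths = np.zeros(n_iter, dtype=np.int64)
    alphas = np.zeros(n_iter)
    divergent = np.zeros(n_iter, dtype=bool)
    capped = np.zeros(n_iter, dtype=bool)
    eps_trace = np.zeros(n_iter)
    n_slice_violations = 0
    for it in range(n_iter):
        res = _nuts_iteration(target, node, eps, rng, m_diag, max_tree_depth)
        node = res.node
        depths[it] = res.depth
        alphas[it] = res.alpha
        divergent[it] = res.divergent
        capped[it] = res.depth_capped
        eps_trace[it] = eps
        n_slice_violations += not res.slice_ok
        if it < warmup:
            if da is not None:
                da = dual_averaging_update(da, res.alpha)
                eps = da.epsilon
            if adapt_mass:
                window_draws.append(node.theta)
                if it in mass_windows and len(window_draws) > 10:
                    w = len(window_draws)
                    var = np.var(np.array(window_draws), axis=0)
                    var = (w / (w + 5.0)) * var + (5.0 / (w + 5.0)) * 1e-3
                    m_diag = 1.0 / np.clip(var, 1e-8, None)
                    window_draws = []
                    if da is not None:
                        eps = find_reasonable_epsilon(target, node.theta, rng, m_diag)
                        da = DualAveragingState(
                            mu=float(np.log(10.0 * eps)),
                            log_eps=float(np.log(eps)),
                            delta=delta,
                        )
            if it == warmup - 1 and da is not None:
                eps = da.epsilon_frozen  # frozen for the sampling phase
        else:
            if keep is None:
                kept_thetas.append(node.theta.copy())
            else:
                keep(it - warmup, node.theta)
    kept = slice(warmup, None)
    post_div = int(divergent[kept].sum())
    n_post = n_iter - warmup
    if n_post > 0 and post_div > 0.10 * n_post:
        warnings.warn(
            f"NUTS: {post_div}/{n_post} post-warm-up iterations were divergent; "
            "the posterior geometry is not being integrated reliably",
            RuntimeWarning,
        )
    return {
        "thetas": np.array(kept_thetas) if keep is None else None,
        "epsilon": eps,
        "eps_trace": eps_trace,
        "depths": depths,
        "alphas": alphas,
        "divergent": divergent,
        "depth_capped": capped,
        "n_slice_violations": n_slice_violations,
        "mass_diag": m_diag,
    }


def nuts_run(
    data: ModelData, factor: RelationshipFactor, config: NUTSConfig
) -> SampleStore:
    """NUTS on the animal model; constrained-scale draws with per-draw h2."""
    rng = np.random.default_rng(config.seed)
    target = make_target(data, factor)
    p_, q_ = data.p, data.q
    dim = p_ + q_ + 2
    theta0 = initial_theta(dim, rng)
    n_kept = config.n_iter - config.warmup
    b_out = np.empty((n_kept, p_))
    la_out = np.empty(n_kept)
    le_out = np.empty(n_kept)
    u_mean = np.zeros(q_)

    def keep(k, theta):
        b_out[k] = theta[:p_]
        la_out[k] = theta[p_ + q_]
        le_out[k] = theta[p_ + q_ + 1]
        u_mean[:] += np.exp(0.5 * theta[p_ + q_]) * theta[p_ : p_ + q_]

    info = nuts_sample(
        target,
        theta0,
        config.n_iter,
        config.warmup,
        rng,
        delta=config.delta,
        max_tree_depth=config.max_tree_depth,
        adapt_mass=config.adapt_mass,
        epsilon=config.epsilon,
        keep=keep,
    )
    u_mean /= n_kept
    kept = slice(config.warmup, None)
    meta = {
        "sampler": "nuts",
        "n_iter": config.n_iter,
        "warmup": config.warmup,
        "delta": config.delta,
        "max_tree_depth": config.max_tree_depth,
        "seed": config.seed,
        "epsilon": info["epsilon"],
        "mean_accept_stat": float(np.mean(info["alphas"][kept])),
        "mean_tree_depth": float(np.mean(info["depths"][kept])),
        "tree_depth_hist": np.bincount(info["depths"][kept]).tolist(),
        "n_divergent": int(info["divergent"][kept].sum()),
        "n_depth_capped": int(info["depth_capped"][kept].sum()),
        "n_slice_violations": int(info["n_slice_violations"]),
        "eps_trace": info["eps_trace"][: config.warmup].tolist(),
    }
    return _assemble_store((b_out, la_out, le_out), u_mean, data, factor, meta)
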