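"""Training, Hessian-salience pruning, the train/prune recipe and k-fold CV.

Training minimizes the population loss J_ALE (mean over individuals of the
per-individual median absolute log error) with ADAM, back-propagating
through the exact PK simulator.  The gradient chain is assembled from three
exact pieces: the median subgradient (0.5/0.5 on the central pair for even
counts), complex-step simulator sensitivities dC/dtheta, and hand-coded
reverse-mode backprop through each symbolic-regression network.

Salience of a trainable scalar is S(gamma_k) = gamma_k^2 * H_k with H_k the
loss Hessian diagonal; covariate salience sums phi_ik^2 times the diagonal
of each individual's MdALE Hessian w.r.t. that network's covariate input.
Hessian diagonals are computed by central second differences of the loss
(no second-order autodiff framework is available); negative values — which
can occur away from an exact minimum — are clamped to zero with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from ._exceptions import DomainError, ScheduleError, TrainingError
from .error_metrics import median_and_weights
from .interface import Dataset
from .pk_model import PARAM_NAMES, build_grid, pack_grids, propagate
from .symreg_network import (
    SymRegNetworkBank,
    bank_forward_many,
    init_bank,
    net_backward,
    net_forward,
    normalize,
)

__all__ = [
    "TrainConfig",
    "PruneSchedule",
    "SalienceTable",
    "FitResult",
    "CrossValidationResult",
    "TrainingData",
    "prepare_training_data",
    "training_loss",
    "training_loss_grad",
    "theta_loss",
    "theta_loss_grad",
    "adam_minimize",
    "fit_theta_individuals",
    "two_stage_init_bank",
    "train",
    "parameter_salience",
    "covariate_salience",
    "prune_covariate",
    "prune_parameters",
    "run_recipe",
    "multi_restart",
    "cross_validate",
    "load_config",
]

logger = logging.getLogger(__name__)

_CSTEP = 1e-200
_PRED_FLOOR = 1e-12  # keeps ln() defined if a sample precedes any dose
_THETA_CAP = 1e6  # keeps the simulator finite while an optimizer explores


def _capped(theta: np.ndarray) -> np.ndarray:
    t = np.asarray(theta, dtype=float)
    t = np.where(np.isfinite(t), t, _THETA_CAP)
    return np.clip(t + _PRED_FLOOR, _PRED_FLOOR, _THETA_CAP)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    max_epochs: int = 5000
    convergence_window: int = 50
    convergence_rtol: float = 1e-5
    batch_mode: str | int = "full"  # "full" or a minibatch size
    #: quasi-Newton refinement after ADAM (iterations; 0 disables).  The
    #: salience theory assumes a sharp loss minimum; ADAM alone tends to
    #: stall on a plateau where Hessian diagonals come out negative.
    polish_iters: int = 100
    #: ADAM epochs on the smooth mean-squared-log-error surrogate before the
    #: median objective takes over (see theta_smooth_loss_grad).
    warmup_epochs: int = 0
    #: sup-norm gradient clip (the power base expression can produce
    #: astronomically steep directions early in training)
    grad_clip: float = 1e3
    #: how many warm-up/median alternations to run; extra cycles help the
    #: final (pruned) networks escape the median loss's plateaus
    cycles: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0:
            raise ScheduleError("learning_rate and max_epochs must be positive")
        for b in (self.adam_beta1, self.adam_beta2):
            if not 0.0 < b < 1.0:
                raise ScheduleError("ADAM betas must lie in (0, 1)")


@dataclass(frozen=True)
class PruneSchedule:
    target_covariates_per_network: int = 2
    first_parameter_prune_count: int = 10
    subsequent_parameter_prune_count: int = 1
    target_parameters_per_network: int = 12

    def __post_init__(self) -> None:
        if min(
            self.target_covariates_per_network,
            self.first_parameter_prune_count,
            self.subsequent_parameter_prune_count,
            self.target_parameters_per_network,
        ) < 1:
            raise ScheduleError("schedule counts must all be >= 1")


@dataclass
class SalienceTable:
    """target id -> salience; ``order`` fixes stable tie-breaking."""

    entries: dict
    order: list  # target ids in canonical (ascending-index) order

    def ranked(self) -> list:
        """Target ids sorted by ascending salience, ties by canonical order."""
        pos = {k: i for i, k in enumerate(self.order)}
        return sorted(self.entries, key=lambda k: (self.entries[k], pos[k]))


@dataclass
class FitResult:
    bank: SymRegNetworkBank
    loss_history: list
    final_loss: float
    restarts_used: int
    seed: int
    expressions: dict | None = None
    phase_log: list = field(default_factory=list)


@dataclass(frozen=True)
class CrossValidationResult:
    fold_losses: list
    mean: float
    min: float
    max: float


# ---------------------------------------------------------------------------
# dataset compilation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingData:
    """Dataset compiled to flat arrays for fast repeated loss evaluation."""

    ids: list
    phi: np.ndarray  # (n, n_phi) normalized covariates
    dts: np.ndarray  # (n, m) padded interval lengths
    rates: np.ndarray  # (n, m)
    obs_ind: np.ndarray  # (K,) individual index per observation
    obs_node: np.ndarray  # (K,) grid-node index per observation
    c_obs: np.ndarray  # (K,) observed concentrations
    offsets: np.ndarray  # (n + 1,) observation segment boundaries

    @property
    def n(self) -> int:
        return len(self.ids)

    def take(self, indices: Sequence[int]) -> "TrainingData":
        indices = np.asarray(indices, dtype=int)
        segs = [np.arange(self.offsets[i], self.offsets[i + 1]) for i in indices]
        flat = np.concatenate(segs) if segs else np.zeros(0, dtype=int)
        sizes = [s.size for s in segs]
        new_ind = np.repeat(np.arange(indices.size), sizes)
        return TrainingData(
            ids=[self.ids[i] for i in indices],
            phi=self.phi[indices],
            dts=self.dts[indices],
            rates=self.rates[indices],
            obs_ind=new_ind,
            obs_node=self.obs_node[flat],
            c_obs=self.c_obs[flat],
            offsets=np.concatenate(([0], np.cumsum(sizes))),
        )


def prepare_training_data(dataset: Dataset) -> TrainingData:
    spec = dataset.normalization
    grids = [
        build_grid(ind.dosing, ind.observations.times)
        for ind in dataset.individuals
    ]
    packed = pack_grids(grids)
    phi = np.stack(
        [normalize(ind.covariates(), spec) for ind in dataset.individuals]
    )
    obs_ind = np.repeat(np.arange(len(grids)), packed.n_obs)
    obs_node = np.concatenate(packed.obs_nodes)
    c_obs = np.concatenate(
        [ind.observations.values for ind in dataset.individuals]
    )
    offsets = np.concatenate(([0], np.cumsum(packed.n_obs)))
    return TrainingData(
        ids=[ind.id for ind in dataset.individuals],
        phi=phi, dts=packed.dts, rates=packed.rates,
        obs_ind=obs_ind, obs_node=obs_node, c_obs=c_obs, offsets=offsets,
    )


def _as_data(dataset) -> TrainingData:
    return dataset if isinstance(dataset, TrainingData) else prepare_training_data(dataset)


# ---------------------------------------------------------------------------
# loss on raw parameter matrices
# ---------------------------------------------------------------------------


def _loss_from_pred(c_pred: np.ndarray, data: TrainingData):
    """(J, per-individual MdALE, per-sample dJ/dC_pred)."""
    c = np.maximum(c_pred, _PRED_FLOOR)
    le = np.log(data.c_obs) - np.log(c)
    ale = np.abs(le)
    n = data.n
    md = np.empty(n)
    djdc = np.zeros_like(c)
    for i in range(n):
        lo, hi = data.offsets[i], data.offsets[i + 1]
        if hi == lo:
            raise DomainError(f"individual {data.ids[i]} has no observations")
        md[i], w = median_and_weights(ale[lo:hi])
        sgn = np.where(le[lo:hi] >= 0, 1.0, -1.0)
        djdc[lo:hi] = (w * sgn) * (-1.0 / c[lo:hi]) / n
    return float(md.mean()), md, djdc


def theta_loss(theta: np.ndarray, data: TrainingData):
    """J_ALE and per-individual MdALE for a parameter matrix theta (n, 6)."""
    nodes = propagate(_capped(theta), data.dts, data.rates)
    c_pred = nodes[data.obs_ind, data.obs_node]
    j, md, _ = _loss_from_pred(c_pred, data)
    return j, md


def theta_smooth_loss_grad(theta: np.ndarray, data: TrainingData):
    """Mean squared log error and its dJ/dtheta — a smooth warm-up surrogate.

    The median loss only passes gradient through one or two samples per
    individual, which lets optimizers park in valleys that fit half the
    samples and ignore the rest; a few warm-up epochs on this surrogate
    (every sample contributes) steer the parameters toward trajectories
    that fit the whole time course before the median objective takes over.
    """
    tc = _capped(theta)
    thc = np.tile(tc.astype(complex), (6, 1, 1))
    for j in range(6):
        thc[j, :, j] += 1j * _CSTEP
    nodes = propagate(thc, data.dts, data.rates)
    obs = nodes[:, data.obs_ind, data.obs_node]
    c = np.maximum(obs[0].real, _PRED_FLOOR)
    dcdth = (obs.imag / _CSTEP).T
    le = np.log(data.c_obs) - np.log(c)
    j_val = float(np.mean(le ** 2))
    djdc = (2.0 * le * (-1.0 / c)) / le.size
    dtheta = np.zeros(theta.shape)
    np.add.at(dtheta, data.obs_ind, djdc[:, None] * dcdth)
    dtheta[tc >= _THETA_CAP] = 0.0  # clipped: no useful gradient there
    return j_val, dtheta


def theta_loss_grad(theta: np.ndarray, data: TrainingData):
    """J_ALE, dJ/dtheta (n, 6) and per-individual MdALE, in one pass.

    Simulator sensitivities come from one batched complex-step evaluation:
    the real part is the unperturbed trajectory, the imaginary parts over
    the step are the six exact partial derivatives.
    """
    tc = _capped(theta)
    thc = np.tile(tc.astype(complex), (6, 1, 1))
    for j in range(6):
        thc[j, :, j] += 1j * _CSTEP
    nodes = propagate(thc, data.dts, data.rates)  # (6, n, m+1)
    obs = nodes[:, data.obs_ind, data.obs_node]  # (6, K)
    c_pred = obs[0].real
    dcdth = (obs.imag / _CSTEP).T  # (K, 6)
    j_val, md, djdc = _loss_from_pred(c_pred, data)
    floored = c_pred <= _PRED_FLOOR
    if np.any(floored):
        dcdth = np.where(floored[:, None], 0.0, dcdth)
    dtheta = np.zeros(theta.shape)
    np.add.at(dtheta, data.obs_ind, djdc[:, None] * dcdth)
    dtheta[tc >= _THETA_CAP] = 0.0
    return j_val, dtheta, md


# ---------------------------------------------------------------------------
# loss on network banks
# ---------------------------------------------------------------------------


def training_loss(bank: SymRegNetworkBank, dataset) -> float:
    """J_ALE of the bank on the dataset (Dataset or TrainingData)."""
    data = _as_data(dataset)
    theta = bank_forward_many(bank, data.phi)
    return theta_loss(theta, data)[0]


def _chain_to_gamma(bank, caches, dtheta):
    parts = []
    for jcol, name in enumerate(PARAM_NAMES):
        net = bank.networks[name]
        grads, _ = net_backward(net, caches[name], dtheta[:, jcol])
        for li, l in enumerate(net.layers):
            dW, db = grads[li]
            parts.append(dW[l.W_mask.astype(bool)])
            parts.append(db[l.b_mask.astype(bool)])
    return np.concatenate(parts) if parts else np.zeros(0)


def training_loss_grad(bank: SymRegNetworkBank, dataset):
    """(J_ALE, gradient w.r.t. the trainable vector gamma)."""
    data = _as_data(dataset)
    caches: dict = {}
    theta = bank_forward_many(bank, data.phi, caches)
    j_val, dtheta, _ = theta_loss_grad(theta, data)
    return j_val, _chain_to_gamma(bank, caches, dtheta)


def training_smooth_loss_grad(bank: SymRegNetworkBank, dataset):
    """(mean squared LE, gradient w.r.t. gamma) — the warm-up surrogate."""
    data = _as_data(dataset)
    caches: dict = {}
    theta = bank_forward_many(bank, data.phi, caches)
    j_val, dtheta = theta_smooth_loss_grad(theta, data)
    return j_val, _chain_to_gamma(bank, caches, dtheta)


# ---------------------------------------------------------------------------
# ADAM
# ---------------------------------------------------------------------------


def adam_minimize(
    fun: Callable[[np.ndarray], tuple],
    x0: np.ndarray,
    cfg: TrainConfig,
) -> tuple[np.ndarray, list]:
    """Minimize fun (returning (value, gradient)) from x0 with ADAM.

    Stops when the relative loss improvement over ``convergence_window``
    epochs drops below ``convergence_rtol``, or at ``max_epochs``.  Returns
    the best iterate seen and the per-epoch loss history.
    """
    x = np.asarray(x0, dtype=float).copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
    history: list = []
    best_x, best_j = x.copy(), np.inf
    for t in range(1, cfg.max_epochs + 1):
        j, g = fun(x)
        if not np.isfinite(j):
            raise TrainingError(
                f"non-finite loss at epoch {t} "
                f"(loss={j!r}, |x|={float(np.abs(x).max()):.3g}); "
                "check guard epsilons and learning rate"
            )
        # overflowed activations produce 0*inf = NaN grad components in the
        # capped region, where there is genuinely no usable gradient
        g = np.where(np.isfinite(g), g, 0.0)
        if cfg.grad_clip > 0 and g.size:
            gmax = np.abs(g).max()
            if gmax > cfg.grad_clip:
                g = g * (cfg.grad_clip / gmax)
        history.append(j)
        if t % 100 == 0:
            logger.debug("epoch %d: loss %.6g", t, j)
        if j < best_j:
            best_j, best_x = j, x.copy()
        w = cfg.convergence_window
        if len(history) > w:
            prev = history[-w - 1]
            rel = (prev - j) / max(abs(prev), 1e-300)
            if rel < cfg.convergence_rtol:
                break
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1 ** t)
        vh = v / (1 - b2 ** t)
        x = x - cfg.learning_rate * mh / (np.sqrt(vh) + eps)
    return best_x, history


def _lbfgs_safe(fun):
    """Wrap a value-and-grad callable for scipy: finite outputs always."""

    def wrapped(x):
        if not np.all(np.isfinite(x)):
            return 1e10, np.zeros_like(x)
        j, g = fun(x)
        g = np.where(np.isfinite(g), g, 0.0)
        if not np.isfinite(j):
            return 1e10, np.zeros_like(g)
        return j, g

    return wrapped


def train(
    bank: SymRegNetworkBank,
    dataset,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """ADAM-train the bank's unmasked parameters on the dataset.

    Full-batch by default (deterministic); ``batch_mode`` may name a
    minibatch size, in which case the per-epoch individual subset is drawn
    from a generator seeded with ``seed``.  The returned bank is a copy —
    masked entries are untouched by construction (they are not in gamma).
    """
    cfg = cfg or TrainConfig()
    data = _as_data(dataset)
    bank = bank.copy()
    work = bank.copy()
    from scipy import optimize

    def warm_fun(gamma):
        work.set_gamma(gamma)
        return training_smooth_loss_grad(work, data)

    def full_fun(g):
        work.set_gamma(g)
        return training_loss_grad(work, data)

    if cfg.batch_mode == "full":
        fun = full_fun
    else:
        size = int(cfg.batch_mode)
        rng = np.random.default_rng(seed)

        def fun(gamma):
            work.set_gamma(gamma)
            idx = rng.choice(data.n, size=min(size, data.n), replace=False)
            return training_loss_grad(work, data.take(np.sort(idx)))

    gamma = bank.get_gamma()
    history: list = []
    for _cycle in range(max(1, cfg.cycles)):
        if cfg.warmup_epochs > 0:
            warm_cfg = replace(
                cfg, max_epochs=cfg.warmup_epochs,
                convergence_window=cfg.warmup_epochs,  # no warm-up early stop
            )
            gamma, _ = adam_minimize(warm_fun, gamma, warm_cfg)
            if cfg.polish_iters > 0:
                # descend the surrogate's flat valley to high precision; the
                # loose scipy defaults quit orders of magnitude too early
                res = optimize.minimize(
                    _lbfgs_safe(warm_fun), gamma, jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": 4 * cfg.polish_iters,
                             "ftol": 1e-18, "gtol": 1e-14},
                )
                if np.isfinite(res.fun) and np.all(np.isfinite(res.x)):
                    gamma = res.x

        gamma, hist = adam_minimize(fun, gamma, cfg)
        history += hist
        if cfg.polish_iters > 0 and gamma.size:
            res = optimize.minimize(
                _lbfgs_safe(full_fun), gamma, jac=True, method="L-BFGS-B",
                options={"maxiter": cfg.polish_iters,
                         "ftol": 1e-16, "gtol": 1e-12},
            )
            if (np.isfinite(res.fun) and np.all(np.isfinite(res.x))
                    and res.fun < min(history)):
                gamma = res.x
                history.append(float(res.fun))
    bank.set_gamma(gamma)
    final = training_loss(bank, data)
    history.append(final)
    return FitResult(
        bank=bank, loss_history=history, final_loss=final,
        restarts_used=1, seed=seed,
    )


# ---------------------------------------------------------------------------
# two-stage initialization
# ---------------------------------------------------------------------------


def fit_theta_individuals(
    data, seed: int = 0, n_starts: int = 0, maxiter: int = 500
) -> np.ndarray:
    """Per-individual parameter estimates via the smooth surrogate loss.

    Returns an (n, 6) matrix.  Each individual is fit independently in
    log-parameter space with tightly-toleranced L-BFGS from a physiologic
    center (plus ``n_starts`` random restarts).  Used to seed the networks;
    the estimates need not be perfect, only informative.
    """
    from scipy import optimize

    data = _as_data(data)
    rng = np.random.default_rng(seed)
    center = np.log(np.array([5e-3, 2e-2, 8e-3, 1e-2, 3e-3, 10.0]))
    theta_hat = np.empty((data.n, 6))
    for i in range(data.n):
        sub = data.take([i])

        def fun(eta):
            th = np.exp(eta)[None, :]
            j, dth = theta_smooth_loss_grad(th, sub)
            return j, dth[0] * np.exp(eta)

        best = None
        starts = [center] + [
            center + rng.normal(0, 1.0, 6) for _ in range(n_starts)
        ]
        for x0 in starts:
            r = optimize.minimize(
                _lbfgs_safe(fun), x0, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-18, "gtol": 1e-14},
            )
            if best is None or r.fun < best.fun:
                best = r
        theta_hat[i] = np.exp(best.x)
    return theta_hat


def two_stage_init_bank(
    dataset, seed: int = 0, architecture=None
) -> SymRegNetworkBank:
    """Initialize a dense bank from two-stage estimates.

    Stage one fits each individual's parameter vector; stage two seeds every
    network's pass-through affine path (z11 -> x21 -> z31) with the ordinary
    least-squares affine regression of those estimates on the normalized
    covariates.  The product/power/division paths keep small random input
    weights but contribute exactly zero output initially (their mixing
    weights start at 0), so training grows nonlinear structure only where
    the data demands it.  All entries remain trainable and unmasked.
    """
    data = _as_data(dataset)
    theta_hat = fit_theta_individuals(data, seed=seed)
    bank = init_bank(seed, architecture)
    rng = np.random.default_rng(seed)
    X = np.column_stack([data.phi, np.ones(data.n)])
    small = 0.05
    for j, name in enumerate(PARAM_NAMES):
        net = bank.networks[name]
        coef, *_ = np.linalg.lstsq(X, theta_hat[:, j], rcond=None)
        l1, l2, l3 = net.layers
        n_phi = l1.W.shape[1]
        l1.W[:] = rng.normal(0, small, l1.W.shape)
        l1.b[:] = rng.normal(0, small, l1.b.shape)
        l2.W[:] = rng.normal(0, small, l2.W.shape)
        l2.b[:] = rng.normal(0, small, l2.b.shape)
        l3.W[:] = 0.0
        l3.b[:] = 0.0
        l1.W[0, :] = coef[:n_phi]
        l1.b[0] = coef[n_phi]
        l2.W[0, :] = [1.0, 0.0, 0.0]
        l2.b[0] = 0.0
        l2.W[:, 1:] = 0.0  # layer-1 product/power outputs start silent
        l3.W[0, 0] = 1.0  # pass-through; product/division outputs silent
        for l in (l1, l2, l3):
            l.apply_masks()
    return bank


# ---------------------------------------------------------------------------
# salience
# ---------------------------------------------------------------------------


def parameter_salience(
    bank: SymRegNetworkBank, dataset, step: float = 1e-3
) -> SalienceTable:
    """S(gamma_k) = gamma_k^2 * H_k, H_k by central second differences."""
    data = _as_data(dataset)
    work = bank.copy()
    gamma = work.get_gamma()
    index = work.gamma_index()
    j0 = training_loss(work, data)
    entries = {}
    n_negative = 0
    for k, key in enumerate(index):
        if gamma[k] == 0.0:
            entries[key] = 0.0  # salience vanishes with the parameter value
            continue
        h = step * (1.0 + abs(gamma[k]))
        g = gamma.copy()
        g[k] = gamma[k] + h
        work.set_gamma(g)
        jp = training_loss(work, data)
        g[k] = gamma[k] - h
        work.set_gamma(g)
        jm = training_loss(work, data)
        hess = (jp - 2.0 * j0 + jm) / (h * h)
        if hess < 0:
            n_negative += 1
            hess = 0.0
        entries[key] = gamma[k] ** 2 * hess
    if n_negative:
        warnings.warn(
            f"{n_negative} negative Hessian diagonal(s) clamped to 0 "
            "(training stopped short of an exact minimum)",
            stacklevel=2,
        )
    return SalienceTable(entries=entries, order=list(index))


def covariate_salience(
    bank: SymRegNetworkBank, dataset, step: float = 1e-3
) -> SalienceTable:
    """Per-(network, covariate) salience sum_i phi_ik^2 (H_i)_k.

    (H_i)_k is the second derivative of individual i's MdALE w.r.t. the
    normalized covariate k as fed into that one network (other networks see
    the unperturbed value), by central second differences.  Covariates whose
    first-layer column is fully masked score exactly zero.
    """
    data = _as_data(dataset)
    theta0 = bank_forward_many(bank, data.phi)
    _, md0 = theta_loss(theta0, data)
    entries = {}
    order = []
    for jcol, name in enumerate(PARAM_NAMES):
        net = bank.networks[name]
        active = set(net.active_covariates().tolist())
        for k in range(net.n_phi):
            key = (name, k)
            order.append(key)
            if k not in active:
                entries[key] = 0.0
                continue
            mds = []
            for sgn in (+1.0, -1.0):
                phi_p = data.phi.copy()
                phi_p[:, k] += sgn * step
                theta_p = theta0.copy()
                theta_p[:, jcol] = net_forward(net, phi_p)[0]
                mds.append(theta_loss(theta_p, data)[1])
            hess_i = (mds[0] - 2.0 * md0 + mds[1]) / (step * step)
            hess_i = np.maximum(hess_i, 0.0)
            entries[key] = float(np.sum(data.phi[:, k] ** 2 * hess_i))
    return SalienceTable(entries=entries, order=order)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def prune_covariate(
    bank: SymRegNetworkBank, network_id: str, covariate_index: int
) -> SymRegNetworkBank:
    """Mask every first-layer weight of one covariate in one network."""
    bank = bank.copy()
    net = bank.networks[network_id]
    l1 = net.layers[0]
    if not l1.W_mask[:, covariate_index].any():
        raise ScheduleError(
            f"covariate {covariate_index} already pruned in {network_id}"
        )
    if net.active_covariates().size <= 1:
        raise ScheduleError(
            f"cannot prune the last covariate of network {network_id}"
        )
    l1.W_mask[:, covariate_index] = 0
    l1.apply_masks()
    return bank


def prune_parameters(
    bank: SymRegNetworkBank,
    count: int,
    salience: SalienceTable | None = None,
    dataset=None,
    networks: Sequence[str] | None = None,
) -> SymRegNetworkBank:
    """Mask the ``count`` lowest-salience unmasked scalars (stable ties).

    ``networks`` restricts the candidate set (used by the per-network
    schedule).  A salience table may be supplied; otherwise it is computed
    from ``dataset``.
    """
    if salience is None:
        if dataset is None:
            raise ScheduleError("need a salience table or a dataset")
        salience = parameter_salience(bank, dataset)
    allowed = set(networks) if networks is not None else None
    candidates = [
        key for key in salience.ranked()
        if allowed is None or key[0] in allowed
    ]
    if count >= len(candidates):
        raise ScheduleError(
            f"cannot prune {count} of {len(candidates)} remaining parameters"
        )
    bank = bank.copy()
    for key in candidates[:count]:
        name, li, kind, flat = key
        layer = bank.networks[name].layers[li]
        if kind == "W":
            layer.W_mask.flat[flat] = 0
        else:
            layer.b_mask.flat[flat] = 0
        layer.apply_masks()
    return bank


# ---------------------------------------------------------------------------
# the recipe
# ---------------------------------------------------------------------------


def run_recipe(
    dataset,
    schedule: PruneSchedule | None = None,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    init: str = "two_stage",
) -> FitResult:
    """Full train/prune sequence from a dense nominal bank to expressions.

    1 init; 2 train; 3-5 covariate-salience pruning (one covariate per
    iteration, retraining after each) until every network is at its
    covariate target; 6-9 parameter-salience pruning (N in the first
    iteration, then one per iteration, per network above target, retraining
    after each); 10 final train; 11 expression extraction.

    ``init`` selects the step-1 initialization: "two_stage" (default) seeds
    the networks from per-individual parameter estimates via
    :func:`two_stage_init_bank`; "random" uses :func:`init_bank`.
    """
    from .expression_export import extract_expression

    schedule = schedule or PruneSchedule()
    cfg = cfg or TrainConfig()
    # post-prune retrains start near a minimum: lighter budget, and no
    # smooth warm-up (it can pull the iterate out of a good median basin)
    retrain_cfg = replace(
        cfg,
        warmup_epochs=0,
        max_epochs=min(cfg.max_epochs, 300),
        polish_iters=min(cfg.polish_iters, 150) if cfg.polish_iters else 0,
        cycles=1,
    )
    final_cfg = replace(cfg, warmup_epochs=0)
    data = _as_data(dataset)
    phase_log = []
    history: list = []

    def _step(stage, action, *args, **kwargs):
        try:
            return action(*args, **kwargs)
        except Exception as exc:
            raise TrainingError(f"recipe {stage} failed: {exc}") from exc

    if init == "two_stage":
        bank = _step("step 1 (init)", two_stage_init_bank, data, seed)
        # the smooth warm-up would drag the seeded iterate away from the
        # two-stage solution; go straight at the median objective
        initial_cfg = replace(cfg, warmup_epochs=0)
    elif init == "random":
        bank = init_bank(seed)
        initial_cfg = cfg
    else:
        raise ScheduleError(f"unknown init strategy {init!r}")
    fit = _step("step 2 (train)", train, bank, data, initial_cfg, seed)
    bank = fit.bank
    history += fit.loss_history
    phase_log.append(("train:init", fit.final_loss))

    target_cov = schedule.target_covariates_per_network
    while True:
        excess = [
            name for name in PARAM_NAMES
            if bank.networks[name].active_covariates().size > target_cov
        ]
        if not excess:
            break
        sal = _step("step 3 (covariate salience)", covariate_salience, bank, data)
        pos = {k: i for i, k in enumerate(sal.order)}
        cand = [
            (name, k) for (name, k) in sal.entries
            if name in excess
            and k in bank.networks[name].active_covariates()
        ]
        victim = min(cand, key=lambda key: (sal.entries[key], pos[key]))
        bank = _step("step 4 (covariate prune)", prune_covariate, bank, *victim)
        logger.info("pruned covariate %s from network %s", victim[1], victim[0])
        phase_log.append((f"prune_covariate:{victim[0]}:{victim[1]}", None))
        fit = _step("step 2 (retrain)", train, bank, data, retrain_cfg, seed)
        bank = fit.bank
        history += fit.loss_history
        logger.info("retrain after covariate prune: J_ALE %.6g", fit.final_loss)
        phase_log.append(("train:cov_prune", fit.final_loss))

    target_par = schedule.target_parameters_per_network
    first = True
    while True:
        excess = {
            name: bank.networks[name].n_unmasked() - target_par
            for name in PARAM_NAMES
            if bank.networks[name].n_unmasked() > target_par
        }
        if not excess:
            break
        sal = _step("step 7 (parameter salience)", parameter_salience, bank, data)
        per_net = (
            schedule.first_parameter_prune_count
            if first
            else schedule.subsequent_parameter_prune_count
        )
        for name, over in excess.items():
            cnt = min(per_net, over)
            bank = _step(
                "step 8 (parameter prune)", prune_parameters,
                bank, cnt, sal, networks=[name],
            )
            phase_log.append((f"prune_parameters:{name}:{cnt}", None))
        first = False
        fit = _step("step 6 (retrain)", train, bank, data, retrain_cfg, seed)
        bank = fit.bank
        history += fit.loss_history
        logger.info("retrain after parameter prune: J_ALE %.6g", fit.final_loss)
        phase_log.append(("train:param_prune", fit.final_loss))

    fit = _step("step 10 (final train)", train, bank, data, final_cfg, seed)
    bank = fit.bank
    history += fit.loss_history
    phase_log.append(("train:final", fit.final_loss))

    expressions = _step("step 11 (convert)", extract_expression, bank)
    final = training_loss(bank, data)
    return FitResult(
        bank=bank, loss_history=history, final_loss=final,
        restarts_used=1, seed=seed, expressions=expressions,
        phase_log=phase_log,
    )


def multi_restart(
    dataset,
    schedule: PruneSchedule | None = None,
    cfg: TrainConfig | None = None,
    n_restarts: int = 8,
    base_seed: int = 0,
) -> FitResult:
    """Run the recipe ``n_restarts`` times, keep the best training fit."""
    if n_restarts < 1:
        raise ScheduleError("n_restarts must be >= 1")
    data = _as_data(dataset)
    best: FitResult | None = None
    failures = []
    for s in range(base_seed, base_seed + n_restarts):
        try:
            fit = run_recipe(data, schedule, cfg, seed=s)
        except TrainingError as exc:
            failures.append((s, str(exc)))
            continue
        if best is None or fit.final_loss < best.final_loss:
            best = fit
    if best is None:
        raise TrainingError(f"all {n_restarts} restarts failed: {failures}")
    best.restarts_used = n_restarts
    return best


def cross_validate(
    dataset: Dataset,
    schedule: PruneSchedule | None = None,
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """k-fold CV over individuals: train on k-1 folds, score J_ALE held-out."""
    if k < 2:
        raise ScheduleError("k must be >= 2")
    n = len(dataset)
    if n < k:
        raise ScheduleError(f"dataset of {n} individuals cannot form {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    losses = []
    for f, fold in enumerate(folds):
        if fold.size == 0:
            raise ScheduleError("empty validation fold")
        val_ids = {dataset.individuals[i].id for i in fold}
        train_set = dataset.subset(
            [ind.id for ind in dataset.individuals if ind.id not in val_ids]
        )
        val_set = dataset.subset(val_ids)
        fit = run_recipe(train_set, schedule, cfg, seed=seed + f)
        losses.append(training_loss(fit.bank, val_set))
    return CrossValidationResult(
        fold_losses=losses,
        mean=float(np.mean(losses)),
        min=float(np.min(losses)),
        max=float(np.max(losses)),
    )


# ---------------------------------------------------------------------------
# config / manifests
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """YAML file -> {'train': TrainConfig, 'schedule': PruneSchedule, ...}."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    train_cfg = TrainConfig(**doc.get("train", {}))
    schedule = PruneSchedule(**doc.get("schedule", {}))
    return {
        "train": train_cfg,
        "schedule": schedule,
        "seed": int(doc.get("seed", 0)),
        "restarts": int(doc.get("restarts", 8)),
    }


def write_manifest(path, *, config: dict, seed: int, loss_history: list,
                   final_loss: float) -> None:
    doc = {
        "seed": seed,
        "config": {
            k: (v.__dict__ if hasattr(v, "__dict__") else v)
            for k, v in config.items()
        },
        "final_loss": final_loss,
        "loss_history": [float(x) for x in loss_history],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
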