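"""Three-compartment mammillary PK model: exact, differentiable simulation.

The model is the linear time-invariant system

    dx1/dt = -(k10 + k12 + k13) x1 + k21 x2 + k31 x3 + u / V1
    dx2/dt =   k12 x1 - k21 x2
    dx3/dt =   k13 x1 - k31 x3

with drug administered at rate ``u`` [ug/s] into the central compartment,
whose concentration x1 [ug/L] is the observed output.  Between dose events
the input is constant, so the state is propagated *exactly* with a matrix
exponential of the augmented 4x4 system (state + constant-input particular
solution); observation times are merged into the event grid and never
interpolated.

Derivatives of the concentration output with respect to the six parameters
are exposed through :func:`simulate_sensitivities`, which uses complex-step
differentiation (the propagation map is holomorphic in the rates, so the
imaginary part at step 1e-200 is the exact derivative to machine precision).

Units throughout: time s, concentration ug/L, rate ug/s, volume L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._exceptions import DomainError, InvalidParameterError

__all__ = [
    "PKRates",
    "PKClearances",
    "DosingProfile",
    "ConcentrationSeries",
    "rates_to_clearances",
    "clearances_to_rates",
    "simulate",
    "simulate_sensitivities",
    "steady_state_concentration",
    "SimulationGrid",
    "build_grid",
    "pack_grids",
    "propagate",
]

PARAM_NAMES = ("k10", "k12", "k13", "k21", "k31", "V1")

#: complex-step size; no subtractive cancellation, so it can be tiny
_CSTEP = 1e-200


def _check_positive_finite(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0.0:
        raise InvalidParameterError(
            f"{name} must be strictly positive and finite, got {value!r}"
        )


@dataclass(frozen=True)
class PKRates:
    """Rate-constant parameterization (k10..k31 [1/s], V1 [L])."""

    k10: float
    k12: float
    k13: float
    k21: float
    k31: float
    V1: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            _check_positive_finite(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "PKRates":
        return cls(*(float(v) for v in np.asarray(theta, dtype=float)))


@dataclass(frozen=True)
class PKClearances:
    """Volume/clearance parameterization (CL,Q2,Q3 [L/s]; V1,V2,V3 [L])."""

    CL: float
    Q2: float
    Q3: float
    V1: float
    V2: float
    V3: float

    def __post_init__(self) -> None:
        for name in ("CL", "Q2", "Q3", "V1", "V2", "V3"):
            _check_positive_finite(name, getattr(self, name))


def rates_to_clearances(p: PKRates) -> PKClearances:
    """Convert rate constants to the volume/clearance parameterization."""
    return PKClearances(
        CL=p.k10 * p.V1,
        Q2=p.k12 * p.V1,
        Q3=p.k13 * p.V1,
        V1=p.V1,
        V2=(p.k12 / p.k21) * p.V1,
        V3=(p.k13 / p.k31) * p.V1,
    )


def clearances_to_rates(c: PKClearances) -> PKRates:
    """Convert volumes/clearances back to rate constants."""
    return PKRates(
        k10=c.CL / c.V1,
        k12=c.Q2 / c.V1,
        k13=c.Q3 / c.V1,
        k21=c.Q2 / c.V2,
        k31=c.Q3 / c.V3,
        V1=c.V1,
    )


@dataclass(frozen=True)
class DosingProfile:
    """Piecewise-constant infusion: each rate holds until the next event."""

    event_times: np.ndarray  # s, strictly increasing, first >= 0
    rates: np.ndarray  # ug/s, one per event

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "rates", rates)
        if times.ndim != 1 or rates.shape != times.shape:
            raise DomainError("event_times and rates must be 1-D and equal length")
        if times.size and times[0] < 0:
            raise DomainError("first event time must be >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("event times must be strictly increasing")
        if np.any(rates < 0):
            raise DomainError("infusion rates must be non-negative")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Timed central-compartment concentrations."""

    times: np.ndarray  # s, non-decreasing
    values: np.ndarray  # ug/L

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise DomainError("times and values must be 1-D and equal length")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise DomainError("observation times must be non-decreasing")

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# batched matrix exponential (Pade-13 scaling and squaring)
# ---------------------------------------------------------------------------

_PADE13_B = (
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0, 670442572800.0,
    33522128640.0, 1323241920.0, 40840800.0, 960960.0, 16380.0, 182.0, 1.0,
)
_THETA13 = 5.371920351148152


def expm_batched(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack (..., k, k) of small matrices.

    Pade-13 with a squaring count shared across the stack (the maximum any
    member needs); members with smaller norms only gain accuracy from the
    extra scaling.  Works for real and complex input and makes no assumption
    about eigenvalue multiplicity.
    """
    M = np.asarray(M)
    k = M.shape[-1]
    norms = np.abs(M).sum(axis=-2).max(axis=-1)  # 1-norms
    eta = float(np.max(norms)) if norms.size else 0.0
    if not np.isfinite(eta):
        raise InvalidParameterError("non-finite entries in system matrix")
    s = max(0, int(np.ceil(np.log2(eta / _THETA13)))) if eta > _THETA13 else 0
    A = M / (2.0 ** s)
    ident = np.broadcast_to(np.eye(k, dtype=A.dtype), A.shape)
    b = _PADE13_B
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A2 @ A4
    U = A @ (
        A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
        + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * ident
    )
    V = (
        A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
        + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * ident
    )
    R = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        R = R @ R
    return R


def system_matrix(theta: np.ndarray) -> np.ndarray:
    """3x3 system matrix A from parameter stack theta (..., 6)."""
    theta = np.asarray(theta)
    k10, k12, k13, k21, k31 = (theta[..., i] for i in range(5))
    A = np.zeros(theta.shape[:-1] + (3, 3), dtype=theta.dtype)
    A[..., 0, 0] = -(k10 + k12 + k13)
    A[..., 0, 1] = k21
    A[..., 0, 2] = k31
    A[..., 1, 0] = k12
    A[..., 1, 1] = -k21
    A[..., 2, 0] = k13
    A[..., 2, 2] = -k31
    return A


# ---------------------------------------------------------------------------
# event grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationGrid:
    """Precompiled union of dose events and observation times.

    ``dts[j]``/``rates[j]`` describe interval j between node j and node j+1;
    node 0 is t=0.  ``obs_nodes[k]`` is the node index whose time equals the
    k-th observation time.
    """

    dts: np.ndarray  # (m,)
    rates: np.ndarray  # (m,)
    obs_nodes: np.ndarray  # (n_obs,) int
    obs_times: np.ndarray  # (n_obs,) original (possibly unsorted) times


def build_grid(dosing: DosingProfile, obs_times: Sequence[float]) -> SimulationGrid:
    obs = np.asarray(obs_times, dtype=float)
    if obs.ndim != 1:
        raise DomainError("obs_times must be 1-D")
    if obs.size and obs.min() < 0:
        raise DomainError("observation times must be >= 0")
    nodes = np.unique(np.concatenate(([0.0], dosing.event_times, obs)))
    dts = np.diff(nodes)
    # rate on [nodes[j], nodes[j+1]) = rate of the latest event <= nodes[j]
    if dosing.event_times.size:
        idx = np.searchsorted(dosing.event_times, nodes[:-1], side="right") - 1
        rates = np.where(idx >= 0, dosing.rates[np.maximum(idx, 0)], 0.0)
    else:
        rates = np.zeros_like(dts)
    obs_nodes = np.searchsorted(nodes, obs)
    return SimulationGrid(dts=dts, rates=rates, obs_nodes=obs_nodes, obs_times=obs)


@dataclass(frozen=True)
class PackedGrids:
    """Grids of several individuals padded to a common interval count."""

    dts: np.ndarray  # (n, m_max), padded with 0
    rates: np.ndarray  # (n, m_max), padded with 0
    obs_nodes: list  # per-individual int arrays
    n_obs: np.ndarray  # (n,)


def pack_grids(grids: Sequence[SimulationGrid]) -> PackedGrids:
    n = len(grids)
    m = max((g.dts.size for g in grids), default=0)
    dts = np.zeros((n, m))
    rates = np.zeros((n, m))
    for i, g in enumerate(grids):
        dts[i, : g.dts.size] = g.dts
        rates[i, : g.rates.size] = g.rates
    return PackedGrids(
        dts=dts,
        rates=rates,
        obs_nodes=[g.obs_nodes for g in grids],
        n_obs=np.array([g.obs_nodes.size for g in grids]),
    )


def _propagate_pade(theta, dts, rates):
    n, m = dts.shape
    A = system_matrix(theta)  # (..., n, 3, 3)
    V1 = theta[..., 5]
    lead = theta.shape[:-2]
    M = np.zeros(lead + (n, m, 4, 4), dtype=theta.dtype)
    M[..., :3, :3] = A[..., :, None, :, :] * dts[..., :, :, None, None]
    M[..., 0, 3] = rates * dts / V1[..., :, None]
    E = expm_batched(M)
    x = np.zeros(lead + (n, 3), dtype=theta.dtype)
    out = np.zeros(lead + (n, m + 1), dtype=theta.dtype)
    for j in range(m):
        x = np.einsum("...ab,...b->...a", E[..., j, :3, :3], x) + E[..., j, :3, 3]
        out[..., j + 1] = x[..., 0]
    return out


def _propagate_eig(theta, dts, rates):
    """Fast path: A is constant per individual, so diagonalize once and
    advance in the eigenbasis with elementwise exponentials.

    Returns None when the eigensystem looks ill-conditioned (possible
    coincident eigenvalues), in which case the caller falls back to the
    Pade route, which makes no diagonalizability assumption.
    """
    A = system_matrix(theta).astype(complex)
    lam, V = np.linalg.eig(A)  # (..., n, 3), (..., n, 3, 3)
    if np.abs(np.linalg.det(V)) .min() < 1e-8:
        return None
    Vinv = np.linalg.inv(V)
    # input direction e1 * u/V1 in the eigenbasis
    c0 = Vinv[..., :, 0]  # (..., n, 3)
    V1 = theta[..., 5]
    row0 = V[..., 0, :]  # (..., n, 3)
    lam_dt = lam[..., :, None, :] * dts[:, :, None]  # (..., n, m, 3)
    grow = np.exp(lam_dt)
    lam_safe = np.where(np.abs(lam) < 1e-300, 1e-300, lam)
    phi1 = np.expm1(lam_dt) / lam_safe[..., :, None, :]
    drive = (rates / V1[..., :, None])[..., :, :, None] * c0[..., :, None, :]
    y = np.zeros_like(c0)
    lead = theta.shape[:-2]
    n, m = dts.shape
    out = np.zeros(lead + (n, m + 1), dtype=complex)
    for j in range(m):
        y = grow[..., j, :] * y + phi1[..., j, :] * drive[..., j, :]
        out[..., j + 1] = np.einsum("...a,...a->...", row0, y)
    return out


def propagate(
    theta: np.ndarray, dts: np.ndarray, rates: np.ndarray,
    method: str = "auto",
) -> np.ndarray:
    """Exact node-by-node propagation of the central concentration.

    Parameters
    ----------
    theta : (..., n, 6) parameter stack (real or complex).
    dts, rates : (n, m) interval lengths and infusion rates.
    method : "auto" (eigendecomposition fast path with Pade fallback),
        "eig", or "pade".

    Returns
    -------
    (..., n, m + 1) central-compartment concentration at every node.
    """
    theta = np.asarray(theta)
    dts = np.asarray(dts, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if not np.all(np.isfinite(theta.real)):
        raise InvalidParameterError("non-finite PK parameters")
    if method in ("auto", "eig"):
        out = _propagate_eig(theta, dts, rates)
        if out is not None:
            bad = not np.all(np.isfinite(out.real))
            if not bad:
                if np.iscomplexobj(theta):
                    return out
                # real input: imaginary residue is eig roundoff
                return out.real
        if method == "eig":
            raise InvalidParameterError("eigendecomposition path failed")
    return _propagate_pade(theta, dts, rates)


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------


def simulate(
    p: PKRates, dosing: DosingProfile, obs_times: Sequence[float]
) -> ConcentrationSeries:
    """Central concentration at ``obs_times`` from a zero initial state."""
    grid = build_grid(dosing, obs_times)
    nodes = propagate(p.as_array()[None, :], grid.dts[None, :], grid.rates[None, :])
    values = nodes[0][grid.obs_nodes]
    return ConcentrationSeries(times=grid.obs_times, values=values)


def simulate_sensitivities(
    p: PKRates, dosing: DosingProfile, obs_times: Sequence[float]
) -> tuple[ConcentrationSeries, np.ndarray]:
    """Concentrations plus the exact Jacobian dC/dtheta, shape (n_obs, 6).

    Complex-step differentiation: each parameter is perturbed by 1e-200 i;
    the imaginary part over the step is the derivative, the real part is the
    unperturbed value (exact in floating point at this step size).
    """
    grid = build_grid(dosing, obs_times)
    theta = p.as_array()
    thc = np.tile(theta.astype(complex), (6, 1, 1))  # (6, 1, 6)
    for j in range(6):
        thc[j, 0, j] += 1j * _CSTEP
    nodes = propagate(thc, grid.dts[None, :], grid.rates[None, :])  # (6, 1, m+1)
    obs = nodes[:, 0, :][:, grid.obs_nodes]  # (6, n_obs)
    jac = (obs.imag / _CSTEP).T  # (n_obs, 6)
    # recompute values on the real path so they match simulate() exactly
    # (real and complex LAPACK eig round differently at the 1e-15 level)
    return simulate(p, dosing, obs_times), jac


def steady_state_concentration(p: PKRates, u: float) -> float:
    """Steady-state central concentration under constant infusion rate u."""
    if u < 0:
        raise DomainError("infusion rate must be non-negative")
    return u / (p.k10 * p.V1)
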