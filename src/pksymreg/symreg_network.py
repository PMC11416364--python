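"""Symbolic-regression networks: pruned affine layers with algebraic bases.

One small three-layer network per PK parameter maps the normalized covariate
vector to that parameter.  Each layer is an affine map z = W x + b followed
by a vector of *base expressions* in place of conventional activations:

    g1(z) = [z1, z2*z3, |z4|^z5]       (identity, product, power)
    g2(z) = [z1, z2*z3, z4/(z5 + 1)]   (identity, product, guarded division)
    g3(z) = |z|                         (guarantees a positive PK parameter)

Pruning is expressed through binary masks on weights and biases: a masked
entry is exactly zero, excluded from the trainable vector gamma, and never
updated.  The bank holds six such networks (k10, k12, k13, k21, k31, V1).

Gradients are provided by hand-coded reverse-mode backprop through this
fixed architecture (vectorized across individuals); validated against
finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import FormatError, StructuralError
from .pk_model import PARAM_NAMES, PKRates

__all__ = [
    "EPS_POW",
    "EPS_DIV",
    "COVARIATE_NAMES",
    "NormalizationSpec",
    "normalize",
    "normalize_many",
    "base_expr_g1",
    "base_expr_g2",
    "base_expr_g3",
    "SymRegLayer",
    "layer_forward",
    "SymRegNetwork",
    "SymRegNetworkBank",
    "ArchitectureConfig",
    "init_bank",
    "net_forward",
    "net_backward",
    "bank_forward",
    "bank_forward_many",
]

EPS_POW = 1e-6  # |base| floor inside the power expression
EPS_DIV = 1e-6  # |denominator| floor inside the division expression

COVARIATE_NAMES = ("age", "weight", "bmi", "gender", "site")


@dataclass(frozen=True)
class NormalizationSpec:
    """Covariate scaling: continuous /max into [0,1]; categorical to ±0.5."""

    age_max: float = 88.0  # years
    weight_max: float = 160.0  # kg
    bmi_max: float = 52.8  # kg/m^2
    gender_map: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.5, "F": -0.5}
    )
    site_map: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.5, "V": -0.5}
    )

    def __post_init__(self) -> None:
        for name in ("age_max", "weight_max", "bmi_max"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be strictly positive")
        for name in ("gender_map", "site_map"):
            if len(getattr(self, name)) != 2:
                raise FormatError(f"{name} must map exactly two labels")

    def to_dict(self) -> dict:
        return {
            "age_max": self.age_max,
            "weight_max": self.weight_max,
            "bmi_max": self.bmi_max,
            "gender_map": dict(self.gender_map),
            "site_map": dict(self.site_map),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(**d)


def _categorical(value: str, mapping: Mapping[str, float], what: str) -> float:
    try:
        return mapping[value]
    except KeyError:
        raise FormatError(
            f"unknown {what} label {value!r}; expected one of {sorted(mapping)}"
        ) from None


def normalize(
    raw: Mapping[str, object], spec: NormalizationSpec | None = None
) -> np.ndarray:
    """Normalized covariate vector [age, weight, bmi, gender, site].

    Out-of-range continuous values are allowed (extrapolation) but warned
    about; unknown categorical labels raise :class:`FormatError`.
    """
    spec = spec or NormalizationSpec()
    age = float(raw["age"]) / spec.age_max
    wgt = float(raw["weight"]) / spec.weight_max
    bmi = float(raw["bmi"]) / spec.bmi_max
    for name, v in (("age", age), ("weight", wgt), ("bmi", bmi)):
        if not 0.0 <= v <= 1.0:
            warnings.warn(
                f"covariate {name} outside its normalization range "
                f"(normalized value {v:.3g}); extrapolating",
                stacklevel=2,
            )
    gender = _categorical(str(raw["gender"]), spec.gender_map, "gender")
    site = _categorical(str(raw["site"]), spec.site_map, "sampling site")
    return np.array([age, wgt, bmi, gender, site])


def normalize_many(
    records: Sequence[Mapping[str, object]], spec: NormalizationSpec | None = None
) -> np.ndarray:
    return np.stack([normalize(r, spec) for r in records])


# ---------------------------------------------------------------------------
# base expressions (vectorized over a leading batch axis)
# ---------------------------------------------------------------------------


def _guarded_base(z4: np.ndarray) -> np.ndarray:
    return np.maximum(np.abs(z4), EPS_POW)


def _guarded_den(d: np.ndarray) -> np.ndarray:
    return np.where(d >= 0, 1.0, -1.0) * np.maximum(np.abs(d), EPS_DIV)


def base_expr_g1(z: np.ndarray) -> np.ndarray:
    """g1: (z1, z2*z3, |z4|^z5) with |z4| floored at EPS_POW (so 0^0 -> 1)."""
    z = np.asarray(z, dtype=float)
    a = _guarded_base(z[..., 3])
    return np.stack(
        [z[..., 0], z[..., 1] * z[..., 2], a ** z[..., 4]], axis=-1
    )


def base_expr_g2(z: np.ndarray) -> np.ndarray:
    """g2: (z1, z2*z3, z4/(z5+1)) with |z5+1| floored at EPS_DIV."""
    z = np.asarray(z, dtype=float)
    den = _guarded_den(z[..., 4] + 1.0)
    return np.stack(
        [z[..., 0], z[..., 1] * z[..., 2], z[..., 3] / den], axis=-1
    )


def base_expr_g3(z):
    """g3: |z| — makes every network output a valid (non-negative) rate."""
    return np.abs(z)


_BASE_EXPRS = {"g1": base_expr_g1, "g2": base_expr_g2, "g3": base_expr_g3}
_BASE_IN_DIM = {"g1": 5, "g2": 5, "g3": 1}


# ---------------------------------------------------------------------------
# layers and networks
# ---------------------------------------------------------------------------


@dataclass
class SymRegLayer:
    """Affine layer with pruning masks and a base-expression id."""

    W: np.ndarray
    b: np.ndarray
    W_mask: np.ndarray  # 1 = trainable, 0 = pruned (entry forced to 0)
    b_mask: np.ndarray
    base_expr: str

    def __post_init__(self) -> None:
        if self.base_expr not in _BASE_EXPRS:
            raise StructuralError(f"unknown base expression {self.base_expr!r}")
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.W_mask = np.asarray(self.W_mask, dtype=np.uint8)
        self.b_mask = np.asarray(self.b_mask, dtype=np.uint8)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise StructuralError("inconsistent layer shapes")
        if self.W_mask.shape != self.W.shape or self.b_mask.shape != self.b.shape:
            raise StructuralError("mask shapes must match weight shapes")
        if self.W.shape[0] != _BASE_IN_DIM[self.base_expr]:
            raise StructuralError(
                f"layer output dim {self.W.shape[0]} incompatible with "
                f"{self.base_expr} (expects {_BASE_IN_DIM[self.base_expr]})"
            )
        self.apply_masks()

    def apply_masks(self) -> None:
        self.W *= self.W_mask
        self.b *= self.b_mask

    def copy(self) -> "SymRegLayer":
        return SymRegLayer(
            W=self.W.copy(), b=self.b.copy(),
            W_mask=self.W_mask.copy(), b_mask=self.b_mask.copy(),
            base_expr=self.base_expr,
        )


def layer_forward(layer: SymRegLayer, x: np.ndarray) -> np.ndarray:
    """g_l(W x + b) for a single input or a batch (..., in_dim)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.W.shape[1]:
        raise StructuralError(
            f"input dim {x.shape[-1]} != layer in-dim {layer.W.shape[1]}"
        )
    z = x @ layer.W.T + layer.b
    return _BASE_EXPRS[layer.base_expr](z)


@dataclass
class SymRegNetwork:
    """Three-layer network for one PK parameter."""

    layers: list  # [SymRegLayer, SymRegLayer, SymRegLayer]

    def copy(self) -> "SymRegNetwork":
        return SymRegNetwork(layers=[l.copy() for l in self.layers])

    @property
    def n_phi(self) -> int:
        return int(self.layers[0].W.shape[1])

    def active_covariates(self) -> np.ndarray:
        """Indices of covariates with at least one unmasked first-layer weight."""
        return np.flatnonzero(self.layers[0].W_mask.any(axis=0))

    def n_unmasked(self) -> int:
        return int(
            sum(int(l.W_mask.sum()) + int(l.b_mask.sum()) for l in self.layers)
        )


@dataclass
class SymRegNetworkBank:
    """Six parallel networks, one per PK parameter, plus provenance."""

    networks: dict  # name -> SymRegNetwork, keys == PARAM_NAMES order
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    seed: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.networks) != tuple(PARAM_NAMES):
            raise StructuralError(
                f"bank must hold networks for {PARAM_NAMES} in order"
            )

    def copy(self) -> "SymRegNetworkBank":
        return SymRegNetworkBank(
            networks={k: v.copy() for k, v in self.networks.items()},
            normalization=self.normalization,
            seed=self.seed,
        )

    # -- trainable vector gamma ------------------------------------------
    def get_gamma(self) -> np.ndarray:
        parts = []
        for net in self.networks.values():
            for l in net.layers:
                parts.append(l.W[l.W_mask.astype(bool)])
                parts.append(l.b[l.b_mask.astype(bool)])
        return np.concatenate(parts) if parts else np.zeros(0)

    def set_gamma(self, gamma: np.ndarray) -> None:
        gamma = np.asarray(gamma, dtype=float)
        if gamma.size != self.n_unmasked():
            raise StructuralError(
                f"gamma length {gamma.size} != unmasked count "
                f"{self.n_unmasked()}"
            )
        pos = 0
        for net in self.networks.values():
            for l in net.layers:
                wm = l.W_mask.astype(bool)
                k = int(wm.sum())
                l.W[wm] = gamma[pos : pos + k]
                pos += k
                bm = l.b_mask.astype(bool)
                k = int(bm.sum())
                l.b[bm] = gamma[pos : pos + k]
                pos += k
        if pos != gamma.size:
            raise StructuralError(
                f"gamma length {gamma.size} != unmasked count {pos}"
            )

    def gamma_index(self) -> list:
        """(network, layer, 'W'|'b', flat_index) for each gamma entry, in order."""
        out = []
        for name, net in self.networks.items():
            for li, l in enumerate(net.layers):
                for flat in np.flatnonzero(l.W_mask):
                    out.append((name, li, "W", int(flat)))
                for flat in np.flatnonzero(l.b_mask):
                    out.append((name, li, "b", int(flat)))
        return out

    def n_unmasked(self) -> int:
        return sum(net.n_unmasked() for net in self.networks.values())

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "format": "pksymreg-bank-v1",
            "seed": self.seed,
            "normalization": self.normalization.to_dict(),
            "networks": {
                name: [
                    {
                        "base_expr": l.base_expr,
                        "W": l.W.tolist(),
                        "b": l.b.tolist(),
                        "W_mask": l.W_mask.tolist(),
                        "b_mask": l.b_mask.tolist(),
                    }
                    for l in net.layers
                ]
                for name, net in self.networks.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SymRegNetworkBank":
        doc = json.loads(text)
        if doc.get("format") != "pksymreg-bank-v1":
            raise FormatError("not a pksymreg bank document")
        networks = {
            name: SymRegNetwork(
                layers=[
                    SymRegLayer(
                        W=np.array(l["W"]), b=np.array(l["b"]),
                        W_mask=np.array(l["W_mask"]),
                        b_mask=np.array(l["b_mask"]),
                        base_expr=l["base_expr"],
                    )
                    for l in doc["networks"][name]
                ]
            )
            for name in PARAM_NAMES
        }
        return cls(
            networks=networks,
            normalization=NormalizationSpec.from_dict(doc["normalization"]),
            seed=doc.get("seed"),
        )


@dataclass(frozen=True)
class ArchitectureConfig:
    """Nominal (dense) architecture: n_phi -> 5 -(g1)-> 3 -> 5 -(g2)-> 3 -> 1 -(g3)."""

    n_phi: int = 5
    init_scale: float = 0.4


def init_bank(
    seed: int, architecture: ArchitectureConfig | None = None
) -> SymRegNetworkBank:
    """Dense bank with reproducible N(0, init_scale^2) weights and biases."""
    arch = architecture or ArchitectureConfig()
    rng = np.random.default_rng(seed)
    shapes = [(5, arch.n_phi), (5, 3), (1, 3)]
    bases = ["g1", "g2", "g3"]
    networks = {}
    for name in PARAM_NAMES:
        layers = []
        for (rows, cols), base in zip(shapes, bases):
            layers.append(
                SymRegLayer(
                    W=rng.normal(scale=arch.init_scale, size=(rows, cols)),
                    b=rng.normal(scale=arch.init_scale, size=rows),
                    W_mask=np.ones((rows, cols), dtype=np.uint8),
                    b_mask=np.ones(rows, dtype=np.uint8),
                    base_expr=base,
                )
            )
        networks[name] = SymRegNetwork(layers=layers)
    return SymRegNetworkBank(networks=networks, seed=seed)


# ---------------------------------------------------------------------------
# forward / backward (vectorized over individuals)
# ---------------------------------------------------------------------------


def net_forward(net: SymRegNetwork, phi: np.ndarray) -> tuple[np.ndarray, dict]:
    """Scalar outputs (n,) for inputs phi (n, n_phi), plus a backprop cache."""
    l1, l2, l3 = net.layers
    z1 = phi @ l1.W.T + l1.b
    a = _guarded_base(z1[:, 3])
    x2 = np.stack([z1[:, 0], z1[:, 1] * z1[:, 2], a ** z1[:, 4]], axis=-1)
    z2 = x2 @ l2.W.T + l2.b
    den = _guarded_den(z2[:, 4] + 1.0)
    x3 = np.stack([z2[:, 0], z2[:, 1] * z2[:, 2], z2[:, 3] / den], axis=-1)
    z3 = x3 @ l3.W.T + l3.b  # (n, 1)
    theta = np.abs(z3[:, 0])
    cache = {"phi": phi, "z1": z1, "a": a, "x2": x2, "z2": z2, "den": den,
             "x3": x3, "z3": z3}
    return theta, cache


def net_backward(
    net: SymRegNetwork, cache: dict, seed: np.ndarray
) -> tuple[dict, np.ndarray]:
    """Reverse pass: gradients of sum_i seed_i * theta_i.

    Returns ({layer_index: (dW, db)}, dphi) where dW/db are summed over the
    batch (masked entries zeroed) and dphi has shape (n, n_phi).
    """
    l1, l2, l3 = net.layers
    phi, z1, a, x2 = cache["phi"], cache["z1"], cache["a"], cache["x2"]
    z2, den, x3, z3 = cache["z2"], cache["den"], cache["x3"], cache["z3"]

    dz3 = (seed * np.where(z3[:, 0] >= 0, 1.0, -1.0))[:, None]  # (n,1)
    dW3 = dz3.T @ x3
    db3 = dz3.sum(axis=0)
    dx3 = dz3 @ l3.W  # (n,3)

    dz2 = np.empty_like(z2)
    dz2[:, 0] = dx3[:, 0]
    dz2[:, 1] = dx3[:, 1] * z2[:, 2]
    dz2[:, 2] = dx3[:, 1] * z2[:, 1]
    dz2[:, 3] = dx3[:, 2] / den
    den_active = np.abs(z2[:, 4] + 1.0) > EPS_DIV
    dz2[:, 4] = np.where(
        den_active, -dx3[:, 2] * z2[:, 3] / (den * den), 0.0
    )
    dW2 = dz2.T @ x2
    db2 = dz2.sum(axis=0)
    dx2 = dz2 @ l2.W

    dz1 = np.empty_like(z1)
    dz1[:, 0] = dx2[:, 0]
    dz1[:, 1] = dx2[:, 1] * z1[:, 2]
    dz1[:, 2] = dx2[:, 1] * z1[:, 1]
    base_active = np.abs(z1[:, 3]) > EPS_POW
    sign4 = np.where(z1[:, 3] >= 0, 1.0, -1.0)
    dz1[:, 3] = np.where(
        base_active,
        dx2[:, 2] * z1[:, 4] * a ** (z1[:, 4] - 1.0) * sign4,
        0.0,
    )
    dz1[:, 4] = dx2[:, 2] * x2[:, 2] * np.log(a)
    dW1 = dz1.T @ phi
    db1 = dz1.sum(axis=0)
    dphi = dz1 @ l1.W

    grads = {0: (dW1 * l1.W_mask, db1 * l1.b_mask),
             1: (dW2 * l2.W_mask, db2 * l2.b_mask),
             2: (dW3 * l3.W_mask, db3 * l3.b_mask)}
    return grads, dphi


def bank_forward_many(
    bank: SymRegNetworkBank, phi: np.ndarray, caches: dict | None = None
) -> np.ndarray:
    """Parameter matrix theta (n, 6) for normalized covariates phi (n, n_phi)."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    theta = np.empty((phi.shape[0], len(PARAM_NAMES)))
    for j, name in enumerate(PARAM_NAMES):
        theta[:, j], cache = net_forward(bank.networks[name], phi)
        if caches is not None:
            caches[name] = cache
    return theta


def bank_forward(bank: SymRegNetworkBank, phi: np.ndarray) -> PKRates:
    """Evaluate all six networks on one normalized covariate vector."""
    theta = bank_forward_many(bank, np.asarray(phi, dtype=float)[None, :])[0]
    # g3 guarantees >= 0; nudge exact zeros so the result is a valid PKRates
    theta = np.maximum(theta, np.finfo(float).tiny)
    return PKRates.from_array(theta)
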