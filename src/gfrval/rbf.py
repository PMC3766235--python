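"""Exact-design Gaussian radial-basis-function regression (1-D).

One hidden unit per distinct training input, Gaussian activation

    phi(x, c) = exp(-(0.8326 * |x - c| / spread)^2)

so that activation is exactly 0.5 at distance ``spread``. The bias-
augmented design has n equations and n+1 unknowns; weights and output
bias are the minimum-norm least-squares solution. An optional Tikhonov
ridge term stabilizes the solve on dense, noisy training sets where the
kernel matrix is numerically singular (documented deviation from the
plain exact design; default off).

Near-duplicate inputs (|dx| < 1e-9) are merged to their target mean
before the design is built, since exact interpolation of conflicting
targets at one site is impossible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

__all__ = ["RBFModel", "train_exact", "predict", "save_model", "load_model"]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: Gaussian width factor: activation = 0.5 at distance == spread.
WIDTH_FACTOR = 0.8326

#: Inputs closer than this are merged before the design is built.
MERGE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class RBFModel:
    """Trained exact-design network: centers, spread, weights, output bias."""

    centers: np.ndarray  # SCr values, mg/dL, strictly increasing
    spread: float
    weights: np.ndarray  # hidden-to-output, mL/min/1.73 m^2 scale
    output_bias: float
    training_hash: str

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "weights", weights)
        if centers.ndim != 1 or len(centers) < 1:
            raise ValueError("centers must be a nonempty 1-D vector")
        if len(weights) != len(centers):
            raise ValueError("weights and centers must have equal length")
        if not np.isfinite(self.spread) or self.spread <= 0:
            raise ValueError(f"spread must be positive, got {self.spread}")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if not (np.all(np.isfinite(weights)) and np.isfinite(self.output_bias)):
            raise ValueError("weights and output_bias must be finite")


def _kernel(x: np.ndarray, centers: np.ndarray, spread: float) -> np.ndarray:
    d = (WIDTH_FACTOR / spread) * np.abs(x[:, None] - centers[None, :])
    return np.exp(-(d ** 2))


def _merge_duplicates(x: np.ndarray, y: np.ndarray) -> tuple:
    """Sort by x and average targets of inputs closer than MERGE_TOL."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    groups = np.concatenate([[0], np.cumsum(np.diff(x) >= MERGE_TOL)])
    n_groups = groups[-1] + 1
    if n_groups == len(x):
        return x, y
    xs = np.bincount(groups, weights=x) / np.bincount(groups)
    ys = np.bincount(groups, weights=y) / np.bincount(groups)
    logger.info("merged %d near-duplicate training inputs", len(x) - n_groups)
    return xs, ys


def _training_hash(x: np.ndarray, y: np.ndarray, spread: float, ridge: float) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.float64).tobytes())
    h.update(np.float64(spread).tobytes())
    h.update(np.float64(ridge).tobytes())
    return h.hexdigest()[:16]


def train_exact(scr, sgfr, spread: float = 1.0, ridge: float = 0.0) -> RBFModel:
    """Fit the exact-design network: one center per distinct training input.

    Parameters
    ----------
    scr, sgfr : array-like, same length >= 1, all entries positive
        Training inputs (serum creatinine, mg/dL) and targets
        (reference GFR, mL/min/1.73 m^2).
    spread : float
        Kernel width; activation falls to 0.5 at this distance.
    ridge : float
        Optional Tikhonov penalty on (weights, bias). 0 gives the plain
        minimum-norm least-squares exact design.
    """
    x = np.asarray(scr, dtype=float).ravel()
    y = np.asarray(sgfr, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("training set must be nonempty")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} inputs vs {len(y)} targets")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all training inputs must be positive and finite")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("all training targets must be positive and finite")
    if not np.isfinite(spread) or spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")

    x, y = _merge_duplicates(x, y)
    n = len(x)
    design = np.hstack([_kernel(x, x, spread), np.ones((n, 1))])
    if ridge > 0:
        aug = np.vstack([design, np.sqrt(ridge) * np.eye(n + 1)])
        rhs = np.concatenate([y, np.zeros(n + 1)])
    else:
        aug, rhs = design, y
    theta, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("solve produced non-finite weights")
    return RBFModel(
        centers=x,
        spread=float(spread),
        weights=theta[:-1],
        output_bias=float(theta[-1]),
        training_hash=_training_hash(x, y, spread, ridge),
    )


def predict(model: RBFModel, scr):
    """Forward pass: sum_j w_j * phi(scr, c_j) + output_bias.

    Accepts a scalar or a vector of creatinine values; all must be positive.
    """
    x = np.atleast_1d(np.asarray(scr, dtype=float))
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all inputs must be positive and finite")
    out = _kernel(x, model.centers, model.spread) @ model.weights + model.output_bias
    return float(out[0]) if np.isscalar(scr) or np.ndim(scr) == 0 else out


def save_model(model: RBFModel, path) -> None:
    """Serialize the model to JSON at full float precision."""
    payload = {
        "format_version": FORMAT_VERSION,
        "centers": model.centers.tolist(),
        "spread": model.spread,
        "weights": model.weights.tolist(),
        "output_bias": model.output_bias,
        "training_hash": model.training_hash,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> RBFModel:
    """Load a model JSON; invariants are re-validated on construction."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed model file: {exc}") from None
    try:
        version = payload["format_version"]
        if version != FORMAT_VERSION:
            logger.warning("%s: format_version %s != %s", path, version, FORMAT_VERSION)
        model = RBFModel(
            centers=np.asarray(payload["centers"], dtype=float),
            spread=float(payload["spread"]),
            weights=np.asarray(payload["weights"], dtype=float),
            output_bias=float(payload["output_bias"]),
            training_hash=str(payload["training_hash"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing model field {exc}") from None
    return model
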