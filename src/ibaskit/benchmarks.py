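"""Classical F1-F23 benchmark suite for validating metaheuristic optimizers.

The suite is the canonical 23-function collection used throughout the
swarm-intelligence literature: seven unimodal functions (F1-F7) probing
local exploitation, six scalable multimodal functions (F8-F13) and ten
fixed-dimension multimodal functions (F14-F23) probing global exploration.
All functions are minimization problems.  F1-F13 are dimension-scalable
(30-D by default); F14-F23 have fixed low dimensions.

Each function is evaluated through :func:`evaluate` (single point) or
:func:`batch_evaluate` (matrix of row vectors, used by the optimizer for
speed).  The noisy quartic (F7) adds uniform(0,1) noise drawn from a
caller-supplied random generator so that runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

UNIMODAL = "unimodal"
MULTIMODAL = "multimodal"

# -- high-precision optima for functions whose minimizer is not analytic --
# (refined numerically to ~1e-12 and frozen; see docs/methods.md)
_SCHWEFEL_XSTAR = 420.96874657644923
_SCHWEFEL_FSTAR_PER_DIM = -418.982887272434
_FOXHOLES_XSTAR = (-31.978330712590456, -31.97833157692572)
_FOXHOLES_FSTAR = 0.99800383779445
_KOWALIK_XSTAR = (0.19283345304274813, 0.19083624027597035,
                  0.12311729907598003, 0.13576599033984466)
_KOWALIK_FSTAR = 3.07485987805605e-04
_CAMEL_XSTAR = (0.08984201652927098, -0.7126564013807202)
_CAMEL_FSTAR = -1.03162845348988
_BRANIN_FSTAR = 10.0 / (8.0 * np.pi)  # exact at (pi, 2.275)
_HARTMANN3_XSTAR = (0.11458887557640371, 0.5556488940378945,
                    0.8525469854710511)
_HARTMANN3_FSTAR = -3.86277978733266
_HARTMANN6_XSTAR = (0.20168951037794658, 0.15001069146456325,
                    0.4768739733706766, 0.2753324288543796,
                    0.3116516165632252, 0.6573005308464771)
_HARTMANN6_FSTAR = -3.32236801141552
_SHEKEL5_XSTAR = (4.000037152376549, 4.000133278657566,
                  4.000037151057555, 4.000133277090425)
_SHEKEL5_FSTAR = -10.1531996790582
_SHEKEL7_XSTAR = (4.00057291611626, 4.000689367181722,
                  3.9994897107938447, 3.9996061600067923)
_SHEKEL7_FSTAR = -10.4029405668187
_SHEKEL10_XSTAR = (4.000746530253313, 4.000592936779709,
                   3.9996633957714787, 3.9995097993299975)
_SHEKEL10_FSTAR = -10.536409816692


@dataclass(frozen=True)
class BenchmarkFunction:
    """One registered test function.

    ``known_optimum_point`` is ``None`` when the minimizer is not unique
    (e.g. the Step function's flat plateau, Branin's three minima) or when
    noise makes point-wise verification meaningless (F7).
    """

    id: int
    name: str
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    category: str
    known_optimum_value: float
    known_optimum_point: Optional[np.ndarray]
    noisy: bool = False
    _batch: Callable[..., np.ndarray] = field(default=None, repr=False)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lower.tolist(), self.upper.tolist()))


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def evaluate(fn: BenchmarkFunction, x, rng: Optional[np.random.Generator] = None) -> float:
    """Evaluate ``fn`` at a single in-bounds point.

    Raises ``ValueError`` on dimension mismatch or out-of-bounds input;
    the optimizer owns bound handling, the suite never clips silently.
    """
    return float(batch_evaluate(fn, np.asarray(x, dtype=float)[None, :], rng)[0])


def batch_evaluate(fn: BenchmarkFunction, X, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Evaluate ``fn`` on each row of ``X`` (shape ``(n, dimension)``)."""
    X = _as_matrix(X)
    if X.shape[1] != fn.dimension:
        raise ValueError(
            f"{fn.name}: expected dimension {fn.dimension}, got {X.shape[1]}"
        )
    if np.any(X < fn.lower) or np.any(X > fn.upper):
        raise ValueError(f"{fn.name}: point outside the search domain")
    if fn.noisy:
        if rng is None:
            raise ValueError(f"{fn.name} is stochastic; pass an rng")
        vals = fn._batch(X, rng)
    else:
        vals = fn._batch(X)
    vals = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError(f"{fn.name}: non-finite value for in-bounds input")
    return vals


# ---------------------------------------------------------------- formulas

def _sphere(X):
    return np.sum(X ** 2, axis=1)


def _schwefel_2_22(X):
    a = np.abs(X)
    return np.sum(a, axis=1) + np.prod(a, axis=1)


def _schwefel_1_2(X):
    return np.sum(np.cumsum(X, axis=1) ** 2, axis=1)


def _schwefel_2_21(X):
    return np.max(np.abs(X), axis=1)


def _rosenbrock(X):
    return np.sum(100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2
                  + (X[:, :-1] - 1.0) ** 2, axis=1)


def _step(X):
    return np.sum(np.floor(X + 0.5) ** 2, axis=1)


def _quartic_noise(X, rng):
    i = np.arange(1, X.shape[1] + 1)
    return np.sum(i * X ** 4, axis=1) + rng.uniform(0.0, 1.0, size=X.shape[0])


def _schwefel_2_26(X):
    return -np.sum(X * np.sin(np.sqrt(np.abs(X))), axis=1)


def _rastrigin(X):
    return np.sum(X ** 2 - 10.0 * np.cos(2.0 * np.pi * X) + 10.0, axis=1)


def _ackley(X):
    n = X.shape[1]
    return (-20.0 * np.exp(-0.2 * np.sqrt(np.sum(X ** 2, axis=1) / n))
            - np.exp(np.sum(np.cos(2.0 * np.pi * X), axis=1) / n)
            + 20.0 + np.e)


def _griewank(X):
    i = np.sqrt(np.arange(1, X.shape[1] + 1))
    return (np.sum(X ** 2, axis=1) / 4000.0
            - np.prod(np.cos(X / i), axis=1) + 1.0)


def _u_penalty(X, a, k, m):
    out = np.zeros_like(X)
    hi = X > a
    lo = X < -a
    out[hi] = k * (X[hi] - a) ** m
    out[lo] = k * (-X[lo] - a) ** m
    return np.sum(out, axis=1)


def _penalized_1(X):
    n = X.shape[1]
    y = 1.0 + (X + 1.0) / 4.0
    term = (10.0 * np.sin(np.pi * y[:, 0]) ** 2
            + np.sum((y[:, :-1] - 1.0) ** 2
                     * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2), axis=1)
            + (y[:, -1] - 1.0) ** 2)
    return np.pi / n * term + _u_penalty(X, 10.0, 100.0, 4)


def _penalized_2(X):
    term = (np.sin(3.0 * np.pi * X[:, 0]) ** 2
            + np.sum((X[:, :-1] - 1.0) ** 2
                     * (1.0 + np.sin(3.0 * np.pi * X[:, 1:]) ** 2), axis=1)
            + (X[:, -1] - 1.0) ** 2
            * (1.0 + np.sin(2.0 * np.pi * X[:, -1]) ** 2))
    return 0.1 * term + _u_penalty(X, 5.0, 100.0, 4)


_FOX_A = np.array([
    [-32, -16, 0, 16, 32] * 5,
    [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
], dtype=float)


def _foxholes(X):
    # Shekel's foxholes: 25 narrow wells on a 2-D grid
    d = (X[:, :, None] - _FOX_A[None, :, :]) ** 6  # (n, 2, 25)
    inner = np.arange(1, 26) + d.sum(axis=1)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / inner, axis=1))


_KOW_A = np.array([0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
                   0.0456, 0.0342, 0.0323, 0.0235, 0.0246])
_KOW_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _kowalik(X):
    b = _KOW_B[None, :]
    num = X[:, [0]] * (b ** 2 + b * X[:, [1]])
    den = b ** 2 + b * X[:, [2]] + X[:, [3]]
    return np.sum((_KOW_A[None, :] - num / den) ** 2, axis=1)


def _camel6(X):
    x, y = X[:, 0], X[:, 1]
    return (4.0 * x ** 2 - 2.1 * x ** 4 + x ** 6 / 3.0
            + x * y - 4.0 * y ** 2 + 4.0 * y ** 4)


def _branin(X):
    x, y = X[:, 0], X[:, 1]
    b = 5.1 / (4.0 * np.pi ** 2)
    c = 5.0 / np.pi
    t = 1.0 / (8.0 * np.pi)
    return ((y - b * x ** 2 + c * x - 6.0) ** 2
            + 10.0 * (1.0 - t) * np.cos(x) + 10.0)


def _goldstein_price(X):
    x, y = X[:, 0], X[:, 1]
    a = 1.0 + (x + y + 1.0) ** 2 * (19.0 - 14.0 * x + 3.0 * x ** 2
                                    - 14.0 * y + 6.0 * x * y + 3.0 * y ** 2)
    b = 30.0 + (2.0 * x - 3.0 * y) ** 2 * (18.0 - 32.0 * x + 12.0 * x ** 2
                                           + 48.0 * y - 36.0 * x * y
                                           + 27.0 * y ** 2)
    return a * b


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3.0, 10.0, 30.0],
                  [0.1, 10.0, 35.0],
                  [3.0, 10.0, 30.0],
                  [0.1, 10.0, 35.0]])
_H3_P = np.array([[0.3689, 0.1170, 0.2673],
                  [0.4699, 0.4387, 0.7470],
                  [0.1091, 0.8732, 0.5547],
                  [0.0381, 0.5743, 0.8828]])

_H6_A = np.array([[10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
                  [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
                  [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
                  [17.0, 8.0, 0.05, 10.0, 0.1, 14.0]])
_H6_P = np.array([[0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
                  [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
                  [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
                  [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381]])


def _hartmann(X, A, P):
    d = np.sum(A[None, :, :] * (X[:, None, :] - P[None, :, :]) ** 2, axis=2)
    return -np.sum(_H3_ALPHA[None, :] * np.exp(-d), axis=1)


def _hartmann3(X):
    return _hartmann(X, _H3_A, _H3_P)


def _hartmann6(X):
    return _hartmann(X, _H6_A, _H6_P)


_SHEKEL_A = np.array([[4.0, 4.0, 4.0, 4.0],
                      [1.0, 1.0, 1.0, 1.0],
                      [8.0, 8.0, 8.0, 8.0],
                      [6.0, 6.0, 6.0, 6.0],
                      [3.0, 7.0, 3.0, 7.0],
                      [2.0, 9.0, 2.0, 9.0],
                      [5.0, 5.0, 3.0, 3.0],
                      [8.0, 1.0, 8.0, 1.0],
                      [6.0, 2.0, 6.0, 2.0],
                      [7.0, 3.6, 7.0, 3.6]])
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(X, m):
    d = np.sum((X[:, None, :] - _SHEKEL_A[None, :m, :]) ** 2, axis=2)
    return -np.sum(1.0 / (d + _SHEKEL_C[None, :m]), axis=1)


def _shekel5(X):
    return _shekel(X, 5)


def _shekel7(X):
    return _shekel(X, 7)


def _shekel10(X):
    return _shekel(X, 10)


# ---------------------------------------------------------------- registry

def _make(id_, name, dim, low, high, category, f_min, x_min, batch, noisy=False):
    if np.isscalar(low):
        lower = np.full(dim, float(low))
        upper = np.full(dim, float(high))
    else:
        lower = np.asarray(low, dtype=float)
        upper = np.asarray(high, dtype=float)
    point = None if x_min is None else np.asarray(x_min, dtype=float)
    return BenchmarkFunction(id=id_, name=name, dimension=dim, lower=lower,
                             upper=upper, category=category,
                             known_optimum_value=float(f_min),
                             known_optimum_point=point, noisy=noisy,
                             _batch=batch)


def list_functions(high_dim: int = 30) -> list[BenchmarkFunction]:
    """Return the 23 registered functions in canonical order.

    ``high_dim`` sets the dimension of the scalable functions F1-F13
    (30 by default); F14-F23 keep their fixed dimensions.
    """
    n = int(high_dim)
    if n < 2:
        raise ValueError("high_dim must be >= 2")
    z = np.zeros(n)
    return [
        _make(1, "Sphere", n, -100, 100, UNIMODAL, 0.0, z, _sphere),
        _make(2, "Schwefel 2.22", n, -10, 10, UNIMODAL, 0.0, z, _schwefel_2_22),
        _make(3, "Schwefel 1.2", n, -100, 100, UNIMODAL, 0.0, z, _schwefel_1_2),
        _make(4, "Schwefel 2.21", n, -100, 100, UNIMODAL, 0.0, z, _schwefel_2_21),
        _make(5, "Rosenbrock", n, -30, 30, UNIMODAL, 0.0, np.ones(n), _rosenbrock),
        _make(6, "Step", n, -100, 100, UNIMODAL, 0.0, None, _step),
        _make(7, "Noisy Quartic", n, -1.28, 1.28, UNIMODAL, 0.0, None,
              _quartic_noise, noisy=True),
        _make(8, "Schwefel 2.26", n, -500, 500, MULTIMODAL,
              n * _SCHWEFEL_FSTAR_PER_DIM, np.full(n, _SCHWEFEL_XSTAR),
              _schwefel_2_26),
        _make(9, "Rastrigin", n, -5.12, 5.12, MULTIMODAL, 0.0, z, _rastrigin),
        _make(10, "Ackley", n, -32, 32, MULTIMODAL, 0.0, z, _ackley),
        _make(11, "Griewank", n, -600, 600, MULTIMODAL, 0.0, z, _griewank),
        _make(12, "Penalized 1", n, -50, 50, MULTIMODAL, 0.0, -np.ones(n),
              _penalized_1),
        _make(13, "Penalized 2", n, -50, 50, MULTIMODAL, 0.0, np.ones(n),
              _penalized_2),
        _make(14, "Shekel's Foxholes", 2, -65.536, 65.536, MULTIMODAL,
              _FOXHOLES_FSTAR, _FOXHOLES_XSTAR, _foxholes),
        _make(15, "Kowalik", 4, -5, 5, MULTIMODAL, _KOWALIK_FSTAR,
              _KOWALIK_XSTAR, _kowalik),
        _make(16, "Six-Hump Camel", 2, -5, 5, MULTIMODAL, _CAMEL_FSTAR,
              _CAMEL_XSTAR, _camel6),
        _make(17, "Branin", 2, (-5.0, 0.0), (10.0, 15.0), MULTIMODAL,
              _BRANIN_FSTAR, None, _branin),
        _make(18, "Goldstein-Price", 2, -2, 2, MULTIMODAL, 3.0, (0.0, -1.0),
              _goldstein_price),
        _make(19, "Hartmann 3", 3, 0, 1, MULTIMODAL, _HARTMANN3_FSTAR,
              _HARTMANN3_XSTAR, _hartmann3),
        _make(20, "Hartmann 6", 6, 0, 1, MULTIMODAL, _HARTMANN6_FSTAR,
              _HARTMANN6_XSTAR, _hartmann6),
        _make(21, "Shekel 5", 4, 0, 10, MULTIMODAL, _SHEKEL5_FSTAR,
              _SHEKEL5_XSTAR, _shekel5),
        _make(22, "Shekel 7", 4, 0, 10, MULTIMODAL, _SHEKEL7_FSTAR,
              _SHEKEL7_XSTAR, _shekel7),
        _make(23, "Shekel 10", 4, 0, 10, MULTIMODAL, _SHEKEL10_FSTAR,
              _SHEKEL10_XSTAR, _shekel10),
    ]


def registry_table(high_dim: int = 30) -> pd.DataFrame:
    """Registry as a flat table (id, name, dim, low, high, category, f_min)."""
    rows = []
    for fn in list_functions(high_dim):
        rows.append({
            "id": fn.id,
            "name": fn.name,
            "dim": fn.dimension,
            "low": fn.lower[0],
            "high": fn.upper[0],
            "category": fn.category,
            "f_min": fn.known_optimum_value,
        })
    return pd.DataFrame(rows)
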