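"""Classical 23-function benchmark suite for whale-optimizer validation.

The suite is the de-facto standard collection behind the WOA literature:
unimodal F1-F7 (exploitation accuracy), multimodal F8-F13 (escape from
local optima) and fixed-dimension multimodal F14-F23 (low-dimensional
landscapes).  Every function is vectorised: it accepts either a single
point of shape ``(d,)`` or a population of shape ``(n, d)``.

F7 (quartic) adds uniform noise on [0, 1) and therefore requires an
explicit :class:`numpy.random.Generator`; every other function is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FunctionSpec", "FUNCTION_IDS", "get_spec", "evaluate", "make_objective", "specs_as_json"]

FUNCTION_IDS = tuple(f"F{i}" for i in range(1, 24))


@dataclass(frozen=True)
class FunctionSpec:
    """Immutable metadata for one benchmark function."""

    id: str
    name: str
    dimension: int
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    category: str  # unimodal | multimodal | fixed_dimension
    reference_minimum: float
    optimum_position: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(self.lower_bound < self.upper_bound):
            raise ValueError(f"{self.id}: lower_bound must be < upper_bound on every axis")


def _as_population(x: np.ndarray, d: int, fid: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != d:
        raise ValueError(f"{fid}: expected dimension {d}, got {x.shape[1]}")
    return x, single


# ---------------------------------------------------------------- unimodal

def _f1(x):  # Sphere
    return np.sum(x**2, axis=1)


def _f2(x):  # Schwefel 2.22
    ax = np.abs(x)
    return np.sum(ax, axis=1) + np.prod(ax, axis=1)


def _f3(x):  # Schwefel 1.2
    return np.sum(np.cumsum(x, axis=1) ** 2, axis=1)


def _f4(x):  # Schwefel 2.21
    return np.max(np.abs(x), axis=1)


def _f5(x):  # Rosenbrock
    return np.sum(100.0 * (x[:, 1:] - x[:, :-1] ** 2) ** 2 + (x[:, :-1] - 1.0) ** 2, axis=1)


def _f6(x):  # Step
    return np.sum(np.floor(x + 0.5) ** 2, axis=1)


def _f7(x, rng):  # Quartic with noise
    i = np.arange(1, x.shape[1] + 1)
    return np.sum(i * x**4, axis=1) + rng.uniform(0.0, 1.0, size=x.shape[0])


# -------------------------------------------------------------- multimodal

def _f8(x):  # Schwefel
    return -np.sum(x * np.sin(np.sqrt(np.abs(x))), axis=1)


def _f9(x):  # Rastrigin
    return np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0, axis=1)


def _f10(x):  # Ackley
    d = x.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2, axis=1) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x), axis=1) / d)
        + 20.0
        + np.e
    )


def _f11(x):  # Griewank
    i = np.arange(1, x.shape[1] + 1)
    return np.sum(x**2, axis=1) / 4000.0 - np.prod(np.cos(x / np.sqrt(i)), axis=1) + 1.0


def _penalty(x, a, k, m):
    # classical piecewise penalty u(x, a, k, m):
    #   k*(x-a)^m  for x >  a;  k*(-x-a)^m  for x < -a;  0 otherwise
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return np.sum(out, axis=1)


def _f12(x):  # Penalized 1
    d = x.shape[1]
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[:, 0]) ** 2
        + np.sum((y[:, :-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2), axis=1)
        + (y[:, -1] - 1.0) ** 2
    )
    return np.pi / d * core + _penalty(x, 10.0, 100.0, 4)


def _f13(x):  # Penalized 2
    core = (
        np.sin(3.0 * np.pi * x[:, 0]) ** 2
        + np.sum((x[:, :-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[:, 1:]) ** 2), axis=1)
        + (x[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[:, -1]) ** 2)
    )
    return 0.1 * core + _penalty(x, 5.0, 100.0, 4)


# --------------------------------------------------------- fixed dimension

_FOXHOLES_A = np.stack(
    [
        np.tile([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
        np.repeat([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
    ]
)  # shape (2, 25)


def _f14(x):  # Shekel's Foxholes
    diff = x[:, :, None] - _FOXHOLES_A[None, :, :]  # (n, 2, 25)
    denom = np.arange(1, 26) + np.sum(diff**6, axis=1)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / denom, axis=1))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _f15(x):  # Kowalik
    b = _KOWALIK_B
    num = x[:, 0:1] * (b**2 + b * x[:, 1:2])
    den = b**2 + b * x[:, 2:3] + x[:, 3:4]
    return np.sum((_KOWALIK_A - num / den) ** 2, axis=1)


def _f16(x):  # Six-hump camel-back
    x1, x2 = x[:, 0], x[:, 1]
    return 4 * x1**2 - 2.1 * x1**4 + x1**6 / 3.0 + x1 * x2 - 4 * x2**2 + 4 * x2**4


def _f17(x):  # Branin
    x1, x2 = x[:, 0], x[:, 1]
    return (
        (x2 - 5.1 / (4 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _f18(x):  # Goldstein-Price
    x1, x2 = x[:, 0], x[:, 1]
    t1 = 1 + (x1 + x2 + 1) ** 2 * (19 - 14 * x1 + 3 * x1**2 - 14 * x2 + 6 * x1 * x2 + 3 * x2**2)
    t2 = 30 + (2 * x1 - 3 * x2) ** 2 * (
        18 - 32 * x1 + 12 * x1**2 + 48 * x2 - 36 * x1 * x2 + 27 * x2**2
    )
    return t1 * t2


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]])
_H3_P = 1e-4 * np.array(
    [[3689, 1170, 2673], [4699, 4387, 7470], [1091, 8732, 5547], [381, 5743, 8828]]
)

_H6_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_H6_P = 1e-4 * np.array(
    [
        [1312, 1696, 5569, 124, 8283, 5886],
        [2329, 4135, 8307, 3736, 1004, 9991],
        [2348, 1451, 3522, 2883, 3047, 6650],
        [4047, 8828, 8732, 5743, 1091, 381],
    ]
)


def _hartmann(x, alpha, A, P):
    inner = np.sum(A[None, :, :] * (x[:, None, :] - P[None, :, :]) ** 2, axis=2)
    return -np.sum(alpha * np.exp(-inner), axis=1)


def _f19(x):
    return _hartmann(x, _H3_ALPHA, _H3_A, _H3_P)


def _f20(x):
    return _hartmann(x, _H6_ALPHA, _H6_A, _H6_P)


_SHEKEL_C = np.array(
    [
        [4.0, 1.0, 8.0, 6.0, 3.0, 2.0, 5.0, 8.0, 6.0, 7.0],
        [4.0, 1.0, 8.0, 6.0, 7.0, 9.0, 3.0, 1.0, 2.0, 3.6],
        [4.0, 1.0, 8.0, 6.0, 3.0, 2.0, 5.0, 8.0, 6.0, 7.0],
        [4.0, 1.0, 8.0, 6.0, 7.0, 9.0, 3.0, 1.0, 2.0, 3.6],
    ]
)
_SHEKEL_BETA = 0.1 * np.array([1.0, 2.0, 2.0, 4.0, 4.0, 6.0, 3.0, 7.0, 5.0, 5.0])


def _shekel(x, m):
    diff = x[:, :, None] - _SHEKEL_C[None, :, :m]
    return -np.sum(1.0 / (np.sum(diff**2, axis=1) + _SHEKEL_BETA[:m]), axis=1)


def _f21(x):
    return _shekel(x, 5)


def _f22(x):
    return _shekel(x, 7)


def _f23(x):
    return _shekel(x, 10)


_FUNCTIONS: dict[str, Callable] = {
    "F1": _f1, "F2": _f2, "F3": _f3, "F4": _f4, "F5": _f5, "F6": _f6, "F7": _f7,
    "F8": _f8, "F9": _f9, "F10": _f10, "F11": _f11, "F12": _f12, "F13": _f13,
    "F14": _f14, "F15": _f15, "F16": _f16, "F17": _f17, "F18": _f18, "F19": _f19,
    "F20": _f20, "F21": _f21, "F22": _f22, "F23": _f23,
}

# (name, dim, lower, upper, category, reference_minimum, optimum_position)
# Fixed-dimension minima/minimizers are frozen from a numerical polish of the
# literature optima so that evaluate(optimum) == reference_minimum to 1e-9.
_TABLE: dict[str, tuple] = {
    "F1": ("Sphere", 30, -100.0, 100.0, "unimodal", 0.0, "zeros"),
    "F2": ("Schwefel 2.22", 30, -10.0, 10.0, "unimodal", 0.0, "zeros"),
    "F3": ("Schwefel 1.2", 30, -100.0, 100.0, "unimodal", 0.0, "zeros"),
    "F4": ("Schwefel 2.21", 30, -100.0, 100.0, "unimodal", 0.0, "zeros"),
    "F5": ("Rosenbrock", 30, -30.0, 30.0, "unimodal", 0.0, "ones"),
    "F6": ("Step", 30, -100.0, 100.0, "unimodal", 0.0, "zeros"),
    "F7": ("Quartic with noise", 30, -1.28, 1.28, "unimodal", 0.0, "zeros"),
    "F8": ("Schwefel", 30, -500.0, 500.0, "multimodal", None, "schwefel"),
    "F9": ("Rastrigin", 30, -5.12, 5.12, "multimodal", 0.0, "zeros"),
    "F10": ("Ackley", 30, -32.0, 32.0, "multimodal", 0.0, "zeros"),
    "F11": ("Griewank", 30, -600.0, 600.0, "multimodal", 0.0, "zeros"),
    "F12": ("Penalized 1", 30, -50.0, 50.0, "multimodal", 0.0, "minus_ones"),
    "F13": ("Penalized 2", 30, -50.0, 50.0, "multimodal", 0.0, "ones"),
    "F14": ("Shekel's Foxholes", 2, -65.536, 65.536, "fixed_dimension", None, None),
    "F15": ("Kowalik", 4, -5.0, 5.0, "fixed_dimension", None, None),
    "F16": ("Six-Hump Camel-Back", 2, -5.0, 5.0, "fixed_dimension", None, None),
    "F17": ("Branin", 2, (-5.0, 0.0), (10.0, 15.0), "fixed_dimension", None, None),
    "F18": ("Goldstein-Price", 2, -2.0, 2.0, "fixed_dimension", None, None),
    "F19": ("Hartmann 3", 3, 0.0, 1.0, "fixed_dimension", None, None),
    "F20": ("Hartmann 6", 6, 0.0, 1.0, "fixed_dimension", None, None),
    "F21": ("Shekel 5", 4, 0.0, 10.0, "fixed_dimension", None, None),
    "F22": ("Shekel 7", 4, 0.0, 10.0, "fixed_dimension", None, None),
    "F23": ("Shekel 10", 4, 0.0, 10.0, "fixed_dimension", None, None),
}

# Frozen polished optima for the fixed-dimension functions (position, value).
_FIXED_OPTIMA: dict[str, tuple[list[float], float]] = {
    "F14": ([-31.978333760055722, -31.978332575458697], 0.998003837794449),
    "F15": ([0.19283339212894037, 0.19083645476907882, 0.12311709838826582, 0.13576575521314953],
            0.00030748598781697983),
    "F16": ([0.08984201313657937, -0.7126564030207396], -1.031628453489877),
    "F17": ([3.141592653589793, 2.275], 0.39788735772973816),
    "F18": ([0.0, -1.0], 3.0),
    "F19": ([0.11458889993513267, 0.5556488896781473, 0.8525469800276596], -3.8627797873326597),
    "F20": ([0.20168951105764128, 0.15001069271431077, 0.47687397791927053,
             0.2753324305645092, 0.31165161598944054, 0.6573005340694833], -3.3223680114155156),
    "F21": ([4.0000371118475455, 4.000132916040856, 4.000037111847544, 4.000132916040859],
            -10.153199679058231),
    "F22": ([4.00057281287291, 3.9996062055214243, 4.00057281368011, 3.999606205585623],
            -10.402915336777735),
    "F23": ([4.000746864687709, 3.999509476730521, 4.000746864334256, 3.999509476652376],
            -10.536443153483525),
}

_SCHWEFEL_X = 420.96874635998194  # argmin of -x*sin(sqrt(|x|)) on [-500, 500]


def _build_specs() -> dict[str, FunctionSpec]:
    specs = {}
    for fid, (name, d, lo, hi, cat, ref, opt) in _TABLE.items():
        lower = np.array(lo if isinstance(lo, tuple) else [lo] * d, dtype=float)
        upper = np.array(hi if isinstance(hi, tuple) else [hi] * d, dtype=float)
        if opt == "zeros":
            pos = np.zeros(d)
        elif opt == "ones":
            pos = np.ones(d)
        elif opt == "minus_ones":
            pos = -np.ones(d)
        elif opt == "schwefel":
            pos = np.full(d, _SCHWEFEL_X)
            ref = float(_f8(pos[None, :])[0])
        elif opt is None:
            p, ref = _FIXED_OPTIMA[fid]
            pos = np.array(p)
        specs[fid] = FunctionSpec(
            id=fid, name=name, dimension=d, lower_bound=lower, upper_bound=upper,
            category=cat, reference_minimum=float(ref), optimum_position=pos,
        )
    return specs


_SPECS = _build_specs()


def get_spec(function_id: str) -> FunctionSpec:
    """Return the immutable spec for ``function_id`` (one of F1..F23)."""
    try:
        return _SPECS[function_id]
    except KeyError:
        raise KeyError(f"unknown benchmark function id: {function_id!r}") from None


def evaluate(function_id: str, x: np.ndarray, rng: np.random.Generator | None = None) -> float | np.ndarray:
    """Evaluate one benchmark function at ``x``.

    ``x`` may be a single point ``(d,)`` (returns a scalar) or a population
    ``(n, d)`` (returns ``(n,)``).  F7 draws its noise from ``rng`` and
    raises if none is supplied.
    """
    spec = get_spec(function_id)
    pop, single = _as_population(x, spec.dimension, function_id)
    if function_id == "F7":
        if rng is None:
            raise ValueError("F7 adds uniform noise and requires an explicit rng")
        vals = _f7(pop, rng)
    else:
        vals = _FUNCTIONS[function_id](pop)
    return float(vals[0]) if single else vals


def make_objective(function_id: str, rng: np.random.Generator | None = None) -> Callable[[np.ndarray], np.ndarray]:
    """Return a vectorised population objective ``(n, d) -> (n,)``."""
    spec = get_spec(function_id)
    fn = _FUNCTIONS[function_id]
    if function_id == "F7":
        if rng is None:
            raise ValueError("F7 requires an rng for its noise stream")

        def objective(x: np.ndarray) -> np.ndarray:
            pop, _ = _as_population(x, spec.dimension, function_id)
            return _f7(pop, rng)

    else:

        def objective(x: np.ndarray) -> np.ndarray:
            pop, _ = _as_population(x, spec.dimension, function_id)
            return fn(pop)

    return objective


def specs_as_json() -> str:
    """Serialise the registry (for ``mwoa benchmark list``)."""
    rows = []
    for fid in FUNCTION_IDS:
        s = _SPECS[fid]
        rows.append(
            {
                "id": s.id,
                "name": s.name,
                "dimension": s.dimension,
                "lower_bound": s.lower_bound.tolist(),
                "upper_bound": s.upper_bound.tolist(),
                "category": s.category,
                "reference_minimum": s.reference_minimum,
            }
        )
    return json.dumps(rows, indent=2)
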