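"""Local (Pearson) and global (PCE total Sobol) sensitivity analysis.

Inputs are classified deterministic / aleatory / epistemic; aleatory inputs
carry uniform ranges.  Sampling is Latin hypercube.  The global analysis fits
a total-degree polynomial chaos expansion (orthonormal Legendre basis, least
squares) to the sampled responses and derives total Sobol indices both
analytically from the coefficients and by Saltelli sampling of the surrogate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import stats
from scipy.stats import qmc

__all__ = [
    "InputSpec",
    "SampleMatrix",
    "PCEModel",
    "SobolReport",
    "TABLE4_INPUTS",
    "lhs_sample",
    "pearson_rho",
    "fit_pce",
    "total_sobol",
    "screen_inputs",
]


@dataclass(frozen=True)
class InputSpec:
    """One model input with its uncertainty classification.

    aleatory inputs are uniform on [lower, upper]; deterministic inputs carry
    a fixed ``value``; epistemic inputs are intervals without a distribution.
    """

    name: str
    classification: str = "aleatory"  # deterministic | aleatory | epistemic
    lower: float | None = None
    upper: float | None = None
    value: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.classification not in ("deterministic", "aleatory", "epistemic"):
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.classification == "deterministic":
            if self.value is None:
                raise ValueError(f"deterministic input {self.name} needs a value")
        else:
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"input {self.name} needs lower < upper bounds")


#: The shared model inputs and their SA ranges.  rho and mu are deterministic;
#: the pump-coefficient ranges bracket the fitted 8k/11k H-Q coefficients.
TABLE4_INPUTS: tuple[InputSpec, ...] = (
    InputSpec("rho", "deterministic", value=1100.0, units="kg/m^3"),
    InputSpec("mu", "deterministic", value=3.72e-3, units="Pa.s"),
    InputSpec("HR", "aleatory", 40.0, 120.0, units="bpm"),
    InputSpec("P_LA", "aleatory", 0.5e3, 1.5e3, units="Pa"),
    InputSpec("EF", "aleatory", 0.10, 0.35, units="-"),
    InputSpec("Rs", "aleatory", 5.0e6, 20.0e6, units="Pa.s/m^3"),
    InputSpec("Rp", "aleatory", 50.0e6, 200.0e6, units="Pa.s/m^3"),
    InputSpec("Cp", "aleatory", 5.0e-7, 20.0e-7, units="m^3/Pa"),
    InputSpec("A_VAD", "aleatory", 0.025e5, 1.0e5, units="Pa"),
    InputSpec("B_VAD", "aleatory", -5.0e8, -0.5e8, units="Pa.s/m^3"),
)


@dataclass(frozen=True)
class SampleMatrix:
    """n x d matrix of sampled input values with column names."""

    values: np.ndarray
    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.names):
            raise ValueError("values must be n x d with d = len(names)")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def rows(self):
        """Iterate samples as dicts name -> value."""
        for row in self.values:
            yield {k: float(v) for k, v in zip(self.names, row)}


def lhs_sample(specs, n: int, seed: int | None = None) -> SampleMatrix:
    """Latin hypercube sample of the non-deterministic inputs.

    One sample falls in each of the ``n`` equal-probability strata per
    dimension; reproducible for a given seed.  Deterministic inputs are
    excluded (their fixed values belong in the model configuration).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    active = [s for s in specs if s.classification != "deterministic"]
    if not active:
        raise ValueError("no non-deterministic inputs to sample")
    sampler = qmc.LatinHypercube(d=len(active), seed=seed)
    u = sampler.random(n)
    lo = np.array([s.lower for s in active])
    hi = np.array([s.upper for s in active])
    return SampleMatrix(
        values=qmc.scale(u, lo, hi),
        names=tuple(s.name for s in active),
        bounds=tuple((s.lower, s.upper) for s in active),
        seed=seed,
    )


def pearson_rho(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance data")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# polynomial chaos expansion
# ---------------------------------------------------------------------------


def _multi_indices(d: int, order: int) -> list[tuple[int, ...]]:
    """Total-degree multi-index set, graded then lexicographic."""
    out = []
    for total in range(order + 1):
        for comb in itertools.combinations_with_replacement(range(d), total):
            idx = [0] * d
            for j in comb:
                idx[j] += 1
            out.append(tuple(idx))
    # combinations_with_replacement enumerates each multiset once per total
    return sorted(set(out), key=lambda ix: (sum(ix), ix))


def _legendre_design(z: np.ndarray, indices) -> np.ndarray:
    """Design matrix of orthonormal Legendre products on z in [-1, 1]^d."""
    n, d = z.shape
    max_deg = max(sum(ix) for ix in indices)
    # uni[j][k] = normalised Legendre_k at column j
    uni = np.empty((d, max_deg + 1, n))
    for k in range(max_deg + 1):
        c = np.zeros(k + 1)
        c[k] = 1.0
        vals = npleg.legval(z, c)  # shape (n, d) broadcast over last axis
        uni[:, k, :] = (math.sqrt(2 * k + 1) * vals).T
    A = np.ones((n, len(indices)))
    for col, ix in enumerate(indices):
        for j, k in enumerate(ix):
            if k:
                A[:, col] *= uni[j, k]
    return A


@dataclass
class PCEModel:
    """Least-squares polynomial chaos surrogate on rescaled inputs.

    Coefficients are stored per output name in the orthonormal Legendre basis,
    so the surrogate mean is the constant coefficient and the variance is the
    sum of squared non-constant coefficients.
    """

    order: int
    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    indices: tuple[tuple[int, ...], ...]
    coefficients: dict[str, np.ndarray]
    residual: dict[str, float] = field(default_factory=dict)
    condition: float = float("nan")

    @property
    def output_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def _rescale(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return 2.0 * (X - lo) / (hi - lo) - 1.0

    def predict(self, X, output: str | None = None):
        """Evaluate the surrogate at physical-space points X (n x d)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        A = _legendre_design(self._rescale(X), self.indices)
        if output is not None:
            return A @ self.coefficients[output]
        return {name: A @ c for name, c in self.coefficients.items()}

    def mean(self, output: str) -> float:
        return float(self.coefficients[output][0])

    def variance(self, output: str) -> float:
        c = self.coefficients[output]
        return float(np.sum(c[1:] ** 2))


def fit_pce(samples: SampleMatrix, outputs, order: int = 5) -> PCEModel:
    """Fit a total-degree PCE by least squares on LHS samples.

    ``outputs`` is a mapping output-name -> response vector (or a single
    vector, stored under "y").  The sample count must reach the basis size;
    a rank-deficient design raises with the condition number.  Any polynomial
    response of total degree <= order is reproduced exactly.
    """
    if isinstance(outputs, (list, tuple, np.ndarray)):
        outputs = {"y": np.asarray(outputs, dtype=float)}
    n, d = samples.values.shape
    indices = tuple(_multi_indices(d, order))
    if n < len(indices):
        raise ValueError(
            f"need at least {len(indices)} samples for a degree-{order} "
            f"basis in {d} inputs, got {n}"
        )
    lo = np.array([b[0] for b in samples.bounds])
    hi = np.array([b[1] for b in samples.bounds])
    z = 2.0 * (samples.values - lo) / (hi - lo) - 1.0
    A = _legendre_design(z, indices)
    cond = float(np.linalg.cond(A))
    coeffs: dict[str, np.ndarray] = {}
    resid: dict[str, float] = {}
    for name, y in outputs.items():
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise ValueError(f"output {name!r} must have one value per sample")
        sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < len(indices):
            raise ValueError(
                f"rank-deficient PCE design (rank {rank} < {len(indices)}, "
                f"condition {cond:.3e})"
            )
        coeffs[name] = sol
        resid[name] = float(np.sqrt(np.mean((A @ sol - y) ** 2)))
    return PCEModel(
        order=order,
        names=samples.names,
        bounds=samples.bounds,
        indices=indices,
        coefficients=coeffs,
        residual=resid,
        condition=cond,
    )


@dataclass(frozen=True)
class SobolReport:
    """Total Sobol indices per input per output, by both estimators.

    ``analytic`` comes exactly from the PCE coefficients; ``sampled`` from
    Saltelli/Jansen sampling of the surrogate with ``n_eval`` base samples.
    """

    names: tuple[str, ...]
    analytic: dict[str, dict[str, float]]
    sampled: dict[str, dict[str, float]] | None = None
    n_eval: int | None = None

    @property
    def total(self) -> dict[str, dict[str, float]]:
        return self.analytic

    def table(self):
        import pandas as pd

        frames = {"analytic": pd.DataFrame(self.analytic)}
        if self.sampled is not None:
            frames["sampled"] = pd.DataFrame(self.sampled)
        return pd.concat(frames, axis=1).reindex(list(self.names))


def _analytic_totals(model: PCEModel) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    idx = np.array(model.indices)  # (terms, d)
    for qoi, c in model.coefficients.items():
        var = np.sum(c[1:] ** 2)
        per_input = {}
        for j, name in enumerate(model.names):
            if var == 0.0:
                per_input[name] = 0.0
                continue
            mask = idx[:, j] > 0
            per_input[name] = float(np.sum(c[mask] ** 2) / var)
        out[qoi] = per_input
    return out


def _sampled_totals(
    model: PCEModel, n_eval: int, seed: int | None
) -> dict[str, dict[str, float]]:
    """Saltelli/Jansen total-index estimator on the surrogate.

    S_Ti = (1/2N) sum (f(A) - f(AB_i))^2 / Var, where the base matrices A and
    B are the two halves of a 2d-dimensional scrambled Sobol' sequence (the
    usual quasi-random Saltelli scheme) and AB_i equals A except for column i
    taken from B.
    """
    d = len(model.names)
    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*balance properties.*")
        base = qmc.Sobol(d=2 * d, seed=seed).random(n_eval)
    A = lo + (hi - lo) * base[:, :d]
    B = lo + (hi - lo) * base[:, d:]
    fA = model.predict(A)
    out: dict[str, dict[str, float]] = {q: {} for q in model.output_names}
    fABi = {}
    for j, name in enumerate(model.names):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        fABi[name] = model.predict(ABj)
    for qoi in model.output_names:
        var = float(np.var(fA[qoi], ddof=1))
        for name in model.names:
            if var == 0.0:
                out[qoi][name] = 0.0
            else:
                num = 0.5 * float(np.mean((fA[qoi] - fABi[name][qoi]) ** 2))
                out[qoi][name] = num / var
    return out


def total_sobol(
    model: PCEModel, n_eval: int = 5000, seed: int | None = None
) -> SobolReport:
    """Total Sobol indices from a fitted PCE.

    Reports the Saltelli-sampled estimate (``n_eval`` surrogate evaluations
    per matrix) alongside the exact analytic-from-coefficients values.
    """
    return SobolReport(
        names=model.names,
        analytic=_analytic_totals(model),
        sampled=_sampled_totals(model, n_eval, seed),
        n_eval=n_eval,
    )


def screen_inputs(
    report: SobolReport, threshold: float = 0.25, rule: str = "all"
) -> tuple[list[str], list[str]]:
    """Split inputs into (kept, dropped) by total-Sobol screening.

    rule="all" (default): drop an input only if its total index is below the
    threshold for every output.  rule="any": drop if below for at least one
    output.
    """
    if rule not in ("all", "any"):
        raise ValueError("rule must be 'all' or 'any'")
    kept, dropped = [], []
    totals = report.total
    for name in report.names:
        below = [totals[q][name] < threshold for q in totals]
        drop = all(below) if rule == "all" else any(below)
        (dropped if drop else kept).append(name)
    return kept, dropped
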