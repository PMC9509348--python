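"""Synthetic measurement generation and transfer-function fitting.

Flow-cytometry characterization of a gene circuit yields, per inducer
combination and biological replicate, a population of single-cell
fluorescence values that is approximately log-normal; the population is
summarized by its geometric median (for one-dimensional samples, the
ordinary median of values, equal to exp of the median of logs — an
unbiased estimator of the model output under multiplicative log-normal
noise).  :func:`generate_measurements` emulates that pipeline around any
perceptgene or network model, with a single explicitly seeded generator
and no global state, so every dataset is exactly reproducible.

:func:`fit_perceptgene` recovers model parameters from such a surface by
nonlinear least squares on log10 output.  Note an intrinsic degeneracy of
the model z = ((B prod x_i^{n_i})^m + beta)/(1 + (...)^m): only the
products m*n_i, m*log B and beta are identified by data, so the input
weights n_i are fit with the activation weight m held fixed (or the
products are reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import least_squares

from .model import PerceptgeneParams, Surface, evaluate_perceptgene

__all__ = [
    "NoiseModel",
    "FitResult",
    "generate_measurements",
    "fit_perceptgene",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal measurement noise with event sampling.

    ``cv`` is the coefficient of variation of single-event fluorescence
    around the model output; ``events`` the number of cytometry events per
    sample (each sample is summarized by its geometric median);
    ``replicates`` the number of independent cultures per condition.
    """

    cv: float = 0.1
    events: int = 10_000
    replicates: int = 3
    seed: int = 0
    detection_floor: float = 0.0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.events < 1 or self.replicates < 1:
            raise ValueError("events and replicates must be >= 1")


def _model_fn(truth) -> Callable[[Mapping[str, float]], float]:
    if isinstance(truth, PerceptgeneParams):
        return lambda point: float(evaluate_perceptgene(truth, point))
    if callable(truth):
        return truth
    # NetworkSpec duck-typed to avoid a hard import cycle
    from .network import evaluate_network
    return lambda point: evaluate_network(truth, point)[truth.output]


def generate_measurements(truth, grid: Mapping[str, np.ndarray],
                          noise: NoiseModel) -> Surface:
    """Simulate a replicate-resolved transfer-function surface.

    ``truth`` is a :class:`PerceptgeneParams`, a network spec, or a
    callable mapping an input dict to a scalar output.  ``grid`` maps each
    input name to its 1-D concentration axis; the surface covers the full
    rectangular grid.  Per grid point and replicate, ``noise.events``
    log-normal fluorescence draws around the model output are summarized
    by their geometric median.  Identical seeds give bit-identical output.
    """
    model = _model_fn(truth)
    rng = np.random.default_rng(noise.seed)
    axes = {k: np.asarray(v, dtype=float) for k, v in grid.items()}
    shape = tuple(len(v) for v in axes.values())
    clean = np.empty(shape)
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    for idx in np.ndindex(shape):
        point = {name: float(m[idx]) for name, m in zip(axes, mesh)}
        clean[idx] = model(point)
    if noise.cv == 0.0:
        out = np.broadcast_to(clean, (noise.replicates, *shape)).copy()
    else:
        sigma = math.sqrt(math.log1p(noise.cv ** 2))
        out = np.empty((noise.replicates, *shape))
        for r in range(noise.replicates):
            for idx in np.ndindex(shape):
                events = np.exp(
                    rng.normal(math.log(clean[idx]), sigma, size=noise.events)
                )
                out[(r, *idx)] = np.exp(np.median(np.log(events)))
    if noise.detection_floor > 0.0:
        out = np.maximum(out, noise.detection_floor)
    if noise.replicates == 1:
        out = out[0]
    return Surface(inputs=axes, outputs=out, coordinates="linear",
                   replicates=noise.replicates)


@dataclass
class FitResult:
    """Fitted parameters and log-space goodness of fit."""

    params: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    success: bool
    message: str = ""

    def __post_init__(self):
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


def fit_perceptgene(surface: Surface, form: str = "single_kd",
                    hill: float | None = None,
                    weight_bounds=(0.0, 3.0),
                    basal_bounds=(1e-6, 0.5)) -> FitResult:
    """Nonlinear least-squares perceptgene fit on log10 output.

    ``form='single_kd'`` fits z = (y^m + beta)/(1 + y^m) with
    y = B prod (x_i/K_i)^{n_i} (K_i taken from the data scale, folded into
    B); ``form='two_kd'`` fits the variant with distinct scale constants
    in numerator and denominator,
    z = ((c/Kn)^m + beta)/((c/Kd)^m + 1).  ``hill`` fixes m (required for
    weight identifiability when the weights are free; if None, m is free
    and the products m*n_i are what the data determine).  Reports R^2 in
    log space; raises with best-so-far diagnostics on convergence failure.
    """
    if form not in ("single_kd", "two_kd"):
        raise ValueError("form must be 'single_kd' or 'two_kd'")
    names = surface.input_names
    k = len(names)
    mesh = surface.meshgrid()
    logx = np.stack([np.log10(mesh[n]).ravel() for n in names], axis=0)
    logz = np.log10(surface.mean_output()).ravel()
    n_free = k + 2 + (1 if hill is None else 0) + (1 if form == "two_kd" else 0)
    if logz.size < n_free + 2:
        raise ValueError(
            f"need at least {n_free + 2} grid points to fit {n_free} parameters"
        )

    def unpack(theta):
        w = theta[:k]
        logB = theta[k]
        logbeta = theta[k + 1]
        pos = k + 2
        m = hill
        if m is None:
            m = theta[pos]
            pos += 1
        dlogk = theta[pos] if form == "two_kd" else 0.0
        return w, logB, logbeta, m, dlogk

    def predict(theta):
        w, logB, logbeta, m, dlogk = unpack(theta)
        logy = logB + w @ logx
        num = 10.0 ** (m * (logy + dlogk)) + 10.0 ** logbeta
        den = 1.0 + 10.0 ** (m * logy)
        return np.log10(num / den)

    def resid(theta):
        return predict(theta) - logz

    z_lo = max(10.0 ** logz.min() / 10.0 ** logz.max(), basal_bounds[0] * 2)
    theta0 = [0.5] * k + [0.0, math.log10(min(z_lo, basal_bounds[1] * 0.9))]
    lb = [weight_bounds[0]] * k + [-6.0, math.log10(basal_bounds[0])]
    ub = [weight_bounds[1]] * k + [6.0, math.log10(basal_bounds[1])]
    if hill is None:
        theta0 += [1.0]; lb += [0.05]; ub += [10.0]
    if form == "two_kd":
        theta0 += [0.0]; lb += [-4.0]; ub += [4.0]
    sol = least_squares(resid, np.clip(theta0, lb, ub), bounds=(lb, ub),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    w, logB, logbeta, m, dlogk = unpack(sol.x)
    params = {f"n_{name}": float(wi) for name, wi in zip(names, w)}
    params["bias"] = float(10.0 ** logB)
    params["basal"] = float(10.0 ** logbeta)
    params["hill"] = float(m)
    if form == "two_kd":
        params["kd_ratio_log10"] = float(dlogk)
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((logz - logz.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not sol.success:
        raise RuntimeError(
            f"perceptgene fit did not converge: {sol.message}; best-so-far {params}"
        )
    return FitResult(params=params, r_squared=min(r2, 1.0),
                     residuals=sol.fun.reshape(surface.grid_shape),
                     success=True, message=sol.message)
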