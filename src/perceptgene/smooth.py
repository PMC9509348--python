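"""Rectifier activations and smooth min / max / average surface extraction.

A perceptgene whose activation stage is driven at low inducer levels
behaves, in log coordinates, like a *negative rectifier*: promoter
activity follows log(activator) up to a threshold u01 and saturates
above it, i.e. it computes ``min(u01, v)`` plus an offset.  Driven at
high inducer levels the same stage is a *positive rectifier*,
``max(u02, v)`` plus an offset.  Because the rectifier input v is itself
a weighted sum of log-inputs, the shift identities

    min(u, x + y) = min(u - y, x) + y
    max(u, x + y) = max(u - y, x) + y

turn the unit into a smooth minimum (or maximum) of two log-transformed
analog signals, up to an affine offset in the second input.  This module
provides the rectifiers, the identities, and the extraction of the
min/max/average computation from a measured or simulated transfer
surface, together with a normalized standard-error figure of merit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .model import Surface

__all__ = [
    "RectifierParams",
    "IdealSurface",
    "neg_rectifier",
    "pos_rectifier",
    "shift_identity_residual",
    "smooth_min",
    "smooth_max",
    "extract_min_surface",
    "extract_max_surface",
    "ideal_average",
    "extract_average_surface",
    "surface_standard_error",
    "simulate_min_circuit",
    "FIG1J_MIN_PARAMS",
    "FIG2F_MAX_PARAMS",
]


@dataclass(frozen=True)
class RectifierParams:
    """Constants of a rectifier-activation perceptgene used for extraction.

    ``threshold`` is u01 (negative kind) or u02 (positive kind) in log10
    units; ``weight_primary`` / ``weight_secondary`` are the power-law
    weights of the input plotted on the min/max branch and of the
    offset-carrying input; ``offset_weight`` is the empirical cross-talk
    slope w of the saturated branch on the secondary input;
    ``offset_const`` and ``log_bias`` are the lumped constants (const and
    log10 B) of the extraction formula; ``idr_log`` holds log10 of the two
    input dynamic ranges.
    """

    kind: str  # "negative" or "positive"
    weight_primary: float
    weight_secondary: float
    offset_weight: float
    offset_const: float
    log_bias: float
    idr_log: tuple[float, float]
    threshold: float = 0.0
    aracmax_log: float = 0.0

    def __post_init__(self):
        if self.kind not in ("negative", "positive"):
            raise ValueError("kind must be 'negative' or 'positive'")
        if any(l <= 0 for l in self.idr_log):
            raise ValueError("IDR must be > 1 for each input (log10 IDR > 0)")


#: Smooth-minimum device constants (IPTG primary branch, aTc offset arm).
FIG1J_MIN_PARAMS = RectifierParams(
    kind="negative",
    weight_primary=0.337,
    weight_secondary=0.473,
    offset_weight=0.3,
    offset_const=0.6,
    log_bias=-1.0,
    idr_log=(2.1, 2.1),
)

#: Smooth-maximum device constants (aTc primary branch, AHL offset arm).
FIG2F_MAX_PARAMS = RectifierParams(
    kind="positive",
    weight_primary=0.45,   # n6, aTc branch
    weight_secondary=0.55,  # n5, AHL offset arm
    offset_weight=0.22,
    offset_const=0.1,
    log_bias=-0.2,
    idr_log=(1.8, 1.5),    # (aTc, AHL)
)


@dataclass
class IdealSurface:
    """An ideal min/max/average surface and residuals of extracted data."""

    grid: dict[str, np.ndarray]       # normalized log10 axes
    ideal: np.ndarray
    extracted: np.ndarray | None = None

    @property
    def residuals(self) -> np.ndarray:
        if self.extracted is None:
            raise ValueError("no extracted surface to compare against")
        return self.extracted - self.ideal


def neg_rectifier(v, u01: float, f_max: float = 0.0):
    """Shifted, biased log-transformed negative rectifier: min(u01, v) + f_max."""
    return np.minimum(u01, v) + f_max


def pos_rectifier(v, u02: float, f_min: float = 0.0):
    """Shifted, biased log-transformed positive rectifier: max(u02, v) + f_min."""
    return np.maximum(u02, v) + f_min


def shift_identity_residual(u: float, x: float, y: float, kind: str = "min") -> float:
    """|min(u, x+y) - (min(u-y, x) + y)| (or the max analog); exactly 0.

    Evaluated in exact rational arithmetic (binary floats are rationals),
    so the shift identity holds to literal zero for every finite triple,
    not merely to rounding error."""
    if kind not in ("min", "max"):
        raise ValueError("kind must be 'min' or 'max'")
    uf, xf, yf = Fraction(u), Fraction(x), Fraction(y)
    op = min if kind == "min" else max
    return float(abs(op(uf, xf + yf) - (op(uf - yf, xf) + yf)))


def smooth_min(p, q, sharpness: float = 2.2):
    """Soft minimum with Hill-type corner rounding of width ~1/sharpness decades.

    Converges to elementwise min as sharpness -> infinity.
    """
    m = float(sharpness)
    pm, qm = -m * np.asarray(p), -m * np.asarray(q)
    hi = np.maximum(pm, qm)
    return -(hi + np.log10(10.0 ** (pm - hi) + 10.0 ** (qm - hi))) / m


def smooth_max(p, q, sharpness: float = 2.2):
    """Soft maximum, the mirror of :func:`smooth_min`."""
    return -smooth_min(-np.asarray(p), -np.asarray(q), sharpness)


def _normalized_axes(surface: Surface, p: RectifierParams):
    if len(surface.inputs) != 2:
        raise ValueError(
            f"extraction requires a two-input surface, got {len(surface.inputs)}"
        )
    (name1, grid1), (name2, grid2) = surface.inputs.items()
    if surface.coordinates == "log10":
        lg1, lg2 = grid1, grid2
    else:
        lg1, lg2 = np.log10(grid1), np.log10(grid2)
    # normalize so the top of each input dynamic range maps to 0
    a = lg1 - lg1.max()
    b = lg2 - lg2.max()
    return (name1, a), (name2, b)


def _log_output(surface: Surface) -> np.ndarray:
    """Measured output normalized by its minimum level, in decades."""
    out = surface.mean_output()
    if surface.coordinates == "log10":
        logout = out
    else:
        logout = np.log10(out)
    return logout - logout.min()


def _extract(surface: Surface, p: RectifierParams, ideal_fn):
    (n1, a), (n2, b) = _normalized_axes(surface, p)
    A, B = np.meshgrid(a, b, indexing="ij")
    ideal = ideal_fn(A, B)
    offset = p.weight_secondary * B + p.offset_const + p.log_bias
    predicted = ideal + offset
    # measured data are normalized by the minimum level, which discards the
    # absolute scale; re-anchor with the predicted surface's own minimum
    extracted = _log_output(surface) - offset + predicted.min()
    return IdealSurface(grid={n1: a, n2: b}, ideal=ideal, extracted=extracted)


def extract_min_surface(surface: Surface, p: RectifierParams) -> IdealSurface:
    """Extract the smooth-minimum computation from a two-input surface.

    The ideal surface is ``min{ n3*a, log B2 - (n4 - w1)*b }`` on the
    IDR-normalized log axes (a, b); the affine offset
    ``n4*b + const1 + log B2`` carried by the measured output is removed
    before comparison.
    """
    if p.kind != "negative":
        raise ValueError("minimum extraction requires a negative-kind rectifier")
    n3, n4, w1 = p.weight_primary, p.weight_secondary, p.offset_weight

    def ideal(A, B):
        return np.minimum(n3 * A, p.log_bias - (n4 - w1) * B)

    return _extract(surface, p, ideal)


def extract_max_surface(surface: Surface, p: RectifierParams) -> IdealSurface:
    """Extract the smooth-maximum computation from a two-input surface.

    Ideal: ``max{ n6*a, log B3 - (n5 - w2)*b }`` with the primary input on
    the first axis and the offset-carrying input on the second.
    """
    if p.kind != "positive":
        raise ValueError("maximum extraction requires a positive-kind rectifier")
    n6, n5, w2 = p.weight_primary, p.weight_secondary, p.offset_weight

    def ideal(A, B):
        return np.maximum(n6 * A, p.log_bias - (n5 - w2) * B)

    return _extract(surface, p, ideal)


def ideal_average(a, b, offset: float = -0.25):
    """Log-domain average (a + b)/2 + offset of two normalized log inputs."""
    return (np.asarray(a) + np.asarray(b)) / 2.0 + offset


def extract_average_surface(surface: Surface, idr_log: tuple[float, float],
                            offset: float = -0.25) -> IdealSurface:
    """Compare a two-input surface against the ideal log-domain average."""
    p = RectifierParams(kind="negative", weight_primary=0.5, weight_secondary=0.0,
                        offset_weight=0.0, offset_const=0.0, log_bias=offset,
                        idr_log=idr_log)
    (n1, a), (n2, b) = _normalized_axes(surface, p)
    A, B = np.meshgrid(a, b, indexing="ij")
    ideal = ideal_average(A, B, offset)
    extracted = _log_output(surface) + ideal.min()
    return IdealSurface(grid={n1: a, n2: b}, ideal=ideal, extracted=extracted)


def surface_standard_error(s: IdealSurface) -> float:
    """Percent standard error: 100 * RMSE(residuals) / ideal log-output span."""
    span = float(np.ptp(s.ideal))
    if span == 0.0:
        raise ValueError("ideal surface has zero output range")
    rmse = float(np.sqrt(np.mean(s.residuals ** 2)))
    return 100.0 * rmse / span


def simulate_min_circuit(
    n_points: int = 17,
    weights: tuple[float, float] = (0.3375, 0.4375),
    sharpness: float = 2.2,
    basal: float = 0.045,
    p: RectifierParams = FIG1J_MIN_PARAMS,
) -> Surface:
    """Simulate the smooth-minimum perceptgene's transfer surface.

    The power-law stage carries the measured input weights (IPTG 0.3375,
    aTc 0.4375); the activation stage is the negative rectifier
    of the device, smoothed with the finite Hill steepness of the measured
    activation (sharpness m = 2.2) and floored at the basal level
    beta = 0.045.  The offset arm (cross-talk of the secondary input on the
    saturated branch, slope w1) and the lumped bias/threshold constants are
    those of the extraction parameter set.
    """
    n3c, n4c = weights
    lo1, lo2 = p.idr_log
    # inputs span their dynamic range: one IDR ending at 10**log10(IDR)
    in1 = np.logspace(0.0, lo1, n_points)
    in2 = np.logspace(0.0, lo2, n_points)
    a = np.log10(in1) - lo1
    b = np.log10(in2) - lo2
    A, B = np.meshgrid(a, b, indexing="ij")
    branch1 = n3c * A
    branch2 = p.log_bias - (n4c - p.offset_weight) * B
    body = smooth_min(branch1, branch2, sharpness)
    offset = n4c * B + p.offset_const + p.log_bias
    logout = body + offset
    # basal floor: activity cannot fall below beta relative to its maximum
    floor = logout.max() + math.log10(basal)
    logout = smooth_max(logout, floor, sharpness)
    return Surface(inputs={"input1": in1, "input2": in2},
                   outputs=10.0 ** logout, coordinates="linear")
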