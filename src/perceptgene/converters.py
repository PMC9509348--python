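"""Behavioral models of genetically encoded data converters.

A 2-bit analog-to-digital converter (ADC) maps one analog inducer input x
onto two promoter outputs read as bits: the most significant bit (MSB)
switches at a high input threshold, while the least significant bit (LSB)
must be high in the second and fourth quarters of the input range only.
The non-monotone LSB is realized by *transcriptional interference*: a
promoter convergently oriented against the LSB promoter, driven by the
MSB signal, subtracts its activity from the LSB's.  Two designs are
modeled: v1 uses a single LSB whose interference is nullified at high
input by a repressor arm (so the LSB recovers for the 11 code); v2 keeps
the interference always on and instead aggregates a second, high-threshold
LSB unit onto the same output.  Dropping the v1 nullification arm
reproduces the control circuit whose code sequence terminates at 10.

The same v2 architecture read out as a single aggregated analog level
(MSB and LSB activities summed onto one reporter) yields a ternary
switch: low / medium / high output plateaus separated by two thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import PerceptgeneParams, collective_signal, evaluate_perceptgene

__all__ = [
    "ConverterDesign",
    "CodeSequence",
    "interference_subtract",
    "adc_evaluate",
    "digitize",
    "code_sequence",
    "ternary_evaluate",
    "TernaryResult",
    "adc_v1_fixture",
    "adc_v2_fixture",
    "default_sweep",
]


def _unit(K: float, hill: float, basal: float) -> PerceptgeneParams:
    return PerceptgeneParams(input_names=("x",), weights=(1.0,), input_scales=(K,),
                             bias=1.0, hill=hill, basal=basal, activation_kind="sigmoid")


@dataclass
class ConverterDesign:
    """Stage perceptgenes plus interference and aggregation links.

    ``interference`` strength rho >= 0 scales the interfering (MSB-driven)
    promoter activity subtracted from the LSB promoter activity.  In v1
    the strength decays once the MSB collective exceeds ``K_null``
    (rho(x) = rho0 / (1 + (y_msb/K_null)**h_null)); in v2 it persists and
    a separate high-threshold LSB unit is aggregated onto the LSB output.
    """

    version: str
    msb: PerceptgeneParams
    lsb_low: PerceptgeneParams
    lsb_high: PerceptgeneParams | None = None
    rho0: float = 1.0
    K_null: float | None = None
    h_null: float = 2.0
    msb_threshold: float = 0.5
    lsb_threshold: float = 0.5
    nullification: bool = False

    def __post_init__(self):
        if self.version not in ("v1", "v2"):
            raise ValueError("design version must be 'v1' or 'v2'")
        if self.rho0 < 0:
            raise ValueError("interference strength rho must be >= 0")
        for name, t, params in (("msb", self.msb_threshold, self.msb),
                                ("lsb", self.lsb_threshold, self.lsb_low)):
            if not (params.basal < t < 1.0):
                raise ValueError(f"{name} threshold must lie in (basal, 1)")
        if self.version == "v2" and self.lsb_high is None:
            raise ValueError("v2 design requires an LSB_high unit")
        if self.nullification and self.K_null is None:
            raise ValueError("nullification arm requires K_null")


def interference_subtract(primary, interfering, rho: float = 1.0, floor: float = 0.0):
    """Net promoter activity max(primary - rho * interfering, floor).

    Models convergent-promoter transcriptional interference as clipped
    linear subtraction; monotone decreasing in the interfering activity.
    """
    primary = np.asarray(primary, dtype=float)
    interfering = np.asarray(interfering, dtype=float)
    if np.any(primary < 0) or np.any(interfering < 0):
        raise ValueError("promoter activities must be >= 0")
    out = np.maximum(primary - rho * interfering, floor)
    return out if out.ndim else float(out)


def _rho(design: ConverterDesign, x: float) -> float:
    if not design.nullification:
        return design.rho0
    y_msb = float(collective_signal(design.msb, {"x": x}))
    return design.rho0 / (1.0 + (y_msb / design.K_null) ** design.h_null)


def adc_evaluate(design: ConverterDesign, x: float) -> tuple[float, float]:
    """Analog (MSB, LSB) promoter activities at input concentration x."""
    if x <= 0:
        raise ValueError("input concentration must be > 0")
    z_msb = float(evaluate_perceptgene(design.msb, {"x": x}))
    z_low = float(evaluate_perceptgene(design.lsb_low, {"x": x}))
    beta = design.lsb_low.basal
    net = interference_subtract(z_low, z_msb, _rho(design, x), floor=beta)
    if design.version == "v1":
        lsb = min(net, 1.0)
    else:
        z_high = float(evaluate_perceptgene(design.lsb_high, {"x": x}))
        lsb = float(np.clip(net + z_high - beta, beta, 1.0))
    return z_msb, lsb


def digitize(msb_analog: float, lsb_analog: float,
             thresholds: tuple[float, float] = (0.5, 0.5)) -> int:
    """Per-bit comparison (>= threshold reads 1); code = 2*MSB + LSB."""
    msb = 1 if msb_analog >= thresholds[0] else 0
    lsb = 1 if lsb_analog >= thresholds[1] else 0
    return 2 * msb + lsb


@dataclass
class CodeSequence:
    """Digitized sweep of a converter over an ascending input grid."""

    grid: np.ndarray
    msb_analog: np.ndarray
    lsb_analog: np.ndarray
    codes: np.ndarray
    runs: list[tuple[int, int, int]] = field(default_factory=list)  # (code, i0, i1)

    @property
    def run_codes(self) -> list[int]:
        return [c for c, _, _ in self.runs]

    @property
    def transitions(self) -> list[tuple[float, int, int]]:
        """(input location, code before, code after) for each code change."""
        out = []
        for (c0, _, i1), (c1, i0b, _) in zip(self.runs, self.runs[1:]):
            out.append((float(np.sqrt(self.grid[i1] * self.grid[i0b])), c0, c1))
        return out

    def glitches(self, max_width_decades: float = 0.1) -> list[tuple[int, float]]:
        """Runs that break the monotone code progression, with their widths.

        A glitch is a run whose code is not >= the previous surviving code;
        widths are measured in decades of input."""
        out = []
        level = None
        for code, i0, i1 in self.runs:
            width = float(np.log10(self.grid[i1] / self.grid[i0])) if i1 > i0 else 0.0
            if level is not None and code < level:
                out.append((code, width))
            else:
                level = code
        return out

    def is_monotone(self, max_glitch_decades: float = 0.1) -> bool:
        return all(w < max_glitch_decades for _, w in self.glitches())


def code_sequence(design: ConverterDesign, grid,
                  thresholds: tuple[float, float] | None = None) -> CodeSequence:
    """Evaluate and digitize the converter over an ascending input grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("input grid must be strictly ascending")
    if thresholds is None:
        thresholds = (design.msb_threshold, design.lsb_threshold)
    msb = np.empty_like(grid)
    lsb = np.empty_like(grid)
    for i, x in enumerate(grid):
        msb[i], lsb[i] = adc_evaluate(design, x)
    codes = np.array([digitize(m, l, thresholds) for m, l in zip(msb, lsb)])
    runs = []
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            runs.append((int(codes[start]), start, i - 1))
            start = i
    return CodeSequence(grid=grid, msb_analog=msb, lsb_analog=lsb,
                        codes=codes, runs=runs)


@dataclass
class TernaryResult:
    grid: np.ndarray
    output: np.ndarray
    levels: np.ndarray          # 0 = low, 1 = medium, 2 = high
    n_plateaus: int

    @property
    def level_sequence(self) -> list[int]:
        seq = [int(self.levels[0])]
        for v in self.levels[1:]:
            if v != seq[-1]:
                seq.append(int(v))
        return seq


def ternary_evaluate(design: ConverterDesign, grid,
                     thresholds: tuple[float, float] = (0.25, 0.75),
                     gains: tuple[float, float] = (1.0, 1.0)) -> TernaryResult:
    """Three-level switch: MSB and LSB activities aggregated on one output.

    The aggregated analog output (g_m * MSB + g_l * LSB) / (g_m + g_l)
    plateaus at low (both off), medium (interference hands the activity
    from LSB to MSB across the middle of the range) and high (both on);
    the classifier cuts at the two supplied thresholds.  Fewer than three
    distinct plateaus raises a quality warning, not an exception."""
    t1, t2 = thresholds
    if not (t1 <= t2):
        raise ValueError("ternary thresholds must be ordered")
    grid = np.asarray(grid, dtype=float)
    g_m, g_l = gains
    out = np.empty_like(grid)
    for i, x in enumerate(grid):
        m, l = adc_evaluate(design, x)
        out[i] = (g_m * m + g_l * l) / (g_m + g_l)
    levels = np.digitize(out, [t1, t2])
    n_plateaus = len({int(v) for v in levels})
    if n_plateaus < 3:
        warnings.warn(
            f"ternary fixture produced only {n_plateaus} distinct levels",
            stacklevel=2,
        )
    return TernaryResult(grid=grid, output=out, levels=levels, n_plateaus=n_plateaus)


# -- pinned fixtures -------------------------------------------------------
# Parameters chosen by automated search so the four codes occupy roughly
# equal decades of a 4-decade sweep; synthetic design points, not the
# biological parameter values.

_BETA = 0.005


def adc_v1_fixture(nullification: bool = True) -> ConverterDesign:
    """v1 design: single LSB; interference nullified at high input.

    With ``nullification=False`` this is the control circuit whose
    interfering promoter stays active at high input, so the code sequence
    terminates at 10."""
    return ConverterDesign(
        version="v1",
        msb=_unit(K=0.1, hill=2.5, basal=_BETA),
        lsb_low=_unit(K=0.01, hill=2.5, basal=_BETA),
        rho0=1.0,
        K_null=10.0,   # in MSB collective units: nullifies for x >> 1
        h_null=2.0,
        nullification=nullification,
    )


def adc_v2_fixture() -> ConverterDesign:
    """v2 design: persistent interference plus aggregated LSB_high unit."""
    return ConverterDesign(
        version="v2",
        msb=_unit(K=0.1, hill=2.5, basal=_BETA),
        lsb_low=_unit(K=0.01, hill=2.5, basal=_BETA),
        lsb_high=_unit(K=1.2, hill=3.0, basal=_BETA),
        rho0=1.0,
    )


def default_sweep(n: int = 64) -> np.ndarray:
    """Four-decade input sweep used by the pinned fixtures."""
    return np.logspace(-3, 1, n)
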