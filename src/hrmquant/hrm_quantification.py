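"""The HRM quantification chain.

Raw melt traces are normalized between fitted pre- and post-melt baselines
(pre-melt = 100 % fluorescence, post-melt = 0 %), the area under the
normalized melt curve (AUC, in % x °C) is integrated, a linear calibration
of known methylation on standard AUC is fitted by ordinary least squares,
and unknown samples are interpolated through that line.  Replicate calls are
aggregated by mean with a discordance flag.

Because a methylated amplicon melts later, its normalized curve stays high
over a wider temperature range and its AUC is larger; on a two-species
mixture the AUC is affine in the methylated fraction, which is what makes
the linear standard curve work.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, NormalizationError
from .melt_simulator import MeltCurve
from .util import round_half_away

__all__ = [
    "NormalizedCurve",
    "CalibrationStandard",
    "CalibrationModel",
    "MethylationCall",
    "InterpolationResult",
    "ReplicateSummary",
    "normalize_curve",
    "melt_auc",
    "fit_calibration",
    "interpolate_methylation",
    "expected_mixture_methylation",
    "aggregate_replicates",
    "calibrate_from_curves",
    "quantify_samples",
]

#: Width of the default pre-/post-melt normalization windows (°C), taken
#: from each end of the acquisition interval.  The fitted baseline is
#: extrapolated across the whole analysis interval, and the variance of an
#: extrapolated line grows as d^2 / Sxx ~ d^2 / width^3; 4 °C keeps that
#: extrapolation well conditioned at realistic read noise while staying
#: clear of the melt transitions on the default 70-90 °C grid.
DEFAULT_WINDOW_WIDTH = 4.0


@dataclass(frozen=True)
class NormalizedCurve:
    """A melt trace rescaled to percent fluorescence between its baselines."""

    temperatures: np.ndarray
    norm_rfu: np.ndarray
    source: str

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        v = np.asarray(self.norm_rfu, float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "norm_rfu", v)
        if t.size != v.size:
            raise ValueError("array length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("normalized values must be finite")


@dataclass(frozen=True)
class CalibrationStandard:
    """One standard level: known methylation (%) and its replicate AUCs."""

    known_methylation: float
    replicate_aucs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.known_methylation <= 100.0:
            raise ValueError("known_methylation must be in [0, 100]")
        if not self.replicate_aucs:
            raise ValueError("at least one replicate AUC required")

    @property
    def auc(self) -> float:
        return float(np.mean(self.replicate_aucs))


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from melt AUC to percent methylation, with fit quality."""

    slope: float
    intercept: float
    r_squared: float
    auc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class InterpolationResult:
    percent: float
    extrapolated: bool


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    range: float
    discordant: bool


@dataclass(frozen=True)
class MethylationCall:
    """Final per-sample call for one assay."""

    sample_id: str
    assay: str  # HRM | MSP | PSQ
    percent_methylation: float | None
    status: str  # methylated | unmethylated
    cutoff_used: float
    extrapolated: bool = False
    replicate_range: float = 0.0


def _fit_window_line(curve: MeltCurve, window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = window
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    if mask.sum() < 3:
        raise NormalizationError(
            f"window {window} contains {int(mask.sum())} points; need >= 3"
        )
    coef = np.polyfit(curve.temperatures[mask], curve.rfu[mask], 1)
    return float(coef[0]), float(coef[1])  # slope, intercept


def normalize_curve(
    curve: MeltCurve,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> NormalizedCurve:
    """Two-line baseline normalization of a melt trace.

    A straight line is least-squares fitted to the fluorescence inside each
    window; the normalized signal is

        100 * (F(T) - L_post(T)) / (L_pre(T) - L_post(T)),

    evaluated pointwise, so the pre-melt region reads ~100 % and the
    post-melt region ~0 %.  Defaults take the first and last 4 °C of the
    trace (see :data:`DEFAULT_WINDOW_WIDTH` for why narrower windows make
    the extrapolated baseline ill-conditioned).  The output is restricted
    to [pre start, post end].
    """
    t = curve.temperatures
    if pre_window is None:
        pre_window = (float(t[0]), float(t[0]) + DEFAULT_WINDOW_WIDTH)
    if post_window is None:
        post_window = (float(t[-1]) - DEFAULT_WINDOW_WIDTH, float(t[-1]))
    if pre_window[1] >= post_window[0]:
        raise NormalizationError(
            f"pre-melt window {pre_window} must end before post-melt window {post_window}"
        )
    pre_s, pre_i = _fit_window_line(curve, pre_window)
    post_s, post_i = _fit_window_line(curve, post_window)

    mask = (t >= pre_window[0]) & (t <= post_window[1])
    tt = t[mask]
    l_pre = pre_s * tt + pre_i
    l_post = post_s * tt + post_i
    denom = l_pre - l_post
    if np.any(denom <= 0):
        raise NormalizationError("pre-melt baseline does not exceed post-melt baseline everywhere")
    norm = 100.0 * (curve.rfu[mask] - l_post) / denom
    return NormalizedCurve(temperatures=tt, norm_rfu=norm, source=curve.well_id)


def melt_auc(
    nc: NormalizedCurve,
    integration_interval: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area under the normalized melt curve, in % x °C."""
    t, v = nc.temperatures, nc.norm_rfu
    if integration_interval is not None:
        lo, hi = integration_interval
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or lo >= hi:
            raise ValueError(
                f"integration interval {integration_interval} outside normalized range "
                f"[{t[0]}, {t[-1]}]"
            )
        mask = (t >= lo) & (t <= hi)
        t, v = t[mask], v[mask]
    return float(np.trapezoid(v, t))


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationModel:
    """OLS of known methylation on mean standard AUC.

    The regression is oriented as a direct interpolation map
    (methylation = slope * AUC + intercept), so reading off an unknown is a
    single evaluation rather than an inversion.
    """
    levels = {s.known_methylation for s in standards}
    if len(levels) < 3:
        raise CalibrationError(
            f"need >= 3 distinct methylation levels, got {len(levels)}"
        )
    x = np.array([s.auc for s in standards], float)
    y = np.array([s.known_methylation for s in standards], float)
    if np.ptp(x) == 0:
        raise CalibrationError("standard AUCs have zero variance")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        auc_range=(float(x.min()), float(x.max())),
    )


def interpolate_methylation(model: CalibrationModel, auc: float) -> InterpolationResult:
    """Map an unknown sample's AUC to percent methylation through the model.

    The raw linear readout is clamped to [0, 100]; an AUC outside the range
    spanned by the standards is flagged as extrapolated.
    """
    if model.slope == 0:
        raise CalibrationError("degenerate calibration model (zero slope)")
    raw = model.slope * auc + model.intercept
    extrapolated = not (model.auc_range[0] <= auc <= model.auc_range[1])
    return InterpolationResult(
        percent=float(np.clip(raw, 0.0, 100.0)),
        extrapolated=extrapolated,
    )


def expected_mixture_methylation(
    fraction_methylated_standard: float,
    meth_endpoint: float = 90.8,
    unmeth_endpoint: float = 2.1,
) -> float:
    """Methylation content of a mix of the two endpoint standard DNAs.

    A standard built by mixing a fully methylated DNA measuring
    ``meth_endpoint`` % with an unmethylated DNA measuring
    ``unmeth_endpoint`` % at volume fraction ``f`` carries
    ``f * meth + (1 - f) * unmeth`` percent methylation; the defaults are
    the endpoint values of the reference standards (90.8 % and 2.1 %), so a
    theoretical 25 % mix actually measures 24.3 %.  Reported to one decimal,
    ties away from zero.
    """
    f = fraction_methylated_standard
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    for e in (meth_endpoint, unmeth_endpoint):
        if not 0.0 <= e <= 100.0:
            raise ValueError("endpoints must be in [0, 100]")
    from decimal import Decimal

    df = Decimal(repr(f))
    val = df * Decimal(repr(meth_endpoint)) + (1 - df) * Decimal(repr(unmeth_endpoint))
    return round_half_away(float(val), 1)


def aggregate_replicates(
    calls: Sequence[float], discordance_threshold: float = 10.0
) -> ReplicateSummary:
    """Mean and range of replicate percent calls, flagging wide disagreement."""
    if len(calls) == 0:
        raise ValueError("at least one replicate required")
    arr = np.asarray(calls, float)
    rng = float(arr.max() - arr.min())
    return ReplicateSummary(
        mean=float(arr.mean()),
        range=rng,
        discordant=rng > discordance_threshold,
    )


# ---------------------------------------------------------------------------
# pipeline helpers over collections of curves
# ---------------------------------------------------------------------------

def _curve_auc(
    curve: MeltCurve,
    pre_window: tuple[float, float] | None,
    post_window: tuple[float, float] | None,
    integration_interval: tuple[float, float] | None,
) -> float:
    nc = normalize_curve(curve, pre_window, post_window)
    return melt_auc(nc, integration_interval)


def calibrate_from_curves(
    curves: Iterable[MeltCurve],
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    integration_interval: tuple[float, float] | None = None,
) -> tuple[CalibrationModel, list[CalibrationStandard]]:
    """Build the standard curve from all role='standard' traces.

    Each standard's known methylation is its known mixture fraction x 100
    (the standards carry their measured methylation content, not the
    theoretical mixing ratio).
    """
    by_level: dict[float, list[float]] = {}
    for c in curves:
        if c.role != "standard":
            continue
        if c.known_fraction is None:
            raise CalibrationError(f"standard curve {c.well_id} lacks known_fraction")
        auc = _curve_auc(c, pre_window, post_window, integration_interval)
        by_level.setdefault(c.known_fraction, []).append(auc)
    if not by_level:
        raise CalibrationError("no standard curves found")
    standards = [
        CalibrationStandard(known_methylation=f * 100.0, replicate_aucs=tuple(aucs))
        for f, aucs in sorted(by_level.items())
    ]
    return fit_calibration(standards), standards


def quantify_samples(
    curves: Iterable[MeltCurve],
    model: CalibrationModel,
    cutoff: float = 5.0,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    integration_interval: tuple[float, float] | None = None,
    discordance_threshold: float = 10.0,
) -> list[MethylationCall]:
    """Quantify all role='sample' traces, aggregating replicates per sample."""
    by_sample: dict[str, list[tuple[float, bool]]] = {}
    order: list[str] = []
    for c in curves:
        if c.role != "sample":
            continue
        auc = _curve_auc(c, pre_window, post_window, integration_interval)
        res = interpolate_methylation(model, auc)
        if c.sample_id not in by_sample:
            order.append(c.sample_id)
        by_sample.setdefault(c.sample_id, []).append((res.percent, res.extrapolated))
    calls: list[MethylationCall] = []
    for sid in order:
        percents = [p for p, _ in by_sample[sid]]
        extrap = any(e for _, e in by_sample[sid])
        summ = aggregate_replicates(percents, discordance_threshold)
        calls.append(
            MethylationCall(
                sample_id=sid,
                assay="HRM",
                percent_methylation=summ.mean,
                status="methylated" if summ.mean >= cutoff else "unmethylated",
                cutoff_used=cutoff,
                extrapolated=extrap,
                replicate_range=summ.range,
            )
        )
    return calls
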