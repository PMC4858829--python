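"""Two-state melt-curve simulator for bisulfite-converted amplicons.

Stands in for a real-time PCR instrument acquiring fluorescence while the
PCR product denatures on a fine temperature ramp (one reading per 0.2 °C).
After bisulfite conversion, a methylated template retains its CpG cytosines,
has higher GC content, and therefore melts at a higher temperature; a sample
is modelled as a two-species mixture of a fully methylated and a fully
unmethylated molecule, matching how quantification standards are built by
mixing the two endpoint DNAs.

Each species follows a two-state (helix/coil) logistic melt:

    theta(T) = 1 / (1 + exp((T - Tm) / w))

with the fluorescence interpolating between a sloped pre-melt dye baseline
(double-stranded, dye bound) and a post-melt baseline.  The mixture signal is
the convex combination of the two species curves plus Gaussian read noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeltModelParams",
    "MeltCurve",
    "species_tm",
    "species_fluorescence",
    "simulate_melt_curve",
    "simulate_standard_series",
]


def _default_grid() -> np.ndarray:
    # 70.0 .. 90.0 inclusive at 0.2 °C, mirroring continuous acquisition
    return np.round(np.arange(0, 101) * 0.2 + 70.0, 10)


@dataclass(frozen=True)
class MeltModelParams:
    """Parameters of the two-species melt model.

    Baselines are straight lines in temperature, parameterised by their
    value at 70 °C and a slope in RFU/°C.  ``delta_tm_per_cpg`` is the Tm
    gain per methylated CpG retained after conversion; with the default
    12-CpG amplicon the fully methylated species melts 3 °C above the
    unmethylated one.
    """

    tm_unmethylated: float = 78.0
    delta_tm_per_cpg: float = 0.25
    n_cpg: int = 12
    transition_width: float = 0.7
    pre_slope: float = -15.0
    pre_intercept: float = 4000.0  # RFU at 70 °C
    post_slope: float = -2.0
    post_intercept: float = 400.0  # RFU at 70 °C
    noise_sd: float = 20.0
    temp_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        grid = np.asarray(self.temp_grid, dtype=float)
        object.__setattr__(self, "temp_grid", grid)
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")
        if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("temp_grid must be a strictly increasing 1-D array")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.pre_line(grid) <= self.post_line(grid)):
            raise ValueError("pre-melt baseline must lie strictly above post-melt baseline")

    def pre_line(self, t: np.ndarray) -> np.ndarray:
        return self.pre_intercept + self.pre_slope * (np.asarray(t, float) - 70.0)

    def post_line(self, t: np.ndarray) -> np.ndarray:
        return self.post_intercept + self.post_slope * (np.asarray(t, float) - 70.0)


@dataclass(frozen=True)
class MeltCurve:
    """One well's raw melt trace."""

    well_id: str
    sample_id: str
    replicate_index: int
    temperatures: np.ndarray
    rfu: np.ndarray
    role: str = "sample"  # sample | standard | no-template-control | genomic-control
    known_fraction: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rfu", f)
        if t.size != f.size or t.size < 10:
            raise ValueError("temperature and RFU arrays must have equal length >= 10")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.role not in ("sample", "standard", "no-template-control", "genomic-control"):
            raise ValueError(f"unknown role {self.role!r}")


def species_tm(params: MeltModelParams, n_meth_cpg: int) -> float:
    """Melting temperature of a species with ``n_meth_cpg`` methylated CpGs."""
    if n_meth_cpg < 0:
        raise ValueError("n_meth_cpg must be >= 0")
    return params.tm_unmethylated + n_meth_cpg * params.delta_tm_per_cpg


def species_fluorescence(params: MeltModelParams, tm: float) -> np.ndarray:
    """Noise-free fluorescence of a single species over the grid."""
    t = params.temp_grid
    theta = 1.0 / (1.0 + np.exp((t - tm) / params.transition_width))
    return theta * params.pre_line(t) + (1.0 - theta) * params.post_line(t)


def simulate_melt_curve(
    params: MeltModelParams,
    fraction_methylated: float,
    seed: int | np.random.SeedSequence,
    *,
    well_id: str = "A01",
    sample_id: str = "sample",
    replicate_index: int = 0,
    role: str = "sample",
    known_fraction: float | None = None,
) -> MeltCurve:
    """Simulate one melt trace for a mixture of methylated fraction ``f``.

    The mixture signal is ``f * F_meth + (1 - f) * F_unmeth`` plus i.i.d.
    Gaussian noise of SD ``params.noise_sd``; identical seeds give identical
    curves.
    """
    f = float(fraction_methylated)
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction_methylated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    f_unmeth = species_fluorescence(params, species_tm(params, 0))
    f_meth = species_fluorescence(params, species_tm(params, params.n_cpg))
    signal = f * f_meth + (1.0 - f) * f_unmeth
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.size)
    return MeltCurve(
        well_id=well_id,
        sample_id=sample_id,
        replicate_index=replicate_index,
        temperatures=params.temp_grid.copy(),
        rfu=signal,
        role=role,
        known_fraction=known_fraction,
    )


def simulate_standard_series(
    params: MeltModelParams,
    fractions: list[float],
    replicates: int = 2,
    seed: int = 0,
) -> list[MeltCurve]:
    """Simulate a calibration-standard plate: each fraction in replicate.

    Per-curve seeds are spawned deterministically from ``(seed, fraction
    index, replicate index)`` so any curve can be regenerated independently.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    curves: list[MeltCurve] = []
    for i, f in enumerate(fractions):
        for r in range(replicates):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, r))
            curves.append(
                simulate_melt_curve(
                    params,
                    f,
                    ss,
                    well_id=f"S{i + 1:02d}-{r + 1}",
                    sample_id=f"std_{f * 100:g}pct",
                    replicate_index=r,
                    role="standard",
                    known_fraction=f,
                )
            )
    return curves
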