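"""Stochastic-dynamics mass spectrometry: intensity-fluctuation dispersions.

The central quantity is a scaled variance of an ion's per-scan intensity,

    D''_SD = 2.6388e-17 * (<I^2> - <I>^2),

where <.> is the arithmetic mean over the scans of the measurement window
(population moments: the fluctuation average is taken over the acquired
window itself).  Its companion D'_SD weights each scan's squared deviation
from the mean,

    D'_SD = 1.3194e-17 * A * (<I^2> - <I>^2) / (I_j - <I>)^2,

aggregated over scans (mean by default; sum optional).  The per-ion peak
weight A is instrument-specific and user-supplied (default 1).

On the theory side a transition-state dispersion is formed from vibrational
frequencies of the ground state and the saddle point plus an activation
enthalpy,

    D_QC = prod(nu_ground) / prod(nu_saddle) * exp(-dH‡ / (R T)),

accumulated in the log domain so large mode counts cannot overflow, and a
theoretical peak intensity follows as I_theor = 2.6388e-17 * sqrt(D_QC).
Correlating experimental D''_SD (or intensities) with D_QC / I_theor over a
set of candidate ion structures is what turns these dispersions into a
structure-assignment tool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "D_PRIME_COEFF",
    "D_DOUBLE_COEFF",
    "GAS_CONSTANT",
    "ScanSeries",
    "SDResult",
    "QCSpecies",
    "SineSqrFit",
    "d_double_sd",
    "d_prime_sd",
    "d_qc",
    "i_theor",
    "i_theor_from_dqc",
    "sd_correlation",
    "sd_pairwise",
    "sinesqr_fit",
    "d_double_from_intensity",
]

#: Scale constant of the per-scan-weighted dispersion D'_SD.
D_PRIME_COEFF = 1.3194e-17
#: Scale constant of the fluctuation dispersion D''_SD (exactly 2x D'_SD's).
D_DOUBLE_COEFF = 2.6388e-17
#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.31446


@dataclass
class ScanSeries:
    """Per-scan intensities of one ion within a measurement window.

    ``a_weight`` is the per-ion peak weighting factor A entering D'_SD; it is
    instrument/workflow specific and must be supplied by the user (default
    1).  ``scan_times`` (seconds, strictly increasing) and the collision
    energy ``ce`` (eV) are optional metadata.
    """

    intensities: np.ndarray
    mz: object | None = None
    scan_times: np.ndarray | None = None
    a_weight: float = 1.0
    ce: float | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size == 0:
            raise ValueError("intensities must be nonempty")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.scan_times is not None:
            self.scan_times = np.asarray(self.scan_times, dtype=float)
            if self.scan_times.shape != self.intensities.shape:
                raise ValueError("scan_times and intensities differ in length")
            if np.any(np.diff(self.scan_times) <= 0):
                raise ValueError("scan_times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class SDResult:
    """Dispersion summary of one scan series."""

    mean_intensity: float
    variance: float
    n_scans: int
    d_double: float
    d_prime: float | None = None
    n_excluded: int = 0

    def summary(self) -> str:
        lines = [
            f"scans            : {self.n_scans}",
            f"<I>              : {self.mean_intensity:.6g}",
            f"<I^2> - <I>^2    : {self.variance:.6g}",
            f"D''_SD           : {self.d_double:.6g}",
        ]
        if self.d_prime is not None:
            lines.append(f"D'_SD            : {self.d_prime:.6g}")
        if self.n_excluded:
            lines.append(f"excluded scans   : {self.n_excluded} (I = <I>)")
        return "\n".join(lines)


@dataclass
class QCSpecies:
    """Vibrational and energetic input of one candidate ion structure.

    3N ground-state frequencies, 3N-1 saddle-point frequencies (one mode is
    the reaction coordinate), the activation enthalpy in J/mol and the
    temperature in K.  Frequencies carry an explicit unit tag (``"cm-1"`` or
    ``"s-1"``); the ground/saddle tags must agree — no silent conversion.
    """

    name: str
    nu_ground: np.ndarray
    nu_saddle: np.ndarray
    dh_activation: float
    temperature: float
    nu_unit: str = "cm-1"
    nu_saddle_unit: str | None = None

    def __post_init__(self) -> None:
        self.nu_ground = np.asarray(self.nu_ground, dtype=float)
        self.nu_saddle = np.asarray(self.nu_saddle, dtype=float)
        if self.nu_saddle_unit is None:
            self.nu_saddle_unit = self.nu_unit
        if self.nu_unit not in ("cm-1", "s-1"):
            raise ValueError(f"unknown frequency unit tag {self.nu_unit!r}")
        if self.nu_ground.size != self.nu_saddle.size + 1:
            raise ValueError(
                f"species {self.name!r}: need len(nu_ground) = "
                f"len(nu_saddle) + 1, got {self.nu_ground.size} and "
                f"{self.nu_saddle.size}"
            )
        if np.any(self.nu_ground <= 0) or np.any(self.nu_saddle <= 0):
            raise ValueError(f"species {self.name!r}: frequencies must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class SineSqrFit:
    """Result of fitting y = offset + amplitude * sin^2(pi (x - phase)/period)."""

    amplitude: float
    offset: float
    phase: float
    period: float
    rss: float

    def summary(self) -> str:
        return (
            f"SineSqr fit: amplitude={self.amplitude:.6g} offset={self.offset:.6g} "
            f"phase={self.phase:.6g} period={self.period:.6g} rss={self.rss:.3g}"
        )


# ---------------------------------------------------------------------------
# Scan-level dispersions
# ---------------------------------------------------------------------------

def _moments(s: ScanSeries) -> tuple[float, float]:
    x = s.intensities
    mean = float(x.mean())
    variance = float(np.mean(x * x) - mean * mean)
    return mean, max(variance, 0.0)


def d_double_sd(s: ScanSeries) -> SDResult:
    """Fluctuation dispersion D''_SD = 2.6388e-17 * (<I^2> - <I>^2)."""
    if s.n_scans < 2:
        raise ValueError("need >= 2 scans")
    mean, variance = _moments(s)
    return SDResult(
        mean_intensity=mean,
        variance=variance,
        n_scans=s.n_scans,
        d_double=D_DOUBLE_COEFF * variance,
    )


def d_prime_sd(s: ScanSeries, reducer: str = "mean") -> SDResult:
    """Per-scan-weighted dispersion D'_SD.

    Each scan contributes 1.3194e-17 * A * variance / (I_j - <I>)^2; scans
    exactly at the mean are excluded (counted in ``n_excluded``) because
    their term is undefined.  ``reducer`` aggregates the per-scan terms:
    ``"mean"`` (default, keeps the scale comparable with D''_SD) or
    ``"sum"``.
    """
    if s.n_scans < 2:
        raise ValueError("need >= 2 scans")
    if reducer not in ("mean", "sum"):
        raise ValueError("reducer must be 'mean' or 'sum'")
    mean, variance = _moments(s)
    dev2 = (s.intensities - mean) ** 2
    usable = dev2 > 0
    n_excluded = int(np.count_nonzero(~usable))
    if not np.any(usable):
        raise ValueError("every scan equals the mean; D'_SD undefined")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} scan(s) equal to the mean excluded from D'_SD",
            stacklevel=2,
        )
    terms = D_PRIME_COEFF * s.a_weight * variance / dev2[usable]
    value = float(terms.mean() if reducer == "mean" else terms.sum())
    return SDResult(
        mean_intensity=mean,
        variance=variance,
        n_scans=s.n_scans,
        d_double=D_DOUBLE_COEFF * variance,
        d_prime=value,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Transition-state dispersion and theoretical intensity
# ---------------------------------------------------------------------------

def d_qc(q: QCSpecies) -> float:
    """Transition-state dispersion from vibrational frequencies.

    log-domain accumulation: exp(sum log nu0 - sum log nus - dH/(R T)), so
    species with hundreds of modes cannot overflow the product.
    """
    if q.nu_unit != q.nu_saddle_unit:
        raise ValueError(
            f"species {q.name!r}: frequency unit tags differ "
            f"({q.nu_unit!r} vs {q.nu_saddle_unit!r})"
        )
    log_ratio = float(np.sum(np.log(q.nu_ground)) - np.sum(np.log(q.nu_saddle)))
    exponent = log_ratio - q.dh_activation / (GAS_CONSTANT * q.temperature)
    return math.exp(exponent)


def i_theor_from_dqc(dqc: float) -> float:
    """Theoretical peak intensity 2.6388e-17 * sqrt(D_QC)."""
    if dqc < 0:
        raise ValueError("D_QC must be >= 0")
    return D_DOUBLE_COEFF * math.sqrt(dqc)


def i_theor(q: QCSpecies) -> float:
    """Theoretical peak intensity of a candidate ion structure."""
    return i_theor_from_dqc(d_qc(q))


def sd_correlation(sds: dict[str, float], dqcs: dict[str, float]) -> float:
    """Pearson r between experimental D''_SD and theoretical D_QC values
    matched by ion name (requires >= 3 shared names)."""
    shared = sorted(set(sds) & set(dqcs))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared ion names (need >= 3)")
    a = np.array([sds[k] for k in shared])
    b = np.array([dqcs[k] for k in shared])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("one value set is constant; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def sd_pairwise(l: ScanSeries, m: ScanSeries, mode: str = "covariance") -> float:
    """Cross-scan coupling of two ions' intensity series.

    ``covariance`` (default): the self-consistent reading — the Pearson
    correlation r_lm obtained from the cross-dispersion
    2.6388e-17 * cov(l, m) = r_lm * 2.6388e-17 * sd_l * sd_m, so l = m gives
    exactly 1.  ``as_printed``: the literal sum form
    (D''_l + D''_m) / (sd_l * sd_m), preserved for auditability although it
    is dimensionally odd (l = m yields 2 * 2.6388e-17).
    """
    if l.n_scans != m.n_scans:
        raise ValueError("series must have equal scan counts")
    if mode not in ("covariance", "as_printed"):
        raise ValueError("mode must be 'covariance' or 'as_printed'")
    _, var_l = _moments(l)
    _, var_m = _moments(m)
    if var_l == 0 or var_m == 0:
        raise ValueError("zero variance in one of the series")
    sd_l, sd_m = math.sqrt(var_l), math.sqrt(var_m)
    if mode == "covariance":
        cov = float(
            np.mean(l.intensities * m.intensities)
            - l.intensities.mean() * m.intensities.mean()
        )
        return cov / (sd_l * sd_m)
    dd_l = D_DOUBLE_COEFF * var_l
    dd_m = D_DOUBLE_COEFF * var_m
    return (dd_l + dd_m) / (sd_l * sd_m)


# ---------------------------------------------------------------------------
# Collision-energy sweeps
# ---------------------------------------------------------------------------

def _sinesqr(x, amplitude, offset, phase, period):
    return offset + amplitude * np.sin(np.pi * (x - phase) / period) ** 2


def sinesqr_fit(x, y, n_period_starts: int = 8) -> SineSqrFit:
    """Least-squares SineSqr fit of a response against collision energy.

    y = offset + amplitude * sin^2(pi (x - phase)/period), fitted by
    Levenberg-Marquardt with a multi-start grid over the period (the only
    parameter with troublesome local minima).  Raises on non-convergence of
    every start, carrying the best residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points")
    span = float(np.ptp(x))
    if span == 0:
        raise ValueError("x values are all identical")
    yspread = float(np.ptp(y))
    if yspread == 0:
        # constant response: exact degenerate fit
        return SineSqrFit(
            amplitude=0.0, offset=float(y[0]), phase=float(x[0]),
            period=span if span > 0 else 1.0, rss=0.0,
        )

    model = lmfit.Model(_sinesqr)
    best: lmfit.model.ModelResult | None = None
    best_rss = math.inf
    for frac in np.linspace(0.5, 4.0, n_period_starts):
        params = model.make_params(
            amplitude=yspread,
            offset=float(y.min()),
            phase=float(x.min()),
            period=span * frac,
        )
        params["period"].set(min=1e-12)
        try:
            res = model.fit(y, params, x=x)
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if res.success and rss < best_rss:
            best, best_rss = res, rss
    if best is None:
        raise RuntimeError(f"SineSqr fit failed to converge (best rss={best_rss})")
    p = best.params
    return SineSqrFit(
        amplitude=float(p["amplitude"].value),
        offset=float(p["offset"].value),
        phase=float(p["phase"].value),
        period=float(p["period"].value),
        rss=best_rss,
    )


def d_double_from_intensity(a_d: float, a_i: float, i_tot_avg: float) -> float:
    """Estimate D''_SD from SineSqr amplitudes of the D'' and total-intensity
    collision-energy sweeps: D'' ~= 2 (A_D / A_I) * <I_TOT>."""
    if a_i == 0:
        raise ValueError("total-intensity amplitude A_I must be nonzero")
    return 2.0 * (a_d / a_i) * i_tot_avg
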