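"""Seeded synthetic-data generators with planted ground truth.

Instrument acquisition and quantum-chemistry runs are replaced by pure
functions of (seed, parameters): spectrum pairs with a planted Pearson
correlation, per-scan intensity series with specified mean/variance,
vibrational species whose transition-state dispersion is solved to a target,
concentration grids following a planted exponential law, and group vectors
reproducing printed summary statistics exactly.  Every generator draws from
its own RNG stream (a per-kind constant mixed with the user seed), so adding
a generator never perturbs existing fixtures, and every planted parameter is
recoverable by the corresponding analysis operation.
"""

from __future__ import annotations

import math

import numpy as np

from .chemometrics import GroupSummary
from .kinetics import ConcentrationGrid
from .spectra import MassSpectrum
from .stochastic import GAS_CONSTANT, QCSpecies, ScanSeries

import pandas as pd

__all__ = [
    "gen_spectrum_pair",
    "gen_scan_series",
    "gen_qc_species",
    "gen_concentration_grid",
    "gen_group_data",
]

# Stable per-generator stream ids (mixed with the user seed).
_STREAM = {
    "spectrum_pair": 101,
    "scan_series": 102,
    "qc_species": 103,
    "concentration_grid": 104,
    "group_data": 105,
}

#: Physically plausible band for vibrational fundamentals (cm^-1).
_FREQ_BAND = (50.0, 4000.0)
#: Cap on the solved activation enthalpy magnitude (J/mol).
_MAX_DH = 500e3


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[kind], int(seed)])


# ---------------------------------------------------------------------------
# Spectrum pairs with planted correlation
# ---------------------------------------------------------------------------

def gen_spectrum_pair(
    r_target: float,
    n_ions: int,
    seed: int,
    max_tries: int = 50,
) -> tuple[MassSpectrum, MassSpectrum, float]:
    """Two normalized spectra over a shared m/z grid with a planted Pearson
    correlation.

    The second intensity vector is built by exact Gram-Schmidt mixing of the
    first with an orthogonalized noise vector, so the sample correlation of
    the standardized vectors equals ``r_target`` to machine precision; the
    affine map onto positive intensities and the base-peak normalization
    both preserve Pearson correlation.  ``r_realized`` is re-measured from
    the final intensity vectors and guaranteed within 0.02 of the target
    (rejection on degenerate draws).
    """
    if abs(r_target) > 1:
        raise ValueError("|r_target| must be <= 1")
    if n_ions < 3:
        raise ValueError("need n_ions >= 3")
    rng = _rng("spectrum_pair", seed)
    for _ in range(max_tries):
        mz_grid = np.sort(rng.choice(np.arange(45, 400), size=n_ions, replace=False))
        x = rng.standard_normal(n_ions)
        z = rng.standard_normal(n_ions)
        x = x - x.mean()
        z = z - z.mean()
        if np.linalg.norm(x) == 0 or np.linalg.norm(z) == 0:
            continue
        z = z - (z @ x) / (x @ x) * x
        if np.linalg.norm(z) == 0:
            continue
        xh = x / np.linalg.norm(x)
        zh = z / np.linalg.norm(z)
        yh = r_target * xh + math.sqrt(max(0.0, 1 - r_target**2)) * zh

        def to_intensities(u: np.ndarray) -> np.ndarray | None:
            top = np.abs(u).max()
            if top == 0:
                return None
            v = 55.0 + 44.0 * u / top  # strictly positive, no clipping
            return v * (100.0 / v.max())

        ia = to_intensities(xh)
        ib = to_intensities(yh)
        if ia is None or ib is None:
            continue
        r_realized = float(np.corrcoef(ia, ib)[0, 1])
        if abs(r_realized - r_target) > 0.02:
            continue
        spec_a = MassSpectrum(
            name="synthetic_A",
            peaks=tuple((int(m), float(v)) for m, v in zip(mz_grid, ia)),
        )
        spec_b = MassSpectrum(
            name="synthetic_B",
            peaks=tuple((int(m), float(v)) for m, v in zip(mz_grid, ib)),
        )
        return spec_a, spec_b, r_realized
    raise RuntimeError(
        f"could not realize r_target={r_target} within 0.02 after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Scan series
# ---------------------------------------------------------------------------

def gen_scan_series(
    mean: float,
    variance: float,
    n_scans: int,
    seed: int,
    distribution: str = "gaussian",
) -> ScanSeries:
    """Per-scan intensity series with specified mean and variance.

    ``gaussian`` draws Normal(mean, variance) and truncates rare negatives
    at zero with a compensating shift; it refuses targets whose truncated
    mass would distort the moments (sd beyond mean/3).  ``poisson-like``
    uses a scaled Poisson (scale var/mean, rate mean^2/var), nonnegative by
    construction.  Sample moments land within ~4/sqrt(n) standard errors of
    the targets.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if n_scans < 2:
        raise ValueError("need n_scans >= 2")
    if mean < 0:
        raise ValueError("mean must be >= 0")
    rng = _rng("scan_series", seed)
    if variance == 0:
        return ScanSeries(intensities=np.full(n_scans, float(mean)))
    sd = math.sqrt(variance)
    if distribution == "gaussian":
        if sd * 3 > mean:
            raise ValueError(
                f"infeasible target: sd={sd:.4g} too large for nonnegative "
                f"series with mean={mean:.4g}"
            )
        x = rng.normal(mean, sd, n_scans)
        if np.any(x < 0):
            deficit = -x[x < 0].sum() / n_scans
            x = np.clip(x, 0.0, None) + deficit
    elif distribution == "poisson-like":
        scale = variance / mean
        lam = mean * mean / variance
        x = scale * rng.poisson(lam, n_scans).astype(float)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return ScanSeries(intensities=x)


# ---------------------------------------------------------------------------
# Vibrational species with a target dispersion
# ---------------------------------------------------------------------------

def gen_qc_species(
    n_atoms: int,
    target_dqc: float,
    temperature: float = 298.15,
    seed: int = 0,
    force_zero_dh: bool = False,
    name: str | None = None,
) -> QCSpecies:
    """A species whose transition-state dispersion equals ``target_dqc``.

    3N ground-state and 3N-1 saddle-point frequencies are drawn uniformly in
    the 50-4000 cm^-1 band; the activation enthalpy is then solved so that
    the dispersion hits the target to machine precision.  With
    ``force_zero_dh`` the enthalpy is pinned at zero and the saddle modes
    are solved as a commonly-scaled copy of the ground modes instead.
    Targets needing |dH| > 500 kJ/mol (or a frequency outside the band)
    are refused.
    """
    if n_atoms < 2:
        raise ValueError("need n_atoms >= 2")
    if target_dqc <= 0:
        raise ValueError("target_dqc must be > 0")
    rng = _rng("qc_species", seed)
    n_modes = 3 * n_atoms
    lo, hi = _FREQ_BAND
    log_target = math.log(target_dqc)
    if force_zero_dh:
        # saddle modes copy the ground modes (minus the reaction coordinate)
        # with a common scale factor solved so the frequency-product ratio
        # alone hits the target; the inner draw band leaves room to scale
        # while staying physical
        nu_ground = rng.uniform(200.0, 2000.0, n_modes)
        log_excess = float(np.log(nu_ground[0])) - log_target
        factor = math.exp(log_excess / (n_modes - 1))
        nu_saddle = nu_ground[1:] * factor
        if np.any(nu_saddle < lo) or np.any(nu_saddle > hi):
            raise ValueError(
                f"target {target_dqc:g} unreachable with dH=0: solved saddle "
                f"frequencies leave the {lo}-{hi} cm^-1 band"
            )
        dh = 0.0
    else:
        nu_ground = rng.uniform(lo, hi, n_modes)
        nu_saddle = rng.uniform(lo, hi, n_modes - 1)
        log_ratio = float(np.sum(np.log(nu_ground)) - np.sum(np.log(nu_saddle)))
        dh = GAS_CONSTANT * temperature * (log_ratio - log_target)
        if abs(dh) > _MAX_DH:
            raise ValueError(
                f"target {target_dqc:g} needs |dH|={abs(dh):.3g} J/mol "
                f"(> {_MAX_DH:g}); unreachable in the physical band"
            )
    return QCSpecies(
        name=name or f"synthetic_species_{seed}",
        nu_ground=nu_ground,
        nu_saddle=nu_saddle,
        dh_activation=dh,
        temperature=temperature,
        nu_unit="cm-1",
    )


# ---------------------------------------------------------------------------
# Concentration grids
# ---------------------------------------------------------------------------

def gen_concentration_grid(
    a_b_by_omega: dict[float, tuple[float, float]],
    times: list[float],
    noise_sd: float,
    seed: int,
    analyte: str = "chlorogenic acid",
) -> ConcentrationGrid:
    """Concentration grid following c = a_w * exp(b_w * t) + Gaussian noise.

    ``a_b_by_omega`` maps pulse frequency (Hz; 0 = untreated control, which
    must be present) to the planted (a, b).  Noise is floored at zero.
    """
    if not times:
        raise ValueError("times must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if 0.0 not in {float(w) for w in a_b_by_omega}:
        raise ValueError("a control frequency omega = 0 must be included")
    rng = _rng("concentration_grid", seed)
    rows = []
    for omega in sorted(a_b_by_omega):
        a, b = a_b_by_omega[omega]
        for t in times:
            conc = a * math.exp(b * t)
            if noise_sd > 0:
                conc += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "analyte": analyte,
                    "time_h": float(t),
                    "omega_hz": float(omega),
                    "conc_mg_per_g": max(conc, 0.0),
                }
            )
    return ConcentrationGrid(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Group vectors with exact summary statistics
# ---------------------------------------------------------------------------

def gen_group_data(summary: GroupSummary, seed: int) -> np.ndarray:
    """A vector whose sample mean and sample sd (denominator n-1) match the
    summary exactly (affine post-standardization of a Gaussian draw)."""
    rng = _rng("group_data", seed)
    n = summary.n
    if summary.sd == 0:
        return np.full(n, summary.mean)
    for _ in range(10):
        z = rng.standard_normal(n)
        s = z.std(ddof=1)
        if s > 0:
            break
    else:  # pragma: no cover - essentially impossible
        raise RuntimeError("degenerate standard normal draw")
    z = (z - z.mean()) / s
    return summary.mean + summary.sd * z
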