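"""Headspace-methane quantitation for serum-bottle incubations.

The measurement chain is: GC-FID peak area -> mixing ratio (ppm) via an
ordinary least-squares standard curve -> bottle CH4 inventory via the
ideal-gas law for the headspace and the Bunsen solubility coefficient for
the dissolved fraction, assuming full liquid/headspace equilibrium (bottles
shaken continuously) -> per-liquid-volume concentration -> production
rates, CH4/DOP consumption stoichiometry and phosphate dose-response /
repression statistics.

Default bottle geometry is a 125-mL serum bottle with 20 mL medium and
105 mL headspace at 30 degC and 1 atm. Reported concentrations are totals
(headspace + dissolved) normalized to the liquid volume, in nmol/L or
umol/L, which makes volumetric rates and the dissolved-P mass balance
commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "R_L_ATM",
    "V_MOLAR_STP",
    "CalibrationCurve",
    "BottleGeometry",
    "GasSample",
    "RateEstimate",
    "StoichResult",
    "fit_calibration",
    "bunsen_coefficient",
    "headspace_partition",
    "mixing_ratio_for_total",
    "production_rate",
    "stoichiometric_series",
    "dose_response_trend",
    "repression_test",
]

#: Gas constant in L atm mol^-1 K^-1.
R_L_ATM = 0.082057
#: Molar volume of an ideal gas at STP, L mol^-1.
V_MOLAR_STP = 22.414

_DEFAULT_STANDARDS_PPM = (2.02, 4.99, 10.1, 100.0, 1000.0)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """OLS standard curve area = slope * ppm + intercept."""

    standards_ppm: tuple[float, ...]
    areas: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float

    def ppm(self, area: float | np.ndarray) -> float | np.ndarray:
        """Invert the curve: mixing ratio from a peak area."""
        return (np.asarray(area, dtype=float) - self.intercept) / self.slope

    def area(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(ppm, dtype=float) + self.intercept


def fit_calibration(
    standards_ppm: Sequence[float] = _DEFAULT_STANDARDS_PPM,
    areas: Sequence[float] = (),
    through_origin: bool = False,
) -> CalibrationCurve:
    """Fit the GC standard curve by ordinary least squares.

    Requires at least two distinct standards and a positive slope (a flat
    or inverted detector response is non-physical). ``through_origin``
    forces the intercept to zero.
    """
    x = np.asarray(standards_ppm, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"standards ({x.size}) and areas ({y.size}) differ in length")
    if np.unique(x).size < 2:
        raise ValueError("calibration needs at least 2 distinct standards")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        dof = max(x.size - 1, 1)
        stderr = math.sqrt(float(np.sum(resid ** 2)) / dof / float(np.dot(x, x)))
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2
        stderr = float(fit.stderr)
    if slope <= 0:
        raise ValueError(f"non-physical calibration: slope {slope:g} <= 0")
    return CalibrationCurve(tuple(map(float, x)), tuple(map(float, y)),
                            slope, intercept, r2, stderr)


# ---------------------------------------------------------------------------
# Solubility
# ---------------------------------------------------------------------------

def _bunsen_config() -> dict:
    with open(Path(__file__).parent / "data" / "bunsen_ch4.yaml") as fh:
        return yaml.safe_load(fh)


_BUNSEN = _bunsen_config()


def bunsen_coefficient(temperature: float, salinity: float = 0.0) -> float:
    """CH4 Bunsen solubility coefficient beta(T, S).

    beta is the volume of CH4 at STP dissolving per volume of solution per
    atmosphere of CH4 partial pressure, from the standard seawater
    solubility polynomial

        ln beta = A1 + A2 (100/T) + A3 ln(T/100)
                  + S [B1 + B2 (T/100) + B3 (T/100)^2]

    with T in kelvin and S in per-mil (coefficients and provenance in
    ``data/bunsen_ch4.yaml``). Raises outside the fitted range
    (273-313 K, 0-40 permil).
    """
    c = _BUNSEN
    if not (c["T_min_K"] <= temperature <= c["T_max_K"]):
        raise ValueError(
            f"temperature {temperature} K outside fitted range "
            f"[{c['T_min_K']}, {c['T_max_K']}]")
    if not (c["S_min"] <= salinity <= c["S_max"]):
        raise ValueError(
            f"salinity {salinity} outside fitted range [{c['S_min']}, {c['S_max']}]")
    t100 = temperature / 100.0
    ln_beta = (c["A1"] + c["A2"] / t100 + c["A3"] * math.log(t100)
               + salinity * (c["B1"] + c["B2"] * t100 + c["B3"] * t100 ** 2))
    return math.exp(ln_beta)


# ---------------------------------------------------------------------------
# Bottle inventory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BottleGeometry:
    """Serum-bottle constants for headspace equilibration."""

    V_liq: float = 0.020        # L of medium
    V_head: float = 0.105       # L of headspace
    temperature: float = 303.15  # K
    pressure: float = 1.0       # atm total headspace pressure
    salinity: float = 0.0       # permil
    bottle_volume: float = 0.125  # L, for the packing sanity check

    def __post_init__(self) -> None:
        if self.V_liq <= 0 or self.V_head <= 0:
            raise ValueError("volumes must be positive")
        if self.V_liq + self.V_head > self.bottle_volume + 1e-12:
            raise ValueError(
                f"V_liq + V_head = {self.V_liq + self.V_head:g} L exceeds the "
                f"bottle volume {self.bottle_volume:g} L")


@dataclass(frozen=True)
class GasSample:
    """Partitioned CH4 inventory of one bottle at one timepoint.

    Invariant: total_amount_nmol = headspace_amount_nmol
    + dissolved_umol_per_l * V_liq * 1000 (checked on construction).
    """

    mixing_ratio_ppm: float
    headspace_amount_nmol: float
    dissolved_umol_per_l: float
    total_amount_nmol: float
    conc_umol_per_l_liquid: float

    def __post_init__(self) -> None:
        if min(self.mixing_ratio_ppm, self.headspace_amount_nmol,
               self.dissolved_umol_per_l, self.total_amount_nmol,
               self.conc_umol_per_l_liquid) < 0:
            raise ValueError("GasSample amounts must be non-negative")


def headspace_partition(mixing_ratio: float, geometry: BottleGeometry = BottleGeometry()) -> GasSample:
    """Reconstruct the bottle CH4 inventory from a headspace mixing ratio.

    Headspace amount follows the ideal-gas law; the dissolved concentration
    follows Henry/Bunsen equilibrium at the CH4 partial pressure
    ``ppm * 1e-6 * P``. Full equilibration between phases is assumed.
    """
    if mixing_ratio < 0:
        raise ValueError(f"negative mixing ratio {mixing_ratio}")
    g = geometry
    p_ch4_atm = mixing_ratio * 1e-6 * g.pressure
    head_mol = p_ch4_atm * g.V_head / (R_L_ATM * g.temperature)
    beta = bunsen_coefficient(g.temperature, g.salinity)
    dissolved_mol_per_l = beta * p_ch4_atm / V_MOLAR_STP
    total_mol = head_mol + dissolved_mol_per_l * g.V_liq
    return GasSample(
        mixing_ratio_ppm=float(mixing_ratio),
        headspace_amount_nmol=head_mol * 1e9,
        dissolved_umol_per_l=dissolved_mol_per_l * 1e6,
        total_amount_nmol=total_mol * 1e9,
        conc_umol_per_l_liquid=total_mol / g.V_liq * 1e6,
    )


def mixing_ratio_for_total(total_nmol: float, geometry: BottleGeometry = BottleGeometry()) -> float:
    """Invert :func:`headspace_partition`: the mixing ratio (ppm) that puts
    ``total_nmol`` of CH4 in the bottle at equilibrium."""
    if total_nmol < 0:
        raise ValueError(f"negative total amount {total_nmol}")
    g = geometry
    beta = bunsen_coefficient(g.temperature, g.salinity)
    per_ppm_mol = 1e-6 * g.pressure * (
        g.V_head / (R_L_ATM * g.temperature) + beta * g.V_liq / V_MOLAR_STP)
    return total_nmol * 1e-9 / per_ppm_mol


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """Volumetric CH4 production rate over a time window."""

    window: tuple[float, float]   # hours
    rate: float                   # nmol L^-1 h^-1, per liquid volume
    stderr: float                 # nmol L^-1 h^-1
    method: str                   # "regression" | "endpoint"
    n_points: int


def production_rate(
    time_h: Sequence[float],
    conc_nmol_per_l: Sequence[float],
    window: tuple[float, float] | None = None,
    method: str = "regression",
) -> RateEstimate:
    """Estimate the CH4 production rate within a time window.

    ``regression`` (default) fits an OLS slope of concentration vs time,
    pooling every supplied point inside the window (replicates may simply
    be concatenated: repeated time values are expected and handled).
    ``endpoint`` uses (C_last - C_first)/(t_last - t_first) of the
    window-mean trajectory.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_nmol_per_l, dtype=float)
    if t.shape != c.shape:
        raise ValueError("time and concentration lengths differ")
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct timepoints inside the window")
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"window end {hi} must exceed start {lo}")
    mask = (t >= lo) & (t <= hi)
    t_w, c_w = t[mask], c[mask]
    if np.unique(t_w).size < 2:
        raise ValueError("need >= 2 distinct timepoints inside the window")
    if method == "regression":
        fit = stats.linregress(t_w, c_w)
        rate, stderr = float(fit.slope), float(fit.stderr)
        if not np.isfinite(stderr):
            stderr = 0.0
    elif method == "endpoint":
        # average replicates at the first and last sampled times
        first_t, last_t = t_w[0], t_w[-1]
        c0 = c_w[t_w == first_t].mean()
        c1 = c_w[t_w == last_t].mean()
        rate = float((c1 - c0) / (last_t - first_t))
        stderr = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    return RateEstimate(window=(float(lo), float(hi)), rate=rate,
                        stderr=stderr, method=method, n_points=int(mask.sum()))


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoichResult:
    """Net CH4 production vs DOP consumption over an incubation.

    ``ratio_trajectory`` holds (time_h, ratio) pairs; the ratio at a
    timepoint is NaN (undefined) when |delta DOP| is below the floor.
    Negative apparent DOP values are flagged, never clamped.
    """

    delta_ch4_umol_per_l: float
    delta_dop_umol_per_l: float
    ratio: float
    ratio_trajectory: tuple[tuple[float, float], ...]
    dop_umol_per_l: tuple[float, ...]
    negative_dop_flag: bool


def stoichiometric_series(
    time_h: Sequence[float],
    ch4_umol_per_l: Sequence[float],
    tdp_umol_per_l: Sequence[float],
    dip_umol_per_l: Sequence[float],
    dop_floor_umol_per_l: float = 1e-3,
) -> StoichResult:
    """Compute the cumulative CH4/DOP consumption stoichiometry.

    DOP is taken pointwise as TDP - DIP. Deltas are relative to the first
    timepoint: delta CH4 = CH4(t) - CH4(0), delta DOP = DOP(0) - DOP(t).
    Each ratio delta CH4 / delta DOP is reported per timepoint; when the
    DOP draw-down is smaller than ``dop_floor_umol_per_l`` the ratio is
    undefined (NaN), never an exception.
    """
    t = np.asarray(time_h, dtype=float)
    ch4 = np.asarray(ch4_umol_per_l, dtype=float)
    tdp = np.asarray(tdp_umol_per_l, dtype=float)
    dip = np.asarray(dip_umol_per_l, dtype=float)
    if not (t.shape == ch4.shape == tdp.shape == dip.shape):
        raise ValueError("series lengths differ")
    if t.size < 2:
        raise ValueError("need at least two timepoints")
    dop = tdp - dip
    delta_ch4 = ch4 - ch4[0]
    delta_dop = dop[0] - dop
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(np.abs(delta_dop) > dop_floor_umol_per_l,
                          delta_ch4 / delta_dop, np.nan)
    final = (float(ratios[-1]) if np.isfinite(ratios[-1]) else float("nan"))
    return StoichResult(
        delta_ch4_umol_per_l=float(delta_ch4[-1]),
        delta_dop_umol_per_l=float(delta_dop[-1]),
        ratio=final,
        ratio_trajectory=tuple(zip(map(float, t), map(float, ratios))),
        dop_umol_per_l=tuple(map(float, dop)),
        negative_dop_flag=bool((dop < 0).any()),
    )


# ---------------------------------------------------------------------------
# Phosphate regulation
# ---------------------------------------------------------------------------

def dose_response_trend(
    final_ch4_by_pi: Mapping[float, Sequence[float]],
    noise_tolerance: float = 0.0,
) -> tuple[float, bool]:
    """Rank-correlate final CH4 against initial Pi across dose levels.

    Returns (Spearman rho of treatment means vs Pi, monotone_decreasing).
    ``monotone_decreasing`` is True when rho < 0 and every consecutive
    difference of the Pi-ordered means is <= ``noise_tolerance``.
    """
    if len(final_ch4_by_pi) < 3:
        raise ValueError("need at least 3 Pi levels for a dose-response trend")
    pi = np.array(sorted(final_ch4_by_pi), dtype=float)
    means = np.array([np.mean(final_ch4_by_pi[p]) for p in pi])
    if np.allclose(means, means[0]):
        return 0.0, False
    rho = float(stats.spearmanr(pi, means).statistic)
    diffs = np.diff(means)
    monotone = bool(rho < 0 and (diffs <= noise_tolerance).all())
    return rho, monotone


def repression_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    equal_var: bool = False,
) -> tuple[float, float, bool]:
    """Two-sample t-test for phosphate repression of CH4 production.

    Welch's unequal-variance form by default; ``alternative='greater'``
    tests the directional hypothesis mean(a) > mean(b). Two groups with
    zero variance and equal means return p = 1 rather than a division
    error. Returns (statistic, p_value, significant at ``alpha``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, False
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    stat, p = float(res.statistic), float(res.pvalue)
    return stat, p, bool(p < alpha)
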