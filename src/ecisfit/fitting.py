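"""Estimate (alpha, rb, cm) from a frequency scan fitted against a cell-free reference.

The fitter minimises, over the analysis window, the per-frequency relative
complex residual

    sum_f |Z_model(f) - Z_meas(f)|^2 / |Z_meas(f)|^2

with the three parameters optimised in log-space inside bounds, from
multiple starting points.  The relative weighting balances the decades of
impedance magnitude a scan spans; absolute residuals are available via
``FitOptions.weighting``.

The analysis window defaults to 62.5–16000 Hz: real electrode leads show a
strong inductive component at higher frequencies that the cell-covered
electrode model cannot represent, so those points are excluded before
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidArgumentError, OutOfRangeError
from .model import (
    CONVENTIONS,
    ComplexSpectrum,
    ElectrodeGeometry,
    MonolayerParams,
    cell_covered_impedance,
    to_specific,
)

__all__ = ["FitOptions", "FitResult", "window_frequencies", "align_reference",
           "fit_monolayer", "qc_flags"]

# smallest parameter values representable in the log-space optimiser;
# a fitted rb or alpha at this floor is indistinguishable from zero
_FLOOR = np.array([1e-6, 1e-6, 1e-3])


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the spectrum fit.

    ``f_min_hz``/``f_max_hz`` bound the analysis window (inclusive).
    ``lower``/``upper`` bound (alpha, rb, cm) in their natural units;
    zeros in the lower bound are clamped to a tiny positive floor so the
    parameters can be optimised in log-space.  ``n_starts`` random
    log-uniform starts are run in addition to one heuristic start; the
    draw is deterministic given ``seed``.
    """

    f_min_hz: float = 62.5
    f_max_hz: float = 16000.0
    weighting: str = "relative"  # or "absolute"
    lower: tuple = (0.0, 0.0, 1e-3)
    upper: tuple = (1e3, 1e4, 1e2)
    n_starts: int = 8
    seed: int = 0
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14

    def __post_init__(self) -> None:
        if not self.f_min_hz < self.f_max_hz:
            raise InvalidArgumentError("f_min_hz must be < f_max_hz")
        if self.weighting not in ("relative", "absolute"):
            raise InvalidArgumentError("weighting must be 'relative' or 'absolute'")
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or up.shape != (3,) or np.any(lo >= up):
            raise InvalidArgumentError("bounds must be ordered triples lower < upper")


@dataclass
class FitResult:
    """A fitted parameter triplet plus residual diagnostics."""

    params: MonolayerParams
    rms_relative_residual: float
    n_frequencies_used: int
    converged: bool
    window_used: tuple
    per_frequency_residuals: np.ndarray
    qc: set = field(default_factory=set)
    cm_ci_decades: float = float("nan")  # span of the curvature CI for cm, log10 units
    metadata: dict = field(default_factory=dict)


def window_frequencies(scan: ComplexSpectrum, options: FitOptions) -> ComplexSpectrum:
    """Restrict a scan to the analysis window, inclusive at both ends."""
    mask = (scan.frequencies_hz >= options.f_min_hz) & (scan.frequencies_hz <= options.f_max_hz)
    n = int(mask.sum())
    if n < 4:
        raise InsufficientDataError(
            f"only {n} frequencies inside [{options.f_min_hz}, {options.f_max_hz}] Hz; "
            "need at least 4")
    return scan.subset(mask)


def align_reference(reference: ComplexSpectrum, target_frequencies) -> np.ndarray:
    """Interpolate the reference scan onto the target frequency grid.

    Real and imaginary parts are interpolated independently, linearly in
    log-frequency; the grids coinciding yields exact passthrough.
    Extrapolation is refused.
    """
    targets = np.asarray(target_frequencies, dtype=float)
    fref = reference.frequencies_hz
    if np.any(targets < fref[0]) or np.any(targets > fref[-1]):
        raise OutOfRangeError(
            f"target frequencies outside reference support [{fref[0]}, {fref[-1]}] Hz")
    logf = np.log(fref)
    logt = np.log(targets)
    re = np.interp(logt, logf, reference.z_real_ohm)
    im = np.interp(logt, logf, reference.z_imag_ohm)
    # exact passthrough where the grids coincide (guard against log rounding)
    idx = np.searchsorted(fref, targets)
    idx = np.clip(idx, 0, len(fref) - 1)
    exact = fref[idx] == targets
    re[exact] = reference.z_real_ohm[idx[exact]]
    im[exact] = reference.z_imag_ohm[idx[exact]]
    return re + 1j * im


def _heuristic_start(f, zc, zn, bounds_log):
    """Physically motivated initial guess.

    rb from the low-frequency real-part excess of the cell scan over the
    reference; alpha from the mid-frequency magnitude ratio; cm at the
    textbook 2 µF/cm².
    """
    rb0 = max(float(zc.real[0] - zn.real[0]), 0.05)
    mid = len(f) // 2
    ratio = abs(zc[mid]) / abs(zn[mid])
    alpha0 = 4.0 * np.sqrt(max(ratio - 1.0, 0.25))
    start = np.log(np.array([alpha0, rb0, 2.0]))
    return np.clip(start, bounds_log[0], bounds_log[1])


def fit_monolayer(cell_scan: ComplexSpectrum, reference_scan: ComplexSpectrum,
                  geometry: ElectrodeGeometry = ElectrodeGeometry(),
                  options: FitOptions = FitOptions()) -> FitResult:
    """Fit the cell-covered electrode model to one frequency scan.

    The cell scan is windowed, the reference scan is aligned onto the
    windowed grid and used as measured (not itself modelled), both are
    converted to specific impedance, and the best of the multi-start
    least-squares runs is returned.  Ties are broken by lowest rms, then
    lowest rb.  Deterministic given ``options.seed``.
    """
    windowed = window_frequencies(cell_scan, options)
    f = windowed.frequencies_hz
    zc_meas = to_specific(windowed.z_ohm, geometry)
    zn_meas = to_specific(align_reference(reference_scan, f), geometry)

    lo = np.maximum(np.asarray(options.lower, float), _FLOOR)
    up = np.asarray(options.upper, float)
    bounds_log = (np.log(lo), np.log(up))

    # Relative (proportional) weighting divides by the MODEL magnitude,
    # recomputed every iteration: weighting by the measured magnitude would
    # correlate the weights with the noise and bias the parameters low.
    def residuals(p_log):
        params = MonolayerParams.from_array(np.exp(p_log))
        model = cell_covered_impedance(f, zn_meas, params)
        scale = np.abs(model) if options.weighting == "relative" else 1.0
        d = (model - zc_meas) / scale
        return np.concatenate([d.real, d.imag])

    rng = np.random.default_rng(options.seed)
    starts = [_heuristic_start(f, zc_meas, zn_meas, bounds_log)]
    span = bounds_log[1] - bounds_log[0]
    for _ in range(options.n_starts):
        starts.append(bounds_log[0] + rng.random(3) * span)

    best = None
    any_success = False
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=bounds_log, method="trf",
                            xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
                            max_nfev=2000)
        any_success = any_success or bool(sol.success)
        key = (sol.cost, np.exp(sol.x[1]))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]

    params = MonolayerParams.from_array(np.exp(sol.x))
    model = cell_covered_impedance(f, zn_meas, params)
    rel = np.abs(model - zc_meas) / np.abs(zc_meas)
    rms = float(np.sqrt(np.mean(rel**2)))

    result = FitResult(
        params=params,
        rms_relative_residual=rms,
        n_frequencies_used=len(f),
        converged=any_success,
        window_used=(options.f_min_hz, options.f_max_hz),
        per_frequency_residuals=rel,
        cm_ci_decades=_cm_ci_decades(sol),
        metadata={
            "electrode_id": cell_scan.electrode_id,
            "phase_label": cell_scan.phase_label,
            "seed": options.seed,
            "weighting": options.weighting,
            "conventions": dict(CONVENTIONS),
        },
    )
    result.qc = qc_flags(result)
    return result


def _cm_ci_decades(sol) -> float:
    """Approximate 95% CI span of cm, in decades, from residual curvature.

    Uses the Gauss-Newton covariance sigma^2 (J^T J)^-1 at the optimum in
    log-parameter space; the log-space standard error converts directly to
    a log10 interval width.
    """
    m, n = sol.jac.shape
    dof = m - n
    if dof <= 0:
        return float("nan")
    sigma2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * sigma2
    except np.linalg.LinAlgError:
        return float("inf")
    var = cov[2, 2]
    if not np.isfinite(var) or var < 0:
        return float("inf")
    return float(2 * 1.96 * np.sqrt(var) / np.log(10))


def qc_flags(result: FitResult, low_barrier_threshold: float = 0.2,
             poor_fit_threshold: float = 0.05,
             unstable_cm_decades: float = 1.0) -> set:
    """Quality-control warnings for one fit.

    LOW_BARRIER
        rb below ``low_barrier_threshold`` Ω·cm² — the monolayer is at the
        edge of what the model can analyse (intact-monolayer requirement).
    POOR_FIT
        rms relative residual above ``poor_fit_threshold``.
    UNSTABLE_CM
        the curvature-based 95% CI for cm spans more than
        ``unstable_cm_decades`` decades — cm is effectively unidentified,
        as happens when a near-zero barrier shorts the membrane path.
    """
    flags = set()
    if result.params.rb < low_barrier_threshold:
        flags.add("LOW_BARRIER")
    if result.rms_relative_residual > poor_fit_threshold:
        flags.add("POOR_FIT")
    if result.cm_ci_decades > unstable_cm_decades:
        flags.add("UNSTABLE_CM")
    return flags
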