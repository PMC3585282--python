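"""Synthetic data emulating an ECIS barrier-function study.

No raw impedance data accompany the study design this package supports,
so every input the pipeline consumes can be simulated here with the
statistical structure the analysis assumes:

* a cell-free **reference electrode** modelled as a constant-phase element
  (CPE) in series with the solution resistance, plus a small series lead
  inductance that dominates above ~20 kHz — the high-frequency artifact
  that motivates restricting fits to 62.5–16000 Hz;
* **cell-covered scans** computed from known (alpha, rb, cm) through the
  forward model, with the same lead artifact added in series (the leads
  sit outside the cell-electrode interface, so the artifact corrupts the
  measurement without obeying the monolayer model);
* **experiment bundles** with the replicate structure of a well array:
  4 electrodes per experiment, several independent experiments, pre- and
  post-treatment scans, log-normal between-experiment and
  between-electrode parameter variation;
* **condition presets** reproducing the study's qualitative effect
  directions (Epac activation by 007-AM ~1.5x rb; Rap2 depletion ~2x rb;
  Rap1 depletion reduced rb; cadherin depletion rb ~ 0 with alpha
  preserved and cm reduced);
* single-frequency **timecourses**, qPCR **Ct tables** with known
  knockdown fractions, and two-channel **junction/actin images** with a
  tunable junctional-actin fraction.

All generators are deterministic given their seed, and every generated
dataset is accompanied by its ground truth so recovery can be measured.

Baseline parameter values (alpha = 6 Ω^0.5·cm, rb = 4 Ω·cm²,
cm = 1.8 µF/cm²; CPE defaults) are plausible values for confluent
endothelial monolayers on small gold electrodes, chosen as fixed study
conditions; they are configuration, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .coloc import ImagePair
from .errors import InvalidArgumentError
from .fitting import FitOptions, fit_monolayer
from .model import (
    ComplexSpectrum,
    ElectrodeGeometry,
    MonolayerParams,
    cell_covered_impedance,
    from_specific,
)
from .timecourse import TimecourseTrace

__all__ = [
    "DEFAULT_FREQUENCIES_HZ", "FINE_FREQUENCIES_HZ", "ElectrodeModel", "Scenario", "preset",
    "PRESET_NAMES", "alpha_from_microscopic", "generate_reference",
    "generate_cell_scan", "generate_experiment", "ExperimentBundle",
    "generate_timecourse", "generate_images", "generate_ct_table",
    "recovery_study", "window_study",
]

#: Doubling frequency series 31.25 Hz ... 64 kHz (12 points).  The analysis
#: window 62.5–16000 Hz leaves out-of-window points on both sides.
DEFAULT_FREQUENCIES_HZ = 31.25 * 2.0 ** np.arange(12)

#: Instrument-style frequency scan, 4 points per octave over the same span
#: (45 points); impedance analysers sample considerably denser than the
#: doubling series summarises.
FINE_FREQUENCIES_HZ = 31.25 * 2.0 ** (np.arange(45) / 4)

DEFAULT_BASELINE = MonolayerParams(alpha=6.0, rb=4.0, cm=1.8)


@dataclass(frozen=True)
class ElectrodeModel:
    """Cell-free electrode stand-in: CPE + solution resistance + lead artifact.

    Interface impedance (specific, Ω·cm²)::

        Z_int(f) = R_sol + 1/(Q · (j·2πf)^β)

    The measured impedance adds the series lead artifact of the well's
    traces: an inductance L resonating with its stray capacitance,

        Z_art(f) = j·2πf·L / (1 − (f/f_res)²),

    which is inductive and steeply growing below the resonance.  With the
    defaults the imaginary part of the reference changes sign between 32
    and 64 kHz — inside the simulated acquisition range but above the
    62.5–16000 Hz analysis window, which is exactly why that window
    exists.
    """

    cpe_q: float = 30e-6          # S·s^beta per cm²; |Z_cpe| = 1/(Q ω^β)
    cpe_beta: float = 0.95
    solution_resistance: float = 2.0   # Ω·cm²
    series_inductance: float = 2e-7    # H·cm²
    resonance_hz: float = 70e3         # lead L/stray-C resonance

    def __post_init__(self) -> None:
        if not (0 < self.cpe_beta <= 1):
            raise InvalidArgumentError("cpe_beta must be in (0, 1]")
        if min(self.cpe_q, self.solution_resistance) <= 0 or self.series_inductance < 0:
            raise InvalidArgumentError("electrode model parameters must be non-negative")
        if not self.resonance_hz > 0:
            raise InvalidArgumentError("resonance_hz must be positive")

    def interface_specific(self, frequency_hz):
        f = np.asarray(frequency_hz, dtype=float)
        omega = 2 * np.pi * f
        return self.solution_resistance + 1.0 / (self.cpe_q * (1j * omega) ** self.cpe_beta)

    def artifact_specific(self, frequency_hz, lead_inductance: float | None = None):
        f = np.asarray(frequency_hz, dtype=float)
        lead = self.series_inductance if lead_inductance is None else lead_inductance
        return 1j * 2 * np.pi * f * lead / (1.0 - (f / self.resonance_hz) ** 2)

    def total_specific(self, frequency_hz):
        return self.interface_specific(frequency_hz) + self.artifact_specific(frequency_hz)


def alpha_from_microscopic(r_c_um: float, rho_ohm_cm: float, h_nm: float) -> float:
    """alpha = r_c·sqrt(rho/h) from cell radius, medium resistivity and gap.

    Units: r_c in µm, rho in Ω·cm, h in nm; result in Ω^0.5·cm.
    """
    if min(r_c_um, rho_ohm_cm, h_nm) <= 0:
        raise InvalidArgumentError("microscopic parameters must be positive")
    r_c = r_c_um * 1e-4   # cm
    h = h_nm * 1e-7       # cm
    return r_c * np.sqrt(rho_ohm_cm / h)


@dataclass(frozen=True)
class Scenario:
    """One simulated experimental condition.

    The condition is expressed as multiplicative factors applied to the
    baseline parameters between the *pre* and *post* scans of each
    electrode (treatment effect).  Between-experiment and
    between-electrode biological variation are log-normal with the given
    coefficients of variation.  ``noise_sd`` is the relative measurement
    noise of cell-covered scans (instrument plus the micromotion of a
    live monolayer); the cell-free reference well fluctuates far less, so
    it gets the smaller instrument-only ``reference_noise_sd``.
    ``microscopic`` optionally derives alpha from (r_c µm, rho Ω·cm, h nm).
    """

    name: str
    baseline: MonolayerParams = DEFAULT_BASELINE
    alpha_factor: float = 1.0
    rb_factor: float = 1.0
    cm_factor: float = 1.0
    noise_sd: float = 0.01
    reference_noise_sd: float = 0.001
    n_electrodes: int = 4
    n_experiments: int = 4
    seed: int = 0
    cv_experiment: float = 0.15
    cv_electrode: float = 0.05
    microscopic: tuple | None = None  # (r_c_um, rho_ohm_cm, h_nm)

    def __post_init__(self) -> None:
        if min(self.alpha_factor, self.rb_factor, self.cm_factor) < 0:
            raise InvalidArgumentError("effect factors must be >= 0")
        if self.n_electrodes < 1 or self.n_experiments < 1:
            raise InvalidArgumentError("need at least one electrode and one experiment")
        if self.microscopic is not None:
            object.__setattr__(self, "baseline", replace(
                self.baseline, alpha=alpha_from_microscopic(*self.microscopic)))


# Effect directions of the emulated conditions: Epac/Rap1 activation by
# 007-AM raises rb ~1.5x with a small cm effect; Rap2 depletion doubles rb;
# Rap1 depletion lowers it; depleting Rap1 and Rap2 together cancels;
# cadherin depletion collapses the barrier (rb ~ 0.05 Ω·cm²) while alpha is
# preserved and cm drops and becomes poorly identified.
_PRESETS = {
    "007AM": dict(rb_factor=1.5, cm_factor=1.1, n_experiments=8),
    "siRap1": dict(rb_factor=0.6, n_experiments=8),
    "siRap2": dict(rb_factor=2.0, n_experiments=6),
    "siRap1+siRap2": dict(rb_factor=1.0, n_experiments=4),
    "siCadherin": dict(rb_factor=0.0125, alpha_factor=1.0, cm_factor=0.5,
                       n_experiments=4),
}
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int = 0, **overrides) -> Scenario:
    """A named condition preset as a :class:`Scenario`."""
    if name not in _PRESETS:
        raise InvalidArgumentError(f"unknown scenario {name!r}; known: {PRESET_NAMES}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return Scenario(name=name, seed=seed, **kw)


def _noised(z: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative complex Gaussian noise, independent per frequency."""
    if noise_sd == 0:
        return z.copy()
    n = z.shape
    return z * (1.0 + noise_sd * rng.standard_normal(n) + 1j * noise_sd * rng.standard_normal(n))


def generate_reference(model: ElectrodeModel = ElectrodeModel(),
                       frequencies_hz=None,
                       geometry: ElectrodeGeometry = ElectrodeGeometry(),
                       noise_sd: float = 0.01, seed: int = 0,
                       electrode_id: str = "ref", phase_label: str = "") -> ComplexSpectrum:
    """Simulated cell-free reference scan in whole-electrode Ω."""
    f = DEFAULT_FREQUENCIES_HZ if frequencies_hz is None else np.asarray(frequencies_hz, float)
    rng = np.random.default_rng(seed)
    z = _noised(from_specific(model.total_specific(f), geometry), noise_sd, rng)
    return ComplexSpectrum(electrode_id, "reference", phase_label, f, z.real, z.imag)


def generate_cell_scan(model: ElectrodeModel, params: MonolayerParams,
                       frequencies_hz=None,
                       geometry: ElectrodeGeometry = ElectrodeGeometry(),
                       noise_sd: float = 0.01, seed: int = 0,
                       electrode_id: str = "e1", phase_label: str = "pre",
                       lead_inductance: float | None = None) -> ComplexSpectrum:
    """Simulated cell-covered scan from known parameters.

    The monolayer transforms the *interface* impedance of the noiseless
    electrode model; the series lead artifact of *this well* is then added
    to the measurement, and noise is applied independently of any
    reference realization.  ``lead_inductance`` overrides the model's
    series inductance for this well — each well of a real array has its
    own lead traces, so its artifact need not match the reference well's.
    """
    f = DEFAULT_FREQUENCIES_HZ if frequencies_hz is None else np.asarray(frequencies_hz, float)
    rng = np.random.default_rng(seed)
    zc = cell_covered_impedance(f, model.interface_specific(f), params) \
        + model.artifact_specific(f, lead_inductance)
    z = _noised(from_specific(zc, geometry), noise_sd, rng)
    return ComplexSpectrum(electrode_id, "cell_covered", phase_label, f, z.real, z.imag)


def _lognormal_factor(cv: float, rng: np.random.Generator, size=3) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, size))


@dataclass
class ExperimentBundle:
    """Everything one simulated multi-experiment condition produces."""

    scenario: Scenario
    reference_scans: dict            # experiment_id -> ComplexSpectrum
    cell_scans: list                 # ComplexSpectrum, pre & post per electrode
    ground_truth: pd.DataFrame       # experiment_id, electrode_id, phase_label, alpha, rb, cm


def generate_experiment(scenario: Scenario,
                        geometry: ElectrodeGeometry = ElectrodeGeometry(),
                        model: ElectrodeModel = ElectrodeModel(),
                        frequencies_hz=None) -> ExperimentBundle:
    """Pre/post frequency scans for every electrode of every experiment.

    Each experiment gets one biological multiplier triple (CV
    ``cv_experiment``), each electrode within it another (CV
    ``cv_electrode``); the post scan applies the scenario's treatment
    factors on top of the electrode's pre parameters, so the pre/post
    contrast is paired within electrodes just as in the real assay.

    Scans use the instrument-density grid (:data:`FINE_FREQUENCIES_HZ`):
    the frequency scans an impedance analyser records for model fitting
    are considerably denser than the doubling summary series, and the
    precision of small fitted barrier resistances depends on that density.
    """
    f = FINE_FREQUENCIES_HZ if frequencies_hz is None else np.asarray(frequencies_hz, float)
    seeds = np.random.SeedSequence(scenario.seed).generate_state(1_000_000, np.uint32)
    k = 0

    def next_seed():
        nonlocal k
        k += 1
        return int(seeds[k - 1] % (2**31))

    rng = np.random.default_rng(next_seed())
    references, scans, truth = {}, [], []
    for e in range(1, scenario.n_experiments + 1):
        exp_id = f"X{e}"
        references[exp_id] = generate_reference(
            model, f, geometry, scenario.reference_noise_sd, next_seed(),
            electrode_id=f"{exp_id}_ref")
        exp_mult = _lognormal_factor(scenario.cv_experiment, rng)
        for el in range(1, scenario.n_electrodes + 1):
            elec_id = f"{exp_id}_E{el}"
            elec_mult = _lognormal_factor(scenario.cv_electrode, rng)
            pre = MonolayerParams.from_array(
                scenario.baseline.as_array() * exp_mult * elec_mult)
            post = pre.scaled(scenario.alpha_factor, scenario.rb_factor,
                              scenario.cm_factor)
            for phase, p in (("pre", pre), ("post", post)):
                scans.append(generate_cell_scan(
                    model, p, f, geometry, scenario.noise_sd, next_seed(),
                    electrode_id=elec_id, phase_label=phase))
                truth.append(dict(experiment_id=exp_id, electrode_id=elec_id,
                                  phase_label=phase, alpha=p.alpha, rb=p.rb, cm=p.cm))
    return ExperimentBundle(scenario, references, scans, pd.DataFrame(truth))


def generate_timecourse(scenario: Scenario,
                        geometry: ElectrodeGeometry = ElectrodeGeometry(),
                        model: ElectrodeModel = ElectrodeModel(),
                        frequency_hz: float = 4000.0,
                        duration_s: float = 7200.0, dt_s: float = 60.0,
                        stimulus_time_s: float = 3600.0,
                        transition: str = "exponential",
                        tau_s: float = 600.0, seed: int | None = None) -> list:
    """Single-frequency timecourses for each electrode of one experiment.

    Before the stimulus the parameters sit at the electrode's baseline;
    afterwards the scenario's factors are approached either instantly
    (``transition="step"``) or along ``1 - exp(-(t - t_stim)/tau)``.
    """
    if transition not in ("exponential", "step"):
        raise InvalidArgumentError("transition must be 'exponential' or 'step'")
    seed = scenario.seed if seed is None else seed
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    after = t > stimulus_time_s
    if transition == "step":
        s = after.astype(float)
    else:
        s = np.where(after, 1.0 - np.exp(-(t - stimulus_time_s) / tau_s), 0.0)

    rng = np.random.default_rng(seed)
    zn = complex(model.interface_specific(frequency_hz))
    art = complex(model.artifact_specific(frequency_hz))
    traces = []
    for el in range(1, scenario.n_electrodes + 1):
        elec_mult = _lognormal_factor(scenario.cv_electrode, rng)
        base = MonolayerParams.from_array(scenario.baseline.as_array() * elec_mult)
        z = np.empty(len(t), dtype=complex)
        for i, si in enumerate(s):
            p = base.scaled(1 + (scenario.alpha_factor - 1) * si,
                            1 + (scenario.rb_factor - 1) * si,
                            1 + (scenario.cm_factor - 1) * si)
            z[i] = cell_covered_impedance(frequency_hz, zn, p) + art
        z = _noised(from_specific(z, geometry), scenario.noise_sd, rng)
        traces.append(TimecourseTrace(f"E{el}", t, z.real, z.imag,
                                      frequency_hz, stimulus_time_s))
    return traces


def generate_images(junctionality: float, dims=(256, 256), n_cells: int = 25,
                    noise_sd: float = 0.05, seed: int = 0,
                    fiber_period_px: float = 12.0, junction_width_px: float = 2.0,
                    blur_sigma: float = 1.0):
    """A junction-marker / F-actin image pair over a Voronoi cell mosaic.

    ``junctionality`` w ∈ [0, 1] sets the fraction of actin signal placed
    at cell boundaries; the remainder forms transverse stress-fiber
    stripes with a random orientation per cell.  Channel a carries the
    junction marker.  Returns ``(ImagePair, ground_truth)`` where the
    ground truth holds the noise-free junction and fiber masks.
    """
    if not 0 <= junctionality <= 1:
        raise InvalidArgumentError("junctionality must be in [0, 1]")
    h, w = dims
    if min(h, w) < 128 or n_cells < 9:
        raise InvalidArgumentError("need dims >= 128x128 and n_cells >= 9")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rng.uniform(0, h, n_cells), rng.uniform(0, w, n_cells)])
    d = np.sqrt((yy[None] - pts[:, 0, None, None]) ** 2
                + (xx[None] - pts[:, 1, None, None]) ** 2)
    order = np.sort(d, axis=0)
    junction = (order[1] - order[0]) < junction_width_px
    labels = np.argmin(d, axis=0)

    fibers = np.zeros(dims, dtype=bool)
    for c in range(n_cells):
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        stripes = np.sin(2 * np.pi * proj / fiber_period_px + phase) > 0.6
        fibers |= stripes & (labels == c) & ~junction

    def render(signal):
        img = 0.2 + gaussian_filter(signal.astype(float), blur_sigma)
        img = img + noise_sd * rng.standard_normal(dims)
        return np.clip(img, 0.0, None)

    channel_a = render(junction.astype(float))
    channel_b = render(junctionality * junction + (1 - junctionality) * fibers)
    pair = ImagePair(channel_a, channel_b, image_id=f"w{junctionality:g}_s{seed}")
    return pair, {"junction_mask": junction, "fiber_mask": fibers}


def generate_ct_table(knockdown_fractions: dict, n_replicates: int = 3,
                      ct_sd: float = 0.15, baseline_ct: float | dict = 24.0,
                      reference_gene: str = "HPRT", reference_gene_ct: float = 20.0,
                      sample_offset_sd: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """qPCR Ct table for known knockdown fractions.

    Treated samples express each target gene at ``fraction`` of the
    untreated level, so Ct = baseline − log2(fraction) + noise.  Every
    sample also receives a global loading/efficiency offset that shifts
    all of its genes equally and must cancel in ΔCt.  Sample
    ``"untreated"`` is the ΔΔCt reference.
    """
    for g, fr in knockdown_fractions.items():
        if not 0 < fr <= 1:
            raise InvalidArgumentError(f"knockdown fraction for {g!r} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(knockdown_fractions) + [reference_gene]

    def base(g):
        if g == reference_gene:
            return reference_gene_ct
        return baseline_ct[g] if isinstance(baseline_ct, dict) else baseline_ct

    rows = []
    samples = ["untreated"] + [f"kd_{i}" for i in range(1, n_replicates + 1)]
    for s in samples:
        offset = rng.normal(0, sample_offset_sd)
        for g in genes:
            shift = 0.0
            if s != "untreated" and g != reference_gene:
                shift = -np.log2(knockdown_fractions[g])
            rows.append(dict(sample_id=s, gene=g,
                             ct_cycles=base(g) + offset + shift + rng.normal(0, ct_sd)))
    return pd.DataFrame(rows)


def recovery_study(n_draws: int = 50, noise_sd: float = 0.01, seed: int = 0,
                   alpha_range=(2.0, 15.0), rb_range=(0.5, 10.0), cm_range=(0.5, 4.0),
                   geometry: ElectrodeGeometry = ElectrodeGeometry(),
                   options: FitOptions | None = None,
                   frequencies_hz=None) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery study of the spectrum fitter.

    Parameters are drawn uniformly from the given ranges; each draw
    generates a noisy cell scan on an instrument-style dense frequency
    grid (:data:`FINE_FREQUENCIES_HZ`) which is fitted back.  The
    electrode model here carries no lead inductance and the reference scan
    is used noise-free, isolating the fitter's estimation error from the
    high-frequency artifact (covered by :func:`window_study`) and from
    reference measurement error.  Returns one row per draw with true and
    fitted parameters and their relative errors.
    """
    model = ElectrodeModel(series_inductance=0.0)
    f = FINE_FREQUENCIES_HZ if frequencies_hz is None else np.asarray(frequencies_hz, float)
    reference = generate_reference(model, f, geometry, noise_sd=0.0, seed=0)
    rng = np.random.default_rng(seed)
    opts = options or FitOptions()
    rows = []
    for i in range(n_draws):
        true = MonolayerParams(alpha=rng.uniform(*alpha_range),
                               rb=rng.uniform(*rb_range),
                               cm=rng.uniform(*cm_range))
        scan = generate_cell_scan(model, true, f, geometry, noise_sd,
                                  seed=int(rng.integers(2**31)),
                                  electrode_id=f"draw{i}")
        fit = fit_monolayer(scan, reference, geometry, opts)
        p = fit.params
        rows.append(dict(
            draw=i, alpha_true=true.alpha, rb_true=true.rb, cm_true=true.cm,
            alpha_fit=p.alpha, rb_fit=p.rb, cm_fit=p.cm,
            alpha_rel_err=(p.alpha - true.alpha) / true.alpha,
            rb_rel_err=(p.rb - true.rb) / true.rb,
            cm_rel_err=(p.cm - true.cm) / true.cm,
            rms=fit.rms_relative_residual, converged=fit.converged))
    return pd.DataFrame(rows)


def window_study(params: MonolayerParams = DEFAULT_BASELINE,
                 model: ElectrodeModel = ElectrodeModel(),
                 geometry: ElectrodeGeometry = ElectrodeGeometry(),
                 frequencies_hz=None, seed: int = 0,
                 cell_lead_inductance: float = 4e-7) -> dict:
    """Why the 62.5–16000 Hz window matters: fits with vs without it.

    Noiseless scans are generated with mismatched lead inductances: the
    cell well's leads (``cell_lead_inductance``) differ from the reference
    well's (``model.series_inductance``), as they do between the physical
    wells of an array.  The model fits the cell scan *in relation to* the
    measured reference, so a mismatched series artifact cannot cancel and
    contaminates the high frequencies.  The same scans are fitted once
    inside the standard window and once over the full acquisition range;
    returns the maximum relative parameter shift from the generating truth
    for both fits.
    """
    f = DEFAULT_FREQUENCIES_HZ if frequencies_hz is None else np.asarray(frequencies_hz, float)
    reference = generate_reference(model, f, geometry, noise_sd=0.0, seed=seed)
    scan = generate_cell_scan(model, params, f, geometry, noise_sd=0.0, seed=seed,
                              lead_inductance=cell_lead_inductance)
    true = params.as_array()

    def max_shift(options):
        fit = fit_monolayer(scan, reference, geometry, options)
        return float(np.max(np.abs(fit.params.as_array() - true) / true))

    windowed = max_shift(FitOptions(seed=seed))
    full = max_shift(FitOptions(f_min_hz=f[0], f_max_hz=f[-1], seed=seed))
    return {"windowed_max_shift": windowed, "full_range_max_shift": full}
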