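"""Synthetic partitioned-sample generator.

Emulates the data a slice-selective 19F experiment produces from a two-phase
octanol/water sample: a declared true log P fixes the per-phase
concentrations, each phase contributes one Lorentzian line at its own
chemical shift, and the observed row amplitudes carry the experimental
weighting of the pulse sequence d1-90-tau-(sel180/grad)-tau-acquire:

  amplitude  ~  c_phase * slice volume * n_F * (1 - exp(-d1/T1)) * exp(-2*tau/T2) * ns

Time-domain noise is additive complex white Gaussian, scaled by sqrt(ns)
after co-addition so that signal-to-noise grows as sqrt(ns).  The slice
profile is an ideal rectangle: both slices have the same volume
(thickness x cross-section), so geometric factors cancel in the integral
ratio exactly as the measurement assumes.

Randomness: a single integer seed expands into independent substreams (one
per FID) through numpy ``SeedSequence`` spawn keys, so identical seeds give
bit-identical datasets and the rows are statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import DomainError
from .geometry import NucleusSpec, SlicePlan, get_nucleus

#: Inner cross-section of a 5 mm NMR tube, mm^2 (4.2 mm bore).  With slice
#: thickness in mm this makes slice volumes come out in uL; it cancels in all
#: ratios and only sets the overall amplitude scale.
CROSS_SECTION_MM2 = math.pi * 2.1**2

GENERATOR_VERSION = "slicelogp-synth/1"


def rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Independent, reproducible substream of the master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=stream))


@dataclass(frozen=True)
class Analyte:
    """A fluorinated solute and its per-phase NMR parameters.

    All values describing the built-in compounds are synthetic placeholders
    chosen to be physically plausible (19F shifts, ~2-3 Hz linewidths,
    seconds-scale T1); only the literature log P values attached to the
    built-in samples are real.
    """

    name: str
    n_fluorine: int
    shift_oct: float  # ppm in the n-octanol phase
    shift_aq: float  # ppm in the aqueous phase
    linewidth_oct: float  # Hz, FWHM
    linewidth_aq: float  # Hz, FWHM
    t1_oct: float  # s
    t1_aq: float  # s
    t2_oct: float  # s
    t2_aq: float  # s
    couplings: tuple[tuple[float, int], ...] | None = None  # (J Hz, multiplicity)

    def __post_init__(self) -> None:
        if self.n_fluorine < 1:
            raise DomainError("n_fluorine must be >= 1")
        for lw in (self.linewidth_oct, self.linewidth_aq):
            if lw <= 0:
                raise DomainError("linewidths must be positive")
        for t1, t2, ph in (
            (self.t1_oct, self.t2_oct, "octanol"),
            (self.t1_aq, self.t2_aq, "aqueous"),
        ):
            if t1 <= 0 or t2 <= 0:
                raise DomainError("relaxation times must be positive")
            if t2 > t1:
                raise DomainError(f"T2 must not exceed T1 in the {ph} phase")


@dataclass(frozen=True)
class PartitionSample:
    """An analyte equilibrated between n-octanol and water.

    ``logp_true`` is log10 of the octanol/water concentration ratio; amounts
    are mmol and volumes uL, so concentrations come out in mol/L.
    """

    analyte: Analyte
    logp_true: float
    n_total: float  # mmol
    v_oct: float = 270.0  # uL
    v_aq: float = 270.0  # uL

    def __post_init__(self) -> None:
        if self.v_oct <= 0 or self.v_aq <= 0:
            raise DomainError("phase volumes must be positive")
        if self.n_total <= 0:
            raise DomainError("n_total must be positive")

    def concentrations(self) -> tuple[float, float]:
        """(c_oct, c_aq) in mol/L from the true log P and mass balance."""
        return partition_concentrations(
            self.logp_true, self.n_total, self.v_oct, self.v_aq
        )


def partition_concentrations(
    logp: float, n_total: float, v_oct: float, v_aq: float
) -> tuple[float, float]:
    """Per-phase equilibrium concentrations (mol/L) of ``n_total`` mmol of
    solute split between ``v_oct``/``v_aq`` uL with partition coefficient
    P = 10**logp.  Mass balance c_oct*v_oct + c_aq*v_aq = n_total is exact."""
    if v_oct <= 0 or v_aq <= 0:
        raise DomainError("phase volumes must be positive")
    if n_total <= 0:
        raise DomainError("n_total must be positive")
    p = 10.0**logp
    c_aq = 1000.0 * n_total / (v_aq + p * v_oct)  # mmol/uL -> mol/L
    return p * c_aq, c_aq


def saturation_factor(d1: float, t1: float) -> float:
    """Steady-state longitudinal recovery factor 1 - exp(-d1/T1).

    Quantitative integrals require d1 >= 5*T1 (factor > 0.993); shorter
    relaxation delays scale each phase's signal by this factor and bias the
    integral ratio whenever the two phases' T1 differ.
    """
    if d1 <= 0 or t1 <= 0:
        raise DomainError("d1 and t1 must be positive")
    return 1.0 - math.exp(-d1 / t1)


def echo_attenuation(tau: float, t2: float) -> float:
    """Transverse attenuation exp(-2*tau/T2) across the spin echo."""
    if tau < 0:
        raise DomainError("tau must be non-negative")
    if t2 <= 0:
        raise DomainError("t2 must be positive")
    return math.exp(-2.0 * tau / t2)


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings for one pseudo-2D (or scout) experiment.

    ``td`` counts real+imaginary points (vendor convention), so the FID holds
    ``td/2`` complex points and the acquisition time is ``td / (2*SW_Hz)``.
    ``noise_sigma`` is the per-point complex-component noise scale for a
    single transient.
    """

    proton_freq: float = 600.13  # MHz
    nucleus: str = "19F"
    o1p: float = -70.0  # ppm, carrier offset
    sweep_width: float = 10.0  # ppm
    td: int = 16384  # real points (complex points = td // 2)
    ns: int = 16  # transients
    ds: int = 2  # dummy transients
    d1: float = 30.0  # s, relaxation delay
    tau: float = 0.002  # s, echo delay
    noise_sigma: float = 0.0
    seed: int = 0
    phase0: float = 0.0  # degrees, receiver zero-order phase

    def __post_init__(self) -> None:
        if self.td < 4 or self.td % 2:
            raise DomainError("td must be an even number of points >= 4")
        if self.d1 <= 0:
            raise DomainError("d1 must be positive")
        if self.ns < 1:
            raise DomainError("ns must be >= 1")

    @property
    def nucleus_spec(self) -> NucleusSpec:
        return get_nucleus(self.nucleus)

    @property
    def f_spec(self) -> float:
        """Observe frequency, MHz."""
        return self.nucleus_spec.frequency(self.proton_freq)

    @property
    def sw_hz(self) -> float:
        return self.sweep_width * self.f_spec

    @property
    def n_complex(self) -> int:
        return self.td // 2

    @property
    def dwell(self) -> float:
        return 1.0 / self.sw_hz

    @property
    def acquisition_time(self) -> float:
        return self.td / (2.0 * self.sw_hz)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PseudoSpectrum2D:
    """A two-row spatially encoded dataset: octanol slice then aqueous slice
    (row order recorded in ``provenance['row_order']``)."""

    rows: np.ndarray  # complex128, shape (2, n_complex)
    params: AcquisitionParams
    plan: SlicePlan | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.complex128)
        if self.rows.ndim != 2 or self.rows.shape[0] != 2:
            raise DomainError("rows must be a (2, n) complex array")
        if self.rows.shape[1] != self.params.n_complex:
            raise DomainError("row length inconsistent with params.td")


def _multiplet(couplings: tuple[tuple[float, int], ...] | None):
    """Expand scalar couplings into (weight, Hz offset) line components."""
    comps = [(1.0, 0.0)]
    for j, mult in couplings or ():
        if mult < 2:
            continue
        pattern = [math.comb(mult - 1, k) for k in range(mult)]
        norm = float(sum(pattern))
        new = []
        for w, off in comps:
            for k, p in enumerate(pattern):
                new.append((w * p / norm, off + j * (k - (mult - 1) / 2.0)))
        comps = new
    return comps


def synth_fid(
    peaks: list[tuple[float, float, float, tuple | None]],
    params: AcquisitionParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one complex FID from ``(amplitude, shift_ppm, fwhm_hz,
    couplings)`` entries.

    Amplitudes are per transient and are co-added over ``params.ns``
    transients; noise is complex Gaussian with per-component scale
    ``noise_sigma * sqrt(ns)``.  An empty peak list yields a noise-only FID.
    """
    n = params.n_complex
    t = np.arange(n) * params.dwell
    fid = np.zeros(n, dtype=np.complex128)
    for amp, shift_ppm, fwhm, couplings in peaks:
        if fwhm <= 0:
            raise DomainError("FWHM must be positive")
        nu0 = (shift_ppm - params.o1p) * params.f_spec  # Hz offset from carrier
        for w, dj in _multiplet(couplings):
            fid += (
                params.ns
                * amp
                * w
                * np.exp((2j * math.pi * (nu0 + dj) - math.pi * fwhm) * t)
            )
    if params.phase0:
        fid *= np.exp(1j * math.radians(params.phase0))
    if params.noise_sigma > 0:
        if rng is None:
            rng = rng_for(params.seed, 0)
        scale = params.noise_sigma * math.sqrt(params.ns)
        fid += scale * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return fid


def _row_amplitude(c: float, sample: PartitionSample, plan: SlicePlan,
                   params: AcquisitionParams, t1: float, t2: float) -> float:
    vol = plan.thickness * CROSS_SECTION_MM2  # uL, equal for both slices
    return (
        c
        * vol
        * sample.analyte.n_fluorine
        * saturation_factor(params.d1, t1)
        * echo_attenuation(params.tau, t2)
    )


def simulate_pseudo2d(
    sample: PartitionSample,
    plan: SlicePlan,
    params: AcquisitionParams,
) -> PseudoSpectrum2D:
    """Simulate the two-increment slice-selective experiment.

    Row 1 is the octanol slice (analyte at ``shift_oct``), row 2 the aqueous
    slice; each row gets an independent noise substream of ``params.seed``.
    Refuses invalid plans, echoing the plan's violation messages.
    """
    if not plan.valid:
        raise DomainError(
            "cannot simulate from an invalid slice plan: " + "; ".join(plan.messages)
        )
    a = sample.analyte
    c_oct, c_aq = sample.concentrations()
    amp_oct = _row_amplitude(c_oct, sample, plan, params, a.t1_oct, a.t2_oct)
    amp_aq = _row_amplitude(c_aq, sample, plan, params, a.t1_aq, a.t2_aq)
    row_oct = synth_fid(
        [(amp_oct, a.shift_oct, a.linewidth_oct, a.couplings)],
        params,
        rng_for(params.seed, 0),
    )
    row_aq = synth_fid(
        [(amp_aq, a.shift_aq, a.linewidth_aq, a.couplings)],
        params,
        rng_for(params.seed, 1),
    )
    provenance = {
        "generator": GENERATOR_VERSION,
        "logp_true": sample.logp_true,
        "seed": params.seed,
        "row_order": "octanol_first",
        "analyte": asdict(a),
        "sample": {
            "n_total_mmol": sample.n_total,
            "v_oct_ul": sample.v_oct,
            "v_aq_ul": sample.v_aq,
        },
    }
    return PseudoSpectrum2D(
        rows=np.vstack([row_oct, row_aq]),
        params=params,
        plan=plan,
        provenance=provenance,
    )


#: Scout-scan defaults: very wide window centred upfield so any 19F signal in
#: the common shift range falls inside it.
SCOUT_SWEEP_PPM = 490.0
SCOUT_O1P = -50.0
SCOUT_TD = 4096


def scout_params(
    base: AcquisitionParams, ns: int = 1, seed: int | None = None
) -> AcquisitionParams:
    """Acquisition settings for a single-pulse scout scan derived from the
    slice experiment's settings (same field, same noise scale)."""
    return replace(
        base,
        o1p=SCOUT_O1P,
        sweep_width=SCOUT_SWEEP_PPM,
        td=SCOUT_TD,
        ns=ns,
        ds=0,
        tau=0.0,
        phase0=base.phase0,
        seed=base.seed if seed is None else seed,
    )


def simulate_scout(
    sample: PartitionSample, params: AcquisitionParams
) -> np.ndarray:
    """Single-pulse whole-sample FID: both phases contribute, weighted by
    concentration x phase volume (no slice selection, no echo)."""
    a = sample.analyte
    c_oct, c_aq = sample.concentrations()
    sat_o = saturation_factor(params.d1, a.t1_oct)
    sat_a = saturation_factor(params.d1, a.t1_aq)
    peaks = [
        (c_oct * sample.v_oct * a.n_fluorine * sat_o, a.shift_oct,
         a.linewidth_oct, a.couplings),
        (c_aq * sample.v_aq * a.n_fluorine * sat_a, a.shift_aq,
         a.linewidth_aq, a.couplings),
    ]
    return synth_fid(peaks, params, rng_for(params.seed, 2, params.ns))


# ---------------------------------------------------------------------------
# Built-in samples.  log P values are the literature values for these
# compounds; every NMR parameter (shifts, linewidths, relaxation) is a
# synthetic placeholder in a plausible range.

ANALYTES: dict[str, Analyte] = {
    "trifluoroethanol": Analyte(
        "trifluoroethanol", 3, -76.8, -74.5, 3.2, 3.6, 3.2, 2.8, 0.8, 0.6
    ),
    "hexafluoroisopropanol": Analyte(
        "hexafluoroisopropanol", 6, -75.9, -73.3, 3.4, 3.6, 3.0, 2.6, 0.7, 0.6
    ),
    "trifluorotoluene": Analyte(
        "trifluorotoluene", 3, -63.9, -59.9, 3.4, 3.4, 3.5, 3.0, 0.6, 0.8
    ),
    "4-fluorophenol": Analyte(
        "4-fluorophenol", 1, -124.5, -121.5, 3.2, 3.4, 2.8, 2.4, 0.5, 0.7
    ),
    "1-fluoroethanol": Analyte(
        "1-fluoroethanol", 1, -221.4, -219.2, 3.6, 3.4, 3.0, 2.6, 0.6, 0.6
    ),
}

#: Literature log P and total amount (mmol in 270+270 uL) for the built-in
#: samples; concentrations follow the 0.01-0.21 mmol loading range used for
#: desk-top shake-flask style preparations.
SAMPLE_DEFAULTS: dict[str, tuple[float, float]] = {
    "trifluoroethanol": (0.41, 0.054),
    "hexafluoroisopropanol": (1.66, 0.054),
    "trifluorotoluene": (3.01, 0.013),
    "4-fluorophenol": (1.77, 0.027),
    "1-fluoroethanol": (-0.68, 0.097),
}


def default_sample(name: str, logp: float | None = None) -> PartitionSample:
    """A ready-made :class:`PartitionSample` for one of the built-in
    compounds, optionally overriding the true log P."""
    if name not in ANALYTES:
        raise DomainError(f"unknown analyte {name!r}; known: {sorted(ANALYTES)}")
    lit, n_total = SAMPLE_DEFAULTS[name]
    return PartitionSample(
        ANALYTES[name], lit if logp is None else logp, n_total
    )


#: The standard synthetic ensemble: every built-in compound at its literature
#: log P, with the summed-spectrum minor-peak SNR targets spanning the
#: working range down to the lowest level the workflow tolerates.
ENSEMBLE_SNR_TARGETS: dict[str, float] = {
    "trifluoroethanol": 14.0,
    "hexafluoroisopropanol": 18.0,
    "trifluorotoluene": 12.0,
    "4-fluorophenol": 25.0,
    "1-fluoroethanol": 35.0,
}


def standard_ensemble() -> list[tuple[PartitionSample, float]]:
    """(sample, summed-spectrum minor-peak SNR target) pairs defining the
    reference conditions used for ensemble statistics."""
    return [
        (default_sample(name), snr) for name, snr in ENSEMBLE_SNR_TARGETS.items()
    ]


def peak_height_factor(fwhm: float, acq_time: float) -> float:
    """Spectral peak height per unit FID amplitude for an exponentially
    damped line, in the dwell-scaled Fourier convention used by
    :mod:`slicelogp.processing`: (1 - exp(-pi*FWHM*T)) / (pi*FWHM)."""
    return (1.0 - math.exp(-math.pi * fwhm * acq_time)) / (math.pi * fwhm)


def noise_sigma_for_snr(
    sample: PartitionSample,
    plan: SlicePlan,
    params: AcquisitionParams,
    target_snr: float,
    spectrum: str = "row",
) -> float:
    """Per-transient noise scale giving the minor phase peak a target SNR.

    SNR is the vendor-style amplitude / (2 x noise RMS); the closed form
    follows from Parseval (spectral noise RMS = sqrt(n) * sigma_t * dwell).
    ``spectrum='summed'`` targets the SNR in the sum of the two rows, whose
    noise RMS is sqrt(2) higher.
    """
    if target_snr <= 0:
        raise DomainError("target_snr must be positive")
    a = sample.analyte
    c_oct, c_aq = sample.concentrations()
    h_oct = _row_amplitude(c_oct, sample, plan, params, a.t1_oct, a.t2_oct) * \
        peak_height_factor(a.linewidth_oct, params.acquisition_time)
    h_aq = _row_amplitude(c_aq, sample, plan, params, a.t1_aq, a.t2_aq) * \
        peak_height_factor(a.linewidth_aq, params.acquisition_time)
    h_min = min(h_oct, h_aq)
    rms_needed = h_min / (2.0 * target_snr)
    if spectrum == "summed":
        rms_needed /= math.sqrt(2.0)
    elif spectrum != "row":
        raise DomainError("spectrum must be 'row' or 'summed'")
    # rms = sigma * sqrt(ns) * sqrt(n) * dwell, heights carry a factor ns
    return (
        rms_needed
        * params.ns
        / (math.sqrt(params.ns) * math.sqrt(params.n_complex) * params.dwell)
    )
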