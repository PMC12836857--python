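"""Spatial-encoding geometry for slice-selective NMR experiments.

In a slice-selective experiment a frequency-selective shaped pulse is applied
while a linear z pulsed-field gradient is on.  The gradient makes the Larmor
frequency a linear function of axial position, so the pulse bandwidth maps to
a slab thickness

    dz = BW / (gamma_bar * G)

and a pulse offset Omega maps to the slab position relative to the gradient
isocentre (placed at the octanol/water interface)

    d = Omega / (gamma_bar * G)

with gamma_bar the gyromagnetic ratio over 2*pi.  This module computes those
numbers, the shaped-pulse durations fixed by each shape's time-bandwidth
product, and packages them into a validated :class:`SlicePlan`.

Sign convention: positive z and positive pulse offsets point into the upper
(*n*-octanol) phase; the solvent interface sits at z = 0 at the centre of the
rf coil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

#: Gyromagnetic ratio over 2*pi of the proton, MHz per tesla.
GAMMA_BAR_1H = 42.577

#: 19F/1H resonance-frequency ratio (dimensionless).
XI_19F = 0.94094

#: Default maximum z-gradient amplitude of a 5 mm liquids probe, G/cm.
G_MAX_DEFAULT = 55.0

#: Default active coil half-length, mm (~18 mm active region of a 5 mm probe).
COIL_HALF_LENGTH_DEFAULT = 9.0

#: Dimensionless time-bandwidth products of the supported selective shapes,
#: keyed by (shape name, flip angle).  duration = factor / bandwidth.
SHAPE_FACTORS: dict[tuple[str, int], float] = {
    ("G4", 90): 7.82,
    ("Rsnob", 180): 2.332,
}


@dataclass(frozen=True)
class NucleusSpec:
    """A nucleus for frequency/field conversions.

    Attributes
    ----------
    name : str
        Text label, e.g. ``"19F"``.
    gamma_bar : float
        Gyromagnetic ratio over 2*pi, MHz/T.
    xi_ratio : float
        Resonance frequency as a fraction of the 1H frequency at the same
        field (Xi).  Must be consistent with ``gamma_bar`` to 0.2%.
    """

    name: str
    gamma_bar: float
    xi_ratio: float

    def __post_init__(self) -> None:
        if self.gamma_bar <= 0:
            raise DomainError(f"gamma_bar must be positive, got {self.gamma_bar}")
        if not 0 < self.xi_ratio <= 1.1:
            raise DomainError(f"xi_ratio must lie in (0, 1.1], got {self.xi_ratio}")
        implied = self.xi_ratio * GAMMA_BAR_1H
        if abs(implied - self.gamma_bar) / implied > 0.002:
            raise DomainError(
                f"gamma_bar={self.gamma_bar} inconsistent with "
                f"xi_ratio*gamma_bar(1H)={implied:.4f} beyond 0.2%"
            )

    def frequency(self, proton_freq: float) -> float:
        """Basic resonance frequency (MHz) at the field where 1H resonates at
        ``proton_freq`` MHz."""
        if proton_freq <= 0:
            raise DomainError("proton_freq must be positive")
        return self.xi_ratio * proton_freq

    @property
    def gamma_bar_hz_per_gauss(self) -> float:
        """gamma_bar expressed in Hz per gauss (1 T = 1e4 G)."""
        return self.gamma_bar * 100.0


#: Registry of built-in nuclei.
NUCLEI: dict[str, NucleusSpec] = {
    "1H": NucleusSpec("1H", GAMMA_BAR_1H, 1.0),
    "19F": NucleusSpec("19F", XI_19F * GAMMA_BAR_1H, XI_19F),
}


def get_nucleus(name: str) -> NucleusSpec:
    try:
        return NUCLEI[name]
    except KeyError:
        raise DomainError(
            f"unknown nucleus {name!r}; known: {sorted(NUCLEI)}"
        ) from None


def gradient_abs(percent: float, g_max: float = G_MAX_DEFAULT) -> float:
    """Absolute gradient amplitude (G/cm) from a percent-of-maximum setting."""
    if not 0 < percent <= 100:
        raise DomainError(f"gradient percent must be in (0, 100], got {percent}")
    if g_max <= 0:
        raise DomainError(f"g_max must be positive, got {g_max}")
    return percent / 100.0 * g_max


@dataclass(frozen=True)
class GradientSpec:
    """A z-gradient setting: percent of maximum plus the hardware maximum."""

    percent: float
    g_max: float = G_MAX_DEFAULT

    def __post_init__(self) -> None:
        gradient_abs(self.percent, self.g_max)  # validate

    @property
    def g_abs(self) -> float:
        """Resolved absolute gradient, G/cm."""
        return gradient_abs(self.percent, self.g_max)


def slice_thickness(bandwidth: float, gradient: float, nucleus: NucleusSpec) -> float:
    """Slice thickness dz (mm) excited by a pulse of ``bandwidth`` Hz under a
    ``gradient`` G/cm for ``nucleus``.

    dz = BW / (gamma_bar * G); thickness scales linearly with bandwidth and
    inversely with gradient strength.
    """
    if bandwidth <= 0:
        raise DomainError(f"bandwidth must be positive, got {bandwidth}")
    if gradient <= 0:
        raise DomainError(f"gradient must be positive, got {gradient}")
    # Hz / (Hz/G * G/cm) = cm; *10 -> mm
    return 10.0 * bandwidth / (nucleus.gamma_bar_hz_per_gauss * gradient)


def offset_to_position(offset: float, gradient: float, nucleus: NucleusSpec) -> float:
    """Signed slice position d (mm) for a pulse ``offset`` in Hz.

    Positive offsets select from the upper (octanol) phase.
    """
    if gradient <= 0:
        raise DomainError(f"gradient must be positive, got {gradient}")
    return 10.0 * offset / (nucleus.gamma_bar_hz_per_gauss * gradient)


def ppm_to_hz(offset_ppm: float, nucleus: NucleusSpec, proton_freq: float) -> float:
    """Convert a ppm offset to Hz at the nucleus frequency implied by the
    spectrometer's ``proton_freq`` (MHz)."""
    return offset_ppm * nucleus.frequency(proton_freq)


def hz_to_ppm(offset_hz: float, nucleus: NucleusSpec, proton_freq: float) -> float:
    """Inverse of :func:`ppm_to_hz` (exact round trip)."""
    return offset_hz / nucleus.frequency(proton_freq)


def pulse_duration(bw_factor: float, bandwidth: float) -> float:
    """Shaped-pulse duration in microseconds, rounded to 0.01 us.

    The duration of a selective shape is its dimensionless time-bandwidth
    product divided by the desired bandwidth.
    """
    if bw_factor <= 0:
        raise DomainError(f"bw_factor must be positive, got {bw_factor}")
    if bandwidth <= 0:
        raise DomainError(f"bandwidth must be positive, got {bandwidth}")
    return round(bw_factor / bandwidth * 1e6, 2)


@dataclass(frozen=True)
class ShapedPulseSpec:
    """A resolved selective pulse: shape, flip angle, bandwidth, duration."""

    shape_name: str
    flip_angle: int
    bw_factor: float
    bandwidth: float
    duration: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "duration", pulse_duration(self.bw_factor, self.bandwidth)
        )


def shaped_pulse(shape_name: str, flip_angle: int, bandwidth: float) -> ShapedPulseSpec:
    """Look up the shape's time-bandwidth product and resolve its duration."""
    try:
        factor = SHAPE_FACTORS[(shape_name, flip_angle)]
    except KeyError:
        raise DomainError(
            f"no time-bandwidth factor for shape {shape_name!r} at "
            f"{flip_angle} degrees; known: {sorted(SHAPE_FACTORS)}"
        ) from None
    return ShapedPulseSpec(shape_name, flip_angle, factor, bandwidth)


@dataclass(frozen=True)
class SlicePlan:
    """Fully resolved slice-selection geometry for a two-phase sample.

    ``position_upper``/``position_lower`` are signed distances (mm) of the two
    slice centres from the interface; ``valid`` is False when either slice
    straddles the interface or falls outside the active coil region, with the
    violations listed in ``messages``.
    """

    nucleus: NucleusSpec
    gradient: GradientSpec
    bandwidth: float
    offset_upper: float
    offset_lower: float
    thickness: float
    position_upper: float
    position_lower: float
    coil_half_length: float
    valid: bool
    messages: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "nucleus": self.nucleus.name,
            "gradient_percent": self.gradient.percent,
            "g_max": self.gradient.g_max,
            "g_abs": self.gradient.g_abs,
            "bandwidth_hz": self.bandwidth,
            "offset_upper_hz": self.offset_upper,
            "offset_lower_hz": self.offset_lower,
            "thickness_mm": self.thickness,
            "position_upper_mm": self.position_upper,
            "position_lower_mm": self.position_lower,
            "coil_half_length_mm": self.coil_half_length,
            "valid": self.valid,
            "messages": list(self.messages),
        }


def plan_slices(
    nucleus: NucleusSpec,
    proton_freq: float,
    gradient: GradientSpec,
    bandwidth: float,
    omega_ppm: float,
    coil_half_length: float = COIL_HALF_LENGTH_DEFAULT,
    interface_clearance: float = 0.0,
) -> SlicePlan:
    """Resolve a symmetric two-slice plan with offsets of +/- ``omega_ppm``.

    Never raises for a geometrically impossible plan: violations are returned
    on the plan (``valid=False`` plus messages) so callers can report them.
    """
    if proton_freq <= 0:
        raise DomainError("proton_freq must be positive")
    if coil_half_length <= 0:
        raise DomainError("coil_half_length must be positive")
    g = gradient.g_abs
    dz = slice_thickness(bandwidth, g, nucleus)
    omega_hz = ppm_to_hz(abs(omega_ppm), nucleus, proton_freq)
    d_up = offset_to_position(omega_hz, g, nucleus)
    d_lo = offset_to_position(-omega_hz, g, nucleus)

    messages: list[str] = []
    for label, d in (("upper", d_up), ("lower", d_lo)):
        if abs(d) - dz / 2.0 <= interface_clearance:
            messages.append(
                f"{label} slice (centre {d:.2f} mm, thickness {dz:.2f} mm) "
                f"straddles or touches the solvent interface"
            )
        if abs(d) + dz / 2.0 > coil_half_length:
            messages.append(
                f"{label} slice (centre {d:.2f} mm, thickness {dz:.2f} mm) "
                f"extends beyond the {coil_half_length:.1f} mm coil half-length"
            )
    return SlicePlan(
        nucleus=nucleus,
        gradient=gradient,
        bandwidth=bandwidth,
        offset_upper=omega_hz,
        offset_lower=-omega_hz,
        thickness=dz,
        position_upper=d_up,
        position_lower=d_lo,
        coil_half_length=coil_half_length,
        valid=not messages,
        messages=tuple(messages),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)
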