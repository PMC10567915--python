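"""Core signal types for time-domain MR spectroscopy.

The in-vivo signal model used throughout the package is a sum of
exponentially damped complex sinusoids (Lorentzian lines).  A *resonance*
is one metabolite signal; it may be a singlet or a J-coupled multiplet
(doublet or 1:2:1 triplet) whose peaks share amplitude, damping and phase:

    s(t) = sum_k A_k exp(i phi_k) sum_m r_km exp((-pi d_k + 2 pi i f_km) t)

with ``A_k`` the amplitude, ``d_k`` the Lorentzian damping (full width at
half maximum, Hz), ``phi_k`` the zero-order phase and ``f_km`` the peak
frequency in Hz derived from the chemical shift (ppm) and the multiplet
offsets (0 for singlets, +-J/2 for doublets, {-J, 0, +J} for triplets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidAcquisitionError, SchemaError

__all__ = [
    "Multiplet",
    "ResonanceSpec",
    "AcquisitionParams",
    "FidRecord",
    "synthesize",
    "spectrum",
    "ppm_axis",
    "singlet",
]

_DEFAULT_RATIOS = {1: (1.0,), 2: (0.5, 0.5), 3: (0.25, 0.5, 0.25)}


@dataclass(frozen=True)
class Multiplet:
    """J-coupled multiplet structure of a resonance.

    ``n_peaks`` may be 1 (singlet), 2 (doublet) or 3 (triplet); ``j_hz`` is
    the scalar coupling in Hz and ``ratios`` the relative peak weights,
    which must sum to one.  Defaults follow the conventional binomial
    pattern: 1/2:1/2 doublet and 1/4:1/2:1/4 triplet.
    """

    n_peaks: int = 1
    j_hz: float = 0.0
    ratios: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_peaks not in (1, 2, 3):
            raise SchemaError(f"n_peaks must be 1, 2 or 3, got {self.n_peaks}")
        if self.j_hz < 0:
            raise SchemaError("J coupling must be >= 0")
        if self.n_peaks == 1 and self.j_hz != 0:
            raise SchemaError("a singlet must have j_hz = 0")
        ratios = self.ratios or _DEFAULT_RATIOS[self.n_peaks]
        if len(ratios) != self.n_peaks:
            raise SchemaError("multiplet ratios must have one entry per peak")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise SchemaError("multiplet ratios must sum to 1")
        object.__setattr__(self, "ratios", tuple(float(r) for r in ratios))

    def offsets_hz(self) -> tuple[float, ...]:
        """Frequency offsets of the peaks relative to the resonance centre."""
        if self.n_peaks == 1:
            return (0.0,)
        if self.n_peaks == 2:
            return (-self.j_hz / 2.0, +self.j_hz / 2.0)
        return (-self.j_hz, 0.0, +self.j_hz)


@dataclass(frozen=True)
class ResonanceSpec:
    """One spectral component: a (possibly multiplet) Lorentzian line."""

    name: str
    shift_ppm: float
    amplitude: float = 1.0
    damping_hz: float = 5.0
    phase_deg: float = 0.0
    multiplet: Multiplet = field(default_factory=Multiplet)

    def __post_init__(self):
        if self.amplitude < 0:
            raise SchemaError(f"{self.name}: amplitude must be >= 0")
        if self.damping_hz <= 0:
            raise SchemaError(f"{self.name}: damping must be > 0")


def singlet(name: str, shift_ppm: float, amplitude: float = 1.0,
            damping_hz: float = 5.0, phase_deg: float = 0.0) -> ResonanceSpec:
    """Convenience constructor for a single Lorentzian line."""
    return ResonanceSpec(name, shift_ppm, amplitude, damping_hz, phase_deg)


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence and spectrometer parameters of one acquisition.

    ``carrier_ppm`` fixes the ppm value at zero frequency offset: 0 ppm
    (the PCr peak) for the phosphorus channel and the water position for
    the proton channel, so that ``f_hz = (shift_ppm - carrier_ppm) *
    nucleus_freq_mhz``.
    """

    tr_ms: float
    te_ms: float
    flip_deg: float
    bandwidth_hz: float
    vector_size: int
    nucleus_freq_mhz: float
    channel: str  # "proton" | "phosphorus"
    carrier_ppm: float = 0.0

    def __post_init__(self):
        if self.bandwidth_hz <= 0:
            raise InvalidAcquisitionError("bandwidth must be > 0")
        if self.vector_size < 64:
            raise InvalidAcquisitionError("vector size must be >= 64")
        if not (0 < self.flip_deg <= 180):
            raise InvalidAcquisitionError("flip angle must lie in (0, 180] degrees")
        if not (self.tr_ms > self.te_ms >= 0):
            raise InvalidAcquisitionError("require TR > TE >= 0")
        if self.nucleus_freq_mhz <= 0:
            raise InvalidAcquisitionError("nucleus frequency must be > 0")
        if self.channel not in ("proton", "phosphorus"):
            raise InvalidAcquisitionError(f"unknown channel {self.channel!r}")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds, including t = 0."""
        return np.arange(self.vector_size) / self.bandwidth_hz

    def ppm_to_hz(self, shift_ppm) -> np.ndarray | float:
        return (np.asarray(shift_ppm, dtype=float) - self.carrier_ppm) * self.nucleus_freq_mhz

    def hz_to_ppm(self, f_hz) -> np.ndarray | float:
        return np.asarray(f_hz, dtype=float) / self.nucleus_freq_mhz + self.carrier_ppm

    @property
    def nucleus(self) -> str:
        return "31P" if self.channel == "phosphorus" else "1H"


@dataclass
class FidRecord:
    """A complex free-induction decay plus its acquisition metadata.

    ``ground_truth`` carries the generating resonance list when the record
    was simulated, enabling recovery tests; ``noise_sd`` is the true noise
    standard deviation per real/imaginary sample, when known.
    """

    samples: np.ndarray
    acquisition: AcquisitionParams
    ground_truth: tuple[ResonanceSpec, ...] | None = None
    noise_sd: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise SchemaError("FID samples must be one-dimensional")
        if self.samples.size != self.acquisition.vector_size:
            raise SchemaError(
                f"FID has {self.samples.size} samples but acquisition declares "
                f"{self.acquisition.vector_size}"
            )

    @property
    def nucleus(self) -> str:
        return self.acquisition.nucleus

    def __len__(self) -> int:
        return self.samples.size


def synthesize(model: Sequence[ResonanceSpec], acquisition: AcquisitionParams) -> np.ndarray:
    """Noiseless model signal s(t_n) for a list of resonances."""
    t = acquisition.times()
    s = np.zeros(acquisition.vector_size, dtype=complex)
    for res in model:
        f0 = acquisition.ppm_to_hz(res.shift_ppm)
        phase = math.radians(res.phase_deg)
        basis = np.zeros_like(s)
        for ratio, off in zip(res.multiplet.ratios, res.multiplet.offsets_hz()):
            basis += ratio * np.exp((-math.pi * res.damping_hz + 2j * math.pi * (f0 + off)) * t)
        s += res.amplitude * np.exp(1j * phase) * basis
    return s


def spectrum(samples: np.ndarray, acquisition: AcquisitionParams,
             zero_fill: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Discrete spectrum of a FID: (frequency axis in Hz, complex spectrum).

    The convention matches ``synthesize``: a component rotating as
    ``exp(+2*pi*i*f*t)`` produces a peak at +f.  Frequencies are returned
    monotonically increasing (fftshift order).
    """
    n = int(zero_fill) if zero_fill else len(samples)
    spec = np.fft.fftshift(np.fft.fft(samples, n=n))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=acquisition.dwell_s))
    return freqs, spec


def ppm_axis(freqs_hz: np.ndarray, acquisition: AcquisitionParams) -> np.ndarray:
    return acquisition.hz_to_ppm(freqs_hz)
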