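"""Single neural mass: PSP kernels, sigmoid rate functions, one-step state update.

A neural mass lumps a cortical patch into one excitatory (pyramidal) and one
inhibitory population.  Each synaptic pathway is a bi-exponential postsynaptic
potential kernel

    h(t) = A * (exp(-a*t) - exp(-b*t)),   0 < a < b,

equivalent to the second-order linear ODE

    y'' + (a + b) y' + a*b*y = A * (b - a) * x(t),

driven by the presynaptic pulse density x(t).  Population mean membrane
potential maps to output pulse density through a logistic sigmoid.  The
pyramidal potential Ve mimics the MEG/EEG signal; the pyramidal pulse density
E(t) is the model's direct readout of neuronal activity.

The kernel filters are advanced with an exact exponential (impulse-invariant)
update of the two modal components exp(-a*t) and exp(-b*t), so the discrete
output equals the dt-scaled convolution of the input train with the
closed-form kernel to machine precision, and the update is unconditionally
stable for any step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "SigmoidParams",
    "NeuralMassParams",
    "MassState",
    "ModelInstabilityError",
    "sigmoid_rate",
    "kernel_impulse_response",
    "kernel_peak",
    "BiExpFilter",
    "step_mass",
    "default_mass_params",
]


class ModelInstabilityError(RuntimeError):
    """Raised when the state of a mass or network becomes non-finite."""


@dataclass(frozen=True)
class KernelParams:
    """Bi-exponential PSP kernel: amplitude [mV], rise a [1/s], decay b [1/s]."""

    amplitude: float
    rise: float
    decay: float

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise ValueError(f"kernel amplitude must be positive, got {self.amplitude}")
        if not (0 < self.rise < self.decay):
            raise ValueError(
                f"kernel requires 0 < rise < decay, got rise={self.rise}, decay={self.decay}"
            )


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic potential-to-rate map: asymptote g [1/s], steepness q [1/mV], threshold Vd [mV]."""

    rate: float
    steepness: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.rate > 0):
            raise ValueError(f"sigmoid rate must be positive, got {self.rate}")
        if not (self.steepness > 0):
            raise ValueError(f"sigmoid steepness must be positive, got {self.steepness}")


@dataclass(frozen=True)
class NeuralMassParams:
    """Complete parameter set of one neural mass.

    ``sigmoid_scale`` selects the saturation convention of the firing
    functions: the effective asymptote is ``sigmoid_scale * g``.  Both the
    plain-``g`` (scale 1) and the ``2g`` (scale 2) conventions found in the
    lumped-model literature are supported; the default is 2, which places the
    calibrated control network in the regime that reproduces the reference
    direction table (see docs/methods.md).
    """

    epsp: KernelParams = KernelParams(amplitude=1.6, rise=55.0, decay=605.0)
    ipsp: KernelParams = KernelParams(amplitude=32.0, rise=27.5, decay=55.0)
    sigmoid_exc: SigmoidParams = SigmoidParams(rate=25.0, steepness=0.34, threshold=7.0)
    sigmoid_inh: SigmoidParams = SigmoidParams(rate=25.0, steepness=0.34, threshold=7.0)
    c1: float = 32.0
    c2: float = 3.0
    drive_mean: float = 550.0
    noise_level: float = 1.0
    noise_base_scale: float = 200.0
    sigmoid_scale: float = 2.0
    dt: float = 0.002
    substeps: int = 4

    def __post_init__(self) -> None:
        if not (self.c1 > 0):
            raise ValueError(f"c1 must be positive, got {self.c1}")
        if self.c2 < 0:
            raise ValueError(f"c2 must be non-negative, got {self.c2}")
        if self.drive_mean < 0:
            raise ValueError(f"drive_mean must be non-negative, got {self.drive_mean}")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.substeps < 1:
            raise ValueError(f"substeps must be >= 1, got {self.substeps}")
        if self.sigmoid_scale <= 0:
            raise ValueError(f"sigmoid_scale must be positive, got {self.sigmoid_scale}")

    @property
    def exc_max_rate(self) -> float:
        return self.sigmoid_scale * self.sigmoid_exc.rate

    @property
    def inh_max_rate(self) -> float:
        return self.sigmoid_scale * self.sigmoid_inh.rate


def default_mass_params() -> NeuralMassParams:
    """Parameter set of the healthy (control) condition."""
    return NeuralMassParams()


def sigmoid_rate(v, p: SigmoidParams, scale: float = 1.0):
    """Map membrane potential [mV] to pulse density [1/s].

    ``scale * g / (1 + exp(-q (v - Vd)))``; strictly increasing, range
    (0, scale*g).  Accepts scalars or arrays; rejects non-finite input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ModelInstabilityError("non-finite membrane potential passed to sigmoid_rate")
    out = scale * p.rate / (1.0 + np.exp(-p.steepness * (v - p.threshold)))
    return float(out) if out.ndim == 0 else out


def kernel_impulse_response(t, k: KernelParams):
    """Closed-form PSP kernel h(t) = A (e^{-a t} - e^{-b t}) for t >= 0 [mV]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel_impulse_response requires t >= 0")
    out = k.amplitude * (np.exp(-k.rise * t) - np.exp(-k.decay * t))
    return float(out) if out.ndim == 0 else out


def kernel_peak(k: KernelParams) -> tuple[float, float]:
    """Analytic argmax of the kernel: (t*, h(t*)) with t* = ln(b/a)/(b-a)."""
    t_star = math.log(k.decay / k.rise) / (k.decay - k.rise)
    return t_star, float(kernel_impulse_response(t_star, k))


class BiExpFilter:
    """Exact discrete update of one bi-exponential kernel at step h.

    Modal form: the transfer A(b-a)/((s+a)(s+b)) splits into A/(s+a) - A/(s+b).
    Each input sample x[n] is treated as an impulse of area h*x[n], so the
    sampled output equals the discrete convolution

        y[n] = h * sum_{m<n} x[m] * h_kernel((n-m) h)

    exactly.  States are kept per mass, vectorised over the last axis.
    """

    def __init__(self, k: KernelParams, h: float, n: int = 1):
        if h <= 0:
            raise ValueError("step size must be positive")
        self.decay_a = math.exp(-k.rise * h)
        self.decay_b = math.exp(-k.decay * h)
        self.gain = k.amplitude * h
        self.z1 = np.zeros(n)
        self.z2 = np.zeros(n)

    def step(self, x) -> np.ndarray:
        """Advance one step with input sample x; return the new output [mV]."""
        self.z1 = self.decay_a * (self.z1 + self.gain * x)
        self.z2 = self.decay_b * (self.z2 + self.gain * x)
        return self.z1 - self.z2

    @property
    def output(self) -> np.ndarray:
        return self.z1 - self.z2


@dataclass
class MassState:
    """State of one neural mass: four kernel filters plus derived quantities.

    Filters: external-drive EPSP and long-range EPSP into the pyramidal
    population, IPSP into the pyramidal population, EPSP into the inhibitory
    population.  ``ve``/``vi`` are the population mean membrane potentials
    [mV]; ``pulse_exc``/``pulse_inh`` the pulse densities E, I [1/s].
    """

    drive_epsp: BiExpFilter
    longrange_epsp: BiExpFilter
    ipsp: BiExpFilter
    inh_epsp: BiExpFilter
    ve: float = 0.0
    vi: float = 0.0
    pulse_exc: float = 0.0
    pulse_inh: float = 0.0

    @classmethod
    def initial(cls, p: NeuralMassParams) -> "MassState":
        """Quiescent state (all filter states zero) at the internal step size."""
        h = p.dt / p.substeps
        state = cls(
            drive_epsp=BiExpFilter(p.epsp, h),
            longrange_epsp=BiExpFilter(p.epsp, h),
            ipsp=BiExpFilter(p.ipsp, h),
            inh_epsp=BiExpFilter(p.epsp, h),
        )
        state.pulse_exc = sigmoid_rate(0.0, p.sigmoid_exc, p.sigmoid_scale)
        state.pulse_inh = sigmoid_rate(0.0, p.sigmoid_inh, p.sigmoid_scale)
        return state


def step_mass(
    state: MassState,
    p: NeuralMassParams,
    long_range_input: float = 0.0,
    drive_sample: float = 0.0,
) -> MassState:
    """Advance one sample time dt (with internal sub-stepping), in place.

    The external drive and long-range pulse densities are held constant over
    the dt interval; the local E->I and I->E feedback is refreshed every
    sub-step.  Returns the same (mutated) state for chaining.
    """
    if not (np.isfinite(long_range_input) and np.isfinite(drive_sample)):
        raise ModelInstabilityError("non-finite input to step_mass")
    for _ in range(p.substeps):
        y_drive = state.drive_epsp.step(drive_sample)
        y_lr = state.longrange_epsp.step(long_range_input)
        y_ipsp = state.ipsp.step(p.c2 * state.pulse_inh)
        y_inh = state.inh_epsp.step(p.c1 * state.pulse_exc)
        state.ve = float((y_drive + y_lr - y_ipsp)[0])
        state.vi = float(y_inh[0])
        if not (np.isfinite(state.ve) and np.isfinite(state.vi)):
            raise ModelInstabilityError(
                f"mass state diverged (ve={state.ve}, vi={state.vi}) with params {p}"
            )
        state.pulse_exc = sigmoid_rate(state.ve, p.sigmoid_exc, p.sigmoid_scale)
        state.pulse_inh = sigmoid_rate(state.vi, p.sigmoid_inh, p.sigmoid_scale)
    return state
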