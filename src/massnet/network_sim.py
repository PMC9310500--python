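"""Coupled neural-mass network: scenarios, seeded runs, batches, sweeps.

N masses are coupled over a binary symmetric connectome.  Long-range input to
mass i at step n is ``S * sum_{j: A_ij=1} E_j(n - T/dt)`` — the delayed
pyramidal pulse densities of its neighbours, scaled by the global coupling
gain S and fed through the EPSP kernel into the pyramidal population only.
Coupling, if present, is always reciprocal and excitatory.

Scenario specifications override exactly one parameter group each, modelling
candidate disease mechanisms (hyperexcitable pyramidal cells, stronger EPSPs,
stronger long-range coupling, hypoexcitable interneurons, weaker IPSPs,
weaker local inhibitory coupling) and their mirrored contrast variants.

Randomness: the drive noise stream of mass ``i`` in a run with seed ``s`` is
``numpy.random.default_rng([s, i])``, so streams are independent across
masses and identical between a network run and a single-mass run with the
same seed (decoupling equivalence at S=0), and iteration ``k`` of a batch
uses seed ``base_seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model_core import (
    BiExpFilter,
    KernelParams,
    ModelInstabilityError,
    NeuralMassParams,
    default_mass_params,
    sigmoid_rate,
)

__all__ = [
    "Connectome",
    "NetworkConfig",
    "ScenarioSpec",
    "SimulationResult",
    "SCENARIOS",
    "PARAMETER_PATHS",
    "get_scenario",
    "apply_scenario",
    "get_parameter",
    "set_parameter",
    "run_network",
    "run_single_mass",
    "run_batch",
    "sweep_parameter",
    "DEFAULT_ITERATIONS_SPECTRA",
    "DEFAULT_ITERATIONS_SPIKE_DENSITY",
]

#: batch sizes used for spectral and spike-density analyses respectively
DEFAULT_ITERATIONS_SPECTRA = 50
DEFAULT_ITERATIONS_SPIKE_DENSITY = 10


@dataclass(frozen=True)
class Connectome:
    """Binary symmetric adjacency over N regions, no self-loops."""

    adjacency: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric (coupling is always reciprocal)")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValueError("adjacency entries must be binary 0/1")
        object.__setattr__(self, "adjacency", adj)
        if self.labels and len(self.labels) != adj.shape[0]:
            raise ValueError("labels length must match number of regions")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"region_{i:02d}" for i in range(adj.shape[0]))
            )

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def density(self) -> float:
        n = self.n_regions
        return float(self.adjacency.sum() / (n * (n - 1))) if n > 1 else 0.0

    @classmethod
    def single_mass(cls) -> "Connectome":
        return cls(adjacency=np.zeros((1, 1)), labels=("mass_00",))


@dataclass(frozen=True)
class NetworkConfig:
    """Network-level configuration shared by all masses."""

    mass: NeuralMassParams = field(default_factory=default_mass_params)
    coupling: float = 1.5
    delay: float = 0.002
    duration_samples: int = 5096
    transient_samples: int = 1000
    normalize_by_degree: bool = False

    def __post_init__(self) -> None:
        if self.coupling < 0:
            raise ValueError(f"coupling S must be non-negative, got {self.coupling}")
        ratio = self.delay / self.mass.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"delay T={self.delay} must be a positive integer multiple of dt={self.mass.dt}"
            )
        if self.duration_samples <= self.transient_samples:
            raise ValueError("duration_samples must exceed transient_samples")

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.mass.dt))

    @property
    def retained_samples(self) -> int:
        return self.duration_samples - self.transient_samples


@dataclass(frozen=True)
class ScenarioSpec:
    """Named parameter override set; paths use the canonical parameter names."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    description: str = ""


# canonical parameter names -> (object, attribute) paths resolved by
# get_parameter/set_parameter on a (NeuralMassParams, NetworkConfig) pair
PARAMETER_PATHS = {
    "Vd1": ("mass", "sigmoid_exc", "threshold"),
    "Vd2": ("mass", "sigmoid_inh", "threshold"),
    "a1": ("mass", "epsp", "rise"),
    "b1": ("mass", "epsp", "decay"),
    "a2": ("mass", "ipsp", "rise"),
    "b2": ("mass", "ipsp", "decay"),
    "A1": ("mass", "epsp", "amplitude"),
    "A2": ("mass", "ipsp", "amplitude"),
    "g1": ("mass", "sigmoid_exc", "rate"),
    "g2": ("mass", "sigmoid_inh", "rate"),
    "q1": ("mass", "sigmoid_exc", "steepness"),
    "q2": ("mass", "sigmoid_inh", "steepness"),
    "C1": ("mass", "c1"),
    "C2": ("mass", "c2"),
    "P": ("mass", "drive_mean"),
    "noise": ("mass", "noise_level"),
    "S": ("coupling",),
    "T": ("delay",),
}


def _scenario(name, desc, **overrides) -> ScenarioSpec:
    return ScenarioSpec(name=name, overrides=overrides, description=desc)


#: registry of the healthy control, six disease-like scenarios, their mirrored
#: contrasts, and the alternate contrast-1B printed in a second place in the
#: source literature with different values
SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in [
        _scenario("control", "healthy condition, no overrides"),
        _scenario("1A_ad", "pyramidal hyperexcitability (lower firing threshold)", Vd1=6.0),
        _scenario("1A_contrast", "pyramidal hypoexcitability", Vd1=8.0),
        _scenario("1B_ad", "increased EPSP amplitude/duration", a1=48.0, b1=540.0),
        _scenario("1B_contrast", "decreased EPSP amplitude/duration", a1=62.0, b1=670.0),
        _scenario(
            "1B_contrast_text",
            "decreased EPSP, alternate published values",
            a1=42.0, b1=670.0,
        ),
        _scenario("1C_ad", "increased global excitatory coupling", S=2.0),
        _scenario("1C_contrast", "decreased global excitatory coupling", S=1.0),
        _scenario("2A_ad", "inhibitory hypoexcitability (higher threshold)", Vd2=8.0),
        _scenario("2A_contrast", "inhibitory hyperexcitability", Vd2=6.0),
        _scenario("2B_ad", "decreased IPSP amplitude/duration", a2=40.0, b2=70.0),
        _scenario("2B_contrast", "increased IPSP amplitude/duration", a2=17.5, b2=35.0),
        _scenario("2C_ad", "reduced inhibitory-to-excitatory coupling", C2=2.0),
        _scenario("2C_contrast", "increased inhibitory-to-excitatory coupling", C2=4.0),
    ]
}

#: the twelve perturbation scenarios, in report order
SCENARIO_ORDER = [
    "1A_ad", "1B_ad", "1C_ad", "2A_ad", "2B_ad", "2C_ad",
    "1A_contrast", "1B_contrast", "1C_contrast",
    "2A_contrast", "2B_contrast", "2C_contrast",
]


def get_scenario(name: str, variant: str | None = None) -> ScenarioSpec:
    """Look up a scenario by full name, or by group plus variant ('1A', 'ad')."""
    key = name if variant is None else f"{name}_{variant}"
    try:
        return SCENARIOS[key]
    except KeyError:
        raise KeyError(
            f"unknown scenario {key!r}; registered: {sorted(SCENARIOS)}"
        ) from None


def get_parameter(cfg: NetworkConfig, path: str) -> float:
    """Read a parameter by canonical name from a network configuration."""
    try:
        chain = PARAMETER_PATHS[path]
    except KeyError:
        raise KeyError(
            f"unknown parameter path {path!r}; known: {sorted(PARAMETER_PATHS)}"
        ) from None
    obj = cfg
    for attr in chain:
        obj = getattr(obj, attr)
    return obj


def set_parameter(cfg: NetworkConfig, path: str, value: float) -> NetworkConfig:
    """Return a new configuration with one parameter replaced (frozen-safe)."""
    chain = PARAMETER_PATHS.get(path)
    if chain is None:
        raise KeyError(
            f"unknown parameter path {path!r}; known: {sorted(PARAMETER_PATHS)}"
        )
    if len(chain) == 1:
        return replace(cfg, **{chain[0]: value})
    # nested frozen dataclasses: rebuild from the leaf outwards
    mass = cfg.mass
    if len(chain) == 2:
        mass = replace(mass, **{chain[1]: value})
    else:
        inner = replace(getattr(mass, chain[1]), **{chain[2]: value})
        mass = replace(mass, **{chain[1]: inner})
    return replace(cfg, mass=mass)


def apply_scenario(cfg: NetworkConfig, scenario: ScenarioSpec | str) -> NetworkConfig:
    """Return a configuration with the scenario's overrides applied."""
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    out = cfg
    for path, value in scenario.overrides.items():
        out = set_parameter(out, path, value)
    return out


@dataclass(frozen=True)
class SimulationResult:
    """Per-mass output series after transient removal.

    ``meg_like``: pyramidal membrane potential Ve [mV], shape (n_regions,
    samples) — the MEG-like signal.  ``pulse_density``: pyramidal pulse
    density E [1/s], same shape — the neuronal-activity readout.
    """

    meg_like: np.ndarray
    pulse_density: np.ndarray
    scenario: ScenarioSpec
    seed: int
    dt: float

    def __post_init__(self) -> None:
        if self.meg_like.shape != self.pulse_density.shape:
            raise ValueError("meg_like and pulse_density must share shape")

    @property
    def n_regions(self) -> int:
        return self.meg_like.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meg_like.shape[1]


def _drive_noise(seed: int, n_masses: int, n_steps: int, p: NeuralMassParams) -> np.ndarray:
    """Per-step drive samples, one independent stream per mass: P + noise*sigma0*xi."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    cols = [
        np.random.default_rng([int(seed), i]).standard_normal(n_steps)
        for i in range(n_masses)
    ]
    xi = np.column_stack(cols) if n_masses > 1 else cols[0][:, None]
    return p.drive_mean + p.noise_level * p.noise_base_scale * xi


def run_network(
    cfg: NetworkConfig,
    scenario: ScenarioSpec | str | None,
    connectome: Connectome,
    seed: int,
) -> SimulationResult:
    """Run one seeded simulation of the coupled network.

    Identical seeds yield bit-identical results.  Raises
    :class:`ModelInstabilityError` naming the scenario and step index if the
    state diverges.
    """
    if scenario is None:
        scenario = SCENARIOS["control"]
    elif isinstance(scenario, str):
        scenario = get_scenario(scenario)
    cfg = apply_scenario(cfg, scenario)
    p = cfg.mass
    n = connectome.n_regions
    adj = connectome.adjacency
    s_gain = cfg.coupling
    if cfg.normalize_by_degree and n > 1:
        deg = np.maximum(connectome.degrees, 1)
        adj = adj / deg[None, :]  # column-normalised: input averaged over senders
    h = p.dt / p.substeps
    f_drive = BiExpFilter(p.epsp, h, n)
    f_lr = BiExpFilter(p.epsp, h, n)
    f_ipsp = BiExpFilter(p.ipsp, h, n)
    f_inh = BiExpFilter(p.epsp, h, n)
    pulse_e = np.full(n, sigmoid_rate(0.0, p.sigmoid_exc, p.sigmoid_scale))
    pulse_i = np.full(n, sigmoid_rate(0.0, p.sigmoid_inh, p.sigmoid_scale))
    n_steps = cfg.duration_samples
    drive = _drive_noise(seed, n, n_steps, p)
    dsteps = cfg.delay_steps
    ring = np.zeros((dsteps, n))  # delayed pulse-density buffer
    q_exc, vd_exc = p.sigmoid_exc.steepness, p.sigmoid_exc.threshold
    q_inh, vd_inh = p.sigmoid_inh.steepness, p.sigmoid_inh.threshold
    gm_exc, gm_inh = p.exc_max_rate, p.inh_max_rate
    ve_out = np.empty((n_steps, n))
    e_out = np.empty((n_steps, n))
    coupled = s_gain > 0 and n > 1
    for step in range(n_steps):
        slot = step % dsteps
        lr = s_gain * (ring[slot] @ adj) if coupled else 0.0
        d = drive[step]
        for _ in range(p.substeps):
            y_drive = f_drive.step(d)
            y_lr = f_lr.step(lr)
            y_ipsp = f_ipsp.step(p.c2 * pulse_i)
            y_inh = f_inh.step(p.c1 * pulse_e)
            ve = y_drive + y_lr - y_ipsp
            vi = y_inh
            pulse_e = gm_exc / (1.0 + np.exp(-q_exc * (ve - vd_exc)))
            pulse_i = gm_inh / (1.0 + np.exp(-q_inh * (vi - vd_inh)))
        if not np.all(np.isfinite(ve)):
            raise ModelInstabilityError(
                f"network state diverged in scenario {scenario.name!r} at step {step}"
            )
        ring[slot] = pulse_e
        ve_out[step] = ve
        e_out[step] = pulse_e
    keep = slice(cfg.transient_samples, None)
    return SimulationResult(
        meg_like=ve_out[keep].T.copy(),
        pulse_density=e_out[keep].T.copy(),
        scenario=scenario,
        seed=int(seed),
        dt=p.dt,
    )


def run_single_mass(
    cfg: NetworkConfig, scenario: ScenarioSpec | str | None, seed: int
) -> SimulationResult:
    """Run one uncoupled mass (N=1; the global coupling gain is irrelevant)."""
    return run_network(cfg, scenario, Connectome.single_mass(), seed)


def run_batch(
    cfg: NetworkConfig,
    scenario: ScenarioSpec | str | None,
    connectome: Connectome | None,
    n_iterations: int = DEFAULT_ITERATIONS_SPECTRA,
    base_seed: int = 0,
) -> list[SimulationResult]:
    """Monte-Carlo batch: iteration k uses seed base_seed + k.

    ``connectome=None`` runs single-mass iterations.  Errors propagate with
    the iteration index attached.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    results = []
    for k in range(n_iterations):
        try:
            if connectome is None:
                results.append(run_single_mass(cfg, scenario, base_seed + k))
            else:
                results.append(run_network(cfg, scenario, connectome, base_seed + k))
        except ModelInstabilityError as err:
            raise ModelInstabilityError(f"iteration {k}: {err}") from err
    return results


def sweep_parameter(
    cfg: NetworkConfig,
    parameter_path: str,
    values: Sequence[float],
    n_iterations: int = DEFAULT_ITERATIONS_SPIKE_DENSITY,
    connectome: Connectome | None = None,
    base_seed: int = 0,
):
    """Stepwise parameter sweep; one summary row per grid value.

    Returns a pandas DataFrame in the order of ``values``; a grid point whose
    simulation destabilises is recorded in its row (status column) rather than
    aborting the sweep.
    """
    import pandas as pd

    from .spectral import summarize_batch

    if not np.all(np.isfinite(values)):
        raise ValueError("sweep values must be finite")
    get_parameter(cfg, parameter_path)  # validate the path up front
    rows = []
    for value in values:
        swept = set_parameter(cfg, parameter_path, float(value))
        row: dict[str, float | str] = {parameter_path: float(value)}
        try:
            batch = run_batch(swept, None, connectome, n_iterations, base_seed)
            summ = summarize_batch(batch)
            row.update({f"rel_{b}": v for b, v in summ.rel_power.items()})
            row.update(
                total_power=summ.total_power,
                peak_frequency=summ.peak_frequency,
                mean_spike_density=summ.mean_spike_density,
                status="ok",
            )
        except ModelInstabilityError as err:
            row["status"] = f"unstable: {err}"
        rows.append(row)
    return pd.DataFrame(rows)
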