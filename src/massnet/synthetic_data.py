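"""Generators for every input the pipeline needs without downloads.

Two stand-ins are provided:

* binary symmetric structural connectomes (small-world by default, matching
  the broad topology of human cortical anatomical networks) standing in for
  an undeposited DTI-derived matrix;
* surrogate two-group multichannel epoch sets whose spectra differ by a
  controlled theta-ward power shift, emulating the patient-vs-control
  contrast used to exercise the statistics path (group sizes default to
  18 + 18 to mirror a typical clinical cohort).

Each surrogate channel is a sum of band-limited noise components: a broadband
floor, a narrowband alpha component at the group's alpha peak frequency, and
a narrowband theta component.  ``theta_shift`` moves that fraction of the
alpha component's power into the theta component in group B only, leaving
total power unchanged in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.signal

from .network_sim import Connectome

__all__ = [
    "ConnectomeRecipe",
    "SurrogateGroupRecipe",
    "generate_connectome",
    "generate_surrogate_groups",
]


@dataclass(frozen=True)
class ConnectomeRecipe:
    """Recipe for a stand-in binary structural connectome.

    Defaults (78 regions, mean degree 16, rewiring 0.1) are the calibrated
    stand-in for the whole-brain network simulations; see docs/methods.md.
    """

    n_regions: int = 78
    topology: str = "small_world"
    mean_degree: int = 16
    rewiring_p: float = 0.1
    seed: int = 0
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not (0 < self.mean_degree < self.n_regions):
            raise ValueError(
                f"mean_degree {self.mean_degree} infeasible for {self.n_regions} regions"
            )
        if self.topology not in ("small_world", "random", "lattice"):
            raise ValueError(
                f"unknown topology {self.topology!r}; use small_world, random or lattice"
            )
        if not (0.0 <= self.rewiring_p <= 1.0):
            raise ValueError("rewiring_p must be in [0, 1]")


def generate_connectome(recipe: ConnectomeRecipe) -> Connectome:
    """Generate a connected, binary, symmetric, zero-diagonal connectome.

    Deterministic given the recipe seed.  Raises if no connected graph is
    found within the attempt budget.
    """
    n, k = recipe.n_regions, recipe.mean_degree
    if recipe.topology == "lattice":
        graph = nx.watts_strogatz_graph(n, k, 0.0, seed=recipe.seed)
        if not nx.is_connected(graph):
            raise RuntimeError("ring lattice disconnected; increase mean_degree")
    elif recipe.topology == "small_world":
        graph = nx.connected_watts_strogatz_graph(
            n, k, recipe.rewiring_p, tries=recipe.max_attempts, seed=recipe.seed
        )
    else:  # random graph with the same edge budget, redrawn until connected
        m = (n * k) // 2
        rng = np.random.default_rng(recipe.seed)
        for _ in range(recipe.max_attempts):
            graph = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            if nx.is_connected(graph):
                break
        else:
            raise RuntimeError(
                f"no connected random graph with n={n}, m={m} "
                f"in {recipe.max_attempts} attempts"
            )
    adjacency = nx.to_numpy_array(graph, dtype=float)
    np.fill_diagonal(adjacency, 0.0)
    return Connectome(adjacency=adjacency)


@dataclass(frozen=True)
class SurrogateGroupRecipe:
    """Recipe for two groups of per-subject multichannel epoch sets."""

    n_subjects: int = 18
    n_channels: int = 78
    n_epochs: int = 5
    epoch_samples: int = 4096
    sample_rate: float = 500.0
    alpha_peak_a: float = 10.0
    alpha_peak_b: float = 10.0
    alpha_power: float = 1.0
    theta_peak: float = 6.0
    theta_shift: float = 0.0
    noise_floor: float = 0.5
    subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_channels < 1 or self.n_epochs < 1:
            raise ValueError("need >= 2 subjects, >= 1 channel, >= 1 epoch")
        if self.epoch_samples < 256:
            raise ValueError("epochs shorter than 256 samples are degenerate")
        if not (0.0 <= self.theta_shift <= 1.0):
            raise ValueError("theta_shift must be in [0, 1]")
        if min(self.alpha_power, self.noise_floor) < 0:
            raise ValueError("component powers must be non-negative")


def _narrowband(rng, n, fs, centre, quality=25.0):
    """Unit-variance narrowband Gaussian noise peaked exactly at `centre` Hz.

    A second-order resonator (peak filter) driven by white noise; the
    quality factor sets the linewidth (~centre/quality Hz).
    """
    b, a = scipy.signal.iirpeak(centre, quality, fs=fs)
    x = scipy.signal.lfilter(b, a, rng.standard_normal(n + 512))[512:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowpass(rng, n, fs, cutoff=45.0):
    sos = scipy.signal.butter(4, cutoff / (fs / 2), btype="lowpass", output="sos")
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n + 512))[512:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_epochs(rng, recipe, alpha_peak, alpha_power, theta_power):
    """One subject: (n_epochs, epoch_samples, n_channels)."""
    gain = float(np.exp(recipe.subject_sd * rng.standard_normal()))
    out = np.empty((recipe.n_epochs, recipe.epoch_samples, recipe.n_channels))
    fs = recipe.sample_rate
    n = recipe.epoch_samples
    for e in range(recipe.n_epochs):
        for c in range(recipe.n_channels):
            x = np.sqrt(recipe.noise_floor) * _lowpass(rng, n, fs)
            if alpha_power > 0:
                x = x + np.sqrt(alpha_power) * _narrowband(rng, n, fs, alpha_peak)
            if theta_power > 0:
                x = x + np.sqrt(theta_power) * _narrowband(rng, n, fs, recipe.theta_peak)
            out[e, :, c] = gain * x
    return out


def generate_surrogate_groups(
    recipe: SurrogateGroupRecipe,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two groups of per-subject epoch stacks, deterministic given the seed.

    Group A keeps its full alpha component; group B has ``theta_shift`` of
    its alpha power moved into the theta band.  Subjects differ by a
    log-normal amplitude factor; groups differ only in the stated parameters.
    """
    rng = np.random.default_rng([recipe.seed, 0x5A])
    shift = recipe.theta_shift * recipe.alpha_power
    group_a = [
        _subject_epochs(rng, recipe, recipe.alpha_peak_a, recipe.alpha_power, 0.0)
        for _ in range(recipe.n_subjects)
    ]
    group_b = [
        _subject_epochs(rng, recipe, recipe.alpha_peak_b, recipe.alpha_power - shift, shift)
        for _ in range(recipe.n_subjects)
    ]
    return group_a, group_b
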