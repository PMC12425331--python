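"""Mean-field Ising simulation of resting-state-like brain function.

Each brain region carries a binary spin s_i ∈ {+1, −1}; the structural
connectome couples spins through the energy

    E = −λ Σ_ij A_ij s_i s_j ,

with a single global coupling strength λ.  Dynamics are Metropolis–Hastings:
per timestep a random 15% of regions have single spin flips proposed in
sequence, each accepted when ΔE ≤ 0 and with probability exp(−ΔE) otherwise.
The spin trajectory is convolved with a canonical double-gamma hemodynamic
response function to yield a BOLD-like signal, and functional connectivity
is the Pearson correlation matrix of those regional signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from numba import njit
from scipy.stats import gamma as gamma_dist

from .core import StructuralConnectome, build_operators, graph_components, DisconnectedGraphError
from .metrics import commute_time


@dataclass(frozen=True)
class IsingConfig:
    """Parameters of one Ising run.

    ``coupling`` is the dimensionless global coupling strength λ;
    ``flip_fraction`` the fraction of regions whose flips are attempted per
    timestep; ``adjacency_normalization`` rescales raw streamline counts so
    that λ lives on a comparable scale across connectomes (``max_one``
    divides by the largest off-diagonal weight).
    """

    coupling: float = 6.0
    n_steps: int = 5000
    flip_fraction: float = 0.15
    burn_in_fraction: float = 0.2
    adjacency_normalization: Literal["max_one", "mean_one", "none"] = "max_one"
    seed: int = 0
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_fraction <= 1.0):
            raise ValueError("flip_fraction must be in (0, 1]")
        if self.coupling < 0:
            raise ValueError("coupling (lambda) must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")

    def as_metadata(self) -> dict:
        return asdict(self)


@dataclass
class IsingTrajectory:
    """Spin states over time plus the per-frame energy trace."""

    spins: np.ndarray  # (T, N) of ±1
    energy_trace: np.ndarray  # (T,)
    config: IsingConfig
    adjacency: np.ndarray  # normalized adjacency actually simulated

    @property
    def n_frames(self) -> int:
        return self.spins.shape[0]


@dataclass
class BoldLikeSeries:
    """HRF-convolved continuous signals, one column per region."""

    signal: np.ndarray  # (T, N)
    sampling_interval: float
    hrf_spec: dict
    burn_in_frames: int = 0


@dataclass
class FCMatrix:
    """Pearson functional-connectivity matrix."""

    values: np.ndarray
    method: str = "pearson"
    constant_regions: list[int] = field(default_factory=list)


def normalize_adjacency(weights: np.ndarray, mode: str) -> np.ndarray:
    """Rescale streamline counts for simulation (raw counts would freeze λ≈6)."""
    a = weights.astype(float)
    if mode == "none":
        return a
    if mode == "max_one":
        m = a.max()
    elif mode == "mean_one":
        off = a[a > 0]
        m = off.mean() if off.size else 0.0
    else:
        raise ValueError(f"unknown adjacency normalization {mode!r}")
    return a / m if m > 0 else a


@njit(cache=True)
def _ising_kernel(a: np.ndarray, lam: float, n_steps: int, n_flip: int, seed: int) -> np.ndarray:
    """Sequential single-flip Metropolis over a random subset each timestep."""
    np.random.seed(seed)
    n = a.shape[0]
    s = np.empty(n, dtype=np.int8)
    for i in range(n):
        s[i] = 1 if np.random.random() < 0.5 else -1
    spins = np.empty((n_steps, n), dtype=np.int8)
    for t in range(n_steps):
        for _ in range(n_flip):
            i = np.random.randint(0, n)
            h = 0.0
            for j in range(n):
                h += a[i, j] * s[j]
            # E = −λ Σ_jk A_jk s_j s_k counts each edge twice, so flipping
            # spin i changes the energy by 4 λ s_i Σ_j A_ij s_j.
            d_e = 4.0 * lam * s[i] * h
            if d_e <= 0.0 or np.random.random() < math.exp(-d_e):
                s[i] = -s[i]
        for j in range(n):
            spins[t, j] = s[j]
    return spins


def metropolis_acceptance(delta_e: float) -> float:
    """Metropolis–Hastings acceptance probability for an energy change ΔE.

    Flips that lower (or keep) the energy are always accepted; a flip that
    destabilizes the system by ΔE is accepted with probability exp(−ΔE)
    (e.g. ΔE = 3λ → probability e^{−3λ}).
    """
    return 1.0 if delta_e <= 0 else float(math.exp(-delta_e))


def energy(spins: np.ndarray, adjacency: np.ndarray, coupling: float) -> np.ndarray:
    """Per-frame energy E_t = −λ s_tᵀ A s_t (ordered-pair sum)."""
    s = spins.astype(float)
    return -coupling * np.einsum("ti,ij,tj->t", s, adjacency, s)


def run_ising(c: StructuralConnectome, cfg: IsingConfig) -> IsingTrajectory:
    """Simulate the mean-field Ising system on a connectome.

    Spins are initialized uniformly at random; each timestep proposes flips
    for ⌈flip_fraction·N⌉ randomly chosen regions, accepted one-by-one by the
    Metropolis rule.  One frame is recorded per timestep.  Identical
    (connectome, config) gives a bit-identical trajectory.
    """
    comps = graph_components(c.weights)
    if len(comps) != 1:
        raise DisconnectedGraphError(comps)
    a = normalize_adjacency(c.weights, cfg.adjacency_normalization)
    n = c.n_regions
    n_flip = int(np.ceil(cfg.flip_fraction * n))
    seed = int(np.random.SeedSequence([int(cfg.seed), 0x15149]).generate_state(1)[0] % (2**31 - 1))
    spins = _ising_kernel(a, float(cfg.coupling), int(cfg.n_steps), n_flip, seed)
    return IsingTrajectory(
        spins=spins,
        energy_trace=energy(spins, a, cfg.coupling),
        config=cfg,
        adjacency=a,
    )


def hrf_kernel(
    sampling_interval: float = 1.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, normalized to unit sum.

    The positive lobe is a gamma density with mode at ``peak_delay`` time
    units (shape = delay + 1, unit scale), minus ``undershoot_ratio`` times a
    gamma density with mode at ``undershoot_delay``.
    """
    t = np.arange(0.0, length, sampling_interval)
    k = gamma_dist.pdf(t, peak_delay + 1.0) - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay + 1.0
    )
    return k / k.sum()


def hrf_convolve(traj: IsingTrajectory, hrf_spec: dict | None = None) -> BoldLikeSeries:
    """Convolve each region's spin series with the HRF (causal, same length)."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    spec = {
        "kernel": "double_gamma",
        "peak_delay": 6.0,
        "undershoot_delay": 16.0,
        "undershoot_ratio": 1.0 / 6.0,
        "length": 32.0,
        "sampling_interval": traj.config.sampling_interval,
    }
    if hrf_spec:
        spec.update(hrf_spec)
    k = hrf_kernel(
        sampling_interval=spec["sampling_interval"],
        peak_delay=spec["peak_delay"],
        undershoot_delay=spec["undershoot_delay"],
        undershoot_ratio=spec["undershoot_ratio"],
        length=spec["length"],
    )
    t = traj.n_frames
    if k.size > t:
        raise ValueError(f"HRF kernel ({k.size} samples) longer than the series ({t})")
    x = traj.spins.astype(float)
    out = np.empty_like(x)
    for col in range(x.shape[1]):
        out[:, col] = np.convolve(x[:, col], k)[:t]
    burn = int(np.floor(traj.config.burn_in_fraction * t))
    return BoldLikeSeries(
        signal=out,
        sampling_interval=spec["sampling_interval"],
        hrf_spec=spec,
        burn_in_frames=burn,
    )


def fc_from_series(b: BoldLikeSeries, discard_burn_in: bool = True) -> FCMatrix:
    """Pearson correlation across regional time series.

    Constant regions (zero variance over the retained frames) get NaN rows
    and columns and are reported in ``constant_regions``; the diagonal is 1.
    """
    x = b.signal[b.burn_in_frames :] if discard_burn_in else b.signal
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 retained frames, got {x.shape[0]}")
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(x, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc, constant_regions=[int(i) for i in constant])


def simulate_fc(c: StructuralConnectome, cfg: IsingConfig, discard_burn_in: bool = True) -> FCMatrix:
    """Full function-simulation pipeline: Ising → HRF → Pearson FC."""
    traj = run_ising(c, cfg)
    bold = hrf_convolve(traj)
    return fc_from_series(bold, discard_burn_in=discard_burn_in)


def lambda_sweep(
    c: StructuralConnectome,
    lambdas,
    replicates: int,
    seed: int,
    cfg: IsingConfig | None = None,
):
    """ρ(commute time, simulated FC) for every (λ, replicate) combination.

    Returns a DataFrame with columns lambda, replicate, seed, rho, p.  Each
    replicate uses an independent stream derived from the master seed.
    """
    import pandas as pd

    from .analysis import PairMask, pair_vector, spearman_correlation

    base = cfg or IsingConfig()
    ops = build_operators(c)
    ct = commute_time(ops).values
    mask = PairMask.all_pairs()
    ct_vec = pair_vector(ct, mask, hemisphere=c.hemisphere)
    rows = []
    for lam_idx, lam in enumerate(lambdas):
        for rep in range(replicates):
            child = int(
                np.random.SeedSequence([int(seed), lam_idx, rep]).generate_state(1)[0]
                % (2**31 - 1)
            )
            run_cfg = IsingConfig(
                coupling=float(lam),
                n_steps=base.n_steps,
                flip_fraction=base.flip_fraction,
                burn_in_fraction=base.burn_in_fraction,
                adjacency_normalization=base.adjacency_normalization,
                seed=child,
                sampling_interval=base.sampling_interval,
            )
            fc = simulate_fc(c, run_cfg)
            fc_vec = pair_vector(fc.values, mask, hemisphere=c.hemisphere)
            try:
                rho, p = spearman_correlation(ct_vec, fc_vec)
            except ValueError:
                # a fully ordered run has no defined correlations; keep the
                # replicate in the table as undefined rather than aborting
                rho, p = float("nan"), float("nan")
            rows.append(
                {"lambda": float(lam), "replicate": rep, "seed": child, "rho": rho, "p": p}
            )
    return pd.DataFrame(rows)
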