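"""Ground-truth gLV communities and sediment-core-like synthetic datasets.

Every pipeline stage can be exercised without external data: the module
simulates generalized Lotka-Volterra dynamics (fixed-step RK4 with optional
multiplicative log-normal environmental noise), converts sampled abundances
to sequencing-like multinomial counts, and builds a two-regime
critical-transition scenario shaped like a dated sediment core: 35
stratigraphically ordered samples spanning 1200-2010 CE, ~12 class-level
taxa dominating the community, two quasi-stationary regimes separated by an
abrupt shift in the late 1300s.

The transition mechanism is a slow environmental driver that linearly erodes
the growth rate of the regime-A dominant taxon.  Its competitor is held in
check until the invasion eigenvalue g = r_B - a_BA * N_A* crosses zero
(loss of local stability of the resident equilibrium), after which the
community reorganizes abruptly; background taxa are coupled to the two core
competitors with opposite signs so the whole composition differs between
regimes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import TaxonTable, UNCLASSIFIED

BLOWUP = 1e6
FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Parameter sampling and forward simulation


def sample_glv_params(S: int, connectance: float = 0.3, interaction_sd: float = 0.3,
                      seed: int = 0, self_limit: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Random gLV parameters: positive self-limitation, sparse signed off-diagonals.

    Off-diagonal a_ij are nonzero with probability ``connectance``; magnitudes
    are half-normal with scale ``interaction_sd`` and signs are +/- with equal
    probability.  Growth rates are uniform on [0.5, 1.5].
    """
    if S < 2:
        raise ValueError("need at least 2 taxa")
    if not 0 <= connectance <= 1:
        raise ValueError("connectance must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.5, 1.5, size=S)
    A = np.zeros((S, S))
    np.fill_diagonal(A, self_limit * rng.uniform(0.8, 1.2, size=S))
    off = ~np.eye(S, dtype=bool)
    present = rng.random((S, S)) < connectance
    signs = rng.choice([-1.0, 1.0], size=(S, S))
    mags = np.abs(rng.normal(0.0, interaction_sd, size=(S, S)))
    A[off] += (present * signs * mags)[off]
    return r, A


def simulate_glv(r, A, N0, t_grid, noise_sd: float = 0.0, seed: int | None = None,
                 r_of_t=None, floor: float = FLOOR) -> np.ndarray:
    """Integrate dN_i/dt = N_i (r_i - sum_j a_ij N_j) with fixed-step RK4.

    ``r_of_t``, if given, is a callable t -> growth-rate vector overriding
    ``r`` (a time-varying environmental driver).  ``noise_sd`` is the scale
    (per unit sqrt-time) of multiplicative log-normal environmental noise
    applied after each step.  Abundances are floored at ``floor``; any
    abundance exceeding 1e6 aborts with the blow-up time.
    """
    A = np.asarray(A, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    N = np.asarray(N0, dtype=float).copy()
    if (N <= 0).any():
        raise ValueError("initial abundances must be positive")
    rfun = r_of_t if r_of_t is not None else (lambda t: np.asarray(r, dtype=float))
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    out = np.empty((t_grid.size, N.size))
    out[0] = N
    for k in range(t_grid.size - 1):
        t, dt = t_grid[k], t_grid[k + 1] - t_grid[k]
        f = lambda tt, y: y * (rfun(tt) - A @ y)  # noqa: E731
        k1 = f(t, N)
        k2 = f(t + dt / 2, N + dt / 2 * k1)
        k3 = f(t + dt / 2, N + dt / 2 * k2)
        k4 = f(t + dt, N + dt * k3)
        N = N + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if rng is not None:
            N = N * np.exp(noise_sd * np.sqrt(dt) * rng.standard_normal(N.size))
        N = np.maximum(N, floor)
        if (N > BLOWUP).any():
            raise RuntimeError(f"simulation blew up at t = {t_grid[k + 1]:.6g}")
        out[k + 1] = N
    return out


def counts_from_abundance(rel, depth: int, seed_or_rng=0) -> np.ndarray:
    """Multinomial sequencing counts of size ``depth`` from a probability vector."""
    p = np.asarray(rel, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("relative abundances must sum to 1")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.multinomial(int(depth), p / p.sum())


# ---------------------------------------------------------------------------
# Two-regime critical-transition scenario


@dataclass
class SyntheticScenario:
    """Ground truth for a simulated sediment-core community."""
    S: int
    n_samples: int
    depth: int
    seed: int
    sample_times: np.ndarray          # calendar years of the 35 samples
    r_start: np.ndarray               # growth rates at the start of the record
    r_end: np.ndarray                 # growth rates at the end (driver-ramped)
    A: np.ndarray
    threshold_time: float | None      # invasion eigenvalue crosses zero
    transition_time: float | None     # noise-free core-pair crossover (mid-shift)
    regime_labels: np.ndarray         # 1 (regime A) / 2 (regime B) per sample
    true_abundance: np.ndarray        # noise-free skeleton at sample times
    noise_sd: float = 0.0
    taxa: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "S": self.S, "n_samples": self.n_samples, "depth": self.depth,
            "seed": self.seed, "noise_sd": self.noise_sd,
            "sample_times": self.sample_times.tolist(),
            "r_start": self.r_start.tolist(), "r_end": self.r_end.tolist(),
            "A": self.A.tolist(),
            "threshold_time": self.threshold_time,
            "transition_time": self.transition_time,
            "regime_labels": self.regime_labels.tolist(),
            "taxa": list(self.taxa),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _scenario_params(S: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core bistable pair + background taxa tilted toward either regime.

    Returns (r_start, r_end, A) in per-year units on the relative-abundance
    scale.  Taxon 0 dominates regime A; taxon 1 regime B; background taxa
    2..S-1 are split between taxa suppressed by the regime-B winner and taxa
    suppressed by the regime-A winner, so the whole composition reorganizes
    at the transition.
    """
    if S < 4:
        raise ValueError("scenario needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    A = np.zeros((S, S))
    r_start = np.zeros(S)
    r_end = np.zeros(S)
    # core competitors: carrying capacity ~0.35, strong mutual competition
    K_core = 0.35
    r_start[0], r_end[0] = 0.30, -0.30   # driver erodes the regime-A dominant
    r_start[1] = r_end[1] = 0.25
    A[0, 0] = 0.30 / K_core
    A[1, 1] = 0.25 / K_core
    A[0, 1] = 1.4 * A[0, 0]
    A[1, 0] = 1.4 * A[1, 1]
    # background taxa: strong self-limitation, opposite-sign coupling to the core
    n_bg = S - 2
    half = n_bg // 2
    for i in range(2, S):
        r_i = rng.uniform(0.2, 0.35)
        K_i = rng.uniform(0.05, 0.09)
        r_start[i] = r_end[i] = r_i
        A[i, i] = r_i / K_i
        if i - 2 < half:  # favored in regime A, suppressed by the regime-B winner
            A[i, 1] = rng.uniform(0.35, 0.7)
            A[i, 0] = -rng.uniform(0.0, 0.25)
        else:             # favored in regime B
            A[i, 0] = rng.uniform(0.35, 0.7)
            A[i, 1] = -rng.uniform(0.0, 0.25)
    # weak random couplings among background taxa
    for i in range(2, S):
        for j in range(2, S):
            if i != j and rng.random() < 0.25:
                A[i, j] = rng.choice([-1.0, 1.0]) * abs(rng.normal(0.0, 0.3))
    return r_start, r_end, A


def transition_scenario(S: int = 12, n_samples: int = 35, depth: int = 20_000,
                        seed: int = 0, noise_sd: float = 0.05,
                        year_start: float = 1200.0, year_end: float = 2010.0,
                        transition: bool = True,
                        ) -> tuple[SyntheticScenario, TaxonTable]:
    """Simulate a dated two-regime community core and emit a count table.

    The driver linearly ramps the regime-A dominant's growth rate downward
    (``transition=True``); the resident equilibrium loses stability when the
    competitor's invasion eigenvalue crosses zero and the community shifts
    abruptly to regime B.  Counts are multinomial at ``depth`` reads per
    sample over the S modeled classes plus an 'unclassified' remainder.
    """
    if n_samples < 20:
        raise ValueError("need at least 20 samples")
    r_start, r_end, A = _scenario_params(S, seed)
    if not transition:
        r_end = r_start.copy()
    span = year_end - year_start

    def r_of_t(t):
        frac = np.clip((t - year_start) / span, 0.0, 1.0)
        return r_start + frac * (r_end - r_start)

    dt = 0.25
    t_grid = np.arange(year_start, year_end + dt / 2, dt)
    N0 = np.empty(S)
    N0[0] = r_start[0] / A[0, 0]
    N0[1] = 0.01
    for i in range(2, S):
        N0[i] = 0.8 * r_start[i] / A[i, i]

    skeleton = simulate_glv(None, A, N0, t_grid, noise_sd=0.0, r_of_t=r_of_t,
                            floor=1e-6)
    noisy = simulate_glv(None, A, N0, t_grid, noise_sd=noise_sd, seed=seed,
                         r_of_t=r_of_t, floor=1e-6)

    sample_times = np.linspace(year_start, year_end, n_samples)
    idx = np.searchsorted(t_grid, sample_times - dt / 2)
    idx = np.clip(idx, 0, t_grid.size - 1)

    threshold_time = transition_time = None
    if transition:
        # invasion eigenvalue of the resident (regime A) equilibrium
        g = np.array([r_of_t(t)[1] - A[1, 0] * n for t, n in zip(t_grid, skeleton[:, 0])])
        crossed = np.flatnonzero(g > 0)
        if crossed.size == 0:
            raise RuntimeError("driver too weak: invasion eigenvalue never crosses zero")
        threshold_time = float(t_grid[crossed[0]])
        swap = np.flatnonzero(skeleton[:, 1] > skeleton[:, 0])
        if swap.size == 0:
            raise RuntimeError("scenario failed to transition (no regime crossover)")
        transition_time = float(t_grid[swap[0]])
        regime = np.where(sample_times < transition_time, 1, 2)
    else:
        regime = np.ones(n_samples, dtype=int)

    taxa = [f"Class{i + 1:02d}" for i in range(S)]
    rng = np.random.default_rng(seed + 1)
    counts = np.empty((n_samples, S + 1), dtype=np.int64)
    for k, j in enumerate(idx):
        p = np.empty(S + 1)
        p[:S] = noisy[j]
        p[S] = max(1.0 - p[:S].sum(), 0.0)
        counts[k] = counts_from_abundance(p / p.sum(), depth, rng)

    sample_ids = [f"DL{k + 1:02d}" for k in range(n_samples)]
    table = TaxonTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=taxa + [UNCLASSIFIED]),
        ages=pd.Series(sample_times, index=sample_ids),
        taxonomy=pd.Series(
            [f"k__Bacteria;p__Phylum{i % 5 + 1};c__{t}" for i, t in enumerate(taxa)]
            + [""],
            index=taxa + [UNCLASSIFIED]),
        depths=pd.Series(np.linspace(140, 0, n_samples), index=sample_ids),
    )
    scenario = SyntheticScenario(
        S=S, n_samples=n_samples, depth=depth, seed=seed,
        sample_times=sample_times, r_start=r_start, r_end=r_end, A=A,
        threshold_time=threshold_time, transition_time=transition_time,
        regime_labels=regime, true_abundance=skeleton[idx], noise_sd=noise_sd,
        taxa=taxa)
    return scenario, table


# ---------------------------------------------------------------------------
# Focused fixtures for method validation


def fold_approach_series(n_samples: int = 300, dt_sample: float = 0.5,
                         r_initial: float = 1.0, r_final: float = 0.05,
                         a: float = 1.0, noise_sd: float = 0.15,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single-taxon gLV approaching loss of stability (recovery rate -> 0).

    The growth rate ramps linearly from ``r_initial`` to ``r_final``; the
    equilibrium's eigenvalue is -r(t), so the recovery rate decays toward
    zero and the log-abundance series shows critical slowing down (rising
    variance and lag-1 autocorrelation).  Returns (times, log-abundance).
    """
    total = n_samples * dt_sample
    dt = 0.05

    def r_of_t(t):
        return np.array([r_initial + (r_final - r_initial) * min(t / total, 1.0)])

    t_grid = np.arange(0.0, total + dt / 2, dt)
    traj = simulate_glv(None, np.array([[a]]), np.array([r_initial / a]),
                        t_grid, noise_sd=noise_sd, seed=seed, r_of_t=r_of_t)
    times = (np.arange(n_samples) + 1) * dt_sample
    idx = np.clip(np.searchsorted(t_grid, times - dt / 2), 0, t_grid.size - 1)
    return times, np.log(traj[idx, 0])


def recovery_dataset(S: int = 3, n_episodes: int = 10, episode_len: int = 6,
                     noise_sd: float = 0.01, depth: int = 50_000,
                     dt_sample: float = 0.3, seed: int = 0):
    """Known (r, A) plus noisy near-equilibrium observations for fit validation.

    Draws a diagonally dominant stable interior system whose equilibrium
    abundances total < 0.9 (the remainder acts as unmodeled community) and
    observes ``n_episodes`` replicate relaxation series of ``episode_len``
    samples each (60 samples by default), every episode starting from an
    independently perturbed state within a factor ~1.7 of equilibrium.
    Replicate episodes are the standard design for interaction inference:
    each supplies an independent excitation direction, and no difference
    equation straddles a perturbation event (a between-sample state jump
    would enter the forward difference as a 1/dt outlier).  Observations are
    multinomial counts at ``depth`` reads converted back to relative
    abundance.  Returns (r, A, episodes) with one samples-x-taxa
    relative-abundance DataFrame per episode; sample times are
    ``dt_sample * arange(episode_len)`` within each episode.
    """
    rng = np.random.default_rng(seed)
    for _ in range(500):
        r = rng.uniform(0.8, 1.2, size=S)
        K = rng.uniform(0.18, 0.28, size=S)
        A = np.diag(r / K)
        off = rng.choice([-1.0, 1.0], size=(S, S)) * rng.uniform(0.2, 0.6, size=(S, S))
        A += np.where(np.eye(S, dtype=bool), 0.0, off)
        try:
            n_star = np.linalg.solve(A, r)
        except np.linalg.LinAlgError:
            continue
        if (n_star <= 0.02).any() or n_star.sum() > 0.85:
            continue
        J = -np.diag(n_star) @ A
        if np.linalg.eigvals(J).real.max() < -0.05:
            break
    else:
        raise RuntimeError("could not draw a stable feasible system")

    dt = 0.05
    taxa = [f"taxon{i + 1}" for i in range(S)]
    episodes = []
    for ep in range(n_episodes):
        N0 = n_star * rng.uniform(0.5, 1.7, size=S)
        t_grid = np.arange(0.0, episode_len * dt_sample + dt / 2, dt)
        traj = simulate_glv(r, A, N0, t_grid, noise_sd=noise_sd,
                            seed=int(rng.integers(2**31)))
        times = np.arange(episode_len) * dt_sample
        idx = np.clip(np.searchsorted(t_grid, times - dt / 2), 0, t_grid.size - 1)
        obs = np.empty((episode_len, S))
        for k, j in enumerate(idx):
            p = np.append(traj[j], max(1.0 - traj[j].sum(), 1e-6))
            obs[k] = counts_from_abundance(p / p.sum(), depth, rng)[:S] / depth
        episodes.append(pd.DataFrame(
            obs, index=[f"e{ep:02d}s{k:02d}" for k in range(episode_len)],
            columns=taxa))
    return r, A, episodes
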