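"""Umbrella-sampling bookkeeping and 1-D WHAM free-energy reconstruction.

Windows carry a harmonic bias ``0.5 * k * (z - z0)**2`` (half-k convention;
the alternative full-k convention used by some MD engines is available via
``bias_convention='full_k'``).  :func:`wham_solve` iterates the standard
self-consistent WHAM equations in log space — the unbiased bin probability
from bias-weighted histogram counts, then each window's free-energy constant
from the unbiased distribution — until the largest per-iteration change in
the window constants falls below the tolerance.  The profile is
``-k_B T ln P(z)`` shifted so that it is exactly zero at the reference z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias centre, spring constant, and samples."""

    center: float                 # z0, A
    spring_k: float               # kcal/mol/A^2
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    def retained(self, burn_in_fraction: float = 0.0) -> np.ndarray:
        """Samples after discarding the leading burn-in fraction."""
        drop = int(len(self.samples) * burn_in_fraction)
        out = self.samples[drop:]
        if len(out) == 0:
            raise ValueError(
                f"window at z={self.center}: no samples remain after burn-in"
            )
        return out


@dataclass
class PMFProfile:
    """Free energy vs axial coordinate with a reference-zero convention."""

    z: np.ndarray                 # bin centres, A
    free_energy: np.ndarray       # kcal/mol
    reference_z: float
    temperature: float
    n_iterations: int = 0
    final_residual: float = 0.0

    def value_at(self, z: float) -> float:
        if not (self.z[0] - 1e-9 <= z <= self.z[-1] + 1e-9):
            raise ValueError(f"z={z} outside profile support [{self.z[0]}, {self.z[-1]}]")
        return float(np.interp(z, self.z, self.free_energy))


def plan_windows(
    z_start: float, z_end: float, spacing: float, spring_k: float
) -> list[UmbrellaWindow]:
    """Umbrella centres from z_start toward z_end (inclusive of the start),
    stepping by ``spacing``.  The count is whatever the range holds; it is
    never inferred from an expected total."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if z_start == z_end:
        raise ValueError("zero-length window range")
    n = int(math.floor(abs(z_end - z_start) / spacing + 1e-9)) + 1
    sign = 1.0 if z_end > z_start else -1.0
    return [UmbrellaWindow(z_start + sign * i * spacing, spring_k) for i in range(n)]


def expected_frames(window_length_ns: float, record_interval_ps: float) -> int:
    """Frames recorded per window: floor(window_length / record_interval)."""
    if window_length_ns <= 0 or record_interval_ps <= 0:
        raise ValueError("window length and record interval must be positive")
    return int(math.floor(window_length_ns * 1000.0 / record_interval_ps + 1e-9))


def write_window(window: UmbrellaWindow, path: str | Path) -> None:
    """Plain-text window file: '# center=<z0> k=<k>' header, one z per line."""
    with open(path, "w") as fh:
        fh.write(f"# center={window.center} k={window.spring_k}\n")
        for z in window.samples:
            fh.write(f"{z:.8f}\n")


def load_window(path: str | Path) -> UmbrellaWindow:
    center = spring_k = None
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for kv in line.lstrip("#").split():
                    key, _, val = kv.partition("=")
                    if key == "center":
                        center = float(val)
                    elif key == "k":
                        spring_k = float(val)
                continue
            samples.append(float(line))
    if center is None or spring_k is None:
        raise ValueError(f"{path}: missing 'center=' / 'k=' header")
    return UmbrellaWindow(center, spring_k, np.asarray(samples))


def _bias_energy(window: UmbrellaWindow, z: np.ndarray, convention: str) -> np.ndarray:
    factor = 0.5 if convention == "half_k" else 1.0
    return factor * window.spring_k * (z - window.center) ** 2


def wham_solve(
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 0.1,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    reference_z: float | None = None,
    burn_in_fraction: float = 0.0,
    bias_convention: str = "half_k",
) -> PMFProfile:
    """Self-consistent WHAM over 1-D umbrella windows.

    Adjacent windows (by centre) must share at least one occupied histogram
    bin; a gap raises an error naming the offending pair.  Raises on
    non-convergence after ``max_iterations`` with the final residual.
    ``reference_z`` defaults to the position of the profile minimum.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    if bias_convention not in ("half_k", "full_k"):
        raise ValueError(f"unknown bias convention {bias_convention!r}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)
    data = [w.retained(burn_in_fraction) for w in windows]

    lo = min(d.min() for d in data)
    hi = max(d.max() for d in data)
    edges = np.arange(
        math.floor(lo / bin_width) * bin_width,
        math.ceil(hi / bin_width) * bin_width + bin_width * 0.5,
        bin_width,
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros((len(windows), len(centers)))
    for i, d in enumerate(data):
        counts[i], _ = np.histogram(d, bins=edges)
    n_j = counts.sum(axis=0)
    N_i = counts.sum(axis=1)

    # adjacent-overlap check on occupied bins
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order, order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise ValueError(
                "no histogram overlap between adjacent windows at "
                f"z={windows[a].center} and z={windows[b].center}"
            )

    occupied = n_j > 0
    log_nj = np.where(occupied, np.log(np.maximum(n_j, 1e-300)), -np.inf)
    log_Ni = np.log(N_i)
    # (n_windows, n_bins) log bias Boltzmann factors at bin centres
    log_c = np.stack([
        -beta * _bias_energy(w, centers, bias_convention) for w in windows
    ])

    beta_f = np.zeros(len(windows))
    n_iter = 0
    residual = np.inf
    for n_iter in range(1, max_iterations + 1):
        # log P_j = log n_j - logsumexp_i(log N_i + beta f_i + log c_ij)
        denom = logsumexp(log_Ni[:, None] + beta_f[:, None] + log_c, axis=0)
        log_p = log_nj - denom
        new_beta_f = -logsumexp(log_p[None, :] + log_c, axis=1)
        new_beta_f -= new_beta_f[0]
        residual = float(np.max(np.abs(new_beta_f - beta_f))) / beta
        beta_f = new_beta_f
        if residual < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(residual {residual:.3e} kcal/mol)"
        )

    z = centers[occupied]
    pmf = (-log_p[occupied] / beta)
    if reference_z is None:
        reference_z = float(z[np.argmin(pmf)])
    profile = PMFProfile(z, pmf, reference_z, temperature, n_iter, residual)
    profile.free_energy = profile.free_energy - profile.value_at(reference_z)
    return profile


def barrier_height(
    pmf: PMFProfile,
    region: tuple[float, float],
    baseline: tuple[float, float] | None = None,
) -> float:
    """Max free energy over ``region`` minus the baseline level (minimum
    over ``baseline``, or the profile's reference zero when omitted)."""
    z, g = pmf.z, pmf.free_energy
    rmask = (z >= min(region)) & (z <= max(region))
    if not rmask.any():
        raise ValueError(f"region {region} outside profile support")
    peak = float(g[rmask].max())
    if baseline is None:
        return peak
    bmask = (z >= min(baseline)) & (z <= max(baseline))
    if not bmask.any():
        raise ValueError(f"baseline {baseline} outside profile support")
    return peak - float(g[bmask].min())


def boltzmann_inversion(
    samples: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = 0.1,
) -> PMFProfile:
    """Direct -k_B T ln(histogram) of unbiased samples (the degenerate
    single-window, zero-bias limit of WHAM), zeroed at its minimum."""
    samples = np.asarray(samples, dtype=float)
    edges = np.arange(samples.min(), samples.max() + bin_width, bin_width)
    if len(edges) < 3:
        edges = np.array([samples.min() - bin_width, samples.min(), samples.min() + bin_width])
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    kT = BOLTZMANN_KCAL * temperature
    g = -kT * np.log(counts[mask] / counts.sum())
    g -= g.min()
    ref = float(centers[mask][np.argmin(g)])
    return PMFProfile(centers[mask], g, ref, temperature)
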