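"""Umbrella-sampling analysis: window placement, WHAM free-energy
reconstruction, bootstrap error bands, split-half convergence checks and
binding free-energy extraction.

The weighted histogram analysis method combines biased histograms from
harmonic umbrella windows into one unbiased free-energy profile along
the reaction coordinate (here the inter-fragment center-of-mass
distance).  With n_i samples in window i, bias U_i(x) = k_i (x - c_i)^2 / 2
and bin populations N(x_b), the self-consistent equations

    P(x_b) = N(x_b) / sum_i n_i exp[-(U_i(x_b) - f_i) / kT]
    exp(-f_i / kT) = sum_b P(x_b) exp[-U_i(x_b) / kT]

are iterated to a tolerance on the window free energies f_i.  The
profile F = -kT ln P is anchored so the unbound plateau (the
largest-distance 10% of populated bins) averages zero.  Uncertainties
come from case-resampling bootstrap over each window's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .tables import KB_KJ_PER_MOL_K

DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_TOLERANCE = 1e-7
DEFAULT_MAX_ITERATIONS = 100_000
DEFAULT_N_BOOTSTRAP = 200


class WhamConvergenceError(RuntimeError):
    """WHAM iteration failed to converge."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias center (nm), spring constant
    (kJ mol^-1 nm^-2, 0 = unbiased) and reaction-coordinate samples (nm)."""

    center: float
    spring_constant: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("window must hold at least one sample")
        if self.spring_constant < 0:
            raise ValueError("spring constant must be >= 0")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile (kJ/mol) with optional bootstrap band."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    temperature: float
    bootstrap_band: np.ndarray | None = None

    def value_at(self, x: float) -> float:
        mask = np.isfinite(self.free_energy)
        return float(np.interp(x, self.bin_centers[mask],
                               self.free_energy[mask]))


def place_windows(start: float, end: float, spacing: float) -> np.ndarray:
    """Arithmetic window centers start, start+spacing, ... <= end
    (count = floor((end-start)/spacing) + 1)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if end < start:
        raise ValueError("end must be >= start")
    n = int(np.floor((end - start) / spacing + 1e-9)) + 1
    return start + spacing * np.arange(n)


def _check_overlap(windows: Sequence[UmbrellaWindow], edges: np.ndarray
                   ) -> None:
    """Diagnose disconnected window coverage before iterating."""
    spans = sorted((w.samples.min(), w.samples.max()) for w in windows)
    gaps = []
    hi = spans[0][1]
    for lo, h in spans[1:]:
        if lo > hi:
            gaps.append((hi, lo))
        hi = max(hi, h)
    if gaps:
        detail = ", ".join(f"({a:.3f}, {b:.3f}) nm" for a, b in gaps)
        raise WhamConvergenceError(
            f"window sample ranges do not overlap; uncovered gaps: {detail}"
        )


def wham_solve(windows: Sequence[UmbrellaWindow],
               n_bins: int | None = None,
               tolerance: float = DEFAULT_TOLERANCE,
               max_iterations: int = DEFAULT_MAX_ITERATIONS,
               bin_range: tuple[float, float] | None = None,
               anchor: str = "plateau") -> FreeEnergyProfile:
    """Self-consistent WHAM solution over all windows.

    ``n_bins`` defaults to twice the window count; ``anchor='plateau'``
    zeroes the mean over the largest-distance 10% of populated bins,
    ``'min'`` zeroes the minimum.  Deterministic for fixed inputs.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows given")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows disagree on temperature: {sorted(temps)}")
    kt = KB_KJ_PER_MOL_K * windows[0].temperature
    if n_bins is None:
        n_bins = max(2 * len(windows), 20)

    all_x = np.concatenate([w.samples for w in windows])
    lo, hi = bin_range if bin_range is not None else (all_x.min(), all_x.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    _check_overlap(windows, edges)

    counts = np.zeros(n_bins)
    n_i = np.array([w.samples.size for w in windows], dtype=float)
    for w in windows:
        c, _ = np.histogram(w.samples, bins=edges)
        counts += c

    # bias energy of every window at every bin center, in kT
    u = np.array([w.bias(centers) for w in windows]) / kt  # (n_win, n_bins)
    expu = np.exp(-u)
    f = np.zeros(len(windows))  # window free energies, kT units
    occupied = counts > 0
    for _ in range(max_iterations):
        denom = (n_i[:, None] * np.exp(f)[:, None] * expu).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, counts / denom, 0.0)
        z = expu @ p  # partition function of each biased window
        f_new = -np.log(z)
        f_new -= f_new[0]
        if np.max(np.abs((f_new - f) * kt)) < tolerance:
            f = f_new
            break
        f = f_new
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(tolerance {tolerance} kJ/mol)"
        )

    denom = (n_i[:, None] * np.exp(f)[:, None] * expu).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(occupied, counts / denom, np.nan)
        free = -kt * np.log(p)
    free = _anchor(free, centers, counts, anchor)
    return FreeEnergyProfile(bin_centers=centers, free_energy=free,
                             counts=counts,
                             temperature=windows[0].temperature)


def _anchor(free: np.ndarray, centers: np.ndarray, counts: np.ndarray,
            mode: str) -> np.ndarray:
    ok = np.isfinite(free)
    if not np.any(ok):
        return free
    if mode == "min":
        return free - np.nanmin(free)
    if mode == "plateau":
        pop = np.flatnonzero(ok)
        n_tail = max(1, int(round(0.1 * pop.size)))
        tail = pop[np.argsort(centers[pop])][-n_tail:]
        return free - np.nanmean(free[tail])
    raise ValueError(f"unknown anchor mode {mode!r}")


def bootstrap_profile(windows: Sequence[UmbrellaWindow],
                      n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
                      seed: int = 0,
                      **wham_kwargs) -> FreeEnergyProfile:
    """WHAM profile with a per-bin bootstrap error band.

    Each replicate resamples every window's samples with replacement
    (per-window case resampling) and re-solves WHAM on the original bin
    grid; the band is the per-bin standard deviation over replicates.
    """
    if n_bootstrap < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    windows = list(windows)
    for w in windows:
        if w.samples.size < 2:
            raise ValueError("bootstrap needs >= 2 samples per window")
    base = wham_solve(windows, **wham_kwargs)
    all_x = np.concatenate([w.samples for w in windows])
    wham_kwargs = dict(wham_kwargs)
    wham_kwargs.setdefault("bin_range", (all_x.min(), all_x.max()))
    wham_kwargs.setdefault("n_bins", base.bin_centers.size)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_bootstrap, base.bin_centers.size))
    for b in range(n_bootstrap):
        resampled = [
            UmbrellaWindow(w.center, w.spring_constant,
                           rng.choice(w.samples, size=w.samples.size,
                                      replace=True),
                           temperature=w.temperature)
            for w in windows
        ]
        reps[b] = wham_solve(resampled, **wham_kwargs).free_energy
    with np.errstate(invalid="ignore"):
        band = np.nanstd(reps, axis=0)
    return FreeEnergyProfile(bin_centers=base.bin_centers,
                             free_energy=base.free_energy,
                             counts=base.counts,
                             temperature=base.temperature,
                             bootstrap_band=band)


def binding_delta_g(profile: FreeEnergyProfile,
                    bound_region: tuple[float, float],
                    unbound_region: tuple[float, float]) -> float:
    """Binding free energy: mean profile over the unbound plateau minus
    the minimum over the bound region (kJ/mol).  The difference of two
    such values across profiles is the mutant-vs-native ddG."""
    def bins_in(region):
        lo, hi = region
        mask = ((profile.bin_centers >= lo) & (profile.bin_centers <= hi)
                & np.isfinite(profile.free_energy))
        if not np.any(mask):
            raise ValueError(f"no populated bins in region {region}")
        return profile.free_energy[mask]
    return float(bins_in(unbound_region).mean() - bins_in(bound_region).min())


def split_half_convergence(windows: Sequence[UmbrellaWindow],
                           **wham_kwargs
                           ) -> tuple[FreeEnergyProfile, FreeEnergyProfile, float]:
    """Profiles from the first and second halves of every window's
    samples plus their maximum absolute discrepancy over common bins —
    the convergence check that motivates analyzing only the second half
    of each umbrella trajectory."""
    windows = list(windows)
    for w in windows:
        if w.samples.size < 2:
            raise ValueError("split-half needs >= 2 samples per window")
    all_x = np.concatenate([w.samples for w in windows])
    wham_kwargs = dict(wham_kwargs)
    wham_kwargs.setdefault("bin_range", (all_x.min(), all_x.max()))

    def half(sel) -> list[UmbrellaWindow]:
        return [UmbrellaWindow(w.center, w.spring_constant,
                               sel(w.samples), temperature=w.temperature)
                for w in windows]

    first = wham_solve(half(lambda s: s[:s.size // 2]), **wham_kwargs)
    second = wham_solve(half(lambda s: s[s.size // 2:]), **wham_kwargs)
    both = np.isfinite(first.free_energy) & np.isfinite(second.free_energy)
    disc = float(np.max(np.abs(first.free_energy[both]
                               - second.free_energy[both])))
    return first, second, disc


# --- window-file dialect --------------------------------------------------------
# Two-column text (time ps, coordinate nm); header line:
#   # umbrella center=<nm> k=<kJ/mol/nm^2> temperature=<K>


def write_window_file(window: UmbrellaWindow, path: str | Path,
                      times: np.ndarray | None = None) -> None:
    t = (np.asarray(times, dtype=float) if times is not None
         else np.arange(window.samples.size, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"# umbrella center={window.center:.6g} "
                 f"k={window.spring_constant:.6g} "
                 f"temperature={window.temperature:.6g}\n")
        for ti, xi in zip(t, window.samples):
            fh.write(f"{ti:.4f} {xi:.8f}\n")


def read_window_file(path: str | Path) -> UmbrellaWindow:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# umbrella"):
        raise ValueError(f"{path}: missing umbrella header line")
    meta = dict(tok.split("=") for tok in lines[0].split()[2:])
    data = np.loadtxt(lines[1:], ndmin=2)
    return UmbrellaWindow(center=float(meta["center"]),
                          spring_constant=float(meta["k"]),
                          samples=data[:, 1],
                          temperature=float(meta.get("temperature",
                                                     DEFAULT_TEMPERATURE_K)))


def com_distance_series(traj, set_a: np.ndarray, set_b: np.ndarray,
                        masses: np.ndarray | None = None) -> np.ndarray:
    """Reaction-coordinate extractor: per-frame center-of-mass distance
    (nm) between two particle groups of a trajectory."""
    set_a = np.asarray(set_a, int)
    set_b = np.asarray(set_b, int)
    if masses is None:
        wa = np.ones(set_a.size)
        wb = np.ones(set_b.size)
    else:
        wa = np.asarray(masses, float)[set_a]
        wb = np.asarray(masses, float)[set_b]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        ca = (traj.frames[i][set_a] * wa[:, None]).sum(0) / wa.sum()
        cb = (traj.frames[i][set_b] * wb[:, None]).sum(0) / wb.sum()
        out[i] = np.linalg.norm(cb - ca)
    return out
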