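"""Umbrella-sampling bookkeeping and WHAM free-energy reconstruction.

Windows carry samples of a scalar reaction coordinate x (nm) collected
under harmonic biases w_i(x) = ½k_i(x−c_i)² (k in kJ/mol/nm²).  The
weighted histogram analysis method (WHAM) combines the biased histograms
into one unbiased distribution by iterating the self-consistent equations

    ρ(x_j) = Σ_i h_ij / Σ_i N_i exp(β(f_i − w_i(x_j)))
    exp(−β f_i) = Σ_j ρ(x_j) exp(−β w_i(x_j)) Δx

until the window free-energy constants f_i stop changing.  The potential
of mean force is −kT ln ρ, shifted so its minimum is zero.  Per-bin errors
come from bootstrap resampling of each window's samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kt_kj_per_mol
from .exceptions import ConvergenceError, DomainMotionError

__all__ = [
    "UmbrellaWindow",
    "PmfProfile",
    "make_windows",
    "wham",
    "bootstrap_errors",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: harmonic bias center/spring and its samples.

    ``center`` and ``samples`` in nm, ``spring_constant`` in kJ/mol/nm²
    (zero means an unbiased window).  The first ``discard`` samples are
    excluded as equilibration.
    """

    center: float
    spring_constant: float
    samples: np.ndarray
    discard: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")
        if len(self.retained) < 1:
            raise ValueError("window retains no samples after discard")

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.discard :]

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_constant * (np.asarray(x) - self.center) ** 2


@dataclass(frozen=True)
class PmfProfile:
    """Reconstructed free-energy profile, minimum shifted to zero.

    ``free_energy`` is kJ/mol over ``bin_centers`` (nm); bins never visited
    by any window hold NaN and are flagged in ``empty``.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    bootstrap_error: np.ndarray | None
    temperature: float
    n_bootstrap: int = 0
    empty: np.ndarray | None = None

    def to_tsv(self, path) -> None:
        errs = (
            self.bootstrap_error
            if self.bootstrap_error is not None
            else np.zeros_like(self.free_energy)
        )
        with open(path, "w") as fh:
            fh.write("coord_nm\tpmf_kJmol\terr_kJmol\n")
            for x, g, e in zip(self.bin_centers, self.free_energy, errs):
                g_str = "NA" if np.isnan(g) else f"{g:.6f}"
                e_str = "NA" if np.isnan(e) else f"{e:.6f}"
                fh.write(f"{x:.6f}\t{g_str}\t{e_str}\n")


def make_windows(reference_series, n_windows: int = 51) -> np.ndarray:
    """Equally spaced window centers spanning a reference series.

    Centers run from the series minimum to its maximum inclusive;
    ``n_windows=1`` degenerates to a single center at the midpoint.
    """
    values = np.asarray(getattr(reference_series, "values", reference_series), float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("reference series spans zero range")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n_windows == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n_windows)


def _default_bin_edges(
    windows: list[UmbrellaWindow], temperature: float, n_bins: int
) -> np.ndarray:
    kt = kt_kj_per_mol(temperature)
    lows, highs = [], []
    for w in windows:
        if w.spring_constant > 0:
            sigma = np.sqrt(kt / w.spring_constant)
            lows.append(w.center - 3 * sigma)
            highs.append(w.center + 3 * sigma)
        else:
            lows.append(w.retained.min())
            highs.append(w.retained.max())
    return np.linspace(min(lows), max(highs), n_bins + 1)


def _check_window_overlap(windows: list[UmbrellaWindow]) -> None:
    """Require the window-support overlap graph to be connected."""
    intervals = [(w.retained.min(), w.retained.max()) for w in windows]
    order = np.argsort([iv[0] for iv in intervals])
    reach = intervals[order[0]][1]
    for k in order[1:]:
        lo, hi = intervals[k]
        if lo > reach:
            raise DomainMotionError(
                "umbrella windows do not overlap along the coordinate; the "
                "profile would be disconnected (gap before window at "
                f"[{lo:.4f}, {hi:.4f}] nm)"
            )
        reach = max(reach, hi)


def _wham_core(
    histograms: np.ndarray,  # (W, B) counts
    n_samples: np.ndarray,  # (W,)
    log_bias: np.ndarray,  # (W, B): −β w_i(x_j)
    bin_width: float,
    kt: float,
    tolerance: float,
    max_iterations: int,
    beta_f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the WHAM equations; returns (log ρ per bin, β f per window)."""
    n_windows, n_bins = histograms.shape
    beta_f = (
        np.zeros(n_windows) if beta_f_init is None else beta_f_init.copy()
    )
    total_counts = histograms.sum(axis=0)
    occupied = total_counts > 0
    log_counts = np.where(occupied, np.log(np.where(occupied, total_counts, 1.0)), -np.inf)
    log_n = np.log(n_samples)
    for _ in range(max_iterations):
        # log ρ_j = log Σ_i h_ij − logsumexp_i(log N_i + β f_i − β w_ij)
        log_denominator = logsumexp(
            log_n[:, None] + beta_f[:, None] + log_bias, axis=0
        )
        log_rho = log_counts - log_denominator
        # exp(−β f_i) = Σ_j ρ_j exp(−β w_ij) Δx
        with np.errstate(invalid="ignore"):
            new_beta_f = -logsumexp(
                log_rho[None, :] + log_bias + np.log(bin_width), axis=1
            )
        new_beta_f -= new_beta_f[0]
        change = kt * np.max(np.abs(new_beta_f - beta_f))
        beta_f = new_beta_f
        if change < tolerance:
            return log_rho, beta_f
    raise ConvergenceError(
        f"WHAM did not converge in {max_iterations} iterations "
        f"(residual {change:.3e} kJ/mol > tolerance {tolerance:g})"
    )


def wham(
    windows: list[UmbrellaWindow],
    temperature: float = 300.0,
    n_bins: int = 100,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    bin_edges: np.ndarray | None = None,
    _beta_f_init: np.ndarray | None = None,
) -> PmfProfile:
    """Reconstruct the PMF from umbrella windows by self-consistent WHAM.

    Default binning: ``n_bins`` bins over the window-center span ± 3 bias
    standard deviations (sample span for unbiased windows).  Samples
    falling outside the binned range are dropped.  Convergence is on the
    maximum change of the window free-energy constants, in kJ/mol.
    """
    if not windows:
        raise ValueError("no umbrella windows given")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    _check_window_overlap(windows)
    kt = kt_kj_per_mol(temperature)
    beta = 1.0 / kt
    if bin_edges is None:
        bin_edges = _default_bin_edges(windows, temperature, n_bins)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    width = float(bin_edges[1] - bin_edges[0])

    histograms = np.stack(
        [np.histogram(w.retained, bins=bin_edges)[0] for w in windows]
    ).astype(float)
    n_samples = histograms.sum(axis=1)
    if np.any(n_samples == 0):
        raise DomainMotionError(
            "a window contributes no samples inside the binned range; "
            "widen the bins or check the window"
        )
    log_bias = np.stack([-beta * w.bias_energy(centers) for w in windows])

    log_rho, _ = _wham_core(
        histograms, n_samples, log_bias, width, kt,
        tolerance, max_iterations, _beta_f_init,
    )
    empty = ~np.isfinite(log_rho)
    free_energy = np.where(empty, np.nan, -kt * log_rho)
    free_energy = free_energy - np.nanmin(free_energy)
    return PmfProfile(
        bin_centers=centers,
        free_energy=free_energy,
        bootstrap_error=None,
        temperature=temperature,
        empty=empty,
    )


def bootstrap_errors(
    windows: list[UmbrellaWindow],
    n_bootstrap: int = 300,
    seed: int = 0,
    temperature: float = 300.0,
    n_bins: int = 100,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    bin_edges: np.ndarray | None = None,
) -> PmfProfile:
    """PMF with per-bin bootstrap errors.

    Each replicate resamples every window's retained samples with
    replacement (within-window bootstrap), reruns WHAM on the same bins,
    aligns the replicate minimum to zero, and the per-bin standard
    deviation across replicates is reported.  A single replicate is
    degenerate and yields zero errors (flagged by ``n_bootstrap``).
    """
    if bin_edges is None:
        bin_edges = _default_bin_edges(windows, temperature, n_bins)
    point = wham(
        windows, temperature, n_bins, tolerance, max_iterations, bin_edges
    )
    if n_bootstrap < 2:
        warnings.warn("n_bootstrap < 2 is degenerate; errors reported as zero")
        errors = np.zeros_like(point.free_energy)
        return PmfProfile(
            point.bin_centers, point.free_energy, errors,
            temperature, n_bootstrap, point.empty,
        )
    rng = np.random.default_rng(seed)
    replicates = np.empty((n_bootstrap, len(point.bin_centers)))
    beta_f_init = None
    for r in range(n_bootstrap):
        resampled = []
        for w in windows:
            retained = w.retained
            draw = retained[rng.integers(0, len(retained), size=len(retained))]
            resampled.append(
                UmbrellaWindow(w.center, w.spring_constant, draw, discard=0)
            )
        profile = wham(
            resampled, temperature, n_bins, tolerance, max_iterations, bin_edges
        )
        replicates[r] = profile.free_energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        errors = np.nanstd(replicates, axis=0, ddof=1)
    return PmfProfile(
        point.bin_centers, point.free_energy, errors,
        temperature, n_bootstrap, point.empty,
    )


def read_window_metadata(meta_path, discard: int = 0) -> list[UmbrellaWindow]:
    """Read windows from a metadata file.

    One line per window: ``samples_file center_nm spring_kJ_mol_nm2``;
    sample files hold one coordinate value per line (a leading time column,
    if present, is detected by column count and skipped).
    """
    from pathlib import Path

    meta_path = Path(meta_path)
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise DomainMotionError(
                f"{meta_path}: expected 'samples_file center spring', got {line!r}"
            )
        sample_file = meta_path.parent / fields[0]
        data = np.loadtxt(sample_file)
        samples = data[:, -1] if data.ndim == 2 else data
        windows.append(
            UmbrellaWindow(float(fields[1]), float(fields[2]), samples, discard)
        )
    if not windows:
        raise DomainMotionError(f"{meta_path}: no windows")
    return windows
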