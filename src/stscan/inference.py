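"""Conditional Monte-Carlo significance testing for scan results.

Under the discrete Poisson null, conditioning on the grand total N makes
the cell counts a single multinomial draw with probabilities mu(cell)/N.
Each replicate redistributes the N cases over all space-time cells, rescans
the identical cylinder set, and records the maximum LLR.  The rank of the
observed statistic among the replicate maxima gives the Monte-Carlo
p-value p = rank/(R+1); with R = 999 the attainable p-values are
0.001, 0.002, ..., 1.000.

Every reported cluster (most-likely and secondary alike) is referenced
against the same replicate-maximum distribution, which is the standard,
conservative-for-secondaries convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

from .core import (
    ClusterResult,
    ExpectedSurface,
    ScanParams,
    Zone,
    _llr_vec,
    build_zones,
    expected_counts,
    scan,
)
from .io import DataError, Dataset

__all__ = [
    "NullReplicateSummary",
    "simulate_null_replicate",
    "null_replicate_maxima",
    "monte_carlo_p",
    "attach_pvalues",
    "ScanAnalysis",
    "analyze",
]

# replicate batches are sized so a batch of cell counts stays ~tens of MB
_MAX_BATCH_CELLS = 40_000_000


@dataclass(frozen=True)
class NullReplicateSummary:
    replicate_index: int
    max_llr: float


@numba.njit(cache=True)
def _max_window_counts(P: np.ndarray, max_len: int) -> np.ndarray:
    """Per window length L = 1..max_len, the maximum windowed count over all
    start positions, for every replicate.  ``P`` is the (B, n_units + 1)
    prefix-sum matrix; returns shape (max_len, B)."""
    B, n1 = P.shape
    n = n1 - 1
    out = np.zeros((max_len, B), dtype=np.int64)
    for b in range(B):
        for L in range(1, max_len + 1):
            m = 0
            for s in range(n - L + 1):
                v = P[b, s + L] - P[b, s]
                if v > m:
                    m = v
            out[L - 1, b] = m
    return out


def _batch_max_llr(
    counts: np.ndarray,
    zones: Sequence[Zone],
    pop_fracs: np.ndarray,
    N: int,
    max_len: int,
    prospective: bool,
    day_prefix: np.ndarray,
    total_days: float,
) -> np.ndarray:
    """Maximum LLR over all cylinders for a batch of count matrices.

    ``counts`` has shape (B, n_locations, n_units); returns shape (B,).
    """
    B, _, n_units = counts.shape
    best = np.zeros(B)
    max_len = min(max_len, n_units)
    # With equal-length time units E depends only on the window length, and
    # the LLR is increasing in O for fixed E, so per (zone, length) only the
    # maximum windowed count matters.
    day_len = np.diff(day_prefix)
    uniform_units = bool(day_len.size) and float(day_len.min()) == float(day_len.max())
    for z, frac in zip(zones, pop_fracs):
        if frac <= 0:
            continue
        series = counts[:, list(z.member_indices), :].sum(axis=1)
        P = np.concatenate(
            [np.zeros((B, 1), dtype=np.int64), np.cumsum(series, axis=1)], axis=1
        )
        if prospective:
            for length in range(1, max_len + 1):
                O = P[:, n_units] - P[:, n_units - length]
                interval_days = day_prefix[n_units] - day_prefix[n_units - length]
                E = N * frac * interval_days / total_days
                np.maximum(best, _llr_vec(O, E, N), out=best)
        elif uniform_units:
            M = _max_window_counts(P, max_len)  # (max_len, B)
            lengths = np.arange(1, max_len + 1, dtype=float)
            E = (N * frac * day_len[0] / total_days) * lengths
            llr = _llr_vec(M, E[:, None], N)
            np.maximum(best, llr.max(axis=0), out=best)
        else:
            for length in range(1, max_len + 1):
                O = P[:, length:] - P[:, :-length]
                interval_days = day_prefix[length:] - day_prefix[:-length]
                E = N * frac * interval_days / total_days
                np.maximum(best, _llr_vec(O, E, N).max(axis=1), out=best)
    return best


def null_replicate_maxima(
    surface: ExpectedSurface,
    params: ScanParams,
    n_replications: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Replicate maxima of the scan statistic under the conditional null.

    Each replicate draws its counts from a dedicated RNG stream spawned
    from the master seed, so results do not depend on batching.  In
    prospective mode only cells inside the live temporal window can enter
    a cylinder; cells outside it are pooled into a single remainder cell
    before the multinomial draw, which leaves the law of the statistic
    unchanged while shrinking the draw dimension.
    """
    R = params.n_replications if n_replications is None else n_replications
    master = params.seed if seed is None else seed
    N = surface.N
    if R == 0:
        return np.zeros(0)
    zones = build_zones(surface.locations, params.max_pop_fraction, params.distance_metric)
    pop_fracs = np.array([z.pop_fraction for z in zones])
    n_loc, n_units = surface.mu.shape
    day_len = surface.period.unit_days().astype(float)
    prospective = params.mode == "prospective"
    max_len = min(params.max_units, n_units)

    if prospective:
        window = surface.mu[:, n_units - max_len :]
        probs = np.concatenate([window.ravel(), [max(0.0, N - window.sum())]])
        kept_units = max_len
    else:
        probs = surface.mu.ravel()
        kept_units = n_units
    if N > 0:
        probs = probs / probs.sum()
    day_prefix = np.concatenate([[0.0], np.cumsum(day_len)])
    total_days = day_prefix[-1]
    if prospective:
        # prefix of interval days measured from the end of the period
        day_prefix = day_prefix[n_units - max_len :] - day_prefix[n_units - max_len]
        total_days = float(surface.period.unit_days().sum())

    streams = np.random.SeedSequence(master).spawn(R)
    maxima = np.zeros(R)
    if N == 0:
        return maxima
    batch_size = max(1, _MAX_BATCH_CELLS // max(1, n_loc * kept_units))
    for lo in range(0, R, batch_size):
        hi = min(R, lo + batch_size)
        draws = np.empty((hi - lo, probs.size), dtype=np.int64)
        for b, idx in enumerate(range(lo, hi)):
            draws[b] = np.random.default_rng(streams[idx]).multinomial(N, probs)
        if prospective:
            cells = draws[:, :-1].reshape(hi - lo, n_loc, kept_units)
        else:
            cells = draws.reshape(hi - lo, n_loc, kept_units)
        maxima[lo:hi] = _batch_max_llr(
            cells, zones, pop_fracs, N, max_len, prospective, day_prefix, total_days
        )
    return maxima


def simulate_null_replicate(
    surface: ExpectedSurface, params: ScanParams, seed: int
) -> float:
    """Maximum LLR over all cylinders for one conditional-null replicate."""
    return float(null_replicate_maxima(surface, params, n_replications=1, seed=seed)[0])


def monte_carlo_p(observed_max_llr: float, replicate_maxima: Sequence[float], R: int) -> float:
    """Rank p-value: p = (1 + #{replicate max >= observed}) / (R + 1)."""
    maxima = np.asarray(replicate_maxima, dtype=float)
    if maxima.shape[0] != R:
        raise DataError(f"expected {R} replicate maxima, got {maxima.shape[0]}")
    if R == 0:
        raise DataError("p-value undefined with zero replications")
    rank = 1 + int((maxima >= observed_max_llr).sum())
    return rank / (R + 1)


def attach_pvalues(
    results: list[ClusterResult],
    replicate_maxima: Sequence[float],
    alpha: float = 0.05,
) -> list[ClusterResult]:
    """Attach p-values (against the replicate-maximum distribution) and
    significance flags in place; returns the same list for convenience."""
    maxima = np.asarray(replicate_maxima, dtype=float)
    R = maxima.shape[0]
    for res in results:
        res.p_value = monte_carlo_p(res.llr, maxima, R)
        res.significant = res.p_value < alpha
    return results


@dataclass
class ScanAnalysis:
    """A complete scan + significance analysis."""

    results: list[ClusterResult]
    replicate_maxima: np.ndarray
    params: ScanParams
    N: int

    @property
    def most_likely(self) -> ClusterResult | None:
        return self.results[0] if self.results else None

    @property
    def min_p(self) -> float | None:
        return self.results[0].p_value if self.results else None


def analyze(dataset: Dataset, params: ScanParams) -> ScanAnalysis:
    """Scan the dataset and significance-test the reported clusters.

    Monte-Carlo replication is skipped when no cluster is reported (there
    is nothing to test) or when ``n_replications`` is zero.
    """
    results = scan(dataset, params)
    if results and params.n_replications > 0:
        surface = expected_counts(dataset.locations, dataset.period, dataset.N)
        maxima = null_replicate_maxima(surface, params)
        attach_pvalues(results, maxima, params.alpha)
    else:
        maxima = np.zeros(0)
    return ScanAnalysis(results=results, replicate_maxima=maxima, params=params, N=dataset.N)
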