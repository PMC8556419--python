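"""Population-level summaries of decoded introgressed segments.

A population's introgression landscape is reduced to a piecewise-constant
local frequency track p(x) (fraction of the population's haplotypes
covered at each position).  On top of the tracks:

* coverage: total length with p above a frequency floor (default 0.02);
* ancestry-sharing ratio S_ij between two populations,

      S_ij = sum_k p_ik p_jk L_k / (P_i P_j L),

  the observed co-localization of introgression relative to random
  sharing given each population's genome-wide proportion P;
* introgression deserts: 100-kb bins whose introgression-covered length
  falls below the lower tail of the empirical bin distribution, merged
  into runs and classified by length;
* introgression diversity: expected union length of segments carried by
  random subsamples of haplotypes, as a function of subsample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import intervals as iv
from .iohub import Segment


@dataclass
class FrequencyTrack:
    """Piecewise-constant local introgression frequency on [0, L)."""

    breaks: np.ndarray    # length n+1, increasing, spanning [0, L]
    p: np.ndarray         # length n, values in [0, 1]
    n_haplotypes: int

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.breaks) != len(self.p) + 1:
            raise ValueError("breaks must have one more entry than p")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.breaks)

    @property
    def total_length(self) -> int:
        return int(self.breaks[-1] - self.breaks[0])

    @property
    def genome_proportion(self) -> float:
        """P_i: length-weighted mean local frequency."""
        return float(np.sum(self.p * self.lengths) / self.total_length)


def local_frequency(segments: list[Segment], haplotypes: list[str],
                    genome_length: int) -> FrequencyTrack:
    """Coverage-count sweep over the population's haplotypes."""
    n_hap = len(haplotypes)
    if n_hap == 0:
        raise ValueError("empty haplotype set")
    hap_set = set(haplotypes)
    events: list[tuple[int, int]] = []
    for s in segments:
        if s.haplotype in hap_set:
            events.append((min(s.start, genome_length), 1))
            events.append((min(s.end, genome_length), -1))
    breaks = np.unique(np.concatenate(
        [[0, genome_length], [e[0] for e in events]]).astype(np.int64))
    delta_arr = np.zeros(len(breaks))
    for pos, delta in events:
        delta_arr[np.searchsorted(breaks, pos)] += delta
    counts = np.cumsum(delta_arr)[:-1]
    return FrequencyTrack(breaks, counts / n_hap, n_hap)


def coverage_length(track: FrequencyTrack, threshold: float = 0.02) -> int:
    """Total bp with local frequency strictly above the threshold."""
    return int(np.sum(track.lengths[track.p > threshold]))


def _refine(a: FrequencyTrack, b: FrequencyTrack
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if a.breaks[0] != b.breaks[0] or a.breaks[-1] != b.breaks[-1]:
        raise ValueError("tracks must span the same interval")
    breaks = np.union1d(a.breaks, b.breaks)
    mids = (breaks[:-1] + breaks[1:]) / 2.0
    pa = a.p[np.searchsorted(a.breaks, mids, side="right") - 1]
    pb = b.p[np.searchsorted(b.breaks, mids, side="right") - 1]
    return breaks, pa, pb


def sharing_ratio(track_i: FrequencyTrack, track_j: FrequencyTrack) -> float:
    """Ancestry-sharing ratio S_ij; NaN when either genome-wide
    proportion is zero (undefined)."""
    breaks, pi, pj = _refine(track_i, track_j)
    L_k = np.diff(breaks)
    L = float(breaks[-1] - breaks[0])
    P_i = float(np.sum(pi * L_k) / L)
    P_j = float(np.sum(pj * L_k) / L)
    if P_i == 0.0 or P_j == 0.0:
        return float("nan")
    return float(np.sum(pi * pj * L_k) / (P_i * P_j * L))


@dataclass
class DesertCall:
    start: int
    end: int
    n_bins: int
    max_bin_coverage: float
    empirical_p: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        if self.length > 10_000_000:
            return ">10Mb"
        if self.length > 5_000_000:
            return ">5Mb"
        return "regular"


def find_deserts(tracks: list[FrequencyTrack], bin_size: int = 100_000,
                 alpha: float = 0.05, threshold: float = 0.02
                 ) -> list[DesertCall]:
    """Two-tailed empirical scan for introgression deserts.

    Per 100-kb bin, the introgression-covered length is the union over
    populations of regions with local frequency above the floor.  Bins
    below the lower alpha/2 empirical quantile are merged into deserts.
    """
    if not tracks:
        raise ValueError("no tracks given")
    L = tracks[0].total_length
    if L < bin_size:
        raise ValueError("genome shorter than one bin")
    covered: list[tuple[np.ndarray, np.ndarray]] = []
    for tr in tracks:
        keep = tr.p > threshold
        covered.append((tr.breaks[:-1][keep], tr.breaks[1:][keep]))
    starts = np.concatenate([c[0] for c in covered])
    ends = np.concatenate([c[1] for c in covered])
    u_s, u_e = iv.merge(starts, ends)
    n_bins = L // bin_size
    edges = np.arange(n_bins + 1) * bin_size
    bin_cov = np.zeros(n_bins)
    for s, e in zip(u_s, u_e):
        first = int(np.searchsorted(edges, s, side="right") - 1)
        last = int(np.searchsorted(edges, min(e, L), side="left"))
        for b in range(max(first, 0), min(last, n_bins)):
            lo = max(s, edges[b])
            hi = min(e, edges[b + 1])
            if hi > lo:
                bin_cov[b] += hi - lo
    q_low = np.quantile(bin_cov, alpha / 2.0)
    ranks_le = np.searchsorted(np.sort(bin_cov), bin_cov, side="right")
    ranks_ge = n_bins - np.searchsorted(np.sort(bin_cov), bin_cov, side="left")
    emp_p = 2.0 * np.minimum(ranks_le, ranks_ge) / n_bins
    low = bin_cov < q_low
    deserts: list[DesertCall] = []
    b = 0
    while b < n_bins:
        if low[b]:
            b0 = b
            while b < n_bins and low[b]:
                b += 1
            deserts.append(DesertCall(
                start=int(edges[b0]), end=int(edges[b]),
                n_bins=b - b0,
                max_bin_coverage=float(bin_cov[b0:b].max()),
                empirical_p=float(np.min(emp_p[b0:b]))))
        else:
            b += 1
    return deserts


def diversity_curve(segments: list[Segment], haplotypes: list[str],
                    sizes=None, n_perm: int = 10_000,
                    seed: int = 0) -> dict[int, float]:
    """Mean union length of segments carried by random hap subsamples.

    At the full sample size the union is deterministic and computed once.
    """
    n = len(haplotypes)
    if n == 0:
        raise ValueError("empty haplotype set")
    if sizes is None:
        sizes = range(1, n + 1)
    by_hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for h in haplotypes:
        by_hap[h] = iv.as_intervals(
            [(s.start, s.end) for s in segments if s.haplotype == h])
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for s in sizes:
        if s < 1 or s > n:
            raise ValueError(f"subsample size {s} out of range")
        if s == n:
            out[s] = _union_length([by_hap[h] for h in haplotypes])
            continue
        acc = 0.0
        for _ in range(n_perm):
            pick = rng.choice(n, size=s, replace=False)
            acc += _union_length([by_hap[haplotypes[i]] for i in pick])
        out[s] = acc / n_perm
    return out


def _union_length(interval_sets) -> float:
    starts = np.concatenate([s for s, _ in interval_sets]) \
        if interval_sets else np.empty(0, np.int64)
    ends = np.concatenate([e for _, e in interval_sets]) \
        if interval_sets else np.empty(0, np.int64)
    return float(iv.total_length(starts, ends))
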