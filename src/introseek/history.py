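"""Multi-wave introgression-history inference from tract lengths.

Under a discrete pulse-admixture model, the genetic length of a surviving
tract from a wave ``t_k`` generations ago is exponential with rate
``u_k = t_k (1 - alpha_total)`` per Morgan; a K-wave history yields a
K-component exponential mixture.  Segments shorter than the 15-kb
detection floor are removed before fitting, so the mixture is fitted on
*left-truncated* lengths (by memorylessness, ``x - c`` given ``x > c`` is
exponential with the same rate, but the component weights observed after
truncation are biased toward slow-decay components and are corrected
back before converting weights to admixture proportions).

The number of waves is chosen by a forward likelihood-ratio test (df=2
per extra wave: one time, one proportion), and parameter uncertainty by
bootstrap over tracts, including re-selection of K ("support ratio").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .iohub import GeneticMap, Segment

DEFAULT_GEN_YEARS = 30.0


@dataclass
class TractLengthSample:
    """Tract lengths for one archaic lineage, in Morgans and bp."""

    lineage: str
    lengths_morgans: np.ndarray
    lengths_bp: np.ndarray
    truncation_morgans: float = 0.0     # detection floor already applied
    total_ancestry: float | None = None  # genome-wide fraction for this lineage

    def __post_init__(self) -> None:
        self.lengths_morgans = np.asarray(self.lengths_morgans, dtype=float)
        self.lengths_bp = np.asarray(self.lengths_bp)
        if np.any(self.lengths_morgans <= 0):
            raise ValueError("tract lengths must be positive")

    @property
    def n(self) -> int:
        return len(self.lengths_morgans)


@dataclass
class WaveModel:
    """K introgression pulses, ordered oldest first."""

    lineage: str
    K: int
    times_gen: np.ndarray        # generations, strictly decreasing
    proportions: np.ndarray      # m_k, sum < 1
    rates: np.ndarray            # mixture rates per Morgan (decreasing)
    weights: np.ndarray          # truncation-corrected mixture weights
    loglik: float
    gen_years: float = DEFAULT_GEN_YEARS

    @property
    def times_kya(self) -> np.ndarray:
        return generations_to_kya(self.times_gen, self.gen_years)


@dataclass
class BootstrapCI:
    support_ratio: dict[int, float]          # K -> fraction of resamples
    times_ci: np.ndarray | None              # (K, 2) kya-free (generations)
    proportions_ci: np.ndarray | None        # (K, 2)
    n_resamples: int = 0


# ---------------------------------------------------------------------------
# Filtering / conversion
# ---------------------------------------------------------------------------

def merge_close_segments(segments: list[Segment],
                         max_gap: int = 15_000) -> list[Segment]:
    """Merge same-haplotype segments separated by less than ``max_gap``.

    Gaps below the detection floor are not resolvable features of the
    tract-length distribution: a marker desert inside one long tract
    splits it into fragments whose lengths would bias the wave-time
    estimate upward.
    """
    out: list[Segment] = []
    by_hap: dict[str, list[Segment]] = {}
    for s in segments:
        by_hap.setdefault(s.haplotype, []).append(s)
    for hap in sorted(by_hap):
        ss = sorted(by_hap[hap], key=lambda s: s.start)
        cur = ss[0]
        for s in ss[1:]:
            if s.start - cur.end < max_gap:
                cur = Segment(cur.chrom, cur.start, max(cur.end, s.end), hap,
                              state=cur.state, label=cur.label)
            else:
                out.append(cur)
                cur = s
        out.append(cur)
    return out


def filter_and_convert(segments: list[Segment], gmap: GeneticMap | None = None,
                       min_bp: int = 15_000, lineage: str = "",
                       total_ancestry: float | None = None,
                       genome_length: int | None = None) -> TractLengthSample:
    """Drop segments shorter than ``min_bp`` and convert bp to Morgans.

    With no map, the default constant 1 cM/Mb applies.  Raises when no
    segment survives the filter.
    """
    kept = [s for s in segments if s.length >= min_bp]
    if not kept:
        raise ValueError("insufficient tracts: none at or above the length floor")
    if gmap is None:
        end = genome_length or max(s.end for s in kept)
        gmap = GeneticMap.constant_rate(end, 1.0)
    starts = np.array([s.start for s in kept], dtype=float)
    ends = np.array([s.end for s in kept], dtype=float)
    lm = gmap.interpolate_morgans(ends) - gmap.interpolate_morgans(starts)
    lm = np.maximum(lm, 1e-12)
    # truncation point in Morgans at the genome-average recombination rate
    span_bp = gmap.anchors_bp[-1] - gmap.anchors_bp[0]
    span_m = (gmap.anchors_cm[-1] - gmap.anchors_cm[0]) / 100.0
    trunc_m = min_bp * span_m / span_bp
    return TractLengthSample(lineage=lineage, lengths_morgans=lm,
                             lengths_bp=ends - starts,
                             truncation_morgans=trunc_m,
                             total_ancestry=total_ancestry)


# ---------------------------------------------------------------------------
# Mixture EM
# ---------------------------------------------------------------------------

def _em_exponential_mixture(y: np.ndarray, K: int, rng, tol: float,
                            max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """EM for a K-component exponential mixture on shifted lengths y >= 0."""
    n = len(y)
    mean = float(np.mean(y)) + 1e-12
    # quantile-spread initialization with jitter
    qs = np.quantile(y, np.linspace(0.15, 0.85, K))
    u = 1.0 / np.maximum(qs * np.exp(rng.normal(0.0, 0.3, K)), 1e-9)
    w = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] * u[None, :] * np.exp(-np.outer(y, u))
        tot = np.maximum(dens.sum(axis=1), 1e-300)
        ll = float(np.sum(np.log(tot)))
        r = dens / tot[:, None]
        w = r.mean(axis=0)
        u = np.maximum(r.sum(axis=0), 1e-12) / np.maximum(r.T @ y, 1e-300)
        u = np.minimum(u, 1.0 / 1e-9)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * abs(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll
    return w, u, ll_prev


def fit_waves_em(sample: TractLengthSample, K: int, seed: int = 0,
                 n_restarts: int = 10, tol: float = 1e-8,
                 max_iter: int = 2000) -> WaveModel:
    """Fit a K-wave model by EM on left-truncated tract lengths.

    Requires at least ``10 K`` tracts.  The observed (truncated) mixture
    weights ``w_k`` are corrected by the truncation survival factor
    ``exp(-u_k c)`` before being converted to admixture proportions
    ``m_k`` proportional to ``w_k / u_k`` and scaled to the lineage's
    genome-wide ancestry fraction (when known).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sample.n < 10 * K:
        raise ValueError(f"insufficient tracts for K={K}: "
                         f"need >= {10 * K}, have {sample.n}")
    y = sample.lengths_morgans - sample.truncation_morgans
    y = np.maximum(y, 1e-12)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        w, u, ll = _em_exponential_mixture(y, K, rng, tol, max_iter)
        if np.any(~np.isfinite(u)) or np.any(~np.isfinite(w)):
            continue
        if best is None or ll > best[2]:
            best = (w, u, ll)
    if best is None:
        raise RuntimeError("exponential-mixture EM failed to converge "
                           f"after {n_restarts} restarts (n={sample.n}, K={K})")
    w_obs, u, ll = best
    order = np.argsort(-u)  # fastest decay = oldest wave first
    u = u[order]
    w_obs = w_obs[order]
    # undo the length-floor bias on the weights
    w_true = w_obs * np.exp(u * sample.truncation_morgans)
    w_true = w_true / w_true.sum()
    alpha = sample.total_ancestry if sample.total_ancestry is not None else 0.0
    times = u / max(1.0 - alpha, 1e-9)
    contrib = w_true / u
    if sample.total_ancestry is not None:
        props = sample.total_ancestry * contrib / contrib.sum()
    else:
        props = contrib / contrib.sum()
    return WaveModel(lineage=sample.lineage, K=K, times_gen=times,
                     proportions=props, rates=u, weights=w_true, loglik=ll)


def select_num_waves(sample: TractLengthSample, K_max: int = 3,
                     alpha_lrt: float = 0.05, seed: int = 0,
                     n_restarts: int = 10) -> WaveModel:
    """Forward LRT selection of the number of waves.

    Tests K vs K+1 with 2*dlogL ~ chi2(df=2); returns the smallest K not
    rejected in favor of K+1.  K+1 is only considered when the sample
    holds at least 10*(K+1) tracts.
    """
    model = fit_waves_em(sample, 1, seed=seed, n_restarts=n_restarts)
    for K in range(1, K_max):
        if sample.n < 10 * (K + 1):
            break
        bigger = fit_waves_em(sample, K + 1, seed=seed, n_restarts=n_restarts)
        lr = 2.0 * (bigger.loglik - model.loglik)
        p = stats.chi2.sf(max(lr, 0.0), df=2)
        if p < alpha_lrt:
            model = bigger
        else:
            break
    return model


def bootstrap_ci(sample: TractLengthSample, model: WaveModel, B: int = 100,
                 seed: int = 0, K_max: int = 3,
                 alpha_lrt: float = 0.05, n_restarts: int = 3) -> BootstrapCI:
    """Percentile bootstrap over tracts, with re-selection of K.

    The support ratio for each K is the fraction of resamples whose LRT
    selects that K; parameter CIs are computed over the resamples that
    agree with the fitted model's K (waves matched by time order).
    """
    if B <= 0:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    support: dict[int, int] = {}
    times_acc, props_acc = [], []
    for b in range(B):
        idx = rng.integers(0, sample.n, sample.n)
        sub = TractLengthSample(
            lineage=sample.lineage,
            lengths_morgans=sample.lengths_morgans[idx],
            lengths_bp=sample.lengths_bp[idx],
            truncation_morgans=sample.truncation_morgans,
            total_ancestry=sample.total_ancestry)
        try:
            m = select_num_waves(sub, K_max=K_max, alpha_lrt=alpha_lrt,
                                 seed=int(rng.integers(0, 2**31 - 1)),
                                 n_restarts=n_restarts)
        except (ValueError, RuntimeError):
            continue
        support[m.K] = support.get(m.K, 0) + 1
        if m.K == model.K:
            times_acc.append(m.times_gen)
            props_acc.append(m.proportions)
    n_ok = sum(support.values())
    ratio = {k: v / n_ok for k, v in sorted(support.items())} if n_ok else {}
    if times_acc:
        t_ci = np.percentile(np.stack(times_acc), [2.5, 97.5], axis=0).T
        p_ci = np.percentile(np.stack(props_acc), [2.5, 97.5], axis=0).T
    else:
        t_ci = p_ci = None
    return BootstrapCI(support_ratio=ratio, times_ci=t_ci,
                       proportions_ci=p_ci, n_resamples=n_ok)


def flag_unstable_waves(model: WaveModel, ci: BootstrapCI,
                        min_prop: float = 0.005,
                        min_support: float = 0.5) -> list[bool]:
    """Mark waves with tiny contributions and weak bootstrap support."""
    weak_k = ci.support_ratio.get(model.K, 0.0) < min_support
    return [bool(m < min_prop and weak_k) for m in model.proportions]


def generations_to_kya(t, gen_years: float = DEFAULT_GEN_YEARS):
    """Convert generations to thousands of years before present."""
    return np.asarray(t, dtype=float) * gen_years / 1000.0
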