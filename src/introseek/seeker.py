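"""SNP observation-state classification, constrained EM, and segment decoding.

Every SNP on a test haplotype is classified into one of four observation
states by comparing its derived allele against the archaic and African
reference panels:

* state 1 -- test-population-specific (derived in the test haplotype,
  absent from all references),
* state 2 -- archaic marker (derived shared with an archaic reference but
  with no African),
* state 3 -- AMH marker (derived shared with an African but with no
  archaic reference),
* state 4 -- common (everything else, including sites where the test
  haplotype carries the ancestral allele).

A two-state HMM over these observations (hidden AMH vs archaic ancestry)
is fitted by a constrained EM: the introgression proportion ``alpha``, the
introgression time ``T`` (generations) and six of the eight emission
entries are updated; the two cross-diagnostic entries --
emission(AMH marker | archaic) and emission(archaic marker | AMH) --
stay at their epsilon-derived initial values to keep the false-detection
rate down.  Decoding is by Viterbi with segment boundaries placed at the
midpoint between the flanking state-switch SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _hmm
from .iohub import ROLE_AFRICAN, ROLE_TEST, Segment, SitePanel

log = logging.getLogger(__name__)

# frozen emission entries: (hidden state, observation index 0-based)
FROZEN_ENTRIES = ((1, 2), (0, 1))  # e(AMH marker | archaic), e(archaic marker | AMH)


@dataclass
class HMMParams:
    """Pulse-admixture HMM parameters.

    ``emission`` rows are hidden states (0=AMH, 1=archaic), columns the
    four observation states; each row sums to 1.
    """

    alpha: float = 0.02
    T: float = 2000.0
    epsilon: float = 0.99
    emission: np.ndarray | None = None
    loglik_trace: list = field(default_factory=list)

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.emission is not None:
            if self.emission.shape != (2, 4):
                raise ValueError("emission must be 2x4")
            if not np.allclose(self.emission.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("emission rows must sum to 1")


# ---------------------------------------------------------------------------
# Observation classification
# ---------------------------------------------------------------------------

def _reference_flags(panel: SitePanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-site flags: derived allele found in any archaic ref / any African."""
    if not panel.polarized:
        raise ValueError("panel must be polarized before classification")
    arch_idx = panel.archaic_indices()
    afr_idx = panel.hap_indices(ROLE_AFRICAN)
    if len(arch_idx) == 0 or len(afr_idx) == 0:
        raise ValueError("panel needs archaic and African reference haplotypes")
    arch_any = np.any(panel.alleles[:, arch_idx] == 1, axis=1)
    afr_any = np.any(panel.alleles[:, afr_idx] == 1, axis=1)
    return arch_any, afr_any


def classify_observations(panel: SitePanel, haplotype: str) -> np.ndarray:
    """Observation-state vector (values 1..4) for one test haplotype."""
    if panel.roles.get(haplotype) != ROLE_TEST:
        raise ValueError(f"haplotype {haplotype!r} does not have role 'test'")
    arch_any, afr_any = _reference_flags(panel)
    h = panel.haplotypes.index(haplotype)
    return _classify(panel.alleles[:, h], arch_any, afr_any)


def _classify(hap: np.ndarray, arch_any: np.ndarray, afr_any: np.ndarray) -> np.ndarray:
    obs = np.full(hap.shape[0], 4, dtype=np.int8)
    der = hap == 1
    obs[der & ~arch_any & ~afr_any] = 1
    obs[der & arch_any & ~afr_any] = 2
    obs[der & ~arch_any & afr_any] = 3
    return obs


def classify_all(panel: SitePanel) -> tuple[np.ndarray, list[str]]:
    """Observation matrix (n_test_hap, n_sites) plus haplotype ids."""
    arch_any, afr_any = _reference_flags(panel)
    idx = panel.hap_indices(ROLE_TEST)
    if len(idx) == 0:
        raise ValueError("panel has no test haplotypes")
    haps = [panel.haplotypes[i] for i in idx]
    obs = np.stack([_classify(panel.alleles[:, i], arch_any, afr_any) for i in idx])
    return obs, haps


# ---------------------------------------------------------------------------
# Transition and emission models
# ---------------------------------------------------------------------------

def transition_matrix(d: float, params: HMMParams) -> np.ndarray:
    """2x2 transition matrix for genetic distance ``d`` Morgans."""
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    q = 1.0 - np.exp(-params.T * d)
    p01 = params.alpha * q
    p10 = (1.0 - params.alpha) * q
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def initial_emission(state_freqs: np.ndarray, epsilon: float = 0.99) -> np.ndarray:
    """Epsilon-parameterized row-stochastic starting emission matrix.

    ``epsilon`` is the probability that a cross-diagnostic marker is *not*
    emitted on the wrong ancestry background: under hidden archaic the
    AMH-marker entry is down-weighted to ``(1 - epsilon) * w3``, and under
    hidden AMH the archaic-marker entry to ``(1 - epsilon) * w2``; all
    remaining entries start at the genome-wide state frequencies,
    renormalized row-wise.  With the default ``epsilon = 0.99`` each
    diagnostic state starts with a 100-fold likelihood contrast between
    the two hidden states.
    """
    w = np.asarray(state_freqs, dtype=float)
    w = np.maximum(w, 1e-6)
    w = w / w.sum()
    emis = np.empty((2, 4))
    # hidden archaic: penalize AMH markers
    row = w.copy()
    row[2] *= (1.0 - epsilon)
    emis[1] = row / row.sum()
    # hidden AMH: penalize archaic markers
    row = w.copy()
    row[1] *= (1.0 - epsilon)
    emis[0] = row / row.sum()
    return emis


def _renormalize_with_frozen(emission: np.ndarray, frozen: np.ndarray) -> np.ndarray:
    """Restore frozen entries and rescale the free entries of each row."""
    out = emission.copy()
    for (i, k) in FROZEN_ENTRIES:
        free = [c for c in range(4) if c != k]
        fv = frozen[i, k]
        s = out[i, free].sum()
        if s <= 0:
            out[i, free] = (1.0 - fv) / 3.0
        else:
            out[i, free] *= (1.0 - fv) / s
        out[i, k] = fv
    return out


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

ALPHA_BOUNDS = (1e-6, 0.5)
T_BOUNDS = (1.0, 1e5)


def em_fit(obs, panel: SitePanel, init: HMMParams | None = None,
           tol: float = 1e-5, max_iter: int = 200) -> HMMParams:
    """Fit alpha, T and the six free emission entries by pooled EM.

    ``obs`` is the (n_hap, n_sites) observation matrix from
    :func:`classify_all` (values 1..4).  The pooled log-likelihood is
    non-decreasing across iterations: the emission M-step is exact, and
    the moment-style alpha/T update is accepted only when it does not
    lower the likelihood (generalized EM with a safeguard).
    """
    init = init or HMMParams()
    init.validate()
    obs_mat = np.ascontiguousarray(np.asarray(obs, dtype=np.int8) - 1)
    if obs_mat.ndim == 1:
        obs_mat = obs_mat[None, :]
    H, S = obs_mat.shape
    if S == 0:
        raise ValueError("no markers: empty observation sequence")
    if panel.genetic_pos is None:
        raise ValueError("panel has no genetic positions; attach a map first")
    if not np.any(obs_mat < 3):
        raise ValueError("no markers: all sites are common (state 4)")
    d = np.ascontiguousarray(np.diff(panel.genetic_pos))

    w = np.bincount(obs_mat.ravel(), minlength=4) / obs_mat.size
    frozen = initial_emission(w, init.epsilon)
    emis = frozen.copy() if init.emission is None else init.emission.copy()
    alpha, T = float(init.alpha), float(init.T)
    G_total = H * float(panel.genetic_pos[-1] - panel.genetic_pos[0])
    gammas = np.zeros((H, S, 2))

    def mstep(counts, alpha_cur, T_cur, emis_cur):
        row_sums = counts.sum(axis=1, keepdims=True)
        emis_new = counts / np.maximum(row_sums, 1e-12)
        emis_new = _renormalize_with_frozen(emis_new, frozen)
        emis_new = np.maximum(emis_new, 1e-12)
        emis_new /= emis_new.sum(axis=1, keepdims=True)
        alpha_new = float(np.clip(gammas[:, :, 1].mean(), *ALPHA_BOUNDS))
        if G_total > 0:
            # MAP switch count rather than the posterior junction
            # expectation: the latter is dominated by micro-flicker at
            # isolated diagnostic sites and runs T far above the tract
            # scale, which then fragments decoded tracts
            switches = _hmm.pooled_viterbi_switches(
                obs_mat, d, alpha_cur, T_cur, emis_cur)
            T_new = max(float(switches), 1.0) / max(
                2.0 * alpha_new * (1.0 - alpha_new) * G_total, 1e-12)
            T_new = float(np.clip(T_new, *T_BOUNDS))
        else:
            T_new = T_cur
        return emis_new, alpha_new, T_new

    trace: list[float] = []
    ll, e01, e10, counts = _hmm.pooled_estep(obs_mat, d, alpha, T, emis, gammas)
    trace.append(ll)
    for _ in range(max_iter):
        emis_new, alpha_new, T_new = mstep(counts, alpha, T, emis)
        cand = _hmm.pooled_estep(obs_mat, d, alpha_new, T_new, emis_new, gammas)
        if cand[0] >= ll:
            emis, alpha, T = emis_new, alpha_new, T_new
            ll_new, e01, e10, counts = cand
        else:
            # moment-style transition update lowered the likelihood: the
            # exact emission M-step alone cannot (generalized-EM safeguard)
            emis = emis_new
            ll_new, e01, e10, counts = _hmm.pooled_estep(
                obs_mat, d, alpha, T, emis, gammas)
        trace.append(ll_new)
        if (ll_new - ll) < tol * abs(ll):
            ll = ll_new
            break
        ll = ll_new

    out = HMMParams(alpha=alpha, T=T, epsilon=init.epsilon, emission=emis,
                    loglik_trace=trace)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def posterior_matrix(obs, panel: SitePanel, params: HMMParams) -> np.ndarray:
    """Posterior P(archaic) per haplotype x site (forward-backward)."""
    obs_mat = np.ascontiguousarray(np.asarray(obs, dtype=np.int8) - 1)
    if obs_mat.ndim == 1:
        obs_mat = obs_mat[None, :]
    d = np.ascontiguousarray(np.diff(panel.genetic_pos))
    H, S = obs_mat.shape
    gammas = np.zeros((H, S, 2))
    _hmm.pooled_estep(obs_mat, d, params.alpha, params.T, params.emission, gammas)
    return gammas[:, :, 1]


def decode_segments(obs, panel: SitePanel, params: HMMParams,
                    haplotypes: list[str] | None = None,
                    bridge_posterior: float = 0.5) -> list[Segment]:
    """Viterbi-decode archaic segments with midpoint boundaries.

    Boundaries between an archaic and an AMH site fall at the midpoint of
    the flanking pair, rounded toward the shorter archaic segment; runs
    touching the first/last site end at that site.

    Viterbi occasionally cuts one long tract in two at a stretch with no
    informative markers even though the posterior stays archaic; a gap
    between two archaic runs whose mean posterior archaic probability
    exceeds ``bridge_posterior`` is therefore re-joined (set it to 1 to
    disable bridging).  This keeps the decoded tract-length distribution
    faithful, which the downstream admixture-dating depends on.
    """
    params.validate()
    obs_mat = np.ascontiguousarray(np.asarray(obs, dtype=np.int8) - 1)
    if obs_mat.ndim == 1:
        obs_mat = obs_mat[None, :]
    H, S = obs_mat.shape
    if haplotypes is None:
        idx = panel.hap_indices(ROLE_TEST)
        haplotypes = [panel.haplotypes[i] for i in idx]
    if len(haplotypes) != H:
        raise ValueError("haplotype id list does not match observation rows")
    d = np.ascontiguousarray(np.diff(panel.genetic_pos))
    gamma = posterior_matrix(obs_mat + 1, panel, params)
    pos = panel.positions
    segments: list[Segment] = []
    for h in range(H):
        path = _hmm.viterbi(obs_mat[h], d, params.alpha, params.T, params.emission)
        if bridge_posterior < 1.0:
            path = _bridge_gaps(path, gamma[h], bridge_posterior)
        boundaries = np.flatnonzero(np.diff(path.astype(np.int8)))
        starts = [0] + (boundaries + 1).tolist()
        ends = boundaries.tolist() + [S - 1]
        for i0, i1 in zip(starts, ends):
            if path[i0] != 1:
                continue
            if i0 == 0:
                s = int(pos[0])
            else:
                s = int((pos[i0 - 1] + pos[i0]) // 2) + 1
            if i1 == S - 1:
                e = int(pos[-1]) + 1
            else:
                e = int((pos[i1] + pos[i1 + 1]) // 2)
            if s >= e:
                continue
            segments.append(Segment(
                chrom=panel.chrom, start=s, end=e, haplotype=haplotypes[h],
                state="archaic",
                mean_posterior=float(gamma[h, i0:i1 + 1].mean()),
                n_snps=int(i1 - i0 + 1),
            ))
    return segments


def _bridge_gaps(path: np.ndarray, post: np.ndarray,
                 threshold: float) -> np.ndarray:
    """Re-join archaic runs across AMH gaps with high mean archaic posterior."""
    path = path.copy()
    n = len(path)
    i = 0
    while i < n:
        if path[i] != 0:
            i += 1
            continue
        j = i
        while j < n and path[j] == 0:
            j += 1
        flanked = i > 0 and j < n  # gap strictly between archaic runs
        if flanked and float(post[i:j].mean()) > threshold:
            path[i:j] = 1
        i = j
    return path


def archaic_fraction(segments: list[Segment], n_hap: int, genome_length: int) -> float:
    """Genome fraction covered by decoded archaic segments, averaged over haps."""
    total = sum(s.length for s in segments)
    return total / float(n_hap * genome_length)
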