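"""Lineage assignment of candidate segments on a calibrated reference tree.

The reference phylogeny is the four-taxon clock tree

    outgroup, (AMH, (archaic_1, archaic_2))

whose internal node depths (in expected substitutions per bp, one-way) are
re-fit from genome-wide mean pairwise difference densities between the
role groups, with the root set by the outgroup.  A candidate segment is
matched against seven possible origins -- placements of the segment's
source lineage on the tree:

1/2. the terminal edge of archaic_1 / archaic_2 (introgression from a
     sampled lineage),
3.   the archaic_1+archaic_2 ancestor node (introgression from their
     common-ancestor population),
4.   the internal edge between the archaic split and the AMH/archaic
     split (an unknown, deeply diverged archaic lineage),
5.   the AMH terminal edge (a false-positive, non-archaic segment),
6.   the AMH/archaic ancestor node (incomplete lineage sorting),
7.   the edge above the AMH/archaic split toward the root.

Each placement implies expected pairwise difference densities to every
reference group; observed mismatch counts are modeled as Poisson and the
placement log-likelihoods compared.  The optimal attachment depth on an
edge also dates the segment's split from the matched reference.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np

from .iohub import (MISSING, ROLE_AFRICAN, ROLE_ARCHAIC_PREFIX,
                    ROLE_OUTGROUP, Segment, SitePanel)

log = logging.getLogger(__name__)

DEFAULT_MU = 1.25e-8  # substitutions /bp/generation

LABEL_AMH = "AMH(false-positive)"
LABEL_ILS = "ILS"
LABEL_ANCESTOR = "archaic-ancestor"
LABEL_UNKNOWN = "unknown-archaic"
LABEL_ROOT = "root/outgroup"


@dataclass
class AncestryTree:
    """Clock-calibrated reference tree as three nested node depths.

    Depths are one-way expected difference densities (per bp): ``h_nd``
    for the archaic_1/archaic_2 ancestor, ``h_arch`` for the AMH/archaic
    ancestor, ``h_root`` for the root set by the outgroup.  The expected
    pairwise density between two leaves is twice their MRCA depth.
    """

    archaic_names: tuple[str, str]
    h_nd: float
    h_arch: float
    h_root: float

    def validate(self) -> None:
        if not (0 <= self.h_nd <= self.h_arch <= self.h_root):
            raise ValueError("node depths must be nested: h_nd <= h_arch <= h_root")

    def to_newick(self) -> str:
        a, b = self.archaic_names
        t1 = self.h_nd
        t2 = self.h_arch
        t3 = self.h_root
        return (f"(outgroup:{t3:.8g},(AMH:{t2:.8g},({a}:{t1:.8g},"
                f"{b}:{t1:.8g}):{t2 - t1:.8g}):{t3 - t2:.8g});")

    @classmethod
    def from_newick(cls, text: str) -> "AncestryTree":
        """Parse a tree written by :meth:`to_newick` (topology fixed)."""
        import skbio
        t = skbio.TreeNode.read(io.StringIO(text))
        names = {n.name for n in t.tips()}
        if "AMH" not in names or "outgroup" not in names:
            raise ValueError("tree must contain 'AMH' and 'outgroup' tips")
        arch = sorted(names - {"AMH", "outgroup"})
        if len(arch) != 2:
            raise ValueError("tree must contain exactly two archaic tips")
        tips = {n.name: n for n in t.tips()}
        h_nd = float(tips[arch[0]].length)
        amh = tips["AMH"]
        h_arch = float(amh.length)
        h_root = float(tips["outgroup"].length)
        return cls((arch[0], arch[1]), h_nd, h_arch, h_root)


@dataclass
class MatchResult:
    segment: Segment
    logliks: dict[str, float]
    label: str
    split_time_kya: float
    split_depth: float  # one-way difference density of the best placement


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _group_indices(panel: SitePanel) -> dict[str, np.ndarray]:
    names = panel.archaic_names()
    if len(names) != 2:
        raise ValueError("matcher requires exactly two archaic reference groups")
    groups = {
        "AMH": panel.hap_indices(ROLE_AFRICAN),
        names[0]: panel.archaic_indices(names[0]),
        names[1]: panel.archaic_indices(names[1]),
        "outgroup": panel.hap_indices(ROLE_OUTGROUP),
    }
    for g, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"missing haplotypes for group {g!r}"
                             if g != "outgroup" else "outgroup missing")
    return groups


def mean_pairwise_density(panel: SitePanel, idx_a: np.ndarray,
                          idx_b: np.ndarray) -> float:
    """Mean pairwise difference density (per bp) between two hap groups."""
    A = panel.alleles
    total = 0.0
    n = 0
    for i in idx_a:
        for j in idx_b:
            if i == j:
                continue
            ok = (A[:, i] != MISSING) & (A[:, j] != MISSING)
            nc = int(ok.sum())
            if nc == 0:
                continue
            callable_bp = panel.length * nc / panel.n_sites
            total += float(np.sum(A[ok, i] != A[ok, j])) / callable_bp
            n += 1
    if n == 0:
        raise ValueError("no callable haplotype pairs between groups")
    return total / n


def calibrate_tree(panel: SitePanel, prior: AncestryTree | None = None
                   ) -> AncestryTree:
    """Fit clock node depths by least squares to genome-wide densities.

    Each observed between-group density estimates twice the depth of the
    corresponding MRCA node; the root is placed on the outgroup edge.
    Negative or non-nested fits are clamped (and logged).  The prior tree
    only fixes the naming of the two archaic groups.
    """
    groups = _group_indices(panel)
    # genome-wide means are stable over a few haplotypes per group
    groups = {g: idx[:8] for g, idx in groups.items()}
    names = [g for g in groups if g not in ("AMH", "outgroup")]
    if prior is not None:
        names = list(prior.archaic_names)
    a, b = names
    d_nd = mean_pairwise_density(panel, groups[a], groups[b])
    d_arch = 0.5 * (mean_pairwise_density(panel, groups["AMH"], groups[a])
                    + mean_pairwise_density(panel, groups["AMH"], groups[b]))
    d_root = np.mean([mean_pairwise_density(panel, groups["outgroup"], groups[g])
                      for g in (a, b, "AMH")])
    depths = np.array([d_nd, d_arch, d_root]) / 2.0
    clamped = np.maximum.accumulate(np.maximum(depths, 0.0))
    if not np.allclose(clamped, depths):
        log.info("calibrate_tree: clamped non-nested node depths %s", depths)
    tree = AncestryTree((a, b), *clamped)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Segment profiles
# ---------------------------------------------------------------------------

def segment_difference_profile(segment: Segment, panel: SitePanel
                               ) -> dict[str, tuple[int, float]]:
    """Per-group (mismatch count, callable bp) for one segment.

    The distance to a group is taken to the *nearest* haplotype in the
    group (minimum density), which is robust to within-group diversity.
    Callable bp scales the physical segment length by the fraction of
    segment sites genotyped in both haplotypes.
    """
    groups = _group_indices(panel)
    h = panel.haplotypes.index(segment.haplotype)
    lo = np.searchsorted(panel.positions, segment.start, side="left")
    hi = np.searchsorted(panel.positions, segment.end, side="left")
    if hi <= lo:
        raise ValueError("uninformative segment: no genotyped site")
    hap = panel.alleles[lo:hi, h]
    out: dict[str, tuple[int, float]] = {}
    n_sites = hi - lo
    hap_ok = hap != MISSING
    for g, idx in groups.items():
        block = panel.alleles[lo:hi, :][:, idx]
        ok = hap_ok[:, None] & (block != MISSING)
        nc = ok.sum(axis=0)
        diffs = np.sum(ok & (block != hap[:, None]), axis=0)
        valid = nc > 0
        if not np.any(valid):
            raise ValueError(f"uninformative segment: no callable site vs {g}")
        callable_bp = segment.length * nc / n_sites
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(valid, diffs / np.maximum(callable_bp, 1e-12), np.inf)
        j = int(np.argmin(dens))
        out[g] = (int(diffs[j]), float(callable_bp[j]))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _poisson_ll(profile, expected) -> float:
    """log L = sum_g [k log(lambda) - lambda], lambda = E_g * callable bp."""
    ll = 0.0
    for g, (k, L) in profile.items():
        lam = max(expected[g], 1e-12) * L
        ll += k * np.log(lam) - lam
    return ll


def _placements(tree: AncestryTree):
    """(label, free-group set, fixed depths, t bounds) for the 7 origins."""
    a, b = tree.archaic_names
    nd, arch, root = tree.h_nd, tree.h_arch, tree.h_root

    # explicit tables are clearer than a general rule for four leaves
    def make(label, free, lo, hi, depth_pair):
        return {"label": label, "free": free, "lo": lo, "hi": hi,
                "fixed": depth_pair}

    return [
        make(a, {a}, 0.0, nd, {b: nd, "AMH": arch}),
        make(b, {b}, 0.0, nd, {a: nd, "AMH": arch}),
        make(LABEL_ANCESTOR, {a, b}, nd, nd, {"AMH": arch}),
        make(LABEL_UNKNOWN, {a, b}, nd, arch, {"AMH": arch}),
        make(LABEL_AMH, {"AMH"}, 0.0, arch, {a: arch, b: arch}),
        make(LABEL_ILS, {a, b, "AMH"}, arch, arch, {}),
        make(LABEL_ROOT, {a, b, "AMH"}, arch, root, {}),
    ]


# rootward preference order for likelihood ties (most rootward first)
_TIE_RANK = [LABEL_ROOT, LABEL_ILS, LABEL_UNKNOWN, LABEL_ANCESTOR]


def _fit_placement(profile, pl, h_root) -> tuple[float, float, float]:
    """Maximize the Poisson likelihood of one placement over the
    attachment depth ``t`` (within the edge) and a per-segment terminal
    nuisance length ``c`` added to every expected distance.

    ``c`` absorbs segment-lineage-specific excess divergence (private
    variants, alleles lost in single reference genomes) that inflates
    all of a segment's distances equally; without it such noise
    masquerades as deep, symmetric divergence.

    Given ``c`` the free attachment depth has the closed-form MLE
    ``t*(c) = clamp((sum k_free / sum L_free - c) / 2)``, so the profile
    likelihood is searched on a refined 1-D grid over ``c``.
    Returns (loglik, t_hat, c_hat).
    """
    free = pl["free"]
    groups = list(profile)
    ks = np.array([profile[g][0] for g in groups], dtype=float)
    Ls = np.array([profile[g][1] for g in groups], dtype=float)
    base = np.empty(len(groups))
    is_free = np.zeros(len(groups), dtype=bool)
    for i, g in enumerate(groups):
        if g in free:
            is_free[i] = True
            base[i] = 0.0
        elif g == "outgroup":
            base[i] = 2.0 * h_root
        else:
            base[i] = 2.0 * pl["fixed"][g]

    lo, hi = pl["lo"], max(pl["hi"], pl["lo"])
    kf = float(np.sum(ks[is_free]))
    Lf = max(float(np.sum(Ls[is_free])), 1e-12)

    def eval_grid(cs: np.ndarray):
        ts = np.clip((kf / Lf - cs) / 2.0, lo, hi)
        lam = (np.where(is_free[None, :], 2.0 * ts[:, None], base[None, :])
               + cs[:, None])
        lam = np.maximum(lam, 1e-12) * Ls[None, :]
        lls = np.sum(ks[None, :] * np.log(lam) - lam, axis=1)
        return lls, ts

    c_max = 2e-3
    cs = np.linspace(0.0, c_max, 64)
    lls, ts = eval_grid(cs)
    i = int(np.argmax(lls))
    span = cs[1] - cs[0]
    cs2 = np.linspace(max(cs[i] - span, 0.0), min(cs[i] + span, c_max), 33)
    lls2, ts2 = eval_grid(cs2)
    j = int(np.argmax(lls2))
    return float(lls2[j]), float(ts2[j]), float(cs2[j])


def match_segment(profile: dict[str, tuple[int, float]], tree: AncestryTree,
                  mu: float = DEFAULT_MU, gen_years: float = 30.0
                  ) -> tuple[dict[str, float], str, float]:
    """Log-likelihoods of the seven origins, the best label, and the
    optimal attachment depth of the best placement.

    Exact likelihood ties go to the more rootward placement.
    """
    tree.validate()
    lls: dict[str, float] = {}
    depths: dict[str, float] = {}
    for pl in _placements(tree):
        ll, t_hat, _ = _fit_placement(profile, pl, tree.h_root)
        lls[pl["label"]] = ll
        depths[pl["label"]] = t_hat
    best = None
    for label, ll in lls.items():
        if best is None or ll > lls[best] or (
                ll == lls[best] and _rank(label) < _rank(best)):
            best = label
    return lls, best, depths[best]


def _rank(label: str) -> int:
    try:
        return _TIE_RANK.index(label)
    except ValueError:
        return len(_TIE_RANK)


def estimate_split_time(depth: float, tree: AncestryTree, label: str,
                        mu: float = DEFAULT_MU, gen_years: float = 30.0) -> float:
    """Split time (kya) implied by an attachment depth on the clock tree."""
    t_gens = depth / mu
    return t_gens * gen_years / 1000.0


def match_segments(segments: list[Segment], panel: SitePanel,
                   tree: AncestryTree | None = None, mu: float = DEFAULT_MU,
                   gen_years: float = 30.0) -> list[MatchResult]:
    """Calibrate (if needed) and match every segment; fills segment labels."""
    if tree is None:
        tree = calibrate_tree(panel)
    results: list[MatchResult] = []
    for seg in segments:
        try:
            profile = segment_difference_profile(seg, panel)
        except ValueError:
            continue
        lls, label, depth = match_segment(profile, tree, mu, gen_years)
        kya = estimate_split_time(depth, tree, label, mu, gen_years)
        seg.label = label
        seg.split_time_kya = kya
        results.append(MatchResult(seg, lls, label, kya, depth))
    return results
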