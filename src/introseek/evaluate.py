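"""Scoring of detections against simulated truth.

Three concordance bases: ``length`` (bp overlap), ``snp`` (panel sites in
the compared regions) and ``aim`` (restricted to non-AMH ancestry
informative markers: sites whose derived allele occurs in an archaic
reference, is monomorphic-absent in the African panel, and is carried by
the test haplotype).  Segment-level accuracy uses the >80 %-overlap rule,
and admixture-model success compares wave counts, times and proportions
within configurable tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import intervals as iv
from .iohub import ROLE_AFRICAN, Segment, SitePanel

BASES = ("length", "snp", "aim")


@dataclass
class ConcordanceReport:
    precision: float
    tpr: float
    fpr: float
    basis: str
    per_haplotype: dict | None = None


def _segments_by_hap(segments: list[Segment]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        by.setdefault(s.haplotype, []).append((s.start, s.end))
    return {h: iv.merge(*iv.as_intervals(p)) for h, p in by.items()}


def _aim_mask(panel: SitePanel) -> np.ndarray:
    """Sites derived in >=1 archaic reference and absent from all Africans."""
    if not panel.polarized:
        raise ValueError("AIM restriction needs a polarized panel")
    arch = panel.archaic_indices()
    afr = panel.hap_indices(ROLE_AFRICAN)
    arch_any = np.any(panel.alleles[:, arch] == 1, axis=1)
    afr_none = ~np.any(panel.alleles[:, afr] == 1, axis=1)
    return arch_any & afr_none


def concordance(inferred: list[Segment], truth, panel: SitePanel | None = None,
                basis: str = "length", genome_length: int | None = None,
                haplotypes: list[str] | None = None) -> ConcordanceReport:
    """Pooled precision / TPR / FPR of inferred segments against truth.

    ``truth`` is a :class:`~introseek.simulate.TruthTracts`.  For the
    ``snp`` and ``aim`` bases a polarized panel is required; counting is
    per haplotype (a site contributes once per test haplotype).
    """
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}")
    if basis != "length" and panel is None:
        raise ValueError("snp/aim bases require the site panel")
    if genome_length is None:
        genome_length = panel.length if panel is not None else None
    if genome_length is None:
        raise ValueError("genome_length required when no panel is given")
    if haplotypes is None:
        haplotypes = sorted(set(truth.table["haplotype"])
                            | {s.haplotype for s in inferred})
    inf_by = _segments_by_hap(inferred)
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))

    site_w = None
    if basis != "length":
        pos = panel.positions
        if basis == "aim":
            aim = _aim_mask(panel)

    tp = fp = fn = tn = 0.0
    per_hap: dict[str, tuple[float, float, float]] = {}
    for hap in haplotypes:
        I = inf_by.get(hap, empty)
        T = truth.intervals(hap)
        inter = iv.intersect(*I, *T)
        only_i = iv.subtract(*I, *T)
        only_t = iv.subtract(*T, *I)
        if basis == "length":
            a = float(np.sum(inter[1] - inter[0]))
            b = float(np.sum(only_i[1] - only_i[0]))
            c = float(np.sum(only_t[1] - only_t[0]))
            t_len = float(np.sum(T[1] - T[0]))
            d = float(genome_length) - t_len - b
        else:
            if basis == "aim":
                h = panel.haplotypes.index(hap)
                use = aim & (panel.alleles[:, h] == 1)
            else:
                use = np.ones(len(pos), dtype=bool)
            p = pos[use]
            a = float(iv.n_sites_in(p, *inter))
            b = float(iv.n_sites_in(p, *only_i))
            c = float(iv.n_sites_in(p, *only_t))
            d = float(len(p)) - a - b - c
        tp += a
        fp += b
        fn += c
        tn += d
        per_hap[hap] = (a, b, c)

    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    tpr = tp / (tp + fn) if tp + fn > 0 else float("nan")
    fpr = fp / (fp + tn) if fp + tn > 0 else float("nan")
    return ConcordanceReport(precision, tpr, fpr, basis, per_hap)


def segment_accuracy(inferred: list[Segment], truth, min_overlap: float = 0.8,
                     min_len: int = 15_000) -> float:
    """Fraction of inferred segments (>= min_len) with >min_overlap truth overlap."""
    n = ok = 0
    for s in inferred:
        if s.length < min_len:
            continue
        T = truth.intervals(s.haplotype)
        ov = iv.intersect_length(np.array([s.start]), np.array([s.end]), *T)
        n += 1
        if ov / s.length > min_overlap:
            ok += 1
    return ok / n if n else float("nan")


def matching_accuracy(assigned: list[str], truth_lineages: list[str],
                      label_map: dict[str, str] | None = None) -> float:
    """Fraction of segments whose assigned label names the true lineage.

    ``label_map`` translates matcher labels to lineage names; by default
    a label counts as correct when it equals the truth lineage string.
    """
    if len(assigned) != len(truth_lineages):
        raise ValueError("label/truth length mismatch")
    if not assigned:
        return float("nan")
    ok = 0
    for lab, tru in zip(assigned, truth_lineages):
        mapped = label_map.get(lab, lab) if label_map else lab
        ok += mapped == tru
    return ok / len(assigned)


def model_success(inferred, truth_waves, tol_time: float = 0.3,
                  tol_prop: float = 0.5) -> bool:
    """True iff wave count matches and each wave's time and proportion are
    within relative tolerances after matching waves by time order.

    ``inferred`` is a fitted :class:`~introseek.history.WaveModel`;
    ``truth_waves`` a list of ``(time_generations, proportion)`` pairs.
    """
    truth = sorted(truth_waves, key=lambda w: -w[0])
    if inferred.K != len(truth):
        return False
    for (t_hat, m_hat), (t, m) in zip(
            zip(inferred.times_gen, inferred.proportions), truth):
        if abs(t_hat - t) > tol_time * t:
            return False
        if abs(m_hat - m) > tol_prop * m:
            return False
    return True
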