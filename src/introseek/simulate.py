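"""Tract-level simulator with branch-painted mutations and exact truth.

The generator lays archaic tracts onto test haplotypes as a Poisson
process (tract starts at density ``m_k * u_k`` per Morgan, lengths
exponential with rate ``u_k = t_k (1 - m_total)`` per Morgan for a pulse
``t_k`` generations ago contributing proportion ``m_k``) and then paints
mutations site by site: each mutation class corresponds to a branch or a
segregating-polymorphism layer of the demography

    outgroup --- (AMH, (unknown?, (archaic_1, archaic_2)))

so that test-specific, archaic-marker, AMH-marker and common sites arise
with the correct sharing structure, including incomplete-lineage-sorting
patterns (ancestral polymorphism carried by the archaic clade and
segregating at low frequency in modern humans) that mimic introgression
without gene flow.  The sequenced archaic references diverge from the
introgressing source population ``t_ref`` before present, so tracts are
close to, but not identical with, the references.

All rates are per bp per generation; times are internally in generations
(config fields in kya are converted with the configured generation time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .iohub import (GeneticMap, ROLE_AFRICAN, ROLE_ARCHAIC_PREFIX,
                    ROLE_OUTGROUP, ROLE_TEST, SitePanel)

LINEAGES = ("NEA", "DEN", "UNK")


@dataclass
class ScenarioConfig:
    """One simulation scenario; ``seed`` is mandatory for reproducibility."""

    seed: int
    length_bp: int = 10_000_000
    mu: float = 1.25e-8                 # mutations /bp/generation
    recomb: float = 1e-8                # Morgans /bp (1 cM/Mb)
    gen_years: float = 30.0
    n_test: int = 20                    # haplotypes
    n_african: int = 40                 # African reference haplotypes
    n_archaic: int = 2                  # haplotypes per archaic reference
    ne_archaic: float = 3000.0          # archaic effective population size
    # split times, kya
    t_out_kya: float = 6500.0
    t_arch_kya: float = 700.0           # AMH / archaic split
    t_nd_kya: float = 450.0             # archaic_1 / archaic_2 split
    t_ref_kya: float = 120.0            # sequenced reference vs introgressing source
    t_afr_kya: float = 80.0             # African / test split (out of Africa)
    t_unknown_kya: float | None = None  # unknown lineage split from known archaics
    # introgression waves: (lineage, time in generations, proportion)
    waves: list = field(default_factory=lambda: [("NEA", 2000.0, 0.02)])
    # diversity layer densities (/bp) and frequency-spectrum floor
    d_amh_poly: float = 1.5e-3
    d_afr_priv: float = 2e-4
    d_test_priv: float = 1e-3
    d_ils: float = 5e-4
    d_ref_het: float = 1e-4
    sfs_fmin: float = 0.02
    p_ils_both: float = 0.5             # ILS allele carried by both archaic lineages
    p_ils_lost: float = 0.2             # ILS allele lost in the sampled references
    name: str = ""

    def gens(self, kya: float) -> float:
        return kya * 1000.0 / self.gen_years

    @property
    def m_total(self) -> float:
        return sum(w[2] for w in self.waves)

    def validate(self) -> None:
        t_out, t_arch = self.gens(self.t_out_kya), self.gens(self.t_arch_kya)
        t_nd, t_ref = self.gens(self.t_nd_kya), self.gens(self.t_ref_kya)
        t_afr = self.gens(self.t_afr_kya)
        if not (t_out > t_arch > t_nd > t_ref > 0 and t_arch > t_afr > 0):
            raise ValueError("inconsistent split times")
        if self.t_unknown_kya is not None:
            t_unk = self.gens(self.t_unknown_kya)
            if not (0 < t_unk < t_arch):
                raise ValueError("unknown-lineage split must predate the "
                                 "AMH/archaic split; below the archaic_1/"
                                 "archaic_2 split it branches off archaic_1")
        if not 0 <= self.m_total < 1:
            raise ValueError("total introgression proportion must be in [0, 1)")
        for lin, t, m in self.waves:
            if lin not in LINEAGES:
                raise ValueError(f"unknown lineage {lin!r}")
            if lin == "UNK" and self.t_unknown_kya is None:
                raise ValueError("UNK wave requires t_unknown_kya")
            ceiling = self.gens(self.t_unknown_kya) if lin == "UNK" else t_ref
            if not 0 < t < ceiling:
                raise ValueError(f"wave time {t} outside (0, {ceiling:.0f}) "
                                 f"for lineage {lin}")
            if not 0 < m < 1:
                raise ValueError("wave proportion must be in (0, 1)")


@dataclass
class TruthTracts:
    """Ground-truth archaic tracts, the reference surface for evaluation."""

    table: pd.DataFrame  # columns: haplotype, start, end, lineage, wave

    COLUMNS = ["haplotype", "start", "end", "lineage", "wave"]

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        for hap, grp in self.table.groupby("haplotype"):
            g = grp.sort_values("start")
            if np.any(g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]):
                raise ValueError(f"overlapping truth tracts on {hap}")

    def intervals(self, haplotype: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.table[self.table["haplotype"] == haplotype]
        return (g["start"].to_numpy(dtype=np.int64),
                g["end"].to_numpy(dtype=np.int64))

    def fraction(self, n_hap: int, genome_length: int) -> float:
        return float((self.table["end"] - self.table["start"]).sum()
                     / (n_hap * genome_length))

    @property
    def lineages(self) -> list[str]:
        return sorted(self.table["lineage"].unique())


def write_truth(tracts: TruthTracts, path) -> None:
    """BED-like TSV: chrom-free truth table, refuses overlapping tracts."""
    tracts.table[TruthTracts.COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTracts:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        df = pd.DataFrame(columns=TruthTracts.COLUMNS)
    return TruthTracts(df)


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------

def _sfs(rng, n, fmin, fmax=0.98):
    """Derived-allele frequencies with density ~ 1/f on [fmin, fmax]."""
    return fmin * (fmax / fmin) ** rng.random(n)


def _lay_tracts(cfg: ScenarioConfig, rng) -> pd.DataFrame:
    """Poisson tract placement per haplotype; overlaps resolved by rejection.

    Each tract also receives the coalescence time of its source lineage
    with the sampled reference lineage of its archaic group: the
    population split plus an exponential within-population waiting time
    with mean ``2 * ne_archaic`` generations.  This is what governs how
    many diagnostic markers a tract shares with the reference.
    """
    L_m = cfg.length_bp * cfg.recomb
    t_nd, t_ref = cfg.gens(cfg.t_nd_kya), cfg.gens(cfg.t_ref_kya)
    t_arch = cfg.gens(cfg.t_arch_kya)
    t_unk = cfg.gens(cfg.t_unknown_kya) if cfg.t_unknown_kya is not None else None
    rows = []
    for h in range(cfg.n_test):
        hap = f"TST{h // 2}_{h % 2}"
        cand = []
        for widx, (lin, t, m) in enumerate(cfg.waves):
            u = t * (1.0 - cfg.m_total)  # tract-length rate per Morgan
            n = rng.poisson(m * u * L_m)
            starts = rng.integers(0, cfg.length_bp, n)
            lens = rng.exponential(1.0 / (u * cfg.recomb), n)
            if lin == "UNK":
                base, cap = t_unk, t_arch
            else:
                base, cap = t_ref, t_nd
            tdivs = np.minimum(base + rng.exponential(2.0 * cfg.ne_archaic, n), cap)
            for s, ln, td in zip(starts, lens, tdivs):
                cand.append((int(s), min(int(s + max(ln, 1.0)), cfg.length_bp),
                             lin, widx, float(td)))
        rng.shuffle(cand)
        taken_s: list[int] = []
        taken_e: list[int] = []
        for s, e, lin, widx, td in cand:
            if e <= s:
                continue
            ok = all(e <= ts or s >= te for ts, te in zip(taken_s, taken_e))
            if ok:
                taken_s.append(s)
                taken_e.append(e)
                rows.append((hap, s, e, lin, widx, td))
    df = pd.DataFrame(rows, columns=TruthTracts.COLUMNS + ["t_div"])
    return df.sort_values(["haplotype", "start"]).reset_index(drop=True)


def _ancestry_codes(truth: pd.DataFrame, hap: str, positions: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lineage code, wave time, lineage divergence time) per position.

    Codes: 0 AMH, 1 NEA, 2 DEN, 3 UNK; times are nan on AMH background.
    """
    n = len(positions)
    lin = np.zeros(n, dtype=np.int8)
    wt = np.full(n, np.nan)
    td = np.full(n, np.nan)
    g = truth[truth["haplotype"] == hap]
    if len(g) == 0:
        return lin, wt, td
    s = g["start"].to_numpy()
    e = g["end"].to_numpy()
    codes = np.asarray([LINEAGES.index(x) + 1 for x in g["lineage"]], dtype=np.int8)
    times = g["wave_time"].to_numpy()
    tdivs = g["t_div"].to_numpy()
    idx = np.searchsorted(s, positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(n, dtype=bool)
    inside[ok] = positions[ok] < e[idx[ok]]
    lin[inside] = codes[idx[inside]]
    wt[inside] = times[idx[inside]]
    td[inside] = tdivs[idx[inside]]
    return lin, wt, td


def simulate_panel(cfg: ScenarioConfig) -> tuple[SitePanel, TruthTracts]:
    """Generate a phased panel plus exact truth tracts for one scenario.

    The returned panel is unpolarized (allele 1 = ALT = the mutation);
    REF is always the true ancestral base, the outgroup haplotypes carry
    the ancestral allele except at outgroup-branch mutations, and the AA
    INFO field records the true ancestral base.  Running the standard
    pipeline (polarize by outgroup, attach map) therefore includes the
    realistic mis-polarization of outgroup-private mutations.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length_bp
    mu = cfg.mu
    t_out, t_arch = cfg.gens(cfg.t_out_kya), cfg.gens(cfg.t_arch_kya)
    t_nd, t_ref = cfg.gens(cfg.t_nd_kya), cfg.gens(cfg.t_ref_kya)
    t_afr = cfg.gens(cfg.t_afr_kya)
    t_unk = cfg.gens(cfg.t_unknown_kya) if cfg.t_unknown_kya is not None else None

    truth_df = _lay_tracts(cfg, rng)
    truth_df["wave_time"] = [cfg.waves[w][1] for w in truth_df["wave"]]

    # haplotype layout: test, african, NEA refs, DEN refs, outgroup (diploid)
    test_haps = [f"TST{i // 2}_{i % 2}" for i in range(cfg.n_test)]
    afr_haps = [f"AFR{i // 2}_{i % 2}" for i in range(cfg.n_african)]
    nea_haps = [f"NEA{i // 2}_{i % 2}" for i in range(cfg.n_archaic)]
    den_haps = [f"DEN{i // 2}_{i % 2}" for i in range(cfg.n_archaic)]
    out_haps = ["OUT0_0", "OUT0_1"]
    haps = test_haps + afr_haps + nea_haps + den_haps + out_haps
    roles = {h: ROLE_TEST for h in test_haps}
    roles |= {h: ROLE_AFRICAN for h in afr_haps}
    roles |= {h: ROLE_ARCHAIC_PREFIX + "NEA" for h in nea_haps}
    roles |= {h: ROLE_ARCHAIC_PREFIX + "DEN" for h in den_haps}
    roles |= {h: ROLE_OUTGROUP for h in out_haps}
    n_hap = len(haps)
    sl = {  # column slices
        "test": slice(0, cfg.n_test),
        "afr": slice(cfg.n_test, cfg.n_test + cfg.n_african),
        "nea": slice(cfg.n_test + cfg.n_african,
                     cfg.n_test + cfg.n_african + cfg.n_archaic),
        "den": slice(cfg.n_test + cfg.n_african + cfg.n_archaic,
                     cfg.n_test + cfg.n_african + 2 * cfg.n_archaic),
        "out": slice(n_hap - 2, n_hap),
    }

    pos_blocks: list[np.ndarray] = []
    mat_blocks: list[np.ndarray] = []

    def draw_positions(density: float) -> np.ndarray:
        n = rng.poisson(density * L)
        return rng.integers(0, L, n)

    def new_block(pos: np.ndarray) -> np.ndarray:
        return np.zeros((len(pos), n_hap), dtype=np.int8)

    def test_ancestry(pos: np.ndarray):
        lins = np.empty((cfg.n_test, len(pos)), dtype=np.int8)
        wts = np.empty((cfg.n_test, len(pos)))
        tds = np.empty((cfg.n_test, len(pos)))
        for i, hap in enumerate(test_haps):
            lins[i], wts[i], tds[i] = _ancestry_codes(truth_df, hap, pos)
        return lins, wts, tds

    def commit(pos, mat):
        if len(pos):
            pos_blocks.append(pos)
            mat_blocks.append(mat)

    # --- outgroup-branch mutations (mis-polarize under outgroup rooting)
    pos = draw_positions(mu * t_out)
    mat = new_block(pos)
    mat[:, sl["out"]] = 1
    commit(pos, mat)

    # --- shared stem above the AMH/archaic split: everyone but outgroup
    pos = draw_positions(mu * (t_out - t_arch))
    mat = new_block(pos)
    mat[:, :n_hap - 2] = 1
    commit(pos, mat)

    # --- AMH stem (fixed modern-human derived alleles)
    pos = draw_positions(mu * (t_arch - t_afr))
    mat = new_block(pos)
    mat[:, sl["afr"]] = 1
    lins, _, _ = test_ancestry(pos)
    mat[:, sl["test"]] = (lins == 0).T
    commit(pos, mat)

    # --- modern-human segregating polymorphism (shared African/test)
    pos = draw_positions(cfg.d_amh_poly)
    f = _sfs(rng, len(pos), cfg.sfs_fmin)
    mat = new_block(pos)
    mat[:, sl["afr"]] = rng.random((len(pos), cfg.n_african)) < f[:, None]
    lins, _, _ = test_ancestry(pos)
    carry = rng.random((len(pos), cfg.n_test)) < f[:, None]
    mat[:, sl["test"]] = carry & (lins == 0).T
    commit(pos, mat)

    # --- African-private polymorphism
    pos = draw_positions(cfg.d_afr_priv)
    f = _sfs(rng, len(pos), cfg.sfs_fmin)
    mat = new_block(pos)
    mat[:, sl["afr"]] = rng.random((len(pos), cfg.n_african)) < f[:, None]
    commit(pos, mat)

    # --- test-population-private polymorphism (post-admixture drift)
    pos = draw_positions(cfg.d_test_priv)
    f = _sfs(rng, len(pos), cfg.sfs_fmin)
    mat = new_block(pos)
    mat[:, sl["test"]] = rng.random((len(pos), cfg.n_test)) < f[:, None]
    commit(pos, mat)

    # --- incomplete lineage sorting: ancestral polymorphism in the
    #     AMH/archaic ancestor, segregating at low frequency in modern
    #     humans while carried by part of the archaic clade; with
    #     probability p_ils_lost the single sequenced reference genomes
    #     have lost the allele that the introgressing source still carries
    pos = draw_positions(cfg.d_ils)
    f = _sfs(rng, len(pos), cfg.sfs_fmin)
    side = rng.random(len(pos))
    both = side < cfg.p_ils_both
    lost = (~both) & (side < cfg.p_ils_both + cfg.p_ils_lost)
    rest = ~both & ~lost
    half = cfg.p_ils_both + cfg.p_ils_lost + (1 - cfg.p_ils_both - cfg.p_ils_lost) / 2
    nea_only = rest & (side < half)
    den_only = rest & ~nea_only
    mat = new_block(pos)
    mat[:, sl["nea"]] = (both | nea_only)[:, None]
    mat[:, sl["den"]] = (both | den_only)[:, None]
    mat[:, sl["afr"]] = rng.random((len(pos), cfg.n_african)) < f[:, None]
    lins, _, _ = test_ancestry(pos)
    amh_carry = rng.random((len(pos), cfg.n_test)) < f[:, None]
    on_tract = lins.T > 0
    tract_carry = ((both | lost)[:, None] & on_tract) \
        | (nea_only[:, None] & (lins.T == 1)) \
        | (den_only[:, None] & (lins.T == 2))
    mat[:, sl["test"]] = (amh_carry & (lins == 0).T) | tract_carry
    commit(pos, mat)

    # --- archaic stem (t_nd .. t_arch); an unknown-lineage tract carries
    #     only mutations older than its lineage divergence from the refs
    pos = draw_positions(mu * (t_arch - t_nd))
    age = rng.uniform(t_nd, t_arch, len(pos))
    mat = new_block(pos)
    mat[:, sl["nea"]] = 1
    mat[:, sl["den"]] = 1
    lins, _, tds = test_ancestry(pos)
    known = (lins.T == 1) | (lins.T == 2)
    unk = (lins.T == 3) & (age[:, None] > tds.T)
    mat[:, sl["test"]] = known | unk
    commit(pos, mat)

    # --- per-lineage branches below the archaic_1/archaic_2 split: the
    #     reference side is shared with a tract only when the mutation is
    #     older than the tract's lineage divergence; the tract side is
    #     private between the wave time and the lineage divergence
    for key, code in (("nea", 1), ("den", 2)):
        pos = draw_positions(mu * t_nd)
        age = rng.uniform(0.0, t_nd, len(pos))
        mat = new_block(pos)
        mat[:, sl[key]] = 1
        lins, _, tds = test_ancestry(pos)
        share = (lins == code) & (age[None, :] > tds)
        if key == "nea":
            # an unknown lineage splitting below the archaic_1/archaic_2
            # node branches off archaic_1 by convention
            share |= (lins == 3) & (age[None, :] > tds)
        mat[:, sl["test"]] = share.T
        commit(pos, mat)

        pos = draw_positions(mu * t_nd)
        age = rng.uniform(0.0, t_nd, len(pos))
        mat = new_block(pos)
        lins, wts, tds = test_ancestry(pos)
        mat[:, sl["test"]] = ((lins == code) & (age[None, :] > wts)
                              & (age[None, :] < tds)).T
        commit(pos, mat)

    # --- unknown-lineage private branch (wave time .. lineage divergence)
    if t_unk is not None:
        pos = draw_positions(mu * t_arch)
        age = rng.uniform(0.0, t_arch, len(pos))
        mat = new_block(pos)
        lins, wts, tds = test_ancestry(pos)
        mat[:, sl["test"]] = ((lins == 3) & (age[None, :] > wts)
                              & (age[None, :] < tds)).T
        commit(pos, mat)

    # --- archaic reference heterozygosity (per-haplotype noise)
    ref_cols = np.concatenate([np.arange(*sl["nea"].indices(n_hap)),
                               np.arange(*sl["den"].indices(n_hap))])
    pos = draw_positions(cfg.d_ref_het * len(ref_cols))
    mat = new_block(pos)
    which = rng.integers(0, len(ref_cols), len(pos))
    mat[np.arange(len(pos)), ref_cols[which]] = 1
    commit(pos, mat)

    # --- assemble, sort, deduplicate
    all_pos = np.concatenate(pos_blocks) if pos_blocks else np.empty(0, np.int64)
    all_mat = (np.concatenate(mat_blocks, axis=0) if mat_blocks
               else np.empty((0, n_hap), np.int8))
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]
    all_mat = all_mat[order]
    uniq, first = np.unique(all_pos, return_index=True)
    all_pos = all_pos[first]
    all_mat = all_mat[first]
    # keep only variable sites
    poly = all_mat.any(axis=1)
    all_pos = all_pos[poly]
    all_mat = all_mat[poly]

    panel = SitePanel(
        chrom="1",
        positions=all_pos.astype(np.int64),
        alleles=all_mat.astype(np.int8),
        haplotypes=haps,
        roles=roles,
        ref=np.full(len(all_pos), "A"),
        alt=np.full(len(all_pos), "G"),
        aa=np.full(len(all_pos), "A"),
        chrom_length=L,
    )
    truth = TruthTracts(truth_df[TruthTracts.COLUMNS])
    return panel, truth


def scenario_map(cfg: ScenarioConfig) -> GeneticMap:
    """Constant-rate genetic map matching the scenario's recombination rate."""
    return GeneticMap.constant_rate(cfg.length_bp, cfg.recomb * 1e8)


# ---------------------------------------------------------------------------
# Preset scenario grids
# ---------------------------------------------------------------------------

def standard_scenario(seed: int, length_bp: int = 10_000_000,
                      n_test: int = 20) -> ScenarioConfig:
    """The standard single-pulse benchmark: 2% archaic at 2000 generations."""
    return ScenarioConfig(seed=seed, length_bp=length_bp, n_test=n_test,
                          waves=[("NEA", 2000.0, 0.02)], name="standard-one-wave")


def unknown_lineage_scenario(seed: int, t_split_kya: float = 610.0,
                             length_bp: int = 10_000_000,
                             n_test: int = 20) -> ScenarioConfig:
    """Introgression from a lineage absent from the reference panel."""
    return ScenarioConfig(seed=seed, length_bp=length_bp, n_test=n_test,
                          t_unknown_kya=t_split_kya,
                          waves=[("UNK", 2000.0, 0.02)],
                          name=f"unknown-{t_split_kya:g}kya")


def two_lineage_scenario(seed: int, length_bp: int = 20_000_000,
                         n_test: int = 20) -> ScenarioConfig:
    """Simultaneous introgression from both archaic reference lineages."""
    return ScenarioConfig(seed=seed, length_bp=length_bp, n_test=n_test,
                          waves=[("NEA", 2000.0, 0.015), ("DEN", 1500.0, 0.01)],
                          name="two-lineage")


def preset_scenarios(family: str, seed: int = 1) -> list[ScenarioConfig]:
    """The four scenario families of the benchmark grid (144 in total).

    Families: ``one-wave`` (36), ``two-wave-one-lineage`` (48),
    ``two-wave-two-lineage`` (36), ``unknown-lineage`` (24).  The grids
    approximate the benchmark scenario families this package's
    evaluation study is built on; per-config seeds derive from ``seed``.
    """
    configs: list[ScenarioConfig] = []
    if family == "one-wave":
        for lin in ("NEA", "DEN"):
            for t in (500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0):
                for m in (0.005, 0.01, 0.02):
                    configs.append(ScenarioConfig(
                        seed=0, length_bp=20_000_000, n_test=20,
                        waves=[(lin, t, m)],
                        name=f"one-wave-{lin}-t{t:g}-m{m:g}"))
    elif family == "two-wave-one-lineage":
        # time separations from well-resolved (6x) down to the close,
        # one-wave-dominant settings where simplification to K=1 is the
        # expected failure mode
        tpairs = [(3000.0, 500.0), (2500.0, 800.0), (3500.0, 1000.0),
                  (2500.0, 1200.0)]
        mpairs = [(0.01, 0.01), (0.02, 0.01), (0.01, 0.02),
                  (0.005, 0.015), (0.015, 0.005), (0.02, 0.02)]
        for lin in ("NEA", "DEN"):
            for t1, t2 in tpairs:
                for m1, m2 in mpairs:
                    configs.append(ScenarioConfig(
                        seed=0, length_bp=55_000_000, n_test=36,
                        waves=[(lin, t1, m1), (lin, t2, m2)],
                        name=f"two-wave-{lin}-t{t1:g}/{t2:g}-m{m1:g}/{m2:g}"))
    elif family == "two-wave-two-lineage":
        tpairs = [(2000.0, 1000.0), (2500.0, 1200.0), (3000.0, 800.0)]
        mpairs = [(0.02, 0.005), (0.015, 0.01), (0.01, 0.01), (0.02, 0.02)]
        for t_nd in (350.0, 450.0, 550.0):
            for tn, td in tpairs:
                for mn, md in mpairs:
                    configs.append(ScenarioConfig(
                        seed=0, length_bp=40_000_000, n_test=30, t_nd_kya=t_nd,
                        waves=[("NEA", tn, mn), ("DEN", td, md)],
                        name=f"two-lin-nd{t_nd:g}-t{tn:g}/{td:g}-m{mn:g}/{md:g}"))
    elif family == "unknown-lineage":
        for ts in (150.0, 250.0, 350.0, 450.0, 530.0, 610.0):
            for t in (1000.0, 2000.0):
                for m in (0.01, 0.02):
                    configs.append(ScenarioConfig(
                        seed=0, length_bp=50_000_000, n_test=30,
                        t_unknown_kya=ts, waves=[("UNK", t, m)],
                        name=f"unknown-ts{ts:g}-t{t:g}-m{m:g}"))
    else:
        raise ValueError(f"unknown scenario family {family!r}")
    return [replace(c, seed=int(seed) * 1000 + i) for i, c in enumerate(configs)]
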