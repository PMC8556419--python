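"""Shared genomic data model and file I/O.

The central container is :class:`SitePanel`: phased biallelic alleles at
ordered sites on one chromosome, with physical (bp) and genetic (Morgan)
coordinates and a role attached to every haplotype.  Roles are

* ``test``              -- haplotypes screened for archaic introgression,
* ``african_ref``       -- modern-human (African) reference haplotypes,
* ``archaic_ref:<NAME>``-- archaic reference haplotypes (e.g. Neanderthal),
* ``outgroup``          -- distant outgroup used to set ancestral states
  and to root the reference tree.

Coordinates are 0-based half-open everywhere internally and in BED output;
the 1-based VCF convention is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # allele code for missing genotype

ROLE_TEST = "test"
ROLE_AFRICAN = "african_ref"
ROLE_ARCHAIC_PREFIX = "archaic_ref:"
ROLE_OUTGROUP = "outgroup"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SitePanel:
    """Phased biallelic sites for a set of role-annotated haplotypes.

    ``alleles`` is an int8 matrix of shape (n_sites, n_haplotypes) with
    codes 0/1/-1.  Before :func:`polarize` the codes mean REF/ALT; after,
    they mean ancestral/derived (``polarized`` flips to True).
    """

    chrom: str
    positions: np.ndarray          # int64 bp, strictly increasing
    alleles: np.ndarray            # int8 (n_sites, n_hap)
    haplotypes: list[str]          # haplotype ids, e.g. "NA001_0"
    roles: dict[str, str]          # haplotype id -> role
    genetic_pos: np.ndarray | None = None   # Morgans, non-decreasing
    ref: np.ndarray | None = None  # per-site REF base (unicode array)
    alt: np.ndarray | None = None  # per-site ALT base
    aa: np.ndarray | None = None   # per-site ancestral base if known ('N' if not)
    polarized: bool = False
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.positions), len(self.haplotypes)):
            raise ValueError("alleles shape does not match sites x haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        missing_roles = [h for h in self.haplotypes if h not in self.roles]
        if missing_roles:
            raise ValueError(f"haplotypes without a role: {missing_roles[:5]}")

    # -- role helpers -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def hap_indices(self, role: str) -> np.ndarray:
        """Indices of haplotypes with exactly this role."""
        return np.asarray(
            [i for i, h in enumerate(self.haplotypes) if self.roles[h] == role],
            dtype=np.int64,
        )

    def archaic_names(self) -> list[str]:
        names: list[str] = []
        for h in self.haplotypes:
            r = self.roles[h]
            if r.startswith(ROLE_ARCHAIC_PREFIX):
                name = r[len(ROLE_ARCHAIC_PREFIX):]
                if name not in names:
                    names.append(name)
        return names

    def archaic_indices(self, name: str | None = None) -> np.ndarray:
        if name is None:
            return np.asarray(
                [i for i, h in enumerate(self.haplotypes)
                 if self.roles[h].startswith(ROLE_ARCHAIC_PREFIX)],
                dtype=np.int64,
            )
        return self.hap_indices(ROLE_ARCHAIC_PREFIX + name)

    def subset_sites(self, mask: np.ndarray) -> "SitePanel":
        def take(a):
            return None if a is None else a[mask]
        return replace(
            self,
            positions=self.positions[mask],
            alleles=self.alleles[mask],
            genetic_pos=take(self.genetic_pos),
            ref=take(self.ref),
            alt=take(self.alt),
            aa=take(self.aa),
        )

    @property
    def length(self) -> int:
        """Chromosome length in bp (declared, or past the last site)."""
        if self.chrom_length is not None:
            return self.chrom_length
        return int(self.positions[-1]) + 1 if self.n_sites else 0


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: anchor bp -> cumulative cM.

    Interpolation is linear between anchors; extrapolation beyond either
    end continues at the nearest flanking recombination rate.
    """

    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self) -> None:
        self.anchors_bp = np.asarray(self.anchors_bp, dtype=np.float64)
        self.anchors_cm = np.asarray(self.anchors_cm, dtype=np.float64)
        if len(self.anchors_bp) < 2:
            raise ValueError("genetic map needs at least two anchors")
        if np.any(np.diff(self.anchors_bp) <= 0):
            raise ValueError("map anchor positions must be strictly increasing")
        if np.any(np.diff(self.anchors_cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")

    @classmethod
    def constant_rate(cls, length_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls(np.array([0.0, float(length_bp)]),
                   np.array([0.0, length_bp / 1e6 * cm_per_mb]))

    @classmethod
    def read(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["pos", "cm"], dtype=str)
        # tolerate a single header line of column names
        try:
            float(df.iloc[0, 0])
        except ValueError:
            df = df.iloc[1:]
        return cls(df["pos"].astype(float).to_numpy(),
                   df["cm"].astype(float).to_numpy())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for p, c in zip(self.anchors_bp, self.anchors_cm):
                fh.write(f"{int(p)}\t{c:.8f}\n")

    def interpolate_cm(self, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.float64)
        cm = np.interp(pos, self.anchors_bp, self.anchors_cm)
        # rate-continued extrapolation at both ends
        left = pos < self.anchors_bp[0]
        right = pos > self.anchors_bp[-1]
        if np.any(left):
            r = ((self.anchors_cm[1] - self.anchors_cm[0])
                 / (self.anchors_bp[1] - self.anchors_bp[0]))
            cm[left] = self.anchors_cm[0] + (pos[left] - self.anchors_bp[0]) * r
        if np.any(right):
            r = ((self.anchors_cm[-1] - self.anchors_cm[-2])
                 / (self.anchors_bp[-1] - self.anchors_bp[-2]))
            cm[right] = self.anchors_cm[-1] + (pos[right] - self.anchors_bp[-1]) * r
        return cm

    def interpolate_morgans(self, positions) -> np.ndarray:
        return self.interpolate_cm(positions) / 100.0


@dataclass
class Segment:
    """One decoded interval on one test haplotype, 0-based half-open."""

    chrom: str
    start: int
    end: int
    haplotype: str
    state: str = "archaic"
    mean_posterior: float = float("nan")
    n_snps: int = 0
    label: str | None = None          # filled by the matcher
    split_time_kya: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_manifest(path) -> dict[str, str]:
    """Read the sample->role manifest TSV (two columns, no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sample", "role"], dtype=str)
    if df.iloc[0]["sample"].lower() == "sample":
        df = df.iloc[1:]
    return dict(zip(df["sample"], df["role"]))


def write_manifest(roles: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, role in roles.items():
            fh.write(f"{sample}\t{role}\n")


def read_phased_panel(vcf_path, manifest: dict[str, str] | str | Path) -> SitePanel:
    """Load a phased biallelic VCF into a :class:`SitePanel`.

    Multi-allelic, non-SNV and unphased sites are dropped (with a logged
    count).  Every sample named in the manifest must be present.
    """
    from cyvcf2 import VCF

    if not isinstance(manifest, dict):
        manifest = read_manifest(manifest)

    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in manifest if s not in vcf_samples]
    if missing:
        raise ValueError(f"samples in manifest but not in VCF: {missing}")
    sample_idx = {s: vcf_samples.index(s) for s in manifest}

    positions: list[int] = []
    rows: list[np.ndarray] = []
    refs: list[str] = []
    alts: list[str] = []
    aas: list[str] = []
    chrom = None
    dropped = 0
    last_pos = -1
    samples = list(manifest)
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("panel must contain a single chromosome")
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            dropped += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1), last col phased flag
        row = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for j, s in enumerate(samples):
            g = gts[sample_idx[s]]
            if g[0] >= 0 and g[1] >= 0 and g[0] != g[1] and not g[2]:
                ok = False  # unphased heterozygote: haplotypes unresolvable
                break
            row[2 * j] = g[0] if g[0] >= 0 else MISSING
            row[2 * j + 1] = g[1] if g[1] >= 0 else MISSING
        if not ok:
            dropped += 1
            continue
        pos0 = var.POS - 1
        if pos0 <= last_pos:
            raise ValueError(f"VCF not sorted/unique at {var.CHROM}:{var.POS}")
        last_pos = pos0
        positions.append(pos0)
        rows.append(row)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        aa = var.INFO.get("AA")
        aas.append(aa if aa else "N")
    if dropped:
        log.info("dropped %d multi-allelic/non-SNV/unphased sites", dropped)

    haplotypes = [f"{s}_{k}" for s in samples for k in (0, 1)]
    roles = {f"{s}_{k}": manifest[s] for s in samples for k in (0, 1)}
    panel = SitePanel(
        chrom=chrom or "1",
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.asarray(rows, dtype=np.int8).reshape(len(positions), -1),
        haplotypes=haplotypes,
        roles=roles,
        ref=np.asarray(refs),
        alt=np.asarray(alts),
        aa=np.asarray(aas),
    )
    panel.n_dropped_sites = dropped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: SitePanel, path) -> None:
    """Write a (pre-polarization) panel as a minimal phased VCF.

    Haplotype pairs ``<sample>_0/<sample>_1`` become diploid samples; the
    ancestral base, when known, goes into the AA INFO tag.
    """
    if panel.n_haplotypes % 2:
        raise ValueError("VCF output needs an even number of haplotypes")
    samples = [panel.haplotypes[i][:-2] for i in range(0, panel.n_haplotypes, 2)]
    ref = panel.ref if panel.ref is not None else np.full(panel.n_sites, "A")
    alt = panel.alt if panel.alt is not None else np.full(panel.n_sites, "G")
    aa = panel.aa if panel.aa is not None else np.full(panel.n_sites, "N")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={panel.length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        A = panel.alleles
        for i in range(panel.n_sites):
            gts = []
            for j in range(0, panel.n_haplotypes, 2):
                a, b = A[i, j], A[i, j + 1]
                gts.append(f"{a if a >= 0 else '.'}|{b if b >= 0 else '.'}")
            fh.write(f"{panel.chrom}\t{panel.positions[i] + 1}\t.\t{ref[i]}\t{alt[i]}"
                     f"\t.\tPASS\tAA={aa[i]}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Polarization and map attachment
# ---------------------------------------------------------------------------

def polarize(panel: SitePanel, ancestral_source="outgroup") -> SitePanel:
    """Re-express allele codes as ancestral(0)/derived(1).

    ``ancestral_source`` is one of

    * ``"outgroup"`` -- use the panel's outgroup haplotype(s),
    * ``"AA"``       -- use the AA INFO field carried from the VCF,
    * a FASTA path   -- look the ancestral base up by position.

    Sites whose ancestral allele matches neither REF nor ALT (or is
    unresolvable, e.g. 'N') are dropped and counted.
    """
    if panel.polarized:
        return panel
    n = panel.n_sites
    anc_base = None
    if ancestral_source == "outgroup":
        out_idx = panel.hap_indices(ROLE_OUTGROUP)
        if len(out_idx) == 0:
            raise ValueError("no outgroup haplotype in panel")
        out = panel.alleles[:, out_idx]
        # consensus across outgroup haplotypes; missing/conflicting -> drop
        anc_code = np.full(n, MISSING, dtype=np.int8)
        valid = np.all((out == out[:, :1]) & (out >= 0), axis=1)
        anc_code[valid] = out[valid, 0]
    else:
        if ancestral_source == "AA":
            if panel.aa is None:
                raise ValueError("panel has no AA field")
            anc_base = np.char.upper(panel.aa.astype(str))
        else:  # FASTA path
            from pyfaidx import Fasta
            fa = Fasta(str(ancestral_source))
            seq = str(fa[panel.chrom][:]).upper()
            anc_base = np.asarray([seq[p] if p < len(seq) else "N"
                                   for p in panel.positions])
        anc_code = np.full(n, MISSING, dtype=np.int8)
        if panel.ref is None or panel.alt is None:
            raise ValueError("panel lacks REF/ALT bases needed for base polarization")
        anc_code[anc_base == np.char.upper(panel.ref.astype(str))] = 0
        anc_code[anc_base == np.char.upper(panel.alt.astype(str))] = 1

    keep = anc_code >= 0
    n_drop = int(np.sum(~keep))
    if n_drop:
        log.info("polarize: dropped %d sites with unresolvable ancestral state", n_drop)
    sub = panel.subset_sites(keep)
    flip_rows = np.where(anc_code[keep] == 1)[0]
    A = sub.alleles.copy()
    block = A[flip_rows]
    A[flip_rows] = np.where(block >= 0, 1 - block, MISSING)
    out = replace(sub, alleles=A, polarized=True)
    out.n_dropped_sites = n_drop  # type: ignore[attr-defined]
    return out


def attach_genetic_map(panel: SitePanel, gmap: GeneticMap | None = None,
                       cm_per_mb: float = 1.0) -> SitePanel:
    """Fill ``genetic_pos`` (Morgans); default is a constant 1 cM/Mb."""
    if gmap is None:
        gmap = GeneticMap.constant_rate(max(panel.length, 1), cm_per_mb)
    gp = gmap.interpolate_morgans(panel.positions)
    gp = np.maximum.accumulate(gp)
    return replace(panel, genetic_pos=gp)


# ---------------------------------------------------------------------------
# Segment tables
# ---------------------------------------------------------------------------

_SEG_COLS = ["chrom", "start", "end", "haplotype", "state",
             "mean_posterior", "n_snps", "label", "split_time_kya"]


def _check_disjoint(segments: list[Segment]) -> None:
    by_hap: dict[str, list[Segment]] = {}
    for s in segments:
        by_hap.setdefault(s.haplotype, []).append(s)
    for hap, segs in by_hap.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments on haplotype {hap}: "
                                 f"[{a.start},{a.end}) and [{b.start},{b.end})")


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    rows = [{c: getattr(s, c) for c in _SEG_COLS} for s in segments]
    return pd.DataFrame(rows, columns=_SEG_COLS)


def write_segments(segments: list[Segment], prefix) -> tuple[Path, Path]:
    """Write a BED file plus a TSV sidecar with full per-segment detail.

    Refuses overlapping segments on one haplotype (container invariant).
    """
    _check_disjoint(segments)
    prefix = Path(prefix)
    bed = prefix.parent / (prefix.name + ".bed")
    tsv = prefix.parent / (prefix.name + ".tsv")
    df = segments_to_frame(segments)
    df.sort_values(["haplotype", "start"], inplace=True, kind="stable")
    with open(bed, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.haplotype}\n")
    df.to_csv(tsv, sep="\t", index=False, na_rep="NA")
    return bed, tsv


def read_segments(path) -> list[Segment]:
    """Read the TSV sidecar back into Segment objects."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(_SEG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    out: list[Segment] = []
    for i, r in df.iterrows():
        try:
            out.append(Segment(
                chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                haplotype=str(r.haplotype), state=str(r.state),
                mean_posterior=float(r.mean_posterior),
                n_snps=int(r.n_snps),
                label=None if pd.isna(r.label) else str(r.label),
                split_time_kya=None if pd.isna(r.split_time_kya)
                else float(r.split_time_kya),
            ))
        except (ValueError, TypeError) as err:
            raise ValueError(f"malformed segment row at line {i + 2}: {err}") from err
    return out
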