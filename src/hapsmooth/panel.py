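"""Haplotype panel container and I/O.

A phased, biallelic haplotype panel is an M x N binary matrix: M haplotype
rows (two per diploid sample, sample ``j`` contributing rows ``2j`` and
``2j+1``) and N variant-site columns in increasing genomic order.  Sites are
0-based and all intervals throughout the package are half-open ``[start,
end)``.

Supported formats: VCF (phased diploid GT, via pysam), a plain 0/1 text
matrix (one haplotype per line), and genetic maps in the PLINK ``.map`` and
HapMap-rate dialects for bp -> cM interpolation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam


class PanelFormatError(ValueError):
    """Raised when an input file violates the panel contracts."""


@dataclasses.dataclass(frozen=True)
class SiteInfo:
    """Metadata for one variant site."""

    chrom: str
    pos_bp: int
    cm: float = 0.0
    id: str = "."


@dataclasses.dataclass(eq=False)
class HaplotypePanel:
    """M x N matrix of 0/1 alleles with per-haplotype and per-site metadata.

    ``alleles`` is haplotype-major (row = haplotype).  Construction
    validates the core invariants: binary alleles, consistent shapes,
    strictly increasing bp positions and non-decreasing cM.
    """

    alleles: np.ndarray
    hap_ids: list[str]
    sites: list[SiteInfo]

    def __post_init__(self) -> None:
        a = np.ascontiguousarray(self.alleles, dtype=np.int8)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise PanelFormatError(f"alleles must be a non-empty 2-D matrix, got shape {a.shape}")
        if not ((a == 0) | (a == 1)).all():
            raise PanelFormatError("alleles must be 0 or 1")
        object.__setattr__(self, "alleles", a)
        if len(self.hap_ids) != a.shape[0]:
            raise PanelFormatError(
                f"{len(self.hap_ids)} haplotype ids for {a.shape[0]} rows"
            )
        if len(self.sites) != a.shape[1]:
            raise PanelFormatError(f"{len(self.sites)} sites for {a.shape[1]} columns")
        bp = np.array([s.pos_bp for s in self.sites], dtype=np.int64)
        if bp.size > 1 and not (np.diff(bp) > 0).all():
            raise PanelFormatError("site bp positions must be strictly increasing")
        cm = np.array([s.cm for s in self.sites], dtype=np.float64)
        if cm.size > 1 and not (np.diff(cm) >= 0).all():
            raise PanelFormatError("site cM positions must be non-decreasing")
        self._bp = bp
        self._cm = cm

    # -- basic geometry -------------------------------------------------
    @property
    def M(self) -> int:
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        return self.alleles.shape[1]

    @property
    def pos_bp(self) -> np.ndarray:
        return self._bp

    @property
    def cm(self) -> np.ndarray:
        return self._cm

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles.copy(), list(self.hap_ids), list(self.sites))

    def with_alleles(self, alleles: np.ndarray) -> "HaplotypePanel":
        """Same metadata, new allele matrix (shape-checked)."""
        if alleles.shape != self.alleles.shape:
            raise PanelFormatError("replacement allele matrix has a different shape")
        return HaplotypePanel(alleles, list(self.hap_ids), list(self.sites))

    def with_genetic_map(self, gmap: "GeneticMap") -> "HaplotypePanel":
        """Return a panel whose site cM values are interpolated from ``gmap``."""
        cms = interpolate_cm(gmap, self.pos_bp)
        sites = [dataclasses.replace(s, cm=float(c)) for s, c in zip(self.sites, cms)]
        return HaplotypePanel(self.alleles.copy(), list(self.hap_ids), sites)


def default_hap_ids(sample_names: Sequence[str]) -> list[str]:
    return [f"{s}_{i}" for s in sample_names for i in (0, 1)]


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased, diploid, biallelic single-chromosome VCF.

    Unphased, multiallelic or missing genotypes are hard errors (no silent
    filtering), so a panel read from disk is reproducible.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise PanelFormatError(f"{path}: VCF has no samples")
    cols: list[np.ndarray] = []
    sites: list[SiteInfo] = []
    chrom_seen: str | None = None
    for rec in vf:
        where = f"{rec.chrom}:{rec.pos}"
        if chrom_seen is None:
            chrom_seen = rec.chrom
        elif rec.chrom != chrom_seen:
            raise PanelFormatError(f"{path}: multiple chromosomes ({chrom_seen}, {rec.chrom})")
        if rec.alts is None or len(rec.alts) != 1:
            raise PanelFormatError(f"{path}: record {where} is not biallelic")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for j, name in enumerate(samples):
            call = rec.samples[name]
            gt = call["GT"]
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                raise PanelFormatError(f"{path}: record {where} sample {name}: missing or non-diploid GT")
            if not call.phased:
                raise PanelFormatError(f"{path}: record {where} sample {name}: unphased genotype")
            if gt[0] not in (0, 1) or gt[1] not in (0, 1):
                raise PanelFormatError(f"{path}: record {where} sample {name}: allele outside {{0,1}}")
            col[2 * j] = gt[0]
            col[2 * j + 1] = gt[1]
        cols.append(col)
        sites.append(SiteInfo(chrom=rec.chrom, pos_bp=rec.pos, id=rec.id or "."))
    vf.close()
    if not cols:
        raise PanelFormatError(f"{path}: VCF contains no records")
    alleles = np.stack(cols, axis=1)
    return HaplotypePanel(alleles, default_hap_ids(samples), sites)


def write_vcf(panel: HaplotypePanel, template_path: str | Path, out_path: str | Path) -> None:
    """Write ``panel`` as a VCF by replacing GT fields of a template VCF.

    The template must have the same number of sites and samples as the
    panel; everything except the GT alleles is carried over verbatim, so
    ``read_vcf(write_vcf(p))`` round-trips ``p.alleles`` exactly.
    """
    inp = pysam.VariantFile(str(template_path))
    samples = list(inp.header.samples)
    if 2 * len(samples) != panel.M:
        inp.close()
        raise PanelFormatError(
            f"template has {len(samples)} samples but panel has {panel.M} haplotypes"
        )
    out = pysam.VariantFile(str(out_path), "w", header=inp.header)
    k = 0
    try:
        for rec in inp:
            if k >= panel.N:
                raise PanelFormatError(
                    f"template has more records than panel sites ({panel.N})"
                )
            for j, name in enumerate(samples):
                rec.samples[name]["GT"] = (
                    int(panel.alleles[2 * j, k]),
                    int(panel.alleles[2 * j + 1, k]),
                )
                rec.samples[name].phased = True
            out.write(rec)
            k += 1
        if k != panel.N:
            raise PanelFormatError(f"template has {k} records but panel has {panel.N} sites")
    finally:
        inp.close()
        out.close()


# ---------------------------------------------------------------------------
# Plain matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    chrom: str = "1",
    default_cm_per_site: float = 0.0,
) -> HaplotypePanel:
    """Read a plain text panel: one haplotype per line, characters in {0,1}.

    Sites are given synthetic 1-bp-spaced positions; cM defaults to
    ``index * default_cm_per_site`` (0 unless configured — genetic distance
    is never invented silently).
    """
    rows: list[np.ndarray] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if set(line) - {"0", "1"}:
                raise PanelFormatError(f"{path}: line {lineno}: characters outside {{0,1}}")
            if width is None:
                width = len(line)
            elif len(line) != width:
                raise PanelFormatError(
                    f"{path}: line {lineno}: ragged row (length {len(line)}, expected {width})"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise PanelFormatError(f"{path}: empty matrix file")
    alleles = np.stack(rows).astype(np.int8)
    sites = [
        SiteInfo(chrom=chrom, pos_bp=k + 1, cm=k * default_cm_per_site)
        for k in range(alleles.shape[1])
    ]
    hap_ids = [f"hap{i}" for i in range(alleles.shape[0])]
    return HaplotypePanel(alleles, hap_ids, sites)


def write_matrix(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in panel.alleles:
            fh.write("".join("1" if v else "0" for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Ordered (pos_bp, cM) anchors; bp strictly increasing, cM non-decreasing."""

    anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise PanelFormatError("genetic map has no anchors")
        bp = np.array([a[0] for a in self.anchors], dtype=np.int64)
        cm = np.array([a[1] for a in self.anchors], dtype=np.float64)
        if bp.size > 1 and not (np.diff(bp) > 0).all():
            raise PanelFormatError("genetic map bp positions must be strictly increasing")
        if cm.size > 1 and not (np.diff(cm) >= 0).all():
            raise PanelFormatError("genetic map cM must be non-decreasing")
        object.__setattr__(self, "_bp", bp)
        object.__setattr__(self, "_cm", cm)


def interpolate_cm(gmap: GeneticMap, positions: Iterable[int]) -> np.ndarray:
    """Piecewise-linear bp -> cM; constant extrapolation outside the anchors."""
    pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
    return np.interp(pos, gmap._bp, gmap._cm)


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a genetic map: PLINK ``.map`` (chrom id cM bp, headerless) or a
    HapMap-style rate file (header line naming a bp position column and a
    cM map column).  The dialect is auto-detected from the first line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise PanelFormatError(f"{path}: empty genetic map")
    first = lines[0].replace(",", " ").split()

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    anchors: list[tuple[int, float]] = []
    plink_like = (
        len(first) == 4
        and _is_number(first[2])
        and _is_number(first[3])
        and float(first[3]) == int(float(first[3]))
    )
    if plink_like:
        # headerless 4-column PLINK .map: chrom, id, cM, bp
        for ln in lines:
            toks = ln.split()
            if len(toks) != 4:
                raise PanelFormatError(f"{path}: expected 4 columns in PLINK .map line: {ln!r}")
            anchors.append((int(toks[3]), float(toks[2])))
    else:
        # HapMap-style with header: find bp and cM columns by name
        header = [h.lower() for h in lines[0].split()]
        try:
            bp_col = next(i for i, h in enumerate(header) if "position" in h or h in ("bp", "pos"))
            cm_col = next(i for i, h in enumerate(header) if "map" in h and "cm" in h or h.endswith("(cm)"))
        except StopIteration:
            raise PanelFormatError(f"{path}: cannot identify bp/cM columns in header {lines[0]!r}")
        for ln in lines[1:]:
            toks = ln.split()
            anchors.append((int(float(toks[bp_col])), float(toks[cm_col])))
    anchors.sort()
    return GeneticMap(tuple(anchors))
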