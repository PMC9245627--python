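"""Synthetic panels with known ground truth.

Two generators:

* ``simulate_coalescent_panel`` — a neutral coalescent panel (msprime)
  under a European-style recent-growth demography, restricted to common
  sites (MAF >= 0.1, the regime in which blocky haplotype sharing and the
  smoothing prior operate), with ground-truth pairwise IBD segments
  extracted from the tree sequence (tskit) and mapped into retained-site
  coordinates.
* ``generate_copy_group_panel`` — a download-free fixture: groups of exact
  haplotype copies over planted intervals on independent random
  backgrounds, so the true clusters are known by construction.

Plus genotype-level error injection: each genotype-site cell is hit
independently with the given rate, flipping one uniformly chosen allele of
that individual — the error process of array/sequencing genotyping
pipelines, acting on genotypes rather than haplotypes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np

from .cluster import IbdCluster
from .evaluation import TrueSegment
from .panel import HaplotypePanel, SiteInfo


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Coalescent / copy-group simulation settings.

    Defaults are the benchmarking conditions used throughout: 4000
    haplotypes over a 10 Mb human-like region, flat 1e-8 recombination and
    mutation (so 1 cM = 1 Mb), common sites only (MAF >= 0.1).

    Ground-truth pairwise IBD is extracted from the tree sequence in one
    of two modes.  ``horizon`` (default): every tract on which a pair
    shares a common ancestor within ``ibd_horizon_gens`` generations — the
    standard time-horizon definition of IBD, under which per-site
    relatedness classes are clades, so multiway ground truth is
    well-defined.  ``span``: every same-ancestor tract of genetic length
    >= ``min_segment_cm`` regardless of age; note that long same-ancestor
    tracts require very recent coalescence, so under growth demographies
    this mode yields few segments and essentially no multiway truth.
    """

    mode: Literal["coalescent", "copy_group"] = "coalescent"
    n_haps: int = 4000
    region_bp: int = 10_000_000
    maf_min: float = 0.1
    error_rate: float = 0.0
    seed: int = 1
    recombination_rate: float = 1e-8
    mutation_rate: float = 1e-8
    ibd_extraction: Literal["horizon", "span"] = "horizon"
    ibd_horizon_gens: float = 300.0
    min_segment_cm: float = 1.0
    demography: Literal["european_growth", "constant"] = "european_growth"
    constant_ne: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.n_haps % 2 != 0:
            raise ValueError("n_haps must be even (two haplotypes per individual)")


@dataclasses.dataclass
class ErrorSet:
    """Ground-truth injected flips: (hap, site) -> original allele."""

    flips: dict[tuple[int, int], int]

    def __len__(self) -> int:
        return len(self.flips)


def _european_growth_demography():
    """Single-population European-style size history (Tennessen-type):
    ancestral 7,310; 14,474 from 5,920 generations ago; out-of-Africa
    bottleneck 1,861 from 2,040; 0.307%/gen growth from 920 (size 1,032 at
    epoch start); 1.95%/gen growth from 205 (size 9,300) to ~512k today."""
    import msprime

    d = msprime.Demography()
    d.add_population(name="EUR", initial_size=512_000, growth_rate=0.0195)
    d.add_population_parameters_change(time=205, initial_size=9_300, growth_rate=0.00307)
    d.add_population_parameters_change(time=920, initial_size=1_861, growth_rate=0.0)
    d.add_population_parameters_change(time=2_040, initial_size=14_474)
    d.add_population_parameters_change(time=5_920, initial_size=7_310)
    return d


def simulate_coalescent_panel(cfg: SimConfig) -> tuple[HaplotypePanel, list[TrueSegment]]:
    """Simulate a panel and its ground-truth pairwise IBD segments.

    Returns the MAF-filtered panel (site cM from the flat recombination
    map) and the ground-truth pairwise tracts covering at least 2 retained
    sites, in retained-site half-open coordinates (see :class:`SimConfig`
    for the two extraction modes).  Deterministic given ``cfg.seed``.
    """
    try:
        import msprime
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "msprime is unavailable; use mode='copy_group' via generate_copy_group_panel"
        ) from exc

    ss = np.random.SeedSequence(cfg.seed)
    seed_anc, seed_mut, _ = (int(s.generate_state(1)[0] % (2**31 - 2)) + 1 for s in ss.spawn(3))
    demography = (
        _european_growth_demography()
        if cfg.demography == "european_growth"
        else msprime.Demography.isolated_model([cfg.constant_ne])
    )
    ts = msprime.sim_ancestry(
        samples=cfg.n_haps // 2,
        demography=demography,
        sequence_length=cfg.region_bp,
        recombination_rate=cfg.recombination_rate,
        random_seed=seed_anc,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=seed_mut,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )
    G = mts.genotype_matrix()  # sites x haps, values in {0, 1}
    pos = mts.tables.sites.position.astype(np.int64)
    freq = G.mean(axis=1)
    keep = np.minimum(freq, 1 - freq) >= cfg.maf_min
    # positions must be strictly increasing after discretisation
    keep &= np.concatenate([[True], np.diff(pos) > 0])
    kept_pos = pos[keep]
    alleles = np.ascontiguousarray(G[keep].T.astype(np.int8))
    cm_per_bp = cfg.recombination_rate * 100.0  # Morgans/bp -> cM/bp
    sites = [
        SiteInfo(chrom="1", pos_bp=int(p) + 1, cm=float(p) * cm_per_bp, id=f"site{i}")
        for i, p in enumerate(kept_pos)
    ]
    hap_ids = [f"tsk{j}_{i}" for j in range(cfg.n_haps // 2) for i in (0, 1)]
    panel = HaplotypePanel(alleles, hap_ids, sites)

    segments: list[TrueSegment] = []
    if cfg.ibd_extraction == "horizon":
        ibd = mts.ibd_segments(
            max_time=cfg.ibd_horizon_gens, store_pairs=True, store_segments=True
        )
    else:
        ibd = mts.ibd_segments(
            min_span=cfg.min_segment_cm / cm_per_bp, store_pairs=True, store_segments=True
        )
    for pair, seglist in ibd.items():
        a, b = int(pair[0]), int(pair[1])
        for seg in seglist:
            s = int(np.searchsorted(kept_pos, seg.left, side="left"))
            e = int(np.searchsorted(kept_pos, seg.right, side="left"))
            if e - s >= 2:
                segments.append(TrueSegment(min(a, b), max(a, b), s, e))
    return panel, segments


def generate_copy_group_panel(
    n_groups: int,
    group_width: int,
    n_sites: int,
    segment_spec: Sequence[tuple[int, int]] | tuple[int, int],
    seed: int,
    cm_per_site: float = 0.01,
) -> tuple[HaplotypePanel, list[IbdCluster]]:
    """Planted-cluster fixture: per group, an identical copied interval on
    otherwise independent Bernoulli(1/2) backgrounds.

    ``segment_spec`` is one (start, end) interval shared by all groups, or
    one interval per group.  Returns the panel and the planted clusters.
    Outside the planted intervals alleles are independent, so unintended
    long matches are exponentially unlikely in the interval spacing.
    """
    if group_width < 2:
        raise ValueError("group_width must be >= 2")
    if isinstance(segment_spec[0], int):
        intervals = [tuple(segment_spec)] * n_groups  # type: ignore[list-item]
    else:
        intervals = [tuple(iv) for iv in segment_spec]  # type: ignore[union-attr]
        if len(intervals) != n_groups:
            raise ValueError("need one interval per group")
    for s, e in intervals:
        if not (0 <= s < e <= n_sites):
            raise ValueError(f"interval [{s}, {e}) out of range for {n_sites} sites")
    rng = np.random.default_rng(seed)
    M = n_groups * group_width
    alleles = rng.integers(0, 2, size=(M, n_sites), dtype=np.int8)
    truth: list[IbdCluster] = []
    for gi, (s, e) in enumerate(intervals):
        rows = range(gi * group_width, (gi + 1) * group_width)
        template = alleles[gi * group_width, s:e]
        for r in rows:
            alleles[r, s:e] = template
        truth.append(
            IbdCluster(tuple(rows), s, e, cm_len=(e - 1 - s) * cm_per_site)
        )
    sites = [SiteInfo(chrom="1", pos_bp=k + 1, cm=k * cm_per_site) for k in range(n_sites)]
    hap_ids = [f"g{gi}_h{i}" for gi in range(n_groups) for i in range(group_width)]
    return HaplotypePanel(alleles, hap_ids, sites), truth


def inject_errors(
    panel: HaplotypePanel, rate: float, seed: int
) -> tuple[HaplotypePanel, ErrorSet]:
    """Flip one random allele of a random genotype at ``rate`` per
    genotype-site cell; expected flip count = rate * (M/2) * N."""
    if not (0.0 <= rate <= 0.05):
        raise ValueError("rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    M, N = panel.M, panel.N
    alleles = panel.alleles.copy()
    flips: dict[tuple[int, int], int] = {}
    if rate > 0:
        if M % 2 == 0:
            hit_g, hit_s = np.nonzero(rng.random((M // 2, N)) < rate)
            which = rng.integers(0, 2, size=hit_g.size)
            hit_h = 2 * hit_g + which
        else:
            warnings.warn("odd haplotype count: falling back to per-haplotype rate/2")
            hit_h, hit_s = np.nonzero(rng.random((M, N)) < rate / 2)
        for h, s in zip(hit_h, hit_s):
            old = int(alleles[h, s])
            alleles[h, s] = 1 - old
            flips[(int(h), int(s))] = old
    return panel.with_alleles(alleles), ErrorSet(flips)
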