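"""Panel smoothing: flip below-threshold minor alleles inside block gaps.

The IBD prior: if a haplotype's allele at site k disagrees with a large set
of haplotypes that match it exactly on both sides of k (the bidirectional
block), the disagreement is far more likely a genotyping error (or a very
recent/private mutation) than a recombination, so the minor allele is
flipped to the block majority.  Operationally, for every bidirectional
block of width |B| >= W and every gap site: let (zeros, ones) be the allele
counts among block members; if 0 < min(zeros, ones) <= |B| * rho, all
minority members are set to the majority allele.

The scan is single-pass: corrections applied at anchor k are visible to the
forward PBWT for all later columns, while reverse block assignments come
from one pass over the original panel.  Sites within L of either panel end
are never corrected (they lack one flank).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .bipbwt import BidirectionalBlock, _group_pairs, block_ids_from_state, reverse_block_table
from .panel import HaplotypePanel
from .pbwt import _pbwt_advance


@dataclasses.dataclass(frozen=True)
class SmootherParams:
    """Smoothing parameters.

    L : flank length in sites (default 20).
    W : minimum bidirectional-block width in haplotypes (default 20).
    g : gap size in sites (default 1).
    rho : block minor-allele-frequency threshold, in (0, 0.5) (default 0.05).
    strict_maf : use the strict comparison min < |B|*rho instead of the
        default non-strict min <= |B|*rho.
    frozen_input : ablation mode — the forward PBWT reads the original
        panel, so corrections do not feed later columns.
    spill_to_disk : keep the reverse block-ID table in a temporary
        memory-map instead of RAM.
    """

    L: int = 20
    W: int = 20
    g: int = 1
    rho: float = 0.05
    strict_maf: bool = False
    frozen_input: bool = False
    spill_to_disk: bool = False

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.W < 2:
            raise ValueError("W must be >= 2")
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if not (0.0 < self.rho < 0.5):
            raise ValueError("rho must lie in (0, 0.5)")


@dataclasses.dataclass(frozen=True)
class GapSiteCounts:
    """Allele counts at one gap site over one block's members."""

    zeros: int
    ones: int


@dataclasses.dataclass(frozen=True)
class Correction:
    """One flipped allele, with the block evidence that justified it."""

    hap: int
    site: int
    old_allele: int
    new_allele: int
    block_width: int
    k: int


def ibd_prior(b: int, counts: GapSiteCounts, W: int, rho: float) -> int:
    """Plausibility of allele value ``b`` given its reference set.

    Returns 0 (implausible) iff the reference set is large enough
    (|R| = zeros + ones >= W) and AF(b) < rho; returns 1 otherwise.  When
    both allele values map to 1 the caller keeps the observed value — the
    evidence is inconclusive.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    if b not in (0, 1):
        raise ValueError("allele must be 0 or 1")
    n = counts.zeros + counts.ones
    if n < W:
        return 1
    af = (counts.ones if b == 1 else counts.zeros) / n
    return 0 if af < rho else 1


def _correct_gap_site(
    work: np.ndarray,
    members_sorted: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    site: int,
    rho: float,
    strict: bool,
    k: int,
    log: list[np.ndarray],
) -> None:
    """Apply the correction rule at one gap site for many disjoint blocks.

    ``members_sorted`` concatenates the member haplotypes of every block;
    block ``i`` occupies ``members_sorted[starts[i]:starts[i]+sizes[i]]``.
    Vectorized over blocks via reduceat; mutates ``work`` in place and
    appends a (hap, site, old, width, k) record batch to ``log``.
    """
    if starts.size == 0:
        return
    vals = work[members_sorted, site]
    ones = np.add.reduceat(vals.astype(np.int64), starts)
    zeros = sizes - ones
    mn = np.minimum(zeros, ones)
    cut = sizes * rho
    qual = (mn > 0) & ((mn < cut) if strict else (mn <= cut))
    if not qual.any():
        return
    minority = np.where(ones < zeros, 1, 0)  # ties never qualify for rho < 0.5
    gid = np.repeat(np.arange(starts.size), sizes)
    flip = qual[gid] & (vals == minority[gid])
    if not flip.any():
        return
    haps = members_sorted[flip]
    old = vals[flip]
    work[haps, site] = 1 - old
    log.append(
        np.column_stack(
            [
                haps.astype(np.int64),
                np.full(haps.size, site, dtype=np.int64),
                old.astype(np.int64),
                sizes[gid][flip].astype(np.int64),
                np.full(haps.size, k, dtype=np.int64),
            ]
        )
    )


def smooth_block(
    block: BidirectionalBlock,
    panel: HaplotypePanel | np.ndarray,
    rho: float,
    strict_maf: bool = False,
) -> list[Correction]:
    """Apply the gap-site correction rule for a single bidirectional block.

    Mutates the panel's allele matrix in place and returns the corrections.
    """
    work = panel.alleles if isinstance(panel, HaplotypePanel) else panel
    members = np.fromiter(sorted(block.haps), dtype=np.int64)
    starts = np.array([0], dtype=np.int64)
    sizes = np.array([members.size], dtype=np.int64)
    log: list[np.ndarray] = []
    for site in range(*block.gap):
        _correct_gap_site(work, members, starts, sizes, site, rho, strict_maf, block.k, log)
    return _log_to_corrections(log)


def _log_to_corrections(log: list[np.ndarray]) -> list[Correction]:
    out: list[Correction] = []
    for batch in log:
        for hap, site, old, width, k in batch:
            out.append(Correction(int(hap), int(site), int(old), 1 - int(old), int(width), int(k)))
    return out


def _smooth_pass(
    panel: HaplotypePanel,
    params: SmootherParams,
    on_column: Callable[[int, np.ndarray], None] | None = None,
) -> tuple[np.ndarray, list[Correction]]:
    """Run the smoothing scan; return (smoothed allele matrix, corrections).

    ``on_column(k, column)`` is invoked once per site, in order, as soon as
    that column can no longer change — this is what lets cluster calling
    fuse into the same forward pass.
    """
    L, W, g, rho = params.L, params.W, params.g, params.rho
    orig = panel.alleles
    M, N = orig.shape
    work = orig.copy()
    if N < 2 * L + g:
        warnings.warn(f"panel has {N} sites < 2L+g = {2 * L + g}; nothing smoothed")
        if on_column is not None:
            for k in range(N):
                on_column(k, work[:, k])
        return work, []
    rev = reverse_block_table(orig, L, W, spill_to_disk=params.spill_to_disk)
    fwd_src = orig if params.frozen_input else work
    ppa = np.arange(M, dtype=np.int32)
    div = np.zeros(M, dtype=np.int32)
    log: list[np.ndarray] = []
    for k in range(N):
        if L <= k <= N - g - L:
            fids = block_ids_from_state(ppa, div, k, L, W)
            rids = rev[k + g].astype(np.int64)
            order, starts, sizes = _group_pairs(fids, rids, W)
            if starts.size:
                members = np.concatenate(
                    [order[st : st + sz] for st, sz in zip(starts, sizes)]
                ).astype(np.int64)
                cstarts = np.zeros(sizes.size, dtype=np.int64)
                np.cumsum(sizes[:-1], out=cstarts[1:])
                for site in range(k, k + g):
                    _correct_gap_site(
                        work, members, cstarts, sizes, site, rho, params.strict_maf, k, log
                    )
        # column k is final: the last anchor whose gap covers k is k itself
        if on_column is not None:
            on_column(k, work[:, k])
        ppa, div = _pbwt_advance(ppa, div, np.ascontiguousarray(fwd_src[:, k]), k)
    return work, _log_to_corrections(log)


def smooth_panel(
    panel: HaplotypePanel, params: SmootherParams | None = None
) -> tuple[HaplotypePanel, list[Correction]]:
    """Smooth a panel; returns (new smoothed panel, correction log).

    The input panel is not modified.  Sites in [0, L) and within L+g-1 of
    the right end are never corrected.
    """
    params = params or SmootherParams()
    work, corrections = _smooth_pass(panel, params)
    return panel.with_alleles(work), corrections


def write_corrections_tsv(
    corrections: Sequence[Correction], panel: HaplotypePanel, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("hap_id\tsite_index\tpos_bp\told_allele\tnew_allele\tblock_width\tanchor_k\n")
        for c in corrections:
            fh.write(
                f"{panel.hap_ids[c.hap]}\t{c.site}\t{panel.sites[c.site].pos_bp}\t"
                f"{c.old_allele}\t{c.new_allele}\t{c.block_width}\t{c.k}\n"
            )
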