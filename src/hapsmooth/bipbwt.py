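"""Bidirectional PBWT: block intersection across a gap.

A bidirectional block at anchor site k is a set of haplotypes identical
over a left flank [k-L, k) and a right flank [k+g, k+g+L), with no
agreement constraint on the g gap sites in between.  It is computed as the
element-wise intersection U(S, T) of the forward block partition S at site
k and the reverse block partition T at site k+g: haplotypes are keyed by
their (forward block ID, reverse block ID) pair and grouped by a radix-style
sort, so each anchor costs O(M).

Reverse block assignments for all sites are produced by one right-to-left
PBWT pass and kept as an (N+1) x M ID table — in memory by default, or
spilled to a temporary memory-map (``spill_to_disk``) so the forward scan's
working memory stays O(gM) beyond the panel itself.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
import warnings
from typing import Iterator, Sequence

import numpy as np

from .panel import HaplotypePanel
from .pbwt import _pbwt_advance


@dataclasses.dataclass
class BlockAssignment:
    """Per-haplotype block IDs at one site for one scan direction.

    Haplotypes sharing a non-negative ID form one width-qualifying match
    block; a haplotype in no qualifying block carries the unique sentinel
    ``-(hap_index + 1)`` so it can never co-sort into a spurious group.
    """

    k: int
    ids: np.ndarray


@dataclasses.dataclass(frozen=True)
class BidirectionalBlock:
    """Haplotypes identical over both flanks around a g-site gap."""

    haps: frozenset[int]
    k: int
    L: int
    g: int

    @property
    def left(self) -> tuple[int, int]:
        return (self.k - self.L, self.k)

    @property
    def gap(self) -> tuple[int, int]:
        return (self.k, self.k + self.g)

    @property
    def right(self) -> tuple[int, int]:
        return (self.k + self.g, self.k + self.g + self.L)


def block_ids_from_state(ppa: np.ndarray, div: np.ndarray, k: int, L: int, W: int) -> np.ndarray:
    """Hap-order block IDs for the runs with internal div <= k-L, width >= W."""
    M = ppa.shape[0]
    boundary = div > k - L
    run_id = (np.cumsum(boundary) - 1).astype(np.int64)
    widths = np.bincount(run_id)
    ok = widths[run_id] >= W
    ids_sorted = np.where(ok, run_id, -(ppa.astype(np.int64) + 1))
    out = np.empty(M, dtype=np.int64)
    out[ppa] = ids_sorted
    return out


def reverse_block_table(
    alleles: np.ndarray,
    L: int,
    W: int,
    spill_to_disk: bool = False,
) -> np.ndarray:
    """Block-ID rows for every right flank [t, t+L), via one reverse pass.

    Row ``t`` holds the hap-order IDs of width->=W blocks matching over
    original sites [t, t+L); rows with t > N-L are all-sentinel.
    """
    M, N = alleles.shape
    if spill_to_disk:
        fd, path = tempfile.mkstemp(suffix=".revpbwt")
        os.close(fd)
        table = np.memmap(path, dtype=np.int32, mode="w+", shape=(N + 1, M))
        # unlink immediately: the mapping stays valid, the file is reclaimed on close
        os.unlink(path)
    else:
        table = np.empty((N + 1, M), dtype=np.int32)
    sentinel = -(np.arange(M, dtype=np.int32) + 1)
    for t in range(max(N - L + 1, 0), N + 1):
        table[t] = sentinel
    ppa = np.arange(M, dtype=np.int32)
    div = np.zeros(M, dtype=np.int32)
    for j in range(N):  # consume original columns right to left
        ppa, div = _pbwt_advance(ppa, div, np.ascontiguousarray(alleles[:, N - 1 - j]), j)
        kprime = j + 1
        if kprime >= L:
            t = N - kprime
            table[t] = block_ids_from_state(ppa, div, kprime, L, W).astype(np.int32)
    return table


def _group_pairs(fids: np.ndarray, rids: np.ndarray, W: int):
    """Sort haplotypes on (forward ID, reverse ID); return the groups of
    width >= W as (members_sorted, starts, sizes) over the sorted array."""
    M = fids.shape[0]
    order = np.lexsort((rids, fids))
    f = fids[order]
    r = rids[order]
    new = np.empty(M, dtype=bool)
    new[0] = True
    np.logical_or(f[1:] != f[:-1], r[1:] != r[:-1], out=new[1:])
    gid = np.cumsum(new) - 1
    sizes = np.bincount(gid)
    starts = np.nonzero(new)[0]
    # sentinel or unpaired haplotypes land in singleton groups; W >= 2 drops them
    keep = (sizes >= W) & (f[starts] >= 0) & (r[starts] >= 0)
    return order, starts[keep], sizes[keep]


def intersect_blocks(
    S: Sequence[set[int] | frozenset[int]],
    T: Sequence[set[int] | frozenset[int]],
) -> list[frozenset[int]]:
    """Element-wise intersection U(S, T) = {s & t for s in S, t in T} - {{}}.

    Computed in O(M) by the (forward ID, reverse ID) sort rather than
    all-pairs set intersection.  Sets within S (and within T) must be
    pairwise disjoint.
    """
    for name, part in (("S", S), ("T", T)):
        seen: set[int] = set()
        for s in part:
            if seen & set(s):
                raise ValueError(f"sets within {name} overlap")
            seen |= set(s)
    universe = sorted({h for s in S for h in s} | {h for t in T for h in t})
    if not universe:
        return []
    M = max(universe) + 1
    fids = -(np.arange(M, dtype=np.int64) + 1)
    rids = fids.copy()
    for i, s in enumerate(S):
        fids[list(s)] = i
    for i, t in enumerate(T):
        rids[list(t)] = i
    order, starts, sizes = _group_pairs(fids, rids, W=1)
    out = []
    for st, sz in zip(starts, sizes):
        out.append(frozenset(int(h) for h in order[st : st + sz]))
    return out


def bidirectional_scan(
    panel: HaplotypePanel | np.ndarray,
    L: int,
    W: int,
    g: int,
    spill_to_disk: bool = False,
) -> Iterator[tuple[int, list[BidirectionalBlock]]]:
    """Stream (k, blocks) for every anchor k in [L, N-g-L].

    Each emitted block has width >= W, members identical over [k-L, k) and
    [k+g, k+g+L).  Panels shorter than 2L+g yield nothing (with a warning).
    """
    if L <= 0 or W < 2 or g < 0:
        raise ValueError("require L > 0, W >= 2, g >= 0")
    alleles = panel.alleles if isinstance(panel, HaplotypePanel) else np.asarray(panel, dtype=np.int8)
    M, N = alleles.shape
    if N < 2 * L + g:
        warnings.warn(f"panel has {N} sites < 2L+g = {2 * L + g}; no bidirectional blocks")
        return
    rev = reverse_block_table(alleles, L, W, spill_to_disk=spill_to_disk)
    ppa = np.arange(M, dtype=np.int32)
    div = np.zeros(M, dtype=np.int32)
    for k in range(N + 1):
        if L <= k <= N - g - L:
            fids = block_ids_from_state(ppa, div, k, L, W)
            rids = rev[k + g].astype(np.int64)
            order, starts, sizes = _group_pairs(fids, rids, W)
            blocks = [
                BidirectionalBlock(
                    frozenset(int(h) for h in order[st : st + sz]), k, L, g
                )
                for st, sz in zip(starts, sizes)
            ]
            yield k, blocks
        if k < N:
            ppa, div = _pbwt_advance(ppa, div, np.ascontiguousarray(alleles[:, k]), k)
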