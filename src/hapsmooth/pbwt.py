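"""Positional Burrows-Wheeler transform core.

At each site k the PBWT keeps the haplotypes sorted by their reversed
prefix over the consumed sites, as the positional prefix array ``ppa``,
together with a divergence array ``div`` giving, for each position in
sorted order, the first site of the match with its predecessor.  Both are
updated in O(M) per site, which is what makes whole-panel scans O(MN).

Conventions (Durbin-style): ``div[0] = k`` is a sentinel (empty match);
haplotypes ``ppa[i-1]`` and ``ppa[i]`` agree on every site in
``[div[i], k)``.  A width-maximal block of haplotypes matching over
``[k-L, k)`` is a maximal run of consecutive ``ppa`` entries whose internal
divergence values are <= k-L.

The update kernel additionally understands a third allele value ``-1``
("matches nothing", not even another -1), used by the evaluation module's
interim ground-truth panels; binary panels never hit that branch.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Literal, Sequence

import numpy as np
from numba import njit

from .panel import HaplotypePanel


@njit(cache=True)
def _pbwt_advance(ppa, div, col, k):  # pragma: no cover - exercised via wrappers
    """One PBWT column update: consume allele column ``col`` (hap order).

    Returns the (ppa, div) arrays valid after k+1 consumed sites.  Alleles
    may be 0, 1 or -1; -1 carriers sort to the end with sentinel divergence
    k+1 (they match nothing at site k).
    """
    M = ppa.shape[0]
    a = np.empty(M, np.int32)
    b = np.empty(M, np.int32)
    c = np.empty(M, np.int32)
    da = np.empty(M, np.int32)
    db = np.empty(M, np.int32)
    na = 0
    nb = 0
    nc = 0
    p = k + 1
    q = k + 1
    for i in range(M):
        h = ppa[i]
        dv = div[i]
        if dv > p:
            p = dv
        if dv > q:
            q = dv
        v = col[h]
        if v == 0:
            a[na] = h
            da[na] = p
            na += 1
            p = 0
        elif v == 1:
            b[nb] = h
            db[nb] = q
            nb += 1
            q = 0
        else:
            # -1: this row matches nothing at site k; its divergence still
            # feeds the running maxima for the rows around it
            c[nc] = h
            nc += 1
    out_p = np.empty(M, np.int32)
    out_d = np.empty(M, np.int32)
    out_p[:na] = a[:na]
    out_d[:na] = da[:na]
    out_p[na : na + nb] = b[:nb]
    out_d[na : na + nb] = db[:nb]
    out_p[na + nb :] = c[:nc]
    out_d[na + nb :] = k + 1
    return out_p, out_d


@dataclasses.dataclass
class PbwtColumn:
    """PBWT state after ``k`` consumed sites in one scan direction.

    Forward columns cover original sites ``[0, k)``; reverse columns cover
    ``[n_sites - k, n_sites)`` read right-to-left.  ``ppa``/``div`` are in
    scan coordinates; :func:`blocks_at` maps block intervals back to
    original site coordinates.
    """

    k: int
    ppa: np.ndarray
    div: np.ndarray
    direction: Literal["forward", "reverse"]
    n_sites: int


@dataclasses.dataclass(frozen=True)
class MatchBlock:
    """A width-maximal set of >= 2 haplotypes identical over [start, end)."""

    haps: frozenset[int]
    start: int
    end: int


@dataclasses.dataclass(frozen=True)
class PairMatch:
    """A locally maximal pairwise match over sites [start, end)."""

    hap_a: int
    hap_b: int
    start: int
    end: int
    cm_len: float = 0.0


def pbwt_scan(
    panel: HaplotypePanel | np.ndarray,
    direction: Literal["forward", "reverse"] = "forward",
) -> Iterator[PbwtColumn]:
    """Yield PBWT columns for k = 0..N (N+1 states), O(M) work per column.

    The yielded arrays are snapshots (safe to keep across iterations).
    """
    alleles = panel.alleles if isinstance(panel, HaplotypePanel) else np.asarray(panel, dtype=np.int8)
    M, N = alleles.shape
    cols = alleles if direction == "forward" else alleles[:, ::-1]
    ppa = np.arange(M, dtype=np.int32)
    div = np.zeros(M, dtype=np.int32)
    yield PbwtColumn(0, ppa.copy(), div.copy(), direction, N)
    for k in range(N):
        ppa, div = _pbwt_advance(ppa, div, np.ascontiguousarray(cols[:, k]), k)
        yield PbwtColumn(k + 1, ppa.copy(), div.copy(), direction, N)


def blocks_at(col: PbwtColumn, L: int, W: int) -> list[MatchBlock]:
    """Width-maximal match blocks of length L ending at the column.

    Runs of consecutive ``ppa`` entries with internal ``div <= k-L`` and
    width >= W.  Forward blocks span original sites ``[k-L, k)``; reverse
    blocks (scan position k) span ``[n_sites-k, n_sites-k+L)``.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if W < 2:
        raise ValueError("W must be at least 2")
    if col.k < L:
        raise ValueError(f"column k={col.k} has consumed fewer than L={L} sites")
    boundary = col.div > col.k - L  # div[0]=k qualifies, so runs start cleanly
    run_id = np.cumsum(boundary) - 1
    widths = np.bincount(run_id)
    keep = np.nonzero(widths >= W)[0]
    if col.direction == "forward":
        start, end = col.k - L, col.k
    else:
        start, end = col.n_sites - col.k, col.n_sites - col.k + L
    out = []
    for r in keep:
        members = col.ppa[run_id == r]
        out.append(MatchBlock(frozenset(int(h) for h in members), start, end))
    return out


# ---------------------------------------------------------------------------
# Pairwise long matches
# ---------------------------------------------------------------------------

def report_long_matches(
    panel: HaplotypePanel,
    min_len: float,
    unit: Literal["sites", "cm"] = "sites",
    queries: Sequence[int] | None = None,
) -> list[PairMatch]:
    """All locally maximal pairwise matches of length >= ``min_len``.

    A match ``[start, end)`` is locally maximal: the pair disagrees at
    ``start-1`` and at ``end`` when those sites exist (edge matches are
    reported without a flanking mismatch).  With ``unit="cm"`` the length
    criterion is ``cm[end-1] - cm[start] >= min_len`` and the panel sites
    must carry cM values.  ``queries`` restricts output to pairs with
    exactly one member in the query set.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    alleles = panel.alleles
    M, N = alleles.shape
    cm = panel.cm
    if unit == "cm" and not (np.diff(cm) > 0).any() and N > 1:
        raise ValueError("panel sites carry no cM information; use unit='sites' or attach a map")
    qset = None if queries is None else frozenset(int(q) for q in queries)

    out: list[PairMatch] = []
    ppa = np.arange(M, dtype=np.int32)
    div = np.zeros(M, dtype=np.int32)

    def emit(run_lo: int, run_hi: int, end: int, y: np.ndarray | None, thr: int) -> None:
        # Pairs inside ppa[run_lo..run_hi] whose match ends exactly at `end`:
        # differing next alleles (or end == N).  Pair start = max div between.
        size = run_hi - run_lo + 1
        if size < 2:
            return
        d = div[run_lo : run_hi + 1]
        best = np.zeros(size, dtype=np.int64)  # best[u] = max div in (u, v]
        for v in range(1, size):
            np.maximum(best[:v], d[v], out=best[:v])
            hv = int(ppa[run_lo + v])
            for u in range(v):
                if y is not None and y[run_lo + u] == y[run_lo + v]:
                    continue
                start = int(best[u])
                if start > thr:
                    continue
                hu = int(ppa[run_lo + u])
                if qset is not None and ((hu in qset) == (hv in qset)):
                    continue
                a, b = (hu, hv) if hu < hv else (hv, hu)
                out.append(PairMatch(a, b, start, end, float(cm[end - 1] - cm[start])))

    for k in range(N + 1):
        # threshold on match start for a match ending at k
        if k == 0:
            thr = -1
        elif unit == "sites":
            thr = k - int(min_len)
        else:
            # largest s with cm[k-1] - cm[s] >= min_len
            thr = int(np.searchsorted(cm, cm[k - 1] - min_len, side="right")) - 1
        if thr >= 0:
            y = alleles[:, k][ppa] if k < N else None
            # maximal runs with div <= thr
            boundary = np.nonzero(div > thr)[0]
            bounds = np.concatenate([boundary, [M]])
            lo = 0
            for b in bounds:
                if b - lo >= 2:
                    emit(lo, b - 1, k, y, thr)
                lo = b
        if k < N:
            ppa, div = _pbwt_advance(ppa, div, np.ascontiguousarray(alleles[:, k]), k)
    return out
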