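"""Multiway IBD cluster calling: maximal PBWT match blocks as clusters.

A cluster is a set of haplotypes identical over a site interval that is
maximal in both dimensions: the member set is the complete set of
haplotypes matching over the interval, and no one-site extension left or
right preserves that member set.  Nested blocks (wider but shorter) are
separately reported when themselves maximal.  Calling on a smoothed panel
(smooth first, then call — optionally fused into one forward pass) is the
error-tolerant cluster caller.

Enumeration: at each PBWT column e, maximal runs of the divergence array
correspond to candidate blocks; a monotone stack over ``div`` emits every
(interval, member-run) pair whose internal maximum divergence s* is its
left boundary, in O(M) amortized per column.  Right-maximality is the
requirement that members do not all share one (non-missing) allele at
site e.  The alphabet includes the -1 sentinel ("matches nothing") used by
ground-truth interim panels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .panel import HaplotypePanel
from .pbwt import _pbwt_advance
from .smoother import Correction, SmootherParams, _smooth_pass, smooth_panel


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Cluster thresholds: minimum length (cM by default) and width."""

    min_len: float
    min_width: int = 2
    unit: Literal["cm", "sites"] = "cm"

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.unit not in ("cm", "sites"):
            raise ValueError("unit must be 'cm' or 'sites'")


@dataclasses.dataclass(frozen=True, eq=False)
class IbdCluster:
    """A maximal multiway match: ``members`` identical over [start, end)."""

    members: tuple[int, ...]
    start: int
    end: int
    cm_len: float

    @property
    def haps(self) -> frozenset[int]:
        return frozenset(self.members)

    @property
    def width(self) -> int:
        return len(self.members)

    @property
    def n_sites(self) -> int:
        return self.end - self.start

    @property
    def area(self) -> int:
        return self.width * self.n_sites

    def key(self) -> tuple[int, int, frozenset[int]]:
        return (self.start, self.end, self.haps)

    def __eq__(self, other) -> bool:  # order-insensitive member comparison
        return isinstance(other, IbdCluster) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


@njit(cache=True)
def _maximal_runs(div, e, y, has_next, min_width, cm, min_cm, min_sites, use_cm):
    """Candidate maximal blocks ending at column e, filtered in place.

    ``div`` is the divergence array (div[0] = e sentinel) and ``y`` the
    next-site alleles in ppa order (ignored when ``has_next`` is false).
    Returns (run_start, run_stop, block_start) triples over ppa positions;
    runs are inclusive [run_start, run_stop].
    """
    M = div.shape[0]
    INF = np.int64(1) << np.int64(60)
    # eq_run_end[i]: last index j >= i with y[i..j] all equal
    eq_end = np.empty(M, np.int64)
    if has_next:
        eq_end[M - 1] = M - 1
        for i in range(M - 2, -1, -1):
            eq_end[i] = eq_end[i + 1] if y[i + 1] == y[i] else i
    out_a = np.empty(M, np.int64)
    out_b = np.empty(M, np.int64)
    out_s = np.empty(M, np.int64)
    n_out = 0
    stack_v = np.empty(M + 1, np.int64)
    stack_a = np.empty(M + 1, np.int64)
    top = -1
    for i in range(1, M + 1):
        d = np.int64(div[i]) if i < M else INF
        a = i - 1
        while top >= 0 and stack_v[top] < d:
            v = stack_v[top]
            sa = stack_a[top]
            top -= 1
            a = sa
            b = i - 1
            if v >= e:
                continue
            if b - sa + 1 < min_width:
                continue
            if use_cm:
                if cm[e - 1] - cm[v] < min_cm:
                    continue
            else:
                if e - v < min_sites:
                    continue
            if has_next and eq_end[sa] >= b and y[sa] >= 0:
                continue  # all members extend right with the same allele
            out_a[n_out] = sa
            out_b[n_out] = b
            out_s[n_out] = v
            n_out += 1
        if not (top >= 0 and stack_v[top] == d):
            top += 1
            stack_v[top] = d
            stack_a[top] = a
    return out_a[:n_out], out_b[:n_out], out_s[:n_out]


class ClusterScanner:
    """Incremental maximal-block caller: push allele columns left to right.

    Columns may be pushed as they become final, which is how cluster
    calling fuses with the smoothing pass.
    """

    def __init__(self, M: int, cm: np.ndarray, params: ClusterParams):
        self.params = params
        self.cm = np.asarray(cm, dtype=np.float64)
        self.ppa = np.arange(M, dtype=np.int32)
        self.div = np.zeros(M, dtype=np.int32)
        self.e = 0
        self._dummy = np.zeros(M, dtype=np.int8)
        self.clusters: list[IbdCluster] = []

    def _collect(self, y: np.ndarray, has_next: bool) -> None:
        p = self.params
        a, b, s = _maximal_runs(
            self.div,
            self.e,
            y,
            has_next,
            p.min_width,
            self.cm,
            p.min_len if p.unit == "cm" else 0.0,
            int(p.min_len) if p.unit == "sites" else 0,
            p.unit == "cm",
        )
        for lo, hi, start in zip(a, b, s):
            members = tuple(int(h) for h in np.sort(self.ppa[lo : hi + 1]))
            cm_len = float(self.cm[self.e - 1] - self.cm[start])
            self.clusters.append(IbdCluster(members, int(start), self.e, cm_len))

    def push(self, column: np.ndarray) -> None:
        col = np.ascontiguousarray(column, dtype=np.int8)
        self._collect(col[self.ppa], True)
        self.ppa, self.div = _pbwt_advance(self.ppa, self.div, col, self.e)
        self.e += 1

    def finish(self) -> list[IbdCluster]:
        self._collect(self._dummy, False)
        self.clusters.sort(key=lambda c: (c.start, -c.width, c.end, c.members))
        return self.clusters


def call_clusters(
    panel: HaplotypePanel | np.ndarray,
    params: ClusterParams,
    cm: np.ndarray | None = None,
) -> list[IbdCluster]:
    """All maximal clusters meeting the thresholds, ordered by start site
    then descending width.

    Accepts a panel or a raw matrix over {-1, 0, 1}; -1 matches nothing
    (not even another -1).  With ``unit='cm'`` the sites must carry cM
    values (pass ``cm`` explicitly for raw matrices).
    """
    if isinstance(panel, HaplotypePanel):
        matrix = panel.alleles
        cm = panel.cm if cm is None else cm
    else:
        matrix = np.asarray(panel, dtype=np.int8)
    M, N = matrix.shape
    if cm is None:
        cm = np.zeros(N)
    if params.unit == "cm" and N > 1 and not (np.diff(cm) > 0).any():
        raise ValueError("sites carry no cM information; use unit='sites' or supply cm")
    scan = ClusterScanner(M, cm, params)
    for k in range(N):
        scan.push(matrix[:, k])
    return scan.finish()


def ps_cluster(
    panel: HaplotypePanel,
    cluster_params: ClusterParams,
    smoother_params: SmootherParams | None = None,
    fused: bool = True,
) -> tuple[list[IbdCluster], list[Correction]]:
    """Smooth, then call clusters.  Smoothing width defaults to the target
    cluster width (W = Wmin); the fused single pass and the sequential
    composition produce identical cluster sets."""
    sp = smoother_params or SmootherParams(W=max(cluster_params.min_width, 2))
    if fused:
        scan = ClusterScanner(panel.M, panel.cm, cluster_params)
        _, corrections = _smooth_pass(panel, sp, on_column=lambda k, col: scan.push(col))
        return scan.finish(), corrections
    smoothed, corrections = smooth_panel(panel, sp)
    return call_clusters(smoothed, cluster_params), corrections


def write_clusters_tsv(
    clusters: Sequence[IbdCluster], panel: HaplotypePanel, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tstart_site\tend_site\tstart_bp\tend_bp\tcm_len\twidth\thap_ids\n"
        )
        for i, c in enumerate(clusters):
            ids = ",".join(panel.hap_ids[h] for h in c.members)
            fh.write(
                f"{i}\t{c.start}\t{c.end}\t{panel.sites[c.start].pos_bp}\t"
                f"{panel.sites[c.end - 1].pos_bp}\t{c.cm_len:.6f}\t{c.width}\t{ids}\n"
            )
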