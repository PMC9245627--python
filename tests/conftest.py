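"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the PBWT machinery: they work by direct
string comparison / exhaustive enumeration on small panels, so the fast
implementations can be checked against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from hapsmooth.panel import HaplotypePanel, SiteInfo


def make_panel(alleles: np.ndarray, cm_per_site: float = 0.01) -> HaplotypePanel:
    alleles = np.asarray(alleles, dtype=np.int8)
    M, N = alleles.shape
    sites = [SiteInfo("1", k + 1, k * cm_per_site) for k in range(N)]
    return HaplotypePanel(alleles, [f"h{i}" for i in range(M)], sites)


def random_panel(rng: np.random.Generator, M: int, N: int, p: float = 0.5) -> HaplotypePanel:
    return make_panel((rng.random((M, N)) < p).astype(np.int8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_ppa_div(alleles: np.ndarray, k: int) -> tuple[list[int], list[int]]:
    """Stable sort of haplotypes by reversed length-k prefix, plus match
    starts computed by direct suffix comparison."""
    M = alleles.shape[0]
    keys = [tuple(alleles[i, :k][::-1]) for i in range(M)]
    ppa = sorted(range(M), key=lambda i: keys[i])  # python sort is stable
    div = [k]
    for r in range(1, M):
        a, b = ppa[r - 1], ppa[r]
        s = k
        while s > 0 and alleles[a, s - 1] == alleles[b, s - 1]:
            s -= 1
        div.append(s)
    return ppa, div


def oracle_blocks(alleles: np.ndarray, start: int, end: int, W: int) -> set[frozenset[int]]:
    """Width-maximal identical groups over [start, end): group haplotypes
    by their substring, keep groups of size >= W."""
    groups: dict[tuple, list[int]] = {}
    for i in range(alleles.shape[0]):
        groups.setdefault(tuple(alleles[i, start:end]), []).append(i)
    return {frozenset(g) for g in groups.values() if len(g) >= W}


def oracle_bidirectional(
    alleles: np.ndarray, k: int, L: int, g: int, W: int
) -> set[frozenset[int]]:
    """Groups identical over both flanks [k-L,k) and [k+g,k+g+L)."""
    groups: dict[tuple, list[int]] = {}
    for i in range(alleles.shape[0]):
        key = (tuple(alleles[i, k - L : k]), tuple(alleles[i, k + g : k + g + L]))
        groups.setdefault(key, []).append(i)
    return {frozenset(g_) for g_ in groups.values() if len(g_) >= W}


def oracle_pair_matches(alleles: np.ndarray, min_len: int) -> set[tuple[int, int, int, int]]:
    """O(M^2 N) scan for locally maximal pairwise matches >= min_len sites."""
    M, N = alleles.shape
    out = set()
    for a in range(M):
        for b in range(a + 1, M):
            eq = alleles[a] == alleles[b]
            s = None
            for k in range(N + 1):
                if k < N and eq[k]:
                    if s is None:
                        s = k
                else:
                    if s is not None and k - s >= min_len:
                        out.add((a, b, s, k))
                    s = None
    return out


def oracle_clusters(
    matrix: np.ndarray, min_sites: int, min_width: int
) -> set[tuple[int, int, frozenset[int]]]:
    """Exhaustive maximal-cluster enumeration on a {-1,0,1} matrix.

    For every interval, group rows without missing values by substring;
    keep groups >= min_width that cannot be extended left or right with
    the same member set (-1 matches nothing, including another -1).
    """
    M, N = matrix.shape
    out = set()
    for s in range(N):
        for e in range(s + min_sites, N + 1):
            groups: dict[tuple, list[int]] = {}
            for i in range(M):
                sub = matrix[i, s:e]
                if (sub == -1).any():
                    continue
                groups.setdefault(tuple(sub), []).append(i)
            for sub, g in groups.items():
                if len(g) < min_width:
                    continue
                if s > 0:
                    prev = matrix[np.array(g), s - 1]
                    if (prev == prev[0]).all() and prev[0] != -1:
                        continue  # extendable left
                if e < N:
                    nxt = matrix[np.array(g), e]
                    if (nxt == nxt[0]).all() and nxt[0] != -1:
                        continue  # extendable right
                out.add((s, e, frozenset(g)))
    return out
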