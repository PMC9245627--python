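"""Benchmarking framework: ground-truth clusters, power/accuracy metrics,
and error-correction recall/precision.

Ground-truth multiway clusters are derived from pairwise IBD segments
through an *interim panel*: an M x N matrix initialized to -1 in which, for
every site of every true segment, the two haplotypes are forced equal
(randomly seeding 0/1 when both are unset, else propagating the set
value).  Running the cluster caller on that ternary panel — where -1
matches nothing, so only genuinely IBD-shared stretches can form blocks —
yields the ground-truth cluster set.

Cluster metrics use areas: area = width x n_sites; overlap(c1, c2) =
shared haplotypes x shared sites.  Power of a truth cluster = max overlap
with any reported cluster / truth area (averaged over truth); accuracy of
a reported cluster = max overlap with any truth cluster / reported area
(averaged over reported).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .cluster import ClusterParams, IbdCluster, call_clusters
from .smoother import Correction


@dataclasses.dataclass(frozen=True)
class TrueSegment:
    """A ground-truth pairwise IBD segment in site coordinates."""

    hap_a: int
    hap_b: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment must have start < end")


@dataclasses.dataclass
class InterimPanel:
    """Ternary {-1, 0, 1} matrix encoding only ground-truth sharing."""

    values: np.ndarray
    cm: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class EvalReport:
    power: float  # NaN when there is no truth
    accuracy: float  # NaN when nothing was reported
    n_truth: int
    n_reported: int


@dataclasses.dataclass(frozen=True)
class ErrorCorrectionReport:
    n_errors: int
    n_corrections: int
    n_errors_corrected: int
    n_nonerrors_corrected: int

    @property
    def recall(self) -> float | None:
        """Fraction of injected errors corrected; None (NA) with no errors."""
        if self.n_errors == 0:
            return None
        return self.n_errors_corrected / self.n_errors

    @property
    def precision(self) -> float | None:
        """Fraction of corrections that undid an injected error; None (NA)
        with no corrections.  A lower bound: rare true mutations flipped by
        smoothing count against it."""
        if self.n_corrections == 0:
            return None
        return self.n_errors_corrected / self.n_corrections

    @classmethod
    def from_counts(
        cls, n_errors: int, n_corrections: int, n_errors_corrected: int
    ) -> "ErrorCorrectionReport":
        return cls(
            n_errors=n_errors,
            n_corrections=n_corrections,
            n_errors_corrected=n_errors_corrected,
            n_nonerrors_corrected=n_corrections - n_errors_corrected,
        )


# ---------------------------------------------------------------------------
# Interim panel / ground-truth clusters
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_interim(values, segs, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    for r in range(segs.shape[0]):
        a = segs[r, 0]
        b = segs[r, 1]
        for k in range(segs[r, 2], segs[r, 3]):
            va = values[a, k]
            vb = values[b, k]
            if va == -1 and vb == -1:
                v = np.int8(np.random.randint(0, 2))
                values[a, k] = v
                values[b, k] = v
            elif va == -1:
                values[a, k] = vb
            elif vb == -1:
                values[b, k] = va
            # both set: left unchanged (conflicting chains are possible
            # because IBD sharing is not transitive at a fixed site)


def build_interim_panel(
    segments: Sequence[TrueSegment],
    M: int,
    N: int,
    seed: int,
    cm: np.ndarray | None = None,
) -> InterimPanel:
    """Implant identical stretches for every true segment (seeded RNG).

    Segments are processed in input order, sites left to right; the result
    is deterministic given (segment order, seed).
    """
    values = np.full((M, N), -1, dtype=np.int8)
    if segments:
        segs = np.empty((len(segments), 4), dtype=np.int64)
        for i, s in enumerate(segments):
            if not (0 <= s.hap_a < M and 0 <= s.hap_b < M and 0 <= s.start < s.end <= N):
                raise ValueError(f"segment out of range: {s}")
            segs[i] = (s.hap_a, s.hap_b, s.start, s.end)
        _fill_interim(values, segs, seed % (2**31 - 1))
    return InterimPanel(values, cm=None if cm is None else np.asarray(cm, dtype=np.float64))


def extract_truth_clusters(interim: InterimPanel, params: ClusterParams) -> list[IbdCluster]:
    """Ground-truth clusters: the cluster caller on the interim panel.

    -1 is a sentinel that matches nothing (two -1 entries do not match), so
    blocks can only form where true segments implanted shared values.
    """
    return call_clusters(interim.values, params, cm=interim.cm)


# ---------------------------------------------------------------------------
# Power / accuracy
# ---------------------------------------------------------------------------

def overlap(c1: IbdCluster, c2: IbdCluster) -> int:
    """Shared haplotypes x shared sites."""
    sites = min(c1.end, c2.end) - max(c1.start, c2.start)
    if sites <= 0:
        return 0
    shared = np.intersect1d(
        np.asarray(c1.members, dtype=np.int64),
        np.asarray(c2.members, dtype=np.int64),
        assume_unique=True,
    ).size
    return shared * sites

def _best_ratios(targets: list[IbdCluster], others: list[IbdCluster]) -> np.ndarray:
    """For each target cluster: max overlap with any other cluster,
    normalized by the target's area.  Branch-and-bound on the upper bound
    site_overlap * min(widths) so only promising pairs pay for the
    haplotype intersection."""
    if not targets:
        return np.empty(0)
    out = np.zeros(len(targets))
    if not others:
        return out
    o_start = np.array([c.start for c in others])
    o_end = np.array([c.end for c in others])
    o_w = np.array([c.width for c in others])
    o_members = [np.asarray(c.members, dtype=np.int64) for c in others]
    for i, t in enumerate(targets):
        sites = np.minimum(t.end, o_end) - np.maximum(t.start, o_start)
        ub = np.maximum(sites, 0) * np.minimum(t.width, o_w)
        order = np.argsort(-ub)
        t_members = np.asarray(t.members, dtype=np.int64)
        best = 0
        for j in order:
            if ub[j] <= best:
                break
            shared = np.intersect1d(t_members, o_members[j], assume_unique=True).size
            best = max(best, shared * int(sites[j]))
        out[i] = best / t.area
    return out


def cluster_power_accuracy(
    truth: Sequence[IbdCluster], reported: Sequence[IbdCluster]
) -> EvalReport:
    truth = list(truth)
    reported = list(reported)
    power = float(np.mean(_best_ratios(truth, reported))) if truth else float("nan")
    accuracy = float(np.mean(_best_ratios(reported, truth))) if reported else float("nan")
    return EvalReport(power=power, accuracy=accuracy, n_truth=len(truth), n_reported=len(reported))


def pairwise_power_accuracy(
    truth_segments: Sequence[TrueSegment],
    reported_matches: Sequence,
    min_len: int | None = None,
) -> EvalReport:
    """Pairwise-segment metrics: each segment is a width-2 cluster and
    overlap is restricted to the identical haplotype pair.  ``min_len``
    (sites) filters the truth segments considered."""
    truth = [s for s in truth_segments if min_len is None or s.end - s.start >= min_len]
    by_pair: dict[tuple[int, int], list] = {}
    for m in reported_matches:
        a, b = (m.hap_a, m.hap_b) if m.hap_a < m.hap_b else (m.hap_b, m.hap_a)
        by_pair.setdefault((a, b), []).append(m)

    def site_overlap(x_start, x_end, y_start, y_end):
        return max(0, min(x_end, y_end) - max(x_start, y_start))

    powers = []
    for s in truth:
        key = (s.hap_a, s.hap_b) if s.hap_a < s.hap_b else (s.hap_b, s.hap_a)
        best = max(
            (site_overlap(s.start, s.end, m.start, m.end) for m in by_pair.get(key, [])),
            default=0,
        )
        powers.append(best / (s.end - s.start))
    truth_by_pair: dict[tuple[int, int], list[TrueSegment]] = {}
    for s in truth:
        key = (s.hap_a, s.hap_b) if s.hap_a < s.hap_b else (s.hap_b, s.hap_a)
        truth_by_pair.setdefault(key, []).append(s)
    accs = []
    for key, matches in by_pair.items():
        for m in matches:
            best = max(
                (site_overlap(m.start, m.end, s.start, s.end) for s in truth_by_pair.get(key, [])),
                default=0,
            )
            accs.append(best / (m.end - m.start))
    power = float(np.mean(powers)) if powers else float("nan")
    accuracy = float(np.mean(accs)) if accs else float("nan")
    return EvalReport(power, accuracy, len(truth), sum(len(v) for v in by_pair.values()))


# ---------------------------------------------------------------------------
# Error-correction bookkeeping
# ---------------------------------------------------------------------------

def error_correction_report(
    injected: dict[tuple[int, int], int],
    corrections: Sequence[Correction],
) -> ErrorCorrectionReport:
    """Score a correction log against the injected error set.

    ``injected`` maps (hap, site) -> the pre-error allele.  A correction
    counts as an error corrected only if it restores that allele.
    """
    n_err_corrected = 0
    for c in corrections:
        orig = injected.get((c.hap, c.site))
        if orig is not None and c.new_allele == orig:
            n_err_corrected += 1
    return ErrorCorrectionReport(
        n_errors=len(injected),
        n_corrections=len(corrections),
        n_errors_corrected=n_err_corrected,
        n_nonerrors_corrected=len(corrections) - n_err_corrected,
    )


def report_to_json(report, path: str | Path) -> None:
    d = dataclasses.asdict(report)
    if isinstance(report, ErrorCorrectionReport):
        d["recall"] = report.recall
        d["precision"] = report.precision
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, allow_nan=True)
        fh.write("\n")
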