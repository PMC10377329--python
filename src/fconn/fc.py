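"""Pairwise dependence measures and functional-connectivity matrices.

Three measures of statistical dependence between two ROI time courses:

* ``pearson`` — the Pearson correlation coefficient rho = cov(A,B)/(sd_A sd_B),
  linear dependence in [-1, 1];
* ``mic`` — the maximal information coefficient: the maximum over admissible
  2-D grid partitions of the empirical mutual information normalized by
  log2 of the smaller bin count, capturing general functional relationships
  in [0, 1];
* ``emic`` — the extended MIC, ``MIC - rho**2``, an index of *purely
  non-linear* dependence (near 0 for linear or independent pairs, large for
  pairs whose dependence Pearson cannot see).

The MIC search follows the MINE family's approximation: each series is
rank-transformed (average ranks on ties), one axis is partitioned into
``nA`` mass-equal bins, and the other axis's cut points are optimized by
dynamic programming over candidate positions at data gaps; both axis
orientations are searched and the maximum taken.  Admissible grids satisfy
``nA * nB < B(n)`` with ``B(n) = max(ceil(n**0.6), 5)`` (the floor of 5
keeps the minimal 2x2 grid admissible at very small n).  An exhaustive
search mode and an independently coded brute-force oracle are provided for
validating the approximation at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._mic_core import dp_best_scores
from .cohort import RoiTimeSeries
from .errors import DegenerateInputError, ParseError, ValidationError

MEASURES = ("PCC", "MIC", "eMIC")

DEFAULT_GRID_EXPONENT = 0.6
DEFAULT_MAX_CUTS = 64


def _validate_pair(a, b, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError("paired series must have equal length")
    if a.size < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("paired series contain non-finite values")
    return a, b


def pearson(a, b) -> float:
    """Pearson correlation, population (divisor n) convention throughout."""
    a, b = _validate_pair(a, b, min_n=2)
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        raise DegenerateInputError("correlation undefined for zero-variance series")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov / (sa * sb))


# ---------------------------------------------------------------------------
# mutual information on explicit grids


@dataclass(frozen=True)
class GridPartition:
    """Explicit bin edges for a 2-D partition of the plane."""

    x_bin_edges: tuple[float, ...]
    y_bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, edges in (("x", self.x_bin_edges), ("y", self.y_bin_edges)):
            if len(edges) < 3:
                raise ValidationError(f"{name}_bin_edges: need >= 2 bins")
            if not np.all(np.diff(edges) > 0):
                raise ValidationError(f"{name}_bin_edges must be strictly increasing")

    @property
    def nA(self) -> int:
        return len(self.x_bin_edges) - 1

    @property
    def nB(self) -> int:
        return len(self.y_bin_edges) - 1


class CharacteristicEntry(NamedTuple):
    """One entry of the characteristic matrix: the normalized maximal MI
    achieved at grid dimensions (nA, nB)."""

    nA: int
    nB: int
    m_value: float


def mi_from_counts(counts: np.ndarray) -> float:
    """I(A,B) = H(A) + H(B) - H(A,B) in bits from a 2-D contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("empty contingency table")

    def _h(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    p = counts / n
    return _h(p.sum(axis=1)) + _h(p.sum(axis=0)) - _h(p.ravel())


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx


def grid_mutual_information(a, b, grid: GridPartition) -> float:
    """Empirical mutual information (bits) of (a, b) over an explicit grid."""
    a, b = _validate_pair(a, b)
    xi = _digitize(a, np.asarray(grid.x_bin_edges))
    yi = _digitize(b, np.asarray(grid.y_bin_edges))
    counts = np.zeros((grid.nA, grid.nB))
    np.add.at(counts, (xi, yi), 1.0)
    return mi_from_counts(counts)


# ---------------------------------------------------------------------------
# MIC


def grid_bound(n: int, exponent: float = DEFAULT_GRID_EXPONENT) -> int:
    """Admissibility bound B(n): grids must satisfy nA*nB < B(n)."""
    return max(math.ceil(n**exponent), 5)


def _equipartition_columns(values: np.ndarray, k: int) -> np.ndarray:
    """Assign each point to one of k mass-equal bins along ``values``."""
    n = values.size
    order = np.argsort(values, kind="stable")
    col = np.empty(n, dtype=np.int32)
    col[order] = (np.arange(n, dtype=np.int64) * k) // n
    return col


def _gap_candidates(sorted_vals: np.ndarray, max_cuts: int) -> np.ndarray:
    """Candidate prefix lengths at value changes, capped, always ending at n."""
    n = sorted_vals.size
    change = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    if change.size > max_cuts - 1:
        pick = np.unique(
            (np.linspace(0, change.size - 1, max_cuts - 1)).round().astype(int)
        )
        change = change[pick]
    return np.append(change, n).astype(np.int64)


class MicResult(NamedTuple):
    value: float
    best_grid: CharacteristicEntry


def _mic_approx(xr: np.ndarray, yr: np.ndarray, bound: int, max_cuts: int) -> MicResult:
    n = xr.size
    best = MicResult(-np.inf, CharacteristicEntry(2, 2, -np.inf))
    for ar, br, swapped in ((xr, yr, False), (yr, xr, True)):
        order = np.argsort(br, kind="stable")
        br_sorted = br[order]
        cand = _gap_candidates(br_sorted, max_cuts)
        col_marg_cache: dict[int, float] = {}
        max_nA = (bound - 1) // 2
        for nA in range(2, max_nA + 1):
            nB_max = (bound - 1) // nA
            if nB_max < 2:
                continue
            col = _equipartition_columns(ar, nA)[order]
            scores = dp_best_scores(col, nA, nB_max, cand)
            if nA not in col_marg_cache:
                cnt = np.bincount(col, minlength=nA).astype(float)
                cnt = cnt[cnt > 0]
                col_marg_cache[nA] = float((cnt * np.log2(cnt)).sum())
            col_term = col_marg_cache[nA]
            for nB in range(2, nB_max + 1):
                mi = scores[nB] / n + math.log2(n) - col_term / n
                mi = max(mi, 0.0)
                grid_a, grid_b = (nB, nA) if swapped else (nA, nB)
                m_val = min(mi / math.log2(min(nA, nB)), 1.0)
                if m_val > best.value:
                    best = MicResult(m_val, CharacteristicEntry(grid_a, grid_b, m_val))
    return best


def _partition_indices(sorted_vals: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.diff(sorted_vals) != 0) + 1


def _mic_exhaustive(xr: np.ndarray, yr: np.ndarray, bound: int) -> MicResult:
    """Full search over all cut-point combinations at data gaps (n <= 20)."""
    n = xr.size
    if n > 20:
        raise ValidationError("exhaustive MIC search refused for n > 20")
    x_order = np.argsort(xr, kind="stable")
    y_order = np.argsort(yr, kind="stable")
    xgaps = _partition_indices(xr[x_order])
    ygaps = _partition_indices(yr[y_order])
    xrank_pos = np.empty(n, dtype=int)
    xrank_pos[x_order] = np.arange(n)
    yrank_pos = np.empty(n, dtype=int)
    yrank_pos[y_order] = np.arange(n)
    best = MicResult(-np.inf, CharacteristicEntry(2, 2, -np.inf))
    for nA in range(2, bound):
        nB_max = (bound - 1) // nA
        if nB_max < 2:
            continue
        for xcuts in itertools.combinations(xgaps, nA - 1):
            xi = np.searchsorted(np.asarray(xcuts), xrank_pos, side="right")
            for nB in range(2, nB_max + 1):
                for ycuts in itertools.combinations(ygaps, nB - 1):
                    yi = np.searchsorted(np.asarray(ycuts), yrank_pos, side="right")
                    counts = np.zeros((nA, nB))
                    np.add.at(counts, (xi, yi), 1.0)
                    m_val = min(mi_from_counts(counts) / math.log2(min(nA, nB)), 1.0)
                    if m_val > best.value:
                        best = MicResult(m_val, CharacteristicEntry(nA, nB, m_val))
    return best


def mic(
    a,
    b,
    *,
    grid_exponent: float = DEFAULT_GRID_EXPONENT,
    max_cuts: int = DEFAULT_MAX_CUTS,
    method: str = "approx",
) -> MicResult:
    """Maximal information coefficient of a pair of series.

    Returns the MIC value together with the grid dimensions that achieved
    it.  ``method='exhaustive'`` replaces the equipartition/DP search by a
    full enumeration of cut combinations (only feasible for n <= 20).
    """
    a, b = _validate_pair(a, b)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("MIC undefined for constant series")
    xr = rankdata(a)
    yr = rankdata(b)
    bound = grid_bound(a.size, grid_exponent)
    if method == "approx":
        return _mic_approx(xr, yr, bound, max_cuts)
    if method == "exhaustive":
        return _mic_exhaustive(xr, yr, bound)
    raise ValidationError(f"unknown MIC method {method!r}")


def exhaustive_mic_oracle(a, b, *, grid_exponent: float = DEFAULT_GRID_EXPONENT) -> float:
    """Brute-force MIC reference, independent of the production estimator.

    Enumerates every admissible grid whose cut points fall at data gaps and
    scores it with plain-Python entropy arithmetic.  Exact by construction;
    test use only (refuses n > 20).
    """
    a, b = _validate_pair(a, b)
    n = a.size
    if n > 20:
        raise ValidationError("oracle refused: combinatorial blow-up for n > 20")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("MIC undefined for constant series")
    bound = grid_bound(n, grid_exponent)
    ax = sorted(range(n), key=lambda i: (a[i], i))
    by = sorted(range(n), key=lambda i: (b[i], i))
    xpos = {idx: pos for pos, idx in enumerate(ax)}
    ypos = {idx: pos for pos, idx in enumerate(by)}
    xgaps = [k for k in range(1, n) if a[ax[k]] != a[ax[k - 1]]]
    ygaps = [k for k in range(1, n) if b[by[k]] != b[by[k - 1]]]

    def bin_of(pos: int, cuts: tuple[int, ...]) -> int:
        c = 0
        for cut in cuts:
            if pos >= cut:
                c += 1
        return c

    def h(probs) -> float:
        return -sum(p * math.log2(p) for p in probs if p > 0)

    best = -math.inf
    for nA in range(2, bound):
        nB_max = (bound - 1) // nA
        if nB_max < 2:
            continue
        for xcuts in itertools.combinations(xgaps, nA - 1):
            for nB in range(2, nB_max + 1):
                for ycuts in itertools.combinations(ygaps, nB - 1):
                    joint: dict[tuple[int, int], int] = {}
                    for i in range(n):
                        key = (bin_of(xpos[i], xcuts), bin_of(ypos[i], ycuts))
                        joint[key] = joint.get(key, 0) + 1
                    rowm: dict[int, int] = {}
                    colm: dict[int, int] = {}
                    for (r, c), cnt in joint.items():
                        rowm[r] = rowm.get(r, 0) + cnt
                        colm[c] = colm.get(c, 0) + cnt
                    mi = (
                        h(v / n for v in rowm.values())
                        + h(v / n for v in colm.values())
                        - h(v / n for v in joint.values())
                    )
                    m_val = mi / math.log2(min(nA, nB))
                    if m_val > best:
                        best = m_val
    return best


def emic(a, b, **mic_kwargs) -> float:
    """Extended MIC: MIC - rho**2 (not clamped; finite-sample values may be
    slightly negative).  Near-zero for linear or independent pairs."""
    rho = pearson(a, b)
    return mic(a, b, **mic_kwargs).value - rho**2


# ---------------------------------------------------------------------------
# FC matrices


@dataclass
class FCMatrix:
    """Symmetric R x R connectivity matrix tagged with its measure."""

    values: np.ndarray
    measure: str
    roi_labels: list[str]
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")
        r = len(self.roi_labels)
        if self.values.shape != (r, r):
            raise ValidationError("values shape must match roi_labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("FC matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("FC matrix contains non-finite values")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


_DIAGONAL = {"PCC": 1.0, "MIC": 1.0, "eMIC": 0.0}


def _pair_value(a: np.ndarray, b: np.ndarray, measure: str, mic_kwargs: dict) -> float:
    if measure == "PCC":
        return pearson(a, b)
    if measure == "MIC":
        return mic(a, b, **mic_kwargs).value
    return emic(a, b, **mic_kwargs)


def fc_matrix(subject: RoiTimeSeries, measure: str, **mic_kwargs) -> FCMatrix:
    """FC matrix for one subject under one measure.

    Fills the upper triangle with R(R-1)/2 pairwise estimator calls, mirrors
    to the lower triangle, and sets the diagonal to the measure's
    self-dependence value (PCC 1, MIC 1, eMIC 0).
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}")
    data = subject.data
    sds = data.std(axis=0)
    if np.any(sds == 0):
        bad = int(np.flatnonzero(sds == 0)[0])
        raise DegenerateInputError(
            f"subject {subject.subject_id}: ROI {subject.roi_labels[bad]} is constant"
        )
    r = subject.n_rois
    values = np.full((r, r), _DIAGONAL[measure])
    for i in range(r):
        for j in range(i + 1, r):
            v = _pair_value(data[:, i], data[:, j], measure, mic_kwargs)
            values[i, j] = values[j, i] = v
    return FCMatrix(values=values, measure=measure,
                    roi_labels=list(subject.roi_labels), subject_id=subject.subject_id)


def all_fc_matrices(
    subject: RoiTimeSeries, measures: Iterable[str] = MEASURES, **mic_kwargs
) -> dict[str, FCMatrix]:
    """All requested measures for one subject, computing each pairwise
    estimate once (eMIC is derived entry-wise as MIC - PCC**2, its
    definition, so the MIC search is not repeated)."""
    measures = list(measures)
    for m in measures:
        if m not in MEASURES:
            raise ValidationError(f"unknown measure {m!r}")
    need_p = "PCC" in measures or "eMIC" in measures
    need_m = "MIC" in measures or "eMIC" in measures
    data = subject.data
    if np.any(data.std(axis=0) == 0):
        bad = int(np.flatnonzero(data.std(axis=0) == 0)[0])
        raise DegenerateInputError(
            f"subject {subject.subject_id}: ROI {subject.roi_labels[bad]} is constant"
        )
    r = subject.n_rois
    pcc = np.eye(r) if need_p else None
    micm = np.eye(r) if need_m else None
    for i in range(r):
        for j in range(i + 1, r):
            if need_p:
                v = pearson(data[:, i], data[:, j])
                pcc[i, j] = pcc[j, i] = v
            if need_m:
                v = mic(data[:, i], data[:, j], **mic_kwargs).value
                micm[i, j] = micm[j, i] = v
    out: dict[str, FCMatrix] = {}
    labels = list(subject.roi_labels)
    if "PCC" in measures:
        out["PCC"] = FCMatrix(pcc.copy(), "PCC", labels, subject.subject_id)
    if "MIC" in measures:
        out["MIC"] = FCMatrix(micm.copy(), "MIC", labels, subject.subject_id)
    if "eMIC" in measures:
        em = micm - pcc**2
        np.fill_diagonal(em, 0.0)
        out["eMIC"] = FCMatrix(em, "eMIC", labels, subject.subject_id)
    return out


def write_fc_matrix(fc: FCMatrix, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{fc.subject_id}.{fc.measure}.tsv"
    pd.DataFrame(fc.values, columns=fc.roi_labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    return path


def read_fc_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    name = path.name
    parts = name.rsplit(".", 2)
    if len(parts) != 3 or parts[2] != "tsv" or parts[1] not in MEASURES:
        raise ParseError(f"{path}: expected filename <subject>.<measure>.tsv")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return FCMatrix(values=df.to_numpy(dtype=float), measure=parts[1],
                    roi_labels=list(df.columns), subject_id=parts[0])
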