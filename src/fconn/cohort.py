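"""Synthetic multi-group ROI time-series cohorts.

Generates resting-state-like, band-limited signals for a configurable number
of regions of interest (ROIs) per subject, with linear and non-linear
inter-regional couplings whose strengths may differ between diagnostic
groups (CN / MCI / AD).  The generator exists so that every downstream stage
— connectivity estimation, graph embedding, classification — can be exercised
and validated without access to restricted clinical fMRI data.

Each ROI starts as white Gaussian noise that is Fourier-masked to a
low-frequency band (default 0.01–0.08 Hz, the conventional resting-state
band) and re-standardized.  Couplings are then injected column-wise:

* linear edge ``(i, j, s)``:    ``col_j <- std(col_j + s * col_i)``
* non-linear edge ``(i, j, f, s)``: ``col_j <- std(col_j + s * std(f(col_i)))``

with ``f`` one of ``x**2``, ``sin(2*pi*x)`` or ``|x|``.  The non-linear
transform output is Fourier-masked back to the pass band before injection
(a pointwise non-linearity creates harmonics outside the band, and any
band-pass preprocessing of real recordings would remove them), then
standardized so that ``s`` is an effect size on a common unit-variance
scale for every transform.  All columns are re-standardized to mean 0,
sd 1 at the end, and every emitted series is band-limited.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

KNOWN_LABELS = ("CN", "MCI", "AD")

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "quadratic": lambda x: x**2,
    "sine": lambda x: np.sin(2.0 * np.pi * x),
    "absolute": np.abs,
}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DegenerateColumn("column has zero variance")
    return (x - x.mean()) / sd


class DegenerateColumn(ValidationError):
    pass


def _as_strength_map(strength, labels: Sequence[str]) -> dict[str, float]:
    """A scalar strength applies to every group; a mapping is per-group."""
    if isinstance(strength, Mapping):
        missing = [g for g in labels if g not in strength]
        if missing:
            raise ValidationError(f"edge strength missing for groups {missing}")
        return {g: float(strength[g]) for g in labels}
    return {g: float(strength) for g in labels}


@dataclass(frozen=True)
class LinearEdge:
    source: int
    target: int
    strength: Mapping[str, float] | float


@dataclass(frozen=True)
class NonlinearEdge:
    source: int
    target: int
    transform: str
    strength: Mapping[str, float] | float


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``linear_edges`` / ``nonlinear_edges`` carry a strength per group
    (mapping label -> strength) or a single float applied to all groups.
    """

    n_per_group: int
    labels: tuple[str, ...] = ("CN", "MCI", "AD")
    n_rois: int = 30
    n_timepoints: int = 140
    tr_seconds: float = 3.0
    band: tuple[float, float] = (0.01, 0.08)
    linear_edges: tuple[LinearEdge, ...] = ()
    nonlinear_edges: tuple[NonlinearEdge, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if not self.labels:
            raise ValidationError("labels must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("labels must be unique")
        for lab in self.labels:
            if lab not in KNOWN_LABELS:
                raise ValidationError(
                    f"labels: unknown group {lab!r}; expected subset of {KNOWN_LABELS}"
                )
        if self.n_rois < 2:
            raise ValidationError("n_rois must be >= 2")
        if self.n_timepoints < 32:
            raise ValidationError("n_timepoints must be >= 32")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValidationError("band: low must be < high and non-negative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        seen: set[tuple[int, int]] = set()
        for e in list(self.linear_edges) + list(self.nonlinear_edges):
            if not (0 <= e.source < self.n_rois and 0 <= e.target < self.n_rois):
                raise ValidationError(
                    f"edge ({e.source},{e.target}): ROI index out of range [0,{self.n_rois})"
                )
            if e.source == e.target:
                raise ValidationError(f"edge ({e.source},{e.target}): self-coupling")
            key = (min(e.source, e.target), max(e.source, e.target))
            if key in seen:
                raise ValidationError(
                    f"edge pair {key} appears in more than one edge list"
                )
            seen.add(key)
            smap = _as_strength_map(e.strength, self.labels)
            if not all(np.isfinite(v) for v in smap.values()):
                raise ValidationError(f"edge ({e.source},{e.target}): non-finite strength")
            if isinstance(e, NonlinearEdge) and e.transform not in TRANSFORMS:
                raise ValidationError(
                    f"edge ({e.source},{e.target}): unknown transform {e.transform!r}"
                )

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI{i:03d}" for i in range(self.n_rois)]


@dataclass
class RoiTimeSeries:
    """One subject's T x R matrix of ROI signals."""

    subject_id: str
    data: np.ndarray
    roi_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a T x R matrix")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValidationError("roi_labels length must match column count")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"subject {self.subject_id}: non-finite values")
        if np.any(self.data.std(axis=0) == 0):
            bad = int(np.flatnonzero(self.data.std(axis=0) == 0)[0])
            raise ValidationError(
                f"subject {self.subject_id}: ROI {self.roi_labels[bad]} is constant"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class LabeledCohort:
    subjects: list[RoiTimeSeries]
    labels: dict[str, str]
    spec: CohortSpec | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValidationError(f"subjects without label: {missing}")
        extra = [i for i in self.labels if i not in set(ids)]
        if extra:
            raise ValidationError(f"labels reference unknown subjects: {extra}")

    def group(self, label: str) -> list[RoiTimeSeries]:
        return [s for s in self.subjects if self.labels[s.subject_id] == label]

    def subset(self, groups: Sequence[str]) -> "LabeledCohort":
        keep = [s for s in self.subjects if self.labels[s.subject_id] in groups]
        labels = {s.subject_id: self.labels[s.subject_id] for s in keep}
        return LabeledCohort(subjects=keep, labels=labels, spec=self.spec)


def band_limited_noise(
    rng: np.random.Generator,
    n_timepoints: int,
    n_series: int,
    tr_seconds: float,
    band: tuple[float, float],
    noise_sd: float = 1.0,
) -> np.ndarray:
    """White Gaussian noise Fourier-masked to [band_low, band_high] Hz.

    The real FFT of each column is zeroed outside the pass band (DC always
    removed) and the inverse transform re-standardized to mean 0, sd
    ``noise_sd``.  Exact band control, no filter roll-off.
    """
    lo, hi = band
    white = rng.standard_normal((n_timepoints, n_series))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    mask = (freqs >= lo) & (freqs <= hi)
    mask[0] = False
    if not mask.any():
        raise ValidationError(
            f"band {band} contains no FFT bins at T={n_timepoints}, TR={tr_seconds}"
        )
    spec[~mask, :] = 0.0
    out = np.fft.irfft(spec, n=n_timepoints, axis=0)
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("band-limited noise degenerated to a constant")
    return noise_sd * out / sd


def _band_mask_filter(
    x: np.ndarray, tr_seconds: float, band: tuple[float, float]
) -> np.ndarray:
    """Fourier-mask a single series to the pass band (DC removed)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=tr_seconds)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    mask[0] = False
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=x.size)


def generate_subject(
    spec: CohortSpec, group: str, subject_id: str, rng: np.random.Generator
) -> RoiTimeSeries:
    data = band_limited_noise(
        rng, spec.n_timepoints, spec.n_rois, spec.tr_seconds, spec.band, spec.noise_sd
    )
    for e in spec.linear_edges:
        s = _as_strength_map(e.strength, spec.labels)[group]
        data[:, e.target] = _standardize(data[:, e.target] + s * data[:, e.source])
    for e in spec.nonlinear_edges:
        s = _as_strength_map(e.strength, spec.labels)[group]
        f = TRANSFORMS[e.transform]
        # the transform creates harmonics outside the pass band; mask the
        # injected component back to the band, as acquisition + band-pass
        # preprocessing would, so every emitted series stays band-limited
        injected = _standardize(
            _band_mask_filter(f(data[:, e.source]), spec.tr_seconds, spec.band)
        )
        data[:, e.target] = _standardize(data[:, e.target] + s * injected)
    data -= data.mean(axis=0)
    data /= data.std(axis=0)
    return RoiTimeSeries(
        subject_id=subject_id,
        data=data,
        roi_labels=spec.roi_labels,
        tr_seconds=spec.tr_seconds,
    )


def generate_cohort(spec: CohortSpec) -> LabeledCohort:
    """Generate ``n_per_group`` subjects for every group label.

    Deterministic given ``spec.seed``: each subject draws from an
    independent child stream of a single seed sequence, so the cohort is
    bit-reproducible and insensitive to generation order.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(spec.labels) * spec.n_per_group)
    subjects: list[RoiTimeSeries] = []
    labels: dict[str, str] = {}
    k = 0
    for group in spec.labels:
        for idx in range(spec.n_per_group):
            sid = f"{group}{idx:03d}"
            rng = np.random.Generator(np.random.PCG64(children[k]))
            subjects.append(generate_subject(spec, group, sid, rng))
            labels[sid] = group
            k += 1
    return LabeledCohort(subjects=subjects, labels=labels, spec=spec)


def default_contrast_spec(
    n_per_group: int = 20,
    labels: tuple[str, ...] = ("CN", "MCI", "AD"),
    n_rois: int = 30,
    n_timepoints: int = 140,
    seed: int = 0,
    linear_strength: float = 0.8,
    nonlinear_strengths: Mapping[str, float] | None = None,
    n_linear_edges: int = 5,
    n_nonlinear_edges: int = 10,
    tr_seconds: float = 3.0,
    band: tuple[float, float] = (0.01, 0.08),
    noise_sd: float = 1.0,
) -> CohortSpec:
    """Cohort whose groups differ ONLY through non-linear coupling strength.

    A backbone of linear edges with identical strength in every group
    (so linear connectivity carries no group information), plus non-linear
    edges whose strength grows with disease severity: CN 0.4, MCI 1.0,
    AD 1.6 by default.  Quadratic and absolute-value transforms are even
    functions of a symmetric source and hence essentially uncorrelated with
    it — invisible to Pearson correlation but visible to MIC/eMIC.
    """
    if nonlinear_strengths is None:
        nonlinear_strengths = {"CN": 0.4, "MCI": 1.0, "AD": 1.6}
    nonlinear_strengths = {g: nonlinear_strengths[g] for g in labels}
    # every non-linear edge gets its OWN source ROI: two targets driven by a
    # shared source would be linearly correlated with each other (their even
    # transforms of the same signal co-vary), leaking a PCC-visible group
    # difference and defeating the purely-non-linear contrast
    if n_rois < 2 * n_linear_edges + 2 * n_nonlinear_edges:
        raise ValidationError(
            "n_rois too small for the requested edge counts "
            f"(need >= {2 * n_linear_edges + 2 * n_nonlinear_edges})"
        )
    linear = tuple(
        LinearEdge(2 * i, 2 * i + 1, linear_strength) for i in range(n_linear_edges)
    )
    src0 = 2 * n_linear_edges
    tgt0 = src0 + n_nonlinear_edges
    cycle = ("quadratic", "absolute", "sine")
    nonlinear = tuple(
        NonlinearEdge(src0 + i, tgt0 + i, cycle[i % 3], dict(nonlinear_strengths))
        for i in range(n_nonlinear_edges)
    )
    return CohortSpec(
        n_per_group=n_per_group,
        labels=labels,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        tr_seconds=tr_seconds,
        band=band,
        linear_edges=linear,
        nonlinear_edges=nonlinear,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk format: one TSV per subject, a labels TSV, a flat-text manifest


def _spec_to_manifest(spec: CohortSpec | None, n_subjects: int) -> str:
    lines = [f"n_subjects = {n_subjects}", "format = fconn-cohort-v1"]
    if spec is not None:
        lines += [
            f"seed = {spec.seed}",
            f"n_per_group = {spec.n_per_group}",
            f"labels = {','.join(spec.labels)}",
            f"n_rois = {spec.n_rois}",
            f"n_timepoints = {spec.n_timepoints}",
            f"tr_seconds = {spec.tr_seconds}",
            f"band = {spec.band[0]},{spec.band[1]}",
            f"noise_sd = {spec.noise_sd}",
            f"n_linear_edges = {len(spec.linear_edges)}",
            f"n_nonlinear_edges = {len(spec.nonlinear_edges)}",
        ]
    return "\n".join(lines) + "\n"


def write_cohort(cohort: LabeledCohort, directory: str | Path) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subj in cohort.subjects:
        df = pd.DataFrame(subj.data, columns=subj.roi_labels)
        df.to_csv(directory / f"{subj.subject_id}.tsv", sep="\t", index=False,
                  float_format="%.17g")
    labels_df = pd.DataFrame(
        {"subject_id": [s.subject_id for s in cohort.subjects],
         "label": [cohort.labels[s.subject_id] for s in cohort.subjects]}
    )
    labels_df.to_csv(directory / "labels.tsv", sep="\t", index=False)
    manifest = _spec_to_manifest(cohort.spec, len(cohort.subjects))
    (directory / "manifest.txt").write_text(manifest)
    tr = cohort.subjects[0].tr_seconds if cohort.subjects else 0.0
    (directory / "tr_seconds.txt").write_text(f"{tr}\n")
    return {"n_subjects": len(cohort.subjects), "directory": str(directory)}


_ID_RE = re.compile(r"^[A-Za-z0-9_\-]+$")


def read_cohort(directory: str | Path) -> LabeledCohort:
    directory = Path(directory)
    labels_path = directory / "labels.tsv"
    if not labels_path.exists():
        raise ParseError(f"{labels_path}: labels file not found")
    labels_df = pd.read_csv(labels_path, sep="\t", dtype=str)
    if list(labels_df.columns) != ["subject_id", "label"]:
        raise ParseError(f"{labels_path}: expected columns subject_id, label")
    tr = 3.0
    tr_path = directory / "tr_seconds.txt"
    if tr_path.exists():
        tr = float(tr_path.read_text().strip())
    subjects = []
    for _, row in labels_df.iterrows():
        sid = row["subject_id"]
        if not _ID_RE.match(str(sid)):
            raise ParseError(f"{labels_path}: invalid subject id {sid!r}")
        path = directory / f"{sid}.tsv"
        if not path.exists():
            raise ParseError(f"{labels_path}: labels reference unknown subject {sid!r}")
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: {exc}") from exc
        if df.isna().any().any():
            bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
            raise ParseError(f"{path}: line {bad + 2}: missing or ragged values")
        subjects.append(
            RoiTimeSeries(
                subject_id=str(sid),
                data=df.to_numpy(dtype=float),
                roi_labels=list(df.columns),
                tr_seconds=tr,
            )
        )
    if not subjects:
        raise ParseError(f"{directory}: no subjects found")
    labels = dict(zip(labels_df["subject_id"], labels_df["label"]))
    return LabeledCohort(subjects=subjects, labels=labels)


def cohort_digest(cohort: LabeledCohort) -> str:
    """SHA-256 digest of all subject matrices; used in determinism checks."""
    h = hashlib.sha256()
    for subj in sorted(cohort.subjects, key=lambda s: s.subject_id):
        h.update(subj.subject_id.encode())
        h.update(np.ascontiguousarray(subj.data).tobytes())
    return h.hexdigest()
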