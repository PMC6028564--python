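"""Synthetic cohorts with planted, known ground truth.

Two generators:

* :func:`generate_cohort` emulates the output of resting-state fMRI
  preprocessing — per-subject ROI time-series matrices — for a two-group
  cohort in which selected region pairs are more strongly correlated in the
  case group than in the control group. Time series are drawn from a
  multivariate normal whose correlation matrix is the group target, so the
  population correlation of every pair is exactly the specified value.
* :func:`generate_feature_table` is the fast path for ensemble tests: it
  skips time series entirely and emits unit-variance Gaussian features with
  a standardized between-class mean shift on planted feature indices.

Default cohort dimensions mirror a typical resting-state study: 50 case /
42 control subjects, 90 regions, 110 retained timepoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rnncluster.features import FeatureTable

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "generate_cohort",
    "generate_feature_table",
    "planted_recovery",
    "write_cohort",
    "read_cohort",
]

#: smallest eigenvalue tolerated before a target correlation matrix is
#: declared non-positive-semidefinite
PSD_TOL = 1e-10


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: ROI time series plus class label and id."""

    subject_id: str
    label: str
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] < 3:
            raise ValueError("timeseries must be 2-D with >= 3 timepoints")
        if not np.all(np.isfinite(ts)):
            raise ValueError("timeseries contains missing/non-finite values")
        object.__setattr__(self, "timeseries", ts)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a planted-effect two-group cohort.

    Parameters
    ----------
    n_per_group : int
        Subjects per class.
    n_regions, n_timepoints : int
        Parcellation size R and retained timepoints T.
    planted_pairs : list of (i, j)
        Region pairs whose population correlation in the case group is
        ``base_rho + delta_rho`` instead of ``base_rho``.
    delta_rho : float in [0, 1)
        Correlation shift magnitude.
    base_rho : float
        Baseline inter-region correlation (all off-diagonal pairs).
    noise_sd : float
        Amplitude scale of the series (arbitrary signal units; Pearson
        correlation is scale-invariant, so this does not affect features).
    seed : int
        RNG seed; generation is reproducible given the seed (PCG64).
    repair : bool
        If True, a target matrix that narrowly fails the PSD check is
        repaired by eigenvalue clipping instead of rejected.
    """

    n_per_group: int
    n_regions: int = 90
    n_timepoints: int = 110
    planted_pairs: tuple = ()
    delta_rho: float = 0.0
    base_rho: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0
    repair: bool = False
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not 0.0 <= self.delta_rho < 1.0:
            raise ValueError("delta_rho must be in [0, 1)")
        if not -1.0 < self.base_rho < 1.0:
            raise ValueError("base_rho must be in (-1, 1)")
        pairs = []
        seen = set()
        for p in self.planted_pairs:
            i, j = int(p[0]), int(p[1])
            if i == j:
                raise ValueError(f"planted pair ({i}, {j}) is degenerate")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(
                    f"planted pair ({i}, {j}) outside {self.n_regions} regions"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"planted pair {key} listed twice")
            seen.add(key)
            pairs.append(key)
        object.__setattr__(self, "planted_pairs", tuple(pairs))
        if not -1.0 <= self.base_rho + self.delta_rho <= 1.0:
            raise ValueError("base_rho + delta_rho outside [-1, 1]")

    def target_correlation(self, group: str) -> np.ndarray:
        """Population correlation matrix for 'case' or 'control'."""
        r = self.n_regions
        c = np.full((r, r), self.base_rho)
        np.fill_diagonal(c, 1.0)
        if group == "case":
            for i, j in self.planted_pairs:
                c[i, j] = c[j, i] = self.base_rho + self.delta_rho
        elif group != "control":
            raise ValueError(f"unknown group {group!r}")
        return c


def _factor_correlation(c: np.ndarray, spec: CohortSpec, group: str) -> np.ndarray:
    """PSD-check a target correlation matrix and return a sampling factor."""
    w, v = np.linalg.eigh(c)
    if w.min() < -PSD_TOL:
        if not spec.repair:
            pairs = ", ".join(str(p) for p in spec.planted_pairs) or "(none)"
            raise ValueError(
                f"target correlation for the {group} group is not positive "
                f"semidefinite (min eigenvalue {w.min():.3g}); planted pairs "
                f"involved: {pairs}. Reduce delta_rho/base_rho or set "
                "repair=True to clip eigenvalues."
            )
        w = np.clip(w, 0.0, None)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw ``2 * n_per_group`` subjects from the planted-effect model.

    Control subjects have population correlation ``base_rho`` on every
    off-diagonal pair; case subjects additionally have
    ``base_rho + delta_rho`` on the planted pairs. Raises ``ValueError``
    (naming the planted pairs) if a target matrix is not positive
    semidefinite.
    """
    rng = np.random.default_rng(spec.seed)
    factors = {
        g: _factor_correlation(spec.target_correlation(g), spec, g)
        for g in ("control", "case")
    }
    labels = {"case": spec.case_label, "control": spec.control_label}
    subjects: list[SubjectRecord] = []
    counter = 0
    for group in ("case", "control"):
        fac = factors[group]
        for _ in range(spec.n_per_group):
            counter += 1
            z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            ts = spec.noise_sd * (z @ fac.T)
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{counter:04d}",
                    label=labels[group],
                    timeseries=ts,
                )
            )
    return subjects


def generate_feature_table(
    n_per_group: int,
    p: int,
    planted_features=(),
    effect_size: float = 0.0,
    seed: int = 0,
    case_label: str = "case",
    control_label: str = "control",
) -> FeatureTable:
    """Gaussian feature table with a planted standardized mean shift.

    Features are unit-variance normal. Planted features differ between
    classes by ``effect_size`` standard deviations (case mean
    ``+effect_size/2``, control ``-effect_size/2``); all other features
    have zero class difference.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    planted = sorted({int(i) for i in planted_features})
    if planted and (planted[0] < 0 or planted[-1] >= p):
        raise ValueError(f"planted feature indices must be in [0, {p})")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    x = rng.standard_normal((n, p))
    shift = np.zeros(p)
    shift[planted] = effect_size / 2.0
    x[:n_per_group] += shift
    x[n_per_group:] -= shift
    y = np.array([case_label] * n_per_group + [control_label] * n_per_group)
    ids = [f"sub-{k + 1:04d}" for k in range(n)]
    return FeatureTable(X=x, y=y, subject_ids=ids, layout=None)


def planted_recovery(selected, planted) -> tuple[float, float]:
    """Recall and precision of a selected feature set against the truth.

    ``recall = |selected ∩ planted| / |planted|``;
    ``precision = |selected ∩ planted| / |selected|`` (0 when selected is
    empty).
    """
    sel = set(int(i) for i in selected)
    tru = set(int(i) for i in planted)
    hit = len(sel & tru)
    recall = hit / len(tru) if tru else 0.0
    precision = hit / len(sel) if sel else 0.0
    return recall, precision


def write_cohort(subjects: list[SubjectRecord], out_dir, spec: CohortSpec | None = None) -> None:
    """Write per-subject TSV time series, a manifest CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        rel = f"{s.subject_id}.tsv"
        np.savetxt(out / rel, s.timeseries, delimiter="\t", fmt="%.10g")
        rows.append({"subject_id": s.subject_id, "label": s.label, "path": rel})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if spec is not None:
        truth = {
            "planted_pairs": [list(p) for p in spec.planted_pairs],
            "delta_rho": spec.delta_rho,
            "base_rho": spec.base_rho,
            "n_per_group": spec.n_per_group,
            "n_regions": spec.n_regions,
            "n_timepoints": spec.n_timepoints,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def read_cohort(in_dir) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort` (manifest order)."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    subjects = []
    for row in manifest.itertuples(index=False):
        ts = np.loadtxt(src / row.path, delimiter="\t")
        subjects.append(
            SubjectRecord(subject_id=str(row.subject_id), label=str(row.label),
                          timeseries=ts)
        )
    return subjects
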