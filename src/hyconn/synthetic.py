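"""Synthetic two-group cohorts of ROI time series with planted connectivity differences.

The generator draws each subject's region-by-time matrix from a zero-mean
multivariate Gaussian whose correlation structure follows a block model
(communities of mutually correlated regions), optionally perturbed in the
patient group only. Because the population Pearson matrix of a Gaussian
sample *is* the target correlation matrix, every downstream stage (network
construction, classification, biomarker ranking) can be tested against a
known ground truth without real fMRI data.

Two named scenarios are packaged:

- :func:`separable_scenario` — large between-group correlation changes, for
  checking that the pipeline recovers strongly planted structure;
- :func:`ordinal_perturbation_scenario` — several small same-sign
  perturbations (each ≤ 0.1) that reorder which regions are mutually
  nearest without much changing any single pairwise correlation, the regime
  the triplet (second-order) network is designed to detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BlockModel",
    "CohortSpec",
    "Subject",
    "SubjectCohort",
    "build_group_correlation",
    "generate_cohort",
    "separable_scenario",
    "ordinal_perturbation_scenario",
]

#: smallest admissible eigenvalue when repairing a perturbed correlation matrix
EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class BlockModel:
    """Block (community) correlation structure.

    ``n_blocks`` contiguous groups of regions; correlation ``within`` inside
    a block, ``between`` across blocks, unit diagonal. Block sizes must
    partition ``n_regions`` (the last block absorbs any remainder).
    """

    n_blocks: int = 4
    within: float = 0.6
    between: float = 0.1


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a two-group synthetic cohort.

    ``perturbations`` is a sequence of ``(i, j, delta)`` triples added to the
    patient group's target correlation matrix only (symmetrically); the
    result is repaired to positive definiteness by eigenvalue flooring.
    Identical spec + seed yields a bit-identical cohort.
    """

    n_patients: int
    n_controls: int
    n_regions: int = 90
    n_timepoints: int = 170
    base_correlation: BlockModel = field(default_factory=BlockModel)
    perturbations: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class Subject:
    subject_id: str
    label: str  # "patient" | "control"
    values: np.ndarray  # n_regions x n_timepoints


@dataclass
class SubjectCohort:
    subjects: list

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    def group(self, label: str) -> list:
        return [s for s in self.subjects if s.label == label]


def _block_sizes(n_regions: int, n_blocks: int) -> list:
    if n_blocks < 1 or n_blocks > n_regions:
        raise ValueError(f"n_blocks={n_blocks} cannot partition {n_regions} regions")
    base = n_regions // n_blocks
    sizes = [base] * n_blocks
    sizes[-1] += n_regions - base * n_blocks
    return sizes


def _repair_pd(R: np.ndarray) -> np.ndarray:
    """Floor eigenvalues at EIG_FLOOR, then rescale back to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w[0] > 0:
        return R
    w = np.maximum(w, EIG_FLOOR)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    if np.any(d <= 0):
        raise ValueError("correlation matrix not repairable: zero diagonal after flooring")
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    w2 = np.linalg.eigvalsh(R)[0]
    if w2 <= 0:
        raise ValueError(f"correlation matrix not repairable: min eigenvalue {w2:g} after flooring")
    return R


def build_group_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Target correlation matrix for ``group`` ('patient' or 'control').

    The control matrix is the pure block model; the patient matrix adds the
    spec's perturbations and is repaired to positive definiteness.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    bm = spec.base_correlation
    sizes = _block_sizes(spec.n_regions, bm.n_blocks)
    R = np.full((spec.n_regions, spec.n_regions), bm.between, dtype=float)
    start = 0
    for s in sizes:
        R[start : start + s, start : start + s] = bm.within
        start += s
    np.fill_diagonal(R, 1.0)
    if group == "patient":
        for i, j, delta in spec.perturbations:
            if i == j:
                raise ValueError("perturbation on the diagonal is not allowed")
            R[i, j] += delta
            R[j, i] += delta
    return _repair_pd(R)


def generate_cohort(spec: CohortSpec) -> SubjectCohort:
    """Draw the cohort: one n_regions × n_timepoints Gaussian sample per subject.

    Each time point is an independent multivariate normal draw with the
    group's target correlation; ``noise_sd`` adds independent N(0, noise_sd²)
    measurement noise per entry.
    """
    if spec.n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2")
    if spec.n_regions < 3:
        raise ValueError("n_regions must be at least 3 (triplets need 3 regions)")
    chol = {
        g: np.linalg.cholesky(build_group_correlation(spec, g))
        for g in ("patient", "control")
    }
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_patients + spec.n_controls
    children = ss.spawn(n_total)
    subjects = []
    idx = 0
    for group, count in (("patient", spec.n_patients), ("control", spec.n_controls)):
        for i in range(count):
            rng = np.random.default_rng(children[idx])
            Z = rng.standard_normal((spec.n_regions, spec.n_timepoints))
            X = chol[group] @ Z
            if spec.noise_sd > 0:
                X = X + spec.noise_sd * rng.standard_normal(X.shape)
            subjects.append(Subject(f"{group}_{i + 1:03d}", group, X))
            idx += 1
    return SubjectCohort(subjects)


def separable_scenario(seed: int = 0) -> CohortSpec:
    """Strongly separated cohort: large planted correlation changes.

    40 + 40 subjects, 20 regions in 4 blocks (within 0.6, between 0.1),
    six between-block edges raised by +0.5 in patients. A classifier that
    sees the connectivity at all should approach perfect accuracy.
    """
    return CohortSpec(
        n_patients=40,
        n_controls=40,
        n_regions=20,
        n_timepoints=170,
        base_correlation=BlockModel(n_blocks=4, within=0.6, between=0.1),
        perturbations=(
            (0, 5, 0.5),
            (1, 6, 0.5),
            (2, 7, 0.5),
            (10, 15, 0.5),
            (11, 16, 0.5),
            (3, 8, 0.5),
        ),
        noise_sd=0.2,
        seed=seed,
    )


def ordinal_perturbation_scenario(seed: int = 0) -> CohortSpec:
    """Cohort whose group difference is mostly ordinal (neighbor-ranking).

    Within each block every pair shares the same base correlation, so a
    region's nearest neighbors are decided by sampling noise alone. In the
    patient group, small same-sign increments (each ≤ 0.1) pull specific
    same-block partners ahead of the rest, deterministically reordering the
    perturbed regions' k-nearest-neighbor sets while changing any single
    pairwise correlation by at most 0.1.
    """
    return CohortSpec(
        n_patients=40,
        n_controls=40,
        n_regions=20,
        n_timepoints=170,
        base_correlation=BlockModel(n_blocks=4, within=0.4, between=0.05),
        perturbations=(
            (0, 4, 0.1),
            (1, 3, 0.1),
            (5, 9, 0.1),
            (6, 8, 0.1),
            (10, 14, 0.1),
            (11, 13, 0.1),
            (15, 19, 0.1),
            (16, 18, 0.1),
            (2, 4, 0.08),
            (7, 9, 0.08),
        ),
        noise_sd=0.2,
        seed=seed,
    )


def write_cohort(cohort: SubjectCohort, directory, region_labels: Sequence[str] | None = None):
    """Write per-subject TSV matrices plus a manifest TSV into ``directory``.

    Returns the manifest path. Format matches :mod:`hyconn.io`.
    """
    from . import io as hio  # local import: io depends on nothing here
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for s in cohort:
        path = directory / f"{s.subject_id}.tsv"
        hio.write_timeseries(
            hio.ROITimeSeriesMatrix(s.values, region_labels=list(region_labels) if region_labels else None,
                                    subject_id=s.subject_id),
            path,
        )
        records.append((s.subject_id, s.label, str(path)))
    manifest_path = directory / "manifest.tsv"
    hio.write_manifest(hio.CohortManifest(records), manifest_path)
    return manifest_path
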