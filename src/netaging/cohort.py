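"""Synthetic longitudinal cohorts with planted modular connectivity.

Emulates the structure of a longitudinal mouse rs-fMRI study: 72 bilateral
ROIs (36 regions x left/right) organised into 6 planted modules, three scan
waves at roughly 12, 18 and 24 months of age (exact ages in days, jittered
per animal), 1-2 sessions per wave, 415 usable volumes per scan, multiple
cohorts of both sexes with dropout, and group-dependent linear aging effects
on within- and between-module correlation. Group "X" animals de-segregate
with age (within-module correlation falls, between-module rises); group "Y"
animals stay flat by default.

All quantities are pure functions of (spec, seed); the generator also emits
the ground truth (planted partition, per-subject true correlations and the
segregation-index trajectory they imply).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTH_DAYS",
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "SpecValidationError",
    "default_partition",
    "default_roi_names",
    "build_cohort_design",
    "target_correlation_matrix",
    "nearest_positive_definite",
    "simulate_timeseries",
    "aging_effect",
    "true_segregation_index",
    "simulate_cohort",
]

MONTH_DAYS = 365.25 / 12.0


class SpecValidationError(ValueError):
    """A cohort spec field violates its invariant; the message names it."""


def default_partition(n_rois: int = 72, n_modules: int = 6) -> np.ndarray:
    """Bilateral-symmetric planted partition: equal modules, ROI pairs
    (2k-1, 2k) are left/right partners with identical labels."""
    if n_rois % (2 * n_modules):
        raise SpecValidationError(
            f"n_rois={n_rois} not divisible into {n_modules} bilateral modules")
    return np.repeat(np.arange(1, n_modules + 1), n_rois // n_modules)


def default_roi_names(n_rois: int = 72) -> list[str]:
    """Region stems with _L/_R hemisphere suffixes; consecutive pairs are
    homotopic partners."""
    if n_rois % 2:
        raise SpecValidationError("n_rois must be even (bilateral atlas)")
    return [f"R{k + 1:02d}_{side}" for k in range(n_rois // 2)
            for side in ("L", "R")]


@dataclass(frozen=True)
class CohortSpec:
    """Design and effect-size parameters of a synthetic longitudinal cohort.

    Correlations age linearly in days (per-group slopes, units 1/day) before
    the Fisher transform, plus a per-subject random offset (sd
    ``subject_sd``) applied to both within- and between-module correlation;
    the result is clipped to [0, 0.95].
    """

    n_subjects_per_cell: int = 4
    cohorts: tuple[tuple[str, str], ...] = (("A", "Y"), ("B", "X"))
    sexes: tuple[str, ...] = ("F", "M")
    timepoints_days: tuple[float, ...] = (365.0, 548.0, 730.0)
    sessions_per_timepoint: int = 2
    n_volumes: int = 415
    n_rois: int = 72
    n_modules: int = 6
    within_r0: float = 0.5
    between_r0: float = 0.1
    within_slope: Mapping[str, float] = field(
        default_factory=lambda: {"X": -1.0e-4, "Y": 0.0})
    between_slope: Mapping[str, float] = field(
        default_factory=lambda: {"X": 1.0e-4, "Y": 0.0})
    subject_sd: float = 0.02
    age_jitter_days: float = 14.0
    dropout_prob_per_timepoint: float = 0.1
    ar1: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_cell < 1:
            raise SpecValidationError("n_subjects_per_cell must be >= 1")
        if not self.cohorts:
            raise SpecValidationError("cohorts must be non-empty")
        for label, group in self.cohorts:
            if group not in ("X", "Y"):
                raise SpecValidationError(
                    f"cohorts: group for cohort {label!r} must be 'X' or 'Y'")
        if self.n_rois % 2 or self.n_rois < 2:
            raise SpecValidationError("n_rois must be even and >= 2")
        if self.n_rois % (2 * self.n_modules):
            raise SpecValidationError(
                "n_modules must divide n_rois into bilateral modules")
        if not (0.0 <= self.between_r0 < self.within_r0 < 1.0):
            raise SpecValidationError(
                "require 0 <= between_r0 < within_r0 < 1 "
                f"(got between_r0={self.between_r0}, within_r0={self.within_r0})")
        if not (0.0 <= self.dropout_prob_per_timepoint < 1.0):
            raise SpecValidationError("dropout_prob_per_timepoint must be in [0, 1)")
        tps = np.asarray(self.timepoints_days, dtype=float)
        if tps.size < 1 or np.any(np.diff(tps) <= 0):
            raise SpecValidationError("timepoints_days must be strictly increasing")
        if self.sessions_per_timepoint < 1:
            raise SpecValidationError("sessions_per_timepoint must be >= 1")
        if self.n_volumes < 10:
            raise SpecValidationError("n_volumes must be >= 10")
        if not (0.0 <= self.ar1 < 1.0):
            raise SpecValidationError("ar1 must be in [0, 1)")
        for name, m in (("within_slope", self.within_slope),
                        ("between_slope", self.between_slope)):
            for _, group in self.cohorts:
                if group not in m:
                    raise SpecValidationError(f"{name} missing group {group!r}")

    @property
    def partition(self) -> np.ndarray:
        return default_partition(self.n_rois, self.n_modules)

    @property
    def roi_names(self) -> list[str]:
        return default_roi_names(self.n_rois)

    def timepoint_label(self, index: int) -> str:
        return f"{round(self.timepoints_days[index] / MONTH_DAYS)}mo"


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind a simulated cohort."""

    partition: np.ndarray
    subject_offsets: Mapping[str, float]
    table: pd.DataFrame   # subject_id, timepoint_label, age_days, within_r, between_r, si_true


def _design_rngs(spec: CohortSpec):
    ss = np.random.SeedSequence([int(spec.seed), 101])
    return [np.random.default_rng(c) for c in ss.spawn(3)]


def true_segregation_index(within_r: float, between_r: float) -> float:
    """SI implied by uniform block correlations, on the Fisher-z scale:
    (zw - zb+)/zw with zb+ the positive part of atanh(between_r)."""
    zw = float(np.arctanh(within_r))
    zb = float(np.arctanh(between_r))
    if zw <= 0:
        return float("nan")
    zb = max(zb, 0.0)
    return (zw - zb) / zw


def aging_effect(spec: CohortSpec, group: str, age_days: float,
                 subject_offset: float = 0.0) -> tuple[float, float]:
    """(within_r, between_r) at an exact age, for one group and subject.

    Linear in days from the first target time point, plus the subject's
    random offset on both correlations, clipped to [0, 0.95].
    """
    dt = float(age_days) - float(spec.timepoints_days[0])
    within = spec.within_r0 + spec.within_slope[group] * dt + subject_offset
    between = spec.between_r0 + spec.between_slope[group] * dt + subject_offset
    return (float(np.clip(within, 0.0, 0.95)),
            float(np.clip(between, 0.0, 0.95)))


def build_cohort_design(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """One row per surviving (subject, time point, session), with jittered
    exact ages, cumulative dropout and per-subject ground truth."""
    spec.validate()
    rng_age, rng_drop, rng_offset = _design_rngs(spec)
    rows, truth_rows, offsets = [], [], {}
    for cohort, group in spec.cohorts:
        for sex in spec.sexes:
            for i in range(spec.n_subjects_per_cell):
                sid = f"{cohort}-{sex}{i + 1:02d}"
                offsets[sid] = float(rng_offset.normal(0.0, spec.subject_sd))
                alive = True
                for ti, target in enumerate(spec.timepoints_days):
                    age = float(target + rng_age.uniform(
                        -spec.age_jitter_days, spec.age_jitter_days))
                    if ti > 0 and alive:
                        if rng_drop.random() < spec.dropout_prob_per_timepoint:
                            alive = False
                    if not alive:
                        continue
                    tp = spec.timepoint_label(ti)
                    w, b = aging_effect(spec, group, age, offsets[sid])
                    truth_rows.append(dict(
                        subject_id=sid, timepoint_label=tp, age_days=age,
                        within_r=w, between_r=b,
                        si_true=true_segregation_index(w, b)))
                    for s in range(spec.sessions_per_timepoint):
                        rows.append(dict(
                            subject_id=sid, sex=sex, cohort=cohort,
                            group=group, timepoint_label=tp, age_days=age,
                            session_id=f"{sid}_{tp}_s{s + 1}"))
    design = pd.DataFrame(rows)
    truth = GroundTruth(partition=spec.partition,
                        subject_offsets=offsets,
                        table=pd.DataFrame(truth_rows))
    return design, truth


def nearest_positive_definite(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue flooring at ``floor`` followed by renormalisation to unit
    diagonal; returns a symmetric positive-definite correlation matrix."""
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    C2 = (V * np.clip(w, floor, None)) @ V.T
    d = np.sqrt(np.diagonal(C2))
    C2 = C2 / np.outer(d, d)
    C2 = (C2 + C2.T) / 2.0
    np.fill_diagonal(C2, 1.0)
    return C2


def target_correlation_matrix(partition: np.ndarray, within_r: float,
                              between_r: float,
                              pd_floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Block correlation matrix: unit diagonal, ``within_r`` inside modules,
    ``between_r`` across. Returns (matrix, repaired); ``repaired`` is True
    when a nearest-PD repair (eigenvalue flooring + renormalisation) was
    needed."""
    if not (0.0 <= between_r <= within_r):
        raise ValueError("require 0 <= between_r <= within_r")
    if within_r >= 1.0:
        raise ValueError("within_r must be < 1")
    lab = np.asarray(partition)
    same = lab[:, None] == lab[None, :]
    C = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(C, 1.0)
    wmin = float(np.linalg.eigvalsh(C)[0])
    repaired = False
    if wmin < pd_floor:
        C = nearest_positive_definite(C, floor=pd_floor)
        repaired = True
    return C, repaired


def simulate_timeseries(target: np.ndarray, n_volumes: int,
                        seed: int | np.random.Generator = 0,
                        ar1: float = 0.0) -> np.ndarray:
    """(n_rois, n_volumes) zero-mean Gaussian draws whose population
    (lag-0) correlation equals ``target``.

    Volumes are i.i.d. by default; ``ar1`` > 0 adds standardised AR(1)
    temporal structure per latent channel (lag-0 cross-correlation is
    unchanged) for robustness experiments.
    """
    if n_volumes < 10:
        raise ValueError("n_volumes must be >= 10")
    target = np.asarray(target, dtype=float)
    try:
        L = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as e:
        raise ValueError("target correlation matrix is not positive definite") from e
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = target.shape[0]
    E = rng.standard_normal((n, n_volumes))
    if ar1 > 0.0:
        phi = float(ar1)
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, n_volumes):
            E[:, t] = phi * E[:, t - 1] + scale * E[:, t]
    return L @ E


@dataclass(frozen=True)
class SimulatedCohort:
    """Design table, ground truth and per-session ROI time series."""

    spec: CohortSpec
    design: pd.DataFrame
    truth: GroundTruth
    sessions: Mapping[str, np.ndarray]   # session_id -> (n_rois, n_volumes)

    def subject_matrices(self, positive_only: bool = False):
        """Averaged Fisher-z matrix per (subject, time point), the Z (or Z+)
        the downstream analysis consumes. Returns
        dict[(subject_id, timepoint_label)] -> ConnectivityMatrix."""
        from .connectivity import (average_sessions, fisher_z, pearson_matrix,
                                   positive_part)
        out = {}
        roi = self.spec.roi_names
        for (sid, tp), grp in self.design.groupby(
                ["subject_id", "timepoint_label"], sort=False):
            mats = [fisher_z(pearson_matrix(self.sessions[s], roi), roi,
                             subject_id=sid, timepoint_label=tp)
                    for s in grp["session_id"]]
            Z = average_sessions(mats)
            out[(sid, tp)] = positive_part(Z) if positive_only else Z
        return out


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Full generation: design + ground truth + session time series.
    Pure function of the spec (which carries the seed)."""
    design, truth = build_cohort_design(spec)
    truth_idx = truth.table.set_index(["subject_id", "timepoint_label"])
    session_ss = np.random.SeedSequence([int(spec.seed), 202])
    child = session_ss.spawn(len(design))
    sessions = {}
    for (_, row), cs in zip(design.iterrows(), child):
        w = truth_idx.loc[(row.subject_id, row.timepoint_label), "within_r"]
        b = truth_idx.loc[(row.subject_id, row.timepoint_label), "between_r"]
        C, _ = target_correlation_matrix(spec.partition, float(w), float(b))
        sessions[row.session_id] = simulate_timeseries(
            C, spec.n_volumes, seed=np.random.default_rng(cs), ar1=spec.ar1)
    return SimulatedCohort(spec=spec, design=design, truth=truth,
                           sessions=sessions)
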