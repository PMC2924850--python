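"""Echo-rule grading, CMR threshold flags and diagnostic performance.

The echo reference grades diastolic dysfunction (DD) from mitral inflow and
tissue-Doppler criteria; the cine-CMR indices are then scored against that
reference per grade, always versus the common pool of patients with normal
echo filling.  Index cutoffs other than the DVR80 normative threshold are
calibrated to a matched specificity (default 83%) on the normal group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import EchoPanel
from .errors import CalibrationError, InfeasibleParametersError

INDETERMINATE = "indeterminate"

#: flag names for the CMR index abnormality set
FLAGS = ("prolonged_dvr", "long_tpfr", "high_pfr", "high_npfr")


@dataclass(frozen=True)
class Thresholds:
    """Diagnostic cutoffs for the cine-CMR indices.

    Defaults are the published operating points: DVR80 normal < 77% of
    diastole (normative threshold from prior controls), with TPFR 221 ms,
    PFR 344 ml/s and nPFR 4.02 /s calibrated to the matched 83% specificity.
    Abnormality is strict exceedance on the ``above`` side.
    """

    dvr80_cut: float = 77.0
    tpfr_cut: float = 221.0
    pfr_cut: float = 344.0
    npfr_cut: float = 4.02
    directions: Mapping[str, str] = field(
        default_factory=lambda: {
            "prolonged_dvr": "above",
            "long_tpfr": "above",
            "high_pfr": "above",
            "high_npfr": "above",
        }
    )

    def __post_init__(self) -> None:
        for name in ("dvr80_cut", "tpfr_cut", "pfr_cut", "npfr_cut"):
            if getattr(self, name) <= 0:
                raise InfeasibleParametersError(f"{name} must be positive")
        for flag, side in self.directions.items():
            if side not in ("above", "below"):
                raise InfeasibleParametersError(
                    f"direction for {flag!r} must be 'above' or 'below'"
                )


# ---------------------------------------------------------------------------
# Echo grading
# ---------------------------------------------------------------------------


def grade_echo(panel: EchoPanel) -> str:
    """Assign a DD grade from an echo panel.

    The four published rules are tested in order normal -> 1 -> 2 -> 3 with
    the first match winning.  Panels with equivocal tissue Doppler (abnormal
    lateral but normal septal e') are adjudicated with e'/a' reversal when
    supplied; anything else returns ``"indeterminate"`` rather than being
    coerced.
    """
    ea, dt = panel.e_over_a, panel.dt_ms
    septal, lateral = panel.septal_e_prime, panel.lateral_e_prime

    if ea >= 0.8 and septal >= 8.0 and lateral >= 10.0 and 140.0 <= dt <= 240.0:
        return "normal"
    low_eprime = septal < 8.0 and lateral < 10.0
    if low_eprime:
        if ea < 0.8 and dt > 240.0:
            return "grade1"
        if 0.8 <= ea <= 1.5 and 140.0 <= dt <= 240.0:
            return "grade2"
        if ea >= 2.0 and dt < 140.0:
            return "grade3"
        return INDETERMINATE

    equivocal = lateral < 10.0 and septal >= 8.0
    if equivocal:
        reversals = [
            r
            for r in (
                panel.eprime_over_aprime_septal,
                panel.eprime_over_aprime_lateral,
            )
            if r is not None
        ]
        if reversals and min(reversals) < 1.0:
            # dysfunction established; sub-grade from the inflow pattern
            if ea < 0.8 and dt > 240.0:
                return "grade1"
            if ea >= 2.0 and dt < 140.0:
                return "grade3"
            return "grade2"
    return INDETERMINATE


# ---------------------------------------------------------------------------
# CMR flags
# ---------------------------------------------------------------------------


def _flag(value: float, cut: float, direction: str) -> bool:
    return value > cut if direction == "above" else value < cut


def classify_cmr(idx, th: Thresholds | None = None) -> frozenset[str]:
    """Abnormality flag set for one patient's indices.

    ``idx`` is a :class:`~cinefill.indices.DiastolicIndices` (or anything
    with ``dvr``, ``tpfr_ms``, ``pfr``, ``npfr`` attributes).  Flags use
    strict inequalities on the abnormal side of each cutoff.
    """
    th = th or Thresholds()
    flags = set()
    if _flag(idx.dvr, th.dvr80_cut, th.directions["prolonged_dvr"]):
        flags.add("prolonged_dvr")
    if _flag(idx.tpfr_ms, th.tpfr_cut, th.directions["long_tpfr"]):
        flags.add("long_tpfr")
    if _flag(idx.pfr, th.pfr_cut, th.directions["high_pfr"]):
        flags.add("high_pfr")
    if _flag(idx.npfr, th.npfr_cut, th.directions["high_npfr"]):
        flags.add("high_npfr")
    return frozenset(flags)


def aggregate_criterion(flags: Iterable[str]) -> bool:
    """Combined filling-interval/filling-rate criterion.

    A patient is called abnormal when either DVR80 is prolonged or PFR is
    high -- the pairing that captures the dissociation between impaired
    relaxation (grade 1) and restrictive filling (grade 3).
    """
    flags = set(flags)
    return "prolonged_dvr" in flags or "high_pfr" in flags


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------


def calibrate_threshold(
    normal_values: Sequence[float],
    direction: str = "above",
    target_specificity: float = 0.83,
) -> float:
    """Most sensitive cutoff achieving a target specificity on normals.

    Candidate cutoffs are the midpoints between sorted distinct normal
    values plus one candidate beyond each extreme; the returned cutoff is
    the smallest (``direction="above"``) or largest (``"below"``) candidate
    whose specificity on ``normal_values`` is at least the target.
    Abnormality is strict exceedance, matching :func:`classify_cmr`.
    """
    values = np.asarray(list(normal_values), dtype=float)
    if values.size < 5:
        raise CalibrationError(
            f"need at least 5 normal values to calibrate, got {values.size}"
        )
    if not (0.0 < target_specificity < 1.0):
        raise CalibrationError("target specificity must be in (0, 1)")
    if direction not in ("above", "below"):
        raise CalibrationError("direction must be 'above' or 'below'")

    distinct = np.unique(values)
    margin = float(distinct[-1] - distinct[0]) * 0.5 or 1.0
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - margin], mids, [distinct[-1] + margin]])

    if direction == "above":
        spec = np.array([(values <= c).mean() for c in candidates])
        order = np.argsort(candidates)  # smallest passing cutoff first
    else:
        spec = np.array([(values >= c).mean() for c in candidates])
        order = np.argsort(candidates)[::-1]  # largest passing cutoff first
    for i in order:
        if spec[i] >= target_specificity:
            return float(candidates[i])
    raise CalibrationError(
        f"no cutoff reaches specificity {target_specificity} on these values"
    )


# ---------------------------------------------------------------------------
# Diagnostic performance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise InfeasibleParametersError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-ward ties up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion-matrix summary with integer-percent renderings.

    Ratios with a zero denominator are reported as ``None`` (absent), never
    as zero.
    """

    matrix: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self) -> dict[str, int | None]:
        return {
            name: None if value is None else round_half_up(100.0 * value)
            for name, value in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "ppv": self.ppv,
                "npv": self.npv,
            }.items()
        }


def performance_from_matrix(matrix: ConfusionMatrix) -> PerformanceMetrics:
    """Sensitivity/specificity/accuracy/PPV/NPV from counts."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return PerformanceMetrics(
        matrix=matrix,
        sensitivity=ratio(matrix.tp, matrix.tp + matrix.fn),
        specificity=ratio(matrix.tn, matrix.tn + matrix.fp),
        accuracy=ratio(matrix.tp + matrix.tn, matrix.total) if matrix.total else None,
        ppv=ratio(matrix.tp, matrix.tp + matrix.fp),
        npv=ratio(matrix.tn, matrix.tn + matrix.fn),
    )


def diagnostic_performance(
    predicted: Sequence[bool],
    truth: Sequence[bool],
) -> PerformanceMetrics:
    """Score predicted abnormality flags against binary reference labels."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise InfeasibleParametersError(
            f"length mismatch: {predicted.shape} vs {truth.shape}"
        )
    matrix = ConfusionMatrix(
        tp=int(np.sum(predicted & truth)),
        fn=int(np.sum(~predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        tn=int(np.sum(~predicted & ~truth)),
    )
    return performance_from_matrix(matrix)


# ---------------------------------------------------------------------------
# Per-grade report assembly
# ---------------------------------------------------------------------------

_INDEX_COLUMNS = {
    "dvr80": ("dvr80_pct", "prolonged_dvr"),
    "tpfr": ("tpfr_ms", "long_tpfr"),
    "pfr": ("pfr_ml_s", "high_pfr"),
    "npfr": ("npfr_per_s", "high_npfr"),
}


@dataclass(frozen=True)
class DiagnosticReport:
    """Per-grade, per-index diagnostic performance table."""

    entries: pd.DataFrame  # columns: grade, index, threshold, tp, fn, fp, tn, metrics

    def metrics(self, grade: str, index: str) -> PerformanceMetrics:
        row = self.entries[
            (self.entries["grade"] == grade) & (self.entries["index"] == index)
        ]
        if row.empty:
            raise KeyError((grade, index))
        r = row.iloc[0]
        return performance_from_matrix(
            ConfusionMatrix(tp=int(r.tp), fn=int(r.fn), fp=int(r.fp), tn=int(r.tn))
        )


def build_report(
    index_table: pd.DataFrame,
    grades: Sequence[str],
    thresholds: Thresholds | None = None,
) -> DiagnosticReport:
    """Score every CMR index against each dysfunction grade.

    ``index_table`` has one row per patient with the documented index column
    names (``dvr80_pct``, ``tpfr_ms``, ``pfr_ml_s``, ``npfr_per_s``);
    ``grades`` gives the per-patient reference grade.  For each dysfunction
    grade g the evaluation set is {grade g} united with the normal group,
    mirroring the published table structure.
    """
    th = thresholds or Thresholds()
    grades = np.asarray([str(g) for g in grades])
    if len(grades) != len(index_table):
        raise InfeasibleParametersError("grades and index_table length mismatch")
    cuts = {
        "dvr80": th.dvr80_cut,
        "tpfr": th.tpfr_cut,
        "pfr": th.pfr_cut,
        "npfr": th.npfr_cut,
    }
    rows = []
    for grade in ("grade1", "grade2", "grade3"):
        mask = (grades == grade) | (grades == "normal")
        truth = grades[mask] == grade
        for index, (column, flag) in _INDEX_COLUMNS.items():
            values = index_table.loc[mask, column].to_numpy(dtype=float)
            side = th.directions[flag]
            predicted = values > cuts[index] if side == "above" else values < cuts[index]
            perf = diagnostic_performance(predicted, truth)
            pct = perf.as_percent()
            rows.append(
                {
                    "grade": grade,
                    "index": index,
                    "threshold": cuts[index],
                    "tp": perf.matrix.tp,
                    "fn": perf.matrix.fn,
                    "fp": perf.matrix.fp,
                    "tn": perf.matrix.tn,
                    **{k: pct[k] for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")},
                }
            )
    return DiagnosticReport(entries=pd.DataFrame(rows))
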