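"""Quantitative measures for tracking and digitization quality.

* ``mptf`` — mean position tracking fluctuation of a nominally fixed
  receiver: the mean Euclidean displacement between consecutive samples,
  with a 1/n prefactor over the n-1 consecutive differences (so the value
  is (n-1)/n of the plain mean step length; see the methods note).
* ``digitization_errors`` — per-point Euclidean distance between digitized
  and true positions in a common (head) frame, and their mean.
* ``summarize`` — mean, Tukey-hinge quartiles, IQR and outlier/extreme
  fractions.  The default outlier rule flags values above 1.5 x Q3
  (extremes above 3.0 x Q3); the conventional Tukey fences
  (Q3 + 1.5 x IQR / Q3 + 3 x IQR) are available via ``fence='tukey'``.
* ``welch_t`` — Welch's unequal-variance two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .digitize import DigitizationSession
from .emt_sim import Fixture, TrackingStream

__all__ = [
    "ErrorStats",
    "mptf",
    "digitization_errors",
    "mean_digitization_error",
    "summarize",
    "welch_t",
]


@dataclass(frozen=True)
class ErrorStats:
    mean: float
    q1: float
    q2: float
    q3: float
    iqr: float
    outlier_fraction: float
    extreme_fraction: float
    n: int

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("mean", self.mean),
            ("q1", self.q1),
            ("q2", self.q2),
            ("q3", self.q3),
            ("iqr", self.iqr),
            ("outlier_fraction", self.outlier_fraction),
            ("extreme_fraction", self.extreme_fraction),
            ("n", float(self.n)),
        ]


def mptf(stream: TrackingStream | np.ndarray) -> float:
    """Mean position tracking fluctuation (mm) of a fixed receiver.

    ``(1/n) * sum_{k=1}^{n-1} |p_{k+1} - p_k|`` over the n samples.
    """
    pos = stream.positions if isinstance(stream, TrackingStream) else np.asarray(stream, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("mptf requires at least 2 samples")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(steps.sum() / n)


def digitization_errors(
    session: DigitizationSession, truth: Fixture | dict
) -> list[tuple[str, float]]:
    """Per-label Euclidean digitization error (mm) against ground truth.

    ``truth`` is a Fixture whose local frame coincides with the head frame,
    a mapping label -> position, or another DigitizationSession.  Labels
    must match one-to-one.
    """
    if isinstance(truth, Fixture):
        true_pos = {p.label: p.position for p in truth.points}
    elif isinstance(truth, DigitizationSession):
        true_pos = {p.label: p.position for p in truth.points}
    else:
        true_pos = {k: np.asarray(v, dtype=float) for k, v in truth.items()}
    est = {p.label: p.position for p in session.points}
    missing = sorted(set(est) ^ set(true_pos))
    if missing:
        raise ValueError(f"labels do not match one-to-one; unmatched: {missing}")
    return [
        (p.label, float(np.linalg.norm(est[p.label] - true_pos[p.label])))
        for p in session.points
    ]


def mean_digitization_error(
    session: DigitizationSession, truth: Fixture | dict
) -> float:
    """Arithmetic mean of the per-point digitization errors (mm)."""
    errs = digitization_errors(session, truth)
    return float(np.mean([e for _, e in errs]))


def _tukey_hinges(x: np.ndarray) -> tuple[float, float, float]:
    """Quartiles as Tukey hinges: medians of the median-inclusive halves."""
    s = np.sort(x)
    n = s.size
    q2 = float(np.median(s))
    half = (n + 1) // 2  # include the median sample in both halves when n odd
    lower, upper = s[:half], s[n - half:]
    return float(np.median(lower)), q2, float(np.median(upper))


def summarize(
    errors, fence: str = "q3_multiple"
) -> ErrorStats:
    """Mean, Tukey-hinge quartiles, IQR and outlier/extreme fractions.

    ``fence='q3_multiple'`` (default): outlier if value > 1.5*Q3, extreme if
    value > 3.0*Q3.  ``fence='tukey'``: conventional fences Q3 + 1.5*IQR and
    Q3 + 3.0*IQR.
    """
    x = np.asarray(errors, dtype=float).reshape(-1)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, q2, q3 = _tukey_hinges(x)
    iqr = q3 - q1
    if fence == "q3_multiple":
        out_thr, ext_thr = 1.5 * q3, 3.0 * q3
    elif fence == "tukey":
        out_thr, ext_thr = q3 + 1.5 * iqr, q3 + 3.0 * iqr
    else:
        raise ValueError(f"unknown fence {fence!r}")
    return ErrorStats(
        mean=float(x.mean()),
        q1=q1,
        q2=q2,
        q3=q3,
        iqr=iqr,
        outlier_fraction=float(np.mean(x > out_thr)),
        extreme_fraction=float(np.mean(x > ext_thr)),
        n=int(x.size),
    )


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-tailed t-test: returns (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
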