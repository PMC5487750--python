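"""Inter-rater agreement statistics.

Implements the two statistics used to evaluate the symmetry score against
human raters: the intraclass correlation coefficient for absolute agreement
in a two-way model — ICC(A,1) and its average-measures form ICC(A,k) in the
McGraw–Wong nomenclature — and the Pearson correlation between subjective
and objective scores.

The ICC is computed from the two-way ANOVA mean squares of a complete
subjects x raters score grid:

    MSR  between-subject mean square (rows)
    MSC  between-rater mean square (columns)
    MSE  residual mean square

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

Absolute agreement charges systematic rater offsets against agreement (a
rater who scores everyone one point higher lowers the ICC), which is the
appropriate reading when the question is whether raters produce the *same
number*.  Confidence bounds use the F-distribution method with the
Satterthwaite degrees of freedom of McGraw & Wong.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationFormatError, UndefinedStatisticError

__all__ = ["RatingMatrix", "ICCResult", "PearsonResult", "icc_absolute_agreement", "pearson_r"]


@dataclass(frozen=True)
class RatingMatrix:
    """A complete n_subjects x k_raters grid of scores.

    The design is assumed complete (no missing cells), as in panel studies
    where every rater scores every image.
    """

    scores: np.ndarray
    subject_ids: tuple[str, ...]
    rater_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2:
            raise ValueError("scores must be a 2-D subjects x raters grid")
        n, k = s.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(s)):
            raise ValueError("rating matrix must be complete (no missing or non-finite cells)")
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("label lengths must match the score grid")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def k_raters(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingMatrix":
        return cls(
            scores=df.to_numpy(dtype=float),
            subject_ids=tuple(str(i) for i in df.index),
            rater_ids=tuple(str(c) for c in df.columns),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingMatrix":
        """Read a CSV with subjects as rows and raters as columns.

        The header row gives the rater ids; a leading ``subject_id`` (or
        ``subject``) column, if present, supplies the subject labels.
        """
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:  # pandas raises several parser error types
            raise AnnotationFormatError(f"cannot parse rating matrix {path}: {exc}") from exc
        if df.shape[1] and str(df.columns[0]).lower() in ("subject", "subject_id"):
            df = df.set_index(df.columns[0])
        try:
            return cls.from_dataframe(df.astype(float))
        except (ValueError, TypeError) as exc:
            raise AnnotationFormatError(f"invalid rating matrix {path}: {exc}") from exc

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.subject_ids), columns=list(self.rater_ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().rename_axis("subject_id").to_csv(path)


@dataclass(frozen=True)
class ICCResult:
    """An intraclass correlation with its confidence interval."""

    value: float
    form: str  # "ICC(A,1)" or "ICC(A,k)"
    ci_low: float
    ci_high: float
    confidence: float
    n_subjects: int
    k_raters: int

    def __str__(self) -> str:
        pct = round(self.confidence * 100)
        return (
            f"{self.form} = {self.value:.4f} "
            f"({pct}% CI {self.ci_low:.4f} to {self.ci_high:.4f}; "
            f"n={self.n_subjects}, k={self.k_raters})"
        )


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(
    m: RatingMatrix, form: str = "average", confidence: float = 0.95
) -> ICCResult:
    """Two-way absolute-agreement ICC of a complete rating grid.

    Parameters
    ----------
    m : RatingMatrix
    form : {"average", "single"}
        ``"average"`` returns ICC(A,k), the reliability of the k-rater mean
        (the form panel studies usually report); ``"single"`` returns
        ICC(A,1), the reliability of one typical rater.
    confidence : float
        Two-sided confidence level for the F-method interval.

    Raises
    ------
    UndefinedStatisticError
        If the between-subject variance is zero — with indistinguishable
        subjects rater agreement has no scale, so the coefficient is
        undefined rather than silently 0.
    """
    if form not in ("average", "single"):
        raise ValueError(f"form must be 'average' or 'single', got {form!r}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    x = m.scores
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    if np.ptp(x.mean(axis=1)) == 0.0 and msr <= 0.0:
        raise UndefinedStatisticError(
            "ICC undefined: zero between-subject variance (all subjects rated identically)"
        )

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icck = (msr - mse) / (msr + (msc - mse) / n)

    alpha = 1.0 - confidence
    if mse == 0.0:
        # no residual variance: the F-method degenerates, the value is exact
        lb1 = ub1 = icc1
        lbk = ubk = icck
    else:
        # Satterthwaite df for the absolute-agreement interval (McGraw & Wong)
        fj = msc / mse
        num = (k - 1) * (n - 1) * (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        den = (n - 1) * k**2 * icc1**2 * fj**2 + (n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        v = num / den
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lb1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        ub1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        lbk = lb1 * k / (1 + lb1 * (k - 1))
        ubk = ub1 * k / (1 + ub1 * (k - 1))

    if form == "single":
        return ICCResult(float(icc1), "ICC(A,1)", float(lb1), float(ub1), confidence, n, k)
    return ICCResult(float(icck), "ICC(A,k)", float(lbk), float(ubk), confidence, n, k)


@dataclass(frozen=True)
class PearsonResult:
    """Product-moment correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int

    @property
    def r_squared(self) -> float:
        """Coefficient of determination of the corresponding linear regression."""
        return self.r**2

    def __str__(self) -> str:
        return f"r = {self.r:.4f} (r^2 = {self.r_squared:.4f}, p = {self.p_value:.3g}, n = {self.n})"


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation between two score sequences (e.g. subjective
    Harris means vs objective BSI), with the two-sided p-value from the t
    transform."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise UndefinedStatisticError("Pearson r undefined for a constant sequence")
    res = stats.pearsonr(xa, ya)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(xa))
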