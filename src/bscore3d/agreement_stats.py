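"""Method-agreement statistics over paired per-subject B-scores.

Given paired measurements of the same quantity by two methods (here the MR
and CT B-score branches), the standard descriptive battery is:

* Pearson's r and the simple-regression coefficient of determination R²
  (which equals r² for a single predictor);
* Lin's concordance correlation coefficient (CCC), which penalizes both
  scatter and location/scale shifts:
  ``ccc = 2 s_xy / (s_x^2 + s_y^2 + (x̄ − ȳ)^2)`` with population (1/n)
  moments — Lin's original convention, which matters at small n;
* Bland-Altman analysis of the differences ``d = x − y``: bias ``d̄``, SD
  of differences ``s_d`` (n−1 denominator), limits of agreement
  ``d̄ ± 1.96 s_d`` and the normal-theory CI of the bias
  ``d̄ ± 1.96 s_d/√n``;
* distribution summaries stratified by KL grade, with Tukey box-plot
  conventions (quartiles by linear interpolation; whiskers at the farthest
  data within 1.5 IQR of the box; fliers beyond).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateRegressionError,
    InsufficientDataError,
    UndefinedStatisticError,
)

__all__ = [
    "PairedRecord",
    "AgreementReport",
    "GradeSummary",
    "lin_ccc",
    "bland_altman",
    "BlandAltmanResult",
    "regression_concordance",
    "grade_summaries",
    "analyze_pairs",
]

_KL_GRADES = {0, 1, 2, 3, 4}


@dataclass
class PairedRecord:
    """One subject-timepoint with B-scores from both modalities.

    ``kl_grade`` is an ordinal 0-4 or None (ungraded); records from
    different timepoints of the same subject are treated as independent.
    """

    subject_id: str
    b_mr: float
    b_ct: float
    timepoint: str = "baseline"
    kl_grade: int | None = None
    acquisition_gap_days: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kl_grade is not None and self.kl_grade not in _KL_GRADES:
            raise ValueError(f"kl_grade must be 0..4 or None, got {self.kl_grade}")
        if self.acquisition_gap_days is not None and self.acquisition_gap_days < 0:
            raise ValueError("acquisition_gap_days must be >= 0")

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.b_mr) and np.isfinite(self.b_ct))


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    means: np.ndarray
    diffs: np.ndarray
    n: int


@dataclass
class AgreementReport:
    """Aggregated agreement statistics for a set of paired records."""

    n: int
    pearson_r: float
    r_squared: float
    lin_ccc: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    slope: float
    intercept: float
    n_dropped: int = 0

    def __post_init__(self):
        # attenuation property of concordance, and R^2 = r^2 for simple OLS
        assert abs(self.lin_ccc) <= abs(self.pearson_r) + 1e-9
        assert abs(self.r_squared - self.pearson_r**2) < 1e-9
        assert self.loa_lower <= self.bias <= self.loa_upper

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "lin_ccc": self.lin_ccc,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "bias_ci_lower": self.bias_ci[0],
            "bias_ci_upper": self.bias_ci[1],
            "slope": self.slope,
            "intercept": self.intercept,
            "n_dropped": self.n_dropped,
        }


@dataclass
class GradeSummary:
    """Tukey box-plot summary of one KL-grade stratum."""

    grade: int
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    fliers: np.ndarray


def _as_arrays(x, y):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _as_arrays(x, y)
    if x.size < 2:
        raise InsufficientDataError("lin_ccc needs n >= 2")
    xm, ym = x.mean(), y.mean()
    sx2 = np.mean((x - xm) ** 2)
    sy2 = np.mean((y - ym) ** 2)
    sxy = np.mean((x - xm) * (y - ym))
    denom = sx2 + sy2 + (xm - ym) ** 2
    if denom < 1e-300:
        raise UndefinedStatisticError(
            "CCC undefined: both sequences constant with equal means"
        )
    return float(2.0 * sxy / denom)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of differences ``d = x − y``."""
    x, y = _as_arrays(x, y)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"bland_altman needs n >= 2, got {n}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    ci_half = half / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - half,
        loa_upper=bias + half,
        bias_ci=(bias - ci_half, bias + ci_half),
        means=(x + y) / 2.0,
        diffs=d,
        n=n,
    )


def regression_concordance(x, y):
    """Ordinary least squares of ``y`` on ``x``.

    Returns ``(pearson_r, r_squared, slope, intercept)``; for simple linear
    regression R² equals the squared Pearson correlation.  Moments are
    accumulated with exactly rounded summation (``math.fsum``) so the
    result is bit-identical under any permutation of the records.
    """
    import math

    x, y = _as_arrays(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("constant predictor: regression undefined")
    xm = math.fsum(x) / n
    ym = math.fsum(y) / n
    sxx = math.fsum((x - xm) ** 2)
    syy = math.fsum((y - ym) ** 2)
    sxy = math.fsum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    r = 1.0 if syy == 0 else sxy / math.sqrt(sxx * syy)
    return r, r * r, slope, intercept


def grade_summaries(
    records: list[PairedRecord], score_field: str = "b_mr"
) -> list[GradeSummary]:
    """Per-KL-grade box-plot summaries; ungraded records are excluded.

    Quartiles use linear interpolation; whiskers sit at the farthest actual
    data values within 1.5 IQR of the box.
    """
    out = []
    for grade in sorted(_KL_GRADES):
        vals = np.array(
            [
                getattr(r, score_field)
                for r in records
                if r.kl_grade == grade and np.isfinite(getattr(r, score_field))
            ]
        )
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        wlo = float(in_lo.min())
        whi = float(in_hi.max())
        fliers = vals[(vals < wlo) | (vals > whi)]
        out.append(
            GradeSummary(
                grade=grade,
                n=int(vals.size),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                iqr=float(iqr),
                whisker_low=wlo,
                whisker_high=whi,
                fliers=fliers,
            )
        )
    return out


def _report_from_xy(x, y, n_dropped=0) -> AgreementReport:
    ba = bland_altman(x, y)
    r, r2, slope, intercept = regression_concordance(y, x)  # b_mr on b_ct
    return AgreementReport(
        n=x.size,
        pearson_r=r,
        r_squared=r2,
        lin_ccc=lin_ccc(x, y),
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        bias_ci=ba.bias_ci,
        slope=slope,
        intercept=intercept,
        n_dropped=n_dropped,
    )


def analyze_pairs(records: list[PairedRecord], subgroup_key=None):
    """Full agreement analysis of paired records.

    Incomplete pairs (non-finite B-scores) are dropped and counted.  With
    ``subgroup_key`` (a callable on a record, e.g.
    ``lambda r: r.acquisition_gap_days == 0``) a per-subgroup report dict
    is returned alongside the global one.
    """
    kept = [r for r in records if r.complete]
    n_dropped = len(records) - len(kept)
    if len(kept) < 3:
        raise InsufficientDataError(
            f"agreement analysis needs >= 3 complete pairs, got {len(kept)}"
        )
    x = np.array([r.b_mr for r in kept])
    y = np.array([r.b_ct for r in kept])
    report = _report_from_xy(x, y, n_dropped)
    if subgroup_key is None:
        return report
    groups: dict = {}
    for r in kept:
        groups.setdefault(subgroup_key(r), []).append(r)
    sub_reports = {}
    for key, grp in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if len(grp) < 3:
            sub_reports[key] = None
            continue
        gx = np.array([r.b_mr for r in grp])
        gy = np.array([r.b_ct for r in grp])
        sub_reports[key] = _report_from_xy(gx, gy)
    return report, sub_reports


# ---------------------------------------------------------------------------
# Plots (optional outputs; matplotlib Agg backend)
# ---------------------------------------------------------------------------

def bland_altman_plot(records: list[PairedRecord], path) -> None:
    """Bland-Altman scatter with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kept = [r for r in records if r.complete]
    ba = bland_altman([r.b_mr for r in kept], [r.b_ct for r in kept])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.6)
    for yv, style in [(ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")]:
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of MR and CT B-score")
    ax.set_ylabel("MR − CT B-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def grade_boxplot(records: list[PairedRecord], path, score_field="b_mr") -> None:
    """Box-and-whisker plot of B-scores per KL grade (Tukey conventions)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    graded = [r for r in records if r.kl_grade is not None]
    grades = sorted({r.kl_grade for r in graded})
    data = [
        [getattr(r, score_field) for r in graded if r.kl_grade == g] for g in grades
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[f"KL{g}" for g in grades], whis=1.5)
    ax.set_ylabel(f"{score_field} (B-score)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
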