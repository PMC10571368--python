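"""Method-comparison statistics for paired RSA measurements.

Compares the dynamic-threshold CBCT estimate against a reference (optical
scan + manual segmentation) over the same specimens: paired t-test,
Bland–Altman bias and limits of agreement, plus the reliability
coefficients used on the reference measurements themselves (Cronbach's
alpha for intra-rater repeats, ICC(2,1) for inter-rater agreement).

The 24 paired RSA values of the published isolated-tooth comparison ship
with the package (:func:`load_published_pairs`) so the whole analysis is
reproducible offline. Note the published report of that comparison contains
internally inconsistent headline numbers (a t statistic that does not follow
from its own data table); this module always reports values recomputed from
the pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

#: Conventional normal-quantile multiplier for 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired surface areas (mm^2) from two methods over the same specimens."""

    ids: np.ndarray
    method_a_mm2: np.ndarray  # experimental: dynamic-threshold CBCT
    method_b_mm2: np.ndarray  # control: optical-scan reference

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a_mm2, dtype=float)
        b = np.asarray(self.method_b_mm2, dtype=float)
        ids = np.asarray(self.ids)
        if not (len(a) == len(b) == len(ids)):
            raise InputError("ids and both measurement vectors must have equal length")
        if len(a) < 2:
            raise InputError("need at least 2 pairs")
        if (a <= 0).any() or (b <= 0).any():
            raise InputError("surface areas must be positive")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "method_a_mm2", a)
        object.__setattr__(self, "method_b_mm2", b)

    @property
    def n(self) -> int:
        return len(self.method_a_mm2)

    @property
    def differences(self) -> np.ndarray:
        return self.method_a_mm2 - self.method_b_mm2


@dataclass(frozen=True)
class AgreementReport:
    """Paired-difference statistics and Bland–Altman limits of agreement."""

    n: int
    mean_diff_mm2: float
    sd_diff_mm2: float
    t_statistic: float
    p_value: float
    ci95_low: float
    ci95_high: float
    loa_low: float
    loa_high: float
    degenerate: bool = False  # zero-variance differences: t/p undefined

    def summary(self) -> str:
        lines = [
            "Paired method comparison (method A - method B)",
            f"  n pairs            {self.n}",
            f"  mean difference    {self.mean_diff_mm2:.4f} mm^2",
            f"  SD of differences  {self.sd_diff_mm2:.4f} mm^2",
        ]
        if self.degenerate:
            lines.append("  t / p              undefined (zero-variance differences)")
        else:
            lines += [
                f"  t (df={self.n - 1})          {self.t_statistic:.4f}",
                f"  two-sided p        {self.p_value:.4f}",
            ]
        lines += [
            f"  95% CI of mean     ({self.ci95_low:.4f}, {self.ci95_high:.4f})",
            f"  limits of agreement ({self.loa_low:.4f}, {self.loa_high:.4f})",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def load_pairs_csv(path: str | Path) -> PairedMeasurements:
    """Read paired measurements from a CSV with columns
    ``tooth_id, experimental_mm2, control_mm2`` (extra columns ignored)."""
    df = pd.read_csv(path)
    required = {"tooth_id", "experimental_mm2", "control_mm2"}
    if not required.issubset(df.columns):
        raise InputError(f"paired CSV must have columns {sorted(required)}; got {list(df.columns)}")
    return PairedMeasurements(
        ids=df["tooth_id"].to_numpy(),
        method_a_mm2=df["experimental_mm2"].to_numpy(),
        method_b_mm2=df["control_mm2"].to_numpy(),
    )


def published_pairs_path() -> Path:
    """Path of the packaged 24-tooth paired-RSA table."""
    return Path(resources.files("rsaseg").joinpath("data/isolated_teeth_rsa.csv"))


def load_published_pairs() -> PairedMeasurements:
    """The packaged 24-tooth CBCT-vs-optical-scan RSA table."""
    return load_pairs_csv(published_pairs_path())


def paired_comparison(data: PairedMeasurements) -> AgreementReport:
    """Paired t-test plus Bland–Altman limits on the per-pair differences.

    Differences are method A minus method B. The mean's 95% CI uses the t
    distribution with n-1 df; the limits of agreement use the fixed 1.96
    multiplier on the sample SD (n-1 denominator).
    """
    d = data.differences
    n = data.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        t_stat, p = float("nan"), float("nan")
        half_width = 0.0
    else:
        t_stat, p = stats.ttest_rel(data.method_a_mm2, data.method_b_mm2)
        t_stat, p = float(t_stat), float(p)
        half_width = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return AgreementReport(
        n=n,
        mean_diff_mm2=mean,
        sd_diff_mm2=sd,
        t_statistic=t_stat,
        p_value=p,
        ci95_low=mean - half_width,
        ci95_high=mean + half_width,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        degenerate=degenerate,
    )


def bland_altman(data: PairedMeasurements) -> tuple[AgreementReport, pd.DataFrame]:
    """Agreement report plus the Bland–Altman scatter (per-pair mean vs. diff).

    The returned frame has columns ``id, pair_mean_mm2, difference_mm2`` and
    a ``trend_slope`` attribute (least-squares slope of difference on mean;
    its sign flags a proportional error trend).
    """
    report = paired_comparison(data)
    x = (data.method_a_mm2 + data.method_b_mm2) / 2.0
    y = data.differences
    frame = pd.DataFrame({"id": data.ids, "pair_mean_mm2": x, "difference_mm2": y})
    slope = float(np.polyfit(x, y, 1)[0]) if len(x) >= 2 and np.ptp(x) > 0 else 0.0
    frame.attrs["trend_slope"] = slope
    return report, frame


def _as_matrix(values: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InputError(f"{what} needs a 2-D matrix with >=2 subjects and >=2 columns")
    if np.isnan(m).any():
        raise InputError(f"{what} does not allow missing cells")
    return m


def cronbach_alpha(matrix: np.ndarray) -> float:
    """Cronbach's alpha over a (subjects x items) matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with n-1 sample variances. Returns NaN when the total score has zero
    variance (alpha undefined).
    """
    m = _as_matrix(matrix, "cronbach_alpha")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def icc_absolute_agreement(matrix: np.ndarray, model: str = "absolute") -> float:
    """Single-measure intraclass correlation over a (subjects x raters) matrix.

    ``model="absolute"`` is ICC(2,1): two-way random effects, absolute
    agreement, from the two-way ANOVA mean squares

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    which charges systematic rater offsets against agreement.
    ``model="consistency"`` drops the rater-variance term:
    (MSR - MSE) / (MSR + (k-1) MSE). Returns NaN on degenerate
    (zero-variance) data.
    """
    m = _as_matrix(matrix, "icc")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "absolute":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif model == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise InputError(f"unknown ICC model {model!r}; use 'absolute' or 'consistency'")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)
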