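"""Pairwise segmentation comparison and cohort agreement statistics.

Two segmentations of the same mass (e.g. from the proposed and from a
manually drawn initial contour) are compared with:

* Jaccard similarity coefficient JSC = |X ∩ Y| / |X ∪ Y|;
* absolute percentage differences of scalar descriptors,
  %Δ = |b − a| / mean(a, b) × 100;
* Euclidean distance between Fourier-descriptor vectors.

Cohort agreement across many masses uses Bland-Altman bias and 95% limits
of agreement plus Pearson correlation / least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegeneratePartitionError, ParameterError
from .shapedesc import ShapeDescriptors

__all__ = [
    "PairComparison",
    "BlandAltman",
    "AgreementReport",
    "jaccard",
    "pct_diff",
    "df_distance",
    "bland_altman",
    "pearson_regression",
    "compare_pair",
    "agreement_report",
]


@dataclass
class PairComparison:
    jsc: float
    df: float
    pd_f1: float
    pd_f2: float
    pd_f3: float
    pd_sc: float
    pd_sr: float


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    outside_count: int


@dataclass
class AgreementReport:
    """Per-descriptor Bland-Altman + regression summary for one cohort."""

    descriptor: str
    bias: float
    loa_low: float
    loa_high: float
    r: float
    slope: float
    p: float


def jaccard(mask_x, mask_y) -> float:
    """Intersection-over-union of two binary masks of the same shape."""
    x = np.asarray(mask_x).astype(bool)
    y = np.asarray(mask_y).astype(bool)
    if x.shape != y.shape:
        raise ParameterError("masks must have the same shape")
    union = np.count_nonzero(x | y)
    if union == 0:
        raise DegeneratePartitionError("both masks are empty")
    return np.count_nonzero(x & y) / union


def pct_diff(a: float, b: float, signed: bool = False) -> float:
    """Percentage difference (b − a) / mean(a, b) × 100.

    The magnitude is returned by default; pass ``signed=True`` for the
    signed value.
    """
    avg = 0.5 * (a + b)
    if avg == 0:
        raise DegeneratePartitionError("percentage difference undefined: mean is 0")
    d = (b - a) / avg * 100.0
    return d if signed else abs(d)


def df_distance(fd_x, fd_y) -> float:
    """Euclidean distance between two Fourier-descriptor vectors."""
    x = np.asarray(fd_x, dtype=float)
    y = np.asarray(fd_y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("descriptor vectors must have equal length")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def bland_altman(xs, ys) -> BlandAltman:
    """Bland-Altman agreement of two paired measurement lists.

    Differences d = y − x give bias = mean(d) and 95% limits of agreement
    bias ± 1.96 · sd(d) (sample sd, n − 1); ``outside_count`` is the number
    of pairs beyond the limits.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("need two equal-length 1-D lists of length >= 3")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.count_nonzero((d < lo) | (d > hi)))
    return BlandAltman(bias=bias, loa_low=lo, loa_high=hi, sd=sd, outside_count=outside)


def pearson_regression(xs, ys) -> tuple[float, float, float]:
    """Pearson r, least-squares slope of y on x, and two-sided p for r.

    The p-value is the t-test on r with n − 2 degrees of freedom.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("need two equal-length 1-D lists of length >= 3")
    if np.ptp(x) == 0:
        raise ParameterError("zero variance in xs")
    res = sps.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.pvalue)


def compare_pair(mask_x, mask_y, desc_x: ShapeDescriptors, desc_y: ShapeDescriptors,
                 signed: bool = False) -> PairComparison:
    """Bundle all pairwise metrics for two segmentations of one mass."""
    return PairComparison(
        jsc=jaccard(mask_x, mask_y),
        df=df_distance(desc_x.fd, desc_y.fd),
        pd_f1=pct_diff(desc_x.f1, desc_y.f1, signed),
        pd_f2=pct_diff(desc_x.f2, desc_y.f2, signed),
        pd_f3=pct_diff(desc_x.f3, desc_y.f3, signed),
        pd_sc=pct_diff(desc_x.sc, desc_y.sc, signed),
        pd_sr=pct_diff(desc_x.sr, desc_y.sr, signed),
    )


def agreement_report(values_x: dict, values_y: dict) -> list[AgreementReport]:
    """Cohort agreement per descriptor.

    ``values_x`` / ``values_y`` map descriptor names to equal-length lists
    of per-mass values from the two methods.
    """
    out = []
    for name in values_x:
        ba = bland_altman(values_x[name], values_y[name])
        r, slope, p = pearson_regression(values_x[name], values_y[name])
        out.append(AgreementReport(
            descriptor=name, bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
            r=r, slope=slope, p=p,
        ))
    return out


def bland_altman_plot(xs, ys, path, title: str = ""):
    """Save a Bland-Altman scatter (mean vs difference) to ``path``.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    ba = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(0.5 * (x + y), y - x, s=18)
    for v, ls in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(v, color="k", ls=ls, lw=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (y - x)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
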