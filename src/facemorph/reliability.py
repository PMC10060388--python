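"""Intra-annotator landmark reliability via intraclass correlation.

Repeated digitization of the same specimens by one annotator gives, for each
landmark and axis, an n-specimen x 2-session measurement table.  Reliability
is summarized by the two-way random-effects, single-measure,
absolute-agreement intraclass correlation ICC(A,1) (McGraw & Wong):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the row (specimen), column (session), and residual mean
squares of the two-way ANOVA.  Absolute agreement is the defensible choice
for coordinate reproducibility — a systematic session offset should count
as disagreement.  The consistency form ICC(C,1) is available via ``form``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from facemorph.tps_io import LandmarkConfiguration


@dataclass
class ReliabilityReport:
    """Per-landmark-per-axis ICC values with the summary used in reporting."""

    icc: np.ndarray  # (k, 2): columns are x and y
    mean_x: float
    mean_y: float
    range_x: tuple[float, float]
    range_y: tuple[float, float]
    n_specimens: int
    icc_form: str

    def to_frame(self) -> pd.DataFrame:
        k = self.icc.shape[0]
        return pd.DataFrame(
            {
                "landmark": np.repeat(np.arange(k), 2),
                "axis": np.tile(["x", "y"], k),
                "icc": self.icc.reshape(-1),
            }
        )

    def summary(self) -> str:
        return (
            f"{self.icc_form} over {self.n_specimens} specimens: "
            f"x mean {self.mean_x:.3f} ({self.range_x[0]:.3f}-{self.range_x[1]:.3f}), "
            f"y mean {self.mean_y:.3f} ({self.range_y[0]:.3f}-{self.range_y[1]:.3f})"
        )


def icc_two_way(y: np.ndarray, form: str = "A-1") -> float:
    """Two-way single-measure ICC of an (n_subjects, k_raters) table.

    ``form``: "A-1" (absolute agreement, default) or "C-1" (consistency).
    Returns NaN when the denominator is degenerate (no between-subject
    variance).
    """
    y = np.asarray(y, float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    if form == "A-1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "C-1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_report(
    session_a: list[LandmarkConfiguration],
    session_b: list[LandmarkConfiguration],
    form: str = "A-1",
) -> ReliabilityReport:
    """Per-landmark-per-axis ICC across two digitization sessions.

    Sessions are matched by ``specimen_id``; at least 3 shared specimens are
    required.  Landmarks with zero between-specimen variance get an undefined
    (NaN) ICC and a warning.
    """
    a_by_id = {c.specimen_id: c for c in session_a}
    b_by_id = {c.specimen_id: c for c in session_b}
    only_a = sorted(set(a_by_id) - set(b_by_id))
    only_b = sorted(set(b_by_id) - set(a_by_id))
    if only_a or only_b:
        raise ValueError(
            f"specimen sets differ between sessions: only in A {only_a}, only in B {only_b}"
        )
    ids = sorted(a_by_id)
    if len(ids) < 3:
        raise ValueError("ICC requires at least 3 matched specimens")
    ks = {a_by_id[i].k for i in ids} | {b_by_id[i].k for i in ids}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts across sessions: {sorted(ks)}")
    k = ks.pop()
    a = np.stack([a_by_id[i].points for i in ids])  # (n, k, 2)
    b = np.stack([b_by_id[i].points for i in ids])

    icc = np.empty((k, 2))
    for lm in range(k):
        for ax in range(2):
            icc[lm, ax] = icc_two_way(
                np.column_stack([a[:, lm, ax], b[:, lm, ax]]), form=form
            )
    if np.any(np.isnan(icc)):
        warnings.warn(
            "ICC undefined (no between-specimen variance) for "
            f"{int(np.isnan(icc).sum())} landmark-axis cells",
            stacklevel=2,
        )
    form_name = {"A-1": "ICC(A,1)", "C-1": "ICC(C,1)"}[form]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ReliabilityReport(
            icc=icc,
            mean_x=float(np.nanmean(icc[:, 0])),
            mean_y=float(np.nanmean(icc[:, 1])),
            range_x=(float(np.nanmin(icc[:, 0])), float(np.nanmax(icc[:, 0]))),
            range_y=(float(np.nanmin(icc[:, 1])), float(np.nanmax(icc[:, 1]))),
            n_specimens=len(ids),
            icc_form=form_name,
        )
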