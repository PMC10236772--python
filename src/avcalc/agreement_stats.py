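"""Method-agreement statistics for paired calcium scores.

Implements the validation protocol used when comparing two Agatston
measurements of the same subjects (two software tools, two observers, or
test-retest): intraclass correlation with a 95% confidence interval,
Bland-Altman limits of agreement, relative-difference discordance counts,
and distribution summaries (median / IQR, Shapiro-Wilk normality).

The default ICC form is the two-way random-effects, absolute-agreement,
single-measure coefficient (ICC(2,1) / "ICC2"): for method comparison a
systematic offset between methods must count against agreement. Other
forms (one-way, consistency, average-measures) are selectable so any
published variant can be reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_ICC_FORMS = {"icc1", "icc2", "icc3", "icc1k", "icc2k", "icc3k"}
# pingouin labels the six forms either "ICC1".."ICC3k" or "ICC(1,1)".."ICC(C,k)"
_PINGOUIN_TYPE = {
    "icc1": ("ICC1", "ICC(1,1)"), "icc2": ("ICC2", "ICC(A,1)"), "icc3": ("ICC3", "ICC(C,1)"),
    "icc1k": ("ICC1k", "ICC(1,k)"), "icc2k": ("ICC2k", "ICC(A,k)"), "icc3k": ("ICC3k", "ICC(C,k)"),
}


class InsufficientDataError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class PairedScores:
    """Per-subject paired scores from two measurement methods."""

    subject_ids: tuple
    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=float)
        b = np.asarray(self.method_b, dtype=float)
        ids = tuple(self.subject_ids)
        if not (len(ids) == a.size == b.size):
            raise ValueError("subject_ids, method_a and method_b must have equal length")
        if a.size < 3:
            raise InsufficientDataError(f"at least 3 subjects required, got {a.size}")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("scores must be finite (no missing values)")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("calcium scores cannot be negative")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n(self) -> int:
        return self.method_a.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedScores":
        """Read a CSV with header ``subject_id,method_a,method_b``."""
        df = pd.read_csv(path)
        required = {"subject_id", "method_a", "method_b"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"paired-scores CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        if df[["method_a", "method_b"]].isna().any().any():
            raise ValueError("paired-scores CSV contains missing values")
        return cls(
            subject_ids=tuple(df["subject_id"]),
            method_a=df["method_a"].to_numpy(float),
            method_b=df["method_b"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"subject_id": self.subject_ids, "method_a": self.method_a, "method_b": self.method_b}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    form: str
    p_value: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]          # mean_diff +/- 1.96 sd
    mean_diff_ci: tuple[float, float]  # mean_diff +/- 1.96 sd / sqrt(n)
    pairs: pd.DataFrame               # columns: mean, difference (a - b)


def icc_agreement(paired: PairedScores, form: str = "icc2") -> ICCResult:
    """Intraclass correlation with its 95% CI for the two paired methods.

    The default ``icc2`` is the two-way random-effects, absolute-agreement,
    single-measure ICC, computed from the mean squares of the subjects x
    methods layout with the standard F-based confidence interval.
    """
    if form not in _ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; choose from {sorted(_ICC_FORMS)}")
    values = np.concatenate([paired.method_a, paired.method_b])
    if np.ptp(values) == 0:
        raise UndefinedStatisticError(
            "all scores identical across subjects and methods; ICC undefined"
        )
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": list(paired.subject_ids) * 2,
            "rater": ["a"] * paired.n + ["b"] * paired.n,
            "score": values,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
    labels = [lab for lab in _PINGOUIN_TYPE[form] if lab in table.index]
    if not labels:
        raise RuntimeError(f"ICC form {form!r} not found in pingouin output")
    row = table.loc[labels[0]]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = (float(x) for x in row[ci_col])
    est = float(row["ICC"])
    if not np.isfinite(est):
        raise UndefinedStatisticError("ICC is undefined for these data")
    # guard against round-off just above 1 and a CI not bracketing the point;
    # with zero residual variance the F-based CI degenerates to the estimate
    est = min(est, 1.0)
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        ci_low = ci_high = est
    ci_low = min(ci_low, est)
    ci_high = min(max(ci_high, est), 1.0)
    return ICCResult(
        estimate=est,
        ci_low=ci_low,
        ci_high=ci_high,
        form=form,
        p_value=float(row["pval"]),
    )


def bland_altman(paired: PairedScores) -> BlandAltmanResult:
    """Bland-Altman agreement of the paired differences d = a - b.

    Limits of agreement are ``mean(d) +/- 1.96 * SD(d)`` (sample SD); the
    CI of the mean difference is ``mean(d) +/- 1.96 * SD(d)/sqrt(n)``. The
    per-subject (mean, difference) pairs are returned for plotting.
    """
    d = paired.method_a - paired.method_b
    n = paired.n
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa = (mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff)
    half = 1.96 * sd_diff / np.sqrt(n)
    pairs = pd.DataFrame(
        {"mean": (paired.method_a + paired.method_b) / 2.0, "difference": d}
    )
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa=loa,
        mean_diff_ci=(mean_diff - half, mean_diff + half),
        pairs=pairs,
    )


def discordance_counts(
    paired: PairedScores,
    thresholds_pct: Sequence[float] = (5.0, 10.0),
    denominator: str = "pair_mean",
) -> dict[float, int]:
    """Count subjects whose relative score difference strictly exceeds each
    threshold (percent).

    The relative difference is ``|a - b| / ((a + b)/2) * 100`` by default;
    with ``denominator="method_a"`` method A is the reference.
    """
    a, b = paired.method_a, paired.method_b
    if denominator == "pair_mean":
        denom = (a + b) / 2.0
    elif denominator == "method_a":
        denom = a.astype(float)
    else:
        raise ValueError("denominator must be 'pair_mean' or 'method_a'")
    if np.any(denom == 0):
        raise UndefinedStatisticError(
            "relative difference undefined: zero denominator for at least one subject"
        )
    rel = np.abs(a - b) / denom * 100.0
    return {float(t): int(np.sum(rel > t)) for t in thresholds_pct}


def summarize(paired: PairedScores) -> dict:
    """Median, 25th-75th percentile and Shapiro-Wilk normality per method.

    Percentiles use linear interpolation (type-7), which the reported
    median/IQR values depend on. For constant input the normality test is
    degenerate and flagged rather than computed.
    """
    out = {}
    for name, vals in (("method_a", paired.method_a), ("method_b", paired.method_b)):
        entry = {
            "median": float(np.percentile(vals, 50)),
            "p25": float(np.percentile(vals, 25)),
            "p75": float(np.percentile(vals, 75)),
        }
        if np.ptp(vals) == 0:
            entry["shapiro_w"] = None
            entry["shapiro_p"] = None
            entry["degenerate"] = True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w, pval = stats.shapiro(vals)
            entry["shapiro_w"] = float(w)
            entry["shapiro_p"] = float(pval)
            entry["degenerate"] = False
        out[name] = entry
    return out


@dataclass
class AgreementReport:
    """Full agreement summary for a paired-score table."""

    icc: ICCResult
    bland_altman: BlandAltmanResult
    pct_exceeding: dict[float, int]
    summaries: dict
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icc": {
                "estimate": self.icc.estimate,
                "ci95": [self.icc.ci_low, self.icc.ci_high],
                "form": self.icc.form,
                "p_value": self.icc.p_value,
            },
            "mean_diff": self.bland_altman.mean_diff,
            "sd_diff": self.bland_altman.sd_diff,
            "mean_diff_ci95": list(self.bland_altman.mean_diff_ci),
            "limits_of_agreement": list(self.bland_altman.loa),
            "pct_exceeding": {str(k): v for k, v in self.pct_exceeding.items()},
            "summaries": self.summaries,
        }


def compare_methods(
    paired: PairedScores,
    icc_form: str = "icc2",
    thresholds_pct: Sequence[float] = (5.0, 10.0),
) -> AgreementReport:
    """Run the full agreement protocol on a paired-score table."""
    return AgreementReport(
        icc=icc_agreement(paired, form=icc_form),
        bland_altman=bland_altman(paired),
        pct_exceeding=discordance_counts(paired, thresholds_pct),
        summaries=summarize(paired),
        n=paired.n,
    )
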