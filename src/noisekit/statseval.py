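"""Statistical evaluation: method agreement, group contrasts and ROC analysis.

Implements the evaluation battery used to relate automatic noise/SNR
measurements to diagnostic image quality: Spearman correlation and
Bland-Altman limits of agreement between the automatic and manual methods,
absolute-error summaries, per-quality-group medians/IQRs with Mann-Whitney
contrasts (with a Kolmogorov-Smirnov normality screen reported alongside),
ROC curves with DeLong AUC confidence intervals and Youden-optimal cutoffs,
and the correlation of noise/SNR with the excluded fraction of the coronary
tree in partially diagnostic studies.

Rank statistics and tests are delegated to scipy.stats and the ROC curve to
scikit-learn; the DeLong covariance estimator is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .roimetrics import StudyRecord


@dataclass
class AgreementReport:
    """Method-agreement summary for one variable (automatic vs reference)."""

    variable: str
    n: int
    spearman_r: float
    spearman_p: float
    bias: float
    loa_low: float
    loa_high: float
    bias_p: float
    mean_abs_diff: float
    mean_abs_diff_ci: tuple[float, float] | None
    mean_abs_rel_err_pct: float
    mean_abs_rel_err_ci: tuple[float, float] | None


@dataclass
class RocResult:
    """ROC curve, DeLong-CI AUC and the Youden-optimal operating point."""

    auc: float
    auc_ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str                      # "higher" or "lower" score = positive
    n_positive: int = 0
    n_negative: int = 0


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 1.96-SD limits of agreement of the paired differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched lengths")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _mean_ci(values: np.ndarray) -> tuple[float, float] | None:
    # 95% CI of the mean, normal approximation; undefined at n == 1
    if values.size < 2:
        return None
    sem = values.std(ddof=1) / np.sqrt(values.size)
    m = values.mean()
    return float(m - 1.96 * sem), float(m + 1.96 * sem)


def abs_error_summary(a, b):
    """Mean absolute difference and mean absolute relative error (vs b).

    ``b`` is the reference method; pairs with a zero reference are excluded
    from the relative error (with their count noted).  Returns
    ``(mad, mad_ci, mare_pct, mare_ci, n_excluded)``; CIs are 95% normal
    approximations and ``None`` for a single pair.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched lengths")
    absd = np.abs(a - b)
    mad = float(absd.mean())
    nonzero = b != 0
    n_excluded = int((~nonzero).sum())
    rel = np.abs(a[nonzero] - b[nonzero]) / np.abs(b[nonzero]) * 100.0
    mare = float(rel.mean()) if rel.size else float("nan")
    return mad, _mean_ci(absd), mare, (_mean_ci(rel) if rel.size else None), n_excluded


def agreement_report(auto, manual, variable: str = "noise") -> AgreementReport:
    """Full agreement battery for one variable: Spearman, Bland-Altman, errors."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    r, p = spearman(auto, manual)
    bias, lo, hi = bland_altman(auto, manual)
    d = auto - manual
    # one-sample test of bias != 0
    bias_p = float(stats.ttest_1samp(d, 0.0).pvalue) if np.ptp(d) > 0 else (
        1.0 if bias == 0 else 0.0)
    mad, mad_ci, mare, mare_ci, _ = abs_error_summary(auto, manual)
    return AgreementReport(variable=variable, n=auto.size, spearman_r=r,
                           spearman_p=p, bias=bias, loa_low=lo, loa_high=hi,
                           bias_p=bias_p, mean_abs_diff=mad,
                           mean_abs_diff_ci=mad_ci, mean_abs_rel_err_pct=mare,
                           mean_abs_rel_err_ci=mare_ci)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # exact when both groups are small and tie-free, else normal approx with
    # tie correction (scipy applies the correction in asymptotic mode)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_compare(records_or_df, variable: str) -> dict:
    """Per-group median + IQR of ``variable`` and pairwise Mann-Whitney tests.

    Accepts a list of :class:`StudyRecord` or a DataFrame with columns
    ``quality_label`` and ``variable``.  A Kolmogorov-Smirnov screen against a
    normal with the group's moments is reported per group (the screen that
    motivates reporting medians and rank tests).
    """
    df = records_to_frame(records_or_df)
    df = df[df["status"] == "ok"] if "status" in df else df
    groups = {lab: sub[variable].dropna().to_numpy(dtype=float)
              for lab, sub in df.groupby("quality_label", sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(v.size == 0 for v in groups.values()):
        raise ValueError("empty group")
    summary = {}
    for lab, v in groups.items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        if v.size >= 3 and v.std(ddof=1) > 0:
            ks_p = float(stats.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue)
        else:
            ks_p = float("nan")
        summary[lab] = {"n": int(v.size), "median": float(med),
                        "iqr": (float(q1), float(q3)), "ks_normality_p": ks_p}
    pairwise = {}
    labs = sorted(groups)
    for i, la in enumerate(labs):
        for lb in labs[i + 1:]:
            u, p = _mann_whitney(groups[la], groups[lb])
            pairwise[(la, lb)] = {"U": u, "p": p}
    return {"variable": variable, "groups": summary, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong CI
# ---------------------------------------------------------------------------

def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (ties count 1/2) and its DeLong variance estimate."""
    m, n = pos.size, neg.size
    # placement values: V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(q < pos) + 0.5 * np.sum(q == pos)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc(records_or_df, score: str, positive_label: str = "non_diagnostic",
        direction: str = "higher") -> RocResult:
    """ROC for predicting ``positive_label`` from ``score``.

    ``direction="higher"`` means a larger score indicates the positive class
    (noise); ``"lower"`` the opposite (SNR).  AUC by the trapezoidal rule over
    all thresholds, 95% CI by DeLong, cutoff by the Youden index; sensitivity
    and specificity are reported at the cutoff on the original score scale.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    df = records_to_frame(records_or_df)
    df = df[df["status"] == "ok"] if "status" in df else df
    df = df.dropna(subset=[score])
    y = (df["quality_label"] == positive_label).to_numpy()
    s = df[score].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    oriented = s if direction == "higher" else -s

    fpr, tpr, thr = _sk_roc_curve(y.astype(int), oriented)
    auc, var = _delong_auc_variance(oriented[y], oriented[~y])
    half = 1.96 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    youden = tpr - fpr
    k = int(np.argmax(youden))
    cutoff_oriented = float(thr[k])
    cutoff = cutoff_oriented if direction == "higher" else -cutoff_oriented
    sens = float(tpr[k])
    spec = float(1.0 - fpr[k])
    return RocResult(auc=auc, auc_ci=ci, fpr=fpr, tpr=tpr,
                     thresholds=(thr if direction == "higher" else -thr),
                     cutoff=cutoff, sensitivity=sens, specificity=spec,
                     direction=direction, n_positive=int(y.sum()),
                     n_negative=int((~y).sum()))


def snr_from_thresholds(attenuation_threshold: float, noise_threshold: float) -> float:
    """SNR implied by an attenuation floor and a noise ceiling, one decimal.

    E.g. an attenuation of > 400 HU with noise < 30 HU corresponds to an SNR
    of 400/30 = 13.3.
    """
    if attenuation_threshold <= 0 or noise_threshold <= 0:
        raise ValueError("thresholds must be positive")
    return round(attenuation_threshold / noise_threshold, 1)


def excluded_fraction_correlation(records_or_df) -> dict:
    """Spearman correlations of noise and SNR with excluded vessel length/fraction.

    Restricted to ``excluded_parts`` studies with both lengths present; the
    number of skipped records is reported.  Returns per-variable ``(r, p)``
    plus the scatter data (for plotting) and a low-n flag below n = 10.
    """
    df = records_to_frame(records_or_df)
    df = df[df["status"] == "ok"] if "status" in df else df
    df = df[df["quality_label"] == "excluded_parts"]
    usable = df.dropna(subset=["excluded_length", "total_length", "noise", "snr"])
    n_skipped = len(df) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable excluded_parts records")
    frac = (usable["excluded_length"] / usable["total_length"]).to_numpy()
    out = {"n": len(usable), "n_skipped": n_skipped, "low_n": len(usable) < 10,
           "scatter": usable[["study_id", "noise", "snr",
                              "excluded_length", "total_length"]].assign(
                                  excluded_fraction=frac)}
    for var in ("noise", "snr"):
        v = usable[var].to_numpy(dtype=float)
        out[f"r_{var}_vs_excluded_length"] = spearman(
            v, usable["excluded_length"].to_numpy())
        out[f"r_{var}_vs_excluded_fraction"] = spearman(v, frac)
    return out


# ---------------------------------------------------------------------------
# Record plumbing
# ---------------------------------------------------------------------------

def records_to_frame(records_or_df) -> pd.DataFrame:
    """Normalise a list of StudyRecord (or a DataFrame) into a DataFrame."""
    if isinstance(records_or_df, pd.DataFrame):
        return records_or_df
    rows = []
    for r in records_or_df:
        if not isinstance(r, StudyRecord):
            raise TypeError(f"expected StudyRecord, got {type(r)}")
        rows.append({
            "study_id": r.study_id, "status": r.status,
            "attenuation": r.attenuation, "noise": r.noise, "snr": r.snr,
            "n_voxels": r.n_voxels, "center_slice": r.center_slice,
            "quality_label": r.quality_label,
            "excluded_length": r.excluded_length,
            "total_length": r.total_length,
        })
    return pd.DataFrame(rows)
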