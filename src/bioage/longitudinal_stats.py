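"""Within- vs between-person consistency of biological-age predictions.

Given long-format predictions (one row per sample and clock) this module
estimates per-clock variance components by one-way random-effects ANOVA,
derives the intraclass correlation (ICC) and the intra/inter variability
ratio (Var_ratio = 1/ICC - 1), computes a per-subject stability index from
pairwise between-visit differences, and tabulates Pearson correlations of
predicted against chronological age.  Technical replicates (replicate_id
> 0) are excluded throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "VariabilityReport",
    "variance_components",
    "icc",
    "var_ratio",
    "icc_from_components",
    "var_ratio_from_components",
    "stability_index",
    "pearson_vs_ca",
]


def _biological(preds: pd.DataFrame, clock: str | None = None) -> pd.DataFrame:
    out = preds[preds["replicate_id"] == 0]
    if clock is not None:
        out = out[out["clock"] == clock]
    return out


def variance_components(preds: pd.DataFrame, clock: str) -> tuple[float, float]:
    """One-way random-effects ANOVA variance components for one clock.

    With subjects i = 1..N contributing m_i visits (M = sum m_i):

        MSW = sum_ij (y_ij - ybar_i)^2 / (M - N)
        MSB = sum_i m_i (ybar_i - ybar)^2 / (N - 1)
        n0  = (M - sum_i m_i^2 / M) / (N - 1)

    and sigma^2_w = MSW, sigma^2_b = max(0, (MSB - MSW) / n0) — the
    unbalanced-group-size moment estimator.  Subjects with fewer than two
    visits are dropped.
    """
    df = _biological(preds, clock)
    counts = df.groupby("subject_id")["ba_pred"].count()
    keep = counts[counts >= 2].index
    df = df[df["subject_id"].isin(keep)]
    n_subj = df["subject_id"].nunique()
    if n_subj < 2:
        raise InsufficientDataError(
            f"clock {clock!r}: need >= 2 subjects with >= 2 visits (have {n_subj})"
        )
    y = df["ba_pred"].to_numpy(dtype=float)
    groups = df.groupby("subject_id")["ba_pred"]
    m = groups.count().to_numpy(dtype=float)
    means = groups.mean()
    big_m, big_n = float(m.sum()), float(len(m))
    grand = y.mean()
    ssw = float(((df["ba_pred"] - df["subject_id"].map(means)) ** 2).sum())
    msw = ssw / (big_m - big_n)
    msb = float((m * (means.to_numpy() - grand) ** 2).sum()) / (big_n - 1)
    n0 = (big_m - float((m**2).sum()) / big_m) / (big_n - 1)
    sigma_b2 = max(0.0, (msb - msw) / n0)
    return sigma_b2, msw


def icc_from_components(sigma_b2: float, sigma_w2: float) -> float:
    if sigma_b2 == 0 and sigma_w2 == 0:
        raise DegenerateDataError("both variance components are zero: ICC undefined")
    return sigma_b2 / (sigma_b2 + sigma_w2)


def var_ratio_from_components(sigma_b2: float, sigma_w2: float) -> float:
    if sigma_b2 == 0:
        warnings.warn("between-subject variance is zero: Var_ratio is infinite")
        return float("inf")
    return sigma_w2 / sigma_b2


def icc(preds: pd.DataFrame, clock: str) -> float:
    """Intraclass correlation sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
    return icc_from_components(*variance_components(preds, clock))


def var_ratio(preds: pd.DataFrame, clock: str) -> float:
    """Ratio of within- to between-person variance (ICC = 1 / (1 + ratio))."""
    return var_ratio_from_components(*variance_components(preds, clock))


@dataclass
class VariabilityReport:
    """Per-clock consistency summary.

    ``per_clock`` columns: icc, var_ratio, n_subjects, n_visits_mean.
    ``per_subject`` columns: clock, subject_id, raw stability (1/years),
    normalised stability in [0, 1].  ``per_category`` maps category to the
    mean normalised stability of its clocks.
    """

    per_clock: pd.DataFrame
    per_subject: pd.DataFrame
    per_category: dict[str, float]


def stability_index(
    preds: pd.DataFrame, categories: dict[str, str] | None = None
) -> VariabilityReport:
    """Stability of predictions across visits, per subject and clock.

    For subject i the raw index is the reciprocal of the mean absolute
    pairwise difference of their predictions across visits,
    ``S_i = 1 / mean_{j<k} |y_ij - y_ik|`` — higher means flatter
    trajectories.  Raw values are min-max normalised to [0, 1] jointly
    across every (clock, subject) pair in the run; a subject with identical
    predictions (infinite raw index) maps to 1 with a warning.  Category
    means average the normalised values over subjects, then over the clocks
    in the category.
    """
    df = _biological(preds)
    if categories is None:
        categories = df.drop_duplicates("clock").set_index("clock")["category"].to_dict()
    rows = []
    for (clock, subj), grp in df.groupby(["clock", "subject_id"]):
        vals = grp.sort_values("visit")["ba_pred"].to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        d = [abs(a - b) for a, b in itertools.combinations(vals, 2)]
        mean_d = float(np.mean(d))
        raw = float("inf") if mean_d == 0 else 1.0 / mean_d
        rows.append({"clock": clock, "subject_id": subj, "stability_raw": raw})
    if not rows:
        raise InsufficientDataError("no subject has >= 2 visits for any clock")
    per_subject = pd.DataFrame(rows)
    raw = per_subject["stability_raw"].to_numpy()
    finite = raw[np.isfinite(raw)]
    if np.isinf(raw).any():
        warnings.warn("subject(s) with identical predictions: raw stability is "
                      "infinite, normalised to 1.0")
    if len(finite) == 0:
        norm = np.ones_like(raw)
    elif finite.max() == finite.min():
        norm = np.where(np.isinf(raw), 1.0, 1.0)
    else:
        span = finite.max() - finite.min()
        norm = np.clip((raw - finite.min()) / span, 0.0, 1.0)
        norm[np.isinf(raw)] = 1.0
    per_subject["stability_norm"] = norm

    per_clock_stab = per_subject.groupby("clock")["stability_norm"].mean()
    per_category: dict[str, float] = {}
    cat_series = pd.Series(categories)
    for cat, clocks in cat_series.groupby(cat_series).groups.items():
        present = [c for c in clocks if c in per_clock_stab.index]
        if present:
            per_category[str(cat)] = float(per_clock_stab[present].mean())

    clock_rows = []
    for clock in df["clock"].unique():
        try:
            sb2, sw2 = variance_components(df, clock)
            icc_val = icc_from_components(sb2, sw2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vr = var_ratio_from_components(sb2, sw2)
        except (InsufficientDataError, DegenerateDataError):
            sb2 = sw2 = icc_val = vr = float("nan")
        sub = df[df["clock"] == clock]
        clock_rows.append(
            {
                "clock": clock,
                "category": categories.get(clock, "unknown"),
                "sigma_b2": sb2,
                "sigma_w2": sw2,
                "icc": icc_val,
                "var_ratio": vr,
                "stability_norm_mean": per_clock_stab.get(clock, float("nan")),
                "n_subjects": sub["subject_id"].nunique(),
            }
        )
    return VariabilityReport(
        per_clock=pd.DataFrame(clock_rows).set_index("clock"),
        per_subject=per_subject,
        per_category=per_category,
    )


def pearson_vs_ca(preds: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Pearson correlation of predicted vs chronological age, per clock.

    Technical replicates are excluded; visits are pooled.  A clock with zero
    variance in either variable raises (``strict``) or is reported as NaN
    with a warning.
    """
    df = _biological(preds)
    rows = []
    for clock, grp in df.groupby("clock"):
        n = len(grp)
        if n < 3:
            raise InsufficientDataError(f"clock {clock!r}: need >= 3 samples, have {n}")
        ba = grp["ba_pred"].to_numpy(dtype=float)
        ca = grp["ca_years"].to_numpy(dtype=float)
        if ba.std() == 0 or ca.std() == 0:
            if strict:
                raise DegenerateDataError(f"clock {clock!r}: zero variance, correlation undefined")
            warnings.warn(f"clock {clock!r}: zero variance, correlation undefined")
            rows.append({"clock": clock, "r": float("nan"), "p_value": float("nan"), "n": n})
            continue
        r, p = stats.pearsonr(ba, ca)
        rows.append({"clock": clock, "r": float(r), "p_value": float(p), "n": n})
    return pd.DataFrame(rows).set_index("clock")
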