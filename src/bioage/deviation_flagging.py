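"""Flagging deviating biological-age predictions.

Two complementary mechanisms:

* **Cross-sectional outliers** — per clock, predictions further than 2 or 3
  robust SDs (scaled median absolute deviation) from the pooled median over
  all biological replicates are flagged; under normality the +/-2 and +/-3
  bands cover ~95.45% and ~99.73% of values.
* **Within-person change** — the largest absolute difference observed
  between technical replicates of a clock, plus the maximum chronological
  time elapsed between visits, bounds how much a prediction may move for
  purely technical + calendar reasons; visit-pair differences above that
  threshold are flagged as candidate biological change.

A cosine-similarity rule selects, among a subject's technical replicates,
the sample most consistent with their other measurements.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "scaled_mad",
    "flag_outliers",
    "replicate_threshold",
    "flag_within_person_change",
    "select_replicate_cosine",
    "elapsed_years",
    "MAD_VARIANTS",
]

#: 1 / Phi^{-1}(3/4): makes the median absolute deviation consistent for the
#: SD of a normal distribution
NORMAL_CONSISTENCY = 1.4826

MAD_VARIANTS = ("median_scaled", "median_raw", "mean")


def scaled_mad(values, variant: str = "median_scaled") -> float:
    """Robust spread estimate in the units of ``values``.

    ``median_scaled`` (default): 1.4826 x median(|x - median|), consistent
    for the SD under normality — the variant whose +/-2 and +/-3 bands match
    the 95th/99th normal percentiles.  ``median_raw`` drops the scaling;
    ``mean`` is the mean absolute deviation about the mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 values for MAD, have {x.size}")
    if variant == "median_scaled":
        return NORMAL_CONSISTENCY * float(np.median(np.abs(x - np.median(x))))
    if variant == "median_raw":
        return float(np.median(np.abs(x - np.median(x))))
    if variant == "mean":
        return float(np.mean(np.abs(x - np.mean(x))))
    raise ValueError(f"unknown MAD variant {variant!r}; choose from {MAD_VARIANTS}")


def flag_outliers(
    preds: pd.DataFrame,
    clock: str,
    levels: tuple[int, ...] = (2, 3),
    variant: str = "median_scaled",
    per_visit_center: bool = False,
    on: str = "ba_pred",
) -> pd.DataFrame:
    """MAD-band outlier flags for one clock's biological replicates.

    The centre is the pooled median across subjects and visits (or the
    per-visit median when ``per_visit_center``); a prediction is flagged at
    level L when ``|y - centre| > L * MAD``.  ``on`` selects the flagged
    quantity: the raw prediction (default) or ``"age_accel"``, which removes
    the chronological-age spread before comparing subjects.  Returns one row
    per biological prediction with ``mad_flag`` in {0} U levels (the highest
    level exceeded).  A zero MAD flags every value off the centre at all
    levels, with a degenerate-spread warning.
    """
    levels = tuple(sorted(levels))
    df = preds[(preds["replicate_id"] == 0) & (preds["clock"] == clock)].copy()
    if len(df) < 3:
        raise InsufficientDataError(f"clock {clock!r}: need >= 3 biological predictions")
    y = df[on].to_numpy(dtype=float)
    if per_visit_center:
        center = df.groupby("visit")[on].transform("median").to_numpy()
        mad = scaled_mad(y - center + np.median(y), variant)
        dev = np.abs(y - center)
    else:
        center = np.median(y)
        mad = scaled_mad(y, variant)
        dev = np.abs(y - center)
    if mad == 0:
        warnings.warn(f"clock {clock!r}: degenerate spread (MAD = 0); every "
                      "off-centre value is flagged at all levels")
        flag = np.where(dev > 0, max(levels), 0)
    else:
        flag = np.zeros(len(df), dtype=int)
        for lvl in levels:
            flag = np.where(dev > lvl * mad, lvl, flag)
    df["value"] = y
    df["flag_on"] = on
    df["center"] = center
    df["mad"] = mad
    df["mad_flag"] = flag
    return df[["sample_id", "subject_id", "visit", "clock", "ba_pred",
               "value", "flag_on", "center", "mad", "mad_flag"]]


def elapsed_years(dates) -> float:
    """Maximum elapsed calendar time across collection dates, in years."""
    d = pd.to_datetime(pd.Series(list(dates)))
    if d.empty:
        return 0.0
    return float((d.max() - d.min()).days) / 365.25


def replicate_threshold(tech_pairs, elapsed_max: float) -> float:
    """Change threshold from technical replicates plus elapsed calendar time.

    ``T_c = max |a - b| over replicate pairs + elapsed_max`` — predictions of
    the same person further apart than technical noise plus the age they
    actually gained are candidate biological change.
    """
    pairs = list(tech_pairs)
    if not pairs:
        raise InsufficientDataError("no technical replicate pairs")
    if elapsed_max < 0:
        raise ValueError("elapsed_max must be >= 0")
    max_diff = max(abs(a - b) for a, b in pairs)
    return float(max_diff + elapsed_max)


def flag_within_person_change(
    preds: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Flag visit pairs whose prediction change exceeds the clock threshold.

    Returns one row per (subject, clock, visit pair) with the observed
    absolute change, the threshold and the flag; clocks without a threshold
    are skipped with a warning.
    """
    df = preds[preds["replicate_id"] == 0]
    rows = []
    for clock, grp in df.groupby("clock"):
        if clock not in thresholds:
            warnings.warn(f"no change threshold for clock {clock!r}; skipped")
            continue
        t_c = thresholds[clock]
        for subj, sub in grp.groupby("subject_id"):
            sub = sub.sort_values("visit")
            for (v1, y1), (v2, y2) in itertools.combinations(
                zip(sub["visit"], sub["ba_pred"]), 2
            ):
                delta = abs(y2 - y1)
                rows.append(
                    {
                        "clock": clock,
                        "subject_id": subj,
                        "visit_a": v1,
                        "visit_b": v2,
                        "abs_change": float(delta),
                        "threshold": float(t_c),
                        "change_flag": bool(delta > t_c),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["clock", "subject_id", "visit_a", "visit_b",
                 "abs_change", "threshold", "change_flag"],
    )


def select_replicate_cosine(
    features: pd.DataFrame, candidates: list[str]
) -> str:
    """Pick the replicate most consistent with a subject's other samples.

    ``features`` holds one subject's sample vectors (sample_id index);
    ``candidates`` are the replicate sample_ids to choose between.  Each
    candidate is scored by its mean cosine similarity to the subject's
    non-candidate samples; the highest-scoring candidate wins, ties going to
    the earliest candidate in the list (callers order by replicate_id).
    """
    if not candidates:
        raise ValueError("no candidate replicates")
    others = features.drop(index=candidates, errors="ignore")
    if others.empty:
        raise InsufficientDataError("subject has no non-candidate samples to compare against")
    o = others.to_numpy(dtype=float)
    o_norm = np.linalg.norm(o, axis=1)
    keep = o_norm > 0
    if not keep.any():
        raise DegenerateDataError("all comparison samples are zero vectors")
    o, o_norm = o[keep], o_norm[keep]
    best_id, best_score = None, -np.inf
    for cid in candidates:
        v = features.loc[cid].to_numpy(dtype=float)
        nv = np.linalg.norm(v)
        if nv == 0:
            warnings.warn(f"candidate {cid!r} is a zero vector; excluded")
            continue
        score = float(np.mean((o @ v) / (o_norm * nv)))
        if score > best_score:
            best_id, best_score = cid, score
    if best_id is None:
        raise DegenerateDataError("every candidate is a zero vector")
    return best_id
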