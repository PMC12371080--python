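"""Biological-age clocks: coefficient-table application and cohort training.

Three families are covered:

* **Coefficient-table clocks** (:class:`ClockDefinition`): a named linear
  predictor ``score = intercept + sum_j w_j x_j`` optionally followed by the
  log-linear age calibration used by epigenetic clocks, with reference-median
  imputation for unavailable inputs.
* **Cohort-trained clocks**: ordinary least-squares regression of
  chronological age on biomarkers (MLR) and a first-principal-component score
  rescaled to the age distribution (PCA), both emitted as equivalent
  :class:`ClockDefinition` objects.
* **Klemera-Doubal (KDM)**: per-biomarker regressions of the marker on age
  combined by inverse-variance weighting, with an optional chronological-age
  anchor ``s_BA``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    MissingFeatureError,
    SingularDesignError,
    UntrainableModelError,
)
from .synthetic_cohort import PREDICTION_COLUMNS

__all__ = [
    "ClockDefinition",
    "KDMModel",
    "predict_clock",
    "inverse_age_transform",
    "impute_missing",
    "fit_mlr_clock",
    "fit_pca_clock",
    "fit_kdm",
    "predict_kdm",
    "batch_center",
    "read_clock",
    "write_clock",
]

TRANSFORMS = ("identity", "log_linear_age")


@dataclass
class ClockDefinition:
    """A named linear ageing clock.

    ``coefficients`` maps feature ids to weights on the transformed-output
    scale; ``reference_medians`` supply imputation values for inputs a cohort
    did not measure.  ``transform`` is ``"identity"`` or ``"log_linear_age"``
    (the piecewise log-linear calibration with knot ``adult_age``).
    """

    name: str
    category: str
    coefficients: dict[str, float]
    intercept: float = 0.0
    transform: str = "identity"
    adult_age: float = 20.0
    uses_ca: bool = False
    reference_medians: dict[str, float] = field(default_factory=dict)
    train_r2: float | None = None

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ConfigurationError(f"clock {self.name!r}: empty coefficient table")
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"clock {self.name!r}: unknown transform {self.transform!r}")
        if self.transform == "log_linear_age" and self.adult_age <= 0:
            raise ConfigurationError("adult_age must be > 0 for log_linear_age")


@dataclass
class KDMModel:
    """Klemera-Doubal parameters: one row per retained biomarker.

    ``params`` columns: ``k`` (feature units / year), ``q`` (feature units),
    ``s`` (residual SD, feature units).  ``s_ba`` (years) anchors the
    CA-corrected estimate; small values pull predictions towards CA.
    """

    name: str
    category: str
    params: pd.DataFrame
    s_ba: float
    ca_range_train: tuple[float, float]

    def __post_init__(self) -> None:
        if (self.params["s"] <= 0).any() or (self.params["k"] == 0).any():
            raise ConfigurationError("KDM requires s_j > 0 and k_j != 0")
        if self.s_ba <= 0:
            raise ConfigurationError("s_ba must be > 0")


def inverse_age_transform(score, adult_age: float = 20.0):
    """Map a log-linear clock score back to years.

    ``age = (1 + adult_age) * exp(score) - 1`` for ``score <= 0`` and
    ``(1 + adult_age) * score + adult_age`` above; continuous at 0 and
    strictly increasing.  Accepts scalars or arrays.
    """
    if adult_age <= 0:
        raise ConfigurationError("adult_age must be > 0")
    s = np.asarray(score, dtype=float)
    out = np.where(s <= 0, (1 + adult_age) * np.exp(np.minimum(s, 0.0)) - 1,
                   (1 + adult_age) * s + adult_age)
    return out.item() if np.isscalar(score) or out.ndim == 0 else out


def impute_missing(features: pd.DataFrame, clock: ClockDefinition) -> tuple[pd.DataFrame, int]:
    """Fill the clock's absent inputs with its reference medians.

    Columns entirely missing from ``features`` and individual NaN entries
    both count as absent.  Returns the completed matrix restricted to the
    clock's features plus the number of imputed cells.
    """
    needed = list(clock.coefficients)
    missing_cols = [f for f in needed if f not in features.columns]
    uncovered = [f for f in missing_cols if f not in clock.reference_medians]
    out = features.reindex(columns=needed).copy()
    n_imputed = 0
    for f in needed:
        mask = out[f].isna()
        if not mask.any():
            continue
        if f not in clock.reference_medians:
            uncovered.append(f)
            continue
        out.loc[mask, f] = clock.reference_medians[f]
        n_imputed += int(mask.sum())
    if uncovered:
        raise MissingFeatureError(set(uncovered))
    return out, n_imputed


def predict_clock(
    clock: ClockDefinition,
    features: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Apply a coefficient-table clock to a sample x feature matrix.

    ``metadata`` (indexed or keyed by ``sample_id``) supplies subject, visit,
    chronological age and replicate labels for the long-format output; age
    acceleration is ``ba_pred - ca_years``.
    """
    x, _ = impute_missing(features, clock)
    w = pd.Series(clock.coefficients)
    score = clock.intercept + x[w.index].to_numpy() @ w.to_numpy()
    if clock.transform == "log_linear_age":
        ba = inverse_age_transform(score, clock.adult_age)
    else:
        ba = score
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[features.index]
    out = pd.DataFrame(
        {
            "sample_id": features.index,
            "subject_id": meta["subject_id"].to_numpy(),
            "visit": meta["visit"].to_numpy(),
            "clock": clock.name,
            "category": clock.category,
            "replicate_id": meta["replicate_id"].to_numpy(),
            "ba_pred": np.asarray(ba, dtype=float),
            "ca_years": meta["ca_years"].to_numpy(dtype=float),
        }
    )
    out["age_accel"] = out["ba_pred"] - out["ca_years"]
    return out[PREDICTION_COLUMNS]


def fit_mlr_clock(
    train_features: pd.DataFrame,
    train_ca: pd.Series | np.ndarray,
    name: str = "MLR",
    category: str = "clinical",
) -> ClockDefinition:
    """OLS regression of chronological age on the biomarker panel."""
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_ca, dtype=float)
    if x.shape[0] <= x.shape[1] + 1:
        raise SingularDesignError("need n_train > n_features + 1")
    if np.any(x.std(axis=0) == 0):
        raise SingularDesignError("constant feature in training design")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("rank-deficient training design")
    fit = sm.OLS(y, design).fit()
    coefs = dict(zip(train_features.columns, fit.params[1:]))
    medians = train_features.median().to_dict()
    return ClockDefinition(
        name=name, category=category, coefficients=coefs, intercept=float(fit.params[0]),
        transform="identity", uses_ca=False, reference_medians=medians,
        train_r2=float(fit.rsquared),
    )


def fit_pca_clock(
    train_features: pd.DataFrame,
    train_ca: pd.Series | np.ndarray,
    name: str = "PCA",
    category: str = "clinical",
) -> ClockDefinition:
    """First-principal-component age score.

    Features are standardised, the first PC score is oriented to correlate
    positively with chronological age, then linearly rescaled to match the
    training-age mean and SD.  The result is emitted as an equivalent linear
    clock on raw features.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_ca, dtype=float)
    if x.shape[0] <= 2:
        raise SingularDesignError("need n_train > 2")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("zero-variance feature: cannot standardise")
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    u = z @ v
    if u.std(ddof=1) == 0:
        raise DegenerateDataError("degenerate first principal component")
    if np.corrcoef(u, y)[0, 1] < 0:
        v, u = -v, -u
    scale = y.std(ddof=1) / u.std(ddof=1)
    # ba = mean(y) + scale * sum_j v_j (x_j - mu_j) / sd_j
    w = scale * v / sd
    intercept = float(y.mean() - w @ mu)
    return ClockDefinition(
        name=name, category=category,
        coefficients=dict(zip(train_features.columns, w)), intercept=intercept,
        transform="identity", uses_ca=False,
        reference_medians=train_features.median().to_dict(),
    )


def fit_kdm(
    train_features: pd.DataFrame,
    train_ca: pd.Series | np.ndarray,
    name: str = "KDM",
    category: str = "clinical",
    slope_t: float = 2.0,
    s_ba_floor: float = 0.25,
) -> KDMModel:
    """Fit Klemera-Doubal per-biomarker regressions and the CA anchor.

    Each biomarker is regressed on chronological age, ``x_j = q_j + k_j CA``;
    biomarkers whose slope fails ``|k_j| / SE > slope_t`` are dropped with a
    warning (uninformative slopes destabilise the inverse-variance weights).
    ``s_BA^2`` is estimated as the training variance of ``BA_E - CA`` minus
    the mean estimation variance of ``BA_E``, floored at ``s_ba_floor``
    (years^2).
    """
    y = np.asarray(train_ca, dtype=float)
    rows, dropped = [], []
    for f in train_features.columns:
        xj = train_features[f].to_numpy(dtype=float)
        res = stats.linregress(y, xj)
        if res.stderr == 0:
            resid_sd = float(np.std(xj - (res.intercept + res.slope * y), ddof=2))
            rows.append((f, res.slope, res.intercept, max(resid_sd, 1e-8)))
            continue
        if abs(res.slope) / res.stderr <= slope_t:
            dropped.append(f)
            continue
        resid = xj - (res.intercept + res.slope * y)
        rows.append((f, res.slope, res.intercept, max(float(np.std(resid, ddof=2)), 1e-8)))
    if dropped:
        warnings.warn(f"KDM dropped {len(dropped)} uninformative biomarker(s): {dropped}")
    if not rows:
        raise UntrainableModelError("no biomarker passed the slope filter")
    params = pd.DataFrame(rows, columns=["feature", "k", "q", "s"]).set_index("feature")

    # anchor variance from the unanchored training estimate
    ba_e = _kdm_ba_e(params, train_features)
    est_var = 1.0 / float((params["k"] ** 2 / params["s"] ** 2).sum())
    s_ba2 = max(float(np.var(ba_e - y, ddof=1)) - est_var, s_ba_floor)
    return KDMModel(
        name=name, category=category, params=params, s_ba=float(np.sqrt(s_ba2)),
        ca_range_train=(float(y.min()), float(y.max())),
    )


def _kdm_ba_e(params: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    missing = [f for f in params.index if f not in features.columns]
    if missing:
        raise MissingFeatureError(set(missing))
    x = features[params.index].to_numpy(dtype=float)
    k = params["k"].to_numpy()
    q = params["q"].to_numpy()
    s2 = params["s"].to_numpy() ** 2
    num = ((x - q) * k / s2).sum(axis=1)
    den = (k**2 / s2).sum()
    return num / den


def predict_kdm(
    model: KDMModel,
    features: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Klemera-Doubal prediction, corrected towards chronological age.

    ``BA_E`` is the inverse-variance-weighted combination of the biomarker
    estimates; the reported ``ba_pred`` is the anchored

        BA_EC = (sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2)
                / (sum_j k_j^2 / s_j^2 + 1 / s_BA^2)

    ``BA_E`` is kept in the output (column ``ba_e``) for diagnostics.
    """
    missing = [f for f in model.params.index if f not in features.columns]
    if missing:
        raise MissingFeatureError(set(missing))
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[features.index]
    ca = meta["ca_years"].to_numpy(dtype=float)
    k = model.params["k"].to_numpy()
    q = model.params["q"].to_numpy()
    s2 = model.params["s"].to_numpy() ** 2
    x = features[model.params.index].to_numpy(dtype=float)
    num = ((x - q) * k / s2).sum(axis=1)
    den = float((k**2 / s2).sum())
    ba_e = num / den
    ba_ec = (num + ca / model.s_ba**2) / (den + 1.0 / model.s_ba**2)
    out = pd.DataFrame(
        {
            "sample_id": features.index,
            "subject_id": meta["subject_id"].to_numpy(),
            "visit": meta["visit"].to_numpy(),
            "clock": model.name,
            "category": model.category,
            "replicate_id": meta["replicate_id"].to_numpy(),
            "ba_pred": ba_ec,
            "ca_years": ca,
        }
    )
    out["age_accel"] = out["ba_pred"] - out["ca_years"]
    out = out[PREDICTION_COLUMNS].copy()
    out["ba_e"] = ba_e
    return out


def batch_center(features: pd.DataFrame, batches: pd.Series | np.ndarray) -> pd.DataFrame:
    """Median-centre each feature within batch, preserving the global median.

    Per feature and batch the batch median is subtracted and the global
    median added back; rank order within a batch is unchanged.  Batches with
    fewer than two samples are left untouched with a warning.
    """
    b = pd.Series(np.asarray(batches), index=features.index)
    if b.nunique() < 2:
        return features.copy()
    out = features.copy()
    global_med = features.median()
    for label, idx in b.groupby(b).groups.items():
        if len(idx) < 2:
            warnings.warn(f"batch {label!r} has < 2 samples; left uncentered")
            continue
        batch_med = features.loc[idx].median()
        out.loc[idx] = features.loc[idx] - batch_med + global_med
    return out


# ---------------------------------------------------------------------------
# clock definition file I/O (TSV with '#key<TAB>value' header lines, or JSON)

def write_clock(clock: ClockDefinition, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "name": clock.name, "category": clock.category,
            "transform": clock.transform, "adult_age": clock.adult_age,
            "intercept": clock.intercept, "uses_ca": clock.uses_ca,
            "coefficients": clock.coefficients,
            "reference_medians": clock.reference_medians,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    lines = [
        f"#name\t{clock.name}",
        f"#category\t{clock.category}",
        f"#transform\t{clock.transform}",
        f"#adult_age\t{clock.adult_age}",
        f"#intercept\t{clock.intercept}",
        f"#uses_ca\t{int(clock.uses_ca)}",
        "feature\tweight\treference_median",
    ]
    for f, w in clock.coefficients.items():
        med = clock.reference_medians.get(f, "")
        lines.append(f"{f}\t{w!r}\t{med!r}" if med != "" else f"{f}\t{w!r}\t")
    path.write_text("\n".join(lines) + "\n")


def read_clock(path) -> ClockDefinition:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return ClockDefinition(
            name=payload["name"], category=payload["category"],
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            intercept=float(payload.get("intercept", 0.0)),
            transform=payload.get("transform", "identity"),
            adult_age=float(payload.get("adult_age", 20.0)),
            uses_ca=bool(payload.get("uses_ca", False)),
            reference_medians={k: float(v) for k, v in payload.get("reference_medians", {}).items()},
        )
    header: dict[str, str] = {}
    coefs: dict[str, float] = {}
    medians: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            header[key.strip()] = val.strip()
        elif not line.startswith("feature\t"):
            parts = line.split("\t")
            coefs[parts[0]] = float(parts[1])
            if len(parts) > 2 and parts[2].strip():
                medians[parts[0]] = float(parts[2])
    return ClockDefinition(
        name=header.get("name", path.stem), category=header.get("category", "clinical"),
        coefficients=coefs, intercept=float(header.get("intercept", 0.0)),
        transform=header.get("transform", "identity"),
        adult_age=float(header.get("adult_age", 20.0)),
        uses_ca=bool(int(header.get("uses_ca", "0"))),
        reference_medians=medians,
    )
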