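"""Synthetic longitudinal multi-modal cohorts with a known variance structure.

The generator emulates a deep-phenotyping study design: 30 middle-aged
subjects (15 male / 15 female, chronological age 45-59 at baseline) followed
for 13 monthly visits; clinical chemistry measured at every visit, proteomics
and metabolomics bimonthly, and a methylation-derived panel at visits 2, 8
and 13; at the final visit only 20 subjects remain, and the methylation-like
modality carries 16 technical replicates.

Every sample is driven by a latent biological age

    BA_i(t) = CA_i(t) + delta_i + gamma_i * (t - 1) / 12 + w_it

with a between-subject offset ``delta_i ~ N(0, sigma_b^2)``, an optional
linear drift ``gamma_i`` (years per year) and visit-to-visit fluctuation
``w_it ~ N(0, sigma_w^2)``.  Features are linear read-outs of the latent BA,
``x_j = q_j + k_j * BA + N(0, s_j^2)``, so downstream clocks can in principle
recover BA exactly.  Technical replicates share the biological sample's
latent BA and feature noise and differ only by a replicate-level perturbation
of magnitude ``sigma_tech`` on the BA scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "FeatureParams",
    "CohortConfig",
    "CohortTables",
    "DirectPredictions",
    "generate_cohort",
    "generate_predictions_direct",
    "write_cohort",
    "load_config",
]

#: canonical metadata column order
METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "sex",
    "visit",
    "collection_date",
    "ca_years",
    "modality",
    "replicate_id",
    "batch",
]

PREDICTION_COLUMNS = [
    "sample_id",
    "subject_id",
    "visit",
    "clock",
    "category",
    "replicate_id",
    "ba_pred",
    "ca_years",
    "age_accel",
]

_DEFAULT_SCHEDULES = {
    "clinical": list(range(1, 14)),
    "proteomic": [1, 3, 5, 7, 9, 11, 13],
    "metabolomic": [1, 3, 5, 7, 9, 11, 13],
    "methylation": [2, 8, 13],
}

# bimonthly visits shipped in four batches, by visit block
_BATCH_BY_VISIT = {1: 1, 3: 1, 5: 2, 7: 2, 9: 3, 11: 3, 13: 4}

_BASELINE_DATE = pd.Timestamp("2019-03-15")


@dataclass
class FeatureParams:
    """Per-modality generative feature panel.

    Each of the ``n_features`` biomarkers is a noisy linear function of the
    latent BA; the slope, intercept and residual SD of feature ``j`` are drawn
    once per cohort from the uniform ranges below (slopes get a random sign
    when ``signed_slopes``).
    """

    n_features: int = 12
    slope_range: tuple[float, float] = (0.4, 1.2)
    intercept_range: tuple[float, float] = (20.0, 60.0)
    noise_sd_range: tuple[float, float] = (2.0, 6.0)
    signed_slopes: bool = True


def _default_feature_params() -> dict[str, FeatureParams]:
    return {
        "clinical": FeatureParams(n_features=10),
        "proteomic": FeatureParams(n_features=16),
        "metabolomic": FeatureParams(n_features=16),
        "methylation": FeatureParams(n_features=12, noise_sd_range=(1.0, 3.0)),
    }


@dataclass
class CohortConfig:
    """Design and variance parameters of a synthetic cohort.

    Defaults reproduce the reference design: 30 subjects (15/15 by sex),
    baseline age uniform on 45-59 years, 13 monthly visits with dropout to 20
    subjects at visit 13, and 16 technical replicates in the
    methylation-like modality.
    """

    n_subjects: int = 30
    n_male: int = 15
    ca_range: tuple[float, float] = (45.0, 59.0)
    n_visits: int = 13
    modality_schedules: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_SCHEDULES.items()}
    )
    dropout_visit: int = 13
    n_retained: int = 20
    tech_replicate_modality: str = "methylation"
    n_tech_replicates: int = 16
    sigma_b: float = 4.0
    sigma_w: float = 1.0
    sigma_tech: float = 0.5
    drift_rate: float = 0.0
    feature_params: dict[str, FeatureParams] = field(default_factory=_default_feature_params)
    batch_shift_sd: float = 0.0
    #: optionally plant a persistent deviator: subject index gets this BA offset
    outlier_subject_idx: int | None = None
    outlier_offset: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or not (0 <= self.n_male <= self.n_subjects):
            raise ConfigurationError("need 0 <= n_male <= n_subjects, n_subjects >= 1")
        for sd_name in ("sigma_b", "sigma_w", "sigma_tech", "batch_shift_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigurationError(f"{sd_name} must be >= 0")
        if self.n_retained > self.n_subjects:
            raise ConfigurationError("n_retained must be <= n_subjects")
        if not self.modality_schedules:
            raise ConfigurationError("at least one modality schedule required")
        for mod, visits in self.modality_schedules.items():
            if not visits:
                raise ConfigurationError(f"empty schedule for modality {mod!r}")
            if not set(visits) <= set(range(1, self.n_visits + 1)):
                raise ConfigurationError(
                    f"schedule for {mod!r} outside 1..{self.n_visits}: {visits}"
                )
            if mod not in self.feature_params:
                raise ConfigurationError(f"no feature_params for modality {mod!r}")
        if self.n_tech_replicates and self.tech_replicate_modality not in self.modality_schedules:
            raise ConfigurationError(
                f"tech_replicate_modality {self.tech_replicate_modality!r} not scheduled"
            )
        if self.outlier_subject_idx is not None and not (
            0 <= self.outlier_subject_idx < self.n_subjects
        ):
            raise ConfigurationError("outlier_subject_idx out of range")


@dataclass
class CohortTables:
    """Generated cohort: metadata, per-modality feature matrices, and truth.

    ``metadata`` is one row per sample (biological and technical replicates);
    ``features[modality]`` is a sample_id-indexed feature matrix;
    ``truth`` holds per-sample latent BA with the subject-level offset and
    drift; ``feature_truth[modality]`` records the generative slope,
    intercept and noise SD of every feature.
    """

    config: CohortConfig
    metadata: pd.DataFrame
    features: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    feature_truth: dict[str, pd.DataFrame]


def generate_cohort(config: CohortConfig) -> CohortTables:
    """Simulate a full multi-modal cohort.

    Deterministic given ``config.seed``; all sample counts honour the
    modality schedules, the final-visit dropout and the technical-replicate
    allocation (two per methylation visit plus ten retrospective replicates
    of the two earlier visits).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects = [f"ID{i + 1:02d}" for i in range(config.n_subjects)]
    sex = np.array(["M"] * config.n_male + ["F"] * (config.n_subjects - config.n_male))
    ca0 = rng.uniform(*config.ca_range, size=config.n_subjects)
    delta = rng.normal(0.0, config.sigma_b, size=config.n_subjects)
    if config.outlier_subject_idx is not None:
        delta[config.outlier_subject_idx] = config.outlier_offset
    gamma = np.full(config.n_subjects, config.drift_rate)

    retained = set(rng.permutation(subjects)[: config.n_retained])

    # latent BA for every (subject, visit): within-subject fluctuation drawn once
    # per visit and shared across modalities sampled at that visit
    w = rng.normal(0.0, config.sigma_w, size=(config.n_subjects, config.n_visits))
    ca = ca0[:, None] + (np.arange(config.n_visits)[None, :]) / 12.0
    latent = ca + delta[:, None] + gamma[:, None] * (np.arange(config.n_visits)[None, :]) / 12.0 + w

    # per-modality generative feature parameters
    feature_truth: dict[str, pd.DataFrame] = {}
    for mod, fp in config.feature_params.items():
        if mod not in config.modality_schedules:
            continue
        k = rng.uniform(*fp.slope_range, size=fp.n_features)
        if fp.signed_slopes:
            k *= rng.choice([-1.0, 1.0], size=fp.n_features)
        q = rng.uniform(*fp.intercept_range, size=fp.n_features)
        s = rng.uniform(*fp.noise_sd_range, size=fp.n_features)
        feature_truth[mod] = pd.DataFrame(
            {"feature": [f"{mod[:4]}_f{j + 1:03d}" for j in range(fp.n_features)],
             "k": k, "q": q, "s": s}
        ).set_index("feature")

    batch_shift: dict[str, np.ndarray] = {}
    for mod in ("proteomic", "metabolomic"):
        if mod in feature_truth and config.batch_shift_sd > 0:
            batch_shift[mod] = rng.normal(
                0.0, config.batch_shift_sd, size=(4, len(feature_truth[mod]))
            )

    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    feat_rows: dict[str, list[np.ndarray]] = {m: [] for m in feature_truth}
    feat_index: dict[str, list[str]] = {m: [] for m in feature_truth}

    bio_x: dict[tuple[int, int, str], np.ndarray] = {}

    def emit(i: int, visit: int, mod: str, replicate_id: int, ba: float) -> None:
        sid = f"{subjects[i]}_{mod[:4]}_v{visit:02d}"
        if replicate_id:
            sid += f"_r{replicate_id}"
        batch = _BATCH_BY_VISIT.get(visit, 1) if mod in ("proteomic", "metabolomic") else 1
        meta_rows.append(
            {
                "sample_id": sid,
                "subject_id": subjects[i],
                "sex": sex[i],
                "visit": visit,
                "collection_date": (_BASELINE_DATE + pd.DateOffset(months=visit - 1)).date().isoformat(),
                "ca_years": ca[i, visit - 1],
                "modality": mod,
                "replicate_id": replicate_id,
                "batch": batch,
            }
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "subject_id": subjects[i],
                "delta": delta[i],
                "gamma": gamma[i],
                "latent_ba": ba,
            }
        )
        ft = feature_truth[mod]
        if replicate_id:
            # replicate = the biological sample's measured vector plus a shared
            # BA-scale technical perturbation mapped through the feature slopes
            base = bio_x[(i, visit, mod)]
            x = base + ft["k"].to_numpy() * (ba - latent[i, visit - 1])
        else:
            x = ft["q"].to_numpy() + ft["k"].to_numpy() * ba + rng.normal(
                0.0, ft["s"].to_numpy()
            )
            if mod in batch_shift:
                x = x + batch_shift[mod][batch - 1]
            bio_x[(i, visit, mod)] = x
        feat_rows[mod].append(x)
        feat_index[mod].append(sid)

    for mod, visits in config.modality_schedules.items():
        for visit in visits:
            for i in range(config.n_subjects):
                if visit >= config.dropout_visit and subjects[i] not in retained:
                    continue
                emit(i, visit, mod, 0, latent[i, visit - 1])

    # technical replicates: same latent BA perturbed by sigma_tech on the BA scale
    mod = config.tech_replicate_modality
    if config.n_tech_replicates and mod in config.modality_schedules:
        sched = config.modality_schedules[mod]
        plan = _replicate_plan(sched, config.n_tech_replicates)
        rep_counter: dict[tuple[str, int], int] = {}
        for visit, count in plan.items():
            pool = [
                i
                for i in range(config.n_subjects)
                if visit < config.dropout_visit or subjects[i] in retained
            ]
            picks = rng.choice(pool, size=min(count, len(pool)), replace=False)
            extra = count - len(picks)
            picks = list(picks) + list(rng.choice(pool, size=extra)) if extra else list(picks)
            for i in picks:
                key = (subjects[i], visit)
                rep_counter[key] = rep_counter.get(key, 0) + 1
                eps = rng.normal(0.0, config.sigma_tech)
                emit(i, visit, mod, rep_counter[key], latent[i, visit - 1] + eps)

    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    features = {
        m: pd.DataFrame(
            np.vstack(feat_rows[m]), index=pd.Index(feat_index[m], name="sample_id"),
            columns=feature_truth[m].index,
        )
        for m in feat_rows
        if feat_rows[m]
    }

    key = metadata[["subject_id", "visit", "modality", "replicate_id"]]
    if key.duplicated().any():  # pragma: no cover - internal consistency
        raise RuntimeError("duplicate (subject, visit, modality, replicate) generated")
    return CohortTables(config, metadata, features, truth, feature_truth)


def _replicate_plan(schedule: list[int], n_reps: int) -> dict[int, int]:
    """Allocate technical replicates across scheduled visits.

    Mirrors the reference design for the 3-visit / 16-replicate default: two
    replicates at each visit plus the remainder split over the earlier
    visits (the retrospective re-assays).  Other configurations spread
    replicates as evenly as possible.
    """
    visits = sorted(schedule)
    plan = {v: 0 for v in visits}
    base = min(2, max(1, n_reps // len(visits)))
    remaining = n_reps
    for v in visits:
        take = min(base, remaining)
        plan[v] += take
        remaining -= take
    early = visits[:-1] if len(visits) > 1 else visits
    i = 0
    while remaining > 0:
        plan[early[i % len(early)]] += 1
        remaining -= 1
        i += 1
    return plan


@dataclass
class DirectPredictions:
    """Synthetic BA predictions with known variance components."""

    predictions: pd.DataFrame
    sigma_b: float
    sigma_w: float

    @property
    def true_icc(self) -> float:
        return self.sigma_b**2 / (self.sigma_b**2 + self.sigma_w**2)


def generate_predictions_direct(
    n_subjects: int,
    visits: int,
    mu: float = 50.0,
    sigma_b: float = 4.0,
    sigma_w: float = 1.0,
    seed: int = 0,
    clock: str = "direct",
    category: str = "synthetic",
) -> DirectPredictions:
    """Draw ``y_ij = mu + b_i + w_ij`` directly, bypassing the clock engine.

    A fixture for the variability statistics: the true intraclass
    correlation ``sigma_b^2 / (sigma_b^2 + sigma_w^2)`` is recorded alongside
    the long-format prediction table.
    """
    if n_subjects < 2 or visits < 2:
        raise ConfigurationError("need n_subjects >= 2 and visits >= 2")
    if sigma_b < 0 or sigma_w < 0:
        raise ConfigurationError("SDs must be >= 0")
    if sigma_b == 0 and sigma_w == 0:
        raise DegenerateDataError("sigma_b = sigma_w = 0: ICC undefined")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, size=n_subjects)
    w = rng.normal(0.0, sigma_w, size=(n_subjects, visits))
    y = mu + b[:, None] + w
    rows = pd.DataFrame(
        {
            "sample_id": [f"ID{i + 1:02d}_v{j + 1:02d}" for i in range(n_subjects) for j in range(visits)],
            "subject_id": np.repeat([f"ID{i + 1:02d}" for i in range(n_subjects)], visits),
            "visit": np.tile(np.arange(1, visits + 1), n_subjects),
            "clock": clock,
            "category": category,
            "replicate_id": 0,
            "ba_pred": y.ravel(),
            "ca_years": mu,
        }
    )
    rows["age_accel"] = rows["ba_pred"] - rows["ca_years"]
    return DirectPredictions(rows[PREDICTION_COLUMNS], sigma_b, sigma_w)


def write_cohort(tables: CohortTables, outdir) -> None:
    """Write metadata.tsv, truth.tsv and one <modality>.features.tsv each."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    tables.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for mod, mat in tables.features.items():
        mat.to_csv(out / f"{mod}.features.tsv", sep="\t")


def load_config(path) -> CohortConfig:
    """Read a :class:`CohortConfig` from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
    if "feature_params" in raw:
        raw["feature_params"] = {
            m: FeatureParams(**fp) for m, fp in raw["feature_params"].items()
        }
    if "ca_range" in raw:
        raw["ca_range"] = tuple(raw["ca_range"])
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg
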