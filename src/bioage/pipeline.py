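"""End-to-end orchestration: simulate -> predict -> stats -> flag -> report.

The pipeline trains cohort-based clocks (MLR, PCA per modality and
Klemera-Doubal on the clinical panel), optionally adds coefficient-table
clocks from files, applies them to every sample of their modality, and runs
the variability and deviation analyses.  All randomness flows from one seed;
all outputs are tab-separated tables plus a pretty-printed, key-sorted
report.json, so reruns are byte-identical.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import clock_engine as ce
from . import deviation_flagging as dv
from . import longitudinal_stats as ls
from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError
from .synthetic_cohort import (
    CohortConfig,
    CohortTables,
    generate_cohort,
    write_cohort,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "density_summary",
    "consistent_deviator_summary",
    "train_cohort_clocks",
    "reference_clocks",
    "planted_outlier_trial",
    "load_cohort_dir",
]

log = logging.getLogger("bioage")

CATEGORY_BY_MODALITY = {
    "methylation": "epigenetic",
    "clinical": "clinical",
    "proteomic": "proteomic",
    "metabolomic": "metabolomic",
}


@dataclass
class RunConfig:
    """Options for a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: Path = Path("bioage_out")
    clock_dir: Path | None = None
    mad_levels: tuple[int, ...] = (2, 3)
    mad_variant: str = "median_scaled"
    #: flag deviations of age acceleration (BA - CA) rather than raw BA, so a
    #: subject's chronological age does not dominate the comparison
    flag_on: str = "age_accel"
    min_clocks_deviator: int = 2
    density_grid_points: int = 101
    seed: int | None = None

    def validate(self) -> None:
        if not self.mad_levels or any(l <= 0 for l in self.mad_levels):
            raise ConfigurationError("mad_levels must be positive")
        if list(self.mad_levels) != sorted(self.mad_levels):
            raise ConfigurationError("mad_levels must be sorted ascending")
        if self.mad_variant not in dv.MAD_VARIANTS:
            raise ConfigurationError(f"unknown mad_variant {self.mad_variant!r}")
        if self.flag_on not in ("ba_pred", "age_accel"):
            raise ConfigurationError(f"flag_on must be 'ba_pred' or 'age_accel'")


@dataclass
class RunReport:
    """Everything a run computed, ready for serialisation."""

    correlations: pd.DataFrame
    variability: ls.VariabilityReport
    deviations: pd.DataFrame
    change_flags: pd.DataFrame
    thresholds: dict[str, float]
    densities: dict[str, dict]
    deviators: pd.DataFrame
    replicate_selection: dict[str, str]
    warnings: list[str]


def density_summary(values, grid=None, grid_points: int = 101) -> dict:
    """Gaussian-kernel density (Silverman bandwidth) on a fixed grid.

    Returns the grid, density values and the trapezoid integral (should be 1
    up to grid truncation).  Zero-variance input is refused.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InsufficientDataError("need >= 5 values for a density summary")
    if x.std() == 0:
        raise DegenerateDataError("zero variance: point mass, density not evaluated")
    kde = sps.gaussian_kde(x, bw_method="silverman")
    if grid is None:
        pad = 3 * x.std()
        grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    grid = np.asarray(grid, dtype=float)
    dens = kde(grid)
    integral = float(np.trapezoid(dens, grid))
    return {"grid": grid.tolist(), "density": dens.tolist(), "integral": integral}


def consistent_deviator_summary(deviations: pd.DataFrame, min_clocks: int = 2) -> pd.DataFrame:
    """Subjects whose predictions deviate across several clocks at once.

    A subject qualifies when, at one or more visits, they carry a MAD flag
    (any level) in at least ``min_clocks`` distinct clocks simultaneously.
    Ranked by total flag count, descending; ties broken by subject id.
    """
    flagged = deviations[deviations["mad_flag"] > 0]
    rows = []
    for subj, grp in flagged.groupby("subject_id"):
        per_visit = grp.groupby("visit")["clock"].nunique()
        shared = per_visit[per_visit >= min_clocks]
        if shared.empty:
            continue
        rows.append(
            {
                "subject_id": subj,
                "n_flags": int(len(grp)),
                "n_clocks": int(grp["clock"].nunique()),
                "shared_visits": ",".join(str(v) for v in sorted(shared.index)),
            }
        )
    out = pd.DataFrame(rows, columns=["subject_id", "n_flags", "n_clocks", "shared_visits"])
    return out.sort_values(["n_flags", "subject_id"], ascending=[False, True]).reset_index(drop=True)


def reference_clocks(tables: CohortTables) -> list[ce.ClockDefinition]:
    """Fixed coefficient-table clocks standing in for published predictors.

    A published clock carries coefficients estimated on its original (large,
    external) training population; here that population is the generative
    feature model itself, so each modality gets the inverse-variance-optimal
    linear read-out of latent BA:

        w_j = (k_j / s_j^2) / sum_j k_j^2 / s_j^2

    These clocks are defined without reference to the cohort's realised
    samples — applying them involves no cohort-specific fitting.
    """
    clocks = []
    for mod, ft in tables.feature_truth.items():
        k = ft["k"].to_numpy()
        q = ft["q"].to_numpy()
        s2 = ft["s"].to_numpy() ** 2
        den = float((k**2 / s2).sum())
        w = (k / s2) / den
        clocks.append(
            ce.ClockDefinition(
                name=f"REF-{mod}",
                category=CATEGORY_BY_MODALITY.get(mod, mod),
                coefficients=dict(zip(ft.index, w)),
                intercept=float(-(q * k / s2).sum() / den),
                reference_medians=dict(zip(ft.index, ft["q"] + ft["k"] * 52.0)),
            )
        )
    return clocks


def train_cohort_clocks(tables: CohortTables) -> list:
    """Train MLR and PCA clocks per modality plus KDM on the clinical panel.

    Training uses biological samples only (replicate_id == 0), pooled over
    visits, with chronological age at collection as the target.
    """
    meta = tables.metadata
    clocks: list = []
    for mod, mat in tables.features.items():
        cat = CATEGORY_BY_MODALITY.get(mod, mod)
        sub = meta[(meta["modality"] == mod) & (meta["replicate_id"] == 0)]
        x = mat.loc[sub["sample_id"]]
        ca = sub.set_index("sample_id").loc[x.index, "ca_years"]
        clocks.append(ce.fit_mlr_clock(x, ca, name=f"MLR-{mod}", category=cat))
        clocks.append(ce.fit_pca_clock(x, ca, name=f"PCA-{mod}", category=cat))
        if mod == "clinical":
            clocks.append(ce.fit_kdm(x, ca, name="KDM-clinical", category=cat))
    return clocks


def _predict_all(tables: CohortTables, clocks: list) -> pd.DataFrame:
    meta = tables.metadata
    frames = []
    for clock in clocks:
        if isinstance(clock, ce.KDMModel):
            mod = "clinical"
        else:
            mod = clock.name.split("-", 1)[1] if "-" in clock.name else None
        if mod not in tables.features:
            # coefficient-table clocks from files: match by feature overlap
            mod = _modality_for_clock(clock, tables)
        mat = tables.features[mod]
        if isinstance(clock, ce.KDMModel):
            frames.append(ce.predict_kdm(clock, mat, meta).drop(columns=["ba_e"]))
        else:
            frames.append(ce.predict_clock(clock, mat, meta))
    return pd.concat(frames, ignore_index=True)


def _modality_for_clock(clock, tables: CohortTables) -> str:
    feats = set(clock.params.index) if isinstance(clock, ce.KDMModel) else set(clock.coefficients)
    best, best_overlap = None, -1
    for mod, mat in tables.features.items():
        overlap = len(feats & set(mat.columns))
        if overlap > best_overlap:
            best, best_overlap = mod, overlap
    if best is None:
        raise ConfigurationError(f"no modality matches clock {getattr(clock, 'name', clock)!r}")
    return best


def _replicate_thresholds(preds: pd.DataFrame, metadata: pd.DataFrame) -> dict[str, float]:
    """Per-clock change thresholds from technical-replicate spreads.

    For every clock with technical replicates: pairs are all combinations of
    the replicate group's predictions (original + replicates of one
    biological sample); the elapsed-time term is the maximum calendar span
    between that clock's analysis visits.
    """
    thresholds: dict[str, float] = {}
    dates = metadata.drop_duplicates("sample_id").set_index("sample_id")["collection_date"]
    for clock, grp in preds.groupby("clock"):
        if (grp["replicate_id"] > 0).sum() == 0:
            continue
        pairs = []
        for (_, _), g in grp.groupby(["subject_id", "visit"]):
            if len(g) < 2:
                continue
            vals = g["ba_pred"].to_numpy()
            pairs.extend(itertools.combinations(vals, 2))
        if not pairs:
            continue
        elapsed = dv.elapsed_years(dates.loc[grp["sample_id"].unique()])
        thresholds[clock] = dv.replicate_threshold(pairs, elapsed)
    return thresholds


def heatmap_matrix(deviations: pd.DataFrame) -> pd.DataFrame:
    """Clock x (subject, visit) grid of flag codes {0, 2, 3}.

    Mirrors a reduced ordered heatmap in which only deviating predictions
    carry a colour code.
    """
    piv = deviations.pivot_table(
        index="clock",
        columns=["subject_id", "visit"],
        values="mad_flag",
        aggfunc="max",
        fill_value=0,
    )
    piv.columns = [f"{s}_v{v:02d}" for s, v in piv.columns]
    return piv.astype(int)


def run_pipeline(config: RunConfig, tables: CohortTables | None = None) -> RunReport:
    """Run every stage and write all artefacts under ``config.outdir``."""
    config.validate()
    if config.seed is not None:
        config.cohort.seed = config.seed
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if tables is None:
            log.info("simulating cohort (seed=%s)", config.cohort.seed)
            tables = generate_cohort(config.cohort)
            write_cohort(tables, out)

        # batch centering for the batched modalities
        for mod in ("proteomic", "metabolomic"):
            if mod in tables.features:
                meta_mod = tables.metadata[tables.metadata["modality"] == mod]
                batches = meta_mod.set_index("sample_id")["batch"]
                mat = tables.features[mod]
                tables.features[mod] = ce.batch_center(mat, batches.loc[mat.index])

        clocks = train_cohort_clocks(tables)
        if tables.feature_truth:
            clocks.extend(reference_clocks(tables))
        if config.clock_dir is not None:
            for path in sorted(Path(config.clock_dir).glob("*")):
                if path.suffix in (".tsv", ".json"):
                    clocks.append(ce.read_clock(path))
        if not clocks:
            raise ConfigurationError("no clocks to apply")

        log.info("predicting %d clocks", len(clocks))
        preds = _predict_all(tables, clocks)
        preds.to_csv(out / "predictions.tsv", sep="\t", index=False)

        # replicate selection (cosine similarity) for modalities with replicates
        selection: dict[str, str] = {}
        rep_meta = tables.metadata[tables.metadata["replicate_id"] > 0]
        for (subj, visit, mod), grp in rep_meta.groupby(["subject_id", "visit", "modality"]):
            mat = tables.features[mod]
            subj_meta = tables.metadata[
                (tables.metadata["subject_id"] == subj) & (tables.metadata["modality"] == mod)
            ].sort_values("replicate_id")
            feats = mat.loc[subj_meta["sample_id"]]
            group_meta = subj_meta[subj_meta["visit"] == visit]
            candidates = list(group_meta["sample_id"])
            try:
                selection[f"{subj}_v{visit:02d}_{mod}"] = dv.select_replicate_cosine(
                    feats, candidates
                )
            except (InsufficientDataError, DegenerateDataError) as exc:
                collected.append(str(exc))

        log.info("variability statistics")
        correlations = ls.pearson_vs_ca(preds, strict=False)
        variability = ls.stability_index(preds)
        variability.per_subject.to_csv(out / "stability.tsv", sep="\t", index=False)

        log.info("deviation flagging")
        frames = []
        for clock in preds["clock"].unique():
            frames.append(
                dv.flag_outliers(preds, clock, levels=config.mad_levels,
                                 variant=config.mad_variant, on=config.flag_on)
            )
        deviations = pd.concat(frames, ignore_index=True)
        deviations.to_csv(out / "deviations.tsv", sep="\t", index=False)
        heatmap_matrix(deviations).to_csv(out / "heatmap_matrix.tsv", sep="\t")

        thresholds = _replicate_thresholds(preds, tables.metadata)
        change_flags = dv.flag_within_person_change(
            preds[preds["clock"].isin(thresholds)], thresholds
        )

        densities: dict[str, dict] = {}
        ca_vals = preds[preds["replicate_id"] == 0].drop_duplicates(
            ["subject_id", "visit"]
        )["ca_years"]
        densities["CA"] = density_summary(ca_vals, grid_points=config.density_grid_points)
        for clock, grp in preds[preds["replicate_id"] == 0].groupby("clock"):
            try:
                densities[clock] = density_summary(
                    grp["ba_pred"], grid_points=config.density_grid_points
                )
            except (InsufficientDataError, DegenerateDataError) as exc:
                collected.append(f"density {clock}: {exc}")

        deviators = consistent_deviator_summary(deviations, config.min_clocks_deviator)

    collected.extend(str(w.message) for w in caught)
    report = RunReport(
        correlations=correlations,
        variability=variability,
        deviations=deviations,
        change_flags=change_flags,
        thresholds=thresholds,
        densities=densities,
        deviators=deviators,
        replicate_selection=selection,
        warnings=collected,
    )
    _write_reports(report, out)
    return report


def _write_reports(report: RunReport, out: Path) -> None:
    stats_payload = {
        "correlations": _df_records(report.correlations.reset_index()),
        "per_clock": _df_records(report.variability.per_clock.reset_index()),
        "stability_by_category": report.variability.per_category,
        "replicate_thresholds": report.thresholds,
    }
    (out / "stats.json").write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True, allow_nan=False,
                   default=_json_safe) + "\n"
    )
    report.change_flags.to_csv(out / "change_flags.tsv", sep="\t", index=False)
    full = {
        **stats_payload,
        "densities": report.densities,
        "consistent_deviators": _df_records(report.deviators),
        "replicate_selection": report.replicate_selection,
        "warnings": sorted(set(report.warnings)),
    }
    (out / "report.json").write_text(
        json.dumps(full, indent=2, sort_keys=True, allow_nan=False, default=_json_safe) + "\n"
    )


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _df_records(df: pd.DataFrame) -> list[dict]:
    records = df.to_dict(orient="records")
    for rec in records:
        for k, v in rec.items():
            if isinstance(v, float) and not np.isfinite(v):
                rec[k] = None
    return records


def planted_outlier_trial(
    seed: int,
    offset_sd: float = 3.0,
    subject_idx: int = 0,
    min_clocks: int = 2,
) -> tuple[str | None, str]:
    """Simulate a cohort with one persistently deviant subject and recover it.

    The chosen subject's between-person BA offset is fixed at
    ``offset_sd * sigma_b`` years; the fixed reference clocks are applied,
    age-acceleration MAD flags computed, and the top consistent deviator
    returned alongside the planted subject's id.  Used to measure the power
    of the deviation analysis.
    """
    import dataclasses as _dc

    cfg = CohortConfig(seed=seed)
    cfg = _dc.replace(cfg, outlier_subject_idx=subject_idx)
    cfg.outlier_offset = offset_sd * cfg.sigma_b
    tables = generate_cohort(cfg)
    clocks = reference_clocks(tables)
    preds = _predict_all(tables, clocks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frames = [
            dv.flag_outliers(preds, c, on="age_accel") for c in preds["clock"].unique()
        ]
    deviators = consistent_deviator_summary(pd.concat(frames, ignore_index=True), min_clocks)
    planted = f"ID{subject_idx + 1:02d}"
    top = deviators["subject_id"].iloc[0] if len(deviators) else None
    return top, planted


def load_cohort_dir(path) -> CohortTables:
    """Reassemble :class:`CohortTables` from a directory of TSVs."""
    p = Path(path)
    metadata = pd.read_csv(p / "metadata.tsv", sep="\t")
    truth_path = p / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
    features = {}
    for f in sorted(p.glob("*.features.tsv")):
        mod = f.name.replace(".features.tsv", "")
        features[mod] = pd.read_csv(f, sep="\t", index_col="sample_id")
    if not features:
        raise ConfigurationError(f"no *.features.tsv found in {p}")
    return CohortTables(CohortConfig(), metadata, features, truth, {})
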