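"""End-to-end orchestration: simulate -> preprocess -> stats -> cluster days
-> cluster users -> validate, with a single config and a hashed run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import daytypes, users, validate
from .preprocess import preprocess_logs
from .simulate import CohortConfig, generate_cohort, write_cohort
from .stats import cohort_use_summary

log = logging.getLogger("wearday")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with study defaults."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    k: int | str = "auto"  # day-type count or "auto" (elbow)
    k_range_max: int = 8
    elbow_ratio_threshold: float = 0.5
    n_restarts: int = 10
    clustering_seed: int = 0
    silhouette_subsample: int | None = 5000
    user_methods: tuple[str, ...] = users.METHODS
    n_user_clusters: int = 3
    min_cluster_fraction: float = users.DEFAULT_MIN_CLUSTER_FRACTION
    split_seed: int = 7
    train_frac: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=cohort, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage in order, writing stage outputs and a manifest.

    The manifest content-hashes every written file, so re-running with an
    identical config must reproduce identical hashes.  Any stage failure
    aborts with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        logs, truth = generate_cohort(config.cohort)
        write_cohort(logs, truth, outdir)
        manifest["stages"][stage] = {
            "n_users": int(truth.user_groups.shape[0]),
            "n_days": int(truth.day_types.shape[0]),
            "n_windows": int(truth.windows.shape[0]),
        }

        stage = "preprocess"
        log.info("stage %s", stage)
        A, audit = preprocess_logs(logs, truth.windows)
        A.to_frame().assign(date=lambda d: d["date"].dt.strftime("%Y-%m-%d")).to_csv(
            outdir / "days.csv", index=False
        )
        _write_json(audit.as_dict(), outdir / "audit.json")
        manifest["stages"][stage] = audit.as_dict()

        stage = "stats"
        log.info("stage %s", stage)
        use = cohort_use_summary(A)
        use.users.to_csv(outdir / "user_summary.csv", index=False)
        _write_json(
            {
                "pooled_mean_hours": use.pooled_mean,
                "pooled_sd_hours": use.pooled_sd,
                "cv": use.cv,
                "q1": use.q1,
                "q3": use.q3,
                "segments": use.users["segment"].value_counts().to_dict(),
                "contrasts": {
                    k: dataclasses.asdict(v) for k, v in use.contrasts.items()
                },
                "variability_curve": dataclasses.asdict(use.curve),
            },
            outdir / "use_summary.json",
        )
        manifest["stages"][stage] = {"users": len(use.users)}

        stage = "cluster_days"
        log.info("stage %s", stage)
        day_res = daytypes.DayTypeKMeans(
            A,
            k=config.k,
            k_range=range(1, config.k_range_max + 1),
            elbow_ratio_threshold=config.elbow_ratio_threshold,
            n_restarts=config.n_restarts,
            seed=config.clustering_seed,
            silhouette_subsample=config.silhouette_subsample,
        ).fit()
        day_table = day_res.day_table()
        day_table.assign(date=lambda d: pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")).to_csv(
            outdir / "day_labels.csv", index=False
        )
        _write_json(
            {
                "k": day_res.model.k,
                "type_names": day_res.model.type_names,
                "centroids": day_res.model.centroids,
                "wss_tss_curve": {str(k): v for k, v in day_res.model.wss_tss_curve.items()},
                "silhouette_mean": day_res.silhouette_mean,
                "weekday_association": {
                    "chi2": day_res.weekday.chi2,
                    "p_value": day_res.weekday.p_value,
                    "cramers_v": day_res.weekday.cramers_v,
                },
            },
            outdir / "day_model.json",
        )
        manifest["stages"][stage] = {
            "k": day_res.model.k,
            "retained": int(day_res.keep_mask.sum()),
        }

        stage = "cluster_users"
        log.info("stage %s", stage)
        B, dropped = users.build_user_proportions(day_table, day_res.model.type_names)
        seg = users.UserSegmentation(
            B,
            methods=config.user_methods,
            n_clusters=config.n_user_clusters,
            min_cluster_fraction=config.min_cluster_fraction,
            seed=config.clustering_seed,
        ).fit()
        seg.label_table().to_csv(outdir / "user_labels.csv", index=False)
        _write_json(
            {
                "scores": {m: dataclasses.asdict(s) for m, s in seg.scores.items()},
                "winner": seg.winner,
                "groups": seg.groups.to_dict(orient="records"),
                "n_noise": seg.groups.attrs.get("n_noise", 0),
                "dropped_users": dropped,
            },
            outdir / "user_clustering.json",
        )
        manifest["stages"][stage] = {
            "winner": seg.winner,
            "group_sizes": seg.groups.set_index("group")["size"].to_dict(),
            "n_noise": int(seg.groups.attrs.get("n_noise", 0)),
        }

        stage = "validate"
        log.info("stage %s", stage)
        D = validate.build_average_day(A, day_res.keep_mask)
        # align winning labels with D's user order
        lab = pd.Series(seg.winning_labels, index=B.user_ids).reindex(D.user_ids)
        mask = lab.notna().to_numpy()
        report = validate.ClusterValidator(
            validate.AverageDayMatrix(D.values[mask], D.user_ids[mask]),
            lab.to_numpy()[mask].astype(int),
            train_frac=config.train_frac,
            seed=config.split_seed,
        ).fit()
        _write_json(report.as_dict(), outdir / "validation_report.json")
        manifest["stages"][stage] = {
            "ensemble_accuracy": report.ensemble.accuracy,
            "best_classifier": report.best_kind,
        }
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {err} "
            f"(completed stages: {list(manifest['stages'])})"
        ) from err

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    _write_json(manifest, outdir / "manifest.json")
    return manifest
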