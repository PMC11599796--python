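"""End-to-end pipeline orchestration with run manifests.

``run_pipeline`` chains the stages — simulate (or ingest) match records,
score them (Elo, David's score, DCI, stability), simulate pose
recordings, extract features, cluster behavioral states, compute
enrichment, and compare assays — driven by a single YAML config. Every
run writes a manifest recording the config snapshot, seeds, package
version and SHA-256 digests of each stage's outputs; re-running with
unchanged inputs skips stages whose recorded digests still match, and
deterministic stages reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import domsuite
from domsuite import cross_assay as xa
from domsuite import ranking, synthetic
from domsuite.errors import ValidationError
from domsuite.pose_features import compute_features, interpolate_and_smooth, pool_zscore_subsample
from domsuite.records_io import Assay, read_matches, write_matches
from domsuite.state_clustering import (
    cluster_distribution,
    fit_states,
    make_assignment,
    percent_enriched,
)

log = logging.getLogger("domsuite.pipeline")

# Every default the study conditions pin, in one place; the logger reports
# any of these the user's config did not set explicitly.
DEFAULTS = {
    "seed": 0,
    "simulate": {
        "n_cages": 4,
        "n_animals": 4,
        "beta": 2.0,
        "tie_prob": 0.1,
        "trials_per_dyad": {"agonistic": 10, "urine": 2, "tube": 10, "reward": 6},
        "inverted_assays": [],
    },
    "pose": {"n_recordings": 4, "frames": 1800, "noise_sd": 2.0,
             "missing_fraction": 0.05, "avert_multiplier": 1.6},
    "features": {"window": 25, "polyorder": 3, "step": 3},
    "states": {"k": 8, "kmeans_seed": 42, "n_init": 10},
}
SCHEMA_VERSION = 1


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config: dict
    seeds: dict
    version: str
    outputs: dict[str, dict] = field(default_factory=dict)  # stage -> {path: digest}
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "version": self.version,
                "outputs": self.outputs,
                "failed_stage": self.failed_stage,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_defaults(cfg: dict, defaults: dict, prefix: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key not in cfg:
            log.info("config: %s%s not set, using default %r", prefix, key, dval)
            out[key] = dval
        elif isinstance(dval, dict):
            out[key] = _merge_defaults(cfg[key], dval, prefix=f"{prefix}{key}.")
        else:
            out[key] = cfg[key]
    for key in cfg:
        if key not in defaults and key not in ("schema_version", "out_dir", "stages",
                                               "matches_csv"):
            raise ValidationError(f"unknown config field {prefix}{key!r}")
    return out


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported schema_version {version!r}, expected {SCHEMA_VERSION}")
    cfg = _merge_defaults(raw, DEFAULTS)
    cfg["schema_version"] = version
    cfg["out_dir"] = raw.get("out_dir", "results/run")
    cfg["stages"] = raw.get("stages", ["simulate", "rank", "pose", "states", "cross_assay"])
    cfg["matches_csv"] = raw.get("matches_csv")
    return cfg


def _stage_fresh(manifest_path: Path, stage: str, paths: list[Path]) -> bool:
    """True if a previous manifest recorded these outputs with matching digests."""
    if not manifest_path.exists():
        return False
    try:
        prev = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    recorded = prev.get("outputs", {}).get(stage)
    if not recorded:
        return False
    return all(
        str(p) in recorded and p.exists() and _sha256(p) == recorded[str(p)]
        for p in paths
    )


def run_pipeline(config_path: str | Path, resume: bool = True) -> RunManifest:
    """Execute the configured stages in dependency order.

    On a stage failure the manifest (with ``failed_stage`` set) is still
    written, and earlier outputs remain intact.
    """
    cfg = load_config(config_path)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config=cfg,
        seeds={"master": seed, "kmeans": cfg["states"]["kmeans_seed"]},
        version=domsuite.__version__,
    )

    def record(stage: str, paths: list[Path]) -> None:
        manifest.outputs[stage] = {str(p): _sha256(p) for p in paths}

    stage = ""
    try:
        matches = None
        truth = None
        if "simulate" in cfg["stages"] and cfg["matches_csv"] is None:
            stage = "simulate"
            m_path, t_path = out_dir / "matches.csv", out_dir / "truth.csv"
            if resume and _stage_fresh(manifest_path, stage, [m_path, t_path]):
                log.info("simulate: outputs fresh, skipping")
                matches = read_matches(m_path)
                truth = dict(pd.read_csv(t_path).set_index("animal")["latent"])
                record(stage, [m_path, t_path])
            else:
                sim = cfg["simulate"]
                hcfg = synthetic.HierarchyConfig(
                    n_animals=sim["n_animals"],
                    latent=tuple(synthetic.HierarchyConfig().latent)
                    if sim["n_animals"] == 4
                    else tuple(float(sim["n_animals"] - 1) / 2 - i for i in range(sim["n_animals"])),
                    beta=sim["beta"],
                    tie_prob=sim["tie_prob"],
                    trials_per_dyad={Assay(k): v for k, v in sim["trials_per_dyad"].items()},
                    inverted_assays=frozenset(Assay(a) for a in sim["inverted_assays"]),
                    n_cages=sim["n_cages"],
                    seed=seed,
                )
                matches, truth = synthetic.generate_matches(hcfg)
                write_matches(matches, m_path)
                pd.DataFrame(
                    {"animal": list(truth), "latent": list(truth.values())}
                ).to_csv(t_path, index=False)
                record(stage, [m_path, t_path])
        elif cfg["matches_csv"]:
            matches = read_matches(cfg["matches_csv"])

        elo_df = None
        stability_rows = None
        if "rank" in cfg["stages"]:
            stage = "rank"
            if matches is None:
                raise ValidationError("rank stage needs simulated or ingested matches")
            elo_df, david_df, dci_df, stab_df, stability_rows = score_all(matches)
            paths = []
            for name, df in (
                ("elo", elo_df), ("david", david_df), ("dci", dci_df), ("stability", stab_df)
            ):
                p = out_dir / f"{name}.csv"
                df.to_csv(p, index=False)
                paths.append(p)
            record(stage, paths)

        feature_matrix = None
        rank_meta = None
        if "pose" in cfg["stages"]:
            stage = "pose"
            pose_cfg = cfg["pose"]
            feats = {}
            meta_rows = []
            for i in range(pose_cfg["n_recordings"]):
                rank_diff = (i % 3) + 1
                rec = synthetic.generate_pose(
                    synthetic.PoseSimConfig(
                        frames=pose_cfg["frames"],
                        noise_sd=pose_cfg["noise_sd"],
                        missing_fraction=pose_cfg["missing_fraction"],
                        rank_diff=rank_diff,
                        rank_diff3_avert_multiplier=pose_cfg["avert_multiplier"],
                        seed=seed * 1000 + i,
                    )
                )
                rec.recording_id = f"rec{i}"
                smooth = interpolate_and_smooth(
                    rec, cfg["features"]["window"], cfg["features"]["polyorder"]
                )
                feats[rec.recording_id] = compute_features(smooth)
                meta_rows.append(
                    {"recording": rec.recording_id, "rank_a": 1, "rank_b": 1 + rank_diff}
                )
            feature_matrix = pool_zscore_subsample(feats, step=cfg["features"]["step"])
            rank_meta = pd.DataFrame(meta_rows)
            f_path = out_dir / "features.csv"
            pd.concat([feature_matrix.provenance, feature_matrix.data], axis=1).to_csv(
                f_path, index=False
            )
            record(stage, [f_path])

        if "states" in cfg["stages"]:
            stage = "states"
            if feature_matrix is None:
                raise ValidationError("states stage needs the pose stage's features")
            model, labels = fit_states(
                feature_matrix,
                k=cfg["states"]["k"],
                seed=cfg["states"]["kmeans_seed"],
                n_init=cfg["states"]["n_init"],
            )
            assign = make_assignment(feature_matrix, labels, rank_meta)
            a_path = out_dir / "assignments.csv"
            assign.table.to_csv(a_path, index=False)
            d_path = out_dir / "cluster_distribution.csv"
            cluster_distribution(assign).to_csv(d_path)
            e_path = out_dir / "enrichment.csv"
            percent_enriched(assign).enrichment.to_csv(e_path)
            model_path = out_dir / "state_model.json"
            model_path.write_text(
                json.dumps(
                    {
                        "k": model.k,
                        "seed": model.seed,
                        "inertia": model.inertia,
                        "centroids": model.centroids.tolist(),
                    },
                    indent=2,
                )
            )
            record(stage, [a_path, d_path, e_path, model_path])

        if "cross_assay" in cfg["stages"]:
            stage = "cross_assay"
            if elo_df is None:
                raise ValidationError("cross_assay stage needs the rank stage")
            panel = elo_df.rename(columns={"elo": "score"})[["animal", "assay", "score"]]
            corr = xa.score_correlation_matrix(panel)
            c_path = out_dir / "elo_correlations.csv"
            corr.r.to_csv(c_path)
            rev_rows = []
            by_assay = {}
            for d in stability_rows:
                by_assay.setdefault(d.assay, []).append(d)
            for a1 in by_assay:
                for a2 in by_assay:
                    if a1.value < a2.value:
                        s = xa.rank_reversals(by_assay[a1], by_assay[a2])
                        rev_rows.append(
                            {
                                "assay_1": a1.value,
                                "assay_2": a2.value,
                                "maintained": s.maintained,
                                "reversed": s.reversed,
                                "excluded": s.excluded,
                            }
                        )
            r_path = out_dir / "reversals.csv"
            pd.DataFrame(rev_rows).to_csv(r_path, index=False)
            record(stage, [c_path, r_path])
    except Exception:
        manifest.failed_stage = stage
        manifest_path.write_text(manifest.to_json())
        raise

    manifest_path.write_text(manifest.to_json())
    return manifest


def score_all(matches):
    """Score every (assay, cage) group: Elo finals + ranks, David's score,
    DCI, and per-dyad stability. Returns four tidy DataFrames plus the raw
    DyadStatus list."""
    elo_rows, david_rows, dci_rows, stab_rows = [], [], [], []
    statuses = []
    for (assay, cage), group in ranking.group_matches(matches).items():
        hist = ranking.elo_ratings(group)
        for animal, score in sorted(hist.final.items()):
            elo_rows.append(
                {"assay": assay.value, "cage": cage, "animal": animal,
                 "elo": score, "rank": hist.rank[animal]}
            )
        try:
            table = ranking.david_scores(group)
            for animal, ds in zip(table.animals, table.ds):
                david_rows.append(
                    {"assay": assay.value, "cage": cage, "animal": animal, "ds": float(ds)}
                )
        except ranking.UnmeasurableError:
            log.warning("david: %s/%s unmeasurable (no decisive interactions)", assay.value, cage)
        try:
            g = ranking.dci(group, cage=cage)
            dci_rows.append({"assay": assay.value, "cage": cage, "dci": g.value})
        except ranking.UnmeasurableError:
            log.warning("dci: %s/%s unmeasurable", assay.value, cage)
        for pair, dyad_matches in ranking.dyads(group).items():
            status = ranking.classify_dyad_stability(dyad_matches, assay)
            statuses.append(status)
            stab_rows.append(
                {
                    "assay": assay.value,
                    "cage": cage,
                    "id_a": status.id_a,
                    "id_b": status.id_b,
                    "n": status.n_interactions,
                    "same_winner_fraction": status.same_winner_fraction,
                    "status": status.status.value,
                    "dominant_id": status.dominant_id,
                }
            )
    return (
        pd.DataFrame(elo_rows),
        pd.DataFrame(david_rows),
        pd.DataFrame(dci_rows),
        pd.DataFrame(stab_rows),
        statuses,
    )
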