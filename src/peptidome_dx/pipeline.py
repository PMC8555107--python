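"""End-to-end orchestration of the biomarker discovery analysis.

Stage order: simulate (or ingest) -> align (when raw ion events are
supplied) -> preprocess -> univariate screen -> exposure model building
-> PLS-DA discriminant refinement -> cross-validation -> unsupervised
PCA. A run manifest records the stage-by-stage peptide counts (a
monotone non-increasing filtering chain), the cross-validation metrics
and the leading PCA variance fractions.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence`` so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, discriminant, exposure_models, preprocessing, stats
from .cohort import HIGH, LOW, CohortConfig, cohort_to_frame, generate_cohort
from .peptidome import PeptidomeConfig, generate_peptidome
from .quant import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either the synthetic generator configs are used (default) or
    ``workers_tsv`` plus one of ``matrix_tsv`` / ``events_dir`` point at
    real input tables.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    peptidome: PeptidomeConfig = field(default_factory=PeptidomeConfig)
    workers_tsv: str | None = None
    matrix_tsv: str | None = None
    events_dir: str | None = None
    intensity_loq: float | None = None

    min_frac_quantified: float = 0.5    # first reproducibility tier
    min_frac_reproducible: float = 0.75  # analysis tier
    detection_rule: str = "both"
    fdr: float = 0.05

    model_space: dict | None = None
    vote_delta: float = 0.0
    vote_q: float = 0.05
    refinement_models: tuple[str, ...] = (
        "logSumExp",
        "logSumExp+logIL6",
        "logSumExp+logIL6+age_bin",
    )
    r2_moderate: float = 0.4
    r2_strong: float = 0.7

    vip_cutoff: float = 1.0
    top_k: int = 5
    cv_scheme: str = discriminant.MONTE_CARLO
    cv_repeats: int = 50
    cv_holdout: int | None = None
    n_components: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    manifest: dict
    workers: pd.DataFrame
    matrix: QuantMatrix                  # processed log2-fold matrix
    univariate: pd.DataFrame
    votes: pd.DataFrame
    correlations: exposure_models.CorrelationTiers | None
    vips: pd.Series | None
    cv: discriminant.CVReport | None
    pca: discriminant.PCAResult | None
    truth: pd.DataFrame | None = None


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, rng: np.random.Generator):
    truth = None
    if config.workers_tsv is not None:
        workers = pd.read_csv(config.workers_tsv, sep="\t", index_col="worker_id")
        if config.matrix_tsv is not None:
            matrix = QuantMatrix.from_tsv(config.matrix_tsv, config.intensity_loq)
        elif config.events_dir is not None:
            events = []
            for path in sorted(Path(config.events_dir).glob("events_*.tsv")):
                events.extend(alignment.read_events_tsv(path))
            matrix = alignment.cluster_ion_events(events)
        else:
            raise ValueError("workers_tsv requires matrix_tsv or events_dir")
    else:
        cohort = generate_cohort(config.cohort, seed=rng)
        workers = cohort_to_frame(cohort)
        synthetic = generate_peptidome(cohort, config.peptidome, seed=rng)
        matrix, truth = synthetic.quant, synthetic.truth
    return workers, matrix, truth


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage and return the result bundle.

    Deterministic given ``config.seed``. When ``outdir`` is given, all
    tabular stage outputs plus ``manifest.json`` are written there.
    """
    config = config or PipelineConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    gen_rng = np.random.default_rng(seeds[0])
    cv_rng = np.random.default_rng(seeds[1])

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "started": datetime.now(timezone.utc).isoformat(),
        "counts": {},
        "stages": [],
    }
    counts = manifest["counts"]

    def stage(name: str) -> None:
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        workers, matrix, truth = _load_inputs(config, gen_rng)
        groups = workers["group"]
        counts["features_total"] = matrix.n_features

        stage("preprocess")
        quantified = preprocessing.filter_by_detection(
            matrix, groups, config.min_frac_quantified, rule=config.detection_rule
        )
        counts["quantified_50pct"] = quantified.n_features
        reproducible = preprocessing.filter_by_detection(
            quantified, groups, config.min_frac_reproducible, rule=config.detection_rule
        )
        counts["reproducible_75pct"] = reproducible.n_features
        processed = preprocessing.median_center(reproducible)
        processed = preprocessing.impute_left_censored(processed)
        processed = preprocessing.log2_and_standardize(processed, groups)

        stage("univariate")
        univariate = stats.t_test_rows(processed.values, groups, HIGH, LOW)
        univariate["q"] = stats.bh_adjust(univariate["p"].to_numpy())
        significant = univariate.index[univariate["q"] < config.fdr].tolist()
        counts["significant_fdr"] = len(significant)

        stage("model_build")
        space = config.model_space or exposure_models.default_model_space()
        models = exposure_models.enumerate_models(space)
        counts["candidate_models"] = len(models)
        Y = processed.values.loc[significant]
        votes_df = pd.DataFrame()
        correlations = None
        common: list[str] = []
        if significant:
            aicc = exposure_models.aicc_table(Y, workers, models)
            votes = exposure_models.vote_models(aicc, delta=config.vote_delta)
            votes_df = pd.DataFrame([asdict(v) for v in votes]).set_index("model_id")
            refine_specs = [
                exposure_models.ModelSpec(mid, tuple(mid.split("+")))
                for mid in config.refinement_models
            ]
            correlations = exposure_models.correlation_filter(
                Y,
                workers,
                refine_specs,
                moderate=config.r2_moderate,
                strong=config.r2_strong,
            )
            common = correlations.common_strong
        counts["strong_common"] = len(common)

        stage("discriminate")
        vips = None
        cv = None
        selected: list[str] = []
        top: list[str] = []
        if len(common) >= 2:
            X = processed.values.loc[common].T  # workers x peptides
            model = discriminant.fit_plsda(
                X, groups.loc[X.index].to_numpy(), n_components=config.n_components
            )
            vips = discriminant.vip_scores(model)
            selected = discriminant.select_discriminant(vips, cutoff=config.vip_cutoff)
            top = selected[: config.top_k]
            if top:
                cv = discriminant.cross_validate(
                    X,
                    groups.loc[X.index].to_numpy(),
                    features=top,
                    scheme=config.cv_scheme,
                    n_repeats=config.cv_repeats,
                    holdout_size=config.cv_holdout,
                    n_components=min(config.n_components, len(top)),
                    seed=cv_rng,
                )
        counts["vip_selected"] = len(selected)
        counts["top_k"] = len(top)
        manifest["top_peptides"] = top
        if cv is not None:
            manifest["cv"] = {
                "scheme": cv.scheme,
                "n_repeats": cv.n_repeats,
                "accuracy": cv.accuracy,
                "r2": cv.r2,
                "q2": cv.q2,
            }

        stage("unsupervised_pca")
        pca = None
        if processed.n_features >= 2:
            pca = discriminant.pca_variance(processed.values.T)
            manifest["pca_explained_fraction"] = [
                float(f) for f in pca.explained_fraction[:5]
            ]
    except Exception as err:
        manifest["error"] = {"stage": manifest["stages"][-1], "message": str(err)}
        if outdir is not None:
            _write_manifest(manifest, outdir)
        raise

    manifest["finished"] = datetime.now(timezone.utc).isoformat()

    result = PipelineResult(
        manifest=manifest,
        workers=workers,
        matrix=processed,
        univariate=univariate,
        votes=votes_df,
        correlations=correlations,
        vips=vips,
        cv=cv,
        pca=pca,
        truth=truth,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_manifest(manifest: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.workers.to_csv(outdir / "workers.tsv", sep="\t")
    result.matrix.to_tsv(outdir / "processed_matrix.tsv")
    result.univariate.to_csv(outdir / "univariate.tsv", sep="\t", index_label="peptide_id")
    if not result.votes.empty:
        result.votes.to_csv(outdir / "model_votes.tsv", sep="\t")
    if result.correlations is not None:
        result.correlations.adj_r2.to_csv(
            outdir / "correlations.tsv", sep="\t", index_label="peptide_id"
        )
        pd.Series(result.correlations.common_strong, name="peptide_id").to_csv(
            outdir / "strong_common_peptides.tsv", sep="\t", index=False
        )
    if result.vips is not None:
        result.vips.to_csv(outdir / "vip_scores.tsv", sep="\t", index_label="peptide_id")
    if result.cv is not None:
        result.cv.class_probability.to_csv(
            outdir / "class_probabilities.tsv", sep="\t", index_label="worker_id"
        )
        with open(outdir / "cv_report.json", "w") as fh:
            json.dump(result.manifest["cv"], fh, indent=2)
    if result.pca is not None:
        pd.Series(
            result.pca.explained_fraction,
            index=[f"PC{i + 1}" for i in range(len(result.pca.explained_fraction))],
            name="explained_fraction",
        ).to_csv(outdir / "pca_variance.tsv", sep="\t", index_label="component")
    if result.truth is not None:
        result.truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
    _write_manifest(result.manifest, outdir)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``cohort`` and
    ``peptidome`` may be nested mappings of their own config fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
    if "peptidome" in kwargs:
        kwargs["peptidome"] = PeptidomeConfig(**kwargs["peptidome"])
    if "refinement_models" in kwargs:
        kwargs["refinement_models"] = tuple(kwargs["refinement_models"])
    return PipelineConfig(**kwargs)
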