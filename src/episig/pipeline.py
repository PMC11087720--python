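"""End-to-end orchestration: discovery, validation, and artifact output.

``run_discovery`` executes the full derivation sequence on one cohort:
optional control matching, per-probe statistics, iterative pruning of
episignature-negative cases, probe selection, SVM training (all retained
cases + 75% of the negative class; the held-out 25% negatives measure
specificity), optional leave-25%-out cross-validation, and the clustering /
MDS robustness views.  Every artifact is written under ``outdir`` with a
manifest that records the configuration hash, so a rerun with the same
config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .classify import (
    TrainedClassifier,
    assess_specificity,
    mvp_report,
    split_train_test,
    train_svm,
)
from .dmp import (
    ProbeSet,
    SelectionParams,
    dmp_table,
    iterative_case_pruning,
)
from .exceptions import ArgumentError, EpisigError
from .validate import cross_validate, cv_report_frame, hierarchical_cluster, mds_embed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-file configuration of an end-to-end run."""

    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    cgi_bed_path: str | None = None
    outdir: str = "episig_run"
    seed: int = 0
    # module parameter blocks
    selection: SelectionParams = field(default_factory=SelectionParams)
    covariates: tuple = ("age", "sex")
    train_fraction: float = 0.75
    svm_c: float = 1.0
    mvp_cutoff: float = 0.25
    max_pruning_rounds: int = 3
    cv_rounds: int = 20
    cv_holdout: float = 0.25
    run_cv: bool = True
    match_ratio: int | None = None  # None = use all controls as given

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel = SelectionParams(**raw.pop("selection", {}))
        cfg = cls(selection=sel, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "selection"}
        d["covariates"] = list(self.covariates)
        d["selection"] = self.selection.__dict__
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DiscoveryArtifacts:
    dmp: pd.DataFrame
    probe_set: ProbeSet
    removed_case_ids: list[str]
    classifier: TrainedClassifier
    scores: pd.DataFrame  # mvp report for all discovery samples
    specificity: float  # % of held-out negatives below the negative cutoff
    cv_report: pd.DataFrame | None
    stage_counts: dict


def _log_stage(stage: str, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s stage=%s %s", time.strftime("%H:%M:%S"), stage, kv)


def run_discovery(
    config: RunConfig,
    beta: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> DiscoveryArtifacts:
    """Run the discovery sequence; returns in-memory artifacts and, when
    ``outdir`` (or ``config.outdir``) is set, writes them to disk.

    ``beta``/``sheet`` may be passed directly (analysis scripts, tests) or
    read from the configured paths.
    """
    if beta is None:
        if not config.beta_path:
            raise ArgumentError("no beta matrix given (config.beta_path unset)")
        beta = mio.read_beta_matrix(config.beta_path)
    if sheet is None:
        if not config.sample_sheet_path:
            raise ArgumentError("no sample sheet given (config.sample_sheet_path unset)")
        sheet = mio.read_sample_sheet(config.sample_sheet_path)
    mio.validate_sample_sheet(sheet)
    counts = {"probes_in": len(beta), "samples_in": len(sheet)}

    beta, n_dropped = mio.drop_incomplete_probes(beta)
    counts["probes_complete"] = len(beta)
    _log_stage("qc", dropped=n_dropped, kept=len(beta))

    # optional control matching against a larger pool
    if config.match_ratio is not None:
        cases = sheet[sheet["group"] == "case"]
        pool = sheet[sheet["group"] == "control"]
        match = mio.match_controls(cases, pool, ratio=config.match_ratio)
        keep = set(cases["sample_id"]) | set(match.selected)
        sheet = sheet[sheet["sample_id"].isin(keep) | ~sheet["group"].isin(["control"])]
        _log_stage("match_controls", selected=len(match.selected),
                   mean_age_gap=round(match.mean_age_gap, 2))

    # iterative removal of episignature-negative cases
    pruning = iterative_case_pruning(
        beta,
        sheet,
        selection=config.selection,
        covariates=config.covariates,
        mvp_cutoff=config.mvp_cutoff,
        max_rounds=config.max_pruning_rounds,
        seed=config.seed,
    )
    retained_sheet = sheet[~sheet["sample_id"].isin(pruning.removed_case_ids)]
    _log_stage("pruning", removed=len(pruning.removed_case_ids))

    table = dmp_table(beta[retained_sheet["sample_id"]], retained_sheet, config.covariates)
    counts["dmps_q05"] = int((table["q"] < 0.05).sum())
    probe_set = pruning.probe_set
    counts["selected_probes"] = len(probe_set.probe_ids)
    _log_stage("selection", selected=len(probe_set.probe_ids))

    # split the negative class 75/25; all retained cases train (the held-out
    # negatives are the specificity test set)
    negatives = retained_sheet[retained_sheet["group"].isin(["control", "other_disorder"])]
    neg_train, neg_test = split_train_test(
        negatives, fraction=config.train_fraction, seed=config.seed
    )
    cases_ids = retained_sheet.loc[retained_sheet["group"] == "case", "sample_id"].tolist()
    train_sheet = retained_sheet[
        retained_sheet["sample_id"].isin(set(cases_ids) | set(neg_train))
    ]
    classifier = train_svm(
        beta, probe_set, train_sheet, c=config.svm_c, seed=config.seed, test_ids=neg_test
    )
    scores = mvp_report(classifier, beta[retained_sheet["sample_id"]])
    specificity = assess_specificity(classifier, beta, neg_test)
    _log_stage("training", train=len(train_sheet), held_out_negatives=len(neg_test),
               specificity=specificity)

    cv = None
    if config.run_cv:
        cv_rounds = cross_validate(
            beta,
            retained_sheet,
            n_rounds=config.cv_rounds,
            holdout_fraction=config.cv_holdout,
            seed=config.seed,
            selection=config.selection,
            covariates=config.covariates,
        )
        cv = cv_report_frame(cv_rounds)
        _log_stage("cross_validation", rounds=config.cv_rounds)

    signature_beta = beta.loc[probe_set.probe_ids, retained_sheet["sample_id"]]
    dendro = hierarchical_cluster(signature_beta)
    mds = mds_embed(signature_beta)

    artifacts = DiscoveryArtifacts(
        dmp=table,
        probe_set=probe_set,
        removed_case_ids=pruning.removed_case_ids,
        classifier=classifier,
        scores=scores,
        specificity=specificity,
        cv_report=cv,
        stage_counts=counts,
    )

    outdir = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "dmp_table.tsv", sep="\t", index_label="probe_id")
        probe_set.to_json(outdir / "probe_set.json")
        classifier.to_json(outdir / "classifier.json")
        scores.to_csv(outdir / "mvp_scores.tsv", sep="\t", index=False)
        (outdir / "removed_cases.txt").write_text(
            "\n".join(pruning.removed_case_ids) + ("\n" if pruning.removed_case_ids else "")
        )
        if cv is not None:
            cv.to_csv(outdir / "cv_report.tsv", sep="\t", index=False)
        (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        mds.to_csv(outdir / "mds_coordinates.tsv", sep="\t", index_label="sample_id")
        manifest = {
            "config_hash": config.content_hash(),
            "config": config.to_dict(),
            "stage_counts": counts,
            "specificity_percent": specificity,
            "removed_cases": pruning.removed_case_ids,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return artifacts


def run_validation(
    config: RunConfig,
    probe_set: ProbeSet,
    classifier: TrainedClassifier,
    new_beta: pd.DataFrame,
    training_beta: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Score a validation cohort with the frozen classifier.

    Returns the MVP report; when ``training_beta`` is given, the combined
    cohort is re-clustered on the signature probes and the dendrogram is
    written alongside the scores.
    """
    if new_beta.shape[1] == 0:
        logger.warning("empty validation set; nothing to score")
        return pd.DataFrame(columns=["sample_id", "mvp", "call"])
    report = mvp_report(classifier, new_beta)
    dendro = None
    if training_beta is not None:
        combined = pd.concat(
            [training_beta.loc[probe_set.probe_ids], new_beta.loc[probe_set.probe_ids]], axis=1
        )
        dendro = hierarchical_cluster(combined)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "validation_scores.tsv", sep="\t", index=False)
        if dendro is not None:
            (outdir / "validation_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    return report
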