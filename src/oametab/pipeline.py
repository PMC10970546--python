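"""End-to-end paired analysis: QC -> volcano -> OPLS-DA -> VIP -> annotation.

Each ionization mode is normalized to its own internal standard and
CV-filtered on its own QC pools; the two filtered tables are then
concatenated into one feature matrix (the two acquisitions share the same
injections, so sample ids match) and the volcano screen, the OPLS-DA model
and the VIP ranking operate on the joint pos+neg variable set. Selected
variables are finally annotated against the compound library with
polarity-appropriate adducts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from oametab import annotate as ann
from oametab import io as oio
from oametab import oplsda, qc
from oametab.volcano import volcano as volcano_table, impute_half_min
from oametab.simulate import ISTD_IDS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pairwise", "run_study"]


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one paired comparison."""

    pos_table: str
    neg_table: str
    sample_sheet: str
    library: str | None = None  # None -> bundled 18-compound library
    t_early: str = "T0"
    t_late: str = "T28"
    istd_pos: str = ISTD_IDS["pos"]
    istd_neg: str = ISTD_IDS["neg"]
    cv_threshold: float = 30.0
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    n_ortho: int | str = 0
    folds: int = 7
    n_permutations: int = 1000
    top_n: int = 30
    tol_ppm: float = 20.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Per-stage counts and diagnostics for one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        data = json.loads(text)
        return cls(config=data["config"], stages=data["stages"])


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log_stage(report: RunReport, stage: str, **info):
    report.stages[stage] = info
    logger.info("stage %s: %s", stage, info)


def run_pairwise(config: PipelineConfig, outdir) -> RunReport:
    """Run the full paired pipeline from files on disk; write artifacts."""
    pos = oio.read_feature_table(config.pos_table, mode="pos")
    neg = oio.read_feature_table(config.neg_table, mode="neg")
    sheet = oio.read_sample_sheet(config.sample_sheet)
    lib_path = config.library or oio.bundled_library_path()
    library = oio.load_compound_library(lib_path)
    return run_study(pos, neg, sheet, library, config, outdir)


def run_study(pos, neg, sheet, library, config: PipelineConfig, outdir) -> RunReport:
    """Run the pipeline on in-memory objects; write artifacts to ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    report = RunReport(
        config={
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (bytes,))
        }
    )
    try:
        result = _run_stages(pos, neg, sheet, library, config, outdir, report)
    except Exception as exc:
        stage = getattr(exc, "stage", "unknown")
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    return result


def _run_stages(pos, neg, sheet, library, config, outdir, report):
    # --- QC: per-mode ISTD normalization + CV filter ---------------------
    filtered = {}
    for table, istd in ((pos, config.istd_pos), (neg, config.istd_neg)):
        mode = table.mode
        try:
            rep = qc.istd_report(table, sheet, istd)
            normed = qc.normalize_to_istd(table, sheet, istd)
            cvres = qc.cv_filter(normed, sheet, threshold_percent=config.cv_threshold)
            kept = cvres.apply(normed)
        except Exception as exc:
            raise StageError(f"qc_{mode}", exc) from exc
        rep.areas.to_csv(os.path.join(outdir, f"istd_{mode}.tsv"), sep="\t", index=False)
        kept.write(os.path.join(outdir, f"filtered_{mode}.tsv"))
        filtered[mode] = kept
        _log_stage(
            report,
            f"qc_{mode}",
            istd=istd,
            istd_slope=rep.slope,
            istd_cv_percent=round(rep.cv_percent, 4),
            n_features_in=table.n_features,
            n_removed=len(cvres.removed),
            n_features_out=kept.n_features,
        )

    # --- joint pos+neg matrix over shared samples ------------------------
    try:
        combined_int, feature_meta = _concatenate(filtered["pos"], filtered["neg"])
    except Exception as exc:
        raise StageError("concatenate", exc) from exc

    # --- volcano ---------------------------------------------------------
    try:
        joint = oio.FeatureTable(
            mode="pos",  # carrier object; per-feature polarity in feature_meta
            features=feature_meta[["mz", "rt"]],
            intensities=combined_int,
        )
        vtab = volcano_table(
            joint,
            sheet,
            config.t_early,
            config.t_late,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
        )
    except Exception as exc:
        raise StageError("volcano", exc) from exc
    vtab.to_csv(os.path.join(outdir, "volcano.tsv"), sep="\t")
    selected_ids = list(vtab.index[vtab["selected"]])
    _log_stage(
        report,
        "volcano",
        n_features=len(vtab),
        n_selected=len(selected_ids),
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
    )
    if len(selected_ids) < 2:
        raise StageError(
            "volcano", ValueError("fewer than 2 volcano-selected variables")
        )

    # --- OPLS-DA on the volcano-selected subset --------------------------
    try:
        X, y, sample_ids = _design_matrix(
            combined_int.loc[selected_ids], sheet, config.t_early, config.t_late
        )
        rng = np.random.default_rng(config.seed)
        cv_seed = int(rng.integers(2**31 - 1))
        perm_seed = int(rng.integers(2**31 - 1))
        model = oplsda.fit_oplsda(
            X, y, n_ortho=config.n_ortho, variable_ids=selected_ids
        )
        cv = oplsda.cross_validate(
            X, y, n_ortho=model.n_ortho, folds=config.folds, seed=cv_seed
        )
        anova = oplsda.cv_anova(cv, y, model)
        perm = oplsda.permutation_test(
            X,
            y,
            n_ortho=model.n_ortho,
            n_iterations=config.n_permutations,
            seed=perm_seed,
            folds=config.folds,
        )
        vip = oplsda.vip_scores(X, y, model, folds=config.folds, seed=cv_seed)
        vip_selected = oplsda.select_variables(vip, top_n=config.top_n)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("oplsda", exc) from exc

    scores = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "y": y,
            "t_pred": model.scores,
            **{
                f"t_ortho{k + 1}": model.ortho_scores[:, k]
                for k in range(model.n_ortho)
            },
        }
    )
    scores.to_csv(os.path.join(outdir, "scores.tsv"), sep="\t", index=False)
    perm.to_frame().to_csv(os.path.join(outdir, "permutation.tsv"), sep="\t", index=False)
    vip_out = vip.copy()
    vip_out["polarity"] = feature_meta.loc[vip_out.index, "polarity"].to_numpy()
    vip_out["selected"] = vip_out.index.isin(vip_selected)
    vip_out.to_csv(os.path.join(outdir, "vip.tsv"), sep="\t")
    _log_stage(
        report,
        "oplsda",
        n_variables=len(selected_ids),
        n_ortho=model.n_ortho,
        r2y=round(model.r2y, 6),
        q2y=round(cv.q2y, 6),
        cv_anova_f=round(anova.f_statistic, 6),
        cv_anova_p=float(f"{anova.p_value:.6g}"),
        permutation_p_q2=perm.p_q2,
        n_permutations=perm.n_iterations,
        n_vip_selected=len(vip_selected),
    )

    # --- annotation of the VIP-selected variables ------------------------
    try:
        feats = feature_meta.loc[vip_selected].reset_index()
        hits = ann.match_features(
            feats[["feature_id", "mz", "polarity"]],
            library,
            tol_ppm=config.tol_ppm,
        )
        groups = ann.distinct_compounds(hits)
    except Exception as exc:
        raise StageError("annotation", exc) from exc
    ann.hits_to_frame(hits).to_csv(os.path.join(outdir, "hits.tsv"), sep="\t", index=False)
    _log_stage(
        report,
        "annotation",
        n_variables=len(vip_selected),
        n_hits=len(hits),
        n_compounds=len(groups),
        tol_ppm=config.tol_ppm,
        compounds=sorted(groups),
    )
    return report


def _concatenate(pos: oio.FeatureTable, neg: oio.FeatureTable):
    """Stack pos and neg tables over the shared samples.

    Feature ids must stay unique in the joint table; a clash across modes
    (possible with printed "mz;rt" ids) gets a polarity suffix.
    """
    shared = [s for s in pos.sample_ids if s in set(neg.sample_ids)]
    if not shared:
        raise ValueError("positive and negative tables share no sample ids")

    def frame(table):
        meta = table.features[["mz", "rt"]].copy()
        meta["polarity"] = table.mode
        return meta, table.intensities[shared]

    pos_meta, pos_int = frame(pos)
    neg_meta, neg_int = frame(neg)
    clash = set(pos_meta.index) & set(neg_meta.index)
    if clash:
        pos_meta = pos_meta.rename(index={i: f"{i};pos" for i in clash})
        pos_int = pos_int.rename(index={i: f"{i};pos" for i in clash})
        neg_meta = neg_meta.rename(index={i: f"{i};neg" for i in clash})
        neg_int = neg_int.rename(index={i: f"{i};neg" for i in clash})
    meta = pd.concat([pos_meta, neg_meta])
    meta.index.name = "feature_id"
    return pd.concat([pos_int, neg_int]), meta


def _design_matrix(intensities: pd.DataFrame, sheet, t_early: str, t_late: str):
    """Samples x variables matrix of log10 intensities with -1/+1 labels."""
    pairs = sheet.pairs(t_early, t_late)
    sample_ids = list(pairs["early"]) + list(pairs["late"])
    imputed = impute_half_min(intensities[sample_ids])
    X = np.log10(imputed[sample_ids].to_numpy(dtype=float)).T
    y = np.array([-1.0] * len(pairs) + [1.0] * len(pairs))
    return X, y, sample_ids
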