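"""Synthetic paired LC-MS study generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes for a
6-subject, two-timepoint serum study acquired in positive and negative ESI:

* log-normal feature intensities with a per-(feature, subject) random
  effect shared across the subject's two timepoints (the paired design);
* a planted fraction of discriminant features whose later-timepoint level
  is shifted by a known log2 fold change of random sign;
* per-feature multiplicative analytical noise with a known CV, including a
  deliberately irreproducible subpopulation to exercise the QC CV filter;
* a pooled-QC channel (per-feature mean of all biological samples plus
  analytical noise) injected periodically, preceded by conditioning QC
  injections that are flagged for exclusion;
* one internal-standard feature per mode at constant true level with an
  optional linear injection-order drift.

Chromatographic peak shapes, isotope envelopes and batch effects beyond
linear drift are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from oametab.io import FeatureTable, SampleSheet

__all__ = ["SimulationConfig", "GroundTruth", "generate_study", "small_config"]

ISTD_IDS = {"pos": "ISTD_leuenk_pos", "neg": "ISTD_reserpine_neg"}
# observed ions of the spiked standards: leucine-enkephalin [M+H]+,
# reserpine [M-H]-
ISTD_MZ = {"pos": 556.2766, "neg": 607.2661}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for :func:`generate_study`."""

    n_subjects: int = 6
    n_features_pos: int = 4045
    n_features_neg: int = 9712
    fraction_discriminant: float = 0.01
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    subject_sd: float = 0.15  # between-subject sd on log10 scale
    noise_cv_median: float = 0.10  # median analytical CV (fraction)
    noise_cv_sigma: float = 0.25  # sigma of ln(CV)
    high_cv_fraction: float = 0.15  # fraction of grossly irreproducible features
    high_cv_range: tuple[float, float] = (0.60, 1.00)
    istd_drift_slope: float = 0.0  # area units per injection
    istd_level: float = 1.0e6
    istd_cv: float = 0.03
    qc_pool_every: int = 6
    n_qc_cond: int = 5
    baseline_log10_range: tuple[float, float] = (4.0, 7.0)
    t_early: str = "T0"
    t_late: str = "T28"
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_discriminant", "high_cv_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects for a paired analysis")
        if self.qc_pool_every < 1:
            raise ValueError("qc_pool_every must be >= 1")
        if min(self.n_features_pos, self.n_features_neg) < 2:
            raise ValueError("need at least 2 features per mode")


def small_config(**overrides) -> SimulationConfig:
    """A small, QC-dense preset (200 features total, 6 subjects).

    A QC pool after every biological injection keeps the per-feature CV
    estimator stable enough to separate the planted reproducible and
    irreproducible feature groups at the 30% threshold.
    """
    base = SimulationConfig(
        n_features_pos=80, n_features_neg=120, qc_pool_every=1
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """What the generator planted, per mode.

    ``features[mode]`` has one row per feature id with its true analytical
    CV, discriminant flag and signed log2 fold change (0 for nulls).
    """

    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    istd_ids: dict[str, str] = field(default_factory=dict)

    def discriminant_ids(self, mode: str | None = None) -> list[str]:
        modes = [mode] if mode else sorted(self.features)
        out: list[str] = []
        for m in modes:
            df = self.features[m]
            out.extend(df.index[df["is_discriminant"]])
        return out


def _injection_plan(config: SimulationConfig, rng: np.random.Generator):
    """Sequence of (sample_id, role, subject, timepoint) in injection order."""
    bio = [
        (f"S{s + 1:02d}_{tp}", "biological", f"S{s + 1:02d}", tp)
        for s in range(config.n_subjects)
        for tp in (config.t_early, config.t_late)
    ]
    order = rng.permutation(len(bio))
    bio = [bio[i] for i in order]

    plan = [
        (f"QCcond_{i + 1}", "qc_cond", None, None) for i in range(config.n_qc_cond)
    ]
    n_pool = 0

    def pool():
        nonlocal n_pool
        n_pool += 1
        return (f"QCpool_{n_pool}", "qc_pool", None, None)

    plan.append(pool())
    for i, inj in enumerate(bio, start=1):
        plan.append(inj)
        if i % config.qc_pool_every == 0 and i < len(bio):
            plan.append(pool())
    plan.append(pool())
    return plan


def _simulate_mode(mode, n_features, config, plan, rng):
    ids = [f"{mode}_{i + 1:05d}" for i in range(n_features - 1)] + [ISTD_IDS[mode]]
    mz = np.round(rng.uniform(100.0, 1700.0, size=n_features - 1), 6)
    rt = np.round(rng.uniform(0.5, 12.0, size=n_features - 1), 3)
    features = pd.DataFrame(
        {"mz": np.append(mz, ISTD_MZ[mode]), "rt": np.append(rt, 6.0)},
        index=pd.Index(ids, name="feature_id"),
    )
    n_ord = n_features - 1  # ordinary (non-ISTD) features

    # per-feature analytical CV; a planted fraction is grossly irreproducible
    cv = np.exp(rng.normal(np.log(config.noise_cv_median), config.noise_cv_sigma, n_ord))
    n_high = int(round(config.high_cv_fraction * n_ord))
    high_idx = rng.choice(n_ord, size=n_high, replace=False)
    cv[high_idx] = rng.uniform(*config.high_cv_range, size=n_high)

    # planted discriminant features with signed log2 fold changes
    n_disc = int(round(config.fraction_discriminant * n_ord))
    disc_idx = rng.choice(n_ord, size=n_disc, replace=False)
    log2fc = np.zeros(n_ord)
    magnitude = rng.uniform(*config.log2fc_range, size=n_disc)
    sign = rng.choice([-1.0, 1.0], size=n_disc)
    log2fc[disc_idx] = sign * magnitude

    mu = rng.uniform(*config.baseline_log10_range, size=n_ord)  # log10 baseline
    subj_eff = rng.normal(0.0, config.subject_sd, size=(n_ord, config.n_subjects))
    log_sd = np.sqrt(np.log1p(cv**2))  # multiplicative noise: CV -> sd of ln

    subjects = [f"S{s + 1:02d}" for s in range(config.n_subjects)]
    subj_index = {s: i for i, s in enumerate(subjects)}

    # expected linear-scale level per (feature, subject, timepoint); the QC
    # pool is the physical mean of the biological aliquots
    base_log10 = mu[:, None] + subj_eff  # feature x subject, early timepoint
    late_log10 = base_log10 + (log2fc * np.log10(2.0))[:, None]
    pool_level = 0.5 * (10.0**base_log10 + 10.0**late_log10).mean(axis=1)

    n_inj = len(plan)
    intensities = np.empty((n_features, n_inj))
    qc_cond_draw = None
    for j, (sample_id, role, subject, timepoint) in enumerate(plan):
        noise = np.exp(rng.normal(0.0, log_sd))
        if role == "biological":
            level_log10 = (
                late_log10[:, subj_index[subject]]
                if timepoint == config.t_late
                else base_log10[:, subj_index[subject]]
            )
            values = 10.0**level_log10 * noise
        elif role == "qc_pool":
            values = pool_level * noise
        else:  # qc_cond: replicate injections of the first conditioning draw
            if qc_cond_draw is None:
                qc_cond_draw = pool_level * noise
            values = qc_cond_draw
        istd_area = (config.istd_level + config.istd_drift_slope * (j + 1)) * np.exp(
            rng.normal(0.0, np.sqrt(np.log1p(config.istd_cv**2)))
        )
        intensities[:, j] = np.append(values, istd_area)

    table = FeatureTable(
        mode=mode,
        features=features,
        intensities=pd.DataFrame(
            intensities, index=features.index, columns=[p[0] for p in plan]
        ),
    )
    truth = pd.DataFrame(
        {
            "true_cv": np.append(cv, config.istd_cv),
            "is_discriminant": np.append(log2fc != 0.0, False),
            "log2fc": np.append(log2fc, 0.0),
            "is_istd": [False] * n_ord + [True],
        },
        index=features.index,
    )
    return table, truth


def generate_study(config: SimulationConfig):
    """Generate (pos table, neg table, sample sheet, ground truth).

    Bit-reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    plan = _injection_plan(config, rng)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "role": [p[1] for p in plan],
                "subject": pd.array([p[2] for p in plan], dtype="string"),
                "timepoint": pd.array([p[3] for p in plan], dtype="string"),
                "injection_order": np.arange(1, len(plan) + 1),
            },
            index=pd.Index([p[0] for p in plan], name="sample_id"),
        )
    )

    pos_table, pos_truth = _simulate_mode("pos", config.n_features_pos, config, plan, rng)
    neg_table, neg_truth = _simulate_mode("neg", config.n_features_neg, config, plan, rng)
    truth = GroundTruth(
        features={"pos": pos_truth, "neg": neg_truth},
        istd_ids=dict(ISTD_IDS),
    )
    return pos_table, neg_table, sheet, truth


def write_study(outdir, pos_table, neg_table, sheet, truth) -> dict:
    """Write the four study artifacts plus ground truth as TSV; return paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pos": os.path.join(outdir, "features_pos.tsv"),
        "neg": os.path.join(outdir, "features_neg.tsv"),
        "sheet": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "ground_truth.tsv"),
    }
    pos_table.write(paths["pos"])
    neg_table.write(paths["neg"])
    sheet.write(paths["sheet"])
    combined = pd.concat(
        [df.assign(mode=m) for m, df in truth.features.items()]
    )
    combined.index.name = "feature_id"
    combined.to_csv(paths["truth"], sep="\t")
    return paths
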