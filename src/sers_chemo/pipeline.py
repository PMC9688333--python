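"""End-to-end case studies: simulate -> preprocess -> cross-validate -> VIP.

Two comparisons are wired in, mirroring the study design the synthetic
cohort emulates:

* ``lung_vs_control`` — lung-cancer subjects versus controls; subjects of
  other cancer types are excluded from both groups.
* ``all_cancer_vs_control`` — every cancer subject (lung plus other types)
  versus controls.

A run writes a report directory of delimited tables (per-fold and aggregate
metrics, fold-averaged ROC, VIP scores and bands, group mean-difference
spectra, LV score scatter) plus a machine-readable ``summary.json``.  Every
table header carries the run seed and a hash of the full configuration, and
all randomness derives from the single top-level seed via stage-name-keyed
substreams, so identical configs reproduce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .io import SpectralDataset
from .plsda import PLSDA, encode_labels, group_mean_difference
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import SimConfig, case1_peaks, case2_peaks, generate_dataset
from .validation import ModelConfig, cross_validate, make_folds

__all__ = [
    "CaseStudyConfig",
    "run_case_study",
    "default_case1_config",
    "default_case2_config",
    "case_groups",
    "stage_seed",
]

logger = logging.getLogger("sers_chemo")

CASES = ("lung_vs_control", "all_cancer_vs_control")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage substream seed from the top-level seed (stage-keyed)."""
    return int((int(seed) ^ zlib.crc32(stage.encode())) % (2**31))


def case_groups(case: str) -> tuple[list[str], list[str]]:
    """(case_labels, kept_labels) for a named comparison."""
    if case == "lung_vs_control":
        return ["lung_cancer"], ["lung_cancer", "control"]
    if case == "all_cancer_vs_control":
        return ["lung_cancer", "other_cancer"], ["lung_cancer", "other_cancer", "control"]
    raise ValueError(f"unknown case {case!r}; expected one of {CASES}")


@dataclass(frozen=True)
class CaseStudyConfig:
    case: str
    sim: SimConfig
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    K: int = 10
    seed: int = 0
    evaluation_level: str = "subject"
    output_dir: str = "case_study_out"

    def __post_init__(self) -> None:
        case_groups(self.case)  # validates


def default_case1_config(seed: int = 0, output_dir: str = "case1_out", **sim_overrides) -> CaseStudyConfig:
    """Lung vs control on a 12/11-subject synthetic cohort."""
    sim = SimConfig(
        n_subjects_per_class={"lung_cancer": 12, "control": 11},
        peaks=case1_peaks(),
        seed=stage_seed(seed, "simulate"),
        **sim_overrides,
    )
    return CaseStudyConfig(case="lung_vs_control", sim=sim, seed=seed, output_dir=output_dir)


def default_case2_config(seed: int = 0, output_dir: str = "case2_out", **sim_overrides) -> CaseStudyConfig:
    """All cancers (15 lung + 7 other) vs 12 controls, the full-roster layout."""
    sim = SimConfig(
        n_subjects_per_class={"lung_cancer": 15, "other_cancer": 7, "control": 12},
        peaks=case2_peaks(),
        seed=stage_seed(seed, "simulate"),
        **sim_overrides,
    )
    return CaseStudyConfig(case="all_cancer_vs_control", sim=sim, seed=seed, output_dir=output_dir)


# ---------------------------------------------------------------------------
# serialization helpers


def _config_dict(config: CaseStudyConfig) -> dict:
    d = asdict(config)
    d["sim"]["grid"] = [float(config.sim.grid[0]), float(config.sim.grid[-1]),
                        float(np.median(np.diff(config.sim.grid)))]
    d["sim"]["peaks"] = [
        {"center": p.center, "fwhm": p.fwhm, "base_amplitude": p.base_amplitude,
         "class_effect": dict(p.class_effect)}
        for p in config.sim.peaks
    ]
    return d


def config_hash(config: CaseStudyConfig) -> str:
    d = _config_dict(config)
    d.pop("output_dir", None)  # where results land is not part of the science
    text = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _table_header(config: CaseStudyConfig) -> str:
    return f"config_hash={config_hash(config)} seed={config.seed}"


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# runner


def run_case_study(config: CaseStudyConfig,
                   dataset: SpectralDataset | None = None) -> dict:
    """Run one comparison end to end; returns the machine-readable summary.

    If *dataset* is given it is used as the raw input instead of simulating
    (its class labels must cover the case's groups).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _table_header(config)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        case_labels, kept = case_groups(config.case)
        truth_bands = None
        if dataset is None:
            logger.info("simulating dataset (%s)", config.case)
            dataset, truth_bands = generate_dataset(config.sim)
        mask = np.isin(dataset.class_labels, kept)
        dataset = dataset.select(mask)
        logger.info("dataset: %d spectra, %d subjects", dataset.n_spectra,
                    len(dataset.subjects))

        t = time.time()
        pp = preprocess_pipeline(dataset, config.preprocess)
        logger.info("preprocess: %.1fs", time.time() - t)

        t = time.time()
        plan = make_folds(pp.subject_ids, pp.class_labels, K=config.K,
                          seed=stage_seed(config.seed, "folds"))
        report = cross_validate(pp, case_labels, plan, config.model,
                                evaluation_level=config.evaluation_level)
        logger.info("cross-validation: %.1fs", time.time() - t)

        # full-data fit for VIP band identification and LV scatter
        y = encode_labels(pp.class_labels, case_labels)
        A_full = (int(np.median([f.n_components for f in report.folds]))
                  if config.model.n_components == "auto"
                  else int(config.model.n_components))
        A_full = max(1, min(A_full, pp.n_spectra - 1, pp.X.shape[1]))
        full = PLSDA.from_dataset(pp, case_labels).fit(A_full)
        vip = full.vip()

        # tables
        _write_table(report.per_fold_frame(), out / "fold_metrics.csv", header)
        _write_table(
            pd.DataFrame({"fpr": report.avg_roc_fpr, "tpr": report.avg_roc_tpr}),
            out / "roc_averaged.csv", header,
        )
        roc_rows = []
        for f in report.folds:
            for x, yv in zip(f.roc_fpr, f.roc_tpr):
                roc_rows.append({"fold": f.fold, "fpr": x, "tpr": yv})
        _write_table(pd.DataFrame(roc_rows), out / "roc_per_fold.csv", header)
        _write_table(vip.to_frame(), out / "vip_scores.csv", header)
        _write_table(
            pd.DataFrame(vip.bands, columns=["start_cm1", "end_cm1"]),
            out / "vip_bands.csv", header,
        )
        diff = group_mean_difference(pp, case_labels, ["control"])
        _write_table(diff, out / "mean_difference.csv", header)
        lv = full.transform(pp.X)
        _write_table(
            pd.DataFrame(
                {
                    "spectrum_id": pp.spectrum_ids,
                    "subject_id": pp.subject_ids,
                    "class_label": pp.class_labels,
                    "lv1": lv[:, 0],
                    "lv2": lv[:, 1] if lv.shape[1] > 1 else np.zeros(len(lv)),
                }
            ),
            out / "lv_scores.csv", header,
        )
        if truth_bands is not None:
            _write_table(
                pd.DataFrame([(b.start_cm1, b.end_cm1, b.effect) for b in truth_bands],
                             columns=["start_cm1", "end_cm1", "effect"]),
                out / "truth_bands.csv", header,
            )

        summary = {
            "case": config.case,
            "config_hash": config_hash(config),
            "seed": config.seed,
            "n_subjects": {
                "case": int(len({s for s, c in zip(pp.subject_ids, pp.class_labels)
                                 if c in case_labels})),
                "control": int(len({s for s, c in zip(pp.subject_ids, pp.class_labels)
                                    if c == "control"})),
            },
            "n_spectra": int(pp.n_spectra),
            "evaluation_level": report.evaluation_level,
            "mean_accuracy": round(report.mean_accuracy, 6),
            "mean_sensitivity": round(report.mean_sensitivity, 6),
            "mean_specificity": round(report.mean_specificity, 6),
            "mean_auc": round(report.mean_auc, 6),
            "n_components_full_fit": int(A_full),
            "vip_bands": [[float(a), float(b)] for a, b in vip.bands],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out / "config_echo.yaml").write_text(yaml.safe_dump(_config_dict(config), sort_keys=True))
        logger.info("case study complete in %.1fs", time.time() - t0)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
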