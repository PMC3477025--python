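"""End-to-end orchestration: cohort -> summaries -> stability selection ->
leave-one-out evaluation -> report files.

A run executes, under one master seed:

1. cohort acquisition (generate from a spec, or load a CSV);
2. per-feature group summaries (baseline-characteristics table);
3. per-modality leave-one-out AUC, each modality's features as one set;
4. bootstrap stability selection on all modalities excluding CSF (the
   biosignature is derived from the larger CSF-free data set);
5. the AUC-vs-top-T curve;
6. the t-test-ranked top-15 comparison;
7. CSF-subset runs on complete cases: each CSF marker alone, the stable set
   alone, and the stable set plus each CSF marker.

The master seed fans out to per-stage seeds through ``numpy.random.
SeedSequence.spawn``, so stages are reproducible independently of each
other.  Every report embeds the resolved configuration; identical config and
seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import (CohortSpec, FeatureTable, default_cohort_spec,
                     generate_cohort, read_cohort, write_cohort,
                     write_ground_truth)
from .evaluate import auc_vs_topT, loo_scores
from .stability import (StabilityConfig, selection_profile, stable_set,
                        top_features)
from .univariate import rank_by_ttest, summarize_by_group, summary_frame

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_STAGES = ("cohort", "summaries", "modality_auc", "stability", "top_t",
           "ttest_baseline", "csf")


@dataclass
class PipelineConfig:
    """Full-run configuration.

    Exactly one of ``input_path`` (cohort CSV) or ``cohort_spec`` must be
    set.  ``n_top_ttest`` is the size of the univariate-ranking comparison
    set; ``t_max`` bounds the top-T curve.
    """

    output_dir: Path
    seed: int = 0
    input_path: Path | None = None
    cohort_spec: CohortSpec | None = None
    stability: StabilityConfig | None = None
    svm_C: float = 1.0
    t_max: int = 30
    n_top_ttest: int = 15
    run_csf: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort_spec is None):
            raise ValueError("exactly one of input_path / cohort_spec required")
        self.output_dir = Path(self.output_dir)


@dataclass
class ReportBundle:
    """Outputs of a pipeline run, with a manifest of the files written."""

    output_dir: Path
    summaries: object
    modality_auc: dict[str, float]
    profile: object
    stable_features: list[str]
    stable_auc: float
    top_t_curve: object
    ttest_top: list[str]
    ttest_auc: float
    csf_auc: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _spawn_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-stage 31-bit seeds from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config and validate it field by field."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {"output_dir", "seed", "input_path", "cohort", "stability",
             "svm_C", "t_max", "n_top_ttest", "run_csf"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "output_dir" not in raw:
        raise ValueError("config requires output_dir")
    seed = int(raw.get("seed", 0))
    spec = None
    if raw.get("cohort") == "default" or "cohort" not in raw and "input_path" not in raw:
        spec = default_cohort_spec(seed)
    elif isinstance(raw.get("cohort"), dict):
        c = raw["cohort"]
        base = default_cohort_spec(seed)
        spec = CohortSpec(n_nonconverter=int(c.get("n_nonconverter", 177)),
                          n_converter=int(c.get("n_converter", 142)),
                          modalities=base.modalities, seed=seed)
    stab = None
    if isinstance(raw.get("stability"), dict):
        s = raw["stability"]
        kw = {}
        if "n_bootstrap" in s:
            kw["n_bootstrap"] = int(s["n_bootstrap"])
        if "tau" in s:
            kw["tau"] = float(s["tau"])
        if "grid_mode" in s:
            kw["grid_mode"] = str(s["grid_mode"])
        stab = StabilityConfig(seed=seed, **kw)
    return PipelineConfig(
        output_dir=Path(raw["output_dir"]),
        seed=seed,
        input_path=Path(raw["input_path"]) if "input_path" in raw else None,
        cohort_spec=spec,
        stability=stab,
        svm_C=float(raw.get("svm_C", 1.0)),
        t_max=int(raw.get("t_max", 30)),
        n_top_ttest=int(raw.get("n_top_ttest", 15)),
        run_csf=bool(raw.get("run_csf", True)),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, len(_STAGES))
    manifest: dict = {"seed": config.seed, "stage_seeds": dict(zip(_STAGES, seeds)),
                      "stages": {}, "files": []}
    t_start = time.time()

    def _done(stage: str, **extra) -> None:
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t_start, 2),
                                     **extra}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str) + "\n")

    # 1. cohort
    if config.input_path is not None:
        table = read_cohort(config.input_path)
        truth = None
    else:
        spec = config.cohort_spec
        table, truth = generate_cohort(spec)
        write_cohort(table, out / "cohort.csv")
        write_ground_truth(truth, out / "ground_truth.json")
        manifest["files"] += ["cohort.csv", "ground_truth.json"]
    _done("cohort", n_subjects=table.n_subjects, n_features=table.n_features)

    # 2. group summaries
    summaries = summarize_by_group(table)
    sframe = summary_frame(summaries)
    sframe.to_csv(out / "group_summaries.tsv", sep="\t", index=False)
    manifest["files"].append("group_summaries.tsv")
    _done("summaries")

    # 3. per-modality AUC (complete cases per modality)
    modality_auc: dict[str, float] = {}
    for tag in dict.fromkeys(table.modality_tags):
        feats = table.modality_features(tag)
        res = loo_scores(table, feats, C=config.svm_C)
        modality_auc[tag] = res.auc
    with open(out / "modality_auc.tsv", "w") as fh:
        fh.write("modality\tauc\n")
        for k, v in modality_auc.items():
            fh.write(f"{k}\t{v:.6f}\n")
    manifest["files"].append("modality_auc.tsv")
    _done("modality_auc", **{k: round(v, 4) for k, v in modality_auc.items()})

    # 4. stability selection on everything except CSF
    non_csf = table.modality_features(*(t for t in dict.fromkeys(table.modality_tags)
                                        if t != "csf"))
    sub = table.subset_features(non_csf).complete_cases()
    stab_cfg = config.stability or StabilityConfig(seed=seeds[3])
    profile = selection_profile(sub, stab_cfg)
    profile.to_frame().to_csv(out / "stability_profile.tsv", sep="\t", index=False)
    stable = top_features(profile, len(stable_set(profile))) \
        if stable_set(profile) else []
    (out / "stable_set.json").write_text(json.dumps({
        "tau": stab_cfg.tau, "features": stable,
        "scores": {n: profile.score_of(n) for n in stable}}, indent=2) + "\n")
    manifest["files"] += ["stability_profile.tsv", "stable_set.json"]
    stable_res = loo_scores(table, stable, C=config.svm_C) if stable else None
    stable_auc = stable_res.auc if stable_res else float("nan")
    _done("stability", n_stable=len(stable), stable_auc=round(stable_auc, 4))

    # 5. AUC vs top-T curve
    curve = auc_vs_topT(table, profile, t_max=config.t_max, C=config.svm_C)
    curve.to_frame().to_csv(out / "top_t_curve.tsv", sep="\t", index=False)
    manifest["files"].append("top_t_curve.tsv")
    _done("top_t")

    # 6. univariate-ranking baseline on the same CSF-free feature pool
    ranking = rank_by_ttest(sub)
    ttest_top = ranking[:config.n_top_ttest]
    ttest_res = loo_scores(table, ttest_top, C=config.svm_C)
    _done("ttest_baseline", ttest_auc=round(ttest_res.auc, 4))

    # 7. CSF complete-case experiments
    csf_auc: dict[str, float] = {}
    csf_feats = table.modality_features("csf")
    if config.run_csf and csf_feats:
        csf_table = table.complete_cases(csf_feats)
        for f in csf_feats:
            csf_auc[f] = loo_scores(csf_table, [f], C=config.svm_C).auc
        if stable:
            csf_auc["stable_set"] = loo_scores(csf_table, stable,
                                               C=config.svm_C).auc
            for f in csf_feats:
                csf_auc[f"stable_set+{f}"] = loo_scores(
                    csf_table, stable + [f], C=config.svm_C).auc
        with open(out / "csf_auc.tsv", "w") as fh:
            fh.write("feature_set\tauc\n")
            for k, v in csf_auc.items():
                fh.write(f"{k}\t{v:.6f}\n")
        manifest["files"].append("csf_auc.tsv")
    _done("csf")

    manifest["complete"] = True
    manifest["config"] = {
        "seed": config.seed,
        "svm_C": config.svm_C,
        "t_max": config.t_max,
        "n_top_ttest": config.n_top_ttest,
        "stability": {
            "n_bootstrap": stab_cfg.n_bootstrap,
            "tau": stab_cfg.tau,
            "grid_mode": stab_cfg.grid_mode,
            "m": stab_cfg.n_lambdas,
            "seed": stab_cfg.seed,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return ReportBundle(
        output_dir=out,
        summaries=sframe,
        modality_auc=modality_auc,
        profile=profile,
        stable_features=stable,
        stable_auc=stable_auc,
        top_t_curve=curve,
        ttest_top=ttest_top,
        ttest_auc=ttest_res.auc,
        csf_auc=csf_auc,
        manifest=manifest,
    )
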