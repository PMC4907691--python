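"""End-to-end orchestration: simulate -> score -> fit -> analyze -> design.

A single YAML config and master seed determine every stochastic stage
(per-stage seeds are spawned from the master seed), and a manifest
records outputs, seeds, and content hashes so a rerun with the same
config reproduces deterministic stages bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import build_fmri_design, collinearity_report
from .fitting import (CohortSCR, RescorlaWagnerSCR, compare_rho_groups,
                      fit_within_cohort)
from .models import INSTRUCTED, ModelParams, simulate_ev_trace
from .scoring import classify_learner, transform_normalize
from .stats import TwoLevelSCRModel, instructed_reversal_contrast
from .synth import Cohort, GenParams, simulate_cohort
from .task import TaskConfig, generate_trial_sequence, validate_sequence

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic stage derives from ``seed``."""

    seed: int = 0
    n_subjects_per_group: int = 20
    order_seeds: tuple[int, int] = (1, 2)
    task: TaskConfig = field(default_factory=TaskConfig)
    instructed_model: ModelParams = field(
        default_factory=lambda: ModelParams.instructed(0.061, 0.943))
    uninstructed_model: ModelParams = field(
        default_factory=lambda: ModelParams.feedback(0.042))
    gen_overrides: dict = field(default_factory=dict)
    n_restarts: int = 10
    analysis_subset: str = "all"
    tr: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "task" in raw:
            kwargs["task"] = TaskConfig(**raw.pop("task"))
        for key in ("instructed_model", "uninstructed_model"):
            if key in raw:
                kwargs[key] = ModelParams(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class RunManifest:
    version: str
    seed: int
    stages: list[dict]

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "seed": self.seed,
                           "stages": self.stages}, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: list[dict], name: str, seed: int | None,
           outputs: list[Path], t0: float) -> None:
    manifest.append({
        "stage": name,
        "seed": seed,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        "outputs": [{"path": str(p), "sha256": _sha256(p)} for p in outputs],
    })


def _score_cohort(cohort: Cohort) -> tuple[list[np.ndarray], list[bool]]:
    """Normalize amplitude tables and classify learners."""
    normalized, learners = [], []
    for s in cohort.subjects:
        seq = cohort.sequences[s.order]
        us = seq.events["us"].to_numpy().astype(bool)
        scores = np.where(us, s.us_amplitudes, s.amplitudes)
        subj = transform_normalize(scores, us)
        subj.learner = classify_learner(subj, seq)
        normalized.append(subj.normalized)
        learners.append(subj.learner)
    return normalized, learners


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage in order, writing artifacts and a manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s % (2**31 - 1)) for s in root.generate_state(8)]
    stages: list[dict] = []

    # stage 1: task sequences
    t0 = time.perf_counter()
    sequences = [generate_trial_sequence(config.task, seed=s) for s in config.order_seeds]
    outputs = []
    for i, seq in enumerate(sequences, 1):
        report = validate_sequence(seq)
        if not report.ok:
            raise RuntimeError(f"task stage: generated order {i} fails validation:\n{report}")
        ev_tsv, in_tsv = seq.to_tsv()
        p1 = out / f"order{i}_events.tsv"
        p2 = out / f"order{i}_instructions.tsv"
        p1.write_text(ev_tsv)
        p2.write_text(in_tsv)
        outputs += [p1, p2]
    _stage(stages, "task", None, outputs, t0)

    # stage 2: synthetic cohorts
    t0 = time.perf_counter()
    cohorts = {}
    for group, model, seed in (("instructed", config.instructed_model, stage_seeds[0]),
                               ("uninstructed", config.uninstructed_model, stage_seeds[1])):
        gen = GenParams(model=model, n_subjects=config.n_subjects_per_group,
                        seed=seed, **config.gen_overrides)
        cohorts[group] = simulate_cohort(sequences, gen)
    outputs = []
    for group, cohort in cohorts.items():
        p = out / f"cohort_{group}_manifest.yaml"
        p.write_text(yaml.safe_dump(cohort.manifest(), sort_keys=False))
        outputs.append(p)
        for s in cohort.subjects:
            ps = out / f"amps_{s.subject_id}.tsv"
            ps.write_text(s.to_tsv())
            outputs.append(ps)
    _stage(stages, "simulate_cohort", stage_seeds[0], outputs, t0)

    # stage 3: scoring (normalization + learner classification)
    t0 = time.perf_counter()
    scored = {}
    outputs = []
    for group, cohort in cohorts.items():
        normalized, learners = _score_cohort(cohort)
        scored[group] = (normalized, learners)
        p = out / f"scores_{group}.tsv"
        rows = ["subject\tlearner"]
        rows += [f"{s.subject_id}\t{int(l)}"
                 for s, l in zip(cohort.subjects, learners)]
        p.write_text("\n".join(rows) + "\n")
        outputs.append(p)
    _stage(stages, "score", None, outputs, t0)

    # stage 4: across-subjects fits (learners only, mirroring the study)
    t0 = time.perf_counter()
    fits = {}
    for group, cohort in cohorts.items():
        normalized, learners = scored[group]
        idx = [i for i, l in enumerate(learners) if l] or list(range(len(cohort)))
        data = CohortSCR(
            sequences=cohorts[group].sequences,
            responses=[normalized[i] for i in idx],
            orders=[cohort.subjects[i].order for i in idx],
            subject_ids=[cohort.subjects[i].subject_id for i in idx],
        )
        variant = INSTRUCTED if group == "instructed" else "feedback"
        est = RescorlaWagnerSCR(variant=variant, n_restarts=config.n_restarts,
                                restart_seed=stage_seeds[2]).fit(data)
        fits[group] = (est, data, idx)
    p = out / "fit_across.json"
    p.write_text(json.dumps({
        g: {"alpha": est.alpha_, "rho": est.rho_, "sse": est.sse_,
            "deviance": est.deviance_, "n_subjects": est.n_subjects_,
            "n_learners": len(idx), "per_subject": est.coef_.tolist()}
        for g, (est, _, idx) in fits.items()}, indent=2))
    _stage(stages, "fit_across", stage_seeds[2], [p], t0)

    # stage 5: within-subject fits and group comparison of rho
    t0 = time.perf_counter()
    within = {}
    for group, (est, data, idx) in fits.items():
        results = fit_within_cohort(data, variant=INSTRUCTED,
                                    n_restarts=config.n_restarts,
                                    restart_seed=stage_seeds[3])
        within[group] = np.array([r.rho for r in results])
    comp = compare_rho_groups(within["instructed"], within["uninstructed"])
    p = out / "fit_within.json"
    p.write_text(json.dumps({
        "rho_by_group": {g: v.tolist() for g, v in within.items()},
        "group_comparison": asdict(comp)}, indent=2))
    _stage(stages, "fit_within", stage_seeds[3], [p], t0)

    # stage 6: behavioral two-level model + instructed reversal contrast
    t0 = time.perf_counter()
    seqs, resp, grps = [], [], []
    for group, cohort in cohorts.items():
        normalized, learners = scored[group]
        for i, l in enumerate(learners):
            if l:
                seqs.append(cohort.sequences[cohort.subjects[i].order])
                resp.append(normalized[i])
                grps.append(group)
    model = TwoLevelSCRModel(subset=config.analysis_subset).fit(seqs, resp, grps)
    inst_resp = [r for r, g in zip(resp, grps) if g == "instructed"]
    inst_seqs = [s for s, g in zip(seqs, grps) if g == "instructed"]
    contrast = instructed_reversal_contrast(inst_resp, inst_seqs)
    p1 = out / "behavioral_stats.tsv"
    p1.write_text(model.second_level_.to_csv(sep="\t", index=False))
    p2 = out / "reversal_contrast.json"
    p2.write_text(json.dumps({
        "estimate": contrast.estimate, "t": contrast.t_stat, "df": contrast.df,
        "p": contrast.p_value, "per_subject": contrast.per_subject.tolist()}, indent=2))
    _stage(stages, "behavioral_stats", None, [p1, p2], t0)

    # stage 7: fMRI design matrices with dual EV modulators
    t0 = time.perf_counter()
    outputs = []
    for i, seq in enumerate(sequences, 1):
        traces = {
            "instructed": simulate_ev_trace(seq, fits["instructed"][0].params_),
            "feedback": simulate_ev_trace(seq, fits["uninstructed"][0].params_),
        }
        dm = build_fmri_design(seq, traces, tr=config.tr, include_shock_pe=True)
        report = collinearity_report(dm)
        p1 = out / f"design_order{i}.tsv"
        p1.write_text(dm.to_tsv())
        p2 = out / f"design_order{i}_collinearity.json"
        p2.write_text(json.dumps({
            "rank": report.modulator_rank, "n_modulators": report.n_modulators,
            "rank_deficient": report.rank_deficient, "flags": report.flags}, indent=2))
        outputs += [p1, p2]
    _stage(stages, "fmri_design", None, outputs, t0)

    manifest = RunManifest(version=__version__, seed=config.seed, stages=stages)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
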