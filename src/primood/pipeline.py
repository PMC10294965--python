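"""End-to-end orchestration: simulate -> train -> evaluate -> score -> attribute.

The demo-scale study runs 8 healthy subjects (LOSO: 8 versions per
architecture) and 9 impaired subjects at impairment theta in
{0.2, 0.5, 0.8} (3 each), scoring impaired subjects with K = 3 sampled
versions.  All stages run in memory; ``run_stages_to_dir`` additionally
materializes the stage outputs (CSV/JSON) carrying a config hash so that
mismatched stage outputs refuse to chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import confidence as conf
from . import seq_metrics as sm
from .attribution import attribution_for_subject, group_profile
from .loso import LOSORun, run_loso
from .models import ModelConfig
from .schema import SubjectMeta, build_channel_schema, impairment_category
from .synth import SynthConfig, simulate_dataset
from .windows import DEFAULT_STRIDE, make_windows

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_metrics",
           "confidence_stage", "attribution_stage", "config_hash", "make_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    seq2seq: ModelConfig = field(default_factory=lambda: ModelConfig(arch="seq2seq",
                                                                     epochs=28))
    asrf: ModelConfig = field(default_factory=lambda: ModelConfig(arch="asrf"))
    archs: tuple[str, ...] = ("seq2seq", "asrf")
    stride: int = DEFAULT_STRIDE
    k_versions: int = 3
    n_perm: int = 999
    attribution_windows_per_subject: int = 2
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, synth=replace(self.synth, seed=seed),
                       seq2seq=replace(self.seq2seq, seed=seed),
                       asrf=replace(self.asrf, seed=seed))

    def model_config(self, arch: str) -> ModelConfig:
        return self.seq2seq if arch == "seq2seq" else self.asrf


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ----------------------------------------------------------------- evaluate

def _window_sequences(predictions: pd.DataFrame):
    """Yield (subject, version, pred sequence, gt sequence) per window."""
    keys = ["subject_id", "version_id", "trial_id", "window_start"]
    for (sid, vid, _, _), grp in predictions.groupby(keys, sort=True):
        grp = grp.sort_values("token_index")
        pred = grp["predicted_label"].tolist()
        gt = grp["ground_truth_sequence"].iloc[0].split("|")
        yield sid, vid, pred, gt


def evaluate_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-subject micro-averaged edit metrics (counts pooled, then rates)."""
    per_subject: dict[str, list[sm.EditCounts]] = {}
    groups: dict[str, str] = dict(zip(predictions["subject_id"], predictions["group"]))
    for sid, _, pred, gt in _window_sequences(predictions):
        per_subject.setdefault(sid, []).append(sm.edit_counts(pred, gt))
    rows = []
    for sid, counts in sorted(per_subject.items()):
        c = sm.aggregate_counts(counts)
        t, f = sm.tpr(c), sm.fdr(c)
        rows.append(dict(subject_id=sid, group=groups[sid], n_pred=c.n_pred,
                         n_gt=c.n_gt, deletions=c.deletions, insertions=c.insertions,
                         substitutions=c.substitutions, fdr=f, tpr=t,
                         f1=sm.f1(t, f)))
    return pd.DataFrame(rows)


def group_f1(metrics: pd.DataFrame, group: str) -> float:
    """Micro-averaged F1 over all subjects of a group."""
    sub = metrics[metrics["group"] == group]
    c = sm.EditCounts(int(sub["deletions"].sum()), int(sub["insertions"].sum()),
                      int(sub["substitutions"].sum()), int(sub["n_pred"].sum()),
                      int(sub["n_gt"].sum()))
    return sm.f1(sm.tpr(c), sm.fdr(c))


# -------------------------------------------------------------------- score

def confidence_stage(predictions: pd.DataFrame, metas: list[SubjectMeta],
                     thetas: dict[str, float], n_perm: int = 999,
                     seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-subject confidence summaries and the cohort-level statistics."""
    healthy_ids = sorted(m.subject_id for m in metas if m.group == "healthy")
    impaired_ids = sorted(m.subject_id for m in metas if m.group == "impaired")
    meta_by_id = {m.subject_id: m for m in metas}

    clusters = {sid: conf.pool_motion_probabilities(predictions, sid)
                for sid in healthy_ids + impaired_ids}
    n_empty = sum(c.is_empty for c in clusters.values())
    if n_empty:
        log.warning("%d empty probability clusters excluded", n_empty)
    healthy_ref = np.concatenate([clusters[s].values for s in healthy_ids
                                  if not clusters[s].is_empty])

    rows = []
    for sid in healthy_ids + impaired_ids:
        cl = clusters[sid]
        if cl.is_empty or cl.values.size < 3:
            continue
        mean, sd = conf.gaussian_summary(cl)
        loc, scale = conf.cauchy_summary(cl)
        m = meta_by_id[sid]
        rows.append(dict(subject_id=sid, group=m.group, theta=thetas[sid],
                         impairment_score=m.impairment_score, category=m.category,
                         n=cl.values.size, mean=mean, sd=sd, cauchy_location=loc,
                         cauchy_scale=scale, cauchy_iqr=2.0 * scale,
                         wasserstein_to_healthy=conf.wasserstein_1d(cl.values, healthy_ref)))
    summaries = pd.DataFrame(rows)

    imp = summaries[summaries["group"] == "impaired"].reset_index(drop=True)
    if len(imp) >= 3:
        g = conf.pc1_scores(imp["mean"], imp["sd"])
        c = conf.pc1_scores(imp["cauchy_location"], imp["cauchy_iqr"])
        summaries.loc[summaries["group"] == "impaired", "pc1_mean_sd"] = g.scores
        summaries.loc[summaries["group"] == "impaired", "pc1_median_iqr"] = c.scores
        imp = summaries[summaries["group"] == "impaired"].reset_index(drop=True)

    healthy_means = summaries.loc[summaries["group"] == "healthy", "mean"].to_numpy()
    impaired_means = imp["mean"].to_numpy()
    if healthy_means.size >= 3 and impaired_means.size >= 3:
        obs, p = conf.group_difference_test(healthy_means, impaired_means,
                                            n_perm=n_perm, seed=seed)
    else:
        log.warning("group test skipped: fewer than 3 subjects in a group")
        obs, p = float("nan"), float("nan")

    def pooled_mean(sids):
        vals = np.concatenate([clusters[s].values for s in sids
                               if not clusters[s].is_empty])
        return float(vals.mean())

    level_means = {}
    level_wasserstein = {}
    for theta in sorted({thetas[s] for s in impaired_ids}):
        sids = [s for s in impaired_ids if thetas[s] == theta]
        level_means[theta] = pooled_mean(sids)
        lvl = imp[imp["theta"] == theta]["wasserstein_to_healthy"]
        level_wasserstein[theta] = float(lvl.mean())
    category_means = {}
    for cat in ("mild", "moderate", "severe"):
        sids = [s for s in impaired_ids if meta_by_id[s].category == cat]
        if sids:
            category_means[cat] = pooled_mean(sids)

    spearman = {}
    scores = imp["impairment_score"].to_numpy()
    for col in ("mean", "cauchy_location", "pc1_mean_sd", "pc1_median_iqr",
                "wasserstein_to_healthy"):
        if col in imp and len(imp) >= 5:
            try:
                spearman[col] = conf.spearman_with_impairment(imp[col], scores)
            except ValueError:
                spearman[col] = (float("nan"), float("nan"))

    stats_report = dict(
        healthy_mean_confidence=pooled_mean(healthy_ids),
        impaired_mean_confidence=pooled_mean(impaired_ids),
        group_test=dict(observed_difference=obs, p=p,
                        n_healthy=int(healthy_means.size),
                        n_impaired=int(impaired_means.size), n_perm=n_perm),
        level_means=level_means,
        level_wasserstein_means=level_wasserstein,
        category_means=category_means,
        spearman={k: dict(rho=v[0], p=v[1]) for k, v in spearman.items()},
        n_empty_clusters=int(n_empty),
    )
    return summaries, stats_report


# -------------------------------------------------------------- attribution

def attribution_stage(run: LOSORun, impaired_windows: dict, sides: dict[str, str],
                      windows_per_subject: int = 2, seed: int = 0) -> dict:
    """Per-subject attribution profiles plus group ranking and localization."""
    version_id = run.impaired_version_ids[0]
    model = run.versions[version_id]
    profiles = []
    per_subject = []
    for i, sid in enumerate(sorted(impaired_windows)):
        prof = attribution_for_subject(model, sid, impaired_windows[sid],
                                       max_windows=windows_per_subject,
                                       seed=seed + i)
        profiles.append(prof)
        schema = build_channel_schema(sides[sid])
        moving = float(prof.contributions[schema.indices(side_tag="moving_ue")].sum())
        trunk = float(prof.contributions[schema.indices(side_tag="trunk")].sum())
        contra = float(prof.contributions[schema.indices(side_tag="contralateral_ue")].sum())
        per_subject.append(dict(subject_id=sid, moving_ue=moving, trunk=trunk,
                                contralateral_ue=contra,
                                total=float(prof.contributions.sum())))
    # group ranking in the frame of the most common moving side
    side_counts = pd.Series(list(sides.values())).value_counts()
    schema = build_channel_schema(side_counts.index[0])
    avg, ranked = group_profile(profiles, schema)
    return dict(profiles=profiles, per_subject=pd.DataFrame(per_subject),
                group=avg, ranked=ranked)


# ---------------------------------------------------------------- full run

def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Execute the complete study; returns every stage's in-memory outputs."""
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg = cfg.with_seed(seed)
    metas, recs, thetas = simulate_dataset(cfg.synth)
    log.info("simulated %d subjects", len(metas))

    healthy_windows, impaired_windows, sides = {}, {}, {}
    for m in metas:
        wins = [w for r in recs[m.subject_id] for w in make_windows(r, cfg.stride)]
        if m.group == "healthy":
            healthy_windows[m.subject_id] = wins
        else:
            impaired_windows[m.subject_id] = wins
            sides[m.subject_id] = recs[m.subject_id][0].side

    schema_hash = config_hash(cfg)
    results: dict = dict(config=cfg, config_hash=schema_hash, metas=metas,
                         thetas=thetas, sides=sides,
                         healthy_windows=healthy_windows,
                         impaired_windows=impaired_windows)
    for arch in cfg.archs:
        run = run_loso(healthy_windows, impaired_windows, cfg.model_config(arch),
                       k_versions_for_impaired=cfg.k_versions, seed=cfg.seed,
                       schema_hash=schema_hash)
        metrics = evaluate_metrics(run.predictions)
        summaries, stats_report = confidence_stage(
            run.predictions, metas, thetas, n_perm=cfg.n_perm, seed=cfg.seed)
        attrib = attribution_stage(run, impaired_windows, sides,
                                   windows_per_subject=cfg.attribution_windows_per_subject,
                                   seed=cfg.seed)
        results[arch] = dict(run=run, predictions=run.predictions, metrics=metrics,
                             healthy_f1=group_f1(metrics, "healthy"),
                             impaired_f1=group_f1(metrics, "impaired"),
                             summaries=summaries, stats=stats_report,
                             attribution=attrib)
        log.info("[%s] healthy F1=%.3f impaired F1=%.3f", arch,
                 results[arch]["healthy_f1"], results[arch]["impaired_f1"])
    return results


# ------------------------------------------------------------------- report

def make_report(results: dict) -> str:
    """Single markdown report: F1 table, category confidence, correlations, channels."""
    lines = ["# Movement-abnormality OOD report", ""]
    lines.append("## Classification performance (micro F1)")
    lines.append("| model | healthy | impaired |")
    lines.append("|---|---|---|")
    for arch in results["config"].archs:
        r = results.get(arch)
        if r is None:
            lines.append(f"| {arch} | (absent) | (absent) |")
            continue
        lines.append(f"| {arch} | {r['healthy_f1']:.3f} | {r['impaired_f1']:.3f} |")
    lines.append("")
    for arch in results["config"].archs:
        r = results.get(arch)
        if r is None:
            lines.append(f"## {arch}: missing stage outputs\n")
            continue
        st = r["stats"]
        lines.append(f"## {arch}: confidence by impairment level")
        lines.append(f"- healthy pooled mean confidence: {st['healthy_mean_confidence']:.3f}")
        lines.append(f"- impaired pooled mean confidence: {st['impaired_mean_confidence']:.3f} "
                     f"(permutation p = {st['group_test']['p']:.4g})")
        for theta, m in st["level_means"].items():
            lines.append(f"- theta {theta}: mean confidence {m:.3f}, "
                         f"Wasserstein-to-healthy {st['level_wasserstein_means'][theta]:.3f}")
        lines.append("")
        lines.append(f"## {arch}: Spearman correlation with impairment score")
        for k, v in st["spearman"].items():
            lines.append(f"- {k}: rho = {v['rho']:+.3f} (p = {v['p']:.3g})")
        lines.append("")
        att = r.get("attribution")
        if att is None:
            lines.append(f"## {arch}: attribution (absent)\n")
        else:
            lines.append(f"## {arch}: top channels driving confidence")
            for name, tag, contrib in att["ranked"][:8]:
                lines.append(f"- {name} [{tag}]: {100 * contrib:.2f}% of gradient")
            lines.append("")
    return "\n".join(lines)
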