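"""End-to-end orchestration: preprocess -> reference -> scoring -> metrics ->
population PCA -> statistics -> report.

Failures are per-subject, not run-fatal: a subject whose recording cannot be
preprocessed is reported with an error note and the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import core, population, stats
from .config import RunConfig
from .errors import KScoreError, ParameterError
from .frame import normalize_frame
from .io import ManifestEntry, SubjectMeta, TrialRecording, read_trial
from .metrics import isolated_metrics
from .preprocess import (
    MotionMatrix,
    Repetition,
    butterworth_filter,
    drop_first_repetition,
    normalize_time,
    restrict_columns,
    segment_repetitions,
    standardize,
)

logger = logging.getLogger(__name__)


@dataclass
class PreparedSubject:
    meta: SubjectMeta
    repetitions: list[Repetition]  # filtered, frame-normalized, first rep dropped
    matrices: list[MotionMatrix]  # standardized, one per repetition


def load_subjects(entries: list[ManifestEntry]) -> list[tuple[SubjectMeta, TrialRecording]]:
    return [
        (e.meta, read_trial(e.trial_path, subject_id=e.meta.subject_id)) for e in entries
    ]


def prepare_subject(
    meta: SubjectMeta,
    rec: TrialRecording,
    config: RunConfig = RunConfig(),
    pre_hook=None,
) -> PreparedSubject:
    """Filter, frame-normalize, segment, drop rep 1, resample and standardize.

    ``pre_hook`` is an optional ``TrialRecording -> TrialRecording`` cleanup
    (e.g. an external biomechanical-constraints correction) applied before
    filtering; the default is the identity.
    """
    if pre_hook is not None:
        rec = pre_hook(rec)
    rec = butterworth_filter(rec, config.filter.cutoff_hz, config.filter.order)
    rec = normalize_frame(rec, config.frame_mode)
    reps = drop_first_repetition(segment_repetitions(rec, config.segmentation))
    if not reps:
        raise ParameterError(f"{meta.subject_id}: no analyzable repetitions")
    matrices = [standardize(normalize_time(r, config.grid_size)) for r in reps]
    return PreparedSubject(meta=meta, repetitions=reps, matrices=matrices)


def _shared_columns(prepared: list[PreparedSubject]) -> list[str]:
    """Intersection of retained channels, in canonical order."""
    shared: set[str] | None = None
    for p in prepared:
        for m in p.matrices:
            cols = set(m.column_labels)
            shared = cols if shared is None else shared & cols
    if not shared:
        raise ParameterError("no channels shared by all subjects")
    order = prepared[0].matrices[0].column_labels
    return [c for c in order if c in shared]


def _subject_pcas(p: PreparedSubject, columns: list[str]) -> list[core.SubjectPCA]:
    return [core.subject_pca(restrict_columns(m, columns)) for m in p.matrices]


def fit_reference(
    controls: list[PreparedSubject], config: RunConfig = RunConfig()
) -> core.ControlReference:
    if len(controls) < 2:
        raise ParameterError("need at least 2 control subjects to build a reference")
    columns = _shared_columns(controls)
    reps = [_subject_pcas(p, columns) for p in controls]
    return core.build_control_reference(
        reps,
        alpha_target=config.alpha_target,
        gpa_tol=config.gpa_tol,
        gpa_max_iter=config.gpa_max_iter,
    )


def score_prepared(
    p: PreparedSubject, ref: core.ControlReference
) -> core.KScoreResult:
    return core.score_subject(_subject_pcas(p, ref.column_labels), ref)


def run_scoring(
    subjects: list[tuple[SubjectMeta, TrialRecording]],
    config: RunConfig = RunConfig(),
    reference: core.ControlReference | None = None,
) -> tuple[pd.DataFrame, core.ControlReference]:
    """Score every subject; fit the control reference first unless given one.

    Returns one row per subject (k_score, deviation_factor, transition time,
    time ratio, repetitions used, error note if the subject failed) plus the
    reference used. Deterministic given config + inputs.
    """
    prepared: dict[str, PreparedSubject] = {}
    failures: dict[str, str] = {}
    for meta, rec in subjects:
        try:
            prepared[meta.subject_id] = prepare_subject(meta, rec, config)
        except KScoreError as exc:
            failures[meta.subject_id] = str(exc)
            logger.warning("subject %s failed preprocessing: %s", meta.subject_id, exc)

    if reference is None:
        controls = [p for p in prepared.values() if p.meta.group == "CTRL"]
        if len(controls) < 2:
            raise ParameterError(
                f"need >= 2 CTRL subjects to fit a reference, got {len(controls)}"
            )
        reference = fit_reference(controls, config)

    rows = []
    for meta, _ in subjects:
        sid = meta.subject_id
        base = {"subject_id": sid, "group": meta.group}
        if sid in failures:
            rows.append({**base, "k_score": np.nan, "error": failures[sid]})
            continue
        try:
            res = score_prepared(prepared[sid], reference)
        except KScoreError as exc:
            rows.append({**base, "k_score": np.nan, "error": str(exc)})
            continue
        rows.append(
            {
                **base,
                "k_score": res.k_score,
                "deviation_factor": res.deviation_factor,
                "mean_transition_time": res.transition_time,
                "time_ratio": res.time_ratio,
                "n_reps": res.n_reps,
                "error": "",
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.provenance_hash
    return df, reference


def export_profiles(
    subjects: list[tuple[SubjectMeta, TrialRecording]],
    reference: core.ControlReference,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Per-subject K-Profile curves (long format: subject, percent, value)
    for external plotting; the control mean profile is included under the
    pseudo-subject id ``__control_mean__``."""
    rows = [
        pd.DataFrame(
            {"subject_id": "__control_mean__", "percent": reference.time_grid,
             "value": reference.mean_profile}
        )
    ]
    for meta, rec in subjects:
        try:
            p = prepare_subject(meta, rec, config)
            profile, _ = core.subject_profile(
                _subject_pcas(p, reference.column_labels), reference.consensus_scores
            )
        except KScoreError as exc:
            logger.warning("profile export: skipping %s (%s)", meta.subject_id, exc)
            continue
        rows.append(
            pd.DataFrame(
                {"subject_id": meta.subject_id, "percent": profile.time_grid,
                 "value": profile.values}
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_metrics(
    subjects: list[tuple[SubjectMeta, TrialRecording]], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    rows = []
    for meta, rec in subjects:
        try:
            p = prepare_subject(meta, rec, config)
            m = isolated_metrics(p.repetitions, height=meta.height)
            rows.append({"subject_id": meta.subject_id, "group": meta.group,
                         **{k: v for k, v in asdict(m).items() if k != "subject_id"},
                         "error": ""})
        except KScoreError as exc:
            rows.append({"subject_id": meta.subject_id, "group": meta.group, "error": str(exc)})
    return pd.DataFrame(rows)


def run_popca(
    subjects: list[tuple[SubjectMeta, TrialRecording]],
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, population.PopulationPCAModel]:
    """Across-patient PCA baseline: one row of retained PC scores per repetition."""
    prepared = []
    for meta, rec in subjects:
        try:
            prepared.append(prepare_subject(meta, rec, config))
        except KScoreError as exc:
            logger.warning("popca: skipping %s (%s)", meta.subject_id, exc)
    raw = {
        p.meta.subject_id: [normalize_time(r, config.grid_size) for r in p.repetitions]
        for p in prepared
    }
    control_first = [
        ms[0] for p in prepared if p.meta.group == "CTRL" for ms in [raw[p.meta.subject_id]]
    ]
    if not control_first:
        raise ParameterError("popca needs at least one CTRL subject for the reference pose")
    ref_pose = population.reference_pose(control_first)
    rows, index, groups = [], [], []
    for p in prepared:
        for m in raw[p.meta.subject_id]:
            aligned = population.frame_procrustes_align(m, ref_pose)
            rows.append(population.vectorize(aligned))
            index.append((p.meta.subject_id, m.repetition_index))
            groups.append(p.meta.group)
    model = population.PopulationPCAModel(retention=config.retention).fit(np.array(rows))
    df = pd.DataFrame(
        model.scores_, columns=[f"PC{i + 1}" for i in range(model.n_components_)]
    )
    df.insert(0, "subject_id", [i[0] for i in index])
    df.insert(1, "repetition", [i[1] for i in index])
    df.insert(2, "group", groups)
    return df, model


_SCORE_MEASURES = ["k_score"]
_METRIC_MEASURES = [
    "max_torso_flexion_deg",
    "peak_sva_norm",
    "max_sup_vel_norm",
    "max_ant_vel_norm",
    "max_sup_acc_norm",
    "max_ant_acc_norm",
]


def run_stats(
    scores: pd.DataFrame,
    metrics: pd.DataFrame | None,
    manifest: list[SubjectMeta],
    pcs: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Statistical battery: per-measure group comparisons (control listed
    first so a positive rank-biserial means controls larger), regressions of
    each measure on age/BMI/height, and a sex comparison within measures."""
    meta_df = pd.DataFrame(
        [
            {"subject_id": m.subject_id, "sex": m.sex, "age": m.age,
             "height_m": m.height, "bmi": m.bmi}
            for m in manifest
        ]
    )
    tables = [scores[["subject_id", "group"] + [c for c in _SCORE_MEASURES if c in scores]]]
    if metrics is not None and not metrics.empty:
        tables.append(metrics[["subject_id"] + [c for c in _METRIC_MEASURES if c in metrics]])
    merged = tables[0]
    for t in tables[1:]:
        merged = merged.merge(t, on="subject_id", how="inner")
    if pcs is not None and not pcs.empty:
        pc_cols = [c for c in pcs.columns if c.startswith("PC")]
        per_subject = pcs.groupby("subject_id", as_index=False)[pc_cols].mean()
        merged = merged.merge(per_subject, on="subject_id", how="left")
    no_meta = sorted(set(merged.subject_id) - set(meta_df.subject_id))
    if no_meta:
        raise ParameterError(f"subjects missing from the manifest: {no_meta}")
    missing = sorted(set(meta_df.subject_id) - set(merged.subject_id))
    merged = merged.merge(meta_df, on="subject_id", how="inner")
    merged = merged.dropna(subset=["k_score"])

    measures = [c for c in merged.columns
                if c in _SCORE_MEASURES + _METRIC_MEASURES or c.startswith("PC")]
    comparisons = []
    for meas in measures:
        samples = {
            g: sub[meas].dropna().to_numpy()
            for g, sub in merged.groupby("group")
        }
        ordered = {g: samples[g] for g in ("CTRL", "PATIENT") if g in samples}
        if len(ordered) < 2 or any(v.size == 0 for v in ordered.values()):
            continue
        comparisons.append(asdict(stats.compare_groups(meas, ordered)))

    regressions = []
    for meas in measures:
        for cov in ("age", "bmi", "height_m"):
            sub = merged[[meas, cov]].dropna()
            if len(sub) < 3 or sub[cov].nunique() < 2:
                continue
            r2, p, slope, intercept = stats.simple_linreg(
                sub[cov].to_numpy(), sub[meas].to_numpy()
            )
            regressions.append(
                {"measure": meas, "covariate": cov, "r2": r2, "p_value": p,
                 "slope": slope, "intercept": intercept}
            )

    sex_tests = []
    for meas in measures:
        groups = {
            s: sub[meas].dropna().to_numpy()
            for s, sub in merged.groupby("sex")
            if sub[meas].notna().sum() > 0 and s in ("F", "M")
        }
        if len(groups) == 2 and all(v.size >= 1 for v in groups.values()):
            h, p = stats.kruskal_wallis(*groups.values())
            sex_tests.append({"measure": meas, "h": h, "p_value": p})

    return {
        "comparisons": comparisons,
        "regressions": regressions,
        "sex": sex_tests,
        "unmatched_subjects": missing,
        "config_hash": config.provenance_hash,
    }


def run_report(stats_doc: dict) -> str:
    """Summary tables (median/IQR per group, H, p, r_s, robust CV, then the
    demographic regression table) as a markdown document."""
    lines = ["# Cohort summary", "", "## Group comparisons", ""]
    lines.append("| measure | " + " | ".join(
        f"{g} median (IQR)" for g in ("CTRL", "PATIENT")) + " | H | p | r_s | CV% |")
    lines.append("|" + "---|" * 7)
    for c in stats_doc["comparisons"]:
        med = " | ".join(
            f"{m:.3f} ({q:.3f})" for m, q in zip(c["medians"], c["iqrs"])
        )
        cvs = "/".join("-" if v is None else f"{v:.1f}" for v in c["robust_cv"])
        rs = "-" if c["rank_biserial"] is None else f"{c['rank_biserial']:.2f}"
        lines.append(
            f"| {c['measure']} | {med} | {c['h_statistic']:.3f} | "
            f"{c['p_value']:.3g} | {rs} | {cvs} |"
        )
    lines += ["", "## Demographic regressions", ""]
    lines.append("| measure | covariate | R2 | p | slope |")
    lines.append("|" + "---|" * 5)
    for r in stats_doc["regressions"]:
        lines.append(
            f"| {r['measure']} | {r['covariate']} | {r['r2']:.4f} | "
            f"{r['p_value']:.3g} | {r['slope']:.4g} |"
        )
    if stats_doc.get("sex"):
        lines += ["", "## Sex comparisons", "", "| measure | H | p |", "|---|---|---|"]
        for s in stats_doc["sex"]:
            lines.append(f"| {s['measure']} | {s['h']:.3f} | {s['p_value']:.3g} |")
    if stats_doc.get("unmatched_subjects"):
        lines += ["", f"Unmatched subject ids: {', '.join(stats_doc['unmatched_subjects'])}"]
    lines += ["", f"config hash: {stats_doc.get('config_hash', '')}"]
    return "\n".join(lines) + "\n"
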