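"""End-to-end analysis orchestration.

Wires the stages together: per-participant measures from the production
and identification tables, cohort screening, Table-1-style descriptives,
and the three perception-production correlations.  Every run writes a
machine-readable record (config snapshot, input digests, counts,
exclusion audit trail) sufficient to re-run the deterministic analysis
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as coh
from .config import AnalysisConfig, MEASURE_COLUMNS
from .errors import SampleSizeError, VowelspaceError
from .perception import PsychometricLogistic
from .preprocessing import flag_window_overlap, WindowSpec
from .production import ProductionProfile

__all__ = ["compute_participant_measures", "analyze_cohort", "AnalysisResult",
           "write_analysis_outputs", "render_report"]


@dataclass
class AnalysisResult:
    """All outputs of one analysis run."""

    measures: pd.DataFrame            # per-participant, all computed participants
    cohort_table: pd.DataFrame        # measures + included flag + reasons
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    normality: pd.DataFrame
    incomplete: pd.DataFrame          # participants skipped, with reasons
    counts: dict = field(default_factory=dict)


def compute_participant_measures(production: pd.DataFrame,
                                 identification: pd.DataFrame,
                                 config: AnalysisConfig = AnalysisConfig()):
    """Per-participant measures from validated production + identification tables.

    A participant missing from either table, or whose data defeat a
    stage (degenerate fit, too few tokens), is reported in the returned
    ``incomplete`` frame with the stage and reason — never silently
    dropped.  Returns ``(measures, incomplete)``.
    """
    prod_ids = set(production["participant_id"])
    ident_ids = set(identification["participant_id"])
    all_ids = sorted(prod_ids | ident_ids)

    spec = WindowSpec(initial_ms=config.initial_window_ms,
                      midpoint_fraction=config.midpoint_fraction)
    rows, problems = [], []
    for pid in all_ids:
        if pid not in prod_ids:
            problems.append({"participant_id": pid, "stage": "input",
                             "reason": "missing from production table"})
            continue
        if pid not in ident_ids:
            problems.append({"participant_id": pid, "stage": "input",
                             "reason": "missing from identification table"})
            continue
        tokens = production.loc[production["participant_id"] == pid]
        trials = identification.loc[identification["participant_id"] == pid]
        try:
            est = PsychometricLogistic(n_steps=config.n_steps)
            est.fit(trials["step"].to_numpy(dtype=float),
                    trials["response"].to_numpy())
            prof = ProductionProfile(coverage=config.ellipse_coverage).fit(tokens)
        except VowelspaceError as exc:
            problems.append({"participant_id": pid, "stage": "measures",
                             "reason": str(exc)})
            continue
        valid = tokens.loc[~tokens["excluded"].astype(bool)]
        eh = valid.loc[valid["vowel"] == "EH", "duration_ms"]
        rows.append({
            "participant_id": pid,
            "labeling_consistency": est.width_,
            "log_contrast_distance": prof.log_contrast_distance_,
            "log_ellipse_area": prof.log_ellipse_area_,
            "centering_ratio": prof.centering_ratio_,
            "boundary": est.boundary_,
            "fit_converged": est.converged_,
            "n_tokens_excluded": prof.n_excluded_,
            "short_duration_flag": bool(len(eh) and eh.mean() < config.overlap_duration_ms),
            "window_overlap_flag": bool(len(eh) and
                                        flag_window_overlap(float(eh.mean()), spec)),
        })
    measures = pd.DataFrame(rows)
    incomplete = pd.DataFrame(problems, columns=["participant_id", "stage", "reason"])
    return measures, incomplete


def analyze_cohort(production: pd.DataFrame, identification: pd.DataFrame,
                   config: AnalysisConfig = AnalysisConfig()) -> AnalysisResult:
    """Full pipeline: measures -> normality -> MAD screen -> descriptives -> correlations."""
    measures, incomplete = compute_participant_measures(production, identification, config)
    if len(measures) < 4:
        raise SampleSizeError(
            f"only {len(measures)} participants with complete measures; need >= 4")

    normality = coh.normality_report(measures)
    cohort_table = coh.mad_outlier_filter(
        measures, variables=config.mad_variables, k=config.mad_k,
        consistency_constant=config.mad_consistency_constant)
    descriptives = coh.descriptive_stats(cohort_table)
    correlations = coh.correlations_to_frame(coh.run_correlation_suite(cohort_table))

    n_total = int(production["participant_id"].nunique())
    counts = {
        "n_participants_input": n_total,
        "n_participants_measured": int(len(measures)),
        "n_participants_incomplete": int(len(incomplete)),
        "n_participants_included": int(cohort_table["included"].sum()),
        "n_participants_mad_excluded": int((~cohort_table["included"]).sum()),
        "n_tokens_read": int(len(production)),
        "n_tokens_excluded": int(production["excluded"].sum())
        if "excluded" in production.columns else 0,
        "mad_exclusions_by_variable": {
            v: int(cohort_table["exclusion_reasons"].str.contains(v, regex=False).sum())
            for v in config.mad_variables},
    }
    return AnalysisResult(measures=measures, cohort_table=cohort_table,
                          descriptives=descriptives, correlations=correlations,
                          normality=normality, incomplete=incomplete, counts=counts)


# --------------------------------------------------------------------
# run records and reports


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_analysis_outputs(result: AnalysisResult, outdir: str | Path,
                           config: AnalysisConfig,
                           input_paths: dict[str, str | Path] | None = None) -> dict:
    """Write all result tables plus the run record under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measures": outdir / "participant_measures.csv",
        "cohort": outdir / "cohort_screened.csv",
        "descriptives": outdir / "descriptives.csv",
        "correlations": outdir / "correlations.csv",
        "normality": outdir / "normality.csv",
        "incomplete": outdir / "incomplete_participants.csv",
    }
    result.measures.to_csv(paths["measures"], index=False, float_format="%.17g")
    result.cohort_table.to_csv(paths["cohort"], index=False, float_format="%.17g")
    result.descriptives.to_csv(paths["descriptives"], float_format="%.17g")
    result.correlations.to_csv(paths["correlations"], index=False, float_format="%.17g")
    result.normality.to_csv(paths["normality"], float_format="%.17g")
    result.incomplete.to_csv(paths["incomplete"], index=False)

    record = {
        "config": config.to_dict(),
        "input_digests": {k: _sha256(Path(p)) for k, p in (input_paths or {}).items()},
        "counts": result.counts,
        "outputs": {k: str(p) for k, p in paths.items()},
    }
    (outdir / "run_record.json").write_text(json.dumps(record, indent=2, sort_keys=True))
    return record


def render_report(outdir: str | Path) -> str:
    """Human-readable summary of a completed analysis run directory."""
    outdir = Path(outdir)
    needed = ["run_record.json", "descriptives.csv", "correlations.csv",
              "cohort_screened.csv", "normality.csv"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run directory {outdir}: missing {missing}")
    record = json.loads((outdir / "run_record.json").read_text())
    desc = pd.read_csv(outdir / "descriptives.csv", index_col=0)
    corr = pd.read_csv(outdir / "correlations.csv")
    normal = pd.read_csv(outdir / "normality.csv", index_col=0)
    screened = pd.read_csv(outdir / "cohort_screened.csv")
    counts = record["counts"]

    lines = []
    lines.append("Perception-production analysis summary")
    lines.append("=" * 42)
    lines.append(f"participants measured: {counts['n_participants_measured']} "
                 f"(of {counts['n_participants_input']} in input)")
    lines.append(f"tokens read: {counts['n_tokens_read']} "
                 f"({counts['n_tokens_excluded']} excluded by tracking flag)")
    excl = screened.loc[~screened["included"]]
    lines.append(f"participants excluded by MAD screen: {len(excl)}")
    for r in excl.itertuples(index=False):
        lines.append(f"  - {r.participant_id}: {r.exclusion_reasons}")
    lines.append(f"participants included: {counts['n_participants_included']}")
    lines.append("")
    lines.append("Shapiro-Wilk normality (full cohort):")
    for m, row in normal.iterrows():
        lines.append(f"  {m:24s} W = {row['W']:.3f}  p = {row['p_value']:.3g}")
    lines.append("")
    lines.append("Descriptive statistics (included participants):")
    lines.append(f"  {'measure':24s} {'mean':>8s} {'SD':>8s} {'min':>8s} {'max':>8s}")
    for m, row in desc.iterrows():
        lines.append(f"  {m:24s} {row['mean']:8.3f} {row['sd']:8.3f} "
                     f"{row['min']:8.3f} {row['max']:8.3f}")
    lines.append("")
    lines.append("Spearman correlations (p-values unadjusted; three related "
                 "tests are reported together):")
    for r in corr.itertuples(index=False):
        lines.append(f"  {r.var_x} x {r.var_y}: rho(df = {r.df}) = {r.rho:.3f}, "
                     f"p = {r.p_value:.3f}")
    return "\n".join(lines) + "\n"
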