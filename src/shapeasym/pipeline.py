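"""Batch orchestration: per-subject processing and cohort analysis.

A manifest (subject id → label-volume path) drives per-subject surface
extraction, spectra and asymmetry; hemispheres are processed completely
independently (no cross-hemisphere registration, hence no lateral
processing bias). Per-subject failures are recorded and the batch
continues. The cohort step merges asymmetry outcomes with a covariate
table, applies the sample filters, fits the six outcome models, applies
Bonferroni correction and runs the Welch subgroup tests, emitting CSV and
Markdown reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .asymmetry import AsymmetryRecord, lateral_asymmetry, records_to_frame, volumetric_asymmetry
from .cohort_stats import (
    DEFAULT_N_TESTS,
    OUTCOME_COLUMNS,
    ModelReport,
    apply_cohort_filters,
    bonferroni,
    cohort_summary,
    fit_asymmetry_model,
    format_summary,
    welch_ttest,
)
from .mesh_io import (
    DEFAULT_STRUCTURES,
    StructureSpec,
    extract_surface,
    mesh_volume,
    read_label_volume,
    validate_mesh,
)
from .spectra import DEFAULT_N_EIGENVALUES, shape_dna

logger = logging.getLogger("shapeasym")

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_batch", "run_cohort"]


@dataclass
class RunConfig:
    """Configuration for a batch run.

    ``manifest`` maps subject id → label-volume path; ``structures`` lists
    the lateralized structures to process (FreeSurfer aseg defaults).
    All randomness (eigensolver start vectors, simulation) derives from
    ``seed``.
    """

    manifest: dict[str, str | Path] = field(default_factory=dict)
    structures: tuple[StructureSpec, ...] = DEFAULT_STRUCTURES
    n_eigenvalues: int = DEFAULT_N_EIGENVALUES
    normalize: bool = True
    smooth: bool = False
    age_max: float = 35.0
    fsiq_sd_limit: float = 2.0
    bonferroni_m: int = DEFAULT_N_TESTS
    alpha: float = 0.05
    interactions: tuple[str, ...] = ()
    outdir: Path | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        structures = tuple(
            StructureSpec(name, int(ids["left"]), int(ids["right"]))
            for name, ids in raw.pop("structures", {}).items()
        ) or DEFAULT_STRUCTURES
        outdir = raw.pop("outdir", None)
        cfg = cls(structures=structures, outdir=Path(outdir) if outdir else None, **raw)
        return cfg


@dataclass
class SubjectResult:
    subject_id: str
    records: list[AsymmetryRecord]
    descriptors: list  # ShapeDescriptor, 2 per structure
    provenance: dict


def run_subject(config: RunConfig, subject_id: str) -> SubjectResult:
    """Process one subject: label volume → meshes → spectra → asymmetry.

    Left and right surfaces are extracted, validated and solved
    independently; provenance records mesh statistics per stage.
    """
    path = config.manifest[subject_id]
    vol = read_label_volume(path)
    records: list[AsymmetryRecord] = []
    descriptors = []
    provenance: dict = {"subject_id": subject_id, "input": str(path), "structures": {}}
    for spec in config.structures:
        sides = {}
        for hemi, label in (("left", spec.left_label_id), ("right", spec.right_label_id)):
            mesh = extract_surface(vol, label, smooth=config.smooth)
            report = validate_mesh(mesh)
            desc = shape_dna(
                mesh,
                l=config.n_eigenvalues,
                normalize=config.normalize,
                structure=spec.name,
                hemisphere=hemi,
                solver_seed=config.seed,
            )
            sides[hemi] = (mesh, desc)
            descriptors.append(desc)
            provenance["structures"][f"{spec.name}_{hemi}"] = {
                "n_vertices": mesh.n_vertices,
                "n_faces": mesh.n_faces,
                "euler": report.euler_characteristic,
                "area_mm2": desc.area,
            }
        lv = mesh_volume(sides["left"][0])
        rv = mesh_volume(sides["right"][0])
        records.append(
            AsymmetryRecord(
                subject_id=subject_id,
                structure=spec.name,
                shape_asymmetry=lateral_asymmetry(sides["left"][1], sides["right"][1]),
                volumetric_asymmetry=volumetric_asymmetry(lv, rv),
                left_volume=lv,
                right_volume=rv,
            )
        )
    return SubjectResult(subject_id, records, descriptors, provenance)


def run_batch(config: RunConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Run every manifest subject; failures are logged, the batch continues.

    Returns the tidy asymmetry table (subject × structure) and a map of
    failed subject id → error message.
    """
    if not config.manifest:
        raise ValueError("empty manifest: nothing to process")
    all_records: list[AsymmetryRecord] = []
    failures: dict[str, str] = {}
    for sid in config.manifest:
        try:
            result = run_subject(config, sid)
        except Exception as exc:  # per-subject isolation is the contract
            logger.warning("subject %s failed: %s", sid, exc)
            failures[sid] = str(exc)
            continue
        all_records.extend(result.records)
    frame = records_to_frame(all_records)
    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        _write_csv(frame, config.outdir / "asymmetry.csv")
        (config.outdir / "failures.json").write_text(json.dumps(failures, indent=2))
    return frame, failures


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float rendering so identical runs yield byte-identical files
    df.to_csv(path, index=False, float_format="%.10g")


def _pivot_outcomes(asym: pd.DataFrame) -> pd.DataFrame:
    """Wide outcome table: one row per subject, {structure}_{measure} columns."""
    shape = asym.pivot(index="subject_id", columns="structure", values="shape_asymmetry")
    vol = asym.pivot(index="subject_id", columns="structure", values="volumetric_asymmetry")
    out = pd.concat(
        {f"{c}_shape": shape[c] for c in shape.columns}
        | {f"{c}_volumetric": vol[c] for c in vol.columns},
        axis=1,
    )
    return out.reset_index()


@dataclass
class CohortReport:
    summary: pd.DataFrame
    models: dict[str, ModelReport]
    welch: pd.DataFrame
    exclusions: pd.DataFrame
    threshold: float
    n_tests: int


def run_cohort(
    config: RunConfig,
    covariates: pd.DataFrame,
    asymmetry_table: pd.DataFrame,
) -> CohortReport:
    """Full cohort analysis on merged covariates + per-subject asymmetries.

    Applies the sample filters, fits one OLS per available outcome with
    Bonferroni flags at the configured family size, and runs Welch tests
    of diagnosis group differences within each sex per outcome.
    """
    wide = _pivot_outcomes(asymmetry_table)
    merged = covariates.merge(wide, on="subject_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between covariate table and asymmetry results")
    kept, exclusions = apply_cohort_filters(
        merged, fsiq_sd_limit=config.fsiq_sd_limit, age_max=config.age_max
    )
    outcomes = [c for c in OUTCOME_COLUMNS if c in kept.columns]
    missing = kept[outcomes].isna().any(axis=1)
    kept = kept.loc[~missing]
    models = {
        outcome: fit_asymmetry_model(
            kept,
            outcome,
            interactions=config.interactions,
            n_tests=config.bonferroni_m,
            alpha=config.alpha,
        )
        for outcome in outcomes
    }
    welch_rows = []
    for outcome in outcomes:
        for sex in ("male", "female"):
            sub = kept[kept["sex"] == sex]
            a = sub.loc[sub["diagnosis"] == "ASD", outcome]
            b = sub.loc[sub["diagnosis"] == "control", outcome]
            if len(a) < 2 or len(b) < 2:
                continue
            t, df, p = welch_ttest(a, b)
            welch_rows.append({"outcome": outcome, "sex": sex, "t": t, "df": df, "p": p})
    report = CohortReport(
        summary=cohort_summary(kept),
        models=models,
        welch=pd.DataFrame(welch_rows, columns=["outcome", "sex", "t", "df", "p"]),
        exclusions=exclusions,
        threshold=bonferroni(config.alpha, config.bonferroni_m),
        n_tests=config.bonferroni_m,
    )
    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, config.outdir)
    return report


def write_report(report: CohortReport, outdir: Path) -> None:
    """Emit CSVs plus a Markdown report mirroring the summary/regression tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_frame = pd.concat([m.to_frame() for m in report.models.values()], ignore_index=True)
    _write_csv(model_frame, outdir / "regression.csv")
    _write_csv(report.welch, outdir / "welch.csv")
    _write_csv(report.exclusions, outdir / "exclusions.csv")

    lines = ["# Cohort asymmetry report", ""]
    lines += ["## Cohort summary", "", format_summary(report.summary), ""]
    lines += [
        "## Regression results",
        "",
        f"Bonferroni family size m = {report.n_tests}; "
        f"per-test threshold = {report.threshold:.5f} "
        "(bold = significant after correction).",
        "",
        "| Outcome | R² | F | p | " + " | ".join(
            f"{t} β / t / p" for t in ("diagnosis", "sex", "age", "icv", "fsiq")
        ) + " |",
        "|---" * 9 + "|",
    ]
    for name, m in report.models.items():
        cells = [f"{m.r_squared:.3f}", f"{m.f_statistic:.2f}", f"{m.f_pvalue:.2g}"]
        for term in ("diagnosis", "sex", "age", "icv", "fsiq"):
            tr = m.terms[term]
            text = f"{tr.beta:.3g} / {tr.t:.2f} / {tr.p:.3g}"
            if tr.bonferroni_significant:
                text = f"**{text}**"
            cells.append(text)
        lines.append("| " + name + " | " + " | ".join(cells) + " |")
    lines += ["", "## Welch tests (ASD vs control within sex)", ""]
    if len(report.welch):
        lines.append("| outcome | sex | t | df | p |")
        lines.append("|---|---|---|---|---|")
        for _, row in report.welch.iterrows():
            lines.append(
                f"| {row['outcome']} | {row['sex']} | {row['t']:.4g} "
                f"| {row['df']:.4g} | {row['p']:.4g} |"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
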