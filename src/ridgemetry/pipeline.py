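"""End-to-end study runs: simulate, measure, analyze, report.

One :class:`RunConfig` drives the whole pipeline: a nested screening cohort
is simulated (thickness-only by default; optionally each exam is rendered as
a phantom volume and measured through the imaging pipeline), low-stage exams
are excluded, and the full analysis battery runs — grader agreement, GEE
stage means, Spearman continuous-stage correlation, repeatability, and the
pre/post-treatment windowed comparison. Every number lands in an
intermediate CSV or the results JSON; figures are optional display
artifacts and never feed any reported number.

Runs are deterministic: all randomness descends from one seed through a
``numpy.random.SeedSequence`` hierarchy, and the results JSON is
byte-identical across repeated invocations with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .phantom import (
    CohortParams,
    PhantomParams,
    TreatmentParams,
    generate_cohort,
    generate_phantom_volume,
    generate_repeat_captures,
    generate_treated_cohort,
)
from .records import ExamRecord, records_to_frame
from .stats import (
    filter_min_stage,
    gee_stage_means,
    grader_agreement,
    repeatability,
    spearman_stage_thickness,
    treatment_window_summary,
)
from .thickness import SegmentationConfig, measure_exam

ALL_ANALYSES = ("agreement", "stage", "repeatability", "treatment")


@dataclass
class RepeatabilityDesign:
    """Shape of the repeat-capture experiment."""

    n_eyes: int = 20
    n_captures: int = 2
    mean_um: float = 330.0
    between_eye_sd_um: float = 95.0
    within_eye_sd_um: float = 23.0


@dataclass
class RunConfig:
    """Everything needed for one full study run."""

    cohort: CohortParams = field(default_factory=CohortParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    repeatability: RepeatabilityDesign = field(default_factory=RepeatabilityDesign)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    analyses: tuple[str, ...] = ALL_ANALYSES
    image_mode: bool = False
    n_treated_patients: int = 4
    seed: int = 0
    make_figures: bool = False
    stage_col: str = "adjudicated_ordinal"

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; choose from {ALL_ANALYSES}")


@dataclass
class StudyReport:
    results: dict[str, Any]
    manifest: dict[str, Any]
    out_dir: Path | None = None


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file mirroring its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = {}
    blocks = {
        "cohort": CohortParams,
        "treatment": TreatmentParams,
        "repeatability": RepeatabilityDesign,
        "phantom": PhantomParams,
    }
    for key, cls in blocks.items():
        if key in raw:
            kwargs[key] = cls(**raw[key])
    for key in ("image_mode", "n_treated_patients", "seed", "make_figures", "stage_col"):
        if key in raw:
            kwargs[key] = raw[key]
    if "analyses" in raw:
        kwargs["analyses"] = tuple(raw["analyses"])
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["analyses"] = list(d["analyses"])
    return d


def version_and_provenance(config: RunConfig) -> dict[str, Any]:
    """Provenance manifest: package version, canonical config hash, seed.

    The hash is SHA-256 of the sorted-key JSON form of the config, so the
    same configuration always hashes identically and any change (including
    the seed) changes the manifest.
    """
    canonical = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return {
        "package": "ridgemetry",
        "version": __version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
    }


MANIFEST_SCHEMA = ("package", "version", "config_sha256", "seed")


def validate_manifest(manifest: dict[str, Any]) -> None:
    missing = [k for k in MANIFEST_SCHEMA if k not in manifest]
    if missing:
        raise ValueError(f"manifest missing fields {missing}")


def _child_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(seed).spawn(index + 1)[index].generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def _measure_cohort_images(
    records: list[ExamRecord], base: PhantomParams, seed: int
) -> list[ExamRecord]:
    """Re-measure every exam through the imaging pipeline.

    Each record's true thickness defines a phantom (ridge height = truth
    minus baseline) rendered with its own speckle seed; the measured top-10
    statistic replaces the thickness-only draw.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        height = max((rec.true_thickness_um or base.baseline_retina_um) - base.baseline_retina_um, 0.0)
        params = dataclasses.replace(base, ridge_height_um=height)
        vol, truth = generate_phantom_volume(params, rng)
        result = measure_exam(vol, truth.true_ridgeline, SegmentationConfig())
        rec = dataclasses.replace(rec, max_thickness_um=result.mean_um)
        out.append(rec)
    return out


def run_full_study(config: RunConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Simulate, measure, and analyze one full study.

    Analyses run independently: a failing analysis is recorded under its
    name with an ``error`` entry and does not abort the others. When
    ``out_dir`` is given, the cohort tables, results JSON, manifest, and
    (optionally) figures are written beneath it.
    """
    manifest = version_and_provenance(config)
    results: dict[str, Any] = {}

    cohort_params = dataclasses.replace(config.cohort, seed=_child_seed(config.seed, 0))
    records = generate_cohort(cohort_params)
    if config.image_mode and records:
        records = _measure_cohort_images(records, config.phantom, _child_seed(config.seed, 3))
    kept, n_excluded = filter_min_stage(records)
    results["cohort"] = {
        "n_patients": len({r.patient_id for r in records}),
        "n_eyes": len({(r.patient_id, r.eye) for r in records}),
        "n_exams": len(records),
        "n_excluded_low_stage": n_excluded,
        "image_mode": config.image_mode,
    }

    repeat_frame = generate_repeat_captures(
        n_eyes=config.repeatability.n_eyes,
        n_captures=config.repeatability.n_captures,
        mean_um=config.repeatability.mean_um,
        between_eye_sd_um=config.repeatability.between_eye_sd_um,
        within_eye_sd_um=config.repeatability.within_eye_sd_um,
        seed=_child_seed(config.seed, 1),
    )
    treated = generate_treated_cohort(
        config.treatment,
        n_patients=config.n_treated_patients,
        seed=_child_seed(config.seed, 2),
    )

    if "agreement" in config.analyses:
        results["agreement"] = _run_safely(
            lambda: _agreement_dict(grader_agreement(kept))
        )
    if "stage" in config.analyses:
        results["stage"] = _run_safely(lambda: _stage_dict(kept, config.stage_col))
    if "repeatability" in config.analyses:
        results["repeatability"] = _run_safely(lambda: _repeat_dict(repeat_frame))
    if "treatment" in config.analyses:
        results["treatment"] = _run_safely(lambda: _treatment_dict(treated))

    report = StudyReport(results=results, manifest=manifest)
    if out_dir is not None:
        report.out_dir = _write_outputs(
            Path(out_dir), config, results, manifest, records, repeat_frame, treated
        )
    return report


def _run_safely(fn) -> dict[str, Any]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fn()
    except Exception as exc:  # partial-failure policy
        return {"error": f"{type(exc).__name__}: {exc}"}


def _agreement_dict(res) -> dict[str, Any]:
    return {
        "percent_agreement": res.percent_agreement,
        "weighted_kappa": res.weighted_kappa,
        "pearson_r": res.pearson_r,
        "n": res.n,
        "kappa_weights": res.kappa_weights,
    }


def _stage_dict(records: list[ExamRecord], stage_col: str) -> dict[str, Any]:
    gee = gee_stage_means(records, stage_col=stage_col)
    rho, p = spearman_stage_thickness(records)
    return {
        "gee": {
            str(stage): {
                "estimate_um": est.estimate_um,
                "se_um": est.se_um,
                "p_value": est.p_value,
                "n": est.n,
            }
            for stage, est in sorted(gee.estimates.items())
        },
        "working_correlation": gee.working_correlation,
        "cluster": gee.cluster_var,
        "spearman_rho": rho,
        "spearman_p": p,
    }


def _repeat_dict(frame) -> dict[str, Any]:
    res = repeatability(frame)
    return {
        "icc": res.icc,
        "mean_cov_percent": res.mean_cov_percent,
        "n_eyes": res.n_eyes,
        "n_measurements": res.n_measurements,
    }


def _treatment_dict(treated: list[ExamRecord]) -> dict[str, Any]:
    res = treatment_window_summary(treated)
    return {
        "windows": {
            name: {
                "mean_um": w.mean_um,
                "se_um": w.se_um,
                "n_obs": w.n_obs,
                "n_patients": w.n_patients,
            }
            for name, w in res.windows.items()
        },
        "n_excluded": res.n_excluded,
    }


def _write_outputs(
    out_dir: Path,
    config: RunConfig,
    results: dict[str, Any],
    manifest: dict[str, Any],
    records: list[ExamRecord],
    repeat_frame,
    treated: list[ExamRecord],
) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out_dir / "cohort.csv", index=False)
    repeat_frame.to_csv(out_dir / "repeat_captures.csv", index=False)
    records_to_frame(treated).to_csv(out_dir / "treated_cohort.csv", index=False)
    payload = {"manifest": manifest, "results": results}
    (out_dir / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out_dir / "report.txt").write_text(_format_report(results, manifest))
    if config.make_figures:
        _write_figures(out_dir, records, treated)
    return out_dir


def _format_report(results: dict[str, Any], manifest: dict[str, Any]) -> str:
    lines = [
        f"ridgemetry {manifest['version']} study report (seed {manifest['seed']})",
        f"config sha256: {manifest['config_sha256']}",
        "",
    ]
    cohort = results.get("cohort", {})
    lines.append(
        f"cohort: {cohort.get('n_patients')} patients, {cohort.get('n_eyes')} eyes, "
        f"{cohort.get('n_exams')} exams ({cohort.get('n_excluded_low_stage')} excluded, "
        f"mean stage < 0.5)"
    )
    ag = results.get("agreement")
    if ag and "error" not in ag:
        lines.append(
            f"agreement: {ag['percent_agreement']:.1f}% exact, weighted kappa "
            f"{ag['weighted_kappa']:.2f}, Pearson r {ag['pearson_r']:.2f}"
        )
    st = results.get("stage")
    if st and "error" not in st:
        for stage, est in st["gee"].items():
            lines.append(
                f"stage {stage}: {est['estimate_um']:.1f} ({est['se_um']:.1f}) um "
                f"[GEE, robust SE, n={est['n']}]"
            )
        lines.append(f"Spearman rho (continuous stage vs thickness): {st['spearman_rho']:.3f}")
    rp = results.get("repeatability")
    if rp and "error" not in rp:
        lines.append(
            f"repeatability: ICC {rp['icc']:.2f}, mean CoV {rp['mean_cov_percent']:.1f}% "
            f"({rp['n_eyes']} eyes, {rp['n_measurements']} measurements)"
        )
    tr = results.get("treatment")
    if tr and "error" not in tr:
        w = tr["windows"]
        lines.append(
            "treatment windows (um): pre "
            f"{w['pre']['mean_um']:.1f} ({w['pre']['se_um']:.1f}), at "
            f"{w['at']['mean_um']:.1f} ({w['at']['se_um']:.1f}), post "
            f"{w['post']['mean_um']:.1f} ({w['post']['se_um']:.1f})"
        )
    for name in ("agreement", "stage", "repeatability", "treatment"):
        block = results.get(name)
        if block and "error" in block:
            lines.append(f"{name}: FAILED ({block['error']})")
    return "\n".join(lines) + "\n"


def _write_figures(out_dir: Path, records: list[ExamRecord], treated: list[ExamRecord]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    stages = sorted(df["adjudicated_ordinal"].unique())
    axes[0].boxplot(
        [df.loc[df["adjudicated_ordinal"] == s, "max_thickness_um"] for s in stages],
        tick_labels=[str(s) for s in stages],
    )
    axes[0].set_xlabel("adjudicated stage")
    axes[0].set_ylabel("max ridge thickness (um)")
    axes[1].scatter(df["mean_continuous"], df["max_thickness_um"], s=12, alpha=0.6)
    axes[1].set_xlabel("mean continuous stage")
    axes[1].set_ylabel("max ridge thickness (um)")
    fig.tight_layout()
    fig.savefig(out_dir / "stage_association.png", dpi=120)
    plt.close(fig)

    tdf = records_to_frame(treated)
    if len(tdf):
        fig, ax = plt.subplots(figsize=(6, 4))
        collapsed = tdf.groupby(["patient_id", "weeks_from_treatment"], as_index=False)[
            "max_thickness_um"
        ].mean()
        for pid, sub in collapsed.groupby("patient_id"):
            ax.plot(sub["weeks_from_treatment"], sub["max_thickness_um"], marker="o", label=pid)
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.set_xlabel("weeks from treatment")
        ax.set_ylabel("max ridge thickness (um)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "treatment_trajectories.png", dpi=120)
        plt.close(fig)
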