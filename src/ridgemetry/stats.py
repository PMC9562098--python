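"""Statistical analyses for ridge-thickness cohorts.

The analysis battery applied to an exam table:

* **Adjudication** — the two graders' continuous labels are averaged; when
  their ordinal labels disagree, the average rounded to the nearest integer
  (half up) is the adjudicated stage. Exams with a mean continuous label
  below 0.5 carry no perceptible ridge and are excluded before measurement.
* **Agreement** — percent exact ordinal agreement, weighted Cohen's kappa
  (linear weights by default), and Pearson r on the continuous labels.
* **Stage association** — per-stage mean maximum thickness from a
  generalized estimating equation (GEE) with identity link, exchangeable
  working correlation, and patient as the cluster, which absorbs both
  intereye and interexamination correlation into a single within-patient
  exchangeable structure. Robust (sandwich) standard errors are reported.
* **Continuous association** — Spearman rank correlation (average ranks on
  ties) between mean continuous stage and thickness.
* **Repeatability** — one-way random-effects intraclass correlation and the
  mean per-eye coefficient of variation over same-session repeat captures.
* **Treatment windows** — mean thickness 1-2 weeks before treatment, at
  treatment, and 1-2 weeks after, eyes averaged within infant, with GEE
  (intercept-only, patient cluster) means and robust SEs per window.

All tests are two-sided with alpha = 0.05; no multiplicity correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.inter_rater import cohens_kappa

from .records import ExamRecord, GraderLabels, records_to_frame, round_half_up

MIN_STAGE_THRESHOLD = 0.5


def _as_frame(records: Iterable[ExamRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return records_to_frame(list(records))


# ---------------------------------------------------------------------------
# adjudication and exclusion
# ---------------------------------------------------------------------------

def adjudicate(labels: GraderLabels) -> tuple[float, int]:
    """Average the continuous labels and resolve ordinal disagreement.

    Returns ``(mean_continuous, adjudicated_ordinal)``. If the graders'
    ordinal labels agree, the agreed label passes through; otherwise the mean
    continuous label is rounded to the nearest integer, with .5 rounding up
    (a tie-break the label protocol leaves open; documented once, used
    everywhere).
    """
    mean_cont = round((labels.grader_a_continuous + labels.grader_b_continuous) / 2.0, 3)
    if labels.grader_a_ordinal == labels.grader_b_ordinal:
        return mean_cont, labels.grader_a_ordinal
    return mean_cont, round_half_up(mean_cont)


def filter_min_stage(
    records: Sequence[ExamRecord], threshold: float = MIN_STAGE_THRESHOLD
) -> tuple[list[ExamRecord], int]:
    """Drop exams whose mean continuous label is strictly below ``threshold``.

    Such exams show no perceptible ridge to trace. A record at exactly the
    threshold is retained. Returns the kept records and the excluded count.
    """
    kept = [r for r in records if r.mean_continuous >= threshold]
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# grader agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    percent_agreement: float
    weighted_kappa: float
    pearson_r: float
    n: int
    kappa_weights: str = "linear"
    notes: list[str] = field(default_factory=list)


def grader_agreement(
    records: Iterable[ExamRecord] | pd.DataFrame, kappa_weights: str = "linear"
) -> AgreementResult:
    """Intergrader agreement on ordinal and continuous stage labels.

    Percent agreement counts exact ordinal matches; kappa is weighted Cohen's
    kappa on the 0-3 ordinal table (``linear`` or ``quadratic`` weights);
    Pearson r is computed on the continuous pairs and reported as NaN (with a
    note) when either grader's labels have zero variance.
    """
    if kappa_weights not in ("linear", "quadratic"):
        raise ValueError(f"kappa_weights must be 'linear' or 'quadratic'; got {kappa_weights!r}")
    df = _as_frame(records)
    if len(df) < 2:
        raise ValueError("agreement needs at least 2 records")
    a_ord = df["grader_a_ordinal"].to_numpy(dtype=int)
    b_ord = df["grader_b_ordinal"].to_numpy(dtype=int)
    percent = float(np.mean(a_ord == b_ord) * 100.0)

    table = np.zeros((4, 4), dtype=float)
    for ai, bi in zip(a_ord, b_ord):
        table[ai, bi] += 1
    # restrict to jointly-observed category range so empty margins don't
    # distort the weight matrix
    used = np.union1d(np.unique(a_ord), np.unique(b_ord))
    lo, hi = used.min(), used.max()
    sub = table[lo : hi + 1, lo : hi + 1]
    notes: list[str] = []
    if sub.shape == (1, 1):
        kappa = float("nan")
        notes.append("kappa undefined: a single ordinal category was used")
    else:
        kappa = float(cohens_kappa(sub, wt=kappa_weights).kappa)

    a_cont = df["grader_a_continuous"].to_numpy(dtype=float)
    b_cont = df["grader_b_continuous"].to_numpy(dtype=float)
    if np.std(a_cont) == 0 or np.std(b_cont) == 0:
        pearson = float("nan")
        notes.append("Pearson r undefined: zero variance in a grader's continuous labels")
    else:
        pearson = float(scipy.stats.pearsonr(a_cont, b_cont)[0])
    return AgreementResult(
        percent_agreement=percent,
        weighted_kappa=kappa,
        pearson_r=pearson,
        n=len(df),
        kappa_weights=kappa_weights,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# GEE stage association
# ---------------------------------------------------------------------------

@dataclass
class StageEstimate:
    estimate_um: float
    se_um: float
    p_value: float
    n: int


@dataclass
class GEEStageResult:
    estimates: dict[int, StageEstimate]
    working_correlation: str = "exchangeable"
    cluster_var: str = "patient_id"

    def ordered_means(self) -> list[float]:
        return [self.estimates[k].estimate_um for k in sorted(self.estimates)]


def gee_stage_means(
    records: Iterable[ExamRecord] | pd.DataFrame,
    stage_col: str = "adjudicated_ordinal",
    value_col: str = "max_thickness_um",
    cluster_col: str = "patient_id",
) -> GEEStageResult:
    """Per-stage mean maximum thickness from a cluster-robust GEE.

    Fits ``value ~ C(stage) - 1`` (no intercept, so coefficients are the
    per-stage marginal means directly) with Gaussian family, identity link,
    exchangeable working correlation within patient, and robust sandwich
    SEs. Eyes and sessions are pooled within the patient cluster. P-values
    test each stage mean against zero, two-sided.
    """
    df = _as_frame(records)[[stage_col, value_col, cluster_col]].dropna()
    n_clusters = df[cluster_col].nunique()
    if n_clusters < 2:
        raise ValueError(
            "GEE needs at least 2 clusters; with a single cluster fit an "
            "independent (OLS) model instead"
        )
    counts = df[stage_col].value_counts()
    thin = sorted(int(k) for k, v in counts.items() if v < 2)
    if thin:
        raise ValueError(f"stage level(s) {thin} have fewer than 2 records; not estimable")
    df = df.rename(columns={stage_col: "_stage", value_col: "_y", cluster_col: "_cluster"})
    model = smf.gee(
        "_y ~ C(_stage) - 1",
        groups="_cluster",
        data=df,
        cov_struct=sm.cov_struct.Exchangeable(),
        family=sm.families.Gaussian(),
    )
    res = model.fit()
    estimates: dict[int, StageEstimate] = {}
    for name in res.params.index:
        stage = int(float(name.split("[")[1].rstrip("]").lstrip("T.")))
        estimates[stage] = StageEstimate(
            estimate_um=float(res.params[name]),
            se_um=float(res.bse[name]),
            p_value=float(res.pvalues[name]),
            n=int((df["_stage"] == stage).sum()),
        )
    return GEEStageResult(estimates=estimates, cluster_var=cluster_col)


def spearman_stage_thickness(
    records: Iterable[ExamRecord] | pd.DataFrame,
    stage_col: str = "mean_continuous",
    value_col: str = "max_thickness_um",
) -> tuple[float, float]:
    """Spearman rank correlation between continuous stage and thickness.

    Ties receive average ranks. Returns ``(rho, p)``; a constant column makes
    the correlation undefined and yields ``(nan, nan)`` with a warning.
    """
    df = _as_frame(records)
    if len(df) < 3:
        raise ValueError("Spearman correlation needs at least 3 records")
    x = df[stage_col].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("Spearman correlation undefined for a constant column")
        return float("nan"), float("nan")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    icc: float
    mean_cov_percent: float
    n_eyes: int
    n_measurements: int


def repeatability(
    data: pd.DataFrame | Sequence[ExamRecord],
    eye_col: str = "eye_id",
    value_col: str = "max_thickness_um",
) -> RepeatabilityResult:
    """Test-retest precision over same-session repeat captures.

    The ICC is the one-way random-effects, single-measurement form
    ICC(1,1): with between-eye mean square MSB, within-eye mean square MSW,
    and average group size n0 (its unbalanced-design correction),
    ``ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW)``. The coefficient of
    variation is computed per eye (SD of repeats / mean, sample SD) and
    averaged across eyes. Eyes contributing fewer than 2 captures are
    excluded with a warning.
    """
    if isinstance(data, pd.DataFrame):
        df = data[[eye_col, value_col]].rename(columns={eye_col: "_eye", value_col: "_y"})
    else:
        frame = records_to_frame(list(data))
        frame["_eye"] = (
            frame["patient_id"].astype(str)
            + ":" + frame["eye"].astype(str)
            + ":" + frame["session_id"].astype(str)
        )
        df = frame[["_eye", "max_thickness_um"]].rename(columns={"max_thickness_um": "_y"})
    sizes = df.groupby("_eye")["_y"].size()
    singles = sizes[sizes < 2]
    if len(singles):
        warnings.warn(
            f"excluding {len(singles)} eye(s) with fewer than 2 captures from repeatability"
        )
        df = df[~df["_eye"].isin(singles.index)]
    if df["_eye"].nunique() < 1:
        raise ValueError("no eye has >= 2 repeat captures")

    groups = df.groupby("_eye")["_y"]
    k = groups.ngroups
    n_i = groups.size().to_numpy(dtype=float)
    n_total = float(n_i.sum())
    grand = df["_y"].mean()
    group_means = groups.mean()
    ssb = float((n_i * (group_means.to_numpy() - grand) ** 2).sum())
    ssw = float(((df["_y"] - df["_eye"].map(group_means)) ** 2).sum())
    if k < 2:
        # a single eye cannot separate between- from within-eye variance
        icc = float("nan")
        warnings.warn("ICC undefined with a single eye; reporting NaN")
    else:
        msb = ssb / (k - 1)
        msw = ssw / (n_total - k)
        n0 = (n_total - float((n_i**2).sum()) / n_total) / (k - 1)
        denom = msb + (n0 - 1.0) * msw
        icc = float((msb - msw) / denom) if denom > 0 else float("nan")

    covs = []
    for _, vals in groups:
        mean = vals.mean()
        if mean == 0:
            warnings.warn("CoV undefined for an eye with zero mean thickness; excluded")
            continue
        covs.append(vals.std(ddof=1) / mean * 100.0)
    mean_cov = float(np.mean(covs)) if covs else float("nan")
    return RepeatabilityResult(
        icc=icc,
        mean_cov_percent=mean_cov,
        n_eyes=k,
        n_measurements=int(n_total),
    )


# ---------------------------------------------------------------------------
# treatment windows
# ---------------------------------------------------------------------------

TREATMENT_WINDOWS: dict[str, tuple[float, float, bool, bool]] = {
    # name: (lo, hi, lo_closed, hi_closed)
    "pre": (-2.0, -1.0, True, True),
    "at": (-1.0, 1.0, False, False),
    "post": (1.0, 2.0, True, True),
}


@dataclass
class WindowEstimate:
    mean_um: float
    se_um: float
    n_obs: int
    n_patients: int


@dataclass
class TreatmentWindowResult:
    windows: dict[str, WindowEstimate]
    n_excluded: int


def _assign_window(week: float) -> str | None:
    for name, (lo, hi, lc, hc) in TREATMENT_WINDOWS.items():
        above = week >= lo if lc else week > lo
        below = week <= hi if hc else week < hi
        if above and below:
            return name
    return None


def treatment_window_summary(
    records: Iterable[ExamRecord] | pd.DataFrame,
) -> TreatmentWindowResult:
    """Mean thickness 1-2 weeks pre-treatment, at treatment, and 1-2 weeks post.

    Window assignment uses ``weeks_from_treatment``: pre = [-2, -1],
    at = (-1, +1), post = [+1, +2], all in weeks; records outside every
    window are excluded (count reported). Right and left eyes of an infant
    are averaged per visit before summarizing. Each window's mean and robust
    SE come from an intercept-only GEE clustered by patient; with a single
    infant the GEE degenerates and a simple mean is reported with a warning.
    """
    df = _as_frame(records)
    df = df[df["weeks_from_treatment"].notna()].copy()
    df["_window"] = df["weeks_from_treatment"].astype(float).map(_assign_window)
    n_excluded = int(df["_window"].isna().sum())
    df = df[df["_window"].notna()]
    # eyes of one infant averaged per visit
    collapsed = (
        df.groupby(["patient_id", "_window", "weeks_from_treatment"], as_index=False)[
            "max_thickness_um"
        ].mean()
    )
    windows: dict[str, WindowEstimate] = {}
    for name in TREATMENT_WINDOWS:
        sub = collapsed[collapsed["_window"] == name]
        if sub.empty:
            raise ValueError(f"treatment window {name!r} contains no records")
        n_pat = sub["patient_id"].nunique()
        vals = sub["max_thickness_um"].to_numpy(dtype=float)
        if vals.var() < 1e-12:
            # degenerate: no residual variance, nothing for GEE to estimate
            windows[name] = WindowEstimate(
                mean_um=float(vals.mean()), se_um=0.0, n_obs=len(sub), n_patients=n_pat
            )
            continue
        if n_pat < 2:
            warnings.warn(
                f"window {name!r}: single infant; reporting a simple mean instead of GEE"
            )
            vals = sub["max_thickness_um"].to_numpy(dtype=float)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        else:
            model = smf.gee(
                "max_thickness_um ~ 1",
                groups="patient_id",
                data=sub,
                cov_struct=sm.cov_struct.Exchangeable(),
                family=sm.families.Gaussian(),
            )
            res = model.fit()
            mean = float(res.params.iloc[0])
            se = float(res.bse.iloc[0])
        windows[name] = WindowEstimate(
            mean_um=mean, se_um=se, n_obs=len(sub), n_patients=n_pat
        )
    return TreatmentWindowResult(windows=windows, n_excluded=n_excluded)
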