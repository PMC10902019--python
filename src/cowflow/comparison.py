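"""Method-agreement statistics for simulated vs measured cerebral velocities.

Compares CFD-derived and TCD-measured M1 velocity metrics across
conditions (rest, hypercapnia, exercise) with the statistical toolkit of
a method-comparison study: paired t-tests, Pearson correlations,
Shapiro-Wilk normality checks and Bland-Altman agreement (bias, 95%
limits of agreement, proportional bias), in both absolute terms and as
relative changes from rest. The difference orientation is fixed as
TCD - CFD throughout.

Statistical routines delegate to scipy.stats; this module owns the study
assembly, the pairing conventions and the Bland-Altman arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES, MetricDelta, VelocityMetrics, relative_change

__all__ = [
    "CONDITIONS",
    "STIMULI",
    "ALPHA",
    "PairedSample",
    "BlandAltmanResult",
    "ConditionRecord",
    "StudyTables",
    "paired_t",
    "pearson_corr",
    "bland_altman",
    "shapiro_wilk",
    "run_study",
]

CONDITIONS = ("rest", "hypercapnia", "exercise")
STIMULI = ("hypercapnia", "exercise")  # compared against rest
ALPHA = 0.05
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Equal-length paired vectors; by convention a = TCD, b = CFD."""

    values_a: np.ndarray
    values_b: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired vectors must be 1-D and equal length")
        if a.size < 3:
            raise ValueError("paired sample needs n >= 3")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired sample contains non-finite values")
        if self.ids is not None and len(self.ids) != a.size:
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return self.values_a.size


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, 95% limits of agreement and proportional-bias trend (a - b)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    proportional_bias_p: float
    n: int


def paired_t(s: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t-test on a - b; returns (t, df, p)."""
    diffs = s.values_a - s.values_b
    if np.ptp(diffs) == 0:
        raise ValueError("paired differences have zero variance (degenerate t-test)")
    res = stats.ttest_rel(s.values_a, s.values_b)
    return float(res.statistic), s.n - 1, float(res.pvalue)


def pearson_corr(s: PairedSample) -> tuple[float, float]:
    """Pearson correlation of the paired vectors; returns (r, p)."""
    if np.ptp(s.values_a) == 0 or np.ptp(s.values_b) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    res = stats.pearsonr(s.values_a, s.values_b)
    return float(res.statistic), float(res.pvalue)


def bland_altman(s: PairedSample) -> BlandAltmanResult:
    """Bland-Altman agreement of a against b (differences a - b).

    Bias is the mean difference, limits of agreement are
    bias +/- 1.96 * SD(differences), and proportional bias is the
    ordinary-least-squares slope of the differences on the pairwise
    means with its two-sided p-value.
    """
    diffs = s.values_a - s.values_b
    means = 0.5 * (s.values_a + s.values_b)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if np.ptp(means) == 0 or np.ptp(diffs) == 0:
        slope, slope_p = 0.0, 1.0
    else:
        reg = stats.linregress(means, diffs)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        proportional_bias_slope=slope,
        proportional_bias_p=slope_p,
        n=s.n,
    )


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p). Requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# study assembly


@dataclass(frozen=True)
class ConditionRecord:
    """One participant-condition cell: CFD and TCD metrics plus tCBF (mL/min)."""

    cfd: VelocityMetrics
    tcd: VelocityMetrics
    tcbf_ml_min: float


@dataclass(frozen=True)
class StudyTables:
    """Tidy result tables of the full CFD-vs-TCD comparison.

    All tables are pandas DataFrames; significance flags use alpha = 0.05
    and differences are oriented TCD - CFD.
    """

    distributions: pd.DataFrame
    paired_inter_source: pd.DataFrame
    paired_vs_rest: pd.DataFrame
    abs_correlations: pd.DataFrame
    tcbf_correlations: pd.DataFrame
    rel_distributions: pd.DataFrame
    paired_rel_inter_source: pd.DataFrame
    rel_correlations: pd.DataFrame
    tcbf_rel_correlations: pd.DataFrame
    bland_altman_abs: pd.DataFrame
    bland_altman_rel: pd.DataFrame

    def to_csv_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.__dict__.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)

    def summary_json(self, path: str | Path) -> None:
        summary = {
            name: df.to_dict(orient="records") for name, df in self.__dict__.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=float)


def _metric_vectors(
    cohort: Mapping[str, Mapping[str, ConditionRecord]],
    condition: str,
    metric: str,
) -> PairedSample:
    pids = sorted(cohort)
    tcd = [cohort[p][condition].tcd.as_dict()[metric] for p in pids]
    cfd = [cohort[p][condition].cfd.as_dict()[metric] for p in pids]
    return PairedSample(np.array(tcd), np.array(cfd), tuple(pids))


def _relative_deltas(
    cohort: Mapping[str, Mapping[str, ConditionRecord]],
    stimulus: str,
) -> dict[str, tuple[MetricDelta, MetricDelta]]:
    """Per participant: (TCD delta, CFD delta) from rest to stimulus."""
    out = {}
    for pid in sorted(cohort):
        rec_rest, rec_stim = cohort[pid]["rest"], cohort[pid][stimulus]
        out[pid] = (
            relative_change(rec_rest.tcd, rec_stim.tcd),
            relative_change(rec_rest.cfd, rec_stim.cfd),
        )
    return out


def _safe_paired_t(s: PairedSample) -> dict[str, float | bool]:
    try:
        t, df, p = paired_t(s)
        return {"t": t, "df": df, "p": p, "significant": p < ALPHA, "degenerate": False}
    except ValueError:
        return {"t": np.nan, "df": s.n - 1, "p": np.nan, "significant": False, "degenerate": True}


def _safe_pearson(s: PairedSample) -> dict[str, float | bool]:
    try:
        r, p = pearson_corr(s)
        return {"r": r, "p": p, "significant": p < ALPHA, "degenerate": False}
    except ValueError:
        return {"r": np.nan, "p": np.nan, "significant": False, "degenerate": True}


def _safe_shapiro(x: np.ndarray) -> dict[str, float | bool]:
    if np.ptp(x) == 0:  # constant sample: normality is undefined
        return {"shapiro_w": np.nan, "shapiro_p": np.nan, "normal": False}
    try:
        w, p = shapiro_wilk(x)
        return {"shapiro_w": w, "shapiro_p": p, "normal": p >= ALPHA}
    except ValueError:
        return {"shapiro_w": np.nan, "shapiro_p": np.nan, "normal": False}


def _holm_adjust(df: pd.DataFrame) -> pd.DataFrame:
    """Append Holm-adjusted p-values and significance to a test table."""
    from statsmodels.stats.multitest import multipletests

    out = df.copy()
    mask = out["p"].notna()
    adjusted = np.full(len(out), np.nan)
    if mask.sum() > 0:
        reject, p_adj, _, _ = multipletests(out.loc[mask, "p"], alpha=ALPHA, method="holm")
        adjusted[mask.to_numpy()] = p_adj
    out["p_holm"] = adjusted
    out["significant_holm"] = out["p_holm"] < ALPHA
    return out


def run_study(
    cohort: Mapping[str, Mapping[str, ConditionRecord]], holm: bool = False
) -> StudyTables:
    """Assemble the full CFD-vs-TCD comparison from a cohort.

    ``cohort`` maps participant id -> condition -> :class:`ConditionRecord`;
    every participant must have all of ``rest``, ``hypercapnia`` and
    ``exercise``. Produces absolute distributions and paired inter-source
    tests per condition and metric, within-source stimulus-vs-rest tests,
    CFD-TCD correlations (absolute and relative change), tCBF-velocity
    correlations per source, and Bland-Altman agreement summaries.

    With ``holm=True`` the paired-test tables gain Holm-adjusted p-values;
    unadjusted two-sided tests at alpha = 0.05 are the default reporting
    convention.
    """
    if len(cohort) < 3:
        raise ValueError("run_study requires >= 3 participants")
    for pid, records in cohort.items():
        missing = set(CONDITIONS) - set(records)
        if missing:
            raise ValueError(f"participant {pid!r} missing conditions {sorted(missing)}")
    pids = sorted(cohort)

    dist_rows, inter_rows, vs_rest_rows, abs_corr_rows = [], [], [], []
    tcbf_rows, ba_abs_rows = [], []
    for condition in CONDITIONS:
        tcbf = np.array([cohort[p][condition].tcbf_ml_min for p in pids])
        for metric in METRIC_NAMES:
            s = _metric_vectors(cohort, condition, metric)
            for source, vals in (("TCD", s.values_a), ("CFD", s.values_b)):
                dist_rows.append(
                    {
                        "condition": condition,
                        "metric": metric,
                        "source": source,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)),
                        "n": s.n,
                        **_safe_shapiro(vals),
                    }
                )
            inter_rows.append(
                {
                    "condition": condition,
                    "metric": metric,
                    **_safe_paired_t(s),
                    **_safe_shapiro(s.values_a - s.values_b),
                }
            )
            abs_corr_rows.append({"condition": condition, "metric": metric, **_safe_pearson(s)})
            for source, vals in (("TCD", s.values_a), ("CFD", s.values_b)):
                tcbf_rows.append(
                    {
                        "condition": condition,
                        "metric": metric,
                        "source": source,
                        **_safe_pearson(PairedSample(tcbf, vals, tuple(pids))),
                    }
                )
            ba = bland_altman(s)
            ba_abs_rows.append(
                {"condition": condition, "metric": metric, **ba.__dict__}
            )

    # within-source stimulus vs rest
    for source in ("TCD", "CFD"):
        for stimulus in STIMULI:
            for metric in METRIC_NAMES:
                rest_vals = np.array(
                    [getattr(cohort[p]["rest"], source.lower()).as_dict()[metric] for p in pids]
                )
                stim_vals = np.array(
                    [getattr(cohort[p][stimulus], source.lower()).as_dict()[metric] for p in pids]
                )
                s = PairedSample(stim_vals, rest_vals, tuple(pids))
                vs_rest_rows.append(
                    {"source": source, "stimulus": stimulus, "metric": metric, **_safe_paired_t(s)}
                )

    # relative changes from rest
    rel_dist_rows, rel_inter_rows, rel_corr_rows, tcbf_rel_rows, ba_rel_rows = [], [], [], [], []
    for stimulus in STIMULI:
        deltas = _relative_deltas(cohort, stimulus)
        tcbf_rest = np.array([cohort[p]["rest"].tcbf_ml_min for p in pids])
        tcbf_stim = np.array([cohort[p][stimulus].tcbf_ml_min for p in pids])
        tcbf_delta = 100.0 * (tcbf_stim - tcbf_rest) / tcbf_rest
        for metric in METRIC_NAMES:
            tcd_d = np.array([deltas[p][0].as_dict()[metric] for p in pids])
            cfd_d = np.array([deltas[p][1].as_dict()[metric] for p in pids])
            s = PairedSample(tcd_d, cfd_d, tuple(pids))
            for source, vals in (("TCD", tcd_d), ("CFD", cfd_d)):
                rel_dist_rows.append(
                    {
                        "stimulus": stimulus,
                        "metric": metric,
                        "source": source,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)),
                        "n": s.n,
                        **_safe_shapiro(vals),
                    }
                )
                tcbf_rel_rows.append(
                    {
                        "stimulus": stimulus,
                        "metric": metric,
                        "source": source,
                        **_safe_pearson(PairedSample(tcbf_delta, vals, tuple(pids))),
                    }
                )
            rel_inter_rows.append({"stimulus": stimulus, "metric": metric, **_safe_paired_t(s)})
            rel_corr_rows.append({"stimulus": stimulus, "metric": metric, **_safe_pearson(s)})
            ba = bland_altman(s)
            ba_rel_rows.append({"stimulus": stimulus, "metric": metric, **ba.__dict__})

    inter_df = pd.DataFrame(inter_rows)
    vs_rest_df = pd.DataFrame(vs_rest_rows)
    rel_inter_df = pd.DataFrame(rel_inter_rows)
    if holm:
        inter_df = _holm_adjust(inter_df)
        vs_rest_df = _holm_adjust(vs_rest_df)
        rel_inter_df = _holm_adjust(rel_inter_df)
    return StudyTables(
        distributions=pd.DataFrame(dist_rows),
        paired_inter_source=inter_df,
        paired_vs_rest=vs_rest_df,
        abs_correlations=pd.DataFrame(abs_corr_rows),
        tcbf_correlations=pd.DataFrame(tcbf_rows),
        rel_distributions=pd.DataFrame(rel_dist_rows),
        paired_rel_inter_source=rel_inter_df,
        rel_correlations=pd.DataFrame(rel_corr_rows),
        tcbf_rel_correlations=pd.DataFrame(tcbf_rel_rows),
        bland_altman_abs=pd.DataFrame(ba_abs_rows),
        bland_altman_rel=pd.DataFrame(ba_rel_rows),
    )
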