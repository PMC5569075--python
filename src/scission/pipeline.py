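"""End-to-end analyses of the three experiments.

Each ``analyze_*`` function runs the stage sequence of its experiment —
predetermined subject exclusions, aggregation to per-subject condition
proportions, the named statistics — and returns a self-contained
:class:`AnalysisReport` whose JSON serialization is byte-reproducible for
identical inputs (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .completion_models import (
    ModelComparison,
    PiecewiseModelSpec,
    compare_models,
    fit_completion_model,
)
from .inference_stats import (
    beta_mode,
    fit_quadratic_lmm,
    lr_test,
    pearson_correlation,
    quadratic_peak,
    t_test,
)
from .stimuli import CENTER_LUMINANCE_LEVELS, build_star_stimulus, classify_color_configuration
from .synthetic_data import EXP2_CONDITIONS, RESPONSE_CATEGORIES

logger = logging.getLogger("scission.pipeline")

__all__ = [
    "ExclusionReport",
    "AnalysisReport",
    "MissingCellError",
    "AlignmentError",
    "aggregate_proportions",
    "apply_exclusions",
    "condition_completion_means",
    "analyze_exp1",
    "analyze_exp2",
    "analyze_exp3",
    "EXCLUSION_RULES",
]


def condition_completion_means(dataset: pd.DataFrame) -> dict[str, float]:
    """Across-subject mean completion proportion per condition id.

    The condition-level input to the experiment-3 correlation: each
    subject's completion proportion is computed per condition, then averaged
    over subjects.
    """
    per_subject, summary = aggregate_proportions(dataset, group_keys=("condition",))
    return dict(zip(summary["condition"], summary["completion_mean"].astype(float)))


class MissingCellError(ValueError):
    """A subject x condition cell has no trials."""


class AlignmentError(ValueError):
    """Rating and completion stimulus sets do not match."""


@dataclass(frozen=True)
class ExclusionReport:
    rule: str
    excluded_subjects: tuple[str, ...]
    retained_subjects: tuple[str, ...]
    no_afterimage_counts: dict[str, int]
    no_afterimage_fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "excluded_subjects": list(self.excluded_subjects),
            "retained_subjects": list(self.retained_subjects),
            "no_afterimage_counts": dict(self.no_afterimage_counts),
            "no_afterimage_fractions": dict(self.no_afterimage_fractions),
        }


@dataclass
class AnalysisReport:
    experiment: str
    aggregated: pd.DataFrame           # per subject x condition proportions
    summary: pd.DataFrame              # per condition mean / sem
    statistics: dict[str, Any]
    exclusions: list[ExclusionReport]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "aggregated": self.aggregated.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="records"),
            "statistics": self.statistics,
            "exclusions": [e.to_dict() for e in self.exclusions],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _config_hash(config: Mapping[str, Any] | None) -> str:
    blob = json.dumps(dict(config or {}), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: Mapping[str, Any] | None, **extra: Any) -> dict:
    return {
        "software_version": __version__,
        "config_hash": _config_hash(config),
        **extra,
    }


# ---------------------------------------------------------------------------
# aggregation and exclusions


def aggregate_proportions(
    dataset: pd.DataFrame,
    group_keys: Sequence[str] = ("condition",),
    categories: Sequence[str] = RESPONSE_CATEGORIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject response-category proportions plus condition-level summary.

    Returns ``(per_subject, summary)``: the first has one row per subject x
    condition with a proportion column per category (summing to 1); the
    second has per-condition across-subject mean and s.e.m. (sd / sqrt(n))
    of each category proportion.
    """
    if dataset.empty:
        raise ValueError("empty dataset")
    keys = ["subject_id", *group_keys]
    counts = (
        dataset.groupby(keys)["response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(categories), fill_value=0)
    )
    # every subject must contribute to every observed condition cell
    conditions = dataset[list(group_keys)].drop_duplicates()
    full_index = pd.MultiIndex.from_tuples(
        [
            (subj, *cond)
            for subj in dataset["subject_id"].unique()
            for cond in conditions.itertuples(index=False)
        ],
        names=keys,
    )
    missing = full_index.difference(counts.index)
    if len(missing):
        raise MissingCellError(f"cells with no trials: {list(missing)}")
    totals = counts.sum(axis=1)
    per_subject = counts.div(totals, axis=0)
    per_subject["n_trials"] = totals
    per_subject = per_subject.reset_index()

    grouped = per_subject.groupby(list(group_keys))
    summary = grouped[list(categories)].agg(["mean", "sem"])
    summary.columns = [f"{cat}_{stat}" for cat, stat in summary.columns]
    summary["n_subjects"] = grouped["subject_id"].nunique()
    return per_subject, summary.reset_index()


def _no_afterimage_stats(dataset: pd.DataFrame) -> tuple[dict[str, int], dict[str, float]]:
    by_subject = dataset.groupby("subject_id")["response"]
    counts = by_subject.apply(lambda s: int((s == "no_afterimage").sum())).to_dict()
    fracs = by_subject.apply(lambda s: float((s == "no_afterimage").mean())).to_dict()
    return counts, fracs


def _exclude_exp1(dataset: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    # predetermined rule: drop subjects with > 2/3 of trials lacking an afterimage
    counts, fracs = _no_afterimage_stats(dataset)
    excluded = tuple(s for s, f in fracs.items() if f > 2.0 / 3.0)
    retained = tuple(s for s in fracs if s not in excluded)
    report = ExclusionReport("no_afterimage_fraction > 2/3", excluded, retained,
                             counts, fracs)
    return dataset[dataset["subject_id"].isin(retained)].copy(), report


def _exclude_exp2(dataset: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    # predetermined rule: drop subjects with > 120 no-afterimage trials (strict)
    counts, fracs = _no_afterimage_stats(dataset)
    excluded = tuple(s for s, c in counts.items() if c > 120)
    retained = tuple(s for s in counts if s not in excluded)
    report = ExclusionReport("no_afterimage_count > 120", excluded, retained,
                             counts, fracs)
    return dataset[dataset["subject_id"].isin(retained)].copy(), report


EXCLUSION_RULES = {
    "exp1_no_afterimage_fraction": _exclude_exp1,
    "exp2_no_afterimage_count": _exclude_exp2,
}


def apply_exclusions(
    dataset: pd.DataFrame, rules: Sequence[str]
) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Apply named predetermined exclusion rules in order."""
    reports: list[ExclusionReport] = []
    out = dataset
    for name in rules:
        if name not in EXCLUSION_RULES:
            raise ValueError(
                f"unknown exclusion rule {name!r}; options: {sorted(EXCLUSION_RULES)}"
            )
        n_before = out["subject_id"].nunique()
        out, report = EXCLUSION_RULES[name](out)
        logger.info("exclusion %s: %d -> %d subjects", name, n_before,
                    len(report.retained_subjects))
        reports.append(report)
    return out, reports


# ---------------------------------------------------------------------------
# experiment 1

#: Nominal condition labels of the printed pairwise contrasts, mapped to the
#: exact luminance-level values.
NOMINAL_LEVELS = {34: 34.1, 55: 54.9, 121: 121.4, 169: 169.0}


def _completion_by_level(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table: one column of completion proportion per luminance."""
    return per_subject.pivot(index="subject_id", columns="center_luminance_cdm2",
                             values="completion")


def analyze_exp1(
    dataset: pd.DataFrame, config: Mapping[str, Any] | None = None
) -> AnalysisReport:
    """Full experiment-1 analysis.

    Stages: exclusions -> aggregation -> quadratic LMM + LR test -> one-sided
    paired contrasts of the transparency-region vs bright conditions ->
    one-sample tests of completion > 0 at the extreme luminances -> beta-mode
    summaries -> transparency vs equiluminance model comparison on the group
    means.
    """
    cfg = dict(config or {})
    b1 = float(cfg.get("b1_cdm2", 41.7))
    b2 = float(cfg.get("b2_cdm2", 84.0))

    logger.info("exp1: %d rows, %d subjects", len(dataset),
                dataset["subject_id"].nunique())
    data, excl = apply_exclusions(dataset, ["exp1_no_afterimage_fraction"])
    per_subject, summary = aggregate_proportions(
        data, group_keys=("center_luminance_cdm2", "coded_level")
    )
    stats: dict[str, Any] = {}

    # quadratic dependence on coded level, random intercept per subject
    lmm_table = per_subject.rename(columns={"completion": "proportion_completion"})
    full = fit_quadratic_lmm(lmm_table, include_quadratic=True)
    reduced = fit_quadratic_lmm(lmm_table, include_quadratic=False)
    chi2, df, p = lr_test(full, reduced)
    stats["lmm"] = {
        "full": full.to_dict(), "reduced": reduced.to_dict(),
        "lr_chi2": chi2, "lr_df": df, "lr_p": p,
    }
    if full.beta2 is not None and full.beta2 < 0:
        stats["lmm"]["peak_luminance_cdm2"] = quadratic_peak(full)

    # one-sided paired contrasts (transparency-region conditions higher)
    wide = _completion_by_level(per_subject)
    l34, l55 = NOMINAL_LEVELS[34], NOMINAL_LEVELS[55]
    l121, l169 = NOMINAL_LEVELS[121], NOMINAL_LEVELS[169]
    contrasts = {
        "34_55_vs_121_169": ((wide[l34] + wide[l55]) / 2,
                             (wide[l121] + wide[l169]) / 2),
        "34_vs_121": (wide[l34], wide[l121]),
        "55_vs_169": (wide[l55], wide[l169]),
    }
    stats["paired_one_sided"] = {
        name: t_test(a.to_numpy(), b.to_numpy(), sidedness="greater").to_dict()
        for name, (a, b) in contrasts.items()
    }

    # completion above zero at the extreme luminances
    lo, hi = CENTER_LUMINANCE_LEVELS[0], CENTER_LUMINANCE_LEVELS[-1]
    stats["above_zero_one_sided"] = {
        f"L{lev:g}": t_test(wide[lev].to_numpy(), sidedness="greater").to_dict()
        for lev in (lo, hi)
    }

    # beta-mode summaries of the per-subject averaged proportions
    extremes = ((wide[lo] + wide[hi]) / 2).to_numpy()
    plateau = ((wide[54.9] + wide[83.7]) / 2).to_numpy()
    stats["beta_modes"] = {
        "extremes_0.1_169": beta_mode(extremes).to_dict(),
        "plateau_55_84": beta_mode(plateau).to_dict(),
    }

    # competing completion models on the group means
    means = summary.sort_values("center_luminance_cdm2")
    xs = np.log10(means["center_luminance_cdm2"].to_numpy(dtype=float))
    ys = means["completion_mean"].to_numpy(dtype=float)
    fit_t = fit_completion_model(xs, ys, PiecewiseModelSpec.transparency(b1, b2))
    fit_e = fit_completion_model(xs, ys, PiecewiseModelSpec.equiluminance(b2))
    comparison = compare_models([fit_t, fit_e])
    stats["model_comparison"] = {
        "transparency": fit_t.to_dict(),
        "equiluminance": fit_e.to_dict(),
        "comparison": comparison.to_dict(),
    }

    return AnalysisReport(
        experiment="exp1",
        aggregated=per_subject,
        summary=summary,
        statistics=stats,
        exclusions=excl,
        provenance=_provenance(config, multiple_testing_correction="none"),
    )


# ---------------------------------------------------------------------------
# experiment 2


def _condition_transparency_flags() -> dict[str, bool]:
    """Transparency capability per experiment-2 condition, via the stimulus
    color-configuration classifier."""
    flags = {}
    for cond, scheme, outline, _expected in EXP2_CONDITIONS:
        stim = build_star_stimulus(center_luminance_cdm2=50.9,
                                   color_scheme=scheme, outline_target=outline)
        flags[cond] = classify_color_configuration(stim)
    return flags


def analyze_exp2(
    dataset: pd.DataFrame, config: Mapping[str, Any] | None = None
) -> AnalysisReport:
    """Full experiment-2 analysis.

    Stages: exclusions -> aggregation by transparency capability (classified
    from the stimulus color configuration) -> two-tailed paired t-tests per
    response category -> beta-mode of the non-transparent completion
    proportions.
    """
    logger.info("exp2: %d rows, %d subjects", len(dataset),
                dataset["subject_id"].nunique())
    data, excl = apply_exclusions(dataset, ["exp2_no_afterimage_count"])
    flags = _condition_transparency_flags()
    unknown = set(data["condition"].unique()) - set(flags)
    if unknown:
        raise ValueError(f"conditions without a stimulus definition: {sorted(unknown)}")
    data = data.assign(
        transparent=data["condition"].map(flags).map({True: "transparent",
                                                      False: "non_transparent"})
    )
    per_subject, summary = aggregate_proportions(data, group_keys=("transparent",))
    wide = {
        cat: per_subject.pivot(index="subject_id", columns="transparent",
                               values=cat)
        for cat in RESPONSE_CATEGORIES
    }
    stats: dict[str, Any] = {"paired_two_sided": {}}
    for cat in RESPONSE_CATEGORIES:
        w = wide[cat]
        stats["paired_two_sided"][cat] = t_test(
            w["transparent"].to_numpy(), w["non_transparent"].to_numpy(),
            sidedness="two",
        ).to_dict()
    stats["beta_mode_non_transparent"] = beta_mode(
        wide["completion"]["non_transparent"].to_numpy()
    ).to_dict()

    return AnalysisReport(
        experiment="exp2",
        aggregated=per_subject,
        summary=summary,
        statistics=stats,
        exclusions=excl,
        provenance=_provenance(config, multiple_testing_correction="none"),
    )


# ---------------------------------------------------------------------------
# experiment 3


def _completion_means_by_condition(report: AnalysisReport) -> dict[str, float]:
    """Across-subject mean completion per condition from an analysis report."""
    if report.experiment == "exp1":
        return {
            f"L{row.center_luminance_cdm2:g}": float(row.completion_mean)
            for row in report.summary.itertuples()
        }
    per_subject = report.aggregated
    # exp2 summary is aggregated by transparency; recover per-condition means
    raise ValueError("per-condition means unavailable; pass a mapping instead")


def analyze_exp3(
    ratings: pd.DataFrame,
    exp1_completion_means: Mapping[str, float] | AnalysisReport,
    exp2_completion_means: Mapping[str, float],
    config: Mapping[str, Any] | None = None,
) -> AnalysisReport:
    """Correlate per-stimulus transparency ratings with completion rates.

    ``ratings`` is a trial-level dataset with transparent / not_transparent
    responses.  Completion means are supplied per stimulus id for each
    experiment family (9 stimuli for experiment 1, 8 for experiment 2) and
    correlated with the across-subject mean rating, separately per family.
    """
    if isinstance(exp1_completion_means, AnalysisReport):
        exp1_completion_means = _completion_means_by_condition(exp1_completion_means)
    logger.info("exp3: %d rows, %d subjects", len(ratings),
                ratings["subject_id"].nunique())
    per_subject, summary = aggregate_proportions(
        ratings, group_keys=("condition",),
        categories=("transparent", "not_transparent"),
    )
    rating_means = dict(zip(summary["condition"], summary["transparent_mean"]))

    stats: dict[str, Any] = {}
    for family, completion in (("exp1", dict(exp1_completion_means)),
                               ("exp2", dict(exp2_completion_means))):
        matched = set(completion) & set(rating_means)
        missing = sorted(set(completion) - matched)
        if missing:
            raise AlignmentError(
                f"{family} stimuli without ratings: {missing}"
            )
        conds = sorted(completion)
        x = [completion[c] for c in conds]
        y = [rating_means[c] for c in conds]
        r, p = pearson_correlation(x, y)
        stats[f"correlation_{family}"] = {"n": len(conds), "r": r, "p": p,
                                          "stimuli": conds}

    return AnalysisReport(
        experiment="exp3",
        aggregated=per_subject,
        summary=summary,
        statistics=stats,
        exclusions=[],
        provenance=_provenance(config),
    )
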