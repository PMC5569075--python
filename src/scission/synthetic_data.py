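"""Synthetic trial-level datasets with the structure of the three experiments.

The generator emulates the statistical skeleton of the behavioral data so
the full analysis pipeline can run without human subjects:

* Experiment 1 — each subject sees 9 center luminances; responses are
  3-category multinomial (completion / no-completion / no-afterimage).  The
  completion probability follows the transparency-plateau curve on log10
  luminance, shifted by a subject-level random intercept on the probability
  scale and clipped into the feasible range.
* Experiment 2 — 8 stimulus conditions at a fixed center luminance, half
  transparency-capable (bicolor, either sub-star outlined) and half uniform;
  condition completion probabilities default to the observed means, with
  subject intercepts shared across conditions.
* Experiment 3 — per-stimulus Bernoulli transparency ratings whose
  probability is a noisy linear function of that stimulus's completion rate.

Default parameters are chosen to mirror the reported condition means (peak
completion 0.54, extremes ~0.30/0.28, experiment-2 conditions 0.46 vs 0.16).
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .completion_models import PiecewiseModelSpec, PiecewiseParams, eval_completion_model
from .stimuli import CENTER_LUMINANCE_LEVELS

__all__ = [
    "GeneratorConfig",
    "RESPONSE_CATEGORIES",
    "EXP2_CONDITIONS",
    "generate_exp1_dataset",
    "generate_exp2_dataset",
    "generate_exp3_ratings",
    "exp3_rating_probabilities",
    "exp1_stimulus_ids",
    "exp2_stimulus_ids",
    "write_trials",
    "read_trials",
]

RESPONSE_CATEGORIES = ("completion", "no_completion", "no_afterimage")

#: Experiment-2 conditions: (condition id, color scheme, outline target,
#: transparency-capable).  The two bicolor schemes appear once per outlined
#: sub-star, giving 4 transparent and 4 uniform stimulus conditions.
EXP2_CONDITIONS: tuple[tuple[str, str, str, bool], ...] = (
    ("red_green_outline_a", "red_green", "substar_a", True),
    ("red_green_outline_b", "red_green", "substar_b", True),
    ("blue_yellow_outline_a", "blue_yellow", "substar_a", True),
    ("blue_yellow_outline_b", "blue_yellow", "substar_b", True),
    ("uniform_red", "uniform_red", "substar_a", False),
    ("uniform_green", "uniform_green", "substar_a", False),
    ("uniform_blue", "uniform_blue", "substar_a", False),
    ("uniform_yellow", "uniform_yellow", "substar_a", False),
)

EXP2_CENTER_LUMINANCE = 50.9  # fixed gray center in experiment 2 (cd/m^2)

TRIAL_COLUMNS = (
    "subject_id",
    "experiment",
    "condition",
    "color_scheme",
    "center_luminance_cdm2",
    "coded_level",
    "response",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic experiments.

    Counts mirror the retained samples of the experiments (12 / 20 / 16
    subjects); 20 trials per condition matches the stated experiment-3
    repetition count and is used throughout.  The completion curve defaults
    to the transparency model with plateau M = 0.54 and slopes chosen so the
    extreme-luminance means are ~0.30 and ~0.28; the no-afterimage rate is a
    luminance-independent 0.15; subject intercepts have SD 0.15 on the
    probability scale.
    """

    n_subjects: int = 12
    trials_per_condition: int = 20
    m: float = 0.54
    s1: float = 0.09
    s2: float = 0.85
    b1_cdm2: float = 41.7
    b2_cdm2: float = 84.0
    p_no_afterimage: float = 0.15
    sigma_subject: float = 0.15
    exp2_n_subjects: int = 20
    exp2_p_transparent: float = 0.46
    exp2_p_nontransparent: float = 0.16
    exp3_n_subjects: int = 16
    exp3_alpha: float = 0.05
    exp3_link_slope: float = 1.0
    exp3_noise: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m", "p_no_afterimage", "exp2_p_transparent",
                     "exp2_p_nontransparent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_subjects", "trials_per_condition", "exp2_n_subjects",
                     "exp3_n_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("s1", "s2", "sigma_subject", "exp3_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def model_spec(self) -> PiecewiseModelSpec:
        return PiecewiseModelSpec.transparency(self.b1_cdm2, self.b2_cdm2)

    @property
    def model_params(self) -> PiecewiseParams:
        return PiecewiseParams(m=self.m, s1=self.s1, s2=self.s2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _subject_ids(n: int, prefix: str = "s") -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def _draw_trials(rng: np.random.Generator, probs: Sequence[float], n: int) -> np.ndarray:
    """Draw ``n`` categorical responses with the given category probabilities."""
    counts = rng.multinomial(n, probs)
    resp = np.repeat(np.arange(len(probs)), counts)
    rng.shuffle(resp)
    return resp


def generate_exp1_dataset(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Trial-level experiment-1 dataset: 9 luminance levels per subject.

    Per subject s and level l the completion probability is
    ``clip(C(log10 L_l) + b_s, 0, 1 - p_no_afterimage)`` with
    ``b_s ~ N(0, sigma_subject)``; trials are drawn from the resulting
    3-category multinomial.  The color scheme alternates red/green and
    blue/yellow across trials (metadata only; it does not affect response
    probabilities here).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sid in _subject_ids(cfg.n_subjects):
        b_s = rng.normal(0.0, cfg.sigma_subject)
        for level, lum in enumerate(CENTER_LUMINANCE_LEVELS, start=1):
            c = eval_completion_model(cfg.model_spec, cfg.model_params,
                                      math.log10(lum))
            p_comp = float(np.clip(c + b_s, 0.0, 1.0 - cfg.p_no_afterimage))
            probs = (p_comp, 1.0 - p_comp - cfg.p_no_afterimage,
                     cfg.p_no_afterimage)
            resp = _draw_trials(rng, probs, cfg.trials_per_condition)
            for t, r in enumerate(resp):
                rows.append(
                    (sid, "exp1", f"L{lum:g}",
                     "red_green" if t % 2 == 0 else "blue_yellow",
                     lum, level, RESPONSE_CATEGORIES[r])
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_exp2_dataset(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Trial-level experiment-2 dataset: 8 conditions at a fixed center gray.

    Subject intercepts are shared across conditions, so the transparent vs
    uniform contrast is within-subject.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sid in _subject_ids(cfg.exp2_n_subjects):
        b_s = rng.normal(0.0, cfg.sigma_subject)
        for cond, scheme, _outline, transparent in EXP2_CONDITIONS:
            base = cfg.exp2_p_transparent if transparent else cfg.exp2_p_nontransparent
            p_comp = float(np.clip(base + b_s, 0.0, 1.0 - cfg.p_no_afterimage))
            probs = (p_comp, 1.0 - p_comp - cfg.p_no_afterimage,
                     cfg.p_no_afterimage)
            resp = _draw_trials(rng, probs, cfg.trials_per_condition)
            for r in resp:
                rows.append((sid, "exp2", cond, scheme, EXP2_CENTER_LUMINANCE,
                             np.nan, RESPONSE_CATEGORIES[r]))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def exp1_stimulus_ids() -> list[str]:
    return [f"L{lum:g}" for lum in CENTER_LUMINANCE_LEVELS]


def exp2_stimulus_ids() -> list[str]:
    return [cond for cond, *_ in EXP2_CONDITIONS]


def exp3_rating_probabilities(
    config: GeneratorConfig,
    condition_completion_means: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Per-stimulus transparency-rating probabilities from the noisy link.

    ``p_rate = clip(alpha + slope * completion_mean + N(0, noise), 0, 1)``,
    with one noise draw per stimulus.  With ``exp3_noise = 0``, slope 1 and
    alpha 0 this is the identity link.
    """
    for k, v in condition_completion_means.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"completion mean for {k!r} outside [0, 1]: {v}")
    rng = rng or np.random.default_rng(config.seed)
    return {
        cond: float(np.clip(
            config.exp3_alpha + config.exp3_link_slope * mean
            + (rng.normal(0.0, config.exp3_noise) if config.exp3_noise > 0 else 0.0),
            0.0, 1.0,
        ))
        for cond, mean in condition_completion_means.items()
    }


def generate_exp3_ratings(
    config: GeneratorConfig,
    condition_completion_means: Mapping[str, float],
) -> pd.DataFrame:
    """Trial-level transparency ratings linked to completion rates.

    Each subject rates each stimulus ``trials_per_condition`` times (default
    20); the Bernoulli probability per stimulus comes from
    :func:`exp3_rating_probabilities`.
    """
    rng = np.random.default_rng(config.seed)
    p_rate = exp3_rating_probabilities(config, condition_completion_means, rng)
    rows = []
    for sid in _subject_ids(config.exp3_n_subjects):
        for cond, p in p_rate.items():
            draws = rng.random(config.trials_per_condition) < p
            for d in draws:
                rows.append((sid, "exp3", cond, "", np.nan, np.nan,
                             "transparent" if d else "not_transparent"))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# CSV round-trip

def write_trials(df: pd.DataFrame, path: str | Path,
                 seed: int | None = None,
                 config: GeneratorConfig | None = None) -> None:
    """Write a tidy trial CSV plus a JSON sidecar recording seed/config."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {"seed": seed if seed is not None else (config.seed if config else None)}
    if config is not None:
        sidecar["config"] = asdict(config)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a tidy trial CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    bad = set(df["response"].dropna().unique()) - set(RESPONSE_CATEGORIES) - {
        "transparent", "not_transparent"}
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    df["color_scheme"] = df["color_scheme"].fillna("")
    return df[list(TRIAL_COLUMNS)]
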