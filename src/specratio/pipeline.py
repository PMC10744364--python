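"""End-to-end orchestration of the power-ratio study.

For every (FFT parameterization x reference) configuration the pipeline
computes lobar band powers, the 65 power ratios, the Mann-Whitney/BH
feature screen, ROC / PR / Youden-cutoff diagnostics and a stepwise
logistic model for the headline markers, and finally a cross-configuration
consistency report: a feature is tier-consistent when it is BH-significant
below the tier with the same direction in every configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .cohort import SyntheticCohortSpec, generate_cohort
from .io import read_bids_cohort, subjects_to_frame
from .modeling import stepwise_select
from .montage import LobeMap
from .referencing import average_reference, build_head_model, rest_reference
from .spectral import BandScheme, SpectralParams, cohort_band_powers, power_ratios
from .stats import demographics_table, screen_features

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ConfigResult",
    "AnalysisBundle",
    "run_analysis",
    "consistency_report",
]

HEADLINE_MARKERS = (
    "F-theta/T-alpha",
    "F-alpha/T-theta",
    "F-theta/F-alpha",
    "T-beta/T-gamma",
)

REFERENCES = ("average", "rest")


@dataclass
class AnalysisConfig:
    """Study configuration.

    ``configurations`` are (window_s, steps_per_hz, reference) triples; the
    default set is the study grid: 2 s/10, 2 s/5 and 1 s/10 under the
    average reference plus 2 s/10 under REST.
    """

    configurations: tuple = (
        (2.0, 10, "average"),
        (2.0, 5, "average"),
        (1.0, 10, "average"),
        (2.0, 10, "rest"),
    )
    bands: BandScheme = field(default_factory=BandScheme)
    lobes: LobeMap = field(default_factory=LobeMap)
    prevalence: float = 0.5
    bootstrap: diag.BootstrapConfig = field(default_factory=diag.BootstrapConfig)
    tiers: tuple[float, ...] = (0.05, 0.01)
    headline_markers: tuple[str, ...] = HEADLINE_MARKERS
    logistic_covariates: tuple[str, ...] = ("age", "sex")
    with_diagnostics: bool = True
    with_model: bool = True

    def __post_init__(self):
        if not self.configurations:
            raise ValueError("need at least one configuration")
        for cfg in self.configurations:
            w, s, ref = cfg
            if ref not in REFERENCES:
                raise ValueError(
                    f"unknown reference {ref!r} in configuration {cfg}; "
                    f"expected one of {REFERENCES}"
                )
            SpectralParams(window_s=w, steps_per_hz=s)  # validates
        if list(self.tiers) != sorted(self.tiers, reverse=True):
            raise ValueError("tiers must be ordered loosest first")


def config_label(window_s, steps_per_hz, reference) -> str:
    w = f"{window_s:g}"
    lab = f"{w}s-{steps_per_hz}"
    return lab if reference == "average" else f"{lab}-REST"


@dataclass
class ConfigResult:
    label: str
    band_power: pd.DataFrame
    ratios: pd.DataFrame
    screen: pd.DataFrame
    diagnostics: pd.DataFrame | None = None
    roc: dict = field(default_factory=dict)
    pr: dict = field(default_factory=dict)
    model: object | None = None


@dataclass
class AnalysisBundle:
    configs: dict[str, ConfigResult]
    consistency: pd.DataFrame
    demographics: pd.DataFrame
    subjects: pd.DataFrame

    def save(self, out_dir) -> Path:
        """Write the bundle as TSV tables plus a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        self.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
        self.consistency.to_csv(out / "consistency.tsv", sep="\t")
        summary = {"configurations": list(self.configs)}
        for label, res in self.configs.items():
            d = out / label
            d.mkdir(exist_ok=True)
            res.band_power.to_csv(d / "band_power.tsv", sep="\t")
            res.ratios.to_csv(d / "ratios.tsv", sep="\t")
            res.screen.to_csv(d / "screen.tsv", sep="\t", index=False)
            if res.diagnostics is not None:
                res.diagnostics.to_csv(d / "diagnostics.tsv", sep="\t")
            if res.model is not None:
                res.model.table.to_csv(d / "logistic.tsv", sep="\t")
                summary.setdefault("logistic", {})[label] = {
                    "selected": res.model.selected,
                    "accuracy": res.model.accuracy,
                    "note": res.model.note,
                }
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=str)
        return out


_MODEL_CACHE: dict[tuple, object] = {}


def _cached_head_model(labels):
    key = tuple(labels)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = build_head_model(labels)
    return _MODEL_CACHE[key]


def _reference_recordings(recordings, reference):
    """Average-reference everything; REST additionally passes data through
    the spherical-model transfer matrix (head model cached per montage)."""
    avg = [average_reference(r) for r in recordings]
    if reference == "average":
        return avg
    return [rest_reference(rec, _cached_head_model(rec.labels)) for rec in avg]


def marker_diagnostics(values: pd.Series, is_pos: np.ndarray,
                       config: AnalysisConfig):
    """Full diagnostic work-up of one marker: ROC (DeLong), PR (logit CI),
    Youden cutoff with bootstrap CIs, PPV/NPV at the configured prevalence."""
    mask = values.notna().to_numpy()
    scores = values.to_numpy(dtype=float)[mask]
    labels = np.asarray(is_pos, dtype=int)[mask]
    roc = diag.roc_auc_delong(scores, labels)
    pr = diag.pr_curve(scores, labels)
    report = diag.youden_cutoff(scores, labels, prevalence=config.prevalence)
    cutoff_ci, youden_ci = diag.bootstrap_cutoff_ci(
        scores, labels, config.bootstrap, direction=report.direction
    )
    report.cutoff_ci = cutoff_ci
    report.youden_ci = youden_ci
    return roc, pr, report


def _diagnostics_table(roc_map, pr_map, cut_map) -> pd.DataFrame:
    rows = {}
    for name in roc_map:
        roc, pr, cut = roc_map[name], pr_map[name], cut_map[name]
        rows[name] = {
            "roc_auc": roc.auc,
            "roc_se": roc.se,
            "roc_ci_lo": roc.ci95[0],
            "roc_ci_hi": roc.ci95[1],
            "pr_auc": pr.auc,
            "pr_ci_lo": pr.ci95[0],
            "pr_ci_hi": pr.ci95[1],
            "cutoff": cut.cutoff,
            "direction": cut.direction,
            "cutoff_ci_lo": cut.cutoff_ci[0],
            "cutoff_ci_hi": cut.cutoff_ci[1],
            "sensitivity": cut.sensitivity,
            "sens_ci_lo": cut.sensitivity_ci[0],
            "sens_ci_hi": cut.sensitivity_ci[1],
            "specificity": cut.specificity,
            "spec_ci_lo": cut.specificity_ci[0],
            "spec_ci_hi": cut.specificity_ci[1],
            "youden_j": cut.youden_j,
            "youden_ci_lo": cut.youden_ci[0],
            "youden_ci_hi": cut.youden_ci[1],
            "ppv": cut.ppv,
            "ppv_ci_lo": cut.ppv_ci[0],
            "ppv_ci_hi": cut.ppv_ci[1],
            "npv": cut.npv,
            "npv_ci_lo": cut.npv_ci[0],
            "npv_ci_hi": cut.npv_ci[1],
        }
    return pd.DataFrame(rows).T.rename_axis("marker")


def run_analysis(cohort, config: AnalysisConfig | None = None) -> AnalysisBundle:
    """Run the full study over a cohort.

    ``cohort`` may be a :class:`SyntheticCohortSpec` (generated on the
    fly), a path to a BIDS-style directory, or an explicit
    ``(recordings, subjects)`` tuple. Each configuration runs
    independently; a failing stage is logged and skipped.
    """
    config = config or AnalysisConfig()
    if isinstance(cohort, SyntheticCohortSpec):
        recordings, subjects = generate_cohort(cohort)
    elif isinstance(cohort, (str, Path)):
        recordings, subjects = read_bids_cohort(cohort)
    else:
        recordings, subjects = cohort
    subj_df = subjects_to_frame(subjects)
    groups = pd.Series(subj_df["group"].to_numpy(), index=subj_df["subject_id"])
    if (groups == "FTD").sum() < 2 or (groups == "CTL").sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    is_pos = (subj_df["group"] == "FTD").to_numpy()

    referenced: dict[str, list] = {}
    results: dict[str, ConfigResult] = {}
    for window_s, steps, reference in config.configurations:
        label = config_label(window_s, steps, reference)
        try:
            if reference not in referenced:
                referenced[reference] = _reference_recordings(recordings, reference)
            recs = referenced[reference]
            params = SpectralParams(
                window_s=window_s, steps_per_hz=steps, fs=recs[0].fs
            )
            bpt = cohort_band_powers(recs, subjects, params, config.lobes,
                                     config.bands)
            ratios = power_ratios(bpt)
            features = pd.concat([bpt, ratios], axis=1)
            screen = screen_features(features, groups)
            result = ConfigResult(label, bpt, ratios, screen)
            if config.with_diagnostics:
                roc_map, pr_map, cut_map = {}, {}, {}
                for marker in config.headline_markers:
                    roc, pr, cut = marker_diagnostics(
                        ratios[marker], is_pos, config
                    )
                    roc_map[marker], pr_map[marker], cut_map[marker] = roc, pr, cut
                result.roc, result.pr = roc_map, pr_map
                result.diagnostics = _diagnostics_table(roc_map, pr_map, cut_map)
            if config.with_model:
                design = ratios[list(config.headline_markers)].copy()
                if "age" in config.logistic_covariates:
                    design["age"] = subj_df["age"].to_numpy()
                if "sex" in config.logistic_covariates:
                    design["sex"] = (subj_df["sex"] == "F").astype(float).to_numpy()
                result.model = stepwise_select(design.dropna(), is_pos)
            results[label] = result
        except Exception:
            logger.exception("configuration %s failed; continuing", label)
    if not results:
        raise RuntimeError("every configuration failed")
    screens = {lab: res.screen for lab, res in results.items()}
    consistency = (
        consistency_report(screens, config.tiers)
        if len(screens) >= 2
        else _single_config_consistency(next(iter(screens.values())), config.tiers)
    )
    return AnalysisBundle(
        configs=results,
        consistency=consistency,
        demographics=demographics_table(subjects),
        subjects=subj_df,
    )


def _single_config_consistency(screen: pd.DataFrame, tiers) -> pd.DataFrame:
    out = screen.set_index("feature")[["p_adj", "direction"]].copy()
    for tier in tiers:
        out[f"tier_{tier}"] = out["p_adj"] < tier
    return out.drop(columns=["p_adj", "direction"])


def consistency_report(screens: dict[str, pd.DataFrame], tiers=(0.05, 0.01)
                       ) -> pd.DataFrame:
    """Cross-configuration agreement table.

    A feature passes a tier iff its BH-adjusted p is below the tier with
    the same group direction in every configuration. Configurations with
    differing feature sets are intersected (logged).
    """
    if len(screens) < 2:
        raise ValueError("need at least 2 configurations")
    sets = [set(s["feature"]) for s in screens.values()]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no common features across configurations")
    if any(s - common for s in sets):
        logger.warning(
            "feature sets differ across configurations; using the "
            "%d-feature intersection", len(common)
        )
    frames = {
        lab: s.set_index("feature").loc[sorted(common)]
        for lab, s in screens.items()
    }
    first = next(iter(frames.values()))
    same_dir = pd.Series(True, index=first.index)
    for f in frames.values():
        same_dir &= f["direction"] == first["direction"]
    out = pd.DataFrame(index=first.index)
    for tier in tiers:
        passing = pd.Series(True, index=first.index)
        for f in frames.values():
            passing &= f["p_adj"] < tier
        out[f"tier_{tier}"] = passing & same_dir
    out["direction"] = first["direction"].where(same_dir, "inconsistent")
    return out
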