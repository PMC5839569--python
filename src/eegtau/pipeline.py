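"""End-to-end orchestration: simulate/load -> preprocess -> features ->
classify -> report, with fixed artifact layouts and resolved-config logging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acf import tau_timecourse
from .classify import (
    CvScheme,
    binomial_threshold,
    detect_timing,
    select_best_channel,
    sensitivity_curve,
)
from .erd import ErdConfig, single_trial_erd
from .errors import ConfigurationError, EmptySetError
from .groupstats import band_comparison, feature_comparison, tau_tap_vs_rest_test
from .prep import (
    STANDARD_BANDS,
    BipolarScheme,
    WindowSpec,
    apply_filters,
    epoch_trials,
    load_events,
    load_recording,
    to_bipolar,
)
from .synth import SynthConfig, generate_session

logger = logging.getLogger(__name__)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_log(outdir: Path, config: dict) -> None:
    resolved = dict(config)
    resolved["eegtau_version"] = __version__
    (outdir / "run_config.json").write_text(json.dumps(resolved, indent=2,
                                                       default=str))


def preprocess_session(recording, events, scheme: BipolarScheme | None = None,
                       span=(3.0, 3.0)):
    """Filter chain -> bipolar montage -> epoching, as one step."""
    filtered = apply_filters(recording)
    bipolar = to_bipolar(filtered, scheme or BipolarScheme())
    return epoch_trials(bipolar, events, span=span)


def analyze_session(
    trials,
    feature: str = "acf",
    band: str = "wide",
    tap_conditions=("right",),
    scheme: CvScheme | None = None,
    alpha: float = 0.05,
):
    """Feature table, per-channel curves, and detection for one session.

    Returns (features_df, curves, threshold, best_channel, detection).
    """
    scheme = scheme or CvScheme()
    spec = WindowSpec()
    if feature == "acf":
        feats = tau_timecourse(trials, band=band, spec=spec)
    elif feature == "erd":
        feats = single_trial_erd(trials, ErdConfig(band=band), spec=spec)
    else:
        raise ConfigurationError(f"unknown feature {feature!r}")
    if isinstance(tap_conditions, str):
        tap_conditions = (tap_conditions,)
    n_tap = len({
        t for t, c in zip(feats["trial"], feats["condition"])
        if c in tap_conditions
    })
    threshold = binomial_threshold(n_tap, alpha)
    curves = {}
    for ch, grp in feats.groupby("channel", sort=False):
        curves[ch] = sensitivity_curve(grp, scheme,
                                       tap_conditions=tap_conditions)
    best, detection = select_best_channel(curves, threshold, n_tap, alpha)
    return feats, curves, threshold, best, detection


def run_pipeline(
    outdir,
    synth_config: SynthConfig | None = None,
    recording_path=None,
    events_path=None,
    feature: str = "acf",
    bands=("wide",),
    tap_conditions=("right",),
    cv_seed: int = 0,
    alpha: float = 0.05,
    scheme: BipolarScheme | None = None,
) -> Path:
    """Run one participant end to end and write the artifact directory.

    Artifacts: events.tsv, features_<feature>_<band>.tsv, per-channel curve
    TSVs, summary_<feature>_<band>.json, tau t-test report, run_config.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in bands:
        if isinstance(b, str) and b not in STANDARD_BANDS:
            raise ConfigurationError(f"unknown band name {b!r}")

    if recording_path is not None:
        rec = load_recording(recording_path)
        events = load_events(events_path, rec.fs)
        input_hashes = {str(recording_path): _hash_file(Path(recording_path)),
                        str(events_path): _hash_file(Path(events_path))}
        cfg_dict = {"input": str(recording_path)}
    else:
        synth_config = synth_config or SynthConfig()
        rec, events = generate_session(synth_config)
        input_hashes = {}
        cfg_dict = {"synth": dataclasses.asdict(synth_config)}

    from .prep import write_events

    write_events(events, outdir / "events.tsv")
    trials = preprocess_session(rec, events, scheme=scheme)

    cv = CvScheme(seed=cv_seed)
    for band in bands:
        feats, curves, threshold, best, det = analyze_session(
            trials, feature=feature, band=band,
            tap_conditions=tap_conditions, scheme=cv, alpha=alpha,
        )
        feats.to_csv(outdir / f"features_{feature}_{band}.tsv", sep="\t",
                     index=False, float_format="%.6g")
        for ch, curve in curves.items():
            safe = ch.replace("-", "")
            curve.to_csv(outdir / f"curve_{feature}_{band}_{safe}.tsv",
                         sep="\t", index=False, float_format="%.6g")
        summary = {
            "feature": feature,
            "band": band,
            "threshold": threshold,
            "best_channel": best,
            "peak_sensitivity": det.peak_sensitivity,
            "peak_time_s": det.peak_time,
            "first_crossing_time_s": det.first_crossing_time,
            "cv_seed": cv_seed,
            "scheme": dataclasses.asdict(cv),
        }
        (outdir / f"summary_{feature}_{band}.json").write_text(
            json.dumps(summary, indent=2)
        )
        if feature == "acf":
            best_feats = feats[feats["channel"] == best]
            try:
                rep = tau_tap_vs_rest_test(best_feats,
                                           tap_conditions=tap_conditions,
                                           alpha=alpha)
                (outdir / f"ttest_{band}.json").write_text(
                    json.dumps(dataclasses.asdict(rep), indent=2)
                )
            except Exception as exc:  # degenerate sessions only
                logger.warning("tau t-test skipped: %s", exc)

    cfg_dict.update({"feature": feature, "bands": list(bands),
                     "cv_seed": cv_seed, "alpha": alpha,
                     "input_hashes": input_hashes})
    _write_log(outdir, cfg_dict)
    return outdir


def run_cohort(
    outdir,
    n_participants: int = 8,
    base_seed: int = 0,
    feature: str = "acf",
    bands=("low", "mu", "beta", "wide"),
    synth_config: SynthConfig | None = None,
    cv_scheme: CvScheme | None = None,
    alpha: float = 0.05,
    scheme: BipolarScheme | None = None,
    tap_conditions=("right",),
) -> pd.DataFrame:
    """Simulated cohort: independent seeded sessions stand in for
    participants.  Returns the participant summary table and writes the
    group-statistics reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_cfg = synth_config or SynthConfig()
    rows = []
    for p in range(n_participants):
        cfg = dataclasses.replace(base_cfg, seed=base_seed + 7919 * p)
        rec, events = generate_session(cfg)
        trials = preprocess_session(rec, events, scheme=scheme)
        cv = cv_scheme or CvScheme(seed=base_seed + p)
        for band in bands:
            _, _, threshold, best, det = analyze_session(
                trials, feature=feature, band=band, scheme=cv,
                alpha=alpha, tap_conditions=tap_conditions,
            )
            rows.append((p, band, feature, det.peak_sensitivity,
                         det.first_crossing_time, best, threshold))
    summaries = pd.DataFrame(
        rows, columns=["participant", "band", "feature", "peak_sensitivity",
                       "first_crossing_time", "best_channel", "threshold"],
    )
    summaries.to_csv(outdir / f"cohort_{feature}.tsv", sep="\t", index=False,
                     float_format="%.6g")
    try:
        reports = band_comparison(summaries, feature, alpha=alpha,
                                  bands=tuple(bands))
        pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
            outdir / f"band_tests_{feature}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
    except EmptySetError as exc:
        logger.warning("band comparison skipped: %s", exc)
    return summaries


def report_from_summaries(summaries: pd.DataFrame, outdir,
                          alpha: float = 0.05) -> None:
    """Write TSV test reports and a plain-text digest from a summary table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["Participant summaries", "=" * 21, ""]
    for feature in sorted(summaries["feature"].unique()):
        sub = summaries[summaries["feature"] == feature]
        lines.append(f"feature={feature}: mean peak sensitivity "
                     f"{100 * sub['peak_sensitivity'].mean():.2f}% "
                     f"+- {100 * sub['peak_sensitivity'].std():.2f}%")
        times = sub["first_crossing_time"].dropna()
        if len(times):
            lines.append(f"  mean detection time {times.mean():+.2f} s "
                         f"({len(times)} detections)")
        try:
            reports = band_comparison(summaries, feature, alpha=alpha)
            pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
                outdir / f"band_tests_{feature}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            n_rej = sum(r.reject for r in reports)
            lines.append(f"  band pairs rejected (Holm): {n_rej}/6")
        except Exception as exc:
            lines.append(f"  band comparison unavailable: {exc}")
    if set(summaries["feature"].unique()) >= {"acf", "erd"}:
        rep = feature_comparison(summaries)
        lines.append(f"acf vs erd pooled: W={rep.statistic:.1f} "
                     f"p={rep.p_value:.3g} reject={rep.reject}")
        (outdir / "feature_test.json").write_text(
            json.dumps(dataclasses.asdict(rep), indent=2)
        )
    summaries.to_csv(outdir / "participant_summaries.tsv", sep="\t",
                     index=False, float_format="%.6g")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
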