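"""End-to-end orchestration: simulate -> score -> aggregate -> associate ->
predict, with delimited-text outputs, a run manifest, and a plain-text
report of what each stage kept and discarded."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import iiv, prediction
from .associations import (association_table, compare_proportions_chisq,
                           flag_sleep_problems, partial_spearman)
from .config import RunConfig
from .io import write_table
from .scoring import nights_to_frame, score_night

log = logging.getLogger("sleepvar")


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    config.save(outdir / "manifest.yaml")


def stage_simulate(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a synthetic cohort."""
    outdir = Path(outdir)
    data = cohort_mod.generate_cohort(
        n_asd=config.cohort.n_asd, n_td=config.cohort.n_td, seed=config.seed)
    paths = cohort_mod.write_cohort(data, outdir)
    _write_manifest(outdir, config)
    log.info("simulate: %d participants, %d nights written to %s",
             len(data.profiles), len(data.epochs), outdir)
    return paths


def _load_overrides(path: str | None) -> dict[tuple[str, str], tuple[int, int]]:
    if not path:
        return {}
    df = pd.read_csv(path)
    return {(str(r.participant_id), str(r.date)): (int(r.start), int(r.end))
            for r in df.itertuples()}


def stage_score(config: RunConfig, epochs_path: str | Path, outdir: str | Path) -> Path:
    """Score every night in an epoch file into the nights table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(epochs_path)
    series_list = cohort_mod.frame_to_epochs(df)
    overrides = _load_overrides(config.scoring.overrides_file)
    records = []
    for s in series_list:
        ov = overrides.get((s.participant_id, str(s.night_date)))
        records.append(score_night(
            s, rescoring_enabled=config.scoring.rescoring_enabled,
            min_run_minutes=config.scoring.min_run_minutes,
            light_threshold=config.scoring.light_threshold, override=ov))
    nights = nights_to_frame(records)
    n_bad = int((~nights["valid"]).sum())
    if n_bad:
        log.warning("score: %d/%d nights discarded (no identifiable sleep period)",
                    n_bad, len(nights))
    out = outdir / "nights.csv"
    write_table(nights, out)
    return out


def stage_aggregate(config: RunConfig, nights_path: str | Path,
                    visits_path: str | Path, profiles_path: str | Path,
                    outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nights = pd.read_csv(nights_path)
    visits = pd.read_csv(visits_path)
    profiles = pd.read_csv(profiles_path)
    windows = iiv.build_window_summaries(
        nights, visits, profiles, span_days=config.window.span_days,
        min_nights=config.window.min_nights, adjust_start=config.window.adjust_start)
    excluded = int((~windows["included"]).sum())
    log.info("aggregate: %d windows, %d excluded by the >=%d-night filter",
             len(windows), excluded, config.window.min_nights)
    out = outdir / "windows.csv"
    write_table(windows, out)
    return out


def stage_associate(config: RunConfig, windows_path: str | Path,
                    scales_path: str | Path, profiles_path: str | Path,
                    outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = pd.read_csv(windows_path)
    scales = pd.read_csv(scales_path)
    profiles = pd.read_csv(profiles_path)

    data = (windows[windows["included"]]
            .merge(scales, on=["participant_id", "visit"])
            .merge(profiles, on="participant_id"))
    data = data[data["group"] == "ASD"].copy()
    data["sex"] = data["sex"].map({"female": 0, "male": 1})

    assoc = association_table(
        data, scales=config.association.scales,
        features=prediction.ACTIGRAPHY_FEATURES)
    assoc_path = outdir / "associations.csv"
    write_table(assoc, assoc_path)

    # caregiver-scale intercorrelations per timepoint, covariate-adjusted
    corr_rows = []
    all_scales = scales.merge(profiles, on="participant_id")
    asd = all_scales[all_scales["group"] == "ASD"].copy()
    asd["sex01"] = asd["sex"].map({"female": 0, "male": 1})
    behaviors = ("srs2", "abc_hyperactivity", "abc_irritability", "casi_anx")
    for tp, g in asd.groupby("visit"):
        cov = g[["sex01", "iq"]].to_numpy(dtype=float)
        for beh in behaviors:
            sub = g[["abi_sleep", beh]].notna().all(axis=1) & np.isfinite(cov).all(axis=1)
            if sub.sum() < 4:
                continue
            try:
                r = partial_spearman(g.loc[sub, "abi_sleep"], g.loc[sub, beh],
                                     cov[sub.to_numpy()], "abi_sleep", beh, tp)
            except ValueError:
                continue
            corr_rows.append({"timepoint": tp, "scale_x": r.scale_x, "scale_y": r.scale_y,
                              "rho": r.rho, "p_value": r.p_value, "n": r.n})
    corr = pd.DataFrame(corr_rows)
    if len(corr):
        from .associations import bh_adjust
        corr["q_value"] = bh_adjust(corr["p_value"], "scale-correlations")
    corr_path = outdir / "scale_correlations.csv"
    write_table(corr, corr_path)

    # ASD vs TD prevalence of more-than-mild caregiver-reported sleep problems
    base = all_scales[all_scales["visit"] == "baseline"].dropna(subset=["abi_sleep"])
    grp_path = outdir / "group_comparison.csv"
    asd_flags = flag_sleep_problems(base.loc[base["group"] == "ASD", "abi_sleep"])
    td_flags = flag_sleep_problems(base.loc[base["group"] == "TD", "abi_sleep"])
    if len(asd_flags) and len(td_flags):
        stat, p = compare_proportions_chisq(asd_flags, td_flags)
        write_table(pd.DataFrame([{
            "asd_pct_sleep_problems": 100 * asd_flags.mean(),
            "td_pct_sleep_problems": 100 * td_flags.mean(),
            "chi2": stat, "p_value": p,
            "n_asd": len(asd_flags), "n_td": len(td_flags),
        }]), grp_path)
    return {"associations": assoc_path, "correlations": corr_path, "groups": grp_path}


def stage_predict(config: RunConfig, windows_path: str | Path,
                  scales_path: str | Path, profiles_path: str | Path,
                  outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = pd.read_csv(windows_path)
    scales = pd.read_csv(scales_path)
    profiles = pd.read_csv(profiles_path)
    X, y, groups = prediction.assemble_features(windows, scales, profiles)
    log.info("predict: %d feature columns assembled over %d observations",
             X.shape[1], len(y))
    pre = prediction.preprocess_features(X)
    log.info("predict: near-zero variance flagged %s; decorrelation dropped %s; "
             "VIF dropped %s; %d features retained",
             pre.nzv_flagged or "none", pre.corr_dropped or "none",
             pre.vif_dropped or "none", len(pre.retained))
    enet_cfg = config.elastic_net
    if enet_cfg.seed != config.seed:
        import dataclasses
        enet_cfg = dataclasses.replace(enet_cfg, seed=config.seed)
    result = prediction.outer_protocol(X[pre.retained], y, groups, enet_cfg)
    rec_path = outdir / "prediction_records.csv"
    imp_path = outdir / "feature_importance.csv"
    write_table(result.records, rec_path)
    write_table(result.importance, imp_path)
    report = outdir / "prediction_report.txt"
    with open(report, "w") as fh:
        fh.write(f"features assembled: {X.shape[1]}\n")
        fh.write(f"near-zero variance flagged: {pre.nzv_flagged or 'none'}\n")
        fh.write(f"removed as correlated: {pre.corr_dropped or 'none'}\n")
        fh.write(f"removed by VIF: {pre.vif_dropped or 'none'}\n")
        fh.write(f"retained features: {pre.retained}\n")
        fh.write(f"outer test sets: {len(result.records)}\n")
        fh.write(f"mean test R2: {result.records['r2'].mean():.4f}\n")
        top = result.importance.sort_values('normalized', ascending=False).head(5)
        fh.write("top importances:\n")
        for _, r in top.iterrows():
            fh.write(f"  {r.feature}: {r.normalized:.3f}\n")
    return {"records": rec_path, "importance": imp_path, "report": report}


def run_protocol_on_synthetic(
    seed: int,
    enet_config: prediction.ElasticNetConfig | None = None,
    coupling: cohort_mod.ScaleCoupling | None = None,
    n_asd: int = 139,
) -> tuple[prediction.ImportanceResult, prediction.PreprocessResult, pd.DataFrame]:
    """Generate a synthetic cohort, run scoring and aggregation in memory,
    and execute the prediction protocol on the assembled feature table.

    Returns the protocol result, the preprocessing summary, and the feature
    table itself.  This is the canonical in-memory path used to study
    recovery of the planted anxiety coupling.
    """
    data = cohort_mod.generate_cohort(n_asd=n_asd, n_td=0, seed=seed, coupling=coupling)
    nights = nights_to_frame([score_night(s) for s in data.epochs])
    windows = iiv.build_window_summaries(nights, data.visits, data.profiles)
    X, y, groups = prediction.assemble_features(windows, data.scales, data.profiles)
    pre = prediction.preprocess_features(X)
    cfg = enet_config or prediction.ElasticNetConfig(seed=seed)
    result = prediction.outer_protocol(X[pre.retained], y, groups, cfg)
    return result, pre, X


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """simulate -> score -> aggregate -> associate -> predict."""
    outdir = Path(outdir)
    sim_dir = outdir / "cohort"
    paths = stage_simulate(config, sim_dir)
    nights = stage_score(config, paths["epochs"], outdir)
    windows = stage_aggregate(config, nights, paths["visits"], paths["profiles"], outdir)
    assoc = stage_associate(config, windows, paths["scales"], paths["profiles"], outdir)
    pred = stage_predict(config, windows, paths["scales"], paths["profiles"], outdir)
    _write_manifest(outdir, config)
    return {"cohort": sim_dir, "nights": nights, "windows": windows, **assoc, **pred}
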