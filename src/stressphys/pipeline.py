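"""End-to-end orchestration: simulate, score, and run the inference layer.

``run_pipeline`` loops participants through preprocessing and every
scorer, assembles tidy per-measure tables mirroring the study's table
structures (ratings means, bias scores by window/combination/hemifield,
group t-tests, ANOVA tables), and optionally writes them as TSV together
with a run log of versions, seed and parameters. A single ``RunConfig``
drives everything and round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autonomic import (ATB_HR_WINDOWS, hr_table, participant_scr_cells,
                        score_scr_trace)
from .containers import EXPRESSIONS
from .endocrine import aucg, auci, series_from_frame
from .erd import ERD_EPOCH_TMIN_MS, alpha_erd
from .erp import component_table
from .preprocess import preprocess_recording
from .ssvep import abs_table
from .stats import AnovaResult, mixed_rmanova, ttest_ind
from .synthetic_data import SimulationConfig, generate_session


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: stage toggles
    run_ssvep: bool = True
    run_erp: bool = True
    run_erd: bool = True
    run_autonomic: bool = True
    run_endocrine: bool = True
    run_ratings: bool = True
    reject_threshold_uv: float = 150.0
    scr_min_valid: int = 5
    outdir: str | None = None


# ---------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------

def _to_plain(obj):
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _from_plain(cls, data):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        default = (f.default_factory() if f.default_factory
                   is not dataclasses.MISSING else f.default)
        if is_dataclass(default):
            val = _from_plain(type(default), val)
        elif isinstance(default, tuple) and isinstance(val, list):
            val = _tuplify(val)
        elif isinstance(default, dict) and isinstance(val, dict):
            val = _match_dict(default, val)
        elif isinstance(default, list) and val and isinstance(val[0], dict):
            # list of component dataclasses
            from .synthetic_data import ErpComponent
            val = [_from_plain(ErpComponent, v) for v in val]
        kwargs[f.name] = val
    return cls(**kwargs)


def _tuplify(val):
    return tuple(_tuplify(v) if isinstance(v, list) else v for v in val)


def _match_dict(default, val):
    # mirror tuple-ness of the default's values, recursively
    sample = next(iter(default.values())) if default else None
    out = {}
    for k, v in val.items():
        if isinstance(v, list):
            out[k] = _tuplify(v)
        elif isinstance(v, dict) and isinstance(sample, dict):
            out[k] = _match_dict(sample, v)
        else:
            out[k] = v
    return out


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    return _from_plain(RunConfig, yaml.safe_load(text))


# ---------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------

def _mean_sd(series):
    return f"{series.mean():.2f} ± {series.std(ddof=1):.2f}"


def _anova_frames(results: dict[str, AnovaResult]) -> dict[str, pd.DataFrame]:
    return {f"anova_{name}": res.table() for name, res in results.items()}


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Simulate both groups and run every enabled stage.

    Returns a dict of tidy tables; writes them under ``config.outdir``
    when set. Deterministic given the configuration (the simulation seed
    covers all randomness).
    """
    sim = config.simulation
    sim.validate()
    per_abs, per_comp, per_erd = [], [], []
    scr_rows, hr_rows, saliva_rows, rating_rows = [], [], [], []

    for group in ("stress", "control"):
        for i in range(sim.n_participants_per_group):
            sess = generate_session(sim, group, i)
            pid = sess.participant
            if config.run_ssvep:
                ep = preprocess_recording(
                    sess.atb, sess.atb_conditions,
                    threshold_uv=config.reject_threshold_uv)
                per_abs.append(abs_table(ep, pid, group))
            if config.run_erp or config.run_erd:
                epv = preprocess_recording(
                    sess.viewing, sess.viewing_conditions,
                    threshold_uv=config.reject_threshold_uv)
                if config.run_erp:
                    per_comp.append(component_table(epv, pid, group))
                if config.run_erd:
                    epw = preprocess_recording(
                        sess.viewing, sess.viewing_conditions,
                        threshold_uv=config.reject_threshold_uv,
                        tmin_ms=ERD_EPOCH_TMIN_MS)
                    r = alpha_erd(epw, pid, group)
                    per_erd.append({"participant": pid, "group": group,
                                    "erd": r.erd_value, "reason": r.reason})
            if config.run_autonomic:
                scores = score_scr_trace(sess.scr_atb)
                cells, included = participant_scr_cells(
                    scores, config.scr_min_valid)
                for _, row in cells.iterrows():
                    scr_rows.append({"participant": pid, "group": group,
                                     "task": "atb", "included": included,
                                     **row.to_dict()})
                hr = hr_table(sess.rr_atb, ATB_HR_WINDOWS)
                hr_cells = hr.groupby(["condition", "window"])["mean_hr"].mean()
                for (cond, win), val in hr_cells.items():
                    hr_rows.append({"participant": pid, "group": group,
                                    "condition": cond, "window": win,
                                    "mean_hr": val})
            if config.run_endocrine:
                for analyte in ("cortisol", "saa", "vas"):
                    t, v = series_from_frame(sess.saliva, analyte)
                    for lab, tv, vv in zip(
                            sim.saliva.labels, t, v):
                        saliva_rows.append({"participant": pid,
                                            "group": group,
                                            "analyte": analyte,
                                            "label": lab, "time_min": tv,
                                            "value": vv})
                    saliva_rows.append({"participant": pid, "group": group,
                                        "analyte": analyte, "label": "AUCg",
                                        "time_min": np.nan,
                                        "value": aucg(t, v)})
                    saliva_rows.append({"participant": pid, "group": group,
                                        "analyte": analyte, "label": "AUCi",
                                        "time_min": np.nan,
                                        "value": auci(t, v)})
            if config.run_ratings:
                for _, row in sess.ratings.iterrows():
                    rating_rows.append({"participant": pid, "group": group,
                                        **row.to_dict()})

    tables: dict[str, pd.DataFrame] = {}
    anovas: dict[str, AnovaResult] = {}

    if config.run_ratings and rating_rows:
        ratings = pd.DataFrame(rating_rows)
        tables["ratings"] = ratings
        cells = []
        for meas in ("arousal", "valence"):
            for expr in EXPRESSIONS:
                row = {"measure": meas, "expression": expr}
                for g in ("stress", "control"):
                    sub = ratings[(ratings.group == g)
                                  & (ratings.expression == expr)]
                    row[g] = _mean_sd(sub[meas])
                cells.append(row)
            anovas[meas] = mixed_rmanova(ratings, meas, "participant",
                                         "group", ["expression"])
        tables["table1_ratings_summary"] = pd.DataFrame(cells)

    if config.run_ssvep and per_abs:
        abs_all = pd.concat(per_abs, ignore_index=True)
        tables["table2_abs"] = abs_all
        for window, sub in abs_all.groupby("window"):
            anovas[f"abs_{window}"] = mixed_rmanova(
                sub, "abs", "participant", "group",
                ["combination", "hemifield"])

    if config.run_erp and per_comp:
        comp = pd.concat(per_comp, ignore_index=True)
        tables["components"] = comp
        for name in ("P1", "N170", "EPN"):
            sub = comp[(comp.component == name)
                       & (comp.hemisphere != "midline")]
            anovas[f"erp_{name}"] = mixed_rmanova(
                sub, "mean_amplitude", "participant", "group",
                ["expression", "hemisphere"])
        sub = comp[comp.component == "N170"]
        sub = sub[sub.hemisphere != "midline"]
        anovas["erp_p2p_p1n170"] = mixed_rmanova(
            sub, "peak_to_peak", "participant", "group",
            ["expression", "hemisphere"])
        lpp = comp[comp.component == "LPP"]
        anovas["erp_LPP"] = mixed_rmanova(
            lpp, "mean_amplitude", "participant", "group", ["expression"])

    ttest_rows = []
    if config.run_erd and per_erd:
        erd_df = pd.DataFrame(per_erd)
        tables["erd"] = erd_df
        s = erd_df[erd_df.group == "stress"]["erd"].dropna()
        c = erd_df[erd_df.group == "control"]["erd"].dropna()
        if len(s) > 1 and len(c) > 1:
            r = ttest_ind(s.to_numpy(), mean2=c.to_numpy())
            ttest_rows.append({"measure": "alpha_erd", "t": r.t, "df": r.df,
                               "p": r.p, "mean_diff": r.mean_diff,
                               "ci_low": r.ci95[0], "ci_high": r.ci95[1]})

    if config.run_autonomic and scr_rows:
        scr = pd.DataFrame(scr_rows)
        tables["scr_cells"] = scr
        inc = scr[scr.included]
        if inc.participant.nunique() >= 4 and inc.groupby(
                "group")["participant"].nunique().min() >= 2:
            anovas["scr"] = mixed_rmanova(
                inc, "mean_amplitude_us", "participant", "group",
                ["condition"])
        hr = pd.DataFrame(hr_rows)
        tables["hr_cells"] = hr
        overall = hr[hr.window == "0-7500"]
        anovas["hr_overall"] = mixed_rmanova(
            overall, "mean_hr", "participant", "group", ["condition"])

    if config.run_endocrine and saliva_rows:
        sal = pd.DataFrame(saliva_rows)
        tables["saliva"] = sal
        for analyte in ("cortisol", "saa", "vas"):
            raw = sal[(sal.analyte == analyte)
                      & (~sal.label.isin(["AUCg", "AUCi"]))]
            anovas[f"{analyte}_time"] = mixed_rmanova(
                raw, "value", "participant", "group", ["label"])
            for auc_label in ("AUCg", "AUCi"):
                sub = sal[(sal.analyte == analyte) & (sal.label == auc_label)]
                s = sub[sub.group == "stress"]["value"]
                c = sub[sub.group == "control"]["value"]
                r = ttest_ind(s.to_numpy(), mean2=c.to_numpy())
                ttest_rows.append({"measure": f"{analyte}_{auc_label}",
                                   "t": r.t, "df": r.df, "p": r.p,
                                   "mean_diff": r.mean_diff,
                                   "ci_low": r.ci95[0],
                                   "ci_high": r.ci95[1]})

    if ttest_rows:
        tables["table3_group_ttests"] = pd.DataFrame(ttest_rows)
    tables.update(_anova_frames(anovas))

    if config.outdir:
        _write_report(config, tables)
    return tables


def _write_report(config: RunConfig, tables) -> None:
    import os

    os.makedirs(config.outdir, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(os.path.join(config.outdir, f"{name}.tsv"),
                     sep="\t", index=False)
    log = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.simulation.seed,
        "config": _to_plain(config),
    }
    with open(os.path.join(config.outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
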