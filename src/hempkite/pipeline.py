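"""End-to-end pipeline: simulate → derive → analyze → report.

Stages form a fixed DAG; each stage reads the previous stage's files and
writes its own (never the same file).  A run manifest records the config
hash, seeds, package version, SHA-256 checksums of every output, and
timestamps, which suffices to reproduce a run bit-for-bit for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .archetypes import archetypal_analysis
from .disease import SeveritySeries, audpc
from .kite import derive_kite_traits
from .importance import LMGImportance, stepwise_aic
from .quantgen import HalfSibFamilyModel, family_summary
from .regression import fit_loglog
from .simulate import TrialConfig, simulate_trial

log = logging.getLogger("hempkite")

STAGES = ("simulate", "derive", "analyze", "report")

DEFAULT_TRAITS = ["HT", "MCD", "MCDH", "TRKL", "DIA", "BPAIR", "VOL",
                  "KITE", "KHR", "KBA", "KC", "INL",
                  "LFLTN", "LFDW", "LFA", "SLA", "PTDW", "PTA", "SPA",
                  "PTFD", "TFD", "AUDPC", "WBM", "DBM", "DSBM",
                  "CB_total", "CB_yield"]

DEFAULT_PREDICTORS = ["DIA", "KITE", "HT", "MCD", "SPA", "PTFD"]


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing input {path}")
    return path


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    tc = TrialConfig.from_dict(cfg.get("trial", {})) if cfg.get("trial") \
        else TrialConfig(master_seed=cfg.get("seed", 0))
    if "seed" in cfg:
        tc.master_seed = cfg["seed"]
    df, _ = simulate_trial(tc)
    out = outdir / "traits.csv"
    df.to_csv(out, index=False)
    return [out]


def stage_derive(cfg: dict, outdir: Path) -> list[Path]:
    df = pd.read_csv(_require(outdir / "traits.csv", "derive"))
    df = derive_kite_traits(df)
    if {"PM71", "PM86", "PM97"}.issubset(df.columns):
        days = np.array([71.0, 86.0, 97.0])
        df["AUDPC"] = [
            audpc(SeveritySeries(days, np.array([r.PM71, r.PM86, r.PM97])))
            for r in df.itertuples()
        ]
    if {"MCD", "MCDH", "HT"}.issubset(df.columns):
        df["R_MCD_HT"] = df["MCD"] / df["HT"]
        df["R_MCDH_HT"] = df["MCDH"] / df["HT"]
    out = outdir / "traits_derived.csv"
    df.to_csv(out, index=False)
    return [out]


def stage_analyze(cfg: dict, outdir: Path) -> list[Path]:
    df = pd.read_csv(_require(outdir / "traits_derived.csv", "analyze"))
    outputs = []

    # per-trait family summary and heritability
    rows = []
    traits = [t for t in cfg.get("traits", DEFAULT_TRAITS) if t in df.columns]
    for t in traits:
        summ = family_summary(df, t)["population"]
        row = {"trait": t, **summ}
        try:
            vc = HalfSibFamilyModel(df[t], df["family"]).fit()
            row["h2"] = vc.h2()
            row["h2_uncapped"] = vc.h2_uncapped
            row["sigma2_family"] = vc.sigma2_family
            row["sigma2_residual"] = vc.sigma2_residual
        except ValueError:
            row["h2"] = np.nan
        rows.append(row)
    summary = outdir / "trait_summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False)
    outputs.append(summary)

    # allometric scaling fits
    fits = {}
    for name, (xc, yc) in {"HT~DIA": ("DIA", "HT"),
                           "WBM~DIA": ("DIA", "WBM"),
                           "LFDW~LI": ("LI", "LFDW"),
                           "SPA~LI": ("LI", "SPA")}.items():
        if xc in df.columns and yc in df.columns:
            sub = df[[xc, yc]].dropna()
            res = fit_loglog(sub[xc], sub[yc])
            fits[name] = {"slope": res.slope, "intercept": res.intercept,
                          "r_squared": res.r_squared, "n": res.n,
                          "slope_ci": list(res.slope_ci)}
    allo = outdir / "allometry.json"
    allo.write_text(json.dumps(fits, indent=2))
    outputs.append(allo)

    # canopy-form archetypes on the two shape ratios
    X = df[["R_MCD_HT", "R_MCDH_HT"]].dropna().to_numpy()
    sol = archetypal_analysis(X, k=cfg.get("archetype_k", 4),
                              nrep=cfg.get("archetype_nrep", 5),
                              seed=cfg.get("seed", 0))
    arch = outdir / "archetypes.json"
    arch.write_text(json.dumps({
        "k": sol.k, "rss": sol.rss,
        "archetypes": sol.Z.tolist(),
        "labels": sol.labels().tolist(),
    }, indent=2))
    outputs.append(arch)

    # yield model: stepwise selection then LMG decomposition
    preds = [p for p in cfg.get("predictors", DEFAULT_PREDICTORS)
             if p in df.columns]
    sub = df[["DSBM"] + preds].dropna()
    step = stepwise_aic(sub["DSBM"], sub[preds])
    sel = step.selected or preds[:1]
    imp = LMGImportance(sub["DSBM"], sub[sel]).fit(
        n_boot=cfg.get("n_boot", 200), seed=cfg.get("seed", 0))
    ymod = outdir / "yield_model.json"
    ymod.write_text(json.dumps({
        "selected": step.selected, "aic": step.aic,
        "r_squared": imp.r_squared,
        "lmg": imp.shares.to_dict(),
        "lmg_ci": None if imp.ci is None else imp.ci.to_dict(),
    }, indent=2))
    outputs.append(ymod)
    return outputs


def stage_report(cfg: dict, outdir: Path) -> list[Path]:
    for f in ("trait_summary.csv", "allometry.json",
              "archetypes.json", "yield_model.json"):
        _require(outdir / f, "report")
    report = {
        "trait_summary": pd.read_csv(outdir / "trait_summary.csv")
        .to_dict(orient="records"),
        "allometry": json.loads((outdir / "allometry.json").read_text()),
        "archetypes": json.loads((outdir / "archetypes.json").read_text()),
        "yield_model": json.loads((outdir / "yield_model.json").read_text()),
    }
    out = outdir / "report.json"
    out.write_text(json.dumps(report, indent=2))
    return [out]


_STAGE_FUNCS = {"simulate": stage_simulate, "derive": stage_derive,
                "analyze": stage_analyze, "report": stage_report}


def run_pipeline(config: dict | str | Path, outdir, stages=None) -> dict:
    """Run the requested stages in dependency order and write the manifest.

    Returns the manifest dict.  Raises :class:`PipelineError` on a missing
    stage input or an unknown stage name.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or config.get("stages", STAGES))
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]       # dependency order

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config_hash": cfg_hash, "seed": config.get("seed", 0),
                "version": __version__, "stages": {}, "outputs": {}}
    for s in stages:
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[s](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {s!r} failed: {exc}") from exc
        dt = time.time() - t0
        log.info("stage %s finished in %.2f s", s, dt)
        manifest["stages"][s] = {"seconds": round(dt, 3),
                                 "finished_at": time.strftime(
                                     "%Y-%m-%dT%H:%M:%S")}
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
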