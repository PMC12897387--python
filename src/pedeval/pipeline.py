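"""Config-driven orchestration: simulate -> edit -> transform -> screen ->
fit the model roster -> compare.

The run configuration is a flat YAML file (see :class:`RunConfig`).  All
randomness flows from a single root seed, split per stage, so a run is
fully reproducible; every output file starts with a comment carrying the
configuration hash.

Model roster semantics: M2/M4 carry the full fixed-effect list regardless
of significance; M1/M3 carry the effects retained by the preliminary
F-test screening.  Threshold fits use the raw scores; linear fits of score
traits use the selected normalising transform.  When the screening drops
the contemporary group from M1, the trait's M1 records are re-edited
without the CG-based filters (the larger second dataset).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import editing as ed
from . import evaluation as ev
from . import mixed_model as mm
from . import simulate as sim
from . import threshold as th
from . import transform as tf
from .pedigree import (a_inverse, inbreeding_coefficients,
                       mendelian_sampling_variances, read_pedigree_csv,
                       write_pedigree_csv)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration.

    Either ``pedigree``/``phenotypes`` paths are given, or ``simulate`` is
    true and the ``sim_*`` keys parameterise the generator.
    """

    outdir: str = "run"
    seed: int = 2024
    simulate: bool = True
    pedigree: str = None
    phenotypes: str = None
    trait: str = "trait"
    trait_scale: str = "linear"          # 'linear' | 'ordinal-9'
    trait_range: tuple = None            # (min, max) for continuous traits
    models: tuple = ("M1", "M2", "M3", "M4")
    fit_threshold: bool = None           # default: ordinal traits only
    alpha: float = 0.05
    min_count: int = 5
    min_links: int = 10
    max_depth: int = 3
    min_daughters: int = 20
    sim: dict = field(default_factory=dict)   # SimulationConfig overrides

    def __post_init__(self):
        if not self.models:
            raise ValueError("model roster is empty")
        if self.min_count <= 0 or self.min_links <= 0:
            raise ValueError("editing thresholds must be positive")
        if self.trait_scale not in ("linear", "ordinal-9"):
            raise ValueError("trait_scale must be 'linear' or 'ordinal-9'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        cfg = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def config_hash(self) -> str:
        def plain(x):
            if isinstance(x, dict):
                return {str(k): plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            if hasattr(x, "__dataclass_fields__"):
                return plain(asdict(x))
            return x

        blob = yaml.safe_dump(plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_artifact_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: RunConfig):
    overrides = dict(config.sim)
    overrides.setdefault("seed", config.seed)
    overrides.setdefault("trait", config.trait)
    overrides.setdefault("trait_scale", config.trait_scale)
    fx = overrides.pop("fixed_effects", None)
    if fx is not None:
        overrides["fixed_effects"] = {
            k: sim.FactorConfig(*v) if not isinstance(v, sim.FactorConfig) else v
            for k, v in fx.items()}
    scfg = sim.SimulationConfig(**overrides)
    ds = sim.simulate_records(config=scfg)
    return ds


@_stage("load")
def stage_load(config: RunConfig):
    if not config.pedigree or not config.phenotypes:
        raise FileNotFoundError("pedigree and phenotypes paths required")
    for p in (config.pedigree, config.phenotypes):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    ped = read_pedigree_csv(config.pedigree)
    rec = read_artifact_csv(config.phenotypes)
    required = {"cow", "herd", "year", "season", "evaluator", "diet",
                "dam_age", "trait", "value"}
    missing = required - set(rec.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return ped, rec


@_stage("edit")
def stage_edit(records, pedigree, config: RunConfig, cg_in_model: bool):
    ranges = {config.trait: config.trait_range} if config.trait_range else {}
    score = (config.trait,) if config.trait_scale == "ordinal-9" else ()
    return ed.apply_editing_plan(
        records, pedigree, cg_in_model=cg_in_model, trait_ranges=ranges,
        score_traits=score, min_count=config.min_count,
        min_links=config.min_links, max_depth=config.max_depth)


@_stage("transform")
def stage_transform(records: pd.DataFrame, config: RunConfig):
    """Add the linear-model response column.

    Ordinal scores are transformed by the best normalising candidate; the
    threshold route keeps the raw scores.  Continuous traits pass through.
    """
    out = records.copy()
    if config.trait_scale == "ordinal-9":
        res = tf.select_transformation(out["value"].to_numpy())
        out["value_linear"] = res.values
        logger.info("transform for linear models: %s (skew %.3f -> %.3f, "
                    "kurt %.3f -> %.3f)", res.method, res.skewness_before,
                    res.skewness_after, res.kurtosis_before, res.kurtosis_after)
        return out, res
    out["value_linear"] = out["value"].astype(float)
    return out, None


@_stage("screen")
def stage_screen(records, config: RunConfig):
    return mm.screen_fixed_effects(
        records, candidate_effects=("cg", "season", "evaluator", "diet"),
        covariates=("L", "Q"), alpha=config.alpha, response="value_linear")


@_stage("fit")
def stage_fit(records, pedigree, spec: mm.ModelSpec, response: str,
              seed: int = 2024, threshold_method: str = "gibbs",
              n_iter: int = 1800, burn: int = 600):
    Ainv = a_inverse(pedigree)
    lda = float(np.sum(np.log(mendelian_sampling_variances(pedigree))))
    if spec.scale == "threshold":
        return th.fit_threshold_model(records, spec, pedigree,
                                      response=response,
                                      method=threshold_method, seed=seed,
                                      n_iter=n_iter, burn=burn)
    design = mm.build_design(records, spec, pedigree, response=response)
    return mm.reml_estimate(design, Ainv, logdet_a=lda, spec=spec)


def _fit_outputs(fit: mm.FitResult, outdir: Path, label: str, chash: str):
    d = outdir / f"fit_{label.replace(':', '_')}"
    d.mkdir(parents=True, exist_ok=True)
    vc = fit.varcomp
    rows = [{"component": k, "estimate": v, "se": vc.se.get(k, np.nan)}
            for k, v in vc.as_dict().items()]
    _write_csv(pd.DataFrame(rows), d / "varcomp.csv", chash)
    ebv = pd.DataFrame({"animal": fit.ebv.index, "ebv": fit.ebv.to_numpy(),
                        "se": fit.se_prediction.reindex(fit.ebv.index).to_numpy()})
    _write_csv(ebv, d / "ebv.csv", chash)
    sol = pd.concat([
        pd.DataFrame({"effect": "fixed", "level": fit.beta.index,
                      "solution": fit.beta.to_numpy()}),
        pd.DataFrame({"effect": "pe", "level": fit.pe.index,
                      "solution": fit.pe.to_numpy()}),
        pd.DataFrame({"effect": "cg", "level": fit.cg.index,
                      "solution": fit.cg.to_numpy()}),
    ])
    _write_csv(sol, d / "solutions.csv", chash)
    _write_csv(pd.DataFrame({"fitted": fit.fitted}), d / "fitted.csv", chash)
    if fit.cutpoints is not None:
        _write_csv(pd.DataFrame({"cutpoint": fit.cutpoints}),
                   d / "cutpoints.csv", chash)
    meta = {"label": label, "trait": fit.spec.trait, "scale": fit.spec.scale,
            "cg_role": fit.spec.cg_role, "rank_x": fit.rank_x,
            "n_records": fit.n_records, "loglik": float(fit.loglik),
            "iterations": fit.iterations, "converged": bool(fit.converged)}
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return d


def run_pipeline(config: RunConfig):
    """Execute the full analysis; returns (ComparisonReport, fits dict)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("pedeval")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run config hash %s", chash)
        if config.simulate:
            ds = stage_simulate(config)
            ped, rec = ds.pedigree, ds.records
            write_pedigree_csv(ped, outdir / "pedigree.csv")
            _write_csv(rec, outdir / "phenotypes.csv", chash)
        else:
            ped, rec = stage_load(config)

        # dataset 1: full editing plan (CG in the model)
        rec1, report1 = stage_edit(rec, ped, config, cg_in_model=True)
        _write_csv(report1.to_frame(), outdir / "edit_report.csv", chash)
        logger.info("editing (dataset 1): %s", report1.removed)

        rec1, tres = stage_transform(rec1, config)
        screened = stage_screen(rec1, config)
        logger.info("screened fixed effects: %s", screened)

        is_ordinal = config.trait_scale == "ordinal-9"
        fit_thr = config.fit_threshold if config.fit_threshold is not None else is_ordinal

        fits = {}
        rec_m1, spec_m1 = rec1, None
        for model in config.models:
            spec = mm.model_spec(model, config.trait, screened=screened)
            if model == "M1" and spec.cg_role == "excluded":
                # dataset-2 rule: no CG-based editing for this trait's M1
                rec2, report2 = stage_edit(rec, ped, config, cg_in_model=False)
                rec2, _ = stage_transform(rec2, config)
                rec_m1 = rec2
                _write_csv(report2.to_frame(), outdir / "edit_report_dataset2.csv", chash)
                logger.info("dataset-2 editing used for M1: %s", report2.removed)
            data = rec_m1 if model == "M1" else rec1
            fits[f"linear:{model}"] = stage_fit(data, ped, spec, "value_linear")
            if fit_thr and is_ordinal:
                tspec = mm.model_spec(model, config.trait, screened=screened,
                                      scale="threshold")
                fits[f"threshold:{model}"] = stage_fit(
                    data, ped, tspec, "value", seed=config.seed + 1)
        for label, fit in fits.items():
            _fit_outputs(fit, outdir, label, chash)

        report = None
        if len(fits) >= 2:
            f = inbreeding_coefficients(ped)
            report = ev.build_comparison_report(
                fits, rec1, ped, f, min_daughters=config.min_daughters)
            for name, tab in report.tables().items():
                _write_csv(tab.reset_index(), outdir / f"report_{name}.csv",
                           chash)
        return report, fits
    finally:
        root.removeHandler(handler)
        handler.close()
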