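"""End-to-end analysis pipeline and command-line interface.

Chains the stages of the pedigree-based analysis: trace the pedigree of the
phenotyped lines, build relationship matrices over a double-reduction grid,
fit the baseline and SCA mixed models, profile the double-reduction rate,
compute heritabilities and the likelihood-ratio test, and cross-validate
predictions.  Every stage is a pure function of (inputs, config, seed); the
combined report records the configuration hash and seeds for provenance.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import drprofile, kinship, pedigree, summary, validation
from .lmm import ModelSpec, build_design, reml_fit
from .simulate import SimConfig, simulate_program, univariate_config

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-serializable)."""

    pedigree_path: str
    phenotype_path: str
    output_dir: str
    traits: Sequence[str]
    alpha_grid: Sequence[float] = kinship.DEFAULT_ALPHA_GRID
    models: Sequence[str] = ("M1", "M2")
    cv_schemes: Sequence[str] = ("five_fold", "lbco")
    cv_seed: int = 1
    alpha: Optional[float] = None       # fixed rate; None -> use profile argmin
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write per-stage artifacts plus a combined
    JSON report into ``cfg.output_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.digest(), "cv_seed": cfg.cv_seed}

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as err:
            raise StageError(name, err) from err

    ped = stage("read_pedigree", lambda: pedigree.read_pedigree(cfg.pedigree_path))
    pheno = stage("read_phenotypes", lambda: pd.read_csv(cfg.phenotype_path))
    traits = tuple(cfg.traits)

    traced = stage("trace", lambda: ped.trace(
        sorted(set(pheno["line_id"].astype(str)))))
    traced.write(out / "pedigree_traced.csv")
    comp = traced.completeness()
    report["pedigree"] = {
        "n_total": len(ped), "n_traced": len(traced),
        "completeness_mean": comp.mean, "completeness_max": comp.max,
        "frac_unknown_parents": comp.frac_unknown_parents,
    }

    base_spec = ModelSpec(traits=traits, include_sca=False,
                          alpha=cfg.alpha_grid[0])
    prof = stage("profile_dr", lambda: drprofile.profile_dr(
        pheno, ped, base_spec, grid=cfg.alpha_grid,
        models=tuple(cfg.models)))
    drprofile.profile_report(prof, out / "dr_profile.tsv",
                             out / "dr_profile.png")
    report["dr_profile"] = {
        "grid": list(prof.grid),
        "best_alpha": prof.best_alpha,
        "flat_below": prof.flat_below,
        "deviance": {m: list(np.asarray(d, dtype=float))
                     for m, d in prof.deviance.items()},
    }

    alpha = cfg.alpha if cfg.alpha is not None else \
        min(prof.best_alpha.values())
    report["alpha_used"] = alpha

    fits = {}
    for model in cfg.models:
        spec = ModelSpec(traits=traits, include_sca=(model == "M2"),
                         alpha=alpha)
        am = stage(f"design_{model}", lambda s=spec: build_design(pheno, ped, s))
        fit = stage(f"fit_{model}", lambda a=am: reml_fit(a))
        fits[model] = fit
        d_A = float(np.diagonal(am.Aff).mean())
        report[model] = stage(f"summary_{model}",
                              lambda f=fit, d=d_A: summary.summary_report(f, d))
        fit.vc_table().to_csv(out / f"vc_{model}.csv", index=False)
        fit.blup["additive"].rename_axis("id").reset_index().to_csv(
            out / f"ebv_{model}.csv", index=False)

    if "M1" in fits and "M2" in fits:
        lr = stage("lrt", lambda: summary.lrt(fits["M1"], fits["M2"]))
        report["lrt"] = {"stat": lr.stat, "df": lr.df, "p": lr.p}

    report["cv"] = {}
    for model, fit in fits.items():
        report["cv"][model] = {}
        for kind in cfg.cv_schemes:
            scheme = stage(f"folds_{kind}", lambda k=kind: validation.make_folds(
                pheno, ped, k, seed=cfg.cv_seed))
            res = stage(f"cv_{model}_{kind}",
                        lambda f=fit, s=scheme: validation.run_cv(
                            pheno, ped, f.spec, s, full_fit=f))
            res.per_fold.to_csv(out / f"cv_{model}_{kind}_folds.tsv",
                                sep="\t", index=False)
            report["cv"][model][kind] = {
                "pa": res.pa, "rc": res.rc,
                "theoretical_max": res.theoretical_max,
                "n_folds": len(res.scheme.folds),
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


# ======================================================================
# command-line interface
# ======================================================================

def _add_io(p):
    p.add_argument("--pedigree", required=True)
    p.add_argument("--phenotypes", required=True)
    p.add_argument("--traits", required=True,
                   help="comma-separated trait column names (one or two)")
    p.add_argument("--out", default="tetraped_out")


def _spec_from_args(args, model=None) -> ModelSpec:
    model = model or getattr(args, "model", "m1")
    return ModelSpec(traits=tuple(args.traits.split(",")),
                     include_sca=model.lower() == "m2",
                     alpha=getattr(args, "alpha", 0.05))


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        prog="tetraped",
        description="pedigree-based quantitative genetics for autotetraploid "
                    "breeding programs")
    sub = ap.add_subparsers(dest="cmd", required=True)

    p = sub.add_parser("simulate", help="generate a synthetic breeding program")
    p.add_argument("--config", help="YAML file of SimConfig overrides")
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--univariate", action="store_true")
    p.add_argument("--out", default="sim_out")

    p = sub.add_parser("trace", help="trace and order a pedigree")
    p.add_argument("--pedigree", required=True)
    p.add_argument("--focal", help="comma-separated focal ids (default: all)")
    p.add_argument("--out", default="traced.csv")

    p = sub.add_parser("build-a", help="build the relationship matrix")
    p.add_argument("--pedigree", required=True)
    p.add_argument("--alpha", type=float, default=0.05)
    p.add_argument("--out", default="amatrix")

    p = sub.add_parser("fit", help="fit one mixed model by REML")
    _add_io(p)
    p.add_argument("--model", choices=["m1", "m2"], default="m1")
    p.add_argument("--alpha", type=float, default=0.05)

    p = sub.add_parser("profile-dr", help="profile the double-reduction rate")
    _add_io(p)
    p.add_argument("--model", choices=["m1", "m2"], default="m1")
    p.add_argument("--grid", default=",".join(
        str(a) for a in kinship.DEFAULT_ALPHA_GRID))

    p = sub.add_parser("cv", help="cross-validate predictions")
    _add_io(p)
    p.add_argument("--model", choices=["m1", "m2"], default="m1")
    p.add_argument("--alpha", type=float, default=0.05)
    p.add_argument("--scheme", choices=["5fold", "lbco"], default="5fold")
    p.add_argument("--seed", type=int, default=1)

    p = sub.add_parser("run-all", help="full pipeline from a YAML config")
    p.add_argument("--config", required=True)

    args = ap.parse_args(argv)

    if args.cmd == "simulate":
        overrides = {}
        if args.config:
            with open(args.config) as fh:
                overrides = yaml.safe_load(fh) or {}
        overrides["seed"] = args.seed
        cfg = univariate_config(**overrides) if args.univariate \
            else SimConfig(**overrides)
        truth = simulate_program(cfg)
        outdir = Path(args.out)
        outdir.mkdir(parents=True, exist_ok=True)
        truth.pedigree.write(outdir / "pedigree.csv")
        truth.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"alpha_true": cfg.alpha_true,
                       "vc_true": {k: np.asarray(v).tolist()
                                   for k, v in cfg.vc_true.items()},
                       "seed": cfg.seed}, fh, indent=2)
        print(f"wrote pedigree ({len(truth.pedigree)} records) and "
              f"{len(truth.phenotypes)} plots to {outdir}")
        return 0

    if args.cmd == "trace":
        ped = pedigree.read_pedigree(args.pedigree)
        focal = args.focal.split(",") if args.focal else ped.ids
        ped.trace(focal).write(args.out)
        print(f"traced pedigree written to {args.out}")
        return 0

    if args.cmd == "build-a":
        ped = pedigree.read_pedigree(args.pedigree)
        tk = kinship.build_amatrix(ped, args.alpha)
        kinship.write_kinship(tk, f"{args.out}_triples.tsv",
                              f"{args.out}_inbreeding.tsv")
        print(f"A matrix for {len(ped)} individuals at alpha={args.alpha}: "
              f"d(A)={tk.d_A:.4f}")
        return 0

    if args.cmd == "run-all":
        report = run_pipeline(RunConfig.from_yaml(args.config))
        print(json.dumps({"alpha_used": report["alpha_used"],
                          "lrt": report.get("lrt")}, indent=2, default=float))
        return 0

    ped = pedigree.read_pedigree(args.pedigree)
    pheno = pd.read_csv(args.phenotypes)
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    if args.cmd == "fit":
        spec = _spec_from_args(args)
        am = build_design(pheno, ped, spec)
        fit = reml_fit(am)
        d_A = float(np.diagonal(am.Aff).mean())
        rep = summary.summary_report(fit, d_A)
        with open(outdir / f"fit_{spec.label}.json", "w") as fh:
            json.dump(rep, fh, indent=2, default=float)
        fit.vc_table().to_csv(outdir / f"vc_{spec.label}.csv", index=False)
        fit.blup["additive"].rename_axis("id").reset_index().to_csv(
            outdir / f"ebv_{spec.label}.csv", index=False)
        print(json.dumps(rep["heritability"], indent=2))
        return 0

    if args.cmd == "profile-dr":
        spec = _spec_from_args(args)
        grid = [float(a) for a in args.grid.split(",")]
        prof = drprofile.profile_dr(pheno, ped, spec, grid=grid,
                                    models=(spec.label,))
        drprofile.profile_report(prof, outdir / "dr_profile.tsv",
                                 outdir / "dr_profile.png")
        print(f"best alpha ({spec.label}): {prof.best_alpha[spec.label]:g}")
        return 0

    if args.cmd == "cv":
        spec = _spec_from_args(args)
        kind = "five_fold" if args.scheme == "5fold" else "lbco"
        scheme = validation.make_folds(pheno, ped, kind, seed=args.seed)
        res = validation.run_cv(pheno, ped, spec, scheme)
        res.per_fold.to_csv(outdir / f"cv_{kind}_folds.tsv", sep="\t",
                            index=False)
        with open(outdir / f"cv_{kind}.json", "w") as fh:
            json.dump({"pa": res.pa, "rc": res.rc,
                       "theoretical_max": res.theoretical_max}, fh, indent=2)
        print(json.dumps({"pa": res.pa, "rc": res.rc}, indent=2))
        return 0

    raise SystemExit(2)  # pragma: no cover


def _run_all(config_path) -> dict:
    return run_pipeline(RunConfig.from_yaml(config_path))


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
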