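"""End-to-end analysis pipeline: diversity → VIF → two-step selection → report.

``run_pipeline`` ties the stages together for one response variable:
population-level estimators (Ae, Fis, uHe, Ho) are modelled at one point
per site (the site's representative tree), the individual-level HL at one
point per genotyped individual.  Outputs are plain TSV/JSON files; the
fit report is byte-reproducible given the same inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net_mod
from .genotypes import (
    diversity_per_population,
    hwe_tests,
    individual_hl,
    read_genotypes,
)
from .model import vif
from .selection import SSNModelSelector

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

POPULATION_RESPONSES = ("Ae", "Fis", "uHe", "Ho")
log = logging.getLogger("ssngen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    network_csv: str
    sites_csv: str
    genotypes_csv: str
    out_dir: str
    response: str = "Ae"
    genotype_dialect: str = "long"
    covariates: list[str] = field(default_factory=lambda: ["DA", "ALT", "BIOC_TH", "BIOC_SO"])
    components: tuple[str, ...] = ("tailup", "taildown", "euclidean")
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.response not in POPULATION_RESPONSES + ("HL",):
            raise PipelineError("config", f"unknown response {self.response!r}")
        for p in (self.network_csv, self.sites_csv, self.genotypes_csv):
            if not Path(p).exists():
                raise PipelineError("config", f"input file not found: {p}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err

        return wrapped

    return deco


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n")


def _fit_report(fit, names, seed) -> dict:
    r2, shares = fit.variance_decomposition()
    summary = fit.summary(names)

    def _num(v):
        v = float(v)
        return v if np.isfinite(v) else None

    return {
        "seed": int(seed),
        "beta": [
            {
                "term": ix,
                "estimate": _num(row["estimate"]),
                "std_error": _num(row["std_error"]),
                "p_value": _num(row["p_value"]),
            }
            for ix, row in summary.iterrows()
        ],
        "spec": json.loads(fit.spec_.to_json()),
        "loglik": _num(fit.loglik_),
        "aic": _num(fit.aic_),
        "rmspe": _num(fit.rmspe_),
        "r2": _num(r2),
        "varcomp": {k: _num(v) for k, v in shares.items()},
        "range_at_bound": bool(fit.range_at_bound_),
    }


@_stage("run")
def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of the written artefacts plus the final fit object.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        net = net_mod.read_network_csv(config.network_csv)
        sites = net_mod.read_sites_csv(config.sites_csv)
        G = read_genotypes(config.genotypes_csv, dialect=config.genotype_dialect)
    except Exception as err:
        raise PipelineError("inputs", str(err)) from err

    # ---- diversity stage -------------------------------------------------
    try:
        div = diversity_per_population(G)
        hwe = hwe_tests(G, n_perm=config.n_perm, seed=config.seed)
        div = div.join(hwe[["P1", "P2"]])
        hl = individual_hl(G)
    except Exception as err:
        raise PipelineError("diversity", str(err)) from err
    table1 = div[["n", "Ae", "uHe", "Ho", "Fis", "P1", "P2"]]
    table1.to_csv(out / "diversity.tsv", sep="\t")
    hl.to_frame().to_csv(out / "hl.tsv", sep="\t")
    log.info("diversity computed for %d populations", len(div))

    # ---- spatial stage ---------------------------------------------------
    try:
        if config.response == "HL":
            pop_col = sites["population"].astype(str)
            keep = hl.dropna()
            ind_sites = sites.set_index("point_id")
            missing_pts = [i for i in keep.index if i not in ind_sites.index]
            if missing_pts:
                raise ValueError(
                    f"individual-level run needs one sites row per individual; "
                    f"missing: {missing_pts[:5]}"
                )
            sites_used = ind_sites.loc[keep.index].reset_index()
            y = keep.to_numpy()
        else:
            div_sites = sites.set_index("point_id")
            pops = [p for p in div.index if p in div_sites.index]
            if len(pops) != len(div):
                raise ValueError("sites file must carry one row per population")
            sites_used = div_sites.loc[pops].reset_index()
            y = div.loc[pops, config.response].to_numpy()
        points = net_mod.points_from_sites(
            sites_used, level="individual" if config.response == "HL" else "population"
        )
        dset = net_mod.hydrologic_distances(net, points)
        if "DA" in config.covariates and "DA" not in sites_used.columns:
            sites_used = sites_used.assign(
                DA=[net_mod.hydrologic_index(net, p) for p in points]
            )
        X_all = sites_used[config.covariates].astype(float)
    except Exception as err:
        raise PipelineError("spatial", str(err)) from err

    # ---- VIF screen ------------------------------------------------------
    try:
        vifs = vif(X_all) if X_all.shape[1] >= 2 else pd.Series(dtype=float, name="VIF")
    except Exception as err:
        raise PipelineError("vif", str(err)) from err
    vifs.to_frame().to_csv(out / "vif.tsv", sep="\t")

    # ---- two-step selection ---------------------------------------------
    try:
        selector = SSNModelSelector(components=tuple(config.components)).fit(X_all, y, dset)
    except Exception as err:
        raise PipelineError("selection", str(err)) from err
    selector.step1_.to_csv(out / "step1.tsv", sep="\t")
    selector.step2_.to_csv(out / "step2.tsv", sep="\t")
    for _, row in selector.step1_.iterrows():
        log.info("step1 %-40s AIC=%.3f", row["covariates"], row["aic"])
    for _, row in selector.step2_.iterrows():
        log.info("step2 %-50s RMSPE=%.5g", row["structure"], row["rmspe"])

    # ---- final fit report ------------------------------------------------
    fit = selector.best_fit_
    report = _fit_report(fit, selector.best_covariates_, config.seed)
    report["response"] = config.response
    report["covariates_selected"] = selector.best_covariates_
    _json_dump(report, out / "final.json")

    r2, shares = fit.variance_decomposition()
    rows = [
        {"name": f"{c.fn}.{c.ctype}", "varcomp": shares[c.ctype], "range_m": c.range_}
        for c in fit.spec_.components
    ] + [{"name": "nugget", "varcomp": shares["nugget"], "range_m": np.nan}]
    pd.DataFrame(rows).assign(R2=r2).to_csv(out / "table2_like.tsv", sep="\t", index=False)

    return {
        "diversity": table1,
        "hl": hl,
        "vif": vifs,
        "step1": selector.step1_,
        "step2": selector.step2_,
        "final": report,
        "fit": fit,
    }
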