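"""Orchestration of the five evaluation areas into one reproducible run.

``run_pipeline`` executes, in order: conditional ML fit, response-category
(threshold-ordering) check, dimensionality screening, per-subscale reruns
when the combined scale is multidimensional, DIF for the configured
covariates, targeting/reliability, and the ordinal-to-interval score
conversion table.  The result is a nested report (tables + JSON-ready
summaries) that can be written to an output directory together with a run
log recording seeds, recodings and decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ITEM_SUBSETS, ResponseMatrix, read_responses
from .dimensionality import assess_unidimensionality
from .exceptions import InvalidArgumentError, RaschError
from .invariance_dif import dif_split_search, dif_two_group
from .item_fit import subsampled_zstd
from .model import PartialCreditModel
from .targeting_reliability import ordered_thresholds_check

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    data_path: str | None = None
    meta_path: str | None = None
    scale_version: str = "PSS14"          # preset name or explicit subset via items
    items: list[str] | None = None
    reverse_code_positives: bool = True   # combined-scale orientation policy
    dif_covariates: list[str] = field(default_factory=lambda: ["gender", "age"])
    dif_cutoff: float = 0.5
    msq_range: tuple[float, float] = (0.7, 1.3)
    zstd_bound: float = 2.0
    zstd_subsamples: int = 40
    zstd_subsample_size: int = 300
    psi_threshold: float = 0.7
    seed: int = 0
    output_dir: str | None = None

    def resolve_items(self, rm: ResponseMatrix) -> list[str]:
        if self.items:
            missing = [i for i in self.items if i not in rm.item_ids]
            if missing:
                raise InvalidArgumentError(f"unknown items in config: {missing}")
            return list(self.items)
        if self.scale_version in ITEM_SUBSETS:
            return [i for i in ITEM_SUBSETS[self.scale_version] if i in rm.item_ids]
        raise InvalidArgumentError(
            f"unknown scale version {self.scale_version!r} and no explicit items"
        )


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _analyse_scale(rm: ResponseMatrix, cfg: RunConfig, label: str) -> dict:
    """Fit one item set and run every per-scale stage on it."""
    model = PartialCreditModel(rm)
    res = model.fit()
    pe = res.person_estimates()
    out: dict = {"label": label, "results": res, "person_estimates": pe}
    out["item_parameters"] = res.params.to_frame()
    out["rating_scale"] = ordered_thresholds_check(res.params)
    out["fit"] = res.item_fit(pe).table
    n_sub = min(cfg.zstd_subsample_size, rm.n_persons)
    out["fit_subsampled"] = subsampled_zstd(
        rm, res.params, k=cfg.zstd_subsamples, n_sub=n_sub, seed=cfg.seed)
    dim = res.dimensionality(pe)
    verdict, reasons = assess_unidimensionality(dim)
    out["dimensionality"] = dim
    out["verdict"] = verdict
    out["verdict_reasons"] = reasons
    out["targeting"] = res.targeting(pe)
    out["reliability"] = res.reliability(cfg.psi_threshold, pe)
    out["score_table"] = res.score_table().table
    out["dif"] = {}
    for cov in cfg.dif_covariates:
        if cov not in rm.person_meta.columns:
            continue
        col = rm.person_meta[cov]
        if col.dtype == object or col.nunique() == 2:
            codes = pd.factorize(col)[0]
            rep = dif_two_group(rm, codes == codes.max(), covariate=cov,
                                split="by category", cutoff=cfg.dif_cutoff)
            out["dif"][cov] = {"split": None, "report": rep}
        else:
            cut, rep = dif_split_search(rm, cov, cutoff=cfg.dif_cutoff)
            out["dif"][cov] = {"split": cut, "report": rep}
    return out


def run_pipeline(cfg: RunConfig, rm: ResponseMatrix | None = None) -> dict:
    """Execute the full evaluation; returns the structured report.

    Stage failures are caught and recorded under ``errors`` with the
    failing stage named; completed stages stay in the report.
    """
    report: dict = {"config": cfg, "errors": {}, "log": []}
    if rm is None:
        rm = read_responses(cfg.data_path, cfg.meta_path)
    items = cfg.resolve_items(rm)
    scale = rm.subset(items)
    if cfg.reverse_code_positives:
        scale = scale.reverse_code()
        report["log"].append("positively worded items reverse-coded (x -> m - x)")
    thin = scale.thin_items()
    if thin:
        report["log"].append(f"items with <2 observed categories: {thin}")

    try:
        combined = _analyse_scale(scale, cfg, cfg.scale_version)
        report["combined"] = combined
        if combined["results"].recodings:
            report["log"].append(
                f"category recodings: {combined['results'].recodings}")
    except RaschError as err:
        report["errors"]["combined"] = str(err)
        return report

    # if the combined scale is multidimensional, rerun per wording subscale
    if combined["verdict"] == "multidimensional":
        report["log"].append(
            "combined scale multidimensional: rerunning per polarity subscale")
        for pol in ("negative", "positive"):
            ids = [i for i in items
                   if rm.item_meta.loc[i, "polarity"] == pol]
            if len(ids) < 2:
                continue
            try:
                sub = rm.subset(ids)  # raw orientation within a subscale
                report[pol] = _analyse_scale(sub, cfg, f"{pol} subscale")
            except RaschError as err:
                report["errors"][pol] = str(err)

    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def write_report(report: dict, outdir) -> None:
    """Serialise tables as CSV and summaries as JSON into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"log": report["log"], "errors": report["errors"]}
    for key in ("combined", "negative", "positive"):
        sec = report.get(key)
        if not sec:
            continue
        tag = key
        for name in ("item_parameters", "rating_scale", "fit", "fit_subsampled",
                     "score_table"):
            sec[name].to_csv(out / f"{tag}_{name}.csv")
        rel = sec["reliability"]
        rel.to_frame().to_csv(out / f"{tag}_reliability_profile.csv", index=False)
        dim = sec["dimensionality"]
        pd.DataFrame({"eigenvalue": dim.eigenvalues}).to_csv(
            out / f"{tag}_eigenvalues.csv", index=False)
        dim.loadings.to_csv(out / f"{tag}_first_contrast.csv")
        t = sec["targeting"]
        summary[tag] = {
            "verdict": sec["verdict"],
            "verdict_reasons": sec["verdict_reasons"],
            "person_mean": t.person_mean,
            "person_sd": t.person_sd,
            "item_location_mean": t.item_location_mean,
            "item_location_sd": t.item_location_sd,
            "psi_threshold": rel.psi_threshold,
            "psi_intervals": rel.intervals,
            "pct_inside": rel.pct_inside,
            "pct_above": rel.pct_above,
            "pct_below": rel.pct_below,
            "dif": {
                cov: {
                    "split": _jsonable(d["split"]),
                    "p_value": None if d["report"] is None else d["report"].p_value,
                    "flagged": [] if d["report"] is None
                    else d["report"].flagged_items,
                }
                for cov, d in sec["dif"].items()
            },
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
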