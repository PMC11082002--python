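"""End-to-end orchestration: tables -> diversity -> ordination -> transition -> gLV.

``run_pipeline`` executes the full critical-transition workflow on a count
table plus chronology and writes every artifact as provenance-headed TSV.
All randomness derives from the config's single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, glv, ordination, tables_io, transition
from ._util import log, write_tsv
from .config import PipelineConfig


@dataclass
class PipelineResult:
    table: tables_io.TaxonTable
    alpha: pd.DataFrame
    alpha_tests: pd.DataFrame
    distances: ordination.DistanceMatrix
    nmds: ordination.OrdinationResult
    zonation: ordination.Zonation
    anosim_r: float
    anosim_p: float
    permanova_f: float
    permanova_p: float
    kde: ordination.KDEResult
    breakpoints: dict[str, transition.BreakpointResult]
    ews: transition.EWSSeries
    forecast: transition.ForecastDeviation | None
    stages: list[glv.StageResult]
    stage_table: pd.DataFrame

    @property
    def n_states(self) -> int:
        return int(len(np.unique(self.zonation.labels)))

    def summary(self) -> str:
        lines = [
            f"samples: {self.table.n_samples}, taxa: {len(self.table.taxon_ids)}",
            f"states: {self.n_states} (boundary at sample index {self.zonation.boundary})",
            f"ANOSIM R = {self.anosim_r:.3f}, p = {self.anosim_p:.3g}; "
            f"PERMANOVA F = {self.permanova_f:.2f}, p = {self.permanova_p:.3g}",
            f"NMDS stress = {self.nmds.stress:.4f}; NMDS1 KDE modes = {self.kde.n_modes}",
        ]
        for name, bp in self.breakpoints.items():
            ages = ", ".join(f"{a:.0f}" for a in (bp.ages or []))
            lines.append(f"breakpoints[{name}]: m = {bp.m}" + (f" at {ages}" if ages else ""))
        lines.append(
            f"EWS (window {self.ews.window}): tau_var = {self.ews.tau_var:.3f} "
            f"(p = {self.ews.p_var:.3g}), tau_ac = {self.ews.tau_ac:.3f} "
            f"(p = {self.ews.p_ac:.3g})")
        if self.forecast is not None:
            lines.append(
                f"ARIMA forecast deviation: {self.forecast.fraction_outside:.0%} of "
                f"state-2 observations outside the {self.forecast.level:.0%} band")
        ok = self.stage_table.dropna(subset=["centroid_re"]) \
            if "centroid_re" in self.stage_table else self.stage_table
        lines.append(f"stages analyzed: {len(self.stage_table)} "
                     f"({len(ok)} with stability estimates)")
        for st, row in ok.iterrows():
            lines.append(
                f"  stage {st}: centroid = {row['centroid_re']:+.4f} "
                f"({'stable' if row['stable'] else 'unstable'})")
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig, quiet: bool = False) -> PipelineResult:
    seeds = config.module_seeds()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log("reading tables", quiet=quiet)
    table = tables_io.read_taxon_table(config.table, config.chronology)
    if table.taxonomy is not None:
        table = tables_io.collapse_taxonomy(table, rank=config.rank)
    rarefied = tables_io.rarefy(table, seed=seeds["rarefy"])

    log("alpha diversity", quiet=quiet)
    alpha = diversity.alpha_diversity(rarefied)

    cm = tables_io.to_relative(rarefied)
    closed = tables_io.select_modeled_taxa(
        cm, min_mean_abund=config.min_mean_abund, max_taxa=config.max_taxa,
        renormalize=True)
    glv_matrix = tables_io.select_modeled_taxa(
        cm, min_mean_abund=config.min_mean_abund, max_taxa=config.max_taxa_glv,
        renormalize=False)

    log("ordination and state tests", quiet=quiet)
    dist = ordination.bray_curtis(closed)
    nmds_res = ordination.nmds(dist, k=config.nmds_k, restarts=config.nmds_restarts,
                               seed=seeds["nmds"], ages=table.ages)
    zon = ordination.constrained_zonation(dist)
    labels = zon.labels
    r_an, p_an = ordination.anosim(dist, labels, n_perm=config.n_perm,
                                   seed=seeds["anosim"])
    f_pm, p_pm = ordination.permanova(dist, labels, n_perm=config.n_perm,
                                      seed=seeds["permanova"])
    state1 = nmds_res.coordinates["NMDS1"].to_numpy()
    kde = ordination.kde_bimodality(state1)
    alpha_tests = diversity.compare_states(alpha, labels)

    log("transition detection", quiet=quiet)
    ages = table.ages.to_numpy()
    bps = {}
    for col in alpha.columns:
        try:
            bps[col] = transition.detect_breakpoints(
                alpha[col].to_numpy(), max_m=config.max_breaks,
                min_seg=config.min_segment, ages=ages)
        except ValueError as exc:
            log(f"breakpoints[{col}] skipped: {exc}", quiet=quiet)
    ews = transition.sliding_ews(state1, window=config.ews_window, ages=ages,
                                 pre_transition_end=zon.boundary - 1)
    forecast = None
    order = (config.arima_p, config.arima_d, config.arima_q)
    try:
        arima_fit = transition.fit_arima(state1[:zon.boundary], order=order)
        forecast = transition.forecast_deviation(arima_fit, state1[zon.boundary:])
    except Exception as exc:  # statsmodels raises a broad range of errors
        log(f"ARIMA forecast skipped: {exc}", quiet=quiet)

    log("per-stage gLV inference", quiet=quiet)
    grid = np.logspace(np.log10(config.lambda_min), np.log10(config.lambda_max),
                       config.lambda_points)
    stages = glv.stage_analysis(glv_matrix, w=config.stage_window,
                                s=config.stage_step, lambda_grid=grid,
                                k_folds=config.k_folds,
                                per_taxon_lambda=config.per_taxon_lambda,
                                classify_on=config.classify_on)
    stage_table = glv.stage_summary(stages, ages=ages)

    result = PipelineResult(
        table=table, alpha=alpha, alpha_tests=alpha_tests, distances=dist,
        nmds=nmds_res, zonation=zon, anosim_r=r_an, anosim_p=p_an,
        permanova_f=f_pm, permanova_p=p_pm, kde=kde, breakpoints=bps, ews=ews,
        forecast=forecast, stages=stages, stage_table=stage_table)
    _write_outputs(result, config, outdir)
    log("done", quiet=quiet)
    return result


def _write_outputs(res: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    seed = config.seed
    write_tsv(res.alpha, outdir / "alpha_diversity.tsv", "diversity", seed)
    write_tsv(res.alpha_tests, outdir / "alpha_state_tests.tsv", "diversity", seed)
    dm = pd.DataFrame(res.distances.d, index=res.distances.sample_ids,
                      columns=res.distances.sample_ids)
    write_tsv(dm, outdir / "bray_curtis.tsv", "ordination", seed)
    write_tsv(res.nmds.coordinates, outdir / "nmds.tsv", "ordination", seed,
              extra_header=[f"stress: {res.nmds.stress:.6f}",
                            f"converged: {res.nmds.converged}"])
    zon_df = pd.DataFrame({"sample_id": res.distances.sample_ids,
                           "state": res.zonation.labels})
    write_tsv(zon_df, outdir / "zonation.tsv", "ordination", seed, index=False,
              extra_header=[f"ANOSIM R: {res.anosim_r:.4f} p: {res.anosim_p}",
                            f"PERMANOVA F: {res.permanova_f:.4f} p: {res.permanova_p}"])
    ews_df = pd.DataFrame({
        "window_end_index": res.ews.window_ends,
        "window_end_age": (res.ews.ages if res.ews.ages is not None
                           else res.ews.window_ends),
        "variance": res.ews.variance, "lag1_ac": res.ews.lag1_ac,
        "degenerate": res.ews.degenerate})
    write_tsv(ews_df, outdir / "ews.tsv", "transition", seed, index=False,
              extra_header=[f"tau_var: {res.ews.tau_var:.4f} p: {res.ews.p_var:.4g}",
                            f"tau_ac: {res.ews.tau_ac:.4f} p: {res.ews.p_ac:.4g}"])
    bp_rows = []
    for name, bp in res.breakpoints.items():
        bp_rows.append({"series": name, "m": bp.m,
                        "break_ages": ";".join(f"{a:.1f}" for a in (bp.ages or [])),
                        "bic": ";".join(f"{m}:{v:.2f}" for m, v in sorted(bp.bic.items()))})
    write_tsv(pd.DataFrame(bp_rows), outdir / "breakpoints.tsv", "transition",
              seed, index=False)
    if res.forecast is not None:
        fc = res.forecast
        fc_df = pd.DataFrame({"forecast": fc.forecast, "lo95": fc.lower,
                              "hi95": fc.upper, "observed": fc.observed,
                              "outside": fc.outside})
        write_tsv(fc_df, outdir / "arima_forecast.tsv", "transition", seed, index=False)
    write_tsv(res.stage_table, outdir / "stage_summary.tsv", "glv", seed)
    for st in res.stages:
        if st.fit is None:
            continue
        k = st.window.index
        mat = pd.DataFrame(st.fit.A, index=st.fit.taxa, columns=st.fit.taxa)
        mat.insert(0, "r", st.fit.r)
        write_tsv(mat, outdir / f"stage{k}_glv.tsv", "glv", seed)
        eig = pd.DataFrame({"re": st.stability.eigenvalues.real,
                            "im": st.stability.eigenvalues.imag})
        write_tsv(eig, outdir / f"stage{k}_eigenvalues.tsv", "glv", seed, index=False)
        write_tsv(st.interactions.pairs, outdir / f"stage{k}_interactions.tsv",
                  "glv", seed, index=False)
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(res.summary() + "\n")
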