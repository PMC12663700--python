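"""Top-down orchestration of the two analysis branches.

The *values* branch measures how differently the sites answered:
encode -> chained imputation -> PCA to 3 axes -> per-site LOF filtering ->
3-D histograms (10 bins/dim) -> Jensen–Shannon simplex -> SPO/GPD.

The *completeness* branch measures how differently the sites *skipped*:
three-code missingness matrix -> MCA -> LOF -> histograms -> SPO/GPD.

Both run for the whole questionnaire and for every section
(hierarchical, multivariate to univariate).  Imputation and categorization
are performed once on the full matrix and then sliced per section, so a
section's result never depends on which other sections are requested.
Sections with at most 3 analyzable variables skip the reduction and are
histogrammed on the encoded variables directly, with bins per dimension
adjusted to keep the total bin count at or below 1000.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ScopeError
from .codebook import Codebook, MultiSourceDataset
from .densities import build_density
from .missingness import (
    CompletenessSummary,
    MissingCategoryMatrix,
    categorize,
    completeness_summary,
    to_categorical_table,
)
from .msv import DistanceMatrix, MSVResult, msv_from_densities
from .outliers import filter_per_site
from .preprocess import EncodedMatrix, encode, impute_chained, select_analyzable
from .reduce import ReducedScores, mca_reduce, pca_reduce, top_contributors


@dataclass
class PipelineConfig:
    """Resolved parameter snapshot for one run (all stages)."""

    impute_max_iter: int = 10
    impute_tol: float = 1e-3
    impute_ridge_lambda: float = 1e-3
    reduce_k: int = 3
    top_vars: int = 20
    standardize: bool = True
    lof_k: int = 20
    lof_threshold: float = 1.5
    lof_max_removed_frac: float = 0.10
    bins_per_dim: int = 10
    weighted_centroid: bool = True
    cascade: str = "propagate"


@dataclass
class AnalysisScope:
    branch: str  # "values" | "completeness"
    section: str  # section name or "all"
    parameters: dict
    seed: int


@dataclass
class ScopeResult:
    scope: AnalysisScope
    msv: MSVResult | None
    contributors: pd.Series | None
    biplot: dict | None
    flags: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


def _effective_bins(bins_per_dim: int, dims: int) -> int:
    """Largest bins/dim <= requested keeping total bins <= 1000."""
    dims = max(dims, 1)
    cap = int(round(1000.0 ** (1.0 / dims)))
    while cap**dims > 1000:
        cap -= 1
    while (cap + 1) ** dims <= 1000:
        cap += 1
    return max(1, min(bins_per_dim, cap))


def _density_msv(
    red: ReducedScores, config: PipelineConfig
) -> tuple[MSVResult, dict[str, int]]:
    filtered, report = filter_per_site(
        red,
        k_neighbors=config.lof_k,
        threshold=config.lof_threshold,
        max_removed_frac=config.lof_max_removed_frac,
    )
    points = {
        label: filtered.scores[np.asarray(filtered.site) == label]
        for label in dict.fromkeys(filtered.site)
    }
    bins = _effective_bins(config.bins_per_dim, filtered.k)
    ad = build_density(points, bins_per_dim=bins)
    result = msv_from_densities(ad, weighted_centroid=config.weighted_centroid)
    kept = {label: len(idx) for label, idx in report.kept_index.items()}
    return result, kept


def _direct_scores(mat: EncodedMatrix) -> ReducedScores:
    """Small-section fallback: encoded variables used as coordinates."""
    return ReducedScores(
        scores=mat.values.astype(float),
        loadings=pd.DataFrame(index=mat.columns),
        explained=np.zeros(0),
        eigenvalues=np.zeros(0),
        contributions=pd.Series(dtype=float),
        site=mat.site.copy(),
        feature_names=list(mat.columns),
        method="direct",
    )


def _biplot_data(red: ReducedScores, contributors: pd.Series) -> dict:
    arrows = red.loadings.iloc[:, : min(2, red.loadings.shape[1])]
    if red.method == "pca":
        arrows = arrows.loc[[v for v in contributors.index if v in arrows.index]]
    return {
        "scores": red.scores[:, : min(2, red.k)],
        "site": np.asarray(red.site),
        "arrows": arrows,
        "explained": red.explained[: min(2, len(red.explained))],
    }


def run_values_analysis(
    ds: MultiSourceDataset,
    codebook: Codebook,
    section: str = "all",
    config: PipelineConfig | None = None,
    seed: int = 0,
    imputed: EncodedMatrix | None = None,
) -> ScopeResult:
    """Values branch for one scope (whole questionnaire or one section).

    ``imputed`` lets the hierarchical driver impute once and slice; when
    omitted, encoding and chained imputation run here on the full
    analyzable matrix (pooled over sites), then the section is sliced.
    """
    config = config or PipelineConfig()
    scope = AnalysisScope("values", section, asdict(config), seed)
    analyzable = [c for c in select_analyzable(codebook) if c in ds.data.columns]
    if not analyzable:
        raise ScopeError("no analyzable variables in dataset")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if imputed is None:
            enc = encode(ds, codebook)
            imputed, _ = impute_chained(
                enc,
                max_iter=config.impute_max_iter,
                tol=config.impute_tol,
                ridge_lambda=config.impute_ridge_lambda,
                seed=seed,
            )
        if section == "all":
            mat = imputed
        else:
            if section not in codebook.sections:
                raise ScopeError(f"unknown section {section!r}")
            ids = [c for c in analyzable if codebook[c].section == section]
            if not ids:
                raise ScopeError(f"section {section!r} has no analyzable variables")
            mat = imputed.subset(ids)
        contributors = None
        biplot = None
        if mat.p <= 3:
            red = _direct_scores(mat)
        else:
            red = pca_reduce(mat, k=config.reduce_k, standardize=config.standardize)
            contributors = top_contributors(red, config.top_vars)
            biplot = _biplot_data(red, contributors)
        msv, kept = _density_msv(red, config)
    return ScopeResult(
        scope=scope,
        msv=msv,
        contributors=contributors,
        biplot=biplot,
        flags=[] if mat.p > 3 else ["direct-histogram (<=3 variables)"],
        warnings=[str(w.message) for w in caught],
    )


def _zero_msv(sites: list[str], counts: dict[str, int]) -> MSVResult:
    s = len(sites)
    wmax = max(counts.values())
    return MSVResult(
        gpd=0.0,
        spo={label: 0.0 for label in sites},
        distances=DistanceMatrix(values=np.zeros((s, s)), sources=list(sites)),
        plot_coords=np.zeros((s, 2)),
        radii={label: counts[label] / wmax for label in sites},
        flags=["no-missingness"],
    )


def run_completeness_analysis(
    ds: MultiSourceDataset,
    codebook: Codebook,
    section: str = "all",
    config: PipelineConfig | None = None,
    seed: int = 0,
    mcm: MissingCategoryMatrix | None = None,
) -> ScopeResult:
    """Completeness branch for one scope.

    A scope whose category table is entirely constant (no missingness
    anywhere) yields GPD = 0 with all SPO = 0 and a ``no-missingness``
    flag rather than running a degenerate MCA.
    """
    config = config or PipelineConfig()
    scope = AnalysisScope("completeness", section, asdict(config), seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if mcm is None:
            mcm = categorize(ds, codebook, cascade=config.cascade)
        if section != "all":
            if section not in codebook.sections:
                raise ScopeError(f"unknown section {section!r}")
            ids = [c for c in mcm.codes.columns if codebook[c].section == section]
            if not ids:
                raise ScopeError(f"section {section!r} has no variables in dataset")
            mcm = mcm.subset(ids)
        table, constant = to_categorical_table(mcm)
        if len(constant) == len(table.columns):
            sites = list(dict.fromkeys(mcm.site))
            counts = {s: int((mcm.site == s).sum()) for s in sites}
            return ScopeResult(
                scope=scope,
                msv=_zero_msv(sites, counts),
                contributors=None,
                biplot=None,
                flags=["no-missingness"],
                warnings=[str(w.message) for w in caught],
            )
        red = mca_reduce(table, k=config.reduce_k, site=mcm.site.to_numpy())
        contributors = top_contributors(red, config.top_vars)
        biplot = _biplot_data(red, contributors)
        msv, _ = _density_msv(red, config)
    return ScopeResult(
        scope=scope,
        msv=msv,
        contributors=contributors,
        biplot=biplot,
        warnings=[str(w.message) for w in caught],
    )


@dataclass
class ReportBundle:
    """Everything one hierarchical run produced, plus its manifest."""

    results: dict[tuple[str, str], ScopeResult]
    completeness: CompletenessSummary
    manifest: dict

    def to_json_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics = {}
        for (branch, section), res in self.results.items():
            key = f"{branch}/{section}"
            metrics[key] = (
                {"error": res.error}
                if res.msv is None
                else {**res.msv.to_dict(), "scope_flags": res.flags}
            )
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
        comp = {
            "total_cells": self.completeness.total_cells,
            "counts": self.completeness.counts,
            "percents": self.completeness.percents,
            "complete_percent_whole": self.completeness.complete_percent_whole,
            "by_site": self.completeness.by_site.to_dict(orient="index"),
            "by_section": self.completeness.by_section.to_dict(orient="index"),
        }
        (out / "completeness.json").write_text(
            json.dumps(comp, indent=1, sort_keys=True)
        )
        rows = []
        for (branch, section), res in self.results.items():
            if res.contributors is None:
                continue
            for rank, (var, score) in enumerate(res.contributors.items(), 1):
                rows.append(
                    {
                        "branch": branch,
                        "section": section,
                        "rank": rank,
                        "variable": var,
                        "contribution": score,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "contributors.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True)
        )


def run_hierarchical(
    ds: MultiSourceDataset,
    codebook: Codebook,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> ReportBundle:
    """Both branches for the whole questionnaire and every section.

    Scope failures (e.g. a section with no analyzable variables) are
    recorded in the bundle and do not abort the run.
    """
    config = config or PipelineConfig()
    enc = encode(ds, codebook)
    imputed, _ = impute_chained(
        enc,
        max_iter=config.impute_max_iter,
        tol=config.impute_tol,
        ridge_lambda=config.impute_ridge_lambda,
        seed=seed,
    )
    mcm = categorize(ds, codebook, cascade=config.cascade)
    sections = ["all"] + codebook.sections
    results: dict[tuple[str, str], ScopeResult] = {}
    all_warnings: list[str] = []
    for section in sections:
        for branch, runner, extra in (
            ("values", run_values_analysis, {"imputed": imputed}),
            ("completeness", run_completeness_analysis, {"mcm": mcm}),
        ):
            try:
                res = runner(
                    ds, codebook, section=section, config=config, seed=seed, **extra
                )
            except ScopeError as exc:
                res = ScopeResult(
                    scope=AnalysisScope(branch, section, asdict(config), seed),
                    msv=None,
                    contributors=None,
                    biplot=None,
                    error=str(exc),
                )
            results[(branch, section)] = res
            all_warnings.extend(res.warnings)
    manifest = {
        "package": "msvdq",
        "version": __version__,
        "seed": seed,
        "config": asdict(config),
        "n_rows": ds.n,
        "sites": {s: int((ds.site == s).sum()) for s in ds.sites},
        "sections": codebook.sections,
        "n_variables": len(ds.data.columns),
        "failed_scopes": [
            f"{b}/{s}" for (b, s), r in results.items() if r.error is not None
        ],
        "warnings": sorted(set(all_warnings)),
    }
    return ReportBundle(
        results=results,
        completeness=completeness_summary(mcm),
        manifest=manifest,
    )
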