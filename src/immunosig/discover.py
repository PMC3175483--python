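"""Multi-step latent-antibody discovery pipeline.

The procedure chains the package's estimators into the antibody-discovery
workflow an immunosignature study follows:

1. median-normalize and log10-transform the raw arrays;
2. sanity-check the contrast with a transposed (samples-as-variables) EFA
   and loading-threshold classification;
3. screen every printed peptide with a Satterthwaite-corrected Welch test
   under Bonferroni familywise control;
4. factor the significant peptides (EFA; optional mixture cross-check) and
   infer the number of latent antibodies from the eigenvalue drop;
5. fit a CFA measurement model assigning each significant peptide to its
   factor;
6. regress disease status on the latent factors (SEM) for odds ratios;
7. annotate each factor's peptides with their direction of change
   (increased vs decreased in disease).

Cross-loading samples are reported, never removed.  If step 3 finds no
significant peptide the report stops there with an explicit notice.  When
two factors' scores correlate above 0.9 the report flags multicollinearity
and fits single-factor structural models alongside the joint one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import efa as efa_mod
from .arraydata import IntensityMatrix, median_normalize_log10
from .cfa import CfaSpec, CFAModel, StructuralResult, sem_fit
from .efa import FactorAnalysis, classify_by_loadings, suggest_n_factors
from .testing import results_frame, test_all_peptides

__all__ = ["DiscoveryConfig", "DiscoveryReport", "discover", "write_report"]


@dataclass
class DiscoveryConfig:
    alpha: float = 0.05
    rotation: str = "promax"
    loading_threshold: float = 0.3
    sem_method: str = "two_stage"
    n_factors: int | None = None        # override the eigenvalue-drop rule
    max_sem_indicators: int = 30        # top-k fallback for identification
    min_peptides_per_factor: int = 3
    collinearity_r: float = 0.9
    seed: int = 0
    zero_offset: float = 1.0


@dataclass
class DiscoveryReport:
    contrast: tuple[str, ...]
    config: DiscoveryConfig
    efa_accuracy: float
    efa_unclassified: int
    cross_loading_samples: list[str]
    scree: list[float]
    n_significant: int
    significant_table: pd.DataFrame
    stopped_at: str | None = None             # stage name if truncated
    n_factors_inferred: int | None = None
    n_factors_used: int | None = None
    factor_peptides: dict[str, list[str]] = field(default_factory=dict)
    factor_loadings: pd.DataFrame | None = None
    factor_directions: dict[str, str] = field(default_factory=dict)
    n_increased: int = 0
    n_decreased: int = 0
    cfa_fit_summary: str | None = None
    cfa_converged: bool | None = None
    structural: StructuralResult | None = None
    single_factor_structural: dict[str, StructuralResult] = field(
        default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    sem_indicators: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Discovery report — contrast {' vs '.join(self.contrast)}",
            f"transposed EFA classification: {self.efa_accuracy:.1f}% "
            f"({self.efa_unclassified} unclassified, "
            f"{len(self.cross_loading_samples)} cross-loading)",
            f"Bonferroni-significant peptides: {self.n_significant}",
        ]
        if self.stopped_at:
            lines.append(f"pipeline stopped after stage: {self.stopped_at}")
            return "\n".join(lines)
        lines.append(
            f"latent factors: {self.n_factors_used} "
            f"(eigenvalue-drop suggestion {self.n_factors_inferred})")
        for f, peps in self.factor_peptides.items():
            lines.append(f"  {f}: {len(peps)} peptides, "
                         f"direction {self.factor_directions.get(f, '?')}")
        lines.append(f"direction counts: {self.n_increased} increased / "
                     f"{self.n_decreased} decreased in {self.contrast[1]}")
        if self.cfa_fit_summary:
            lines.append("measurement model: " + self.cfa_fit_summary)
        if self.structural is not None:
            lines.append(self.structural.summary())
        for w in self.warnings:
            lines.append("warning: " + w)
        return "\n".join(lines)


def discover(data: IntensityMatrix, contrast, config: DiscoveryConfig | None = None,
             labels=None) -> DiscoveryReport:
    """Run the full discovery pipeline on a raw intensity matrix.

    *contrast* is a pair of group labels (reference group second is treated
    as the disease direction ``increased in contrast[1]``); *labels*
    optionally overrides the matrix's group labels.
    """
    cfg = config or DiscoveryConfig()
    if labels is not None:
        data = IntensityMatrix(
            data.values, data.sample_ids, [str(g) for g in labels],
            data.peptide_ids, data.peptide_sequences, data.empty_spot)
    contrast = tuple(contrast)
    if len(contrast) < 2:
        raise ValueError("contrast needs at least two groups")
    keep = np.array([g in contrast for g in data.group_labels])
    if keep.sum() < 4:
        raise ValueError("need at least 2 samples per contrast group")
    sub = IntensityMatrix(
        data.values[keep],
        [s for s, k in zip(data.sample_ids, keep) if k],
        [g for g, k in zip(data.group_labels, keep) if k],
        data.peptide_ids, data.peptide_sequences, data.empty_spot)

    # 1. normalize
    norm = median_normalize_log10(sub, zero_offset=cfg.zero_offset)

    # 2. transposed EFA sanity check
    sol_t = FactorAnalysis(norm, n_factors=len(contrast),
                           mode="samples_as_variables").fit(
        rotation=cfg.rotation, seed=cfg.seed)
    cls = classify_by_loadings(sol_t, norm.group_labels,
                               threshold=cfg.loading_threshold)

    # 3. peptide screening
    tests = test_all_peptides(norm, contrast[0], contrast[1], alpha=cfg.alpha)
    sig = [r for r in tests if r.significant_after_bonferroni]
    report = DiscoveryReport(
        contrast=contrast,
        config=cfg,
        efa_accuracy=cls.accuracy,
        efa_unclassified=cls.n_unclassified,
        cross_loading_samples=cls.cross_loadings,
        scree=[float(e) for e in sol_t.eigenvalues[: min(20, len(sol_t.eigenvalues))]],
        n_significant=len(sig),
        significant_table=results_frame(sig),
    )
    if not sig:
        report.stopped_at = "peptide_screening"
        report.warnings.append(
            "no peptide passed the Bonferroni threshold; downstream "
            "factor/SEM stages not run")
        return report

    # 4. EFA on significant peptides, factor count by eigenvalue drop
    sig_ids = [r.peptide_id for r in sig]
    frame = norm.to_frame()[sig_ids]
    if len(sig_ids) < 3:
        report.stopped_at = "significant_efa"
        report.warnings.append(
            f"only {len(sig_ids)} significant peptides; at least 3 are "
            "needed to factor them")
        return report
    corr_p = efa_mod.correlation(_FrameAdapter(frame), mode="peptides_as_variables")
    ev = efa_mod.eigen_scree(corr_p)
    m_hat = suggest_n_factors(ev)
    m_used = cfg.n_factors or m_hat
    m_used = max(1, min(m_used, len(sig_ids) - 1))
    report.n_factors_inferred = m_hat
    report.n_factors_used = m_used
    sol_p = FactorAnalysis(corr_p, n_factors=m_used).fit(
        rotation=cfg.rotation if m_used > 1 else "none", seed=cfg.seed)
    if sol_p.heywood_flags.any():
        report.warnings.append(
            f"Heywood cases for {int(sol_p.heywood_flags.sum())} peptide(s) "
            "in the significant-peptide EFA")
    report.factor_loadings = sol_p.loadings_frame()

    # factor membership: argmax |loading| over factors
    names = [f"factor{j+1}" for j in range(m_used)]
    member: dict[str, list[str]] = {f: [] for f in names}
    best = np.argmax(np.abs(sol_p.loadings), axis=1)
    for pid, j in zip(sig_ids, best):
        member[names[j]].append(pid)
    dropped = [f for f, peps in member.items()
               if len(peps) < cfg.min_peptides_per_factor]
    for f in dropped:
        report.warnings.append(
            f"{f} carried fewer than {cfg.min_peptides_per_factor} peptides "
            "and was merged into the remaining structure")
    member = {f: peps for f, peps in member.items() if f not in dropped}
    if not member:
        report.stopped_at = "factor_membership"
        report.warnings.append("no factor retained at least "
                               f"{cfg.min_peptides_per_factor} peptides")
        return report
    member = {f"factor{j+1}": peps
              for j, (_, peps) in enumerate(sorted(member.items()))}
    report.factor_peptides = member

    # 7 (early). direction annotation from group means on the log scale
    g1 = norm.group_mask(contrast[0])
    g2 = norm.group_mask(contrast[1])
    mean_diff = {}
    cols = {p: i for i, p in enumerate(norm.peptide_ids)}
    for pid in sig_ids:
        c = cols[pid]
        mean_diff[pid] = float(norm.values[g2, c].mean() - norm.values[g1, c].mean())
    report.n_increased = sum(1 for d in mean_diff.values() if d > 0)
    report.n_decreased = sum(1 for d in mean_diff.values() if d <= 0)
    for f, peps in member.items():
        up = sum(1 for p in peps if mean_diff[p] > 0)
        report.factor_directions[f] = (
            "increased" if up >= len(peps) / 2 else "decreased"
        ) + f" in {contrast[1]}"

    # 5+6. CFA measurement model and SEM, with top-k fallback
    indicators = [p for peps in member.values() for p in peps]
    if len(indicators) > cfg.max_sem_indicators:
        rank = {r.peptide_id: i for i, r in enumerate(sig)}
        budget = cfg.max_sem_indicators
        trimmed = {}
        for f, peps in member.items():
            share = max(cfg.min_peptides_per_factor,
                        budget * len(peps) // max(len(indicators), 1))
            trimmed[f] = sorted(peps, key=lambda p: rank[p])[:share]
        member_sem = trimmed
        report.warnings.append(
            f"{len(indicators)} indicators exceed the identification budget "
            f"({cfg.max_sem_indicators}); structural stage used the top "
            "peptides per factor")
    else:
        member_sem = member
    report.sem_indicators = [p for peps in member_sem.values() for p in peps]

    spec = CfaSpec(factors={f: list(peps) for f, peps in member_sem.items()},
                   outcome="disease", link="logistic",
                   reference_level=contrast[0])
    try:
        cfa_res, fi, struct = sem_fit(spec, frame, list(_contrast_labels(norm)),
                                      method=cfg.sem_method)
    except Exception as exc:  # pragma: no cover - surfaced, not raised
        report.stopped_at = "sem"
        report.warnings.append(f"SEM stage failed: {exc}")
        return report
    report.cfa_fit_summary = fi.summary()
    report.cfa_converged = cfa_res.converged
    report.structural = struct
    if cfa_res.at_bound is not None and cfa_res.at_bound.any():
        report.warnings.append("residual variance at the lower bound for "
                               f"{int(cfa_res.at_bound.sum())} indicator(s)")

    # collinear factors: flag and also fit single-factor structural models
    if len(member_sem) > 1 and cfa_res.factor_scores is not None:
        sc = cfa_res.factor_scores.corr().to_numpy()
        iu = np.triu_indices_from(sc, k=1)
        if np.any(np.abs(sc[iu]) > cfg.collinearity_r):
            report.warnings.append(
                "factor scores are collinear (|r| > "
                f"{cfg.collinearity_r}); single-factor structural models "
                "fitted alongside the joint model")
        for f, peps in member_sem.items():
            spec1 = CfaSpec(factors={f: list(peps)}, outcome="disease",
                            link="logistic", reference_level=contrast[0])
            try:
                _, _, st1 = sem_fit(spec1, frame, list(_contrast_labels(norm)),
                                    method=cfg.sem_method)
                report.single_factor_structural[f] = st1
            except Exception as exc:
                report.warnings.append(f"single-factor SEM for {f} failed: {exc}")
    return report


class _FrameAdapter:
    """Duck-typed view so efa.correlation can consume a plain DataFrame."""

    def __init__(self, frame: pd.DataFrame):
        self.values = frame.to_numpy(dtype=float)
        self.sample_ids = [str(i) for i in frame.index]
        self.peptide_ids = [str(c) for c in frame.columns]
        self.empty_spot = np.zeros(frame.shape[1], dtype=bool)


def _contrast_labels(norm):
    return norm.group_labels


def write_report(report: DiscoveryReport, out_dir: str) -> list[str]:
    """Write the plain-text summary, TSV tables, and a JSON digest.

    Output is deterministic for identical inputs and seed; re-running
    produces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _path(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    with open(_path("summary.txt"), "w") as fh:
        fh.write(report.summary() + "\n")
    report.significant_table.to_csv(_path("significant_peptides.tsv"),
                                    sep="\t", index=False,
                                    float_format="%.6g")
    if report.factor_loadings is not None:
        report.factor_loadings.round(5).to_csv(_path("factor_loadings.tsv"),
                                               sep="\t", index_label="Peptide ID")
    if report.structural is not None:
        report.structural.coefficients.join(
            report.structural.odds_ratios, lsuffix="_coef", rsuffix="_OR"
        ).round(6).to_csv(_path("structural.tsv"), sep="\t")
    digest = {
        "contrast": list(report.contrast),
        "stopped_at": report.stopped_at,
        "efa_accuracy": report.efa_accuracy,
        "n_significant": report.n_significant,
        "n_factors_inferred": report.n_factors_inferred,
        "n_factors_used": report.n_factors_used,
        "factor_peptides": report.factor_peptides,
        "factor_directions": report.factor_directions,
        "n_increased": report.n_increased,
        "n_decreased": report.n_decreased,
        "odds_ratios": (
            {f: report.structural.odds_ratios.loc[f].to_dict()
             for f in report.structural.odds_ratios.index}
            if report.structural is not None else None),
        "warnings": report.warnings,
        "seed": report.config.seed,
    }
    with open(_path("report.json"), "w") as fh:
        json.dump(digest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return written
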