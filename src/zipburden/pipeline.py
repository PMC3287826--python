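"""Per-gene association scan, multiple-testing control, replicate power.

The scan collapses rare variants per gene, assembles the ZIP design
(trait + age + sex + smoking + K ancestry eigenvectors in both model
components), fits, and tests the trait coefficient.  Genes whose fit is
degenerate are reported as NA rows with a skip reason, never dropped.
Power over phenotype replicates is the fraction of replicates whose
p-value falls below the nominal level and below the Bonferroni
threshold alpha / m, with m the number of genes actually tested.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .collapse import CollapsedCounts, collapse_all
from .io import GeneMap, GenotypeMatrix
from .popstruct import EigenDecomposition
from .zip_model import (DegenerateFitError, OptimizationFailure, ZipDesign,
                        fit_zip, lrt_test, wald_test)

logger = logging.getLogger(__name__)

TRAITS = ("disease", "Q1", "Q2", "Q4")


@dataclass
class ScanConfig:
    """Knobs of a scan: which test, how many eigenvector covariates,
    significance levels, and the collapsing filter."""

    trait: str = "disease"
    function_filter: str = "all"
    maf_ceiling: float | None = None
    n_pcs: int = 10
    alpha: float = 0.05
    test: str = "wald"            # or "lrt" (trait in both components, 2 df)
    bonferroni_m: int | None = None   # fixed m; None = genes actually tested
    seed: int = 0


@dataclass
class AssociationResult:
    gene: str
    trait: str
    function_filter: str
    group: str
    n: int
    beta1: float | None
    se: float | None
    statistic: float | None
    p: float | None
    skip_reason: str | None = None
    significant_nominal: bool | None = None
    significant_bonferroni: bool | None = None

    def flag(self, alpha: float, bonferroni: float) -> None:
        if self.p is None:
            self.significant_nominal = self.significant_bonferroni = None
            return
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        self.significant_nominal = self.p < alpha
        self.significant_bonferroni = self.p < bonferroni


@dataclass
class PowerSummary:
    gene: str
    trait: str
    function_filter: str
    group: str
    n_replicates: int
    n_na: int
    prop_nominal: float
    prop_bonferroni: float
    ci_nominal: tuple[float, float]
    ci_bonferroni: tuple[float, float]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling family-wise error over m
    gene tests (e.g. 0.05 / 3205 = 1.56e-5)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def _trait_values(phen: pd.DataFrame, trait: str, subjects: list[str]
                  ) -> np.ndarray:
    col = "affected" if trait == "disease" else trait
    if col not in phen.columns:
        raise ValueError(f"phenotype table lacks column {col!r}")
    ser = phen.set_index("subject")[col]
    missing = [s for s in subjects if s not in ser.index]
    if missing:
        raise ValueError(f"phenotypes missing for subjects: {missing[:5]}")
    return ser.loc[subjects].to_numpy(dtype=float)


def build_design(counts: CollapsedCounts, phen: pd.DataFrame, trait: str,
                 eig: EigenDecomposition | None, n_pcs: int = 10) -> ZipDesign:
    """Assemble the two-component design for one gene.

    Columns: intercept, trait, age, sex, smoke, PC1..PCK — identical in
    the zero and mean components.  Age and eigenvector columns are
    mean-centered (p-values are invariant to centering; the optimizer
    conditioning is not).  Constant columns (e.g. sex in a single-sex
    subset) are dropped.
    """
    subjects = counts.subjects
    x = _trait_values(phen, trait, subjects)
    covs = phen.drop_duplicates("subject").set_index("subject")
    missing = [s for s in subjects if s not in covs.index]
    if missing:
        raise ValueError(f"covariates missing for subjects: {missing[:5]}")
    covs = covs.loc[subjects]
    cols = [np.ones(len(subjects)), x,
            covs["age"].to_numpy(float) - covs["age"].to_numpy(float).mean(),
            covs["sex"].to_numpy(float), covs["smoke"].to_numpy(float)]
    names = ["intercept", "trait", "age", "sex", "smoke"]
    if eig is not None and n_pcs > 0:
        V = eig.subset(subjects)[:, :n_pcs]
        V = V - V.mean(axis=0)
        for j in range(V.shape[1]):
            cols.append(V[:, j])
            names.append(f"PC{j + 1}")
    X = np.column_stack(cols)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    kept = [names[j] for j in keep]
    return ZipDesign(counts.counts, X, X.copy(), list(kept), list(kept))


def test_gene(counts: CollapsedCounts, phen: pd.DataFrame, trait: str,
              eig: EigenDecomposition | None = None,
              config: ScanConfig | None = None,
              group: str = "pooled") -> AssociationResult:
    """Fit the ZIP model for one gene and test the trait coefficient.

    Returns an NA result (p = None, skip reason recorded) when the gene
    is degenerate instead of raising.
    """
    config = config or ScanConfig(trait=trait)
    base = dict(gene=counts.gene, trait=trait,
                function_filter=counts.function_filter, group=group,
                n=len(counts.subjects))
    try:
        design = build_design(counts, phen, trait, eig, config.n_pcs)
    except ValueError as exc:
        if "rank deficient" in str(exc):
            return AssociationResult(**base, beta1=None, se=None,
                                     statistic=None, p=None,
                                     skip_reason=str(exc))
        raise
    if design.n <= design.n_params:
        return AssociationResult(**base, beta1=None, se=None, statistic=None,
                                 p=None, skip_reason="fewer subjects than "
                                 "coefficients")
    fit = fit_zip(design, seed=config.seed)
    if "trait" not in design.mean_names:
        return AssociationResult(**base, beta1=None, se=None, statistic=None,
                                 p=None, skip_reason="trait constant in group")
    try:
        if config.test == "lrt":
            reduced = fit_zip(design.drop_column("trait"), seed=config.seed)
            try:
                stat, p = lrt_test(fit, reduced)
            except OptimizationFailure:
                fit = fit_zip(design, seed=config.seed + 1)
                stat, p = lrt_test(fit, reduced)
            j = design.mean_names.index("trait")
            b1 = None if fit.beta is None else float(fit.beta[j])
            se = None
        else:
            stat, p = wald_test(fit, "trait")
            j = fit.mean_names.index("trait")
            b1 = float(fit.beta[j])
            se = fit.se_beta(j)
    except DegenerateFitError as exc:
        return AssociationResult(**base, beta1=None, se=None, statistic=None,
                                 p=None, skip_reason=f"degenerate: {exc}")
    return AssociationResult(**base, beta1=b1, se=se, statistic=float(stat),
                             p=float(p))


def run_scan(geno: GenotypeMatrix, gene_map: GeneMap, phen: pd.DataFrame,
             config: ScanConfig, eig: EigenDecomposition | None = None,
             groups: dict[str, str] | None = None
             ) -> tuple[list[AssociationResult], dict]:
    """Scan every testable gene for one phenotype replicate.

    ``groups`` = None runs a pooled scan; otherwise one scan per group,
    with minor alleles and collapsed counts recomputed within each
    group.  Eigenvector covariates (when supplied) adjust both cases.
    Returns (results, metadata); metadata records m (genes actually
    tested) per group and the Bonferroni thresholds.
    """
    group_map = {"pooled": None} if groups is None else _invert_groups(groups)
    results: list[AssociationResult] = []
    meta: dict = {"config": dataclasses.asdict(config), "groups": {}}
    for label in sorted(group_map):
        subset = group_map[label]
        collapsed = collapse_all(geno, gene_map, subset,
                                 config.function_filter, config.maf_ceiling)
        if subset is not None and len(subset) <= 2 * (5 + config.n_pcs):
            logger.warning("group %s has %d subjects; too few for the "
                           "design, skipped", label, len(subset))
            meta["groups"][label] = {"m": 0, "skipped": True}
            continue
        group_results = [
            test_gene(cc, phen, config.trait, eig, config, group=label)
            for cc in collapsed.values()
        ]
        m_tested = sum(1 for r in group_results if r.p is not None)
        m = config.bonferroni_m or max(m_tested, 1)
        thr = bonferroni_threshold(config.alpha, m)
        for r in group_results:
            r.flag(config.alpha, thr)
        results.extend(group_results)
        meta["groups"][label] = {"m": m_tested, "m_bonferroni": m,
                                 "bonferroni_threshold": thr,
                                 "n_collapsed": len(collapsed)}
    return results, meta


def _invert_groups(groups: dict[str, str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for subject, label in groups.items():
        out.setdefault(label, []).append(subject)
    return out


def _clopper_pearson(k: int, n: int, level: float = 0.95
                     ) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def replicate_power(results: list[list[AssociationResult]], alpha: float,
                    bonferroni: float) -> list[PowerSummary]:
    """Empirical power per (gene, trait, filter, group) across replicates.

    Each inner list is one replicate's scan output.  NA results count in
    the denominator and as non-significant; the NA count is reported.
    """
    if not results:
        raise ValueError("no replicates supplied")
    cells: dict[tuple, list[AssociationResult]] = {}
    for rep in results:
        for r in rep:
            cells.setdefault((r.gene, r.trait, r.function_filter, r.group),
                             []).append(r)
    out = []
    for (gene, trait, filt, group), rs in sorted(cells.items()):
        n = len(rs)
        n_na = sum(1 for r in rs if r.p is None)
        k_nom = sum(1 for r in rs if r.p is not None and r.p < alpha)
        k_bon = sum(1 for r in rs if r.p is not None and r.p < bonferroni)
        out.append(PowerSummary(
            gene=gene, trait=trait, function_filter=filt, group=group,
            n_replicates=n, n_na=n_na,
            prop_nominal=k_nom / n, prop_bonferroni=k_bon / n,
            ci_nominal=_clopper_pearson(k_nom, n),
            ci_bonferroni=_clopper_pearson(k_bon, n)))
    return out


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def power_frame(power: list[PowerSummary]) -> pd.DataFrame:
    rows = []
    for p in power:
        d = dataclasses.asdict(p)
        d["ci_nominal_lo"], d["ci_nominal_hi"] = d.pop("ci_nominal")
        d["ci_bonferroni_lo"], d["ci_bonferroni_hi"] = d.pop("ci_bonferroni")
        rows.append(d)
    return pd.DataFrame(rows)


def report_scan(results: list[AssociationResult],
                power: list[PowerSummary] | None,
                out_dir: str | Path, meta: dict | None = None,
                seed: int | None = None) -> dict[str, Path]:
    """Write results.tsv, power.tsv (if any) and manifest.json."""
    if not results:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = results_frame(results).sort_values(["group", "trait", "gene"])
    paths["results"] = out / "results.tsv"
    df.to_csv(paths["results"], sep="\t", index=False, float_format="%.6g")
    if power:
        pdf = power_frame(power).sort_values(["group", "trait", "gene"])
        paths["power"] = out / "power.tsv"
        pdf.to_csv(paths["power"], sep="\t", index=False, float_format="%.6g")
    from . import __version__
    manifest = {"software": "zipburden", "version": __version__,
                "seed": seed, "n_results": len(results)}
    if meta:
        manifest.update(meta)
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
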