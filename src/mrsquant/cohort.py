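"""Cohort contrast statistics: group and hemispheric comparisons.

Implements the statistical layer of the cohort analysis:

* relative group differences Δmf = (mN - fN)/fN and ΔCN = (mC - mN)/mN,
  and hemispheric differences Δrl = (right - left)/left, reported as
  fractions and as integer percentages (half away from zero);
* one-way MANOVA per region with the Wilks-Λ statistic
  Λ = det(E)/det(E + H) and Rao's F approximation;
* post hoc Scheffé pairwise comparisons on the pooled within-group
  variance;
* repeated-measures hemispheric tests realised as one-sample multivariate
  (Hotelling T²) tests on the right-minus-left difference vectors, pooled
  and per group, plus per-metabolite paired t tests;
* Bonferroni thresholds 0.05/9 -> 0.0056 (phosphorus regions) and
  0.05/4 -> 0.0125 (proton regions / bilateral comparisons);
* Table-shaped report assembly.

NAD is excluded from all multivariate tests (weak, frequently rejected by
quality control) but remains representable in the data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import tables
from .config import StatsConfig
from .errors import (PairingError, RankDeficiencyError, SchemaError,
                     UndefinedContrastError)

__all__ = [
    "RelativeDiff",
    "ManovaResult",
    "ContrastResult",
    "HemisphericResult",
    "relative_diff",
    "round_percent",
    "group_manova",
    "posthoc_scheffe",
    "hemispheric_contrast",
    "build_report",
    "CohortAnalysis",
]

_COHORT_COLUMNS = {"subject_id", "group", "region", "hemisphere",
                   "metabolite", "concentration_mmol_per_kg"}


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = _COHORT_COLUMNS - set(cohort.columns)
    if missing:
        raise SchemaError(f"cohort table lacks columns: {sorted(missing)}")
    return cohort


def round_percent(fraction: float) -> int:
    """100x fraction rounded half away from zero, as the printed tables round."""
    x = 100.0 * fraction
    return int(math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5))


@dataclass(frozen=True)
class RelativeDiff:
    """A relative group difference as a fraction and a rounded percentage."""

    fraction: float
    percent: int


def relative_diff(numerator_mean: float, reference_mean: float) -> RelativeDiff:
    """(a - b)/b with the percent rounded half away from zero.

    Used for Δmf (mN vs fN), ΔCN (mC vs mN) and Δrl (right vs left).
    """
    if reference_mean == 0:
        raise UndefinedContrastError("reference group mean is zero")
    fraction = (numerator_mean - reference_mean) / reference_mean
    return RelativeDiff(fraction=fraction, percent=round_percent(fraction))


# --------------------------------------------------------------------------
# MANOVA (Wilks-Lambda with Rao's F approximation)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    n_per_group: dict[str, int]
    dependents: tuple[str, ...]


def _region_wide(cohort: pd.DataFrame, region: str,
                 dependents: tuple[str, ...]) -> pd.DataFrame:
    """subject x metabolite value matrix for one region, listwise complete."""
    sub = cohort[(cohort["region"] == region)
                 & (cohort["metabolite"].isin(dependents))]
    if sub.empty:
        raise SchemaError(f"no data for region {region!r}")
    wide = sub.pivot_table(index=["subject_id", "group"], columns="metabolite",
                           values="concentration_mmol_per_kg", aggfunc="mean")
    wide = wide.reindex(columns=list(dependents)).dropna()
    return wide


def group_manova(cohort: pd.DataFrame, region: str,
                 dependents: tuple[str, ...] = tables.PHOSPHORUS_METABOLITES,
                 groups: tuple[str, ...] = tables.GROUPS) -> ManovaResult:
    """One-way MANOVA of the dependents across groups in one region.

    Wilks Λ = det(E)/det(E+H) from the within- and between-group
    cross-product matrices, with Rao's F approximation for the p value.
    """
    _validate_cohort(cohort)
    dependents = tuple(d for d in dependents if d != "NAD")
    wide = _region_wide(cohort, region, dependents)
    by_group = {g: wide.xs(g, level="group").to_numpy() for g in groups
                if g in wide.index.get_level_values("group")}
    if len(by_group) < 2:
        raise SchemaError("MANOVA needs at least two groups with data")
    p = len(dependents)
    for g, x in by_group.items():
        if x.shape[0] <= p:
            raise SchemaError(
                f"group {g}: n = {x.shape[0]} must exceed the {p} dependents")
    grand = np.vstack(list(by_group.values())).mean(axis=0)
    e = np.zeros((p, p))
    h = np.zeros((p, p))
    n_total = 0
    for x in by_group.values():
        mu = x.mean(axis=0)
        centred = x - mu
        e += centred.T @ centred
        d = (mu - grand)[:, None]
        h += x.shape[0] * (d @ d.T)
        n_total += x.shape[0]
    diag = np.diag(e).copy()
    scale = max(float(diag.max()), 1e-300)
    constant = [dependents[i] for i in range(p) if diag[i] <= 1e-12 * scale]
    if constant:
        raise RankDeficiencyError(constant)
    d_inv = 1.0 / np.sqrt(diag)
    corr = e * np.outer(d_inv, d_inv)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] <= 1e-10 * eigvals[-1]:
        loading = np.abs(eigvecs[:, 0])
        raise RankDeficiencyError(
            [dependents[i] for i in range(p) if loading[i] > 0.3])
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(e + h)
    lam = float(np.exp(logdet_e - logdet_t))
    k = len(by_group)
    q = k - 1
    m = n_total - 1 - (p + q + 1) / 2.0
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_value = (1.0 - lam_s) / lam_s * df2 / df1 if lam_s > 0 else float("inf")
    p_value = float(sps.f.sf(f_value, df1, df2)) if np.isfinite(f_value) else 0.0
    return ManovaResult(lam, f_value, df1, df2, p_value,
                        {g: x.shape[0] for g, x in by_group.items()}, dependents)


def posthoc_scheffe(cohort: pd.DataFrame, region: str, metabolite: str,
                    pair: tuple[str, str],
                    groups: tuple[str, ...] = tables.GROUPS) -> float:
    """Scheffé-adjusted p value for one pairwise mean contrast.

    Uses the pooled within-group variance over all ``groups`` present in
    the region (the MANOVA context), so the adjustment controls the
    family of all possible contrasts.
    """
    _validate_cohort(cohort)
    sub = cohort[(cohort["region"] == region) & (cohort["metabolite"] == metabolite)]
    if sub.empty:
        raise SchemaError(f"no data for {region}/{metabolite}")
    samples = {}
    for g in groups:
        x = sub[sub["group"] == g]["concentration_mmol_per_kg"].to_numpy()
        if x.size >= 2:
            samples[g] = x
    for g in pair:
        if g not in samples:
            raise SchemaError(f"group {g!r} absent from {region}/{metabolite}")
    k = len(samples)
    n_total = sum(x.size for x in samples.values())
    sse = sum(((x - x.mean()) ** 2).sum() for x in samples.values())
    df_err = n_total - k
    mse = sse / df_err
    a, b = samples[pair[0]], samples[pair[1]]
    if mse == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    f_contrast = (a.mean() - b.mean()) ** 2 / (mse * (1.0 / a.size + 1.0 / b.size))
    f_scheffe = f_contrast / (k - 1)
    return float(sps.f.sf(f_scheffe, k - 1, df_err))


# --------------------------------------------------------------------------
# hemispheric (repeated-measures) comparisons
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """One region x metabolite contrast with its test outcome."""

    region: str
    metabolite: str
    contrast: str          # "d_mf" | "d_CN" | "d_rl"
    group: str | None
    fraction: float
    percent: int
    p_value: float
    test: str
    significant_raw: bool
    significant_bonferroni: bool


@dataclass
class HemisphericResult:
    """Right-vs-left outcome for one bilateral region stem."""

    region: str
    pooled_p: float
    per_group_p: dict[str, float]
    contrasts: list[ContrastResult]
    n_pairs: dict[str, int]
    dependents: tuple[str, ...]


def _hotelling_one_sample(diff: np.ndarray) -> float:
    """p value of the one-sample Hotelling T^2 test of mean difference = 0."""
    n, p = diff.shape
    if n <= p:
        raise SchemaError(f"need more than {p} paired subjects, got {n}")
    mean = diff.mean(axis=0)
    if np.allclose(diff, 0.0):
        return 1.0
    cov = np.cov(diff, rowvar=False, ddof=1)
    try:
        sol = np.linalg.solve(cov, mean)
    except np.linalg.LinAlgError:
        # degenerate difference covariance (e.g. noise-free input): the
        # multivariate test is undefined; per-metabolite contrasts remain valid
        return float("nan")
    t2 = n * float(mean @ sol)
    f_value = (n - p) / (p * (n - 1.0)) * t2
    return float(sps.f.sf(f_value, p, n - p))


def hemispheric_contrast(cohort: pd.DataFrame, region: str,
                         dependents: tuple[str, ...] = tables.PHOSPHORUS_METABOLITES,
                         groups: tuple[str, ...] = tables.GROUPS,
                         stats_config: StatsConfig | None = None) -> HemisphericResult:
    """Right-vs-left comparison for one bilateral region stem (TH/BG/TL/FWM).

    Per metabolite and group: Δrl of the group means with a paired t test;
    multivariately: one-sample Hotelling T² on the right-minus-left
    difference vectors, per group and pooled over all subjects.  The
    Bonferroni threshold for the four bilateral comparisons applies.
    """
    _validate_cohort(cohort)
    cfg = stats_config or StatsConfig()
    dependents = tuple(d for d in dependents if d != "NAD")
    if region in tables.PHOSPHORUS_REGIONS:
        raise SchemaError(f"pass a region stem such as 'TH', not {region!r}")
    left, right = f"l_{region}", f"r_{region}"
    wide_l = _region_wide(cohort, left, dependents)
    wide_r = _region_wide(cohort, right, dependents)
    idx_l = set(wide_l.index)
    idx_r = set(wide_r.index)
    unpaired = {sid for sid, _ in idx_l ^ idx_r}
    if unpaired:
        raise PairingError(unpaired)
    common = sorted(idx_l)
    wide_l = wide_l.loc[common]
    wide_r = wide_r.loc[common]
    diff_all = wide_r.to_numpy() - wide_l.to_numpy()

    contrasts: list[ContrastResult] = []
    per_group_p: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    present = [g for g in groups if g in wide_l.index.get_level_values("group")]
    for g in present:
        gl = wide_l.xs(g, level="group")
        gr = wide_r.xs(g, level="group")
        n_pairs[g] = len(gl)
        per_group_p[g] = _hotelling_one_sample(gr.to_numpy() - gl.to_numpy())
        for metab in dependents:
            delta = relative_diff(gr[metab].mean(), gl[metab].mean())
            d = gr[metab].to_numpy() - gl[metab].to_numpy()
            if np.allclose(d, 0.0):
                p_val = 1.0
            elif np.std(d) < 1e-12 * max(abs(d.mean()), 1e-300):
                p_val = float("nan")  # constant non-zero difference: t undefined
            else:
                p_val = float(sps.ttest_rel(gr[metab], gl[metab]).pvalue)
            contrasts.append(ContrastResult(
                region=region, metabolite=metab, contrast="d_rl", group=g,
                fraction=delta.fraction, percent=delta.percent, p_value=p_val,
                test="paired_t", significant_raw=p_val < cfg.alpha,
                significant_bonferroni=p_val < cfg.bonferroni_proton))
    pooled_p = _hotelling_one_sample(diff_all)
    return HemisphericResult(region=region, pooled_p=pooled_p,
                             per_group_p=per_group_p, contrasts=contrasts,
                             n_pairs=n_pairs, dependents=dependents)


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

@dataclass
class Report:
    """Table-shaped cohort report with deterministic serialisation."""

    phosphorus_groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    phosphorus_manova_p: dict[str, float] = field(default_factory=dict)
    hemispheric: dict[str, HemisphericResult] = field(default_factory=dict)
    proton_groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    proton_manova_p: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        out: list[str] = []

        def emit_block(region: str, table: pd.DataFrame, manova_p: float):
            p_txt = "NA" if not np.isfinite(manova_p) else f"{manova_p:.3f}"
            out.append(f"# region\t{region}\tMANOVA_Wilks_p\t{p_txt}")
            out.append("metabolite\tfN\tmN\tmC\tdCN_percent\tscheffe_p")
            for metab, row in table.iterrows():
                cells = [str(metab)]
                for g in tables.GROUPS:
                    v = row.get(g, float("nan"))
                    cells.append("NA" if pd.isna(v) else f"{v:.2f}")
                pc = row.get("dCN_percent")
                cells.append("NA" if pd.isna(pc) else f"{int(pc):d}")
                sp = row.get("scheffe_p")
                cells.append("NA" if pd.isna(sp) else f"{sp:.3f}")
                out.append("\t".join(cells))
            out.append("")

        out.append("## phosphorus: group comparison")
        for region in tables.PHOSPHORUS_REGIONS:
            if region in self.phosphorus_groups:
                emit_block(region, self.phosphorus_groups[region],
                           self.phosphorus_manova_p.get(region, float("nan")))
        out.append("## phosphorus: hemispheric comparison")
        for stem in tables.BILATERAL_REGIONS:
            if stem not in self.hemispheric:
                continue
            h = self.hemispheric[stem]
            out.append(f"# region\t{stem}\tRM_MANOVA_p\t{h.pooled_p:.3f}")
            for g in tables.GROUPS:
                if g in h.per_group_p:
                    out.append(f"group\t{g}\tdrl_p\t{h.per_group_p[g]:.3f}")
            out.append("group\tmetabolite\tdrl_percent\tpaired_t_p")
            for c in h.contrasts:
                out.append(f"{c.group}\t{c.metabolite}\t{c.percent:d}\t{c.p_value:.3f}")
            out.append("")
        out.append("## proton: group comparison")
        for region in tables.PROTON_REGIONS:
            if region in self.proton_groups:
                emit_block(region, self.proton_groups[region],
                           self.proton_manova_p.get(region, float("nan")))
        if self.warnings:
            out.append("## warnings")
            out.extend(self.warnings)
        return "\n".join(out) + "\n"

    def contrast_rows(self) -> pd.DataFrame:
        """All contrasts as one machine-readable frame."""
        rows = []
        for channel, blocks in (("phosphorus", self.phosphorus_groups),
                                ("proton", self.proton_groups)):
            for region, table in blocks.items():
                for metab, row in table.iterrows():
                    for name, num, ref in (("d_mf", "mN", "fN"), ("d_CN", "mC", "mN")):
                        if pd.isna(row.get(num)) or pd.isna(row.get(ref)):
                            continue
                        d = relative_diff(row[num], row[ref])
                        rows.append((channel, region, metab, name, None,
                                     d.fraction, d.percent))
        for stem, h in self.hemispheric.items():
            for c in h.contrasts:
                rows.append(("phosphorus", stem, c.metabolite, "d_rl", c.group,
                             c.fraction, c.percent))
        return pd.DataFrame(rows, columns=["channel", "region", "metabolite",
                                           "contrast", "group", "fraction", "percent"])


def _group_block(cohort: pd.DataFrame, region: str, metabolites: tuple[str, ...],
                 warnings: list[str]) -> tuple[pd.DataFrame, float]:
    rows = {}
    try:
        manova_p = group_manova(cohort, region, metabolites).p_value
    except (RankDeficiencyError, SchemaError) as exc:
        manova_p = float("nan")
        warnings.append(f"{region}: MANOVA unavailable ({exc})")
    for metab in metabolites:
        sub = cohort[(cohort["region"] == region) & (cohort["metabolite"] == metab)]
        row: dict[str, float] = {}
        for g in tables.GROUPS:
            vals = sub[sub["group"] == g]["concentration_mmol_per_kg"]
            if vals.empty:
                warnings.append(f"{region}/{metab}: group {g} has no data")
                row[g] = float("nan")
            else:
                row[g] = float(vals.mean())
        if np.isfinite(row.get("mC", np.nan)) and np.isfinite(row.get("mN", np.nan)):
            row["dCN_percent"] = relative_diff(row["mC"], row["mN"]).percent
        else:
            row["dCN_percent"] = float("nan")
        try:
            row["scheffe_p"] = posthoc_scheffe(cohort, region, metab, ("mC", "mN"))
        except SchemaError:
            row["scheffe_p"] = float("nan")
        rows[metab] = row
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(list(metabolites))
    return table, manova_p


def build_report(cohort: pd.DataFrame,
                 stats_config: StatsConfig | None = None) -> Report:
    """Assemble the full table-shaped cohort report.

    Per phosphorus region: group means (2 decimals in serialisation), the
    ΔCN percent column, the MANOVA header p and the per-metabolite Scheffé
    p.  Per bilateral stem: the hemispheric comparison.  Per proton
    region: the three-metabolite analogue.  The midline FGM voxel has no
    hemispheric block.  Ordering is fixed, so serialisation is
    byte-stable for a fixed input.
    """
    _validate_cohort(cohort)
    report = Report()
    present_regions = set(cohort["region"])
    present_metabs = set(cohort["metabolite"])
    p_metabs = tuple(m for m in tables.PHOSPHORUS_METABOLITES if m in present_metabs)
    h_metabs = tuple(m for m in tables.PROTON_METABOLITES if m in present_metabs)
    if p_metabs:
        for region in tables.PHOSPHORUS_REGIONS:
            if region not in present_regions:
                report.warnings.append(f"{region}: region absent from cohort")
                continue
            table, manova_p = _group_block(cohort, region, p_metabs, report.warnings)
            report.phosphorus_groups[region] = table
            report.phosphorus_manova_p[region] = manova_p
        for stem in tables.BILATERAL_REGIONS:
            if f"l_{stem}" in present_regions and f"r_{stem}" in present_regions:
                try:
                    report.hemispheric[stem] = hemispheric_contrast(
                        cohort, stem, p_metabs, stats_config=stats_config)
                except (RankDeficiencyError, SchemaError, PairingError) as exc:
                    report.warnings.append(f"{stem}: hemispheric test unavailable ({exc})")
    if h_metabs:
        for region in tables.PROTON_REGIONS:
            if region not in present_regions:
                continue
            sub = cohort[cohort["metabolite"].isin(h_metabs)]
            table, manova_p = _group_block(sub, region, h_metabs, report.warnings)
            report.proton_groups[region] = table
            report.proton_manova_p[region] = manova_p
    return report


class CohortAnalysis:
    """Model-style wrapper: bind a cohort table, ``fit()`` builds the report."""

    def __init__(self, cohort: pd.DataFrame, stats_config: StatsConfig | None = None):
        self.cohort = _validate_cohort(cohort)
        self.stats_config = stats_config or StatsConfig()

    def fit(self) -> Report:
        return build_report(self.cohort, self.stats_config)

    def manova(self, region: str, dependents=tables.PHOSPHORUS_METABOLITES) -> ManovaResult:
        return group_manova(self.cohort, region, dependents)

    def scheffe(self, region: str, metabolite: str, pair=("mC", "mN")) -> float:
        return posthoc_scheffe(self.cohort, region, metabolite, pair)

    def hemispheric(self, stem: str,
                    dependents=tables.PHOSPHORUS_METABOLITES) -> HemisphericResult:
        return hemispheric_contrast(self.cohort, stem, dependents,
                                    stats_config=self.stats_config)
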