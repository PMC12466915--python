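"""Individual-level survival assays, sex-dependent effect classification,
and qPCR knockdown-efficiency statistics.

Knockdown-vs-control survival is summarised per sex by mean survival, its
log2 fold change, and a log-rank test; a proportional-hazards fit with a
genotype-by-sex interaction term (shared engine with the pooled
association model) supplies the interaction p-value.  Genes are then
classified as having no effect, consistent, sex-specific, sex-biased or
sexually antagonistic effects, following fold-change-based rules: because
females survive starvation far longer than males, sex comparisons use the
fold change relative to the sex-specific control rather than absolute
hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .association import CoxModel, bh_adjust, fit_cox

__all__ = [
    "SEX_EFFECT_CATEGORIES",
    "SexEffectResult",
    "mean_survival",
    "logrank_test",
    "survival_log2fc",
    "cox_interaction",
    "anova_genotype_sex",
    "classify_sex_effect",
    "analyze_sex_effects",
    "qpcr_relative_expression",
    "knockdown_sex_bias_tests",
]

SEX_EFFECT_CATEGORIES = [
    "no_effect",
    "consistent_enhanced",
    "consistent_weakened",
    "female_specific_enhanced",
    "female_specific_weakened",
    "male_specific_enhanced",
    "male_specific_weakened",
    "female_biased_enhanced",
    "female_biased_weakened",
    "male_biased_enhanced",
    "male_biased_weakened",
    "antagonistic",
]


@dataclass
class SexEffectResult:
    gene: str
    mean_f_kd: float
    mean_f_ctl: float
    mean_m_kd: float
    mean_m_ctl: float
    log2fc_f: float
    log2fc_m: float
    p_logrank_f: float
    p_logrank_m: float
    p_interaction: float
    category: str
    q: float = np.nan


def mean_survival(records: pd.DataFrame) -> float:
    """Mean survival time of one group, in hours.

    With complete mortality (every record an event) this is the
    arithmetic mean; with censoring it falls back to the restricted mean
    of the product-limit (Kaplan-Meier) curve up to the last observed
    time, which coincides with the arithmetic mean in the all-event case.
    """
    if len(records) == 0:
        raise ValueError("empty group")
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool) if "event" in records else np.ones(len(records), bool)
    if events.all():
        return float(times.mean())
    kmf = KaplanMeierFitter().fit(times, events)
    return float(restricted_mean_survival_time(kmf, t=times.max()))


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test; returns (chi2, p)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 individuals")
    ev_a = group_a["event"] if "event" in group_a else np.ones(len(group_a), bool)
    ev_b = group_b["event"] if "event" in group_b else np.ones(len(group_b), bool)
    res = _ll_logrank(
        group_a["time"], group_b["time"], event_observed_A=ev_a, event_observed_B=ev_b
    )
    return float(res.test_statistic), float(res.p_value)


def survival_log2fc(mean_kd: float, mean_ctl: float) -> float:
    """log2 fold change of knockdown vs control mean survival."""
    if mean_kd <= 0 or mean_ctl <= 0:
        raise ValueError("mean survival times must be positive")
    return float(np.log2(mean_kd / mean_ctl))


def cox_interaction(records: pd.DataFrame, ties: str = "efron") -> CoxModel:
    """Proportional-hazards fit with genotype, sex and genotype-by-sex terms.

    Coefficient order: [genotype (knockdown=1), sex (male=1),
    genotype x sex].  The interaction Wald p is ``fit.p_wald[2]``.
    """
    for sex in ("F", "M"):
        for group in ("control", "knockdown"):
            if not ((records["sex"] == sex) & (records["group"] == group)).any():
                raise ValueError(f"empty cell: sex={sex}, group={group}")
    gt = (records["group"] == "knockdown").to_numpy(dtype=float)
    sex = (records["sex"] == "M").to_numpy(dtype=float)
    X = np.column_stack([gt, sex, gt * sex])
    return fit_cox(records["time"].to_numpy(dtype=float), X, ties=ties)


def anova_genotype_sex(records: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of survival time on genotype and sex.

    Type-II sums of squares; returns the statsmodels ANOVA table with
    rows for genotype, sex and their interaction.
    """
    for sex in ("F", "M"):
        for group in ("control", "knockdown"):
            if not ((records["sex"] == sex) & (records["group"] == group)).any():
                raise ValueError(f"empty cell: sex={sex}, group={group}")
    df = records.rename(columns={"group": "genotype"})
    model = smf.ols("time ~ C(genotype) * C(sex)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def classify_sex_effect(
    p_logrank_f: float,
    log2fc_f: float,
    p_logrank_m: float,
    log2fc_m: float,
    p_interaction: float,
    alpha: float = 0.05,
) -> str:
    """Classify a gene's sex-dependent effect on survival.

    Decision order: (1) neither sex significant -> no_effect; (2) exactly
    one sex significant -> sex-specific, regardless of the interaction
    term, with direction from that sex's fold-change sign; (3) both
    significant with opposite fold-change signs -> antagonistic; (4) both
    significant, same sign: a significant genotype-by-sex interaction
    makes the effect sex-biased toward the sex with the larger |log2FC|,
    otherwise it is consistent across sexes.
    """
    sig_f = p_logrank_f < alpha
    sig_m = p_logrank_m < alpha
    if (sig_f and log2fc_f == 0) or (sig_m and log2fc_m == 0):
        raise ValueError("significant effect with a zero fold change is inconsistent")
    if not sig_f and not sig_m:
        return "no_effect"
    if sig_f != sig_m:
        sex = "female" if sig_f else "male"
        fc = log2fc_f if sig_f else log2fc_m
        direction = "enhanced" if fc > 0 else "weakened"
        return f"{sex}_specific_{direction}"
    if np.sign(log2fc_f) != np.sign(log2fc_m):
        return "antagonistic"
    direction = "enhanced" if log2fc_f > 0 else "weakened"
    if p_interaction < alpha:
        sex = "female" if abs(log2fc_f) >= abs(log2fc_m) else "male"
        return f"{sex}_biased_{direction}"
    return f"consistent_{direction}"


def _sex_effect_one(gene: str, records: pd.DataFrame, alpha: float) -> SexEffectResult:
    cells = {}
    for sex in ("F", "M"):
        for group in ("knockdown", "control"):
            cells[(sex, group)] = records[
                (records["sex"] == sex) & (records["group"] == group)
            ]
    means = {k: mean_survival(v) for k, v in cells.items()}
    fc_f = survival_log2fc(means[("F", "knockdown")], means[("F", "control")])
    fc_m = survival_log2fc(means[("M", "knockdown")], means[("M", "control")])
    _, p_f = logrank_test(cells[("F", "knockdown")], cells[("F", "control")])
    _, p_m = logrank_test(cells[("M", "knockdown")], cells[("M", "control")])
    inter = cox_interaction(records)
    p_int = float(inter.p_wald[2]) if inter.converged else np.nan
    category = classify_sex_effect(p_f, fc_f, p_m, fc_m, p_int, alpha=alpha)
    return SexEffectResult(
        gene=gene,
        mean_f_kd=means[("F", "knockdown")],
        mean_f_ctl=means[("F", "control")],
        mean_m_kd=means[("M", "knockdown")],
        mean_m_ctl=means[("M", "control")],
        log2fc_f=fc_f,
        log2fc_m=fc_m,
        p_logrank_f=p_f,
        p_logrank_m=p_m,
        p_interaction=p_int,
        category=category,
    )


def analyze_sex_effects(
    records: pd.DataFrame, gene_col: str = "line", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene sex-effect analysis over a multi-gene assay table.

    Log-rank p-values (both sexes pooled per gene) are BH-adjusted across
    genes and reported as ``q``; classification uses the unadjusted
    per-sex thresholds.
    """
    results = [
        _sex_effect_one(str(gene), sub, alpha)
        for gene, sub in records.groupby(gene_col, sort=True)
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    if len(df):
        pooled = np.minimum(df["p_logrank_f"], df["p_logrank_m"]).clip(1e-300, 1.0)
        df["q"] = bh_adjust(pooled)
    return df


# ---------------------------------------------------------------------------
# qPCR (comparative Ct)
# ---------------------------------------------------------------------------

def qpcr_relative_expression(
    records: pd.DataFrame, gene: str | None = None, sex: str | None = None
) -> tuple[np.ndarray, float]:
    """Relative expression of knockdown vs control by the comparative-Ct
    method.

    Technical replicates are averaged within each biological replicate;
    dCt = Ct(target) - Ct(reference) per biological replicate, and each
    knockdown replicate's relative expression is 2^-(dCt_kd - mean
    dCt_ctl).  Returns (per-replicate values, their mean).  Records with
    a missing reference Ct are dropped with a warning.
    """
    df = records
    if gene is not None:
        df = df[df["gene"] == gene]
    if sex is not None:
        df = df[df["sex"] == sex]
    missing = df["ct_reference"].isna() | df["ct_target"].isna()
    if missing.any():
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d qPCR record(s) with missing Ct", int(missing.sum())
        )
        df = df[~missing]
    bio = (
        df.groupby(["group", "bio_rep"])[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    bio["dct"] = bio["ct_target"] - bio["ct_reference"]
    ctl = bio.loc[bio["group"] == "control", "dct"]
    if ctl.empty:
        raise ValueError("no control group in qPCR records")
    kd = bio.loc[bio["group"] == "knockdown", "dct"]
    rel = np.power(2.0, -(kd.to_numpy() - ctl.mean()))
    return rel, float(rel.mean())


def knockdown_sex_bias_tests(
    expression: pd.DataFrame, categories: dict | pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sex bias in knockdown efficiency: per-category paired t and
    per-gene t tests.

    ``expression`` is long-form (gene, sex, bio_rep, rel_expr).  The
    category test pairs each gene's female and male mean relative
    expression (paired two-sided t; skipped for categories with a single
    gene); the per-gene test compares the biological replicates of the
    two sexes (two-sided two-sample t) with BH adjustment across genes.
    """
    gene_means = (
        expression.groupby(["gene", "sex"])["rel_expr"].mean().unstack()
    )
    per_gene = []
    for gene, sub in expression.groupby("gene"):
        f = sub.loc[sub["sex"] == "F", "rel_expr"].to_numpy()
        m = sub.loc[sub["sex"] == "M", "rel_expr"].to_numpy()
        if f.size >= 2 and m.size >= 2:
            if np.ptp(f) == 0 and np.ptp(m) == 0 and f[0] == m[0]:
                t, p = 0.0, 1.0  # degenerate: identical constant groups
            else:
                t, p = stats.ttest_ind(f, m)
        else:
            t, p = np.nan, np.nan
        per_gene.append({"gene": gene, "t": float(t), "p": float(p)})
    gene_df = pd.DataFrame(per_gene)
    valid = gene_df["p"].notna()
    gene_df["q"] = np.nan
    if valid.any():
        gene_df.loc[valid, "q"] = bh_adjust(gene_df.loc[valid, "p"])

    cat_rows = []
    if categories is not None:
        cat_of = pd.Series(categories)
        for cat in sorted(cat_of.unique()):
            genes = [g for g in cat_of.index[cat_of == cat] if g in gene_means.index]
            if len(genes) < 2:
                continue
            f = gene_means.loc[genes, "F"].to_numpy()
            m = gene_means.loc[genes, "M"].to_numpy()
            if np.ptp(f - m) == 0 and (f - m)[0] == 0:
                t, p = 0.0, 1.0  # no sex difference anywhere
            else:
                t, p = stats.ttest_rel(f, m)
            cat_rows.append(
                {"category": cat, "n_genes": len(genes), "t": float(t), "p": float(p)}
            )
    return pd.DataFrame(cat_rows, columns=["category", "n_genes", "t", "p"]), gene_df
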