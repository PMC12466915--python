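"""Cox proportional-hazards association core for binned pooled counts.

The central idea of the PCSS association test is to treat the sequencing
reads of each phenotypic bin as pseudo-individuals: a variant with ``m``
reference and ``n`` alternative reads in a bin contributes ``m`` REF deaths
and ``n`` ALT deaths, all at the bin's mean survival time.  With a handful
of distinct event times and hundreds of tied deaths at each, the tie
correction (Efron by default, Breslow optionally) dominates the numerics,
so the partial likelihood, score and information are evaluated directly on
the collapsed ``(time, ref_reads, alt_reads)`` table — the sufficient
statistic of the model — rather than on expanded per-read rows.

A variant is called a candidate when it is nominally significant in both
replicates (p < 0.05), has a consistent effect direction across replicates,
and survives Benjamini-Hochberg adjustment of the combined two-replicate
model at q < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxFit",
    "expand_counts_to_survival",
    "collapse_survival",
    "counts_to_collapsed",
    "cox_fit",
    "fit_cox",
    "bh_adjust",
    "fit_all_variants",
    "call_candidates",
]

_MAX_ABS_BETA = 15.0  # |log HR| beyond this is treated as complete separation


@dataclass
class CoxFit:
    """A fitted proportional-hazards coefficient for one contrast.

    ``beta`` is the log hazard ratio of ALT relative to REF; ``hr > 1``
    means the alternative allele increases the death rate (is associated
    with shorter survival).  Non-converged fits (separation, iteration
    cap) carry NaN estimates and must be excluded downstream.
    """

    beta: float
    se: float
    z: float
    p_wald: float
    hr: float
    converged: bool
    n_events: int
    ties_method: str
    n_iter: int = 0


@dataclass
class CoxModel:
    """Full multi-coefficient fit (used by the interaction model too)."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_events: int
    ties_method: str

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_wald(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))


# ---------------------------------------------------------------------------
# count <-> survival-row transforms
# ---------------------------------------------------------------------------

def _bins_with_sample_ids(bins: pd.DataFrame) -> pd.DataFrame:
    out = bins.copy()
    if "sample" not in out.columns:
        out["sample"] = out["replicate"].astype(str) + out["bin_index"].astype(str)
    return out


def expand_counts_to_survival(counts: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Expand one variant's pooled counts into per-read survival rows.

    For a bin with ``ref_reads = m`` and ``alt_reads = n`` the result holds
    exactly m rows with genotype REF and n rows with genotype ALT, each
    carrying the bin's mean survival time; every row is an observed event.
    """
    bins = _bins_with_sample_ids(bins)
    unknown = set(counts["sample"]) - set(bins["sample"])
    if unknown:
        raise ValueError(f"unknown sample id(s) in counts: {sorted(unknown)}")
    merged = counts.merge(
        bins[["sample", "replicate", "mean_survival_h"]], on="sample", how="left"
    )
    times, genotypes, replicates = [], [], []
    for row in merged.itertuples(index=False):
        for gt, k in (("REF", int(row.ref_reads)), ("ALT", int(row.alt_reads))):
            times.extend([row.mean_survival_h] * k)
            genotypes.extend([gt] * k)
            replicates.extend([row.replicate] * k)
    return pd.DataFrame(
        {
            "time": times,
            "event": True,
            "genotype": pd.Categorical(genotypes, categories=["REF", "ALT"]),
            "replicate": replicates,
        }
    )


def collapse_survival(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-read survival rows back to (replicate, time, m, n).

    Inverse of :func:`expand_counts_to_survival` up to row order; the
    collapsed table is the sufficient statistic for the tied-time partial
    likelihood.
    """
    tab = (
        rows.groupby(["replicate", "time"], observed=True)["genotype"]
        .value_counts()
        .unstack(fill_value=0)
        .reset_index()
        .rename(columns={"REF": "ref_reads", "ALT": "alt_reads"})
    )
    for col in ("ref_reads", "alt_reads"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["replicate", "time", "ref_reads", "alt_reads"]]
    tab.columns.name = None
    return tab.sort_values(["replicate", "time"], ignore_index=True)


def counts_to_collapsed(counts: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Directly map one variant's counts to the collapsed survival table."""
    bins = _bins_with_sample_ids(bins)
    unknown = set(counts["sample"]) - set(bins["sample"])
    if unknown:
        raise ValueError(f"unknown sample id(s) in counts: {sorted(unknown)}")
    merged = counts.merge(
        bins[["sample", "replicate", "mean_survival_h"]], on="sample", how="left"
    )
    out = (
        merged.groupby(["replicate", "mean_survival_h"], as_index=False)[
            ["ref_reads", "alt_reads"]
        ]
        .sum()
        .rename(columns={"mean_survival_h": "time"})
    )
    return out.sort_values(["replicate", "time"], ignore_index=True)


# ---------------------------------------------------------------------------
# partial likelihood with ties
# ---------------------------------------------------------------------------

def _group_by_time(times, X, counts):
    """Sort ascending by time and split into tied groups (ascending)."""
    order = np.argsort(times, kind="stable")
    times, X, counts = times[order], X[order], counts[order]
    groups = []
    uniq, starts = np.unique(times, return_index=True)
    bounds = list(starts) + [len(times)]
    for i in range(len(uniq)):
        sl = slice(bounds[i], bounds[i + 1])
        groups.append((X[sl], counts[sl]))
    return groups


def _loglik_parts(beta, groups_desc, ties):
    """Log partial likelihood, score and observed information.

    ``groups_desc`` iterates tied-time groups from the latest event time to
    the earliest so the risk-set sums S0, S1, S2 can be accumulated.
    """
    p = beta.shape[0]
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for Xg, cg in groups_desc:
        eta = Xg @ beta
        w = cg * np.exp(eta)
        S0 += w.sum()
        S1 += w @ Xg
        S2 += (Xg * w[:, None]).T @ Xg
        d = int(cg.sum())
        if d == 0:
            continue
        ll += float(cg @ eta)
        grad += cg @ Xg
        if ties == "breslow":
            ll -= d * np.log(S0)
            xbar = S1 / S0
            grad -= d * xbar
            info += d * (S2 / S0 - np.outer(xbar, xbar))
        else:  # efron
            S0d = w.sum()
            S1d = w @ Xg
            S2d = (Xg * w[:, None]).T @ Xg
            frac = np.arange(d) / d
            A = S0 - frac * S0d  # (d,)
            ll -= float(np.log(A).sum())
            B = S1[None, :] - frac[:, None] * S1d[None, :]  # (d, p)
            g = B / A[:, None]
            grad -= g.sum(axis=0)
            C = S2[None, :, :] - frac[:, None, None] * S2d[None, :, :]
            info += (C / A[:, None, None]).sum(axis=0) - g.T @ g
    return ll, grad, info


def partial_loglik(beta, times, X, counts, ties="efron", strata=None):
    """Log partial likelihood at ``beta`` (exposed for oracle comparisons)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _parts_strata(beta, _build_groups(times, X, counts, strata), ties)
    return ll


def _build_groups(times, X, counts, strata):
    times = np.asarray(times, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    counts = np.asarray(counts, dtype=float)
    if strata is None:
        return [list(reversed(_group_by_time(times, X, counts)))]
    strata = np.asarray(strata)
    out = []
    for s in np.unique(strata):
        m = strata == s
        out.append(list(reversed(_group_by_time(times[m], X[m], counts[m]))))
    return out


def _parts_strata(beta, strata_groups, ties):
    p = beta.shape[0]
    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    for groups_desc in strata_groups:
        l, g, i = _loglik_parts(beta, groups_desc, ties)
        ll += l
        grad += g
        info += i
    return ll, grad, info


def _binary_groups(strata_groups):
    """Precompute (m, n, frac) per tied group for a single 0/1 covariate.

    ``m``/``n`` are the REF/ALT event multiplicities at that time and
    ``frac`` the Efron weights l/d, l = 0..d-1.  Returns None when the
    covariate is not a single binary column.
    """
    out = []
    for groups_desc in strata_groups:
        bg = []
        for Xg, cg in groups_desc:
            if Xg.shape[1] != 1 or not np.isin(Xg, (0.0, 1.0)).all():
                return None
            x = Xg[:, 0]
            m = float(cg[x == 0.0].sum())
            n = float(cg[x == 1.0].sum())
            d = int(m + n)
            bg.append((m, n, np.arange(d) / d if d else np.empty(0)))
        out.append(bg)
    return out


def _parts_binary(beta, binary_groups, ties):
    """Scalar fast path of :func:`_loglik_parts` for one 0/1 covariate."""
    b = float(beta[0])
    eb = np.exp(b)
    ll = grad = info = 0.0
    for bg in binary_groups:
        S0 = S1 = 0.0
        for m, n, frac in bg:
            S0d = m + n * eb
            S1d = n * eb
            S0 += S0d
            S1 += S1d
            d = m + n
            if d == 0:
                continue
            ll += n * b
            grad += n
            if ties == "breslow":
                xbar = S1 / S0
                ll -= d * np.log(S0)
                grad -= d * xbar
                info += d * (xbar - xbar * xbar)
            else:
                A = S0 - frac * S0d
                B = S1 - frac * S1d
                g = B / A
                ll -= float(np.log(A).sum())
                grad -= float(g.sum())
                info += float((B / A - g * g).sum())  # S2 == S1 for x in {0,1}
    return ll, np.array([grad]), np.array([[info]])


def fit_cox(
    times,
    X,
    counts=None,
    ties: str = "efron",
    strata=None,
    max_iter: int = 25,
    tol: float = 1e-9,
) -> CoxModel:
    """Maximise the tied-data Cox partial likelihood by damped Newton steps.

    Parameters
    ----------
    times, X, counts
        Event times, covariate rows, and multiplicities (``counts=None``
        means one event per row).  All rows are events — the design
        observes every individual to death.
    ties
        ``"efron"`` (default) or ``"breslow"`` tie correction.
    strata
        Optional stratum label per row; each stratum contributes its own
        risk sets (used by the stratified-replicate variant of the
        combined model).

    Newton iterations start at beta = 0 with step-halving whenever a step
    does not increase the likelihood; convergence requires the score's
    max-norm to drop below ``tol``.  Monotone likelihoods (complete
    separation) are reported as ``converged=False`` with NaN estimates.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    times = np.asarray(times, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    if counts is None:
        counts = np.ones(len(times))
    counts = np.asarray(counts, dtype=float)
    n_events = int(counts.sum())
    strata_groups = _build_groups(times, X, counts, strata)
    binary = _binary_groups(strata_groups) if X.shape[1] == 1 else None
    if binary is not None:
        parts = lambda b: _parts_binary(b, binary, ties)
    else:
        parts = lambda b: _parts_strata(b, strata_groups, ties)

    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    n_iter = 0
    ll, grad, info = parts(beta)
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: insist on non-decreasing log-likelihood
        new_beta = beta + step
        new = parts(new_beta)
        halvings = 0
        # slack is relative to |ll| so float round-off near the optimum
        # cannot masquerade as a likelihood decrease
        slack = 1e-10 * (1.0 + abs(ll))
        while (not np.isfinite(new[0]) or new[0] < ll - slack) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new = parts(new_beta)
            halvings += 1
        beta = new_beta
        ll, grad, info = new
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _MAX_ABS_BETA:
            break
    else:
        n_iter = max_iter
    if converged and np.max(np.abs(grad)) >= tol:
        converged = False
    if converged and np.max(np.abs(beta)) > _MAX_ABS_BETA:
        # a monotone (separated) likelihood flattens out at extreme beta and
        # can satisfy the score tolerance there; report it as non-convergence
        converged = False
    if converged:
        cov = np.linalg.inv(info)
    else:
        beta = np.full(p, np.nan)
        cov = np.full((p, p), np.nan)
    return CoxModel(
        beta=beta,
        cov=cov,
        loglik=ll if converged else np.nan,
        converged=converged,
        n_iter=n_iter,
        n_events=n_events,
        ties_method=ties,
    )


def _collapsed_to_rows(collapsed: pd.DataFrame, covariates, strata_by_replicate=False):
    """Turn a collapsed table into (times, X, counts, strata) arrays."""
    reps = sorted(collapsed["replicate"].unique())
    times, rows_x, counts, strata = [], [], [], []
    for row in collapsed.itertuples(index=False):
        for gt, k in ((0, row.ref_reads), (1, row.alt_reads)):
            if k <= 0:
                continue
            x = [float(gt)]
            if "replicate" in covariates:
                x.append(float(reps.index(row.replicate) > 0))
            times.append(row.time)
            rows_x.append(x)
            counts.append(k)
            strata.append(row.replicate)
    strata_arr = np.array(strata) if strata_by_replicate else None
    return (
        np.array(times),
        np.array(rows_x),
        np.array(counts, dtype=float),
        strata_arr,
    )


def cox_fit(
    collapsed: pd.DataFrame,
    covariates=("GT",),
    ties: str = "efron",
    stratify_replicate: bool = False,
) -> CoxFit:
    """Fit the proportional-hazards model for one variant.

    ``covariates=("GT",)`` fits a single replicate; ``("GT", "replicate")``
    is the combined model with replicate as a binary covariate (the
    default form), or as a stratum if ``stratify_replicate`` is set.
    Returns the GT (ALT vs REF) coefficient.
    """
    total_ref = collapsed["ref_reads"].sum()
    total_alt = collapsed["alt_reads"].sum()
    if total_ref == 0 or total_alt == 0:
        raise ValueError("undefined contrast: variant is monomorphic in these samples")
    if collapsed["time"].nunique() < 2:
        raise ValueError("need >= 2 distinct event times")
    use_cov = tuple(c for c in covariates if not (stratify_replicate and c == "replicate"))
    times, X, counts, strata = _collapsed_to_rows(
        collapsed, use_cov, strata_by_replicate=stratify_replicate
    )
    model = fit_cox(times, X, counts, ties=ties, strata=strata)
    if not model.converged:
        return CoxFit(
            beta=np.nan, se=np.nan, z=np.nan, p_wald=np.nan, hr=np.nan,
            converged=False, n_events=model.n_events, ties_method=ties,
            n_iter=model.n_iter,
        )
    beta = float(model.beta[0])
    se = float(model.se[0])
    z = beta / se
    return CoxFit(
        beta=beta,
        se=se,
        z=z,
        p_wald=float(2.0 * stats.norm.sf(abs(z))),
        hr=float(np.exp(beta)),
        converged=True,
        n_events=model.n_events,
        ties_method=ties,
        n_iter=model.n_iter,
    )


# ---------------------------------------------------------------------------
# multiple testing and candidate calling
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def variant_id(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def fit_all_variants(
    counts: pd.DataFrame,
    bins: pd.DataFrame,
    ties: str = "efron",
    stratify_replicate: bool = False,
) -> pd.DataFrame:
    """Per-variant Cox fits: each replicate separately plus combined.

    Replicate-specific fits use that replicate's own bin mean times.
    Variants that are monomorphic or degenerate in a fit carry NaN for
    that fit and ``converged=False``.
    """
    bins = _bins_with_sample_ids(bins)
    reps = sorted(bins["replicate"].unique())
    if len(reps) != 2:
        raise ValueError(f"expected exactly 2 replicates, got {reps}")
    counts = counts.copy()
    counts["variant_id"] = variant_id(counts)
    records = []
    for vid, sub in counts.groupby("variant_id", sort=True):
        collapsed = counts_to_collapsed(
            sub[["sample", "ref_reads", "alt_reads"]], bins
        )
        rec = {"variant_id": vid}
        first = sub.iloc[0]
        for key in ("chrom", "pos", "ref", "alt"):
            rec[key] = first[key]
        ok = True
        for rep in reps:
            part = collapsed[collapsed["replicate"] == rep]
            try:
                fit = cox_fit(part, covariates=("GT",), ties=ties)
            except ValueError:
                fit = None
            tag = f"rep{rep}"
            rec[f"beta_{tag}"] = fit.beta if fit else np.nan
            rec[f"p_{tag}"] = fit.p_wald if fit else np.nan
            rec[f"converged_{tag}"] = bool(fit and fit.converged)
            ok = ok and bool(fit and fit.converged)
        try:
            comb = cox_fit(
                collapsed,
                covariates=("GT", "replicate"),
                ties=ties,
                stratify_replicate=stratify_replicate,
            )
        except ValueError:
            comb = None
        rec["beta_combined"] = comb.beta if comb else np.nan
        rec["se_combined"] = comb.se if comb else np.nan
        rec["hr_combined"] = comb.hr if comb else np.nan
        rec["p_combined"] = comb.p_wald if comb else np.nan
        rec["converged_combined"] = bool(comb and comb.converged)
        records.append(rec)
    return pd.DataFrame(records)


def call_candidates(
    fits: pd.DataFrame,
    p_rep_threshold: float = 0.05,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Apply the three-part candidate rule to a per-variant fit table.

    A variant is a candidate iff (i) p < 0.05 in each replicate-specific
    fit, (ii) the replicate effect directions agree, and (iii) the BH
    q-value of the combined model is < 0.01.  BH is adjusted across all
    variants whose combined fit converged; non-converged variants are
    retained in the output with ``is_candidate=False`` and NaN q.
    """
    rep_p_cols = sorted(
        c for c in fits.columns if c.startswith("p_rep") and c != "p_combined"
    )
    if len(rep_p_cols) != 2:
        raise ValueError("fit table must carry exactly two replicate p columns")
    rep_beta_cols = [c.replace("p_", "beta_") for c in rep_p_cols]
    rep_conv_cols = [c.replace("p_", "converged_") for c in rep_p_cols]
    out = fits.copy()
    usable = (
        out["converged_combined"]
        & out[rep_conv_cols[0]]
        & out[rep_conv_cols[1]]
        & out["p_combined"].notna()
    )
    out["q_combined"] = np.nan
    if usable.any():
        out.loc[usable, "q_combined"] = bh_adjust(out.loc[usable, "p_combined"])
    out["n_tested"] = int(usable.sum())
    same_sign = np.sign(out[rep_beta_cols[0]]) == np.sign(out[rep_beta_cols[1]])
    out["is_candidate"] = (
        usable
        & (out[rep_p_cols[0]] < p_rep_threshold)
        & (out[rep_p_cols[1]] < p_rep_threshold)
        & same_sign
        & (out["q_combined"] < q_threshold)
    )
    return out
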