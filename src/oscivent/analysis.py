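"""Study analysis stage on long-format measurement tables.

Implements the statistical workflow applied to the cohort data: per-subject
relative changes versus the post-injury reference point, group summaries as
mean +/- half-width of the 95 % confidence interval, many-to-one
reference-level contrasts with a Dunnett-type multiplicity family, and the
principal-component composite built from the seven primary variables.

The heavy mixed-model machinery is delegated to statsmodels (repeated
measures, subject-level random intercept) and, for the one-way case, to
scipy's Dunnett test; this module owns what the study protocol specifies:
the factor structure (time reference T0, PEEP reference 6 cmH2O, mode
reference PVV), the per-variable Shapiro-Wilk screen with log-transform on
failure, and the single-step many-to-one adjustment within each factor
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from sklearn.decomposition import PCA

from .cohort import VARIABLES

__all__ = [
    "relative_change",
    "summarize",
    "reference_contrasts",
    "pca_composites",
    "PCAResult",
]

_FACTOR_REFS = {"timepoint": "T0", "peep": 6.0, "mode": "PVV"}


def relative_change(
    table: pd.DataFrame, reference: str = "T0"
) -> pd.DataFrame:
    """Per-subject percentage change of each variable versus a reference time.

    Returns the table restricted to non-reference timepoints with ``value``
    replaced by ``(value / value_at_reference - 1) * 100``.  Subject x
    variable pairs with no reference row are excluded with a warning.
    """
    ref = table[table["timepoint"] == reference]
    if ref.empty:
        raise ValueError(f"no rows at reference timepoint {reference!r}")
    ref_map = ref.set_index(["subject_id", "variable"])["value"]
    if ref_map.index.duplicated().any():
        raise ValueError("multiple reference rows per subject x variable")
    out = table[table["timepoint"] != reference].copy()
    keys = pd.MultiIndex.from_frame(out[["subject_id", "variable"]])
    have_ref = keys.isin(ref_map.index)
    if not have_ref.all():
        missing = out.loc[~have_ref, ["subject_id", "variable"]].drop_duplicates()
        warnings.warn(
            f"excluding {len(missing)} subject x variable pairs without a "
            f"{reference} reference row",
            RuntimeWarning,
            stacklevel=2,
        )
        out = out[have_ref]
        keys = keys[have_ref]
    out["value"] = (out["value"].to_numpy() / ref_map.loc[keys].to_numpy() - 1.0) * 100.0
    return out


def _ci_half_width(x: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return np.nan
    return float(stats.t.ppf(0.975, n - 1) * np.std(x, ddof=1) / np.sqrt(n))


def summarize(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("mode", "peep", "timepoint", "variable"),
) -> pd.DataFrame:
    """Mean and t-based 95 % CI half-width per group x timepoint x variable.

    Cells with a single subject get a mean with an undefined (NaN)
    half-width, flagged in the ``ci_defined`` column.
    """
    rows = []
    for key, sub in table.groupby(list(by), sort=True):
        x = sub["value"].to_numpy(dtype=float)
        rows.append(
            dict(
                zip(by, key),
                mean=float(np.mean(x)),
                ci_half_width=_ci_half_width(x),
                n=len(x),
                ci_defined=len(x) >= 2,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference-level contrasts


def _dunnett_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step max-|Z| adjustment: P(max_i |Z_i| >= |z_j|) under N(0, R)."""
    k = len(z)
    if k == 1:
        return 2.0 * stats.norm.sf(np.abs(z))
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    out = np.empty(k)
    for j, zj in enumerate(np.abs(z)):
        lo = np.full(k, -zj)
        hi = np.full(k, zj)
        out[j] = 1.0 - float(mvn.cdf(hi, lower_limit=lo))
    return np.clip(out, 0.0, 1.0)


def _needs_log(values: np.ndarray) -> bool:
    """Shapiro-Wilk normality screen; log-transform on failure if possible."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or np.ptp(v) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(v if len(v) <= 5000 else v[:5000]).pvalue
    return bool(p < 0.05) and bool(np.all(v > 0))


def _mixed_model_contrasts(df: pd.DataFrame, factors: list[str]) -> list[dict]:
    terms = []
    for f in factors:
        ref = _FACTOR_REFS[f]
        ref_repr = repr(ref) if isinstance(ref, str) else ref
        terms.append(f"C({f}, Treatment({ref_repr}))")
    formula = "value ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, df, groups=df["subject_id"]).fit(reml=True)
    rows = []
    params = fit.params
    cov = fit.cov_params()
    for f, term in zip(factors, terms):
        names = [n for n in params.index if n.startswith(term)]
        if not names:
            continue
        est = params[names].to_numpy()
        v = cov.loc[names, names].to_numpy()
        se = np.sqrt(np.diag(v))
        zstat = est / se
        corr = v / np.outer(se, se)
        p_adj = _dunnett_adjust(zstat, corr)
        for name, e, s, zv, pa in zip(names, est, se, zstat, p_adj):
            level = name.split("[T.")[-1].rstrip("]")
            rows.append(
                dict(
                    factor=f,
                    level=level,
                    reference=_FACTOR_REFS[f],
                    estimate=float(e),
                    se=float(s),
                    stat=float(zv),
                    p_adj=float(pa),
                    method="mixedlm+maxz",
                )
            )
    return rows


def _oneway_dunnett(df: pd.DataFrame, factor: str) -> list[dict]:
    ref = _FACTOR_REFS[factor]
    levels = [l for l in df[factor].unique() if l != ref]
    control = df.loc[df[factor] == ref, "value"].to_numpy(dtype=float)
    samples = [df.loc[df[factor] == l, "value"].to_numpy(dtype=float) for l in levels]
    res = stats.dunnett(*samples, control=control)
    rows = []
    for l, s, st, p in zip(levels, samples, res.statistic, res.pvalue):
        rows.append(
            dict(
                factor=factor,
                level=l,
                reference=ref,
                estimate=float(np.mean(s) - np.mean(control)),
                se=np.nan,
                stat=float(st),
                p_adj=float(p),
                method="dunnett",
            )
        )
    return rows


def reference_contrasts(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Many-to-one contrasts against the protocol reference levels.

    Per variable: a Shapiro-Wilk screen decides a log transform; with
    repeated timepoints a linear mixed model (random subject intercept) is
    fitted on the varying factors among time / PEEP / mode, and each
    factor's levels are compared against its reference (T0, 6 cmH2O, PVV)
    with a single-step max-|Z| family adjustment.  With a single timepoint
    and a single varying factor the exact one-way Dunnett test is used.
    Factor levels carried by fewer than two subjects are excluded.
    """
    rows = []
    for var, sub in table.groupby("variable"):
        df = sub.copy()
        # exclude levels with < 2 subjects
        for f in ("timepoint", "peep", "mode"):
            counts = df.groupby(f)["subject_id"].nunique()
            thin = counts[counts < 2].index
            if len(thin):
                warnings.warn(
                    f"{var}: excluding {f} levels {list(thin)} with < 2 subjects",
                    RuntimeWarning,
                    stacklevel=2,
                )
                df = df[~df[f].isin(thin)]
        transformed = _needs_log(df["value"].to_numpy())
        if transformed:
            df["value"] = np.log(df["value"])
        factors = []
        for f in ("timepoint", "peep", "mode"):
            if df[f].nunique() <= 1:
                continue
            if _FACTOR_REFS[f] not in set(df[f]):
                warnings.warn(
                    f"{var}: reference level {_FACTOR_REFS[f]!r} absent for "
                    f"factor {f}; skipping its contrasts",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            factors.append(f)
        if not factors:
            continue
        repeated = df["timepoint"].nunique() > 1
        if not repeated and len(factors) == 1:
            var_rows = _oneway_dunnett(df, factors[0])
        else:
            var_rows = _mixed_model_contrasts(df, factors)
        for r in var_rows:
            r.update(variable=var, log_transformed=transformed,
                     significant=r["p_adj"] < alpha)
            rows.append(r)
    cols = [
        "variable", "factor", "level", "reference", "estimate", "se",
        "stat", "p_adj", "significant", "log_transformed", "method",
    ]
    return pd.DataFrame(rows)[cols] if rows else pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# PCA composite


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of the per-subject T5/T0 - 1 composites."""

    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # subjects x components (PC1..)

    @property
    def n_components(self) -> int:
        return len(self.explained_variance_ratio)


def pca_composites(
    table: pd.DataFrame,
    variables: tuple[str, ...] = VARIABLES,
    end: str = "T5",
    reference: str = "T0",
) -> PCAResult:
    """PCA on standardized per-subject ``end/reference - 1`` composites.

    The seven primary variables have incommensurable units, so each
    composite column is z-scored (correlation-matrix PCA).  The sign of
    each component is fixed by making its largest-magnitude loading
    positive.  At least 8 subjects are required.
    """
    sub = table[table["variable"].isin(variables)]
    wide_ref = sub[sub["timepoint"] == reference].pivot(
        index="subject_id", columns="variable", values="value"
    )
    wide_end = sub[sub["timepoint"] == end].pivot(
        index="subject_id", columns="variable", values="value"
    )
    common = wide_ref.index.intersection(wide_end.index)
    comp = (wide_end.loc[common, list(variables)] /
            wide_ref.loc[common, list(variables)] - 1.0).dropna()
    if len(comp) < 8:
        raise ValueError(f"need >= 8 complete subjects, got {len(comp)}")
    x = comp.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    pca = PCA(n_components=len(variables), svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # variables x components
    # deterministic sign convention
    for j in range(loadings.shape[1]):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=list(variables), columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores, index=comp.index, columns=names),
    )
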