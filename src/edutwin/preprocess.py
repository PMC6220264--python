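"""Phenotype preparation for twin analyses.

Achievement measures are prepared in the order: composite construction,
covariate (age/sex) residualization, then rank-based normalization to
correct skew.  Because co-twins are identical in age (and MZ co-twins in
sex), leaving covariate means in the scores would inflate the apparent
shared environment; residualizing first removes that artifact.  All
transforms preserve missingness and operate on aligned pandas Series or
numpy arrays with NaN for missing.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from edutwin.synthetic import TwinPairTable

logger = logging.getLogger("edutwin")


def _as_series(x, name: str = "pheno") -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(np.asarray(x, dtype=float), name=name)


def _zscore(values: np.ndarray) -> np.ndarray:
    """Standardize over non-missing entries (mean 0, sd 1, ddof 0)."""
    mask = np.isfinite(values)
    mu = values[mask].mean()
    sd = values[mask].std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    out = np.full_like(values, np.nan, dtype=float)
    out[mask] = (values[mask] - mu) / sd
    return out


def _check_full_rank(design: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the first column that is linearly dependent on the ones
    before it (the intercept is column 0)."""
    rank = 0
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            raise ValueError(
                f"covariate column {names[j]!r} is collinear with the "
                "preceding columns (rank-deficient design)"
            )
        rank = new_rank


def residualize(
    pheno,
    covariates,
    covariate_names: Sequence[str] | None = None,
    fit_mask: np.ndarray | None = None,
) -> pd.Series:
    """Standardized residuals of an OLS fit of the phenotype on covariates.

    ``fit_mask`` restricts the regression fit to a subset of rows (e.g. one
    randomly chosen twin per family) while the correction is applied to all
    rows; missing phenotype entries stay missing.
    """
    s = _as_series(pheno)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(s) != x.shape[0]:
        raise ValueError("covariates must be row-aligned with the phenotype")
    if covariate_names is None:
        covariate_names = [f"covariate_{j}" for j in range(x.shape[1])]
    y = s.to_numpy(dtype=float)
    obs = np.isfinite(y) & np.isfinite(x).all(axis=1)
    if not obs.any():
        raise ValueError("phenotype has no non-missing values")
    use = obs & (fit_mask if fit_mask is not None else True)
    if use.sum() < x.shape[1] + 2:
        raise ValueError("too few rows available to fit the covariate regression")
    design = np.column_stack([np.ones(int(use.sum())), x[use]])
    _check_full_rank(design, ["intercept", *covariate_names])
    coef, *_ = np.linalg.lstsq(design, y[use], rcond=None)
    resid = np.full_like(y, np.nan)
    full_design = np.column_stack([np.ones(int(obs.sum())), x[obs]])
    resid[obs] = y[obs] - full_design @ coef
    if np.nanstd(resid) < 1e-12:
        raise ValueError(
            "phenotype is an exact linear function of the covariates; "
            "residuals are degenerate"
        )
    return pd.Series(_zscore(resid), index=s.index, name=s.name)


def vdw_transform(pheno) -> pd.Series:
    """Van der Waerden rank-based inverse normal transform.

    The value of rank r among n non-missing observations maps to the
    standard-normal quantile at r / (n + 1); ties receive the quantile of
    their mid-rank.  The result is symmetric around zero and invariant to
    any strictly monotone transform of the input.
    """
    s = _as_series(pheno)
    y = s.to_numpy(dtype=float)
    mask = np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    vals = y[mask]
    if np.ptp(vals) == 0:
        raise ValueError("all values identical: ranks carry no information")
    ranks = stats.rankdata(vals, method="average")
    out = np.full_like(y, np.nan)
    out[mask] = stats.norm.ppf(ranks / (n + 1))
    return pd.Series(out, index=s.index, name=s.name)


def composite_mean(components: Sequence, min_available: int = 1) -> pd.Series:
    """Mean of standardized components, per row, using whatever is present.

    A row's composite is missing when fewer than ``min_available``
    components are non-missing there.
    """
    if len(components) == 0:
        raise ValueError("need at least one component")
    if min_available < 1:
        raise ValueError("min_available must be >= 1")
    mats = []
    index = None
    for comp in components:
        s = _as_series(comp)
        if index is None:
            index = s.index
        elif len(s) != len(index):
            raise ValueError("components must be row-aligned")
        mats.append(_zscore(s.to_numpy(dtype=float)))
    z = np.column_stack(mats)
    count = np.isfinite(z).sum(axis=1)
    sums = np.nansum(z, axis=1)
    comp_mean = np.where(count >= min_available, sums / np.maximum(count, 1), np.nan)
    return pd.Series(comp_mean, index=index, name="composite")


def variance_explained_by_groups(pheno, sex, zygosity) -> float:
    """Eta-squared from a two-factor ANOVA (sex, zygosity, interaction).

    Returns the between-groups sum of squares over the total — the fraction
    of phenotypic variance the grouping explains.
    """
    s = _as_series(pheno)
    sex = pd.Series(np.asarray(sex, dtype=object))
    zyg = pd.Series(np.asarray(zygosity, dtype=object))
    mask = s.notna().to_numpy()
    y = s.to_numpy(dtype=float)[mask]
    sex, zyg = sex[mask], zyg[mask]
    for name, f in (("sex", sex), ("zygosity", zyg)):
        if f.nunique() < 2:
            raise ValueError(f"factor {name!r} has a single level")
    cells = pd.Series(y).groupby([sex.to_numpy(), zyg.to_numpy()])
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("phenotype is constant")
    ss_within = float(cells.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    return (ss_total - ss_within) / ss_total


def regress_out_g(phenos: Sequence, g) -> list[pd.Series]:
    """Replace each phenotype by its standardized residual on g.

    Residuals are exactly uncorrelated with g over the jointly observed
    rows.  Raises for a constant g; a phenotype that is itself (a linear
    function of) g is degenerate and raises too.
    """
    g_s = _as_series(g, name="g")
    gv = g_s.to_numpy(dtype=float)
    if np.nanstd(gv) < 1e-12:
        raise ValueError("g is constant; cannot regress it out")
    out = []
    for pheno in phenos:
        out.append(residualize(pheno, gv[:, None], covariate_names=["g"]))
    return out


def prepare_twin_table(
    table: TwinPairTable,
    seed: int = 0,
    use_age_sex: bool = True,
    skew_correct: bool = True,
) -> TwinPairTable:
    """Paper-style preparation of every occasion of a twin table.

    For each occasion, an age/sex OLS correction is fitted on one randomly
    selected twin per family (so families are not double-counted) and
    applied to both twins jointly; the corrected scores are then mapped
    through the van der Waerden transform (both twins pooled so co-twins
    stay on one scale).
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n = len(df)
    pick_first = rng.random(n) < 0.5
    sex_num = {"F": 1.0, "M": 0.0}
    for t in range(table.n_occasions):
        c1, c2 = f"{table.measure}{t + 1}_1", f"{table.measure}{t + 1}_2"
        age = df[f"age{t + 1}"].to_numpy(dtype=float) if f"age{t + 1}" in df else np.zeros(n)
        stacked = pd.concat([df[c1], df[c2]], ignore_index=True)
        sex = np.concatenate([
            df["sex1"].map(sex_num).to_numpy(),
            df["sex2"].map(sex_num).to_numpy(),
        ])
        ages = np.concatenate([age, age])
        fit_mask = np.concatenate([pick_first, ~pick_first])
        covs = np.column_stack([ages, sex])
        names = ["age", "sex"]
        if np.ptp(ages[np.isfinite(ages)]) == 0:  # shared assessment age: no age term
            covs, names = covs[:, 1:], names[1:]
        if use_age_sex:
            stacked = residualize(stacked, covs, covariate_names=names, fit_mask=fit_mask)
        if skew_correct:
            stacked = vdw_transform(stacked)
        df[c1] = stacked.to_numpy()[:n]
        df[c2] = stacked.to_numpy()[n:]
    meta = dict(table.meta)
    meta["preprocess"] = {
        "seed": seed, "age_sex_correction": use_age_sex, "vdw": skew_correct,
    }
    return TwinPairTable(
        data=df, n_occasions=table.n_occasions, measure=table.measure, meta=meta
    )
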