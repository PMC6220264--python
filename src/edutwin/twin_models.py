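"""Twin structural-equation models: ACE, Cholesky, simplex, common pathway.

The estimation strategy throughout is maximum likelihood on per-zygosity
sample covariance matrices over the stacked vector
(twin-1 occasions, twin-2 occasions).  Each model supplies an implied
covariance with the twin structure

    [[Sigma_within, Sigma_cross], [Sigma_cross, Sigma_within]]

where the additive-genetic block enters Sigma_cross with weight 1 for MZ
pairs and 0.5 for DZ pairs, the shared-environment block with weight 1, and
the non-shared block with weight 0.  Minimizing the multigroup normal-theory
(Wishart) discrepancy gives the path estimates; profile likelihood gives
confidence intervals; likelihood-ratio tests compare nested models.

Variance components are parameterized as path coefficients (variances enter
as squares) so non-negativity holds by construction without box constraints
on the variances themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from edutwin.synthetic import (
    ACEParams,
    CommonPathwayParams,
    ParameterError,
    SimplexComponent,
    SimplexParams,
    TwinPairTable,
)

logger = logging.getLogger("edutwin")

_NONPD_PENALTY = 1e10
_DZ_A_WEIGHT = 0.5  # no assortative-mating correction; conservative for A

ZYGOSITY_GROUPS = ("MZ", "DZ")


class FitError(RuntimeError):
    """Model fitting failed (non-convergence or infeasible configuration)."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GroupCovariances:
    """Per-zygosity sample covariance of (twin1 occasions, twin2 occasions).

    Covariances are symmetrized over the arbitrary twin ordering (averaged
    with the twin-swapped matrix) since the models treat co-twins as
    exchangeable.
    """

    covs: dict[str, np.ndarray]
    ns: dict[str, int]
    labels: list[str]

    def __post_init__(self) -> None:
        dims = {g: s.shape for g, s in self.covs.items()}
        if len(set(dims.values())) != 1:
            raise ValueError(f"group covariance dimensions differ: {dims}")
        p = next(iter(dims.values()))[0]
        for g, s in self.covs.items():
            if not np.allclose(s, s.T, atol=1e-10):
                raise ValueError(f"{g} covariance matrix is not symmetric")
            if self.ns[g] < p + 1:
                raise ValueError(f"{g} sample size {self.ns[g]} < dimension + 1")

    @property
    def n_vars(self) -> int:
        return next(iter(self.covs.values())).shape[0] // 2

    @classmethod
    def from_table(
        cls,
        table: TwinPairTable,
        measures: Sequence[str] | None = None,
        symmetrize: bool = True,
    ) -> "GroupCovariances":
        if measures is None:
            measures = [f"{table.measure}{t + 1}" for t in range(table.n_occasions)]
        covs: dict[str, np.ndarray] = {}
        ns: dict[str, int] = {}
        for zyg in ZYGOSITY_GROUPS:
            arr = table.pair_matrix(zyg, measures)
            if arr.shape[0] < 2 * len(measures) + 1:
                raise ValueError(
                    f"too few complete pairs in group {zyg}: {arr.shape[0]}"
                )
            s = np.cov(arr, rowvar=False, ddof=1)
            if symmetrize:
                p = len(measures)
                perm = np.r_[p : 2 * p, 0:p]
                s = 0.5 * (s + s[np.ix_(perm, perm)])
            covs[zyg] = s
            ns[zyg] = arr.shape[0]
        return cls(covs=covs, ns=ns, labels=list(measures))


@dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular path matrices for A, C, E over the measured variables."""

    l_a: np.ndarray
    l_c: np.ndarray
    l_e: np.ndarray

    def __post_init__(self) -> None:
        for name in ("l_a", "l_c", "l_e"):
            m = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, m)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ParameterError(f"{name} must be square")
            if not np.allclose(m, np.tril(m)):
                raise ParameterError(f"{name} must be lower triangular")
            if np.any(np.diag(m) < 0):
                raise ParameterError(f"{name} diagonal must be >= 0 (sign convention)")
        if not (self.l_a.shape == self.l_c.shape == self.l_e.shape):
            raise ParameterError("A, C, E path matrices must share a shape")

    @property
    def n_vars(self) -> int:
        return self.l_a.shape[0]


@dataclass
class FitResult:
    """Estimates, fit statistics and derived quantities for one fitted model."""

    model: str
    estimates: dict[str, float]
    neg2ll: float
    n_free: int
    converged: bool
    grad_norm: float
    derived: dict = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    data: GroupCovariances | None = None
    _x: np.ndarray | None = None
    _labels: list[str] | None = None
    _objective: Callable[[np.ndarray], float] | None = None
    _bounds: list[tuple[float | None, float | None]] | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "neg2ll": float(self.neg2ll),
            "n_free": self.n_free,
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "derived": {k: _to_plain(v) for k, v in self.derived.items()},
            "ci": {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()},
            "flags": list(self.flags),
        }


def _to_plain(v):
    import dataclasses

    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return _to_plain(dataclasses.asdict(v))
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, dict):
        return {k: _to_plain(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_to_plain(x) for x in v]
    return v


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def intraclass_correlations(
    table: TwinPairTable, measure: str | None = None
) -> dict[str, float]:
    """Double-entry Pearson twin correlation per zygosity group.

    Each pair is entered twice, as (twin1, twin2) and (twin2, twin1), which
    makes the estimate invariant to the arbitrary twin labelling.
    """
    if measure is None:
        measure = f"{table.measure}1"
    out: dict[str, float] = {}
    for zyg in ZYGOSITY_GROUPS:
        arr = table.pair_matrix(zyg, [measure])
        if arr.shape[0] < 3:
            raise ValueError(f"fewer than 3 complete pairs in group {zyg}")
        x = np.concatenate([arr[:, 0], arr[:, 1]])
        y = np.concatenate([arr[:, 1], arr[:, 0]])
        out[zyg] = float(np.corrcoef(x, y)[0, 1])
    return out


@dataclass(frozen=True)
class FalconerEstimates:
    a2: float
    c2: float
    e2: float
    out_of_bounds: bool


def falconer_estimates(r_mz: float, r_dz: float) -> FalconerEstimates:
    """Falconer's formula: A = 2(rMZ - rDZ), C = rMZ - A, E = 1 - rMZ.

    Values are returned unclipped; ``out_of_bounds`` flags estimates outside
    [0, 1] (e.g. when rDZ > rMZ).
    """
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    oob = not all(0.0 <= v <= 1.0 for v in (a2, c2, e2))
    return FalconerEstimates(a2=a2, c2=c2, e2=e2, out_of_bounds=oob)


# ---------------------------------------------------------------------------
# implied covariance
# ---------------------------------------------------------------------------

def _twin_block(sig_a: np.ndarray, sig_c: np.ndarray, sig_e: np.ndarray, zygosity: str) -> np.ndarray:
    r = 1.0 if zygosity == "MZ" else _DZ_A_WEIGHT
    within = sig_a + sig_c + sig_e
    cross = r * sig_a + sig_c
    return np.block([[within, cross], [cross, within]])


def simplex_component_cov(comp: SimplexComponent) -> np.ndarray:
    """Occasion-by-occasion covariance implied by one autoregressive chain."""
    t_n = comp.n_occasions
    var = np.empty(t_n)
    var[0] = comp.init_sd**2
    for t in range(1, t_n):
        var[t] = comp.betas[t - 1] ** 2 * var[t - 1] + comp.innov_sd[t - 1] ** 2
    cov = np.diag(var).astype(float)
    for i in range(t_n):
        prod = 1.0
        for j in range(i + 1, t_n):
            prod *= comp.betas[j - 1]
            cov[i, j] = cov[j, i] = var[i] * prod
    cov += np.diag(np.asarray(comp.spec_sd) ** 2)
    return cov


def _component_covs(model: str, params) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if model == "ace":
        if isinstance(params, ACEParams):
            a2, c2, e2 = params.a2, params.c2, params.e2
        else:
            a, c, e = params
            a2, c2, e2 = a * a, c * c, e * e
        return (np.array([[a2]]), np.array([[c2]]), np.array([[e2]]))
    if model == "cholesky":
        return (
            params.l_a @ params.l_a.T,
            params.l_c @ params.l_c.T,
            params.l_e @ params.l_e.T,
        )
    if model == "simplex":
        return (
            simplex_component_cov(params.a),
            simplex_component_cov(params.c),
            simplex_component_cov(params.e),
        )
    if model == "cpm":
        lam = np.asarray(params.loadings, dtype=float)
        outer = np.outer(lam, lam)
        return (
            params.latent_a**2 * outer + np.diag(params.resid_a2),
            params.latent_c**2 * outer + np.diag(params.resid_c2),
            params.latent_e**2 * outer + np.diag(params.resid_e2),
        )
    raise ValueError(f"unknown model {model!r}")


def implied_covariance(model: str, params, zygosity: str) -> np.ndarray:
    """Model-implied covariance of (twin1 variables, twin2 variables)."""
    if zygosity not in ZYGOSITY_GROUPS:
        raise ValueError(f"zygosity must be one of {ZYGOSITY_GROUPS}")
    sig_a, sig_c, sig_e = _component_covs(model, params)
    return _twin_block(sig_a, sig_c, sig_e, zygosity)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def neg2ll(
    sigmas: dict[str, np.ndarray],
    data: GroupCovariances,
    on_nonpd: str = "penalty",
) -> float:
    """Multigroup normal-theory -2 log-likelihood of the sample covariances.

    For each group with n observed pairs, sample covariance S and implied
    covariance Sigma over p variables the contribution is
    n * (p*log(2*pi) + log|Sigma| + tr(S Sigma^{-1})).  The value is
    minimized (over unstructured Sigma) at Sigma = S, the saturated model.

    A non-positive-definite implied matrix returns a large penalized value
    (``on_nonpd='penalty'``, keeps optimizers in the feasible region) or
    raises (``on_nonpd='raise'``).
    """
    from scipy.linalg import cho_solve

    total = 0.0
    for g, s in data.covs.items():
        sigma = sigmas[g]
        p = sigma.shape[0]
        n = data.ns[g]
        if not np.all(np.isfinite(sigma)):
            if on_nonpd == "raise":
                raise FitError(f"implied covariance for group {g} has non-finite entries")
            return _NONPD_PENALTY
        try:
            chol = np.linalg.cholesky(sigma)
            diag = np.diag(chol)
            if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
                raise np.linalg.LinAlgError
            logdet = 2.0 * float(np.sum(np.log(diag)))
            trace = float(np.trace(cho_solve((chol, True), s)))
        except np.linalg.LinAlgError:
            if on_nonpd == "raise":
                raise FitError(f"implied covariance for group {g} is not positive definite")
            eigmin = float(np.linalg.eigvalsh(np.nan_to_num(sigma)).min())
            return _NONPD_PENALTY * (1.0 + abs(eigmin))
        contrib = n * (p * np.log(2.0 * np.pi) + logdet + trace)
        if not np.isfinite(contrib):
            if on_nonpd == "raise":
                raise FitError(f"likelihood non-finite for group {g}")
            return _NONPD_PENALTY
        total += contrib
    return total


def saturated_neg2ll(data: GroupCovariances) -> float:
    return neg2ll({g: s for g, s in data.covs.items()}, data, on_nonpd="raise")


# ---------------------------------------------------------------------------
# generic optimizer
# ---------------------------------------------------------------------------

def _minimize_restarts(
    objective: Callable[[np.ndarray], float],
    starts: list[np.ndarray],
    bounds=None,
    scale: float = 1.0,
    gtol: float = 1e-7,
    agree_tol: float = 1e-4,
):
    """Quasi-Newton minimization from several starts; best solution wins.

    The objective is minimized on a per-observation scale (divided by
    ``scale``, typically the total sample size) so gradient tolerances are
    comparable across sample sizes with finite-difference gradients.
    Convergence requires the best run's scaled projected gradient norm
    below 5e-4 and is cross-checked by agreement of near-optimal restarts.
    """
    scaled = (lambda x: objective(x) / scale) if scale != 1.0 else objective
    results = []
    for x0 in starts:
        res = optimize.minimize(
            scaled, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 3000, "maxfun": 200000, "ftol": 1e-12, "gtol": gtol},
        )
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    best.fun = float(best.fun) * scale
    grad_norm = float(np.max(np.abs(best.jac)))
    near = [r for r in results if float(r.fun) * (1.0 if r is best else scale) < best.fun + agree_tol * scale]
    agree = max(
        (float(np.max(np.abs(r.x - best.x))) for r in near), default=0.0
    )
    # the scaled objective is O(10) per observation; finite-difference
    # gradients carry noise ~1e-3 at the optimum, so require better than 2e-3
    converged = grad_norm < 2e-3 and best.fun < _NONPD_PENALTY / 2
    if len(near) > 1 and agree > 0.05:
        logger.debug("restarts agree in fit but differ in params (max |dx|=%.3g)", agree)
    return best, converged, grad_norm, results


def _jittered_starts(
    rng: np.random.Generator, x0: np.ndarray, n_restarts: int, scale: float = 0.15,
    bounds=None,
) -> list[np.ndarray]:
    starts = [x0.copy()]
    for _ in range(max(0, n_restarts - 1)):
        x = x0 + scale * rng.standard_normal(x0.shape) * (1.0 + np.abs(x0))
        if bounds is not None:
            lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
            hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
            x = np.clip(x, lo, hi)
        starts.append(x)
    return starts


def _finish_fit(
    model: str,
    labels: list[str],
    best,
    converged: bool,
    grad_norm: float,
    data: GroupCovariances,
    objective,
    bounds,
) -> FitResult:
    if not converged:
        raise FitError(
            f"{model} fit did not converge (gradient norm {grad_norm:.3g}, "
            f"-2lnL {best.fun:.6g}); optimizer message: {best.message}"
        )
    return FitResult(
        model=model,
        estimates=dict(zip(labels, (float(v) for v in best.x))),
        neg2ll=float(best.fun),
        n_free=len(labels),
        converged=converged,
        grad_norm=grad_norm,
        data=data,
        _x=np.asarray(best.x, dtype=float),
        _labels=labels,
        _objective=objective,
        _bounds=bounds,
    )


def _falconer_from_data(data: GroupCovariances, var_index: int = 0) -> FalconerEstimates:
    p = data.n_vars
    rs = {}
    for g in ZYGOSITY_GROUPS:
        s = data.covs[g]
        i, j = var_index, var_index + p
        rs[g] = s[i, j] / np.sqrt(s[i, i] * s[j, j])
    return falconer_estimates(min(rs["MZ"], 1.0), np.clip(rs["DZ"], -1.0, 1.0))


# ---------------------------------------------------------------------------
# univariate ACE
# ---------------------------------------------------------------------------

def fit_univariate_ace(
    data: TwinPairTable | GroupCovariances,
    measure: str | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood univariate ACE decomposition.

    Parameters are the a, c, e path coefficients; ``derived`` carries the
    standardized variance proportions (which sum to one) and the Falconer
    estimates from the observed twin correlations for comparison.
    """
    if isinstance(data, TwinPairTable):
        measure = measure or f"{data.measure}1"
        data = GroupCovariances.from_table(data, [measure])
    if data.n_vars != 1:
        raise ValueError("fit_univariate_ace expects a single measure")

    def objective(x: np.ndarray) -> float:
        sigmas = {g: implied_covariance("ace", x, g) for g in ZYGOSITY_GROUPS}
        return neg2ll(sigmas, data)

    fal = _falconer_from_data(data)
    var1 = 0.5 * (data.covs["MZ"][0, 0] + data.covs["DZ"][0, 0])
    x0 = np.sqrt(var1 * np.clip([fal.a2, fal.c2, fal.e2], 0.05, 0.95))
    rng = np.random.default_rng(seed)
    bounds = [(0.0, None)] * 3
    starts = _jittered_starts(rng, x0, n_restarts, bounds=bounds)
    best, converged, grad_norm, _ = _minimize_restarts(
        objective, starts, bounds, scale=float(sum(data.ns.values()))
    )
    fit = _finish_fit("ace", ["a", "c", "e"], best, converged, grad_norm, data, objective, bounds)
    a, c, e = best.x
    total = a * a + c * c + e * e
    fit.derived["a2"] = a * a / total
    fit.derived["c2"] = c * c / total
    fit.derived["e2"] = e * e / total
    fit.derived["total_variance"] = total
    fit.derived["falconer"] = {"a2": fal.a2, "c2": fal.c2, "e2": fal.e2}
    return fit


# ---------------------------------------------------------------------------
# Cholesky (multivariate; bivariate wrapper adds correlations and shares)
# ---------------------------------------------------------------------------

def _tril_indices(p: int):
    return np.tril_indices(p)


def _cholesky_from_vector(x: np.ndarray, p: int) -> CholeskyParams:
    k = p * (p + 1) // 2
    idx = _tril_indices(p)
    mats = []
    for block in range(3):
        m = np.zeros((p, p))
        m[idx] = x[block * k : (block + 1) * k]
        mats.append(m)
    return CholeskyParams(*mats)


def fit_cholesky(
    data: TwinPairTable | GroupCovariances,
    measures: Sequence[str] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Saturated-structure ACE decomposition via triangular path matrices."""
    if isinstance(data, TwinPairTable):
        data = GroupCovariances.from_table(data, measures)
    p = data.n_vars
    k = p * (p + 1) // 2
    idx = _tril_indices(p)
    diag_pos = [r * (r + 1) // 2 + r for r in range(p)]  # position of (r, r) in tril order

    def objective(x: np.ndarray) -> float:
        params = _cholesky_from_vector(x, p)
        sigmas = {g: implied_covariance("cholesky", params, g) for g in ZYGOSITY_GROUPS}
        return neg2ll(sigmas, data)

    # start from per-variable Falconer shares applied to the phenotypic covariance
    s_ph = 0.25 * (
        data.covs["MZ"][:p, :p] + data.covs["MZ"][p:, p:]
        + data.covs["DZ"][:p, :p] + data.covs["DZ"][p:, p:]
    )
    x0 = np.zeros(3 * k)
    for block, share in enumerate((0.5, 0.25, 0.25)):
        target = share * s_ph + 1e-3 * np.eye(p)
        l0 = np.linalg.cholesky(target)
        x0[block * k : (block + 1) * k] = l0[idx]
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * (3 * k)
    for block in range(3):
        for dpos in diag_pos:
            bounds[block * k + dpos] = (0.0, None)
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(rng, x0, n_restarts, bounds=bounds)
    best, converged, grad_norm, _ = _minimize_restarts(
        objective, starts, bounds, scale=float(sum(data.ns.values()))
    )
    labels = []
    for comp in ("a", "c", "e"):
        labels += [f"l{comp}_{i + 1}{j + 1}" for i, j in zip(*idx)]
    fit = _finish_fit("cholesky", labels, best, converged, grad_norm, data, objective, bounds)
    params = _cholesky_from_vector(best.x, p)
    sig_a, sig_c, sig_e = _component_covs("cholesky", params)
    fit.derived["sigma_a"] = sig_a
    fit.derived["sigma_c"] = sig_c
    fit.derived["sigma_e"] = sig_e
    tot = np.diag(sig_a + sig_c + sig_e)
    fit.derived["a2"] = np.diag(sig_a) / tot
    fit.derived["c2"] = np.diag(sig_c) / tot
    fit.derived["e2"] = np.diag(sig_e) / tot
    return fit


def _safe_corr(sig: np.ndarray, i: int, j: int) -> float:
    denom = np.sqrt(sig[i, i] * sig[j, j])
    return float(sig[i, j] / denom) if denom > 1e-12 else np.nan


def fit_bivariate_cholesky(
    data: TwinPairTable | GroupCovariances,
    measures: Sequence[str] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Bivariate Cholesky decomposition with genetic/environmental
    correlations (rG, rC, rE) and the share of the phenotypic correlation
    attributable to each component (shares sum to one)."""
    if isinstance(data, TwinPairTable):
        if measures is None:
            measures = [f"{data.measure}1", f"{data.measure}2"]
        data = GroupCovariances.from_table(data, measures)
    if data.n_vars != 2:
        raise ValueError("fit_bivariate_cholesky expects exactly two measures")
    fit = fit_cholesky(data, n_restarts=n_restarts, seed=seed)
    fit.model = "bivariate_cholesky"
    sig_a = fit.derived["sigma_a"]
    sig_c = fit.derived["sigma_c"]
    sig_e = fit.derived["sigma_e"]
    sig_ph = sig_a + sig_c + sig_e
    fit.derived["rG"] = _safe_corr(sig_a, 0, 1)
    fit.derived["rC"] = _safe_corr(sig_c, 0, 1)
    fit.derived["rE"] = _safe_corr(sig_e, 0, 1)
    r_ph = _safe_corr(sig_ph, 0, 1)
    fit.derived["rPh"] = r_ph
    cov_ph = sig_ph[0, 1]
    if abs(cov_ph) < 1e-8 or abs(r_ph) < 0.02:
        fit.flags.append("phenotypic correlation near zero: covariance shares undefined")
        fit.derived["share_a"] = fit.derived["share_c"] = fit.derived["share_e"] = np.nan
    else:
        fit.derived["share_a"] = float(sig_a[0, 1] / cov_ph)
        fit.derived["share_c"] = float(sig_c[0, 1] / cov_ph)
        fit.derived["share_e"] = float(sig_e[0, 1] / cov_ph)
    return fit


# ---------------------------------------------------------------------------
# simplex
# ---------------------------------------------------------------------------

def _simplex_labels(t_n: int) -> list[str]:
    labels = []
    for comp in ("a", "c", "e"):
        labels.append(f"{comp}_init_sd")
        labels += [f"{comp}_beta_{t + 1}{t + 2}" for t in range(t_n - 1)]
        labels += [f"{comp}_innov_sd_{t + 2}" for t in range(t_n - 1)]
        labels += [f"{comp}_spec_sd_{t + 2}" for t in range(t_n - 2)]
    return labels


def _simplex_from_vector(x: np.ndarray, t_n: int) -> SimplexParams:
    per = 1 + (t_n - 1) + (t_n - 1) + (t_n - 2)
    comps = []
    for b in range(3):
        v = x[b * per : (b + 1) * per]
        init_sd = v[0]
        betas = tuple(v[1 : t_n])
        innov = tuple(v[t_n : 2 * t_n - 1])
        spec = (0.0,) + tuple(v[2 * t_n - 1 :]) + (0.0,)
        comps.append(
            SimplexComponent(init_sd=init_sd, betas=betas, innov_sd=innov, spec_sd=spec)
        )
    return SimplexParams(a=comps[0], c=comps[1], e=comps[2])


def _simplex_bounds(t_n: int) -> list[tuple[float | None, float | None]]:
    per_bounds: list[tuple[float | None, float | None]] = (
        [(0.0, None)]
        + [(None, None)] * (t_n - 1)
        + [(0.0, None)] * (t_n - 1)
        + [(0.0, None)] * (t_n - 2)
    )
    return per_bounds * 3


def fit_simplex(
    data: TwinPairTable | GroupCovariances,
    measures: Sequence[str] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    min_pairs: int = 200,
) -> FitResult:
    """Genetic simplex model: per-component initial variance, age-to-age
    transmission paths, innovations, and interior occasion-specific paths.

    Occasion-specific paths are fixed to zero at the first occasion (they are
    confounded with the initial variance) and at the last (confounded with
    the final innovation).  A, C and E all receive the full autoregressive
    structure; whether E transmits is left to the data.  Derived quantities
    include per-occasion standardized components and transmitted/innovation
    shares of heritability.
    """
    if isinstance(data, TwinPairTable):
        data = GroupCovariances.from_table(data, measures)
    t_n = data.n_vars
    if t_n < 3:
        raise ValueError("the simplex model needs at least 3 occasions")
    for g, n in data.ns.items():
        if n < min_pairs:
            raise ValueError(f"group {g} has {n} complete pairs; need >= {min_pairs}")

    def objective(x: np.ndarray) -> float:
        try:
            params = _simplex_from_vector(x, t_n)
        except ParameterError:
            return _NONPD_PENALTY
        sigmas = {g: implied_covariance("simplex", params, g) for g in ZYGOSITY_GROUPS}
        return neg2ll(sigmas, data)

    # Falconer-informed start: occasion-1 shares set the initial sds, lag-1
    # phenotypic regressions set the transmission paths
    fal = _falconer_from_data(data, 0)
    s_ph = 0.25 * (
        data.covs["MZ"][:t_n, :t_n] + data.covs["MZ"][t_n:, t_n:]
        + data.covs["DZ"][:t_n, :t_n] + data.covs["DZ"][t_n:, t_n:]
    )
    var1 = s_ph[0, 0]
    beta0 = [s_ph[t, t + 1] / s_ph[t, t] for t in range(t_n - 1)]
    shares = np.clip([fal.a2, fal.c2, fal.e2], 0.05, 0.9)
    per = 1 + 2 * (t_n - 1) + (t_n - 2)
    x0 = np.zeros(3 * per)
    for b, share in enumerate(shares):
        x0[b * per] = np.sqrt(share * var1)
        x0[b * per + 1 : b * per + t_n] = beta0
        x0[b * per + t_n : b * per + 2 * t_n - 1] = np.sqrt(0.3 * share * var1)
        x0[b * per + 2 * t_n - 1 : (b + 1) * per] = 0.05
    bounds = _simplex_bounds(t_n)
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(rng, x0, n_restarts, bounds=bounds)
    best, converged, grad_norm, _ = _minimize_restarts(
        objective, starts, bounds, scale=float(sum(data.ns.values()))
    )
    labels = _simplex_labels(t_n)
    fit = _finish_fit("simplex", labels, best, converged, grad_norm, data, objective, bounds)

    params = _simplex_from_vector(best.x, t_n)
    sig_a, sig_c, sig_e = _component_covs("simplex", params)
    tot = np.diag(sig_a + sig_c + sig_e)
    fit.derived["a2"] = np.diag(sig_a) / tot
    fit.derived["c2"] = np.diag(sig_c) / tot
    fit.derived["e2"] = np.diag(sig_e) / tot
    fit.derived["params"] = params
    # paths rescaled to unit phenotypic variance per occasion, then the
    # transmitted / innovation share arithmetic on heritabilities
    h2 = fit.derived["a2"]
    scale = np.sqrt(tot)
    betas_std = [
        params.a.betas[t] * scale[t] / scale[t + 1] for t in range(t_n - 1)
    ]
    trans, innov = [], []
    for t in range(1, t_n):
        innov_std = params.a.innov_sd[t - 1] / scale[t]
        spec_std = params.a.spec_sd[t] / scale[t]
        if h2[t] > 1e-6:
            trans.append(transmitted_share(h2[t - 1], betas_std[t - 1], h2[t]))
            innov.append(innovation_share(innov_std, spec_std, h2[t]))
        else:
            trans.append(np.nan)
            innov.append(np.nan)
            fit.flags.append(f"heritability at occasion {t + 1} near zero: shares undefined")
    fit.derived["transmitted_share"] = trans
    fit.derived["innovation_share"] = innov
    fit.derived["genetic_betas"] = list(params.a.betas)
    fit.derived["genetic_betas_std"] = betas_std
    return fit


def innovation_share(innov_path: float, specific_path: float, h2: float) -> float:
    """Fraction of heritability at an occasion due to genetic influences not
    operating at the previous occasion: (innovation^2 + specific^2) / h2."""
    if h2 <= 0:
        raise ValueError("heritability must be > 0 to form an innovation share")
    return (innov_path**2 + specific_path**2) / h2


def transmitted_share(h2_prev: float, beta: float, h2_curr: float) -> float:
    """Fraction of current genetic variance transmitted from the previous
    occasion: h2_prev * beta^2 / h2_curr."""
    if h2_curr <= 0:
        raise ValueError("current heritability must be > 0 to form a transmitted share")
    return h2_prev * beta**2 / h2_curr


# ---------------------------------------------------------------------------
# common pathway
# ---------------------------------------------------------------------------

def _cpm_labels(t_n: int) -> list[str]:
    labels = ["latent_a", "latent_c", "latent_e"]
    labels += [f"loading_{t + 2}" for t in range(t_n - 1)]
    for comp in ("a", "c", "e"):
        labels += [f"resid_{comp}_{t + 1}" for t in range(t_n)]
    return labels


def _cpm_sigmas(x: np.ndarray, t_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    la, lc, le = x[0], x[1], x[2]
    lam = np.concatenate([[1.0], x[3 : 3 + t_n - 1]])  # first loading fixed (scale)
    res = x[3 + t_n - 1 :].reshape(3, t_n)
    outer = np.outer(lam, lam)
    return (
        la**2 * outer + np.diag(res[0] ** 2),
        lc**2 * outer + np.diag(res[1] ** 2),
        le**2 * outer + np.diag(res[2] ** 2),
    )


def fit_common_pathway(
    data: TwinPairTable | GroupCovariances,
    measures: Sequence[str] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Common pathway model: one latent trait decomposed into A, C, E, with
    occasion loadings and residual ACE variances per occasion.

    The scale is identified by fixing the first loading to 1; reported
    derived quantities are the standardized squared latent paths
    (``latent_a2`` etc., summing to one — the headline share of stability
    explained by each source), the unit-variance-latent loadings, and the
    residual variances.  Residual variances enter as squared paths, which
    rules out negative (Heywood) residuals by construction.
    """
    if isinstance(data, TwinPairTable):
        data = GroupCovariances.from_table(data, measures)
    t_n = data.n_vars
    if t_n < 3:
        raise ValueError("the common pathway model needs at least 3 occasions")

    def objective(x: np.ndarray) -> float:
        sig_a, sig_c, sig_e = _cpm_sigmas(x, t_n)
        sigmas = {g: _twin_block(sig_a, sig_c, sig_e, g) for g in ZYGOSITY_GROUPS}
        return neg2ll(sigmas, data)

    fal = _falconer_from_data(data, 0)
    s_ph = 0.25 * (
        data.covs["MZ"][:t_n, :t_n] + data.covs["MZ"][t_n:, t_n:]
        + data.covs["DZ"][:t_n, :t_n] + data.covs["DZ"][t_n:, t_n:]
    )
    # common variance start: mean off-diagonal covariance
    off = s_ph[np.triu_indices(t_n, 1)]
    common0 = float(np.clip(np.mean(off), 0.05, None))
    shares = np.clip([fal.a2, fal.c2, fal.e2], 0.05, 0.9)
    shares = shares / shares.sum()
    x0 = np.concatenate([
        np.sqrt(shares * common0),
        np.ones(t_n - 1),
        np.sqrt(np.clip(np.concatenate([
            0.4 * (np.diag(s_ph) - common0),
            0.2 * (np.diag(s_ph) - common0),
            0.4 * (np.diag(s_ph) - common0),
        ]), 0.01, None)),
    ])
    bounds = (
        [(0.0, None)] * 3 + [(None, None)] * (t_n - 1) + [(0.0, None)] * (3 * t_n)
    )
    rng = np.random.default_rng(seed)
    starts = _jittered_starts(rng, x0, n_restarts, bounds=bounds)
    best, converged, grad_norm, _ = _minimize_restarts(
        objective, starts, bounds, scale=float(sum(data.ns.values()))
    )
    labels = _cpm_labels(t_n)
    fit = _finish_fit("cpm", labels, best, converged, grad_norm, data, objective, bounds)

    la, lc, le = best.x[:3]
    latent_var = la**2 + lc**2 + le**2
    lam = np.concatenate([[1.0], best.x[3 : 3 + t_n - 1]]) * np.sqrt(latent_var)
    res = best.x[3 + t_n - 1 :].reshape(3, t_n) ** 2
    fit.derived["latent_a2"] = la**2 / latent_var
    fit.derived["latent_c2"] = lc**2 / latent_var
    fit.derived["latent_e2"] = le**2 / latent_var
    fit.derived["loadings"] = lam  # scaled to a unit-variance latent factor
    fit.derived["resid_a2"] = res[0]
    fit.derived["resid_c2"] = res[1]
    fit.derived["resid_e2"] = res[2]
    sig_a, sig_c, sig_e = _cpm_sigmas(best.x, t_n)
    tot = np.diag(sig_a + sig_c + sig_e)
    fit.derived["a2"] = np.diag(sig_a) / tot
    fit.derived["c2"] = np.diag(sig_c) / tot
    fit.derived["e2"] = np.diag(sig_e) / tot
    return fit


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def profile_interval(
    objective: Callable[[np.ndarray], float],
    x_best: np.ndarray,
    index: int,
    crit: float,
    bounds=None,
    search_halfwidth: float | None = None,
) -> tuple[float, float, list[str]]:
    """Profile-likelihood interval for one coordinate of a -2lnL objective.

    Bounds are where the profiled -2lnL (other coordinates re-minimized)
    rises ``crit`` above its minimum.  Returns (lower, upper, flags); a
    bound that cannot be bracketed inside the search range, or that sits on
    a box constraint, is returned at that limit with a flag.
    """
    x_best = np.asarray(x_best, dtype=float)
    f_best = objective(x_best)
    target = f_best + crit
    theta0 = x_best[index]
    others = [i for i in range(len(x_best)) if i != index]
    if search_halfwidth is None:
        search_halfwidth = 10.0 * abs(theta0) + 2.0
    lo_box, hi_box = -np.inf, np.inf
    if bounds is not None:
        b = bounds[index]
        lo_box = -np.inf if b[0] is None else b[0]
        hi_box = np.inf if b[1] is None else b[1]

    def profiled(theta: float) -> float:
        if not others:
            x = x_best.copy()
            x[index] = theta
            return objective(x)
        x0 = x_best[others]
        sub_bounds = [bounds[i] for i in others] if bounds is not None else None

        def sub(xo: np.ndarray) -> float:
            x = x_best.copy()
            x[index] = theta
            x[others] = xo
            return objective(x)

        res = optimize.minimize(sub, x0, method="L-BFGS-B", bounds=sub_bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        return float(res.fun)

    flags: list[str] = []
    out = []
    for direction in (-1.0, 1.0):
        limit = lo_box if direction < 0 else hi_box
        far = theta0 + direction * search_halfwidth
        far = max(far, limit) if direction < 0 else min(far, limit)
        if abs(far - theta0) < 1e-12:
            out.append(theta0)
            flags.append(f"{'lower' if direction < 0 else 'upper'} bound at box constraint")
            continue
        # walk outward until the profile crosses the target
        bracket = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            theta = theta0 + frac * (far - theta0)
            if profiled(theta) >= target:
                bracket = (theta0 + (frac - 0.25) * (far - theta0), theta)
                break
        if bracket is None:
            if np.isfinite(limit) and abs(far - limit) < 1e-12:
                out.append(limit)
                flags.append(
                    f"{'lower' if direction < 0 else 'upper'} bound open to box constraint"
                )
            else:
                out.append(far)
                flags.append(
                    f"{'lower' if direction < 0 else 'upper'} bound not found in search range"
                )
            continue
        root = optimize.brentq(lambda t: profiled(t) - target, *sorted(bracket), xtol=1e-6)
        out.append(float(root))
    lower, upper = min(out), max(out)
    return lower, upper, flags


def likelihood_ci(fit: FitResult, param: str, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a fitted parameter."""
    if not fit.converged or fit._objective is None:
        raise FitError("confidence intervals require a converged fit")
    if param not in fit._labels:
        raise KeyError(f"unknown parameter {param!r}; have {fit._labels}")
    crit = stats.chi2.ppf(level, df=1)
    index = fit._labels.index(param)
    lower, upper, flags = profile_interval(
        fit._objective, fit._x, index, crit, bounds=fit._bounds
    )
    fit.ci[param] = (lower, upper)
    fit.flags.extend(f"{param}: {f}" for f in flags)
    return lower, upper


def compare_models(
    fit_full: FitResult, fit_nested: FitResult, tol: float = 1e-3
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller model fitted to the
    same data.  Returns (LRT statistic, df, p)."""
    lrt = fit_nested.neg2ll - fit_full.neg2ll
    df = fit_full.n_free - fit_nested.n_free
    if df < 0:
        raise ValueError("the first argument must be the fuller model")
    scale = max(1.0, abs(fit_full.neg2ll))
    if lrt < -tol * scale:
        raise FitError(
            f"nested model fits better than the full model (LRT {lrt:.6g}); "
            "this signals an optimization failure"
        )
    lrt = max(lrt, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(lrt, df))
    return float(lrt), df, p
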