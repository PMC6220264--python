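"""DNA-based analyses: GRM construction, relatedness pruning, REML
SNP-heritability, GRM principal components, polygenic scoring and
incremental prediction.

The genetic relationship matrix (GRM) follows the GCTA convention:
dosages are centred at twice the sample allele frequency and scaled by the
Hardy-Weinberg standard deviation, so G = Z Z' / m for the standardized
dosage matrix Z.  SNP heritability is estimated among (pruned) unrelated
individuals by restricted maximum likelihood with average-information
updates and an EM fallback, using a one-off eigendecomposition of the GRM
so each iteration is cheap.  Polygenic scores are allele-weighted dosage
sums; their predictive value is reported as the incremental R^2 over a
baseline regression (typically ancestry principal components, optionally
earlier-age achievement).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from edutwin.synthetic import GenotypePanel, ParameterError

logger = logging.getLogger("edutwin")


class ConvergenceError(RuntimeError):
    """REML estimation failed to converge."""


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Symmetric genetic relationship matrix with sample ids and SNP count."""

    matrix: np.ndarray
    sample_ids: list[str]
    n_snps: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids must match the GRM dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM entries must be finite")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def subset(self, ids: list[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return GRM(self.matrix[np.ix_(idx, idx)], list(ids), self.n_snps)

    def write_gcta(self, prefix: str | Path) -> None:
        """GCTA text convention: gzipped triplets (i, j, SNP count, value),
        1-based lower triangle, plus a companion id file."""
        prefix = Path(prefix)
        with gzip.open(prefix.with_suffix(".grm.gz"), "wt") as fh:
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{self.n_snps}\t{self.matrix[i, j]:.8g}\n")
        with open(prefix.with_suffix(".grm.id"), "w") as fh:
            for s in self.sample_ids:
                fh.write(f"{s}\t{s}\n")

    @classmethod
    def read_gcta(cls, prefix: str | Path) -> "GRM":
        prefix = Path(prefix)
        ids = [line.split()[1] for line in prefix.with_suffix(".grm.id").read_text().splitlines() if line.strip()]
        n = len(ids)
        mat = np.zeros((n, n))
        n_snps = 0
        with gzip.open(prefix.with_suffix(".grm.gz"), "rt") as fh:
            for line in fh:
                i, j, m, v = line.split()
                i, j = int(i) - 1, int(j) - 1
                mat[i, j] = mat[j, i] = float(v)
                n_snps = int(m)
        return cls(mat, ids, n_snps)


def compute_grm(panel: GenotypePanel, monomorphic: str = "drop") -> GRM:
    """GCTA-style GRM: G_ij = (1/m) sum_k (x_ik - 2p_k)(x_jk - 2p_k) / (2 p_k (1-p_k))
    with p_k the sample allele frequency.  Missing dosages are mean-imputed
    per SNP.  Monomorphic SNPs are dropped with a logged count
    (``monomorphic='drop'``) or raise (``'strict'``)."""
    if panel.n_snps < 2:
        raise ValueError("need at least 2 SNPs to build a GRM")
    x = panel.dosages.astype(float)
    p_hat = np.nanmean(x, axis=0) / 2.0
    mono = (p_hat <= 0.0) | (p_hat >= 1.0)
    if mono.any():
        ids = [panel.snp_ids[k] for k in np.flatnonzero(mono)]
        if monomorphic == "strict":
            raise ValueError(f"monomorphic SNPs present: {ids}")
        logger.info("dropping %d monomorphic SNPs from the GRM", len(ids))
    keep = ~mono
    x = x[:, keep]
    p = p_hat[keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic SNPs remain")
    centred = x - 2.0 * p
    centred = np.where(np.isnan(centred), 0.0, centred)  # mean imputation
    z = centred / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    g = (z @ z.T) / m
    return GRM(matrix=g, sample_ids=list(panel.sample_ids), n_snps=m)


def prune_related(grm: GRM, cutoff: float = 0.025) -> list[str]:
    """Ids of a subset with no pairwise relatedness above ``cutoff``.

    Greedy rule: while any off-diagonal exceeds the cutoff, remove the
    individual involved in the most offending pairs (ties broken by id
    order), so the result is deterministic.
    """
    adj = (np.abs(np.triu(grm.matrix, 1)) > cutoff) | (np.abs(np.tril(grm.matrix, -1)) > cutoff)
    np.fill_diagonal(adj, False)
    alive = np.ones(grm.n, dtype=bool)
    deg = adj.sum(axis=1).astype(int)
    while True:
        deg_alive = np.where(alive, deg, -1)
        worst = int(np.argmax(deg_alive))
        if deg_alive[worst] <= 0:
            break
        alive[worst] = False
        nb = np.flatnonzero(adj[worst] & alive)
        deg[nb] -= 1
        deg[worst] = 0
    return [s for s, a in zip(grm.sample_ids, alive) if a]


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class RemlResult:
    sigma2_g: float
    sigma2_e: float
    h2_snp: float
    se_h2: float
    se_sigma2_g: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool
    loglik_trajectory: list[float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_snp <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")


def _reml_pieces(d: np.ndarray, x: np.ndarray, y: np.ndarray, sg: float, se: float):
    """Log-likelihood, scores, AI matrix and Py in the GRM eigenbasis."""
    v = sg * d + se
    vinv = 1.0 / v
    xtvx = x.T @ (vinv[:, None] * x)
    xtvy = x.T @ (vinv * y)
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ xtvy
    py = vinv * (y - x @ beta)
    # P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv; products with diag(d) stay cheap
    wx = vinv[:, None] * x

    def quad(a: np.ndarray, b: np.ndarray) -> float:
        return float(a @ b)

    def p_dot(vec: np.ndarray) -> np.ndarray:
        return vinv * vec - wx @ (xtvx_inv @ (wx.T @ vec))

    ll = -0.5 * (
        float(np.sum(np.log(v)))
        + float(np.linalg.slogdet(xtvx)[1])
        + quad(y - x @ beta, py)
    )
    tr_p = float(np.sum(vinv)) - float(np.trace(xtvx_inv @ (wx.T @ wx)))
    wxd = wx * d[:, None]
    tr_pg = float(np.sum(vinv * d)) - float(np.trace(xtvx_inv @ (wx.T @ wxd)))
    gpy = d * py
    pgpy = p_dot(gpy)
    ppy = p_dot(py)
    score_g = -0.5 * (tr_pg - quad(gpy, py))
    score_e = -0.5 * (tr_p - quad(py, py))
    ai = 0.5 * np.array(
        [
            [quad(gpy, pgpy), quad(gpy, ppy)],
            [quad(gpy, ppy), quad(py, ppy)],
        ]
    )
    return ll, np.array([score_g, score_e]), ai, py, tr_pg, tr_p


def reml_fit(
    grm: GRM,
    pheno,
    covariates: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    method: str = "ai",
) -> RemlResult:
    """SNP heritability by restricted maximum likelihood on a GRM.

    Model: y = X beta + g + e with g ~ N(0, G sigma2_g), e ~ N(0, I sigma2_e).
    ``method='ai'`` takes average-information steps with an EM fallback
    whenever a step would leave the parameter space or decrease the
    restricted likelihood; ``method='em'`` uses EM throughout (monotone in
    the likelihood but slower).  Standard errors come from the inverse AI
    matrix; the SE of h2 = sigma2_g / (sigma2_g + sigma2_e) by the delta
    method.
    """
    y = np.asarray(pheno, dtype=float)
    if y.ndim != 1 or len(y) != grm.n:
        raise ValueError("phenotype must be a vector aligned with the GRM")
    if np.isnan(y).any():
        raise ValueError("REML requires complete phenotypes; drop missing first")
    n = grm.n
    if covariates is None:
        x = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        x = np.column_stack([np.ones(n), covariates])
    p = x.shape[1]
    if n <= p + 2:
        raise ValueError("need n > number of covariates + 2")
    d, u = np.linalg.eigh(grm.matrix)
    if np.ptp(d) < 1e-8:
        raise ValueError(
            "GRM has (near-)constant eigenvalues: genetic and residual "
            "variance are not separately identifiable"
        )
    d = np.clip(d, 0.0, None)
    ystar = u.T @ y
    xstar = u.T @ x

    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    sg = se = 0.5 * vary
    ll_prev = -np.inf
    traj: list[float] = []
    ai = np.eye(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, ai, py, tr_pg, tr_p = _reml_pieces(d, xstar, ystar, sg, se)
        traj.append(ll)
        if abs(ll - ll_prev) < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        gpy = d * py
        em_g = sg + sg**2 * (float(py @ gpy) - tr_pg) / n
        em_e = se + se**2 * (float(py @ py) - tr_p) / n
        use_em = method == "em"
        if not use_em:
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                use_em = True
            else:
                cand_g, cand_e = sg + step[0], se + step[1]
                if not (np.isfinite(cand_g) and np.isfinite(cand_e)):
                    use_em = True
                elif cand_g < floor or cand_e < floor:
                    use_em = True
                else:
                    cand_ll = _reml_pieces(d, xstar, ystar, cand_g, cand_e)[0]
                    if cand_ll < ll - 1e-10:
                        use_em = True
                    else:
                        sg, se = cand_g, cand_e
        if use_em:
            sg = max(em_g, floor)
            se = max(em_e, floor)
    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations; "
            f"log-likelihood trajectory: {traj[-5:]}"
        )
    boundary = bool(sg <= 2 * floor or se <= 2 * floor)
    if boundary:
        logger.warning("REML variance component at its boundary (h2 ~ 0 or 1)")
    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_inv = np.full((2, 2), np.nan)
    total = sg + se
    grad = np.array([se, -sg]) / total**2
    var_h2 = float(grad @ ai_inv @ grad)
    h2 = min(max(sg / total, 0.0), 1.0)
    return RemlResult(
        sigma2_g=float(sg),
        sigma2_e=float(se),
        h2_snp=float(h2),
        se_h2=float(np.sqrt(var_h2)) if var_h2 > 0 else float("nan"),
        se_sigma2_g=float(np.sqrt(ai_inv[0, 0])) if ai_inv[0, 0] > 0 else float("nan"),
        loglik=float(traj[-1]),
        n_iter=it,
        converged=converged,
        boundary=boundary,
        loglik_trajectory=traj,
    )


# ---------------------------------------------------------------------------
# principal components, scoring, incremental prediction
# ---------------------------------------------------------------------------

def grm_pca(grm: GRM, k: int) -> np.ndarray:
    """Top-k principal components of the GRM, scaled by root eigenvalues."""
    if not (0 < k < grm.n):
        raise ValueError(f"k must lie in (0, n); got k={k}, n={grm.n}")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    top_vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(top_vals)


@dataclass
class WeightTable:
    """Per-SNP scoring weights: SNP id, effect allele, per-allele weight."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = {"snp_id", "effect_allele", "weight"}
        if not cols.issubset(self.table.columns):
            raise ValueError(f"weight table needs columns {sorted(cols)}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("snp_ids in the weight table must be unique")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("weights must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["snp_id", "effect_allele", "weight"])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table[["snp_id", "effect_allele", "weight"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def polygenic_score(panel: GenotypePanel, weights: WeightTable) -> np.ndarray:
    """Z-standardized weighted dosage sum over the SNPs shared with the
    weight table.  A weight whose effect allele is the complement of the
    panel's counts the opposite dosage (2 - x); unmatched SNPs are dropped
    with a logged count."""
    wt = weights.table.set_index("snp_id")
    matched, cols, w = [], [], []
    for k, sid in enumerate(panel.snp_ids):
        if sid in wt.index:
            matched.append(sid)
            cols.append(k)
            w.append(float(wt.loc[sid, "weight"]))
    dropped = len(wt) - len(matched)
    if dropped:
        logger.info("polygenic score: %d weight-table SNPs not in the panel", dropped)
    if not matched:
        raise ValueError("no weight-table SNPs matched the panel")
    x = panel.dosages[:, cols].astype(float)
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x)
    flip = np.array(
        [wt.loc[sid, "effect_allele"] != panel.effect_alleles[k]
         for sid, k in zip(matched, cols)]
    )
    if flip.any():
        x[:, flip] = 2.0 - x[:, flip]
    raw = x @ np.asarray(w)
    sd = raw.std()
    if sd == 0:
        return raw - raw.mean()
    return (raw - raw.mean()) / sd


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("outcome is constant")
    return 1.0 - float((resid**2).sum()) / ss_tot


def incremental_r2(y, baseline, addition) -> float:
    """Increase in regression R^2 from adding one predictor to a baseline.

    Invariant to affine transformations of the addition; non-negative up to
    numerical tolerance.  Raises for a rank-deficient baseline design.
    """
    y = np.asarray(y, dtype=float)
    base = np.asarray(baseline, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    add = np.asarray(addition, dtype=float).reshape(len(y), -1)
    if base.shape[0] != len(y) or add.shape[0] != len(y):
        raise ValueError("rows of y, baseline and addition must align")
    mask = np.isfinite(y) & np.isfinite(base).all(axis=1) & np.isfinite(add).all(axis=1)
    y, base, add = y[mask], base[mask], add[mask]
    design_base = np.column_stack([np.ones(len(y)), base])
    if np.linalg.matrix_rank(design_base) < design_base.shape[1]:
        raise ValueError("baseline design matrix is rank deficient")
    r2_base = _ols_r2(y, design_base)
    r2_full = _ols_r2(y, np.column_stack([design_base, add]))
    delta = r2_full - r2_base
    return float(max(delta, 0.0)) if delta > -1e-10 else float(delta)


def age_specific_gps_r2(y_t, gps, prior_achievement, pcs=None) -> float:
    """Incremental R^2 of the polygenic score beyond ancestry PCs and all
    earlier-age achievement: the age-specific part of the score's
    prediction."""
    prior = np.asarray(prior_achievement, dtype=float)
    if prior.ndim == 1:
        prior = prior[:, None]
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        baseline = np.column_stack([pcs, prior])
    else:
        baseline = prior
    return incremental_r2(y_t, baseline, gps)
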