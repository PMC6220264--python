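"""Synthetic twin cohorts, genotype panels, and polygenic-score cohorts.

Twin phenotypes are simulated directly from latent additive-genetic (A),
shared-environment (C), and non-shared-environment (E) scores rather than
from genotypes: the A score is identical within MZ pairs and correlated 0.5
within DZ pairs (via a common + segregating split), C is identical within
all pairs, and E is independent. This reproduces the expected twin
covariance structure exactly and is the generating model that the fitting
routines in :mod:`edutwin.twin_models` are meant to recover.

All simulators take an integer seed, use one `numpy` generator per call,
and record generating parameters plus seed in the output metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("edutwin")

_PARAM_TOL = 1e-9

# default assessment ages: UK Key Stage 1/2/3 and GCSE
DEFAULT_AGES = (7.0, 11.0, 14.0, 16.0)


class ParameterError(ValueError):
    """A generating-parameter invariant was violated."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACEParams:
    """Standardized single-occasion variance decomposition.

    a2, c2, e2 are the proportions of phenotypic variance attributed to
    additive-genetic, shared-environment, and non-shared-environment
    influences; they must be non-negative and sum to one.
    """

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        total = self.a2 + self.c2 + self.e2
        if abs(total - 1.0) > _PARAM_TOL:
            raise ParameterError(
                f"a2 + c2 + e2 must equal 1 (got {total!r}); "
                "components are proportions of a unit phenotypic variance"
            )


@dataclass(frozen=True)
class SimplexComponent:
    """First-order autoregressive latent series for one variance component.

    The latent score at occasion 1 has standard deviation ``init_sd``; at
    each later occasion it equals ``beta[t]`` times the previous latent
    score plus a fresh innovation with standard deviation ``innov_sd[t]``.
    ``spec_sd`` holds occasion-specific standard deviations: influences that
    load on a single occasion and are not transmitted.  For identification
    the occasion-specific path is fixed to zero at the first occasion
    (confounded with the initial variance) and at the last occasion
    (confounded with the final innovation).
    """

    init_sd: float
    betas: tuple[float, ...]
    innov_sd: tuple[float, ...]
    spec_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        object.__setattr__(self, "innov_sd", tuple(float(s) for s in self.innov_sd))
        object.__setattr__(self, "spec_sd", tuple(float(s) for s in self.spec_sd))
        t = len(self.betas) + 1
        if t < 2:
            raise ParameterError("a simplex component needs at least 2 occasions")
        if len(self.innov_sd) != t - 1:
            raise ParameterError(
                f"innov_sd must have {t - 1} entries (occasions 2..{t}), "
                f"got {len(self.innov_sd)}"
            )
        if len(self.spec_sd) != t:
            raise ParameterError(
                f"spec_sd must have one entry per occasion ({t}), got {len(self.spec_sd)}"
            )
        for name in ("init_sd",):
            if self.init_sd < 0 or not np.isfinite(self.init_sd):
                raise ParameterError(f"init_sd must be finite and >= 0, got {self.init_sd}")
        if any(s < 0 for s in self.innov_sd):
            raise ParameterError("innovation standard deviations must be >= 0")
        if any(s < 0 for s in self.spec_sd):
            raise ParameterError("occasion-specific standard deviations must be >= 0")
        if self.spec_sd[0] != 0.0 or self.spec_sd[-1] != 0.0:
            raise ParameterError(
                "occasion-specific paths must be fixed to 0 at the first and "
                "last occasion (identification)"
            )

    @property
    def n_occasions(self) -> int:
        return len(self.betas) + 1


@dataclass(frozen=True)
class SimplexParams:
    """Genetic simplex model parameters: one AR(1) chain per A, C, E."""

    a: SimplexComponent
    c: SimplexComponent
    e: SimplexComponent

    def __post_init__(self) -> None:
        t = self.a.n_occasions
        if self.c.n_occasions != t or self.e.n_occasions != t:
            raise ParameterError("A, C, E components must share the number of occasions")
        from edutwin.twin_models import simplex_component_cov  # local, avoids cycle at import

        total = np.zeros(t)
        for comp in (self.a, self.c, self.e):
            total += np.diag(simplex_component_cov(comp))
        if np.any(total <= 0):
            raise ParameterError("implied per-occasion total variance must be > 0")

    @property
    def n_occasions(self) -> int:
        return self.a.n_occasions

    def components(self) -> dict[str, SimplexComponent]:
        return {"A": self.a, "C": self.c, "E": self.e}


@dataclass(frozen=True)
class CommonPathwayParams:
    """Common pathway model: a single latent trait, itself ACE-decomposed.

    ``latent_a``, ``latent_c``, ``latent_e`` are paths from the latent A, C,
    E influences to the common factor, whose variance is fixed to 1 (squares
    sum to one).  ``loadings[t]`` carries the factor to each occasion, and
    each occasion keeps residual ACE variances of its own.
    """

    latent_a: float
    latent_c: float
    latent_e: float
    loadings: tuple[float, ...]
    resid_a2: tuple[float, ...]
    resid_c2: tuple[float, ...]
    resid_e2: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", tuple(float(v) for v in self.loadings))
        for name in ("resid_a2", "resid_c2", "resid_e2"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        total = self.latent_a**2 + self.latent_c**2 + self.latent_e**2
        if abs(total - 1.0) > _PARAM_TOL:
            raise ParameterError(
                f"latent path squares must sum to 1 (latent variance fixed), got {total!r}"
            )
        t = len(self.loadings)
        if t < 2:
            raise ParameterError("common pathway model needs at least 2 occasions")
        for name in ("resid_a2", "resid_c2", "resid_e2"):
            vals = getattr(self, name)
            if len(vals) != t:
                raise ParameterError(f"{name} must have one entry per occasion ({t})")
            if any(v < 0 for v in vals):
                raise ParameterError(f"{name} entries must be >= 0")

    @property
    def n_occasions(self) -> int:
        return len(self.loadings)


# ---------------------------------------------------------------------------
# twin pair table
# ---------------------------------------------------------------------------

@dataclass
class TwinPairTable:
    """Wide table of twin pairs: one row per family.

    Columns: ``family_id``, ``zygosity`` (MZ / DZ / DZO), ``sex1``/``sex2``,
    ``age{t}`` shared per occasion, phenotypes ``{measure}{t}_1`` and
    ``{measure}{t}_2`` for twin 1 and twin 2, and optionally ``g_1``/``g_2``.
    """

    data: pd.DataFrame
    n_occasions: int
    measure: str = "ach"
    meta: dict = field(default_factory=dict)

    def pheno_columns(self, twin: int) -> list[str]:
        return [f"{self.measure}{t + 1}_{twin}" for t in range(self.n_occasions)]

    def group(self, zygosity: str) -> pd.DataFrame:
        """Rows for one analysis group; 'DZ' pools same- and opposite-sex pairs."""
        if zygosity == "DZ":
            return self.data[self.data["zygosity"].isin(["DZ", "DZO"])]
        return self.data[self.data["zygosity"] == zygosity]

    def pair_matrix(self, zygosity: str, measures: Sequence[str] | None = None) -> np.ndarray:
        """Complete-case (n_pairs, 2*T) array: twin-1 block then twin-2 block."""
        g = self.group(zygosity)
        if measures is None:
            cols = self.pheno_columns(1) + self.pheno_columns(2)
        else:
            cols = [f"{m}_1" for m in measures] + [f"{m}_2" for m in measures]
        arr = g[cols].to_numpy(dtype=float)
        return arr[~np.isnan(arr).any(axis=1)]

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        if sidecar:
            side = path.with_suffix(path.suffix + ".json")
            side.write_text(json.dumps(_jsonable(self.meta), indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, measure: str = "ach") -> "TwinPairTable":
        path = Path(path)
        data = pd.read_csv(path)
        occ = sorted(
            int(c[len(measure):-2])
            for c in data.columns
            if c.startswith(measure) and c.endswith("_1") and c[len(measure):-2].isdigit()
        )
        if not occ:
            raise ValueError(f"no '{measure}<occasion>_1' phenotype columns in {path}")
        meta: dict = {}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            meta = json.loads(side.read_text())
        return cls(data=data, n_occasions=max(occ), measure=measure, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# latent-draw machinery
# ---------------------------------------------------------------------------

def _paired_normal(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """(n, 2) standard-normal draws with within-pair correlation rho.

    rho=1 duplicates one draw (MZ genetic / shared environment), rho=0.5
    splits into a common and a segregating part (DZ genetic), rho=0 is
    independent (non-shared environment).
    """
    if rho >= 1.0:
        z = rng.standard_normal((n, 1))
        return np.repeat(z, 2, axis=1)
    if rho <= 0.0:
        return rng.standard_normal((n, 2))
    common = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, 2))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own


def _component_series(
    rng: np.random.Generator, n: int, comp: SimplexComponent, rho: float
) -> np.ndarray:
    """(n, 2, T) latent contribution of one ACE component to the phenotype."""
    t_n = comp.n_occasions
    latent = np.empty((n, 2, t_n))
    latent[:, :, 0] = comp.init_sd * _paired_normal(rng, n, rho)
    for t in range(1, t_n):
        innov = comp.innov_sd[t - 1] * _paired_normal(rng, n, rho)
        latent[:, :, t] = comp.betas[t - 1] * latent[:, :, t - 1] + innov
    out = latent.copy()
    for t in range(t_n):
        if comp.spec_sd[t] > 0:
            out[:, :, t] += comp.spec_sd[t] * _paired_normal(rng, n, rho)
    return out


def _assign_sexes(rng: np.random.Generator, n_mz: int, n_dz: int):
    mz_sex = np.where(rng.random(n_mz) < 0.5, "F", "M")
    dz_sex1 = np.where(rng.random(n_dz) < 0.5, "F", "M")
    dz_sex2 = np.where(rng.random(n_dz) < 0.5, "F", "M")
    return mz_sex, dz_sex1, dz_sex2


def _assemble_table(
    pheno_mz: np.ndarray,
    pheno_dz: np.ndarray,
    rng: np.random.Generator,
    ages: Sequence[float],
    measure: str,
    meta: dict,
    g_mz: np.ndarray | None = None,
    g_dz: np.ndarray | None = None,
    sex_effect: float = 0.0,
    pheno_mean: float = 0.0,
    pheno_sd: float = 1.0,
    missing_rate: float = 0.0,
) -> TwinPairTable:
    n_mz, _, t_n = pheno_mz.shape
    n_dz = pheno_dz.shape[0]
    mz_sex, dz_sex1, dz_sex2 = _assign_sexes(rng, n_mz, n_dz)
    zyg = np.concatenate(
        [
            np.repeat("MZ", n_mz),
            np.where(dz_sex1 == dz_sex2, "DZ", "DZO"),
        ]
    )
    sex1 = np.concatenate([mz_sex, dz_sex1])
    sex2 = np.concatenate([mz_sex, dz_sex2])
    pheno = np.concatenate([pheno_mz, pheno_dz], axis=0)
    if sex_effect != 0.0:
        shift1 = np.where(sex1 == "F", sex_effect / 2.0, -sex_effect / 2.0)
        shift2 = np.where(sex2 == "F", sex_effect / 2.0, -sex_effect / 2.0)
        pheno[:, 0, :] += shift1[:, None]
        pheno[:, 1, :] += shift2[:, None]
    pheno = pheno_mean + pheno_sd * pheno
    if missing_rate > 0.0:
        mask = rng.random(pheno.shape) < missing_rate
        pheno = np.where(mask, np.nan, pheno)

    n = n_mz + n_dz
    cols: dict[str, np.ndarray] = {
        "family_id": np.array([f"fam{i:06d}" for i in range(n)]),
        "zygosity": zyg,
        "sex1": sex1,
        "sex2": sex2,
    }
    for t in range(t_n):
        cols[f"age{t + 1}"] = np.full(n, float(ages[t]))
    for t in range(t_n):
        cols[f"{measure}{t + 1}_1"] = pheno[:, 0, t]
        cols[f"{measure}{t + 1}_2"] = pheno[:, 1, t]
    if g_mz is not None and g_dz is not None:
        g = np.concatenate([g_mz, g_dz], axis=0)
        cols["g_1"] = g[:, 0]
        cols["g_2"] = g[:, 1]
    return TwinPairTable(
        data=pd.DataFrame(cols), n_occasions=t_n, measure=measure, meta=meta
    )


# ---------------------------------------------------------------------------
# twin simulators
# ---------------------------------------------------------------------------

def simulate_ace(
    n_mz: int,
    n_dz: int,
    params: ACEParams,
    seed: int,
    *,
    pheno_mean: float = 0.0,
    pheno_sd: float = 1.0,
    sex_effect: float = 0.0,
    missing_rate: float = 0.0,
    measure: str = "ach",
) -> TwinPairTable:
    """Single-occasion twin pairs with unit variance and twin covariances
    a2 + c2 (MZ) and a2/2 + c2 (DZ) in expectation."""
    if n_mz < 1 or n_dz < 1:
        raise ParameterError("need at least one pair in each zygosity group")
    if not isinstance(params, ACEParams):
        params = ACEParams(*params)
    rng = np.random.default_rng(seed)
    paths = {"A": np.sqrt(params.a2), "C": np.sqrt(params.c2), "E": np.sqrt(params.e2)}
    rhos = {"A": None, "C": 1.0, "E": 0.0}

    def draw(n: int, rho_a: float) -> np.ndarray:
        p = np.zeros((n, 2, 1))
        for name, path in paths.items():
            rho = rho_a if name == "A" else rhos[name]
            p[:, :, 0] += path * _paired_normal(rng, n, rho)
        return p

    pheno_mz = draw(n_mz, 1.0)
    pheno_dz = draw(n_dz, 0.5)
    meta = {"model": "ace", "params": params, "seed": seed, "n_mz": n_mz, "n_dz": n_dz}
    return _assemble_table(
        pheno_mz, pheno_dz, rng, ages=DEFAULT_AGES[:1], measure=measure, meta=meta,
        sex_effect=sex_effect, pheno_mean=pheno_mean, pheno_sd=pheno_sd,
        missing_rate=missing_rate,
    )


def simulate_simplex(
    n_mz: int,
    n_dz: int,
    params: SimplexParams,
    seed: int,
    *,
    ages: Sequence[float] | None = None,
    pheno_mean: float = 0.0,
    pheno_sd: float = 1.0,
    sex_effect: float = 0.0,
    missing_rate: float = 0.0,
    g_loading: float = 0.0,
    measure: str = "ach",
) -> TwinPairTable:
    """Multi-occasion twin pairs following the genetic simplex model.

    If ``g_loading`` > 0 a general-cognitive-ability composite ``g`` is also
    emitted per twin, loading on the occasion-1 genetic latent score (the
    stable genetic factor) with the given coefficient plus independent noise,
    so downstream analyses can regress achievement on g.
    """
    if n_mz < 1 or n_dz < 1:
        raise ParameterError("need at least one pair in each zygosity group")
    t_n = params.n_occasions
    if ages is None:
        ages = DEFAULT_AGES[:t_n] if t_n <= len(DEFAULT_AGES) else tuple(range(7, 7 + t_n))
    rng = np.random.default_rng(seed)

    def draw(n: int, rho_a: float):
        a = _component_series(rng, n, params.a, rho_a)
        c = _component_series(rng, n, params.c, 1.0)
        e = _component_series(rng, n, params.e, 0.0)
        g = None
        if g_loading != 0.0:
            init = params.a.init_sd
            a1 = a[:, :, 0] / init if init > 0 else np.zeros(a[:, :, 0].shape)
            noise = np.sqrt(max(0.0, 1.0 - g_loading**2)) * rng.standard_normal((n, 2))
            g = g_loading * a1 + noise
        return a + c + e, g

    pheno_mz, g_mz = draw(n_mz, 1.0)
    pheno_dz, g_dz = draw(n_dz, 0.5)
    meta = {
        "model": "simplex", "params": params, "seed": seed,
        "n_mz": n_mz, "n_dz": n_dz, "g_loading": g_loading,
    }
    return _assemble_table(
        pheno_mz, pheno_dz, rng, ages=ages, measure=measure, meta=meta,
        g_mz=g_mz, g_dz=g_dz, sex_effect=sex_effect,
        pheno_mean=pheno_mean, pheno_sd=pheno_sd, missing_rate=missing_rate,
    )


def simulate_common_pathway(
    n_mz: int,
    n_dz: int,
    params: CommonPathwayParams,
    seed: int,
    *,
    ages: Sequence[float] | None = None,
    pheno_mean: float = 0.0,
    pheno_sd: float = 1.0,
    sex_effect: float = 0.0,
    missing_rate: float = 0.0,
    measure: str = "ach",
) -> TwinPairTable:
    """Multi-occasion twin pairs from the common pathway model."""
    if n_mz < 1 or n_dz < 1:
        raise ParameterError("need at least one pair in each zygosity group")
    t_n = params.n_occasions
    if ages is None:
        ages = DEFAULT_AGES[:t_n] if t_n <= len(DEFAULT_AGES) else tuple(range(7, 7 + t_n))
    rng = np.random.default_rng(seed)
    lam = np.asarray(params.loadings)

    def draw(n: int, rho_a: float) -> np.ndarray:
        factor = (
            params.latent_a * _paired_normal(rng, n, rho_a)
            + params.latent_c * _paired_normal(rng, n, 1.0)
            + params.latent_e * _paired_normal(rng, n, 0.0)
        )
        pheno = factor[:, :, None] * lam[None, None, :]
        for t in range(t_n):
            pheno[:, :, t] += np.sqrt(params.resid_a2[t]) * _paired_normal(rng, n, rho_a)
            pheno[:, :, t] += np.sqrt(params.resid_c2[t]) * _paired_normal(rng, n, 1.0)
            pheno[:, :, t] += np.sqrt(params.resid_e2[t]) * _paired_normal(rng, n, 0.0)
        return pheno

    pheno_mz = draw(n_mz, 1.0)
    pheno_dz = draw(n_dz, 0.5)
    meta = {"model": "cpm", "params": params, "seed": seed, "n_mz": n_mz, "n_dz": n_dz}
    return _assemble_table(
        pheno_mz, pheno_dz, rng, ages=ages, measure=measure, meta=meta,
        sex_effect=sex_effect, pheno_mean=pheno_mean, pheno_sd=pheno_sd,
        missing_rate=missing_rate,
    )


# ---------------------------------------------------------------------------
# genotypes and polygenic-score cohorts
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Biallelic dosage panel: individuals x SNPs, dosages in {0, 1, 2}."""

    dosages: np.ndarray
    allele_freqs: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    effect_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ParameterError("id lists must match dosage matrix dimensions")
        if len(self.allele_freqs) != m:
            raise ParameterError("allele_freqs must have one entry per SNP")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ParameterError("allele frequencies must lie strictly inside (0, 1)")
        finite = self.dosages[np.isfinite(self.dosages)]
        if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ParameterError("dosages must be 0, 1, or 2 (NaN for missing)")
        if self.effect_alleles is None:
            self.effect_alleles = ["A1"] * m

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def to_dosage_text(self, path: str | Path) -> None:
        """Tab-separated text: family id, sample id, then one column per SNP."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("FID\tIID\t" + "\t".join(self.snp_ids) + "\n")
            for i, sid in enumerate(self.sample_ids):
                row = self.dosages[i]
                vals = "\t".join("NA" if np.isnan(v) else str(int(v)) for v in row)
                fh.write(f"{sid}\t{sid}\t{vals}\n")

    @classmethod
    def from_dosage_text(cls, path: str | Path) -> "GenotypePanel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        snp_ids = list(df.columns[2:])
        dos = df[snp_ids].to_numpy(dtype=float)
        freqs = np.nanmean(dos, axis=0) / 2.0
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
        return cls(
            dosages=dos, allele_freqs=freqs, snp_ids=snp_ids,
            sample_ids=[str(s) for s in df.iloc[:, 1]],
        )


def simulate_genotypes(
    n: int, m: int, maf_low: float, maf_high: float, seed: int
) -> GenotypePanel:
    """Independent biallelic SNPs in Hardy-Weinberg equilibrium.

    Effect-allele frequencies are drawn uniformly on [maf_low, maf_high] and
    dosages binomial(2, p) per SNP; no linkage disequilibrium is simulated.
    """
    if n < 1 or m < 1:
        raise ParameterError("panel dimensions must be positive")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ParameterError(
            f"need 0 < maf_low <= maf_high <= 0.5, got ({maf_low}, {maf_high})"
        )
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=m) if maf_low < maf_high else np.full(m, maf_low)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypePanel(
        dosages=dosages,
        allele_freqs=p,
        snp_ids=[f"snp{k}" for k in range(m)],
        sample_ids=[f"id{i:05d}" for i in range(n)],
    )


@dataclass
class SnpPhenotype:
    """Phenotype with additive polygenic signal; generating pieces retained."""

    values: np.ndarray
    h2_snp: float
    causal_ids: list[str]
    effects: np.ndarray          # per-causal-SNP effect on the standardized dosage
    genetic_values: np.ndarray   # the heritable component, sample variance h2_snp

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def simulate_snp_phenotype(
    panel: GenotypePanel, h2_snp: float, n_causal: int, seed: int
) -> SnpPhenotype:
    """Additive polygenic phenotype: standardized causal dosages times normal
    effects, rescaled so the genetic part has sample variance exactly h2_snp,
    plus independent normal noise of variance 1 - h2_snp."""
    if not (0.0 <= h2_snp < 1.0):
        raise ParameterError(f"h2_snp must be in [0, 1), got {h2_snp}")
    if n_causal < 1 or n_causal > panel.n_snps:
        raise ParameterError("n_causal must be between 1 and the number of SNPs")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(panel.n_snps, size=n_causal, replace=False))
    x = panel.dosages[:, idx]
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (np.where(np.isnan(x), mu, x) - mu) / sd
    effects = rng.standard_normal(n_causal)
    g_raw = z @ effects
    if h2_snp > 0:
        g_sd = g_raw.std()
        if g_sd == 0:
            raise ParameterError("causal genotypes carry no variance")
        g = g_raw / g_sd * np.sqrt(h2_snp)
    else:
        g = np.zeros(panel.n_individuals)
    noise = rng.standard_normal(panel.n_individuals) * np.sqrt(1.0 - h2_snp)
    return SnpPhenotype(
        values=g + noise,
        h2_snp=h2_snp,
        causal_ids=[panel.snp_ids[k] for k in idx],
        effects=effects,
        genetic_values=g,
    )


def simulate_gps_cohort(
    n: int,
    r2_schedule: Sequence[float],
    seed: int,
    *,
    stable_share: float = 0.92,
) -> tuple[np.ndarray, np.ndarray]:
    """Cohort with one fixed polygenic score and one achievement variable per
    schedule entry.

    Achievement at occasion t is
    ``sqrt(r2_t) * s + sqrt(rho * (1 - r2_t)) * u + sqrt((1-rho)(1-r2_t)) * e_t``
    with ``s`` the score, ``u`` a persistent non-score trait and ``e_t``
    occasion noise, so the population R^2 of the score on achievement at
    occasion t equals ``r2_schedule[t]`` exactly while the score's prediction
    is carried almost entirely by the stable part: incremental prediction
    beyond earlier occasions is small.  ``stable_share`` (rho) is the fraction
    of non-score variance that is persistent.

    Returns ``(score, achievement)`` with achievement of shape (n, len(schedule)).
    """
    r2 = np.asarray(list(r2_schedule), dtype=float)
    if r2.ndim != 1 or len(r2) < 1:
        raise ParameterError("r2_schedule must be a non-empty sequence")
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ParameterError("each schedule entry must lie in [0, 1)")
    if not (0.0 <= stable_share < 1.0):
        raise ParameterError("stable_share must lie in [0, 1)")
    if n < 2:
        raise ParameterError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    u = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(r2)))
    ach = (
        np.sqrt(r2)[None, :] * s[:, None]
        + np.sqrt(stable_share * (1.0 - r2))[None, :] * u[:, None]
        + np.sqrt((1.0 - stable_share) * (1.0 - r2))[None, :] * eps
    )
    return s, ach


# ---------------------------------------------------------------------------
# canonical generating regimes for school achievement
# ---------------------------------------------------------------------------

def achievement_simplex_params() -> SimplexParams:
    """Four-occasion generating regime for core school achievement.

    Occasion heritabilities 0.73, 0.70, 0.63, 0.58 with genetic transmission
    paths 0.86, 0.84, 0.86 (innovation variances chosen for consistency);
    shared environment ~0.20 per occasion and highly stable; non-shared
    environment purely occasion-specific.  Phenotypic variance is 1 at every
    occasion.
    """
    h2 = (0.73, 0.70, 0.63, 0.58)
    a_betas = (0.86, 0.84, 0.86)
    a_innov = tuple(
        np.sqrt(h2[t + 1] - a_betas[t] ** 2 * h2[t]) for t in range(3)
    )
    c2, c_beta = 0.20, 0.9
    c_innov = (np.sqrt(c2 - c_beta**2 * c2),) * 3
    e2 = tuple(1.0 - h - c2 for h in h2)
    return SimplexParams(
        a=SimplexComponent(np.sqrt(h2[0]), a_betas, a_innov, (0.0,) * 4),
        c=SimplexComponent(np.sqrt(c2), (c_beta,) * 3, c_innov, (0.0,) * 4),
        e=SimplexComponent(np.sqrt(e2[0]), (0.0,) * 3,
                           tuple(np.sqrt(v) for v in e2[1:]), (0.0,) * 4),
    )


def achievement_cpm_params() -> CommonPathwayParams:
    """Common pathway generating regime: the latent achievement-stability
    factor is 70% genetic, 24% shared-environmental, 6% non-shared; equal
    loadings of 0.85 and residual ACE variances filling each occasion's
    variance to 1."""
    lam = 0.85
    resid_total = 1.0 - lam**2
    return CommonPathwayParams(
        latent_a=np.sqrt(0.70),
        latent_c=np.sqrt(0.24),
        latent_e=np.sqrt(0.06),
        loadings=(lam,) * 4,
        resid_a2=(0.45 * resid_total,) * 4,
        resid_c2=(0.15 * resid_total,) * 4,
        resid_e2=(0.40 * resid_total,) * 4,
    )
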