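"""Synthetic honey tables: a calibrated realistic generator and a fixture.

Two generators live here.

``generate_realistic`` draws tables whose per-type marginals follow the
published descriptive statistics of Serbian honey (truncated normals with
the per-type mean/SD/min/max embedded below) and whose pooled dependence
structure follows the published correlation matrix via a Gaussian copula.
Because the pooled Pearson correlation of a type *mixture* has a
between-type component (type means differ), the latent copula correlation
is calibrated per pair so that the pooled output correlation approaches the
embedded target as n grows (see docs/methods.md).

``build_fixture`` constructs a deterministic 609-record table embodying a
known deviation inventory — 25 conductivity reclassifications (9 in / 16
out of honeydew), 9 low-conductivity, 53 suspect-grade low-sugar-sum, 5
high-sucrose (4 of which also low-sum), 12 high-5-HMF, 1 high-acidity, 4
low-diastase, 2 high-moisture, 3 blend-profile records — together with the
manifest of every expected downstream count.  The deviation categories that
define the 22 adulterated / 64 suspect split are mutually disjoint across
samples.  The same seed yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, truncnorm

from .data_model import LOQ, PARAMETERS, HoneySample, HoneyType, Region, SampleTable

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "FixtureManifest",
    "SURVEY_MARGINALS",
    "TARGET_CORRELATION",
    "TYPE_COUNTS",
    "REGION_COUNTS",
    "YEAR_COUNTS",
    "sample_truncated_normal",
    "truncated_normal_mean",
    "generate_realistic",
    "build_fixture",
    "nearest_positive_definite",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Truncated-normal marginal for one honey type x parameter cell.

    ``mean``/``sd`` are the location/scale of the parent normal; the
    distribution is truncated to [vmin, vmax].  ``sd == 0`` degenerates to
    the constant ``mean``.
    """

    honey_type: HoneyType
    parameter: str
    mean: float
    sd: float
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.vmin > self.vmax:
            raise ValueError(f"min {self.vmin} > max {self.vmax}")
        if not (self.vmin <= self.mean <= self.vmax):
            raise ValueError(
                f"mean {self.mean} outside [{self.vmin}, {self.vmax}] "
                f"for {self.honey_type.value}/{self.parameter}"
            )

    @property
    def _ab(self) -> tuple[float, float]:
        return (self.vmin - self.mean) / self.sd, (self.vmax - self.mean) / self.sd


def sample_truncated_normal(
    spec: MarginalSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw of ``n`` values from a truncated-normal marginal.

    Deterministic for a fixed seed; every value lies in [vmin, vmax]; a
    zero-SD spec yields the constant mean.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    return _ppf(spec, u)


def _ppf(spec: MarginalSpec, u: np.ndarray) -> np.ndarray:
    if spec.sd == 0:
        return np.full_like(np.asarray(u, dtype=float), spec.mean)
    a, b = spec._ab
    x = truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.sd)
    # guard against ppf landing an ulp outside the interval
    return np.clip(x, spec.vmin, spec.vmax)


def truncated_normal_mean(spec: MarginalSpec) -> float:
    """Analytic mean of the truncated distribution (oracle for tests)."""
    if spec.sd == 0:
        return spec.mean
    a, b = spec._ab
    return float(truncnorm.mean(a, b, loc=spec.mean, scale=spec.sd))


def _truncnorm_moments(spec: MarginalSpec) -> tuple[float, float]:
    if spec.sd == 0:
        return spec.mean, 0.0
    a, b = spec._ab
    m, v = truncnorm.stats(a, b, loc=spec.mean, scale=spec.sd, moments="mv")
    return float(m), float(np.sqrt(v))


# --------------------------------------------------------------------------
# Embedded study conditions: per-type marginals, sample counts, and the
# pooled correlation targets of the 609-sample Serbian honey survey.
# Sucrose/5-HMF marginals with a censored ("<0.50") printed minimum are
# generated from a floor of 0; values below the LOQ are censored on output.
# The monofloral sucrose row is entirely below the LOQ in the source table,
# so its marginal here is a synthetic stand-in confined to [0, 0.49].
# --------------------------------------------------------------------------

_A, _H, _L, _M, _P, _S = (
    HoneyType.ACACIA,
    HoneyType.HONEYDEW,
    HoneyType.LINDEN,
    HoneyType.MONOFLORAL,
    HoneyType.POLYFLORAL,
    HoneyType.SUNFLOWER,
)

_MARGINAL_ROWS: list[tuple[HoneyType, str, float, float, float, float]] = [
    (_A, "glu", 27.40, 3.87, 16.02, 40.00),
    (_H, "glu", 29.33, 5.17, 16.19, 38.85),
    (_L, "glu", 29.20, 3.91, 17.18, 35.74),
    (_M, "glu", 31.67, 7.53, 13.44, 36.10),
    (_P, "glu", 31.39, 4.60, 15.72, 44.80),
    (_S, "glu", 34.57, 3.98, 24.10, 40.42),
    (_A, "fru", 40.83, 5.83, 13.60, 53.10),
    (_H, "fru", 37.84, 6.32, 22.65, 49.72),
    (_L, "fru", 35.39, 5.82, 21.80, 44.80),
    (_M, "fru", 35.41, 5.17, 26.66, 42.09),
    (_P, "fru", 38.68, 5.20, 18.94, 53.64),
    (_S, "fru", 37.83, 3.26, 30.61, 45.34),
    (_A, "suc", 1.19, 1.79, 0.00, 16.58),
    (_H, "suc", 0.46, 0.61, 0.00, 2.70),
    (_L, "suc", 0.64, 1.08, 0.00, 5.60),
    (_M, "suc", 0.30, 0.15, 0.00, 0.49),
    (_P, "suc", 0.63, 1.41, 0.00, 16.34),
    (_S, "suc", 0.34, 0.23, 0.00, 1.03),
    (_A, "hmf", 5.71, 8.20, 0.00, 54.80),
    (_H, "hmf", 6.34, 12.66, 0.00, 63.41),
    (_L, "hmf", 5.41, 6.37, 0.00, 21.80),
    (_M, "hmf", 11.84, 19.74, 0.00, 59.20),
    (_P, "hmf", 8.31, 12.36, 0.00, 93.50),
    (_S, "hmf", 4.85, 8.34, 0.00, 40.80),
    (_A, "mc", 16.19, 1.07, 13.50, 19.80),
    (_H, "mc", 16.36, 2.10, 13.40, 26.00),
    (_L, "mc", 16.61, 1.10, 14.20, 19.80),
    (_M, "mc", 17.20, 2.04, 15.40, 22.00),
    (_P, "mc", 16.45, 1.13, 13.00, 19.90),
    (_S, "mc", 17.51, 1.37, 14.90, 19.90),
    (_A, "acid", 11.44, 5.05, 2.30, 31.43),
    (_H, "acid", 30.17, 8.07, 6.00, 46.00),
    (_L, "acid", 16.33, 6.90, 5.50, 34.72),
    (_M, "acid", 15.08, 8.16, 7.50, 30.00),
    (_P, "acid", 21.04, 9.33, 4.00, 61.26),
    (_S, "acid", 23.00, 7.22, 8.61, 37.50),
    (_A, "dia", 13.06, 7.64, 3.90, 114.00),
    (_H, "dia", 12.80, 3.14, 8.40, 19.80),
    (_L, "dia", 12.90, 2.36, 8.40, 19.07),
    (_M, "dia", 11.90, 2.87, 9.70, 18.18),
    (_P, "dia", 12.90, 3.43, 0.50, 32.54),
    (_S, "dia", 13.45, 2.50, 9.60, 17.42),
    (_A, "ins", 0.01, 0.01, 0.00, 0.07),
    (_H, "ins", 0.01, 0.00, 0.00, 0.01),
    (_L, "ins", 0.01, 0.00, 0.00, 0.01),
    (_M, "ins", 0.01, 0.00, 0.00, 0.02),
    (_P, "ins", 0.01, 0.01, 0.00, 0.10),
    (_S, "ins", 0.01, 0.01, 0.00, 0.04),
    (_A, "econd", 0.20, 0.10, 0.03, 0.69),
    (_H, "econd", 1.14, 0.27, 0.82, 1.80),
    (_L, "econd", 0.48, 0.19, 0.04, 0.78),
    (_M, "econd", 0.25, 0.16, 0.12, 0.52),
    (_P, "econd", 0.40, 0.15, 0.03, 0.79),
    (_S, "econd", 0.39, 0.09, 0.15, 0.54),
]

SURVEY_MARGINALS: dict[tuple[HoneyType, str], MarginalSpec] = {
    (t, p): MarginalSpec(t, p, m, s, lo, hi) for t, p, m, s, lo, hi in _MARGINAL_ROWS
}

#: Final per-type sample counts of the survey.
TYPE_COUNTS: dict[HoneyType, int] = {
    _A: 213,
    _H: 29,
    _L: 34,
    _M: 8,
    _P: 302,
    _S: 23,
}

REGION_COUNTS: dict[Region, int] = {
    Region.WESTERN: 114,
    Region.BELGRADE: 205,
    Region.NORTHERN: 149,
    Region.CENTRAL: 29,
    Region.EASTERN: 92,
    Region.SOUTHERN: 20,
}

YEAR_COUNTS: dict[int, int] = {2018: 209, 2019: 80, 2020: 78, 2021: 108, 2022: 113, 2023: 21}

#: Pooled Pearson correlation targets (order = PARAMETERS).  The strong
#: r = 0.570 entry sits on the acidity-conductivity pair, consistent with
#: honeydew honey being high in both organic acids and mineral content.
_T = np.eye(9)
_IDX = {p: i for i, p in enumerate(PARAMETERS)}


def _set(p1: str, p2: str, r: float) -> None:
    i, j = _IDX[p1], _IDX[p2]
    _T[i, j] = _T[j, i] = r


_set("glu", "fru", 0.237)
_set("glu", "suc", -0.129)
_set("glu", "hmf", 0.096)
_set("glu", "mc", 0.046)
_set("glu", "acid", 0.189)
_set("glu", "dia", 0.004)
_set("glu", "ins", -0.007)
_set("glu", "econd", 0.144)
_set("fru", "suc", -0.057)
_set("fru", "hmf", -0.087)
_set("fru", "mc", -0.081)
_set("fru", "acid", -0.076)
_set("fru", "dia", -0.047)
_set("fru", "ins", 0.074)
_set("fru", "econd", -0.105)
_set("suc", "hmf", 0.001)
_set("suc", "mc", -0.044)
_set("suc", "acid", -0.150)
_set("suc", "dia", -0.023)
_set("suc", "ins", -0.066)
_set("suc", "econd", -0.144)
_set("hmf", "mc", -0.085)
_set("hmf", "acid", 0.107)
_set("hmf", "dia", -0.129)
_set("hmf", "ins", -0.032)
_set("hmf", "econd", 0.011)
_set("mc", "acid", 0.147)
_set("mc", "dia", 0.027)
_set("mc", "ins", 0.017)
_set("mc", "econd", 0.061)
_set("acid", "dia", 0.034)
_set("acid", "ins", 0.028)
_set("acid", "econd", 0.570)
_set("dia", "ins", -0.034)
_set("dia", "econd", 0.022)
_set("ins", "econd", -0.023)

TARGET_CORRELATION: np.ndarray = _T
del _T


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix (unit diagonal)."""
    c = np.asarray(corr, dtype=float)
    c = (c + c.T) / 2.0
    for _ in range(10):
        w, v = np.linalg.eigh(c)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the realistic generator."""

    counts: Mapping[HoneyType, int] = field(default_factory=lambda: dict(TYPE_COUNTS))
    marginals: Mapping[tuple[HoneyType, str], MarginalSpec] = field(
        default_factory=lambda: dict(SURVEY_MARGINALS)
    )
    target_correlation: np.ndarray = field(default_factory=lambda: TARGET_CORRELATION.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.counts.values()):
            raise ValueError("per-type counts must be positive")
        c = np.asarray(self.target_correlation, dtype=float)
        if c.shape != (9, 9) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("target correlation must be symmetric 9x9 with unit diagonal")
        repaired = nearest_positive_definite(c)
        if np.linalg.eigvalsh(repaired).min() < 0:
            raise ValueError("target correlation not repairable to positive definite")


def _latent_linearity(spec: MarginalSpec, nodes: int = 96) -> float:
    """corr(X, Z) for X = F^{-1}(Phi(Z)), by Gauss-Hermite quadrature."""
    m, s = _truncnorm_moments(spec)
    if s == 0:
        return 0.0
    z, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / np.sqrt(2 * np.pi)
    x = _ppf(spec, norm.cdf(z))
    exz = float(np.sum(w * x * z))
    return exz / s


def _calibrate_latent(
    counts: Mapping[HoneyType, int],
    marginals: Mapping[tuple[HoneyType, str], MarginalSpec],
    target: np.ndarray,
) -> np.ndarray:
    """Latent copula correlation such that the pooled mixture Pearson of the
    generated table matches ``target`` (first-order moment matching).

    For parameters j, k with per-type truncated means m_tj, SDs s_tj, latent
    linearity c_tj and type weights w_t, the pooled covariance decomposes as
    between-means + rho * sum_t w_t c_tj c_tk s_tj s_tk; the equation is
    solved for rho per pair and clipped to [-0.985, 0.985].
    """
    types = list(counts)
    n_total = sum(counts.values())
    w = np.array([counts[t] / n_total for t in types])
    m = np.zeros((len(types), 9))
    s = np.zeros((len(types), 9))
    c = np.zeros((len(types), 9))
    for ti, t in enumerate(types):
        for pj, p in enumerate(PARAMETERS):
            spec = marginals[(t, p)]
            m[ti, pj], s[ti, pj] = _truncnorm_moments(spec)
            c[ti, pj] = _latent_linearity(spec)
    pooled_mean = w @ m
    dev = m - pooled_mean
    pooled_var = w @ (s**2 + dev**2)
    latent = np.eye(9)
    for j in range(9):
        for k in range(j + 1, 9):
            between = float(np.sum(w * dev[:, j] * dev[:, k]))
            within_scale = float(np.sum(w * c[:, j] * c[:, k] * s[:, j] * s[:, k]))
            want_cov = target[j, k] * np.sqrt(pooled_var[j] * pooled_var[k])
            if within_scale <= 0:
                rho = 0.0
            else:
                rho = (want_cov - between) / within_scale
            latent[j, k] = latent[k, j] = float(np.clip(rho, -0.985, 0.985))
    return nearest_positive_definite(latent)


def generate_realistic(config: GeneratorConfig | None = None) -> SampleTable:
    """Draw a calibrated synthetic honey table.

    Per-type counts match the config; each parameter follows its truncated
    marginal; honeydew conductivity (>= 0.82 mS/cm) is disjoint from all
    other types (<= 0.79), so the table is reclassification-stable.  Region
    and harvest year are drawn from the survey margins.  Sucrose/5-HMF
    values below the LOQ are stored censored.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    latent = _calibrate_latent(config.counts, config.marginals, np.asarray(config.target_correlation))
    chol = np.linalg.cholesky(latent)

    region_labels = list(REGION_COUNTS)
    region_p = np.array([REGION_COUNTS[r] for r in region_labels], dtype=float)
    region_p /= region_p.sum()
    year_labels = list(YEAR_COUNTS)
    year_p = np.array([YEAR_COUNTS[y] for y in year_labels], dtype=float)
    year_p /= year_p.sum()

    samples: list[HoneySample] = []
    idx = 1
    for t, n in config.counts.items():
        z = rng.standard_normal((n, 9)) @ chol.T
        u = norm.cdf(z)
        cols = {
            p: _ppf(config.marginals[(t, p)], u[:, j]) for j, p in enumerate(PARAMETERS)
        }
        regions = rng.choice(len(region_labels), size=n, p=region_p)
        years = rng.choice(len(year_labels), size=n, p=year_p)
        for i in range(n):
            values = {p: float(cols[p][i]) for p in PARAMETERS}
            suc_cens = values["suc"] < LOQ
            hmf_cens = values["hmf"] < LOQ
            if suc_cens:
                values["suc"] = LOQ
            if hmf_cens:
                values["hmf"] = LOQ
            samples.append(
                HoneySample(
                    sample_id=f"SYN-{idx:04d}",
                    declared_type=t,
                    region=region_labels[int(regions[i])],
                    year=year_labels[int(years[i])],
                    suc_censored=suc_cens,
                    hmf_censored=hmf_cens,
                    **values,
                )
            )
            idx += 1
    return SampleTable(samples, provenance=f"realistic(seed={config.seed})")


# --------------------------------------------------------------------------
# Deterministic fixture
# --------------------------------------------------------------------------

#: Declared-type counts chosen so the conductivity rule (9 in / 16 out of
#: honeydew) lands exactly on the survey's final counts above.
DECLARED_COUNTS: dict[HoneyType, int] = {
    _A: 218,
    _H: 36,
    _L: 36,
    _M: 8,
    _P: 288,
    _S: 23,
}


@dataclass(frozen=True)
class FixtureManifest:
    """Every count the downstream pipeline must recover from the fixture."""

    total: int
    declared_type_counts: dict[str, int]
    final_type_counts: dict[str, int]
    region_counts: dict[str, int]
    year_counts: dict[int, int]
    reclassified_in: int
    reclassified_out: int
    reclassified_total: int
    final_honeydew: int
    low_econd: int
    low_sugar_sum_suspect: int
    low_sugar_sum_total: int
    high_sucrose: int
    high_hmf: int
    high_acidity: int
    low_diastase: int
    high_moisture: int
    high_insoluble: int
    adulterated: int
    suspect: int
    compliant: int
    blend_flags: int
    nonconforming_pct: float

    def __post_init__(self) -> None:
        if sum(self.declared_type_counts.values()) != self.total:
            raise ValueError("declared type counts must sum to total")
        if self.adulterated + self.suspect + self.compliant != self.total:
            raise ValueError("grade counts must sum to total")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _compliant_spec(
    t: HoneyType, p: str, lo: float | None = None, hi: float | None = None
) -> MarginalSpec:
    """Table marginal clipped into the region where no rule fires."""
    base = SURVEY_MARGINALS[(t, p)]
    vmin = base.vmin if lo is None else max(base.vmin, lo)
    vmax = base.vmax if hi is None else min(base.vmax, hi)
    mean = min(max(base.mean, vmin), vmax)
    return MarginalSpec(t, p, mean, base.sd, vmin, vmax)


_CLIP: dict[str, tuple[float | None, float | None]] = {
    "suc": (None, 4.5),
    "hmf": (None, 35.0),
    "mc": (None, 19.9),
    "acid": (None, 46.0),
    "dia": (8.05, None),
    "ins": (None, 0.095),
}


def _baseline_values(rng: np.random.Generator, t: HoneyType) -> dict[str, float]:
    """One fully compliant record for declared type ``t``.

    Sugars are drawn so glucose+fructose clears the type's floor by at least
    one unit; conductivity stays inside the type's class band (>= 0.82 for
    honeydew, [0.105, 0.79] otherwise).
    """
    floor = 45.0 if t is _H else 60.0
    values: dict[str, float] = {}
    fru_base = SURVEY_MARGINALS[(t, "fru")]
    glu_spec = _compliant_spec(t, "glu", lo=floor + 2.0 - fru_base.vmax)
    values["glu"] = float(sample_truncated_normal(glu_spec, 1, rng)[0])
    fru_spec = _compliant_spec(t, "fru", lo=floor + 1.0 - values["glu"])
    values["fru"] = float(sample_truncated_normal(fru_spec, 1, rng)[0])
    for p, (lo, hi) in _CLIP.items():
        values[p] = float(sample_truncated_normal(_compliant_spec(t, p, lo, hi), 1, rng)[0])
    if t is _H:
        econd_spec = _compliant_spec(t, "econd")  # already [0.82, 1.80]
    else:
        econd_spec = _compliant_spec(t, "econd", lo=0.105)
    values["econd"] = float(sample_truncated_normal(econd_spec, 1, rng)[0])
    return values


def _apply_overrides(
    rng: np.random.Generator, values: dict[str, float], overrides: Mapping
) -> None:
    for key, spec in overrides.items():
        if key == "sugar_sum":
            lo, hi = spec
            total = float(rng.uniform(lo, hi))
            glu = float(rng.uniform(21.0, 26.0))
            values["glu"] = glu
            values["fru"] = total - glu
        elif isinstance(spec, tuple):
            values[key] = float(rng.uniform(*spec))
        else:
            values[key] = float(spec)


# Special-record profiles: (declared type, overrides, pinned region, pinned year).
# ``None`` region/year is filled from the remaining survey-margin quota.
def _special_profiles() -> list[tuple[HoneyType, dict, Region | None, int | None]]:
    W, B, N, C, E, S = (
        Region.WESTERN,
        Region.BELGRADE,
        Region.NORTHERN,
        Region.CENTRAL,
        Region.EASTERN,
        Region.SOUTHERN,
    )
    rows: list[tuple[HoneyType, dict, Region | None, int | None]] = []

    # conductivity in-moves: flower types measured above the honeydew cut
    rows += [(_A, {"econd": (0.85, 1.40)}, None, None)] * 5
    rows += [(_L, {"econd": (0.85, 1.30)}, None, None)] * 2
    rows += [(_P, {"econd": (0.85, 1.30)}, None, None)] * 2
    # conductivity out-moves: declared honeydew measured in the flower band;
    # sugars at blossom level so the reclassified record stays compliant
    rows += [
        (_H, {"econd": (0.15, 0.78), "glu": (25.0, 38.0), "fru": (36.0, 49.0)}, None, None)
    ] * 16

    # high sucrose (5; the first four also miss the monosaccharide floor)
    rows += [
        (_A, {"suc": 16.58, "glu": 22.00, "fru": 30.72}, E, 2020),
        (_L, {"suc": 5.60, "glu": 24.00, "fru": 31.80, "econd": (0.15, 0.60)}, W, 2022),
        (_P, {"suc": 15.40, "glu": 22.16, "fru": 30.00, "econd": (0.15, 0.60)}, B, 2021),
        (_P, {"suc": 16.34, "glu": 20.50, "fru": 29.00, "econd": (0.15, 0.60)}, W, 2018),
        (_P, {"suc": 6.48}, N, 2023),
    ]

    # high 5-HMF (12)
    rows += [
        (_A, {"hmf": 54.80}, B, 2018),
        (_H, {"hmf": 63.41}, E, 2018),
        (_M, {"hmf": 59.20}, N, 2019),
        (_S, {"hmf": 40.80}, W, 2019),
        (_P, {"hmf": 93.50}, B, 2019),
        (_P, {"hmf": 71.30}, N, 2021),
        (_P, {"hmf": 57.00}, B, 2022),
        (_P, {"hmf": 63.20}, N, 2018),
        (_P, {"hmf": 58.60}, W, 2018),
        (_P, {"hmf": 45.00}, B, 2018),
        (_P, {"hmf": 48.30}, E, 2019),
        (_P, {"hmf": 42.70}, B, 2021),
    ]

    # high acidity (1) and low diastase (4)
    rows += [(_P, {"acid": 61.26}, E, 2023)]
    rows += [
        (_A, {"dia": 3.90}, C, 2022),
        (_A, {"dia": 6.50}, B, 2018),
        (_P, {"dia": 0.50}, B, 2018),
        (_P, {"dia": 7.20}, B, 2018),
    ]

    # high moisture (2)
    rows += [(_M, {"mc": 22.00}, N, 2023), (_H, {"mc": 26.00}, E, 2018)]

    # low conductivity (9): two acacia, one linden, six polyfloral
    rows += [
        (_A, {"econd": 0.033}, E, 2018),
        (_A, {"econd": 0.045}, E, 2018),
        (_L, {"econd": 0.040}, E, 2018),
        (_P, {"econd": 0.035}, E, 2018),
        (_P, {"econd": 0.050}, N, 2018),
        (_P, {"econd": 0.060}, N, 2018),
        (_P, {"econd": 0.075}, N, 2018),
        (_P, {"econd": 0.080}, B, 2019),
        (_P, {"econd": 0.096}, B, 2019),
    ]

    # suspect-grade low monosaccharide sum (53): 18 acacia, 1 honeydew,
    # 10 linden, 1 monofloral, 22 polyfloral, 1 sunflower; most from 2018.
    # Three of them carry the nectar/honeydew blend conductivity profile.
    low = {"sugar_sum": (50.0, 59.0)}
    low_ec = {"sugar_sum": (50.0, 59.0), "econd": (0.15, 0.65)}
    rows += [(_A, dict(low), None, 2018)] * 10
    rows += [(_A, dict(low), None, None)] * 8
    rows += [(_L, {**low_ec}, None, 2018)] * 8
    rows += [(_L, {"sugar_sum": (53.0, 58.0), "econd": 0.76}, None, None)]  # blend
    rows += [(_L, {**low_ec}, None, None)]
    rows += [(_P, {**low_ec}, None, 2018)] * 17
    rows += [(_P, {"sugar_sum": (53.0, 58.0), "econd": 0.71}, None, None)]  # blend
    rows += [(_P, {"sugar_sum": (53.0, 58.0), "econd": 0.73}, None, None)]  # blend
    rows += [(_P, {**low_ec}, None, None)] * 3
    rows += [(_H, {"glu": 20.00, "fru": 22.00}, None, None)]
    rows += [(_M, {"sugar_sum": (50.0, 59.0), "econd": (0.15, 0.50)}, None, None)]
    rows += [(_S, dict(low), None, None)]
    return rows


def build_fixture(seed: int = 0) -> tuple[SampleTable, FixtureManifest]:
    """Deterministic 609-record table with a known deviation inventory.

    Returns the table (declared types only; reclassification is a downstream
    stage) and the manifest of every count the pipeline must recover.
    Identical seeds yield byte-identical CSV exports.
    """
    rng = np.random.default_rng(seed)
    profiles = _special_profiles()

    # baseline compliant records fill each declared-type count
    special_per_type: dict[HoneyType, int] = {}
    for t, _, _, _ in profiles:
        special_per_type[t] = special_per_type.get(t, 0) + 1
    for t, declared in DECLARED_COUNTS.items():
        n_base = declared - special_per_type.get(t, 0)
        profiles += [(t, {}, None, None)] * n_base
    assert len(profiles) == 609

    # region / year quota fill around the pinned assignments
    region_quota = dict(REGION_COUNTS)
    year_quota = dict(YEAR_COUNTS)
    for _, _, r, y in profiles:
        if r is not None:
            region_quota[r] -= 1
        if y is not None:
            year_quota[y] -= 1
    region_pool = [r for r, n in region_quota.items() for _ in range(n)]
    year_pool = [y for y, n in year_quota.items() for _ in range(n)]
    rng.shuffle(region_pool)
    rng.shuffle(year_pool)

    records: list[HoneySample] = []
    ri = yi = 0
    order = rng.permutation(len(profiles))
    for out_i, prof_i in enumerate(order, start=1):
        t, overrides, region, year = profiles[prof_i]
        if region is None:
            region = region_pool[ri]
            ri += 1
        if year is None:
            year = year_pool[yi]
            yi += 1
        values = _baseline_values(rng, t)
        _apply_overrides(rng, values, overrides)
        suc_cens = values["suc"] < LOQ
        hmf_cens = values["hmf"] < LOQ
        if suc_cens:
            values["suc"] = LOQ
        if hmf_cens:
            values["hmf"] = LOQ
        records.append(
            HoneySample(
                sample_id=f"FIX-{out_i:04d}",
                declared_type=t,
                region=region,
                year=year,
                suc_censored=suc_cens,
                hmf_censored=hmf_cens,
                **values,
            )
        )

    manifest = FixtureManifest(
        total=609,
        declared_type_counts={t.value: n for t, n in DECLARED_COUNTS.items()},
        final_type_counts={t.value: n for t, n in TYPE_COUNTS.items()},
        region_counts={r.value: n for r, n in REGION_COUNTS.items()},
        year_counts=dict(YEAR_COUNTS),
        reclassified_in=9,
        reclassified_out=16,
        reclassified_total=25,
        final_honeydew=29,
        low_econd=9,
        low_sugar_sum_suspect=53,
        low_sugar_sum_total=57,
        high_sucrose=5,
        high_hmf=12,
        high_acidity=1,
        low_diastase=4,
        high_moisture=2,
        high_insoluble=0,
        adulterated=22,
        suspect=64,
        compliant=523,
        blend_flags=3,
        nonconforming_pct=14.1,
    )
    return SampleTable(records, provenance=f"fixture(seed={seed})"), manifest
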