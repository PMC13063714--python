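"""Synthetic patient cohorts matched to published group-wise summary statistics.

The study population behind this package is summarised only as group-wise
quartiles (median, Q1, Q3) of five features — age, CK18-positive CTC count,
MGB-positive CTC count, WBC count and platelet count — for 228 breast-cancer
and 170 benign/healthy subjects, with WBC/platelet jointly missing for 33 of
the benign/healthy subjects.  Patient-level data are not deposited, so this
module generates cohorts with that statistical structure: each feature is
drawn, per outcome group, from a parametric family whose theoretical
quartiles are fitted to the published targets by least squares.

Families
--------
``truncated-normal``
    Symmetric-ish continuous features; a normal truncated to explicit
    bounds, two free parameters fitted by least squares.
``log-normal``
    Continuous skewed features (age, WBC, platelet).  A three-parameter
    shifted log-normal, reflected for left-skewed triples and truncated to
    the feature's support, is used: the published quartile triples are
    asymmetric (the benign-group age triple strongly so) and no
    two-parameter symmetric family can reproduce all three quartiles, while
    the shift/reflection/truncation construction matches them exactly and
    keeps samples inside physiological bounds without clipping artefacts.
``negative-binomial``
    CTC counts (non-negative, overdispersed integers).  Quartile targets may
    be non-integer (interpolated sample quantiles); the fit therefore uses a
    continuous, linearly interpolated quantile function on the integer
    lattice, minimised over a bounded (mean, dispersion) grid and polished
    by Nelder-Mead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FeatureSpec",
    "GeneratorConfig",
    "Cohort",
    "fit_quartile_params",
    "generate_cohort",
    "compare_features",
    "DEFAULT_FEATURE_SPECS",
    "DEFAULT_SUBGROUP_FREQS",
    "FEATURES",
    "COHORT_COLUMNS",
]

FEATURES = ["age", "ck18", "mgb", "wbc", "platelet"]
COHORT_COLUMNS = [
    "subject_id",
    "outcome",
    "age",
    "ck18",
    "mgb",
    "wbc",
    "platelet",
    "birads",
    "stage",
    "subtype",
    "density",
]

OUTCOME_CANCER = "cancer"
OUTCOME_BENIGN = "benign_healthy"

#: z-score of the 75th percentile of the standard normal; quartile spacing
#: of (log-)normal families is expressed through it.
_Z75 = float(stats.norm.ppf(0.75))

AGE_TRUNCATION = (20.0, 95.0)


@dataclass(frozen=True)
class FeatureSpec:
    """Distribution target for one feature in one outcome group.

    ``bounds`` restricts the support (truncation for the continuous
    families); ``None`` selects the family default — the age range for
    ``truncated-normal``, ``(0, inf)`` for ``log-normal``.
    """

    family: str  # truncated-normal | log-normal | negative-binomial
    median: float
    q1: float
    q3: float
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"quartile targets must be non-decreasing, got "
                f"({self.q1}, {self.median}, {self.q3})"
            )


# Group-wise quartile targets of the study population (cancer n=228,
# benign/healthy n=170).  Units: age years; ck18/mgb cells per processed
# 2 mL blood sample; wbc, platelet cells/µL.
DEFAULT_FEATURE_SPECS: dict[str, dict[str, FeatureSpec]] = {
    OUTCOME_CANCER: {
        "age": FeatureSpec("log-normal", 56, 46.75, 64, bounds=(18.0, 100.0)),
        "ck18": FeatureSpec("negative-binomial", 3, 1, 7),
        "mgb": FeatureSpec("negative-binomial", 5, 2, 10),
        "wbc": FeatureSpec("log-normal", 6400, 5400, 7700),
        "platelet": FeatureSpec("log-normal", 254_000, 216_000, 291_000),
    },
    OUTCOME_BENIGN: {
        "age": FeatureSpec("log-normal", 46.5, 34, 54, bounds=(18.0, 100.0)),
        "ck18": FeatureSpec("negative-binomial", 2, 1, 4),
        "mgb": FeatureSpec("negative-binomial", 3, 1.25, 7),
        "wbc": FeatureSpec("log-normal", 6300, 5400, 7700),
        "platelet": FeatureSpec("log-normal", 255_000, 224_000, 297_000),
    },
}

# Subgroup label frequencies per outcome group (counts from the study's
# case-distribution table; "NA" is carried as an explicit category).
DEFAULT_SUBGROUP_FREQS: dict[str, dict[str, dict[str, float]]] = {
    OUTCOME_CANCER: {
        "stage": {"0": 16, "1": 71, "2": 99, "3": 26, "4": 15, "NA": 1},
        "subtype": {
            "ER+HER2-": 144,
            "ER+HER2+": 26,
            "ER-HER2+": 22,
            "ER-HER2-": 36,
        },
        "density": {"B": 11, "C": 189, "D": 19, "NA": 9},
        "birads": {"0": 2, "2": 2, "3": 2, "4": 122, "5": 30, "6": 67, "NA": 3},
    },
    OUTCOME_BENIGN: {
        "stage": {"NA": 170},
        "subtype": {"NA": 170},
        "density": {"B": 5, "C": 96, "D": 12, "NA": 57},
        "birads": {"1": 15, "2": 63, "3": 16, "4": 75, "NA": 1},
    },
}


def _normalise_freqs(freqs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(freqs)
    p = np.asarray([freqs[k] for k in labels], dtype=float)
    if np.any(p < 0):
        raise ValueError("subgroup frequencies must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("subgroup frequencies must not all be zero")
    p = p / total
    return labels, p


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    Defaults reproduce the study conditions: 228 cancer / 170 benign
    subjects, group-wise feature quartiles matched to the published
    summaries, and 33/170 benign subjects with WBC and platelet jointly
    missing.
    """

    n_cancer: int = 228
    n_benign: int = 170
    feature_specs: Mapping[str, Mapping[str, FeatureSpec]] = field(
        default_factory=lambda: DEFAULT_FEATURE_SPECS
    )
    missing_fraction_benign: float = 33 / 170
    subgroup_freqs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_SUBGROUP_FREQS
    )
    ctc_copula_rho: float = 0.0  # CK18/MGB within-subject Gaussian-copula corr.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer <= 0 or self.n_benign <= 0:
            raise ValueError("both outcome groups need at least one subject")
        if not 0.0 <= self.missing_fraction_benign <= 1.0:
            raise ValueError("missing_fraction_benign must be in [0, 1]")
        if not -1.0 < self.ctc_copula_rho < 1.0:
            raise ValueError("ctc_copula_rho must be in (-1, 1)")
        for group in (OUTCOME_CANCER, OUTCOME_BENIGN):
            if group not in self.feature_specs:
                raise ValueError(f"feature_specs missing group {group!r}")
            for feat in FEATURES:
                if feat not in self.feature_specs[group]:
                    raise ValueError(f"no spec for feature {feat!r} in {group!r}")
        for group, per_var in self.subgroup_freqs.items():
            for var, freqs in per_var.items():
                _normalise_freqs(freqs)  # validates

    def with_sizes(self, n_cancer: int, n_benign: int) -> "GeneratorConfig":
        return replace(self, n_cancer=n_cancer, n_benign=n_benign)


@dataclass
class Cohort:
    """An ordered table of patient records plus provenance.

    ``frame`` has the columns of :data:`COHORT_COLUMNS`; missing WBC/platelet
    values are ``NaN``; subgroup NA is ``pd.NA``/empty.
    """

    frame: pd.DataFrame
    provenance: object = "observed"
    feature_names: tuple[str, ...] = tuple(FEATURES)

    def __post_init__(self) -> None:
        missing_cols = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing_cols:
            raise ValueError(f"cohort frame lacks columns {missing_cols}")
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        outcomes = set(self.frame["outcome"].unique())
        if not outcomes <= {OUTCOME_CANCER, OUTCOME_BENIGN}:
            raise ValueError(f"unknown outcome labels: {outcomes}")
        if len(outcomes) < 2:
            raise ValueError("cohort must contain at least one record per class")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    @property
    def y(self) -> np.ndarray:
        return (self.frame["outcome"] == OUTCOME_CANCER).to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, provenance: object = "observed") -> "Cohort":
        frame = pd.read_csv(
            path,
            dtype={
                "subject_id": str,
                "outcome": str,
                "birads": "string",
                "stage": "string",
                "subtype": "string",
                "density": "string",
            },
        )
        return cls(frame=frame, provenance=provenance)


# ---------------------------------------------------------------------------
# Quartile fitting
# ---------------------------------------------------------------------------

_QUARTILE_PS = np.array([0.25, 0.5, 0.75])


def _truncnorm_quartiles(mu: float, sigma: float, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(_QUARTILE_PS, a, b, loc=mu, scale=sigma)


def _sln_parent_cdf(y, s: float, loc: float, scale: float):
    """CDF of the parent shifted log-normal Y = loc + scale * exp(s Z)."""
    t = (np.asarray(y, dtype=float) - loc) / scale
    return np.where(t <= 0, 0.0, stats.norm.cdf(np.log(np.maximum(t, 1e-300)) / s))


def _sln_quantile(p, params: Mapping[str, float]) -> np.ndarray:
    """Quantile of the truncated, optionally reflected, shifted log-normal.

    The parent is Y = loc + scale*exp(s Z); a left-skewed feature is the
    reflection X = 2*anchor - Y; truncation to [lo, hi] maps the requested
    probabilities into the parent CDF range covered by the bounds.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    s, loc, scale = params["s"], params["loc"], params["scale"]
    lo, hi = params["lo"], params["hi"]
    anchor = params["anchor"]
    if params["reflected"]:
        ya = 2 * anchor - hi if np.isfinite(hi) else -np.inf
        yb = 2 * anchor - lo
    else:
        ya, yb = lo, hi
    fa = float(_sln_parent_cdf(ya, s, loc, scale)) if np.isfinite(ya) else 0.0
    fb = float(_sln_parent_cdf(yb, s, loc, scale)) if np.isfinite(yb) else 1.0
    pp = 1.0 - p if params["reflected"] else p
    u = np.clip(fa + pp * (fb - fa), 1e-12, 1 - 1e-12)
    y = loc + scale * np.exp(s * stats.norm.ppf(u))
    x = 2 * anchor - y if params["reflected"] else y
    return np.clip(x, lo, hi)


def _nbinom_cont_quantile(p: np.ndarray, mean: float, disp: float) -> np.ndarray:
    """Linearly interpolated quantile of NB(mean, dispersion) on the lattice.

    ``disp`` is the size/shape parameter r; variance = mean + mean^2 / r.
    Between lattice points k-1 and k the quantile interpolates the CDF gap,
    so non-integer targets (interpolated sample quantiles of integer data)
    can be matched.
    """
    r = disp
    prob = r / (r + mean)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    k = stats.nbinom.ppf(p, r, prob)  # smallest k with F(k) >= p
    f_k = stats.nbinom.cdf(k, r, prob)
    f_km1 = np.where(k > 0, stats.nbinom.cdf(k - 1, r, prob), 0.0)
    gap = np.clip(f_k - f_km1, 1e-300, None)
    # centre each lattice point on its probability mass, so the continuous
    # value k corresponds to the middle of P(X = k); the fitted integer
    # quantiles then agree with the targets after rounding
    return k - 0.5 + (p - f_km1) / gap


def _fit_truncated_normal(median, q1, q3, lo, hi):
    sigma0 = max((q3 - q1) / (2 * _Z75), 1e-6)

    def objective(theta):
        mu, log_sigma = theta
        q = _truncnorm_quartiles(mu, np.exp(log_sigma), lo, hi)
        return float(np.sum((q - np.array([q1, median, q3])) ** 2))

    res = optimize.minimize(
        objective,
        x0=[median, np.log(sigma0)],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    params = {"mu": float(mu), "sigma": sigma, "lo": lo, "hi": hi}
    fitted = _truncnorm_quartiles(mu, sigma, lo, hi)
    return params, fitted, bool(res.success)


def _fit_shifted_lognormal(median, q1, q3, lo=0.0, hi=np.inf):
    # Closed-form untruncated solution — (q3-q2)/(q2-q1) = exp(z75*s), then
    # scale and loc follow — polished by least squares on the *truncated*
    # quantiles so the bounds are respected exactly.  Left-skewed triples
    # are fitted through the reflection around the median.
    upper, lower = q3 - median, median - q1
    reflected = upper < lower
    if reflected:
        upper, lower = lower, upper
    ratio = max(upper / lower, 1.0 + 1e-9)
    s0 = float(np.log(ratio) / _Z75)
    scale0 = lower / (1.0 - np.exp(-_Z75 * s0))
    loc0 = median - scale0
    targets = np.array([q1, median, q3], dtype=float)

    def mk(theta):
        return {
            "s": float(np.exp(theta[0])),
            "loc": float(theta[1]),
            "scale": float(np.exp(theta[2])),
            "reflected": reflected,
            "anchor": float(median),
            "lo": float(lo),
            "hi": float(hi),
        }

    def objective(theta):
        q = _sln_quantile(_QUARTILE_PS, mk(theta))
        return float(np.sum((q - targets) ** 2))

    x0 = [np.log(s0), loc0, np.log(scale0)]
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 5000},
    )
    theta = res.x if res.fun <= objective(x0) else np.asarray(x0)
    params = mk(theta)
    fitted = _sln_quantile(_QUARTILE_PS, params)
    # near-symmetric triples leave a flat ridge in s; a tiny residual is a
    # converged fit even when the simplex hits its iteration budget
    tol = (1e-4 * max(abs(q1), abs(q3), 1.0)) ** 2 * 3
    ok = bool(res.success) or float(min(res.fun, objective(theta))) <= tol
    return params, fitted, ok


# Bounded brute-force grid over which the NB fit is initialised; the same
# grid serves as the reference optimum in tests.
NB_MEAN_GRID = np.geomspace(0.5, 20.0, 40)
NB_DISP_GRID = np.geomspace(0.1, 50.0, 40)


def nbinom_grid_objective(median, q1, q3, mean_grid=None, disp_grid=None):
    """Brute-force objective evaluation over the bounded NB parameter grid.

    Returns ``(best_params, best_objective)``; exposed so the polished fit
    can be checked against the exhaustive grid optimum.
    """
    mean_grid = NB_MEAN_GRID if mean_grid is None else mean_grid
    disp_grid = NB_DISP_GRID if disp_grid is None else disp_grid
    targets = np.array([q1, median, q3], dtype=float)
    best = (None, np.inf)
    for m in mean_grid:
        for d in disp_grid:
            q = _nbinom_cont_quantile(_QUARTILE_PS, m, d)
            obj = float(np.sum((q - targets) ** 2))
            if obj < best[1]:
                best = ({"mean": float(m), "dispersion": float(d)}, obj)
    return best


def _fit_negative_binomial(median, q1, q3):
    targets = np.array([q1, median, q3], dtype=float)
    (start, grid_obj) = nbinom_grid_objective(median, q1, q3)

    def objective(theta):
        m, d = np.exp(theta)
        q = _nbinom_cont_quantile(_QUARTILE_PS, m, d)
        return float(np.sum((q - targets) ** 2))

    res = optimize.minimize(
        objective,
        x0=np.log([start["mean"], start["dispersion"]]),
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 2000},
    )
    m, d = np.exp(res.x)
    polished_obj = objective(res.x)
    if polished_obj > grid_obj + 1e-12:  # polish never trusted past the grid
        m, d = start["mean"], start["dispersion"]
        polished_obj = grid_obj
    params = {"mean": float(m), "dispersion": float(d)}
    fitted = _nbinom_cont_quantile(_QUARTILE_PS, m, d)
    return params, fitted, bool(res.success)


def fit_quartile_params(
    family: str,
    median: float,
    q1: float,
    q3: float,
    *,
    bounds: tuple[float, float] | None = None,
    feature: str = "",
) -> dict:
    """Fit a distribution family to target quartiles by least squares.

    Returns a dict with ``family``, ``params``, ``fitted_quartiles`` and a
    ``converged`` flag.  Degenerate targets (``q1 == q3``) are rejected.
    ``bounds`` truncates the continuous families (defaults: the adult age
    range for ``truncated-normal``, ``(0, inf)`` for ``log-normal``).
    """
    if not (q1 <= median <= q3):
        raise ValueError(
            f"quartiles must satisfy q1 <= median <= q3 for {feature or family}"
        )
    if q1 == q3:
        raise ValueError(
            f"degenerate quartile targets (q1 == q3 == {q1}) for "
            f"{feature or 'feature'}: cannot identify a spread"
        )
    if family == "truncated-normal":
        lo, hi = bounds if bounds is not None else AGE_TRUNCATION
        params, fitted, ok = _fit_truncated_normal(median, q1, q3, lo, hi)
    elif family == "log-normal":
        lo, hi = bounds if bounds is not None else (0.0, np.inf)
        params, fitted, ok = _fit_shifted_lognormal(median, q1, q3, lo, hi)
    elif family == "negative-binomial":
        params, fitted, ok = _fit_negative_binomial(median, q1, q3)
    else:
        raise ValueError(f"unknown distribution family {family!r}")
    if not ok:
        warnings.warn(
            f"quartile fit for {feature or family} did not formally converge; "
            "reporting best-found parameters",
            RuntimeWarning,
            stacklevel=2,
        )
    return {
        "family": family,
        "params": params,
        "fitted_quartiles": np.asarray(fitted, dtype=float),
        "targets": np.array([q1, median, q3], dtype=float),
        "converged": ok,
    }


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_feature(
    fit: dict, n: int, rng: np.random.Generator, *, uniforms: np.ndarray | None = None
) -> np.ndarray:
    """Draw n values from a fitted family (optionally via given U(0,1) draws)."""
    family, params = fit["family"], fit["params"]
    u = rng.uniform(size=n) if uniforms is None else uniforms
    if family == "truncated-normal":
        a = (params["lo"] - params["mu"]) / params["sigma"]
        b = (params["hi"] - params["mu"]) / params["sigma"]
        return stats.truncnorm.ppf(u, a, b, loc=params["mu"], scale=params["sigma"])
    if family == "log-normal":
        return _sln_quantile(u, params)
    if family == "negative-binomial":
        r = params["dispersion"]
        prob = r / (r + params["mean"])
        return stats.nbinom.ppf(u, r, prob)
    raise ValueError(f"unknown family {family!r}")


def _sample_group(
    specs: Mapping[str, FeatureSpec],
    n: int,
    rng: np.random.Generator,
    rho: float,
) -> dict[str, np.ndarray]:
    fits = {
        feat: fit_quartile_params(
            s.family, s.median, s.q1, s.q3, bounds=s.bounds, feature=feat
        )
        for feat, s in specs.items()
    }
    out: dict[str, np.ndarray] = {}
    if rho != 0.0:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u_ck18, u_mgb = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
        out["ck18"] = _sample_feature(fits["ck18"], n, rng, uniforms=u_ck18)
        out["mgb"] = _sample_feature(fits["mgb"], n, rng, uniforms=u_mgb)
    else:
        out["ck18"] = _sample_feature(fits["ck18"], n, rng)
        out["mgb"] = _sample_feature(fits["mgb"], n, rng)
    out["age"] = np.clip(_sample_feature(fits["age"], n, rng), 18.0, 100.0)
    for feat in ("wbc", "platelet"):
        out[feat] = _sample_feature(fits[feat], n, rng)  # truncated at 0
    return out


def _sample_labels(
    freq_table: Mapping[str, Mapping[str, float]],
    var: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if var not in freq_table:
        return np.array(["NA"] * n, dtype=object)
    labels, p = _normalise_freqs(freq_table[var])
    return rng.choice(np.array(labels, dtype=object), size=n, p=p)


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Generate a synthetic cohort under the study conditions.

    Deterministic given ``config.seed``; exactly
    ``round(missing_fraction_benign * n_benign)`` benign subjects get WBC and
    platelet jointly missing; cancer records are always complete.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    parts = []
    for outcome, n in ((OUTCOME_CANCER, config.n_cancer), (OUTCOME_BENIGN, config.n_benign)):
        feats = _sample_group(
            config.feature_specs[outcome], n, rng, config.ctc_copula_rho
        )
        block = pd.DataFrame(
            {
                "outcome": outcome,
                "age": feats["age"],
                "ck18": feats["ck18"].astype(int),
                "mgb": feats["mgb"].astype(int),
                "wbc": feats["wbc"],
                "platelet": feats["platelet"],
            }
        )
        for var in ("birads", "stage", "subtype", "density"):
            block[var] = _sample_labels(
                config.subgroup_freqs.get(outcome, {}), var, n, rng
            )
        parts.append(block)

    frame = pd.concat(parts, ignore_index=True)
    frame.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(frame))])

    n_missing = round(config.missing_fraction_benign * config.n_benign)
    if n_missing:
        benign_idx = frame.index[frame["outcome"] == OUTCOME_BENIGN].to_numpy()
        chosen = rng.choice(benign_idx, size=n_missing, replace=False)
        frame.loc[chosen, ["wbc", "platelet"]] = np.nan

    for var in ("birads", "stage", "subtype", "density"):
        frame[var] = frame[var].astype("string")
        frame.loc[frame[var] == "NA", var] = pd.NA

    return Cohort(frame=frame[COHORT_COLUMNS], provenance=config)


def separated_feature_specs() -> dict[str, dict[str, FeatureSpec]]:
    """Feature specs with group shifts of at least 2 SD in age, CK18 and MGB.

    A strongly separated variant of the default study conditions, used for
    signal-recovery checks: a correct pipeline must classify such cohorts
    almost perfectly, so failures indicate leakage or wiring defects rather
    than statistical noise.
    """
    specs = {group: dict(feats) for group, feats in DEFAULT_FEATURE_SPECS.items()}
    specs[OUTCOME_CANCER]["age"] = FeatureSpec(
        "log-normal", 58, 54, 62, bounds=(18.0, 100.0)
    )
    specs[OUTCOME_BENIGN]["age"] = FeatureSpec(
        "log-normal", 38, 34, 42, bounds=(18.0, 100.0)
    )
    specs[OUTCOME_CANCER]["ck18"] = FeatureSpec("negative-binomial", 12, 9, 15)
    specs[OUTCOME_BENIGN]["ck18"] = FeatureSpec("negative-binomial", 2, 1, 3)
    specs[OUTCOME_CANCER]["mgb"] = FeatureSpec("negative-binomial", 15, 12, 18)
    specs[OUTCOME_BENIGN]["mgb"] = FeatureSpec("negative-binomial", 3, 2, 4)
    return specs


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_features(cohort: Cohort) -> pd.DataFrame:
    """Two-group feature comparison as reported for the study cohort.

    Per feature: group-wise median/Q1/Q3 on non-missing values, a two-sided
    Mann-Whitney-Wilcoxon p-value, and Shapiro normality p-values per group.
    Degenerate inputs (all-missing group, zero variance) yield NA with a
    warning.
    """
    frame = cohort.frame
    rows = []
    for feat in cohort.feature_names:
        row: dict[str, object] = {"feature": feat}
        groups = {}
        for outcome, tag in ((OUTCOME_CANCER, "cancer"), (OUTCOME_BENIGN, "benign")):
            x = frame.loc[frame["outcome"] == outcome, feat].dropna().to_numpy(float)
            groups[tag] = x
            if x.size == 0:
                warnings.warn(
                    f"feature {feat!r} all-missing in {tag} group", RuntimeWarning,
                    stacklevel=2,
                )
                row.update(
                    {f"{tag}_median": np.nan, f"{tag}_q1": np.nan, f"{tag}_q3": np.nan,
                     f"{tag}_n": 0, f"{tag}_shapiro_p": np.nan}
                )
                continue
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            row.update(
                {f"{tag}_median": med, f"{tag}_q1": q1, f"{tag}_q3": q3,
                 f"{tag}_n": int(x.size)}
            )
            if x.size >= 3 and np.ptp(x) > 0:
                row[f"{tag}_shapiro_p"] = float(stats.shapiro(x).pvalue)
            else:
                row[f"{tag}_shapiro_p"] = np.nan
        a, b = groups["cancer"], groups["benign"]
        if a.size and b.size:
            pooled = np.concatenate([a, b])
            if np.ptp(pooled) == 0:
                warnings.warn(
                    f"feature {feat!r} has zero variance; MWW p-value undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                row["mww_p"] = np.nan
            else:
                row["mww_p"] = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
        else:
            row["mww_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
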