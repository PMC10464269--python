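"""Inferential layer: BCa bootstrap regression inference and cohort tests.

Implements the analysis toolkit for two-group (SGA vs control) cohort
comparisons of physical-activity outcomes:

* sex-adjusted group differences from linear regression, with confidence
  intervals and p-values from a bias-corrected and accelerated (BCa)
  case-resampling bootstrap stratified by group;
* PA ~ SF-36 association models with a group x SF-36 interaction term,
  reporting group-specific slopes (MET minutes per SF-36 point);
* Spearman rank correlations, Pearson chi-square proportion tests,
  Student's t-tests and permutation Mann-Whitney tests for descriptive
  tables;
* the a-priori minimum detectable effect size (MDES) for a two-sample
  comparison.

The BCa machinery is written here from first principles (bias correction
``z0`` from the bootstrap distribution, acceleration ``a`` from jackknife
skewness); bootstrap p-values invert the CI over a fixed alpha grid, so
``p < alpha`` exactly when the (1 - alpha) interval excludes zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

__all__ = [
    "BootstrapConfig",
    "ComparisonResult",
    "AssociationResult",
    "bca_interval",
    "bootstrap_p",
    "adjusted_group_difference",
    "interaction_association",
    "spearman_rho",
    "proportion_test",
    "ProportionTestResult",
    "mdes_power",
    "mannwhitney_permutation",
    "descriptive_table",
    "ponderal_index",
    "percent",
]


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.001, 1.0, 0.001), 3)


@dataclass
class BootstrapConfig:
    """Settings for the BCa case-resampling bootstrap.

    ``B`` resamples (study default 2000); ``stratify_by_group`` resamples
    within each group so group sizes are preserved; ``alpha_grid`` is the
    grid used to invert confidence intervals into p-values.
    """

    B: int = 2000
    seed: int = 0
    stratify_by_group: bool = True
    alpha_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be at least 100")
        grid = np.asarray(self.alpha_grid, dtype=float)
        if grid.size == 0 or grid.min() <= 0 or grid.max() >= 1:
            raise ValueError("alpha grid must lie strictly inside (0, 1)")
        self.alpha_grid = np.sort(grid)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# BCa engine
# ---------------------------------------------------------------------------


def _resample_indices(rng: np.random.Generator, n: int, B: int, strata=None) -> np.ndarray:
    """(B, n) bootstrap index matrix, resampling within strata if given."""
    if strata is None:
        return rng.integers(0, n, size=(B, n))
    strata = np.asarray(strata)
    out = np.empty((B, n), dtype=np.intp)
    pos = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[:, pos : pos + idx.size] = idx[rng.integers(0, idx.size, size=(B, idx.size))]
        pos += idx.size
    return out


@dataclass
class _BootDist:
    """Point estimate plus bootstrap and jackknife replicate statistics."""

    est: np.ndarray      # (k,)
    boot: np.ndarray     # (B, k)
    accel: np.ndarray    # (k,)

    @property
    def k(self) -> int:
        return self.est.size


def _bootstrap_distribution(stat_idx, n: int, cfg: BootstrapConfig, strata=None) -> _BootDist:
    """Run the bootstrap and jackknife for an index-based statistic.

    ``stat_idx(indices)`` evaluates the statistic on the rows named by
    ``indices`` and may return a scalar or a vector of functionals.
    """
    est = np.atleast_1d(np.asarray(stat_idx(np.arange(n)), dtype=float))
    rng = cfg.rng()
    idx = _resample_indices(rng, n, cfg.B, strata)
    boot = np.empty((cfg.B, est.size))
    for b in range(cfg.B):
        boot[b] = stat_idx(idx[b])
    jack = np.empty((n, est.size))
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = stat_idx(np.delete(all_idx, i))
    jmean = jack.mean(axis=0)
    d = jmean - jack
    denom = (d**2).sum(axis=0) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        accel = np.where(denom > 0, (d**3).sum(axis=0) / (6.0 * denom), 0.0)
    return _BootDist(est=est, boot=boot, accel=accel)


def _z0(boot: np.ndarray, est: float) -> float:
    B = boot.size
    p0 = (np.sum(boot < est) + 0.5 * np.sum(boot == est)) / B
    p0 = min(max(p0, 1.0 / (B + 1)), B / (B + 1.0))
    return float(ndtri(p0))


def _bca_levels(z0: float, a: float, alphas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted quantile levels for the lower/upper endpoints per alpha."""
    zlo = ndtri(alphas / 2.0)
    zhi = ndtri(1.0 - alphas / 2.0)

    def adj(z):
        denom = 1.0 - a * (z0 + z)
        denom = np.where(denom <= 1e-12, 1e-12, denom)
        return ndtr(z0 + (z0 + z) / denom)

    return adj(zlo), adj(zhi)


def _interval_from_dist(dist: _BootDist, alpha: float, component: int = 0) -> tuple[float, float]:
    boot = dist.boot[:, component]
    est = float(dist.est[component])
    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; zero-width interval", stacklevel=3)
        return est, est
    z0 = _z0(boot, est)
    lo_lev, hi_lev = _bca_levels(z0, float(dist.accel[component]), np.array([alpha]))
    # median-unbiased quantiles: the default linear interpolation gives
    # too-narrow tails at small B, inflating the type-I error
    lo, hi = np.quantile(boot, [lo_lev[0], hi_lev[0]], method="median_unbiased")
    return float(lo), float(hi)


def _p_from_dist(dist: _BootDist, grid: np.ndarray, component: int = 0, null_value: float = 0.0) -> float:
    boot = dist.boot[:, component]
    est = float(dist.est[component])
    if np.ptp(boot) == 0.0:
        return 1.0 if est == null_value else float(grid[0])
    z0 = _z0(boot, est)
    lo_lev, hi_lev = _bca_levels(z0, float(dist.accel[component]), grid)
    lo = np.quantile(boot, lo_lev, method="median_unbiased")
    hi = np.quantile(boot, hi_lev, method="median_unbiased")
    excluded = (lo > null_value) | (hi < null_value)
    if not excluded.any():
        return 1.0
    return float(grid[np.flatnonzero(excluded)[0]])


def _as_stat_idx(statistic, data):
    arr = np.asarray(data)
    n = arr.shape[0]
    return (lambda idx: statistic(arr[idx])), n


def bca_interval(statistic, data, cfg: BootstrapConfig | None = None, alpha: float = 0.05, strata=None):
    """BCa bootstrap confidence interval for ``statistic(data)``.

    ``data`` is resampled along its first axis (cases). The bias
    correction z0 is the normal quantile of the fraction of bootstrap
    replicates below the point estimate; the acceleration is the jackknife
    skewness estimate; interval endpoints sit at the correspondingly
    adjusted percentiles of the bootstrap distribution. A degenerate
    (zero-variance) bootstrap distribution yields a zero-width interval
    with a warning.
    """
    cfg = cfg or BootstrapConfig()
    stat_idx, n = _as_stat_idx(statistic, data)
    dist = _bootstrap_distribution(stat_idx, n, cfg, strata)
    return _interval_from_dist(dist, alpha)


def bootstrap_p(statistic, data, cfg: BootstrapConfig | None = None, strata=None, null_value: float = 0.0) -> float:
    """Bootstrap p-value by CI inversion over the config's alpha grid.

    Returns the smallest grid alpha at which the (1 - alpha) BCa interval
    excludes ``null_value``; 1.0 if no grid level excludes it. A result
    equal to the grid floor means "p at or below the grid floor".
    """
    cfg = cfg or BootstrapConfig()
    stat_idx, n = _as_stat_idx(statistic, data)
    dist = _bootstrap_distribution(stat_idx, n, cfg, strata)
    return _p_from_dist(dist, cfg.alpha_grid, null_value=null_value)


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def _encode_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "bif":
        return arr.astype(float)
    levels = sorted(pd.unique(arr))
    if len(levels) > 2:
        raise ValueError(f"{name} has more than two levels: {levels}")
    return (arr == levels[-1]).astype(float)


def _group_indicator(group, index_group=None) -> tuple[np.ndarray, str, str]:
    arr = np.asarray(group)
    levels = list(pd.unique(arr))
    if len(levels) < 2:
        raise ValueError("both groups must be represented")
    if len(levels) > 2:
        raise ValueError(f"group has more than two levels: {levels}")
    if index_group is None:
        index_group = "SGA" if "SGA" in levels else sorted(map(str, levels))[-1]
    ref = [l for l in levels if str(l) != str(index_group)][0]
    return (arr.astype(str) == str(index_group)).astype(float), str(index_group), str(ref)


def _expand_covariates(extra: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Continuous columns pass through; categorical/object columns become
    indicator sets (first level as reference)."""
    if extra is None or extra.shape[1] == 0:
        return np.empty((0, 0)), []
    cols, names = [], []
    for c in extra.columns:
        s = extra[c]
        if s.dtype.kind in "bif":
            cols.append(s.to_numpy(dtype=float))
            names.append(str(c))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=str(c), drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(str(dc))
    return np.column_stack(cols) if cols else np.empty((len(extra), 0)), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns expressible from the preceding ones
        collinear = []
        for j in range(1, X.shape[1]):
            sub = X[:, :j]
            resid = X[:, j] - sub @ np.linalg.lstsq(sub, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                collinear.append(names[j])
        raise ValueError(f"singular design matrix; collinear columns: {collinear or names}")


def _ols_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(X.T @ X, X.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, y, rcond=None)[0]


def _listwise(arrays: dict[str, np.ndarray], extra: pd.DataFrame | None):
    n = len(next(iter(arrays.values())))
    mask = np.ones(n, dtype=bool)
    dropped: dict[str, int] = {}
    for name, a in arrays.items():
        a = np.asarray(a)
        bad = pd.isna(a)
        if a.dtype.kind in "if":
            bad = bad | ~np.isfinite(a.astype(float))
        dropped[name] = int(bad.sum())
        mask &= ~bad
    if extra is not None:
        bad = extra.isna().any(axis=1).to_numpy()
        dropped["extra_covariates"] = int(bad.sum())
        mask &= ~bad
    return mask, dropped


# ---------------------------------------------------------------------------
# Regression inference
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Sex-adjusted group difference (index group minus reference)."""

    outcome: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_per_group: dict[str, int]
    covariates: list[str]
    index_group: str
    reference_group: str
    B: int
    seed: int
    n_dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise AssertionError("interval must contain the point estimate")

    def to_record(self) -> dict:
        return {
            "outcome": self.outcome,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            **{f"n_{g}": n for g, n in self.n_per_group.items()},
            "covariates": "+".join(self.covariates),
            "B": self.B,
            "seed": self.seed,
        }


def adjusted_group_difference(
    y,
    group,
    sex,
    extra_covariates: pd.DataFrame | None = None,
    cfg: BootstrapConfig | None = None,
    outcome: str = "outcome",
    index_group: str | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Group difference in ``y`` from linear regression adjusted for sex.

    The point estimate is the group coefficient of an OLS fit of
    ``y ~ group + sex (+ extras)``; the CI and p-value come from a BCa
    bootstrap that resamples participants within group. Categorical extra
    covariates (e.g. month of assessment) enter as indicator sets,
    continuous ones (e.g. weekly work hours) as-is. Rows with missing
    values in any used column are dropped first (listwise deletion,
    reported in ``n_dropped``).
    """
    cfg = cfg or BootstrapConfig()
    y = np.asarray(y, dtype=float)
    mask, dropped = _listwise({"y": y, "group": np.asarray(group), "sex": np.asarray(sex)}, extra_covariates)
    y = y[mask]
    g_ind, index_name, ref_name = _group_indicator(np.asarray(group)[mask], index_group)
    sex_ind = _encode_binary(np.asarray(sex)[mask], "sex")
    extra = extra_covariates.loc[mask].reset_index(drop=True) if extra_covariates is not None else None
    Xextra, extra_names = _expand_covariates(extra)
    n = y.size
    n_index = int(g_ind.sum())
    if n_index < 10 or n - n_index < 10:
        raise ValueError(f"need at least 10 participants per group (have {n_index} and {n - n_index})")
    cols = [np.ones(n), g_ind, sex_ind]
    names = ["intercept", "group", "sex"]
    if Xextra.size:
        cols.extend(Xextra.T)
        names.extend(extra_names)
    X = np.column_stack(cols)
    _check_full_rank(X, names)

    def stat_idx(idx):
        return _ols_coefs(X[idx], y[idx])[1]

    strata = g_ind if cfg.stratify_by_group else None
    dist = _bootstrap_distribution(stat_idx, n, cfg, strata)
    lo, hi = _interval_from_dist(dist, alpha)
    p = _p_from_dist(dist, cfg.alpha_grid)
    est = float(dist.est[0])
    # the BCa interval is percentile-based; guard the containment contract
    lo, hi = min(lo, est), max(hi, est)
    return ComparisonResult(
        outcome=outcome,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_per_group={index_name: n_index, ref_name: n - n_index},
        covariates=names[2:],
        index_group=index_name,
        reference_group=ref_name,
        B=cfg.B,
        seed=cfg.seed,
        n_dropped=dropped,
    )


@dataclass
class AssociationResult:
    """PA ~ SF-36 association with a group interaction.

    ``slopes`` maps group name -> (estimate, ci_low, ci_high, p); slopes
    are in outcome units (MET minutes/day) per SF-36 point.
    """

    pa_category: str
    sf36_measure: str
    slopes: dict[str, tuple[float, float, float, float]]
    interaction_p: float
    n_per_group: dict[str, int]
    B: int
    seed: int

    def __post_init__(self) -> None:
        for g, (est, lo, hi, _) in self.slopes.items():
            if not (lo <= est <= hi):
                raise AssertionError(f"slope interval for {g} must contain its estimate")

    def to_record(self) -> dict:
        rec = {"pa_category": self.pa_category, "sf36_measure": self.sf36_measure}
        for g, (est, lo, hi, p) in self.slopes.items():
            rec.update({f"B_{g}": est, f"ci_low_{g}": lo, f"ci_high_{g}": hi, f"p_{g}": p})
        rec.update({"interaction_p": self.interaction_p, **{f"n_{g}": n for g, n in self.n_per_group.items()}})
        rec.update({"B": self.B, "seed": self.seed})
        return rec


def interaction_association(
    pa,
    sf36,
    group,
    sex,
    cfg: BootstrapConfig | None = None,
    pa_name: str = "pa",
    sf36_name: str = "sf36",
    index_group: str | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Fit ``pa ~ sf36 + group + sex + sf36 x group`` with BCa inference.

    Reports the group-specific SF-36 slopes (reference-group slope, and
    reference + interaction for the index group) with BCa CIs and
    p-values, plus the interaction p-value testing whether the slopes
    differ between groups. Complete cases only.
    """
    cfg = cfg or BootstrapConfig()
    pa = np.asarray(pa, dtype=float)
    sf = np.asarray(sf36, dtype=float)
    mask, _ = _listwise({"pa": pa, "sf36": sf, "group": np.asarray(group), "sex": np.asarray(sex)}, None)
    pa, sf = pa[mask], sf[mask]
    g_ind, index_name, ref_name = _group_indicator(np.asarray(group)[mask], index_group)
    sex_ind = _encode_binary(np.asarray(sex)[mask], "sex")
    n = pa.size
    X = np.column_stack([np.ones(n), sf, g_ind, sex_ind, sf * g_ind])
    _check_full_rank(X, ["intercept", "sf36", "group", "sex", "sf36:group"])

    def stat_idx(idx):
        b = _ols_coefs(X[idx], pa[idx])
        # (reference slope, index-group slope, interaction)
        return np.array([b[1], b[1] + b[4], b[4]])

    strata = g_ind if cfg.stratify_by_group else None
    dist = _bootstrap_distribution(stat_idx, n, cfg, strata)
    slopes: dict[str, tuple[float, float, float, float]] = {}
    for comp, gname in ((0, ref_name), (1, index_name)):
        lo, hi = _interval_from_dist(dist, alpha, component=comp)
        est = float(dist.est[comp])
        lo, hi = min(lo, est), max(hi, est)
        slopes[gname] = (est, lo, hi, _p_from_dist(dist, cfg.alpha_grid, component=comp))
    return AssociationResult(
        pa_category=pa_name,
        sf36_measure=sf36_name,
        slopes=slopes,
        interaction_p=_p_from_dist(dist, cfg.alpha_grid, component=2),
        n_per_group={index_name: int(g_ind.sum()), ref_name: int(n - g_ind.sum())},
        B=cfg.B,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# Classical tests and descriptives
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined: zero variance in ranks")
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    p_value: float
    prop1_pct: float
    prop2_pct: float


def proportion_test(k1: int, n1: int, k2: int, n2: int, correction: bool = False) -> ProportionTestResult:
    """Pearson chi-square test of two proportions (2x2 table).

    No continuity correction by default. Proportions are reported as
    percentages to one decimal. Raises on a zero table margin.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero table margin")
    res = sps.chi2_contingency(table, correction=correction)
    return ProportionTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        prop1_pct=percent(k1, n1),
        prop2_pct=percent(k2, n2),
    )


def percent(k: float, n: float, decimals: int = 1) -> float:
    """Percentage k/n rounded to the given number of decimals."""
    return round(100.0 * k / n, decimals)


def ponderal_index(weight_g: float, length_cm: float) -> float:
    """Ponderal index 100 x weight(g) / length(cm)^3, in g/cm^3."""
    return 100.0 * weight_g / length_cm**3


def mdes_power(n1: int, n2: int, alpha: float = 0.05, power: float = 0.80, method: str = "normal") -> float:
    """Minimum detectable standardized difference for a two-sample test.

    ``method="normal"`` uses the closed form
    ``(z_{1-alpha/2} + z_{power}) * sqrt(1/n1 + 1/n2)``;
    ``method="noncentral_t"`` solves the exact two-sample t power equation.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if method == "normal":
        return float((ndtri(1 - alpha / 2) + ndtri(power)) * math.sqrt(1.0 / n1 + 1.0 / n2))
    if method == "noncentral_t":
        from statsmodels.stats.power import TTestIndPower

        return float(
            TTestIndPower().solve_power(
                effect_size=None, nobs1=n1, ratio=n2 / n1, alpha=alpha, power=power
            )
        )
    raise ValueError(f"unknown method {method!r}")


def mannwhitney_permutation(
    x,
    y,
    n_perm: int = 100_000,
    exact_limit: int = 12,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test by permutation of the rank sum.

    Enumerates all group assignments exactly when the total sample size is
    at most ``exact_limit``; otherwise uses a seeded Monte-Carlo
    approximation with ``n_perm`` permutations (p includes the observed
    assignment). Returns ``(U statistic of x, p value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    obs_rs = ranks[:n1].sum()
    u_obs = obs_rs - n1 * (n1 + 1) / 2.0
    mean_rs = n1 * (n1 + n2 + 1) / 2.0
    obs_dev = abs(obs_rs - mean_rs)
    ntot = n1 + n2
    if ntot <= exact_limit:
        count = total = 0
        for comb in itertools.combinations(range(ntot), n1):
            rs = ranks[list(comb)].sum()
            total += 1
            if abs(rs - mean_rs) >= obs_dev - 1e-9:
                count += 1
        return float(u_obs), count / total
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 10_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, ntot)).argsort(axis=1)[:, :n1]
        rs = ranks[u].sum(axis=1)
        count += int(np.sum(np.abs(rs - mean_rs) >= obs_dev - 1e-9))
        done += m
    return float(u_obs), (count + 1) / (n_perm + 1)


def descriptive_table(
    data: pd.DataFrame,
    var_types: dict[str, str],
    group_col: str = "group",
    index_group: str | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group descriptives with between-group tests.

    ``var_types`` maps variable name to ``continuous`` (mean/SD, Student's
    t-test), ``ordinal`` (mean/SD, permutation Mann-Whitney — exact for
    tiny samples) or ``dichotomous`` (n/%, Pearson chi-square).
    """
    g_ind, index_name, ref_name = _group_indicator(data[group_col], index_group)
    rows = []
    for var, vtype in var_types.items():
        s = pd.to_numeric(data[var], errors="coerce")
        a = s[g_ind == 1].dropna().to_numpy()
        b = s[g_ind == 0].dropna().to_numpy()
        row: dict = {"variable": var, "type": vtype, f"n_{index_name}": a.size, f"n_{ref_name}": b.size}
        if vtype == "continuous":
            row.update(
                {
                    f"mean_{index_name}": a.mean(),
                    f"sd_{index_name}": a.std(ddof=1),
                    f"mean_{ref_name}": b.mean(),
                    f"sd_{ref_name}": b.std(ddof=1),
                    "p_value": float(sps.ttest_ind(a, b, equal_var=True).pvalue),
                }
            )
        elif vtype == "ordinal":
            _, p = mannwhitney_permutation(a, b, n_perm=n_perm, seed=seed)
            row.update(
                {
                    f"mean_{index_name}": a.mean(),
                    f"sd_{index_name}": a.std(ddof=1),
                    f"mean_{ref_name}": b.mean(),
                    f"sd_{ref_name}": b.std(ddof=1),
                    "p_value": p,
                }
            )
        elif vtype == "dichotomous":
            k1, k2 = int(a.sum()), int(b.sum())
            res = proportion_test(k1, a.size, k2, b.size)
            row.update(
                {
                    f"k_{index_name}": k1,
                    f"pct_{index_name}": res.prop1_pct,
                    f"k_{ref_name}": k2,
                    f"pct_{ref_name}": res.prop2_pct,
                    "p_value": res.p_value,
                }
            )
        else:
            raise ValueError(f"unknown variable type {vtype!r} for {var!r}")
        rows.append(row)
    return pd.DataFrame(rows)
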