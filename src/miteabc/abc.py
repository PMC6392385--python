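"""The ABC engine: reference table, rejection, scenario choice, parameter
posteriors, posterior-predictive model checking and time conversion.

The workflow mirrors DIYABC.  A reference table of (scenario, parameters,
summary statistics) rows is simulated from the priors; the rows closest to
the observed statistics (robustly standardized Euclidean distance) are
retained with Epanechnikov weights; scenario posterior probabilities come
from a weighted polychotomous logistic regression of the scenario indicator
on statistic deviations evaluated at the observed point; parameters of the
chosen scenario are estimated by weighted local-linear regression adjustment
on a logit scale bounded by the priors; model fit is checked by
posterior-predictive simulation with PCA and per-statistic tail
probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, softmax
from scipy.stats import gaussian_kde

from . import sumstats
from .coalsim import MutationModel, evolve_matrix, simulate_genealogy
from .scenarios import PARAM_NAMES, ParameterDraw, PriorSet, build_scenario, sample_prior

DEFAULT_SAMPLE_SIZES = {"LW": 10, "ML": 13, "HG": 18}
DEFAULT_LENGTH = 618

#: parameters reported per scenario (r only enters admixture scenarios;
#: t1 is unused by the simple-split scenario 9)
def scenario_parameters(scenario_id: int) -> tuple[str, ...]:
    base = ["N_LW", "N_ML", "N_HG"]
    if scenario_id == 9:
        return tuple(base + ["t2", "mu", "kappa"])
    if scenario_id in (7, 8):
        return tuple(base + ["t1", "t2", "r", "mu", "kappa"])
    return tuple(base + ["t1", "t2", "mu", "kappa"])


@dataclass
class SampleConfig:
    """Shape of the data every simulation must mimic."""

    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    length: int = DEFAULT_LENGTH
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    @property
    def group_indices(self) -> dict[str, np.ndarray]:
        idx, start = {}, 0
        for form in sumstats.FORM_ORDER:
            n = self.sample_sizes[form]
            idx[form] = np.arange(start, start + n)
            start += n
        return idx


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) rows for ABC."""

    scenario: np.ndarray  # (n,) int
    params: np.ndarray  # (n, 8) in PARAM_NAMES order
    stats: np.ndarray  # (n, 33) in sumstats.STAT_NAMES order
    priors: PriorSet
    sample_config: SampleConfig
    seed: int | None = None

    @property
    def n_rows(self) -> int:
        return len(self.scenario)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=list(sumstats.STAT_NAMES))
        for j, p in enumerate(PARAM_NAMES):
            df.insert(j, p, self.params[:, j])
        df.insert(0, "scenario", self.scenario)
        return df

    def write(self, path) -> None:
        """Delimited text with a header block recording priors and seed."""
        with open(path, "w") as fh:
            fh.write(f"# miteabc reference table; seed={self.seed}\n")
            for name in PARAM_NAMES:
                pr = self.priors[name]
                fh.write(f"# prior {name}: U({pr.low:g}, {pr.high:g}) [{pr.scale}]\n")
            ss = self.sample_config
            fh.write(f"# samples: {ss.sample_sizes}; length={ss.length}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path, priors: PriorSet | None = None,
             sample_config: SampleConfig | None = None) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            scenario=df["scenario"].to_numpy(),
            params=df[list(PARAM_NAMES)].to_numpy(),
            stats=df[list(sumstats.STAT_NAMES)].to_numpy(),
            priors=priors or PriorSet(),
            sample_config=sample_config or SampleConfig(),
            seed=None,
        )


def simulate_one(
    scenario_id: int,
    draw: ParameterDraw,
    cfg: SampleConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One (draw -> genealogy -> alignment -> statistics) row."""
    spec = build_scenario(scenario_id, draw)
    tree = simulate_genealogy(spec, cfg.sample_sizes, rng)
    model = MutationModel(mu=draw.mu, kappa=draw.kappa, freqs=cfg.freqs, length=cfg.length)
    m = evolve_matrix(tree, model, rng)
    return sumstats.summarize_matrix(m, cfg.group_indices)


def build_reference_table(
    scenario_ids,
    priors: PriorSet,
    n_per_scenario: int,
    sample_config: SampleConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows for each scenario (blocked by
    scenario, in the given id order); reproducible under ``seed``."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    cfg = sample_config or SampleConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    scenario_ids = list(scenario_ids)
    n_total = n_per_scenario * len(scenario_ids)
    scen = np.empty(n_total, dtype=np.int64)
    params = np.empty((n_total, len(PARAM_NAMES)))
    stats = np.empty((n_total, len(sumstats.STAT_NAMES)))
    row = 0
    for sid in scenario_ids:
        for _ in range(n_per_scenario):
            draw = sample_prior(priors, sid, rng)
            scen[row] = sid
            params[row] = draw.as_array()
            stats[row] = simulate_one(sid, draw, cfg, rng)
            row += 1
    return ReferenceTable(scen, params, stats, priors, cfg, seed)


@dataclass
class Retained:
    """Output of the rejection step: the closest reference rows."""

    indices: np.ndarray
    distances: np.ndarray
    weights: np.ndarray  # Epanechnikov kernel weights
    scenario: np.ndarray
    params: np.ndarray
    deviations: np.ndarray  # standardized (stats - observed)
    scale: np.ndarray
    center: np.ndarray
    tolerance: float


def _robust_scale(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = np.median(stats, axis=0)
    scale = np.median(np.abs(stats - center), axis=0)
    zero = scale == 0
    if zero.any():
        scale = scale.copy()
        scale[zero] = stats[:, zero].std(axis=0)
    return center, scale


def reject(table: ReferenceTable, observed: np.ndarray, tolerance: float = 0.01) -> Retained:
    """Retain the ``ceil(tolerance * n)`` reference rows closest to the
    observed statistics in robustly standardized Euclidean distance.

    Statistics are centred/scaled by the table's median and median absolute
    deviation (std fallback; constant columns are dropped from the
    distance).  Retained rows get Epanechnikov weights
    ``1 - (d / d_max)^2``.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    observed = np.asarray(observed, dtype=float)
    n_keep = math.ceil(tolerance * table.n_rows)
    n_scen = len(np.unique(table.scenario))
    if n_keep < n_scen:
        raise ValueError(
            f"tolerance {tolerance} retains {n_keep} rows < {n_scen} scenarios;"
            " increase tolerance or the table size"
        )
    center, scale = _robust_scale(table.stats)
    usable = scale > 0
    z = (table.stats[:, usable] - center[usable]) / scale[usable]
    z_obs = (observed[usable] - center[usable]) / scale[usable]
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    idx = np.argpartition(dist, n_keep - 1)[:n_keep]
    idx = idx[np.argsort(dist[idx], kind="stable")]
    d = dist[idx]
    dmax = d[-1]
    weights = np.ones_like(d) if dmax == 0 else 1.0 - (d / dmax) ** 2
    # the boundary row would get weight exactly 0; keep it infinitesimal
    weights = np.maximum(weights, 1e-12)
    dev = np.zeros((n_keep, table.stats.shape[1]))
    dev[:, usable] = z[idx] - z_obs
    return Retained(
        indices=idx,
        distances=d,
        weights=weights,
        scenario=table.scenario[idx],
        params=table.params[idx],
        deviations=dev,
        scale=scale,
        center=center,
        tolerance=tolerance,
    )


@dataclass
class ModelChoiceResult:
    """Scenario posterior probabilities with delta-method 95% CIs."""

    table: pd.DataFrame  # index scenario; columns prob, lower, upper
    n_retained: int
    tolerance: float
    ridge: float

    @property
    def best_scenario(self) -> int:
        return int(self.table["prob"].idxmax())


def _multinomial_nll(beta, X, y_codes, w, K, ridge):
    d = X.shape[1]
    B = beta.reshape(K - 1, d)
    eta = np.zeros((X.shape[0], K))
    eta[:, 1:] = X @ B.T
    eta -= eta.max(axis=1, keepdims=True)
    logz = np.log(np.exp(eta).sum(axis=1))
    nll = -(w * (eta[np.arange(len(y_codes)), y_codes] - logz)).sum()
    P = np.exp(eta - logz[:, None])
    G = np.zeros((K - 1, d))
    for k in range(1, K):
        G[k - 1] = ((w * (P[:, k] - (y_codes == k))) @ X)
    # ridge on slopes only (not intercepts)
    nll += 0.5 * ridge * (B[:, 1:] ** 2).sum()
    G[:, 1:] += ridge * B[:, 1:]
    return nll, G.ravel()


def _multinomial_hessian(beta, X, w, K, ridge):
    n, d = X.shape
    B = beta.reshape(K - 1, d)
    eta = np.zeros((n, K))
    eta[:, 1:] = X @ B.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    H = np.zeros((K - 1, d, K - 1, d))
    for k in range(1, K):
        for l in range(k, K):
            coef = w * P[:, k] * ((k == l) - P[:, l])
            block = X.T @ (coef[:, None] * X)
            H[k - 1, :, l - 1, :] = block
            H[l - 1, :, k - 1, :] = block
    H = H.reshape((K - 1) * d, (K - 1) * d)
    ridge_diag = np.tile(np.r_[0.0, np.full(d - 1, ridge)], K - 1)
    return H + np.diag(ridge_diag)


def choose_model(retained: Retained, ridge: float = 1e-3) -> ModelChoiceResult:
    """Weighted polychotomous logistic regression of the scenario indicator
    on standardized statistic deviations; posterior probabilities are the
    fitted category probabilities at the observed point (zero deviation).

    A small ridge penalty on the slope coefficients stabilises separation
    and collinearity; 95% CIs come from the asymptotic covariance of the
    coefficients via the delta method.
    """
    scen_ids = np.unique(retained.scenario)
    K = len(scen_ids)
    if K < 2:
        raise ValueError("model choice requires retained rows from >= 2 scenarios")
    y = np.searchsorted(scen_ids, retained.scenario)
    keep = retained.deviations.std(axis=0) > 0
    X = np.column_stack([np.ones(len(y)), retained.deviations[:, keep]])
    w = retained.weights * (len(y) / retained.weights.sum())
    d = X.shape[1]
    x0 = np.zeros((K - 1) * d)
    ridge_eff = ridge * len(y)
    res = minimize(
        _multinomial_nll, x0, args=(X, y, w, K, ridge_eff), jac=True,
        method="L-BFGS-B", options={"maxiter": 500},
    )
    # separation (or non-convergence) shows up as runaway slopes; refit with
    # a stronger ridge so probabilities stay finite and calibrated
    slopes = res.x.reshape(K - 1, d)[:, 1:]
    if not res.success or np.abs(slopes).max() > 10.0:
        ridge_eff *= 100
        res = minimize(
            _multinomial_nll, x0, args=(X, y, w, K, ridge_eff), jac=True,
            method="L-BFGS-B", options={"maxiter": 1000},
        )
    B = res.x.reshape(K - 1, d)
    eta0 = np.r_[0.0, B[:, 0]]
    probs = softmax(eta0)
    H = _multinomial_hessian(res.x, X, w, K, ridge_eff)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    # delta method: p depends on the K-1 intercepts only
    intercept_pos = np.arange(0, (K - 1) * d, d)
    icov = cov[np.ix_(intercept_pos, intercept_pos)]
    lower = np.empty(K)
    upper = np.empty(K)
    for k in range(K):
        grad = probs[k] * ((np.arange(1, K) == k) - probs[1:])  # d p_k / d intercept_j
        var = float(grad @ icov @ grad)
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
        lower[k] = max(probs[k] - half, 0.0)
        upper[k] = min(probs[k] + half, 1.0)
    out = pd.DataFrame(
        {"prob": probs, "lower": lower, "upper": upper},
        index=pd.Index(scen_ids, name="scenario"),
    )
    return ModelChoiceResult(out, n_retained=len(y), tolerance=retained.tolerance,
                             ridge=ridge_eff)


@dataclass
class ParameterPosterior:
    """Regression-adjusted posterior summaries, one row per parameter."""

    table: pd.DataFrame  # columns mean, median, mode, q2.5, q5, q95, q97.5
    samples: pd.DataFrame  # adjusted posterior draws per parameter
    weights: np.ndarray
    scenario_id: int
    adjusted: bool


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return np.interp(np.atleast_1d(q), cum, xs)


def _weighted_mode(x: np.ndarray, w: np.ndarray, low: float, high: float) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman", weights=w)
    grid = np.linspace(max(low, x.min()), min(high, x.max()), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_parameters(
    retained: Retained,
    scenario_id: int,
    priors: PriorSet,
    min_rows: int = 50,
) -> ParameterPosterior:
    """Local-linear regression adjustment of the retained draws of one
    scenario, on a logit scale bounded by each parameter's prior.

    Each parameter is transformed by ``logit((x - a) / (b - a))``, regressed
    (weighted) on the standardized statistic deviations, shifted to zero
    deviation and back-transformed.  Mean, median, mode (Gaussian KDE,
    Silverman bandwidth, 512-point grid) and the 2.5/5/95/97.5% weighted
    quantiles are reported.
    """
    mask = retained.scenario == scenario_id
    if mask.sum() < min_rows:
        raise ValueError(
            f"only {int(mask.sum())} retained rows for scenario {scenario_id};"
            f" need >= {min_rows}"
        )
    names = scenario_parameters(scenario_id)
    cols = [PARAM_NAMES.index(p) for p in names]
    theta = retained.params[mask][:, cols]
    w = retained.weights[mask]
    dev = retained.deviations[mask]
    keep = dev.std(axis=0) > 0
    X = np.column_stack([np.ones(mask.sum()), dev[:, keep]])

    bounds = np.array([[priors[p].low, priors[p].high] for p in names])
    a, b = bounds[:, 0], bounds[:, 1]
    frac = (theta - a) / (b - a)
    eps = 1e-10
    frac = np.clip(frac, eps, 1 - eps)
    z = np.log(frac / (1 - frac))

    adjusted = True
    if w.sum() <= 0 or np.allclose(dev[:, keep], 0):
        warnings.warn("degenerate retained set; reporting unadjusted quantiles")
        z_star = z
        adjusted = False
    else:
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw[:, None], rcond=None)
        z_star = z - X[:, 1:] @ beta[1:]
    theta_star = a + (b - a) * expit(z_star)

    rows = []
    for j, p in enumerate(names):
        x = theta_star[:, j]
        q = _weighted_quantile(x, w, [0.025, 0.05, 0.5, 0.95, 0.975])
        rows.append(
            {
                "parameter": p,
                "mean": float(np.average(x, weights=w)),
                "median": float(q[2]),
                "mode": _weighted_mode(x, w, a[j], b[j]),
                "q2.5": float(q[0]),
                "q5": float(q[1]),
                "q95": float(q[3]),
                "q97.5": float(q[4]),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    samples = pd.DataFrame(theta_star, columns=list(names))
    return ParameterPosterior(table, samples, w, scenario_id, adjusted)


@dataclass
class ModelCheckReport:
    """Posterior-predictive check of the chosen scenario."""

    stat_table: pd.DataFrame  # observed, simulated mean, tail prob, flag
    pc_scores: np.ndarray  # simulated datasets in PC space
    observed_score: np.ndarray
    observed_depth: float  # fraction of simulated points farther from the
    # cloud centre than the observed point

    @property
    def flagged(self) -> list[str]:
        return list(self.stat_table.index[self.stat_table["flagged"]])


def model_check(
    posterior: ParameterPosterior,
    observed: np.ndarray,
    n_sims: int = 500,
    sample_config: SampleConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_components: int = 2,
) -> ModelCheckReport:
    """Simulate statistics from posterior parameter draws, compare with the
    observed vector via PCA and two-sided tail probabilities, and flag
    statistics with tail probability < 0.05."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(posterior.samples) == 0:
        raise ValueError("empty posterior sample")
    cfg = sample_config or SampleConfig()
    sid = posterior.scenario_id
    names = list(posterior.samples.columns)
    p = posterior.weights / posterior.weights.sum()
    picks = rng.choice(len(posterior.samples), size=n_sims, replace=True, p=p)
    defaults = {"r": 0.5, "t1": 0.0}
    sims = np.empty((n_sims, len(sumstats.STAT_NAMES)))
    for i, pick in enumerate(picks):
        vals = {p_: defaults.get(p_, np.nan) for p_ in PARAM_NAMES}
        vals.update(posterior.samples.iloc[pick].to_dict())
        if np.isnan(vals["t1"]):
            vals["t1"] = 0.0
        # per-parameter regression adjustment can break the t1 < t2 ordering;
        # such draws are invalid under the scenario and are nudged back
        if sid != 9 and vals["t1"] >= vals["t2"]:
            vals["t1"] = 0.999 * vals["t2"]
        draw = ParameterDraw(sid, vals)
        sims[i] = simulate_one(sid, draw, cfg, rng)

    observed = np.asarray(observed, dtype=float)
    mean = sims.mean(axis=0)
    std = sims.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    zs = (sims - mean) / std_safe
    z_obs = (observed - mean) / std_safe

    from sklearn.decomposition import PCA

    pca = PCA(n_components=min(n_components, zs.shape[1]))
    scores = pca.fit_transform(zs)
    obs_score = pca.transform(z_obs[None, :])[0]
    centre_dist = np.linalg.norm(scores, axis=1)
    depth = float((centre_dist >= np.linalg.norm(obs_score)).mean())

    lo = (sims <= observed[None, :]).mean(axis=0)
    hi = (sims >= observed[None, :]).mean(axis=0)
    tail = 2.0 * np.minimum(lo, hi)
    tail = np.minimum(tail, 1.0)
    stat_table = pd.DataFrame(
        {
            "observed": observed,
            "sim_mean": mean,
            "sim_sd": std,
            "tail_prob": tail,
            "flagged": tail < 0.05,
        },
        index=pd.Index(sumstats.STAT_NAMES, name="statistic"),
    )
    return ModelCheckReport(stat_table, scores, obs_score, depth)


def generations_to_years(generations: float, generations_per_year: float) -> int:
    """Convert a generation count to calendar years, rounding half-up.

    The mite completes an estimated 8 (minimum) to 16 (maximum) generations
    per year, so e.g. 87,900 generations spans 5,494-10,988 years.
    """
    if generations < 0:
        raise ValueError("generations must be nonnegative")
    if generations_per_year <= 0:
        raise ValueError("generations_per_year must be positive")
    return int(math.floor(generations / generations_per_year + 0.5))
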