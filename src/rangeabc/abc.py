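"""Approximate Bayesian computation: model choice and parameter estimation.

Model choice follows the classic rejection + multinomial-logistic-
regression recipe: summaries are standardized with reference-table column
means/SDs, the ``tolerance`` fraction of simulations closest (Euclidean
distance) to the observed vector is retained, and a distance-weighted
(Epanechnikov kernel) multinomial logistic regression of the model label
on the summaries is evaluated at the observed point.  Uncertainty from the
choice of loci is propagated by recomputing the observed vector over
bootstrap resamples of loci and reporting order-statistic medians and 95%
intervals of the per-model posterior probabilities.

Parameter estimation Box-Cox transforms each summary, projects onto
partial-least-squares components fitted against the parameters, runs
rejection in component space, and applies a weighted local-linear
regression adjustment, truncating adjusted draws to the prior support.
Posterior modes come from a Gaussian KDE (Silverman bandwidth, 512-point
grid); intervals are highest-posterior-density (shortest) intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .sumstats import SUMMARY_NAMES

# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summaries) rows — the ABC exchange
    table.  ``df`` columns: sim_id, model, <parameter columns>, <39 summary
    columns>."""

    df: pd.DataFrame
    param_names: list[str]

    def __post_init__(self):
        missing = [c for c in SUMMARY_NAMES if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table lacks summary columns: {missing[:3]}...")

    @property
    def summaries(self) -> pd.DataFrame:
        return self.df[list(SUMMARY_NAMES)]

    @property
    def models(self) -> pd.Series:
        return self.df["model"]

    def restrict(self, model: str) -> "ReferenceTable":
        return ReferenceTable(self.df[self.df["model"] == model].reset_index(drop=True), self.param_names)

    def drop_rows(self, idx) -> "ReferenceTable":
        return ReferenceTable(self.df.drop(index=idx).reset_index(drop=True), self.param_names)

    def counts(self) -> pd.Series:
        return self.df["model"].value_counts()

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, param_names) -> "ReferenceTable":
        # round_trip parsing: resumed tables must re-serialize bit-exact
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(df, list(param_names))


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


def rejection(summaries: pd.DataFrame, observed: pd.Series, tolerance: float):
    """Retain the ``ceil(tolerance * n)`` simulations closest to the
    observed summary vector.

    Standardization uses the full table's column means/SDs; zero-variance
    columns are dropped from the distance with a warning.  Ties are broken
    by row order.  Returns ``(indices, distances)`` sorted by distance.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    X = summaries.to_numpy(dtype=float)
    obs = observed.reindex(summaries.columns).to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance summary column(s) from the distance"
        )
    d = np.sqrt((((X[:, keep] - mu[keep]) / sd[keep] - (obs[keep] - mu[keep]) / sd[keep]) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(d)))
    order = np.argsort(d, kind="stable")[:n_keep]
    return order, d[order]


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    """1 - (d/d_max)^2, strictly positive (the boundary point gets a small
    positive weight so every retained row contributes)."""
    d = np.asarray(distances, dtype=float)
    dmax = d.max() * (1.0 + 1e-9) if d.max() > 0 else 1.0
    w = 1.0 - (d / dmax) ** 2
    return np.maximum(w, 1e-12)


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    """Per-replicate model posterior probabilities plus bootstrap
    aggregates (order-statistic median and central 95% interval)."""

    probabilities: pd.DataFrame  # one row per observed replicate
    separation_flagged: bool = False

    @property
    def models(self) -> list[str]:
        return list(self.probabilities.columns)

    def aggregate(self) -> pd.DataFrame:
        q = self.probabilities.quantile([0.5, 0.025, 0.975])
        q.index = ["median", "lo95", "hi95"]
        return q.T


def mlr_model_posterior(
    retained: pd.DataFrame,
    models: pd.Series,
    distances: np.ndarray,
    observed: pd.Series,
    c_scale: float = 3.0,
) -> pd.Series:
    """Distance-weighted multinomial logistic regression of model labels on
    summaries within the retained set, evaluated at the observed vector.

    Returns a probability simplex over the model labels.  An L2 penalty
    scaled to the retained count (``C = c_scale / n``) keeps the fit
    defined under complete separation and near-uniform when the summaries
    carry no model information; ``c_scale`` is a config switch.
    """
    labels = sorted(models.unique())
    if len(labels) == 1:
        warnings.warn("only one model among retained simulations; returning probability 1")
        return pd.Series([1.0], index=labels)
    X = retained.to_numpy(dtype=float)
    obs = observed.reindex(retained.columns).to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    obs_s = (obs[keep] - mu[keep]) / sd[keep]
    w = epanechnikov_weights(distances)
    clf = LogisticRegression(C=c_scale / len(Xs), max_iter=2000)
    clf.fit(Xs, models.to_numpy(), sample_weight=w)
    p = clf.predict_proba(obs_s[None, :])[0]
    out = pd.Series(0.0, index=labels)
    out[list(clf.classes_)] = p
    return out / out.sum()


def model_choice(
    table: ReferenceTable,
    observed_vectors,
    tolerance: float,
    c_scale: float = 3.0,
) -> ModelChoiceResult:
    """Full model-choice loop over one or many observed summary vectors.

    ``c_scale`` tunes the regression penalty (see
    :func:`mlr_model_posterior`); small reference tables need larger
    values to produce confident assignments.
    """
    if isinstance(observed_vectors, pd.Series):
        observed_vectors = [observed_vectors]
    rows = []
    labels = sorted(table.models.unique())
    for obs in observed_vectors:
        idx, dist = rejection(table.summaries, obs, tolerance)
        probs = mlr_model_posterior(
            table.summaries.iloc[idx], table.models.iloc[idx], dist, obs, c_scale=c_scale
        )
        rows.append(probs.reindex(labels, fill_value=0.0))
    return ModelChoiceResult(pd.DataFrame(rows).reset_index(drop=True))


# ---------------------------------------------------------------------------
# locus bootstrap of the observed data
# ---------------------------------------------------------------------------


def bootstrap_observed(
    dataset,
    landscape=None,
    distances=None,
    loci_per_replicate: int = 50,
    n_replicates: int = 1000,
    seed=0,
) -> list[pd.Series]:
    """Summary vectors of bootstrap panels: each replicate draws
    ``loci_per_replicate`` distinct loci without replacement and recomputes
    the full 39-statistic vector.  Deterministic given the seed."""
    from .sumstats import summarize
    from .landscape import least_cost_distance

    if dataset.n_loci < loci_per_replicate:
        raise ValueError(
            f"dataset has {dataset.n_loci} loci; cannot resample {loci_per_replicate}"
        )
    rng = np.random.default_rng(seed)
    if distances is None:
        distances = {
            r: least_cost_distance(landscape, routing=r)
            for r in ("levant_only", "levant_horn_gibraltar")
        }
    out = []
    for _ in range(n_replicates):
        loci = rng.choice(dataset.n_loci, size=loci_per_replicate, replace=False)
        out.append(summarize(dataset.subset_loci(np.sort(loci)), distances=distances))
    return out


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


def _boxcox_fit(x: np.ndarray):
    """Shift-and-Box-Cox a column; returns (shifted+transformed, shift, lam)."""
    shift = 0.0
    xmin = x.min()
    if xmin <= 0:
        span = x.max() - xmin
        shift = -xmin + max(1e-3 * span, 1e-9)
    y = x + shift
    lam = stats.boxcox_normmax(y, method="mle", brack=(-2.0, 2.0))
    lam = float(np.clip(lam, -2.0, 2.0))
    return stats.boxcox(y, lmbda=lam), shift, lam


def _boxcox_apply(x, shift, lam):
    y = np.maximum(x + shift, 1e-12)
    return stats.boxcox(y, lmbda=lam)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return float(np.interp(q, cw, x))


def _hpdi(x, w, mass=0.95):
    """Shortest interval containing the given weighted mass."""
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cw /= cw[-1]
    n = len(x)
    best = (x[0], x[-1])
    width = x[-1] - x[0]
    for i in range(n):
        target = cw[i] + mass
        if target > 1.0:
            break
        j = int(np.searchsorted(cw, target))
        j = min(j, n)
        if x[j - 1] - x[i] < width:
            width = x[j - 1] - x[i]
            best = (x[i], x[j - 1])
    return best


@dataclass
class PosteriorResult:
    """Adjusted ABC posterior for one model's parameters."""

    samples: pd.DataFrame          # adjusted posterior draws
    weights: np.ndarray
    stats: pd.DataFrame            # mode/mean/median/hpdi_lo/hpdi_hi per parameter
    rmse_curve: np.ndarray
    n_components: int
    boxcox: dict = field(default_factory=dict)
    truncated_fraction: float = 0.0

    def hpdi(self, param: str) -> tuple[float, float]:
        row = self.stats.loc[param]
        return (row["hpdi_lo"], row["hpdi_hi"])


def estimate_parameters(
    table: ReferenceTable,
    observed: pd.Series,
    tolerance: float,
    n_pls: int = 12,
    prior_bounds: dict[str, tuple[float, float]] | None = None,
    param_names: list[str] | None = None,
) -> PosteriorResult:
    """ABC parameter estimation: Box-Cox + PLS + rejection + local-linear
    adjustment.  ``table`` should be restricted to a single model."""
    params = param_names or table.param_names
    theta = table.df[params].to_numpy(dtype=float)
    n = len(theta)
    if int(np.ceil(tolerance * n)) < 50:
        raise ValueError("table too small: need ceil(tolerance*n) >= 50 retained rows")

    # --- Box-Cox transform summaries (columns with spread only) ---
    S = table.summaries.to_numpy(dtype=float)
    obs = observed.reindex(list(SUMMARY_NAMES)).to_numpy(dtype=float)
    cols, bc = [], {}
    Xt, obs_t = [], []
    for j, name in enumerate(SUMMARY_NAMES):
        x = S[:, j]
        if x.std() <= 0:
            continue
        y, shift, lam = _boxcox_fit(x)
        Xt.append(y)
        obs_t.append(_boxcox_apply(np.array([obs[j]]), shift, lam)[0])
        bc[name] = (shift, lam)
        cols.append(name)
    Xt = np.column_stack(Xt)
    obs_t = np.asarray(obs_t)
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    Xs = (Xt - mu) / sd
    obs_s = (obs_t - mu) / sd

    # --- PLS projection and RMSE curve ---
    n_comp = int(min(n_pls, Xs.shape[1], n - 1))
    th_mu, th_sd = theta.mean(axis=0), np.where(theta.std(axis=0) > 0, theta.std(axis=0), 1.0)
    th_s = (theta - th_mu) / th_sd
    rmse = []
    for k in range(1, n_comp + 1):
        pls_k = PLSRegression(n_components=k, scale=False)
        pls_k.fit(Xs, th_s)
        pred = pls_k.predict(Xs)
        rmse.append(float(np.sqrt(np.mean((pred - th_s) ** 2))))
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(Xs, th_s)
    scores = pls.transform(Xs)
    obs_score = pls.transform(obs_s[None, :])[0]

    # --- rejection in component space ---
    sc_sd = scores.std(axis=0)
    d = np.sqrt((((scores - obs_score) / sc_sd) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * n))
    idx = np.argsort(d, kind="stable")[:n_keep]
    w = epanechnikov_weights(d[idx])

    # --- weighted local-linear adjustment ---
    # regress on at most n_keep/5 leading components (more regressors than
    # that overfit the retained set), and use cross-fitted (out-of-fold)
    # residuals: in-sample residuals are variance-deflated by the hat
    # matrix and make the adjusted posterior artificially narrow
    n_adj = max(1, min(n_comp, n_keep // 5))
    Z = np.column_stack([np.ones(n_keep), scores[idx, :n_adj] - obs_score[:n_adj]])
    sw = np.sqrt(w)
    adj = np.empty((n_keep, theta.shape[1]))
    n_folds = 5
    fold = np.arange(n_keep) % n_folds
    for p in range(theta.shape[1]):
        y = theta[idx, p]
        beta, *_ = np.linalg.lstsq(Z * sw[:, None], y * sw, rcond=None)
        resid = np.empty(n_keep)
        for f in range(n_folds):
            tr = fold != f
            bf, *_ = np.linalg.lstsq(Z[tr] * sw[tr, None], y[tr] * sw[tr], rcond=None)
            resid[~tr] = y[~tr] - Z[~tr] @ bf
        adj[:, p] = beta[0] + resid

    trunc = 0
    if prior_bounds:
        for p, name in enumerate(params):
            if name in prior_bounds:
                lo, hi = prior_bounds[name]
                out_of = (adj[:, p] < lo) | (adj[:, p] > hi)
                trunc += int(out_of.sum())
                adj[:, p] = np.clip(adj[:, p], lo, hi)
    trunc_frac = trunc / adj.size

    # --- posterior summaries ---
    rows = {}
    for p, name in enumerate(params):
        x = adj[:, p]
        try:
            kde = stats.gaussian_kde(x, weights=w)
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        except np.linalg.LinAlgError:  # degenerate (e.g. fully truncated) sample
            mode = float(np.median(x))
        mean = float(np.average(x, weights=w))
        median = _weighted_quantile(x, w, 0.5)
        lo, hi = _hpdi(x, w, 0.95)
        rows[name] = dict(mode=mode, mean=mean, median=median, hpdi_lo=lo, hpdi_hi=hi)
    return PosteriorResult(
        samples=pd.DataFrame(adj, columns=params),
        weights=w,
        stats=pd.DataFrame(rows).T[["mode", "mean", "median", "hpdi_lo", "hpdi_hi"]],
        rmse_curve=np.asarray(rmse),
        n_components=n_comp,
        boxcox=bc,
        truncated_fraction=trunc_frac,
    )


# ---------------------------------------------------------------------------
# power study with pseudo-observed data sets
# ---------------------------------------------------------------------------


def power_study(
    table: ReferenceTable,
    n_pods: int,
    tolerance: float,
    thresholds=(0.50, 0.85),
    seed=0,
    c_scale: float = 3.0,
) -> dict[float, pd.DataFrame]:
    """Confusion matrices of the model-choice procedure.

    PODS are drawn from the reference simulations themselves and removed
    from the table when scoring themselves (leave-one-out).  For each
    assignment threshold, returns a DataFrame of assignment fractions
    (rows: true model; columns: assigned models plus 'unassigned')."""
    rng = np.random.default_rng(seed)
    labels = sorted(table.models.unique())
    results = {thr: pd.DataFrame(0.0, index=labels, columns=labels + ["unassigned"]) for thr in thresholds}
    for true_model in labels:
        rows = np.flatnonzero((table.models == true_model).to_numpy())
        chosen = rng.choice(rows, size=min(n_pods, len(rows)), replace=False)
        for row in chosen:
            obs = table.summaries.iloc[row]
            rest = table.drop_rows([row])
            idx, dist = rejection(rest.summaries, obs, tolerance)
            probs = mlr_model_posterior(
                rest.summaries.iloc[idx], rest.models.iloc[idx], dist, obs, c_scale=c_scale
            )
            best = probs.idxmax()
            for thr in thresholds:
                col = best if probs[best] > thr else "unassigned"
                results[thr].loc[true_model, col] += 1
        for thr in thresholds:
            results[thr].loc[true_model] /= len(chosen)
    return results


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def gof_2d_pvalue(bootstrap_vectors, query: tuple[float, float], pair: tuple[str, str]) -> float:
    """Highest-density-region tail probability of a 2D point against the
    bootstrap cloud of observed summary vectors.

    p = fraction of bootstrap points whose KDE density is below the
    density at the query; ~1 at the cloud centre, ~0 far outside."""
    pts = np.array([[v[pair[0]], v[pair[1]]] for v in bootstrap_vectors], dtype=float).T
    if pts.shape[1] < 100:
        raise ValueError("need at least 100 bootstrap vectors")
    if np.any(pts.std(axis=1) <= 0):
        raise ValueError(f"degenerate (zero-variance) pair {pair}")
    sd = pts.std(axis=1)
    kde = stats.gaussian_kde(pts / sd[:, None])
    dens_pts = kde(pts / sd[:, None])
    dens_q = kde((np.asarray(query) / sd)[:, None])[0]
    return float(np.mean(dens_pts < dens_q))


def posterior_predictive_pca(posterior_vectors, observed: pd.Series, n_pcs: int = 4):
    """Posterior predictive check in PCA space.

    Fits a PCA on the posterior replicate summary vectors, projects the
    observed vector, and for every PC pair returns the replicate scores,
    the observed point, HDR density thresholds for the 50/75/95% envelopes
    and the observed point's HDR p-value."""
    X = np.array([v.reindex(list(SUMMARY_NAMES)).to_numpy(dtype=float) for v in posterior_vectors])
    if len(X) <= n_pcs:
        raise ValueError("need more posterior replicates than PCA dimensions")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(Xs)
    obs_score = pca.transform(((observed.reindex(list(SUMMARY_NAMES)).to_numpy(dtype=float) - mu) / sd)[None, :])[0]
    out = {}
    for i, j in itertools.combinations(range(n_pcs), 2):
        pts = scores[:, [i, j]].T
        kde = stats.gaussian_kde(pts)
        dens = kde(pts)
        dens_obs = kde(np.asarray(obs_score[[i, j]])[:, None])[0]
        levels = {m: float(np.quantile(dens, 1.0 - m)) for m in (0.50, 0.75, 0.95)}
        out[(f"PC{i + 1}", f"PC{j + 1}")] = {
            "scores": scores[:, [i, j]],
            "observed": obs_score[[i, j]],
            "levels": levels,
            "p": float(np.mean(dens < dens_obs)),
            "explained_variance_ratio": pca.explained_variance_ratio_[[i, j]],
        }
    return out
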