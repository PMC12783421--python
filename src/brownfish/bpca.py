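"""Composite browning index via Bayesian probabilistic PCA.

Three browning metrics — DOC concentration (mg l-1), Secchi transparency
(m) and water colour (mg Pt l-1) — measure one underlying optical
gradient.  After per-metric Box-Cox transformation and standardization,
a probabilistic PCA with an automatic-relevance (ARD) shrinkage prior on
the component vectors is fitted by expectation-maximization.  The EM
E-step doubles as an imputation step for missing metric values, so lakes
with partial records are retained rather than dropped.  The first
component score (BPC1) is the composite browning index, oriented so that
larger scores mean browner water (positive correlation with transformed
DOC).

The fitter is the probabilistic-PCA EM for incomplete data with
hierarchical shrinkage of component vectors: irrelevant components are
automatically suppressed, so extracting a single component is
well-defined even though the data are three-dimensional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transform import TransformSpec, apply_boxcox, invert_boxcox, select_boxcox_lambda

METRICS = ("doc", "secchi", "colour")


# --------------------------------------------------------------------------
# EM fitter
# --------------------------------------------------------------------------

@dataclass
class BPCAResults:
    """Output of the EM fit on a standardized (possibly incomplete) matrix."""

    scores: np.ndarray            # (n, q) posterior-mean latent scores
    loadings: np.ndarray          # (d, q) principal-axis loadings
    sigma2: float                 # residual noise variance
    alpha: np.ndarray             # ARD precisions, one per component
    variance_explained: np.ndarray  # fraction per component (model-based)
    imputed: np.ndarray           # (n, d) matrix with missing entries filled
    missing_mask: np.ndarray
    n_iter: int
    objective_trace: np.ndarray
    converged: bool


class BayesianPCA:
    """Probabilistic PCA with ARD shrinkage and EM imputation.

    Parameters
    ----------
    matrix : (n, d) array
        Column-standardized data; NaN marks missing entries.
    n_components : int
        Components to extract (<= d); default 1, the composite-index case.
    """

    def __init__(self, matrix: np.ndarray, n_components: int = 1):
        Y = np.asarray(matrix, dtype=float)
        if Y.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, d = Y.shape
        if not 1 <= n_components <= d:
            raise ValueError("n_components must be in 1..n_cols")
        obs = np.isfinite(Y)
        if np.any(obs.sum(axis=0) == 0):
            raise ValueError("a column is entirely missing")
        if np.any(obs.sum(axis=1) == 0):
            raise ValueError("a row has no observed entries")
        self.Y = Y
        self.obs = obs
        self.q = n_components

    def _objective(self, W, mu, s2, alpha) -> float:
        """Penalized observed-data log-likelihood (per-pattern Gaussian
        marginal plus the ARD prior and its normalizer)."""
        n, d = self.Y.shape
        ll = 0.0
        patterns = {}
        for i in range(n):
            patterns.setdefault(self.obs[i].tobytes(), []).append(i)
        for key, idx in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            k = int(o.sum())
            C = W[o] @ W[o].T + s2 * np.eye(k)
            sign, logdet = np.linalg.slogdet(C)
            Ci = np.linalg.inv(C)
            R = self.Y[np.ix_(idx, o)] - mu[o]
            ll += -0.5 * (len(idx) * (k * np.log(2 * np.pi) + logdet)
                          + np.einsum("ij,jk,ik->", R, Ci, R))
        pen = 0.5 * d * np.sum(np.log(alpha)) - 0.5 * np.sum(
            alpha * (W ** 2).sum(axis=0))
        return ll + pen

    def fit(self, tol: float = 1e-6, max_iter: int = 2000,
            debug_monotone: bool = False, seed: int = 0) -> BPCAResults:
        """Run EM to convergence (relative objective change < ``tol``).

        Raises ``RuntimeError`` with the objective trace if ``max_iter`` is
        reached first.  With ``debug_monotone`` the objective is asserted
        non-decreasing (to numerical tolerance) at every iteration.
        """
        Y, obs, q = self.Y, self.obs, self.q
        n, d = Y.shape
        rng = np.random.default_rng(seed)

        col_mean = np.array([Y[obs[:, j], j].mean() for j in range(d)])
        Yf = np.where(obs, Y, col_mean)          # initial fill
        mu = col_mean.copy()
        # initialize W from classical SVD of the filled matrix
        U, L, Vt = np.linalg.svd(Yf - mu, full_matrices=False)
        W = (Vt[:q].T * (L[:q] / np.sqrt(n))) + 1e-3 * rng.standard_normal((d, q))
        s2 = 0.5
        alpha = np.full(q, 1.0)

        trace = []
        Iq = np.eye(q)
        pattern_rows = {}
        for i in range(n):
            pattern_rows.setdefault(obs[i].tobytes(), []).append(i)

        X = np.zeros((n, q))
        converged = False
        for it in range(max_iter):
            # ---- E-step (grouped by missingness pattern)
            Sxx = np.zeros((q, q))          # sum <x x'>
            Syx = np.zeros((d, q))          # sum <y x'> (centred y)
            resid_obs = 0.0
            n_missing = 0
            cov_store = {}
            for key, idx in pattern_rows.items():
                o = np.frombuffer(key, dtype=bool)
                Wo = W[o]
                M = Wo.T @ Wo + s2 * Iq
                Minv = np.linalg.inv(M)
                Cx = s2 * Minv
                Rows = Y[np.ix_(idx, o)] - mu[o]
                Xp = Rows @ Wo @ Minv.T
                X[idx] = Xp
                cov_store[key] = Cx
                Sxx += len(idx) * Cx + Xp.T @ Xp
                # observed part of <y x'>
                Syx[o] += Rows.T @ Xp
                # missing part: <y_m x'> = W_m <xx'> (centred)
                m = ~o
                if m.any():
                    Wm = W[m]
                    Syx[m] += Wm @ (len(idx) * Cx + Xp.T @ Xp)
                    n_missing += len(idx) * int(m.sum())
                # fill imputations (current parameters)
                Yf[np.ix_(idx, m)] = Xp @ W[m].T + mu[m]
                # observed residual second moment
                E = Rows - Xp @ Wo.T
                resid_obs += (E ** 2).sum() + len(idx) * np.trace(Wo @ Cx @ Wo.T)

            # ---- M-step
            W_new = Syx @ np.linalg.inv(Sxx + s2 * np.diag(alpha))
            n_obs_entries = int(obs.sum())
            # noise variance from observed entries only (missing ones carry
            # no information about s2 beyond their prior contribution)
            Wo_term = 0.0
            for key, idx in pattern_rows.items():
                o = np.frombuffer(key, dtype=bool)
                Rows = Y[np.ix_(idx, o)] - mu[o]
                Xp = X[idx]
                E = Rows - Xp @ W_new[o].T
                Wo_term += (E ** 2).sum() + len(idx) * np.trace(
                    W_new[o] @ cov_store[key] @ W_new[o].T)
            s2 = max(Wo_term / n_obs_entries, 1e-12)
            W = W_new
            alpha = d / np.maximum((W ** 2).sum(axis=0), 1e-12)
            alpha = np.minimum(alpha, 1e12)

            objective = self._objective(W, mu, s2, alpha)
            trace.append(objective)
            if debug_monotone and len(trace) > 1:
                scale = max(1.0, abs(trace[-2]))
                assert objective >= trace[-2] - 1e-6 * scale, (
                    f"EM objective decreased at iter {it}")
            if len(trace) > 1:
                rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
                if rel < tol:
                    converged = True
                    break
        if not converged:
            raise RuntimeError(
                "BPCA EM did not converge within "
                f"{max_iter} iterations; objective trace tail: {trace[-5:]}")

        # principal-axis rotation: order components by singular value
        Us, Ls, Vts = np.linalg.svd(W, full_matrices=False)
        W_rot = Us * Ls
        X_rot = X @ Vts.T
        order = np.argsort(Ls)[::-1]
        W_rot = W_rot[:, order]
        X_rot = X_rot[:, order]
        Ls = Ls[order]

        total = float((Ls ** 2).sum() + d * s2)
        var_frac = (Ls ** 2 + s2) / total

        return BPCAResults(
            scores=X_rot, loadings=W_rot, sigma2=float(s2), alpha=alpha,
            variance_explained=var_frac, imputed=Yf, missing_mask=~obs,
            n_iter=len(trace), objective_trace=np.asarray(trace),
            converged=True,
        )


def fit_bpca(matrix: np.ndarray, n_components: int = 1, **kwargs) -> BPCAResults:
    """Functional wrapper around :class:`BayesianPCA`."""
    return BayesianPCA(matrix, n_components).fit(**kwargs)


def missingness_summary(lakes: pd.DataFrame) -> dict:
    """Per-metric missing-value counts and percentages (1 decimal, as
    reported for survey compilations), plus their mean."""
    n = len(lakes)
    counts = {m: int(lakes[m].isna().sum()) for m in METRICS}
    pcts = {m: round(100.0 * c / n, 1) for m, c in counts.items()}
    return {"n_lakes": n, "n_missing": counts, "pct_missing": pcts,
            "mean_pct_missing": round(float(np.mean(list(pcts.values()))), 1)}


# --------------------------------------------------------------------------
# the browning index
# --------------------------------------------------------------------------

@dataclass
class BrowningIndex:
    """Per-lake composite browning score with its supporting pieces."""

    lake_ids: list
    bpc1: np.ndarray
    loadings: np.ndarray                 # (3,) component-1 loadings
    variance_explained: float            # fraction for component 1
    correlations: dict                   # bpc1 vs each transformed metric
    transforms: dict[str, TransformSpec]
    column_means: np.ndarray             # of transformed metrics
    column_sds: np.ndarray
    imputed_values: pd.DataFrame         # filled entries, metric x lake
    fit: BPCAResults = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lake_id": self.lake_ids, "bpc1": self.bpc1})


def orient_scores(index: BrowningIndex, transformed_doc: np.ndarray) -> BrowningIndex:
    """Fix the arbitrary PCA sign so larger BPC1 means browner water.

    Flips scores and loadings when BPC1 correlates negatively with
    transformed DOC; idempotent.
    """
    td = np.asarray(transformed_doc, dtype=float)
    ok = np.isfinite(td) & np.isfinite(index.bpc1)
    s = index.bpc1[ok]
    if np.std(s) == 0:
        raise ValueError("zero-variance scores cannot be oriented")
    r = float(np.corrcoef(s, td[ok])[0, 1])
    if r < 0:
        index.bpc1 = -index.bpc1
        index.loadings = -index.loadings
        index.correlations = {k: -v for k, v in index.correlations.items()}
    return index


def fit_browning_index(lakes: pd.DataFrame, n_components: int = 1,
                       lambda_grid: np.ndarray | None = None,
                       tol: float = 1e-6, max_iter: int = 2000) -> BrowningIndex:
    """Full index pipeline: Box-Cox -> standardize -> BPCA -> orient.

    ``lakes`` must carry columns ``lake_id, doc, secchi, colour`` with NaN
    (or empty cells) marking missing metrics.  Lakes with no observed
    metric at all are rejected.
    """
    missing_cols = [m for m in METRICS if m not in lakes.columns]
    if missing_cols:
        raise ValueError(f"lakes table lacks columns {missing_cols}")
    raw = lakes[list(METRICS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(raw).any(axis=1)):
        raise ValueError("every retained lake needs at least one observed metric")

    transforms: dict[str, TransformSpec] = {}
    T = np.full_like(raw, np.nan)
    for k, m in enumerate(METRICS):
        vals = raw[:, k]
        spec = select_boxcox_lambda(vals[np.isfinite(vals)], grid=lambda_grid, metric=m)
        transforms[m] = spec
        T[:, k] = apply_boxcox(vals, spec)

    obs = np.isfinite(T)
    means = np.array([T[obs[:, k], k].mean() for k in range(3)])
    sds = np.array([T[obs[:, k], k].std(ddof=0) for k in range(3)])
    Z = (T - means) / sds

    res = BayesianPCA(Z, n_components=n_components).fit(tol=tol, max_iter=max_iter)
    scores = res.scores[:, 0]
    loadings = res.loadings[:, 0]

    corr = {}
    for k, m in enumerate(METRICS):
        ok = obs[:, k]
        corr[m] = float(np.corrcoef(scores[ok], Z[ok, k])[0, 1])

    imput_rows = []
    lake_ids = list(lakes["lake_id"]) if "lake_id" in lakes.columns else list(lakes.index)
    for i, j in zip(*np.nonzero(res.missing_mask)):
        imput_rows.append({
            "lake_id": lake_ids[i], "metric": METRICS[j],
            "transformed": res.imputed[i, j] * sds[j] + means[j],
            "raw": float(invert_boxcox(res.imputed[i, j] * sds[j] + means[j],
                                       transforms[METRICS[j]])),
        })
    imputed = pd.DataFrame(imput_rows,
                           columns=["lake_id", "metric", "transformed", "raw"])

    index = BrowningIndex(
        lake_ids=lake_ids, bpc1=scores, loadings=loadings,
        variance_explained=float(res.variance_explained[0]),
        correlations=corr, transforms=transforms,
        column_means=means, column_sds=sds, imputed_values=imputed, fit=res,
    )
    return orient_scores(index, T[:, 0])


def build_nomogram(index: BrowningIndex, grid_size: int = 101,
                   score_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Map BPC1 scores back to raw metric values (the index nomogram).

    For each grid score the predicted transformed metric is
    ``loading_k * score * col_sd + col_mean``, then inverse Box-Cox back to
    the measurement scale.  Each column is monotone in the score, in the
    direction of its loading sign.  Scores whose inverse transform leaves
    the Box-Cox domain are clipped to the nearest attainable value, with a
    warning.
    """
    if score_range is None:
        score_range = (float(index.bpc1.min()), float(index.bpc1.max()))
    grid = np.linspace(score_range[0], score_range[1], grid_size)
    out = {"bpc1": grid}
    clipped = False
    for k, m in enumerate(METRICS):
        t = index.loadings[k] * grid * index.column_sds[k] + index.column_means[k]
        raw = invert_boxcox(t, index.transforms[m])
        bad = ~np.isfinite(raw)
        if bad.any():
            clipped = True
            good = np.flatnonzero(~bad)
            raw[bad] = np.interp(np.flatnonzero(bad), good, raw[good])
        out[m] = raw
    if clipped:
        warnings.warn("some nomogram values fell outside the inverse-transform "
                      "domain and were clipped")
    return pd.DataFrame(out)
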