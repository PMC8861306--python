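"""Variational-Bayes inference for a group-level Gaussian hidden Markov model.

The observation model treats each hidden state as a multivariate normal
over the retained principal components (a mean activation vector plus a
full covariance). Inference is variational Bayes with conjugate priors:
symmetric Dirichlet (concentration 1) on the initial distribution and on
each transition row, and a Normal-Wishart prior on each state's mean and
precision. "Free energy" throughout is the negative evidence lower bound;
it is non-increasing across iterations and is recorded per iteration.

The model is estimated at the group level: the forward-backward recursions
run independently per subject (each subject's chain restarts from the
initial distribution; no transition is bridged across subject boundaries)
while the transition pseudo-counts are pooled across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .preprocessing import CohortPCA
from .temporal import fractional_occupancy

logger = logging.getLogger(__name__)

__all__ = [
    "VBGaussianHMM",
    "StatePosterior",
    "fit_hmm",
    "scan_states",
    "select_n_states",
    "hard_assign",
    "match_states",
    "state_maps",
]

LN2PI = np.log(2.0 * np.pi)


@dataclass
class StatePosterior:
    """Per-subject posterior state probabilities and hard paths."""

    probabilities: list[np.ndarray]  # each T x K, rows sum to 1
    paths: list[np.ndarray]  # each length T, ids in [0, K)


def _spans_from_lengths(n_rows: int, lengths) -> list[tuple[int, int]]:
    if lengths is None:
        return [(0, n_rows)]
    lengths = [int(t) for t in lengths]
    if sum(lengths) != n_rows or any(t < 1 for t in lengths):
        raise ValueError("lengths must be positive and sum to the number of rows")
    spans, start = [], 0
    for t in lengths:
        spans.append((start, start + t))
        start += t
    return spans


def _kl_dirichlet(a: np.ndarray, a0: np.ndarray) -> float:
    sa, sa0 = a.sum(), a0.sum()
    return float(
        gammaln(sa) - gammaln(sa0)
        - gammaln(a).sum() + gammaln(a0).sum()
        + ((a - a0) * (digamma(a) - digamma(sa))).sum()
    )


def _ln_wishart_b(ln_det_w: float, nu: float, d: int) -> float:
    i = np.arange(1, d + 1)
    return float(
        -0.5 * nu * ln_det_w
        - 0.5 * nu * d * np.log(2.0)
        - 0.25 * d * (d - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu + 1 - i)).sum()
    )


class _StateSuffStats:
    """Variational posterior over one run's parameters."""

    __slots__ = ("alpha_start", "alpha_trans", "beta", "m", "nu",
                 "chol_winv", "ln_det_w")

    def __init__(self, alpha_start, alpha_trans, beta, m, nu, chol_winv, ln_det_w):
        self.alpha_start = alpha_start
        self.alpha_trans = alpha_trans
        self.beta = beta
        self.m = m
        self.nu = nu
        self.chol_winv = chol_winv  # list of lower Cholesky factors of W^{-1}
        self.ln_det_w = ln_det_w  # list of ln|W|


class VBGaussianHMM(BaseEstimator):
    """K-state hidden Markov model with Gaussian emissions, fit by VB.

    Parameters
    ----------
    n_states : number of hidden states K.
    n_restarts : independent k-means-initialized runs; the run with the
        lowest final free energy wins.
    max_iter, tol : iteration cap and relative free-energy change below
        which a run is declared converged.
    alpha_prior : symmetric Dirichlet concentration for the initial
        distribution and each transition row.
    beta_prior : Normal-Wishart mean-precision scale (small = weak).
    reg_covar : diagonal jitter, relative to the mean eigenvalue, applied
        when a scale matrix turns numerically non-PD.
    kmeans_subsample : at most this many rows feed the k-means init.
    random_state : seed fanning out to every restart.

    Attributes (after ``fit``)
    --------------------------
    means_ : (K, D) posterior state means.
    covariances_ : (K, D, D) posterior expected state covariances.
    transmat_ : (K, K) posterior mean transition matrix (rows sum to 1).
    startprob_ : (K,) posterior mean initial distribution.
    free_energy_trace_ : per-iteration free energy of the winning restart.
    all_free_energy_traces_ : traces of every restart (for diagnostics).
    lower_bound_ : final evidence lower bound (= -free energy).
    """

    def __init__(self, n_states: int = 5, n_restarts: int = 5, max_iter: int = 500,
                 tol: float = 1e-6, alpha_prior: float = 1.0, beta_prior: float = 1e-2,
                 reg_covar: float = 1e-6, kmeans_subsample: int = 10000,
                 random_state: int | None = None):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.alpha_prior = alpha_prior
        self.beta_prior = beta_prior
        self.reg_covar = reg_covar
        self.kmeans_subsample = kmeans_subsample
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: np.ndarray, lengths=None) -> "VBGaussianHMM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-D array")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        spans = _spans_from_lengths(X.shape[0], lengths)
        self._init_priors(X)

        best = None
        traces: list[list[float]] = []
        errors: list[Exception] = []
        for r in range(self.n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence([0 if self.random_state is None else
                                        int(self.random_state) % (2**31), r])
            )
            try:
                params, trace, gamma = self._fit_once(X, spans, rng)
            except np.linalg.LinAlgError as exc:  # covariance collapse
                logger.warning("restart %d failed (%s); reseeding", r, exc)
                errors.append(exc)
                continue
            traces.append(trace)
            if best is None or trace[-1] < best[1][-1]:
                best = (params, trace, gamma, r)
        if best is None:
            raise RuntimeError(
                f"all {self.n_restarts} restarts failed; last error: {errors[-1]}"
            )
        params, trace, gamma, r = best
        self._params = params
        self._spans = spans
        self.free_energy_trace_ = np.array(trace)
        self.all_free_energy_traces_ = [np.array(t) for t in traces]
        self.lower_bound_ = -trace[-1]
        self.best_restart_ = r
        self.n_iter_ = len(trace)
        self._publish(params, X.shape[1])
        return self

    def _init_priors(self, X: np.ndarray) -> None:
        d = X.shape[1]
        var = np.maximum(X.var(axis=0), 1e-12)
        self._m0 = X.mean(axis=0)
        self._beta0 = float(self.beta_prior)
        self._nu0 = float(d + 2)
        # prior expected covariance matches the diagonal of the data covariance
        self._w0_inv_diag = self._nu0 * var
        self._ln_det_w0 = float(-np.log(self._w0_inv_diag).sum())
        self._alpha0 = float(self.alpha_prior)

    def _publish(self, p: _StateSuffStats, d: int) -> None:
        k = self.n_states
        self.means_ = p.m.copy()
        covs = np.empty((k, d, d))
        for j in range(k):
            l = p.chol_winv[j]
            winv = l @ l.T
            covs[j] = winv / (p.nu[j] - d - 1.0)
        self.covariances_ = covs
        self.transmat_ = p.alpha_trans / p.alpha_trans.sum(axis=1, keepdims=True)
        self.startprob_ = p.alpha_start / p.alpha_start.sum()

    # ------------------------------------------------------------- VB steps

    def _initial_responsibilities(self, X: np.ndarray, rng) -> np.ndarray:
        n, k = X.shape[0], self.n_states
        if n > self.kmeans_subsample:
            idx = rng.choice(n, size=self.kmeans_subsample, replace=False)
            sub = X[idx]
        else:
            sub = X
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31))).fit(sub)
        labels = km.predict(X)
        resp = np.full((n, k), 0.1 / k)
        resp[np.arange(n), labels] += 0.9
        return resp

    def _fit_once(self, X, spans, rng):
        resp = self._initial_responsibilities(X, rng)
        starts = np.array([a for a, _ in spans])
        inner_prev = np.concatenate([np.arange(a, b - 1) for a, b in spans])
        xi = resp[inner_prev].T @ resp[inner_prev + 1]
        start_sum = resp[starts].sum(axis=0)
        params = self._mstep(X, resp, xi, start_sum)
        trace: list[float] = []
        gamma = resp
        for it in range(self.max_iter):
            gamma, xi, start_sum, ln_z = self._estep(X, spans, params)
            f = -(ln_z - self._kl_total(params))
            trace.append(f)
            if it > 0 and abs(trace[-2] - f) <= self.tol * (abs(trace[-2]) + 1e-12):
                break
            params = self._mstep(X, gamma, xi, start_sum)
        return params, trace, gamma

    def _expected_log_emission(self, X: np.ndarray, p: _StateSuffStats) -> np.ndarray:
        n, d = X.shape
        out = np.empty((n, self.n_states))
        for k in range(self.n_states):
            nu, beta = p.nu[k], p.beta[k]
            eln_lam = (digamma(0.5 * (nu + 1 - np.arange(1, d + 1))).sum()
                       + d * np.log(2.0) + p.ln_det_w[k])
            diff = (X - p.m[k]).T  # D x N
            y = solve_triangular(p.chol_winv[k], diff, lower=True)
            quad = (y * y).sum(axis=0)
            out[:, k] = 0.5 * (eln_lam - d / beta - d * LN2PI) - 0.5 * nu * quad
        return out

    def _estep(self, X, spans, p: _StateSuffStats):
        log_b = self._expected_log_emission(X, p)
        ln_pi = digamma(p.alpha_start) - digamma(p.alpha_start.sum())
        ln_a = digamma(p.alpha_trans) - digamma(p.alpha_trans.sum(axis=1))[:, None]
        return _forward_backward(log_b, spans, np.exp(ln_pi), np.exp(ln_a))

    def _mstep(self, X, gamma, xi, start_sum) -> _StateSuffStats:
        n, d = X.shape
        k = self.n_states
        nk = gamma.sum(axis=0) + 1e-12
        xbar = (gamma.T @ X) / nk[:, None]
        beta = self._beta0 + nk
        nu = self._nu0 + nk
        m = (self._beta0 * self._m0[None, :] + nk[:, None] * xbar) / beta[:, None]
        chols, ln_det_w = [], []
        for j in range(k):
            diff = X - xbar[j]
            s = (gamma[:, j, None] * diff).T @ diff
            dm = xbar[j] - self._m0
            winv = (np.diag(self._w0_inv_diag) + s
                    + (self._beta0 * nk[j] / beta[j]) * np.outer(dm, dm))
            winv = 0.5 * (winv + winv.T)
            try:
                l = np.linalg.cholesky(winv)
            except np.linalg.LinAlgError:
                jitter = self.reg_covar * np.trace(winv) / d
                l = np.linalg.cholesky(winv + jitter * np.eye(d))
            chols.append(l)
            ln_det_w.append(float(-2.0 * np.log(np.diag(l)).sum()))
        return _StateSuffStats(
            alpha_start=self._alpha0 + start_sum,
            alpha_trans=self._alpha0 + xi,
            beta=beta, m=m, nu=nu, chol_winv=chols, ln_det_w=ln_det_w,
        )

    def _kl_total(self, p: _StateSuffStats) -> float:
        k = self.n_states
        d = p.m.shape[1]
        a0 = np.full(k, self._alpha0)
        kl = _kl_dirichlet(p.alpha_start, a0)
        for j in range(k):
            kl += _kl_dirichlet(p.alpha_trans[j], a0)
        ln_b0 = _ln_wishart_b(self._ln_det_w0, self._nu0, d)
        for j in range(k):
            nu, beta = p.nu[j], p.beta[j]
            l = p.chol_winv[j]
            eln_lam = (digamma(0.5 * (nu + 1 - np.arange(1, d + 1))).sum()
                       + d * np.log(2.0) + p.ln_det_w[j])
            # quadratic and trace terms under W = (L L^T)^{-1}
            y = solve_triangular(l, (p.m[j] - self._m0), lower=True)
            quad = float(y @ y)
            a = solve_triangular(l, np.eye(d), lower=True)
            diag_w = (a * a).sum(axis=0)
            tr_w0inv_w = float((self._w0_inv_diag * diag_w).sum())
            kl_n = 0.5 * (d * np.log(beta / self._beta0) + d * self._beta0 / beta
                          - d + self._beta0 * nu * quad)
            kl_w = (_ln_wishart_b(p.ln_det_w[j], nu, d) - ln_b0
                    + 0.5 * (nu - self._nu0) * eln_lam
                    - 0.5 * nu * d + 0.5 * nu * tr_w0inv_w)
            kl += kl_n + kl_w
        return kl

    # ------------------------------------------------------------ inference

    def predict_proba(self, X: np.ndarray, lengths=None) -> np.ndarray:
        """Posterior state probabilities (rows sum to 1)."""
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        spans = _spans_from_lengths(X.shape[0], lengths)
        gamma, _, _, _ = self._estep(X, spans, self._params)
        return gamma

    def predict(self, X: np.ndarray, lengths=None) -> np.ndarray:
        """Hard maximum-probability state path."""
        return hard_assign(self.predict_proba(X, lengths))

    def free_energy(self, X: np.ndarray, lengths=None) -> float:
        """Free energy (negative ELBO) of the fitted posterior on ``X``."""
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        spans = _spans_from_lengths(X.shape[0], lengths)
        _, _, _, ln_z = self._estep(X, spans, self._params)
        return -(ln_z - self._kl_total(self._params))

    def permute_states(self, perm) -> "VBGaussianHMM":
        """Return a copy with relabeled states (label-symmetry helper)."""
        check_is_fitted(self, "means_")
        perm = np.asarray(perm)
        import copy

        other = copy.deepcopy(self)
        p = other._params
        p.alpha_start = p.alpha_start[perm]
        p.alpha_trans = p.alpha_trans[np.ix_(perm, perm)]
        p.beta = p.beta[perm]
        p.m = p.m[perm]
        p.nu = p.nu[perm]
        p.chol_winv = [p.chol_winv[i] for i in perm]
        p.ln_det_w = [p.ln_det_w[i] for i in perm]
        other._publish(p, p.m.shape[1])
        return other

    def posterior(self, X: np.ndarray, lengths=None) -> StatePosterior:
        """Per-subject probabilities and hard paths."""
        X = np.asarray(X, dtype=float)
        spans = _spans_from_lengths(X.shape[0], lengths)
        gamma = self.predict_proba(X, lengths)
        probs = [gamma[a:b] for a, b in spans]
        return StatePosterior(probabilities=probs,
                              paths=[hard_assign(g) for g in probs])


def _forward_backward(log_b: np.ndarray, spans, pi_t: np.ndarray, a_t: np.ndarray):
    """Scaled forward-backward over subjects, batched by sequence length.

    ``pi_t`` and ``a_t`` are the exponentiated expected log parameters
    (subnormalized), so the accumulated log normalizer is the VB data term.
    Returns pooled (gamma, xi_sum, start_sum, ln_z).
    """
    n, k = log_b.shape
    gamma = np.empty_like(log_b)
    xi = np.zeros((k, k))
    start_sum = np.zeros(k)
    ln_z = 0.0
    groups: dict[int, list[tuple[int, int]]] = {}
    for a, b in spans:
        groups.setdefault(b - a, []).append((a, b))
    for t_len, sp in groups.items():
        b_log = np.stack([log_b[a:b] for a, b in sp])  # S x T x K
        mx = b_log.max(axis=2)
        bn = np.exp(b_log - mx[..., None])
        s = b_log.shape[0]
        ahat = np.empty((s, t_len, k))
        c = np.empty((s, t_len))
        a0 = pi_t[None, :] * bn[:, 0]
        c[:, 0] = a0.sum(axis=1)
        ahat[:, 0] = a0 / c[:, 0, None]
        for t in range(1, t_len):
            at = (ahat[:, t - 1] @ a_t) * bn[:, t]
            c[:, t] = at.sum(axis=1)
            ahat[:, t] = at / c[:, t, None]
        ln_z += float(np.log(c).sum() + mx.sum())
        bhat = np.empty((s, t_len, k))
        bhat[:, -1] = 1.0
        for t in range(t_len - 2, -1, -1):
            nxt = bn[:, t + 1] * bhat[:, t + 1] / c[:, t + 1, None]
            bhat[:, t] = nxt @ a_t.T
            xi += a_t * (ahat[:, t].T @ nxt)
        g = ahat * bhat
        g /= g.sum(axis=2, keepdims=True)
        start_sum += g[:, 0].sum(axis=0)
        for (a, b), gs in zip(sp, g):
            gamma[a:b] = gs
    return gamma, xi, start_sum, ln_z


def match_states(reference: np.ndarray, estimated: np.ndarray) -> np.ndarray:
    """Best one-to-one state relabeling by mean-pattern correlation.

    Returns ``perm`` such that estimated state ``k`` corresponds to
    reference state ``perm[k]`` (Hungarian assignment maximizing the sum
    of Pearson correlations between matched mean vectors).
    """
    from scipy.optimize import linear_sum_assignment

    reference = np.asarray(reference, float)
    estimated = np.asarray(estimated, float)
    if reference.shape != estimated.shape:
        raise ValueError("reference and estimated must have matching shapes")
    k = reference.shape[0]
    corr = np.array([[np.corrcoef(r, e)[0, 1] for e in estimated] for r in reference])
    ref_idx, est_idx = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[est_idx] = ref_idx
    return perm


def hard_assign(posterior: np.ndarray) -> np.ndarray:
    """Argmax state per row; ties break toward the lowest state index."""
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim != 2:
        raise ValueError("posterior must be a T x K matrix")
    rowsums = posterior.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-6) or np.any(posterior < -1e-12):
        raise ValueError("posterior rows must be probability vectors")
    n_ties = int((np.sum(posterior == posterior.max(axis=1, keepdims=True), axis=1) > 1).sum())
    if n_ties:
        logger.info("hard_assign: %d row(s) had ties, broken toward the lowest index", n_ties)
    return np.argmax(posterior, axis=1)


def state_maps(model: VBGaussianHMM, transform: CohortPCA) -> np.ndarray:
    """Back-project state means to ROI space (K x R, standardized z units)."""
    check_is_fitted(model, "means_")
    if model.means_.shape[1] != transform.loadings_.shape[1]:
        raise ValueError(
            f"model has {model.means_.shape[1]} components, "
            f"transform has {transform.loadings_.shape[1]}"
        )
    return transform.inverse_transform(model.means_)


def fit_hmm(X: np.ndarray, lengths, n_states: int, n_restarts: int = 5,
            max_iter: int = 500, tol: float = 1e-6,
            random_state: int | None = None, **kwargs) -> tuple[VBGaussianHMM, StatePosterior]:
    """Fit the VB HMM and return the model with per-subject posteriors."""
    model = VBGaussianHMM(n_states=n_states, n_restarts=n_restarts,
                          max_iter=max_iter, tol=tol, random_state=random_state,
                          **kwargs).fit(X, lengths)
    return model, model.posterior(X, lengths)


# conventional scan range for whole-brain state models
DEFAULT_K_RANGE = range(4, 46)


def scan_states(X: np.ndarray, lengths, k_range=None, n_restarts: int = 5,
                max_iter: int = 500, tol: float = 1e-6,
                random_state: int | None = None, **kwargs):
    """Fit one model per K and record free energy and median occupancy.

    ``k_range`` defaults to 4..45. The median fractional occupancy is
    taken over all (subject, state) occupancy values of the best restart.
    Failed fits are recorded and the scan continues.
    """
    import pandas as pd

    k_range = list(DEFAULT_K_RANGE if k_range is None else k_range)
    if not k_range or any(b <= a for a, b in zip(k_range, k_range[1:])):
        raise ValueError("k_range must be non-empty and strictly ascending")
    records = []
    for k in k_range:
        try:
            model, post = fit_hmm(X, lengths, n_states=k, n_restarts=n_restarts,
                                  max_iter=max_iter, tol=tol,
                                  random_state=random_state, **kwargs)
        except Exception as exc:  # record and continue scanning
            logger.warning("scan: K=%d failed: %s", k, exc)
            records.append({"K": k, "free_energy": np.nan, "median_fo": np.nan,
                            "best_restart": -1, "failed": True})
            continue
        fo = np.array([fractional_occupancy(p, k) for p in post.paths])
        records.append({
            "K": k,
            "free_energy": float(model.free_energy_trace_[-1]),
            "median_fo": float(np.median(fo)),
            "best_restart": model.best_restart_,
            "failed": False,
        })
    return pd.DataFrame(records)


@dataclass
class SelectionResult:
    """Outcome of the occupancy-plateau model-order rule."""

    n_states: int
    plateau_found: bool
    free_energy_monotone: bool


def select_n_states(scan, epsilon: float = 0.05) -> SelectionResult:
    """Choose K where the median-occupancy curve stops dropping.

    Returns the smallest scanned K whose relative decrease in median
    fractional occupancy to the next scanned K falls below ``epsilon``.
    If no plateau exists the largest scanned K is returned with
    ``plateau_found=False``. The free energy is typically monotone in K
    and therefore uninformative for model order; its monotonicity is
    reported for reference.
    """
    ok = scan[~scan["failed"]].sort_values("K")
    if len(ok) < 3:
        raise ValueError("need at least 3 successfully scanned K values")
    ks = ok["K"].to_numpy()
    fo = ok["median_fo"].to_numpy()
    fe = ok["free_energy"].to_numpy()
    fe_monotone = bool(np.all(np.diff(fe) <= np.abs(fe[:-1]) * 1e-6))
    for i in range(len(ks) - 1):
        if fo[i] <= 0:
            continue
        if (fo[i] - fo[i + 1]) / fo[i] < epsilon:
            return SelectionResult(int(ks[i]), True, fe_monotone)
    logger.warning("no occupancy plateau found; returning the largest scanned K")
    return SelectionResult(int(ks[-1]), False, fe_monotone)
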