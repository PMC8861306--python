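"""Synthetic multi-subject cohorts with a known ground-truth Gaussian HMM.

The generator plants K state-specific mean activation patterns over R
regions, a hidden Markov chain with optional block (community) structure in
its transition matrix, and a group effect expressed purely through
group-specific transition matrices, so that both groups share the same
state identities — mirroring group-level state estimation on concatenated
data. Every downstream stage of the pipeline can therefore be tested
against stored truth without any external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocessing import SubjectSeries

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "make_ground_truth",
    "simulate_cohort",
    "bias_transitions",
    "stationary_distribution",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults describe the package's reference cohort: two groups of 20
    subjects, 200 timepoints over 30 regions, 5 states whose means are
    separated by 3 noise-SD, unit isotropic observation noise.

    ``effect_size`` is expressed in units of the between-subject SD of the
    target state's fractional occupancy under the unbiased chain, so a
    value of 1.0 plants a one-SD group difference in expected occupancy.
    ``covariate_leakage`` maps covariate names to coefficients that tilt a
    subject's transition matrix toward the effect state in proportion to
    the subject's standardized covariate value.
    """

    n_per_group: int = 20
    T: int = 200
    R: int = 30
    n_states: int = 5
    state_separation: float = 3.0
    noise_scale: float = 1.0
    n_modules: int = 1
    stay_prob: float = 0.8
    within_module_fraction: float = 0.75
    covariance: str = "isotropic"  # or "full"
    groups: tuple[str, str] = ("case", "control")
    n_sites: int = 3
    site_offset: float = 0.0
    effect_state: int | None = None
    effect_size: float = 0.0
    effect_group: str = "case"
    covariate_leakage: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if not (0.0 < self.stay_prob < 1.0):
            raise ValueError("stay_prob must lie in (0, 1)")
        if not (0.0 <= self.within_module_fraction <= 1.0):
            raise ValueError("within_module_fraction must lie in [0, 1]")
        if not (1 <= self.n_modules <= self.n_states):
            raise ValueError("n_modules must lie in [1, n_states]")
        if self.covariance not in ("isotropic", "full"):
            raise ValueError("covariance must be 'isotropic' or 'full'")
        if self.effect_state is not None and not (0 <= self.effect_state < self.n_states):
            raise ValueError("effect_state out of range")
        if self.effect_group not in self.groups:
            raise ValueError(f"effect_group {self.effect_group!r} not in groups")
        if self.n_states > self.R:
            warnings.warn(
                f"K={self.n_states} exceeds R={self.R}; state means may not be "
                "linearly separable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Generative parameters a cohort was sampled from."""

    n_states: int
    roi_means: np.ndarray  # K x R
    roi_covs: np.ndarray  # K x R x R
    trans_by_group: dict[str, np.ndarray]  # each K x K row-stochastic
    initial_dist: np.ndarray  # length K
    community_labels: np.ndarray  # length K module ids

    def validate(self) -> None:
        k = self.n_states
        if self.roi_means.shape[0] != k or self.roi_covs.shape[0] != k:
            raise ValueError("means/covs inconsistent with n_states")
        if abs(self.initial_dist.sum() - 1.0) > 1e-12 or np.any(self.initial_dist < 0):
            raise ValueError("initial_dist is not a probability simplex vector")
        for g, a in self.trans_by_group.items():
            if a.shape != (k, k):
                raise ValueError(f"group {g}: transition matrix must be {k}x{k}")
            if np.any(a < 0) or np.max(np.abs(a.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"group {g}: transition matrix is not row-stochastic")
        for c in self.roi_covs:
            if np.max(np.abs(c - c.T)) > 1e-10:
                raise ValueError("covariance not symmetric")
            np.linalg.cholesky(c)  # raises if not positive definite
        counts = np.bincount(self.community_labels)
        if len(self.community_labels) != k or np.any(counts == 0):
            raise ValueError("community_labels must cover every module")


@dataclass
class Cohort:
    """Simulated subjects with their hidden state paths and truth."""

    subjects: list[SubjectSeries]
    true_paths: dict[str, np.ndarray]
    truth: GroundTruth
    manifest: pd.DataFrame


def stationary_distribution(trans: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic row-stochastic matrix."""
    vals, vecs = np.linalg.eig(trans.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def bias_transitions(trans: np.ndarray, state: int, delta: float,
                     rows: np.ndarray | list[int] | None = None) -> np.ndarray:
    """Tilt a chain toward (delta > 0) or away from (delta < 0) one state.

    Positive delta mixes each affected row with a point mass on ``state``;
    negative delta removes a |delta| fraction of the affected rows' mass at
    ``state`` and renormalizes. ``rows`` limits the tilt to a subset of
    rows (e.g. the target's own community, which leaves cross-community
    transition weights untouched); default is all rows. Rows stay
    stochastic for |delta| <= 1.
    """
    if not (-1.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [-1, 1]")
    a = np.array(trans, dtype=float)
    idx = np.arange(a.shape[0]) if rows is None else np.asarray(rows)
    if delta >= 0:
        onehot = np.zeros(a.shape[1])
        onehot[state] = 1.0
        a[idx] = (1.0 - delta) * a[idx] + delta * onehot[None, :]
    else:
        a[idx, state] *= 1.0 + delta
        a[idx] /= a[idx].sum(axis=1, keepdims=True)
    return a


def _block_transition_matrix(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Base chain with planted module blocks.

    Each row keeps ``stay_prob`` on the diagonal; of the remaining mass,
    ``within_module_fraction`` goes (uniformly) to the other states of the
    same module and the rest (uniformly) to states of other modules.
    """
    k = config.n_states
    labels = np.sort(np.arange(k) % config.n_modules)
    if k == 1:
        return np.ones((1, 1)), np.zeros(1, dtype=int)
    a = np.zeros((k, k))
    off = 1.0 - config.stay_prob
    wf = config.within_module_fraction
    for i in range(k):
        same = np.flatnonzero((labels == labels[i]) & (np.arange(k) != i))
        other = np.flatnonzero(labels != labels[i])
        a[i, i] = config.stay_prob
        if same.size and other.size:
            a[i, same] = off * wf / same.size
            a[i, other] = off * (1.0 - wf) / other.size
        elif same.size:
            a[i, same] = off / same.size
        else:
            a[i, other] = off / other.size
    a /= a.sum(axis=1, keepdims=True)
    return a, labels


def _sample_paths(trans: np.ndarray, initial: np.ndarray, T: int, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` hidden paths of length ``T`` from one chain."""
    k = trans.shape[0]
    cum_init = np.cumsum(initial)
    cum_trans = np.cumsum(trans, axis=1)
    u = rng.random((n, T))
    paths = np.empty((n, T), dtype=np.int64)
    paths[:, 0] = np.searchsorted(cum_init, u[:, 0], side="right").clip(max=k - 1)
    for t in range(1, T):
        rows = cum_trans[paths[:, t - 1]]
        paths[:, t] = (u[:, t][:, None] > rows).sum(axis=1).clip(max=k - 1)
    return paths


def occupancy_variance(trans: np.ndarray, state: int, T: int) -> float:
    """Exact between-subject variance of a state's fractional occupancy.

    For a stationary chain the occupancy indicator's T-sample mean has

        var = (1/T) * [ pi(1-pi) + 2 * sum_{l=1}^{T-1} (1 - l/T)
                        * pi * (P^l_{ss} - pi) ]

    with pi the state's stationary probability.
    """
    pi = stationary_distribution(trans)
    p0 = pi[state]
    row = np.zeros(len(pi))
    row[state] = 1.0
    acc = p0 * (1.0 - p0)
    for lag in range(1, T):
        row = row @ trans
        acc += 2.0 * (1.0 - lag / T) * p0 * (row[state] - p0)
    return float(acc / T)


def _calibrate_bias(trans: np.ndarray, state: int, effect_size: float, T: int,
                    rows=None) -> float:
    """Bisection for the mixing weight delta producing the target occupancy shift.

    The target shift is ``effect_size`` times the pooled between-subject SD
    of the state's occupancy over the two groups (the tilted chain has a
    higher occupancy variance, which would otherwise dilute the realized
    standardized effect). Shifts are measured on stationary distributions,
    which the mean path occupancy is unbiased for under equilibrium starts;
    variances come from :func:`occupancy_variance`, so the calibration is
    fully deterministic.
    """
    if effect_size == 0.0:
        return 0.0
    base = stationary_distribution(trans)[state]
    var0 = occupancy_variance(trans, state, T)

    def gap(delta: float) -> float:
        tilted = bias_transitions(trans, state, delta, rows=rows)
        shift = stationary_distribution(tilted)[state] - base
        pooled_sd = np.sqrt((var0 + occupancy_variance(tilted, state, T)) / 2.0)
        return abs(shift) - abs(effect_size) * pooled_sd

    sign = 1.0 if effect_size >= 0 else -1.0
    lo, hi = 0.0, 0.95 * sign
    if gap(hi) < 0:
        raise ValueError("requested occupancy effect is not attainable")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw deterministic generative parameters for a cohort.

    State means are sampled isotropically and rescaled so the minimum
    pairwise Euclidean distance equals ``state_separation`` (in noise-SD
    units). Covariances default to isotropic ``noise_scale**2 * I``. The
    group effect, if any, is applied by tilting the effect group's
    transition matrix toward ``effect_state`` with a calibrated mixing
    weight.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    k, r = config.n_states, config.R

    if k == 1:
        means = np.zeros((1, r))
    else:
        means = rng.standard_normal((k, r))
        means -= means.mean(axis=0)
        dists = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
        min_dist = dists[np.triu_indices(k, 1)].min()
        means *= config.state_separation * config.noise_scale / min_dist

    if config.covariance == "isotropic":
        covs = np.broadcast_to(
            config.noise_scale**2 * np.eye(r), (k, r, r)
        ).copy()
    else:
        covs = np.empty((k, r, r))
        for i in range(k):
            w = rng.standard_normal((r, r)) / np.sqrt(r)
            covs[i] = config.noise_scale**2 * (0.5 * np.eye(r) + w @ w.T)

    base, labels = _block_transition_matrix(config)
    trans_by_group: dict[str, np.ndarray] = {}
    # the tilt stays inside the target's own community so that planted
    # cross-community transition weights are untouched by the group effect
    bias_rows = None
    if config.n_modules > 1 and config.effect_state is not None:
        bias_rows = np.flatnonzero(labels == labels[config.effect_state])
    for g in config.groups:
        if g == config.effect_group and config.effect_state is not None and config.effect_size:
            delta = _calibrate_bias(
                base, config.effect_state, config.effect_size, config.T,
                rows=bias_rows,
            )
            trans_by_group[g] = bias_transitions(base, config.effect_state, delta,
                                                 rows=bias_rows)
        else:
            trans_by_group[g] = base.copy()

    # chains start at equilibrium, as resting-state acquisition implies
    truth = GroundTruth(
        n_states=k,
        roi_means=means,
        roi_covs=covs,
        trans_by_group=trans_by_group,
        initial_dist=stationary_distribution(base),
        community_labels=labels,
    )
    truth.validate()
    return truth


def _covariates(rng: np.random.Generator, n_sites: int) -> dict[str, float | str]:
    return {
        "site": f"site{int(rng.integers(n_sites)) + 1:02d}",
        "age": float(np.round(rng.uniform(8.0, 30.0), 2)),
        "fiq": float(np.round(rng.normal(105.0, 15.0), 1)),
        "mean_fd": float(np.round(rng.gamma(2.0, 0.05), 4)),
    }


def simulate_cohort(truth: GroundTruth, config: CohortConfig) -> Cohort:
    """Sample a two-group cohort from the ground truth.

    Each subject gets an independent random stream derived from the global
    seed and the subject's global index, so cohorts are reproducible
    subject-by-subject. True hidden paths are retained for recovery tests.
    """
    config.validate()
    if truth.n_states != config.n_states or truth.roi_means.shape[1] != config.R:
        raise ValueError("truth and config disagree on K or R")
    chol = np.linalg.cholesky(truth.roi_covs)  # K x R x R lower factors
    site_shift = {
        f"site{i + 1:02d}": config.site_offset * (i - (config.n_sites - 1) / 2.0)
        for i in range(config.n_sites)
    }

    subjects: list[SubjectSeries] = []
    true_paths: dict[str, np.ndarray] = {}
    rows = []
    idx = 0
    for group in config.groups:
        trans = truth.trans_by_group[group]
        group_initial = stationary_distribution(trans)
        for j in range(config.n_per_group):
            rng = np.random.default_rng([config.seed % (2**31), 17, idx])
            cov = _covariates(rng, config.n_sites)
            subj_trans = trans
            if config.covariate_leakage and config.effect_state is not None:
                # linear leakage of covariates into occupancy via the chain
                z = {"age": (cov["age"] - 19.0) / 6.35, "fiq": (cov["fiq"] - 105.0) / 15.0,
                     "mean_fd": (cov["mean_fd"] - 0.1) / 0.07}
                delta = sum(c * z.get(name, 0.0) for name, c in config.covariate_leakage.items())
                subj_trans = bias_transitions(trans, config.effect_state,
                                              float(np.clip(delta, -0.5, 0.5)))
            initial = (group_initial if subj_trans is trans
                       else stationary_distribution(subj_trans))
            path = _sample_paths(subj_trans, initial, config.T, 1, rng)[0]
            noise = rng.standard_normal((config.T, config.R))
            data = truth.roi_means[path] + np.einsum(
                "trs,ts->tr", chol[path], noise
            )
            data += site_shift[cov["site"]]
            sid = f"sub-{group}-{j + 1:03d}"
            subjects.append(
                SubjectSeries(
                    subject_id=sid, group=group, site=cov["site"], age=cov["age"],
                    fiq=cov["fiq"], mean_fd=cov["mean_fd"], data=data,
                )
            )
            true_paths[sid] = path
            rows.append(
                {"subject_id": sid, "group": group, "site": cov["site"],
                 "age": cov["age"], "fiq": cov["fiq"], "mean_fd": cov["mean_fd"],
                 "path": f"{sid}.tsv"}
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    return Cohort(subjects=subjects, true_paths=true_paths, truth=truth, manifest=manifest)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject TSVs, the manifest, truth JSON, and true paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        df = pd.DataFrame(s.data, columns=s.roi_labels)
        df.to_csv(outdir / f"{s.subject_id}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    cohort.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth = cohort.truth
    payload = {
        "n_states": truth.n_states,
        "roi_means": truth.roi_means.tolist(),
        "roi_covs": truth.roi_covs.tolist(),
        "trans_by_group": {g: a.tolist() for g, a in truth.trans_by_group.items()},
        "initial_dist": truth.initial_dist.tolist(),
        "community_labels": truth.community_labels.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload))
    paths = pd.DataFrame(
        {sid: pd.Series(p) for sid, p in cohort.true_paths.items()}
    )
    paths.to_csv(outdir / "true_paths.tsv", sep="\t", index=False)
    return outdir / "manifest.tsv"
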