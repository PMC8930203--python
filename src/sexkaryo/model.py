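"""Two-component Gaussian mixture clustering of scaled sex features.

The cohort is z-scored per feature, clustered into two full-covariance
Gaussian components by EM (seeded random restarts, diagonal ridge on every
covariance so the zero-variance male-XH pathology cannot break the fit),
and the two clusters are named male/female from their unscaled feature
means. A sample's uncertainty is one minus its larger posterior; samples
above the uncertainty threshold are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateFeatureError,
    LabelingError,
)
from .features import FeatureTable, SampleFeatures

DEFAULT_UNCERTAINTY_THRESHOLD = 0.1

#: Cluster-naming rules in decreasing biological decisiveness: the named
#: feature separates the clusters, and the comparison sends the male
#: cluster the stated way.  Y-linked features come first; X-only panels
#: fall through to heterozygosity and X coverage.
_SEX_RULES: tuple[tuple[str, str], ...] = (
    ("Ymap", "higher"),
    ("SRY_dep", "higher"),
    ("XYratio", "lower"),
    ("XH", "lower"),
    ("Xmap", "lower"),
)


@dataclass(frozen=True)
class ScalingParams:
    features: tuple[str, ...]
    center: np.ndarray
    spread: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.spread


@dataclass(frozen=True)
class MixtureFit:
    """A fitted 2-component Gaussian mixture on scaled features."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    seed: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Bayes-rule posterior over components for rows of ``x``."""
        x = np.atleast_2d(x)
        log_r = _log_responsibilities(
            x, self.weights, self.means, self.covariances
        )[0]
        return np.exp(log_r)


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    sex: str
    uncertainty: float
    outlier: bool


def scale_features(table: FeatureTable) -> tuple[np.ndarray, ScalingParams]:
    """Z-score each selected feature (mean 0, sample sd 1, ddof=1)."""
    x = table.matrix()
    if x.shape[0] < 2:
        raise ConfigurationError("scaling needs at least 2 samples")
    center = x.mean(axis=0)
    spread = x.std(axis=0, ddof=1)
    for j, s in enumerate(spread):
        # relative floor: a column of identical values has sd ~ float noise
        if s <= 1e-12 * max(abs(center[j]), 1.0) or not np.isfinite(s):
            raise DegenerateFeatureError(
                f"feature {table.selected_features[j]!r} has zero variance"
            )
    params = ScalingParams(table.selected_features, center, spread)
    return params.transform(x), params


def _log_responsibilities(x, weights, means, covs):
    n, k = x.shape[0], len(weights)
    log_prob = np.empty((n, k))
    for j in range(k):
        log_prob[:, j] = np.log(weights[j]) + multivariate_normal.logpdf(
            x, mean=means[j], cov=covs[j], allow_singular=False
        )
    norm = logsumexp(log_prob, axis=1)
    return log_prob - norm[:, None], norm.sum()


def _em_once(x, k, rng, max_iter, tol, ridge):
    n, d = x.shape
    eye = ridge * np.eye(d)
    # init: means at distinct random samples, shared data covariance
    idx = rng.choice(n, size=k, replace=False)
    means = x[idx].copy()
    base_cov = np.cov(x, rowvar=False).reshape(d, d) + eye
    covs = np.stack([base_cov.copy() for _ in range(k)])
    weights = np.full(k, 1.0 / k)
    trace = []
    converged = False
    log_r = None
    for _ in range(max_iter):
        log_r, ll = _log_responsibilities(x, weights, means, covs)
        trace.append(ll)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if (trace[-1] - trace[-2]) / denom < tol:
                converged = True
                break
        r = np.exp(log_r)
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (r.T @ x) / nk[:, None]
        for j in range(k):
            diff = x - means[j]
            covs[j] = (r[:, j][:, None] * diff).T @ diff / nk[j] + eye
    return weights, means, covs, np.exp(log_r), np.array(trace), converged


def fit_gmm(
    scaled: np.ndarray,
    k: int = 2,
    seed: int = 0,
    *,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> MixtureFit:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    ``n_restarts`` seeded restarts keep the best final log-likelihood;
    every covariance carries a diagonal ridge. Deterministic given ``seed``.
    """
    x = np.asarray(scaled, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2 * k:
        raise ConfigurationError(f"need at least {2 * k} samples to fit {k} components")
    best = None
    traces = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        try:
            out = _em_once(x, k, rng, max_iter, tol, ridge)
        except (np.linalg.LinAlgError, ValueError):
            continue
        traces.append(out[4])
        if not np.isfinite(out[4][-1]):
            continue
        if best is None or out[4][-1] > best[4][-1]:
            best = out
    if best is None:
        raise ConvergenceError(
            f"EM failed across all {n_restarts} restarts", traces=traces
        )
    weights, means, covs, resp, trace, converged = best
    return MixtureFit(
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=resp,
        loglik_trace=trace,
        seed=seed,
        converged=converged,
    )


def _cluster_feature_means(
    fit: MixtureFit, table: FeatureTable
) -> dict[str, np.ndarray]:
    """Responsibility-weighted unscaled feature means per cluster.

    Uses every feature present for all rows, selected or not, so Y-linked
    evidence can name the clusters even when modeling ran on X features.
    """
    r = fit.responsibilities
    nk = np.maximum(r.sum(axis=0), 1e-12)
    out: dict[str, np.ndarray] = {}
    from .config import FEATURE_NAMES

    for f in FEATURE_NAMES:
        vals = table.feature_values(f)
        if any(v is None for v in vals):
            continue
        v = np.asarray(vals, dtype=float)
        out[f] = (r * v[:, None]).sum(axis=0) / nk
    return out


def label_clusters(fit: MixtureFit, table: FeatureTable) -> dict[int, str]:
    """Map cluster index → sex via the first applicable naming rule."""
    means = _cluster_feature_means(fit, table)
    for feature, male_side in _SEX_RULES:
        if feature not in means:
            continue
        m = means[feature]
        if m[0] == m[1]:
            continue
        hi = int(np.argmax(m))
        male = hi if male_side == "higher" else 1 - hi
        return {male: "male", 1 - male: "female"}
    raise LabelingError("no feature separates the two cluster means")


def assign_sexes(
    fit: MixtureFit,
    table: FeatureTable,
    threshold: float = DEFAULT_UNCERTAINTY_THRESHOLD,
) -> list[SexCall]:
    """Turn mixture responsibilities into per-sample sex calls.

    ``uncertainty`` is 1 − max posterior; samples with uncertainty strictly
    above ``threshold`` are flagged as outliers.
    """
    if fit.responsibilities.shape[0] != len(table):
        raise ConfigurationError("fit and table are not aligned")
    sex_of = label_clusters(fit, table)
    calls = []
    for i, row in enumerate(table.rows):
        post = fit.responsibilities[i]
        cluster = int(np.argmax(post))
        uncertainty = float(1.0 - post[cluster])
        calls.append(
            SexCall(
                sample_id=row.sample_id,
                sex=sex_of[cluster],
                uncertainty=uncertainty,
                outlier=uncertainty > threshold,
            )
        )
    return calls


def infer_cohort(
    table: FeatureTable,
    seed: int = 0,
    threshold: float = DEFAULT_UNCERTAINTY_THRESHOLD,
    **fit_kwargs,
) -> tuple[MixtureFit, list[SexCall]]:
    """Scale → fit → assign for a whole cohort."""
    scaled, _ = scale_features(table)
    fit = fit_gmm(scaled, k=2, seed=seed, **fit_kwargs)
    return fit, assign_sexes(fit, table, threshold=threshold)


def infer_single_sample(
    sample: SampleFeatures,
    reference: FeatureTable,
    seed: int = 0,
    threshold: float = DEFAULT_UNCERTAINTY_THRESHOLD,
    **fit_kwargs,
) -> SexCall:
    """Classify one sample against a reference cohort.

    The sample is appended to the reference table, the pooled table is
    rescaled and refit, and the appended sample's call is returned —
    identical to running the cohort path on reference + sample.
    """
    missing = [
        f for f in reference.selected_features if sample.get(f) is None
    ]
    if missing:
        raise ConfigurationError(
            f"sample {sample.sample_id!r} lacks reference features: {missing}"
        )
    if sample.sample_id in reference.sample_ids:
        sample = SampleFeatures(
            **{
                **{f: sample.get(f) for f in
                   ("XH", "Xmap", "Ymap", "XYratio", "SRY_dep")},
                "sample_id": sample.sample_id + "_query",
            }
        )
    pooled = reference.with_rows([sample])
    _, calls = infer_cohort(pooled, seed=seed, threshold=threshold, **fit_kwargs)
    return calls[-1]


def sex_calls_to_tsv(calls: Sequence[SexCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\tuncertainty\toutlier\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.sex}\t{c.uncertainty!r}\t"
                f"{'TRUE' if c.outlier else 'FALSE'}\n"
            )


def sex_calls_from_tsv(path) -> list[SexCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            calls.append(
                SexCall(
                    sample_id=rec["sample_id"],
                    sex=rec["sex"],
                    uncertainty=float(rec["uncertainty"]),
                    outlier=rec["outlier"] == "TRUE",
                )
            )
    return calls
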