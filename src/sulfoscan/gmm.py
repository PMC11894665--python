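"""Gaussian mixture modelling of calibrated mass errors and bin assignment.

For each robustly detected peptidoform, 1-, 2- and 3-component univariate
Gaussian mixtures are fit to its calibrated precursor mass errors by EM.
The number of components is selected by BIC with a strong-evidence rule:
a larger model is preferred only if its BIC is at least 10 points lower.
The fitted density is then integrated over nine predefined 0.005 Da bins
spanning [-0.0225, 0.0225) Da — three Bins of Interest (BOI) over the
singly/doubly sulfated shifts (-0.0096 / -0.0192 Da), three TRUEp bins
around 0, and three DECOY bins mirroring the BOIs on the positive side —
and the peptidoform is assigned to every bin capturing >= 15% of the
model's probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

VARIANCE_FLOOR = 1e-8  # Da^2; guards against components collapsing on a point
DEFAULT_TOL = 1e-8  # convergence tolerance on mean log-likelihood
MAX_ITER = 500
N_RESTARTS = 5


@dataclass
class GmmModel:
    """A fitted 1-3 component univariate Gaussian mixture over mass error."""

    components: list[tuple[float, float, float]]  # (weight, mean Da, sd Da)
    bic_by_k: dict[int, float]
    selected_k: int
    n_samples: int
    log_likelihood: float
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(
            w * norm.pdf(x, loc=mu, scale=sd) for w, mu, sd in self.components
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.components), size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])


@dataclass(frozen=True)
class MassErrorBin:
    """Half-open mass error interval [lower, upper) with a group label."""

    name: str
    group: str  # BOI | TRUEp | DECOY
    lower: float
    upper: float

    def contains(self, x: float) -> bool:
        return self.lower <= x < self.upper


def standard_bins() -> list[MassErrorBin]:
    """The nine predefined 0.005 Da bins covering [-0.0225, 0.0225) Da.

    BOI1 (-0.0125:-0.0075), BOI2 (-0.0175:-0.0125), BOI3 (-0.0225:-0.0175)
    cover single and double sulfation shifts; TRUEp1-3 cover
    (-0.0075:+0.0075); DECOY1-3 mirror the BOIs about zero.
    """
    return [
        MassErrorBin("BOI3", "BOI", -0.0225, -0.0175),
        MassErrorBin("BOI2", "BOI", -0.0175, -0.0125),
        MassErrorBin("BOI1", "BOI", -0.0125, -0.0075),
        MassErrorBin("TRUEp1", "TRUEp", -0.0075, -0.0025),
        MassErrorBin("TRUEp2", "TRUEp", -0.0025, 0.0025),
        MassErrorBin("TRUEp3", "TRUEp", 0.0025, 0.0075),
        MassErrorBin("DECOY1", "DECOY", 0.0075, 0.0125),
        MassErrorBin("DECOY2", "DECOY", 0.0125, 0.0175),
        MassErrorBin("DECOY3", "DECOY", 0.0175, 0.0225),
    ]


def _loglik(x: np.ndarray, weights: np.ndarray, means: np.ndarray, sds: np.ndarray) -> float:
    # log-sum-exp over components, vectorised over samples
    log_dens = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi)
        - np.log(sds)[None, :]
        - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
    )
    m = log_dens.max(axis=1, keepdims=True)
    return float(np.sum(m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))))


def _em(
    x: np.ndarray,
    means0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Run EM from an initial set of means; returns (w, mu, sd, loglik, converged)."""
    k = len(means0)
    n = len(x)
    weights = np.full(k, 1.0 / k)
    means = means0.astype(float).copy()
    var = np.full(k, max(float(np.var(x)), VARIANCE_FLOOR))
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        sds = np.sqrt(var)
        # E step: responsibilities via log densities
        log_dens = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = log_dens.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        resp = np.exp(log_dens - log_norm[:, None])
        ll = float(log_norm.sum())
        # EM monotonicity is a model invariant; a decrease signals a bug.
        assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        if abs(ll - prev_ll) / n < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VARIANCE_FLOOR)
    return weights, means, np.sqrt(var), prev_ll, converged


def fit_gmm(
    errors: np.ndarray | list[float],
    k: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
    n_restarts: int = N_RESTARTS,
) -> tuple[list[tuple[float, float, float]], float, bool]:
    """Fit a k-component univariate Gaussian mixture by EM.

    k=1 uses the closed-form Gaussian MLE (sample mean, population-style
    sd); k>1 runs EM from k evenly spaced sample quantiles, with
    ``n_restarts`` jittered restarts, keeping the best log-likelihood.
    Deterministic given the seed.

    Returns ``(components, log_likelihood, converged)`` with components as
    (weight, mean, sd) tuples.
    """
    x = np.asarray(errors, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite mass errors")
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if len(x) < max(2 * k, 2):
        raise ValueError(f"need at least {max(2 * k, 2)} samples for k={k}, got {len(x)}")

    if k == 1:
        mu = float(np.mean(x))
        sd = float(np.sqrt(max(np.var(x), VARIANCE_FLOOR)))
        ll = _loglik(x, np.array([1.0]), np.array([mu]), np.array([sd]))
        return [(1.0, mu, sd)], ll, True

    rng = np.random.default_rng(seed)
    # initial means at evenly spaced sample quantiles
    qs = np.quantile(x, (np.arange(k) + 0.5) / k)
    scale = max(float(np.std(x)), np.sqrt(VARIANCE_FLOOR))
    best: tuple[np.ndarray, np.ndarray, np.ndarray, float, bool] | None = None
    for restart in range(n_restarts):
        means0 = qs if restart == 0 else qs + rng.normal(0.0, 0.5 * scale, size=k)
        fit = _em(x, means0, tol=tol, max_iter=max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    weights, means, sds, ll, converged = best
    order = np.argsort(means)
    components = [
        (float(weights[j]), float(means[j]), float(sds[j])) for j in order
    ]
    return components, ll, converged


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion, p*ln(n) - 2*lnL with p = 3k - 1.

    The free parameters are k means, k variances and k-1 mixture weights.
    Lower is better.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = 3 * k - 1
    return p * np.log(n) - 2.0 * log_likelihood


def select_model(bic_by_k: dict[int, float], delta: float = 10.0) -> int:
    """Sequential strong-evidence model selection over k = 1, 2, 3.

    Starting from k=1, a larger model replaces the current choice only if
    its BIC is at least ``delta`` points smaller — first 2 vs 1, then 3 vs
    the winner.  This prioritises the smallest number of components.
    """
    for k in (1, 2, 3):
        if not np.isfinite(bic_by_k[k]):
            raise ValueError(f"BIC for k={k} is not finite")
    chosen = 1
    for k in (2, 3):
        if bic_by_k[k] <= bic_by_k[chosen] - delta:
            chosen = k
    return chosen


def fit_peptidoform(
    errors: np.ndarray | list[float],
    seed: int = 0,
    delta: float = 10.0,
    **fit_kwargs,
) -> GmmModel:
    """Fit k = 1..3 mixtures, select k by the BIC rule, return the model."""
    x = np.asarray(errors, dtype=float)
    fits = {}
    bics = {}
    for k in (1, 2, 3):
        components, ll, converged = fit_gmm(x, k, seed=seed, **fit_kwargs)
        fits[k] = (components, ll, converged)
        bics[k] = bic(ll, k, len(x))
    k_sel = select_model(bics, delta=delta)
    components, ll, converged = fits[k_sel]
    return GmmModel(
        components=components,
        bic_by_k=bics,
        selected_k=k_sel,
        n_samples=len(x),
        log_likelihood=ll,
        converged=converged,
    )


def bin_auc(model: GmmModel, bin_: MassErrorBin) -> float:
    """Probability mass of the fitted mixture inside the bin's interval.

    Closed form: the weighted difference of normal CDFs at the bin edges.
    """
    total = 0.0
    for w, mu, sd in model.components:
        total += w * (norm.cdf((bin_.upper - mu) / sd) - norm.cdf((bin_.lower - mu) / sd))
    return float(total)


@dataclass
class BinAssignment:
    """Per-peptidoform bin AUC fractions and the >=threshold assignments."""

    peptidoform_id: str
    auc_by_bin: dict[str, float]
    assigned_bins: set[str]
    auc_threshold: float


def assign_bins(
    model: GmmModel,
    bins: list[MassErrorBin] | None = None,
    threshold: float = 0.15,
    peptidoform_id: str = "",
) -> BinAssignment:
    """Assign a peptidoform to every bin whose AUC is >= the threshold.

    The denominator is the model's total probability mass (1.0).  Multiple
    assignments and empty assignments are both possible.
    """
    bins = bins if bins is not None else standard_bins()
    aucs = {b.name: bin_auc(model, b) for b in bins}
    assigned = {name for name, a in aucs.items() if a >= threshold}
    return BinAssignment(
        peptidoform_id=peptidoform_id,
        auc_by_bin=aucs,
        assigned_bins=assigned,
        auc_threshold=threshold,
    )
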