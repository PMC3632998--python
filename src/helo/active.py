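"""Active k-optimization of a compound library with a GP surrogate.

The task: find the k most active compounds in a library (activity measured
as pGI50, the negative log-concentration for 50% growth inhibition — higher
is more potent) while measuring as few compounds as possible.  The loop
bootstraps by measuring a small random batch, then repeatedly (1) fits a
Gaussian-process QSAR surrogate to all measured activities, (2) scores every
untested compound with an acquisition strategy, and (3) measures the
top-scoring compound.

Strategies
----------
``mpi``         most probable improvement: Φ((μ − y_kbest)/σ), the probability
                a compound beats the current k-th best measured value.
``mei``         maximum expected improvement: E[max(Y − y_kbest, 0)] under the
                predictive Normal.
``optimistic``  confidence bound μ + β·σ (β ≥ 0).  The criterion is usually
                stated as a *lower* confidence bound for minimization; this
                package maximizes activity, so optimism under uncertainty
                means adding the uncertainty term.
``random``      uniform choice among untested compounds; never consults the
                surrogate.

The surrogate predicts a Normal distribution per compound (mean μ_i, standard
deviation σ_i), which is what makes the probabilistic acquisition scores
well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .errors import HeloError, ValidationError

__all__ = [
    "CompoundLibrary",
    "GPHyperparams",
    "Surrogate",
    "fit_surrogate",
    "acq_mpi",
    "acq_mei",
    "acq_optimistic",
    "IterationRecord",
    "ActiveRunResult",
    "run_active_optimization",
    "compare_strategies",
    "STRATEGIES",
]

STRATEGIES = ("optimistic", "mpi", "mei", "random")

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class CompoundLibrary:
    """A screening library: ids, a feature matrix and activity bookkeeping.

    ``true_activity`` is the hidden assay ground truth used to simulate
    measurements (synthetic libraries); ``measured`` grows as compounds are
    assayed.  Features are plain numeric columns — molecular featurization is
    assumed to have happened upstream.
    """

    compound_ids: List[str]
    features: np.ndarray
    true_activity: Optional[np.ndarray] = None
    measured: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if len(self.compound_ids) != self.features.shape[0]:
            raise ValidationError("one feature row per compound id required")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValidationError("compound ids must be unique")
        if not np.isfinite(self.features).all():
            raise ValidationError("feature matrix contains non-finite values")
        if self.true_activity is not None:
            self.true_activity = np.asarray(self.true_activity, dtype=float)
            if self.true_activity.shape != (len(self.compound_ids),):
                raise ValidationError("true_activity length mismatch")
        unknown = set(self.measured) - set(self.compound_ids)
        if unknown:
            raise ValidationError(f"measured ids not in library: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def index_of(self, compound_id: str) -> int:
        return self.compound_ids.index(compound_id)

    def assay(self, compound_id: str) -> float:
        """Simulated measurement: read the hidden true activity."""
        if self.true_activity is None:
            raise HeloError(
                "library has no ground-truth activities to simulate assays"
            )
        return float(self.true_activity[self.index_of(compound_id)])


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential GP configuration.

    amplitude     prior standard deviation of the latent function
    length_scale  shared per-dimension RBF length scale
    noise_sd      observation noise standard deviation
    jitter        diagonal stabilizer added to the kernel matrix
    optimize      fit amplitude/length_scale/noise by marginal likelihood
                  instead of keeping them fixed
    """

    amplitude: float = 1.0
    length_scale: float = 0.2
    noise_sd: float = 0.1
    jitter: float = 1e-8
    optimize: bool = False

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.length_scale <= 0:
            raise ValidationError("amplitude and length_scale must be positive")
        if self.noise_sd < 0 or self.jitter < 0:
            raise ValidationError("noise_sd and jitter must be nonnegative")


class Surrogate:
    """A fitted GP that returns a Normal predictive per query compound."""

    def __init__(self, gpr: GaussianProcessRegressor, y_mean: float) -> None:
        self._gpr = gpr
        self._y_mean = y_mean

    def predict(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation (latent, noise-free)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu, sd = self._gpr.predict(X, return_std=True)
        return mu + self._y_mean, np.maximum(sd, 0.0)


def fit_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Optional[GPHyperparams] = None,
) -> Surrogate:
    """Fit a squared-exponential GP to measured (features, activity) pairs.

    The observed mean of ``y`` is used as the (constant) prior mean, so far
    from the data the predictive reverts to it with standard deviation equal
    to the prior ``amplitude``.  With ``noise_sd == 0`` the posterior mean
    interpolates the training targets.
    """
    hp = hyperparams or GPHyperparams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must have matching first dimension")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 measurements to fit a surrogate")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in training data")
    kernel = ConstantKernel(
        hp.amplitude**2,
        constant_value_bounds="fixed" if not hp.optimize else (1e-4, 1e4),
    ) * RBF(
        hp.length_scale,
        length_scale_bounds="fixed" if not hp.optimize else (1e-3, 1e3),
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=hp.noise_sd**2 + hp.jitter,
        optimizer="fmin_l_bfgs_b" if hp.optimize else None,
        n_restarts_optimizer=2 if hp.optimize else 0,
        normalize_y=False,
        random_state=0,
    )
    y_mean = float(y.mean())
    try:
        gpr.fit(X, y - y_mean)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise HeloError(
            f"kernel matrix is singular ({exc}); increase the jitter"
        ) from exc
    return Surrogate(gpr, y_mean)


def _as_float_arrays(*vals):
    arrays = [np.asarray(v, dtype=float) for v in vals]
    scalar = all(a.ndim == 0 for a in arrays)
    return [np.atleast_1d(a) for a in arrays], scalar


def acq_mpi(mu, sigma, y_kbest) -> Union[float, np.ndarray]:
    """Probability of improvement: P(Y > y_kbest) for Y ~ N(mu, sigma²).

    σ == 0 is treated as a point mass: 1 if mu > y_kbest else 0.
    """
    (mu, sigma, y_kbest), scalar = _as_float_arrays(mu, sigma, y_kbest)
    if (sigma < 0).any():
        raise ValidationError("sigma must be nonnegative")
    z = np.divide(mu - y_kbest, sigma, out=np.zeros_like(mu), where=sigma > 0)
    out = np.where(sigma > 0, ndtr(z), (mu > y_kbest).astype(float))
    return float(out[0]) if scalar else out


def acq_mei(mu, sigma, y_kbest) -> Union[float, np.ndarray]:
    """Expected improvement E[max(Y − y_kbest, 0)] for Y ~ N(mu, sigma²).

    Closed form (mu − y)Φ(z) + σφ(z) with z = (mu − y)/σ; the σ == 0 limit is
    max(mu − y_kbest, 0).
    """
    (mu, sigma, y_kbest), scalar = _as_float_arrays(mu, sigma, y_kbest)
    if (sigma < 0).any():
        raise ValidationError("sigma must be nonnegative")
    diff = mu - y_kbest
    z = np.divide(diff, sigma, out=np.zeros_like(mu), where=sigma > 0)
    pdf = np.exp(-0.5 * z**2) / _SQRT_2PI
    ei = diff * ndtr(z) + sigma * pdf
    out = np.where(sigma > 0, ei, np.maximum(diff, 0.0))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def acq_optimistic(mu, sigma, beta: float = 2.0) -> Union[float, np.ndarray]:
    """Confidence-bound score μ + β·σ (optimism under uncertainty)."""
    (mu, sigma), scalar = _as_float_arrays(mu, sigma)
    if (sigma < 0).any():
        raise ValidationError("sigma must be nonnegative")
    if beta < 0:
        raise ValidationError("beta must be nonnegative")
    out = mu + beta * sigma
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class IterationRecord:
    """One model-guided pick: acquisition score plus improvement probabilities.

    ``p_improve_bootstrap`` (P1): probability the pick beats the best
    bootstrap compound.  ``p_improve_current`` (P2): probability it beats the
    current best measured value.  ``p_max_remaining`` (P3): the highest
    probability of beating the current k-th best among all untested
    compounds.  All are None for the random strategy, which never consults
    the surrogate.
    """

    n_measured: int
    selected_id: str
    score: Optional[float] = None
    p_improve_bootstrap: Optional[float] = None
    p_improve_current: Optional[float] = None
    p_max_remaining: Optional[float] = None


@dataclass
class ActiveRunResult:
    strategy: str
    k: int
    bootstrap_ids: List[str]
    records: List[IterationRecord]
    measured: Dict[str, float]
    best_trajectory: List[float]
    kth_best_trajectory: List[float]

    @property
    def top_k(self) -> List[float]:
        """The k best measured activities, descending."""
        return sorted(self.measured.values(), reverse=True)[: self.k]

    @property
    def best_found(self) -> float:
        return max(self.measured.values())

    @property
    def kth_best_found(self) -> float:
        return self.top_k[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per model-guided iteration (columns mirror a run log)."""
        return pd.DataFrame(
            {
                "n_measured": [r.n_measured for r in self.records],
                "selected_id": [r.selected_id for r in self.records],
                "score": [r.score for r in self.records],
                "P1": [r.p_improve_bootstrap for r in self.records],
                "P2": [r.p_improve_current for r in self.records],
                "P3": [r.p_max_remaining for r in self.records],
            }
        )


def _kth_largest(values: Sequence[float], k: int) -> float:
    return sorted(values, reverse=True)[k - 1]


def run_active_optimization(
    library: CompoundLibrary,
    strategy: str,
    k: int = 1,
    budget: int = 60,
    bootstrap_n: int = 10,
    seed: int = 0,
    hyperparams: Optional[GPHyperparams] = None,
    beta: float = 2.0,
) -> ActiveRunResult:
    """Run one active-screening campaign on a (synthetic) library.

    Measures ``bootstrap_n`` random compounds, then model-guided picks until
    ``budget`` compounds are measured in total.  The input library is not
    mutated; measurements are simulated from its hidden true activities.
    Identical seeds give identical bootstrap samples across strategies, so
    runs differ only through the selection rule.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    if budget < bootstrap_n:
        raise ValidationError("budget must be at least bootstrap_n")
    if budget > len(library):
        raise ValidationError(
            f"budget {budget} exceeds library size {len(library)}"
        )
    if not 1 <= k <= bootstrap_n:
        raise ValidationError("k must satisfy 1 <= k <= bootstrap_n")
    rng = np.random.default_rng(seed)
    ids = library.compound_ids
    n = len(library)

    measured: Dict[str, float] = {}
    measured_idx: List[int] = []
    best_traj: List[float] = []
    kth_traj: List[float] = []

    def measure(i: int) -> None:
        cid = ids[i]
        measured[cid] = library.assay(cid)
        measured_idx.append(i)
        vals = list(measured.values())
        best_traj.append(max(vals))
        kth_traj.append(
            _kth_largest(vals, k) if len(vals) >= k else float("nan")
        )

    boot = rng.choice(n, size=bootstrap_n, replace=False)
    for i in boot:
        measure(int(i))
    bootstrap_ids = [ids[int(i)] for i in boot]
    best_bootstrap = max(measured.values())

    records: List[IterationRecord] = []
    while len(measured) < budget:
        untested = np.array(
            [i for i in range(n) if ids[i] not in measured], dtype=int
        )
        n_known = len(measured)
        if strategy == "random":
            pick = int(rng.choice(untested))
            records.append(IterationRecord(n_known, ids[pick]))
            measure(pick)
            continue
        X_train = library.features[measured_idx]
        y_train = np.array([measured[ids[i]] for i in measured_idx])
        surrogate = fit_surrogate(X_train, y_train, hyperparams)
        mu, sd = surrogate.predict(library.features[untested])
        y_kbest = _kth_largest(list(measured.values()), k)
        if strategy == "mpi":
            scores = acq_mpi(mu, sd, y_kbest)
        elif strategy == "mei":
            scores = acq_mei(mu, sd, y_kbest)
        else:
            scores = acq_optimistic(mu, sd, beta)
        j = int(np.argmax(scores))  # first max -> lowest compound index
        pick = int(untested[j])
        p_improve = acq_mpi(mu, sd, y_kbest)
        records.append(
            IterationRecord(
                n_measured=n_known,
                selected_id=ids[pick],
                score=float(scores[j]),
                p_improve_bootstrap=float(acq_mpi(mu[j], sd[j], best_bootstrap)),
                p_improve_current=float(
                    acq_mpi(mu[j], sd[j], max(measured.values()))
                ),
                p_max_remaining=float(np.max(p_improve)),
            )
        )
        measure(pick)

    return ActiveRunResult(
        strategy=strategy,
        k=k,
        bootstrap_ids=bootstrap_ids,
        records=records,
        measured=measured,
        best_trajectory=best_traj,
        kth_best_trajectory=kth_traj,
    )


def compare_strategies(
    library_generator: Callable[[int], CompoundLibrary],
    strategies: Sequence[str] = STRATEGIES,
    reps: int = 20,
    seeds: Optional[Sequence[int]] = None,
    k: int = 1,
    budget: int = 60,
    bootstrap_n: int = 10,
    checkpoints: Optional[Sequence[int]] = None,
    hyperparams: Optional[GPHyperparams] = None,
) -> pd.DataFrame:
    """Average strategy performance over repeated campaigns.

    Each repetition draws a fresh library from ``library_generator(seed)``
    and runs every strategy with the same seed (hence the same bootstrap
    sample).  Returns a tidy frame with mean and standard deviation of the
    best-found and k-th-best-found activity per strategy per budget
    checkpoint.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    seeds = list(seeds) if seeds is not None else list(range(reps))
    if len(seeds) != reps:
        raise ValidationError("need exactly one seed per repetition")
    checkpoints = sorted(checkpoints) if checkpoints else [budget]
    if checkpoints[-1] > budget:
        raise ValidationError("checkpoints cannot exceed the budget")

    rows = []
    for strategy in strategies:
        # best[c][r]: running best at checkpoint c in repetition r
        best = {c: [] for c in checkpoints}
        kth = {c: [] for c in checkpoints}
        for seed in seeds:
            library = library_generator(seed)
            result = run_active_optimization(
                library, strategy, k=k, budget=budget,
                bootstrap_n=bootstrap_n, seed=seed, hyperparams=hyperparams,
            )
            for c in checkpoints:
                best[c].append(result.best_trajectory[c - 1])
                kth[c].append(result.kth_best_trajectory[c - 1])
        for c in checkpoints:
            rows.append(
                {
                    "strategy": strategy,
                    "budget": c,
                    "best_mean": float(np.mean(best[c])),
                    "best_std": float(np.std(best[c], ddof=1)) if reps > 1 else 0.0,
                    "kth_best_mean": float(np.nanmean(kth[c])),
                    "kth_best_std": (
                        float(np.nanstd(kth[c], ddof=1)) if reps > 1 else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)
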