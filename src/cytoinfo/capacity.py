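"""Channel capacity of the dose -> response channel.

Capacity is the maximum of MI(S; R) over input distributions p(S), with
the finite applied dose set as the input alphabet; 2**CC is the number of
dose states the response can reliably distinguish.  Two estimation routes
are provided:

* an exact Blahut–Arimoto solver on a discretised channel (response
  binned by pooled quantiles) — the package's oracle and default 1-D path;
* a statistical-learning estimator for continuous, possibly multivariate
  responses: a regularised multinomial logistic classifier predicts the
  dose from the response, its per-cell posteriors stand in for the
  likelihood ratios, and a Blahut–Arimoto-type fixed point on those
  posteriors maximises the Monte-Carlo MI over the input simplex.

``capacity_var`` gives the decoder the stimulus-independent expression
covariate alongside the response, removing the blur that expression
heterogeneity adds to the dose-response mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .data import ChannelDataset, truncate_heterogeneity, validate_cells
from .exceptions import DegenerateDataError, ParameterError
from .mi import transform_values

__all__ = [
    "BlahutArimotoResult",
    "CapacityEstimate",
    "DiscreteChannel",
    "DiscreteChannelCapacity",
    "LogisticCapacity",
    "blahut_arimoto",
    "build_discrete_channel",
    "capacity_basic",
    "capacity_var",
    "estimate_cc_classifier",
    "truncation_capacity_sweep",
]

_EPS = 1e-300


@dataclass
class DiscreteChannel:
    """A discrete memoryless channel: inputs, output bins, row-stochastic matrix."""

    inputs: np.ndarray
    outputs: np.ndarray
    transition: np.ndarray

    def validate(self) -> "DiscreteChannel":
        t = np.asarray(self.transition, dtype=float)
        if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
            raise ParameterError("channel needs >= 2 inputs and >= 2 outputs")
        if (t < 0).any():
            raise ParameterError("transition probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ParameterError("transition matrix rows must sum to 1")
        return self


@dataclass
class CapacityEstimate:
    """Channel capacity in bits with the maximising input distribution."""

    cc_bits: float
    optimal_input: np.ndarray
    estimator: str
    converged: bool
    iterations: int
    tolerance_bits: float
    input_levels: np.ndarray = field(default_factory=lambda: np.array([]))
    bootstrap_sd: float = np.nan

    @property
    def distinguishable_states(self) -> float:
        return float(2.0 ** self.cc_bits)


# alias kept for callers that think of the solver output rather than the estimate
BlahutArimotoResult = CapacityEstimate


def blahut_arimoto(
    channel: DiscreteChannel | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> CapacityEstimate:
    """Capacity of a discrete memoryless channel by alternating maximisation.

    Starts from the uniform input distribution and iterates the classic
    update ``p_s <- p_s * 2**D_s / Z`` where ``D_s`` is the KL divergence
    (bits) of row ``s`` from the current output distribution.  At every
    iteration ``max_s D_s`` upper-bounds capacity and ``sum_s p_s D_s``
    lower-bounds it; iteration stops when the gap drops below ``tol`` bits.
    """
    if isinstance(channel, DiscreteChannel):
        channel.validate()
        P = np.asarray(channel.transition, dtype=float)
        inputs = np.asarray(channel.inputs)
    else:
        P = np.asarray(channel, dtype=float)
        channel = DiscreteChannel(np.arange(P.shape[0]), np.arange(P.shape[1]), P)
        channel.validate()
        inputs = channel.inputs

    k = P.shape[0]
    p = np.full(k, 1.0 / k)
    logP = np.log2(P + _EPS)
    cc = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = p @ P
        # KL(P_s || q) in bits, rows with P=0 contribute 0
        D = np.einsum("sj,sj->s", P, logP - np.log2(q + _EPS))
        lower = float(p @ D)
        upper = float(D.max())
        cc = lower
        if upper - lower < tol:
            converged = True
            break
        p = p * np.exp2(D - D.max())
        p /= p.sum()
    return CapacityEstimate(
        cc_bits=max(cc, 0.0),
        optimal_input=p,
        estimator="blahut_arimoto",
        converged=converged,
        iterations=it,
        tolerance_bits=tol,
        input_levels=inputs,
    )


# ---------------------------------------------------------------------------
# discretisation


def build_discrete_channel(
    dataset: ChannelDataset,
    response_features: tuple[str, ...] = ("response",),
    bins: int = 20,
    binning: str = "equal_frequency",
    alpha: float = 0.5,
) -> DiscreteChannel:
    """Discretise the empirical conditional response distributions.

    Bin edges are computed on the pooled response (per feature for the
    multivariate case, which uses a product quantile grid); each input
    level's cells are histogrammed over the bins, smoothed with an
    additive pseudocount ``alpha`` per bin, and row-normalised.
    """
    dataset.require_channel()
    feats = list(response_features)
    X, y = dataset.samples(feats)
    k = len(dataset.input_levels)
    if (dataset.counts == 0).any():
        raise ParameterError("every input level needs at least one cell")

    if len(feats) == 1:
        nb = bins
    else:
        # product grid: `bins` quantile bins per feature
        nb = bins ** len(feats)
    codes = np.zeros(len(X), dtype=int)
    for j in range(X.shape[1]):
        v = X[:, j]
        if binning == "equal_frequency":
            edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
        elif binning == "equal_width":
            edges = np.linspace(v.min(), v.max(), bins + 1)[1:-1]
        else:
            raise ParameterError(f"unknown binning {binning!r}")
        codes = codes * bins + np.searchsorted(edges, v, side="right")

    transition = np.zeros((k, nb))
    for s in range(k):
        counts = np.bincount(codes[y == s], minlength=nb).astype(float)
        counts += alpha
        transition[s] = counts / counts.sum()
    return DiscreteChannel(
        inputs=dataset.input_levels, outputs=np.arange(nb), transition=transition
    ).validate()


class DiscreteChannelCapacity(BaseEstimator):
    """Capacity via discretisation plus exact Blahut–Arimoto.

    ``fit(X, y)`` takes response features ``X`` (n_cells, n_features) and
    integer input labels ``y``; 1-D responses use ``bins`` quantile bins,
    multivariate ones a per-feature product quantile grid.

    Attributes: ``capacity_bits_``, ``optimal_input_``, ``converged_``,
    ``n_iter_``, ``estimate_``.
    """

    def __init__(
        self,
        bins: int = 20,
        binning: str = "equal_frequency",
        alpha: float = 0.5,
        tol: float = 1e-8,
        max_iter: int = 10_000,
        transform: str | None = None,
    ):
        self.bins = bins
        self.binning = binning
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.transform = transform

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and np.asarray(y).size != 1:
            X = X.T
        X = transform_values(X, self.transform)
        y = np.asarray(y)
        levels, codes = np.unique(y, return_inverse=True)
        if len(levels) < 2:
            raise ParameterError("capacity needs >= 2 input levels")
        # bins per feature: keep the product grid near `bins` cells total
        bins = self.bins if X.shape[1] == 1 else max(2, int(round(self.bins ** (1 / X.shape[1]))))
        k = len(levels)
        nb = bins ** X.shape[1]
        allcodes = np.zeros(len(X), dtype=int)
        for j in range(X.shape[1]):
            v = X[:, j]
            if self.binning == "equal_frequency":
                edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
            else:
                edges = np.linspace(v.min(), v.max(), bins + 1)[1:-1]
            allcodes = allcodes * bins + np.searchsorted(edges, v, side="right")
        transition = np.zeros((k, nb))
        for s in range(k):
            counts = np.bincount(allcodes[codes == s], minlength=nb).astype(float)
            counts += self.alpha
            transition[s] = counts / counts.sum()
        res = blahut_arimoto(
            DiscreteChannel(levels, np.arange(nb), transition), self.tol, self.max_iter
        )
        self.capacity_bits_ = res.cc_bits
        self.optimal_input_ = res.optimal_input
        self.converged_ = res.converged
        self.n_iter_ = res.iterations
        self.input_levels_ = levels
        self.estimate_ = res
        return self

    def score(self, X=None, y=None) -> float:
        return self.capacity_bits_


# ---------------------------------------------------------------------------
# classifier-based estimator


class LogisticCapacity(BaseEstimator):
    """Statistical-learning capacity estimator for continuous responses.

    The estimator (1) fits a ridge-regularised multinomial logistic
    regression predicting the input level from basis-expanded response
    features under the empirical input frequencies, picking the ridge
    strength from a small grid by held-out log-loss; (2) treats the
    per-cell posteriors as estimates of p(s | x) and evaluates, for any
    candidate input distribution p, the Monte-Carlo MI as the average
    log2 ratio of the reweighted posterior to the prior; (3) maximises
    over the simplex with the Blahut–Arimoto fixed point applied to the
    per-cell posteriors.

    Parameters
    ----------
    basis : {"linear", "quadratic", "spline"}
        Feature expansion before the linear classifier; "quadratic" is the
        default and adds squares and cross terms.
    Cs : tuple of float
        Inverse-regularisation grid for the logistic fit.
    transform : {None, "raw", "log10", "arcsinh"}
        Monotone transform applied to features first.
    n_boot : int
        Optional bootstrap resamples (over cells) for a capacity spread.
    tol, max_iter : Blahut–Arimoto stopping rule on the posterior channel.

    Attributes
    ----------
    capacity_bits_ : float
    optimal_input_ : ndarray
    converged_ : bool
        False when the optimisation did not close its bound gap or the
        classifier degenerated (some level received ~zero posterior mass
        everywhere).
    n_iter_ : int
    bootstrap_sd_ : float (nan unless ``n_boot > 0``)
    """

    def __init__(
        self,
        basis: str = "quadratic",
        Cs: tuple[float, ...] = (0.1, 1.0, 10.0),
        transform: str | None = None,
        n_boot: int = 0,
        tol: float = 1e-6,
        max_iter: int = 5_000,
        random_state: int | None = 0,
    ):
        self.basis = basis
        self.Cs = Cs
        self.transform = transform
        self.n_boot = n_boot
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _pipeline(self, C: float):
        if self.basis == "linear":
            expand = PolynomialFeatures(degree=1, include_bias=False)
        elif self.basis == "quadratic":
            expand = PolynomialFeatures(degree=2, include_bias=False)
        elif self.basis == "spline":
            from sklearn.preprocessing import SplineTransformer

            expand = SplineTransformer(n_knots=5, degree=3)
        else:
            raise ParameterError(f"unknown basis {self.basis!r}")
        clf = LogisticRegression(C=C, max_iter=500)
        return make_pipeline(expand, StandardScaler(), clf)

    @staticmethod
    def _posterior_capacity(post: np.ndarray, y: np.ndarray, p0: np.ndarray, tol: float, max_iter: int):
        """Blahut–Arimoto on per-cell posteriors.

        ``post[i, s]`` estimates p(s | x_i) under the training prior
        ``p0``; samples are grouped by their true level ``y``.  For input
        distribution p the per-level divergence is
        ``D_s = E_{x~s}[ log2( p_s(s|x) / p_s ) ]`` with
        ``p_s(s|x) ∝ post * p/p0`` — the Monte-Carlo analogue of
        KL(P(.|s) || output distribution).
        """
        n, k = post.shape
        idx = [np.flatnonzero(y == s) for s in range(k)]
        p = np.full(k, 1.0 / k)
        ratio_base = np.maximum(post, 1e-15) / p0[None, :]
        # D_s = E_{i~s}[log2 ratio(i,s)] - E_{i~s}[log2 sum_t ratio(i,t) p_t]
        # so the per-iteration work is one matvec and n logs
        log_ratio = np.log2(ratio_base)
        own_mean = np.array(
            [log_ratio[ids, s].mean() if len(ids) else 0.0 for s, ids in enumerate(idx)]
        )
        cc, it, converged = 0.0, 0, False
        for it in range(1, max_iter + 1):
            logZ = np.log2(ratio_base @ p)
            D = own_mean - np.array(
                [logZ[ids].mean() if len(ids) else 0.0 for ids in idx]
            )
            lower = float(p @ D)
            upper = float(D.max())
            cc = lower
            if upper - lower < tol:
                converged = True
                break
            p = p * np.exp2(D - D.max())
            p /= p.sum()
        return max(cc, 0.0), p, it, converged

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = transform_values(X, self.transform)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise DegenerateDataError("response features contain non-finite values")
        levels, codes = np.unique(y, return_inverse=True)
        k = len(levels)
        if k < 2:
            raise ParameterError("capacity needs >= 2 input levels")
        p0 = np.bincount(codes, minlength=k) / len(codes)

        # ridge strength by held-out log-loss on a single stratified split;
        # selection runs on a subsample — it only has to rank the grid
        if len(self.Cs) > 1:
            Xs, cs = X, codes
            if len(codes) > 8_000:
                rng = np.random.default_rng(self.random_state)
                take = rng.choice(len(codes), size=8_000, replace=False)
                Xs, cs = X[take], codes[take]
            Xtr, Xte, ytr, yte = train_test_split(
                Xs, cs, test_size=0.25, random_state=self.random_state, stratify=cs
            )
            losses = []
            for C in self.Cs:
                pipe = self._pipeline(C).fit(Xtr, ytr)
                losses.append(log_loss(yte, pipe.predict_proba(Xte), labels=np.arange(k)))
            best_C = self.Cs[int(np.argmin(losses))]
        else:
            best_C = self.Cs[0]
        self.C_ = best_C

        pipe = self._pipeline(best_C).fit(X, codes)
        post = pipe.predict_proba(X)
        degenerate = bool((post.max(axis=0) < 1e-6).any())

        cc, p_opt, it, converged = self._posterior_capacity(
            post, codes, p0, self.tol, self.max_iter
        )
        if degenerate:
            converged = False
            warnings.warn("classifier degenerate: an input level is never predicted", stacklevel=2)

        boot_sd = np.nan
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            vals = []
            for _ in range(self.n_boot):
                take = rng.integers(0, len(codes), size=len(codes))
                cc_b, _, _, _ = self._posterior_capacity(
                    post[take], codes[take], p0, self.tol, self.max_iter
                )
                vals.append(cc_b)
            boot_sd = float(np.std(vals, ddof=1))

        self.classifier_ = pipe
        self.capacity_bits_ = float(cc)
        self.optimal_input_ = p_opt
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.input_levels_ = levels
        self.bootstrap_sd_ = boot_sd
        self.estimate_ = CapacityEstimate(
            cc_bits=float(cc),
            optimal_input=p_opt,
            estimator="classifier",
            converged=bool(converged),
            iterations=it,
            tolerance_bits=self.tol,
            input_levels=levels,
            bootstrap_sd=boot_sd,
        )
        return self

    def score(self, X=None, y=None) -> float:
        return self.capacity_bits_


# ---------------------------------------------------------------------------
# wrappers on cell tables


def _make_estimator(estimator: str, transform, params: dict):
    if estimator in ("classifier", "logistic"):
        return LogisticCapacity(transform=transform, **params)
    if estimator in ("ba", "blahut_arimoto", "discrete"):
        return DiscreteChannelCapacity(transform=transform, **params)
    raise ParameterError(f"unknown capacity estimator {estimator!r}")


def estimate_cc_classifier(
    dataset: ChannelDataset,
    response_features: tuple[str, ...] = ("response",),
    basis: str = "quadratic",
    regularization: tuple[float, ...] = (0.1, 1.0, 10.0),
    n_boot: int = 0,
    seed: int | None = 0,
    transform: str | None = "log10",
) -> CapacityEstimate:
    """Classifier-based capacity of a channel dataset (functional wrapper)."""
    dataset.require_channel()
    X, y = dataset.samples(response_features)
    est = LogisticCapacity(
        basis=basis, Cs=regularization, n_boot=n_boot, random_state=seed, transform=transform
    ).fit(X, y)
    return est.estimate_


def capacity_basic(
    dataset: ChannelDataset,
    estimator: str = "classifier",
    transform: str | None = "log10",
    **params,
) -> CapacityEstimate:
    """Capacity using the response alone as the decoder's observable."""
    dataset.require_channel()
    X, y = dataset.samples(("response",))
    return _make_estimator(estimator, transform, params).fit(X, y).estimate_


def capacity_var(
    dataset: ChannelDataset,
    estimator: str = "classifier",
    transform: str | None = "log10",
    **params,
) -> CapacityEstimate:
    """Capacity with the expression covariate available to the decoder.

    The decoder conditions on the stimulus-independent expression level
    alongside the response, which removes the dose-response blur caused by
    expression heterogeneity. Requires the classifier estimator (the
    discretised path falls back to a 2-D product-quantile grid).
    """
    dataset.require_channel()
    X, y = dataset.samples(("response", "expression"))
    if estimator in ("ba", "blahut_arimoto", "discrete"):
        params.setdefault("bins", 144)  # 12x12 product grid
    return _make_estimator(estimator, transform, params).fit(X, y).estimate_


def truncation_capacity_sweep(
    cells: pd.DataFrame,
    residuals: tuple[float, ...] = (1.0, 0.9, 0.7, 0.5, 0.3, 0.15),
    estimator: str = "classifier",
    per_replicate: bool = True,
    min_cells_per_level: int = 50,
    transform: str | None = "log10",
    **params,
) -> pd.DataFrame:
    """Capacity basic and var after truncating expression heterogeneity.

    For each residual-variability level, cells outside the central
    expression band are excluded (per replicate when ``per_replicate``),
    and both capacities are computed on the truncated stratum.  Returns a
    tidy frame keyed by (residual, replicate) with across-replicate
    summaries obtainable by grouping.
    """
    validate_cells(cells)
    reps = sorted(cells["replicate"].unique()) if per_replicate else [None]
    rows = []
    for residual in residuals:
        for rep in reps:
            sub = cells if rep is None else cells[cells["replicate"] == rep]
            trunc = truncate_heterogeneity(sub, residual)
            counts = trunc.groupby("dose").size()
            if (counts < min_cells_per_level).any():
                warnings.warn(
                    f"residual={residual}, replicate={rep}: a dose level has fewer than "
                    f"{min_cells_per_level} cells after truncation; row skipped",
                    stacklevel=2,
                )
                rows.append(
                    dict(residual=residual, replicate=rep, skipped=True,
                         capacity_basic=np.nan, capacity_var=np.nan)
                )
                continue
            ds = ChannelDataset.from_cells(trunc)
            cb = capacity_basic(ds, estimator=estimator, transform=transform, **params)
            cv = capacity_var(ds, estimator="classifier", transform=transform, **params)
            rows.append(
                dict(
                    residual=residual,
                    replicate=rep,
                    skipped=False,
                    capacity_basic=cb.cc_bits,
                    capacity_var=cv.cc_bits,
                    n_cells=len(trunc),
                )
            )
    return pd.DataFrame(rows)
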