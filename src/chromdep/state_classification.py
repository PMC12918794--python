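"""Melanoma differentiation-state scoring and binary class assignment.

Seven per-state signature scores (mean z-scored expression), a single
differentiation axis (melanocytic aggregate minus undifferentiated
aggregate), and a two-component 1-D Gaussian mixture whose analytic
density-intersection boundary provides the classification threshold.
The mixture machinery here is reused verbatim by single-cell gating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: The seven ordered transcriptional states, melanocytic to undifferentiated.
STATES = (
    "melanocytic",
    "transitory-melanocytic",
    "transitory",
    "neural crest-like-transitory",
    "neural crest-like",
    "undifferentiated-neural crest-like",
    "undifferentiated",
)

MELANOCYTIC_AGGREGATE = ("melanocytic", "transitory-melanocytic", "transitory")
UNDIFFERENTIATED_AGGREGATE = (
    "neural crest-like",
    "undifferentiated-neural crest-like",
    "undifferentiated",
)

MELANOCYTIC_LIKE = "melanocytic_like"
UNDIFFERENTIATED_NCL = "undifferentiated_ncl"


@dataclass
class StateSignature:
    """Signature gene -> one of the seven states."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.assignments.values() if s not in STATES}
        if bad:
            raise FormatError(f"unrecognized state labels: {sorted(bad)}")

    def genes_for(self, state: str) -> list[str]:
        return [g for g, s in self.assignments.items() if s == state]


@dataclass
class GmmFit1D:
    """Two-component 1-D Gaussian mixture, components ordered mu1 < mu2."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    boundary: float | None
    n_iter: int
    converged: bool
    seed: int | None = None

    def component_density(self, x: np.ndarray, k: int) -> np.ndarray:
        w, mu, sd = self.weights[k], self.means[k], self.sds[k]
        return w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))

    def posterior_high(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of the higher-mean component."""
        d0 = self.component_density(np.asarray(x, dtype=float), 0)
        d1 = self.component_density(np.asarray(x, dtype=float), 1)
        total = d0 + d1
        # In far tails both densities underflow; fall back to the nearest mean.
        with np.errstate(invalid="ignore"):
            post = np.where(total > 0, d1 / np.where(total > 0, total, 1.0),
                            (np.asarray(x) > (self.means[0] + self.means[1]) / 2).astype(float))
        return post


def read_signature(path: str | Path) -> StateSignature:
    """Read a signature CSV with columns gene, state."""
    df = pd.read_csv(path, dtype=str)
    if not {"gene", "state"}.issubset(df.columns):
        raise FormatError("signature CSV needs columns gene, state")
    if df["gene"].duplicated().any():
        raise FormatError("a signature gene maps to more than one state")
    return StateSignature(dict(zip(df["gene"], df["state"])))


def state_scores(expr, sig: StateSignature) -> pd.DataFrame:
    """Seven state scores per cell line: mean z-scored signature expression.

    Each signature gene is z-scored (sample sd) across cell lines; genes
    absent from the matrix or with zero variance are dropped with a log entry.
    """
    data = expr.data  # genes x samples
    present = [g for g in sig.assignments if g in data.index]
    missing = len(sig.assignments) - len(present)
    if missing:
        logger.info("%d signature genes absent from expression matrix", missing)
    sub = data.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("dropping %d zero-variance signature genes", int(degenerate.sum()))
        sub = sub.loc[~degenerate]
        sd = sd[~degenerate]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    scores = {}
    for state in STATES:
        genes = [g for g in sig.genes_for(state) if g in z.index]
        if not genes:
            raise DataError(f"state {state!r} has no usable signature genes")
        scores[state] = z.loc[genes].mean(axis=0)
    out = pd.DataFrame(scores, columns=list(STATES))
    out.index.name = "cell_line_id"
    return out


def diff_axis(scores: pd.DataFrame) -> pd.DataFrame:
    """Append melanocytic/undifferentiated aggregates and DiffAxis."""
    out = scores.copy()
    out["melanocytic_aggregate"] = scores[list(MELANOCYTIC_AGGREGATE)].mean(axis=1)
    out["undifferentiated_aggregate"] = scores[list(UNDIFFERENTIATED_AGGREGATE)].mean(axis=1)
    out["diff_axis"] = out["melanocytic_aggregate"] - out["undifferentiated_aggregate"]
    return out


def fit_gmm_1d(x: np.ndarray, seed: int | None = None, max_iter: int = 1000,
               tol: float = 1e-8, restarts: int = 0) -> GmmFit1D:
    """EM fit of a two-component Gaussian mixture to 1-D data.

    Deterministic median-split initialization; optional random restarts use a
    generator seeded from ``seed``. Components are ordered by mean and a
    variance floor of 1e-6 * var(x) prevents collapse.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in mixture input")
    if x.size < 4:
        raise DataError("need at least four observations")
    if np.all(x == x[0]):
        raise DataError("degenerate input: all observations identical")

    var_floor = 1e-6 * float(np.var(x))
    inits = [_median_split_init(x)]
    if restarts:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            mus = rng.choice(x, size=2, replace=False)
            inits.append((np.array([0.5, 0.5]), np.sort(mus),
                          np.full(2, max(float(np.std(x)), math.sqrt(var_floor)))))

    best: GmmFit1D | None = None
    for pi, mu, sd in inits:
        fit = _em(x, pi.copy(), mu.copy(), sd.copy(), var_floor, max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.seed = seed
    try:
        best.boundary = gmm_boundary(best)
    except DataError:
        best.boundary = None
    return best


def _median_split_init(x: np.ndarray):
    med = np.median(x)
    lo = x[x <= med]
    hi = x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = np.sort(x)[: x.size // 2], np.sort(x)[x.size // 2:]
    sd_floor = max(float(np.std(x)) * 1e-3, 1e-12)
    return (
        np.array([lo.size / x.size, hi.size / x.size]),
        np.array([lo.mean(), hi.mean()]),
        np.array([max(lo.std(), sd_floor), max(hi.std(), sd_floor)]),
    )


def _em(x, pi, mu, sd, var_floor, max_iter, tol) -> GmmFit1D:
    n = x.size
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for tail robustness
        log_comp = np.stack([
            np.log(pi[k]) - np.log(sd[k]) - 0.5 * math.log(2 * math.pi)
            - 0.5 * ((x - mu[k]) / sd[k]) ** 2
            for k in range(2)
        ])
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        pi = nk / n
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
        if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    order = np.argsort(mu)
    return GmmFit1D(
        weights=(float(pi[order[0]]), float(pi[order[1]])),
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        log_likelihood=ll_prev,
        boundary=None,
        n_iter=it,
        converged=converged,
    )


def gmm_boundary(fit: GmmFit1D) -> float:
    """Intersection of the two weighted component densities between the means.

    Solves the quadratic from equating the weighted log-densities; if no root
    lies strictly between the means, falls back to the posterior-0.5 crossing
    located by bisection on (mu1, mu2).
    """
    (pi1, pi2), (mu1, mu2), (sd1, sd2) = fit.weights, fit.means, fit.sds
    if mu1 == mu2 and sd1 == sd2:
        raise DataError("identical components have no decision boundary")
    a = 1.0 / (2 * sd2**2) - 1.0 / (2 * sd1**2)
    b = mu1 / sd1**2 - mu2 / sd2**2
    c = (mu2**2 / (2 * sd2**2) - mu1**2 / (2 * sd1**2)
         + math.log(pi1) - math.log(pi2) + math.log(sd2) - math.log(sd1))
    roots: list[float] = []
    if abs(a) < 1e-300:
        if b != 0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if mu1 < r < mu2]
    if inside:
        return min(inside, key=lambda r: abs(r - (mu1 + mu2) / 2))
    # fall back: posterior-0.5 crossing by bisection
    lo, hi = mu1, mu2
    f = lambda t: fit.component_density(np.array([t]), 0)[0] - fit.component_density(np.array([t]), 1)[0]
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DataError("no density crossing between component means")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0:
            return mid
        if flo * fm < 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def assign_classes(profile: pd.DataFrame, fit: GmmFit1D,
                   axis_column: str = "diff_axis") -> pd.DataFrame:
    """Assign binary classes by posterior component membership.

    The higher-mean component is labeled melanocytic-like; exact ties at the
    boundary (posterior 0.5) go to the higher-mean component.
    """
    out = profile.copy()
    post_high = fit.posterior_high(out[axis_column].to_numpy())
    out["posterior_melanocytic"] = post_high
    out["assigned_class"] = np.where(post_high >= 0.5, MELANOCYTIC_LIKE, UNDIFFERENTIATED_NCL)
    out["boundary"] = fit.boundary
    return out


def classify_lines(expr, sig: StateSignature, seed: int | None = None) -> tuple[pd.DataFrame, GmmFit1D]:
    """Full stage: state scores -> DiffAxis -> GMM -> class labels."""
    profile = diff_axis(state_scores(expr, sig))
    fit = fit_gmm_1d(profile["diff_axis"].to_numpy(), seed=seed)
    return assign_classes(profile, fit), fit
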