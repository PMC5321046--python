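"""Multivariate adaptive regression splines (MARS) with sample-count knot constraints.

The engine fits a response ``y`` as a linear combination of basis functions

    f(X) = theta_0 + sum_m theta_m * B_m(X)

where each ``B_m`` is a product of hinge functions ``(x - t)+`` / ``(t - x)+``
with a knot at value ``t``.  Fitting proceeds in two passes: a greedy forward
pass that adds reflected hinge pairs (and products with existing basis
functions) while they reduce the residual sum of squares, and a backward pass
that deletes one basis function at a time, keeping the model that minimises a
generalised cross-validation (GCV) score.

Knot placement is constrained by subject counts rather than by knot spacing in
predictor units: a candidate knot needs a minimum number of observations
between itself and each end of the data, and between itself and every other
knot already placed on the same variable.  This stabilises fits near the
margins of sparsely sampled cohorts.

Binary predictors enter as plain linear terms (a hinge on a two-level variable
is affinely equivalent to a linear term, and knot-spacing constraints are
degenerate there).

An optional cubic mode replaces every hinge by a C1 piecewise-cubic that
matches the linear hinge outside a side-knot interval, preserving smoothly
varying trajectories; coefficients are refit on the cubic basis.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "HingeTerm",
    "BasisFunction",
    "FitConstraints",
    "MarsModel",
    "hinge_eval",
    "forward_pass",
    "backward_prune",
    "gcv",
    "select_penalty_cv",
    "r_squared",
    "to_cubic",
    "fit_mars",
]

_DEFAULT_PENALTY_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

# Relative tolerance below which an SSE reduction is considered zero / tied.
_REDUCTION_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Basis-function types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HingeTerm:
    """One factor of a basis function.

    ``linear=True`` marks a plain linear entry (used for binary predictors);
    ``knot`` and ``direction`` are ignored in that case.  ``t_minus`` /
    ``t_plus`` are the side knots of the cubic reformulation; they are ``None``
    for a purely linear-mode hinge.
    """

    variable: int
    knot: float = 0.0
    direction: int = 1
    linear: bool = False
    t_minus: float | None = None
    t_plus: float | None = None

    def eval(self, x: np.ndarray, cubic: bool = False) -> np.ndarray:
        if self.linear:
            return np.asarray(x, dtype=float)
        if cubic and self.t_minus is not None and self.t_plus is not None \
                and self.t_minus < self.knot < self.t_plus:
            return _cubic_hinge(np.asarray(x, dtype=float), self.knot,
                                self.direction, self.t_minus, self.t_plus)
        return hinge_eval(np.asarray(x, dtype=float), self.knot, self.direction)


@dataclass(frozen=True)
class BasisFunction:
    """Product of hinge terms; no two terms share a variable."""

    terms: tuple[HingeTerm, ...]

    def __post_init__(self) -> None:
        vs = [t.variable for t in self.terms]
        if len(set(vs)) != len(vs):
            raise ValueError("basis function reuses a variable")

    @property
    def order(self) -> int:
        return len(self.terms)

    @property
    def variables(self) -> frozenset[int]:
        return frozenset(t.variable for t in self.terms)

    def eval(self, X: np.ndarray, cubic: bool = False) -> np.ndarray:
        out = np.ones(X.shape[0])
        for t in self.terms:
            out = out * t.eval(X[:, t.variable], cubic=cubic)
        return out


@dataclass
class FitConstraints:
    """Sample-count and size constraints on the spline fit.

    max_final_funcs: basis functions retained after pruning (default 8).
    max_initial_funcs: forward-pass cap; default five times the final count.
    min_obs_between_knots: observations required strictly between two knots
        on the same variable (default 20).
    min_obs_to_edge: observations required between a knot and either end of
        the data (default 10).
    penalty: GCV knot penalty, or "cv" to select it by k-fold
        cross-validation on the data at hand.
    """

    max_final_funcs: int = 8
    max_initial_funcs: int | None = None
    min_obs_between_knots: int = 20
    min_obs_to_edge: int = 10
    penalty: float | str = "cv"
    penalty_grid: tuple[float, ...] = _DEFAULT_PENALTY_GRID
    cv_folds: int = 5
    max_interaction: int = 2
    cubic: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_initial_funcs is None:
            self.max_initial_funcs = 5 * self.max_final_funcs
        if self.max_initial_funcs < self.max_final_funcs:
            raise ValueError("max_initial_funcs must be >= max_final_funcs")
        if self.min_obs_between_knots < 1 or self.min_obs_to_edge < 1:
            raise ValueError("minimum observation counts must be >= 1")
        if self.max_interaction < 1:
            raise ValueError("max_interaction must be >= 1")

    def replace(self, **kw) -> "FitConstraints":
        return dataclasses.replace(self, **kw)


@dataclass
class MarsModel:
    """A fitted spline model: intercept + coefficient-weighted basis functions."""

    intercept: float
    coefficients: np.ndarray          # shape (M,)
    basis: list[BasisFunction]
    cubic: bool = False
    var_min: np.ndarray | None = None  # training range per predictor column
    var_max: np.ndarray | None = None
    n_vars: int = 0
    training_sse: float = np.nan
    training_r2: float = np.nan
    n_train: int = 0
    penalty: float = 0.0

    # -- evaluation ---------------------------------------------------------

    def basis_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_vars:
            raise ValueError(
                f"design matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.n_vars}")
        cols = [np.ones(X.shape[0])]
        cols.extend(b.eval(X, cubic=self.cubic) for b in self.basis)
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        B = self.basis_matrix(X)
        return B @ np.concatenate(([self.intercept], self.coefficients))

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    @property
    def n_knots(self) -> int:
        """Distinct (variable, knot) pairs over all hinge (non-linear) terms."""
        return len({(t.variable, t.knot)
                    for b in self.basis for t in b.terms if not t.linear})

    def knots_on(self, variable: int) -> list[float]:
        ks = {t.knot for b in self.basis for t in b.terms
              if not t.linear and t.variable == variable}
        return sorted(ks)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": [float(c) for c in self.coefficients],
            "basis": [[dataclasses.asdict(t) for t in b.terms] for b in self.basis],
            "cubic": bool(self.cubic),
            "var_min": None if self.var_min is None else [float(v) for v in self.var_min],
            "var_max": None if self.var_max is None else [float(v) for v in self.var_max],
            "n_vars": int(self.n_vars),
            "training_sse": float(self.training_sse),
            "training_r2": float(self.training_r2),
            "n_train": int(self.n_train),
            "penalty": float(self.penalty),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarsModel":
        basis = [BasisFunction(tuple(HingeTerm(**t) for t in terms))
                 for terms in d["basis"]]
        return cls(
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            basis=basis,
            cubic=d["cubic"],
            var_min=None if d["var_min"] is None else np.asarray(d["var_min"]),
            var_max=None if d["var_max"] is None else np.asarray(d["var_max"]),
            n_vars=d["n_vars"],
            training_sse=d["training_sse"],
            training_r2=d["training_r2"],
            n_train=d["n_train"],
            penalty=d.get("penalty", 0.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MarsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Hinge evaluation
# ---------------------------------------------------------------------------

def hinge_eval(x, knot: float, direction) -> np.ndarray | float:
    """Evaluate the hinge function ``(x - t)+`` (direction +1) or ``(t - x)+``.

    ``direction`` may be +1/-1 or the strings "+" / "-".
    """
    if direction in ("+", 1, +1):
        d = 1.0
    elif direction in ("-", -1):
        d = -1.0
    else:
        raise ValueError(f"direction must be +1 or -1, got {direction!r}")
    val = np.maximum(0.0, d * (np.asarray(x, dtype=float) - knot))
    if np.isscalar(x):
        return float(val)
    return val


def _cubic_hinge(x: np.ndarray, t: float, direction: int,
                 t_minus: float, t_plus: float) -> np.ndarray:
    """C1 piecewise-cubic hinge matching (x-t)+ outside [t_minus, t_plus]."""
    if direction < 0:
        # mirror: (t - x)+ is the positive hinge of -x about -t
        return _cubic_hinge(-x, -t, +1, -t_plus, -t_minus)
    d = t_plus - t_minus
    p = (2.0 * t_plus + t_minus - 3.0 * t) / d ** 2
    r = (2.0 * t - t_plus - t_minus) / d ** 3
    out = np.where(x >= t_plus, x - t, 0.0)
    mid = (x > t_minus) & (x < t_plus)
    xm = x[mid] - t_minus
    out[mid] = p * xm ** 2 + r * xm ** 3
    return out


# ---------------------------------------------------------------------------
# Admissible knots
# ---------------------------------------------------------------------------

def _is_binary(col: np.ndarray) -> bool:
    return np.unique(col).size == 2


def admissible_knots(col: np.ndarray, existing: Sequence[float],
                     min_between: int, min_edge: int) -> np.ndarray:
    """Observed values of ``col`` admissible as new knots.

    A value t qualifies when at least ``min_edge`` observations lie strictly
    below and strictly above it, and at least ``min_between`` observations lie
    strictly between t and every knot in ``existing`` (ties in predictor
    values count with multiplicity).
    """
    s = np.sort(col)
    n = s.size
    cand = np.unique(s)
    below = np.searchsorted(s, cand, side="left")
    above = n - np.searchsorted(s, cand, side="right")
    ok = (below >= min_edge) & (above >= min_edge)
    for t0 in existing:
        lo = np.minimum(cand, t0)
        hi = np.maximum(cand, t0)
        between = np.searchsorted(s, hi, side="left") - np.searchsorted(s, lo, side="right")
        ok &= (between >= min_between) & (cand != t0)
    return cand[ok]


# ---------------------------------------------------------------------------
# Least-squares helpers
# ---------------------------------------------------------------------------

def _lstsq_fit(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-norm least squares; returns (coefficients, SSE)."""
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _cheapest_deletion(G: np.ndarray, b: np.ndarray, current: np.ndarray,
                       protected: int = 1) -> int:
    """Position in ``current`` whose deletion least increases the OLS SSE.

    Uses the exact single-deletion identity dSSE_j = beta_j^2 / (G^-1)_jj;
    positions below ``protected`` (the intercept) are never deleted.
    """
    Gs = G[np.ix_(current, current)]
    m = len(current)
    Gs = Gs + 1e-12 * (np.trace(Gs) / m) * np.eye(m)
    try:
        Ginv = np.linalg.inv(Gs)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(Gs)
    beta = Ginv @ b[current]
    diag = np.clip(np.diag(Ginv), 1e-300, None)
    delta = beta ** 2 / diag
    return int(protected + np.argmin(delta[protected:]))


def _subset_sse(G: np.ndarray, b: np.ndarray, yty: float,
                idx: np.ndarray) -> float:
    """SSE of regressing y on the column subset ``idx`` given Gram pieces."""
    Gs = G[np.ix_(idx, idx)]
    bs = b[idx]
    try:
        c = np.linalg.solve(Gs + 1e-12 * np.trace(Gs) / max(len(idx), 1) * np.eye(len(idx)), bs)
    except np.linalg.LinAlgError:
        c = np.linalg.lstsq(Gs, bs, rcond=None)[0]
    return max(float(yty - bs @ c), 0.0)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def forward_pass(X: np.ndarray, y: np.ndarray,
                 constraints: FitConstraints | None = None) -> MarsModel:
    """Greedy constrained forward selection of hinge-pair basis functions.

    At every step the reflected hinge pair (or, for binary variables, the
    single linear term), possibly multiplied with an existing basis function
    up to ``max_interaction``, that most reduces the residual sum of squares
    is added.  Candidate knots are observed predictor values satisfying the
    edge and between-knot sample-count constraints.  Ties are broken toward
    the lowest variable index, then the smallest knot value, then the
    intercept-most parent.  Stops when no admissible candidate reduces the
    SSE or ``max_initial_funcs`` is reached.
    """
    c = constraints or FitConstraints()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * c.min_obs_to_edge + 1:
        raise ValueError(
            f"need at least {2 * c.min_obs_to_edge + 1} rows for "
            f"min_obs_to_edge={c.min_obs_to_edge}, got {n}")
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")

    binary = [bool(np.unique(X[:, j]).size <= 2) for j in range(p)]
    yty = float(y @ y)
    # a reduction must be meaningful against both the response variance and
    # the absolute response scale (a constant y has SST at rounding level)
    sse_scale = max(float(np.sum((y - y.mean()) ** 2)), yty / max(n, 1), 1e-300)

    cols: list[np.ndarray] = [np.ones(n)]
    basis: list[BasisFunction] = []

    while len(basis) < c.max_initial_funcs:
        Bmat = np.column_stack(cols)
        G = Bmat.T @ Bmat
        ridge = 1e-10 * (np.trace(G) / G.shape[0])
        cho = cho_factor(G + ridge * np.eye(G.shape[0]), lower=True)
        bty = Bmat.T @ y
        coef_cur = cho_solve(cho, bty)
        sse_cur = max(yty - float(bty @ coef_cur), 0.0)

        all_cands: list[tuple[float, int, float, int, bool]] = []
        room_for_pair = len(basis) + 2 <= c.max_initial_funcs
        # parent -1 denotes the intercept (order-0 parent)
        parents = [-1] + list(range(len(basis)))
        for var in range(p):
            xcol = X[:, var]
            knots_var = [t.knot for b in basis for t in b.terms
                         if not t.linear and t.variable == var]
            cand = None
            if not binary[var]:
                cand = admissible_knots(xcol, knots_var,
                                        c.min_obs_between_knots, c.min_obs_to_edge)
            for pi in parents:
                if pi >= 0:
                    parent = basis[pi]
                    if parent.order >= c.max_interaction or var in parent.variables:
                        continue
                    pcol = cols[pi + 1]
                else:
                    pcol = cols[0]
                if binary[var]:
                    # single linear entry; skip if this product already exists
                    terms = ((basis[pi].terms if pi >= 0 else ()) +
                             (HingeTerm(var, linear=True),))
                    key = frozenset(terms)
                    if any(frozenset(b.terms) == key for b in basis):
                        continue
                    u = pcol * xcol
                    red = _score_single(u, Bmat, cho, bty, coef_cur, y)
                    all_cands.append((red, var, float(np.min(xcol)), pi, False))
                elif cand is not None and cand.size and room_for_pair:
                    reds = _score_pairs(pcol, xcol, cand, Bmat, cho, bty, coef_cur, y)
                    for k in range(cand.size):
                        all_cands.append((reds[k], var, float(cand[k]), pi, True))
        # largest SSE reduction wins; near-ties break toward the lowest
        # variable index, then the smallest knot, then the earliest parent
        best = None
        if all_cands:
            top = max(r for r, *_ in all_cands)
            if top > _REDUCTION_RTOL * sse_scale:
                tied = [cd for cd in all_cands
                        if cd[0] >= top * (1 - _REDUCTION_RTOL)]
                best = min(tied, key=lambda cd: (cd[1], cd[2], cd[3]))
        if best is None:
            break

        _, var, knot, pi, is_pair = best
        parent_terms = basis[pi].terms if pi >= 0 else ()
        if is_pair:
            for direction in (+1, -1):
                terms = parent_terms + (HingeTerm(var, knot, direction),)
                basis.append(BasisFunction(terms))
                cols.append(cols[pi + 1] * hinge_eval(X[:, var], knot, direction))
        else:
            terms = parent_terms + (HingeTerm(var, linear=True),)
            basis.append(BasisFunction(terms))
            cols.append(cols[pi + 1] * X[:, var])

    Bmat = np.column_stack(cols)
    coef, sse = _lstsq_fit(Bmat, y)
    return _finalize(coef, sse, basis, X, y, cubic=False)


def _score_single(u, Bmat, cho, bty, coef_cur, y) -> float:
    a = Bmat.T @ u
    gia = cho_solve(cho, a)
    s = float(u @ u - a @ gia)
    if s <= 1e-10 * max(float(u @ u), 1.0):
        return 0.0
    r = float(u @ y - gia @ bty)
    return r * r / s


def _score_pairs(pcol, xcol, knots, Bmat, cho, bty, coef_cur, y) -> np.ndarray:
    """SSE reduction of adding the reflected hinge pair at each knot.

    Uses the 2x2 Schur complement of the augmented normal equations; exact up
    to the scoring ridge.  The accepted model is always refit exactly.
    """
    Hp = np.maximum(0.0, xcol[:, None] - knots[None, :]) * pcol[:, None]
    Hm = np.maximum(0.0, knots[None, :] - xcol[:, None]) * pcol[:, None]
    Ap = Bmat.T @ Hp
    Am = Bmat.T @ Hm
    GiAp = cho_solve(cho, Ap)
    GiAm = cho_solve(cho, Am)
    spp = np.einsum("ij,ij->j", Hp, Hp) - np.einsum("ij,ij->j", Ap, GiAp)
    smm = np.einsum("ij,ij->j", Hm, Hm) - np.einsum("ij,ij->j", Am, GiAm)
    spm = np.einsum("ij,ij->j", Hp, Hm) - np.einsum("ij,ij->j", Ap, GiAm)
    rp = Hp.T @ y - GiAp.T @ bty
    rm = Hm.T @ y - GiAm.T @ bty

    scale = np.maximum(np.einsum("ij,ij->j", Hp, Hp), 1.0) * \
        np.maximum(np.einsum("ij,ij->j", Hm, Hm), 1.0)
    det = spp * smm - spm ** 2
    good = det > 1e-12 * np.maximum(scale, 1e-300)
    red = np.zeros(knots.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = (smm * rp ** 2 - 2.0 * spm * rp * rm + spp * rm ** 2) / det
        red = np.where(good, full, red)
        # rank-deficient pair: best single direction
        only_p = (~good) & (spp > 1e-12 * np.maximum(np.einsum("ij,ij->j", Hp, Hp), 1e-300))
        only_m = (~good) & (smm > 1e-12 * np.maximum(np.einsum("ij,ij->j", Hm, Hm), 1e-300))
        red = np.where(only_p, np.maximum(red, rp ** 2 / np.where(spp > 0, spp, 1.0)), red)
        red = np.where(only_m, np.maximum(red, rm ** 2 / np.where(smm > 0, smm, 1.0)), red)
    return np.maximum(red, 0.0)


def _finalize(coef: np.ndarray, sse: float, basis: list[BasisFunction],
              X: np.ndarray, y: np.ndarray, cubic: bool,
              penalty: float = 0.0) -> MarsModel:
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return MarsModel(
        intercept=float(coef[0]),
        coefficients=np.asarray(coef[1:], dtype=float),
        basis=list(basis),
        cubic=cubic,
        var_min=X.min(axis=0),
        var_max=X.max(axis=0),
        n_vars=X.shape[1],
        training_sse=float(sse),
        training_r2=float(r2),
        n_train=X.shape[0],
        penalty=penalty,
    )


# ---------------------------------------------------------------------------
# GCV and backward pass
# ---------------------------------------------------------------------------

def gcv(sse: float, n: int, n_basis: int, n_knots: int, penalty: float) -> float:
    """Generalised cross-validation score (sse/n) / (1 - C/n)^2.

    Effective parameters C = n_basis + 1 + penalty * n_knots; models with
    C >= n are inadmissible and score +inf.
    """
    C = n_basis + 1 + penalty * n_knots
    if C >= n:
        return float("inf")
    return (sse / n) / (1.0 - C / n) ** 2


def _model_gcv(sse: float, n: int, basis: Sequence[BasisFunction],
               penalty: float) -> float:
    knots = {(t.variable, t.knot) for b in basis for t in b.terms if not t.linear}
    return gcv(sse, n, len(basis), len(knots), penalty)


def backward_prune(model: MarsModel, X: np.ndarray, y: np.ndarray,
                   constraints: FitConstraints | None = None) -> MarsModel:
    """Iterative one-at-a-time basis deletion guided by GCV.

    Deletes, at each step, the basis function whose removal yields the lowest
    SSE (hence the lowest GCV at that size); records the best model of each
    size and returns the GCV-optimal model among those with at most
    ``max_final_funcs`` basis functions.  Requires a numeric penalty (resolve
    "cv" with :func:`select_penalty_cv` first).
    """
    c = constraints or FitConstraints()
    penalty = c.penalty
    if not isinstance(penalty, (int, float)):
        raise ValueError("backward_prune needs a numeric penalty; "
                         "resolve 'cv' with select_penalty_cv first")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if model.n_basis == 0:
        return model

    lin = dataclasses.replace(model, cubic=False)
    Bmat = lin.basis_matrix(X)
    G = Bmat.T @ Bmat
    b = Bmat.T @ y
    yty = float(y @ y)

    current = np.arange(Bmat.shape[1])  # 0 is the intercept, always kept
    sse_cur = _subset_sse(G, b, yty, current)
    best_by_size: dict[int, tuple[float, np.ndarray]] = {
        len(current) - 1: (sse_cur, current.copy())}

    while len(current) > 1:
        jpos = _cheapest_deletion(G, b, current, protected=1)
        current = np.delete(current, jpos)
        best_by_size[len(current) - 1] = (
            _subset_sse(G, b, yty, current), current.copy())

    # SSEs at rounding level are ties; flooring them lets GCV prefer the
    # smaller model instead of chasing machine noise
    sse_floor = 1e-12 * yty
    best_score, best_subset, best_sse = np.inf, None, np.nan
    for size in sorted(best_by_size):
        if size > c.max_final_funcs:
            continue
        sse, subset = best_by_size[size]
        basis_sub = [model.basis[i - 1] for i in subset[1:]]
        score = _model_gcv(max(sse, sse_floor), n, basis_sub, penalty)
        if score < best_score * (1 - 1e-12):
            best_score, best_subset, best_sse = score, subset, sse

    basis = [model.basis[i - 1] for i in best_subset[1:]]
    coef, sse = _lstsq_fit(Bmat[:, best_subset], y)
    return _finalize(coef, sse, basis, X, y, cubic=False, penalty=float(penalty))


# ---------------------------------------------------------------------------
# Penalty selection by cross-validation
# ---------------------------------------------------------------------------

def select_penalty_cv(X: np.ndarray, y: np.ndarray,
                      constraints: FitConstraints | None = None,
                      grid: Sequence[float] | None = None) -> float:
    """Pick the GCV penalty from ``grid`` by k-fold cross-validation.

    For each grid value the full forward+backward fit is run on each training
    fold and scored by mean squared prediction error on the held-out fold.
    Ties break toward the smallest penalty.  Fold assignment is a
    deterministic permutation from ``constraints.rng_seed``.
    """
    c = constraints or FitConstraints()
    if grid is None:
        grid = c.penalty_grid
    grid = list(grid)
    if not grid:
        raise ValueError("penalty grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    k = c.cv_folds
    if n < k:
        raise ValueError(f"need at least cv_folds={k} rows, got {n}")

    rng = np.random.default_rng(c.rng_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    best_pen, best_mse = None, np.inf
    for pen in sorted(grid):
        sq_err, n_test = 0.0, 0
        for f in folds:
            test = np.zeros(n, dtype=bool)
            test[f] = True
            cf = c.replace(penalty=float(pen))
            try:
                m = forward_pass(X[~test], y[~test], cf)
                m = backward_prune(m, X[~test], y[~test], cf)
                if c.cubic:
                    m = to_cubic(m, X[~test], y[~test])
            except ValueError:
                sq_err, n_test = np.inf, 1
                break
            pred = m.predict(X[test])
            sq_err += float(np.sum((pred - y[test]) ** 2))
            n_test += len(f)
        mse = sq_err / n_test
        if mse < best_mse * (1 - 1e-12) or best_pen is None:
            best_pen, best_mse = float(pen), mse
    return best_pen


# ---------------------------------------------------------------------------
# Fit statistics and cubic mode
# ---------------------------------------------------------------------------

def r_squared(model: MarsModel, X: np.ndarray, y: np.ndarray) -> float:
    """Proportion of variance explained, 1 - SSE/SST (0 when var(y) = 0)."""
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        warnings.warn("response has zero variance; r^2 defined as 0")
        return 0.0
    resid = y - model.predict(X)
    return 1.0 - float(resid @ resid) / sst


def to_cubic(model: MarsModel, X: np.ndarray,
             y: np.ndarray | None = None) -> MarsModel:
    """Replace hinges by C1 piecewise cubics and refit coefficients.

    Side knots sit at the midpoints between each knot and its neighbouring
    knots on the same variable (or the training data extremes for the
    outermost knots).  Outside the side-knot interval the cubic piece equals
    the linear hinge exactly.  When ``y`` is given, coefficients are refit by
    least squares on the cubic basis.
    """
    if model.cubic:
        return model
    X = np.asarray(X, dtype=float)
    new_basis: list[BasisFunction] = []
    for b in model.basis:
        terms = []
        for t in b.terms:
            if t.linear:
                terms.append(t)
                continue
            knots = model.knots_on(t.variable)
            lo = float(X[:, t.variable].min())
            hi = float(X[:, t.variable].max())
            i = knots.index(t.knot)
            left = knots[i - 1] if i > 0 else lo
            right = knots[i + 1] if i + 1 < len(knots) else hi
            t_minus = 0.5 * (left + t.knot)
            t_plus = 0.5 * (t.knot + right)
            terms.append(dataclasses.replace(t, t_minus=t_minus, t_plus=t_plus))
        new_basis.append(BasisFunction(tuple(terms)))

    out = dataclasses.replace(model, basis=new_basis, cubic=True)
    if y is not None:
        y = np.asarray(y, dtype=float)
        Bmat = out.basis_matrix(X)
        coef, sse = _lstsq_fit(Bmat, y)
        out = _finalize(coef, sse, new_basis, X, y, cubic=True,
                        penalty=model.penalty)
    return out


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def fit_mars(X: np.ndarray, y: np.ndarray,
             constraints: FitConstraints | None = None,
             ) -> tuple[MarsModel, MarsModel]:
    """Full fit: penalty resolution, forward pass, pruning, optional cubic.

    Returns ``(pruned, unpruned)``: the GCV-pruned final model and the raw
    forward-pass model (in linear mode; used as a frozen candidate basis by
    the less conservative voxelwise options).
    """
    c = constraints or FitConstraints()
    if c.penalty == "cv":
        pen = select_penalty_cv(X, y, c)
        c = c.replace(penalty=pen)
    unpruned = forward_pass(X, y, c)
    pruned = backward_prune(unpruned, X, y, c)
    if c.cubic:
        pruned = to_cubic(pruned, X, y)
    return pruned, unpruned
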