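"""Voxelwise spline fitting of tissue-probability cohorts.

Each tissue class is a 4D stack (subjects x X x Y x Z) of spatially
normalized probability maps on one shared grid.  A spline model of the
demographic design matrix (age, sex, field strength, quality) is fitted at
every voxel whose cohort-average probability exceeds a mask threshold.

Because neighbouring voxels are not independent observations, four options
trade spatial homogeneity against per-voxel flexibility:

* option 1 (most conservative): a model is fitted to the per-subject global
  tissue volumes and pruned; every voxel is restricted to follow that global
  pattern, fitting only a per-voxel intercept and scale of the global curve.
* option 2: the unpruned (overfitted) global basis is frozen as the candidate
  set; per voxel, coefficients are refit and backward pruning is run.  The
  selected per-voxel model must fit at least as well as option 1's
  scaled-global-curve fit at that voxel (which remains the fallback), so
  per-voxel explained variance dominates option 1 exactly while pruning is
  otherwise unrestricted.
* option 3: a full per-voxel forward+backward fit, but the number of final
  basis functions and the minimum between-knot subject count are inherited
  from the fitted global model.
* option 4 (most liberal): fully independent per-voxel fits with the
  configured defaults.

The GCV penalty, when set to "cv", is resolved once on the global series by
k-fold cross-validation and reused for all voxel fits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .mars import (BasisFunction, FitConstraints, HingeTerm, MarsModel,
                   backward_prune, fit_mars, forward_pass, gcv, select_penalty_cv,
                   to_cubic, _lstsq_fit, _subset_sse, _model_gcv)

__all__ = [
    "TISSUE_CLASSES",
    "TissueStack",
    "VoxelwiseModelSet",
    "compute_mask",
    "compute_globals",
    "fit_global_model",
    "fit_voxelwise",
    "load_stack",
    "save_stack",
]

#: fixed class order used throughout: three brain classes, then the
#: non-brain classes, background last
TISSUE_CLASSES = ("GM", "WM", "CSF", "bone", "soft", "background")

_AFFINE_TOL = 1e-4
_DEGENERATE_VAR = 1e-12  # response variance below this -> intercept-only


@dataclass
class TissueStack:
    """4D probability stack for one tissue class: (n_subjects, nx, ny, nz)."""

    class_label: str
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (subjects, x, y, z)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(
                f"probabilities must lie in [0, 1]; got range [{lo}, {hi}]")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 from the affine's linear block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "TissueStack") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=_AFFINE_TOL))


def check_shared_grid(stacks: dict[str, TissueStack]) -> None:
    labels = list(stacks)
    ref = stacks[labels[0]]
    for lb in labels[1:]:
        if not ref.same_grid(stacks[lb]):
            raise ValueError(f"stack {lb!r} is not on the same grid as {labels[0]!r}")


# ---------------------------------------------------------------------------
# NIfTI plumbing
# ---------------------------------------------------------------------------

def load_stack(path, class_label: str) -> TissueStack:
    """Load one tissue class from a 4D NIfTI (subjects along the 4th axis)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    # NIfTI stores subjects last; internal layout puts them first
    return TissueStack(class_label, np.moveaxis(data, -1, 0), img.affine)


def save_stack(stack: TissueStack, path) -> None:
    data = np.moveaxis(stack.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, stack.affine), str(path))


# ---------------------------------------------------------------------------
# Mask and globals
# ---------------------------------------------------------------------------

def compute_mask(stack: TissueStack, threshold: float = 0.10) -> np.ndarray:
    """Boolean mask of voxels whose cohort-mean probability strictly exceeds
    ``threshold`` (default 10%)."""
    mean = stack.data.mean(axis=0)
    mask = mean > threshold
    if not mask.any():
        raise ValueError(
            f"class {stack.class_label!r}: no voxel exceeds the mask "
            f"threshold {threshold}")
    return mask


def compute_globals(stack: TissueStack, volume_units: bool = True) -> np.ndarray:
    """Per-subject global tissue volume: probability mass x voxel volume (mm^3).

    With ``volume_units=False`` the plain probability sum is returned.
    """
    sums = stack.data.reshape(stack.n_subjects, -1).sum(axis=1)
    return sums * stack.voxel_volume if volume_units else sums


def fit_global_model(globals_: np.ndarray, X: np.ndarray,
                     constraints: FitConstraints | None = None,
                     ) -> tuple[MarsModel, MarsModel]:
    """Fit the spline model to the global series; returns (pruned, unpruned).

    The unpruned forward-pass model is retained as the frozen candidate basis
    of option 2; the GCV penalty is resolved here when set to "cv".
    """
    return fit_mars(np.asarray(X, float), np.asarray(globals_, float), constraints)


# ---------------------------------------------------------------------------
# Voxelwise model set
# ---------------------------------------------------------------------------

@dataclass
class VoxelwiseModelSet:
    """A fitted model per in-mask voxel for one tissue class.

    Options 1-2 share one basis (from the global model) and store a dense
    per-voxel coefficient matrix; pruned-away entries are zero.  Options 3-4
    store an independent model per voxel.  Out-of-mask voxels carry the
    cohort-mean value so assembled priors stay smooth at mask edges.
    """

    option: int
    class_label: str
    mask: np.ndarray                       # 3D bool
    mean_map: np.ndarray                   # 3D cohort mean
    r2_map: np.ndarray                     # 3D, NaN outside the mask
    affine: np.ndarray
    var_min: np.ndarray                    # training range per predictor
    var_max: np.ndarray
    n_train: int
    constraints: dict
    shared_model: MarsModel | None = None  # basis carrier for options 1-2
    coef: np.ndarray | None = None         # (n_mask, M+1) for options 1-2
    models: list[MarsModel] | None = None  # per-voxel models, options 3-4
    global_pruned: MarsModel | None = None
    global_unpruned: MarsModel | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def predict(self, X_rows: np.ndarray) -> np.ndarray:
        """Predicted volumes for each design row: (n_rows, nx, ny, nz).

        Out-of-mask voxels are filled with the cohort mean map.
        """
        X_rows = np.atleast_2d(np.asarray(X_rows, dtype=float))
        n_rows = X_rows.shape[0]
        out = np.empty((n_rows,) + self.mask.shape)
        out[:] = self.mean_map[None]
        flat = out.reshape(n_rows, -1)
        idx = np.flatnonzero(self.mask.ravel())
        if self.coef is not None:
            B = self.shared_model.basis_matrix(X_rows)   # (n_rows, M+1)
            flat[:, idx] = B @ self.coef.T
        else:
            for k, i in enumerate(idx):
                flat[:, idx[k]] = self.models[k].predict(X_rows)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "option": self.option,
            "class_label": self.class_label,
            "shape": list(self.mask.shape),
            "mask": self.mask.ravel().astype(int).tolist(),
            "mean_map": self.mean_map.ravel().tolist(),
            "r2_map": [None if np.isnan(v) else float(v)
                       for v in self.r2_map.ravel()],
            "affine": self.affine.tolist(),
            "var_min": self.var_min.tolist(),
            "var_max": self.var_max.tolist(),
            "n_train": self.n_train,
            "constraints": self.constraints,
            "shared_model": None if self.shared_model is None
                            else self.shared_model.to_dict(),
            "coef": None if self.coef is None else self.coef.tolist(),
            "models": None if self.models is None
                      else [m.to_dict() for m in self.models],
            "global_pruned": None if self.global_pruned is None
                             else self.global_pruned.to_dict(),
            "global_unpruned": None if self.global_unpruned is None
                               else self.global_unpruned.to_dict(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelwiseModelSet":
        shape = tuple(d["shape"])
        r2 = np.array([np.nan if v is None else v for v in d["r2_map"]])
        return cls(
            option=d["option"],
            class_label=d["class_label"],
            mask=np.asarray(d["mask"], dtype=bool).reshape(shape),
            mean_map=np.asarray(d["mean_map"], dtype=float).reshape(shape),
            r2_map=r2.reshape(shape),
            affine=np.asarray(d["affine"], dtype=float),
            var_min=np.asarray(d["var_min"], dtype=float),
            var_max=np.asarray(d["var_max"], dtype=float),
            n_train=d["n_train"],
            constraints=d["constraints"],
            shared_model=None if d["shared_model"] is None
                         else MarsModel.from_dict(d["shared_model"]),
            coef=None if d["coef"] is None else np.asarray(d["coef"], dtype=float),
            models=None if d["models"] is None
                   else [MarsModel.from_dict(m) for m in d["models"]],
            global_pruned=None if d["global_pruned"] is None
                          else MarsModel.from_dict(d["global_pruned"]),
            global_unpruned=None if d["global_unpruned"] is None
                            else MarsModel.from_dict(d["global_unpruned"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "VoxelwiseModelSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean(self.r2_map[self.mask]))


# ---------------------------------------------------------------------------
# Fitting drivers
# ---------------------------------------------------------------------------

def _r2_from_sse(sse: np.ndarray, sst: np.ndarray) -> np.ndarray:
    r2 = np.zeros_like(sse)
    ok = sst > 0
    r2[ok] = 1.0 - sse[ok] / sst[ok]
    return r2


def _min_interknot_count(model: MarsModel, X: np.ndarray) -> int | None:
    """Smallest observed number of subjects strictly between adjacent knots
    on any variable of the model (None when no variable carries two knots)."""
    counts = []
    for v in range(X.shape[1]):
        ks = model.knots_on(v)
        if len(ks) < 2:
            continue
        s = np.sort(X[:, v])
        for a, b in zip(ks, ks[1:]):
            counts.append(int(np.searchsorted(s, b, side="left")
                              - np.searchsorted(s, a, side="right")))
    return min(counts) if counts else None


def fit_voxelwise(stack: TissueStack, X: np.ndarray,
                  constraints: FitConstraints | None = None,
                  option: int = 2,
                  global_models: tuple[MarsModel, MarsModel] | None = None,
                  mask_threshold: float = 0.10) -> VoxelwiseModelSet:
    """Fit spline models to every in-mask voxel under one of the four options.

    ``global_models`` is the ``(pruned, unpruned)`` pair from
    :func:`fit_global_model`; it is fitted here when absent (required for
    options 1-3, and used for penalty resolution in option 4).
    """
    c = constraints or FitConstraints()
    if option not in (1, 2, 3, 4):
        raise ValueError(f"option must be 1..4, got {option}")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n != stack.n_subjects:
        raise ValueError("design matrix rows do not match stack subjects")

    mask = compute_mask(stack, mask_threshold)
    mean_map = stack.data.mean(axis=0)
    Y = stack.data.reshape(n, -1)[:, mask.ravel()]       # (n, n_mask)
    n_mask = Y.shape[1]
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)

    if global_models is None:
        global_models = fit_global_model(compute_globals(stack), X, c)
    g_pruned, g_unpruned = global_models
    # penalty: resolved on the globals (echoed on the pruned model)
    if c.penalty == "cv":
        c = c.replace(penalty=float(g_pruned.penalty))

    r2_map = np.full(mask.shape, np.nan)
    meta = {k: (v if not isinstance(v, tuple) else list(v))
            for k, v in dataclasses.asdict(c).items()}
    common = dict(option=option, class_label=stack.class_label, mask=mask,
                  mean_map=mean_map, affine=stack.affine,
                  var_min=X.min(axis=0), var_max=X.max(axis=0), n_train=n,
                  constraints=meta, global_pruned=g_pruned,
                  global_unpruned=g_unpruned)

    if option in (1, 2):
        # one shared basis family for both options: the unpruned global basis
        # (cubic side knots computed on its full knot inventory); the global
        # pattern lives on the protected (pruned-model) columns
        carrier = to_cubic(g_unpruned, X) if c.cubic else g_unpruned
        protected = _protected_columns(g_pruned, carrier)
        B = carrier.basis_matrix(X)
        gl = compute_globals(stack)
        coef1, sse1, r2_1 = _scaled_global_fit(B, protected, gl, Y, sst)
        if option == 1:
            coef, r2 = coef1, r2_1
        else:
            coef, r2 = _prune_per_voxel(carrier, B, Y, sst, c,
                                        coef1, sse1)
        r2_map[mask] = r2
        return VoxelwiseModelSet(r2_map=r2_map, shared_model=carrier,
                                 coef=coef, **common)

    # options 3 and 4: independent per-voxel forward+backward fits
    cv = c
    if option == 3:
        mfinal = max(g_pruned.n_basis, 1)
        cv = c.replace(max_final_funcs=mfinal, max_initial_funcs=5 * mfinal)
        inter = _min_interknot_count(g_pruned, X)
        if inter is not None:
            cv = cv.replace(min_obs_between_knots=max(inter, 1))
    models: list[MarsModel] = []
    r2 = np.zeros(n_mask)
    ybar = Y.mean(axis=0)
    for j in range(n_mask):
        if sst[j] < _DEGENERATE_VAR:
            m = MarsModel(intercept=float(ybar[j]), coefficients=np.empty(0),
                          basis=[], cubic=cv.cubic, var_min=X.min(axis=0),
                          var_max=X.max(axis=0), n_vars=X.shape[1],
                          training_sse=0.0, training_r2=0.0, n_train=n,
                          penalty=float(cv.penalty))
        else:
            m = forward_pass(X, Y[:, j], cv)
            m = backward_prune(m, X, Y[:, j], cv)
            if cv.cubic:
                m = to_cubic(m, X, Y[:, j])
        models.append(m)
        r2[j] = m.training_r2
    r2_map[mask] = r2
    return VoxelwiseModelSet(r2_map=r2_map, models=models, **common)


def _protected_columns(pruned: MarsModel, carrier: MarsModel) -> np.ndarray:
    """Column indices of the carrier basis present in the pruned global model.

    Matching is by linear-mode term structure (variable, knot, direction),
    side knots aside, so it is valid for both linear and cubic carriers.
    """
    def key(b: BasisFunction):
        return frozenset((t.variable, t.knot, t.direction, t.linear)
                         for t in b.terms)

    pruned_keys = {key(b) for b in pruned.basis}
    cols = [0]  # intercept always kept
    for i, b in enumerate(carrier.basis):
        if key(b) in pruned_keys:
            cols.append(i + 1)
    return np.asarray(cols, dtype=int)


def _scaled_global_fit(B: np.ndarray, protected: np.ndarray, gl: np.ndarray,
                       Y: np.ndarray, sst: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Option 1: per voxel, intercept + scale of the one global curve.

    The global series ``gl`` is projected onto the protected carrier columns
    to give the global pattern; each voxel then fits only two parameters
    (offset and gain).  Returns dense carrier-space coefficients
    (n_mask, M+1), per-voxel SSE, and per-voxel r^2.
    """
    n = B.shape[0]
    cg, _ = _lstsq_fit(B[:, protected], gl)
    ghat = B[:, protected] @ cg
    D = np.column_stack([np.ones(n), ghat])
    ab, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)          # (2, n_mask)
    sse = np.sum((Y - D @ ab) ** 2, axis=0)
    degenerate = sst < _DEGENERATE_VAR
    ab[0, degenerate] = Y.mean(axis=0)[degenerate]
    ab[1, degenerate] = 0.0
    sse[degenerate] = 0.0
    coef = np.zeros((Y.shape[1], B.shape[1]))
    coef[:, protected] = np.outer(ab[1], cg)
    coef[:, 0] += ab[0]
    r2 = _r2_from_sse(sse, sst)
    r2[degenerate] = 0.0
    return coef, sse, r2


def _prune_per_voxel(carrier: MarsModel, B: np.ndarray, Y: np.ndarray,
                     sst: np.ndarray, c: FitConstraints,
                     coef_floor: np.ndarray, sse_floor_all: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Option 2: backward pruning of the frozen carrier basis at every voxel.

    Deletions proceed greedily by smallest SSE increase; the GCV-best
    recorded subset with at most ``max_final_funcs`` basis functions wins,
    restricted to subsets fitting at least as well as the scaled-global-curve
    fit at that voxel (option 1), which remains the fallback — so per-voxel
    explained variance dominates the most conservative option exactly while
    pruning stays otherwise unrestricted.  Returns dense coefficients
    (n_mask, M+1) with zeros for deleted columns, and per-voxel r^2.
    """
    from .mars import _cheapest_deletion

    penalty = float(c.penalty)
    n, M1 = B.shape
    G = B.T @ B
    bty_all = B.T @ Y                       # (M+1, n_mask)
    yty_all = np.sum(Y ** 2, axis=0)
    ybar = Y.mean(axis=0)
    n_mask = Y.shape[1]

    coef_out = np.zeros((n_mask, M1))
    r2_out = np.zeros(n_mask)

    knotset_of = [{(t.variable, t.knot) for t in b.terms if not t.linear}
                  for b in carrier.basis]

    def model_gcv(sse_k: float, subset) -> float:
        size = len(subset) - 1
        nk = len(set().union(*(knotset_of[i - 1] for i in subset[1:]))
                 ) if size else 0
        return gcv(sse_k, n, size, nk, penalty)

    for j in range(n_mask):
        if sst[j] < _DEGENERATE_VAR:
            coef_out[j, 0] = ybar[j]
            continue
        b_j = bty_all[:, j]
        yty = yty_all[j]
        tie_floor = 1e-12 * yty          # rounding-level SSEs count as ties
        sse_floor = float(sse_floor_all[j])
        floor_tol = sse_floor * (1 + 1e-9) + 1e-12

        current = np.arange(M1)
        path = [(_subset_sse(G, b_j, yty, current), current.copy())]
        while len(current) > 1:
            jpos = _cheapest_deletion(G, b_j, current, protected=1)
            current = np.delete(current, jpos)
            path.append((_subset_sse(G, b_j, yty, current), current.copy()))

        best_score, best_subset = np.inf, None
        for sse_k, subset in path:
            if len(subset) - 1 > c.max_final_funcs or sse_k > floor_tol:
                continue
            score = model_gcv(max(sse_k, tie_floor), subset)
            if score < best_score * (1 - 1e-12):
                best_score, best_subset = score, subset

        use_floor = best_subset is None
        if not use_floor:
            idx = np.asarray(best_subset)
            coef, sse_fit = _lstsq_fit(B[:, idx], Y[:, j])
            use_floor = sse_fit > floor_tol
        if use_floor:
            # no pruned subset beats the scaled global curve here
            coef_out[j] = coef_floor[j]
            sse_fit = sse_floor
        else:
            coef_out[j, idx] = coef
        r2_out[j] = max(1.0 - sse_fit / sst[j], 0.0) if sst[j] > 0 else 0.0
    return coef_out, r2_out
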