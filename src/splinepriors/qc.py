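"""Quantitative quality indicators for template construction.

Deformation summaries (affine scaling, nonlinear volume change from Jacobian
determinants), cohort dissimilarity-from-the-mean, neighbourhood
inhomogeneity of probability maps, explained-variance baselines (voxelwise
polynomial GLM, moving-average curves), a Lilliefors normality test, and the
prior-versus-average comparison protocol that scores statistically
generated priors against straight subgroup means relative to a large
population's gold-standard mean.
"""

from __future__ import annotations

import itertools

import numpy as np

from .mars import FitConstraints
from .phantom import DeformationField
from .priors import PriorRequest, predict_priors
from .voxelwise import TissueStack, VoxelwiseModelSet, compute_mask

__all__ = [
    "affine_scaling",
    "nonlinear_volume_change",
    "dissimilarity_from_mean",
    "neighborhood_inhomogeneity",
    "relative_metric",
    "glm_baseline",
    "moving_average_baseline",
    "compare_to_gold_standard",
    "shrinking_population_curve",
    "lilliefors_normality",
]


# ---------------------------------------------------------------------------
# Deformation
# ---------------------------------------------------------------------------

def affine_scaling(affine: np.ndarray) -> float:
    """|determinant| of the 3x3 linear block: the global volume scaling of a
    12-parameter affine normalization."""
    A = np.asarray(affine, dtype=float)
    det = np.linalg.det(A[:3, :3])
    if abs(det) < 1e-12:
        raise ValueError("affine matrix is singular")
    return float(abs(det))


def nonlinear_volume_change(field: DeformationField, brain_mask: np.ndarray,
                            centered: bool = False) -> dict:
    """Voxel volume change due to the nonlinear part of a deformation.

    The total mapping is the affine composed with the voxel displacement u;
    its Jacobian determinant is det(A) * det(I + grad u).  Dividing by the
    affine determinant removes the global scaling already accounted for, so
    the metric reflects nonlinear deformation only.  Returns the sum and the
    mean of |det J| over in-mask voxels (with ``centered=True``, of
    |det J - 1|).  Gradients use central differences with one-sided stencils
    at the volume borders.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if field.displacement.shape[:3] != mask.shape:
        raise ValueError("field and mask are on different grids")
    h = field.voxel_size_mm
    u = field.displacement
    grads = [np.gradient(u[..., i], h, axis=(0, 1, 2)) for i in range(3)]
    J = np.empty(mask.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            J[..., i, j] = (i == j) + grads[i][j]
    jac = np.linalg.det(J)
    vals = np.abs(jac[mask] - 1.0) if centered else np.abs(jac[mask])
    return {"sum": float(vals.sum()), "mean": float(vals.mean()),
            "n_voxels": int(mask.sum())}


# ---------------------------------------------------------------------------
# Dissimilarity and inhomogeneity
# ---------------------------------------------------------------------------

def dissimilarity_from_mean(stack: TissueStack,
                            mask: np.ndarray | None = None) -> np.ndarray:
    """Per-subject sum of absolute voxelwise differences from the cohort mean.

    Computed over all voxels by default (background included; a structural
    similarity index would be unduly biased by the many background voxels),
    or over an optional mask.
    """
    if stack.n_subjects < 2:
        raise ValueError("dissimilarity needs at least 2 subjects")
    data = stack.data
    if mask is not None:
        data = data[:, np.asarray(mask, dtype=bool)]
    else:
        data = data.reshape(stack.n_subjects, -1)
    mean = data.mean(axis=0)
    return np.abs(data - mean[None]).sum(axis=1)


_NEIGHBOR_OFFSETS = [off for off in itertools.product((-1, 0, 1), repeat=3)
                     if off != (0, 0, 0)]


def neighborhood_inhomogeneity(volume: np.ndarray,
                               mask_threshold: float = 0.10) -> float:
    """Mean absolute deviation between supra-threshold voxels and their 26
    neighbours, in percent intensity.

    For every voxel with value > threshold, the mean of |center - neighbour|
    over its (up to) 26 face/edge/corner neighbours is taken, excluding
    neighbours outside the volume; the average over all qualifying voxels is
    returned, scaled by 100.  Zero for a perfectly homogeneous volume.
    """
    v = np.asarray(volume, dtype=float)
    qualify = v > mask_threshold
    if not qualify.any():
        raise ValueError("no voxel exceeds the inhomogeneity threshold")
    diff_sum = np.zeros_like(v)
    count = np.zeros_like(v)
    for ox, oy, oz in _NEIGHBOR_OFFSETS:
        src = tuple(slice(max(o, 0), v.shape[k] + min(o, 0))
                    for k, o in enumerate((ox, oy, oz)))
        dst = tuple(slice(max(-o, 0), v.shape[k] + min(-o, 0))
                    for k, o in enumerate((ox, oy, oz)))
        diff_sum[dst] += np.abs(v[dst] - v[src])
        count[dst] += 1.0
    per_voxel = diff_sum[qualify] / count[qualify]
    return float(per_voxel.mean() * 100.0)


def relative_metric(values, reference_index: int = 0) -> np.ndarray:
    """Normalise per-option values by the reference option (which becomes 1.00)."""
    vals = np.asarray(values, dtype=float)
    ref = vals[reference_index]
    if ref == 0:
        raise ValueError("reference option value is zero")
    return vals / ref


# ---------------------------------------------------------------------------
# Explained-variance baselines
# ---------------------------------------------------------------------------

def glm_baseline(stack: TissueStack, X: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise polynomial GLM baseline r^2.

    Ordinary least squares per voxel on (intercept, age, age^2, age^3, sex,
    field strength, quality); age powers are standardized before squaring to
    keep the normal equations well conditioned.  Returns the r^2 volume
    (NaN outside the mask).
    """
    X = np.asarray(X, dtype=float)
    if mask is None:
        mask = compute_mask(stack)
    age = X[:, 0]
    a = (age - age.mean()) / (age.std() or 1.0)
    D = np.column_stack([np.ones_like(a), a, a ** 2, a ** 3,
                         X[:, 1], X[:, 2], X[:, 3]])
    Y = stack.data.reshape(stack.n_subjects, -1)[:, mask.ravel()]
    coef, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    sse = np.sum(resid ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    r2 = np.zeros_like(sse)
    # variance at float-rounding level counts as constant
    ok = sst > 1e-12 * np.maximum(np.sum(Y ** 2, axis=0), 1e-300)
    r2[ok] = 1.0 - sse[ok] / sst[ok]
    out = np.full(mask.shape, np.nan)
    out[mask] = r2
    return out


def moving_average_baseline(values: np.ndarray, ages: np.ndarray,
                            window_n: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average over the ``window_n`` nearest-by-rank subjects.

    Values are sorted by age; edge windows are truncated.  Returns (sorted
    ages, smoothed values).  Mirrors the conventional way of building
    age-binned template curves, whose peaks flatten as the window grows.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = values.size
    if window_n > n:
        raise ValueError(f"window ({window_n}) exceeds series length ({n})")
    order = np.argsort(ages, kind="stable")
    v = values[order]
    half_lo = (window_n - 1) // 2
    half_hi = window_n - 1 - half_lo
    sm = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        sm[i] = v[lo:hi].mean()
    return ages[order], sm


# ---------------------------------------------------------------------------
# Prior-vs-average comparison protocol
# ---------------------------------------------------------------------------

def _sum_abs_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum())


def compare_to_gold_standard(stack: TissueStack,
                             models: VoxelwiseModelSet,
                             table, group_sizes=(25, 50, 100),
                             repeats: int = 100, seed: int = 0) -> dict:
    """Score subgroup averages and matched synthetic priors against the
    population mean.

    Per repeat and group size: a random subgroup is drawn without
    replacement; (a) the plain average of its maps and (b) the matched
    synthetic prior built from its demographics (quality at best) are each
    scored by the sum of absolute voxelwise differences from the
    full-population mean map (the gold standard).  Returns the score
    distributions keyed by group size.
    """
    n = stack.n_subjects
    for gs in group_sizes:
        if gs > n:
            raise ValueError(f"group size {gs} exceeds population {n}")
    rng = np.random.default_rng(seed)
    gold = stack.data.mean(axis=0)
    rows = [(r.age_months, r.sex, r.field_strength) for r in table.records]
    out = {"metric": "sum_abs_diff_vs_population_mean", "seed": seed,
           "repeats": repeats, "population_n": n, "group_sizes": list(group_sizes),
           "average": {}, "synthetic": {}}
    for gs in group_sizes:
        avg_scores, syn_scores = [], []
        for _ in range(repeats):
            pick = rng.choice(n, size=gs, replace=False)
            avg_map = stack.data[pick].mean(axis=0)
            avg_scores.append(_sum_abs_diff(avg_map, gold))
            req = PriorRequest.from_demographics([rows[i] for i in pick])
            syn = predict_priors({stack.class_label: models}, req)[stack.class_label]
            syn_scores.append(_sum_abs_diff(np.clip(syn, 0, 1), gold))
        out["average"][gs] = avg_scores
        out["synthetic"][gs] = syn_scores
    return out


def shrinking_population_curve(stack: TissueStack,
                               models: VoxelwiseModelSet,
                               table, subgroup_n: int = 25,
                               repeats: int = 10, step: int = 25,
                               min_population: int = 43,
                               seed: int = 0) -> dict:
    """Disagreement of matched synthetic priors as the population shrinks.

    Starting from the full population, ``step`` randomly chosen subjects are
    iteratively removed; at every size, ``repeats`` subgroups of
    ``subgroup_n`` are drawn, their matched synthetic priors generated, and
    each scored against the current population's mean map.  Reports the
    score distribution per population size.
    """
    n = stack.n_subjects
    if n < max(subgroup_n, min_population):
        raise ValueError("population too small")
    rng = np.random.default_rng(seed)
    rows = [(r.age_months, r.sex, r.field_strength) for r in table.records]
    members = np.arange(n)
    sizes, scores = [], []
    while len(members) >= max(subgroup_n, min_population):
        pop_mean = stack.data[members].mean(axis=0)
        rep_scores = []
        for _ in range(repeats):
            pick = rng.choice(members, size=subgroup_n, replace=False)
            req = PriorRequest.from_demographics([rows[i] for i in pick])
            syn = predict_priors({stack.class_label: models}, req)[stack.class_label]
            rep_scores.append(_sum_abs_diff(np.clip(syn, 0, 1), pop_mean))
        sizes.append(int(len(members)))
        scores.append(rep_scores)
        drop = rng.choice(len(members), size=min(step, len(members)), replace=False)
        members = np.delete(members, drop)
    return {"metric": "sum_abs_diff_vs_population_mean", "seed": seed,
            "subgroup_n": subgroup_n, "repeats": repeats,
            "population_sizes": sizes, "scores": scores}


# ---------------------------------------------------------------------------
# Normality testing
# ---------------------------------------------------------------------------

def lilliefors_normality(values: np.ndarray, alpha: float = 0.05,
                         n_mc: int = 1000, seed: int = 0) -> dict:
    """Lilliefors (Kolmogorov-Smirnov with estimated parameters) normality test.

    The KS statistic is computed against a normal with the sample's mean and
    SD; since parameters are estimated, critical values come from a seeded
    Monte-Carlo null (``n_mc`` standard-normal samples of the same size).
    Returns the statistic, the critical value at ``alpha``, an approximate
    p-value, and the rejection decision.  The statistic is invariant to
    affine transformations of the data.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("Lilliefors test needs at least 5 observations")

    def ks_stat(sample: np.ndarray) -> float:
        s = np.sort(sample)
        mu, sd = s.mean(), s.std(ddof=1)
        if sd == 0:
            return 1.0
        from scipy.stats import norm
        z = norm.cdf((s - mu) / sd)
        i = np.arange(1, s.size + 1)
        return float(max((i / s.size - z).max(), (z - (i - 1) / s.size).max()))

    stat = ks_stat(x)
    rng = np.random.default_rng(seed)
    null = np.array([ks_stat(rng.standard_normal(n)) for _ in range(n_mc)])
    crit = float(np.quantile(null, 1.0 - alpha))
    pval = float((null >= stat).mean())
    return {"statistic": stat, "critical_value": crit, "alpha": alpha,
            "p_value": pval, "reject_normality": bool(stat > crit),
            "n": n, "n_mc": n_mc, "seed": seed}
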