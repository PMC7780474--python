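"""Quantitative assessment: sampling sufficiency, covariance correspondence,
and fit between datasets.

* :func:`sampling_curve` — landmark sampling curves: repeatedly subsample
  k = 3, 4, ... n points, re-align, and measure the fit of the subsampled
  to the full dataset in specimen space; a plateau signals that shape
  variation is fully characterized and more points are redundant.
* :func:`random_skewers` — compare two trait covariance matrices by
  correlating their responses to common random selection vectors.
* :func:`fit_between_datasets` — PROTEST-style Procrustean fit between two
  aligned datasets of the same specimens (e.g. landmark-only vs full), with
  a permutation p-value.
* :func:`compare_sliding_workflows` — slide a sample globally vs per group
  and quantify the agreement (skewers correspondence of the two covariance
  matrices, R² of pairwise Procrustes distances).

The fit statistic is the Procrustean correlation
``fit = sqrt(1 - ss_residual / ss_total)`` between specimen score matrices
after least-squares superimposition; it ranges 0–1 and equals 1 for a
dataset compared with itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .sliding import AlignmentResult, SlidingSpec, gpa, procrustes_distance, slide

__all__ = [
    "SamplingCurveResult",
    "SkewersResult",
    "sampling_curve",
    "fit_between_datasets",
    "random_skewers",
    "procrustes_fit",
    "compare_sliding_workflows",
]


# ---------------------------------------------------------------------------
# Procrustean fit between score matrices
# ---------------------------------------------------------------------------


def procrustes_fit(x: np.ndarray, y: np.ndarray) -> float:
    """Procrustean correlation between two specimen-space matrices.

    Rows are specimens; columns are padded with zeros to a common count.
    Both matrices are column-centered and scaled to unit total sum of
    squares, then optimally rotated onto each other; the fit is the sum of
    singular values of X^T Y, which equals sqrt(1 - m²) for the Procrustes
    statistic m² and is invariant to orthogonal rotation of either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("matrices must have the same number of rows")
    w = max(x.shape[1], y.shape[1])
    if x.shape[1] < w:
        x = np.pad(x, ((0, 0), (0, w - x.shape[1])))
    if y.shape[1] < w:
        y = np.pad(y, ((0, 0), (0, w - y.shape[1])))
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    nx = np.sqrt((x**2).sum())
    ny = np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("degenerate (zero-variance) score matrix")
    s = np.linalg.svd(x.T @ y / (nx * ny), compute_uv=False)
    return float(min(s.sum(), 1.0))


# ---------------------------------------------------------------------------
# Sampling curves
# ---------------------------------------------------------------------------


@dataclass
class SamplingCurveResult:
    """Fit-vs-number-of-points traces from repeated random subsampling."""

    ks: np.ndarray                      # point counts, 3..n
    fits: np.ndarray                    # (iterations, len(ks))
    median_curve: np.ndarray            # per-k median fit
    k_at_fit: dict[float, int | None] = field(default_factory=dict)

    def quantile_curve(self, q: float) -> np.ndarray:
        return np.quantile(self.fits, q, axis=0)


def sampling_curve(
    aligned: AlignmentResult,
    iterations: int = 20,
    seed: int = 0,
    realign: bool = True,
    thresholds: tuple[float, ...] = (0.90, 0.95, 0.99),
) -> SamplingCurveResult:
    """Landmark sampling curve of an aligned dataset.

    For each iteration and each k in 3..n_points, k point labels are drawn
    uniformly without replacement, the subsampled configurations are
    re-aligned (GPA; ``realign=False`` skips this and subsets the aligned
    coordinates directly), and the fit to the full dataset is the
    Procrustean correlation between specimen score matrices.  Reports the
    median curve and the smallest k whose median fit reaches each
    threshold.  A plateau in the curve signifies stationarity of the shape
    characterization.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n_pts = len(aligned.aligned[0])
    if n_pts < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    ks = np.arange(3, n_pts + 1)
    full_scores = aligned.scores
    labels = aligned.aligned[0].labels
    fits = np.empty((iterations, len(ks)))
    for it in range(iterations):
        for j, k in enumerate(ks):
            pick = rng.choice(n_pts, size=k, replace=False)
            sub_labels = [labels[i] for i in np.sort(pick)]
            if realign:
                sub = [c.subset(sub_labels) for c in aligned.aligned]
                res = gpa(sub)
                scores = res.scores
            else:
                arr = aligned.aligned_array()[:, np.sort(pick), :]
                flat = arr.reshape(arr.shape[0], -1)
                scores = flat - flat.mean(axis=0)
            fits[it, j] = procrustes_fit(scores, full_scores)
    median = np.median(fits, axis=0)
    k_at = {}
    for th in thresholds:
        hit = np.nonzero(median >= th)[0]
        k_at[th] = int(ks[hit[0]]) if hit.size else None
    return SamplingCurveResult(ks=ks, fits=fits, median_curve=median,
                               k_at_fit=k_at)


def fit_between_datasets(
    a: AlignmentResult,
    b: AlignmentResult,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Procrustean fit between two aligned datasets of the same specimens.

    Typical use: landmark-only vs full landmark+semilandmark data.  The fit
    compares the specimens' positions in the two shape spaces; the p-value
    permutes specimen rows of the second dataset.
    """
    if a.specimen_ids != b.specimen_ids:
        raise ValueError("datasets must contain the same specimens in order")
    if permutations < 0:
        raise ValueError("permutations must be >= 0")
    obs = procrustes_fit(a.scores, b.scores)
    if permutations == 0:
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    n = a.scores.shape[0]
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if procrustes_fit(a.scores, b.scores[perm]) >= obs:
            count += 1
    p = (1 + count) / (permutations + 1)
    return obs, float(p)


# ---------------------------------------------------------------------------
# Random skewers
# ---------------------------------------------------------------------------


@dataclass
class SkewersResult:
    correspondence: float
    p_value: float
    n_iterations: int


def random_skewers(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> SkewersResult:
    """Random-skewers correspondence between two covariance matrices.

    Unit selection vectors are drawn uniformly on the sphere (normalized
    Gaussians); the correspondence is the mean cosine between the two
    response vectors cov_a·s and cov_b·s.  The p-value is the fraction of
    cosines between *independent* random unit-vector pairs of the same
    dimension exceeding the observed correspondence.
    """
    a = np.asarray(cov_a, dtype=float)
    b = np.asarray(cov_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("covariance matrices must be square and same shape")
    if not (np.allclose(a, a.T, atol=1e-8) and np.allclose(b, b.T, atol=1e-8)):
        raise ValueError("covariance matrices must be symmetric")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    p = a.shape[0]
    rng = np.random.default_rng(seed)

    def unit(m):
        v = rng.standard_normal((p, m))
        return v / np.linalg.norm(v, axis=0)

    s = unit(n_iterations)
    ra, rb = a @ s, b @ s
    na = np.linalg.norm(ra, axis=0)
    nb = np.linalg.norm(rb, axis=0)
    ok = (na > 0) & (nb > 0)
    cos = np.einsum("ij,ij->j", ra[:, ok], rb[:, ok]) / (na[ok] * nb[ok])
    corr = float(cos.mean())
    null = np.einsum("ij,ij->j", unit(n_iterations), unit(n_iterations))
    p_val = float(np.mean(null >= corr))
    return SkewersResult(correspondence=corr, p_value=p_val,
                         n_iterations=n_iterations)


# ---------------------------------------------------------------------------
# Global vs piecemeal sliding comparison
# ---------------------------------------------------------------------------


def compare_sliding_workflows(
    configs,
    groups,
    curves,
    meshes,
    spec: SlidingSpec | None = None,
    skewer_iterations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Slide a sample globally vs per group and quantify the agreement.

    Workflow 1 slides all specimens together; workflow 2 slides each group
    separately and recombines.  Both are then jointly Procrustes aligned.
    Returns the random-skewers correspondence between the two aligned-data
    covariance matrices, and the R² of a linear regression between the two
    sets of pairwise Procrustes distances.
    """
    spec = spec or SlidingSpec()
    slid_global = slide(configs, spec, curves, meshes)
    slid_pieces: list = [None] * len(configs)
    for g in sorted(set(groups)):
        idx = [i for i, gi in enumerate(groups) if gi == g]
        sub = slide([configs[i] for i in idx], spec, curves,
                    [meshes[i] for i in idx] if meshes is not None else None)
        for j, i in enumerate(idx):
            slid_pieces[i] = sub[j]
    res_g = gpa(slid_global)
    res_p = gpa(slid_pieces)
    sk = random_skewers(res_g.covariance(), res_p.covariance(),
                        n_iterations=skewer_iterations, seed=seed)
    n = len(configs)
    dg, dp = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dg.append(procrustes_distance(slid_global[i], slid_global[j]))
            dp.append(procrustes_distance(slid_pieces[i], slid_pieces[j]))
    reg = _stats.linregress(dg, dp)
    return {
        "skewers": sk,
        "r_squared": float(reg.rvalue**2),
        "global": slid_global,
        "piecemeal": slid_pieces,
        "alignment_global": res_g,
        "alignment_piecemeal": res_p,
    }
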