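"""Group-structure inference and classification for e-nose feature tables.

Four tools operate on tables whose rows are corrected, normalized sensor
readings:

* **ANOSIM** — the rank-based analysis of similarities on a distance
  matrix: ``R = (mean rank of between-group distances - mean rank of
  within-group distances) / (n(n-1)/4)``, with midranks for ties.  R is 0
  when group labels carry no structure and 1 when every between-group
  distance exceeds every within-group distance.  Significance comes from a
  seeded label-permutation test, switching to exact enumeration of all
  relabelings when there are at most ``EXACT_ENUMERATION_LIMIT`` of them.
* **PCA** — centered, unit-variance-scaled principal components, used to
  draw each fruit's daily odor trajectory.
* **Ripeness staging** — days are staged against the fruit-cracking day by
  whether their 95% coverage ellipses in PC1-PC2 (Mahalanobis radius
  chi2(0.95, 2), per-day covariance) intersect the cracking day's ellipse.
* **LDA** — canonical discriminant axes, the eigenvectors of
  ``Sw^-1 Sb`` (pooled within-class vs between-class scatter), with
  nearest-class-mean classification in the whitened discriminant space and
  a confusion matrix in predicted-rows / true-columns orientation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SKPCA

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: switch from Monte-Carlo permutation to exact enumeration at or below this
#: number of distinct relabelings
EXACT_ENUMERATION_LIMIT = 20_000

STAGES = ("before_ripening", "ripened", "after_ripening", "unassigned")


# ---------------------------------------------------------------------------
# distances

def pairwise_distances(table, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise distance matrix of the table's rows."""
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D table with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite cells in feature table")
    return squareform(pdist(X, metric=metric))


def _validate_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    return D


# ---------------------------------------------------------------------------
# ANOSIM

@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "exact" | "permutation"


def _anosim_r_many(labels: np.ndarray, ranks: np.ndarray, iu: np.ndarray,
                   ju: np.ndarray, denom: float,
                   chunk: int = 64) -> np.ndarray:
    """R statistic for each row of a (B, n) label matrix, chunked to bound
    the (chunk, M) boolean mask memory."""
    out = np.empty(labels.shape[0])
    for lo in range(0, labels.shape[0], chunk):
        L = labels[lo:lo + chunk]
        within = L[:, iu] == L[:, ju]
        n_within = within.sum(axis=1)
        sum_within = (ranks * within).sum(axis=1)
        sum_total = ranks.sum()
        mean_w = sum_within / n_within
        mean_b = (sum_total - sum_within) / (ranks.size - n_within)
        out[lo:lo + chunk] = (mean_b - mean_w) / denom
    return out


def _enumerate_relabelings(counts: list[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def anosim(D, groups, n_permutations: int = 9999,
           seed: int | None = 0, method: str = "auto") -> AnosimResult:
    """One-way analysis of similarities on a distance matrix.

    ``groups`` is one label per row of ``D``; every group needs at least two
    members.  The permutation p-value is ``(#{R_perm >= R_obs} + 1) /
    (n_permutations + 1)``; when the number of distinct relabelings is at
    most :data:`EXACT_ENUMERATION_LIMIT` the full permutation distribution
    is enumerated instead and the p-value is exact.  ``method`` can force
    ``"exact"`` or ``"permutation"`` instead of the automatic switch.
    """
    if method not in ("auto", "exact", "permutation"):
        raise ValidationError(f"unknown method {method!r}")
    D = _validate_square(D)
    labels, counts = np.unique(np.asarray(groups), return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValidationError(f"groups of size 1 not allowed: {small}")
    n = D.shape[0]
    if len(np.asarray(groups)) != n:
        raise ValidationError("groups length must match distance matrix")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(D[iu, ju])  # midranks over condensed distances
    denom = n * (n - 1) / 4.0
    codes = np.searchsorted(labels, np.asarray(groups))
    r_obs = float(_anosim_r_many(codes[None, :], ranks, iu, ju, denom)[0])

    n_exact = _enumerate_relabelings(counts.tolist())
    if method == "exact" and n_exact > EXACT_ENUMERATION_LIMIT:
        raise ValidationError(
            f"{n_exact} relabelings exceed the exact-enumeration limit")
    if method != "permutation" and n_exact <= EXACT_ENUMERATION_LIMIT or \
            method == "exact":
        assignments = np.empty((n_exact, n), dtype=np.int64)
        idx_all = tuple(range(n))

        def fill(row: int, remaining: tuple, group: int,
                 current: np.ndarray) -> int:
            if group == len(labels) - 1:
                current[list(remaining)] = group
                assignments[row] = current
                return row + 1
            for combo in itertools.combinations(remaining, counts[group]):
                nxt = current.copy()
                nxt[list(combo)] = group
                row = fill(row, tuple(i for i in remaining if i not in combo),
                           group + 1, nxt)
            return row

        filled = fill(0, idx_all, 0, np.empty(n, dtype=np.int64))
        assert filled == n_exact
        r_all = _anosim_r_many(assignments, ranks, iu, ju, denom)
        p = float(np.sum(r_all >= r_obs - 1e-12) / n_exact)
        return AnosimResult(R=r_obs, p_value=p, n_permutations=n_exact,
                            seed=seed, method="exact")

    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(codes, (n_permutations, n)).copy(), axis=1)
    r_perm = _anosim_r_many(perms, ranks, iu, ju, denom)
    p = float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_permutations + 1))
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations,
                        seed=seed, method="permutation")


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray            # (n, m)
    loadings: np.ndarray          # (p, m), columns are components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...]

    def reconstruct(self) -> np.ndarray:
        """Data rebuilt from all retained components (original units)."""
        return (self.scores @ self.loadings.T) * self.scale + self.mean


def pca_fit(table, scale: bool = True) -> PCAResult:
    """PCA of a readings table: column-centered and, by default, scaled to
    unit variance (channels share units but differ widely in dynamic
    range).  Components are ordered by decreasing explained variance."""
    if isinstance(table, pd.DataFrame):
        columns = tuple(str(c) for c in table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        columns = tuple(f"x{j}" for j in range(X.shape[1]))
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 rows and >= 2 columns")
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(X.shape[1])
    Z = (X - mean) / sd
    pca = _SKPCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    return PCAResult(scores=scores, loadings=pca.components_.T,
                     explained_variance=pca.explained_variance_,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     mean=mean, scale=sd, columns=columns)


# ---------------------------------------------------------------------------
# ripeness staging

@dataclass(frozen=True)
class RipenessStage:
    fruit_id: str
    day: int
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")


def _coverage_ellipse(points: np.ndarray, coverage: float):
    """Mean, covariance and squared Mahalanobis radius of the coverage
    ellipse of a 2-D point cloud; None when the covariance is undefined."""
    if len(points) < 3:
        return None
    mu = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    # floor tiny/negative eigenvalues so degenerate (collinear) clouds still
    # yield a usable, pancake-thin ellipse
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, 1e-12 * max(w.max(), 1e-300))
    cov = (V * w) @ V.T
    c2 = stats.chi2.ppf(coverage, df=2)
    return mu, cov, c2


def _inside(points: np.ndarray, mu: np.ndarray, cov: np.ndarray,
            c2: float) -> np.ndarray:
    d = points - mu
    m2 = np.einsum("ij,ij->i", d, np.linalg.solve(cov, d.T).T)
    return m2 <= c2


def ellipses_overlap(e1, e2, n_boundary: int = 256) -> bool:
    """Whether two coverage ellipses intersect (boundary sampling plus
    mutual center containment, adequate at the plotting resolution the
    staging rule mimics)."""
    mu1, cov1, c1 = e1
    mu2, cov2, c2 = e2
    if _inside(mu1[None, :], mu2, cov2, c2)[0]:
        return True
    if _inside(mu2[None, :], mu1, cov1, c1)[0]:
        return True
    theta = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    for (mu_a, cov_a, ca), (mu_b, cov_b, cb) in ((e1, e2), (e2, e1)):
        w, V = np.linalg.eigh(cov_a)
        A = V * np.sqrt(np.maximum(w, 0.0))
        boundary = mu_a + math.sqrt(ca) * circle @ A.T
        if np.any(_inside(boundary, mu_b, cov_b, cb)):
            return True
    return False


def assign_ripeness_stages(daily_scores: pd.DataFrame, cracking_day: int,
                           coverage: float = 0.95,
                           fruit_id: str = "") -> list[RipenessStage]:
    """Stage each day of one fruit's PC1-PC2 trajectory against cracking.

    ``daily_scores`` needs columns ``day, PC1, PC2``.  A day *overlaps*
    cracking when its ``coverage`` ellipse intersects the cracking day's;
    overlapping days are ``ripened``, earlier non-overlapping days
    ``before_ripening``, later non-overlapping days ``after_ripening``.
    Days with fewer than 3 readings have no covariance and are returned
    ``unassigned`` with a warning.
    """
    for col in ("day", "PC1", "PC2"):
        if col not in daily_scores.columns:
            raise ValidationError(f"daily_scores lacks column {col!r}")
    days = sorted(daily_scores["day"].unique())
    if cracking_day not in days:
        raise ValidationError(f"cracking_day {cracking_day} not among days {days}")

    ellipses = {}
    for day in days:
        pts = daily_scores.loc[daily_scores["day"] == day,
                               ["PC1", "PC2"]].to_numpy(dtype=float)
        ellipses[day] = _coverage_ellipse(pts, coverage)
        if ellipses[day] is None:
            logger.warning("day %s has < 3 readings; stage unassigned", day)

    crack = ellipses[cracking_day]
    stages = []
    for day in days:
        e = ellipses[day]
        if e is None or crack is None:
            stage = "unassigned"
        elif day == cracking_day or ellipses_overlap(e, crack):
            stage = "ripened"
        elif day < cracking_day:
            stage = "before_ripening"
        else:
            stage = "after_ripening"
        stages.append(RipenessStage(fruit_id=fruit_id, day=int(day),
                                    stage=stage))
    return stages


# ---------------------------------------------------------------------------
# LDA

@dataclass(frozen=True)
class LDAModel:
    """Canonical discriminant model over named sensor channels.

    ``coefficients`` maps channels to per-axis weights (p x m); projections
    are ``(x - mean) @ coefficients``.  Axes are scaled so the pooled
    within-class covariance is the identity in discriminant space, and each
    axis's largest-magnitude coefficient is positive (canonical sign).
    """

    channels: tuple[str, ...]
    coefficients: np.ndarray            # (p, m)
    mean: np.ndarray                    # (p,)
    classes: tuple[str, ...] = ()
    class_means: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    priors: np.ndarray = field(default_factory=lambda: np.empty(0))
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_axes(self) -> int:
        return self.coefficients.shape[1]

    @classmethod
    def from_coefficients(cls, axes: dict[str, dict[str, float]]
                          ) -> "LDAModel":
        """Build a projection-only model from stored axis coefficients
        (e.g. published discriminant functions)."""
        channels = tuple(next(iter(axes.values())).keys())
        W = np.column_stack([
            [coefs[ch] for ch in channels] for coefs in axes.values()
        ])
        return cls(channels=channels, coefficients=W,
                   mean=np.zeros(len(channels)))

    def project(self, table) -> np.ndarray:
        X = _as_matrix(table, self.channels)
        return (X - self.mean) @ self.coefficients

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients,
            index=list(self.channels),
            columns=[f"Axis {i + 1}" for i in range(self.n_axes)])


def _as_matrix(table, channels: tuple[str, ...]) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        missing = set(channels) - set(map(str, table.columns))
        if missing:
            raise ValidationError(f"table lacks channels {sorted(missing)}")
        return table[list(channels)].to_numpy(dtype=float)
    X = np.asarray(table, dtype=float)
    if X.shape[1] != len(channels):
        raise ValidationError(
            f"expected {len(channels)} channels, got {X.shape[1]}")
    return X


def lda_fit(table, labels, ridge: float | None = None) -> LDAModel:
    """Fit canonical discriminant axes maximizing between- to within-class
    scatter.

    Axes are the leading eigenvectors of the generalized problem
    ``Sb v = lambda Sw v`` (at most ``min(#classes - 1, #channels)``).
    A near-singular pooled within-class covariance gets a logged ridge of
    ``1e-8 * trace(Sw)/p`` unless an explicit ``ridge`` is given.
    """
    if isinstance(table, pd.DataFrame):
        channels = tuple(str(c) for c in table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        channels = tuple(f"x{j}" for j in range(X.shape[1]))
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValidationError("labels length must match table rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("LDA needs >= 2 classes")
    if counts.min() < 2:
        raise ValidationError("every class needs >= 2 rows")
    n, p = X.shape
    k = len(classes)

    mu = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    mus = np.empty((k, p))
    for j, cls in enumerate(classes):
        Xc = X[y == cls]
        mus[j] = Xc.mean(axis=0)
        d = Xc - mus[j]
        Sw += d.T @ d
        db = (mus[j] - mu)[:, None]
        Sb += counts[j] * (db @ db.T)
    Sw /= (n - k)
    Sb /= max(k - 1, 1)

    if ridge is None:
        cond = np.linalg.cond(Sw)
        if not np.isfinite(cond) or cond > 1e10:
            ridge = 1e-8 * np.trace(Sw) / p
            logger.warning("near-singular within-class covariance "
                           "(cond=%.2e); adding ridge %.3e", cond, ridge)
        else:
            ridge = 0.0
    if ridge:
        Sw = Sw + ridge * np.eye(p)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise ValidationError(
            "singular within-class covariance; pass an explicit ridge"
        ) from exc
    order = np.argsort(evals)[::-1]
    m = min(k - 1, p)
    W = evecs[:, order[:m]]
    evals = evals[order[:m]]
    # canonical sign: largest-magnitude coefficient of each axis positive
    for j in range(m):
        lead = np.argmax(np.abs(W[:, j]))
        if W[lead, j] < 0:
            W[:, j] = -W[:, j]

    class_means_z = (mus - mu) @ W
    priors = counts / n
    return LDAModel(channels=channels, coefficients=W, mean=mu,
                    classes=tuple(str(c) for c in classes),
                    class_means=class_means_z, priors=priors,
                    eigenvalues=evals)


def lda_predict(model: LDAModel, table) -> np.ndarray:
    """Nearest class mean in discriminant space, under the training priors.

    The axes whiten the pooled within-class covariance, so the Euclidean
    nearest-mean rule with a ``log prior`` offset is the Gaussian
    equal-covariance classifier restricted to the discriminant subspace.
    """
    if not model.classes:
        raise ValidationError("model has no fitted class means")
    Z = model.project(table)
    d2 = ((Z[:, None, :] - model.class_means[None, :, :]) ** 2).sum(axis=2)
    scores = -0.5 * d2 + np.log(model.priors)[None, :]
    return np.asarray(model.classes)[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# confusion matrix

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = predicted class and columns = true class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> dict[str, float]:
        """Diagonal over true-class (column) total, in percent; NaN for a
        class absent from the truth."""
        out = {}
        for j, cls in enumerate(self.classes):
            total = self.counts[:, j].sum()
            out[cls] = (100.0 * self.counts[j, j] / total if total
                        else math.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(true, pred, classes=None) -> ConfusionMatrix:
    """Confusion matrix in predicted-rows / true-columns orientation.

    ``classes`` fixes the ordering (and may include classes absent from the
    test set, which then have zero column totals).
    """
    true = np.asarray(true)
    pred = np.asarray(pred)
    if len(true) != len(pred):
        raise ValidationError("true and pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([true, pred])).tolist()
    classes = [str(c) for c in classes]
    index = {c: i for i, c in enumerate(classes)}
    unknown = {str(v) for v in np.concatenate([true, pred])} - set(classes)
    if unknown:
        raise ValidationError(f"labels outside the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        counts[index[str(p)], index[str(t)]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)
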