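"""Alpha/beta diversity, rarefaction, ordination and community-level tests.

Shannon entropy is reported in nats. Bray-Curtis is computed on per-sample
percentage-normalized abundances by default, matching how the raw reads were
normalized before dissimilarity analysis. Permutation p-values always use the
(1 + exceedances) / (1 + permutations) convention and never report zero.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AsvCountTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal dissimilarity matrix with sample labels."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(d)).max(initial=0) > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValidationError("negative dissimilarity")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x k
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_perm: int
    df_between: int
    df_within: int


# ---------------------------------------------------------------------------


def rarefy_counts(table: AsvCountTable, depth: int, seed: int = 0) -> AsvCountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning; an error is raised only if nothing survives.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts
    keep_rows = []
    dropped = []
    out = []
    for sid, row in counts.iterrows():
        vec = row.to_numpy()
        total = int(vec.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            out.append(vec.copy())
        else:
            out.append(rng.multivariate_hypergeometric(vec, depth))
        keep_rows.append(sid)
    if dropped:
        logger.warning("rarefaction dropped %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    if not keep_rows:
        raise ValueError(f"all samples have fewer than {depth} reads")
    df = pd.DataFrame(np.asarray(out), index=keep_rows, columns=counts.columns)
    return AsvCountTable(df.astype(np.int64))


def alpha_diversity(table: AsvCountTable) -> pd.DataFrame:
    """Observed richness and Shannon entropy (nats) per sample."""
    arr = table.counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    observed = (arr > 0).sum(axis=1)
    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"observed": observed.astype(int), "shannon": shannon},
        index=table.counts.index.copy(),
    )


def rarefaction_curve(
    table: AsvCountTable, depths, reps: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Mean observed richness per sample over a grid of subsampling depths.

    Depths exceeding a sample's total are reported as NaN for that sample.
    """
    depths = [int(d) for d in depths]
    if not depths:
        raise ValueError("empty depth grid")
    rng = np.random.default_rng(seed)
    counts = table.counts
    result = pd.DataFrame(index=counts.index.copy(), columns=depths, dtype=float)
    for sid, row in counts.iterrows():
        vec = row.to_numpy()
        total = int(vec.sum())
        for depth in depths:
            if depth > total:
                result.at[sid, depth] = np.nan
                continue
            if depth == total:
                result.at[sid, depth] = float((vec > 0).sum())
                continue
            obs = [
                (rng.multivariate_hypergeometric(vec, depth) > 0).sum()
                for _ in range(reps)
            ]
            result.at[sid, depth] = float(np.mean(obs))
    return result


def bray_curtis_matrix(table: AsvCountTable, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities, on percentages when normalized."""
    data = table.relative(percent=True).to_numpy() if normalize else \
        table.counts.to_numpy(dtype=float)
    d = squareform(pdist(data, metric="braycurtis"))
    return DistanceMatrix(list(table.counts.index), d)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_starts``.

    The optimization alternates isotonic regression of the configuration
    distances against the input dissimilarity ranks with gradient (SMACOF)
    configuration updates (delegated to scikit-learn's non-metric MDS).
    """
    from sklearn.manifold import MDS

    n = len(dm.ids)
    if n < k + 1:
        raise ValueError("need at least k+1 points")
    if np.all(dm.d == 0):
        raise ValueError("degenerate all-zero distance matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(
            n_components=k,
            metric=False,
            n_init=n_starts,
            max_iter=max_iter,
            eps=tol,
            dissimilarity="precomputed",
            random_state=np.random.default_rng(seed).integers(2**31 - 1),
            normalized_stress=True,
            n_jobs=1,
        )
        coords = model.fit_transform(dm.d)
    stress = float(model.stress_)
    return OrdinationResult(
        ids=list(dm.ids),
        coordinates=coords,
        stress=stress,
        n_starts=n_starts,
        converged=bool(model.n_iter_ < max_iter),
    )


def stress1(dm: DistanceMatrix, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a given configuration against a dissimilarity matrix.

    The monotone fit is the isotonic regression of configuration distances on
    the rank order of the input dissimilarities.
    """
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(len(dm.ids), k=1)
    delta = dm.d[iu]
    conf = squareform(pdist(coordinates))[iu]
    order = np.argsort(delta, kind="stable")
    fitted = np.empty_like(conf)
    fitted[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), conf[order]
    )
    denom = float((conf**2).sum())
    return float(np.sqrt(((conf - fitted) ** 2).sum() / denom))


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from the Gower-centered partition of squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    groups = np.unique(labels)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA with a label-permutation null."""
    labels = np.asarray(pd.Series(groups, index=dm.ids).loc[dm.ids]) \
        if isinstance(groups, (pd.Series, dict)) else np.asarray(list(groups))
    if labels.shape[0] != len(dm.ids):
        raise ValueError("group labels must match distance matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    d2 = dm.d**2
    f_obs = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm) >= f_obs:
            exceed += 1
    n = len(labels)
    a = len(uniq)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p=(1 + exceed) / (n_perm + 1),
        n_perm=n_perm,
        df_between=a - 1,
        df_within=n - a,
    )


# ---------------------------------------------------------------------------
# rank-based group tests


@dataclass
class GroupTestReport:
    """Omnibus statistic plus Holm-adjusted pairwise comparisons."""

    method: str
    statistic: float
    p: float
    pairwise: pd.DataFrame | None  # columns: group1, group2, z, p, p_adj


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks with tie correction, Holm-adjusted."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    groups = sorted(pd.unique(labels).tolist())
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": min(1.0, p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    return df


def group_difference_tests(values, groups, alternative: str = "two-sided") -> GroupTestReport:
    """Kruskal-Wallis + Dunn/Holm for >=3 groups; Wilcoxon rank-sum for 2.

    The two-group rank-sum test is exact when both groups have at most 8
    observations, otherwise a tie-corrected normal approximation is used.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and groups must align")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if len(uniq) == 2:
        x = values[labels == uniq[0]]
        y = values[labels == uniq[1]]
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and
                             len(np.unique(values)) == len(values)) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
        return GroupTestReport("wilcoxon_rank_sum", float(res.statistic),
                               float(res.pvalue), None)
    samples = [values[labels == g] for g in uniq]
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, labels)
    return GroupTestReport("kruskal_wallis", float(h), float(p), pairwise)


def holm_adjust(p) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="holm")[1]
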