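"""Community-ecology statistics on diet profiles.

Formula-level implementations of Shannon diversity with the Hutcheson
variance and t-test, Bray-Curtis dissimilarity, PCoA, Mantel, ANOSIM,
indicator-value (IndVal) analysis, and per-item Spearman correlations.
All permutation p-values use the (1 + hits) / (1 + n_permutations)
estimator and are reproducible from an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import DietProfileMatrix
from .model import DietBarcoderError


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise DietBarcoderError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise DietBarcoderError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise DietBarcoderError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any():
            raise DietBarcoderError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]


@dataclass
class PermutationResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int | None

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise DietBarcoderError("permutation p-value out of (0, 1]")


@dataclass
class DiversityResult:
    H: float
    variance: float
    N: float
    S: int

    def __post_init__(self):
        if self.H < -1e-12 or self.variance < 0:
            raise DietBarcoderError("invalid diversity result")
        if self.S > 0 and self.H > np.log(self.S) + 1e-9:
            raise DietBarcoderError("H exceeds ln(S)")


@dataclass
class IndValResult:
    indval: pd.DataFrame  # taxa x groups, values in [0, 100]
    specificity: pd.DataFrame  # A
    fidelity: pd.DataFrame  # B
    statistic: pd.Series  # max over groups per taxon
    best_group: pd.Series
    p_value: pd.Series
    n_permutations: int
    seed: int | None


def _perm_p(observed: float, perm_stats: np.ndarray) -> float:
    return (1 + int((perm_stats >= observed - 1e-12).sum())) / (1 + len(perm_stats))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def shannon(counts) -> DiversityResult:
    """Shannon-Wiener index (natural log) with the Hutcheson variance
    approximation; ``counts`` should be counts, not fractions, for the
    variance to be meaningful."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise DietBarcoderError("negative counts")
    total = x.sum()
    if total <= 0:
        raise DietBarcoderError("all-zero input")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    s = int((x > 0).sum())
    sum_plnp2 = float((p * np.log(p) ** 2).sum())
    variance = (sum_plnp2 - h**2) / total + (s - 1) / (2 * total**2)
    return DiversityResult(H=h, variance=max(variance, 0.0), N=float(total), S=s)


def hutcheson_t(c1, c2) -> tuple:
    """Two-sided Hutcheson t-test comparing two Shannon indices.

    Returns ``(t, df, p)`` with Welch-style degrees of freedom
    ``(V1+V2)^2 / (V1^2/N1 + V2^2/N2)``.
    """
    d1, d2 = shannon(c1), shannon(c2)
    pooled = d1.variance + d2.variance
    if pooled <= 0:
        raise DietBarcoderError("zero pooled variance")
    t = (d1.H - d2.H) / np.sqrt(pooled)
    df = pooled**2 / (d1.variance**2 / d1.N + d2.variance**2 / d2.N)
    p = float(2 * sps.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


# ---------------------------------------------------------------------------
# dissimilarity and ordination
# ---------------------------------------------------------------------------


def _profile_values(profiles) -> tuple:
    if isinstance(profiles, DietProfileMatrix):
        return profiles.values.to_numpy(dtype=float), list(profiles.values.index)
    if isinstance(profiles, pd.DataFrame):
        return profiles.to_numpy(dtype=float), list(profiles.index)
    arr = np.asarray(profiles, dtype=float)
    return arr, list(range(arr.shape[0]))


def bray_curtis(profiles) -> DistanceMatrix:
    """d(i,j) = sum |x_ik - y_jk| / sum (x_ik + y_jk)."""
    x, labels = _profile_values(profiles)
    if (x < 0).any():
        raise DietBarcoderError("negative abundances")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        if (den == 0).any():
            raise DietBarcoderError("Bray-Curtis undefined for two all-zero rows")
        d[i, i + 1:] = d[i + 1:, i] = num / den
    return DistanceMatrix(labels, d)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # rows = labels, columns = axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives included)
    relative_eigenvalues: np.ndarray  # positive eigenvalues / their sum


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Principal coordinates: Gower-center -0.5 d^2, eigendecompose, embed on
    the positive axes.  Negative eigenvalues are reported, not dropped
    silently; relative eigenvalues are normalized over positive ones."""
    a = -0.5 * d.data**2
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # sign convention: first nonzero loading of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    rel = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    frame = pd.DataFrame(
        coords,
        index=pd.Index(d.labels),
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return PCoAResult(coordinates=frame, eigenvalues=evals, relative_eigenvalues=rel)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationResult:
    """Mantel test: Pearson correlation of upper-triangle entries, one-sided
    (positive association), null by joint row/column permutation of d2."""
    if d1.labels != d2.labels:
        raise DietBarcoderError("distance matrices must share labels and order")
    if d1.n < 3:
        raise DietBarcoderError("need at least 3 objects")
    v1 = d1.condensed()
    v1c = v1 - v1.mean()
    denom1 = np.sqrt((v1c**2).sum())

    iu = np.triu_indices(d1.n, k=1)

    def corr(mat):
        v2 = mat[iu]
        v2c = v2 - v2.mean()
        den = denom1 * np.sqrt((v2c**2).sum())
        if den == 0:
            raise DietBarcoderError("zero variance in distances")
        return float((v1c * v2c).sum() / den)

    observed = corr(d2.data)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(d1.n)
        perm_stats[i] = corr(d2.data[np.ix_(p, p)])
    return PermutationResult(observed, n_perm, _perm_p(observed, perm_stats), seed)


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) divided
    by n(n-1)/4, on midranks of all pairwise distances; one-sided
    permutation null over group labels."""
    groups = np.asarray(list(groups))
    if len(groups) != d.n:
        raise DietBarcoderError("one group label per object required")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise DietBarcoderError("need at least 2 groups")
    if (counts < 2).any():
        raise DietBarcoderError("every group needs at least 2 members")
    ranks = sps.rankdata(d.condensed())
    iu, ju = np.triu_indices(d.n, k=1)
    divisor = d.n * (d.n - 1) / 4

    def r_stat(g):
        within = g[iu] == g[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / divisor)

    observed = r_stat(groups)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_stats[i] = r_stat(groups[rng.permutation(d.n)])
    return PermutationResult(observed, n_perm, _perm_p(observed, perm_stats), seed)


def indval(
    profiles,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> IndValResult:
    """Indicator value analysis (specificity x fidelity x 100).

    A_kg is the group mean abundance of taxon k divided by the sum of group
    means (group-equalized), B_kg the fraction of group-g rows where k > 0;
    per-taxon significance is a permutation test of max_g IndVal_kg under
    group-label reshuffling.
    """
    x, _ = _profile_values(profiles)
    taxa = (
        list(profiles.values.columns)
        if isinstance(profiles, DietProfileMatrix)
        else list(profiles.columns)
        if isinstance(profiles, pd.DataFrame)
        else [f"taxon{i}" for i in range(x.shape[1])]
    )
    groups = np.asarray(list(groups))
    if len(groups) != x.shape[0]:
        raise DietBarcoderError("one group label per row required")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise DietBarcoderError("need at least 2 groups")
    absent = x.sum(axis=0) == 0
    if absent.any():
        warnings.warn(f"{int(absent.sum())} taxa absent everywhere: excluded")
        x = x[:, ~absent]
        taxa = [t for t, a in zip(taxa, absent) if not a]

    masks = [groups == g for g in uniq]

    def iv(mat_masks):
        means = np.array([x[m].mean(axis=0) for m in mat_masks])  # groups x taxa
        denom = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(denom > 0, means / denom, 0.0)
        b = np.array([(x[m] > 0).mean(axis=0) for m in mat_masks])
        return a, b, a * b * 100

    a_obs, b_obs, iv_obs = iv(masks)
    stat = iv_obs.max(axis=0)
    best = iv_obs.argmax(axis=0)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(taxa))
    for _ in range(n_perm):
        perm = groups[rng.permutation(len(groups))]
        pmasks = [perm == g for g in uniq]
        _, _, iv_p = iv(pmasks)
        hits += iv_p.max(axis=0) >= stat - 1e-12
    p = (1 + hits) / (1 + n_perm)

    gi = list(uniq)
    return IndValResult(
        indval=pd.DataFrame(iv_obs.T, index=taxa, columns=gi),
        specificity=pd.DataFrame(a_obs.T, index=taxa, columns=gi),
        fidelity=pd.DataFrame(b_obs.T, index=taxa, columns=gi),
        statistic=pd.Series(stat, index=taxa),
        best_group=pd.Series([gi[k] for k in best], index=taxa),
        p_value=pd.Series(p, index=taxa),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# inter-method correlation
# ---------------------------------------------------------------------------


def _match_focal_item(edna_label: str, focal_items: set) -> list:
    members = edna_label.split("/")
    return [f for f in focal_items if f in members or f == edna_label]


def spearman_by_item(
    edna: DietProfileMatrix,
    focal: DietProfileMatrix,
    focal_totals=None,
    min_focal_count: int = 350,
) -> pd.DataFrame:
    """Per-item Spearman rank correlation of monthly series.

    Items below ``min_focal_count`` total observations in the focal log
    (when ``focal_totals`` is given), and multi-species barcode labels that
    match more than one observed item, are excluded.  Items with fewer than
    3 shared months are skipped with a warning.
    """
    months = [m for m in edna.values.index if m in set(focal.values.index)]
    if len(months) < 3:
        raise DietBarcoderError("need at least 3 shared temporal units")
    focal_items = set(focal.values.columns)
    rows = []
    for label in edna.values.columns:
        matches = _match_focal_item(label, focal_items)
        if not matches:
            continue
        if "/" in label and len(matches) > 1:
            continue  # barcode shared by several observed species
        item = matches[0]
        if focal_totals is not None and focal_totals.get(item, 0) < min_focal_count:
            continue
        x = edna.values.loc[months, label].to_numpy(dtype=float)
        y = focal.values.loc[months, item].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            warnings.warn(f"item {item!r}: fewer than 3 paired months, skipped")
            continue
        rho, p = sps.spearmanr(x[ok], y[ok])
        rows.append(
            {"edna_label": label, "focal_item": item, "rho": float(rho),
             "p": float(p), "n_months": int(ok.sum())}
        )
    return pd.DataFrame(rows, columns=["edna_label", "focal_item", "rho", "p", "n_months"])
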