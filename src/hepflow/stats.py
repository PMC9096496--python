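"""Inferential machinery for sensor-space and summary analyses.

The centerpiece is the spatio-temporal cluster-based permutation test:
element-wise t statistics are thresholded at the two-tailed critical value,
supra-threshold channel×time bins of equal sign are clustered by spatial
(electrode-neighborhood) and temporal adjacency, each cluster is scored by
its mass (sum of t values), and the null distribution of the maximum
absolute cluster mass over random sign-flips (paired) or label shuffles
(independent) yields Monte-Carlo p values.  Using the maximum statistic
controls the family-wise error over all channels and time points jointly.

Also here: bin-wise permutation p values with Benjamini–Hochberg FDR,
normality-gated Pearson/Spearman correlations, mixed repeated-measures
ANOVA with Greenhouse–Geisser correction, and summary-statistic tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import canonical_label

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterTestResult",
    "build_adjacency",
    "standard_montage_positions",
    "cluster_perm_test",
    "pointwise_perm_fdr",
    "bh_fdr",
    "correlate_gate",
    "CorrelationEntry",
    "rm_anova_gg",
    "AnovaResult",
    "ttest_summary",
    "mannwhitney_u",
]


# ---------------------------------------------------------------------------
# Channel adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive electrode neighbor graph."""

    labels: list[str]
    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        for a, ns in self.neighbors.items():
            if a in ns:
                raise ValueError(f"self-adjacency at {a}")
            for b in ns:
                if a not in self.neighbors.get(b, set()):
                    raise ValueError(f"asymmetric adjacency {a}->{b}")

    def index_lists(self, labels: list[str]) -> list[np.ndarray]:
        """Neighbor indices restricted and re-indexed to ``labels`` order."""
        labels = [canonical_label(l) for l in labels]
        pos = {l: i for i, l in enumerate(labels)}
        out = []
        for lab in labels:
            ns = self.neighbors.get(lab, set())
            out.append(np.array(sorted(pos[n] for n in ns if n in pos), dtype=int))
        return out


def standard_montage_positions(labels: list[str]) -> dict[str, np.ndarray]:
    """3-D electrode positions from the bundled standard 10-10 cap montage."""
    import mne

    m = mne.channels.make_standard_montage("easycap-M1")
    pos = m.get_positions()["ch_pos"]
    out = {}
    for lab in labels:
        c = canonical_label(lab)
        if c not in pos:
            raise KeyError(f"no montage position for channel {c!r}")
        out[c] = np.asarray(pos[c], dtype=float)
    return out


def build_adjacency(
    montage: dict[str, np.ndarray],
    method: str = "distance",
    param: float = 1.6,
) -> AdjacencyGraph:
    """Neighbor graph from electrode positions.

    ``distance`` links every pair closer than ``param`` × the median
    nearest-neighbor distance; ``delaunay`` triangulates the (first two)
    position coordinates.  Both produce symmetric irreflexive graphs.
    """
    labels = [canonical_label(l) for l in montage]
    if len(labels) < 3:
        raise ValueError("need at least 3 positioned channels")
    P = np.array([np.asarray(montage[l], dtype=float) for l in montage])
    neighbors: dict[str, set[str]] = {l: set() for l in labels}

    if method == "distance":
        D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
        np.fill_diagonal(D, np.inf)
        nn = D.min(axis=1)
        cutoff = param * np.median(nn)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if D[i, j] <= cutoff:
                    neighbors[labels[i]].add(labels[j])
                    neighbors[labels[j]].add(labels[i])
    elif method == "delaunay":
        from scipy.spatial import Delaunay

        tri = Delaunay(P[:, :2])
        for simplex in tri.simplices:
            for i in simplex:
                for j in simplex:
                    if i != j:
                        neighbors[labels[i]].add(labels[j])
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    return AdjacencyGraph(labels=labels, neighbors=neighbors)


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: list[tuple[int, int]]     # (channel index, time index) bins
    mass: float                        # sum of t values (signed)
    sign: int
    p: float = float("nan")

    @property
    def channels(self) -> set[int]:
        return {c for c, _ in self.members}

    @property
    def time_bins(self) -> set[int]:
        return {t for _, t in self.members}


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_distribution: np.ndarray      # max |mass| per permutation
    n_permutations: int
    t_threshold: float
    t_obs: np.ndarray                  # (channels, time)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]


def _find_clusters(
    tmap: np.ndarray, thr: float, neighbors: list[np.ndarray]
) -> list[Cluster]:
    """Connected supra-threshold sets under channel adjacency × time contiguity."""
    C, T = tmap.shape
    out: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * tmap) > thr
        if not mask.any():
            continue
        visited = np.zeros((C, T), dtype=bool)
        for c0, t0 in zip(*np.nonzero(mask)):
            if visited[c0, t0]:
                continue
            stack = [(c0, t0)]
            visited[c0, t0] = True
            members: list[tuple[int, int]] = []
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                if t > 0 and mask[c, t - 1] and not visited[c, t - 1]:
                    visited[c, t - 1] = True
                    stack.append((c, t - 1))
                if t < T - 1 and mask[c, t + 1] and not visited[c, t + 1]:
                    visited[c, t + 1] = True
                    stack.append((c, t + 1))
                for cn in neighbors[c]:
                    if mask[cn, t] and not visited[cn, t]:
                        visited[cn, t] = True
                        stack.append((cn, t))
            cs = np.array([c for c, _ in members])
            ts = np.array([t for _, t in members])
            out.append(
                Cluster(members=members, mass=float(tmap[cs, ts].sum()), sign=sign)
            )
    return out


def _max_cluster_mass(
    tmap: np.ndarray, thr: float, neighbors: list[np.ndarray]
) -> float:
    clusters = _find_clusters(tmap, thr, neighbors)
    if not clusters:
        return 0.0
    return max(abs(c.mass) for c in clusters)


def _paired_tmaps(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps of sign-flipped differences, one row per flip."""
    n = diffs_flat.shape[0]
    sumsq = (diffs_flat ** 2).sum(axis=0)
    m = signs @ diffs_flat / n
    var = (sumsq / n - m ** 2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    return m / np.sqrt(var / n)


def _indep_tmap(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    sp = np.maximum(sp, 1e-300)
    return (ma - mb) / np.sqrt(sp * (1 / na + 1 / nb))


def cluster_perm_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    adjacency: AdjacencyGraph | list[np.ndarray],
    labels: list[str] | None = None,
    n_perm: int = 10000,
    alpha_thresh: float = 0.05,
    paired: bool = True,
    seed: int = 0,
) -> ClusterTestResult:
    """Spatio-temporal cluster permutation test between two conditions.

    ``data_a``/``data_b`` are per-subject (subjects × channels × time)
    arrays on a common channel/time grid.  Paired designs permute by
    per-subject sign flips of the difference maps; independent designs
    shuffle group labels.  The null is the maximum absolute cluster mass
    per permutation (two-tailed, both signs jointly), and Monte-Carlo
    p = (1 + #{null ≥ |mass|}) / (n_perm + 1).
    """
    data_a = np.asarray(data_a, dtype=float)
    data_b = np.asarray(data_b, dtype=float)
    if data_a.shape[1:] != data_b.shape[1:]:
        raise ValueError("channel/time grids differ between conditions")
    if isinstance(adjacency, AdjacencyGraph):
        if labels is None:
            labels = adjacency.labels
        neighbors = adjacency.index_lists(labels)
    else:
        neighbors = [np.asarray(a, dtype=int) for a in adjacency]
    C, T = data_a.shape[1:]
    if len(neighbors) != C:
        raise ValueError(f"adjacency covers {len(neighbors)} channels, data has {C}")
    rng = np.random.default_rng(seed)

    if paired:
        if data_a.shape[0] != data_b.shape[0]:
            raise ValueError("paired test requires equal subject counts")
        n = data_a.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 subjects, got {n}")
        diffs = (data_a - data_b).reshape(n, -1)
        thr = float(stats.t.ppf(1 - alpha_thresh / 2, n - 1))
        t_obs = _paired_tmaps(diffs, np.ones((1, n)))[0].reshape(C, T)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = np.empty(n_perm)
        chunk = 256
        for s in range(0, n_perm, chunk):
            tmaps = _paired_tmaps(diffs, signs[s : s + chunk])
            for r in range(tmaps.shape[0]):
                null[s + r] = _max_cluster_mass(
                    tmaps[r].reshape(C, T), thr, neighbors
                )
    else:
        na, nb = data_a.shape[0], data_b.shape[0]
        if min(na, nb) < 3:
            raise ValueError("need >= 3 subjects per group")
        xa = data_a.reshape(na, -1)
        xb = data_b.reshape(nb, -1)
        pooled = np.vstack([xa, xb])
        thr = float(stats.t.ppf(1 - alpha_thresh / 2, na + nb - 2))
        t_obs = _indep_tmap(xa, xb).reshape(C, T)
        null = np.empty(n_perm)
        for r in range(n_perm):
            perm = rng.permutation(na + nb)
            tm = _indep_tmap(pooled[perm[:na]], pooled[perm[na:]])
            null[r] = _max_cluster_mass(tm.reshape(C, T), thr, neighbors)

    clusters = _find_clusters(t_obs, thr, neighbors)
    for cl in clusters:
        cl.p = float((1 + np.sum(null >= abs(cl.mass))) / (n_perm + 1))
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(
        clusters=clusters,
        null_distribution=null,
        n_permutations=n_perm,
        t_threshold=thr,
        t_obs=t_obs,
    )


def pointwise_perm_fdr(
    data_a: np.ndarray,
    data_b: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    paired: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise permutation p values with BH-FDR across all bins.

    Returns ``(p, mask)`` with the channel×time shape of the input; each
    bin's p value comes from its own sign-flip (or label-shuffle) null,
    and the survivor mask applies Benjamini–Hochberg at level ``q``.
    """
    data_a = np.asarray(data_a, dtype=float)
    data_b = np.asarray(data_b, dtype=float)
    shape = data_a.shape[1:]
    rng = np.random.default_rng(seed)
    if paired:
        n = data_a.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 subjects, got {n}")
        diffs = (data_a - data_b).reshape(n, -1)
        t_obs = _paired_tmaps(diffs, np.ones((1, n)))[0]
        count = np.ones_like(t_obs)  # +1 correction numerator
        chunk = 256
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            tmaps = _paired_tmaps(diffs, signs)
            count += (np.abs(tmaps) >= np.abs(t_obs)[None, :]).sum(axis=0)
            done += m
    else:
        na, nb = data_a.shape[0], data_b.shape[0]
        xa, xb = data_a.reshape(na, -1), data_b.reshape(nb, -1)
        pooled = np.vstack([xa, xb])
        t_obs = _indep_tmap(xa, xb)
        count = np.ones_like(t_obs)
        for _ in range(n_perm):
            perm = rng.permutation(na + nb)
            tm = _indep_tmap(pooled[perm[:na]], pooled[perm[na:]])
            count += np.abs(tm) >= np.abs(t_obs)
    p = count / (n_perm + 1)
    _, mask = bh_fdr(p.ravel(), q)
    return p.reshape(shape), mask.reshape(shape)


def bh_fdr(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR.

    Returns ``(p_adjusted, survivor_mask)``; adjusted p values are monotone
    non-decreasing in rank.  Empty input yields empty output.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# Correlations with a normality gate
# ---------------------------------------------------------------------------

@dataclass
class CorrelationEntry:
    method: str                        # 'pearson_r' | 'spearman_rho'
    coefficient: float
    p: float
    shapiro_p_x: float
    shapiro_p_y: float
    n: int
    n_dropped: int = 0
    p_fdr: float = float("nan")


def correlate_gate(x, y, shapiro_alpha: float = 0.05) -> CorrelationEntry:
    """Pearson correlation, falling back to Spearman on non-normality.

    Shapiro–Wilk is run on each variable; if either rejects at
    ``shapiro_alpha`` the Spearman rank coefficient is reported instead of
    Pearson.  Missing values are dropped pairwise (count recorded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    ok = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    sw_x = float(stats.shapiro(x).pvalue)
    sw_y = float(stats.shapiro(y).pvalue)
    if sw_x < shapiro_alpha or sw_y < shapiro_alpha:
        r, p = stats.spearmanr(x, y)
        method = "spearman_rho"
    else:
        r, p = stats.pearsonr(x, y)
        method = "pearson_r"
    return CorrelationEntry(
        method=method, coefficient=float(r), p=float(p),
        shapiro_p_x=sw_x, shapiro_p_y=sw_y, n=int(x.size),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float                      # partial eta squared
    epsilon: float = 1.0               # GG epsilon (within effects)
    p_uncorrected: float = float("nan")


def _gg_epsilon(data: np.ndarray, groups: np.ndarray | None) -> float:
    """Greenhouse–Geisser ε from the pooled within-group covariance."""
    k = data.shape[1]
    if k == 2:
        return 1.0  # two levels cannot violate sphericity
    if groups is None:
        centered = data - data.mean(axis=0, keepdims=True)
        dof = data.shape[0] - 1
    else:
        centered = np.empty_like(data)
        dof = 0
        for g in np.unique(groups):
            sel = groups == g
            centered[sel] = data[sel] - data[sel].mean(axis=0, keepdims=True)
            dof += sel.sum() - 1
    S = centered.T @ centered / dof
    # double-center the covariance matrix
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sstar = S - row - col + S.mean()
    num = np.trace(Sstar) ** 2
    den = (k - 1) * np.sum(Sstar ** 2)
    eps = float(num / den) if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(
    data: np.ndarray, groups=None
) -> dict[str, AnovaResult]:
    """Mixed repeated-measures ANOVA with Greenhouse–Geisser correction.

    ``data`` is (subjects × within-levels), complete cases only; ``groups``
    is an optional per-subject between-group label.  Returns results for
    the within effect (``condition``), and — when groups are given — the
    between effect (``group``) and the ``interaction``.  Within-effect
    degrees of freedom are multiplied by the GG ε estimated from the
    pooled within-group covariance of the level scores.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be (subjects x k>=2 within-levels)")
    if np.isnan(data).any():
        raise ValueError("missing cells; listwise-delete before calling")
    n, k = data.shape
    groups = None if groups is None else np.asarray(groups)
    if groups is not None and len(groups) != n:
        raise ValueError("groups must align with subjects")

    gm = data.mean()
    subj_means = data.mean(axis=1)
    level_means = data.mean(axis=0)
    ss_between_subj = k * np.sum((subj_means - gm) ** 2)
    ss_within_total = np.sum((data - subj_means[:, None]) ** 2)
    ss_cond = n * np.sum((level_means - gm) ** 2)

    if groups is None:
        g = 1
        ss_group = 0.0
        ss_inter = 0.0
    else:
        uniq = np.unique(groups)
        g = len(uniq)
        ss_group = 0.0
        ss_inter = 0.0
        for gv in uniq:
            sel = groups == gv
            nj = sel.sum()
            gmean = data[sel].mean()
            ss_group += k * nj * (gmean - gm) ** 2
            cell = data[sel].mean(axis=0)
            ss_inter += nj * np.sum((cell - gmean - level_means + gm) ** 2)
    ss_subj = ss_between_subj - ss_group
    ss_err_within = ss_within_total - ss_cond - ss_inter

    df_cond = k - 1
    df_err_w = (n - g) * (k - 1)
    df_group = g - 1
    df_subj = n - g
    eps = _gg_epsilon(data, groups)

    def _within(name: str, ss_eff: float, df_eff: float) -> AnovaResult:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err_within / df_err_w
        F = ms_eff / ms_err
        p_unc = float(stats.f.sf(F, df_eff, df_err_w))
        p_gg = float(stats.f.sf(F, df_eff * eps, df_err_w * eps))
        return AnovaResult(
            effect=name, F=float(F), df1=df_eff * eps, df2=df_err_w * eps,
            p=p_gg, p_uncorrected=p_unc, epsilon=eps,
            eta_sq=float(ss_eff / (ss_eff + ss_err_within)),
        )

    out = {"condition": _within("condition", ss_cond, df_cond)}
    if groups is not None:
        ms_g = ss_group / df_group
        ms_s = ss_subj / df_subj
        Fg = ms_g / ms_s
        out["group"] = AnovaResult(
            effect="group", F=float(Fg), df1=float(df_group),
            df2=float(df_subj), p=float(stats.f.sf(Fg, df_group, df_subj)),
            p_uncorrected=float(stats.f.sf(Fg, df_group, df_subj)),
            epsilon=1.0,
            eta_sq=float(ss_group / (ss_group + ss_subj)),
        )
        out["interaction"] = _within(
            "interaction", ss_inter, df_group * df_cond
        )
    return out


# ---------------------------------------------------------------------------
# Summary-statistic tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    orientation: str = "b_minus_a"


def ttest_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TTestResult:
    """Pooled-variance two-sample t test from printed summary statistics.

    The statistic is oriented as (mean_b − mean_a): reporting groups in the
    order (first group, second group) reproduces published group-order-
    dependent signs.  df = n_a + n_b − 2.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return TTestResult(t=0.0, df=n_a + n_b - 2, p=1.0)
        raise ValueError("zero variance with unequal means: t is infinite")
    res = stats.ttest_ind_from_stats(
        mean_b, sd_b, n_b, mean_a, sd_a, n_a, equal_var=True
    )
    return TTestResult(
        t=float(res.statistic), df=float(n_a + n_b - 2), p=float(res.pvalue)
    )


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (x-orientation) with midrank ties.

    Exact p for small tie-free samples (n ≤ 20 per group), otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
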