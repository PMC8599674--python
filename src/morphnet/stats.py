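"""Group statistics: volumetric, edgewise, nodewise and correlational tests.

Implements the statistical battery applied to a two-group cohort:

* per-ROI GMV comparison by a linear model with a TIV nuisance covariate;
* edgewise MC comparison by independent two-sample t-tests with
  Benjamini-Hochberg FDR across all N(N-1)/2 edges, followed by
  summarization of significant edges into same-sign connected clusters
  (clusters with more than ``min_cluster_edges`` edges reported);
* nodewise degree comparison at every sparsity threshold (BH across
  nodes within each threshold), plus the same machinery for global
  metrics;
* Pearson correlation of selected features with pain scores within each
  group, BH-corrected within each feature family;
* per-ROI GLM of GMV on pain score with TIV covariate, with a primary
  p < 0.005 threshold followed by FDR (an ROI-level stand-in for
  voxel-cluster inference).

The two-sample test defaults to the Student (pooled-variance) variant;
Welch is available behind a flag and the variant used is recorded in
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, ZeroVarianceError

TTEST_VARIANTS = ("student", "welch")


def validate_subject_table(table: pd.DataFrame, min_per_group: int = 3) -> list[str]:
    """Check a subject table and return the two group labels, sorted."""
    required = {"subject_id", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"subject table missing columns: {sorted(missing)}")
    groups = sorted(table["group"].unique().tolist())
    if len(groups) != 2:
        raise ConfigError(f"need exactly two groups, found {groups}")
    counts = table["group"].value_counts()
    if (counts < min_per_group).any():
        raise ConfigError(
            f"each group needs >= {min_per_group} subjects, got {counts.to_dict()}"
        )
    return groups


# ---------------------------------------------------------------------------
# primitive tests


def welch_or_student_ttest(
    x: np.ndarray, y: np.ndarray, variant: str = "student", label: str = ""
) -> tuple[float, float]:
    """Two-sided independent two-sample t-test.

    ``variant`` selects Student's pooled-variance test (default) or
    Welch's unequal-variance test.
    """
    if variant not in TTEST_VARIANTS:
        raise ConfigError(f"t-test variant must be one of {TTEST_VARIANTS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ConfigError("each sample needs length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigError("non-finite values in t-test input")
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0.0:
        raise ZeroVarianceError(
            f"zero pooled variance in t-test{f' for {label}' if label else ''}"
        )
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection mask.

    The mask follows the step-up definition (reject where the adjusted
    value is <= q); adjusted values are monotone and >= p. Empty input
    yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ConfigError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


@dataclass
class EdgeStatsResult:
    """Edgewise group-comparison result over the upper triangle."""

    roi_ids: list[int]
    edge_i: np.ndarray  # node indices (into roi_ids) of each edge
    edge_j: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    variant: str = "student"
    alpha: float = 0.05

    @property
    def direction(self) -> np.ndarray:
        """+1 where group A exceeds group B, -1 otherwise."""
        return np.where(self.t >= 0, 1, -1)

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.roi_ids)
        return pd.DataFrame(
            {
                "roi_i": ids[self.edge_i],
                "roi_j": ids[self.edge_j],
                "group_A_mean": self.mean_a,
                "group_B_mean": self.mean_b,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "significant": self.mask,
            }
        )


def _vectorized_ttest(
    a: np.ndarray, b: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise two-sample t over (n_subjects, n_features) stacks."""
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    dead = np.flatnonzero(var_a + var_b == 0.0)
    if dead.size:
        raise ZeroVarianceError(
            f"zero pooled variance at feature indices {dead[:10].tolist()}"
        )
    res = sps.ttest_ind(a, b, axis=0, equal_var=(variant == "student"))
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def edgewise_group_test(
    mc_stack_a: np.ndarray,
    mc_stack_b: np.ndarray,
    roi_ids: list[int],
    q: float = 0.05,
    variant: str = "student",
) -> EdgeStatsResult:
    """Independent two-sample t-test per MC edge with joint BH-FDR.

    ``mc_stack_a``/``mc_stack_b`` are (n_subjects, N, N) arrays sharing
    the parcellation's node order; only the N(N-1)/2 upper-triangle edges
    are tested and corrected jointly.
    """
    if variant not in TTEST_VARIANTS:
        raise ConfigError(f"t-test variant must be one of {TTEST_VARIANTS}")
    a = np.asarray(mc_stack_a, dtype=float)
    b = np.asarray(mc_stack_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ConfigError("MC stacks must be (n_subjects, N, N) on a shared grid")
    n = a.shape[1]
    if n != len(roi_ids):
        raise ConfigError("roi_ids length does not match matrix size")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ConfigError("each group needs >= 3 subjects")
    iu, ju = np.triu_indices(n, k=1)
    ea, eb = a[:, iu, ju], b[:, iu, ju]
    t, p = _vectorized_ttest(ea, eb, variant)
    qvals, mask = fdr_bh(p, q)
    return EdgeStatsResult(
        roi_ids=list(roi_ids),
        edge_i=iu,
        edge_j=ju,
        t=t,
        p=p,
        q=qvals,
        mask=mask,
        mean_a=ea.mean(axis=0),
        mean_b=eb.mean(axis=0),
        variant=variant,
        alpha=q,
    )


@dataclass
class EdgeCluster:
    """A connected component of same-sign significant edges."""

    edges: list[tuple[int, int]]  # ROI-id pairs
    sign: int  # +1 increased in group A, -1 decreased

    @property
    def size(self) -> int:
        return len(self.edges)


def cluster_significant_edges(
    result: EdgeStatsResult,
    min_cluster_edges: int = 4,
    use_uncorrected: bool = False,
) -> list[EdgeCluster]:
    """Group significant edges into same-sign connected clusters.

    Vertices are ROIs; an edge joins its two ROIs when it is significant.
    Components are formed separately for positive-t and negative-t edges
    and only components with strictly more than ``min_cluster_edges``
    edges are returned, sorted by size descending. ``use_uncorrected``
    clusters on the raw-p mask (p < alpha) instead of the FDR mask.
    """
    sig = (result.p < result.alpha) if use_uncorrected else result.mask
    ids = np.asarray(result.roi_ids)
    clusters: list[EdgeCluster] = []
    for sign in (1, -1):
        sel = sig & (result.direction == sign)
        g = nx.Graph()
        g.add_edges_from(
            zip(ids[result.edge_i[sel]].tolist(), ids[result.edge_j[sel]].tolist())
        )
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            if sub.number_of_edges() > min_cluster_edges:
                edges = sorted(tuple(sorted(e)) for e in sub.edges())
                clusters.append(EdgeCluster(edges=edges, sign=sign))
    clusters.sort(key=lambda c: -c.size)
    return clusters


# ---------------------------------------------------------------------------
# network-property comparisons


def nodewise_degree_test(
    degrees_a: np.ndarray,
    degrees_b: np.ndarray,
    sparsities: np.ndarray,
    roi_ids: list[int],
    q: float = 0.05,
    variant: str = "student",
    report_fraction: float = 1.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-(node, sparsity) degree comparison; BH across nodes per threshold.

    ``degrees_a``/``degrees_b`` are (n_subjects, n_sparsities, N) arrays.
    A node with zero degree variance in both groups at some threshold
    (floor/ceiling effects of the sweep) is assigned t = 0, p = 1 there
    rather than raising. Returns the tidy per-cell table and the list of
    ROI ids significant in at least ``report_fraction`` of thresholds.
    """
    a = np.asarray(degrees_a, dtype=float)
    b = np.asarray(degrees_b, dtype=float)
    if a.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ConfigError("degree stacks must be (n_subjects, n_sparsities, N)")
    n_s, n_nodes = a.shape[1], a.shape[2]
    if n_s != len(sparsities) or n_nodes != len(roi_ids):
        raise ConfigError("sparsity grid or node order mismatch")
    rows = []
    sig_counts = np.zeros(n_nodes, dtype=int)
    for k, s in enumerate(np.asarray(sparsities, dtype=float)):
        xa, xb = a[:, k, :], b[:, k, :]
        var_sum = xa.var(axis=0, ddof=1) + xb.var(axis=0, ddof=1)
        t = np.zeros(n_nodes)
        p = np.ones(n_nodes)
        live = var_sum > 0
        if live.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sps.ttest_ind(
                    xa[:, live], xb[:, live], axis=0, equal_var=(variant == "student")
                )
            t[live] = res.statistic
            p[live] = res.pvalue
        qvals, mask = fdr_bh(p, q)
        sig_counts += mask.astype(int)
        for idx in range(n_nodes):
            rows.append(
                {
                    "sparsity": s,
                    "roi_id": roi_ids[idx],
                    "group_A_mean": xa[:, idx].mean(),
                    "group_B_mean": xb[:, idx].mean(),
                    "t": t[idx],
                    "p": p[idx],
                    "q": qvals[idx],
                    "significant": bool(mask[idx]),
                }
            )
    need = int(np.ceil(report_fraction * n_s))
    reported = [roi_ids[i] for i in range(n_nodes) if sig_counts[i] >= need]
    return pd.DataFrame(rows), reported


def global_metric_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    sparsities: np.ndarray,
    metric: str,
    q: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Group comparison of one global metric at every sparsity (BH across
    the sweep's thresholds). Thresholds where the metric is constant in
    both groups (floor/ceiling effects of the binarization) get t = 0,
    p = 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != len(sparsities):
        raise ConfigError("global metric stacks must be (n_subjects, n_sparsities)")
    var_sum = a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)
    t = np.zeros(a.shape[1])
    p = np.ones(a.shape[1])
    live = var_sum > 0
    if live.any():
        t[live], p[live] = _vectorized_ttest(a[:, live], b[:, live], variant)
    qvals, mask = fdr_bh(p, q)
    return pd.DataFrame(
        {
            "metric": metric,
            "sparsity": np.asarray(sparsities, dtype=float),
            "group_A_mean": a.mean(axis=0),
            "group_B_mean": b.mean(axis=0),
            "t": t,
            "p": p,
            "q": qvals,
            "significant": mask,
        }
    )


# ---------------------------------------------------------------------------
# volumetric models


def _group_covariate_fit(
    y: np.ndarray, group_ind: np.ndarray, covariate: np.ndarray | None, label: str
) -> tuple[float, float]:
    """t and p of the group indicator in y ~ 1 + group + covariate."""
    cols = [group_ind]
    if covariate is not None:
        cols.append(covariate)
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError(f"rank-deficient design for {label}")
    fit = sm.OLS(y, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def roi_gmv_group_test(
    gmv_table: pd.DataFrame,
    subject_table: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI GMV ~ group + TIV linear model; BH across ROIs.

    The reported t is for the group indicator (positive when the first
    group label, sorted alphabetically, has larger adjusted GMV). A TIV
    column with zero variance is dropped from the design with a warning,
    reducing the model to a plain two-sample comparison.
    """
    groups = validate_subject_table(subject_table)
    merged = gmv_table.merge(subject_table, on="subject_id", validate="many_to_one")
    if "tiv_mm3" not in merged.columns:
        raise ConfigError("subject table must carry a tiv_mm3 column")
    rows = []
    for roi_id, sub in merged.groupby("roi_id", sort=True):
        y = sub["gmv_mm3"].to_numpy(float)
        g = (sub["group"] == groups[0]).to_numpy(float)
        tiv = sub["tiv_mm3"].to_numpy(float)
        cov: np.ndarray | None = tiv
        if np.var(tiv) == 0.0:
            warnings.warn(
                "TIV is constant across subjects; dropping the covariate",
                stacklevel=2,
            )
            cov = None
        t, p = _group_covariate_fit(y, g, cov, f"ROI {roi_id}")
        rows.append(
            {
                "roi_id": roi_id,
                "group_A_mean": y[g == 1].mean(),
                "group_B_mean": y[g == 0].mean(),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"], out["significant"] = fdr_bh(out["p"].to_numpy(), q)
    return out


def gmv_pain_glm(
    gmv_table: pd.DataFrame,
    subject_table: pd.DataFrame,
    p_threshold: float = 0.005,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-ROI GLM of GMV on pain score with TIV covariate, one group.

    ROIs first pass a primary uncorrected threshold (default p < 0.005,
    the conventional cluster-forming level); BH-FDR is then applied
    across the ROIs surviving it. This is an ROI-level stand-in for
    voxel-cluster inference.
    """
    if subject_table["group"].nunique() != 1:
        raise ConfigError("gmv_pain_glm expects a single-group subject table")
    merged = gmv_table.merge(subject_table, on="subject_id", validate="many_to_one")
    rows = []
    for roi_id, sub in merged.groupby("roi_id", sort=True):
        y = sub["gmv_mm3"].to_numpy(float)
        pain = sub["pain_score"].to_numpy(float)
        tiv = sub["tiv_mm3"].to_numpy(float)
        cov: np.ndarray | None = tiv
        if np.var(tiv) == 0.0:
            cov = None
        t, p = _group_covariate_fit(y, pain, cov, f"ROI {roi_id}")
        rows.append({"roi_id": roi_id, "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["primary"] = out["p"] < p_threshold
    out["q"] = np.nan
    out["significant"] = False
    if out["primary"].any():
        sel = out.index[out["primary"]]
        qvals, mask = fdr_bh(out.loc[sel, "p"].to_numpy(), q)
        out.loc[sel, "q"] = qvals
        out.loc[sel, "significant"] = mask
    return out


# ---------------------------------------------------------------------------
# correlations


def pearson_correlation(feature: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and two-sided p between a feature and pain scores."""
    f = np.asarray(feature, dtype=float)
    s = np.asarray(scores, dtype=float)
    if f.size != s.size or f.size < 4:
        raise ConfigError("correlation needs matched vectors of length >= 4")
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(s))):
        raise ConfigError("non-finite values in correlation input")
    if np.var(f) == 0.0 or np.var(s) == 0.0:
        raise ZeroVarianceError("zero variance in correlation input")
    r, p = sps.pearsonr(f, s)
    return float(r), float(p)


def correlate_features(
    features: pd.DataFrame, scores: np.ndarray, q: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each feature column with the scores, BH
    across the columns (one feature family). A column with zero variance
    (e.g. a degree saturated by the sweep) yields r = NaN and is excluded
    from the correction."""
    rows = []
    for name in features.columns:
        try:
            r, p = pearson_correlation(features[name].to_numpy(float), scores)
        except ZeroVarianceError:
            r, p = float("nan"), float("nan")
        rows.append({"feature": name, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    live = out.index[out["p"].notna()]
    if len(live):
        qvals, mask = fdr_bh(out.loc[live, "p"].to_numpy(), q)
        out.loc[live, "q"] = qvals
        out.loc[live, "significant"] = mask
    return out


def fisher_z_interval(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence band for a population correlation at sample size n."""
    if n < 4:
        raise ConfigError("Fisher-z interval needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = sps.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))
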