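"""Behavioural statistics for the host-acceptance and tracking assays.

Implements the full analysis chain applied to a classified-larva bioassay
table: proportion metrics (survival, host acceptance, dispersal rate,
post-feeding dispersal *PFD*, on-plant feeders *IFP*), quasi-binomial
logistic regression of survival on exposure time, factorial ANOVA after a
Box-Cox transform, Tukey / Tukey–Kramer multiple comparisons with a compact
letter display, Pearson correlation, correlation-matrix PCA with
Kaiser-criterion retention, and average-linkage (UPGMA) hierarchical
clustering of treatments with a dendrogram cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.special import boxcox as _boxcox_tf
from statsmodels.stats.anova import anova_lm

from .synthetic import BIOASSAY_COLUMNS
from .util import as_rng, expit

FATE_COLUMNS = ["on_fed", "on_notfed", "off_fed", "off_notfed", "unrecovered"]
METRIC_COLUMNS = ["survival", "host_acceptance", "dispersal_rate", "pfd", "ifp"]


# ---------------------------------------------------------------------------
# Proportion metrics
# ---------------------------------------------------------------------------

def validate_bioassay(records: pd.DataFrame) -> None:
    """Check schema, non-negative counts and the five-category sum identity."""
    missing = [c for c in BIOASSAY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"bioassay table missing columns: {missing}")
    counts = records[FATE_COLUMNS + ["released"]]
    if (counts.to_numpy() < 0).any():
        bad = records.index[(counts < 0).any(axis=1)].tolist()
        raise ValueError(f"negative counts in rows {bad}")
    total = records[FATE_COLUMNS].sum(axis=1)
    bad = records.index[total != records["released"]].tolist()
    if bad:
        raise ValueError(
            f"count conservation violated (fates != released) in rows {bad}")


def compute_metrics(records: pd.DataFrame,
                    denominator_mode: str = "recovered") -> pd.DataFrame:
    """Per-plant behavioural proportions from classified larval counts.

    survival
        recovered-alive larvae / released.  ``unrecovered`` absorbs both
        death and escape; the assay cannot separate them.
    host_acceptance, dispersal_rate, pfd, ifp
        on-plant, off-plant, fed-and-off (*PFD*) and fed-and-on (*IFP*)
        larvae divided by recovered-alive larvae (``denominator_mode =
        "recovered"``, the default, keeps on/off complementary) or by
        released larvae (``"released"``).

    Plants with zero recovered larvae get NaN for the four conditional
    metrics rather than 0/0.
    """
    if denominator_mode not in ("recovered", "released"):
        raise ValueError("denominator_mode must be 'recovered' or 'released'")
    validate_bioassay(records)
    out = records[["block", "strain", "variety", "interval_h"]].copy()
    recovered = records[FATE_COLUMNS[:4]].sum(axis=1)
    out["survival"] = recovered / records["released"]
    denom = (recovered if denominator_mode == "recovered"
             else records["released"]).astype(float)
    denom = denom.where(denom > 0, np.nan)
    out["host_acceptance"] = (records["on_fed"] + records["on_notfed"]) / denom
    out["dispersal_rate"] = (records["off_fed"] + records["off_notfed"]) / denom
    out["pfd"] = records["off_fed"] / denom
    out["ifp"] = records["on_fed"] / denom
    return out


# ---------------------------------------------------------------------------
# Quasi-binomial logistic survival regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Quasi-binomial logit fit of survival on exposure time for one strain."""

    strain: str
    b0: float
    b1: float
    se_b0: float
    se_b1: float
    deviance: float
    dispersion: float
    df_resid: int
    separable: bool = False

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return expit(self.b0 + self.b1 * np.asarray(t, dtype=float))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald intervals (normal quantiles, dispersion-scaled SEs)."""
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        return np.array([
            [self.b0 - z * self.se_b0, self.b0 + z * self.se_b0],
            [self.b1 - z * self.se_b1, self.b1 + z * self.se_b1],
        ])


def fit_survival_logistic(records: pd.DataFrame, strain: str) -> LogisticFit:
    """Fit recovered-alive/released ~ exposure time, logit link,
    quasi-binomial dispersion (Pearson X^2 / df) scaling the SEs."""
    validate_bioassay(records)
    sub = records[records["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no records for strain {strain!r}")
    times = sub["interval_h"].to_numpy(dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError("need >= 2 distinct exposure times to fit a slope")
    alive = sub[FATE_COLUMNS[:4]].sum(axis=1).to_numpy(dtype=float)
    dead = sub["released"].to_numpy(dtype=float) - alive
    endog = np.column_stack([alive, dead])
    exog = sm.add_constant(times)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    res = model.fit()
    # Quasi-binomial dispersion = Pearson X^2 / df.  Computed from
    # res.pearson_chi2 (which weights by the number of trials) rather than
    # fit(scale="X2"), whose scale estimate ignores the trial counts for
    # two-column endog and comes out ~1/n too small.
    dispersion = float(res.pearson_chi2 / res.df_resid)
    b0, b1 = res.params
    se0, se1 = res.bse * np.sqrt(dispersion)
    separable = bool(np.abs(res.params).max() > 25 or not np.isfinite(res.bse).all())
    if separable:
        warnings.warn(
            f"survival fit for strain {strain!r} shows (quasi-)complete "
            "separation; coefficients are unreliable", RuntimeWarning)
    return LogisticFit(strain, float(b0), float(b1), float(se0), float(se1),
                       float(res.deviance), dispersion,
                       int(res.df_resid), separable)


# ---------------------------------------------------------------------------
# Box-Cox factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Effect table (effect, df, F, P) plus the Box-Cox lambda used."""

    table: pd.DataFrame
    lam: float

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def boxcox_lambda(y: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Profile-likelihood Box-Cox lambda on a grid over [-2, 2] (step 0.01)."""
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("Box-Cox requires a strictly positive response")
    if grid is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    ll = np.array([sps.boxcox_llf(l, y) for l in grid])
    return float(grid[int(np.argmax(ll))])


def boxcox_anova(data: pd.DataFrame, response: str, formula_rhs: str,
                 lam: float | None = None,
                 zero_offset: float | None = None) -> AnovaTable:
    """Box-Cox-transform ``response`` and fit the factorial linear model.

    ``lam=None`` estimates lambda by profile likelihood on a [-2, 2] grid
    (step 0.01).  Zero or negative responses are shifted by ``zero_offset``
    (e.g. 0.5/n for proportions out of n trials); without an offset they
    raise, naming the option.  F statistics under ``lam=1`` equal those of
    the untransformed ANOVA (the transform is then affine).
    """
    df = data.dropna(subset=[response]).copy()
    y = df[response].to_numpy(dtype=float)
    if len(y) == 0:
        raise ValueError("no non-missing response values")
    if (y <= 0).any():
        if zero_offset is None:
            raise ValueError(
                f"response {response!r} has non-positive values; pass "
                "zero_offset (e.g. 0.5/n for proportions of n trials)")
        y = y + zero_offset
        if (y <= 0).any():
            raise ValueError("response still non-positive after zero_offset")
    if lam is None:
        lam = boxcox_lambda(y)
    df["_bc"] = _boxcox_tf(y, lam)
    fit = smf.ols(f"_bc ~ {formula_rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NaN F for aliased rows is expected
        tab = anova_lm(fit, typ=2)
    tab = tab.rename(columns={"df": "df", "F": "F", "PR(>F)": "P"})
    tab.index = [i.replace("C(", "").replace(")", "").replace(":", " x ")
                 for i in tab.index]
    return AnovaTable(tab[["df", "F", "P"]], float(lam))


# ---------------------------------------------------------------------------
# Tukey / Tukey-Kramer pairwise comparisons + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    pairs: pd.DataFrame           # group_a, group_b, diff, se, q, p_adj
    letters: dict[str, str]       # compact letter display
    means: pd.Series
    mse: float
    df_resid: int


def tukey_pairwise(data: pd.DataFrame, response: str, group: str,
                   alpha: float = 0.05) -> TukeyResult:
    """Studentized-range pairwise comparisons of group means.

    Unequal group sizes use the Tukey–Kramer standard error
    ``sqrt(MSE/2 * (1/n_i + 1/n_j))``.  Groups sharing a letter in the
    compact letter display are not significantly different at ``alpha``.
    """
    df = data.dropna(subset=[response])
    groups = df.groupby(group, observed=True)[response]
    means = groups.mean()
    ns = groups.size()
    k = len(means)
    if k < 2:
        raise ValueError("need >= 2 groups for pairwise comparisons")
    n_tot = int(ns.sum())
    df_resid = n_tot - k
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (one obs per group)")
    sse = float(((df[response] - df[group].map(means)) ** 2).sum())
    mse = sse / df_resid
    labels = list(means.index)
    rows = []
    sig_pairs: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            diff = float(means[a] - means[b])
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
            else:
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            p = min(p, 1.0)
            rows.append((a, b, diff, float(se), float(q), p))
            if p < alpha:
                sig_pairs.add((a, b))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "diff",
                                        "se", "q", "p_adj"])
    letters = compact_letter_display(means, sig_pairs)
    return TukeyResult(pairs, letters, means, mse, df_resid)


def compact_letter_display(means: pd.Series,
                           sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb letter assignment; ties broken by descending mean."""
    order = list(means.sort_values(ascending=False).index)
    sig = {frozenset(p) for p in sig_pairs}
    cols: list[set[str]] = [set(order)]
    for a, b in [tuple(p) for p in sig]:
        new_cols = []
        for col in cols:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns contained in another
        cols = []
        for col in new_cols:
            if not any(col < other for other in new_cols if other is not col):
                if col not in cols:
                    cols.append(col)
    # letter columns ordered by the highest-mean member they contain
    def col_key(col: set[str]) -> int:
        return min(order.index(g) for g in col) if col else len(order)
    cols.sort(key=col_key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, col in zip(alphabet, cols):
        for g in order:
            if g in col:
                out[g] += letter
    return out


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on constant or mismatched input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Correlation-matrix PCA with Kaiser retention
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending
    eigenvectors: np.ndarray       # columns, unit norm
    variance_explained: np.ndarray  # percent, sums to 100
    retained: int                   # Kaiser criterion (eigenvalue > 1)
    scores: np.ndarray | None = None
    columns: list[str] = field(default_factory=list)


def kaiser_retained(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue > 1 (correlation-matrix PCA)."""
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def pca_correlation(data: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix (z-scored variables).

    Eigenvalues sum to the number of variables; components are retained by
    the Kaiser criterion (eigenvalue > 1).
    """
    df = data.dropna()
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 complete rows")
    sd = df.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    z = (df - df.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    vals = np.clip(vals, 0.0, None)
    return PCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        variance_explained=vals / df.shape[1] * 100.0,
        retained=kaiser_retained(vals),
        scores=z.to_numpy() @ vecs,
        columns=list(df.columns),
    )


# ---------------------------------------------------------------------------
# Average-linkage (UPGMA) clustering of treatments
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Ordered merge list of an agglomerative clustering.

    ``merges`` rows are (cluster_a, cluster_b, height, size); clusters
    0..n-1 are the leaves (in ``labels`` order), cluster n+i is the result
    of merge i.  Average linkage on a metric gives non-decreasing heights.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, height: float) -> dict[str, int]:
        """Group membership after cutting all links above ``height``."""
        flat = sch.fcluster(self.merges, t=height, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def n_groups(self, height: float) -> int:
        return len(set(self.cut(height).values()))

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = sch.to_tree(self.merges)

        def rec(node, parent_h: float) -> str:
            bl = parent_h - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{bl:.6g}")

        return (f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});")


def cluster_treatments(data: pd.DataFrame | np.ndarray,
                       labels: list[str] | None = None) -> Dendrogram:
    """UPGMA (unweighted average linkage) on Euclidean distances."""
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in data.index]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in the metric matrix")
    Z = sch.linkage(ssd.pdist(X), method="average")
    return Dendrogram(Z, list(labels))


# ---------------------------------------------------------------------------
# Video-tracking endpoint analysis
# ---------------------------------------------------------------------------

def analyze_tracks(tracks: pd.DataFrame,
                   endpoints: tuple[str, ...] = ("distance_cm", "velocity_cm_s",
                                                 "mobility_s"),
                   lam: float = 1.0) -> dict[str, tuple[AnovaTable, TukeyResult]]:
    """Strain x variety ANOVA plus Tukey letters for each movement endpoint.

    Track endpoints are analysed untransformed by default (``lam = 1``).
    """
    out = {}
    df = tracks.copy()
    df["cell"] = df["strain"].astype(str) + ":" + df["variety"].astype(str)
    for ep in endpoints:
        anova = boxcox_anova(df, ep, "C(strain) * C(variety)", lam=lam)
        tukey = tukey_pairwise(df, ep, "cell")
        out[ep] = (anova, tukey)
    return out


# ---------------------------------------------------------------------------
# Half-normal residual diagnostic with simulated envelope
# ---------------------------------------------------------------------------

def halfnormal_envelope(records: pd.DataFrame, strain: str,
                        n_sims: int = 99,
                        rng: np.random.Generator | int | None = None
                        ) -> pd.DataFrame:
    """Half-normal plot coordinates for the survival GLM, with a simulated
    envelope: columns quantile, observed, lower, upper (data, not graphics)."""
    fit = fit_survival_logistic(records, strain)
    sub = records[records["strain"] == strain]
    t = sub["interval_h"].to_numpy(dtype=float)
    n = sub["released"].to_numpy(dtype=float)
    alive = sub[FATE_COLUMNS[:4]].sum(axis=1).to_numpy(dtype=float)
    p_hat = fit.predict(t)

    def abs_dev_resid(obs: np.ndarray) -> np.ndarray:
        eps = 1e-12
        p = np.clip(p_hat, eps, 1 - eps)
        o = np.clip(obs / n, eps, 1 - eps)
        d2 = 2 * n * (o * np.log(o / p) + (1 - o) * np.log((1 - o) / (1 - p)))
        return np.sort(np.sqrt(np.clip(d2, 0, None)))

    m = len(t)
    rng = as_rng(rng)
    sims = np.empty((n_sims, m))
    for s in range(n_sims):
        sim_alive = rng.binomial(n.astype(int), p_hat).astype(float)
        sims[s] = abs_dev_resid(sim_alive)
    q = sps.halfnorm.ppf((np.arange(1, m + 1) + m - 1 / 8) / (2 * m + 1 / 2))
    return pd.DataFrame({
        "quantile": q,
        "observed": abs_dev_resid(alive),
        "lower": sims.min(axis=0),
        "upper": sims.max(axis=0),
    })
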