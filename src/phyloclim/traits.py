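"""Trait coding, contingency tests, regressions, partitioning, ploidy.

Leaf architecture is coded 0 simple / 1 unifoliolate / 2 trifoliolate /
3 multifoliolate and collapsed to simple-vs-compound for the statistical
models.  Climate-group contrasts use Pearson chi-squared with pairwise
Yates-corrected posthoc tests (BH-adjusted); continuous trait-climate
models are ordinary and Firth-penalized logistic regressions, Gini-based
recursive partitioning with a minimum terminal-node size, and a bagged
random forest with out-of-bag permutation importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

LEAF_CODES = {0: "simple", 1: "unifoliolate", 2: "trifoliolate", 3: "multifoliolate"}


def collapse_leaf_binary(leaf_type):
    """Collapse the 4-state leaf coding to 0 simple / 1 compound.

    Accepts a scalar, a dict, or a pandas Series; uni-, tri-, and
    multifoliolate all count as compound.
    """
    def one(v):
        v = int(v)
        if v not in LEAF_CODES:
            raise ValueError(f"unknown leaf code {v}")
        return 0 if v == 0 else 1

    if isinstance(leaf_type, dict):
        return {k: one(v) for k, v in leaf_type.items()}
    if isinstance(leaf_type, pd.Series):
        return leaf_type.map(one)
    return one(leaf_type)


# ----------------------------------------------------------------------
# contingency


@dataclass
class ContingencyResult:
    observed: pd.DataFrame  # groups x trait states
    chi2: float
    df: int
    p: float
    posthoc: pd.DataFrame  # pairwise 2x2 tests, BH-adjusted


def crosstab(trait, group, adjust: str = "fdr_bh") -> ContingencyResult:
    """Trait-by-group contingency test with pairwise posthoc comparisons.

    The overall Pearson chi-squared on the full groups-by-states table is
    uncorrected; posthoc tests are all pairwise group comparisons on 2x2
    (or 2xc) subtables with Yates continuity correction for 2x2, p-values
    adjusted by Benjamini-Hochberg (configurable via ``adjust``).
    """
    trait = pd.Series(trait)
    group = pd.Series(group)
    df = pd.DataFrame({"trait": trait, "group": group}).dropna()
    obs = pd.crosstab(df["group"], df["trait"])
    empty = [g for g in obs.index if obs.loc[g].sum() == 0]
    if empty:
        warnings.warn(f"groups with zero members excluded: {empty}", stacklevel=2)
        obs = obs.drop(index=empty)
    if len(obs) < 2:
        raise ValueError("need at least two non-empty groups")
    chi2, p, dof, _ = stats.chi2_contingency(obs.to_numpy(), correction=False)

    rows = []
    for g1, g2 in combinations(obs.index, 2):
        sub = obs.loc[[g1, g2]].to_numpy()
        sub = sub[:, sub.sum(axis=0) > 0]
        c2, pr, d, _ = stats.chi2_contingency(sub, correction=(sub.shape == (2, 2)))
        rows.append({"group1": g1, "group2": g2, "chi2": c2, "df": d, "p_raw": pr})
    ph = pd.DataFrame(rows)
    if len(ph):
        ph["p_adj"] = multipletests(ph["p_raw"], method=adjust)[1]
    return ContingencyResult(observed=obs, chi2=float(chi2), df=int(dof),
                             p=float(p), posthoc=ph)


def crosstab_leaf_by_region(traits: pd.DataFrame) -> pd.DataFrame:
    """Region-by-leaf-type species counts.

    The ``region`` column may list several regions separated by ``;``;
    such species are counted once in every listed region.
    """
    rows = []
    for _, r in traits.iterrows():
        for region in str(r["region"]).split(";"):
            region = region.strip()
            if region:
                rows.append({"region": region, "leaf_type": int(r["leaf_type"])})
    if not rows:
        return pd.DataFrame()
    long = pd.DataFrame(rows)
    return pd.crosstab(long["region"], long["leaf_type"])


# ----------------------------------------------------------------------
# logistic regressions


@dataclass
class RegressionResult:
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    converged: bool
    n_iter: int = 0
    method: str = "ml"


def _design(X) -> tuple[np.ndarray, list[str]]:
    X = pd.DataFrame(X)
    names = ["(Intercept)"] + list(X.columns.astype(str))
    M = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return M, names


def glm_logistic(y, X) -> RegressionResult:
    """Maximum-likelihood logistic regression (IRLS) with Wald tests.

    Separation / non-convergence is flagged rather than raised; the
    estimates are then reported but unreliable.
    """
    import statsmodels.api as sm

    M, names = _design(X)
    y = np.asarray(y, dtype=float)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, M).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
            params, bse = res.params, res.bse
        except Exception:
            converged = False
            res = sm.Logit(y, M).fit(disp=0, maxiter=100, method="bfgs", gtol=1e-4)
            params, bse = res.params, res.bse
    if np.any(np.abs(params) > 15.0) or not np.all(np.isfinite(bse)):
        converged = False
    z = params / bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionResult(
        coef=pd.Series(params, index=names),
        se=pd.Series(bse, index=names),
        z=pd.Series(z, index=names),
        p=pd.Series(p, index=names),
        converged=converged,
        method="ml",
    )


def firth_logistic(y, X, max_iter: int = 100, tol: float = 1e-8) -> RegressionResult:
    """Firth's bias-reduced (Jeffreys-prior penalized) logistic regression.

    Newton iterations on the modified score U*(b) = X'(y - mu + h(1/2 - mu))
    with h the hat-matrix diagonal; estimates are finite even under
    complete separation.
    """
    M, names = _design(X)
    y = np.asarray(y, dtype=float)
    n, q = M.shape
    if np.linalg.matrix_rank(M) < q:
        raise ValueError("design matrix is singular")
    beta = np.zeros(q)

    def penalized_loglik(b):
        eta = M @ b
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), 1e-12, None)
        F = M.T @ (M * W[:, None])
        sign, logdet = np.linalg.slogdet(F)
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        return ll + 0.5 * logdet

    ll_old = penalized_loglik(beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = M @ beta
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), 1e-12, None)
        F = M.T @ (M * W[:, None])
        Finv = np.linalg.inv(F)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", M * W[:, None], Finv, M)
        U = M.T @ (y - mu + h * (0.5 - mu))
        step = Finv @ U
        # step-halving on the penalized likelihood
        lam = 1.0
        for _ in range(20):
            ll_new = penalized_loglik(beta + lam * step)
            if ll_new >= ll_old - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll_old = penalized_loglik(beta)
        if np.max(np.abs(lam * step)) < tol:
            break
    mu = expit(M @ beta)
    W = np.clip(mu * (1 - mu), 1e-12, None)
    Finv = np.linalg.inv(M.T @ (M * W[:, None]))
    se = np.sqrt(np.diag(Finv))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionResult(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(z, index=names),
        p=pd.Series(p, index=names),
        converged=it < max_iter,
        n_iter=it,
        method="firth",
    )


# ----------------------------------------------------------------------
# recursive partitioning


@dataclass
class PartitionNode:
    n: int
    counts: tuple[int, int]  # (class 0, class 1)
    variable: str | None = None
    threshold: float | None = None
    left: "PartitionNode | None" = None
    right: "PartitionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def describe(self, indent: int = 0) -> str:
        frac1 = self.counts[1] / max(self.n, 1)
        lab = f"n={self.n} p(class1)={frac1:.2f}"
        if self.is_leaf:
            return " " * indent + f"leaf {lab}"
        out = " " * indent + f"{self.variable} < {self.threshold:.4g} {lab}"
        return "\n".join(
            [out, self.left.describe(indent + 2), self.right.describe(indent + 2)]
        )


def cart_partition(
    y, X: pd.DataFrame, min_node: int = 25, cp: float = 0.01
) -> PartitionNode:
    """Greedy Gini partition tree over the climate predictors.

    Splits must leave at least ``min_node`` observations in each child and
    achieve a relative impurity decrease of at least ``cp`` of the root
    impurity (rpart-style complexity gate); thresholds sit at the midpoint
    of the bounding data gap.  Fewer than ``2 * min_node`` observations
    give a single-leaf tree.
    """
    y = np.asarray(y, dtype=int)
    X = pd.DataFrame(X)
    p1 = y.mean() if len(y) else 0.0
    root_gini = 2.0 * p1 * (1.0 - p1)

    def node_of(counts0, counts1):
        return PartitionNode(n=int(counts0 + counts1), counts=(int(counts0), int(counts1)))

    if len(y) < 2 * min_node or root_gini == 0.0:
        return node_of((y == 0).sum(), (y == 1).sum())

    clf = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_node,
        min_impurity_decrease=cp * root_gini,
        random_state=0,
    )
    clf.fit(X.to_numpy(dtype=float), y)
    t = clf.tree_
    cols = list(X.columns.astype(str))

    def build(i: int) -> PartitionNode:
        # recent sklearn stores per-class fractions in tree_.value
        raw = t.value[i][0]
        if not np.isclose(raw.sum(), t.n_node_samples[i]):
            raw = raw * t.n_node_samples[i] / raw.sum()
        c = np.zeros(2)
        for cls, cnt in zip(clf.classes_, raw):
            c[int(cls)] = cnt
        node = PartitionNode(n=int(t.n_node_samples[i]),
                             counts=(int(round(c[0])), int(round(c[1]))))
        if t.children_left[i] != -1:
            node.variable = cols[t.feature[i]]
            node.threshold = float(t.threshold[i])
            node.left = build(t.children_left[i])
            node.right = build(t.children_right[i])
        return node

    return build(0)


# ----------------------------------------------------------------------
# random forest with OOB permutation importance


def random_forest_importance(
    y, X: pd.DataFrame, n_trees: int = 500, seed: int = 0
) -> pd.Series:
    """Bagged Gini trees with out-of-bag permutation importance.

    Each tree is fit on a bootstrap sample with sqrt(p) candidate
    predictors per split; importance of a variable is the mean OOB
    accuracy drop when that variable is permuted.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)
    Xm = pd.DataFrame(X).to_numpy(dtype=float)
    n, p = Xm.shape
    imp = np.zeros(p)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        base = float((tree.predict(Xm[oob]) == y[oob]).mean())
        for j in range(p):
            Xp = Xm[oob].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            imp[j] += base - float((tree.predict(Xp) == y[oob]).mean())
        used += 1
    imp /= max(used, 1)
    return pd.Series(imp, index=pd.DataFrame(X).columns.astype(str),
                     name="oob_permutation_importance")


# ----------------------------------------------------------------------
# ploidy


def classify_ploidy(two_n: int, base_x: int = 8) -> str:
    """Classify a somatic chromosome count against a base number.

    2n = 2x is diploid, 2n = 4x tetraploid, anything larger than 2x that
    is neither is ``polyploid_other`` (odd counts get a warning, since
    they fall outside the base-number frame); counts below 2x are errors.
    """
    two_n = int(two_n)
    if two_n <= 0:
        raise ValueError("chromosome count must be positive")
    if two_n < 2 * base_x:
        raise ValueError(f"2n={two_n} below the diploid count 2x={2 * base_x}")
    if two_n % 2 == 1:
        warnings.warn(f"odd chromosome count 2n={two_n}", stacklevel=2)
        return "polyploid_other"
    if two_n == 2 * base_x:
        return "diploid"
    if two_n == 4 * base_x:
        return "tetraploid"
    return "polyploid_other"
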