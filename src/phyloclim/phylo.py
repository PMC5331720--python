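"""Phylogenetically-informed comparative methods.

Implements the Mk likelihood (Felsenstein pruning) with ER/SYM/ARD rate
structures and AIC model choice, marginal ancestral-state reconstruction,
MAP-state transition counting, the Fritz-Purvis D statistic for binary
traits (tip-shuffle and Brownian-threshold nulls), a phylogenetic binary
regression estimated by penalized quasi-likelihood, and the transition-
recoding sensitivity experiment that asks how many extra trait
transitions would be needed before a trait-climate correlation becomes
significant under the phylogenetic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit

from .trees import TreeArrays, as_arrays

RATE_LO, RATE_HI = 1e-8, 1e3

MODELS = ("ER", "SYM", "ARD")


def n_free_rates(model: str, k: int) -> int:
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model {model!r}")


def build_q(model: str, k: int, rates) -> np.ndarray:
    """Assemble a rate matrix from the model's free rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (n_free_rates(model, k),):
        raise ValueError("wrong number of free rates")
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    elif model == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    else:  # ARD, row-major over off-diagonals
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _validate_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("negative off-diagonal rate")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-6):
        raise ValueError("rate-matrix rows must sum to zero")
    return Q


def _edge_pmats(Q: np.ndarray, blens: np.ndarray) -> np.ndarray:
    """Transition matrices exp(Q t) for every edge, (n_edges, k, k).

    Eigendecomposition when well-conditioned, scaling-and-squaring
    (scipy expm) fallback otherwise.
    """
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.outer(blens, w))  # (n, k)
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
        P = np.real(P)
        if not np.all(np.isfinite(P)) or P.min() < -1e-7:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([linalg.expm(Q * t) for t in blens])
    return np.clip(P, 0.0, None)


def _tip_state_array(ta: TreeArrays, tip_states: dict, k: int) -> np.ndarray:
    s = np.empty(ta.n_tips, dtype=np.int64)
    for i, lab in enumerate(ta.tip_labels):
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no state")
        v = int(tip_states[lab])
        if not (0 <= v < k):
            raise ValueError(f"state {v} out of range for k={k}")
        s[i] = v
    return s


def _downpass(ta: TreeArrays, states: np.ndarray, P: np.ndarray, k: int):
    """Scaled conditional likelihoods; returns (L, total log scale)."""
    L = np.zeros((ta.n_nodes, k))
    L[np.arange(ta.n_tips), states] = 1.0
    logscale = 0.0
    for u in range(ta.n_tips, ta.n_nodes):
        prod = np.ones(k)
        for v in ta.children[u]:
            prod = prod * (P[v] @ L[v])
        s = prod.max()
        if s <= 0:
            return L, -np.inf
        L[u] = prod / s
        logscale += np.log(s)
    return L, logscale


def mk_loglik(tree, tip_states: dict, Q, root_prior=None) -> float:
    """Felsenstein pruning log-likelihood of discrete tip states under Q.

    The root is combined with a flat prior 1/k unless ``root_prior`` is
    given.  Branch lengths must be non-negative and every tip must carry
    a state index in ``0..k-1``.
    """
    ta = as_arrays(tree)
    Q = _validate_q(Q)
    k = Q.shape[0]
    states = _tip_state_array(ta, tip_states, k)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    P = _edge_pmats(Q, ta.edge_length)
    L, logscale = _downpass(ta, states, P, k)
    if not np.isfinite(logscale):
        return -np.inf
    lik = float(prior @ L[ta.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


# ----------------------------------------------------------------------
# fitting


@dataclass
class MkFit:
    model: str
    k: int
    states: list  # original state labels, index-aligned with Q
    rates: np.ndarray  # free rates
    Q: np.ndarray
    lnl: float
    aic: float
    converged: bool
    boundary: bool  # rates pinned at the optimizer bounds (e.g. constant data)
    data_key: tuple = field(repr=False, default=())

    @property
    def n_free(self) -> int:
        return n_free_rates(self.model, self.k)


def _encode_states(tip_states: dict):
    labels = sorted(set(tip_states.values()))
    index = {s: i for i, s in enumerate(labels)}
    return labels, {tip: index[s] for tip, s in tip_states.items()}


def fit_mk(
    tree,
    tip_states: dict,
    model: str = "SYM",
    n_starts: int = 5,
    seed: int = 0,
    k: int | None = None,
) -> MkFit:
    """Maximum-likelihood Mk fit with a bounded optimizer and multistarts.

    States may be arbitrary sortable labels; they are indexed in sorted
    order.  AIC = -2 lnL + 2 * (number of free rates).  Constant tip data
    drive the rates to the lower bound and set the ``boundary`` flag.
    """
    ta = as_arrays(tree)
    labels, enc = _encode_states(tip_states)
    kk = k if k is not None else len(labels)
    if kk < 2:
        kk = 2  # constant data still fit on a 2-state space
    nf = n_free_rates(model, kk)
    states = _tip_state_array(ta, enc, kk)
    tree_len = float(ta.edge_length[: ta.n_nodes - 1].sum())
    base_rate = max(len(labels), 2) / max(tree_len, 1e-6)
    rng = np.random.default_rng(seed)

    def nll(log_rates):
        Q = build_q(model, kk, np.exp(log_rates))
        P = _edge_pmats(Q, ta.edge_length)
        L, logscale = _downpass(ta, states, P, kk)
        if not np.isfinite(logscale):
            return 1e12
        lik = float(np.full(kk, 1.0 / kk) @ L[ta.root])
        if lik <= 0:
            return 1e12
        return -(np.log(lik) + logscale)

    lo, hi = np.log(RATE_LO), np.log(RATE_HI)
    best = None
    starts = [np.full(nf, np.log(base_rate))]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.log(base_rate) + rng.normal(0.0, 1.5, nf))
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * nf,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    rates = np.exp(best.x)
    boundary = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    if boundary and len(labels) < 2:
        warnings.warn("constant tip states: rates at boundary", stacklevel=2)
    lnl = -float(best.fun)
    return MkFit(
        model=model,
        k=kk,
        states=labels,
        rates=rates,
        Q=build_q(model, kk, rates),
        lnl=lnl,
        aic=-2.0 * lnl + 2.0 * nf,
        converged=converged,
        boundary=boundary,
        data_key=tuple(sorted((str(t), s) for t, s in tip_states.items())),
    )


def select_model_aic(fits) -> MkFit:
    """Minimum-AIC fit; ties go to the model with fewer free rates."""
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    key0 = fits[0].data_key
    if any(f.data_key != key0 for f in fits):
        raise ValueError("fits were made on different data")
    return min(fits, key=lambda f: (f.aic, f.n_free))


# ----------------------------------------------------------------------
# ancestral states


@dataclass
class AsrResult:
    probs: np.ndarray  # (n_nodes, k); tips are one-hot
    map_states: np.ndarray  # (n_nodes,) state indices
    states: list  # state labels
    n_tips: int


def marginal_asr(tree, fit_or_q, tip_states: dict | None = None,
                 states: list | None = None) -> AsrResult:
    """Marginal (empirical-Bayes) ancestral state probabilities.

    Standard two-pass computation at the fixed rate matrix: conditional
    likelihoods up the tree, complement ("rest-of-tree") likelihoods down
    from the root with a flat prior, marginals proportional to their
    product at every node.  Pass either an :class:`MkFit` (tip states
    taken from the fitting call must be re-supplied) or a raw Q.
    """
    ta = as_arrays(tree)
    if isinstance(fit_or_q, MkFit):
        Q = fit_or_q.Q
        labels = fit_or_q.states
        if tip_states is None:
            raise ValueError("tip_states must be supplied alongside a fit")
        _, enc = _encode_states(tip_states)
        k = fit_or_q.k
    else:
        Q = _validate_q(fit_or_q)
        k = Q.shape[0]
        if tip_states is None:
            raise ValueError("tip_states required")
        enc = {t: int(s) for t, s in tip_states.items()}
        labels = states if states is not None else list(range(k))
    st = _tip_state_array(ta, enc, k)
    P = _edge_pmats(Q, ta.edge_length)
    L, logscale = _downpass(ta, st, P, k)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under Q")

    # child-partials seen from each parent: D[v] = P[v] @ L[v]
    D = np.zeros((ta.n_nodes, k))
    for v in range(ta.n_nodes - 1):
        D[v] = P[v] @ L[v]

    G = np.zeros((ta.n_nodes, k))
    G[ta.root] = 1.0 / k
    for u in range(ta.n_nodes - 1, ta.n_tips - 1, -1):
        kids = ta.children[u]
        for v in kids:
            sib = G[u].copy()
            for w in kids:
                if w != v:
                    sib = sib * D[w]
            G[v] = P[v].T @ sib
            s = G[v].max()
            if s > 0:
                G[v] /= s

    probs = G * L
    norm = probs.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    probs = probs / norm
    map_states = probs.argmax(axis=1)
    map_states[: ta.n_tips] = st
    return AsrResult(probs=probs, map_states=map_states, states=list(labels),
                     n_tips=ta.n_tips)


def count_transitions(tree, asr: AsrResult, tip_states: dict | None = None) -> dict:
    """Ordered (from, to) transition counts over edges from MAP states.

    Tip states override the reconstruction at the tips when supplied.
    Keys are state labels as carried by the reconstruction.
    """
    ta = as_arrays(tree)
    st = asr.map_states.copy()
    if tip_states is not None:
        index = {lab: i for i, lab in enumerate(asr.states)}
        for i, lab in enumerate(ta.tip_labels):
            st[i] = index[tip_states[lab]]
    counts: dict = {}
    for v in range(ta.n_nodes - 1):
        a, b = st[ta.parent[v]], st[v]
        if a != b:
            key = (asr.states[a], asr.states[b])
            counts[key] = counts.get(key, 0) + 1
    return counts


# ----------------------------------------------------------------------
# Fritz-Purvis D


@dataclass
class DStatResult:
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    n_sim: int


def _d_metric(ta: TreeArrays, tip_matrix: np.ndarray) -> np.ndarray:
    """Sum of |nodal value changes| per trait column.

    Nodal values are unweighted means of child values (tips carry the
    0/1 data); the statistic sums absolute parent-child differences over
    all edges.  ``tip_matrix`` is (n_tips, m); returns (m,).
    """
    m = tip_matrix.shape[1]
    V = np.zeros((ta.n_nodes, m))
    V[: ta.n_tips] = tip_matrix
    for u in range(ta.n_tips, ta.n_nodes):
        kids = ta.children[u]
        V[u] = sum(V[v] for v in kids) / len(kids)
    d = np.zeros(m)
    for v in range(ta.n_nodes - 1):
        d += np.abs(V[ta.parent[v]] - V[v])
    return d


def phylo_d(tree, binary_trait: dict, n_perm: int = 1000, n_sim: int = 1000,
            seed: int = 0) -> DStatResult:
    """Fritz-Purvis D for a binary trait.

    D scales the observed sum of nodal changes between two null
    distributions: tip-shuffle (phylogenetic randomness, D = 1) and
    Brownian-threshold simulations at matched prevalence (D = 0).
    Negative D indicates stronger-than-Brownian conservation.
    ``p_random``/``p_brownian`` are the fractions of null statistics at
    or below the observed value.
    """
    ta = as_arrays(tree)
    y = np.array([binary_trait[lab] for lab in ta.tip_labels], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("trait is constant: signal undefined")
    if ta.n_tips < 10:
        warnings.warn("fewer than 10 tips: D is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    n1 = int(y.sum())

    d_obs = float(_d_metric(ta, y[:, None])[0])

    perm = np.empty((ta.n_tips, n_perm))
    for c in range(n_perm):
        perm[:, c] = rng.permutation(y)
    d_perm = _d_metric(ta, perm)

    # Brownian liabilities, thresholded at the empirical-prevalence rank
    X = np.zeros((ta.n_nodes, n_sim))
    for v in range(ta.n_nodes - 2, -1, -1):
        X[v] = X[ta.parent[v]] + np.sqrt(ta.edge_length[v]) * rng.standard_normal(n_sim)
    tips = X[: ta.n_tips]
    thr = np.partition(tips, ta.n_tips - n1, axis=0)[ta.n_tips - n1]
    sim = (tips >= thr[None, :]).astype(float)
    d_sim = _d_metric(ta, sim)

    mean_r = float(d_perm.mean())
    mean_b = float(d_sim.mean())
    denom = mean_r - mean_b
    D = float((d_obs - mean_b) / denom) if denom != 0 else np.nan
    return DStatResult(
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=D,
        p_random=float((d_perm <= d_obs).mean()),
        p_brownian=float((d_sim <= d_obs).mean()),
        n_perm=n_perm,
        n_sim=n_sim,
    )


# ----------------------------------------------------------------------
# phylogenetic binary regression (PQL)


@dataclass
class PglmmResult:
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    s2: float
    converged: bool
    n_iter: int


def binary_pglmm(
    tree_or_C,
    y,
    X,
    s2_fixed: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> PglmmResult:
    """Phylogenetic logistic regression by penalized quasi-likelihood.

    Model: logit P(y=1) = X b + u, u ~ Normal(0, s2 * C) with C the
    tree's shared-branch-length matrix scaled to unit mean diagonal.  The
    phylogenetic variance s2 is profiled on a REML-type criterion at each
    PQL iteration; Wald tests for the fixed effects.  An intercept column
    is prepended automatically.
    """
    if isinstance(tree_or_C, np.ndarray):
        C = np.asarray(tree_or_C, dtype=float)
    else:
        C = as_arrays(tree_or_C).vcv()
    C = C / C.diagonal().mean()
    y = np.asarray(y, dtype=float)
    Xdf = pd.DataFrame(X)
    names = ["(Intercept)"] + list(Xdf.columns.astype(str))
    M = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy(dtype=float)])
    n, q = M.shape
    if C.shape != (n, n):
        raise ValueError("covariance matrix does not match data")

    beta = np.zeros(q)
    b = np.zeros(n)
    s2 = 0.1 if s2_fixed is None else float(s2_fixed)

    def solve_given(s2v, W, Z):
        V = s2v * C + np.diag(1.0 / W)
        cho = linalg.cho_factor(V, lower=True)
        Vi_X = linalg.cho_solve(cho, M)
        Vi_Z = linalg.cho_solve(cho, Z)
        XtViX = M.T @ Vi_X
        bhat = np.linalg.solve(XtViX, M.T @ Vi_Z)
        resid = Z - M @ bhat
        Vi_r = linalg.cho_solve(cho, resid)
        crit = (
            2.0 * np.sum(np.log(np.diag(cho[0])))
            + float(np.linalg.slogdet(XtViX)[1])
            + float(resid @ Vi_r)
        )
        return bhat, Vi_r, XtViX, crit

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = M @ beta + b
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        Z = eta + (y - mu) / W
        if s2_fixed is None:
            res = optimize.minimize_scalar(
                lambda ls: solve_given(np.exp(ls), W, Z)[3],
                bounds=(np.log(1e-8), np.log(50.0)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            s2_new = float(np.exp(res.x))
            if s2_new < 1e-6:
                s2_new = 0.0
        else:
            s2_new = float(s2_fixed)
        beta_new, Vi_r, XtViX, _ = solve_given(max(s2_new, 0.0), W, Z)
        b_new = max(s2_new, 0.0) * (C @ Vi_r)
        delta = max(
            float(np.max(np.abs(beta_new - beta))),
            abs(s2_new - s2),
            float(np.max(np.abs(b_new - b))) if n else 0.0,
        )
        beta, b, s2 = beta_new, b_new, s2_new
        if delta < tol:
            converged = True
            break
    cov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return PglmmResult(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(z, index=names),
        p=pd.Series(p, index=names),
        s2=float(s2),
        converged=converged,
        n_iter=it,
    )


# ----------------------------------------------------------------------
# recoding sensitivity experiment


@dataclass
class RecodingResult:
    baseline_transitions: int
    baseline_p: float
    baseline_significant: bool
    achieved: bool
    transitions_needed: int | None
    n_recoded: int | None
    trajectory: list  # dicts: n_recoded, transitions, p

    @property
    def not_achievable(self) -> bool:
        return not self.achieved and not self.baseline_significant


def recoding_experiment(
    tree,
    leaf_binary: dict,
    species_map: dict,
    map_threshold: float = 1250.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> RecodingResult:
    """How many compound->simple transitions make the MAP effect significant?

    Compound-leaved species (state 1) occurring above ``map_threshold``
    mm of mean annual precipitation are recoded to simple one at a time
    in descending-MAP order.  After each recoding a binary Mk model is
    refit (SYM, which equals ER for two states), compound->simple
    transitions are counted on the MAP reconstruction, and a phylogenetic
    binary regression of the leaf state on standardized MAP is run; the
    experiment reports the smallest transition count at which the MAP
    coefficient's Wald p falls below ``alpha``.
    """
    ta = as_arrays(tree)
    missing = [t for t in ta.tip_labels if t not in leaf_binary or t not in species_map]
    if missing:
        raise ValueError(f"species without trait or MAP values: {missing[:5]}")
    state = {t: int(leaf_binary[t]) for t in ta.tip_labels}
    mapv = np.array([species_map[t] for t in ta.tip_labels], dtype=float)
    zmap = (mapv - mapv.mean()) / mapv.std(ddof=1)
    Xz = pd.DataFrame({"MAP": zmap})

    def evaluate(st: dict):
        fit = fit_mk(ta, st, model="SYM", seed=seed)
        asr = marginal_asr(ta, fit, tip_states=st)
        trans = count_transitions(ta, asr, tip_states=st)
        n10 = int(trans.get((1, 0), 0))
        yv = np.array([st[t] for t in ta.tip_labels], dtype=float)
        pg = binary_pglmm(ta, yv, Xz)
        return n10, float(pg.p["MAP"])

    base_t, base_p = evaluate(state)
    trajectory = [{"n_recoded": 0, "transitions": base_t, "p": base_p}]
    if base_p < alpha:
        return RecodingResult(
            baseline_transitions=base_t,
            baseline_p=base_p,
            baseline_significant=True,
            achieved=True,
            transitions_needed=base_t,
            n_recoded=0,
            trajectory=trajectory,
        )

    candidates = [
        t for t in ta.tip_labels if state[t] == 1 and species_map[t] > map_threshold
    ]
    candidates.sort(key=lambda t: -species_map[t])
    for i, sp in enumerate(candidates, start=1):
        state[sp] = 0
        n10, p = evaluate(state)
        trajectory.append({"n_recoded": i, "transitions": n10, "p": p})
        if p < alpha:
            return RecodingResult(
                baseline_transitions=base_t,
                baseline_p=base_p,
                baseline_significant=False,
                achieved=True,
                transitions_needed=n10,
                n_recoded=i,
                trajectory=trajectory,
            )
    return RecodingResult(
        baseline_transitions=base_t,
        baseline_p=base_p,
        baseline_significant=False,
        achieved=False,
        transitions_needed=None,
        n_recoded=None,
        trajectory=trajectory,
    )
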