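"""Single-threshold GMYC species delimitation on ultrametric trees.

The generalised mixed Yule coalescent (GMYC) model assumes that on an
ultrametric (clock-like) tree of sequences, branching events older than some
time threshold T reflect between-species diversification (a Yule-type pure
birth process) while events younger than T reflect within-species coalescence.
Cutting the tree at the maximum-likelihood T partitions the tips into
putative species: clusters of two or more tips plus singletons.

Model.  Scanning the tree from the tips towards the root, let the branching
events have heights 0 < h_1 <= ... <= h_{n-1} (the root), and let interval i
be the waiting time x_i = h_i - h_{i-1} before event i.  Events with h > T
are diversification events; events with h <= T are coalescences inside the
clusters obtained by cutting all branches at height T.  The instantaneous
branching rate during interval i is

    r_i = lambda_div * k_i**p_div
        + lambda_coal * sum_j (m_ij * (m_ij - 1))**p_coal

where k_i is the number of between-species lineages present in interval i
(all current lineages above T; the constant number of branches crossing T
below it) and m_ij is the number of lineages of within-species cluster j in
interval i.  The power-law exponents p_div and p_coal generalise the linear
Yule (p = 1 on k) and Kingman coalescent (p = 1 on m(m-1)) rate laws.  Each
process is an independent competing exponential clock, so

    logL = sum_i [ log r_event(i) - r_i * x_i ]

with r_event(i) the rate of the process class (diversification, or the
coalescent summed over clusters) that produced event i.  The null model is a
single branching process r_i = lambda * (N_i (N_i - 1))**p over the whole
tree; the GMYC fit can never fall below it because placing T at the root
reproduces the null exactly.

The likelihood separates into a diversification part in (lambda_div, p_div)
and a coalescent part in (lambda_coal, p_coal), and each rate has a
closed-form conditional maximum (events / exposure), so fitting reduces to
two bounded one-dimensional searches over the exponents per candidate
threshold.  Candidate thresholds are midpoints between consecutive distinct
branching times, plus one just below the shallowest event (every tip its own
species) and one at the root (a single species).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "UltrametricTree",
    "GMYCParams",
    "GMYCFit",
    "UltrametricityError",
    "parse_newick",
    "validate_ultrametric",
    "branching_times",
    "delimit",
    "gmyc_loglik",
    "fit_null",
    "fit_at_threshold",
    "fit_single_threshold",
]


class UltrametricityError(ValueError):
    """Tree violates the ultrametric (equal root-to-tip path) assumption."""


@dataclass(frozen=True)
class GMYCParams:
    """Rates and rate exponents of the two branching processes."""

    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float

    def __post_init__(self) -> None:
        if self.lambda_div <= 0 or self.lambda_coal <= 0:
            raise ValueError("rate scales must be positive")
        if not (math.isfinite(self.p_div) and math.isfinite(self.p_coal)):
            raise ValueError("rate exponents must be finite")


@dataclass
class GMYCFit:
    """Fitted threshold, likelihoods, LR test, and the tip partition."""

    threshold_time: float
    logL_gmyc: float
    logL_null: float
    LR: float
    p_value: float
    entities: tuple[tuple[str, ...], ...]
    n_species: int
    params: GMYCParams
    null_params: tuple[float, float]  # (lambda, p)
    profile: list[tuple[float, float]] = field(default_factory=list)

    @property
    def clusters(self) -> tuple[tuple[str, ...], ...]:
        return tuple(e for e in self.entities if len(e) >= 2)

    @property
    def singletons(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entities if len(e) == 1)


class UltrametricTree:
    """A rooted ultrametric tree indexed for GMYC computations.

    Node heights are times before present: tips at 0, internal nodes at
    their branching time, the root highest.  Internal nodes carry event
    indices 1..n-1 in ascending height order.
    """

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-6, strict: bool = True):
        violations = validate_ultrametric(tree, tol)
        if strict and violations:
            worst = max(violations, key=lambda v: v[1])
            raise UltrametricityError(
                f"{len(violations)} tip(s) violate ultrametricity "
                f"(worst: {worst[0]!r}, deviation {worst[1]:.3g})"
            )
        depths = tree.calc_node_root_distances(return_leaf_distances_only=False)
        max_depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())

        leaves = list(tree.leaf_node_iter())
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        internals.sort(key=lambda nd: max_depth - nd.root_distance)  # ascending height

        self.n_tips = len(leaves)
        self.tip_labels: list[str] = [lf.taxon.label if lf.taxon else "?" for lf in leaves]
        ids = {nd: i for i, nd in enumerate(leaves)}
        ids.update({nd: self.n_tips + i for i, nd in enumerate(internals)})

        total = self.n_tips + len(internals)
        self.parent = np.full(total, -1, dtype=np.int64)
        self.height = np.zeros(total, dtype=float)
        self.event_index = np.zeros(total, dtype=np.int64)  # 0 for tips
        for nd, i in ids.items():
            if nd.parent_node is not None:
                self.parent[i] = ids[nd.parent_node]
            if not nd.is_leaf():
                self.height[i] = max(max_depth - nd.root_distance, 0.0)
        for rank, nd in enumerate(internals, start=1):
            self.event_index[ids[nd]] = rank

        # heights of events 1..n-1, ascending
        self.event_heights = np.sort(self.height[self.n_tips :])
        self._dendropy = tree

    @property
    def root_height(self) -> float:
        return float(self.event_heights[-1]) if len(self.event_heights) else 0.0

    def branching_times(self) -> list[float]:
        """Internal-node heights, descending; first entry is the root."""
        return [float(h) for h in self.event_heights[::-1]]

    def _cluster_roots(self, n_below: int) -> np.ndarray:
        """Per-node id of its cluster root when the ``n_below`` shallowest
        events lie below the threshold; -1 for nodes above the threshold."""
        total = len(self.parent)
        root = np.full(total, -1, dtype=np.int64)

        def below(i: int) -> bool:
            return i < self.n_tips or self.event_index[i] <= n_below

        for i in range(total):
            if not below(i):
                continue
            # walk up while the parent is still below the threshold
            chain = [i]
            cur = i
            while True:
                par = self.parent[cur]
                if par == -1 or not below(par):
                    break
                if root[par] != -1:
                    cur = root[par]
                    break
                chain.append(par)
                cur = par
            for node in chain:
                root[node] = cur
        return root


def parse_newick(text: str, tol: float = 1e-6) -> UltrametricTree:
    """Parse a Newick string with branch lengths into an ultrametric tree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"unparseable Newick: {exc}") from exc
    return UltrametricTree(tree, tol=tol)


def validate_ultrametric(
    tree: dendropy.Tree, tol: float = 1e-6
) -> list[tuple[str, float]]:
    """Relative root-to-tip deviations beyond ``tol``; empty means OK."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    dists = [(lf.taxon.label if lf.taxon else "?", lf.root_distance)
             for lf in tree.leaf_node_iter()]
    dmax = max(d for _, d in dists)
    if dmax <= 0:
        return [(label, 0.0) for label, _ in dists][:0]
    return [
        (label, (dmax - d) / dmax)
        for label, d in dists
        if (dmax - d) / dmax > tol
    ]


def branching_times(tree: UltrametricTree) -> list[float]:
    return tree.branching_times()


def delimit(tree: UltrametricTree, T: float) -> tuple[tuple[str, ...], ...]:
    """Cut all branches crossing height T; each resulting subtree's tips form
    one entity.  Entities are sorted by their lexicographically smallest tip."""
    if T < 0:
        raise ValueError("threshold must be non-negative")
    n_below = int(np.count_nonzero(tree.event_heights <= T))
    roots = tree._cluster_roots(n_below)
    groups: dict[int, list[str]] = {}
    for tip in range(tree.n_tips):
        groups.setdefault(int(roots[tip]), []).append(tree.tip_labels[tip])
    entities = [tuple(sorted(tips)) for tips in groups.values()]
    entities.sort(key=lambda e: e[0])
    return tuple(entities)


# ---------------------------------------------------------------------------
# Sufficient statistics and profile likelihood
# ---------------------------------------------------------------------------


@dataclass
class _ProcessStats:
    """One branching-process class: event rate factors and exposures.

    The class rate in the interval preceding event i is
    lambda * S_i(p) with S_i(p) = sum_j v_ij**p over the class's rate
    factors (one per cluster for the coalescent class; the single lineage
    count for the diversification class).  Events of the class contribute
    log(lambda * S_i(p)); exposure segments contribute -lambda * v**p * x.
    At the conditional rate MLE lambda = E / exposure(p), the profile
    log-likelihood is E*log(E/B) - E + sum_i log S_i(p).
    """

    ev_flat: np.ndarray     # concatenated per-event rate factors
    ev_offsets: np.ndarray  # start offset of each event's factors in ev_flat
    v_exp: np.ndarray       # rate factor of each exposure segment
    x_exp: np.ndarray       # duration of each exposure segment

    @property
    def n_events(self) -> int:
        return len(self.ev_offsets)

    def exposure(self, p: float) -> float:
        if len(self.v_exp) == 0:
            return 0.0
        return float(np.sum(self.v_exp**p * self.x_exp))

    def _event_logsum(self, p: float) -> float:
        if self.n_events == 0:
            return 0.0
        S = np.add.reduceat(self.ev_flat**p, self.ev_offsets)
        return float(np.sum(np.log(S)))

    def loglik(self, lam: float, p: float) -> float:
        return (
            self.n_events * math.log(lam)
            + self._event_logsum(p)
            - lam * self.exposure(p)
        )

    def profile(self, p: float) -> tuple[float, float]:
        """(lambda_hat, logL) at the conditional rate maximum for given p."""
        A = self.exposure(p)
        if self.n_events == 0:
            # no events of this class: sup over lambda -> 0 contributes 0
            return (1.0, 0.0) if A == 0 else (np.finfo(float).tiny, 0.0)
        if A <= 0:
            raise ValueError("zero exposure with observed events")
        lam = self.n_events / A
        return lam, self.n_events * math.log(lam) + self._event_logsum(p) - self.n_events

    def fit(self, p_bounds: tuple[float, float] = (0.0, 2.0), grid: int = 41,
            fix_p: float | None = None) -> tuple[float, float, float]:
        """Maximise over (lambda, p); returns (lambda_hat, p_hat, logL)."""
        if fix_p is not None:
            lam, ll = self.profile(fix_p)
            return lam, fix_p, ll
        if self.n_events == 0:
            lam, ll = self.profile(1.0)
            return lam, 1.0, ll
        ps = np.linspace(p_bounds[0], p_bounds[1], grid)
        lls = [self.profile(p)[1] for p in ps]
        best = int(np.argmax(lls))
        lo = ps[max(best - 1, 0)]
        hi = ps[min(best + 1, grid - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda p: -self.profile(p)[1], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            p_hat = float(res.x) if -res.fun >= lls[best] else float(ps[best])
        else:
            p_hat = float(ps[best])
        lam, ll = self.profile(p_hat)
        return lam, p_hat, ll


def _threshold_stats(tree: UltrametricTree, n_below: int) -> tuple[_ProcessStats, _ProcessStats]:
    """Diversification and coalescent statistics when the ``n_below``
    shallowest events lie below the threshold."""
    n = tree.n_tips
    H = tree.event_heights  # ascending, 1-based events: event i at H[i-1]
    s = n_below

    # diversification: events s+1..n-1 with N_i = n-i+1 current lineages
    div_v, div_vx, div_xx = [], [], []
    for i in range(s + 1, n):
        N = n - i + 1
        prev_h = H[i - 2] if i >= 2 else 0.0
        div_v.append(float(N))
        div_vx.append(float(N))
        div_xx.append(float(H[i - 1] - prev_h))
    # the k species lineages persist (without diversifying) below the
    # threshold; no lineage crosses the threshold when it sits at the root
    if 0 < s < n - 1:
        k = n - s
        div_vx.append(float(k))
        div_xx.append(float(H[s - 1]))

    # coalescent: events 1..s inside the clusters cut at the threshold; the
    # class rate before event i sums m(m-1) over all clusters still holding
    # multiple lineages in that interval
    ev_flat: list[float] = []
    ev_offsets: list[int] = []
    coal_vx, coal_xx = [], []
    if s > 0:
        roots = tree._cluster_roots(s)
        m_of: dict[int, int] = {}
        for tip in range(n):
            r = int(roots[tip])
            m_of[r] = m_of.get(r, 0) + 1
        event_cluster: dict[int, int] = {}
        for node in range(n, len(tree.parent)):
            e = int(tree.event_index[node])
            if e <= s:
                event_cluster[e] = int(roots[node])
        prev_h = 0.0
        for e in range(1, s + 1):
            vs = [float(m * (m - 1)) for m in m_of.values() if m >= 2]
            ev_offsets.append(len(ev_flat))
            ev_flat.extend(vs)
            x = float(H[e - 1] - prev_h)
            if x > 0:
                coal_vx.extend(vs)
                coal_xx.extend([x] * len(vs))
            prev_h = float(H[e - 1])
            m_of[event_cluster[e]] -= 1

    div = _ProcessStats(
        np.asarray(div_v), np.arange(len(div_v)),
        np.asarray(div_vx), np.asarray(div_xx),
    )
    coal = _ProcessStats(
        np.asarray(ev_flat), np.asarray(ev_offsets, dtype=np.intp),
        np.asarray(coal_vx), np.asarray(coal_xx),
    )
    return div, coal


def _n_below(tree: UltrametricTree, T: float) -> int:
    if T < 0 or T > tree.root_height * (1 + 1e-12):
        raise ValueError(f"threshold {T} outside [0, root height {tree.root_height}]")
    return int(np.count_nonzero(tree.event_heights <= T))


def gmyc_loglik(tree: UltrametricTree, T: float, params: GMYCParams) -> float:
    """Mixed Yule-coalescent log-likelihood at threshold height T."""
    div, coal = _threshold_stats(tree, _n_below(tree, T))
    ll = 0.0
    if div.n_events or len(div.v_exp):
        ll += div.loglik(params.lambda_div, params.p_div)
    if coal.n_events or len(coal.v_exp):
        ll += coal.loglik(params.lambda_coal, params.p_coal)
    return ll


def _null_stats(tree: UltrametricTree) -> _ProcessStats:
    n = tree.n_tips
    H = tree.event_heights
    v, x = [], []
    for i in range(1, n):
        N = n - i + 1
        prev_h = H[i - 2] if i >= 2 else 0.0
        v.append(float(N * (N - 1)))
        x.append(float(H[i - 1] - prev_h))
    arr_v = np.asarray(v)
    return _ProcessStats(arr_v, np.arange(len(arr_v)), arr_v, np.asarray(x))


def fit_null(tree: UltrametricTree, p_bounds: tuple[float, float] = (0.0, 2.0),
             fix_p: float | None = None) -> tuple[tuple[float, float], float]:
    """Maximum-likelihood single-process fit: r_i = lambda * (N_i(N_i-1))**p.

    Returns ((lambda_hat, p_hat), logL_null).
    """
    lam, p, ll = _null_stats(tree).fit(p_bounds, fix_p=fix_p)
    return (lam, p), ll


def fit_at_threshold(
    tree: UltrametricTree,
    T: float,
    p_bounds: tuple[float, float] = (0.0, 2.0),
    fix_p_div: float | None = None,
    fix_p_coal: float | None = None,
) -> tuple[GMYCParams, float]:
    """Maximise the GMYC likelihood over the four rate parameters at fixed T.

    The likelihood separates into the two process classes, so each is fitted
    by a bounded search over its exponent with the rate profiled out.
    """
    div, coal = _threshold_stats(tree, _n_below(tree, T))
    lam_d, p_d, ll_d = div.fit(p_bounds, fix_p=fix_p_div)
    lam_c, p_c, ll_c = coal.fit(p_bounds, fix_p=fix_p_coal)
    return GMYCParams(lam_d, p_d, lam_c, p_c), ll_d + ll_c


def _candidate_thresholds(tree: UltrametricTree) -> list[float]:
    """Midpoints between consecutive distinct branching times, plus a
    threshold just below the shallowest event and one at the root."""
    distinct = np.unique(tree.event_heights)
    cands = [float(distinct[0]) / 2.0]
    cands += [float((a + b) / 2.0) for a, b in zip(distinct[:-1], distinct[1:])]
    cands.append(float(distinct[-1]))  # root: single species, the null limit
    return cands


def fit_single_threshold(
    tree: UltrametricTree,
    df: int = 3,
    p_bounds: tuple[float, float] = (0.0, 2.0),
    keep_profile: bool = False,
) -> GMYCFit:
    """Fit the single-threshold GMYC model and delimit species.

    Evaluates every candidate threshold, keeps the maximum-likelihood one
    (ties resolved towards the larger threshold, i.e. fewer species), and
    tests it against the single-process null with a chi-square LR test on
    ``df`` degrees of freedom.
    """
    if tree.n_tips < 3:
        raise ValueError("GMYC fitting requires at least 3 tips")
    null_params, ll_null = fit_null(tree, p_bounds)

    best: tuple[float, float, GMYCParams] | None = None
    profile = []
    for T in _candidate_thresholds(tree):
        params, ll = fit_at_threshold(tree, T, p_bounds)
        profile.append((T, ll))
        if best is None or ll > best[1] + 1e-12 or (
            abs(ll - best[1]) <= 1e-12 and T > best[0]
        ):
            best = (T, ll, params)
    assert best is not None
    T_hat, ll_gmyc, params = best

    ll_gmyc = max(ll_gmyc, ll_null)  # guard tiny negative optimisation slack
    LR = 2.0 * (ll_gmyc - ll_null)
    p_value = float(chi2.sf(LR, df))
    entities = delimit(tree, T_hat)
    return GMYCFit(
        threshold_time=T_hat,
        logL_gmyc=ll_gmyc,
        logL_null=ll_null,
        LR=LR,
        p_value=p_value,
        entities=entities,
        n_species=len(entities),
        params=params,
        null_params=null_params,
        profile=profile if keep_profile else [],
    )
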