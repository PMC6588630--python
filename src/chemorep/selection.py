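"""Positive-selection analysis with GY94 codon models.

Implements the standard site-model ladder (M0, M1a/M2a, M7/M8/M8a), the
branch-site model A with its omega2 = 1 null, likelihood-ratio tests, and
naive / Bayes empirical-Bayes identification of sites in the positive
selection class.

Branch lengths are taken from the input tree up to a single free scale
factor: class rate matrices are normalized against the omega = 1 matrix at
the current kappa, so relative rates between site classes are preserved
and the overall rate is absorbed by the scale parameter (estimated under
M0 and then fixed for the other models unless re-estimation is requested).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import codon as C
from .phylogeny import ConservationProfile

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8", "M8a")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def beta_bin_omegas(p: float, q: float, K: int = 10) -> np.ndarray:
    """Means of K equal-probability bins of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    upper = special.betainc(p + 1, q, edges)
    means = (p / (p + q)) * (upper[1:] - upper[:-1]) * K
    return np.clip(means, 1e-8, 1 - 1e-8)


@dataclasses.dataclass
class CodonModelFit:
    model: str
    lnL: float
    kappa: float
    scale: float
    proportions: np.ndarray
    omegas: np.ndarray                      # background omega per class
    params: dict[str, float]
    n_params: int
    converged: bool
    foreground_omegas: np.ndarray | None = None
    # Ingredients for empirical-Bayes posteriors:
    class_site_loglik: np.ndarray | None = None   # classes x sites
    positive_class: np.ndarray | None = None      # boolean per class


@dataclasses.dataclass
class LrtResult:
    two_delta: float
    df: int
    p_value: float


def likelihood_ratio_test(lnL_alt: float, lnL_null: float, df: int,
                          tol: float = 1e-6) -> LrtResult:
    """2(lnL_alt - lnL_null) against the chi-square with ``df`` degrees of
    freedom; small negative statistics (optimizer noise) clamp to 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < 0:
        if stat < -tol * max(1.0, abs(lnL_null)):
            raise ValueError(f"alternative lnL below null by {stat / 2:.6g}; not nested?")
        stat = 0.0
    return LrtResult(stat, df, float(stats.chi2.sf(stat, df)))


class _Engine:
    """Caches per-class conditional site log-likelihood vectors keyed by
    (kappa, scale, background omega, foreground omega)."""

    def __init__(self, tree: dendropy.Tree, seqs: dict[str, str],
                 codon_freqs: np.ndarray | None = None,
                 foreground: set[int] | None = None):
        self.tree = tree
        self.taxa = list(seqs.keys())
        codes = C.encode_codon_alignment([seqs[t] for t in self.taxa])
        self.patterns, self.weights, self.site_index = C.compress_patterns(codes)
        self.n_sites = codes.shape[1]
        self.pi = (
            C.f3x4_freqs([seqs[t] for t in self.taxa])
            if codon_freqs is None else np.asarray(codon_freqs, dtype=float)
        )
        self.foreground = foreground
        self._cache: dict[tuple, np.ndarray] = {}
        self._ref_rate: dict[float, float] = {}

    def _reference_rate(self, kappa: float) -> float:
        key = round(kappa, 10)
        if key not in self._ref_rate:
            Q1 = C.gy94_rate_matrix(kappa, 1.0, self.pi, scale=False)
            self._ref_rate[key] = -float(self.pi @ np.diag(Q1))
        return self._ref_rate[key]

    def class_loglik(self, kappa: float, scale: float, omega: float,
                     fg_omega: float | None = None) -> np.ndarray:
        key = (round(kappa, 12), round(scale, 12), round(omega, 12),
               None if fg_omega is None else round(fg_omega, 12))
        if key in self._cache:
            return self._cache[key]
        ref = self._reference_rate(kappa)
        Q = C.gy94_rate_matrix(kappa, omega, self.pi, scale=False) / ref
        trans = C.CodonTransitions(Q, self.pi)
        branch_trans = None
        if fg_omega is not None and self.foreground:
            Qf = C.gy94_rate_matrix(kappa, fg_omega, self.pi, scale=False) / ref
            ft = C.CodonTransitions(Qf, self.pi)
            branch_trans = {nid: ft for nid in self.foreground}
        ll = C.pruning_loglik(self.tree, self.patterns, self.taxa, trans,
                              scale=scale, branch_trans=branch_trans)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = ll
        return ll

    def mixture_loglik(self, proportions: Sequence[float],
                       class_lls: Sequence[np.ndarray]) -> float:
        mat = np.stack(class_lls)  # classes x patterns
        logp = np.log(np.maximum(np.asarray(proportions, dtype=float), 1e-300))
        site = special.logsumexp(mat + logp[:, None], axis=0)
        return float(self.weights @ site)


def _model_structure(model: str, theta: np.ndarray, fixed_scale: float | None):
    """Decode the unconstrained parameter vector of a site model into
    (kappa, scale, proportions, omegas, named params)."""
    i = 0
    kappa = math.exp(theta[i]); i += 1
    if fixed_scale is None:
        scale = math.exp(theta[i]); i += 1
    else:
        scale = fixed_scale
    named: dict[str, float] = {"kappa": kappa, "tree_scale": scale}
    if model == "M0":
        w = math.exp(theta[i]); i += 1
        named["omega"] = w
        return kappa, scale, np.array([1.0]), np.array([w]), named
    if model == "M1a":
        p0 = _sigmoid(theta[i]); w0 = _sigmoid(theta[i + 1]); i += 2
        named.update(p0=p0, omega0=w0)
        return kappa, scale, np.array([p0, 1 - p0]), np.array([w0, 1.0]), named
    if model == "M2a":
        s0 = _sigmoid(theta[i]); s1 = _sigmoid(theta[i + 1])
        w0 = _sigmoid(theta[i + 2]); w2 = 1.0 + math.exp(theta[i + 3]); i += 4
        p0, p1 = s0, (1 - s0) * s1
        p2 = 1 - p0 - p1
        named.update(p0=p0, p1=p1, p2=p2, omega0=w0, omega2=w2)
        return kappa, scale, np.array([p0, p1, p2]), np.array([w0, 1.0, w2]), named
    if model in ("M7", "M8", "M8a"):
        p = math.exp(theta[i]); q = math.exp(theta[i + 1]); i += 2
        p = min(max(p, 0.005), 99.0)
        q = min(max(q, 0.005), 99.0)
        bins = beta_bin_omegas(p, q)
        named.update(beta_p=p, beta_q=q)
        if model == "M7":
            K = len(bins)
            return kappa, scale, np.full(K, 1.0 / K), bins, named
        p0 = _sigmoid(theta[i]); i += 1
        ws = 1.0 if model == "M8a" else 1.0 + math.exp(theta[i])
        named.update(p0=p0, omega_s=ws)
        K = len(bins)
        props = np.concatenate([np.full(K, p0 / K), [1 - p0]])
        omegas = np.concatenate([bins, [ws]])
        return kappa, scale, props, omegas, named
    raise ValueError(f"unknown site model {model!r}")


# free parameters including kappa and the tree-scale factor (subtract one
# when the scale is pinned to the M0 estimate)
_N_FREE = {"M0": 3, "M1a": 4, "M2a": 6, "M7": 4, "M8": 6, "M8a": 5}


def _default_start(model: str, rng: np.random.Generator,
                   fixed_scale: float | None) -> np.ndarray:
    parts = [math.log(2.0) + 0.3 * rng.standard_normal()]
    if fixed_scale is None:
        parts.append(0.3 * rng.standard_normal())
    if model == "M0":
        parts.append(math.log(0.4) + 0.5 * rng.standard_normal())
    elif model == "M1a":
        parts += [_logit(0.7), _logit(0.2)]
    elif model == "M2a":
        parts += [_logit(0.6), _logit(0.7), _logit(0.2), math.log(0.5)]
    elif model in ("M7", "M8", "M8a"):
        parts += [math.log(0.5) + 0.3 * rng.standard_normal(),
                  math.log(1.5) + 0.3 * rng.standard_normal()]
        if model in ("M8", "M8a"):
            parts.append(_logit(0.9))
        if model == "M8":
            parts.append(math.log(0.5))  # omega_s starts at 1.5
    return np.array(parts)


def _theta_from_named(model: str, named: dict[str, float],
                      fixed_scale: float | None) -> np.ndarray | None:
    """Embed a (possibly simpler) model's named parameters as a start
    vector, so a nested alternative never scores below its null."""
    def g(key: str, default: float) -> float:
        return float(named.get(key, default))
    parts = [math.log(g("kappa", 2.0))]
    if fixed_scale is None:
        parts.append(math.log(g("tree_scale", 1.0)))
    if model == "M0":
        parts.append(math.log(g("omega", 0.4)))
    elif model == "M1a":
        parts += [_logit(g("p0", 0.7)), _logit(g("omega0", 0.2))]
    elif model == "M2a":
        p0 = g("p0", 0.6)
        p1 = named.get("p1")
        s1 = 1 - 1e-6 if p1 is None else min(p1 / max(1 - p0, 1e-9), 1 - 1e-6)
        w2 = max(g("omega2", 1.5) - 1.0, 1e-9)
        parts += [_logit(p0), _logit(s1), _logit(g("omega0", 0.2)), math.log(w2)]
    elif model in ("M7", "M8", "M8a"):
        parts += [math.log(g("beta_p", 0.5)), math.log(g("beta_q", 1.5))]
        if model in ("M8", "M8a"):
            parts.append(_logit(g("p0", 1 - 1e-6)))
        if model == "M8":
            parts.append(math.log(max(g("omega_s", 1.5) - 1.0, 1e-9)))
    else:
        return None
    return np.array(parts)


def fit_site_model(tree: dendropy.Tree, seqs: dict[str, str], model: str,
                   codon_freqs: np.ndarray | None = None,
                   fixed_scale: float | None = None,
                   starts: int = 3, seed: int = 0,
                   engine: _Engine | None = None,
                   init_from: Sequence[dict[str, float]] = ()) -> CodonModelFit:
    """Maximum-likelihood fit of one GY94 site model.

    ``fixed_scale`` pins the tree-scale factor (normally to the M0
    estimate); otherwise it is a free parameter.  ``starts`` random
    restarts guard against local optima; ``init_from`` adds warm starts
    built from previously fitted (nested) models' named parameters, which
    also guarantees the nesting inequality numerically.  The best lnL is
    kept.
    """
    if model not in SITE_MODELS:
        raise ValueError(f"model must be one of {SITE_MODELS}")
    eng = engine or _Engine(tree, seqs, codon_freqs)
    rng = np.random.default_rng(seed)

    def negloglik(theta: np.ndarray) -> float:
        try:
            kappa, scale, props, omegas, _ = _model_structure(model, theta, fixed_scale)
            lls = [eng.class_loglik(kappa, scale, w) for w in omegas]
            return -eng.mixture_loglik(props, lls)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e10

    start_points = [
        _default_start(model, rng if s else np.random.default_rng(seed), fixed_scale)
        for s in range(max(1, starts))
    ]
    for named0 in init_from:
        x0 = _theta_from_named(model, named0, fixed_scale)
        if x0 is not None:
            start_points.append(x0)
    best = None
    any_converged = False
    for x0 in start_points:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-9})
        any_converged = any_converged or bool(res.success)
        if res.fun > 1e9:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    kappa, scale, props, omegas, named = _model_structure(model, best.x, fixed_scale)
    lls = np.stack([eng.class_loglik(kappa, scale, w) for w in omegas])
    site_ll = lls[:, eng.site_index]
    if model == "M2a":
        positive = np.array([False, False, True])
    elif model == "M8":
        positive = np.array([False] * (len(omegas) - 1) + [True])
    else:
        positive = np.zeros(len(omegas), dtype=bool)
    n_params = _N_FREE[model] - (1 if fixed_scale is not None else 0)
    return CodonModelFit(
        model=model, lnL=-float(best.fun), kappa=kappa, scale=scale,
        proportions=props, omegas=omegas, params=named, n_params=n_params,
        converged=any_converged, class_site_loglik=site_ll,
        positive_class=positive,
    )


# ---------------------------------------------------------------------------
# Branch-site model A


def foreground_ids(tree: dendropy.Tree, leaf_labels: Sequence[str]) -> set[int]:
    """id() of the branch (node) subtending exactly the given leaves."""
    want = frozenset(leaf_labels)
    for nd in tree.preorder_node_iter():
        got = frozenset(
            lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
        )
        if got == want and nd.parent_node is not None:
            return {id(nd)}
    raise ValueError(f"no branch subtends exactly {sorted(want)}")


def _bs_structure(theta: np.ndarray, null: bool, fixed_scale: float | None):
    i = 0
    kappa = math.exp(theta[i]); i += 1
    if fixed_scale is None:
        scale = math.exp(theta[i]); i += 1
    else:
        scale = fixed_scale
    s0 = _sigmoid(theta[i]); s1 = _sigmoid(theta[i + 1])
    w0 = _sigmoid(theta[i + 2]); i += 3
    w2 = 1.0 if null else 1.0 + math.exp(theta[i])
    p0, p1 = s0 * s1, s0 * (1 - s1)
    p2 = 1 - s0
    # classes 2a/2b split the remaining mass in the p0:p1 ratio
    denom = p0 + p1 if p0 + p1 > 0 else 1.0
    props = np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])
    bg = np.array([w0, 1.0, w0, 1.0])
    fg = np.array([w0, 1.0, w2, w2])
    named = {"kappa": kappa, "tree_scale": scale, "p0": p0, "p1": p1,
             "p2a": props[2], "p2b": props[3], "omega0": w0, "omega2": w2}
    return kappa, scale, props, bg, fg, named


def fit_branch_site(tree: dendropy.Tree, seqs: dict[str, str],
                    foreground: set[int], null: bool,
                    codon_freqs: np.ndarray | None = None,
                    fixed_scale: float | None = None,
                    starts: int = 2, seed: int = 0,
                    engine: _Engine | None = None,
                    init_from: Sequence[dict[str, float]] = ()) -> CodonModelFit:
    """Branch-site model A (4 site classes; classes 2a/2b allow omega2 on
    the foreground branches).  ``null=True`` fixes omega2 = 1; the
    alternative starts omega2 at 1.5."""
    all_branches = {
        id(nd) for nd in tree.preorder_node_iter() if nd.parent_node is not None
    }
    if not foreground:
        raise ValueError("foreground branch set is empty")
    if foreground >= all_branches:
        raise ValueError("foreground cannot be every branch")
    eng = engine or _Engine(tree, seqs, codon_freqs, foreground=foreground)
    if eng.foreground != foreground:
        eng = _Engine(tree, seqs, codon_freqs if codon_freqs is not None else eng.pi,
                      foreground=foreground)
    rng = np.random.default_rng(seed)
    n_free = (3 if null else 4) + (0 if fixed_scale is not None else 1) + 1

    def negloglik(theta: np.ndarray) -> float:
        try:
            kappa, scale, props, bg, fg, _ = _bs_structure(theta, null, fixed_scale)
            lls = [
                eng.class_loglik(kappa, scale, bg[k], fg[k]) for k in range(4)
            ]
            return -eng.mixture_loglik(props, lls)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e10

    start_points = []
    for s in range(max(1, starts)):
        r = rng if s else np.random.default_rng(seed)
        x0 = [math.log(2.0) + 0.2 * r.standard_normal()]
        if fixed_scale is None:
            x0.append(0.2 * r.standard_normal())
        x0 += [_logit(0.85), _logit(0.75), _logit(0.2)]
        if not null:
            x0.append(math.log(0.5))  # omega2 starts at 1.5
        start_points.append(np.array(x0))
    for named0 in init_from:
        p0, p1 = named0.get("p0", 0.6), named0.get("p1", 0.2)
        s0 = min(max(p0 + p1, 1e-6), 1 - 1e-6)
        s1 = min(max(p0 / s0, 1e-6), 1 - 1e-6)
        x0 = [math.log(named0.get("kappa", 2.0))]
        if fixed_scale is None:
            x0.append(math.log(named0.get("tree_scale", 1.0)))
        x0 += [_logit(s0), _logit(s1), _logit(named0.get("omega0", 0.2))]
        if not null:
            x0.append(math.log(max(named0.get("omega2", 1.5) - 1.0, 1e-9)))
        start_points.append(np.array(x0))
    best = None
    any_converged = False
    for x0 in start_points:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-9})
        any_converged = any_converged or bool(res.success)
        if res.fun > 1e9:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    kappa, scale, props, bg, fg, named = _bs_structure(best.x, null, fixed_scale)
    lls = np.stack(
        [eng.class_loglik(kappa, scale, bg[k], fg[k]) for k in range(4)]
    )
    return CodonModelFit(
        model="branch-site A-null" if null else "branch-site A",
        lnL=-float(best.fun), kappa=kappa, scale=scale, proportions=props,
        omegas=bg, params=named, n_params=n_free, converged=any_converged,
        foreground_omegas=fg, class_site_loglik=lls[:, eng.site_index],
        positive_class=np.array([False, False, True, True]),
    )


# ---------------------------------------------------------------------------
# Empirical Bayes site identification


@dataclasses.dataclass
class SiteClassPosterior:
    method: str
    posterior_positive: np.ndarray       # per original site
    class_posteriors: np.ndarray         # sites x classes
    above_95: np.ndarray


def _class_posterior(props: np.ndarray, site_ll: np.ndarray) -> np.ndarray:
    logp = np.log(np.maximum(props, 1e-300))[:, None]
    joint = site_ll + logp
    joint -= special.logsumexp(joint, axis=0, keepdims=True)
    return np.exp(joint).T  # sites x classes


def _mixing_grid(fit: CodonModelFit, n: int = 10):
    """Uniform grid over the free mixing proportions, omegas at the MLEs."""
    mids = (np.arange(n) + 0.5) / n
    model = fit.model
    grids = []
    if model == "M2a" or model.startswith("branch-site"):
        for u in mids:
            for v in mids:
                if model == "M2a":
                    p0, p1 = u, (1 - u) * v
                    grids.append(np.array([p0, p1, 1 - p0 - p1]))
                else:
                    p0, p1 = u * v, u * (1 - v)
                    p2 = 1 - u
                    denom = (p0 + p1) or 1.0
                    grids.append(
                        np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])
                    )
    elif model == "M8":
        K = len(fit.omegas) - 1
        for u in mids:
            grids.append(np.concatenate([np.full(K, u / K), [1 - u]]))
    else:
        raise ValueError(f"model {model} has no positive-selection class")
    return grids


def posterior_site_classes(fit: CodonModelFit, method: str = "BEB"
                           ) -> SiteClassPosterior:
    """Posterior probability per site of the positive-selection class.

    NEB conditions on the MLEs; BEB averages the class posteriors over a
    uniform grid on the mixing proportions weighted by the data likelihood
    of each grid point (omega parameters held at their MLEs).
    """
    if fit.class_site_loglik is None or fit.positive_class is None:
        raise ValueError("fit carries no site-likelihood information")
    if not fit.positive_class.any():
        raise ValueError(f"model {fit.model} has no positive-selection class")
    site_ll = fit.class_site_loglik
    if method.upper() == "NEB":
        post = _class_posterior(fit.proportions, site_ll)
    elif method.upper() == "BEB":
        grids = _mixing_grid(fit)
        log_weights = np.array(
            [
                float(np.sum(special.logsumexp(
                    site_ll + np.log(np.maximum(g, 1e-300))[:, None], axis=0
                )))
                for g in grids
            ]
        )
        log_weights -= special.logsumexp(log_weights)
        post = np.zeros((site_ll.shape[1], site_ll.shape[0]))
        for g, lw in zip(grids, log_weights):
            post += math.exp(lw) * _class_posterior(g, site_ll)
    else:
        raise ValueError("method must be 'NEB' or 'BEB'")
    positive = post[:, fit.positive_class].sum(axis=1)
    return SiteClassPosterior(method.upper(), positive, post, positive > 0.95)


# ---------------------------------------------------------------------------
# Conservation comparison between gene sets


def compare_site_variability(profiles: dict[str, ConservationProfile],
                             categories: Sequence[str] | None = None
                             ) -> pd.DataFrame:
    """Mean information content per site category per gene set, with a
    rank-sum comparison of per-column IC between the two sets."""
    if len(profiles) != 2:
        raise ValueError("exactly two gene sets are compared")
    (name_a, prof_a), (name_b, prof_b) = profiles.items()
    cats = set(categories) if categories is not None else (
        set(prof_a.categories or []) | set(prof_b.categories or [])
    ) or {"all"}
    rows = []
    for cat in sorted(cats):
        def _vals(prof: ConservationProfile) -> np.ndarray:
            mask = ~prof.all_gap
            if cat != "all" and prof.categories is not None:
                mask &= np.array([c == cat for c in prof.categories])
            return prof.ic[mask]
        va, vb = _vals(prof_a), _vals(prof_b)
        if va.size == 0 or vb.size == 0:
            continue  # category absent in one set; skipped with note
        if np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append(
            {"category": cat, f"mean_ic_{name_a}": float(np.mean(va)),
             f"mean_ic_{name_b}": float(np.mean(vb)),
             "rank_sum_p": p, "n_sites_a": va.size, "n_sites_b": vb.size}
        )
    return pd.DataFrame(rows)
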