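"""Maximum-likelihood fitting of divergence/migration models to SFS and bSFS
data, model comparison, bootstrap confidence intervals, conversion to
absolute quantities, and excess-block tests.

Two likelihood schemes are supported.  The SFS scheme fits the average
per-site frequencies of the four mutation classes (a five-category
multinomial including the invariant complement); it ignores linkage and
supports at most three free parameters, so the ``IM2`` class is not
fittable in this mode.  The bSFS scheme uses the exact joint probability
``p(k)`` of each block's mutation configuration, treating blocks as
independent replicates of the coalescent; blocks failing the four-gamete
test are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

from .coalcore import (
    SiteClassCounts,
    block_count_distribution,
    expected_site_frequencies,
    pattern_probability_marginal,
)
from .haploblocks import Block, four_gamete_pass
from .models import CLASSES, DemographicModel, ModelVariant

log = logging.getLogger(__name__)

INVARIANT = "invariant"

#: optimisation bounds; they bracket all published-scale estimates by >10x
DEFAULT_BOUNDS = {
    "theta": (1e-5, 0.05),
    "T": (0.01, 100.0),
    "M": (0.0, 2.0),
    "size_factor": (0.05, 20.0),
}

#: an IM-type fit with M-hat below this is a boundary collapse to strict
#: divergence
COLLAPSE_TOL = 1e-4

_LOG_PARAMS = {"theta", "T", "size_factor"}  # optimised on log10 scale


@dataclass
class FitResult:
    variant: ModelVariant
    params: dict
    lnL: float
    mode: str
    n_starts: int
    converged: bool
    at_bounds: tuple = ()
    collapsed: bool = False

    @property
    def model(self) -> DemographicModel:
        return self.variant.bind(self.params)

    def label(self) -> str:
        return self.variant.label()


@dataclass
class ComparisonEntry:
    label: str
    lnL: float
    delta: float
    collapsed_to: str | None = None


@dataclass
class ModelComparison:
    entries: list

    @property
    def best(self) -> ComparisonEntry:
        return max(self.entries, key=lambda e: e.lnL)


@dataclass
class BootstrapResult:
    n_replicates: int
    estimates: dict  # param -> array of replicate estimates
    sd: dict
    ci: dict  # param -> (low, high), point +/- 1.96 SD
    point: dict
    seed: int | None


@dataclass
class AbsoluteEstimates:
    N_anc: float
    t_years: float
    immigrant_waiting_years: float
    introgressed_fraction: float
    mu: float
    g: float


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def sfs_loglik(model: DemographicModel, category_counts: dict) -> float:
    """Multinomial log-likelihood of per-site category counts under the
    model's expected site frequencies (constant terms omitted)."""
    if model.model_class == "IM2":
        raise ValueError("IM2 is not identifiable from the SFS alone")
    try:
        probs = expected_site_frequencies(model)
    except ValueError:
        return -math.inf
    lnL = 0.0
    for cat in (*CLASSES, INVARIANT):
        n = category_counts.get(cat, 0)
        if n == 0:
            continue
        p = probs[cat]
        if p <= 0:
            log.info("category %s has non-positive probability %g", cat, p)
            return -math.inf
        lnL += n * math.log(p)
    return lnL


def _counts_of(block) -> SiteClassCounts:
    return block.counts if isinstance(block, Block) else block


def _passing(blocks) -> list[SiteClassCounts]:
    kept, dropped = [], 0
    for b in blocks:
        c = _counts_of(b)
        ok = b.four_gamete_pass if isinstance(b, Block) else four_gamete_pass(c)
        if ok:
            kept.append(c)
        else:
            dropped += 1
    if dropped:
        log.info("excluded %d four-gamete-violating blocks from the bSFS", dropped)
    return kept


def bsfs_loglik(model: DemographicModel, blocks, n_sites: int = 150) -> float:
    """Sum of log pattern probabilities over blocks (the bSFS likelihood).

    The bSFS is a multiset: one count-distribution table covering every
    observed configuration is computed per call, so the cost is independent
    of the number of blocks.
    """
    kept = _passing(blocks)
    if not kept:
        raise ValueError("no four-gamete-compatible blocks")
    tallies: dict[tuple, int] = {}
    for c in kept:
        tallies[c.as_tuple()] = tallies.get(c.as_tuple(), 0) + 1
    caps = tuple(max(k[i] for k in tallies) for i in range(len(CLASSES)))
    dist = block_count_distribution(model, caps, n_sites)
    lnL = 0.0
    for k, n in tallies.items():
        p = float(dist[k])
        if p <= 0.0:
            return -math.inf
        lnL += n * math.log(p)
    return lnL


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def blocks_to_category_counts(blocks, n_sites: int = 150) -> dict:
    """All-site category counts for SFS fitting (invariant complement)."""
    counts = dict.fromkeys(CLASSES, 0)
    total = 0
    for b in blocks:
        c = _counts_of(b)
        for klass in CLASSES:
            counts[klass] += c[klass]
        total += b.n_sites if isinstance(b, Block) else n_sites
    counts[INVARIANT] = total - sum(counts[c] for c in CLASSES)
    return counts


def _to_x(params: dict, names) -> np.ndarray:
    return np.array(
        [math.log10(params[n]) if n in _LOG_PARAMS else params[n] for n in names]
    )


def _from_x(x, names) -> dict:
    return {
        n: 10.0 ** xi if n in _LOG_PARAMS else float(xi)
        for n, xi in zip(names, x)
    }


def _heuristic_start(freqs: dict, variant: ModelVariant, bounds: dict) -> dict:
    """Moment-style starting point from observed class frequencies."""
    fA = max(freqs.get("kA", 0.0), 1e-6)
    fB = max(freqs.get("kB", 0.0), 1e-6)
    fD = max(freqs.get("kAABB", 0.0), 1e-6)
    theta0 = math.sqrt(fA * fB)
    T0 = fD / theta0 - 1.0
    start = {"theta": theta0, "T": T0}
    if "M" in variant.param_names:
        start["M"] = 0.02
    if "size_factor" in variant.param_names:
        het = fA if variant.size_target == "A" else fB
        start["size_factor"] = het / theta0
    return {
        n: float(np.clip(start[n], bounds[n][0] * 1.01, bounds[n][1] * 0.99))
        for n in variant.param_names
    }


def fit(
    data,
    mode: str,
    variants,
    *,
    n_sites: int = 150,
    n_starts: int = 10,
    seed: int | None = 0,
    bounds: dict | None = None,
    options: dict | None = None,
    extra_starts=None,
) -> list[FitResult]:
    """Fit each model variant by bounded multi-start maximum likelihood.

    ``data`` is a category-count dict for ``mode='SFS'`` or a sequence of
    blocks for ``mode='bSFS'``.  One start is moment-based, the remainder
    are log-uniform draws over the bounds; ``extra_starts`` adds caller
    supplied parameter dicts (e.g. the optimum of a nested model), with
    missing parameters filled from the moment-based start.  Nelder-Mead
    simplex search is used (the likelihood surface is smooth but gradients
    are not available in closed form).
    """
    variants = list(variants)
    if not variants:
        raise ValueError("at least one model variant is required")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    opts = {"xatol": 1e-4, "fatol": 1e-8, "maxfev": 4000, **(options or {})}

    if mode == "SFS":
        counts = dict(data)
        total = sum(counts.values())
        freqs = {c: counts.get(c, 0) / total for c in CLASSES}
        loglik = lambda model: sfs_loglik(model, counts)
        for v in variants:
            if v.model_class == "IM2":
                raise ValueError("IM2 cannot be fitted in SFS mode")
    elif mode == "bSFS":
        blocks = list(data)
        cat = blocks_to_category_counts(blocks, n_sites)
        total = sum(cat.values())
        freqs = {c: cat[c] / total for c in CLASSES}
        loglik = lambda model: bsfs_loglik(model, blocks, n_sites)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    results = []
    for variant in variants:
        names = variant.param_names
        xbounds = [
            (
                (math.log10(bounds[n][0]), math.log10(bounds[n][1]))
                if n in _LOG_PARAMS
                else bounds[n]
            )
            for n in names
        ]

        def objective(x):
            params = _from_x(x, names)
            try:
                value = loglik(variant.bind(params))
            except (ValueError, FloatingPointError):
                return 1e12
            return -value if math.isfinite(value) else 1e12

        heuristic = _heuristic_start(freqs, variant, bounds)
        starts = [_to_x(heuristic, names)]
        for extra in extra_starts or ():
            filled = {
                n: float(np.clip(extra.get(n, heuristic[n]),
                                 bounds[n][0] * 1.01, bounds[n][1] * 0.99))
                for n in names
            }
            starts.append(_to_x(filled, names))
        for _ in range(max(0, n_starts - 1)):
            x0 = []
            for n, (lo, hi) in zip(names, xbounds):
                if n == "M":
                    x0.append(10 ** rng.uniform(-3, math.log10(max(hi, 1e-3))))
                else:
                    x0.append(rng.uniform(lo, hi))
            starts.append(np.array(x0))

        best = None
        converged = False
        for x0 in starts:
            res = minimize(
                objective, x0, method="Nelder-Mead", bounds=xbounds, options=opts
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        if best is None or best.fun >= 1e12:
            raise RuntimeError(
                f"no convergent start for {variant.label()}; last result: {best}"
            )
        params = _from_x(best.x, names)
        at_bounds = tuple(
            n
            for n, xi, (lo, hi) in zip(names, best.x, xbounds)
            if xi <= lo + 1e-6 or xi >= hi - 1e-6
        )
        collapsed = (
            variant.model_class in ("IM", "IM2") and params.get("M", 1.0) < COLLAPSE_TOL
        )
        results.append(
            FitResult(
                variant=variant,
                params=params,
                lnL=-best.fun,
                mode=mode,
                n_starts=len(starts),
                converged=converged,
                at_bounds=at_bounds,
                collapsed=collapsed,
            )
        )
    return results


def compare_models(fits) -> ModelComparison:
    """Per-variant difference in maximised lnL relative to the best fit.

    Collapsed IM-type fits (M-hat at the zero boundary) are reported as a
    collapse onto the nested strict-divergence model rather than as a
    distinct optimum.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    modes = {f.mode for f in fits}
    if len(modes) > 1:
        raise ValueError(f"cannot compare fits of mixed modes {modes}")
    best = max(f.lnL for f in fits)
    entries = []
    for f in sorted(fits, key=lambda f: -f.lnL):
        collapsed_to = None
        if f.collapsed:
            collapsed_to = "Div" if f.variant.model_class == "IM" else "Div2"
        entries.append(
            ComparisonEntry(f.label(), f.lnL, f.lnL - best, collapsed_to)
        )
    return ModelComparison(entries)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_sfs(
    blocks,
    variant: ModelVariant,
    B: int = 1000,
    seed: int | None = None,
    n_sites: int = 150,
    point: dict | None = None,
    **fit_kwargs,
) -> BootstrapResult:
    """Block bootstrap of the SFS fit, one randomly drawn variable site per
    block.

    Each replicate resamples blocks with replacement; every resampled block
    is represented by a single uniformly drawn variable site (blocks without
    variable sites contribute only invariants), weighted by the block's
    variable-site count so that replicate category counts stay on the
    per-site scale.  The replicate SFS is refitted and the 95% CI is the
    point estimate +/- 1.96 SD across replicates.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    blocks = list(blocks)
    counts_matrix = np.array(
        [[_counts_of(b)[c] for c in CLASSES] for b in blocks], dtype=float
    )
    totals = counts_matrix.sum(axis=1)
    n_blocks = len(blocks)
    total_sites = n_blocks * n_sites

    fit_kwargs.setdefault("n_starts", 2)
    if point is None:
        point = fit(
            blocks_to_category_counts(blocks, n_sites), "SFS", [variant],
            n_sites=n_sites, **fit_kwargs,
        )[0].params

    rng = np.random.default_rng(seed)
    reps: list[dict] = []
    for _ in range(B):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        cat = dict.fromkeys(CLASSES, 0.0)
        for i in idx:
            w = totals[i]
            if w == 0:
                continue
            drawn = rng.choice(len(CLASSES), p=counts_matrix[i] / w)
            cat[CLASSES[drawn]] += w
        cat[INVARIANT] = total_sites - sum(cat[c] for c in CLASSES)
        cat = {k: int(round(v)) for k, v in cat.items()}
        reps.append(
            fit(cat, "SFS", [variant], n_sites=n_sites, **fit_kwargs)[0].params
        )
    estimates = {
        n: np.array([r[n] for r in reps]) for n in variant.param_names
    }
    sd = {n: float(v.std(ddof=1)) for n, v in estimates.items()}
    ci = {
        n: (point[n] - 1.96 * sd[n], point[n] + 1.96 * sd[n])
        for n in variant.param_names
    }
    return BootstrapResult(
        n_replicates=B, estimates=estimates, sd=sd, ci=ci, point=point, seed=seed
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def to_absolute(fit_result, mu: float = 9.15e-9, g: float = 3.0) -> AbsoluteEstimates:
    """Convert scaled estimates to absolute quantities.

    ``N_anc = theta / (4 mu)`` (diploid individuals), ``t = T x 2 N_anc x g``
    years, expected waiting time between immigrants ``g / M`` years, and the
    expected introgressed fraction ``1 - exp(-M T)``.
    """
    if mu <= 0 or g <= 0:
        raise ValueError("mu and g must be positive")
    params = fit_result.params if isinstance(fit_result, FitResult) else dict(fit_result)
    theta, T = params["theta"], params["T"]
    M = params.get("M", 0.0)
    N = theta / (4.0 * mu)
    return AbsoluteEstimates(
        N_anc=N,
        t_years=T * 2.0 * N * g,
        immigrant_waiting_years=(g / M) if M > 0 else math.inf,
        introgressed_fraction=1.0 - math.exp(-M * T),
        mu=mu,
        g=g,
    )


def map_density_cM_per_block(total_map_cM: float, n_blocks: int) -> float:
    """Maximum genetic-map density of blocks, cM per block, used to argue
    that physical linkage between blocks is negligible."""
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")
    return total_map_cM / n_blocks


def excess_block_test(
    blocks, model: DemographicModel, pinned, n_sites: int = 150
) -> dict:
    """One-sided binomial test for an excess of blocks with zero mutations in
    the pinned classes (e.g. no fixed differences, or fully invariant)."""
    blocks = list(blocks)
    n = len(blocks)
    if n == 0:
        raise ValueError("no blocks")
    pinned = set(pinned)
    observed = sum(
        1 for b in blocks if all(_counts_of(b)[c] == 0 for c in pinned)
    )
    p_model = pattern_probability_marginal(model, pinned, n_sites)
    P = float(binom.sf(observed - 1, n, p_model))
    return {"observed": observed, "n": n, "p_model": p_model, "P_binomial": P}
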