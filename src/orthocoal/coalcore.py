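"""Structured-coalescent machinery for two unphased diploids.

For a sample ``{a1, a2}`` from taxon A and ``{b1, b2}`` from taxon B, every
branch of the (unrooted, unphased) genealogy maps to one of four folded
mutation classes, depending on the set of sampled lineages it subtends:

* ``kA``    -- {a1} or {a2} (or the complementary triple): a site mutated on
  such a branch is heterozygous in A only;
* ``kB``    -- symmetric for B;
* ``kAB``   -- {ai, bj}: heterozygous in both taxa;
* ``kAABB`` -- {a1, a2} or {b1, b2}: alternate homozygotes.

Everything here works on the continuous-time Markov chain of lineage
configurations (a partition of the sample, each block tagged by its current
population).  Between time 0 and the split time ``T`` (backwards), lineages
coalesce pairwise within a population at rate ``1/size`` and lineages in the
forward-time recipient population migrate to the donor at rate ``M/2``
(rates per ``2 N_anc`` generations).  Beyond ``T`` the chain is the ordinary
Kingman coalescent in the ancestral population.

Three exact quantities are derived from this chain:

* :func:`expected_branch_lengths` -- occupation-time rewards E[t_c];
* :func:`block_count_distribution` / :func:`pattern_probability` -- the
  probability ``p(k)`` of observing mutation-count vector ``k`` in a
  non-recombining block, via a count-augmented chain (matrix exponential
  before ``T``, absorption cascade afterwards);
* :func:`simulate_block` -- a Gillespie draw used as an independent
  Monte-Carlo oracle and as the synthetic-data backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.linalg import expm

from .models import CLASSES, K_A, K_AB, K_AABB, K_B, DemographicModel

LABELS = frozenset({"a1", "a2", "b1", "b2"})

__all__ = [
    "SiteClassCounts",
    "BranchClassLengths",
    "branch_class_of",
    "expected_branch_lengths",
    "expected_site_frequencies",
    "pattern_probability",
    "pattern_probability_marginal",
    "block_count_distribution",
    "simulate_block",
    "simulate_branch_lengths",
]


@dataclass(frozen=True)
class SiteClassCounts:
    """Mutation configuration of one block, ``k = {kA, kB, kAB, kAABB}``."""

    kA: int = 0
    kB: int = 0
    kAB: int = 0
    kAABB: int = 0

    def __post_init__(self) -> None:
        if min(self.as_tuple()) < 0:
            raise ValueError("site class counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.kA, self.kB, self.kAB, self.kAABB)

    def __getitem__(self, klass: str) -> int:
        return getattr(self, klass)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class BranchClassLengths:
    """Expected total branch length per folded class, in ``2 N_anc`` gens."""

    E_tA: float
    E_tB: float
    E_tAB: float
    E_tAABB: float

    def as_dict(self) -> dict[str, float]:
        return {K_A: self.E_tA, K_B: self.E_tB, K_AB: self.E_tAB, K_AABB: self.E_tAABB}

    @property
    def total(self) -> float:
        return self.E_tA + self.E_tB + self.E_tAB + self.E_tAABB


def branch_class_of(subtended: frozenset | set) -> str:
    """Folded mutation class of a branch subtending the given sample labels.

    Raises ``ValueError`` for the empty or full set (a mutation there is not
    observable as polymorphism between the two diploids).
    """
    sub = frozenset(subtended)
    if not sub or not sub < LABELS:
        raise ValueError(f"no observable mutation class for {set(sub)!r}")
    if len(sub) == 3:  # fold onto the complementary singleton
        sub = LABELS - sub
    if len(sub) == 1:
        return K_A if next(iter(sub)).startswith("a") else K_B
    first, second = sorted(sub)
    if first[0] == second[0]:
        return K_AABB
    return K_AB


def _class_index(labels: frozenset) -> int | None:
    """Class index of a lineage, or None for the root (full set)."""
    if labels == LABELS:
        return None
    return CLASSES.index(branch_class_of(labels))


# ---------------------------------------------------------------------------
# configuration state spaces
# ---------------------------------------------------------------------------

Config = tuple  # sorted tuple of (sorted-label-tuple, pop)


def _canon(lineages) -> Config:
    return tuple(sorted((tuple(sorted(lab)), pop) for lab, pop in lineages))


def _config_transitions(config: Config, model: DemographicModel, structured: bool):
    """Yield (successor, rate) pairs; structured=True means the pre-T phase."""
    lineages = [(frozenset(lab), pop) for lab, pop in config]
    n = len(lineages)
    # coalescence within a population
    for i, j in combinations(range(n), 2):
        (lab_i, pop_i), (lab_j, pop_j) = lineages[i], lineages[j]
        if pop_i != pop_j:
            continue
        rate = 1.0 / model.population_size(pop_i) if structured else 1.0
        merged = lineages[:i] + lineages[i + 1 : j] + lineages[j + 1 :]
        merged.append((lab_i | lab_j, pop_i))
        yield _canon(merged), rate
    # backward migration out of the forward-time recipient
    if structured and model.M > 0:
        recipient, donor = model.recipient, model.donor
        for i, (lab, pop) in enumerate(lineages):
            if pop == recipient:
                moved = lineages[:i] + [(lab, donor)] + lineages[i + 1 :]
                yield _canon(moved), model.M / 2.0


class _Chain:
    """Indexed configuration chain for one phase of the model."""

    def __init__(self, model: DemographicModel, structured: bool):
        if structured:
            initial = _canon(
                [({"a1"}, "A"), ({"a2"}, "A"), ({"b1"}, "B"), ({"b2"}, "B")]
            )
        else:
            initial = _canon(
                [({"a1"}, "ANC"), ({"a2"}, "ANC"), ({"b1"}, "ANC"), ({"b2"}, "ANC")]
            )
        configs = []
        index: dict[Config, int] = {}
        stack = [initial]
        index[initial] = 0
        configs.append(initial)
        edges = []  # (src, dst, rate)
        while stack:
            cfg = stack.pop()
            i = index[cfg]
            for succ, rate in _config_transitions(cfg, model, structured):
                if succ not in index:
                    index[succ] = len(configs)
                    configs.append(succ)
                    stack.append(succ)
                edges.append((i, index[succ], rate))
        self.configs = configs
        self.index = index
        self.n = len(configs)
        self.initial = index[initial]
        # rate matrix of configuration moves (no mutation)
        Q = np.zeros((self.n, self.n))
        for i, j, rate in edges:
            Q[i, j] += rate
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        self.Q = Q
        # per-config lineage count in each mutation class
        r = np.zeros((self.n, len(CLASSES)))
        for i, cfg in enumerate(configs):
            for lab, _pop in cfg:
                ci = _class_index(frozenset(lab))
                if ci is not None:
                    r[i, ci] += 1
        self.class_counts = r
        self.n_lineages = np.array([len(cfg) for cfg in configs])

    def partition_of(self, i: int) -> tuple:
        """Configuration with population tags dropped (for the phase hand-over)."""
        return tuple(sorted(lab for lab, _pop in self.configs[i]))


@lru_cache(maxsize=64)
def _chains(model_key) -> tuple[_Chain, _Chain]:
    model = DemographicModel(**dict(model_key))
    return _Chain(model, structured=True), _Chain(model, structured=False)


def _model_key(model: DemographicModel):
    return tuple(sorted(vars(model).items()))


def _get_chains(model: DemographicModel) -> tuple[_Chain, _Chain]:
    return _chains(_model_key(model))


# ---------------------------------------------------------------------------
# expected branch lengths
# ---------------------------------------------------------------------------

def expected_branch_lengths(model: DemographicModel) -> BranchClassLengths:
    """Exact expected total branch length per folded mutation class.

    Occupation times of the configuration chain are accumulated over the
    structured phase ``[0, T)`` via an augmented matrix exponential, and over
    the ancestral phase via the fundamental matrix of the panmictic chain.
    """
    pre, post = _get_chains(model)
    occupancy_post_start = np.zeros(post.n)
    E = np.zeros(len(CLASSES))

    if model.T > 0:
        Q = pre.Q
        n = pre.n
        aug = np.zeros((2 * n, 2 * n))
        aug[:n, :n] = Q
        aug[:n, n:] = np.eye(n)
        eAT = expm(aug * model.T)
        p0 = np.zeros(n)
        p0[pre.initial] = 1.0
        occ_pre = p0 @ eAT[:n, n:]  # \int_0^T P(X_s = j) ds
        E += occ_pre @ pre.class_counts
        p_T = p0 @ eAT[:n, :n]
        for i, mass in enumerate(p_T):
            if mass > 0:
                partition = pre.partition_of(i)
                j = post.index[_canon((lab, "ANC") for lab in partition)]
                occupancy_post_start[j] += mass
    else:
        occupancy_post_start[post.initial] = 1.0

    transient = np.where(post.n_lineages > 1)[0]
    Qtt = post.Q[np.ix_(transient, transient)]
    occ_post = np.linalg.solve(-Qtt.T, occupancy_post_start[transient])
    E += occ_post @ post.class_counts[transient]
    return BranchClassLengths(*E)


def expected_site_frequencies(model: DemographicModel) -> dict[str, float]:
    """Per-site expected frequency of each class, ``E[k_c] = (theta/2) E[t_c]``,
    plus the invariant complement (small-theta linearisation)."""
    lengths = expected_branch_lengths(model)
    freqs = {c: model.theta / 2.0 * t for c, t in lengths.as_dict().items()}
    total = sum(freqs.values())
    if total >= 1.0:
        raise ValueError("theta too large for per-site linearization")
    freqs["invariant"] = 1.0 - total
    return freqs


# ---------------------------------------------------------------------------
# blockwise pattern probabilities
# ---------------------------------------------------------------------------

def _mutation_rates(model: DemographicModel, n_sites: int, lam_scale=None) -> np.ndarray:
    lam = np.full(len(CLASSES), n_sites * model.theta / 2.0)
    if lam_scale is not None:
        lam = lam * np.asarray(lam_scale, dtype=float)
    return lam


def _phase1_distribution(model, chain: _Chain, caps, lam) -> np.ndarray:
    """Distribution over (config, counts) at time T by uniformisation.

    Mass that would exceed a cap is dropped (it can never return), so every
    retained entry is the exact probability of that joint state.
    """
    shape = (chain.n, *[c + 1 for c in caps])
    p = np.zeros(shape)
    p[(chain.initial,) + (0,) * len(caps)] = 1.0

    Qoff = chain.Q - np.diag(chain.Q.diagonal())
    out_rate = -chain.Q.diagonal() + chain.class_counts @ lam  # per config
    Lam = float(out_rate.max())
    if Lam == 0.0 or model.T == 0.0:
        return p

    # one sparse jump operator P = I + Q/Lam over (config, counts)
    dims = [c + 1 for c in caps]
    D = int(np.prod(dims))
    P = sparse.kron(sparse.csr_matrix(Qoff.T / Lam), sparse.identity(D), format="csr")
    for c in range(len(CLASSES)):
        if caps[c] > 0 and lam[c] > 0:
            mats = [sparse.identity(d, format="csr") for d in dims]
            mats[c] = sparse.diags(np.ones(dims[c] - 1), -1)  # count + 1
            shift = mats[0]
            for m in mats[1:]:
                shift = sparse.kron(shift, m)
            P = P + sparse.kron(
                sparse.diags(lam[c] * chain.class_counts[:, c] / Lam), shift,
                format="csr",
            )
    P = (P + sparse.diags(np.repeat(1.0 - out_rate / Lam, D))).tocsr()

    # uniformised series e^{Qt} p = sum_n Pois(Lam t; n) P^n p
    v = p.reshape(-1)
    n_steps = max(1, math.ceil(Lam * model.T / 150.0))
    a = Lam * model.T / n_steps
    for _ in range(n_steps):
        term = v
        log_weight = -a
        weight = math.exp(log_weight) if log_weight > -700 else 0.0
        acc = term * weight
        cum = weight
        n = 0
        while cum < 1.0 - 1e-13 and n < 100_000:
            n += 1
            term = P @ term
            log_weight += math.log(a / n)
            if log_weight > -700:
                weight = math.exp(log_weight)
                acc += weight * term
                cum += weight
        v = acc
    return v.reshape(p.shape)


def _phase2_absorb(post: _Chain, p: np.ndarray, caps, lam) -> np.ndarray:
    """Count distribution at full coalescence, by a jump-chain cascade.

    Counts only increase and lineage number only decreases, so partitions can
    be processed in order of decreasing lineage count; within a partition the
    geometric series of mutation self-transitions is summed directly.
    """
    mass = p.copy()
    final = np.zeros(p.shape[1:])
    order = np.argsort(-post.n_lineages)
    for i in order:
        if post.n_lineages[i] == 1:
            final += mass[i]
            continue
        m = mass[i]
        if not m.any():
            continue
        coal_total = -post.Q[i, i] - 0.0  # post chain has no migration
        mut_rates = lam * post.class_counts[i]
        R = coal_total + mut_rates.sum()
        # sum_{n>=0} S^n m  with S the normalised mutation-shift operator
        tot = m.copy()
        cur = m
        while True:
            nxt = np.zeros_like(cur)
            for c in range(len(CLASSES)):
                if mut_rates[c] > 0 and caps[c] > 0:
                    src = [slice(None)] * cur.ndim
                    dst = [slice(None)] * cur.ndim
                    src[c] = slice(0, caps[c])
                    dst[c] = slice(1, caps[c] + 1)
                    nxt[tuple(dst)] += (mut_rates[c] / R) * cur[tuple(src)]
            cur = nxt
            s = cur.sum()
            tot += cur
            if s < 1e-16:
                break
        exit_mass = (coal_total / R) * tot
        for j in range(post.n):
            if j != i and post.Q[i, j] > 0:
                mass[j] += (post.Q[i, j] / coal_total) * exit_mass
    return final


def block_count_distribution(
    model: DemographicModel,
    caps: tuple[int, int, int, int],
    n_sites: int = 150,
    lam_scale=None,
) -> np.ndarray:
    """Joint probability array ``P[kA, kB, kAB, kAABB]`` for a block.

    Each entry with ``k <= caps`` componentwise is the exact probability of
    that mutation configuration under per-class Poisson intensity
    ``lambda_c = n_sites * theta / 2`` per unit branch length; mass beyond
    the caps is discarded (the array therefore sums to < 1).
    """
    lam = _mutation_rates(model, n_sites, lam_scale)
    pre, post = _get_chains(model)
    if model.T > 0:
        p1 = _phase1_distribution(model, pre, caps, lam)
        shape2 = (post.n, *[c + 1 for c in caps])
        p2 = np.zeros(shape2)
        for i in range(pre.n):
            block = p1[i]
            if not block.any():
                continue
            j = post.index[_canon((lab, "ANC") for lab in pre.partition_of(i))]
            p2[j] += block
    else:
        shape2 = (post.n, *[c + 1 for c in caps])
        p2 = np.zeros(shape2)
        p2[(post.initial,) + (0,) * len(caps)] = 1.0
    return _phase2_absorb(post, p2, caps, lam)


def pattern_probability(
    model: DemographicModel, k: SiteClassCounts, n_sites: int = 150
) -> float:
    """Exact probability ``p(k)`` of the blockwise mutation configuration."""
    caps = k.as_tuple()
    dist = block_count_distribution(model, caps, n_sites)
    p = float(dist[caps])
    total = dist.sum()
    if total > 1.0 + 1e-9:
        raise ValueError(f"probability mass {total} exceeds 1: numerical failure")
    return p


def pattern_probability_marginal(
    model: DemographicModel, pinned: set[str], n_sites: int = 150
) -> float:
    """Probability that every class in ``pinned`` has zero mutations in a
    block, other classes free (their intensity is integrated out)."""
    if not pinned:
        return 1.0
    unknown = set(pinned) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes {unknown}")
    scale = [1.0 if c in pinned else 0.0 for c in CLASSES]
    dist = block_count_distribution(model, (0, 0, 0, 0), n_sites, lam_scale=scale)
    return float(dist[0, 0, 0, 0])


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def simulate_branch_lengths(
    model: DemographicModel, rng: np.random.Generator
) -> dict[str, float]:
    """One Gillespie draw of the genealogy; total branch length per class."""
    lengths = dict.fromkeys(CLASSES, 0.0)
    lineages = [
        (frozenset({"a1"}), "A"),
        (frozenset({"a2"}), "A"),
        (frozenset({"b1"}), "B"),
        (frozenset({"b2"}), "B"),
    ]
    t = 0.0

    def accrue(dt):
        for lab, _pop in lineages:
            if lab != LABELS:
                lengths[branch_class_of(lab)] += dt

    # structured phase [0, T)
    recipient, donor = model.recipient, model.donor
    while len(lineages) > 1 and t < model.T:
        events = []
        for i, j in combinations(range(len(lineages)), 2):
            if lineages[i][1] == lineages[j][1]:
                events.append(("coal", i, j, 1.0 / model.population_size(lineages[i][1])))
        if model.M > 0:
            for i, (lab, pop) in enumerate(lineages):
                if pop == recipient:
                    events.append(("mig", i, None, model.M / 2.0))
        total = sum(e[3] for e in events)
        if total == 0.0:
            accrue(model.T - t)
            t = model.T
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= model.T:
            accrue(model.T - t)
            t = model.T
            break
        accrue(dt)
        t += dt
        u = rng.uniform(0, total)
        for kind, i, j, rate in events:
            u -= rate
            if u <= 0:
                break
        if kind == "coal":
            merged = (lineages[i][0] | lineages[j][0], lineages[i][1])
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(merged)
        else:
            lineages[i] = (lineages[i][0], donor)
    # ancestral panmictic phase
    lineages = [(lab, "ANC") for lab, _pop in lineages]
    while len(lineages) > 1:
        n = len(lineages)
        total = n * (n - 1) / 2.0
        accrue(rng.exponential(1.0 / total))
        i, j = map(int, rng.choice(n, size=2, replace=False))
        merged = (lineages[i][0] | lineages[j][0], "ANC")
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lengths


def simulate_block(
    model: DemographicModel, n_sites: int, rng: np.random.Generator
) -> SiteClassCounts:
    """Simulate one block: genealogy draw + Poisson mutation counts."""
    lengths = simulate_branch_lengths(model, rng)
    lam = n_sites * model.theta / 2.0
    return SiteClassCounts(
        *(int(rng.poisson(lam * lengths[c])) for c in CLASSES)
    )
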