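"""Enhanced greedy political optimization (EGPO) for wrapper feature selection.

Candidate solutions ("policies") are continuous positions in [0,1]^F,
thresholded at 0.5 into binary feature masks. The population is organized
into ``n_parties`` parties of ``b_members`` members; the member holding
seat j of every party forms constituency j. Fitness is

    alpha * (1 - balanced accuracy of a surrogate classifier under
             3-fold stratified cross-validation on the selected columns)
    + (1 - alpha) * |mask| / F,

so lower is better and the second term exerts explicit dimensionality
pressure. The surrogate is a seeded nearest-centroid classifier on
standardized selected features: cheap, deterministic and tuning-free.

One iteration applies, in order: the recent-past position update rule
(RPPUS) pulling members toward a blend of their party leader and
constituency winner; stochastic party switching at the linearly decaying
rate lambda(s) = (1 - s/S) * lambda_max toward the currently best party;
re-evaluation and leader/constituency updates; elite preservation (the
best-ever policy overwrites the current worst member, making the best
fitness history non-increasing); adaptive coalition restructuring of the
worst party around the best leader after ``stagnation_window`` elite-flat
iterations; and periodic greedy single-bit-flip refinement of the elite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EGPOConfig", "PolicyVector", "Population", "SelectionResult",
    "evaluate_fitness", "nearest_centroid_cv", "rppus_update",
    "switching_rate", "party_switch", "greedy_refine",
    "coalition_restructure", "elite_preserve", "run_egpo",
    "mask_from_position",
]


@dataclass
class EGPOConfig:
    n_parties: int = 10
    b_members: int = 5
    iterations: int = 100
    lambda_max: float = 0.5
    alpha: float = 0.9
    threshold: float = 0.5
    stagnation_window: int = 10
    greedy_budget: int | None = None     # default 2F, resolved at run time
    refine_every: int = 10
    surrogate_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_parties * self.b_members < 4:
            raise ValueError("population must hold at least 4 members")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class PolicyVector:
    position: np.ndarray
    prev_position: np.ndarray
    mask: np.ndarray
    fitness: float
    party_id: int
    member_id: int


@dataclass
class Population:
    parties: list[list[PolicyVector]]
    elite: PolicyVector | None = None
    iteration: int = 0

    def members(self):
        for party in self.parties:
            yield from party

    def leader(self, party_id: int) -> PolicyVector:
        """Party best; ties broken by lowest (party_id, member_id)."""
        return min(self.parties[party_id],
                   key=lambda m: (m.fitness, m.party_id, m.member_id))

    def constituency_winner(self, seat: int) -> PolicyVector:
        """Best member across parties holding the given seat."""
        contenders = [party[seat] for party in self.parties]
        return min(contenders, key=lambda m: (m.fitness, m.party_id, m.member_id))

    def best(self) -> PolicyVector:
        return min(self.members(), key=lambda m: (m.fitness, m.party_id, m.member_id))

    def worst(self) -> PolicyVector:
        return max(self.members(), key=lambda m: (m.fitness, -m.party_id, -m.member_id))


@dataclass
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    history: list[float]
    selected_groups: list[str] = field(default_factory=list)
    n_evaluations: int = 0

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.best_mask)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def mask_from_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask with empty-mask repair (highest position flipped on)."""
    mask = position > threshold
    if not mask.any():
        mask = mask.copy()
        mask[int(np.argmax(position))] = True
    return mask


def _stratified_fold_ids(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xCF]))
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        folds[idx] = np.arange(idx.size) % k
    return folds


def nearest_centroid_cv(X: np.ndarray, y: np.ndarray, k: int = 3,
                        seed: int = 0) -> float:
    """Balanced accuracy of a nearest-centroid classifier under k-fold CV.

    Features are standardized with training-fold statistics; prediction is
    the class with the nearest (Euclidean) training centroid. Balanced
    accuracy is the macro average of per-class recall.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("surrogate needs at least two classes")
    folds = _stratified_fold_ids(y, k, seed)
    recall_num = np.zeros(classes.size)
    recall_den = np.zeros(classes.size)
    for f in range(k):
        train, test = folds != f, folds == f
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd < 1e-12] = 1e-12
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        centroids = np.stack([Xtr[y[train] == c].mean(axis=0) for c in classes])
        d2 = ((Xte[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = classes[np.argmin(d2, axis=1)]
        for ci, c in enumerate(classes):
            sel = y[test] == c
            recall_num[ci] += np.sum(pred[sel] == c)
            recall_den[ci] += np.sum(sel)
    return float(np.mean(recall_num / np.maximum(recall_den, 1)))


def evaluate_fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
                     cfg: EGPOConfig) -> float:
    """Wrapper fitness: alpha * surrogate error + (1-alpha) * mask ratio."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one feature (repair first)")
    balacc = nearest_centroid_cv(X[:, mask], y, k=cfg.surrogate_folds,
                                 seed=cfg.seed)
    size_ratio = mask.sum() / mask.size
    return cfg.alpha * (1.0 - balacc) + (1.0 - cfg.alpha) * size_ratio


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def rppus_update(prev_position: np.ndarray, position: np.ndarray,
                 a_star: np.ndarray, R: float) -> np.ndarray:
    """Recent-past position update rule, applied coordinate-wise.

    With x(s-1) the previous position, x(s) the current one and a* the
    attractor (leader/winner blend), the three cases are:

    1. x(s) between x(s-1) and a*          -> a* + (2R-1)|a* - x(s)|
    2. a* between x(s-1) and x(s)          -> x(s-1) + R (x(s) - x(s-1))
    3. x(s-1) between a* and x(s),
       with a* outermost                   -> a* + (2R-1)|a* - x(s-1)|

    Exact ties resolve to the first matching case (case 1 first). The
    result is clamped to [0, 1].
    """
    xp, xc, a = np.broadcast_arrays(prev_position, position, a_star)
    case1 = ((xp <= xc) & (xc <= a)) | ((xp >= xc) & (xc >= a))
    case2 = ((xp <= a) & (a <= xc)) | ((xp >= a) & (a >= xc))
    new = np.select(
        [case1, case2],
        [a + (2 * R - 1) * np.abs(a - xc), xp + R * (xc - xp)],
        default=a + (2 * R - 1) * np.abs(a - xp),
    )
    return np.clip(new, 0.0, 1.0)


def switching_rate(s: int, S: int, lambda_max: float) -> float:
    """Linearly decaying party-switching rate lambda(s) = (1 - s/S) lambda_max."""
    return (1.0 - s / S) * lambda_max


def party_switch(pop: Population, lam: float, rng: np.random.Generator) -> int:
    """Members defect to the best leader's party with probability ``lam``.

    A defector swaps seats with the worst member of the target party, so
    party sizes are preserved. Returns the number of switches drawn.
    """
    if lam <= 0:
        return 0
    best_party = min(range(len(pop.parties)),
                     key=lambda p: (pop.leader(p).fitness, p))
    n_switches = 0
    for party in pop.parties:
        for member in party:
            if rng.uniform() < lam:
                n_switches += 1
                target = pop.parties[best_party]
                worst = max(range(len(target)),
                            key=lambda i: (target[i].fitness, i))
                other = target[worst]
                if other is member:
                    continue
                # swap seats (and the party/seat bookkeeping)
                p_a, m_a = member.party_id, member.member_id
                p_b, m_b = other.party_id, other.member_id
                pop.parties[p_a][m_a], pop.parties[p_b][m_b] = other, member
                member.party_id, member.member_id = p_b, m_b
                other.party_id, other.member_id = p_a, m_a
    return n_switches


def greedy_refine(best: PolicyVector, X: np.ndarray, y: np.ndarray,
                  cfg: EGPOConfig, budget: int | None = None,
                  _cache: dict | None = None) -> PolicyVector:
    """First-improvement single-bit-flip hill climbing on the mask.

    Scans bits in index order, flips one, re-evaluates, keeps the flip on
    strict improvement and restarts the scan; stops after ``budget``
    evaluations or a full scan without improvement. The returned fitness
    never exceeds the input fitness.
    """
    F = best.mask.size
    budget = (2 * F if cfg.greedy_budget is None else cfg.greedy_budget) \
        if budget is None else budget
    cache = _cache if _cache is not None else {}

    def fit(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(mask, X, y, cfg)
        return cache[key]

    mask = best.mask.copy()
    fitness = best.fitness
    evals = 0
    improved = True
    while improved and evals < budget:
        improved = False
        for j in range(F):
            if evals >= budget:
                break
            cand = mask.copy()
            cand[j] = ~cand[j]
            if not cand.any():
                continue
            evals += 1
            f = fit(cand)
            if f < fitness:
                mask, fitness = cand, f
                improved = True
                break
    position = best.position.copy()
    position[mask] = np.maximum(position[mask], 0.5 + 1e-6)
    position[~mask] = np.minimum(position[~mask], 0.5 - 1e-6)
    return PolicyVector(position=position, prev_position=best.prev_position.copy(),
                        mask=mask, fitness=fitness, party_id=best.party_id,
                        member_id=best.member_id)


def coalition_restructure(pop: Population, stagnation: int, window: int,
                          rng: np.random.Generator, sigma: float = 0.1) -> bool:
    """Re-seed the worst party around the best leader after stagnation.

    If the elite has not improved for ``window`` iterations, every member
    of the party with the worst leader is re-sampled at the best party's
    leader position plus Normal(0, sigma) noise, clamped to [0, 1].
    Returns whether a restructuring happened.
    """
    if stagnation < window:
        return False
    order = sorted(range(len(pop.parties)),
                   key=lambda p: (pop.leader(p).fitness, p))
    best_leader = pop.leader(order[0])
    worst_party = order[-1]
    for member in pop.parties[worst_party]:
        member.prev_position = member.position.copy()
        member.position = np.clip(
            best_leader.position + sigma * rng.standard_normal(member.position.size),
            0.0, 1.0)
        member.fitness = np.inf  # stale, re-evaluated by the caller
    return True


def elite_preserve(pop: Population) -> None:
    """Overwrite the current worst member with the archived global best."""
    if pop.elite is None:
        return
    worst = pop.worst()
    worst.position = pop.elite.position.copy()
    worst.prev_position = pop.elite.prev_position.copy()
    worst.mask = pop.elite.mask.copy()
    worst.fitness = pop.elite.fitness


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_egpo(X: np.ndarray, y: np.ndarray, cfg: EGPOConfig | None = None,
             group_map: dict[str, tuple[int, int]] | None = None
             ) -> SelectionResult:
    """Full EGPO feature-selection run; deterministic given ``cfg.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cfg = cfg or EGPOConfig()
    F = X.shape[1]
    if F < 2:
        raise ValueError("need at least two features to select from")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xE690]))
    cache: dict[bytes, float] = {}
    n_evals = 0

    def fit(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = mask.tobytes()
        if key not in cache:
            n_evals += 1
            cache[key] = evaluate_fitness(mask, X, y, cfg)
        return cache[key]

    # init population
    parties = []
    for p in range(cfg.n_parties):
        party = []
        for m in range(cfg.b_members):
            pos = rng.uniform(size=F)
            mask = mask_from_position(pos, cfg.threshold)
            party.append(PolicyVector(position=pos, prev_position=pos.copy(),
                                      mask=mask, fitness=fit(mask),
                                      party_id=p, member_id=m))
        parties.append(party)
    pop = Population(parties=parties)
    best = pop.best()
    pop.elite = PolicyVector(position=best.position.copy(),
                             prev_position=best.prev_position.copy(),
                             mask=best.mask.copy(), fitness=best.fitness,
                             party_id=best.party_id, member_id=best.member_id)
    history = [pop.elite.fitness]
    stagnation = 0

    for s in range(1, cfg.iterations + 1):
        pop.iteration = s
        # RPPUS move toward leader/constituency-winner blend
        leaders = [pop.leader(p).position.copy() for p in range(len(pop.parties))]
        winners = [pop.constituency_winner(m).position.copy()
                   for m in range(cfg.b_members)]
        for party in pop.parties:
            for member in party:
                a_star = 0.5 * (leaders[member.party_id] + winners[member.member_id])
                R = rng.uniform()
                new_pos = rppus_update(member.prev_position, member.position,
                                       a_star, R)
                member.prev_position = member.position
                member.position = new_pos

        party_switch(pop, switching_rate(s, cfg.iterations, cfg.lambda_max), rng)

        for member in pop.members():
            member.mask = mask_from_position(member.position, cfg.threshold)
            member.fitness = fit(member.mask)

        best = pop.best()
        if best.fitness < pop.elite.fitness:
            pop.elite = PolicyVector(position=best.position.copy(),
                                     prev_position=best.prev_position.copy(),
                                     mask=best.mask.copy(), fitness=best.fitness,
                                     party_id=best.party_id,
                                     member_id=best.member_id)
            stagnation = 0
        else:
            stagnation += 1

        elite_preserve(pop)
        if coalition_restructure(pop, stagnation, cfg.stagnation_window, rng):
            stagnation = 0
            for member in pop.members():
                if not np.isfinite(member.fitness):
                    member.mask = mask_from_position(member.position, cfg.threshold)
                    member.fitness = fit(member.mask)

        if s % cfg.refine_every == 0 or s == cfg.iterations:
            refined = greedy_refine(pop.elite, X, y, cfg, _cache=cache)
            n_evals = max(n_evals, len(cache))
            if refined.fitness < pop.elite.fitness:
                pop.elite = refined
                stagnation = 0
        history.append(pop.elite.fitness)

    selected_groups = []
    if group_map:
        idx = np.flatnonzero(pop.elite.mask)
        for name, (lo, hi) in group_map.items():
            if np.any((idx >= lo) & (idx < hi)):
                selected_groups.append(name)

    return SelectionResult(best_mask=pop.elite.mask.copy(),
                           best_fitness=pop.elite.fitness,
                           history=history, selected_groups=selected_groups,
                           n_evaluations=len(cache))
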