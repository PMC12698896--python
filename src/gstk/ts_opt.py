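"""Training-set optimization by genetic-algorithm subset search.

Given a genomic kernel over candidate strains, pick the fixed-size
training subset whose phenotyping would be most informative about a
target set (default: all non-training candidates).  Information is
measured from the mixed-model equations of

    y_T = 1 mu + u_T + e,   u ~ (0, sigma2_u K),  sigma2_u = 1,
    sigma2_e = lambda

where only the training subset is phenotyped.  Criteria:

* PEVMean / PEVMax — mean / max prediction error variance of the
  targets (minimized);
* CDMean — mean coefficient of determination
  ``CD_i = 1 - PEV_i / K_ii`` over targets (maximized).

The search is a genetic algorithm over fixed-size subsets with elitism,
union-subsample crossover, and member-swap mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import GenomicKernel

__all__ = ["TsOptConfig", "TsOptResult", "criterion_value", "pev_targets", "ga_select", "ts_opt_cv_compare"]

CRITERIA = ("PEVMean", "PEVMax", "CDMean")


@dataclass
class TsOptConfig:
    n_train: int
    criterion: str = "CDMean"
    targets: list[str] | None = None  # default: all non-train candidates
    lambda_: float = 1.0  # variance ratio; 1 corresponds to h2 = 0.5
    pop_size: int = 100
    elite: int = 5
    mutation_rate: float = 0.05
    max_generations: int = 200
    stall_limit: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.elite >= self.pop_size:
            raise ValueError("elite must be smaller than pop_size")


@dataclass
class TsOptResult:
    selected: list[str]
    criterion: str
    value: float  # criterion on its natural scale (CDMean: larger better)
    trace: np.ndarray  # best minimized objective per generation
    comparison: dict = field(default_factory=dict)


def pev_targets(
    k: np.ndarray, train: np.ndarray, targets: np.ndarray, lam: float
) -> np.ndarray:
    """PEV of target candidates when only ``train`` is phenotyped.

    Builds the Henderson coefficient matrix for intercept + genetic
    effect over all candidates (sigma2_u = 1, sigma2_e = lambda) and
    reads the target PEVs off the inverted random-effect block.
    A singular kernel gets a 1e-8 ridge jitter.
    """
    n = k.shape[0]
    z = np.zeros((len(train), n))
    z[np.arange(len(train)), train] = 1.0
    x = np.ones((len(train), 1))
    try:
        kinv = np.linalg.inv(k)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular kernel; applying 1e-8 ridge jitter", stacklevel=2)
        kinv = np.linalg.inv(k + 1e-8 * np.eye(n))
    coeff = np.block([[x.T @ x, x.T @ z], [z.T @ x, z.T @ z + lam * kinv]])
    try:
        cinv = np.linalg.inv(coeff)
    except np.linalg.LinAlgError:
        cinv = np.linalg.inv(coeff + 1e-8 * np.eye(n + 1))
    pev = lam * np.diag(cinv)[1:]
    return pev[targets]


def criterion_value(
    k: GenomicKernel | np.ndarray,
    train: np.ndarray,
    targets: np.ndarray | None,
    criterion: str,
    lam: float = 1.0,
) -> float:
    """Evaluate one training subset (natural scale; CDMean larger-better)."""
    km = k.matrix if isinstance(k, GenomicKernel) else np.asarray(k, float)
    train = np.asarray(train, int)
    if train.size == 0:
        raise ValueError("training subset is empty")
    if targets is None:
        targets = np.setdiff1d(np.arange(km.shape[0]), train)
    targets = np.asarray(targets, int)
    pev = pev_targets(km, train, targets, lam)
    if criterion == "PEVMean":
        return float(np.mean(pev))
    if criterion == "PEVMax":
        return float(np.max(pev))
    if criterion == "CDMean":
        kdiag = np.diag(km)[targets]
        return float(np.mean(1.0 - pev / kdiag))
    raise ValueError(f"criterion must be one of {CRITERIA}")


def _objective(km, train, targets, criterion, lam) -> float:
    """Minimized form of the criterion (CDMean negated)."""
    v = criterion_value(km, train, targets, criterion, lam)
    return -v if criterion == "CDMean" else v


def ga_select(k: GenomicKernel | np.ndarray, cfg: TsOptConfig) -> TsOptResult:
    """Genetic-algorithm search for the best training subset.

    Population of random subsets; elitism keeps the top ``elite``
    verbatim; offspring take the union of two tournament-free random
    parents subsampled back to ``n_train``; each member then swaps with a
    random non-member at ``mutation_rate``.  Stops at ``max_generations``
    or after ``stall_limit`` generations without improvement.  The
    best-so-far trace is monotone by construction.
    """
    km = k.matrix if isinstance(k, GenomicKernel) else np.asarray(k, float)
    names = list(k.taxa) if isinstance(k, GenomicKernel) else [str(i) for i in range(len(km))]
    n = km.shape[0]
    if cfg.n_train >= n:
        raise ValueError("n_train must be smaller than the number of candidates")
    tgt = (
        np.asarray([names.index(t) for t in cfg.targets], int)
        if cfg.targets is not None
        else None
    )
    rng = np.random.default_rng(cfg.seed)

    def fitness(subset: np.ndarray) -> float:
        return _objective(km, subset, tgt, cfg.criterion, cfg.lambda_)

    pop = [np.sort(rng.choice(n, cfg.n_train, replace=False)) for _ in range(cfg.pop_size)]
    fits = np.array([fitness(s) for s in pop])
    best_val = np.inf
    best_sub = pop[int(np.argmin(fits))]
    trace = []
    stall = 0
    for gen in range(cfg.max_generations):
        order = np.argsort(fits)
        if fits[order[0]] < best_val - 1e-15:
            best_val = fits[order[0]]
            best_sub = pop[order[0]].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_val)
        if stall >= cfg.stall_limit:
            break
        elite = [pop[i].copy() for i in order[: cfg.elite]]
        children = []
        while len(children) < cfg.pop_size - cfg.elite:
            p1, p2 = rng.choice(cfg.pop_size, 2, replace=False)
            pool = np.union1d(pop[p1], pop[p2])
            child = rng.choice(pool, cfg.n_train, replace=False)
            # mutation: swap members for non-members
            outside = np.setdiff1d(np.arange(n), child)
            if outside.size:
                mutate = rng.random(cfg.n_train) < cfg.mutation_rate
                for pos in np.flatnonzero(mutate):
                    child[pos] = rng.choice(outside)
                    outside = np.setdiff1d(np.arange(n), child)
                    if outside.size == 0:
                        break
            children.append(np.sort(np.unique(child)))
            if len(children[-1]) < cfg.n_train:  # degenerate after mutation
                extra = rng.choice(
                    np.setdiff1d(np.arange(n), children[-1]),
                    cfg.n_train - len(children[-1]),
                    replace=False,
                )
                children[-1] = np.sort(np.concatenate([children[-1], extra]))
        pop = elite + children
        fits = np.array([fitness(s) for s in pop])
    value = criterion_value(km, best_sub, tgt, cfg.criterion, cfg.lambda_)
    return TsOptResult(
        selected=[names[i] for i in best_sub],
        criterion=cfg.criterion,
        value=value,
        trace=np.array(trace),
    )


def ts_opt_cv_compare(
    dataset,
    k: GenomicKernel,
    cfg: TsOptConfig,
    holdout_seed: int = 0,
) -> dict:
    """Compare GA-optimized vs random training sets by prediction PA.

    Fits single-trait G-BLUP with (a) the GA-selected subset and (b) a
    size-matched random subset, and reports the predictive ability of
    each on the common non-training candidates.  With fewer than 3
    common evaluation strains the PAs are flagged undefined.
    """
    from .cross_validation import gblup_fitter, run_cv  # noqa: F401 (adapter reuse)

    rec = dataset.records.reset_index(drop=True)
    strains = list(k.taxa)
    opt = ga_select(k, cfg)
    rng = np.random.default_rng(holdout_seed)
    rand_sub = sorted(rng.choice(len(strains), cfg.n_train, replace=False).tolist())
    rand_names = [strains[i] for i in rand_sub]

    common_eval = sorted(set(strains) - set(opt.selected) - set(rand_names))
    out = {"optimized_set": opt.selected, "random_set": rand_names}
    if len(common_eval) < 3:
        out.update({"pa_optimized": np.nan, "pa_random": np.nan, "undefined": True})
        return out

    def pa_with(train_names: list[str]) -> float:
        train_idx = np.flatnonzero(rec["strain"].isin(train_names))
        test_idx = np.flatnonzero(rec["strain"].isin(common_eval))
        fit = gblup_fitter(k)
        pred = fit(dataset, train_idx, test_idx)
        y = rec["value"].to_numpy(float)[test_idx]
        return float(np.corrcoef(y, pred)[0, 1])

    out["pa_optimized"] = pa_with(opt.selected)
    out["pa_random"] = pa_with(rand_names)
    out["undefined"] = False
    opt.comparison = out
    return out
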