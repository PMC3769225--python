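"""Conservation versus allostery: beta-binomial analysis of mutation counts.

From an aligned family of protein sequences, each position's minimum
mutation count n_i is estimated by nearest-neighbour parsimony: every
sequence is compared with its closest relative(s) (all ties included) and
the observed differences are tallied per position, giving N = sum_i n_i
total events. The per-position mutation probability is linked to the
position's allosteric contribution x_i (|change in K2/K1| under spring
loosening at that residue) through a logistic curve

    mu(x) = 1 / (1 + exp(-(b0 + b1*x + b2*x^2))),

and overdispersion among positions is absorbed by a beta-binomial with
variance mu(1-mu)*phi/(1+phi). Likelihood-ratio tests compare the full
model against b1 = b2 = 0 (no allostery effect, 2 df) and against the
binomial limit phi -> 0 (no overdispersion, 1 df); profile likelihood gives
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit, gammaln
from scipy.stats import binom, chi2

__all__ = [
    "SequenceFamily",
    "MutationProfile",
    "BetaBinomialFit",
    "pairwise_distance",
    "min_mutation_profile",
    "mutation_rate_link",
    "betabinomial_loglik",
    "fit_betabinomial",
    "lrt",
    "profile_ci",
    "read_fasta_family",
]

#: Below this, the beta-binomial is evaluated in its binomial limit.
BINOMIAL_LIMIT_PHI = 1e-10


@dataclass(frozen=True)
class SequenceFamily:
    """Aligned, equal-length protein sequences."""

    sequences: tuple
    ids: tuple

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids must be parallel")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class MutationProfile:
    """Total minimum mutation count N and its per-position split n_i."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, int)
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BetaBinomialFit:
    """Maximum-likelihood estimates under a given constraint set."""

    beta0: float
    beta1: float
    beta2: float
    phi: float
    loglik: float
    constraint: str  # "full" | "no_allostery" | "binomial"
    converged: bool = True

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.phi])


def pairwise_distance(a: str, b: str) -> int:
    """Hamming distance between aligned sequences (a gap is a difference)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_mutation_profile(family: SequenceFamily) -> MutationProfile:
    """Nearest-neighbour parsimony estimate of per-position mutation counts.

    For each sequence, the smallest Hamming distance to any other sequence
    is found; all sequences achieving that minimum are included, and every
    differing position of every such pair is counted. By construction the
    per-position counts sum to the total N.
    """
    seqs = family.sequences
    m = len(seqs)
    if m < 2:
        raise ValueError("family must contain at least two sequences")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(m, -1)
    counts = np.zeros(family.length, int)
    for p in range(m):
        diff = arr != arr[p]
        d = diff.sum(axis=1)
        d[p] = np.iinfo(d.dtype).max
        dmin = d.min()
        if dmin == 0:
            continue
        for q in np.flatnonzero(d == dmin):
            counts += diff[q]
    return MutationProfile(counts)


def mutation_rate_link(x, beta0: float, beta1: float, beta2: float):
    """Logistic mean mutation probability mu(x) in (0, 1)."""
    x = np.asarray(x, float)
    return expit(beta0 + beta1 * x + beta2 * x ** 2)


def _bb_logpmf(n, N, mu, phi):
    """Beta-binomial log-pmf with shapes a = mu/phi, b = (1-mu)/phi.

    This parameterization has mean N*mu and per-trial variance
    mu(1-mu)*phi/(1+phi), matching the stated overdispersion model.
    """
    a = mu / phi
    b = (1.0 - mu) / phi
    return (
        gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
        + gammaln(n + a) + gammaln(N - n + b) - gammaln(N + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def betabinomial_loglik(
    profile: MutationProfile,
    scores,
    beta0: float,
    beta1: float,
    beta2: float,
    phi: float,
) -> float:
    """Log-likelihood of per-position counts under the linked beta-binomial."""
    n = profile.counts
    N = profile.total
    if (n > N).any():
        raise ValueError("a position count exceeds the total")
    x = np.asarray(scores, float)
    if len(x) != len(n):
        raise ValueError("scores and counts must be parallel")
    mu = mutation_rate_link(x, beta0, beta1, beta2)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if phi < BINOMIAL_LIMIT_PHI:
        return float(binom.logpmf(n, N, mu).sum())
    return float(_bb_logpmf(n, N, mu, phi).sum())


def fit_betabinomial(
    profile: MutationProfile,
    scores,
    constraint: str = "full",
) -> BetaBinomialFit:
    """Maximum-likelihood fit, optionally constrained.

    constraint = "full"          : free {b0, b1, b2, phi}
                 "no_allostery"  : b1 = b2 = 0
                 "binomial"      : phi -> 0 (pure binomial)
    phi is optimized on a log scale; a small deterministic multistart grid
    makes the optimum reproducible.
    """
    n = profile.counts
    N = profile.total
    x = np.asarray(scores, float)
    p_hat = max(n.mean() / N, 1e-8)
    b0_init = float(np.log(p_hat / (1 - p_hat)))

    free_beta = constraint != "no_allostery"
    free_phi = constraint != "binomial"
    if constraint not in ("full", "no_allostery", "binomial"):
        raise ValueError(f"unknown constraint {constraint!r}")

    def unpack(t):
        i = 1
        b1 = b2 = 0.0
        if free_beta:
            b1, b2 = t[i], t[i + 1]
            i += 2
        phi = float(np.exp(t[i])) if free_phi else 0.0
        return t[0], b1, b2, phi

    def negll(t):
        b0, b1, b2, phi = unpack(t)
        try:
            return -betabinomial_loglik(profile, x, b0, b1, b2, phi)
        except (OverflowError, FloatingPointError):
            return 1e12

    starts = []
    for b1_0 in ([0.0] if not free_beta else [0.0, -2.0]):
        t = [b0_init]
        if free_beta:
            t += [b1_0, 0.0]
        if free_phi:
            t += [-4.0]
        starts.append(np.array(t))

    best = None
    for t0 in starts:
        sol = minimize(negll, t0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 3000})
        sol2 = minimize(negll, sol.x, method="BFGS",
                        options={"maxiter": 80, "gtol": 1e-6})
        cand = sol2 if sol2.fun <= sol.fun else sol
        if best is None or cand.fun < best.fun:
            best = cand
    b0, b1, b2, phi = unpack(best.x)
    return BetaBinomialFit(b0, b1, b2, phi, -float(best.fun), constraint,
                           converged=bool(best.success or best.fun < 1e11))


def lrt(full: BetaBinomialFit, reduced: BetaBinomialFit, df: int) -> tuple:
    """Likelihood-ratio test G = 2(LL_full - LL_reduced), chi-square with df."""
    G = 2.0 * (full.loglik - reduced.loglik)
    if G < -1e-6:
        raise ValueError(
            f"reduced model beats full model (G = {G:.3g}); optimization failure"
        )
    G = max(G, 0.0)
    return G, float(chi2.sf(G, df))


def profile_ci(
    profile: MutationProfile,
    scores,
    fit: BetaBinomialFit,
    parameter: str,
    level: float = 0.95,
    span: float = 12.0,
) -> tuple:
    """Profile-likelihood confidence interval for one full-model parameter.

    Each endpoint is the value at which the log-likelihood, re-maximized
    over the other parameters, drops chi2_1(level)/2 below the maximum;
    endpoints beyond ``span`` profile units are reported as open (inf).
    """
    if fit.constraint != "full":
        raise ValueError("profile CIs are defined for the full-model fit")
    names = ("beta0", "beta1", "beta2", "phi")
    if parameter not in names:
        raise ValueError(f"parameter must be one of {names}")
    drop = chi2.ppf(level, 1) / 2.0
    target = fit.loglik - drop
    mle = getattr(fit, parameter)
    x = np.asarray(scores, float)
    warm = {"t": np.array([fit.beta0, fit.beta1, fit.beta2,
                           np.log(max(fit.phi, 1e-8))])}

    def profiled_ll(value):
        def unpack(t):
            vals = {"beta0": t[0], "beta1": t[1], "beta2": t[2],
                    "phi": float(np.exp(t[3]))}
            vals[parameter] = value
            return vals

        def negll(t):
            v = unpack(t)
            try:
                return -betabinomial_loglik(profile, x, v["beta0"], v["beta1"],
                                            v["beta2"], v["phi"])
            except (ValueError, OverflowError, FloatingPointError):
                return 1e12

        sol = minimize(negll, warm["t"], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
        warm["t"] = sol.x
        return -float(sol.fun)

    scale = max(abs(mle), 0.5)
    t_mle = warm["t"].copy()
    lo = hi = None
    for sign in (-1, 1):
        warm["t"] = t_mle.copy()
        step = 0.25 * scale
        bound = None
        prev = mle
        cur = mle
        while abs(cur - mle) < span * scale:
            cur = cur + sign * step
            if parameter == "phi" and cur <= 0:
                bound = 0.0
                break
            if profiled_ll(cur) < target:
                bound = brentq(lambda v: profiled_ll(v) - target, *sorted((prev, cur)),
                               xtol=1e-4 * scale)
                break
            prev = cur
            step *= 1.6
        if bound is None:
            bound = -np.inf if sign < 0 else np.inf
        if sign < 0:
            lo = bound
        else:
            hi = bound
    return lo, hi


def read_fasta_family(path) -> SequenceFamily:
    """Read an aligned FASTA file into a SequenceFamily."""
    ids, seqs = [], []
    cur = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            elif line:
                cur.append(line)
    if cur:
        seqs.append("".join(cur))
    return SequenceFamily(tuple(seqs), tuple(ids))
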