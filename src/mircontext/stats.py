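"""Statistical core: expression breadth, bespoke randomization nulls,
cross-species divergence, correlation comparison and exact tests.

The two bespoke procedures are

* a constrained resampling null for host-gene ages: for each miRNA of branch
  age a, a gene is drawn from the pool restricted to genes just as old or
  older (branch <= a), and the fraction of oldest-branch genes across the set
  is recorded; the observed old-host fraction is compared against that null;
* a tissue rank-order permutation test of miRNA-host co-expression: tissues
  are ranked by expression in the miRNA and, independently, in the host, and
  the statistic is the fraction of rank positions occupied by the same tissue;
  the null shuffles the miRNA's tissue labels.

Empirical P values use the add-one rule (k+1)/(N+1) and can therefore never
be 0. Because permutation statistics are discrete, results also carry the
standard randomized p-value (exactly Uniform(0,1) under the null), used to
assess calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .intervals import ValidationError

OLD_BRANCH = 1  # the most ancient branch; "old" genes/hosts sit on it


# ---------------------------------------------------------------------------
# expression breadth


@dataclass(frozen=True)
class TauResult:
    entity_id: str
    tau: float
    n_tissues: int


def tau(values: Sequence[float], entity_id: str = "") -> TauResult:
    """Tissue-specificity index on log-transformed c.p.m. values.

    With x_i = log2(v_i + 1) and xhat_i = x_i / max_j x_j,
    tau = sum(1 - xhat_i) / (N - 1); 0 means uniformly broad expression, 1
    single-tissue expression. Undefined (error) for all-zero profiles or
    fewer than two tissues.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("tau needs a 1-d profile over >= 2 tissues")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValidationError("tau needs finite non-negative values")
    x = np.log2(v + 1.0)
    m = x.max()
    if m <= 0:
        raise ValidationError(f"tau undefined for all-zero profile ({entity_id or 'unnamed'})")
    xhat = x / m
    t = float(np.sum(1.0 - xhat) / (v.size - 1))
    return TauResult(entity_id=entity_id, tau=t, n_tissues=int(v.size))


def breadth_count(values: Sequence[float], threshold_cpm: float = 1.0) -> int:
    """Number of tissues with expression >= threshold (inclusive)."""
    if threshold_cpm <= 0:
        raise ValidationError("threshold_cpm must be > 0")
    v = np.asarray(values, dtype=float)
    return int(np.sum(v >= threshold_cpm))


# ---------------------------------------------------------------------------
# randomization machinery


@dataclass
class RandomizationResult:
    """Observed statistic, its permutation/resampling null and empirical P.

    ``empirical_p`` is (#{null >= observed} + 1)/(n_draws + 1).
    ``randomized_p`` is (#{null > observed} + V*(#{null = observed} + 1)) /
    (n_draws + 1) with V ~ Uniform(0,1) — exactly uniform under the null for
    discrete statistics, kept for calibration checks.
    """

    observed_statistic: float
    null_values: np.ndarray
    empirical_p: float
    n_draws: int
    seed: Optional[int] = None
    randomized_p: Optional[float] = None
    chi2_stat: Optional[float] = None
    chi2_p: Optional[float] = None

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size != self.n_draws:
            raise ValidationError("null_values length must equal n_draws")
        if not 0.0 < self.empirical_p <= 1.0:
            raise ValidationError("empirical_p must lie in (0, 1]")


def _empirical_p(null: np.ndarray, observed: float) -> float:
    return (int(np.sum(null >= observed)) + 1) / (null.size + 1)


def _randomized_p(null: np.ndarray, observed: float, rng: np.random.Generator) -> float:
    greater = int(np.sum(null > observed))
    equal = int(np.sum(null == observed))
    return (greater + float(rng.random()) * (equal + 1)) / (null.size + 1)


def host_age_randomization(
    host_ages: Sequence[int],
    mirna_ages: Sequence[int],
    pool_ages: Sequence[int],
    n_draws: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    old_branch: int = OLD_BRANCH,
) -> RandomizationResult:
    """Constrained resampling test of old-host excess.

    For each of the n miRNAs (branch age a_i) a draw samples, independently
    and with replacement, one gene from the pool restricted to branch ages
    <= a_i, and records the fraction of branch-``old_branch`` genes among the
    n sampled. The observed statistic is the fraction of actual hosts on
    ``old_branch``. Also reports a 1-df chi-squared test of the observed
    old-host count against the expected count implied by the null mean.
    """
    rng = rng if rng is not None else np.random.default_rng()
    host = np.asarray(host_ages, dtype=int)
    mirna = np.asarray(mirna_ages, dtype=int)
    pool = np.asarray(pool_ages, dtype=int)
    if host.size != mirna.size or host.size == 0:
        raise ValidationError("host_ages and mirna_ages must be non-empty and aligned")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")

    n = host.size
    observed = float(np.mean(host == old_branch))

    # per distinct miRNA age: eligible-pool size and old-gene count
    old_count_total = np.zeros(n_draws, dtype=np.int64)
    for a in np.unique(mirna):
        eligible = pool[pool <= a]
        m = eligible.size
        if m == 0:
            raise ValidationError(f"no pool gene as old or older than miRNA age {a}")
        k = int(np.sum(eligible == old_branch))
        c = int(np.sum(mirna == a))
        # uniform gene draws from the eligible pool, old genes first
        u = rng.integers(0, m, size=(n_draws, c))
        old_count_total += (u < k).sum(axis=1)
    null = old_count_total / n

    emp = _empirical_p(null, observed)
    rand_p = _randomized_p(null, observed, rng)

    exp_frac = float(null.mean())
    chi2_stat = chi2_p = None
    exp_old = exp_frac * n
    if 0 < exp_old < n:
        chi2 = sps.chisquare(
            [observed * n, n - observed * n], f_exp=[exp_old, n - exp_old]
        )
        chi2_stat, chi2_p = float(chi2.statistic), float(chi2.pvalue)
    return RandomizationResult(
        observed_statistic=observed,
        null_values=null,
        empirical_p=emp,
        n_draws=n_draws,
        randomized_p=rand_p,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
    )


RANK_MATCH = "rank-match"
EXPRESSED_RANK_MATCH = "expressed-rank-match"


def _rank_order(values: np.ndarray) -> np.ndarray:
    """Tissue indices sorted by descending value; ties keep fixed tissue order."""
    return np.argsort(-values, axis=-1, kind="stable")


def rank_match_statistic(
    mirna_values: Sequence[float],
    host_values: Sequence[float],
    method: str = RANK_MATCH,
    threshold_cpm: float = 1.0,
) -> float:
    """Fraction of rank positions occupied by the same tissue in both
    orderings (descending expression).

    ``expressed-rank-match`` restricts the count to rank positions where the
    miRNA is expressed (>= threshold) and divides by the number of expressed
    tissues.
    """
    m = np.asarray(mirna_values, dtype=float)
    h = np.asarray(host_values, dtype=float)
    if m.shape != h.shape or m.ndim != 1 or m.size < 3:
        raise ValidationError("profiles must align over >= 3 tissues")
    if np.all(m == m[0]) or np.all(h == h[0]):
        raise ValidationError("constant profile: tissue ordering undefined")
    om, oh = _rank_order(m), _rank_order(h)
    match = om == oh
    if method == RANK_MATCH:
        return float(np.mean(match))
    if method == EXPRESSED_RANK_MATCH:
        expressed = m[om] >= threshold_cpm
        if not expressed.any():
            raise ValidationError("no expressed tissue under the cutoff")
        return float(np.sum(match & expressed) / np.sum(expressed))
    raise ValidationError(f"unknown method {method!r}")


def coexpression_randomization(
    mirna_values: Sequence[float],
    host_values: Sequence[float],
    n_shuffles: int = 3_000,
    rng: Optional[np.random.Generator] = None,
    method: str = RANK_MATCH,
    threshold_cpm: float = 1.0,
) -> RandomizationResult:
    """Permutation test of miRNA-host tissue rank-order agreement.

    The null shuffles the miRNA's tissue labels ``n_shuffles`` times and
    recomputes the rank-match statistic against the fixed host ordering.
    """
    rng = rng if rng is not None else np.random.default_rng()
    m = np.asarray(mirna_values, dtype=float)
    observed = rank_match_statistic(m, host_values, method, threshold_cpm)
    perms = np.array([rng.permutation(m.size) for _ in range(n_shuffles)])
    shuffled = m[perms]  # (n_shuffles, T)
    h = np.asarray(host_values, dtype=float)
    oh = _rank_order(h)
    om = _rank_order(shuffled)
    match = om == oh[None, :]
    if method == RANK_MATCH:
        null = match.mean(axis=1)
    else:
        expressed = np.take_along_axis(shuffled, om, axis=1) >= threshold_cpm
        denom = expressed.sum(axis=1)
        if np.any(denom == 0):
            raise ValidationError("shuffle produced no expressed tissue")
        null = (match & expressed).sum(axis=1) / denom
    return RandomizationResult(
        observed_statistic=observed,
        null_values=null,
        empirical_p=_empirical_p(null, observed),
        n_draws=n_shuffles,
        randomized_p=_randomized_p(null, observed, rng),
    )


def coexpression_randomization_group(
    pairs: Sequence[Tuple[Sequence[float], Sequence[float]]],
    n_shuffles: int = 3_000,
    rng: Optional[np.random.Generator] = None,
) -> RandomizationResult:
    """Group-level co-expression test: the observed statistic is the average
    rank-match proportion over pairs, the null shuffles every miRNA's tissue
    labels independently in each draw."""
    rng = rng if rng is not None else np.random.default_rng()
    if not pairs:
        raise ValidationError("no pairs")
    ms = np.array([np.asarray(m, dtype=float) for m, _ in pairs])
    hs = np.array([np.asarray(h, dtype=float) for _, h in pairs])
    observed = float(
        np.mean([rank_match_statistic(m, h) for m, h in zip(ms, hs)])
    )
    oh = _rank_order(hs)  # (P, T)
    null = np.empty(n_shuffles)
    n_p, n_t = ms.shape
    for i in range(n_shuffles):
        perms = np.argsort(rng.random((n_p, n_t)), axis=1)
        om = _rank_order(np.take_along_axis(ms, perms, axis=1))
        null[i] = float((om == oh).mean())
    return RandomizationResult(
        observed_statistic=observed,
        null_values=null,
        empirical_p=_empirical_p(null, observed),
        n_draws=n_shuffles,
        randomized_p=_randomized_p(null, observed, rng),
    )


# ---------------------------------------------------------------------------
# cross-species expression divergence


@dataclass(frozen=True)
class DivergenceResult:
    mirna_id: str
    species_pair: Tuple[str, str]
    euclidean_distance: Optional[float]
    tissues: Tuple[str, ...]
    excluded: bool = False


def expression_divergence(
    profile_a: pd.Series,
    profile_b: pd.Series,
    min_cpm: float = 1.0,
    mirna_id: str = "",
    species_pair: Tuple[str, str] = ("a", "b"),
) -> DivergenceResult:
    """Euclidean distance between log2(v+1) tissue profiles of an ortholog
    pair; the pair is excluded unless each side reaches ``min_cpm`` in at
    least one tissue."""
    if list(profile_a.index) != list(profile_b.index):
        raise ValidationError("tissue panels differ between profiles")
    a = profile_a.to_numpy(dtype=float)
    b = profile_b.to_numpy(dtype=float)
    tissues = tuple(profile_a.index)
    if a.max() < min_cpm or b.max() < min_cpm:
        return DivergenceResult(mirna_id, species_pair, None, tissues, excluded=True)
    d = float(np.linalg.norm(np.log2(a + 1.0) - np.log2(b + 1.0)))
    return DivergenceResult(mirna_id, species_pair, d, tissues)


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    one_tailed_p: float


def correlate(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with midrank ties."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("correlate needs aligned samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("correlate needs finite values")
    res = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), n=int(x.size), p=float(res.pvalue))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher z comparison of two independent correlation coefficients.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); the one-tailed P
    is the standard normal upper tail of z (testing r1 > r2).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("compare_correlations needs n > 3 in both groups")
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValidationError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return CorrelationComparison(
        r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), one_tailed_p=float(sps.norm.sf(z))
    )


# ---------------------------------------------------------------------------
# exact tests


@dataclass(frozen=True)
class EnrichmentResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p: float
    undefined: bool = False


_FISHER_REL_TOL = 1.0 + 1e-7


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, n_success: int, n_draws: int) -> np.ndarray:
    return (
        gammaln(n_success + 1)
        - gammaln(k + 1)
        - gammaln(n_success - k + 1)
        + gammaln(n_total - n_success + 1)
        - gammaln(n_draws - k + 1)
        - gammaln(n_total - n_success - n_draws + k + 1)
        - gammaln(n_total + 1)
        + gammaln(n_draws + 1)
        + gammaln(n_total - n_draws + 1)
    )


def fisher_exact_p(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Exact conditional P for a 2x2 table [[a, b], [c, d]].

    Two-sided: the sum of hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (small-mass rule). One-sided ``greater``/``less`` are tails in a.
    """
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, n_total, col1, row1)
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()  # guard accumulated rounding
    obs = pmf[a - lo]
    if alternative == "two-sided":
        return float(min(1.0, pmf[pmf <= obs * _FISHER_REL_TOL].sum()))
    if alternative == "greater":
        return float(min(1.0, pmf[support >= a].sum()))
    if alternative == "less":
        return float(min(1.0, pmf[support <= a].sum()))
    raise ValidationError(f"unknown alternative {alternative!r}")


def enrichment_fisher(
    table: Sequence[Sequence[int]], alternative: str = "two-sided"
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 contingency table.

    The odds ratio is the sample odds ratio ad/bc (inf when bc = 0 and
    ad > 0). A zero row or column margin makes the test undefined: the result
    is flagged and carries p = 1, OR = nan.
    """
    (a, b), (c, d) = ((int(table[0][0]), int(table[0][1])), (int(table[1][0]), int(table[1][1])))
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative integers")
    t = ((a, b), (c, d))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return EnrichmentResult(table=t, odds_ratio=float("nan"), p=1.0, undefined=True)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(table=t, odds_ratio=odds, p=fisher_exact_p(a, b, c, d, alternative))


def kaks_compare(
    host_values: Sequence[float], nonhost_values: Sequence[float]
) -> Tuple[float, float]:
    """Two-sample KS test of Ka/Ks distributions after discarding ratios > 1."""
    h = np.asarray(host_values, dtype=float)
    n = np.asarray(nonhost_values, dtype=float)
    h = h[h <= 1.0]
    n = n[n <= 1.0]
    if h.size < 2 or n.size < 2:
        raise ValidationError("need >= 2 retained Ka/Ks values per group")
    res = sps.ks_2samp(h, n)
    return float(res.statistic), float(res.pvalue)


TARGET_SITE_TYPES = ("7mer-m8", "8mer")
KNOWN_SITE_TYPES = ("6mer", "7mer-1a", "7mer-m8", "8mer")
TARGET_CONTEXT_SCORE_MAX = -0.25


def target_counts(
    predictions: pd.DataFrame,
    site_types: Sequence[str] = TARGET_SITE_TYPES,
    context_score_max: float = TARGET_CONTEXT_SCORE_MAX,
) -> pd.Series:
    """Distinct predicted target genes per miRNA after site-type and
    context-score filtering.

    Rows are kept iff ``site_type`` is one of ``site_types`` (default 7mer-m8
    and 8mer) and ``context_score < context_score_max``. Unknown site types
    raise a warning and are excluded.
    """
    required = {"mirna_id", "gene_id", "site_type", "context_score"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValidationError(f"prediction table missing columns {sorted(missing)}")
    unknown = set(predictions["site_type"].unique()) - set(KNOWN_SITE_TYPES)
    if unknown:
        warnings.warn(f"unknown site types excluded: {sorted(unknown)}", stacklevel=2)
    kept = predictions[
        predictions["site_type"].isin(site_types)
        & (predictions["context_score"] < context_score_max)
    ]
    return kept.groupby("mirna_id")["gene_id"].nunique()


def mannwhitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U (plumbing wrapper)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
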