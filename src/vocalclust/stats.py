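"""Resampling statistics for vocal-repertoire comparisons.

All procedures are exact-style resampling tests with a fixed seed and
10,000 draws by default:

* independent mean differences — both groups are pooled; null groups of the
  observed sizes are redrawn from the pool with replacement; the two-sided
  p-value counts null mean differences at least as extreme as the observed
  one (and its inverse);
* paired differences — the signs of the observed pairwise differences are
  flipped at random to simulate the null of no systematic direction;
* one-way resampling ANOVA — the classical F statistic under label
  permutation, with Bonferroni-corrected pairwise post-hoc tests;
* repertoire difference — a per-call-type over/under-representation test: a
  resampling pool built from the reference genotype's median counts is
  drawn at the test genotype's total call count; a call type is flagged
  when the test animals' mean count +/- SEM falls entirely outside the 95%
  confidence interval of the resampled counts;
* repertoire correlation — within/between-genotype mean Pearson
  correlations of per-animal call-count vectors, with a resampling test on
  the within-group correlation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResamplingResult",
    "RepertoireTable",
    "resample_independent",
    "resample_paired",
    "resample_anova",
    "repertoire_difference",
    "repertoire_correlation",
]

DEFAULT_DRAWS = 10_000


@dataclass
class ResamplingResult:
    """Observed statistic, two-sided resampling p, and reproducibility info."""

    observed: float
    n_draws: int
    p: float
    seed: int
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


def _two_sided_p(null: np.ndarray, observed: float, smooth: bool = False) -> float:
    """#{|null| >= |observed|} / n_draws; optional (k+1)/(n+1) smoothing."""
    k = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
    if smooth:
        return (k + 1) / (len(null) + 1)
    return k / len(null)


def resample_independent(
    x,
    y,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    smooth: bool = False,
) -> ResamplingResult:
    """Resampling test of the difference in means of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    observed = float(x.mean() - y.mean())
    pool = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    xs = rng.choice(pool, size=(n_draws, len(x)), replace=True).mean(axis=1)
    ys = rng.choice(pool, size=(n_draws, len(y)), replace=True).mean(axis=1)
    null = xs - ys
    return ResamplingResult(
        observed, n_draws, _two_sided_p(null, observed, smooth), seed
    )


def resample_paired(
    diffs,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    smooth: bool = False,
) -> ResamplingResult:
    """Sign-flip resampling test of a mean paired difference."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least 2 pairs")
    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_draws, len(diffs)))
    null = (signs * diffs).mean(axis=1)
    return ResamplingResult(
        observed, n_draws, _two_sided_p(null, observed, smooth), seed
    )


def _f_statistic(data: np.ndarray, slices: list[slice], k: int) -> np.ndarray:
    """Vectorized one-way F over the last axis of (draws, N) data."""
    n_total = data.shape[-1]
    grand = data.mean(axis=-1)
    ssb = np.zeros(data.shape[:-1])
    ssw = np.zeros(data.shape[:-1])
    for sl in slices:
        g = data[..., sl]
        gm = g.mean(axis=-1)
        ssb += g.shape[-1] * (gm - grand) ** 2
        ssw += ((g - gm[..., None]) ** 2).sum(axis=-1)
    return (ssb / (k - 1)) / (ssw / (n_total - k))


def resample_anova(
    groups,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    smooth: bool = False,
) -> ResamplingResult:
    """One-way resampling ANOVA: F statistic under label permutation.

    The result's ``extra["pairwise"]`` table holds Bonferroni-corrected
    pairwise resampling comparisons (correction over all group pairs).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    sizes = [len(g) for g in groups]
    data = np.concatenate(groups)
    edges = np.cumsum([0] + sizes)
    slices = [slice(edges[i], edges[i + 1]) for i in range(len(groups))]
    k = len(groups)
    observed = float(_f_statistic(data[None, :], slices, k)[0])
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_draws, len(data))), axis=1)
    null = _f_statistic(data[perm], slices, k)
    # F is non-negative: the permutation p is one-sided by construction
    kk = int(np.count_nonzero(null >= observed - 1e-12))
    p = (kk + 1) / (n_draws + 1) if smooth else kk / n_draws
    n_pairs = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            r = resample_independent(
                groups[i], groups[j], n_draws=n_draws, seed=seed + 1 + i * k + j,
                smooth=smooth,
            )
            pairwise.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "observed_diff": r.observed,
                    "p_raw": r.p,
                    "p_bonferroni": min(1.0, r.p * n_pairs),
                }
            )
    return ResamplingResult(
        observed, n_draws, p, seed, extra={"pairwise": pd.DataFrame(pairwise)}
    )


@dataclass
class RepertoireTable:
    """Animal x call-type count table with genotype labels.

    ``df`` columns: ``animal``, ``genotype``, then one non-negative integer
    count column per call type.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "genotype"}
        if not required <= set(self.df.columns):
            raise ValueError("repertoire table needs 'animal' and 'genotype' columns")
        counts = self.counts()
        if (counts.to_numpy() < 0).any():
            raise ValueError("call counts must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RepertoireTable":
        return cls(pd.read_csv(path))

    @property
    def call_types(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("animal", "genotype")]

    def counts(self, genotype: str | None = None) -> pd.DataFrame:
        df = self.df if genotype is None else self.df[self.df["genotype"] == genotype]
        return df.set_index("animal")[self.call_types]


def repertoire_difference(
    rt: RepertoireTable,
    reference_genotype: str,
    test_genotype: str,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-call-type over/under-representation of the test genotype.

    The resampling pool replicates each call type by the reference
    genotype's median count. Each draw samples the test genotype's total
    call count from the pool with replacement and tallies per type (scaled
    to the per-animal level). A type is flagged "over"/"under" when the test
    animals' mean count +/- SEM lies entirely outside the 95% CI of the
    resampled counts.
    """
    ref = rt.counts(reference_genotype)
    test = rt.counts(test_genotype)
    if len(ref) < 2 or len(test) < 2:
        raise ValueError("need at least 2 animals per genotype")
    medians = ref.median(axis=0).to_numpy(float)
    if medians.sum() <= 0:
        raise ValueError("reference genotype has all-zero median counts")
    probs = medians / medians.sum()
    n_test_total = int(test.to_numpy().sum())
    n_animals = len(test)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_test_total, probs, size=n_draws) / n_animals
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    obs_mean = test.mean(axis=0).to_numpy(float)
    sem = test.std(axis=0, ddof=1).to_numpy(float) / np.sqrt(n_animals)
    verdict = np.where(
        obs_mean - sem > hi, "over", np.where(obs_mean + sem < lo, "under", "none")
    )
    return pd.DataFrame(
        {
            "call_type": rt.call_types,
            "expected_mean": draws.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "observed_mean": obs_mean,
            "sem": sem,
            "verdict": verdict,
        }
    )


def repertoire_correlation(
    rt: RepertoireTable,
    genotype_a: str,
    genotype_b: str,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> dict:
    """Within/between-genotype repertoire correlations.

    All pairwise Pearson correlations between animals' call-count vectors
    are computed; constant vectors are excluded with a warning. The
    difference between the two within-genotype correlation sets is tested
    with the independent-resampling procedure.
    """
    import warnings

    counts = {g: rt.counts(g) for g in (genotype_a, genotype_b)}
    for g, c in counts.items():
        if len(c) < 2:
            raise ValueError(f"genotype {g!r} needs at least 2 animals")
    vectors: dict[str, list[tuple[str, np.ndarray]]] = {}
    for g, c in counts.items():
        keep = []
        for animal, row in c.iterrows():
            v = row.to_numpy(float)
            if v.std() < 1e-12:
                warnings.warn(
                    f"animal {animal!r} has a constant count vector; excluded "
                    "from correlation analysis"
                )
                continue
            keep.append((str(animal), v))
        vectors[g] = keep

    def pairwise_within(items):
        return [
            float(np.corrcoef(items[i][1], items[j][1])[0, 1])
            for i in range(len(items))
            for j in range(i + 1, len(items))
        ]

    within_a = pairwise_within(vectors[genotype_a])
    within_b = pairwise_within(vectors[genotype_b])
    between = [
        float(np.corrcoef(va[1], vb[1])[0, 1])
        for va in vectors[genotype_a]
        for vb in vectors[genotype_b]
    ]
    if len(within_a) >= 2 and len(within_b) >= 2:
        test = resample_independent(within_a, within_b, n_draws=n_draws, seed=seed)
    else:
        test = None  # two animals per group give a single correlation: untestable
    return {
        "within": {
            genotype_a: float(np.mean(within_a)) if within_a else float("nan"),
            genotype_b: float(np.mean(within_b)) if within_b else float("nan"),
        },
        "between": float(np.mean(between)) if between else float("nan"),
        "difference_test": test,
    }
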