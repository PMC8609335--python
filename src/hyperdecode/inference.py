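"""Permutation and bootstrap inference for decoding accuracy maps.

The null model shuffles identity labels independently within every
(participant, head view) cell — preserving the label balance of the design
— and reruns the full decoding analysis per permutation (100 by default).
Per location, an empirical null distribution of *mean* accuracies is built
by bootstrap: draw n_folds fold-level accuracies with replacement from the
pooled permuted folds, average, and repeat (10,000 draws by default).  The
empirical p-value is bias-corrected, (exceedances + 1) / (draws + 1), so it
can never be exactly zero under finite resampling; ties count as
exceedances, which keeps p conservative.  Multiple comparisons are
controlled with the Benjamini-Hochberg step-up FDR procedure.

Condition-difference maps first floor each condition's across-fold mean
accuracy at chance (25% for four balanced identities) — below-chance values
are noise and would otherwise inflate difference estimates — then subtract.
Their null bootstraps the two conditions' permuted folds independently,
applies the same floor-and-subtract rule, and uses the two-sided
absolute-value exceedance count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .decoding import (
    CHANCE_4WAY,
    AccuracyResult,
    ClassifierConfig,
    SampleSet,
    _accuracies_over,
)


@dataclass
class PermutationScheme:
    """Label-shuffling scheme: identity labels permuted within each
    (participant, head view) cell, independently per cell."""

    n_permutations: int = 100
    seed: int = 0


@dataclass
class NullDistribution:
    """Bootstrap draws of mean accuracy per location under the null."""

    draws: np.ndarray  # (n_locations, n_bootstrap)
    chance_level: float = CHANCE_4WAY

    @property
    def n_bootstrap(self) -> int:
        return self.draws.shape[1]


@dataclass
class StatMap:
    """Observed statistic, empirical p, BH-FDR q and significance flags."""

    locations: list
    observed: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location": self.locations,
                "observed": self.observed,
                "p": self.p,
                "q": self.q,
                "significant": self.significant.astype(int),
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def thresholded(self, floor: float = CHANCE_4WAY) -> np.ndarray:
        """Observed values where significant, ``floor`` elsewhere."""
        return np.where(self.significant, self.observed, floor)


def permute_labels(
    samples: SampleSet, scheme: PermutationScheme, permutation_index: int
) -> SampleSet:
    """Permute identity labels within each (subject, view) cell.

    Implemented by shuffling the data rows of each cell while keeping the
    label arrays fixed; the label multiset per cell is preserved exactly.
    Reproducible from (scheme.seed, permutation_index).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(scheme.seed, spawn_key=(permutation_index,))
    )
    data = samples.data.copy()
    for s in range(samples.n_subjects):
        for v in np.unique(samples.views):
            cell = np.flatnonzero(samples.views == v)
            data[s, cell] = data[s, cell[rng.permutation(len(cell))]]
    return replace(samples, data=data)


def permuted_accuracies(
    samples: SampleSet,
    node_sets: list,
    folds: list,
    scheme: PermutationScheme,
    config: ClassifierConfig = None,
) -> np.ndarray:
    """Re-run decoding under each label permutation.

    Returns (n_locations, n_permutations, n_folds) fold accuracies: the raw
    material for bootstrap null distributions.
    """
    if config is None:
        config = ClassifierConfig()
    out = np.empty((len(node_sets), scheme.n_permutations, len(folds)))
    for p in range(scheme.n_permutations):
        permuted = permute_labels(samples, scheme, p)
        out[:, p, :] = _accuracies_over(permuted, node_sets, folds, config)
    return out


def build_null(
    permuted_folds: np.ndarray,
    n_bootstrap: int = 10_000,
    n_folds: int = None,
    seed: int = 0,
    stratify_by_permutation: bool = False,
) -> NullDistribution:
    """Bootstrap mean-accuracy null per location.

    ``permuted_folds`` is (n_locations, n_permutations, n_folds).  Each
    draw samples ``n_folds`` fold accuracies with replacement — by default
    from the pool of all permutations' folds — and records their mean.
    With ``stratify_by_permutation`` each draw instead resamples folds
    within one randomly chosen permutation.
    """
    permuted_folds = np.asarray(permuted_folds, dtype=float)
    if permuted_folds.ndim != 3:
        raise ValueError("expected (n_locations, n_permutations, n_folds)")
    n_loc, n_perm, nf = permuted_folds.shape
    if n_perm == 0 or nf == 0:
        raise ValueError("empty permutation pool")
    if n_folds is None:
        n_folds = nf
    rng = np.random.default_rng(seed)
    draws = np.empty((n_loc, n_bootstrap))
    for i in range(n_loc):
        if stratify_by_permutation:
            perm_idx = rng.integers(0, n_perm, n_bootstrap)
            fold_idx = rng.integers(0, nf, (n_bootstrap, n_folds))
            draws[i] = permuted_folds[i, perm_idx[:, None], fold_idx].mean(
                axis=1
            )
        else:
            pool = permuted_folds[i].ravel()
            idx = rng.integers(0, pool.size, (n_bootstrap, n_folds))
            draws[i] = pool[idx].mean(axis=1)
    return NullDistribution(draws)


def empirical_p(
    observed: np.ndarray, null: NullDistribution, sided: str = "one"
) -> np.ndarray:
    """Bias-corrected empirical p-value: (exceedances + 1) / (draws + 1).

    One-sided counts null draws >= observed; two-sided counts
    |null| >= |observed| (for difference maps).  Ties count as exceedances.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    draws = null.draws
    if draws.shape[0] != observed.shape[0]:
        raise ValueError("one null distribution per observed value required")
    n = draws.shape[1]
    if sided == "one":
        exceed = (draws >= observed[:, None]).sum(axis=1)
    elif sided == "two":
        exceed = (np.abs(draws) >= np.abs(observed)[:, None]).sum(axis=1)
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return (exceed + 1) / (n + 1)


def fdr_bh(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted q values and significance flags."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(pvalues <= 0) or np.any(pvalues > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return q, reject


def accuracy_statmap(
    result: AccuracyResult,
    permuted_folds: np.ndarray,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatMap:
    """One-sided permutation/bootstrap inference on a mean accuracy map."""
    observed = result.mean_map()
    null = build_null(
        permuted_folds, n_bootstrap, result.accuracies.shape[1], seed
    )
    p = empirical_p(observed, null, sided="one")
    q, sig = fdr_bh(p, alpha)
    return StatMap(result.locations, observed, p, q, sig, alpha)


def difference_map(
    personal: AccuracyResult,
    visual: AccuracyResult,
    permuted_personal: np.ndarray,
    permuted_visual: np.ndarray,
    chance: float = CHANCE_4WAY,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatMap:
    """Floored condition-difference map (personal - visual) with two-sided
    permutation inference.

    Each condition's across-fold mean is floored at ``chance`` before
    subtraction, observed and null alike; the null bootstraps the two
    conditions' permuted fold pools independently.
    """
    if list(personal.locations) != list(visual.locations):
        raise ValueError("condition maps cover different locations")
    if personal.accuracies.shape != visual.accuracies.shape:
        raise ValueError("condition maps have mismatched fold structure")
    n_folds = personal.accuracies.shape[1]
    obs = np.maximum(personal.mean_map(), chance) - np.maximum(
        visual.mean_map(), chance
    )
    null_p = build_null(permuted_personal, n_bootstrap, n_folds, seed)
    null_v = build_null(permuted_visual, n_bootstrap, n_folds, seed + 1)
    diff_draws = np.maximum(null_p.draws, chance) - np.maximum(
        null_v.draws, chance
    )
    p = empirical_p(obs, NullDistribution(diff_draws), sided="two")
    q, sig = fdr_bh(p, alpha)
    return StatMap(list(personal.locations), obs, p, q, sig, alpha)
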