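"""Two-level hierarchical bootstrap tests for nested animals x trials data.

Resampling draws n animals with replacement, then for each drawn animal its
own number of trials with replacement from that animal's trials; the test
statistic is the animal-wide mean (mean over animals of per-animal trial
means).  10,000 resamples by default.

The within test builds the distribution of mu* - mu and reads the p-value
as the quantile of mu in it.  The between test draws independent pairs
(mu_a*, mu_b*), forms their joint distribution on a 2-D histogram and takes
the density on one side of the diagonal; the binning-free pair fraction is
reported alongside as an internal cross-check.
"""

from __future__ import annotations

import numpy as np

from .types import BootstrapResult, HierarchicalDataset

_QUANTS = (0.025, 0.25, 0.5, 0.75, 0.975)


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.005, '***' p<0.0005 (strict inequalities)."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def animal_wide_mean(ds: HierarchicalDataset) -> float:
    """Mean over animals of per-animal trial means (animals weighted
    equally regardless of trial count)."""
    return float(np.mean([a.mean() for a in ds.animals]))


def hb_resample(ds: HierarchicalDataset,
                rng: np.random.Generator) -> HierarchicalDataset:
    """One hierarchical resample: n animals with replacement, then each
    drawn animal's own trial count of trials with replacement."""
    n = ds.n_animals
    picks = rng.integers(0, n, size=n)
    animals = []
    for i in picks:
        a = ds.animals[i]
        animals.append(a[rng.integers(0, a.size, size=a.size)])
    return HierarchicalDataset(ds.group, animals,
                               [ds.animal_ids[i] for i in picks])


def bootstrap_means(ds: HierarchicalDataset, n_boot: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized animal-wide means of ``n_boot`` hierarchical resamples."""
    n = ds.n_animals
    picks = rng.integers(0, n, size=(n_boot, n))
    # per-animal resampled trial means, computed animal-by-animal for all
    # occurrences at once (trial counts may differ between animals)
    means = np.empty((n_boot, n))
    for i, a in enumerate(ds.animals):
        mask = picks == i
        count = int(mask.sum())
        if count == 0:
            continue
        draws = rng.integers(0, a.size, size=(count, a.size))
        means[mask] = a[draws].mean(axis=1)
    return means.mean(axis=1)


def _directional_p(upper: float, lower: float, sidedness: str,
                   n_boot: int) -> float:
    if sidedness == "greater":
        p = upper
    elif sidedness == "less":
        p = lower
    else:
        p = min(1.0, 2.0 * min(upper, lower))
    return max(p, 1.0 / n_boot)


def _summary(dist: np.ndarray) -> dict:
    return {f"q{q}": float(np.quantile(dist, q)) for q in _QUANTS}


def hb_test_within(ds: HierarchicalDataset, n_boot: int = 10_000,
                   seed: int = 0, sidedness: str = "two") -> BootstrapResult:
    """Test whether per-trial change scores differ from zero.

    Builds {mu*_b - mu}; the one-sided p is the fraction of draws at or
    beyond mu itself (upper or lower), the two-sided p is twice the smaller
    one, capped at 1 and floored at 1/n_boot.  All-identical values yield a
    degenerate result with p = 1.
    """
    mu = animal_wide_mean(ds)
    flat = np.concatenate(ds.animals)
    if np.all(flat == flat[0]):
        return BootstrapResult("within", n_boot, seed, sidedness, mu, mu, 0.0,
                               {f"q{q}": mu for q in _QUANTS}, 1.0, "",
                               degenerate=True)
    rng = np.random.default_rng(seed)
    dist = bootstrap_means(ds, n_boot, rng) - mu
    upper = float(np.mean(dist >= mu))
    lower = float(np.mean(dist <= mu))
    p = _directional_p(upper, lower, sidedness, n_boot)
    return BootstrapResult("within", n_boot, seed, sidedness, mu,
                           float(dist.mean()), float(dist.std()),
                           _summary(dist), p, significance_stars(p))


def hb_test_between(ds_a: HierarchicalDataset, ds_b: HierarchicalDataset,
                    n_boot: int = 10_000, seed: int = 0,
                    sidedness: str = "two",
                    n_bins: int = 100) -> BootstrapResult:
    """Compare the animal-wide means of two independent groups.

    Draws n_boot independent pairs (mu_a*, mu_b*), histograms them on an
    n_bins x n_bins grid spanning both marginals and takes the mass on one
    side of the diagonal (diagonal bins split evenly); the binning-free pair
    fraction is reported as ``p_value_pairwise``.
    """
    flat_a = np.concatenate(ds_a.animals)
    flat_b = np.concatenate(ds_b.animals)
    degenerate = bool(np.all(flat_a == flat_a[0]) and
                      np.all(flat_b == flat_b[0]))
    rng = np.random.default_rng(seed)
    mu_a = bootstrap_means(ds_a, n_boot, rng)
    mu_b = bootstrap_means(ds_b, n_boot, rng)
    observed = animal_wide_mean(ds_a) - animal_wide_mean(ds_b)
    diff = mu_a - mu_b
    # binning-free pair fractions (oracle for the binned construction)
    up_pair = float(np.mean(mu_a <= mu_b))
    lo_pair = float(np.mean(mu_a >= mu_b))
    p_pair = _directional_p(up_pair, lo_pair, sidedness, n_boot)
    if degenerate:
        p = p_pair
        upper, lower = up_pair, lo_pair
    else:
        lo = float(min(mu_a.min(), mu_b.min()))
        hi = float(max(mu_a.max(), mu_b.max()))
        edges = np.linspace(lo, hi, n_bins + 1)
        hist, _, _ = np.histogram2d(mu_a, mu_b, bins=[edges, edges])
        hist /= hist.sum()
        ia, ib = np.indices(hist.shape)
        upper = float(hist[ia < ib].sum() + 0.5 * hist[ia == ib].sum())
        lower = float(hist[ia > ib].sum() + 0.5 * hist[ia == ib].sum())
        p = _directional_p(upper, lower, sidedness, n_boot)
    return BootstrapResult("between", n_boot, seed, sidedness, observed,
                           float(diff.mean()), float(diff.std()),
                           _summary(diff), p, significance_stars(p),
                           degenerate=degenerate, p_value_pairwise=p_pair)
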