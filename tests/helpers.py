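"""Oracles shared between test modules: closed-form and brute-force checks."""

import numpy as np
import pandas as pd

from owl_divergence.io import MISSING


def one_way(g, n, sigma_pop, sigma_res, seed, beta_morph=0.0):
    """Balanced one-way layout with an optional morph fixed effect."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_pop, g)
    morph = rng.integers(0, 2, g * n)
    y = np.repeat(u, n) + beta_morph * morph + rng.normal(0, sigma_res, g * n)
    return pd.DataFrame(
        {
            "y": y,
            "population_id": np.repeat([f"p{i:03d}" for i in range(g)], n),
            "morph": morph,
        }
    )


def anova_oracle(df, g, n):
    """Closed-form balanced one-way estimators (intercept-only model)."""
    gm = df.groupby("population_id")["y"]
    msw = ((df["y"] - gm.transform("mean")) ** 2).sum() / (g * (n - 1))
    msb = n * ((gm.mean() - df["y"].mean()) ** 2).sum() / (g - 1)
    return (msb - msw) / n, msw


def brute_force_amova_fst(g, locus):
    """Pairwise allele-identity-distance AMOVA, computed the slow way."""
    l = g.loci.index(locus)
    copies, labels = [], []
    for i in range(g.n_individuals):
        a1, a2 = g.calls[i, l]
        if a1 != MISSING:
            copies.extend([a1, a2])
            labels.extend([g.population_ids[i]] * 2)
    copies = np.array(copies)
    labels = np.array(labels)
    N = len(copies)
    d = (copies[:, None] != copies[None, :]).astype(float)
    ssd_total = d[np.triu_indices(N, 1)].sum() / N
    ssd_within = 0.0
    k = 0
    n_sizes = []
    for pop in np.unique(labels):
        idx = np.flatnonzero(labels == pop)
        if len(idx) == 0:
            continue
        k += 1
        n_sizes.append(len(idx))
        sub = d[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    s2_w = ssd_within / (N - k)
    n0 = (N - sum(n * n for n in n_sizes) / N) / (k - 1)
    s2_a = (ssd_among / (k - 1) - s2_w) / n0
    if s2_a + s2_w == 0:
        return float("nan")
    return s2_a / (s2_a + s2_w)
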