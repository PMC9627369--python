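"""Remove planted scanner/site effects with empirical-Bayes harmonization.

Plants an additive offset of 1.0 and a variance ratio of 4 between two
sites, then fits the parametric ComBat model and verifies both effects are
gone while a planted group difference survives.
"""

import numpy as np

from nacfc.combat import harmonize

rng = np.random.default_rng(0)
p, n_per = 500, 200
batch = np.array(["site_a"] * n_per + ["site_b"] * n_per)
group = np.tile([0.0, 1.0], n_per)  # balanced PD/HC indicator

Y = rng.normal(size=(p, 2 * n_per))
Y[:, batch == "site_b"] = Y[:, batch == "site_b"] * 2.0 + 1.0  # site effect
Y += 0.3 * group  # group effect to preserve

adj = harmonize(Y, batch, design=group[:, None])


def site_stats(M):
    a, b = M[:, batch == "site_a"], M[:, batch == "site_b"]
    return (b.mean(1) - a.mean(1)).mean(), (b.var(1) / a.var(1)).mean()


off0, ratio0 = site_stats(Y)
off1, ratio1 = site_stats(adj)
gdiff = (adj[:, group == 1].mean(1) - adj[:, group == 0].mean(1)).mean()
print(f"between-site offset:   {off0:+.3f} -> {off1:+.3f}")
print(f"between-site var ratio: {ratio0:.2f} -> {ratio1:.2f}")
print(f"planted group difference of 0.30 after harmonization: {gdiff:.3f}")
print("\nSite location/scale effects are removed; the biological covariate")
print("named in the design matrix is left intact.")
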