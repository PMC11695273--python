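"""WC84 theta, bootstrap CI, per-SNP divergence, Phi_ST and heterozygosity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from introscan import divergence
from introscan.divergence import (
    amova_phi_st,
    bootstrap_ci,
    diversity_table,
    het_stats,
    per_snp_divergence,
    per_snp_theta,
    wc84_components,
    wc84_theta,
)
from introscan.genio import GenotypeMatrix
from introscan.simdata import SimConfig, simulate_dataset

from conftest import make_loci, make_matrix, make_popmap


def wc84_scalar(dosages, groups):
    """Independent unvectorised WC84 oracle (scalar path over the component formulas)."""
    labels = sorted(set(groups))
    r = len(labels)
    num = den = 0.0
    for l in range(dosages.shape[1]):
        n_i, p_i, h_i = [], [], []
        for g in labels:
            vals = [dosages[i, l] for i, gg in enumerate(groups)
                    if gg == g and not np.isnan(dosages[i, l])]
            n_i.append(len(vals))
            p_i.append(sum(vals) / (2 * len(vals)))
            h_i.append(sum(1 for v in vals if v == 1) / len(vals))
        nbar = sum(n_i) / r
        nc = (sum(n_i) - sum(n * n for n in n_i) / sum(n_i)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum(n_i)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum(n_i)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


def amova_scalar(haps_by_group):
    """Brute-force AMOVA Phi_ST by exhaustive pairwise-difference enumeration."""
    allh = [tuple(h) for grp in haps_by_group for h in grp]
    sizes = [len(g) for g in haps_by_group]
    N, G = len(allh), len(haps_by_group)

    def d(x, y):
        return sum(a != b for a, b in zip(x, y))

    ssd_total = sum(d(allh[i], allh[j]) for i, j in itertools.combinations(range(N), 2)) / N
    ssd_within = 0.0
    off = 0
    for grp in haps_by_group:
        n = len(grp)
        ssd_within += sum(
            d(tuple(grp[i]), tuple(grp[j])) for i, j in itertools.combinations(range(n), 2)
        ) / n
        off += n
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (N - G)
    n_prime = (N - sum(s * s for s in sizes) / N) / (G - 1)
    sigma_a = (ssd_among / (G - 1) - ms_within) / n_prime
    return sigma_a / (sigma_a + ms_within)


def test_no_divergence_theta_near_zero():
    cfg = SimConfig(n_loci=5000, target_fst=0.0, n_parvulus=50, n_pauper=50,
                    n_f1=0, n_backcross=0, seed=8)
    G, _, pm, _ = simulate_dataset(cfg)
    res = wc84_theta(G, pm, ("parvulus", "pauper"))
    assert abs(res.theta) < 0.01


def test_fixed_differences_theta_one():
    G = make_matrix([[0] * 5] * 4 + [[2] * 5] * 4)
    pm = make_popmap(G.samples, ["parvulus"] * 4 + ["pauper"] * 4)
    res = wc84_theta(G, pm, ("parvulus", "pauper"))
    assert res.theta == pytest.approx(1.0)


def test_theta_matches_scalar_oracle_on_toy():
    """Vectorised theta equals an independent scalar WC84 computation."""
    rng = np.random.default_rng(12)
    D = rng.choice([0.0, 1.0, 2.0, np.nan], size=(20, 30), p=[0.4, 0.3, 0.25, 0.05])
    G = GenotypeMatrix([f"s{i}" for i in range(20)], D)
    groups = ["parvulus"] * 10 + ["pauper"] * 10
    pm = make_popmap(G.samples, groups)
    res = wc84_theta(G, pm, ("parvulus", "pauper"))
    assert res.theta == pytest.approx(wc84_scalar(D, groups), abs=1e-12)


def test_theta_invariant_to_order_and_allele_relabel():
    rng = np.random.default_rng(13)
    D = rng.choice([0.0, 1.0, 2.0], size=(16, 50))
    pm = make_popmap([f"s{i}" for i in range(16)], ["parvulus"] * 8 + ["pauper"] * 8)
    G = GenotypeMatrix(pm["sample"].tolist(), D)
    t0 = wc84_theta(G, pm, ("parvulus", "pauper")).theta
    perm = rng.permutation(50)
    t1 = wc84_theta(GenotypeMatrix(G.samples, D[:, perm]), pm, ("parvulus", "pauper")).theta
    D2 = D.copy()
    swap = rng.random(50) < 0.5
    D2[:, swap] = 2 - D2[:, swap]
    t2 = wc84_theta(GenotypeMatrix(G.samples, D2), pm, ("parvulus", "pauper")).theta
    assert t0 == pytest.approx(t1, abs=1e-12)
    assert t0 == pytest.approx(t2, abs=1e-12)


def test_bootstrap_degenerate_cases():
    comp = pd.DataFrame({"a": [0.1] * 10, "b": [0.2] * 10, "c": [0.3] * 10})
    lo, hi = bootstrap_ci(comp, iterations=50, seed=1)
    theta = 0.1 / 0.6
    assert lo == pytest.approx(theta) and hi == pytest.approx(theta)
    lo1, hi1 = bootstrap_ci(comp, iterations=1, seed=1)
    assert lo1 == hi1


def test_bootstrap_brackets_theta_on_sim(swarm_sim):
    _, G, _, pm, _ = swarm_sim
    res = wc84_theta(G, pm, ("parvulus", "pauper"), bootstrap=100, seed=2)
    assert res.ci_low <= res.theta <= res.ci_high


def test_hybrid_ordering_of_pairwise_theta(swarm_sim):
    _, G, _, pm, _ = swarm_sim
    t_pp = wc84_theta(G, pm, ("parvulus", "pauper")).theta
    t_ph = wc84_theta(G, pm, ("parvulus", "hybrid")).theta
    t_qh = wc84_theta(G, pm, ("pauper", "hybrid")).theta
    assert t_ph < t_pp and t_qh < t_pp


def test_per_snp_theta_trivials():
    # identical genotype distributions in both groups, n = 60 each
    block = [[0, 0], [1, 0], [2, 0]] * 20
    G = make_matrix(block + block)
    pm = make_popmap(G.samples, ["parvulus"] * 60 + ["pauper"] * 60)
    comp = wc84_components(G, [np.arange(60), np.arange(60, 120)])
    t = per_snp_theta(comp)
    assert abs(t[0]) < 0.02  # identical frequencies -> theta ~ 0
    assert np.isnan(t[1])    # monomorphic -> undefined


def test_phi_st_fixed_haplotypes_is_one():
    h1 = np.zeros((6, 2))
    h2 = np.ones((6, 2))
    assert amova_phi_st([h1, h2]) == pytest.approx(1.0)


def test_phi_st_matches_brute_force_enumeration():
    """6-individual, 2-SNP toy: AMOVA arithmetic against exhaustive enumeration."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        h_a = rng.integers(0, 2, size=(6, 2)).astype(float)
        h_b = rng.integers(0, 2, size=(6, 2)).astype(float)
        allh = np.vstack([h_a, h_b])
        if np.all(allh == allh[0]):
            continue
        got = amova_phi_st([h_a, h_b])
        want = amova_scalar([h_a.tolist(), h_b.tolist()])
        assert got == pytest.approx(want, abs=1e-12)


def test_per_snp_divergence_table(swarm_sim):
    _, G, loci, pm, _ = swarm_sim
    tab = per_snp_divergence(G, loci, pm, ("parvulus", "pauper"), seed=1)
    assert len(tab) == G.n_snps
    finite_phi = tab["phi_st"].dropna()
    assert (finite_phi <= 1.0 + 1e-9).all()
    # planted fixed-difference loci should be near-maximally divergent
    planted = loci["radlocus_id"].isin(["rad_0", "rad_1", "rad_2"])
    assert tab.loc[planted, "theta"].mean() > 0.8


def test_het_stats_hand_example():
    # genotypes (0,1,1,2): Ho = 0.5, p = 0.5, He = 2*0.25*(8/7), Fis = 0.125
    G = make_matrix([[0], [1], [1], [2]])
    s = het_stats(G, np.arange(4))
    assert s["Ho"] == pytest.approx(0.5)
    assert s["He"] == pytest.approx(2 * 0.25 * 8 / 7)
    assert s["Fis"] == pytest.approx(0.125)


def test_het_stats_monomorphic_undefined():
    G = make_matrix([[0, 0], [0, 0], [0, 0]])
    s = het_stats(G, np.arange(3))
    assert s["Ho"] == 0.0 and s["He"] == 0.0
    assert np.isnan(s["Fis"])


def test_hwe_population_fis_near_zero():
    cfg = SimConfig(n_loci=5000, target_fst=0.0, n_parvulus=40, n_pauper=0,
                    n_f1=0, n_backcross=0, seed=14)
    G, _, pm, _ = simulate_dataset(cfg)
    tab = diversity_table(G, pm, ["parvulus"])
    assert abs(tab["Fis"].iloc[0]) < 0.02


def test_group_too_small_rejected():
    G = make_matrix([[0, 1], [1, 1], [2, 0]])
    pm = make_popmap(G.samples, ["parvulus", "parvulus", "pauper"])
    with pytest.raises(ValueError):
        wc84_theta(G, pm, ("parvulus", "pauper"))
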