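"""Pairwise relatedness (KING-robust kinship) for duplicate/sib screening.

For a sample pair (i, j), over the SNPs genotyped in both:

    phi_hat = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa,i + N_Aa,j)

where N_Aa,Aa counts SNPs heterozygous in both, N_AA,aa counts SNPs with
opposite homozygotes, and N_Aa,i counts heterozygous SNPs in sample i
restricted to the co-genotyped set. Self-kinship is 0.5 whenever the
sample has at least one heterozygous call; pairs with a zero denominator
are undefined (NaN) and flagged. Unrelated pairs are centred near 0;
parent-offspring and full sibs near 0.25; duplicates near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

SECOND_DEGREE_CUTOFF = 0.177  # standard KING cut between 1st and 2nd degree


@dataclass
class KinshipMatrix:
    kinship: pd.DataFrame      # samples x samples, NaN where undefined
    n_cogenotyped: pd.DataFrame

    def pairs_above(self, threshold: float = SECOND_DEGREE_CUTOFF) -> pd.DataFrame:
        """Upper-triangle pairs with kinship >= threshold (candidate close kin)."""
        k = self.kinship.to_numpy()
        n = self.n_cogenotyped.to_numpy()
        samples = list(self.kinship.index)
        rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                if np.isfinite(k[i, j]) and k[i, j] >= threshold:
                    rows.append((samples[i], samples[j], int(n[i, j]), float(k[i, j])))
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_snps", "kinship"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format pairwise table (sample_i, sample_j, n_snps, kinship)."""
        k = self.kinship.to_numpy()
        n = self.n_cogenotyped.to_numpy()
        samples = list(self.kinship.index)
        rows = [
            (samples[i], samples[j], int(n[i, j]), float(k[i, j]))
            for i in range(len(samples)) for j in range(i + 1, len(samples))
        ]
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_snps", "kinship"])


def king_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust kinship for every sample pair (vectorised)."""
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    D = G.dosages
    called = (~np.isnan(D)).astype(float)
    het = (D == 1).astype(float)
    hom0 = (D == 0).astype(float)
    hom2 = (D == 2).astype(float)

    n_het_both = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    # het count of i over SNPs co-genotyped with j (het rows are 0 at missing)
    n_het_i = het @ called.T
    denom = n_het_i + n_het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_both - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    n_co = called @ called.T
    idx = pd.Index(G.samples)
    return KinshipMatrix(
        kinship=pd.DataFrame(phi, index=idx, columns=idx),
        n_cogenotyped=pd.DataFrame(n_co.astype(int), index=idx, columns=idx),
    )
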