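"""Multilocus pairwise Fst between species.

Nei-style Gst from expected heterozygosities: per locus, Hs is the
unweighted mean of the two within-group expected heterozygosities 2p(1-p)
and Ht = 2*p_bar*(1-p_bar) with p_bar the unweighted mean of the two group
frequencies; the multilocus value is the ratio of sums
Fst = 1 - sum(Hs)/sum(Ht) over loci with Ht > 0.  No sample-size correction
is applied.  A Hudson-style estimator from a joint SFS is also provided for
checking expected spectra against island-model theory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, allele_freqs
from .sfs import JointSFS

__all__ = ["nei_fst", "pairwise_fst", "hudson_fst_from_sfs"]


def nei_fst(gm: GenotypeMatrix, popA: str, popB: str, clamp: bool = False) -> float:
    """Multilocus Nei Fst between two species groups (ratio of sums)."""
    fa = allele_freqs(gm, popA)
    fb = allele_freqs(gm, popB)
    pa = fa["freq"].to_numpy()
    pb = fb["freq"].to_numpy()
    ok = np.isfinite(pa) & np.isfinite(pb)
    if not ok.any():
        raise ValueError("no locus genotyped in both groups")
    pa, pb = pa[ok], pb[ok]
    hs = 0.5 * (2 * pa * (1 - pa) + 2 * pb * (1 - pb))
    pbar = 0.5 * (pa + pb)
    ht = 2 * pbar * (1 - pbar)
    use = ht > 0
    if not use.any():
        return 0.0
    fst = 1.0 - hs[use].sum() / ht[use].sum()
    return float(np.clip(fst, 0.0, 1.0)) if clamp else float(fst)


def pairwise_fst(gm: GenotypeMatrix, groups: list[str] | None = None, clamp: bool = False) -> pd.DataFrame:
    """Symmetric matrix of pairwise Fst over species labels (diagonal 0)."""
    groups = list(groups) if groups is not None else gm.species_labels
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            v = nei_fst(gm, a, b, clamp=clamp)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def hudson_fst_from_sfs(s: JointSFS) -> float:
    """Hudson-style Fst (1 - Hw/Hb) from a two-population spectrum.

    Within-population heterozygosity uses the unbiased n/(n-1) estimator per
    cell; under the engine's scaled units a symmetric two-deme equilibrium
    at migration rate M has expectation 1/(1+2M).
    """
    if s.ndim != 2:
        raise ValueError("requires a two-population spectrum")
    n1, n2 = s.sample_sizes
    ii, jj = np.meshgrid(np.arange(n1 + 1), np.arange(n2 + 1), indexing="ij")
    p1, p2 = ii / n1, jj / n2
    hw = 0.5 * (2 * ii * (n1 - ii) / (n1 * (n1 - 1)) + 2 * jj * (n2 - jj) / (n2 * (n2 - 1)))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    w = s.entries.copy()
    w[s.mask] = 0.0
    denom = (w * hb).sum()
    if denom <= 0:
        raise ValueError("spectrum carries no between-population heterozygosity")
    return float(1.0 - (w * hw).sum() / denom)
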