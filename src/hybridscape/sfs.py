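"""Joint allele-frequency spectra: construction, projection, folding, misorientation.

A :class:`JointSFS` holds a 2-D or 3-D array of (possibly fractional) SNP
counts indexed by the alternate/derived allele count in each population, with
the all-ancestral and all-derived corners masked.  Projection to smaller
sample sizes is the exact hypergeometric expectation, which is how per-site
missing genotypes are absorbed when a spectrum is built directly from a
genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "JointSFS",
    "build_jafs",
    "project_jafs",
    "fold_jafs",
    "misorient_jafs",
    "read_sfs",
    "write_sfs",
]


@dataclass
class JointSFS:
    """A joint site-frequency spectrum over 2 or 3 populations.

    ``entries[i, j(, k)]`` is the (expected or observed) number of SNPs with
    ``i`` alternate copies in population 1, ``j`` in population 2, etc.;
    ``sample_sizes`` are haploid counts, so the array shape is
    ``(n1+1, n2+1[, n3+1])``.
    """

    entries: np.ndarray
    sample_sizes: tuple[int, ...]
    pop_ids: tuple[str, ...] | None = None
    folded: bool = False
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        expect = tuple(n + 1 for n in self.sample_sizes)
        if self.entries.shape != expect:
            raise ValueError(f"entries shape {self.entries.shape} != {expect}")
        if (self.entries < -1e-9).any():
            raise ValueError("spectrum entries must be non-negative")
        self.entries = np.clip(self.entries, 0.0, None)
        if self.mask is None:
            self.mask = corner_mask(self.sample_sizes, self.folded)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.entries.shape:
                raise ValueError("mask shape mismatch")

    @property
    def ndim(self) -> int:
        return self.entries.ndim

    def unmasked_sum(self) -> float:
        return float(self.entries[~self.mask].sum())

    def total_sum(self) -> float:
        return float(self.entries.sum())

    def copy(self) -> "JointSFS":
        return JointSFS(
            self.entries.copy(), self.sample_sizes, self.pop_ids, self.folded, self.mask.copy()
        )

    def compatible_with(self, other: "JointSFS") -> bool:
        return (
            self.sample_sizes == other.sample_sizes
            and self.folded == other.folded
            and bool((self.mask == other.mask).all())
        )

    def marginal(self, axis: int) -> np.ndarray:
        """1-D SFS of one population (sums over the other axes, mask ignored)."""
        axes = tuple(a for a in range(self.ndim) if a != axis)
        return self.entries.sum(axis=axes)


def corner_mask(sample_sizes, folded: bool = False) -> np.ndarray:
    """Mask for the all-ancestral corner, the all-derived corner, and (if
    folded) the majority-allele half of the spectrum."""
    shape = tuple(n + 1 for n in sample_sizes)
    mask = np.zeros(shape, dtype=bool)
    mask[(0,) * len(shape)] = True
    mask[tuple(n for n in sample_sizes)] = True
    if folded:
        tot = _derived_total(sample_sizes)
        mask |= tot > sum(sample_sizes) / 2.0
    return mask


def _derived_total(sample_sizes) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n + 1) for n in sample_sizes), indexing="ij")
    return sum(grids)


# ---------------------------------------------------------------------------
# Construction from genotypes


def build_jafs(
    gm: GenotypeMatrix,
    groups: list,
    polarization: str = "unfolded_ref_alt",
    project_to: tuple[int, ...] | None = None,
) -> JointSFS:
    """Build a joint SFS between 2 or 3 species from a genotype matrix.

    *groups* are species labels (or explicit row-index arrays); they must be
    disjoint.  Without ``project_to`` only loci fully genotyped in every group
    member are used and entries are integer counts.  With ``project_to``
    (haploid target sizes) each locus is independently downsampled to the
    target by the hypergeometric expectation over its genotyped chromosomes,
    so missing data cost partial rather than whole sites.
    """
    if len(groups) not in (2, 3):
        raise ValueError("groups must name 2 or 3 populations")
    if polarization not in ("folded", "unfolded_ref_alt"):
        raise ValueError(f"unknown polarization {polarization!r}")
    rows, labels = [], []
    for g in groups:
        if isinstance(g, str):
            rows.append(gm.individuals_of(g))
            labels.append(g)
        else:
            rows.append(np.asarray(g))
            labels.append("custom")
    flat = np.concatenate(rows)
    if len(set(flat.tolist())) != flat.size:
        raise ValueError("groups overlap")
    if project_to is None:
        sizes = tuple(2 * r.size for r in rows)
    else:
        sizes = tuple(int(n) for n in project_to)
        for n, r in zip(sizes, rows):
            if n > 2 * r.size:
                raise ValueError("projection target exceeds group size")
    shape = tuple(n + 1 for n in sizes)
    entries = np.zeros(shape)
    for j in range(gm.n_loci):
        weights = []
        for n_target, r in zip(sizes, rows):
            g = gm.genotypes[r, j]
            called = g != MISSING
            m = 2 * int(called.sum())
            if m < n_target:
                weights = None
                break
            d = int(g[called].sum())
            if project_to is None and m == n_target:
                w = np.zeros(n_target + 1)
                w[d] = 1.0
            else:
                w = _hyper_weights(d, m, n_target)
            weights.append(w)
        if weights is None:
            continue
        cell = weights[0]
        for w in weights[1:]:
            cell = np.multiply.outer(cell, w)
        entries += cell
    s = JointSFS(entries, sizes, tuple(labels), folded=False)
    if polarization == "folded":
        s = fold_jafs(s)
    return s


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hyper_weights(d: int, m: int, n: int) -> np.ndarray:
    """P(j of n sampled chromosomes carry alt | d of m do), j = 0..n."""
    j = np.arange(n + 1)
    with np.errstate(invalid="ignore"):
        logw = _log_comb(d, j) + _log_comb(m - d, n - j) - _log_comb(m, n)
    w = np.where((j <= d) & (n - j <= m - d), np.exp(logw), 0.0)
    return w


def _projection_matrix(m: int, n: int) -> np.ndarray:
    """(m+1, n+1) matrix of hypergeometric downsampling weights."""
    return np.vstack([_hyper_weights(d, m, n) for d in range(m + 1)])


def project_jafs(s: JointSFS, target_sizes) -> JointSFS:
    """Project *s* down to smaller haploid sample sizes (expectation under
    hypergeometric subsampling, applied independently per axis)."""
    target_sizes = tuple(int(n) for n in target_sizes)
    if len(target_sizes) != s.ndim:
        raise ValueError("target_sizes dimensionality mismatch")
    for n, m in zip(target_sizes, s.sample_sizes):
        if n > m:
            raise ValueError(f"target size {n} exceeds current {m}")
    ent = s.entries.copy()
    ent[s.mask] = 0.0  # masked mass does not flow into the projection
    for axis, (m, n) in enumerate(zip(s.sample_sizes, target_sizes)):
        if n == m:
            continue
        P = _projection_matrix(m, n)
        ent = np.tensordot(ent, P, axes=([axis], [0]))
        ent = np.moveaxis(ent, -1, axis)
    return JointSFS(ent, target_sizes, s.pop_ids, s.folded)


def fold_jafs(s: JointSFS) -> JointSFS:
    """Fold onto minor-allele configurations (ancestral state unknown)."""
    if s.folded:
        raise ValueError("spectrum is already folded")
    rev = s.entries[tuple(slice(None, None, -1) for _ in range(s.ndim))]
    tot = _derived_total(s.sample_sizes)
    half = sum(s.sample_sizes) / 2.0
    ent = s.entries + rev
    ent[tot > half] = 0.0
    ent[tot == half] *= 0.5
    return JointSFS(ent, s.sample_sizes, s.pop_ids, folded=True)


def misorient_jafs(s: JointSFS, O: float) -> JointSFS:
    """Mix a spectrum with its orientation-reversed image.

    With probability ``1 - O`` a site's ancestral/derived assignment is
    flipped: ``S' = O*S + (1-O)*reverse(S)``.
    """
    if s.folded:
        raise ValueError("misorientation applies to unfolded spectra only")
    if not 0.0 <= O <= 1.0:
        raise ValueError("O must be in [0, 1]")
    rev = s.entries[tuple(slice(None, None, -1) for _ in range(s.ndim))]
    ent = O * s.entries + (1.0 - O) * rev
    return JointSFS(ent, s.sample_sizes, s.pop_ids, folded=False)


# ---------------------------------------------------------------------------
# dadi-style flat text i/o


def write_sfs(s: JointSFS, path) -> None:
    """Write dadi-style flat text: a header line ``n1+1 [n2+1 ...] folded/unfolded``,
    the flattened entries, then a flattened 0/1 mask line."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        dims = " ".join(str(n + 1) for n in s.sample_sizes)
        fold = "folded" if s.folded else "unfolded"
        ids = " ".join(f'"{p}"' for p in s.pop_ids) if s.pop_ids else ""
        fh.write(f"{dims} {fold} {ids}".rstrip() + "\n")
        fh.write(" ".join(f"{x:.12g}" for x in s.entries.ravel()) + "\n")
        fh.write(" ".join("1" if b else "0" for b in s.mask.ravel()) + "\n")
    finally:
        if own:
            fh.close()


def read_sfs(path) -> JointSFS:
    own = not hasattr(path, "read")
    fh = open(path) if own else path
    try:
        header = fh.readline().split()
        dims, rest = [], []
        for tok in header:
            if tok.isdigit() and not rest:
                dims.append(int(tok))
            else:
                rest.append(tok)
        folded = rest[0] == "folded"
        pop_ids = tuple(t.strip('"') for t in rest[1:]) or None
        shape = tuple(dims)
        entries = np.array(fh.readline().split(), dtype=float).reshape(shape)
        mask_line = fh.readline().split()
        mask = None
        if mask_line:
            mask = np.array([t == "1" for t in mask_line]).reshape(shape)
        return JointSFS(entries, tuple(d - 1 for d in dims), pop_ids, folded, mask)
    finally:
        if own:
            fh.close()
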