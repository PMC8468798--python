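"""Site-frequency spectrum containers, folding, masking, projection and text I/O.

The spectra here follow the conventions common in diffusion-based demographic
inference: a 1D spectrum is a vector of site counts indexed by the number of
sampled allele copies (0..n) carrying the alternate (or, after folding, minor)
allele; a joint 2D spectrum is the analogous matrix over two samples.  Folded
spectra keep the full array length with the redundant upper half zeroed and
masked, which keeps index arithmetic and the text format uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "Sfs1D",
    "Sfs2D",
    "fold",
    "apply_mask",
    "read_sfs",
    "write_sfs",
]


@dataclass
class Sfs1D:
    """A one-dimensional site-frequency spectrum.

    Attributes
    ----------
    data : array of length ``n + 1``
        Site counts (possibly fractional after projection) per allele-count
        class.  For a folded spectrum entries above ``n // 2`` are zero.
    n : int
        Haploid sample size.
    folded : bool
        Whether the spectrum is indexed by minor-allele count.
    mask : boolean array of length ``n + 1``
        ``True`` marks entries excluded from likelihood computations.
    L : float or None
        Total callable sequence length (bp) that produced the spectrum.
    stderr : array or None
        Per-entry Monte-Carlo standard errors, set by the simulator.
    """

    data: np.ndarray
    n: int
    folded: bool = False
    mask: np.ndarray | None = None
    L: float | None = None
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.n + 1,):
            raise ValueError(
                f"data length {self.data.shape} does not match n={self.n}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.n + 1, dtype=bool)
            if self.folded:
                self.mask[self.n // 2 + 1 :] = True
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    def copy(self) -> "Sfs1D":
        return Sfs1D(
            self.data.copy(),
            self.n,
            self.folded,
            self.mask.copy(),
            self.L,
            None if self.stderr is None else self.stderr.copy(),
        )

    @property
    def unmasked(self) -> np.ndarray:
        return self.data[~self.mask]

    def total(self) -> float:
        """Total (unmasked + masked) site count."""
        return float(self.data.sum())

    def segregating(self) -> float:
        """Sites in polymorphic classes (excludes entries 0 and n)."""
        return float(self.data[1 : self.n].sum())


@dataclass
class Sfs2D:
    """A joint two-population site-frequency spectrum (shape (n1+1, n2+1))."""

    data: np.ndarray
    n1: int
    n2: int
    folded: bool = False
    mask: np.ndarray | None = None
    L: float | None = None
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("data shape does not match (n1+1, n2+1)")
        if self.mask is None:
            self.mask = np.zeros_like(self.data, dtype=bool)
            if self.folded:
                tot = _total_grid(self.n1, self.n2)
                self.mask[tot * 2 > self.n1 + self.n2] = True
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    def copy(self) -> "Sfs2D":
        return Sfs2D(
            self.data.copy(),
            self.n1,
            self.n2,
            self.folded,
            self.mask.copy(),
            self.L,
            None if self.stderr is None else self.stderr.copy(),
        )

    def total(self) -> float:
        return float(self.data.sum())

    def marginal(self, pop: int) -> Sfs1D:
        """Sum out one population, returning the other's 1D spectrum.

        Only defined for unfolded spectra (folding does not commute with
        marginalization cell-by-cell).
        """
        if self.folded:
            raise ValueError("marginal of a folded joint spectrum is undefined")
        axis = 1 if pop == 0 else 0
        n = self.n1 if pop == 0 else self.n2
        return Sfs1D(self.data.sum(axis=axis), n, folded=False, L=self.L)


def _total_grid(n1: int, n2: int) -> np.ndarray:
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    return i + j


def fold(sfs: Sfs1D | Sfs2D):
    """Fold a spectrum onto minor-allele orientation.

    Entry ``i`` receives ``entry(n - i)`` for ``i < n/2``; the central class
    (when ``n`` is even) is left as is.  Folding a folded spectrum is a no-op
    with a warning.  The total site count is conserved.
    """
    if sfs.folded:
        warnings.warn("spectrum is already folded; returning a copy")
        return sfs.copy()
    if isinstance(sfs, Sfs1D):
        n = sfs.n
        data = sfs.data.copy()
        mask = sfs.mask.copy()
        for i in range(n // 2 + 1, n + 1):
            data[n - i] += data[i]
            mask[n - i] = mask[n - i] | mask[i]
            data[i] = 0.0
            mask[i] = True
        return Sfs1D(data, n, folded=True, mask=mask, L=sfs.L)
    n1, n2 = sfs.n1, sfs.n2
    S = n1 + n2
    data = sfs.data.copy()
    mask = sfs.mask.copy()
    tot = _total_grid(n1, n2)
    # cells strictly past the midpoint fold onto their complement
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if tot[i, j] * 2 > S:
                data[n1 - i, n2 - j] += data[i, j]
                mask[n1 - i, n2 - j] |= mask[i, j]
                data[i, j] = 0.0
                mask[i, j] = True
    # ambiguous diagonal (total == S/2): aggregate each complement pair once
    if S % 2 == 0:
        for i in range(n1 + 1):
            j = S // 2 - i
            if 0 <= j <= n2:
                ci, cj = n1 - i, n2 - j
                if (i, j) < (ci, cj):
                    data[i, j] += data[ci, cj]
                    mask[i, j] |= mask[ci, cj]
                    data[ci, cj] = 0.0
                    mask[ci, cj] = True
    return Sfs2D(data, n1, n2, folded=True, mask=mask, L=sfs.L)


def apply_mask(sfs: Sfs1D | Sfs2D, rule: str = "singletons_and_full"):
    """Mask uninformative frequency classes.

    ``singletons_and_full`` masks the monomorphic classes and the classes in
    which the variant is carried by a single sampled chromosome (minor-allele
    count 1).  Idempotent.
    """
    if rule != "singletons_and_full":
        raise ValueError(f"unknown mask rule: {rule!r}")
    out = sfs.copy()
    if isinstance(sfs, Sfs1D):
        n = sfs.n
        out.mask[0] = True
        out.mask[1] = True
        if not sfs.folded:
            out.mask[n] = True
            out.mask[n - 1] = True
        return out
    S = sfs.n1 + sfs.n2
    tot = _total_grid(sfs.n1, sfs.n2)
    sel = (tot <= 1) | (tot >= S - 1)
    out.mask |= sel
    return out


# ---------------------------------------------------------------------------
# Projection

def projection_weights(n_from: int, n_to: int, hits: int) -> np.ndarray:
    """Hypergeometric weights for down-projecting ``hits`` of ``n_from``
    alleles onto a subsample of ``n_to`` alleles.  Weights sum to 1."""
    if n_to > n_from:
        raise ValueError("cannot project up")
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j, n_from, hits, n_to)


def project_sfs_1d(sfs: Sfs1D, n_to: int) -> Sfs1D:
    """Project an unfolded 1D spectrum down to haploid size ``n_to``."""
    if sfs.folded:
        raise ValueError("project before folding")
    if n_to > sfs.n:
        raise ValueError("projection size exceeds sample size")
    data = np.zeros(n_to + 1)
    for i in range(sfs.n + 1):
        if sfs.data[i]:
            data += sfs.data[i] * projection_weights(sfs.n, n_to, i)
    return Sfs1D(data, n_to, folded=False, L=sfs.L)


# ---------------------------------------------------------------------------
# Text I/O (single-population and joint spectra share one format: a header
# line with the array shape and fold state, an entries line, and a 0/1 mask
# line, as used by diffusion-based SFS inference tools)

def write_sfs(sfs: Sfs1D | Sfs2D, path) -> None:
    with open(path, "w") as fh:
        if sfs.L is not None:
            fh.write(f"# L = {sfs.L!r}\n")
        state = "folded" if sfs.folded else "unfolded"
        if isinstance(sfs, Sfs1D):
            fh.write(f"{sfs.n + 1} {state}\n")
        else:
            fh.write(f"{sfs.n1 + 1} {sfs.n2 + 1} {state}\n")
        flat = np.ravel(sfs.data)
        if np.allclose(flat, np.round(flat)):
            fh.write(" ".join(str(int(round(x))) for x in flat) + "\n")
        else:
            fh.write(" ".join(repr(float(x)) for x in flat) + "\n")
        fh.write(" ".join("1" if m else "0" for m in np.ravel(sfs.mask)) + "\n")


def read_sfs(path) -> Sfs1D | Sfs2D:
    L = None
    with open(path) as fh:
        lines = []
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if line.startswith("# L ="):
                    L = float(line.split("=", 1)[1])
                continue
            if line:
                lines.append(line)
    header = lines[0].split()
    shape = [int(x) for x in header[:-1]]
    folded = header[-1] == "folded"
    data = np.array([float(x) for x in lines[1].split()])
    mask = np.array([x == "1" for x in lines[2].split()])
    if len(shape) == 1:
        return Sfs1D(data, shape[0] - 1, folded=folded, mask=mask, L=L)
    data = data.reshape(shape)
    mask = mask.reshape(shape)
    return Sfs2D(data, shape[0] - 1, shape[1] - 1, folded=folded, mask=mask, L=L)
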