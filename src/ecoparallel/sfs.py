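"""Folded site-frequency-spectrum containers and text I/O.

The folded SFS is the unit of demographic inference here: with no outgroup
the ancestral allele is unknown, so sites are summarized by minor-allele
counts.  One-dimensional spectra are indexed 0..n//2 (class 0 = monomorphic);
joint two-dimensional spectra are (n1+1) x (n2+1) matrices with the redundant
half zeroed by the folding map.

The text dialect mirrors the fastsimcoal2 ``.obs`` layout: a first line
``1 observations``, then a tab-separated matrix with column labels ``d0_i``
(first population) and row labels ``d1_j`` (second population).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FoldedSFS",
    "JointFoldedSFS",
    "read_sfs_obs",
    "write_sfs_obs",
    "read_jsfs_obs",
    "write_jsfs_obs",
]


@dataclass
class FoldedSFS:
    """1D folded spectrum: ``counts[i]`` sites with minor-allele count i."""

    counts: np.ndarray
    n: int
    pop: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != self.n // 2 + 1:
            raise ValueError(
                f"folded SFS for n={self.n} needs {self.n // 2 + 1} classes, "
                f"got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative SFS entries")

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def segregating(self) -> float:
        """Polymorphic site count (classes 1..n//2)."""
        return float(self.counts[1:].sum())


@dataclass
class JointFoldedSFS:
    """2D folded spectrum over a population pair.

    ``matrix[i, j]`` = sites with i copies of the (jointly) minor allele in
    pop1 and j in pop2.  Cells on the redundant half of the folding map are
    zero.  Entries may be fractional (Monte-Carlo expectations, tie splits).
    """

    matrix: np.ndarray
    n1: int
    n2: int
    pops: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError(
                f"jSFS shape {self.matrix.shape} does not match sample sizes "
                f"({self.n1 + 1}, {self.n2 + 1})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("negative jSFS entries")

    @property
    def n_sites(self) -> float:
        return float(self.matrix.sum())

    def polymorphic_mask(self) -> np.ndarray:
        """Cells that represent sites polymorphic within the pair.

        After folding, all monomorphic mass sits in cell (0, 0); every other
        retained cell is polymorphic.
        """
        mask = kept_half_mask(self.n1, self.n2)
        mask[0, 0] = False
        return mask

    def transpose(self) -> "JointFoldedSFS":
        return JointFoldedSFS(
            self.matrix.T.copy(), self.n2, self.n1, (self.pops[1], self.pops[0])
        )


def kept_half_mask(n1: int, n2: int) -> np.ndarray:
    """Boolean mask of cells retained by the joint folding convention.

    Keep (i, j) when i + j < (n1 + n2)/2; on the exact anti-diagonal tie keep
    the cell with the smaller first-population count, and split the double tie
    (i = n1 - i and j = n2 - j), which is its own image and is retained.
    """
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    s = i + j
    half = (n1 + n2) / 2.0
    keep = s < half
    tie = s == half
    keep |= tie & (i < n1 - i)
    keep |= tie & (i == n1 - i) & (j <= n2 - j)
    return np.broadcast_to(keep, (n1 + 1, n2 + 1)).copy()


def fold_joint_matrix(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded (derived/arbitrary-allele) joint matrix in place-free form."""
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    out = np.zeros_like(unfolded, dtype=float)
    half = (n1 + n2) / 2.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            m = unfolded[i, j]
            if m == 0:
                continue
            i2, j2 = n1 - i, n2 - j
            s = i + j
            if s < half:
                out[i, j] += m
            elif s > half:
                out[i2, j2] += m
            else:  # anti-diagonal tie
                if i < i2:
                    out[i, j] += m
                elif i > i2:
                    out[i2, j2] += m
                else:  # i == i2: double tie, self-image cell
                    out[i, j] += m
    return out


def fold_1d(unfolded: np.ndarray) -> np.ndarray:
    """Fold a 1D spectrum: class c pooled with n - c into min(c, n - c)."""
    n = len(unfolded) - 1
    out = np.zeros(n // 2 + 1, dtype=float)
    for c in range(n + 1):
        out[min(c, n - c)] += unfolded[c]
    return out


# ---------------------------------------------------------------------------
# .obs dialect I/O
# ---------------------------------------------------------------------------

def write_sfs_obs(sfs: FoldedSFS, path: str | Path) -> None:
    path = Path(path)
    labels = "\t".join(f"d0_{i}" for i in range(len(sfs.counts)))
    vals = "\t".join(repr(float(v)) for v in sfs.counts)
    path.write_text(f"1 observations\n{labels}\n{vals}\n")


def read_sfs_obs(path: str | Path, pop: str = "") -> FoldedSFS:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or "observation" not in lines[0]:
        raise ValueError(f"{path}: not an .obs SFS file")
    counts = np.array([float(x) for x in lines[2].split("\t")])
    n_classes = len(counts)
    # classes 0..n//2; the even/odd ambiguity is resolved toward even n
    n = 2 * (n_classes - 1)
    return FoldedSFS(counts, n=n, pop=pop)


def write_jsfs_obs(jsfs: JointFoldedSFS, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{i}" for i in range(jsfs.n1 + 1)) + "\n")
        for j in range(jsfs.n2 + 1):
            row = "\t".join(repr(float(jsfs.matrix[i, j])) for i in range(jsfs.n1 + 1))
            fh.write(f"d1_{j}\t{row}\n")


def read_jsfs_obs(path: str | Path, pops: tuple[str, str] = ("pop1", "pop2")) -> JointFoldedSFS:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or "observation" not in lines[0]:
        raise ValueError(f"{path}: not an .obs jSFS file")
    header = lines[1].split("\t")
    n1 = len([h for h in header if h.startswith("d0_")]) - 1
    rows = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        rows.append([float(x) for x in parts[1:]])
    mat = np.array(rows).T  # stored rows = pop2 classes
    n2 = mat.shape[1] - 1
    return JointFoldedSFS(mat, n1=n1, n2=n2, pops=pops)


def read_jsfs_long_tsv(path: str | Path, n1: int, n2: int,
                       pops: tuple[str, str] = ("pop1", "pop2")) -> JointFoldedSFS:
    """Long-format alternative: columns pop1_count, pop2_count, n_sites."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    mat = np.zeros((n1 + 1, n2 + 1))
    for _, row in df.iterrows():
        mat[int(row["pop1_count"]), int(row["pop2_count"])] += float(row["n_sites"])
    return JointFoldedSFS(mat, n1=n1, n2=n2, pops=pops)


def write_jsfs_long_tsv(jsfs: JointFoldedSFS, path: str | Path) -> None:
    import pandas as pd

    ii, jj = np.nonzero(jsfs.matrix)
    pd.DataFrame(
        {"pop1_count": ii, "pop2_count": jj, "n_sites": jsfs.matrix[ii, jj]}
    ).to_csv(path, sep="\t", index=False)
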