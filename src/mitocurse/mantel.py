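"""Distance matrices and the Mantel permutation test.

Genetic distances between mitochondrial haplotypes are pairwise SNP counts
from an alignment of the mtDNA protein-coding region (the hypervariable
control region is masked out because short reads map poorly to it, so calls
there are unreliable).  Phenotypic distances are absolute differences of
line means within one nucleus x sex group.  Their association is assessed
with a Mantel test: the Pearson correlation of the lower-triangle entries,
with significance from jointly permuting the rows and columns of one matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix


class MantelError(ValueError):
    """Raised for degenerate or mismatched distance-matrix input."""


_VALID_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mask_array(length: int, mask: "list[tuple[int, int]] | None") -> np.ndarray:
    keep = np.ones(length, dtype=bool)
    for start, end in mask or ():
        if not (0 <= start <= end <= length):
            raise MantelError(
                f"mask interval [{start}, {end}) outside sequence bounds [0, {length})"
            )
        keep[start:end] = False
    return keep


def snp_distance_matrix(
    alignment_path, mask: "list[tuple[int, int]] | None" = None
) -> DistanceMatrix:
    """Pairwise SNP-count matrix from an aligned multi-FASTA.

    Entry (i, j) counts alignment positions, outside every mask interval
    (zero-based, half-open), where sequences i and j carry different
    unambiguous bases.  Positions where either sequence has a gap or an
    ambiguity code are excluded for that pair.
    """
    records = list(SeqIO.parse(str(alignment_path), "fasta"))
    if len(records) < 2:
        raise MantelError("alignment must contain at least two sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MantelError(f"duplicate FASTA identifiers: {dupes}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MantelError(
            f"sequences are not aligned (lengths {sorted(lengths)}); "
            "equal lengths required"
        )
    length = lengths.pop()
    keep = _mask_array(length, mask)

    seqs = np.array(
        [np.frombuffer(str(r.seq).upper().encode(), dtype="S1") for r in records]
    )
    seqs = seqs[:, keep]
    valid = np.isin(seqs, _VALID_BASES)

    k = len(records)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            mat[i, j] = mat[j, i] = np.sum((seqs[i] != seqs[j]) & both)
    return DistanceMatrix(mat, ids=ids)


def phenotypic_divergence_matrix(
    means: pd.DataFrame, nuc: str, sex: str
) -> DistanceMatrix:
    """Pairwise |difference of mitochondrial line means| within (nuc, sex).

    Labels are restricted to haplotypes actually observed for that group
    (a nucleus with an inviable cell contributes one fewer haplotype).
    """
    try:
        group = means.loc[(nuc, sex)]
    except KeyError:
        raise MantelError(f"no line means for (nuc={nuc!r}, sex={sex!r})") from None
    labels = list(group.index)
    vals = group["mean"].to_numpy(dtype=float)
    if len(labels) < 3:
        raise MantelError(
            f"(nuc={nuc!r}, sex={sex!r}) has {len(labels)} haplotypes; "
            "a Mantel test needs >= 3"
        )
    mat = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(mat, ids=labels)


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix correlation with its permutation null."""

    r_obs: float
    p_value: float
    n_perm: int
    alternative: str
    n_labels: int
    null_mean: float
    null_sd: float

    def as_dict(self) -> dict:
        return {
            "r": self.r_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "alternative": self.alternative,
            "n_labels": self.n_labels,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
        }


def _tri_pearson(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson correlation of x against each row of ys."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=-1, keepdims=True)
    num = yc @ xc
    den = np.sqrt(np.sum(xc**2) * np.sum(yc**2, axis=-1))
    return num / den


def mantel_test(
    genetic: DistanceMatrix,
    phenotypic: DistanceMatrix,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel test between two labelled distance matrices.

    Labels are intersected and both matrices reordered to the shared set.
    ``r_obs`` is the Pearson correlation of lower-triangle entries; the null
    is built by jointly permuting rows and columns of the second matrix
    ``n_perm`` times, and the p-value uses the add-one estimator
    ``(1 + #extreme) / (1 + n_perm)`` so it is never zero.
    """
    if alternative not in ("greater", "two-sided"):
        raise MantelError(f"unknown alternative {alternative!r}")
    shared = [i for i in genetic.ids if i in set(phenotypic.ids)]
    if len(shared) < 3:
        raise MantelError(
            f"only {len(shared)} shared labels between matrices; need >= 3"
        )
    a = genetic.filter(shared).data
    b = phenotypic.filter(shared).data
    k = len(shared)
    ii, jj = np.tril_indices(k, -1)
    x = a[ii, jj]
    y = b[ii, jj]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MantelError("constant distance matrix: Mantel correlation undefined")

    r_obs = float(_tri_pearson(x, y[None, :])[0])

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, k)), axis=1)
    y_perm = b[perms[:, ii], perms[:, jj]]
    r_null = _tri_pearson(x, y_perm)

    # ties count as extreme (conservative); the epsilon guards against
    # float jitter between the vectorized null and the observed statistic
    tol = 1e-12
    if alternative == "greater":
        extreme = int(np.sum(r_null >= r_obs - tol))
    else:
        extreme = int(np.sum(np.abs(r_null) >= abs(r_obs) - tol))
    p = (1 + extreme) / (1 + n_perm)
    return MantelResult(
        r_obs=r_obs,
        p_value=float(p),
        n_perm=int(n_perm),
        alternative=alternative,
        n_labels=k,
        null_mean=float(r_null.mean()),
        null_sd=float(r_null.std(ddof=1)),
    )
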