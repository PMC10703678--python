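"""Gene-family occupancy classes, pan/core rarefaction and alignment diversity.

Occupancy classes generalize the N=32 rule: a family present in all N
genomes is core; in N-2..N-1 softcore; in exactly 1 private; otherwise
dispensable.  For small N the windows can collide; precedence is
core -> softcore -> private -> dispensable.

Per-family nucleotide diversity uses the alignment formula
pi = D / L / (N * (N - 1) / 2), where D is the total number of pairwise
mismatches over the conserved (gap-free) columns, L the number of such
columns and N the number of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("core", "softcore", "dispensable", "private")


@dataclass
class OccupancyMatrix:
    """Binary families x genomes presence table."""

    table: pd.DataFrame    # index: family ids; columns: genome ids; values 0/1

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occupancy entries must be 0/1")
        zero = self.table.sum(axis=1) == 0
        if zero.any():
            bad = self.table.index[zero][0]
            raise ValueError(f"family {bad!r} present in no genome")

    @property
    def n_genomes(self) -> int:
        return self.table.shape[1]

    @property
    def n_families(self) -> int:
        return self.table.shape[0]


def classify_occupancy(matrix: OccupancyMatrix,
                       softcore_margin: int = 2) -> pd.Series:
    """Per-family class from occupancy counts (precedence for small N)."""
    N = matrix.n_genomes
    if N < 4:
        raise ValueError("need at least 4 genomes to classify occupancy")
    k = matrix.table.sum(axis=1)
    out = pd.Series("dispensable", index=matrix.table.index, name="class")
    out[k == N] = "core"
    out[(k >= N - softcore_margin) & (k < N)] = "softcore"
    out[(k == 1) & (out == "dispensable")] = "private"
    return out


def class_counts(classes: pd.Series) -> dict[str, int]:
    return {c: int((classes == c).sum()) for c in CLASSES}


def class_shares(counts: dict[str, int]) -> dict[str, float]:
    """Percentage share of each occupancy class among all families."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no families")
    return {c: 100.0 * n / total for c, n in counts.items()}


def rarefaction(matrix: OccupancyMatrix, n_draws: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Pan and core family counts over random genome subsamples.

    For each subsample size k = 1..N, ``n_draws`` uniform draws without
    replacement; pan counts families present in >= 1 sampled genome,
    core counts families present in all k.  Returns per-k mean and
    standard deviation of both curves.
    """
    rng = np.random.default_rng(seed)
    N = matrix.n_genomes
    presence = matrix.table.to_numpy(dtype=bool)
    rows = []
    for k in range(1, N + 1):
        pans = np.empty(n_draws)
        cores = np.empty(n_draws)
        for d in range(n_draws):
            cols = rng.choice(N, size=k, replace=False)
            sub = presence[:, cols]
            pans[d] = sub.any(axis=1).sum()
            cores[d] = sub.all(axis=1).sum()
        rows.append({"k": k, "pan_mean": pans.mean(), "pan_sd": pans.std(ddof=0),
                     "core_mean": cores.mean(), "core_sd": cores.std(ddof=0)})
    return pd.DataFrame(rows)


@dataclass
class MultipleAlignment:
    """Equal-length aligned sequences (gaps as '-')."""

    sequences: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def n(self) -> int:
        return len(self.sequences)


def alignment_pi(msa: MultipleAlignment) -> float:
    """pi = D / L / (N*(N-1)/2) over gap-free (conserved) columns."""
    N = msa.n
    if N < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s.upper()) for s in msa.sequences])
    conserved = ~np.any((arr == "-") | (arr == "N"), axis=0)
    L = int(conserved.sum())
    if L == 0:
        raise ValueError("no conserved (gap-free) columns: pi undefined")
    sub = arr[:, conserved]
    D = 0
    for i in range(N):
        for j in range(i + 1, N):
            D += int((sub[i] != sub[j]).sum())
    return D / L / (N * (N - 1) / 2)


def occupancy_from_orthogroups(path: str) -> OccupancyMatrix:
    """OrthoFinder Orthogroups.tsv dialect -> binary occupancy matrix.

    First column: orthogroup id; remaining columns: per-genome
    comma-separated gene lists (empty when absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    presence = df.notna() & (df.astype(str).apply(lambda c: c.str.strip() != ""))
    return OccupancyMatrix(presence.astype(int))
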