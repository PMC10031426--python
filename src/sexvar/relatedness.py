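"""Expected-relatedness matrices from pedigrees.

Four kernels drive the variance decomposition:

* ``A`` — autosomal numerator relationship matrix, by the tabular recursion
  ``a_ij = (a_{i,sire(j)} + a_{i,dam(j)}) / 2`` with diagonal
  ``1 + a_{sire(j),dam(j)} / 2``.
* ``D`` — dominance relatedness under the non-inbred approximation,
  ``d_ij = (a_{s(i)s(j)} a_{d(i)d(j)} + a_{s(i)d(j)} a_{d(i)s(j)}) / 4``.
* ``X`` — X-linked relatedness from sex-specific transmission (sons take their
  single X from the dam; daughters take the sire's X and one of the dam's).
  Entries are ``2 * phi_X`` between females, ``phi_X`` between males, and
  ``sqrt(2) * phi_X`` cross-sex, where ``phi_X`` is the X-kinship coefficient.
  The cross-sex scaling only makes the stored matrix positive semi-definite;
  the animal model fixes the cross-sex X covariance to zero and never uses it.
  No dosage-compensation factor is applied: scale differences between
  hemizygous males and diploid females are absorbed by the sex-specific
  X-linked variance parameters.
* ``Y`` — patriline membership: 1 between males connected by father->son
  chains to the same male founder, else 0; all-female entries 0.  The
  non-recombining Y behaves as a single haplotype shared along patrilines.

A Monte-Carlo gene-dropping oracle (:func:`gene_drop_oracle`) estimates every
kernel directly from simulated transmission and serves as ground truth in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree

KINDS = ("A", "D", "X", "Y")


@dataclass
class RelatednessMatrix:
    """Symmetric expected-relatedness matrix over the pedigree's individuals."""

    kind: str
    ids: list[str]
    values: np.ndarray
    stderr: np.ndarray | None = None  # per-entry Monte-Carlo SE, oracle only

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.values = np.asarray(self.values, dtype=float)

    def loc(self, i: str, j: str) -> float:
        ii, jj = self.ids.index(i), self.ids.index(j)
        return float(self.values[ii, jj])


def additive_matrix(ped: Pedigree) -> RelatednessMatrix:
    """Autosomal numerator relationship matrix (tabular method)."""
    n = len(ped)
    parents = ped.parent_indices()
    a = np.zeros((n, n))
    for j in range(n):
        s, d = parents[j]
        if s < 0:  # founder
            a[j, j] = 1.0
            continue
        a[:j, j] = 0.5 * (a[:j, s] + a[:j, d])
        a[j, :j] = a[:j, j]
        a[j, j] = 1.0 + 0.5 * a[s, d]
    return RelatednessMatrix("A", ped.ids, a)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-individual autosomal inbreeding coefficients F (diag(A) - 1)."""
    return np.diag(additive_matrix(ped).values) - 1.0


def additive_inverse(ped: Pedigree, sparse: bool = False):
    """Inverse of the numerator relationship matrix.

    Built directly from parent triplets (Henderson's rules with inbreeding):
    each individual contributes 1/d_j to (j,j), -1/(2 d_j) to (j, parent) and
    1/(4 d_j) to the parent block, where d_j is its Mendelian-sampling
    variance.  The result is sparse by construction; pass ``sparse=True`` for
    a CSR matrix instead of a dense array.
    """
    n = len(ped)
    parents = ped.parent_indices()
    f = inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for j in range(n):
        s, d = parents[j]
        if s < 0:
            add(j, j, 1.0)
            continue
        dj = 0.5 - 0.25 * (f[s] + f[d])  # Mendelian sampling variance
        inv = 1.0 / dj
        add(j, j, inv)
        for p in (s, d):
            add(j, p, -0.5 * inv)
            add(p, j, -0.5 * inv)
        for p in (s, d):
            for q in (s, d):
                add(p, q, 0.25 * inv)
    ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return ainv if sparse else ainv.toarray()


def dominance_matrix(ped: Pedigree, A: np.ndarray | None = None) -> RelatednessMatrix:
    """Dominance relatedness (non-inbred approximation), diagonal 1."""
    if A is None:
        A = additive_matrix(ped).values
    n = len(ped)
    parents = ped.parent_indices()
    nonf = np.where(parents[:, 0] >= 0)[0]
    d = np.zeros((n, n))
    if nonf.size:
        s = parents[nonf, 0]
        m = parents[nonf, 1]
        block = 0.25 * (A[np.ix_(s, s)] * A[np.ix_(m, m)] + A[np.ix_(s, m)] * A[np.ix_(m, s)])
        d[np.ix_(nonf, nonf)] = block
    np.fill_diagonal(d, 1.0)
    return RelatednessMatrix("D", ped.ids, d)


def x_kinship(ped: Pedigree) -> np.ndarray:
    """X-chromosome kinship matrix phi_X (probability of IBD between random
    X alleles of two individuals), founders unrelated and non-inbred."""
    n = len(ped)
    parents = ped.parent_indices()
    female = ped.sexes()
    phi = np.zeros((n, n))
    for j in range(n):
        s, d = parents[j]
        if s < 0:
            phi[j, j] = 0.5 if female[j] else 1.0
            continue
        if female[j]:
            phi[:j, j] = 0.5 * (phi[:j, s] + phi[:j, d])
            phi[j, j] = 0.5 * (1.0 + phi[s, d])
        else:
            phi[:j, j] = phi[:j, d]
            phi[j, j] = 1.0
        phi[j, :j] = phi[:j, j]
    return phi


def x_matrix(ped: Pedigree) -> RelatednessMatrix:
    """X-linked relatedness: 2*phi_X (F/F), phi_X (M/M), sqrt(2)*phi_X (F/M)."""
    phi = x_kinship(ped)
    female = ped.sexes()
    scale = np.where(female, np.sqrt(2.0), 1.0)
    values = phi * np.outer(scale, scale)
    return RelatednessMatrix("X", ped.ids, values)


def y_patrilines(ped: Pedigree) -> dict[str, str]:
    """Map each male id to its patriline label (the founding sire's id)."""
    out: dict[str, str] = {}
    for r in ped.records:
        if r.sex != "F":
            out[r.id] = r.id if r.is_founder else out[r.sire]
    return out


def y_patriline_matrix(ped: Pedigree) -> RelatednessMatrix:
    """Y-linked relatedness: patriline-membership indicator among males."""
    n = len(ped)
    lines = y_patrilines(ped)
    labels = np.array([lines.get(r.id, "") for r in ped.records], dtype=object)
    male = ~ped.sexes()
    values = (labels[:, None] == labels[None, :]) & male[:, None] & male[None, :]
    return RelatednessMatrix("Y", ped.ids, values.astype(float))


def relatedness_matrix(ped: Pedigree, kind: str) -> RelatednessMatrix:
    """Dispatch to the analytic builder for the requested kind."""
    builders = {
        "A": additive_matrix,
        "D": dominance_matrix,
        "X": x_matrix,
        "Y": y_patriline_matrix,
    }
    if kind not in builders:
        raise ValueError(f"kind must be one of {KINDS}")
    return builders[kind](ped)


# ---------------------------------------------------------------------------
# Monte-Carlo gene-dropping oracle
# ---------------------------------------------------------------------------

def _drop_autosomal(ped: Pedigree, n_reps: int, rng) -> np.ndarray:
    """Unique founder alleles dropped through the pedigree.

    Returns int array of shape (n, 2, n_reps): the two allele labels per
    individual per replicate.
    """
    n = len(ped)
    parents = ped.parent_indices()
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    label = 0
    for j in range(n):
        s, d = parents[j]
        if s < 0:
            alleles[j, 0] = 2 * label
            alleles[j, 1] = 2 * label + 1
            label += 1
            continue
        pick_s = rng.integers(0, 2, n_reps)
        pick_d = rng.integers(0, 2, n_reps)
        alleles[j, 0] = alleles[s, pick_s, np.arange(n_reps)]
        alleles[j, 1] = alleles[d, pick_d, np.arange(n_reps)]
    return alleles


def _drop_x(ped: Pedigree, n_reps: int, rng) -> np.ndarray:
    """X alleles: shape (n, 2, n_reps); males carry their X in both slots."""
    n = len(ped)
    parents = ped.parent_indices()
    female = ped.sexes()
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    label = 0
    for j in range(n):
        s, d = parents[j]
        if s < 0:
            if female[j]:
                alleles[j, 0] = 2 * label
                alleles[j, 1] = 2 * label + 1
            else:
                alleles[j, 0] = alleles[j, 1] = 2 * label
            label += 1
            continue
        pick_d = rng.integers(0, 2, n_reps)
        from_dam = alleles[d, pick_d, np.arange(n_reps)]
        if female[j]:
            alleles[j, 0] = alleles[s, 0]  # sire's single X
            alleles[j, 1] = from_dam
        else:
            alleles[j, 0] = alleles[j, 1] = from_dam
    return alleles


def _pair_kinship(ai: np.ndarray, aj: np.ndarray) -> np.ndarray:
    """Per-replicate kinship statistic: mean IBD indicator over allele pairs."""
    return 0.25 * (
        (ai[0] == aj[0]).astype(float) + (ai[0] == aj[1])
        + (ai[1] == aj[0]) + (ai[1] == aj[1])
    )


def gene_drop_oracle(ped: Pedigree, kind: str, n_reps: int = 100_000,
                     seed: int | None = None) -> RelatednessMatrix:
    """Monte-Carlo estimate of a relatedness matrix by gene dropping.

    Founders receive unique allele labels, alleles are transmitted by the
    chromosome class's rules, and IBD-sharing statistics are averaged over
    ``n_reps`` replicates.  Entries come with a per-entry standard error.
    Intended for small verification pedigrees (cost is quadratic in size and
    linear in replicates).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ped)
    female = ped.sexes()
    values = np.zeros((n, n))
    stderr = np.zeros((n, n))

    if kind == "Y":
        # patrilineal transmission is deterministic: one drop settles it
        parents = ped.parent_indices()
        hap = np.full(n, -1, dtype=np.int64)
        label = 0
        for j, rec in enumerate(ped.records):
            if female[j]:
                continue
            s = parents[j, 0]
            if s < 0:
                hap[j] = label
                label += 1
            else:
                hap[j] = hap[s]
        male = ~female
        shared = (hap[:, None] == hap[None, :]) & male[:, None] & male[None, :]
        return RelatednessMatrix("Y", ped.ids, shared.astype(float), np.zeros((n, n)))

    alleles = _drop_x(ped, n_reps, rng) if kind == "X" else _drop_autosomal(ped, n_reps, rng)

    for i in range(n):
        for j in range(i, n):
            ai, aj = alleles[i], alleles[j]
            if kind == "D":
                if i == j:
                    values[i, j] = 1.0
                    continue
                stat = (
                    ((ai[0] == aj[0]) & (ai[1] == aj[1]))
                    | ((ai[0] == aj[1]) & (ai[1] == aj[0]))
                ).astype(float)
            else:
                if i == j:
                    # self-kinship from the two own alleles' IBD status
                    if kind == "X" and not female[i]:
                        stat = np.ones(n_reps)
                    else:
                        stat = 0.5 * (1.0 + (ai[0] == ai[1]))
                else:
                    stat = _pair_kinship(ai, aj)
            m = float(stat.mean())
            se = float(stat.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.inf
            if kind == "A":
                m, se = 2 * m, 2 * se
            elif kind == "X":
                sc = (np.sqrt(2.0) if female[i] else 1.0) * (np.sqrt(2.0) if female[j] else 1.0)
                m, se = sc * m, sc * se
            values[i, j] = values[j, i] = m
            stderr[i, j] = stderr[j, i] = se
    return RelatednessMatrix(kind, ped.ids, values, stderr)
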