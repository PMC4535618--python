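"""Genotype similarity and K2P/neighbour-joining population structure.

Two complementary views of cohort structure:

* a pairwise similarity matrix — the fraction of SNPs at which two animals
  carry the identical unphased genotype, computed over sites where both
  calls are present;
* an unrooted neighbour-joining tree over Kimura two-parameter (K2P)
  distances, one tip per animal.  Transition (P) and transversion (Q)
  difference proportions between two animals are averaged over the four
  cross-haplotype comparisons of their phased genotypes, and

      d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).

The NJ implementation is the classic Saitou–Nei agglomeration (minimise
the Q-criterion, join, reduce), with deterministic lowest-index
tie-breaking and negative branch lengths clamped to zero (the deficit
moved to the sibling branch).  On an additive matrix it reproduces the
generating tree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "similarity_matrix",
    "k2p_distance",
    "pairwise_k2p",
    "nj_tree",
    "load_genotypes",
    "K2PInputs",
]


@dataclass(frozen=True)
class K2PInputs:
    """Per-pair transition/transversion difference proportions."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("need P, Q >= 0 and P + Q <= 1")


def load_genotypes(vcf_path: str):
    """Read a GT VCF into (samples, dosage matrix, phased haplotypes, site table).

    Dosages are (n_samples, n_sites) with 0/1/2 and -1 for missing; the
    haplotype matrix is (2*n_samples, n_sites) (allele order as written,
    meaningful when GT is phased).  The site table has chrom/pos/ref/alt.
    Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    dos, haps, rows = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        a1 = np.array([x[0] for x in v.genotypes], dtype=np.int8)
        a2 = np.array([x[1] for x in v.genotypes], dtype=np.int8)
        d = np.where((a1 < 0) | (a2 < 0), -1, a1 + a2).astype(np.int8)
        dos.append(d)
        haps.append(np.stack([a1, a2], axis=1).reshape(-1))
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.array(dos, dtype=np.int8).T  # (n_samples, n_sites)
    hap = np.array(haps, dtype=np.int8).T  # (2*n_samples, n_sites)
    return samples, dosage, hap, sites


def similarity_matrix(
    dosages: np.ndarray, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise genotype identity: same-genotype sites / comparable sites.

    ``dosages`` is (n_samples, n_sites) coded 0/1/2 with -1 for missing;
    each pair is compared over sites where both calls are non-missing.
    Raises when a pair shares no comparable site.  Result is symmetric with
    unit diagonal and invariant to site and sample order.
    """
    n = dosages.shape[0]
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n)]
    sim = np.ones((n, n))
    valid = dosages >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({labels[i]}, {labels[j]})")
            same = int((dosages[i, both] == dosages[j, both]).sum())
            sim[i, j] = sim[j, i] = same / m
    return pd.DataFrame(sim, index=labels, columns=labels)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are the transition and transversion difference proportions.
    Raises when the pair is saturated (log-domain violation)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"K2P distance undefined (saturated pair): P={P:.4f}, Q={Q:.4f}"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _transition_mask(sites: pd.DataFrame) -> np.ndarray:
    ref = sites["ref"].str.upper()
    alt = sites["alt"].str.upper()
    return (
        ((ref == "A") & (alt == "G"))
        | ((ref == "G") & (alt == "A"))
        | ((ref == "C") & (alt == "T"))
        | ((ref == "T") & (alt == "C"))
    ).to_numpy()


def pairwise_k2p(
    haplotypes: np.ndarray,
    sites: pd.DataFrame,
    labels: Sequence[str] | None = None,
    return_pq: bool = False,
):
    """K2P distance matrix over individuals from phased haplotypes.

    ``haplotypes`` is (2*n_individuals, n_sites) of 0/1 alleles; whether a
    differing site counts toward P (transition) or Q (transversion) is
    decided by the site's ref/alt base pair.  For each pair of individuals
    the difference proportions are averaged over the 4 cross-haplotype
    comparisons, then converted with :func:`k2p_distance`.
    """
    n2, n_sites = haplotypes.shape
    if n2 % 2:
        raise ValueError("haplotype matrix must have an even number of rows")
    n = n2 // 2
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n)]
    ti = _transition_mask(sites)
    if len(ti) != n_sites:
        raise ValueError("site table does not match haplotype matrix width")
    h = haplotypes.astype(bool)
    D = np.zeros((n, n))
    pq_rows = []
    for i in range(n):
        for j in range(i + 1, n):
            p_acc = q_acc = 0
            for a in (h[2 * i], h[2 * i + 1]):
                for b in (h[2 * j], h[2 * j + 1]):
                    diff = a ^ b
                    p_acc += int((diff & ti).sum())
                    q_acc += int((diff & ~ti).sum())
            P = p_acc / (4 * n_sites)
            Q = q_acc / (4 * n_sites)
            D[i, j] = D[j, i] = k2p_distance(P, Q)
            if return_pq:
                pq_rows.append((labels[i], labels[j], P, Q, n_sites))
    dm = pd.DataFrame(D, index=labels, columns=labels)
    if return_pq:
        return dm, pd.DataFrame(pq_rows, columns=["a", "b", "P", "Q", "n_sites"])
    return dm


def pairwise_k2p_unphased(
    dosages: np.ndarray,
    sites: pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """K2P distances from unphased genotypes (approximation).

    A het-vs-hom comparison counts as a 0.5 difference and opposite
    homozygotes as 1.0, credited to the site's Ti or Tv bin; missing calls
    are excluded pairwise (per-pair denominator).  Use
    :func:`pairwise_k2p` when phased haplotypes are available.
    """
    n = dosages.shape[0]
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n)]
    ti = _transition_mask(sites)
    valid = dosages >= 0
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({labels[i]}, {labels[j]})")
            diff = np.abs(dosages[i] - dosages[j]) / 2.0
            diff[~both] = 0.0
            P = float(diff[ti & both].sum()) / m
            Q = float(diff[~ti & both].sum()) / m
            D[i, j] = D[j, i] = k2p_distance(P, Q)
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=()):
        self.label = label
        self.children = list(children)  # (child, branch_length)

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if not self.children:
            return str(self.label)
        inner = ",".join(f"{c._fmt()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(distances: pd.DataFrame) -> str:
    """Saitou–Nei neighbour joining; returns an unrooted Newick string.

    Joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j at each
    step (first minimum in row-major order on ties), computes the two
    branch lengths, and reduces the matrix; the final three nodes are
    joined at an unresolved (trifurcating) root, as is conventional for an
    unrooted NJ tree.  Negative branch lengths are clamped to zero with the
    deficit transferred to the sibling branch.
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    D = distances.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("invalid distance matrix")
    nodes: list[_Node] = [_Node(label=l) for l in labels]
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first min, row-major
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (n - 2))
        lj = d_ij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
    # root: join the last three at a trifurcation (three-point formulas)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    branches = [b0, b1, b2]
    for k in range(3):
        if branches[k] < 0:
            for m in range(3):
                if m != k:
                    branches[m] += branches[k] / 2
            branches[k] = 0.0
    root = _Node(children=list(zip(nodes, branches)))
    return root.newick()
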