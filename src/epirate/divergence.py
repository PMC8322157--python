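"""Pedigree divergence times and pairwise methylation divergence.

A mutation-accumulation pedigree is a tree of single-seed-descent selfing
events: each parent->child edge is one selfing generation, the line is
propagated through one sibling while another sibling is sequenced.  The
divergence time between two sequenced plants is the number of independent
selfing events separating them through their most recent common ancestor.

The genome-wide methylation divergence between plants i and j is

    D_ij = (1/N) * sum_n d_ij,n

where d_ij,n is 1 for discordant calls {M, U}, 0.5 when exactly one of the
two calls is intermediate, and 0 for identical calls.  d is a metric on
{U, I, M} (it equals half the distance between the states coded 0/1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

_STATUS_CODE = {"U": 0, "I": 1, "M": 2}


@dataclass
class PedigreeNode:
    node_id: str
    generation: int
    parent: str | None
    sequenced: bool


@dataclass
class Pedigree:
    """A selfing pedigree: single founder, one parent per node, one
    generation per edge."""

    nodes: dict[str, PedigreeNode] = field(default_factory=dict)

    def add_node(
        self,
        node_id: str,
        generation: int,
        parent: str | None = None,
        sequenced: bool = False,
    ) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        if parent is not None:
            if parent not in self.nodes:
                raise ValueError(f"parent {parent!r} of {node_id!r} not yet defined")
            pgen = self.nodes[parent].generation
            if generation != pgen + 1:
                raise ValueError(
                    f"node {node_id!r}: generation {generation} is not "
                    f"parent generation {pgen} + 1"
                )
        self.nodes[node_id] = PedigreeNode(node_id, generation, parent, sequenced)

    @property
    def founder(self) -> str:
        roots = [n.node_id for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"pedigree must have exactly one founder, found {roots}")
        return roots[0]

    @property
    def sequenced_samples(self) -> list[str]:
        return sorted(
            (n.node_id for n in self.nodes.values() if n.sequenced),
            key=lambda i: (self.nodes[i].generation, i),
        )

    def topological_order(self) -> list[str]:
        """Node ids ordered parents-before-children."""
        return sorted(self.nodes, key=lambda i: (self.nodes[i].generation, i))

    def _ancestor_depths(self, node_id: str) -> dict[str, int]:
        if node_id not in self.nodes:
            raise KeyError(f"node {node_id!r} not in pedigree")
        depths = {}
        cur, d = node_id, 0
        while cur is not None:
            depths[cur] = d
            cur = self.nodes[cur].parent
            d += 1
        return depths

    def mrca(self, i: str, j: str) -> str:
        anc_i = self._ancestor_depths(i)
        cur = j
        while cur is not None:
            if cur in anc_i:
                return cur
            cur = self.nodes[cur].parent
        raise ValueError(f"no common ancestor of {i!r} and {j!r}")

    def branch_lengths(self, i: str, j: str) -> tuple[int, int]:
        """Selfing generations from each of i, j up to their MRCA."""
        if i == j:
            raise ValueError("branch lengths require two distinct samples")
        m = self.mrca(i, j)
        anc_i = self._ancestor_depths(i)
        anc_j = self._ancestor_depths(j)
        return anc_i[m], anc_j[m]

    def delta_t(self, i: str, j: str) -> int:
        """Divergence time: independent selfing events through the MRCA."""
        t_i, t_j = self.branch_lengths(i, j)
        return t_i + t_j


@dataclass
class DivergenceRecord:
    sample_i: str
    sample_j: str
    delta_t: int
    t_i: int
    t_j: int
    divergence: float
    n_regions: int
    context: str = "CG"


def status_distance(status_i: np.ndarray, status_j: np.ndarray) -> np.ndarray:
    """Per-region divergence weights: |code_i - code_j| / 2 with U,I,M coded
    0,1,2 — i.e. 1 for {M,U}, 0.5 when exactly one call is I, 0 for ties."""
    ci = np.vectorize(_STATUS_CODE.get)(np.asarray(status_i))
    cj = np.vectorize(_STATUS_CODE.get)(np.asarray(status_j))
    return np.abs(ci - cj) / 2.0


def pair_divergence(
    status_i: np.ndarray, status_j: np.ndarray
) -> tuple[float, int]:
    """Mean divergence over retained regions; returns (D_ij, N)."""
    si = np.asarray(status_i)
    sj = np.asarray(status_j)
    if si.shape != sj.shape:
        raise ValueError("call vectors differ in length (missing calls?)")
    if si.size == 0:
        raise ValueError("no retained regions")
    d = status_distance(si, sj)
    return float(d.mean()), int(si.size)


def divergence_table(
    pedigree: Pedigree,
    status: pd.DataFrame,
    retained: pd.Series | None = None,
    context: str = "CG",
) -> pd.DataFrame:
    """One divergence record per unordered pair of sequenced samples.

    ``status`` is a region x sample DataFrame of U/I/M calls; rows are
    restricted to ``retained`` when given.
    """
    samples = pedigree.sequenced_samples
    if len(samples) < 2:
        raise ValueError("need at least two sequenced samples")
    missing = set(samples) - set(status.columns)
    if missing:
        raise ValueError(f"calls missing for sequenced samples: {sorted(missing)}")
    if retained is not None:
        status = status.loc[retained.reindex(status.index).fillna(False).astype(bool)]
    records = []
    for i, j in combinations(samples, 2):
        t_i, t_j = pedigree.branch_lengths(i, j)
        d, n = pair_divergence(status[i].to_numpy(), status[j].to_numpy())
        records.append(
            DivergenceRecord(i, j, t_i + t_j, t_i, t_j, d, n, context)
        )
    return pd.DataFrame(
        {
            "sample_i": [r.sample_i for r in records],
            "sample_j": [r.sample_j for r in records],
            "delta_t": [r.delta_t for r in records],
            "t_i": [r.t_i for r in records],
            "t_j": [r.t_j for r in records],
            "divergence": [r.divergence for r in records],
            "n_regions": [r.n_regions for r in records],
            "context": [r.context for r in records],
        }
    )


def pair_weight_matrix(
    pedigree: Pedigree,
    status: pd.DataFrame,
    retained: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-region divergence weights for every sequenced pair.

    Returns (t_i, t_j, W, m_frac): branch-length arrays over pairs, the
    (n_regions x n_pairs) matrix of per-region divergence weights, and each
    region's fraction of M calls across samples.  Column means of W are the
    observed pairwise divergences; resampling rows gives the region-level
    bootstrap, which propagates the correlation between pairs that share
    regions.
    """
    samples = pedigree.sequenced_samples
    if retained is not None:
        status = status.loc[retained.reindex(status.index).fillna(False).astype(bool)]
    codes = status[samples].apply(lambda col: col.map(_STATUS_CODE)).to_numpy(dtype=float)
    pairs = list(combinations(range(len(samples)), 2))
    ti = np.empty(len(pairs), dtype=int)
    tj = np.empty(len(pairs), dtype=int)
    W = np.empty((codes.shape[0], len(pairs)), dtype=np.float32)
    for k, (a, b) in enumerate(pairs):
        ti[k], tj[k] = pedigree.branch_lengths(samples[a], samples[b])
        W[:, k] = np.abs(codes[:, a] - codes[:, b]) / 2.0
    m_frac = (codes == 2).mean(axis=1)
    return ti, tj, W, m_frac


def state_frequencies(
    status: pd.DataFrame, retained: pd.Series | None = None
) -> np.ndarray:
    """Observed (U, I, M) call frequencies pooled over retained regions and
    samples — the empirical counterpart of the inheritance model's
    stationary distribution."""
    if retained is not None:
        status = status.loc[retained.reindex(status.index).fillna(False).astype(bool)]
    vals = status.to_numpy().ravel()
    return np.array([(vals == s).mean() for s in ("U", "I", "M")])


def status_change_summary(
    status: pd.DataFrame, generations: dict[str, int]
) -> tuple[int, float]:
    """Count regions that switch between the U and M poles along a
    time-ordered branch, and the fraction that stay switched.

    A region "changed" if both U and M appear among its calls across the
    ordered samples (intermediate-only excursions do not count).  Among
    changed regions, one is "stable" if, after its first U<->M transition,
    no later sampled generation reverts to the original pole; intermediate
    calls are ignored for stability.

    Returns (n_changed, fraction_stable); the fraction is NaN when nothing
    changed.
    """
    samples = list(status.columns)
    gens = [generations[s] for s in samples]
    if len(set(gens)) != len(gens):
        raise ValueError("samples are not totally ordered by generation")
    order = np.argsort(gens)
    mat = status.to_numpy()[:, order]
    n_changed = 0
    n_stable = 0
    for row in mat:
        poles = [s for s in row if s in ("U", "M")]
        if "U" not in poles or "M" not in poles:
            continue
        n_changed += 1
        first = poles[0]
        flip_at = next(k for k, s in enumerate(poles) if s != first)
        after = poles[flip_at:]
        if all(s == after[0] for s in after):
            n_stable += 1
    frac = n_stable / n_changed if n_changed else float("nan")
    return n_changed, frac
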