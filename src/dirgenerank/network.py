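"""Directed gene dependency network from pairwise conditional-information tests.

For every PPI pair (A, B) both orientations are tested: a significant
CMI(A, P | B) permutation test yields the directed edge B -> A ("A's
information about the phenotype depends on B"), and symmetrically for
A -> B.  Genes with many outgoing edges modulate many partners and are the
prime driver candidates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .discretize import BinaryMatrix, BinaryPhenotype
from .information import Sidedness, _cmi_from_counts, _joint_counts, _null_cmi, _TIE_TOL
from .io import PPIEdgeList

__all__ = [
    "DependencyEdge",
    "DependencyNetwork",
    "DegreeFit",
    "build_network",
    "degree_powerlaw_fit",
    "read_network",
]


@dataclass(frozen=True)
class DependencyEdge:
    """Directed edge modulator -> dependent with its test results."""

    source: str  # modulator (B)
    target: str  # dependent (A)
    cmi: float  # observed CMI(target, P | source), bits
    p_value: float


@dataclass
class DependencyNetwork:
    edges: list[DependencyEdge]
    alpha: float
    n_perm: int
    nodes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for e in self.edges:
            if e.source == e.target:
                raise ValueError("self-loop edge")
            seen.setdefault(e.source)
            seen.setdefault(e.target)
        self.nodes = list(seen)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.cmi, e.p_value) for e in self.edges],
            columns=["source", "target", "cmi_bits", "p_value"],
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, cmi=e.cmi, p_value=e.p_value)
        return g

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_network(path, alpha: float = 0.05, n_perm: int = 0) -> DependencyNetwork:
    """Load a network TSV written by :meth:`DependencyNetwork.write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = [
        DependencyEdge(r.source, r.target, float(r.cmi_bits), float(r.p_value))
        for r in df.itertuples()
    ]
    return DependencyNetwork(edges, alpha=alpha, n_perm=n_perm)


def _pair_rng(seed: int, source: str, target: str) -> np.random.Generator:
    # dedicated stream per directed pair: results do not depend on the order
    # in which pairs are evaluated
    tag = zlib.crc32(f"{source}\t{target}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def build_network(
    bm: BinaryMatrix,
    ph: BinaryPhenotype,
    ppi: PPIEdgeList,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    sided: Sidedness = "two-sided",
) -> DependencyNetwork:
    """Test both directions of every PPI pair and keep significant edges.

    The PPI is first restricted to genes present in ``bm``; samples are
    restricted to those carrying a phenotype label.  An edge is kept when its
    permutation p-value is <= ``alpha`` (inclusive).
    """
    gene_pos = {g: i for i, g in enumerate(bm.gene_ids)}
    pairs = [p for p in ppi.pairs if p[0] in gene_pos and p[1] in gene_pos]
    if ppi.pairs and not pairs:
        raise ValueError("no PPI gene overlaps the expression matrix")
    sample_pos = {s: i for i, s in enumerate(bm.sample_ids)}
    shared = [s for s in ph.sample_ids if s in sample_pos]
    if not shared:
        raise ValueError("no samples shared between expression and phenotype")
    col_idx = np.array([sample_pos[s] for s in shared])
    ph_pos = {s: i for i, s in enumerate(ph.sample_ids)}
    p_vec = ph.labels[np.array([ph_pos[s] for s in shared])].astype(np.int64)
    bits = bm.bits[:, col_idx].astype(np.int64)

    edges: list[DependencyEdge] = []
    for g1, g2 in pairs:
        for dependent, modulator in ((g1, g2), (g2, g1)):
            a = bits[gene_pos[dependent]]
            b = bits[gene_pos[modulator]]
            rng = _pair_rng(rng_seed, modulator, dependent)
            obs = float(_cmi_from_counts(_joint_counts(a, p_vec, b)))
            null = _null_cmi(a, p_vec, b, n_perm, rng)
            upper = (1 + int((null >= obs - _TIE_TOL).sum())) / (n_perm + 1)
            lower = (1 + int((null <= obs + _TIE_TOL).sum())) / (n_perm + 1)
            if sided == "greater":
                p_val = upper
            elif sided == "less":
                p_val = lower
            else:
                p_val = min(1.0, 2.0 * min(upper, lower))
            if p_val <= alpha:
                edges.append(DependencyEdge(modulator, dependent, obs, p_val))
    return DependencyNetwork(edges, alpha=alpha, n_perm=n_perm)


@dataclass(frozen=True)
class DegreeFit:
    """Log-log least-squares fit of the degree distribution."""

    direction: str  # "in" or "out"
    exponent: float  # power-law exponent (= -slope of the log-log line)
    correlation: float  # Pearson r of the log-log points
    r_squared: float


def degree_powerlaw_fit(net: DependencyNetwork, direction: str) -> DegreeFit:
    """Fit count(degree) ~ degree^(-exponent) by linear regression in log10 space.

    Zero degrees and degrees observed in no node are excluded (their logs are
    undefined); at least 3 distinct positive degrees are required.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    g = net.to_networkx()
    degs = dict(g.in_degree()) if direction == "in" else dict(g.out_degree())
    values = np.array([d for d in degs.values() if d >= 1])
    if values.size == 0:
        raise ValueError("insufficient support: no positive degrees")
    ks, counts = np.unique(values, return_counts=True)
    if ks.size < 3:
        raise ValueError("insufficient support: fewer than 3 distinct positive degrees")
    res = stats.linregress(np.log10(ks), np.log10(counts))
    return DegreeFit(
        direction=direction,
        exponent=-float(res.slope),
        correlation=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
    )
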