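"""Modified-cosine similarity, molecular-network construction and
MASST-style filtered library search.

The modified cosine allows peak pairs to match either directly or offset by
the precursor mass difference, so structural analogues that share shifted
fragment ladders still score highly.  Intensities are square-root
transformed and L2-normalized before pairing (the convention of public
networking infrastructure); the one-to-one pairing is chosen greedily by
descending intensity product, which on realistic sparse spectra coincides
with the optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .spectrum import Peak, Spectrum

__all__ = [
    "SimilarityEdge",
    "SpectralNetwork",
    "LibraryMatch",
    "modified_cosine",
    "build_fbmn_network",
    "masst_prefilter",
    "masst_search",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected pairwise result; (node_a, node_b) stored id-sorted."""

    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float


@dataclass
class SpectralNetwork:
    graph: nx.Graph
    edges: list[SimilarityEdge] = field(default_factory=list)

    def components(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    def edges_tsv(self) -> str:
        lines = ["source\ttarget\tcosine\tmatched_peaks\tprecursor_delta"]
        for e in sorted(self.edges, key=lambda e: (e.node_a, e.node_b)):
            lines.append(
                f"{e.node_a}\t{e.node_b}\t{e.cosine:.4f}\t{e.matched_peaks}\t"
                f"{e.precursor_delta:.4f}"
            )
        return "\n".join(lines) + "\n"

    def write_graphml(self, destination) -> None:
        nx.write_graphml(self.graph, destination)


@dataclass(frozen=True)
class LibraryMatch:
    query_id: str
    library_id: str
    score: float
    matched_peaks: int


def _pairing(
    a: Spectrum, b: Spectrum, frag_tol: float, allow_shift: bool
) -> tuple[float, int]:
    """Greedy one-to-one pairing score on sqrt/L2-normalized intensities."""
    amz, bmz = a.mz_array, b.mz_array
    av = np.sqrt(a.intensity_array)
    bv = np.sqrt(b.intensity_array)
    an = np.linalg.norm(av)
    bn = np.linalg.norm(bv)
    if an == 0 or bn == 0:
        return 0.0, 0
    av, bv = av / an, bv / bn

    shift = a.precursor_mz - b.precursor_mz
    diff = amz[:, None] - bmz[None, :]
    mask = np.abs(diff) <= frag_tol
    if allow_shift:
        mask |= np.abs(diff - shift) <= frag_tol

    ii, jj = np.nonzero(mask)
    products = av[ii] * bv[jj]
    # descending product; index tie-break keeps the result deterministic
    order = np.lexsort((jj, ii, -products))

    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(products[k])
        matched += 1
    return score, matched


def modified_cosine(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02, allow_shift: bool = True
) -> tuple[float, int]:
    """Modified-cosine score in [0, 1] and the matched-peak count.

    Symmetric under argument swap (computed in a canonical order).
    ``allow_shift=False`` reduces to the plain cosine on direct matches.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("modified cosine needs two non-empty spectra")
    if frag_tol <= 0:
        raise ValueError("fragment tolerance must be positive")
    if (a.id, a.precursor_mz) > (b.id, b.precursor_mz):
        a, b = b, a
    return _pairing(a, b, frag_tol, allow_shift)


def build_fbmn_network(
    spectra: list[Spectrum],
    min_cosine: float = 0.65,
    min_matched: int = 7,
    top_k: int = 10,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
) -> SpectralNetwork:
    """All-pairs modified-cosine network with threshold and mutual top-K
    pruning.

    Defaults follow published feature-based molecular networking practice:
    cosine >= 0.65, more than 6 matched peaks (i.e. >= 7), and an edge is
    retained only if each endpoint ranks in the other's top 10 most similar
    nodes.  Ties in the ranking break lexicographically by spectrum id.
    """
    if len(spectra) < 2:
        raise ValueError("a network needs at least two spectra")
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique")

    candidate: dict[tuple[str, str], SimilarityEdge] = {}
    neighbors: dict[str, list[tuple[float, str]]] = {s.id: [] for s in spectra}
    for x in range(len(spectra)):
        for y in range(x + 1, len(spectra)):
            a, b = spectra[x], spectra[y]
            cosine, matched = modified_cosine(a, b, frag_tol, allow_shift)
            if cosine >= min_cosine and matched >= min_matched:
                key = tuple(sorted((a.id, b.id)))
                candidate[key] = SimilarityEdge(
                    key[0], key[1], cosine, matched, a.precursor_mz - b.precursor_mz
                    if key == (a.id, b.id)
                    else b.precursor_mz - a.precursor_mz,
                )
                neighbors[a.id].append((cosine, b.id))
                neighbors[b.id].append((cosine, a.id))

    rank: dict[str, dict[str, int]] = {}
    for node, nbrs in neighbors.items():
        nbrs.sort(key=lambda t: (-t[0], t[1]))
        rank[node] = {other: pos for pos, (_, other) in enumerate(nbrs)}

    graph = nx.Graph()
    for s in spectra:
        graph.add_node(s.id, precursor_mz=s.precursor_mz)
    kept: list[SimilarityEdge] = []
    for (na, nb), edge in sorted(candidate.items()):
        if rank[na][nb] < top_k and rank[nb][na] < top_k:
            kept.append(edge)
            graph.add_edge(
                na,
                nb,
                cosine=edge.cosine,
                matched_peaks=edge.matched_peaks,
                precursor_delta=edge.precursor_delta,
            )
    return SpectralNetwork(graph, kept)


def masst_prefilter(
    s: Spectrum,
    precursor_exclusion: float = 17.0,
    window: float = 50.0,
    top_n: int = 6,
) -> Spectrum:
    """Single-spectrum search peak filter: drop fragments within
    +/-``precursor_exclusion`` Da of the precursor, then keep a peak only if
    it is among the ``top_n`` most intense within its +/-``window`` Da
    neighborhood.  Idempotent."""
    peaks = [
        p for p in s.peaks if abs(p.mz - s.precursor_mz) > precursor_exclusion
    ]
    kept: list[Peak] = []
    for p in peaks:
        local = [q for q in peaks if abs(q.mz - p.mz) <= window]
        local.sort(key=lambda q: (-q.intensity, q.mz))
        if p in local[:top_n]:
            kept.append(p)
    return Spectrum(
        id=s.id,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        retention_time=s.retention_time,
        peaks=tuple(kept),
    )


def masst_search(
    query: Spectrum,
    library: list[Spectrum],
    prec_tol: float = 2.0,
    frag_tol: float = 0.5,
    min_score: float = 0.2,
    min_matched: int = 3,
    allow_shift: bool = True,
) -> list[LibraryMatch]:
    """MASST-style library search: query and library spectra are prefiltered
    identically, candidates restricted to precursors within ``prec_tol`` Da,
    scored by modified cosine at ``frag_tol``, and thresholded at
    ``min_score`` / ``min_matched``.  Results sorted by score descending."""
    if not library:
        raise ValueError("library must be non-empty")
    q = masst_prefilter(query)
    matches: list[LibraryMatch] = []
    for entry in library:
        if abs(entry.precursor_mz - query.precursor_mz) > prec_tol:
            continue
        lib = masst_prefilter(entry)
        if not q.peaks or not lib.peaks:
            continue
        score, matched = modified_cosine(q, lib, frag_tol, allow_shift)
        if score > min_score and matched >= min_matched:
            matches.append(LibraryMatch(query.id, entry.id, score, matched))
    matches.sort(key=lambda m: (-m.score, m.library_id))
    return matches
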