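"""Signed directed networks over genes, and their file formats.

An edge (regulator, target) carries sign +1 (activation) or -1
(inhibition); pairs absent from the map are non-interactions.  Self-loops
are ordinary edges.  On disk the network is a SIF-style three-column TSV
``source <tab> sign <tab> target``; a dense signed-adjacency TSV writer is
also provided for the fitted coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import InvalidInputError

__all__ = [
    "SignedNetwork",
    "extract_edges",
    "read_network",
    "write_network",
    "write_adjacency",
]

_SIGN_TOKENS = {
    "+": 1, "-": -1, "+1": 1, "-1": -1,
    "activation": 1, "inhibition": -1,
}


@dataclass(frozen=True)
class SignedNetwork:
    """Ordered-pair signed adjacency over a fixed gene set.

    ``sign`` maps (regulator, target) -> +/-1; ``magnitude`` optionally
    carries |coefficient| for edges that came from a fitted matrix (used to
    pick the dominant sign when collapsing complexes).
    """

    gene_ids: tuple[str, ...]
    sign: dict = field(default_factory=dict)
    magnitude: "dict | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        genes = set(self.gene_ids)
        if len(genes) != len(self.gene_ids):
            raise InvalidInputError("gene ids must be unique")
        for (src, tgt), s in self.sign.items():
            if src not in genes or tgt not in genes:
                raise InvalidInputError(
                    f"edge ({src!r}, {tgt!r}) references an unknown gene"
                )
            if s not in (1, -1):
                raise InvalidInputError(
                    f"edge ({src!r}, {tgt!r}) has sign {s!r}, expected +1/-1"
                )

    @property
    def n_edges(self) -> int:
        return len(self.sign)

    def get(self, src: str, tgt: str) -> int:
        """Sign of the ordered pair, 0 when absent."""
        return self.sign.get((src, tgt), 0)

    def edges(self):
        """Iterate (source, sign, target) sorted for deterministic output."""
        for (src, tgt) in sorted(self.sign):
            yield src, self.sign[(src, tgt)], tgt

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for src, s, tgt in self.edges():
            attrs = {"sign": s}
            if self.magnitude is not None:
                attrs["magnitude"] = self.magnitude.get((src, tgt))
            g.add_edge(src, tgt, **attrs)
        return g


def extract_edges(A_hat: np.ndarray, gene_ids, threshold: float = 1e-6) -> SignedNetwork:
    """Read the signed network off a coefficient matrix.

    ``|A_hat[i, j]| > threshold`` yields the edge gene_j -> gene_i with
    sign(A_hat[i, j]); exact threshold equality is a non-edge.  Self-loops
    (diagonal entries) are included.
    """
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    A_hat = np.asarray(A_hat, dtype=float)
    gene_ids = tuple(str(g) for g in gene_ids)
    n = len(gene_ids)
    if A_hat.shape != (n, n):
        raise InvalidInputError(
            f"coefficient matrix {A_hat.shape} does not match {n} gene ids"
        )
    sign: dict = {}
    mag: dict = {}
    for i, j in zip(*np.nonzero(np.abs(A_hat) > threshold)):
        key = (gene_ids[j], gene_ids[i])  # source j regulates target i
        sign[key] = 1 if A_hat[i, j] > 0 else -1
        mag[key] = abs(float(A_hat[i, j]))
    return SignedNetwork(gene_ids=gene_ids, sign=sign, magnitude=mag)


def read_network(path, gene_ids=None) -> SignedNetwork:
    """Read a SIF-style signed edge list.

    Sign tokens accepted: ``+ - +1 -1 activation inhibition``.  Duplicate
    (source, target) lines with conflicting signs are an error; the gene
    set defaults to the genes appearing in the file (sorted) unless given.
    """
    sign: dict = {}
    first_line: dict = {}
    seen_genes: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            src, tok, tgt = (p.strip() for p in parts)
            if tok.lower() not in _SIGN_TOKENS:
                raise InvalidInputError(
                    f"{path}:{lineno}: unknown sign token {tok!r}"
                )
            s = _SIGN_TOKENS[tok.lower()]
            key = (src, tgt)
            if key in sign:
                if sign[key] != s:
                    raise InvalidInputError(
                        f"{path}:{lineno}: edge {src}->{tgt} conflicts with "
                        f"line {first_line[key]}"
                    )
                continue
            sign[key] = s
            first_line[key] = lineno
            for g in (src, tgt):
                if g not in seen_genes:
                    seen_genes.append(g)
    if gene_ids is None:
        gene_ids = tuple(sorted(seen_genes))
    return SignedNetwork(gene_ids=tuple(gene_ids), sign=sign)


def write_network(net: SignedNetwork, path) -> None:
    with open(path, "w") as fh:
        for src, s, tgt in net.edges():
            fh.write(f"{src}\t{'+' if s > 0 else '-'}\t{tgt}\n")


def write_adjacency(A_hat: np.ndarray, gene_ids, path) -> None:
    """Dense signed-adjacency TSV with gene ids on both axes.

    Full double precision, so re-loaded matrices satisfy the same
    constraint checks as the in-memory ones.
    """
    import pandas as pd

    pd.DataFrame(
        np.asarray(A_hat, dtype=float),
        index=list(gene_ids),
        columns=list(gene_ids),
    ).to_csv(path, sep="\t", float_format="%.17g")
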