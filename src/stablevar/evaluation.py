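"""Sign-aware comparison of an inferred network against a reference.

Every ordered gene pair (self-pairs included) falls into exactly one
confusion cell, so TP + FP + TN + FN = N^2:

* both networks carry the pair with the same sign            -> TP
* the inference carries it but the reference does not, or
  the signs disagree (the inferred interaction is false)     -> FP
* neither carries it                                         -> TN
* the reference carries it and the inference does not        -> FN

FP is sub-divided into false activations (+) and false inhibitions (-) by
the inferred sign; every FN is a false no-interaction.  A recovered edge
with the wrong sign counts as FP, not FN: the interaction that was actually
inferred does not exist in the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .expression import InvalidInputError
from .network import SignedNetwork

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "ComplexGrouping",
    "confusion",
    "metrics",
    "summary_rates",
    "collapse_complexes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    false_activations: int = 0
    false_inhibitions: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "false_activations", "false_inhibitions"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")

    @property
    def false_no_interactions(self) -> int:
        return self.fn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and precision; NaN when undefined.

    A zero denominator leaves the metric undefined (NaN) and listed in
    ``undefined`` rather than silently coerced to 0 or 1.
    """

    sensitivity: float
    specificity: float
    precision: float
    undefined: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComplexGrouping:
    """gene -> complex label; unmapped genes are singleton complexes."""

    labels: dict = field(default_factory=dict)

    def label(self, gene: str) -> str:
        return self.labels.get(gene, gene)


def confusion(inferred: SignedNetwork, truth: SignedNetwork) -> ConfusionCounts:
    """Classify every ordered pair of the shared gene set."""
    gi, gt = set(inferred.gene_ids), set(truth.gene_ids)
    if gi != gt:
        diff = sorted(gi.symmetric_difference(gt))
        raise InvalidInputError(
            f"gene sets differ; symmetric difference: {diff}"
        )
    tp = fp = tn = fn = fa = fi = 0
    genes = inferred.gene_ids
    for src in genes:
        for tgt in genes:
            si = inferred.get(src, tgt)
            st = truth.get(src, tgt)
            if si != 0 and st != 0 and si == st:
                tp += 1
            elif si == 0 and st == 0:
                tn += 1
            elif si != 0:  # spurious edge or wrong sign
                fp += 1
                if si > 0:
                    fa += 1
                else:
                    fi += 1
            else:
                fn += 1
    return ConfusionCounts(
        tp=tp, fp=fp, tn=tn, fn=fn, false_activations=fa, false_inhibitions=fi
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """sen = TP/(TP+FN), spc = TN/(TN+FP), pre = TP/(TP+FP)."""
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sen = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spc = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    pre = ratio(counts.tp, counts.tp + counts.fp, "precision")
    return Metrics(sen, spc, pre, tuple(undefined))


def summary_rates(counts: ConfusionCounts, n_genes: int) -> "tuple[float, float]":
    """(false-identification %, net-connectivity %) over N^2 ordered pairs.

    False identifications are the FP + FN pairs (spurious, wrong-sign, or
    missed interactions); net connectivity is the fraction of ordered pairs
    the inference reports as interactions (TP + FP).
    """
    n2 = n_genes * n_genes
    if counts.total != n2:
        raise InvalidInputError(
            f"counts sum to {counts.total}, expected N^2 = {n2}"
        )
    return (
        100.0 * (counts.fp + counts.fn) / n2,
        100.0 * (counts.tp + counts.fp) / n2,
    )


def collapse_complexes(net: SignedNetwork, grouping: ComplexGrouping) -> SignedNetwork:
    """Merge genes of a complex into a single node before evaluation.

    Inter-complex ordered pairs carry an edge iff at least one member pair
    does; intra-complex edges are dropped.  The sign of a collapsed edge is
    the sign of the largest-magnitude contributing coefficient when
    magnitudes are available, otherwise the majority sign with ties going
    to + (logged as a warning).
    """
    for gene in grouping.labels:
        if gene not in net.gene_ids:
            raise InvalidInputError(
                f"grouping maps unknown gene {gene!r}"
            )
    nodes: list[str] = []
    for g in net.gene_ids:
        lbl = grouping.label(g)
        if lbl not in nodes:
            nodes.append(lbl)
    contributions: dict = {}
    for (src, tgt), s in net.sign.items():
        cs, ct = grouping.label(src), grouping.label(tgt)
        if cs == ct:
            continue
        mag = None
        if net.magnitude is not None:
            mag = net.magnitude.get((src, tgt))
        contributions.setdefault((cs, ct), []).append((s, mag))
    sign: dict = {}
    mag_out: dict = {}
    for key, contrib in contributions.items():
        mags = [m for _, m in contrib]
        if all(m is not None for m in mags):
            s, m = max(contrib, key=lambda sm: sm[1])
            sign[key] = s
            mag_out[key] = m
        else:
            pos = sum(1 for s, _ in contrib if s > 0)
            neg = len(contrib) - pos
            if pos == neg:
                logger.warning(
                    "collapsed edge %s->%s has an exact sign tie; using +",
                    key[0], key[1],
                )
            sign[key] = 1 if pos >= neg else -1
    magnitude = mag_out if net.magnitude is not None else None
    return SignedNetwork(gene_ids=tuple(nodes), sign=sign, magnitude=magnitude)


def read_grouping(path) -> ComplexGrouping:
    """Two-column TSV: gene <tab> complex label."""
    labels: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            labels[parts[0].strip()] = parts[1].strip()
    return ComplexGrouping(labels=labels)
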