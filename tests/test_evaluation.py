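"""Sign-aware confusion counting, metrics, summary rates, complex collapsing."""

import math

import pytest

from stablevar import (
    ComplexGrouping,
    ConfusionCounts,
    InvalidInputError,
    SignedNetwork,
    collapse_complexes,
    confusion,
    metrics,
    summary_rates,
)


def _net(genes, edges):
    return SignedNetwork(gene_ids=tuple(genes), sign=dict(edges))


# ---------------------------------------------------------------------------
# confusion

def test_identical_networks():
    net = _net("abc", {("a", "b"): 1, ("b", "c"): -1})
    c = confusion(net, net)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 7, 0)
    assert c.total == 9


def test_empty_inferred():
    truth = _net("abc", {("a", "b"): 1, ("c", "c"): -1, ("b", "a"): -1})
    c = confusion(_net("abc", {}), truth)
    assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 6, 3)


def test_two_gene_sign_mismatch_enumeration():
    """Exhaustive 4-pair case: a wrong-sign edge and a spurious self-loop.

    truth = {g1->g2: +}; inferred = {g1->g2: -, g2->g2: -}.  The sign
    mismatch consumes the true pair as a false positive (the inferred
    inhibition does not exist), so no pair is left to count as missed.
    """
    truth = _net(("g1", "g2"), {("g1", "g2"): 1})
    inferred = _net(("g1", "g2"), {("g1", "g2"): -1, ("g2", "g2"): -1})
    c = confusion(inferred, truth)
    assert (c.tp, c.fp, c.tn, c.fn) == (0, 2, 2, 0)
    assert c.false_inhibitions == 2
    assert c.false_activations == 0
    assert c.total == 4


def test_partition_property(rng):
    """Every ordered pair lands in exactly one cell: counts sum to N^2."""
    genes = tuple("abcde")
    for _ in range(25):
        def rand_net():
            sign = {}
            for s in genes:
                for t in genes:
                    r = rng.integers(0, 3)
                    if r:
                        sign[(s, t)] = 1 if r == 1 else -1
            return _net(genes, sign)

        c = confusion(rand_net(), rand_net())
        assert c.total == 25
        assert c.false_activations + c.false_inhibitions == c.fp


def test_gene_set_mismatch_lists_difference():
    with pytest.raises(InvalidInputError, match="recA"):
        confusion(_net(("lexA",), {}), _net(("lexA", "recA"), {}))


def test_self_loops_scored():
    truth = _net(("a", "b"), {("a", "a"): -1})
    inferred = _net(("a", "b"), {("a", "a"): -1})
    c = confusion(inferred, truth)
    assert c.tp == 1


# ---------------------------------------------------------------------------
# metrics and rates

def test_metrics_basic():
    m = metrics(ConfusionCounts(tp=8, fp=2, tn=6, fn=4))
    assert m.sensitivity == pytest.approx(8 / 12)
    assert m.specificity == pytest.approx(6 / 8)
    assert m.precision == pytest.approx(8 / 10)
    assert m.undefined == ()


def test_metrics_zero_sensitivity():
    m = metrics(ConfusionCounts(tp=0, fp=1, tn=1, fn=3))
    assert m.sensitivity == 0.0


def test_metrics_undefined_flagged_not_coerced():
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
    assert math.isnan(m.sensitivity)
    assert math.isnan(m.precision)
    assert set(m.undefined) == {"sensitivity", "precision"}
    assert m.specificity == 1.0


def test_metrics_scale_free():
    a = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
    b = metrics(ConfusionCounts(tp=9, fp=3, tn=12, fn=6))
    assert a.sensitivity == pytest.approx(b.sensitivity)
    assert a.specificity == pytest.approx(b.specificity)
    assert a.precision == pytest.approx(b.precision)


def test_summary_rates_hand_values():
    c = ConfusionCounts(tp=2, fp=1, tn=5, fn=1)
    false_id, net_conn = summary_rates(c, 3)
    assert false_id == pytest.approx(100 * 2 / 9)
    assert net_conn == pytest.approx(100 * 3 / 9)


def test_summary_rates_consistency_check():
    with pytest.raises(InvalidInputError, match="N\\^2"):
        summary_rates(ConfusionCounts(tp=1, fp=1, tn=1, fn=1), 3)


def test_counts_reject_negative():
    with pytest.raises(InvalidInputError):
        ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


def test_false_no_interactions_alias():
    c = ConfusionCounts(tp=0, fp=0, tn=0, fn=7)
    assert c.false_no_interactions == 7


# ---------------------------------------------------------------------------
# complex collapsing

def test_collapse_identity_grouping():
    net = _net("abc", {("a", "b"): 1, ("b", "c"): -1})
    out = collapse_complexes(net, ComplexGrouping())
    assert out.sign == net.sign
    assert out.gene_ids == net.gene_ids


def test_collapse_drops_intra_complex_edges():
    net = _net("ab", {("a", "b"): 1, ("b", "a"): -1})
    out = collapse_complexes(net, ComplexGrouping(labels={"a": "C", "b": "C"}))
    assert out.n_edges == 0
    assert out.gene_ids == ("C",)


def test_collapse_deduplicates_inter_complex():
    net = _net("abc", {("a", "c"): 1, ("b", "c"): 1})
    out = collapse_complexes(
        net, ComplexGrouping(labels={"a": "C1", "b": "C1", "c": "C2"})
    )
    assert out.sign == {("C1", "C2"): 1}


def test_collapse_sign_by_largest_magnitude():
    net = SignedNetwork(
        gene_ids=("a", "b", "c"),
        sign={("a", "c"): 1, ("b", "c"): -1},
        magnitude={("a", "c"): 0.1, ("b", "c"): 0.9},
    )
    out = collapse_complexes(
        net, ComplexGrouping(labels={"a": "C1", "b": "C1", "c": "C2"})
    )
    assert out.sign == {("C1", "C2"): -1}


def test_collapse_majority_sign_tie_goes_positive():
    net = _net("abc", {("a", "c"): 1, ("b", "c"): -1})
    out = collapse_complexes(
        net, ComplexGrouping(labels={"a": "C1", "b": "C1", "c": "C2"})
    )
    assert out.sign == {("C1", "C2"): 1}


def test_collapse_unknown_gene_rejected():
    net = _net("ab", {})
    with pytest.raises(InvalidInputError, match="unknown gene"):
        collapse_complexes(net, ComplexGrouping(labels={"zzz": "C"}))
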