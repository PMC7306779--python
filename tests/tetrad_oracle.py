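"""Brute-force tetrad-class oracle, independent of the package classifier.

Enumerates every configuration of at most two crossovers per interval
(positions ordered within an interval, each crossover involving one of the
two chromatids of each homolog), traces the four spores through the
exchanges from the centromere side, and labels the resulting spore multiset
by the *most parsimonious* generating configuration:

    (0,0) -> A   (0,1) -> B   (1,0) -> C   (0,2) -> H   (2,0) -> I
    (1,2) -> J   (2,1) -> K   (2,2) -> L
    (1,1) -> D (same chromatid pair), E (configs sharing a fluorescent-parent
              chromatid), F (sharing a non-fluorescent chromatid),
              G (disjoint chromatids)

Configurations that are genetically invisible (e.g. a two-strand double
crossover within one interval) collapse onto the multiset of a smaller
configuration, which parsimony resolves. The oracle never inspects ditypes,
so it is an independent route to the class of every reachable spore set.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

# chromatids: ('P', 0), ('P', 1) carry all three colors; ('Q', *) carry none
_P_CHROMATIDS = (("P", 0), ("P", 1))
_Q_CHROMATIDS = (("Q", 0), ("Q", 1))


def _trace_spores(cos_interval1, cos_interval2):
    """Spore color triples for ordered CO lists (each CO = (p_idx, q_idx)).

    The three color loci sit telomere-to-centromere as locus1, interval 1,
    locus2, interval 2, locus3, centromere. Each spore is anchored at the
    centromere on one original chromatid; walking toward the telomere, the
    trace switches to the partner chromatid at every crossover involving the
    strand currently followed, flipping parental origin.
    """
    spores = []
    for anchor in _P_CHROMATIDS + _Q_CHROMATIDS:
        homolog, strand = anchor
        # locus3 is centromere-proximal: no crossovers between it and the anchor
        allele3 = 1 if homolog == "P" else 0
        for p_idx, q_idx in reversed(cos_interval2):  # sweep outward
            if (homolog, strand) in ((("P", p_idx)), ("Q", q_idx)):
                homolog, strand = ("Q", q_idx) if homolog == "P" else ("P", p_idx)
        allele2 = 1 if homolog == "P" else 0
        for p_idx, q_idx in reversed(cos_interval1):
            if (homolog, strand) in ((("P", p_idx)), ("Q", q_idx)):
                homolog, strand = ("Q", q_idx) if homolog == "P" else ("P", p_idx)
        allele1 = 1 if homolog == "P" else 0
        spores.append((allele1, allele2, allele3))
    return tuple(sorted(spores))


def _nominal_class(cos1, cos2) -> str:
    n1, n2 = len(cos1), len(cos2)
    simple = {(0, 0): "A", (0, 1): "B", (1, 0): "C", (0, 2): "H",
              (2, 0): "I", (1, 2): "J", (2, 1): "K", (2, 2): "L"}
    if (n1, n2) in simple:
        return simple[(n1, n2)]
    (p1, q1), (p2, q2) = cos1[0], cos2[0]
    if (p1, q1) == (p2, q2):
        return "D"
    if p1 == p2:
        return "E"  # three-strand DCO sharing a fluorescent-parent chromatid
    if q1 == q2:
        return "F"  # three-strand DCO sharing a non-fluorescent chromatid
    return "G"


def enumerate_reachable() -> dict[tuple, str]:
    """Map every reachable sorted spore multiset to its parsimony class."""
    best: dict[tuple, tuple[int, set[str]]] = defaultdict(lambda: (99, set()))
    pair_choices = list(itertools.product(range(2), range(2)))
    for n1 in range(3):
        for n2 in range(3):
            for cos1 in itertools.product(pair_choices, repeat=n1):
                for cos2 in itertools.product(pair_choices, repeat=n2):
                    key = _trace_spores(list(cos1), list(cos2))
                    label = _nominal_class(list(cos1), list(cos2))
                    total = n1 + n2
                    cur_total, cur_labels = best[key]
                    if total < cur_total:
                        best[key] = (total, {label})
                    elif total == cur_total:
                        cur_labels.add(label)
    out = {}
    for key, (total, labels) in best.items():
        assert len(labels) == 1, f"ambiguous parsimony class for {key}: {labels}"
        out[key] = labels.pop()
    return out
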