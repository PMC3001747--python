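"""Substitution-pair (SP) matrices and directional substitution-bias tests.

An SP-matrix is the count n_{x,y} of aligned residue pairs where residue
x in one group faces residue y in the other, summed over all sites where
x != y.  Counting follows the highest-identity disjoint-pairing rule
("Jones method"): the maximum number of cross-group sequence pairs is
formed greedily by pairwise identity, each sequence used only once, to
avoid oversampling.  The gap/indel state participates as the 21st
symbol, rendered '~' in outputs.

Substitution biases are assessed per (x, y) by a 2x2 table that compares
the forward (between-group, e.g. mesophile -> psychrophile) counts
against the within-source-group background, tested with the mid-p
Fisher exact test (or chi-square for large counts), with
Benjamini-Yekutieli q-values across the full scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats
from .align_io import AlignedSequence, AnnotatedAlignment, SiteFilter, filter_sites
from .alphabet import STATE_LABELS21

N_STATES = 21
_GAP_CODE = 20


@dataclass
class SPMatrix:
    """21x21 substitution-pair count matrix (20 amino acids + gap).

    ``kind`` is one of ``directional_between`` (ordered counts from the
    source group to the target group over disjoint highest-identity
    pairs), ``symmetric_within`` (unordered counts inside one group) and
    ``representative`` (all-ordered-pairs counts divided by the number
    of ordered pairs, G_MP).
    """

    counts: np.ndarray
    kind: str
    group_from: int
    group_to: int
    n_pairs: int = 0
    g_mp: int = 0  # ordered-pair denominator (representative kind)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_STATES, N_STATES):
            raise ValueError("SP-matrix must be 21x21")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("SP-matrix diagonal must be zero (x != y only)")

    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = list(STATE_LABELS21)
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "from\\to"
        df.to_csv(path, sep="\t")


def pairwise_identity(a: AlignedSequence, b: AlignedSequence) -> float:
    """Fraction of matching residues over columns where both sequences
    are non-gap; 0 (with a warning) when no such column exists."""
    ca, cb = a.codes, b.codes
    if ca.size != cb.size:
        raise ValueError(
            f"sequences {a.seq_id!r} and {b.seq_id!r} differ in length"
        )
    both = (ca != _GAP_CODE) & (cb != _GAP_CODE)
    n = int(both.sum())
    if n == 0:
        warnings.warn(
            f"no shared non-gap column between {a.seq_id!r} and {b.seq_id!r}",
            stacklevel=2,
        )
        return 0.0
    return float(np.sum(ca[both] == cb[both]) / n)


@dataclass(frozen=True)
class PairingResult:
    pairs: tuple  # ((seq_id_a, seq_id_b, identity), ...)
    unpaired: tuple


def _greedy_pairs(candidates: List[Tuple[float, str, str]]) -> list:
    """Repeatedly take the highest-identity candidate pair (ties broken
    lexicographically by the id pair), never reusing a sequence."""
    chosen = []
    used: set = set()
    for ident, ia, ib in sorted(candidates, key=lambda t: (-t[0], t[1], t[2])):
        if ia in used or ib in used:
            continue
        used.update((ia, ib))
        chosen.append((ia, ib, ident))
    return chosen


def jones_pairing(
    group_a: Sequence[AlignedSequence],
    group_b: Sequence[AlignedSequence],
    optimal: bool = False,
) -> PairingResult:
    """Disjoint cross-group pairing by highest pairwise identity.

    The default is the greedy procedure (pick the best remaining pair,
    remove both sequences, repeat), which yields min(|A|, |B|) pairs.
    ``optimal=True`` instead solves the assignment problem maximising
    total identity — a non-default alternative, since greedy can miss
    the global optimum.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ids_a = [s.seq_id for s in group_a]
    ids_b = [s.seq_id for s in group_b]
    ident = np.array(
        [[pairwise_identity(sa, sb) for sb in group_b] for sa in group_a]
    )
    if optimal:
        from scipy.optimize import linear_sum_assignment

        ri, ci = linear_sum_assignment(-ident)
        chosen = sorted(
            (ids_a[i], ids_b[j], float(ident[i, j])) for i, j in zip(ri, ci)
        )
    else:
        cands = [
            (float(ident[i, j]), ids_a[i], ids_b[j])
            for i in range(len(group_a))
            for j in range(len(group_b))
        ]
        chosen = _greedy_pairs(cands)
    paired = {x for p in chosen for x in p[:2]}
    unpaired = tuple(i for i in ids_a + ids_b if i not in paired)
    return PairingResult(tuple(chosen), unpaired)


def jones_pairing_within(group: Sequence[AlignedSequence]) -> PairingResult:
    """Greedy highest-identity pairing inside one group: floor(n/2)
    disjoint pairs, each sequence used once."""
    if not group:
        raise ValueError("group must be non-empty")
    ids = [s.seq_id for s in group]
    cands = []
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            ia, ib = sorted((ids[i], ids[j]))
            cands.append((pairwise_identity(group[i], group[j]), ia, ib))
    chosen = _greedy_pairs(cands)
    paired = {x for p in chosen for x in p[:2]}
    return PairingResult(tuple(chosen), tuple(i for i in ids if i not in paired))


def _tally_directional(counts: np.ndarray, ca: np.ndarray, cb: np.ndarray) -> None:
    """Add ordered pair counts (ca -> cb) at columns where residues
    differ and are not both gaps."""
    mask = (ca != cb) & ~((ca == _GAP_CODE) & (cb == _GAP_CODE))
    np.add.at(counts, (ca[mask], cb[mask]), 1.0)


def sp_matrix(
    alns: Iterable[AnnotatedAlignment],
    group_from: int,
    group_to: int,
    kind: str = "directional_between",
    sites: Optional[SiteFilter] = None,
) -> SPMatrix:
    """Accumulated SP-matrix over alignments.

    ``directional_between``: for every disjoint highest-identity pair
    (m, p) across the two groups, each column where the residues differ
    (and are not both gaps) increments counts[res_m][res_p].

    ``symmetric_within`` (requires group_from == group_to): unordered
    tallies over floor(n/2) disjoint within-group pairs; counts[x][y]
    and counts[y][x] each receive the tally, so the matrix is symmetric
    and there is no direction.
    """
    if kind not in ("directional_between", "symmetric_within"):
        raise ValueError(f"unknown SP-matrix kind {kind!r}")
    if kind == "symmetric_within" and group_from != group_to:
        raise ValueError("within-group SP-matrix needs group_from == group_to")
    counts = np.zeros((N_STATES, N_STATES))
    n_pairs = 0
    for aln in alns:
        if sites is not None:
            aln = filter_sites(aln, sites)
        by_id = {s.seq_id: s for s in aln}
        if kind == "directional_between":
            ga, gb = aln.by_group(group_from), aln.by_group(group_to)
            if not ga or not gb:
                continue
            pairing = jones_pairing(ga, gb)
            for ida, idb, _ in pairing.pairs:
                _tally_directional(counts, by_id[ida].codes, by_id[idb].codes)
            n_pairs += len(pairing.pairs)
        else:
            g = aln.by_group(group_from)
            if len(g) < 2:
                continue
            pairing = jones_pairing_within(g)
            for ida, idb, _ in pairing.pairs:
                ca, cb = by_id[ida].codes, by_id[idb].codes
                mask = (ca != cb) & ~((ca == _GAP_CODE) & (cb == _GAP_CODE))
                np.add.at(counts, (ca[mask], cb[mask]), 1.0)
                np.add.at(counts, (cb[mask], ca[mask]), 1.0)
            n_pairs += len(pairing.pairs)
    if n_pairs == 0:
        raise ValueError(
            f"no sequence pairs formable for groups {group_from}->{group_to}"
        )
    return SPMatrix(counts, kind, group_from, group_to, n_pairs=n_pairs)


def representative_sp_matrix(
    alns: Iterable[AnnotatedAlignment],
    group_from: int,
    group_to: int,
    sites: Optional[SiteFilter] = None,
) -> SPMatrix:
    """Representative SP-matrix: counts accumulated over *all* ordered
    cross-group sequence pairs, divided elementwise by G_MP, the number
    of ordered pairs (summed over alignments).  A dependence-robust
    average; fractional entries are expected."""
    counts = np.zeros((N_STATES, N_STATES))
    g_mp = 0
    for aln in alns:
        if sites is not None:
            aln = filter_sites(aln, sites)
        ga, gb = aln.by_group(group_from), aln.by_group(group_to)
        for sa in ga:
            for sb in gb:
                _tally_directional(counts, sa.codes, sb.codes)
        g_mp += len(ga) * len(gb)
    if g_mp == 0:
        raise ValueError(
            f"no ordered sequence pairs for groups {group_from}->{group_to}"
        )
    return SPMatrix(
        counts / g_mp,
        "representative",
        group_from,
        group_to,
        n_pairs=g_mp,
        g_mp=g_mp,
    )


def pool_substitutions(m: SPMatrix, target: str) -> Tuple[np.ndarray, np.ndarray]:
    """Pool substitutions sharing one outcome: returns (into, out_of)
    where ``into``[x] = counts[x][target] (all x -> target) and
    ``out_of``[y] = counts[target][y]."""
    if m.kind == "symmetric_within":
        raise ValueError("pooling is defined for directional matrices")
    try:
        j = STATE_LABELS21.index(target) if target != "-" else _GAP_CODE
    except ValueError:
        raise ValueError(f"unknown target state {target!r}") from None
    return m.counts[:, j].copy(), m.counts[j, :].copy()


def _round_half_even(counts: np.ndarray, kind: str) -> np.ndarray:
    if kind == "representative" and not np.allclose(counts, np.round(counts)):
        warnings.warn(
            "representative SP-matrix has fractional counts; rounding "
            "half-to-even for the exact test",
            stacklevel=3,
        )
    return np.round(counts)


def substitution_bias_test(
    forward: SPMatrix,
    background: SPMatrix,
    x: str,
    y: str,
    method: str = "mid_p_fisher",
):
    """Test whether x -> y is over-represented in the forward
    (between-group) direction relative to the within-source background.

    The 2x2 table compares [counts_fwd[x][y], sum_{z != y} counts_fwd[x][z]]
    against the same quantities in the background matrix.  ``direction``
    is ``favoured`` when the forward odds exceed the background odds
    (the upward-triangle semantics), ``non_favoured`` when smaller, and
    ``undefined`` for equal odds or a forward row with no data
    (``not-testable``).

    Returns (table, p, direction, not_testable).
    """
    ix = STATE_LABELS21.index(x) if x != "-" else _GAP_CODE
    iy = STATE_LABELS21.index(y) if y != "-" else _GAP_CODE
    fwd = _round_half_even(forward.counts, forward.kind)
    bkg = _round_half_even(background.counts, background.kind)
    a = fwd[ix, iy]
    b = fwd[ix, :].sum() - a
    c = bkg[ix, iy]
    d = bkg[ix, :].sum() - c
    table = stats.ContingencyTable2x2(a, b, c, d)
    if a + b == 0:
        return table, 1.0, "undefined", True
    if a + b + c + d == 0 or c + d == 0:
        return table, 1.0, "undefined", True
    if method == "mid_p_fisher":
        res = stats.mid_p_fisher(table)
    elif method == "chi_square":
        res = stats.chi_square_2x2(table)
    else:
        raise ValueError(f"unknown method {method!r}")
    cross1, cross2 = a * d, b * c
    if cross1 > cross2:
        direction = "favoured"
    elif cross1 < cross2:
        direction = "non_favoured"
    else:
        direction = "undefined"
    return table, float(res.p), direction, res.not_testable


def scan_substitution_bias(
    forward: SPMatrix,
    background: SPMatrix,
    method: str = "mid_p_fisher",
    include_gap: bool = True,
) -> pd.DataFrame:
    """Full scan over ordered state pairs (x, y), x != y.

    Pairs whose forward row has no data are reported ``not-testable``
    (p = NaN) — absence of data is not absence of effect.  q_BY adjusts
    the testable p-values.
    """
    labels = list(STATE_LABELS21) if include_gap else list(STATE_LABELS21[:20])
    rows = []
    for x in labels:
        for y in labels:
            if x == y:
                continue
            table, p, direction, not_testable = substitution_bias_test(
                forward, background, x, y, method
            )
            rows.append(
                {
                    "x": x,
                    "y": y,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "p": np.nan if not_testable else p,
                    "direction": direction,
                    "testable": not not_testable,
                }
            )
    df = pd.DataFrame(rows)
    df["q_BY"] = stats.benjamini_yekutieli(df["p"].to_numpy())
    return df


def mantel_haenszel_bias(
    per_stratum: Sequence[Tuple[SPMatrix, SPMatrix]],
    x: str,
    y: str,
) -> stats.MHResult:
    """Stratified substitution-bias test: one forward/background 2x2
    table per taxonomic stratum, combined by Mantel-Haenszel."""
    tables = []
    for forward, background in per_stratum:
        table, _, _, _ = substitution_bias_test(forward, background, x, y)
        tables.append(table)
    return stats.mantel_haenszel(tables)
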