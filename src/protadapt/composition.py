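"""Amino-acid and category composition analysis across phenotypic groups.

Per-sequence compositions are frequencies over non-gap residues.  The
group comparison reports, per feature, the across-alignment mean of the
"delta" (mean composition in the target group minus the source group),
its empirical standard deviation, and a trend test dispatched to the
statistical kernels; p-values over many features carry a
Benjamini-Yekutieli q-value alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .alphabet import AMINO_ACIDS, GAP
from .align_io import AlignedSequence, AnnotatedAlignment

DESIGNS = ("anova", "regression", "cumulative_mk", "wilcoxon")


@dataclass(frozen=True)
class CategoryScheme:
    """Named, disjoint sets of amino acids (a partition or sub-partition)."""

    categories: dict  # name -> frozenset of one-letter codes

    def __post_init__(self) -> None:
        seen: set = set()
        for name, members in self.categories.items():
            members = frozenset(members)
            bad = members - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"category {name!r} has non-amino-acid members {sorted(bad)}")
            if members & seen:
                raise ValueError(
                    f"amino acid(s) {sorted(members & seen)} appear in two categories"
                )
            seen |= members
        object.__setattr__(
            self,
            "categories",
            {k: frozenset(v) for k, v in self.categories.items()},
        )

    @property
    def names(self) -> list:
        return list(self.categories)


@dataclass(frozen=True)
class CompositionVector:
    freqs: dict  # feature -> frequency
    n_residues: int
    computable: bool = True


def builtin_charge_scheme() -> CategoryScheme:
    """The four-way charge partition of the 20 amino acids:
    negatively charged (D, E), positively charged (K, R), uncharged polar
    (C, S, T, Y, N, Q, W, H) and hydrophobic (G, A, V, L, I, F, P, M)."""
    return CategoryScheme(
        {
            "negative": frozenset("DE"),
            "positive": frozenset("KR"),
            "uncharged_polar": frozenset("CSTYNQWH"),
            "hydrophobic": frozenset("GAVLIFPM"),
        }
    )


def composition_vector(
    seq: AlignedSequence,
    scheme: Optional[CategoryScheme] = None,
    sites: Optional[Sequence[int]] = None,
) -> CompositionVector:
    """Frequency of each amino acid (or category) over non-gap residues.

    ``sites`` is an optional iterable of 0-based column indices to
    restrict to.  An all-gap selection yields ``computable=False``.
    """
    residues = seq.residues
    if sites is not None:
        residues = "".join(residues[j] for j in sites)
    residues = residues.replace(GAP, "")
    n = len(residues)
    features = list(AMINO_ACIDS) if scheme is None else scheme.names
    if n == 0:
        return CompositionVector({f: np.nan for f in features}, 0, computable=False)
    if scheme is None:
        freqs = {aa: residues.count(aa) / n for aa in AMINO_ACIDS}
    else:
        freqs = {
            name: sum(residues.count(aa) for aa in members) / n
            for name, members in scheme.categories.items()
        }
    return CompositionVector(freqs, n)


def _features(scheme: Optional[CategoryScheme]) -> list:
    return list(AMINO_ACIDS) if scheme is None else scheme.names


def _per_alignment_group_means(
    aln: AnnotatedAlignment,
    code: int,
    scheme: Optional[CategoryScheme],
    collapse_dependent: bool,
) -> Optional[pd.Series]:
    """Mean composition of one group in one alignment, optionally
    collapsing within-(group, stratum) sequences to their mean first."""
    seqs = aln.by_group(code)
    if not seqs:
        return None
    rows = []
    strata = []
    for s in seqs:
        cv = composition_vector(s, scheme)
        if not cv.computable:
            continue
        rows.append(cv.freqs)
        strata.append(s.stratum)
    if not rows:
        return None
    df = pd.DataFrame(rows)
    if collapse_dependent:
        df = df.groupby(pd.Series(strata, index=df.index, dtype=object)
                        .fillna("__none__").to_numpy()).mean()
    return df.mean(axis=0)


def delta_composition(
    alns: Iterable[AnnotatedAlignment],
    group_from: int,
    group_to: int,
    scheme: Optional[CategoryScheme] = None,
    collapse_dependent: bool = False,
) -> pd.DataFrame:
    """Per-feature compositional change in the direction from
    ``group_from`` to ``group_to``.

    For each alignment the delta is (mean composition in ``group_to``)
    minus (mean composition in ``group_from``); with
    ``collapse_dependent`` sequence compositions are first averaged
    within group at each stratum.  Returns a DataFrame indexed by
    feature with columns ``mean_delta``, ``sd``, ``n`` (the
    across-alignment mean, empirical standard deviation and count).
    """
    deltas = []
    for aln in alns:
        m_from = _per_alignment_group_means(aln, group_from, scheme, collapse_dependent)
        m_to = _per_alignment_group_means(aln, group_to, scheme, collapse_dependent)
        if m_from is None or m_to is None:
            continue
        deltas.append(m_to - m_from)
    if not deltas:
        raise ValueError(
            f"groups {group_from} and {group_to} never co-occur in any alignment"
        )
    mat = pd.DataFrame(deltas)[_features(scheme)]
    return pd.DataFrame(
        {
            "mean_delta": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1) if len(mat) > 1 else np.zeros(mat.shape[1]),
            "n": len(mat),
        }
    )


def _feature_response(
    aln: AnnotatedAlignment,
    feature: str,
    scheme: Optional[CategoryScheme],
    collapse_dependent: bool = False,
    restrict_codes: Optional[set] = None,
):
    """(x, y, strata) for one alignment: per-sequence ordinal code and
    feature frequency (optionally collapsed to group/stratum means)."""
    xs, ys, st = [], [], []
    for s in aln:
        if s.group is None:
            continue
        if restrict_codes is not None and s.group not in restrict_codes:
            continue
        cv = composition_vector(s, scheme)
        if not cv.computable:
            continue
        xs.append(s.group)
        ys.append(cv.freqs[feature])
        st.append(s.stratum)
    if collapse_dependent and xs:
        df = pd.DataFrame({"x": xs, "y": ys,
                           "s": pd.Series(st, dtype=object).fillna("__none__")})
        df = df.groupby(["x", "s"], as_index=False)["y"].mean()
        return df["x"].to_numpy(float), df["y"].to_numpy(float), None
    return np.asarray(xs, float), np.asarray(ys, float), st


def composition_trend(
    alns: Sequence[AnnotatedAlignment],
    feature: str,
    design: str,
    scheme: Optional[CategoryScheme] = None,
    collapse_dependent: bool = False,
    use_strata: bool = False,
):
    """Test one composition feature for a group trend.

    ``design`` selects the statistical model: ``anova`` and ``wilcoxon``
    require exactly 2 phenotypic groups; ``regression`` and
    ``cumulative_mk`` accept 2 or more (the ordinal group code is the
    predictor).  For ``cumulative_mk`` each alignment is one block; for
    ``wilcoxon`` the per-alignment paired group-mean deltas form the
    sample.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    codes = sorted({s.group for aln in alns for s in aln if s.group is not None})
    if len(codes) < 2:
        raise ValueError("need at least 2 phenotypic groups")
    if design in ("anova", "wilcoxon") and len(codes) != 2:
        raise ValueError(
            f"design {design!r} requires exactly 2 phenotypic groups, got "
            f"{len(codes)}; use 'regression' or 'cumulative_mk' for more "
            f"than two ordered groups"
        )
    if design == "cumulative_mk":
        blocks = []
        for aln in alns:
            x, y, _ = _feature_response(aln, feature, scheme, collapse_dependent)
            blocks.append((x, y))
        return stats.cumulative_mann_kendall(blocks)
    if design == "wilcoxon":
        lo, hi = codes
        table = delta_composition(alns, lo, hi, scheme, collapse_dependent)
        # per-alignment deltas for this feature
        deltas = []
        for aln in alns:
            m_from = _per_alignment_group_means(aln, lo, scheme, collapse_dependent)
            m_to = _per_alignment_group_means(aln, hi, scheme, collapse_dependent)
            if m_from is None or m_to is None:
                continue
            deltas.append(float((m_to - m_from)[feature]))
        return stats.wilcoxon_paired(deltas)
    # pooled per-sequence designs
    xs, ys, st = [], [], []
    for aln in alns:
        x, y, strata = _feature_response(aln, feature, scheme, collapse_dependent)
        xs.append(x)
        ys.append(y)
        st.extend(strata if strata is not None else [None] * len(x))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    strata = [s if s is not None else "__none__" for s in st]
    if design == "anova":
        return stats.anova_group_effect(
            y, x, strata if use_strata and len(set(strata)) > 1 else None
        )
    return stats.ols_trend(
        y, x, strata if use_strata and len(set(strata)) > 1 else None
    )


def composition_scan(
    alns: Sequence[AnnotatedAlignment],
    group_from: int,
    group_to: int,
    scheme: Optional[CategoryScheme] = None,
    design: str = "cumulative_mk",
    collapse_dependent: bool = False,
) -> pd.DataFrame:
    """Per-feature delta table with trend p-values and BY q-values.

    Columns: feature, mean_delta, sd, n, p, q_BY — the data behind the
    compositional-change bar plot.
    """
    codes = {s.group for aln in alns for s in aln if s.group is not None}
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    if design in ("anova", "wilcoxon") and len(codes) != 2:
        raise ValueError(
            f"design {design!r} requires exactly 2 phenotypic groups, got "
            f"{len(codes)}; use 'regression' or 'cumulative_mk' for more "
            f"than two ordered groups"
        )
    table = delta_composition(alns, group_from, group_to, scheme, collapse_dependent)
    pvals = []
    for feature in table.index:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = composition_trend(
                    alns, feature, design, scheme, collapse_dependent
                )
        except ValueError:
            pvals.append(np.nan)
            continue
        if isinstance(res, tuple):
            pvals.append(res[1])
        elif hasattr(res, "p_slope"):
            pvals.append(res.p_slope)
        else:
            pvals.append(res.p)
    table = table.copy()
    table["p"] = pvals
    table["q_BY"] = stats.benjamini_yekutieli(pvals)
    table.index.name = "feature"
    return table.reset_index()
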