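"""Physicochemical property trends across phenotypic groups.

Each sequence is reduced to the arithmetic mean Y of a property scale
over its non-gap residues (optionally restricted to structurally
filtered sites); Y is then regressed on the ordinal group code X —
per-family slopes feed the ranked-slope plot, while significance comes
from the cumulative Mann-Kendall trend test over all families.

A handful of standard published scales (hydrophobicity, residue volume,
net charge at pH 7, polarity, flexibility) ship with the package; user
scales are read from a simple 20-line format or from AAindex1 flat-file
records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .alphabet import AMINO_ACIDS, GAP
from .align_io import AlignedSequence, AnnotatedAlignment, GroupScheme, SiteFilter, filter_sites

#: AAindex1 residue order (two rows of ten in the 'I' block).
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class PropertyScale:
    """A named map from the 20 amino acids to numeric values."""

    name: str
    values: dict
    source: str = "user file"

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ValueError(
                f"scale {self.name!r} is missing amino acid(s): {', '.join(missing)}"
            )
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if extra:
            raise ValueError(f"scale {self.name!r} has unknown key(s): {extra}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    def vector(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)


@dataclass(frozen=True)
class FamilySlope:
    alignment_id: str
    beta1: float
    n_seqs: int
    scale_name: str


def _parse_simple_scale(text: str, fallback_name: str, source: str) -> PropertyScale:
    name = fallback_name
    values = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if body.lower().startswith("name:"):
                name = body[5:].strip()
            elif body.lower().startswith("source:"):
                source = body[7:].strip()
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"malformed scale line: {ln!r}")
        values[parts[0].upper()] = float(parts[1])
    return PropertyScale(name, values, source)


def _parse_aaindex(text: str) -> List[PropertyScale]:
    scales = []
    accession = ""
    in_values = False
    nums: list = []
    for ln in text.splitlines():
        if ln.startswith("H "):
            accession = ln[2:].strip()
        elif ln.startswith("I "):
            in_values = True
            nums = []
        elif in_values and ln.startswith(" "):
            nums.extend(ln.split())
        elif ln.startswith("//"):
            if accession and nums:
                vals = {}
                for aa, tok in zip(_AAINDEX_ORDER, nums):
                    if tok.upper() != "NA":
                        vals[aa] = float(tok)
                scales.append(PropertyScale(accession, vals, "AAindex1"))
            accession, in_values, nums = "", False, []
    return scales


def load_property_scales(path=None) -> List[PropertyScale]:
    """Load property scales.

    Without ``path``: the bundled scales (each with its literature
    source in the metadata).  With ``path``: parse a user file — either
    the 20-line ``AA<TAB>value`` format with optional ``# name:`` /
    ``# source:`` headers, or AAindex1 flat-file records (detected by
    the leading ``H `` line).
    """
    if path is None:
        scales = []
        pkg = resources.files("protadapt").joinpath("data/scales")
        for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
            if entry.name.endswith(".tsv"):
                scale = _parse_simple_scale(
                    entry.read_text(), entry.name[:-4], "bundled"
                )
                scales.append(
                    PropertyScale(scale.name, scale.values, f"bundled: {scale.source}")
                )
        return scales
    text = Path(path).read_text()
    if any(ln.startswith("H ") for ln in text.splitlines()[:5]):
        return _parse_aaindex(text)
    return [_parse_simple_scale(text, Path(path).stem, "user file")]


def get_scale(name: str, path=None) -> PropertyScale:
    """Fetch one scale by name from the bundled (or user) collection."""
    scales = load_property_scales(path)
    for s in scales:
        if s.name == name:
            return s
    raise KeyError(f"no property scale named {name!r}; available: "
                   f"{[s.name for s in scales]}")


def mean_property(
    seq: AlignedSequence,
    scale: PropertyScale,
    sites: Optional[Sequence[int]] = None,
) -> float:
    """Mean scale value over non-gap residues (NaN if the selection is
    all gaps, flagged by a warning)."""
    residues = seq.residues
    if sites is not None:
        residues = "".join(residues[j] for j in sites)
    residues = residues.replace(GAP, "")
    if not residues:
        warnings.warn(f"all-gap selection for {seq.seq_id!r}", stacklevel=2)
        return float("nan")
    return float(np.mean([scale.values[aa] for aa in residues]))


def _xy_for_alignment(
    aln: AnnotatedAlignment, scale: PropertyScale, collapse_dependent: bool = False
):
    xs, ys, st = [], [], []
    for s in aln:
        if s.group is None:
            continue
        y = mean_property(s, scale)
        if not np.isfinite(y):
            continue
        xs.append(float(s.group))
        ys.append(y)
        st.append(s.stratum if s.stratum is not None else "__none__")
    if collapse_dependent and xs:
        df = pd.DataFrame({"x": xs, "y": ys, "s": st})
        df = df.groupby(["x", "s"], as_index=False)["y"].mean()
        return df["x"].to_numpy(), df["y"].to_numpy(), None
    return np.asarray(xs), np.asarray(ys), st


def family_slopes(
    alns: Sequence[AnnotatedAlignment],
    scale: PropertyScale,
    sites: Optional[SiteFilter] = None,
) -> List[FamilySlope]:
    """Per-alignment OLS slope of mean property on the ordinal group
    code; alignments without >= 2 distinct codes are skipped with a
    warning."""
    out = []
    n_skipped = 0
    for aln in alns:
        if sites is not None:
            aln = filter_sites(aln, sites)
        x, y, _ = _xy_for_alignment(aln, scale)
        if len(x) < 2 or len(np.unique(x)) < 2:
            n_skipped += 1
            continue
        if len(x) == 2:
            beta1 = (y[1] - y[0]) / (x[1] - x[0])
        else:
            beta1 = float(np.polyfit(x, y, 1)[0])
        out.append(FamilySlope(aln.alignment_id, float(beta1), len(x), scale.name))
    if n_skipped:
        warnings.warn(f"{n_skipped} alignment(s) skipped (need >= 2 groups)",
                      stacklevel=2)
    if not out:
        raise ValueError("no alignment contributes a family slope")
    return out


def slopes_frame(slopes: Sequence[FamilySlope]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"alignment_id": s.alignment_id, "beta1": s.beta1, "n_seqs": s.n_seqs}
            for s in slopes
        ]
    )


def property_trend_test(
    alns: Sequence[AnnotatedAlignment],
    scale: PropertyScale,
    sites: Optional[SiteFilter] = None,
    collapse_dependent: bool = False,
) -> stats.TrendResult:
    """Cumulative Mann-Kendall trend of mean property on the ordinal
    group code, one block per alignment.  With ``collapse_dependent``,
    within-(group, stratum) sequences are first averaged, treating each
    group mean as one representative observation."""
    blocks = []
    for aln in alns:
        if sites is not None:
            aln = filter_sites(aln, sites)
        x, y, _ = _xy_for_alignment(aln, scale, collapse_dependent)
        blocks.append((x, y))
    return stats.cumulative_mann_kendall(blocks)


def stratified_property_regression(
    aln: AnnotatedAlignment,
    scale: PropertyScale,
    sites: Optional[SiteFilter] = None,
) -> stats.RegressionResult:
    """Parallelism regression for a single alignment: common slope on
    the ordinal code plus stratum-specific intercepts.  Falls back to
    the unstratified fit (with a warning) when fewer than two usable
    strata are present."""
    if sites is not None:
        aln = filter_sites(aln, sites)
    x, y, st = _xy_for_alignment(aln, scale)
    strata = np.asarray(st)
    usable = 0
    for lab in np.unique(strata):
        xs = x[strata == lab]
        if len(xs) >= 2 and len(np.unique(xs)) >= 2:
            usable += 1
    if usable < 2:
        if len(np.unique(strata)) > 1:
            warnings.warn(
                "fewer than 2 usable strata; falling back to unstratified "
                "regression",
                stacklevel=2,
            )
        return stats.ols_trend(y, x)
    return stats.ols_trend(y, x, strata)
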