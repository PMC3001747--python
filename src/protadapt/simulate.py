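"""Synthetic annotated alignments with controllable adaptive signals.

The generator emulates a set of orthologous protein families sampled
from organisms in K ordered phenotypic groups.  Per family an ancestral
sequence is drawn from a base residue-frequency vector; every sequence
then resamples each site independently with probability ``divergence``
from a group-specific frequency vector chosen so that the *expected*
composition of group g is exactly ``base + (g - 1) * shift`` (the shift
mass is compensated proportionally from the unshifted residues, so the
vector stays a distribution).  Three adaptive signals can be injected:

* ``composition_shift`` — a per-group-step additive frequency delta for
  selected residues;
* ``substitution_bias`` — at ancestral-x sites, conversion x -> y at a
  rate that scales linearly with the group code up to ``multiplier``
  times the baseline in the top group;
* ``property_slope`` — a per-group-step change of the mean value of a
  named property scale, realised as a composition shift along the
  centered scale vector.

Sites are independent (no within-group phylogeny), matching the
independence assumption of the statistical models; the group-mean
collapsing analysis path covers the dependent case.  Output is fully
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alphabet import AMINO_ACIDS, GAP, decode
from .align_io import (
    AlignedSequence,
    AnnotatedAlignment,
    GroupScheme,
    write_annotated_fasta,
    write_group_config,
)

#: Average amino-acid background frequencies (SwissProt-like), order ACDEFGHIKLMNPQRSTVWY.
NATURAL_FREQUENCIES = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0674, 0.0386, 0.0708, 0.0227, 0.0593,
        0.0582, 0.0965, 0.0241, 0.0406, 0.0472, 0.0393, 0.0553, 0.0660,
        0.0535, 0.0687, 0.0110, 0.0292,
    ]
)
NATURAL_FREQUENCIES = NATURAL_FREQUENCIES / NATURAL_FREQUENCIES.sum()

#: Baseline x->y conversion rate on which ``substitution_bias`` multiplies.
BASE_SUBSTITUTION_RATE = 0.05


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults mirror the scale of a typical comparative screen: 65
    orthologous families, 6 sequences each from 3 ordered temperature
    groups (2 per group), 150 aligned columns, 30% per-site divergence
    from the family ancestor, 2% gaps.
    """

    n_families: int = 65
    groups: tuple = (("mesophile", 2), ("intermediate", 2), ("psychrophile", 2))
    n_sites: int = 150
    base_frequencies: np.ndarray = field(
        default_factory=lambda: NATURAL_FREQUENCIES.copy()
    )
    composition_shift: dict = field(default_factory=dict)  # AA -> delta/step
    substitution_bias: Optional[tuple] = None  # (x, y, multiplier)
    property_slope: Optional[tuple] = None  # (scale_name, beta1, noise_sd)
    divergence: float = 0.3
    gap_rate: float = 0.02
    annotate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.base_frequencies.shape != (20,):
            raise ValueError("base_frequencies must have 20 entries")
        if not np.isclose(self.base_frequencies.sum(), 1.0):
            raise ValueError("base_frequencies must sum to 1")
        if not 0.0 < self.divergence <= 1.0:
            raise ValueError("divergence must be in (0, 1]")


def _shift_vector(spec: FixtureSpec) -> np.ndarray:
    """Signed per-step composition delta (sums to zero): explicit shifts
    plus the property-slope-derived component, with the added mass
    compensated proportionally from the unshifted residues."""
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    raw = np.zeros(20)
    shifted = np.zeros(20, dtype=bool)
    for aa, delta in spec.composition_shift.items():
        raw[aa_index[aa.upper()]] += float(delta)
        shifted[aa_index[aa.upper()]] = True
    if spec.property_slope is not None:
        from .properties import get_scale

        scale_name, beta1 = spec.property_slope[0], float(spec.property_slope[1])
        v = get_scale(scale_name).vector()
        u = v - v.mean()
        raw = raw + beta1 * u / np.sum(u * u)
        shifted[:] = True  # slope component touches every residue
    added = raw[shifted].sum()
    if not shifted.all():
        weights = spec.base_frequencies * ~shifted
        raw = raw - added * weights / weights.sum()
    else:
        raw = raw - raw.sum() * spec.base_frequencies  # keep sum at zero
    return raw


def group_frequency(spec: FixtureSpec, code: int) -> np.ndarray:
    """Expected composition of group ``code``: base + (code-1)*shift."""
    q = spec.base_frequencies + (code - 1) * _shift_vector(spec)
    if np.any(q < 0):
        raise ValueError("infeasible composition shift (negative frequency)")
    return q


def expected_property_slope(spec: FixtureSpec, scale) -> float:
    """Exact expected per-step change of the mean property under the
    generative model: the inner product of the shift vector with the
    scale values."""
    return float(np.dot(_shift_vector(spec), scale.vector()))


def _resample_dist(spec: FixtureSpec, code: int, jitter: float = 0.0) -> np.ndarray:
    """Distribution used when a site diverges, chosen so the marginal
    composition equals base + (code-1)*shift."""
    delta = _shift_vector(spec)
    q = spec.base_frequencies + ((code - 1) * delta + jitter * delta) / spec.divergence
    if np.any(q < 0):
        raise ValueError(
            "infeasible composition shift (negative resampling frequency); "
            "reduce the shift or raise the divergence"
        )
    return q


def group_scheme(spec: FixtureSpec, n_strata: int = 0) -> GroupScheme:
    """The group/stratum scheme matching :func:`generate`'s sequence ids
    (ids are shared across families: the same organisms contribute one
    orthologue to every family)."""
    labels = tuple(label for label, _ in spec.groups)
    assignments = {}
    for label, n in spec.groups:
        for i in range(1, n + 1):
            stratum = f"order{(i - 1) % n_strata + 1}" if n_strata else None
            assignments[f"{label}_{i}"] = (label, stratum)
    return GroupScheme(labels, assignments)


def _markov_ss(rng: np.random.Generator, n_sites: int) -> str:
    """Secondary-structure string from a sticky 3-state Markov chain."""
    states = "HEC"
    out = [rng.integers(0, 3)]
    for _ in range(n_sites - 1):
        if rng.random() < 0.85:
            out.append(out[-1])
        else:
            out.append(rng.integers(0, 3))
    return "".join(states[i] for i in out)


def generate(spec: FixtureSpec, n_strata: int = 0) -> List[AnnotatedAlignment]:
    """Generate ``spec.n_families`` annotated alignments.

    Sequences carry their group codes (and strata when ``n_strata`` is
    set); ids are consistent across families so one group config file
    covers the whole set.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = group_scheme(spec, n_strata)
    codes = scheme.codes
    n_groups = len(spec.groups)
    sub = None
    if spec.substitution_bias is not None:
        x, y, mult = spec.substitution_bias
        aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        sub = (aa_index[x.upper()], aa_index[y.upper()], float(mult))
    noise_sd = 0.0
    if spec.property_slope is not None and len(spec.property_slope) > 2:
        noise_sd = float(spec.property_slope[2])
    # precompute per-group resample distributions (jitter-free)
    alignments = []
    for fam in range(spec.n_families):
        anc = rng.choice(20, size=spec.n_sites, p=spec.base_frequencies)
        seqs = []
        for label, n in spec.groups:
            g = codes[label]
            for i in range(1, n + 1):
                jitter = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                q = _resample_dist(spec, g, jitter)
                r = anc.copy()
                mask = rng.random(spec.n_sites) < spec.divergence
                k = int(mask.sum())
                if k:
                    r[mask] = rng.choice(20, size=k, p=q)
                if sub is not None:
                    xi, yi, mult = sub
                    rate = BASE_SUBSTITUTION_RATE * (
                        1.0 + (mult - 1.0) * (g - 1) / max(n_groups - 1, 1)
                    )
                    hit = (anc == xi) & (r == xi) & (
                        rng.random(spec.n_sites) < rate
                    )
                    r[hit] = yi
                gap_mask = rng.random(spec.n_sites) < spec.gap_rate
                residues = decode(np.where(gap_mask, 20, r))
                ss = None
                rsa = None
                if spec.annotate:
                    ss_str = _markov_ss(rng, spec.n_sites)
                    ss = "".join(
                        GAP if gap_mask[j] else ss_str[j]
                        for j in range(spec.n_sites)
                    )
                    digits = rng.integers(0, 10, size=spec.n_sites)
                    rsa = (digits + 0.5) / 10.0
                    rsa[gap_mask] = np.nan
                sid = f"{label}_{i}"
                stratum = scheme.assignments[sid][1]
                seqs.append(
                    AlignedSequence(sid, residues, group=g, stratum=stratum,
                                    ss=ss, rsa=rsa)
                )
        alignments.append(AnnotatedAlignment(f"fam{fam + 1:03d}", seqs))
    return alignments


def write_fixture(
    spec: FixtureSpec, out_dir, n_strata: int = 0
) -> Tuple[Path, Path]:
    """Generate and write the fixture: ``alignments.fasta`` in the
    annotated dialect plus ``groups.yaml``; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alns = generate(spec, n_strata)
    fasta = out_dir / "alignments.fasta"
    cfg = out_dir / "groups.yaml"
    write_annotated_fasta(alns, fasta)
    write_group_config(group_scheme(spec, n_strata), cfg)
    return fasta, cfg
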