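"""Reading, writing and filtering of annotated protein alignments.

The on-disk format is plain FASTA with two optional annotation record
types attached by header suffix, keeping files valid FASTA for any other
tool:

* ``><seq_id>|2D`` — per-site secondary structure, a string over
  ``H`` (helix), ``E`` (strand), ``C`` (coil/loop), with a gap symbol at
  gap sites;
* ``><seq_id>|3D`` — per-site relative accessible surface area (RSA),
  either a digit string (SABLE-style deciles, digit ``d`` mapping to the
  bin midpoint ``(d + 0.5) / 10``) or whitespace-separated decimals in
  [0, 1] (values in [0, 100] are divided by 100); gap sites may carry
  ``-`` or ``nan``.

Several alignments may live in one file; a comment line starting with
``#`` opens a new alignment block and supplies its identifier.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .alphabet import GAP, encode, normalize_gaps, validate_residues

_SS_VALID = frozenset("HEC") | {GAP}


@dataclass
class AlignedSequence:
    """One aligned protein sequence with optional structure annotation.

    Parameters
    ----------
    seq_id:
        Unique identifier within the alignment.
    residues:
        Aligned residue string over the 20 amino acids plus gap; the gap
        symbols '.', '~' are normalized to '-'.
    group:
        Ordinal phenotypic group code (1..K), or ``None`` if unassigned.
    stratum:
        Taxonomic stratum label, or ``None``.
    ss:
        Optional secondary-structure string (H/E/C plus gap), same length.
    rsa:
        Optional per-site relative accessible surface area in [0, 1];
        NaN allowed at gap sites.
    """

    seq_id: str
    residues: str
    group: Optional[int] = None
    stratum: Optional[str] = None
    ss: Optional[str] = None
    rsa: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.residues = normalize_gaps(self.residues).upper()
        validate_residues(self.residues, self.seq_id)
        n = len(self.residues)
        if self.ss is not None:
            self.ss = normalize_gaps(self.ss).upper()
            if len(self.ss) != n:
                raise ValueError(
                    f"2D record length {len(self.ss)} does not match sequence "
                    f"length {n} for {self.seq_id!r}"
                )
            bad = set(self.ss) - _SS_VALID
            if bad:
                raise ValueError(
                    f"illegal secondary-structure symbol(s) {sorted(bad)} "
                    f"for {self.seq_id!r}"
                )
        if self.rsa is not None:
            self.rsa = np.asarray(self.rsa, dtype=float)
            if self.rsa.shape != (n,):
                raise ValueError(
                    f"3D record length {self.rsa.size} does not match sequence "
                    f"length {n} for {self.seq_id!r}"
                )
            finite = self.rsa[np.isfinite(self.rsa)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError(f"RSA values outside [0, 1] for {self.seq_id!r}")

    @property
    def codes(self) -> np.ndarray:
        """Residues as int8 state codes (gap = 20)."""
        return encode(self.residues)

    def non_gap_mask(self) -> np.ndarray:
        return self.codes != 20


@dataclass
class AnnotatedAlignment:
    """An equal-length multiple protein alignment with metadata.

    ``site_index`` holds the 1-based column numbers of the *original*
    alignment each current column refers to; after :func:`filter_sites`
    it records which sites survived.
    """

    alignment_id: str
    sequences: list
    site_index: tuple = ()

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(
                f"alignment {self.alignment_id!r} needs at least 2 sequences"
            )
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.alignment_id!r} has unequal sequence lengths "
                f"{sorted(lengths)}"
            )
        if not self.site_index:
            self.site_index = tuple(range(1, self.n_sites + 1))
        elif len(self.site_index) != self.n_sites:
            raise ValueError("site_index length must equal n_sites")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0].residues)

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def by_group(self, code: int) -> list:
        return [s for s in self.sequences if s.group == code]

    def group_codes(self) -> list:
        return sorted({s.group for s in self.sequences if s.group is not None})


@dataclass(frozen=True)
class GroupScheme:
    """Ordered phenotypic groups plus the per-sequence assignment map.

    ``labels`` is the ordered list of group labels; the ordinal code of
    ``labels[i]`` is ``i + 1``, and the order defines the ordinal scale
    (e.g. mesophile=1 < intermediate=2 < psychrophile=3).
    ``assignments`` maps seq_id -> (group_label, stratum-or-None).
    """

    labels: tuple
    assignments: dict

    def __post_init__(self) -> None:
        for seq_id, (label, _stratum) in self.assignments.items():
            if label not in self.labels:
                raise ValueError(
                    f"sequence {seq_id!r} assigned to unknown group {label!r}"
                )

    @property
    def codes(self) -> dict:
        return {label: i + 1 for i, label in enumerate(self.labels)}

    def code_of(self, label: str) -> int:
        return self.codes[label]

    @property
    def n_groups(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SiteFilter:
    """Structural constraint on alignment columns.

    A column passes when, among sequences that are annotated and non-gap
    there, the fraction satisfying the constraint is >= ``consensus_rule``.
    ``surface`` means RSA >= ``rsa_threshold``; ``core`` means
    RSA < ``rsa_threshold``.
    """

    ss_classes: Optional[frozenset] = None  # subset of {H, E, C}; None = all
    exposure: str = "any"  # any | surface | core
    rsa_threshold: float = 0.25
    consensus_rule: float = 0.5

    def __post_init__(self) -> None:
        if self.ss_classes is not None:
            object.__setattr__(self, "ss_classes", frozenset(self.ss_classes))
            bad = set(self.ss_classes) - set("HEC")
            if bad:
                raise ValueError(f"unknown secondary-structure classes {sorted(bad)}")
        if self.exposure not in ("any", "surface", "core"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if not 0.0 <= self.rsa_threshold <= 1.0:
            raise ValueError("rsa_threshold must be in [0, 1]")
        if not 0.0 < self.consensus_rule <= 1.0:
            raise ValueError("consensus_rule must be in (0, 1]")

    @property
    def restricts(self) -> bool:
        return self.ss_classes is not None or self.exposure != "any"


# ---------------------------------------------------------------------------
# FASTA dialect I/O
# ---------------------------------------------------------------------------


def _parse_rsa_body(body: str, n_sites: int, seq_id: str) -> np.ndarray:
    body = body.strip()
    compact = body.replace(" ", "")
    if len(compact) == n_sites and all(c.isdigit() or c in "-.~" for c in compact):
        # SABLE-style decile digits; '-'/'.'/'~' mark missing (gap) sites
        vals = [
            np.nan if c in "-.~" else (int(c) + 0.5) / 10.0 for c in compact
        ]
        return np.asarray(vals)
    tokens = body.split()
    vals = []
    for tok in tokens:
        if tok in ("-", "~", "."):
            vals.append(np.nan)
        else:
            vals.append(float(tok))
    arr = np.asarray(vals, dtype=float)
    if arr.size != n_sites:
        raise ValueError(
            f"3D record length {arr.size} does not match sequence length "
            f"{n_sites} for {seq_id!r}"
        )
    finite = arr[np.isfinite(arr)]
    if finite.size and finite.max() > 1.0:
        arr = arr / 100.0
    return arr


def _split_records(block_text: str) -> list:
    """Split a FASTA block into (id, raw_body_lines) records.

    Annotation bodies may be whitespace-separated number lists, which a
    generic FASTA reader would concatenate without separators, so the
    dialect keeps its own splitter; residue bodies are joined with
    whitespace removed, annotation bodies joined with a space.
    """
    records = []
    rid = None
    body: list = []
    for ln in block_text.splitlines():
        if ln.startswith(">"):
            if rid is not None:
                records.append((rid, body))
            rid = ln[1:].split()[0] if ln[1:].split() else ""
            body = []
        elif rid is not None and ln.strip():
            body.append(ln.strip())
    if rid is not None:
        records.append((rid, body))
    return records


def _parse_block(block_text: str, alignment_id: str) -> AnnotatedAlignment:
    records = _split_records(block_text)
    if not records:
        raise ValueError(f"alignment block {alignment_id!r} contains no records")
    order: list = []
    main: dict = {}
    ann2d: dict = {}
    ann3d: dict = {}
    for rid, body in records:
        if rid.endswith("|2D") or rid.endswith("|3D"):
            base, kind = rid[:-3], rid[-2:]
            target = ann2d if kind == "2D" else ann3d
            if base in target:
                raise ValueError(f"duplicate {kind} record for {base!r}")
            target[base] = " ".join(body)
        else:
            if rid in main:
                raise ValueError(f"duplicate sequence id {rid!r}")
            main[rid] = "".join("".join(body).split())
            order.append(rid)
    for ann, kind in ((ann2d, "2D"), (ann3d, "3D")):
        orphans = set(ann) - set(main)
        if orphans:
            raise ValueError(
                f"{kind} annotation record(s) {sorted(orphans)} have no "
                f"matching sequence in alignment {alignment_id!r}"
            )
    sequences = []
    for rid in order:
        residues = main[rid]
        ss = ann2d.get(rid)
        if ss is not None:
            ss = "".join(ss.split())
        rsa = None
        if rid in ann3d:
            rsa = _parse_rsa_body(ann3d[rid], len(residues), rid)
        sequences.append(AlignedSequence(rid, residues, ss=ss, rsa=rsa))
    return AnnotatedAlignment(alignment_id, sequences)


def read_annotated_fasta(path) -> list:
    """Parse one or more annotated alignments from a FASTA file.

    Returns a list of :class:`AnnotatedAlignment` in file order.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    blocks: list = []  # (alignment_id, [lines])
    current: list = []
    current_id: Optional[str] = None
    n_auto = 0
    for ln in lines:
        if ln.startswith("#"):
            if any(l.strip() for l in current):
                blocks.append((current_id, current))
            current = []
            current_id = ln.lstrip("#").strip() or None
        else:
            current.append(ln)
    if any(l.strip() for l in current):
        blocks.append((current_id, current))
    if not blocks:
        raise ValueError(f"no alignment records found in {path}")
    alignments = []
    for i, (aln_id, blk) in enumerate(blocks):
        if aln_id is None:
            aln_id = path.stem if len(blocks) == 1 else f"{path.stem}_{i + 1}"
            n_auto += 1
        alignments.append(_parse_block("\n".join(blk) + "\n", aln_id))
    return alignments


def write_annotated_fasta(alignments: Iterable, path) -> None:
    """Write alignments in the annotated-FASTA dialect (RSA as decimals)."""
    path = Path(path)
    chunks = []
    for aln in alignments:
        lines = [f"# {aln.alignment_id}"]
        for s in aln:
            lines.append(f">{s.seq_id}")
            lines.append(s.residues)
            if s.ss is not None:
                lines.append(f">{s.seq_id}|2D")
                lines.append(s.ss)
            if s.rsa is not None:
                vals = " ".join(
                    "-" if not np.isfinite(v) else f"{v:.4f}" for v in s.rsa
                )
                lines.append(f">{s.seq_id}|3D")
                lines.append(vals)
        chunks.append("\n".join(lines))
    path.write_text("\n\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# Group configuration
# ---------------------------------------------------------------------------


def read_group_config(path) -> GroupScheme:
    """Read a YAML group/stratum configuration.

    Layout::

        groups: [mesophile, intermediate, psychrophile]
        assignments:
          seq1: mesophile
          seq2: {group: psychrophile, stratum: Alteromonadales}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc or "assignments" not in doc:
        raise ValueError(f"group config {path} must define 'groups' and 'assignments'")
    labels = tuple(str(g) for g in doc["groups"])
    assignments = {}
    for seq_id, val in doc["assignments"].items():
        if isinstance(val, dict):
            assignments[str(seq_id)] = (str(val["group"]), val.get("stratum"))
        else:
            assignments[str(seq_id)] = (str(val), None)
    return GroupScheme(labels, assignments)


def write_group_config(scheme: GroupScheme, path) -> None:
    doc = {
        "groups": list(scheme.labels),
        "assignments": {
            sid: (label if stratum is None else {"group": label, "stratum": stratum})
            for sid, (label, stratum) in scheme.assignments.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def assign_groups(aln: AnnotatedAlignment, scheme: GroupScheme) -> AnnotatedAlignment:
    """Return a copy of ``aln`` whose sequences carry ordinal group codes
    and strata from ``scheme``; the input is left unmodified."""
    missing = [s.seq_id for s in aln if s.seq_id not in scheme.assignments]
    if missing:
        raise ValueError(
            f"sequence id(s) not in the group scheme: {', '.join(sorted(missing))}"
        )
    codes = scheme.codes
    new_seqs = []
    for s in aln:
        label, stratum = scheme.assignments[s.seq_id]
        new_seqs.append(
            dataclasses.replace(s, group=codes[label], stratum=stratum)
        )
    present = {s.group for s in new_seqs}
    for label, code in codes.items():
        if code not in present:
            warnings.warn(
                f"group {label!r} (code {code}) has no sequences in alignment "
                f"{aln.alignment_id!r}",
                stacklevel=2,
            )
    return AnnotatedAlignment(aln.alignment_id, new_seqs, aln.site_index)


# ---------------------------------------------------------------------------
# Structural site filtering
# ---------------------------------------------------------------------------


def filter_sites(aln: AnnotatedAlignment, f: SiteFilter) -> AnnotatedAlignment:
    """Keep the columns that satisfy the structural constraint.

    For each column, the fraction of annotated, non-gap sequences meeting
    the constraint must be >= ``f.consensus_rule``.  The surviving 1-based
    original column numbers are recorded in ``site_index``.
    """
    if not f.restricts:
        return aln
    need_ss = f.ss_classes is not None
    need_rsa = f.exposure != "any"
    if need_ss and not any(s.ss is not None for s in aln):
        raise ValueError(
            f"filter requires secondary-structure (2D) annotation, but no "
            f"sequence of {aln.alignment_id!r} carries it"
        )
    if need_rsa and not any(s.rsa is not None for s in aln):
        raise ValueError(
            f"filter requires surface-area (3D) annotation, but no sequence "
            f"of {aln.alignment_id!r} carries it"
        )
    keep = []
    for j in range(aln.n_sites):
        n_eval = 0
        n_ok = 0
        for s in aln:
            if s.residues[j] == GAP:
                continue
            if need_ss and (s.ss is None or s.ss[j] == GAP):
                continue
            if need_rsa and (s.rsa is None or not np.isfinite(s.rsa[j])):
                continue
            n_eval += 1
            ok = True
            if need_ss and s.ss[j] not in f.ss_classes:
                ok = False
            if ok and need_rsa:
                is_surface = s.rsa[j] >= f.rsa_threshold
                if f.exposure == "surface" and not is_surface:
                    ok = False
                if f.exposure == "core" and is_surface:
                    ok = False
            n_ok += ok
        if n_eval > 0 and n_ok / n_eval >= f.consensus_rule:
            keep.append(j)
    new_seqs = []
    for s in aln:
        residues = "".join(s.residues[j] for j in keep)
        ss = "".join(s.ss[j] for j in keep) if s.ss is not None else None
        rsa = s.rsa[keep] if s.rsa is not None else None
        new_seqs.append(
            AlignedSequence(s.seq_id, residues, s.group, s.stratum, ss, rsa)
        )
    site_index = tuple(aln.site_index[j] for j in keep)
    if len(keep) == 0:
        raise ValueError(
            f"no column of alignment {aln.alignment_id!r} passes the filter"
        )
    return AnnotatedAlignment(aln.alignment_id, new_seqs, site_index)
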