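"""Readers and writers for every external format the aligner touches.

Profile HMMs come in the hhsuite ``.hhm`` text dialect (per-column amino-acid
emission probabilities, seven transition probabilities and diversity values,
all encoded as ``-1000*log2(p)`` integers with ``*`` standing for probability
zero).  Structural annotations arrive either as PSIPRED ``.ss2`` VFORMAT
predictions (target side) or as a plain whitespace table of DSSP-style
secondary structure plus relative solvent accessibility (template side).
Reference alignments are gapped two-record FASTA; predicted alignments are
written back as gapped FASTA or Modeller-compatible PIR.

All residue indices are 0-based internally; rendered text output is 1-based.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Amino-acid column order used by hhsuite .hhm files and everywhere internally.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(AA_ORDER)}

#: Transition column order of the .hhm dialect.
TRANSITION_ORDER = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

#: Background amino-acid frequencies (Robinson & Robinson counts, normalised),
#: in AA_ORDER; used when a profile file carries no NULL line.
DEFAULT_BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
DEFAULT_BACKGROUND = DEFAULT_BACKGROUND / DEFAULT_BACKGROUND.sum()

SS_CLASSES = "HEC"
SS_INDEX = {c: k for k, c in enumerate(SS_CLASSES)}
#: 8-class DSSP letters collapsed onto 3 classes.
DSSP_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", ".": "C", "P": "C",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProfileHMM:
    """Per-column emission/transition probabilities for one protein chain.

    ``emissions`` has shape (L, 20) in :data:`AA_ORDER`; ``transitions`` has
    shape (L, 7) in :data:`TRANSITION_ORDER`; ``neff`` is the per-column
    effective sequence count (>= 1).
    """

    name: str
    sequence: str
    emissions: np.ndarray
    transitions: np.ndarray
    neff: np.ndarray
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.neff = np.asarray(self.neff, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise ParseError(f"profile {self.name!r} has zero columns")
        if self.emissions.shape != (L, 20):
            raise ParseError(
                f"profile {self.name!r}: {self.emissions.shape[0]} emission "
                f"columns but sequence length {L}"
            )
        if self.transitions.shape != (L, 7):
            raise ParseError(f"profile {self.name!r}: bad transition table shape")
        if np.any(self.emissions < -1e-12) or np.any(self.emissions > 1 + 1e-9):
            raise ParseError(f"profile {self.name!r}: emission outside [0, 1]")
        if np.any(np.abs(self.emissions.sum(axis=1) - 1.0) > 1e-6):
            raise ParseError(f"profile {self.name!r}: emission rows do not sum to 1")
        t = self.transitions
        for cols, label in (((0, 1, 2), "M"), ((3, 4), "I"), ((5, 6), "D")):
            if np.any(np.abs(t[:, list(cols)].sum(axis=1) - 1.0) > 1e-6):
                raise ParseError(
                    f"profile {self.name!r}: transitions out of {label} do not sum to 1"
                )
        if np.any(self.neff < 1.0 - 1e-9):
            raise ParseError(f"profile {self.name!r}: neff below 1")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ParseError(f"profile {self.name!r}: background does not sum to 1")


@dataclass
class StructuralAnnotation:
    """Per-residue 3-class secondary structure and solvent accessibility.

    ``ss_probs`` has shape (L, 3) in H/E/C order (one-hot when observed);
    ``rsa`` is relative solvent accessibility clamped to [0, 1]; ``source``
    is ``"observed"`` (template, e.g. DSSP-derived) or ``"predicted"``
    (target, e.g. PSIPRED).
    """

    ss: str
    ss_probs: np.ndarray
    rsa: np.ndarray
    source: str = "observed"

    def __post_init__(self) -> None:
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.ss)

    def validate(self) -> None:
        L = len(self.ss)
        if self.ss_probs.shape != (L, 3):
            raise ParseError("annotation: ss_probs shape mismatch")
        if self.rsa.shape != (L,):
            raise ParseError("annotation: rsa length mismatch")
        if np.any(np.abs(self.ss_probs.sum(axis=1) - 1.0) > 1e-6):
            raise ParseError("annotation: ss_probs rows do not sum to 1")
        if np.any(self.rsa < -1e-12) or np.any(self.rsa > 1 + 1e-12):
            raise ParseError("annotation: rsa outside [0, 1]")
        if self.source not in ("observed", "predicted"):
            raise ParseError(f"annotation: unknown source {self.source!r}")
        for k, c in enumerate(self.ss):
            if c not in SS_INDEX:
                raise ParseError(f"annotation: unknown ss class {c!r}")
            # argmax with the fixed H > E > C tie order
            row = self.ss_probs[k]
            if SS_INDEX[c] != int(np.argmax(row)):
                raise ParseError(f"annotation: ss[{k}] is not the argmax class")

    @property
    def ss_indices(self) -> np.ndarray:
        return np.array([SS_INDEX[c] for c in self.ss], dtype=int)


@dataclass
class ReferenceAlignment:
    """A reference (training) alignment: matched residue pairs plus its path.

    ``pairs`` is an ordered list of 0-based ``(template_index, target_index)``
    matches, strictly increasing in both coordinates.  ``path`` is the implied
    three-state global alignment path over the full lattice (set lazily by
    :func:`parse_reference_alignment`).
    """

    template_name: str
    target_name: str
    pairs: List[Tuple[int, int]]
    template_length: int
    target_length: int
    path: "object" = None  # AlignmentPath; typed loosely to avoid an import cycle

    def __post_init__(self) -> None:
        last = (-1, -1)
        for i, j in self.pairs:
            if not (i > last[0] and j > last[1]):
                raise ParseError("reference alignment pairs not strictly increasing")
            if not (0 <= i < self.template_length and 0 <= j < self.target_length):
                raise ParseError("reference alignment pair index out of range")
            last = (i, j)


# ---------------------------------------------------------------------------
# .hhm profiles
# ---------------------------------------------------------------------------


def _decode_hhm_field(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        v = float(tok)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric hhm field {tok!r}") from exc
    return 2.0 ** (-v / 1000.0)


def parse_hhm(stream) -> ProfileHMM:
    """Parse one profile from an hhsuite ``.hhm`` text stream.

    Fields encode ``-1000*log2(p)``; ``*`` decodes to probability 0.  Emission
    rows and transition groups are renormalised after decoding (the integer
    encoding quantises probabilities), with the raw sums validated first.
    Multi-model streams yield the first model with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()

    name = "profile"
    background = None
    hmm_start = None
    for n, line in enumerate(lines):
        if line.startswith("NAME"):
            parts = line.split()
            if len(parts) > 1:
                name = parts[1]
        elif line.startswith("NULL"):
            toks = line.split()[1:]
            if len(toks) != 20:
                raise ParseError(f"line {n + 1}: NULL line needs 20 fields")
            background = np.array(
                [_decode_hhm_field(t, n + 1) for t in toks], dtype=float
            )
        elif line.startswith("HMM"):
            hmm_start = n
            break
    if hmm_start is None:
        raise ParseError("no HMM tag found in .hhm stream")
    if background is None:
        background = DEFAULT_BACKGROUND.copy()
    else:
        s = background.sum()
        if not 0.9 < s < 1.1:
            raise ParseError("NULL background far from a probability vector")
        background = background / s

    seq_chars: List[str] = []
    emis_rows: List[List[float]] = []
    tran_rows: List[List[float]] = []
    neff_vals: List[float] = []

    n = hmm_start + 2  # skip HMM header line and the transition-name line
    while n < len(lines):
        line = lines[n]
        stripped = line.strip()
        if stripped == "" :
            n += 1
            continue
        if stripped.startswith("//"):
            break
        toks = stripped.split()
        # emission line: residue letter, 1-based column, 20 fields, trailing column
        if len(toks) < 22:
            raise ParseError(f"line {n + 1}: expected 22 emission fields, got {len(toks)}")
        seq_chars.append(toks[0])
        emis_rows.append([_decode_hhm_field(t, n + 1) for t in toks[2:22]])
        n += 1
        if n >= len(lines):
            raise ParseError(f"line {n}: truncated .hhm (missing transition line)")
        ttoks = lines[n].split()
        if len(ttoks) < 10:
            raise ParseError(f"line {n + 1}: expected 10 transition fields, got {len(ttoks)}")
        tran_rows.append([_decode_hhm_field(t, n + 1) for t in ttoks[:7]])
        neff_vals.append(_decode_hhm_field(ttoks[7], n + 1))
        n += 1
    else:
        raise ParseError("missing '//' terminator in .hhm stream")

    rest = "\n".join(lines[n + 1:])
    if "HMM" in rest or "NAME" in rest:
        logger.warning("multi-model .hhm stream: keeping first model %r", name)

    if not emis_rows:
        raise ParseError("length-0 profile in .hhm stream")

    emissions = np.array(emis_rows, dtype=float)
    sums = emissions.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 5e-3):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ParseError(f"emission column {bad + 1} sums to {sums[bad]:.4f}, not 1")
    emissions /= sums[:, None]

    transitions = np.array(tran_rows, dtype=float)
    for cols in ((0, 1, 2), (3, 4), (5, 6)):
        block = transitions[:, list(cols)]
        s = block.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 5e-3):
            bad = int(np.argmax(np.abs(s - 1.0)))
            raise ParseError(f"transition group {cols} at column {bad + 1} sums to {s[bad]:.4f}")
        transitions[:, list(cols)] = block / s[:, None]

    # hhm NEFF fields are 1000 * neff, not probabilities: invert the decode
    neff = np.array(
        [-math.log2(v) if v > 0 else 1.0 for v in neff_vals], dtype=float
    )
    neff = np.maximum(neff, 1.0)

    return ProfileHMM(
        name=name,
        sequence="".join(seq_chars),
        emissions=emissions,
        transitions=transitions,
        neff=neff,
        background=background,
    )


def _encode_hhm_field(p: float) -> str:
    if p <= 0.0:
        return "*"
    return str(int(round(-1000.0 * math.log2(p))))


def write_hhm(profile: ProfileHMM) -> str:
    """Render a :class:`ProfileHMM` in the ``.hhm`` dialect read by parse_hhm."""
    out = [
        "HHsearch 1.5",
        f"NAME {profile.name}",
        f"LENG {len(profile)}",
        "NULL " + " ".join(_encode_hhm_field(p) for p in profile.background),
        "HMM " + " ".join(AA_ORDER),
        "     " + " ".join(f"{t[0]}->{t[1]}" for t in TRANSITION_ORDER)
        + " Neff Neff_I Neff_D",
    ]
    for k in range(len(profile)):
        emis = " ".join(_encode_hhm_field(p) for p in profile.emissions[k])
        out.append(f"{profile.sequence[k]} {k + 1} {emis} {k + 1}")
        trans = " ".join(_encode_hhm_field(p) for p in profile.transitions[k])
        # hhm stores 1000*neff directly; the parser inverts via -log2(2^(-v/1000))
        neff_enc = str(int(round(1000.0 * profile.neff[k])))
        out.append(f"     {trans} {neff_enc} {neff_enc} {neff_enc}")
    out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def parse_ss2(stream) -> StructuralAnnotation:
    """Parse a PSIPRED VFORMAT ``.ss2`` stream into a predicted annotation.

    PSIPRED scores are in (C, H, E) column order; they are renormalised and
    reordered to the internal (H, E, C) order.  ``ss`` is the argmax class
    with ties broken H > E > C.  RSA is not part of .ss2; it is set to 0.5
    and expected to be overridden from a companion accessibility source.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    probs: List[List[float]] = []
    for n, line in enumerate(stream):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.split()
        if len(toks) < 6:
            raise ParseError(f"line {n + 1}: malformed .ss2 line {s!r}")
        try:
            c, h, e = float(toks[3]), float(toks[4]), float(toks[5])
        except ValueError as exc:
            raise ParseError(f"line {n + 1}: non-numeric .ss2 score") from exc
        probs.append([h, e, c])
    if not probs:
        raise ParseError("empty .ss2 stream")
    arr = np.array(probs, dtype=float)
    sums = arr.sum(axis=1)
    if np.any(sums <= 0):
        raise ParseError("zero-score .ss2 row")
    arr /= sums[:, None]
    ss = "".join(SS_CLASSES[int(np.argmax(row))] for row in arr)
    return StructuralAnnotation(
        ss=ss, ss_probs=arr, rsa=np.full(len(ss), 0.5), source="predicted"
    )


def parse_annotation_table(stream, source: str = "observed") -> StructuralAnnotation:
    """Parse a plain whitespace annotation table: index, residue, ss, rsa.

    Accepts 8-class DSSP letters, collapsed as {H,G,I}->H, {E,B}->E, else C.
    RSA values are clamped to [0, 1]; a clamp logs a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ss_chars: List[str] = []
    rsa_vals: List[float] = []
    for n, line in enumerate(stream):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        toks = s.split()
        if len(toks) < 4:
            raise ParseError(f"line {n + 1}: malformed annotation line {s!r}")
        letter = toks[2].upper()
        if letter not in DSSP_TO_3:
            raise ParseError(f"line {n + 1}: unknown ss letter {letter!r}")
        try:
            rsa = float(toks[3])
        except ValueError as exc:
            raise ParseError(f"line {n + 1}: non-numeric rsa") from exc
        if rsa < 0.0 or rsa > 1.0:
            logger.warning("line %d: rsa %.3f clamped to [0, 1]", n + 1, rsa)
            rsa = min(max(rsa, 0.0), 1.0)
        ss_chars.append(DSSP_TO_3[letter])
        rsa_vals.append(rsa)
    if not ss_chars:
        raise ParseError("empty annotation table")
    ss = "".join(ss_chars)
    probs = np.zeros((len(ss), 3))
    for k, c in enumerate(ss):
        probs[k, SS_INDEX[c]] = 1.0
    return StructuralAnnotation(
        ss=ss, ss_probs=probs, rsa=np.array(rsa_vals), source=source
    )


def write_annotation_table(ann: StructuralAnnotation, sequence: str | None = None) -> str:
    seq = sequence or "X" * len(ann)
    lines = ["# idx res ss rsa"]
    for k in range(len(ann)):
        lines.append(f"{k + 1} {seq[k]} {ann.ss[k]} {ann.rsa[k]:.4f}")
    return "\n".join(lines) + "\n"


def write_ss2(ann: StructuralAnnotation, sequence: str | None = None) -> str:
    """Render a predicted annotation in PSIPRED VFORMAT (C, H, E score order)."""
    seq = sequence or "X" * len(ann)
    lines = ["# PSIPRED VFORMAT", ""]
    for k in range(len(ann)):
        h, e, c = ann.ss_probs[k]
        lines.append(
            f"{k + 1:4d} {seq[k]} {ann.ss[k]}   {c:.3f}  {h:.3f}  {e:.3f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def _gapped_records(path, template: ProfileHMM, target: ProfileHMM) -> Tuple[str, str]:
    """Render an alignment path as two equal-length gapped strings.

    Unaligned flanks (local/glocal paths) are emitted as gaps so that both
    records always cover their full ungapped sequences.
    """
    Ls, Lt = len(template), len(target)
    i0, j0 = path.start_cell
    srow = list(template.sequence[:i0]) + ["-"] * j0
    trow = ["-"] * i0 + list(target.sequence[:j0])
    i, j = i0, j0
    for state, (ci, cj) in zip(path.states, path.cells):
        di, dj = ci - i, cj - j
        if (di, dj) == (1, 1):
            srow.append(template.sequence[i])
            trow.append(target.sequence[j])
        elif (di, dj) == (1, 0):
            srow.append(template.sequence[i])
            trow.append("-")
        elif (di, dj) == (0, 1):
            srow.append("-")
            trow.append(target.sequence[j])
        else:
            raise ValueError(f"path step {state!r} has illegal delta ({di},{dj})")
        i, j = ci, cj
    if i > Ls or j > Lt:
        raise ValueError("path inconsistent with sequence lengths")
    srow += list(template.sequence[i:]) + ["-"] * (Lt - j)
    trow += ["-"] * (Ls - i) + list(target.sequence[j:])
    return "".join(srow), "".join(trow)


def write_alignment(path, template: ProfileHMM, target: ProfileHMM,
                    fmt: str = "fasta") -> str:
    """Emit a pairwise alignment as gapped FASTA or Modeller-compatible PIR."""
    srow, trow = _gapped_records(path, template, target)
    if fmt == "fasta":
        recs = [
            SeqRecord(Seq(srow), id=template.name, description=""),
            SeqRecord(Seq(trow), id=target.name, description=""),
        ]
        buf = io.StringIO()
        SeqIO.write(recs, buf, "fasta")
        return buf.getvalue()
    if fmt == "pir":
        ls, lt = len(template), len(target)
        return (
            f">P1;{template.name}\n"
            f"structureX:{template.name}:1:A:{ls}:A::::\n"
            f"{srow}*\n"
            f">P1;{target.name}\n"
            f"sequence:{target.name}:1:A:{lt}:A::::\n"
            f"{trow}*\n"
        )
    raise ValueError(f"unknown alignment format {fmt!r}")


def parse_reference_alignment(stream, Ls: int, Lt: int) -> ReferenceAlignment:
    """Parse a gapped two-record FASTA into a :class:`ReferenceAlignment`.

    The first record is the template (structure), the second the target.
    Columns with residues in both records are matches (M); template-only
    columns are D, target-only columns are I; gap-only columns are an error.
    """
    from .crf_engine import AlignmentPath  # local import: avoid cycle

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    recs = list(SeqIO.parse(stream, "fasta"))
    if len(recs) != 2:
        raise ParseError(f"expected 2 FASTA records, got {len(recs)}")
    srow, trow = str(recs[0].seq), str(recs[1].seq)
    if len(srow) != len(trow):
        raise ParseError("alignment records have unequal lengths")
    s_len = len(srow.replace("-", ""))
    t_len = len(trow.replace("-", ""))
    if s_len != Ls or t_len != Lt:
        raise ParseError(
            f"ungapped lengths ({s_len}, {t_len}) do not match declared ({Ls}, {Lt})"
        )
    pairs: List[Tuple[int, int]] = []
    states: List[str] = []
    cells: List[Tuple[int, int]] = []
    i = j = 0
    for col, (a, b) in enumerate(zip(srow, trow)):
        if a != "-" and b != "-":
            pairs.append((i, j))
            i, j = i + 1, j + 1
            states.append("M")
        elif a != "-":
            i += 1
            states.append("D")
        elif b != "-":
            j += 1
            states.append("I")
        else:
            raise ParseError(f"gap-only column {col + 1} in reference alignment")
        cells.append((i, j))
    path = AlignmentPath(
        scheme="three_state", states=states, cells=cells, Ls=Ls, Lt=Lt
    )
    return ReferenceAlignment(
        template_name=recs[0].id,
        target_name=recs[1].id,
        pairs=pairs,
        template_length=Ls,
        target_length=Lt,
        path=path,
    )
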