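"""Position-weight-matrix motifs: parsing, similarity scoring, scanning, enrichment.

A motif is modelled as per-position base frequencies over {A,C,G,T} plus a
per-position information weight ``info[i] = sum_b f(i,b) * ln(4 f(i,b))``.
Windows are scored with the information-weighted matrix-similarity score
normalised to [0, 1] (the scheme used with TRANSFAC matrix profiles): the
consensus window scores exactly 1, the anti-consensus exactly 0.  The TFBS
enrichment score of a sequence for one matrix is the sum of the similarity
scores of all windows, on either strand, that reach the matrix cutoff.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# integer complement permutation for A,C,G,T plus the ambiguity slot
_COMP_PERM = np.array([3, 2, 1, 0, 4])


class MotifParseError(ValueError):
    """Raised for malformed motif input; the message names the offending line."""


class ConfigurationError(RuntimeError):
    """Raised when an operation needs configuration (e.g. a cutoff) that is unset."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMatrix:
    """One motif: per-position base frequencies, information weights, cutoff.

    ``freqs`` has shape (length, 4), each row summing to 1.  ``info`` defaults
    to the relative-entropy weight computed from ``freqs`` but may be supplied
    explicitly (the similarity score is invariant to rescaling it by a
    positive constant).  ``cutoff`` is the similarity threshold in [0, 1]
    below which windows are not counted as hits.
    """

    matrix_id: str
    freqs: np.ndarray
    info: np.ndarray | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError(f"{self.matrix_id}: freqs must have shape (length, 4)")
        if (f < 0).any():
            raise ValueError(f"{self.matrix_id}: negative frequency")
        sums = f.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{self.matrix_id}: frequency rows must sum to 1")
        self.freqs = f
        if self.info is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
            self.info = np.maximum(terms.sum(axis=1), 0.0)
        else:
            info = np.asarray(self.info, dtype=float)
            if info.shape != (f.shape[0],) or (info < 0).any():
                raise ValueError(f"{self.matrix_id}: info must be non-negative, one per position")
            self.info = info
        if self.cutoff is not None and not (0.0 <= self.cutoff <= 1.0):
            raise ValueError(f"{self.matrix_id}: cutoff must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def _score_table(self) -> tuple[np.ndarray, float, float]:
        """Info-weighted lookup (length x 5; column 4 = ambiguous base) and the
        per-window min / max achievable raw scores."""
        w = self.info[:, None] * self.freqs
        table = np.empty((self.length, 5))
        table[:, :4] = w
        table[:, 4] = w.mean(axis=1)  # ambiguous base: mean contribution
        lo = float(w.min(axis=1).sum())
        hi = float(w.max(axis=1).sum())
        return table, lo, hi


@dataclass(frozen=True)
class MotifHit:
    """A window passing the cutoff, reported on forward coordinates (0-based)."""

    matrix_id: str
    sequence_id: str
    offset: int
    strand: str  # "+" or "-"
    score: float


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, anything else 4."""
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(codes.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[codes == ord(base)] = idx
    return out


def _window_scores(table: np.ndarray, lo: float, hi: float, codes: np.ndarray) -> np.ndarray:
    """Normalised scores of every forward window of a coded sequence."""
    L = table.shape[0]
    n_win = codes.shape[-1] - L + 1
    if n_win <= 0:
        return np.empty(codes.shape[:-1] + (0,))
    acc = np.zeros(codes.shape[:-1] + (n_win,))
    for k in range(L):
        acc += table[k][codes[..., k : k + n_win]]
    span = hi - lo
    if span <= 1e-12:  # degenerate matrix: every window is maximal
        return np.ones_like(acc)
    return (acc - lo) / span


def _reverse_table(table: np.ndarray) -> np.ndarray:
    """Score table whose forward application scores the reverse complement."""
    return table[::-1][:, _COMP_PERM]


def match_score(pwm: PWMatrix, window: str) -> float:
    """Similarity of one window to the matrix, in [0, 1]."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != matrix length {pwm.length} for {pwm.matrix_id}"
        )
    table, lo, hi = pwm._score_table()
    return float(_window_scores(table, lo, hi, encode_sequence(window))[0])


def scan(
    pwm: PWMatrix,
    sequence: str,
    cutoff: float | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All windows on either strand scoring >= cutoff, sorted by forward offset."""
    if cutoff is None:
        cutoff = pwm.cutoff
    if cutoff is None:
        raise ConfigurationError(f"{pwm.matrix_id}: no cutoff set and none supplied")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    codes = encode_sequence(sequence)
    if codes.shape[0] < pwm.length:
        return []
    table, lo, hi = pwm._score_table()
    fwd = _window_scores(table, lo, hi, codes)
    rev = _window_scores(_reverse_table(table), lo, hi, codes)
    hits: list[MotifHit] = []
    for offset in range(fwd.shape[0]):
        if fwd[offset] >= cutoff:
            hits.append(MotifHit(pwm.matrix_id, sequence_id, offset, "+", float(fwd[offset])))
        if rev[offset] >= cutoff:
            hits.append(MotifHit(pwm.matrix_id, sequence_id, offset, "-", float(rev[offset])))
    return hits


def enrichment_score(pwm: PWMatrix, sequence: str) -> float:
    """Sum of above-cutoff window scores over both strands (0 when no hit)."""
    if pwm.cutoff is None:
        raise ConfigurationError(f"{pwm.matrix_id}: cutoff unset; set PWMatrix.cutoff first")
    codes = encode_sequence(sequence)
    if codes.shape[0] < pwm.length:
        return 0.0
    table, lo, hi = pwm._score_table()
    total = 0.0
    for t in (table, _reverse_table(table)):
        s = _window_scores(t, lo, hi, codes)
        total += float(s[s >= pwm.cutoff].sum())
    return total


def enrichment_matrix(pwms: list[PWMatrix], sequences: dict[str, str]) -> pd.DataFrame:
    """Per-sequence enrichment scores for every matrix (rows: sequence ids).

    Sequences of equal length are scored in one vectorised batch, which is the
    fast path for simulated libraries of fixed-length constructs.
    """
    for pwm in pwms:
        if pwm.cutoff is None:
            raise ConfigurationError(f"{pwm.matrix_id}: cutoff unset")
    ids = list(sequences)
    out = pd.DataFrame(0.0, index=pd.Index(ids, name="sequence_id"),
                       columns=[p.matrix_id for p in pwms])
    by_length: dict[int, list[str]] = {}
    for sid in ids:
        by_length.setdefault(len(sequences[sid]), []).append(sid)
    for length, group in by_length.items():
        codes = np.stack([encode_sequence(sequences[sid]) for sid in group])
        for pwm in pwms:
            if length < pwm.length:
                continue
            table, lo, hi = pwm._score_table()
            total = np.zeros(len(group))
            for t in (table, _reverse_table(table)):
                s = _window_scores(t, lo, hi, codes)
                total += np.where(s >= pwm.cutoff, s, 0.0).sum(axis=1)
            out.loc[group, pwm.matrix_id] = total
    return out


def calibrate_minfn_cutoff(
    pwm: PWMatrix,
    target_fnr: float = 0.05,
    n_samples: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo cutoff bounding the false-negative rate on true sites.

    Windows are drawn from the matrix's own frequency model; the cutoff is the
    ``target_fnr`` quantile of their similarity scores, so at least
    ``1 - target_fnr`` of model-generated sites pass.  Deterministic per seed.
    """
    if not (0.0 < target_fnr < 1.0):
        raise ValueError("target_fnr must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(pwm.freqs, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random((n_samples, pwm.length))
    codes = np.empty((n_samples, pwm.length), dtype=np.int8)
    for i in range(pwm.length):
        codes[:, i] = np.searchsorted(cum[i], u[:, i], side="right")
    table, lo, hi = pwm._score_table()
    acc = np.zeros(n_samples)
    for k in range(pwm.length):
        acc += table[k][codes[:, k]]
    span = hi - lo
    if span <= 1e-12:
        return 1.0 - 1e-9
    scores = (acc - lo) / span
    q = float(np.quantile(scores, target_fnr))
    return min(q, 1.0 - 1e-9)


def copy_number_range(total_score: float, cutoff: float, tol: float = 1e-9) -> list[int]:
    """Site counts consistent with a total enrichment score.

    Each counted hit scores in [cutoff, 1], so a total S is attainable with k
    sites iff k*cutoff <= S <= k.  With a stringent cutoff a single total can
    pin the copy number exactly (e.g. cutoff 0.866: a total of 3.9 is only
    attainable with 4 sites).
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    if total_score < -tol:
        raise ValueError("total score must be non-negative")
    if total_score <= tol:
        return [0]
    upper = int(math.floor(total_score / cutoff + tol))
    return [k for k in range(1, upper + 1)
            if k * cutoff <= total_score + tol and total_score <= k + tol]


# ---------------------------------------------------------------------------
# Motif file formats
# ---------------------------------------------------------------------------

def _looks_like_counts(rows: np.ndarray) -> bool:
    return bool((rows > 1.0 + 1e-9).any() or not np.allclose(rows.sum(axis=1), 1.0, atol=1e-3))


def _rows_to_matrix(matrix_id: str, rows: np.ndarray, pseudocount: float | None) -> PWMatrix:
    if pseudocount is None:
        pseudocount = 1.0 if _looks_like_counts(rows) else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    adj = rows + pseudocount
    sums = adj.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise MotifParseError(f"{matrix_id}: a position has zero total weight")
    return PWMatrix(matrix_id, adj / sums)


def _parse_transfac(text: str, pseudocount: float | None) -> list[PWMatrix]:
    motifs: list[PWMatrix] = []
    matrix_id: str | None = None
    col_order: list[int] | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal matrix_id, col_order, rows
        if rows:
            if matrix_id is None:
                raise MotifParseError(f"line {lineno}: matrix block without ID/NA/AC label")
            arr = np.asarray(rows, dtype=float)
            motifs.append(_rows_to_matrix(matrix_id, arr, pseudocount))
        matrix_id, col_order, rows = None, None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line == "XX":
            continue
        if line.startswith("//"):
            flush(lineno)
            continue
        tag = line.split()[0]
        if tag in ("ID", "NA", "AC", "DE"):
            if matrix_id is None or tag == "ID":
                parts = line.split(None, 1)
                matrix_id = parts[1].strip() if len(parts) > 1 else ""
            continue
        if tag in ("P0", "PO"):
            labels = line.split()[1:]
            if sorted(labels[:4]) != ["A", "C", "G", "T"]:
                raise MotifParseError(f"line {lineno}: P0 header must list bases A C G T")
            col_order = [labels.index(b) for b in BASES]
            continue
        if tag[0].isdigit():
            fields = line.split()
            vals = fields[1:5]
            if len(vals) < 4:
                raise MotifParseError(f"line {lineno}: expected 4 base counts, got {len(vals)}")
            try:
                nums = [float(v) for v in vals]
            except ValueError as exc:
                raise MotifParseError(f"line {lineno}: non-numeric count ({exc})") from None
            if col_order is None:
                col_order = [0, 1, 2, 3]
            rows.append([nums[i] for i in col_order])
            continue
        # other annotation tags (BF, CC, ...) are ignored
    flush(lineno=len(text.splitlines()))
    return motifs


def _parse_jaspar(text: str, pseudocount: float | None) -> list[PWMatrix]:
    from Bio import motifs as bio_motifs

    if not text.strip():
        return []
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
        parsed = [(m.name or m.base_id or "motif", m.counts) for m in records]
    except Exception as exc:
        raise MotifParseError(f"malformed JASPAR input: {exc}") from exc
    out = []
    for name, counts in parsed:
        arr = np.asarray([counts[b] for b in BASES], dtype=float).T
        out.append(_rows_to_matrix(name, arr, pseudocount))
    return out


def parse_motifs(text: str, fmt: str = "transfac", pseudocount: float | None = None) -> list[PWMatrix]:
    """Parse TRANSFAC flat-file blocks or JASPAR PFM records.

    ``pseudocount`` is added to every cell before row normalisation; by
    default it is 1.0 for count matrices and 0.0 for matrices already given
    as frequencies.  Cutoffs are left unset.
    """
    fmt = fmt.lower()
    if fmt == "transfac":
        return _parse_transfac(text, pseudocount)
    if fmt in ("jaspar", "pfm"):
        return _parse_jaspar(text, pseudocount)
    raise ValueError(f"unknown motif format: {fmt!r}")


def write_motifs(pwms: list[PWMatrix], fmt: str = "transfac") -> str:
    """Serialise matrices (frequencies) in TRANSFAC or JASPAR PFM layout."""
    fmt = fmt.lower()
    chunks: list[str] = []
    if fmt == "transfac":
        for pwm in pwms:
            lines = [f"ID {pwm.matrix_id}", "XX", "P0      A      C      G      T"]
            for i, row in enumerate(pwm.freqs, start=1):
                cells = "  ".join(f"{v:8.6f}" for v in row)
                lines.append(f"{i:02d}  {cells}  {pwm.consensus[i - 1]}")
            lines += ["XX", "//"]
            chunks.append("\n".join(lines))
        return "\n".join(chunks) + "\n"
    if fmt in ("jaspar", "pfm"):
        for pwm in pwms:
            lines = [f">{pwm.matrix_id}"]
            for b in BASES:
                vals = " ".join(f"{v:.6f}" for v in pwm.freqs[:, _BASE_INDEX[b]])
                lines.append(f"{b} [ {vals} ]")
            chunks.append("\n".join(lines))
        return "\n".join(chunks) + "\n"
    raise ValueError(f"unknown motif format: {fmt!r}")


def read_fasta(source) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines, any case) as id -> uppercase sequence."""
    from Bio import SeqIO

    handle = io.StringIO(source.read()) if hasattr(source, "read") else source
    if isinstance(handle, str):
        with open(handle) as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def hits_to_bed(hits: list[MotifHit], lengths: dict[str, int]) -> pd.DataFrame:
    """BED-like table (seq_id, start, end, matrix_id, score, strand)."""
    rows = [
        (h.sequence_id, h.offset, h.offset + lengths[h.matrix_id], h.matrix_id, h.score, h.strand)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "matrix_id", "score", "strand"])
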