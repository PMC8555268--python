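"""Alignment, weight-file and Potts-parameter-file input/output.

Sequences are stored integer-encoded over a fixed :class:`Alphabet` whose
first symbol is always the alignment gap ``'-'`` (code 0).  The protein
alphabet has q=21 states (20 amino acids plus gap), the RNA alphabet q=5
(four nucleotides plus gap).  Encoding is case-insensitive; ``'.'`` and any
character outside the alphabet (ambiguity codes such as ``'X'`` or ``'B'``)
map to the gap state, the usual DCA convention.

Parameter files are plain text, one entry per line::

    J i j a b value      (couplings, 0-based indices, i < j)
    h i a value          (fields)

Entries absent from a file are zero; in *topology mode* they are additionally
masked inactive, i.e. pinned to zero for the rest of a training run.  Files
written by :func:`write_parameters` round-trip bitwise through
:func:`read_parameters` (values are printed with 17 significant digits).
External files using a different dialect (e.g. letter labels or 1-based
indices) should be converted to this format first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "MSA",
    "PROTEIN",
    "RNA",
    "encode_sequence",
    "read_fasta",
    "write_fasta",
    "read_weights",
    "write_weights",
    "write_parameters",
    "read_parameters",
    "read_pair_list",
]

GAP = "-"
PROTEIN_SYMBOLS = "-ACDEFGHIKLMNPQRSTVWY"
RNA_SYMBOLS = "-ACGU"


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol table; gap first, so gap code is always 0."""

    name: str
    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.symbols[0] != GAP:
            raise ValueError("the gap symbol '-' must come first")

    @property
    def q(self) -> int:
        return len(self.symbols)

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("protein", PROTEIN_SYMBOLS)

    @classmethod
    def rna(cls) -> "Alphabet":
        return cls("rna", RNA_SYMBOLS)

    @classmethod
    def custom(cls, symbols: str, name: str = "custom") -> "Alphabet":
        return cls(name, symbols)

    def encode(self, text: str) -> np.ndarray:
        """Integer-encode one sequence; unknown symbols become the gap (0)."""
        if not text:
            raise ValueError("cannot encode an empty sequence")
        table = {c: i for i, c in enumerate(self.symbols.upper())}
        return np.array([table.get(c, 0) for c in text.upper()], dtype=np.int8)

    def decode(self, codes: np.ndarray) -> str:
        codes = np.asarray(codes)
        if codes.size and (codes.min() < 0 or codes.max() >= self.q):
            raise ValueError(
                f"code out of range for alphabet {self.name!r} (q={self.q})"
            )
        return "".join(self.symbols[int(c)] for c in codes)


PROTEIN = Alphabet.protein()
RNA = Alphabet.rna()


def encode_sequence(text: str, alphabet: Alphabet) -> np.ndarray:
    return alphabet.encode(text)


@dataclass
class MSA:
    """An integer-encoded multiple sequence alignment.

    ``data`` is an M x L matrix of codes in ``[0, q)``; ``weights``, when
    present, are the per-sequence statistical weights w^mu in (0, 1].
    """

    names: list[str]
    data: np.ndarray
    alphabet: Alphabet
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("MSA data must be a 2-D matrix")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per sequence required")
        if self.data.size and (
            self.data.min() < 0 or self.data.max() >= self.alphabet.q
        ):
            raise ValueError("sequence codes must lie in [0, q)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.data.shape[0],):
                raise ValueError("weights must have one entry per sequence")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]


def read_fasta(path: str | Path, alphabet: Alphabet) -> MSA:
    """Read an aligned FASTA file and encode it over ``alphabet``.

    Raises on empty files and on ragged (unequal-length) alignments.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    rows = [alphabet.encode(str(r.seq)) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return MSA([r.id for r in records], np.vstack(rows), alphabet)


def write_fasta(
    names: Sequence[str],
    data: np.ndarray,
    alphabet: Alphabet,
    path: str | Path,
) -> None:
    data = np.asarray(data)
    records = [
        SeqRecord(Seq(alphabet.decode(row)), id=str(name), description="")
        for name, row in zip(names, data, strict=True)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_weights(path: str | Path, n_sequences: int | None = None) -> np.ndarray:
    """Read a weight file: one decimal per line."""
    w = np.loadtxt(str(path), dtype=float, ndmin=1)
    if n_sequences is not None and w.shape != (n_sequences,):
        raise ValueError(
            f"weight file has {w.size} entries, expected {n_sequences}"
        )
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w


def write_weights(weights: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(weights, dtype=float), fmt="%.17g")


def write_parameters(model, path: str | Path) -> None:
    """Write fields and active couplings, one entry per line.

    Masked (inactive) coupling entries are omitted; for a fully active model
    the file has exactly N_p = L(L-1)/2 * q^2 + L*q lines.
    """
    L, q = model.L, model.q
    with open(path, "w") as fh:
        for i in range(L):
            for j in range(i + 1, L):
                block = model.J[i, j]
                active = model.mask[i, j]
                for a in range(q):
                    for b in range(q):
                        if active[a, b]:
                            fh.write(f"J {i} {j} {a} {b} {block[a, b]:.17g}\n")
        for i in range(L):
            for a in range(q):
                fh.write(f"h {i} {a} {model.h[i, a]:.17g}\n")


def read_parameters(path: str | Path, L: int, q: int, topology_mode: bool = False):
    """Read a parameter file into a :class:`~pottsdca.potts_core.PottsModel`.

    With ``topology_mode=True`` coupling entries absent from the file are
    masked inactive (pinned to zero during any later training); otherwise they
    are active with value zero.
    """
    from .potts_core import PottsModel  # deferred to avoid import cycle

    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    mask = np.zeros((L, L, q, q), dtype=bool)
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "J":
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: malformed J line")
                i, j, a, b = (int(x) for x in parts[1:5])
                if not (0 <= i < j < L):
                    raise ValueError(
                        f"{path}:{lineno}: coupling indices require 0 <= i < j < L"
                    )
                if not (0 <= a < q and 0 <= b < q):
                    raise ValueError(f"{path}:{lineno}: state index out of range")
                key = ("J", i, j, a, b)
                if key in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate entry {key}")
                seen.add(key)
                v = float(parts[5])
                J[i, j, a, b] = v
                J[j, i, b, a] = v
                mask[i, j, a, b] = True
                mask[j, i, b, a] = True
            elif parts[0] == "h":
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed h line")
                i, a = int(parts[1]), int(parts[2])
                if not (0 <= i < L and 0 <= a < q):
                    raise ValueError(f"{path}:{lineno}: field index out of range")
                key = ("h", i, a)
                if key in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate entry {key}")
                seen.add(key)
                h[i, a] = float(parts[3])
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {parts[0]!r}")
    if not topology_mode:
        mask = None  # PottsModel default: all off-diagonal entries active
    return PottsModel(h=h, J=J, mask=mask)


def read_pair_list(path: str | Path, L: int) -> list[tuple[int, int]]:
    """Read a whitespace "i j" pair list (1-based on disk, 0-based in memory).

    Used both for coupling-topology files and ground-truth contact lists; a
    trailing distance column, if present, is ignored.
    """
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            i, j = int(parts[0]), int(parts[1])
            if not (1 <= i <= L and 1 <= j <= L) or i == j:
                raise ValueError(f"{path}:{lineno}: bad pair ({i}, {j}) for L={L}")
            i, j = i - 1, j - 1
            pairs.append((min(i, j), max(i, j)))
    return pairs
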