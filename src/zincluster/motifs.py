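"""CXC-superfamily consensus pattern parsing and sequence scanning.

The CXC superfamily (MSL2/tesmin/TSO1 CXC domains and the pre-SET motifs of
SUV39-, SET2- and EZ-family histone methyltransferases) is defined by nine
metal-binding ligand positions with constrained spacing and an invariant
asparagine two residues C-terminal of the ninth ligand.  The consensus is

    CX[C/H]X2-13CX4-7CXCX5-60CX2-4CX1-2CX2-15CXN

where ``X`` is exactly one arbitrary residue and ``Xa-b`` a gap of a..b
arbitrary residues.  The scanner enumerates *all* ligand registrations
consistent with the pattern by bounded backtracking over gap lengths, since
variable gaps can admit several valid registrations of the same region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .errors import PatternError

#: The CXC-superfamily consensus (plain-text gap form).
CXC_CONSENSUS_TEXT = "CX[C/H]X2-13CX4-7CXCX5-60CX2-4CX1-2CX2-15CXN"

_DASHES = "-–—"  # hyphen, en dash, em dash


@dataclass(frozen=True)
class Ligand:
    """A constrained single-residue token (metal ligand or signature residue)."""

    allowed: tuple[str, ...]

    def matches(self, letter: str) -> bool:
        return letter in self.allowed


@dataclass(frozen=True)
class Gap:
    """A run of min..max arbitrary residues."""

    min: int
    max: int


Token = Union[Ligand, Gap]


@dataclass(frozen=True)
class MotifPattern:
    tokens: tuple[Token, ...]

    @property
    def ligand_tokens(self) -> tuple[Ligand, ...]:
        return tuple(t for t in self.tokens if isinstance(t, Ligand))

    @property
    def gap_tokens(self) -> tuple[Gap, ...]:
        return tuple(t for t in self.tokens if isinstance(t, Gap))

    @property
    def has_signature(self) -> bool:
        """True when the final constrained token is a lone Asn (signature)."""
        lt = self.ligand_tokens
        return len(lt) >= 2 and lt[-1].allowed == ("N",)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_tokens) - (1 if self.has_signature else 0)

    def to_text(self) -> str:
        parts = []
        for t in self.tokens:
            if isinstance(t, Ligand):
                parts.append(
                    t.allowed[0] if len(t.allowed) == 1 else "[" + "/".join(t.allowed) + "]"
                )
            elif t.min == t.max:
                parts.append("X" if t.min == 1 else f"X{t.min}")
            else:
                parts.append(f"X{t.min}-{t.max}")
        return "".join(parts)


def parse_pattern(text: str) -> MotifPattern:
    """Parse a pattern string into tokens.

    Grammar: uppercase residue letters; ``[A/B]`` alternatives; ``X`` one
    arbitrary residue; ``Xa-b`` or ``X_a-b_`` a bounded gap (en dash
    accepted).  Adjacent gaps are merged.  Malformed bounds or unknown
    symbols raise :class:`PatternError` with the character offset.
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)

    def read_int(j: int) -> tuple[int, int]:
        k = j
        while k < n and text[k].isdigit():
            k += 1
        if k == j:
            raise PatternError(f"expected number at offset {j}", offset=j)
        return int(text[j:k]), k

    while i < n:
        c = text[i]
        if c == "X":
            j = i + 1
            underscore = j < n and text[j] == "_"
            if underscore:
                j += 1
            if j < n and text[j].isdigit():
                a, j = read_int(j)
                if j < n and text[j] in _DASHES:
                    b, j = read_int(j + 1)
                else:
                    b = a
                if underscore:
                    if j < n and text[j] == "_":
                        j += 1
                    else:
                        raise PatternError(
                            f"unterminated gap subscript at offset {i}", offset=i
                        )
                if a > b:
                    raise PatternError(
                        f"inverted gap bounds {a}-{b} at offset {i}", offset=i
                    )
                tokens.append(Gap(a, b))
                i = j
            elif underscore:
                raise PatternError(f"malformed gap at offset {i}", offset=i)
            else:
                tokens.append(Gap(1, 1))
                i = j
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' at offset {i}", offset=i)
            alts = tuple(s.strip() for s in text[i + 1 : j].split("/"))
            if not alts or any(len(a) != 1 or not a.isalpha() for a in alts):
                raise PatternError(f"malformed alternative at offset {i}", offset=i)
            tokens.append(Ligand(tuple(a.upper() for a in alts)))
            i = j + 1
        elif c.isalpha() and c.isupper():
            tokens.append(Ligand((c,)))
            i += 1
        else:
            raise PatternError(f"unknown symbol {c!r} at offset {i}", offset=i)

    # merge adjacent gaps
    merged: list[Token] = []
    for t in tokens:
        if merged and isinstance(t, Gap) and isinstance(merged[-1], Gap):
            prev = merged.pop()
            merged.append(Gap(prev.min + t.min, prev.max + t.max))
        else:
            merged.append(t)
    return MotifPattern(tokens=tuple(merged))


#: The parsed consensus, ready for scanning.
CXC_CONSENSUS = parse_pattern(CXC_CONSENSUS_TEXT)


@dataclass(frozen=True)
class MotifMatch:
    """A located consensus match with 1-based ligand positions."""

    seq_id: str
    ligand_positions: tuple[int, ...]
    signature_position: int | None
    span: tuple[int, int]  # 1-based inclusive

    @property
    def gap_lengths(self) -> tuple[int, ...]:
        """Residue counts between consecutive ligands (and ligand-9 to the
        signature when present)."""
        positions = list(self.ligand_positions)
        if self.signature_position is not None:
            positions.append(self.signature_position)
        return tuple(b - a - 1 for a, b in zip(positions, positions[1:]))


def scan(
    sequence: str, pattern: MotifPattern = CXC_CONSENSUS, seq_id: str = ""
) -> list[MotifMatch]:
    """All distinct ligand registrations of ``pattern`` in ``sequence``.

    Input is case-normalized; non-canonical letters never satisfy ligand
    tokens but do fill gap positions.  Matches are deduplicated by ligand
    tuple and ordered by (start, ligand tuple).  No match yields an empty
    list, never an error.
    """
    seq = sequence.upper()
    n = len(seq)
    tokens = pattern.tokens
    found: dict[tuple[int, ...], MotifMatch] = {}

    def rec(ti: int, pos: int, constrained: list[int], start: int) -> None:
        if ti == len(tokens):
            lig = tuple(constrained)
            if pattern.has_signature:
                positions, signature = lig[:-1], lig[-1]
            else:
                positions, signature = lig, None
            key = lig
            if key not in found:
                found[key] = MotifMatch(
                    seq_id=seq_id,
                    ligand_positions=positions,
                    signature_position=signature,
                    span=(start, pos),  # pos is 1 past last matched (0-based) => 1-based inclusive
                )
            return
        tok = tokens[ti]
        if isinstance(tok, Ligand):
            if pos < n and tok.matches(seq[pos]):
                constrained.append(pos + 1)  # 1-based
                rec(ti + 1, pos + 1, constrained, start)
                constrained.pop()
        else:
            for gap in range(tok.min, tok.max + 1):
                if pos + gap > n:
                    break
                rec(ti + 1, pos + gap, constrained, start)

    for start0 in range(n):
        rec(0, start0, [], start0 + 1)

    return sorted(found.values(), key=lambda m: (m.span[0], m.ligand_positions))


def gap_report(m: MotifMatch) -> tuple[int, ...]:
    """Inter-ligand gap lengths, including the ligand-to-signature gap."""
    return m.gap_lengths


@dataclass(frozen=True)
class TandemPair:
    first: MotifMatch
    second: MotifMatch
    spacer: int


def tandem_scan(
    sequence: str,
    pattern: MotifPattern = CXC_CONSENSUS,
    max_spacer: int = 60,
    seq_id: str = "",
) -> list[TandemPair]:
    """Pairs of non-overlapping matches separated by at most ``max_spacer``
    residues.  ``spacer`` 0 means immediately adjacent domains (EZ pre-SET
    style); spacers of 40-60 correspond to tesmin/TSO1-style arrangements.
    """
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    matches = scan(sequence, pattern, seq_id=seq_id)
    pairs = []
    for a in matches:
        for b in matches:
            spacer = b.span[0] - a.span[1] - 1
            if 0 <= spacer <= max_spacer:
                pairs.append(TandemPair(a, b, spacer))
    return pairs


def scan_fasta(
    path_or_handle, pattern: MotifPattern = CXC_CONSENSUS
) -> list[MotifMatch]:
    """Scan every record of a (multi-record) FASTA file."""
    if isinstance(path_or_handle, (str, Path)):
        records = list(SeqIO.parse(str(path_or_handle), "fasta"))
    else:
        records = list(SeqIO.parse(path_or_handle, "fasta"))
    out: list[MotifMatch] = []
    for rec in records:
        out.extend(scan(str(rec.seq), pattern, seq_id=rec.id))
    return out


def matches_to_tsv(matches: Iterable[MotifMatch]) -> str:
    """TSV report: seq_id, ligand positions, gaps, signature position, span."""
    lines = ["seq_id\tligands\tgaps\tsignature\tstart\tend"]
    for m in matches:
        lines.append(
            "\t".join(
                [
                    m.seq_id,
                    ",".join(str(p) for p in m.ligand_positions),
                    ",".join(str(g) for g in m.gap_lengths),
                    str(m.signature_position or ""),
                    str(m.span[0]),
                    str(m.span[1]),
                ]
            )
        )
    return "\n".join(lines) + "\n"
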