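"""Readers and writers for structure and alignment formats.

Structures: extended dot-bracket (multiple bracket layers, so crossing pairs
survive), BPSEQ, and classic 6-column CT.  Alignments: Stockholm with
per-sequence ``#=GR <id> SS`` annotation lines, a Clustal-like block format,
and FASTA with a structure line per record.  All text, UTF-8, LF newlines.
Gap character on output is '-'; '.' is accepted as unpaired on input.
"""

from __future__ import annotations

from pathlib import Path

from .metrics import AlignmentColumns
from .structures import Structure, find_stems

_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_CLOSE_OF = dict(zip(_OPENERS, _CLOSERS))
_OPEN_OF = dict(zip(_CLOSERS, _OPENERS))
_UNPAIRED = ".-:,_~"

GAP = "-"


class FormatError(ValueError):
    """Malformed input file."""


def _get_text(path_or_text: str | Path) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    if "\n" not in path_or_text and Path(path_or_text).is_file():
        return Path(path_or_text).read_text()
    return path_or_text


# ---------------------------------------------------------------- dot-bracket

def parse_dotbracket_pairs(db: str) -> frozenset:
    """Pairs encoded by an extended dot-bracket string (1-based)."""
    stacks: dict[str, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(db, 1):
        if ch in _UNPAIRED:
            continue
        if ch in _CLOSE_OF:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _OPEN_OF:
            opener = _OPEN_OF[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise FormatError(f"unbalanced bracket {ch!r} at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise FormatError(f"unknown structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(
                f"unbalanced bracket {opener!r} opened at position {stack[-1]}"
            )
    return frozenset(pairs)


def _read_dotbracket(text: str) -> Structure:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    sid = "structure"
    if lines and lines[0].startswith(">"):
        sid = lines[0][1:].strip() or sid
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError("dot-bracket input needs a sequence and a structure line")
    seq, db = lines[0], lines[1]
    if len(seq) != len(db):
        raise FormatError(
            f"sequence length {len(seq)} != structure length {len(db)}"
        )
    return Structure(sid, seq, parse_dotbracket_pairs(db))


def layered_dotbracket(s: Structure) -> str:
    """Dot-bracket string with greedy first-fit layering of stems.

    Stems are assigned to the first bracket layer holding no stem they
    cross; deterministic and minimal in the common cases.
    """
    stems = find_stems(s)
    stems.sort(key=lambda st: st.span)
    layers: list[list] = []
    assignment = {}
    for st in stems:
        placed = False
        for li, members in enumerate(layers):
            if not any(_stems_cross(st, other) for other in members):
                members.append(st)
                assignment[st] = li
                placed = True
                break
        if not placed:
            layers.append([st])
            assignment[st] = len(layers) - 1
    if len(layers) > len(_OPENERS[:4]) + 26:
        raise FormatError("structure needs more bracket layers than available")
    out = ["."] * len(s)
    for st, li in assignment.items():
        for i, j in st.pairs:
            out[i - 1] = _OPENERS[li]
            out[j - 1] = _CLOSERS[li]
    return "".join(out)


def _stems_cross(a, b) -> bool:
    (i, j), (u, v) = a.span, b.span
    return (i < u < j < v) or (u < i < v < j)


def _write_dotbracket(s: Structure) -> str:
    return f">{s.id}\n{s.sequence}\n{layered_dotbracket(s)}\n"


# --------------------------------------------------------------------- BPSEQ

def _read_bpseq(text: str) -> Structure:
    sid = "structure"
    chars: dict[int, str] = {}
    partner: dict[int, int] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            if ln.startswith("#") and len(ln) > 1:
                sid = ln[1:].strip() or sid
            continue
        toks = ln.split()
        if len(toks) != 3:
            raise FormatError(f"line {lineno}: expected 'i base j', got {ln!r}")
        i, base, j = int(toks[0]), toks[1], int(toks[2])
        chars[i] = base
        partner[i] = j
    m = max(chars) if chars else 0
    if sorted(chars) != list(range(1, m + 1)):
        raise FormatError("BPSEQ positions must cover 1..N without holes")
    pairs = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise FormatError(f"position {i} pairs {j} but {j} does not pair {i}")
        if i < j:
            pairs.add((i, j))
    return Structure(sid, "".join(chars[i] for i in range(1, m + 1)), pairs)


def _write_bpseq(s: Structure) -> str:
    partner = s.partner
    lines = [f"# {s.id}"]
    for i in range(1, len(s) + 1):
        lines.append(f"{i} {s.nt(i)} {partner.get(i, 0)}")
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------------ CT

def _read_ct(text: str) -> Structure:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT input")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as e:
        raise FormatError("CT header must start with the sequence length") from e
    sid = " ".join(header[1:]) or "structure"
    chars = []
    partner = {}
    for lineno, ln in enumerate(lines[1 : 1 + n], 2):
        toks = ln.split()
        if len(toks) < 6:
            raise FormatError(f"line {lineno}: expected 6 CT columns")
        i, base, j = int(toks[0]), toks[1], int(toks[4])
        chars.append(base)
        partner[i] = j
    if len(chars) != n:
        raise FormatError(f"CT declares {n} rows but {len(chars)} present")
    pairs = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise FormatError(f"position {i} pairs {j} but {j} does not pair {i}")
        if i < j:
            pairs.add((i, j))
    return Structure(sid, "".join(chars), pairs)


def _write_ct(s: Structure) -> str:
    partner = s.partner
    lines = [f"{len(s)}  {s.id}"]
    for i in range(1, len(s) + 1):
        nxt = i + 1 if i < len(s) else 0
        lines.append(f"{i} {s.nt(i)} {i - 1} {nxt} {partner.get(i, 0)} {i}")
    return "\n".join(lines) + "\n"


_READERS = {"dotbracket": _read_dotbracket, "bpseq": _read_bpseq, "ct": _read_ct}
_WRITERS = {"dotbracket": _write_dotbracket, "bpseq": _write_bpseq, "ct": _write_ct}

FORMAT_BY_SUFFIX = {
    ".dbn": "dotbracket",
    ".db": "dotbracket",
    ".dot": "dotbracket",
    ".bpseq": "bpseq",
    ".ct": "ct",
}


def read_structure(path_or_text: str | Path, format: str = "dotbracket") -> Structure:
    """Parse a structure from a file path or raw text in the named dialect."""
    if format not in _READERS:
        raise FormatError(f"unknown structure format {format!r}")
    return _READERS[format](_get_text(path_or_text))


def write_structure(s: Structure, format: str = "dotbracket") -> str:
    if format not in _WRITERS:
        raise FormatError(f"unknown structure format {format!r}")
    return _WRITERS[format](s)


# ------------------------------------------------------------------ alignment

class AlignmentDocument:
    """Records of (id, gapped sequence, gapped dot-bracket structure)."""

    def __init__(self, records: list[tuple[str, str, str]], metadata: str = ""):
        widths = {len(seq) for _, seq, _ in records} | {
            len(db) for _, _, db in records
        }
        if len(widths) > 1:
            raise FormatError("all gapped strings must share one length")
        self.records = records
        self.metadata = metadata

    def __eq__(self, other):
        return isinstance(other, AlignmentDocument) and self.records == other.records

    def structures(self) -> list[Structure]:
        """Member structures recovered by stripping gaps."""
        out = []
        for sid, seq, db in self.records:
            ungapped_seq = "".join(c for c in seq if c != GAP)
            ungapped_db = "".join(d for c, d in zip(seq, db) if c != GAP)
            out.append(Structure(sid, ungapped_seq, parse_dotbracket_pairs(ungapped_db)))
        return out

    def to_columns(self) -> AlignmentColumns:
        from .pairwise import position_tag

        structs = self.structures()
        cells = []
        counters = [0] * len(structs)
        width = len(self.records[0][1]) if self.records else 0
        for col in range(width):
            row = []
            for r, (sid, seq, db) in enumerate(self.records):
                if seq[col] == GAP:
                    row.append(None)
                else:
                    counters[r] += 1
                    pos = counters[r]
                    row.append((structs[r].nt(pos), position_tag(structs[r], pos)))
            cells.append(row)
        return AlignmentColumns([r[0] for r in self.records], cells)


def columns_to_document(
    cols: AlignmentColumns, structures: list[Structure]
) -> AlignmentDocument:
    """Gap the per-structure dot-bracket annotation along the columns."""
    dbs = [layered_dotbracket(s) for s in structures]
    counters = [0] * len(structures)
    seqs = [[] for _ in structures]
    anns = [[] for _ in structures]
    for col in cols.cells:
        for r, cell in enumerate(col):
            if cell is None:
                seqs[r].append(GAP)
                anns[r].append(GAP)
            else:
                seqs[r].append(cell[0])
                anns[r].append(dbs[r][counters[r]])
                counters[r] += 1
    records = [
        (s.id, "".join(seqs[r]), "".join(anns[r])) for r, s in enumerate(structures)
    ]
    return AlignmentDocument(records)


def write_alignment(doc: AlignmentDocument, format: str = "stockholm") -> str:
    if format == "stockholm":
        return _write_stockholm(doc)
    if format == "clustal":
        return _write_clustal(doc)
    if format == "fasta":
        return _write_fasta(doc)
    raise FormatError(f"unknown alignment format {format!r}")


def read_alignment(path_or_text: str | Path, format: str = "stockholm") -> AlignmentDocument:
    text = _get_text(path_or_text)
    if format == "stockholm":
        return _read_stockholm(text)
    if format == "fasta":
        return _read_fasta(text)
    raise FormatError(f"unknown alignment format {format!r}")


def _write_stockholm(doc: AlignmentDocument) -> str:
    width = max(len(sid) for sid, _, _ in doc.records) if doc.records else 0
    gr_width = max(width + 8, 12)
    lines = ["# STOCKHOLM 1.0"]
    if doc.metadata:
        lines += [f"#=GF CC {ln}" for ln in doc.metadata.splitlines()]
    for sid, seq, db in doc.records:
        lines.append(f"{sid:<{gr_width}} {seq}")
        lines.append(f"{'#=GR ' + sid + ' SS':<{gr_width}} {db}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def _read_stockholm(text: str) -> AlignmentDocument:
    seqs: dict[str, str] = {}
    sss: dict[str, str] = {}
    order: list[str] = []
    for raw in text.splitlines():
        ln = raw.rstrip()
        if not ln or ln == "//" or ln.startswith("# STOCKHOLM"):
            continue
        if ln.startswith("#=GR"):
            toks = ln.split()
            if len(toks) >= 4 and toks[2] == "SS":
                sss[toks[1]] = sss.get(toks[1], "") + toks[3]
        elif ln.startswith("#"):
            continue
        else:
            toks = ln.split()
            if len(toks) != 2:
                raise FormatError(f"bad Stockholm sequence line: {ln!r}")
            if toks[0] not in seqs:
                order.append(toks[0])
            seqs[toks[0]] = seqs.get(toks[0], "") + toks[1]
    records = []
    for sid in order:
        if sid not in sss:
            raise FormatError(f"missing #=GR {sid} SS annotation")
        records.append((sid, seqs[sid], sss[sid]))
    return AlignmentDocument(records)


def _write_clustal(doc: AlignmentDocument) -> str:
    lines = ["RKALIGN structural alignment", ""]
    width = max(len(sid) for sid, _, _ in doc.records) + 10
    for sid, seq, db in doc.records:
        lines.append(f"{sid:<{width}}{seq}")
        lines.append(f"{sid + '/SS':<{width}}{db}")
    return "\n".join(lines) + "\n"


def _write_fasta(doc: AlignmentDocument) -> str:
    lines = []
    for sid, seq, db in doc.records:
        lines += [f">{sid}", seq, db]
    return "\n".join(lines) + "\n"


def _read_fasta(text: str) -> AlignmentDocument:
    records = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError("expected FASTA header line")
        try:
            records.append((lines[i][1:].strip(), lines[i + 1], lines[i + 2]))
        except IndexError as e:
            raise FormatError("FASTA+structure record truncated") from e
        i += 3
    return AlignmentDocument(records)
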