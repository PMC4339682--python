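"""Substitution and gap scoring.

Element matches are scored with the RIBOSUM85-60 log-odds matrices: the 4x4
base matrix for single/single alignments and the 16x16 dinucleotide matrix
for pair/pair alignments.  Mixed single/pair alignment is prohibited and is
a programming error here, not a score.  Boltzmann weights used by the
partition functions are ``exp(score / T)`` with a configurable temperature
constant ``T``; scaling all scores and ``T`` by the same factor therefore
leaves every posterior unchanged.

The ambiguity code N is scored as the mean of the four concrete nucleotides
in the relevant matrix row/column (expectation under uniform uncertainty),
which keeps the extended matrices symmetric.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .structures import Element, PAIR, SINGLE, Structure

_NTS = "ACGU"

DEFAULT_TEMPERATURE = 1.0
DEFAULT_GAP_BASE = -2.0
DEFAULT_GAP_PAIR = -4.0


class ScoringError(ValueError):
    pass


def _parse_matrix(lines: list[str], labels: list[str]) -> dict:
    header = lines[0].split()
    if header != labels:
        raise ScoringError(f"bad matrix header: {header}")
    mat = {}
    for row in lines[1 : 1 + len(labels)]:
        toks = row.split()
        rl = toks[0]
        for cl, v in zip(labels, toks[1:]):
            mat[(rl, cl)] = float(v)
    for a, b in itertools.product(labels, repeat=2):
        if abs(mat[(a, b)] - mat[(b, a)]) > 1e-12:
            raise ScoringError(f"matrix not symmetric at ({a},{b})")
    return mat


def _extend_with_n(mat: dict, labels: list[str]) -> dict:
    """Add N-containing keys scored as uniform means over concrete bases."""

    def expand(lbl: str) -> list[str]:
        outs = [""]
        for ch in lbl:
            opts = _NTS if ch == "N" else ch
            outs = [o + c for o in outs for c in opts]
        return outs

    full = dict(mat)
    width = len(labels[0])
    all_lbls = ["".join(t) for t in itertools.product("ACGUN", repeat=width)]
    for a, b in itertools.product(all_lbls, repeat=2):
        if (a, b) in full:
            continue
        vals = [mat[(x, y)] for x in expand(a) for y in expand(b)]
        full[(a, b)] = sum(vals) / len(vals)
    return full


def load_matrices(path: str | Path | None = None) -> tuple[dict, dict]:
    """Load (base_matrix, pair_matrix) from a plain-text matrix file.

    With ``path=None`` the packaged RIBOSUM85-60 transcription is used.
    """
    if path is None:
        text = (
            resources.files("rkalign").joinpath("data/ribosum85_60.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    try:
        bi = lines.index("bases")
        pi = lines.index("pairs")
    except ValueError as e:
        raise ScoringError("matrix file needs 'bases' and 'pairs' sections") from e
    base_labels = list(_NTS)
    pair_labels = ["".join(t) for t in itertools.product(_NTS, repeat=2)]
    base = _parse_matrix(lines[bi + 1 : pi], base_labels)
    pairm = _parse_matrix(lines[pi + 1 :], pair_labels)
    return base, pairm


def packaged_matrix_sha256() -> str:
    """Checksum of the shipped matrix file, pinning the transcription."""
    data = resources.files("rkalign").joinpath("data/ribosum85_60.txt").read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass(frozen=True)
class ScoringParams:
    """Scoring model: RIBOSUM matrices, gap penalties, temperature."""

    base_matrix: dict = field(repr=False, default=None)
    pair_matrix: dict = field(repr=False, default=None)
    gap_base: float = DEFAULT_GAP_BASE
    gap_pair: float = DEFAULT_GAP_PAIR
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.T <= 0:
            raise ScoringError("temperature T must be positive")
        if self.base_matrix is None or self.pair_matrix is None:
            base, pairm = load_matrices()
            if self.base_matrix is None:
                object.__setattr__(self, "base_matrix", _extend_with_n(base, list(_NTS)))
            if self.pair_matrix is None:
                labels = ["".join(t) for t in itertools.product(_NTS, repeat=2)]
                object.__setattr__(self, "pair_matrix", _extend_with_n(pairm, labels))
        else:
            object.__setattr__(
                self, "base_matrix", _extend_with_n(self.base_matrix, list(_NTS))
            )
            labels = ["".join(t) for t in itertools.product(_NTS, repeat=2)]
            object.__setattr__(
                self, "pair_matrix", _extend_with_n(self.pair_matrix, labels)
            )

    def scaled(self, factor: float) -> "ScoringParams":
        """All scores and T multiplied by ``factor`` (posteriors invariant)."""
        return ScoringParams(
            base_matrix={k: v * factor for k, v in self.base_matrix.items()},
            pair_matrix={k: v * factor for k, v in self.pair_matrix.items()},
            gap_base=self.gap_base * factor,
            gap_pair=self.gap_pair * factor,
            T=self.T * factor,
        )


def default_params(**overrides) -> ScoringParams:
    return ScoringParams(**overrides)


def element_score(
    a: Element, sa: Structure, b: Element, sb: Structure, params: ScoringParams
) -> float:
    """RIBOSUM score of aligning element ``a`` of ``sa`` with ``b`` of ``sb``.

    Raises if the elements differ in kind: a single base is never aligned
    with a base pair.
    """
    if a.kind != b.kind:
        raise ScoringError("aligning a single base with a base pair is prohibited")
    if a.kind == SINGLE:
        return params.base_matrix[(a.nts(sa), b.nts(sb))]
    return params.pair_matrix[(a.nts(sa), b.nts(sb))]


def gap_score(e: Element, params: ScoringParams) -> float:
    """Penalty for aligning element ``e`` to gaps."""
    return params.gap_pair if e.kind == PAIR else params.gap_base
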