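"""Random pseudoknotted structures and homologous variants for testing.

The generator emulates the composition of curated pseudoknot collections:
H-type pseudoknots (two crossing stems in ABAB interleaving) and recursive
pseudoknots (an H-type scaffold with additional nested structure inside the
spanned region), plus pseudoknot-free controls.  Homologs are produced by
mutating sequences at a configurable rate, with a configurable fraction of
pair mutations applied compensatorily (both partners replaced by another
pairing-compatible dinucleotide) so that RIBOSUM pair scoring has real
covariation to reward.

All randomness flows through an explicitly seeded ``numpy`` generator; the
same seed reproduces the same structures on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structures import (
    PK_H_TYPE,
    PK_NONE,
    PK_RECURSIVE,
    Structure,
    classify_pseudoknot_type,
)

_CANONICAL = ["AU", "UA", "GC", "CG", "GU", "UG"]
_NTS = "ACGU"
MIN_LOOP = 3  # minimum unpaired run between stem halves


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-structure generator.

    Defaults draw H-type pseudoknots of 30-70 nt with stems of 3-6 pairs,
    mutate homologs at 10% per element and apply 70% of pair mutations
    compensatorily — magnitudes typical of small curated pseudoknots and of
    homologous families with covarying stems.
    """

    seed: int = 0
    length: tuple[int, int] = (30, 70)
    n_stems: int = 2
    stem_len: tuple[int, int] = (3, 6)
    topology: str = PK_H_TYPE
    mutation_rate: float = 0.1
    compensatory_fraction: float = 0.7

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_sequence(m: int, pairs: set, rng: np.random.Generator) -> str:
    seq = [None] * m
    for i, j in pairs:
        pr = _CANONICAL[rng.integers(len(_CANONICAL))]
        seq[i - 1], seq[j - 1] = pr[0], pr[1]
    for t in range(m):
        if seq[t] is None:
            seq[t] = _NTS[rng.integers(4)]
    return "".join(seq)


def _stem_pairs(left_start: int, right_end: int, size: int) -> set:
    """Stacked pairs (left_start+t, right_end-t) for t in 0..size-1."""
    return {(left_start + t, right_end - t) for t in range(size)}


def generate_structure(cfg: GeneratorConfig, sid: str = "synthetic") -> Structure:
    """Draw a random structure of the requested pseudoknot topology."""
    rng = cfg.rng()
    lo, hi = cfg.stem_len
    if cfg.topology == PK_NONE:
        return _generate_nested(cfg, rng, sid)
    a = int(rng.integers(lo, hi + 1))
    b = int(rng.integers(lo, hi + 1))
    c = int(rng.integers(lo, hi + 1)) if cfg.topology == PK_RECURSIVE else 0
    # layout: [S1L][loop1][S2L][loop2(+hairpin)][S1R][loop3][S2R][tail]
    loop2_extra = (2 * c + MIN_LOOP + 2) if c else 0
    minimum = a + b + a + b + 3 * MIN_LOOP + loop2_extra + 2
    if minimum > cfg.length[1]:
        raise GenerationError(
            f"stems of {a}+{b} pairs do not fit in length <= {cfg.length[1]}"
        )
    m = int(rng.integers(max(cfg.length[0], minimum), cfg.length[1] + 1))
    slack = m - minimum
    extra = rng.multinomial(slack, [0.25, 0.25, 0.25, 0.25])
    l1 = MIN_LOOP + int(extra[0])
    l2 = MIN_LOOP + loop2_extra + int(extra[1])
    l3 = MIN_LOOP + int(extra[2])

    s1l = 1
    s2l = s1l + a + l1
    s1r_start = s2l + b + l2
    s1r_end = s1r_start + a - 1
    s2r_start = s1r_end + 1 + l3
    s2r_end = s2r_start + b - 1
    pairs = _stem_pairs(s1l, s1r_end, a) | _stem_pairs(s2l, s2r_end, b)
    if c:
        # nested hairpin inside loop2, between the crossing stems
        h_start = s2l + b + 1
        h_end = h_start + 2 * c + MIN_LOOP - 1
        pairs |= _stem_pairs(h_start, h_end, c)
    s = Structure(sid, _random_sequence(m, pairs, rng), pairs)
    got = classify_pseudoknot_type(s)
    if got != cfg.topology:
        raise GenerationError(f"generated {got} structure, wanted {cfg.topology}")
    return s


def _generate_nested(
    cfg: GeneratorConfig, rng: np.random.Generator, sid: str
) -> Structure:
    lo, hi = cfg.stem_len
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_stems)]
    minimum = sum(2 * s + MIN_LOOP for s in sizes) + 2
    if minimum > cfg.length[1]:
        raise GenerationError("stems do not fit in the length budget")
    m = int(rng.integers(max(cfg.length[0], minimum), cfg.length[1] + 1))
    pairs: set = set()
    cursor = 1
    for s in sizes:  # side-by-side hairpins: nested, never crossing
        start = cursor
        end = start + 2 * s + MIN_LOOP - 1
        pairs |= _stem_pairs(start, end, s)
        cursor = end + 2
    return Structure(sid, _random_sequence(m, pairs, rng), pairs)


def mutate_homolog(
    s: Structure, cfg: GeneratorConfig, sid: str | None = None
) -> Structure:
    """Mutate a structure's sequence, preserving its pair topology.

    Each element (single base or base pair) mutates with probability
    ``mutation_rate``.  A mutated pair is replaced compensatorily (another
    canonical/wobble dinucleotide) with probability
    ``compensatory_fraction``; otherwise one of its bases changes freely.
    """
    rng = cfg.rng()
    seq = list(s.sequence)
    partner = s.partner
    for i, j in sorted(s.pairs):
        if rng.random() >= cfg.mutation_rate:
            continue
        if rng.random() < cfg.compensatory_fraction:
            current = seq[i - 1] + seq[j - 1]
            options = [p for p in _CANONICAL if p != current]
            pr = options[rng.integers(len(options))]
            seq[i - 1], seq[j - 1] = pr[0], pr[1]
        else:
            side = i if rng.random() < 0.5 else j
            options = [n for n in _NTS if n != seq[side - 1]]
            seq[side - 1] = options[rng.integers(3)]
    for p in range(1, len(s) + 1):
        if p in partner:
            continue
        if rng.random() < cfg.mutation_rate:
            options = [n for n in _NTS if n != seq[p - 1]]
            seq[p - 1] = options[rng.integers(3)]
    return Structure(sid or f"{s.id}_homolog", "".join(seq), s.pairs)


def generate_family(
    cfg: GeneratorConfig, k: int, sid_prefix: str = "syn"
) -> list[Structure]:
    """A reference structure plus ``k - 1`` homologs drawn from it."""
    ref = generate_structure(cfg, sid=f"{sid_prefix}0")
    out = [ref]
    for t in range(1, k):
        sub = replace(cfg, seed=cfg.seed + 1000 + t)
        out.append(mutate_homolog(ref, sub, sid=f"{sid_prefix}{t}"))
    return out
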