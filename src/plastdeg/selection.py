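"""Pairwise dN/dS screen by the Nei-Gojobori (1986) counting method.

A lightweight per-gene screen for elevated or depressed nonsynonymous
divergence between aligned coding sequences: synonymous/nonsynonymous site
counting per codon, pathway-averaged difference counting for codons
differing at 2-3 positions, and Jukes-Cantor correction of the proportions.
It deliberately fits no codon model and tests no hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log

from Bio.Data import CodonTable

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)
_AA = dict(_TABLE11.forward_table)
_BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when a difference proportion reaches the Jukes-Cantor pole (3/4)."""


@dataclass(frozen=True)
class NGResult:
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float | None  # None when dS = 0


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(S, N) for one codon: each position contributes the synonymous
    fraction of its 3 possible point changes; changes to stops count as
    nonsynonymous."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _AA[alt] == aa:
                s += 1 / 3
    return s, 3.0 - s


def _check_codon_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"{name}: length {len(seq)} not a multiple of 3")
    if set(seq) - set(_BASES):
        raise ValueError(f"{name}: sequence must be gap-free A/C/G/T")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        raise ValueError(f"{name}: trailing stop codon; strip terminators first")
    return seq


def ng86_site_counts(codon_sequence: str) -> tuple[float, float]:
    """Total synonymous and nonsynonymous site counts (S + N = 3 x codons)."""
    seq = _check_codon_seq(codon_sequence, "sequence")
    s = n = 0.0
    for i in range(0, len(seq), 3):
        cs, cn = _codon_site_counts(seq[i : i + 3])
        s += cs
        n += cn
    return s, n


@lru_cache(maxsize=None)
def _codon_pair_diffs(a: str, b: str, include_stop_paths: bool = False) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over mutational pathways.

    Pathways passing through stop codons are excluded (with a fallback to
    all pathways if every one hits a stop, which cannot occur for sense
    codons differing at <= 3 positions under table 11 in practice).
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not include_stop_paths:
                ok = False
                break
            syn = nxt not in STOP_CODONS and cur not in STOP_CODONS and _AA[nxt] == _AA[cur]
            steps.append(1.0 if syn else 0.0)
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return _codon_pair_diffs(a, b, include_stop_paths=True)
    sd = sum(sum(p) for p in paths) / len(paths)
    return sd, len(diff_pos) - sd


def _jc_correct(p: float, what: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{what} proportion {p:.3f} >= 3/4: Jukes-Cantor undefined")
    return -0.75 * log(1 - 4 * p / 3)


def ng86_diff_counts(
    seq_a: str, seq_b: str, include_stop_paths: bool = False
) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) difference counts between two aligned CDS."""
    a = _check_codon_seq(seq_a, "seq_a")
    b = _check_codon_seq(seq_b, "seq_b")
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    sd = nd = 0.0
    for i in range(0, len(a), 3):
        # average over both substitution directions so that excluded stop
        # pathways cannot break symmetry
        d_ab = _codon_pair_diffs(a[i : i + 3], b[i : i + 3], include_stop_paths)
        d_ba = _codon_pair_diffs(b[i : i + 3], a[i : i + 3], include_stop_paths)
        sd += (d_ab[0] + d_ba[0]) / 2
        nd += (d_ab[1] + d_ba[1]) / 2
    return sd, nd


def ng86_pairwise(seq_a: str, seq_b: str, include_stop_paths: bool = False) -> NGResult:
    """Nei-Gojobori pairwise dN/dS for two codon-aligned, gap-free CDS.

    Site counts are averaged between the two sequences; omega is None when
    dS = 0. Symmetric in its arguments. A difference proportion at or
    beyond the Jukes-Cantor pole (3/4) raises SaturationError; the raw
    counts are available through :func:`ng86_diff_counts`.
    """
    a = _check_codon_seq(seq_a, "seq_a")
    b = _check_codon_seq(seq_b, "seq_b")
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    sa, na = ng86_site_counts(a)
    sb, nb = ng86_site_counts(b)
    s_sites, n_sites = (sa + sb) / 2, (na + nb) / 2
    sd, nd = ng86_diff_counts(a, b, include_stop_paths)
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ds = _jc_correct(ps, "synonymous")
    dn = _jc_correct(pn, "nonsynonymous")
    omega = dn / ds if ds > 0 else None
    return NGResult(
        s_sites=s_sites, n_sites=n_sites, s_diffs=sd, n_diffs=nd,
        ps=ps, pn=pn, ds=ds, dn=dn, omega=omega,
    )
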