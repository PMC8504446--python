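"""Call per-gene degradation states and build the taxa x gene matrix.

Each target gene is scored against an intact reference CDS on a four-state
code: 0 functional, 1 full-length but carrying a premature stop codon,
2 truncated, 3 completely lost. Location uses exact k-mer seeding with
diagonal chaining (circular genomes handled by doubling the search text,
never the data model), followed by a gapped alignment of the chained span
with edlib to count mismatches, frameshift indels and in-frame stops.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import edlib
from Bio.Data import CodonTable

from ._model import CharacterMatrix, PlastomeRecord, revcomp

log = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA TAG TGA
START_CODONS = ("ATG", "GTG", "TTG")  # plastid/bacterial convention


class TranslationResult(NamedTuple):
    protein: str
    internal_stops: tuple[int, ...]  # codon indices, strictly before the last codon
    incomplete_tail: bool


def conceptual_translate(cds_sequence: str, table: int = 11) -> TranslationResult:
    """Codon-by-codon translation reporting internal stop positions.

    Internal stops are stop codons strictly before the final (complete)
    codon; a trailing incomplete codon is flagged, not translated.
    """
    seq = cds_sequence.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    code = CodonTable.unambiguous_dna_by_id[table]
    n_codons = len(seq) // 3
    incomplete = len(seq) % 3 != 0
    protein = []
    stops = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in code.stop_codons:
            protein.append("*")
            if i < n_codons - 1:
                stops.append(i)
        else:
            protein.append(code.forward_table.get(codon, "X"))
    return TranslationResult("".join(protein), tuple(stops), incomplete)


# -- locating gene remnants --------------------------------------------------


@dataclass
class GeneHit:
    """A located (possibly degraded) copy of a reference CDS."""

    interval: tuple[int, int]  # on the doubled-genome axis, start < end
    strand: str
    coverage: float  # fraction of the reference CDS spanned
    identity: float  # matches / alignment columns over the spanned region
    internal_stops: int
    frameshifts: int  # indel runs with length not divisible by 3
    ref_span: tuple[int, int]
    has_start: bool = False
    has_stop: bool = False

    @property
    def defective(self) -> bool:
        return self.internal_stops > 0 or self.frameshifts > 0


_SEED_K = 15
_SEED_STEP = 6
_DIAG_BAND = 60
_MIN_HIT_BP = 50
_MIN_IDENTITY = 0.60


def _kmer_index(text: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for j in range(len(text) - k + 1):
        idx.setdefault(text[j : j + k], []).append(j)
    return idx


def locate_gene_all(
    record: PlastomeRecord,
    reference_cds: str,
    _index: dict[str, list[int]] | None = None,
) -> list[GeneHit]:
    """All qualifying matches of the reference CDS in the genome, best first.

    IR-duplicated genes yield one hit per copy. A hit qualifies when its
    aligned span is >= 50 bp at >= 60% identity.
    """
    ref_fwd = reference_cds.upper()
    if not ref_fwd:
        raise ValueError("empty reference CDS")
    genome = record.sequence
    text = genome + genome if record.circular else genome
    L = len(genome)
    idx = _index if _index is not None else _kmer_index(text, _SEED_K)

    hits: list[GeneHit] = []
    for strand, ref in (("+", ref_fwd), ("-", revcomp(ref_fwd))):
        for cluster in _seed_clusters(ref, idx):
            hit = _align_cluster(ref, text, L, cluster, strand)
            if hit is None:
                continue
            span = hit.coverage * len(ref)
            if span >= _MIN_HIT_BP and hit.identity >= _MIN_IDENTITY:
                hits.append(hit)
    hits = _dedupe_hits(hits, L)
    hits.sort(key=lambda h: (h.coverage, h.identity), reverse=True)
    return hits


def locate_gene(record, reference_cds, _index=None) -> GeneHit | None:
    """Best match of the reference CDS in the genome, or None."""
    hits = locate_gene_all(record, reference_cds, _index)
    return hits[0] if hits else None


def _seed_clusters(ref: str, idx) -> list[tuple[int, int, int, int]]:
    """Chain seed matches into (ref_lo, ref_hi, tgt_lo, tgt_hi) clusters."""
    raw: list[tuple[int, int]] = []  # (diagonal, ref_pos)
    seeds: dict[tuple[int, int], tuple[int, int]] = {}
    positions = list(range(0, max(len(ref) - _SEED_K, 0) + 1, _SEED_STEP))
    if positions and positions[-1] != len(ref) - _SEED_K:
        positions.append(len(ref) - _SEED_K)
    matches = []
    for i in positions:
        for j in idx.get(ref[i : i + _SEED_K], ()):
            matches.append((j - i, i, j))
    if not matches:
        return []
    matches.sort()
    clusters = []
    cur = None
    for d, i, j in matches:
        if cur is not None and d - cur[0] <= _DIAG_BAND:
            cur = (d, min(cur[1], i), max(cur[2], i + _SEED_K), min(cur[3], j), max(cur[4], j + _SEED_K))
        else:
            if cur is not None:
                clusters.append(cur)
            cur = (d, i, i + _SEED_K, j, j + _SEED_K)
    clusters.append(cur)
    return [(c[1], c[2], c[3], c[4]) for c in clusters]


def _align_cluster(ref, text, L, cluster, strand) -> GeneHit | None:
    ref_lo, ref_hi, t_lo, t_hi = cluster
    # mismatch-free exact extension of the chained span
    while ref_lo > 0 and t_lo > 0 and ref[ref_lo - 1] == text[t_lo - 1]:
        ref_lo -= 1
        t_lo -= 1
    while ref_hi < len(ref) and t_hi < len(text) and ref[ref_hi] == text[t_hi]:
        ref_hi += 1
        t_hi += 1
    ref_seg = ref[ref_lo:ref_hi]
    pad = 30
    w_lo, w_hi = max(0, t_lo - pad), min(len(text), t_hi + pad)
    window = text[w_lo:w_hi]
    if not ref_seg or not window:
        return None
    aln = edlib.align(ref_seg, window, mode="HW", task="path")
    if aln["editDistance"] < 0 or not aln["locations"]:
        return None
    loc_start, loc_end = aln["locations"][0]
    cigar = aln["cigar"] or ""
    matches = columns = 0
    frameshifts = 0
    for length, op in _cigar_ops(cigar):
        columns += length
        if op == "=":
            matches += length
        if op in "ID" and length % 3 != 0:
            frameshifts += 1
    identity = matches / columns if columns else 0.0
    target_seg = window[loc_start : loc_end + 1]
    # work on the coding strand in forward-reference coordinates
    if strand == "-":
        coding_seg = revcomp(target_seg)
        a, b = len(ref) - ref_hi, len(ref) - ref_lo
    else:
        coding_seg = target_seg
        a, b = ref_lo, ref_hi
    stops = _count_internal_stops(coding_seg, a, b, len(ref))
    has_start = a == 0 and coding_seg[:3] in START_CODONS
    has_stop = b == len(ref) and coding_seg[-3:] in STOP_CODONS
    return GeneHit(
        interval=(w_lo + loc_start, w_lo + loc_end + 1),
        strand=strand,
        coverage=(ref_hi - ref_lo) / len(ref),
        identity=identity,
        internal_stops=stops,
        frameshifts=frameshifts,
        ref_span=(a, b),
        has_start=has_start,
        has_stop=has_stop,
    )


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _count_internal_stops(target_seg: str, ref_lo: int, ref_hi: int, ref_len: int) -> int:
    phase = (-ref_lo) % 3  # bases until the next reference codon boundary
    framed = target_seg[phase:]
    n_codons = len(framed) // 3
    # when the hit reaches the reference 3' end its final codon is the
    # gene's own terminator, which is not "internal"
    last = n_codons - 1 if ref_hi >= ref_len - 2 else n_codons
    count = 0
    for i in range(max(last, 0)):
        if framed[3 * i : 3 * i + 3] in STOP_CODONS:
            count += 1
    return count


def _dedupe_hits(hits: list[GeneHit], L: int) -> list[GeneHit]:
    """Collapse hits that cover the same circular locus (doubled-text aliases)."""
    out: list[GeneHit] = []
    for h in sorted(hits, key=lambda h: (h.coverage, h.identity), reverse=True):
        a, b = h.interval
        dup = False
        for o in out:
            oa, ob = o.interval
            for shift in (-L, 0, L):
                lo = max(a + shift, oa)
                hi = min(b + shift, ob)
                if hi - lo > 0.5 * min(b - a, ob - oa):
                    dup = True
            if dup:
                break
        if not dup:
            out.append(h)
    return out


# -- state classification ----------------------------------------------------


class BorderlineCoverageWarning(UserWarning):
    pass


def classify_gene_state(
    hit: GeneHit | None,
    reference_cds: str,
    t_trunc: float = 0.90,
    t_full: float = 0.95,
) -> int:
    """Map a located hit to the four-state degradation code.

    3 = no remnant found; 2 = truncated (coverage below ``t_trunc``, or
    full-length with eroded start/stop codons); 1 = essentially full-length
    with internal stops or frameshifts; 0 = intact. Coverage in
    [t_trunc, t_full) without defects is called 0 with a warning.
    """
    for t in (t_trunc, t_full):
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    if hit is None:
        return 3
    if hit.coverage < t_trunc:
        return 2
    if hit.defective:
        return 1
    if not (hit.has_start and hit.has_stop):
        return 2
    if hit.coverage < t_full:
        warnings.warn(
            f"coverage {hit.coverage:.3f} in [{t_trunc}, {t_full}): "
            "borderline full-length call",
            BorderlineCoverageWarning,
            stacklevel=2,
        )
    return 0


DEFAULT_GENE_LIST = (
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF",
    "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK", "accD", "ccsA",
)


def reference_cds_set(reference: PlastomeRecord, gene_list: Sequence[str]) -> dict[str, str]:
    """Extract intact reference CDS sequences from a functional reference taxon."""
    refs = {}
    for gene in gene_list:
        copies = [f for f in reference.genes(gene) if f.kind == "CDS" and not f.pseudo]
        if not copies:
            raise ValueError(f"reference taxon lacks a functional {gene}")
        refs[gene] = copies[0].extract(reference.sequence)
    return refs


def build_state_matrix(
    records: Sequence[PlastomeRecord],
    reference: PlastomeRecord | dict[str, str],
    gene_list: Sequence[str] = DEFAULT_GENE_LIST,
    t_trunc: float = 0.90,
    t_full: float = 0.95,
) -> tuple[CharacterMatrix, dict]:
    """Call every (taxon, gene) state; returns the matrix and an evidence log.

    IR-duplicated genes are called per copy and the per-taxon state is the
    least degraded copy (a functional copy anywhere implies function).
    """
    refs = (
        reference
        if isinstance(reference, dict)
        else reference_cds_set(reference, gene_list)
    )
    taxa = [r.taxon for r in records]
    if len(taxa) != len(set(taxa)):
        raise ValueError("duplicate taxon ids")
    states: dict[str, dict[str, int]] = {}
    evidence: dict[tuple[str, str], dict] = {}
    for rec in records:
        text = rec.sequence + rec.sequence if rec.circular else rec.sequence
        idx = _kmer_index(text, _SEED_K)
        row = {}
        for gene in gene_list:
            hits = locate_gene_all(rec, refs[gene], _index=idx)
            if hits:
                calls = [
                    classify_gene_state(h, refs[gene], t_trunc, t_full) for h in hits
                ]
                state = min(calls)
                best = hits[calls.index(state)]
                evidence[(rec.taxon, gene)] = {
                    "state": state,
                    "n_copies": len(hits),
                    "coverage": round(best.coverage, 4),
                    "identity": round(best.identity, 4),
                    "internal_stops": best.internal_stops,
                    "frameshifts": best.frameshifts,
                }
            else:
                state = 3
                evidence[(rec.taxon, gene)] = {"state": 3, "n_copies": 0}
            row[gene] = state
        states[rec.taxon] = row
        log.debug("called %s: %s", rec.taxon, row)
    matrix = CharacterMatrix.from_dict(states, taxa=taxa, genes=gene_list)
    return matrix, evidence
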