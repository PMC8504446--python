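"""Quadripartite structure: IR detection, region statistics, junction typing.

A plastome is modeled as a circle carrying two exactly reverse-complementary
inverted-repeat copies (IRa/IRb) separated by a large and a small
single-copy region (LSC/SSC). Detection finds the maximal pair of disjoint
reverse-complementary arcs; the junction architecture is then typed I-IV
from the placement of the landmark genes ycf1, ndhF, ndhH and ndhA relative
to the IR/SSC boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._model import PlastomeRecord, revcomp

LANDMARKS = ("ycf1", "ndhF", "ndhH", "ndhA")

# a gene counts as inside a region when >= IN_FRACTION of its span lies
# there; it spans a junction when both sides hold >= 1 - IN_FRACTION
IN_FRACTION = 0.95


class NoInvertedRepeatError(ValueError):
    """Raised when no inverted repeat of the requested length exists."""


@dataclass(frozen=True)
class Arc:
    """A (possibly origin-wrapping) arc on a circle: start + length."""

    start: int
    length: int

    def intervals(self, genome_len: int) -> list[tuple[int, int]]:
        """Linear half-open intervals covered by the arc."""
        if self.length == 0:
            return []
        end = self.start + self.length
        if end <= genome_len:
            return [(self.start, end)]
        return [(self.start, genome_len), (0, end - genome_len)]

    def extract(self, sequence: str) -> str:
        doubled = sequence + sequence
        return doubled[self.start : self.start + self.length]


@dataclass
class RegionPartition:
    """The four quadripartite intervals on one genome, forward-strand order
    LSC -> IRb -> SSC -> IRa starting at the canonical rotation offset."""

    lsc: Arc
    irb: Arc
    ssc: Arc
    ira: Arc
    genome_len: int

    REGION_ORDER = ("LSC", "IRb", "SSC", "IRa")

    @property
    def offset(self) -> int:
        """Canonical rotation offset (start of the LSC)."""
        return self.lsc.start

    def regions(self) -> dict[str, Arc]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def validate(self, sequence: str) -> None:
        if sum(a.length for a in self.regions().values()) != self.genome_len:
            raise ValueError("regions do not cover the genome")
        if self.lsc.length < self.ssc.length:
            raise ValueError("LSC shorter than SSC")
        if self.ira.extract(sequence) != revcomp(self.irb.extract(sequence)):
            raise ValueError("IRa is not the reverse complement of IRb")

    def junctions(self) -> dict[str, int]:
        """Junction name -> coordinate (start of the downstream region)."""
        return {
            "LSC-IRb": self.irb.start,
            "IRb-SSC": self.ssc.start,
            "SSC-IRa": self.ira.start,
            "IRa-LSC": self.lsc.start,
        }


@dataclass
class RegionStats:
    lengths: dict[str, int]
    gc: dict[str, float]
    genome_length: int
    genome_gc: float


@dataclass
class IRTypeResult:
    type: str  # 'I' | 'II' | 'III' | 'IV' | 'unclassified'
    evidence: list[tuple[str, str, str]] = field(default_factory=list)
    ycf1_overlap_bp: int = 0


# -- detection ---------------------------------------------------------------


def detect_inverted_repeat(sequence: str, min_len: int = 1000) -> RegionPartition:
    """Find the quadripartite partition of a circular sequence.

    Locates the maximal-length pair of disjoint, exactly reverse-complementary
    arcs of length >= ``min_len`` (seeded k-mer match on the doubled sequence,
    maximal mismatch-free extension). Ties break to the smaller canonical
    start. Raises NoInvertedRepeatError when no such pair exists.
    """
    sequence = sequence.upper()
    L = len(sequence)
    if min_len < 1:
        raise ValueError("min_len must be positive")
    if L < 4 * min_len:
        raise ValueError(f"sequence length {L} < 4 x min_len {min_len}")

    k = min(24, min_len)
    s2 = sequence + sequence
    r2 = revcomp(s2)

    kmer_pos: dict[str, list[int]] = {}
    for j in range(len(r2) - k + 1):
        kmer_pos.setdefault(r2[j : j + k], []).append(j)

    # seeds stepped by k: any exact common substring of length >= 2k-1
    # (<< min_len) contains an aligned seed
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    pairs: dict[frozenset, tuple[int, Arc, Arc]] = {}
    for i in range(0, len(s2) - k + 1, k):
        hits = kmer_pos.get(s2[i : i + k])
        if not hits:
            continue
        for j in hits:
            d = i - j
            covered = False
            for a, b in seen_diag.get(d, ()):
                if a <= i and i + k <= b:
                    covered = True
                    break
            if covered:
                continue
            # maximal mismatch-free extension, capped at one genome length
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and s2[lo_i - 1] == r2[lo_j - 1] and i + k - lo_i < L:
                lo_i -= 1
                lo_j -= 1
            hi = i + k
            hj = j + k
            while hi < len(s2) and hj < len(r2) and s2[hi] == r2[hj] and hi - lo_i < L:
                hi += 1
                hj += 1
            m = hi - lo_i
            seen_diag.setdefault(d, []).append((lo_i, hi))
            if m < min_len:
                continue
            arc_a = Arc(lo_i % L, m)
            arc_b = Arc((2 * L - (lo_j + m)) % L, m)
            if _arcs_overlap(arc_a, arc_b, L):
                continue
            key = frozenset({(arc_a.start, m), (arc_b.start, m)})
            pairs.setdefault(key, (m, arc_a, arc_b))

    if not pairs:
        raise NoInvertedRepeatError(f"no inverted repeat of length >= {min_len}")

    best = max(pairs.values(), key=lambda t: (t[0], -min(t[1].start, t[2].start)))
    _, arc_a, arc_b = best
    return _partition_from_ir_pair(arc_a, arc_b, L)


def _arcs_overlap(a: Arc, b: Arc, L: int) -> bool:
    for x1, x2 in a.intervals(L):
        for y1, y2 in b.intervals(L):
            if x1 < y2 and y1 < x2:
                return True
    return False


def _partition_from_ir_pair(arc_a: Arc, arc_b: Arc, L: int) -> RegionPartition:
    # single-copy gaps between the two IR arcs, walking forward
    end_a = (arc_a.start + arc_a.length) % L
    end_b = (arc_b.start + arc_b.length) % L
    gap_ab = Arc(end_a, (arc_b.start - end_a) % L)  # follows arc_a
    gap_ba = Arc(end_b, (arc_a.start - end_b) % L)  # follows arc_b

    if (gap_ab.length, -gap_ab.start) > (gap_ba.length, -gap_ba.start):
        lsc, ssc = gap_ab, gap_ba
        irb, ira = arc_b, arc_a  # SSC follows arc_b => arc_b is IRb
    else:
        lsc, ssc = gap_ba, gap_ab
        irb, ira = arc_a, arc_b
    return RegionPartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_len=L)


# -- statistics --------------------------------------------------------------


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def region_stats(record: PlastomeRecord, partition: RegionPartition) -> RegionStats:
    """Per-region and whole-genome length and GC fraction (N excluded)."""
    if partition.genome_len != len(record):
        raise ValueError("partition does not match record length")
    lengths, gc = {}, {}
    for name, arc in partition.regions().items():
        seq = arc.extract(record.sequence)
        lengths[name] = arc.length
        gc[name] = _gc_fraction(seq) if arc.length else float("nan")
    return RegionStats(
        lengths=lengths,
        gc=gc,
        genome_length=len(record),
        genome_gc=_gc_fraction(record.sequence),
    )


# -- junction typing ---------------------------------------------------------


def _overlap_bp(feature, arc: Arc, L: int) -> int:
    total = 0
    for fa, fb in feature.location:
        for ra, rb in arc.intervals(L):
            total += max(0, min(fb, rb) - max(fa, ra))
    return total


def _placements(record: PlastomeRecord, partition: RegionPartition, symbol: str):
    """Per-copy placement of a gene relative to the IR and SSC."""
    L = partition.genome_len
    out = []
    for f in record.genes(symbol):
        in_ir = _overlap_bp(f, partition.irb, L) + _overlap_bp(f, partition.ira, L)
        in_ssc = _overlap_bp(f, partition.ssc, L)
        fr_ir = in_ir / f.length
        fr_ssc = in_ssc / f.length
        if fr_ir >= 1 - IN_FRACTION and fr_ssc >= 1 - IN_FRACTION:
            place = "spans_junction"
        elif fr_ir >= IN_FRACTION:
            place = "in_IR"
        elif fr_ssc >= IN_FRACTION:
            place = "in_SSC"
        else:
            place = "elsewhere"
        out.append((f, place, fr_ir, fr_ssc))
    return out


def classify_ir_type(record: PlastomeRecord, partition: RegionPartition) -> IRTypeResult:
    """Type the IR/SSC junction architecture (I-IV) from landmark genes.

    Pseudogene remnants count as landmarks as long as they are annotated;
    the evidence list records every copy consulted.
    """
    place: dict[str, str] = {}
    strand: dict[str, str] = {}
    evidence: list[tuple[str, str, str]] = []
    ycf1_overlap = 0
    for sym in LANDMARKS:
        copies = _placements(record, partition, sym)
        if not copies:
            continue
        for f, p, fr_ir, fr_ssc in copies:
            evidence.append((sym, p, f.strand))
        # prefer the copy with the clearest call: spanning > in_IR > in_SSC
        order = {"spans_junction": 0, "in_IR": 1, "in_SSC": 2, "elsewhere": 3}
        f, p, fr_ir, fr_ssc = min(copies, key=lambda c: order[c[1]])
        place[sym] = p
        strand[sym] = f.strand
        if sym == "ycf1":
            ycf1_overlap = max(
                _overlap_bp(f2, partition.irb, partition.genome_len)
                for f2, _, _, _ in copies
            )

    def is_(sym, p):
        return place.get(sym) == p

    typ = "unclassified"
    if is_("ycf1", "spans_junction") and all(is_(s, "in_SSC") for s in ("ndhF", "ndhH", "ndhA")):
        typ = "I"
    elif all(is_(s, "in_IR") for s in ("ycf1", "ndhF", "ndhH", "ndhA")):
        typ = "II"
    elif (
        all(is_(s, "in_IR") for s in ("ycf1", "ndhH", "ndhA"))
        and place.get("ndhF") is not None
        and not is_("ndhF", "in_IR")
    ):
        typ = "III"
    elif (
        is_("ycf1", "in_IR")
        and is_("ndhH", "in_IR")
        and is_("ndhA", "in_SSC")
        and "ndhF" in strand
        # in the canonical (type I/II) arrangement ndhA and ndhF share a
        # strand; "inverted in the SSC" flips ndhA relative to ndhF
        and strand["ndhA"] != strand["ndhF"]
    ):
        typ = "IV"
    return IRTypeResult(type=typ, evidence=evidence, ycf1_overlap_bp=ycf1_overlap)


def junction_genes(record: PlastomeRecord, partition: RegionPartition) -> dict:
    """For each junction: nearest gene on each side plus any spanning gene.

    Distances are in bp from the junction point to the closest feature
    boundary; a feature ending exactly at the junction is reported at
    distance 0 on the upstream side (half-open convention), not as spanning.
    """
    L = partition.genome_len
    report = {}
    for name, j in partition.junctions().items():
        spanning = []
        up_best = None  # (distance, gene)
        down_best = None
        for f in record.features:
            covered = set()
            for a, b in f.location:
                covered.add("prev") if _covers(a, b, (j - 1) % L) else None
                covered.add("next") if _covers(a, b, j % L) else None
            if {"prev", "next"} <= covered:
                spanning.append(f.gene)
                continue
            d_up = min((j - b) % L for _, b in f.location)
            d_down = min((a - j) % L for a, _ in f.location)
            if up_best is None or d_up < up_best[0]:
                up_best = (d_up, f.gene)
            if down_best is None or d_down < down_best[0]:
                down_best = (d_down, f.gene)
        report[name] = {
            "upstream": (up_best[1], up_best[0]) if up_best else None,
            "downstream": (down_best[1], down_best[0]) if down_best else None,
            "spanning": spanning,
        }
    return report


def _covers(a: int, b: int, pos: int) -> bool:
    return a <= pos < b
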