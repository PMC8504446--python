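"""Synthetic inputs with known ground truth.

Generators for every input the pipeline consumes: Yule trees, discrete
characters evolved under the Mk equal-rates kernel or a Dollo regime
(single origin, optional reversals), and fully annotated circular
plastomes with a planted quadripartite structure, configurable IR/SSC
junction type (I-IV) and scripted pseudogenization edits. Every generator
is deterministic under its seed and returns the truth it planted.

The packaged study fixtures (state matrix, region table, tree) are
re-exported from :mod:`plastdeg.fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._model import CharacterMatrix, GeneFeature, PlastomeRecord, revcomp
from .quadripartite import Arc, RegionPartition
from .tree import Node, Tree

# re-exported fixture API
from .fixtures import (  # noqa: F401
    FIXTURE_ERRATA,
    fixture_table1,
    fixture_tree,
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_CODON_GC = np.array([sum(ch in "GC" for ch in c) for c in _SENSE_CODONS], dtype=float)


# -- trees -------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int) -> Tree:
    """Yule (pure-birth) tree on ``n_tips``, rescaled to height 1."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = Node()
    active = [root.add(Node()), root.add(Node())]
    pendant = {id(n): 0.0 for n in active}
    while True:
        dt = rng.exponential(1.0 / len(active))
        for n in active:
            pendant[id(n)] += dt
        if len(active) == n_tips:
            break
        parent = active.pop(rng.integers(len(active)))
        parent.length = pendant.pop(id(parent))
        for _ in range(2):
            child = parent.add(Node())
            active.append(child)
            pendant[id(child)] = 0.0
    for n in active:
        n.length = pendant[id(n)]
    # all tips are contemporaneous under pure birth: rescale height to 1
    height = 0.0
    n = active[0]
    while n.parent is not None:
        height += n.length
        n = n.parent
    i = 0
    for node in _descendants(root):
        node.length /= height
        if not node.children:
            i += 1
            node.name = f"t{i}"
    return Tree(root)


def _descendants(root: Node) -> list[Node]:
    out, stack = [], list(root.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


# -- discrete characters -----------------------------------------------------


def simulate_mk(
    tree: Tree, mu: float, k: int, n_chars: int, seed: int
) -> tuple[CharacterMatrix, dict[Node, np.ndarray]]:
    """Evolve characters under the equal-rates kernel; truth retained.

    The root state is uniform on ``k`` states; along a branch of length t
    the child copies the parent with probability exp(-k mu t) and is
    otherwise uniform on all k states (the mixture form of the ER kernel).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(seed)
    node_states: dict[Node, np.ndarray] = {
        tree.root: rng.integers(0, k, size=n_chars)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = tree.branch_length(node)
        keep = rng.random(n_chars) < np.exp(-k * mu * t)
        fresh = rng.integers(0, k, size=n_chars)
        node_states[node] = np.where(keep, node_states[node.parent], fresh)
    data = {n.name: node_states[n].tolist() for n in tree.leaves()}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = [f"c{i}" for i in range(n_chars)]
    return CharacterMatrix(df, alphabet=tuple(range(k))), node_states


@dataclass
class DolloTruth:
    origin: Node | None
    reversals: list[Node]


def simulate_dollo(
    tree: Tree, p_origin: float, p_reversal: float, n_chars: int, seed: int
) -> tuple[CharacterMatrix, list[DolloTruth]]:
    """Binary characters under a Dollo regime, with the true event script.

    Each character gains at most one origin (with probability ``p_origin``,
    on a branch drawn proportionally to branch length); below the origin
    every branch reverts independently with probability ``p_reversal``, and
    a reverted lineage stays ancestral.
    """
    for p in (p_origin, p_reversal):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    branches = [n for n in tree.postorder() if n.parent is not None]
    lengths = np.array([tree.branch_length(n) for n in branches], dtype=float)
    weights = lengths / lengths.sum() if lengths.sum() > 0 else np.full(len(branches), 1 / len(branches))

    tips = tree.tip_labels()
    columns = {}
    truths: list[DolloTruth] = []
    for c in range(n_chars):
        states = {n: 0 for n in tree.postorder()}
        truth = DolloTruth(origin=None, reversals=[])
        if rng.random() < p_origin:
            origin = branches[rng.choice(len(branches), p=weights)]
            truth.origin = origin
            states[origin] = 1
            for node in tree.preorder():
                if node is origin or states.get(node.parent) != 1:
                    continue
                if rng.random() < p_reversal:
                    states[node] = 0
                    truth.reversals.append(node)
                else:
                    states[node] = 1
        columns[f"c{c}"] = {n.name: states[n] for n in tree.leaves()}
        truths.append(truth)
    df = pd.DataFrame({c: pd.Series(v) for c, v in columns.items()}).loc[tips]
    return CharacterMatrix(df, alphabet=(0, 1)), truths


# -- synthetic plastomes -----------------------------------------------------


@dataclass(frozen=True)
class TemplateGene:
    symbol: str
    kind: str  # CDS | tRNA | rRNA
    length: int
    strand: str


@dataclass
class PlastomeTemplate:
    """Gene layout and composition targets for one synthetic plastome."""

    ir_type: str  # 'I' | 'II' | 'III' | 'IV'
    lsc_genes: tuple[TemplateGene, ...]
    ir_genes: tuple[TemplateGene, ...]
    ssc_genes: tuple[TemplateGene, ...]
    gc_targets: dict[str, float] = field(
        default_factory=lambda: {"LSC": 0.36, "IR": 0.43, "SSC": 0.33}
    )
    spacer_mean: int = 150
    ycf1_ir_overlap: int = 900  # type I only

    def __post_init__(self) -> None:
        if self.ir_type not in ("I", "II", "III", "IV"):
            raise ValueError(f"unknown IR type {self.ir_type!r}")
        symbols = [g.symbol for g in self.lsc_genes + self.ir_genes + self.ssc_genes]
        for landmark in ("rps19", "rpl2", "trnH-GUG", "ycf1", "ndhF", "ndhH", "ndhA"):
            if landmark not in symbols:
                raise ValueError(f"template lacks landmark gene {landmark}")


_G = TemplateGene
_LSC_CORE = (
    _G("trnH-GUG", "tRNA", 74, "+"),
    _G("psbA", "CDS", 1062, "-"),
    _G("atpA", "CDS", 1524, "+"),
    _G("rpoB", "CDS", 1500, "+"),
    _G("petA", "CDS", 963, "+"),
    _G("psaA", "CDS", 1200, "+"),
    _G("psbB", "CDS", 900, "+"),
    _G("rbcL", "CDS", 1428, "+"),
    _G("ndhC", "CDS", 363, "+"),
    _G("ndhJ", "CDS", 477, "+"),
    _G("ndhK", "CDS", 678, "+"),
    _G("clpP", "CDS", 591, "+"),
    _G("accD", "CDS", 1497, "+"),
    _G("rps16", "CDS", 261, "+"),
    _G("rps19", "CDS", 279, "+"),
)
_IR_CORE = (
    _G("rpl2", "CDS", 822, "-"),
    _G("rpl23", "CDS", 282, "-"),
    _G("ycf2", "CDS", 1500, "+"),
    _G("ndhB", "CDS", 1533, "-"),
    _G("rps7", "CDS", 468, "-"),
    _G("rrn16", "rRNA", 1491, "+"),
    _G("rrn23", "rRNA", 1800, "+"),
    _G("rrn5", "rRNA", 121, "+"),
    _G("trnN-GUU", "tRNA", 72, "-"),
)
_YCF1 = _G("ycf1", "CDS", 3000, "+")
_NDHF = _G("ndhF", "CDS", 2220, "-")
_SSC_MID = (
    _G("ccsA", "CDS", 960, "+"),
    _G("ndhD", "CDS", 1503, "-"),
    _G("ndhE", "CDS", 306, "-"),
    _G("ndhG", "CDS", 531, "-"),
    _G("ndhI", "CDS", 501, "-"),
)
_NDHA = _G("ndhA", "CDS", 1092, "-")
_NDHH = _G("ndhH", "CDS", 1182, "-")


def default_template(ir_type: str = "I", **kwargs) -> PlastomeTemplate:
    """The stock gene layout for each junction type.

    Region membership of the landmark genes follows the type's rule: type I
    keeps ycf1 on the IRb/SSC junction with ndhF/ndhH/ndhA in the SSC;
    types II-IV capture ycf1 (and II: ndhF+ndhA+ndhH; III: ndhA+ndhH;
    IV: ndhH, with ndhA strand-inverted in the SSC) into the IR.
    """
    if ir_type == "I":
        ir = _IR_CORE
        ssc = (_YCF1, _NDHF) + _SSC_MID + (_NDHA, _NDHH)
    elif ir_type == "II":
        ir = _IR_CORE + (_YCF1, _NDHF, _NDHA, _NDHH)
        ssc = _SSC_MID
    elif ir_type == "III":
        ir = _IR_CORE + (_YCF1, _NDHA, _NDHH)
        ssc = (_NDHF,) + _SSC_MID
    elif ir_type == "IV":
        ir = _IR_CORE + (_YCF1, _NDHH)
        ssc = (_NDHF,) + _SSC_MID + (replace(_NDHA, strand="+"),)
    else:
        raise ValueError(f"unknown IR type {ir_type!r}")
    return PlastomeTemplate(ir_type=ir_type, lsc_genes=_LSC_CORE, ir_genes=ir, ssc_genes=ssc, **kwargs)


@dataclass(frozen=True)
class Edit:
    """One scripted degradation edit and the state it should be called as."""

    gene: str
    op: str  # 'premature_stop' | 'truncate' | 'delete_all'
    position: float = 0.5  # fractional codon position of the planted stop
    fraction: float = 0.4  # fraction of the CDS removed by 'truncate'
    end: str = "5p"  # truncated end: '5p' | '3p'

    @property
    def expected_state(self) -> int:
        return {"premature_stop": 1, "truncate": 2, "delete_all": 3}[self.op]


@dataclass
class PlastomeTruth:
    partition: RegionPartition
    ir_type: str
    gene_states: dict[str, int]
    edits: tuple[Edit, ...]
    reference_cds: dict[str, str]  # unedited CDS per gene


def _gc_solved_weights(target: float) -> np.ndarray:
    """Codon weights over the 61 sense codons whose expected per-base GC
    equals ``target`` (stop exclusion biases a naive i.i.d. draw)."""
    lo, hi = 1e-3, 1 - 1e-3

    def expected(p: float) -> float:
        w = p ** _CODON_GC * (1 - p) ** (3 - _CODON_GC)
        return float((w * _CODON_GC).sum() / (3 * w.sum()))

    for _ in range(60):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    p = (lo + hi) / 2
    w = p ** _CODON_GC * (1 - p) ** (3 - _CODON_GC)
    return w / w.sum()


def _random_cds(length: int, weights: np.ndarray, rng) -> str:
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    n_mid = length // 3 - 2
    idx = rng.choice(len(_SENSE_CODONS), size=n_mid, p=weights)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


def _spacer_pool(total: int, gc_count: int, rng) -> list[str]:
    gc_count = int(np.clip(gc_count, 0, total))
    bases = np.empty(total, dtype="<U1")
    gc_pos = rng.choice(total, size=gc_count, replace=False) if total else []
    at = rng.choice(list("AT"), size=total)
    bases[:] = at
    if gc_count:
        bases[gc_pos] = rng.choice(list("GC"), size=gc_count)
    return bases.tolist()


def _build_region(
    genes: Sequence[TemplateGene],
    gene_seqs: dict[str, str | None],
    gc_target: float,
    spacer_mean: int,
    rng,
) -> tuple[str, list[tuple[TemplateGene, int, int]]]:
    """Assemble genes and GC-compensating spacers into one region block."""
    placed = [g for g in genes if gene_seqs.get(g.symbol) is not None]
    seqs = [gene_seqs[g.symbol] for g in placed]
    spacer_lens = [
        int(rng.integers(spacer_mean // 2, spacer_mean * 3 // 2 + 1))
        for _ in range(len(placed) + 1)
    ]
    total_spacer = sum(spacer_lens)
    region_len = total_spacer + sum(len(s) for s in seqs)
    gene_gc = sum(s.count("G") + s.count("C") for s in seqs)
    need = int(round(gc_target * region_len)) - gene_gc
    pool = _spacer_pool(total_spacer, need, rng)
    rng.shuffle(pool)

    parts: list[str] = []
    feats: list[tuple[TemplateGene, int, int]] = []
    cursor = 0
    pool_i = 0
    for i, gene in enumerate(placed):
        sp = "".join(pool[pool_i : pool_i + spacer_lens[i]])
        pool_i += spacer_lens[i]
        parts.append(sp)
        cursor += len(sp)
        seq = seqs[i]
        body = seq if gene.strand == "+" else revcomp(seq)
        parts.append(body)
        feats.append((gene, cursor, cursor + len(body)))
        cursor += len(body)
    parts.append("".join(pool[pool_i:]))
    return "".join(parts), feats


def synthesize_plastome(
    template: PlastomeTemplate,
    edit_script: Sequence[Edit] = (),
    seed: int = 0,
    record_id: str = "SYN000001",
    taxon: str = "Synthome example",
) -> tuple[PlastomeRecord, PlastomeTruth]:
    """Assemble LSC + IRb + SSC + revcomp(IRb) with scripted degradation.

    CDS are stop-free with ATG start and TAA stop; spacer composition is
    balanced so that each region hits its GC target to within rounding.
    The returned truth bundle carries the planted partition, junction type,
    per-gene expected states and the unedited reference CDS set.
    """
    rng = np.random.default_rng(seed)
    all_genes = template.lsc_genes + template.ir_genes + template.ssc_genes
    symbols = [g.symbol for g in all_genes]
    if len(symbols) != len(set(symbols)):
        raise ValueError("template assigns a gene to more than one region")
    edits_by_gene: dict[str, Edit] = {}
    for e in edit_script:
        if e.gene not in symbols:
            raise ValueError(f"edit targets unknown gene {e.gene}")
        if e.gene in edits_by_gene:
            raise ValueError(f"multiple edits for gene {e.gene}")
        edits_by_gene[e.gene] = e

    region_of = {}
    for g in template.lsc_genes:
        region_of[g.symbol] = "LSC"
    for g in template.ir_genes:
        region_of[g.symbol] = "IR"
    for g in template.ssc_genes:
        region_of[g.symbol] = "SSC"
    weights = {r: _gc_solved_weights(t) for r, t in template.gc_targets.items()}

    reference_cds: dict[str, str] = {}
    gene_seqs: dict[str, str | None] = {}
    gene_states: dict[str, int] = {}
    for g in all_genes:
        w = weights[region_of[g.symbol]]
        if g.kind == "CDS":
            seq = _random_cds(g.length, w, rng)
            reference_cds[g.symbol] = seq
            gene_states[g.symbol] = 0
        else:
            p = template.gc_targets[region_of[g.symbol]]
            seq = "".join(rng.choice(list("ACGT"), size=g.length, p=[(1 - p) / 2, p / 2, p / 2, (1 - p) / 2]))
        edit = edits_by_gene.get(g.symbol)
        if edit is not None:
            if g.kind != "CDS":
                raise ValueError(f"edits only apply to CDS genes, not {g.symbol}")
            seq = _apply_edit(seq, edit)
            gene_states[g.symbol] = edit.expected_state
        gene_seqs[g.symbol] = seq
    # type I: ycf1 rides the IRb/SSC junction; keep it first in the SSC block
    lsc_seq, lsc_feats = _build_region(
        template.lsc_genes, gene_seqs, template.gc_targets["LSC"], template.spacer_mean, rng
    )
    irb_core, irb_feats = _build_region(
        template.ir_genes, gene_seqs, template.gc_targets["IR"], template.spacer_mean, rng
    )
    ssc_block, ssc_feats = _build_region(
        template.ssc_genes, gene_seqs, template.gc_targets["SSC"], template.spacer_mean, rng
    )
    if template.ir_type == "I" and gene_seqs.get("ycf1"):
        # strip the leading spacer so ycf1 abuts (and overlaps) the junction
        lead = ssc_feats[0][1]
        ssc_block = ssc_block[lead:]
        ssc_feats = [(g, a - lead, b - lead) for g, a, b in ssc_feats]
        overlap = min(template.ycf1_ir_overlap, len(gene_seqs["ycf1"]) - 3)
    else:
        overlap = 0

    irb_seq = irb_core + ssc_block[:overlap]
    ssc_seq = ssc_block[overlap:]
    lsc_seq, ssc_seq = _break_boundary_complementarity(lsc_seq, ssc_seq)

    lsc_len, ir_len, ssc_len = len(lsc_seq), len(irb_seq), len(ssc_seq)
    irb_start = lsc_len
    ssc_start = irb_start + ir_len
    ira_start = ssc_start + ssc_len
    genome = lsc_seq + irb_seq + ssc_seq + revcomp(irb_seq)
    L = len(genome)

    features: list[GeneFeature] = []
    for g, a, b in lsc_feats:
        features.append(GeneFeature(g.symbol, g.kind, g.strand, ((a, b),)))
    for g, a, b in irb_feats:
        ga, gb = irb_start + a, irb_start + b
        features.append(GeneFeature(g.symbol, g.kind, g.strand, ((ga, gb),)))
        flip = "-" if g.strand == "+" else "+"
        irb_end = irb_start + ir_len
        features.append(
            GeneFeature(g.symbol, g.kind, flip, ((ira_start + irb_end - gb, ira_start + irb_end - ga),))
        )
    for g, a, b in ssc_feats:
        # SSC-block coordinates start at the junction minus the ycf1 overlap
        ga, gb = ssc_start - overlap + a, ssc_start - overlap + b
        features.append(GeneFeature(g.symbol, g.kind, g.strand, ((ga, gb),)))

    record = PlastomeRecord(id=record_id, taxon=taxon, sequence=genome, features=features)
    partition = RegionPartition(
        lsc=Arc(0, lsc_len),
        irb=Arc(irb_start, ir_len),
        ssc=Arc(ssc_start, ssc_len),
        ira=Arc(ira_start, ir_len),
        genome_len=L,
    )
    partition.validate(genome)
    truth = PlastomeTruth(
        partition=partition,
        ir_type=template.ir_type,
        gene_states=gene_states,
        edits=tuple(edit_script),
        reference_cds=reference_cds,
    )
    return record, truth


def _apply_edit(seq: str, edit: Edit) -> str | None:
    n_codons = len(seq) // 3
    if edit.op == "delete_all":
        return None
    if edit.op == "premature_stop":
        i = int(np.clip(int(edit.position * n_codons), 1, n_codons - 2))
        return seq[: 3 * i] + "TAA" + seq[3 * i + 3 :]
    if edit.op == "truncate":
        cut = 3 * int(round(edit.fraction * n_codons))
        if cut <= 0 or cut >= len(seq):
            raise ValueError("truncation fraction out of range")
        return seq[cut:] if edit.end == "5p" else seq[: len(seq) - cut]
    raise ValueError(f"unknown edit op {edit.op!r}")


def _break_boundary_complementarity(lsc: str, ssc: str) -> tuple[str, str]:
    """Pin spacer bases at region boundaries so maximal exact extension of
    the planted IR pair stops exactly at the designed junctions."""
    lsc = "A" + lsc[1:-1] + "A"  # genome[0] vs last LSC base: A/A never pairs
    ssc = ssc[:-1] + ssc[0]  # a base never complements itself
    return lsc, ssc
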