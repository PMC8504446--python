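"""Codon-usage and GC-content statistics (RSCU, per-group GC, deviations)."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from ._model import PlastomeRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: synonymous families (amino acid -> codons), stop codons excluded
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

CODON_TO_AA = dict(_TABLE11.forward_table)

DEFAULT_GENE_GROUPS = ("atp", "ndh", "pet", "psa", "psb", "rpl", "rps", "rpo", "clp", "ycf")


def rscu(cds_collection: Iterable[str]) -> pd.DataFrame:
    """Relative synonymous codon usage, pooled over a collection of CDS.

    RSCU(c) = count(c) * family_size / sum of counts over c's synonymous
    family. Families with zero total are reported as NaN; the single-codon
    families (Met/ATG, Trp/TGG) are fixed at 1 and flagged uninformative.
    """
    counts: dict[str, int] = {c: 0 for c in CODON_TO_AA}
    for seq in cds_collection:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"CDS length {len(seq)} not a multiple of 3: {seq[:24]}...")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:  # stop codons and ambiguous codons excluded
                counts[codon] += 1
    rows = []
    for aa, codons in sorted(FAMILIES.items()):
        fam_total = sum(counts[c] for c in codons)
        for c in sorted(codons):
            if len(codons) == 1:
                value, informative = 1.0, False
            elif fam_total == 0:
                value, informative = float("nan"), False
            else:
                value, informative = counts[c] * len(codons) / fam_total, True
            rows.append(
                {"codon": c, "aa": aa, "count": counts[c], "rscu": value, "informative": informative}
            )
    return pd.DataFrame(rows).set_index("codon")


def gc_content(sequence: str, codon_position: int | None = None) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N never counted.

    ``codon_position`` (1, 2 or 3) restricts to that position of each codon.
    """
    seq = sequence.upper()
    if codon_position is not None:
        if codon_position not in (1, 2, 3):
            raise ValueError("codon_position must be 1, 2 or 3")
        seq = seq[codon_position - 1 :: 3]
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def _group_of(gene: str, groups: Sequence[str]) -> str:
    for g in groups:
        if gene.lower().startswith(g.lower()):
            return g
    return gene  # singletons keep their own name


def gc_group_matrix(
    records: Sequence[PlastomeRecord],
    grouping: Mapping[str, str] | Sequence[str] = DEFAULT_GENE_GROUPS,
    kinds: tuple[str, ...] = ("CDS",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled GC per (sample, gene group) and its deviation from the column mean.

    ``grouping`` is either an explicit gene->group map or a list of symbol
    prefixes (genes not matching any prefix form their own single-gene
    group). Empty cells are NaN; deviations are value minus the per-group
    mean across samples, so every group's deviations average to zero.
    """
    values: dict[str, dict[str, float]] = {}
    for rec in records:
        pooled: dict[str, list[str]] = {}
        for f in rec.features:
            if f.kind not in kinds:
                continue
            group = (
                grouping.get(f.gene, f.gene)
                if isinstance(grouping, Mapping)
                else _group_of(f.gene, grouping)
            )
            pooled.setdefault(group, []).append(f.extract(rec.sequence))
        values[rec.taxon] = {
            g: gc_content("".join(seqs)) for g, seqs in pooled.items()
        }
    matrix = pd.DataFrame.from_dict(values, orient="index")
    deviations = matrix - matrix.mean(axis=0)
    return matrix, deviations
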