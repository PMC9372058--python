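"""Variant-set intersection, allele reconciliation, and panel merging.

The WGS cohort is the orientation reference: array records are matched
to it by (chrom, pos), classified by allele comparison, and re-oriented
(SWAP complements genotype counts / flips haplotype alleles).
Palindromic A/T and C/G records are dropped unconditionally because
their strand cannot be resolved without frequency heuristics, a known
false-positive source in merged GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    GenotypeMatrix,
    HaplotypePanel,
    MISSING,
    VariantTable,
)

__all__ = [
    "VariantMatch",
    "intersect_variants",
    "subset_to_matches",
    "merge_phased",
]

IDENTICAL = "IDENTICAL"
SWAP = "SWAP"
STRAND_FLIP = "STRAND_FLIP"
SWAP_AND_FLIP = "SWAP_AND_FLIP"
DROP_AMBIGUOUS = "DROP_AMBIGUOUS"
DROP_MISMATCH = "DROP_MISMATCH"

KEPT_ACTIONS = frozenset({IDENTICAL, SWAP, STRAND_FLIP, SWAP_AND_FLIP})

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantMatch:
    array_index: int
    wgs_index: int
    action: str


def _classify(ref_a: str, alt_a: str, ref_w: str, alt_w: str) -> str:
    if {ref_a, alt_a} in ({"A", "T"}, {"C", "G"}):
        return DROP_AMBIGUOUS
    if (ref_a, alt_a) == (ref_w, alt_w):
        return IDENTICAL
    if (ref_a, alt_a) == (alt_w, ref_w):
        return SWAP
    ref_c, alt_c = _COMP[ref_a], _COMP[alt_a]
    if (ref_c, alt_c) == (ref_w, alt_w):
        return STRAND_FLIP
    if (ref_c, alt_c) == (alt_w, ref_w):
        return SWAP_AND_FLIP
    return DROP_MISMATCH


def intersect_variants(
    array_table: VariantTable, wgs_table: VariantTable
) -> tuple[list[VariantMatch], float]:
    """Match variants by (chrom, pos) and classify allele agreement.

    Returns every positional match with its action plus the overlap
    rate = kept matches / array variant count.
    """
    def pos_map(table: VariantTable) -> dict:
        d = {}
        for j, (c, p) in enumerate(zip(table.df["chrom"], table.df["pos"])):
            key = (c, int(p))
            if key in d:
                raise FormatError(f"duplicate position {key} prevents matching")
            d[key] = j
        return d

    a_map = pos_map(array_table)
    w_map = pos_map(wgs_table)
    matches = []
    a_df = array_table.df
    w_df = wgs_table.df
    for key, aj in a_map.items():
        wj = w_map.get(key)
        if wj is None:
            continue
        action = _classify(
            a_df["ref"].iat[aj], a_df["alt"].iat[aj],
            w_df["ref"].iat[wj], w_df["alt"].iat[wj],
        )
        matches.append(VariantMatch(aj, wj, action))
    kept = sum(1 for m in matches if m.action in KEPT_ACTIONS)
    overlap_rate = kept / len(array_table) if len(array_table) else 0.0
    return matches, overlap_rate


def subset_to_matches(
    data: GenotypeMatrix | HaplotypePanel,
    matches: list[VariantMatch],
    side: str,
    wgs_table: VariantTable,
) -> GenotypeMatrix | HaplotypePanel:
    """Restrict to kept matches and re-orient to the WGS convention.

    ``side`` is "array" or "wgs".  For the array side, SWAP-class
    variants have genotypes complemented (g -> 2-g) or haplotype
    alleles flipped; output variant tables are identical across sides.
    """
    kept = [m for m in matches if m.action in KEPT_ACTIONS]
    kept.sort(key=lambda m: m.wgs_index)
    if side == "array":
        idx = np.asarray([m.array_index for m in kept], dtype=int)
    elif side == "wgs":
        idx = np.asarray([m.wgs_index for m in kept], dtype=int)
    else:
        raise ValueError("side must be 'array' or 'wgs'")
    swap = np.asarray([m.action in (SWAP, SWAP_AND_FLIP) for m in kept])
    table = wgs_table.subset(np.asarray([m.wgs_index for m in kept], dtype=int))

    if isinstance(data, GenotypeMatrix):
        values = data.values[:, idx].copy()
        if side == "array" and swap.any():
            cols = values[:, swap]
            obs = cols != MISSING
            values[:, swap] = np.where(obs, 2 - cols, MISSING)
        return GenotypeMatrix(table, list(data.sample_ids), data.platform, values)
    haps = data.haplotypes[:, idx].copy()
    if side == "array" and swap.any():
        haps[:, swap] = 1 - haps[:, swap]
    return HaplotypePanel(table, list(data.sample_ids), data.platform, haps)


def merge_phased(
    panel_array: HaplotypePanel, panel_wgs: HaplotypePanel
) -> HaplotypePanel:
    """Concatenate two phased panels over an identical variant set.

    Order: array samples then WGS samples; platform labels preserved.
    """
    if not panel_array.variants.equals(panel_wgs.variants):
        a, b = panel_array.variants.keys, panel_wgs.variants.keys
        first = None
        for x, y in zip(a, b):
            if x != y:
                first = (x, y)
                break
        if first is None:
            first = ("length", (len(a), len(b)))
        raise FormatError(f"variant tables differ; first discrepancy: {first}")
    dup = set(panel_array.sample_ids) & set(panel_wgs.sample_ids)
    if dup:
        raise FormatError(f"duplicate sample IDs across panels: {sorted(dup)[:5]}")
    return HaplotypePanel(
        panel_array.variants,
        list(panel_array.sample_ids) + list(panel_wgs.sample_ids),
        np.concatenate([panel_array.platform, panel_wgs.platform]),
        np.vstack([panel_array.haplotypes, panel_wgs.haplotypes]),
    )


def match_report(matches: list[VariantMatch], array_table: VariantTable) -> pd.DataFrame:
    """TSV-ready table of (chrom, pos, action) for every match."""
    df = array_table.df
    rows = [
        {
            "chrom": df["chrom"].iat[m.array_index],
            "pos": int(df["pos"].iat[m.array_index]),
            "action": m.action,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "action"])
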