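"""Multi-evidence priority score (PS) for resistance-associated variants.

Each candidate somatic alteration is scored on five 0-100 components and PS
is their mean:

* AS — alternative allele frequency x 100;
* DS — mean of three deleteriousness predictions (CADD, SIFT, PROVEAN),
  each orientation-normalized and min-max scaled to 0-100 over the
  candidate set; frameshift deletions, stop gains and splicing variants are
  unscorable by the tools and receive the maximum (100); other unscored
  variants receive the median of the scaled, tool-scored values;
* CS — CRISPR resistance-screen functional score (gene log2 fold change,
  scaled 0-100, positive = enriched under drug);
* GS — 100 iff the gene appears in a clinical resistance gene list;
* MS — 100 iff the specific mutation appears in the clinical list.

Variants in genes that are not expressed (FPKM < 0.1 in every sample) are
likely passengers and score 0 outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_SCORE_TYPES = frozenset({"frameshift_deletion", "stop_gain", "splicing"})

HIGHER_IS_DELETERIOUS = "higher_is_deleterious"
LOWER_IS_DELETERIOUS = "lower_is_deleterious"


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    gene: str
    mutation_type: str = "missense"
    allele_frequency: float = 0.0
    cadd_raw: float | None = None
    sift_raw: float | None = None
    provean_raw: float | None = None
    crispr_lfc: float | None = None
    in_clinical_gene_list: bool = False
    in_clinical_mutation_list: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele_frequency must be in [0, 1]")
        if self.in_clinical_mutation_list and not self.in_clinical_gene_list:
            raise ValueError(
                "a clinically listed mutation implies a clinically listed gene"
            )


def expression_filter(
    fpkm_table: pd.DataFrame, threshold: float = 0.1
) -> dict[str, bool]:
    """Gene -> expressed flag: expressed iff FPKM >= threshold in at least
    one sample (rows are genes, columns samples)."""
    if (fpkm_table.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return {
        gene: bool((fpkm_table.loc[gene] >= threshold).any())
        for gene in fpkm_table.index
    }


def scale_component(
    values: pd.Series,
    orientation: str = HIGHER_IS_DELETERIOUS,
    mutation_types: pd.Series | None = None,
) -> pd.Series:
    """Min-max scale raw tool scores to 0-100 over the candidate set.

    ``values`` may contain NaN for unscorable variants.  After sign-flipping
    when lower raw scores mean more deleterious, scored values map linearly
    onto [0, 100].  Missing values are imputed: variant types in
    ``MAX_SCORE_TYPES`` get 100, anything else gets the median of the
    scaled, tool-scored values (the median is fixed before imputation).
    """
    if orientation not in (HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS):
        raise ValueError(f"unknown orientation {orientation!r}")
    v = values.astype(float)
    if orientation == LOWER_IS_DELETERIOUS:
        v = -v
    scored = v.dropna()
    if scored.empty:
        raise ValueError("no numerically scored candidate")
    lo, hi = scored.min(), scored.max()
    if hi == lo:
        warnings.warn("degenerate score spread: all scored values set to 50")
        scaled = pd.Series(np.where(v.notna(), 50.0, np.nan), index=v.index)
    else:
        scaled = (v - lo) / (hi - lo) * 100.0
    median = float(scaled.dropna().median())
    out = scaled.copy()
    if mutation_types is not None:
        force_max = mutation_types.isin(MAX_SCORE_TYPES) & out.isna()
        out[force_max] = 100.0
    out = out.fillna(median)
    return out


@dataclass(frozen=True)
class ScoreBreakdown:
    variant_id: str
    AS: float
    DS: float
    CS: float
    GS: float
    MS: float
    PS: float
    expressed: bool


def priority_score(
    record: VariantRecord,
    expressed: bool,
    ds_scaled: float,
    cs_scaled: float,
) -> ScoreBreakdown:
    """PS for one variant from its scaled components.

    AS = allele_frequency x 100; GS/MS from the clinical flags; PS is the
    mean of the five components, zeroed when the gene is not expressed.
    """
    AS = record.allele_frequency * 100.0
    GS = 100.0 if record.in_clinical_gene_list else 0.0
    MS = 100.0 if record.in_clinical_mutation_list else 0.0
    if expressed:
        PS = (AS + ds_scaled + cs_scaled + GS + MS) / 5.0
    else:
        PS = 0.0
    return ScoreBreakdown(record.variant_id, AS, ds_scaled, cs_scaled, GS, MS,
                          PS, expressed)


def rank_variants(
    records: list[VariantRecord],
    fpkm_table: pd.DataFrame,
    expression_threshold: float = 0.1,
    cadd_orientation: str = HIGHER_IS_DELETERIOUS,
    sift_orientation: str = LOWER_IS_DELETERIOUS,
    provean_orientation: str = LOWER_IS_DELETERIOUS,
    cs_orientation: str = HIGHER_IS_DELETERIOUS,
) -> pd.DataFrame:
    """Score a candidate set and return the ranked table.

    Sorted by PS descending with ties broken by DS, then AS, then
    variant_id.  Genes absent from the FPKM table are treated as not
    expressed with a warning.
    """
    if not records:
        raise ValueError("no variant records")
    flags = expression_filter(fpkm_table, expression_threshold)
    missing = sorted({r.gene for r in records} - set(flags))
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from FPKM table treated as "
            f"not expressed: {', '.join(missing[:5])}"
        )
    idx = pd.Index([r.variant_id for r in records], name="variant_id")
    mtypes = pd.Series([r.mutation_type for r in records], index=idx)
    tool_scaled = {}
    for col, raw, orient in (
        ("cadd", [r.cadd_raw for r in records], cadd_orientation),
        ("sift", [r.sift_raw for r in records], sift_orientation),
        ("provean", [r.provean_raw for r in records], provean_orientation),
    ):
        tool_scaled[col] = scale_component(
            pd.Series(raw, index=idx, dtype=float), orient, mtypes
        )
    ds = (tool_scaled["cadd"] + tool_scaled["sift"] + tool_scaled["provean"]) / 3.0
    cs = scale_component(
        pd.Series([r.crispr_lfc for r in records], index=idx, dtype=float),
        cs_orientation,
        mtypes,
    )
    rows = []
    for r in records:
        br = priority_score(
            r,
            expressed=flags.get(r.gene, False),
            ds_scaled=float(ds[r.variant_id]),
            cs_scaled=float(cs[r.variant_id]),
        )
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene": r.gene,
                "mutation_type": r.mutation_type,
                "expressed": br.expressed,
                "AS": br.AS,
                "DS": br.DS,
                "CS": br.CS,
                "GS": br.GS,
                "MS": br.MS,
                "PS": br.PS,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["PS", "DS", "AS", "variant_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def load_variants(
    variants_tsv,
    gene_list: set[str] | None = None,
    mutation_list: set[str] | None = None,
) -> list[VariantRecord]:
    """Variant records from a TSV with VariantRecord column names; clinical
    membership may come from the flag columns or from explicit lists keyed
    by gene and variant_id."""
    df = pd.read_csv(variants_tsv, sep="\t")
    records = []
    for _, row in df.iterrows():
        in_gene = bool(row.get("in_clinical_gene_list", False))
        in_mut = bool(row.get("in_clinical_mutation_list", False))
        if gene_list is not None:
            in_gene = in_gene or row["gene"] in gene_list
        if mutation_list is not None:
            in_mut = in_mut or row["variant_id"] in mutation_list
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                mutation_type=str(row.get("mutation_type", "missense")),
                allele_frequency=float(row["allele_frequency"]),
                cadd_raw=_opt(row, "cadd_raw"),
                sift_raw=_opt(row, "sift_raw"),
                provean_raw=_opt(row, "provean_raw"),
                crispr_lfc=_opt(row, "crispr_lfc"),
                in_clinical_gene_list=in_gene or in_mut,
                in_clinical_mutation_list=in_mut,
            )
        )
    return records


def _opt(row, col) -> float | None:
    val = row.get(col)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return float(val)
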