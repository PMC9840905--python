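"""Gene-level variant filtering and susceptibility screening.

Whole-exome variant calls arrive as a long-form table: one row per
(sample, variant) with the harbouring gene, a 5-level pathogenicity category
(3 = uncertain significance, 4 = likely pathogenic, 5 = pathogenic) and the
variant type (SNV or INDEL).  A sample *carries* a gene when it harbours at
least one qualifying variant there — presence, not dosage.  The
susceptibility screen compares per-gene carrier fractions between the
sepsis (S) and non-sepsis (NS) burn groups and selects genes whose absolute
difference exceeds a threshold (default 18%, strict).
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigError, SeptimarkError, ValidationError
from .matrix import samples_in_group

VARIANT_COLUMNS = ("sample_id", "gene", "variant_id", "category", "variant_type")
VARIANT_TYPES = ("SNV", "INDEL")


def validate_variants(records: pd.DataFrame) -> pd.DataFrame:
    """Check the variant table invariants; returns a typed copy."""
    for col in VARIANT_COLUMNS:
        if col not in records.columns:
            raise ValidationError(f"variant table lacks required column {col!r}")
    records = records.copy()
    for col in ("sample_id", "gene", "variant_id", "variant_type"):
        records[col] = records[col].astype(str)
    records["category"] = records["category"].astype(int)
    bad = records.loc[~records["category"].isin(range(1, 6))]
    if not bad.empty:
        offender = bad.iloc[0]
        raise ValidationError(
            f"variant {offender['variant_id']!r} of sample {offender['sample_id']!r} "
            f"has category {offender['category']} outside 1..5")
    bad = records.loc[~records["variant_type"].isin(VARIANT_TYPES)]
    if not bad.empty:
        raise ValidationError(
            f"unknown variant types: {sorted(bad['variant_type'].unique())}")
    dup = records.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        offender = records.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (sample_id, variant_id): ({offender['sample_id']!r}, "
            f"{offender['variant_id']!r})")
    return records


def load_variants(path) -> pd.DataFrame:
    return validate_variants(pd.read_csv(path, sep="\t"))


def save_variants(records: pd.DataFrame, path) -> None:
    validate_variants(records).to_csv(path, sep="\t", index=False)


def filter_by_category(records: pd.DataFrame, min_category: int) -> pd.DataFrame:
    """Keep variants of pathogenicity category >= ``min_category`` (3 or 4).

    Order is stable; input categories outside 1..5 raise a validation error
    naming the record.
    """
    if min_category not in (3, 4):
        raise ConfigError(f"min_category must be 3 or 4, got {min_category}")
    records = validate_variants(records)
    return records.loc[records["category"] >= min_category].reset_index(drop=True)


def gene_carrier_frequency(records: pd.DataFrame, samples: pd.DataFrame,
                           group: str, day: int = 0) -> pd.Series:
    """Fraction of a group's samples carrying >=1 record per gene.

    Genomic carrier status is a subject-level property, so the denominator
    is the group's enrollment (day-0 by default) sample set — follow-up
    plasma samples of the same subjects do not inflate it.  Every gene
    appearing anywhere in ``records`` gets an entry; a gene carried by no
    sample of the group maps to 0.0.
    """
    group_ids = samples_in_group(samples, group, day)
    if not group_ids:
        raise SeptimarkError(f"group {group!r} has no samples")
    records = validate_variants(records)
    unknown = sorted(set(records["sample_id"]) - set(samples["sample_id"].astype(str)))
    if unknown:
        raise ValidationError(f"variant records reference unknown samples: {unknown}")
    genes = sorted(records["gene"].unique())
    in_group = records.loc[records["sample_id"].isin(group_ids)]
    carriers = in_group.groupby("gene")["sample_id"].nunique()
    freq = carriers.reindex(genes, fill_value=0).astype(float) / len(group_ids)
    freq.name = f"freq_{group}"
    return freq


def susceptibility_screen(
    records: pd.DataFrame,
    samples: pd.DataFrame,
    min_category: int = 3,
    delta_threshold: float = 0.18,
) -> pd.DataFrame:
    """Between-group carrier-frequency screen over category-filtered variants.

    Returns one row per gene surviving the category filter with carrier
    fractions in S and NS, their difference ``delta = freq_S - freq_NS``, and
    ``selected`` = |delta| strictly above the threshold.  Sorted by |delta|
    descending, ties broken by gene symbol ascending.
    """
    if not 0 < delta_threshold < 1:
        raise ConfigError(f"delta_threshold must lie in (0, 1), got {delta_threshold}")
    qualifying = filter_by_category(records, min_category)
    freq_s = gene_carrier_frequency(qualifying, samples, "S") if not qualifying.empty else pd.Series(dtype=float)
    freq_ns = gene_carrier_frequency(qualifying, samples, "NS") if not qualifying.empty else pd.Series(dtype=float)
    out = pd.DataFrame({
        "gene": freq_s.index,
        "freq_S": freq_s.to_numpy(),
        "freq_NS": freq_ns.to_numpy(),
    })
    out["delta"] = out["freq_S"] - out["freq_NS"]
    out["selected"] = out["delta"].abs() > delta_threshold
    out = out.sort_values("gene", kind="mergesort")
    out = out.sort_values("delta", key=lambda s: s.abs(), ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
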