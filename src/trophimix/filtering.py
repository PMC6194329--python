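"""Quality filtering of metabarcoding hit tables and collapse to prey lists.

Consumes BLAST-outfmt-6-style tables of taxonomic assignments (one row
per contig per stomach library, with a read count). Three quality rules
remove likely off-target or artefactual assignments:

1. read share: a hit's reads must be at least ``min_read_fraction`` of
   its stomach library's total reads (default 0.1%);
2. identity: pairwise identity to the database match must be at least
   ``min_identity`` (default 98%);
3. length: fragment length must lie within ``length_tolerance``
   (default 10%) of the expected amplicon length (default 313 bp).

Rejection thresholds are strict inequalities in the original
description ("<0.1%", "<98%", "outside a 10% range"), so a value
exactly at a threshold is KEPT.

Surviving hits are deduplicated within each stomach at species rank —
one prey item per distinct species per stomach — then rolled up to the
requested rank (family by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from trophimix.diet import DEFAULT_TAXONOMY, SCARINAE_CATEGORY, UNKNOWN_CATEGORY


@dataclass(frozen=True)
class FilterParams:
    """Hit-table quality-filter thresholds (kept-iff-at-or-beyond)."""

    min_read_fraction: float = 0.001
    min_identity: float = 98.0
    expected_length: float = 313.0
    length_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_read_fraction < 1.0:
            raise ValueError("min_read_fraction must be in [0, 1)")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if self.expected_length <= 0:
            raise ValueError("expected_length must be > 0")
        if not 0.0 <= self.length_tolerance < 1.0:
            raise ValueError("length_tolerance must be in [0, 1)")

    @property
    def length_window(self) -> tuple[float, float]:
        lo = self.expected_length * (1.0 - self.length_tolerance)
        hi = self.expected_length * (1.0 + self.length_tolerance)
        return lo, hi


def filter_hits(
    hits: pd.DataFrame, params: FilterParams = FilterParams()
) -> tuple[pd.DataFrame, dict]:
    """Apply the three quality rules; return kept hits and a rejection report.

    The read-share denominator is the stomach library's total reads
    *before* filtering. A hit failing several rules is counted once per
    rule in the report. Raises if any stomach's total reads is zero.
    """
    required = {"stomach_id", "pairwise_identity", "fragment_length", "read_count"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    totals = hits.groupby("stomach_id")["read_count"].transform("sum")
    zero = hits.loc[totals <= 0, "stomach_id"].unique()
    if len(zero):
        raise ValueError(f"stomach(s) with zero total reads: {sorted(map(str, zero))}")

    frac_ok = hits["read_count"] / totals >= params.min_read_fraction
    ident_ok = hits["pairwise_identity"] >= params.min_identity
    lo, hi = params.length_window
    len_ok = hits["fragment_length"].between(lo, hi, inclusive="both")

    keep = frac_ok & ident_ok & len_ok
    report = {
        "n_input": int(len(hits)),
        "n_kept": int(keep.sum()),
        "rejected_low_read_fraction": int((~frac_ok).sum()),
        "rejected_low_identity": int((~ident_ok).sum()),
        "rejected_length_out_of_range": int((~len_ok).sum()),
        "params": {
            "min_read_fraction": params.min_read_fraction,
            "min_identity": params.min_identity,
            "expected_length": params.expected_length,
            "length_tolerance": params.length_tolerance,
        },
    }
    return hits[keep].copy(), report


def _resolve_family(
    taxon: str, taxonomy: Mapping[str, tuple[str, str | None]], labridae_split: bool
) -> str:
    if taxon in taxonomy:
        family, sub = taxonomy[taxon]
    elif "::" in taxon:
        family, sub = taxon.split("::", 1)[0], None
        if family == SCARINAE_CATEGORY:
            family, sub = "Labridae", "Scarinae"
    else:
        return UNKNOWN_CATEGORY
    if labridae_split and family == "Labridae" and sub == "Scarinae":
        return SCARINAE_CATEGORY
    return family


def hits_to_prey(
    kept: pd.DataFrame,
    rank: str = "family",
    taxonomy: Mapping[str, tuple[str, str | None]] | None = None,
    labridae_split: bool = True,
    all_stomach_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse kept hits to DNA prey records and a pooled composition.

    One prey item = one distinct species (the ``assigned_taxon`` label)
    per stomach: contigs assigned to the same species within a stomach
    are deduplicated before rolling up to ``rank``. Taxa not resolvable
    to the rank go to ``"Unknown"`` and are listed in
    ``records.attrs['unknown_taxa']``.

    When ``all_stomach_ids`` is given, stomachs without any kept hit are
    counted in ``records.attrs['stomachs_without_prey']``.
    """
    if rank not in ("family", "species"):
        raise ValueError(f"unsupported rank {rank!r}")
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    dedup = kept.drop_duplicates(subset=["stomach_id", "assigned_taxon"])
    rows = []
    unknown: set[str] = set()
    for _, h in dedup.iterrows():
        taxon = str(h["assigned_taxon"])
        family = _resolve_family(taxon, taxonomy, labridae_split)
        if family == UNKNOWN_CATEGORY:
            unknown.add(taxon)
        rows.append(
            {
                "stomach_id": h["stomach_id"],
                "predator_group": h.get("predator_group", pd.NA),
                "prey_taxon": taxon,
                "prey_category": family if rank == "family" else taxon,
                "digestion_level": pd.NA,
                "weight": np.nan,
                "method": "dna",
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "stomach_id",
            "predator_group",
            "prey_taxon",
            "prey_category",
            "digestion_level",
            "weight",
            "method",
        ],
    )
    records.attrs["unknown_taxa"] = sorted(unknown)
    if all_stomach_ids is not None:
        with_prey = set(records["stomach_id"])
        records.attrs["stomachs_without_prey"] = sorted(
            str(s) for s in all_stomach_ids if s not in with_prey
        )
        records.attrs["n_stomachs_sampled"] = len(all_stomach_ids)
        records.attrs["n_stomachs_with_prey"] = len(with_prey)
    known = records[records["prey_category"] != UNKNOWN_CATEGORY]
    if known.empty:
        composition = pd.Series(dtype=float, name="proportion")
    else:
        counts = known.groupby("prey_category").size().astype(float)
        composition = (counts / counts.sum()).sort_values(ascending=False)
        composition.name = "proportion"
    return records, composition
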