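"""Dietary indices and prey-accumulation curves from stomach contents.

Prey records (visual or DNA) are grouped to family-level categories and
summarised with the classic stomach-content indices:

* %N_i — percent prey contribution by item count,
* %O_i — frequency of occurrence across stomachs with identifiable prey,
* %W_i — percent wet weight (fresh items only, digestion level <= 2),
* %IRI_i — index of relative importance, IRI_i = (%N_i + %W_i) * %O_i,
  normalised to sum to 100.

Sampling adequacy is diagnosed with prey accumulation curves: the mean
cumulative number of distinct prey families over random stomach
orderings, plus the slope of the final stretch as an asymptote check.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

UNKNOWN_CATEGORY = "Unknown"

#: minimal species/genus -> (family, subfamily) lookup for real taxa;
#: synthetic taxa encode their family as "<Family>::spNN" and are parsed.
DEFAULT_TAXONOMY: Mapping[str, tuple[str, str | None]] = {
    "Pterocaesio digramma": ("Caesionidae", None),
    "Caesio cuning": ("Caesionidae", None),
    "Neopomacentrus azysron": ("Pomacentridae", None),
    "Acanthochromis polyacanthus": ("Pomacentridae", None),
    "Pomacentrus trichrourus": ("Pomacentridae", None),
    "Thalassoma lunare": ("Labridae", None),
    "Choerodon fasciatus": ("Labridae", None),
    "Scarus ghobban": ("Labridae", "Scarinae"),
    "Chlorurus microrhinos": ("Labridae", "Scarinae"),
    "Ctenochaetus striatus": ("Acanthuridae", None),
    "Epinephelus quoyanus": ("Serranidae", None),
    "Siganus doliatus": ("Siganidae", None),
    "Gobiodon okinawae": ("Gobiidae", None),
    "Ostorhinchus doederleini": ("Apogonidae", None),
    "Lethrinus atkinsoni": ("Lethrinidae", None),
    "Lutjanus carponotatus": ("Lutjanidae", None),
    "Alpheus sp.": ("Crustacea", None),
    "Penaeus sp.": ("Crustacea", None),
}

SCARINAE_CATEGORY = "Labridae (Scarinae)"


def group_to_category(
    records: pd.DataFrame,
    taxonomy: Mapping[str, tuple[str, str | None]] | None = None,
    labridae_split: bool = True,
) -> pd.DataFrame:
    """Assign the family-level ``prey_category`` for each prey record.

    Labridae is optionally subdivided into parrotfishes (Scarinae,
    herbivores/detritivores) and all other, mostly predatory, labrids —
    the two feeding modes warrant separate diet categories.

    Taxa with no family mapping are routed to ``"Unknown"`` and listed
    in ``result.attrs['unknown_taxa']``.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    out = records.copy()
    unknown: list[str] = []

    def resolve(taxon) -> str:
        if pd.isna(taxon):
            return UNKNOWN_CATEGORY
        taxon = str(taxon)
        if taxon in taxonomy:
            family, sub = taxonomy[taxon]
        elif "::" in taxon:  # synthetic label "<Family>::spNN"
            family, sub = taxon.split("::", 1)[0], None
            if family == SCARINAE_CATEGORY:
                family, sub = "Labridae", "Scarinae"
        else:
            unknown.append(taxon)
            return UNKNOWN_CATEGORY
        if labridae_split and family == "Labridae" and sub == "Scarinae":
            return SCARINAE_CATEGORY
        return family

    out["prey_category"] = out["prey_taxon"].map(resolve)
    out.attrs["unknown_taxa"] = sorted(set(unknown))
    return out


def _identifiable(records: pd.DataFrame) -> pd.DataFrame:
    cat = records["prey_category"]
    return records[cat.notna() & (cat != UNKNOWN_CATEGORY)]


def compute_indices(records: pd.DataFrame, weight_digestion_max: int = 2) -> pd.DataFrame:
    """Compute %N, %O, %W and %IRI per prey category.

    %N uses item counts; %O uses, as its base, the number of stomachs
    containing at least one identifiable prey item; %W uses wet weight
    of fresh items only (digestion level <= ``weight_digestion_max``,
    weight present); IRI_i = (%N_i + %W_i) * %O_i, reported normalised.
    Prey weight is not adjusted for partial digestion.

    Returns a DataFrame indexed by category (descending %N, ties
    alphabetical) with columns ``percent_N/percent_O/percent_W/
    percent_IRI``; bases in ``attrs`` (``n_items``, ``n_stomachs``,
    ``total_weight``, ``unweighed_categories``). If no record carries a
    usable weight, %W and %IRI are NaN and a warning is issued.
    """
    ident = _identifiable(records)
    if ident.empty:
        raise ValueError("no identifiable prey records")
    n_items = ident.groupby("prey_category").size()
    pct_n = 100.0 * n_items / n_items.sum()
    occ = ident.groupby("prey_category")["stomach_id"].nunique()
    n_stomachs = ident["stomach_id"].nunique()
    pct_o = 100.0 * occ / n_stomachs

    weighable = ident[
        (ident["digestion_level"] <= weight_digestion_max) & ident["weight"].notna()
    ]
    out = pd.DataFrame({"percent_N": pct_n, "percent_O": pct_o})
    total_weight = float(weighable["weight"].sum()) if not weighable.empty else 0.0
    if weighable.empty:
        warnings.warn(
            "no records with digestion level <= "
            f"{weight_digestion_max} and a recorded weight; %W and %IRI unavailable",
            stacklevel=2,
        )
        out["percent_W"] = np.nan
        out["percent_IRI"] = np.nan
        unweighed = list(out.index)
    else:
        w = weighable.groupby("prey_category")["weight"].sum()
        pct_w = (100.0 * w / w.sum()).reindex(out.index).fillna(0.0)
        out["percent_W"] = pct_w
        iri = (out["percent_N"] + out["percent_W"]) * out["percent_O"]
        out["percent_IRI"] = 100.0 * iri / iri.sum()
        unweighed = sorted(out.index[pct_w == 0.0])

    order = (
        out.assign(_name=out.index.astype(str))
        .sort_values(["percent_N", "_name"], ascending=[False, True])
        .index
    )
    out = out.loc[order]
    out.attrs.update(
        n_items=int(n_items.sum()),
        n_stomachs_with_identifiable_prey=int(n_stomachs),
        total_weight=total_weight,
        unweighed_categories=unweighed,
    )
    return out


def composition_from_counts(
    data: pd.DataFrame | pd.Series | Mapping[str, float],
    lump_threshold: float | None = None,
    others_label: str = "Others",
) -> pd.Series:
    """Diet composition (proportions on the simplex) from records or counts.

    Accepts a prey-record table or a category -> count mapping. With
    ``lump_threshold`` (a proportion, e.g. 0.05), categories whose share
    falls below it are merged into ``"Others"``; the total is conserved.
    """
    if isinstance(data, pd.DataFrame):
        ident = _identifiable(data)
        if ident.empty:
            raise ValueError("no identifiable prey records")
        counts = ident.groupby("prey_category").size().astype(float)
    else:
        counts = pd.Series(data, dtype=float)
        if counts.empty or counts.sum() <= 0:
            raise ValueError("counts are empty or sum to zero")
    props = counts / counts.sum()
    if lump_threshold is not None:
        small = props[props < lump_threshold]
        if not small.empty:
            props = props[props >= lump_threshold]
            props.loc[others_label] = props.get(others_label, 0.0) + small.sum()
    props = props.sort_values(ascending=False, kind="mergesort")
    props.name = "proportion"
    return props


def presence_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Stomach x category presence/absence matrix from prey records."""
    ident = _identifiable(records)
    return pd.crosstab(ident["stomach_id"], ident["prey_category"]).clip(upper=1)


def accumulation_curve(
    presence: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Prey accumulation curve over random stomach orderings.

    For each k = 1..n, the mean (and SD) over ``n_permutations`` random
    stomach orderings of the number of distinct prey families seen in
    the first k stomachs — the random-order species accumulation curve
    used to judge whether sampling approached an asymptote.

    Returns a DataFrame (``k``, ``mean_new_taxa``, ``sd``) with
    ``attrs['final_slope']``: the least-squares slope of the last 20%
    of the mean curve (near zero once the curve has flattened), plus
    ``attrs['n_permutations']`` and ``attrs['seed']``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    mat = np.asarray(presence, dtype=bool)
    n = mat.shape[0]
    if n == 0:
        raise ValueError("presence matrix has no stomachs")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n), dtype=float)
    for b in range(n_permutations):
        order = rng.permutation(n)
        seen = np.cumsum(mat[order], axis=0) > 0
        curves[b] = seen.sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=0)
    out = pd.DataFrame({"k": np.arange(1, n + 1), "mean_new_taxa": mean, "sd": sd})
    tail = max(2, int(np.ceil(0.2 * n)))
    ks = out["k"].to_numpy()[-tail:]
    ys = mean[-tail:]
    slope = float(np.polyfit(ks, ys, 1)[0]) if len(ks) > 1 else 0.0
    out.attrs.update(final_slope=slope, n_permutations=n_permutations, seed=seed)
    return out
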